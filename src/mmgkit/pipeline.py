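"""End-to-end pipeline: simulate -> stage 1 -> stage 2 -> expression -> evaluate.

One :func:`run_pipeline` call produces the full artifact set in an output
directory, deterministically under a fixed seed: the synthetic
genome/annotation, per-sample stage-1 counts and fate files, the multi-map
group matrix (raw, filtered, collapsed), FPKM/FPM tables, rescue statistics
and the evaluation report, plus a machine-readable echo of the configuration.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import expression
from .annotation import build_gene_models, build_index
from .counting import CountingMode, Stage1Result, Strandedness, count_stage1, write_fates
from .evaluate import classify_genes, correlate, corr_distance
from .formats import write_count_table
from .groups import MmgFilterParams, collapse_mmgs, count_mmgs, filter_mmgs, rescue_stats
from .simulate import (
    SimDesign,
    TruthAligner,
    generate_transcriptome,
    simulate_reads,
    write_simulation,
)

log = logging.getLogger("mmgkit")

__all__ = ["RunConfig", "PipelineError", "run_pipeline"]

_SEED_MOD = 2**31


class PipelineError(RuntimeError):
    """A stage failure; the message names the stage."""


@dataclass(frozen=True)
class RunConfig:
    """Configuration of one end-to-end run."""

    design: SimDesign
    n_samples: int = 3
    mode: CountingMode = CountingMode.UNION
    stranded: Strandedness = Strandedness.NO
    min_reads: int = 100
    min_samples: int = 2
    collapse_min_size: int = 5
    low_threshold: float = 100.0
    high_threshold: float = 1900.0
    out_dir: str = "mmgkit_run"
    write_reads: bool = True

    def validate(self) -> None:
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")
        if self.min_samples > self.n_samples:
            raise ValueError(
                f"min_samples={self.min_samples} exceeds n_samples={self.n_samples}"
            )

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        d["mode"] = self.mode.value
        d["stranded"] = self.stranded.value
        return json.dumps(d, indent=2, default=list)


def _sample_seed(base: int, i: int) -> int:
    return (base * 1_000_003 + 7_919 * (i + 1) + 1) % _SEED_MOD


def run_pipeline(config: RunConfig) -> dict:
    """Run the whole two-stage analysis; returns a summary dict.

    Raises :class:`PipelineError` naming the failing stage. Identical config
    (including the seed) gives byte-identical TSV outputs.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "run_config.json").write_text(config.to_json() + "\n")
    design = config.design
    timings: dict[str, float] = {}

    def stage(name):
        class _Timer:
            def __enter__(self):
                self.t0 = time.perf_counter()
                log.info("stage %s: start", name)
                return self

            def __exit__(self, exc_type, exc, tb):
                timings[name] = time.perf_counter() - self.t0
                if exc is not None:
                    (out / "FAILED").write_text(f"stage {name} failed: {exc}\n")
                    raise PipelineError(f"stage {name} failed: {exc}") from exc
                log.info("stage %s: %.2fs", name, timings[name])

        return _Timer()

    with stage("simulate"):
        transcriptome = generate_transcriptome(design)
        aligner = TruthAligner(transcriptome, design.read_len, design.insert_len)
        samples = [f"sample{i + 1}" for i in range(config.n_samples)]
        reads = {}
        truths = {}
        for i, sample in enumerate(samples):
            pairs, truth = simulate_reads(
                transcriptome, design, seed=_sample_seed(design.seed, i)
            )
            reads[sample] = pairs
            truths[sample] = truth
        if config.write_reads:
            write_simulation(
                transcriptome, reads[samples[0]], truths[samples[0]],
                None, out / "sim",
            )

    with stage("count"):
        gene_ids = transcriptome.gene_ids
        index = build_index(build_gene_models(transcriptome.annotation))
        stage1: dict[str, Stage1Result] = {}
        for sample in samples:
            fragments = aligner.align(reads[sample])
            stage1[sample] = count_stage1(
                fragments, config.mode, index, stranded=config.stranded
            )
            write_fates(stage1[sample].fates, out / f"fates_{sample}.tsv")
        counts = pd.DataFrame(
            {s: stage1[s].counts_series(gene_ids) for s in samples}
        )
        write_count_table(counts, out / "stage1_counts.tsv")
        tallies = pd.DataFrame({s: stage1[s].tallies_series() for s in samples})
        write_count_table(tallies, out / "stage1_tallies.tsv")

    with stage("mmg"):
        params = MmgFilterParams(
            min_reads=config.min_reads,
            min_samples=config.min_samples,
            collapse_min_size=config.collapse_min_size,
        )
        raw = count_mmgs(stage1)
        kept = collapse_mmgs(filter_mmgs(raw, params), params)
        write_count_table(raw, out / "mmg_counts_raw.tsv")
        write_count_table(kept, out / "mmg_counts.tsv")
        stats = rescue_stats(stage1, kept)
        stats.to_csv(out / "rescue.tsv", sep="\t")

    with stage("expression"):
        lengths = {g: len(s) for g, s in transcriptome.transcripts.items()}
        lib_sizes = {s: stage1[s].total_fragments for s in samples}
        fpkm = expression.fpkm_table(counts, lengths, lib_sizes)
        fpkm.to_csv(out / "fpkm.tsv", sep="\t", index_label="id")
        if not kept.empty:
            fpm = expression.fpm_table(kept, lib_sizes)
            fpm.to_csv(out / "mmg_fpm.tsv", sep="\t", index_label="id")

    with stage("evaluate"):
        expected = {}
        correlations = {}
        for sample in samples:
            table = expression.expected_fpkm_table(
                truths[sample].true_counts, lengths, truths[sample].total_pairs
            )
            expected[sample] = table["expected_fpkm"]
            correlations[sample] = correlate(fpkm[sample], table["expected_fpkm"])
        pd.Series(correlations, name="pearson_r").to_csv(
            out / "correlations.tsv", sep="\t", index_label="sample"
        )
        verdicts, summary = classify_genes(
            counts, low=config.low_threshold, high=config.high_threshold
        )
        verdicts.to_csv(out / "verdicts.tsv", sep="\t", index_label="id")
        if not kept.empty and kept.shape[0] >= 2 and len(samples) >= 2:
            logfpm = expression.log_fpm(expression.fpm_table(kept, lib_sizes))
            logfpm_df = pd.DataFrame(logfpm, index=kept.index, columns=kept.columns)
            corr_distance(logfpm_df, axis="rows").to_csv(
                out / "mmg_distance.tsv", sep="\t", index_label="id"
            )

    # global conservation: simulated == stage-1 total == assigned + rescued + discarded
    conservation = {}
    for sample in samples:
        res = stage1[sample]
        rescued = int(kept[sample].sum()) if sample in kept else 0
        conservation[sample] = {
            "simulated": truths[sample].total_pairs,
            "stage1_total": res.total_fragments,
            "assigned": int(res.tallies_series()["assigned"]),
            "rescued": rescued,
            "discarded": res.unassigned - rescued,
        }

    summary_dict = {
        "samples": samples,
        "n_genes": len(gene_ids),
        "n_mmgs_raw": int(raw.shape[0]),
        "n_mmgs_kept": int(kept.shape[0]),
        "correlations": correlations,
        "classification": dataclasses.asdict(summary),
        "conservation": conservation,
        "timings_s": timings,
    }
    (out / "summary.json").write_text(json.dumps(summary_dict, indent=2) + "\n")
    return summary_dict
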