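"""Conversion between fragment counts and FPKM / FPM.

FPKM (fragments per kilobase of transcript per million fragments) follows the
plain count-based definition

    FPKM = (Rc / T) / Rm        Rc = FPKM * Rm * T

with Rc the fragment count of a gene, T its transcript length in kilobases and
Rm the library size in millions of fragments. No effective-length adjustment
is applied — for perfect simulated reads annotated length and effective length
coincide, and the adjustment is a documented bias source in model-based tools.

Multi-map groups have no single defensible length, so group-level expression
is length-free FPM = Rc / Rm.
"""

from __future__ import annotations

from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "fpkm_from_count",
    "count_from_fpkm",
    "fpm_from_count",
    "log_fpm",
    "expected_fpkm_table",
    "fpkm_table",
    "fpm_table",
]


def _check_positive(name: str, value) -> None:
    if np.any(np.asarray(value) <= 0):
        raise ValueError(f"{name} must be positive")


def fpkm_from_count(rc, t_kb, rm_millions):
    """FPKM = (Rc / T) / Rm. Scalar or array-valued."""
    _check_positive("transcript length (kb)", t_kb)
    _check_positive("library size (millions)", rm_millions)
    return (np.asarray(rc, dtype=float) / t_kb) / rm_millions


def count_from_fpkm(fpkm, t_kb, rm_millions):
    """Rc = FPKM * Rm * T — the exact inverse; not rounded."""
    _check_positive("transcript length (kb)", t_kb)
    _check_positive("library size (millions)", rm_millions)
    return np.asarray(fpkm, dtype=float) * rm_millions * t_kb


def fpm_from_count(rc, rm_millions):
    """FPM = Rc / Rm (length-free; used for multi-map groups)."""
    _check_positive("library size (millions)", rm_millions)
    return np.asarray(rc, dtype=float) / rm_millions


def log_fpm(fpm, pseudocount: float = 1.0, base: float = 2.0):
    """log(FPM + pseudocount); base 2 by default."""
    return np.log(np.asarray(fpm, dtype=float) + pseudocount) / np.log(base)


def expected_fpkm_table(
    true_counts: Mapping[str, int],
    transcript_lengths_bp: Mapping[str, int],
    total_pairs: int,
) -> pd.DataFrame:
    """Ground-truth expression of a simulated design.

    expected_fpkm(g) = (true_count(g) / T_kb(g)) / Rm with Rm the total number
    of simulated pairs in millions.
    """
    rm = total_pairs / 1e6
    rows = {
        g: {
            "true_count": n,
            "transcript_len": transcript_lengths_bp[g],
            "expected_fpkm": float(
                fpkm_from_count(n, transcript_lengths_bp[g] / 1000.0, rm)
            ),
        }
        for g, n in true_counts.items()
    }
    return pd.DataFrame.from_dict(rows, orient="index")


def fpkm_table(
    counts: pd.DataFrame | pd.Series,
    transcript_lengths_bp: Mapping[str, int],
    library_sizes: Mapping[str, int] | int,
) -> pd.DataFrame | pd.Series:
    """Per-sample FPKM for a gene x sample count matrix (or one sample)."""
    if isinstance(counts, pd.Series):
        _check_positive("library size", library_sizes)
        t_kb = pd.Series({g: transcript_lengths_bp[g] / 1000.0 for g in counts.index})
        return (counts / t_kb) / (library_sizes / 1e6)
    out = {}
    for sample in counts.columns:
        rm = (library_sizes[sample] if isinstance(library_sizes, Mapping)
              else library_sizes)
        out[sample] = fpkm_table(counts[sample], transcript_lengths_bp, rm)
    return pd.DataFrame(out)


def fpm_table(
    counts: pd.DataFrame, library_sizes: Mapping[str, int] | int
) -> pd.DataFrame:
    """Per-sample FPM for a group x sample count matrix."""
    out = {}
    for sample in counts.columns:
        rm = (library_sizes[sample] if isinstance(library_sizes, Mapping)
              else library_sizes)
        _check_positive("library size", rm)
        out[sample] = counts[sample] / (rm / 1e6)
    return pd.DataFrame(out)
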