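"""Comparison of HER island sets between populations.

Shared-ness is judged from the reference side: a reference island counts
as shared when it intersects any island of the other set by at least
``min_overlap_bp`` (default 1 bp — no reciprocal-overlap requirement),
and the percentage in common uses the reference island count as
denominator.  Both island sets must use the same 1-based inclusive
coordinate convention.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class OverlapReport:
    """Island-set overlap between a reference and another population."""

    ref_n: int
    other_n: int
    n_shared: int
    pct_in_common: float  # NaN when the reference set is empty
    ref_specific: pd.DataFrame = field(repr=False, default=None)
    other_specific: pd.DataFrame = field(repr=False, default=None)


def _overlap_mask(
    a: pd.DataFrame, b: pd.DataFrame, min_overlap_bp: int
) -> np.ndarray:
    """For each interval in *a*, whether any interval of *b* on the same
    chromosome overlaps it by >= min_overlap_bp (closed coordinates)."""
    mask = np.zeros(len(a), dtype=bool)
    by_chrom = {c: g for c, g in b.groupby("chrom")}
    for i, row in enumerate(a.itertuples(index=False)):
        g = by_chrom.get(row.chrom)
        if g is None:
            continue
        ov = np.minimum(g["end"].to_numpy(), row.end) - np.maximum(
            g["start"].to_numpy(), row.start
        ) + 1
        mask[i] = bool((ov >= min_overlap_bp).any())
    return mask


def overlap_islands(
    ref: pd.DataFrame, other: pd.DataFrame, min_overlap_bp: int = 1
) -> OverlapReport:
    """Compare two island tables (columns chrom, start, end).

    Returns counts, the percentage of reference islands shared with the
    other set, and the population-specific interval lists on both sides.
    Rows are sorted (chrom, start) so the report is order-invariant.
    """
    if min_overlap_bp < 1:
        raise ValueError("min_overlap_bp must be >= 1")
    ref = ref.sort_values(["chrom", "start"]).reset_index(drop=True)
    other = other.sort_values(["chrom", "start"]).reset_index(drop=True)

    ref_shared = _overlap_mask(ref, other, min_overlap_bp)
    other_shared = _overlap_mask(other, ref, min_overlap_bp)
    n_shared = int(ref_shared.sum())
    if len(ref) == 0:
        warnings.warn("empty reference island set; percentage undefined")
        pct = float("nan")
    else:
        pct = 100.0 * n_shared / len(ref)
    return OverlapReport(
        ref_n=len(ref),
        other_n=len(other),
        n_shared=n_shared,
        pct_in_common=pct,
        ref_specific=ref[~ref_shared].reset_index(drop=True),
        other_specific=other[~other_shared].reset_index(drop=True),
    )
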