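"""Consecutive-approach detection of heterozygous-enriched regions (HERs).

A HER (also called a run of heterozygosity, ROHet) is, for one individual
and chromosome, a maximal stretch of SNPs dominated by heterozygous
genotypes.  The scanner is window-free: it walks the ordered SNPs and
closes a run when a tolerance is exhausted.  Four parameters control the
call, mirroring standard run-detection software:

``min_snp``
    minimum number of SNPs spanned by a run (post-filter);
``max_gap``
    maximum physical distance (bp) between two consecutive SNPs inside a
    run — a positional constraint applied regardless of genotype;
``min_length``
    minimum run length in bp, with length = end - start (post-filter);
``max_hom``
    maximum number of homozygous SNPs tolerated anywhere inside a run.

A fifth knob, ``max_miss``, bounds missing calls inside a run (they do
not count as homozygous but do count toward the SNP span).  Runs are
trimmed so that the first and last SNP are heterozygous; when extending
a run would exceed a tolerance, the run is closed at the last
heterozygous SNP and scanning resumes after it.  This greedy rule is
deterministic and is pinned by an exhaustive-enumeration oracle in the
test-suite.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator, NamedTuple

import numpy as np
import pandas as pd

from .genotype_io import HET, HOM_ALT, HOM_REF, MISSING, GenotypeMatrix

HER_COLUMNS = [
    "individual", "chrom", "start", "end", "start_idx", "end_idx",
    "n_snp", "n_hom", "n_miss", "length_bp",
]


@dataclass(frozen=True)
class DetectionParams:
    """The four run-detection parameters plus the missing-call tolerance."""

    min_snp: int = 10
    max_gap: int = 500_000
    min_length: int = 10_000
    max_hom: int = 2
    max_miss: int = 1

    def __post_init__(self) -> None:
        if self.min_snp < 1:
            raise ValueError("min_snp must be >= 1")
        if self.max_gap <= 0:
            raise ValueError("max_gap must be > 0")
        if self.min_length < 0 or self.max_hom < 0 or self.max_miss < 0:
            raise ValueError("min_length, max_hom and max_miss must be >= 0")


class Her(NamedTuple):
    """One detected run for one individual (record view of a table row)."""

    individual: str
    chrom: str
    start: int
    end: int
    n_snp: int
    n_hom: int
    n_miss: int
    length_bp: int


def as_her_records(hers: pd.DataFrame) -> Iterator[Her]:
    for row in hers.itertuples(index=False):
        yield Her(row.individual, row.chrom, int(row.start), int(row.end),
                  int(row.n_snp), int(row.n_hom), int(row.n_miss),
                  int(row.length_bp))


def _scan_runs(
    geno: np.ndarray, pos: np.ndarray, max_gap: int, max_hom: int, max_miss: int
) -> list[tuple[int, int, int, int]]:
    """Greedy consecutive scan of one individual on one chromosome.

    Returns (start_idx, end_idx, n_hom, n_miss) tuples of maximal runs with
    heterozygous endpoints, before the min_snp/min_length post-filters.
    Runs jump from tolerance violation to tolerance violation, so the cost
    is proportional to the number of runs, not the number of SNPs.
    """
    n = geno.size
    het_idx = np.flatnonzero(geno == HET)
    if het_idx.size == 0:
        return []
    hom_idx = np.flatnonzero((geno == HOM_REF) | (geno == HOM_ALT))
    mis_idx = np.flatnonzero(geno == MISSING)

    breaks = np.flatnonzero(np.diff(pos) > max_gap)
    seg_starts = np.concatenate([[0], breaks + 1])
    seg_ends = np.concatenate([breaks, [n - 1]])

    runs: list[tuple[int, int, int, int]] = []
    n_hom_all, n_mis_all = hom_idx.size, mis_idx.size
    for a, b in zip(seg_starts, seg_ends):
        hp = int(np.searchsorted(het_idx, a))
        while hp < het_idx.size and het_idx[hp] <= b:
            s = int(het_idx[hp])
            ho = int(np.searchsorted(hom_idx, s))
            t_hom = int(hom_idx[ho + max_hom]) if ho + max_hom < n_hom_all else n
            mo = int(np.searchsorted(mis_idx, s))
            t_mis = int(mis_idx[mo + max_miss]) if mo + max_miss < n_mis_all else n
            t = min(t_hom, t_mis, b + 1)
            e = int(het_idx[int(np.searchsorted(het_idx, t)) - 1])
            n_hom = int(np.searchsorted(hom_idx, e, side="right")) - ho
            n_mis = int(np.searchsorted(mis_idx, e, side="right")) - mo
            runs.append((s, e, n_hom, n_mis))
            hp = int(np.searchsorted(het_idx, e + 1))
    return runs


def _scan_genome(
    gm: GenotypeMatrix, max_gap: int, max_hom: int, max_miss: int
) -> dict[str, np.ndarray]:
    """Raw runs for every individual and chromosome, as flat arrays of
    global site indices.  Shared by detect_hers and the parameter sweep
    (min_snp / min_length are applied afterwards)."""
    ind_l: list[np.ndarray] = []
    s_l: list[np.ndarray] = []
    e_l: list[np.ndarray] = []
    hom_l: list[np.ndarray] = []
    mis_l: list[np.ndarray] = []
    pos_all = gm.sites["pos"].to_numpy()
    for chrom, block in gm.chrom_blocks():
        pos = pos_all[block]
        for i in range(gm.n_samples):
            runs = _scan_runs(gm.calls[i, block], pos, max_gap, max_hom, max_miss)
            if not runs:
                continue
            arr = np.asarray(runs, dtype=np.int64)
            ind_l.append(np.full(len(runs), i, dtype=np.int32))
            s_l.append(arr[:, 0] + block.start)
            e_l.append(arr[:, 1] + block.start)
            hom_l.append(arr[:, 2])
            mis_l.append(arr[:, 3])

    def cat(parts, dtype):
        return np.concatenate(parts) if parts else np.array([], dtype=dtype)

    s = cat(s_l, np.int64)
    e = cat(e_l, np.int64)
    return {
        "ind": cat(ind_l, np.int32),
        "start_idx": s,
        "end_idx": e,
        "n_hom": cat(hom_l, np.int64),
        "n_miss": cat(mis_l, np.int64),
        "n_snp": e - s + 1,
        "length_bp": pos_all[e] - pos_all[s] if s.size else np.array([], np.int64),
    }


def _runs_to_frame(
    gm: GenotypeMatrix, raw: dict[str, np.ndarray], mask: np.ndarray
) -> pd.DataFrame:
    idx = np.flatnonzero(mask)
    samples = np.asarray(gm.samples, dtype=object)
    chroms = gm.sites["chrom"].to_numpy()
    pos = gm.sites["pos"].to_numpy()
    s, e = raw["start_idx"][idx], raw["end_idx"][idx]
    df = pd.DataFrame(
        {
            "individual": samples[raw["ind"][idx]],
            "chrom": chroms[s] if s.size else np.array([], dtype=object),
            "start": pos[s] if s.size else np.array([], dtype=np.int64),
            "end": pos[e] if e.size else np.array([], dtype=np.int64),
            "start_idx": s,
            "end_idx": e,
            "n_snp": raw["n_snp"][idx],
            "n_hom": raw["n_hom"][idx],
            "n_miss": raw["n_miss"][idx],
            "length_bp": raw["length_bp"][idx],
        }
    )
    return df.reset_index(drop=True)


def detect_hers(gm: GenotypeMatrix, params: DetectionParams) -> pd.DataFrame:
    """Detect HERs for every individual under one parameter set.

    Returns a DataFrame with one row per run (columns: individual, chrom,
    start, end, start_idx, end_idx, n_snp, n_hom, n_miss, length_bp),
    sorted by individual, chromosome block and start.  ``start``/``end``
    are the positions of the first and last SNP of the run (both
    heterozygous); ``n_snp`` counts every SNP spanned, including tolerated
    homozygous and missing calls.
    """
    raw = _scan_genome(gm, params.max_gap, params.max_hom, params.max_miss)
    mask = (raw["n_snp"] >= params.min_snp) & (
        raw["length_bp"] >= params.min_length
    )
    df = _runs_to_frame(gm, raw, mask)
    if len(df):
        df = df.sort_values(
            ["individual", "start_idx"], kind="stable"
        ).reset_index(drop=True)
    return df


# -- summaries ----------------------------------------------------------

LENGTH_BINS_BP = (10_000, 20_000, 30_000, 40_000, 50_000)
LENGTH_LABELS = ("10-20 Kb", "20-30 Kb", "30-40 Kb", "40-50 Kb", ">=50 Kb")
BELOW_RANGE_LABEL = "<10 Kb"


def classify_lengths(
    lengths_bp: pd.Series | np.ndarray,
    bins_bp: tuple[int, ...] = LENGTH_BINS_BP,
    labels: tuple[str, ...] = LENGTH_LABELS,
) -> pd.Series:
    """Count runs per length class (left-closed, right-open bins; the last
    class is open-ended).  Runs shorter than the lowest bin edge are counted
    in an explicit below-range bucket, never dropped."""
    if len(labels) != len(bins_bp):
        raise ValueError("need one label per bin edge")
    lengths = np.asarray(lengths_bp, dtype=np.int64)
    edges = np.asarray(bins_bp, dtype=np.int64)
    out = {BELOW_RANGE_LABEL: int((lengths < edges[0]).sum())}
    for i, label in enumerate(labels):
        lo = edges[i]
        if i + 1 < len(edges):
            out[label] = int(((lengths >= lo) & (lengths < edges[i + 1])).sum())
        else:
            out[label] = int((lengths >= lo).sum())
    return pd.Series(out, name="n_her")


def chromosome_coverage(
    hers: pd.DataFrame, chrom_lengths: dict[str, int], n_individuals: int
) -> pd.Series:
    """Mean per-individual fraction of each chromosome covered by HERs,
    as a percentage.  Individuals without runs on a chromosome contribute
    zero, so *n_individuals* (the population size) is required."""
    if n_individuals < 1:
        raise ValueError("n_individuals must be >= 1")
    for chrom, length in chrom_lengths.items():
        if length <= 0:
            raise ValueError(f"chromosome {chrom!r} has non-positive length")
    unknown = set(hers["chrom"].astype(str)) - set(chrom_lengths)
    if unknown:
        raise ValueError(f"HERs on chromosomes without a length: {sorted(unknown)}")
    out = {}
    for chrom, length in chrom_lengths.items():
        sub = hers[hers["chrom"].astype(str) == chrom]
        total_bp = sub.groupby("individual")["length_bp"].sum()
        out[chrom] = 100.0 * total_bp.sum() / (length * n_individuals)
    return pd.Series(out, name="mean_coverage_pct")
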