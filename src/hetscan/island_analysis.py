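"""HER islands: population-level pile-ups of heterozygous-enriched regions.

An island is a genomic interval whose SNPs are covered by runs in at
least a threshold fraction of individuals (default 10%) under *every*
evaluated scenario — intersecting the scenarios makes the call robust to
the detection parameters.  Supported SNPs closer than a merge gap are
joined into one interval; island boundaries are the first and last
supported SNP positions.

Within-island linkage disequilibrium is summarised as the mean pairwise
r^2 of genotype dosages, and islands are characterised by per-scenario
occurrence percentages, mirroring the island tables of run-of-
heterozygosity studies in cattle.
"""

from __future__ import annotations

import warnings
from importlib import resources

import numpy as np
import pandas as pd

from .genotype_io import MISSING, GenotypeMatrix

ISLAND_COLUMNS = ["chrom", "start", "end", "n_snp"]


def call_islands(
    tracks: dict[str, np.ndarray],
    gm: GenotypeMatrix,
    threshold: float = 0.10,
    merge_gap: int = 500_000,
) -> pd.DataFrame:
    """Call islands from per-scenario incidence tracks.

    A SNP is *supported* iff its incidence is >= *threshold* (inclusive:
    "at least") in every scenario track.  Consecutive supported SNPs on the
    same chromosome at most *merge_gap* bp apart form one island; stretches
    of a single supported SNP are discarded (an interval needs end > start).
    Returns a DataFrame with chrom, start, end, n_snp (supported markers)
    and length_bp.
    """
    if not tracks:
        raise ValueError("need at least one incidence track")
    n_sites = gm.n_sites
    for name, tr in tracks.items():
        if np.asarray(tr).shape != (n_sites,):
            raise ValueError(
                f"track {name!r} does not match the site set "
                f"({np.asarray(tr).shape} vs {n_sites} sites)"
            )
    supported = np.ones(n_sites, dtype=bool)
    for tr in tracks.values():
        supported &= np.asarray(tr) >= threshold

    rows = []
    pos_all = gm.sites["pos"].to_numpy()
    for chrom, block in gm.chrom_blocks():
        idx = np.flatnonzero(supported[block]) + block.start
        if idx.size == 0:
            continue
        pos = pos_all[idx]
        breaks = np.flatnonzero(np.diff(pos) > merge_gap)
        starts = np.concatenate([[0], breaks + 1])
        ends = np.concatenate([breaks, [idx.size - 1]])
        for a, b in zip(starts, ends):
            if b == a:  # single supported SNP: no interval
                continue
            rows.append(
                {
                    "chrom": chrom,
                    "start": int(pos[a]),
                    "end": int(pos[b]),
                    "start_idx": int(idx[a]),
                    "end_idx": int(idx[b]),
                    "n_snp": int(b - a + 1),
                    "length_bp": int(pos[b] - pos[a]),
                }
            )
    return pd.DataFrame(
        rows,
        columns=["chrom", "start", "end", "start_idx", "end_idx", "n_snp",
                 "length_bp"],
    )


def island_scenario_frequency(
    island: pd.Series | dict,
    hers_by_scenario: dict[str, pd.DataFrame],
    n_individuals: int,
) -> dict[str, float]:
    """Percentage of individuals with >= 1 run overlapping the island, per
    scenario (the island's occurrence profile across parameter sets)."""
    chrom, start, end = island["chrom"], island["start"], island["end"]
    out = {}
    for name, hers in hers_by_scenario.items():
        sub = hers[
            (hers["chrom"] == chrom)
            & (hers["start"] <= end)
            & (hers["end"] >= start)
        ]
        out[name] = 100.0 * sub["individual"].nunique() / n_individuals
    return out


def island_ld(
    gm: GenotypeMatrix, island: pd.Series | dict
) -> tuple[np.ndarray, float]:
    """Pairwise LD (r^2 of genotype dosages) for markers inside an island.

    r^2 is the squared Pearson correlation of 0/1/2 dosages over the
    individuals with both sites called.  Returns the full pairwise matrix
    (NaN where undefined) and the mean over the strict upper triangle of
    defined pairs; the mean is NaN (with a warning) when no pair is usable.
    """
    chrom, start, end = island["chrom"], island["start"], island["end"]
    in_isl = (
        (gm.sites["chrom"] == chrom)
        & (gm.sites["pos"] >= start)
        & (gm.sites["pos"] <= end)
    ).to_numpy()
    idx = np.flatnonzero(in_isl)
    m = idx.size
    r2 = np.full((m, m), np.nan)
    np.fill_diagonal(r2, 1.0)
    dose = gm.calls[:, idx].astype(np.float64)
    dose[gm.calls[:, idx] == MISSING] = np.nan
    for a in range(m):
        xa = dose[:, a]
        for b in range(a + 1, m):
            xb = dose[:, b]
            ok = np.isfinite(xa) & np.isfinite(xb)
            if ok.sum() < 2:
                continue
            va, vb = xa[ok], xb[ok]
            if va.std() == 0 or vb.std() == 0:
                continue
            r = np.corrcoef(va, vb)[0, 1]
            r2[a, b] = r2[b, a] = r * r
    upper = r2[np.triu_indices(m, k=1)]
    usable = upper[np.isfinite(upper)]
    if usable.size == 0:
        warnings.warn(
            f"island {chrom}:{start}-{end} has <2 usable sites; mean r^2 undefined"
        )
        return r2, float("nan")
    return r2, float(usable.mean())


def island_summary(islands: pd.DataFrame) -> dict:
    """Headline statistics of an island set: count, distinct chromosomes,
    total markers, and mean / sample SD / max of the lengths (end - start)."""
    if len(islands) == 0:
        raise ValueError("island_summary needs at least one island")
    lengths = (islands["end"] - islands["start"]).to_numpy(dtype=np.float64)
    sd = float(lengths.std(ddof=1)) if len(lengths) > 1 else 0.0
    return {
        "count": int(len(islands)),
        "n_chromosomes": int(islands["chrom"].nunique()),
        "total_snp": int(islands["n_snp"].sum()) if "n_snp" in islands else None,
        "mean_length": float(lengths.mean()),
        "sd_length": sd,
        "max_length": float(lengths.max()),
    }


def load_reference_islands() -> pd.DataFrame:
    """The packaged reference island set: 45 HER islands on 23 autosomes
    reported for Holstein cattle from whole-genome sequence data, with
    marker counts, mean within-island LD and per-scenario occurrence
    percentages.  Used as a regression fixture for the summary statistics."""
    with resources.files("hetscan.data").joinpath(
        "holstein_her_islands.tsv"
    ).open() as fh:
        return pd.read_csv(fh, sep="\t", dtype={"chrom": str})
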