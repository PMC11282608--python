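"""Diversity statistics used to validate detected heterozygous-enriched regions.

Per-site observed/expected heterozygosity and nucleotide diversity (pi),
windowed Tajima's D, the per-SNP HER incidence track (the fraction of
individuals whose runs cover each SNP), and Spearman rank correlations
between the two families of signals.

Tajima's D contrasts mean pairwise diversity with the scaled number of
segregating sites: D = (pi - S/a1) / sqrt(e1*S + e2*S*(S-1)), with the
variance constants a1, a2, b1, b2, c1, c2, e1, e2 derived from the number
of sequences n (Tajima 1989).  Positive D in a window indicates an excess
of intermediate-frequency variants, the signature of balancing selection
that HER islands are expected to carry.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .genotype_io import HET, MISSING, GenotypeMatrix


def site_heterozygosity(gm: GenotypeMatrix) -> pd.DataFrame:
    """Per-site observed and expected heterozygosity.

    obs_het = heterozygous calls / called individuals;
    exp_het = 2 p (1 - p) with p the alternate-allele frequency among
    called alleles.  Sites with no called genotype get NaN.
    """
    called = gm.calls != MISSING
    n_called = called.sum(axis=0)
    n_het = (gm.calls == HET).sum(axis=0)
    alt = np.where(called, gm.calls, 0).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        obs = np.where(n_called > 0, n_het / n_called, np.nan)
        p = np.where(n_called > 0, alt / (2 * n_called), np.nan)
        exp = 2.0 * p * (1.0 - p)
    return pd.DataFrame(
        {
            "chrom": gm.sites["chrom"],
            "pos": gm.sites["pos"],
            "n_called": n_called,
            "obs_het": obs,
            "exp_het": exp,
        }
    )


def site_pi(gm: GenotypeMatrix) -> pd.DataFrame:
    """Per-site nucleotide diversity: the probability that two alleles drawn
    without replacement differ, pi = 2 j (k - j) / (k (k - 1)) for j
    alternate alleles among k called alleles.  Undefined (NaN) when fewer
    than two alleles are called."""
    called = gm.calls != MISSING
    k = 2 * called.sum(axis=0)
    j = np.where(called, gm.calls, 0).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        pi = np.where(k >= 2, 2.0 * j * (k - j) / (k * (k - 1.0)), np.nan)
    return pd.DataFrame(
        {"chrom": gm.sites["chrom"], "pos": gm.sites["pos"], "pi": pi,
         "n_alleles": k}
    )


def tajima_constants(n: int) -> dict[str, float]:
    """Variance constants for Tajima's D with n sequences."""
    if n < 2:
        raise ValueError("Tajima constants need n >= 2 sequences")
    i = np.arange(1, n)
    a1 = float(np.sum(1.0 / i))
    a2 = float(np.sum(1.0 / i**2))
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n**2 + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return {"a1": a1, "a2": a2, "b1": b1, "b2": b2,
            "c1": c1, "c2": c2, "e1": e1, "e2": e2}


@dataclass
class TajimaWindow:
    """Windowed segregating-site count, pi sum and Tajima's D."""

    chrom: str
    window_start: int
    window_end: int
    n_sites: int
    S: int
    pi_sum: float
    n: int  # sequences used for the constants
    D: float  # NaN when undefined (S == 0)


def tajimas_d(gm: GenotypeMatrix, window_bp: int = 10_000) -> pd.DataFrame:
    """Tajima's D in non-overlapping windows of *window_bp* per chromosome.

    Windows are anchored at position 1 ([1, w], [w+1, 2w], ...).  Within a
    window, S counts sites polymorphic among called alleles and pi_sum is
    the sum of per-site pi.  The constants use n = 2 x the maximum number
    of called individuals at any site in the window (diploid, unphased).
    Windows without polymorphism, or with fewer than 4 usable sequences,
    report D as NaN.  Raises if the population cannot provide 4 sequences.
    """
    if window_bp <= 0:
        raise ValueError("window_bp must be > 0")
    if 2 * gm.n_samples < 4:
        raise ValueError("Tajima's D needs at least 2 diploid individuals")

    pi_df = site_pi(gm)
    pi = pi_df["pi"].to_numpy()
    k = pi_df["n_alleles"].to_numpy()
    j = np.where(gm.calls != MISSING, gm.calls, 0).sum(axis=0)
    polymorphic = (k >= 2) & (j > 0) & (j < k)

    rows: list[TajimaWindow] = []
    pos_all = gm.sites["pos"].to_numpy()
    for chrom, block in gm.chrom_blocks():
        pos = pos_all[block]
        bins = (pos - 1) // window_bp
        for b in np.unique(bins):
            sel = np.flatnonzero(bins == b) + block.start
            S = int(polymorphic[sel].sum())
            pi_sum = float(np.nansum(pi[sel]))
            n = int(k[sel].max()) if sel.size else 0
            D = np.nan
            if S > 0 and n >= 4:
                c = tajima_constants(n)
                var = c["e1"] * S + c["e2"] * S * (S - 1)
                D = float((pi_sum - S / c["a1"]) / np.sqrt(var))
            rows.append(
                TajimaWindow(
                    chrom=chrom,
                    window_start=int(b * window_bp + 1),
                    window_end=int((b + 1) * window_bp),
                    n_sites=int(sel.size),
                    S=S,
                    pi_sum=pi_sum,
                    n=n,
                    D=D,
                )
            )
    return pd.DataFrame([vars(r) for r in rows])


def snp_her_incidence(hers: pd.DataFrame, gm: GenotypeMatrix) -> np.ndarray:
    """Per-site fraction of individuals with at least one run covering the
    site (the incidence track for one scenario).

    Relies on the scanner guarantee that runs of one individual never
    overlap, so summing run indicators never double-counts an individual.
    """
    delta = np.zeros(gm.n_sites + 1, dtype=np.int64)
    if len(hers):
        s = hers["start_idx"].to_numpy(dtype=np.intp)
        e = hers["end_idx"].to_numpy(dtype=np.intp)
        np.add.at(delta, s, 1)
        np.add.at(delta, e + 1, -1)
    counts = np.cumsum(delta[:-1])
    return counts / gm.n_samples


def rank_correlation(x, y) -> float:
    """Spearman's rho with average ranks for ties, over paired non-missing
    entries.  Returns NaN (with a warning) when either vector is constant."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    ok = np.isfinite(x) & np.isfinite(y)
    if ok.sum() < 3:
        raise ValueError("need at least 3 paired non-missing observations")
    xs, ys = x[ok], y[ok]
    if np.ptp(xs) == 0 or np.ptp(ys) == 0:
        warnings.warn("rank correlation undefined for a constant vector")
        return float("nan")
    rho, _ = stats.spearmanr(xs, ys)
    return float(rho)
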