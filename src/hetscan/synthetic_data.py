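"""Synthetic diploid genotype data with planted heterozygous-enriched islands.

The generator emulates the statistical structure that the run scanner
assumes, not the biology that produces it: background sites are
Hardy-Weinberg draws at allele frequencies sampled from a configurable
minor-allele-frequency band, and each planted island forces a chosen
fraction of "carrier" individuals to be heterozygous with high
probability across a contiguous interval — the genotype-level footprint
of a region under balancing selection.  Genotyping error (symmetric flip
to a uniformly chosen other state) and missingness are applied last.

Everything is reproducible from a single integer seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genotype_io import HET, MISSING, GenotypeMatrix

_BASES = ("A", "C", "G", "T")


@dataclass(frozen=True)
class IslandSpec:
    """A planted heterozygous-enriched interval.

    ``het_prob`` is the per-site probability that a carrier individual is
    heterozygous at an island site; ``carrier_fraction`` the fraction of
    individuals carrying the heterozygous stretch.
    """

    chrom: str
    start: int
    end: int
    het_prob: float = 0.95
    carrier_fraction: float = 0.5

    def __post_init__(self) -> None:
        if not self.end > self.start:
            raise ValueError(f"island end must exceed start ({self})")
        if not 0.0 <= self.het_prob <= 1.0:
            raise ValueError("het_prob must be within [0, 1]")
        if not 0.0 <= self.carrier_fraction <= 1.0:
            raise ValueError("carrier_fraction must be within [0, 1]")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class SyntheticConfig:
    """Study-design parameters for :func:`simulate_population`.

    Defaults describe the reference simulated population used throughout
    the test-suite: 200 individuals on two 5-Mb autosomes at one marker
    per 500 bp (a sequence-like density at desk scale), background minor
    allele frequencies uniform on [0.05, 0.5], 0.1% genotyping error and
    1% missingness.
    """

    n_individuals: int = 200
    chromosomes: list[tuple[str, int]] = field(
        default_factory=lambda: [("1", 5_000_000), ("2", 5_000_000)]
    )
    marker_density: float = 1 / 500  # expected markers per bp
    background_maf_range: tuple[float, float] = (0.05, 0.5)
    islands: list[IslandSpec] = field(default_factory=list)
    genotype_error_rate: float = 0.001
    missing_rate: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_individuals < 1:
            raise ValueError("n_individuals must be >= 1")
        if self.marker_density <= 0:
            raise ValueError("marker_density must be > 0")
        lo, hi = self.background_maf_range
        if not 0.0 <= lo <= hi <= 0.5:
            raise ValueError("background_maf_range must satisfy 0 <= lo <= hi <= 0.5")
        for rate in (self.genotype_error_rate, self.missing_rate):
            if not 0.0 <= rate <= 1.0:
                raise ValueError("rates must be within [0, 1]")
        lengths = dict(self.chromosomes)
        for isl in self.islands:
            if isl.chrom not in lengths:
                raise ValueError(f"island on unknown chromosome {isl.chrom!r}")
            if isl.start < 1 or isl.end > lengths[isl.chrom]:
                raise ValueError(f"island {isl} outside its chromosome")
        by_chrom: dict[str, list[IslandSpec]] = {}
        for isl in self.islands:
            by_chrom.setdefault(isl.chrom, []).append(isl)
        for chrom, group in by_chrom.items():
            group = sorted(group, key=lambda i: i.start)
            for a, b in zip(group, group[1:]):
                if b.start <= a.end:
                    raise ValueError(
                        f"overlapping islands on chromosome {chrom}: "
                        f"[{a.start}, {a.end}] and [{b.start}, {b.end}]"
                    )


def default_study_config(seed: int = 0) -> SyntheticConfig:
    """The reference simulation: 200 individuals, two 5-Mb chromosomes and
    five planted islands (40-60 Kb, het_prob 0.95, carrier_fraction 0.5)."""
    islands = [
        IslandSpec("1", 1_000_001, 1_050_000),
        IslandSpec("1", 2_500_001, 2_560_000),
        IslandSpec("1", 4_000_001, 4_040_000),
        IslandSpec("2", 1_500_001, 1_555_000),
        IslandSpec("2", 3_800_001, 3_845_000),
    ]
    return SyntheticConfig(islands=islands, seed=seed)


def simulate_population(
    config: SyntheticConfig,
) -> tuple[GenotypeMatrix, list[IslandSpec]]:
    """Simulate a genotype matrix with known heterozygous-enriched islands.

    Returns the matrix and the ground-truth island list (a copy of
    ``config.islands``).  Positions are a sorted uniform draw per
    chromosome; genotypes outside islands are Hardy-Weinberg; carriers are
    heterozygous with probability ``het_prob`` at island sites (otherwise
    homozygous, split by the conditional Hardy-Weinberg odds); error and
    missingness are applied last.
    """
    rng = np.random.default_rng(config.seed)
    n_ind = config.n_individuals
    samples = [f"ind_{i:04d}" for i in range(n_ind)]

    chrom_l: list[np.ndarray] = []
    pos_l: list[np.ndarray] = []
    geno_l: list[np.ndarray] = []
    freq_l: list[np.ndarray] = []

    for chrom, length in config.chromosomes:
        n_markers = int(round(config.marker_density * length))
        n_markers = min(n_markers, length)
        pos = np.sort(rng.choice(length, size=n_markers, replace=False)) + 1
        maf = rng.uniform(*config.background_maf_range, size=n_markers)
        flip = rng.random(n_markers) < 0.5
        p_alt = np.where(flip, 1.0 - maf, maf)  # alternate-allele frequency
        geno = rng.binomial(2, p_alt, size=(n_ind, n_markers)).astype(np.int8)

        for isl in [i for i in config.islands if i.chrom == chrom]:
            in_isl = np.flatnonzero((pos >= isl.start) & (pos <= isl.end))
            if in_isl.size == 0:
                warnings.warn(
                    f"island {isl.chrom}:{isl.start}-{isl.end} contains no markers"
                )
                continue
            n_car = int(round(isl.carrier_fraction * n_ind))
            carriers = rng.choice(n_ind, size=n_car, replace=False)
            u = rng.random((n_car, in_isl.size))
            is_het = u < isl.het_prob
            # non-het carrier calls: homozygote drawn by conditional HWE odds
            p = p_alt[in_isl]
            p_hom_alt = p**2 / (p**2 + (1.0 - p) ** 2)
            hom = np.where(
                rng.random((n_car, in_isl.size)) < p_hom_alt[None, :], 2, 0
            )
            block = np.where(is_het, HET, hom).astype(np.int8)
            geno[np.ix_(carriers, in_isl)] = block

        chrom_l.append(np.repeat(chrom, n_markers))
        pos_l.append(pos.astype(np.int64))
        geno_l.append(geno)
        freq_l.append(p_alt)

    calls = np.concatenate(geno_l, axis=1) if geno_l else np.zeros((n_ind, 0), np.int8)
    n_sites = calls.shape[1]

    if config.genotype_error_rate > 0 and n_sites:
        err = rng.random(calls.shape) < config.genotype_error_rate
        shift = rng.integers(1, 3, size=calls.shape, dtype=np.int8)
        calls = np.where(err, (calls + shift) % 3, calls).astype(np.int8)
    if config.missing_rate > 0 and n_sites:
        miss = rng.random(calls.shape) < config.missing_rate
        calls = np.where(miss, MISSING, calls).astype(np.int8)

    pos_all = np.concatenate(pos_l) if pos_l else np.array([], dtype=np.int64)
    chrom_all = np.concatenate(chrom_l) if chrom_l else np.array([], dtype=object)
    ref = rng.choice(_BASES, size=n_sites)
    offs = rng.integers(1, 4, size=n_sites)
    base_idx = np.array([_BASES.index(b) for b in ref])
    alt = np.array(_BASES)[(base_idx + offs) % 4]

    sites = pd.DataFrame(
        {"chrom": chrom_all, "pos": pos_all, "ref": ref, "alt": alt}
    )
    gm = GenotypeMatrix(
        samples=samples,
        sites=sites,
        calls=calls,
        meta={"seed": config.seed, "alt_freq": np.concatenate(freq_l) if freq_l else None},
    )
    return gm, list(config.islands)


def thin_to_panel(
    gm: GenotypeMatrix,
    keep: pd.DataFrame | None = None,
    target_density: float | None = None,
    strict: bool = False,
) -> GenotypeMatrix:
    """Thin a matrix to a lower marker density, emulating a SNP-chip panel.

    Exactly one of *keep* (chrom/pos DataFrame of panel content) or
    *target_density* (markers per bp, at most the current density) must be
    given.  Retained sites keep their original order; genotypes are
    untouched.  With *keep*, positions absent from the matrix raise in
    ``strict`` mode and otherwise produce a warning with the unmatched count.
    With *target_density*, an evenly spaced deterministic subset is taken
    per chromosome.
    """
    if (keep is None) == (target_density is None):
        raise ValueError("provide exactly one of keep / target_density")

    if keep is not None:
        want = set(zip(keep["chrom"].astype(str), keep["pos"].astype(int)))
        here = list(zip(gm.sites["chrom"].astype(str), gm.sites["pos"].astype(int)))
        mask = np.array([key in want for key in here], dtype=bool)
        n_unmatched = len(want) - int(mask.sum())
        if n_unmatched:
            msg = f"{n_unmatched} panel positions not present in the matrix"
            if strict:
                raise ValueError(msg)
            warnings.warn(msg)
        return gm.take_sites(np.flatnonzero(mask))

    idx_parts: list[np.ndarray] = []
    for chrom, block in gm.chrom_blocks():
        pos = gm.sites["pos"].to_numpy()[block]
        n = len(pos)
        span = int(pos[-1] - pos[0]) + 1 if n else 0
        if n <= 1:
            idx_parts.append(np.arange(block.start, block.stop))
            continue
        current = n / span
        if target_density > current:
            raise ValueError(
                f"target density {target_density:g}/bp exceeds current "
                f"{current:g}/bp on chromosome {chrom}"
            )
        n_target = max(1, int(round(target_density * span)))
        sel = np.unique(np.round(np.linspace(0, n - 1, n_target)).astype(np.intp))
        idx_parts.append(sel + block.start)
    idx = np.concatenate(idx_parts) if idx_parts else np.array([], dtype=np.intp)
    return gm.take_sites(idx)
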