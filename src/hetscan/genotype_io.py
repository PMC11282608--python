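"""Genotype container, VCF input/output, and marker quality control.

The central in-memory object is :class:`GenotypeMatrix`: individuals by
ordered biallelic SNPs, with genotypes coded as alternate-allele dosage
(0 = homozygous reference, 1 = heterozygous, 2 = homozygous alternate,
-1 = missing).  Sites are kept sorted by chromosome block and strictly
increasing physical position, which the run scanner relies on.

Coordinates are 1-based inclusive VCF positions throughout; interval
lengths are reported as ``end - start`` base pairs, the convention used
for run-of-heterozygosity tables in the livestock literature.  BED input
(0-based half-open) is converted on read.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

MISSING: int = -1
HOM_REF: int = 0
HET: int = 1
HOM_ALT: int = 2

_GT_STRING = {HOM_REF: "0/0", HET: "0/1", HOM_ALT: "1/1", MISSING: "./."}

SITE_COLUMNS = ["chrom", "pos", "ref", "alt"]


@dataclass
class GenotypeMatrix:
    """Diploid biallelic genotypes for a set of individuals.

    Parameters
    ----------
    samples : list of str
        Ordered individual identifiers.
    sites : pandas.DataFrame
        One row per SNP with columns ``chrom`` (str), ``pos`` (int, 1-based),
        ``ref`` and ``alt`` (single bases).  Chromosomes must form contiguous
        blocks and positions must be strictly increasing within each block.
    calls : numpy.ndarray
        ``(n_samples, n_sites)`` int8 array of dosage codes
        (-1 missing, 0 hom-ref, 1 het, 2 hom-alt).
    meta : dict
        Free-form provenance (e.g. skipped-record counters from VCF parsing).
    """

    samples: list[str]
    sites: pd.DataFrame
    calls: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.ndim != 2:
            raise ValueError("calls must be a 2-D (individuals x sites) array")
        if self.calls.shape != (len(self.samples), len(self.sites)):
            raise ValueError(
                f"calls shape {self.calls.shape} does not match "
                f"{len(self.samples)} samples x {len(self.sites)} sites"
            )
        missing_cols = [c for c in SITE_COLUMNS if c not in self.sites.columns]
        if missing_cols:
            raise ValueError(f"sites table lacks columns {missing_cols}")
        self.sites = self.sites.reset_index(drop=True)
        bad = ~np.isin(self.calls, (MISSING, HOM_REF, HET, HOM_ALT))
        if bad.any():
            raise ValueError("calls contain codes outside {-1, 0, 1, 2}")
        self._check_sorted()

    def _check_sorted(self) -> None:
        chroms = self.sites["chrom"].to_numpy()
        pos = self.sites["pos"].to_numpy()
        seen: set[str] = set()
        prev_chrom = None
        for i, (c, p) in enumerate(zip(chroms, pos)):
            if c != prev_chrom:
                if c in seen:
                    raise ValueError(f"chromosome {c!r} is not a contiguous block")
                seen.add(c)
                prev_chrom = c
            elif p <= pos[i - 1]:
                raise ValueError(
                    f"positions not strictly increasing on {c!r} at row {i} "
                    f"(pos {p} after {pos[i - 1]})"
                )

    # -- basic accessors -------------------------------------------------

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    def chromosomes(self) -> list[str]:
        return list(pd.unique(self.sites["chrom"]))

    def chrom_blocks(self) -> list[tuple[str, slice]]:
        """Contiguous (chromosome, site-index slice) pairs in storage order."""
        chroms = self.sites["chrom"].to_numpy()
        if len(chroms) == 0:
            return []
        change = np.flatnonzero(chroms[1:] != chroms[:-1]) + 1
        starts = np.concatenate([[0], change])
        ends = np.concatenate([change, [len(chroms)]])
        return [(chroms[a], slice(a, b)) for a, b in zip(starts, ends)]

    def take_sites(self, index: np.ndarray) -> "GenotypeMatrix":
        """New matrix restricted to the given site indices (original order kept)."""
        index = np.asarray(index, dtype=np.intp)
        if index.size and np.any(np.diff(index) <= 0):
            raise ValueError("site indices must be strictly increasing")
        return GenotypeMatrix(
            samples=list(self.samples),
            sites=self.sites.iloc[index].reset_index(drop=True),
            calls=self.calls[:, index],
            meta=dict(self.meta),
        )

    def equals(self, other: "GenotypeMatrix") -> bool:
        return (
            self.samples == other.samples
            and self.sites[SITE_COLUMNS].equals(other.sites[SITE_COLUMNS])
            and np.array_equal(self.calls, other.calls)
        )

    def dosage(self, dtype=np.float64) -> np.ndarray:
        """Calls as float dosage with missing as NaN."""
        d = self.calls.astype(dtype)
        d[self.calls == MISSING] = np.nan
        return d


@dataclass
class QcReport:
    """Bookkeeping for marker quality control (one removal reason per site)."""

    n_sites_in: int
    n_removed_callrate: int
    n_removed_duplicate: int
    n_removed_nonautosomal: int
    n_removed_unknown_pos: int
    n_sites_out: int

    def __post_init__(self) -> None:
        removed = (
            self.n_removed_callrate
            + self.n_removed_duplicate
            + self.n_removed_nonautosomal
            + self.n_removed_unknown_pos
        )
        if self.n_sites_out != self.n_sites_in - removed:
            raise ValueError("QC counts do not reconcile")


# -- VCF input ----------------------------------------------------------


def read_vcf(path: str | Path, autosomes: list[str] | None = None) -> GenotypeMatrix:
    """Read biallelic SNPs from a VCF into a :class:`GenotypeMatrix`.

    Multi-allelic and non-SNP records are skipped; the counts are stored in
    ``meta['n_skipped_multiallelic']`` and ``meta['n_skipped_non_snp']``.
    Half-missing genotypes (e.g. ``./0``) are treated as missing.  If
    *autosomes* is given, records on other chromosomes are dropped here
    (counted in ``meta['n_skipped_chrom']``); otherwise all chromosomes load
    and :func:`qc_filter` handles the autosome rule.

    Raises ``ValueError`` if positions within a chromosome are unsorted,
    naming the offending record.
    """
    from cyvcf2 import VCF

    path = str(path)
    vcf = VCF(path, gts012=False)
    samples = list(vcf.samples)
    keep = set(autosomes) if autosomes is not None else None

    chrom_l: list[str] = []
    pos_l: list[int] = []
    ref_l: list[str] = []
    alt_l: list[str] = []
    geno_l: list[np.ndarray] = []
    n_multi = n_non_snp = n_chrom = 0
    last_pos: dict[str, int] = {}

    for var in vcf:
        if keep is not None and var.CHROM not in keep:
            n_chrom += 1
            continue
        if len(var.ALT) != 1:
            n_multi += 1
            continue
        if len(var.REF) != 1 or len(var.ALT[0]) != 1 or var.ALT[0] not in "ACGT":
            n_non_snp += 1
            continue
        prev = last_pos.get(var.CHROM)
        if prev is not None and var.POS < prev:
            raise ValueError(
                f"unsorted VCF: {var.CHROM}:{var.POS} follows position {prev}"
            )
        last_pos[var.CHROM] = max(var.POS, prev or 0)
        gts = np.asarray(var.genotypes, dtype=np.int16)  # (n, 3): a0, a1, phased
        a0, a1 = gts[:, 0], gts[:, 1]
        code = np.where(
            (a0 < 0) | (a1 < 0),
            MISSING,
            (a0 > 0).astype(np.int16) + (a1 > 0).astype(np.int16),
        ).astype(np.int8)
        chrom_l.append(var.CHROM)
        pos_l.append(var.POS)
        ref_l.append(var.REF)
        alt_l.append(var.ALT[0])
        geno_l.append(code)
    vcf.close()

    sites = pd.DataFrame(
        {"chrom": chrom_l, "pos": np.array(pos_l, dtype=np.int64),
         "ref": ref_l, "alt": alt_l}
    )
    calls = (
        np.stack(geno_l, axis=1)
        if geno_l
        else np.zeros((len(samples), 0), dtype=np.int8)
    )
    # duplicated positions may exist at this stage (QC removes them); relax the
    # strict-increase check by bumping duplicates is not acceptable -> we only
    # reject *decreasing* positions above, and defer duplicates to qc_filter.
    gm = GenotypeMatrix.__new__(GenotypeMatrix)
    gm.samples = samples
    gm.sites = sites
    gm.calls = calls
    gm.meta = {
        "n_skipped_multiallelic": n_multi,
        "n_skipped_non_snp": n_non_snp,
        "n_skipped_chrom": n_chrom,
        "source": path,
    }
    # validate everything except strict monotonicity (duplicates allowed pre-QC)
    _validate_loose(gm)
    return gm


def _validate_loose(gm: GenotypeMatrix) -> None:
    if gm.calls.shape != (len(gm.samples), len(gm.sites)):
        raise ValueError("calls shape mismatch")
    chroms = gm.sites["chrom"].to_numpy()
    pos = gm.sites["pos"].to_numpy()
    seen: set[str] = set()
    prev = None
    for i, c in enumerate(chroms):
        if c != prev:
            if c in seen:
                raise ValueError(f"chromosome {c!r} is not a contiguous block")
            seen.add(c)
            prev = c
        elif pos[i] < pos[i - 1]:
            raise ValueError(f"unsorted positions on {c!r} at row {i}")


# -- VCF output ---------------------------------------------------------


def write_vcf(
    gm: GenotypeMatrix,
    path: str | Path,
    contig_lengths: dict[str, int] | None = None,
) -> None:
    """Write a minimal VCFv4.2 (GT field only) readable by standard tools."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=hetscan\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in gm.chromosomes():
            if contig_lengths and chrom in contig_lengths:
                fh.write(f"##contig=<ID={chrom},length={contig_lengths[chrom]}>\n")
            else:
                fh.write(f"##contig=<ID={chrom}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(gm.samples)
            + "\n"
        )
        chroms = gm.sites["chrom"].to_numpy()
        pos = gm.sites["pos"].to_numpy()
        ref = gm.sites["ref"].to_numpy()
        alt = gm.sites["alt"].to_numpy()
        for j in range(gm.n_sites):
            gts = "\t".join(_GT_STRING[int(g)] for g in gm.calls[:, j])
            fh.write(
                f"{chroms[j]}\t{pos[j]}\t.\t{ref[j]}\t{alt[j]}\t.\tPASS\t.\tGT\t{gts}\n"
            )


# -- quality control ----------------------------------------------------


def call_rate(gm: GenotypeMatrix) -> np.ndarray:
    """Per-site fraction of non-missing genotypes (PLINK convention)."""
    if gm.n_samples == 0:
        return np.zeros(gm.n_sites)
    return (gm.calls != MISSING).mean(axis=0)


def qc_filter(
    gm: GenotypeMatrix,
    min_call_rate: float = 0.95,
    autosomes: list[str] | None = None,
) -> tuple[GenotypeMatrix, QcReport]:
    """Apply the standard marker QC used in run-detection studies.

    A site is removed iff its call rate is below *min_call_rate*, it shares
    chrom+pos with an earlier site (first record kept), its chromosome is not
    in *autosomes* (no filtering when ``autosomes is None``), or its position
    is missing/non-positive.  Each removed site is attributed to exactly one
    reason with precedence: unknown position, non-autosomal, duplicate,
    call rate.
    """
    if not 0.0 <= min_call_rate <= 1.0:
        raise ValueError("min_call_rate must be within [0, 1]")
    n_in = gm.n_sites
    chroms = gm.sites["chrom"].to_numpy()
    pos = pd.to_numeric(gm.sites["pos"], errors="coerce").to_numpy(dtype=float)

    bad_pos = ~np.isfinite(pos) | (pos <= 0)
    if autosomes is not None:
        auto = set(autosomes)
        bad_chrom = np.array([c not in auto for c in chroms]) & ~bad_pos
    else:
        bad_chrom = np.zeros(n_in, dtype=bool)
    dup = pd.Series(
        pd.MultiIndex.from_arrays([chroms, pos]).duplicated(keep="first")
    ).to_numpy()
    bad_dup = dup & ~bad_pos & ~bad_chrom
    cr = call_rate(gm)
    bad_cr = (cr < min_call_rate) & ~bad_pos & ~bad_chrom & ~bad_dup

    removed = bad_pos | bad_chrom | bad_dup | bad_cr
    keep_idx = np.flatnonzero(~removed)
    out = GenotypeMatrix(
        samples=list(gm.samples),
        sites=gm.sites.iloc[keep_idx].reset_index(drop=True),
        calls=gm.calls[:, keep_idx],
        meta=dict(gm.meta),
    )
    report = QcReport(
        n_sites_in=n_in,
        n_removed_callrate=int(bad_cr.sum()),
        n_removed_duplicate=int(bad_dup.sum()),
        n_removed_nonautosomal=int(bad_chrom.sum()),
        n_removed_unknown_pos=int(bad_pos.sum()),
        n_sites_out=int(len(keep_idx)),
    )
    return out, report


# -- tabular artifacts --------------------------------------------------


def read_site_list(path: str | Path) -> pd.DataFrame:
    """Read a site list as chrom/pos (1-based).

    Accepts a 2-column TSV (``chrom<TAB>pos``) or a BED file (3+ columns,
    0-based half-open; each record contributes its start position + 1).
    Files whose first non-comment line has >= 3 numeric-range columns are
    treated as BED.
    """
    path = Path(path)
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            rows.append(line.split("\t"))
    if not rows:
        return pd.DataFrame({"chrom": [], "pos": []})
    is_bed = len(rows[0]) >= 3 and rows[0][1].isdigit() and rows[0][2].isdigit()
    if is_bed:
        chrom = [r[0] for r in rows]
        pos = [int(r[1]) + 1 for r in rows]
    else:
        chrom = [r[0] for r in rows]
        pos = [int(r[1]) for r in rows]
    return pd.DataFrame({"chrom": chrom, "pos": np.array(pos, dtype=np.int64)})


def write_her_table(hers: pd.DataFrame, path: str | Path) -> None:
    """Write a HER table (TSV: individual, chrom, start, end, n_snp, n_hom,
    n_miss, length_bp)."""
    cols = ["individual", "chrom", "start", "end", "n_snp", "n_hom", "n_miss",
            "length_bp"]
    hers.loc[:, cols].to_csv(path, sep="\t", index=False)


def read_her_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"chrom": str})


def write_island_table(islands: pd.DataFrame, path: str | Path) -> None:
    islands.to_csv(path, sep="\t", index=False)


def read_island_table(path: str | Path) -> pd.DataFrame:
    """Read an island table (TSV with at least chrom, start, end)."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    for col in ("chrom", "start", "end"):
        if col not in df.columns:
            raise ValueError(f"island table {path} lacks column {col!r}")
    return df


def write_truth_bed(islands, path: str | Path) -> None:
    """Write island intervals as BED (0-based half-open)."""
    with open(path, "w") as fh:
        for isl in islands:
            fh.write(f"{isl.chrom}\t{isl.start - 1}\t{isl.end}\n")
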