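"""Parameter grids for the run scanner and their marginal summaries.

Two named presets mirror the study design this package re-implements:

``FULL_GRID`` (648 scenarios)
    the Cartesian product of min_snp {5,10,15,20,25,30} x max_gap
    {500 Kb, 1 Mb, 2 Mb} x min_length {10,25,50,100,500,1000 Kb} x
    max_hom {0..5};

``ADDITIONAL_SCENARIOS`` (9 scenarios, named ``5_0`` .. ``10_5``)
    min_snp 5 with max_hom 0-2 and min_snp 10 with max_hom 0-5, at
    max_gap 500 Kb and min_length 10 Kb — the scenarios intersected when
    calling HER islands.

Because min_snp and min_length are post-filters, scenarios sharing
(max_gap, max_hom) reuse one genome scan, which keeps the full grid
tractable at sequence-like densities.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genotype_io import GenotypeMatrix
from .her_detection import (
    DetectionParams,
    _runs_to_frame,
    _scan_genome,
    classify_lengths,
)

FULL_GRID: dict[str, list[int]] = {
    "min_snp": [5, 10, 15, 20, 25, 30],
    "max_gap": [500_000, 1_000_000, 2_000_000],
    "min_length": [10_000, 25_000, 50_000, 100_000, 500_000, 1_000_000],
    "max_hom": [0, 1, 2, 3, 4, 5],
}

ADDITIONAL_SCENARIOS: dict[str, DetectionParams] = {
    f"{ms}_{mh}": DetectionParams(
        min_snp=ms, max_gap=500_000, min_length=10_000, max_hom=mh
    )
    for ms, homs in ((5, range(3)), (10, range(6)))
    for mh in homs
}

#: Parameter set used for the cross-breed island comparison.
BREED_COMPARISON_PARAMS = DetectionParams(
    min_snp=10, max_gap=500_000, min_length=10_000, max_hom=2
)

PRESETS = {"grid648": FULL_GRID, "scenarios9": ADDITIONAL_SCENARIOS}


@dataclass
class ScenarioResult:
    """Detection outcome for one parameter combination."""

    name: str
    params: DetectionParams
    n_her: int
    per_individual: np.ndarray  # run count per individual
    hers: pd.DataFrame | None = None  # populated when keep_hers=True

    def __post_init__(self) -> None:
        if self.hers is not None and len(self.hers) != self.n_her:
            raise ValueError("n_her does not match the run table")


def expand_grid(grid: dict[str, list[int]]) -> list[DetectionParams]:
    """All parameter combinations, lexicographic over the listed values."""
    for key in ("min_snp", "max_gap", "min_length", "max_hom"):
        if not grid.get(key):
            raise ValueError(f"grid value list for {key!r} is empty")
    return [
        DetectionParams(min_snp=ms, max_gap=mg, min_length=ml, max_hom=mh)
        for ms, mg, ml, mh in itertools.product(
            grid["min_snp"], grid["max_gap"], grid["min_length"], grid["max_hom"]
        )
    ]


def _scenario_name(p: DetectionParams) -> str:
    return (
        f"snp{p.min_snp}_gap{p.max_gap // 1000}kb_"
        f"len{p.min_length // 1000}kb_hom{p.max_hom}"
    )


def run_scenarios(
    gm: GenotypeMatrix,
    scenarios: dict[str, DetectionParams],
    keep_hers: bool = True,
) -> list[ScenarioResult]:
    """Run the detector for named parameter sets, reusing genome scans
    across scenarios that share (max_gap, max_hom, max_miss)."""
    results: list[ScenarioResult] = []
    cache: dict[tuple[int, int, int], dict[str, np.ndarray]] = {}
    for name, p in scenarios.items():
        key = (p.max_gap, p.max_hom, p.max_miss)
        if key not in cache:
            cache[key] = _scan_genome(gm, *key)
        raw = cache[key]
        mask = (raw["n_snp"] >= p.min_snp) & (raw["length_bp"] >= p.min_length)
        per_ind = np.bincount(
            raw["ind"][mask], minlength=gm.n_samples
        ).astype(np.int64)
        hers = None
        if keep_hers:
            hers = _runs_to_frame(gm, raw, mask)
            hers = hers.sort_values(
                ["individual", "start_idx"], kind="stable"
            ).reset_index(drop=True)
        results.append(
            ScenarioResult(
                name=name,
                params=p,
                n_her=int(mask.sum()),
                per_individual=per_ind,
                hers=hers,
            )
        )
    return results


def run_grid(
    gm: GenotypeMatrix,
    grid: dict[str, list[int]] | None = None,
    max_miss: int = 1,
    keep_hers: bool = False,
) -> list[ScenarioResult]:
    """Run the detector over a full parameter grid (default: the 648-scenario
    preset).  Results come back in lexicographic grid order.  Run tables are
    dropped by default — a full grid at sequence density holds millions of
    runs — and kept only when ``keep_hers=True``."""
    grid = dict(FULL_GRID if grid is None else grid)
    params = expand_grid(grid)
    scenarios = {
        _scenario_name(p): DetectionParams(
            p.min_snp, p.max_gap, p.min_length, p.max_hom, max_miss
        )
        for p in params
    }
    return run_scenarios(gm, scenarios, keep_hers=keep_hers)


@dataclass
class MarginalSummary:
    """Mean and SD of the total run count at one level of one parameter."""

    parameter: str
    level: int
    mean_n_her: float
    sd_n_her: float
    n_scenarios: int


def marginal_summary(
    results: list[ScenarioResult], parameter: str
) -> list[MarginalSummary]:
    """Average and sample (n-1) standard deviation of the number of runs
    across all scenarios sharing each level of *parameter* — the marginal
    effect of one detection parameter over the rest of the grid."""
    if parameter not in ("min_snp", "max_gap", "min_length", "max_hom", "max_miss"):
        raise ValueError(f"unknown parameter {parameter!r}")
    levels: dict[int, list[int]] = {}
    for res in results:
        levels.setdefault(getattr(res.params, parameter), []).append(res.n_her)
    out = []
    for level in sorted(levels):
        counts = np.asarray(levels[level], dtype=np.float64)
        if counts.size == 1:
            warnings.warn(
                f"single scenario at {parameter}={level}; SD reported as 0"
            )
            sd = 0.0
        else:
            sd = float(counts.std(ddof=1))
        out.append(
            MarginalSummary(
                parameter=parameter,
                level=int(level),
                mean_n_her=float(counts.mean()),
                sd_n_her=sd,
                n_scenarios=int(counts.size),
            )
        )
    return out


def marginal_summary_frame(
    results: list[ScenarioResult], parameters: tuple[str, ...] = (
        "min_snp", "max_gap", "min_length", "max_hom")
) -> pd.DataFrame:
    rows = [
        vars(m) for p in parameters for m in marginal_summary(results, p)
    ]
    return pd.DataFrame(rows)


def scenario_table(
    results: list[ScenarioResult], scenarios: list[str] | None = None
) -> pd.DataFrame:
    """Length-class x scenario counts (rows: below-range bucket, the five
    standard classes, and Total; columns: scenario names)."""
    by_name = {r.name: r for r in results}
    names = list(by_name) if scenarios is None else list(scenarios)
    missing = [n for n in names if n not in by_name]
    if missing:
        raise KeyError(f"scenarios not present in results: {missing}")
    cols = {}
    for name in names:
        res = by_name[name]
        if res.hers is None:
            raise ValueError(
                f"scenario {name!r} was run without keep_hers=True"
            )
        cols[name] = classify_lengths(res.hers["length_bp"].to_numpy())
    table = pd.DataFrame(cols)
    table.loc["Total"] = table.sum(axis=0)
    return table
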