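"""Monte Carlo estimation of diagnostic accuracy of 15-subject ranges.

Each simulation draws a random reference sample (default 15 values)
from a configured pool, builds its mean +/- 2 SD range, and scores the
fraction of an evaluation group's global mapping values classified
normal. 20,000 simulations are summarised as median (inter-quartile
range) of the per-simulation accuracies, in percent.

The evaluation group is the full cohort, including any subjects that
happened to be drawn into the reference sample (no leave-out): the
question is how a candidate local range performs on the healthy
population it came from, not out-of-sample generalisation. A
``leave_out`` switch supports the sensitivity analysis.

An independent brute-force :func:`coverage_oracle` (fresh Gaussian
reference and evaluation draws each repetition, no pooling or
resampling machinery) validates the engine on single-Gaussian
scenarios.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .reference_range import PoolRecipe, build_range, classify, draw_reference, make_pool
from .segment_qc import apply_qc
from .synthetic_cohort import CohortSpec, Subject, generate_cohort

__all__ = [
    "Scenario",
    "AccuracySummary",
    "CohortMap",
    "cohort_key",
    "generate_study_cohorts",
    "global_values",
    "run_scenario",
    "coverage_oracle",
    "scenario_table",
    "default_scenarios",
    "averaged_medians",
    "round_half_away",
]

#: Cohorts keyed by (scanner, map_type, sex), all lower/upper-case normalised.
CohortMap = dict[tuple[str, str, str], list[Subject]]

_CHUNK = 4000  # simulations per vectorised block; bounds peak memory


def cohort_key(scanner: str, map_type: str, sex: str) -> tuple[str, str, str]:
    return (scanner.lower(), map_type.upper(), sex.lower())


@dataclass(frozen=True)
class Scenario:
    """A named pairing of reference-pool recipe and evaluation group."""

    name: str
    recipe: PoolRecipe
    eval_scanner: str
    eval_sex: str
    map_type: str = "T1"

    @property
    def cross_scanner(self) -> bool:
        return self.recipe.source_scanner.lower() != self.eval_scanner.lower()


@dataclass
class AccuracySummary:
    """Median and quartiles (percent) of per-simulation accuracies."""

    median_pct: float
    q1_pct: float
    q3_pct: float
    mean_pct: float
    n_sims: int
    n_eval: int
    accuracies: np.ndarray | None = field(default=None, repr=False, compare=False)

    def formatted(self) -> str:
        """Table-style cell: rounded ``"median% (q1-q3)"``."""
        return (
            f"{round_half_away(self.median_pct)}% "
            f"({round_half_away(self.q1_pct)}-{round_half_away(self.q3_pct)})"
        )

    def to_dict(self) -> dict:
        return {
            "median_pct": self.median_pct,
            "q1_pct": self.q1_pct,
            "q3_pct": self.q3_pct,
            "mean_pct": self.mean_pct,
            "n_sims": self.n_sims,
            "n_eval": self.n_eval,
        }


def round_half_away(x: float) -> int:
    """Round to nearest integer, halves away from zero."""
    return int(math.floor(x + 0.5)) if x >= 0 else int(math.ceil(x - 0.5))


def generate_study_cohorts(
    specs: Sequence[CohortSpec], seed: int | np.random.Generator, qc: bool = True
) -> CohortMap:
    """Generate one cohort per spec and (optionally) run QC on each."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    cohorts: CohortMap = {}
    for spec in specs:
        subjects = generate_cohort(spec, rng)
        if qc:
            subjects, _ = apply_qc(subjects)
        cohorts[cohort_key(spec.scanner_label, spec.map_type, spec.sex)] = subjects
    return cohorts


def global_values(cohorts: CohortMap, scanner: str, map_type: str, sex: str) -> np.ndarray:
    key = cohort_key(scanner, map_type, sex)
    if key not in cohorts:
        raise KeyError(f"no cohort for scanner={scanner!r}, map_type={map_type!r}, sex={sex!r}")
    vals = [s.global_value for s in cohorts[key]]
    if any(v is None for v in vals):
        raise ValueError(f"cohort {key}: global_value missing; run apply_qc first")
    return np.asarray(vals, dtype=float)


def _rank_draw(rng: np.random.Generator, rows: int, n: int, k: int) -> np.ndarray:
    """Row-wise uniform draws without replacement: k column indices out of n."""
    return np.argsort(rng.random((rows, n)), axis=1)[:, :k]


def run_scenario(
    scenario: Scenario,
    cohorts: CohortMap,
    n_sims: int = 20_000,
    seed: int | np.random.Generator = 0,
    engine: str = "vectorized",
    keep_accuracies: bool = False,
    leave_out: bool = False,
) -> AccuracySummary:
    """Run the Monte Carlo accuracy simulation for one scenario.

    Per iteration: assemble the reference pool (mixed-balanced recipes
    re-draw the balancing subsample every iteration), sample ``n_draw``
    values without replacement, build mean +/- 2 SD, and score the
    fraction of the evaluation group's global values inside the range
    (bounds inclusive). Accuracies are therefore exact multiples of
    ``100 / n_eval``.

    Parameters
    ----------
    engine : {"vectorized", "loop"}
        The vectorised engine processes simulations in blocks; the loop
        engine goes through :func:`~cmrnorms.reference_range.make_pool`,
        :func:`~cmrnorms.reference_range.draw_reference`,
        :func:`~cmrnorms.reference_range.build_range` and
        :func:`~cmrnorms.reference_range.classify` one iteration at a
        time and exists as a slow cross-check.
    leave_out : bool
        If True, subjects drawn into the reference sample are excluded
        from that iteration's evaluation set (sensitivity analysis;
        only supported when the evaluation group is the pool source of
        a single-sex recipe).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    recipe = scenario.recipe
    eval_vals = global_values(cohorts, scenario.eval_scanner, scenario.map_type, scenario.eval_sex)
    males = global_values(cohorts, recipe.source_scanner, scenario.map_type, "male")
    females = global_values(cohorts, recipe.source_scanner, scenario.map_type, "female")
    n_eval = eval_vals.size
    if n_eval == 0:
        raise ValueError(f"scenario {scenario.name}: empty evaluation group")
    if leave_out and engine != "loop":
        raise ValueError("leave_out is only supported by the loop engine")

    if engine == "loop":
        acc = np.empty(n_sims)
        for i in range(n_sims):
            pool = make_pool(males, females, recipe, rng)
            ref = draw_reference(pool, recipe.n_draw, rng)
            rr = build_range(ref)
            ev = eval_vals
            if leave_out:
                ev = np.array([v for v in eval_vals if v not in ref])
                if ev.size == 0:
                    acc[i] = np.nan
                    continue
            acc[i] = np.mean([classify(v, rr) == "normal" for v in ev]) * 100.0
    elif engine == "vectorized":
        acc = np.empty(n_sims)
        mixed = recipe.composition == "mixed_balanced"
        if mixed:
            big, small = (males, females) if males.size >= females.size else (females, males)
            cap = big.size if recipe.balance_cap is None else min(big.size, recipe.balance_cap)
            pool_size = cap + small.size
        else:
            fixed_pool = males if recipe.composition == "male_only" else females
            pool_size = fixed_pool.size
        if recipe.n_draw > pool_size:
            raise ValueError(
                f"infeasible scenario {scenario.name}: n_draw={recipe.n_draw} "
                f"exceeds pool size {pool_size}"
            )
        for start in range(0, n_sims, _CHUNK):
            b = min(_CHUNK, n_sims - start)
            if mixed:
                sub = big[_rank_draw(rng, b, big.size, cap)]
                pool = np.concatenate([sub, np.broadcast_to(small, (b, small.size))], axis=1)
                ref = np.take_along_axis(
                    pool, _rank_draw(rng, b, pool_size, recipe.n_draw), axis=1
                )
            else:
                ref = fixed_pool[_rank_draw(rng, b, pool_size, recipe.n_draw)]
            m = ref.mean(axis=1)
            s = ref.std(axis=1, ddof=1)
            lo = m - 2.0 * s
            hi = m + 2.0 * s
            inside = (eval_vals >= lo[:, None]) & (eval_vals <= hi[:, None])
            acc[start : start + b] = inside.mean(axis=1) * 100.0
    else:
        raise ValueError(f"unknown engine {engine!r}")

    ok = acc[~np.isnan(acc)]
    q1, med, q3 = np.percentile(ok, [25, 50, 75])
    return AccuracySummary(
        median_pct=float(med),
        q1_pct=float(q1),
        q3_pct=float(q3),
        mean_pct=float(ok.mean()),
        n_sims=n_sims,
        n_eval=n_eval,
        accuracies=acc if keep_accuracies else None,
    )


def coverage_oracle(
    mu_eval: float,
    sd_eval: float,
    mu_ref: float,
    sd_ref: float,
    n_ref: int,
    reps: int = 1_000_000,
    seed: int | np.random.Generator = 0,
) -> float:
    """Brute-force expected coverage of a mean +/- 2 SD range.

    Each repetition draws ``n_ref`` fresh reference values from
    ``N(mu_ref, sd_ref**2)`` and one evaluation value from
    ``N(mu_eval, sd_eval**2)`` and checks whether the evaluation value
    falls inside the reference sample's mean +/- 2 SD. Returns the
    fraction inside (a probability in [0, 1]). This is an independent
    code path from :func:`run_scenario`, used to validate it.
    """
    if sd_eval < 0 or sd_ref < 0:
        raise ValueError("standard deviations must be >= 0")
    if n_ref < 2:
        raise ValueError("n_ref must be >= 2")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    inside = 0
    chunk = 200_000
    for start in range(0, reps, chunk):
        b = min(chunk, reps - start)
        ref = rng.normal(mu_ref, sd_ref, (b, n_ref))
        ev = rng.normal(mu_eval, sd_eval, b)
        m = ref.mean(axis=1)
        s = ref.std(axis=1, ddof=1)
        inside += int(np.count_nonzero((ev >= m - 2 * s) & (ev <= m + 2 * s)))
    return inside / reps


# ---------------------------------------------------------------------------
# Scenario grids

def default_scenarios(n_draw: int = 15) -> list[Scenario]:
    """The full accuracy grid of the study design.

    Twelve same-scanner cells (mixed-balanced and opposite-sex ranges
    for each of Trio T1, Prisma T1 and Prisma T2, by evaluated sex) and
    eight cross-scanner T1 cells (T2 was acquired on one scanner only,
    so cross-scanner T2 cells do not exist). The Trio cohort has 57
    males vs 35 females, so its mixed-balanced recipe caps the male
    subsample at 35; the Prisma cohort is already balanced at 25/25.
    """
    caps = {"trio": 35, "prisma": None}
    scens: list[Scenario] = []
    cells = [("trio", "T1"), ("prisma", "T1"), ("prisma", "T2")]
    for scanner, mt in cells:
        for sex in ("male", "female"):
            opp = "female_only" if sex == "male" else "male_only"
            scens.append(Scenario(
                name=f"{scanner}_{mt.lower()}_{sex}_vs_{scanner}_mixed_balanced",
                recipe=PoolRecipe(scanner, "mixed_balanced", caps[scanner], n_draw),
                eval_scanner=scanner, eval_sex=sex, map_type=mt,
            ))
            scens.append(Scenario(
                name=f"{scanner}_{mt.lower()}_{sex}_vs_{scanner}_{opp}",
                recipe=PoolRecipe(scanner, opp, None, n_draw),
                eval_scanner=scanner, eval_sex=sex, map_type=mt,
            ))
    for scanner, other in (("trio", "prisma"), ("prisma", "trio")):
        for sex in ("male", "female"):
            opp = "female_only" if sex == "male" else "male_only"
            scens.append(Scenario(
                name=f"{scanner}_t1_{sex}_vs_{other}_mixed_balanced",
                recipe=PoolRecipe(other, "mixed_balanced", caps[other], n_draw),
                eval_scanner=scanner, eval_sex=sex, map_type="T1",
            ))
            scens.append(Scenario(
                name=f"{scanner}_t1_{sex}_vs_{other}_{opp}",
                recipe=PoolRecipe(other, opp, None, n_draw),
                eval_scanner=scanner, eval_sex=sex, map_type="T1",
            ))
    return scens


def scenario_table(
    scenarios: Sequence[Scenario],
    cohorts: CohortMap,
    n_sims: int = 20_000,
    seed: int | np.random.Generator = 0,
) -> dict[str, AccuracySummary]:
    """Run every scenario and return ``{name: AccuracySummary}``.

    Deterministic for a fixed seed: each scenario consumes an
    independent child stream spawned from the top-level seed, so the
    result does not depend on evaluation order.
    """
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    children = ss.spawn(len(scenarios))
    out: dict[str, AccuracySummary] = {}
    for scen, child in zip(scenarios, children):
        out[scen.name] = run_scenario(scen, cohorts, n_sims, np.random.default_rng(child))
    return out


def grid_frame(results: Mapping[str, AccuracySummary], scenarios: Sequence[Scenario]):
    """Arrange scenario results as a printed-table-shaped DataFrame.

    Rows are the four pool recipes (mixed/opposite x same/cross
    scanner); columns are evaluation cohorts; cells hold
    ``"median% (q1-q3)"`` strings, empty where a cell is structurally
    absent.
    """
    import pandas as pd

    rows = ["mixed sex; same scanner", "opposite sex; same scanner",
            "mixed sex; cross-scanner", "opposite sex; cross-scanner"]
    by_name = {s.name: s for s in scenarios}
    cols: list[str] = []
    grid: dict[str, dict[str, str]] = {r: {} for r in rows}
    for name, summ in results.items():
        scen = by_name[name]
        col = f"{scen.eval_scanner} {scen.map_type} {scen.eval_sex}"
        if col not in cols:
            cols.append(col)
        kind = "mixed sex" if scen.recipe.composition == "mixed_balanced" else "opposite sex"
        span = "cross-scanner" if scen.cross_scanner else "same scanner"
        grid[f"{kind}; {span}"][col] = summ.formatted()
    return pd.DataFrame([[grid[r].get(c, "") for c in cols] for r in rows],
                        index=rows, columns=cols)


def averaged_medians(
    specs: Sequence[CohortSpec],
    scenarios: Sequence[Scenario],
    n_replicates: int = 50,
    n_sims: int = 20_000,
    seed: int = 0,
) -> dict[str, float]:
    """Per-scenario median accuracy averaged over replicate cohorts.

    Generates ``n_replicates`` independent synthetic studies from
    ``specs`` (full per-segment simulation plus QC), runs every scenario
    on each, and averages the per-replicate medians. Averaging removes
    the single-cohort sampling noise that a one-shot empirical study
    cannot avoid.
    """
    ss = np.random.SeedSequence(seed)
    totals = {s.name: 0.0 for s in scenarios}
    for child in ss.spawn(n_replicates):
        gen_seed, sim_seed = child.spawn(2)
        cohorts = generate_study_cohorts(specs, np.random.default_rng(gen_seed))
        results = scenario_table(scenarios, cohorts, n_sims, sim_seed)
        for name, summ in results.items():
            totals[name] += summ.median_pct
    return {name: tot / n_replicates for name, tot in totals.items()}
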