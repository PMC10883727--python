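"""Mean +/- 2 SD normal ranges and the reference-pool recipes.

A normal (reference) range here is ``sample_mean +/- 2 * sample_sd``
from a sample of healthy values; values outside it are flagged
abnormal. Pools feeding the range can be single-sex, or mixed-sex
balanced by subsampling the larger sex before the reference draw.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "ReferenceRange",
    "PoolRecipe",
    "COMPOSITIONS",
    "build_range",
    "classify",
    "make_pool",
    "draw_reference",
]

COMPOSITIONS = ("male_only", "female_only", "mixed_balanced")


def _as_rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


@dataclass(frozen=True)
class ReferenceRange:
    """A mean +/- 2 SD interval with the sample that produced it.

    ``lower = sample_mean - 2 * sample_sd`` and
    ``upper = sample_mean + 2 * sample_sd``; the SD uses the n-1
    denominator (see :func:`build_range`).
    """

    lower: float
    upper: float
    sample_mean: float
    sample_sd: float
    n_ref: int

    def to_json(self) -> str:
        return json.dumps(asdict(self))


@dataclass(frozen=True)
class PoolRecipe:
    """How to assemble the reference pool for one scenario.

    Parameters
    ----------
    source_scanner : str
        Scanner whose cohort supplies the pool.
    composition : {"male_only", "female_only", "mixed_balanced"}
    balance_cap : int or None
        For ``mixed_balanced``: the larger sex is subsampled (without
        replacement, fresh every simulation) down to
        ``min(count, balance_cap)``; ``None`` leaves already-balanced
        cohorts untouched.
    n_draw : int
        Reference-sample size drawn from the pool (15 by convention).
    """

    source_scanner: str
    composition: str
    balance_cap: int | None = None
    n_draw: int = 15

    def __post_init__(self):
        if self.composition not in COMPOSITIONS:
            raise ValueError(f"composition must be one of {COMPOSITIONS}, got {self.composition!r}")
        if self.n_draw < 2:
            raise ValueError("n_draw must be >= 2")


def build_range(values: Sequence[float], ddof: int = 1) -> ReferenceRange:
    """Build the mean +/- 2 SD range from a reference sample.

    Parameters
    ----------
    values : sequence of float
        At least two reference values (ms).
    ddof : int
        Degrees-of-freedom correction for the SD; the default ``1``
        (n-1 denominator) is the reference-sample convention, ``0``
        gives the population SD.
    """
    arr = np.asarray(values, dtype=float)
    if arr.size < 2:
        raise ValueError(f"need >= 2 values to build a range, got {arr.size}")
    mean = float(arr.mean())
    sd = float(arr.std(ddof=ddof))
    return ReferenceRange(
        lower=mean - 2.0 * sd,
        upper=mean + 2.0 * sd,
        sample_mean=mean,
        sample_sd=sd,
        n_ref=int(arr.size),
    )


def classify(value: float, rng_: ReferenceRange, strict: bool = False) -> str:
    """Classify a value against a range: ``"normal"`` or ``"abnormal"``.

    Bounds are inclusive by default (a value exactly on a bound is
    normal); ``strict=True`` switches to open-interval comparison for
    sensitivity analysis.
    """
    if strict:
        inside = rng_.lower < value < rng_.upper
    else:
        inside = rng_.lower <= value <= rng_.upper
    return "normal" if inside else "abnormal"


def make_pool(
    males: Sequence[float],
    females: Sequence[float],
    recipe: PoolRecipe,
    seed=None,
) -> np.ndarray:
    """Assemble one reference pool according to ``recipe``.

    ``male_only``/``female_only`` return that sex's values unchanged.
    ``mixed_balanced`` subsamples the larger sex down to
    ``min(count, balance_cap)`` without replacement and concatenates all
    of the smaller sex; the subsample is randomised per call, so each
    Monte Carlo iteration should call this afresh.
    """
    males = np.asarray(males, dtype=float)
    females = np.asarray(females, dtype=float)
    if recipe.composition == "male_only":
        pool = males
    elif recipe.composition == "female_only":
        pool = females
    else:
        rng = _as_rng(seed)
        big, small = (males, females) if males.size >= females.size else (females, males)
        cap = big.size if recipe.balance_cap is None else min(big.size, recipe.balance_cap)
        if cap < 1:
            raise ValueError("mixed_balanced recipe with empty subsample")
        sub = rng.choice(big, size=cap, replace=False)
        pool = np.concatenate([sub, small])
    if recipe.n_draw > pool.size:
        raise ValueError(
            f"infeasible recipe: n_draw={recipe.n_draw} exceeds pool size {pool.size}"
        )
    return pool


def draw_reference(pool: Sequence[float], n_draw: int, seed=None) -> np.ndarray:
    """Uniform sample of ``n_draw`` values without replacement from the pool."""
    pool = np.asarray(pool, dtype=float)
    if n_draw > pool.size:
        raise ValueError(f"n_draw={n_draw} exceeds pool size {pool.size}")
    rng = _as_rng(seed)
    return rng.choice(pool, size=n_draw, replace=False)
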