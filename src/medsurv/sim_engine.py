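"""Monte-Carlo size and power study for the median survival test.

The engine reproduces the design of a six-table simulation study with K = 4
groups.  Survival time families (per group):

* ``uniform``:      U(-a/c, a/c) + theta — median theta, half-width a/c.
* ``exponential``:  theta + Exponential(rate a) — median theta + log(2)/a.
* ``lognormal``:    exp(theta + a * N(0, 1)) — median exp(theta).

Each family pairs with a censoring-time family chosen so that the expected
censoring proportion is (approximately) a nominal rate p:

* uniform survival:      U(-a/c, a/c + (1 - 2p)/p) + theta.
* exponential survival:  theta + Exponential(rate a * p / (1 - p)) — exactly
  rate p by the competing-exponentials identity.
* lognormal survival:    exp(theta + a * U(-2, -2 + 2/p)), a log-uniform law
  mirroring the lognormal's exp(theta + a * Z) construction.

With p = 0 no observation is censored.  For the uniform family the realized
rate equals p only when a/c = 1 (it is w/(2W) for support widths w = 2a/c and
W = 2a/c + (1-2p)/p); scenarios are run with their printed parameters, not
re-tuned.

A scenario is one table cell: families and parameters per group, a censoring
rate, sample sizes, significance level, replicate count and seed.  Replicates
on which the test is degenerate (undefined pooled median, zero variance) are
redrawn from a fresh RNG stream and counted, so the rejection denominator
stays at ``reps``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, Sequence

import numpy as np

from .errors import ConfigurationError, DegenerateDataError
from .km_core import SurvivalSample
from .median_test import GroupedSurvivalData, VARIANTS, median_survival_test

__all__ = [
    "GroupSpec",
    "ScenarioSpec",
    "SimulationResult",
    "sample_survival",
    "sample_censoring",
    "generate_grouped_data",
    "run_simulation",
    "scenario_catalog",
    "catalog_keys",
    "LARGE_N",
    "SMALL_N",
]

FAMILIES = ("uniform", "exponential", "lognormal")

LARGE_N = (100, 150, 150, 200)
SMALL_N = (20, 25, 25, 30)


@dataclass(frozen=True)
class GroupSpec:
    """Survival-time family and parameters for one simulated group."""

    family: str
    theta: float
    a: float
    n: int
    c: Optional[float] = None

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ConfigurationError(
                f"unknown family {self.family!r}; expected one of {FAMILIES}"
            )
        if self.n < 2:
            raise ConfigurationError(f"need n >= 2, got {self.n}")
        if self.a <= 0:
            raise ConfigurationError(f"need a > 0, got {self.a}")
        if self.family == "uniform" and (self.c is None or self.c <= 0):
            raise ConfigurationError("uniform family needs divisor c > 0")


@dataclass(frozen=True)
class ScenarioSpec:
    """One simulation cell: groups, censoring rate, alpha, reps, seed."""

    groups: tuple
    censor_rate: float
    alpha: float = 0.05
    reps: int = 10_000
    seed: Optional[int] = None
    label: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "groups", tuple(self.groups))
        if not 0.0 <= self.censor_rate < 1.0:
            raise ConfigurationError(
                f"censoring rate must be in [0, 1), got {self.censor_rate}"
            )
        if not 0.0 < self.alpha < 1.0:
            raise ConfigurationError(f"alpha must be in (0, 1), got {self.alpha}")
        if self.reps < 1:
            raise ConfigurationError(f"need reps >= 1, got {self.reps}")


@dataclass
class SimulationResult:
    """Empirical rejection proportions per test variant for one scenario."""

    rejection: dict
    mc_se: dict
    degenerate_count: int
    reps_done: int
    spec: ScenarioSpec
    statistics: Optional[dict] = field(default=None, repr=False)

    def to_records(self) -> list[dict]:
        """One flat record per variant, ready for a delimited-text summary."""
        return [
            {
                "label": self.spec.label,
                "variant": v,
                "rejection": self.rejection[v],
                "mc_se": self.mc_se[v],
                "reps": self.reps_done,
                "degenerate_count": self.degenerate_count,
                "censor_rate": self.spec.censor_rate,
                "alpha": self.spec.alpha,
                "seed": self.spec.seed,
            }
            for v in self.rejection
        ]


def sample_survival(spec: GroupSpec, rng: np.random.Generator) -> np.ndarray:
    """Draw ``spec.n`` survival times from the group's family."""
    if spec.family == "uniform":
        half = spec.a / spec.c
        return rng.uniform(spec.theta - half, spec.theta + half, spec.n)
    if spec.family == "exponential":
        return spec.theta + rng.exponential(1.0 / spec.a, spec.n)
    # lognormal: theta is the log-location, a the log-scale
    return np.exp(spec.theta + spec.a * rng.standard_normal(spec.n))


def sample_censoring(
    spec: GroupSpec, p: float, rng: np.random.Generator
) -> np.ndarray:
    """Draw censoring times targeting nominal censoring rate ``p``."""
    if not 0.0 <= p < 1.0:
        raise ConfigurationError(f"censoring rate must be in [0, 1), got {p}")
    if p == 0.0:
        return np.full(spec.n, np.inf)
    if spec.family == "uniform":
        half = spec.a / spec.c
        hi = spec.theta + half + (1.0 - 2.0 * p) / p
        return rng.uniform(spec.theta - half, hi, spec.n)
    if spec.family == "exponential":
        rate = spec.a * p / (1.0 - p)
        return spec.theta + rng.exponential(1.0 / rate, spec.n)
    u = rng.uniform(-2.0, -2.0 + 2.0 / p, spec.n)
    return np.exp(spec.theta + spec.a * u)


def generate_grouped_data(
    spec: ScenarioSpec, rng: np.random.Generator
) -> GroupedSurvivalData:
    """One replicate: Z = min(X, Y), delta = 1{X <= Y} for every group."""
    samples = []
    for i, g in enumerate(spec.groups):
        x = sample_survival(g, rng)
        y = sample_censoring(g, spec.censor_rate, rng)
        samples.append(
            SurvivalSample(
                times=np.minimum(x, y),
                events=(x <= y).astype(np.int8),
                label=i,
            )
        )
    return GroupedSurvivalData(samples)


def run_simulation(
    spec: ScenarioSpec,
    tests: Sequence[str] = VARIANTS,
    keep_statistics: bool = False,
) -> SimulationResult:
    """Estimate rejection proportions at level ``spec.alpha`` over replicates.

    Every replicate runs all requested variants on the same generated data.
    A replicate that raises :class:`DegenerateDataError` under ANY requested
    variant is redrawn from the next independent RNG stream and counted in
    ``degenerate_count``; if redraws ever exceed ``reps`` the scenario is
    declared ill-posed and aborted.

    Each replicate gets its own child stream of ``spec.seed``, so results are
    reproducible and independent of any execution order.
    """
    for v in tests:
        if v not in VARIANTS:
            raise ConfigurationError(
                f"unknown test variant {v!r}; expected subset of {VARIANTS}"
            )
    root = np.random.SeedSequence(spec.seed)
    rejected = {v: 0 for v in tests}
    stats_kept: dict = {v: [] for v in tests} if keep_statistics else None
    degenerate = 0
    done = 0
    while done < spec.reps:
        rng = np.random.default_rng(root.spawn(1)[0])
        data = generate_grouped_data(spec, rng)
        try:
            results = {v: median_survival_test(data, variant=v) for v in tests}
        except DegenerateDataError:
            degenerate += 1
            if degenerate > spec.reps:
                raise DegenerateDataError(
                    f"scenario {spec.label!r}: more degenerate replicates "
                    f"({degenerate}) than requested reps ({spec.reps}); "
                    "the scenario is ill-posed"
                )
            continue
        for v, res in results.items():
            if res.p_value <= spec.alpha:
                rejected[v] += 1
            if keep_statistics:
                stats_kept[v].append(res.statistic)
        done += 1
    rej = {v: rejected[v] / spec.reps for v in tests}
    se = {v: math.sqrt(r * (1.0 - r) / spec.reps) for v, r in rej.items()}
    return SimulationResult(
        rejection=rej,
        mc_se=se,
        degenerate_count=degenerate,
        reps_done=done,
        spec=spec,
        statistics=(
            {v: np.asarray(s) for v, s in stats_kept.items()}
            if keep_statistics
            else None
        ),
    )


# --------------------------------------------------------------------------
# Scenario catalog: the parameter grid of the six simulation tables.
# Tables 1-3 use the large sample sizes, tables 4-6 the small ones; tables
# (1, 4), (2, 5) and (3, 6) share their distribution rows.  Mixed rows list
# families in the order the row label reads them (e.g. two uniform groups
# first, then two exponential).

_LOG2 = math.log(2.0)
_L10 = math.log(10.0)

# row -> (families, thetas, a, c); c entries are ignored for non-uniform groups
_NULL_EQUAL_ROWS = {
    "uniform": (
        ("uniform",) * 4,
        (10.0,) * 4,
        (4.0,) * 4,
        (2.0,) * 4,
    ),
    "exponential": (
        ("exponential",) * 4,
        (10.0,) * 4,
        (0.1,) * 4,
        (None,) * 4,
    ),
    "lognormal": (
        ("lognormal",) * 4,
        (_L10,) * 4,
        (0.3,) * 4,
        (None,) * 4,
    ),
}

_NULL_UNEQUAL_ROWS = {
    "uniform": (
        ("uniform",) * 4,
        (10.0,) * 4,
        (4.0,) * 4,
        (2.0, 3.0, 4.0, 5.0),
    ),
    "exponential": (
        ("exponential",) * 4,
        (10 - 2 * _LOG2, 10 - 3 * _LOG2, 10 - 4 * _LOG2, 10 - 5 * _LOG2),
        (1 / 2, 1 / 3, 1 / 4, 1 / 5),
        (None,) * 4,
    ),
    "lognormal": (
        ("lognormal",) * 4,
        (_L10,) * 4,
        (0.2, 0.3, 0.4, 0.5),
        (None,) * 4,
    ),
    "uniform_exponential": (
        ("uniform", "uniform", "exponential", "exponential"),
        (10.0, 10.0, 10 - 10 * _LOG2, 10 - 10 * _LOG2),
        (0.1,) * 4,
        (0.01, 0.01, None, None),
    ),
    "uniform_lognormal": (
        ("uniform", "uniform", "lognormal", "lognormal"),
        (10.0, 10.0, _L10, _L10),
        (5.0, 5.0, 0.3, 0.3),
        (2.0, 2.0, None, None),
    ),
    "lognormal_exponential": (
        ("lognormal", "lognormal", "exponential", "exponential"),
        (_L10, _L10, 10 - _LOG2 / 0.3, 10 - _LOG2 / 0.3),
        (0.3,) * 4,
        (None,) * 4,
    ),
}

_POWER_ROWS = {
    "uniform": (
        ("uniform",) * 4,
        (10.0, 10.0, 10.5, 10.0),
        (4.0,) * 4,
        (2.0,) * 4,
    ),
    "exponential": (
        ("exponential",) * 4,
        (10.0,) * 4,
        (0.1, 0.15, 0.15, 0.1),
        (None,) * 4,
    ),
    # thetas are log-locations: population medians 10, 14, 14, 10
    "lognormal": (
        ("lognormal",) * 4,
        (_L10, math.log(14.0), math.log(14.0), _L10),
        (1.0,) * 4,
        (None,) * 4,
    ),
    "uniform_exponential": (
        ("uniform", "uniform", "exponential", "exponential"),
        (10.0, 13.0, 13 - 10 * _LOG2, 10 - 10 * _LOG2),
        (0.1,) * 4,
        (0.01, 0.01, None, None),
    ),
    "uniform_lognormal": (
        ("uniform", "uniform", "lognormal", "lognormal"),
        (10.0, 12.0, 2.5, 2.5),
        (1.0,) * 4,
        (0.2, 0.2, None, None),
    ),
    "lognormal_exponential": (
        ("lognormal", "lognormal", "exponential", "exponential"),
        (_L10, math.log(13.0), 13 - 10 * _LOG2, 10 - 10 * _LOG2),
        (1.0, 1.0, 0.1, 0.1),
        (None,) * 4,
    ),
}

_TABLES = {
    1: (_NULL_EQUAL_ROWS, LARGE_N),
    2: (_NULL_UNEQUAL_ROWS, LARGE_N),
    3: (_POWER_ROWS, LARGE_N),
    4: (_NULL_EQUAL_ROWS, SMALL_N),
    5: (_NULL_UNEQUAL_ROWS, SMALL_N),
    6: (_POWER_ROWS, SMALL_N),
}

CENSOR_RATES = (0.0, 0.1, 0.2, 0.3)


def catalog_keys() -> dict:
    """Valid (table -> row names) of the scenario catalog."""
    return {t: tuple(rows) for t, (rows, _) in _TABLES.items()}


def scenario_catalog(
    table: int,
    row: str,
    censor_rate: float,
    alpha: float = 0.05,
    reps: int = 10_000,
    seed: Optional[int] = None,
) -> ScenarioSpec:
    """Fully populated scenario for one cell of the simulation tables.

    ``table`` in 1..6 picks the distribution block and the sample-size set
    (tables 1-3: n = (100, 150, 150, 200); tables 4-6: n = (20, 25, 25, 30));
    ``row`` names the distribution row; ``censor_rate`` is one of
    0, 0.1, 0.2, 0.3.
    """
    if table not in _TABLES:
        raise ConfigurationError(
            f"unknown table {table!r}; valid tables: {sorted(_TABLES)}"
        )
    rows, sizes = _TABLES[table]
    if row not in rows:
        raise ConfigurationError(
            f"unknown row {row!r} for table {table}; "
            f"valid rows: {sorted(rows)}"
        )
    rates = [abs(censor_rate - r) < 1e-9 for r in CENSOR_RATES]
    if not any(rates):
        raise ConfigurationError(
            f"censoring rate {censor_rate!r} not in catalog; "
            f"valid rates: {CENSOR_RATES}"
        )
    censor_rate = CENSOR_RATES[rates.index(True)]
    fams, thetas, avals, cvals = rows[row]
    groups = tuple(
        GroupSpec(
            family=f,
            theta=th,
            a=a,
            c=c if f == "uniform" else None,
            n=n,
        )
        for f, th, a, c, n in zip(fams, thetas, avals, cvals, sizes)
    )
    return ScenarioSpec(
        groups=groups,
        censor_rate=censor_rate,
        alpha=alpha,
        reps=reps,
        seed=seed,
        label=f"table{table}:{row}:p{censor_rate:g}",
    )
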