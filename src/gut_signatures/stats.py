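"""Exact 2x2 inference and the pre-registered comparison battery.

Two-sided Fisher p-values follow the probability-mass rule: conditioning on
both margins, the p-value sums the central hypergeometric probabilities of
every table whose probability does not exceed the observed table's (with a
relative tolerance of 1e-7 when comparing probabilities, so exact ties are
kept despite floating-point rounding).

The reported odds ratio is the *conditional maximum-likelihood estimate*:
the noncentrality parameter psi maximising the noncentral hypergeometric
likelihood of the observed table given its margins.  Because the noncentral
hypergeometric family is a one-parameter exponential family in log(psi),
the CMLE solves the score equation

    E_psi[A | margins] = a,

which is monotone in log(psi) and is found by bracketed root finding.
Boundary tables (the observed cell at the edge of its support) report an
odds ratio of 0 or +infinity.  This is the same convention as R's
``fisher.test`` and SciPy's ``odds_ratio(kind="conditional")``, which serve
as independent cross-checks in the test suite — never as the implementation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import gammaln, logsumexp

__all__ = [
    "fisher_exact_2x2",
    "conditional_or_ci",
    "hypergeom_enumeration_oracle",
    "ComparisonSpec",
    "ContingencyResult",
    "run_comparison_battery",
    "default_battery",
]

_P_REL_TOL = 1e-7  # ties in hypergeometric mass are equal up to this
_OR_REL_TOL = 1e-8  # relative tolerance of the CMLE root find


def _check_cells(a: int, b: int, c: int, d: int) -> None:
    for name, x in zip("abcd", (a, b, c, d)):
        if x != int(x) or x < 0:
            raise ValueError(f"cell {name} must be a non-negative integer, got {x}")
    if a + b + c + d == 0:
        raise ValueError("all four cells are zero")


def _support(r1: int, r2: int, c1: int) -> np.ndarray:
    lo = max(0, c1 - r2)
    hi = min(r1, c1)
    return np.arange(lo, hi + 1)


def _log_binom(n: int, k: np.ndarray) -> np.ndarray:
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


def _two_sided_p(a: int, b: int, c: int, d: int) -> float:
    """Probability-mass two-sided p for the table given both margins."""
    r1, r2, c1 = a + b, c + d, a + c
    xs = _support(r1, r2, c1)
    logpmf = _log_binom(r1, xs) + _log_binom(r2, c1 - xs) - _log_binom(r1 + r2, np.array([c1]))
    pmf = np.exp(logpmf)
    obs = pmf[xs == a][0]
    p = float(pmf[pmf <= obs * (1 + _P_REL_TOL)].sum())
    return min(p, 1.0)


def _conditional_mean(xs: np.ndarray, logw: np.ndarray, log_psi: float) -> float:
    logterms = logw + xs * log_psi
    return float(np.exp(logsumexp(logterms, b=xs) - logsumexp(logterms)))


def _cmle_or(a: int, b: int, c: int, d: int) -> float:
    r1, r2, c1 = a + b, c + d, a + c
    xs = _support(r1, r2, c1)
    if len(xs) == 1:
        return math.nan  # margins fix the table; psi is not identifiable
    if a == xs[0]:
        return 0.0
    if a == xs[-1]:
        return math.inf
    logw = _log_binom(r1, xs) + _log_binom(r2, c1 - xs)

    def score(t: float) -> float:
        return _conditional_mean(xs, logw, t) - a

    lo, hi = -1.0, 1.0
    while score(lo) > 0:
        lo *= 2
        if lo < -700:
            return 0.0
    while score(hi) < 0:
        hi *= 2
        if hi > 700:
            return math.inf
    t = brentq(score, lo, hi, xtol=1e-12, rtol=4 * _OR_REL_TOL)
    return float(np.exp(t))


def fisher_exact_2x2(a: int, b: int, c: int, d: int) -> tuple[float, float]:
    """Exact two-sided test and conditional-MLE odds ratio for a 2x2 table.

    Parameters
    ----------
    a, b, c, d
        Non-negative cell counts, ``a`` being row 1 / column 1.

    Returns
    -------
    (odds_ratio, p_value)
        The conditional MLE (0 or +inf at boundary tables, NaN when the
        margins admit a single table) and the two-sided exact p-value.
    """
    _check_cells(a, b, c, d)
    return _cmle_or(a, b, c, d), _two_sided_p(a, b, c, d)


def conditional_or_ci(
    a: int, b: int, c: int, d: int, confidence: float = 0.95
) -> tuple[float, float]:
    """Exact conditional (Cornfield-type) confidence interval for the odds
    ratio, by inverting the noncentral hypergeometric tail probabilities."""
    _check_cells(a, b, c, d)
    if not 0 < confidence < 1:
        raise ValueError("confidence must be in (0, 1)")
    alpha = 1 - confidence
    r1, r2, c1 = a + b, c + d, a + c
    xs = _support(r1, r2, c1)
    if len(xs) == 1:
        return 0.0, math.inf
    logw = _log_binom(r1, xs) + _log_binom(r2, c1 - xs)

    def tail(t: float, upper: bool) -> float:
        logterms = logw + xs * t
        mask = xs >= a if upper else xs <= a
        return float(np.exp(logsumexp(logterms[mask]) - logsumexp(logterms)))

    def solve(f: Callable[[float], float]) -> float:
        lo, hi = -1.0, 1.0
        while f(lo) > 0:
            lo *= 2
            if lo < -700:
                return 0.0
        while f(hi) < 0:
            hi *= 2
            if hi > 700:
                return math.inf
        return float(np.exp(brentq(f, lo, hi, xtol=1e-12, rtol=1e-8)))

    lower = 0.0 if a == xs[0] else solve(lambda t: tail(t, upper=True) - alpha / 2)
    upper = math.inf if a == xs[-1] else solve(lambda t: alpha / 2 - tail(t, upper=False))
    return lower, upper


def hypergeom_enumeration_oracle(a: int, b: int, c: int, d: int) -> float:
    """Brute-force two-sided p by exact integer enumeration (tests only).

    Enumerates the full conditional support with exact binomial-coefficient
    arithmetic; a table enters the sum when its (integer) weight does not
    exceed the observed weight inflated by the same 1e-7 relative tolerance
    used by :func:`fisher_exact_2x2`, applied in exact rational arithmetic.
    """
    _check_cells(a, b, c, d)
    n = a + b + c + d
    if n > 1000:
        raise ValueError("enumeration oracle capped at n <= 1000")
    r1, r2, c1 = a + b, c + d, a + c
    lo, hi = max(0, c1 - r2), min(r1, c1)
    weights = {x: math.comb(r1, x) * math.comb(r2, c1 - x) for x in range(lo, hi + 1)}
    w_obs = weights[a]
    # w <= w_obs * (1 + 1e-7), exactly: 1e7 * w <= (1e7 + 1) * w_obs
    num = sum(w for w in weights.values() if 10_000_000 * w <= 10_000_001 * w_obs)
    return num / math.comb(r1 + r2, c1)


# ---------------------------------------------------------------------------
# the comparison battery


@dataclass(frozen=True)
class ComparisonSpec:
    """One named 2x2 comparison over the master annotation table.

    ``row`` and ``col`` are (column, level_1, level_2) triples; annotations
    whose value is neither level are excluded (and logged) — this is how the
    exclusion rules attach to individual comparisons: species of unknown
    aerotolerance drop only from aerotolerance comparisons, multi-site and
    indeterminate species only from body-site comparisons.  ``stratum``
    filters the table before the factors apply.
    """

    comparison_id: str
    row: tuple[str, object, object]
    col: tuple[str, object, object]
    stratum: dict[str, object] = field(default_factory=dict)

    def describe(self) -> str:
        parts = [f"{k}={v!r}" for k, v in self.stratum.items()]
        return "; ".join(parts) if parts else "overall"


@dataclass
class ContingencyResult:
    """A named 2x2 outcome: cells, CMLE odds ratio, exact p, exclusion log."""

    comparison_id: str
    cells: tuple[int, int, int, int]
    odds_ratio: float | None
    p_value: float | None
    excluded: list[tuple[str, str]]
    stratum: str
    degenerate: bool = False


def _evaluate_spec(frame: pd.DataFrame, spec: ComparisonSpec) -> ContingencyResult:
    df = frame
    for col, value in spec.stratum.items():
        allowed = value if isinstance(value, (list, tuple, set)) else (value,)
        df = df[df[col].isin(allowed)]
    excluded: list[tuple[str, str]] = []
    for axis_name, (col, l1, l2) in (("row", spec.row), ("col", spec.col)):
        keep = df[col].isin([l1, l2])
        for sp, val in zip(df.loc[~keep, "species"], df.loc[~keep, col]):
            excluded.append((sp, f"{col}={val!r} outside {axis_name} levels ({l1!r}, {l2!r})"))
        df = df[keep]
    rcol, r1, r2 = spec.row
    ccol, c1, c2 = spec.col
    a = int(((df[rcol] == r1) & (df[ccol] == c1)).sum())
    b = int(((df[rcol] == r1) & (df[ccol] == c2)).sum())
    c = int(((df[rcol] == r2) & (df[ccol] == c1)).sum())
    d = int(((df[rcol] == r2) & (df[ccol] == c2)).sum())
    degenerate = min(a + b, c + d, a + c, b + d) == 0 or (a + b + c + d) == 0
    if degenerate:
        or_, p = None, None
    else:
        or_, p = fisher_exact_2x2(a, b, c, d)
    return ContingencyResult(
        comparison_id=spec.comparison_id,
        cells=(a, b, c, d),
        odds_ratio=or_,
        p_value=p,
        excluded=excluded,
        stratum=spec.describe(),
        degenerate=degenerate,
    )


_DIRECTION = ("direction_class", "enriched", "depleted")
_BACTEREMIA = ("bacteremia", "yes", "no")
_AERO = ("aerotolerance", "aerotolerant", "nonaerotolerant")
_HABITAT = ("habitat_class", "extra-intestinal", "intestinal")
_ORAL = ("oral_flag", True, False)
_MULTI = ("multi_disease", True, False)


def default_battery() -> list[ComparisonSpec]:
    """The pre-registered comparison list mirroring the published analysis:
    direction against bacteremia, body site, and aerotolerance (overall and
    stratified), plus bacteremia against aerotolerance, disease count and
    habitat within each direction class."""
    specs: list[ComparisonSpec] = []

    def add(cid, row, col, **stratum):
        specs.append(ComparisonSpec(cid, row, col, stratum))

    strata_all = {
        "habitat_intestinal": {"habitat_class": "intestinal"},
        "habitat_extra": {"habitat_class": "extra-intestinal"},
        "aerotolerant": {"aerotolerance": "aerotolerant"},
        "nonaerotolerant": {"aerotolerance": "nonaerotolerant"},
        "one_disease": {"multi_disease": False},
        "multi_disease": {"multi_disease": True},
    }
    add("direction_bacteremia", _DIRECTION, _BACTEREMIA)
    for name, stratum in strata_all.items():
        add(f"direction_bacteremia__{name}", _DIRECTION, _BACTEREMIA, **stratum)

    site_strata = {
        "bacteremia_yes": {"bacteremia": "yes"},
        "bacteremia_no": {"bacteremia": "no"},
        "aerotolerant": {"aerotolerance": "aerotolerant"},
        "nonaerotolerant": {"aerotolerance": "nonaerotolerant"},
        "one_disease": {"multi_disease": False},
        "multi_disease": {"multi_disease": True},
    }
    add("direction_extraintestinal", _DIRECTION, _HABITAT)
    for name, stratum in site_strata.items():
        add(f"direction_extraintestinal__{name}", _DIRECTION, _HABITAT, **stratum)
    add("direction_oral", _DIRECTION, _ORAL,
        habitat_class=("intestinal", "extra-intestinal"))
    for name, stratum in site_strata.items():
        add(f"direction_oral__{name}", _DIRECTION, _ORAL,
            habitat_class=("intestinal", "extra-intestinal"), **stratum)

    add("direction_aerotolerant", _DIRECTION, _AERO)
    add("direction_aerotolerant__one_disease", _DIRECTION, _AERO, multi_disease=False)
    add("direction_aerotolerant__multi_disease", _DIRECTION, _AERO, multi_disease=True)

    for direction in ("enriched", "depleted"):
        add(f"aerotolerance_bacteremia__{direction}", _AERO, _BACTEREMIA,
            direction_class=direction)
        add(f"multidisease_bacteremia__{direction}", _MULTI, _BACTEREMIA,
            direction_class=direction)
        add(f"habitat_bacteremia__{direction}", _HABITAT, _BACTEREMIA,
            direction_class=direction)
        add(f"habitat_aerotolerant__{direction}", _HABITAT, _AERO,
            direction_class=direction)
    return specs


def run_comparison_battery(
    annotations: Sequence, specs: Sequence[ComparisonSpec] | None = None
) -> list[ContingencyResult]:
    """Evaluate every comparison spec against the master annotations.

    ``annotations`` may be a sequence of :class:`SpeciesAnnotation` or an
    equivalent DataFrame.  Each spec's exclusions are applied independently
    and recorded in its result.
    """
    if specs is None:
        specs = default_battery()
    if isinstance(annotations, pd.DataFrame):
        frame = annotations
    else:
        from gut_signatures.annotate import annotations_to_frame

        if not len(annotations):
            raise ValueError("no annotations provided")
        frame = annotations_to_frame(annotations)
    return [_evaluate_spec(frame, spec) for spec in specs]


def results_to_frame(results: Sequence[ContingencyResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "comparison_id": [r.comparison_id for r in results],
            "a": [r.cells[0] for r in results],
            "b": [r.cells[1] for r in results],
            "c": [r.cells[2] for r in results],
            "d": [r.cells[3] for r in results],
            "odds_ratio": [r.odds_ratio for r in results],
            "p_value": [r.p_value for r in results],
            "n_excluded": [len(r.excluded) for r in results],
            "stratum": [r.stratum for r in results],
            "degenerate": [r.degenerate for r in results],
        }
    )
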