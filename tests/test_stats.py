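"""Exact 2x2 machinery: p-value conventions, conditional-MLE odds ratio,
confidence intervals, and the comparison battery."""

import math

import numpy as np
import pytest
from scipy.stats import fisher_exact as scipy_fisher
from scipy.stats.contingency import odds_ratio as scipy_odds_ratio

from gut_signatures.stats import (
    ComparisonSpec,
    conditional_or_ci,
    default_battery,
    fisher_exact_2x2,
    hypergeom_enumeration_oracle,
    run_comparison_battery,
)


@pytest.mark.parametrize(
    "cells,expected_or,expected_p",
    [
        ((1, 1, 1, 1), 1.0, 1.0),
        # support {0,1,2} with central probabilities 1/6, 4/6, 1/6:
        # tables at mass <= observed are the two extremes -> p = 1/3
        ((2, 0, 0, 2), math.inf, 1 / 3),
        ((0, 5, 5, 0), 0.0, pytest.approx(1 / 126)),
    ],
    ids=["balanced", "diagonal", "antidiagonal"],
)
def test_reference_tables(cells, expected_or, expected_p):
    or_, p = fisher_exact_2x2(*cells)
    if math.isfinite(expected_or):
        assert or_ == pytest.approx(expected_or, rel=1e-7)
    else:
        assert or_ == expected_or
    assert p == pytest.approx(expected_p)


def test_direction_bacteremia_table_rounds_to_published_or():
    """The direction x bacteremia table assembled from the published totals."""
    or_, p = fisher_exact_2x2(105, 58, 16, 82)
    assert round(or_, 1) == 9.2
    assert p == pytest.approx(1.1e-14, rel=0.05)


def test_balanced_product_gives_unit_or():
    # a*d == b*c with all cells positive forces OR = 1
    or_, _ = fisher_exact_2x2(6, 3, 4, 2)
    assert or_ == pytest.approx(1.0, abs=1e-9)


def test_invalid_cells_rejected():
    with pytest.raises(ValueError):
        fisher_exact_2x2(0, 0, 0, 0)
    with pytest.raises(ValueError):
        fisher_exact_2x2(-1, 2, 3, 4)
    with pytest.raises(ValueError):
        hypergeom_enumeration_oracle(600, 200, 150, 100)


def test_oracle_transposition_symmetry():
    assert hypergeom_enumeration_oracle(0, 5, 5, 0) == pytest.approx(
        hypergeom_enumeration_oracle(5, 0, 0, 5)
    )


@pytest.mark.parametrize(
    "cells",
    [(105, 58, 16, 82), (44, 8, 61, 50), (3, 7, 9, 2), (12, 0, 3, 9), (1, 9, 11, 3)],
)
def test_agreement_with_scipy(cells):
    """Independent cross-check of both routes against scipy's implementation."""
    or_, p = fisher_exact_2x2(*cells)
    table = [[cells[0], cells[1]], [cells[2], cells[3]]]
    assert p == pytest.approx(scipy_fisher(table).pvalue, rel=1e-9)
    sp_or = scipy_odds_ratio(table, kind="conditional").statistic
    if math.isinf(or_):
        assert math.isinf(sp_or)
    else:
        assert or_ == pytest.approx(sp_or, rel=1e-6)
    ci = conditional_or_ci(*cells)
    sp_ci = scipy_odds_ratio(table, kind="conditional").confidence_interval()
    assert ci[0] == pytest.approx(sp_ci.low, rel=1e-4, abs=1e-12)
    if math.isinf(ci[1]):
        assert math.isinf(sp_ci.high)
    else:
        assert ci[1] == pytest.approx(sp_ci.high, rel=1e-4)


def test_symmetry_invariants():
    """p and OR invariant under full transpose; OR inverts under row swap."""
    for cells in [(7, 2, 3, 11), (5, 5, 1, 9), (2, 8, 8, 2)]:
        a, b, c, d = cells
        or1, p1 = fisher_exact_2x2(a, b, c, d)
        or2, p2 = fisher_exact_2x2(d, c, b, a)  # simultaneous row+col swap
        assert p1 == pytest.approx(p2)
        assert or1 == pytest.approx(or2, rel=1e-6)
        or3, p3 = fisher_exact_2x2(c, d, a, b)  # row swap only
        assert p1 == pytest.approx(p3)
        assert or3 == pytest.approx(1 / or1, rel=1e-6)


def test_cmle_monotone_in_a_with_margins_fixed():
    r1, r2, c1 = 12, 10, 8
    previous = -1.0
    for a in range(max(0, c1 - r2) + 1, min(r1, c1)):
        or_, _ = fisher_exact_2x2(a, r1 - a, c1 - a, r2 - (c1 - a))
        assert or_ > previous
        previous = or_


def test_cmle_within_factor_two_of_sample_or_small_sweep():
    """For all-positive tables with margins <= 12 the CMLE stays within a
    factor of two of the sample cross-product ratio."""
    for r1 in range(2, 13):
        for r2 in range(2, 13):
            for c1 in range(1, min(12, r1 + r2)):
                if r1 + r2 - c1 > 12:
                    continue
                for a in range(max(1, c1 - r2 + 1), min(r1, c1)):
                    b, c, d = r1 - a, c1 - a, r2 - (c1 - a)
                    if min(b, c, d) < 1:
                        continue
                    sample = a * d / (b * c)
                    cmle, _ = fisher_exact_2x2(a, b, c, d)
                    assert cmle <= 2 * sample + 1e-12
                    assert cmle >= sample / 2 - 1e-12


def test_degenerate_support_returns_nan_or():
    or_, p = fisher_exact_2x2(5, 0, 5, 0)  # margins admit a single table
    assert math.isnan(or_)
    assert p == 1.0


def test_battery_default_spec_cells(master_annotations):
    results = run_comparison_battery(master_annotations)
    by_id = {r.comparison_id: r for r in results}
    assert by_id["direction_bacteremia"].cells == (105, 58, 16, 82)
    assert by_id["multidisease_bacteremia__enriched"].cells == (44, 8, 61, 50)
    assert by_id["multidisease_bacteremia__enriched"].p_value == pytest.approx(
        2.0e-4, rel=0.05
    )
    # the 12 inconsistent species are excluded from direction comparisons
    assert len(by_id["direction_bacteremia"].excluded) == 12
    assert all(
        reason.startswith("direction_class=")
        for _, reason in by_id["direction_bacteremia"].excluded
    )


def test_battery_degenerate_stratum_flagged(master_annotations):
    spec = ComparisonSpec(
        "empty_stratum",
        ("direction_class", "enriched", "depleted"),
        ("bacteremia", "yes", "no"),
        {"assigned_site": "does-not-exist"},
    )
    (result,) = run_comparison_battery(master_annotations, [spec])
    assert result.degenerate
    assert result.odds_ratio is None and result.p_value is None


def test_battery_covers_preregistered_comparisons():
    ids = {s.comparison_id for s in default_battery()}
    for required in [
        "direction_bacteremia",
        "direction_extraintestinal",
        "direction_oral",
        "direction_aerotolerant",
        "aerotolerance_bacteremia__enriched",
        "aerotolerance_bacteremia__depleted",
        "multidisease_bacteremia__enriched",
        "habitat_bacteremia__enriched",
    ]:
        assert required in ids
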