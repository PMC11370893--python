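"""Body-site profiles, the primary designation rule, fallbacks, and
secondary-evidence resolution."""

import math

import numpy as np
import pandas as pd
import pytest

from gut_signatures.io import SITES, AbundanceMatrix
from gut_signatures.niche import (
    SiteProfile,
    assign_body_site,
    compute_site_profiles,
    resolve_with_secondary_evidence,
)


def matrix_from(values: dict[str, list[float]], sites: list[str]) -> AbundanceMatrix:
    samples = [f"s{i}" for i in range(len(sites))]
    df = pd.DataFrame(values, index=samples).T
    df.columns = samples
    return AbundanceMatrix(abundances=df, sites=pd.Series(sites, index=samples))


def profile(freqs: dict[str, float], abunds: dict[str, float], species="X") -> SiteProfile:
    f = {s: freqs.get(s, 0.0) for s in SITES}
    a = {s: abunds.get(s, 0.0) for s in SITES}
    return SiteProfile(species=species, frequency=f, mean_abundance=a)


def test_profiles_match_hand_computation():
    # two samples per site; species X detected in 1 of 2 gut samples
    sites = ["gut", "gut", "oral", "oral", "vagina", "vagina", "skin", "skin"]
    values = {
        "X": [0.04, 0.0, 0.2, 0.1, 0.0, 0.0, 0.0, 0.0],
        "Y": [0.5, 0.5, 0.0, 0.0, 0.01, 0.0, 0.0, 0.0],
        "Z": [0.0] * 8,
    }
    profiles = {p.species: p for p in compute_site_profiles(matrix_from(values, sites))}
    assert profiles["X"].frequency == {"gut": 0.5, "oral": 1.0, "vagina": 0.0, "skin": 0.0}
    assert profiles["X"].mean_abundance["gut"] == pytest.approx(0.02)
    assert profiles["X"].mean_abundance["oral"] == pytest.approx(0.15)
    assert profiles["Y"].frequency["vagina"] == 0.5
    assert profiles["Y"].mean_abundance["vagina"] == pytest.approx(0.005)
    assert all(profiles["Z"].frequency[s] == 0.0 for s in SITES)
    assert all(profiles["Z"].mean_abundance[s] == 0.0 for s in SITES)


def test_profiles_match_per_sample_brute_force():
    rng = np.random.default_rng(21)
    sites = ["gut"] * 5 + ["oral"] * 4 + ["vagina"] * 3 + ["skin"] * 2
    values = {f"sp{i}": (rng.random(len(sites)) * (rng.random(len(sites)) < 0.5) / 20).tolist()
              for i in range(6)}
    m = matrix_from(values, sites)
    profiles = {p.species: p for p in compute_site_profiles(m)}
    for species, row in values.items():
        for site in SITES:
            idx = [i for i, s in enumerate(sites) if s == site]
            f = sum(row[i] > 0 for i in idx) / len(idx)
            a = sum(row[i] for i in idx) / len(idx)
            assert profiles[species].frequency[site] == pytest.approx(f)
            assert profiles[species].mean_abundance[site] == pytest.approx(a)


def test_detection_threshold_applies_to_frequency():
    m = matrix_from({"X": [0.004, 0.5]}, ["gut", "gut"])
    (p,) = compute_site_profiles(m, detection_threshold=0.01)
    assert p.frequency["gut"] == 0.5


def test_gut_oral_ratio_conventions():
    assert profile({"gut": 1}, {"gut": 0.1, "oral": 0.01}).gut_oral_ratio == pytest.approx(10)
    assert profile({"gut": 1}, {"gut": 0.1}).gut_oral_ratio == math.inf
    assert math.isnan(profile({"skin": 1}, {"skin": 0.2}).gut_oral_ratio)


def test_primary_rule_assigns_concordant_winner():
    p = profile({"gut": 0.9, "oral": 0.2}, {"gut": 0.02, "oral": 0.001})
    a = assign_body_site(p)  # ratio 20 > 10: unambiguous gut
    assert (a.assigned_site, a.confidence_flag) == ("gut", "primary-rule")


def test_fallback_not_detected():
    a = assign_body_site(profile({}, {}))
    assert (a.assigned_site, a.confidence_flag) == ("indeterminate", "not-detected")


def test_fallback_low_frequency():
    a = assign_body_site(profile({"gut": 0.03, "oral": 0.01}, {"gut": 0.01}))
    assert a.confidence_flag == "low-frequency"


def test_fallback_discordant():
    p = profile({"gut": 0.9, "oral": 0.5}, {"gut": 0.001, "oral": 0.05})
    assert assign_body_site(p).confidence_flag == "discordant"


def test_fallback_ambiguous_gut_oral():
    p = profile({"gut": 0.9, "oral": 0.5}, {"gut": 0.02, "oral": 0.01})  # ratio 2
    assert assign_body_site(p).confidence_flag == "ambiguous-gut-oral"


def test_ratio_band_does_not_affect_other_sites():
    p = profile({"vagina": 0.9, "gut": 0.2, "oral": 0.2},
                {"vagina": 0.1, "gut": 0.01, "oral": 0.01})  # gut/oral ratio 1
    a = assign_body_site(p)
    assert (a.assigned_site, a.confidence_flag) == ("vagina", "primary-rule")


def test_monotonicity_toward_gut():
    base = profile({"gut": 0.6, "oral": 0.5}, {"gut": 0.011, "oral": 0.01})
    boosted = profile({"gut": 0.9, "oral": 0.5}, {"gut": 0.2, "oral": 0.01})
    a0 = assign_body_site(base)  # ambiguous: ratio 1.1
    a1 = assign_body_site(boosted)  # ratio 20
    assert a0.assigned_site != "gut"
    assert (a1.assigned_site, a1.confidence_flag) == ("gut", "primary-rule")


def evidence(*rows):
    return pd.DataFrame(rows, columns=["species", "source", "claimed_site", "weight"])


def test_secondary_evidence_resolution():
    indeterminate = assign_body_site(profile({}, {}))
    resolved = resolve_with_secondary_evidence(
        indeterminate, evidence(("X", "eHOMD", "oral", 1))
    )
    assert (resolved.assigned_site, resolved.confidence_flag) == ("oral", "secondary-evidence")
    assert resolved.evidence_source == "external-evidence-table"


def test_secondary_evidence_tie_gives_multi():
    indeterminate = assign_body_site(profile({}, {}))
    resolved = resolve_with_secondary_evidence(
        indeterminate,
        evidence(("X", "eHOMD", "oral", 1), ("X", "isolation", "gut", 1)),
    )
    assert resolved.assigned_site == "multi"


def test_secondary_evidence_weighting_breaks_tie():
    indeterminate = assign_body_site(profile({}, {}))
    resolved = resolve_with_secondary_evidence(
        indeterminate,
        evidence(("X", "cohort-profile", "gut", 2), ("X", "eHOMD", "oral", 1)),
    )
    assert resolved.assigned_site == "gut"


def test_secondary_evidence_no_rows_is_noop():
    indeterminate = assign_body_site(profile({}, {}))
    resolved = resolve_with_secondary_evidence(indeterminate, evidence(("Y", "e", "gut", 1)))
    assert resolved == indeterminate


def test_secondary_evidence_unknown_site_rejected():
    indeterminate = assign_body_site(profile({}, {}))
    with pytest.raises(Exception, match="unknown site"):
        resolve_with_secondary_evidence(indeterminate, evidence(("X", "e", "liver", 1)))


def test_sample_permutation_invariance():
    sites = ["gut", "oral", "gut", "oral"]
    values = {"X": [0.2, 0.01, 0.1, 0.0]}
    m = matrix_from(values, sites)
    perm = [2, 0, 3, 1]
    m2 = matrix_from({"X": [values["X"][i] for i in perm]}, [sites[i] for i in perm])
    (p1,), (p2,) = compute_site_profiles(m), compute_site_profiles(m2)
    assert p1.frequency == p2.frequency
    assert p1.mean_abundance == pytest.approx(p2.mean_abundance)
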