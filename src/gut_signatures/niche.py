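"""Assign each species a typical body site from multi-site abundance profiles.

The primary rule mirrors standard criteria for calling a species "oral",
generalised to four sites: compute, per site, the detection *frequency*
(fraction of the site's samples in which the species is seen) and the
*average relative abundance* (mean over all the site's samples, zeros
included).  The site that wins on **both** statistics is designated the
species' typical site, provided the winning frequency is at least 5% and the
gut/oral abundance ratio does not sit in the ambiguous band [0.1, 10].

Species failing the primary rule are flagged, in fixed precedence order:

``not-detected`` -> ``low-frequency`` -> ``discordant`` -> ``ambiguous-gut-oral``

and may then be resolved by weighted secondary evidence (curated database
membership, reference gut-cohort profiles, isolation sources).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from gut_signatures.io import SITES, AbundanceMatrix, SchemaError

#: sites eligible as secondary-evidence claims (the reference profile's four
#: sites plus the "other"/food-origin bucket of curated sources)
EVIDENCE_SITES = set(SITES) | {"other"}


@dataclass(frozen=True)
class SiteProfile:
    """Per-site detection frequency and mean relative abundance."""

    species: str
    frequency: dict[str, float]  # site -> fraction of samples with detection
    mean_abundance: dict[str, float]  # site -> mean over all samples, zeros included

    @property
    def gut_oral_ratio(self) -> float:
        """Mean-abundance ratio gut/oral; +inf when oral is 0 and gut > 0,
        NaN when both are 0."""
        a_gut = self.mean_abundance.get("gut", 0.0)
        a_oral = self.mean_abundance.get("oral", 0.0)
        if a_oral == 0.0:
            return math.inf if a_gut > 0 else math.nan
        return a_gut / a_oral


@dataclass(frozen=True)
class SiteAssignment:
    """Outcome of the body-site decision for one species."""

    species: str
    assigned_site: str  # gut|oral|vagina|skin|multi|indeterminate
    confidence_flag: str  # primary-rule | not-detected | low-frequency |
    #                       discordant | ambiguous-gut-oral | secondary-evidence
    evidence_source: str = "HMP-like-profile"


def compute_site_profiles(
    matrix: AbundanceMatrix, detection_threshold: float = 0.0
) -> list[SiteProfile]:
    """Per-species, per-site frequency and mean relative abundance.

    ``frequency`` counts samples with abundance strictly above
    ``detection_threshold`` (default 0: any non-zero abundance is a
    detection); ``mean_abundance`` averages over *all* the site's samples so
    absences pull the mean down.
    """
    if not matrix.samples:
        raise SchemaError("abundance matrix has no samples")
    values = matrix.abundances
    site_labels = matrix.sites.loc[values.columns]
    freq = (values > detection_threshold).T.groupby(site_labels.values).mean().T
    mean_ab = values.T.groupby(site_labels.values).mean().T

    profiles = []
    for species in values.index:
        profiles.append(
            SiteProfile(
                species=str(species),
                frequency={s: float(freq.loc[species].get(s, 0.0)) for s in SITES},
                mean_abundance={s: float(mean_ab.loc[species].get(s, 0.0)) for s in SITES},
            )
        )
    return profiles


def _argmax_site(stats: dict[str, float]) -> str:
    # deterministic tie-break: canonical site order
    best = max(stats.get(s, 0.0) for s in SITES)
    for s in SITES:
        if stats.get(s, 0.0) == best:
            return s
    raise AssertionError("unreachable")


def assign_body_site(
    profile: SiteProfile,
    min_frequency: float = 0.05,
    ratio_bounds: tuple[float, float] = (0.1, 10.0),
) -> SiteAssignment:
    """Apply the primary designation rule with ordered fallback flags.

    The species is assigned the site that maximises *both* frequency and
    mean abundance, provided that maximum frequency is at least
    ``min_frequency`` and — when the winner is gut or oral — the gut/oral
    abundance ratio lies outside ``ratio_bounds``.  Otherwise the assignment
    is ``indeterminate`` with the first matching flag in the order
    not-detected, low-frequency, discordant, ambiguous-gut-oral.
    """
    freqs = profile.frequency
    max_f = max(freqs.get(s, 0.0) for s in SITES)
    if max_f == 0.0:
        return SiteAssignment(profile.species, "indeterminate", "not-detected")
    if max_f < min_frequency:
        return SiteAssignment(profile.species, "indeterminate", "low-frequency")
    winner_f = _argmax_site(freqs)
    winner_a = _argmax_site(profile.mean_abundance)
    if winner_f != winner_a:
        return SiteAssignment(profile.species, "indeterminate", "discordant")
    if winner_f in ("gut", "oral"):
        ratio = profile.gut_oral_ratio
        if not math.isnan(ratio) and ratio_bounds[0] <= ratio <= ratio_bounds[1]:
            return SiteAssignment(profile.species, "indeterminate", "ambiguous-gut-oral")
    return SiteAssignment(profile.species, winner_f, "primary-rule")


def resolve_with_secondary_evidence(
    assignment: SiteAssignment, evidence: pd.DataFrame
) -> SiteAssignment:
    """Resolve an indeterminate assignment by weighted evidence voting.

    ``evidence`` has columns (species, source, claimed_site, weight).  Site
    weights are summed over the species' rows; a unique top site wins with
    flag ``secondary-evidence``, a tie yields ``multi``, and with no
    applicable rows the assignment is returned unchanged.
    """
    if assignment.assigned_site != "indeterminate":
        return assignment
    required = {"species", "source", "claimed_site", "weight"}
    missing = required - set(evidence.columns)
    if missing:
        raise SchemaError(f"evidence table missing column(s) {sorted(missing)}")
    bad = set(evidence["claimed_site"]) - EVIDENCE_SITES
    if bad:
        raise SchemaError(f"unknown site label(s) in evidence: {sorted(bad)}")
    rows = evidence[evidence["species"] == assignment.species]
    if rows.empty:
        return assignment
    votes = rows.groupby("claimed_site")["weight"].apply(
        lambda w: w.astype(float).sum()
    )
    top = votes.max()
    winners = sorted(votes.index[votes == top])
    if len(winners) > 1:
        return SiteAssignment(assignment.species, "multi",
                              "secondary-evidence", "external-evidence-table")
    return SiteAssignment(assignment.species, winners[0],
                          "secondary-evidence", "external-evidence-table")


def assign_all(
    matrix: AbundanceMatrix,
    evidence: pd.DataFrame | None = None,
    detection_threshold: float = 0.0,
    min_frequency: float = 0.05,
    ratio_bounds: tuple[float, float] = (0.1, 10.0),
) -> list[SiteAssignment]:
    """Profile every species in ``matrix`` and assign sites end to end."""
    out = []
    for profile in compute_site_profiles(matrix, detection_threshold):
        assignment = assign_body_site(profile, min_frequency, ratio_bounds)
        if evidence is not None and assignment.assigned_site == "indeterminate":
            assignment = resolve_with_secondary_evidence(assignment, evidence)
        out.append(assignment)
    return out
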