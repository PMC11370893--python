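"""Consolidate per-study signature records into per-species consensus.

A species reported enriched in at least one disease and depleted in at least
one other is *inconsistent*; otherwise its direction class is the shared
direction.  Disease counting follows two conventions:

* a disease reported by several studies with the same direction counts once;
* the pooled multiple-disease label ``MD`` is one disease on input, but a
  species whose only disease is MD is assigned ``n_diseases = 2`` — a lower
  bound, since an MD association implies at least two diseases.
"""

from __future__ import annotations

import math
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from gut_signatures.io import SignatureRecord, canonical_species
from gut_signatures.util import percentage

MD_LABEL = "MD"


@dataclass(frozen=True)
class SpeciesConsensus:
    """Consolidated view of one species across all studies and diseases."""

    species: str
    diseases_enriched: frozenset[str]
    diseases_depleted: frozenset[str]
    direction_class: str  # enriched | depleted | inconsistent
    n_diseases: int
    multi_disease: bool


def _disease_count(diseases: frozenset[str]) -> int:
    if diseases == frozenset({MD_LABEL}):
        return 2  # MD alone implies association with >= 2 diseases
    return len(diseases)


def consolidate(
    records: Iterable[SignatureRecord],
    synonyms: Mapping[str, str] | None = None,
) -> list[SpeciesConsensus]:
    """Collapse signature records into one consensus per canonical species.

    Duplicate (study, disease, direction) assertions for a species are
    idempotent.  The three direction classes partition the species set.
    """
    enriched: dict[str, set[str]] = defaultdict(set)
    depleted: dict[str, set[str]] = defaultdict(set)
    for rec in records:
        name = canonical_species(rec.species, synonyms)
        if rec.direction == "enriched":
            enriched[name].add(rec.disease)
        else:
            depleted[name].add(rec.disease)

    out: list[SpeciesConsensus] = []
    for species in sorted(set(enriched) | set(depleted)):
        enr = frozenset(enriched.get(species, set()))
        dep = frozenset(depleted.get(species, set()))
        if enr and dep:
            direction = "inconsistent"
        elif enr:
            direction = "enriched"
        else:
            direction = "depleted"
        n = _disease_count(enr | dep)
        out.append(
            SpeciesConsensus(
                species=species,
                diseases_enriched=enr,
                diseases_depleted=dep,
                direction_class=direction,
                n_diseases=n,
                multi_disease=n >= 2,
            )
        )
    return out


def shared_signatures(
    consensus: Sequence[SpeciesConsensus],
    n_total_diseases: int = 6,
    threshold_fraction: float = 0.5,
) -> tuple[set[str], set[str]]:
    """Species enriched (resp. depleted) in at least a fraction of diseases.

    A species qualifies when ``n_diseases >= ceil(threshold_fraction *
    n_total_diseases)`` and its direction class is pure; inconsistent
    species are never returned.
    """
    if n_total_diseases < 1:
        raise ValueError("n_total_diseases must be >= 1")
    if not 0 < threshold_fraction <= 1:
        raise ValueError("threshold_fraction must be in (0, 1]")
    cut = math.ceil(threshold_fraction * n_total_diseases)
    enr = {c.species for c in consensus
           if c.direction_class == "enriched" and c.n_diseases >= cut}
    dep = {c.species for c in consensus
           if c.direction_class == "depleted" and c.n_diseases >= cut}
    return enr, dep


@dataclass
class OverlapHistogram:
    """How many species a disease's studies agree on.

    ``counts[k-1]`` is the number of species reported by exactly ``k`` of
    the disease's studies; percentages are printed at one decimal.
    """

    disease: str
    n_studies: int
    counts: list[int]
    percentages: list[float] = field(init=False)

    def __post_init__(self) -> None:
        total = sum(self.counts)
        self.percentages = [percentage(c, total) for c in self.counts]

    @property
    def n_species(self) -> int:
        return sum(self.counts)


def study_overlap_histogram(
    records: Iterable[SignatureRecord], disease: str
) -> OverlapHistogram:
    """Cross-study reproducibility histogram for one disease.

    Counts, for each ``k`` from 1 to the number of studies reporting the
    disease, how many unique species appear in exactly ``k`` of them.
    """
    studies_per_species: dict[str, set[str]] = defaultdict(set)
    studies: set[str] = set()
    for rec in records:
        if rec.disease == disease:
            studies_per_species[rec.species].add(rec.study_id)
            studies.add(rec.study_id)
    if not studies:
        raise ValueError(f"no study reports disease {disease!r}")
    k_max = len(studies)
    counts = [0] * k_max
    for members in studies_per_species.values():
        counts[len(members) - 1] += 1
    return OverlapHistogram(disease=disease, n_studies=k_max, counts=counts)
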