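"""Join consensus, site assignments, and curated phenotype tables into the
master per-species annotation, and summarise it in the two-direction table.

Bacteremia is a curated literature flag: "yes" means at least one reported
positive blood culture, and species absent from the curated table default to
"no" (absence of a report, not evidence of absence).  Aerotolerance maps
facultative/aerotolerant anaerobes and aerobes to ``aerotolerant``, obligate
anaerobes to ``nonaerotolerant``, and anything else (including "unclassified
anaerobe") to ``unknown``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from gut_signatures.compile import SpeciesConsensus
from gut_signatures.io import SchemaError
from gut_signatures.niche import SiteAssignment
from gut_signatures.util import percentage

_AEROTOLERANT = {
    "aerobe",
    "facultative anaerobe",
    "aerotolerant anaerobe",
    "facultative/aerotolerant anaerobe",
    "aerotolerant",
}
_NONAEROTOLERANT = {"obligate anaerobe", "nonaerotolerant"}


def classify_aerotolerance(category: str | None) -> str:
    if category is None or pd.isna(category):
        return "unknown"
    cat = str(category).strip().casefold()
    if cat in _AEROTOLERANT:
        return "aerotolerant"
    if cat in _NONAEROTOLERANT:
        return "nonaerotolerant"
    return "unknown"


def habitat_of(assigned_site: str) -> str:
    """intestinal for gut; oral/vagina/skin/other are extra-intestinal;
    multi and indeterminate pass through."""
    if assigned_site == "gut":
        return "intestinal"
    if assigned_site in ("oral", "vagina", "skin", "other"):
        return "extra-intestinal"
    if assigned_site in ("multi", "indeterminate"):
        return assigned_site
    raise SchemaError(f"unknown assigned site {assigned_site!r}")


@dataclass(frozen=True)
class SpeciesAnnotation:
    """One row of the master annotated table."""

    species: str
    direction_class: str
    n_diseases: int
    multi_disease: bool
    bacteremia: str  # yes | no
    aerotolerance: str  # aerotolerant | nonaerotolerant | unknown
    assigned_site: str
    habitat_class: str  # intestinal | extra-intestinal | multi | indeterminate
    oral_flag: bool


def _keyed(table: pd.DataFrame, key: str, what: str) -> pd.DataFrame:
    if table[key].duplicated().any():
        dups = table[key][table[key].duplicated()].unique().tolist()
        raise SchemaError(f"duplicate species key(s) in {what} table: {dups}")
    return table.set_index(key)


def merge_annotations(
    consensus: Sequence[SpeciesConsensus],
    assignments: Iterable[SiteAssignment],
    bacteremia_table: pd.DataFrame,
    aerotolerance_table: pd.DataFrame,
) -> list[SpeciesAnnotation]:
    """Loss-free join keyed on canonical species names.

    Every consensus species appears exactly once in the output.  Missing
    bacteremia rows default to "no", missing aerotolerance to "unknown",
    and species without a site assignment are ``indeterminate``.
    """
    assign_by_species: dict[str, SiteAssignment] = {}
    for a in assignments:
        if a.species in assign_by_species:
            raise SchemaError(f"duplicate species key(s) in assignment table: "
                              f"[{a.species!r}]")
        assign_by_species[a.species] = a
    bact = _keyed(bacteremia_table, "species", "bacteremia")
    aero = _keyed(aerotolerance_table, "species", "aerotolerance")

    out: list[SpeciesAnnotation] = []
    for cons in consensus:
        sp = cons.species
        bacteremia = "no"
        if sp in bact.index:
            bacteremia = "yes" if str(bact.loc[sp].iloc[0]).strip().casefold() in (
                "yes", "true", "1") else "no"
        aerotolerance = "unknown"
        if sp in aero.index:
            aerotolerance = classify_aerotolerance(aero.loc[sp].iloc[0])
        site = assign_by_species[sp].assigned_site if sp in assign_by_species \
            else "indeterminate"
        out.append(
            SpeciesAnnotation(
                species=sp,
                direction_class=cons.direction_class,
                n_diseases=cons.n_diseases,
                multi_disease=cons.multi_disease,
                bacteremia=bacteremia,
                aerotolerance=aerotolerance,
                assigned_site=site,
                habitat_class=habitat_of(site),
                oral_flag=site == "oral",
            )
        )
    return out


def annotations_to_frame(annotations: Sequence[SpeciesAnnotation]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "species": [a.species for a in annotations],
            "direction_class": [a.direction_class for a in annotations],
            "n_diseases": [a.n_diseases for a in annotations],
            "multi_disease": [a.multi_disease for a in annotations],
            "bacteremia": [a.bacteremia for a in annotations],
            "aerotolerance": [a.aerotolerance for a in annotations],
            "assigned_site": [a.assigned_site for a in annotations],
            "habitat_class": [a.habitat_class for a in annotations],
            "oral_flag": [a.oral_flag for a in annotations],
        }
    )


#: (row label, predicate) pairs of the summary's category rows
_CATEGORY_ROWS = (
    ("total", lambda a: True),
    ("bacteremia", lambda a: a.bacteremia == "yes"),
    ("aerotolerant", lambda a: a.aerotolerance == "aerotolerant"),
    ("oral", lambda a: a.oral_flag),
    ("extra_intestinal", lambda a: a.habitat_class == "extra-intestinal"),
)

_COLUMNS = ("total", "one_disease", "multi_disease")


def table1_summary(annotations: Sequence[SpeciesAnnotation]) -> pd.DataFrame:
    """Counts and one-decimal percentages by direction and disease-count
    stratum for each phenotype category.

    Inconsistent species are excluded; percentages are relative to the
    column's species total (the ``total`` row).
    """
    if not annotations:
        raise ValueError("no annotations to summarise")
    rows = []
    for direction in ("enriched", "depleted"):
        pool = [a for a in annotations if a.direction_class == direction]
        strata = {
            "total": pool,
            "one_disease": [a for a in pool if not a.multi_disease],
            "multi_disease": [a for a in pool if a.multi_disease],
        }
        for label, pred in _CATEGORY_ROWS:
            for col in _COLUMNS:
                members = [a for a in strata[col] if pred(a)]
                denom = len(strata[col])
                rows.append(
                    {
                        "direction": direction,
                        "stratum": col,
                        "category": label,
                        "count": len(members),
                        "percent": percentage(len(members), denom) if denom else float("nan"),
                    }
                )
    df = pd.DataFrame(rows)
    return df.set_index(["category", "direction", "stratum"]).sort_index()


def summary_cell(summary: pd.DataFrame, category: str, direction: str,
                 stratum: str) -> tuple[int, float]:
    """(count, percent) for one cell of :func:`table1_summary` output."""
    row = summary.loc[(category, direction, stratum)]
    return int(row["count"]), float(row["percent"])
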