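"""Deterministic synthetic fixture mirroring the published summary table.

The fixture plants a signature-record set and curated annotation tables
whose consolidated marginals reproduce the published two-direction summary
exactly: 273 species partitioned 163 enriched / 98 depleted / 12
inconsistent; within the enriched class 111 single-disease and 52
multi-disease species with 105/61/44 bacteremia, 65/45/20 aerotolerant,
51/32/19 oral and 68/47/21 extra-intestinal counts; within the depleted
class 64/34 species with 16/11/5 bacteremia, 9 aerotolerant (all
single-disease), 2 oral and 7 extra-intestinal.  Eight enriched and nine
depleted species are planted in at least three of the six diseases, and 30
species carry only the pooled multiple-disease (MD) label.

The joint distribution *within* each stratum (which bacteremia-positive
species are also oral, say) is a synthetic choice — the source tables
publish only the marginals — so stratified cells beyond the published ones
are fixture-specific.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from gut_signatures.io import SignatureRecord
from gut_signatures.niche import SiteAssignment

_DISEASES = ("CRC", "UC", "CD", "IBS", "PC", "COVID-19")

#: planted CRC cross-meta-study overlap: k studies -> species count
CRC_OVERLAP_PLAN: dict[int, int] = {1: 36, 2: 12, 3: 3, 4: 4}


@dataclass
class Table1Fixture:
    records: list[SignatureRecord]
    assignments: list[SiteAssignment]
    bacteremia_table: pd.DataFrame
    aerotolerance_table: pd.DataFrame


def _records_for(species: str, diseases: list[str], direction: str) -> list[SignatureRecord]:
    return [
        SignatureRecord(study_id=f"{d}-meta1", disease=d, species=species,
                        direction=direction)
        for d in diseases
    ]


def _stratum(
    prefix: str,
    disease_lists: list[list[str]],
    direction: str,
    n_bacteremia: int,
    n_aerotolerant: int,
    n_oral: int,
    n_extra: int,
) -> tuple[list[SignatureRecord], list[dict]]:
    """Build one stratum; the first ``n_x`` species get each property."""
    records: list[SignatureRecord] = []
    props: list[dict] = []
    for i, diseases in enumerate(disease_lists):
        species = f"{prefix}-{i:03d}"
        records.extend(_records_for(species, diseases, direction))
        if i < n_oral:
            site = "oral"
        elif i < n_extra:
            site = "vagina" if i % 2 == 0 else "skin"
        else:
            site = "gut"
        props.append(
            {
                "species": species,
                "bacteremia": i < n_bacteremia,
                "aerotolerant": i < n_aerotolerant,
                "site": site,
            }
        )
    return records, props


def table1_fixture() -> Table1Fixture:
    """The packaged fixture with the published marginal structure planted."""
    records: list[SignatureRecord] = []
    props: list[dict] = []

    # enriched, single disease: 111 species cycling the six diseases
    r, p = _stratum(
        "enr1", [[_DISEASES[i % 6]] for i in range(111)], "enriched",
        n_bacteremia=61, n_aerotolerant=45, n_oral=32, n_extra=47,
    )
    records += r
    props += p

    # enriched, >=2 diseases: one 6-disease species, seven 3-disease,
    # twenty MD-only (n_diseases = 2 by convention), twenty-four pairs
    multi_lists: list[list[str]] = [list(_DISEASES)]
    for i in range(7):
        multi_lists.append([_DISEASES[(i + j) % 6] for j in range(3)])
    multi_lists += [["MD"]] * 20
    for i in range(24):
        multi_lists.append([_DISEASES[i % 6], _DISEASES[(i + 1) % 6]])
    r, p = _stratum("enr2", multi_lists, "enriched",
                    n_bacteremia=44, n_aerotolerant=20, n_oral=19, n_extra=21)
    records += r
    props += p

    # depleted, single disease: 64 species
    r, p = _stratum(
        "dep1", [[_DISEASES[i % 6]] for i in range(64)], "depleted",
        n_bacteremia=11, n_aerotolerant=9, n_oral=2, n_extra=7,
    )
    records += r
    props += p

    # depleted, >=2 diseases: nine 3-disease, ten MD-only, fifteen pairs
    dep_lists: list[list[str]] = []
    for i in range(9):
        dep_lists.append([_DISEASES[(i + j) % 6] for j in range(3)])
    dep_lists += [["MD"]] * 10
    for i in range(15):
        dep_lists.append([_DISEASES[i % 6], _DISEASES[(i + 2) % 6]])
    r, p = _stratum("dep2", dep_lists, "depleted",
                    n_bacteremia=5, n_aerotolerant=0, n_oral=0, n_extra=0)
    records += r
    props += p

    # inconsistent: enriched in CRC, depleted in CD
    for i in range(12):
        species = f"inc-{i:03d}"
        records += _records_for(species, ["CRC"], "enriched")
        records += _records_for(species, ["CD"], "depleted")
        props.append({"species": species, "bacteremia": False,
                      "aerotolerant": False, "site": "gut"})

    bacteremia = pd.DataFrame(
        {"species": [q["species"] for q in props if q["bacteremia"]],
         "bacteremia": "yes"}
    )
    aerotolerance = pd.DataFrame(
        {
            "species": [q["species"] for q in props],
            "category": [
                "facultative/aerotolerant anaerobe" if q["aerotolerant"]
                else "obligate anaerobe"
                for q in props
            ],
        }
    )
    assignments = [
        SiteAssignment(species=q["species"], assigned_site=q["site"],
                       confidence_flag="primary-rule")
        for q in props
    ]
    return Table1Fixture(
        records=records,
        assignments=assignments,
        bacteremia_table=bacteremia,
        aerotolerance_table=aerotolerance,
    )


def table1_annotations():
    """Consolidate and annotate the fixture end to end."""
    from gut_signatures.annotate import merge_annotations
    from gut_signatures.compile import consolidate

    fx = table1_fixture()
    consensus = consolidate(fx.records)
    return merge_annotations(
        consensus, fx.assignments, fx.bacteremia_table, fx.aerotolerance_table
    )
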