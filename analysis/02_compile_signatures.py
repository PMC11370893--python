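"""Consolidate signature records into per-species consensus.

Uses the packaged fixture (whose marginals mirror the compiled ten-study
table) for the direction-class partition and shared-signature sets, and the
simulated four-study CRC table for the cross-study overlap histogram.
"""

from collections import Counter
from pathlib import Path

import pandas as pd

from gut_signatures.compile import consolidate, shared_signatures, study_overlap_histogram
from gut_signatures.fixtures import table1_fixture
from gut_signatures.io import read_signature_tables

ROOT = Path(__file__).resolve().parent.parent
OUT = ROOT / "results"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    fx = table1_fixture()
    consensus = consolidate(fx.records)
    sizes = Counter(c.direction_class for c in consensus)
    print(f"{len(consensus)} unique species: "
          f"{sizes['enriched']} enriched, {sizes['depleted']} depleted, "
          f"{sizes['inconsistent']} inconsistent")

    pd.DataFrame(
        {
            "species": [c.species for c in consensus],
            "direction_class": [c.direction_class for c in consensus],
            "n_diseases": [c.n_diseases for c in consensus],
            "multi_disease": [c.multi_disease for c in consensus],
        }
    ).to_csv(OUT / "consensus.tsv", sep="\t", index=False)

    enr, dep = shared_signatures(consensus, n_total_diseases=6)
    print(f"shared signatures (>= half of 6 diseases): "
          f"{len(enr)} enriched, {len(dep)} depleted")

    crc_path = OUT / "simulated" / "crc_signatures.tsv"
    if crc_path.exists():
        records = read_signature_tables([crc_path])
        hist = study_overlap_histogram(records, "CRC")
        pd.DataFrame(
            {"k_studies": range(1, hist.n_studies + 1),
             "n_species": hist.counts, "percent": hist.percentages}
        ).to_csv(OUT / "crc_overlap.tsv", sep="\t", index=False)
        print(f"CRC overlap: counts {hist.counts} -> "
              f"percentages {hist.percentages}")
    else:
        print("run 01_simulate.py first for the CRC overlap histogram")


if __name__ == "__main__":
    main()
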