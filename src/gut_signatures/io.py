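"""Readers and writers for the tabular formats used throughout the pipeline.

All tables are UTF-8, tab-separated, with a header row and ``.`` as the
decimal separator.  Readers validate eagerly and fail with positional
diagnostics; nothing is silently coerced.

Core containers
---------------
:class:`AbundanceMatrix`
    Species x sample relative abundances plus a per-sample body-site label
    (``gut``/``oral``/``vagina``/``skin``).
:class:`SignatureRecord`
    One (study, disease, species, direction) assertion from a meta-study
    signature table.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

log = logging.getLogger("gut_signatures")

#: Body sites profiled in the multi-site reference survey.
SITES: tuple[str, ...] = ("gut", "oral", "vagina", "skin")

#: Controlled disease vocabulary; "MD" is a pooled multiple-disease label
#: treated as one disease on input.
DEFAULT_DISEASES: tuple[str, ...] = ("CRC", "UC", "CD", "IBS", "PC", "COVID-19", "MD")

DIRECTIONS: tuple[str, str] = ("enriched", "depleted")


class SchemaError(ValueError):
    """Malformed or contract-violating tabular input."""


# ---------------------------------------------------------------------------
# species-name normalisation


def canonical_species(name: str, synonyms: Mapping[str, str] | None = None) -> str:
    """Normalise a species name and resolve it through a synonym map.

    Whitespace and underscores are collapsed to single spaces; synonym lookup
    is case-insensitive.  Former names and genus-abbreviated forms are
    resolved only if present in ``synonyms``.
    """
    cleaned = re.sub(r"[\s_]+", " ", str(name)).strip()
    if not cleaned:
        raise SchemaError("empty species name")
    if synonyms:
        folded = {k.casefold(): v for k, v in synonyms.items()}
        return folded.get(cleaned.casefold(), cleaned)
    return cleaned


def read_synonym_map(path: str | Path) -> dict[str, str]:
    """Read a two-column TSV of ``alias<TAB>canonical`` species names."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise SchemaError(f"{path}: synonym map needs two columns (alias, canonical)")
    alias_col, canon_col = df.columns[:2]
    return dict(zip(df[alias_col].str.strip(), df[canon_col].str.strip()))


# ---------------------------------------------------------------------------
# containers


@dataclass(frozen=True)
class SignatureRecord:
    """A single signature assertion from one meta-study."""

    study_id: str
    disease: str
    species: str
    direction: str  # "enriched" | "depleted"

    def __post_init__(self) -> None:
        if self.direction not in DIRECTIONS:
            raise SchemaError(
                f"direction must be one of {DIRECTIONS}, got {self.direction!r}"
            )


@dataclass
class AbundanceMatrix:
    """Species x sample relative abundances with per-sample site labels.

    Parameters
    ----------
    abundances
        DataFrame indexed by canonical species name, columns are sample ids,
        values are relative abundances in [0, 1].
    sites
        Series mapping sample id -> body-site label; must cover every column
        of ``abundances``.
    """

    abundances: pd.DataFrame
    sites: pd.Series

    def __post_init__(self) -> None:
        ab = self.abundances
        if ab.index.duplicated().any():
            dups = ab.index[ab.index.duplicated()].unique().tolist()
            raise SchemaError(f"duplicate species identifiers: {dups}")
        if ab.columns.duplicated().any():
            dups = ab.columns[ab.columns.duplicated()].unique().tolist()
            raise SchemaError(f"duplicate sample identifiers: {dups}")
        missing = [s for s in ab.columns if s not in self.sites.index]
        if missing:
            raise SchemaError(f"samples missing a body-site label: {missing}")
        vals = ab.to_numpy(dtype=float)
        if np.isnan(vals).any():
            r, c = np.argwhere(np.isnan(vals))[0]
            raise SchemaError(
                f"non-numeric abundance at species {ab.index[r]!r}, "
                f"sample {ab.columns[c]!r}"
            )
        if (vals < 0).any():
            r, c = np.argwhere(vals < 0)[0]
            raise SchemaError(
                f"negative abundance {vals[r, c]} at species {ab.index[r]!r}, "
                f"sample {ab.columns[c]!r}"
            )
        sums = vals.sum(axis=0)
        bad = np.flatnonzero(sums > 1 + 1e-9)
        if bad.size:
            raise SchemaError(
                f"sample {ab.columns[bad[0]]!r} abundances sum to "
                f"{sums[bad[0]]:.6g} > 1"
            )
        self.sites = self.sites.loc[ab.columns]

    @property
    def species(self) -> list[str]:
        return list(self.abundances.index)

    @property
    def samples(self) -> list[str]:
        return list(self.abundances.columns)

    def site_of(self, sample: str) -> str:
        return str(self.sites.loc[sample])


# ---------------------------------------------------------------------------
# abundance tables


def read_abundance_table(
    path: str | Path,
    metadata_path: str | Path,
    synonyms: Mapping[str, str] | None = None,
) -> AbundanceMatrix:
    """Read a species x sample abundance TSV plus a sample->site metadata TSV.

    The first column of the abundance file holds species names; remaining
    columns are samples.  Abundances given as percentages (column sums well
    above 1) are auto-detected and rescaled to proportions, with a log line.
    Samples absent from the metadata are rejected.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    try:
        df = df.astype(float)
    except (TypeError, ValueError):
        for col in df.columns:
            coerced = pd.to_numeric(df[col], errors="coerce")
            if coerced.isna().any() and not df[col].isna().any():
                row = df.index[coerced.isna().argmax()]
                raise SchemaError(
                    f"{path}: non-numeric abundance at species {row!r}, sample {col!r}"
                )
        raise
    neg = df.lt(0)
    if neg.any().any():
        col = neg.any().idxmax()
        row = neg[col].idxmax()
        raise SchemaError(
            f"{path}: negative abundance {df.loc[row, col]} at species "
            f"{row!r}, sample {col!r}"
        )
    colsums = df.sum(axis=0)
    if (colsums > 1.5).any():
        log.info("%s: column sums up to %.3g; interpreting values as percentages",
                 path, colsums.max())
        df = df / 100.0

    meta = pd.read_csv(metadata_path, sep="\t", dtype=str)
    if meta.shape[1] < 2:
        raise SchemaError(f"{metadata_path}: metadata needs columns (sample, site)")
    sample_col, site_col = meta.columns[:2]
    sites = pd.Series(meta[site_col].values, index=meta[sample_col].values)
    missing = [s for s in df.columns if s not in sites.index]
    if missing:
        raise SchemaError(f"{metadata_path}: no body-site metadata for sample(s) {missing}")

    df.index = [canonical_species(s, synonyms) for s in df.index]
    return AbundanceMatrix(abundances=df, sites=sites)


def write_abundance_table(
    matrix: AbundanceMatrix, path: str | Path, metadata_path: str | Path
) -> None:
    matrix.abundances.rename_axis("species").to_csv(path, sep="\t")
    meta = pd.DataFrame({"sample": matrix.samples,
                         "site": [matrix.site_of(s) for s in matrix.samples]})
    meta.to_csv(metadata_path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# signature tables


def read_signature_tables(
    paths: Sequence[str | Path],
    diseases: Sequence[str] = DEFAULT_DISEASES,
    synonyms: Mapping[str, str] | None = None,
) -> list[SignatureRecord]:
    """Read one or more meta-study signature TSVs into validated records.

    Each file needs columns ``study_id``, ``disease``, ``species``,
    ``direction``.  Disease labels outside ``diseases`` and direction tokens
    other than enriched/depleted are rejected.
    """
    vocab = set(diseases)
    records: list[SignatureRecord] = []
    for path in paths:
        df = pd.read_csv(path, sep="\t", dtype=str)
        required = ["study_id", "disease", "species", "direction"]
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise SchemaError(f"{path}: missing column(s) {missing}")
        if df.empty:
            raise SchemaError(f"{path}: signature table is empty")
        for i, row in df.iterrows():
            if row["direction"] not in DIRECTIONS:
                raise SchemaError(
                    f"{path} row {i}: unknown direction {row['direction']!r} "
                    f"(expected one of {DIRECTIONS})"
                )
            if row["disease"] not in vocab:
                raise SchemaError(
                    f"{path} row {i}: disease {row['disease']!r} not in the "
                    f"configured vocabulary {sorted(vocab)}"
                )
            records.append(
                SignatureRecord(
                    study_id=str(row["study_id"]),
                    disease=str(row["disease"]),
                    species=canonical_species(row["species"], synonyms),
                    direction=str(row["direction"]),
                )
            )
    return records


def write_signature_table(records: Iterable[SignatureRecord], path: str | Path) -> None:
    df = pd.DataFrame(
        [(r.study_id, r.disease, r.species, r.direction) for r in records],
        columns=["study_id", "disease", "species", "direction"],
    )
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# generic annotation tables (bacteremia, aerotolerance, secondary evidence)


def read_two_column_table(
    path: str | Path, key: str, value: str
) -> pd.DataFrame:
    """Read a TSV expected to contain at least the columns ``key``, ``value``."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in (key, value):
        if col not in df.columns:
            raise SchemaError(f"{path}: missing column {col!r}")
    return df[[key, value]]


# ---------------------------------------------------------------------------
# iTOL annotation export

_ITOL_SEP = ","

_SITE_FIELDS = ("gut", "oral", "vagina", "skin")

# shape codes: 1 square (direction), 3 star (blood detection),
# 4/5 triangles (aerotolerance), 2 circle (body-site membership)
_FIELD_SHAPES = ("1", "1", "3", "4", "5") + ("2",) * len(_SITE_FIELDS)


def write_itol_annotation(annotations: Sequence, path: str | Path) -> None:
    """Export the master annotations as an iTOL binary-dataset text file.

    One data line per species encodes the four attribute groups of the
    figure-legend semantics: direction (enriched/depleted squares),
    bacteremia (blood-detection star), aerotolerance class (triangles, -1
    when unknown), and per-site membership circles.  Rendering itself
    happens in iTOL; this is export only.
    """
    annotations = list(annotations)
    if not annotations:
        raise ValueError("cannot export an empty annotation list")
    fields = ["enriched", "depleted", "bacteremia",
              "aerotolerant", "nonaerotolerant", *_SITE_FIELDS]
    header = [
        "DATASET_BINARY",
        "SEPARATOR COMMA",
        "DATASET_LABEL,signature species properties",
        "COLOR,#000000",
        "FIELD_SHAPES," + _ITOL_SEP.join(_FIELD_SHAPES),
        "FIELD_LABELS," + _ITOL_SEP.join(fields),
        "DATA",
    ]
    lines = []
    for ann in annotations:
        if _ITOL_SEP in ann.species:
            raise SchemaError(
                f"species name {ann.species!r} contains the iTOL field separator"
            )
        direction = getattr(ann, "direction_class", "inconsistent")
        aero = getattr(ann, "aerotolerance", "unknown")
        site = getattr(ann, "assigned_site", "indeterminate")
        vals = [
            "1" if direction == "enriched" else "0",
            "1" if direction == "depleted" else "0",
            "1" if getattr(ann, "bacteremia", "no") == "yes" else "0",
            "1" if aero == "aerotolerant" else ("-1" if aero == "unknown" else "0"),
            "1" if aero == "nonaerotolerant" else ("-1" if aero == "unknown" else "0"),
        ]
        for s in _SITE_FIELDS:
            vals.append("1" if site in (s, "multi") else "0")
        lines.append(_ITOL_SEP.join([ann.species, *vals]))
    Path(path).write_text("\n".join(header + lines) + "\n", encoding="utf-8")
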