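"""Synthetic inputs with known ground truth for every pipeline stage.

Three generators emulate the study's three curated inputs:

* :func:`generate_abundance_matrix` — site-structured compositional
  abundance matrices.  Presence of a species in a sample is Bernoulli with
  the site's configured prevalence; when present, the pre-normalisation
  magnitude is log-normal; each sample is closed to sum 1.  A ``background``
  filler taxon absorbs the whole mass of samples in which no species is
  present, so normalisation never divides by zero.
* :func:`generate_annotated_species` — per-species direction and a binary
  property (e.g. bacteremia) with a *planted* odds ratio linking them, so
  the exact-test machinery can be checked by parameter recovery.
* :func:`generate_signature_studies` — per-study signature tables with a
  planted cross-study overlap design (how many species appear in exactly k
  studies), the fixture for reproducibility histograms.

All generators are pure functions of their parameters and seed.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field, model_validator

from gut_signatures.io import SITES, AbundanceMatrix, SignatureRecord

BACKGROUND_TAXON = "background"


class SiteSimParams(BaseModel):
    """Per-site simulation parameters.

    ``prevalence`` maps species -> probability of presence in a sample of
    this site; ``log_mean``/``log_sd`` give the log-space location and scale
    of the pre-normalisation magnitude when present (dimensionless).
    """

    model_config = ConfigDict(frozen=True)

    site: str
    n_samples: int = Field(ge=1)
    prevalence: Mapping[str, float]
    log_mean: Mapping[str, float] = Field(default_factory=dict)
    log_sd: Mapping[str, float] = Field(default_factory=dict)
    default_log_mean: float = 0.0
    default_log_sd: float = 1.0

    @model_validator(mode="after")
    def _check(self) -> "SiteSimParams":
        if self.site not in SITES:
            raise ValueError(f"site must be one of {SITES}, got {self.site!r}")
        for sp, p in self.prevalence.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"prevalence[{sp!r}] = {p} outside [0, 1]")
        for sp, s in self.log_sd.items():
            if s <= 0:
                raise ValueError(f"log_sd[{sp!r}] = {s} must be > 0")
        if self.default_log_sd <= 0:
            raise ValueError("default_log_sd must be > 0")
        return self


class AnnotationSimParams(BaseModel):
    """Parameters of the direction/property generator with a planted OR."""

    model_config = ConfigDict(frozen=True)

    n_species: int = Field(ge=1)
    p_enriched: float = Field(gt=0, lt=1)
    target_or: float = Field(gt=0)
    baseline_p: float = Field(gt=0, lt=1)
    seed: int = 0

    @property
    def enriched_p(self) -> float:
        """Property probability in the enriched class implied by the target
        odds ratio: odds(p_enr) = target_or * odds(baseline_p)."""
        odds = self.target_or * self.baseline_p / (1 - self.baseline_p)
        p = odds / (1 + odds)
        if not 0 < p < 1:
            raise ValueError("implied enriched-class probability outside (0, 1)")
        return p


def generate_abundance_matrix(
    params: Sequence[SiteSimParams], seed: int
) -> AbundanceMatrix:
    """Draw a site-structured compositional species x sample matrix.

    Every site block shares the same species set; each sample is normalised
    to sum exactly 1, with the ``background`` taxon carrying mass 1 in
    samples where no species is present (the taxon appears in the output
    only when needed).  Identical seed and params give an identical matrix.
    """
    if not params:
        raise ValueError("at least one site is required")
    sites = [p.site for p in params]
    if len(set(sites)) != len(sites):
        raise ValueError(f"duplicate site labels: {sites}")
    species_sets = [frozenset(p.prevalence) for p in params]
    if not species_sets[0]:
        raise ValueError("empty species set")
    if len(set(species_sets)) != 1:
        raise ValueError("all sites must share the same species set")
    species = sorted(species_sets[0])
    if BACKGROUND_TAXON in species:
        raise ValueError(f"species set may not contain {BACKGROUND_TAXON!r}")

    rng = np.random.default_rng(seed)
    blocks: list[np.ndarray] = []
    sample_ids: list[str] = []
    site_labels: list[str] = []
    for p in params:
        n = p.n_samples
        prev = np.array([p.prevalence[s] for s in species])
        loc = np.array([p.log_mean.get(s, p.default_log_mean) for s in species])
        sd = np.array([p.log_sd.get(s, p.default_log_sd) for s in species])
        present = rng.random((len(species), n)) < prev[:, None]
        magnitude = np.exp(loc[:, None] + sd[:, None] * rng.standard_normal((len(species), n)))
        blocks.append(np.where(present, magnitude, 0.0))
        sample_ids.extend(f"{p.site}_{i:05d}" for i in range(n))
        site_labels.extend([p.site] * n)

    values = np.concatenate(blocks, axis=1)
    totals = values.sum(axis=0)
    empty = totals == 0.0
    if empty.any():
        background = np.where(empty, 1.0, 0.0)
        values = np.vstack([values, background])
        totals = values.sum(axis=0)
        index = species + [BACKGROUND_TAXON]
    else:
        index = species
    values = values / totals

    df = pd.DataFrame(values, index=index, columns=sample_ids)
    sites_series = pd.Series(site_labels, index=sample_ids)
    return AbundanceMatrix(abundances=df, sites=sites_series)


def generate_annotated_species(params: AnnotationSimParams) -> pd.DataFrame:
    """Species table (species, direction, property) with a planted OR.

    Direction is Bernoulli(``p_enriched``); the binary property has
    probability ``baseline_p`` in the depleted class and the odds-inverted
    probability in the enriched class, so the population odds ratio equals
    ``target_or`` exactly.
    """
    p_enr = params.enriched_p  # validates before drawing
    rng = np.random.default_rng(params.seed)
    enriched = rng.random(params.n_species) < params.p_enriched
    prop_p = np.where(enriched, p_enr, params.baseline_p)
    has_property = rng.random(params.n_species) < prop_p
    return pd.DataFrame(
        {
            "species": [f"sim-species-{i:05d}" for i in range(params.n_species)],
            "direction": np.where(enriched, "enriched", "depleted"),
            "property": has_property,
        }
    )


def planted_or_cells(table: pd.DataFrame) -> tuple[int, int, int, int]:
    """2x2 cells (enriched&property, enriched&~property, depleted&property,
    depleted&~property) of a :func:`generate_annotated_species` table."""
    enr = table["direction"] == "enriched"
    prop = table["property"].astype(bool)
    return (
        int((enr & prop).sum()),
        int((enr & ~prop).sum()),
        int((~enr & prop).sum()),
        int((~enr & ~prop).sum()),
    )


def generate_signature_studies(
    n_studies: int,
    diseases: Sequence[str],
    overlap_design: Mapping[int, int],
    seed: int,
    direction: str = "enriched",
) -> list[SignatureRecord]:
    """Per-study signature records realising a planted overlap design.

    ``overlap_design`` maps k -> number of species reported by exactly k of
    the ``n_studies`` studies; which k studies carry each species is drawn
    uniformly (seeded).  Disease labels cycle through ``diseases``.  The
    output overlap histogram reproduces the design exactly.
    """
    if n_studies < 1:
        raise ValueError("n_studies must be >= 1")
    if not diseases:
        raise ValueError("at least one disease label is required")
    for k in overlap_design:
        if not 1 <= k <= n_studies:
            raise ValueError(
                f"overlap design references {k} studies but only "
                f"{n_studies} exist"
            )
    rng = np.random.default_rng(seed)
    study_ids = [f"study{i + 1}" for i in range(n_studies)]
    records: list[SignatureRecord] = []
    idx = 0
    for k in sorted(overlap_design):
        for _ in range(overlap_design[k]):
            disease = diseases[idx % len(diseases)]
            members = rng.choice(n_studies, size=k, replace=False)
            species = f"sig-species-{idx:04d}"
            for m in sorted(members):
                records.append(
                    SignatureRecord(
                        study_id=study_ids[m],
                        disease=disease,
                        species=species,
                        direction=direction,
                    )
                )
            idx += 1
    return records
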