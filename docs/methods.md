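# Methods

## Signature consolidation

Input records assert that a meta-study found a species enriched or depleted
in one disease. Consolidation collects, per canonical species, the set of
diseases with enriched reports and the set with depleted reports; the
direction class is *enriched* or *depleted* when only one set is non-empty
and *inconsistent* otherwise, so the three classes partition the species
set by construction. Duplicate assertions are idempotent, and a disease
reported by several studies in the same direction counts once.

**Disease counting and the MD convention.** The pooled multiple-disease
label (MD) is carried as a single disease on input because the underlying
meta-study does not enumerate its member diseases. A species whose only
source is MD receives `n_diseases = 2`: an MD association implies at least
two diseases, so 2 is the defensible lower bound. When MD co-occurs with
named diseases it counts as one member of the union — also a lower bound,
since its hidden members may overlap the named ones. Ulcerative colitis and
Crohn's disease are distinct diseases throughout.

**Shared signatures.** A species is a shared signature when
`n_diseases >= ceil(threshold_fraction * n_total_diseases)` in a pure
direction class. The denominator is configurable and defaults to 6 (the six
named diseases, MD excluded): the pooled label is not a disease of its own,
and with the fixture's planted counts this choice yields the expected
8 enriched / 9 depleted shared species at the one-half threshold.
Inconsistent species never qualify.

**Percentages** are printed at one decimal with ties rounded away from zero,
which reproduces every printed value in the compiled summaries.

## Body-site classification

Per species and site *s* we compute the detection frequency
*f_s* = (samples at *s* with abundance > detection threshold) / (samples at
*s*) and the average relative abundance *a_s*, a mean over **all** the
site's samples with absences contributing zero, so *a_s* blends prevalence
and within-carrier abundance. The detection threshold defaults to 0 — any
non-zero relative abundance counts as detection — because taxonomic
profilers already apply their own floor before the table is written.

The primary rule designates the site that attains **both** the maximum
*f_s* and the maximum *a_s*, subject to max *f_s* ≥ 5% (`min_frequency`)
and, when the winner is gut or oral, to the gut/oral ratio lying outside
[0.1, 10]. The ratio is computed on mean abundance rather than frequency:
abundance measures residency strength, while frequency saturates for
ubiquitous taxa; it is +∞ when the oral mean is zero (unambiguously gut)
and undefined when both are zero (irrelevant, since neither site can then
win). The band check applies only to gut/oral winners — a clear vaginal or
skin resident is not made ambiguous by a balanced gut/oral trace signal.

Species failing the primary rule are flagged in a fixed precedence order —
`not-detected`, `low-frequency`, `discordant`, `ambiguous-gut-oral` — so a
species absent everywhere is reported as such rather than as low-frequency,
and a frequency failure pre-empts the concordance check. Argmax ties break
to the canonical site order (gut, oral, vagina, skin); with continuous
abundances ties essentially only arise between zero-signal sites, which the
earlier flags intercept.

Indeterminate species can be resolved by a curated evidence table
(database membership, reference-cohort profiles, isolation sources) via
weighted voting: a unique top site wins with flag `secondary-evidence`, a
tie yields `multi`, no evidence leaves the species indeterminate. Suggested
weights are 2 for a reference gut-cohort abundance profile and 1 for
database membership or an isolation source: a quantitative profile in the
target habitat is stronger evidence than presence in a catalogue. Multi-site
species are excluded from site-stratified statistics downstream.

## Annotation merge

The master table is a loss-free left join on the consensus: every consensus
species appears exactly once. Missing bacteremia rows default to "no"
because the curated search records positives only — the flag means
"reported in a blood culture at least once", not "causes bloodstream
infection". Aerotolerance maps aerobes and facultative/aerotolerant
anaerobes to *aerotolerant*, obligate anaerobes to *nonaerotolerant*, and
anything else (including "unclassified anaerobe") to *unknown*. Habitat
class derives from the assigned site: gut → intestinal; oral, vagina, skin
or other → extra-intestinal; multi and indeterminate pass through and are
excluded from habitat-stratified tests. The two-direction summary excludes
the inconsistent species from both columns, mirroring how the compiled
totals count only pure-direction species; inconsistent species are still
emitted in the master table and the tree export.

## Exact 2×2 inference

The two-sided p-value conditions on both margins and sums the central
hypergeometric probabilities of all tables whose probability does not
exceed the observed table's, with a relative tolerance of 1e-7 so that
exact ties (which occur at symmetric tables) are included despite
floating-point rounding. The odds ratio is the conditional MLE: the
noncentral hypergeometric family is a one-parameter exponential family in
log ψ, so the MLE solves the monotone score equation E_ψ[a | margins] = a,
found by bracketed root finding (Brent, relative tolerance 1e-8). Boundary
tables (observed count at the edge of its support) report 0 or +∞; margins
admitting a single table leave ψ unidentified and report NaN with p = 1.
Exact conditional confidence intervals invert the noncentral tail
probabilities the same way. An independent enumeration oracle recomputes
the p-value in exact integer arithmetic (capped at n ≤ 1000) and agrees
with the implementation to 1e-10 over every table with all margins ≤ 40;
the conditional MLE and CI are additionally cross-checked against an
independent library implementation on reference tables, and the
factor-of-two sanity bound against the sample cross-product ratio is swept
exhaustively at margins ≤ 12, where root finding per table stays cheap.

**The comparison battery** attaches exclusion rules to comparisons, not
globally: inconsistent species drop only from direction comparisons,
unknown-aerotolerance species only from aerotolerance comparisons,
multi-site/indeterminate species only from body-site comparisons. Each
result carries its cells, CMLE odds ratio, exact p, and a per-species
exclusion log; a filtered table with an empty row or column is flagged
degenerate instead of reporting a meaningless p = 1. No multiplicity
correction is applied — the battery reports unadjusted exact p-values, as
is conventional for this kind of descriptive enrichment screen.

## Synthetic data

The abundance generator models what the classifier consumes — per-site
prevalence and mean relative abundance — not read-level sequencing.
Presence is Bernoulli(prevalence per site); present species draw a
log-normal pre-normalisation magnitude (default log-mean 0, log-sd 1, a
heavy-tailed within-carrier distribution typical of relative-abundance
data); each sample is closed to sum exactly 1, with a `background` filler
taxon carrying the mass of samples in which no focal species occurs. It
does not model taxon–taxon correlation, overdispersed prevalence, or
within-subject dynamics, so passing tests demonstrate correctness of the
decision rules on niche-structured compositions, not classifier performance
on real surveys. The niche-recovery check uses the separated regime
(prevalence 0.9 at home vs 0.01 elsewhere, e^6 ≈ 400-fold abundance
separation, 200 samples per site, 8 species, 100 replicates), under which
≥ 99% of species must return their planted home site by the primary rule.

The annotation generator plants an exact population odds ratio: the
property probability in the enriched class is the odds inversion
p = OR·odds(p₀) / (1 + OR·odds(p₀)) of the depleted-class baseline p₀.
Calibration checks run at 300 species per table — comfortably asymptotic
for a 2×2 exact test while keeping 100-replicate CI-coverage and
1000-replicate type-I sweeps fast: the planted OR must fall inside the
exact conditional CI in ≥ 95 of 100 replicates, and at OR = 1 (baseline
0.3, half enriched) the 5%-level rejection rate must lie in [0.025, 0.075]
— the exact test is conservative, so the interval is deliberately
asymmetric around 0.05.

The signature-study generator realises an overlap design (k studies →
species count) exactly, drawing only *which* studies carry each species;
overlap histograms on its output reproduce the design deterministically.

**The packaged fixture** plants the compiled two-direction structure —
273 species split 163/98/12, with the published bacteremia, aerotolerance,
oral and extra-intestinal marginals in each direction × disease-count
stratum, eight enriched and nine depleted shared signatures, and 30
MD-only species. Within each stratum the properties are assigned by prefix
(the first *k* species get the property), so all marginals are exact but
the joint distribution across properties is synthetic: stratified cells
beyond the published marginals (and the handful of degenerate strata they
produce) are fixture-specific, not estimates of the real tables, whose
exact exclusions are not recoverable from the published summaries.

## Known limitations

* The body-site rule is a deterministic argmax; no uncertainty is attached
  to assignments near the 5% frequency or ratio-band boundaries.
* The MD lower-bound convention can undercount diseases for species seen
  both in MD and in several named diseases.
* The enumeration oracle's 1e-7 tie tolerance matches the implementation's;
  a genuine (non-tie) probability pair closer than 1e-7 in relative terms
  would be treated as a tie by both routes.
* Synthetic compositions are independent across taxa; real microbiome
  profiles are compositionally coupled and overdispersed.
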