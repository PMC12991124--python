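# Methods

## Scope and data model

The pipeline starts from quantified peptide tables (protein accession,
peptide sequence, modified-cysteine offsets, one reporter intensity per TMT
channel) and a plex layout mapping channels to (condition, replicate,
treatment). It deliberately does not touch spectra, peptide-spectrum
matching or search-level FDR; the quant-table schema is a generic TSV so
that both the built-in simulator and real search-engine exports (via a thin
column mapping) can feed it. Offsets are 1-based within the peptide; site
identifiers are `ACCESSION_C<residue>` with 1-based residues on the full
FASTA sequence. Missing intensities are empty cells and stay missing —
zeros are treated as observed values and nothing is imputed anywhere; all
filters are explicit.

## Quantification conventions

**Channel normalization.** Factors are estimated per plex from complete-case
records only (observed in every channel), so missingness cannot bias them.
Two estimators are provided:

- `total`: each channel's total intensity is scaled to the across-channel
  mean total ("normalization by protein content"). Exact and simple, but the
  factors absorb any unbalanced true differential signal.
- `median` (pipeline default): each channel is scaled by the median of
  record-centered log2 intensities, mean-centered in log space so overall
  scale is preserved and the operation is idempotent. With fewer than half
  of records truly changing, the median factor is exactly zero in the
  noise-free limit, so planted effects propagate unbiased — this is why the
  noise-free pipeline recovers planted fold changes to machine precision,
  and why it is the default. The estimator is the reporter-ion analogue of
  median-ratio (size-factor) normalization.

**Ratios.** Per record, the reference value is the geometric mean of the
observed reference-condition channels (arithmetic mean in log2 space,
consistent with the multiplicative error model); each condition's value is
the median over that condition's channel ratios. Records with no observed
reference channel are dropped and counted in the log.

**Rollup.** Site values per (condition, donor) are medians over distinct
peptide forms; protein values are medians over peptides. The residue number
comes from the peptide's first exact occurrence in the protein (ambiguity is
logged); peptides carrying more than one modified cysteine map to a
composite site id and are excluded from single-site calling. Donor-level
values are kept separate through rollup; the cross-donor median is taken
only at calling time, so one aberrant donor out of five cannot move a call.

## Reactivity calling

The calling rule is two-gated at a configurable fold-change threshold
(default 2): the raw cross-donor median must pass, and so must the
abundance-corrected value (raw minus baseline). The baseline is the matched
protein's unenriched fold change where quantified ("comparison to the whole
proteome"), otherwise the leave-one-out median of the protein's other
cysteines — requiring at least two others, so single-cysteine proteins can
never self-normalize. Evidence tiers implement the two-peptide rule:
`multi_peptide` when the protein carries ≥ 2 distinct quantified cysteine
peptides, else `single_peptide_with_proteome` when unenriched data exist for
the comparison; otherwise the verdict is `insufficient_evidence`. There is
no multiple-testing correction in calling: the rule is threshold-based, not
p-value-based. Per-donor pass counts are reported for transparency but no
per-donor consistency gate is applied.

## ATP add-back and engagement

The add-back is a paired lysate-level perturbation, so deltas are computed
within plex between replicate-paired control/ATP channels before donor
aggregation; this cancels channel loading exactly. Occlusion (decreased
labeling) is the expected biology but both directions are reported. The
cross-state rule flags `|Δ(D8C) − Δ(D2)| ≥ log2(threshold)`, algebraically
identical to a ratio-of-fold-changes cutoff. Covalent-inhibitor engagement
is `1 − treated/control`, clamped to [0, 1] with a flag when clamping fired.

## Statistics

Class enrichment: hypergeometric upper tail with the quantified-protein set
as background and BH adjustment across classes; the enrichment unit is the
parent protein (deduplicated) to avoid pseudo-replication from multi-site
proteins. Volcano tables: two-sided Welch t (unequal variances), p and fold
change gated jointly (defaults 0.05 and 1.5-fold); unadjusted p drives the
flag, a BH column is always emitted. Degenerate zero-variance pairs resolve
to p = 1 for identical groups and p = 0 for different constants. PCA:
complete-case features, centering without unit-variance scaling (inputs
share the log2-ratio scale; scaling is an option), components by SVD, sign
fixed by making each component's largest-magnitude loading positive,
variance fractions validated against a direct covariance eigendecomposition.

## Metabolomics and tracing

Different T cell states differ in cell size, so feature intensities are
divided by total sampled biovolume (cell count × mean cell volume, fL);
dividing by volume alone is available as an option. Natural-abundance
correction is carbon-only with p_nat = 0.0107 and configurable tracer
purity: column j of the (n+1)×(n+1) matrix is the binomial mass-shift
distribution of n−j natural carbons convolved with j tracer carbons,
truncated at n. Correction solves the system by nonnegative least squares
(direct inversion can produce negative fractions under noise) and
renormalizes to sum 1. Only carbon is corrected: the reported readouts are
carbon isotopologue fractions, and H/N/O corrections would need
formula-level metadata the pipeline does not ingest.

## The synthetic-data generator

The generator emulates the profiled study design and is the test bed for
the whole chain:

- **Design.** Five states (D2 reference, D4A, D4C, D8A, D8C) × two channels
  in a TMT 10-plex, one plex per donor, five donors; enriched and unenriched
  arms share layouts. ATP add-back: one 16-plex per donor, two donors, with
  3/3/2 control+ATP replicate pairs for D2/D8A/D8C. Metabolomics: three
  states × four donors.
- **Proteome geometry.** Random sequences are built from tryptic segments
  (terminal K/R); each cysteine sits inside a 6–20-residue segment and extra
  peptide forms are missed-cleavage extensions into cysteine-free flanking
  segments, so every enriched form carries exactly one modified cysteine and
  maps uniquely by first occurrence.
- **Intensity model.** log2 intensity = peptide base (N(16, 1.5), an
  ionization/abundance proxy) + donor×protein effect (N(0, 0.1)) + planted
  abundance offset + planted reactivity offset (enriched only) + occlusion
  (ATP arm only) + N(0, 0.25) reporter noise. Noise is log-normal because
  reporter-ion error is multiplicative. Ratio compression is not modeled.
- **Missingness** is applied after noise, by default logistic in log2
  intensity (steeper loss for dim signals) centered at the missing-rate
  quantile of the realized intensities so the overall rate matches the
  configured 20%; an MCAR mode exists for calibration checks. The logistic
  steepness is 0.8 per log2 unit, i.e. detection fades over roughly five
  log2 units, matching published MS detection-probability curves; a much
  steeper value behaves like a detection cliff and is not realistic.
- **Planted effects.** 5% of proteins get a ±4-fold abundance shift in one
  random non-reference condition; 5% of sites on *other* proteins get a
  ±4-fold reactivity shift (disjoint sets keep ground-truth scoring of the
  two effect classes unambiguous); 5% of sites get a −4-fold ATP occlusion,
  D8C-specific by default, sampled with configurable odds in favor of the
  "nucleotide_binding" class (odds 1 = independence). All planted effects
  are recorded in a ground-truth table sufficient to score any call set.
- **Metabolomics.** Per-volume abundances are log-normal with planted
  2-fold shifts in 10% of features; observed intensities scale with
  biovolume (cell volumes 480/400/330 fL for D2/D8A/D8C — plausible sizes
  for activated blasts versus smaller chronically stimulated cells; the
  study states only that sizes differ). Tracing true MIDs put mass at m+0
  and m+2 (oxidative TCA turns of a glucose tracer) with depressed D8C
  fractions, forward-convolved with natural abundance and noised.

What the generator does **not** emulate: co-isolation/ratio compression,
isotopic impurity of reporter labels, shared peptides across proteins,
retention-time effects, batch effects beyond the donor random effect, and
real GO-annotation structure. Passing tests therefore demonstrate that the
analysis logic is correct under the stated generative model, not that the
thresholds are optimal for any particular real dataset.

## Problem sizes and determinism

Validation runs use 500 simulated proteins (≈ 1,000 cysteine sites,
≈ 2,000 enriched peptide forms) over 5 donors, with stochastic properties
pooled over 10 seeds — sizes at which every recovery statistic is stable to
a couple of percent while the full suite stays fast. All randomness flows
through seeded numpy Generators keyed by (seed, stage), so every artifact is
bit-for-bit reproducible; output tables are written with stable row and
column order, and the run manifest records parameters and sha256 digests.

## Known limitations

- The calling rule is threshold-based by design; it reports no p-values or
  FDR for reactivity calls.
- Peptides mapping to multiple proteins are not resolved (accession identity
  is the protein-inference model); such data should be pre-grouped.
- The leave-one-out median-cysteine baseline assumes most cysteines of a
  protein are reactivity-stable; proteins with pervasive site changes will
  be under-called in that mode.
- Engagement fractions from single-concentration competition carry no
  dose-response information.
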