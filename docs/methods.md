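# Methods

`labelaudit` implements a complete market-survey authentication analysis for
seafood labels: molecular species identification from paired Sanger COI
reads, resolution of market labels to permitted species sets, misnaming and
mislabelling adjudication, and a censoring-aware statistical standardisation
of mislabelling rates to species-level resolution. This note records the
models, the tunable parameters, the synthetic-data assumptions, and the
design choices made where the design was genuinely open.

## 1. Species assignment from Sanger pairs

**Trimming.** Each read is quality-trimmed with parameters typical for COI
barcode cleanup: 30 bases removed from the 5' end (primer region), a 10-base
sliding window from the 3' end that repeatedly drops the trailing window
while its mean Phred quality is below 20, truncation at 250 bases, and
rejection when fewer than 100 bases remain or the mean quality is below 20.
All five parameters sit on `TrimConfig`.

**Consensus.** The reverse read is reverse-complemented (qualities reversed
in step) and the pair is aligned with an exact Needleman–Wunsch global
alignment (match +1, mismatch −1, gap −2; traceback ties resolved
diagonal > up > left, so output is deterministic). For two sequences an
optimal pairwise alignment is exactly equivalent in intent to running a
general multiple-sequence aligner, while being fully specified and
oracle-checkable. Consensus rule per column: agreement emits the base;
base-vs-base disagreement emits the higher-quality base (quality ties emit
`N`, configurable); gap columns emit the non-gap base regardless of quality
— the quality rule covers only base-vs-base conflicts, and discarding
single-read overhangs would shorten the barcode for no benefit.

**Hit curation.** Reference-database hits (BLAST outfmt-6-like rows plus a
species name and a per-species database entry count) are filtered by query
coverage ≥ 98%, identity ≥ 98%, e-value ≤ 1e−10, and species-rank subject
names only. The thresholds are inclusive (≥); a strict reading (">98%") is
available by configuration. Two confidence rules guard against reference
mislabelling: the hits for a species must amount to at least 1% of that
species' total database entries, and species represented by a single
database entry are dropped. The entry count is data (a column), not code:
database snapshots vary. Support counts are computed after the threshold
filters, which makes the operation idempotent and order-independent.

**Assignment.** Among surviving species the winner maximises
(max identity, max coverage, support), with an alphabetical tie-break; a
full tie sets an ambiguity flag rather than failing. Failure is a status,
not an exception: `no_amplification` (no reads), `low_quality` (both reads
rejected), `no_hits` (empty raw table), `low_confidence` (raw hits, none
surviving curation), `contamination_excluded` (winner is on the product's
declared co-ingredient list, e.g. pig in a pork-and-prawn dumpling). The
mapping of trimming outcomes to the first two statuses is a package
convention; the categories themselves are standard QC outcomes.

## 2. Labels, specificity, misnaming

A label term resolves, under a named definition regime, to a permitted
species set from a long-format reference table (term, regime, species).
Four regimes are configured: `comprehensive` (the analysis default),
`afns` (stricter standard-name definitions), and `strict_flake` /
`lenient_flake`, which differ from comprehensive only on the term "flake"
(exactly the two *Mustelus* species, or all selachimorphs plus
holocephalans, respectively). Synonyms are resolved at load time so all
comparisons use accepted names — e.g. a database hit recorded under
*Melicertus plebejus* matches a "king prawn" label defined via *Penaeus
plebejus*. Unknown terms resolve to the empty set with an explicit flag and
are never silently counted as mislabelled.

**Specificity** is the finest taxonomic rank a label pins down, coded
ordinally: higher-than-family (1) < family (2) < genus (3) < species (4).
A singleton set is species level; all-same-genus is genus; all-same-family
is family; anything broader (including pure generics like "fish", which
resolve to the universal set) is higher. Enlarging a set can never raise
the code.

**Misnaming** asks only whether the label uses an approved standard name,
independent of biological accuracy; no operation reads mislabelling state
to set misnaming or vice versa. A product is correctly named when either
its main label or its maximum-detail string is within an optimal string
alignment (OSA) distance of 2 (configurable) of an approved name, or
contains a valid scientific binomial. OSA with bound 2 was chosen because
the reference matching function in the field's standard tooling is
transposition-aware and the tolerated mismatches are plurals and spacing;
the bound is declared, not inferred. Distance is monotone: tightening the
bound never converts a misnamed product to correctly named.

## 3. Adjudication and rates

A product is **mislabelled** under a regime when its assigned species is
outside the permitted set of its maximum-detail label; coarse labels are
judged against their own (coarse) set, exactly as a consumer-facing
assessment requires — the species-level counterfactual belongs to the
standardisation model, not to adjudication. Products without an assigned
species are unassessable and leave denominators (but are tallied).
Universal-set generics remain in denominators and can never be mislabelled.

Rates carry Wald 95% intervals (truncated to [0, 100]); multinomial
breakdowns (e.g. specificity shares) use Goodman's simultaneous chi-square
intervals with the Bonferroni-adjusted quantile A = χ²₁(1 − α/k):

    (A + 2nᵢ ∓ √(A(A + 4nᵢ(N − nᵢ)/N))) / (2(N + A))

The regime sensitivity analysis re-adjudicates the identical sample set
under each regime and tabulates regime × group rates. Monotonicity is
structural and asserted: shrinking a permitted set can only create
mislabelling (strict flake ≥ comprehensive), enlarging can only remove it
(lenient flake ≤ comprehensive), and flake regimes touch only the
shark-and-ray group's cells.

Vendor verbal claims are compared descriptively (agree / disagree / absent,
plus "rescued": mislabelled products whose vendor claim covered the
assigned species); they never alter the written-label adjudication.

## 4. Censoring-aware standardisation

Cohorts labelled at different resolutions are not comparable: a "snapper"
label can only be wrong if the DNA identification leaves a 5-family set,
while a species-level label must match one species. The package treats
label specificity as the time axis of a survival problem (levels 1–4, unit
spacing by default; the spacing is configurable to probe sensitivity).
A correct product is right-censored at its label's level.

**Event likelihood.** For a mislabelled product, the mismatch is known only
to have occurred *by* the label's level — current-status information. The
default likelihood therefore treats events as interval-censored on
(0, level] (`event_likelihood="interval"`); the classic coding that places
the event exactly at the label's level is available as `"exact"`. The
distinction matters: under a latent-mismatch mechanism with a true
species-level rate of 25%, the interval likelihood recovers ~25% while the
exact-event coding inflates to ~35% in simulation. The interval form is the
package default because it is the one consistent with what adjudication
actually observes.

**Fitting.** Parametric accelerated-failure-time models (Weibull default;
log-normal and log-logistic selectable) are fitted by maximum likelihood
via lifelines, with covariates on the log-scale parameter and the shape
parameter intercept-only. Non-converged candidates are flagged and excluded
from averaging with a record.

**Model selection and averaging.** All subsets of the supplied terms
(including the null model) are ranked by AIC = 2k − 2ℓ. Akaike weights
w ∝ exp(−ΔAIC/2); the confidence set is the smallest AIC-ranked prefix with
cumulative weight ≥ 0.95; coefficients are averaged zero-filled over the
confidence set ("full" averaging — the convention is declared since either
is defensible), and term importance is the renormalised sum of weights of
models containing the term.

**Prediction.** Per product, cumulative mislabelling at level ℓ is
1 − S(ℓ) under each candidate, combined with Akaike weights; the population
curve is the mean over products, and the species-level standardised rate is
the curve at level 4. The 95% band propagates each product's linear-
predictor interval through S with the shape fixed at its MLE, then averages
per-product bounds — deliberately reproducing the wide, asymmetric bands
this construction yields (upper limits can approach 100%). Optional
standardisation fixes every covariate at its median (numeric) or mode
(categorical). The observed ("censored") curve at level ℓ is the
adjudicated rate among products labelled at resolution ≤ ℓ.

**Price imputation.** Missing prices are filled by predictive mean
matching: a linear model of log price on seafood group, outlet and origin
is fitted to observed rows, and each missing row receives the observed
price of one of the 5 nearest predicted values (seeded draw). Imputed
values are always members of the observed support.

**Ordinal specificity model.** What drives label specificity is modelled
with a cumulative-logit ordinal regression (statsmodels), price entering
through a cubic B-spline basis with 4 degrees of freedom, other terms
categorical; the same AIC machinery selects and averages, and per-model
explained deviance 1 − D/D₀ is reported. Likely separation (divergent
coefficients or failed convergence) is flagged, never silently reported.

## 5. Synthetic data: what it emulates, what it does not

The generator reproduces the survey design the analysis assumes: 7 states ×
96 products (672 total), six seafood groups in their survey shares, outlet
shares (fishmonger/restaurant/supermarket), an exact 48:48
domestic:imported split per state, group-specific specificity mixes
(defaults: 25.5% species, 18.8% genus, 17.6% family, 38.1% higher), prices
log-uniform on [3.43, 299.90] $/kg (only the range is known; log-uniform
spreads mass across price decades) with 5.5% missing completely at random,
and per-(group × level) substitution probabilities (defaults mirror the
observed group rates: sharks/rays 35.9%, snapper 25.2%, squid 12.6%, tuna
4.2%, prawns 2.0%, hoki 1.0%, applied at every level).
Stratum allocation uses largest-remainder rounding with lexicographic
tie-breaks, so integer counts match the design exactly for every seed.

Substituted species are drawn from a per-group confusion table (defaults:
holocephalans for flake/shark labels, tilapia/barramundi/jewfish for
snapper, Alaska pollock for tuna — the qualitative substitution patterns
the field reports). A substitution is always outside the label's
comprehensive-regime set, so adjudicated rates estimate the configured cell
probabilities directly. For recovery studies of the survival layer,
`cumulative_true_mislabel_prob` derives cell probabilities from a latent
constant-hazard coarsening mechanism (a product labelled at level ℓ is
mislabelled with probability P(T ≤ ℓ)); because each product is observed
only at its own label's level, this is exactly equivalent to drawing the
latent mismatch level.

Sequence data are toy barcodes: hierarchical random sequences (family base,
~8% mutation per genus, ~3% per species) so congeners sit near — but below —
the 98% identity threshold. Reads cover an overlapping ~350-base amplicon
window from both ends; qualities are Phred-like integers in [2, 40] with
miscall probability 10^(−Q/10), so quality scores mean what they claim.
Hit tables score infix edit-distance identity (via edlib) with a monotone
e-value proxy; no BLAST statistics are recomputed.

Not emulated: chromatograms and basecalling, sequencing chemistry,
insertions/deletions in reads, heteroplasmy or mixed templates, real
taxonomic breadth (the demo table has ~44 species against the hundreds a
real label-to-species table carries), geographic structure, or any
dependence of label specificity on covariates. Passing tests therefore
demonstrate the correctness of the pipeline's logic and the calibration of
its statistics under the stated design — not robustness to chromatogram
artefacts or to reference databases richer than the demo table.

## 6. Numerical conventions and degenerate inputs

- Alignment DP ties: diagonal > up > left; assignment ties: alphabetical,
  flagged ambiguous; largest-remainder ties: lexicographic.
- Interval-censored events use a lower bound of 1e−8 (a true zero is
  outside the log-time domain).
- AFT fits carry a 1e−6 ridge penalty for numerical stability of the
  covariance; model-averaging weights are invariant to constant
  log-likelihood shifts by construction.
- Empty strata are absent from rate tables rather than zero; zero-event
  cells report a Wald lower bound truncated at 0.
- Goodman intervals are clipped to [0, 1]; a zero total is an error.
- `filter_hits` on an empty table returns an empty table; `assign_species`
  distinguishes "no raw hits" from "nothing survived curation".

## 7. Problem sizes used by the test suite and acceptance script

The suite runs the full survey scale (672 products) for pipeline checks,
n = 1,000 × 100 seeds for rate-recovery calibration, n = 2,000 × 20 seeds
for censoring-model recovery, 10,000 replicates for Goodman coverage, and
200 read pairs for consensus-oracle equivalence; these sizes give the
binomial checks 3-standard-error resolution while keeping a laptop-class
run comfortable. The acceptance script executes one full 672-product
survey end to end.

## 8. Known limitations

- The survival standardisation assumes the coarsening (label specificity)
  is independent of the latent mismatch given covariates; informative
  labelling beyond the modelled covariates biases the species-level
  prediction.
- The CI band construction (mean of per-product bounds) is a descriptive
  envelope, not a frequentist interval for the population curve; a
  delta-method band would be narrower.
- COI cannot separate very close congeners (e.g. within *Thunnus*); the
  generator's 3% congener divergence is optimistic about real barcode gaps.
- The AFNS list and label-to-species tables packaged here are small
  synthetic demonstrations; real analyses should load the full curated
  tables through the same CSV interfaces.
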