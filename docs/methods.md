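# Methods

## Model and assumptions

`transpec` scores tissue specificity of transcript isoforms from bulk
RNA-seq TPM estimates. It deliberately avoids modelling expression
*magnitude* distributions; the primary statistic is the per-tissue
expression probability

    P_ij = #{samples of tissue i with TPM_ij >= tpm_threshold} / n_i ,

which exploits large per-tissue sample counts and is robust to the poor
mean–variance behaviour of TPM. The assumptions behind the pipeline are:

1. **A fixed detection baseline.** A transcript is "expressed in a sample"
   when TPM ≥ 0.5 (the comparison is ≥, configurable). The method is only
   meaningful if this baseline separates noise from signal for the
   quantification pipeline that produced the TPMs.
2. **A U-shaped probability distribution.** Across a transcriptome, each
   tissue's P_ij values concentrate near 0 (unexpressed) and near 1
   (expressed), with a sparse middle. The data-driven cutoffs are the
   density inflection points delimiting these peaks; on data that are not
   U-shaped the window fallbacks fire and are flagged.
3. **Exchangeable samples within a tissue.** The permutation p-value treats
   tissue labels as exchangeable under the null; batch structure or donor
   effects violate this and are out of scope (no batch correction is
   attempted).

## Pipeline and parameters

| stage | parameter | default | notes |
|---|---|---|---|
| QC | `min_rin` | 7 | samples with RNA integrity number < 7 are discarded first (strict `<`; 7.0 is kept) |
| QC | `min_samples_per_tissue` | 50 | applied *after* the RIN filter, on surviving counts (strict `<`; 50 is kept) |
| QC | `tissue_grouping` | none | optional label map collapsing subregions (e.g. brain) into one tissue group |
| probabilities | `tpm_threshold` | 0.5 TPM | detection baseline |
| thresholds | `rip_window` | [0.75, 0.9] | closed window for the right cutoff |
| thresholds | `lip_window` | [0.05, 0.25] | closed window for the left cutoff |
| thresholds | bandwidth | Silverman | normal-reference rule `(3n/4)^(-1/5)·sd`; fixed override available |
| specificity | `pseudocount` | 0.001 TPM | added to both sides of the FC-MAX ratio |
| specificity | `n_iterations` | 999 | resampling iterations (≥ 99 enforced) |
| specificity | `mode` | `permutation_null` | or `subsample_stability` (80% per-tissue subsample, instability of FC ≥ 1) |
| classifier | `fc_cutoff` / `emp_p_cutoff` | 1.0 / 0.05 | log2 units; boundary comparisons are ≥ / ≤ |
| classifier | `ten_max_fraction` | 0.5 | TEn covers 2 ≤ k ≤ ⌊0.5·n⌋; Wide is k > ⌊0.5·n⌋ |
| tau | `log_transform` | true | τ on log2(x+1)-transformed means; raw scale selectable |
| promoters | `tss_thresholds` | 50/500/5000 bp | all three reported side by side |

The QC order (RIN before tissue size) is chosen so tissue sample counts
reflect quality-passing samples. Filtering is idempotent.

## Density estimation and the inflection cutoffs

The per-tissue density is a Gaussian KDE on a 512-point uniform grid over
[0, 1], boundary-reflected at 0 and 1 (`f(x) + f(−x) + f(2−x)`) so mass is
conserved; curves failing to integrate to 1 ± 0.02 are rejected as
degenerate. Inflection points are sign changes of the central-difference
second derivative, located by linear interpolation; curvature below the
floating-point resolution of the differencing is treated as zero so exactly
linear segments report no inflection.

Two choices here matter and were settled by the geometry of U-shaped data:

* **Bandwidth.** Silverman's *normal-reference* rule on the standard
  deviation is used, not the IQR-robust variant: P_ij vectors are
  zero-inflated (most transcripts are unexpressed in any one tissue), so
  their IQR can be nearly zero, which collapses the robust bandwidth and
  turns the KDE into a comb of spikes with spurious inflections at every
  data atom.
* **R-IP on the right peak only.** The right cutoff is estimated from the
  density of the subset P_ij > 0.5 (`rip_subset_min`, configurable; the full
  vector is used if the subset has fewer than 100 values). On the full
  vector, the dominant near-zero mass sets the overall standard deviation
  (≈ 0.4) and hence a bandwidth (≈ 0.08) so large that the expressed peak's
  internal structure — exactly where the cutoff lives — is smoothed into a
  single terminal bump whose only inflection sits above 0.9, outside the
  search window. Restricting to the right peak scales the bandwidth to the
  peak's own spread and resolves the shoulder where the inflection belongs.
  The left cutoff, by contrast, delimits the dominant left peak and is
  stable on the full-vector density, so it is read from there.

Within a window the *rightmost* inflection point is selected. If none
qualifies, the window bound nearer the centre of the distribution is used
(0.75 for R-IP, 0.25 for L-IP) and flagged `fallback` in all outputs.

## Fold change, empirical p-values, τ

FC-MAX compares a transcript's mean TPM in the candidate tissue against the
*best* competing tissue: `log2((m_i + c)/(max_{k≠i} m_k + c))`. The
pseudocount c (0.001 TPM) defines the statistic when all competing means are
zero; ties at the row maximum give FC-MAX = 0 for every tied tissue, so the
exclusivity invariant (at most one tissue per transcript with FC-MAX ≥ 1)
holds by construction. For multi-tissue TEn candidates the statistic is
set-versus-rest: the set's minimum mean over the strongest outside tissue
(`ten_mode="set"`); a per-best-tissue alternative is selectable.

EMP-p uses the add-one estimator `p = (1 + #extreme)/(B + 1)`, which is
valid (never anti-conservative in expectation) and bounded below by
1/(B + 1). In `permutation_null` mode, tissue labels are permuted across all
samples, preserving each tissue's sample count, and the candidate statistic
is recomputed against the same candidate set; one permutation stream is
shared across candidates for speed. In `subsample_stability` mode, 80% of
each tissue's samples are redrawn without replacement and p is the add-one
fraction of iterations with FC-MAX below the fold-change cutoff — a call
instability measure rather than a null-hypothesis p-value. Both readings of
"stratified subsampling" are implemented because the procedure admits
either; the mode is recorded in every output. All resampling derives from a
single seeded generator: same seed, same input, bitwise-identical output.

Two statistical caveats are documented rather than hidden. First, the
permutation p-value is exactly calibrated for a candidate (transcript,
tissue) pair chosen independently of the expression values; the type-I-error
check therefore pre-specifies candidate tissues (transcript index mod
n_tissues) on a null corpus. In the pipeline proper, candidates are selected
by the probability cutoff, so downstream p-values are conditional on that
selection — the sequential-cutoff design inherited from the method. Second,
candidates failing FC/EMP-p are *demoted* to Low (configurable): the rules
do not say where failed candidates go, and Low is the only class consistent
with their pattern (expressed somewhere, but not distinguishably).

τ follows the classical definition τ = Σ(1 − x̂_i)/(n − 1) with
x̂_i = x_i/max_i x_i, on log2(x+1)-transformed means by default (standard
practice; the raw scale is selectable and is scale-invariant). All-zero
transcripts get τ = 0 with an `all_zero` flag rather than NaN.

## Promoter analysis

The TSS is the strand-aware 5′ end (start on +, end on −; 1-based). A gene's
TSp transcripts are `same_promoter` at threshold t when the *maximum*
pairwise TSS distance is strictly below t — max-linkage, so every pair of a
same-promoter gene is within threshold; equality at the boundary is
`multi_promoter`. Calls are therefore monotone in t and invariant under
coordinate mirroring with strand flip. Tissue scope is `single_tissue` when
all of a gene's TSp transcripts are assigned the same tissue.

## The synthetic corpus generator

The generator emulates a GTEx-like design — 26 tissues, 60 samples each,
~10% of samples with RIN < 7 (assigned stratified per tissue so QC removes a
fixed share everywhere) — with five planted transcript classes. Expression
is a two-state mixture per sample: an expressed state (lognormal, median
20 TPM, σ = 0.8) entered with a class-dependent per-sample probability, and
a background state (lognormal, median 0.01 TPM, σ = 1.0, far below the
0.5 TPM baseline).

* **TSp/TEn**: detection probability 1 − dropout (default dropout 0.05) in
  the target tissue(s); one competitor tissue detects the transcript in a
  fraction 1/`fc_effect` of samples (default 8), so the true mean ratio to
  the best other tissue is ≈ `fc_effect` while the competitor's probability
  stays far below R-IP. TEn targets 2 … ⌊n/2⌋ tissues.
* **Wide**: housekeeping-like — detection probability uniform(0.98, 1.0) in
  a core of > 50% of tissues and uniform(0.70, 0.95) elsewhere. The partial
  tissues may fall on either side of R-IP, which is harmless for a Wide
  call, and they give the pooled right peak the anatomy real corpora show: a
  mode anchored at 1 plus a broad left shoulder whose inflection is the
  R-IP. The partial range was chosen so that shoulder inflections fall
  centrally within [0.75, 0.9] across tissues and seeds; a narrower or lower
  shoulder leaves the search window without any inflection.
* **Low**: detection probability uniform(0.30, 0.70) in 1–3 tissues — the
  interior of the low band, so binomial noise at ~54 samples keeps realized
  probabilities between the cutoffs.
* **Null**: background everywhere with a leak probability uniform(0, 0.005),
  small enough that realized probabilities stay below L-IP in every tissue.

Default class counts are 500 TSp / 500 TEn / 1500 Wide / 1250 Low /
1250 Null (5,000 transcripts); the acceptance checks use the study-scale
counts (5,000 transcripts with 1,000 Wide). Generation is O(transcripts ×
samples); a default corpus builds in ~2 s and a full fit with 199
permutation iterations takes ~6 s on one CPU, so all checks run at full
published scale.

What the generator does **not** emulate — and hence what passing tests do
not show about real data: gene-level covariance and co-expression, batch and
donor effects, isoform-count structure within genes (all non-TSp transcripts
are singleton genes), realistic library-size variation, and RIN that
correlates with expression quality (RIN is independent metadata here, enough
to exercise the QC path). Recovery rates on planted corpora measure internal
consistency of the machinery under its own assumptions, not accuracy on
GTEx.

## Numerical and degenerate-input behaviour

* Grid 512 points; inflection roots by linear interpolation between
  bracketing grid points; zero-curvature plateaus contribute their midpoint
  when flanked by opposite signs.
* Silverman bandwidth requires ≥ 100 values and non-zero variance; constant
  vectors raise a validation error (a spike density has no usable
  inflection). A fixed bandwidth lifts the size requirement.
* Expression files are parsed with round-trip float precision; all TSVs are
  written with pandas' shortest round-tripping representation, so
  write→read is exact and reruns are byte-identical. Output files carry the
  run-manifest hash as a leading comment line.
* Empty candidate lists, empty transcript sets and header-only outputs are
  legal; mismatched transcript sets between tables are errors.

## Limitations

* The inflection cutoffs assume enough transcripts (hundreds per tissue)
  for a stable KDE; small panels should use fixed windows or a fixed
  bandwidth.
* Shared permutation streams across candidates introduce weak positive
  dependence between p-values of different transcripts; this does not bias
  individual p-values but slightly inflates the variance of aggregate
  error-rate estimates.
* Demotion of failed candidates to Low and the set-versus-rest TEn statistic
  are this package's documented readings of under-specified rules; both are
  configurable.
* Multiple-testing control across transcripts is intentionally not applied —
  the class definition uses a fixed EMP-p cutoff; users needing FDR control
  can apply it to the emitted per-candidate p-values.
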