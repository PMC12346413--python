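# Methods

## Study design and data model

The pipeline targets bulk RNA-seq of flight (pectoralis) muscle sampled
cross-sectionally around an acute glucose stimulation: distinct animals at
baseline (T0, n = 4 by default) and at 30 (T30, n = 3) and 60 (T60, n = 5)
minutes post-bolus. Because animals differ between timepoints, no
per-animal pairing across timepoints exists; all timepoint contrasts are
built on group means. Inputs are a raw integer gene × sample count matrix
with a sample design (timepoint, replicate), a housekeeping gene panel, a
candidate gene list, GMT gene-set annotations, and externally produced
differential-expression (DEG) tables; DEG estimation itself (a
negative-binomial GLM of the edgeR kind) is upstream of this package and
out of scope.

## Normalisation

Counts are scaled to counts per million (CPM) per sample and
log2-transformed as log₂(CPM + c) with pseudocount c = 1 (default,
configurable). c = 1 bounds absent genes at 0 and is standard practice; no
gene-length normalisation is applied since all statistics compare the same
gene across samples. Lowly expressed genes are removed by the common
convention CPM ≥ 1 in at least min(group sizes) samples; both the value
and the sample cutoff are configurable because the exact rule is a
convention, not an identity. "Normalisation to the housekeeping panel" is
implemented as per-sample subtraction of the panel's mean log₂CPM
(equivalently, division of CPM by the panel's geometric mean). Centering
is idempotent and configurable (`center_on_hk`); whether the centered or
the plain log₂CPM matrix feeds the candidate statistic is recorded in the
run metadata. Note that per-sample centering cancels exactly in the
group-mean Δ minus the housekeeping-Δ mean, so the default choice does not
change z-scores; it matters only for the baseline-elevation comparison and
for inspection of the matrix itself.

## Candidate responsiveness: the housekeeping empirical null

For gene g and stimulated timepoint t,
Δ(g, t) = mean log₂CPM over samples at t − mean over baseline samples.
The housekeeping panel (13 genes by default) supplies an empirical null
for Δ at each timepoint: μ_HK and σ_HK are the mean and sample standard
deviation (n − 1 denominator; material at n = 13 and recorded in output
metadata) of the panel's Δ values. Candidates are scored as
z = (Δ − μ_HK)/σ_HK with a two-tailed p from the standard normal
reference, then Benjamini–Hochberg adjusted jointly across all
candidate × timepoint tests (per-timepoint families available);
responsive ⇔ q < α (default 0.05).

Assumptions and caveats:

- The null transfers the housekeeping panel's variability to candidates.
  If candidate genes are intrinsically noisier than the stability-selected
  panel — which is the typical situation — the z-scores are
  anticonservative. This is visible in the package's own synthetic runs:
  unplanted candidates simulated with ordinary (higher) dispersion are
  frequently called responsive against the stabilized panel. Calls should
  be read as "changed more than housekeeping variation", exactly what the
  statistic encodes, not as a calibrated per-gene test.
- With n_HK = 13 the studentized statistic has heavier-than-normal tails;
  the empirical type-I rate at nominal 0.05 is ≈ 0.08 in the package's
  null simulations (bounded below 0.10 in the acceptance suite). A
  Student-t reference with n_HK − 1 degrees of freedom is available as
  `p_reference: t`; the normal reference is the default because the
  statistic is defined on the normal scale and the miscalibration is
  documented rather than silently corrected.
- Degenerate nulls (all housekeeping Δ identical) raise an error rather
  than emitting infinite z-scores.

Baseline elevation ("expressed above housekeeping") is a separate
question: a Wilcoxon signed-rank test pairs each sample's candidate
log₂CPM with that sample's housekeeping-panel mean, across all samples by
default. Zero differences are dropped (Wilcoxon's convention), tied
absolute differences receive midranks, and the two-sided p is exact for
n ≤ 25 — computed from the full sign-assignment distribution by
rank-polynomial convolution, which handles midrank ties exactly, unlike
the common exact tables — with a tie-corrected, continuity-corrected
normal approximation above. A gene is called elevated when p < α and the
median paired difference is positive.

## DEG thresholds, overlap, enrichment and modules

DEG filtering uses strict inequalities, matching the conventional
phrasing: |log₂FC| > 1 and adjusted p < 0.05 for the global DEG set;
|log₂FC| > 1.5 and adjusted p < 0.01 for module construction. Direction
is the sign of log₂FC. Cross-contrast overlap is an exact two-set
partition (counts conserve cardinalities by construction).

Over-representation of a study set against each annotation term uses the
hypergeometric upper tail P(X ≥ k) with universe N = all genes of the
annotation map (a larger background can be supplied as a gene-list file
via `ora_universe`; the appropriate background is the expressed-gene set,
not the study set). Terms outside a configurable size window are skipped;
BH adjustment runs across the reported terms.

Functional modules are built from per-gene term profiles. Whether
profiles should span all annotated terms or only the enriched ones is a
genuine design freedom; the default restricts profiles to terms enriched
at q < `ora_alpha`, so that module structure is driven by the signal
rather than the whole annotation graph, and `profile_mode: all` switches
to full annotation profiles. Pairwise gene distance is
1 − Jaccard between profiles; average-linkage agglomerative clustering is
cut at k = 4 modules (k and linkage configurable; four reflects the
module count this style of analysis typically reports). Genes with empty
profiles are excluded and reported. Module labels are renumbered by first
appearance over lexicographically sorted gene ids, making the assignment
invariant to input order. Shared ("secondary") membership is a
reconstruction, not a standard definition: gene g additionally joins
module m ≠ primary(g) when Jaccard(profile(g), union of m's member
profiles) ≥ 0.2 (configurable). The module Venn counts each gene once in
the exclusive region of its full membership set.

## Fiber-type contrasts and growth kinetics

Fast/slow paralog pairs are compared with the classical paired t-test on
per-individual log₂CPM differences (two-sided, n − 1 df); zero-variance
differences raise an error recommending an exact sign test. A paralog is
"not detected" when its CPM never exceeds a configurable floor (default:
zero counts in every sample). The dominant paralog is the one with the
larger median; the composition call lists dominant paralogs significant
at α.

Doubling times come from the two-point formula
DT = (t₂ − t₁)·ln 2 / ln(n₂/n₁) and from an ordinary least-squares fit of
ln(count) on time (DT = ln 2/k, with the fit's r²). The log-linear fit is
used instead of a nonlinear exponential fit because it is closed-form and
deterministic; the two agree exactly on noiseless exponential data.
Declining cultures yield negative DT with a flag rather than an error.

## Synthetic data

The generator emulates the statistical shape of the study, and its
defaults are the study conditions: group sizes 4/3/5; 13 housekeeping
genes (carrying the real panel's names so default configurations work
end-to-end); 30 candidates of which half carry planted ±2 log₂ effects at
both stimulated timepoints; 2000 genes total; baseline log₂ abundances
uniform on (3, 9); library sizes log-uniform on (5×10⁵, 2×10⁶) so CPM
normalisation is load-bearing; negative-binomial counts with
mean/dispersion parameterization variance = μ + μ²/φ and φ = 10 (φ = ∞
gives Poisson), with the housekeeping panel's φ multiplied by a stability
factor of 8 to emulate stability-selected genes; fast paralogs placed 4
log₂ units above their slow partners. Annotations: 40 terms split evenly
over 4 modules, 40 module genes assigned cyclically, within-module
annotation probability 0.8 versus background 0.05 (a term left empty by
chance is anchored to one gene of its module). Synthetic DEG tables draw
log₂FC = planted Δ + N(0, 0.1) and adjusted p from a null/alternative
mixture (Uniform(0,1) vs 10^−U(2,8)). All generators are deterministic
given the seed (NumPy PCG64, fixed integer stream ids per generator).

What the simulator does not emulate: batch effects, library-preparation
biases, gene–gene correlation, length effects, outlier samples, or the
dependence structure of real adjusted p-values. Passing recovery tests
therefore demonstrates correctness of the implemented computations under
the assumed model, not robustness to real-data pathologies.

## Numerical choices

- p-values are clipped into (0, 1]; BH is the standard step-up (delegated
  to statsmodels, verified against an independent brute-force oracle).
- The exact signed-rank distribution is computed by integer convolution
  over doubled midranks (doubling makes .5 midranks integral), giving
  exact two-sided p-values as the symmetric tail mass about n(n+1)/4.
- Hypergeometric tails use the survival function at k − 1.
- Clustering ties are broken by lexicographic gene order; outputs are
  written with a fixed `%.10g` float format so fixed seed + config gives
  byte-identical files.
- Problem sizes in the test and acceptance runs (e.g. 300–1000 simulated
  genes, 200 replicates for recovery rates, 5000 null candidates for the
  calibration check) are chosen to make Monte-Carlo error small relative
  to the asserted margins while keeping the suite fast to iterate on.

## Known limitations

- The empirical-null statistic is not a calibrated per-gene test when
  candidate and housekeeping variances differ (see above); it ranks
  responsiveness relative to the panel.
- ORA treats genes as exchangeable and ignores term overlap structure and
  expression-level bias.
- Secondary module membership is a heuristic reconstruction with a free
  threshold.
- TPM-quantified input is not supported; the pipeline computes CPM from
  raw counts, and the two normalisations are not reconciled.
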