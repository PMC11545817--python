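# Methods

## Data model

A dataset is a flat table of samples with an origin label, a harvest year
and eight isotope markers in ‰: `d18O_bulk` (bulk kernel oxygen-18),
`d13C_16_0 … d13C_18_2` (carbon-13 of the palmitic, stearic, oleic and
linoleic fatty acid methyl esters) and `d2H_16_0, d2H_18_1, d2H_18_2`
(deuterium of the palmitic, oleic and linoleic esters). The schema is fixed:
every stage exchanges the same eight columns in the same order, values are
required to be finite, and missing values are rejected at read time rather
than imputed — the modelling stack assumes a complete matrix. CSV files are
comma-separated UTF-8 with `.` decimals; floats are serialized with `repr`
so a write/read cycle is bit-exact. Sample standard deviations use the n−1
denominator throughout (reported as 0 for singleton groups).

## Synthetic data generator

Only per-origin marker means and SDs of the real study are public, so each
(origin, harvest-year) cell is drawn from a multivariate Gaussian: mean =
origin mean + optional additive year shift, covariance =
diag(sd)·C·diag(sd). The default configuration uses the published four
origins × eight markers means/SDs, the real per-year sampling counts
(n = 207 total), C = I (independent markers) and zero year shifts.

What this emulates and what it does not: the generator reproduces the
published *marginal* class structure exactly, but real markers are
correlated within a class (they share the same source water and
biosynthesis), real distributions need not be Gaussian, and real
inter-annual shifts are nonzero. In particular the documented overlap
between the Spanish and Italian origins in the real data is stronger than
independent Gaussian marginals imply, so four-class classification rates on
synthetic data say nothing about four-class rates on real data; the
four-class configuration is exercised end-to-end but its rates are not
compared to the real study's. A shared correlation matrix and per-cell year
shifts are available to probe robustness.

Reproducibility contract: `generate` is a pure function of its config
including the seed. Every cell draws from a substream keyed by
(seed, CRC32(origin), year), so resizing one cell never perturbs another
cell's samples.

## Univariate screening

Per marker, the route is gated on per-group Shapiro–Wilk normality at
α = 0.05: if every origin passes, one-way ANOVA with Scheffé's post hoc
test; otherwise Kruskal–Wallis (tie-corrected) with pairwise Mann–Whitney U
under Bonferroni correction over the k(k−1)/2 pairs. The gate is applied
per group, the conservative reading; note that with k Gaussian groups the
parametric route is then taken with probability ≈ 0.95^k (≈ 0.81 for k = 4),
which is the expected behaviour of a per-group gate, not a defect. A
zero-variance group routes to the nonparametric path since Shapiro–Wilk is
undefined there. Year-effect tests within one origin use Student's t (both
years normal) or Mann–Whitney for two years and the gated k-group path
otherwise. No correction is applied across markers.

The Scheffé criterion declares groups i, j different iff
(m_i − m_j)² > (k−1)·F₁₋α(k−1, N−k)·MSE·(1/n_i + 1/n_j). Pairwise outcomes
are condensed into a compact letter display: letters label the maximal
cliques of the "not significantly different" graph, ordered by the highest
group mean in each clique, so `a` marks the top group and two groups share
a letter iff they are not significantly different. With zero within-group
variance the ANOVA degenerates without division: equal means give F = 0,
p = 1; unequal means give p = 0 with every unequal pair significant.

## PLS-DA

Class membership is dummy-coded (0/1, one column per class, centred);
predictors are autoscaled (mean-centred, unit n−1 variance). NIPALS PLS2
iterates u → w = Xᵀu/‖Xᵀu‖ → t = Xw → q = Yᵀt/tᵀt → u = Yq/qᵀq to a 10⁻¹⁰
relative score tolerance per component (10,000-iteration budget), deflates
X by t pᵀ with p = Xᵀt/tᵀt, and leaves Y undeflated — Y-deflation in PLS2
changes intermediate quantities but not predictions. Each weight vector's
largest-magnitude element is made positive so score plots are reproducible.
Coefficients are assembled as B = W(PᵀW)⁻¹Qᵀ; predictions add back the
dummy-column means and are *unconstrained* reals (no clipping to [0, 1], no
sum-to-one).

Cross-validation is leave-10%-out: ten folds by seeded stratified
round-robin assignment within each class (an assignment stripping a whole
class from any training set is re-drawn, up to 100 attempts). All
preprocessing — autoscaling constants and dummy-column means — is
re-estimated inside each fold, so held-out samples never influence their own
scaling. RMSEcv pools all dummy columns, RMSEcv(A) = √(PRESS(A)/nk), and
Q²(A) = 1 − PRESS(A)/SS with SS the total sum of squares of the centred
dummy matrix. The retained A minimises RMSEcv, ties to fewer components.

Overfitting diagnostics:

* **Permutation test** (20 permutations by default): class labels are
  shuffled and Q² recomputed by the same CV at the same A; the verdict is
  "not overfit" iff the original Q² strictly exceeds every permuted Q².
  Under pure noise the original wins with probability ≈ 1/(n_perm+1), the
  calibration the tests check.
* **CV-ANOVA**: F-test of the model's PRESS against the PRESS of the
  class-mean-only null model. Degrees of freedom: nk − k for the null
  (k column means) and nk − k(A+1) for the model, charging each latent
  variable one fitted direction per dummy column. This df convention is a
  design choice of this package (the convention of the commercial tool that
  popularised the statistic is not published); it is conservative under the
  null, where PRESS_model ≥ PRESS_null gives F ≤ 0 and p → 1.

## ROC thresholds and the rejection rule

One ROC curve per class is built from the cross-validated PVs of the final
training model against true binary membership. Candidate thresholds are
midpoints between consecutive distinct PVs plus ∓∞ sentinels; assignment is
strict (`PV > threshold`). The operating threshold maximises Youden's
J = sensitivity + specificity − 1, ties resolved toward the *higher*
(more specific) threshold. Classification of a PV row: take the argmax
class; assign iff its PV strictly exceeds that class's threshold, else
`NO_CLASS`. There is deliberately no fallback to the runner-up when the top
class fails its threshold — the rule names only the highest-PV class — and
this semantics is the package's documented reading of the rejection rule.

## Validation pipeline

Optionally merge origins (e.g. ESP and ITA into one Mediterranean class:
marker values untouched, labels rewritten). Each iteration draws a
stratified 80/20 split: per class, round-half-away-from-zero of 0.8·n
training samples (giving 32/73/32/29 = 166 for the four-class design and a
41-sample validation set), apportioned over (origin, year) cells by largest
remainder and clamped so every cell with ≥ 2 samples appears in both sets;
singleton cells go to training with a warning. Train → select A → refit →
calibrate thresholds on CV PVs → predict the validation set → confusion
table including the `NO_CLASS` column. Internal rates classify the CV PVs
of the training set with the same thresholds.

Seven iterations by default; iteration seeds derive from one root seed by
fixed offsets (root + 7919·i for the split, +104729 for the CV), so a single
integer reproduces the whole report. Summary rates are means over
per-iteration rates — not rates of mean counts; with per-iteration class
sizes fixed the two are close but not identical, and the former is what the
summary reports. SDs over iterations use n−1 (0 for a single iteration).

Exploratory PCA runs on autoscaled markers via SVD. Hotelling's T² sums
squared scores over retained components scaled by their variances, with the
95% limit A(n²−1)/(n(n−A))·F₀.₉₅(A, n−A). The residual distance is each
sample's residual SD normalised by the pooled residual SD with an
approximate F-based 95% limit — a simple convention chosen here because the
commercial "distance to model" limit is proprietary; the raw residual sum
of squares is also exposed.

## Problem sizes and numerical choices

Default study runs use the real design (n = 207, 7 iterations, A ≤ 8,
10 CV folds); the repeated-study checks average 5 independent root seeds.
NIPALS tolerance 10⁻¹⁰; autoscaling requires strictly positive column
variance and names the offending marker otherwise; a PV tie at argmax is
broken by class order with a logged warning; Kruskal–Wallis on fully tied
data returns p = 1 with one shared letter.

## Known limitations

* The generator's independence default understates real within-class
  correlation; synthetic classification rates are optimistic relative to
  real data for classes separated by correlated markers, and the ESP/ITA
  overlap cannot be reproduced from marginals.
* With the published marginals, the Georgian class is *almost* but not
  exactly always recovered: ≈ 2% of its validation samples are either
  rejected by their class threshold or narrowly out-scored by the Chilean
  class at small A. Claims of exactly 100% recovery do not survive this
  simulation.
* At 500 samples/origin the bulk δ¹⁸O compact letters reproduce the
  published ordering in only ≈ 70–75% of draws: the published CHL–ESP
  difference (0.1‰ against SDs of 0.7–0.8‰) sits below the Scheffé
  detection limit at that n, so the pair is split into different letters in
  the remaining draws.
* The univariate letters depend on the post hoc convention; the
  nonparametric post hoc (pairwise Mann–Whitney + Bonferroni) is a
  documented choice, swappable in principle.
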