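# Methods

## Statistical model

Each protein g is modelled on the variance-stabilized (glog2) scale by
ordinary least squares,

    y_gs = mu_{g, tissue(s) x condition(s)} + r_{g, replicate(s)} + e_gs,

a cell-means design over (tissue, condition) with a replicate factor.
Replicate dummies are added only while they increase the design rank and
leave at least one residual degree of freedom for complete rows; with a
constant replicate label the model reduces to plain group means. All
tissues of an assay are fitted jointly, so the residual variance and the
replicate factor are shared across organs, and each tissue contributes one
enrichment contrast (+UV cell minus -UV cell). Missing cells are handled
per protein by refitting on the observed rows; the estimable columns are
chosen by greedy rank-increasing selection in design order, and a protein
whose observed cells cannot identify the contrast is reported untestable
rather than failing.

Capture designs are tiny — typically two +UV eluates against a single
pooled -UV control — so the per-protein residual variances s2_g (d_g
degrees of freedom) are unusable alone. They are assumed drawn from a
scaled inverse-chi-square prior with d0 degrees of freedom and scale s0^2.
The prior is estimated by the closed-form moment fit on log variances:
with e_g = ln s2_g − psi(d_g/2) + ln(d_g/2), the excess of Var(e) over the
chi-square sampling variance mean psi'(d_g/2) determines d0 through the
trigamma inverse (monotone Newton iteration), and s0^2 follows from the
mean of e. Variances are floored at 1e-5 times their median before the
logarithm so a single near-zero residual variance cannot dominate the
spread estimate; when the excess is non-positive the prior is degenerate
(d0 = infinity, s0^2 = mean variance). The moderated statistic

    t_g = beta_g / (s_tilde_g sqrt(v_g)),
    s_tilde_g^2 = (d0 s0^2 + d_g s2_g) / (d0 + d_g)

is referred to t with d0 + d_g degrees of freedom (standard normal when d0
is infinite). Two-sided p-values are Benjamini-Hochberg corrected within
the tested set. A unit test verifies exact agreement (1e-10) of d0, s0^2,
t, p and the contrast with Bioconductor limma on a shared matrix.

Hit calling: hit iff FDR < 0.05 and log2 fold-change >= 1; candidate iff
not a hit, FDR < 0.2 and log2 fold-change >= log2(1.5). Enrichment must be
in the +UV direction; depleted proteins are never hits. Boundary cases use
>= on the log2 threshold (a measure-zero choice in practice). Proteins
quantified with fewer than 2 unique peptides are detected-but-untestable
and are classed no_hit; proteins absent from an assay are not_detected.

## Normalization

Raw reporter-ion intensities are first cleaned for batch effects on the
log2(x+1) scale: per protein, least squares of log intensity on the
preserved biological design (intercept, condition, tissue) plus
sum-to-zero batch indicators, subtracting only the fitted batch component;
the result is transformed back to the linear scale. Estimating the batch
coefficients jointly with the biological terms means condition estimates
re-derived from the corrected matrix equal the joint-fit estimates
exactly. A batch confounded with a preserved term raises an error naming
the columns. The scale for batch removal (the data do not dictate one) is
a documented package choice.

The variance-stabilizing transform is the affine-arsinh
h_s(x) = arsinh(a_s + b_s x)/ln 2, logarithmic at high intensity and
linear near zero. Calibration alternates (i) protein row means in
transformed space, computed over **all** fitted samples so the strata stay
on one common scale, restricted to the least-variable 90% of proteins
(trimmed by residual sum of squares), and (ii) a per-stratum refit of
(a, b) by L-BFGS with analytic gradients on the profile-likelihood
objective (m/2) ln RSS − Σ ln h'. The Jacobian term is essential: without
it the alternation drifts toward a degenerate constant transform by
shrinking every b jointly. Iteration stops at relative parameter change
< 1e-8 or 50 rounds (non-convergence is recorded in the returned
parameters; the best iterate is used). The initial scale is b = 1/q01 of
the positive intensities, a noise-floor proxy that places the bulk of
proteins in the logarithmic regime. On matrices beyond 600 proteins the
calibration uses a deterministic, evenly spaced subset of rows (the
transform is still applied to every row), keeping repeated fits cheap.

Sample-grouping strategies: `per-tissue-condition` gives every sample its
own coefficient pair (coefficients therefore differ freely across tissues
and conditions) — sharing one pair within a group was tried and rejected
because per-sample loading differences then inflate the residual variance;
`single-plusUV` fits one pair for all +UV samples, for cross-tissue
comparisons of the +UV eluates; `plusUV-only` fits on +UV samples only and
transforms the -UV control with its assay's fitted pair, preserving the
abundance difference from the non-crosslinked control. Equal-mean
renormalization (used for between-organ comparisons of individual RBPs)
subtracts per-sample means over the shared complete proteins and restores
the grand mean.

## Integration and downstream summaries

The biotype class of a (protein, organ) pair is a pure function of its
poly(A) and non-poly(A) enrichment classes: dual iff both qualify;
exclusive iff one qualifies and the protein is undetected on the other
side; unresolved iff it qualifies on one side and is detected but not
enriched on the other; none otherwise. Qualification is hit-only
(`organ_atlas` preset) or hit-or-candidate (`liver_deep` preset). An
optional per-organ exclusion list promotes proteins detected in a deeper
non-poly(A) run from not_detected to no_hit, so they cannot be exclusive
poly(A) binders. The 4x4x2 truth table is committed as an exhaustive test
fixture.

Cross-organ overlaps, novel-RBP identification (organ hits absent from the
published-atlas membership flag), cell-line presence histograms and the
staged missing-in-organ cascade are exact set algebra, each tested against
brute-force enumeration. Mean-signal summaries average linear-scale
intensities over all observed (protein, sample) cells per group; the
relative-abundance matrix uses the arithmetic row mean on the linear scale
within each sample family (pinned by a hand-computed fixture: row [1, 2, 4]
maps to log2 ratios [-1.222, -0.222, 0.778]); clustering is average
linkage on 1 − Pearson correlation (scipy), deterministic given the input
row order. Binding-versus-abundance decoupling compares organ-pair
contrasts from eluates and inputs fitted under equal-mean renormalization,
with an abundance tolerance of log2(1.5) by default.

## Gel-fraction crosslink QC

Fraction boundaries default to 20, 25, 37, 50, 75, 100, 150 kDa with an
open top fraction. A (protein, fraction) is validly detected when seen
with >= 2 unique peptides in >= 2 of 3 replicates. Valid iBAQ cells are
divided by the protein's total valid iBAQ (cell proportions sum to 1), and
per-fraction profiles sum the cells over replicates. Classification:
bimodal iff two local maxima (ties toward lower mass), each carrying
>= tau = 0.25 of the mass, separated by at least one fraction, one of them
at the predicted (or boundary) fraction — bimodality is checked first so a
genuine second high-mass mode is not hidden by a slightly taller predicted
peak; otherwise monomeric iff the modal fraction contains the predicted
mass; boundary_proximal iff the modal fraction is one above and the
predicted mass lies within 10 kDa below the fraction boundary; shifted
iff modal above predicted; unclassified below. "Preferential high-mass
localization" means more than half of the mass above the predicted
fraction; the committed convention for the piggy-back risk statistic is
the percentage of such proteins that are capture hits within 10 kDa of a
boundary.

## Enrichment testing

Fisher exact tests use the hypergeometric distribution; two-sided
p-values follow the point-probability (minimum-likelihood) convention,
matching scipy and verified against full enumeration for all small
tables. Sample odds ratios apply the Haldane 0.5 correction when a cell is
zero. Multiple testing across terms is Benjamini-Hochberg everywhere; the
catalytic-class panel is deliberately uncorrected and flags itself as
such. The enzyme cofactor/domain comparison takes metabolite-
interconversion enzymes that are capture hits in any organ against enzymes
detected in inputs but never in eluates. Pathway RBP fractions default to
all annotated members as the denominator, with an option to restrict to
input-detected members.

## Synthetic data

The generator emulates the study design: per tissue, two +UV and one
pooled -UV capture sample for each chemistry plus duplicate inputs.
Intensities follow 2^(a_g + t_gT + b_B + u_s + delta_g 1[+UV] + eps) with
baseline a_g ~ N(10, 2) on log2, tissue effects (SD 0.5), scalar batch
effects per TMT run (SD 0.3), per-sample loadings (SD 0.5), noise
(SD 0.3), and planted enrichment delta ~ N(2, 0.5) (clipped at 0) in 25%
of proteins, scaled per organ by activity multipliers 0.6 / 1.3 / 1.0
(brain / kidney / liver) to mimic organ-specific binding activity. 60% of
true RBPs also bind non-poly(A) RNA; 5% of non-RBPs bind only non-poly(A)
RNA. Cells go missing with logistic abundance-dependent probability
(midpoint 5 on log2 intensity, slope 0.8), and unique-peptide counts are
1 + Poisson tied to abundance so the two-peptide filter is exercised.
Gel-fraction profiles concentrate Dirichlet-perturbed mass at the
predicted fraction (monomeric, 80%), at least two fractions higher
(shifted, 10%), or split between the two (bimodal, 10%); proteins whose
predicted fraction is already near the top of the gel stay monomeric
because a shift is not realizable. Annotation catalogs plant a
configurable cofactor odds ratio among enzymes (default 4), a novel-RBP
fraction (default 20%) and cell-line detection flags. Every output is a
pure function of (config, seed); sub-generators derive streams from the
seed by fixed offsets.

What the generator does **not** emulate: reporter-ion ratio compression
and isotope-impurity interference, correlated (protein-level) missingness,
contaminants and decoys, and between-run protein-identity drift. Passing
tests therefore demonstrate correctness of the statistical machinery under
the stated design, not robustness to every artifact of real TMT data.

## Problem sizes and runtime choices

Test and acceptance runs use sizes chosen to make the statistical checks
well-powered yet quick on a single CPU: 800-2000 proteins per simulated
experiment, 200 replicate null simulations for calibration, 100 replicates
for prior-recovery coverage, 300 proteins for gel-fraction recovery, and
exhaustive Fisher enumeration over small tables. The full suite runs in
about two minutes; the acceptance script in under half a minute.

## Known limitations

- The VST is a reimplementation of the affine-arsinh model with a trimmed
  alternating fit; it matches the reference on parameter ratios and
  variance flattening but is not bit-identical to the reference robust-ML
  fit.
- With per-condition calibration, a genuinely global enrichment component
  is partially absorbed into the -UV/+UV offset (observed as a small
  negative shift of non-enriched proteins); per-protein enrichment above
  that baseline is preserved, which is the quantity the hit rule tests.
- Under the null the end-to-end pipeline is conservative (hit rates well
  below nominal FDR) because normalization smooths part of the
  between-sample variability; the moderated test itself is calibrated
  (type-I rate 0.05 on direct simulations).
- Independent hypothesis weighting is not implemented; all multiple
  testing is Benjamini-Hochberg and outputs are labelled accordingly.
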