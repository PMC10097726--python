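# ricproteo

Analysis of organ RNA-binding proteomes from UV-crosslink RNA-capture
proteomics (eRIC and non-poly(A) RIC).

In RNA interactome capture, tissue is UV-irradiated to crosslink proteins
to RNA in situ, poly(A) RNA is isolated with oligo(dT) probes (or
non-poly(A) RNA over silica after poly(A) depletion), and the co-purified
proteins are quantified by isobaric-label (TMT) mass spectrometry. A
protein that binds RNA in vivo is *enriched* in the crosslinked (+UV)
eluate over the non-irradiated (-UV) control. `ricproteo` implements the
full downstream analysis that turns protein-level reporter-ion tables into
organ RBP atlases:

- **Normalization** — batch-effect removal by per-protein least squares and
  an affine-arsinh variance-stabilizing transform
  h_s(x) = arsinh(a_s + b_s·x)/ln 2, calibrated by iterative trimmed least
  squares against common protein row means, with the sample-grouping
  strategies needed for capture data (per-sample, single +UV coefficient,
  or +UV-only fitting that preserves the -UV abundance gap).
- **Moderated enrichment testing** — per-protein OLS with tissue-condition
  cell means and a replicate factor, empirical-Bayes variance shrinkage
  toward a scaled inverse-chi-square prior (d₀, s₀²) estimated by a
  closed-form moment fit on log variances, moderated t statistics
  t_g = β̂_g / (s̃_g √v_g) on d₀ + d_g degrees of freedom,
  Benjamini-Hochberg correction, and hit/candidate calling
  (hit: FDR < 0.05 and FC ≥ 2; candidate: FDR < 0.2 and FC ≥ 1.5;
  ≥ 2 unique peptides).
- **Interactome integration** — dual / exclusive / unresolved biotype
  classes from paired poly(A) and non-poly(A) results, cross-organ Venn
  overlaps, novel-RBP calls against a published-atlas catalog, and the
  staged "missing in organs" cascade.
- **Organ activity** — RNA-content-adjusted signal, mean-signal ratios
  between organs, relative-abundance heatmap matrices with average-linkage
  correlation clustering, replicate correlation, and binding-versus-
  abundance decoupling under equal-mean renormalization.
- **Crosslink QC** — gel-fraction iBAQ proportion profiles, a
  proportion-weighted molecular-weight density, and migration
  classification (monomeric / boundary-proximal / bimodal / shifted) that
  flags potential protein-protein crosslink "piggy-back" artifacts.
- **Annotation enrichment** — exact Fisher tests (one-tailed or two-sided
  by the point-probability rule) for domains, cofactors, catalytic classes
  and pathway RBP fractions.
- **Synthetic data** — a generator that emulates the study design (two +UV
  and one pooled -UV capture per organ, matched inputs, batch effects,
  sample scaling, abundance-dependent missingness, planted enrichment and
  planted gel-migration classes) so every stage is testable against known
  ground truth.

## Worked example

```python
import ricproteo as rp
from ricproteo.simulate import SimConfig, simulate_eric_experiment

cfg = SimConfig(n_proteins=800, seed=1)
quant, truth = simulate_eric_experiment(cfg)
eric = quant.subset_samples(
    [s.sample_id for s in quant.samples if s.assay == "eric"]
)
results = rp.EnrichmentModel.from_quant(eric).fit()
print(results.summary())
```

prints

```
Moderated enrichment test (+UV vs -UV)
====================================================
proteins:            800
prior df (d0):       36.4
prior variance s0^2: 0.08382
hit rule:  FDR < 0.05 and FC >= 2
cand rule: FDR < 0.2 and FC >= 1.5

              brain  kidney  liver
enrich_class
hit              61     149    132
candidate        48       6     16
no_hit          689     641    651
not_detected      2       4      1
```

The prior degrees of freedom d₀ = 36.4 say the 800 per-protein variances
are strongly shrunk toward the common prior s₀² = 0.084 — that is what
makes a two-versus-one design testable at all. The hit counts per organ
track the planted organ-activity multipliers (kidney > liver > brain).
Comparing the union of hits with the planted truth recovers 151 of the 179
simulated RBPs (84.4%). `results.tables[tissue]` holds the per-protein
log₂ fold-change, moderated t, p, FDR and class; `results.volcano("kidney")`
draws the volcano plot.

The same analysis runs from the shell:

```bash
ricproteo simulate --out data/ --seed 1
ricproteo test --quant data/quant.tsv --samples data/samples.tsv \
    --tissue kidney --out kidney_diff.tsv
ricproteo demo --out demo_out/ --seed 1     # full pipeline end to end
```

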