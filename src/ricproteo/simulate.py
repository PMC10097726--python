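"""Synthetic crosslink-capture experiments with known ground truth.

The generator emulates the organ study design: per tissue, two +UV capture
eluates and one pooled -UV control for the poly(A) capture (eRIC) and the
non-poly(A) capture, plus matched total-proteome input samples. Intensities
follow a multiplicative model on the log2 scale

    intensity = 2^(a_g + t_gT + b_B + u_s + delta_g * 1[+UV] + eps) + bg

with protein baseline ``a_g``, tissue effect ``t_gT``, additive batch effect
``b_B``, per-sample scaling ``u_s``, planted crosslink enrichment
``delta_g`` in true RNA-binding proteins (scaled per tissue by an organ
activity multiplier), and Gaussian noise. Cells go missing with
abundance-dependent (logistic) probability, and unique-peptide counts track
abundance so the two-peptide filter is exercised. A companion generator
plants monomeric / shifted / bimodal gel-migration profiles for the
crosslink QC, and a third plants annotation catalogs with a configurable
cofactor odds ratio and novel-RBP fraction.

Everything is a pure function of (config, seed); sub-generators derive
their streams from the config seed by fixed offsets.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datatypes import (
    DEFAULT_FRACTION_BOUNDS,
    AnnotationCatalog,
    FractionProfile,
    QuantMatrix,
    SampleInfo,
    ValidationError,
)


class ConfigError(ValueError):
    """Degenerate simulation configuration."""


@dataclass
class SimConfig:
    """Study-design parameters for the synthetic experiment.

    Defaults reproduce the organ study's layout (three tissues; two +UV and
    one -UV capture sample per tissue and assay; duplicate inputs) with
    effect sizes and noise levels typical of TMT capture data: ~25% true
    RBPs with mean log2 enrichment 2 (FC 4), organ activity highest in
    kidney and lowest in brain, batch SD 0.3, sample scaling SD 0.5,
    residual noise SD 0.3 on the log2 scale.
    """

    n_proteins: int = 1500
    tissues: tuple[str, ...] = ("brain", "kidney", "liver")
    n_plus_uv: int = 2
    n_minus_uv: int = 1
    n_input: int = 2
    include_nonpolya: bool = True
    include_input: bool = True
    rbp_fraction: float = 0.25
    enrichment_log2fc_loc: float = 2.0
    enrichment_log2fc_scale: float = 0.5
    organ_activity_multiplier: dict = field(
        default_factory=lambda: {"brain": 0.6, "kidney": 1.3, "liver": 1.0}
    )
    nonpolya_overlap: float = 0.6     # fraction of RBPs that also bind non-poly(A) RNA
    nonpolya_exclusive_fraction: float = 0.05  # non-RBPs binding only non-poly(A)
    baseline_log2_mean: float = 10.0
    baseline_log2_sd: float = 2.0
    tissue_effect_sd: float = 0.5
    batch_sd: float = 0.3
    sample_scale_sd: float = 0.5
    noise_sd: float = 0.3
    additive_background: float = 0.0
    detection_midpoint: float = 5.0
    detection_slope: float = 0.8
    peptide_lambda: float = 6.0
    peptide_cap: int = 60
    # gel-fraction QC
    n_fraction_proteins: int = 300
    fraction_bounds: tuple[float, ...] = DEFAULT_FRACTION_BOUNDS
    monomeric_fraction: float = 0.8
    shifted_fraction: float = 0.1
    fraction_noise: float = 0.02      # off-target share of the mean profile
    replicate_concentration: float = 400.0  # Dirichlet concentration across replicates
    # annotations
    cofactor_or: float = 4.0
    cofactor_base_rate: float = 0.2
    enzyme_fraction: float = 0.3
    novel_fraction: float = 0.2
    rbd_fraction: float = 0.2
    n_cell_lines: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_proteins <= 0:
            raise ConfigError("n_proteins must be positive")
        if not (0 <= self.rbp_fraction <= 1):
            raise ConfigError("rbp_fraction must lie in [0, 1]")
        if self.n_plus_uv < 1 or self.n_minus_uv < 1:
            raise ConfigError("need at least one +UV and one -UV sample")
        for name in ("batch_sd", "sample_scale_sd", "noise_sd", "additive_background"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")


def _rng(cfg_seed: int, offset: int) -> np.random.Generator:
    return np.random.default_rng((int(cfg_seed) * 1009 + offset) % (2**31 - 1))


def _logistic(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def _build_samples(cfg: SimConfig) -> list[SampleInfo]:
    samples: list[SampleInfo] = []
    assays = ["eric"]
    if cfg.include_nonpolya:
        assays.append("nonpolya_ric")
    for tissue in cfg.tissues:
        for assay in assays:
            for r in range(1, cfg.n_plus_uv + 1):
                samples.append(
                    SampleInfo(
                        sample_id=f"{tissue}_{assay}_plusUV_r{r}",
                        tissue=tissue,
                        assay=assay,
                        condition="plusUV",
                        replicate=r,
                        batch=f"{assay}_r{r}",
                    )
                )
            for r in range(1, cfg.n_minus_uv + 1):
                samples.append(
                    SampleInfo(
                        sample_id=f"{tissue}_{assay}_minusUV_r{r}",
                        tissue=tissue,
                        assay=assay,
                        condition="minusUV",
                        replicate=r,
                        batch=f"{assay}_r{r}",
                    )
                )
        if cfg.include_input:
            for r in range(1, cfg.n_input + 1):
                samples.append(
                    SampleInfo(
                        sample_id=f"{tissue}_input_plusUV_r{r}",
                        tissue=tissue,
                        assay="input",
                        condition="plusUV",
                        replicate=r,
                        batch=f"input_r{r}",
                    )
                )
    return samples


def simulate_eric_experiment(cfg: SimConfig) -> tuple[QuantMatrix, pd.DataFrame]:
    """Simulate one full multi-tissue capture experiment.

    Returns the quantification matrix and a ground-truth table with one row
    per protein: ``is_rbp`` (true poly(A) binder), ``is_nonpolya_binder``,
    and the planted ``true_log2fc_<tissue>`` for the poly(A) capture.
    """
    samples = _build_samples(cfg)
    if not samples:
        raise ConfigError("configuration produces no samples")
    G = cfg.n_proteins
    proteins = pd.Index([f"P{i:05d}" for i in range(G)], name="accession")

    rng_truth = _rng(cfg.seed, 1)
    rng_effects = _rng(cfg.seed, 2)
    rng_noise = _rng(cfg.seed, 3)

    is_rbp = rng_truth.random(G) < cfg.rbp_fraction
    dual = is_rbp & (rng_truth.random(G) < cfg.nonpolya_overlap)
    nonpolya_only = ~is_rbp & (rng_truth.random(G) < cfg.nonpolya_exclusive_fraction)
    is_nonpolya = dual | nonpolya_only

    base_delta = rng_truth.normal(cfg.enrichment_log2fc_loc, cfg.enrichment_log2fc_scale, G)
    base_delta = np.clip(base_delta, 0.0, None)
    base_delta_np = np.clip(
        rng_truth.normal(cfg.enrichment_log2fc_loc, cfg.enrichment_log2fc_scale, G), 0.0, None
    )

    a_g = rng_effects.normal(cfg.baseline_log2_mean, cfg.baseline_log2_sd, G)
    tissue_eff = {
        t: rng_effects.normal(0.0, cfg.tissue_effect_sd, G) for t in cfg.tissues
    }
    batches = sorted({s.batch for s in samples})
    batch_eff = {b: rng_effects.normal(0.0, cfg.batch_sd) for b in batches}
    sample_scale = {
        s.sample_id: rng_effects.normal(0.0, cfg.sample_scale_sd) for s in samples
    }

    truth = pd.DataFrame(index=proteins)
    truth["is_rbp"] = is_rbp
    truth["is_nonpolya_binder"] = is_nonpolya
    delta_by_tissue: dict[str, dict[str, np.ndarray]] = {"eric": {}, "nonpolya_ric": {}}
    for t in cfg.tissues:
        mult = float(cfg.organ_activity_multiplier.get(t, 1.0))
        d_e = np.where(is_rbp, base_delta * mult, 0.0)
        d_n = np.where(is_nonpolya, base_delta_np * mult, 0.0)
        delta_by_tissue["eric"][t] = d_e
        delta_by_tissue["nonpolya_ric"][t] = d_n
        truth[f"true_log2fc_{t}"] = d_e
        truth[f"true_log2fc_nonpolya_{t}"] = d_n

    cols = {}
    for s in samples:
        mu = a_g + tissue_eff[s.tissue] + batch_eff[s.batch] + sample_scale[s.sample_id]
        if s.assay in ("eric", "nonpolya_ric") and s.condition == "plusUV":
            mu = mu + delta_by_tissue[s.assay][s.tissue]
        eps = rng_noise.normal(0.0, cfg.noise_sd, G)
        x = np.exp2(mu + eps) + cfg.additive_background
        p_obs = _logistic((np.log2(np.maximum(x, 1e-12)) - cfg.detection_midpoint) * cfg.detection_slope)
        observed = rng_noise.random(G) < p_obs
        cols[s.sample_id] = np.where(observed, x, np.nan)
    intensity = pd.DataFrame(cols, index=proteins)

    lam = cfg.peptide_lambda * np.exp2(a_g - cfg.baseline_log2_mean)
    peptides = 1 + rng_noise.poisson(np.minimum(lam, cfg.peptide_cap))
    peptides = np.minimum(peptides, cfg.peptide_cap)
    q = QuantMatrix(
        intensity=intensity,
        samples=samples,
        unique_peptides=pd.Series(peptides, index=proteins),
    )
    return q, truth


# ------------------------------------------------------------- fractions
def _fraction_of_mass(mass: float, bounds) -> int:
    for i, b in enumerate(bounds):
        if mass <= b:
            return i
    return len(bounds) - 1


def simulate_fraction_profiles(
    cfg: SimConfig, seed: int | None = None
) -> tuple[FractionProfile, pd.DataFrame]:
    """Plant monomeric / shifted / bimodal gel-migration profiles.

    Monomeric proteins put essentially all iBAQ mass in the fraction
    containing their predicted mass (all of it when ``fraction_noise`` is
    0); shifted proteins migrate at least two fractions above; bimodal
    proteins split between the predicted fraction and a distant higher one.
    Three replicates with Dirichlet replicate noise.
    """
    rng = _rng(cfg.seed if seed is None else seed, 7)
    bounds = tuple(cfg.fraction_bounds)
    if not np.all(np.diff([b for b in bounds if np.isfinite(b)]) > 0):
        raise ConfigError("fraction bounds must increase")
    G = cfg.n_fraction_proteins
    F = len(bounds)
    proteins = pd.Index([f"F{i:04d}" for i in range(G)], name="accession")
    mass = np.exp(rng.uniform(np.log(15.0), np.log(250.0), G))
    u = rng.random(G)
    klass = np.where(
        u < cfg.monomeric_fraction,
        "monomeric",
        np.where(u < cfg.monomeric_fraction + cfg.shifted_fraction, "shifted", "bimodal"),
    )
    # a protein already migrating near the top of the gel has no room to
    # shift: keep those monomeric so the planted truth is realizable
    pf_all = np.array([_fraction_of_mass(m, bounds) for m in mass])
    klass = np.where(pf_all > F - 3, "monomeric", klass)

    reps = [1, 2, 3]
    arr = np.zeros((G, len(reps), F))
    valid = np.zeros((G, len(reps), F), dtype=bool)
    peps = np.zeros((G, len(reps), F), dtype=int)
    target2 = np.full(G, -1)
    for g in range(G):
        pf = _fraction_of_mass(mass[g], bounds)
        mean = np.full(F, cfg.fraction_noise / max(F - 1, 1))
        if klass[g] == "monomeric":
            mean[:] = cfg.fraction_noise / max(F - 1, 1)
            mean[pf] = 1.0 - cfg.fraction_noise
        elif klass[g] == "shifted":
            hi = min(pf + 2 + int(rng.integers(0, 2)), F - 1)
            if hi == pf:
                hi = min(pf + 1, F - 1)
            mean[hi] = 1.0 - cfg.fraction_noise
            target2[g] = hi
        else:  # bimodal: predicted peak plus a distant high-mass peak
            hi = min(pf + 2 + int(rng.integers(0, 2)), F - 1)
            if hi - pf < 2:
                hi = F - 1
                if hi - pf < 2:
                    pf = max(0, hi - 2)
            mean[pf] = (1.0 - cfg.fraction_noise) * 0.5
            mean[hi] = (1.0 - cfg.fraction_noise) * 0.5
            target2[g] = hi
        mean = mean / mean.sum()
        total = np.exp(rng.normal(np.log(1e7), 0.5))
        for ri in range(len(reps)):
            if cfg.fraction_noise <= 0 and cfg.replicate_concentration >= 1e9:
                p = mean
            else:
                conc = np.maximum(mean * cfg.replicate_concentration, 1e-3)
                p = rng.dirichlet(conc)
            arr[g, ri] = p * total
            peps[g, ri] = rng.poisson(np.maximum(p, 0.0) * 25.0)
            valid[g, ri] = arr[g, ri] > 0
    cols = pd.MultiIndex.from_product([reps, range(F)], names=["replicate", "fraction"])
    ibaq = pd.DataFrame(arr.reshape(G, -1), index=proteins, columns=cols)
    vmask = pd.DataFrame(valid.reshape(G, -1), index=proteins, columns=cols)
    pep = pd.DataFrame(peps.reshape(G, -1), index=proteins, columns=cols)
    fp = FractionProfile(
        ibaq=ibaq,
        valid=vmask,
        bounds=bounds,
        predicted_mass_kda=pd.Series(mass, index=proteins),
        peptides=pep,
    )
    truth = pd.DataFrame(
        {"true_mass_class": klass, "predicted_mass_kda": mass, "high_fraction": target2},
        index=proteins,
    )
    return fp, truth


# ----------------------------------------------------------- annotations
PROTEIN_CLASSES = (
    "metabolite interconversion enzyme",
    "nucleic acid-binding protein",
    "translational protein",
    "transporter",
    "cytoskeletal protein",
    "other",
)
CATALYTIC_TYPES = ("oxidoreductase", "transferase", "hydrolase", "ligase", "lyase", "isomerase")
COFACTOR_POOL = ("NAD(P)", "ATP", "AMP", "FAD", "CoA", "metal")
NUCLEOTIDE_COFACTORS = {"NAD(P)", "ATP", "AMP", "FAD", "CoA"}


def simulate_annotations(
    cfg: SimConfig, truth: pd.DataFrame, seed: int | None = None
) -> AnnotationCatalog:
    """Plant an annotation catalog consistent with the simulated truth.

    Among enzymes, possession of a nucleotide cofactor is planted with odds
    ratio ``cfg.cofactor_or`` for RBP-enzymes versus non-RBP enzymes. A
    fraction ``cfg.novel_fraction`` of true RBPs is left out of the
    published-atlas flag (the novel RBPs), and cell-line detection flags,
    pathways, domains and per-organ input-proteome flags are drawn with
    realistic incidence.
    """
    rng = _rng(cfg.seed if seed is None else seed, 11)
    proteins = truth.index
    G = len(proteins)
    is_rbp = truth["is_rbp"].to_numpy(bool)

    is_enzyme = rng.random(G) < cfg.enzyme_fraction
    classes = np.where(
        is_enzyme,
        "metabolite interconversion enzyme",
        rng.choice(PROTEIN_CLASSES[1:], size=G),
    )
    cat_type = np.where(is_enzyme, rng.choice(CATALYTIC_TYPES, size=G), None)

    p0 = cfg.cofactor_base_rate
    odds0 = p0 / (1 - p0)
    odds1 = odds0 * cfg.cofactor_or
    p1 = odds1 / (1 + odds1)
    has_nuc_cof = np.where(
        is_enzyme, rng.random(G) < np.where(is_rbp, p1, p0), False
    ).astype(bool)

    cofactors: dict[str, set[str]] = {}
    domains: dict[str, set[str]] = {}
    nuc_map: dict[str, str] = {"dom_generic": "none"}
    for c in COFACTOR_POOL:
        nuc_map[f"dom_{c}"] = c if c in NUCLEOTIDE_COFACTORS else "none"
    for i, acc in enumerate(proteins):
        cs: set[str] = set()
        ds: set[str] = set()
        if has_nuc_cof[i]:
            pick = rng.choice(sorted(NUCLEOTIDE_COFACTORS))
            cs.add(str(pick))
            ds.add(f"dom_{pick}")
        if rng.random() < 0.3:
            cs.add("metal")
        if rng.random() < 0.4:
            ds.add("dom_generic")
        cofactors[str(acc)] = cs
        domains[str(acc)] = ds

    known = is_rbp & (rng.random(G) >= cfg.novel_fraction)
    known |= ~is_rbp & (rng.random(G) < 0.02)
    has_rbd = is_rbp & (rng.random(G) < cfg.rbd_fraction)
    n_studies = np.where(known, rng.integers(1, 31, G), 0)

    lines = [f"CL{i}" for i in range(1, cfg.n_cell_lines + 1)]
    cell_lines = {}
    for i, acc in enumerate(proteins):
        k = rng.binomial(cfg.n_cell_lines, 0.6)
        cell_lines[str(acc)] = set(rng.choice(lines, size=k, replace=False).tolist())

    pathway_ids = [f"pw{j:02d}" for j in range(20)]
    pathways = {}
    for acc in proteins:
        k = int(rng.integers(0, 4))
        pathways[str(acc)] = set(rng.choice(pathway_ids, size=k, replace=False).tolist())

    table = pd.DataFrame(
        {
            "known_rbp": known,
            "has_rbd": has_rbd,
            "protein_class": classes,
            "catalytic_type": cat_type,
            "catalytic_subtype": cat_type,
            "n_atlas_studies": n_studies,
        },
        index=proteins,
    )
    for organ in cfg.tissues:
        table[f"input_{organ}"] = rng.random(G) < 0.9
    return AnnotationCatalog(
        table=table,
        pathways=pathways,
        domains=domains,
        cofactors=cofactors,
        cell_lines=cell_lines,
        domain_nucleotide_map=nuc_map,
    )


__all__ = [
    "ConfigError",
    "SimConfig",
    "simulate_eric_experiment",
    "simulate_fraction_profiles",
    "simulate_annotations",
    "PROTEIN_CLASSES",
    "CATALYTIC_TYPES",
    "NUCLEOTIDE_COFACTORS",
]
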