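"""Moderated differential enrichment testing of +UV over -UV capture.

The statistical core of the pipeline. Each protein g is modelled on the
variance-stabilized (glog2) scale by ordinary least squares with a design of
intercept + UV condition + replicate factor, giving the contrast estimate
beta_g (log2 fold-change +UV minus -UV), residual variance s2_g on d_g
degrees of freedom, and the unscaled contrast variance v_g.

Because capture designs are tiny (typically two +UV against a single pooled
-UV control), the per-protein variances are unusable on their own. They are
shrunk toward an empirical-Bayes prior: the residual variances are assumed
to follow a scaled inverse-chi-square prior with d0 degrees of freedom and
scale s0^2, estimated from all proteins by a closed-form moment fit on the
log variances. The moderated statistic

    t_g = beta_g / (s_tilde_g * sqrt(v_g)),
    s_tilde_g^2 = (d0 * s0^2 + d_g * s2_g) / (d0 + d_g)

is referred to a t distribution on d0 + d_g degrees of freedom (standard
normal when d0 is infinite). Two-sided p-values are corrected by
Benjamini-Hochberg, and proteins are called *hits* (FDR < 0.05 and fold
change >= 2) or *candidates* (FDR < 0.2 and fold change >= 1.5), enrichment
direction +UV only.

The statsmodels-style entry point is :class:`EnrichmentModel`, whose
``fit()`` returns an :class:`EnrichmentResults` carrying the per-protein
table, the moderation prior and a ``summary()``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats

from .datatypes import (
    ModerationParams,
    QuantMatrix,
    SampleInfo,
    Thresholds,
    ValidationError,
)

# --------------------------------------------------------------- designs


def build_design(samples: list[SampleInfo]) -> pd.DataFrame:
    """Cell-means design over (tissue, condition) plus a replicate factor.

    One indicator column per (tissue, condition) cell present in the data,
    then replicate dummies added while they increase the design rank
    *without* exhausting the residual degrees of freedom (at least one df
    is kept for complete rows). With a constant replicate label this
    reduces to plain group means, i.e. a two-sample comparison per tissue.
    """
    ids = [s.sample_id for s in samples]
    conds = {s.condition for s in samples}
    if len(conds) < 2:
        raise ValidationError("design needs both plusUV and minusUV samples")
    cells = sorted({(s.tissue, s.condition) for s in samples})
    cols = {
        f"cell_{t}_{c}": np.array(
            [1.0 if (s.tissue, s.condition) == (t, c) else 0.0 for s in samples]
        )
        for t, c in cells
    }
    X = np.column_stack(list(cols.values()))
    reps = sorted({s.replicate for s in samples})
    for r in reps[1:]:
        col = np.array([1.0 if s.replicate == r else 0.0 for s in samples])
        Xc = np.column_stack([X, col])
        rank = np.linalg.matrix_rank(Xc)
        if rank > np.linalg.matrix_rank(X) and rank <= len(ids) - 1:
            cols[f"rep_{r}"] = col
            X = Xc
    return pd.DataFrame(cols, index=ids)


def tissue_contrasts(design: pd.DataFrame, samples: list[SampleInfo]) -> dict[str, np.ndarray]:
    """Per-tissue enrichment contrast vectors (plusUV cell minus minusUV cell)."""
    out = {}
    for tissue in sorted({s.tissue for s in samples}):
        plus, minus = f"cell_{tissue}_plusUV", f"cell_{tissue}_minusUV"
        if plus in design.columns and minus in design.columns:
            c = np.zeros(design.shape[1])
            c[design.columns.get_loc(plus)] = 1.0
            c[design.columns.get_loc(minus)] = -1.0
            out[tissue] = c
    if not out:
        raise ValidationError("no tissue has both plusUV and minusUV samples")
    return out


@dataclass
class FitResult:
    """Per-protein OLS output for the enrichment contrast."""

    proteins: pd.Index
    beta: np.ndarray        # contrast estimate (plusUV - minusUV), NaN if untestable
    s_sq: np.ndarray        # residual variance, NaN when df_resid == 0
    df_resid: np.ndarray    # integer residual df (0 allowed)
    v_contrast: np.ndarray  # unscaled variance of the contrast
    testable: np.ndarray    # bool: contrast estimable from observed cells

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "beta": self.beta,
                "s_sq": self.s_sq,
                "df_resid": self.df_resid,
                "v_contrast": self.v_contrast,
                "testable": self.testable,
            },
            index=self.proteins,
        )


def _solve_pattern(Xs: np.ndarray, contrast: np.ndarray):
    """Select estimable columns for one missingness pattern.

    Greedy rank-increasing column selection in design order; the contrast
    is estimable only if every column it loads on is kept. Returns
    (kept indices, rank, v_contrast, restricted contrast) or None.
    """
    n, p = Xs.shape
    kept: list[int] = []
    rank = 0
    for j in range(p):
        if not np.any(Xs[:, j] != 0):
            continue
        r2 = np.linalg.matrix_rank(Xs[:, kept + [j]])
        if r2 > rank:
            kept.append(j)
            rank = r2
    if not kept:
        return None
    needed = np.where(contrast != 0)[0]
    if not set(needed) <= set(kept):
        return None
    Xk = Xs[:, kept]
    ck = contrast[kept]
    xtx_inv = np.linalg.pinv(Xk.T @ Xk)
    v = float(ck @ xtx_inv @ ck)
    if v <= 0:
        return None
    return np.array(kept), rank, v, ck


def fit_linear_models(
    matrix: pd.DataFrame,
    samples: list[SampleInfo],
    design: pd.DataFrame | None = None,
    contrast: np.ndarray | None = None,
) -> FitResult:
    """OLS per protein on the observed cells for one enrichment contrast.

    ``contrast`` is a vector over the design columns; by default the
    plusUV-minusUV contrast averaged over the tissues present. Proteins
    whose observed cells cannot estimate the contrast (missing condition,
    rank-deficient subset) are flagged untestable rather than raising.
    """
    if design is None:
        design = build_design(samples)
    if contrast is None:
        percell = tissue_contrasts(design, samples)
        contrast = np.mean(list(percell.values()), axis=0)
    contrast = np.asarray(contrast, float)
    if contrast.shape != (design.shape[1],):
        raise ValidationError("contrast length must match design columns")
    ids = [s.sample_id for s in samples]
    if list(matrix.columns) != ids:
        matrix = matrix[ids]
    X = design.to_numpy(float)
    Y = matrix.to_numpy(float)
    G, n = Y.shape
    obs = ~np.isnan(Y)

    beta = np.full(G, np.nan)
    s_sq = np.full(G, np.nan)
    df_resid = np.zeros(G, dtype=int)
    v_contrast = np.full(G, np.nan)
    testable = np.zeros(G, dtype=bool)

    pat_codes = obs @ (1 << np.arange(n, dtype=np.int64))
    for code in np.unique(pat_codes):
        rows = np.where(pat_codes == code)[0]
        cols = obs[rows[0]]
        m = int(cols.sum())
        if m < 2:
            continue
        sel = _solve_pattern(X[cols], contrast)
        if sel is None:
            continue
        kept, rank, v, ck = sel
        if m < rank:
            continue
        Xk = X[cols][:, kept]
        Ys = Y[np.ix_(rows, np.where(cols)[0])]
        pinv = np.linalg.pinv(Xk)
        coef = pinv @ Ys.T                      # (k, len(rows))
        resid = Ys.T - Xk @ coef
        rss = np.sum(resid ** 2, axis=0)
        df = m - rank
        beta[rows] = ck @ coef
        v_contrast[rows] = v
        df_resid[rows] = df
        testable[rows] = True
        if df >= 1:
            s_sq[rows] = rss / df
    return FitResult(
        proteins=matrix.index,
        beta=beta,
        s_sq=s_sq,
        df_resid=df_resid,
        v_contrast=v_contrast,
        testable=testable,
    )


# ----------------------------------------------------------- moderation


def trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 by monotone Newton iteration."""
    if y <= 0:
        raise ValidationError("trigamma_inverse requires y > 0")
    if y > 1e7:
        return 1.0 / math.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(100):
        tri = float(special.polygamma(1, x))
        dif = tri * (1.0 - tri / y) / float(special.polygamma(2, x))
        x = x + dif
        if abs(dif) / x < 1e-10:
            break
    return float(x)


def estimate_moderation(s_sq: np.ndarray, df: np.ndarray) -> ModerationParams:
    """Moment estimator of the inverse-chi-square variance prior (d0, s0^2).

    Works on z_g = ln s2_g, whose sampling distribution given the prior is a
    shifted log-F; matching the mean and excess variance of
    e_g = z_g - digamma(d_g/2) + ln(d_g/2) yields d0 via the trigamma
    inverse and s0^2 in closed form. When the observed spread does not
    exceed chi-square sampling noise the prior is degenerate: d0 = inf and
    s0^2 = exp(mean e).
    """
    s_sq = np.asarray(s_sq, float)
    df = np.asarray(df, float)
    ok = np.isfinite(s_sq) & (df >= 1) & (s_sq >= 0)
    s = s_sq[ok]
    d = df[ok]
    if s.size < 10:
        raise ValidationError("need >= 10 proteins with residual df >= 1")
    if np.all(s == 0):
        return ModerationParams(
            d0=math.inf, s0_sq=np.finfo(float).tiny, warning="all residual variances zero"
        )
    # floor tiny variances at 1e-5 x median before taking logs; otherwise a
    # single near-zero residual variance dominates the spread estimate
    med = float(np.median(s))
    if med == 0:
        med = float(np.mean(s))
    z = np.log(np.maximum(s, 1e-5 * med))
    e = z - special.digamma(d / 2.0) + np.log(d / 2.0)
    ebar = float(np.mean(e))
    G = e.size
    rhs = float(np.mean((e - ebar) ** 2 * G / (G - 1) - special.polygamma(1, d / 2.0)))
    if rhs <= 0:
        # no excess spread over chi-square sampling noise: degenerate prior
        # located at the average observed variance
        return ModerationParams(d0=math.inf, s0_sq=float(np.mean(s)))
    d0 = 2.0 * trigamma_inverse(rhs)
    s0_sq = float(np.exp(ebar + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    return ModerationParams(d0=float(d0), s0_sq=s0_sq)


def benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    """Step-up adjusted p-values; NaNs are excluded from m and stay NaN."""
    p = np.asarray(p, float)
    out = np.full(p.shape, np.nan)
    ok = np.isfinite(p)
    pv = p[ok]
    m = pv.size
    if m == 0:
        return out
    if np.any((pv < 0) | (pv > 1)):
        raise ValidationError("p-values must lie in [0, 1]")
    order = np.argsort(pv, kind="stable")
    ranked = pv[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    res = np.empty(m)
    res[order] = adj
    out[ok] = res
    return out


def moderated_test(fit: FitResult, mod: ModerationParams | tuple[float, float]) -> pd.DataFrame:
    """Moderated t-test of the enrichment contrast for every fitted protein.

    ``mod`` may be a ModerationParams or a raw ``(d0, s0_sq)`` pair; d0 = 0
    reduces to the ordinary t-test, d0 = inf to a normal reference with the
    prior variance alone.
    """
    if isinstance(mod, ModerationParams):
        d0, s0_sq = mod.d0, mod.s0_sq
    else:
        d0, s0_sq = mod
    G = len(fit.proteins)
    log2fc = fit.beta.copy()
    t_mod = np.full(G, np.nan)
    p_val = np.full(G, np.nan)
    df_total = np.full(G, np.nan)

    ok = fit.testable & np.isfinite(fit.v_contrast) & (fit.v_contrast > 0)
    d = fit.df_resid.astype(float)
    s2 = np.where(np.isfinite(fit.s_sq), fit.s_sq, 0.0)
    if math.isinf(d0):
        s_tilde_sq = np.full(G, s0_sq)
        dft = np.full(G, np.inf)
        usable = ok
    else:
        with np.errstate(invalid="ignore", divide="ignore"):
            s_tilde_sq = (d0 * s0_sq + d * s2) / (d0 + d)
        dft = d0 + d
        # with d0 = 0 only proteins with residual df can be tested
        usable = ok & (dft >= 1) & np.isfinite(fit.s_sq if d0 == 0 else fit.v_contrast)
        if d0 == 0:
            usable = ok & (d >= 1) & np.isfinite(fit.s_sq)
    se = np.sqrt(np.maximum(s_tilde_sq, 0.0) * fit.v_contrast)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = fit.beta / se
    good = usable & np.isfinite(t)
    t_mod[good] = t[good]
    df_total[good] = dft[good] if not math.isinf(d0) else np.inf
    inf_df = good & ~np.isfinite(df_total)
    fin_df = good & np.isfinite(df_total)
    p_val[inf_df] = 2.0 * stats.norm.sf(np.abs(t_mod[inf_df]))
    p_val[fin_df] = 2.0 * stats.t.sf(np.abs(t_mod[fin_df]), df_total[fin_df])

    return pd.DataFrame(
        {
            "log2fc": log2fc,
            "t_mod": t_mod,
            "p_value": p_val,
            "fdr": benjamini_hochberg(p_val),
            "df_total": df_total,
        },
        index=fit.proteins,
    )


# ------------------------------------------------------------- calling


def call_enrichment_classes(
    table: pd.DataFrame,
    thresholds: Thresholds = Thresholds(),
    detected: pd.Series | None = None,
) -> pd.DataFrame:
    """Attach hit/candidate/no_hit/not_detected calls to a test table.

    A *hit* needs FDR < hit_fdr and log2fc >= log2(hit_fc) in the +UV
    direction; a *candidate* needs FDR < cand_fdr and log2fc >=
    log2(cand_fc). Untestable but detected proteins are no_hit (detected but
    not enriched over the control); proteins absent from the assay are
    not_detected.
    """
    out = table.copy()
    fdr = out["fdr"].to_numpy(float)
    lfc = out["log2fc"].to_numpy(float)
    cls = np.full(len(out), "no_hit", dtype=object)
    with np.errstate(invalid="ignore"):
        hit = (fdr < thresholds.hit_fdr) & (lfc >= thresholds.hit_log2fc)
        cand = ~hit & (fdr < thresholds.cand_fdr) & (lfc >= thresholds.cand_log2fc)
    hit &= np.isfinite(fdr) & np.isfinite(lfc)
    cand &= np.isfinite(fdr) & np.isfinite(lfc)
    cls[hit] = "hit"
    cls[cand] = "candidate"
    if detected is not None:
        det = detected.reindex(out.index).fillna(False).to_numpy(bool)
        cls[~det] = "not_detected"
    out["enrich_class"] = cls
    return out


def peptide_filter(q: QuantMatrix, min_unique: int = 2) -> QuantMatrix:
    """Drop proteins quantified with fewer than ``min_unique`` unique peptides."""
    keep = q.proteins[q.unique_peptides >= min_unique]
    return q.subset_proteins(keep)


# --------------------------------------------------- model/results API


class EnrichmentModel:
    """Per-protein moderated enrichment model on a normalized matrix.

    Parameters
    ----------
    matrix
        Protein x sample table on the glog2 (VST) scale.
    samples
        Sample annotations matching the columns.
    unique_peptides
        Optional counts used for the testability filter and reporting.
    thresholds
        Hit/candidate calling thresholds.

    Use :meth:`from_quant` to go from raw intensities (batch removal, VST,
    peptide filter) to a ready model.
    """

    def __init__(
        self,
        matrix: pd.DataFrame,
        samples: list[SampleInfo],
        unique_peptides: pd.Series | None = None,
        thresholds: Thresholds = Thresholds(),
        design: pd.DataFrame | None = None,
    ) -> None:
        self.matrix = matrix
        self.samples = samples
        self.unique_peptides = (
            unique_peptides
            if unique_peptides is not None
            else pd.Series(np.iinfo(np.int32).max, index=matrix.index)
        )
        self.thresholds = thresholds
        self.design = design if design is not None else build_design(samples)

    @classmethod
    def from_quant(
        cls,
        q: QuantMatrix,
        strategy: str = "per-tissue-condition",
        batch_correct: bool = True,
        thresholds: Thresholds = Thresholds(),
    ) -> "EnrichmentModel":
        """Normalize raw intensities and build the model.

        Batch effects are removed on log2(x+1) and back-transformed, the
        affine-arsinh VST is calibrated per the named strategy, and proteins
        failing the unique-peptide filter are excluded from testing (they
        remain in the results as detected-but-untestable).
        """
        from .normalize import (
            make_strata,
            remove_batch_effects_linear,
            variance_stabilizing_transform,
        )

        qn = remove_batch_effects_linear(q) if batch_correct else q
        strata, fit_on = make_strata(q.samples, strategy)
        transformed, _ = variance_stabilizing_transform(qn, strata=strata, fit_on=fit_on)
        model = cls(
            matrix=transformed,
            samples=q.samples,
            unique_peptides=q.unique_peptides,
            thresholds=thresholds,
        )
        model._source = q
        return model

    def fit(self, moderation: ModerationParams | None = None) -> "EnrichmentResults":
        """Fit per-protein OLS, estimate the variance prior, test, and call.

        All tissues are fitted jointly (shared residual variance and
        replicate factor); one differential table is produced per tissue
        from its plusUV-minusUV contrast.
        """
        testable_prot = self.matrix.index[
            self.unique_peptides.reindex(self.matrix.index).fillna(0)
            >= self.thresholds.min_unique_peptides
        ]
        sub = self.matrix.loc[testable_prot]
        contrasts = tissue_contrasts(self.design, self.samples)
        fits = {
            t: fit_linear_models(sub, self.samples, self.design, contrast=c)
            for t, c in contrasts.items()
        }
        first = next(iter(fits.values()))
        if moderation is None:
            ok = np.isfinite(first.s_sq) & (first.df_resid >= 1)
            moderation = estimate_moderation(first.s_sq[ok], first.df_resid[ok])
        tables = {}
        for tissue, fit in fits.items():
            table = moderated_test(fit, moderation)
            table["fdr"] = benjamini_hochberg(table["p_value"].to_numpy())
            full = table.reindex(self.matrix.index)
            tissue_ids = [
                s.sample_id for s in self.samples if s.tissue == tissue
            ]
            detected = self.matrix[tissue_ids].notna().any(axis=1)
            full = call_enrichment_classes(full, self.thresholds, detected=detected)
            full["n_unique_peptides"] = (
                self.unique_peptides.reindex(self.matrix.index).fillna(0).astype(int)
            )
            tables[tissue] = full
        return EnrichmentResults(model=self, fits=fits, moderation=moderation, tables=tables)


class EnrichmentResults:
    """Fitted enrichment results: per-tissue tables, prior, and summaries."""

    def __init__(
        self,
        model: EnrichmentModel,
        fits: dict[str, FitResult],
        moderation: ModerationParams,
        tables: dict[str, pd.DataFrame],
    ) -> None:
        self.model = model
        self.fits = fits
        self.moderation = moderation
        self.tables = tables

    @property
    def table(self) -> pd.DataFrame:
        """The differential table (single-tissue fits only)."""
        if len(self.tables) != 1:
            raise ValidationError(
                f"multiple tissues fitted ({sorted(self.tables)}); use .tables"
            )
        return next(iter(self.tables.values()))

    # convenience accessors -------------------------------------------------
    def hits_for(self, tissue: str) -> pd.Index:
        t = self.tables[tissue]
        return t.index[t["enrich_class"] == "hit"]

    @property
    def hits(self) -> pd.Index:
        return self.table.index[self.table["enrich_class"] == "hit"]

    @property
    def candidates(self) -> pd.Index:
        return self.table.index[self.table["enrich_class"] == "candidate"]

    def class_counts(self) -> pd.DataFrame:
        return pd.DataFrame(
            {t: tab["enrich_class"].value_counts() for t, tab in self.tables.items()}
        ).fillna(0).astype(int)

    def summary(self) -> str:
        t = self.model.thresholds
        counts = self.class_counts()
        d0 = "inf" if math.isinf(self.moderation.d0) else f"{self.moderation.d0:.3g}"
        lines = [
            "Moderated enrichment test (+UV vs -UV)",
            "=" * 52,
            f"proteins:            {len(next(iter(self.tables.values())))}",
            f"prior df (d0):       {d0}",
            f"prior variance s0^2: {self.moderation.s0_sq:.4g}",
            f"hit rule:  FDR < {t.hit_fdr:g} and FC >= {t.hit_fc:g}",
            f"cand rule: FDR < {t.cand_fdr:g} and FC >= {t.cand_fc:g}",
            "",
            counts.reindex(["hit", "candidate", "no_hit", "not_detected"])
            .fillna(0)
            .astype(int)
            .to_string(),
        ]
        return "\n".join(lines)

    def volcano(self, tissue: str | None = None, ax=None):
        """Volcano plot: log2 fold-change vs -log10 p, hits red, candidates blue."""
        import matplotlib

        matplotlib.use("Agg", force=False)
        import matplotlib.pyplot as plt

        tab = self.tables[tissue] if tissue else self.table
        if ax is None:
            _, ax = plt.subplots(figsize=(5, 4))
        tab = tab.dropna(subset=["p_value"])
        colors = tab["enrich_class"].map(
            {"hit": "crimson", "candidate": "royalblue"}
        ).fillna("0.6")
        ax.scatter(tab["log2fc"], -np.log10(tab["p_value"]), s=6, c=colors, lw=0)
        ax.axvline(self.model.thresholds.hit_log2fc, ls="--", c="0.3", lw=0.7)
        ax.set_xlabel("log2 fold-change (+UV / -UV)")
        ax.set_ylabel("-log10 p")
        return ax


__all__ = [
    "FitResult",
    "build_design",
    "tissue_contrasts",
    "fit_linear_models",
    "trigamma_inverse",
    "estimate_moderation",
    "benjamini_hochberg",
    "moderated_test",
    "call_enrichment_classes",
    "peptide_filter",
    "EnrichmentModel",
    "EnrichmentResults",
]
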