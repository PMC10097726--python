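"""Batch-effect removal and variance-stabilizing normalization.

Reporter-ion intensities carry multiplicative sample-to-sample scaling and
additive background, so the pipeline normalizes with an affine-arsinh
transform

    h_s(x) = arsinh(a_s + b_s * x) / ln 2,

which behaves like ``log2(2 * b_s * x)`` at high intensity and stays linear
near zero (a generalized-log / glog transform). Calibration parameters
``(a_s, b_s)`` are estimated per *stratum* of samples by an alternating
trimmed least-squares fit: protein row means are computed in transformed
space over the least-variable 90% of proteins, then each sample's ``(a, b)``
is refit to minimize squared deviation from those means; the two steps
alternate to convergence. Strata implement the different normalization
strategies (per tissue-and-condition, a single stratum across +UV samples,
or +UV-only fitting that preserves the -UV abundance gap).

Batch effects are removed before the transform on the log2 scale, by a
per-protein least-squares fit that estimates batch offsets jointly with the
biological design and subtracts only the batch component.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .datatypes import QuantMatrix, SampleInfo, ValidationError

LN2 = np.log(2.0)


# ---------------------------------------------------------------- batch
def batch_design(samples: list[SampleInfo]) -> pd.DataFrame:
    """Sum-to-zero batch indicator columns (k-1 columns for k batches)."""
    batches = sorted({s.batch for s in samples})
    ids = [s.sample_id for s in samples]
    cols = {}
    for b in batches[:-1]:
        col = np.array([1.0 if s.batch == b else 0.0 for s in samples])
        col -= np.array([1.0 if s.batch == batches[-1] else 0.0 for s in samples])
        cols[f"batch_{b}"] = col
    return pd.DataFrame(cols, index=ids)


def condition_design(samples: list[SampleInfo], terms=("condition", "tissue")) -> pd.DataFrame:
    """Intercept + treatment-coded dummies for the biological terms to keep."""
    meta = pd.DataFrame(
        {
            "condition": [s.condition for s in samples],
            "tissue": [s.tissue for s in samples],
        },
        index=[s.sample_id for s in samples],
    )
    X = pd.DataFrame({"intercept": np.ones(len(samples))}, index=meta.index)
    for t in terms:
        levels = sorted(meta[t].unique())
        for lev in levels[1:]:
            X[f"{t}_{lev}"] = (meta[t] == lev).astype(float)
    return X


def remove_batch_effects(
    log_matrix: pd.DataFrame,
    samples: list[SampleInfo],
    keep_design: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Subtract per-protein batch offsets, preserving the biological design.

    ``log_matrix`` must be on a log scale. For each protein, a least-squares
    fit of log intensity on [keep_design | batch indicators] is computed on
    the observed cells and only the fitted batch component is subtracted.
    With a single batch the input is returned unchanged.

    Raises
    ------
    ValidationError
        If a batch indicator is confounded with a preserved design column.
    """
    ids = [s.sample_id for s in samples]
    if list(log_matrix.columns) != ids:
        raise ValidationError("log_matrix columns must match sample order")
    B = batch_design(samples)
    if B.shape[1] == 0:
        return log_matrix.copy()
    if keep_design is None:
        keep_design = condition_design(samples)
    X = np.column_stack([keep_design.to_numpy(float), B.to_numpy(float)])
    k_keep = keep_design.shape[1]
    rank_full = np.linalg.matrix_rank(X)
    rank_keep = np.linalg.matrix_rank(keep_design.to_numpy(float))
    if rank_full < rank_keep + B.shape[1]:
        raise ValidationError(
            "batch confounded with preserved design; check columns "
            f"{list(keep_design.columns)} vs {list(B.columns)}"
        )
    Y = log_matrix.to_numpy(float)
    out = Y.copy()
    obs = ~np.isnan(Y)
    # group proteins by missingness pattern so each pattern is solved once
    pat_codes = obs @ (1 << np.arange(obs.shape[1], dtype=np.int64))
    for code in np.unique(pat_codes):
        rows = np.where(pat_codes == code)[0]
        cols = obs[rows[0]]
        if cols.sum() == 0:
            continue
        Xs = X[cols]
        coef, *_ = np.linalg.lstsq(Xs, Y[np.ix_(rows, np.where(cols)[0])].T, rcond=None)
        batch_part = X[:, k_keep:] @ coef[k_keep:]
        out[rows] = Y[rows] - batch_part.T
    out[~obs] = np.nan
    return pd.DataFrame(out, index=log_matrix.index, columns=log_matrix.columns)


def remove_batch_effects_linear(
    q: QuantMatrix, keep_design: pd.DataFrame | None = None
) -> QuantMatrix:
    """Batch-clean raw intensities: log2(x+1) -> correct -> back-transform."""
    logm = np.log2(q.intensity + 1.0)
    corrected = remove_batch_effects(logm, q.samples, keep_design)
    lin = (2.0 ** corrected - 1.0).clip(lower=0.0)
    return q.with_intensity(lin)


# ------------------------------------------------------------------- VST
@dataclass
class VstParams:
    """Fitted affine-arsinh calibration, one (offset a, scale b) per sample."""

    params: pd.DataFrame  # index sample_id; columns a, b, stratum
    convergence: dict = field(default_factory=dict)  # stratum -> info dict
    warnings: list = field(default_factory=list)

    def transform(self, x: pd.Series | np.ndarray, sample_id: str) -> np.ndarray:
        a = self.params.loc[sample_id, "a"]
        b = self.params.loc[sample_id, "b"]
        return np.arcsinh(a + b * np.asarray(x, float)) / LN2


def glog2(x, a, b):
    """arsinh(a + b x)/ln2 — the affine generalized log2."""
    return np.arcsinh(a + b * x) / LN2


def _init_scale(x: np.ndarray) -> float:
    """Initial calibration scale 1/q01 of the positive intensities."""
    pos = x[np.isfinite(x) & (x > 0)]
    if pos.size == 0:
        return 1.0
    return float(1.0 / max(np.quantile(pos, 0.01), 1e-300))


def _fit_stratum(x: np.ndarray, mu: np.ndarray, a0: float, b0: float) -> tuple[float, float]:
    """Refit one stratum's shared (a, b) against fixed row means (b > 0).

    ``x`` stacks the observed intensities of every fitted sample in the
    stratum, ``mu`` the matching global row means. Minimizes the
    profile-likelihood objective (m/2) ln RSS - sum ln h', where h' is the
    transform derivative; the Jacobian term anchors the scale (without it,
    shrinking b for every stratum jointly deflates the residuals toward a
    degenerate constant transform). Analytic gradients, L-BFGS.
    """
    from scipy.optimize import minimize

    m = x.size

    def objective(theta):
        a, logb = theta
        b = np.exp(logb)
        u = a + b * x
        s = np.sqrt(1.0 + u * u)
        r = np.arcsinh(u) / LN2 - mu
        rss = float(r @ r) + 1e-300
        f = 0.5 * m * np.log(rss) - (m * logb - 0.5 * float(np.sum(np.log1p(u * u))))
        drss_da = float(np.sum(2.0 * r / (LN2 * s)))
        drss_dlb = float(np.sum(2.0 * r * x * b / (LN2 * s)))
        djac_da = float(np.sum(u / (s * s)))
        djac_dlb = float(np.sum(u * x * b / (s * s))) - m
        g = np.array(
            [0.5 * m * drss_da / rss + djac_da, 0.5 * m * drss_dlb / rss + djac_dlb]
        )
        return f, g

    sol = minimize(
        objective,
        x0=[a0, np.log(max(b0, 1e-300))],
        method="L-BFGS-B",
        jac=True,
        options={"maxiter": 200, "ftol": 1e-14, "gtol": 1e-10},
    )
    a, logb = sol.x
    return float(a), float(np.exp(logb))


def variance_stabilizing_transform(
    q: QuantMatrix,
    strata: dict[str, str] | None = None,
    fit_on: list[str] | None = None,
    trim: float = 0.9,
    max_iter: int = 50,
    tol: float = 1e-8,
    max_calib_rows: int = 600,
) -> tuple[pd.DataFrame, VstParams]:
    """Calibrate and apply the affine-arsinh transform.

    All fitted samples are calibrated against *common* protein row means
    (computed across every fitted sample), which anchors the relative level
    of the strata; within a stratum the calibration coefficients (a, b) are
    shared. One stratum per sample (the default) gives fully per-sample
    coefficients; coarser strata reproduce the shared-coefficient
    strategies (one coefficient pair per tissue-and-condition group, or a
    single pair for all +UV samples).

    Parameters
    ----------
    q
        Quantification matrix; intensities must be >= 0.
    strata
        sample_id -> calibration-group label. Default: each sample its own
        group.
    fit_on
        Optional subset of sample_ids allowed to influence the fit.
        Excluded samples are transformed with their stratum's fitted
        coefficients (or the mean over fitted strata if their stratum has
        no fitted member). Used to normalize only +UV samples while
        keeping the -UV abundance difference intact.
    trim
        Fraction of proteins kept in the trimmed least-squares step
        (least-variable by residual sum of squares).

    Returns
    -------
    (transformed, VstParams)
        ``transformed`` is on the glog2 scale, missing cells stay missing.
    """
    ids = [s.sample_id for s in q.samples]
    if strata is None:
        strata = {i: i for i in ids}
    unknown = set(strata) - set(ids)
    if unknown:
        raise ValidationError(f"strata reference unknown samples: {sorted(unknown)}")
    fit_set = set(ids if fit_on is None else fit_on)
    X = q.intensity.to_numpy(float)
    obs = ~np.isnan(X)
    if (obs.sum(axis=0) == 0).any():
        bad = [ids[j] for j in range(len(ids)) if obs[:, j].sum() == 0]
        raise ValidationError(f"all-missing sample(s): {bad}")

    stratum_of = {i: strata.get(i, "_unstratified") for i in ids}
    fitted_ids = [i for i in ids if i in fit_set and stratum_of[i] != "_unstratified"]
    if not fitted_ids:
        raise ValidationError("no samples available to fit on")
    groups: dict[str, list[int]] = {}
    for i in fitted_ids:
        groups.setdefault(stratum_of[i], []).append(ids.index(i))
    group_names = sorted(groups)

    # init: a=0, b = 1/(low quantile of the group) so the bulk of proteins
    # sits in the logarithmic regime; the low quantile proxies the noise floor
    a = {g: 0.0 for g in group_names}
    b = {
        g: float(np.mean([_init_scale(X[:, j]) for j in groups[g]]))
        for g in group_names
    }
    jf = sorted(j for js in groups.values() for j in js)
    col_group = [stratum_of[ids[j]] for j in jf]
    # calibrate on a deterministic, evenly spaced subset of proteins when
    # the matrix is large; the transform is still applied to all rows
    n_rows = X.shape[0]
    if n_rows > max_calib_rows:
        rows_cal = np.linspace(0, n_rows - 1, max_calib_rows).astype(int)
    else:
        rows_cal = np.arange(n_rows)
    Xs = X[np.ix_(rows_cal, jf)]
    obs_s = obs[np.ix_(rows_cal, jf)]
    warnings: list[str] = []
    info = {"iterations": 0, "final_change": np.nan, "converged": True}

    for it in range(max_iter):
        A = np.array([a[g] for g in col_group])
        Bv = np.array([b[g] for g in col_group])
        H = np.arcsinh(A[None, :] + Bv[None, :] * Xs) / LN2
        H[~obs_s] = np.nan
        n_obs_row = obs_s.sum(axis=1)
        with np.errstate(invalid="ignore"):
            mu = np.where(
                n_obs_row > 0,
                np.nansum(np.nan_to_num(H), axis=1) / np.maximum(n_obs_row, 1),
                np.nan,
            )
        resid_ss = np.nansum((H - mu[:, None]) ** 2, axis=1)
        cand = np.where(n_obs_row >= 2)[0]
        if cand.size < 10:
            warnings.append("too few proteins observed in >= 2 fitted samples")
            info["converged"] = False
            break
        k = max(int(np.floor(trim * cand.size)), 10)
        keep = cand[np.argsort(resid_ss[cand], kind="stable")[:k]]
        new_a, new_b = dict(a), dict(b)
        for g in group_names:
            xs, mus = [], []
            for jj, jcol in enumerate(jf):
                if col_group[jj] != g:
                    continue
                rows = keep[obs_s[keep, jj]]
                xs.append(Xs[rows, jj])
                mus.append(mu[rows])
            xg = np.concatenate(xs) if xs else np.empty(0)
            if xg.size < 3:
                continue
            new_a[g], new_b[g] = _fit_stratum(xg, np.concatenate(mus), a[g], b[g])
        old = np.array([a[g] for g in group_names] + [b[g] for g in group_names])
        new = np.array([new_a[g] for g in group_names] + [new_b[g] for g in group_names])
        change = float(np.max(np.abs(new - old) / np.maximum(np.abs(old), 1e-12)))
        a, b = new_a, new_b
        info["iterations"] = it + 1
        info["final_change"] = change
        if change < tol:
            break
    else:
        info["converged"] = False
        warnings.append(f"VST did not converge in {max_iter} iterations")

    params = pd.DataFrame(index=pd.Index(ids, name="sample_id"), columns=["a", "b", "stratum"])
    mean_a = float(np.mean([a[g] for g in group_names]))
    mean_b = float(np.mean([b[g] for g in group_names]))
    for i in ids:
        g = stratum_of[i]
        if g in a:
            params.loc[i, ["a", "b", "stratum"]] = [a[g], b[g], g]
        else:
            # stratum never fitted: fall back to the mean fitted calibration
            params.loc[i, ["a", "b", "stratum"]] = [mean_a, mean_b, g]
    vp = VstParams(params=params, convergence={"global": info}, warnings=warnings)
    out = np.empty_like(X)
    for j, s in enumerate(ids):
        out[:, j] = np.arcsinh(params.loc[s, "a"] + params.loc[s, "b"] * X[:, j]) / LN2
    out[~obs] = np.nan
    return pd.DataFrame(out, index=q.intensity.index, columns=ids), vp


def make_strata(samples: list[SampleInfo], strategy: str) -> tuple[dict[str, str], list[str] | None]:
    """Map a named normalization strategy to (strata, fit_on).

    * ``per-tissue-condition`` — every sample gets its own coefficient
      pair (so coefficients differ freely across tissues and conditions);
      all samples share the global row means.
    * ``single-plusUV``        — a single coefficient pair for all +UV
      samples (cross-tissue comparability of the +UV eluates); -UV samples
      get their own per-condition pair.
    * ``plusUV-only``          — coefficients fitted on +UV samples only,
      per assay; -UV samples share their assay's fitted pair, preserving
      the abundance difference from the non-crosslinked control.
    """
    if strategy == "per-tissue-condition":
        return {s.sample_id: s.sample_id for s in samples}, None
    if strategy == "single-plusUV":
        strata = {
            s.sample_id: "plusUV" if s.condition == "plusUV" else "minusUV"
            for s in samples
        }
        return strata, None
    if strategy == "plusUV-only":
        strata = {s.sample_id: s.assay for s in samples}
        fit_on = [s.sample_id for s in samples if s.condition == "plusUV"]
        return strata, fit_on
    raise ValidationError(f"unknown normalization strategy {strategy!r}")


# ------------------------------------------------- equal-mean adjustment
def equal_mean_renormalization(
    matrix: pd.DataFrame, sample_ids: list[str] | None = None
) -> pd.DataFrame:
    """Force equal mean signal intensity across the listed samples.

    Per-sample means are computed over the proteins observed in *all* listed
    samples (the shared set), subtracted, and the grand mean added back.
    Columns not listed are left untouched.
    """
    cols = list(matrix.columns) if sample_ids is None else list(sample_ids)
    sub = matrix[cols]
    shared = sub.dropna().index
    if len(shared) == 0:
        raise ValidationError("no proteins observed in all samples to renormalize on")
    col_means = sub.loc[shared].mean(axis=0)
    grand = float(col_means.mean())
    out = matrix.copy()
    out[cols] = sub - col_means + grand
    return out


__all__ = [
    "VstParams",
    "glog2",
    "batch_design",
    "condition_design",
    "remove_batch_effects",
    "remove_batch_effects_linear",
    "variance_stabilizing_transform",
    "make_strata",
    "equal_mean_renormalization",
]
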