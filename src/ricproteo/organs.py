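"""Cross-organ RBP activity summaries.

Mean capture-signal comparisons between tissues, RNA-content adjustment,
relative-abundance heatmap matrices with hierarchical clustering, replicate
correlation, and the classification of proteins whose RNA binding changes
between organs without a matching change in abundance.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .datatypes import QuantMatrix, RnaContent, Thresholds, ValidationError


def rna_adjust_signal(q: QuantMatrix, rna: RnaContent) -> QuantMatrix:
    """Divide each sample's linear-scale signal by its tissue's RNA content.

    Poly(A) content is used for eRIC samples, non-poly(A) content for
    non-poly(A) capture samples; input samples are left unadjusted.
    """
    out = q.intensity.copy()
    for s in q.samples:
        if s.assay in ("eric", "nonpolya_ric"):
            out[s.sample_id] = out[s.sample_id] / rna.for_assay(s.assay, s.tissue)
    return q.with_intensity(out)


def mean_signal_summary(
    matrix: pd.DataFrame,
    samples,
    protein_set,
    group_by: str = "tissue",
) -> tuple[pd.Series, pd.DataFrame]:
    """Mean linear-scale signal per group and all pairwise ratios.

    The mean is taken over all observed (protein, sample) cells of the
    listed proteins within each group.
    """
    prots = [p for p in matrix.index if p in set(protein_set)]
    if not prots:
        raise ValidationError("protein_set is empty or disjoint from the matrix")
    groups: dict[str, list[str]] = {}
    for s in samples:
        groups.setdefault(getattr(s, group_by), []).append(s.sample_id)
    means = {}
    for g, ids in sorted(groups.items()):
        vals = matrix.loc[prots, ids].to_numpy(float)
        if np.isnan(vals).all():
            raise ValidationError(f"group {g!r} has no observed values")
        means[g] = float(np.nanmean(vals))
    mean_s = pd.Series(means, name="mean_signal")
    names = list(mean_s.index)
    ratio = pd.DataFrame(
        [[mean_s[a] / mean_s[b] for b in names] for a in names],
        index=names,
        columns=names,
    )
    return mean_s, ratio


def relative_abundance_matrix(
    matrix: pd.DataFrame, families: dict[str, list[str]]
) -> pd.DataFrame:
    """log2 ratio of each cell to its protein's family row average.

    ``families`` maps a family name (e.g. 'eric', 'input') to its sample
    columns. The row average is the arithmetic mean on the linear scale,
    taken within each family separately; rows with any missing family cell
    are dropped.
    """
    pieces = []
    keep = matrix.index
    for fam, cols in families.items():
        sub = matrix[cols]
        keep = keep.intersection(sub.dropna().index)
    for fam, cols in families.items():
        sub = matrix.loc[keep, cols].astype(float)
        row_mean = sub.mean(axis=1)
        if (row_mean <= 0).any():
            raise ValidationError(f"family {fam!r}: non-positive row means")
        pieces.append(np.log2(sub.div(row_mean, axis=0)))
    return pd.concat(pieces, axis=1)


def cluster_rbps(matrix: pd.DataFrame, k: int | None = None, cut_height: float | None = None):
    """Average-linkage hierarchical clustering on 1 - Pearson distance.

    Returns (labels Series, leaf-ordered matrix, linkage array). Leaf order
    is deterministic; exact ties are resolved by scipy's stable merge order
    on the (row-order fixed) condensed distances, so identical inputs give
    identical outputs.
    """
    if matrix.isna().any().any():
        raise ValidationError("clustering input must have no missing cells")
    if len(matrix) < 2:
        raise ValidationError("need at least two proteins to cluster")
    X = matrix.to_numpy(float)
    # 1 - Pearson correlation across columns
    corr = np.corrcoef(X)
    corr = np.clip(corr, -1.0, 1.0)
    dist = 1.0 - corr
    np.fill_diagonal(dist, 0.0)
    dist = (dist + dist.T) / 2.0
    Z = hierarchy.linkage(squareform(dist, checks=False), method="average")
    if k is not None:
        labels = hierarchy.fcluster(Z, t=k, criterion="maxclust")
    elif cut_height is not None:
        labels = hierarchy.fcluster(Z, t=cut_height, criterion="distance")
    else:
        labels = hierarchy.fcluster(Z, t=2, criterion="maxclust")
    order = hierarchy.leaves_list(Z)
    ordered = matrix.iloc[order]
    return pd.Series(labels, index=matrix.index, name="cluster"), ordered, Z


def replicate_correlation(
    matrix: pd.DataFrame, pairs: list[tuple[str, str]], min_shared: int = 3
) -> pd.Series:
    """Pearson r per sample pair over pairwise-complete proteins."""
    out = {}
    for a, b in pairs:
        sub = matrix[[a, b]].dropna()
        if len(sub) < min_shared:
            out[(a, b)] = np.nan
            continue
        x = sub[a].to_numpy(float)
        y = sub[b].to_numpy(float)
        xm, ym = x - x.mean(), y - y.mean()
        denom = np.sqrt((xm**2).sum() * (ym**2).sum())
        out[(a, b)] = float((xm * ym).sum() / denom) if denom > 0 else np.nan
    return pd.Series(out, name="pearson_r")


def binding_vs_abundance(
    eric_table: pd.DataFrame,
    input_table: pd.DataFrame,
    thresholds: Thresholds = Thresholds(),
    abundance_tol_log2: float = float(np.log2(1.5)),
) -> pd.DataFrame:
    """Classify organ-pair changes as binding- or abundance-driven.

    Both tables come from the same organ-pair contrast fitted under
    equal-mean renormalization. Classes:

    * concordant     — significant in both, same direction
    * binding_only   — capture significant (hit thresholds), input
      |log2fc| below ``abundance_tol_log2``
    * abundance_only — the reverse
    * neither        — everything else
    """
    shared = eric_table.index.intersection(input_table.index)
    e = eric_table.loc[shared]
    i = input_table.loc[shared]
    e_sig = (e["fdr"] < thresholds.hit_fdr) & (e["log2fc"].abs() >= thresholds.hit_log2fc)
    i_sig = (i["fdr"] < thresholds.hit_fdr) & (i["log2fc"].abs() >= thresholds.hit_log2fc)
    e_flat = e["log2fc"].abs() < abundance_tol_log2
    i_flat = i["log2fc"].abs() < abundance_tol_log2
    same_sign = np.sign(e["log2fc"]) == np.sign(i["log2fc"])
    cls = np.full(len(shared), "neither", dtype=object)
    cls[(e_sig & i_sig & same_sign).to_numpy()] = "concordant"
    cls[(e_sig & i_flat).to_numpy()] = "binding_only"
    cls[(i_sig & e_flat).to_numpy()] = "abundance_only"
    return pd.DataFrame(
        {
            "eric_log2fc": e["log2fc"],
            "eric_fdr": e["fdr"],
            "input_log2fc": i["log2fc"],
            "input_fdr": i["fdr"],
            "decoupling_class": cls,
        },
        index=shared,
    )


__all__ = [
    "rna_adjust_signal",
    "mean_signal_summary",
    "relative_abundance_matrix",
    "cluster_rbps",
    "replicate_correlation",
    "binding_vs_abundance",
]
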