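"""Gel-fraction migration analysis for protein-protein crosslink QC.

Captured proteins separated by SDS-PAGE are cut into mass fractions and
quantified (iBAQ) per fraction and replicate. A direct RNA binder migrates
at its predicted monomeric mass; a protein riding piggy-back on a
crosslinked partner shifts to higher mass. Each protein's valid iBAQ cells
are converted to proportions, and the per-fraction profile is classified:

* monomeric          — modal fraction contains the predicted mass
* boundary_proximal  — modal fraction is one above, and the predicted mass
  lies within ``boundary_kda`` (default 10) below the fraction boundary
* bimodal            — two separated peaks, one at the predicted (or
  boundary) fraction, each carrying at least ``bimodal_tau`` of the mass
* shifted            — modal fraction above predicted, none of the above
* unclassified       — modal fraction below predicted, or mass unknown

The summary statistic reports, among proteins that preferentially localize
to higher-mass fractions (share above the predicted fraction > 0.5), the
fraction that are capture hits with a mass within 10 kDa of a boundary —
the plausible boundary-migration cases rather than true piggy-back riders.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datatypes import FractionProfile, ValidationError


def filter_fraction_detections(
    fp: FractionProfile,
    min_peptides: int = 2,
    min_replicates: int = 2,
) -> FractionProfile:
    """Keep (protein, fraction) cells detected reproducibly.

    A fraction is retained for a protein only when it was detected with at
    least ``min_peptides`` unique peptides in at least ``min_replicates``
    replicates; all other cells are masked.
    """
    valid = fp.valid.copy()
    if fp.peptides is not None:
        good_cell = valid & (fp.peptides >= min_peptides)
    else:
        good_cell = valid
    by_fraction = good_cell.T.groupby(level="fraction").sum().T  # detections per fraction
    frac_ok = by_fraction >= min_replicates
    new_valid = valid.copy()
    for rep, frac in valid.columns:
        new_valid[(rep, frac)] = good_cell[(rep, frac)] & frac_ok[frac]
    return FractionProfile(
        ibaq=fp.ibaq.copy(),
        valid=new_valid,
        bounds=fp.bounds,
        predicted_mass_kda=None if fp.predicted_mass_kda is None else fp.predicted_mass_kda.copy(),
        peptides=None if fp.peptides is None else fp.peptides.copy(),
    )


def fraction_proportions(fp: FractionProfile) -> tuple[pd.DataFrame, pd.DataFrame, list[str]]:
    """Per-cell and per-fraction iBAQ proportions.

    Each valid cell's iBAQ is divided by the protein's total valid iBAQ, so
    cell proportions sum to 1 per protein; the per-fraction profile sums
    the cell proportions over replicates. Proteins with no valid signal are
    dropped and their accessions returned.
    """
    vals = fp.ibaq.where(fp.valid, 0.0).to_numpy(float)
    vals = np.nan_to_num(vals, nan=0.0)
    totals = vals.sum(axis=1)
    dropped = [str(a) for a in fp.proteins[totals <= 0]]
    keep = totals > 0
    cell = pd.DataFrame(
        vals[keep] / totals[keep, None], index=fp.proteins[keep], columns=fp.ibaq.columns
    )
    profile = cell.T.groupby(level="fraction").sum().T
    profile = profile.reindex(columns=range(fp.n_fractions), fill_value=0.0)
    return cell, profile, dropped


def weighted_mass_density(
    profile: pd.DataFrame, bounds: tuple[float, ...]
) -> pd.DataFrame:
    """Pooled proportion-weighted density over the fraction mass intervals.

    Each protein contributes its per-fraction proportions as weights, so
    the pooled weight integrates to the number of proteins.
    """
    lowers = np.concatenate([[0.0], np.asarray(bounds[:-1], float)])
    uppers = np.asarray(bounds, float)
    total = profile.sum(axis=0).reindex(range(len(bounds)), fill_value=0.0)
    widths = uppers - lowers
    density = np.where(np.isfinite(widths), total / np.where(widths > 0, widths, np.nan), np.nan)
    return pd.DataFrame(
        {
            "lower_kda": lowers,
            "upper_kda": uppers,
            "weight": total.to_numpy(),
            "density_per_kda": density,
        },
        index=pd.RangeIndex(len(bounds), name="fraction"),
    )


# -------------------------------------------------------- classification
@dataclass
class MigrationCall:
    accession: str
    predicted_fraction: int
    modal_fraction: int
    call: str
    higher_mass_fraction_share: float
    boundary_distance_kda: float


def _fraction_index(mass: float, bounds) -> int:
    for i, b in enumerate(bounds):
        if mass <= b:
            return i
    return len(bounds) - 1


def _local_maxima(p: np.ndarray) -> list[int]:
    """Indices of local maxima over the ordered fractions, ties to lower mass."""
    F = len(p)
    out = []
    for i in range(F):
        left_ok = i == 0 or p[i] > p[i - 1]
        right_ok = i == F - 1 or p[i] >= p[i + 1]
        if left_ok and right_ok and p[i] > 0:
            out.append(i)
    return out


def classify_migration(
    profile: np.ndarray | pd.Series,
    predicted_mass_kda: float,
    bounds: tuple[float, ...],
    boundary_kda: float = 10.0,
    bimodal_tau: float = 0.25,
    accession: str = "",
) -> MigrationCall:
    """Classify one protein's per-fraction proportion profile.

    See the module docstring for the rule set. ``higher_mass_fraction_share``
    is the summed proportion in fractions strictly above the predicted one.
    """
    p = np.asarray(profile, float)
    if predicted_mass_kda is None or not np.isfinite(predicted_mass_kda):
        return MigrationCall(accession, -1, -1, "unclassified", np.nan, np.nan)
    if p.size == 0 or not np.any(p > 0):
        return MigrationCall(accession, -1, -1, "unclassified", np.nan, np.nan)
    pf = _fraction_index(predicted_mass_kda, bounds)
    modal = int(np.argmax(p))  # argmax takes the lowest index on ties
    share_hi = float(p[pf + 1:].sum())
    upper = bounds[pf]
    bdist = float(upper - predicted_mass_kda) if np.isfinite(upper) else np.inf

    peaks = [i for i in _local_maxima(p) if p[i] >= bimodal_tau]
    anchor = {pf, pf + 1} if bdist <= boundary_kda else {pf}
    bimodal = any(
        j - i >= 2 and (i in anchor or j in anchor) for i in peaks for j in peaks
    )
    # two qualifying peaks outrank the single-mode calls: a genuine second
    # high-mass mode must not be hidden by a slightly taller predicted peak
    if bimodal:
        call = "bimodal"
    elif modal == pf:
        call = "monomeric"
    elif modal == pf + 1 and bdist <= boundary_kda:
        call = "boundary_proximal"
    elif modal > pf:
        call = "shifted"
    else:
        call = "unclassified"
    return MigrationCall(accession, pf, modal, call, share_hi, bdist)


def classify_all(
    fp: FractionProfile,
    boundary_kda: float = 10.0,
    bimodal_tau: float = 0.25,
) -> pd.DataFrame:
    """Run proportions + migration classification for every protein."""
    if fp.predicted_mass_kda is None:
        raise ValidationError("fraction profile lacks predicted masses")
    _, profile, dropped = fraction_proportions(fp)
    rows = []
    for acc in profile.index:
        call = classify_migration(
            profile.loc[acc].to_numpy(),
            float(fp.predicted_mass_kda.get(acc, np.nan)),
            fp.bounds,
            boundary_kda=boundary_kda,
            bimodal_tau=bimodal_tau,
            accession=str(acc),
        )
        rows.append(call.__dict__)
    out = pd.DataFrame(rows).set_index("accession")
    out.attrs["dropped"] = dropped
    return out


def piggyback_summary(
    calls: pd.DataFrame, hit_set: set, boundary_kda: float = 10.0
) -> dict:
    """Risk statistic for protein-protein crosslink artifacts.

    Among proteins preferentially localizing to higher-mass fractions
    (share > 0.5): the percentage that are capture hits whose predicted
    mass lies within ``boundary_kda`` below their fraction boundary. NaN
    when no protein qualifies.
    """
    hi = calls[calls["higher_mass_fraction_share"] > 0.5]
    n_hi = len(hi)
    if n_hi == 0:
        pct = np.nan
        n_flag = 0
    else:
        flagged = hi.index.isin(hit_set) & (hi["boundary_distance_kda"] <= boundary_kda)
        n_flag = int(flagged.sum())
        pct = 100.0 * n_flag / n_hi
    return {
        "n_high_mass_localized": n_hi,
        "n_boundary_proximal_hits": n_flag,
        "pct_boundary_proximal_hits": pct,
        "call_counts": calls["call"].value_counts().to_dict(),
    }


__all__ = [
    "MigrationCall",
    "filter_fraction_detections",
    "fraction_proportions",
    "weighted_mass_density",
    "classify_migration",
    "classify_all",
    "piggyback_summary",
]
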