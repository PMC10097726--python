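"""Fisher-exact overrepresentation analysis of annotations.

Generic term enrichment of a foreground protein set against a contrast set
(2x2 tables, exact hypergeometric p one-tailed or two-sided by the
point-probability rule, Benjamini-Hochberg across terms), plus the
specialized comparisons used for capture data: nucleotide-binding domain
and cofactor enrichment among enzyme-RBPs, catalytic-class profiles, and
per-pathway RBP fractions.

Multiple testing here is Benjamini-Hochberg throughout; outputs of the
catalytic-class profile are uncorrected by design and flagged as such.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import AnnotationCatalog, ValidationError
from .diffexp import benjamini_hochberg
from .simulate import NUCLEOTIDE_COFACTORS


def _sample_odds_ratio(a: int, b: int, c: int, d: int) -> float:
    """(a*d)/(b*c), with Haldane 0.5 continuity correction on any zero cell."""
    if min(a, b, c, d) == 0:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    return (a * d) / (b * c)


def fisher_enrichment(
    foreground: set,
    background: set,
    annotation: dict[str, set],
    tail: str = "greater",
    disjoint_contrast: bool = False,
) -> pd.DataFrame:
    """Per-term Fisher exact test of foreground vs contrast membership.

    By default the contrast is ``background - foreground`` (the foreground
    must then be a subset of the background); with ``disjoint_contrast``
    the background set is used as-is as the contrast group. Terms absent
    from both groups are skipped. Two-sided p-values use the
    point-probability (minimum-likelihood) rule.
    """
    if not foreground:
        raise ValidationError("empty foreground set")
    if tail not in ("greater", "two_sided"):
        raise ValidationError(f"unknown tail {tail!r}")
    if disjoint_contrast:
        contrast = set(background)
    else:
        if not foreground <= set(background):
            raise ValidationError("foreground must be a subset of background")
        contrast = set(background) - foreground
    terms: set[str] = set()
    for p in foreground | contrast:
        terms |= annotation.get(p, set())
    rows = []
    n_fg, n_bg = len(foreground), len(contrast)
    for term in sorted(terms):
        a = sum(1 for p in foreground if term in annotation.get(p, set()))
        c = sum(1 for p in contrast if term in annotation.get(p, set()))
        if a + c == 0:
            continue
        b = n_fg - a
        d = n_bg - c
        alt = "greater" if tail == "greater" else "two-sided"
        _, p_val = stats.fisher_exact([[a, b], [c, d]], alternative=alt)
        rows.append(
            {
                "term": term,
                "fg_with": a,
                "fg_without": b,
                "bg_with": c,
                "bg_without": d,
                "odds_ratio": _sample_odds_ratio(a, b, c, d),
                "p_value": float(p_val),
            }
        )
    out = pd.DataFrame(
        rows,
        columns=["term", "fg_with", "fg_without", "bg_with", "bg_without", "odds_ratio", "p_value"],
    ).set_index("term")
    out["fdr"] = benjamini_hochberg(out["p_value"].to_numpy()) if len(out) else []
    return out


def cofactor_domain_enrichment(
    hit_sets: dict[str, set],
    input_sets: dict[str, set],
    eluate_detected: set,
    catalog: AnnotationCatalog,
) -> pd.DataFrame:
    """Nucleotide-domain and cofactor enrichment among enzyme-RBPs.

    Foreground: metabolite-interconversion enzymes that are capture hits in
    at least one organ. Contrast: enzymes detected in the input proteomes
    but never in the capture eluates. Tested categories: possession of any
    nucleotide cofactor/domain plus each individual cofactor class;
    two-sided Fisher with BH correction, proportions in both groups
    reported.
    """
    t = catalog.table
    enzymes = set(t.index[t["protein_class"] == "metabolite interconversion enzyme"])
    all_hits = set().union(*hit_sets.values()) if hit_sets else set()
    all_inputs = set().union(*input_sets.values()) if input_sets else set()
    fg = enzymes & all_hits
    contrast = (enzymes & all_inputs) - eluate_detected
    if not fg or not contrast:
        raise ValidationError("empty enzyme foreground or contrast group")

    def nuc_classes(p: str) -> set[str]:
        out = set()
        for cof in catalog.cofactors.get(p, set()):
            if cof in NUCLEOTIDE_COFACTORS:
                out |= {cof, "any_nucleotide"}
        for dom in catalog.domains.get(p, set()):
            cls = catalog.domain_nucleotide_map.get(dom, "none")
            if cls in NUCLEOTIDE_COFACTORS:
                out |= {cls, "any_nucleotide"}
        for cof in catalog.cofactors.get(p, set()):
            if cof == "metal":
                out.add("metal")
        return out

    annotation = {p: nuc_classes(p) for p in fg | contrast}
    res = fisher_enrichment(fg, fg | contrast, annotation, tail="two_sided")
    res["fg_proportion"] = res["fg_with"] / len(fg)
    res["bg_proportion"] = res["bg_with"] / len(contrast)
    return res


def catalytic_class_profile(
    rbp_enzymes: set, other_enzymes: set, catalog: AnnotationCatalog, level: str = "catalytic_type"
) -> pd.DataFrame:
    """Catalytic-activity counts for RBP vs non-RBP enzymes.

    One-tailed Fisher per class, deliberately uncorrected (a descriptive
    panel, flagged by the ``corrected`` column).
    """
    t = catalog.table
    classes = sorted(t[level].dropna().unique())
    rows = []
    n_fg, n_bg = len(rbp_enzymes), len(other_enzymes)
    for cls in classes:
        members = set(t.index[t[level] == cls])
        a = len(rbp_enzymes & members)
        c = len(other_enzymes & members)
        b, d = n_fg - a, n_bg - c
        _, p = stats.fisher_exact([[a, b], [c, d]], alternative="greater")
        rows.append(
            {
                "class": cls,
                "rbp_count": a,
                "other_count": c,
                "odds_ratio": _sample_odds_ratio(a, b, c, d),
                "p_value": float(p),
                "corrected": False,
            }
        )
    return pd.DataFrame(rows).set_index("class")


def pathway_rbp_fraction(
    pathway_members: dict[str, set],
    hit_sets: dict[str, set],
    input_sets: dict[str, set] | None = None,
) -> pd.DataFrame:
    """Per-pathway, per-organ fraction of member proteins that are hits.

    The denominator is all annotated pathway members by default, or the
    members detected in that organ's input proteome when ``input_sets`` is
    given.
    """
    rows = []
    for pw, members in sorted(pathway_members.items()):
        if not members:
            continue
        row: dict = {"pathway": pw, "n_members": len(members)}
        for organ, hits in sorted(hit_sets.items()):
            denom_set = members & input_sets[organ] if input_sets else members
            inter = len(members & hits)
            row[f"n_hits_{organ}"] = inter
            row[f"fraction_{organ}"] = inter / len(denom_set) if denom_set else np.nan
        rows.append(row)
    return pd.DataFrame(rows).set_index("pathway")


__all__ = [
    "fisher_enrichment",
    "cofactor_domain_enrichment",
    "catalytic_class_profile",
    "pathway_rbp_fraction",
]
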