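"""Integration of poly(A) and non-poly(A) capture results into an atlas.

Combines per-organ differential tables from the two capture chemistries
into per-protein biotype classes (dual / exclusive / unresolved), computes
cross-organ Venn overlaps, flags novel RBPs against a published-atlas
catalog, and runs the staged "missing in organs" cascade for RBPs commonly
seen in cultured cells but absent from the organ data.
"""

from __future__ import annotations

from itertools import combinations

import pandas as pd

from .datatypes import ENRICH_CLASSES, ValidationError

#: qualification presets: organ-level atlas uses hits only, the deep liver
#: comparison accepts hits or candidates
MODES = {"hit_only": ("hit",), "hit_or_candidate": ("hit", "candidate")}
MODE_PRESETS = {"organ_atlas": "hit_only", "liver_deep": "hit_or_candidate"}


def _qualifies(cls: str, mode: str) -> bool:
    return cls in MODES[mode]


def classify_biotype(polya: str, nonpolya: str, mode: str = "hit_or_candidate") -> str:
    """Biotype class from the poly(A) and non-poly(A) enrichment classes.

    * dual                 — qualifies in both captures
    * exclusive_polya      — qualifies in poly(A), not detected in non-poly(A)
    * polya_unresolved     — qualifies in poly(A), detected but not enriched
      in non-poly(A) (and symmetrically for the non-poly(A) side)
    * none                 — qualifies in neither
    """
    if mode in MODE_PRESETS:
        mode = MODE_PRESETS[mode]
    if mode not in MODES:
        raise ValidationError(f"unknown mode {mode!r}")
    for name, c in (("polya", polya), ("nonpolya", nonpolya)):
        if c not in ENRICH_CLASSES:
            raise ValidationError(f"unknown {name} enrich_class {c!r}")
    pq = _qualifies(polya, mode)
    nq = _qualifies(nonpolya, mode)
    if pq and nq:
        return "dual"
    if pq:
        return "exclusive_polya" if nonpolya == "not_detected" else "polya_unresolved"
    if nq:
        return "exclusive_nonpolya" if polya == "not_detected" else "nonpolya_unresolved"
    return "none"


def build_atlas(
    polya_tables: dict[str, pd.DataFrame],
    nonpolya_tables: dict[str, pd.DataFrame],
    mode: str = "hit_or_candidate",
    extra_nonpolya_detected: dict[str, set] | None = None,
) -> pd.DataFrame:
    """Per-(protein, organ) atlas from paired differential tables.

    ``extra_nonpolya_detected`` optionally supplies, per organ, accessions
    detected in a deeper non-poly(A) run: proteins on that list cannot be
    exclusive poly(A) binders even if undetected in the shallow run (their
    non-poly(A) class is promoted from not_detected to no_hit).
    """
    rows = []
    organs = sorted(set(polya_tables) | set(nonpolya_tables))
    for organ in organs:
        pt = polya_tables.get(organ)
        nt = nonpolya_tables.get(organ)
        extra = (extra_nonpolya_detected or {}).get(organ, set())
        prots = set()
        if pt is not None:
            prots |= set(pt.index)
        if nt is not None:
            prots |= set(nt.index)
        for acc in sorted(prots):
            pc = str(pt.loc[acc, "enrich_class"]) if pt is not None and acc in pt.index else "not_detected"
            nc = str(nt.loc[acc, "enrich_class"]) if nt is not None and acc in nt.index else "not_detected"
            if nc == "not_detected" and acc in extra:
                nc = "no_hit"
            rows.append(
                {
                    "accession": acc,
                    "organ": organ,
                    "polya_class": pc,
                    "nonpolya_class": nc,
                    "biotype_class": classify_biotype(pc, nc, mode),
                }
            )
    return pd.DataFrame(rows, columns=["accession", "organ", "polya_class", "nonpolya_class", "biotype_class"])


# ----------------------------------------------------------- set algebra
def organ_sets(
    atlas: pd.DataFrame, organs: list[str], class_filter=("hit",), side: str = "polya"
) -> dict[str, set]:
    col = {"polya": "polya_class", "nonpolya": "nonpolya_class", "biotype": "biotype_class"}[side]
    out = {}
    for organ in organs:
        sub = atlas[atlas["organ"] == organ]
        out[organ] = set(sub.loc[sub[col].isin(class_filter), "accession"])
    return out


def cross_organ_overlap(sets: dict[str, set]) -> dict[tuple[str, ...], int]:
    """Exact Venn region counts over >= 2 organ sets.

    Keys are sorted tuples of the organs a region belongs to; values count
    proteins in exactly those organs. Region counts sum to the union size.
    """
    organs = sorted(sets)
    if len(organs) < 2:
        raise ValidationError("need at least two organs for an overlap")
    regions: dict[tuple[str, ...], int] = {}
    for r in range(1, len(organs) + 1):
        for combo in combinations(organs, r):
            inside = set.intersection(*(sets[o] for o in combo))
            outside = set.union(*(sets[o] for o in organs if o not in combo), set())
            regions[combo] = len(inside - outside)
    return regions


def identify_novel_rbps(
    hit_sets: dict[str, set], known_rbps: set
) -> tuple[set, dict[tuple[str, ...], int]]:
    """Organ hits absent from the published-atlas membership.

    Returns the novel set and its breakdown over organ-combination regions
    (regions partition the set, so their counts sum to the total).
    """
    all_hits = set().union(*hit_sets.values()) if hit_sets else set()
    novel = all_hits - known_rbps
    breakdown = {}
    if len(hit_sets) >= 2:
        novel_sets = {o: s & novel for o, s in hit_sets.items()}
        breakdown = {k: v for k, v in cross_organ_overlap(novel_sets).items() if v > 0}
    return novel, breakdown


def cell_line_presence_profile(
    protein_set: set, cell_lines: dict[str, set], k_max: int | None = None
) -> pd.Series:
    """Count proteins detected in >= k cell lines, for k = 1..K."""
    sizes = [len(cell_lines.get(p, set())) for p in protein_set]
    if k_max is None:
        k_max = max(sizes, default=0)
    counts = {k: sum(1 for s in sizes if s >= k) for k in range(1, max(k_max, 1) + 1)}
    return pd.Series(counts, name="n_proteins").rename_axis("min_cell_lines")


def missing_in_organ_cascade(
    common_cell_line_rbps: set,
    polya_hit_sets: dict[str, set],
    nonpolya_hit_sets: dict[str, set],
    input_detected: dict[str, set],
) -> dict[str, set]:
    """Staged exclusion of cell-line RBPs absent from the organ data.

    Stage 1: RBPs commonly identified in cultured cells but absent from all
    organ poly(A) hit sets. Stage 2: remove those recovered in any
    non-poly(A) hit set. Stage 3: split the remainder by detection in the
    total-proteome inputs — proteins undetected in the inputs are excluded
    (insufficient expression), those detected in all organs' inputs form
    the final focus set.
    """
    polya_union = set().union(*polya_hit_sets.values()) if polya_hit_sets else set()
    nonpolya_union = set().union(*nonpolya_hit_sets.values()) if nonpolya_hit_sets else set()
    stage1 = common_cell_line_rbps - polya_union
    in_nonpolya = stage1 & nonpolya_union
    stage2 = stage1 - nonpolya_union
    if input_detected:
        undetected = {p for p in stage2 if not any(p in s for s in input_detected.values())}
        final = {p for p in stage2 if all(p in s for s in input_detected.values())}
    else:
        undetected, final = set(), set()
    partial = stage2 - undetected - final
    return {
        "stage1_absent_polya": stage1,
        "found_in_nonpolya": in_nonpolya,
        "stage2_absent_both": stage2,
        "undetected_in_inputs": undetected,
        "detected_some_inputs": partial,
        "final_focus": final,
    }


__all__ = [
    "MODES",
    "MODE_PRESETS",
    "classify_biotype",
    "build_atlas",
    "organ_sets",
    "cross_organ_overlap",
    "identify_novel_rbps",
    "cell_line_presence_profile",
    "missing_in_organ_cascade",
]
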