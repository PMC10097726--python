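"""Biotype classification, set algebra, novel RBPs, cascade."""

from itertools import combinations

import numpy as np
import pandas as pd
import pytest

from ricproteo.datatypes import ENRICH_CLASSES, ValidationError
from ricproteo.integrate import (
    build_atlas,
    cell_line_presence_profile,
    classify_biotype,
    cross_organ_overlap,
    identify_novel_rbps,
    missing_in_organ_cascade,
    organ_sets,
)

# Exhaustive truth table: (polya, nonpolya) -> class, for both qualification
# modes. Derived by hand from the rules: a protein qualifies per mode; an
# exclusive binder is undetected on the other side; a qualifying protein
# detected-but-unenriched on the other side is unresolved.
TRUTH_HIT_ONLY = {
    ("hit", "hit"): "dual",
    ("hit", "candidate"): "polya_unresolved",
    ("hit", "no_hit"): "polya_unresolved",
    ("hit", "not_detected"): "exclusive_polya",
    ("candidate", "hit"): "nonpolya_unresolved",
    ("candidate", "candidate"): "none",
    ("candidate", "no_hit"): "none",
    ("candidate", "not_detected"): "none",
    ("no_hit", "hit"): "nonpolya_unresolved",
    ("no_hit", "candidate"): "none",
    ("no_hit", "no_hit"): "none",
    ("no_hit", "not_detected"): "none",
    ("not_detected", "hit"): "exclusive_nonpolya",
    ("not_detected", "candidate"): "none",
    ("not_detected", "no_hit"): "none",
    ("not_detected", "not_detected"): "none",
}
TRUTH_HIT_OR_CANDIDATE = {
    ("hit", "hit"): "dual",
    ("hit", "candidate"): "dual",
    ("hit", "no_hit"): "polya_unresolved",
    ("hit", "not_detected"): "exclusive_polya",
    ("candidate", "hit"): "dual",
    ("candidate", "candidate"): "dual",
    ("candidate", "no_hit"): "polya_unresolved",
    ("candidate", "not_detected"): "exclusive_polya",
    ("no_hit", "hit"): "nonpolya_unresolved",
    ("no_hit", "candidate"): "nonpolya_unresolved",
    ("no_hit", "no_hit"): "none",
    ("no_hit", "not_detected"): "none",
    ("not_detected", "hit"): "exclusive_nonpolya",
    ("not_detected", "candidate"): "exclusive_nonpolya",
    ("not_detected", "no_hit"): "none",
    ("not_detected", "not_detected"): "none",
}


@pytest.mark.parametrize("mode,table", [("hit_only", TRUTH_HIT_ONLY),
                                        ("hit_or_candidate", TRUTH_HIT_OR_CANDIDATE)])
def test_biotype_truth_table(mode, table):
    for pc in ENRICH_CLASSES:
        for nc in ENRICH_CLASSES:
            assert classify_biotype(pc, nc, mode) == table[(pc, nc)], (pc, nc, mode)


def test_biotype_named_presets_and_errors():
    assert classify_biotype("hit", "candidate", "liver_deep") == "dual"
    assert classify_biotype("hit", "candidate", "organ_atlas") == "polya_unresolved"
    with pytest.raises(ValidationError):
        classify_biotype("hit", "hit", "nope")
    with pytest.raises(ValidationError):
        classify_biotype("maybe", "hit")


def test_build_atlas_with_deep_run_exclusion():
    """A protein undetected in the shallow non-poly(A) run but present in the
    deep run cannot be an exclusive poly(A) binder."""
    pt = pd.DataFrame({"enrich_class": ["hit", "hit"]}, index=["A", "B"])
    nt = pd.DataFrame({"enrich_class": ["not_detected", "not_detected"]}, index=["A", "B"])
    atlas = build_atlas({"liver": pt}, {"liver": nt}, mode="hit_or_candidate",
                        extra_nonpolya_detected={"liver": {"B"}})
    by_acc = atlas.set_index("accession")
    assert by_acc.loc["A", "biotype_class"] == "exclusive_polya"
    assert by_acc.loc["B", "biotype_class"] == "polya_unresolved"


def test_liver_style_classification_counts():
    """Constructed liver-style dataset with planted class counts
    (583 exclusive poly(A), 404 exclusive non-poly(A), 588 dual) is
    recovered exactly by the atlas set algebra."""
    n_exc_p, n_exc_n, n_dual = 583, 404, 588
    rows_p, rows_n = {}, {}
    k = 0
    for _ in range(n_exc_p):
        acc = f"P{k:05d}"; k += 1
        rows_p[acc] = "hit" if k % 3 else "candidate"
    for _ in range(n_dual):
        acc = f"P{k:05d}"; k += 1
        rows_p[acc] = "hit" if k % 2 else "candidate"
        rows_n[acc] = "candidate" if k % 5 else "hit"
    for _ in range(n_exc_n):
        acc = f"P{k:05d}"; k += 1
        rows_n[acc] = "hit" if k % 4 else "candidate"
    for _ in range(250):  # background: detected, not enriched
        acc = f"P{k:05d}"; k += 1
        rows_p[acc] = "no_hit"
        rows_n[acc] = "no_hit"
    pt = pd.DataFrame({"enrich_class": pd.Series(rows_p)})
    nt = pd.DataFrame({"enrich_class": pd.Series(rows_n)})
    atlas = build_atlas({"liver": pt}, {"liver": nt}, mode="hit_or_candidate")
    counts = atlas["biotype_class"].value_counts()
    assert counts["exclusive_polya"] == n_exc_p
    assert counts["exclusive_nonpolya"] == n_exc_n
    assert counts["dual"] == n_dual
    assert counts["none"] == 250


# ------------------------------------------------------------ set algebra
def _brute_force_venn(sets):
    organs = sorted(sets)
    regions = {}
    for p in set().union(*sets.values()):
        member = tuple(o for o in organs if p in sets[o])
        regions[member] = regions.get(member, 0) + 1
    return regions


def test_cross_organ_overlap():
    # identical sets: everything in the all-organs region
    s = {"brain": {"A", "B"}, "kidney": {"A", "B"}, "liver": {"A", "B"}}
    v = cross_organ_overlap(s)
    assert v[("brain", "kidney", "liver")] == 2
    assert sum(v.values()) == 2
    # disjoint: only exclusive regions populated
    s = {"brain": {"A"}, "kidney": {"B"}}
    v = cross_organ_overlap(s)
    assert v[("brain",)] == 1 and v[("kidney",)] == 1 and v[("brain", "kidney")] == 0
    # random sets vs brute-force membership enumeration
    rng = np.random.default_rng(1)
    universe = [f"P{i}" for i in range(200)]
    for _ in range(10):
        sets = {
            o: {p for p in universe if rng.random() < q}
            for o, q in (("brain", 0.3), ("kidney", 0.5), ("liver", 0.4))
        }
        v = cross_organ_overlap(sets)
        bf = _brute_force_venn(sets)
        for combo, n in v.items():
            assert bf.get(combo, 0) == n
        assert sum(v.values()) == len(set().union(*sets.values()))
    with pytest.raises(ValidationError):
        cross_organ_overlap({"brain": {"A"}})


def test_identify_novel_rbps():
    hit_sets = {"brain": {"A", "B"}, "kidney": {"B", "C", "D"}}
    known = {"A", "C"}
    novel, breakdown = identify_novel_rbps(hit_sets, known)
    assert novel == {"B", "D"}
    assert sum(breakdown.values()) == len(novel)
    assert breakdown[("brain", "kidney")] == 1  # B
    assert breakdown[("kidney",)] == 1  # D
    # all hits annotated -> empty
    novel, _ = identify_novel_rbps(hit_sets, {"A", "B", "C", "D"})
    assert novel == set()


def test_planted_novel_fraction_recovered():
    rng = np.random.default_rng(2)
    hits = {f"P{i}" for i in range(200)}
    novel_truth = set(rng.choice(sorted(hits), size=20, replace=False))
    known = hits - novel_truth
    novel, _ = identify_novel_rbps({"liver": hits}, known)
    assert novel == novel_truth


def test_cell_line_presence_profile():
    lines = {f"P{i}": set() for i in range(5)}
    prof = cell_line_presence_profile(set(lines), lines, k_max=10)
    assert (prof == 0).all()
    lines = {"A": {f"CL{i}" for i in range(1, 11)}}
    prof = cell_line_presence_profile({"A"}, lines, k_max=10)
    assert (prof == 1).all()
    # random incidence vs brute force; cumulative counts non-increasing
    rng = np.random.default_rng(3)
    cl = [f"CL{i}" for i in range(10)]
    lines = {f"P{i}": set(rng.choice(cl, size=rng.integers(0, 11), replace=False))
             for i in range(50)}
    prof = cell_line_presence_profile(set(lines), lines, k_max=10)
    for k in range(1, 11):
        assert prof[k] == sum(1 for s in lines.values() if len(s) >= k)
    assert (prof.diff().dropna() <= 0).all()


def test_missing_in_organ_cascade_planted_sizes():
    """Constructed cascade: 20 in the non-poly(A) rescue, 5 undetected in
    inputs, 10 partially detected, 5 in the final focus set."""
    mk = lambda pref, n: {f"{pref}{i}" for i in range(n)}
    rescued = mk("R", 20)
    undet = mk("U", 5)
    partial = mk("Q", 10)
    final = mk("F", 5)
    common = rescued | undet | partial | final | {"H1", "H2"}  # two organ hits
    polya_hits = {"liver": {"H1"}, "kidney": {"H2", "X9"}}
    nonpolya_hits = {"liver": rescued}
    inputs = {
        "brain": set(final),
        "kidney": final | partial,
        "liver": final | partial,
    }
    stages = missing_in_organ_cascade(common, polya_hits, nonpolya_hits, inputs)
    assert len(stages["stage1_absent_polya"]) == 40
    assert stages["found_in_nonpolya"] == rescued
    assert len(stages["stage2_absent_both"]) == 20
    assert stages["undetected_in_inputs"] == undet
    assert stages["final_focus"] == final
    assert stages["detected_some_inputs"] == partial
    # nesting and partition invariants
    s1, s2 = stages["stage1_absent_polya"], stages["stage2_absent_both"]
    assert s2 <= s1
    assert stages["found_in_nonpolya"] == s1 - s2
    assert (stages["undetected_in_inputs"] | stages["detected_some_inputs"]
            | stages["final_focus"]) == s2


def test_cascade_empty_input():
    stages = missing_in_organ_cascade(set(), {"liver": {"A"}}, {}, {})
    assert all(len(v) == 0 for v in stages.values())


def test_organ_sets_from_atlas():
    atlas = pd.DataFrame(
        [
            {"accession": "A", "organ": "liver", "polya_class": "hit",
             "nonpolya_class": "no_hit", "biotype_class": "polya_unresolved"},
            {"accession": "B", "organ": "liver", "polya_class": "candidate",
             "nonpolya_class": "hit", "biotype_class": "dual"},
            {"accession": "A", "organ": "brain", "polya_class": "no_hit",
             "nonpolya_class": "not_detected", "biotype_class": "none"},
        ]
    )
    assert organ_sets(atlas, ["liver"], ("hit",), "polya") == {"liver": {"A"}}
    assert organ_sets(atlas, ["liver"], ("hit", "candidate"), "polya") == {"liver": {"A", "B"}}
    assert organ_sets(atlas, ["brain"], ("hit",), "polya") == {"brain": set()}
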