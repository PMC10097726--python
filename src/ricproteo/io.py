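"""Tab-separated readers and writers for every pipeline table.

All tables are TSV with a ``#schema: ricproteo/<kind>/v1`` header comment,
'.' decimal point regardless of locale, and empty cells for missing values.
Readers are strict: a missing required column raises :class:`SchemaError`
naming the column, and structural violations raise
:class:`ValidationError`.

Schemas (columns in order):

* quant table      — accession, unique_peptides, [predicted_mass_kda],
                     one intensity column per sample_id
* sample sheet     — sample_id, tissue, assay, condition, replicate, batch,
                     [channel]
* differential     — accession, log2fc, t_mod, p_value, fdr, enrich_class,
                     n_unique_peptides
* atlas            — accession, organ, polya_class, nonpolya_class,
                     biotype_class
* fraction profile — accession, [predicted_mass_kda],
                     ibaq_r<rep>_f<idx> per (replicate, fraction); empty
                     cell = not validly detected
* annotation       — accession, known_rbp, has_rbd, protein_class,
                     catalytic_type, catalytic_subtype, n_atlas_studies,
                     input_<organ>..., pathways, domains, cofactors,
                     cell_lines (semicolon-joined sets)
* RNA content      — tissue, polya_ug_per_mg_protein,
                     nonpolya_ug_per_mg_protein
"""

from __future__ import annotations

import io as _io
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .datatypes import (
    DEFAULT_FRACTION_BOUNDS,
    AnnotationCatalog,
    FractionProfile,
    QuantMatrix,
    RnaContent,
    SampleInfo,
    SchemaError,
    ValidationError,
    samples_to_frame,
)

SCHEMA_PREFIX = "#schema: ricproteo/"


def _write_tsv(df: pd.DataFrame, path, kind: str, index: bool = False) -> None:
    path = Path(path)
    buf = _io.StringIO()
    df.to_csv(buf, sep="\t", index=index, na_rep="")
    path.write_text(f"{SCHEMA_PREFIX}{kind}/v1\n" + buf.getvalue())


def _read_tsv(path, **kwargs) -> pd.DataFrame:
    path = Path(path)
    with path.open() as fh:
        first = fh.readline()
        skip = 1 if first.startswith("#") else 0
    return pd.read_csv(path, sep="\t", skiprows=skip, **kwargs)


def _require(df: pd.DataFrame, cols: Sequence[str], kind: str) -> None:
    for c in cols:
        if c not in df.columns:
            raise SchemaError(f"{kind} table: missing required column {c!r}")


# ----------------------------------------------------------------- samples
def read_sample_sheet(path) -> list[SampleInfo]:
    df = _read_tsv(path, dtype={"sample_id": str, "batch": str, "tissue": str})
    _require(df, ["sample_id", "tissue", "assay", "condition", "replicate", "batch"], "sample sheet")
    samples = []
    for _, r in df.iterrows():
        channel = r.get("channel")
        if pd.isna(channel):
            channel = None
        samples.append(
            SampleInfo(
                sample_id=str(r["sample_id"]),
                tissue=str(r["tissue"]),
                assay=str(r["assay"]),
                condition=str(r["condition"]),
                replicate=int(r["replicate"]),
                batch=str(r["batch"]),
                channel=channel,
            )
        )
    return samples


def write_sample_sheet(samples: Sequence[SampleInfo], path) -> None:
    _write_tsv(samples_to_frame(list(samples)).reset_index(drop=True), path, "sample_sheet")


# ------------------------------------------------------------- quant table
def read_quant_table(path, sample_sheet) -> QuantMatrix:
    """Read a protein quantification TSV against its sample sheet.

    Every intensity column must be declared in the sheet; empty cells become
    explicit missing values. Row order is preserved from the file.
    """
    samples = read_sample_sheet(sample_sheet)
    df = _read_tsv(path, dtype={"accession": str})
    _require(df, ["accession", "unique_peptides"], "quant")
    ids = [s.sample_id for s in samples]
    missing = [c for c in ids if c not in df.columns]
    if missing:
        raise SchemaError(f"quant table: missing intensity column(s) {missing}")
    df = df.set_index("accession")
    if df.index.duplicated().any():
        raise ValidationError("quant table: duplicate protein accessions")
    intensity = df[ids].astype(float)
    if (intensity.to_numpy() < 0).any():
        raise ValidationError("quant table: negative intensities")
    mass = None
    if "predicted_mass_kda" in df.columns:
        mass = df["predicted_mass_kda"].astype(float)
    return QuantMatrix(
        intensity=intensity,
        samples=samples,
        unique_peptides=df["unique_peptides"].astype(int),
        predicted_mass_kda=mass,
    )


def write_quant_table(q: QuantMatrix, path, sample_sheet=None) -> None:
    out = pd.DataFrame(index=q.proteins)
    out.insert(0, "accession", q.proteins)
    out["unique_peptides"] = q.unique_peptides
    if q.predicted_mass_kda is not None:
        out["predicted_mass_kda"] = q.predicted_mass_kda
    for s in q.samples:
        out[s.sample_id] = q.intensity[s.sample_id]
    _write_tsv(out, path, "quant")
    if sample_sheet is not None:
        write_sample_sheet(q.samples, sample_sheet)


# ---------------------------------------------------------- differential
DIFF_COLS = ["accession", "log2fc", "t_mod", "p_value", "fdr", "enrich_class", "n_unique_peptides"]


def write_differential_table(table: pd.DataFrame, path) -> None:
    out = table.reset_index() if "accession" not in table.columns else table.copy()
    if "index" in out.columns and "accession" not in out.columns:
        out = out.rename(columns={"index": "accession"})
    _require(out, DIFF_COLS, "differential")
    _write_tsv(out[DIFF_COLS], path, "differential")


def read_differential_table(path) -> pd.DataFrame:
    df = _read_tsv(path, dtype={"accession": str, "enrich_class": str})
    _require(df, DIFF_COLS, "differential")
    df = df.set_index("accession")
    bad = ~df["enrich_class"].isin(["hit", "candidate", "no_hit", "not_detected"])
    if bad.any():
        raise ValidationError(f"differential table: unknown enrich_class values {df['enrich_class'][bad].unique()}")
    return df


# ------------------------------------------------------------------ atlas
ATLAS_COLS = ["accession", "organ", "polya_class", "nonpolya_class", "biotype_class"]


def write_atlas_table(atlas: pd.DataFrame, path) -> None:
    out = atlas.reset_index(drop=True) if set(ATLAS_COLS) <= set(atlas.columns) else atlas.reset_index()
    _require(out, ATLAS_COLS, "atlas")
    _write_tsv(out[ATLAS_COLS], path, "atlas")


def read_atlas_table(path) -> pd.DataFrame:
    df = _read_tsv(path, dtype=str)
    _require(df, ATLAS_COLS, "atlas")
    return df


# --------------------------------------------------------------- fractions
def write_fraction_table(fp: FractionProfile, path) -> None:
    out = pd.DataFrame(index=fp.proteins)
    out.insert(0, "accession", fp.proteins)
    if fp.predicted_mass_kda is not None:
        out["predicted_mass_kda"] = fp.predicted_mass_kda
    for rep, frac in fp.ibaq.columns:
        col = f"ibaq_r{rep}_f{frac}"
        vals = fp.ibaq[(rep, frac)].where(fp.valid[(rep, frac)])
        out[col] = vals
    bounds = ",".join("inf" if not np.isfinite(b) else f"{b:g}" for b in fp.bounds)
    path = Path(path)
    buf = _io.StringIO()
    out.to_csv(buf, sep="\t", index=False, na_rep="")
    path.write_text(
        f"{SCHEMA_PREFIX}fractions/v1\n#bounds_kda: {bounds}\n" + buf.getvalue()
    )


def read_fraction_table(path) -> FractionProfile:
    path = Path(path)
    bounds = DEFAULT_FRACTION_BOUNDS
    skip = 0
    with path.open() as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            skip += 1
            if line.startswith("#bounds_kda:"):
                bounds = tuple(
                    np.inf if t.strip() == "inf" else float(t)
                    for t in line.split(":", 1)[1].split(",")
                )
    df = pd.read_csv(path, sep="\t", skiprows=skip, dtype={"accession": str})
    _require(df, ["accession"], "fractions")
    df = df.set_index("accession")
    ibaq_cols = [c for c in df.columns if c.startswith("ibaq_r")]
    if not ibaq_cols:
        raise SchemaError("fractions table: no ibaq_r<rep>_f<frac> columns")
    tuples = []
    for c in ibaq_cols:
        body = c[len("ibaq_r"):]
        rep, frac = body.split("_f")
        tuples.append((int(rep), int(frac)))
    ibaq = df[ibaq_cols].astype(float)
    ibaq.columns = pd.MultiIndex.from_tuples(tuples, names=["replicate", "fraction"])
    valid = ibaq.notna()
    mass = df["predicted_mass_kda"].astype(float) if "predicted_mass_kda" in df.columns else None
    return FractionProfile(ibaq=ibaq, valid=valid, bounds=bounds, predicted_mass_kda=mass)


# ------------------------------------------------------------- annotations
def _join_set(s: set[str]) -> str:
    return ";".join(sorted(s))


def _split_set(x) -> set[str]:
    if pd.isna(x) or x == "":
        return set()
    return set(str(x).split(";"))


def write_annotation_table(cat: AnnotationCatalog, path, nucleotide_map_path=None) -> None:
    out = cat.table.copy()
    out.insert(0, "accession", out.index)
    for name, mapping in (
        ("pathways", cat.pathways),
        ("domains", cat.domains),
        ("cofactors", cat.cofactors),
        ("cell_lines", cat.cell_lines),
    ):
        out[name] = [_join_set(mapping.get(a, set())) for a in cat.table.index]
    _write_tsv(out, path, "annotation")
    if nucleotide_map_path is not None:
        m = pd.DataFrame(
            sorted(cat.domain_nucleotide_map.items()), columns=["domain", "nucleotide_class"]
        )
        _write_tsv(m, nucleotide_map_path, "domain_nucleotide_map")


def read_annotation_table(path, nucleotide_map_path=None) -> AnnotationCatalog:
    df = _read_tsv(path, dtype={"accession": str})
    _require(df, ["accession", "known_rbp"], "annotation")
    df = df.set_index("accession", drop=True)
    sets = {}
    for name in ("pathways", "domains", "cofactors", "cell_lines"):
        if name in df.columns:
            sets[name] = {a: _split_set(v) for a, v in df[name].items()}
            df = df.drop(columns=[name])
        else:
            sets[name] = {}
    for col in df.columns:
        if col in ("known_rbp", "has_rbd") or col.startswith("input_"):
            df[col] = df[col].astype(bool)
    nuc_map = {}
    if nucleotide_map_path is not None:
        m = _read_tsv(nucleotide_map_path, dtype=str)
        _require(m, ["domain", "nucleotide_class"], "domain_nucleotide_map")
        nuc_map = dict(zip(m["domain"], m["nucleotide_class"]))
    return AnnotationCatalog(
        table=df,
        pathways=sets["pathways"],
        domains=sets["domains"],
        cofactors=sets["cofactors"],
        cell_lines=sets["cell_lines"],
        domain_nucleotide_map=nuc_map,
    )


# ------------------------------------------------------------- RNA content
def write_rna_content(rna: RnaContent, path) -> None:
    tissues = sorted(set(rna.polya) | set(rna.nonpolya))
    df = pd.DataFrame(
        {
            "tissue": tissues,
            "polya_ug_per_mg_protein": [rna.polya.get(t, np.nan) for t in tissues],
            "nonpolya_ug_per_mg_protein": [rna.nonpolya.get(t, np.nan) for t in tissues],
        }
    )
    _write_tsv(df, path, "rna_content")


def read_rna_content(path) -> RnaContent:
    df = _read_tsv(path, dtype={"tissue": str})
    _require(
        df,
        ["tissue", "polya_ug_per_mg_protein", "nonpolya_ug_per_mg_protein"],
        "rna_content",
    )
    return RnaContent(
        polya=dict(zip(df["tissue"], df["polya_ug_per_mg_protein"].astype(float))),
        nonpolya=dict(zip(df["tissue"], df["nonpolya_ug_per_mg_protein"].astype(float))),
    )


__all__ = [
    "read_sample_sheet",
    "write_sample_sheet",
    "read_quant_table",
    "write_quant_table",
    "read_differential_table",
    "write_differential_table",
    "read_atlas_table",
    "write_atlas_table",
    "read_fraction_table",
    "write_fraction_table",
    "read_annotation_table",
    "write_annotation_table",
    "read_rna_content",
    "write_rna_content",
]
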