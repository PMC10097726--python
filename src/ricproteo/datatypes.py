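"""Core data containers for RNA-interactome capture proteomics.

The central object is :class:`QuantMatrix`, a protein x sample intensity
table (raw TMT reporter-ion signal sums or iBAQ values) together with the
sample annotation needed downstream: tissue, assay, UV condition, replicate
and batch. Missing values are explicit ``NaN``; observed zeros are kept as
zeros, since a reporter-ion zero is informative.

Protein identity is the UniProt accession string, compared case-sensitively
with isoform suffixes kept verbatim.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

ASSAYS = ("eric", "nonpolya_ric", "input", "fraction")
CONDITIONS = ("plusUV", "minusUV")
ENRICH_CLASSES = ("hit", "candidate", "no_hit", "not_detected")
BIOTYPE_CLASSES = (
    "dual",
    "exclusive_polya",
    "exclusive_nonpolya",
    "polya_unresolved",
    "nonpolya_unresolved",
    "none",
)

#: default gel-fraction upper mass bounds in kDa; the final slice is open-ended
DEFAULT_FRACTION_BOUNDS = (20.0, 25.0, 37.0, 50.0, 75.0, 100.0, 150.0, np.inf)


class ValidationError(ValueError):
    """An object violates one of its structural invariants."""


class SchemaError(ValueError):
    """A table on disk does not match the documented column schema."""


@dataclass(frozen=True)
class SampleInfo:
    """Annotation of a single MS sample (one reporter channel or run)."""

    sample_id: str
    tissue: str
    assay: str
    condition: str
    replicate: int
    batch: str
    channel: str | None = None

    def __post_init__(self) -> None:
        if self.assay not in ASSAYS:
            raise ValidationError(
                f"sample {self.sample_id!r}: unknown assay {self.assay!r}; "
                f"expected one of {ASSAYS}"
            )
        if self.condition not in CONDITIONS:
            raise ValidationError(
                f"sample {self.sample_id!r}: unknown condition {self.condition!r}; "
                f"expected one of {CONDITIONS}"
            )


def samples_to_frame(samples: Sequence[SampleInfo]) -> pd.DataFrame:
    """Sample sheet as a DataFrame indexed by sample_id."""
    df = pd.DataFrame(
        {
            "sample_id": [s.sample_id for s in samples],
            "tissue": [s.tissue for s in samples],
            "assay": [s.assay for s in samples],
            "condition": [s.condition for s in samples],
            "replicate": [s.replicate for s in samples],
            "batch": [s.batch for s in samples],
            "channel": [s.channel for s in samples],
        }
    )
    return df.set_index("sample_id", drop=False)


@dataclass
class QuantMatrix:
    """Protein-level quantification: intensities plus sample metadata.

    Parameters
    ----------
    intensity
        DataFrame (proteins x samples), non-negative, NaN = missing.
    samples
        One :class:`SampleInfo` per intensity column, same order.
    unique_peptides
        Unique-peptide count per protein (Series aligned to the index).
    predicted_mass_kda
        Optional predicted monomeric mass per protein, kDa.
    """

    intensity: pd.DataFrame
    samples: list[SampleInfo]
    unique_peptides: pd.Series
    predicted_mass_kda: pd.Series | None = None

    def __post_init__(self) -> None:
        idx = self.intensity.index
        if idx.duplicated().any():
            dups = idx[idx.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate protein accessions: {dups[:5]}")
        sample_ids = [s.sample_id for s in self.samples]
        if len(set(sample_ids)) != len(sample_ids):
            raise ValidationError("duplicate sample_id in sample list")
        if list(self.intensity.columns) != sample_ids:
            raise ValidationError(
                "intensity columns do not match sample list "
                f"({list(self.intensity.columns)} vs {sample_ids})"
            )
        vals = self.intensity.to_numpy(dtype=float)
        if np.nanmin(vals, initial=0.0) < 0:
            raise ValidationError("negative intensity values are not allowed")
        self.unique_peptides = self.unique_peptides.reindex(idx)
        if self.unique_peptides.isna().any():
            raise ValidationError("unique_peptides missing for some proteins")
        if (self.unique_peptides < 0).any():
            raise ValidationError("unique_peptides must be >= 0")
        if self.predicted_mass_kda is not None:
            self.predicted_mass_kda = self.predicted_mass_kda.reindex(idx)
            m = self.predicted_mass_kda.dropna()
            if (m <= 0).any():
                raise ValidationError("predicted_mass_kda must be positive")

    # ------------------------------------------------------------------
    @property
    def proteins(self) -> pd.Index:
        return self.intensity.index

    @property
    def sample_frame(self) -> pd.DataFrame:
        return samples_to_frame(self.samples)

    @property
    def n_proteins(self) -> int:
        return len(self.intensity.index)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def subset_samples(self, sample_ids: Iterable[str]) -> "QuantMatrix":
        keep = list(sample_ids)
        by_id = {s.sample_id: s for s in self.samples}
        missing = [s for s in keep if s not in by_id]
        if missing:
            raise ValidationError(f"unknown sample ids: {missing}")
        return QuantMatrix(
            intensity=self.intensity[keep].copy(),
            samples=[by_id[s] for s in keep],
            unique_peptides=self.unique_peptides.copy(),
            predicted_mass_kda=(
                None if self.predicted_mass_kda is None else self.predicted_mass_kda.copy()
            ),
        )

    def subset_proteins(self, accessions: Iterable[str]) -> "QuantMatrix":
        keep = [a for a in self.proteins if a in set(accessions)]
        return QuantMatrix(
            intensity=self.intensity.loc[keep].copy(),
            samples=list(self.samples),
            unique_peptides=self.unique_peptides.loc[keep].copy(),
            predicted_mass_kda=(
                None
                if self.predicted_mass_kda is None
                else self.predicted_mass_kda.loc[keep].copy()
            ),
        )

    def with_intensity(self, intensity: pd.DataFrame) -> "QuantMatrix":
        return QuantMatrix(
            intensity=intensity,
            samples=list(self.samples),
            unique_peptides=self.unique_peptides.copy(),
            predicted_mass_kda=(
                None if self.predicted_mass_kda is None else self.predicted_mass_kda.copy()
            ),
        )


@dataclass(frozen=True)
class Thresholds:
    """Hit/candidate calling thresholds.

    Defaults follow the field convention for crosslink-enrichment capture:
    hit = FDR < 0.05 and fold change > 2; candidate = FDR < 0.2 and fold
    change > 1.5; proteins need >= 2 unique peptides to be testable.
    """

    hit_fdr: float = 0.05
    hit_fc: float = 2.0
    cand_fdr: float = 0.2
    cand_fc: float = 1.5
    min_unique_peptides: int = 2

    def __post_init__(self) -> None:
        if not (0 < self.hit_fdr <= self.cand_fdr <= 1):
            raise ValidationError("need 0 < hit_fdr <= cand_fdr <= 1")
        if not (self.hit_fc >= self.cand_fc > 1):
            raise ValidationError("need hit_fc >= cand_fc > 1")
        if self.min_unique_peptides < 1:
            raise ValidationError("min_unique_peptides must be >= 1")

    @property
    def hit_log2fc(self) -> float:
        return float(np.log2(self.hit_fc))

    @property
    def cand_log2fc(self) -> float:
        return float(np.log2(self.cand_fc))


@dataclass(frozen=True)
class ModerationParams:
    """Empirical-Bayes prior for variance moderation.

    ``d0`` is the prior degrees of freedom (``math.inf`` when the observed
    residual variances show no excess spread over chi-square sampling noise)
    and ``s0_sq`` the prior variance toward which per-protein variances are
    shrunk.
    """

    d0: float
    s0_sq: float
    warning: str | None = None

    def __post_init__(self) -> None:
        if not (self.d0 > 0):
            raise ValidationError("d0 must be > 0")
        if not (self.s0_sq > 0):
            raise ValidationError("s0_sq must be > 0")


@dataclass
class FractionProfile:
    """Gel-fraction iBAQ profiles with replicate structure.

    ``ibaq`` has a protein index and a 2-level (replicate, fraction) column
    MultiIndex; ``valid`` is a same-shaped boolean mask of detections that
    pass the per-cell filters. Fractions are labelled by their upper mass
    bound (kDa), the last one open-ended.
    """

    ibaq: pd.DataFrame
    valid: pd.DataFrame
    bounds: tuple[float, ...] = DEFAULT_FRACTION_BOUNDS
    predicted_mass_kda: pd.Series | None = None
    peptides: pd.DataFrame | None = None  # unique peptides per (replicate, fraction)

    def __post_init__(self) -> None:
        b = np.asarray(self.bounds, dtype=float)
        if not np.all(np.diff(b) > 0):
            raise ValidationError("fraction bounds must be strictly increasing")
        if self.ibaq.shape != self.valid.shape:
            raise ValidationError("ibaq and valid shapes differ")
        vals = self.ibaq.to_numpy(dtype=float)
        mask = self.valid.to_numpy(dtype=bool)
        if np.any(vals[mask] < 0):
            raise ValidationError("iBAQ must be >= 0 where valid")

    @property
    def replicates(self) -> list:
        return sorted(set(self.ibaq.columns.get_level_values(0)))

    @property
    def n_fractions(self) -> int:
        return len(self.bounds)

    @property
    def proteins(self) -> pd.Index:
        return self.ibaq.index


@dataclass
class AnnotationCatalog:
    """Per-protein annotation table plus term catalogs.

    ``table`` is indexed by accession with boolean/categorical columns
    (known_rbp, has_rbd, protein_class, catalytic_type, catalytic_subtype,
    n_atlas_studies, plus ``input_<organ>`` detection flags); set-valued
    annotations live in the mapping attributes.
    """

    table: pd.DataFrame
    pathways: dict[str, set[str]] = field(default_factory=dict)  # protein -> pathway ids
    domains: dict[str, set[str]] = field(default_factory=dict)
    cofactors: dict[str, set[str]] = field(default_factory=dict)
    cell_lines: dict[str, set[str]] = field(default_factory=dict)
    domain_nucleotide_map: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.table.index.duplicated().any():
            raise ValidationError("duplicate accessions in annotation catalog")
        missing = set(self.domains_referenced()) - set(self.domain_nucleotide_map)
        if missing:
            # classification map must be total over referenced domains
            for d in missing:
                self.domain_nucleotide_map[d] = "none"

    def domains_referenced(self) -> set[str]:
        out: set[str] = set()
        for s in self.domains.values():
            out |= s
        return out

    def known_rbps(self) -> set[str]:
        t = self.table
        return set(t.index[t["known_rbp"].astype(bool)])

    def input_detected(self, organ: str) -> set[str]:
        col = f"input_{organ}"
        if col not in self.table.columns:
            raise ValidationError(f"no input-proteome flag for organ {organ!r}")
        return set(self.table.index[self.table[col].astype(bool)])


@dataclass(frozen=True)
class RnaContent:
    """Per-tissue RNA yield, ug RNA per mg total protein."""

    polya: Mapping[str, float]
    nonpolya: Mapping[str, float]

    def __post_init__(self) -> None:
        for name, m in (("polya", self.polya), ("nonpolya", self.nonpolya)):
            for tissue, v in m.items():
                if not v > 0:
                    raise ValidationError(f"{name} RNA content for {tissue!r} must be > 0")

    def for_assay(self, assay: str, tissue: str) -> float:
        m = self.polya if assay == "eric" else self.nonpolya
        if tissue not in m:
            raise ValidationError(f"no RNA content for tissue {tissue!r}")
        return float(m[tissue])


__all__ = [
    "ASSAYS",
    "CONDITIONS",
    "ENRICH_CLASSES",
    "BIOTYPE_CLASSES",
    "DEFAULT_FRACTION_BOUNDS",
    "ValidationError",
    "SchemaError",
    "SampleInfo",
    "samples_to_frame",
    "QuantMatrix",
    "Thresholds",
    "ModerationParams",
    "FractionProfile",
    "AnnotationCatalog",
    "RnaContent",
]
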