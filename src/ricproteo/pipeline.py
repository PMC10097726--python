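"""End-to-end pipeline orchestration.

Runs simulate (optional) -> peptide filter -> normalize -> moderated test ->
hit calling -> poly(A)/non-poly(A) integration -> cross-organ summaries ->
gel-fraction QC (optional) -> annotation enrichment, writing versioned TSVs,
a JSON run manifest with every parameter and seed, and a log. The manifest
plus the package version suffice to reproduce every output byte for byte.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as rio
from .annot_enrich import cofactor_domain_enrichment, fisher_enrichment
from .datatypes import QuantMatrix, Thresholds
from .diffexp import EnrichmentModel
from .fractions import classify_all, filter_fraction_detections, piggyback_summary
from .integrate import build_atlas, cross_organ_overlap, identify_novel_rbps, organ_sets
from .organs import mean_signal_summary, replicate_correlation
from .simulate import SimConfig, simulate_annotations, simulate_eric_experiment, simulate_fraction_profiles

log = logging.getLogger("ricproteo")

DEFAULT_CONFIG = {
    "seed": 0,
    "strategy": "per-tissue-condition",
    "thresholds": {},
    "simulate": {},
    "run_fractions": True,
    "run_enrichment": True,
    "atlas_mode": "hit_or_candidate",
}


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str) -> None:
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


def _thresholds_from(cfg: dict) -> Thresholds:
    return Thresholds(**cfg.get("thresholds", {}))


def fit_assay_tables(
    q: QuantMatrix,
    thresholds: Thresholds,
    strategy: str = "per-tissue-condition",
    assays: tuple[str, ...] = ("eric", "nonpolya_ric"),
) -> dict[str, dict[str, pd.DataFrame]]:
    """Per-(assay, tissue) differential tables from one quantification matrix."""
    out: dict[str, dict[str, pd.DataFrame]] = {}
    for assay in assays:
        ids = [s.sample_id for s in q.samples if s.assay == assay]
        if not ids:
            continue
        sub = q.subset_samples(ids)
        # drop proteins never observed in this assay
        detected = sub.intensity.notna().any(axis=1)
        sub = sub.subset_proteins(sub.proteins[detected])
        if sub.n_proteins < 10:
            continue
        model = EnrichmentModel.from_quant(sub, strategy=strategy, thresholds=thresholds)
        res = model.fit()
        out[assay] = res.tables
        for tissue, table in res.tables.items():
            log.info(
                "%s/%s: %d proteins, %d hits",
                assay,
                tissue,
                len(table),
                int((table["enrich_class"] == "hit").sum()),
            )
    return out


def run_pipeline(config: dict, out_dir) -> dict:
    """Execute the full analysis described by ``config`` into ``out_dir``.

    Returns the manifest dict (also written to manifest.json). Any stage
    failure raises :class:`PipelineError` naming the stage; partial outputs
    are retained next to a FAILED marker file.
    """
    cfg = {**DEFAULT_CONFIG, **(config or {})}
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=logging.INFO)
    manifest: dict = {"config": cfg, "outputs": {}}
    stage = "setup"
    try:
        thresholds = _thresholds_from(cfg)
        seed = int(cfg["seed"])

        stage = "simulate"
        if cfg.get("quant_table") and cfg.get("sample_sheet"):
            q = rio.read_quant_table(cfg["quant_table"], cfg["sample_sheet"])
            truth = None
        else:
            sim = SimConfig(**{**cfg.get("simulate", {}), "seed": seed})
            q, truth = simulate_eric_experiment(sim)
            rio.write_quant_table(q, out / "quant.tsv", out / "samples.tsv")
            truth.to_csv(out / "truth.tsv", sep="\t")
            manifest["outputs"]["quant"] = "quant.tsv"

        stage = "filter"
        n0 = q.n_proteins
        log.info("quantified proteins: %d", n0)

        stage = "test"
        tables = fit_assay_tables(q, thresholds, strategy=cfg["strategy"])
        if "eric" not in tables:
            raise PipelineError(stage, "no poly(A) capture samples found")
        for assay, per_tissue in tables.items():
            for tissue, table in per_tissue.items():
                fname = f"differential_{assay}_{tissue}.tsv"
                rio.write_differential_table(table, out / fname)
                manifest["outputs"][f"differential/{assay}/{tissue}"] = fname

        stage = "integrate"
        atlas = build_atlas(
            tables.get("eric", {}), tables.get("nonpolya_ric", {}), mode=cfg["atlas_mode"]
        )
        rio.write_atlas_table(atlas, out / "atlas.tsv")
        manifest["outputs"]["atlas"] = "atlas.tsv"
        tissues = sorted(tables["eric"])
        hit_sets = organ_sets(atlas, tissues, class_filter=("hit",), side="polya")
        if len(tissues) >= 2:
            venn = cross_organ_overlap(hit_sets)
            pd.DataFrame(
                [{"region": "+".join(k), "count": v} for k, v in sorted(venn.items())]
            ).to_csv(out / "venn_polya_hits.tsv", sep="\t", index=False)
            manifest["outputs"]["venn"] = "venn_polya_hits.tsv"

        stage = "compare-organs"
        eric_ids = [s.sample_id for s in q.samples if s.assay == "eric" and s.condition == "plusUV"]
        union_hits = set().union(*hit_sets.values()) if hit_sets else set()
        if union_hits and eric_ids:
            eric_samples = [s for s in q.samples if s.sample_id in eric_ids]
            means, ratios = mean_signal_summary(
                q.intensity[eric_ids], eric_samples, union_hits
            )
            means.rename_axis("tissue").to_csv(out / "mean_signal.tsv", sep="\t")
            ratios.to_csv(out / "mean_signal_ratios.tsv", sep="\t")
            manifest["outputs"]["mean_signal"] = "mean_signal.tsv"
        pairs = []
        for tissue in tissues:
            ids = [
                s.sample_id
                for s in q.samples
                if s.assay == "eric" and s.tissue == tissue and s.condition == "plusUV"
            ]
            pairs += [(a, b) for i, a in enumerate(ids) for b in ids[i + 1:]]
        if pairs:
            corr = replicate_correlation(np.log2(q.intensity + 1.0), pairs)
            corr.rename_axis(["sample_a", "sample_b"]).to_csv(out / "replicate_correlation.tsv", sep="\t")
            manifest["outputs"]["replicate_correlation"] = "replicate_correlation.tsv"

        stage = "fractions"
        if cfg.get("run_fractions") and truth is not None:
            simf = SimConfig(**{**cfg.get("simulate", {}), "seed": seed})
            fp, ftruth = simulate_fraction_profiles(simf)
            fp = filter_fraction_detections(fp)
            calls = classify_all(fp)
            calls.to_csv(out / "migration_calls.tsv", sep="\t")
            summary = piggyback_summary(calls, set(calls.index))
            (out / "piggyback_summary.json").write_text(json.dumps(summary, default=str, indent=1))
            manifest["outputs"]["migration_calls"] = "migration_calls.tsv"

        stage = "enrich"
        if cfg.get("run_enrichment") and truth is not None:
            simc = SimConfig(**{**cfg.get("simulate", {}), "seed": seed})
            catalog = simulate_annotations(simc, truth)
            novel, _ = identify_novel_rbps(hit_sets, catalog.known_rbps())
            manifest["n_novel_rbps"] = len(novel)
            detected_eluates = set(atlas["accession"])
            input_sets = {t: catalog.input_detected(t) for t in tissues if f"input_{t}" in catalog.table.columns}
            if input_sets:
                try:
                    enr = cofactor_domain_enrichment(hit_sets, input_sets, detected_eluates, catalog)
                    enr.to_csv(out / "cofactor_enrichment.tsv", sep="\t")
                    manifest["outputs"]["cofactor_enrichment"] = "cofactor_enrichment.tsv"
                except Exception as exc:  # small sims can have empty groups
                    log.warning("cofactor enrichment skipped: %s", exc)

        stage = "manifest"
        if truth is not None:
            truth_rbps = {t: set(truth.index[truth["is_rbp"]]) for t in tissues}
            recall = {
                t: (len(hit_sets[t] & truth_rbps[t]) / len(truth_rbps[t]) if truth_rbps[t] else np.nan)
                for t in tissues
                if t in hit_sets
            }
            manifest["planted_rbp_recall"] = recall
        manifest["thresholds"] = dataclasses.asdict(thresholds)
        manifest["seed"] = seed
        (out / "manifest.json").write_text(json.dumps(manifest, indent=1, default=str))
        return manifest
    except PipelineError:
        (out / "FAILED").write_text(stage)
        raise
    except Exception as exc:
        (out / "FAILED").write_text(f"{stage}: {exc}")
        raise PipelineError(stage, str(exc)) from exc


__all__ = ["DEFAULT_CONFIG", "PipelineError", "fit_assay_tables", "run_pipeline"]
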