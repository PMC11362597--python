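"""End-to-end pipeline orchestration with a resolved-config manifest.

``run_full`` chains read -> log2 -> filter -> impute -> normalize ->
differential enrichment -> candidate selection -> co-IP credibility scoring
-> paired loading analysis -> QC, writing results tables, a QC report, the
tier summary and a run manifest (fully resolved parameters, seed, input
checksums). Every stage that draws random numbers gets a seed derived from
the single global seed by a fixed offset, so stages rerun standalone
reproduce the pipeline's values.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import __version__
from .core import Condition, ProteinQuantTable, StudyDesign
from .credibility import score_candidates
from .enrichment import DifferentialEnrichment
from .io import read_combined_protein_tsv, read_design, write_results_tsv
from .loading import PairedLoading
from .preprocess import (
    FilterParams,
    ImputeParams,
    filter_by_detection,
    impute_mnar,
    log2_transform,
    normalize,
)
from .qc import qc_report

logger = logging.getLogger("apmstools")

__all__ = ["PipelineConfig", "run_full", "preprocess_table", "derive_seed"]

_SEED_OFFSETS = {"impute": 1, "impute_coip": 2, "impute_loading": 3}


def derive_seed(global_seed: Optional[int], stage: str) -> Optional[int]:
    """Stage seed = fixed derivation from the single global seed."""
    if global_seed is None:
        return None
    return (int(global_seed) * 1000003 + _SEED_OFFSETS[stage]) % (2**31 - 1)


@dataclass
class PipelineConfig:
    """Fully resolved pipeline parameters; unknown keys are rejected."""

    pulldown_table: str = ""
    coip_table: str = ""
    loading_table: str = ""
    design: str = ""
    out_dir: str = "results"
    intensity_suffix: str = "MaxLFQ Intensity"
    cond_bait: str = Condition.BAIT_INTACT.value
    cond_ctrl: str = Condition.GST_CTRL.value
    filter_min_frac_global: float = 0.0
    filter_min_frac_one_condition: float = 0.60
    impute_shift_sd: float = 1.8
    impute_width_sd: float = 0.3
    normalize_method: str = "vsn_like"
    alpha: float = 0.01
    lfc_cut: float = 2.0
    direction: str = "bait_enriched"
    coip_fc_scale: str = "linear"
    loading_delta_cut: float = 0.2
    loading_alpha: float = 0.05
    bait_id: str = ""
    seed: Optional[int] = None

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        known = set(cls.__dataclass_fields__)
        unknown = sorted(set(raw) - known)
        if unknown:
            raise ValueError(f"unknown config keys: {unknown}")
        return cls(**raw)


def _sha256(path: "str | Path") -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def preprocess_table(
    table: ProteinQuantTable,
    design: StudyDesign,
    config: PipelineConfig,
    impute_seed: Optional[int],
) -> tuple[ProteinQuantTable, ProteinQuantTable]:
    """log2 -> filter -> impute -> normalize; returns (raw log2 filtered, processed)."""
    logged = log2_transform(table)
    filtered = filter_by_detection(
        logged,
        design,
        FilterParams(config.filter_min_frac_global, config.filter_min_frac_one_condition),
    )
    imputed = impute_mnar(
        filtered,
        ImputeParams(config.impute_shift_sd, config.impute_width_sd, seed=impute_seed),
    )
    return filtered, normalize(imputed, config.normalize_method)


def run_full(config: PipelineConfig) -> dict:
    """Execute the full pipeline per the resolved config.

    Returns a results bundle (dict of DataFrames/dicts) and writes all
    outputs plus ``manifest.json`` under ``config.out_dir``. Any stage
    failure is re-raised annotated with the stage name.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    bundle: dict = {}
    manifest: dict = {
        "package_version": __version__,
        "config": asdict(config),
        "inputs": {},
        "stage_seeds": {},
    }

    def stage(name):
        logger.info("stage: %s", name)
        return name

    current = stage("read")
    try:
        for key in ("pulldown_table", "coip_table", "loading_table", "design"):
            path = getattr(config, key)
            if path:
                if not Path(path).exists():
                    raise FileNotFoundError(f"{key} file not found: {path}")
                manifest["inputs"][key] = {"path": str(path), "sha256": _sha256(path)}
        design = read_design(config.design)
        pulldown = read_combined_protein_tsv(config.pulldown_table, config.intensity_suffix)

        current = stage("preprocess")
        seed_imp = derive_seed(config.seed, "impute")
        manifest["stage_seeds"]["impute"] = seed_imp
        raw_log2, processed = preprocess_table(pulldown, design, config, seed_imp)

        current = stage("diff_enrichment")
        model = DifferentialEnrichment(processed, design, config.cond_bait, config.cond_ctrl)
        res = model.fit(alpha=config.alpha, lfc_cut=config.lfc_cut, direction=config.direction)
        bundle["enrichment"] = res
        write_results_tsv(res.frame, out_dir / "enrichment.tsv")
        write_results_tsv(res.volcano_coords(), out_dir / "volcano.tsv")
        candidates = res.candidates["protein_id"].tolist()
        bundle["candidates"] = candidates

        current = stage("qc")
        qc = qc_report(raw_log2, processed, design, config.cond_bait, config.cond_ctrl)
        bundle["qc"] = qc
        qc_json = {
            "variance_explained": qc["pca"]["variance_explained"],
            "detected_counts": qc["detected_counts"],
            "overlap": qc["overlap"],
            "normality": qc["normality"],
        }
        (out_dir / "qc.json").write_text(json.dumps(qc_json, indent=2, sort_keys=True))
        qc["pearson"].to_csv(out_dir / "pearson.tsv", sep="\t", float_format="%.6g")
        qc["pca"]["coords"].to_csv(out_dir / "pca.tsv", sep="\t", float_format="%.6g")

        if config.coip_table and candidates:
            current = stage("coip_scoring")
            coip = read_combined_protein_tsv(config.coip_table, config.intensity_suffix)
            coip_design = design
            coip_log2 = log2_transform(coip)
            records, tiers, not_evaluable = score_candidates(
                candidates,
                coip_log2,
                coip_design,
                scale=config.coip_fc_scale,
                bait_id=config.bait_id or None,
            )
            bundle["credibility"] = records
            bundle["tier_counts"] = tiers
            write_results_tsv(records, out_dir / "credibility.tsv")
            (out_dir / "tiers.json").write_text(
                json.dumps({"tier_counts": tiers, "not_evaluable": not_evaluable},
                           indent=2, sort_keys=True)
            )

        if config.loading_table:
            current = stage("loading")
            load = read_combined_protein_tsv(config.loading_table, config.intensity_suffix)
            load_log2 = log2_transform(load)
            lres = PairedLoading(load_log2, design).fit(
                delta_cut=config.loading_delta_cut, alpha=config.loading_alpha
            )
            bundle["loading"] = lres
            write_results_tsv(lres.frame, out_dir / "loading.tsv")
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {current!r} failed: {exc}") from exc

    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    bundle["manifest"] = manifest
    return bundle
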