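"""Credibility scoring of pulldown candidates against co-IP data.

Each candidate gets a confidence label from its detection rate across the
co-IP bait samples (> 80% high, 60–80% inclusive moderate, < 60% unlikely)
and an enrichment label from its bait-vs-control fold change relative to the
median fold change of the examined candidates (above the median: high; at or
below: low). The two labels combine into four credibility tiers:

    confidence   enrichment   category
    unlikely     (any)        unlikely (excluded from the partner tally)
    moderate     low          low_credibility
    moderate     high         satisfactory
    high         low          satisfactory
    high         high         high_credibility
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .core import Condition, ProteinQuantTable, StudyDesign

__all__ = [
    "CredibilityRecord",
    "detection_rate",
    "confidence_label",
    "enrichment_label",
    "median_fc_threshold",
    "classify",
    "score_candidates",
    "CONFIDENCE_LABELS",
    "ENRICHMENT_LABELS",
    "CATEGORIES",
]

CONFIDENCE_LABELS = ("high", "moderate", "unlikely")
ENRICHMENT_LABELS = ("high", "low")
CATEGORIES = ("unlikely", "low_credibility", "satisfactory", "high_credibility")

_CLASSIFY = {
    ("high", "high"): "high_credibility",
    ("high", "low"): "satisfactory",
    ("moderate", "high"): "satisfactory",
    ("moderate", "low"): "low_credibility",
    ("unlikely", "high"): "unlikely",
    ("unlikely", "low"): "unlikely",
}


@dataclass
class CredibilityRecord:
    protein_id: str
    detection_rate: float
    confidence: str
    fold_change: Optional[float]
    enrichment: Optional[str]
    category: str


def detection_rate(
    protein_id: str,
    table: ProteinQuantTable,
    design: StudyDesign,
    condition: "str | Condition",
) -> float:
    """Non-missing fraction of a protein across the samples of a condition.

    Uses the pre-imputation missingness mask; the table passed here must not
    have been imputed.
    """
    condition = Condition.parse(condition)
    row = table.row_index(protein_id)
    cols = [table.col_index(s) for s in design.samples_in(condition) if s in table.sample_ids]
    if not cols:
        raise ValueError(f"condition {condition.value} has no samples in the table")
    detected = ~table.missing_mask[row, cols]
    return float(detected.mean())


def confidence_label(rate: float) -> str:
    """Detection-rate bins: > 0.80 high; 0.60–0.80 inclusive moderate; < 0.60 unlikely."""
    if not 0.0 <= rate <= 1.0:
        raise ValueError(f"rate must be in [0, 1], got {rate}")
    if rate > 0.80:
        return "high"
    if rate >= 0.60:
        return "moderate"
    return "unlikely"


def enrichment_label(fc: float, threshold: float) -> str:
    """Fold change above the threshold is high; at or below is low."""
    if not fc > 0:
        raise ValueError(f"fold change must be positive, got {fc}")
    return "high" if fc > threshold else "low"


def median_fc_threshold(fcs: Sequence[float]) -> float:
    """Sample median (midpoint convention) of the candidates' fold changes."""
    fcs = np.asarray(list(fcs), dtype=float)
    if fcs.size == 0:
        raise ValueError("cannot take the median of an empty fold-change list")
    return float(np.median(fcs))


def classify(confidence: str, enrichment: Optional[str]) -> str:
    """Combine confidence and enrichment labels into a credibility tier."""
    if confidence not in CONFIDENCE_LABELS:
        raise ValueError(f"unknown confidence label {confidence!r}")
    if confidence == "unlikely":
        return "unlikely"
    if enrichment not in ENRICHMENT_LABELS:
        raise ValueError(f"unknown enrichment label {enrichment!r}")
    return _CLASSIFY[(confidence, enrichment)]


def _coip_fold_changes(
    candidates: list[str],
    table: ProteinQuantTable,
    design: StudyDesign,
    bait_condition: Condition,
    control_condition: Condition,
    scale: str,
) -> dict[str, float]:
    """Bait-vs-control fold change per candidate from observed log2 values.

    Group means use observed (non-missing) cells only. A candidate with no
    observed control value is right-censored at the control samples'
    per-sample observed minima (detection-floor convention), so it still
    gets a large, finite fold change.
    """
    if table.scale_tag != "log2":
        raise ValueError("fold changes are computed on a log2-scale table")
    bait_cols = [table.col_index(s) for s in design.samples_in(bait_condition)
                 if s in table.sample_ids]
    ctrl_cols = [table.col_index(s) for s in design.samples_in(control_condition)
                 if s in table.sample_ids]
    obs = ~table.missing_mask
    floor = np.array([
        table.intensities[obs[:, c], c].min() if obs[:, c].any() else np.nan
        for c in ctrl_cols
    ])
    out: dict[str, float] = {}
    for pid in candidates:
        r = table.row_index(pid)
        b_vals = [table.intensities[r, c] for c in bait_cols if obs[r, c]]
        if not b_vals:
            continue
        c_vals = [table.intensities[r, c] for c in ctrl_cols if obs[r, c]]
        ctrl_mean = float(np.mean(c_vals)) if c_vals else float(np.nanmean(floor))
        log2fc = float(np.mean(b_vals)) - ctrl_mean
        out[pid] = 2.0 ** log2fc if scale == "linear" else log2fc
    return out


def score_candidates(
    candidates: Iterable[str],
    coip_table: ProteinQuantTable,
    design: StudyDesign,
    bait_condition: "str | Condition" = Condition.COIP_BAIT,
    control_condition: "str | Condition" = Condition.IGG_CTRL,
    scale: str = "linear",
    fc_threshold: Optional[float] = None,
    bait_id: Optional[str] = None,
) -> tuple[pd.DataFrame, dict[str, int], list[str]]:
    """Score pulldown candidates against a (non-imputed) co-IP table.

    Returns ``(records, tier_counts, not_evaluable)``: one record per
    candidate present in the table, the histogram over the four categories
    (with the bait protein itself excluded from the tally), and the list of
    candidates absent from the co-IP table. The enrichment threshold
    defaults to the median fold change over the evaluable candidates, on the
    scale requested (``linear`` = 2**log2FC, or ``log2``).
    """
    candidates = list(dict.fromkeys(candidates))
    if not candidates:
        raise ValueError("empty candidate list")
    bait_condition = Condition.parse(bait_condition)
    control_condition = Condition.parse(control_condition)
    present = [c for c in candidates if c in coip_table.protein_ids]
    not_evaluable = [c for c in candidates if c not in coip_table.protein_ids]

    rates = {
        pid: detection_rate(pid, coip_table, design, bait_condition) for pid in present
    }
    fcs = _coip_fold_changes(
        present, coip_table, design, bait_condition, control_condition, scale
    )
    threshold = fc_threshold
    if threshold is None:
        evaluable_fcs = [fcs[p] for p in present
                         if p in fcs and confidence_label(rates[p]) != "unlikely"]
        threshold = median_fc_threshold(evaluable_fcs) if evaluable_fcs else np.nan

    records = []
    for pid in present:
        conf = confidence_label(rates[pid])
        fc = fcs.get(pid)
        if conf == "unlikely" or fc is None:
            enr = None
            cat = "unlikely"
        else:
            enr = enrichment_label(fc, threshold)
            cat = classify(conf, enr)
        records.append(
            {
                "protein_id": pid,
                "detection_rate": rates[pid],
                "confidence": conf,
                "fold_change": fc if fc is not None else np.nan,
                "enrichment": enr if enr is not None else "",
                "category": cat,
            }
        )
    frame = pd.DataFrame.from_records(records)
    frame.attrs["fc_threshold"] = threshold
    frame.attrs["fc_scale"] = scale
    tally = frame[frame["protein_id"] != bait_id] if bait_id else frame
    tier_counts = {cat: int((tally["category"] == cat).sum()) for cat in CATEGORIES}
    return frame, tier_counts, not_evaluable
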