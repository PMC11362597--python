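"""Synthetic AP-MS data with ground truth.

The generator emulates the statistical structure the pipeline assumes:
log2-normal protein baselines, replicate noise, a minority of true
bait-specific interactors with large positive log2 fold changes,
intensity-dependent (logistic) dropout producing left-censored missingness,
a co-IP replicate set with attenuated effects, and paired GTPγS/GDPβS
pulldowns sharing a per-lysate random effect with a state-dependent shift
for a subset of interactors.

Default condition sizes mirror the study design the pipeline targets:
6 control vs 6 bait pulldowns, 5 + 5 co-IP samples, and 3 loading pairs;
the default state effect (0.785 log2 units) is a realistic
nucleotide-dependent shift for a GTPase partner.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.special import expit

from .core import Condition, ProteinQuantTable, SampleInfo, StudyDesign

__all__ = ["SimParams", "SyntheticTruth", "generate_pulldown", "generate_coip", "generate_loading"]


@dataclass
class SimParams:
    """Parameters of the synthetic AP-MS experiment.

    All intensity-scale parameters are in log2 units. Dropout probability
    for a cell with log2 intensity x is ``expit(mnar_slope * (mnar_mid - x))``,
    i.e. logistic and monotone decreasing in intensity.
    """

    n_proteins: int = 775
    frac_true: float = 90 / 775
    effect_low: float = 2.5
    effect_high: float = 6.0
    baseline_mean: float = 25.0
    baseline_sd: float = 2.0
    noise_sd: float = 0.5
    n_ctrl: int = 6
    n_bait: int = 6
    n_coip_ctrl: int = 5
    n_coip_bait: int = 5
    n_pairs: int = 3
    mnar_mid: float = 22.0
    mnar_slope: float = 1.0
    frac_state_dependent: float = 0.1
    state_effect: float = 0.785
    pair_effect_sd: float = 0.5
    coip_attenuation: float = 0.8
    coip_low_detection_frac: float = 0.15
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        for name in ("frac_true", "frac_state_dependent", "coip_low_detection_frac"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.effect_low > self.effect_high:
            raise ValueError("effect bounds must be ordered")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")


@dataclass
class SyntheticTruth:
    """Ground truth emitted alongside the synthetic tables."""

    true_interactors: set[str]
    assigned_log2fc: dict[str, float]
    state_dependent: set[str]
    baseline: dict[str, float]
    dropout_probabilities: dict[str, np.ndarray] = field(default_factory=dict)
    coip_low_detection: set[str] = field(default_factory=set)


def _protein_ids(n: int) -> list[str]:
    return [f"P{i:05d}" for i in range(1, n + 1)]


def _dropout(log2_matrix: np.ndarray, params: SimParams, rng: np.random.Generator):
    prob = expit(params.mnar_slope * (params.mnar_mid - log2_matrix))
    mask = rng.random(log2_matrix.shape) < prob
    return mask, prob


def _to_linear_table(
    log2_matrix: np.ndarray,
    mask: np.ndarray,
    protein_ids: list[str],
    sample_ids: list[str],
) -> ProteinQuantTable:
    linear = np.exp2(log2_matrix)
    linear[mask] = 0.0
    return ProteinQuantTable(
        protein_ids=protein_ids,
        intensities=linear,
        sample_ids=sample_ids,
        missing_mask=mask,
        scale_tag="linear",
    )


def generate_pulldown(
    params: SimParams,
) -> tuple[ProteinQuantTable, StudyDesign, SyntheticTruth]:
    """Simulate the control-vs-bait pulldown experiment.

    Control samples draw each protein around its log2 baseline; bait samples
    add the assigned log2 fold change for true interactors; logistic MNAR
    dropout is applied cell-wise and dropped cells become zeros of the
    returned linear-scale table. Reproducible given ``params.seed``.
    """
    rng = np.random.default_rng(params.seed)
    ids = _protein_ids(params.n_proteins)
    n_true = int(round(params.frac_true * params.n_proteins))
    if params.frac_true > 0 and n_true == 0:
        warnings.warn(
            "frac_true * n_proteins < 1; generating zero true interactors",
            stacklevel=2,
        )
    true_idx = rng.choice(params.n_proteins, size=n_true, replace=False) if n_true else np.array([], dtype=int)
    effects = np.zeros(params.n_proteins)
    effects[true_idx] = rng.uniform(params.effect_low, params.effect_high, size=n_true)
    n_state = int(round(params.frac_state_dependent * n_true))
    state_idx = rng.choice(true_idx, size=n_state, replace=False) if n_state else np.array([], dtype=int)

    baseline = rng.normal(params.baseline_mean, params.baseline_sd, size=params.n_proteins)
    n_s = params.n_ctrl + params.n_bait
    truth_mat = baseline[:, None] + np.zeros((params.n_proteins, n_s))
    truth_mat[:, params.n_ctrl:] += effects[:, None]
    log2_matrix = truth_mat + rng.normal(0.0, params.noise_sd, size=truth_mat.shape)
    mask, prob = _dropout(log2_matrix, params, rng)

    sample_ids = [f"GST_{i + 1}" for i in range(params.n_ctrl)] + [
        f"BAIT_{i + 1}" for i in range(params.n_bait)
    ]
    design = StudyDesign(
        [SampleInfo(f"GST_{i + 1}", Condition.GST_CTRL, i + 1) for i in range(params.n_ctrl)]
        + [SampleInfo(f"BAIT_{i + 1}", Condition.BAIT_INTACT, i + 1) for i in range(params.n_bait)]
    )
    table = _to_linear_table(log2_matrix, mask, ids, sample_ids)
    truth = SyntheticTruth(
        true_interactors={ids[i] for i in true_idx},
        assigned_log2fc={ids[i]: float(effects[i]) for i in true_idx},
        state_dependent={ids[i] for i in state_idx},
        baseline={ids[i]: float(baseline[i]) for i in range(params.n_proteins)},
        dropout_probabilities={"pulldown": prob},
    )
    return table, design, truth


def generate_coip(
    params: SimParams,
    truth: SyntheticTruth,
) -> tuple[ProteinQuantTable, StudyDesign]:
    """Simulate the co-IP validation experiment for the same protein panel.

    True interactors keep their pulldown effects, attenuated by
    ``coip_attenuation``; a configurable fraction of them is additionally
    forced to low detection (kept in at most 2 of the bait samples) to
    exercise the scorer's exclusion tier. The chosen proteins are recorded
    in ``truth.coip_low_detection``.
    """
    seed = None if params.seed is None else params.seed + 104729
    rng = np.random.default_rng(seed)
    ids = sorted(truth.baseline)
    baseline = np.array([truth.baseline[p] for p in ids])
    effects = np.array([truth.assigned_log2fc.get(p, 0.0) for p in ids])
    n_s = params.n_coip_ctrl + params.n_coip_bait
    truth_mat = baseline[:, None] + np.zeros((len(ids), n_s))
    truth_mat[:, params.n_coip_ctrl:] += params.coip_attenuation * effects[:, None]
    log2_matrix = truth_mat + rng.normal(0.0, params.noise_sd, size=truth_mat.shape)
    mask, prob = _dropout(log2_matrix, params, rng)

    true_list = sorted(truth.true_interactors)
    n_low = int(round(params.coip_low_detection_frac * len(true_list)))
    low_det = set(
        rng.choice(true_list, size=n_low, replace=False).tolist() if n_low else []
    )
    keep_max = max(0, min(2, params.n_coip_bait - 1))
    for pid in low_det:
        r = ids.index(pid)
        bait_cols = np.arange(params.n_coip_ctrl, n_s)
        drop_cols = rng.choice(bait_cols, size=len(bait_cols) - keep_max, replace=False)
        mask[r, drop_cols] = True
    truth.coip_low_detection = low_det
    truth.dropout_probabilities["coip"] = prob

    sample_ids = [f"IGG_{i + 1}" for i in range(params.n_coip_ctrl)] + [
        f"COIP_{i + 1}" for i in range(params.n_coip_bait)
    ]
    design = StudyDesign(
        [SampleInfo(f"IGG_{i + 1}", Condition.IGG_CTRL, i + 1) for i in range(params.n_coip_ctrl)]
        + [SampleInfo(f"COIP_{i + 1}", Condition.COIP_BAIT, i + 1) for i in range(params.n_coip_bait)]
    )
    table = _to_linear_table(log2_matrix, mask, list(ids), sample_ids)
    return table, design


def generate_loading(
    params: SimParams,
    truth: SyntheticTruth,
) -> tuple[ProteinQuantTable, StudyDesign]:
    """Simulate paired GTPγS/GDPβS bait pulldowns.

    Both members of a pair share a per-lysate random effect (SD
    ``pair_effect_sd``) per protein; state-dependent interactors get
    ``state_effect`` added to the GTPγS member only. Residual noise is
    ``noise_sd`` per sample.
    """
    seed = None if params.seed is None else params.seed + 224737
    rng = np.random.default_rng(seed)
    ids = sorted(truth.baseline)
    baseline = np.array([truth.baseline[p] for p in ids])
    effects = np.array([truth.assigned_log2fc.get(p, 0.0) for p in ids])
    state = np.array([p in truth.state_dependent for p in ids], dtype=float)
    n_p = len(ids)
    n_s = 2 * params.n_pairs
    level = baseline + effects  # bait pulldown level in both loading states

    log2_matrix = np.empty((n_p, n_s))
    for k in range(params.n_pairs):
        lysate = rng.normal(0.0, params.pair_effect_sd, size=n_p)
        gtp = level + lysate + state * params.state_effect
        gdp = level + lysate
        log2_matrix[:, 2 * k] = gtp + rng.normal(0.0, params.noise_sd, size=n_p)
        log2_matrix[:, 2 * k + 1] = gdp + rng.normal(0.0, params.noise_sd, size=n_p)
    mask, prob = _dropout(log2_matrix, params, rng)
    truth.dropout_probabilities["loading"] = prob

    sample_ids: list[str] = []
    samples: list[SampleInfo] = []
    for k in range(params.n_pairs):
        g, d = f"GTPGS_{k + 1}", f"GDPBS_{k + 1}"
        sample_ids += [g, d]
        samples.append(SampleInfo(g, Condition.BAIT_GTPGS, k + 1, pair_id=f"L{k + 1}"))
        samples.append(SampleInfo(d, Condition.BAIT_GDPBS, k + 1, pair_id=f"L{k + 1}"))
    table = _to_linear_table(log2_matrix, mask, list(ids), sample_ids)
    return table, StudyDesign(samples)
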