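"""Calibration and recovery experiments run on the synthetic generator.

These are the package's standing benchmarks: false-positive calibration of
candidate selection under a global null, sensitivity/FDR with spiked
interactors, the sampling distribution of the MNAR imputation, paired
loading-shift recovery, and an end-to-end tier-recovery run. Both the test
suite and the reproduction script call these functions, so the numbers they
report are always recomputed from scratch.
"""

from __future__ import annotations

import numpy as np

from .core import Condition, ProteinQuantTable
from .credibility import score_candidates
from .enrichment import DifferentialEnrichment
from .loading import paired_delta
from .pipeline import PipelineConfig, preprocess_table
from .preprocess import ImputeParams, impute_mnar, log2_transform
from .simulate import SimParams, generate_coip, generate_loading, generate_pulldown

__all__ = [
    "run_enrichment_replicate",
    "null_calibration",
    "spike_recovery",
    "imputation_distribution",
    "loading_shift_recovery",
    "end_to_end_tier_recovery",
]


def _child_seeds(seed: int | None, n: int) -> list[int]:
    rng = np.random.default_rng(seed)
    return [int(s) for s in rng.integers(0, 2**31 - 1, size=n)]


def run_enrichment_replicate(params: SimParams, alpha: float = 0.01,
                             lfc_cut: float = 2.0) -> tuple[set, set]:
    """One pulldown simulation through the full pipeline; returns
    (selected protein ids, true interactor ids)."""
    table, design, truth = generate_pulldown(params)
    cfg = PipelineConfig(alpha=alpha, lfc_cut=lfc_cut)
    _, processed = preprocess_table(
        table, design, cfg, impute_seed=None if params.seed is None else params.seed + 1
    )
    res = DifferentialEnrichment(
        processed, design, Condition.BAIT_INTACT, Condition.GST_CTRL
    ).fit(alpha=alpha, lfc_cut=lfc_cut)
    return set(res.candidates["protein_id"]), truth.true_interactors


def null_calibration(n_reps: int = 500, seed: int | None = 0,
                     alpha: float = 0.01) -> dict:
    """Fraction of no-effect datasets yielding any selected candidate.

    Uses the default study design (6 vs 6) with ``frac_true = 0``; with the
    fold-change cut in place this fraction should be far below alpha.
    """
    datasets_with_fp = 0
    for s in _child_seeds(seed, n_reps):
        params = SimParams(frac_true=0.0, seed=s)
        selected, _ = run_enrichment_replicate(params, alpha=alpha)
        datasets_with_fp += bool(selected)
    return {"fp_dataset_rate": datasets_with_fp / n_reps, "n_reps": n_reps}


def spike_recovery(n_reps: int = 200, seed: int | None = 0,
                   effect: float = 4.0, noise_sd: float = 0.5) -> dict:
    """Sensitivity and observed FDR with fixed-size spiked interactors.

    Spikes all true interactors at the same log2 fold change (default 4)
    with replicate SD 0.5 on the default 6-vs-6 design.
    """
    tp = fp = fn = 0
    for s in _child_seeds(seed, n_reps):
        params = SimParams(effect_low=effect, effect_high=effect,
                           noise_sd=noise_sd, seed=s)
        selected, truth = run_enrichment_replicate(params)
        tp += len(selected & truth)
        fp += len(selected - truth)
        fn += len(truth - selected)
    sensitivity = tp / (tp + fn) if tp + fn else float("nan")
    fdr = fp / (tp + fp) if tp + fp else 0.0
    return {"sensitivity": sensitivity, "fdr": fdr, "n_reps": n_reps}


def imputation_distribution(n_draws: int = 100_000, mu: float = 25.0,
                            sd: float = 2.0, seed: int | None = 0) -> dict:
    """Empirical mean/SD of imputed values for a sample with known moments.

    The observed values are constructed to have exactly the requested mean
    and (sample) SD, so the imputation distribution is exactly
    Normal(mu - 1.8 sd, (0.3 sd)^2).
    """
    n_obs = 100
    obs = np.linspace(-1.0, 1.0, n_obs)
    obs = (obs - obs.mean()) / obs.std(ddof=1) * sd + mu
    n_rows = n_obs + n_draws
    values = np.full((n_rows, 2), mu)
    missing = np.zeros((n_rows, 2), dtype=bool)
    values[:n_obs, 1] = obs
    values[n_obs:, 1] = np.nan
    missing[n_obs:, 1] = True
    table = ProteinQuantTable(
        protein_ids=[f"P{i}" for i in range(n_rows)],
        intensities=values,
        sample_ids=["FULL", "TARGET"],
        missing_mask=missing,
        scale_tag="log2",
    )
    out = impute_mnar(table, ImputeParams(seed=seed))
    draws = out.intensities[n_obs:, 1]
    return {
        "mean": float(draws.mean()),
        "sd": float(draws.std(ddof=1)),
        "expected_mean": mu - 1.8 * sd,
        "expected_sd": 0.3 * sd,
        "n_draws": n_draws,
    }


def loading_shift_recovery(n_reps: int = 1000, seed: int | None = 0,
                           shift: float = 0.785, noise_sd: float = 0.1,
                           n_pairs: int = 3) -> dict:
    """Replicate-averaged recovery of a paired nucleotide-state shift."""
    estimates = []
    for s in _child_seeds(seed, n_reps):
        params = SimParams(
            n_proteins=40, frac_true=0.5, frac_state_dependent=1.0,
            state_effect=shift, noise_sd=noise_sd, pair_effect_sd=0.3,
            n_pairs=n_pairs, mnar_mid=-1e6, mnar_slope=100.0, seed=s,
        )
        _, _, truth = generate_pulldown(params)
        table, design = generate_loading(params, truth)
        res = paired_delta(log2_transform(table), design, sorted(truth.state_dependent))
        estimates.append(float(res["log2_delta_fc"].mean()))
    return {"mean_delta": float(np.mean(estimates)), "true_delta": shift, "n_reps": n_reps}


def end_to_end_tier_recovery(n_reps: int = 25, seed: int | None = 0) -> dict:
    """Pulldown + co-IP pipeline recovery of fully detected interactors.

    Effects >= 3 log2 units, no dropout, no co-IP attenuation: the fraction
    of true interactors ending in the satisfactory-or-better tiers.
    """
    rates = []
    for s in _child_seeds(seed, n_reps):
        params = SimParams(
            n_proteins=300, frac_true=0.2, effect_low=3.0, effect_high=6.0,
            mnar_mid=-1e6, mnar_slope=100.0, coip_low_detection_frac=0.0,
            coip_attenuation=1.0, seed=s,
        )
        table, design, truth = generate_pulldown(params)
        cfg = PipelineConfig()
        _, processed = preprocess_table(table, design, cfg, impute_seed=s + 1)
        res = DifferentialEnrichment(
            processed, design, Condition.BAIT_INTACT, Condition.GST_CTRL
        ).fit()
        selected = res.candidates["protein_id"].tolist()
        coip, coip_design = generate_coip(params, truth)
        records, _, _ = score_candidates(selected, log2_transform(coip), coip_design)
        good = records["category"].isin(["satisfactory", "high_credibility"])
        credible = set(records.loc[good, "protein_id"])
        rates.append(len(credible & truth.true_interactors) / len(truth.true_interactors))
    return {"tier_recovery": float(np.mean(rates)), "n_reps": n_reps}
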