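"""Preprocessing: log2 transform, detection filtering, MNAR imputation,
normalization and row standardisation.

The imputation follows the Perseus-style "missing not at random" convention:
missing cells of sample *j* are drawn from a Gaussian shifted 1.8 observed
standard deviations below the sample's observed mean, with width 0.3 observed
standard deviations — emulating the left-censored tail that intensity-dependent
dropout removes from LFQ data.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .core import Condition, DesignError, ProteinQuantTable, StudyDesign

__all__ = [
    "FilterParams",
    "ImputeParams",
    "log2_transform",
    "filter_by_detection",
    "impute_mnar",
    "normalize",
    "zscore_rows",
]


@dataclass
class FilterParams:
    """Detection-based filtering thresholds (inclusive minima, as fractions)."""

    min_frac_global: float = 0.0
    min_frac_one_condition: float = 0.60

    def __post_init__(self) -> None:
        for name in ("min_frac_global", "min_frac_one_condition"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")


@dataclass
class ImputeParams:
    """Left-shifted Gaussian imputation parameters (in units of observed SD)."""

    shift_sd: float = 1.8
    width_sd: float = 0.3
    seed: Optional[int] = None
    per_sample: bool = True  # Perseus convention; False pools all observed values

    def __post_init__(self) -> None:
        if self.width_sd < 0:
            raise ValueError("width_sd must be >= 0")


def log2_transform(table: ProteinQuantTable) -> ProteinQuantTable:
    """Convert linear MaxLFQ intensities to log2; missing entries stay missing."""
    if table.scale_tag == "log2":
        raise ValueError("table is already on the log2 scale (double transform)")
    out = table.copy()
    values = out.intensities
    obs = ~out.missing_mask
    values[obs] = np.log2(values[obs])
    values[out.missing_mask] = np.nan
    out.scale_tag = "log2"
    return out


def filter_by_detection(
    table: ProteinQuantTable,
    design: StudyDesign,
    params: FilterParams | None = None,
) -> ProteinQuantTable:
    """Keep proteins detected often enough.

    A protein is retained iff its non-missing fraction over all samples is
    >= ``min_frac_global`` AND its non-missing fraction within at least one
    condition is >= ``min_frac_one_condition``. Both comparisons are
    inclusive; row order is preserved.
    """
    params = params or FilterParams()
    if len(design) == 0:
        raise DesignError("empty design")
    design.validate_against(table)
    detected = ~table.missing_mask
    frac_global = detected.mean(axis=1)
    keep = frac_global >= params.min_frac_global
    any_cond = np.zeros(table.n_proteins, dtype=bool)
    for cond in design.conditions:
        cols = [table.col_index(s) for s in design.samples_in(cond) if s in table.sample_ids]
        if not cols:
            continue
        frac = detected[:, cols].mean(axis=1)
        any_cond |= frac >= params.min_frac_one_condition
    keep &= any_cond
    return table.subset_proteins(keep)


def impute_mnar(table: ProteinQuantTable, params: ImputeParams | None = None) -> ProteinQuantTable:
    """Impute missing log2 values from a left-shifted Gaussian.

    For sample *j* with observed mean ``mu_j`` and (sample) standard
    deviation ``sd_j``, each missing cell is an independent draw from
    ``Normal(mu_j - shift_sd * sd_j, (width_sd * sd_j)**2)``. Deterministic
    given ``params.seed``; observed cells are never altered.
    """
    params = params or ImputeParams()
    if table.scale_tag != "log2":
        raise ValueError("impute_mnar requires a log2-scale table")
    out = table.copy()
    rng = np.random.default_rng(params.seed)
    obs_mask = ~out.missing_mask

    if not params.per_sample:
        pooled = out.intensities[obs_mask]
        if pooled.size < 2:
            raise ValueError("fewer than 2 observed values in the whole table")
        g_mu, g_sd = float(pooled.mean()), float(pooled.std(ddof=1))

    for j, sample in enumerate(out.sample_ids):
        miss = out.missing_mask[:, j]
        n_missing = int(miss.sum())
        if n_missing == 0:
            continue
        obs = out.intensities[obs_mask[:, j], j]
        if obs.size == 0:
            raise ValueError(f"sample {sample!r} has no observed values to impute from")
        if obs.size < 2:
            raise ValueError(
                f"sample {sample!r} has fewer than 2 observed values; cannot "
                f"estimate an imputation distribution"
            )
        if params.per_sample:
            mu, sd = float(obs.mean()), float(obs.std(ddof=1))
        else:
            mu, sd = g_mu, g_sd
        draws = rng.normal(mu - params.shift_sd * sd, params.width_sd * sd, size=n_missing)
        out.intensities[miss, j] = draws
    out.missing_mask[:] = False
    return out


def _vsn_like(values: np.ndarray) -> np.ndarray:
    # Per-sample affine calibration on rank-matched quantiles against the
    # pooled reference, then a glog/arsinh stabilisation shared by all
    # samples. The scale is fitted on lower quantiles (10th-50th) so that a
    # minority of strongly enriched proteins in the upper tail of a bait
    # sample cannot shrink the very fold changes being tested; monotone
    # within each sample, so ranks are preserved.
    n_p, n_s = values.shape
    sorted_vals = np.sort(values, axis=0)
    reference = sorted_vals.mean(axis=1)
    ref_med = np.quantile(reference, 0.5)
    ref_spread = ref_med - np.quantile(reference, 0.1)
    calibrated = np.empty_like(values)
    for j in range(n_s):
        x = values[:, j]
        med = np.quantile(x, 0.5)
        spread = med - np.quantile(x, 0.1)
        a = ref_spread / spread if spread > 0 and ref_spread > 0 else 1.0
        b = ref_med - a * med
        calibrated[:, j] = a * x + b
    # arsinh of the linear intensity, expressed in log2-like units
    linear = np.exp2(calibrated)
    return np.arcsinh(linear) / np.log(2.0)


def normalize(table: ProteinQuantTable, method: str = "vsn_like") -> ProteinQuantTable:
    """Between-sample normalization of a fully imputed log2 table.

    ``vsn_like``: robust per-sample scale-and-shift calibration fitted on
    rank-matched quantiles against the pooled reference, followed by an
    inverse-hyperbolic-sine variance stabilisation. ``median_center``:
    subtract each sample's median. ``none``: identity.
    """
    if table.scale_tag != "log2":
        raise ValueError("normalize expects a log2-scale table")
    if table.missing_mask.any():
        raise ValueError("normalize expects a fully imputed table (no missing cells)")
    out = table.copy()
    if method == "none":
        return out
    if method == "median_center":
        med = np.median(out.intensities, axis=0, keepdims=True)
        out.intensities = out.intensities - med
        return out
    if method == "vsn_like":
        if table.n_samples < 2:
            raise ValueError("vsn_like needs at least 2 samples")
        out.intensities = _vsn_like(out.intensities)
        return out
    raise ValueError(f"unknown normalization method {method!r}")


def zscore_rows(matrix: np.ndarray, ddof: int = 0) -> np.ndarray:
    """Standardise each row to mean 0 and SD 1 (population SD by default)."""
    matrix = np.asarray(matrix, dtype=float)
    mean = matrix.mean(axis=1, keepdims=True)
    sd = matrix.std(axis=1, ddof=ddof, keepdims=True)
    constant = np.flatnonzero(sd.ravel() == 0)
    if constant.size:
        raise ValueError(f"constant rows cannot be Z-scored: indices {constant.tolist()}")
    return (matrix - mean) / sd
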