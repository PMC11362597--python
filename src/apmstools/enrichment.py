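"""Empirical-Bayes moderated-t differential enrichment between two conditions.

Per protein, an ordinary two-group linear model gives the log2 fold change
and a pooled residual variance s^2 on d degrees of freedom. Across proteins
the variances are modelled as s^2 ~ s0^2 * chi^2_d / d with a scaled
inverse-chi-square prior on the true variances (prior df d0, prior value
s0^2); the hyperparameters are estimated by matching the first two moments
of log s^2 via digamma/trigamma inversion. The posterior variance

    s~^2 = (d0 * s0^2 + d * s^2) / (d0 + d)

replaces s^2 in the t statistic, which then has d + d0 degrees of freedom.
Benjamini–Hochberg step-up adjustment controls the FDR across proteins, and
candidates are selected at adjusted p < alpha and log2FC >= lfc_cut.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import special, stats

from .core import Condition, DesignError, ProteinQuantTable, StudyDesign

__all__ = [
    "EBayesPrior",
    "fit_group_contrast",
    "estimate_ebayes_prior",
    "moderated_t",
    "bh_adjust",
    "select_candidates",
    "DifferentialEnrichment",
    "EnrichmentResults",
]


@dataclass(frozen=True)
class EBayesPrior:
    """Scaled inverse-chi-square prior on residual variances."""

    d0: float      # prior degrees of freedom; may be math.inf
    s0sq: float    # prior variance

    def __post_init__(self) -> None:
        if not self.d0 > 0:
            raise ValueError("d0 must be positive (possibly infinite)")
        if not self.s0sq > 0:
            raise ValueError("s0sq must be positive")


def fit_group_contrast(
    table: ProteinQuantTable,
    design: StudyDesign,
    cond_a: "str | Condition",
    cond_b: "str | Condition",
) -> pd.DataFrame:
    """Per-protein two-group contrast: log2FC = mean(a) - mean(b).

    Returns a DataFrame with columns ``protein_id, gene, log2fc, avg_expr,
    s2, df_resid`` plus the group sizes as attributes ``n_a`` / ``n_b``.
    ``s2`` is the pooled within-group variance on ``n_a + n_b - 2`` df.
    """
    cond_a, cond_b = Condition.parse(cond_a), Condition.parse(cond_b)
    if table.missing_mask.any():
        raise ValueError("contrast requires an imputed table (no missing values)")
    cols_a = [table.col_index(s) for s in design.samples_in(cond_a) if s in table.sample_ids]
    cols_b = [table.col_index(s) for s in design.samples_in(cond_b) if s in table.sample_ids]
    if len(cols_a) < 2 or len(cols_b) < 2:
        raise DesignError(
            f"need >= 2 samples per condition; got {len(cols_a)} for "
            f"{cond_a.value} and {len(cols_b)} for {cond_b.value}"
        )
    a = table.intensities[:, cols_a]
    b = table.intensities[:, cols_b]
    n_a, n_b = a.shape[1], b.shape[1]
    log2fc = a.mean(axis=1) - b.mean(axis=1)
    ss = a.var(axis=1, ddof=1) * (n_a - 1) + b.var(axis=1, ddof=1) * (n_b - 1)
    df_resid = n_a + n_b - 2
    s2 = ss / df_resid
    out = pd.DataFrame(
        {
            "protein_id": table.protein_ids,
            "gene": table.gene_symbols,
            "log2fc": log2fc,
            "avg_expr": np.hstack([a, b]).mean(axis=1),
            "s2": s2,
            "df_resid": float(df_resid),
        }
    )
    out.attrs["n_a"] = n_a
    out.attrs["n_b"] = n_b
    return out


def _trigamma_inverse(x: float) -> float:
    # Newton iteration on trigamma(y) = x (monotone decreasing).
    if x > 1e7:
        return 1.0 / math.sqrt(x)
    if x < 1e-6:
        return 1.0 / x
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = float(special.polygamma(1, y))
        dif = tri * (1.0 - tri / x) / float(special.polygamma(2, y))
        y += dif
        if -dif / y < 1e-8:
            break
    return y


def estimate_ebayes_prior(
    variances: Sequence[float] | np.ndarray,
    dfs: "float | Sequence[float] | np.ndarray",
) -> EBayesPrior:
    """Moment-match (d0, s0^2) from observed residual variances.

    Works on log s^2: with e_g = log s^2_g - digamma(d_g/2) + log(d_g/2),
    the model implies E[e] = log s0^2 - digamma(d0/2) + log(d0/2) and
    Var[e] = trigamma(d0/2) + trigamma(d_g/2). When the empirical variance
    of e does not exceed the trigamma floor, d0 is infinite and s0^2 is the
    mean observed variance.
    """
    s2 = np.asarray(variances, dtype=float)
    d = np.broadcast_to(np.asarray(dfs, dtype=float), s2.shape).astype(float)
    ok = np.isfinite(s2) & (s2 > 0) & (d > 0)
    if ok.sum() < 2:
        raise ValueError("need at least 2 finite positive variances")
    s2, d = s2[ok], d[ok]
    z = np.log(s2)
    e = z - special.digamma(d / 2.0) + np.log(d / 2.0)
    emean = float(e.mean())
    evar = float(e.var(ddof=1)) - float(np.mean(special.polygamma(1, d / 2.0)))
    if evar > 0:
        half_d0 = _trigamma_inverse(evar)
        d0 = 2.0 * half_d0
        s0sq = math.exp(emean + float(special.digamma(half_d0)) - math.log(half_d0))
    else:
        d0 = math.inf
        s0sq = float(s2.mean())
    return EBayesPrior(d0=d0, s0sq=s0sq)


def moderated_t(
    contrasts: pd.DataFrame,
    prior: EBayesPrior,
    n_a: Optional[int] = None,
    n_b: Optional[int] = None,
) -> pd.DataFrame:
    """Add moderated t statistics and two-sided p-values to a contrast frame.

    ``prior.d0 = 0`` is accepted as the no-shrinkage limit (ordinary t);
    infinite ``d0`` gives full shrinkage (s~^2 = s0^2, normal reference).
    """
    n_a = n_a if n_a is not None else contrasts.attrs["n_a"]
    n_b = n_b if n_b is not None else contrasts.attrs["n_b"]
    s2 = contrasts["s2"].to_numpy(dtype=float)
    d = contrasts["df_resid"].to_numpy(dtype=float)
    d0, s0sq = prior.d0, prior.s0sq
    if math.isinf(d0):
        s2_post = np.full_like(s2, s0sq)
        df_total = np.full_like(s2, np.inf)
    else:
        s2_post = (d0 * s0sq + d * s2) / (d0 + d)
        df_total = d + d0
    se = np.sqrt(s2_post * (1.0 / n_a + 1.0 / n_b))
    with np.errstate(divide="ignore", invalid="ignore"):
        t_mod = contrasts["log2fc"].to_numpy(dtype=float) / se
    p = np.where(
        np.isinf(df_total),
        2.0 * stats.norm.sf(np.abs(t_mod)),
        2.0 * stats.t.sf(np.abs(t_mod), df_total),
    )
    out = contrasts.copy()
    out["s2_post"] = s2_post
    out["t_mod"] = t_mod
    out["df_total"] = df_total
    out["p_value"] = np.clip(p, np.nextafter(0.0, 1.0), 1.0)
    out.attrs.update(contrasts.attrs)
    return out


def bh_adjust(p_values: Sequence[float] | np.ndarray) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, in input order.

    adj_(i) = min_{j >= i} ( p_(j) * n / j ), capped at 1.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("p_values must be a non-empty 1-D sequence")
    if np.any(~np.isfinite(p)) or np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p-values must lie in (0, 1]")
    n = p.size
    order = np.argsort(p, kind="stable")
    scaled = p[order] * n / np.arange(1, n + 1)
    adj_sorted = np.minimum.accumulate(scaled[::-1])[::-1]
    adj = np.empty(n)
    adj[order] = np.minimum(adj_sorted, 1.0)
    return adj


def select_candidates(
    results: pd.DataFrame,
    alpha: float = 0.01,
    lfc_cut: float = 2.0,
    direction: str = "bait_enriched",
) -> pd.DataFrame:
    """Significant candidates at adjusted p < alpha and the fold-change cut.

    ``bait_enriched`` requires log2fc >= lfc_cut (one-directional, the
    reported convention); ``both`` uses \\|log2fc\\| >= lfc_cut.
    """
    if "adj_p" not in results.columns:
        raise ValueError("results lack adj_p; run bh_adjust first")
    lfc = results["log2fc"]
    if direction == "bait_enriched":
        fc_ok = lfc >= lfc_cut
    elif direction == "both":
        fc_ok = lfc.abs() >= lfc_cut
    else:
        raise ValueError(f"unknown direction {direction!r}")
    return results[(results["adj_p"] < alpha) & fc_ok].copy()


class DifferentialEnrichment:
    """Two-group differential-enrichment model on an imputed log2 table.

    Parameters
    ----------
    table
        Fully imputed log2-scale :class:`ProteinQuantTable`.
    design
        :class:`StudyDesign` assigning every table sample a condition.
    cond_a, cond_b
        The enriched (bait) and reference (control) conditions; log2FC is
        ``mean(cond_a) - mean(cond_b)``.
    """

    def __init__(
        self,
        table: ProteinQuantTable,
        design: StudyDesign,
        cond_a: "str | Condition",
        cond_b: "str | Condition",
    ):
        self.table = table
        self.design = design
        self.cond_a = Condition.parse(cond_a)
        self.cond_b = Condition.parse(cond_b)

    @classmethod
    def from_frames(
        cls,
        intensities: pd.DataFrame,
        design: StudyDesign,
        cond_a: "str | Condition",
        cond_b: "str | Condition",
        scale_tag: str = "log2",
    ) -> "DifferentialEnrichment":
        """Build from a proteins-x-samples DataFrame (no missing values)."""
        values = intensities.to_numpy(dtype=float)
        table = ProteinQuantTable(
            protein_ids=[str(i) for i in intensities.index],
            intensities=values,
            sample_ids=[str(c) for c in intensities.columns],
            missing_mask=np.zeros_like(values, dtype=bool),
            scale_tag=scale_tag,
        )
        return cls(table, design, cond_a, cond_b)

    def fit(
        self,
        alpha: float = 0.01,
        lfc_cut: float = 2.0,
        direction: str = "bait_enriched",
        prior: Optional[EBayesPrior] = None,
    ) -> "EnrichmentResults":
        contrasts = fit_group_contrast(self.table, self.design, self.cond_a, self.cond_b)
        if prior is None:
            prior = estimate_ebayes_prior(
                contrasts["s2"].to_numpy(), contrasts["df_resid"].to_numpy()
            )
        frame = moderated_t(contrasts, prior)
        frame["adj_p"] = bh_adjust(frame["p_value"].to_numpy())
        lfc = frame["log2fc"]
        fc_ok = lfc >= lfc_cut if direction == "bait_enriched" else lfc.abs() >= lfc_cut
        frame["significant"] = (frame["adj_p"] < alpha) & fc_ok
        return EnrichmentResults(
            model=self, frame=frame, prior=prior,
            alpha=alpha, lfc_cut=lfc_cut, direction=direction,
        )


class EnrichmentResults:
    """Fitted differential-enrichment results.

    Attributes
    ----------
    frame
        Per-protein table: log2fc, avg_expr, s2, s2_post, t_mod, df_total,
        p_value, adj_p, significant.
    prior
        The :class:`EBayesPrior` used for shrinkage.
    """

    def __init__(self, model, frame: pd.DataFrame, prior: EBayesPrior,
                 alpha: float, lfc_cut: float, direction: str):
        self.model = model
        self.frame = frame
        self.prior = prior
        self.alpha = alpha
        self.lfc_cut = lfc_cut
        self.direction = direction

    @property
    def candidates(self) -> pd.DataFrame:
        return select_candidates(self.frame, self.alpha, self.lfc_cut, self.direction)

    def volcano_coords(self) -> pd.DataFrame:
        """(log2fc, -log10 adjusted p) coordinates for a volcano plot."""
        return pd.DataFrame(
            {
                "protein_id": self.frame["protein_id"],
                "log2fc": self.frame["log2fc"],
                "neg_log10_adj_p": -np.log10(self.frame["adj_p"]),
                "significant": self.frame["significant"],
            }
        )

    def summary(self, top: int = 10) -> str:
        n_sig = int(self.frame["significant"].sum())
        d0 = "inf" if math.isinf(self.prior.d0) else f"{self.prior.d0:.3f}"
        lines = [
            "Differential enrichment (empirical-Bayes moderated t)",
            "=" * 56,
            f"contrast:        {self.model.cond_a.value} - {self.model.cond_b.value}",
            f"proteins tested: {len(self.frame)}",
            f"prior:           d0 = {d0}, s0^2 = {self.prior.s0sq:.5f}",
            f"selection:       adj_p < {self.alpha}, log2FC cut {self.lfc_cut} ({self.direction})",
            f"candidates:      {n_sig}",
            "",
            f"top {min(top, len(self.frame))} by adjusted p:",
        ]
        cols = ["protein_id", "gene", "log2fc", "t_mod", "p_value", "adj_p", "significant"]
        head = self.frame.sort_values(["adj_p", "p_value"]).head(top)[cols]
        lines.append(head.to_string(index=False, float_format=lambda v: f"{v:.3g}"))
        return "\n".join(lines)
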