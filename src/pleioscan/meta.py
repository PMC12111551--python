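"""Fixed-effect inverse-variance-weighted (IVW) cross-disorder meta-analysis.

Each screen combines exactly two studies: one cancer GWAS and one
autoimmune/autoinflammatory GWAS whose betas have been sign-reversed.
Under the fixed-effect model with weights :math:`w_i = 1/se_i^2`,

.. math::

    \\hat\\beta = \\frac{w_a \\beta_a + w_b \\beta_b}{w_a + w_b},
    \\qquad se(\\hat\\beta) = (w_a + w_b)^{-1/2},
    \\qquad Z = \\hat\\beta / se(\\hat\\beta),

and Cochran's heterogeneity statistic

.. math::

    Q = w_a(\\beta_a - \\hat\\beta)^2 + w_b(\\beta_b - \\hat\\beta)^2

is referred to a chi-square distribution with k-1 = 1 degree of freedom.

A SNP survives the screen when, jointly: both original per-trait p-values
are below ``p_trait_max``; the heterogeneity p is at least ``p_het_min``;
and the combined p is below ``p_meta_max``. Because one study is
sign-reversed, joint retention implies the original allelic effects ran in
opposite directions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import StateError
from .sumstats import HarmonizedPair


@dataclass
class ScreenConfig:
    """Thresholds and tuning parameters of the cross-disorder screen.

    Defaults are the screen's operating point: per-trait inclusion at
    p < 1e-3, combined genome-wide significance at p < 5e-8, exclusion of
    heterogeneous SNPs at Cochran's Q p < 0.05, QC at MAF >= 0.5% and
    imputation quality >= 0.3, lead-SNP clumping at r^2 = 0.1 with LD
    blocks merged within 1 Mb, and expression prioritization at
    Spearman's rho > 0.5.
    """

    p_trait_max: float = 1e-3
    p_meta_max: float = 5e-8
    p_het_min: float = 0.05
    maf_min: float = 0.005
    info_min: float = 0.3
    r2_lead: float = 0.1
    merge_distance: int = 1_000_000
    rho_min: float = 0.5

    def __post_init__(self):
        for name in ("p_trait_max", "p_meta_max", "p_het_min"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ValueError(f"{name} must be in (0, 1], got {v}")
        if not 0 <= self.r2_lead <= 1:
            raise ValueError("r2_lead must be in [0, 1]")
        if not 0 <= self.rho_min <= 1:
            raise ValueError("rho_min must be in [0, 1]")
        if self.merge_distance < 0:
            raise ValueError("merge_distance must be non-negative")


def _check_se(*ses):
    for se in ses:
        arr = np.asarray(se, dtype=float)
        if np.any(~(arr > 0)):
            raise ValueError("standard errors must be strictly positive")


def ivw_meta(beta_a, se_a, beta_b_flipped, se_b):
    """Combine two per-study estimates under the fixed-effect IVW model.

    Accepts scalars or arrays (broadcast elementwise). Returns
    ``(beta_meta, se_meta, z, p_meta)`` with a two-sided p computed via the
    normal survival function, which stays accurate deep into the tail
    (p-values below 1e-300 are representable).
    """
    _check_se(se_a, se_b)
    beta_a = np.asarray(beta_a, dtype=float)
    beta_b = np.asarray(beta_b_flipped, dtype=float)
    w_a = 1.0 / np.square(np.asarray(se_a, dtype=float))
    w_b = 1.0 / np.square(np.asarray(se_b, dtype=float))
    beta_meta = (w_a * beta_a + w_b * beta_b) / (w_a + w_b)
    se_meta = 1.0 / np.sqrt(w_a + w_b)
    z = beta_meta / se_meta
    p_meta = 2.0 * stats.norm.sf(np.abs(z))
    # z exactly 0 -> two-sided p of 1, not 1.0000000000000002
    p_meta = np.minimum(p_meta, 1.0)
    if beta_meta.ndim == 0:
        return float(beta_meta), float(se_meta), float(z), float(p_meta)
    return beta_meta, se_meta, z, p_meta


def cochran_q(beta_a, se_a, beta_b_flipped, se_b, beta_meta):
    """Cochran's Q for two studies against their combined estimate.

    Returns ``(q, p_het)`` with the p-value from the upper tail of the
    chi-square distribution with one degree of freedom.
    """
    _check_se(se_a, se_b)
    beta_a = np.asarray(beta_a, dtype=float)
    beta_b = np.asarray(beta_b_flipped, dtype=float)
    beta_meta = np.asarray(beta_meta, dtype=float)
    w_a = 1.0 / np.square(np.asarray(se_a, dtype=float))
    w_b = 1.0 / np.square(np.asarray(se_b, dtype=float))
    q = w_a * np.square(beta_a - beta_meta) + w_b * np.square(beta_b - beta_meta)
    p_het = stats.chi2.sf(q, df=1)
    if q.ndim == 0:
        return float(q), float(p_het)
    return q, p_het


def _direction(beta_a, beta_b_original):
    """Two-character direction string on the ORIGINAL trait scales."""
    sa = np.where(beta_a > 0, "+", np.where(beta_a < 0, "-", "0"))
    sb = np.where(beta_b_original > 0, "+", np.where(beta_b_original < 0, "-", "0"))
    return np.char.add(sa.astype(str), sb.astype(str))


def screen_pair(pair: HarmonizedPair, config: ScreenConfig | None = None
                ) -> tuple[pd.DataFrame, dict]:
    """Run the full per-SNP screen on one harmonized, sign-flipped pair.

    Filter order: per-trait p filter first, then IVW meta-analysis and
    Cochran's Q on the survivors, then the heterogeneity and combined
    significance filters. The retained set is order-invariant; the stage
    counts in the report are specific to this order.

    Returns the table of retained meta records (with a ``direction``
    column giving the allelic effect signs on the original trait scales)
    and a dict of per-stage counts.

    Raises
    ------
    StateError
        If the autoimmune sign reversal has not been applied to trait B.
    """
    if config is None:
        config = ScreenConfig()
    if not pair.b_flipped:
        raise StateError(
            "screen_pair requires the autoimmune sign reversal "
            "(flip_sign) to have been applied to trait B")
    df = pair.df
    report = {"n_input": len(df)}

    both_nominal = (df["p_a"] < config.p_trait_max) & (df["p_b"] < config.p_trait_max)
    report["n_both_traits_nominal"] = int(both_nominal.sum())
    df = df[both_nominal].copy()
    if df.empty:
        report["n_retained"] = 0
        return df.assign(beta_meta=[], se_meta=[], z=[], p_meta=[],
                         mlog10_p_meta=[], q=[], p_het=[], direction=[]), report

    beta_meta, se_meta, z, p_meta = ivw_meta(
        df["beta_a"].to_numpy(), df["se_a"].to_numpy(),
        df["beta_b"].to_numpy(), df["se_b"].to_numpy())
    q, p_het = cochran_q(
        df["beta_a"].to_numpy(), df["se_a"].to_numpy(),
        df["beta_b"].to_numpy(), df["se_b"].to_numpy(), beta_meta)
    df["beta_meta"], df["se_meta"], df["z"], df["p_meta"] = beta_meta, se_meta, z, p_meta
    # -log10 p computed in log space: still ranks SNPs whose p underflows
    df["mlog10_p_meta"] = -(np.log(2.0) + stats.norm.logsf(np.abs(z))) / np.log(10.0)
    df["q"], df["p_het"] = q, p_het
    df["direction"] = _direction(df["beta_a"].to_numpy(), -df["beta_b"].to_numpy())

    homogeneous = df["p_het"] >= config.p_het_min
    report["n_homogeneous"] = int(homogeneous.sum())
    significant = homogeneous & (df["p_meta"] < config.p_meta_max)
    report["n_retained"] = int(significant.sum())
    return df[significant].reset_index(drop=True), report
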