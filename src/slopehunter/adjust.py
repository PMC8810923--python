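"""Bias-adjusted SNP-outcome associations and the DHO comparator.

Given the correction factor b₁, every conditional association is de-biased
as ``beta_adj = beta_P - b1 * beta_I`` — the residual of the observed
association from the collider-bias line — with a propagated standard error
and two-sided Wald p-value.  The regression-based comparator (DHO) estimates
a single slope over *all* SNPs by ordinary least squares, with the
Hedges-Olkin correction for regression dilution dividing out the
measurement-error share of var(β̂_I).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .selection import EstimationError, wald_pvalue

#: column layout of the side-by-side comparison report
REPORT_COLUMNS = [
    "snp", "ea", "oa", "beta_I", "se_I",
    "beta_unadj", "se_unadj", "p_unadj",
    "beta_adj", "se_adj", "p_adj", "method",
]


@dataclass
class DhoFit:
    """OLS slope of β̂'_P on β̂_I with Hedges-Olkin dilution correction.

    ``b_raw`` is the uncorrected slope, ``b_ho`` divides by
    ``var(beta_I) - mean(se_I**2)`` — the noise-free variance of the
    regressor — and is the comparator's correction factor.
    """

    b_raw: float
    b_ho: float
    mean_sI2: float
    n_snps: int


def adjust_associations(harmonised: pd.DataFrame, b1: float,
                        se_b1: float = 0.0,
                        se_mode: str = "propagate",
                        method: str = "SH") -> pd.DataFrame:
    """De-bias all conditional associations with a fitted slope.

    ``se_mode='propagate'`` (default) uses independent-error propagation
    ``sqrt(se_P**2 + b1**2 * se_I**2)``; ``'propagate+slope'`` additionally
    carries the slope's own uncertainty,
    ``sqrt(se_P**2 + b1**2*se_I**2 + beta_I**2*se_b1**2)``.
    """
    if not np.isfinite(b1):
        raise ValueError("b1 must be finite")
    if se_mode not in ("propagate", "propagate+slope"):
        raise ValueError(f"unknown se_mode {se_mode!r}")
    beta_i = harmonised["beta_I"].to_numpy(dtype=float)
    se_i = harmonised["se_I"].to_numpy(dtype=float)
    beta_p = harmonised["beta_P"].to_numpy(dtype=float)
    se_p = harmonised["se_P"].to_numpy(dtype=float)

    beta_adj = beta_p - b1 * beta_i
    var_adj = se_p**2 + b1**2 * se_i**2
    if se_mode == "propagate+slope":
        var_adj = var_adj + beta_i**2 * se_b1**2
    se_adj = np.sqrt(var_adj)

    out = pd.DataFrame({
        "snp": harmonised["snp"],
        "beta_adj": beta_adj,
        "se_adj": se_adj,
        "p_adj": wald_pvalue(beta_adj, se_adj) if len(beta_adj) else [],
        "method": method,
    })
    return out


def dho_estimate(harmonised: pd.DataFrame) -> DhoFit:
    """Regression-based estimate of the bias slope over all SNPs.

    No λ-selection is applied — the comparator regresses over every
    harmonised variant.  Raises when fewer than 3 SNPs are available or
    when the dilution-corrected denominator is not positive.
    """
    if len(harmonised) < 3:
        raise EstimationError("dho_estimate needs at least 3 SNPs")
    x = harmonised["beta_I"].to_numpy(dtype=float)
    y = harmonised["beta_P"].to_numpy(dtype=float)
    se_i = harmonised["se_I"].to_numpy(dtype=float)
    var_x = float(np.var(x, ddof=1))
    cov_xy = float(np.cov(x, y, ddof=1)[0, 1])
    mean_s2 = float(np.mean(se_i**2))
    denom = var_x - mean_s2
    if denom <= 0:
        raise EstimationError(
            "Hedges-Olkin dilution correction undefined: var(beta_I) "
            f"({var_x:.3g}) does not exceed mean se_I^2 ({mean_s2:.3g})")
    return DhoFit(b_raw=cov_xy / var_x, b_ho=cov_xy / denom,
                  mean_sI2=mean_s2, n_snps=len(x))


def compare_report(harmonised: pd.DataFrame,
                   b1_sh: float | None = None,
                   b1_dho: float | None = None,
                   se_b1_sh: float = 0.0,
                   se_mode: str = "propagate") -> pd.DataFrame:
    """Side-by-side unadjusted / SH-adjusted / DHO-adjusted table.

    One row per SNP and method with unadjusted and adjusted effect, SE and
    p-value columns; serialises losslessly through
    :func:`slopehunter.sumstats.write_sumstats`.
    """
    base_cols = [c for c in ("snp", "ea", "oa", "beta_I", "se_I") if c in harmonised.columns]
    frames = []
    methods: list[tuple[str, float | None, float]] = [("unadjusted", 0.0, 0.0)]
    if b1_sh is not None:
        methods.append(("SH", b1_sh, se_b1_sh))
    if b1_dho is not None:
        methods.append(("DHO", b1_dho, 0.0))
    for name, b1, se_b1 in methods:
        if harmonised.empty:
            continue
        adj = adjust_associations(harmonised, b1, se_b1, se_mode, method=name)
        block = harmonised[base_cols].copy()
        block["beta_unadj"] = harmonised["beta_P"].to_numpy()
        block["se_unadj"] = harmonised["se_P"].to_numpy()
        block["p_unadj"] = wald_pvalue(harmonised["beta_P"], harmonised["se_P"])
        block["beta_adj"] = adj["beta_adj"].to_numpy()
        block["se_adj"] = adj["se_adj"].to_numpy()
        block["p_adj"] = adj["p_adj"].to_numpy()
        block["method"] = name
        frames.append(block)
    if not frames:
        return pd.DataFrame(columns=REPORT_COLUMNS)
    out = pd.concat(frames, ignore_index=True)
    return out[[c for c in REPORT_COLUMNS if c in out.columns]]
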