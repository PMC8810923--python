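"""Performance metrics for bias-correction estimators on simulated studies.

Type-1 error is evaluated at p < 0.05 over the SNPs with no direct outcome
effect, reported both over all such SNPs (``GI.`` ∪ ``G..``) and over the
collider-bias-affected ``GI.`` cluster alone (the nulls in ``G..`` carry no
bias and dominate the average).  Power is reported over all outcome-causal
SNPs (``GIP`` ∪ ``G.P``) and over ``GIP``; the family-wise error rate is the
share of replicates with at least one Bonferroni-significant ``GI.`` SNP.
Bias and mean squared error are measured against the true direct effects.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .adjust import adjust_associations, dho_estimate
from .mixture import EMConfig, hunt_slope
from .selection import SelectionConfig
from .simulate import ScenarioConfig, SimulatedStudy, preset_scenario, simulate

logger = logging.getLogger(__name__)

METHODS = ("unadjusted", "SH", "DHO")

_METRICS = [
    "type1_null_all", "type1_GI", "fwer_GI",
    "power_causal_all", "power_GIP",
    "mean_abs_bias", "mse", "mean_abs_bias_I", "mse_I",
    "slope_bias", "slope_est",
]


@dataclass
class MetricsReport:
    """Tidy per-method metrics, one row per (method, metric)."""

    table: pd.DataFrame
    n_replicates: int = 1
    seed: int | None = None

    def value(self, method: str, metric: str) -> float:
        sel = self.table[(self.table["method"] == method)
                         & (self.table["metric"] == metric)]
        if sel.empty:
            raise KeyError((method, metric))
        return float(sel["value"].iloc[0])


def evaluate(study: SimulatedStudy, adjusted: dict[str, pd.DataFrame],
             alpha: float = 0.05,
             slopes: dict[str, float] | None = None) -> MetricsReport:
    """Single-replicate metrics for each estimator's adjusted table.

    ``adjusted`` maps method name to a table with ``snp``, ``beta_adj``,
    ``se_adj``, ``p_adj`` (as produced by
    :func:`slopehunter.adjust.adjust_associations`); ``slopes`` optionally
    maps method name to its fitted correction factor so slope bias against
    the study's realised slope is reported.
    """
    truth = study.truth
    if "cluster" not in truth.columns:
        raise ValueError("study truth lacks cluster labels")
    cluster = truth["cluster"].to_numpy()
    beta_true = truth["beta_P_true"].to_numpy()
    m = len(truth)
    bonf = alpha / m

    null_all = np.isin(cluster, ("GI.", "G.."))
    gi = cluster == "GI."
    causal = np.isin(cluster, ("GIP", "G.P"))
    gip = cluster == "GIP"
    affected = np.isin(cluster, ("GI.", "GIP"))

    rows = []
    for method, table in adjusted.items():
        merged = truth[["snp"]].merge(table, on="snp", how="left")
        if merged["beta_adj"].isna().any():
            raise ValueError(f"adjusted table for {method!r} is missing SNPs")
        p = merged["p_adj"].to_numpy()
        err = merged["beta_adj"].to_numpy() - beta_true
        sig = p < alpha
        vals = {
            "type1_null_all": float(sig[null_all].mean()),
            "type1_GI": float(sig[gi].mean()),
            "fwer_GI": float((p[gi] < bonf).any()),
            "power_causal_all": float(sig[causal].mean()),
            "power_GIP": float(sig[gip].mean()),
            "mean_abs_bias": float(np.abs(err).mean()),
            "mse": float((err**2).mean()),
            "mean_abs_bias_I": float(np.abs(err[affected]).mean()),
            "mse_I": float((err[affected] ** 2).mean()),
        }
        if slopes and method in slopes and slopes[method] is not None:
            vals["slope_est"] = float(slopes[method])
            vals["slope_bias"] = float(slopes[method] - study.realized_slope)
        rows.extend({"method": method, "metric": k, "value": v}
                    for k, v in vals.items())
    return MetricsReport(table=pd.DataFrame(rows), n_replicates=1,
                         seed=study.seed)


def _adjusted_tables(study: SimulatedStudy, methods, lam, em_cfg,
                     se_mode="propagate"):
    """Fit each estimator on one replicate and adjust all SNPs."""
    ss = study.sumstats
    tables, slopes = {}, {}
    for method in methods:
        if method == "unadjusted":
            b1, se_b1 = 0.0, 0.0
        elif method == "SH":
            fit = hunt_slope(ss, SelectionConfig(lam=lam), em_cfg)
            b1, se_b1 = fit.b1, fit.se_b1 or 0.0
        elif method == "DHO":
            b1, se_b1 = dho_estimate(ss).b_ho, 0.0
        else:
            raise ValueError(f"unknown method {method!r}")
        mode = se_mode if method == "SH" else "propagate"
        tables[method] = adjust_associations(ss, b1, se_b1, se_mode=mode,
                                             method=method)
        slopes[method] = None if method == "unadjusted" else b1
    return tables, slopes


def run_replicate(cfg: ScenarioConfig, methods=METHODS, lam: float = 1e-3,
                  em_cfg: EMConfig | None = None, alpha: float = 0.05,
                  mode: str = "summary",
                  se_mode: str = "propagate") -> MetricsReport:
    """Simulate one replicate and evaluate every estimator on it."""
    em_cfg = em_cfg or EMConfig(bootstrap_B=0, seed=cfg.seed)
    study = simulate(cfg, mode=mode)
    tables, slopes = _adjusted_tables(study, methods, lam, em_cfg, se_mode)
    return evaluate(study, tables, alpha=alpha, slopes=slopes)


def run_grid(presets, rho_levels, methods=METHODS, n_replicates: int = 100,
             seed: int | None = 0, mode: str = "summary", lam: float = 1e-3,
             alpha: float = 0.05, scenario_kwargs: dict | None = None,
             bootstrap_B: int = 0,
             se_mode: str = "propagate") -> pd.DataFrame:
    """Scenario × rho_d × method evaluation grid.

    Runs ``n_replicates`` independently seeded replicates per cell and
    aggregates metric means with Monte-Carlo standard errors into a
    long-format table (columns: scenario, rho_d, method, metric, value,
    mc_se, n_reps, n_failed).  Replicate failures are logged and excluded.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    ss = np.random.SeedSequence(0 if seed is None else seed)
    out_rows = []
    for preset in presets:
        for rho in rho_levels:
            cell_ss = ss.spawn(1)[0]
            reps = []
            n_failed = 0
            for child in cell_ss.spawn(n_replicates):
                rep_seed = int(child.generate_state(1)[0] % (2**31))
                cfg = preset_scenario(preset, rho_d=rho, seed=rep_seed,
                                      **(scenario_kwargs or {}))
                try:
                    em_cfg = EMConfig(bootstrap_B=bootstrap_B, seed=rep_seed)
                    study = simulate(cfg, mode=mode)
                    tables, slopes = _adjusted_tables(study, methods, lam,
                                                      em_cfg, se_mode)
                    rep = evaluate(study, tables, alpha=alpha, slopes=slopes)
                except Exception as exc:   # noqa: BLE001 - replicate isolation
                    n_failed += 1
                    logger.warning("replicate failed (%s rho=%s seed=%d): %s",
                                   preset, rho, rep_seed, exc)
                    continue
                reps.append(rep.table)
            if not reps:
                logger.error("all replicates failed for %s rho=%s", preset, rho)
                continue
            stacked = pd.concat(reps)
            agg = (stacked.groupby(["method", "metric"])["value"]
                   .agg(value="mean",
                        mc_se=lambda v: v.std(ddof=1) / np.sqrt(len(v))
                        if len(v) > 1 else 0.0,
                        n_reps="count")
                   .reset_index())
            agg.insert(0, "scenario", preset)
            agg.insert(1, "rho_d", rho)
            agg["n_failed"] = n_failed
            out_rows.append(agg)
    if not out_rows:
        raise RuntimeError("no grid cell produced results")
    return pd.concat(out_rows, ignore_index=True)
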