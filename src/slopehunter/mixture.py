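"""Two-component bivariate Gaussian mixture for the correction factor.

The conditional-analysis estimates of SNPs associated with the conditioning
trait *I* fall into two clusters in the (β̂_I, β̂'_P) plane: variants
affecting *I* only, which lie on the line β̂'_P = b₁·β̂_I (the collider-bias
line), and variants with direct effects on both traits, which scatter about a
second line with slope b₁ + σ_IP/σ_I² and extra conditional variance σ_P² −
σ_IP²/σ_I².  This module fits that mixture by EM, identifies the *I*-only
component (the one explaining more variation in *I*), and returns its slope
b₁ — the factor by which conditional associations must be de-biased — with a
bootstrap standard error.

The *I*-only component's nominal covariance is rank-1 (all mass exactly on
the line), which has no density; a residual variance ``tau2`` about the line
— observed points carry sampling noise of order se_P² — regularises it while
preserving the mixture's structure.  The fit is parameterised conditionally
(two responsibility-weighted least-squares lines) which is algebraically
equivalent.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .selection import EstimationError, SelectionConfig, select_incidence_snps

logger = logging.getLogger(__name__)

_LOG2PI = float(np.log(2.0 * np.pi))


@dataclass
class EMConfig:
    """Settings of the EM fit and the bootstrap.

    ``eq12_faithful`` shares the marginal variance of β̂_I across the two
    components (the mixture's canonical form); disabling it frees one
    variance per component, which makes the "explains more variation in I"
    component-selection rule non-trivial.
    """

    max_iter: int = 5000
    tol: float = 1e-8
    n_restarts: int = 10
    seed: int | None = None
    eq12_faithful: bool = True
    bootstrap_B: int = 1000
    min_snps: int = 20
    tau2_floor_factor: float = 1e-3

    def __post_init__(self):
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")
        if self.bootstrap_B and self.bootstrap_B < 100:
            raise ValueError("bootstrap_B must be >= 100 (or 0 to disable)")


@dataclass
class MixtureParams:
    """Fitted mixture parameters, component 1 being the target (*I*-only) one.

    ``b1``/``tau2`` describe the target line and its residual variance;
    ``cov_IP`` and ``var_bP_direct`` are the second component's excess
    covariance and direct-effect variance, so its line slope is
    ``b1 + cov_IP/var_bI_2`` and its conditional variance
    ``tau2 + var_bP_direct - cov_IP**2/var_bI_2``.
    """

    b1: float
    pi1: float
    var_bI_1: float
    var_bI_2: float
    cov_IP: float
    var_bP_direct: float
    tau2: float

    @property
    def slope2(self) -> float:
        return self.b1 + self.cov_IP / self.var_bI_2

    @property
    def cond_var_2(self) -> float:
        return self.tau2 + self.var_bP_direct - self.cov_IP**2 / self.var_bI_2


@dataclass
class MixtureFit:
    """Result of the mixture fit.

    ``responsibilities`` are per-SNP posterior probabilities of the target
    component; ``loglik_trace`` is non-decreasing (within 1e-8).
    """

    params: MixtureParams
    responsibilities: np.ndarray
    loglik_trace: np.ndarray
    converged: bool
    n_iter: int
    n_snps: int
    target_component: int
    se_b1: float | None = None
    ci_b1: tuple[float, float] | None = None
    seed_state: int | None = None
    warnings: list[str] = field(default_factory=list)
    snp_ids: np.ndarray | None = None

    @property
    def b1(self) -> float:
        return self.params.b1

    def to_dict(self) -> dict:
        d = asdict(self.params)
        d.update(pi1=self.params.pi1, converged=bool(self.converged),
                 n_iter=int(self.n_iter), n_snps=int(self.n_snps),
                 loglik=float(self.loglik_trace[-1]),
                 se_b1=self.se_b1,
                 ci_b1=list(self.ci_b1) if self.ci_b1 is not None else None,
                 seed=self.seed_state, warnings=list(self.warnings))
        return d

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


# ---------------------------------------------------------------------------
# internal free-slope state: components are (slope_k, cond_var_k, var_x_k)
# ---------------------------------------------------------------------------

@dataclass
class _State:
    pi1: float
    slope: np.ndarray      # (2,)
    cond_var: np.ndarray   # (2,)
    var_x: np.ndarray      # (2,)


def _log_norm(z2_over_var, var):
    """log N(z; 0, var) given z**2/var precomputed-friendly pieces."""
    return -0.5 * (_LOG2PI + np.log(var) + z2_over_var)


def _component_logpdf(x, y, st: _State, k: int):
    rx = x * x / st.var_x[k]
    ry = (y - st.slope[k] * x) ** 2 / st.cond_var[k]
    return (_log_norm(rx, st.var_x[k]) + _log_norm(ry, st.cond_var[k]))


def _estep(x, y, st: _State):
    with np.errstate(divide="ignore"):   # pi1 of exactly 0 or 1 is legal here
        l1 = np.log(st.pi1) + _component_logpdf(x, y, st, 0)
        l2 = np.log1p(-st.pi1) + _component_logpdf(x, y, st, 1)
    m = np.maximum(l1, l2)
    ll = m + np.log(np.exp(l1 - m) + np.exp(l2 - m))
    gamma1 = np.exp(l1 - ll)
    return float(ll.sum()), gamma1


def _mstep(x, y, gamma1, st: _State, tau_floor, eq12_faithful):
    eps = 1e-300
    g = np.stack([gamma1, 1.0 - gamma1])
    pi1 = float(np.clip(gamma1.mean(), 1e-6, 1.0 - 1e-6))
    slope = st.slope.copy()
    cond_var = st.cond_var.copy()
    var_x = st.var_x.copy()
    if eq12_faithful:
        var_x[:] = max(float(np.mean(x * x)), eps)
    for k in range(2):
        wk = g[k]
        swk = wk.sum()
        if swk < 1e-12:          # empty component: keep previous line
            continue
        sxx = float(wk @ (x * x))
        if not eq12_faithful:
            var_x[k] = max(sxx / swk, eps)
        if sxx > 0:
            slope[k] = float(wk @ (x * y)) / sxx
        r = y - slope[k] * x
        cond_var[k] = max(float(wk @ (r * r)) / swk, tau_floor)
    return _State(pi1, slope, cond_var, var_x)


def _tls_slope(x, y):
    """Total-least-squares slope of a line through the origin."""
    m = np.array([[x @ x, x @ y], [x @ y, y @ y]])
    w, v = np.linalg.eigh(m)
    major = v[:, np.argmax(w)]
    if abs(major[0]) < 1e-30:
        return 0.0
    return float(major[1] / major[0])


def _ratio_spread(x, y):
    """Spread of per-SNP slope ratios y/x among well-determined points."""
    ax = np.abs(x)
    big = ax >= np.median(ax)
    if big.sum() < 2:
        big = ax > 0
    r = y[big] / x[big]
    s = float(np.std(r))
    return s if s > 0 else 0.1 * (abs(np.median(r)) + 1e-3)


def _run_em(x, y, st: _State, cfg: EMConfig, tau_floor):
    trace = []
    gamma1 = None
    converged = False
    ll_prev = -np.inf
    for it in range(cfg.max_iter):
        ll, gamma1 = _estep(x, y, st)
        if not np.isfinite(ll):
            bad = int(np.argmin(np.isfinite(
                _component_logpdf(x, y, st, 0) + _component_logpdf(x, y, st, 1))))
            raise FloatingPointError(
                f"non-finite mixture density (first offending SNP index {bad})")
        trace.append(ll)
        if ll - ll_prev < cfg.tol and it > 0:
            converged = True
            break
        ll_prev = ll
        st = _mstep(x, y, gamma1, st, tau_floor, cfg.eq12_faithful)
    return st, np.asarray(trace), gamma1, converged


def _extract_xy(selected: pd.DataFrame):
    x = selected["beta_I"].to_numpy(dtype=float)
    y = selected["beta_P"].to_numpy(dtype=float)
    if "se_P" in selected.columns:
        se_p2 = np.square(selected["se_P"].to_numpy(dtype=float))
    else:
        se_p2 = np.full_like(y, 1e-4 * max(float(np.var(y)), 1e-30))
    if "se_I" in selected.columns:
        se_i2 = np.square(selected["se_I"].to_numpy(dtype=float))
    else:
        se_i2 = np.zeros_like(x)
    return x, y, se_p2, se_i2


def _initial_states(x, y, se_p2, cfg: EMConfig, rng):
    b0 = _tls_slope(x, y)
    spread = _ratio_spread(x, y)
    tau0 = max(float(np.median(se_p2)), 1e-300)
    resid = y - b0 * x
    psi0 = max(float(np.mean(resid * resid)), 2.0 * tau0)
    vx = max(float(np.mean(x * x)), 1e-300)
    # candidate slopes from the per-SNP ratio distribution: two genuinely
    # distinct line clusters show up as separated ratio quantiles
    ax = np.abs(x)
    big = ax >= np.median(ax)
    ratios = y[big] / x[big] if big.any() else np.array([b0])
    q10, q25, q50, q75, q90 = np.quantile(ratios, [0.1, 0.25, 0.5, 0.75, 0.9])
    fixed = [(b0, b0 + spread), (b0, b0 - spread),
             (q25, q75), (q75, q25), (q50, q90), (q50, q10)]
    states = []
    for r in range(cfg.n_restarts):
        if r < len(fixed):
            b_init, s_init = fixed[r]
        else:
            b_init = b0 + spread * rng.normal()
            s_init = b0 + spread * rng.normal()
        states.append(_State(0.5,
                             np.array([b_init, s_init]),
                             np.array([tau0, psi0]),
                             np.array([vx, vx])))
    return states


def em_fit(selected: pd.DataFrame, cfg: EMConfig | None = None) -> MixtureFit:
    """Fit the two-component mixture to λ-selected summary statistics.

    Runs ``cfg.n_restarts`` seeded EM starts (slope initialised by
    total-least-squares through the origin, then jittered) and keeps the
    highest final log-likelihood.  Components are then relabelled so that
    component 1 is the target (*I*-only) cluster per
    :func:`select_target_component`.  Deterministic given ``cfg.seed``.
    """
    cfg = cfg or EMConfig()
    x, y, se_p2, se_i2 = _extract_xy(selected)
    n = x.size
    if n < cfg.min_snps:
        raise EstimationError(
            f"only {n} selected SNPs; need at least {cfg.min_snps}")
    if np.all(np.abs(x) < 1e-30):
        raise EstimationError("degenerate selection: all beta_I are ~0")
    tau_floor = cfg.tau2_floor_factor * max(float(np.median(se_p2)), 1e-300)
    rng = np.random.default_rng(cfg.seed)

    best = None
    for st0 in _initial_states(x, y, se_p2, cfg, rng):
        st, trace, gamma1, conv = _run_em(x, y, st0, cfg, tau_floor)
        if best is None or trace[-1] > best[1][-1]:
            best = (st, trace, gamma1, conv)
    st, trace, gamma1, converged = best
    if not converged:
        logger.warning("EM did not converge in %d iterations; best iterate kept",
                       cfg.max_iter)

    fit = _canonicalise(st, trace, gamma1, converged, n, cfg,
                        x, y, se_p2, se_i2)
    fit.snp_ids = selected["snp"].to_numpy() if "snp" in selected.columns else None
    return fit


def _canonicalise(st: _State, trace, gamma1, converged, n, cfg,
                  x=None, y=None, se_p2=None, se_i2=None) -> MixtureFit:
    warnings = []
    # unidentifiable fit: both components converged onto the same line (e.g.
    # all points exactly on one line) -> a single cluster absorbs all mass
    sd_x = float(np.sqrt(np.mean(st.var_x)))
    sep = abs(st.slope[0] - st.slope[1]) * sd_x
    cv_scale = float(np.sqrt(st.cond_var.max()))
    if sep < 1e-6 * cv_scale and abs(st.cond_var[0] - st.cond_var[1]) < 1e-6 * st.cond_var.max():
        warnings.append("components indistinguishable; merged into the target")
        st = _State(1.0 - 1e-6, st.slope.copy(), st.cond_var.copy(),
                    st.var_x.copy())
        gamma1 = np.ones_like(gamma1)
    target = select_target_component(
        np.array([st.pi1, 1.0 - st.pi1]), st.var_x, st.cond_var,
        x=x, y=y, se_p2=se_p2, se_i2=se_i2, slopes=st.slope,
        gamma1=gamma1, warnings=warnings)
    other = 1 - target
    pi_t = st.pi1 if target == 0 else 1.0 - st.pi1
    gam_t = gamma1 if target == 0 else 1.0 - gamma1
    v2 = float(st.var_x[other])
    cov_ip = (st.slope[other] - st.slope[target]) * v2
    var_bp = st.cond_var[other] - st.cond_var[target] + cov_ip**2 / v2
    if var_bp < 0:
        warnings.append("component-2 direct-effect variance clipped at 0")
        var_bp = 0.0
    params = MixtureParams(
        b1=float(st.slope[target]), pi1=float(pi_t),
        var_bI_1=float(st.var_x[target]), var_bI_2=v2,
        cov_IP=float(cov_ip), var_bP_direct=float(var_bp),
        tau2=float(st.cond_var[target]))
    return MixtureFit(params=params, responsibilities=gam_t,
                      loglik_trace=trace, converged=converged,
                      n_iter=len(trace), n_snps=n, target_component=target,
                      seed_state=cfg.seed, warnings=warnings)


#: median of a chi-square(1) variate, for the robust noise-consistency score
_CHI2_MEDIAN = 0.45493642311957174
#: weight of the log noise-inflation ratio against the log explained-variation
#: margin, and the conservatism offset the inflation evidence must clear
#: before the explained-variation pick is overridden
_CHI2_WEIGHT = 1.7
_SWITCH_MARGIN = 0.8


def select_target_component(pi, var_x, cond_var, x=None, y=None, se_p2=None,
                            se_i2=None, slopes=None, gamma1=None,
                            warnings=None) -> int:
    """Index of the component identified as the *I*-only cluster.

    The primary rule follows the method's identifying assumption: the
    *I*-only cluster explains more variation in *I* than any other class,
    so the target maximises ``pi_k`` times the component's β̂_I variance
    (the responsibility-weighted empirical variance when data are given).

    A second signature guards the regime where that assumption fails: a
    member of the *I*-only cluster scatters about its line by pure sampling
    noise (residual variance ``se_P**2 + slope**2 * se_I**2``), so the
    member-median squared standardised residual sits at the chi-square(1)
    median, whereas a both-trait cluster carries extra direct-effect
    variance.  The two signals are weighed on the log scale: the pick
    switches to the other component only when the weighted excess of its
    noise inflation clears the explained-variation margin plus a
    conservatism offset.  Residual variances below the sampling-noise level
    (a fitted line cannot genuinely beat the measurement error) earn no
    credit.

    Without data (parameters only) the rule is ``argmax pi_k * var_x_k``
    with ties broken toward the smaller conditional variance; an exact tie
    keeps component 1 with a warning.
    """
    pi = np.asarray(pi, dtype=float)
    if x is not None and gamma1 is not None and se_p2 is not None:
        if se_i2 is None:
            se_i2 = np.zeros_like(x)
        g = np.stack([gamma1, 1.0 - gamma1])
        v_emp = np.empty(2)
        chi2 = np.empty(2)
        for k in range(2):
            wsum = max(g[k].sum(), 1e-12)
            v_emp[k] = (g[k] @ (x * x)) / wsum
            z = (y - slopes[k] * x) ** 2 / (se_p2 + slopes[k] ** 2 * se_i2)
            members = g[k] >= 0.5
            if members.any():
                med = float(np.median(z[members]))
            else:
                med = _CHI2_MEDIAN * (g[k] @ z) / wsum
            chi2[k] = max(med / _CHI2_MEDIAN, 1e-12)
        piv = np.maximum(pi * v_emp, 1e-300)
        pref = int(np.argmax(piv))
        other = 1 - pref
        chi2c = np.maximum(chi2, 1.0)
        evidence = _CHI2_WEIGHT * (np.log(chi2c[pref]) - np.log(chi2c[other]))
        margin = np.log(piv[pref]) - np.log(piv[other])
        if evidence - _SWITCH_MARGIN > margin:
            if warnings is not None:
                warnings.append(
                    "explained-variation pick overridden by noise-consistency")
            return other
        return pref
    score = pi * np.asarray(var_x, dtype=float)
    rel = abs(score[0] - score[1]) / max(abs(score).max(), 1e-300)
    if rel > 1e-9:
        return int(np.argmax(score))
    if abs(cond_var[0] - cond_var[1]) > 1e-300 * max(cond_var):
        return int(np.argmin(cond_var))
    msg = "exact tie in target-component selection; keeping component 1"
    logger.warning(msg)
    if warnings is not None:
        warnings.append(msg)
    return 0


def loglikelihood(params: MixtureParams, selected: pd.DataFrame) -> float:
    """Observed-data log-likelihood of ``params`` on a selected table."""
    x, y, _, _ = _extract_xy(selected)
    st = _State(params.pi1,
                np.array([params.b1, params.slope2]),
                np.array([params.tau2, params.cond_var_2]),
                np.array([params.var_bI_1, params.var_bI_2]))
    ll, _ = _estep(x, y, st)
    if not np.isfinite(ll):
        raise FloatingPointError("non-finite mixture log-likelihood")
    return ll


def bootstrap_se(selected: pd.DataFrame, cfg: EMConfig,
                 point_fit: MixtureFit) -> tuple[float, tuple[float, float], float]:
    """Bootstrap SE and percentile CI of b̂₁.

    Resamples SNPs with replacement ``cfg.bootstrap_B`` times and refits the
    EM initialised at the point estimate (single start, warm).  Returns
    ``(se, (lo, hi), nonconv_frac)``; deterministic given ``cfg.seed``.
    """
    x, y, se_p2, se_i2 = _extract_xy(selected)
    n = x.size
    tau_floor = cfg.tau2_floor_factor * max(float(np.median(se_p2)), 1e-300)
    rng = np.random.default_rng(
        None if cfg.seed is None else (int(cfg.seed) + 0x5EED) % (2**31))
    p = point_fit.params
    warm = _State(p.pi1,
                  np.array([p.b1, p.slope2]),
                  np.array([p.tau2, p.cond_var_2]),
                  np.array([p.var_bI_1, p.var_bI_2]))
    boot_cfg = EMConfig(max_iter=min(cfg.max_iter, 500), tol=cfg.tol,
                        n_restarts=1, seed=cfg.seed,
                        eq12_faithful=cfg.eq12_faithful, bootstrap_B=0,
                        min_snps=2, tau2_floor_factor=cfg.tau2_floor_factor)
    b1s = np.empty(cfg.bootstrap_B)
    n_fail = 0
    for b in range(cfg.bootstrap_B):
        idx = rng.integers(0, n, n)
        xb, yb = x[idx], y[idx]
        st0 = _State(warm.pi1, warm.slope.copy(), warm.cond_var.copy(),
                     warm.var_x.copy())
        st, trace, gamma1, conv = _run_em(xb, yb, st0, boot_cfg, tau_floor)
        if not conv:
            n_fail += 1
        target = select_target_component(
            np.array([st.pi1, 1.0 - st.pi1]), st.var_x, st.cond_var,
            x=xb, y=yb, se_p2=se_p2[idx], se_i2=se_i2[idx],
            slopes=st.slope, gamma1=gamma1)
        b1s[b] = st.slope[target]
    se = float(np.std(b1s, ddof=1))
    ci = (float(np.percentile(b1s, 2.5)), float(np.percentile(b1s, 97.5)))
    frac = n_fail / cfg.bootstrap_B
    if frac > 0.05:
        logger.warning("bootstrap: %.1f%% of resample fits did not converge",
                       100 * frac)
    return se, ci, frac


def hunt_slope(harmonised: pd.DataFrame,
               selection_cfg: SelectionConfig | None = None,
               em_cfg: EMConfig | None = None) -> MixtureFit:
    """End-to-end correction-factor estimation.

    Pipeline: λ-selection of *I*-associated SNPs → EM mixture fit → target
    component identification → bootstrap SE (skipped when
    ``em_cfg.bootstrap_B == 0``).  The returned fit's ``b1`` is the
    collider-bias correction factor.
    """
    em_cfg = em_cfg or EMConfig()
    selected = select_incidence_snps(harmonised, selection_cfg)
    fit = em_fit(selected, em_cfg)
    if em_cfg.bootstrap_B:
        se, ci, frac = bootstrap_se(selected, em_cfg, fit)
        fit.se_b1, fit.ci_b1 = se, ci
        if frac > 0.05:
            fit.warnings.append(
                f"{100 * frac:.1f}% of bootstrap refits did not converge")
    return fit
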