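"""Generative model for conditional-GWAS collider-bias studies.

SNP effect sizes follow a four-cluster model: variants affecting only the
conditioning trait *I* (``GI.``), both traits (``GIP``, with direct-effect
correlation ``rho_d``), only the outcome (``G.P``) or neither (``G..``).
Both traits are quantitative with unit variance: a share ``h2_I``/``h2_P``
of variance is genetic, ``conf2`` comes from a shared non-genetic confounder
with positive loadings on both traits, and the remainder is idiosyncratic
noise.  Conditioning the outcome regression on *I* then induces a negative
bias, linear in the SNP's effect on *I*, in every *I*-affecting variant.

Two generation modes share a configuration and truth: ``individual`` draws
genotypes for ``n_individuals`` under Hardy-Weinberg equilibrium and runs
the per-SNP OLS regressions a GWAS would (I ~ G, and P ~ G + I); ``summary``
draws the estimated coefficients directly from their sampling distributions
(roughly two orders of magnitude faster, ignoring the small sampling
correlation between the two estimates).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

CLUSTERS = ("GI.", "GIP", "G.P", "G..")

#: (cluster_props, r2_I_split, mediated) per preset family
_PRESETS = {
    "sc1": ((0.05, 0.05, 0.05, 0.85), (0.35, 0.15), False),
    "sc2": ((0.05, 0.05, 0.05, 0.85), (0.25, 0.25), False),
    "sc3": ((0.05, 0.05, 0.05, 0.85), (0.15, 0.35), False),
    "s1": ((0.01, 0.09, 0.05, 0.85), (0.35, 0.15), False),
    "s2": ((0.01, 0.09, 0.05, 0.85), (0.25, 0.25), False),
    "s3": ((0.05, 0.05, 0.05, 0.85), (0.35, 0.15), True),
    "s4": ((0.05, 0.05, 0.05, 0.85), (0.15, 0.35), True),
}


class ConfigurationError(ValueError):
    pass


@dataclass
class ScenarioConfig:
    """Parameters of one simulated study.

    ``r2_I_split`` divides the heritability of *I* between the ``GI.`` and
    ``GIP`` clusters.  ``p_split`` does the same for the outcome between
    ``GIP`` and ``G.P``; by default it mirrors the *I* split (``GIP``
    explains the same share of *P* as of *I*, ``G.P`` takes the rest).
    ``rho_d`` is the correlation of the ``GIP`` direct effects on the two
    traits; under ``mediated`` those effects act through a single shared
    exposure and are perfectly correlated with the sign of ``rho_d``.
    """

    n_individuals: int = 20_000
    n_snps: int = 10_000
    cluster_props: tuple = (0.05, 0.05, 0.05, 0.85)
    r2_I_split: tuple = (0.25, 0.25)
    h2_I: float = 0.5
    h2_P: float = 0.5
    conf2: float = 0.40
    rho_d: float = 0.0
    p_split: tuple | None = None
    maf_range: tuple = (0.01, 0.49)
    mediated: bool = False
    beta_IP: float = 0.0
    seed: int | None = None
    name: str = "custom"

    def __post_init__(self):
        if abs(sum(self.cluster_props) - 1.0) > 1e-9:
            raise ConfigurationError("cluster_props must sum to 1")
        if abs(sum(self.r2_I_split) - self.h2_I) > 1e-9:
            raise ConfigurationError("r2_I_split must sum to h2_I")
        if not (-1.0 <= self.rho_d <= 1.0):
            raise ConfigurationError("rho_d must lie in [-1, 1]")
        if 1.0 - self.h2_I - self.conf2 <= 0 or 1.0 - self.h2_P - self.conf2 <= 0:
            raise ConfigurationError(
                "infeasible variance budget: genetic + confounder shares "
                "must leave a positive residual for both traits")
        if self.p_split is not None and abs(sum(self.p_split) - self.h2_P) > 1e-9:
            raise ConfigurationError("p_split must sum to h2_P")

    @property
    def effective_p_split(self) -> tuple:
        """(R² of GIP on P, R² of G.P on P); defaults mirror the I split."""
        if self.p_split is not None:
            return self.p_split
        r2_gip = min(self.r2_I_split[1], self.h2_P)
        return (r2_gip, self.h2_P - r2_gip)

    @property
    def cluster_counts(self) -> tuple:
        m = self.n_snps
        counts = [round(p * m) for p in self.cluster_props[:3]]
        counts.append(m - sum(counts))
        return tuple(counts)


@dataclass
class SimulatedStudy:
    """Ground truth plus estimated summary statistics for one replicate.

    ``truth`` has per-SNP maf, cluster label and true per-allele effects;
    ``sumstats`` is a harmonised-format table of per-SNP estimates.
    ``true_slope`` is the analytic population bias slope and
    ``realized_slope`` the regression of realised bias on estimated
    incidence effects over the *I*-affecting SNPs of this replicate.
    """

    config: ScenarioConfig
    truth: pd.DataFrame
    sumstats: pd.DataFrame
    true_slope: float
    realized_slope: float
    seed: int | None
    mode: str
    var_I: float | None = None
    var_P: float | None = None

    @property
    def cluster(self) -> pd.Series:
        return self.truth["cluster"]


def preset_scenario(name: str, rho_d: float | None = None,
                    seed: int | None = None, **overrides) -> ScenarioConfig:
    """Named study configurations.

    ``sc1``–``sc3`` are the main scenarios (equal 5%/5%/5%/85% clusters with
    the ``GI.`` cluster explaining more/equal/less of *I* than ``GIP``);
    ``s1``/``s2`` shrink the ``GI.`` cluster to 1% of SNPs against 9%
    ``GIP``; ``s3``/``s4`` route the ``GIP`` effects through a single shared
    exposure (perfect effect correlation; ``s4`` gives the exposure cluster
    the larger share of *I*, violating the zero-modal-residual assumption).
    ``fig5a``/``fig5b`` are the balanced configuration with uncorrelated and
    0.4-correlated direct effects.  A ``"name, rho 0.9"``-style spec is
    also accepted.
    """
    key = name.strip().lower()
    if "," in key:  # e.g. "sc1, rho 0.9"
        key, _, tail = key.partition(",")
        key = key.strip()
        tail = tail.replace("rho", "").replace("=", "").strip()
        if tail:
            rho_d = float(tail)
    if key == "fig5a":
        key, rho_d = "sc2", 0.0
        overrides.setdefault("name", "fig5a")
    elif key == "fig5b":
        key, rho_d = "sc2", 0.4
        overrides.setdefault("name", "fig5b")
    if key not in _PRESETS:
        raise ConfigurationError(
            f"unknown scenario {name!r}; known: {sorted(_PRESETS)} + fig5a/fig5b")
    props, split, mediated = _PRESETS[key]
    overrides.setdefault("name", key)
    return ScenarioConfig(cluster_props=props, r2_I_split=split,
                          mediated=mediated,
                          rho_d=0.0 if rho_d is None else rho_d,
                          seed=seed, **overrides)


# ---------------------------------------------------------------------------
# effect-size generation
# ---------------------------------------------------------------------------

def _rescale(v: np.ndarray, target_r2: float) -> np.ndarray:
    """Scale a vector of standardised effects so its summed squares hit
    ``target_r2`` exactly."""
    nrm = np.linalg.norm(v)
    if nrm == 0:
        return v
    return v * (np.sqrt(target_r2) / nrm)


def _draw_effects(cfg: ScenarioConfig, rng: np.random.Generator):
    """True standardised-scale effects per cluster (exact variance shares)."""
    m = cfg.n_snps
    n1, n2, n3, n4 = cfg.cluster_counts
    r2_gi, r2_gip = cfg.r2_I_split
    p2_gip, p2_gp = cfg.effective_p_split
    beta_i = np.zeros(m)
    beta_p = np.zeros(m)

    beta_i[:n1] = _rescale(rng.standard_normal(n1), r2_gi)
    s = slice(n1, n1 + n2)
    if cfg.mediated:
        u = rng.standard_normal(n2)
        sign = 1.0 if cfg.rho_d >= 0 else -1.0
        beta_i[s] = _rescale(u, r2_gip)
        beta_p[s] = sign * _rescale(u, p2_gip)
    else:
        # exact realised correlation: orthonormalise the two draws so the
        # sample correlation of the cluster's direct effects is rho_d itself
        # (same philosophy as the exact variance rescaling; it also makes
        # "uncorrelated direct effects" hold per run, not just on average)
        z1 = rng.standard_normal(n2)
        z2 = rng.standard_normal(n2)
        if n2 >= 2:
            u1 = z1 / np.linalg.norm(z1)
            e = z2 - (z2 @ u1) * u1
            u2 = e / np.linalg.norm(e)
            mix = cfg.rho_d * u1 + np.sqrt(1.0 - cfg.rho_d**2) * u2
        else:
            u1, mix = z1, z1
        beta_i[s] = _rescale(u1, r2_gip)
        beta_p[s] = _rescale(mix, p2_gip)
    beta_p[n1 + n2:n1 + n2 + n3] = _rescale(rng.standard_normal(n3), p2_gp)
    return beta_i, beta_p


def _truth_frame(cfg, maf, beta_i_std, beta_p_std, sd_g):
    n1, n2, n3, n4 = cfg.cluster_counts
    cluster = np.repeat(CLUSTERS, [n1, n2, n3, n4])
    return pd.DataFrame({
        "snp": [f"snp{i:06d}" for i in range(cfg.n_snps)],
        "maf": maf,
        "cluster": cluster,
        "beta_I_true": beta_i_std / sd_g,
        "beta_P_true": beta_p_std / sd_g,
    })


def _analytic_true_slope(cfg: ScenarioConfig, beta_i_std, beta_p_std,
                         cluster) -> float:
    """Population bias slope: minus the shared (confounder + GIP-genetic)
    covariance of the two traits over the variance of *I* left after the
    focal SNP (≈ 1)."""
    gip = cluster == "GIP"
    c_shared = float(beta_i_std[gip] @ beta_p_std[gip])
    return -(cfg.conf2 + c_shared)


def _attenuated_true_slope(cfg: ScenarioConfig, beta_i_std, beta_p_std,
                           cluster) -> float:
    """Expected regression of realised bias on *estimated* incidence effects
    over I-affecting SNPs: the population slope shrunk by the
    noise-in-regressor factor at this n and SNP count."""
    b_pop = _analytic_true_slope(cfg, beta_i_std, beta_p_std, cluster)
    aff = cluster != "G.P"
    aff &= cluster != "G.."
    s2 = float(np.sum(beta_i_std[aff] ** 2))
    noise = aff.sum() / cfg.n_individuals
    return b_pop * s2 / (s2 + noise)


def _realized_slope(truth: pd.DataFrame, sumstats: pd.DataFrame) -> float:
    """Regression through the origin of realised bias on β̂_I over the
    I-affecting SNPs (per-allele scale)."""
    aff = truth["cluster"].isin(["GI.", "GIP"]).to_numpy()
    x = sumstats["beta_I"].to_numpy()[aff]
    bias = (sumstats["beta_P"].to_numpy() - truth["beta_P_true"].to_numpy())[aff]
    sxx = float(x @ x)
    if sxx == 0:
        return 0.0
    return float(x @ bias) / sxx


def _sumstats_frame(truth, beta_i, se_i, beta_p, se_p, n):
    p_i = 2.0 * stats.norm.sf(np.abs(beta_i / se_i))
    p_p = 2.0 * stats.norm.sf(np.abs(beta_p / se_p))
    return pd.DataFrame({
        "snp": truth["snp"],
        "ea": "A", "oa": "G",
        "eaf": truth["maf"],
        "beta_I": beta_i, "se_I": se_i, "p_I": np.maximum(p_i, 1e-320),
        "beta_P": beta_p, "se_P": se_p, "p_P": np.maximum(p_p, 1e-320),
        "n": n,
    })


def simulate_individual(cfg: ScenarioConfig,
                        block_size: int = 2000) -> SimulatedStudy:
    """Individual-level replicate: HWE genotypes, trait construction, and
    the per-SNP GWAS regressions (I ~ G; P ~ G + I).

    Deterministic given ``cfg.seed``.  Genotypes are held as int8 and
    processed in SNP blocks, so the default study size (20,000 × 10,000)
    needs ~200 MB.
    """
    rng = np.random.default_rng(cfg.seed)
    m, n = cfg.n_snps, cfg.n_individuals
    maf = rng.uniform(*cfg.maf_range, m)
    sd_g = np.sqrt(2.0 * maf * (1.0 - maf))
    beta_i_std, beta_p_std = _draw_effects(cfg, rng)
    truth = _truth_frame(cfg, maf, beta_i_std, beta_p_std, sd_g)
    a_i = truth["beta_I_true"].to_numpy()
    a_p = truth["beta_P_true"].to_numpy()

    # pass 1: genotypes (kept) and genetic trait components
    G = np.empty((n, m), dtype=np.int8)
    I = np.zeros(n)
    P = np.zeros(n)
    for lo in range(0, m, block_size):
        hi = min(lo + block_size, m)
        p = maf[lo:hi]
        g = (rng.random((n, hi - lo)) < p).astype(np.int8)
        g += (rng.random((n, hi - lo)) < p).astype(np.int8)
        G[:, lo:hi] = g
        gc = g - 2.0 * p
        I += gc @ a_i[lo:hi]
        P += gc @ a_p[lo:hi]
    conf_load = np.sqrt(cfg.conf2)
    U = rng.standard_normal(n)
    I += conf_load * U + np.sqrt(1.0 - cfg.h2_I - cfg.conf2) * rng.standard_normal(n)
    P += conf_load * U + np.sqrt(1.0 - cfg.h2_P - cfg.conf2) * rng.standard_normal(n)
    if cfg.beta_IP:
        P += cfg.beta_IP * I

    # pass 2: per-SNP OLS
    Ic = I - I.mean()
    Pc = P - P.mean()
    SII = float(Ic @ Ic)
    SPP = float(Pc @ Pc)
    SIP = float(Ic @ Pc)
    bI = np.empty(m); seI = np.empty(m)
    bP = np.empty(m); seP = np.empty(m)
    for lo in range(0, m, block_size):
        hi = min(lo + block_size, m)
        g = G[:, lo:hi].astype(np.float64)
        g -= g.mean(axis=0)
        Sgg = np.einsum("ij,ij->j", g, g)
        SgI = g.T @ Ic
        SgP = g.T @ Pc
        # marginal regression I ~ G
        bI[lo:hi] = SgI / Sgg
        rss = SII - SgI**2 / Sgg
        seI[lo:hi] = np.sqrt(rss / (n - 2) / Sgg)
        # conditional regression P ~ G + I
        det = Sgg * SII - SgI**2
        bg = (SgP * SII - SgI * SIP) / det
        th = (Sgg * SIP - SgI * SgP) / det
        rss2 = SPP - bg * SgP - th * SIP
        bP[lo:hi] = bg
        seP[lo:hi] = np.sqrt(rss2 / (n - 3) * SII / det)

    sumstats = _sumstats_frame(truth, bI, seI, bP, seP, n)
    study = SimulatedStudy(
        config=cfg, truth=truth, sumstats=sumstats,
        true_slope=_analytic_true_slope(cfg, beta_i_std, beta_p_std,
                                        truth["cluster"].to_numpy()),
        realized_slope=_realized_slope(truth, sumstats),
        seed=cfg.seed, mode="individual",
        var_I=float(SII / (n - 1)), var_P=float(SPP / (n - 1)))
    return study


def simulate_summary(cfg: ScenarioConfig) -> SimulatedStudy:
    """Summary-level replicate: estimated coefficients drawn directly from
    the OLS sampling distributions implied by the individual-level model.

    β̂_I ~ N(β_I, s_I²) and β̂'_P ~ N(β_P + b·β_I, s'_P²), with b the
    population bias slope and the standard errors from the OLS formulas at
    ``n_individuals``.  The small sampling correlation between the two
    estimates is ignored — an approximation, flagged by ``mode``.
    """
    rng = np.random.default_rng(cfg.seed)
    m, n = cfg.n_snps, cfg.n_individuals
    maf = rng.uniform(*cfg.maf_range, m)
    sd_g = np.sqrt(2.0 * maf * (1.0 - maf))
    beta_i_std, beta_p_std = _draw_effects(cfg, rng)
    truth = _truth_frame(cfg, maf, beta_i_std, beta_p_std, sd_g)
    cluster = truth["cluster"].to_numpy()
    b_pop = _analytic_true_slope(cfg, beta_i_std, beta_p_std, cluster)

    # per-SNP population conditional coefficient of G and residual variances
    gip = cluster == "GIP"
    c_shared = float(beta_i_std[gip] @ beta_p_std[gip])
    s_tot = cfg.conf2 + c_shared + beta_i_std * beta_p_std  # cov(I, P)
    var_i_given_g = 1.0 - beta_i_std**2
    s_i2_std = var_i_given_g / n
    # coefficients of P ~ G + I at the population level
    det = 1.0 - beta_i_std**2
    b_cond = (beta_p_std - beta_i_std * s_tot) / det
    theta = (s_tot - beta_i_std * beta_p_std) / det
    var_resid = np.maximum(1.0 - b_cond * beta_p_std - theta * s_tot, 1e-12)
    s_p2_std = var_resid / (n * det)

    beta_i_hat = beta_i_std + rng.standard_normal(m) * np.sqrt(s_i2_std)
    beta_p_hat = b_cond + rng.standard_normal(m) * np.sqrt(s_p2_std)

    sumstats = _sumstats_frame(
        truth, beta_i_hat / sd_g, np.sqrt(s_i2_std) / sd_g,
        beta_p_hat / sd_g, np.sqrt(s_p2_std) / sd_g, n)
    return SimulatedStudy(
        config=cfg, truth=truth, sumstats=sumstats, true_slope=b_pop,
        realized_slope=_realized_slope(truth, sumstats),
        seed=cfg.seed, mode="summary")


def simulate(cfg: ScenarioConfig, mode: str = "individual") -> SimulatedStudy:
    if mode == "individual":
        return simulate_individual(cfg)
    if mode == "summary":
        return simulate_summary(cfg)
    raise ConfigurationError(f"unknown simulation mode {mode!r}")


def true_slope(cfg: ScenarioConfig, n_reps: int = 3,
               seed: int | None = None, tol: float = 0.05) -> float:
    """Empirical bias-slope oracle for a configuration.

    Runs ``n_reps`` individual-level replicates and averages the realised
    bias slope (regression of realised bias on β̂_I over I-affecting SNPs).
    Cross-checked against the attenuation-aware closed form; a discrepancy
    beyond ``tol`` is logged as a warning.  Returns the empirical value.
    """
    base = cfg.seed if seed is None else seed
    ss = np.random.SeedSequence(0 if base is None else base)
    slopes = []
    analytic = None
    for child in ss.spawn(n_reps):
        rep_cfg = replace(cfg, seed=int(child.generate_state(1)[0] % (2**31)))
        study = simulate_individual(rep_cfg)
        slopes.append(study.realized_slope)
        if analytic is None:
            analytic = _attenuated_true_slope(
                rep_cfg, study.truth["beta_I_true"].to_numpy() *
                np.sqrt(2 * study.truth["maf"] * (1 - study.truth["maf"])),
                study.truth["beta_P_true"].to_numpy() *
                np.sqrt(2 * study.truth["maf"] * (1 - study.truth["maf"])),
                study.truth["cluster"].to_numpy())
    emp = float(np.mean(slopes))
    logger.info("true_slope: empirical %.4f, closed-form %.4f", emp, analytic)
    if abs(emp - analytic) > tol:
        logger.warning("true_slope: empirical (%.4f) and closed-form (%.4f) "
                       "oracles disagree beyond %.2f", emp, analytic, tol)
    return emp


def mixture_draws(n: int, b1: float, pi1: float, s_i2: float,
                  sigma_ip: float, sigma_p2: float, noise: float = 0.0,
                  seed: int | None = None) -> pd.DataFrame:
    """Draw (β̂_I, β̂'_P) pairs directly from the two-component mixture.

    Component 1 puts points on the line β̂'_P = b1·β̂_I; component 2 adds a
    direct-effect variance ``sigma_p2`` and covariance ``sigma_ip``.
    ``noise`` adds independent N(0, noise²) measurement error to β̂'_P so
    the rank-1 component has a density.  Used by parameter-recovery tests.
    """
    rng = np.random.default_rng(seed)
    comp2 = rng.random(n) >= pi1
    x = rng.standard_normal(n) * np.sqrt(s_i2)
    y = b1 * x
    k = comp2.sum()
    if k:
        # conditional distribution of the direct part given beta_I
        mu = (sigma_ip / s_i2) * x[comp2]
        var = max(sigma_p2 - sigma_ip**2 / s_i2, 0.0)
        y[comp2] += mu + rng.standard_normal(k) * np.sqrt(var)
    if noise > 0:
        y = y + rng.standard_normal(n) * noise
    se = np.full(n, noise if noise > 0 else np.sqrt(s_i2) * 1e-3)
    return pd.DataFrame({
        "snp": [f"m{i:05d}" for i in range(n)],
        "beta_I": x, "se_I": se.copy(),
        "beta_P": y, "se_P": se,
        "component": np.where(comp2, 2, 1),
    })
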