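"""Selection of variants associated with the conditioning trait.

Only SNPs that affect *I* carry collider bias, so the mixture model is fitted
to the subset with incidence-association p-value below a threshold λ
(default 0.001).  Selection p-values may come from the harmonised table
itself, be recomputed as two-sided Wald tests, or be supplied from an
independent study of *I* to avoid winner's curse.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)


class EstimationError(RuntimeError):
    """Raised when a quantity cannot be estimated from the data supplied."""


@dataclass
class SelectionConfig:
    """Configuration of the λ-threshold SNP selection.

    Parameters
    ----------
    lam
        p-value threshold in (0, 1]; SNPs with ``p_I < lam`` (strict) are
        retained.  Default 0.001.
    selection_pvalues
        Optional per-SNP p-value mapping from an independent study of *I*,
        used instead of the table's own p-values (winner's-curse guard).
    """

    lam: float = 1e-3
    selection_pvalues: dict[str, float] | None = None

    def __post_init__(self):
        if not (0.0 < self.lam <= 1.0):
            raise ValueError(f"lambda must be in (0, 1], got {self.lam}")


def wald_pvalue(beta, se):
    """Two-sided Wald p-value ``2*Phi(-|beta/se|)``.

    Accepts scalars or arrays; every ``se`` must be positive.
    """
    beta = np.asarray(beta, dtype=float)
    se = np.asarray(se, dtype=float)
    if np.any(se <= 0) or not np.all(np.isfinite(se)):
        raise ValueError("wald_pvalue requires se > 0")
    p = 2.0 * stats.norm.sf(np.abs(beta / se))
    # guard against exact 0 from underflow so p stays in (0, 1]
    p = np.maximum(p, np.finfo(float).tiny)
    return p if p.ndim else float(p)


def select_incidence_snps(table: pd.DataFrame,
                          cfg: SelectionConfig | None = None) -> pd.DataFrame:
    """Return the subset of a harmonised table with ``p_I < lambda``.

    The incidence p-value is taken, in order of preference, from
    ``cfg.selection_pvalues``, from a ``p_I`` column already present, or is
    recomputed as a Wald test from ``beta_I``/``se_I`` (logged).  Betas and
    standard errors are never altered.
    """
    cfg = cfg or SelectionConfig()
    if cfg.selection_pvalues is not None:
        p = table["snp"].map(cfg.selection_pvalues).to_numpy(dtype=float)
        if np.isnan(p).any():
            n_miss = int(np.isnan(p).sum())
            logger.warning("select: %d SNP(s) missing from external selection "
                           "p-values; treated as unselected", n_miss)
            p = np.where(np.isnan(p), 1.0, p)
    elif "p_I" in table.columns and table["p_I"].notna().all():
        p = table["p_I"].to_numpy(dtype=float)
    else:
        logger.info("select: recomputing incidence p-values from beta_I/se_I")
        p = wald_pvalue(table["beta_I"], table["se_I"])
    selected = table[p < cfg.lam].reset_index(drop=True)
    if selected.empty:
        raise EstimationError(
            f"no SNPs pass the selection threshold lambda={cfg.lam}; "
            "consider raising lambda")
    return selected
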