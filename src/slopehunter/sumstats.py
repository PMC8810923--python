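"""Reading, harmonising, pruning and writing GWAS summary statistics.

Two tables drive a collider-bias correction analysis: summary statistics for
the conditioning trait *I* (e.g. BMI, disease incidence) and for the outcome
*P* estimated conditional on *I* (e.g. BMI-adjusted fasting insulin, case-only
mortality).  This module aligns the two on SNP identity and effect allele and
optionally thins the joint table to near-independent SNPs with a greedy,
seeded LD prune.

Tables are plain :class:`pandas.DataFrame` objects with canonical column
names (``snp``, ``ea``, ``oa``, ``beta``, ``se`` ...); a :class:`ColumnMap`
translates arbitrary input headers into them.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, fields

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: canonical column order for a single-trait summary-statistics table
SUMSTAT_COLUMNS = ["snp", "chrom", "pos", "ea", "oa", "eaf", "beta", "se", "p", "n"]

#: columns of a harmonised (two-trait) table
HARMONISED_COLUMNS = [
    "snp", "ea", "oa", "eaf",
    "beta_I", "se_I", "p_I",
    "beta_P", "se_P", "p_P",
]

_PALINDROMIC = {("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")}


class InputError(ValueError):
    """Raised for unusable input data (empty tables, empty intersections)."""


class ConfigurationError(ValueError):
    """Raised for invalid configuration (missing mandatory columns ...)."""


@dataclass
class ColumnMap:
    """Mapping from canonical field names to the physical column headers.

    Only ``beta`` and ``se`` are mandatory; any other field set to ``None``
    is treated as absent from the file.
    """

    snp: str = "SNP"
    beta: str = "BETA"
    se: str = "SE"
    ea: str | None = "EA"
    oa: str | None = "OA"
    eaf: str | None = None
    p: str | None = None
    n: str | None = None
    chrom: str | None = None
    pos: str | None = None

    def as_dict(self) -> dict[str, str]:
        return {f.name: getattr(self, f.name) for f in fields(self)
                if getattr(self, f.name) is not None}


def read_sumstats(path, column_map: ColumnMap | None = None,
                  delimiter: str | None = None) -> pd.DataFrame:
    r"""Read a delimited summary-statistics file into canonical form.

    Parameters
    ----------
    path
        Text file with one row per SNP.
    column_map
        Physical column names; defaults to ``SNP/EA/OA/BETA/SE``.
    delimiter
        Field separator; ``None`` autodetects whitespace/tab/comma.

    Rows with missing or unparsable ``beta``, or with ``se <= 0``, are
    dropped (counted in the log), as are duplicated SNP ids.
    """
    cmap = column_map or ColumnMap()
    if delimiter is None:
        raw = pd.read_csv(path, sep=r"\s+|,|\t", engine="python",
                          comment="#")
    else:
        raw = pd.read_csv(path, sep=delimiter, comment="#",
                          float_precision="round_trip")
    missing = [col for col in (cmap.beta, cmap.se) if col not in raw.columns]
    if missing:
        raise ConfigurationError(
            f"mandatory column(s) {missing} not found in {path}; "
            f"available: {list(raw.columns)}")
    out = pd.DataFrame(index=raw.index)
    for canon, phys in cmap.as_dict().items():
        if phys in raw.columns:
            out[canon] = raw[phys]
    if "snp" not in out.columns:
        out["snp"] = [f"row{i}" for i in range(len(out))]

    n0 = len(out)
    out["beta"] = pd.to_numeric(out["beta"], errors="coerce")
    out["se"] = pd.to_numeric(out["se"], errors="coerce")
    out = out[np.isfinite(out["beta"]) & np.isfinite(out["se"]) & (out["se"] > 0)]
    if (dropped := n0 - len(out)):
        logger.info("read_sumstats: dropped %d row(s) with bad beta/se", dropped)
    dups = out["snp"].duplicated(keep=False)
    if dups.any():
        logger.warning("read_sumstats: dropping %d duplicated SNP id(s)", int(dups.sum()))
        out = out[~dups]
    for col in ("ea", "oa"):
        if col in out.columns:
            out[col] = out[col].astype(str).str.upper()
    if out.empty:
        raise InputError(f"no usable records in {path}")
    return out.reset_index(drop=True)


def write_sumstats(table: pd.DataFrame, path, delimiter: str = "\t") -> None:
    """Write a table as delimited text with full float precision."""
    table.to_csv(path, sep=delimiter, index=False, float_format="%.17g")


def _is_palindromic(a1: str, a2: str) -> bool:
    return (a1, a2) in _PALINDROMIC


def harmonise(incidence: pd.DataFrame, outcome: pd.DataFrame,
              palindromic_policy: str = "keep") -> pd.DataFrame:
    """Align two summary-statistics tables on SNP id and effect allele.

    The incidence table's allele orientation is authoritative: when the
    outcome's effect/other alleles are swapped relative to it the outcome
    beta sign is flipped (and eaf complemented); SNPs whose allele sets do
    not match even after the swap are dropped.  Palindromic SNPs (A/T, C/G),
    for which strand cannot be resolved from alleles alone, are handled per
    ``palindromic_policy``:

    ``keep``
        retain as-is (default),
    ``drop``
        remove them,
    ``drop_if_eaf_ambiguous``
        remove only those whose effect-allele frequency is missing or close
        to 0.5 (within 0.08) in either table.
    """
    if incidence.empty or outcome.empty:
        raise InputError("harmonise requires two non-empty tables")
    if palindromic_policy not in ("keep", "drop", "drop_if_eaf_ambiguous"):
        raise ConfigurationError(f"unknown palindromic policy {palindromic_policy!r}")

    inc = incidence.rename(columns={"beta": "beta_I", "se": "se_I", "p": "p_I",
                                    "eaf": "eaf", "ea": "ea", "oa": "oa"})
    suffix = {"beta": "beta_P", "se": "se_P", "p": "p_P", "ea": "ea_P",
              "oa": "oa_P", "eaf": "eaf_P"}
    outc = outcome.rename(columns={k: v for k, v in suffix.items() if k in outcome.columns})
    merged = inc.merge(outc[["snp"] + [c for c in outc.columns if c in suffix.values()]],
                       on="snp", how="inner")
    if merged.empty:
        raise InputError("no SNPs shared between the two tables")

    have_alleles = {"ea", "oa", "ea_P", "oa_P"}.issubset(merged.columns)
    if have_alleles:
        same = (merged["ea"] == merged["ea_P"]) & (merged["oa"] == merged["oa_P"])
        swapped = (merged["ea"] == merged["oa_P"]) & (merged["oa"] == merged["ea_P"])
        merged.loc[swapped, "beta_P"] = -merged.loc[swapped, "beta_P"]
        if "eaf_P" in merged.columns:
            merged.loc[swapped, "eaf_P"] = 1.0 - merged.loc[swapped, "eaf_P"]
        keep = same | swapped
        if (n_bad := int((~keep).sum())):
            logger.info("harmonise: dropped %d SNP(s) with mismatched alleles", n_bad)
        merged = merged[keep]

        pal = merged.apply(lambda r: _is_palindromic(r["ea"], r["oa"]), axis=1)
        if palindromic_policy == "drop":
            merged = merged[~pal]
        elif palindromic_policy == "drop_if_eaf_ambiguous":
            eaf = merged["eaf"] if "eaf" in merged.columns else pd.Series(np.nan, index=merged.index)
            ambiguous = eaf.isna() | ((eaf - 0.5).abs() < 0.08)
            merged = merged[~(pal & ambiguous)]

    if merged.empty:
        raise InputError("no SNPs survived harmonisation")
    cols = [c for c in HARMONISED_COLUMNS if c in merged.columns]
    return merged[cols].reset_index(drop=True)


def read_ld_report(path, delimiter: str | None = None) -> dict[frozenset, float]:
    """Read a 3-column (snp_a, snp_b, r2) pairwise-LD text file.

    Headers are optional; plink ``.ld`` exports work after reducing to the
    three columns.  Returns a dict keyed by unordered SNP pair.
    """
    sep = delimiter if delimiter is not None else r"\s+"
    df = pd.read_csv(path, sep=sep, engine="python")
    if df.shape[1] < 3:
        raise ConfigurationError("LD report needs >= 3 columns: snp_a snp_b r2")
    # tolerate headerless files
    first = df.columns[2]
    try:
        float(first)
        df = pd.read_csv(path, sep=sep, engine="python", header=None)
    except (TypeError, ValueError):
        pass
    a, b, r2 = df.columns[:3]
    return {frozenset((str(x), str(y))): float(v)
            for x, y, v in zip(df[a], df[b], df[r2])}


def ld_prune(table: pd.DataFrame, ld_report: dict[frozenset, float],
             r2_threshold: float = 0.1, window_snps: int = 250,
             seed: int | None = 0) -> pd.DataFrame:
    """Greedy random-order LD pruning of a harmonised table.

    SNPs are visited in a seeded random order (pruning on a random basis
    rather than by p-value avoids winner's-curse artefacts); a SNP is
    retained unless its r² with an already-retained SNP within
    ``window_snps`` positions (in table order) exceeds ``r2_threshold``.
    Pairs absent from the report count as r² = 0.  The output preserves the
    input row order and is deterministic given the seed.
    """
    n = len(table)
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    snps = table["snp"].to_numpy()
    kept: list[int] = []
    kept_mask = np.zeros(n, dtype=bool)
    n_missing = 0
    for i in order:
        ok = True
        lo, hi = i - window_snps, i + window_snps
        for j in kept:
            if lo < j < hi:
                key = frozenset((snps[i], snps[j]))
                r2 = ld_report.get(key)
                if r2 is None:
                    n_missing += 1
                    r2 = 0.0
                if r2 > r2_threshold:
                    ok = False
                    break
        if ok:
            kept.append(i)
            kept_mask[i] = True
    if n_missing:
        logger.info("ld_prune: %d pair(s) absent from LD report, treated as r2=0",
                    n_missing)
    return table[kept_mask].reset_index(drop=True)
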