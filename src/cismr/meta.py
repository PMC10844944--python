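"""Fixed-effects inverse-variance meta-analysis of per-variant pQTL effects.

Combines a protein's per-variant associations across contributing GWAS with
inverse-variance weights, computes Cochran's Q heterogeneity per variant, and
quantifies cross-study agreement of SNP effects (Pearson correlation and
directional consistency on LD-pruned significant SNPs).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .instruments import greedy_ld_prune
from .summary_io import LDMatrix

logger = logging.getLogger(__name__)


def pool_fixed(betas, ses) -> tuple[float, float, float, float, float]:
    """Inverse-variance fixed-effects pool of one variant's study effects.

    Returns (beta, se, pvalue, q, p_het) with weights 1/se^2,
    Q = sum w_i (b_i - b_pool)^2 on chi2(k-1); p_het = 1 for a single study.
    """
    betas = np.asarray(betas, dtype=float)
    ses = np.asarray(ses, dtype=float)
    if betas.size == 0:
        raise ValueError("no records to meta-analyse")
    w = 1.0 / ses**2
    beta = float(np.sum(w * betas) / np.sum(w))
    se = float(np.sum(w) ** -0.5)
    p = float(2 * stats.norm.sf(abs(beta / se)))
    q = float(np.sum(w * (betas - beta) ** 2))
    df = betas.size - 1
    p_het = float(stats.chi2.sf(q, df)) if df > 0 else 1.0
    return beta, se, p, q, p_het


def fixed_effects_meta(records: pd.DataFrame) -> pd.Series:
    """Meta-analyse one variant's harmonised records (one row per study)."""
    beta, se, p, q, p_het = pool_fixed(records["beta"], records["se"])
    first = records.iloc[0]
    return pd.Series(
        {
            "chrom": first["chrom"],
            "pos": first["pos"],
            "rsid": first["rsid"],
            "ea": first["ea"],
            "oa": first["oa"],
            "eaf": float(np.average(records["eaf"], weights=records["n"])),
            "beta": beta,
            "se": se,
            "pvalue": p,
            "n": float(records["n"].sum()),
            "q_stat": q,
            "df": len(records) - 1,
            "p_het": p_het,
            "n_studies": len(records),
        }
    )


def meta_analyse(studies: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Pool several studies' summary frames variant by variant.

    ``studies`` maps study labels to harmonised summary frames (one row per
    variant, identical allele coding).  Variants present in a single study
    pass through with q_stat = 0 and p_het = 1.  The pooled frame is in the
    canonical summary dialect with added q_stat/df/p_het/n_studies columns.
    """
    long = pd.concat(
        [df.assign(study_id=sid) for sid, df in studies.items()],
        ignore_index=True,
    )
    long["key"] = long["chrom"].astype(str) + ":" + long["pos"].astype(str)
    rows = [fixed_effects_meta(grp) for _, grp in long.groupby("key", sort=True)]
    out = pd.DataFrame(rows).sort_values(["chrom", "pos"]).reset_index(drop=True)
    return out


def filter_heterogeneous(
    meta: pd.DataFrame, p_het_threshold: float = 0.001
) -> pd.DataFrame:
    """Drop variants with cross-study heterogeneity p_het < threshold."""
    if not 0 < p_het_threshold < 1:
        raise ValueError("p_het_threshold must be in (0, 1)")
    keep = meta["p_het"] >= p_het_threshold
    removed = int((~keep).sum())
    logger.info(
        "heterogeneity filter (p_het < %g): removed %d of %d variants",
        p_het_threshold, removed, len(meta),
    )
    out = meta.loc[keep].reset_index(drop=True)
    out.attrs["removed_heterogeneous"] = removed
    return out


@dataclass
class Concordance:
    pearson_r: float  # NaN when < 2 SNPs survive
    consistency: float  # fraction of SNPs with matching effect sign
    n_snps: int


def study_concordance(
    study_a: pd.DataFrame,
    study_b: pd.DataFrame,
    ld: LDMatrix,
    p_threshold: float = 5e-8,
    prune_r2: float = 0.01,
) -> Concordance:
    """Agreement of SNP effects between two studies of the same protein.

    SNPs significant in ``study_a`` at ``p_threshold`` are greedily pruned to
    pairwise r^2 < ``prune_r2``; effects are aligned to study_a's
    protein-increasing allele before correlating, which avoids correlation
    inflated purely by shared allele coding.
    """
    study_a = study_a.copy()
    study_b = study_b.copy()
    study_a.attrs = {}
    study_b.attrs = {}
    merged = study_a.merge(
        study_b,
        on=["chrom", "pos"],
        suffixes=("_a", "_b"),
        validate="1:1",
    )
    aligned = merged["ea_a"] == merged["ea_b"]
    swapped = (merged["ea_a"] == merged["oa_b"]) & (merged["oa_a"] == merged["ea_b"])
    if not (aligned | swapped).all():
        raise ValueError("studies not allele-reconcilable; harmonise first")
    merged.loc[swapped, "beta_b"] = -merged.loc[swapped, "beta_b"]

    sig = merged.loc[merged["pvalue_a"] < p_threshold].copy()
    sig = sig.rename(
        columns={"rsid_a": "rsid", "pvalue_a": "pvalue", "ea_a": "ea", "oa_a": "oa"}
    )
    kept = greedy_ld_prune(sig, ld, r2_max=prune_r2)
    sig["key"] = sig["chrom"].astype(str) + ":" + sig["pos"].astype(str)
    sig = sig.set_index("key").loc[kept]

    # align both studies to the allele that increases the protein in study_a
    flip = np.sign(sig["beta_a"].to_numpy())
    flip[flip == 0] = 1.0
    ba = sig["beta_a"].to_numpy() * flip
    bb = sig["beta_b"].to_numpy() * flip

    n = len(sig)
    consistency = float(np.mean(np.sign(bb) == np.sign(ba))) if n >= 1 else np.nan
    if n >= 2 and np.std(ba) > 0 and np.std(bb) > 0:
        pearson = float(stats.pearsonr(ba, bb)[0])
    else:
        pearson = float("nan")
    return Concordance(pearson, consistency, n)
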