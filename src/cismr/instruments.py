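"""Construction of cis-acting genetic instruments for protein exposures.

An instrument is the set of SNPs within a window of the protein-coding gene
(default ±250 kb) that pass frequency/significance filters, survive greedy LD
pruning to pairwise r^2 below a threshold (default 0.10), and carry
harmonised exposure and outcome effects together with their LD submatrix.
Instrument strength is summarised by the variance explained r^2 and the
F-statistic; F > 10 conventionally indicates low weak-instrument bias.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .summary_io import LDMatrix, is_strand_ambiguous, variant_key

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class GeneRegion:
    gene_id: str
    chrom: str
    start: int
    end: int

    def __post_init__(self):
        if self.start > self.end:
            raise ValueError("gene region start > end")


def read_gene_regions(path) -> dict[str, GeneRegion]:
    """Read a gene/chrom/start/end table into GeneRegion objects."""
    df = pd.read_csv(path, sep=None, engine="python")
    return {
        str(r["gene_id"]): GeneRegion(
            str(r["gene_id"]), str(r["chrom"]), int(r["start"]), int(r["end"])
        )
        for _, r in df.iterrows()
    }


def select_cis(
    summary: pd.DataFrame, region: GeneRegion, window: int = 250_000
) -> pd.DataFrame:
    """Keep variants on the gene's chromosome within [start-window, end+window].

    Boundaries are inclusive on both ends (1-based coordinates).
    """
    lo = region.start - window
    hi = region.end + window
    mask = (
        (summary["chrom"].astype(str) == str(region.chrom))
        & (summary["pos"] >= lo)
        & (summary["pos"] <= hi)
    )
    return summary.loc[mask].reset_index(drop=True)


def apply_qc_filters(
    records: pd.DataFrame,
    maf_min: float = 0.01,
    palindrome_maf_limit: float = 0.40,
    p_sig: float = 5e-8,
) -> pd.DataFrame:
    """MAF, palindrome and significance filters, applied in that order.

    Removes MAF < maf_min; removes strand-ambiguous (A/T, C/G) variants with
    MAF > palindrome_maf_limit; retains p < p_sig (strict).  Per-filter
    removal counts are attached as ``.attrs["filter_counts"]``.
    """
    counts = {}
    maf = np.minimum(records["eaf"], 1 - records["eaf"])
    keep = maf >= maf_min
    counts["maf"] = int((~keep).sum())
    df = records.loc[keep]

    maf = np.minimum(df["eaf"], 1 - df["eaf"])
    palin = df.apply(lambda r: is_strand_ambiguous(r["ea"], r["oa"]), axis=1)
    if len(df) == 0:
        palin = pd.Series(False, index=df.index)
    keep = ~(palin & (maf > palindrome_maf_limit))
    counts["palindrome"] = int((~keep).sum())
    df = df.loc[keep]

    keep = df["pvalue"] < p_sig
    counts["significance"] = int((~keep).sum())
    df = df.loc[keep].reset_index(drop=True)
    df.attrs["filter_counts"] = counts
    logger.info("qc filters removed %s; %d variants retained", counts, len(df))
    return df


def greedy_ld_prune(
    records: pd.DataFrame, ld: LDMatrix, r2_max: float = 0.10
) -> list[str]:
    """Greedy p-value-ordered LD pruning to pairwise r^2 < r2_max.

    Records are ranked by ascending p-value (ties: ascending position, then
    lexicographic rsid); the best remaining record is kept and every
    remaining record with r^2 >= r2_max against any kept record discarded.
    Returns kept "chrom:pos" keys in keep order.  Deterministic by the
    tie-break rule.
    """
    if len(records) == 0:
        return []
    df = records.copy()
    df["key"] = [
        variant_key(c, p) for c, p in zip(df["chrom"], df["pos"])
    ]
    missing = [k for k in df["key"] if k not in ld._index]
    if missing:
        raise KeyError(f"variants missing from LD matrix: {missing}")
    df = df.sort_values(
        ["pvalue", "pos", "rsid"], kind="mergesort"
    ).reset_index(drop=True)
    order = [ld.index_of(k) for k in df["key"]]
    r2 = ld.r[np.ix_(order, order)] ** 2

    kept: list[int] = []
    alive = np.ones(len(df), dtype=bool)
    for i in range(len(df)):
        if not alive[i]:
            continue
        kept.append(i)
        alive &= r2[i] < r2_max
        alive[i] = False
    return [df["key"].iloc[i] for i in kept]


@dataclass
class Instrument:
    """A protein's pruned cis-SNP set with harmonised effects and LD."""

    protein_id: str
    snps: pd.DataFrame  # chrom,pos,rsid,ea,oa,eaf,beta_exp,se_exp,pvalue_exp,
    #                     beta_out,se_out (outcome columns optional pre-harmonise)
    ld: LDMatrix
    r2_total: float = field(default=np.nan)
    f_stat: float = field(default=np.nan)

    def __post_init__(self):
        keys = [
            variant_key(c, p)
            for c, p in zip(self.snps["chrom"], self.snps["pos"])
        ]
        if keys != list(self.ld.variants):
            self.ld = self.ld.submatrix(keys)

    @property
    def k(self) -> int:
        return len(self.snps)

    @property
    def keys(self) -> list[str]:
        return list(self.ld.variants)

    @property
    def sentinel(self) -> pd.Series:
        """SNP with the smallest exposure p-value (ties: ascending position)."""
        idx = self.snps.sort_values(
            ["pvalue_exp", "pos"], kind="mergesort"
        ).index[0]
        return self.snps.loc[idx]

    def max_offdiag_r2(self) -> float:
        if self.k < 2:
            return 0.0
        r2 = self.ld.r**2
        return float((r2 - np.eye(self.k)).max())

    def drop(self, key: str) -> "Instrument":
        mask = [k != key for k in self.keys]
        return Instrument(
            self.protein_id,
            self.snps.loc[mask].reset_index(drop=True),
            self.ld.submatrix([k for k in self.keys if k != key]),
        )


def build_instrument(
    protein_id: str,
    harmonised: pd.DataFrame,
    ld: LDMatrix,
    r2_max: float = 0.10,
) -> Instrument | None:
    """Prune a harmonised cis table and assemble the Instrument.

    ``harmonised`` must carry exposure columns suffixed _exp (and _out
    columns when an outcome is attached).  Returns None when no SNP survives.
    """
    df = harmonised.rename(columns={"pvalue_exp": "pvalue"}).copy()
    kept = greedy_ld_prune(df, ld, r2_max=r2_max)
    if not kept:
        return None
    df["key"] = df["chrom"].astype(str) + ":" + df["pos"].astype(str)
    snps = (
        df.set_index("key")
        .loc[kept]
        .reset_index(drop=True)
        .rename(columns={"pvalue": "pvalue_exp"})
    )
    return Instrument(protein_id, snps, ld.submatrix(kept))


def instrument_strength(
    instrument: Instrument, n_exposure: float
) -> tuple[float, float]:
    """Variance explained and F-statistic of the instrument.

    Per-SNP r^2_j = 2 eaf_j (1-eaf_j) beta_j^2 for per-allele effects on an
    SD-standardised trait; r2_total sums contributions over the pruned set
    (no LD cross-term; mild with pairwise r^2 < 0.10).
    F = [r2/(1-r2)] [(n-k-1)/k].
    """
    eaf = instrument.snps["eaf"].to_numpy(dtype=float)
    beta = instrument.snps["beta_exp"].to_numpy(dtype=float)
    r2 = float(np.sum(2 * eaf * (1 - eaf) * beta**2))
    if r2 >= 1:
        raise ValueError(
            f"r2_total = {r2:.3f} >= 1: exposure betas not on an SD scale?"
        )
    k = instrument.k
    f = (r2 / (1 - r2)) * ((n_exposure - k - 1) / k)
    instrument.r2_total = r2
    instrument.f_stat = f
    return r2, f


def write_instrument(instrument: Instrument, path) -> None:
    df = instrument.snps.copy()
    df.insert(0, "protein_id", instrument.protein_id)
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")
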