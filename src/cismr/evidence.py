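"""Evidence tiering: FDR correction, arm partitioning, replication pooling,
and missense-artefact flagging.

Protein-outcome pairs are split into a validation arm (prior-evidence score
at or above a threshold, default 0.05) and a discovery arm; Benjamini-
Hochberg FDR correction is applied within each arm separately.  q < 0.05 is
"strong" evidence, 0.05 <= q < 0.20 "suggestive", else "little".  Replication
estimates are pooled with both fixed-effects and DerSimonian-Laird
random-effects meta-analysis.  Instrument SNPs that are missense variants,
or in high LD (r^2 > 0.80) with one, are flagged as potential assay binding
artefacts and a revised estimate excluding them is produced when possible.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .instruments import Instrument
from .mr import MREstimate, estimate
from .summary_io import LDMatrix

logger = logging.getLogger(__name__)

TIER_STRONG = 0.05
TIER_SUGGESTIVE = 0.20


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values).

    q_i = min over j with p_j >= p_i (by rank) of p_j * m / rank_j, clipped
    at 1; returned aligned to the input order.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p <= 0) | (p > 1)) or np.isnan(p).any():
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def tier(q_value: float) -> str:
    """Evidence tier from the q-value: strong / suggestive / little."""
    if not 0 <= q_value <= 1:
        raise ValueError("q-value outside [0, 1]")
    if q_value < TIER_STRONG:
        return "strong"
    if q_value < TIER_SUGGESTIVE:
        return "suggestive"
    return "little"


def partition_arms(
    pairs: list[tuple[str, str]],
    scores: pd.DataFrame,
    threshold: float = 0.05,
) -> tuple[list[tuple[str, str]], list[tuple[str, str]]]:
    """Split protein-outcome pairs into validation and discovery arms.

    ``scores`` has columns protein_id, outcome_id, score (prior-evidence,
    e.g. an Open Targets overall association score in [0, 1]).  Pairs with
    score >= threshold go to validation; missing scores count as 0, so those
    pairs go to discovery.  The partition is exhaustive and disjoint.
    """
    lookup = {
        (str(r["protein_id"]), str(r["outcome_id"])): float(r["score"])
        for _, r in scores.iterrows()
    }
    validation, discovery = [], []
    for pair in pairs:
        if lookup.get((str(pair[0]), str(pair[1])), 0.0) >= threshold:
            validation.append(pair)
        else:
            discovery.append(pair)
    return validation, discovery


@dataclass
class ReplicationMeta:
    beta_fixed: float
    se_fixed: float
    beta_random: float
    se_random: float
    q: float
    i2: float  # percentage
    tau2: float

    @property
    def p_fixed(self) -> float:
        return float(2 * stats.norm.sf(abs(self.beta_fixed / self.se_fixed)))

    @property
    def p_random(self) -> float:
        return float(2 * stats.norm.sf(abs(self.beta_random / self.se_random)))


def replication_meta(
    primary: MREstimate, replication: MREstimate
) -> ReplicationMeta:
    """Pool a primary and a replication estimate (both log-OR scale).

    Fixed effects by inverse variance; random effects by DerSimonian-Laird:
    tau^2 = max(0, (Q - df) / (sum w - sum w^2 / sum w)) with w = 1/se^2,
    random weights 1/(se^2 + tau^2); I^2 = max(0, (Q - df)/Q) * 100.
    """
    b = np.array([primary.beta, replication.beta])
    se = np.array([primary.se, replication.se])
    w = 1.0 / se**2
    beta_f = float(np.sum(w * b) / np.sum(w))
    se_f = float(np.sum(w) ** -0.5)
    q = float(np.sum(w * (b - beta_f) ** 2))
    df = b.size - 1
    c = float(np.sum(w) - np.sum(w**2) / np.sum(w))
    tau2 = max(0.0, (q - df) / c) if c > 0 else 0.0
    i2 = max(0.0, (q - df) / q) * 100 if q > 0 else 0.0
    wr = 1.0 / (se**2 + tau2)
    beta_r = float(np.sum(wr * b) / np.sum(wr))
    se_r = float(np.sum(wr) ** -0.5)
    return ReplicationMeta(beta_f, se_f, beta_r, se_r, q, i2, tau2)


@dataclass
class MissenseFlags:
    flags: dict[str, bool]  # instrument SNP key -> flagged
    revised: MREstimate | None  # estimate excluding flagged SNPs, when possible
    unresolvable: bool  # single-SNP instrument whose only SNP is flagged


def flag_missense(
    instrument: Instrument,
    annotations: pd.DataFrame,
    ld: LDMatrix,
    r2_flag: float = 0.80,
    outcome_id: str = "",
) -> MissenseFlags:
    """Flag instrument SNPs that are, or tag (r^2 > r2_flag), missense variants.

    ``annotations`` has columns chrom, pos, missense (truthy); ``ld`` must
    cover the instrument SNPs and every annotated missense variant in the
    window.  For multi-SNP instruments a revised estimate excluding flagged
    SNPs is computed when at least one SNP survives; a flagged single-SNP
    instrument is unresolvable by exclusion.
    """
    ann = annotations.loc[annotations["missense"].astype(bool)]
    missense_keys = {
        f"{c}:{int(p)}" for c, p in zip(ann["chrom"], ann["pos"])
    }
    flags = {}
    for key in instrument.keys:
        if key in missense_keys:
            flags[key] = True
            continue
        flagged = False
        for mk in missense_keys:
            if mk in ld._index and key in ld._index:
                r = ld.r[ld.index_of(key), ld.index_of(mk)]
                if r**2 > r2_flag:
                    flagged = True
                    break
        flags[key] = flagged

    surviving = [k for k in instrument.keys if not flags[k]]
    revised = None
    unresolvable = False
    if all(flags.values()):
        unresolvable = instrument.k == 1
        if instrument.k > 1:
            logger.warning(
                "%s: every instrument SNP flagged; no revised estimate",
                instrument.protein_id,
            )
    elif len(surviving) < instrument.k:
        sub = instrument
        for key in instrument.keys:
            if flags[key]:
                sub = sub.drop(key)
        revised = estimate(sub, outcome_id)
    return MissenseFlags(flags, revised, unresolvable)
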