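"""Synthetic GWAS inputs with known ground truth.

Generates LD-structured haplotype reference panels (thresholded stationary
AR(1) Gaussian latent process, variant MAFs uniform on 0.05-0.5), multi-study
cis-pQTL summary statistics from individual-level regressions on a unit-
variance protein trait, and binary-outcome GWAS from an individual-level
logistic model, under explicit colocalisation scenarios:

* ``h0`` - neither trait associated in the region;
* ``h1``/``null`` - protein pQTL present, no outcome signal (alpha = 0);
* ``h2`` - outcome signal only;
* ``h3`` - protein and outcome driven by *distinct* causal variants
  (LD-confounding / horizontal pleiotropy);
* ``h4``/``causal`` - the outcome is causally downstream of the protein
  (log-odds alpha per SD), sharing the protein's causal variant.

A fast multivariate-normal summary-statistic mode
(:func:`mvn_marginal_stats`: z ~ N(sqrt(n) R b, R) on the standardised
scale) is provided for large replicate counts; it is an approximation that
bypasses genotype sampling and the case-control likelihood.

All generators are pure functions of (spec, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .instruments import GeneRegion
from .summary_io import ReferencePanel

SCENARIOS = ("null", "causal", "h0", "h1", "h2", "h3", "h4")


def replace_spec(spec: "ScenarioSpec", **kw) -> "ScenarioSpec":
    """Copy a spec with fields replaced (post-init defaults re-resolved)."""
    return replace(spec, **kw)

#: default causal log-OR of outcome per SD of exposure in shared scenarios.
#: Chosen with the default desk-scale sample sizes (10k per trait) so the
#: shared signal is detectable in the outcome GWAS; the study this emulates
#: pairs weaker effects with far larger outcome GWAS.
DEFAULT_ALPHA = float(np.log(2.0))


@dataclass
class ScenarioSpec:
    """Parameters of one synthetic protein-outcome region."""

    scenario: str = "h4"
    n_variants: int = 200
    ld_decay: float = 0.5  # AR(1) latent correlation between adjacent variants
    n_haplotypes: int = 1000
    causal_snps_exposure: dict[int, float] = field(default=None)  # idx -> beta (SD)
    causal_snps_outcome: dict[int, float] = field(default=None)  # idx -> log-OR
    alpha: float = None  # causal log-OR per SD of exposure
    n_exposure: int = 10_000
    n_outcome: int = 10_000
    case_fraction: float = 0.33
    n_studies: int = 2
    het_sd: float = 0.0  # between-study SD of exposure effects
    seed: int = 0
    chrom: str = "1"
    pos_start: int = 1_000_000
    pos_step: int = 1000

    def __post_init__(self):
        if self.scenario not in SCENARIOS:
            raise ValueError(f"unknown scenario {self.scenario!r}")
        if not 0 <= self.ld_decay < 1:
            raise ValueError("ld_decay must be in [0, 1)")
        if not 0 < self.case_fraction < 1:
            raise ValueError("case_fraction must be in (0, 1)")
        m = self.n_variants
        gap = min(10, max(1, m // 4))  # distinct-variant separation (h3)
        if self.causal_snps_exposure is None:
            self.causal_snps_exposure = (
                {} if self.scenario in ("h0", "h2") else {m // 2 - gap: 0.3}
            )
        if self.causal_snps_outcome is None:
            self.causal_snps_outcome = (
                {m // 2 + gap: 0.35} if self.scenario in ("h2", "h3") else {}
            )
        if self.alpha is None:
            self.alpha = (
                DEFAULT_ALPHA if self.scenario in ("causal", "h4") else 0.0
            )
        for idx in list(self.causal_snps_exposure) + list(self.causal_snps_outcome):
            if not 0 <= idx < m:
                raise ValueError(f"causal index {idx} out of range")

    def positions(self) -> np.ndarray:
        return self.pos_start + self.pos_step * np.arange(self.n_variants)

    def gene_region(self, gene_id: str = "GENE") -> GeneRegion:
        """A gene placed at the window centre, so every simulated variant is
        cis (within 250 kb) to it."""
        centre = int(self.pos_start + self.pos_step * (self.n_variants // 2))
        return GeneRegion(gene_id, self.chrom, centre, centre + 2000)


# ---------------------------------------------------------------------------
# reference panel and genotypes


def simulate_panel(spec: ScenarioSpec, rng: np.random.Generator = None) -> ReferencePanel:
    """Haplotypes by thresholding a stationary AR(1) Gaussian process.

    hap[h, j] = 1 where the latent value falls below the MAF-quantile of
    variant j (MAF ~ U(0.05, 0.5)), so adjacent-variant dosage correlation
    rises with ``ld_decay``.  Monomorphic columns (possible only in very
    small panels) are repaired by flipping one entry.
    """
    rng = rng or np.random.default_rng(spec.seed)
    m, h = spec.n_variants, spec.n_haplotypes
    rho = spec.ld_decay
    maf = rng.uniform(0.05, 0.5, size=m)
    lat = np.empty((h, m))
    lat[:, 0] = rng.standard_normal(h)
    innov = rng.standard_normal((h, m))
    scale = np.sqrt(1 - rho**2)
    for j in range(1, m):
        lat[:, j] = rho * lat[:, j - 1] + scale * innov[:, j]
    hap = (lat < stats.norm.ppf(maf)).astype(np.int8)

    counts = hap.sum(axis=0)
    for j in np.flatnonzero((counts == 0) | (counts == h)):
        hap[rng.integers(h), j] ^= 1
    variants = pd.DataFrame(
        {
            "chrom": spec.chrom,
            "pos": spec.positions(),
            "rsid": [f"rs{j + 1}" for j in range(m)],
            "ea": "A",
            "oa": "G",
        }
    )
    return ReferencePanel(hap, variants)


def sample_genotypes(
    panel: ReferencePanel, n: int, rng: np.random.Generator
) -> np.ndarray:
    """n diploid genotypes (0/1/2) by pairing panel haplotypes at random."""
    h = panel.haplotypes.shape[0]
    i = rng.integers(h, size=n)
    j = rng.integers(h, size=n)
    return (panel.haplotypes[i] + panel.haplotypes[j]).astype(np.int8)


def _marginal_ols(G: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, ...]:
    """Per-variant simple regression of y on each genotype column."""
    n = y.size
    gc = G - G.mean(axis=0)
    yc = y - y.mean()
    denom = np.einsum("ij,ij->j", gc, gc)
    beta = (gc.T @ yc) / denom
    rss = np.sum(yc**2) - beta**2 * denom
    sigma2 = rss / (n - 2)
    se = np.sqrt(sigma2 / denom)
    z = beta / se
    p = 2 * stats.norm.sf(np.abs(z))
    return beta, se, np.clip(p, 1e-300, 1.0)


def _summary_frame(spec, panel, beta, se, p, eaf, n) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "chrom": spec.chrom,
            "pos": spec.positions(),
            "rsid": panel.variants["rsid"],
            "ea": "A",
            "oa": "G",
            "eaf": eaf,
            "beta": beta,
            "se": se,
            "pvalue": p,
            "n": float(n),
        }
    )


def simulate_exposure_gwas(
    panel: ReferencePanel,
    spec: ScenarioSpec,
    rng: np.random.Generator = None,
) -> dict[str, pd.DataFrame]:
    """Per-study marginal pQTL summary statistics.

    Each study draws its own genotypes; the protein is the causal genetic
    score plus Gaussian noise scaled so the trait has unit variance; each
    study's causal effects are perturbed by N(0, het_sd) to create
    between-study heterogeneity.
    """
    rng = rng or np.random.default_rng(spec.seed + 1)
    m = spec.n_variants
    b = np.zeros(m)
    for idx, eff in spec.causal_snps_exposure.items():
        b[idx] = eff
    out = {}
    for s in range(spec.n_studies):
        G = sample_genotypes(panel, spec.n_exposure, rng).astype(float)
        bs = b.copy()
        nz = b != 0
        bs[nz] = b[nz] + rng.normal(0.0, spec.het_sd, size=nz.sum())
        score = (G - G.mean(axis=0)) @ bs
        noise_var = max(0.05, 1.0 - score.var())
        y = score + rng.normal(0.0, np.sqrt(noise_var), size=spec.n_exposure)
        beta, se, p = _marginal_ols(G, y)
        eaf = G.mean(axis=0) / 2.0
        out[f"study{s + 1}"] = _summary_frame(
            spec, panel, beta, se, p, eaf, spec.n_exposure
        )
    return out


def _vectorised_logistic(G: np.ndarray, y: np.ndarray, n_iter: int = 12):
    """Per-variant logistic regression (intercept + dosage), Newton-Raphson
    vectorised across variants.  Returns (beta, se) for the dosage term."""
    n, m = G.shape
    a = np.full(m, np.log(y.mean() / (1 - y.mean())))
    b = np.zeros(m)
    yv = y[:, None].astype(float)
    for _ in range(n_iter):
        eta = a[None, :] + G * b[None, :]
        p = 1.0 / (1.0 + np.exp(-eta))
        w = p * (1 - p)
        resid = yv - p
        ga = resid.sum(axis=0)
        gb = np.einsum("ij,ij->j", G, resid)
        haa = w.sum(axis=0)
        hab = np.einsum("ij,ij->j", G, w)
        hbb = np.einsum("ij,ij->j", G * G, w)
        det = haa * hbb - hab**2
        da = (hbb * ga - hab * gb) / det
        db = (haa * gb - hab * ga) / det
        a += da
        b += db
        if np.max(np.abs(db)) < 1e-10:
            break
    eta = a[None, :] + G * b[None, :]
    p = 1.0 / (1.0 + np.exp(-eta))
    w = p * (1 - p)
    haa = w.sum(axis=0)
    hab = np.einsum("ij,ij->j", G, w)
    hbb = np.einsum("ij,ij->j", G * G, w)
    se = np.sqrt(haa / (haa * hbb - hab**2))
    return b, se


def simulate_outcome_gwas(
    panel: ReferencePanel,
    spec: ScenarioSpec,
    exposure_truth: dict[int, float] = None,
    rng: np.random.Generator = None,
) -> pd.DataFrame:
    """Binary-outcome GWAS under the scenario's causal structure.

    Linear predictor = alpha * (true genetic exposure score) + direct variant
    effects + intercept solving the case fraction; the per-variant logistic
    regressions give (beta, se, p) on the log-odds scale.
    """
    rng = rng or np.random.default_rng(spec.seed + 2)
    if exposure_truth is None:
        exposure_truth = spec.causal_snps_exposure
    m = spec.n_variants
    G = sample_genotypes(panel, spec.n_outcome, rng).astype(float)
    bexp = np.zeros(m)
    for idx, eff in exposure_truth.items():
        bexp[idx] = eff
    direct = np.zeros(m)
    for idx, eff in spec.causal_snps_outcome.items():
        direct[idx] = eff
    gc = G - G.mean(axis=0)
    lin = spec.alpha * (gc @ bexp) + gc @ direct

    def excess(c):
        return np.mean(1.0 / (1.0 + np.exp(-(lin + c)))) - spec.case_fraction

    c = optimize.brentq(excess, -30, 30)
    y = (rng.random(spec.n_outcome) < 1.0 / (1.0 + np.exp(-(lin + c)))).astype(
        np.int8
    )
    beta, se = _vectorised_logistic(G, y)
    p = np.clip(2 * stats.norm.sf(np.abs(beta / se)), 1e-300, 1.0)
    return _summary_frame(spec, panel, beta, se, p, G.mean(axis=0) / 2.0,
                          spec.n_outcome)


# ---------------------------------------------------------------------------
# fast multivariate-normal summary-statistic mode


def ar1_corr(m: int, rho: float) -> np.ndarray:
    """AR(1) correlation matrix rho^|i-j|."""
    idx = np.arange(m)
    return rho ** np.abs(idx[:, None] - idx[None, :])


def mvn_marginal_stats(
    R: np.ndarray,
    b_joint: np.ndarray,
    n: float,
    rng: np.random.Generator,
    chol: np.ndarray = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Fast summary-statistic draw: z ~ N(sqrt(n) R b, R).

    ``b_joint`` holds joint (conditional) effects on the standardised
    genotype/trait scale; marginal true effects are R b.  Returns
    (beta_hat, se) with se = 1/sqrt(n).  Approximate: no genotype sampling,
    no case-control likelihood; intended for large replicate counts.
    """
    m = len(b_joint)
    if chol is None:
        chol = np.linalg.cholesky(R + 1e-10 * np.eye(m))
    se = np.full(m, 1.0 / np.sqrt(n))
    z = np.sqrt(n) * (R @ b_joint) + chol @ rng.standard_normal(m)
    return z * se, se
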