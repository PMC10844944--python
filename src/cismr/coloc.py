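"""Bayesian colocalisation from summary statistics.

Implements the single-causal-variant colocalisation model on Wakefield
approximate Bayes factors: for each variant, the evidence that it is causal
for a trait is ABF = sqrt(V/(V+W)) * exp(z^2 W / (2(V+W))) with V the squared
standard error and W the squared prior SD of the true effect.  The five
pairwise hypotheses (H0 no association; H1/H2 one trait only; H3 two distinct
causal variants; H4 one shared causal variant) get evidences by summing
variant configurations, weighted by per-variant priors p1, p2, p12.

Also provided: stepwise conditional analysis of a region against an LD
matrix (z-space forward selection), pairwise-conditional colocalisation
(coloc run on every marginal/conditional combination of the two traits,
reporting the maximum-PPH4 cell), and the three-trait extension over the 15
sharing configurations with priors p1, p2, p3 by number of traits sharing a
variant.

All evidence sums use log-sum-exp; per-variant ABFs are never exponentiated
directly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .summary_io import LDMatrix

logger = logging.getLogger(__name__)

#: default configuration priors for a variant associated with trait 1 only,
#: trait 2 only, or both
DEFAULT_PRIORS = (1e-4, 1e-4, 1e-5)
#: three-trait priors by number of traits a causal variant is shared by
DEFAULT_MOLOC_PRIORS = (1e-4, 1e-6, 1e-7)
#: effect-size prior SD by trait type
PRIOR_SD = {"quantitative": 0.2, "case_control": 0.15}

COLLINEAR_TOL = 1e-6


def log_abf(beta, se, prior_sd: float) -> np.ndarray:
    """Log Wakefield approximate Bayes factor, vectorised over variants.

    log ABF = 0.5 ln(V/(V+W)) + z^2 W / (2 (V+W)), V = se^2, W = prior_sd^2.
    Monotone increasing in |z| for fixed V, W; tends to 0 as prior_sd -> 0.
    """
    beta = np.asarray(beta, dtype=float)
    se = np.asarray(se, dtype=float)
    if np.any(se <= 0) or prior_sd <= 0:
        raise ValueError("se and prior_sd must be positive")
    v = se**2
    w = prior_sd**2
    z2 = (beta / se) ** 2
    return 0.5 * np.log(v / (v + w)) + z2 * w / (2 * (v + w))


@dataclass
class ColocWindow:
    """Aligned per-variant (beta, se) for two traits in one region."""

    variants: list[str]
    beta1: np.ndarray
    se1: np.ndarray
    beta2: np.ndarray
    se2: np.ndarray
    type1: str = "quantitative"
    type2: str = "case_control"

    def __post_init__(self):
        m = len(self.variants)
        for name in ("beta1", "se1", "beta2", "se2"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != (m,):
                raise ValueError(f"{name} does not match variant list length")
            if np.isnan(arr).any():
                raise ValueError(f"NaN in {name}")
            setattr(self, name, arr)

    @classmethod
    def from_harmonised(cls, df: pd.DataFrame, **kw) -> "ColocWindow":
        keys = (df["chrom"].astype(str) + ":" + df["pos"].astype(str)).tolist()
        return cls(
            keys,
            df["beta_exp"].to_numpy(),
            df["se_exp"].to_numpy(),
            df["beta_out"].to_numpy(),
            df["se_out"].to_numpy(),
            **kw,
        )


@dataclass
class ColocResult:
    pph: np.ndarray  # posteriors of H0..H4
    n_variants: int
    priors: tuple[float, float, float]
    conditional_context: str = "marginal"

    def __post_init__(self):
        s = float(np.sum(self.pph))
        if not np.isclose(s, 1.0, atol=1e-10):
            raise ValueError(f"posteriors sum to {s}, not 1")

    @property
    def pph0(self):
        return float(self.pph[0])

    @property
    def pph1(self):
        return float(self.pph[1])

    @property
    def pph2(self):
        return float(self.pph[2])

    @property
    def pph3(self):
        return float(self.pph[3])

    @property
    def pph4(self):
        return float(self.pph[4])


def _log_distinct_sum(labs: list[np.ndarray]) -> float:
    """log of the sum over assignments of distinct variants to each group of
    the product of group evidences, by inclusion-exclusion (1-3 groups)."""
    g = len(labs)
    S = [logsumexp(a) for a in labs]
    if g == 1:
        return S[0]
    if g == 2:
        both = logsumexp(labs[0] + labs[1])
        val, sign = logsumexp(
            [S[0] + S[1], both], b=[1.0, -1.0], return_sign=True
        )
        return val if sign > 0 else -np.inf
    if g == 3:
        a, b, c = labs
        pab = logsumexp(a + b)
        pac = logsumexp(a + c)
        pbc = logsumexp(b + c)
        pabc = logsumexp(a + b + c)
        terms = [S[0] + S[1] + S[2], S[0] + pbc, S[1] + pac, S[2] + pab,
                 np.log(2.0) + pabc]
        signs = [1.0, -1.0, -1.0, -1.0, 1.0]
        val, sign = logsumexp(terms, b=signs, return_sign=True)
        return val if sign > 0 else -np.inf
    raise ValueError("at most three groups supported")


def coloc_pairwise(
    window: ColocWindow,
    priors: tuple[float, float, float] = DEFAULT_PRIORS,
    conditional_context: str = "marginal",
) -> ColocResult:
    """Five-hypothesis posterior for one trait pair in a window.

    Per-variant log ABFs feed hypothesis log-evidences via log-sum-exp; the
    posteriors are proportional to
    {1, p1 e^L1, p2 e^L2, p1 p2 e^L3, p12 e^L4} where L3 sums over ordered
    pairs of *distinct* causal variants and L4 over a single shared one.
    """
    m = len(window.variants)
    if m < 2:
        raise ValueError("colocalisation needs at least two variants")
    p1, p2, p12 = priors
    lab1 = log_abf(window.beta1, window.se1, PRIOR_SD[window.type1])
    lab2 = log_abf(window.beta2, window.se2, PRIOR_SD[window.type2])

    l1 = logsumexp(lab1)
    l2 = logsumexp(lab2)
    l4 = logsumexp(lab1 + lab2)
    l3 = _log_distinct_sum([lab1, lab2])

    logw = np.array(
        [
            0.0,
            np.log(p1) + l1,
            np.log(p2) + l2,
            np.log(p1) + np.log(p2) + l3,
            np.log(p12) + l4,
        ]
    )
    pph = np.exp(logw - logsumexp(logw))
    pph /= pph.sum()
    return ColocResult(pph, m, priors, conditional_context)


# ---------------------------------------------------------------------------
# stepwise conditional analysis


@dataclass
class Signal:
    key: str
    index: int
    z_marginal: float
    conditional: pd.DataFrame  # per-variant beta/se/z conditioned on the
    #                            other selected signals


def _conditional_z(
    z: np.ndarray, R: np.ndarray, selected: list[int]
) -> tuple[np.ndarray, np.ndarray]:
    """z of every variant conditional on the selected set, with a validity
    mask (False where 1 - r' R_SS^-1 r is at or below the collinearity
    tolerance; those variants get conditional z = 0)."""
    m = z.size
    if not selected:
        return z.copy(), np.ones(m, dtype=bool)
    S = np.asarray(selected)
    rss = R[np.ix_(S, S)]
    rjs = R[:, S]  # m x |S|
    shrink = rjs @ np.linalg.solve(rss, z[S])
    denom2 = 1.0 - np.einsum("ij,ij->i", rjs @ np.linalg.inv(rss), rjs)
    ok = denom2 > COLLINEAR_TOL
    zc = np.zeros(m)
    zc[ok] = (z[ok] - shrink[ok]) / np.sqrt(denom2[ok])
    if (~ok).sum() > len(S):
        logger.warning(
            "%d variants collinear with the selected set; conditional z set "
            "to 0", int((~ok).sum()) - len(S),
        )
    return zc, ok


def stepwise_conditional(
    stats: pd.DataFrame,
    ld: LDMatrix,
    p_select: float = 5e-8,
) -> list[Signal]:
    """Forward selection of conditionally independent association signals.

    ``stats`` needs beta/se columns aligned with ``ld``.  At each step the
    variant with the largest conditional |z| is added while its two-sided
    normal p-value is below ``p_select``.  Each returned signal carries the
    region's statistics conditioned on all *other* selected signals (betas
    shrunk with z, standard errors preserved), which isolates that signal for
    colocalisation.
    """
    from scipy import stats as sps

    z = (stats["beta"] / stats["se"]).to_numpy(dtype=float)
    se = stats["se"].to_numpy(dtype=float)
    R = ld.r
    z_crit = float(sps.norm.isf(p_select / 2))

    selected: list[int] = []
    while True:
        zc, ok = _conditional_z(z, R, selected)
        zc[selected] = 0.0
        j = int(np.argmax(np.abs(zc)))
        if abs(zc[j]) < z_crit:
            break
        selected.append(j)
        if len(selected) >= len(z):
            break

    signals = []
    for idx in selected:
        others = [s for s in selected if s != idx]
        zc, _ = _conditional_z(z, R, others)
        cond = pd.DataFrame(
            {
                "variant": ld.variants,
                "beta": zc * se,
                "se": se,
                "z": zc,
            }
        )
        signals.append(Signal(ld.variants[idx], idx, float(z[idx]), cond))
    return signals


# ---------------------------------------------------------------------------
# pairwise-conditional colocalisation


@dataclass
class PwcocoResult:
    best: ColocResult
    grid: list[ColocResult]
    signals1: list[Signal]
    signals2: list[Signal]


def _datasets(
    beta: np.ndarray, se: np.ndarray, signals: list[Signal]
) -> list[tuple[str, np.ndarray, np.ndarray]]:
    """Marginal stats plus, when a trait has >= 2 signals, one conditional
    dataset per signal (conditioned on all the others)."""
    out = [("marginal", beta, se)]
    if len(signals) >= 2:
        for s in signals:
            out.append(
                (
                    f"signal:{s.key}",
                    s.conditional["beta"].to_numpy(),
                    s.conditional["se"].to_numpy(),
                )
            )
    return out


def pwcoco(
    window: ColocWindow,
    ld: LDMatrix,
    priors: tuple[float, float, float] = DEFAULT_PRIORS,
    p_select: float = 5e-8,
) -> PwcocoResult:
    """Colocalisation over every marginal/conditional combination.

    Each trait is decomposed into conditionally independent signals; coloc
    runs on the product grid of {marginal, per-signal conditional} statistics
    of trait 1 x trait 2, and the cell with maximal PPH4 is the headline
    (the full grid is retained).  Single-signal traits contribute only their
    marginal statistics, so the grid degenerates to marginal x marginal.
    """
    if list(ld.variants) != list(window.variants):
        ld = ld.submatrix(window.variants)
    sig1 = stepwise_conditional(
        pd.DataFrame({"beta": window.beta1, "se": window.se1}), ld, p_select
    )
    sig2 = stepwise_conditional(
        pd.DataFrame({"beta": window.beta2, "se": window.se2}), ld, p_select
    )
    grid = []
    for lab1, b1, s1 in _datasets(window.beta1, window.se1, sig1):
        for lab2, b2, s2 in _datasets(window.beta2, window.se2, sig2):
            w = ColocWindow(
                window.variants, b1, s1, b2, s2, window.type1, window.type2
            )
            grid.append(
                coloc_pairwise(
                    w, priors, conditional_context=f"{lab1} x {lab2}"
                )
            )
    best = max(grid, key=lambda r: r.pph4)
    return PwcocoResult(best, grid, sig1, sig2)


# ---------------------------------------------------------------------------
# three-trait colocalisation

#: the 15 sharing configurations of three traits: which traits are
#: associated, partitioned into groups sharing one causal variant
#: (groups separated by "."; letters a/b/c = traits 1/2/3)
MOLOC_CONFIGS: list[tuple[str, list[list[int]]]] = [
    ("h0", []),
    ("a", [[0]]),
    ("b", [[1]]),
    ("c", [[2]]),
    ("ab", [[0, 1]]),
    ("ac", [[0, 2]]),
    ("bc", [[1, 2]]),
    ("a.b", [[0], [1]]),
    ("a.c", [[0], [2]]),
    ("b.c", [[1], [2]]),
    ("ab.c", [[0, 1], [2]]),
    ("ac.b", [[0, 2], [1]]),
    ("bc.a", [[1, 2], [0]]),
    ("a.b.c", [[0], [1], [2]]),
    ("abc", [[0, 1, 2]]),
]


@dataclass
class MolocResult:
    posteriors: dict[str, float]
    n_variants: int
    priors: tuple[float, float, float]

    def __post_init__(self):
        s = sum(self.posteriors.values())
        if not np.isclose(s, 1.0, atol=1e-10):
            raise ValueError(f"configuration posteriors sum to {s}")

    @property
    def posterior_abc(self) -> float:
        """Probability that all three traits share one causal variant."""
        return self.posteriors["abc"]


def moloc_three(
    stats: list[pd.DataFrame],
    trait_types: tuple[str, str, str] = (
        "quantitative", "quantitative", "case_control",
    ),
    priors: tuple[float, float, float] = DEFAULT_MOLOC_PRIORS,
) -> MolocResult:
    """Posterior over the 15 sharing configurations of three traits.

    ``stats`` holds three aligned frames with beta/se columns.  A causal
    variant associated with one, two or all three traits carries prior p1,
    p2, p3; a configuration's evidence sums, over assignments of distinct
    variants to its trait groups, the product of within-group ABF products.
    """
    m = len(stats[0])
    if any(len(s) != m for s in stats):
        raise ValueError("trait stats not aligned")
    if m < 2:
        raise ValueError("colocalisation needs at least two variants")
    labs = [
        log_abf(s["beta"].to_numpy(), s["se"].to_numpy(), PRIOR_SD[t])
        for s, t in zip(stats, trait_types)
    ]
    logp = np.log(np.asarray(priors))
    names = []
    logw = []
    for name, groups in MOLOC_CONFIGS:
        names.append(name)
        if not groups:
            logw.append(0.0)
            continue
        prior = sum(logp[len(g) - 1] for g in groups)
        group_labs = [sum(labs[t] for t in g) for g in groups]
        logw.append(prior + _log_distinct_sum(group_labs))
    logw = np.array(logw)
    post = np.exp(logw - logsumexp(logw))
    post /= post.sum()
    return MolocResult(dict(zip(names, post.astype(float))), m, priors)
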