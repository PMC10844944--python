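"""Causal-effect estimation from cis instruments.

Single-SNP instruments use the Wald ratio with a first-order delta-method
standard error (including the exposure-uncertainty term).  Multi-SNP
instruments use generalised (correlated-variant) inverse-variance weighting:
a GLS fit of outcome betas on exposure betas with covariance D R D, where R
is the signed LD correlation matrix and D the diagonal of outcome SEs, with
multiplicative random-effects inflation phi = max(1, Q/(k-1)) of the
standard error so that weak-LD residual heterogeneity never deflates it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .instruments import Instrument

#: ridge added to the LD diagonal when its smallest eigenvalue < RIDGE_EIG_TOL
RIDGE = 1e-6
RIDGE_EIG_TOL = 1e-8
Z95 = 1.959963984540054  # two-sided 95% normal quantile


@dataclass
class MREstimate:
    """Causal log-odds of outcome per SD of exposure, with diagnostics."""

    protein_id: str
    outcome_id: str
    beta: float
    se: float
    method: str  # wald_ratio | ivw_correlated
    k_snps: int
    q_gls: float = 0.0
    phi: float = 1.0

    or_value: float = field(init=False)
    ci_low: float = field(init=False)
    ci_high: float = field(init=False)
    pvalue: float = field(init=False)

    def __post_init__(self):
        self.or_value = float(np.exp(self.beta))
        self.ci_low = float(np.exp(self.beta - Z95 * self.se))
        self.ci_high = float(np.exp(self.beta + Z95 * self.se))
        self.pvalue = float(2 * stats.norm.sf(abs(self.beta / self.se)))


def wald_ratio(
    bx: float,
    sex: float,
    by: float,
    sey: float,
    protein_id: str = "",
    outcome_id: str = "",
) -> MREstimate:
    """Single-variant causal estimate by/bx.

    First-order delta-method SE: sqrt(sey^2/bx^2 + by^2 sex^2 / bx^4); the
    second (exposure-uncertainty) term is cheap and conservative.
    """
    if bx == 0:
        raise ValueError("exposure beta is zero: not an instrument")
    beta = by / bx
    se = float(np.sqrt(sey**2 / bx**2 + by**2 * sex**2 / bx**4))
    return MREstimate(protein_id, outcome_id, float(beta), se, "wald_ratio", 1)


def _regularise(R: np.ndarray) -> np.ndarray:
    """Ridge-adjust the LD correlation when nearly singular."""
    eigmin = float(np.linalg.eigvalsh(R).min())
    if eigmin < RIDGE_EIG_TOL:
        R = R + RIDGE * np.eye(R.shape[0])
    return R


def ivw_correlated_arrays(
    bx: np.ndarray,
    by: np.ndarray,
    sey: np.ndarray,
    R: np.ndarray,
    random_effects: bool = True,
) -> tuple[float, float, float, float]:
    """Correlated-variant IVW on raw arrays.

    Returns (beta, se, q_gls, phi).  With Omega = D R D (D = diag(sey)):
    beta = (Bx' Om^-1 Bx)^-1 Bx' Om^-1 By, base variance its inverse,
    Q = residual' Om^-1 residual, phi = max(1, Q/(k-1)) applied
    multiplicatively when ``random_effects`` (phi = 1 when k = 1 is not
    reachable here; k >= 2 enforced by the caller).
    """
    bx = np.asarray(bx, dtype=float)
    by = np.asarray(by, dtype=float)
    sey = np.asarray(sey, dtype=float)
    k = bx.size
    R = _regularise(np.asarray(R, dtype=float))
    omega = R * np.outer(sey, sey)
    try:
        cho = np.linalg.cholesky(omega)
    except np.linalg.LinAlgError as exc:
        cond = np.linalg.cond(omega)
        raise np.linalg.LinAlgError(
            f"singular Omega after ridge (condition number {cond:.3g})"
        ) from exc
    oi_bx = np.linalg.solve(cho.T, np.linalg.solve(cho, bx))
    oi_by = np.linalg.solve(cho.T, np.linalg.solve(cho, by))
    xtx = float(bx @ oi_bx)
    beta = float(bx @ oi_by) / xtx
    base_var = 1.0 / xtx
    resid = by - bx * beta
    q = float(resid @ np.linalg.solve(cho.T, np.linalg.solve(cho, resid)))
    phi = max(1.0, q / (k - 1)) if (random_effects and k > 1) else 1.0
    se = float(np.sqrt(phi * base_var))
    return beta, se, q, phi


def ivw_correlated(
    instrument: Instrument,
    outcome_id: str = "",
    random_effects: bool = True,
) -> MREstimate:
    """Correlated-variant IVW estimate for a multi-SNP instrument (k >= 2)."""
    if instrument.k < 2:
        raise ValueError("ivw_correlated requires k >= 2 SNPs")
    beta, se, q, phi = ivw_correlated_arrays(
        instrument.snps["beta_exp"].to_numpy(),
        instrument.snps["beta_out"].to_numpy(),
        instrument.snps["se_out"].to_numpy(),
        instrument.ld.r,
        random_effects=random_effects,
    )
    return MREstimate(
        instrument.protein_id, outcome_id, beta, se, "ivw_correlated",
        instrument.k, q, phi,
    )


def estimate(
    instrument: Instrument,
    outcome_id: str = "",
    random_effects: bool = True,
) -> MREstimate:
    """Dispatch: Wald ratio for single-SNP instruments, else correlated IVW."""
    if instrument.k == 1:
        row = instrument.snps.iloc[0]
        est = wald_ratio(
            row["beta_exp"], row["se_exp"], row["beta_out"], row["se_out"],
            instrument.protein_id, outcome_id,
        )
        return est
    return ivw_correlated(instrument, outcome_id, random_effects)


@dataclass
class LeaveOneOutSet:
    base: MREstimate
    per_snp: list[tuple[str, MREstimate]]
    influential: list[str]  # dropped-SNP keys whose removal moves the estimate
    #                         outside the base CI or flips its sign

    def max_shift(self) -> tuple[str, float]:
        key, est = max(
            self.per_snp, key=lambda kv: abs(kv[1].beta - self.base.beta)
        )
        return key, abs(est.beta - self.base.beta)


def leave_one_out(
    instrument: Instrument, outcome_id: str = ""
) -> LeaveOneOutSet:
    """Re-estimate dropping one SNP at a time (k >= 3; k-1 = 1 falls back to
    the Wald ratio of the surviving SNP via :func:`estimate`)."""
    if instrument.k < 2:
        raise ValueError("leave-one-out needs a multi-SNP instrument")
    base = estimate(instrument, outcome_id)
    per_snp = []
    influential = []
    ci_lo = base.beta - Z95 * base.se
    ci_hi = base.beta + Z95 * base.se
    for key in instrument.keys:
        sub = estimate(instrument.drop(key), outcome_id)
        per_snp.append((key, sub))
        outside = not (ci_lo <= sub.beta <= ci_hi)
        flipped = np.sign(sub.beta) != np.sign(base.beta)
        if outside or flipped:
            influential.append(key)
    return LeaveOneOutSet(base, per_snp, influential)
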