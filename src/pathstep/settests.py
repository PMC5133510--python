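"""Variant-set association statistics: variance-component and burden.

Both tests consume the per-variant score vector ``U`` and its null
covariance ``C`` produced by the fitted familial null model:

* variance-component (SKAT-like):  ``Q = sum_j w_j U_j^2``, null
  distribution a positive mixture of chi-square(1) with weights equal to
  the eigenvalues of ``W^{1/2} C W^{1/2}``;
* burden (CMC-like):  ``S = sum_j w_j U_j``, ``Q = S^2 / (w' C w)``,
  chi-square(1) null — equivalent to the score test of the trait on the
  weighted genotype sum.

Default weighting follows rare-variant practice: the variance-component
test uses Beta(1, 25) density weights in the minor-allele frequency
(upweighting rare variants), the burden test flat weights ``w_j = 1``.
Common variants are not excluded; any MAF filtering happens upstream.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import beta as beta_dist
from scipy.stats import chi2

from .qfc import mixture_chi2_sf

__all__ = ["WeightScheme", "SetTestResult", "beta_maf_weights",
           "resolve_weights", "vc_test", "burden_test"]

_EIG_DROP = 1e-10  # relative threshold for numerically-zero eigenvalues


@dataclass(frozen=True)
class WeightScheme:
    """Per-variant weighting rule.

    kind "beta_maf" evaluates the Beta(a, b) density at each variant's
    MAF (defaults a=1, b=25: strictly decreasing in MAF); kind "flat"
    gives every variant the same weight.
    """

    kind: str = "beta_maf"
    a: float = 1.0
    b: float = 25.0
    flat_value: float = 1.0

    def __post_init__(self):
        if self.kind not in ("beta_maf", "flat"):
            raise ValueError(f"unknown weight kind {self.kind!r}")
        if self.kind == "beta_maf" and (self.a <= 0 or self.b <= 0):
            raise ValueError("beta weight parameters must be positive")


VC_DEFAULT_WEIGHTS = WeightScheme("beta_maf", 1.0, 25.0)
BURDEN_DEFAULT_WEIGHTS = WeightScheme("flat")


@dataclass(frozen=True)
class SetTestResult:
    set_id: str
    method: str                  # "VC" or "Burden"
    n_variants_tested: int
    statistic: float
    p_value: float
    pvalue_method: str           # davies | liu | saddlepoint | normal
    untestable: bool = False

    def __post_init__(self):
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError("p_value outside [0, 1]")


def beta_maf_weights(mafs, a: float = 1.0, b: float = 25.0) -> np.ndarray:
    """Beta-density weights evaluated at each MAF.

    With the defaults (1, 25) this is ``25 * (1 - maf)^24``.
    """
    mafs = np.asarray(mafs, dtype=float)
    if a <= 0 or b <= 0:
        raise ValueError("beta parameters must be positive")
    if np.any(mafs <= 0) or np.any(mafs > 0.5):
        raise ValueError("MAFs must lie in (0, 0.5]; monomorphic variants "
                         "must be handled upstream")
    return beta_dist.pdf(mafs, a, b)


def resolve_weights(weights, mafs=None) -> np.ndarray:
    """Turn a WeightScheme or explicit array into a weight vector."""
    if isinstance(weights, WeightScheme):
        if weights.kind == "beta_maf":
            if mafs is None:
                raise ValueError("beta_maf weights require MAFs")
            return beta_maf_weights(mafs, weights.a, weights.b)
        m = len(mafs) if mafs is not None else None
        if m is None:
            raise ValueError("flat weights need MAFs (for the length)")
        return np.full(m, weights.flat_value, dtype=float)
    w = np.asarray(weights, dtype=float)
    if np.any(w < 0):
        raise ValueError("weights must be non-negative")
    return w


def _untestable(set_id, method, m) -> SetTestResult:
    return SetTestResult(set_id, method, m, 0.0, 1.0, "normal",
                         untestable=True)


def vc_test(U, C, weights=VC_DEFAULT_WEIGHTS, mafs=None,
            set_id: str = "") -> SetTestResult:
    """Variance-component (SKAT-like) set test from scores (U, C)."""
    U = np.asarray(U, dtype=float).ravel()
    C = np.atleast_2d(np.asarray(C, dtype=float))
    m = U.size
    if C.shape != (m, m):
        raise ValueError("C must be m x m matching U")
    w = resolve_weights(weights, mafs)
    if w.size != m:
        raise ValueError("weight vector length mismatch")
    if not np.any(w > 0):
        return _untestable(set_id, "VC", m)
    q = float(np.sum(w * U ** 2))
    sw = np.sqrt(w)
    A = (sw[:, None] * C) * sw[None, :]
    lam = np.linalg.eigvalsh((A + A.T) / 2.0)
    lam = lam[lam > _EIG_DROP * max(lam.max(initial=0.0), 1e-300)]
    if lam.size == 0:  # all variants monomorphic/annihilated
        return _untestable(set_id, "VC", m)
    p, method = mixture_chi2_sf(q, lam)
    return SetTestResult(set_id, "VC", m, q, p, method)


def burden_test(U, C, weights=BURDEN_DEFAULT_WEIGHTS, mafs=None,
                set_id: str = "") -> SetTestResult:
    """Burden (CMC-like) set test from scores (U, C)."""
    U = np.asarray(U, dtype=float).ravel()
    C = np.atleast_2d(np.asarray(C, dtype=float))
    m = U.size
    if C.shape != (m, m):
        raise ValueError("C must be m x m matching U")
    w = resolve_weights(weights, mafs)
    if w.size != m:
        raise ValueError("weight vector length mismatch")
    s = float(w @ U)
    var_s = float(w @ C @ w)
    if var_s <= 0:
        return _untestable(set_id, "Burden", m)
    q = s * s / var_s
    p = float(chi2.sf(q, df=1))
    return SetTestResult(set_id, "Burden", m, q, p, "normal")
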