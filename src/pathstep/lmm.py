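"""Kinship-covariance linear mixed model fitted by REML.

The null model for a quantitative trait ``y`` on a family cohort is

    y = X beta + g + e,   g ~ N(0, sigma2_g * 2 Phi),  e ~ N(0, sigma2_e I)

with ``Phi`` the theoretical kinship matrix.  Variance components are
estimated by restricted maximum likelihood using a one-time
eigendecomposition ``2 Phi = Q diag(lam) Q^T``: rotating ``y`` and ``X``
by ``Q^T`` diagonalises the covariance, ``V = sigma2 * D(h2)`` with
``D = h2 * lam + (1 - h2)`` and ``h2 = sigma2_g / (sigma2_g + sigma2_e)``,
so the restricted likelihood is profiled down to a smooth 1-D function
of the heritability and maximised by bounded Brent search.  The fit is
deterministic.

The fitted :class:`FamilialLMMResults` carries everything set tests
need: per-variant score statistics ``U_j = g_j' V^{-1} (y - X beta)``
and their null covariance ``C = G' P G`` with
``P = V^{-1} - V^{-1} X (X' V^{-1} X)^{-1} X' V^{-1}``.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

from .kinship import KinshipMatrix
from .settests import (BURDEN_DEFAULT_WEIGHTS, VC_DEFAULT_WEIGHTS,
                       SetTestResult, burden_test, vc_test)

__all__ = ["FamilialLMM", "FamilialLMMResults"]

_H2_UPPER = 1.0 - 1e-6


class FamilialLMM:
    """Linear mixed model with familial covariance ``2*Phi``.

    Parameters
    ----------
    endog : (n,) array
        Quantitative trait.
    exog : (n, p) array
        Fixed-effect design including the intercept column.
    kinship : KinshipMatrix or (n, n) array
        Theoretical kinship ``Phi``; its doubled form is the polygenic
        covariance multiplier.  When a :class:`KinshipMatrix` is passed
        its cached eigendecomposition is reused across fits, which is
        what makes per-replicate refitting cheap in simulation studies.
    ids : list of str, optional
        Individual ids aligned with ``endog`` rows (required for
        id-checked genotype alignment later).
    exog_names : list of str, optional
    """

    def __init__(self, endog, exog, kinship, ids=None, exog_names=None):
        y = np.asarray(endog, dtype=float).ravel()
        X = np.atleast_2d(np.asarray(exog, dtype=float))
        if X.shape[0] != y.size:
            raise ValueError("endog and exog row counts differ")
        if np.linalg.matrix_rank(X) < X.shape[1]:
            bad = _collinear_columns(X, exog_names)
            raise ValueError(f"exog is rank deficient; collinear columns: {bad}")
        if isinstance(kinship, KinshipMatrix):
            if ids is not None:
                kinship = kinship.reindex(list(ids))
            elif len(kinship.ids) != y.size:
                raise ValueError("kinship dimension does not match endog")
            self._kin = kinship
        else:
            phi = np.asarray(kinship, dtype=float)
            if phi.shape != (y.size, y.size):
                raise ValueError("kinship dimension does not match endog")
            self._kin = KinshipMatrix(
                ids if ids is not None else [str(i) for i in range(y.size)],
                phi)
        self.endog = y
        self.exog = X
        self.ids = list(ids) if ids is not None else list(self._kin.ids)
        self.exog_names = (list(exog_names) if exog_names is not None
                           else [f"x{i}" for i in range(X.shape[1])])
        self.nobs = y.size

    @classmethod
    def from_dataframe(cls, data: pd.DataFrame, response: str,
                       covariates: list[str], kinship: KinshipMatrix,
                       id_col: str = "individual_id") -> "FamilialLMM":
        """Build the model from a collapsed-phenotype table.

        Adds an intercept, drops rows with any missing response or
        covariate, and reorders the kinship matrix to the retained ids.
        """
        cols = [id_col, response] + list(covariates)
        df = data[cols].dropna()
        if df[id_col].duplicated().any():
            raise ValueError("duplicate individual ids in phenotype table")
        ids = df[id_col].astype(str).tolist()
        X = np.column_stack([np.ones(len(df))] +
                            [df[c].to_numpy(dtype=float) for c in covariates])
        return cls(df[response].to_numpy(dtype=float), X, kinship,
                   ids=ids, exog_names=["intercept"] + list(covariates))

    # -- fitting -------------------------------------------------------

    def fit(self) -> "FamilialLMMResults":
        """REML fit; returns a results object."""
        lam, Q = self._kin.eig()
        y, X = self.endog, self.exog
        yt = Q.T @ y
        Xt = Q.T @ X
        n, p = X.shape

        if lam.max() - lam.min() < 1e-8:
            # 2*Phi proportional to I: variance components confounded
            warnings.warn("kinship is (a multiple of) the identity; "
                          "heritability is unidentifiable, returning the "
                          "h2 = 0 boundary fit", stacklevel=2)
            return self._results_at(0.0, lam, Q, yt, Xt)

        def neg_restricted_ll(h2):
            return -_profile_reml_ll(h2, lam, yt, Xt)[0]

        opt = minimize_scalar(neg_restricted_ll, bounds=(0.0, _H2_UPPER),
                              method="bounded",
                              options={"xatol": 1e-9})
        h2 = float(opt.x)
        # bounded Brent can stall just inside the boundary; check ends
        for cand in (0.0, _H2_UPPER):
            if neg_restricted_ll(cand) < neg_restricted_ll(h2):
                h2 = cand
        return self._results_at(h2, lam, Q, yt, Xt)

    def _results_at(self, h2, lam, Q, yt, Xt) -> "FamilialLMMResults":
        ll, beta, sigma2, d = _profile_reml_ll(h2, lam, yt, Xt,
                                               return_all=True)
        return FamilialLMMResults(self, h2=h2, beta=beta, sigma2=sigma2,
                                  reml_loglik=ll, lam=lam, Q=Q, yt=yt,
                                  Xt=Xt, d=d)


class FamilialLMMResults:
    """Fitted null model: estimates, diagnostics and score machinery."""

    def __init__(self, model, *, h2, beta, sigma2, reml_loglik,
                 lam, Q, yt, Xt, d):
        self.model = model
        self.h2 = float(h2)
        self.params = np.asarray(beta, dtype=float)
        self.sigma2 = float(sigma2)               # total variance
        self.sigma2_g = self.h2 * self.sigma2
        self.sigma2_e = (1.0 - self.h2) * self.sigma2
        self.reml_loglik = float(reml_loglik)
        self._lam, self._Q, self._yt, self._Xt, self._d = lam, Q, yt, Xt, d
        self._rt = yt - Xt @ self.params          # rotated residuals
        Dinv_Xt = Xt / d[:, None]
        self._XtVX = Xt.T @ Dinv_Xt               # X' D^-1 X (sigma2-free)
        self._XtVX_inv = np.linalg.inv(self._XtVX)
        self.nobs = model.nobs
        self.df_resid = model.nobs - Xt.shape[1]

    # -- basic accessors ----------------------------------------------

    @property
    def fe_names(self):
        return self.model.exog_names

    @property
    def resid(self) -> np.ndarray:
        """Marginal residuals ``y - X beta`` in the original basis."""
        return self._Q @ self._rt

    def bse(self) -> np.ndarray:
        return np.sqrt(np.diag(self.cov_params()))

    def cov_params(self) -> np.ndarray:
        return self.sigma2 * self._XtVX_inv

    def solve_v(self, b) -> np.ndarray:
        """Apply ``V^{-1} = (sigma2_g 2Phi + sigma2_e I)^{-1}``."""
        b = np.asarray(b, dtype=float)
        one_d = b.ndim == 1
        bt = self._Q.T @ (b[:, None] if one_d else b)
        out = self._Q @ (bt / (self.sigma2 * self._d)[:, None])
        return out.ravel() if one_d else out

    # -- score statistics ---------------------------------------------

    def score_statistics(self, G, ids=None):
        """Per-variant scores and their null covariance for a set.

        Parameters
        ----------
        G : (n, m) array
            Alternate-allele counts for the model's individuals (rows in
            model order unless ``ids`` re-specifies them).  Missing
            entries (NaN) are mean-imputed per variant, which preserves
            the zero mean of the scores.

        Returns
        -------
        U : (m,) array  — scores ``g_j' V^{-1} (y - X beta)``
        C : (m, m) array — ``G' P G``, symmetric PSD; monomorphic
            variants yield ``U_j = 0`` and a zero row/column.
        """
        G = np.asarray(G, dtype=float)
        if G.ndim == 1:
            G = G[:, None]
        if ids is not None:
            order = {iid: i for i, iid in enumerate(ids)}
            try:
                idx = [order[i] for i in self.model.ids]
            except KeyError as e:
                raise ValueError(f"genotype ids missing individual {e}") from e
            G = G[idx]
        if G.shape[0] != self.nobs:
            raise ValueError("genotype rows do not match model individuals")
        G = _mean_impute(G)
        Gt = self._Q.T @ G
        d = self._d
        U = Gt.T @ (self._rt / d) / self.sigma2
        Dinv_Gt = Gt / d[:, None]
        XtVG = self._Xt.T @ Dinv_Gt
        C = (Gt.T @ Dinv_Gt - XtVG.T @ self._XtVX_inv @ XtVG) / self.sigma2
        C = (C + C.T) / 2.0
        return U, C

    # -- set tests ------------------------------------------------------

    def vc_test(self, G, mafs=None, weights=VC_DEFAULT_WEIGHTS,
                set_id: str = "", ids=None) -> SetTestResult:
        """Variance-component set test on the genotype block ``G``."""
        U, C = self.score_statistics(G, ids=ids)
        if mafs is None:
            mafs = _sample_mafs(G)
        return vc_test(U, C, weights=weights, mafs=mafs, set_id=set_id)

    def burden_test(self, G, mafs=None, weights=BURDEN_DEFAULT_WEIGHTS,
                    set_id: str = "", ids=None) -> SetTestResult:
        """Burden set test on the genotype block ``G``."""
        U, C = self.score_statistics(G, ids=ids)
        if mafs is None:
            mafs = _sample_mafs(G)
        return burden_test(U, C, weights=weights, mafs=mafs, set_id=set_id)

    # -- reporting -----------------------------------------------------

    def summary(self) -> str:
        lines = ["Familial linear mixed model (REML)",
                 "=" * 50,
                 f"n obs            {self.nobs}",
                 f"REML loglik      {self.reml_loglik:.4f}",
                 f"sigma2_g         {self.sigma2_g:.4f}",
                 f"sigma2_e         {self.sigma2_e:.4f}",
                 f"heritability h2  {self.h2:.4f}",
                 "-" * 50,
                 f"{'coef':<14}{'estimate':>12}{'std err':>12}"]
        for name, b, se in zip(self.fe_names, self.params, self.bse()):
            lines.append(f"{name:<14}{b:>12.4f}{se:>12.4f}")
        lines.append("=" * 50)
        return "\n".join(lines)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"coef": self.fe_names, "estimate": self.params,
                             "std_err": self.bse()})


# ----------------------------------------------------------------------


def _profile_reml_ll(h2, lam, yt, Xt, return_all=False):
    """Restricted log-likelihood profiled over beta and total variance.

    Up to an additive constant:
        -1/2 [ (n-p)(log s2 + 1) + sum(log d) + logdet(X' D^-1 X) ]
    with s2 the REML variance estimate at this h2.
    """
    n, p = Xt.shape
    d = h2 * lam + (1.0 - h2)
    if d.min() <= 0:
        return (-np.inf, None, None, d) if return_all else (-np.inf,)
    Dinv_Xt = Xt / d[:, None]
    XtVX = Xt.T @ Dinv_Xt
    beta = np.linalg.solve(XtVX, Dinv_Xt.T @ yt)
    r = yt - Xt @ beta
    s2 = float(r @ (r / d)) / (n - p)
    sign, logdet = np.linalg.slogdet(XtVX)
    ll = -0.5 * ((n - p) * (np.log(s2) + 1.0) + np.sum(np.log(d)) + logdet)
    if return_all:
        return ll, beta, s2, d
    return (ll,)


def _mean_impute(G: np.ndarray) -> np.ndarray:
    if not np.isnan(G).any():
        return G
    G = G.copy()
    col_mean = np.nanmean(G, axis=0)
    col_mean = np.where(np.isnan(col_mean), 0.0, col_mean)
    nan_r, nan_c = np.nonzero(np.isnan(G))
    G[nan_r, nan_c] = col_mean[nan_c]
    return G


def _sample_mafs(G: np.ndarray) -> np.ndarray:
    """Folded sample allele frequency per variant, clipped away from 0."""
    G = np.asarray(G, dtype=float)
    if G.ndim == 1:
        G = G[:, None]
    freq = np.nanmean(G, axis=0) / 2.0
    maf = np.minimum(freq, 1.0 - freq)
    return np.clip(maf, 1e-8, 0.5)


def _collinear_columns(X, names):
    names = names or [f"x{i}" for i in range(X.shape[1])]
    bad = []
    for j in range(X.shape[1]):
        others = np.delete(X, j, axis=1)
        if np.linalg.matrix_rank(others) == np.linalg.matrix_rank(X):
            bad.append(names[j])
    return bad or names
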