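"""Binomial logit mixed models for kit survival at birth.

The response is the number of kits born alive out of kits born per
kindling, modelled on the logit scale with fixed effects of parity class,
kindling season and z-standardised inbreeding covariates, plus a polygenic
"animal" random effect attached to the dam of each record:

    logit P(survival) = parity + season + z.covariates + a_dam,
    a ~ N(0, sigma2_a * A),

where A is the additive relationship matrix of the dams (and their
ancestors).  The marginal likelihood is maximised under the Laplace
approximation; the random-effect covariance enters through Henderson's
sparse inverse A^-1, so every inner step is a sparse solve.

The fitting strategy is two-stage: a fast profiling stage alternates
penalized IRLS over (beta, a) with a bounded 1-D search over log sigma_a
(the objective evaluated at the joint mode), after which the default
``method="laplace"`` refines (beta, log sigma_a) with bounded quasi-Newton
against the exact Laplace objective (inner mode over a only).
``method="profile"`` stops after the first stage and is appropriate for
large simulation studies where thousands of fits are needed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, sparse
from scipy.sparse.linalg import splu
from scipy.special import expit, gammaln
from sklearn.base import BaseEstimator

from .pedigree import Pedigree, a_inverse, dummy_id

__all__ = [
    "BALLOU_COVARIATES",
    "KALINOWSKI_COVARIATES",
    "ModelSpec",
    "ModelFit",
    "StandardisedCovariate",
    "PedigreeGLMM",
    "encode_season",
    "encode_parity",
    "standardise",
    "aicc",
    "laplace_loglik",
    "prepare_analysis_frame",
    "fit_glmm",
]

BALLOU_COVARIATES = ("z.F_D", "z.F_L", "z.F_A-BL")
KALINOWSKI_COVARIATES = ("z.F_NEWD", "z.F_NEWL", "z.F_A-KL")

#: raw coefficient feeding each standardised covariate: (role, column)
_COVARIATE_SOURCE = {
    "z.F_D": ("dam", "F"),
    "z.F_L": ("litter", "F"),
    "z.F_A-BL": ("litter", "F_ab"),
    "z.F_NEWD": ("dam", "F_new"),
    "z.F_NEWL": ("litter", "F_new"),
    "z.F_A-KL": ("litter", "F_ak"),
}

PARITY_LEVELS = ("P1", "P2", "P3_10", "P11plus")
#: report labels for the non-reference parity classes
PARITY_LABELS = {"P2": "Parity A", "P3_10": "Parity B", "P11plus": "Parity C"}


# -- covariate encodings -----------------------------------------------------


def encode_season(dates) -> np.ndarray:
    """Kindling season: ``summer`` iff 15 June <= (month, day) <= 15 September,
    both boundaries inclusive; everything else is ``non_summer``."""
    arr = pd.to_datetime(pd.Series(np.atleast_1d(dates)))
    md = list(zip(arr.dt.month, arr.dt.day))
    out = np.array(
        ["summer" if (6, 15) <= t <= (9, 15) else "non_summer" for t in md], dtype=object
    )
    return out if np.ndim(dates) else out[0]

def encode_parity(parity) -> np.ndarray:
    """Parity class: 1 -> P1 (reference), 2 -> P2, 3-10 -> P3_10, 11+ -> P11plus."""
    arr = np.atleast_1d(np.asarray(parity, dtype=int))
    if (arr < 1).any():
        raise ValueError("parity must be >= 1")
    out = np.where(
        arr == 1, "P1", np.where(arr == 2, "P2", np.where(arr <= 10, "P3_10", "P11plus"))
    ).astype(object)
    return out if np.ndim(parity) else out[0]


@dataclass(frozen=True)
class StandardisedCovariate:
    """A covariate together with the centering/scaling that produced z."""

    raw: np.ndarray
    center: float
    scale: float
    z: np.ndarray
    method: str


def standardise(values, method: str = "z_1sd") -> StandardisedCovariate:
    """z-standardise a covariate.

    ``z_1sd`` divides the centred values by the sample SD (ddof=1);
    ``gelman_2sd`` divides by twice the sample SD, which puts continuous
    covariates on the scale of a binary predictor.
    """
    raw = np.asarray(values, dtype=float)
    if np.unique(raw).size < 2:
        raise ValueError("cannot standardise a covariate with zero variance")
    center = float(raw.mean())
    sd = float(raw.std(ddof=1))
    if method == "z_1sd":
        scale = sd
    elif method == "gelman_2sd":
        scale = 2.0 * sd
    else:
        raise ValueError(f"unknown standardisation method {method!r}")
    return StandardisedCovariate(raw, center, scale, (raw - center) / scale, method)


def aicc(loglik: float, k: int, n: int) -> float:
    """Small-sample corrected AIC: -2*loglik + 2k + 2k(k+1)/(n-k-1)."""
    if n <= k + 1:
        raise ValueError(f"AICc undefined for n={n} <= k+1={k + 1}")
    return -2.0 * loglik + 2.0 * k + 2.0 * k * (k + 1.0) / (n - k - 1.0)


# -- model specification and fit containers ---------------------------------


@dataclass(frozen=True)
class ModelSpec:
    """One candidate model structure.

    ``inbreeding_covariates`` is a subset of one covariate family (never
    mixed); parity, season and the animal effect are always present.
    """

    inbreeding_covariates: tuple[str, ...] = ()
    response: str = "binomial_counts"  # or "bernoulli_expanded"
    random_animal: bool = True

    def __post_init__(self):
        covs = tuple(self.inbreeding_covariates)
        object.__setattr__(self, "inbreeding_covariates", covs)
        families = [f for f in (BALLOU_COVARIATES, KALINOWSKI_COVARIATES)
                    if set(covs) <= set(f)]
        if not families:
            raise ValueError(
                f"inbreeding covariates {covs} mix families or are unknown"
            )

    @property
    def label(self) -> str:
        base = "Parity + season"
        for c in self.inbreeding_covariates:
            base += f" + {c}"
        return base + " + animal"


@dataclass(frozen=True)
class ModelFit:
    """A fitted candidate: coefficients, SEs and information criteria."""

    terms: tuple[str, ...]
    coef: dict
    se: dict
    loglik: float
    k: int
    n: int
    aic: float
    aicc: float
    sigma2_a: float
    converged: bool
    covariates: tuple[str, ...] = ()
    label: str = ""


# -- Laplace machinery -------------------------------------------------------


def _softplus(eta):
    return np.logaddexp(0.0, eta)


class _GLMMProblem:
    """Design + response + random-effect structure, with Laplace evaluation."""

    def __init__(self, X, succ, trials, gpos=None, Ainv=None):
        self.X = np.asarray(X, dtype=float)
        self.succ = np.asarray(succ, dtype=float)
        self.trials = np.asarray(trials, dtype=float)
        self.n, self.p = self.X.shape
        self.const = float(
            np.sum(gammaln(self.trials + 1) - gammaln(self.succ + 1)
                   - gammaln(self.trials - self.succ + 1))
        )
        self.gpos = None if gpos is None else np.asarray(gpos, dtype=np.int64)
        if self.gpos is not None:
            if Ainv is None:
                m = int(self.gpos.max()) + 1
                Ainv = sparse.identity(m, format="csc")
            self.Ainv = sparse.csc_matrix(Ainv)
            self.m = self.Ainv.shape[0]
            lu = splu(self.Ainv)
            self.logdet_ainv = float(np.sum(np.log(np.abs(lu.U.diagonal()))))

    # conditional (given random effects) log-likelihood
    def cond_loglik(self, eta):
        return float(np.sum(self.succ * eta - self.trials * _softplus(eta)) + self.const)

    def _weights(self, eta):
        p = expit(eta)
        return np.clip(self.trials * p * (1.0 - p), 1e-12, None), p

    def glm_fit(self, tol=1e-10, max_iter=100):
        """Plain logistic (binomial) Newton fit, no random effect."""
        beta = np.zeros(self.p)
        ll = self.cond_loglik(self.X @ beta)
        for _ in range(max_iter):
            eta = self.X @ beta
            w, p = self._weights(eta)
            score = self.X.T @ (self.succ - self.trials * p)
            H = self.X.T @ (self.X * w[:, None])
            try:
                step = np.linalg.solve(H, score)
            except np.linalg.LinAlgError:
                raise ValueError("singular design matrix in GLM fit") from None
            for _ in range(40):
                cand = beta + step
                ll_new = self.cond_loglik(self.X @ cand)
                if ll_new >= ll - 1e-12:
                    break
                step = step / 2.0
            beta, ll = cand, ll_new
            if np.max(np.abs(score)) < tol * max(1.0, abs(ll)):
                break
        eta = self.X @ beta
        w, _ = self._weights(eta)
        cov = np.linalg.inv(self.X.T @ (self.X * w[:, None]))
        return beta, ll, cov

    def _agg(self, values):
        return np.bincount(self.gpos, weights=values, minlength=self.m)

    def a_mode(self, beta, sig2, a0=None, tol=1e-10, max_iter=100):
        """Conditional mode of the random effects at fixed (beta, sigma2)."""
        P = self.Ainv / sig2
        a = np.zeros(self.m) if a0 is None else a0.copy()
        eta_fix = self.X @ beta

        def pen(a):
            return self.cond_loglik(eta_fix + a[self.gpos]) - 0.5 * float(a @ (P @ a))

        val = pen(a)
        lu = wg = None
        for _ in range(max_iter):
            eta = eta_fix + a[self.gpos]
            w, p = self._weights(eta)
            score = self._agg(self.succ - self.trials * p) - P @ a
            wg = self._agg(w)
            Q = sparse.diags(wg) + P
            lu = splu(Q.tocsc())
            step = lu.solve(score)
            for _ in range(40):
                cand = a + step
                val_new = pen(cand)
                if val_new >= val - 1e-12:
                    break
                step = step / 2.0
            a, val = cand, val_new
            if np.max(np.abs(score)) < tol * max(1.0, abs(val)):
                break
        return a, lu, wg, val

    def laplace(self, beta, sig2, a0=None):
        """Laplace-approximated marginal log-likelihood at (beta, sigma2)."""
        a, lu, wg, pen_val = self.a_mode(beta, sig2, a0=a0)
        # recompute Q at the mode so the determinant matches the mode weights
        eta = self.X @ beta + a[self.gpos]
        w, _ = self._weights(eta)
        Q = sparse.diags(self._agg(w)) + self.Ainv / sig2
        lu = splu(Q.tocsc())
        logdet_q = float(np.sum(np.log(np.abs(lu.U.diagonal()))))
        pa = 0.5 * float(a @ (self.Ainv @ a)) / sig2
        ell = (
            self.cond_loglik(eta)
            - pa
            - 0.5 * (self.m * np.log(sig2) - self.logdet_ainv + logdet_q)
        )
        return ell, a, lu, w

    def joint_mode(self, beta, a, sig2, tol=1e-10, max_iter=100):
        """Penalized IRLS over (beta, a) at fixed sigma2 (Schur complement)."""
        P = self.Ainv / sig2

        def pen(beta, a):
            return self.cond_loglik(self.X @ beta + a[self.gpos]) - 0.5 * float(a @ (P @ a))

        val = pen(beta, a)
        lu = wg = None
        for _ in range(max_iter):
            eta = self.X @ beta + a[self.gpos]
            w, p = self._weights(eta)
            resid = self.succ - self.trials * p
            g1 = self.X.T @ resid
            g2 = self._agg(resid) - P @ a
            wx = self.X * w[:, None]
            A11 = self.X.T @ wx
            B = np.zeros((self.m, self.p))
            np.add.at(B, self.gpos, wx)
            wg = self._agg(w)
            lu = splu((sparse.diags(wg) + P).tocsc())
            QinvB = lu.solve(B)
            QinvG2 = lu.solve(g2)
            S = A11 - B.T @ QinvB
            db = np.linalg.solve(S, g1 - B.T @ QinvG2)
            da = lu.solve(g2 - B @ db)
            for _ in range(40):
                cb, ca = beta + db, a + da
                val_new = pen(cb, ca)
                if val_new >= val - 1e-12:
                    break
                db, da = db / 2.0, da / 2.0
            beta, a, val = cb, ca, val_new
            if max(np.max(np.abs(g1)), np.max(np.abs(g2))) < tol * max(1.0, abs(val)):
                break
        return beta, a, val, lu, wg

    def profile_objective(self, log_sigma, beta, a):
        """Laplace objective with (beta, a) at their joint mode (fast stage)."""
        sig2 = np.exp(2.0 * log_sigma)
        beta, a, pen_val, lu, wg = self.joint_mode(beta, a, sig2)
        logdet_q = float(np.sum(np.log(np.abs(lu.U.diagonal()))))
        ell = pen_val - 0.5 * (self.m * np.log(sig2) - self.logdet_ainv + logdet_q)
        return ell, beta, a

    def beta_covariance(self, beta, sig2, a):
        """Wald covariance of beta from the mixed-model equations."""
        eta = self.X @ beta + a[self.gpos]
        w, _ = self._weights(eta)
        wx = self.X * w[:, None]
        A11 = self.X.T @ wx
        B = np.zeros((self.m, self.p))
        np.add.at(B, self.gpos, wx)
        lu = splu((sparse.diags(self._agg(w)) + self.Ainv / sig2).tocsc())
        S = A11 - B.T @ lu.solve(B)
        return np.linalg.inv(S)


def laplace_loglik(X, y, groups=None, a_inv=None, *, beta, sigma2_a) -> float:
    """Laplace marginal log-likelihood at given parameters (no fitting).

    ``X`` is used as supplied (no intercept added); ``y`` is (n, 2) counts
    ``[alive, total]`` or a binary vector.  With ``groups=None`` the plain
    binomial log-likelihood is returned.
    """
    succ, trials = _split_response(y)
    prob = _GLMMProblem(X, succ, trials, gpos=groups, Ainv=a_inv)
    beta = np.asarray(beta, dtype=float)
    if groups is None or sigma2_a == 0.0:
        return prob.cond_loglik(prob.X @ beta)
    return prob.laplace(beta, float(sigma2_a))[0]


def _split_response(y):
    y = np.asarray(y, dtype=float)
    if y.ndim == 2 and y.shape[1] == 2:
        succ, trials = y[:, 0], y[:, 1]
    else:
        succ, trials = y, np.ones_like(y)
    if (succ < 0).any() or (succ > trials).any() or (trials < 1).any():
        raise ValueError("response must satisfy 0 <= n_alive <= n_total, n_total >= 1")
    return succ, trials


# -- the estimator -----------------------------------------------------------


class PedigreeGLMM(BaseEstimator):
    """Binomial logit mixed model with a pedigree-structured random effect.

    Parameters
    ----------
    a_inv : sparse matrix or None
        Inverse relationship matrix of the random-effect levels (from
        :func:`purgekit.pedigree.a_inverse`).  ``None`` with ``groups``
        supplied means independent (identity) random intercepts.
    sigma_a : "ml" or float
        Estimate the additive standard deviation by maximum likelihood, or
        hold it fixed (0 collapses to plain logistic regression).
    method : {"laplace", "profile"}
        "laplace" (default) refines (beta, log sigma_a) against the exact
        Laplace objective with L-BFGS-B; "profile" stops after the fast
        profiling stage (joint-mode objective), for large batch fits.
    fit_intercept : bool
        Prepend an intercept column named "Intercept".
    sigma_bounds : (float, float)
        Box for sigma_a in the outer search.
    start_sigma : float
        Starting value of sigma_a for the outer search.

    Attributes
    ----------
    coef_, se_ : ndarray aligned with ``terms_`` (intercept included)
    sigma2_a_ : float additive variance
    loglik_, aic_, aicc_, k_, n_ : fit summaries (k counts fixed
        coefficients plus the estimated variance component)
    random_effects_ : ndarray of conditional modes (one per level)
    converged_ : bool
    """

    def __init__(self, a_inv=None, sigma_a="ml", method="laplace", fit_intercept=True,
                 tol=1e-8, sigma_bounds=(1e-4, 10.0), start_sigma=0.3, polish="auto"):
        self.a_inv = a_inv
        self.sigma_a = sigma_a
        self.method = method
        self.fit_intercept = fit_intercept
        self.tol = tol
        self.sigma_bounds = sigma_bounds
        self.start_sigma = start_sigma
        self.polish = polish

    def _design(self, X):
        if isinstance(X, pd.DataFrame):
            names = list(X.columns)
            Xm = X.to_numpy(dtype=float)
        else:
            Xm = np.asarray(X, dtype=float)
            names = [f"x{i}" for i in range(Xm.shape[1])]
        if self.fit_intercept:
            Xm = np.column_stack([np.ones(len(Xm)), Xm])
            names = ["Intercept"] + names
        return Xm, names

    def fit(self, X, y, groups=None):
        Xm, names = self._design(X)
        succ, trials = _split_response(y)
        if len(succ) != len(Xm):
            raise ValueError("X and y have different lengths")
        self.terms_ = tuple(names)
        self.n_ = len(succ)
        p = Xm.shape[1]

        fixed_sigma = None if self.sigma_a == "ml" else float(self.sigma_a)
        has_re = groups is not None and (fixed_sigma is None or fixed_sigma > 0.0)

        if not has_re:
            prob = _GLMMProblem(Xm, succ, trials)
            beta, ll, cov = prob.glm_fit()
            self.coef_, self.cov_ = beta, cov
            self.se_ = np.sqrt(np.diag(cov))
            self.sigma2_a_ = 0.0
            self.random_effects_ = None
            self.loglik_ = ll
            self.k_ = p + (1 if groups is not None else 0)
            self.converged_ = True
        else:
            prob = _GLMMProblem(Xm, succ, trials, gpos=groups, Ainv=self.a_inv)
            beta0, _, _ = prob.glm_fit()
            a0 = np.zeros(prob.m)

            if fixed_sigma is not None:
                ls = np.log(fixed_sigma)
                _, beta, a = prob.profile_objective(ls, beta0, a0)
                sig2 = fixed_sigma**2
                opt_ok = True
            else:
                lo, hi = np.log(self.sigma_bounds[0]), np.log(self.sigma_bounds[1])
                state = {"beta": beta0, "a": a0}

                def neg_prof(ls):
                    ell, b, a = prob.profile_objective(ls, state["beta"], state["a"])
                    state["beta"], state["a"] = b, a
                    return -ell

                res = optimize.minimize_scalar(
                    neg_prof, bounds=(lo, hi), method="bounded",
                    options={"xatol": 1e-3},
                )
                ls = float(res.x)
                _, beta, a = prob.profile_objective(ls, state["beta"], state["a"])
                sig2 = float(np.exp(2.0 * ls))
                opt_ok = True

                if self.method == "laplace":
                    warm = {"a": a.copy()}

                    def neg_laplace(theta):
                        b, ls_ = theta[:p], theta[p]
                        s2 = float(np.exp(2.0 * np.clip(ls_, lo, hi)))
                        ell, amode, _, _ = prob.laplace(b, s2, a0=warm["a"])
                        warm["a"] = amode
                        return -ell

                    theta0 = np.concatenate([beta, [ls]])
                    bounds = [(None, None)] * p + [(lo, hi)]
                    res2 = optimize.minimize(
                        neg_laplace, theta0, method="L-BFGS-B", bounds=bounds,
                        options={"maxiter": 200, "ftol": 1e-13, "gtol": self.tol,
                                 "eps": 1e-7},
                    )
                    theta = res2.x if res2.fun <= neg_laplace(theta0) else theta0
                    do_polish = self.polish is True or (
                        self.polish == "auto" and self.n_ <= 2000
                    )
                    if do_polish:
                        res3 = optimize.minimize(
                            neg_laplace, theta, method="Nelder-Mead",
                            options={"xatol": 1e-7, "fatol": 1e-11,
                                     "maxfev": 4000, "adaptive": True},
                        )
                        if res3.fun < neg_laplace(theta):
                            theta = res3.x
                    beta, ls = theta[:p], float(np.clip(theta[p], lo, hi))
                    sig2 = float(np.exp(2.0 * ls))
                    opt_ok = bool(res2.success)

            ell, a, _, _ = prob.laplace(beta, sig2)
            self.coef_ = beta
            self.cov_ = prob.beta_covariance(beta, sig2, a)
            self.se_ = np.sqrt(np.diag(self.cov_))
            self.sigma2_a_ = sig2
            self.random_effects_ = a
            self.loglik_ = ell
            self.k_ = p + (1 if fixed_sigma is None else 0)
            self.converged_ = opt_ok

        self.aic_ = -2.0 * self.loglik_ + 2.0 * self.k_
        self.aicc_ = aicc(self.loglik_, self.k_, self.n_)
        self._problem = prob
        return self

    def predict_proba(self, X) -> np.ndarray:
        """Population-level survival probability (random effect at zero)."""
        Xm, _ = self._design(X)
        return expit(Xm @ self.coef_)

    def predict(self, X) -> np.ndarray:
        return self.predict_proba(X)


# -- analysis-frame helpers and functional wrapper ---------------------------


def prepare_analysis_frame(
    records: pd.DataFrame,
    coefficients: pd.DataFrame,
    *,
    period: tuple | None = None,
    standardisation: str = "z_1sd",
) -> pd.DataFrame:
    """Attach encoded covariates to kindling records.

    ``records`` needs columns dam, sire, kindling_date, parity, n_total,
    n_alive (litter_dummy is derived from (dam, sire) when absent);
    ``coefficients`` is a per-individual table with F, F_new, F_ak, F_ab
    (from gene dropping).  Inbreeding covariates are z-standardised within
    the supplied period, since models are fitted per period.
    """
    df = records.copy()
    df["kindling_date"] = pd.to_datetime(df["kindling_date"])
    if period is not None:
        start, end = _period_bounds(period)
        df = df.loc[(df["kindling_date"] >= start) & (df["kindling_date"] <= end)].copy()
    if df.empty:
        return df
    if "litter_dummy" not in df.columns:
        df["litter_dummy"] = [dummy_id(d, s) for d, s in zip(df["dam"], df["sire"])]
    df["season"] = encode_season(df["kindling_date"].to_numpy())
    df["parity_class"] = encode_parity(df["parity"].to_numpy())
    for zname, (role, col) in _COVARIATE_SOURCE.items():
        key = df["dam"] if role == "dam" else df["litter_dummy"]
        raw = coefficients[col].reindex(key).to_numpy()
        if np.isnan(raw).any():
            missing = key[np.isnan(raw)].iloc[0]
            raise KeyError(f"no coefficient row for individual {missing!r}")
        try:
            df[zname] = standardise(raw, method=standardisation).z
        except ValueError:
            df[zname] = np.nan  # zero-variance covariate: unusable this period
    return df


def _period_bounds(period):
    """Month-precision (start, end) bounds, both months fully included."""
    start = pd.Timestamp(str(period[0]))
    end = pd.Timestamp(str(period[1])) + pd.offsets.MonthEnd(0)
    return start, end


def build_design(frame: pd.DataFrame, covariates: Sequence[str]):
    """Fixed-effect design (parity classes + summer indicator + covariates)."""
    cols = {}
    for lvl, label in PARITY_LABELS.items():
        ind = (frame["parity_class"] == lvl).astype(float).to_numpy()
        if ind.any():  # a parity class absent from the period would be all-zero
            cols[label] = ind
    cols["Season"] = (frame["season"] == "summer").astype(float).to_numpy()
    for c in covariates:
        v = frame[c].to_numpy(dtype=float)
        if np.isnan(v).any():
            raise ValueError(f"covariate {c} is undefined (zero variance) in this period")
        cols[c] = v
    return pd.DataFrame(cols, index=frame.index)


def fit_glmm(
    frame: pd.DataFrame,
    ped: Pedigree,
    spec: ModelSpec,
    *,
    sigma_a="ml",
    method: str = "laplace",
    dam_structure=None,
) -> ModelFit:
    """Fit one candidate model on a prepared analysis frame.

    ``dam_structure`` may carry a precomputed ``(ids, Ainv)`` pair from
    :func:`purgekit.pedigree.a_inverse` over the dams' ancestor closure,
    to share the factorisation across the candidate set.
    """
    df = frame
    if spec.response == "bernoulli_expanded":
        rows, alive = [], []
        for idx, r in df.iterrows():
            n_tot, n_alv = int(r["n_total"]), int(r["n_alive"])
            rows += [idx] * n_tot
            alive += [1] * n_alv + [0] * (n_tot - n_alv)
        df = df.loc[rows].reset_index(drop=True)
        df["n_total"] = 1
        df["n_alive"] = alive
    X = build_design(df, spec.inbreeding_covariates)
    y = df[["n_alive", "n_total"]].to_numpy(dtype=float)

    groups = ainv = None
    if spec.random_animal:
        if dam_structure is None:
            dam_structure = a_inverse(ped, sorted(set(df["dam"])))
        ids, ainv = dam_structure
        pos = {i: k for k, i in enumerate(ids)}
        groups = np.array([pos[d] for d in df["dam"]], dtype=np.int64)

    est = PedigreeGLMM(a_inv=ainv, sigma_a=sigma_a, method=method).fit(X, y, groups=groups)
    if not est.converged_:
        warnings.warn(f"non-convergent fit for model {spec.label!r}", RuntimeWarning)
    return ModelFit(
        terms=est.terms_,
        coef=dict(zip(est.terms_, est.coef_)),
        se=dict(zip(est.terms_, est.se_)),
        loglik=est.loglik_,
        k=est.k_,
        n=est.n_,
        aic=est.aic_,
        aicc=est.aicc_,
        sigma2_a=est.sigma2_a_,
        converged=est.converged_,
        covariates=spec.inbreeding_covariates,
        label=spec.label,
    )
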