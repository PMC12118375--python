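"""Multinomial logistic regression of femoral component size.

The femoral component of the PFC Sigma knee system comes in seven modeled
sizes (1.5, 2, 2.5, 3, 4, 5, 6; the "4 Narrow" variant is merged into size 4
for modeling). Size is regressed on five routinely available preoperative
predictors — sex, height, weight, BMI, and prosthesis side — with size 3 as
the reference category, so that ``exp(slope)`` is the odds ratio of a given
size versus size 3 per unit of the predictor (per cm, per kg, per BMI unit,
female vs male, right vs left).

The estimator follows scikit-learn conventions (``fit`` / ``predict`` /
``predict_proba``, fitted attributes with a trailing underscore) and adds a
small ridge penalty on the slopes: height, weight, and BMI are strongly
collinear (BMI is a near-deterministic function of the other two), and rare
sizes can be quasi-separated, so an unpenalized ML fit can be unstable.
"""

from __future__ import annotations

import json
import warnings
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import logsumexp, softmax
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.exceptions import NotFittedError

#: Predictor columns, in design-matrix order. Indicators are coded female=1,
#: right=1; continuous predictors stay on their natural units.
PREDICTORS = ("sex_female", "height_cm", "weight_kg", "bmi", "side_right")

#: Modeled femoral sizes in ascending physical order ("4N" is merged into "4").
MODEL_SIZES = ("1.5", "2", "2.5", "3", "4", "5", "6")

_SIZE_VALUE = {"1.5": 1.5, "2": 2.0, "2.5": 2.5, "3": 3.0, "4": 4.0, "5": 5.0, "6": 6.0}

#: Odds ratios (vs reference size 3, per predictor unit) of the multinomial
#: logit fitted to the Dutch-registry TKA cohort that the default synthetic
#: generator emulates. Rows are the non-reference sizes.
REFERENCE_ODDS_RATIOS = pd.DataFrame(
    {
        "sex_female": {"1.5": 0.16, "2": 5.82, "2.5": 3.86, "4": 0.21, "5": 0.02, "6": 0.02},
        "height_cm": {"1.5": 0.85, "2": 0.74, "2.5": 0.84, "4": 1.20, "5": 1.30, "6": 1.64},
        "weight_kg": {"1.5": 0.75, "2": 1.08, "2.5": 1.07, "4": 0.96, "5": 1.01, "6": 0.91},
        "bmi": {"1.5": 1.44, "2": 0.77, "2.5": 0.80, "4": 1.16, "5": 1.03, "6": 1.46},
        "side_right": {"1.5": 0.09, "2": 1.18, "2.5": 1.35, "4": 0.90, "5": 0.81, "6": 0.86},
    }
).loc[["1.5", "2", "2.5", "4", "5", "6"], list(PREDICTORS)]


def reference_log_odds() -> pd.DataFrame:
    """Log odds-ratio slope matrix for all 7 modeled sizes (reference row = 0)."""
    out = pd.DataFrame(0.0, index=list(MODEL_SIZES), columns=list(PREDICTORS))
    out.loc[REFERENCE_ODDS_RATIOS.index] = np.log(REFERENCE_ODDS_RATIOS.to_numpy())
    return out


def normalize_size(value) -> str:
    """Canonical femoral-size label: 2.0 -> "2", "4n" -> "4N", 1.5 -> "1.5"."""
    s = str(value).strip().upper()
    if s in {"4N", "4 NARROW", "4NARROW"}:
        return "4N"
    try:
        f = float(s)
    except ValueError as exc:
        raise ValueError(f"unrecognized femoral size {value!r}") from exc
    for label, num in _SIZE_VALUE.items():
        if f == num:
            return label
    raise ValueError(f"unrecognized femoral size {value!r}")


def merge_narrow(sizes) -> np.ndarray:
    """Map the 8-level catalog onto the 7 modeled sizes ("4N" -> "4")."""
    arr = np.asarray([normalize_size(s) for s in np.asarray(sizes, dtype=object)], dtype=object)
    arr[arr == "4N"] = "4"
    return arr.astype(str)


def _as_design(X) -> np.ndarray:
    if isinstance(X, pd.DataFrame):
        missing = [c for c in PREDICTORS if c not in X.columns]
        if missing:
            raise ValueError(f"design matrix is missing predictor columns {missing}")
        X = X.loc[:, list(PREDICTORS)]
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X.reshape(1, -1)
    if X.shape[1] != len(PREDICTORS):
        raise ValueError(f"expected {len(PREDICTORS)} predictor columns, got {X.shape[1]}")
    if not np.all(np.isfinite(X)):
        raise ValueError("predictors must be finite")
    return X


class FemoralSizeClassifier(ClassifierMixin, BaseEstimator):
    """Ridge-stabilized multinomial logit for femoral component size.

    Parameters
    ----------
    ridge : float
        L2 penalty on the slopes (not the intercepts). The default 1e-6 is
        numerically negligible for well-populated sizes but keeps
        quasi-separated rare sizes bounded.
    reference : str
        Reference size; its coefficients are fixed at zero. If absent from
        the training data the most frequent class is used instead and
        ``reference_used_`` records it.
    solver : {"newton", "lbfgs"}
        Newton–Raphson with step halving (default; the observed-information
        matrix it forms is reused for Wald intervals) or scipy L-BFGS-B.
    max_iter : int
        Iteration cap for the solver.
    tol : float
        Relative decrease of the penalized negative log-likelihood below
        which the Newton solver declares convergence (the mean absolute
        score is additionally required to be < 1e-7 for early exit).

    Attributes
    ----------
    classes_ : ndarray of str, ascending size order.
    coef_ : ndarray (n_classes, 5), slopes on natural units; reference row 0.
    intercept_ : ndarray (n_classes,), natural-scale intercepts; reference 0.
    covariance_ : ndarray, Wald covariance of the free (centered) parameters,
        ordered class-major as [intercept, 5 slopes] per non-reference class,
        or None when the information matrix was singular.
    condition_number_ : float, condition number of the centered design.
    converged_ : bool.
    """

    def __init__(self, ridge: float = 1e-6, reference: str = "3",
                 solver: str = "newton", max_iter: int = 200, tol: float = 1e-9):
        self.ridge = ridge
        self.reference = reference
        self.solver = solver
        self.max_iter = max_iter
        self.tol = tol

    # ------------------------------------------------------------------ fit

    def fit(self, X, y):
        X = _as_design(X)
        y = merge_narrow(y)
        if len(y) != X.shape[0]:
            raise ValueError("X and y have different lengths")
        classes = sorted(set(y), key=lambda s: _SIZE_VALUE[s])
        if len(classes) < 2:
            raise ValueError("single class: training data contains only one femoral size")
        counts = {c: int(np.sum(y == c)) for c in classes}
        if self.reference in classes:
            ref = self.reference
        else:
            ref = max(classes, key=counts.get)
            warnings.warn(
                f"reference size {self.reference!r} absent from training data; "
                f"using most frequent class {ref!r}", stacklevel=2)
        self.reference_used_ = ref
        others = [c for c in classes if c != ref]

        self.classes_ = np.asarray(classes, dtype=object)
        self.n_features_in_ = X.shape[1]
        center = X.mean(axis=0)
        Xc = X - center
        X1 = np.hstack([np.ones((X.shape[0], 1)), Xc])
        self.condition_number_ = float(np.linalg.cond(X1))

        internal = [ref] + others           # class 0 is the reference
        code = {c: i for i, c in enumerate(internal)}
        yi = np.asarray([code[v] for v in y])
        K, p1 = len(classes), X1.shape[1]
        # one-hot for the non-reference classes
        Y = np.zeros((len(y), K - 1))
        nz = yi > 0
        Y[np.nonzero(nz)[0], yi[nz] - 1] = 1.0

        theta0 = np.zeros((K - 1, p1))
        theta0[:, 0] = [np.log(counts[c] / counts[ref]) for c in others]

        if self.solver == "newton":
            theta, converged, n_iter, H = self._fit_newton(X1, Y, theta0)
        elif self.solver == "lbfgs":
            theta, converged, n_iter = self._fit_lbfgs(X1, Y, theta0)
            H = self._hessian(X1, theta)
        else:
            raise ValueError(f"unknown solver {self.solver!r}")
        self.converged_ = converged
        self.n_iter_ = n_iter
        if not converged:
            warnings.warn("size model did not converge; estimates are the last iterate",
                          stacklevel=2)

        try:
            cov = np.linalg.inv(H)
        except np.linalg.LinAlgError:
            cov = None
        self.covariance_ = cov

        # back to natural scale, rows ordered by classes_
        coef = np.zeros((K, len(PREDICTORS)))
        icept_c = np.zeros(K)
        for j, c in enumerate(others):
            k = classes.index(c)
            coef[k] = theta[j, 1:]
            icept_c[k] = theta[j, 0]
        self.coef_ = coef
        self.intercept_centered_ = icept_c
        self.center_ = center
        self.intercept_ = icept_c - coef @ center
        self._others = others
        return self

    def _penalty(self, theta):
        return 0.5 * self.ridge * float(np.sum(theta[:, 1:] ** 2))

    def _nll_grad(self, X1, Y, theta):
        eta = X1 @ theta.T                                  # (n, K-1)
        Z = np.hstack([np.zeros((X1.shape[0], 1)), eta])    # reference logit 0
        lse = logsumexp(Z, axis=1)
        nll = float(np.sum(lse) - np.sum(eta * Y)) + self._penalty(theta)
        P = np.exp(Z - lse[:, None])[:, 1:]
        G = (P - Y).T @ X1
        G[:, 1:] += self.ridge * theta[:, 1:]
        return nll, G, P

    def _hessian(self, X1, theta, P=None):
        if P is None:
            _, _, P = self._nll_grad(X1, np.zeros((X1.shape[0], theta.shape[0])), theta)
        Km1, p1 = theta.shape
        H = np.empty((Km1 * p1, Km1 * p1))
        for j in range(Km1):
            for l in range(j, Km1):
                w = P[:, j] * ((1.0 if j == l else 0.0) - P[:, l])
                blk = X1.T @ (w[:, None] * X1)
                H[j * p1:(j + 1) * p1, l * p1:(l + 1) * p1] = blk
                H[l * p1:(l + 1) * p1, j * p1:(j + 1) * p1] = blk.T
        ridge_diag = np.tile(np.r_[0.0, np.full(p1 - 1, self.ridge)], Km1)
        H[np.diag_indices_from(H)] += ridge_diag
        return H

    def _fit_newton(self, X1, Y, theta0):
        theta = theta0.copy()
        n = X1.shape[0]
        nll, G, P = self._nll_grad(X1, Y, theta)
        for it in range(1, self.max_iter + 1):
            if np.max(np.abs(G)) / n < 1e-7:
                return theta, True, it - 1, self._hessian(X1, theta, P)
            H = self._hessian(X1, theta, P)
            try:
                step = np.linalg.solve(H, G.ravel()).reshape(theta.shape)
            except np.linalg.LinAlgError:
                step = G / n  # gradient fallback on singular information
            t, accepted = 1.0, False
            for _ in range(30):  # step halving keeps the objective monotone
                cand = theta - t * step
                nll_c, G_c, P_c = self._nll_grad(X1, Y, cand)
                if nll_c <= nll + 1e-12 * abs(nll):
                    improved = nll - nll_c
                    theta, nll, G, P = cand, nll_c, G_c, P_c
                    accepted = True
                    break
                t *= 0.5
            if not accepted:
                return theta, False, it, self._hessian(X1, theta, P)
            # objective has flattened (e.g. quasi-separation drifting under the
            # weak ridge): accept the iterate rather than polish indefinitely
            if improved < self.tol * (1.0 + abs(nll)):
                return theta, True, it, self._hessian(X1, theta, P)
        return theta, False, self.max_iter, self._hessian(X1, theta, P)

    def _fit_lbfgs(self, X1, Y, theta0):
        shape = theta0.shape

        def fun(t):
            nll, G, _ = self._nll_grad(X1, Y, t.reshape(shape))
            return nll, G.ravel()

        res = minimize(fun, theta0.ravel(), jac=True, method="L-BFGS-B",
                       options={"maxiter": max(self.max_iter, 1000), "ftol": 1e-12,
                                "gtol": 1e-8})
        return res.x.reshape(shape), bool(res.success), int(res.nit)

    # --------------------------------------------------------------- predict

    def _check_fitted(self):
        if not hasattr(self, "coef_"):
            raise NotFittedError("this FemoralSizeClassifier instance is not fitted yet")

    def decision_function(self, X):
        self._check_fitted()
        X = _as_design(X)
        return self.intercept_centered_ + (X - self.center_) @ self.coef_.T

    def predict_proba(self, X):
        """Class probabilities, columns ordered as ``classes_``; rows sum to 1."""
        return softmax(self.decision_function(X), axis=1)

    def predict(self, X):
        """Most probable size; exact ties resolve to the smaller size."""
        proba = self.predict_proba(X)
        return self.classes_[np.argmax(proba, axis=1)]  # first max = smallest size

    def log_likelihood(self, X, y):
        proba = self.predict_proba(X)
        y = merge_narrow(y)
        idx = {c: i for i, c in enumerate(self.classes_)}
        cols = np.asarray([idx[v] for v in y])
        return float(np.sum(np.log(proba[np.arange(len(y)), cols])))

    # ----------------------------------------------------------- reporting

    def odds_ratios(self, level: float = 0.95) -> pd.DataFrame:
        """Odds ratios vs the reference with Wald confidence intervals.

        Returns a tidy frame (size, predictor, odds_ratio, ci_low, ci_high).
        When the covariance is unavailable the intervals are NaN and
        ``ci_available`` is False in ``.attrs``.
        """
        self._check_fitted()
        from scipy.stats import norm
        z = norm.ppf(0.5 + level / 2)
        p1 = len(PREDICTORS) + 1
        rows = []
        have_cov = self.covariance_ is not None
        classes = list(self.classes_)
        for j, c in enumerate(self._others):
            k = classes.index(c)
            for m, pred in enumerate(PREDICTORS):
                b = self.coef_[k, m]
                if have_cov:
                    se = np.sqrt(self.covariance_[j * p1 + 1 + m, j * p1 + 1 + m])
                    lo, hi = np.exp(b - z * se), np.exp(b + z * se)
                else:
                    lo = hi = np.nan
                rows.append((c, pred, np.exp(b), lo, hi))
        out = pd.DataFrame(rows, columns=["size", "predictor", "odds_ratio", "ci_low", "ci_high"])
        out.attrs["ci_available"] = have_cov
        out.attrs["reference"] = self.reference_used_
        return out

    # -------------------------------------------------------- serialization

    def to_json(self) -> str:
        self._check_fitted()
        doc = {
            "params": self.get_params(),
            "classes": list(map(str, self.classes_)),
            "reference_used": self.reference_used_,
            "coef": self.coef_.tolist(),
            "intercept": self.intercept_.tolist(),
            "center": self.center_.tolist(),
            "intercept_centered": self.intercept_centered_.tolist(),
            "covariance": None if self.covariance_ is None else self.covariance_.tolist(),
            "condition_number": self.condition_number_,
            "converged": self.converged_,
            "n_iter": self.n_iter_,
        }
        return json.dumps(doc, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "FemoralSizeClassifier":
        doc = json.loads(text)
        est = cls(**doc["params"])
        est.classes_ = np.asarray(doc["classes"], dtype=object)
        est.reference_used_ = doc["reference_used"]
        est.coef_ = np.asarray(doc["coef"], dtype=float)
        est.intercept_ = np.asarray(doc["intercept"], dtype=float)
        est.center_ = np.asarray(doc["center"], dtype=float)
        est.intercept_centered_ = np.asarray(doc["intercept_centered"], dtype=float)
        est.covariance_ = None if doc["covariance"] is None else np.asarray(doc["covariance"])
        est.condition_number_ = doc["condition_number"]
        est.converged_ = doc["converged"]
        est.n_iter_ = doc["n_iter"]
        est.n_features_in_ = est.coef_.shape[1]
        est._others = [c for c in est.classes_ if c != est.reference_used_]
        return est

    @classmethod
    def from_parameters(cls, classes: Sequence[str], coef, intercept,
                        reference: str = "3") -> "FemoralSizeClassifier":
        """Construct a fitted model from explicit coefficients (no covariance)."""
        est = cls(reference=reference)
        est.classes_ = np.asarray([normalize_size(c) for c in classes], dtype=object)
        est.coef_ = np.asarray(coef, dtype=float).reshape(len(classes), len(PREDICTORS))
        est.intercept_ = np.asarray(intercept, dtype=float)
        est.center_ = np.zeros(len(PREDICTORS))
        est.intercept_centered_ = est.intercept_.copy()
        est.covariance_ = None
        est.condition_number_ = np.nan
        est.converged_ = True
        est.n_iter_ = 0
        est.n_features_in_ = len(PREDICTORS)
        est.reference_used_ = reference if reference in est.classes_ else str(est.classes_[0])
        est._others = [c for c in est.classes_ if c != est.reference_used_]
        return est


# thin functional wrappers -------------------------------------------------

def fit_size_model(cohort: pd.DataFrame, **params) -> FemoralSizeClassifier:
    """Fit a :class:`FemoralSizeClassifier` on a cohort table."""
    from .cohort import design_matrix
    return FemoralSizeClassifier(**params).fit(design_matrix(cohort), cohort["femur_size"])


def predict_probabilities(model: FemoralSizeClassifier, x) -> pd.Series:
    """Per-size probabilities for one predictor vector (mapping or sequence)."""
    if isinstance(x, Mapping):
        x = [x[p] for p in PREDICTORS]
    proba = model.predict_proba(np.asarray(x, dtype=float).reshape(1, -1))[0]
    return pd.Series(proba, index=list(model.classes_))


def predict_size(model: FemoralSizeClassifier, x) -> str:
    probs = predict_probabilities(model, x)
    return str(probs.index[int(np.argmax(probs.to_numpy()))])
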