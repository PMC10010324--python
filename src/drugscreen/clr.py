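"""Conditional logistic regression for matched case-control sets.

The conditional likelihood of a matched set with one case and m controls is
the softmax probability of the case's covariate row within the set,

    P_s(beta) = exp(x_case . beta) / sum_{j in s} exp(x_j . beta),

which is exactly the partial-likelihood contribution of a risk-set sampled
stratum. The log likelihood is concave; we maximize it by Newton-Raphson
with analytic gradient and Hessian and step-halving, starting from beta=0.
Wald 95% intervals use the inverse negative Hessian at the optimum.

Two model parametrizations are provided:

- categorical: dummies for low (1-2 fills), intermediate (3-7) and high
  (8+) use versus nonuse, plus Charlson score (numeric) and education
  (three dummies versus the basic level);
- dose-response: an ever-use indicator plus log2(cumulative fills), so
  exp(beta_log2) is the OR per doubling of cumulative use among ever-users,
  with the same covariates.

Columns with no within-set variation anywhere carry no information in the
conditional likelihood and are dropped from the fit with a warning; their
coefficients are reported as NaN.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import FitError, NoExposedSubjectsError

Z95 = 1.959963984540054  # two-sided 95% normal quantile
SEPARATION_BOUND = 15.0  # |log OR| beyond this is treated as divergence

CATEGORICAL_TERMS = ["low", "intermediate", "high", "cci",
                     "edu_vocational", "edu_higher", "edu_unknown"]
DOSE_TERMS = ["ever_use", "log2_fills", "cci",
              "edu_vocational", "edu_higher", "edu_unknown"]


@dataclass
class MatchedDesign:
    """Row-per-subject design with contiguous sets, one case per set."""
    X: np.ndarray            # (n_rows, p)
    y: np.ndarray            # bool, case indicator
    set_index: np.ndarray    # int, 0..n_sets-1, sorted ascending
    param_names: list[str]
    set_ids: list[str] = field(default_factory=list)
    n_dropped_sets: int = 0  # sets discarded for having zero controls

    def __post_init__(self):
        if np.any(np.diff(self.set_index) < 0):
            raise FitError("set_index must be sorted ascending")
        starts = self._starts()
        cases_per_set = np.add.reduceat(self.y.astype(int), starts)
        if np.any(cases_per_set != 1):
            raise FitError("every matched set must contain exactly one case")

    def _starts(self) -> np.ndarray:
        return np.concatenate(([0], 1 + np.flatnonzero(np.diff(self.set_index))))

    @property
    def n_sets(self) -> int:
        return int(self.set_index[-1]) + 1 if self.set_index.size else 0

    @classmethod
    def from_rows(cls, X, y, set_labels, param_names,
                  n_dropped_sets: int = 0) -> "MatchedDesign":
        """Build from possibly unsorted rows; drops zero-control sets."""
        X = np.asarray(X, dtype=float)
        y = np.asarray(y).astype(bool)
        labels = pd.Series(set_labels).astype(str).to_numpy()
        order = np.argsort(labels, kind="stable")
        X, y, labels = X[order], y[order], labels[order]
        sizes = pd.Series(labels).groupby(labels).transform("size").to_numpy()
        keep = sizes > 1
        dropped = len(np.unique(labels[~keep])) if (~keep).any() else 0
        X, y, labels = X[keep], y[keep], labels[keep]
        if X.shape[0] == 0:
            raise FitError("no usable matched sets (all sets lack controls)")
        codes = pd.factorize(labels, sort=True)[0]
        return cls(X=X, y=y, set_index=codes, param_names=list(param_names),
                   set_ids=list(pd.unique(labels)),
                   n_dropped_sets=n_dropped_sets + dropped)


@dataclass
class FitResult:
    """Coefficients on the log-OR scale with Wald 95% intervals."""
    param_names: list[str]
    beta: np.ndarray
    cov: np.ndarray
    se: np.ndarray
    or_: np.ndarray
    ci95: np.ndarray          # (p, 2) on the OR scale
    converged: bool
    loglik: float
    n_iter: int
    n_sets_used: int
    n_exposed_cases: int
    warnings: list[str] = field(default_factory=list)

    def _ix(self, name: str) -> int:
        try:
            return self.param_names.index(name)
        except ValueError:
            raise KeyError(f"no parameter named {name!r}") from None

    def or_for(self, name: str) -> float:
        return float(self.or_[self._ix(name)])

    def ci_for(self, name: str) -> tuple[float, float]:
        lo, hi = self.ci95[self._ix(name)]
        return float(lo), float(hi)

    def to_dict(self) -> dict:
        return {
            "params": self.param_names,
            "beta": [None if np.isnan(b) else float(b) for b in self.beta],
            "se": [None if np.isnan(s) else float(s) for s in self.se],
            "or": [None if np.isnan(o) else float(o) for o in self.or_],
            "ci95": [[None if np.isnan(v) else float(v) for v in row]
                     for row in self.ci95],
            "converged": bool(self.converged),
            "loglik": float(self.loglik),
            "n_sets_used": int(self.n_sets_used),
            "n_exposed_cases": int(self.n_exposed_cases),
            "warnings": list(self.warnings),
        }


def conditional_loglik(design: MatchedDesign, beta: np.ndarray):
    """Exact conditional log likelihood with analytic gradient and Hessian."""
    beta = np.asarray(beta, dtype=float)
    X, y, sets = design.X, design.y, design.set_index
    starts = design._starts()
    eta = X @ beta
    if not np.all(np.isfinite(eta)):
        bad = int(sets[np.flatnonzero(~np.isfinite(eta))[0]])
        sid = design.set_ids[bad] if design.set_ids else str(bad)
        raise FitError(f"non-finite linear predictor in set {sid}")
    m = np.maximum.reduceat(eta, starts)
    z = np.exp(eta - m[sets])
    denom = np.add.reduceat(z, starts)
    ll = float(eta[y].sum() - (m + np.log(denom)).sum())
    w = z / denom[sets]
    wx = w[:, None] * X
    xbar = np.add.reduceat(wx, starts, axis=0)      # (S, p) per-set E[x]
    grad = X[y].sum(axis=0) - xbar.sum(axis=0)
    hess = -(wx.T @ X - xbar.T @ xbar)              # -sum_s Cov_s(x)
    return ll, grad, hess


def fit_clr(design: MatchedDesign, tol: float = 1e-8,
            max_iter: int = 50, n_exposed_cases: int = 0) -> FitResult:
    """Newton-Raphson maximization of the conditional likelihood.

    Starts from beta=0, halves steps that fail to increase the likelihood,
    and stops when the gradient max-norm drops below ``tol``. A coefficient
    drifting beyond +-15 on the log scale triggers a separation warning and
    ``converged=False``; a singular Hessian triggers one ridge-stabilized
    retry before giving up.
    """
    p = design.X.shape[1]
    beta = np.zeros(p)
    warnings: list[str] = []
    ll, grad, hess = conditional_loglik(design, beta)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        if np.max(np.abs(grad)) < tol:
            converged = True
            break
        neg_h = -hess
        try:
            step = np.linalg.solve(neg_h, grad)
        except np.linalg.LinAlgError:
            warnings.append("singular hessian; ridge-stabilized step")
            step = np.linalg.solve(neg_h + 1e-6 * np.eye(p), grad)
        # step-halving: require a non-decreasing log likelihood
        scale = 1.0
        for _ in range(40):
            cand = beta + scale * step
            ll_new, g_new, h_new = conditional_loglik(design, cand)
            if np.isfinite(ll_new) and ll_new >= ll - 1e-12:
                break
            scale *= 0.5
        else:
            warnings.append("step-halving failed to improve the likelihood")
            break
        beta, ll, grad, hess = cand, ll_new, g_new, h_new
        if np.max(np.abs(beta)) > SEPARATION_BOUND:
            warnings.append("possible separation: a coefficient exceeded "
                            f"|{SEPARATION_BOUND}| on the log-OR scale")
            break
    else:
        if np.max(np.abs(grad)) < tol:
            converged = True
        else:
            warnings.append(f"no convergence in {max_iter} iterations")

    neg_h = -hess
    try:
        cov = np.linalg.inv(neg_h)
    except np.linalg.LinAlgError:
        warnings.append("singular hessian at optimum; ridge-stabilized covariance")
        cov = np.linalg.inv(neg_h + 1e-6 * np.eye(p))
        converged = False
    se = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    with np.errstate(over="ignore"):  # separated coefficients -> infinite CI
        or_ = np.exp(beta)
        ci = np.column_stack([np.exp(beta - Z95 * se), np.exp(beta + Z95 * se)])
    return FitResult(param_names=list(design.param_names), beta=beta, cov=cov,
                     se=se, or_=or_, ci95=ci, converged=converged, loglik=ll,
                     n_iter=it, n_sets_used=design.n_sets,
                     n_exposed_cases=n_exposed_cases, warnings=warnings)


def _education_dummies(df: pd.DataFrame) -> pd.DataFrame:
    edu = pd.Categorical(df["education"],
                         categories=["basic", "vocational", "higher", "unknown"])
    return pd.DataFrame({
        "edu_vocational": (edu == "vocational").astype(float),
        "edu_higher": (edu == "higher").astype(float),
        "edu_unknown": (edu == "unknown").astype(float),
    }, index=df.index)


def _informative_columns(X: np.ndarray, set_labels: np.ndarray) -> np.ndarray:
    """True for columns that vary within at least one set."""
    df = pd.DataFrame(X)
    g = df.groupby(pd.Series(set_labels).to_numpy())
    spread = (g.transform("max") - g.transform("min")).max(axis=0)
    return (spread.to_numpy() > 0)


def _fit_design_frame(df: pd.DataFrame, terms: list[str]) -> FitResult:
    """Shared assembly for both models: builds columns, prunes, fits."""
    n_exposed_cases = int(((df["is_case"] == 1)
                           & (df["category"] == "high")).sum())
    cols = _education_dummies(df)
    cols["cci"] = df["cci"].astype(float)
    cols["low"] = (df["category"] == "low").astype(float)
    cols["intermediate"] = (df["category"] == "intermediate").astype(float)
    cols["high"] = (df["category"] == "high").astype(float)
    cols["ever_use"] = df["ever_use"].astype(float)
    cols["log2_fills"] = df["log2_fills"].astype(float)
    X = cols[terms].to_numpy(dtype=float)
    labels = df["set_id"].to_numpy()
    keep = _informative_columns(X, labels)
    kept_terms = [t for t, k in zip(terms, keep) if k]
    dropped_terms = [t for t, k in zip(terms, keep) if not k]
    if not kept_terms:
        raise FitError("no informative covariate columns in the design")
    design = MatchedDesign.from_rows(X[:, keep], df["is_case"].to_numpy(),
                                     labels, kept_terms)
    res = fit_clr(design, n_exposed_cases=n_exposed_cases)
    if dropped_terms:
        res.warnings.append("dropped constant-within-sets columns: "
                            + ", ".join(dropped_terms))
        res = _expand_result(res, terms)
    return res


def _expand_result(res: FitResult, terms: list[str]) -> FitResult:
    """Re-insert NaN rows for dropped parameters so names stay stable."""
    p = len(terms)
    beta = np.full(p, np.nan)
    se = np.full(p, np.nan)
    cov = np.full((p, p), np.nan)
    ci = np.full((p, 2), np.nan)
    pos = {t: i for i, t in enumerate(terms)}
    src = [pos[t] for t in res.param_names]
    beta[src] = res.beta
    se[src] = res.se
    ci[src] = res.ci95
    for a, ia in zip(src, range(len(src))):
        for b, ib in zip(src, range(len(src))):
            cov[a, b] = res.cov[ia, ib]
    return FitResult(param_names=terms, beta=beta, cov=cov, se=se,
                     or_=np.exp(beta), ci95=ci, converged=res.converged,
                     loglik=res.loglik, n_iter=res.n_iter,
                     n_sets_used=res.n_sets_used,
                     n_exposed_cases=res.n_exposed_cases,
                     warnings=res.warnings)


def fit_categorical_model(pair_design: pd.DataFrame) -> FitResult:
    """ORs for low/intermediate/high use versus nonuse, covariate-adjusted."""
    if int(pair_design["ever_use"].sum()) == 0:
        raise NoExposedSubjectsError(
            "no exposed subjects: every case and control is a never-user")
    return _fit_design_frame(pair_design, CATEGORICAL_TERMS)


def fit_dose_response_model(pair_design: pd.DataFrame) -> FitResult:
    """OR per doubling of cumulative fills among ever-users."""
    if int(pair_design["ever_use"].sum()) == 0:
        raise NoExposedSubjectsError(
            "no exposed subjects: every case and control is a never-user")
    return _fit_design_frame(pair_design, DOSE_TERMS)
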