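"""Binomial (mixed) models for triploidy and aneuploidy incidence.

Two model classes in the statsmodels idiom -- construct from a DataFrame,
``fit()`` returns a results object with estimates, standard errors, AIC and
a ``summary()`` table:

* :class:`BinomialGLM` -- fixed-effects logistic regression (backed by
  statsmodels IRLS) for the un-nested experiment.
* :class:`RandomInterceptLogit` -- logistic regression with a Gaussian
  random intercept per group (treatment replicate), for the nested
  experiment.  The marginal likelihood integrates the random effect by
  adaptive Gauss-Hermite quadrature (default 15 nodes; 1 node is the
  Laplace approximation), and reduces to the plain GLM as the
  random-intercept SD goes to 0.

Also here: ``drop1_aic`` term evaluation (refit dropping each fixed effect,
never the random intercept), quasi-complete separation detection with the
drop-the-offending-level remedy, and stage-wise mortality rates.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from numpy.polynomial.hermite_e import hermegauss
from scipy.optimize import minimize
from scipy.special import expit, logsumexp

__all__ = [
    "ModelSpec", "FitResult", "BinomialGLM", "RandomInterceptLogit",
    "fit_binomial_glm", "fit_random_intercept_logit", "drop1_aic",
    "detect_separation", "mortality_rates", "SeparationError",
]


class SeparationError(RuntimeError):
    pass


@dataclass(frozen=True)
class ModelSpec:
    """What to fit: Bernoulli response, categorical fixed effects, optional
    random intercept grouping, logit link."""
    response: str
    fixed_effects: tuple[str, ...] = ()
    random_intercept_group: str | None = None
    ref_levels: Mapping[str, object] = field(default_factory=dict)

    def without(self, term: str) -> "ModelSpec":
        if term not in self.fixed_effects:
            raise ValueError(f"{term!r} is not a fixed effect of this model")
        return replace(self, fixed_effects=tuple(
            t for t in self.fixed_effects if t != term))


def build_design(data: pd.DataFrame, spec: ModelSpec
                 ) -> tuple[np.ndarray, pd.DataFrame, dict[str, list[str]]]:
    """Response vector, design matrix (intercept + treatment-coded factors)
    and the term -> columns map."""
    y = data[spec.response].to_numpy(dtype=float)
    if not np.isin(y, [0.0, 1.0]).all():
        raise ValueError(f"response {spec.response!r} must be 0/1")
    cols = {"Intercept": np.ones(len(data))}
    term_map: dict[str, list[str]] = {}
    for term in spec.fixed_effects:
        values = data[term]
        levels = sorted(values.unique(), key=str)
        if len(levels) < 2:
            term_map[term] = []     # single level left: absorbed by intercept
            continue
        ref = spec.ref_levels.get(term, levels[0])
        if ref not in levels:
            ref = levels[0]         # configured reference absent after subsetting
        names = []
        for lvl in levels:
            if lvl == ref:
                continue
            name = f"{term}[{lvl}]"
            cols[name] = (values == lvl).to_numpy(dtype=float)
            names.append(name)
        term_map[term] = names
    X = pd.DataFrame(cols, index=data.index)
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        # name the aliased columns via QR
        _, r = np.linalg.qr(X.to_numpy())
        aliased = [X.columns[j] for j in range(X.shape[1])
                   if abs(r[j, j]) < 1e-8]
        raise ValueError(f"rank-deficient design; aliased column(s): {aliased}")
    return y, X, term_map


def detect_separation(data: pd.DataFrame, response: str,
                      factors: Sequence[str]
                      ) -> tuple[bool, list[tuple[str, object, float]]]:
    """Flag factor levels whose response cells are all-0 or all-1
    (quasi-complete separation: the MLE for that level diverges)."""
    offending = []
    y = data[response]
    for factor in factors:
        for level, idx in data.groupby(factor, sort=True).groups.items():
            mean = float(y.loc[idx].mean())
            if len(idx) > 0 and mean in (0.0, 1.0):
                offending.append((factor, level, mean))
    return bool(offending), offending


@dataclass
class FitResult:
    """Estimates and diagnostics of a fitted binomial (mixed) model.

    ``aic`` always equals 2k - 2*loglik with k the number of estimated
    parameters (including the random-intercept SD when present).
    """
    model: object
    params: pd.Series
    bse: pd.Series
    re_sd: float | None
    loglik: float
    nparams: int
    converged: bool
    separation_flag: bool
    offending_levels: list = field(default_factory=list)
    dropped_levels: list = field(default_factory=list)

    @property
    def aic(self) -> float:
        return 2.0 * self.nparams - 2.0 * self.loglik

    def summary(self) -> str:
        lines = []
        spec = self.model.spec
        kind = ("random-intercept logit"
                if spec.random_intercept_group else "binomial GLM (logit)")
        lines.append(f"{kind}: {spec.response} ~ "
                     + (" + ".join(spec.fixed_effects) or "1"))
        if spec.random_intercept_group:
            lines.append(f"random intercept: {spec.random_intercept_group} "
                         f"(SD = {self.re_sd:.4f})")
        lines.append(f"loglik = {self.loglik:.3f}   AIC = {self.aic:.3f}   "
                     f"k = {self.nparams}   converged = {self.converged}")
        if self.separation_flag:
            lines.append("WARNING: quasi-complete separation detected; "
                         "standard errors are unreliable for: "
                         + ", ".join(f"{f}={l}" for f, l, _ in
                                     self.offending_levels))
        lines.append(f"{'term':<24}{'estimate':>12}{'SE':>12}")
        for name in self.params.index:
            lines.append(f"{name:<24}{self.params[name]:>12.4f}"
                         f"{self.bse[name]:>12.4f}")
        return "\n".join(lines)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"term": self.params.index,
                           "estimate": self.params.values,
                           "se": self.bse.values})
        df["loglik"] = self.loglik
        df["aic"] = self.aic
        df["re_sd"] = self.re_sd if self.re_sd is not None else np.nan
        df["converged"] = self.converged
        df["separation_flag"] = self.separation_flag
        return df


class BinomialGLM:
    """Fixed-effects logistic regression on a Bernoulli response.

    Thin model object over statsmodels' IRLS; the fit is deterministic
    given the data and invariant to row order.
    """

    def __init__(self, data: pd.DataFrame, spec: ModelSpec):
        if spec.random_intercept_group:
            raise ValueError("use RandomInterceptLogit for a grouped model")
        self.data = data.reset_index(drop=True)
        self.spec = spec
        self.y, self.X, self.term_map = build_design(self.data, spec)

    @classmethod
    def from_dataframe(cls, data, response, fixed_effects,
                       ref_levels=None) -> "BinomialGLM":
        return cls(data, ModelSpec(response=response,
                                   fixed_effects=tuple(fixed_effects),
                                   ref_levels=ref_levels or {}))

    def fit(self) -> FitResult:
        sep_flag, offending = detect_separation(
            self.data, self.spec.response, self.spec.fixed_effects)
        if not sep_flag and len(self.spec.fixed_effects) == 0:
            # intercept-only: separation is an all-constant response
            m = float(self.y.mean())
            sep_flag = m in (0.0, 1.0)
            offending = [("(intercept)", "all", m)] if sep_flag else []
        res = sm.GLM(self.y, self.X, family=sm.families.Binomial()).fit()
        return FitResult(
            model=self, params=res.params, bse=res.bse, re_sd=None,
            loglik=float(res.llf), nparams=self.X.shape[1],
            converged=bool(res.converged), separation_flag=sep_flag,
            offending_levels=offending)

    # -- interface shared with RandomInterceptLogit (drop1, remedies) ------
    def refit_without_term(self, term: str) -> "BinomialGLM":
        return BinomialGLM(self.data, self.spec.without(term))

    def refit_without_levels(self, drop: Mapping[str, Sequence]) -> "BinomialGLM":
        """Drop the observations of the named factor levels (the study's
        separation remedy) and rebuild the model."""
        keep = np.ones(len(self.data), dtype=bool)
        for factor, levels in drop.items():
            keep &= ~self.data[factor].isin(list(levels)).to_numpy()
        return BinomialGLM(self.data.loc[keep], self.spec)


class RandomInterceptLogit:
    """Logistic regression with a Gaussian random intercept per group.

    The marginal log-likelihood sums, over groups j,

        log integral prod_i Bernoulli(y_ij | logit^-1(x_ij'b + u_j))
                     N(u_j; 0, sigma^2) du_j

    evaluated by adaptive Gauss-Hermite quadrature centred on each group's
    posterior mode.  sigma is estimated jointly with the fixed effects
    (bounded at 0, where the model collapses to the plain GLM).
    """

    def __init__(self, data: pd.DataFrame, spec: ModelSpec):
        if not spec.random_intercept_group:
            raise ValueError("spec lacks a random-intercept group")
        self.data = data.reset_index(drop=True)
        self.spec = spec
        self.y, self.X, self.term_map = build_design(self.data, spec)
        groups = self.data[spec.random_intercept_group]
        labels = sorted(groups.unique(), key=str)
        if len(labels) < 2:
            raise ValueError("need >= 2 groups for a random intercept")
        self.group_labels = labels
        self._group_rows = [np.flatnonzero((groups == g).to_numpy())
                            for g in labels]

    @classmethod
    def from_dataframe(cls, data, response, fixed_effects, group,
                       ref_levels=None) -> "RandomInterceptLogit":
        return cls(data, ModelSpec(response=response,
                                   fixed_effects=tuple(fixed_effects),
                                   random_intercept_group=group,
                                   ref_levels=ref_levels or {}))

    # ------------------------------------------------------------------
    @staticmethod
    def _bernoulli_ll(eta: np.ndarray, y: np.ndarray) -> np.ndarray:
        # stable log f(y | eta) elementwise
        return -np.logaddexp(0.0, np.where(y > 0.5, -eta, eta))

    def _group_marginal(self, eta: np.ndarray, y: np.ndarray, sigma: float,
                        nodes: np.ndarray, logw: np.ndarray) -> float:
        s2 = sigma * sigma
        # posterior mode of the group intercept (Newton, scalar)
        b = 0.0
        for _ in range(100):
            p = expit(eta + b)
            grad = float(np.sum(y - p)) - b / s2
            hess = -float(np.sum(p * (1.0 - p))) - 1.0 / s2
            step = grad / hess
            b -= step
            if abs(step) < 1e-11:
                break
        tau = 1.0 / np.sqrt(-hess)
        bk = b + tau * nodes                                   # (K,)
        ll = self._bernoulli_ll(eta[:, None] + bk[None, :],
                                y[:, None]).sum(axis=0)
        ll += -0.5 * bk * bk / s2 - 0.5 * np.log(2.0 * np.pi * s2)
        # int g(u) du ~ tau * sum_k w_k exp(z_k^2/2) g(b_k)  (Hermite_e)
        return float(logsumexp(ll + 0.5 * nodes ** 2 + logw) + np.log(tau))

    def loglike(self, beta: np.ndarray, sigma: float,
                n_quad: int = 15) -> float:
        Xb = self.X.to_numpy() @ beta
        if sigma < 1e-8:
            return float(self._bernoulli_ll(Xb, self.y).sum())
        nodes, weights = hermegauss(n_quad)
        logw = np.log(weights)
        return sum(self._group_marginal(Xb[rows], self.y[rows], sigma,
                                        nodes, logw)
                   for rows in self._group_rows)

    def fit(self, n_quad: int = 15, method: str = "aghq",
            start_params: np.ndarray | None = None,
            fix_re_sd: float | None = None) -> FitResult:
        """Maximise the marginal likelihood.

        ``method='laplace'`` is the 1-node shortcut; anything else uses
        ``n_quad`` adaptive Gauss-Hermite nodes.  ``fix_re_sd`` profiles
        the fixed effects at a fixed random-intercept SD (0 gives the
        plain-GLM limit exactly).
        """
        if method == "laplace":
            n_quad = 1
        p = self.X.shape[1]
        if start_params is None:
            glm = sm.GLM(self.y, self.X, family=sm.families.Binomial()).fit()
            start = np.r_[glm.params.to_numpy(),
                          0.3 if fix_re_sd is None else fix_re_sd]
        else:
            start = np.asarray(start_params, dtype=float)

        def nll(theta):
            return -self.loglike(theta[:p], theta[p], n_quad=n_quad)

        sd_bound = ((0.0, None) if fix_re_sd is None
                    else (fix_re_sd, fix_re_sd))
        bounds = [(None, None)] * p + [sd_bound]
        opt = minimize(nll, start, method="L-BFGS-B", bounds=bounds,
                       options={"maxiter": 500, "ftol": 1e-11})
        theta = opt.x
        sep_flag, offending = detect_separation(
            self.data, self.spec.response, self.spec.fixed_effects)

        # standard errors from the numerical Hessian at the optimum
        from statsmodels.tools.numdiff import approx_hess1
        bse = np.full(p + 1, np.nan)
        try:
            H = approx_hess1(theta, nll)
            cov = np.linalg.inv(H)
            d = np.diag(cov)
            bse = np.sqrt(np.where(d > 0, d, np.nan))
        except np.linalg.LinAlgError:
            pass

        names = list(self.X.columns)
        return FitResult(
            model=self, params=pd.Series(theta[:p], index=names),
            bse=pd.Series(bse[:p], index=names),
            re_sd=float(theta[p]), loglik=float(-opt.fun),
            nparams=p + 1, converged=bool(opt.success),
            separation_flag=sep_flag, offending_levels=offending)

    def refit_without_term(self, term: str) -> "RandomInterceptLogit":
        return RandomInterceptLogit(self.data, self.spec.without(term))

    def refit_without_levels(self, drop: Mapping[str, Sequence]
                             ) -> "RandomInterceptLogit":
        keep = np.ones(len(self.data), dtype=bool)
        for factor, levels in drop.items():
            keep &= ~self.data[factor].isin(list(levels)).to_numpy()
        return RandomInterceptLogit(self.data.loc[keep], self.spec)


# ---------------------------------------------------------------------------
# functional wrappers and model selection
# ---------------------------------------------------------------------------

def fit_binomial_glm(data: pd.DataFrame, spec: ModelSpec) -> FitResult:
    return BinomialGLM(data, spec).fit()


def fit_random_intercept_logit(data: pd.DataFrame, spec: ModelSpec,
                               n_quad: int = 15) -> FitResult:
    return RandomInterceptLogit(data, spec).fit(n_quad=n_quad)


def drop1_aic(model) -> pd.DataFrame:
    """Single-term deletions: refit the model dropping each fixed effect in
    turn (the random intercept, when present, is always retained) and
    tabulate AIC.  The lowest-AIC row is the recommendation.
    """
    full = model.fit()
    rows = [{"dropped": "<none>", "k": full.nparams, "loglik": full.loglik,
             "aic": full.aic, "converged": full.converged}]
    for term in model.spec.fixed_effects:
        try:
            res = model.refit_without_term(term).fit()
            rows.append({"dropped": term, "k": res.nparams,
                         "loglik": res.loglik, "aic": res.aic,
                         "converged": res.converged})
        except Exception as exc:  # propagate as a labelled row
            rows.append({"dropped": term, "k": np.nan, "loglik": np.nan,
                         "aic": np.nan, "converged": False,
                         "error": str(exc)})
    out = pd.DataFrame(rows)
    out["delta_aic"] = out["aic"] - out["aic"].iloc[0]
    out["recommended"] = out["aic"] == out["aic"].min()
    return out


def mortality_rates(counts: pd.DataFrame,
                    by: Sequence[str] | None = None) -> pd.DataFrame:
    """Stage-interval mortality rates, n_dead / n_start.

    With ``by`` given, counts are pooled (summed) within each group x
    interval before dividing -- the pooled-count rate, not a mean of rates.
    A unit with n_start = 0 yields an undefined (NaN) rate, flagged.
    """
    df = counts.copy()
    if by:
        df = (df.groupby([*by, "interval"], sort=True, as_index=False)
                [["n_start", "n_dead"]].sum())
    df["mortality_rate"] = df["n_dead"] / df["n_start"].replace(0, np.nan)
    df["undefined_rate"] = df["n_start"] == 0
    return df
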