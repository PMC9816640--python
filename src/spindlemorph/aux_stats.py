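"""Supporting statistical fits.

* Poisson GLM (log link) for KMT-per-fiber counts, fitted by iteratively
  reweighted least squares.  With a single categorical covariate the MLE
  reproduces the group means exactly, so the condition coefficient is the
  log ratio of group mean counts.
* OLS linear models for angle comparisons with an experiment covariate.
* Pooled-variance two-tailed Student's t test.
* Logarithmic tortuosity-vs-length fit t = a + b·ln(length).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats


class StatsError(ValueError):
    pass


@dataclass
class GlmFit:
    """A fitted regression: estimates, standard errors, Wald tests."""

    model: str
    terms: list[str]
    params: np.ndarray
    se: np.ndarray
    zvalues: np.ndarray
    pvalues: np.ndarray
    loglik: float
    n: int
    extra: dict = field(default_factory=dict)

    def coef(self, term: str) -> float:
        return float(self.params[self.terms.index(term)])

    def pvalue(self, term: str) -> float:
        return float(self.pvalues[self.terms.index(term)])

    def to_dict(self) -> dict:
        return {
            "model": self.model,
            "n": self.n,
            "terms": {
                t: {
                    "estimate": float(b),
                    "se": float(s),
                    "z": float(z),
                    "p": float(p),
                }
                for t, b, s, z, p in zip(self.terms, self.params, self.se, self.zvalues, self.pvalues)
            },
            "loglik": self.loglik,
            **self.extra,
        }


# ---------------------------------------------------------------------------
# Poisson GLM by IRLS
# ---------------------------------------------------------------------------


def fit_poisson_counts(
    counts: np.ndarray,
    condition_labels: np.ndarray,
    reference: str | None = None,
    max_iter: int = 100,
    tol: float = 1e-12,
) -> GlmFit:
    """Poisson GLM with log link comparing count distributions across
    conditions, fitted by IRLS with treatment coding.

    *reference* picks the baseline condition (default: first label in order
    of appearance).  Coefficients for the other conditions are log mean
    ratios; p-values are Wald.
    """
    y = np.asarray(counts, float)
    labels = np.asarray(condition_labels)
    if y.shape != labels.shape:
        raise StatsError("counts and condition_labels must align")
    if np.any(y < 0) or np.any(y != np.round(y)):
        raise StatsError("counts must be non-negative integers")
    levels = list(dict.fromkeys(labels.tolist()))
    if len(levels) < 2:
        raise StatsError("at least 2 conditions required")
    if reference is None:
        reference = levels[0]
    if reference not in levels:
        raise StatsError(f"unknown reference level {reference!r}")
    others = [l for l in levels if l != reference]
    terms = ["(Intercept)"] + [f"condition[{l}]" for l in others]
    X = np.column_stack([np.ones(len(y))] + [(labels == l).astype(float) for l in others])

    beta = np.zeros(X.shape[1])
    beta[0] = np.log(max(y.mean(), 1e-8))
    deviance = np.inf
    dev_trace = []
    converged = False
    for _ in range(max_iter):
        eta = X @ beta
        if np.any(eta > 30):
            break
        mu = np.exp(eta)
        # working response and weights for the log link
        z = eta + (y - mu) / mu
        W = mu
        XtW = X.T * W
        try:
            beta_new = np.linalg.solve(XtW @ X, XtW @ z)
        except np.linalg.LinAlgError as e:
            raise StatsError(f"singular IRLS system: {e}") from e
        with np.errstate(divide="ignore", invalid="ignore"):
            dev_terms = np.where(y > 0, y * np.log(y / mu), 0.0) - (y - mu)
        new_dev = 2.0 * float(np.sum(dev_terms))
        dev_trace.append(new_dev)
        if abs(deviance - new_dev) < tol * (abs(new_dev) + 1):
            beta = beta_new
            converged = True
            break
        beta, deviance = beta_new, new_dev
    if not converged or np.any(np.abs(beta) > 30):
        raise StatsError(
            "Poisson IRLS did not converge (a group with mean zero makes the "
            "coefficient diverge)"
        )
    eta = X @ beta
    mu = np.exp(eta)
    info = (X.T * mu) @ X
    cov = np.linalg.inv(info)
    se = np.sqrt(np.diag(cov))
    zvals = beta / se
    pvals = 2 * stats.norm.sf(np.abs(zvals))
    ll = float(np.sum(stats.poisson.logpmf(y.astype(int), mu)))
    return GlmFit(
        model="poisson-log",
        terms=terms,
        params=beta,
        se=se,
        zvalues=zvals,
        pvalues=pvals,
        loglik=ll,
        n=len(y),
        extra={"reference": reference, "deviance_trace": dev_trace},
    )


# ---------------------------------------------------------------------------
# linear model for angles
# ---------------------------------------------------------------------------


def fit_linear_angles(
    values: np.ndarray,
    condition: np.ndarray,
    experiment: np.ndarray | None = None,
    reference: str | None = None,
) -> GlmFit:
    """OLS of angle measurements on condition (+ experiment fixed effect).

    The p-value for the condition term is t-based.
    """
    import statsmodels.api as sm

    y = np.asarray(values, float)
    cond = np.asarray(condition)
    levels = list(dict.fromkeys(cond.tolist()))
    if reference is None:
        reference = levels[0]
    others = [l for l in levels if l != reference]
    terms = ["(Intercept)"] + [f"condition[{l}]" for l in others]
    cols = [np.ones(len(y))] + [(cond == l).astype(float) for l in others]
    if experiment is not None:
        exp = np.asarray(experiment)
        exp_levels = list(dict.fromkeys(exp.tolist()))
        for l in exp_levels[1:]:
            terms.append(f"experiment[{l}]")
            cols.append((exp == l).astype(float))
    X = np.column_stack(cols)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise StatsError("rank-deficient design")
    fit = sm.OLS(y, X).fit()
    return GlmFit(
        model="ols",
        terms=terms,
        params=np.asarray(fit.params),
        se=np.asarray(fit.bse),
        zvalues=np.asarray(fit.tvalues),
        pvalues=np.asarray(fit.pvalues),
        loglik=float(fit.llf),
        n=len(y),
        extra={"reference": reference},
    )


def two_tailed_t_test(sample_a: np.ndarray, sample_b: np.ndarray) -> tuple[float, float]:
    """Pooled-variance two-tailed Student's t test."""
    a = np.asarray(sample_a, float)
    b = np.asarray(sample_b, float)
    if len(a) < 2 or len(b) < 2:
        raise StatsError("each sample needs n >= 2")
    pooled = ((len(a) - 1) * a.var(ddof=1) + (len(b) - 1) * b.var(ddof=1)) / (len(a) + len(b) - 2)
    if pooled == 0 and a.mean() == b.mean():
        return 0.0, 1.0
    if pooled == 0:
        raise StatsError("zero pooled variance with unequal means")
    t, p = stats.ttest_ind(a, b, equal_var=True)
    return float(t), float(p)


def tortuosity_length_fit(lengths: np.ndarray, tortuosities: np.ndarray) -> tuple[float, float]:
    """Least-squares fit of tortuosity = a + b·ln(length); returns (a, b)."""
    L = np.asarray(lengths, float)
    t = np.asarray(tortuosities, float)
    if np.any(L <= 0):
        raise StatsError("lengths must be positive")
    if np.unique(L).size < 2:
        raise StatsError("at least 2 distinct lengths required")
    X = np.column_stack([np.ones(len(L)), np.log(L)])
    coef, *_ = np.linalg.lstsq(X, t, rcond=None)
    return float(coef[0]), float(coef[1])
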