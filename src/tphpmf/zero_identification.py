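"""Distinguishing non-biological zeros from true absences.

Each taxon's log-abundance column is modelled as a two-component mixture:
with probability ``p`` the value comes from a gamma distribution
Gamma(alpha, beta) concentrated near the zero placeholder (dropout /
technical zeros), and with probability ``1 - p`` from a normal regression
``N(x_i' gamma, sigma^2)`` on the sample covariates (true signal).  The
mixture is fitted per taxon by EM; taxa for which the mixture beats the
plain normal regression in a likelihood-ratio test are screened for zeros
whose posterior gamma membership ``e_ij`` is at least 0.5 — those zeros
are declared non-biological and queued for imputation.

Before any fitting, a one-sided binomial screen drops taxa that are
essentially absent everywhere: a taxon is kept only when the one-sided
Wilson lower confidence bound on the proportion of samples exceeding an
abundance threshold is strictly positive.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import digamma, gammaln, polygamma
from statsmodels.stats.proportion import proportion_confint

from .preprocessing import LogMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "CovariateTable",
    "EMConfig",
    "MixtureFit",
    "ZeroFlagReport",
    "filter_taxa_binomial",
    "fit_gamma_normal_mixture",
    "likelihood_ratio_test",
    "posterior_membership",
    "flag_nonbiological_zeros",
]


@dataclass
class CovariateTable:
    """Sample covariate design matrix with a leading intercept column."""

    X: np.ndarray
    covariate_names: list[str]

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        if self.X.ndim != 2:
            raise ValueError("covariate matrix must be two-dimensional")
        if len(self.covariate_names) != self.X.shape[1]:
            raise ValueError("covariate name count mismatch")
        if not np.all(np.isfinite(self.X)):
            raise ValueError("missing or non-finite covariate entries")
        if not np.allclose(self.X[:, 0], 1.0):
            raise ValueError("first covariate column must be the intercept")

    @classmethod
    def intercept_only(cls, n_samples: int) -> "CovariateTable":
        return cls(np.ones((n_samples, 1)), ["intercept"])

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "CovariateTable":
        """Build a design matrix: continuous columns standardized,
        categoricals one-hot encoded with the first level dropped."""
        cols: list[np.ndarray] = [np.ones(len(df))]
        names: list[str] = ["intercept"]
        for name in df.columns:
            col = df[name]
            if pd.api.types.is_numeric_dtype(col):
                v = col.to_numpy(dtype=float)
                sd = v.std(ddof=0)
                if sd == 0:
                    continue  # constant column carries no information
                cols.append((v - v.mean()) / sd)
                names.append(name)
            else:
                dummies = pd.get_dummies(col, drop_first=True)
                for dname in dummies.columns:
                    cols.append(dummies[dname].to_numpy(dtype=float))
                    names.append(f"{name}[{dname}]")
        return cls(np.column_stack(cols), names)


@dataclass
class EMConfig:
    tol: float = 1e-6
    max_iter: int = 100
    seed: int | None = None


@dataclass
class MixtureFit:
    """Fitted gamma-normal mixture for one taxon."""

    taxon_id: str
    p: float
    alpha: float
    beta: float  # gamma rate
    gamma_coef: np.ndarray
    sigma: float
    loglik_mixture: float
    loglik_null: float
    lrt_pvalue: float
    converged: bool
    n_iter: int


@dataclass
class ZeroFlagReport:
    kept_taxa: set[str]
    e: np.ndarray  # posterior gamma membership, NaN where not fitted
    flags: np.ndarray  # boolean, True = non-biological zero
    fits: dict[str, MixtureFit] = field(default_factory=dict)
    failures: dict[str, str] = field(default_factory=dict)


def filter_taxa_binomial(
    log_matrix: LogMatrix,
    abundance_threshold: float | None = None,
    confidence: float = 0.95,
) -> set[str]:
    """Keep taxa whose prevalence is significantly above zero.

    For each taxon the proportion of samples with abundance strictly above
    ``abundance_threshold`` (default: the zero placeholder, i.e. any
    non-zero count) is tested via the one-sided Wilson lower bound at the
    given confidence level; the taxon is retained iff that bound is > 0.
    """
    if not 0 < confidence < 1:
        raise ValueError("confidence must be in (0, 1)")
    if abundance_threshold is None:
        abundance_threshold = log_matrix.zero_value
    n = log_matrix.shape[0]
    kept: set[str] = set()
    above = (log_matrix.values > abundance_threshold + 1e-12) & ~log_matrix.missing_mask
    counts = above.sum(axis=0)
    # one-sided lower bound at `confidence` == two-sided Wilson at
    # alpha = 2 * (1 - confidence)
    alpha = 2 * (1 - confidence)
    for j, taxon in enumerate(log_matrix.taxon_ids):
        lower, _ = proportion_confint(counts[j], n, alpha=alpha, method="wilson")
        if lower > 0:
            kept.add(taxon)
    return kept


def _gamma_logpdf(y: np.ndarray, alpha: float, beta: float) -> np.ndarray:
    # rate parameterization
    return alpha * np.log(beta) - gammaln(alpha) + (alpha - 1) * np.log(y) - beta * y


def _normal_logpdf(y: np.ndarray, mu: np.ndarray, sigma: float) -> np.ndarray:
    return -0.5 * np.log(2 * np.pi) - np.log(sigma) - 0.5 * ((y - mu) / sigma) ** 2


def _weighted_gamma_fit(y: np.ndarray, w: np.ndarray) -> tuple[float, float]:
    """Responsibility-weighted gamma MLE.

    With weights fixed, the M-step maximizer satisfies ``beta = alpha /
    mean_w`` and ``log(alpha) - digamma(alpha) = log(mean_w) -
    mean_w(log y)``; the shape equation is solved by safeguarded Newton
    from a method-of-moments start (an exact maximizer keeps the EM
    log-likelihood monotone)."""
    wsum = w.sum()
    mean = float(np.dot(w, y) / wsum)
    var = float(np.dot(w, (y - mean) ** 2) / wsum)
    var = max(var, 1e-12)
    alpha = mean * mean / var
    s = np.log(mean) - float(np.dot(w, np.log(y)) / wsum)
    if s > 1e-12:
        # f(a) = log a - psi(a) - s is strictly decreasing in a
        alpha = max(alpha, 1e-8)
        for _ in range(100):
            f = np.log(alpha) - digamma(alpha) - s
            if abs(f) < 1e-12:
                break
            fp = 1.0 / alpha - polygamma(1, alpha)
            step = f / fp
            new = alpha - step
            if not np.isfinite(new) or new <= 0:
                new = alpha / 2 if f < 0 else alpha * 2
            alpha = new
    alpha = float(np.clip(alpha, 1e-8, 1e8))
    beta = alpha / mean
    return alpha, beta


def _wls(y: np.ndarray, X: np.ndarray, w: np.ndarray) -> tuple[np.ndarray, float]:
    """Weighted least squares; returns coefficients and weighted residual sd."""
    sw = np.sqrt(w)
    coef, *_ = np.linalg.lstsq(X * sw[:, None], y * sw, rcond=None)
    resid = y - X @ coef
    sigma2 = float(np.dot(w, resid**2) / w.sum())
    return coef, float(np.sqrt(max(sigma2, 1e-12)))


def _null_loglik(y: np.ndarray, X: np.ndarray) -> float:
    """Log-likelihood of the normal-regression-only model (MLE sigma)."""
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    sigma2 = max(float(np.mean(resid**2)), 1e-12)
    n = len(y)
    return float(-0.5 * n * (np.log(2 * np.pi * sigma2) + 1))


def fit_gamma_normal_mixture(
    y: np.ndarray,
    X: CovariateTable | np.ndarray,
    config: EMConfig | None = None,
    taxon_id: str = "",
) -> MixtureFit:
    """Fit ``p * Gamma(alpha, beta) + (1 - p) * N(x' gamma, sigma^2)`` by EM.

    Initialization splits ``y`` at its 25th percentile: the low part seeds
    the gamma component (method of moments), the high part seeds the normal
    regression.  The observed-data log-likelihood is checked to be
    non-decreasing at every iteration.
    """
    config = config or EMConfig()
    Xmat = X.X if isinstance(X, CovariateTable) else np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    finite = np.isfinite(y)
    y, Xmat = y[finite], Xmat[finite]
    q = Xmat.shape[1]
    if len(y) < q + 3:
        raise ValueError(f"too few observations ({len(y)}) to fit mixture")
    if np.any(y <= 0):
        raise ValueError("mixture requires strictly positive values")
    if np.std(y) < 1e-10:
        raise ValueError(f"degenerate column: taxon {taxon_id!r} is near-constant")

    split = np.quantile(y, 0.25)
    low = y <= split
    if low.sum() < 2 or (~low).sum() < q + 1:
        order = np.argsort(y)
        low = np.zeros(len(y), dtype=bool)
        low[order[: max(2, len(y) // 4)]] = True
    p = float(np.clip(low.mean(), 0.05, 0.95))
    alpha, beta = _weighted_gamma_fit(y, low.astype(float) + 1e-6)
    coef, sigma = _wls(y, Xmat, (~low).astype(float) + 1e-6)

    loglik = -np.inf
    converged = False
    it = 0
    for it in range(1, config.max_iter + 1):
        # E-step in log space
        mu = Xmat @ coef
        lg = np.log(p + 1e-300) + _gamma_logpdf(y, alpha, beta)
        ln = np.log(1 - p + 1e-300) + _normal_logpdf(y, mu, sigma)
        lse = np.logaddexp(lg, ln)
        r = np.exp(lg - lse)  # gamma responsibility
        new_loglik = float(lse.sum())
        if new_loglik < loglik - 1e-8:
            warnings.warn(
                f"EM log-likelihood decreased for taxon {taxon_id!r} "
                f"({loglik:.6g} -> {new_loglik:.6g})"
            )
        if abs(new_loglik - loglik) < config.tol:
            loglik = new_loglik
            converged = True
            break
        loglik = new_loglik
        # M-step
        p = float(np.clip(r.mean(), 1e-6, 1 - 1e-6))
        if r.sum() > 1e-8:
            alpha, beta = _weighted_gamma_fit(y, r)
        wn = 1 - r
        if wn.sum() > q:
            coef, sigma = _wls(y, Xmat, wn)
    if not converged:
        warnings.warn(f"EM did not converge for taxon {taxon_id!r} in {it} iters")

    ll_null = _null_loglik(y, Xmat)
    if loglik < ll_null - 1e-10:
        # the null (p = 0) lies in the mixture's closure, so when EM lands
        # on an interior local mode below it the boundary solution is the
        # actual MLE: report the null fit with p = 0
        coef, *_ = np.linalg.lstsq(Xmat, y, rcond=None)
        sigma = float(np.sqrt(max(np.mean((y - Xmat @ coef) ** 2), 1e-12)))
        p = 0.0
        loglik = ll_null
    fit = MixtureFit(
        taxon_id=taxon_id,
        p=p,
        alpha=alpha,
        beta=beta,
        gamma_coef=coef,
        sigma=sigma,
        loglik_mixture=loglik,
        loglik_null=ll_null,
        lrt_pvalue=np.nan,
        converged=converged,
        n_iter=it,
    )
    fit.lrt_pvalue = likelihood_ratio_test(fit)
    return fit


def likelihood_ratio_test(fit: MixtureFit, df: int = 3) -> float:
    """Chi-square LRT of the mixture against the normal-only regression.

    The mixture adds the mixing weight and the two gamma parameters, hence
    df = 3; the null sits on the boundary p = 0, so the reference is
    approximate (conservative).
    """
    stat = 2.0 * (fit.loglik_mixture - fit.loglik_null)
    if stat < -1e-6 * max(1.0, abs(fit.loglik_null)):
        raise ValueError(
            f"negative LRT statistic {stat:.6g} for taxon {fit.taxon_id!r}: "
            "mixture fit worse than null beyond tolerance"
        )
    stat = max(stat, 0.0)
    return float(np.clip(stats.chi2.sf(stat, df), 0.0, 1.0))


def posterior_membership(
    fit: MixtureFit, y: np.ndarray | float, x: np.ndarray | None = None
) -> np.ndarray | float:
    """Posterior probability that an observation came from the gamma
    (dropout) component, computed in log space."""
    scalar = np.isscalar(y)
    y = np.atleast_1d(np.asarray(y, dtype=float))
    if x is None:
        mu = np.full(len(y), float(fit.gamma_coef[0]))
    else:
        x = np.atleast_2d(np.asarray(x, dtype=float))
        mu = x @ fit.gamma_coef
    if fit.p <= 0:
        e = np.zeros(len(y))
    elif fit.p >= 1:
        e = np.ones(len(y))
    else:
        lg = np.log(fit.p) + _gamma_logpdf(y, fit.alpha, fit.beta)
        ln = np.log(1 - fit.p) + _normal_logpdf(y, mu, fit.sigma)
        if np.any(np.isneginf(lg) & np.isneginf(ln)):
            raise FloatingPointError("numerical underflow: both densities zero")
        e = np.exp(lg - np.logaddexp(lg, ln))
    return float(e[0]) if scalar else e


def flag_nonbiological_zeros(
    log_matrix: LogMatrix,
    X: CovariateTable | None = None,
    config: EMConfig | None = None,
    e_threshold: float = 0.5,
    lrt_alpha: float = 0.05,
    filter_confidence: float = 0.95,
) -> ZeroFlagReport:
    """Flag zero entries judged non-biological.

    Runs the binomial prevalence filter, fits the mixture per kept taxon,
    screens by LRT p-value, and flags zero-valued entries with posterior
    gamma membership >= ``e_threshold``.  Per-taxon fit failures are
    recorded as warnings; the run never aborts on one bad column.
    """
    n, m = log_matrix.shape
    if X is None:
        X = CovariateTable.intercept_only(n)
    kept = filter_taxa_binomial(log_matrix, confidence=filter_confidence)
    e = np.full((n, m), np.nan)
    flags = np.zeros((n, m), dtype=bool)
    fits: dict[str, MixtureFit] = {}
    failures: dict[str, str] = {}
    is_zero = np.isclose(log_matrix.values, log_matrix.zero_value, atol=1e-12)
    for j, taxon in enumerate(log_matrix.taxon_ids):
        if taxon not in kept:
            continue
        y = log_matrix.values[:, j]
        try:
            fit = fit_gamma_normal_mixture(y, X, config, taxon_id=taxon)
        except (ValueError, FloatingPointError) as exc:
            failures[taxon] = str(exc)
            logger.warning("skipping taxon %s: %s", taxon, exc)
            continue
        fits[taxon] = fit
        e[:, j] = posterior_membership(fit, y, X.X)
        if fit.lrt_pvalue <= lrt_alpha:
            flags[:, j] = is_zero[:, j] & (e[:, j] >= e_threshold)
    return ZeroFlagReport(kept_taxa=kept, e=e, flags=flags, fits=fits, failures=failures)
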