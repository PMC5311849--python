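"""Weighted reverse regression of the burden proportion on phenotype subsets.

The regional burden proportion ``z_i`` is modelled as a linear combination of
K phenotypes,

    z_i = alpha + beta' y_i + eps_i,      eps_i ~ Normal(0, sigma^2 / w_i),

with precision weight ``w_i = n_i``, the number of rare variants successfully
typed for the individual.  Every non-empty phenotype subset is fitted on one
shared complete-case sample; each fit is compared with the intercept-only
null on the same individuals and weights via a likelihood-ratio test whose
statistic is approximately chi-squared with as many degrees of freedom as
phenotypes in the model.  BIC, computed with the residual variance counted as
a parameter, ranks the subsets.

The maximised weighted Gaussian log-likelihood is

    loglik = 0.5 * sum(log w_i) - (N/2) * (log(2 pi sigma2_mle) + 1),

with ``sigma2_mle = sum(w_i e_i^2) / N`` (MLE, so that loglik and BIC are
coherent); standard errors use the unbiased residual variance
``sum(w_i e_i^2) / (N - K - 1)``.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .burden import BurdenVector
from .errors import (
    DegenerateVarianceError,
    MultiburdenError,
    RegionSkipped,
    SingularModelError,
    UsageError,
)
from .formats import PhenotypeTable

__all__ = [
    "ModelSpec",
    "ModelFit",
    "WLSFit",
    "enumerate_models",
    "complete_cases",
    "fit_weighted_lm",
    "fit_null",
    "lrt_pvalue",
    "bic",
    "analyse_region",
    "bonferroni_threshold",
]

DEFAULT_MODEL_CAP = 16
LRT_TOLERANCE = 1e-8
#: minimum complete-case sample: K slopes + intercept + variance + 1 df
MIN_SAMPLE_MARGIN = 3


@dataclass(frozen=True)
class ModelSpec:
    """One phenotype combination: an ordered, non-empty subset."""

    phenotype_names: tuple[str, ...]
    indices: tuple[int, ...]

    @property
    def label(self) -> str:
        return "+".join(self.phenotype_names)

    @property
    def df(self) -> int:
        return len(self.phenotype_names)


def enumerate_models(
    phenotype_names: list[str] | tuple[str, ...], cap: int = DEFAULT_MODEL_CAP
) -> list[ModelSpec]:
    """All 2^K − 1 non-empty phenotype subsets in a deterministic order.

    The full model comes first, then subsets by decreasing size, ties broken
    lexicographically by member indices (the order of the user's phenotype
    list).
    """
    k = len(phenotype_names)
    if k == 0:
        raise UsageError("at least one phenotype must be specified")
    if k > cap:
        raise UsageError(
            f"{k} phenotypes would require {2**k - 1} models; the cap is "
            f"{cap} phenotypes (raise it with --model_cap if intended)"
        )
    specs = []
    for size in range(k, 0, -1):
        for combo in itertools.combinations(range(k), size):
            specs.append(
                ModelSpec(tuple(phenotype_names[i] for i in combo), combo)
            )
    return specs


def complete_cases(
    phenotable: PhenotypeTable,
    phenotype_names: list[str] | tuple[str, ...],
    burden: BurdenVector,
) -> np.ndarray:
    """Boolean mask of individuals usable by *every* sub-model.

    An individual is retained iff it has a usable burden (``n_i > 0``) and
    no missing value in any analysed phenotype.  One shared sample keeps the
    sub-models' BICs comparable.  Raises :class:`RegionSkipped` when fewer
    than K + 3 individuals remain.
    """
    y = phenotable.phenotype_matrix(phenotype_names)
    mask = (burden.n > 0) & ~np.isnan(y).any(axis=1)
    k = len(phenotype_names)
    if int(mask.sum()) < k + MIN_SAMPLE_MARGIN:
        raise RegionSkipped(
            f"insufficient sample: {int(mask.sum())} complete cases for "
            f"{k} phenotypes"
        )
    return mask


@dataclass
class WLSFit:
    """A single weighted least-squares fit (intercept plus slopes)."""

    alpha: float
    betas: np.ndarray
    ses: np.ndarray
    sigma2_hat: float
    loglik: float
    n_used: int


def _weighted_fit(z: np.ndarray, x: np.ndarray, w: np.ndarray) -> WLSFit:
    n, p = x.shape
    sw = np.sqrt(w)
    xs = x * sw[:, None]
    zs = z * sw
    coef, _, rank, _ = np.linalg.lstsq(xs, zs, rcond=None)
    if rank < p:
        raise SingularModelError("weighted cross-product matrix is singular")
    resid = z - x @ coef
    wrss = float(np.sum(w * resid * resid))
    scale = max(1.0, float(np.sum(w * z * z)))
    sigma2_mle = wrss / n
    if sigma2_mle <= 1e-14 * scale:
        raise DegenerateVarianceError(
            "degenerate variance (perfect fit or constant outcome)",
            alpha=float(coef[0]),
            betas=coef[1:],
        )
    loglik = 0.5 * float(np.sum(np.log(w))) - 0.5 * n * (
        math.log(2.0 * math.pi * sigma2_mle) + 1.0
    )
    if n > p:
        s2_unbiased = wrss / (n - p)
        xtwx_inv = np.linalg.inv(xs.T @ xs)
        ses_all = np.sqrt(np.diag(xtwx_inv) * s2_unbiased)
    else:
        ses_all = np.full(p, np.nan)
    return WLSFit(
        alpha=float(coef[0]),
        betas=coef[1:],
        ses=ses_all[1:],
        sigma2_hat=sigma2_mle,
        loglik=loglik,
        n_used=n,
    )


def fit_weighted_lm(z: np.ndarray, y: np.ndarray, w: np.ndarray) -> WLSFit:
    """Fit ``z = alpha + Y beta + eps`` with precision weights ``w``.

    Raises :class:`SingularModelError` for collinear phenotypes and
    :class:`DegenerateVarianceError` when the residual variance vanishes.
    """
    z = np.asarray(z, dtype=float)
    y = np.asarray(y, dtype=float)
    w = np.asarray(w, dtype=float)
    if y.ndim == 1:
        y = y[:, None]
    x = np.column_stack([np.ones(len(z)), y])
    return _weighted_fit(z, x, w)


def fit_null(z: np.ndarray, w: np.ndarray) -> WLSFit:
    """Intercept-only weighted fit: alpha-hat is the weighted mean of z."""
    z = np.asarray(z, dtype=float)
    w = np.asarray(w, dtype=float)
    return _weighted_fit(z, np.ones((len(z), 1)), w)


def lrt_pvalue(loglik_alt: float, loglik_null: float, df: int) -> float:
    """Likelihood-ratio p-value against chi-squared with ``df`` degrees.

    Statistics negative within :data:`LRT_TOLERANCE` are clamped to zero;
    larger violations signal a broken nesting and raise.
    """
    stat = 2.0 * (loglik_alt - loglik_null)
    if stat < -LRT_TOLERANCE:
        raise MultiburdenError(
            f"nested-model violation: alternative log-likelihood "
            f"{loglik_alt:.10g} below null {loglik_null:.10g}"
        )
    stat = max(stat, 0.0)
    return float(stats.chi2.sf(stat, df))


def bic(loglik: float, k_params: int, n_used: int) -> float:
    """Bayesian Information Criterion, ``k ln(n) − 2 loglik``."""
    return k_params * math.log(n_used) - 2.0 * loglik


def bonferroni_threshold(alpha: float, n_tests: int) -> float:
    """Family-wise significance level divided by the number of tests."""
    return alpha / n_tests


@dataclass
class ModelFit:
    """One phenotype combination's fitted model (or its failure status)."""

    spec: ModelSpec
    status: str = "ok"
    alpha: float | None = None
    betas: np.ndarray | None = None
    ses: np.ndarray | None = None
    sigma2_hat: float | None = None
    loglik: float | None = None
    null_loglik: float | None = None
    lrt_stat: float | None = None
    df: int = 0
    p_value: float | None = None
    bic: float | None = None
    n_used: int = 0


def analyse_region(
    burden: BurdenVector,
    phenotable: PhenotypeTable,
    phenotype_names: list[str] | tuple[str, ...],
    model_cap: int = DEFAULT_MODEL_CAP,
) -> list[ModelFit]:
    """Fit all 2^K − 1 phenotype combinations for one region.

    All sub-models share one complete-case sample; each is tested against
    the intercept-only null on the same individuals and weights.  Returns
    fits in :func:`enumerate_models` order (full model first); fits that
    fail (collinearity, degenerate variance) carry a non-"ok" status.
    Raises :class:`RegionSkipped` when the region cannot be analysed at all.
    """
    specs = enumerate_models(list(phenotype_names), cap=model_cap)
    mask = complete_cases(phenotable, phenotype_names, burden)
    z = burden.z[mask]
    w = burden.w[mask]
    y_all = phenotable.phenotype_matrix(phenotype_names)[mask]
    n = len(z)

    try:
        null = fit_null(z, w)
    except DegenerateVarianceError:
        return [
            ModelFit(spec=s, status="degenerate variance", df=s.df, n_used=n)
            for s in specs
        ]

    fits: list[ModelFit] = []
    for spec in specs:
        try:
            fit = fit_weighted_lm(z, y_all[:, spec.indices], w)
        except SingularModelError:
            fits.append(
                ModelFit(spec=spec, status="singular (collinear phenotypes)",
                         df=spec.df, n_used=n)
            )
            continue
        except DegenerateVarianceError:
            fits.append(
                ModelFit(spec=spec, status="degenerate variance",
                         df=spec.df, n_used=n)
            )
            continue
        stat = max(2.0 * (fit.loglik - null.loglik), 0.0)
        fits.append(
            ModelFit(
                spec=spec,
                alpha=fit.alpha,
                betas=fit.betas,
                ses=fit.ses,
                sigma2_hat=fit.sigma2_hat,
                loglik=fit.loglik,
                null_loglik=null.loglik,
                lrt_stat=stat,
                df=spec.df,
                p_value=lrt_pvalue(fit.loglik, null.loglik, spec.df),
                bic=bic(fit.loglik, spec.df + 2, n),
                n_used=n,
            )
        )
    return fits


def best_bic_fit(fits: list[ModelFit]) -> ModelFit | None:
    """The minimum-BIC fit among those with status "ok" (None if none)."""
    ok = [f for f in fits if f.status == "ok"]
    return min(ok, key=lambda f: f.bic) if ok else None
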