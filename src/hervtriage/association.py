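"""Per-variant case-control logistic association with ancestry adjustment.

Each biallelic variant is tested under an additive model: case status is
regressed on genotype dosage (0/1/2), unadjusted and then adjusted for sex
and continuous ancestry covariates. Effects are per-allele log-odds; odds
ratios are exp(beta); p-values are two-sided Wald tests, matching the
behaviour of standard GWAS logistic regression. Confounding is quantified
as the relative change in OR between the two models, with >10% flagged.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .cohort import MISSING

log = logging.getLogger(__name__)

CONFOUNDING_CUTOFF = 0.10


@dataclass
class LogisticFit:
    beta: np.ndarray
    se: np.ndarray
    p: np.ndarray  # NaN where the Wald test is unavailable (separation)
    n_iter: int
    converged: bool
    separated: bool
    n_obs: int


class RankDeficiencyError(ValueError):
    pass


def fit_logistic(
    response: np.ndarray,
    design: np.ndarray,
    max_iter: int = 100,
    score_tol: float = 1e-8,
    step_tol: float = 1e-10,
    separation_beta: float = 15.0,
) -> LogisticFit:
    """Maximum-likelihood logistic regression by IRLS (Newton-Raphson).

    ``design`` must already include an intercept column. Rows with any
    non-finite entry (or non-finite response) are dropped. Convergence when
    the score norm falls below ``score_tol`` or the parameter step below
    ``step_tol``. Complete or quasi-complete separation — recognised by a
    coefficient drifting beyond ``separation_beta`` while the likelihood
    keeps climbing — yields a flagged result with p-values set to NaN.
    Collinear designs raise RankDeficiencyError naming the columns.
    """
    y = np.asarray(response, dtype=float)
    X = np.atleast_2d(np.asarray(design, dtype=float))
    ok = np.isfinite(y) & np.isfinite(X).all(axis=1)
    y, X = y[ok], X[ok]
    n, p = X.shape
    if not np.isin(y, [0.0, 1.0]).all():
        raise ValueError("response must be binary 0/1")
    if n <= p:
        raise ValueError(f"need more observations ({n}) than columns ({p})")
    rank = np.linalg.matrix_rank(X)
    if rank < p:
        # identify columns involved via QR pivoting on the gram matrix
        _, r = np.linalg.qr(X)
        dep = [j for j in range(p) if abs(r[j, j]) < 1e-10] or list(range(p))
        raise RankDeficiencyError(
            f"design is rank deficient (rank {rank} < {p}); "
            f"suspect column(s) {dep}"
        )

    beta = np.zeros(p)
    converged = False
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        eta = X @ beta
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = mu * (1.0 - mu)
        score = X.T @ (y - mu)
        info = (X * w[:, None]).T @ X
        try:
            step = np.linalg.solve(info, score)
        except np.linalg.LinAlgError:
            break
        beta = beta + step
        if np.linalg.norm(score) < score_tol or np.linalg.norm(step) < step_tol:
            converged = True
            break

    separated = bool(np.abs(beta).max() > separation_beta) or not converged
    eta = X @ beta
    mu = 1.0 / (1.0 + np.exp(-eta))
    w = np.clip(mu * (1.0 - mu), 1e-12, None)
    info = (X * w[:, None]).T @ X
    try:
        cov = np.linalg.inv(info)
        se = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    except np.linalg.LinAlgError:
        se = np.full(p, np.nan)
        separated = True
    with np.errstate(divide="ignore", invalid="ignore"):
        z = beta / se
    pvals = 2.0 * stats.norm.sf(np.abs(z))
    if separated:
        pvals = np.full(p, np.nan)
        log.warning("separation detected (max |beta| = %.2f); p set to NaN",
                    float(np.abs(beta).max()))
    return LogisticFit(
        beta=beta, se=se, p=pvals, n_iter=n_iter,
        converged=converged, separated=separated, n_obs=n,
    )


@dataclass
class AssociationResult:
    """Unadjusted and covariate-adjusted per-variant association."""

    variant: tuple
    n_used: int
    beta_unadj: float
    se_unadj: float
    p_unadj: float
    beta_adj: float
    se_adj: float
    p_adj: float
    delta_or_fraction: float
    confounded: bool
    monomorphic: bool = False
    separated: bool = False
    significant_unadj: bool = False
    significant_adj: bool = False

    @property
    def or_unadj(self) -> float:
        return math.exp(self.beta_unadj)

    @property
    def or_adj(self) -> float:
        return math.exp(self.beta_adj)


def test_variant(
    genotypes: np.ndarray,
    phenotype: np.ndarray,
    sex: np.ndarray | None = None,
    ancestry_covariates: np.ndarray | None = None,
    variant_key: tuple = (),
    threshold: float | None = None,
) -> AssociationResult:
    """Fit the unadjusted and adjusted additive models for one variant.

    Samples with a missing genotype are excluded from both fits
    (complete-case per variant). The unadjusted model is intercept +
    dosage; the adjusted model adds sex and the continuous ancestry
    covariates. A variant monomorphic in the analysed samples is returned
    flagged with undefined effects.
    """
    g = np.asarray(genotypes, dtype=float)
    y = np.asarray(phenotype, dtype=float)
    keep = g != MISSING
    g, y = g[keep], y[keep]
    if y.sum() == 0 or y.sum() == len(y):
        raise ValueError("need at least one case and one control")
    nan = float("nan")
    if np.unique(g).size < 2:
        return AssociationResult(
            variant=variant_key, n_used=int(keep.sum()),
            beta_unadj=nan, se_unadj=nan, p_unadj=nan,
            beta_adj=nan, se_adj=nan, p_adj=nan,
            delta_or_fraction=nan, confounded=False, monomorphic=True,
        )
    X_un = np.column_stack([np.ones_like(g), g])
    covs = [np.ones_like(g), g]
    if sex is not None:
        covs.append(np.asarray(sex, dtype=float)[keep])
    if ancestry_covariates is not None:
        ac = np.atleast_2d(np.asarray(ancestry_covariates, dtype=float))
        covs.extend(ac[keep].T)
    X_adj = np.column_stack(covs)

    fit_un = fit_logistic(y, X_un)
    fit_adj = fit_logistic(y, X_adj)
    separated = fit_un.separated or fit_adj.separated
    if separated:
        frac, confounded = nan, False
    else:
        frac, confounded = confounding_change(
            math.exp(fit_un.beta[1]), math.exp(fit_adj.beta[1])
        )
    res = AssociationResult(
        variant=variant_key,
        n_used=int(keep.sum()),
        beta_unadj=float(fit_un.beta[1]),
        se_unadj=float(fit_un.se[1]),
        p_unadj=float(fit_un.p[1]),
        beta_adj=float(fit_adj.beta[1]),
        se_adj=float(fit_adj.se[1]),
        p_adj=float(fit_adj.p[1]),
        delta_or_fraction=frac,
        confounded=confounded,
        separated=separated,
    )
    if threshold is not None and not separated:
        res.significant_unadj = res.p_unadj < threshold
        res.significant_adj = res.p_adj < threshold
    return res


def confounding_change(or_unadj: float, or_adj: float) -> tuple[float, bool]:
    """Relative OR change between models: |OR_adj - OR_unadj| / OR_unadj.

    A change strictly greater than 10% flags the variant as confounded by
    the covariates.
    """
    if or_unadj <= 0 or or_adj <= 0:
        raise ValueError("odds ratios must be positive")
    fraction = abs(or_adj - or_unadj) / or_unadj
    # strict inequality, robust to FP noise exactly at the 10% boundary
    confounded = fraction > CONFOUNDING_CUTOFF and not math.isclose(
        fraction, CONFOUNDING_CUTOFF, rel_tol=1e-9
    )
    return fraction, confounded


def confounding_summary(confounded_flags) -> tuple[int, int, float]:
    """Report (n_confounded, n_total, percent) over a set of flags."""
    flags = [bool(f) for f in confounded_flags]
    total = len(flags)
    if total == 0:
        raise ValueError("no variants to summarize")
    n_conf = sum(flags)
    return n_conf, total, 100.0 * n_conf / total


@dataclass(frozen=True)
class SignificanceThreshold:
    threshold: float
    neg_log10: float
    alpha: float | None = None
    n_variants: int | None = None


def significance_threshold(
    alpha: float = 0.05,
    n_variants: int | None = None,
    threshold: float | None = None,
) -> SignificanceThreshold:
    """Multiplicity-corrected per-variant threshold, alpha / n_variants.

    Either derive the threshold from (alpha, n_variants) or supply an
    explicit ``threshold`` (the study-level cutoff is a config input).
    Also carries -log10(threshold) for Manhattan-style plotting.
    """
    if threshold is None:
        if n_variants is None or n_variants < 1:
            raise ValueError("need n_variants >= 1 (or an explicit threshold)")
        if not (0.0 < alpha < 1.0):
            raise ValueError("alpha must be in (0, 1)")
        threshold = alpha / n_variants
        return SignificanceThreshold(
            threshold=threshold,
            neg_log10=-math.log10(threshold),
            alpha=alpha,
            n_variants=n_variants,
        )
    if threshold <= 0 or threshold >= 1:
        raise ValueError("threshold must be in (0, 1)")
    return SignificanceThreshold(threshold=threshold, neg_log10=-math.log10(threshold))
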