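"""Supervised admixture estimation from ancestry-informative markers (AIMs).

Each individual's genotype g_m at marker m is modelled as
Binomial(2, f_m) with f_m = sum_k q_k * p_km, where p_km are fixed
alternate-allele frequencies of K reference populations and q is the
individual's admixture vector on the simplex. q is estimated by
maximum likelihood via EM:

    q_k <- (1 / 2M') * sum_m [ g_m * q_k p_km / f_m
                               + (2 - g_m) * q_k (1 - p_km) / (1 - f_m) ]

with M' the number of non-missing markers. The log-likelihood is
non-decreasing across iterations. Categorical ancestry labels follow
threshold rules on q (EUR > 0.90; AFR >= 0.70; EAS >= 0.70; HIS when
Native-American ancestry is >= 0.10 and exceeds both AFR and EAS; else
AMR, admixed American).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import MISSING

log = logging.getLogger(__name__)

DEFAULT_POPULATIONS = ("EUR", "AFR", "EAS", "NAT")

#: q_k below which a component cannot dominate; used only for validation.
_SIMPLEX_TOL = 1e-8


@dataclass
class ReferencePanel:
    """Fixed per-population alternate-allele frequencies for the AIMs."""

    populations: list[str]
    marker_ids: list[str]
    frequencies: np.ndarray  # (K, M), clamped to (0, 1)

    def __post_init__(self) -> None:
        k, m = self.frequencies.shape
        if k != len(self.populations) or m != len(self.marker_ids):
            raise ValueError("panel dimensions inconsistent")
        if k < 2:
            raise ValueError("panel needs at least two populations")
        if len(set(self.marker_ids)) != len(self.marker_ids):
            raise ValueError("marker IDs must be unique")
        if not ((self.frequencies > 0) & (self.frequencies < 1)).all():
            raise ValueError("panel frequencies must lie strictly in (0, 1)")

    @property
    def n_populations(self) -> int:
        return len(self.populations)

    @property
    def n_markers(self) -> int:
        return len(self.marker_ids)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"marker_id": self.marker_ids})
        for i, pop in enumerate(self.populations):
            df[f"freq_{pop}"] = self.frequencies[i]
        return df


@dataclass
class AncestryProfile:
    """Per-sample admixture estimate with its categorical label."""

    q: np.ndarray
    label: str
    log_likelihood: float
    n_iterations: int
    converged: bool
    identifiable: bool = True


class EstimationError(ValueError):
    pass


def admixture_em(
    genotypes: np.ndarray,
    panel: ReferencePanel,
    tol: float = 1e-6,
    max_iter: int = 2000,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized EM over many samples at once.

    genotypes: (n, M) dosage codes with -1 for missing.
    Returns (Q, loglik, n_iter, converged) with Q of shape (n, K).
    Convergence is per-sample on the log-likelihood increase.
    """
    G = np.asarray(genotypes, dtype=float)
    if G.ndim == 1:
        G = G[None, :]
    n, m = G.shape
    P = panel.frequencies  # (K, M)
    k = panel.n_populations
    obs = G != MISSING
    if (obs.sum(axis=1) == 0).any():
        raise EstimationError("sample with zero usable AIM genotypes")
    Gm = np.where(obs, G, 0.0)

    Q = np.full((n, k), 1.0 / k)
    prev_ll = np.full(n, -np.inf)
    ll = prev_ll.copy()
    n_iter = np.zeros(n, dtype=int)
    active = np.ones(n, dtype=bool)
    for it in range(1, max_iter + 1):
        F = Q @ P  # (n, M)
        F = np.clip(F, 1e-12, 1 - 1e-12)
        ll_terms = np.where(obs, Gm * np.log(F) + (2 - Gm) * np.log1p(-F), 0.0)
        ll = ll_terms.sum(axis=1)
        just_converged = active & (ll - prev_ll < tol) & (it > 1)
        active &= ~just_converged
        n_iter[active] = it
        prev_ll = ll
        if not active.any():
            break
        # E+M step: per-population expected allele-origin counts
        alt_ratio = np.where(obs, Gm / F, 0.0)  # (n, M)
        ref_ratio = np.where(obs, (2 - Gm) / (1 - F), 0.0)
        num = Q * (alt_ratio @ P.T + ref_ratio @ (1 - P).T)  # (n, K)
        m_prime = obs.sum(axis=1, keepdims=True)
        Q_new = num / (2.0 * m_prime)
        Q_new /= Q_new.sum(axis=1, keepdims=True)  # guard FP drift
        Q[active] = Q_new[active]
    converged = ~active
    return Q, ll, n_iter, converged


def estimate_admixture(
    genotypes: np.ndarray,
    panel: ReferencePanel,
    tol: float = 1e-6,
    max_iter: int = 2000,
) -> list[AncestryProfile]:
    """Estimate admixture and label each sample.

    Missing AIMs are skipped per sample. With a completely uninformative
    panel (identical frequencies in every population) the likelihood is
    flat in q; the uniform vector is returned with an unidentifiability
    warning. Non-convergence at ``max_iter`` returns the current estimate
    flagged unconverged.
    """
    flat = bool(np.allclose(panel.frequencies, panel.frequencies[0]))
    if flat:
        log.warning(
            "panel frequencies identical across populations; admixture is "
            "unidentifiable, returning uniform proportions"
        )
    Q, ll, n_iter, converged = admixture_em(genotypes, panel, tol, max_iter)
    if not converged.all():
        log.warning("%d sample(s) did not converge in %d iterations",
                    int((~converged).sum()), max_iter)
    profiles = []
    for i in range(Q.shape[0]):
        profiles.append(
            AncestryProfile(
                q=Q[i],
                label=classify_ancestry(Q[i], panel.populations),
                log_likelihood=float(ll[i]),
                n_iterations=int(n_iter[i]),
                converged=bool(converged[i]),
                identifiable=not flat,
            )
        )
    return profiles


def _check_simplex(q: np.ndarray) -> None:
    if (np.asarray(q) < -_SIMPLEX_TOL).any() or abs(float(np.sum(q)) - 1.0) > 1e-6:
        raise ValueError(f"q must lie on the probability simplex, got {q}")


def classify_ancestry(
    q: np.ndarray, populations: tuple[str, ...] | list[str] = DEFAULT_POPULATIONS
) -> str:
    """Apply the threshold classification to an admixture vector.

    Rules in order: EUR if q_EUR > 0.90; AFR if q_AFR >= 0.70; EAS if
    q_EAS >= 0.70; HIS if Native-American ancestry q_NAT >= 0.10 and
    exceeds both q_AFR and q_EAS; otherwise AMR (admixed American).
    """
    _check_simplex(q)
    idx = {pop: i for i, pop in enumerate(populations)}
    q = np.asarray(q, dtype=float)
    if q[idx["EUR"]] > 0.90:
        return "EUR"
    if q[idx["AFR"]] >= 0.70:
        return "AFR"
    if q[idx["EAS"]] >= 0.70:
        return "EAS"
    nat = q[idx["NAT"]]
    if nat >= 0.10 and nat > q[idx["AFR"]] and nat > q[idx["EAS"]]:
        return "HIS"
    return "AMR"


def classification_rate(labels: list[str] | pd.Series, label: str) -> tuple[int, int, float]:
    """Count how often a category was assigned; returns (hits, total, percent)."""
    labels = pd.Series(list(labels))
    hits = int((labels == label).sum())
    total = int(len(labels))
    if total == 0:
        raise ValueError("no labels supplied")
    return hits, total, 100.0 * hits / total


def ancestry_covariates(
    Q: np.ndarray,
    populations: tuple[str, ...] | list[str] = DEFAULT_POPULATIONS,
    baseline: str = "EUR",
) -> pd.DataFrame:
    """Continuous admixture covariates for regression, dropping a baseline.

    One component (default EUR) is removed to avoid exact collinearity with
    the model intercept; a pure-baseline individual therefore has all-zero
    covariates. The Native-American component doubles as the continuous
    Hispanic-ancestry covariate.
    """
    Q = np.atleast_2d(np.asarray(Q, dtype=float))
    for row in Q:
        _check_simplex(row)
    keep = [p for p in populations if p != baseline]
    idx = [list(populations).index(p) for p in keep]
    return pd.DataFrame(Q[:, idx], columns=[f"q_{p}" for p in keep])
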