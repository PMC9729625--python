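"""False-quantitation-rate control for evidence matching.

Decoy precursors (+10 Da) are run through the identical enumerate/score path
as targets; the pooled match scores are modelled as a two-component Gaussian
mixture (component 0 = false matches, component 1 = true matches), initialized
by k-means and fitted by EM. The FQR at a score threshold t is the posterior
mass of the false component above t, and the acceptance threshold is the
smallest observed score whose FQR is at or below the requested level
(0.01 by default).
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
from scipy.stats import norm
from sklearn.cluster import KMeans

from .model import GPSM, GMMParams

DECOY_MASS_SHIFT = 10.0  # Da added to each target precursor mass
SIGMA_FLOOR = 1e-4


def make_decoys(gpsms: list[GPSM]) -> list[GPSM]:
    """One decoy per target: precursor mass +10 Da, m/z shifted by 10/charge."""
    decoys = []
    for g in gpsms:
        d = dataclasses.replace(
            g,
            precursor_mass=g.precursor_mass + DECOY_MASS_SHIFT,
            precursor_mz=g.precursor_mz + DECOY_MASS_SHIFT / g.charge,
            is_decoy=True,
        )
        decoys.append(d)
    return decoys


def kmeans_init(scores: np.ndarray, seed: int = 0) -> GMMParams:
    """Initialize the mixture by 2-cluster k-means on the scores.

    The cluster with the smaller mean becomes component 0 (the false set).
    """
    x = np.asarray(scores, dtype=float).reshape(-1, 1)
    if len(np.unique(x)) < 2:
        raise ValueError("k-means initialization needs at least 2 distinct scores")
    km = KMeans(n_clusters=2, n_init=10, random_state=seed).fit(x)
    labels = km.labels_
    stats = []
    for k in (0, 1):
        part = x[labels == k, 0]
        sd = part.std()
        stats.append((part.mean(), max(sd, SIGMA_FLOOR), len(part) / len(x)))
    stats.sort(key=lambda s: s[0])
    (mu0, s0, pi0), (mu1, s1, pi1) = stats
    return GMMParams(pi0=pi0, pi1=pi1, mu0=mu0, mu1=mu1, sigma0=s0, sigma1=s1)


def _log_likelihood(x: np.ndarray, p: GMMParams) -> float:
    dens = p.pi0 * norm.pdf(x, p.mu0, p.sigma0) + p.pi1 * norm.pdf(
        x, p.mu1, p.sigma1
    )
    return float(np.log(np.maximum(dens, 1e-300)).sum())


def posteriors(x: np.ndarray, p: GMMParams) -> np.ndarray:
    """E-step: posterior probability of each component per score, shape (2, n)."""
    f0 = p.pi0 * norm.pdf(x, p.mu0, p.sigma0)
    f1 = p.pi1 * norm.pdf(x, p.mu1, p.sigma1)
    total = np.maximum(f0 + f1, 1e-300)
    return np.vstack([f0 / total, f1 / total])


def em_fit(
    scores: np.ndarray,
    init: GMMParams,
    max_iter: int = 500,
    eps: float = 1e-6,
    track_loglik: list[float] | None = None,
) -> GMMParams:
    """Fit the two-component mixture by EM from the given initialization.

    Component identity (0 = false) is fixed by the initialization and kept by
    label through the iterations. Stops when the maximum absolute parameter
    change falls below ``eps`` or after ``max_iter`` cycles. A collapsing
    component has its standard deviation floored at 1e-4 with a warning.
    """
    x = np.asarray(scores, dtype=float)
    p = init
    if track_loglik is not None:
        track_loglik.append(_log_likelihood(x, p))
    for _ in range(max_iter):
        resp = posteriors(x, p)
        n_k = resp.sum(axis=1)
        n_k = np.maximum(n_k, 1e-12)
        pi = n_k / len(x)
        mu = (resp @ x) / n_k
        var = np.array(
            [(resp[k] @ (x - mu[k]) ** 2) / n_k[k] for k in (0, 1)]
        )
        sigma = np.sqrt(var)
        if np.any(sigma < SIGMA_FLOOR):
            warnings.warn("mixture component collapsed; flooring sigma at 1e-4")
            sigma = np.maximum(sigma, SIGMA_FLOOR)
        new = GMMParams(
            pi0=float(pi[0]),
            pi1=float(pi[1]),
            mu0=float(mu[0]),
            mu1=float(mu[1]),
            sigma0=float(sigma[0]),
            sigma1=float(sigma[1]),
        )
        if track_loglik is not None:
            track_loglik.append(_log_likelihood(x, new))
        delta = np.abs(new.as_array() - p.as_array()).max()
        p = new
        if delta < eps:
            break
    return p


def fqr_at_threshold(p: GMMParams, t: float, double_pi: bool = False) -> float:
    """FQR at threshold t: false-component mass above t over total mass above t.

    Survival integrals use the Gaussian survival function (complementary error
    function), not quadrature. ``double_pi=True`` multiplies each survival
    term by its mixture probability a second time, reproducing the literal
    composition of the published formulas; the default is the standard
    single-π mixture posterior.
    """
    s0 = norm.sf(t, p.mu0, p.sigma0)
    s1 = norm.sf(t, p.mu1, p.sigma1)
    w0, w1 = (p.pi0**2, p.pi1**2) if double_pi else (p.pi0, p.pi1)
    numer = w0 * s0
    denom = numer + w1 * s1
    if denom <= 0:
        return 0.0
    return float(numer / denom)


def threshold_for_fqr(
    p: GMMParams, scores: np.ndarray, alpha: float = 0.01
) -> float | None:
    """Smallest observed score t with FQR(t) <= alpha; None if unattainable.

    Results with score strictly greater than t are accepted.
    """
    x = np.sort(np.asarray(scores, dtype=float))
    for t in x:
        if fqr_at_threshold(p, t) <= alpha:
            return float(t)
    warnings.warn(f"no threshold achieves FQR <= {alpha}; accepting nothing")
    return None
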