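"""Negative-binomial probability kernel, dispersion estimation with
weighted-likelihood empirical-Bayes shrinkage, and log-linear coefficient fits.

The NB is parameterized by mean ``mu`` and dispersion ``phi`` with
``Var(Y) = mu + phi * mu**2``; ``phi -> 0`` recovers the Poisson law.
All likelihood arithmetic runs in log space via ``gammaln`` so counts up to
1e9 never overflow.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import TYPE_CHECKING

import numpy as np
from scipy.optimize import minimize_scalar
from scipy.special import gammaln

from .data_model import CountMatrix
from .errors import DomainError

if TYPE_CHECKING:  # pragma: no cover - avoid import cycle with preprocessing
    from .preprocessing import ClassMeans

logger = logging.getLogger(__name__)

#: at or below this the NB pmf switches to its Poisson limit
POISSON_SWITCH = 1e-10

PHI_MIN = 1e-6
PHI_MAX = 1e3
TAU2_FLOOR = 1e-8
#: tau^2 assigned when the observed information is non-positive (flat or
#: boundary likelihood) — the gene then carries ~no weight in shrinkage
TAU2_UNINFORMATIVE = 1e12


def _lgamma_ratio(r, y):
    """gammaln(r + y) - gammaln(r), stable for huge r.

    The naive difference loses ~r * 1e-16 absolute precision to cancellation;
    for r > 1e6 a Stirling-series form (truncation error < 1e-20 there) is
    used instead.
    """
    r = np.asarray(r, dtype=float)
    y = np.asarray(y, dtype=float)
    r, y = np.broadcast_arrays(r, y)
    out = np.empty(r.shape, dtype=float)
    small = r <= 1e6
    if small.any():
        out[small] = gammaln(r[small] + y[small]) - gammaln(r[small])
    big = ~small
    if big.any():
        rb, yb = r[big], y[big]
        out[big] = (
            yb * np.log(rb)
            + (rb + yb - 0.5) * np.log1p(yb / rb)
            - yb
            - yb / (12.0 * rb * (rb + yb))
        )
    return out


def nb_log_pmf(y, mu, phi):
    """Log pmf of NB(mean=mu, dispersion=phi) at count y; Poisson limit for tiny phi.

    Broadcasts over array arguments. ``mu`` must be strictly positive and
    ``phi`` non-negative.
    """
    y = np.asarray(y)
    mu = np.asarray(mu, dtype=float)
    phi = np.asarray(phi, dtype=float)
    if np.any(mu <= 0):
        raise DomainError("nb_log_pmf requires mu > 0")
    if np.any(phi < 0):
        raise DomainError("nb_log_pmf requires phi >= 0")
    if np.any(y < 0) or np.any(np.asarray(y, dtype=float) != np.floor(y)):
        raise DomainError("nb_log_pmf requires non-negative integer y")

    y, mu, phi = np.broadcast_arrays(y, mu, phi)
    y = np.asarray(y, dtype=float)
    out = np.empty(y.shape, dtype=float)

    pois = phi <= POISSON_SWITCH
    if pois.any():
        yp, mp = y[pois], mu[pois]
        out[pois] = yp * np.log(mp) - mp - gammaln(yp + 1.0)
    nb = ~pois
    if nb.any():
        yn, mn, pn = y[nb], mu[nb], phi[nb]
        r = 1.0 / pn
        out[nb] = (
            _lgamma_ratio(r, yn) - gammaln(yn + 1.0)
            + yn * np.log(pn * mn)
            - (yn + r) * np.log1p(pn * mn)
        )
    return out if out.ndim else float(out)


def sample_log_likelihood(y_vec, mu_vec, phi_vec) -> float:
    """Joint log-likelihood of one sample: sum of independent per-gene NB terms."""
    y = np.atleast_1d(np.asarray(y_vec))
    mu = np.atleast_1d(np.asarray(mu_vec, dtype=float))
    phi = np.atleast_1d(np.asarray(phi_vec, dtype=float))
    if not (y.shape == mu.shape == phi.shape):
        raise ValueError(
            f"length mismatch: y {y.shape}, mu {mu.shape}, phi {phi.shape}"
        )
    return float(np.sum(nb_log_pmf(y, mu, phi)))


@dataclass
class DispersionEstimates:
    """Raw and shrunken per-gene dispersions with the shrinkage hyperparameters."""

    gene_ids: list[str]
    phi_raw: np.ndarray  # (G,)
    tau2: np.ndarray  # (G,) sampling variance of each raw estimate
    phi0: float  # common prior mean
    tau02: float  # prior variance
    alpha: float  # common-likelihood weight
    phi_shrunk: np.ndarray  # (G,)


@dataclass
class BetaEstimates:
    """Per-gene coefficient vectors for one class plus residual diagnostics."""

    betas: np.ndarray  # (G, p)
    rss: np.ndarray  # (G,) residual sum of squares of the log-mean fit


def _gene_negll(log_phi: float, y: np.ndarray, mu: np.ndarray) -> float:
    return -float(np.sum(nb_log_pmf(y, mu, np.exp(log_phi))))


def estimate_dispersion_raw(
    counts: CountMatrix,
    class_means: "ClassMeans",
    phi_min: float = PHI_MIN,
    phi_max: float = PHI_MAX,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-gene dispersion MLE over all training samples with means held fixed.

    Maximizes the NB log-likelihood over log(phi) on [log(phi_min), log(phi_max)]
    by bounded scalar optimization. Returns ``(phi_hat, tau2)`` where ``tau2``
    is the inverse observed information (negative second derivative of the
    log-likelihood in phi, by central difference), floored at ``TAU2_FLOOR``.
    """
    mu = class_means.mean_matrix(counts)
    G, _ = counts.counts.shape
    phi_hat = np.empty(G)
    tau2 = np.empty(G)
    lo, hi = np.log(phi_min), np.log(phi_max)
    for g in range(G):
        y_g = counts.counts[g]
        mu_g = mu[g]
        try:
            res = minimize_scalar(
                _gene_negll, bounds=(lo, hi), args=(y_g, mu_g),
                method="bounded", options={"xatol": 1e-8},
            )
            if not np.isfinite(res.fun):
                raise FloatingPointError("non-finite likelihood")
            phi = float(np.exp(res.x))
        except (FloatingPointError, ValueError) as exc:
            logger.warning("dispersion fit failed for gene %s (%s); using phi_min",
                           counts.gene_ids[g], exc)
            phi_hat[g] = phi_min
            tau2[g] = TAU2_FLOOR
            continue
        phi_hat[g] = min(max(phi, phi_min), phi_max)
        h = 1e-4 * max(phi_hat[g], 1e-3)
        if phi_hat[g] - h <= 0:
            h = phi_hat[g] / 2.0
        ll = lambda p: -_gene_negll(np.log(p), y_g, mu_g)  # noqa: E731
        d2 = (ll(phi_hat[g] + h) - 2.0 * ll(phi_hat[g]) + ll(phi_hat[g] - h)) / h**2
        if np.isfinite(d2) and -d2 > 0:
            tau2[g] = max(1.0 / -d2, TAU2_FLOOR)
        else:
            tau2[g] = TAU2_UNINFORMATIVE
    return phi_hat, tau2


def shrink_dispersion_wl(
    phi_hat: np.ndarray,
    tau2: np.ndarray,
    gene_ids: list[str] | None = None,
    phi_min: float = PHI_MIN,
    phi_max: float = PHI_MAX,
    alpha: float | None = None,
    tau02: float | None = None,
) -> DispersionEstimates:
    """Weighted-likelihood empirical-Bayes shrinkage of raw dispersions.

    Under the hierarchical normal model (raw estimate ~ N(phi_g, tau_g^2),
    phi_g ~ N(phi0, tau0^2)) the shrunken estimate is the precision-weighted
    convex combination of the per-gene estimate and the common value::

        phi_g^WL = (phi_g/tau_g^2 + alpha * sum_i phi_i/tau_i^2)
                   / (1/tau_g^2 + alpha * sum_i 1/tau_i^2)

    with phi0 the precision-weighted mean, tau0^2 a method-of-moments estimate
    (population variance of raw estimates minus the mean sampling variance,
    floored at 1e-8) and 1/alpha = sum_i tau0^2/tau_i^2. ``alpha``/``tau02``
    overrides exist for testing and for callers with external prior knowledge.
    """
    phi_hat = np.asarray(phi_hat, dtype=float)
    tau2 = np.asarray(tau2, dtype=float)
    if phi_hat.shape != tau2.shape or phi_hat.ndim != 1:
        raise ValueError("phi_hat and tau2 must be 1-D of equal length")
    if gene_ids is None:
        gene_ids = [f"g{i}" for i in range(len(phi_hat))]
    if len(phi_hat) < 1:
        raise ValueError("need at least one gene")
    if len(phi_hat) == 1:
        warnings.warn("single gene: returning raw dispersion unshrunken")
        return DispersionEstimates(
            gene_ids=list(gene_ids), phi_raw=phi_hat.copy(), tau2=tau2.copy(),
            phi0=float(phi_hat[0]), tau02=TAU2_FLOOR, alpha=0.0,
            phi_shrunk=np.clip(phi_hat, phi_min, phi_max),
        )

    w = 1.0 / tau2
    phi0 = float(np.sum(phi_hat * w) / np.sum(w))
    if tau02 is None:
        tau02 = float(max(np.var(phi_hat) - np.mean(tau2), TAU2_FLOOR))
    if alpha is None:
        alpha = float(1.0 / np.sum(tau02 / tau2))
    sum_pw = float(np.sum(phi_hat * w))
    sum_w = float(np.sum(w))
    shrunk = (phi_hat * w + alpha * sum_pw) / (w + alpha * sum_w)
    return DispersionEstimates(
        gene_ids=list(gene_ids),
        phi_raw=phi_hat.copy(),
        tau2=tau2.copy(),
        phi0=phi0,
        tau02=float(tau02),
        alpha=float(alpha),
        phi_shrunk=np.clip(shrunk, phi_min, phi_max),
    )


def fit_beta(X: np.ndarray, mu: np.ndarray) -> BetaEstimates:
    """Least-squares fit of ``log(mu) = X @ beta`` per gene for one class.

    ``X`` is the (n_c, p) class design matrix, ``mu`` the (n_c, G) per-sample
    per-gene fitted means (all strictly positive). Rank-deficient designs get
    the minimum-norm solution via the pseudoinverse. With an intercept-only
    design this reduces to the per-gene mean of log(mu).
    """
    X = np.asarray(X, dtype=float)
    mu = np.asarray(mu, dtype=float)
    if X.ndim != 2 or mu.ndim != 2 or X.shape[0] != mu.shape[0]:
        raise ValueError(f"incompatible shapes X {X.shape}, mu {mu.shape}")
    if np.any(mu <= 0):
        raise DomainError("fit_beta requires all means > 0")
    log_mu = np.log(mu)  # (n_c, G)
    betas = np.linalg.pinv(X) @ log_mu  # (p, G)
    resid = log_mu - X @ betas
    return BetaEstimates(betas=betas.T, rss=np.sum(resid**2, axis=0))
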