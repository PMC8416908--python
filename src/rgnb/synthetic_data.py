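"""Synthetic dataset generator matching the model's own assumptions.

Counts are drawn NB(mean = exp(X_i @ beta_gc), dispersion = phi_g) via the
gamma-Poisson mixture, covariates from a multivariate normal (optionally with
class-shifted means), so every pipeline stage is testable without external
downloads.

Preset design note: the fitting pipeline approximates per-sample means by the
rank-one product (size factor x per-gene class total). That product can only
reproduce ``exp(X_i beta_gc)`` when, within a class, the covariate slopes are
shared across genes (gene-specific intercepts are free). All presets respect
this so that parameter-recovery tests are well-posed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .data_model import CountMatrix, CovariateMatrix, LabelVector

#: guardrail against overflowing NB means
MAX_LOG_MEAN = 30.0


@dataclass
class ScenarioSpec:
    """Complete description of one synthetic dataset.

    ``beta`` has shape (G, C, 1 + p): a leading intercept column followed by
    ``p`` covariate slopes. ``covariate_means`` is (C, p) so each class may
    have its own covariate location; ``covariate_cov`` is the shared (p, p)
    covariance.
    """

    name: str
    n_per_class: tuple[int, ...]
    class_names: tuple[str, ...]
    beta: np.ndarray  # (G, C, 1 + p)
    phi: np.ndarray  # (G,)
    covariate_means: np.ndarray  # (C, p)
    covariate_cov: np.ndarray  # (p, p)
    seed: int = 0
    feature_names: tuple[str, ...] = ()
    ordinal_features: tuple[int, ...] = ()  # indices thresholded at their mean
    null_gene_fraction: float = 0.0  # bookkeeping: fraction with class-equal beta

    def __post_init__(self) -> None:
        self.beta = np.asarray(self.beta, dtype=float)
        self.phi = np.asarray(self.phi, dtype=float)
        self.covariate_means = np.atleast_2d(np.asarray(self.covariate_means, float))
        self.covariate_cov = np.atleast_2d(np.asarray(self.covariate_cov, float))
        C = len(self.class_names)
        if len(self.n_per_class) != C or any(n < 1 for n in self.n_per_class):
            raise ValueError("n_per_class must give a positive count per class")
        G, C_b, _ = self.beta.shape
        if C_b != C:
            raise ValueError("beta second axis must match the number of classes")
        if self.phi.shape != (G,) or (self.phi <= 0).any():
            raise ValueError("phi must be positive, one per gene")
        p = self.covariate_cov.shape[0]
        if self.covariate_cov.shape != (p, p):
            raise ValueError("covariate covariance must be square")
        if not np.allclose(self.covariate_cov, self.covariate_cov.T):
            raise ValueError("covariate covariance must be symmetric")
        if np.linalg.eigvalsh(self.covariate_cov).min() < -1e-10:
            raise ValueError("covariate covariance must be positive semi-definite")
        if self.covariate_means.shape != (C, p):
            raise ValueError(f"covariate_means must be ({C}, {p})")
        if self.beta.shape[2] != 1 + p:
            raise ValueError("beta last axis must be 1 (intercept) + n covariates")
        if not self.feature_names:
            self.feature_names = tuple(f"feat_{j + 1}" for j in range(p))

    @property
    def n_genes(self) -> int:
        return self.beta.shape[0]

    @property
    def n_covariates(self) -> int:
        return self.covariate_cov.shape[0]

    @property
    def n_samples(self) -> int:
        return int(sum(self.n_per_class))


def sample_nb(
    rng: np.random.Generator, mu: np.ndarray, phi: np.ndarray
) -> np.ndarray:
    """Draw NB(mean=mu, dispersion=phi) via the gamma-Poisson mixture.

    rate ~ Gamma(shape=1/phi, scale=phi*mu), count ~ Poisson(rate): exact for
    any real phi > 0.
    """
    mu = np.asarray(mu, dtype=float)
    phi = np.asarray(phi, dtype=float)
    shape = 1.0 / phi
    lam = rng.gamma(np.broadcast_to(shape, mu.shape), phi * mu)
    return rng.poisson(lam).astype(np.int64)


def generate_dataset(
    spec: ScenarioSpec,
) -> tuple[CountMatrix, CovariateMatrix, LabelVector, dict]:
    """Draw one dataset from a scenario; fully reproducible from spec.seed.

    Returns the aligned (counts, covariates, labels) triple plus a truth
    record holding every generating parameter.
    """
    rng = np.random.default_rng(spec.seed)
    C = len(spec.class_names)
    G = spec.n_genes
    n = spec.n_samples

    sample_ids = [f"s{i + 1:04d}" for i in range(n)]
    labels: list[str] = []
    class_of: list[int] = []
    for ci, cls in enumerate(spec.class_names):
        labels.extend([cls] * spec.n_per_class[ci])
        class_of.extend([ci] * spec.n_per_class[ci])
    class_of_arr = np.asarray(class_of)

    X = np.empty((n, spec.n_covariates))
    for ci in range(C):
        idx = np.flatnonzero(class_of_arr == ci)
        X[idx] = rng.multivariate_normal(
            spec.covariate_means[ci], spec.covariate_cov, size=len(idx),
            method="cholesky",
        )
    for j in spec.ordinal_features:
        X[:, j] = (X[:, j] > X[:, j].mean()).astype(float)

    design = np.column_stack([np.ones(n), X])  # (n, 1 + p)
    log_mu = np.einsum("np,gcp->ngc", design, spec.beta)
    log_mu_own = log_mu[np.arange(n), :, class_of_arr]  # (n, G)
    if np.any(log_mu_own > MAX_LOG_MEAN):
        raise ValueError(
            f"log-mean exceeds {MAX_LOG_MEAN}; rescale beta or covariates"
        )
    mu = np.exp(log_mu_own)  # (n, G)
    counts = sample_nb(rng, mu, spec.phi[None, :]).T  # (G, n)

    gene_ids = [f"gene_{g + 1:04d}" for g in range(G)]
    truth = {
        "name": spec.name,
        "seed": spec.seed,
        "class_names": list(spec.class_names),
        "n_per_class": list(spec.n_per_class),
        "gene_ids": gene_ids,
        "feature_names": list(spec.feature_names),
        "beta": spec.beta.tolist(),
        "phi": spec.phi.tolist(),
        "covariate_means": spec.covariate_means.tolist(),
        "covariate_cov": spec.covariate_cov.tolist(),
        "null_gene_fraction": spec.null_gene_fraction,
    }
    return (
        CountMatrix(gene_ids, sample_ids, counts),
        CovariateMatrix(sample_ids, list(spec.feature_names), X),
        LabelVector(sample_ids, labels, list(spec.class_names)),
        truth,
    )


def write_truth(truth: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(truth, indent=1))


def _build_beta(
    rng: np.random.Generator,
    G: int,
    base_log_mean: float,
    class_gap: float,
    slopes_per_class: np.ndarray,  # (C, p)
    signal_fraction: float,
) -> np.ndarray:
    """Gene-specific intercepts; class gap applied to a leading block of genes;
    covariate slopes shared across genes within each class."""
    C, p = slopes_per_class.shape
    intercepts = rng.uniform(base_log_mean - 0.5, base_log_mean + 0.5, size=G)
    beta = np.zeros((G, C, 1 + p))
    n_signal = int(round(signal_fraction * G))
    for ci in range(C):
        beta[:, ci, 0] = intercepts
        beta[:, ci, 1:] = slopes_per_class[ci]
    # alternate gap sign across signal genes so library sizes stay comparable
    for g in range(n_signal):
        sign = 1.0 if g % 2 == 0 else -1.0
        beta[g, 1, 0] += sign * class_gap
    return beta


def _phi_draw(rng: np.random.Generator, G: int, center: float = 0.3) -> np.ndarray:
    return center * np.exp(rng.normal(0.0, 0.25, size=G))


def well_separated(
    n_per_class: tuple[int, int] = (150, 150),
    n_genes: int = 20,
    n_covariates: int = 2,
    seed: int = 0,
    class_gap: float = 1.5,
    slope: float = 0.5,
    phi_center: float = 0.2,
) -> ScenarioSpec:
    """Strong class signal in both the counts (log-mean gap on half the genes)
    and the count-covariate coupling (opposite-sign shared slopes)."""
    rng = np.random.default_rng(seed + 10_000)
    slopes = np.zeros((2, n_covariates))
    slopes[0, 0] = slope
    slopes[1, 0] = -slope
    beta = _build_beta(rng, n_genes, 3.0, class_gap, slopes, signal_fraction=0.5)
    return ScenarioSpec(
        name="well_separated",
        n_per_class=tuple(n_per_class),
        class_names=("pos", "neg"),
        beta=beta,
        phi=_phi_draw(rng, n_genes, center=phi_center),
        covariate_means=np.zeros((2, n_covariates)),
        covariate_cov=np.eye(n_covariates),
        seed=seed,
        null_gene_fraction=0.5,
    )


def null_scenario(
    n_per_class: tuple[int, int] = (60, 60),
    n_genes: int = 30,
    n_covariates: int = 2,
    seed: int = 0,
) -> ScenarioSpec:
    """No class signal anywhere: identical beta across classes, zero slopes,
    identical covariate distributions."""
    rng = np.random.default_rng(seed + 20_000)
    slopes = np.zeros((2, n_covariates))
    beta = _build_beta(rng, n_genes, 3.0, 0.0, slopes, signal_fraction=0.0)
    return ScenarioSpec(
        name="null",
        n_per_class=tuple(n_per_class),
        class_names=("pos", "neg"),
        beta=beta,
        phi=_phi_draw(rng, n_genes),
        covariate_means=np.zeros((2, n_covariates)),
        covariate_cov=np.eye(n_covariates),
        seed=seed,
        null_gene_fraction=1.0,
    )


def covariate_only_signal(
    n_per_class: tuple[int, int] = (100, 100),
    n_genes: int = 20,
    n_covariates: int = 2,
    seed: int = 0,
    slope: float = 0.8,
) -> ScenarioSpec:
    """Class signal lives only in the count-covariate coupling: identical gene
    intercepts and covariate marginals across classes, but opposite-sign
    slopes, so counts alone (and covariates alone) are exchangeable between
    classes."""
    rng = np.random.default_rng(seed + 30_000)
    slopes = np.zeros((2, n_covariates))
    slopes[0, 0] = slope
    slopes[1, 0] = -slope
    beta = _build_beta(rng, n_genes, 3.0, 0.0, slopes, signal_fraction=0.0)
    return ScenarioSpec(
        name="covariate_only_signal",
        n_per_class=tuple(n_per_class),
        class_names=("pos", "neg"),
        beta=beta,
        phi=_phi_draw(rng, n_genes),
        covariate_means=np.zeros((2, n_covariates)),
        covariate_cov=np.eye(n_covariates),
        seed=seed,
        null_gene_fraction=1.0,
    )


def count_only_signal(
    n_per_class: tuple[int, int] = (100, 100),
    n_genes: int = 20,
    n_covariates: int = 2,
    seed: int = 0,
    class_gap: float = 1.2,
) -> ScenarioSpec:
    """Class signal lives only in the count intercepts; covariates are noise."""
    rng = np.random.default_rng(seed + 40_000)
    slopes = np.zeros((2, n_covariates))
    beta = _build_beta(rng, n_genes, 3.0, class_gap, slopes, signal_fraction=0.5)
    return ScenarioSpec(
        name="count_only_signal",
        n_per_class=tuple(n_per_class),
        class_names=("pos", "neg"),
        beta=beta,
        phi=_phi_draw(rng, n_genes),
        covariate_means=np.zeros((2, n_covariates)),
        covariate_cov=np.eye(n_covariates),
        seed=seed,
        null_gene_fraction=0.5,
    )


def idh_like_imbalance(
    n_per_class: tuple[int, int] = (85, 23),
    n_genes: int = 60,
    n_covariates: int = 8,
    seed: int = 0,
    class_gap: float = 1.0,
    slope: float = 0.4,
) -> ScenarioSpec:
    """Imbalanced two-class setting with eight correlated volumetric-style
    covariates, one of them thresholded to an ordinal feature."""
    rng = np.random.default_rng(seed + 50_000)
    slopes = np.zeros((2, n_covariates))
    slopes[0, :2] = slope
    slopes[1, :2] = -slope
    beta = _build_beta(rng, n_genes, 3.0, class_gap, slopes, signal_fraction=0.3)
    cov = 0.3 * np.ones((n_covariates, n_covariates)) + 0.7 * np.eye(n_covariates)
    means = np.zeros((2, n_covariates))
    means[1, :2] = 0.5  # mildly shifted covariates in the minority class
    return ScenarioSpec(
        name="idh_like_imbalance",
        n_per_class=tuple(n_per_class),
        class_names=("mutant", "wildtype"),
        beta=beta,
        phi=_phi_draw(rng, n_genes),
        covariate_means=means,
        covariate_cov=cov,
        seed=seed,
        ordinal_features=(5,),
        null_gene_fraction=0.7,
    )


SCENARIO_BUILDERS = {
    "well_separated": well_separated,
    "null": null_scenario,
    "covariate_only_signal": covariate_only_signal,
    "count_only_signal": count_only_signal,
    "idh_like_imbalance": idh_like_imbalance,
}


def preset_scenarios(seed: int = 0) -> dict[str, ScenarioSpec]:
    """All named presets at their default sizes."""
    return {name: build(seed=seed) for name, build in SCENARIO_BUILDERS.items()}
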