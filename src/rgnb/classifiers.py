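"""Training and prediction for the covariate-linked NB Bayes classifier and
the counts-only NBLDA baseline.

Both share the same preprocessing pipeline (quantile filter, per-split
differential-expression ranking, top-k panel, class-wise size-factor means,
empirical-Bayes dispersion shrinkage). They differ in how a test sample's
per-gene, per-class mean is formed:

* covariate-linked model: ``mu_tgc = exp(X_t @ beta_gc)`` — the covariates
  carry the sample scale, no test size factor is applied;
* NBLDA: ``mu_tgc = s_t * rate_gc`` with ``s_t`` = test total / mean training
  total and ``rate_gc`` the per-gene class rate scaled to an average library.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.special import logsumexp

from .data_model import (
    CountMatrix,
    CovariateMatrix,
    LabelVector,
    NBClassModel,
    PredictionResult,
    config_hash,
)
from .errors import FitError, PredictionError, ValidationError
from .nb_core import (
    PHI_MAX,
    PHI_MIN,
    estimate_dispersion_raw,
    fit_beta,
    nb_log_pmf,
    shrink_dispersion_wl,
)
from .preprocessing import (
    compute_class_means,
    quantile_filter,
    rank_genes_lrt,
    top_k_panel,
)

MAX_TEST_COUNT = 10**9


@dataclass
class TrainingConfig:
    """Knobs for the shared fit pipeline."""

    prior_mode: str = "uniform"  # or "empirical"
    k: int = 10
    q: float | None = 0.25  # None disables the quantile filter
    intercept: bool = True
    phi_min: float = PHI_MIN
    phi_max: float = PHI_MAX
    seed: int = 0
    panel: list[str] | None = None  # externally supplied gene panel overrides ranking

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if self.q is not None and not 0.0 <= self.q <= 1.0:
            raise ValueError("q must be in [0, 1]")
        if self.prior_mode not in ("uniform", "empirical"):
            raise ValueError(f"unknown prior mode {self.prior_mode!r}")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _priors(labels: LabelVector, mode: str) -> np.ndarray:
    C = len(labels.class_set)
    if mode == "uniform":
        return np.full(C, 1.0 / C)
    counts = np.array([len(labels.class_indices(c)) for c in labels.class_set], float)
    return counts / counts.sum()


def _prepare_panel(
    counts: CountMatrix, labels: LabelVector, config: TrainingConfig
) -> CountMatrix:
    if config.q is not None:
        counts = quantile_filter(counts, config.q)
    if config.panel is not None:
        panel = top_k_panel(config.panel, min(config.k, len(config.panel)))
    else:
        ranking = rank_genes_lrt(counts, labels)
        panel = top_k_panel(ranking, config.k)
    if not panel:
        raise FitError("empty gene panel")
    return counts.subset_genes(panel)


def _check_fit_preconditions(counts: CountMatrix, labels: LabelVector) -> None:
    if counts.sample_ids != labels.sample_ids:
        raise ValidationError("counts and labels must be aligned before fitting")
    labels.require_all_classes()
    small = [c for c, n in labels.class_counts().items() if n < 2]
    if small:
        raise FitError(f"classes with fewer than 2 samples: {small}")


def fit_radiogenomics_nb(
    counts: CountMatrix,
    covars: CovariateMatrix,
    labels: LabelVector,
    config: TrainingConfig | None = None,
) -> NBClassModel:
    """Fit the covariate-linked NB classifier on an aligned training triple.

    Pipeline: quantile filter -> differential-expression ranking on the
    training data -> top-k panel -> class size-factor means -> raw + shrunken
    dispersions -> per-class least-squares fit of log(mean) on covariates ->
    class priors.
    """
    config = config or TrainingConfig()
    _check_fit_preconditions(counts, labels)
    if covars.sample_ids != counts.sample_ids:
        raise ValidationError("covariates and counts must be aligned before fitting")

    X_full = covars.with_intercept() if config.intercept else covars
    panel_counts = _prepare_panel(counts, labels, config)
    class_means = compute_class_means(panel_counts, labels)

    phi_raw, tau2 = estimate_dispersion_raw(
        panel_counts, class_means, config.phi_min, config.phi_max
    )
    disp = shrink_dispersion_wl(
        phi_raw, tau2, panel_counts.gene_ids, config.phi_min, config.phi_max
    )

    G = panel_counts.n_genes
    C = len(labels.class_set)
    p = X_full.n_features
    betas = np.empty((G, C, p))
    for ci, cls in enumerate(labels.class_set):
        idx = class_means.class_positions[cls]
        X_c = X_full.values[idx]
        fit = fit_beta(X_c, class_means.mu(cls))
        betas[:, ci, :] = fit.betas

    return NBClassModel(
        kind="radiogenomics_nb",
        gene_ids=list(panel_counts.gene_ids),
        class_set=list(labels.class_set),
        feature_names=list(X_full.feature_names),
        dispersions=disp.phi_shrunk,
        betas=betas,
        priors=_priors(labels, config.prior_mode),
        fit_metadata={
            "config": config.to_dict(),
            "config_hash": config_hash(config.to_dict()),
            "seed": config.seed,
            "alpha": disp.alpha,
            "phi0": disp.phi0,
            "tau02": disp.tau02,
            "tau2": disp.tau2.tolist(),
            "phi_raw": disp.phi_raw.tolist(),
            "n_train": counts.n_samples,
        },
    )


def fit_nblda(
    counts: CountMatrix,
    labels: LabelVector,
    config: TrainingConfig | None = None,
) -> NBClassModel:
    """Fit the counts-only NBLDA baseline with the shared preprocessing pipeline.

    Per gene and class the model stores a log rate scaled so that a test sample
    of average training library size has mean ``rate_gc``.
    """
    config = config or TrainingConfig()
    _check_fit_preconditions(counts, labels)

    panel_counts = _prepare_panel(counts, labels, config)
    class_means = compute_class_means(panel_counts, labels)
    phi_raw, tau2 = estimate_dispersion_raw(
        panel_counts, class_means, config.phi_min, config.phi_max
    )
    disp = shrink_dispersion_wl(
        phi_raw, tau2, panel_counts.gene_ids, config.phi_min, config.phi_max
    )

    mean_train_total = float(panel_counts.counts.sum(axis=0).mean())
    G = panel_counts.n_genes
    C = len(labels.class_set)
    log_rates = np.empty((G, C, 1))
    for ci, cls in enumerate(labels.class_set):
        lam = class_means.lambdas[cls]
        class_total = float(
            panel_counts.counts[:, class_means.class_positions[cls]].sum()
        )
        log_rates[:, ci, 0] = np.log(lam / class_total * mean_train_total)

    return NBClassModel(
        kind="nblda",
        gene_ids=list(panel_counts.gene_ids),
        class_set=list(labels.class_set),
        feature_names=["log_rate"],
        dispersions=disp.phi_shrunk,
        betas=log_rates,
        priors=_priors(labels, config.prior_mode),
        fit_metadata={
            "config": config.to_dict(),
            "config_hash": config_hash(config.to_dict()),
            "seed": config.seed,
            "alpha": disp.alpha,
            "phi0": disp.phi0,
            "tau02": disp.tau02,
            "mean_train_total": mean_train_total,
            "n_train": counts.n_samples,
        },
    )


def _panel_counts_for_prediction(
    model: NBClassModel, test_counts: CountMatrix
) -> np.ndarray:
    missing = [g for g in model.gene_ids if g not in set(test_counts.gene_ids)]
    if missing:
        raise PredictionError(f"test counts missing panel genes: {missing}")
    sub = test_counts.subset_genes(model.gene_ids)
    if (sub.counts > MAX_TEST_COUNT).any():
        raise PredictionError(f"test counts exceed the {MAX_TEST_COUNT} guardrail")
    return sub.counts


def _score_to_result(
    sample_id: str, class_set: list[str], scores: np.ndarray
) -> PredictionResult:
    post = np.exp(scores - logsumexp(scores))
    post /= post.sum()
    return PredictionResult(
        sample_id=sample_id,
        class_set=list(class_set),
        scores=scores,
        posteriors=post,
        predicted_class=class_set[int(np.argmax(scores))],
    )


def predict_radiogenomics_nb(
    model: NBClassModel,
    test_counts: CountMatrix,
    test_covars: CovariateMatrix,
) -> list[PredictionResult]:
    """Score test samples: per class, sum of per-gene NB log-pmfs at mean
    ``exp(X_t @ beta_gc)`` plus the log prior."""
    if model.kind != "radiogenomics_nb":
        raise PredictionError(f"model kind {model.kind!r} is not radiogenomics_nb")
    X = test_covars.with_intercept() if "_intercept" in model.feature_names else test_covars
    if list(X.feature_names) != list(model.feature_names):
        raise PredictionError(
            f"covariate names {X.feature_names} do not match model "
            f"features {model.feature_names}"
        )
    if X.sample_ids != test_counts.sample_ids:
        raise ValidationError("test counts and covariates must be aligned")
    y = _panel_counts_for_prediction(model, test_counts)  # (G, n)
    log_prior = np.log(model.priors)
    results = []
    for si, sample_id in enumerate(test_counts.sample_ids):
        x_t = X.values[si]  # (p,)
        mu = np.exp(model.betas @ x_t)  # (G, C)
        ll = nb_log_pmf(y[:, si][:, None], mu, model.dispersions[:, None])
        scores = ll.sum(axis=0) + log_prior
        results.append(_score_to_result(sample_id, model.class_set, scores))
    return results


def predict_nblda(
    model: NBClassModel, test_counts: CountMatrix
) -> list[PredictionResult]:
    """Score test samples with class rates rescaled by the test size factor
    (test library total over the mean training library total)."""
    if model.kind != "nblda":
        raise PredictionError(f"model kind {model.kind!r} is not nblda")
    y = _panel_counts_for_prediction(model, test_counts)
    mean_train_total = float(model.fit_metadata["mean_train_total"])
    rates = np.exp(model.betas[:, :, 0])  # (G, C)
    log_prior = np.log(model.priors)
    results = []
    for si, sample_id in enumerate(test_counts.sample_ids):
        s_t = max(float(y[:, si].sum()) / mean_train_total, 1e-8)
        mu = s_t * rates
        ll = nb_log_pmf(y[:, si][:, None], mu, model.dispersions[:, None])
        scores = ll.sum(axis=0) + log_prior
        results.append(_score_to_result(sample_id, model.class_set, scores))
    return results


def predictions_to_rows(results: Sequence[PredictionResult]) -> list[dict]:
    """Flatten prediction results into CSV-ready row dicts."""
    rows = []
    for r in results:
        row: dict = {"sample_id": r.sample_id, "predicted_class": r.predicted_class}
        for cls, sc, po in zip(r.class_set, r.scores, r.posteriors):
            row[f"score_{cls}"] = float(sc)
            row[f"posterior_{cls}"] = float(po)
        rows.append(row)
    return rows
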