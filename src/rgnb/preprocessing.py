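"""Low-count filtering, per-gene differential-expression ranking, and
class-wise size-factor / mean computation.

The ranking is a per-gene NB likelihood-ratio statistic (class-specific means
vs. a pooled mean, with a shared method-of-moments dispersion per gene). It
stands in for an external differential-expression tool; ``top_k_panel`` also
accepts any externally supplied ranked gene list.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .data_model import CountMatrix, LabelVector
from .errors import FilterError, FitError, ValidationError
from .nb_core import nb_log_pmf

#: pseudo-total substituted for a zero per-gene class total so log-means stay finite
PSEUDO_TOTAL = 0.5


def quantile_filter(counts: CountMatrix, q: float) -> CountMatrix:
    """Keep genes whose across-sample mean count strictly exceeds the q-quantile
    of all genes' means (linear-interpolation sample quantile). Gene order kept."""
    if not 0.0 <= q <= 1.0:
        raise ValueError(f"quantile q must be in [0, 1], got {q}")
    means = counts.counts.mean(axis=1)
    threshold = float(np.quantile(means, q))
    keep = means > threshold
    if not keep.any():
        raise FilterError(
            f"quantile filter at q={q} removed all {counts.n_genes} genes"
        )
    kept = [g for g, k in zip(counts.gene_ids, keep) if k]
    return counts.subset_genes(kept)


@dataclass
class GeneRanking:
    """Genes ordered by a non-negative differential-expression score (descending).

    ``direction`` is the sign of the second-class minus first-class mean."""

    gene_ids: list[str]
    scores: np.ndarray
    directions: np.ndarray

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        self.directions = np.asarray(self.directions, dtype=int)
        if (self.scores < 0).any():
            raise ValidationError("ranking scores must be non-negative")
        if np.any(np.diff(self.scores) > 1e-12):
            raise ValidationError("ranking scores must be sorted non-increasing")


def _mom_dispersion(y: np.ndarray, phi_max: float = 1e3) -> np.ndarray:
    """Method-of-moments dispersion per gene from (G, n) counts: (s^2 - m)/m^2."""
    m = y.mean(axis=1)
    v = y.var(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        phi = (v - m) / m**2
    phi = np.where(np.isfinite(phi), phi, 0.0)
    return np.clip(phi, 0.0, phi_max)


def rank_genes_lrt(counts: CountMatrix, labels: LabelVector) -> GeneRanking:
    """Rank genes by 2*[ll(class-specific NB means) - ll(pooled NB mean)].

    A shared method-of-moments dispersion per gene is used in both nested
    models, so the statistic is non-negative up to numerical noise. Ties are
    broken by gene id.
    """
    if counts.sample_ids != labels.sample_ids:
        raise ValidationError("counts and labels must be aligned before ranking")
    if len(labels.class_set) != 2:
        raise ValidationError("ranking requires exactly 2 classes")
    labels.require_all_classes()

    y = counts.counts.astype(float)  # (G, n)
    G, n = y.shape
    phi = _mom_dispersion(y)[:, None]

    pooled = np.maximum(y.mean(axis=1), PSEUDO_TOTAL / n)[:, None]
    ll_pooled = nb_log_pmf(y, pooled, phi).sum(axis=1)

    ll_split = np.zeros(G)
    class_mean = {}
    for cls in labels.class_set:
        idx = labels.class_indices(cls)
        yc = y[:, idx]
        mc = np.maximum(yc.mean(axis=1), PSEUDO_TOTAL / len(idx))
        class_mean[cls] = mc
        ll_split += nb_log_pmf(yc, mc[:, None], phi).sum(axis=1)

    stat = np.maximum(2.0 * (ll_split - ll_pooled), 0.0)
    delta = class_mean[labels.class_set[1]] - class_mean[labels.class_set[0]]
    directions = np.sign(delta).astype(int)

    order = np.lexsort((np.asarray(counts.gene_ids), -stat))
    return GeneRanking(
        gene_ids=[counts.gene_ids[i] for i in order],
        scores=stat[order],
        directions=directions[order],
    )


def top_k_panel(ranking: GeneRanking | Sequence[str], k: int) -> list[str]:
    """First ``k`` gene ids of a ranking (or of any pre-ranked gene list)."""
    gene_ids = ranking.gene_ids if isinstance(ranking, GeneRanking) else list(ranking)
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    if k > len(gene_ids):
        raise ValueError(f"k={k} exceeds the {len(gene_ids)} ranked genes")
    return list(gene_ids[:k])


def read_panel(path: str | Path) -> list[str]:
    return [ln.strip() for ln in Path(path).read_text().splitlines() if ln.strip()]


def write_panel(panel: Sequence[str], path: str | Path) -> None:
    Path(path).write_text("\n".join(panel) + "\n")


@dataclass
class ClassMeans:
    """Per-class size factors, per-gene class totals, and the implied means.

    For each class c: size factor s_ic = (sample i total) / (class grand total),
    so they sum to exactly 1 within a class; lambda_gc = per-gene class total
    (zero totals replaced by ``PSEUDO_TOTAL``); mu_igc = s_ic * lambda_gc.
    """

    gene_ids: list[str]
    class_set: list[str]
    sample_ids: list[str]
    labels: list[str]
    size_factors: dict  # cls -> (n_c,) in class sample order
    lambdas: dict  # cls -> (G,)
    class_positions: dict  # cls -> positions into sample_ids

    def mu(self, cls: str) -> np.ndarray:
        """(n_c, G) per-sample per-gene means for one class."""
        return np.outer(self.size_factors[cls], self.lambdas[cls])

    def mean_matrix(self, counts: CountMatrix) -> np.ndarray:
        """(G, n) means aligned to ``counts``' gene/sample order."""
        if counts.gene_ids != self.gene_ids:
            raise ValidationError("gene panel mismatch between counts and class means")
        if counts.sample_ids != self.sample_ids:
            raise ValidationError("sample order mismatch between counts and class means")
        out = np.empty((len(self.gene_ids), len(self.sample_ids)))
        for cls in self.class_set:
            out[:, self.class_positions[cls]] = self.mu(cls).T
        return out


def compute_class_means(counts: CountMatrix, labels: LabelVector) -> ClassMeans:
    if counts.sample_ids != labels.sample_ids:
        raise ValidationError("counts and labels must be aligned")
    labels.require_all_classes()
    size_factors, lambdas, positions = {}, {}, {}
    for cls in labels.class_set:
        idx = labels.class_indices(cls)
        block = counts.counts[:, idx]
        sample_totals = block.sum(axis=0).astype(float)
        if sample_totals.sum() <= 0:
            raise FitError(f"class {cls!r} has zero total read count")
        # zero-total samples get the same pseudo-total as zero-total genes,
        # keeping every mu_igc strictly positive and sum(s) exactly 1
        sample_totals[sample_totals == 0] = PSEUDO_TOTAL
        grand = sample_totals.sum()
        lam = block.sum(axis=1).astype(float)
        lam[lam == 0] = PSEUDO_TOTAL
        size_factors[cls] = sample_totals / grand
        lambdas[cls] = lam
        positions[cls] = idx
    return ClassMeans(
        gene_ids=list(counts.gene_ids),
        class_set=list(labels.class_set),
        sample_ids=list(counts.sample_ids),
        labels=list(labels.labels),
        size_factors=size_factors,
        lambdas=lambdas,
        class_positions=positions,
    )
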