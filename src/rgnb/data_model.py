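"""Typed containers and delimited-text I/O for counts, covariates, labels and models.

Counts are canonically oriented genes x samples; covariates samples x features.
Model serialization uses a versioned JSON container so fitted models diff cleanly
in version control.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import (
    AlignmentError,
    FormatError,
    ModelIOError,
    ValidationError,
)

logger = logging.getLogger(__name__)

MODEL_SCHEMA = "rgnb-model/1"

INTERCEPT_NAME = "_intercept"


def _check_unique(ids: Sequence[str], what: str) -> list[str]:
    ids = [str(x) for x in ids]
    if len(set(ids)) != len(ids):
        seen: set[str] = set()
        dup = next(x for x in ids if x in seen or seen.add(x))
        raise FormatError(f"duplicate {what} id: {dup!r}")
    return ids


@dataclass
class CountMatrix:
    """Genes x samples matrix of non-negative integer read counts."""

    gene_ids: list[str]
    sample_ids: list[str]
    counts: np.ndarray  # (G, n), integer dtype

    def __post_init__(self) -> None:
        self.gene_ids = _check_unique(self.gene_ids, "gene")
        self.sample_ids = _check_unique(self.sample_ids, "sample")
        arr = np.asarray(self.counts)
        if arr.ndim != 2:
            raise ValidationError("counts must be a 2-D matrix")
        if arr.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValidationError(
                f"counts shape {arr.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        if np.issubdtype(arr.dtype, np.floating):
            bad = ~np.isfinite(arr) | (arr != np.floor(arr))
            if bad.any():
                g, s = np.argwhere(bad)[0]
                raise ValidationError(
                    f"non-integer count {arr[g, s]!r} at gene "
                    f"{self.gene_ids[g]!r}, sample {self.sample_ids[s]!r}"
                )
            arr = arr.astype(np.int64)
        elif not np.issubdtype(arr.dtype, np.integer):
            raise ValidationError(f"counts dtype {arr.dtype} is not numeric integer")
        if (arr < 0).any():
            g, s = np.argwhere(arr < 0)[0]
            raise ValidationError(
                f"negative count {arr[g, s]} at gene "
                f"{self.gene_ids[g]!r}, sample {self.sample_ids[s]!r}"
            )
        self.counts = arr.astype(np.int64)

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def subset_genes(self, gene_ids: Sequence[str]) -> "CountMatrix":
        index = {g: i for i, g in enumerate(self.gene_ids)}
        missing = [g for g in gene_ids if g not in index]
        if missing:
            raise ValidationError(f"unknown gene ids: {missing[:5]}")
        rows = [index[g] for g in gene_ids]
        return CountMatrix(list(gene_ids), list(self.sample_ids), self.counts[rows])

    def subset_samples(self, sample_ids: Sequence[str]) -> "CountMatrix":
        index = {s: i for i, s in enumerate(self.sample_ids)}
        cols = [index[s] for s in sample_ids]
        return CountMatrix(list(self.gene_ids), list(sample_ids), self.counts[:, cols])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.gene_ids, columns=self.sample_ids)


@dataclass
class CovariateMatrix:
    """Samples x features matrix of finite continuous covariates."""

    sample_ids: list[str]
    feature_names: list[str]
    values: np.ndarray  # (n, p)
    has_intercept: bool = False

    def __post_init__(self) -> None:
        self.sample_ids = _check_unique(self.sample_ids, "sample")
        self.feature_names = _check_unique(self.feature_names, "feature")
        arr = np.asarray(self.values, dtype=float)
        if arr.ndim != 2 or arr.shape != (len(self.sample_ids), len(self.feature_names)):
            raise ValidationError(
                f"covariate shape {arr.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.feature_names)} features"
            )
        if not np.isfinite(arr).all():
            i, j = np.argwhere(~np.isfinite(arr))[0]
            raise ValidationError(
                f"non-finite covariate at sample {self.sample_ids[i]!r}, "
                f"feature {self.feature_names[j]!r}"
            )
        if self.has_intercept and (arr.shape[1] == 0 or not np.all(arr[:, 0] == 1.0)):
            raise ValidationError("has_intercept set but first column is not all ones")
        self.values = arr

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_features(self) -> int:
        return len(self.feature_names)

    def with_intercept(self) -> "CovariateMatrix":
        """Return a copy with a leading all-ones column (no-op if already present)."""
        if self.has_intercept:
            return self
        values = np.column_stack([np.ones(self.n_samples), self.values])
        return CovariateMatrix(
            list(self.sample_ids), [INTERCEPT_NAME] + list(self.feature_names),
            values, has_intercept=True,
        )

    def subset_samples(self, sample_ids: Sequence[str]) -> "CovariateMatrix":
        index = {s: i for i, s in enumerate(self.sample_ids)}
        rows = [index[s] for s in sample_ids]
        return CovariateMatrix(
            list(sample_ids), list(self.feature_names), self.values[rows],
            has_intercept=self.has_intercept,
        )


@dataclass
class LabelVector:
    """Per-sample class labels drawn from an ordered class set of size C >= 2."""

    sample_ids: list[str]
    labels: list[str]
    class_set: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.sample_ids = _check_unique(self.sample_ids, "sample")
        self.labels = [str(x) for x in self.labels]
        if len(self.labels) != len(self.sample_ids):
            raise ValidationError("labels length does not match sample ids")
        if not self.class_set:
            self.class_set = sorted(set(self.labels))
        self.class_set = _check_unique(self.class_set, "class")
        if len(self.class_set) < 2:
            raise ValidationError("need at least two classes")
        unknown = set(self.labels) - set(self.class_set)
        if unknown:
            raise ValidationError(f"labels outside declared class set: {sorted(unknown)}")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def class_indices(self, cls: str) -> np.ndarray:
        """Positions of samples belonging to ``cls`` in declared sample order."""
        lab = np.asarray(self.labels)
        return np.flatnonzero(lab == cls)

    def class_counts(self) -> dict[str, int]:
        return {c: int(len(self.class_indices(c))) for c in self.class_set}

    def require_all_classes(self) -> None:
        empty = [c for c, n in self.class_counts().items() if n == 0]
        if empty:
            raise ValidationError(f"classes with no samples: {empty}")

    def subset_samples(self, sample_ids: Sequence[str]) -> "LabelVector":
        index = {s: i for i, s in enumerate(self.sample_ids)}
        rows = [index[s] for s in sample_ids]
        return LabelVector(
            list(sample_ids), [self.labels[i] for i in rows], list(self.class_set)
        )


@dataclass
class NBClassModel:
    """A fitted count classifier: per-gene dispersions plus per-gene-per-class parameters.

    ``kind`` is ``"radiogenomics_nb"`` (betas link covariates to the log mean)
    or ``"nblda"`` (betas hold a single log class rate per gene; prediction
    rescales by a test size factor).
    """

    kind: str
    gene_ids: list[str]
    class_set: list[str]
    feature_names: list[str]
    dispersions: np.ndarray  # (G',)
    betas: np.ndarray  # (G', C, p)
    priors: np.ndarray  # (C,)
    fit_metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.dispersions = np.asarray(self.dispersions, dtype=float)
        self.betas = np.asarray(self.betas, dtype=float)
        self.priors = np.asarray(self.priors, dtype=float)
        self.validate()

    def validate(self) -> None:
        G, C, p = len(self.gene_ids), len(self.class_set), len(self.feature_names)
        if self.kind not in ("radiogenomics_nb", "nblda"):
            raise ValidationError(f"unknown model kind {self.kind!r}")
        if self.dispersions.shape != (G,):
            raise ValidationError("dispersions shape mismatch")
        if (self.dispersions <= 0).any():
            raise ValidationError("all dispersions must be > 0")
        if self.betas.shape != (G, C, p):
            raise ValidationError(
                f"betas shape {self.betas.shape} != ({G}, {C}, {p})"
            )
        if not np.isfinite(self.betas).all():
            raise ValidationError("betas must be finite")
        if self.priors.shape != (C,):
            raise ValidationError("priors shape mismatch")
        if abs(float(self.priors.sum()) - 1.0) > 1e-12:
            raise ValidationError("priors must sum to 1")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)


@dataclass
class PredictionResult:
    """Per-sample classification outcome: unnormalized log-joint scores per class,
    normalized posteriors and the argmax class (ties broken by class order)."""

    sample_id: str
    class_set: list[str]
    scores: np.ndarray  # (C,) log p(Y, c) up to a shared constant
    posteriors: np.ndarray  # (C,) sums to 1
    predicted_class: str


def _sep_for(path: str | Path) -> str:
    return "\t" if str(path).endswith((".tsv", ".txt", ".tab")) else ","


def read_count_matrix(path: str | Path, orientation: str = "genes_in_rows") -> CountMatrix:
    """Read a delimited counts table (TSV/CSV sniffed by extension).

    ``orientation`` declares what the file's rows are; the result is always
    genes x samples.
    """
    if orientation not in ("genes_in_rows", "samples_in_rows"):
        raise ValueError(f"unknown orientation {orientation!r}")
    df = pd.read_csv(path, sep=_sep_for(path), index_col=0)
    if df.index.has_duplicates or df.columns.has_duplicates:
        raise FormatError(f"duplicate row/column ids in {path}")
    if orientation == "samples_in_rows":
        df = df.T
    arr = df.to_numpy()
    if arr.dtype == object:
        try:
            arr = arr.astype(float)
        except (TypeError, ValueError) as exc:
            raise ValidationError(f"non-numeric cell in {path}: {exc}") from exc
    return CountMatrix(list(df.index.astype(str)), list(df.columns.astype(str)), arr)


def write_count_matrix(cm: CountMatrix, path: str | Path) -> None:
    cm.to_frame().to_csv(path, sep=_sep_for(path))


def read_covariate_matrix(path: str | Path) -> CovariateMatrix:
    """Read a samples x features covariate table (first column = sample ids)."""
    df = pd.read_csv(path, sep=_sep_for(path), index_col=0)
    if df.index.has_duplicates or df.columns.has_duplicates:
        raise FormatError(f"duplicate ids in {path}")
    return CovariateMatrix(
        list(df.index.astype(str)), list(df.columns.astype(str)),
        df.to_numpy(dtype=float),
    )


def write_covariate_matrix(cov: CovariateMatrix, path: str | Path) -> None:
    pd.DataFrame(cov.values, index=cov.sample_ids, columns=cov.feature_names).to_csv(
        path, sep=_sep_for(path)
    )


def read_label_vector(
    path: str | Path, column: str | None = None, class_set: Sequence[str] | None = None
) -> LabelVector:
    """Read per-sample labels; ``column`` picks the label column (default: first)."""
    df = pd.read_csv(path, sep=_sep_for(path), index_col=0, dtype=str)
    if df.index.has_duplicates:
        raise FormatError(f"duplicate sample ids in {path}")
    col = column if column is not None else df.columns[0]
    if col not in df.columns:
        raise FormatError(f"label column {col!r} not found in {path}")
    return LabelVector(
        list(df.index.astype(str)),
        list(df[col].astype(str)),
        list(class_set) if class_set else [],
    )


def write_label_vector(lv: LabelVector, path: str | Path, column: str = "label") -> None:
    pd.DataFrame({column: lv.labels}, index=lv.sample_ids).rename_axis("sample_id").to_csv(
        path, sep=_sep_for(path)
    )


def align_dataset(
    counts: CountMatrix, covars: CovariateMatrix, labels: LabelVector
) -> tuple[CountMatrix, CovariateMatrix, LabelVector]:
    """Restrict all three inputs to the shared sample ids, in counts' sample order.

    Dropped ids are logged, never silently swallowed.
    """
    shared = set(counts.sample_ids) & set(covars.sample_ids) & set(labels.sample_ids)
    if not shared:
        raise AlignmentError("no sample ids shared between counts, covariates and labels")
    order = [s for s in counts.sample_ids if s in shared]
    for name, ids in (
        ("counts", counts.sample_ids),
        ("covariates", covars.sample_ids),
        ("labels", labels.sample_ids),
    ):
        dropped = [s for s in ids if s not in shared]
        if dropped:
            logger.warning("align_dataset: dropping %d sample(s) from %s: %s",
                           len(dropped), name, dropped[:10])
    return (
        counts.subset_samples(order),
        covars.subset_samples(order),
        labels.subset_samples(order),
    )


def config_hash(payload: dict) -> str:
    return hashlib.sha256(
        json.dumps(payload, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def save_model(model: NBClassModel, path: str | Path) -> None:
    model.validate()
    doc = {
        "schema": MODEL_SCHEMA,
        "kind": model.kind,
        "gene_ids": model.gene_ids,
        "class_set": model.class_set,
        "feature_names": model.feature_names,
        "dispersions": model.dispersions.tolist(),
        "betas": model.betas.tolist(),
        "priors": model.priors.tolist(),
        "fit_metadata": model.fit_metadata,
    }
    Path(path).write_text(json.dumps(doc, indent=1))


def load_model(path: str | Path) -> NBClassModel:
    try:
        doc = json.loads(Path(path).read_text())
    except (OSError, json.JSONDecodeError) as exc:
        raise ModelIOError(f"cannot read model file {path}: {exc}") from exc
    if not isinstance(doc, dict) or doc.get("schema") != MODEL_SCHEMA:
        raise ModelIOError(
            f"unsupported model schema {doc.get('schema')!r} in {path} "
            f"(expected {MODEL_SCHEMA!r})"
        )
    try:
        return NBClassModel(
            kind=doc["kind"],
            gene_ids=list(doc["gene_ids"]),
            class_set=list(doc["class_set"]),
            feature_names=list(doc["feature_names"]),
            dispersions=np.asarray(doc["dispersions"], dtype=float),
            betas=np.asarray(doc["betas"], dtype=float),
            priors=np.asarray(doc["priors"], dtype=float),
            fit_metadata=doc.get("fit_metadata", {}),
        )
    except (KeyError, ValidationError, ValueError) as exc:
        raise ModelIOError(f"corrupted model payload in {path}: {exc}") from exc
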