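"""Leave-one-out cross-validation of signature-restricted immunosignatures.

Each mouse is predicted in turn by a linear maximum-margin classifier
(linear-kernel SVM, fixed C) trained on all remaining mice, using only the
peptides of a chosen signature. Per-peptide centering and scaling are fit
on the training fold only, so the held-out mouse never leaks into the
model. Two modes are offered:

* ``asis`` (default) — the feature set is fixed in advance. This
  replicates the historical procedure (features chosen on the full cohort
  before cross-validation) and therefore carries the usual selection
  optimism; treat its error as a reproduction figure, not an unbiased
  estimate.
* ``nested`` — a feature-selection callback is re-run inside every
  training fold, giving an honest generalization estimate.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .array_io import IntensityMatrix
from .signature_selection import PeptideSet

FeatureSelector = Callable[[pd.DataFrame, pd.Series], Sequence[str]]


@dataclass(frozen=True)
class CVResult:
    """Outcome of a leave-one-out run."""

    n_samples: int
    n_errors: int
    per_sample: pd.DataFrame  # sample_id, true_label, predicted_label

    def __post_init__(self) -> None:
        if len(self.per_sample) != self.n_samples:
            raise ValueError("per-sample table length mismatch")

    @property
    def error_rate(self) -> float:
        return self.n_errors / self.n_samples

    def to_tsv(self, path, header_comment: str | None = None) -> None:
        with open(path, "w") as fh:
            if header_comment:
                fh.write(f"# {header_comment}\n")
            fh.write(f"# n={self.n_samples} errors={self.n_errors} "
                     f"error_rate={self.error_rate:.4f}\n")
            self.per_sample.to_csv(fh, sep="\t", index=False)


def _feature_ids(features: PeptideSet | Sequence[str]) -> list[str]:
    if isinstance(features, PeptideSet):
        return list(features.members.index)
    return list(features)


def loocv(
    m: IntensityMatrix,
    labels: pd.Series,
    features: PeptideSet | Sequence[str],
    seed: int = 0,
    mode: str = "asis",
    C: float = 1.0,
    selector: FeatureSelector | None = None,
) -> CVResult:
    """Leave-one-mouse-out cross-validation with a linear SVM.

    ``m`` should be log10-scale and replicate-averaged (one column per
    mouse); ``labels`` is a binary series indexed by those column ids.
    The run is deterministic for a given seed and input; the seed only
    breaks ties in the underlying solver and never reorders samples.
    """
    if mode not in ("asis", "nested"):
        raise ValueError(f"unknown mode {mode!r}")
    if mode == "nested" and selector is None:
        raise ValueError("nested mode needs a feature selector")
    ids = _feature_ids(features)
    if not ids:
        raise ValueError("empty feature set")
    labels = labels.reindex(m.values.columns)
    if labels.isna().any():
        raise ValueError("labels missing for some samples")
    classes = labels.unique()
    if len(classes) != 2:
        raise ValueError(f"need exactly two classes, got {list(classes)}")
    if (labels.value_counts() < 2).any():
        raise ValueError("need >= 2 mice per class for leave-one-out")

    X_all = m.values.T  # samples x peptides
    rows = []
    n_errors = 0
    for held_out in X_all.index:
        train_idx = X_all.index.drop(held_out)
        y_train = labels[train_idx]
        if y_train.nunique() < 2:
            raise ValueError(f"single-class training fold when holding out {held_out}")
        fold_ids = ids
        if mode == "nested":
            fold_ids = list(selector(m.values[train_idx], y_train))
            if not fold_ids:
                raise ValueError(f"selector returned no features for fold {held_out}")
        X_train = X_all.loc[train_idx, fold_ids].to_numpy()
        X_test = X_all.loc[[held_out], fold_ids].to_numpy()
        scaler = StandardScaler().fit(X_train)
        clf = SVC(kernel="linear", C=C, random_state=seed)
        clf.fit(scaler.transform(X_train), y_train.to_numpy())
        pred = clf.predict(scaler.transform(X_test))[0]
        truth = labels[held_out]
        n_errors += int(pred != truth)
        rows.append(
            {"sample_id": held_out, "true_label": truth, "predicted_label": pred}
        )
    return CVResult(
        n_samples=len(rows), n_errors=n_errors, per_sample=pd.DataFrame(rows)
    )
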