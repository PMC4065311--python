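"""Slide normalization, replicate handling, and array QC statistics.

Transforms follow the ordering of the analysis: raw intensities are median
normalized per slide, log-10 transformed, and technical replicates are
averaged on the log scale (a geometric mean of raw intensities) before any
group testing. All transforms return new matrices; inputs are never
mutated, so pipelines are replayable.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd

from .array_io import (
    SCALE_LOG10,
    SCALE_MEDIAN_NORMALIZED,
    SCALE_RAW,
    IntensityMatrix,
)


def median_normalize(
    m: IntensityMatrix, floor: float | None = None
) -> IntensityMatrix:
    """Divide each slide by its own median; column medians become exactly 1.

    Idempotent. ``floor`` clips values from below first, for instruments
    that report zero or negative intensities after background handling.
    """
    if m.scale not in (SCALE_RAW, SCALE_MEDIAN_NORMALIZED):
        raise ValueError(f"cannot median-normalize a {m.scale} matrix")
    values = m.values
    if floor is not None:
        values = values.clip(lower=floor)
    if (values.to_numpy() <= 0).any():
        raise ValueError(
            "non-positive intensities; pass floor=<small positive> to clip them"
        )
    normalized = values / values.median(axis=0)
    return IntensityMatrix(normalized, m.samples.copy(), SCALE_MEDIAN_NORMALIZED)


def log10_transform(m: IntensityMatrix) -> IntensityMatrix:
    """Elementwise log10 of a median-normalized matrix; column medians become 0."""
    if m.scale != SCALE_MEDIAN_NORMALIZED:
        raise ValueError("log10_transform expects a median-normalized matrix")
    if (m.values.to_numpy() <= 0).any():
        raise ValueError("log10 of non-positive intensity")
    return IntensityMatrix(np.log10(m.values), m.samples.copy(), SCALE_LOG10)


def delog10(m: IntensityMatrix) -> IntensityMatrix:
    """Inverse of :func:`log10_transform` (back to the linear normalized scale).

    Applied after replicate averaging this turns log-scale means into
    geometric means of the raw replicates, the scale on which binding
    ratios are computed.
    """
    if m.scale != SCALE_LOG10:
        raise ValueError("delog10 expects a log10 matrix")
    return IntensityMatrix(10.0 ** m.values, m.samples.copy(), SCALE_MEDIAN_NORMALIZED)


def average_technical_replicates(m: IntensityMatrix) -> IntensityMatrix:
    """Collapse technical replicates to one column per mouse (arithmetic mean
    on the current scale).

    The resulting sample table is indexed by ``<study>:<mouse_id>`` and
    carries ``n_replicates`` instead of ``replicate``.
    """
    samples = m.samples
    keys = list(zip(samples["study"], samples["mouse_id"]))
    meta_cols = ["mouse_id", "strain", "age_months", "phenotype", "study"]
    seen: dict[tuple, dict] = {}
    order: list[tuple] = []
    for sid, key in zip(samples.index, keys):
        row = samples.loc[sid, meta_cols].to_dict()
        if key not in seen:
            seen[key] = {"meta": row, "cols": [sid]}
            order.append(key)
        else:
            prior = seen[key]["meta"]
            if any(
                not (pd.isna(prior[c]) and pd.isna(row[c])) and prior[c] != row[c]
                for c in meta_cols
            ):
                raise ValueError(f"inconsistent replicate metadata for mouse {key}")
            seen[key]["cols"].append(sid)

    values = {}
    meta_rows = []
    for key in order:
        study, mouse = key
        new_id = f"{study}:{mouse}"
        cols = seen[key]["cols"]
        values[new_id] = m.values[cols].mean(axis=1)
        meta = dict(seen[key]["meta"])
        meta["n_replicates"] = len(cols)
        meta_rows.append((new_id, meta))
    new_samples = pd.DataFrame(
        [meta for _, meta in meta_rows], index=[sid for sid, _ in meta_rows]
    )
    return IntensityMatrix(pd.DataFrame(values, index=m.values.index), new_samples, m.scale)


# ---------------------------------------------------------------------------
# QC
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class QCReport:
    """Array QC summary.

    replicate_pearson
        minimum, over mice, of the minimum pairwise Pearson correlation
        between that mouse's technical replicate slides.
    slide_cv
        mean per-peptide coefficient of variation (SD/mean) across
        technical replicate slides, averaged over peptides and mice —
        the linear-scale slide-to-slide reproducibility.
    mdfc_95
        minimum detectable fold change at the 95th percentile: the 95th
        percentile of the null between-replicate fold-change distribution
        (see :func:`qc_report` for the two definitions offered).
    """

    replicate_pearson: float
    slide_cv: float
    mdfc_95: float

    def __post_init__(self) -> None:
        if not -1.0 <= self.replicate_pearson <= 1.0 + 1e-12:
            raise ValueError("pearson out of [-1, 1]")
        if self.slide_cv < 0 or self.mdfc_95 < 1.0 - 1e-12:
            raise ValueError("slide_cv must be >= 0 and mdfc_95 >= 1")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "metric": ["replicate_pearson", "slide_cv", "mdfc_95"],
                "value": [self.replicate_pearson, self.slide_cv, self.mdfc_95],
            }
        )

    def to_tsv(self, path: str | Path, header_comment: str | None = None) -> None:
        with open(path, "w") as fh:
            if header_comment:
                fh.write(f"# {header_comment}\n")
            self.to_frame().to_csv(fh, sep="\t", index=False)


def _replicate_groups(m: IntensityMatrix) -> list[list[str]]:
    groups: dict[tuple, list[str]] = {}
    for sid, row in m.samples.iterrows():
        groups.setdefault((row["study"], row["mouse_id"]), []).append(sid)
    multi = [cols for cols in groups.values() if len(cols) >= 2]
    return multi


def qc_report(m: IntensityMatrix, mdfc_method: str = "pairwise") -> QCReport:
    """Compute the QC triplet on a (preferably median-normalized) matrix.

    CV and fold changes are taken within each mouse's technical replicate
    set and pooled; with no replicate structure all columns are treated as
    one replicate group. ``mdfc_method``:

    * ``pairwise`` — 95th percentile of max/min intensity ratios over all
      replicate pairs per peptide (an empirical single-slide-vs-single-slide
      detection limit).
    * ``consensus`` — 95th percentile of the fold deviation of single
      replicates from their replicate-set geometric mean (a detection limit
      relative to the replicate consensus; smaller, and the reading most
      compatible with a 1.3-fold limit at 14% CV).
    """
    if m.n_samples < 2:
        raise ValueError("QC needs at least two slides")
    groups = _replicate_groups(m)
    if not groups:
        groups = [list(m.values.columns)]

    pearson_min = np.inf
    cvs = []
    folds = []
    for cols in groups:
        block = m.values[cols].to_numpy()
        corr = np.corrcoef(block.T)
        for i, j in combinations(range(len(cols)), 2):
            pearson_min = min(pearson_min, corr[i, j])
            ratio = block[:, i] / block[:, j]
            folds.append(np.maximum(ratio, 1.0 / ratio))
        cvs.append(block.std(axis=1, ddof=1) / block.mean(axis=1))
    if not np.isfinite(pearson_min):
        raise ValueError("QC needs at least one mouse with >= 2 replicates")

    slide_cv = float(np.mean(np.concatenate(cvs)))

    if mdfc_method == "pairwise":
        pooled = np.concatenate(folds)
        mdfc = float(np.quantile(pooled, 0.95))
    elif mdfc_method == "consensus":
        devs = []
        for cols in groups:
            logs = np.log10(m.values[cols].to_numpy())
            devs.append(np.abs(logs - logs.mean(axis=1, keepdims=True)).ravel())
        mdfc = float(10 ** np.quantile(np.concatenate(devs), 0.95))
    else:
        raise ValueError(f"unknown mdfc_method {mdfc_method!r}")

    return QCReport(
        replicate_pearson=float(pearson_min),
        slide_cv=slide_cv,
        mdfc_95=max(mdfc, 1.0),
    )
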