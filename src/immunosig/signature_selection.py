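"""Peptide-signature selection statistics.

The core selection rule of the analysis: per-peptide **binding ratios**
(mean case intensity / mean control intensity on the median-normalized
linear scale, after replicate averaging) thresholded at **mean + k·SD** of a
reference distribution, optionally gated by a subgroup **prefilter**
(e.g. high floaters must exceed low floaters). Signatures from two
independent studies are intersected to retain only recurring peptides.
A conventional two-sample t-test with Benjamini–Hochberg FDR control is
provided alongside as the differential-binding companion analysis, and the
ELISA S-value arithmetic used for clone screening lives here too.

The reference distribution for the mean + k·SD cutoff is configurable
because the source analyses phrase it loosely; see :class:`ThresholdRule`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .array_io import IntensityMatrix, SCALE_LOG10

K_DIAGNOSTIC = 1.5       # symptomatic case vs control contrasts
K_PREDICTIVE_LENIENT = 0.25  # late-onset genetic control (longer horizon)
K_PREDICTIVE_STRICT = 2.5    # behavior prediction (most conservative)

REFERENCE_CHOICES = (
    "control_intensity_distribution",
    "ratio_distribution",
    "per_peptide_control",
)


# ---------------------------------------------------------------------------
# Sample filters and contrasts
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SampleFilter:
    """Metadata predicate selecting a group of (replicate-averaged) samples."""

    strain: str | None = None
    age_months: float | None = None
    phenotype: str | None = None
    study: int | None = None
    mouse_ids: tuple[str, ...] | None = None

    def mask(self, samples: pd.DataFrame) -> pd.Series:
        keep = pd.Series(True, index=samples.index)
        if self.strain is not None:
            keep &= samples["strain"] == self.strain
        if self.age_months is not None:
            keep &= samples["age_months"] == self.age_months
        if self.phenotype is not None:
            keep &= samples["phenotype"] == self.phenotype
        if self.study is not None:
            keep &= samples["study"] == self.study
        if self.mouse_ids is not None:
            keep &= samples["mouse_id"].isin(self.mouse_ids)
        return keep

    @classmethod
    def from_dict(cls, d: Mapping) -> "SampleFilter":
        d = dict(d)
        if "mouse_ids" in d and d["mouse_ids"] is not None:
            d["mouse_ids"] = tuple(d["mouse_ids"])
        return cls(**d)


@dataclass(frozen=True)
class ContrastSpec:
    """Case vs control group definition, with an optional A > B prefilter.

    The prefilter subgroups are expected to partition the case stratum
    (e.g. high- vs low-floater MRL/lpr); the control group is the ratio
    denominator (typically 4-month C3H/HeJ).
    """

    name: str
    case: SampleFilter
    control: SampleFilter
    prefilter: tuple[SampleFilter, SampleFilter] | None = None

    def groups(
        self, samples: pd.DataFrame
    ) -> tuple[pd.Series, pd.Series]:
        case = self.case.mask(samples)
        control = self.control.mask(samples)
        if not case.any():
            raise ValueError(f"{self.name}: empty case group")
        if not control.any():
            raise ValueError(f"{self.name}: empty control group")
        if (case & control).any():
            raise ValueError(f"{self.name}: case and control overlap")
        return case, control


# ---------------------------------------------------------------------------
# Binding ratios and thresholds
# ---------------------------------------------------------------------------

def binding_ratio(m: IntensityMatrix, contrast: ContrastSpec) -> pd.Series:
    """Per-peptide mean(case) / mean(control) on the normalized linear scale."""
    if m.scale == SCALE_LOG10:
        raise ValueError("binding ratios are computed on the linear scale")
    case, control = contrast.groups(m.samples)
    case_mean = m.values.loc[:, case.to_numpy()].mean(axis=1)
    control_mean = m.values.loc[:, control.to_numpy()].mean(axis=1)
    if (control_mean <= 0).any():
        raise ValueError("zero control mean; normalize positive data first")
    return case_mean / control_mean


def prefilter_greater(
    m: IntensityMatrix, group_a: SampleFilter, group_b: SampleFilter
) -> pd.Series:
    """Boolean mask: mean intensity of A strictly exceeds mean of B, per peptide."""
    mask_a = group_a.mask(m.samples)
    mask_b = group_b.mask(m.samples)
    if not mask_a.any() or not mask_b.any():
        raise ValueError("prefilter groups must be non-empty")
    if (mask_a & mask_b).any():
        raise ValueError("prefilter groups must be disjoint")
    a = m.values.loc[:, mask_a.to_numpy()].mean(axis=1)
    b = m.values.loc[:, mask_b.to_numpy()].mean(axis=1)
    return a > b


@dataclass(frozen=True)
class ThresholdRule:
    """The mean + k·SD selection statistic.

    ``reference`` chooses the distribution whose mean and SD set the cutoff:

    * ``control_intensity_distribution`` (default, the literal reading):
      the control group's per-peptide mean intensities across all peptides;
      one scalar tau compared against ratios.
    * ``ratio_distribution``: the binding-ratio vector itself.
    * ``per_peptide_control``: per-peptide tau_p = (mu_p + k*sigma_p)/mu_p
      from that peptide's control replicate statistics.

    ``tau`` is attached by :func:`compute_threshold` and must be recomputed
    whenever the inputs change.
    """

    k: float
    reference: str = "control_intensity_distribution"
    tau: float | pd.Series | None = None

    def __post_init__(self) -> None:
        if self.k < 0:
            raise ValueError("k must be >= 0")
        if self.reference not in REFERENCE_CHOICES:
            raise ValueError(f"unknown reference {self.reference!r}")


def compute_threshold(
    m: IntensityMatrix,
    contrast: ContrastSpec,
    ratios: pd.Series,
    rule: ThresholdRule,
) -> ThresholdRule:
    """Return a copy of ``rule`` with the cutoff tau attached."""
    if m.n_peptides < 2:
        raise ValueError("SD undefined with a single peptide")
    _, control = contrast.groups(m.samples)
    if rule.reference == "control_intensity_distribution":
        control_means = m.values.loc[:, control.to_numpy()].mean(axis=1)
        tau = float(control_means.mean() + rule.k * control_means.std(ddof=1))
    elif rule.reference == "ratio_distribution":
        tau = float(ratios.mean() + rule.k * ratios.std(ddof=1))
    else:  # per_peptide_control
        block = m.values.loc[:, control.to_numpy()]
        if block.shape[1] < 2:
            raise ValueError("per_peptide_control needs >= 2 control columns")
        mu = block.mean(axis=1)
        sigma = block.std(axis=1, ddof=1)
        tau = (mu + rule.k * sigma) / mu
    return replace(rule, tau=tau)


# ---------------------------------------------------------------------------
# Peptide sets
# ---------------------------------------------------------------------------

@dataclass
class PeptideSet:
    """A named signature: member peptides with the ratios that selected them.

    ``members`` is indexed by peptide_id; ratio columns are either a single
    ``ratio`` (one study) or ``ratio_study1``/``ratio_study2`` after
    intersection; boolean ``in_<name>`` columns flag cross-membership.
    """

    name: str
    members: pd.DataFrame
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.members.index.has_duplicates:
            raise ValueError(f"duplicate members in signature {self.name!r}")

    def __len__(self) -> int:
        return len(self.members)

    @property
    def ids(self) -> frozenset[str]:
        return frozenset(self.members.index)

    def sequences(self) -> pd.Series | None:
        return self.members["sequence"] if "sequence" in self.members.columns else None


def select_signature(
    ratios: pd.Series,
    rule: ThresholdRule,
    prefilter_mask: pd.Series | None = None,
    name: str = "signature",
    sequences: pd.Series | None = None,
    study: int | None = None,
    contrast: ContrastSpec | None = None,
) -> PeptideSet:
    """Members are peptides with ratio strictly above tau (and passing the mask).

    An empty result is valid — strictness at the boundary means a zero-SD
    reference with all-equal ratios selects nothing.
    """
    if rule.tau is None:
        raise ValueError("rule has no tau; call compute_threshold first")
    if prefilter_mask is not None:
        if not prefilter_mask.index.equals(ratios.index):
            raise ValueError("prefilter mask is not aligned to the ratio vector")
        keep = prefilter_mask & (ratios > rule.tau)
    else:
        keep = ratios > rule.tau
    members = pd.DataFrame({"ratio": ratios[keep]})
    if sequences is not None:
        members.insert(0, "sequence", sequences.reindex(members.index))
    provenance = {
        "contrast": contrast.name if contrast is not None else None,
        "k": rule.k,
        "reference": rule.reference,
        "tau": rule.tau if np.isscalar(rule.tau) else "per_peptide",
        "study": study,
    }
    return PeptideSet(name=name, members=members, provenance=provenance)


def intersect_signatures(a: PeptideSet, b: PeptideSet) -> PeptideSet:
    """Peptides present in both signatures, carrying both studies' ratios.

    Commutative and associative on member ids. Raises if shared peptide ids
    map to different sequences (sets keyed on different libraries).
    """
    common = a.members.index.intersection(b.members.index)
    if (
        "sequence" in a.members.columns
        and "sequence" in b.members.columns
        and not a.members.loc[common, "sequence"].equals(
            b.members.loc[common, "sequence"]
        )
    ):
        raise ValueError("signatures are keyed on different libraries")

    def ratio_cols(s: PeptideSet) -> pd.DataFrame:
        cols = [c for c in s.members.columns if c.startswith("ratio")]
        out = s.members.loc[common, cols]
        study = s.provenance.get("study")
        if list(out.columns) == ["ratio"]:
            out = out.rename(
                columns={"ratio": f"ratio_study{study}" if study else f"ratio_{s.name}"}
            )
        return out

    members = pd.concat([ratio_cols(a), ratio_cols(b)], axis=1)
    # keep one ratio column per label if both parents carry the same study
    members = members.loc[:, ~members.columns.duplicated()]
    seqs = a.sequences()
    if seqs is not None:
        members.insert(0, "sequence", seqs.reindex(common))
    return PeptideSet(
        name=f"{a.name}&{b.name}",
        members=members,
        provenance={"parents": (a.name, b.name),
                    "parent_provenance": (a.provenance, b.provenance)},
    )


def flag_memberships(pset: PeptideSet, others: Mapping[str, PeptideSet]) -> PeptideSet:
    """Add boolean ``in_<name>`` columns marking overlap with other signatures."""
    members = pset.members.copy()
    for label, other in others.items():
        members[f"in_{label}"] = members.index.isin(other.members.index)
    return PeptideSet(pset.name, members, dict(pset.provenance))


# ---------------------------------------------------------------------------
# Differential binding (t-test + BH)
# ---------------------------------------------------------------------------

def differential_binding(
    m: IntensityMatrix,
    contrast: ContrastSpec,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-peptide two-sample t-test (log10, replicate-averaged) with BH FDR.

    Returns a table with columns t, p, q, significant (q <= alpha,
    inclusive, the standard step-up convention).
    """
    if m.scale != SCALE_LOG10:
        raise ValueError("differential binding runs on the log10 scale")
    case, control = contrast.groups(m.samples)
    if case.sum() < 2 or control.sum() < 2:
        raise ValueError(f"{contrast.name}: each group needs >= 2 mice")
    x = m.values.loc[:, case.to_numpy()].to_numpy()
    y = m.values.loc[:, control.to_numpy()].to_numpy()
    t, p = stats.ttest_ind(x, y, axis=1)
    p = np.nan_to_num(p, nan=1.0)  # zero-variance peptides carry no evidence
    _, q, _, _ = multipletests(p, method="fdr_bh")
    return pd.DataFrame(
        {"t": t, "p": p, "q": q, "significant": q <= alpha},
        index=m.values.index,
    )


# ---------------------------------------------------------------------------
# ELISA S-values
# ---------------------------------------------------------------------------

CLONE_POSITIVITY_OD = 0.1


def s_value(odd_od: float, even_od: float) -> float:
    """Antigen-well OD minus paired control-well OD; may be negative."""
    if odd_od < 0 or even_od < 0:
        raise ValueError("optical densities must be >= 0")
    return odd_od - even_od


def clone_positive(s: float, threshold: float = CLONE_POSITIVITY_OD) -> bool:
    """Clone screening rule: an S-value strictly above threshold counts positive."""
    return s > threshold
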