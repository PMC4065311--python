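"""Synthetic peptide libraries and multi-group array cohorts.

The generator emulates the statistical structure the downstream analysis
assumes: a random-sequence 20-mer library with an invariant C-terminal GSC
linker, multi-strain mouse cohorts sampled at 1.5 and 4 months with
triplicate technical replicates, log-normal multiplicative noise calibrated
to ~14% slide-to-slide CV with technical-replicate Pearson r > 0.80, and
spiked peptide subsets with elevated binding in designated groups
(diagnostic, behavior-linked, and attenuated presymptomatic/predictive
effects).

Intensities are built multiplicatively on the linear scale::

    I[p, slide] = 10 ** ( baseline[p] + log10 fold[p, group]
                          + mouse[p, m] + scale[slide] + scatter[p, slide] )

``baseline`` is a per-peptide affinity drawn once per library and shared by
every group and study — without it, binding-ratio statistics would be
degenerate. ``scale`` is a per-slide global brightness jitter (removed by
median normalization); ``scatter`` is the per-(peptide, slide) technical
noise whose linear CV is the slide-to-slide CV and which also sets the
technical-replicate Pearson correlation. Generation is a pure function of
(design, effects, noise): the seed lives in :class:`NoiseModel` and no
global random state is consulted.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .array_io import (
    AMINO_ACIDS,
    DEFAULT_LINKER,
    IntensityMatrix,
    PeptideLibrary,
    SampleRecord,
    samples_frame,
)

#: Variable-region alphabet: the 20 proteinogenic residues minus cysteine,
#: which is reserved for the attachment linker (none of the published array
#: sequences contains a C upstream of the GSC tail).
DEFAULT_VARIABLE_ALPHABET = "".join(c for c in AMINO_ACIDS if c != "C")

#: Age (months) past which MRL/lpr mice are considered symptomatic.
SYMPTOMATIC_AGE_MONTHS = 2.0

_LN10 = np.log(10.0)


def generate_library(
    n: int = 10_000,
    length: int = 20,
    linker: str = DEFAULT_LINKER,
    seed: int = 0,
    alphabet: str = DEFAULT_VARIABLE_ALPHABET,
) -> PeptideLibrary:
    """Random-sequence peptide library of ``n`` ``length``-mers ending in ``linker``."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if not alphabet:
        raise ValueError("variable-region alphabet is empty")
    var_len = length - len(linker)
    if var_len <= 0:
        raise ValueError("length must exceed the linker length")
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(101,)))
    letters = np.frombuffer(alphabet.encode(), dtype="S1")
    draws = rng.integers(0, len(letters), size=(n, var_len))
    width = len(str(n))
    # 1-based GenePix-style coordinates on 20x20 blocks
    records = []
    for i in range(n):
        seq = b"".join(letters[draws[i]]).decode() + linker
        block, rest = divmod(i, 400)
        row, col = divmod(rest, 20)
        records.append((f"pep_{i + 1:0{width}d}", seq, block + 1, row + 1, col + 1))
    return PeptideLibrary.from_records(records, linker=linker)


# ---------------------------------------------------------------------------
# Cohort design
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GroupSpec:
    strain: str
    age_months: float
    n_mice: int
    phenotype: str | None = None

    def __post_init__(self) -> None:
        if self.n_mice < 1:
            raise ValueError("n_mice must be >= 1")


@dataclass(frozen=True)
class CohortDesign:
    groups: tuple[GroupSpec, ...]
    replicates_per_mouse: int = 3
    study_label: int = 1

    def __post_init__(self) -> None:
        if self.replicates_per_mouse < 1:
            raise ValueError("need at least one technical replicate")


def study1_design() -> CohortDesign:
    """First study: three strains at 4 months, MRL/lpr split 3 high / 2 low floaters."""
    return CohortDesign(
        groups=(
            GroupSpec("MRL/lpr", 4.0, 3, "high_floater"),
            GroupSpec("MRL/lpr", 4.0, 2, "low_floater"),
            GroupSpec("MRL/mp", 4.0, 3),
            GroupSpec("C3H/HeJ", 4.0, 3),
        ),
        study_label=1,
    )


def study2_design() -> CohortDesign:
    """Second study: MRL/lpr and MRL/mp at 1.5 and 4 months (no new C3H/HeJ arm).

    The 1.5-month MRL/lpr carry their *future* 4-month floater phenotype
    (6 high / 3 low), which the behavior-prediction contrast relies on.
    """
    return CohortDesign(
        groups=(
            GroupSpec("MRL/lpr", 1.5, 6, "high_floater"),
            GroupSpec("MRL/lpr", 1.5, 3, "low_floater"),
            GroupSpec("MRL/lpr", 4.0, 6, "high_floater"),
            GroupSpec("MRL/lpr", 4.0, 3, "low_floater"),
            GroupSpec("MRL/mp", 1.5, 9),
            GroupSpec("MRL/mp", 4.0, 9),
        ),
        study_label=2,
    )


# ---------------------------------------------------------------------------
# Effect and noise models
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EffectModel:
    """Which peptides are spiked, how strongly, and in which groups.

    * ``diagnostic`` folds apply to symptomatic MRL/lpr samples
      (age > :data:`SYMPTOMATIC_AGE_MONTHS`).
    * ``behavior`` folds apply to high-floater MRL/lpr samples — at full
      strength once symptomatic, attenuated before then (the future
      high floaters), which is what makes behavior *prediction* possible.
    * ``predictive`` folds apply, attenuated, to presymptomatic lupus-prone
      samples: MRL/mp at any sampled age and MRL/lpr before symptom onset.

    ``attenuation`` scales the fold on the log scale (0.5 halves
    log10(fold)), modelling the lower presymptomatic autoantibody titers.
    The three sets may overlap. ``baseline_log10_sd`` is the per-peptide
    affinity spread; it determines where the mean + k*SD cutoffs fall on
    the binding-ratio scale (see docs/methods.md).
    """

    diagnostic: dict[str, float] = field(default_factory=dict)
    behavior: dict[str, float] = field(default_factory=dict)
    predictive: dict[str, float] = field(default_factory=dict)
    attenuation: float = 0.5
    baseline_log10_mean: float = 3.0
    baseline_log10_sd: float = 0.23

    def __post_init__(self) -> None:
        for role, folds in self.role_sets().items():
            bad = [p for p, f in folds.items() if f < 1.0]
            if bad:
                raise ValueError(f"{role} fold < 1 for {bad[:3]}")

    def role_sets(self) -> dict[str, dict[str, float]]:
        return {
            "diagnostic": self.diagnostic,
            "behavior": self.behavior,
            "predictive": self.predictive,
        }

    @classmethod
    def random(
        cls,
        library: PeptideLibrary,
        seed: int,
        n_diagnostic: int = 58,
        n_behavior: int = 39,
        n_predictive: int = 18,
        fold_median: float = 2.5,
        fold_log10_sd: float = 0.02,
        attenuation: float = 0.5,
        baseline_log10_sd: float = 0.23,
    ) -> "EffectModel":
        """Draw spiked sets independently (they may overlap) with log-normal folds.

        Default cardinalities mirror the published intersected signatures
        (58 diagnostic, 39 behavior-diagnostic, 18 predictive peptides).
        """
        rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(202,)))
        ids = library.ids.to_numpy()

        def draw(n: int) -> dict[str, float]:
            chosen = rng.choice(ids, size=n, replace=False)
            folds = fold_median * 10 ** rng.normal(0.0, fold_log10_sd, size=n)
            return dict(zip(chosen.tolist(), np.maximum(folds, 1.0).tolist()))

        return cls(
            diagnostic=draw(n_diagnostic),
            behavior=draw(n_behavior),
            predictive=draw(n_predictive),
            attenuation=attenuation,
            baseline_log10_sd=baseline_log10_sd,
        )

    def log_fold(self, peptide_index: pd.Index, sample: SampleRecord) -> np.ndarray:
        """Per-peptide log10 fold effect for one sample's group."""
        lf = pd.Series(0.0, index=peptide_index)
        symptomatic = (
            sample.strain == "MRL/lpr"
            and sample.age_months > SYMPTOMATIC_AGE_MONTHS
        )
        presymptomatic = sample.strain == "MRL/mp" or (
            sample.strain == "MRL/lpr" and not symptomatic
        )
        if symptomatic:
            for pid, fold in self.diagnostic.items():
                lf[pid] += np.log10(fold)
        if sample.phenotype == "high_floater":
            scale = 1.0 if symptomatic else self.attenuation
            for pid, fold in self.behavior.items():
                lf[pid] += scale * np.log10(fold)
        if presymptomatic:
            for pid, fold in self.predictive.items():
                lf[pid] += self.attenuation * np.log10(fold)
        return lf.to_numpy()


def spike_truth(effects: EffectModel) -> pd.DataFrame:
    """Exhaustive ground-truth table: one row per spiked (peptide, role)."""
    rows = [
        {"peptide_id": pid, "role": role, "fold": fold}
        for role, folds in effects.role_sets().items()
        for pid, fold in sorted(folds.items())
    ]
    return pd.DataFrame(rows, columns=["peptide_id", "role", "fold"])


@dataclass(frozen=True)
class NoiseModel:
    """Dispersion parameters of the multiplicative noise, plus the seed.

    ``slide_cv`` is the linear coefficient of variation of the
    per-(peptide, slide) technical scatter; 0.14 reproduces the quoted 14%
    slide-to-slide CV and, against a baseline affinity spread of ~0.23
    log10, yields technical-replicate Pearson correlations well above 0.80
    (the calibration is checked by the QC tests rather than re-derived
    here). ``slide_scale_log10_sd`` is a whole-slide brightness jitter that
    median normalization removes; ``mouse_log10_sd`` is biological
    mouse-to-mouse variation.
    """

    slide_cv: float = 0.14
    mouse_log10_sd: float = 0.05
    slide_scale_log10_sd: float = 0.10
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.slide_cv, self.mouse_log10_sd, self.slide_scale_log10_sd) < 0:
            raise ValueError("dispersion parameters must be >= 0")

    @property
    def scatter_log10_sd(self) -> float:
        """log10-scale sd of a log-normal with linear CV ``slide_cv``."""
        return float(np.sqrt(np.log1p(self.slide_cv**2)) / _LN10)

    def silent(self) -> "NoiseModel":
        """Copy with every dispersion parameter zeroed (degenerate noise)."""
        return replace(self, slide_cv=0.0, mouse_log10_sd=0.0, slide_scale_log10_sd=0.0)


# ---------------------------------------------------------------------------
# Cohort generation
# ---------------------------------------------------------------------------

def _design_samples(design: CohortDesign) -> list[SampleRecord]:
    records = []
    for g, group in enumerate(design.groups):
        tag = group.strain.replace("/", "").replace("MRL", "").lower() or "x"
        pheno = {"high_floater": "hf", "low_floater": "lf", None: ""}[group.phenotype]
        for m in range(group.n_mice):
            mouse = f"s{design.study_label}_{tag}{group.age_months:g}m{pheno}_{m + 1}"
            for r in range(1, design.replicates_per_mouse + 1):
                records.append(
                    SampleRecord(
                        sample_id=f"{mouse}_r{r}",
                        mouse_id=mouse,
                        strain=group.strain,
                        age_months=group.age_months,
                        replicate=r,
                        phenotype=group.phenotype,
                        study=design.study_label,
                    )
                )
    return records


def generate_cohort(
    library: PeptideLibrary,
    design: CohortDesign,
    effects: EffectModel,
    noise: NoiseModel,
) -> IntensityMatrix:
    """Simulate one study's raw intensity matrix, one column per (mouse, replicate).

    The per-peptide baseline is derived from ``noise.seed`` alone, so the
    two studies of a cohort share identical baselines when generated with
    the same :class:`NoiseModel` — as the two studies of the real
    experiment share one physical array library.
    """
    unknown = {
        pid
        for folds in effects.role_sets().values()
        for pid in folds
        if pid not in library.ids
    }
    if unknown:
        raise ValueError(f"effect peptides not in library: {sorted(unknown)[:5]}")

    records = _design_samples(design)
    n_pep = len(library)

    base_rng = np.random.default_rng(np.random.SeedSequence(noise.seed, spawn_key=(1,)))
    baseline = base_rng.normal(
        effects.baseline_log10_mean, effects.baseline_log10_sd, size=n_pep
    )
    study_rng = np.random.default_rng(
        np.random.SeedSequence(noise.seed, spawn_key=(2, design.study_label))
    )

    mice = sorted({r.mouse_id for r in records})
    mouse_dev = {
        m: study_rng.normal(0.0, noise.mouse_log10_sd, size=n_pep) for m in mice
    }
    scatter_sd = noise.scatter_log10_sd

    columns = {}
    for rec in records:
        log10_i = baseline + effects.log_fold(library.ids, rec)
        log10_i = log10_i + mouse_dev[rec.mouse_id]
        log10_i = log10_i + study_rng.normal(0.0, noise.slide_scale_log10_sd)
        if scatter_sd > 0:
            log10_i = log10_i + study_rng.normal(0.0, scatter_sd, size=n_pep)
        columns[rec.sample_id] = 10.0 ** log10_i

    values = pd.DataFrame(columns, index=library.ids)
    return IntensityMatrix(values, samples_frame(records), scale="raw")


def generate_two_study_cohort(
    library: PeptideLibrary,
    effects: EffectModel,
    noise: NoiseModel,
    designs: tuple[CohortDesign, CohortDesign] | None = None,
) -> IntensityMatrix:
    """Both studies, concatenated column-wise into one matrix."""
    from .array_io import concat_matrices

    if designs is None:
        designs = (study1_design(), study2_design())
    return concat_matrices(
        [generate_cohort(library, d, effects, noise) for d in designs]
    )


def generate_proteome(
    n_proteins: int = 100,
    length_range: tuple[int, int] = (80, 400),
    seed: int = 0,
):
    """Random amino-acid proteome (synthetic stand-in for a real release).

    Used for desk-scale target-mapping runs and null-calibration tests;
    compositions are uniform over the 20-letter alphabet, so it reproduces
    the alignment machinery's statistics but not real-proteome composition
    biases.
    """
    from .array_io import ProteinRecord

    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(303,)))
    letters = np.frombuffer(AMINO_ACIDS.encode(), dtype="S1")
    width = len(str(n_proteins))
    out = []
    for i in range(n_proteins):
        n = int(rng.integers(length_range[0], length_range[1] + 1))
        seq = b"".join(letters[rng.integers(0, len(letters), size=n)]).decode()
        out.append(ProteinRecord(f"prot_{i + 1:0{width}d}", "synthetic", seq))
    return out
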