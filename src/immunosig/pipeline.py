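"""End-to-end two-study workflow driven by a single declarative config.

The pipeline mirrors the sequencing of the analysis it reproduces:
simulate (or read) two array studies -> median normalize -> QC -> log10 ->
average technical replicates -> per-contrast binding-ratio selection with
mean + k*SD cutoffs -> cross-study intersections -> leave-one-out SVM
cross-validation on the selected signatures -> proteome target mapping with
permutation p-values.

Configs are plain nested dicts (YAML on disk). Every output table carries
the config hash in a comment header, outputs contain no timestamps, and all
randomness flows from the config seed, so the same config always produces
byte-identical artifacts.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import pandas as pd
import yaml

from . import array_io, classification, epitope_mapping, preprocess, synthetic_cohort
from .array_io import IntensityMatrix, PeptideLibrary
from .epitope_mapping import SubstitutionMatrix
from .signature_selection import (
    ContrastSpec,
    PeptideSet,
    SampleFilter,
    ThresholdRule,
    binding_ratio,
    compute_threshold,
    differential_binding,
    flag_memberships,
    intersect_signatures,
    prefilter_greater,
    select_signature,
)

logger = logging.getLogger("immunosig")
if not logger.handlers:  # library default: informative but quiet under pytest -q
    logging.basicConfig(level=logging.INFO, format="%(name)s %(levelname)s %(message)s")


def config_hash(config: Mapping[str, Any]) -> str:
    """Stable 12-hex-digit digest of a config dict."""
    canon = json.dumps(config, sort_keys=True, default=str)
    return hashlib.sha256(canon.encode()).hexdigest()[:12]


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def save_config(config: Mapping[str, Any], path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(dict(config), fh, sort_keys=True)


# ---------------------------------------------------------------------------
# Demo configuration: the packaged synthetic two-study cohort
# ---------------------------------------------------------------------------

_C3H_S1 = {"strain": "C3H/HeJ", "age_months": 4.0, "study": 1}


def demo_config(
    seed: int = 0,
    n_peptides: int = 10_000,
    zero_noise: bool = False,
    attenuation: float = 0.5,
    n_perm: int = 100,
) -> dict:
    """Synthetic two-study cohort mirroring the historical study layout.

    Study 1: three strains at 4 months (MRL/lpr split 3 high / 2 low
    floaters); Study 2: MRL/lpr and MRL/mp at 1.5 and 4 months with the
    4-month C3H/HeJ of Study 1 reused as the ratio denominator. Contrast
    cutoffs are k = 1.5 for the diagnostic and behavior contrasts, 0.25 for
    the late-onset-control predictive contrast, and 2.5 for behavior
    prediction. ``zero_noise`` switches every dispersion parameter off
    (truth-recovery runs); ``attenuation`` scales presymptomatic effects.
    """
    lpr4 = {"strain": "MRL/lpr", "age_months": 4.0}
    return {
        "seed": int(seed),
        "library": {"n": int(n_peptides), "length": 20, "linker": "GSC"},
        "effects": {
            "n_diagnostic": 58,
            "n_behavior": 39,
            "n_predictive": 18,
            "fold_median": 2.5,
            "fold_log10_sd": 0.0 if zero_noise else 0.02,
            "attenuation": attenuation,
            "baseline_log10_sd": 0.23,
        },
        "noise": (
            {"slide_cv": 0.0, "mouse_log10_sd": 0.0, "slide_scale_log10_sd": 0.0}
            if zero_noise
            else {"slide_cv": 0.14, "mouse_log10_sd": 0.05, "slide_scale_log10_sd": 0.10}
        ),
        "qc": {"mdfc_method": "pairwise"},
        "contrasts": [
            {
                "name": "diagnostic_study1",
                "case": {**lpr4, "study": 1},
                "control": _C3H_S1,
                "k": 1.5,
                "study": 1,
            },
            {
                "name": "diagnostic_study2",
                "case": {**lpr4, "study": 2},
                "control": _C3H_S1,
                "k": 1.5,
                "study": 2,
            },
            {
                "name": "behavior_study1",
                "case": {**lpr4, "phenotype": "high_floater", "study": 1},
                "control": _C3H_S1,
                "prefilter": [
                    {**lpr4, "phenotype": "high_floater", "study": 1},
                    {**lpr4, "phenotype": "low_floater", "study": 1},
                ],
                "k": 1.5,
                "study": 1,
            },
            {
                "name": "behavior_study2",
                "case": {**lpr4, "phenotype": "high_floater", "study": 2},
                "control": _C3H_S1,
                "prefilter": [
                    {**lpr4, "phenotype": "high_floater", "study": 2},
                    {**lpr4, "phenotype": "low_floater", "study": 2},
                ],
                "k": 1.5,
                "study": 2,
            },
            {
                "name": "predictive_study1",
                "case": {"strain": "MRL/mp", "age_months": 4.0, "study": 1},
                "control": _C3H_S1,
                "k": 0.25,
                "study": 1,
            },
            {
                "name": "predictive_study2",
                "case": {"strain": "MRL/lpr", "age_months": 1.5, "study": 2},
                "control": _C3H_S1,
                "k": 1.5,
                "study": 2,
            },
            {
                # at k = 2.5 the control-intensity cutoff sits above any
                # plausible presymptomatic fold; this most-conservative rule
                # is read on the ratio distribution instead (see methods)
                "name": "behavior_predictive",
                "case": {"strain": "MRL/lpr", "age_months": 1.5,
                         "phenotype": "high_floater", "study": 2},
                "control": _C3H_S1,
                "prefilter": [
                    {"strain": "MRL/lpr", "age_months": 1.5,
                     "phenotype": "high_floater", "study": 2},
                    {"strain": "MRL/lpr", "age_months": 1.5,
                     "phenotype": "low_floater", "study": 2},
                ],
                "k": 2.5,
                "reference": "ratio_distribution",
                "study": 2,
            },
        ],
        "intersections": [
            {"name": "diagnostic", "a": "diagnostic_study1", "b": "diagnostic_study2"},
            {"name": "behavior_diagnostic", "a": "behavior_study1", "b": "behavior_study2"},
            {"name": "predictive", "a": "predictive_study1", "b": "predictive_study2"},
        ],
        "final_sets": {
            "diagnostic": "diagnostic",
            "behavior_diagnostic": "behavior_diagnostic",
            "predictive": "predictive",
            "behavior_predictive": "behavior_predictive",
        },
        "difftests": ["diagnostic_study1", "diagnostic_study2"],
        "classification": [
            {"name": "lupus_study1", "features": "diagnostic",
             "case": {**lpr4, "study": 1}, "control": _C3H_S1, "mode": "asis"},
            {"name": "lupus_study2", "features": "diagnostic",
             "case": {**lpr4, "study": 2}, "control": _C3H_S1, "mode": "asis"},
            {"name": "behavior_study2", "features": "behavior_diagnostic",
             "case": {**lpr4, "phenotype": "high_floater", "study": 2},
             "control": {**lpr4, "phenotype": "low_floater", "study": 2},
             "mode": "asis"},
        ],
        "mapping": {
            "enabled": True,
            "feature_set": "diagnostic",
            "proteome": {"n_proteins": 40, "length_range": [80, 250]},
            "matrix": "blosum62",
            "n_perm": int(n_perm),
        },
    }


# ---------------------------------------------------------------------------
# Pipeline
# ---------------------------------------------------------------------------

@dataclass
class PipelineResult:
    config: dict
    config_hash: str
    library: PeptideLibrary
    effects: synthetic_cohort.EffectModel | None
    qc: preprocess.QCReport
    contrast_sets: dict[str, PeptideSet]
    sets: dict[str, PeptideSet]
    cv: dict[str, classification.CVResult]
    targets: pd.DataFrame | None
    out_dir: Path | None
    log_lines: list[str] = field(default_factory=list)

    def truth(self) -> pd.DataFrame | None:
        return synthetic_cohort.spike_truth(self.effects) if self.effects else None


def _contrast_from_cfg(cfg: Mapping[str, Any]) -> tuple[ContrastSpec, ThresholdRule]:
    prefilter = None
    if cfg.get("prefilter"):
        a, b = cfg["prefilter"]
        prefilter = (SampleFilter.from_dict(a), SampleFilter.from_dict(b))
    contrast = ContrastSpec(
        name=cfg["name"],
        case=SampleFilter.from_dict(cfg["case"]),
        control=SampleFilter.from_dict(cfg["control"]),
        prefilter=prefilter,
    )
    rule = ThresholdRule(
        k=float(cfg["k"]),
        reference=cfg.get("reference", "control_intensity_distribution"),
    )
    return contrast, rule


def _build_inputs(
    config: Mapping[str, Any]
) -> tuple[PeptideLibrary, IntensityMatrix, synthetic_cohort.EffectModel | None]:
    seed = int(config["seed"])
    if "input" in config and config["input"]:
        lib = array_io.read_library(config["input"]["library"])
        parts = [
            array_io.read_cohort_gpr(d, lib) for d in config["input"]["gpr_dirs"]
        ]
        return lib, array_io.concat_matrices(parts), None
    lib_cfg = config.get("library", {})
    library = synthetic_cohort.generate_library(
        n=lib_cfg.get("n", 10_000),
        length=lib_cfg.get("length", 20),
        linker=lib_cfg.get("linker", "GSC"),
        seed=seed,
    )
    effects = synthetic_cohort.EffectModel.random(
        library, seed=seed, **config.get("effects", {})
    )
    noise = synthetic_cohort.NoiseModel(seed=seed, **config.get("noise", {}))
    raw = synthetic_cohort.generate_two_study_cohort(library, effects, noise)
    return library, raw, effects


def run_pipeline(config: Mapping[str, Any], out_dir: str | Path | None = None) -> PipelineResult:
    """Execute every configured stage; returns results and (optionally) writes artifacts."""
    config = dict(config)
    chash = config_hash(config)
    log_lines: list[str] = [f"config_hash={chash}"]

    def log(stage: str, msg: str) -> None:
        line = f"[{stage}] {msg}"
        log_lines.append(line)
        logger.info(line)

    def stage_guard(stage: str):
        class _Guard:
            def __enter__(self):
                return None

            def __exit__(self, exc_type, exc, tb):
                if exc is not None:
                    raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
                return False

        return _Guard()

    with stage_guard("inputs"):
        library, raw, effects = _build_inputs(config)
        log("inputs", f"library={len(library)} peptides, {raw.n_samples} slides")

    with stage_guard("preprocess"):
        norm = preprocess.median_normalize(raw)
        qc = preprocess.qc_report(norm, **config.get("qc", {}))
        logm = preprocess.log10_transform(norm)
        avg_log = preprocess.average_technical_replicates(logm)
        avg_lin = preprocess.delog10(avg_log)
        log("preprocess",
            f"{avg_log.n_samples} mice; pearson_min={qc.replicate_pearson:.3f} "
            f"slide_cv={qc.slide_cv:.3f} mdfc95={qc.mdfc_95:.3f}")

    contrast_sets: dict[str, PeptideSet] = {}
    with stage_guard("select"):
        for cfg in config.get("contrasts", []):
            contrast, rule = _contrast_from_cfg(cfg)
            ratios = binding_ratio(avg_lin, contrast)
            rule = compute_threshold(avg_lin, contrast, ratios, rule)
            mask = None
            if contrast.prefilter is not None:
                mask = prefilter_greater(avg_lin, *contrast.prefilter)
            pset = select_signature(
                ratios,
                rule,
                prefilter_mask=mask,
                name=contrast.name,
                sequences=library.sequences,
                study=cfg.get("study"),
                contrast=contrast,
            )
            contrast_sets[contrast.name] = pset
            tau = rule.tau if pd.api.types.is_number(rule.tau) else float("nan")
            log("select", f"{contrast.name}: k={rule.k} tau={tau:.4f} "
                          f"selected={len(pset)}")

    sets: dict[str, PeptideSet] = {}
    with stage_guard("intersect"):
        for icfg in config.get("intersections", []):
            inter = intersect_signatures(
                contrast_sets[icfg["a"]], contrast_sets[icfg["b"]]
            )
            inter.name = icfg["name"]
            sets[icfg["name"]] = inter
            log("intersect", f"{icfg['name']}: |{icfg['a']}|={len(contrast_sets[icfg['a']])} "
                             f"& |{icfg['b']}|={len(contrast_sets[icfg['b']])} -> {len(inter)}")
        for label, source in config.get("final_sets", {}).items():
            if label not in sets:
                sets[label] = sets[source] if source in sets else contrast_sets[source]
                sets[label].name = label
        # cross-membership flags among the final sets
        for label in list(sets):
            others = {k: v for k, v in sets.items() if k != label}
            sets[label] = flag_memberships(sets[label], others)

    difftables: dict[str, pd.DataFrame] = {}
    with stage_guard("difftest"):
        for cname in config.get("difftests", []):
            cfg = next(c for c in config["contrasts"] if c["name"] == cname)
            contrast, _ = _contrast_from_cfg(cfg)
            table = differential_binding(avg_log, contrast)
            difftables[cname] = table
            log("difftest", f"{cname}: {int(table['significant'].sum())} significant "
                            f"at BH 5% of {len(table)}")

    cv_results: dict[str, classification.CVResult] = {}
    with stage_guard("crossval"):
        for ccfg in config.get("classification", []):
            feats = sets[ccfg["features"]]
            if len(feats) == 0:
                log("crossval", f"{ccfg['name']}: skipped (empty feature set)")
                continue
            case = SampleFilter.from_dict(ccfg["case"])
            control = SampleFilter.from_dict(ccfg["control"])
            mask = case.mask(avg_log.samples) | control.mask(avg_log.samples)
            sub = avg_log.subset_samples(mask)
            labels = pd.Series(
                ["case" if c else "control" for c in case.mask(sub.samples)],
                index=sub.samples.index,
            )
            res = classification.loocv(
                sub, labels, feats, seed=int(config["seed"]),
                mode=ccfg.get("mode", "asis"),
            )
            cv_results[ccfg["name"]] = res
            log("crossval", f"{ccfg['name']}: n={res.n_samples} errors={res.n_errors} "
                            f"error_rate={res.error_rate:.3f}")

    targets = None
    map_cfg = config.get("mapping") or {}
    if map_cfg.get("enabled"):
        with stage_guard("map-targets"):
            feats = sets[map_cfg["feature_set"]]
            if len(feats) == 0:
                log("map-targets", "skipped (empty feature set)")
            else:
                prot_cfg = map_cfg.get("proteome", {})
                if isinstance(prot_cfg, (str, Path)):
                    proteome = array_io.read_proteome(prot_cfg)
                else:
                    proteome = synthetic_cohort.generate_proteome(
                        n_proteins=prot_cfg.get("n_proteins", 40),
                        length_range=tuple(prot_cfg.get("length_range", (80, 250))),
                        seed=int(config["seed"]),
                    )
                matrix = (
                    SubstitutionMatrix.identity()
                    if map_cfg.get("matrix") == "identity"
                    else SubstitutionMatrix.blosum62()
                )
                scored = epitope_mapping.empirical_pvalues(
                    feats,
                    library,
                    proteome,
                    matrix=matrix,
                    n_perm=int(map_cfg.get("n_perm", 100)),
                    seed=int(config["seed"]),
                    trim_linker=library.linker if map_cfg.get("trim_linker", True) else None,
                )
                targets = epitope_mapping.protein_score_table(scored)
                log("map-targets", f"{len(proteome)} proteins scored against "
                                   f"{len(feats)} peptides; top={targets.iloc[0]['protein_id']}")

    result = PipelineResult(
        config=config,
        config_hash=chash,
        library=library,
        effects=effects,
        qc=qc,
        contrast_sets=contrast_sets,
        sets=sets,
        cv=cv_results,
        targets=targets,
        out_dir=Path(out_dir) if out_dir else None,
        log_lines=log_lines,
    )
    if out_dir is not None:
        _write_artifacts(result, difftables, Path(out_dir))
    return result


def _write_artifacts(
    result: PipelineResult, difftables: dict[str, pd.DataFrame], out_dir: Path
) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    stamp = f"config_hash={result.config_hash}"
    save_config(result.config, out_dir / "config.yaml")
    result.qc.to_tsv(out_dir / "qc.tsv", header_comment=stamp)
    sig_dir = out_dir / "signatures"
    sig_dir.mkdir(exist_ok=True)
    for name, pset in {**result.contrast_sets, **result.sets}.items():
        if len(pset):
            array_io.write_signature_table(pset, sig_dir / f"{name}.tsv",
                                           header_comment=stamp)
    for name, table in difftables.items():
        with open(out_dir / f"difftest_{name}.tsv", "w") as fh:
            fh.write(f"# {stamp}\n")
            table.to_csv(fh, sep="\t")
    for name, res in result.cv.items():
        res.to_tsv(out_dir / f"crossval_{name}.tsv", header_comment=stamp)
    if result.targets is not None:
        with open(out_dir / "targets.tsv", "w") as fh:
            fh.write(f"# {stamp}\n")
            result.targets.to_csv(fh, sep="\t", index=False)
    truth = result.truth()
    if truth is not None:
        with open(out_dir / "spike_truth.tsv", "w") as fh:
            fh.write(f"# {stamp}\n")
            truth.to_csv(fh, sep="\t", index=False)
    (out_dir / "log.txt").write_text("\n".join(result.log_lines) + "\n")


# ---------------------------------------------------------------------------
# Truth-recovery accounting for synthetic cohorts
# ---------------------------------------------------------------------------

#: Which spiked role each final signature is expected to recover.
ROLE_FOR_SET = {
    "diagnostic": "diagnostic",
    "behavior_diagnostic": "behavior",
    "predictive": "predictive",
    "behavior_predictive": "behavior",
}


def recovery_table(result: PipelineResult) -> pd.DataFrame:
    """Sensitivity / false-selection accounting of final sets vs spiked truth."""
    truth = result.truth()
    if truth is None:
        raise ValueError("recovery accounting needs a synthetic cohort")
    rows = []
    for set_name, role in ROLE_FOR_SET.items():
        if set_name not in result.sets:
            continue
        selected = set(result.sets[set_name].members.index)
        expected = set(truth.loc[truth["role"] == role, "peptide_id"])
        tp = len(selected & expected)
        rows.append(
            {
                "set": set_name,
                "role": role,
                "n_selected": len(selected),
                "n_expected": len(expected),
                "true_positives": tp,
                "sensitivity": tp / len(expected) if expected else float("nan"),
                "false_selections": len(selected - expected),
                "false_selection_rate": (
                    (len(selected) - tp) / len(selected) if selected else 0.0
                ),
            }
        )
    return pd.DataFrame(rows)
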