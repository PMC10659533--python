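"""End-to-end study orchestration.

``run_study`` executes the whole protocol from one config: generate (or
load) a cohort, compute outcomes, draw the balance-tested 80/20 split and
the stratified folds, fit the four models per fold, score the untouched
test set, run the fold-wise model comparison, and produce the occlusion
heatmap for the deep model.  Every artifact (cohort tables, NIfTI volumes,
fitted models, evaluation report, heatmaps, manifest with all seeds and
defaults) lands in the output directory.
"""

from __future__ import annotations

import dataclasses
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .errors import ConfigurationError, NeuroprogError
from .evaluation import (CohortSplit, EvaluationReport, FoldAssignment,
                         make_balanced_split, make_stratified_folds,
                         run_comparison, ModelSpec)
from .multitask_cnn import (ArchConfig, DeepDataset, LossWeights, MultiTaskCNN,
                            PROGRESSION_WEIGHTS, SLOPE_WEIGHTS, TrainingSchedule,
                            build_network, train_deep)
from .occlusion import (OcclusionConfig, average_heatmaps, heatmap_to_nifti,
                        occlusion_map)
from .outcomes import outcome_table
from .preprocessing import (NormalizationStats, crop_or_pad, fit_minmax,
                            fit_mri_range, minmax_unit, normalize_mri)
from .synthetic_cohort import (AtrophyBlock, GeneratorConfig, SubjectRecord,
                               VolumePair, generate_cohort, write_cohort)
from .tabular_models import (CLINICAL_FEATURES, DEFAULT_LEARNER, PREDICTOR_SETS,
                             assemble_features, fit_tabular, predict_tabular)

__all__ = ["RunConfig", "TabularSpec", "DeepSpec", "validate_config", "run_study"]

KNOWN_MODELS = ("clinical", "hippocampus", "freesurfer", "deep")


# ---------------------------------------------------------------------------
# Model specs
# ---------------------------------------------------------------------------

class TabularSpec(ModelSpec):
    """Comparable tabular model bound to a predictor set and task."""

    def __init__(self, predictor_set: str, task: str):
        self.name = predictor_set
        self.predictor_set = predictor_set
        self.task = "binary" if task == "progression" else "continuous"

    def fit(self, records, outcome, seed: int):
        X = assemble_features(records, self.predictor_set)
        return fit_tabular(X, outcome.to_numpy(dtype=float), task=self.task,
                           learner=DEFAULT_LEARNER[self.predictor_set],
                           seed=seed, predictor_set=self.predictor_set)

    def predict(self, fitted, records):
        return predict_tabular(fitted, assemble_features(records, self.predictor_set))


@dataclass
class DeepFitted:
    network: MultiTaskCNN
    clinical_stats: NormalizationStats
    mri_stats: NormalizationStats | None
    slope_range: tuple[float, float]
    hippo_range: tuple[float, float]
    history: pd.DataFrame


class DeepSpec(ModelSpec):
    """Comparable deep model: normalizes inputs on the training fold, trains
    the multi-task CNN, and scores with the requested head.

    Keeps the per-fold fitted models (``fitted_by_fold``) so the occlusion
    stage can reuse them.
    """

    name = "deep"

    def __init__(self, volumes: dict[str, VolumePair], outcomes: pd.DataFrame,
                 task: str, arch: ArchConfig, schedule: TrainingSchedule,
                 weights: LossWeights | None = None):
        self.volumes = volumes
        self.outcomes = outcomes
        self.task = task
        self.arch = arch
        self.schedule = schedule
        self.weights = weights or (PROGRESSION_WEIGHTS if task == "progression"
                                   else SLOPE_WEIGHTS)
        self.fitted_by_fold: list[DeepFitted] = []

    # -- dataset assembly ------------------------------------------------
    def _clinical_matrix(self, records) -> np.ndarray:
        X = assemble_features(records, "clinical")
        return X.to_numpy(dtype=float)

    def _image_stack(self, records, channel: str,
                     mri_stats: NormalizationStats | None) -> np.ndarray | None:
        use = getattr(self.arch, f"use_{channel}")
        if not use:
            return None
        grids = []
        target = self.arch.grid_shape
        for r in records:
            vol = getattr(self.volumes[r.subject_id], channel)
            v = np.asarray(vol, dtype=float)
            if any(s > t for s, t in zip(v.shape, target)):
                v = crop_or_pad(v, target, "crop")  # MRI-style harmonization
            elif any(s < t for s, t in zip(v.shape, target)):
                v = crop_or_pad(v, target, "pad")  # JD-style zero padding
            grids.append(v)
        stack = np.stack(grids)[:, None]
        if channel == "mri" and mri_stats is not None:
            stack = normalize_mri(mri_stats, stack)
        return stack

    def _targets(self, records, slope_range, hippo_range):
        ids = [r.subject_id for r in records]
        prog = self.outcomes.loc[ids, "progressed_4y"].to_numpy(dtype=float)
        slope = self.outcomes.loc[ids, "mmse_slope"].to_numpy(dtype=float)
        hippo = np.array([r.hippocampal_volume for r in records], dtype=float)
        slope_s = _scale_unit(slope, slope_range)
        hippo_s = _scale_unit(hippo, hippo_range)
        return prog, slope_s, hippo_s

    def make_dataset(self, records, fitted: "DeepFitted | None" = None,
                     clinical_stats=None, mri_stats=None,
                     slope_range=None, hippo_range=None) -> DeepDataset:
        if fitted is not None:
            clinical_stats = fitted.clinical_stats
            mri_stats = fitted.mri_stats
            slope_range = fitted.slope_range
            hippo_range = fitted.hippo_range
        clin = minmax_unit(clinical_stats, self._clinical_matrix(records))
        prog, slope_s, hippo_s = self._targets(records, slope_range, hippo_range)
        return DeepDataset(
            clinical=clin, y_progression=prog, y_slope=slope_s,
            y_hippocampus=hippo_s,
            mri=self._image_stack(records, "mri", mri_stats),
            jd=self._image_stack(records, "jd", None),
            subject_ids=[r.subject_id for r in records],
        )

    # -- ModelSpec interface ---------------------------------------------
    def fit(self, records, outcome, seed: int):
        clin_stats = fit_minmax(self._clinical_matrix(records),
                                list(CLINICAL_FEATURES), fitted_on="train-fold")
        mri_stats = None
        if self.arch.use_mri:
            mri_stats = fit_mri_range(
                (np.asarray(self.volumes[r.subject_id].mri) for r in records),
                fitted_on="train-fold")
        ids = [r.subject_id for r in records]
        slope = self.outcomes.loc[ids, "mmse_slope"].to_numpy(dtype=float)
        hippo = np.array([r.hippocampal_volume for r in records])
        slope_range = _finite_range(slope)
        hippo_range = _finite_range(hippo)

        data = self.make_dataset(records, clinical_stats=clin_stats,
                                 mri_stats=mri_stats, slope_range=slope_range,
                                 hippo_range=hippo_range)
        net = build_network(dataclasses.replace(self.arch, seed=seed))
        history = train_deep(net, data, schedule=self.schedule,
                             weights=self.weights, seed=seed)
        fitted = DeepFitted(network=net, clinical_stats=clin_stats,
                            mri_stats=mri_stats, slope_range=slope_range,
                            hippo_range=hippo_range, history=history)
        self.fitted_by_fold.append(fitted)
        return fitted

    def predict(self, fitted: DeepFitted, records):
        out = fitted.network.predict(self.make_dataset(records, fitted=fitted))
        if self.task == "progression":
            return out.p_progression
        lo, hi = fitted.slope_range
        return out.mmse_slope_hat * (hi - lo) + lo


def _finite_range(x: np.ndarray) -> tuple[float, float]:
    v = x[np.isfinite(x)]
    lo, hi = float(v.min()), float(v.max())
    if hi <= lo:
        hi = lo + 1.0
    return lo, hi


def _scale_unit(x: np.ndarray, rng: tuple[float, float]) -> np.ndarray:
    lo, hi = rng
    return (x - lo) / (hi - lo)


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """One-file description of a study run; defaults give the desk-scale
    reproduction (n=332, 32-cubed grids, 10 folds, alpha 0.05, B=2000)."""

    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    models: tuple[str, ...] = ("clinical", "hippocampus", "freesurfer", "deep")
    tasks: tuple[str, ...] = ("progression", "slope")
    test_frac: float = 0.2
    split_alpha: float = 0.05
    split_max_attempts: int = 10_000
    split_seed: int = 101
    k_folds: int = 10
    fold_seed: int = 202
    eval_seed: int = 303
    eval_alpha: float = 0.05
    bootstrap_B: int = 2000
    # deep-model settings (epoch count is desk-scale; 50 is the full recipe)
    deep_epochs: int = 12
    deep_batch_size: int = 32
    deep_lr0: float = 1e-3
    deep_lr_decay: float = 0.97
    deep_use_mri: bool = True
    deep_use_jd: bool = True
    deep_w1: float = 1.0
    deep_w2: float = 0.025
    deep_w3: float = 0.025
    occlusion_block: int = 4
    occlusion_channel: str = "both"
    occlusion_per_class: int = 5
    out_dir: str = "study_out"
    on_existing: str = "refuse"  # "refuse" | "overwrite"
    write_volumes: bool = False

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        gen_raw = dict(raw.pop("generator", {}))
        for key in ("grid_shape", "visit_times_years"):
            if key in gen_raw:
                gen_raw[key] = tuple(gen_raw[key])
        if "atrophy_region_spec" in gen_raw:
            gen_raw["atrophy_region_spec"] = tuple(
                AtrophyBlock(center=tuple(b["center"]), radius=tuple(b["radius"]),
                             coefficient=float(b["coefficient"]))
                for b in gen_raw["atrophy_region_spec"])
        for key in ("models", "tasks"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(generator=GeneratorConfig(**gen_raw), **raw)


def validate_config(config: RunConfig) -> list[str]:
    """Return a list of problems; empty iff the config can run."""
    problems = []
    try:
        config.generator.validate()
    except ConfigurationError as exc:
        problems.append(f"generator: {exc}")
    for m in config.models:
        if m not in KNOWN_MODELS:
            problems.append(f"models: unknown model {m!r} (known: {KNOWN_MODELS})")
    for t in config.tasks:
        if t not in ("progression", "slope"):
            problems.append(f"tasks: unknown task {t!r}")
    if not 0.0 < config.test_frac < 1.0:
        problems.append("test_frac: must lie strictly in (0, 1)")
    if not 0.0 < config.split_alpha <= 1.0:
        problems.append("split_alpha: must lie in (0, 1]")
    if config.k_folds < 2:
        problems.append("k_folds: must be >= 2")
    for w in ("deep_w1", "deep_w2", "deep_w3"):
        if getattr(config, w) < 0:
            problems.append(f"{w}: loss weight must be non-negative")
    if config.deep_epochs < 0:
        problems.append("deep_epochs: must be >= 0")
    if config.bootstrap_B < 1:
        problems.append("bootstrap_B: must be >= 1")
    if config.on_existing not in ("refuse", "overwrite"):
        problems.append("on_existing: must be 'refuse' or 'overwrite'")
    return problems


# ---------------------------------------------------------------------------
# Study driver
# ---------------------------------------------------------------------------

def run_study(config: RunConfig) -> dict[str, EvaluationReport]:
    """Execute the full protocol; returns one report per task.

    Artifacts (cohort tables, outcome CSV, reports, heatmap, manifest) are
    written under ``config.out_dir``.  A failing stage aborts with the
    stage name; partial artifacts stay on disk.
    """
    problems = validate_config(config)
    if problems:
        raise ConfigurationError("invalid run config: " + "; ".join(problems))
    out = Path(config.out_dir)
    if (out / "manifest.json").exists():
        if config.on_existing == "refuse":
            raise ConfigurationError(
                f"output directory {out} already holds a run "
                "(set on_existing='overwrite' to replace it)")
    out.mkdir(parents=True, exist_ok=True)

    manifest: dict = {
        "package_version": __version__,
        "library_versions": _library_versions(),
        "config": _config_dict(config),
        "stages": {},
    }
    reports: dict[str, EvaluationReport] = {}
    need_volumes = "deep" in config.models

    def stage(name):
        def deco(fn):
            t0 = time.perf_counter()
            try:
                result = fn()
            except Exception as exc:
                manifest["stages"][name] = {"status": "failed", "error": str(exc)}
                _write_manifest(out, manifest)
                raise NeuroprogError(f"stage '{name}' failed: {exc}") from exc
            manifest["stages"][name] = {
                "status": "ok", "seconds": round(time.perf_counter() - t0, 3)}
            return result
        return deco

    records = volumes = None

    def _generate():
        nonlocal records, volumes
        records, volumes = generate_cohort(config.generator, with_volumes=need_volumes)
        write_cohort(records, out / "cohort",
                     volumes=volumes if config.write_volumes else None)
    stage("generate")(_generate)

    outcomes = stage("outcomes")(lambda: outcome_table(records))
    outcomes.to_csv(out / "outcomes.csv")

    split = stage("split")(lambda: make_balanced_split(
        records, test_frac=config.test_frac, alpha=config.split_alpha,
        max_attempts=config.split_max_attempts, seed=config.split_seed))
    (out / "split.json").write_text(json.dumps({
        "development_ids": split.development_ids, "test_ids": split.test_ids,
        "balance_pvalues": split.balance_pvalues, "attempts": split.attempts}, indent=1))

    dev_labels = outcomes.loc[split.development_ids, "progressed_4y"].astype(int)
    folds = stage("folds")(lambda: make_stratified_folds(
        split.development_ids, dev_labels.to_numpy(), k=config.k_folds,
        seed=config.fold_seed))

    deep_specs: dict[str, DeepSpec] = {}

    def _evaluate():
        for task in config.tasks:
            specs = []
            for m in config.models:
                if m == "deep":
                    arch = ArchConfig(
                        grid_shape=config.generator.grid_shape,
                        n_clinical=len(CLINICAL_FEATURES),
                        use_mri=config.deep_use_mri, use_jd=config.deep_use_jd)
                    schedule = TrainingSchedule(
                        epochs=config.deep_epochs, batch_size=config.deep_batch_size,
                        lr0=config.deep_lr0, lr_decay=config.deep_lr_decay)
                    weights = (LossWeights(config.deep_w1, config.deep_w2, config.deep_w3)
                               if task == "progression"
                               else LossWeights(config.deep_w3, 1.0, config.deep_w3))
                    spec = DeepSpec(volumes, outcomes, task, arch, schedule, weights)
                    deep_specs[task] = spec
                    specs.append(spec)
                else:
                    specs.append(TabularSpec(m, task))
            outcome = (outcomes["progressed_4y"].astype(float)
                       if task == "progression" else outcomes["mmse_slope"])
            report = run_comparison(records, outcome, specs, task, split, folds,
                                    B=config.bootstrap_B, seed=config.eval_seed,
                                    alpha=config.eval_alpha)
            reports[task] = report
            (out / f"report_{task}.json").write_text(json.dumps(report.to_dict(), indent=1))
            report.fold_metrics.to_csv(out / f"fold_metrics_{task}.csv")
            report.summary.to_csv(out / f"summary_{task}.csv")
            report.pairwise.to_csv(out / f"pairwise_{task}.csv", index=False)
    stage("evaluate")(_evaluate)

    if "deep" in config.models and "progression" in config.tasks:
        def _occlusion():
            spec = deep_specs["progression"]
            by_id = {r.subject_id: r for r in records}
            test = [by_id[s] for s in split.test_ids]
            ad = [r for r in test if r.group == "early-AD"][:config.occlusion_per_class]
            non = [r for r in test if r.group == "non-AD"][:config.occlusion_per_class]
            b = config.occlusion_block
            occ_cfg = OcclusionConfig(block_size=(b, b, b),
                                      channel=config.occlusion_channel)
            maps = []
            for fold_id, fitted in enumerate(spec.fitted_by_fold, start=1):
                for r in ad + non:
                    data = spec.make_dataset([r], fitted=fitted)
                    maps.append(occlusion_map(fitted.network, data, occ_cfg,
                                              fold_id=fold_id))
            mean_map = average_heatmaps(maps)
            heatmap_to_nifti(mean_map, config.generator.voxel_size_mm,
                             out / "occlusion_heatmap.nii.gz")
            return mean_map
        stage("occlusion")(_occlusion)

    _write_manifest(out, manifest)
    return reports


def _config_dict(config: RunConfig) -> dict:
    d = dataclasses.asdict(config)
    d["generator"]["atrophy_region_spec"] = [
        dataclasses.asdict(b) for b in config.generator.atrophy_region_spec]
    d["generator"]["effect_sizes"] = dict(config.generator.effect_sizes)
    return d


def _library_versions() -> dict[str, str]:
    import nibabel
    import scipy
    import sklearn
    return {"numpy": np.__version__, "scipy": scipy.__version__,
            "pandas": pd.__version__, "scikit-learn": sklearn.__version__,
            "nibabel": nibabel.__version__}


def _write_manifest(out: Path, manifest: dict) -> None:
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, default=str))
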