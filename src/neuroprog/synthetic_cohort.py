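"""Synthetic memory-clinic cohort generator.

Emulates the statistical structure of a prospective SCD/MCI cohort followed
for four years: two latent groups (``non-AD`` — cognitively stable, and
``early-AD`` — progressing to AD dementia), a latent disease-severity
variable in [0, 1] that drives hippocampal/regional atrophy and the rate of
MMSE decline, and per-subject co-registered image pairs (a smooth T1-like
intensity phantom and a Jacobian-determinant map in which atrophic blocks
have values below 1).

Group-level calibration defaults (means and SDs of age, education, MMSE,
ADAS delayed recall, APOE e4 allele count, hippocampal and intracranial
volume, and the MCI/female fractions) reproduce the published demographics
of a 332-subject Swedish memory-clinic sample; see ``docs/methods.md`` for
the table and the coupling model.

Everything is deterministic given ``GeneratorConfig.seed``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import nibabel as nib
import numpy as np
import pandas as pd

from .errors import ConfigurationError, DataError, GenerationError

__all__ = [
    "GeneratorConfig",
    "SubjectRecord",
    "Visit",
    "VolumePair",
    "AtrophyBlock",
    "REGION_NAMES",
    "DEFAULT_ATROPHY_BLOCKS",
    "ATROPHY_COUPLED_REGIONS",
    "CALIBRATION",
    "null_effect_sizes",
    "generate_cohort",
    "render_brain_volume",
    "subject_rng",
    "write_cohort",
    "read_cohort",
]

# Desikan-Killiany cortical parcellation: 34 regions per hemisphere.
_DK34 = [
    "bankssts", "caudalanteriorcingulate", "caudalmiddlefrontal", "cuneus",
    "entorhinal", "fusiform", "inferiorparietal", "inferiortemporal",
    "isthmuscingulate", "lateraloccipital", "lateralorbitofrontal", "lingual",
    "medialorbitofrontal", "middletemporal", "parahippocampal", "paracentral",
    "parsopercularis", "parsorbitalis", "parstriangularis", "pericalcarine",
    "postcentral", "posteriorcingulate", "precentral", "precuneus",
    "rostralanteriorcingulate", "rostralmiddlefrontal", "superiorfrontal",
    "superiorparietal", "superiortemporal", "supramarginal", "frontalpole",
    "temporalpole", "transversetemporal", "insula",
]
REGION_NAMES: tuple[str, ...] = tuple(
    f"{hemi}_{r}" for hemi in ("lh", "rh") for r in _DK34
)

# Approximate gray-matter volumes (mm^3) per DK region, one hemisphere.
_REGION_BASE_MM3 = {
    "bankssts": 2500, "caudalanteriorcingulate": 1900, "caudalmiddlefrontal": 6300,
    "cuneus": 2900, "entorhinal": 1800, "fusiform": 9200, "inferiorparietal": 12500,
    "inferiortemporal": 10300, "isthmuscingulate": 2600, "lateraloccipital": 11200,
    "lateralorbitofrontal": 7500, "lingual": 6200, "medialorbitofrontal": 5100,
    "middletemporal": 10500, "parahippocampal": 2100, "paracentral": 3500,
    "parsopercularis": 4400, "parsorbitalis": 2300, "parstriangularis": 3800,
    "pericalcarine": 2100, "postcentral": 9600, "posteriorcingulate": 3100,
    "precentral": 12800, "precuneus": 9800, "rostralanteriorcingulate": 2400,
    "rostralmiddlefrontal": 9500, "superiorfrontal": 21000, "superiorparietal": 12100,
    "superiortemporal": 11200, "supramarginal": 9800, "frontalpole": 1200,
    "temporalpole": 2400, "transversetemporal": 1100, "insula": 6600,
}

# AD-signature regions whose volumes are coupled to latent severity by default.
ATROPHY_COUPLED_REGIONS = tuple(
    f"{hemi}_{r}" for hemi in ("lh", "rh")
    for r in ("entorhinal", "parahippocampal", "middletemporal", "inferiortemporal",
              "fusiform", "inferiorparietal", "precuneus", "temporalpole")
)

# Calibration table: feature -> (non-AD mean, non-AD SD, early-AD mean, early-AD SD).
CALIBRATION = {
    "age": (70.2, 5.4, 71.8, 4.8),
    "education": (12.0, 3.6, 11.8, 3.6),
    "mmse_baseline": (28.2, 1.7, 27.2, 1.7),
    "adas_delayed_recall": (4.1, 2.4, 6.5, 2.0),
    "hippocampal_volume": (3327.1, 489.6, 2972.6, 400.8),
    "intracranial_volume": (1139.0, 158.0, 1116.0, 111.0),
}
# Categorical calibration: (non-AD, early-AD) probabilities.
_P_FEMALE = (0.458, 0.489)
_P_MCI = (0.419, 0.693)
# APOE e4 allele-count distributions matched to mean/SD 0.4±0.6 and 1.0±0.7.
_P_APOE = (np.array([0.65, 0.30, 0.05]), np.array([0.27, 0.46, 0.27]))

# Latent severity: Beta(2,5) for non-AD, Beta(5,2) for early-AD.
_SEV_PARAMS = {"non-AD": (2.0, 5.0), "early-AD": (5.0, 2.0)}
SEVERITY_MEAN = {"non-AD": 2.0 / 7.0, "early-AD": 5.0 / 7.0}
_SEV_VAR = 10.0 / (49.0 * 8.0)  # identical for Beta(2,5) and Beta(5,2)

CONTINUOUS_EFFECT_FEATURES = tuple(CALIBRATION)
CATEGORICAL_EFFECT_FEATURES = ("sex", "diagnosis", "apoe_e4", "regional_volumes")


def null_effect_sizes() -> dict[str, float]:
    """Effect-size map that removes every group separation (null configuration)."""
    return {f: 0.0 for f in CONTINUOUS_EFFECT_FEATURES + CATEGORICAL_EFFECT_FEATURES}


@dataclass(frozen=True)
class AtrophyBlock:
    """Axis-aligned block in fractional grid coordinates.

    ``center`` and ``radius`` are per-axis fractions of the grid extent;
    ``coefficient`` is the fractional local volume loss inside the block at
    severity 1 (Jacobian determinant ``1 - severity * coefficient``).
    """

    center: tuple[float, float, float]
    radius: tuple[float, float, float]
    coefficient: float

    def voxel_slices(self, shape: Sequence[int]) -> tuple[slice, ...]:
        slices = []
        for c, r, n in zip(self.center, self.radius, shape):
            lo = int(round((c - r) * n))
            hi = int(round((c + r) * n))
            if lo < 0 or hi > n or hi <= lo:
                raise GenerationError(
                    f"atrophy block center={self.center} radius={self.radius} "
                    f"extends outside the {tuple(shape)} grid"
                )
            slices.append(slice(lo, hi))
        return tuple(slices)


# Bilateral medial-temporal blocks: the default atrophy focus.
DEFAULT_ATROPHY_BLOCKS = (
    AtrophyBlock(center=(0.34, 0.42, 0.38), radius=(0.09, 0.09, 0.09), coefficient=0.35),
    AtrophyBlock(center=(0.66, 0.42, 0.38), radius=(0.09, 0.09, 0.09), coefficient=0.35),
)


@dataclass(frozen=True)
class GeneratorConfig:
    """Parameters of the synthetic cohort.

    Defaults state the cohort the downstream analysis assumes: 332 subjects
    of whom 32.8% progress to AD dementia within four years, visits at 0/2/4
    years, 32-cubed image grids, and group separations from the calibration
    table.
    """

    n_subjects: int = 332
    frac_early_ad: float = 109.0 / 332.0
    grid_shape: tuple[int, int, int] = (32, 32, 32)
    voxel_size_mm: float = 4.0
    visit_times_years: tuple[float, ...] = (0.0, 2.0, 4.0)
    #: Continuous features: group separation in pooled-SD units (negative =
    #: early-AD lower).  Categorical features ("sex", "diagnosis", "apoe_e4")
    #: and "regional_volumes": multiplier on the default group difference.
    effect_sizes: Mapping[str, float] = field(default_factory=dict)
    atrophy_region_spec: tuple[AtrophyBlock, ...] = DEFAULT_ATROPHY_BLOCKS
    noise_sd_mmse: float = 1.0
    seed: int = 0
    # -- secondary knobs -------------------------------------------------
    noise_sd_image: float = 0.02
    noise_sd_jd: float = 0.01
    visit_jitter_sd_years: float = 0.0
    #: MMSE decline rate at severity 1, in points/year (slope = -scale * severity).
    mmse_slope_scale: float = 1.5
    #: Fractional volume loss of severity-coupled DK regions at severity 1.
    regional_atrophy_frac: float = 0.15
    #: Round visit MMSE to integers (the scale is integer-valued); disable for
    #: exact slope-recovery oracles.
    round_mmse: bool = True

    def validate(self) -> None:
        if self.n_subjects < 20:
            raise ConfigurationError(f"n_subjects must be >= 20, got {self.n_subjects}")
        if not 0.0 < self.frac_early_ad < 1.0:
            raise ConfigurationError(
                f"frac_early_ad must lie strictly in (0, 1), got {self.frac_early_ad}"
            )
        if len(self.grid_shape) != 3 or any(int(n) < 8 for n in self.grid_shape):
            raise ConfigurationError(
                f"grid_shape must have three axes of >= 8 voxels, got {self.grid_shape}"
            )
        if self.voxel_size_mm <= 0:
            raise ConfigurationError("voxel_size_mm must be positive")
        t = np.asarray(self.visit_times_years, dtype=float)
        if t.size == 0 or np.any(t < 0) or (t.size > 1 and np.any(np.diff(t) <= 0)):
            raise ConfigurationError("visit_times_years must be ascending and non-negative")
        if t.max() - t.min() < 4.0:
            raise ConfigurationError(
                "visit_times_years must span >= 4 years so the 4-year "
                "progression outcome can be labeled"
            )
        if self.noise_sd_mmse < 0:
            raise ConfigurationError("noise_sd_mmse must be non-negative")


@dataclass(frozen=True)
class Visit:
    time_years: float
    mmse: float
    ad_dementia_flag: bool


@dataclass
class SubjectRecord:
    subject_id: str
    group: str  # "non-AD" | "early-AD"
    severity: float  # latent, retained for test oracles
    diagnosis: str  # "SCD" | "MCI"
    age: float
    sex: str  # "F" | "M"
    education: float
    mmse_baseline: int
    adas_delayed_recall: float
    apoe_e4_count: int
    hippocampal_volume: float
    intracranial_volume: float
    regional_volumes: dict[str, float]
    visits: list[Visit]
    #: Pre-rounding MMSE slope (points/year) driving the trajectory; latent.
    true_mmse_slope: float = 0.0


@dataclass
class VolumePair:
    """Co-registered T1-like intensity grid and Jacobian-determinant grid."""

    mri: np.ndarray
    jd: np.ndarray
    voxel_size_mm: float
    orientation_tag: str = "RAS"


def _pooled_sd(s0: float, s1: float) -> float:
    return float(np.sqrt((s0 * s0 + s1 * s1) / 2.0))


def _continuous_params(config: GeneratorConfig, feature: str):
    """(non-AD mean, effective early-AD mean, (sd0, sd1), pooled sd)."""
    m0, s0, m1, s1 = CALIBRATION[feature]
    sp = _pooled_sd(s0, s1)
    es = config.effect_sizes.get(feature, (m1 - m0) / sp)
    return m0, m0 + es * sp, (s0, s1), sp


def _group_ms(config: GeneratorConfig, feature: str, gi: int) -> tuple[float, float]:
    m0, m1, sds, _ = _continuous_params(config, feature)
    return (m0, sds[0]) if gi == 0 else (m1, sds[1])


def _interp_prob(p0, p1, scale):
    return np.clip(np.asarray(p0) + scale * (np.asarray(p1) - np.asarray(p0)), 0.0, 1.0)


def _draw_trunc(rng: np.random.Generator, mean: float, sd: float,
                lo: float, hi: float) -> float:
    for _ in range(1000):
        x = rng.normal(mean, sd)
        if lo <= x <= hi:
            return float(x)
    return float(np.clip(mean, lo, hi))


def subject_rng(config: GeneratorConfig, subject_index: int) -> np.random.Generator:
    """Per-subject generator for image rendering, independent of draw order."""
    return np.random.default_rng([config.seed, 7919, subject_index])


def generate_cohort(
    config: GeneratorConfig, with_volumes: bool = True
) -> tuple[list[SubjectRecord], dict[str, VolumePair]]:
    """Draw a full cohort: subject records plus (optionally) image pairs.

    Exactly ``round(n_subjects * frac_early_ad)`` subjects belong to the
    early-AD group.  Identical configs (including seed) yield identical
    cohorts; different seeds yield different cohorts.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    n_ad = int(round(config.n_subjects * config.frac_early_ad))
    groups = ["non-AD"] * (config.n_subjects - n_ad) + ["early-AD"] * n_ad

    # Hippocampal volume is a linear function of latent severity across the
    # whole cohort, with slope chosen so group means land on the calibration
    # targets and residual noise topping within-group SD up to the target.
    sev_gap = SEVERITY_MEAN["early-AD"] - SEVERITY_MEAN["non-AD"]
    m0_hv, m1_hv, _, sp_hv = _continuous_params(config, "hippocampal_volume")
    hv_slope = (m1_hv - m0_hv) / sev_gap
    hv_intercept = m0_hv - hv_slope * SEVERITY_MEAN["non-AD"]
    hv_noise = float(np.sqrt(max(sp_hv**2 - hv_slope**2 * _SEV_VAR, 0.0)))

    s_sex = config.effect_sizes.get("sex", 1.0)
    s_dx = config.effect_sizes.get("diagnosis", 1.0)
    s_apoe = config.effect_sizes.get("apoe_e4", 1.0)
    s_reg = config.effect_sizes.get("regional_volumes", 1.0)
    reg_frac = config.regional_atrophy_frac * s_reg

    records: list[SubjectRecord] = []
    volumes: dict[str, VolumePair] = {}
    for i, group in enumerate(groups):
        gi = 0 if group == "non-AD" else 1
        a, b = _SEV_PARAMS[group]
        severity = float(rng.beta(a, b))

        age = _draw_trunc(rng, *_group_ms(config, "age", gi), lo=60.0, hi=80.0)
        education = max(0.0, float(rng.normal(*_group_ms(config, "education", gi))))
        mmse_raw = float(rng.normal(*_group_ms(config, "mmse_baseline", gi)))
        mmse_baseline = int(np.clip(round(mmse_raw), 24, 30))
        adas = max(0.0, float(rng.normal(*_group_ms(config, "adas_delayed_recall", gi))))
        icv = float(rng.normal(*_group_ms(config, "intracranial_volume", gi)))
        hv = max(100.0, hv_intercept + hv_slope * severity + rng.normal(0.0, hv_noise))

        sex = "F" if rng.random() < float(_interp_prob(_P_FEMALE[0], _P_FEMALE[1], s_sex if gi else 0.0)) else "M"
        diagnosis = "MCI" if rng.random() < float(_interp_prob(_P_MCI[0], _P_MCI[1], s_dx if gi else 0.0)) else "SCD"
        p_apoe = _interp_prob(_P_APOE[0], _P_APOE[1], s_apoe if gi else 0.0)
        p_apoe = p_apoe / p_apoe.sum()
        apoe = int(rng.choice(3, p=p_apoe))

        regional = {}
        for name in REGION_NAMES:
            base = float(_REGION_BASE_MM3[name.split("_", 1)[1]])
            mean = base * (1.0 - reg_frac * severity) if name in ATROPHY_COUPLED_REGIONS else base
            regional[name] = max(10.0, float(rng.normal(mean, 0.08 * base)))

        slope = -config.mmse_slope_scale * severity
        visits = _make_visits(config, rng, group, severity, mmse_baseline, slope)

        rec = SubjectRecord(
            subject_id=f"sub-{i:04d}", group=group, severity=severity,
            diagnosis=diagnosis, age=age, sex=sex, education=education,
            mmse_baseline=mmse_baseline, adas_delayed_recall=adas,
            apoe_e4_count=apoe, hippocampal_volume=hv, intracranial_volume=icv,
            regional_volumes=regional, visits=visits, true_mmse_slope=slope,
        )
        records.append(rec)
        if with_volumes:
            volumes[rec.subject_id] = render_brain_volume(rec, config, subject_rng(config, i))
    return records, volumes


def _make_visits(config, rng, group, severity, mmse_baseline, slope) -> list[Visit]:
    times = np.asarray(config.visit_times_years, dtype=float).copy()
    if config.visit_jitter_sd_years > 0:
        times[1:] += rng.normal(0.0, config.visit_jitter_sd_years, size=times.size - 1)
        times[1:] = np.maximum.accumulate(np.maximum(times[1:], 1e-3))
    # AD-dementia onset: earlier for higher severity, always within 4 years.
    onset = 0.5 + 3.5 * (1.0 - severity) if group == "early-AD" else np.inf

    visits = []
    for t in times:
        y = mmse_baseline + slope * t
        if t > 0 and config.noise_sd_mmse > 0:
            y += rng.normal(0.0, config.noise_sd_mmse)
        y = float(np.clip(round(y) if config.round_mmse else y, 0.0, 30.0))
        visits.append(Visit(float(t), y, bool(t >= onset)))
    if group == "early-AD" and not any(v.ad_dementia_flag and v.time_years <= 4.0 for v in visits):
        idx = max(j for j, v in enumerate(visits) if v.time_years <= 4.0)
        visits[idx] = Visit(visits[idx].time_years, visits[idx].mmse, True)
    return visits


def _template(shape: Sequence[int]) -> np.ndarray:
    """Smooth radial "brain" inside an ellipsoid mask, near-zero outside."""
    axes = [np.linspace(-1.0, 1.0, n) for n in shape]
    x, y, z = np.meshgrid(*axes, indexing="ij")
    r2 = (x / 0.85) ** 2 + (y / 0.92) ** 2 + (z / 0.85) ** 2
    inside = r2 < 1.0
    vol = np.full(shape, 0.02, dtype=np.float64)
    vol[inside] = 0.15 + 0.75 * (1.0 - r2[inside])
    return vol


def render_brain_volume(
    subject: SubjectRecord, config: GeneratorConfig, rng_state: np.random.Generator
) -> VolumePair:
    """Render the subject's MRI/JD pair on the configured grid.

    The Jacobian determinant is 1 everywhere except inside the configured
    atrophy blocks, where it is reduced by ``severity * coefficient``; the
    MRI intensity is reduced by the same factor.  Additive Gaussian voxel
    noise is applied to both channels.
    """
    shape = tuple(int(n) for n in config.grid_shape)
    mri = _template(shape).copy()
    jd = np.ones(shape, dtype=np.float64)
    for block in config.atrophy_region_spec:
        sl = block.voxel_slices(shape)
        reduction = float(np.clip(subject.severity * block.coefficient, 0.0, 0.95))
        mri[sl] *= 1.0 - reduction
        jd[sl] = 1.0 - reduction
    if config.noise_sd_image > 0:
        mri = mri + rng_state.normal(0.0, config.noise_sd_image, size=shape)
    if config.noise_sd_jd > 0:
        jd = jd + rng_state.normal(0.0, config.noise_sd_jd, size=shape)
    jd = np.maximum(jd, 1e-3)
    return VolumePair(mri=mri.astype(np.float32), jd=jd.astype(np.float32),
                      voxel_size_mm=config.voxel_size_mm)


# ---------------------------------------------------------------------------
# Disk round-trip: subject table + visit table as CSV, volumes as NIfTI.
# ---------------------------------------------------------------------------

_SCALAR_COLUMNS = [
    "subject_id", "group", "severity", "diagnosis", "age", "sex", "education",
    "mmse_baseline", "adas_delayed_recall", "apoe_e4_count",
    "hippocampal_volume", "intracranial_volume", "true_mmse_slope",
]


def write_cohort(cohort, out_dir, volumes: Mapping[str, VolumePair] | None = None) -> dict:
    """Write subjects.csv, visits.csv and one NIfTI per subject per channel.

    Returns a manifest of the written paths.  Raises on an empty cohort
    instead of producing empty files.
    """
    records = list(cohort)
    if not records:
        raise DataError("refusing to write an empty cohort")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    rows = []
    for r in records:
        row = {c: getattr(r, c) for c in _SCALAR_COLUMNS}
        row.update(r.regional_volumes)
        rows.append(row)
    subjects_csv = out / "subjects.csv"
    pd.DataFrame(rows).to_csv(subjects_csv, index=False)

    vrows = [
        {"subject_id": r.subject_id, "time_years": v.time_years,
         "mmse": v.mmse, "ad_dementia_flag": v.ad_dementia_flag}
        for r in records for v in r.visits
    ]
    visits_csv = out / "visits.csv"
    pd.DataFrame(vrows).to_csv(visits_csv, index=False)

    manifest = {"subjects": str(subjects_csv), "visits": str(visits_csv), "volumes": {}}
    for sid, pair in (volumes or {}).items():
        affine = np.diag([pair.voxel_size_mm] * 3 + [1.0])
        paths = {}
        for channel, grid in (("mri", pair.mri), ("jd", pair.jd)):
            p = out / f"{sid}_{channel}.nii.gz"
            nib.save(nib.Nifti1Image(np.asarray(grid, dtype=np.float32), affine), p)
            paths[channel] = str(p)
        manifest["volumes"][sid] = paths
    return manifest


def read_cohort(out_dir) -> tuple[list[SubjectRecord], dict[str, VolumePair]]:
    """Read back a cohort written by :func:`write_cohort`."""
    out = Path(out_dir)
    subjects_csv = out / "subjects.csv"
    if not subjects_csv.exists():
        raise DataError(f"no subjects.csv under {out}")
    subs = pd.read_csv(subjects_csv, float_precision="round_trip")
    visits = pd.read_csv(out / "visits.csv", float_precision="round_trip")

    records = []
    region_cols = [c for c in subs.columns if c in REGION_NAMES]
    for _, row in subs.iterrows():
        sid = row["subject_id"]
        vrows = visits[visits["subject_id"] == sid].sort_values("time_years")
        recs = [Visit(float(v.time_years), float(v.mmse), bool(v.ad_dementia_flag))
                for v in vrows.itertuples()]
        records.append(SubjectRecord(
            subject_id=sid, group=row["group"], severity=float(row["severity"]),
            diagnosis=row["diagnosis"], age=float(row["age"]), sex=row["sex"],
            education=float(row["education"]), mmse_baseline=int(row["mmse_baseline"]),
            adas_delayed_recall=float(row["adas_delayed_recall"]),
            apoe_e4_count=int(row["apoe_e4_count"]),
            hippocampal_volume=float(row["hippocampal_volume"]),
            intracranial_volume=float(row["intracranial_volume"]),
            regional_volumes={c: float(row[c]) for c in region_cols},
            visits=recs, true_mmse_slope=float(row["true_mmse_slope"]),
        ))

    volumes: dict[str, VolumePair] = {}
    for r in records:
        mri_p = out / f"{r.subject_id}_mri.nii.gz"
        jd_p = out / f"{r.subject_id}_jd.nii.gz"
        if mri_p.exists() and jd_p.exists():
            mri_img = nib.load(mri_p)
            jd_img = nib.load(jd_p)
            volumes[r.subject_id] = VolumePair(
                mri=np.asarray(mri_img.dataobj, dtype=np.float32),
                jd=np.asarray(jd_img.dataobj, dtype=np.float32),
                voxel_size_mm=float(mri_img.header.get_zooms()[0]),
            )
    return records, volumes
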