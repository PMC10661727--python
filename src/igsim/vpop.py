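"""Virtual patient populations for IgG replacement-therapy simulation.

Generates stratified cohorts whose body-size covariates emulate the joint
age/sex/height/weight structure of the general US population (NHANES-like
marginals, parametrically).  Adults are stratified by body mass index (BMI),
children and adults together by age band.  Each subject carries the two
body-size covariates the pharmacokinetic model uses: total body weight
(dosing) and fat-free mass (disposition scaling).
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "Subject",
    "PopulationSpec",
    "BMI_GROUPS",
    "AGE_GROUPS",
    "compute_bmi",
    "compute_lbm",
    "assign_bmi_group",
    "assign_age_group",
    "sample_population",
    "subjects_to_frame",
    "frame_to_subjects",
    "write_subjects_csv",
    "read_subjects_csv",
]

# Stratum definitions: (label, lower bound inclusive, upper bound exclusive).
BMI_GROUPS: tuple[tuple[str, float, float], ...] = (
    ("underweight", 10.0, 18.5),
    ("healthy", 18.5, 25.0),
    ("overweight", 25.0, 30.0),
    ("obese", 30.0, 60.0),
)

AGE_GROUPS: tuple[tuple[str, float, float], ...] = (
    ("2-<6 years", 2.0, 6.0),
    ("6-<12 years", 6.0, 12.0),
    ("12-<18 years", 12.0, 18.0),
    (">=18 years", 18.0, float("inf")),
)

_BMI_RANGE = (10.0, 60.0)
_MIN_AGE = 2.0

# Median stature (m) by age for the pediatric height model, one curve per sex.
# Values follow standard US growth-reference medians; a multiplicative
# log-normal deviate (4% CV) is applied around the interpolated median.
_HEIGHT_AGES = np.array(
    [2, 3, 4, 5, 6, 7, 8, 9, 10, 11, 12, 13, 14, 15, 16, 17, 18], dtype=float
)
_HEIGHT_MEDIAN_M = np.array(
    [0.87, 0.96, 1.03, 1.10, 1.16, 1.22, 1.28, 1.34, 1.39, 1.44,
     1.50, 1.57, 1.64, 1.70, 1.74, 1.75, 1.76]
)
_HEIGHT_MEDIAN_F = np.array(
    [0.86, 0.95, 1.02, 1.09, 1.15, 1.21, 1.27, 1.33, 1.39, 1.45,
     1.52, 1.57, 1.60, 1.62, 1.63, 1.63, 1.63]
)

# Pediatric BMI median rises through childhood; anchor points interpolated
# linearly (and extended flat-sloped outside the anchors).
_PED_BMI_AGES = np.array([2.0, 4.0, 15.0, 18.0])
_PED_BMI_MEDIANS = np.array([15.5, 15.8, 20.5, 21.3])
_PED_BMI_GSD = 1.15
_PED_BMI_RANGE = (12.0, 40.0)

_REJECTION_CAP_FACTOR = 1000  # max draws per stratum = cap_factor * n


@dataclass(frozen=True)
class Subject:
    """One virtual patient: demographics plus derived body-size covariates."""

    subject_id: str
    age: float        # years
    sex: str          # "male" | "female"
    height: float     # m
    weight: float     # kg
    bmi: float        # kg/m^2
    lbm: float        # kg (fat-free mass)
    bmi_group: str
    age_group: str

    def __post_init__(self) -> None:
        if self.sex not in ("male", "female"):
            raise ValueError(f"invalid sex: {self.sex!r}")
        if not np.isclose(self.bmi, self.weight / self.height**2, rtol=1e-9):
            raise ValueError("bmi inconsistent with weight/height^2")
        if not 0.0 < self.lbm < self.weight:
            raise ValueError("lbm must lie strictly between 0 and weight")
        if self.age < _MIN_AGE:
            raise ValueError(f"age {self.age} below youngest simulated age {_MIN_AGE}")
        if not _BMI_RANGE[0] <= self.bmi < _BMI_RANGE[1]:
            raise ValueError(f"bmi {self.bmi} outside [{_BMI_RANGE[0]}, {_BMI_RANGE[1]})")


@dataclass(frozen=True)
class CovariateParams:
    """Distribution parameters driving covariate generation.

    Adults: age ~ Uniform(adult_age_range); height ~ Normal(height_mean_[mf],
    height_sd); within a BMI stratum, BMI ~ LogNormal(median, GSD) truncated to
    the stratum interval; weight = BMI * height^2.  For age-stratified runs the
    adult BMI marginal (`adult_bmi_median`/`adult_bmi_gsd`) mimics the NHANES
    adult distribution.  Children: age uniform in band, height from the
    packaged median-stature curve with `ped_height_cv`, BMI log-normal around
    an age-dependent median.
    """

    p_male: float = 0.5
    adult_age_range: tuple[float, float] = (18.0, 80.0)
    height_mean_m: float = 1.75
    height_mean_f: float = 1.62
    height_sd: float = 0.07
    # BMI medians / geometric SDs per adult BMI stratum label
    bmi_medians: dict = field(default_factory=lambda: {
        "underweight": 17.5, "healthy": 21.5, "overweight": 27.3, "obese": 33.0,
    })
    bmi_gsds: dict = field(default_factory=lambda: {
        "underweight": 1.05, "healthy": 1.10, "overweight": 1.05, "obese": 1.12,
    })
    # NHANES-like adult BMI marginal for age-stratified runs
    adult_bmi_median: float = 27.5
    adult_bmi_gsd: float = 1.25
    adult_bmi_range: tuple[float, float] = (15.0, 60.0)
    ped_height_cv: float = 0.04


@dataclass(frozen=True)
class PopulationSpec:
    """Recipe for a stratified virtual population."""

    stratify_by: str                    # "bmi" | "age"
    n_per_group: int = 1000
    seed: int = 0
    groups: tuple = ()                  # defaults to Table-style strata
    covariate_params: CovariateParams = field(default_factory=CovariateParams)

    def __post_init__(self) -> None:
        if self.stratify_by not in ("bmi", "age"):
            raise ValueError(f"stratify_by must be 'bmi' or 'age', got {self.stratify_by!r}")
        if self.n_per_group <= 0:
            raise ValueError("n_per_group must be positive")
        if not self.groups:
            default = BMI_GROUPS if self.stratify_by == "bmi" else AGE_GROUPS
            object.__setattr__(self, "groups", default)
        los = [g[1] for g in self.groups]
        his = [g[2] for g in self.groups]
        for (_, lo, hi) in self.groups:
            if not lo < hi:
                raise ValueError("each group must be a non-empty half-open interval")
        for hi, lo_next in zip(his[:-1], los[1:]):
            if hi != lo_next:
                raise ValueError("groups must be contiguous, non-overlapping half-open intervals")


def compute_bmi(weight: float, height: float) -> float:
    """Body mass index, weight / height^2 (kg/m^2)."""
    if weight <= 0 or height <= 0:
        raise ValueError("weight and height must be positive")
    return weight / height**2


def compute_lbm(weight, bmi, sex):
    """Fat-free mass (kg) from total body weight and BMI.

    Janmahasatian's fat-free-mass equations:

        male:   FFM = 9270 * WT / (6680 + 216 * BMI)
        female: FFM = 9270 * WT / (8780 + 244 * BMI)

    Strictly below total weight for BMI > 10 and strictly increasing in
    weight at fixed BMI.  Applied at all ages >= 2 (no pediatric variant).
    Accepts scalars or arrays for ``weight``/``bmi``.
    """
    weight = np.asarray(weight, dtype=float)
    bmi = np.asarray(bmi, dtype=float)
    if np.any(weight <= 0):
        raise ValueError("weight must be positive")
    if isinstance(sex, str):
        if sex == "male":
            out = 9270.0 * weight / (6680.0 + 216.0 * bmi)
        elif sex == "female":
            out = 9270.0 * weight / (8780.0 + 244.0 * bmi)
        else:
            raise ValueError(f"invalid sex: {sex!r}")
    else:
        sex = np.asarray(sex)
        bad = ~np.isin(sex, ("male", "female"))
        if np.any(bad):
            raise ValueError(f"invalid sex labels: {np.unique(sex[bad])}")
        male = sex == "male"
        out = np.where(
            male,
            9270.0 * weight / (6680.0 + 216.0 * bmi),
            9270.0 * weight / (8780.0 + 244.0 * bmi),
        )
    return float(out) if out.ndim == 0 else out


def _assign_interval(value: float, groups, what: str) -> str:
    for label, lo, hi in groups:
        if lo <= value < hi:
            return label
    raise ValueError(f"{what} {value} outside the defined strata")


def assign_bmi_group(bmi: float) -> str:
    """Stratum label for a BMI value (lower-inclusive, upper-exclusive)."""
    return _assign_interval(float(bmi), BMI_GROUPS, "bmi")


def assign_age_group(age: float) -> str:
    """Age-band label; the adult band is unbounded above."""
    return _assign_interval(float(age), AGE_GROUPS, "age")


def _ped_height_median(age, sex_is_male):
    med_m = np.interp(age, _HEIGHT_AGES, _HEIGHT_MEDIAN_M)
    med_f = np.interp(age, _HEIGHT_AGES, _HEIGHT_MEDIAN_F)
    return np.where(sex_is_male, med_m, med_f)


def _truncated_lognormal(rng, median, gsd, lo, hi, n, cap, context):
    """Rejection-sample n draws of LogNormal(ln median, ln gsd) on [lo, hi)."""
    mu, sigma = np.log(median), np.log(gsd)
    out = np.empty(0)
    drawn = 0
    while out.size < n:
        batch = min(max(4 * (n - out.size), 64), cap - drawn)
        if batch <= 0:
            raise RuntimeError(
                f"rejection sampling failed to fill stratum {context!r} "
                f"within {cap} draws"
            )
        x = rng.lognormal(mu, sigma, size=batch)
        drawn += batch
        out = np.concatenate([out, x[(x >= lo) & (x < hi)]])
    return out[:n]


def _sample_stratum(label, lo, hi, spec: PopulationSpec, rng) -> pd.DataFrame:
    p = spec.covariate_params
    n = spec.n_per_group
    cap = _REJECTION_CAP_FACTOR * n
    sex_is_male = rng.random(n) < p.p_male
    sex = np.where(sex_is_male, "male", "female")

    if spec.stratify_by == "bmi":
        # Adult cohort stratified by BMI.
        age = rng.uniform(*p.adult_age_range, size=n)
        height = np.where(
            sex_is_male,
            rng.normal(p.height_mean_m, p.height_sd, size=n),
            rng.normal(p.height_mean_f, p.height_sd, size=n),
        )
        bmi = _truncated_lognormal(
            rng, p.bmi_medians[label], p.bmi_gsds[label], lo, hi, n, cap, label
        )
    else:
        hi_eff = min(hi, p.adult_age_range[1])
        age = rng.uniform(lo, hi_eff, size=n)
        if lo >= 18.0:
            height = np.where(
                sex_is_male,
                rng.normal(p.height_mean_m, p.height_sd, size=n),
                rng.normal(p.height_mean_f, p.height_sd, size=n),
            )
            bmi = _truncated_lognormal(
                rng, p.adult_bmi_median, p.adult_bmi_gsd,
                *p.adult_bmi_range, n, cap, label,
            )
        else:
            median_h = _ped_height_median(age, sex_is_male)
            height = median_h * rng.lognormal(
                0.0, np.sqrt(np.log(1 + p.ped_height_cv**2)), size=n
            )
            bmi_median = np.interp(age, _PED_BMI_AGES, _PED_BMI_MEDIANS)
            # age-dependent median: draw the multiplicative deviate, then clip
            # to the pediatric BMI range by rejection per subject
            bmi = np.empty(n)
            sigma = np.log(_PED_BMI_GSD)
            pending = np.arange(n)
            drawn = 0
            while pending.size:
                if drawn >= cap:
                    raise RuntimeError(
                        f"rejection sampling failed to fill stratum {label!r} "
                        f"within {cap} draws"
                    )
                x = bmi_median[pending] * rng.lognormal(0.0, sigma, size=pending.size)
                drawn += pending.size
                ok = (x >= _PED_BMI_RANGE[0]) & (x < _PED_BMI_RANGE[1])
                bmi[pending[ok]] = x[ok]
                pending = pending[~ok]

    weight = bmi * height**2
    lbm = compute_lbm(weight, bmi, sex)
    return pd.DataFrame({
        "age_years": age, "sex": sex, "height_m": height,
        "weight_kg": weight, "bmi": bmi, "lbm_kg": lbm,
    })


def sample_population(spec: PopulationSpec) -> list[Subject]:
    """Draw the full stratified population for a simulation scenario.

    Exactly ``n_per_group`` subjects per stratum; identical spec and seed
    reproduce the identical population.  BMI-stratified cohorts contain
    adults only.
    """
    subjects: list[Subject] = []
    root = np.random.SeedSequence(spec.seed)
    stratum_seeds = root.spawn(len(spec.groups))
    for (label, lo, hi), ss in zip(spec.groups, stratum_seeds):
        rng = np.random.default_rng(ss)
        df = _sample_stratum(label, lo, hi, spec, rng)
        for i, row in enumerate(df.itertuples(index=False)):
            sid = f"{label.replace(' ', '_')}-{i:04d}"
            subjects.append(Subject(
                subject_id=sid,
                age=float(row.age_years),
                sex=str(row.sex),
                height=float(row.height_m),
                weight=float(row.weight_kg),
                bmi=float(row.bmi),
                lbm=float(row.lbm_kg),
                bmi_group=assign_bmi_group(row.bmi),
                age_group=assign_age_group(row.age_years),
            ))
    return subjects


_CSV_COLUMNS = ["subject_id", "age_years", "sex", "height_m", "weight_kg",
                "bmi", "lbm_kg", "bmi_group", "age_group"]


def subjects_to_frame(subjects: list[Subject]) -> pd.DataFrame:
    return pd.DataFrame(
        [(s.subject_id, s.age, s.sex, s.height, s.weight, s.bmi, s.lbm,
          s.bmi_group, s.age_group) for s in subjects],
        columns=_CSV_COLUMNS,
    )


def frame_to_subjects(df: pd.DataFrame) -> list[Subject]:
    missing = set(_CSV_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"subject table missing columns: {sorted(missing)}")
    return [
        Subject(
            subject_id=str(r.subject_id), age=float(r.age_years), sex=str(r.sex),
            height=float(r.height_m), weight=float(r.weight_kg), bmi=float(r.bmi),
            lbm=float(r.lbm_kg), bmi_group=str(r.bmi_group), age_group=str(r.age_group),
        )
        for r in df.itertuples(index=False)
    ]


def write_subjects_csv(subjects: list[Subject], path) -> None:
    subjects_to_frame(subjects).to_csv(path, index=False)


def read_subjects_csv(path) -> list[Subject]:
    """Load a user-supplied subject table (same dialect as written)."""
    if isinstance(path, (str, bytes)) or hasattr(path, "__fspath__"):
        df = pd.read_csv(path)
    else:
        df = pd.read_csv(io.StringIO(path.read()) if hasattr(path, "read") else path)
    return frame_to_subjects(df)
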