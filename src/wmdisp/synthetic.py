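"""Synthetic cohorts with planted cognitive-dispersion and imaging effects.

The generator emulates the statistical structure the analysis assumes in a
cohort of healthy older adults:

* ages from a truncated normal (mean 72.0, SD 6.4, bounds 59-89 years);
* a latent per-subject *damage* factor D (right-skewed, lognormal),
  independent of age by construction, standing in for diffuse
  white-matter damage;
* 15 battery scores with linear + quadratic age trends, a latent ability
  factor, and residual noise whose within-person SD is inflated by D —
  so D drives dispersion (ISD) but not mean-level age trends;
* skeletonized FA/MD maps on a toy-atlas grid with negative FA-age and
  positive MD-age slopes everywhere, plus an MD increment proportional to
  standardized D in configured effect regions, and smooth spatial noise.

Every stage is deterministic given its seed, and the exact voxel sets
carrying the planted D effect are returned as ground-truth masks.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from scipy.ndimage import gaussian_filter

from .atlas import LabelVolume, make_toy_atlas, write_label_volume
from .battery import BatterySpec, default_battery
from .voxelwise import SkeletonDataset, SkeletonMask


@dataclass
class CohortConfig:
    """Cohort size, truncated-normal age distribution and seed."""

    n_subjects: int = 80
    age_mean: float = 72.0
    age_sd: float = 6.4
    age_min: float = 59.0
    age_max: float = 89.0
    damage_sigma: float = 0.4  # lognormal(0, sigma) damage factor D
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 8:
            raise ValueError("need at least 8 subjects")
        if not self.age_min < self.age_max:
            raise ValueError("invalid age bounds")


@dataclass
class TestSimParams:
    """Generative parameters for one test, on the oriented scale."""

    intercept: float
    age_slope: float
    age2_slope: float
    loading: float
    residual_sd: float


@dataclass
class BatterySimConfig:
    """Score-generator settings: per-test params, dispersion gain, missingness."""

    params: dict[str, TestSimParams] = field(default_factory=dict)
    noise_gain: float = 1.0  # g: residual-SD multiplier is 1 + g * D
    missing_rate: float = 0.02
    seed: int = 1

    def __post_init__(self) -> None:
        if self.noise_gain < 0:
            raise ValueError("noise_gain must be >= 0")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must be in [0, 1)")
        for name, p in self.params.items():
            if p.residual_sd <= 0:
                raise ValueError(f"test {name!r}: residual_sd must be positive")


def default_test_params(battery: BatterySpec | None = None) -> dict[str, TestSimParams]:
    """Plausible generative parameters for the default battery.

    Intercepts and residual SDs are scaled to each test's typical score
    range; age slopes put roughly half of the total variance under the
    age trend (so raw-score composites correlate strongly and negatively
    with age), and ability loadings add shared within-domain variance.
    """
    battery = battery or default_battery()
    # (natural-scale midpoint, residual sd) per test
    base = {
        "adas_cog": (10.0, 4.0), "lm_i": (14.0, 3.0), "lm_ii": (12.0, 3.0),
        "ravlt_a15": (40.0, 11.0), "ravlt_a6": (8.0, 3.5), "ravlt_a7": (8.0, 3.5),
        "category_fluency": (25.0, 6.0), "clock_copy": (4.5, 0.6),
        "clock_score": (4.2, 0.6), "tmt_a": (35.0, 11.0), "tmt_b": (100.0, 45.0),
        "moca": (55.0, 7.0), "mmse": (28.0, 1.5), "anart": (24.0, 3.0),
        "bnt": (27.0, 4.0),
    }
    out: dict[str, TestSimParams] = {}
    for i, t in enumerate(battery.tests):
        mid, sd = base.get(t.name, (0.0, 1.0))
        oriented_mid = -mid if t.direction == "lower_better" else mid
        # contribution SDs relative to residual sd: age ~0.7, quad small,
        # loading varied 0.5-0.9 across tests
        loading = (0.5 + 0.4 * ((i * 7) % 5) / 4.0) * sd
        out[t.name] = TestSimParams(
            intercept=oriented_mid,
            age_slope=-0.7 * sd / 6.4,
            age2_slope=-0.10 * sd / 58.0,
            loading=loading,
            residual_sd=sd,
        )
    return out


def simulate_cohort(config: CohortConfig) -> tuple[pd.DataFrame, np.ndarray]:
    """Draw covariates and the latent damage factor D.

    Returns a covariate frame (participant_id, age, sex, education) and D,
    lognormal and independent of age.  Deterministic given the seed.
    """
    rng = np.random.default_rng(config.seed)
    a = (config.age_min - config.age_mean) / config.age_sd
    b = (config.age_max - config.age_mean) / config.age_sd
    age = stats.truncnorm.rvs(
        a, b, loc=config.age_mean, scale=config.age_sd,
        size=config.n_subjects, random_state=rng,
    )
    damage = rng.lognormal(mean=0.0, sigma=config.damage_sigma,
                           size=config.n_subjects)
    cov = pd.DataFrame(
        {
            "participant_id": [f"sub-{i:04d}" for i in range(config.n_subjects)],
            "age": age,
            "sex": rng.choice(["F", "M"], size=config.n_subjects),
            "education": rng.integers(12, 21, size=config.n_subjects),
        }
    )
    return cov, damage


def simulate_battery_scores(
    cohort: pd.DataFrame,
    damage: np.ndarray,
    config: BatterySimConfig | None = None,
    battery: BatterySpec | None = None,
) -> pd.DataFrame:
    """Generate the score table on each test's natural scale.

    score_oriented = intercept + b*age_c + c*age_c^2 + loading*ability + eps
    with sd(eps) = residual_sd * (1 + g*D).  Lower-better tests are then
    emitted negated (their natural scale).  Missing cells at the configured
    rate.
    """
    battery = battery or default_battery()
    config = config or BatterySimConfig(params=default_test_params(battery))
    if not config.params:
        config.params = default_test_params(battery)
    missing = set(battery.names) - set(config.params)
    if missing:
        raise ValueError(f"no generative parameters for tests: {sorted(missing)}")
    rng = np.random.default_rng(config.seed)
    n = len(cohort)
    age_c = cohort["age"].to_numpy() - cohort["age"].mean()
    ability = rng.standard_normal(n)
    sd_mult = 1.0 + config.noise_gain * np.asarray(damage)

    out = cohort[["participant_id", "age"]].copy()
    for t in battery.tests:
        p = config.params[t.name]
        eps = rng.standard_normal(n) * p.residual_sd * sd_mult
        oriented = (
            p.intercept + p.age_slope * age_c + p.age2_slope * age_c**2
            + p.loading * ability + eps
        )
        natural = -oriented if t.direction == "lower_better" else oriented
        if config.missing_rate > 0:
            drop = rng.random(n) < config.missing_rate
            natural = np.where(drop, np.nan, natural)
        out[t.name] = natural
    return out


DEFAULT_EFFECT_REGIONS = (
    "genu_of_corpus_callosum",
    "anterior_corona_radiata_l",
    "anterior_corona_radiata_r",
    "superior_longitudinal_fasciculus_l",
)


@dataclass
class ImagingSimConfig:
    """Skeleton-image generator settings.

    MD is simulated in units of 1e-3 mm^2/s (baseline ~0.7, rising with
    age); FA baselines vary by region within [0.3, 0.8] and decline with
    age.  ``effect_beta`` is the standardized effect size linking the
    damage factor to MD in the effect regions: the correlation (equiv.
    standardized regression slope) between standardized damage and the
    voxel value net of age, so the additive MD increment per SD of D is
    ``beta / sqrt(1 - beta^2)`` voxel-noise SDs.  Spatial noise is white
    Gaussian smoothed with a fixed kernel (so it is spatially correlated,
    which keeps permutation FWER calibration honest), renormalized to unit
    variance before scaling.
    """

    background_density: float = 0.08
    fa_background: float = 0.45
    fa_baseline_range: tuple[float, float] = (0.3, 0.8)
    fa_age_slope: float = -0.003  # per year
    md_baseline: float = 0.7
    md_age_slope: float = 0.003  # per year, units 1e-3 mm^2/s
    effect_regions: tuple[str, ...] = DEFAULT_EFFECT_REGIONS
    effect_beta: float = 0.5  # MD, positive correlation with damage
    fa_effect_beta: float = 0.0  # FA, applied negatively when > 0

    def __post_init__(self) -> None:
        for name, b in (("effect_beta", self.effect_beta),
                        ("fa_effect_beta", self.fa_effect_beta)):
            if not 0 <= b < 1:
                raise ValueError(f"{name} must be a correlation in [0, 1)")

    def effect_amplitude(self, beta: float, noise_sd: float) -> float:
        """Additive increment per SD of damage yielding correlation beta."""
        return beta / np.sqrt(1.0 - beta**2) * noise_sd
    noise_sd_fa: float = 0.04
    noise_sd_md: float = 0.04
    smooth_sigma: float = 1.5  # voxels
    seed: int = 2


@dataclass
class SyntheticImaging:
    """Bundle of generated imaging data and ground truth."""

    fa: SkeletonDataset
    md: SkeletonDataset
    mean_fa: np.ndarray
    mask: SkeletonMask
    truth_masks: dict[str, np.ndarray]


def _smooth_noise(rng: np.random.Generator, shape, sigma: float,
                  n_fields: int) -> np.ndarray:
    """Unit-variance smoothed Gaussian fields, stacked (n_fields, *shape)."""
    fields = rng.standard_normal((n_fields, *shape))
    if sigma <= 0:
        return fields
    impulse = np.zeros(shape)
    impulse[tuple(s // 2 for s in shape)] = 1.0
    kernel = gaussian_filter(impulse, sigma)
    norm = np.sqrt((kernel**2).sum())
    for i in range(n_fields):
        fields[i] = gaussian_filter(fields[i], sigma) / norm
    return fields


def simulate_skeleton_images(
    cohort: pd.DataFrame,
    damage: np.ndarray,
    config: ImagingSimConfig | None = None,
    atlas: LabelVolume | None = None,
) -> SyntheticImaging:
    """Generate per-subject skeletonized FA and MD datasets with ground truth.

    The skeleton is the union of the atlas blocks and a sparse random
    background (density ``background_density``); the returned mean-FA
    volume reproduces it exactly under the FA > 0.2 mask rule.
    """
    config = config or ImagingSimConfig()
    atlas = atlas or make_toy_atlas()
    rng = np.random.default_rng(config.seed)
    shape = atlas.data.shape

    for name in config.effect_regions:
        atlas.label_of(name)  # raises if unresolvable

    # Region FA baselines spread deterministically over the configured range.
    ids = sorted(atlas.lookup)
    lo, hi = config.fa_baseline_range
    fa_baselines = {
        lid: lo + (hi - lo) * (i / max(len(ids) - 1, 1))
        for i, lid in enumerate(ids)
    }

    background = (rng.random(shape) < config.background_density) & (atlas.data == 0)
    skeleton = (atlas.data > 0) | background

    mean_fa = np.zeros(shape)
    mean_fa[background] = config.fa_background
    for lid, base in fa_baselines.items():
        mean_fa[atlas.data == lid] = base
    mask = SkeletonMask(data=skeleton, affine=np.eye(4))
    mvox = skeleton  # 3D bool
    n_vox = int(mvox.sum())

    fa_base_v = mean_fa[mvox]
    md_base_v = np.full(n_vox, config.md_baseline)

    effect = np.zeros(shape, dtype=bool)
    for name in config.effect_regions:
        effect |= atlas.region_mask(name)
    effect &= mvox
    effect_v = effect[mvox]

    n = len(cohort)
    age_c = cohort["age"].to_numpy() - cohort["age"].mean()
    d = np.asarray(damage, dtype=float)
    d_z = (d - d.mean()) / d.std(ddof=0)

    noise_fa = _smooth_noise(rng, shape, config.smooth_sigma, n)[:, mvox]
    noise_md = _smooth_noise(rng, shape, config.smooth_sigma, n)[:, mvox]

    fa_vals = (
        fa_base_v[None, :]
        + config.fa_age_slope * age_c[:, None]
        + config.noise_sd_fa * noise_fa
    )
    if config.fa_effect_beta > 0:
        amp_fa = config.effect_amplitude(config.fa_effect_beta, config.noise_sd_fa)
        fa_vals -= amp_fa * d_z[:, None] * effect_v[None, :]
    np.clip(fa_vals, 0.0, 1.0, out=fa_vals)

    amp_md = config.effect_amplitude(config.effect_beta, config.noise_sd_md)
    md_vals = (
        md_base_v[None, :]
        + config.md_age_slope * age_c[:, None]
        + amp_md * d_z[:, None] * effect_v[None, :]
        + config.noise_sd_md * noise_md
    )
    np.clip(md_vals, 1e-6, None, out=md_vals)

    ids_list = cohort["participant_id"].tolist()
    truth = {"MD": effect.copy()}
    if config.fa_effect_beta > 0:
        truth["FA"] = effect.copy()
    return SyntheticImaging(
        fa=SkeletonDataset("FA", fa_vals, mask, ids_list),
        md=SkeletonDataset("MD", md_vals, mask, ids_list),
        mean_fa=mean_fa,
        mask=mask,
        truth_masks=truth,
    )


def make_study(
    out_dir,
    n_subjects: int = 80,
    seed: int = 0,
    cohort_config: CohortConfig | None = None,
    battery_config: BatterySimConfig | None = None,
    imaging_config: ImagingSimConfig | None = None,
    battery: BatterySpec | None = None,
    atlas: LabelVolume | None = None,
) -> Path:
    """Write a complete ready-to-run synthetic study folder.

    Layout: ``scores.csv``, ``mean_fa.nii.gz``, ``atlas.nii.gz`` +
    ``atlas_labels.csv``, ``subjects/<id>_{FA,MD}.nii.gz``, ground-truth
    ``truth_md_effect.nii.gz`` and ``truth_damage.csv`` (latent D, for
    validation only — the pipeline never reads it).  Stage seeds are
    derived from ``seed`` deterministically.
    """
    import nibabel as nib

    out = Path(out_dir)
    (out / "subjects").mkdir(parents=True, exist_ok=True)
    child = np.random.SeedSequence(seed).generate_state(3) % (2**31)
    battery = battery or default_battery()
    atlas = atlas or make_toy_atlas()

    cohort_config = cohort_config or CohortConfig(n_subjects=n_subjects,
                                                  seed=int(child[0]))
    battery_config = battery_config or BatterySimConfig(
        params=default_test_params(battery), seed=int(child[1])
    )
    imaging_config = imaging_config or ImagingSimConfig(seed=int(child[2]))

    cohort, damage = simulate_cohort(cohort_config)
    scores = simulate_battery_scores(cohort, damage, battery_config, battery)
    imaging = simulate_skeleton_images(cohort, damage, imaging_config, atlas)

    scores.to_csv(out / "scores.csv", index=False)
    pd.DataFrame(
        {"participant_id": cohort["participant_id"], "damage": damage}
    ).to_csv(out / "truth_damage.csv", index=False)

    affine = np.eye(4)
    nib.save(nib.Nifti1Image(imaging.mean_fa.astype(np.float32), affine),
             str(out / "mean_fa.nii.gz"))
    write_label_volume(atlas, out / "atlas.nii.gz", out / "atlas_labels.csv")
    nib.save(
        nib.Nifti1Image(imaging.truth_masks["MD"].astype(np.uint8), affine),
        str(out / "truth_md_effect.nii.gz"),
    )
    for ds in (imaging.fa, imaging.md):
        for i, sid in enumerate(ds.subject_ids):
            vol = ds.mask.embed(ds.values[i])
            nib.save(
                nib.Nifti1Image(vol.astype(np.float32), affine),
                str(out / "subjects" / f"{sid}_{ds.metric}.nii.gz"),
            )
    return out
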