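"""End-to-end study pipeline: cognition scores -> voxelwise inference -> report.

Mirrors the analysis structure of a dispersion/white-matter study: scores
are oriented, age-detrended and T-standardized; dispersion (ISD) and proxy
composites computed; the bivariate correlation table produced; then each
requested (score, metric, direction) contrast is tested voxelwise with
TFCE + permutation FWER correction, both with and without a second age
residualization of the predictor, thresholded at the 95% and 90% corrected
levels, and summarized per atlas region.  A JSON manifest records inputs,
parameters, seeds and outputs so a run can be reproduced exactly.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .battery import BatterySpec, default_battery, orient_scores
from .cognition import (
    age_detrend_standardize,
    compute_composites,
    compute_dispersion,
    correlation_table,
    default_tails,
    residualize_on_age,
)
from .io import read_study, save_volume
from .voxelwise import (
    Design,
    TFCEParams,
    permutation_test,
    summarize_regions,
    threshold_map,
)

logger = logging.getLogger(__name__)

DISPERSION_VARS = ["isd_bp", "isd_mem", "isd_ef"]
COMPOSITE_VARS = ["com_mem", "com_ef"]


@dataclass
class Analysis:
    """One voxelwise contrast: predictor score, metric, tail."""

    score: str = "isd_bp"
    metric: str = "MD"
    tail: str = "positive"


@dataclass
class RunConfig:
    """Everything needed to (re)produce one pipeline run."""

    study_dir: str
    out_dir: str
    seed: int
    analyses: list[Analysis] = field(default_factory=lambda: [Analysis()])
    n_perm: int = 1000
    tfce: TFCEParams = field(default_factory=TFCEParams)
    levels: tuple[float, ...] = (0.95, 0.90)
    min_fraction: float = 0.5
    fa_threshold: float = 0.2

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if "seed" not in raw:
            raise ValueError("config must set an explicit seed")
        tfce = TFCEParams(**raw.pop("tfce", {}))
        analyses = [Analysis(**a) for a in raw.pop("analyses", [{}])]
        levels = tuple(raw.pop("levels", (0.95, 0.90)))
        return cls(tfce=tfce, analyses=analyses, levels=levels, **raw)


def _stage(name):
    """Abort with a stage-named message on any error inside the stage."""
    class _Ctx:
        def __init__(self):
            self.t0 = 0.0
            self.elapsed = 0.0

        def __enter__(self):
            logger.info("stage %s: start", name)
            self.t0 = time.perf_counter()
            return self

        def __exit__(self, exc_type, exc, tb):
            self.elapsed = time.perf_counter() - self.t0
            if exc is not None:
                raise RuntimeError(f"stage {name!r} failed: {exc}") from exc
            logger.info("stage %s: done in %.2fs", name, self.elapsed)
            return False

    return _Ctx()


def run_pipeline(config: RunConfig, battery: BatterySpec | None = None) -> dict:
    """Execute the full analysis; returns the manifest dict.

    Writes, under ``config.out_dir``: ``tscores.csv``, ``dispersion.csv``,
    ``correlations.csv``; per contrast and predictor variant (raw /
    age-residualized): t-statistic, TFCE and 1-p_FWE NIfTI maps, binary
    significance masks and region-summary CSVs at each level; and
    ``manifest.json``.
    """
    battery = battery or default_battery()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    timings: dict[str, float] = {}
    outputs: list[str] = []

    def _write_csv(df: pd.DataFrame, name: str) -> None:
        df.to_csv(out / name, index=False)
        outputs.append(name)

    with _stage("read_study") as st:
        scores, datasets, atlas, mask = read_study(
            config.study_dir, fa_threshold=config.fa_threshold
        )
    timings["read_study"] = st.elapsed

    with _stage("cognition") as st:
        oriented = orient_scores(scores, battery)
        model, tscores = age_detrend_standardize(oriented, battery)
        disp = compute_dispersion(tscores, battery, config.min_fraction)
        comp = compute_composites(tscores, battery)
        table = pd.concat(
            [scores[["participant_id", "age"]], tscores, disp,
             comp[COMPOSITE_VARS]], axis=1,
        )
        _write_csv(pd.concat([scores[["participant_id"]], tscores], axis=1),
                   "tscores.csv")
        _write_csv(table.drop(columns=battery.names, errors="ignore"),
                   "dispersion.csv")
        variables = {
            "age": scores["age"].to_numpy(dtype=float),
            **{v: comp[v].to_numpy() for v in COMPOSITE_VARS},
            **{v: disp[v].mask(disp["excluded"]).to_numpy()
               for v in DISPERSION_VARS},
        }
        corr = correlation_table(
            variables, default_tails(DISPERSION_VARS, COMPOSITE_VARS)
        )
        _write_csv(corr, "correlations.csv")
    timings["cognition"] = st.elapsed

    seeds = np.random.SeedSequence(config.seed).generate_state(
        2 * len(config.analyses)
    ) % (2**31)
    affine = mask.affine
    age = scores["age"].to_numpy(dtype=float)

    for i, an in enumerate(config.analyses):
        if an.metric not in datasets:
            raise RuntimeError(f"stage 'voxelwise' failed: no {an.metric} dataset")
        data = datasets[an.metric]
        if an.score == "age":
            base = age.copy()
        elif an.score in DISPERSION_VARS:
            base = disp[an.score].mask(disp["excluded"]).to_numpy(dtype=float)
        elif an.score in COMPOSITE_VARS:
            base = comp[an.score].to_numpy(dtype=float)
        else:
            raise RuntimeError(
                f"stage 'voxelwise' failed: unknown predictor {an.score!r}"
            )
        variants = {"raw": base}
        if an.score != "age":
            resid = np.full_like(base, np.nan)
            ok = np.isfinite(base) & np.isfinite(age)
            resid[ok] = residualize_on_age(base[ok], age[ok])
            variants["age_resid"] = resid

        for j, (variant, pred) in enumerate(variants.items()):
            tag = f"{an.score}_{an.metric}_{an.tail}_{variant}"
            with _stage(f"voxelwise[{tag}]") as st:
                keep = np.isfinite(pred)
                sub = data.values[keep]
                from .voxelwise import SkeletonDataset

                ds = SkeletonDataset(
                    an.metric, sub, mask,
                    [s for s, k in zip(data.subject_ids, keep) if k],
                )
                design = Design(predictor=pred[keep], tail=an.tail)
                result = permutation_test(
                    ds, design, config.tfce, n_perm=config.n_perm,
                    seed=int(seeds[2 * i + (j % 2)]),
                )
                save_volume(out / f"tstat_{tag}.nii.gz",
                            mask.embed(result.t_observed), affine)
                save_volume(out / f"tfce_{tag}.nii.gz",
                            mask.embed(result.tfce_observed), affine)
                save_volume(out / f"corrp_{tag}.nii.gz",
                            mask.embed(result.one_minus_p), affine)
                outputs += [f"tstat_{tag}.nii.gz", f"tfce_{tag}.nii.gz",
                            f"corrp_{tag}.nii.gz"]
                for level in config.levels:
                    pct = int(round(level * 100))
                    sig = threshold_map(result, level)
                    save_volume(out / f"sig{pct}_{tag}.nii.gz",
                                sig.astype(float), affine)
                    _write_csv(summarize_regions(sig, atlas, mask),
                               f"regions{pct}_{tag}.csv")
                    outputs.append(f"sig{pct}_{tag}.nii.gz")
            timings[f"voxelwise[{tag}]"] = st.elapsed

    import scipy

    from . import __version__ as pkg_version

    manifest = {
        "package": "wmdisp",
        "version": pkg_version,
        "numpy": np.__version__,
        "scipy": scipy.__version__,
        "config": {
            "study_dir": str(config.study_dir),
            "out_dir": str(config.out_dir),
            "seed": config.seed,
            "n_perm": config.n_perm,
            "analyses": [asdict(a) for a in config.analyses],
            "tfce": asdict(config.tfce),
            "levels": list(config.levels),
            "min_fraction": config.min_fraction,
            "fa_threshold": config.fa_threshold,
        },
        "n_subjects": len(scores),
        "outputs": outputs,
        "timings_s": {k: round(v, 3) for k, v in timings.items()},
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest
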