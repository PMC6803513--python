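"""Voxelwise GLM, permutation FWER inference and region summaries.

The mass-univariate model regresses each skeleton voxel's scalar value
(FA or MD) on a predictor of interest plus optional nuisance covariates,
and tests the predictor's t statistic one-tailed.  Familywise error across
voxels is controlled with the max-statistic permutation method applied to
the TFCE-enhanced t map: each permutation's maximum enhanced value over
the skeleton forms the null distribution, so the corrected p-value of a
voxel is the fraction of permutations whose maximum reaches its observed
enhancement (with the add-one convention, p >= 1/(n_perm + 1)).

When nuisance covariates are present, permutation follows the
Freedman-Lane scheme: residuals from the nuisance-only model are permuted
and the full model refit.  The nuisance design always includes the
intercept, so with no other covariates the scheme reduces to a full row
permutation of the (centered) data.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .tfce import TfceEngine

_EPS = 1e-12


@dataclass
class SkeletonMask:
    """Boolean white-matter skeleton with spatial metadata."""

    data: np.ndarray
    affine: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=bool)
        if self.data.ndim != 3:
            raise ValueError("skeleton mask must be 3D")
        if not self.data.any():
            raise ValueError("skeleton mask is empty")

    @property
    def n_voxels(self) -> int:
        return int(self.data.sum())

    @property
    def voxel_size(self) -> np.ndarray | None:
        if self.affine is None:
            return None
        return np.sqrt((self.affine[:3, :3] ** 2).sum(axis=0))

    def embed(self, values: np.ndarray, fill: float = 0.0) -> np.ndarray:
        """Scatter a per-voxel vector back into a full 3D volume."""
        out = np.full(self.data.shape, fill, dtype=float)
        out[self.data] = values
        return out


@dataclass
class SkeletonDataset:
    """Subjects x mask-voxels values for one scalar metric (FA or MD)."""

    metric: str
    values: np.ndarray
    mask: SkeletonMask
    subject_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.metric not in ("FA", "MD"):
            raise ValueError("metric must be 'FA' or 'MD'")
        if self.values.ndim != 2:
            raise ValueError("values must be subjects x voxels")
        if self.values.shape[1] != self.mask.n_voxels:
            raise ValueError("values column count does not match mask voxels")
        if len(self.subject_ids) != self.values.shape[0]:
            raise ValueError("subject_ids length does not match values rows")

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]


@dataclass
class Design:
    """Predictor of interest, optional nuisance covariates and a tail."""

    predictor: np.ndarray
    nuisance: np.ndarray | None = None
    tail: str = "positive"

    def __post_init__(self) -> None:
        self.predictor = np.asarray(self.predictor, dtype=float).ravel()
        if self.nuisance is not None:
            self.nuisance = np.atleast_2d(np.asarray(self.nuisance, dtype=float))
            if self.nuisance.shape[0] != self.predictor.shape[0]:
                self.nuisance = self.nuisance.T
            if self.nuisance.shape[0] != self.predictor.shape[0]:
                raise ValueError("nuisance rows do not match predictor length")
            if self.nuisance.size == 0:
                self.nuisance = None
        if self.tail not in ("positive", "negative"):
            raise ValueError("tail must be 'positive' or 'negative'")
        if not np.all(np.isfinite(self.predictor)):
            raise ValueError("predictor contains non-finite values")

    def matrix(self) -> np.ndarray:
        """Full design: [intercept, nuisance..., predictor]."""
        n = self.predictor.shape[0]
        cols = [np.ones(n)]
        if self.nuisance is not None:
            cols.extend(self.nuisance.T)
        cols.append(self.predictor)
        X = np.column_stack(cols)
        if np.linalg.matrix_rank(X) < X.shape[1]:
            raise ValueError("design matrix is rank deficient")
        return X

    def nuisance_matrix(self) -> np.ndarray:
        n = self.predictor.shape[0]
        if self.nuisance is None:
            return np.ones((n, 1))
        return np.column_stack([np.ones(n), self.nuisance])


@dataclass
class TFCEParams:
    """TFCE exponents, step size and neighborhood connectivity."""

    E: float = 0.5
    H: float = 2.0
    dh: float | None = None  # None -> max(stat)/n_steps per map
    connectivity: int = 26
    n_steps: int = 100

    def __post_init__(self) -> None:
        if self.E <= 0 or self.H <= 0:
            raise ValueError("E and H must be positive")
        if self.dh is not None and self.dh <= 0:
            raise ValueError("dh must be positive")
        if self.connectivity not in (6, 18, 26):
            raise ValueError("connectivity must be 6, 18 or 26")


@dataclass
class VoxelStatMap:
    """Per-voxel t statistics for the predictor of interest."""

    t: np.ndarray
    df: int
    mask: SkeletonMask


@dataclass
class PermutationResult:
    """Corrected voxelwise significance (stored as 1 - p_FWE) plus the null."""

    one_minus_p: np.ndarray
    tfce_observed: np.ndarray
    null_max: np.ndarray
    n_perm: int
    seed: int | None
    mask: SkeletonMask
    t_observed: np.ndarray | None = None
    exhaustive: bool = False


def make_mask(mean_fa: np.ndarray, threshold: float = 0.2,
              affine: np.ndarray | None = None) -> SkeletonMask:
    """Skeleton mask from a mean-FA volume: voxels with FA strictly > threshold."""
    mean_fa = np.asarray(mean_fa, dtype=float)
    if not np.all(np.isfinite(mean_fa)):
        raise ValueError("mean FA volume contains non-finite values")
    data = mean_fa > threshold
    if not data.any():
        raise ValueError(f"no voxels exceed FA threshold {threshold}")
    return SkeletonMask(data=data, affine=affine)


def _fit_t(X: np.ndarray, Y: np.ndarray) -> tuple[np.ndarray, int]:
    """t statistic of the last design column, vectorized over voxel columns."""
    n, p = X.shape
    df = n - p
    if df < 1:
        raise ValueError("not enough subjects for the design (df < 1)")
    pinv = np.linalg.pinv(X)
    B = pinv @ Y
    resid = Y - X @ B
    sigma2 = (resid**2).sum(axis=0) / df
    xtx_inv_last = np.linalg.inv(X.T @ X)[-1, -1]
    se = np.sqrt(np.maximum(sigma2 * xtx_inv_last, _EPS))
    return B[-1] / se, df


def fit_voxelwise(data: SkeletonDataset, design: Design) -> VoxelStatMap:
    """Per-voxel OLS of the metric on [1, nuisance, predictor]; t for the predictor.

    A tiny epsilon guards the standard error so perfectly explained voxels
    yield a large finite t instead of infinity.
    """
    X = design.matrix()
    if data.n_subjects != X.shape[0]:
        raise ValueError("dataset subjects do not match design rows")
    if data.n_subjects <= X.shape[1] + 1:
        raise ValueError("need n_subjects > n_design_columns + 1")
    t, df = _fit_t(X, data.values)
    return VoxelStatMap(t=t, df=df, mask=data.mask)


def _permutation_iter(n: int, n_perm: int, rng: np.random.Generator,
                      exhaustive: bool):
    if exhaustive:
        for perm in itertools.permutations(range(n)):
            yield np.asarray(perm, dtype=np.intp)
    else:
        for _ in range(n_perm):
            yield rng.permutation(n)


def permutation_test(
    data: SkeletonDataset,
    design: Design,
    params: TFCEParams | None = None,
    n_perm: int = 1000,
    seed: int | None = None,
    exhaustive: bool = False,
) -> PermutationResult:
    """Max-TFCE permutation test with familywise-error correction.

    The observed map is the TFCE-enhanced one-tailed t map.  The null
    distribution collects, for each permutation of the Freedman-Lane
    residuals, the maximum enhanced value over the skeleton.  Voxelwise
    ``p_FWE = (1 + #{null max >= observed}) / (n_perm + 1)``; the result
    stores ``1 - p_FWE``.  Deterministic given ``seed``.

    With ``exhaustive=True`` all n! row permutations are enumerated
    (feasible only for small n); ``n_perm`` is then ignored.
    """
    params = params or TFCEParams()
    if not exhaustive and n_perm < 100:
        raise ValueError("n_perm < 100 gives too coarse an inference")
    X = design.matrix()
    Z = design.nuisance_matrix()
    Y = data.values
    n = data.n_subjects
    if X.shape[0] != n:
        raise ValueError("design rows do not match dataset subjects")

    sign = 1.0 if design.tail == "positive" else -1.0
    t_obs, df = _fit_t(X, Y)
    engine = TfceEngine(data.mask.data, params.connectivity)
    stat_obs = np.maximum(sign * t_obs, 0.0)
    tfce_obs = engine.transform(
        stat_obs, E=params.E, H=params.H, dh=params.dh, n_steps=params.n_steps
    )

    # Freedman-Lane: permute residuals from the nuisance-only model.
    Rz = Y - Z @ (np.linalg.pinv(Z) @ Y)
    pinvX = np.linalg.pinv(X)
    xtx_inv_last = np.linalg.inv(X.T @ X)[-1, -1]

    rng = np.random.default_rng(seed)
    if exhaustive:
        n_perm = math.factorial(n)
    null_max = np.empty(n_perm, dtype=float)
    for i, perm in enumerate(_permutation_iter(n, n_perm, rng, exhaustive)):
        Yp = Rz[perm]
        B = pinvX @ Yp
        resid = Yp - X @ B
        sigma2 = (resid**2).sum(axis=0) / df
        se = np.sqrt(np.maximum(sigma2 * xtx_inv_last, _EPS))
        t_perm = np.maximum(sign * (B[-1] / se), 0.0)
        enhanced = engine.transform(
            t_perm, E=params.E, H=params.H, dh=params.dh, n_steps=params.n_steps
        )
        null_max[i] = enhanced.max(initial=0.0)

    exceed = (null_max[None, :] >= tfce_obs[:, None]).sum(axis=1)
    p_fwe = (1.0 + exceed) / (n_perm + 1.0)
    return PermutationResult(
        one_minus_p=1.0 - p_fwe,
        tfce_observed=tfce_obs,
        null_max=null_max,
        n_perm=n_perm,
        seed=seed,
        mask=data.mask,
        t_observed=t_obs,
        exhaustive=exhaustive,
    )


def threshold_map(result: PermutationResult, level: float = 0.95) -> np.ndarray:
    """Binary 3D map of voxels significant at ``1 - p_FWE >= level``."""
    if not 0.0 < level < 1.0:
        raise ValueError("level must be in (0, 1)")
    sig = result.one_minus_p >= level
    out = np.zeros(result.mask.data.shape, dtype=bool)
    out[result.mask.data] = sig
    return out


def summarize_regions(binary: np.ndarray, atlas, mask: SkeletonMask) -> pd.DataFrame:
    """Percent of significant skeleton voxels per atlas region.

    For each atlas label overlapping the mask:
    ``percent = 100 * |significant & region & mask| / |region & mask|``.
    Regions with no mask overlap are omitted.  Returns a frame sorted by
    descending percent with columns label_id, name, hemisphere, n_voxels,
    n_significant, percent.
    """
    binary = np.asarray(binary, dtype=bool)
    if binary.shape != mask.data.shape:
        raise ValueError("binary map shape does not match mask")
    if atlas.data.shape != mask.data.shape:
        raise ValueError("atlas label volume shape does not match mask")
    rows = []
    for label_id, (name, hemi) in sorted(atlas.lookup.items()):
        region = (atlas.data == label_id) & mask.data
        n_vox = int(region.sum())
        if n_vox == 0:
            continue
        n_sig = int((region & binary).sum())
        rows.append((label_id, name, hemi, n_vox, n_sig, 100.0 * n_sig / n_vox))
    df = pd.DataFrame(
        rows,
        columns=["label_id", "name", "hemisphere", "n_voxels",
                 "n_significant", "percent"],
    )
    return df.sort_values("percent", ascending=False, ignore_index=True)
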