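"""Age detrending, T-standardization, dispersion and composite scores.

The dispersion statistic (ISD, intraindividual standard deviation) measures
how inconsistent one person's performance is across a profile of tests at a
single occasion.  Because mean performance varies with age, each test is
first regressed on linear and quadratic age trends; the residuals are then
expressed as T-scores (mean 50, SD 10) so that tests with very different
raw units contribute on a common metric.  ISD is then simply the sample
standard deviation of one participant's T-scores over a profile: the whole
battery (ISD-BP), the memory tests (ISD-Mem) or the executive tests
(ISD-EF).

Domain composites (COM-Mem, COM-EF) are mean-of-T proxies: the mean of a
participant's within-domain T-scores, re-expressed as a cohort z-score.
They stand in for externally derived psychometric composites and are
labelled as proxies throughout.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .battery import BatterySpec

logger = logging.getLogger(__name__)

#: Minimum rows needed to fit intercept + age + age^2 with a df to spare.
MIN_FIT_ROWS = 4


@dataclass
class TestDetrend:
    """Quadratic-age OLS fit for one test (on the oriented scale)."""

    intercept: float
    beta_age: float
    beta_age2: float
    residual_sd: float
    n_fit: int
    available: bool = True


@dataclass
class DetrendModel:
    """Per-test quadratic age-detrending models plus the age centering."""

    age_center: float
    tests: dict[str, TestDetrend] = field(default_factory=dict)


def _quad_design(age_c: np.ndarray) -> np.ndarray:
    return np.column_stack([np.ones_like(age_c), age_c, age_c**2])


def age_detrend_standardize(
    oriented: pd.DataFrame,
    battery: BatterySpec | None = None,
) -> tuple[DetrendModel, pd.DataFrame]:
    """Regress each test on age and age^2, T-standardize the residuals.

    Parameters
    ----------
    oriented
        Score table with an ``age`` column and oriented test columns
        (high = better).  Missing cells allowed.
    battery
        If given, restricts the fitted columns to the battery tests;
        otherwise every non-covariate column is fitted.

    Returns
    -------
    model, tscores
        The per-test fits and a participants x tests frame of T-scores
        (mean 50, SD 10 over the fitted rows of each column, sample SD).
        Cells missing in the input remain missing.  A test with fewer than
        4 usable rows is marked unavailable and its column is all-missing.

    Raises
    ------
    ValueError
        If a fitted test has zero residual variance (degenerate column
        perfectly explained by the age trend), or ``age`` is absent.
    """
    if "age" not in oriented.columns:
        raise ValueError("score table has no 'age' column")
    from .battery import COVARIATE_COLUMNS

    if battery is not None:
        cols = [c for c in battery.names if c in oriented.columns]
    else:
        cols = [c for c in oriented.columns if c not in COVARIATE_COLUMNS]

    age = np.asarray(oriented["age"], dtype=float)
    if not np.all(np.isfinite(age)) or np.any(age <= 0):
        raise ValueError("ages must be finite and positive")
    center = float(np.mean(age))
    age_c = age - center

    model = DetrendModel(age_center=center)
    t_out = pd.DataFrame(
        np.nan, index=oriented.index, columns=cols, dtype=float
    )
    for col in cols:
        y = np.asarray(oriented[col], dtype=float)
        ok = np.isfinite(y) & np.isfinite(age_c)
        n_fit = int(ok.sum())
        if n_fit < MIN_FIT_ROWS:
            model.tests[col] = TestDetrend(np.nan, np.nan, np.nan, np.nan, n_fit, False)
            msg = f"test {col!r}: only {n_fit} usable rows, column left missing"
            logger.warning(msg)
            warnings.warn(msg, stacklevel=2)
            continue
        if np.ptp(y[ok]) == 0.0:
            # scatterless test: every residual is 0, every T-score is the mean
            model.tests[col] = TestDetrend(float(y[ok][0]), 0.0, 0.0, 0.0, n_fit)
            vals = np.full(len(y), np.nan)
            vals[ok] = 50.0
            t_out[col] = vals
            continue
        X = _quad_design(age_c[ok])
        beta, *_ = np.linalg.lstsq(X, y[ok], rcond=None)
        resid = y[ok] - X @ beta
        sd = float(np.std(resid, ddof=1))
        # degenerate = residual scatter at rounding-error level vs the data scale
        if sd <= 1e-8 * float(np.std(y[ok], ddof=1)):
            raise ValueError(
                f"test {col!r}: zero residual variance after age detrending "
                "(degenerate column)"
            )
        model.tests[col] = TestDetrend(
            float(beta[0]), float(beta[1]), float(beta[2]), sd, n_fit
        )
        t = 50.0 + 10.0 * (resid - resid.mean()) / sd
        vals = np.full(len(y), np.nan)
        vals[ok] = t
        t_out[col] = vals
    return model, t_out


def standardize_scores(
    oriented: pd.DataFrame, battery: BatterySpec | None = None
) -> pd.DataFrame:
    """T-standardize oriented scores *without* age detrending.

    Useful for composites that should retain the raw-score age structure.
    Columns with zero variance raise; per-column sample mean/SD are used.
    """
    from .battery import COVARIATE_COLUMNS

    if battery is not None:
        cols = [c for c in battery.names if c in oriented.columns]
    else:
        cols = [c for c in oriented.columns if c not in COVARIATE_COLUMNS]
    out = pd.DataFrame(np.nan, index=oriented.index, columns=cols, dtype=float)
    for col in cols:
        y = np.asarray(oriented[col], dtype=float)
        ok = np.isfinite(y)
        sd = float(np.std(y[ok], ddof=1)) if ok.sum() > 1 else 0.0
        if sd == 0.0:
            raise ValueError(f"test {col!r}: zero variance, cannot standardize")
        vals = np.full(len(y), np.nan)
        vals[ok] = 50.0 + 10.0 * (y[ok] - y[ok].mean()) / sd
        out[col] = vals
    return out


def compute_dispersion(
    tscores: pd.DataFrame,
    battery: BatterySpec,
    min_fraction: float = 0.5,
) -> pd.DataFrame:
    """Per-participant dispersion (ISD) over broad, memory and executive profiles.

    ISD is the sample standard deviation (denominator n-1) of a
    participant's non-missing T-scores over the profile.  A profile with
    fewer than 2 scores yields a missing ISD.  Participants are flagged
    ``excluded`` when they completed fewer than ``min_fraction`` of the
    battery, or when their ISD-BP exceeds the included-group mean + 3 SD.

    Returns a frame indexed like ``tscores`` with columns ``isd_bp``,
    ``isd_mem``, ``isd_ef``, ``n_tests_bp/mem/ef``, ``excluded``,
    ``exclusion_reason``.
    """
    if not 0 < min_fraction <= 1:
        raise ValueError("min_fraction must be in (0, 1]")
    profiles = {
        "bp": [c for c in battery.names if c in tscores.columns],
        "mem": [c for c in battery.memory_tests if c in tscores.columns],
        "ef": [c for c in battery.executive_tests if c in tscores.columns],
    }
    out = pd.DataFrame(index=tscores.index)
    for key, cols in profiles.items():
        vals = tscores[cols].to_numpy(dtype=float)
        n = np.isfinite(vals).sum(axis=1)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            sd = np.nanstd(vals, axis=1, ddof=1)
        sd[n < 2] = np.nan
        out[f"isd_{key}"] = sd
        out[f"n_tests_{key}"] = n

    min_tests = min_fraction * len(battery)
    too_few = out["n_tests_bp"].to_numpy() < min_tests
    reasons = np.where(too_few, "insufficient_tests", "")

    included = out["isd_bp"].to_numpy(dtype=float).copy()
    included[too_few] = np.nan
    ok = np.isfinite(included)
    if ok.sum() >= 2:
        mu, sigma = included[ok].mean(), included[ok].std(ddof=1)
        outlier = np.isfinite(out["isd_bp"].to_numpy()) & (
            out["isd_bp"].to_numpy() > mu + 3.0 * sigma
        ) & ~too_few
        reasons = np.where(outlier, "isd_bp_outlier", reasons)
    out["excluded"] = reasons != ""
    out["exclusion_reason"] = reasons
    return out


def compute_composites(tscores: pd.DataFrame, battery: BatterySpec) -> pd.DataFrame:
    """Proxy domain composites: within-domain mean T, cohort z-scored.

    ``com_mem`` / ``com_ef`` are missing for participants with fewer than
    2 non-missing domain scores.  Raises on an empty domain or a
    zero-variance cohort (all participants identical).
    """
    out = pd.DataFrame(index=tscores.index)
    for key, domain in (("com_mem", "memory"), ("com_ef", "executive")):
        cols = [c for c in battery.domain_tests(domain) if c in tscores.columns]
        if not cols:
            raise ValueError(f"no {domain} tests present in the T-score matrix")
        vals = tscores[cols].to_numpy(dtype=float)
        n = np.isfinite(vals).sum(axis=1)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            m = np.nanmean(vals, axis=1)
        m[n < 2] = np.nan
        ok = np.isfinite(m)
        if ok.sum() < 2:
            raise ValueError(f"fewer than 2 participants with a {domain} composite")
        sd = m[ok].std(ddof=1)
        if sd == 0.0:
            raise ValueError(f"{domain} composite has zero variance across the cohort")
        out[key] = (m - m[ok].mean()) / sd
        out[f"n_tests_{key.split('_')[1]}"] = n
    return out


def residualize_on_age(score: np.ndarray, age: np.ndarray) -> np.ndarray:
    """OLS residuals of a score on [1, age_c, age_c^2].

    Missing entries (in score or age) propagate as missing residuals; at
    least 4 complete pairs are required.  Residuals are uncorrelated with
    the centered age terms by construction.
    """
    score = np.asarray(score, dtype=float)
    age = np.asarray(age, dtype=float)
    if score.shape != age.shape:
        raise ValueError("score and age must have the same length")
    ok = np.isfinite(score) & np.isfinite(age)
    if ok.sum() < MIN_FIT_ROWS:
        raise ValueError(f"need >= {MIN_FIT_ROWS} complete (score, age) pairs")
    age_c = age - age[ok].mean()
    X = _quad_design(age_c[ok])
    beta, *_ = np.linalg.lstsq(X, score[ok], rcond=None)
    out = np.full_like(score, np.nan)
    out[ok] = score[ok] - X @ beta
    return out


def correlation_table(
    variables: dict[str, np.ndarray],
    tails: dict[tuple[str, str], str] | None = None,
) -> pd.DataFrame:
    """Pairwise Pearson correlations on pairwise-complete observations.

    Parameters
    ----------
    variables
        Named vectors of equal length (missing allowed).
    tails
        Optional map from an (unordered) variable pair to a tail spec:
        ``"two"``, ``"one-negative"`` or ``"one-positive"``.  One-tailed
        p-values are halved when the observed r lies in the hypothesized
        direction and are ``1 - p/2`` otherwise.  Default: two-tailed.

    Returns a frame with columns ``var1, var2, r, n, p, tail``; pairs with
    fewer than 3 complete observations get missing r/p with a warning.
    """
    tails = tails or {}

    def tail_for(a: str, b: str) -> str:
        return tails.get((a, b), tails.get((b, a), "two"))

    names = list(variables)
    arrays = {k: np.asarray(v, dtype=float) for k, v in variables.items()}
    lengths = {a.shape[0] for a in arrays.values()}
    if len(lengths) != 1:
        raise ValueError("all variables must have the same length")

    rows = []
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            x, y = arrays[a], arrays[b]
            ok = np.isfinite(x) & np.isfinite(y)
            n = int(ok.sum())
            tail = tail_for(a, b)
            if n < 3:
                warnings.warn(
                    f"pair ({a}, {b}): only {n} complete observations, "
                    "correlation left missing",
                    stacklevel=2,
                )
                rows.append((a, b, np.nan, n, np.nan, tail))
                continue
            r, p_two = stats.pearsonr(x[ok], y[ok])
            if tail == "two":
                p = p_two
            elif tail in ("one-negative", "one-positive"):
                hypothesized_sign = -1.0 if tail == "one-negative" else 1.0
                p = p_two / 2.0 if r * hypothesized_sign >= 0 else 1.0 - p_two / 2.0
            else:
                raise ValueError(f"unknown tail spec {tail!r} for pair ({a}, {b})")
            rows.append((a, b, float(r), n, float(p), tail))
    return pd.DataFrame(rows, columns=["var1", "var2", "r", "n", "p", "tail"])


def default_tails(dispersion_vars: list[str], composite_vars: list[str]) -> dict:
    """One-tailed (negative) for dispersion-composite pairs, two-tailed else.

    More consistent performance is hypothesized to accompany better
    aggregate performance, so dispersion-composite correlations are tested
    one-tailed in the negative direction.
    """
    return {
        (d, c): "one-negative" for d in dispersion_vars for c in composite_vars
    }
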