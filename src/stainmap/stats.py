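"""Bootstrap Cohen's-d discriminability and group-level comparisons.

With only a handful of sections per ROI, a single Cohen's d is a noisy
summary. The bootstrap draws, with replacement, new per-section intensity
sets of the original group sizes (10,000 iterations by default) and
records Cohen's d for each draw; two conditions (CO vs myelin, outer vs
inner depths, individual vs probabilistic ROI definitions) are then
compared by a two-sample KS test between their bootstrap d distributions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps

logger = logging.getLogger(__name__)

DEFAULT_N_ITER = 10_000


def cohens_d(x: np.ndarray, y: np.ndarray) -> float:
    """Cohen's d with the unbiased pooled standard deviation.

    d = (mean(x) - mean(y)) / s_p, with
    s_p^2 = ((n_x - 1) s_x^2 + (n_y - 1) s_y^2) / (n_x + n_y - 2).
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size < 2 or y.size < 2:
        raise ValueError("need at least 2 values per group")
    sp2 = (((x.size - 1) * x.var(ddof=1) + (y.size - 1) * y.var(ddof=1))
           / (x.size + y.size - 2))
    if sp2 <= 0:
        raise ValueError("zero pooled standard deviation")
    return float((x.mean() - y.mean()) / np.sqrt(sp2))


def _batch_d(xs: np.ndarray, ys: np.ndarray) -> np.ndarray:
    """Cohen's d per row of two resample matrices."""
    nx, ny = xs.shape[1], ys.shape[1]
    vx = xs.var(axis=1, ddof=1)
    vy = ys.var(axis=1, ddof=1)
    sp2 = ((nx - 1) * vx + (ny - 1) * vy) / (nx + ny - 2)
    with np.errstate(divide="ignore", invalid="ignore"):
        return (xs.mean(axis=1) - ys.mean(axis=1)) / np.sqrt(sp2)


def bootstrap_cohens_d(x: np.ndarray, y: np.ndarray,
                       n_iter: int = DEFAULT_N_ITER, seed: int = 0,
                       max_redraws: int = 100) -> np.ndarray:
    """Bootstrap distribution of Cohen's d (group sizes preserved).

    Each iteration resamples |x| values from x and |y| values from y with
    replacement. Iterations with zero pooled SD are redrawn (up to
    ``max_redraws`` rounds, logged) so exactly ``n_iter`` values return.
    Deterministic in ``seed``; the per-group resampling streams are bound
    to the group *contents* rather than the argument order, so swapping
    the groups negates every d sample exactly.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size < 2 or y.size < 2:
        raise ValueError("need at least 2 values per group")
    if x.var() == 0 and y.var() == 0:
        raise ValueError("both groups constant: bootstrap d undefined")
    child_a, child_b = np.random.SeedSequence(seed).spawn(2)
    if (x.tobytes(), x.size) <= (y.tobytes(), y.size):
        rng_x, rng_y = np.random.default_rng(child_a), np.random.default_rng(child_b)
    else:
        rng_x, rng_y = np.random.default_rng(child_b), np.random.default_rng(child_a)
    xs = rng_x.choice(x, size=(n_iter, x.size), replace=True)
    ys = rng_y.choice(y, size=(n_iter, y.size), replace=True)
    d = _batch_d(xs, ys)
    bad = ~np.isfinite(d)
    rounds = 0
    while bad.any():
        rounds += 1
        if rounds > max_redraws:
            raise RuntimeError("could not draw non-degenerate bootstrap samples")
        k = int(bad.sum())
        logger.warning("redrawing %d degenerate bootstrap iterations", k)
        d[bad] = _batch_d(rng_x.choice(x, size=(k, x.size)),
                          rng_y.choice(y, size=(k, y.size)))
        bad = ~np.isfinite(d)
    return d


def ks_two_sample(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Two-sample KS: (sup ECDF distance, asymptotic p-value)."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size == 0 or y.size == 0:
        raise ValueError("empty input")
    res = sps.ks_2samp(x, y, method="asymp")
    return float(res.statistic), float(res.pvalue)


@dataclass
class EffectContrast:
    """Bootstrap d distributions of one ROI pair under two conditions."""

    roi_pair: tuple[str, str]
    condition_labels: tuple[str, str]
    d_samples: dict[str, np.ndarray]
    sample_d: dict[str, float]
    delta_d: float                 # mean d(cond1) - mean d(cond2)
    ks_distance: float
    ks_p: float
    seed: int


def contrast_discriminability(condition1: dict[str, np.ndarray],
                              condition2: dict[str, np.ndarray],
                              roi_pairs: list[tuple[str, str]],
                              condition_labels: tuple[str, str] = ("cond1", "cond2"),
                              n_iter: int = DEFAULT_N_ITER,
                              seed: int = 0) -> list[EffectContrast]:
    """Compare bootstrap-d distributions between two conditions per ROI pair.

    Both conditions of a pair use the same bootstrap seed, so identical
    condition data yield identical d distributions (KS distance 0).
    """
    out = []
    for k, (a, b) in enumerate(roi_pairs):
        for label, cond in zip(condition_labels, (condition1, condition2)):
            for roi in (a, b):
                if roi not in cond:
                    raise KeyError(
                        f"condition {label!r} is missing ROI {roi!r}")
        pair_seed = (seed * 1_000_003 + k) % (2 ** 31 - 1)
        d1 = bootstrap_cohens_d(condition1[a], condition1[b],
                                n_iter=n_iter, seed=pair_seed)
        d2 = bootstrap_cohens_d(condition2[a], condition2[b],
                                n_iter=n_iter, seed=pair_seed)
        ks_d, ks_p = ks_two_sample(d1, d2)
        out.append(EffectContrast(
            roi_pair=(a, b), condition_labels=condition_labels,
            d_samples={condition_labels[0]: d1, condition_labels[1]: d2},
            sample_d={condition_labels[0]: cohens_d(condition1[a], condition1[b]),
                      condition_labels[1]: cohens_d(condition2[a], condition2[b])},
            delta_d=float(d1.mean() - d2.mean()),
            ks_distance=ks_d, ks_p=ks_p, seed=pair_seed))
    return out


def contrasts_to_frame(contrasts: list[EffectContrast]) -> pd.DataFrame:
    rows = []
    for c in contrasts:
        rows.append({"roi_a": c.roi_pair[0], "roi_b": c.roi_pair[1],
                     "cond1": c.condition_labels[0],
                     "cond2": c.condition_labels[1],
                     "mean_d_cond1": float(c.d_samples[c.condition_labels[0]].mean()),
                     "mean_d_cond2": float(c.d_samples[c.condition_labels[1]].mean()),
                     "delta_d": c.delta_d, "ks_distance": c.ks_distance,
                     "ks_p": c.ks_p, "seed": c.seed})
    return pd.DataFrame(rows)


@dataclass
class GroupFit:
    """Normal fit to depth-profile values pooled across hemispheres."""

    roi: str
    values: np.ndarray             # n = bins x hemispheres
    mean: float
    sd: float
    n_hemispheres: int
    n_bins: int


def group_level_analysis(mean_profiles: dict[str, np.ndarray],
                         alpha: float = 0.05
                         ) -> tuple[dict[str, GroupFit], pd.DataFrame]:
    """Group-level normal fits and pairwise KS tests between ROIs.

    ``mean_profiles[roi]`` is an (n_hemispheres, n_bins) array of mean
    depth profiles. Values are pooled across hemispheres per ROI, fitted
    with a normal PDF (sample mean/SD), and compared pairwise with
    two-sample KS tests under a Bonferroni family-wise correction.
    """
    fits: dict[str, GroupFit] = {}
    bins = None
    for roi, prof in mean_profiles.items():
        arr = np.atleast_2d(np.asarray(prof, float))
        if arr.shape[0] < 2:
            raise ValueError("need at least 2 hemispheres")
        if bins is None:
            bins = arr.shape[1]
        elif arr.shape[1] != bins:
            raise ValueError("unequal bin counts across ROIs")
        pooled = arr.ravel()
        if pooled.var() == 0:
            raise ValueError(f"zero pooled variance for ROI {roi!r}")
        fits[roi] = GroupFit(roi=roi, values=pooled, mean=float(pooled.mean()),
                             sd=float(pooled.std(ddof=1)),
                             n_hemispheres=arr.shape[0], n_bins=bins)
    pairs = list(combinations(sorted(fits), 2))
    rows = []
    for a, b in pairs:
        d, p = ks_two_sample(fits[a].values, fits[b].values)
        rows.append({"roi_a": a, "roi_b": b, "ks_distance": d, "p": p})
    table = pd.DataFrame(rows)
    if len(table):
        m = len(table)
        table["p_bonferroni"] = np.minimum(table["p"] * m, 1.0)
        table["significant"] = table["p_bonferroni"] < alpha
    return fits, table
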