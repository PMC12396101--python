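"""Depth profiles, between-ROI statistics, and tangential 2D maps.

All staining statistics operate on *darkness*: 8-bit intensities rescaled
to [0, 1] with 0 = no staining and 1 = darkest staining (a linear flip,
``1 - raw/255``). The unit of analysis is the per-section, per-depth-bin
mean darkness inside an ROI; section-level summary intensities (mean over
all bins, or over the outer 7 / inner 8 bins) feed the t-tests and the
bootstrap effect sizes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .laminar import ColumnField, DepthField

logger = logging.getLogger(__name__)

OUTER_BINS = 7   # "outer layers" = depth bins 1..7 of 15
TOTAL_BINS = 15


def normalize_stain(image: np.ndarray) -> np.ndarray:
    """Rescale an 8-bit section to darkness in [0, 1] (1 = darkest stain)."""
    return 1.0 - np.asarray(image, float) / 255.0


@dataclass
class DepthProfile:
    """Per-section, per-depth-bin mean darkness for one ROI and stain."""

    roi: str
    stain: str
    matrix: np.ndarray            # (n_sections, n_bins)
    section_ids: list[int]
    excluded_sections: list[int] = field(default_factory=list)

    @property
    def n_bins(self) -> int:
        return self.matrix.shape[1]

    @property
    def n_sections(self) -> int:
        return self.matrix.shape[0]

    @property
    def mean(self) -> np.ndarray:
        return np.nanmean(self.matrix, axis=0)

    @property
    def sem(self) -> np.ndarray:
        n = np.sum(np.isfinite(self.matrix), axis=0)
        return np.nanstd(self.matrix, axis=0, ddof=1) / np.sqrt(n)


def depth_profile(darkness_sections: list[np.ndarray],
                  depth_fields: list[DepthField],
                  roi_masks: list[np.ndarray],
                  section_ids: list[int] | None = None,
                  roi: str = "", stain: str = "") -> DepthProfile:
    """Mean darkness per depth bin, per section, inside an ROI.

    Sections whose ROI does not intersect GM are excluded (and logged);
    bins an ROI misses within a kept section are NaN.
    """
    if section_ids is None:
        section_ids = list(range(len(darkness_sections)))
    rows, kept, excluded = [], [], []
    for dark, df, mask, sid in zip(darkness_sections, depth_fields,
                                   roi_masks, section_ids):
        m = np.asarray(mask, bool) & df.gm_mask
        if not m.any():
            excluded.append(sid)
            continue
        k = df.n_bins
        row = np.full(k, np.nan)
        b = df.bin_index[m]
        d = dark[m]
        for bi in range(1, k + 1):
            sel = b == bi
            if sel.any():
                row[bi - 1] = float(d[sel].mean())
        rows.append(row)
        kept.append(sid)
    if not rows:
        raise ValueError(f"ROI {roi!r} empty in all sections of stain {stain!r}")
    if excluded:
        logger.warning("ROI %s (%s): excluded sections with empty ROI: %s",
                       roi, stain, excluded)
    return DepthProfile(roi=roi, stain=stain, matrix=np.vstack(rows),
                        section_ids=kept, excluded_sections=excluded)


def laminar_similarity(profile_a: np.ndarray, profile_b: np.ndarray) -> float:
    """Pearson correlation between two mean laminar profiles."""
    a = np.asarray(profile_a, float)
    b = np.asarray(profile_b, float)
    if a.shape != b.shape:
        raise ValueError("profiles must have equal bin counts")
    if a.std() == 0 or b.std() == 0:
        raise ValueError("zero variance profile")
    return float(np.corrcoef(a, b)[0, 1])


def outer_inner_means(profile: DepthProfile,
                      split: int | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Per-section mean darkness of the outer (bins 1..split) and inner bins.

    The default split follows the upper-seven / lower-eight convention and
    therefore requires 15 bins.
    """
    if split is None:
        if profile.n_bins != TOTAL_BINS:
            raise ValueError("default 7/8 split requires 15 depth bins; "
                             "pass an explicit split otherwise")
        split = OUTER_BINS
    outer = np.nanmean(profile.matrix[:, :split], axis=1)
    inner = np.nanmean(profile.matrix[:, split:], axis=1)
    return outer, inner


def section_intensities(profile: DepthProfile, scope: str = "all",
                        split: int | None = None) -> np.ndarray:
    """Section-level summary intensity: mean over bins in ``scope``."""
    if scope == "all":
        return np.nanmean(profile.matrix, axis=1)
    outer, inner = outer_inner_means(profile, split=split)
    if scope == "outer":
        return outer
    if scope == "inner":
        return inner
    raise ValueError(f"unknown scope {scope!r}")


def compare_patches_ttest(values_a: np.ndarray, values_b: np.ndarray
                          ) -> tuple[float, int, float]:
    """Classical pooled-variance unpaired two-sample t-test: (t, df, p)."""
    a = np.asarray(values_a, float)
    b = np.asarray(values_b, float)
    a, b = a[np.isfinite(a)], b[np.isfinite(b)]
    if a.size < 2 or b.size < 2:
        raise ValueError("need at least 2 sections per ROI")
    res = sps.ttest_ind(a, b, equal_var=True)
    return float(res.statistic), a.size + b.size - 2, float(res.pvalue)


def fdr_correct(pvalues, q: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up: (rejected, adjusted p)."""
    rej, p_adj, _, _ = multipletests(np.asarray(pvalues, float),
                                     alpha=q, method="fdr_bh")
    return rej, p_adj


def compare_patch_family(profiles: dict[str, DepthProfile],
                         pairs: list[tuple[str, str]] | None = None,
                         scopes: tuple[str, ...] = ("all", "outer", "inner"),
                         q: float = 0.05) -> pd.DataFrame:
    """All requested pairwise comparisons with one BH family correction."""
    if pairs is None:
        pairs = list(combinations(sorted(profiles), 2))
    rows = []
    for a, b in pairs:
        for scope in scopes:
            t, df, p = compare_patches_ttest(
                section_intensities(profiles[a], scope),
                section_intensities(profiles[b], scope))
            rows.append({"roi_a": a, "roi_b": b, "scope": scope,
                         "t": t, "df": df, "p": p})
    out = pd.DataFrame(rows)
    rej, p_adj = fdr_correct(out["p"].to_numpy(), q=q)
    out["p_fdr"] = p_adj
    out["significant"] = rej
    return out


@dataclass
class TangentialMap:
    """Depth-collapsed darkness on normalized tangential position x section."""

    grid: np.ndarray                      # (n_sections, n_positions)
    positions: np.ndarray                 # common normalized axis in [0, 1]
    section_ids: list[int]
    roi_spans: dict[str, list[tuple[float, float] | None]]  # per ROI, per row


def build_tangential_map(darkness_sections: list[np.ndarray],
                         column_fields: list[ColumnField],
                         roi_masks: dict[str, list[np.ndarray]] | None = None,
                         section_ids: list[int] | None = None,
                         n_positions: int = 100) -> TangentialMap:
    """Collapse depth per columnar bin and concatenate length-normalized rows.

    For every section, darkness is averaged over all depth bins within each
    columnar bin, bin centers are rescaled to [0, 1] by the section's
    mid-layer arc length, and values are linearly interpolated onto a
    common tangential grid. ROI outlines are carried through as normalized
    spans per row.
    """
    if not column_fields:
        raise ValueError("no column fields given")
    if section_ids is None:
        section_ids = list(range(len(darkness_sections)))
    positions = np.linspace(0.0, 1.0, n_positions)
    rows = []
    spans: dict[str, list] = {k: [] for k in (roi_masks or {})}
    for s, (dark, cf) in enumerate(zip(darkness_sections, column_fields)):
        ids = np.unique(cf.bin_index[cf.bin_index >= 0])
        if ids.size == 0:
            raise ValueError(f"section {section_ids[s]} has no valid columns")
        centers = (ids + 0.5) * cf.bin_width_px / cf.total_length_px
        vals = np.array([float(dark[cf.bin_index == b].mean()) for b in ids])
        rows.append(np.interp(positions, np.clip(centers, 0, 1), vals))
        for name, masks in (roi_masks or {}).items():
            m = np.asarray(masks[s], bool) & cf.roi_mask
            if m.any():
                nv = cf.normalized[m]
                spans[name].append((float(np.nanmin(nv)), float(np.nanmax(nv))))
            else:
                spans[name].append(None)
    return TangentialMap(grid=np.vstack(rows), positions=positions,
                         section_ids=list(section_ids), roi_spans=spans)


@dataclass
class FaceNonfaceResult:
    differences: dict[str, np.ndarray]    # per ROI: darkness - non-face mean
    mean_difference: dict[str, float]
    tests: pd.DataFrame                   # pairwise t-tests across ROIs, FDR
    dropped_bins: dict[str, int]


def face_vs_nonface(tmap: TangentialMap, guard: float = 0.0,
                    q: float = 0.05) -> FaceNonfaceResult:
    """Positional subtraction of non-face intensity from each face ROI.

    At each normalized tangential position, the non-face intensity is the
    mean over sections whose cortex at that position lies outside every ROI
    (plus an optional guard margin); each ROI bin's difference is its
    darkness minus that positional non-face mean, which cancels any purely
    tangential gradient. ROI differences are then compared pairwise with
    pooled t-tests under one BH correction.
    """
    n_rows, n_pos = tmap.grid.shape
    in_roi = {name: np.zeros((n_rows, n_pos), bool) for name in tmap.roi_spans}
    for name, spans in tmap.roi_spans.items():
        for r, span in enumerate(spans):
            if span is not None:
                lo, hi = span[0] - guard, span[1] + guard
                in_roi[name][r] = (tmap.positions >= lo) & (tmap.positions <= hi)
    any_roi = np.zeros((n_rows, n_pos), bool)
    for m in in_roi.values():
        any_roi |= m

    nonface_mean = np.full(n_pos, np.nan)
    for g in range(n_pos):
        rows = ~any_roi[:, g]
        if rows.any():
            nonface_mean[g] = tmap.grid[rows, g].mean()

    diffs, dropped = {}, {}
    for name, m in in_roi.items():
        rr, gg = np.nonzero(m)
        ok = np.isfinite(nonface_mean[gg])
        dropped[name] = int(np.count_nonzero(~ok))
        if dropped[name]:
            logger.warning("ROI %s: dropped %d bins with no matched non-face "
                           "position", name, dropped[name])
        diffs[name] = tmap.grid[rr[ok], gg[ok]] - nonface_mean[gg[ok]]

    rows = []
    for a, b in combinations(sorted(diffs), 2):
        if diffs[a].size >= 2 and diffs[b].size >= 2:
            t, df, p = compare_patches_ttest(diffs[a], diffs[b])
            rows.append({"roi_a": a, "roi_b": b, "t": t, "df": df, "p": p})
    tests = pd.DataFrame(rows)
    if len(tests):
        rej, p_adj = fdr_correct(tests["p"].to_numpy(), q=q)
        tests["p_fdr"] = p_adj
        tests["significant"] = rej
    return FaceNonfaceResult(
        differences=diffs,
        mean_difference={k: float(v.mean()) if v.size else float("nan")
                         for k, v in diffs.items()},
        tests=tests, dropped_bins=dropped)
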