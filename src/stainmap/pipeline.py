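"""End-to-end orchestration of the reconstruction and profiling pipeline.

Stage order mirrors the acquisition-to-statistics workflow: segment ->
serial-align -> drift-correct -> stack -> align-reference -> project-roi
-> depth-bins -> profiles -> stats -> bootstrap -> map2d. Every stochastic
stage takes an explicit seed from the configuration; given one
configuration the whole run is deterministic.
"""

from __future__ import annotations

import hashlib
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as smio
from .core import STAIN_CO, STAIN_MYELIN
from .laminar import columnar_distance, equivolume_depth
from .phantom import default_config, generate_phantom
from .profiles import (build_tangential_map, compare_patch_family,
                       depth_profile, face_vs_nonface, normalize_stain,
                       section_intensities)
from .registration import correct_intensity_drift, serial_align, stack_to_volume
from .segmentation import segment_section
from .stats import contrast_discriminability, contrasts_to_frame
from .volume import align_volumes, extend_roi_across_depth, validate_alignment

logger = logging.getLogger(__name__)

STAGES = ["segment", "serial-align", "drift-correct", "stack",
          "align-reference", "project-roi", "depth-bins", "profiles",
          "stats", "bootstrap", "map2d"]


@dataclass
class RunConfig:
    """Serializable configuration for a full pipeline run."""

    output_dir: str = "stainmap_out"
    input_mode: str = "phantom"            # phantom | section-directory
    section_dir: str | None = None
    # phantom parameters
    n_sections: int = 30
    section_spacing_um: float = 50.0
    phantom_seed: int = 0
    misalignment_deg: float = 4.0
    misalignment_px: float = 8.0
    noise_sd: float = 0.01
    roi_jitter_px: float = 16.0
    roi_dilation_px: int = 0
    # analysis parameters
    n_bins: int = 15
    outer_split: int = 7
    column_width_px: float = 20.0
    columnar_bin_width_px: float = 5.0
    max_rotation_deg: float = 10.0
    align_reference: bool = True
    nonlinear: bool = False
    n_iter: int = 10_000
    bootstrap_seed: int = 1
    null_seed: int = 2
    fdr_q: float = 0.05
    include_al_afad_pair: bool = False     # AL/AF-AD pair in bootstrap contrasts
    map_positions: int = 100

    def validate(self) -> None:
        for name in ("phantom_seed", "bootstrap_seed", "null_seed"):
            v = getattr(self, name)
            if v is None or not isinstance(v, (int, np.integer)):
                raise ValueError(f"config requires an explicit integer {name}")
        if self.input_mode not in ("phantom", "section-directory"):
            raise ValueError(f"unknown input_mode {self.input_mode!r}")
        if self.input_mode == "section-directory" and not self.section_dir:
            raise ValueError("section-directory mode requires section_dir")

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(yaml.safe_dump(asdict(self), sort_keys=True))
        return path

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text())
        cfg = cls(**data)
        cfg.validate()
        return cfg


@dataclass
class RunManifest:
    config: dict
    stages: list[dict] = field(default_factory=list)
    versions: dict = field(default_factory=dict)
    output_hashes: dict = field(default_factory=dict)
    failed_stage: str | None = None
    error: str | None = None


@dataclass
class RunResult:
    manifest: RunManifest
    context: dict
    output_dir: Path


def _hash_file(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _versions() -> dict:
    import scipy
    import skimage

    from . import __version__
    return {"stainmap": __version__, "numpy": np.__version__,
            "scipy": scipy.__version__, "scikit-image": skimage.__version__,
            "pandas": pd.__version__}


# ---------------------------------------------------------------- stages

def _prepare_input(cfg: RunConfig, ctx: dict) -> None:
    if cfg.input_mode == "phantom":
        pcfg = default_config(
            n_sections=cfg.n_sections, seed=cfg.phantom_seed,
            section_spacing_um=cfg.section_spacing_um,
            misalignment_amplitude=(cfg.misalignment_deg, cfg.misalignment_px),
            noise_sd=cfg.noise_sd, roi_jitter_px=cfg.roi_jitter_px,
            roi_dilation_px=cfg.roi_dilation_px)
        ds = generate_phantom(pcfg)
        ctx["dataset"] = ds
        ctx["sections"] = ds.sections
        ctx["reference_volume"] = ds.reference_volume
        ctx["roi_masks"] = ds.roi_masks
        ctx["roi_masks_jittered"] = ds.roi_masks_jittered
    else:
        ctx["sections"] = smio.load_sections(cfg.section_dir)
        ctx["dataset"] = None
        ctx["reference_volume"] = None
        ctx["roi_masks"] = {}
        ctx["roi_masks_jittered"] = {}


def _stage_segment(cfg: RunConfig, ctx: dict, out: Path) -> None:
    ctx["segmentations"] = [segment_section(s) for s in ctx["sections"]]
    smio.save_label_stack([s.labels for s in ctx["segmentations"]],
                          out / "labels.tif")


def _stage_serial_align(cfg: RunConfig, ctx: dict, out: Path) -> None:
    aln = serial_align(ctx["sections"], segmentations=ctx["segmentations"],
                       max_rotation=cfg.max_rotation_deg)
    ctx["alignment"] = aln
    smio.save_transforms(aln.transforms, out / "transforms.json")
    # carry truth ROI masks into the aligned frame if running on a phantom:
    # the reference keeps the clean frame, so masks apply directly
    ctx["aligned_segs"] = aln.aligned_segmentations


def _stain_indices(ctx: dict, stain: str) -> list[int]:
    return [i for i, s in enumerate(ctx["sections"]) if s.stain == stain]


def _stage_drift(cfg: RunConfig, ctx: dict, out: Path) -> None:
    aln = ctx["alignment"]
    corrected = [None] * len(ctx["sections"])
    ctx["drift_models"] = {}
    for stain in (STAIN_CO, STAIN_MYELIN):
        idx = _stain_indices(ctx, stain)
        if len(idx) < 3:
            continue
        imgs = [aln.aligned_images[i] for i in idx]
        masks = [ctx["aligned_segs"][i].labels > 0 for i in idx]
        fixed, model = correct_intensity_drift(imgs, masks, section_indices=idx)
        for i, im in zip(idx, fixed):
            corrected[i] = im
        ctx["drift_models"][stain] = model
        pd.DataFrame({"section": model.section_indices,
                      "raw_mean": model.raw_means,
                      "fitted_mean": model.fitted_means,
                      "corrected_mean": model.fitted_means}).to_csv(
            out / f"drift_{stain}.csv", index=False)
    for i, im in enumerate(corrected):
        if im is None:
            corrected[i] = aln.aligned_images[i]
    ctx["corrected_images"] = corrected


def _stage_stack(cfg: RunConfig, ctx: dict, out: Path) -> None:
    sec0 = ctx["sections"][0]
    ctx["volumes"] = {}
    for stain in (STAIN_CO, STAIN_MYELIN):
        idx = _stain_indices(ctx, stain)
        if not idx:
            continue
        # same-stain spacing: alternating stains double the cutting interval
        spacing = 2 * cfg.section_spacing_um
        vol = stack_to_volume([ctx["corrected_images"][i] for i in idx],
                              spacing_um=spacing,
                              pixel_size_um=sec0.pixel_size_um, stain=stain)
        ctx["volumes"][stain] = (vol, idx)
        mm = sec0.pixel_size_um / 1000.0
        smio.save_nifti(vol.data, out / f"volume_{stain}.nii.gz", (mm, mm, mm))


def _stage_align_reference(cfg: RunConfig, ctx: dict, out: Path) -> None:
    """Affine-align each stain volume to the structural reference, validate.

    Correlations are computed on darkness: the shared tissue texture makes
    corresponding histology/reference slices correlate above the null of
    non-corresponding pairs regardless of each stain's GM/WM polarity.
    """
    ctx["alignment_reports"] = {}
    ctx["volume_transforms"] = {}
    if ctx.get("reference_volume") is None or not cfg.align_reference:
        return
    ref = np.asarray(ctx["reference_volume"])
    sec0 = ctx["sections"][0]
    for stain, (vol, idx) in ctx["volumes"].items():
        ref_stack = stack_to_volume([ref[i] for i in idx],
                                    spacing_um=2 * cfg.section_spacing_um,
                                    pixel_size_um=sec0.pixel_size_um,
                                    stain=stain)
        brain = vol.data > 0
        # per-stain contrast polarity: CO as intensity (WM bright, like
        # T1), myelin as darkness (WM dark in intensity, bright flipped)
        if stain == STAIN_CO:
            moving = np.where(brain, vol.data / 255.0, 0.0)
        else:
            moving = np.where(brain, 1.0 - vol.data / 255.0, 0.0)
        tf = align_volumes(moving, ref_stack.data, nonlinear=cfg.nonlinear,
                           iterations=(50, 25, 10), sampling_fraction=0.5,
                           sampling_seed=cfg.null_seed + 1)
        ctx["volume_transforms"][stain] = tf
        aligned = tf.resample_into_reference(moving, ref_stack.data.shape)
        # validate at original-section slices: interpolated slices are
        # mixtures of neighbors and would blur the correspondence signal
        js = sorted(vol.section_slices.values())
        report = validate_alignment(aligned[js], ref_stack.data[js],
                                    axis=0, seed=cfg.null_seed)
        ctx["alignment_reports"][stain] = report
        pd.DataFrame({"slice": np.arange(report.correlations.size),
                      "r": report.correlations}).to_csv(
            out / f"alignment_{stain}.csv", index=False)


def _stage_project_roi(cfg: RunConfig, ctx: dict, out: Path) -> None:
    """Restrict section-space ROI masks to GM and extend across full depth.

    Depth fields are computed here (cached for the depth-bins stage)
    because the perpendicular extension follows cortical columns.
    """
    segs = ctx["aligned_segs"]
    ctx["depth_fields"] = [equivolume_depth(s, n_bins=cfg.n_bins,
                                            column_width_px=cfg.column_width_px)
                           for s in segs]
    summary = {}
    for key in ("roi_masks", "roi_masks_jittered"):
        projected = {}
        for name, masks in ctx.get(key, {}).items():
            proj = []
            for m, df in zip(masks, ctx["depth_fields"]):
                proj.append(extend_roi_across_depth(m, df)
                            if np.asarray(m).any() else np.zeros_like(m))
            projected[name] = proj
            summary[f"{key}:{name}"] = int(sum(int(p.sum()) for p in proj))
        ctx[key + "_projected"] = projected
    smio.save_json(summary, out / "roi_projection.json")


def _stage_depth_bins(cfg: RunConfig, ctx: dict, out: Path) -> None:
    smio.save_label_stack([df.bin_index.astype(np.uint16)
                           for df in ctx["depth_fields"]],
                          out / "depth_bins.tif")


def _stage_profiles(cfg: RunConfig, ctx: dict, out: Path) -> None:
    dark = [normalize_stain(im) for im in ctx["corrected_images"]]
    ctx["darkness"] = dark
    profs: dict[str, dict[str, object]] = {}
    rows = []
    for roi_key, tag in (("roi_masks_projected", "individual"),
                         ("roi_masks_jittered_projected", "probabilistic")):
        for stain in (STAIN_CO, STAIN_MYELIN):
            idx = _stain_indices(ctx, stain)
            for name, masks in ctx.get(roi_key, {}).items():
                try:
                    prof = depth_profile([dark[i] for i in idx],
                                         [ctx["depth_fields"][i] for i in idx],
                                         [masks[i] for i in idx],
                                         section_ids=idx, roi=name, stain=stain)
                except ValueError:
                    continue
                profs.setdefault(tag, {}).setdefault(stain, {})[name] = prof
                for r, sid in enumerate(prof.section_ids):
                    for b in range(prof.n_bins):
                        rows.append({"definition": tag, "roi": name,
                                     "stain": stain, "section": sid,
                                     "bin": b + 1,
                                     "darkness": prof.matrix[r, b]})
    ctx["profiles"] = profs
    pd.DataFrame(rows).to_csv(out / "profiles.csv", index=False)


def _stage_stats(cfg: RunConfig, ctx: dict, out: Path) -> None:
    tables = []
    for stain in (STAIN_CO, STAIN_MYELIN):
        group = ctx["profiles"].get("individual", {}).get(stain, {})
        if len(group) < 2:
            continue
        tab = compare_patch_family(group, q=cfg.fdr_q)
        tab.insert(0, "stain", stain)
        tables.append(tab)
    ctx["ttests"] = pd.concat(tables, ignore_index=True) if tables else \
        pd.DataFrame()
    ctx["ttests"].to_csv(out / "ttests.csv", index=False)


def _roi_pairs(cfg: RunConfig, rois) -> list[tuple[str, str]]:
    pairs = [("ML", "AL"), ("ML", "AFAD")]
    if cfg.include_al_afad_pair:
        pairs.append(("AL", "AFAD"))
    return [(a, b) for a, b in pairs if a in rois and b in rois]


def _stage_bootstrap(cfg: RunConfig, ctx: dict, out: Path) -> None:
    profs = ctx["profiles"]
    ind = profs.get("individual", {})
    prob = profs.get("probabilistic", {})
    contrasts = []

    def intensities(group, scope="all"):
        split = cfg.outer_split if scope != "all" else None
        return {name: section_intensities(p, scope, split=split)
                for name, p in group.items()}

    if STAIN_CO in ind and STAIN_MYELIN in ind:
        pairs = _roi_pairs(cfg, set(ind[STAIN_CO]) & set(ind[STAIN_MYELIN]))
        contrasts += contrast_discriminability(
            intensities(ind[STAIN_CO]), intensities(ind[STAIN_MYELIN]),
            pairs, ("co", "myelin"), cfg.n_iter, cfg.bootstrap_seed)
    for stain in (STAIN_CO, STAIN_MYELIN):
        if stain in ind:
            pairs = _roi_pairs(cfg, set(ind[stain]))
            contrasts += contrast_discriminability(
                intensities(ind[stain], "outer"),
                intensities(ind[stain], "inner"),
                pairs, (f"{stain}-outer", f"{stain}-inner"),
                cfg.n_iter, cfg.bootstrap_seed + 1)
        if stain in ind and stain in prob:
            pairs = _roi_pairs(cfg, set(ind[stain]) & set(prob[stain]))
            contrasts += contrast_discriminability(
                intensities(ind[stain]), intensities(prob[stain]),
                pairs, (f"{stain}-individual", f"{stain}-probabilistic"),
                cfg.n_iter, cfg.bootstrap_seed + 2)
    ctx["contrasts"] = contrasts
    contrasts_to_frame(contrasts).to_csv(out / "contrasts.csv", index=False)


def _stage_map2d(cfg: RunConfig, ctx: dict, out: Path) -> None:
    ctx["tangential_maps"] = {}
    ctx["face_nonface"] = {}
    roi_masks = ctx.get("roi_masks", {})
    for stain in (STAIN_CO, STAIN_MYELIN):
        idx = _stain_indices(ctx, stain)
        cfs, dark, kept = [], [], []
        for i in idx:
            seg = ctx["aligned_segs"][i]
            df = ctx["depth_fields"][i]
            try:
                cf = columnar_distance(seg, seg.gm_mask, df,
                                       bin_width_px=cfg.columnar_bin_width_px)
            except Exception as exc:  # disconnected ribbon in this section
                logger.warning("map2d: skipping section %d (%s)", i, exc)
                continue
            cfs.append(cf)
            dark.append(ctx["darkness"][i])
            kept.append(i)
        if not cfs:
            continue
        masks = {name: [m[i] for i in kept] for name, m in roi_masks.items()}
        tmap = build_tangential_map(dark, cfs, roi_masks=masks,
                                    section_ids=kept,
                                    n_positions=cfg.map_positions)
        ctx["tangential_maps"][stain] = tmap
        result = face_vs_nonface(tmap, q=cfg.fdr_q)
        ctx["face_nonface"][stain] = result
        pd.DataFrame(tmap.grid,
                     index=pd.Index(kept, name="section")).to_csv(
            out / f"map2d_{stain}.csv")
        if len(result.tests):
            result.tests.to_csv(out / f"face_nonface_{stain}.csv", index=False)


_STAGE_FNS = {
    "segment": _stage_segment,
    "serial-align": _stage_serial_align,
    "drift-correct": _stage_drift,
    "stack": _stage_stack,
    "align-reference": _stage_align_reference,
    "project-roi": _stage_project_roi,
    "depth-bins": _stage_depth_bins,
    "profiles": _stage_profiles,
    "stats": _stage_stats,
    "bootstrap": _stage_bootstrap,
    "map2d": _stage_map2d,
}


def run_pipeline(config: RunConfig, upto: str | None = None) -> RunResult:
    """Run the pipeline (optionally only up to a named stage).

    The manifest is written even on failure, identifying the failing
    stage. Deterministic stages recompute bit-identically from the same
    configuration, so re-running any prefix reproduces the full run's
    artifacts for those stages.
    """
    config.validate()
    if upto is not None and upto not in STAGES:
        raise ValueError(f"unknown stage {upto!r}")
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "config.yaml")
    manifest = RunManifest(config=asdict(config), versions=_versions())
    ctx: dict = {}
    try:
        _prepare_input(config, ctx)
        for name in STAGES:
            fn = _STAGE_FNS[name]
            t0 = time.perf_counter()
            fn(config, ctx, out)
            manifest.stages.append(
                {"name": name, "status": "completed",
                 "wall_time_s": round(time.perf_counter() - t0, 3)})
            if name == upto:
                break
    except Exception as exc:
        manifest.failed_stage = (manifest.stages[-1]["name"] + "/next"
                                 if manifest.stages else "input")
        failing = STAGES[len(manifest.stages)] if len(manifest.stages) < len(STAGES) \
            else "unknown"
        manifest.failed_stage = failing
        manifest.error = f"{type(exc).__name__}: {exc}"
        _write_manifest(manifest, out)
        raise
    for p in sorted(out.iterdir()):
        if p.suffix in (".csv", ".json", ".yaml") and p.name != "manifest.json":
            manifest.output_hashes[p.name] = _hash_file(p)
    _write_manifest(manifest, out)
    return RunResult(manifest=manifest, context=ctx, output_dir=out)


def _write_manifest(manifest: RunManifest, out: Path) -> None:
    smio.save_json(asdict(manifest), out / "manifest.json")
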