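"""Readers/writers for the pipeline's on-disk artifacts.

Sections are 8-bit grayscale TIFFs named ``<stain>_<index:04d>.tif``;
volumes are NIfTI-1 with correct pixdim; transforms and ground truth are
JSON; tables are CSV.
"""

from __future__ import annotations

import json
import re
from pathlib import Path

import nibabel as nib
import numpy as np
import tifffile

from .core import StainSection
from .transforms import RigidTransform2D

_SECTION_RE = re.compile(r"^(?P<stain>[a-z]+)_(?P<index>\d{4})\.tif$")


def save_sections(sections: list[StainSection], directory: str | Path) -> list[Path]:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    for sec in sections:
        p = directory / f"{sec.stain}_{sec.index:04d}.tif"
        tifffile.imwrite(p, np.asarray(sec.image, np.uint8))
        paths.append(p)
    return paths


def load_sections(directory: str | Path,
                  pixel_size_um: float = 25.0) -> list[StainSection]:
    directory = Path(directory)
    out = []
    for p in sorted(directory.glob("*.tif")):
        m = _SECTION_RE.match(p.name)
        if not m:
            continue
        out.append(StainSection(image=tifffile.imread(p),
                                stain=m.group("stain"),
                                index=int(m.group("index")),
                                pixel_size_um=pixel_size_um))
    out.sort(key=lambda s: s.index)
    return out


def save_nifti(volume: np.ndarray, path: str | Path,
               voxel_size_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)) -> Path:
    """Write a (slice, row, col) array as NIfTI-1 with the given pixdim."""
    path = Path(path)
    affine = np.diag([*voxel_size_mm[::-1], 1.0])
    img = nib.Nifti1Image(np.asarray(volume, np.float32).T, affine)
    img.header.set_zooms(voxel_size_mm[::-1])
    nib.save(img, path)
    return path


def load_nifti(path: str | Path) -> np.ndarray:
    img = nib.load(str(path))
    return np.asarray(img.get_fdata()).T


def save_transforms(transforms: list[RigidTransform2D], path: str | Path) -> Path:
    path = Path(path)
    payload = [t.to_dict() for t in transforms]
    path.write_text(json.dumps(payload, indent=1, sort_keys=True))
    return path


def load_transforms(path: str | Path) -> list[RigidTransform2D]:
    return [RigidTransform2D.from_dict(d)
            for d in json.loads(Path(path).read_text())]


def save_json(obj, path: str | Path) -> Path:
    path = Path(path)
    path.write_text(json.dumps(obj, indent=1, sort_keys=True, default=_default))
    return path


def _default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")


def save_mask_stack(masks: list[np.ndarray], path: str | Path) -> Path:
    path = Path(path)
    tifffile.imwrite(path, np.stack([np.asarray(m, np.uint8) * 255
                                     for m in masks]))
    return path


def save_label_stack(labels: list[np.ndarray], path: str | Path) -> Path:
    path = Path(path)
    tifffile.imwrite(path, np.stack([np.asarray(l, np.uint16) for l in labels]))
    return path
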