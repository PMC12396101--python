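"""Shared fixtures: small phantoms, analytic sections, one full pipeline run."""

import numpy as np
import pytest

from stainmap.core import LABEL_GM, LABEL_WM, SegmentedSection
from stainmap.laminar import equivolume_depth
from stainmap.phantom import default_config, generate_phantom, render_annulus_section
from stainmap.pipeline import RunConfig, run_pipeline
from stainmap.segmentation import boundary_masks

ANNULUS_R_IN = 40.0
ANNULUS_R_OUT = 80.0


@pytest.fixture(scope="session")
def annulus():
    """Analytic annulus fixture with a linear radial profile."""
    sec, seg = render_annulus_section(ANNULUS_R_IN, ANNULUS_R_OUT,
                                      lambda d: 0.45 + 0.25 * np.asarray(d))
    return sec, seg


@pytest.fixture(scope="session")
def annulus_depth(annulus):
    _, seg = annulus
    return equivolume_depth(seg, n_bins=15)


@pytest.fixture(scope="session")
def slab():
    """Straight horizontal cortical ribbon: GM slab over a WM slab."""
    lab = np.zeros((60, 160), np.uint8)
    lab[10:40, 5:155] = LABEL_GM
    lab[40:55, 5:155] = LABEL_WM
    outer, inner = boundary_masks(lab)
    return SegmentedSection(labels=lab, outer_boundary=outer,
                            inner_boundary=inner)


@pytest.fixture(scope="session")
def phantom_small():
    """12-section phantom with all nuisance processes enabled."""
    return generate_phantom(default_config(n_sections=12, seed=7))


@pytest.fixture(scope="session")
def phantom_clean():
    """12-section phantom with no misalignment, drift, noise, or texture."""
    return generate_phantom(default_config(
        n_sections=12, seed=7, misalignment_amplitude=(0.0, 0.0),
        drift_quad=(0.0, 0.0, 0.0), drift_hf_amplitude=0.0, noise_sd=0.0,
        texture_amplitude=0.0))


@pytest.fixture(scope="session")
def e2e_run(tmp_path_factory):
    """One full standard-conditions pipeline run, shared across tests."""
    out = tmp_path_factory.mktemp("e2e")
    cfg = RunConfig(output_dir=str(out), n_sections=30, phantom_seed=0,
                    bootstrap_seed=1, null_seed=2, n_iter=10_000)
    return run_pipeline(cfg)
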