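"""Shared fixtures: desk-scale study conditions and cached pipeline runs.

The synthetic pairs are 256x256 images at 4 um/px (structure scale and
edge density proportionate, after downscaling, to slide tissue at the
resolutions where registration is typically run).  Prealignment operates
at ~32 um/px (8x downsampled) and the deformable control grid is 17x17
nodes (~64 um spacing, coarser than both the pixels and the blobs).
Pipeline runs are session-scoped because several tests interrogate the
same registration result.
"""

from __future__ import annotations

import numpy as np
import pytest

import histovar as hv
from histovar.registration import _pyramid_for

SPACING_UM = 4.0
EXTENT_UM = (255 * SPACING_UM, 255 * SPACING_UM)
PREALIGN_SPACING_UM = 32.0
GRID_NODES = (17, 17)


def desk_config() -> hv.RegistrationConfig:
    cfg = hv.RegistrationConfig()
    cfg.prealign.target_spacing_um = PREALIGN_SPACING_UM
    cfg.deformable.grid_nodes = GRID_NODES
    return cfg


def run_steps(pair, config=None):
    """Run the three steps, returning (rigid, affine, grid, diagnostics)."""
    cfg = config or desk_config()
    ref_pyr = _pyramid_for(pair.reference, cfg.prealign.target_spacing_um)
    tmpl_pyr = _pyramid_for(pair.template, cfg.prealign.target_spacing_um)
    rigid = hv.prealign(ref_pyr, tmpl_pyr, cfg.prealign, cfg.optimizer)
    affine = hv.register_affine(ref_pyr, tmpl_pyr, rigid, cfg.affine, cfg.optimizer)
    diag: dict = {}
    grid = hv.register_deformable(ref_pyr, tmpl_pyr, affine, cfg.deformable,
                                  cfg.optimizer, diag)
    return rigid, affine, grid, diag


def smooth_pair(seed: int = 7, kind: str = "restained") -> hv.SynthPair:
    spec = hv.SynthSpec(seed=seed, pair_kind=kind)
    spec.deformation = hv.smooth_deformation(5.0, 40.0, seed + 4, EXTENT_UM,
                                             SPACING_UM)
    return hv.make_pair(spec)


@pytest.fixture(scope="session")
def restained_pair():
    """Restained-like pair with a smooth 5 px bump field (seed 7)."""
    return smooth_pair(7, "restained")


@pytest.fixture(scope="session")
def consecutive_pair():
    """Consecutive-like pair (30% dropout) with a smooth bump field."""
    return smooth_pair(8, "consecutive")


@pytest.fixture(scope="session")
def restained_result(restained_pair):
    return run_steps(restained_pair)


@pytest.fixture(scope="session")
def consecutive_result(consecutive_pair):
    return run_steps(consecutive_pair)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
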