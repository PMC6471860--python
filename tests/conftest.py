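"""Shared fixtures: small noise-free phantoms and synthetic annulus sections.

Phantom fixtures are session-scoped — rasterization and segmentation are
the expensive steps and every module downstream of them can share one
instance because nothing mutates them.
"""

from __future__ import annotations

import numpy as np
import pytest
from scipy import ndimage

from awvct import imaging_io
from awvct.airway_seg import find_trachea_seed, grow_airway_tree
from awvct.phantom import PhantomSpec, build_tree_spec, rasterize_phantom
from awvct.skeleton_graph import (
    build_branch_graph,
    main_bifurcation_children,
    partition_subtrees,
    prune_spurs,
    skeletonize_mask,
)

CRISP = dict(blur_sigma_mm=0.0, noise_sd_hu=0.0)


@pytest.fixture(scope="session")
def tree3():
    return build_tree_spec(3)


@pytest.fixture(scope="session")
def crisp_spec():
    return PhantomSpec(shape=(160, 160, 144), **CRISP)


@pytest.fixture(scope="session")
def crisp_phantom(tree3, crisp_spec):
    """Depth-3 phantom, no blur/noise/emphysema: (ct, lumen, wall, lung)."""
    return rasterize_phantom(tree3, crisp_spec)


@pytest.fixture(scope="session")
def emph_phantom(tree3):
    """Depth-3 phantom with a 30% emphysema voxel fraction."""
    spec = PhantomSpec(shape=(160, 160, 144), emphysema_fraction=0.30, **CRISP)
    return spec, rasterize_phantom(tree3, spec)


@pytest.fixture(scope="session")
def crisp_airway_mask(crisp_phantom):
    ct = crisp_phantom[0]
    return grow_airway_tree(ct, find_trachea_seed(ct))


@pytest.fixture(scope="session")
def crisp_graph(crisp_phantom, crisp_spec):
    """Partitioned branch graph of the crisp depth-3 phantom truth lumen."""
    lumen = crisp_phantom[1]
    g = prune_spurs(build_branch_graph(skeletonize_mask(lumen), crisp_spec.spacing), 2.0)
    rul, rmll = main_bifurcation_children(g)
    return partition_subtrees(g, rul, rmll)


def make_annulus(
    r_mm: float,
    wall_mm: float,
    res_mm: float = 0.1,
    sigma_mm: float = 0.6,
    size_mm: float = 40.0,
    hu_lumen: float = -1000.0,
    hu_wall: float = 0.0,
    hu_outside: float = -870.0,
) -> np.ndarray:
    """A blurred annular cross-section image with known lumen radius."""
    n = int(size_mm / res_mm) + 1
    c = (n - 1) / 2.0
    ii, jj = np.meshgrid(np.arange(n), np.arange(n), indexing="ij")
    d = np.hypot(ii - c, jj - c) * res_mm
    img = np.full((n, n), float(hu_outside))
    img[d <= r_mm + wall_mm] = hu_wall
    img[d <= r_mm] = hu_lumen
    if sigma_mm > 0:
        img = ndimage.gaussian_filter(img, sigma_mm / res_mm)
    return img


@pytest.fixture(scope="session")
def annulus_factory():
    return make_annulus
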