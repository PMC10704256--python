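"""Synthetic stained-section image pairs with known ground truth.

Real inputs are pairs of bright-field slide scans: either *restained*
sections (the same physical tissue stained twice, so structures
correspond one-to-one but intensities map differently) or *consecutive*
sections (neighboring slices, where a fraction of structures has no
counterpart).  This module emulates both regimes at desk scale:
nucleus-like Gaussian blobs are scattered over a dark background, two
renderings with different monotone intensity mappings and per-blob
contrast stand in for the two stains, and a known rigid, affine, or
smooth nonlinear deformation relates the two images.  Blob centers
shared by both renderings become exact ground-truth landmark pairs.

Defaults — 256 x 256 pixels at 4 um/px, 60 blobs of ~6 px mean radius,
30% structural dropout for consecutive-like pairs — give images with
edge density and structure scale comparable (after downscaling) to
tissue at the resolutions where slide registration is typically run,
while keeping every test seconds-fast.  Everything is driven by a
seeded generator: the same spec yields bit-identical pairs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .evaluation import LandmarkSet
from .imgio import Image
from .transforms import (
    AffineTransform,
    DeformationGrid,
    RigidTransform,
    sample_bilinear,
)

__all__ = [
    "SynthSpec",
    "SynthPair",
    "SectionImage",
    "SmoothDeformation",
    "smooth_deformation",
    "make_section",
    "render_stains",
    "make_pair",
]


@dataclass
class SmoothDeformation:
    """Analytic smooth displacement field: a sum of Gaussian bumps.

    ``y(x) = x + sum_b a_b * exp(-|x - c_b|^2 / (2 sigma^2))`` with bump
    centers ``c_b`` (um), vector amplitudes ``a_b`` (um), and a shared
    width ``sigma_um``.  Being closed-form, it can be evaluated (and
    differentiated) at any point, which makes it usable as an oracle.
    Fold-freeness is guaranteed when ``max_b |a_b| < 0.3 * sigma`` per
    bump triple (the displacement gradient then stays well below 1).
    """

    centers: np.ndarray  # (n_bumps, 2) um
    amplitudes: np.ndarray  # (n_bumps, 2) um
    sigma_um: float

    def __post_init__(self) -> None:
        self.centers = np.atleast_2d(np.asarray(self.centers, dtype=np.float64))
        self.amplitudes = np.atleast_2d(np.asarray(self.amplitudes, dtype=np.float64))
        if self.centers.shape != self.amplitudes.shape or self.centers.shape[1] != 2:
            raise ValueError("centers and amplitudes must be matching (n, 2) arrays")
        self.sigma_um = float(self.sigma_um)
        if not self.sigma_um > 0:
            raise ValueError("sigma_um must be positive")

    def displacement(self, points) -> np.ndarray:
        p = np.asarray(points, dtype=np.float64)
        u = np.zeros_like(p)
        for c, a in zip(self.centers, self.amplitudes):
            d2 = np.sum((p - c) ** 2, axis=-1)
            u = u + a * np.exp(-d2 / (2.0 * self.sigma_um ** 2))[..., None]
        return u

    def map_points(self, points) -> np.ndarray:
        p = np.asarray(points, dtype=np.float64)
        return p + self.displacement(p)

    def inverse_map(self, points, n_iter: int = 40) -> np.ndarray:
        """Fixed-point inversion x = z - u(x); contractive under the
        amplitude guard."""
        z = np.asarray(points, dtype=np.float64)
        x = z.copy()
        for _ in range(n_iter):
            x = z - self.displacement(x)
        return x

    def to_grid(self, grid_shape, domain_extent, origin=(0.0, 0.0)) -> DeformationGrid:
        """Sample the analytic field on a nodal control grid."""
        grid = DeformationGrid(np.zeros((*grid_shape, 2)), domain_extent, origin)
        grid.node_displacements = self.displacement(grid.node_positions())
        return grid


def smooth_deformation(amplitude_px: float, sigma_px: float, seed: int,
                       extent_um: tuple[float, float], spacing_um: float = 1.0,
                       n_bumps: int = 3) -> SmoothDeformation:
    """Seeded random bump field over a domain, fold-free by construction."""
    if amplitude_px < 0:
        raise ValueError("amplitude_px must be nonnegative")
    if sigma_px <= 0:
        raise ValueError("sigma_px must be positive")
    if amplitude_px >= 0.3 * sigma_px:
        raise ValueError(
            f"amplitude {amplitude_px} px too large for sigma {sigma_px} px: "
            f"require amplitude < 0.3 * sigma so the field cannot fold"
        )
    rng = np.random.default_rng(seed)
    lo, hi = 0.25, 0.75  # keep bumps inside the central region
    centers = rng.uniform(lo, hi, size=(n_bumps, 2)) * np.asarray(extent_um)
    direction = rng.normal(size=(n_bumps, 2))
    direction /= np.linalg.norm(direction, axis=1, keepdims=True)
    scale = rng.uniform(0.5, 1.0, size=(n_bumps, 1)) * amplitude_px * spacing_um
    return SmoothDeformation(centers, direction * scale, sigma_px * spacing_um)


@dataclass
class SynthSpec:
    """Recipe for one synthetic section pair."""

    seed: int = 0
    size: tuple[int, int] = (256, 256)  # (rows, cols)
    n_blobs: int = 60
    blob_radius_px: float = 6.0
    spacing_um: float = 4.0
    pair_kind: str = "restained"  # or "consecutive"
    dropout_fraction: float = 0.3  # consecutive only
    deformation: object = None  # None | Rigid | Affine | SmoothDeformation

    def __post_init__(self) -> None:
        if self.pair_kind not in ("restained", "consecutive"):
            raise ValueError(f"unknown pair_kind {self.pair_kind!r}")
        if self.pair_kind == "restained":
            self.dropout_fraction = 0.0
        if not (0 <= self.dropout_fraction < 1):
            raise ValueError("dropout_fraction must lie in [0, 1)")
        if self.n_blobs < 0:
            raise ValueError("n_blobs must be nonnegative")


@dataclass
class SectionImage(Image):
    """Rendered section carrying its blob bookkeeping."""

    blob_centers_um: np.ndarray = field(default_factory=lambda: np.zeros((0, 2)))
    blob_radii_um: np.ndarray = field(default_factory=lambda: np.zeros(0))
    blob_intensities: np.ndarray = field(default_factory=lambda: np.zeros(0))


@dataclass
class SynthPair:
    reference: Image
    template: Image
    true_transform: object  # maps reference coords -> template coords
    landmarks: LandmarkSet


def _render_blobs(shape, spacing_um, centers_um, radii_um, intensities) -> np.ndarray:
    """Sum of Gaussian radial profiles, evaluated over local windows."""
    nr, nc = shape
    data = np.zeros((nr, nc))
    for (cx, cy), rho, amp in zip(centers_um, radii_um, intensities):
        cut = 3.5 * rho
        j_lo = max(0, int(np.floor((cx - cut) / spacing_um)))
        j_hi = min(nc, int(np.ceil((cx + cut) / spacing_um)) + 1)
        i_lo = max(0, int(np.floor((cy - cut) / spacing_um)))
        i_hi = min(nr, int(np.ceil((cy + cut) / spacing_um)) + 1)
        if j_lo >= j_hi or i_lo >= i_hi:
            continue
        x = np.arange(j_lo, j_hi) * spacing_um
        y = np.arange(i_lo, i_hi) * spacing_um
        d2 = (x[None, :] - cx) ** 2 + (y[:, None] - cy) ** 2
        data[i_lo:i_hi, j_lo:j_hi] += amp * np.exp(-d2 / (2.0 * rho ** 2))
    return np.clip(data, 0.0, 255.0)


def make_section(spec: SynthSpec) -> SectionImage:
    """Scatter nucleus-like blobs over a zero background (seeded).

    Blob centers are placed in a central disc so that the rotations and
    deformations applied later keep the structure inside the frame.
    """
    nr, nc = spec.size
    spacing = spec.spacing_um
    extent = ((nc - 1) * spacing, (nr - 1) * spacing)
    rng = np.random.default_rng(spec.seed)
    max_r = 0.42 * min(extent)
    if spec.n_blobs > 0 and 3 * spec.blob_radius_px * spacing > max_r:
        raise ValueError(
            f"blobs of radius {spec.blob_radius_px} px cannot fit a "
            f"{spec.size} image"
        )
    mid = np.array(extent) / 2.0
    radii = rng.uniform(0.6, 1.4, spec.n_blobs) * spec.blob_radius_px * spacing
    # dart-throwing placement in a central disc: nuclei are disjoint
    # objects, and non-overlapping blobs keep the two stain renderings
    # structurally identical (per-blob contrast changes cannot bend
    # gradient directions where profiles would overlap)
    centers = np.zeros((spec.n_blobs, 2))
    placed = 0
    for attempt in range(200 * max(spec.n_blobs, 1)):
        if placed == spec.n_blobs:
            break
        theta = rng.uniform(0, 2 * np.pi)
        rad = max_r * np.sqrt(rng.uniform())
        cand = mid + rad * np.array([np.cos(theta), np.sin(theta)])
        if placed:
            gap = np.linalg.norm(centers[:placed] - cand, axis=1)
            if np.any(gap < 1.1 * (radii[:placed] + radii[placed])):
                continue
        centers[placed] = cand
        placed += 1
    if placed < spec.n_blobs:
        raise ValueError(
            f"could only place {placed} of {spec.n_blobs} non-overlapping "
            f"blobs in a {spec.size} image"
        )
    intensities = rng.uniform(90.0, 220.0, spec.n_blobs)
    data = _render_blobs(spec.size, spacing, centers, radii, intensities)
    return SectionImage(data, spacing, (0.0, 0.0),
                        blob_centers_um=centers,
                        blob_radii_um=radii,
                        blob_intensities=intensities)


def _stain_response(amplitudes: np.ndarray, gamma: float) -> np.ndarray:
    """Monotone intensity remapping standing in for a stain's response.

    The response acts on the blobs' peak intensities (how strongly each
    object takes up the stain), leaving the spatial profile untouched: a
    pointwise remap of the *image* would rescale every Gaussian blob's
    width by 1/sqrt(gamma) and thereby change the geometry, which is
    exactly what restained sections do not do.
    """
    return 255.0 * (np.clip(amplitudes, 0, 255) / 255.0) ** gamma


def render_stains(section: SectionImage, pair_kind: str = "restained",
                  seed: int = 0, dropout_fraction: float = 0.3):
    """Render a section under two different 'stains'.

    Both renderings keep the structure (blob centers, radii) but remap
    intensities monotonically and rescale each blob's contrast, mimicking
    multimodal appearance.  For ``consecutive`` pairs a seeded fraction
    of blobs is dropped from the second rendering and replaced by new
    blobs that exist only there, mimicking structures without
    correspondence in a neighboring slice.

    Returns ``(stain_a, stain_b, shared_centers_um)`` where the shared
    centers are the landmark candidates present in both renderings.
    """
    rng = np.random.default_rng(seed)
    n = len(section.blob_centers_um)
    # both stains see the same per-object uptake (it is the same tissue);
    # each applies its own global monotone response plus mild (~15%)
    # per-object staining variability
    amp_a = _stain_response(section.blob_intensities * rng.uniform(0.85, 1.0, n), 0.8)
    amp_b = _stain_response(section.blob_intensities * rng.uniform(0.85, 1.0, n), 1.4)
    keep = np.ones(n, dtype=bool)
    extra = 0
    if pair_kind == "consecutive":
        n_drop = int(round(dropout_fraction * n)) if n else 0
        drop = rng.choice(n, size=n_drop, replace=False) if n_drop else []
        keep[drop] = False
        extra = n_drop
    data_a = _render_blobs(section.shape, section.spacing_um,
                           section.blob_centers_um, section.blob_radii_um, amp_a)
    centers_b = section.blob_centers_um[keep]
    radii_b = section.blob_radii_um[keep]
    amps_b = amp_b[keep]
    if extra:
        # replacement structures present only in the second section
        extent = section.extent_um
        mid = np.array(extent) / 2.0
        theta = rng.uniform(0, 2 * np.pi, extra)
        rad = 0.42 * min(extent) * np.sqrt(rng.uniform(0, 1, extra))
        new_centers = mid + np.stack([rad * np.cos(theta), rad * np.sin(theta)],
                                     axis=1)
        centers_b = np.vstack([centers_b, new_centers])
        radii_b = np.concatenate([
            radii_b,
            rng.uniform(0.6, 1.4, extra) * np.mean(section.blob_radii_um) if n
            else rng.uniform(0.6, 1.4, extra),
        ])
        amps_b = np.concatenate([amps_b, rng.uniform(60.0, 200.0, extra)])
    data_b = _render_blobs(section.shape, section.spacing_um,
                           centers_b, radii_b, amps_b)
    stain_a = SectionImage(data_a, section.spacing_um, section.origin,
                           blob_centers_um=section.blob_centers_um,
                           blob_radii_um=section.blob_radii_um,
                           blob_intensities=amp_a)
    stain_b = SectionImage(data_b, section.spacing_um, section.origin,
                           blob_centers_um=centers_b,
                           blob_radii_um=radii_b,
                           blob_intensities=amps_b)
    return stain_a, stain_b, section.blob_centers_um[keep]


class _Identity:
    def map_points(self, points):
        return np.asarray(points, dtype=np.float64)


def _inverse_of(transform):
    if transform is None or isinstance(transform, _Identity):
        return _Identity()
    if isinstance(transform, RigidTransform):
        from .transforms import promote

        return promote(transform).inverse()
    if isinstance(transform, AffineTransform):
        return transform.inverse()
    if isinstance(transform, SmoothDeformation):
        class _Inv:
            def __init__(self, fwd):
                self.fwd = fwd

            def map_points(self, points):
                return self.fwd.inverse_map(points)

        return _Inv(transform)
    raise TypeError(f"cannot invert a {type(transform).__name__}")


def make_pair(spec: SynthSpec) -> SynthPair:
    """Generate a reference/template pair with exact ground truth.

    The reference is the first stain rendering; the template is the
    second rendering resampled at the inverse of the true transform, so
    that ``true_transform`` maps reference coordinates onto template
    coordinates exactly.  Landmark pairs are the shared blob centers
    ``r_k`` and their images ``t_k = y(r_k)``.
    """
    if isinstance(spec.deformation, SmoothDeformation):
        amp = float(np.max(np.linalg.norm(spec.deformation.amplitudes, axis=1)))
        if amp >= 0.3 * spec.deformation.sigma_um:
            raise ValueError(
                "smooth deformation amplitude too large relative to sigma; "
                "the fixture field could fold"
            )
    section = make_section(spec)
    stain_a, stain_b, shared = render_stains(section, spec.pair_kind, spec.seed + 1,
                                             spec.dropout_fraction)
    transform = spec.deformation if spec.deformation is not None else _Identity()
    inv = _inverse_of(transform)
    # template(z) = stain_b(y^{-1}(z)), sampled bilinearly on the same grid
    z = stain_a.pixel_centers()
    template = Image(sample_bilinear(stain_b, inv.map_points(z)),
                     stain_a.spacing_um, stain_a.origin)
    reference = Image(stain_a.data, stain_a.spacing_um, stain_a.origin)
    if len(shared) == 0:
        raise ValueError("no shared blobs left to serve as landmarks")
    landmarks = LandmarkSet(shared, transform.map_points(shared))
    return SynthPair(reference, template, transform, landmarks)
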