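"""Image containers, slide loading, and multilevel pyramids.

Registration operates on single-channel floating-point images in the
inverted bright-field convention: tissue is bright, the glass background
is 0.  Physical coordinates are used throughout: the center of pixel
``(i, j)`` (row ``i``, column ``j``) sits at
``origin + (j * spacing_um, i * spacing_um)`` with points ordered
``(x, y) = (column direction, row direction)`` in micrometers.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "Image",
    "ImagePyramid",
    "load_image",
    "save_image",
    "to_registration_gray",
    "build_pyramid",
]

#: ITU-R 601 luma weights used for the color -> gray conversion.
GRAY_WEIGHTS = (0.299, 0.587, 0.114)


@dataclass
class Image:
    """A 2-D scalar image with uniform physical pixel spacing.

    Parameters
    ----------
    data
        2-D array of intensities (converted to float64).
    spacing_um
        Physical pixel size h in micrometers per pixel, identical in
        both dimensions.
    origin
        Physical ``(x, y)`` coordinate of the center of pixel (0, 0),
        in micrometers.
    """

    data: np.ndarray
    spacing_um: float
    origin: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 2:
            raise ValueError(f"image data must be 2-D, got shape {self.data.shape}")
        if self.data.shape[0] < 2 or self.data.shape[1] < 2:
            raise ValueError(
                f"image must be at least 2x2 (gradients must be computable), "
                f"got {self.data.shape}"
            )
        if not np.all(np.isfinite(self.data)):
            raise ValueError("image intensities must be finite")
        self.spacing_um = float(self.spacing_um)
        if not (self.spacing_um > 0):
            raise ValueError(f"spacing_um must be positive, got {self.spacing_um}")
        self.origin = (float(self.origin[0]), float(self.origin[1]))

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    @property
    def n_pixels(self) -> int:
        return self.data.size

    @property
    def extent_um(self) -> tuple[float, float]:
        """Physical (width, height) spanned by the pixel centers."""
        nr, nc = self.data.shape
        return ((nc - 1) * self.spacing_um, (nr - 1) * self.spacing_um)

    def pixel_centers(self) -> np.ndarray:
        """Physical coordinates of all pixel centers, shape (rows, cols, 2)."""
        nr, nc = self.data.shape
        x = self.origin[0] + np.arange(nc) * self.spacing_um
        y = self.origin[1] + np.arange(nr) * self.spacing_um
        xx, yy = np.meshgrid(x, y)
        return np.stack([xx, yy], axis=-1)


@dataclass
class ImagePyramid:
    """Ordered multilevel representation, level 0 finest.

    Each level halves the resolution: spacing doubles and the row and
    column counts are the ceiling of half the previous level's.
    """

    levels: list[Image] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.levels:
            raise ValueError("pyramid needs at least one level")
        for k in range(1, len(self.levels)):
            prev, cur = self.levels[k - 1], self.levels[k]
            if not math.isclose(cur.spacing_um, 2.0 * prev.spacing_um, rel_tol=1e-9):
                raise ValueError(
                    f"level {k} spacing {cur.spacing_um} is not twice level "
                    f"{k - 1} spacing {prev.spacing_um}"
                )
            expect = (math.ceil(prev.shape[0] / 2), math.ceil(prev.shape[1] / 2))
            if cur.shape != expect:
                raise ValueError(
                    f"level {k} shape {cur.shape} != ceil-half of level "
                    f"{k - 1} shape {prev.shape}"
                )

    @property
    def n_levels(self) -> int:
        return len(self.levels)

    def __getitem__(self, level: int) -> Image:
        return self.levels[level]

    def closest_level(self, target_spacing_um: float) -> int:
        """Index of the level whose spacing is closest to the target (log scale)."""
        gaps = [
            abs(math.log(lv.spacing_um) - math.log(target_spacing_um))
            for lv in self.levels
        ]
        return int(np.argmin(gaps))


def to_registration_gray(rgb: np.ndarray, spacing_um: float = 1.0,
                         origin: tuple[float, float] = (0.0, 0.0)) -> Image:
    """Convert an 8-bit RGB array to the inverted grayscale convention.

    ``gray = round(0.299 R + 0.587 G + 0.114 B)``; the returned intensity
    is ``255 - gray`` so a white slide background maps to 0 and tissue is
    bright.  Already-gray (2-D) input is rejected rather than passed
    through: callers must be explicit about which convention their data
    is in.
    """
    rgb = np.asarray(rgb)
    if rgb.ndim != 3 or rgb.shape[2] != 3:
        raise ValueError(
            f"expected an RGB array of shape (rows, cols, 3), got {rgb.shape}"
        )
    w = np.asarray(GRAY_WEIGHTS)
    gray = np.rint(rgb[..., 0] * w[0] + rgb[..., 1] * w[1] + rgb[..., 2] * w[2])
    return Image(255.0 - gray, spacing_um, origin)


def _read_array(path: Path, level: int) -> np.ndarray:
    suffix = path.suffix.lower()
    if suffix in (".tif", ".tiff", ".btf"):
        import tifffile

        with tifffile.TiffFile(str(path)) as tf:
            series = tf.series[0]
            pyramid_levels = getattr(series, "levels", [series])
            if level >= len(pyramid_levels):
                raise IndexError(
                    f"level {level} not present in {path.name} "
                    f"({len(pyramid_levels)} level(s) available)"
                )
            return np.asarray(pyramid_levels[level].asarray())
    # flat raster formats expose only level 0
    if level != 0:
        raise IndexError(
            f"level {level} requested, but {path.name} is a flat file with a "
            f"single level"
        )
    from PIL import Image as PILImage

    with PILImage.open(path) as im:
        return np.asarray(im)


def load_image(path: str | Path, level: int = 0,
               spacing_um_level0: float = 1.0) -> Image:
    """Load a slide image at the requested pyramid level.

    Reads pyramidal/flat TIFF and PNG.  The spacing of level ``L`` is
    ``spacing_um_level0 * 2**L``.  Color input is converted with
    :func:`to_registration_gray`; single-channel input is used as-is
    (assumed already in the inverted convention).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    if level < 0:
        raise IndexError(f"level must be non-negative, got {level}")
    arr = _read_array(path, level)
    if arr.ndim == 3 and arr.shape[2] == 4:  # drop alpha
        arr = arr[..., :3]
    spacing = float(spacing_um_level0) * (2.0 ** level)
    if arr.ndim == 3:
        return to_registration_gray(arr, spacing)
    if arr.ndim != 2:
        raise ValueError(f"unsupported image payload of shape {arr.shape}")
    return Image(np.asarray(arr, dtype=np.float64), spacing)


def save_image(image: Image, path: str | Path) -> None:
    """Write an image to disk; PNG as clipped 8-bit, TIFF as float32."""
    path = Path(path)
    if path.suffix.lower() == ".png":
        from PIL import Image as PILImage

        arr = np.clip(np.rint(image.data), 0, 255).astype(np.uint8)
        PILImage.fromarray(arr).save(path)
    else:
        import tifffile

        tifffile.imwrite(str(path), image.data.astype(np.float32))


def _block_mean_halve(a: np.ndarray) -> np.ndarray:
    """2x2 block mean; a trailing odd row/column is averaged over the
    pixels actually present."""
    nr, nc = a.shape
    ridx = np.arange(0, nr, 2)
    cidx = np.arange(0, nc, 2)
    s = np.add.reduceat(np.add.reduceat(a, ridx, axis=0), cidx, axis=1)
    rcnt = np.minimum(2, nr - ridx)
    ccnt = np.minimum(2, nc - cidx)
    return s / np.outer(rcnt, ccnt)


def build_pyramid(image: Image, n_levels: int) -> ImagePyramid:
    """Build a multilevel pyramid by repeated 2x2 block averaging.

    Level L+1 pixel centers sit at the mean position of their 2x2 block,
    so the origin shifts by half the parent spacing per level and physical
    coordinates remain comparable across levels.
    """
    if n_levels < 1:
        raise ValueError(f"n_levels must be >= 1, got {n_levels}")
    min_dim = min(image.shape)
    if math.ceil(min_dim / 2 ** (n_levels - 1)) < 2:
        raise ValueError(
            f"n_levels={n_levels} too large: coarsest level of a "
            f"{image.shape} image would have < 2 pixels per dimension"
        )
    levels = [image]
    for _ in range(n_levels - 1):
        prev = levels[-1]
        data = _block_mean_halve(prev.data)
        shift = prev.spacing_um / 2.0
        levels.append(
            Image(
                data,
                2.0 * prev.spacing_um,
                (prev.origin[0] + shift, prev.origin[1] + shift),
            )
        )
    return ImagePyramid(levels)
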