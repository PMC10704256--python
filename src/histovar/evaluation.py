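"""Landmark-based registration accuracy: TRE, MTRE, resolution sweeps.

A landmark pair consists of a point ``r_k`` in the reference image and
the corresponding point ``t_k`` in the template image, both in physical
micrometers.  Since transforms map reference coordinates to template
coordinates, the target registration error of a pair is
``TRE_k = || y(r_k) - t_k ||_2`` and MTRE is the median over all pairs
(mean of the two central values for even counts).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .imgio import Image, ImagePyramid
from .registration import (
    RegistrationConfig,
    prealign,
    register_affine,
    register_deformable,
)
from .transforms import count_folds

__all__ = [
    "LandmarkSet",
    "TreReport",
    "compute_tre",
    "read_landmark_points",
    "write_landmark_points",
    "read_landmarks",
    "write_landmarks",
    "resolution_sweep",
]


@dataclass
class LandmarkSet:
    """Paired reference/template landmarks in physical micrometers."""

    ref_points: np.ndarray  # (n, 2), um
    tmpl_points: np.ndarray  # (n, 2), um

    def __post_init__(self) -> None:
        self.ref_points = np.atleast_2d(np.asarray(self.ref_points, dtype=np.float64))
        self.tmpl_points = np.atleast_2d(np.asarray(self.tmpl_points, dtype=np.float64))
        if self.ref_points.shape != self.tmpl_points.shape or self.ref_points.shape[1] != 2:
            raise ValueError("ref and template landmarks must be matching (n, 2) arrays")
        if self.ref_points.shape[0] < 1:
            raise ValueError("landmark set must contain at least one pair")
        if not (np.all(np.isfinite(self.ref_points))
                and np.all(np.isfinite(self.tmpl_points))):
            raise ValueError("landmark coordinates must be finite")

    def __len__(self) -> int:
        return self.ref_points.shape[0]


@dataclass
class TreReport:
    per_landmark_um: np.ndarray
    mtre_um: float
    n: int


def compute_tre(landmarks: LandmarkSet, transform=None) -> TreReport:
    """Target registration error of each pair after applying a transform.

    ``transform=None`` evaluates the raw (pre-registration) distances.
    """
    if len(landmarks) < 1:
        raise ValueError("empty landmark set")
    mapped = landmarks.ref_points if transform is None else transform.map_points(
        landmarks.ref_points)
    err = np.linalg.norm(mapped - landmarks.tmpl_points, axis=1)
    return TreReport(err, float(np.median(err)), len(landmarks))


def read_landmark_points(path: str | Path, spacing_um: float = 1.0) -> np.ndarray:
    """Read one landmark CSV (header then ``index,X,Y``; X = column pixel,
    Y = row pixel, 0-based, at level 0) into physical (x, y) um."""
    path = Path(path)
    df = pd.read_csv(path)
    if df.shape[1] < 3:
        raise ValueError(f"{path.name}: expected columns index,X,Y")
    if df.shape[0] < 1:
        raise ValueError(f"{path.name}: file contains no landmarks")
    try:
        pts = df.iloc[:, 1:3].to_numpy(dtype=np.float64)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"{path.name}: malformed landmark row: {exc}") from exc
    if not np.all(np.isfinite(pts)):
        bad = int(np.where(~np.all(np.isfinite(pts), axis=1))[0][0])
        raise ValueError(f"{path.name}: malformed landmark at data line {bad + 1}")
    return pts * float(spacing_um)


def write_landmark_points(points: np.ndarray, path: str | Path,
                          spacing_um: float = 1.0) -> None:
    """Write physical (x, y) um points as an ``index,X,Y`` pixel CSV."""
    pts = np.atleast_2d(np.asarray(points, dtype=np.float64)) / float(spacing_um)
    df = pd.DataFrame({"index": np.arange(len(pts)), "X": pts[:, 0], "Y": pts[:, 1]})
    df.to_csv(path, index=False)


def read_landmarks(ref_path: str | Path, tmpl_path: str | Path,
                   spacing_um: float = 1.0) -> LandmarkSet:
    """Read a pair of landmark CSVs (same dialect, same ordering)."""
    return LandmarkSet(read_landmark_points(ref_path, spacing_um),
                       read_landmark_points(tmpl_path, spacing_um))


def write_landmarks(landmarks: LandmarkSet, ref_path: str | Path,
                    tmpl_path: str | Path, spacing_um: float = 1.0) -> None:
    write_landmark_points(landmarks.ref_points, ref_path, spacing_um)
    write_landmark_points(landmarks.tmpl_points, tmpl_path, spacing_um)


def resolution_sweep(ref_source: Image | ImagePyramid,
                     tmpl_source: Image | ImagePyramid,
                     landmarks: LandmarkSet,
                     spacing_list,
                     config: RegistrationConfig | None = None) -> pd.DataFrame:
    """Accuracy of the affine and deformable steps across finest resolutions.

    Runs the pipeline once per requested finest spacing (prealignment is
    resolution-fixed and computed once, at the coarsest requested run's
    configuration) and reports MTRE after step 2 and step 3, their ratio,
    and the fold count.  A failing row is reported with NaNs and the
    sweep continues.
    """
    import copy

    from .registration import _pyramid_for  # shared level plumbing

    config = config or RegistrationConfig()
    ref_pyr = _pyramid_for(ref_source, config.prealign.target_spacing_um)
    tmpl_pyr = _pyramid_for(tmpl_source, config.prealign.target_spacing_um)
    rigid = prealign(ref_pyr, tmpl_pyr, config.prealign, config.optimizer)
    rows = []
    for spacing in sorted(spacing_list, reverse=True):
        row = {"spacing_um": float(spacing), "mtre_affine_um": np.nan,
               "mtre_deformable_um": np.nan, "affine_deformable_ratio": np.nan,
               "fold_count": np.nan}
        try:
            cfg = copy.deepcopy(config)
            cfg.affine.finest_spacing_um = float(spacing)
            cfg.deformable.finest_spacing_um = float(spacing)
            affine = register_affine(ref_pyr, tmpl_pyr, rigid, cfg.affine,
                                     cfg.optimizer)
            grid = register_deformable(ref_pyr, tmpl_pyr, affine, cfg.deformable,
                                       cfg.optimizer)
            mtre_aff = compute_tre(landmarks, affine).mtre_um
            mtre_def = compute_tre(landmarks, grid).mtre_um
            row.update(
                mtre_affine_um=mtre_aff,
                mtre_deformable_um=mtre_def,
                affine_deformable_ratio=mtre_aff / mtre_def if mtre_def > 0 else np.inf,
                fold_count=count_folds(grid),
            )
        except Exception as exc:
            row["error"] = str(exc)
        rows.append(row)
    return pd.DataFrame(rows)
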