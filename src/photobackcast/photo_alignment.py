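"""Affine registration of repeat photographs from manually selected tie points.

The historical photograph is warped onto the repeat photograph's pixel grid
(the repeat frame is the reference), using a least-squares affine estimated
from control-point pairs marking unchanging landscape features (summits,
boulders). Labels are categorical, so resampling is strictly nearest-neighbour.
"""

from __future__ import annotations

import csv
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from ._core import ClassifiedImage

__all__ = [
    "AffineTransform",
    "TiePointSet",
    "PhotoPair",
    "ResidualSummary",
    "DegenerateGeometryError",
    "estimate_affine",
    "apply_transform",
    "alignment_residuals",
]

#: Fill label written to pixels that have no source (always paired with valid=False).
FILL_LABEL = 0


class DegenerateGeometryError(ValueError):
    """Tie-point configuration too degenerate (collinear / too few) to solve."""


@dataclass(frozen=True)
class AffineTransform:
    """Six-parameter affine map ``(x, y) -> (a x + b y + tx, c x + d y + ty)``."""

    a: float
    b: float
    c: float
    d: float
    tx: float
    ty: float

    @property
    def det(self) -> float:
        return self.a * self.d - self.b * self.c

    @property
    def matrix(self) -> np.ndarray:
        """3x3 homogeneous matrix acting on column vectors (x, y, 1)."""
        return np.array(
            [[self.a, self.b, self.tx], [self.c, self.d, self.ty], [0.0, 0.0, 1.0]]
        )

    @classmethod
    def from_matrix(cls, m: np.ndarray) -> "AffineTransform":
        return cls(m[0, 0], m[0, 1], m[1, 0], m[1, 1], m[0, 2], m[1, 2])

    @classmethod
    def identity(cls) -> "AffineTransform":
        return cls(1.0, 0.0, 0.0, 1.0, 0.0, 0.0)

    @classmethod
    def similarity(
        cls, rotation_deg: float = 0.0, scale: float = 1.0, translation: tuple[float, float] = (0.0, 0.0)
    ) -> "AffineTransform":
        """Rotation + uniform scale + translation (the 4-parameter model)."""
        th = np.deg2rad(rotation_deg)
        a = scale * np.cos(th)
        b = -scale * np.sin(th)
        return cls(a, b, -b, a, translation[0], translation[1])

    def apply(self, points: np.ndarray) -> np.ndarray:
        """Map an (N, 2) array of (x, y) points."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        out = pts @ np.array([[self.a, self.c], [self.b, self.d]])
        out += np.array([self.tx, self.ty])
        return out

    def inverse(self) -> "AffineTransform":
        if abs(self.det) < 1e-300:
            raise DegenerateGeometryError("transform is not invertible")
        return AffineTransform.from_matrix(np.linalg.inv(self.matrix))

    def params(self) -> tuple[float, float, float, float, float, float]:
        return (self.a, self.b, self.c, self.d, self.tx, self.ty)

    def to_json(self, path: str | Path, rms: float | None = None) -> None:
        payload = dict(zip("a b c d tx ty".split(), self.params()))
        if rms is not None:
            payload["rms"] = rms
        Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "AffineTransform":
        payload = json.loads(Path(path).read_text())
        return cls(*(payload[k] for k in "a b c d tx ty".split()))


@dataclass
class TiePointSet:
    """Control-point correspondences ``historical[i] <-> repeat[i]`` in pixels."""

    historical: np.ndarray  # (N, 2) x, y
    repeat: np.ndarray  # (N, 2) x, y

    def __post_init__(self) -> None:
        self.historical = np.atleast_2d(np.asarray(self.historical, dtype=float))
        self.repeat = np.atleast_2d(np.asarray(self.repeat, dtype=float))
        if self.historical.shape != self.repeat.shape or self.historical.shape[1] != 2:
            raise ValueError("tie points must be matching (N, 2) arrays")
        if not (np.isfinite(self.historical).all() and np.isfinite(self.repeat).all()):
            raise ValueError("tie-point coordinates must be finite")

    def __len__(self) -> int:
        return self.historical.shape[0]

    def to_csv(self, path: str | Path) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["pair_id", "x_hist", "y_hist", "x_rep", "y_rep"])
            for i, (h, r) in enumerate(zip(self.historical, self.repeat)):
                w.writerow([i, h[0], h[1], r[0], r[1]])

    @classmethod
    def from_csv(cls, path: str | Path) -> "TiePointSet":
        hist, rep = [], []
        with open(path, newline="") as fh:
            for row in csv.DictReader(fh):
                hist.append((float(row["x_hist"]), float(row["y_hist"])))
                rep.append((float(row["x_rep"]), float(row["y_rep"])))
        return cls(np.array(hist), np.array(rep))


@dataclass
class PhotoPair:
    """A historical/repeat classified photograph pair sharing one pixel grid."""

    station_id: str
    historical: ClassifiedImage
    modern: ClassifiedImage
    year_hist: int
    year_mod: int
    alignment_rms: float | None = None

    def __post_init__(self) -> None:
        if self.historical.shape != self.modern.shape:
            raise ValueError("aligned pair must share one pixel grid")
        if self.year_hist > self.year_mod:
            raise ValueError("years must be ordered historical <= modern")


@dataclass
class ResidualSummary:
    """Per-pair alignment residuals of mapped historical vs repeat points."""

    distances: np.ndarray
    rms: float
    max: float
    flagged: np.ndarray  # indices with distance > threshold
    threshold: float


def estimate_affine(points: TiePointSet, model: str = "affine") -> AffineTransform:
    """Least-squares transform mapping historical points onto repeat points.

    Parameters
    ----------
    points
        At least 3 non-collinear correspondences.
    model
        ``"affine"`` (6 parameters, default) or ``"similarity"`` (4 parameters:
        translation, rotation, uniform scale — the transform family a
        straight-line-preserving manual alignment tool applies).

    Raises
    ------
    DegenerateGeometryError
        Fewer than 3 pairs, or a collinear configuration.
    """
    n = len(points)
    if n < 3:
        raise DegenerateGeometryError(f"need >= 3 tie points, got {n}")
    src, dst = points.historical, points.repeat
    if model == "affine":
        design = np.column_stack([src, np.ones(n)])
        if np.linalg.matrix_rank(design) < 3:
            raise DegenerateGeometryError("tie points are collinear")
        sol, *_ = np.linalg.lstsq(design, dst, rcond=None)
        (a, c), (b, d), (tx, ty) = sol
        return AffineTransform(a, b, c, d, tx, ty)
    if model == "similarity":
        # x' = a x - b y + tx ; y' = b x + a y + ty
        x, y = src[:, 0], src[:, 1]
        zeros, ones = np.zeros(n), np.ones(n)
        design = np.block(
            [
                [x[:, None], -y[:, None], ones[:, None], zeros[:, None]],
                [y[:, None], x[:, None], zeros[:, None], ones[:, None]],
            ]
        )
        rhs = np.concatenate([dst[:, 0], dst[:, 1]])
        if np.linalg.matrix_rank(design) < 4:
            raise DegenerateGeometryError("tie points are degenerate for similarity fit")
        a, b, tx, ty = np.linalg.lstsq(design, rhs, rcond=None)[0]
        return AffineTransform(a, -b, b, a, tx, ty)
    raise ValueError(f"unknown model {model!r}")


def apply_transform(
    image: ClassifiedImage, t: AffineTransform, out_shape: tuple[int, int] | None = None
) -> ClassifiedImage:
    """Warp a classified image by ``t`` onto an output grid.

    Output pixel ``p`` takes the label of input pixel ``t^{-1}(p)`` rounded to
    the nearest neighbour — categorical labels are never interpolated. Output
    pixels whose source falls outside the input grid (or on an invalid input
    pixel) are marked invalid.
    """
    inv = t.inverse()
    h_out, w_out = out_shape if out_shape is not None else image.shape
    xs, ys = np.meshgrid(np.arange(w_out), np.arange(h_out))
    coords = np.column_stack([xs.ravel(), ys.ravel()]).astype(float)
    src = inv.apply(coords)
    xi = np.rint(src[:, 0]).astype(int)
    yi = np.rint(src[:, 1]).astype(int)
    h_in, w_in = image.shape
    inside = (xi >= 0) & (xi < w_in) & (yi >= 0) & (yi < h_in)
    labels = np.full(h_out * w_out, FILL_LABEL, dtype=image.labels.dtype)
    valid = np.zeros(h_out * w_out, dtype=bool)
    if inside.any():
        labels[inside] = image.labels[yi[inside], xi[inside]]
        valid[inside] = image.valid[yi[inside], xi[inside]]
    else:
        warnings.warn("transform maps the entire output outside the source image")
    return ClassifiedImage(labels.reshape(h_out, w_out), valid.reshape(h_out, w_out))


def alignment_residuals(
    t: AffineTransform, points: TiePointSet, threshold: float = 3.0
) -> ResidualSummary:
    """Euclidean residuals of ``t``-mapped historical points vs repeat points.

    Pairs farther than ``threshold`` pixels (default 3, i.e., worse than
    "within a few pixels") are flagged but never silently dropped.
    """
    mapped = t.apply(points.historical)
    d = np.linalg.norm(mapped - points.repeat, axis=1)
    return ResidualSummary(
        distances=d,
        rms=float(np.sqrt(np.mean(d**2))),
        max=float(d.max()),
        flagged=np.flatnonzero(d > threshold),
        threshold=threshold,
    )
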