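"""Shared containers: land cover schemes, rasters, classified images, compositions.

Conventions used throughout the package:

* Pixel coordinates are 0-based ``(x, y)`` with ``x`` = column and ``y`` = row,
  origin at the top-left pixel center.
* Map coordinates place the raster origin at the top-left corner; ``x`` grows
  with columns and ``y`` grows with rows (row-aligned map frame).
* Land cover covariates are expressed in PERCENT (0-100), never fractions:
  fitted log-odds coefficients are per percentage point of cover.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

__all__ = [
    "LandCoverScheme",
    "RasterMap",
    "ClassifiedImage",
    "CompositionVector",
    "EmptyImageError",
    "default_scheme",
    "DEFAULT_CATEGORIES",
]


class EmptyImageError(ValueError):
    """Raised when an operation needs valid pixels and none exist."""


#: The ten simplified land cover categories used for oblique-photo comparison.
DEFAULT_CATEGORIES: tuple[tuple[int, str], ...] = (
    (1, "coniferous forest"),
    (2, "mixedwood forest"),
    (3, "broadleaf forest"),
    (4, "wetland"),
    (5, "shrubs"),
    (6, "herbaceous"),
    (7, "regenerating area"),
    (8, "barren land"),
    (9, "water"),
    (10, "ice/snow"),
)


@dataclass(frozen=True)
class LandCoverScheme:
    """An ordered categorical land cover legend.

    Parameters
    ----------
    categories
        Ordered ``(id, name)`` pairs. Ids are small non-negative integers.
    merge_map
        Optional total mapping from fine category ids to coarse category ids
        (e.g., dense/moderate/open conifer -> conifer). When present,
        ``merged_categories`` must list the coarse legend.
    merged_categories
        The coarse legend targeted by ``merge_map``.
    invalid_id
        Reserved id marking excluded pixels (foreground, haze, out-of-frame).
    """

    categories: tuple[tuple[int, str], ...]
    merge_map: Mapping[int, int] | None = None
    merged_categories: tuple[tuple[int, str], ...] | None = None
    invalid_id: int = 255

    def __post_init__(self) -> None:
        ids = [i for i, _ in self.categories]
        if len(set(ids)) != len(ids):
            raise ValueError("category ids must be unique")
        if self.invalid_id in ids:
            raise ValueError("invalid_id must not collide with a category id")
        if self.merge_map is not None:
            if self.merged_categories is None:
                raise ValueError("merge_map requires merged_categories")
            missing = set(ids) - set(self.merge_map)
            if missing:
                raise ValueError(f"merge_map is not total; missing ids {sorted(missing)}")
            coarse_ids = {i for i, _ in self.merged_categories}
            bad = set(self.merge_map.values()) - coarse_ids
            if bad:
                raise ValueError(f"merge_map targets unknown coarse ids {sorted(bad)}")

    @property
    def ids(self) -> tuple[int, ...]:
        return tuple(i for i, _ in self.categories)

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(n for _, n in self.categories)

    def name_of(self, cat_id: int) -> str:
        for i, n in self.categories:
            if i == cat_id:
                return n
        raise KeyError(cat_id)

    def id_of(self, name: str) -> int:
        for i, n in self.categories:
            if n == name:
                return i
        raise KeyError(name)

    def merged(self) -> "LandCoverScheme":
        """The coarse scheme targeted by ``merge_map``."""
        if self.merge_map is None or self.merged_categories is None:
            raise ValueError("scheme has no merge_map")
        return LandCoverScheme(self.merged_categories, invalid_id=self.invalid_id)

    def merge_name_map(self) -> dict[str, str]:
        """Fine category name -> coarse category name."""
        if self.merge_map is None:
            raise ValueError("scheme has no merge_map")
        coarse = dict(self.merged_categories)  # type: ignore[arg-type]
        return {self.name_of(f): coarse[c] for f, c in self.merge_map.items()}


def default_scheme() -> LandCoverScheme:
    """The 10-category oblique-photograph legend."""
    return LandCoverScheme(DEFAULT_CATEGORIES)


@dataclass
class RasterMap:
    """A categorical thematic raster (Landsat-like) in metric map units.

    ``labels[r, c]`` covers the square cell whose center sits at
    ``(origin_x + (c + 0.5) * cell_size, origin_y + (r + 0.5) * cell_size)``.
    """

    labels: np.ndarray
    cell_size: float
    origin: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 2 or self.labels.size == 0:
            raise ValueError("labels must be a non-empty 2-D grid")
        if not self.cell_size > 0:
            raise ValueError("cell_size must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape  # type: ignore[return-value]

    @property
    def extent(self) -> tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax) in map units."""
        h, w = self.labels.shape
        x0, y0 = self.origin
        return (x0, y0, x0 + w * self.cell_size, y0 + h * self.cell_size)

    def contains(self, point: tuple[float, float]) -> bool:
        xmin, ymin, xmax, ymax = self.extent
        x, y = point
        return xmin <= x <= xmax and ymin <= y <= ymax

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Map-unit x and y coordinates of all cell centers (1-D each)."""
        h, w = self.labels.shape
        x0, y0 = self.origin
        xs = x0 + (np.arange(w) + 0.5) * self.cell_size
        ys = y0 + (np.arange(h) + 0.5) * self.cell_size
        return xs, ys


@dataclass
class ClassifiedImage:
    """An integer label mask plus validity mask — one classified photograph.

    ``valid`` is False on foreground, high-uncertainty and out-of-frame pixels;
    those pixels are excluded from every composition.
    """

    labels: np.ndarray
    valid: np.ndarray

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        self.valid = np.asarray(self.valid, dtype=bool)
        if self.labels.shape != self.valid.shape:
            raise ValueError("labels and valid must share a shape")
        if self.labels.ndim != 2:
            raise ValueError("labels must be 2-D")

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape  # type: ignore[return-value]

    @property
    def n_valid(self) -> int:
        return int(self.valid.sum())

    def copy(self) -> "ClassifiedImage":
        return ClassifiedImage(self.labels.copy(), self.valid.copy())


@dataclass
class CompositionVector:
    """Per-category land cover shares in percent of valid pixels.

    Closed composition: values are non-negative and sum to 100.
    ``truncation_fraction`` reports, for buffer extractions, the fraction of
    the ideal buffer disc that fell outside the raster (0 for full coverage).
    """

    values: dict[str, float]
    n_valid: int
    truncation_fraction: float = 0.0

    def __post_init__(self) -> None:
        if self.n_valid <= 0:
            raise EmptyImageError("composition needs at least one valid pixel")
        vals = np.array(list(self.values.values()), dtype=float)
        if (vals < -1e-9).any():
            raise ValueError("composition values must be non-negative")
        total = float(vals.sum())
        if abs(total - 100.0) > 1e-6:
            raise ValueError(f"composition must sum to 100, got {total!r}")

    def percent(self, name: str) -> float:
        """Share of ``name`` in percent; categories absent from the vector are 0."""
        return float(self.values.get(name, 0.0))

    def as_fractions(self) -> dict[str, float]:
        return {k: v / 100.0 for k, v in self.values.items()}
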