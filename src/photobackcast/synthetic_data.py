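"""Synthetic landscapes, bird surveys and photo pairs with known ground truth.

The generator emulates the study system — a conifer-dominated subalpine
mosaic with rarer herbaceous meadows and wetlands, repeat-survey songbird
detections, and historical/repeat classified photograph pairs — so that every
downstream stage (alignment, accounting, model fitting, backcasting) has a
parameter-recovery test with no field data.

* Landscapes: a Gaussian-smoothed random field thresholded at the quantiles
  of the target composition, giving spatially autocorrelated categorical
  rasters whose pixel fractions match the target almost exactly.
* Surveys: per site, occurrence probability follows a logistic model on
  buffer land cover percentages at the species' characteristic scale;
  detections are k independent Bernoulli trials (k = 9 sampling units).
  Zeros are temporary emigration; an optional detection probability < 1
  thins detections to exercise the false-absence computation.
* Photo pairs: the modern mask applies a per-category transition process to
  a base classification; the historical mask is the base pushed through a
  known affine warp, with noisy tie points emitted so the alignment stage
  must recover the warp.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from PIL import Image
from scipy.ndimage import gaussian_filter
from scipy.special import expit

from ._core import ClassifiedImage, CompositionVector, LandCoverScheme, RasterMap
from .photo_alignment import AffineTransform, PhotoPair, TiePointSet, apply_transform
from .multiscale_sdm import buffer_proportions

__all__ = [
    "SpeciesTruth",
    "SiteSurvey",
    "SyntheticPhotoPair",
    "generate_landscape",
    "default_truths",
    "study_world",
    "simulate_surveys",
    "occurrence_probability",
    "generate_photo_pair",
    "random_sites",
    "save_mask_png",
    "load_mask_png",
    "save_raster_png",
    "load_raster_png",
    "surveys_to_csv",
    "surveys_from_csv",
    "truths_to_json",
    "truths_from_json",
    "DEFAULT_COMPOSITION",
]

#: Default landscape composition: conifer-dominated subalpine mosaic with
#: rarer herbaceous meadows and wetlands (fractions, sum to 1).
DEFAULT_COMPOSITION: dict[str, float] = {
    "coniferous forest": 0.45,
    "mixedwood forest": 0.05,
    "broadleaf forest": 0.02,
    "wetland": 0.08,
    "shrubs": 0.12,
    "herbaceous": 0.18,
    "regenerating area": 0.03,
    "barren land": 0.05,
    "water": 0.01,
    "ice/snow": 0.01,
}


#: Default landscape grain: Gaussian smoothing sigma in cells. At the default
#: 50-m cell size this is a ~200-m patch scale — the grain of subalpine
#: meadow/krummholz/forest mosaics — and makes buffer compositions
#: distinguishable across the 250-m radius grid.
DEFAULT_AUTOCORR_CELLS = 4.0
DEFAULT_CELL_SIZE = 50.0
DEFAULT_SHAPE = (400, 400)  # 20 x 20 km at 50-m cells


@dataclass(frozen=True)
class SpeciesTruth:
    """Generative analogue of one fitted species model.

    ``coefficients`` map scheme category names to log-odds per percentage
    point of cover within the ``scale_m`` buffer.
    """

    species: str
    scale_m: float
    intercept: float
    coefficients: Mapping[str, float]


@dataclass
class SiteSurvey:
    """Detection counts (out of k sampling units) for each species at a site."""

    site_id: str
    coords: tuple[float, float]
    detections: dict[str, int]
    k: int = 9

    def __post_init__(self) -> None:
        for sp, c in self.detections.items():
            if not 0 <= c <= self.k:
                raise ValueError(f"count {c} for {sp} outside [0, {self.k}]")


@dataclass
class SyntheticPhotoPair:
    """A simulated photo pair plus its generation ground truth."""

    pair: PhotoPair
    tie_points: TiePointSet
    true_change: dict[str, float]  # category -> percentage-point change (modern - base)
    warp: AffineTransform  # ground-truth historical -> repeat alignment


def default_truths() -> list[SpeciesTruth]:
    """A small synthetic community with known habitat associations.

    The conifer specialist reuses the magnitude of a real conifer-associated
    corvid model (intercept -4.41, +0.04/% conifer, +0.06/% shrub at 1250 m);
    the others span forest, shrub and meadow associations so that forest
    expansion at the expense of meadows must raise the former group and
    depress the meadow specialist.
    """
    return [
        SpeciesTruth("conifer specialist", 1250.0, -4.41,
                     {"coniferous forest": 0.04, "shrubs": 0.06}),
        SpeciesTruth("forest generalist", 1000.0, -3.2, {"coniferous forest": 0.035}),
        SpeciesTruth("shrub nester", 500.0, -2.4, {"shrubs": 0.07}),
        SpeciesTruth("meadow specialist", 750.0, -2.6, {"herbaceous": 0.08}),
    ]


def study_world(
    seed: int,
    n_sites: int = 500,
    shape: tuple[int, int] = DEFAULT_SHAPE,
    cell_size: float = DEFAULT_CELL_SIZE,
    autocorr_length: float = DEFAULT_AUTOCORR_CELLS,
    composition: Mapping[str, float] | None = None,
    margin_m: float = 500.0,
) -> tuple[LandCoverScheme, RasterMap, pd.DataFrame]:
    """The canonical synthetic study system: scheme, landscape, survey sites."""
    from ._core import default_scheme

    scheme = default_scheme()
    raster = generate_landscape(
        scheme,
        shape,
        composition or DEFAULT_COMPOSITION,
        autocorr_length,
        seed=seed,
        cell_size=cell_size,
    )
    sites = random_sites(raster, n_sites, seed=seed + 1, margin_m=margin_m)
    return scheme, raster, sites


# ------------------------------------------------------------------ landscapes


def generate_landscape(
    scheme: LandCoverScheme,
    shape: tuple[int, int],
    target_composition: Mapping[str, float],
    autocorr_length: float,
    seed: int,
    cell_size: float = 50.0,
    origin: tuple[float, float] = (0.0, 0.0),
) -> RasterMap:
    """Spatially autocorrelated categorical raster with controlled composition.

    A standard-normal field smoothed with a Gaussian kernel of standard
    deviation ``autocorr_length`` (in cells) is thresholded at the cumulative
    quantiles of ``target_composition``, so per-category pixel fractions match
    the target up to integer rounding. Deterministic for a fixed seed.
    """
    h, w = shape
    if h <= 0 or w <= 0:
        raise ValueError("landscape shape must be positive")
    names = list(target_composition)
    props = np.array([target_composition[n] for n in names], dtype=float)
    if (props < 0).any() or abs(props.sum() - 1.0) > 1e-6:
        raise ValueError("target composition must be non-negative and sum to 1")
    if autocorr_length < 0:
        raise ValueError("autocorr_length must be >= 0")
    rng = np.random.default_rng(seed)
    field = rng.standard_normal((h, w))
    if autocorr_length > 0:
        field = gaussian_filter(field, sigma=autocorr_length, mode="wrap")
    order = np.argsort(field, axis=None, kind="stable")
    n = h * w
    # Largest-remainder apportionment of cells to categories.
    exact = props * n
    counts = np.floor(exact).astype(int)
    remainder = n - counts.sum()
    if remainder > 0:
        frac_order = np.argsort(-(exact - counts), kind="stable")
        counts[frac_order[:remainder]] += 1
    labels = np.empty(n, dtype=np.uint8)
    start = 0
    for name, cnt in zip(names, counts):
        labels[order[start : start + cnt]] = scheme.id_of(name)
        start += cnt
    return RasterMap(labels.reshape(h, w), cell_size=cell_size, origin=origin)


def random_sites(
    raster: RasterMap, n: int, seed: int, margin_m: float = 0.0
) -> pd.DataFrame:
    """Uniformly random survey sites inside the raster (optionally inset)."""
    rng = np.random.default_rng(seed)
    xmin, ymin, xmax, ymax = raster.extent
    xs = rng.uniform(xmin + margin_m, xmax - margin_m, size=n)
    ys = rng.uniform(ymin + margin_m, ymax - margin_m, size=n)
    return pd.DataFrame(
        {"site_id": [f"site{i:04d}" for i in range(n)], "x": xs, "y": ys}
    )


# ------------------------------------------------------------------ surveys


def occurrence_probability(
    truth: SpeciesTruth, comp: CompositionVector
) -> float:
    """Logistic occurrence probability at a buffer composition (percent units)."""
    eta = truth.intercept + sum(
        b * comp.percent(name) for name, b in truth.coefficients.items()
    )
    return float(expit(eta))


def simulate_surveys(
    raster: RasterMap,
    truths: Sequence[SpeciesTruth],
    sites: pd.DataFrame,
    scheme: LandCoverScheme,
    k: int = 9,
    seed: int = 0,
    detection_p: float = 1.0,
) -> list[SiteSurvey]:
    """Bernoulli-trial songbird surveys from known occurrence models.

    Per site and species: the buffer composition at the species' true
    characteristic scale sets a logistic occurrence probability P; the
    detection count is a Binomial(k, P * detection_p) draw. Sites whose
    buffer spills past the raster edge are truncated with a warning.
    """
    if not 0.0 < detection_p <= 1.0:
        raise ValueError("detection_p must lie in (0, 1]")
    rng = np.random.default_rng(seed)
    surveys: list[SiteSurvey] = []
    warned = False
    for rec in sites.itertuples(index=False):
        point = (float(rec.x), float(rec.y))
        if not raster.contains(point):
            raise ValueError(f"site {rec.site_id} at {point} is outside the raster")
        detections: dict[str, int] = {}
        for truth in truths:
            comp = buffer_proportions(raster, point, truth.scale_m, scheme)
            if comp.truncation_fraction > 0 and not warned:
                warnings.warn(
                    "buffers extend past the raster edge and were truncated"
                )
                warned = True
            p_occ = occurrence_probability(truth, comp)
            detections[truth.species] = int(rng.binomial(k, p_occ * detection_p))
        surveys.append(
            SiteSurvey(site_id=str(rec.site_id), coords=point, detections=detections, k=k)
        )
    return surveys


# ------------------------------------------------------------------ photo pairs


def generate_photo_pair(
    base: ClassifiedImage,
    transition: Mapping[str, tuple[str, float]],
    warp: AffineTransform,
    tiepoint_noise_sd: float,
    seed: int,
    scheme: LandCoverScheme,
    station_id: str = "station",
    n_tiepoints: int = 12,
    year_hist: int = 1925,
    year_mod: int = 2010,
) -> SyntheticPhotoPair:
    """A historical/repeat classified pair with a known warp and transitions.

    The modern mask flips each pixel of a transitioning category to its
    target independently with the given rate (e.g., herbaceous -> conifer
    in-filling); the historical mask is the base classification as seen
    through the inverse of ``warp``, so applying ``warp`` re-registers it to
    the repeat (base) grid. Tie points are true correspondences with
    Gaussian noise of ``tiepoint_noise_sd`` pixels added on the historical
    side. Ground-truth per-category change (modern vs base, percentage
    points over base-valid pixels) is recorded.
    """
    if abs(warp.det) < 1e-12:
        raise ValueError("warp must be invertible")
    for frm, (to, rate) in transition.items():
        if not 0.0 <= rate <= 1.0:
            raise ValueError(f"transition rate for {frm} outside [0, 1]")
        scheme.id_of(frm), scheme.id_of(to)  # validate names
    rng = np.random.default_rng(seed)

    modern = base.copy()
    for frm, (to, rate) in transition.items():
        mask = (base.labels == scheme.id_of(frm)) & base.valid
        flips = rng.random(int(mask.sum())) < rate
        idx = np.nonzero(mask)
        modern.labels[idx[0][flips], idx[1][flips]] = scheme.id_of(to)

    # historical(x) = base(warp(x)): inverse-warp the base off the repeat grid.
    historical = apply_transform(base, warp.inverse(), out_shape=base.shape)

    h, w = base.shape
    ref_pts = np.column_stack(
        [rng.uniform(0, w - 1, n_tiepoints), rng.uniform(0, h - 1, n_tiepoints)]
    )
    hist_pts = warp.inverse().apply(ref_pts)
    if tiepoint_noise_sd > 0:
        hist_pts = hist_pts + rng.normal(0.0, tiepoint_noise_sd, size=hist_pts.shape)
    ties = TiePointSet(historical=hist_pts, repeat=ref_pts)

    n_valid = int(base.valid.sum())
    true_change: dict[str, float] = {}
    for cat_id, name in scheme.categories:
        before = int(((base.labels == cat_id) & base.valid).sum())
        after = int(((modern.labels == cat_id) & modern.valid).sum())
        true_change[name] = 100.0 * (after - before) / n_valid
    pair = PhotoPair(
        station_id=station_id,
        historical=historical,
        modern=modern,
        year_hist=year_hist,
        year_mod=year_mod,
    )
    return SyntheticPhotoPair(pair=pair, tie_points=ties, true_change=true_change, warp=warp)


# ------------------------------------------------------------------ I/O


def save_raster_png(raster: RasterMap, path: str | Path) -> None:
    """Write a thematic raster as 8-bit PNG plus a JSON sidecar with geometry."""
    path = Path(path)
    Image.fromarray(raster.labels.astype(np.uint8), mode="L").save(path)
    meta = {"cell_size": raster.cell_size, "origin": list(raster.origin)}
    path.with_suffix(".json").write_text(json.dumps(meta))


def load_raster_png(path: str | Path) -> RasterMap:
    path = Path(path)
    arr = np.asarray(Image.open(path).convert("L")).copy()
    meta = json.loads(path.with_suffix(".json").read_text())
    return RasterMap(arr, cell_size=meta["cell_size"], origin=tuple(meta["origin"]))


def save_mask_png(image: ClassifiedImage, path: str | Path, invalid_id: int = 255) -> None:
    """Write a label mask as single-channel 8-bit PNG (invalid pixels = 255)."""
    arr = image.labels.astype(np.uint8).copy()
    arr[~image.valid] = invalid_id
    Image.fromarray(arr, mode="L").save(path)


def load_mask_png(path: str | Path, invalid_id: int = 255) -> ClassifiedImage:
    arr = np.asarray(Image.open(path).convert("L"))
    return ClassifiedImage(labels=arr.copy(), valid=arr != invalid_id)


def surveys_to_csv(surveys: Sequence[SiteSurvey], path: str | Path) -> None:
    rows = []
    for s in surveys:
        for sp, c in s.detections.items():
            rows.append(
                {"site_id": s.site_id, "x": s.coords[0], "y": s.coords[1], "species": sp, "count": c, "k": s.k}
            )
    pd.DataFrame(rows).to_csv(path, index=False)


def surveys_from_csv(path: str | Path) -> list[SiteSurvey]:
    df = pd.read_csv(path)
    out = []
    for (site, x, y, k), grp in df.groupby(["site_id", "x", "y", "k"], sort=True):
        out.append(
            SiteSurvey(
                site_id=str(site),
                coords=(float(x), float(y)),
                detections=dict(zip(grp["species"], grp["count"].astype(int))),
                k=int(k),
            )
        )
    return out


def truths_to_json(truths: Sequence[SpeciesTruth], path: str | Path) -> None:
    payload = [
        {
            "species": t.species,
            "scale_m": t.scale_m,
            "intercept": t.intercept,
            "coefficients": dict(t.coefficients),
        }
        for t in truths
    ]
    Path(path).write_text(json.dumps(payload, indent=2))


def truths_from_json(path: str | Path) -> list[SpeciesTruth]:
    payload = json.loads(Path(path).read_text())
    return [SpeciesTruth(**d) for d in payload]
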