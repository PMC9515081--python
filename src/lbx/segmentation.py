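"""Segmentation of nucleated events and DAPI-negative PanCK+ candidates.

Nucleated events are seeded from the DAPI foreground (per-channel Otsu
threshold with an absolute floor, watershed split of touching nuclei);
the cell extent grows from each nucleus into the union of the marker
foregrounds, capped at 3x the nucleus equivalent radius. PanCK+
connected components with < 10% DAPI overlap are emitted separately as
anucleate candidates (nucleus area 0) for the downstream vesicle gate.

Every emitted event carries the full morphometric/intensity descriptor
vector: cell and nucleus size and eccentricity, equivalent diameter,
the four raw channel means over the cell area, and (after
``extract_features``) all pairwise ratios of those base features.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage.feature import peak_local_max
from skimage.filters import threshold_otsu
from skimage.measure import regionprops
from skimage.morphology import remove_small_objects
from skimage.segmentation import watershed

from .labels import CHANNELS

logger = logging.getLogger(__name__)

#: Column-safe names for the four channels, in canonical order.
CHANNEL_COLUMNS: tuple[str, ...] = tuple(
    "mean_" + c.replace("/", "_") for c in CHANNELS
)

#: Morphometric base features; together with the channel means these are
#: the base descriptor set from which all pairwise ratios are formed.
MORPHOMETRIC_COLUMNS: tuple[str, ...] = (
    "nucleus_area_um2",
    "cell_area_um2",
    "nucleus_eccentricity",
    "cell_eccentricity",
    "equivalent_diameter_um",
)

BASE_FEATURE_COLUMNS: tuple[str, ...] = MORPHOMETRIC_COLUMNS + CHANNEL_COLUMNS

#: Frozen ratio column set: every ordered pair of distinct base features.
RATIO_COLUMNS: tuple[str, ...] = tuple(
    f"ratio_{a}_over_{b}"
    for a, b in itertools.permutations(BASE_FEATURE_COLUMNS, 2)
)

METADATA_COLUMNS: tuple[str, ...] = (
    "event_id",
    "slide_id",
    "frame_id",
    "x_px",
    "y_px",
    "dapi_negative",
)

FEATURE_COLUMNS: tuple[str, ...] = BASE_FEATURE_COLUMNS + RATIO_COLUMNS


@dataclass(frozen=True)
class FrameImage:
    """One 4-channel frame with physical pixel scale.

    ``pixels`` has shape (4, H, W) in the fixed channel order
    DAPI, PanCK, VIM, CD45/CD31, with finite, non-negative intensities.
    """

    pixels: np.ndarray
    um_per_px: float
    frame_id: str
    slide_id: str

    def __post_init__(self) -> None:
        if self.pixels.ndim != 3 or self.pixels.shape[0] != len(CHANNELS):
            raise ValueError(
                f"expected {len(CHANNELS)}-channel image, got shape {self.pixels.shape}"
            )
        if self.um_per_px <= 0:
            raise ValueError("um_per_px must be positive")
        if not np.all(np.isfinite(self.pixels)) or np.any(self.pixels < 0):
            raise ValueError("intensities must be finite and non-negative")


@dataclass
class SegmentationParams:
    """Tunable thresholds of the segmentation stage.

    ``threshold_floor`` is an absolute lower bound applied on top of the
    per-channel per-frame Otsu threshold so that blank or noise-only
    channels produce no foreground.
    """

    threshold_floor: float = 0.08
    min_nucleus_area_um2: float = 10.0
    min_candidate_area_um2: float = 0.5
    nucleus_split_min_distance_um: float = 2.5
    cell_radius_cap_factor: float = 3.0
    dapi_overlap_max: float = 0.10
    saturation_warn_fraction: float = 0.5


@dataclass(frozen=True)
class DetectedEvent:
    """One segmented object with its descriptor vector."""

    event_id: str
    slide_id: str
    frame_id: str
    x_px: float
    y_px: float
    nucleus_area_um2: float
    cell_area_um2: float
    nucleus_eccentricity: float
    cell_eccentricity: float
    raw_channel_means: dict[str, float]

    @property
    def equivalent_diameter_um(self) -> float:
        return 2.0 * math.sqrt(self.cell_area_um2 / math.pi)

    @property
    def dapi_negative(self) -> bool:
        return self.nucleus_area_um2 == 0.0


def _foreground_mask(channel: np.ndarray, floor: float) -> np.ndarray:
    finite = channel[np.isfinite(channel)]
    if finite.size == 0 or finite.max() <= floor:
        return np.zeros_like(channel, dtype=bool)
    try:
        thr = threshold_otsu(channel)
    except ValueError:  # constant image
        return np.zeros_like(channel, dtype=bool)
    return channel > max(thr, floor)


def segment_frame(
    frame: FrameImage, params: SegmentationParams | None = None
) -> list[DetectedEvent]:
    """Segment one frame into nucleated events and DAPI- candidates.

    A blank frame yields an empty list; a frame whose foreground covers
    more than half the area is processed but logged as saturated.
    """
    params = params or SegmentationParams()
    scale = frame.um_per_px
    px_area_um2 = scale * scale

    masks = {
        ch: _foreground_mask(frame.pixels[i], params.threshold_floor)
        for i, ch in enumerate(CHANNELS)
    }
    combined = np.logical_or.reduce(list(masks.values()))
    if combined.mean() > params.saturation_warn_fraction:
        logger.warning(
            "frame %s: foreground covers %.0f%% of the image (saturated?)",
            frame.frame_id, 100 * combined.mean(),
        )
    if not combined.any():
        return []

    # --- nucleated events: DAPI-seeded watershed -------------------------
    min_nucleus_px = max(1, int(round(params.min_nucleus_area_um2 / px_area_um2)))
    dapi_mask = ndi.binary_fill_holes(masks["DAPI"])
    dapi_mask = remove_small_objects(dapi_mask, max_size=min_nucleus_px - 1)

    events: list[DetectedEvent] = []
    counter = 0
    if dapi_mask.any():
        distance = ndi.distance_transform_edt(dapi_mask, sampling=scale)
        min_dist_px = max(3, int(round(params.nucleus_split_min_distance_um / scale)))
        peaks = peak_local_max(
            distance, min_distance=min_dist_px, labels=dapi_mask,
            exclude_border=False,
        )
        markers = np.zeros(dapi_mask.shape, dtype=np.int32)
        for i, (r, c) in enumerate(peaks, start=1):
            markers[r, c] = i
        if markers.max() == 0:  # tiny blobs without a clear peak
            markers, _ = ndi.label(dapi_mask)
        nucleus_labels = watershed(-distance, markers, mask=dapi_mask)

        # cell extent: grow each nucleus into the combined foreground,
        # assigning contested pixels to the nearest nucleus
        outside_dist = ndi.distance_transform_edt(nucleus_labels == 0, sampling=scale)
        cell_labels = watershed(
            outside_dist, nucleus_labels, mask=np.logical_or(combined, dapi_mask)
        )

        nucleus_props = {p.label: p for p in regionprops(nucleus_labels)}
        for prop in regionprops(cell_labels):
            nprop = nucleus_props.get(prop.label)
            if nprop is None or nprop.area < min_nucleus_px:
                continue
            nucleus_area = float(nprop.area) * px_area_um2
            r_eq_um = math.sqrt(nucleus_area / math.pi)
            cap_um = params.cell_radius_cap_factor * r_eq_um

            region_mask = cell_labels == prop.label
            # cap: drop pixels farther than (cap - r_eq) from the nucleus
            keep = region_mask & (outside_dist <= max(cap_um - r_eq_um, 0.0))
            keep |= nucleus_labels == prop.label
            cell_area_px = int(keep.sum())

            cprops = regionprops(keep.astype(np.uint8))
            if not cprops:
                continue
            cprop = cprops[0]
            counter += 1
            events.append(
                DetectedEvent(
                    event_id=f"{frame.slide_id}:{frame.frame_id}:{counter:04d}",
                    slide_id=frame.slide_id,
                    frame_id=frame.frame_id,
                    x_px=float(cprop.centroid[1]),
                    y_px=float(cprop.centroid[0]),
                    nucleus_area_um2=nucleus_area,
                    cell_area_um2=float(cell_area_px) * px_area_um2,
                    nucleus_eccentricity=float(nprop.eccentricity),
                    cell_eccentricity=float(cprop.eccentricity),
                    raw_channel_means={
                        ch: float(frame.pixels[i][keep].mean())
                        for i, ch in enumerate(CHANNELS)
                    },
                )
            )

    # --- DAPI-negative PanCK+ candidates ---------------------------------
    min_cand_px = max(1, int(round(params.min_candidate_area_um2 / px_area_um2)))
    panck_labels, n_panck = ndi.label(masks["PanCK"])
    for prop in regionprops(panck_labels):
        if prop.area < min_cand_px:
            continue
        comp = panck_labels == prop.label
        overlap = np.logical_and(comp, dapi_mask).sum() / prop.area
        if overlap >= params.dapi_overlap_max:
            continue
        counter += 1
        events.append(
            DetectedEvent(
                event_id=f"{frame.slide_id}:{frame.frame_id}:{counter:04d}",
                slide_id=frame.slide_id,
                frame_id=frame.frame_id,
                x_px=float(prop.centroid[1]),
                y_px=float(prop.centroid[0]),
                nucleus_area_um2=0.0,
                cell_area_um2=float(prop.area) * px_area_um2,
                nucleus_eccentricity=0.0,
                cell_eccentricity=float(prop.eccentricity),
                raw_channel_means={
                    ch: float(frame.pixels[i][comp].mean())
                    for i, ch in enumerate(CHANNELS)
                },
            )
        )
    return events


def segment_slide(
    frames: list[FrameImage], params: SegmentationParams | None = None
) -> list[DetectedEvent]:
    """Segment every frame of a slide."""
    events: list[DetectedEvent] = []
    for frame in frames:
        events.extend(segment_frame(frame, params))
    return events


# ---------------------------------------------------------------------------
# Feature matrix
# ---------------------------------------------------------------------------


@dataclass
class FeatureMatrix:
    """Per-event descriptor table with a per-slide normalization flag.

    ``data`` holds metadata columns, the base features, the frozen ratio
    set, and a ``zero_denominator`` flag marking rows where any ratio had
    a zero denominator (those ratios carry the sentinel 0).
    """

    data: pd.DataFrame
    normalized: bool = False

    def __len__(self) -> int:
        return len(self.data)

    @property
    def intensity_columns(self) -> tuple[str, ...]:
        return CHANNEL_COLUMNS

    @property
    def feature_columns(self) -> tuple[str, ...]:
        return FEATURE_COLUMNS

    def copy(self) -> "FeatureMatrix":
        return FeatureMatrix(self.data.copy(), self.normalized)

    def to_csv(self, path) -> None:
        df = self.data.copy()
        df["normalized"] = self.normalized
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "FeatureMatrix":
        df = pd.read_csv(path)
        normalized = bool(df["normalized"].iloc[0]) if len(df) else False
        return cls(df.drop(columns=["normalized"], errors="ignore"), normalized)


def extract_features(events: list[DetectedEvent]) -> FeatureMatrix:
    """Build the descriptor matrix: base features plus all pairwise ratios.

    Ratios with a zero denominator take the sentinel value 0 and set the
    row's ``zero_denominator`` flag. The column set is identical for
    every call; an empty event list yields an empty matrix with headers.
    """
    rows = []
    for ev in events:
        row = {
            "event_id": ev.event_id,
            "slide_id": ev.slide_id,
            "frame_id": ev.frame_id,
            "x_px": ev.x_px,
            "y_px": ev.y_px,
            "dapi_negative": ev.dapi_negative,
            "nucleus_area_um2": ev.nucleus_area_um2,
            "cell_area_um2": ev.cell_area_um2,
            "nucleus_eccentricity": ev.nucleus_eccentricity,
            "cell_eccentricity": ev.cell_eccentricity,
            "equivalent_diameter_um": ev.equivalent_diameter_um,
        }
        for ch, col in zip(CHANNELS, CHANNEL_COLUMNS):
            if ch not in ev.raw_channel_means:
                raise ValueError(f"event {ev.event_id} missing channel {ch!r}")
            row[col] = ev.raw_channel_means[ch]
        rows.append(row)

    columns = list(METADATA_COLUMNS) + list(BASE_FEATURE_COLUMNS)
    df = pd.DataFrame(rows, columns=columns)

    flag = np.zeros(len(df), dtype=bool)
    ratio_data = {}
    for a, b in itertools.permutations(BASE_FEATURE_COLUMNS, 2):
        denom = df[b].to_numpy(dtype=float) if len(df) else np.array([])
        numer = df[a].to_numpy(dtype=float) if len(df) else np.array([])
        zero = denom == 0.0
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where(zero, 0.0, numer / np.where(zero, 1.0, denom))
        ratio_data[f"ratio_{a}_over_{b}"] = ratio
        flag |= zero
    ratio_df = pd.DataFrame(ratio_data, index=df.index, columns=list(RATIO_COLUMNS))
    df = pd.concat([df, ratio_df], axis=1)
    df["zero_denominator"] = flag
    return FeatureMatrix(df, normalized=False)


def normalize_per_slide(matrix: FeatureMatrix) -> FeatureMatrix:
    """Min-max rescale each intensity column to [0, 1] within each slide.

    Constant columns map to 0. Applying the operation twice is an error:
    normalized intensities are no longer on the raw scale and a second
    pass would silently distort them.
    """
    if matrix.normalized:
        raise ValueError("matrix is already normalized per slide")
    df = matrix.data.copy()
    for col in matrix.intensity_columns:
        grouped = df.groupby("slide_id")[col]
        lo = grouped.transform("min")
        hi = grouped.transform("max")
        span = hi - lo
        with np.errstate(invalid="ignore"):
            scaled = (df[col] - lo) / span.where(span > 0, np.nan)
        df[col] = scaled.fillna(0.0)
    return FeatureMatrix(df, normalized=True)
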