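"""Seeded synthetic 4-channel slide renderer with ground-truth annotations.

Emulates a plated monolayer of nucleated blood cells (DAPI+ | CD45/CD31+
leukocyte background) with spiked rare cells and anucleate DAPI- | PanCK+
large extracellular vesicles, so that segmentation, rare-event detection,
and marker classification can be exercised end to end against known truth.

Objects are anisotropic Gaussian-profile ellipses with hard support at
1.5 sigma, i.e. the support ellipse *is* the specified cell outline, and
the amplitude is scaled so that the mean intensity over the support
equals the requested per-channel foreground mean. Frames carry additive
Gaussian read noise on a small constant baseline.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .labels import (
    CHANNELS,
    LEV,
)
from .segmentation import FrameImage

# Mean of exp(-u/2) over the elliptical support u <= 1.5**2, where u is the
# squared Mahalanobis radius: (2/R^2) * (1 - exp(-R^2/2)) with R = 1.5.
_SUPPORT_SIGMA = 1.5
_PROFILE_MEAN_FACTOR = (2.0 / _SUPPORT_SIGMA**2) * (1.0 - math.exp(-_SUPPORT_SIGMA**2 / 2.0))

#: Leukocytes are the common background population on every slide.
LEUKOCYTE = "leukocyte"


class PlacementError(RuntimeError):
    """Raised when an object cannot be placed without overlap."""


@dataclass(frozen=True)
class EventSpec:
    """Recipe for one population of rendered objects.

    ``channel_means`` are the expected *mean* foreground intensities (in
    [0, 1]) over the object support, per channel. For anucleate LEVs the
    DAPI mean must be 0 and the PanCK mean positive; ``nucleus_diameter_um``
    is ignored (set it to 0).
    """

    label: str
    count: int
    nucleus_diameter_um: float
    cell_diameter_um: float
    channel_means: dict[str, float]
    eccentricity: float = 0.3

    def __post_init__(self) -> None:
        if self.count < 0:
            raise ValueError("count must be non-negative")
        if not 0.0 <= self.eccentricity < 1.0:
            raise ValueError("eccentricity must lie in [0, 1)")
        if self.cell_diameter_um <= 0:
            raise ValueError("cell_diameter_um must be positive")
        missing = [c for c in CHANNELS if c not in self.channel_means]
        if missing:
            raise ValueError(f"channel_means missing channels: {missing}")
        if self.label == LEV:
            if self.channel_means["DAPI"] != 0.0:
                raise ValueError("LEV events must have zero DAPI intensity")
            if self.channel_means["PanCK"] <= 0.0:
                raise ValueError("LEV events must be PanCK positive")
        else:
            if self.nucleus_diameter_um <= 0:
                raise ValueError("nucleated events need a positive nucleus diameter")
            if self.cell_diameter_um < self.nucleus_diameter_um:
                raise ValueError("cell diameter must be >= nucleus diameter")

    @property
    def nucleated(self) -> bool:
        return self.label != LEV


@dataclass(frozen=True)
class SlideSpec:
    """Full description of one synthetic slide.

    The default profile is a desk-scale stand-in for a production slide
    (which carries ~3 million cells over thousands of frames): 16 frames
    of 1024 x 1024 px at 0.33 um/px with ~2,000 background leukocytes,
    keeping per-frame densities realistic.
    """

    background_cells: EventSpec
    rare_events: tuple[EventSpec, ...] = ()
    n_frames: int = 16
    frame_shape_px: tuple[int, int] = (1024, 1024)
    um_per_px: float = 0.33
    noise_sd: float = 0.01
    baseline: float = 0.02
    seed: int = 0
    slide_id: str = "synthetic-slide"
    max_retries: int = 1000

    def __post_init__(self) -> None:
        if self.n_frames <= 0:
            raise ValueError("n_frames must be positive")
        if self.um_per_px <= 0:
            raise ValueError("um_per_px (pixel scale) must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


def leukocyte_spec(count: int = 2000) -> EventSpec:
    """Default DAPI+ | CD45/CD31+ leukocyte background population."""
    return EventSpec(
        label=LEUKOCYTE,
        count=count,
        nucleus_diameter_um=7.0,
        cell_diameter_um=9.0,
        channel_means={"DAPI": 0.55, "PanCK": 0.02, "VIM": 0.02, "CD45/CD31": 0.5},
        eccentricity=0.3,
    )


def default_rare_events(n_per_class: int = 3, n_lev: int = 4) -> tuple[EventSpec, ...]:
    """Default spike-in panel: every nucleated rare class plus LEVs.

    Marker means follow the class definitions (positive markers bright,
    negative markers at autofluorescence level); rare cells are rendered
    larger than leukocytes, as tumor-derived and morphologically distinct
    cells are in practice.
    """
    hi, lo, dapi = 0.55, 0.02, 0.55

    def cms(panck: float, vim: float, cd45: float) -> dict[str, float]:
        return {"DAPI": dapi, "PanCK": panck, "VIM": vim, "CD45/CD31": cd45}

    specs = [
        EventSpec("epi.CTC", n_per_class, 10.0, 14.0, cms(hi, lo, lo)),
        EventSpec("mes.CTC", n_per_class, 10.0, 14.0, cms(hi, 0.45, lo)),
        EventSpec("dp.CTC", n_per_class, 10.0, 14.0, cms(hi, lo, 0.45)),
        EventSpec("tp.CTC", n_per_class, 10.0, 14.0, cms(0.5, 0.4, 0.35)),
        EventSpec("vim.cell", n_per_class, 9.0, 13.0, cms(lo, 0.5, lo)),
        EventSpec("hem.cell", n_per_class, 12.0, 16.0, cms(lo, lo, 0.5)),
        EventSpec("vim.hem.cell", n_per_class, 12.0, 16.0, cms(lo, 0.45, 0.45)),
        EventSpec("dapi.only", n_per_class, 12.0, 15.0, cms(lo, lo, lo)),
        EventSpec(
            LEV, n_lev, 0.0, 6.0,
            {"DAPI": 0.0, "PanCK": 0.5, "VIM": 0.03, "CD45/CD31": 0.02},
        ),
    ]
    return tuple(s for s in specs if s.count > 0)


def default_slide_spec(seed: int = 0, **overrides) -> SlideSpec:
    """The default study slide: leukocyte monolayer plus the spike-in panel."""
    kwargs = dict(
        background_cells=leukocyte_spec(),
        rare_events=default_rare_events(),
        seed=seed,
        slide_id=f"synthetic-slide-{seed}",
    )
    kwargs.update(overrides)
    return SlideSpec(**kwargs)


def _ellipse_axes_px(diameter_um: float, eccentricity: float, um_per_px: float) -> tuple[float, float]:
    """Semi-axes (a >= b) in px preserving the equivalent-diameter area."""
    r = diameter_um / 2.0 / um_per_px
    stretch = (1.0 - eccentricity**2) ** 0.25
    return r / stretch, r * stretch


def _render_object(
    frame: np.ndarray,
    row: float,
    col: float,
    theta: float,
    diameter_um: float,
    eccentricity: float,
    um_per_px: float,
    channel_means: dict[str, float],
    channel_subset: tuple[str, ...],
) -> None:
    a, b = _ellipse_axes_px(diameter_um, eccentricity, um_per_px)
    half = int(math.ceil(max(a, b))) + 1
    r0, r1 = int(row) - half, int(row) + half + 1
    c0, c1 = int(col) - half, int(col) + half + 1
    rr, cc = np.meshgrid(np.arange(r0, r1), np.arange(c0, c1), indexing="ij")
    dy, dx = rr - row, cc - col
    # rotate into the ellipse frame
    xr = dx * math.cos(theta) + dy * math.sin(theta)
    yr = -dx * math.sin(theta) + dy * math.cos(theta)
    # squared Mahalanobis radius in sigma units (support ellipse at 1.5 sigma)
    u = (xr / (a / _SUPPORT_SIGMA)) ** 2 + (yr / (b / _SUPPORT_SIGMA)) ** 2
    inside = u <= _SUPPORT_SIGMA**2
    profile = np.where(inside, np.exp(-u / 2.0), 0.0)
    for ch in channel_subset:
        mean = channel_means[ch]
        if mean <= 0.0:
            continue
        amplitude = mean / _PROFILE_MEAN_FACTOR
        idx = CHANNELS.index(ch)
        frame[idx, r0:r1, c0:c1] += amplitude * profile


def render_slide(spec: SlideSpec) -> tuple[list[FrameImage], pd.DataFrame]:
    """Render one slide; returns frames and the ground-truth table.

    Ground truth has one row per synthesized foreground object with
    columns ``frame_id, x_px, y_px, label, diameter_um``. Identical specs
    (including the seed) render bit-identical output.
    """
    rng = np.random.default_rng(spec.seed)
    h, w = spec.frame_shape_px
    stacks = [np.zeros((len(CHANNELS), h, w), dtype=np.float64) for _ in range(spec.n_frames)]
    placed: list[list[tuple[float, float, float]]] = [[] for _ in range(spec.n_frames)]

    truth_rows: list[dict] = []
    populations = [spec.background_cells, *spec.rare_events]
    for pop in populations:
        radius_px = pop.cell_diameter_um / 2.0 / spec.um_per_px
        # widest extent of the support ellipse
        a, _ = _ellipse_axes_px(pop.cell_diameter_um, pop.eccentricity, spec.um_per_px)
        margin = a + 2.0
        for _ in range(pop.count):
            for attempt in range(spec.max_retries):
                fid = int(rng.integers(spec.n_frames))
                row = rng.uniform(margin, h - margin)
                col = rng.uniform(margin, w - margin)
                ok = all(
                    (row - pr) ** 2 + (col - pc) ** 2 > (radius_px + prad + 2.0) ** 2
                    for pr, pc, prad in placed[fid]
                )
                if ok:
                    break
            else:
                raise PlacementError(
                    f"could not place a {pop.label!r} object after "
                    f"{spec.max_retries} retries (last attempted frame {fid}); "
                    "slide too crowded"
                )
            theta = rng.uniform(0.0, math.pi)
            placed[fid].append((row, col, a))
            _render_object(
                stacks[fid], row, col, theta,
                pop.cell_diameter_um, pop.eccentricity, spec.um_per_px,
                pop.channel_means, CHANNELS,
            )
            if pop.nucleated:
                # nucleus carries the DAPI signal at the nucleus diameter
                _render_object(
                    stacks[fid], row, col, theta,
                    pop.nucleus_diameter_um, pop.eccentricity, spec.um_per_px,
                    pop.channel_means, ("DAPI",),
                )
            truth_rows.append(
                dict(
                    frame_id=fid,
                    x_px=col,
                    y_px=row,
                    label=pop.label,
                    diameter_um=pop.cell_diameter_um,
                )
            )

    frames: list[FrameImage] = []
    for fid, stack in enumerate(stacks):
        noisy = stack + spec.baseline + rng.normal(0.0, spec.noise_sd, size=stack.shape)
        np.clip(noisy, 0.0, 1.0, out=noisy)
        frames.append(
            FrameImage(
                pixels=noisy,
                um_per_px=spec.um_per_px,
                frame_id=f"frame_{fid:04d}",
                slide_id=spec.slide_id,
            )
        )
    truth = pd.DataFrame(truth_rows, columns=["frame_id", "x_px", "y_px", "label", "diameter_um"])
    truth["frame_id"] = truth["frame_id"].map(lambda i: f"frame_{i:04d}")
    return frames, truth


# ---------------------------------------------------------------------------
# Frame I/O: one multi-page TIFF per frame, 16-bit, metadata in the
# image description. Pixel data are quantized to 16 bits at write time;
# a second write/read round trip is exactly lossless.
# ---------------------------------------------------------------------------

_SCALE = np.float64(65535.0)


def write_frames(frames: list[FrameImage], path: str | Path) -> list[Path]:
    """Write each frame as a 4-page TIFF under ``path``; returns file paths."""
    out = Path(path)
    out.mkdir(parents=True, exist_ok=True)
    written = []
    for frame in frames:
        desc = json.dumps(
            {
                "um_per_px": frame.um_per_px,
                "channels": list(CHANNELS),
                "frame_id": frame.frame_id,
                "slide_id": frame.slide_id,
            }
        )
        data = np.round(np.clip(frame.pixels, 0.0, 1.0) * _SCALE).astype(np.uint16)
        fpath = out / f"{frame.frame_id}.tif"
        tifffile.imwrite(fpath, data, photometric="minisblack", description=desc)
        written.append(fpath)
    return written


def read_frames(path: str | Path) -> list[FrameImage]:
    """Read all ``*.tif`` frames under ``path`` (sorted by file name)."""
    frames = []
    for fpath in sorted(Path(path).glob("*.tif")):
        with tifffile.TiffFile(fpath) as tif:
            data = tif.asarray()
            desc = tif.pages[0].description
        if data.ndim != 3 or data.shape[0] != len(CHANNELS):
            raise ValueError(
                f"{fpath.name}: expected {len(CHANNELS)} channels, "
                f"got shape {data.shape}"
            )
        meta = json.loads(desc)
        frames.append(
            FrameImage(
                pixels=data.astype(np.float64) / float(_SCALE),
                um_per_px=float(meta["um_per_px"]),
                frame_id=str(meta["frame_id"]),
                slide_id=str(meta["slide_id"]),
            )
        )
    return frames


def write_ground_truth(truth: pd.DataFrame, path: str | Path) -> None:
    truth.to_csv(path, index=False)


def read_ground_truth(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)
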