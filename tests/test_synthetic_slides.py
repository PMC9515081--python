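"""Renderer fidelity: counts, photometry, geometry, determinism, I/O."""

from __future__ import annotations

import numpy as np
import pytest

from lbx.labels import CHANNELS
from lbx.segmentation import extract_features, segment_slide
from lbx.synthetic_slides import (
    EventSpec,
    PlacementError,
    SlideSpec,
    leukocyte_spec,
    read_frames,
    render_slide,
    write_frames,
)

EPI = EventSpec(
    "epi.CTC", 5, 10.0, 14.0,
    {"DAPI": 0.55, "PanCK": 0.55, "VIM": 0.02, "CD45/CD31": 0.02},
)


def _slide(background=100, rare=(), **kw):
    defaults = dict(
        background_cells=leukocyte_spec(count=background),
        rare_events=tuple(rare),
        n_frames=2,
        frame_shape_px=(512, 512),
        seed=5,
    )
    defaults.update(kw)
    return SlideSpec(**defaults)


class TestGroundTruthBookkeeping:
    def test_background_only_count_conservation(self):
        frames, truth = render_slide(_slide(background=100))
        assert len(truth) == 100
        assert (truth["label"] == "leukocyte").all()

    def test_spiked_events_are_recorded(self):
        frames, truth = render_slide(_slide(background=500, rare=[EPI], n_frames=4))
        assert len(truth) == 505
        assert (truth["label"] == "epi.CTC").sum() == 5

    def test_every_frame_has_four_channels(self):
        frames, _ = render_slide(_slide(background=20))
        for f in frames:
            assert f.pixels.shape[0] == len(CHANNELS)


class TestPhotometry:
    def test_lev_objects_carry_no_dapi_signal(self):
        lev = EventSpec(
            "LEV", 3, 0.0, 6.0,
            {"DAPI": 0.0, "PanCK": 0.5, "VIM": 0.0, "CD45/CD31": 0.0},
        )
        spec = _slide(background=0, rare=[lev], background_cells=leukocyte_spec(0))
        frames, truth = render_slide(spec)
        r_px = 3.0 / spec.um_per_px  # LEV radius in px
        for _, row in truth.iterrows():
            fid = int(row["frame_id"].split("_")[1])
            img = frames[fid].pixels[CHANNELS.index("DAPI")]
            yy, xx = np.ogrid[: img.shape[0], : img.shape[1]]
            disk = (yy - row["y_px"]) ** 2 + (xx - row["x_px"]) ** 2 <= r_px**2
            assert img[disk].mean() < spec.baseline + 3 * spec.noise_sd

    def test_mean_foreground_intensity_matches_spec(self):
        # 30 round cells; per-object mean over the support disk should
        # estimate the specified channel means within 3 standard errors
        pop = EventSpec(
            "leukocyte", 30, 8.0, 10.0,
            {"DAPI": 0.5, "PanCK": 0.3, "VIM": 0.02, "CD45/CD31": 0.4},
            eccentricity=0.0,
        )
        spec = _slide(background=0, background_cells=pop, n_frames=2)
        frames, truth = render_slide(spec)
        r_px = pop.cell_diameter_um / 2 / spec.um_per_px
        for ch in ("PanCK", "VIM", "CD45/CD31"):
            idx = CHANNELS.index(ch)
            means = []
            for _, row in truth.iterrows():
                fid = int(row["frame_id"].split("_")[1])
                img = frames[fid].pixels[idx]
                yy, xx = np.ogrid[: img.shape[0], : img.shape[1]]
                disk = (yy - row["y_px"]) ** 2 + (xx - row["x_px"]) ** 2 <= r_px**2
                means.append(img[disk].mean() - spec.baseline)
            means = np.array(means)
            se = means.std(ddof=1) / np.sqrt(len(means))
            assert abs(means.mean() - pop.channel_means[ch]) < 3 * se + 0.01

    def test_geometric_fidelity_of_rendered_diameters(self):
        spec = _slide(background=60, n_frames=2)
        frames, _ = render_slide(spec)
        events = [e for e in segment_slide(frames) if not e.dapi_negative]
        assert len(events) >= 50
        diam = np.median([e.equivalent_diameter_um for e in events])
        target = spec.background_cells.cell_diameter_um
        assert abs(diam - target) / target < 0.15


class TestDeterminismAndErrors:
    def test_identical_seed_gives_identical_output(self):
        spec = _slide(background=50, rare=[EPI])
        f1, t1 = render_slide(spec)
        f2, t2 = render_slide(spec)
        for a, b in zip(f1, f2):
            np.testing.assert_array_equal(a.pixels, b.pixels)
        assert t1.equals(t2)

    def test_overcrowded_slide_raises_placement_error(self):
        spec = _slide(
            background=2000, n_frames=1, frame_shape_px=(128, 128), max_retries=50
        )
        with pytest.raises(PlacementError, match="frame"):
            render_slide(spec)

    def test_nonpositive_pixel_scale_rejected(self):
        with pytest.raises(ValueError, match="um_per_px"):
            _slide(background=10, um_per_px=0.0)

    def test_lev_spec_requires_zero_dapi(self):
        with pytest.raises(ValueError, match="DAPI"):
            EventSpec("LEV", 1, 0.0, 6.0,
                      {"DAPI": 0.3, "PanCK": 0.5, "VIM": 0.0, "CD45/CD31": 0.0})

    def test_cell_smaller_than_nucleus_rejected(self):
        with pytest.raises(ValueError, match="diameter"):
            EventSpec("epi.CTC", 1, 10.0, 8.0,
                      {"DAPI": 0.5, "PanCK": 0.5, "VIM": 0.0, "CD45/CD31": 0.0})


class TestFrameIO:
    def test_round_trip_preserves_pixels_and_metadata(self, tmp_path):
        spec = _slide(background=30, um_per_px=0.325)
        frames, _ = render_slide(spec)
        write_frames(frames, tmp_path)
        back = read_frames(tmp_path)
        assert len(back) == len(frames)
        for orig, rt in zip(frames, back):
            # first round trip is exact up to 16-bit quantization ...
            np.testing.assert_allclose(rt.pixels, orig.pixels, atol=0.5 / 65535 + 1e-12)
            assert rt.um_per_px == 0.325
            assert rt.frame_id == orig.frame_id
        # ... and a second round trip is exactly lossless
        write_frames(back, tmp_path / "again")
        again = read_frames(tmp_path / "again")
        for rt, rt2 in zip(back, again):
            np.testing.assert_array_equal(rt.pixels, rt2.pixels)

    def test_wrong_channel_count_raises(self, tmp_path):
        import tifffile

        tifffile.imwrite(
            tmp_path / "bad.tif",
            np.zeros((3, 32, 32), dtype=np.uint16),
            photometric="minisblack",
            planarconfig="separate",
            description='{"um_per_px": 0.33, "frame_id": "x", "slide_id": "y"}',
        )
        with pytest.raises(ValueError, match="channels"):
            read_frames(tmp_path)
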