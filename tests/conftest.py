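"""Shared fixtures: one small rendered slide reused across image tests."""

from __future__ import annotations

import pytest

from lbx.pipeline import process_slide
from lbx.synthetic_slides import (
    SlideSpec,
    default_rare_events,
    leukocyte_spec,
    render_slide,
)


@pytest.fixture(scope="session")
def small_slide():
    """A reduced slide (4 frames, 300 leukocytes, full spike panel)."""
    spec = SlideSpec(
        background_cells=leukocyte_spec(count=300),
        rare_events=default_rare_events(n_per_class=1, n_lev=2),
        n_frames=4,
        frame_shape_px=(512, 512),
        seed=11,
        slide_id="test-slide",
    )
    frames, truth = render_slide(spec)
    return spec, frames, truth


@pytest.fixture(scope="session")
def small_slide_processed(small_slide):
    _, frames, truth = small_slide
    labelled, matrix = process_slide(frames)
    return labelled, matrix, truth
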