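"""End-to-end slide processing and ground-truth evaluation helpers."""

from __future__ import annotations

import numpy as np
import pandas as pd

from .classification import PositivityThresholds, classify_all
from .rare_detection import RareDetectionParams, detect_rare, merge_dapi_negative
from .segmentation import (
    FeatureMatrix,
    FrameImage,
    SegmentationParams,
    extract_features,
    normalize_per_slide,
    segment_slide,
)


def process_slide(
    frames: list[FrameImage],
    seg_params: SegmentationParams | None = None,
    det_params: RareDetectionParams | None = None,
    thresholds: PositivityThresholds | None = None,
) -> tuple[pd.DataFrame, FeatureMatrix]:
    """Segment, featurize, detect rare candidates, and classify a slide.

    Returns the labelled event table and the normalized feature matrix.
    """
    events = segment_slide(frames, seg_params)
    matrix = normalize_per_slide(extract_features(events))
    calls = detect_rare(matrix, det_params)
    calls = merge_dapi_negative(calls, matrix)
    labelled = classify_all(matrix, calls, thresholds)
    return labelled, matrix


def match_ground_truth(
    truth: pd.DataFrame, labelled: pd.DataFrame, tolerance_px: float = 5.0
) -> pd.DataFrame:
    """Greedy nearest-neighbour match of truth objects to detected events.

    Matches within the same frame at the given pixel tolerance; each
    detected event is consumed by at most one truth object. Returns the
    truth table with ``detected`` (bool) and ``detected_label`` columns.
    """
    out = truth.copy()
    out["detected"] = False
    out["detected_label"] = None
    for frame_id, t_sub in truth.groupby("frame_id"):
        d_sub = labelled[labelled["frame_id"] == frame_id]
        if d_sub.empty:
            continue
        d_xy = d_sub[["x_px", "y_px"]].to_numpy(dtype=float)
        taken = np.zeros(len(d_sub), dtype=bool)
        for idx, t_row in t_sub.iterrows():
            d2 = (d_xy[:, 0] - t_row["x_px"]) ** 2 + (d_xy[:, 1] - t_row["y_px"]) ** 2
            d2[taken] = np.inf
            j = int(np.argmin(d2))
            if d2[j] <= tolerance_px**2:
                taken[j] = True
                out.loc[idx, "detected"] = True
                out.loc[idx, "detected_label"] = d_sub.iloc[j]["label"]
    return out


def spike_in_recovery(matched: pd.DataFrame, rare_labels: list[str]) -> dict:
    """Detection and classification rates for ground-truth rare events."""
    rare = matched[matched["label"].isin(rare_labels)]
    if rare.empty:
        raise ValueError("ground truth contains no rare events")
    detected = rare["detected"].to_numpy()
    correct = (rare["detected_label"] == rare["label"]).to_numpy()
    return {
        "n_rare": int(len(rare)),
        "detection_rate": float(detected.mean()),
        "classification_rate": float(correct.mean()),
    }
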