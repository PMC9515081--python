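"""PCA + hierarchical clustering rare-event calls."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from lbx.labels import ENUMERATED_CLASSES
from lbx.rare_detection import (
    CALL_COMMON,
    CALL_RARE,
    RareDetectionParams,
    detect_rare,
    merge_dapi_negative,
)
from lbx.segmentation import DetectedEvent, extract_features, normalize_per_slide


def _gaussian_matrix(n=300, seed=0, dapi_negative_tail=0):
    """One homogeneous background population (plus optional DAPI- events)."""
    rng = np.random.default_rng(seed)
    events = []
    for i in range(n):
        events.append(
            DetectedEvent(
                event_id=f"e{i:04d}",
                slide_id="s0",
                frame_id="f0",
                x_px=float(i),
                y_px=0.0,
                nucleus_area_um2=40 + rng.normal(0, 3),
                cell_area_um2=70 + rng.normal(0, 5),
                nucleus_eccentricity=float(np.clip(rng.normal(0.3, 0.05), 0, 0.9)),
                cell_eccentricity=float(np.clip(rng.normal(0.3, 0.05), 0, 0.9)),
                raw_channel_means={
                    "DAPI": 0.5 + rng.normal(0, 0.02),
                    "PanCK": 0.05 + rng.normal(0, 0.01),
                    "VIM": 0.05 + rng.normal(0, 0.01),
                    "CD45/CD31": 0.4 + rng.normal(0, 0.02),
                },
            )
        )
    for j in range(dapi_negative_tail):
        events.append(
            DetectedEvent(
                event_id=f"lev{j:02d}",
                slide_id="s0",
                frame_id="f0",
                x_px=0.0,
                y_px=float(j),
                nucleus_area_um2=0.0,
                cell_area_um2=28.0,
                nucleus_eccentricity=0.0,
                cell_eccentricity=0.2,
                raw_channel_means={
                    "DAPI": 0.01, "PanCK": 0.4 if j % 2 == 0 else 0.0,
                    "VIM": 0.0, "CD45/CD31": 0.0,
                },
            )
        )
    return normalize_per_slide(extract_features(events))


class TestDetectRare:
    def test_spiked_rare_events_recovered(self, small_slide_processed):
        labelled, matrix, truth = small_slide_processed
        nucleated_rare = [c for c in ENUMERATED_CLASSES if c != "LEV"]
        n_spiked = truth["label"].isin(nucleated_rare).sum()
        n_called = (
            labelled["label"].isin(nucleated_rare).sum()
        )
        assert n_called >= 0.9 * n_spiked

    def test_homogeneous_background_has_no_rare_calls(self):
        result = detect_rare(_gaussian_matrix(n=400))
        assert (result.calls["call"] == CALL_COMMON).all()

    def test_small_input_passes_all_through_with_warning(self):
        with pytest.warns(UserWarning, match="rare-candidates"):
            result = detect_rare(_gaussian_matrix(n=10))
        assert (result.calls["call"] == CALL_RARE).all()

    def test_unnormalized_matrix_rejected(self):
        from lbx.segmentation import extract_features

        matrix = _gaussian_matrix(n=60)
        matrix.normalized = False
        with pytest.raises(ValueError, match="normalized"):
            detect_rare(matrix)

    def test_degenerate_zero_variance_matrix_all_common(self):
        matrix = _gaussian_matrix(n=60)
        for col in matrix.feature_columns:
            matrix.data[col] = 1.0
        with pytest.warns(UserWarning, match="degenerate"):
            result = detect_rare(matrix)
        assert (result.calls["call"] == CALL_COMMON).all()

    def test_calls_partition_event_set(self, small_slide_processed):
        _, matrix, _ = small_slide_processed
        result = merge_dapi_negative(detect_rare(matrix), matrix)
        assert sorted(result.calls["event_id"]) == sorted(matrix.data["event_id"])
        assert result.calls["call"].isin([CALL_COMMON, CALL_RARE]).all()
        assert not result.calls["event_id"].duplicated().any()

    def test_rare_fraction_respects_ceiling(self, small_slide_processed):
        _, matrix, _ = small_slide_processed
        params = RareDetectionParams()
        result = detect_rare(matrix, params)
        n = (~matrix.data["dapi_negative"]).sum()
        assert (result.calls["call"] == CALL_RARE).sum() <= params.ceiling_fraction * n

    def test_rarity_fraction_monotone(self):
        matrix = _gaussian_matrix(n=300, seed=7)
        # perturb a handful of events into outliers
        matrix.data.loc[:4, "mean_PanCK"] = 1.0
        counts = []
        for rf in (0.005, 0.02, 0.04):
            params = RareDetectionParams(rarity_fraction=rf)
            res = detect_rare(matrix, params)
            counts.append((res.calls["call"] == CALL_RARE).sum())
        assert counts == sorted(counts)

    def test_determinism(self, small_slide_processed):
        _, matrix, _ = small_slide_processed
        r1 = detect_rare(matrix)
        r2 = detect_rare(matrix)
        pd.testing.assert_frame_equal(r1.calls, r2.calls)


class TestMergeDapiNegative:
    def test_panck_positive_negatives_become_lev_candidates(self):
        matrix = _gaussian_matrix(n=100, dapi_negative_tail=4)
        result = merge_dapi_negative(detect_rare(matrix), matrix)
        negatives = result.calls[result.calls["event_id"].str.startswith("lev")]
        tagged = negatives[negatives["lev_candidate"]]
        # half the tail was rendered PanCK+ (j even)
        assert len(tagged) == 2
        assert (tagged["call"] == CALL_RARE).all()

    def test_panck_zero_negatives_excluded_from_lev_path(self):
        matrix = _gaussian_matrix(n=100, dapi_negative_tail=2)
        result = merge_dapi_negative(detect_rare(matrix), matrix)
        dark = result.calls[result.calls["event_id"] == "lev01"]
        assert not dark["lev_candidate"].iloc[0]
        assert dark["call"].iloc[0] == CALL_COMMON

    def test_merge_preserves_id_partition(self):
        matrix = _gaussian_matrix(n=80, dapi_negative_tail=3)
        before = detect_rare(matrix)
        after = merge_dapi_negative(before, matrix)
        added = set(after.calls["event_id"]) - set(before.calls["event_id"])
        assert added == {"lev00", "lev01", "lev02"}
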