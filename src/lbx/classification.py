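"""Marker-combination classification of rare-event candidates.

Nucleated (DAPI+) candidates map onto the 8 rare-cell classes given by
the 2**3 positivity combinations of PanCK, VIM, and CD45/CD31 (the two
leukocyte/endothelial markers share one fluorescence channel, so their
positivity is necessarily joint). Anucleate candidates are large
extracellular vesicles when PanCK-positive and within the 1-10 um
equivalent-diameter gate (closed interval); anything else returns to
the common pool.

Positivity is judged on per-slide min-max-normalized mean intensities
against configurable thresholds; the manual analyst curation step of
production workflows is replaced by this deterministic rule.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .labels import COMMON, LEV, RARE_CLASS_BY_TRIPLE
from .rare_detection import CALL_RARE, RareCallResult
from .segmentation import CHANNEL_COLUMNS, FeatureMatrix

_DAPI, _PANCK, _VIM, _CD45 = CHANNEL_COLUMNS


@dataclass(frozen=True)
class PositivityThresholds:
    """Per-channel positivity cutoffs on normalized intensity, plus the
    LEV diameter gate (closed interval, micrometers)."""

    dapi: float = 0.1
    panck: float = 0.1
    vim: float = 0.1
    cd45_cd31: float = 0.1
    lev_diameter_range_um: tuple[float, float] = (1.0, 10.0)

    def __post_init__(self) -> None:
        for name in ("dapi", "panck", "vim", "cd45_cd31"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} threshold must lie strictly in (0, 1)")
        lo, hi = self.lev_diameter_range_um
        if lo <= 0 or hi < lo:
            raise ValueError("lev_diameter_range_um must satisfy 0 < lo <= hi")

    def to_dict(self) -> dict:
        return {
            "dapi": self.dapi,
            "panck": self.panck,
            "vim": self.vim,
            "cd45_cd31": self.cd45_cd31,
            "lev_diameter_range_um": list(self.lev_diameter_range_um),
        }


def classify_event(
    event: pd.Series | dict, thresholds: PositivityThresholds | None = None
) -> str:
    """Label one rare-candidate from its normalized means and diameter.

    ``event`` must provide the four ``mean_*`` channel columns and
    ``equivalent_diameter_um``. Returns exactly one class label.
    """
    thresholds = thresholds or PositivityThresholds()
    for col in (*CHANNEL_COLUMNS, "equivalent_diameter_um"):
        value = event.get(col)
        if value is None or (isinstance(value, float) and np.isnan(value)):
            raise ValueError(f"event is missing channel/feature value {col!r}")

    dapi_pos = event[_DAPI] >= thresholds.dapi
    panck_pos = event[_PANCK] >= thresholds.panck
    if dapi_pos:
        triple = (
            bool(panck_pos),
            bool(event[_VIM] >= thresholds.vim),
            bool(event[_CD45] >= thresholds.cd45_cd31),
        )
        return RARE_CLASS_BY_TRIPLE[triple]
    lo, hi = thresholds.lev_diameter_range_um
    if panck_pos and lo <= event["equivalent_diameter_um"] <= hi:
        return LEV
    return COMMON


def classify_all(
    matrix: FeatureMatrix,
    calls: RareCallResult,
    thresholds: PositivityThresholds | None = None,
) -> pd.DataFrame:
    """Label every event: common calls stay common, candidates are
    classified by the positivity rules.

    Returns the event table (metadata + normalized means + diameter)
    with an added ``label`` column; logs per-slide class counts.
    """
    thresholds = thresholds or PositivityThresholds()
    if not matrix.normalized:
        raise ValueError("classify_all requires a per-slide-normalized matrix")
    df = matrix.data
    call_map = calls.calls.set_index("event_id")["call"]
    missing = set(df["event_id"]).symmetric_difference(call_map.index)
    if missing:
        raise ValueError(
            f"event/call id mismatch for {len(missing)} events, e.g. {sorted(missing)[:3]}"
        )

    out = df[
        [
            "event_id",
            "slide_id",
            "frame_id",
            "x_px",
            "y_px",
            "dapi_negative",
            "equivalent_diameter_um",
            *CHANNEL_COLUMNS,
        ]
    ].copy()
    out["call"] = call_map.loc[out["event_id"]].to_numpy()
    labels = []
    for _, row in out.iterrows():
        if row["call"] != CALL_RARE:
            labels.append(COMMON)
        else:
            labels.append(classify_event(row, thresholds))
    out["label"] = labels
    return out
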