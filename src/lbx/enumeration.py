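"""Conversion of per-slide event counts to events per ml of blood.

Each blood draw is plated on two slides; the DAPI nuclei counted across
those two slides (N) together with the complete-blood-count nucleated
cell concentration (W, cells/ml) define the blood-volume equivalent
N / W analyzed, so a raw class count k converts to a rate
c = k * W / N events per ml. Counts and nuclei from the two slides are
pooled before division; per-slide rates are never averaged.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .labels import ENUMERATED_CLASSES, GROUPS


def events_per_ml(k: int, nuclei: int, wbc_per_ml: float) -> float:
    """Rate (events/ml) for k events against nuclei counted and CBC W."""
    if nuclei <= 0:
        raise ValueError("nuclei counted must be positive")
    if wbc_per_ml <= 0:
        raise ValueError("wbc_per_ml must be positive")
    if k < 0:
        raise ValueError("event count must be non-negative")
    return k * wbc_per_ml / nuclei


def summarize_group(
    records: pd.DataFrame,
    class_label: str,
    positive_threshold: float = 0.0,
) -> dict:
    """Per-group summary of one class's per-ml rates.

    Returns mean, median, range, and the detected fraction. With the
    default ``positive_threshold=0`` a sample counts as positive when
    its rate is strictly greater than zero (at least one event seen);
    pass 1.0 to count samples with at least one event per ml, the
    convention used for vesicles.
    """
    if records.empty:
        raise ValueError("cannot summarize an empty group")
    col = f"rate_{class_label}"
    if col not in records.columns:
        raise KeyError(f"no rate column for class {class_label!r}")
    rates = records[col].to_numpy(dtype=float)
    if positive_threshold == 0.0:
        positive = rates > 0.0
    else:
        positive = rates >= positive_threshold
    return {
        "class": class_label,
        "n": len(rates),
        "mean": float(rates.mean()),
        "median": float(np.median(rates)),
        "range": (float(rates.min()), float(rates.max())),
        "fraction_positive": float(positive.mean()),
    }


def build_sample_table(labels: pd.DataFrame, meta: pd.DataFrame) -> pd.DataFrame:
    """Aggregate a labelled event table into per-sample counts and rates.

    ``labels`` needs columns slide_id and label; ``meta`` needs one row
    per sample with sample_id, group, cbc_wbc_per_ml, nuclei_counted and
    a way to map slides to samples (column sample_id per slide via a
    slide manifest merged beforehand, or labels already carrying
    sample_id). Slides of a sample are pooled before division.
    """
    if "sample_id" not in labels.columns:
        raise ValueError("labels table must carry a sample_id column (merge the slide manifest first)")
    rows = []
    for _, m in meta.iterrows():
        sub = labels[labels["sample_id"] == m["sample_id"]]
        row = {
            "sample_id": m["sample_id"],
            "group": m["group"],
            "cbc_wbc_per_ml": float(m["cbc_wbc_per_ml"]),
            "nuclei_counted": int(m["nuclei_counted"]),
        }
        for cls in ENUMERATED_CLASSES:
            k = int((sub["label"] == cls).sum())
            row[f"count_{cls}"] = k
            row[f"rate_{cls}"] = events_per_ml(
                k, row["nuclei_counted"], row["cbc_wbc_per_ml"]
            )
        rows.append(row)
    return pd.DataFrame(rows)


def slide_manifest(sample_ids: list[str], slides_per_sample: int = 2) -> pd.DataFrame:
    """Slide bookkeeping: each blood draw is plated on a fixed number of
    slides (two in the standard workflow)."""
    rows = [
        {"sample_id": sid, "slide_id": f"{sid}-s{i + 1}"}
        for sid in sample_ids
        for i in range(slides_per_sample)
    ]
    return pd.DataFrame(rows, columns=["sample_id", "slide_id"])


def default_study_manifest() -> pd.DataFrame:
    """Draw-level manifest of the default study layout.

    74 treatment-naive early-stage draws (one per patient), 51 draws
    from the 26 late-stage patients (serial draws assigned round-robin),
    and 30 normal-donor draws: 155 draws, two slides each.
    """
    sample_rows = []
    for i in range(74):
        sample_rows.append({"sample_id": f"early-{i + 1:03d}", "group": "early",
                            "participant_id": f"pt-early-{i + 1:03d}"})
    for d in range(51):
        patient = d % 26 + 1
        sample_rows.append({"sample_id": f"late-{d + 1:03d}", "group": "late",
                            "participant_id": f"pt-late-{patient:03d}"})
    for i in range(30):
        sample_rows.append({"sample_id": f"normal-{i + 1:03d}", "group": "normal",
                            "participant_id": f"pt-normal-{i + 1:03d}"})
    samples = pd.DataFrame(sample_rows)
    manifest = slide_manifest(samples["sample_id"].tolist(), slides_per_sample=2)
    return manifest.merge(samples, on="sample_id")
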