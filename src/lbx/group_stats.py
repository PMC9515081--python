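"""Nonparametric group comparisons and correlations over cohort tables.

The primary comparison is the Kruskal-Wallis H test (one-way ANOVA on
ranks, tie-corrected, chi-square p approximation), applied per event
class across two or three cohort groups. A Welch t-test is available as
a secondary mean comparison. Planned comparisons are reported without
multiplicity adjustment by design (a Benjamini-Hochberg option exists,
off by default); significance is flagged at alpha = 0.05.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

ALPHA = 0.05


@dataclass
class ComparisonResult:
    """Outcome of one planned comparison."""

    class_label: str
    groups: tuple[str, ...]
    statistic: float
    p_value: float
    test: str
    group_summaries: dict[str, dict] = field(default_factory=dict)

    @property
    def significant(self) -> bool:
        return self.p_value < ALPHA

    def to_row(self) -> dict:
        row = {
            "class": self.class_label,
            "groups": "|".join(self.groups),
            "test": self.test,
            "statistic": self.statistic,
            "p_value": self.p_value,
            "significant": self.significant,
        }
        for g, s in self.group_summaries.items():
            row[f"{g}_mean"] = s["mean"]
            row[f"{g}_median"] = s["median"]
            row[f"{g}_min"] = s["range"][0]
            row[f"{g}_max"] = s["range"][1]
        return row


def _summaries(values_by_group: dict[str, np.ndarray]) -> dict[str, dict]:
    return {
        g: {
            "mean": float(np.mean(v)),
            "median": float(np.median(v)),
            "range": (float(np.min(v)), float(np.max(v))),
        }
        for g, v in values_by_group.items()
    }


def kruskal_wallis(
    values_by_group: dict[str, "np.typing.ArrayLike"], class_label: str = ""
) -> ComparisonResult:
    """Tie-corrected Kruskal-Wallis H across >= 2 non-empty groups.

    Identical pooled values give H = 0 and p = 1 (no rank information).
    """
    arrays = {g: np.asarray(v, dtype=float) for g, v in values_by_group.items()}
    if len(arrays) < 2:
        raise ValueError("need at least two groups")
    for g, v in arrays.items():
        if v.size == 0:
            raise ValueError(f"group {g!r} has no observations")
    pooled = np.concatenate(list(arrays.values()))
    if np.all(pooled == pooled[0]):
        h, p = 0.0, 1.0
    else:
        h, p = sps.kruskal(*arrays.values())
    return ComparisonResult(
        class_label=class_label,
        groups=tuple(arrays),
        statistic=float(h),
        p_value=float(p),
        test="kruskal-wallis",
        group_summaries=_summaries(arrays),
    )


def welch_t(
    values_by_group: dict[str, "np.typing.ArrayLike"], class_label: str = ""
) -> ComparisonResult:
    """Two-group t-test without the equal-variance assumption."""
    arrays = {g: np.asarray(v, dtype=float) for g, v in values_by_group.items()}
    if len(arrays) != 2:
        raise ValueError("the t-test compares exactly two groups")
    a, b = arrays.values()
    t, p = sps.ttest_ind(a, b, equal_var=False)
    return ComparisonResult(
        class_label=class_label,
        groups=tuple(arrays),
        statistic=float(t),
        p_value=float(p),
        test="welch-t",
        group_summaries=_summaries(arrays),
    )


def pairwise_correlations(
    cohort: pd.DataFrame, classes: list[str]
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pearson correlation matrix of per-ml rates across event classes.

    Returns (r, undefined) where ``undefined`` flags pairs involving a
    zero-variance class (their r is NaN). The matrix is symmetric with a
    unit diagonal on well-defined entries.
    """
    if len(cohort) < 3:
        raise ValueError("need at least 3 samples for correlations")
    cols = [f"rate_{c}" for c in classes]
    x = cohort[cols].to_numpy(dtype=float)
    sd = x.std(axis=0)
    degenerate = sd == 0.0
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(x, rowvar=False)
    r = np.asarray(r, dtype=float)
    undefined = np.logical_or.outer(degenerate, degenerate)
    r[undefined] = np.nan
    np.fill_diagonal(r, np.where(degenerate, np.nan, 1.0))
    r_df = pd.DataFrame(r, index=classes, columns=classes)
    flag_df = pd.DataFrame(undefined, index=classes, columns=classes)
    return r_df, flag_df


def compare_all(
    cohort: pd.DataFrame,
    plan: list[dict],
    adjust: str | None = None,
) -> pd.DataFrame:
    """Run a battery of planned per-class group comparisons.

    ``plan`` entries are {"class": <label>, "groups": [<g1>, <g2>, ...]}.
    P values are reported unadjusted by default (planned comparisons);
    pass ``adjust="bh"`` for Benjamini-Hochberg. The report carries an
    ``adjusted`` header column either way.
    """
    known_groups = set(cohort["group"].unique())
    results = []
    for item in plan:
        cls = item["class"]
        col = f"rate_{cls}"
        if col not in cohort.columns:
            raise KeyError(f"unknown class in plan: {cls!r}")
        groups = list(item["groups"])
        unknown = [g for g in groups if g not in known_groups]
        if unknown:
            raise KeyError(f"unknown group(s) in plan: {unknown}")
        values = {
            g: cohort.loc[cohort["group"] == g, col].to_numpy(dtype=float)
            for g in groups
        }
        results.append(kruskal_wallis(values, class_label=cls))

    report = pd.DataFrame([r.to_row() for r in results])
    report["adjusted"] = adjust or "none"
    if adjust == "bh" and len(report):
        p = report["p_value"].to_numpy()
        order = np.argsort(p)
        ranked = p[order] * len(p) / (np.arange(len(p)) + 1)
        adj = np.minimum.accumulate(ranked[::-1])[::-1]
        out = np.empty_like(adj)
        out[order] = np.minimum(adj, 1.0)
        report["p_adjusted"] = out
        report["significant"] = report["p_adjusted"] < ALPHA
    return report
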