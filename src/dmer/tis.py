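"""Total Improvement Score: core-set improvements, points and categories.

TIS converts the absolute percent improvement of six core-set measures
(physician and patient global activity, MMT-8, HAQ, most abnormal muscle
enzyme, extramuscular global activity) into points via a threshold table and
sums them to a 0-100 composite.  Response categories (minimal/moderate/major)
are nested: every major responder is also a moderate and a minimal responder.

The threshold table and category cutoffs are supplied as configuration; the
shipped default transcribes the 2016 ACR/EULAR adult myositis response
criteria.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
import yaml

CORE_SET = ["phga", "ptga", "mmt8", "haq", "enzyme", "exga"]

__all__ = ["CoreSetPanel", "TISConversionTable", "TISResult",
           "absolute_percent_improvement", "tis_total", "CORE_SET",
           "default_tis_table"]


def absolute_percent_improvement(value, baseline, range_lo, range_hi,
                                 direction):
    """Change from baseline relative to the measure's total range, in percent.

    Positive values are improvement irrespective of the measure's direction
    convention; worsening yields negative values (floored at zero only when
    assigning points).
    """
    span = range_hi - range_lo
    if not span > 0:
        raise ValueError("degenerate measure range")
    change = np.asarray(value, dtype=float) - np.asarray(baseline, dtype=float)
    if direction == "lower":
        change = -change
    elif direction != "higher":
        raise ValueError(f"unknown improvement direction: {direction!r}")
    out = 100.0 * change / span
    return out if out.ndim else float(out)


@dataclass
class TISConversionTable:
    """Improvement thresholds -> points per core-set measure, plus cutoffs."""

    thresholds: dict           # measure -> increasing thresholds (percent)
    points: dict               # measure -> non-decreasing points per bin
    category_cutoffs: dict     # {"minimal": c1, "moderate": c2, "major": c3}
    enzyme_range_span: float = 10.0
    ranges: dict = field(default_factory=lambda: {
        "phga": (0.0, 10.0), "ptga": (0.0, 100.0), "mmt8": (0.0, 150.0),
        "haq": (0.0, 100.0), "exga": (0.0, 10.0)})
    directions: dict = field(default_factory=lambda: {
        "phga": "lower", "ptga": "lower", "mmt8": "higher",
        "haq": "lower", "enzyme": "lower", "exga": "lower"})
    checksum: str = ""

    def __post_init__(self):
        for m in CORE_SET:
            if m not in self.thresholds or m not in self.points:
                raise ValueError(f"conversion table missing measure '{m}'")
            th = np.asarray(self.thresholds[m], dtype=float)
            pt = np.asarray(self.points[m], dtype=float)
            if th.shape != pt.shape or np.any(np.diff(th) <= 0):
                raise ValueError(f"{m}: thresholds must be strictly increasing")
            if np.any(np.diff(pt) < 0) or np.any(pt < 0):
                raise ValueError(f"{m}: points must be non-decreasing, >= 0")
        cuts = [self.category_cutoffs[k]
                for k in ("minimal", "moderate", "major")]
        if not (0 < cuts[0] <= cuts[1] <= cuts[2]):
            raise ValueError("category cutoffs must be increasing")

    @property
    def max_total(self) -> float:
        return float(sum(np.max(self.points[m]) for m in CORE_SET))

    def measure_points(self, measure: str, improvement):
        """Points awarded for an absolute percent improvement (vectorized)."""
        th = np.asarray(self.thresholds[measure], dtype=float)
        pt = np.concatenate([[0.0], np.asarray(self.points[measure],
                                               dtype=float)])
        idx = np.searchsorted(th, np.asarray(improvement, dtype=float),
                              side="right")
        out = pt[idx]
        return out if out.ndim else float(out)

    def measure_range(self, measure: str):
        if measure == "enzyme":
            return 0.0, self.enzyme_range_span
        return self.ranges[measure]

    @classmethod
    def from_dict(cls, doc: dict, checksum: str = "") -> "TISConversionTable":
        meas = doc["measures"]
        return cls(
            thresholds={m: meas[m]["thresholds"] for m in meas},
            points={m: meas[m]["points"] for m in meas},
            category_cutoffs=dict(doc["categories"]),
            enzyme_range_span=float(doc.get("enzyme_range_span", 10.0)),
            checksum=checksum,
        )

    @classmethod
    def from_yaml(cls, path) -> "TISConversionTable":
        with open(path) as fh:
            text = fh.read()
        return cls.from_dict(yaml.safe_load(text),
                             hashlib.sha256(text.encode()).hexdigest()[:12])


def default_tis_table() -> TISConversionTable:
    """The shipped conversion table (2016 adult response criteria)."""
    text = resources.files("dmer.data").joinpath("tis_table.yaml").read_text()
    return TISConversionTable.from_dict(
        yaml.safe_load(text), hashlib.sha256(text.encode()).hexdigest()[:12])


@dataclass
class CoreSetPanel:
    """Per-visit values and baselines for the six core-set measures."""

    values: dict
    baselines: dict

    def __post_init__(self):
        missing = [m for m in CORE_SET
                   if m not in self.values or m not in self.baselines]
        if missing:
            raise ValueError(f"incomplete core-set panel, missing: {missing}")


@dataclass
class TISResult:
    improvements: dict
    points: dict
    total: float
    minimal: bool
    moderate: bool
    major: bool
    table_checksum: str = ""

    def __post_init__(self):
        if self.major and not self.moderate:
            raise ValueError("category nesting violated (major w/o moderate)")
        if self.moderate and not self.minimal:
            raise ValueError("category nesting violated (moderate w/o minimal)")


def tis_total(panel: CoreSetPanel, table: TISConversionTable) -> TISResult:
    """Score one visit: improvements -> points -> total -> nested categories."""
    improvements, points = {}, {}
    for m in CORE_SET:
        lo, hi = table.measure_range(m)
        imp = absolute_percent_improvement(
            panel.values[m], panel.baselines[m], lo, hi, table.directions[m])
        improvements[m] = imp
        points[m] = table.measure_points(m, max(imp, 0.0))
    total = float(sum(points.values()))
    cuts = table.category_cutoffs
    return TISResult(
        improvements=improvements, points=points, total=total,
        minimal=total >= cuts["minimal"], moderate=total >= cuts["moderate"],
        major=total >= cuts["major"], table_checksum=table.checksum)


def score_panel_frame(values: pd.DataFrame, baselines: pd.DataFrame,
                      table: TISConversionTable) -> pd.DataFrame:
    """Vectorized TIS over aligned frames with one column per core measure.

    Rows are scoring units (subject-visits); returns improvements, points,
    total and category flags as a tidy frame.
    """
    out = {}
    total = np.zeros(len(values))
    for m in CORE_SET:
        lo, hi = table.measure_range(m)
        imp = absolute_percent_improvement(
            values[m].to_numpy(), baselines[m].to_numpy(), lo, hi,
            table.directions[m])
        pts = table.measure_points(m, np.maximum(imp, 0.0))
        out[f"imp_{m}"] = imp
        out[f"pts_{m}"] = pts
        total = total + pts
    cuts = table.category_cutoffs
    out["tis"] = total
    out["minimal"] = total >= cuts["minimal"]
    out["moderate"] = total >= cuts["moderate"]
    out["major"] = total >= cuts["major"]
    return pd.DataFrame(out, index=values.index)
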