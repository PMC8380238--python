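"""The eight-region score-plane partition and the final decision rule.

The four thresholds split the (allosteric, orthosteric) score plane into
2 × 4 = 8 regions: the allosteric axis into strong vs weak allosteric
binders (at T_sab), the orthosteric axis into strong / moderate / weak
orthosteric binders and non-binders (at T_sob, T_wob, T_ob). The final
screening rule calls a compound an inhibitor when it is

* a strong allosteric binder — unless it is also a moderate orthosteric
  binder (scores in the low-density gap are dominated by non-inhibitors), or
* a strong orthosteric binder, regardless of its allosteric score.

Everything else is predicted non-inhibitor.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .score_data import CompoundRecord, Label, PotencyBand
from .thresholds import ClassMetrics, ThresholdSet, class_metrics


class AlloBand(str, Enum):
    STRONG_ALLOSTERIC = "strong_allosteric"
    WEAK_ALLOSTERIC = "weak_allosteric"


class OrthoBand(str, Enum):
    STRONG_ORTHO = "strong_ortho"
    MODERATE_ORTHO = "moderate_ortho"
    WEAK_ORTHO = "weak_ortho"
    NON_BINDER = "non_binder"


@dataclass(frozen=True)
class Region:
    allo_band: AlloBand
    ortho_band: OrthoBand

    @property
    def name(self) -> str:
        return f"{self.allo_band.value}/{self.ortho_band.value}"


ALL_REGIONS: tuple[Region, ...] = tuple(
    Region(a, o) for a in AlloBand for o in OrthoBand
)


def assign_region(allo_score: float, ortho_score: float, thresholds: ThresholdSet) -> Region:
    """Map one (capped) score pair to its region.

    Strict ``<`` convention: a score exactly at a threshold falls in the
    weaker band.
    """
    allo = AlloBand.STRONG_ALLOSTERIC if allo_score < thresholds.t_sab else AlloBand.WEAK_ALLOSTERIC
    if ortho_score < thresholds.t_sob:
        ortho = OrthoBand.STRONG_ORTHO
    elif ortho_score < thresholds.t_wob:
        ortho = OrthoBand.MODERATE_ORTHO
    elif ortho_score < thresholds.t_ob:
        ortho = OrthoBand.WEAK_ORTHO
    else:
        ortho = OrthoBand.NON_BINDER
    return Region(allo, ortho)


def predict(allo_score: float, ortho_score: float, thresholds: ThresholdSet) -> Label:
    """Final rule: inhibitor iff (strong allosteric and not moderate ortho)
    or (weak allosteric and strong ortho)."""
    return Label(predict_region(assign_region(allo_score, ortho_score, thresholds)))


def predict_orthosteric_only(ortho_score: float, thresholds: ThresholdSet) -> Label:
    """Orthosteric-scores-only rule: inhibitor iff the compound is an
    orthosteric binder outside the moderate gap."""
    inhibitor = ortho_score < thresholds.t_ob and (
        ortho_score < thresholds.t_sob or ortho_score >= thresholds.t_wob
    )
    return Label.INHIBITOR if inhibitor else Label.NON_INHIBITOR


def _require_labeled(records: Sequence[CompoundRecord]) -> np.ndarray:
    labels = []
    for r in records:
        if r.label is Label.UNLABELED:
            raise ValueError(f"{r.compound_id}: unlabeled record in evaluation set")
        labels.append(r.label is Label.INHIBITOR)
    return np.asarray(labels, dtype=bool)


def evaluate(records: Sequence[CompoundRecord], thresholds: ThresholdSet) -> ClassMetrics:
    """Apply the final rule to every labeled record; confusion + metrics."""
    actual = _require_labeled(records)
    pred = np.asarray(
        [predict(r.allo_score, r.ortho_score, thresholds) is Label.INHIBITOR for r in records],
        dtype=bool,
    )
    return class_metrics(pred, actual)


def evaluate_orthosteric_only(
    records: Sequence[CompoundRecord], thresholds: ThresholdSet
) -> ClassMetrics:
    """Metrics of the orthosteric-only rule over all labeled records."""
    actual = _require_labeled(records)
    pred = np.asarray(
        [predict_orthosteric_only(r.ortho_score, thresholds) is Label.INHIBITOR for r in records],
        dtype=bool,
    )
    return class_metrics(pred, actual)


def region_composition(
    records: Sequence[CompoundRecord], thresholds: ThresholdSet
) -> pd.DataFrame:
    """Per-region counts and percentages of each compound category.

    Categories: non-inhibitors, all inhibitors, strong inhibitors, weak
    inhibitors. Percentages are per category (denominator = category
    total), so each percentage column sums to 100 across regions; the
    all-inhibitor percentage of a region is generally not the sum of the
    strong and weak ones because the denominators differ.
    """
    actual = _require_labeled(records)
    regions = [assign_region(r.allo_score, r.ortho_score, thresholds) for r in records]
    cats = {
        "non_inhibitors": np.array([r.label is Label.NON_INHIBITOR for r in records]),
        "all_inhibitors": actual,
        "strong_inhibitors": np.array(
            [r.potency_band is PotencyBand.STRONG for r in records]
        ),
        "weak_inhibitors": np.array([r.potency_band is PotencyBand.WEAK for r in records]),
    }
    rows = []
    for region in ALL_REGIONS:
        mask = np.array([rg == region for rg in regions])
        row: dict = {
            "region": region.name,
            "allo_band": region.allo_band.value,
            "ortho_band": region.ortho_band.value,
            "prediction": predict_region(region),
        }
        for cat, cmask in cats.items():
            total = int(cmask.sum())
            count = int((mask & cmask).sum())
            row[f"n_{cat}"] = count
            row[f"pct_{cat}"] = _round_half_away(100.0 * count / total, 1) if total else float("nan")
        rows.append(row)
    return pd.DataFrame(rows)


def predict_region(region: Region) -> str:
    """The shared prediction of every compound in a region."""
    inhibitor = (
        region.allo_band is AlloBand.STRONG_ALLOSTERIC
        and region.ortho_band is not OrthoBand.MODERATE_ORTHO
    ) or (
        region.allo_band is AlloBand.WEAK_ALLOSTERIC
        and region.ortho_band is OrthoBand.STRONG_ORTHO
    )
    return Label.INHIBITOR.value if inhibitor else Label.NON_INHIBITOR.value


def _round_half_away(x: float, ndigits: int) -> float:
    """Round half away from zero (presentation rounding for percentages)."""
    factor = 10.0**ndigits
    return np.sign(x) * np.floor(abs(x) * factor + 0.5) / factor


def classify_records(
    records: Iterable[CompoundRecord], thresholds: ThresholdSet
) -> pd.DataFrame:
    """Predictions table: one row per compound with region and call."""
    rows = []
    for r in records:
        region = assign_region(r.allo_score, r.ortho_score, thresholds)
        rows.append(
            {
                "compound_id": r.compound_id,
                "allo_score": r.allo_score,
                "ortho_score": r.ortho_score,
                "region": region.name,
                "prediction": predict(r.allo_score, r.ortho_score, thresholds).value,
            }
        )
    return pd.DataFrame(rows)
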