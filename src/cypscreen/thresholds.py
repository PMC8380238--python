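"""Learning the four docking-score decision thresholds.

Three procedures, all operating on a labeled, capped reference set:

* ``find_allosteric_threshold`` — 1-D grid search for the strong allosteric
  binder threshold T_sab, maximizing sensitivity subject to balanced
  accuracy ≥ the 95th percentile of all achievable balanced accuracies;
* ``orthosteric_binder_threshold`` — kernel-density inflection analysis of
  the orthosteric score distribution; T_ob is the first local minimum after
  the first local maximum (the valley after the leading mode);
* ``find_orthosteric_pair`` — constrained 2-D grid search over predicted
  orthosteric binders for (T_sob, T_wob): scores below T_sob or at/above
  T_wob predict inhibitor, the gap between them predicts non-inhibitor.

Prediction convention throughout: strict ``<`` against a threshold puts a
compound on the binder/inhibitor side; a score exactly equal to a threshold
falls on the non-binder side.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Sequence

import numpy as np
import pandas as pd


class UndefinedMetricError(ValueError):
    """Balanced accuracy needs both classes present in the truth vector."""


class DensityAnalysisError(RuntimeError):
    """The smoothed density has no usable minimum-after-maximum structure."""


@dataclass(frozen=True)
class ClassMetrics:
    """Confusion counts and the derived screening metrics."""

    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def sensitivity(self) -> float:
        return self.tp / (self.tp + self.fn)

    @property
    def specificity(self) -> float:
        return self.tn / (self.tn + self.fp)

    @property
    def balanced_accuracy(self) -> float:
        return 0.5 * (self.sensitivity + self.specificity)

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass(frozen=True)
class ThresholdSet:
    """The four learned decision thresholds, kcal/mol.

    ``t_sab``: strong allosteric binder; ``t_ob``: orthosteric binder;
    ``t_sob``/``t_wob``: strong/weak orthosteric binder. Must satisfy
    t_sob < t_wob < t_ob.
    """

    t_sab: float
    t_ob: float
    t_sob: float
    t_wob: float

    def __post_init__(self) -> None:
        if not (self.t_sob < self.t_wob < self.t_ob):
            raise ValueError(
                f"thresholds must satisfy t_sob < t_wob < t_ob, got "
                f"({self.t_sob}, {self.t_wob}, {self.t_ob})"
            )

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ThresholdSet":
        return cls(t_sab=d["t_sab"], t_ob=d["t_ob"], t_sob=d["t_sob"], t_wob=d["t_wob"])


@dataclass
class GridSearchResult:
    """Chosen threshold(s) with metrics and the full candidate table."""

    chosen: float | tuple[float, float]
    metrics: ClassMetrics
    percentile95: float
    candidates: pd.DataFrame  # threshold col(s) + sensitivity/specificity/balanced_accuracy

    @property
    def sensitivity(self) -> float:
        return self.metrics.sensitivity

    @property
    def specificity(self) -> float:
        return self.metrics.specificity

    @property
    def balanced_accuracy(self) -> float:
        return self.metrics.balanced_accuracy


@dataclass
class DensityProfile:
    """A smoothed score density with its located extrema."""

    grid: np.ndarray
    density: np.ndarray
    bandwidth: float
    extrema: list[tuple[float, str]]  # (position, "max"|"min"), grid order


def class_metrics(predicted: Sequence[bool], actual: Sequence[bool]) -> ClassMetrics:
    """Confusion counts of a binary prediction (True = inhibitor/positive)."""
    p = np.asarray(predicted, dtype=bool)
    a = np.asarray(actual, dtype=bool)
    if p.shape != a.shape:
        raise ValueError("predicted and actual must have equal length")
    if a.all() or not a.any():
        raise UndefinedMetricError("both classes must be present in `actual`")
    return ClassMetrics(
        tp=int((p & a).sum()),
        fp=int((p & ~a).sum()),
        tn=int((~p & ~a).sum()),
        fn=int((~p & a).sum()),
    )


def _grid_metrics(pred_matrix: np.ndarray, actual: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Sensitivity and specificity for each row of a candidate×n prediction matrix."""
    pos = actual
    neg = ~actual
    sens = (pred_matrix & pos).sum(axis=1) / pos.sum()
    spec = (~pred_matrix & neg).sum(axis=1) / neg.sum()
    return sens, spec


def _select(
    cand: pd.DataFrame, order_cols: list[str]
) -> tuple[int, float]:
    """Index of the winning candidate and the 95th-percentile balanced accuracy.

    Winner = maximum sensitivity among candidates with balanced accuracy ≥
    the 95th percentile (linear-interpolation sample quantile over all
    candidates); ties broken by higher balanced accuracy, then by the
    most-negative threshold(s) (``order_cols`` ascending).
    """
    p95 = float(np.percentile(cand["balanced_accuracy"].to_numpy(), 95))
    ok = cand[cand["balanced_accuracy"] >= p95]
    ok = ok.sort_values(
        ["sensitivity", "balanced_accuracy"] + order_cols,
        ascending=[False, False] + [True] * len(order_cols),
        kind="mergesort",
    )
    return int(ok.index[0]), p95


def find_allosteric_threshold(
    allo_scores: Sequence[float],
    labels: Sequence[bool],
    grid: Sequence[float] | None = None,
) -> GridSearchResult:
    """Grid search for T_sab over allosteric scores capped at 0.

    For each candidate T the rule "inhibitor iff score < T" is evaluated;
    the returned threshold maximizes sensitivity among candidates whose
    balanced accuracy reaches the 95th percentile of all candidates'.
    """
    scores = np.asarray(allo_scores, dtype=float)
    y = np.asarray(labels, dtype=bool)
    if grid is None:
        grid = np.arange(-60.0, 1.0)  # {-60, ..., 0}
    grid = np.asarray(list(grid), dtype=float)
    if grid.size == 0:
        raise ValueError("grid must be nonempty")
    if y.all() or not y.any():
        raise UndefinedMetricError("both classes must be present")

    pred = scores[None, :] < grid[:, None]
    sens, spec = _grid_metrics(pred, y)
    cand = pd.DataFrame(
        {
            "threshold": grid,
            "sensitivity": sens,
            "specificity": spec,
            "balanced_accuracy": 0.5 * (sens + spec),
        }
    )
    i, p95 = _select(cand, ["threshold"])
    t = float(cand.loc[i, "threshold"])
    return GridSearchResult(
        chosen=t,
        metrics=class_metrics(scores < t, y),
        percentile95=p95,
        candidates=cand,
    )


def density_profile(
    scores: Sequence[float],
    bandwidth: float = 3.0,
    n_grid: int = 512,
    cut: float = 3.0,
    min_rel_height: float = 0.01,
) -> DensityProfile:
    """Gaussian kernel density estimate on an even grid.

    The grid spans [min − cut·bw, max + cut·bw] with ``n_grid`` points; the
    kernel standard deviation equals ``bandwidth`` (kcal/mol). Capped scores
    participate as point mass at the cap. Modes (local maxima) below
    ``min_rel_height`` × the global peak density are ignored — a single
    stray score would otherwise register as its own mode — and one local
    minimum (the deepest valley) is kept between consecutive accepted
    modes, so the extrema list alternates max/min.
    """
    x = np.asarray(scores, dtype=float)
    if np.unique(x).size < 2:
        raise ValueError("need at least 2 distinct scores")
    lo = x.min() - cut * bandwidth
    hi = x.max() + cut * bandwidth
    grid = np.linspace(lo, hi, n_grid)

    dens = np.zeros(n_grid)
    norm = 1.0 / (bandwidth * np.sqrt(2.0 * np.pi))
    for chunk in np.array_split(x, max(1, x.size // 4096)):
        z = (grid[:, None] - chunk[None, :]) / bandwidth
        dens += norm * np.exp(-0.5 * z * z).sum(axis=1)
    dens /= x.size

    from scipy.signal import find_peaks

    peaks, _ = find_peaks(dens, height=min_rel_height * dens.max())
    extrema: list[tuple[float, str]] = []
    for j, p in enumerate(peaks):
        extrema.append((float(grid[p]), "max"))
        if j + 1 < len(peaks):
            q = peaks[j + 1]
            valley = p + int(np.argmin(dens[p : q + 1]))
            extrema.append((float(grid[valley]), "min"))
    return DensityProfile(grid=grid, density=dens, bandwidth=bandwidth, extrema=extrema)


def orthosteric_binder_threshold(
    ortho_scores: Sequence[float],
    bandwidth: float = 3.0,
    n_grid: int = 512,
) -> tuple[float, DensityProfile]:
    """T_ob: the first density minimum after the first maximum.

    Scanning the smoothed orthosteric score density from the most negative
    score upward, the first local maximum is the mode of favorable binders
    and the following local minimum — the valley separating binders from
    the bulk — is returned as the orthosteric binder threshold.
    """
    prof = density_profile(ortho_scores, bandwidth=bandwidth, n_grid=n_grid)
    seen_max = False
    for pos, kind in prof.extrema:
        if kind == "max":
            seen_max = True
        elif seen_max and kind == "min":
            return pos, prof
    raise DensityAnalysisError(
        "no local minimum after the first local maximum; try a different bandwidth"
    )


def find_orthosteric_pair(
    ortho_scores: Sequence[float],
    labels: Sequence[bool],
    grid: Sequence[float] | None = None,
) -> GridSearchResult:
    """2-D grid search for (T_sob, T_wob) over orthosteric binders only.

    Rule per pair: inhibitor iff score < T_sob or score ≥ T_wob — the gap
    [T_sob, T_wob) predicts non-inhibitor. Only pairs with T_sob < T_wob are
    candidates; selection matches :func:`find_allosteric_threshold`, with
    lexicographic most-negative-first tie-breaking on (T_sob, T_wob).
    """
    scores = np.asarray(ortho_scores, dtype=float)
    y = np.asarray(labels, dtype=bool)
    if grid is None:
        grid = np.arange(-60.0, -3.0)  # {-60, ..., -4}
    grid = np.asarray(list(grid), dtype=float)
    if y.all() or not y.any():
        raise UndefinedMetricError("both classes must be present")

    lo_idx, hi_idx = np.triu_indices(grid.size, k=1)
    t_sob = grid[lo_idx]
    t_wob = grid[hi_idx]
    pred = (scores[None, :] < t_sob[:, None]) | (scores[None, :] >= t_wob[:, None])
    sens, spec = _grid_metrics(pred, y)
    cand = pd.DataFrame(
        {
            "t_sob": t_sob,
            "t_wob": t_wob,
            "sensitivity": sens,
            "specificity": spec,
            "balanced_accuracy": 0.5 * (sens + spec),
        }
    )
    i, p95 = _select(cand, ["t_sob", "t_wob"])
    pair = (float(cand.loc[i, "t_sob"]), float(cand.loc[i, "t_wob"]))
    return GridSearchResult(
        chosen=pair,
        metrics=class_metrics((scores < pair[0]) | (scores >= pair[1]), y),
        percentile95=p95,
        candidates=cand,
    )
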