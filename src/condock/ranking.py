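"""Borda-count aggregation of heterogeneous docking scores.

Each matched pair carries three scores of incompatible scale and direction —
an empirical free-energy estimate (lower better) and two engine fitness
functions (higher better). Every metric ranks the pairs independently
(fractional ranks for ties) and each pair earns n − rank points per metric;
the points sum is the Borda score, and pairs are ordered by it descending.
Only the relative order matters downstream.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import rankdata

logger = logging.getLogger("condock")


class RankingError(ValueError):
    pass


@dataclass(frozen=True)
class MetricSpec:
    name: str
    orientation: str = "higher_better"  # or "lower_better"

    def __post_init__(self) -> None:
        if self.orientation not in {"higher_better", "lower_better"}:
            raise RankingError(f"bad orientation: {self.orientation}")


# Engine-documented conventions; override via config if an engine is rescored.
DEFAULT_METRICS = (
    MetricSpec("vina", "lower_better"),
    MetricSpec("goldscore", "higher_better"),
    MetricSpec("chemplp", "higher_better"),
)


@dataclass
class BordaResult:
    items: list                       # the ranked objects, input order
    ranks: dict[str, np.ndarray]      # metric name -> rank per item (1 = best)
    points: np.ndarray                # Borda points per item
    final_order: list[int]            # item indices, best first
    n_items: int = 0
    excluded: list[int] = field(default_factory=list)

    def final_rank(self, i: int) -> int:
        return self.final_order.index(i) + 1


def _scores_of(item, metric: str):
    """Pull a metric from an item: MatchedPair (native-engine pose), Pose, or dict."""
    if hasattr(item, "pose_a"):  # MatchedPair: vina from engine B, rest engine A
        source = item.pose_b if metric == "vina" else item.pose_a
        return source.scores.get(metric)
    if hasattr(item, "scores"):
        return item.scores.get(metric)
    return item.get(metric)


def rank_by_metric(items: list, metric: MetricSpec) -> np.ndarray:
    """Per-metric ranks, 1 = best, ties share the mean occupied rank."""
    vals = []
    for it in items:
        v = _scores_of(it, metric.name)
        if v is None:
            raise RankingError(f"item missing metric {metric.name}")
        vals.append(float(v))
    if not vals:
        raise RankingError("zero rankable items")
    arr = np.asarray(vals)
    if metric.orientation == "higher_better":
        arr = -arr
    return rankdata(arr, method="average")


def borda_rank(items: list, metrics=DEFAULT_METRICS,
               tiebreak_metric: MetricSpec | None = None) -> BordaResult:
    """Aggregate metrics into Borda points = Σ_m (n − rank_m), order descending.

    Items missing any metric are excluded from the run with a warning (so n
    is a single number for every metric). Ties in points break by the
    tie-break metric's value (default: the first lower-better metric), then
    input order.
    """
    if not metrics:
        raise RankingError("need at least one metric")
    if not items:
        raise RankingError("need at least one item")
    names = [m.name for m in metrics]
    if len(set(names)) != len(names):
        raise RankingError("metric names must be unique")

    usable, excluded = [], []
    for i, it in enumerate(items):
        if all(_scores_of(it, m.name) is not None for m in metrics):
            usable.append(i)
        else:
            excluded.append(i)
    if excluded:
        warnings.warn(f"{len(excluded)} item(s) metric-incomplete, excluded "
                      f"from ranking", stacklevel=2)
    if not usable:
        raise RankingError("zero rankable items after exclusions")
    sub = [items[i] for i in usable]
    n = len(sub)
    ranks = {m.name: rank_by_metric(sub, m) for m in metrics}
    points = np.sum([n - ranks[m.name] for m in metrics], axis=0)

    if tiebreak_metric is None:
        lowers = [m for m in metrics if m.orientation == "lower_better"]
        tiebreak_metric = lowers[0] if lowers else metrics[0]
    tb_vals = np.array([float(_scores_of(it, tiebreak_metric.name)) for it in sub])
    if tiebreak_metric.orientation == "higher_better":
        tb_vals = -tb_vals
    order_local = sorted(range(n), key=lambda k: (-points[k], tb_vals[k], k))
    final_order = [usable[k] for k in order_local]
    full_ranks = {m: _expand(ranks[m], usable, len(items)) for m in ranks}
    full_points = _expand(points, usable, len(items))
    return BordaResult(items=list(items), ranks=full_ranks, points=full_points,
                       final_order=final_order, n_items=n, excluded=excluded)


def _expand(values: np.ndarray, idx: list[int], total: int) -> np.ndarray:
    out = np.full(total, np.nan)
    out[idx] = values
    return out


def top_k(result: BordaResult, k: int = 5) -> list:
    """First ``k`` items of the final Borda order (all if fewer, warned)."""
    if k < 1:
        raise RankingError("k must be >= 1")
    if k > len(result.final_order):
        warnings.warn(f"requested top {k} of {len(result.final_order)} ranked "
                      f"items; returning all", stacklevel=2)
    return [result.items[i] for i in result.final_order[:k]]
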