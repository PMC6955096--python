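"""Power-law time-dependent-rate (TDRP) dating.

The TDRP model relates an apparent amount of molecular change s (average
node-to-tip distance, substitutions per site) to its timescale t (myr) by

    t = alpha * s ** beta,       alpha, beta > 0

fitted as ordinary least squares on (log s, log t): the slope is beta and
the intercept is log alpha.  Fitting is repeated over every tree in a
posterior ensemble and the per-sample parameters, s estimates and predicted
dates are summarised as medians with 95% highest-posterior-density (HPD)
intervals.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

import dendropy

from .cospeciation import CospeciationEvent
from .trees import Phylogeny, PosteriorEnsemble, TipAssociation

__all__ = [
    "CalibrationPoint",
    "TDRPModel",
    "QueryDef",
    "DateEstimate",
    "ParamSummary",
    "PosteriorDatingResult",
    "ExtrapolationWarning",
    "average_node_to_tip_distance",
    "node_to_tip_distances",
    "fit_tdrp",
    "predict_time",
    "hpd_interval",
    "date_nodes_posterior",
]

logger = logging.getLogger(__name__)


class ExtrapolationWarning(UserWarning):
    """Prediction requested outside the calibration s-range."""


@dataclass(frozen=True)
class CalibrationPoint:
    """One (s, t) pair: molecular change below a calibrated node and its age."""

    event_id: str
    s: float
    t: float

    def __post_init__(self):
        if self.s <= 0:
            raise ValueError(f"point {self.event_id}: s must be > 0 (log-transform)")
        if self.t <= 0:
            raise ValueError(f"point {self.event_id}: t must be > 0")


@dataclass(frozen=True)
class TDRPModel:
    """A fitted power law t = alpha * s**beta with its log-log goodness of fit."""

    alpha: float
    beta: float
    adj_r2: float
    n_points: int

    def predict(self, s: float) -> float:
        return predict_time(self, s)


@dataclass(frozen=True)
class QueryDef:
    """An undated virus divergence to extrapolate, defined by its tip set."""

    query_id: str
    virus_tips: frozenset[str]


@dataclass(frozen=True)
class ParamSummary:
    median: float
    hpd_low: float
    hpd_high: float
    n: int


@dataclass(frozen=True)
class DateEstimate:
    """Posterior summary of an extrapolated divergence date."""

    query_id: str
    median_t: float
    hpd_low: float
    hpd_high: float
    n_samples: int
    fraction_monophyletic: float
    median_s: float
    s_hpd_low: float
    s_hpd_high: float


@dataclass
class PosteriorDatingResult:
    dates: list[DateEstimate]
    model: dict[str, ParamSummary]  # alpha, beta, adj_r2
    event_s: dict[str, ParamSummary]
    event_monophyletic: dict[str, float]
    per_sample: list[dict]  # alpha/beta/adj_r2 per retained sample
    n_samples: int
    n_skipped: int
    warnings: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# Distances
# ---------------------------------------------------------------------------


def node_to_tip_distances(node: dendropy.Node) -> dict[str, float]:
    """Path length (sum of branch lengths) from ``node`` to each descendant tip."""
    out: dict[str, float] = {}

    def walk(n: dendropy.Node, acc: float) -> None:
        if n.is_leaf():
            out[n.taxon.label] = acc
            return
        for child in n.child_nodes():
            walk(child, acc + child.edge.length)

    walk(node, 0.0)
    return out


def average_node_to_tip_distance(
    tree: Phylogeny,
    node: dendropy.Node,
    excluded_tips: Iterable[str] = (),
) -> float:
    """Mean root-to-tip path length below ``node``, skipping excluded tips.

    Excluded tips (endogenous copies evolving at host rates) contribute to
    neither numerator nor denominator.  Raises if every descendant tip is
    excluded — the node cannot be calibrated.
    """
    if node.is_leaf():
        raise ValueError("average node-to-tip distance requires an internal node")
    excluded = set(excluded_tips)
    dists = [d for tip, d in node_to_tip_distances(node).items() if tip not in excluded]
    if not dists:
        raise ValueError(
            "all descendant tips are excluded; node cannot be calibrated"
        )
    return float(np.mean(dists))


# ---------------------------------------------------------------------------
# Model fit / prediction
# ---------------------------------------------------------------------------


def fit_tdrp(points: Sequence[CalibrationPoint]) -> TDRPModel:
    """Fit t = alpha * s**beta by OLS on natural-log-transformed (s, t).

    adj R^2 is computed on the log-log scale as 1 - (1 - R^2)(n-1)/(n-2);
    it is NaN for n = 2 (a perfect two-point line carries no fit information).
    """
    if len(points) < 2:
        raise ValueError("fit_tdrp needs at least 2 calibration points")
    s = np.array([p.s for p in points], dtype=float)
    t = np.array([p.t for p in points], dtype=float)
    if np.any(s <= 0) or np.any(t <= 0):
        raise ValueError("all calibration points must have s > 0 and t > 0")
    log_s, log_t = np.log(s), np.log(t)
    if np.ptp(log_s) == 0:
        raise ValueError("singular fit: all s values identical")
    n = len(points)
    with warnings.catch_warnings():
        # two-point fits trip scipy's internal sqrt of a zero residual
        warnings.simplefilter("ignore")
        res = stats.linregress(log_s, log_t)
    beta = float(res.slope)
    alpha = float(math.exp(res.intercept))
    r2 = float(res.rvalue) ** 2
    adj_r2 = 1.0 - (1.0 - r2) * (n - 1) / (n - 2) if n > 2 else float("nan")
    return TDRPModel(alpha=alpha, beta=beta, adj_r2=adj_r2, n_points=n)


def predict_time(model: TDRPModel, s: float) -> float:
    """t = alpha * s**beta (requires s > 0)."""
    if s <= 0:
        raise ValueError("predict_time requires s > 0")
    return model.alpha * s ** model.beta


# ---------------------------------------------------------------------------
# HPD
# ---------------------------------------------------------------------------


def hpd_interval(samples: Sequence[float], mass: float = 0.95) -> tuple[float, float]:
    """Shortest contiguous interval of sorted samples holding ceil(mass*n) values.

    Ties in width are broken toward the lower start index, so the interval is
    deterministic.  With mass = 1 this is simply (min, max).
    """
    x = np.sort(np.asarray(samples, dtype=float))
    n = x.size
    if n == 0:
        raise ValueError("hpd_interval requires a non-empty sample")
    if not 0.0 < mass <= 1.0:
        raise ValueError("mass must be in (0, 1]")
    k = math.ceil(mass * n)
    if k == n:
        return float(x[0]), float(x[-1])
    widths = x[k - 1 :] - x[: n - k + 1]
    i = int(np.argmin(widths))  # argmin returns the first minimum
    return float(x[i]), float(x[i + k - 1])


def _summary(values: Sequence[float], mass: float = 0.95) -> ParamSummary:
    lo, hi = hpd_interval(values, mass)
    return ParamSummary(
        median=float(np.median(values)), hpd_low=lo, hpd_high=hi, n=len(values)
    )


# ---------------------------------------------------------------------------
# Posterior propagation
# ---------------------------------------------------------------------------


def date_nodes_posterior(
    ensemble: PosteriorEnsemble,
    association: TipAssociation,
    events: Sequence[CospeciationEvent],
    queries: Sequence[QueryDef],
    *,
    hpd_mass: float = 0.95,
    min_points: int = 2,
) -> PosteriorDatingResult:
    """Fit a TDRP model per posterior sample and summarise dates across samples.

    Calibration times t come from the host chronogram (via the events) and
    are fixed across samples; only the s estimates vary.  In each sample the
    calibration and query nodes are located as the MRCA of their configured
    tip sets (well-defined even when non-monophyletic; the monophyly fraction
    is reported so users can filter).  Endogenous tips are excluded from
    every node-to-tip average.  Samples yielding fewer than ``min_points``
    usable calibration points are skipped and counted.
    """
    usable = [e for e in events if e.origin != "excluded"]
    if not usable:
        raise ValueError("no calibration events supplied")
    erv = association.erv_tips
    notes: list[str] = []
    dropped_events: dict[str, int] = {}
    dropped_queries: dict[str, int] = {}

    per_sample: list[dict] = []
    event_s: dict[str, list[float]] = {e.event_id: [] for e in usable}
    event_mono: dict[str, int] = {e.event_id: 0 for e in usable}
    query_t: dict[str, list[float]] = {q.query_id: [] for q in queries}
    query_s: dict[str, list[float]] = {q.query_id: [] for q in queries}
    query_mono: dict[str, int] = {q.query_id: 0 for q in queries}
    n_skipped = 0
    extrapolated = False

    for idx, sample in enumerate(ensemble):
        points: list[CalibrationPoint] = []
        sample_s: dict[str, float] = {}
        for event in usable:
            node = sample.mrca(event.virus_tips)
            if sample.leaf_labels_under(node) == event.virus_tips:
                event_mono[event.event_id] += 1
            try:
                s = average_node_to_tip_distance(sample, node, erv)
            except ValueError:
                dropped_events[event.event_id] = dropped_events.get(event.event_id, 0) + 1
                continue
            if s <= 0:
                dropped_events[event.event_id] = dropped_events.get(event.event_id, 0) + 1
                continue
            points.append(CalibrationPoint(event.event_id, s, event.t))
            sample_s[event.event_id] = s
        distinct = len({p.s for p in points})
        if len(points) < max(min_points, 2) or distinct < 2:
            n_skipped += 1
            continue
        model = fit_tdrp(points)
        per_sample.append(
            {
                "sample": idx + 1,
                "alpha": model.alpha,
                "beta": model.beta,
                "adj_r2": model.adj_r2,
                "n_points": model.n_points,
            }
        )
        for event_id, s in sample_s.items():
            event_s[event_id].append(s)
        s_lo = min(p.s for p in points)
        s_hi = max(p.s for p in points)
        for query in queries:
            node = sample.mrca(query.virus_tips)
            if sample.leaf_labels_under(node) == query.virus_tips:
                query_mono[query.query_id] += 1
            try:
                s = average_node_to_tip_distance(sample, node, erv)
            except ValueError:
                dropped_queries[query.query_id] = dropped_queries.get(query.query_id, 0) + 1
                continue
            if s <= 0:
                continue
            if not s_lo <= s <= s_hi:
                extrapolated = True
            query_s[query.query_id].append(s)
            query_t[query.query_id].append(predict_time(model, s))

    n_total = len(ensemble)
    for event_id, count in dropped_events.items():
        notes.append(
            f"event {event_id}: only endogenous descendants (or zero distance) in "
            f"{count}/{n_total} sample(s); point dropped there"
        )
    for query_id, count in dropped_queries.items():
        notes.append(
            f"query {query_id}: only endogenous descendants in "
            f"{count}/{n_total} sample(s); no date there"
        )
    if n_skipped:
        notes.append(
            f"{n_skipped}/{n_total} sample(s) skipped: fewer than "
            f"{max(min_points, 2)} usable calibration points"
        )
    if not per_sample:
        raise ValueError("no posterior sample yielded a usable TDRP fit")
    if extrapolated:
        msg = "one or more query s estimates lie outside the calibration range"
        notes.append(msg)
        warnings.warn(msg, ExtrapolationWarning, stacklevel=2)

    model_summary = {
        name: _summary([row[name] for row in per_sample], hpd_mass)
        for name in ("alpha", "beta", "adj_r2")
        if not any(math.isnan(row[name]) for row in per_sample)
    }
    dates = []
    for query in queries:
        ts = query_t[query.query_id]
        if not ts:
            notes.append(f"query {query.query_id}: no sample yielded a date")
            continue
        t_sum = _summary(ts, hpd_mass)
        s_sum = _summary(query_s[query.query_id], hpd_mass)
        dates.append(
            DateEstimate(
                query_id=query.query_id,
                median_t=t_sum.median,
                hpd_low=t_sum.hpd_low,
                hpd_high=t_sum.hpd_high,
                n_samples=len(ts),
                fraction_monophyletic=query_mono[query.query_id] / n_total,
                median_s=s_sum.median,
                s_hpd_low=s_sum.hpd_low,
                s_hpd_high=s_sum.hpd_high,
            )
        )
    for note in notes:
        logger.warning(note)
    return PosteriorDatingResult(
        dates=dates,
        model=model_summary,
        event_s={eid: _summary(v, hpd_mass) for eid, v in event_s.items() if v},
        event_monophyletic={eid: c / n_total for eid, c in event_mono.items()},
        per_sample=per_sample,
        n_samples=n_total,
        n_skipped=n_skipped,
        warnings=notes,
    )
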