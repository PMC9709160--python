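"""Composite physiological stress scoring (the D-score system).

Chronic HPA-axis activation in mice shrinks the thymus, enlarges the adrenal
glands and blunts body-weight gain, but individual responses are
heterogeneous: group labels alone ("control" vs "stress") misclassify a
substantial fraction of animals. The D-score system treats each physiological
marker as a binary classifier: a ROC curve is built per marker with the
stress group as the positive class, the Youden index J = TPR - FPR picks the
optimal cutoff, and each mouse scores one point per marker strictly beyond
its cutoff in the stress direction. The cumulative 0-3 score classifies a
mouse as stressed (D-score 2 or 3) or non-stressed (0 or 1).

The module exposes the individual operations (``roc_curve``,
``youden_cutoff``, ``assign_dscore``, ``classify_mouse``,
``cohort_retention``, ``marker_predictiveness``) and a model/results pair
(``DScoreModel`` / ``DScoreResults``) wrapping the whole cohort workflow.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "MarkerDirection",
    "PhysioRecord",
    "RocResult",
    "DScoreResult",
    "roc_curve",
    "youden_cutoff",
    "assign_dscore",
    "classify_mouse",
    "cohort_retention",
    "marker_predictiveness",
    "DScoreModel",
    "DScoreResults",
]

GROUPS = ("control", "stress")


@dataclass(frozen=True)
class MarkerDirection:
    """A scored marker and the direction chronic stress moves it.

    ``direction`` is ``"stress_higher"`` (stressed animals have larger
    values, e.g. adrenal weight) or ``"stress_lower"`` (body-weight gain,
    thymus weight).
    """

    name: str
    direction: str

    def __post_init__(self) -> None:
        if self.direction not in ("stress_higher", "stress_lower"):
            raise ValueError(
                f"direction must be 'stress_higher' or 'stress_lower', got {self.direction!r}"
            )

    def flipped(self) -> "MarkerDirection":
        other = "stress_lower" if self.direction == "stress_higher" else "stress_higher"
        return MarkerDirection(self.name, other)


@dataclass
class PhysioRecord:
    """One mouse's physiological markers plus its experimental group label."""

    mouse_id: str
    group: str
    bw_gain_g: float
    adrenal_norm: float
    thymus_norm: float
    cort: float | None = None

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValueError(f"group must be one of {GROUPS}, got {self.group!r}")
        if self.adrenal_norm is not None and np.isfinite(self.adrenal_norm) and self.adrenal_norm <= 0:
            raise ValueError("adrenal_norm must be > 0")
        if self.thymus_norm is not None and np.isfinite(self.thymus_norm) and self.thymus_norm <= 0:
            raise ValueError("thymus_norm must be > 0")

    def marker(self, name: str) -> float:
        try:
            value = getattr(self, name)
        except AttributeError:
            raise KeyError(f"unknown marker {name!r}") from None
        return value


@dataclass
class RocResult:
    """ROC sweep for one marker: thresholds, rates, AUC, Youden cutoff.

    Thresholds are ordered along the sweep so that FPR and TPR are
    non-decreasing, starting at (0, 0) and ending at (1, 1).
    """

    marker: str
    direction: str
    thresholds: np.ndarray
    tpr: np.ndarray
    fpr: np.ndarray
    auc: float
    youden_cutoff: float
    max_j: float

    @property
    def j(self) -> np.ndarray:
        return self.tpr - self.fpr


@dataclass
class DScoreResult:
    """Per-mouse scoring outcome: marker flags, D-score, classification."""

    mouse_id: str
    flags: dict[str, bool]
    dscore: int
    classification: str


def _candidate_thresholds(values: np.ndarray) -> np.ndarray:
    """Midpoints between consecutive distinct values plus sentinels outside the range."""
    distinct = np.unique(values)
    if distinct.size > 1:
        pad = 0.5 * np.min(np.diff(distinct))
    else:
        pad = max(1.0, abs(float(distinct[0])))
    mids = 0.5 * (distinct[:-1] + distinct[1:])
    return np.concatenate(([distinct[0] - pad], mids, [distinct[-1] + pad]))


def roc_curve(
    values: Sequence[float],
    labels: Sequence[str],
    direction: MarkerDirection,
) -> RocResult:
    """ROC sweep for one marker with the stress group as positive class.

    Candidate thresholds are the midpoints between consecutive distinct
    sorted values, plus one sentinel below the minimum and one above the
    maximum (guaranteeing the (0,0) and (1,1) endpoints). A mouse tests
    positive when its value is strictly beyond the threshold in the stress
    direction (``> t`` for stress-higher markers, ``< t`` for stress-lower).
    AUC is the trapezoid integral of TPR over FPR, which equals the
    tie-corrected Mann-Whitney rank statistic U/(n1*n2).
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    if values.shape != labels.shape:
        raise ValueError("values and labels must have the same length")
    if values.size == 0:
        raise ValueError("empty input")
    if not np.all(np.isfinite(values)):
        raise ValueError(f"marker {direction.name!r} contains missing/non-finite values")
    pos = labels == "stress"
    neg = labels == "control"
    if not np.all(pos | neg):
        bad = sorted(set(labels[~(pos | neg)]))
        raise ValueError(f"unknown group labels: {bad}")
    n_pos, n_neg = int(pos.sum()), int(neg.sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("need at least one mouse in each group")

    thresholds = _candidate_thresholds(values)
    # cumulative counts per distinct value avoid the O(n * thresholds) sweep
    distinct = np.unique(values)
    pos_at = np.zeros(distinct.size)
    neg_at = np.zeros(distinct.size)
    idx = np.searchsorted(distinct, values)
    np.add.at(pos_at, idx[pos], 1.0)
    np.add.at(neg_at, idx[neg], 1.0)
    if direction.direction == "stress_higher":
        # sweep from high to low so FPR/TPR increase along the curve;
        # hits at the threshold between distinct[k-1] and distinct[k] are the
        # values >= distinct[k]
        thresholds = thresholds[::-1]
        suffix_pos = np.concatenate(([0.0], np.cumsum(pos_at[::-1])))
        suffix_neg = np.concatenate(([0.0], np.cumsum(neg_at[::-1])))
        tpr = suffix_pos / n_pos
        fpr = suffix_neg / n_neg
    else:
        # hits at the threshold between distinct[k-1] and distinct[k] are the
        # values <= distinct[k-1]
        tpr = np.concatenate(([0.0], np.cumsum(pos_at))) / n_pos
        fpr = np.concatenate(([0.0], np.cumsum(neg_at))) / n_neg
    auc = float(np.trapezoid(tpr, fpr))

    roc = RocResult(
        marker=direction.name,
        direction=direction.direction,
        thresholds=thresholds,
        tpr=tpr,
        fpr=fpr,
        auc=auc,
        youden_cutoff=np.nan,
        max_j=np.nan,
    )
    roc.youden_cutoff, roc.max_j = _youden(roc)
    return roc


def _youden(roc: RocResult) -> tuple[float, float]:
    j = roc.tpr - roc.fpr
    if j.size == 0:
        raise ValueError("empty ROC curve")
    max_j = float(j.max())
    tied = np.flatnonzero(j >= max_j - 1e-12)
    # ties: prefer highest TPR, then smallest threshold value
    best_tpr = roc.tpr[tied].max()
    tied = tied[roc.tpr[tied] >= best_tpr - 1e-12]
    cutoff = float(roc.thresholds[tied].min())
    return cutoff, max_j


def youden_cutoff(roc: RocResult) -> float:
    """Threshold maximizing J = TPR - FPR (ties: highest TPR, then smallest value)."""
    cutoff, _ = _youden(roc)
    return cutoff


def assign_dscore(
    record: PhysioRecord | Mapping[str, object],
    cutoffs: Mapping[str, float],
    directions: Sequence[MarkerDirection],
) -> DScoreResult:
    """Score one mouse: one point per marker strictly beyond its cutoff.

    A stress-higher marker counts when its value is strictly above the
    cutoff; a stress-lower marker when strictly below. Equality at the
    cutoff never counts (cutoffs sit at midpoints between observed values,
    so exact equality is a degenerate case resolved conservatively).
    """
    if isinstance(record, Mapping):
        get = record.__getitem__
        mouse_id = str(record.get("mouse_id", ""))
    else:
        get = record.marker
        mouse_id = record.mouse_id
    flags: dict[str, bool] = {}
    for md in directions:
        if md.name not in cutoffs:
            raise ValueError(f"missing cutoff for marker {md.name!r}")
        try:
            value = get(md.name)
        except KeyError:
            raise ValueError(f"missing marker value {md.name!r}") from None
        if value is None or not np.isfinite(value):
            raise ValueError(f"missing marker value {md.name!r}")
        cut = float(cutoffs[md.name])
        if md.direction == "stress_higher":
            flags[md.name] = bool(value > cut)
        else:
            flags[md.name] = bool(value < cut)
    dscore = int(sum(flags.values()))
    return DScoreResult(
        mouse_id=mouse_id,
        flags=flags,
        dscore=dscore,
        classification=classify_mouse(dscore),
    )


def classify_mouse(dscore: int | DScoreResult) -> str:
    """Map a D-score to its class: 0/1 -> non-stressed, 2/3 -> stressed."""
    score = dscore.dscore if isinstance(dscore, DScoreResult) else int(dscore)
    if score not in (0, 1, 2, 3):
        raise ValueError(f"D-score must be in 0..3, got {score}")
    return "stressed" if score >= 2 else "non-stressed"


def cohort_retention(scores: pd.DataFrame) -> dict:
    """Per-group D-score percentages and retention fractions.

    ``scores`` needs columns ``group`` and ``dscore``. Retention is the
    percentage of the control group with D-score 0 or 1 ("true" controls)
    and of the stress group with D-score 2 or 3 ("true" stressed mice).
    """
    if len(scores) == 0:
        raise ValueError("empty cohort")
    table = {}
    retention = {}
    for group in GROUPS:
        sub = scores.loc[scores["group"] == group, "dscore"]
        if len(sub) == 0:
            continue
        counts = sub.value_counts().reindex(range(4), fill_value=0)
        pct = 100.0 * counts / len(sub)
        table[group] = {int(k): float(v) for k, v in pct.items()}
        if group == "control":
            retention[group] = float(pct[0] + pct[1])
        else:
            retention[group] = float(pct[2] + pct[3])
    return {"dscore_percent": table, "retention_percent": retention}


def marker_predictiveness(
    data: pd.DataFrame,
    markers: Sequence[MarkerDirection],
    margin: float = 0.05,
) -> pd.DataFrame:
    """AUC per marker with an uninformativeness flag.

    A marker whose AUC lies within ``margin`` of 0.5 is flagged as a poor
    predictor of the group label (this is how a circulating-hormone marker
    like corticosterone can be checked and rejected).
    """
    rows = []
    for md in markers:
        roc = roc_curve(data[md.name].to_numpy(), data["group"].to_numpy(), md)
        rows.append(
            {
                "marker": md.name,
                "direction": md.direction,
                "auc": roc.auc,
                "max_j": roc.max_j,
                "youden_cutoff": roc.youden_cutoff,
                "uninformative": bool(abs(roc.auc - 0.5) < margin),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# model / results wrappers


class DScoreModel:
    """Cohort-level D-score model.

    Parameters
    ----------
    data : DataFrame
        One row per mouse with columns ``mouse_id``, ``group`` and the
        scored marker columns (``bw_gain_g``, ``adrenal_norm``,
        ``thymus_norm`` by default). An optional ``cort`` column is carried
        along for predictiveness reports but never scored.
    markers : sequence of MarkerDirection, optional
        The scored markers; defaults to the three-marker design.
    """

    def __init__(self, data: pd.DataFrame, markers: Sequence[MarkerDirection] | None = None):
        if markers is None:
            from .config import SCORED_MARKERS

            markers = SCORED_MARKERS
        self.markers = tuple(markers)
        required = {"mouse_id", "group"} | {m.name for m in self.markers}
        missing = required - set(data.columns)
        if missing:
            raise ValueError(f"data is missing columns: {sorted(missing)}")
        unknown = set(data["group"]) - set(GROUPS)
        if unknown:
            raise ValueError(f"unknown group labels: {sorted(unknown)}")
        self.data = data.reset_index(drop=True)

    @classmethod
    def from_csv(cls, path, **kwargs) -> "DScoreModel":
        return cls(pd.read_csv(path), **kwargs)

    def fit(self, cutoffs: str | Mapping[str, float] = "auto") -> "DScoreResults":
        """Derive (or freeze) cutoffs and score every mouse.

        ``cutoffs="auto"`` fits per-marker ROC curves on this cohort and
        takes the Youden cutoffs; passing a mapping freezes external
        cutoffs (e.g. previously published values) instead.
        """
        roc: dict[str, RocResult] = {}
        if isinstance(cutoffs, str):
            if cutoffs != "auto":
                raise ValueError(f"cutoffs must be 'auto' or a mapping, got {cutoffs!r}")
            source = "auto"
            cut_map = {}
            for md in self.markers:
                r = roc_curve(self.data[md.name].to_numpy(), self.data["group"].to_numpy(), md)
                roc[md.name] = r
                cut_map[md.name] = r.youden_cutoff
        else:
            source = "frozen"
            missing = {m.name for m in self.markers} - set(cutoffs)
            if missing:
                raise ValueError(f"frozen cutoffs missing markers: {sorted(missing)}")
            cut_map = {m.name: float(cutoffs[m.name]) for m in self.markers}

        rows = []
        for _, rec in self.data.iterrows():
            res = assign_dscore(rec.to_dict(), cut_map, self.markers)
            row = {
                "mouse_id": rec["mouse_id"],
                "group": rec["group"],
                "dscore": res.dscore,
                "classification": res.classification,
            }
            row.update({f"altered_{k}": v for k, v in res.flags.items()})
            rows.append(row)
        scores = pd.DataFrame(rows)
        return DScoreResults(self, cut_map, source, roc, scores)


class DScoreResults:
    """Fitted D-score results: cutoffs, ROC curves, per-mouse scores."""

    def __init__(self, model, cutoffs, cutoff_source, roc, scores):
        self.model = model
        self.cutoffs: dict[str, float] = dict(cutoffs)
        self.cutoff_source: str = cutoff_source
        self.roc: dict[str, RocResult] = roc
        self.scores: pd.DataFrame = scores

    def retention(self) -> dict:
        return cohort_retention(self.scores)

    def predictiveness(self, extra_markers: Sequence[MarkerDirection] = (), margin: float = 0.05) -> pd.DataFrame:
        return marker_predictiveness(
            self.model.data, tuple(self.model.markers) + tuple(extra_markers), margin=margin
        )

    def summary(self) -> str:
        lines = [
            "D-score classification summary",
            f"  mice: {len(self.scores)}  (cutoff source: {self.cutoff_source})",
            "  cutoffs:",
        ]
        for name, cut in self.cutoffs.items():
            auc = f", AUC={self.roc[name].auc:.3f}" if name in self.roc else ""
            lines.append(f"    {name:>14s} = {cut:.6g}{auc}")
        ret = self.retention()
        lines.append("  D-score distribution (% of group):")
        for group, pct in ret["dscore_percent"].items():
            dist = "  ".join(f"D{k}:{v:5.1f}" for k, v in pct.items())
            lines.append(f"    {group:>8s}  {dist}")
        for group, r in ret["retention_percent"].items():
            kept = "D0+D1" if group == "control" else "D2+D3"
            lines.append(f"  retention {group}: {r:.1f}% ({kept})")
        return "\n".join(lines)
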