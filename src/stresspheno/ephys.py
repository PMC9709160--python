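"""Striatal unit typing from extracellular spike waveforms.

Putative medium spiny neurons (MSNs) have broad extracellular spikes while
striatal interneurons fire narrow ones. Two shape features are measured on
each sorted unit's mean waveform — the half-width of the trough (width at
half the trough amplitude) and the trough-to-peak duration (delay from the
trough minimum to the subsequent positive peak) — and a two-component
Gaussian mixture fitted to the pooled 2-D feature cloud separates the two
classes. The component with the larger mean trough-to-peak duration is the
MSN class (long-duration spikes). Firing-rate summaries per (group, class)
cell follow.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.mixture import GaussianMixture

logger = logging.getLogger(__name__)

__all__ = [
    "UnitRecord",
    "UnitFeatures",
    "MixtureSummary",
    "waveform_features",
    "features_table",
    "classify_units",
    "firing_rate",
    "rate_histogram",
    "class_rate_report",
    "UnitTypeModel",
    "UnitTypeResults",
]


@dataclass
class UnitRecord:
    """A sorted unit: mean waveform, spike times, and metadata."""

    unit_id: str
    mouse_id: str
    group: str
    waveform_uv: np.ndarray
    sampling_rate_hz: float
    spike_times_s: np.ndarray
    duration_s: float
    true_class: str | None = None  # synthetic ground truth only

    def __post_init__(self) -> None:
        self.waveform_uv = np.asarray(self.waveform_uv, dtype=float)
        self.spike_times_s = np.asarray(self.spike_times_s, dtype=float)
        if self.waveform_uv.size == 0:
            raise ValueError("waveform must be non-empty")
        if self.sampling_rate_hz <= 0:
            raise ValueError("sampling rate must be > 0")
        if self.spike_times_s.size and np.any(np.diff(self.spike_times_s) < 0):
            raise ValueError("spike times must be non-decreasing")


@dataclass(frozen=True)
class UnitFeatures:
    """Waveform shape features in milliseconds."""

    half_width_ms: float
    trough_to_peak_ms: float


def waveform_features(waveform: Sequence[float], sampling_rate_hz: float) -> UnitFeatures:
    """Half-width and trough-to-peak duration of a mean spike waveform.

    The baseline is the median of the first quarter of the window (robust
    to the spike occupying the window center) and is subtracted before any
    measurement. The trough is the global minimum; if the waveform is
    peak-dominant it is inverted first (with a logged warning). The
    half-width is the time between the two linearly interpolated crossings
    of half the trough amplitude bracketing the trough; the trough-to-peak
    duration runs from the trough sample to the maximum after the trough.
    """
    w = np.asarray(waveform, dtype=float)
    if w.ndim != 1 or w.size < 4:
        raise ValueError("waveform must be a 1-D array with at least 4 samples")
    if sampling_rate_hz <= 0:
        raise ValueError("sampling rate must be > 0")
    baseline = np.median(w[: max(1, w.size // 4)])
    w = w - baseline
    if np.ptp(w) == 0:
        raise ValueError("flat waveform")
    if abs(w.min()) < abs(w.max()):
        logger.warning("peak-dominant waveform: inverting before feature extraction")
        w = -w

    trough = int(np.argmin(w))
    if trough >= w.size - 1:
        raise ValueError("no post-trough peak within the waveform window")
    amp = -w[trough]
    half = -amp / 2.0

    def _cross(i0: int, i1: int) -> float:
        # linear interpolation of the half-amplitude crossing between samples
        y0, y1 = w[i0], w[i1]
        return i0 + (half - y0) / (y1 - y0) * (i1 - i0)

    left = None
    for i in range(trough, 0, -1):
        if w[i - 1] > half >= w[i]:
            left = _cross(i - 1, i)
            break
    right = None
    for i in range(trough, w.size - 1):
        if w[i] <= half < w[i + 1]:
            right = _cross(i, i + 1)
            break
    if left is None or right is None:
        raise ValueError("trough is not bracketed by half-amplitude crossings")
    half_width_ms = (right - left) / sampling_rate_hz * 1e3

    if trough >= w.size - 1:
        raise ValueError("no post-trough peak within the waveform window")
    post = w[trough + 1 :]
    peak = trough + 1 + int(np.argmax(post))
    if w[peak] <= w[trough]:
        raise ValueError("no post-trough peak within the waveform window")
    trough_to_peak_ms = (peak - trough) / sampling_rate_hz * 1e3
    return UnitFeatures(float(half_width_ms), float(trough_to_peak_ms))


def features_table(units: Iterable[UnitRecord]) -> pd.DataFrame:
    """Feature extraction over a unit collection -> tidy DataFrame."""
    rows = []
    for u in units:
        f = waveform_features(u.waveform_uv, u.sampling_rate_hz)
        rows.append(
            {
                "unit_id": u.unit_id,
                "mouse_id": u.mouse_id,
                "group": u.group,
                "half_width_ms": f.half_width_ms,
                "trough_to_peak_ms": f.trough_to_peak_ms,
                "firing_rate_hz": firing_rate(u.spike_times_s, u.duration_s),
                "true_class": u.true_class,
            }
        )
    return pd.DataFrame(rows)


@dataclass
class MixtureSummary:
    """Fitted two-component mixture: parameters and the MSN labeling rule."""

    means: np.ndarray          # (2, 2) in (half_width_ms, trough_to_peak_ms)
    covariances: np.ndarray    # (2, 2, 2)
    weights: np.ndarray        # (2,)
    msn_component: int         # component with larger mean trough-to-peak
    seed: int
    n_init: int
    standardized: bool = False  # features fitted in raw ms units


FEATURE_COLUMNS = ["half_width_ms", "trough_to_peak_ms"]


def classify_units(
    features: pd.DataFrame,
    seed: int = 0,
    n_init: int = 10,
) -> tuple[pd.DataFrame, MixtureSummary]:
    """Two-component Gaussian-mixture unit typing on pooled features.

    The mixture (full covariances, ``n_init`` restarts, fixed seed) is
    fitted to all units pooled across groups; the component with the larger
    mean trough-to-peak duration is deterministically labeled MSN
    regardless of the component order the fit returns. Units are assigned
    by maximum posterior.
    """
    X = features[FEATURE_COLUMNS].to_numpy(dtype=float)
    if len(X) < 4:
        raise ValueError("need at least 4 units to fit the mixture")
    if not np.all(np.isfinite(X)):
        raise ValueError("features must be finite")
    if np.ptp(X, axis=0).max() == 0:
        raise ValueError("degenerate features: all units identical")

    gmm = GaussianMixture(
        n_components=2,
        covariance_type="full",
        n_init=n_init,
        random_state=seed,
    ).fit(X)
    msn_component = int(np.argmax(gmm.means_[:, 1]))
    post = gmm.predict_proba(X)
    assigned = np.argmax(post, axis=1)
    labels = np.where(assigned == msn_component, "MSN", "interneuron")
    out = features.copy()
    out["unit_class"] = labels
    out["posterior"] = post[np.arange(len(X)), assigned]
    summary = MixtureSummary(
        means=gmm.means_.copy(),
        covariances=gmm.covariances_.copy(),
        weights=gmm.weights_.copy(),
        msn_component=msn_component,
        seed=seed,
        n_init=n_init,
    )
    return out, summary


def firing_rate(spike_times_s: Sequence[float], duration_s: float) -> float:
    """Mean firing rate: spike count over recording duration (Hz)."""
    t = np.asarray(spike_times_s, dtype=float)
    if duration_s <= 0:
        raise ValueError("duration must be > 0")
    if t.size and (t.min() < 0 or t.max() > duration_s):
        raise ValueError("spike times outside the recording window")
    return float(t.size / duration_s)


def rate_histogram(rates_hz: Sequence[float], bins=20, range=None) -> tuple[np.ndarray, np.ndarray]:
    """Firing-rate histogram (counts, bin edges) with configurable bins."""
    return np.histogram(np.asarray(rates_hz, dtype=float), bins=bins, range=range)


def class_rate_report(units: pd.DataFrame) -> dict:
    """Group x class firing-rate summary with Welch between-group tests.

    ``units`` needs columns ``group``, ``unit_class`` and
    ``firing_rate_hz``. Empty (group, class) cells are reported as absent;
    the Welch comparison for a class is included only when both groups have
    at least two units of that class.
    """
    required = {"group", "unit_class", "firing_rate_hz"}
    missing = required - set(units.columns)
    if missing:
        raise ValueError(f"units table is missing columns: {sorted(missing)}")
    cells: dict = {}
    for (group, cls), sub in units.groupby(["group", "unit_class"]):
        r = sub["firing_rate_hz"].to_numpy()
        cells[(group, cls)] = {
            "n": int(len(r)),
            "mean_hz": float(np.mean(r)),
            "sd_hz": float(np.std(r, ddof=1)) if len(r) > 1 else 0.0,
            "sem_hz": float(np.std(r, ddof=1) / np.sqrt(len(r))) if len(r) > 1 else 0.0,
        }
    counts: dict = {}
    for group, sub in units.groupby("group"):
        n = len(sub)
        per_class = sub["unit_class"].value_counts().to_dict()
        counts[group] = {
            "n_units": int(n),
            "class_counts": {k: int(v) for k, v in per_class.items()},
            "class_percent": {k: 100.0 * v / n for k, v in per_class.items()},
        }
    tests: dict = {}
    groups = sorted(units["group"].unique())
    if len(groups) == 2:
        g0, g1 = groups
        for cls in sorted(units["unit_class"].unique()):
            a = units.query("group == @g0 and unit_class == @cls")["firing_rate_hz"].to_numpy()
            b = units.query("group == @g1 and unit_class == @cls")["firing_rate_hz"].to_numpy()
            if len(a) >= 2 and len(b) >= 2:
                t = stats.ttest_ind(a, b, equal_var=False)
                tests[cls] = {
                    "comparison": f"{g0} vs {g1}",
                    "mean_diff_hz": float(np.mean(a) - np.mean(b)),
                    "t": float(t.statistic),
                    "p": float(t.pvalue),
                    "df": float(t.df),
                }
    return {"cells": {f"{g}/{c}": v for (g, c), v in cells.items()}, "groups": counts, "welch": tests}


class UnitTypeModel:
    """Unit-typing model over a waveform-feature table (or UnitRecords)."""

    def __init__(self, features: pd.DataFrame):
        missing = set(FEATURE_COLUMNS) - set(features.columns)
        if missing:
            raise ValueError(f"features table is missing columns: {sorted(missing)}")
        self.features = features.reset_index(drop=True)

    @classmethod
    def from_units(cls, units: Iterable[UnitRecord]) -> "UnitTypeModel":
        return cls(features_table(units))

    def fit(self, seed: int = 0, n_init: int = 10) -> "UnitTypeResults":
        classification, mixture = classify_units(self.features, seed=seed, n_init=n_init)
        return UnitTypeResults(self, classification, mixture)


class UnitTypeResults:
    """Fitted unit classification plus rate summaries."""

    def __init__(self, model: UnitTypeModel, classification: pd.DataFrame, mixture: MixtureSummary):
        self.model = model
        self.classification = classification
        self.mixture = mixture

    def rate_report(self) -> dict:
        return class_rate_report(self.classification)

    def summary(self) -> str:
        n = len(self.classification)
        n_msn = int((self.classification["unit_class"] == "MSN").sum())
        lines = [
            "Unit classification summary (2-component Gaussian mixture, full covariance)",
            f"  units: {n}   MSN: {n_msn} ({100.0 * n_msn / n:.1f}%)   "
            f"interneuron: {n - n_msn} ({100.0 * (n - n_msn) / n:.1f}%)",
            f"  mixture seed: {self.mixture.seed}, restarts: {self.mixture.n_init}, "
            f"features in raw ms (standardized={self.mixture.standardized})",
        ]
        for k in range(2):
            tag = "MSN" if k == self.mixture.msn_component else "interneuron"
            hw, tp = self.mixture.means[k]
            lines.append(
                f"  component {k} ({tag:>11s}): half-width {hw:.3f} ms, "
                f"trough-to-peak {tp:.3f} ms, weight {self.mixture.weights[k]:.3f}"
            )
        if "group" in self.classification.columns and "firing_rate_hz" in self.classification.columns:
            rep = self.rate_report()
            for cell, v in rep["cells"].items():
                lines.append(
                    f"  {cell:>20s}: n={v['n']:4d}  rate {v['mean_hz']:.2f} ± {v['sem_hz']:.2f} Hz (mean ± sem)"
                )
        return "\n".join(lines)
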