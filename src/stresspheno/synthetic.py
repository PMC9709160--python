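"""Seeded generators for the three input modalities of the pipeline.

Three generators emulate the statistical structure each analysis stage
assumes, so the whole pipeline can be exercised end-to-end without any
recorded data:

* :func:`gen_physio_cohort` — a two-group Gaussian cohort of physiological
  markers (body-weight gain, normalized adrenal and thymus weight, plus an
  optional uninformative corticosterone column). Markers are drawn
  independently per mouse — in the real cohort the individual markers were
  not mutually correlated — and the stress group is given a wider spread
  than the controls, reflecting the heterogeneity of individual stress
  responses that motivates composite scoring in the first place.
* :func:`gen_units` — sorted-unit stand-ins: a noisy trough-dominant mean
  waveform per unit (raised-cosine trough plus a smaller raised-cosine
  peak, so half-width and trough-to-peak are analytically known) and a
  homogeneous Poisson spike train, with ground-truth class labels kept for
  recovery tests.
* :func:`gen_motif_sequences` — frame-wise motif labels from a Markov chain
  whose between-distinct-motif transition matrix has block (community)
  structure, with a scalar self-persistence probability so motifs last
  multiple frames.

All generators are driven by ``numpy.random.default_rng(seed)``: identical
spec and seed give bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd

from .config import PAPER_COMMUNITIES
from .ephys import UnitRecord
from .motifs import MotifSequence

__all__ = [
    "MarkerParams",
    "PhysioGenSpec",
    "ClassTemplate",
    "UnitGenSpec",
    "MotifGenSpec",
    "gen_physio_cohort",
    "gen_units",
    "gen_motif_sequences",
    "cosine_spike_template",
]


# ---------------------------------------------------------------------------
# physiological cohort


@dataclass(frozen=True)
class MarkerParams:
    """Group means and standard deviations of one Gaussian marker."""

    control_mean: float
    control_sd: float
    stress_mean: float
    stress_sd: float

    def validate(self, name: str) -> None:
        if self.control_sd < 0 or self.stress_sd < 0:
            raise ValueError(f"{name}: standard deviations must be >= 0")


@dataclass(frozen=True)
class PhysioGenSpec:
    """Two-group Gaussian cohort specification.

    Defaults emulate a 21-day chronic-unpredictable-stress cohort of 88
    control and 90 stressed mice. The stress-group spreads are set wide
    relative to the mean shifts (heterogeneous individual responses), so a
    three-marker composite score retains roughly three quarters of controls
    and three fifths of stressed animals as "true" members of their group.
    Corticosterone defaults to the same distribution in both groups: an
    intentionally uninformative marker.
    """

    n_control: int = 88
    n_stress: int = 90
    bw_gain_g: MarkerParams = MarkerParams(5.0, 1.0, 4.25, 1.12)
    adrenal_norm: MarkerParams = MarkerParams(1.10e-4, 0.15e-4, 1.21e-4, 0.17e-4)
    thymus_norm: MarkerParams = MarkerParams(1.75e-3, 0.20e-3, 1.60e-3, 0.22e-3)
    cort: MarkerParams | None = MarkerParams(70.0, 25.0, 70.0, 25.0)  # ng/mL
    seed: int = 0

    def validate(self) -> None:
        if self.n_control < 0 or self.n_stress < 0:
            raise ValueError("group sizes must be >= 0")
        for name in ("bw_gain_g", "adrenal_norm", "thymus_norm"):
            getattr(self, name).validate(name)
        if self.cort is not None:
            self.cort.validate("cort")


def gen_physio_cohort(spec: PhysioGenSpec) -> pd.DataFrame:
    """Draw a two-group physiological cohort as a tidy per-mouse table.

    Columns: ``mouse_id``, ``group``, ``bw_gain_g``, ``adrenal_norm``,
    ``thymus_norm`` and (unless disabled) ``cort``. Organ weights are
    floored at a tiny positive value so normalized weights stay strictly
    positive even in the far Gaussian tail.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    frames = []
    for group, n in (("control", spec.n_control), ("stress", spec.n_stress)):
        prefix = "c" if group == "control" else "s"
        cols: dict = {
            "mouse_id": [f"{prefix}{i + 1:03d}" for i in range(n)],
            "group": [group] * n,
        }
        for name in ("bw_gain_g", "adrenal_norm", "thymus_norm", "cort"):
            mp: MarkerParams | None = getattr(spec, name)
            if mp is None:
                continue
            mean = mp.control_mean if group == "control" else mp.stress_mean
            sd = mp.control_sd if group == "control" else mp.stress_sd
            vals = rng.normal(mean, sd, size=n)
            if name in ("adrenal_norm", "thymus_norm"):
                vals = np.maximum(vals, 1e-3 * mp.control_mean)
            cols[name] = vals
        frames.append(pd.DataFrame(cols))
    out = pd.concat(frames, ignore_index=True)
    if spec.cort is None and "cort" in out.columns:
        out = out.drop(columns="cort")
    return out


# ---------------------------------------------------------------------------
# spike waveforms and trains


@dataclass(frozen=True)
class ClassTemplate:
    """Parametric trough-dominant spike template for one cell class.

    The waveform is a negative raised-cosine (Hann) lobe of full width
    ``trough_width_ms`` reaching ``-trough_amp_uv``, followed by a positive
    raised-cosine lobe of amplitude ``peak_fraction * trough_amp_uv``
    centered ``trough_to_peak_ms`` after the trough minimum. With this
    shape the measured half-width is exactly ``trough_width_ms / 2`` and
    the measured trough-to-peak duration is exactly ``trough_to_peak_ms``
    (up to sample interpolation).
    """

    trough_amp_uv: float
    trough_width_ms: float
    trough_to_peak_ms: float
    peak_fraction: float = 0.35
    peak_width_ms: float | None = None  # defaults to trough_width_ms

    @property
    def peak_width(self) -> float:
        return self.peak_width_ms if self.peak_width_ms is not None else self.trough_width_ms

    def validate(self, name: str) -> None:
        if self.trough_amp_uv <= 0:
            raise ValueError(f"{name}: trough amplitude must be > 0")
        if self.trough_width_ms <= 0 or self.peak_width <= 0:
            raise ValueError(f"{name}: lobe widths must be > 0")
        if self.trough_to_peak_ms <= 0:
            raise ValueError(f"{name}: trough-to-peak lag must be > 0")
        if self.trough_to_peak_ms < (self.trough_width_ms + self.peak_width) / 2:
            raise ValueError(
                f"{name}: lobes overlap (lag must be >= half the summed lobe widths)"
            )


def cosine_spike_template(
    times_ms: np.ndarray, template: ClassTemplate, trough_time_ms: float
) -> np.ndarray:
    """Evaluate the raised-cosine spike template at arbitrary times (ms)."""
    t = np.asarray(times_ms, dtype=float) - trough_time_ms
    v = np.zeros_like(t)
    w = template.trough_width_ms
    in_trough = np.abs(t) <= w / 2
    v[in_trough] -= template.trough_amp_uv * 0.5 * (1 + np.cos(2 * np.pi * t[in_trough] / w))
    wp = template.peak_width
    tp = t - template.trough_to_peak_ms
    in_peak = np.abs(tp) <= wp / 2
    v[in_peak] += (
        template.peak_fraction
        * template.trough_amp_uv
        * 0.5
        * (1 + np.cos(2 * np.pi * tp[in_peak] / wp))
    )
    return v


@dataclass(frozen=True)
class UnitGenSpec:
    """Sorted-unit ensemble specification.

    Defaults emulate one group's striatal recording: ~300 units of which a
    handful are interneurons, mean waveforms sampled at 30 kS/s over a 3 ms
    window, 30 min of spontaneous activity. MSN templates are broad
    (half-width 0.25 ms, trough-to-peak 0.75 ms) and slow-firing;
    interneuron templates are narrow (0.11 ms, 0.30 ms) and faster-firing.
    Per-unit rates are lognormal around the class mean (``rate_log_sd`` of
    the log; 0 disables the spread), giving realistic rate histograms.
    """

    n_msn: int = 285
    n_interneuron: int = 16
    sampling_rate_hz: float = 30000.0
    window_samples: int = 90
    trough_sample: int = 30
    msn: ClassTemplate = ClassTemplate(80.0, 0.50, 0.75)
    interneuron: ClassTemplate = ClassTemplate(60.0, 0.22, 0.30)
    noise_sd_uv: float = 2.0
    msn_rate_hz: float = 2.0
    interneuron_rate_hz: float = 6.5
    rate_log_sd: float = 0.4
    duration_s: float = 1800.0
    mouse_id: str = "sim"
    group: str = "control"
    seed: int = 0

    def validate(self) -> None:
        if self.n_msn < 0 or self.n_interneuron < 0:
            raise ValueError("unit counts must be >= 0")
        if self.sampling_rate_hz <= 0:
            raise ValueError("sampling rate must be > 0")
        if self.noise_sd_uv < 0:
            raise ValueError("noise sd must be >= 0")
        if self.msn_rate_hz < 0 or self.interneuron_rate_hz < 0:
            raise ValueError("firing rates must be >= 0")
        if self.duration_s <= 0:
            raise ValueError("duration must be > 0")
        window_ms = self.window_samples / self.sampling_rate_hz * 1e3
        trough_ms = self.trough_sample / self.sampling_rate_hz * 1e3
        for name in ("msn", "interneuron"):
            tpl: ClassTemplate = getattr(self, name)
            tpl.validate(name)
            if trough_ms - tpl.trough_width_ms / 2 < 0:
                raise ValueError(f"{name}: window too short before the trough")
            if trough_ms + tpl.trough_to_peak_ms + tpl.peak_width / 2 >= window_ms:
                raise ValueError(f"{name}: window too short to contain the post-trough peak")


def gen_units(spec: UnitGenSpec) -> list[UnitRecord]:
    """Generate noisy template waveforms and Poisson spike trains.

    Each unit carries its ground-truth class in ``true_class`` so
    classification stages can be scored against the generator.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    times_ms = np.arange(spec.window_samples) / spec.sampling_rate_hz * 1e3
    trough_ms = spec.trough_sample / spec.sampling_rate_hz * 1e3
    units: list[UnitRecord] = []
    plan = [("MSN", spec.msn, spec.msn_rate_hz)] * spec.n_msn + [
        ("interneuron", spec.interneuron, spec.interneuron_rate_hz)
    ] * spec.n_interneuron
    for i, (cls, tpl, class_rate) in enumerate(plan):
        clean = cosine_spike_template(times_ms, tpl, trough_ms)
        wf = clean + rng.normal(0.0, spec.noise_sd_uv, size=clean.shape)
        if spec.rate_log_sd > 0:
            # lognormal with mean exactly class_rate
            rate = class_rate * rng.lognormal(-spec.rate_log_sd**2 / 2, spec.rate_log_sd)
        else:
            rate = class_rate
        n_spikes = rng.poisson(rate * spec.duration_s)
        spikes = np.sort(rng.uniform(0.0, spec.duration_s, size=n_spikes))
        units.append(
            UnitRecord(
                unit_id=f"{spec.mouse_id}_u{i:04d}",
                mouse_id=spec.mouse_id,
                group=spec.group,
                waveform_uv=wf,
                sampling_rate_hz=spec.sampling_rate_hz,
                spike_times_s=spikes,
                duration_s=spec.duration_s,
                true_class=cls,
            )
        )
    return units


# ---------------------------------------------------------------------------
# motif sequences


@dataclass(frozen=True)
class MotifGenSpec:
    """Block-structured Markov motif-sequence specification.

    The between-distinct-motif chain gives weight ``within_weight`` to
    transitions inside a community and ``between_weight`` across
    communities (row-normalized, zero diagonal); a scalar
    ``self_persistence`` probability of repeating the current label at
    every frame makes motifs last multiple frames. Defaults emulate a
    10-minute open-field session at 60 frames/s with 38 motifs in the 8
    published communities. ``community_bias`` optionally scales the inflow
    weight into whole communities (per community id), shifting their
    stationary usage — a simple way to configure group/condition effects.
    """

    n_motifs: int = 38
    partition: Mapping[int, int] = field(default_factory=lambda: dict(PAPER_COMMUNITIES))
    within_weight: float = 1.0
    between_weight: float = 0.1
    self_persistence: float = 0.95
    frames: int = 36000
    frame_rate: float = 60.0
    n_mice: int = 20
    group: str = "control"
    condition: str = "saline"
    community_bias: Mapping[int, float] | None = None
    seed: int = 0

    def validate(self) -> None:
        if self.n_motifs < 1:
            raise ValueError("need at least 1 motif")
        if sorted(self.partition) != list(range(self.n_motifs)):
            raise ValueError("partition must cover motifs 0..n_motifs-1 exactly once")
        if self.within_weight < 0 or self.between_weight < 0:
            raise ValueError("transition weights must be >= 0")
        if not 0 <= self.self_persistence < 1:
            raise ValueError("self persistence must be in [0, 1)")
        if self.frames < 1 or self.n_mice < 0:
            raise ValueError("frames must be >= 1 and n_mice >= 0")
        if self.frame_rate <= 0:
            raise ValueError("frame rate must be > 0")

    def move_matrix(self) -> np.ndarray:
        """The generating off-diagonal-normalized transition matrix."""
        self.validate()
        K = self.n_motifs
        comm = np.array([self.partition[m] for m in range(K)])
        W = np.where(comm[:, None] == comm[None, :], self.within_weight, self.between_weight)
        W = W.astype(float)
        if self.community_bias:
            for c, factor in self.community_bias.items():
                W[:, comm == c] *= factor
        np.fill_diagonal(W, 0.0)
        rows = W.sum(axis=1)
        if np.any(rows <= 0) and K > 1:
            bad = np.flatnonzero(rows <= 0).tolist()
            raise ValueError(f"unnormalizable transition rows for motifs {bad}")
        if K == 1:
            return np.zeros((1, 1))
        return W / rows[:, None]


def gen_motif_sequences(spec: MotifGenSpec) -> list[MotifSequence]:
    """Sample one frame-wise label sequence per mouse from the block chain."""
    spec.validate()
    P = spec.move_matrix()
    K = spec.n_motifs
    cum = np.cumsum(P, axis=1)
    rng = np.random.default_rng(spec.seed)
    seqs: list[MotifSequence] = []
    for m in range(spec.n_mice):
        labels = np.empty(spec.frames, dtype=int)
        state = int(rng.integers(K))
        stay = rng.random(spec.frames)
        move_u = rng.random(spec.frames)
        labels[0] = state
        for t in range(1, spec.frames):
            if stay[t] >= spec.self_persistence and K > 1:
                state = int(np.searchsorted(cum[state], move_u[t]))
            labels[t] = state
        seqs.append(
            MotifSequence(
                # same mouse id across conditions: sessions pair within group
                mouse_id=f"{spec.group[:1]}{m + 1:03d}",
                group=spec.group,
                condition=spec.condition,
                labels=labels,
                frame_rate=spec.frame_rate,
            )
        )
    return seqs
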