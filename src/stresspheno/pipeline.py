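"""End-to-end orchestration: config validation, stage execution, manifest.

A single human-readable YAML/JSON config drives the four stages —
``simulate`` (synthetic inputs), ``phenoscore``, ``ephys`` and ``motifs`` —
each reading/writing plain CSV/JSON files. Every run writes a manifest
recording the config snapshot, package version, per-file SHA-256 checksums
and timestamps, so identical configs and seeds give identical outputs
(checksums verify it).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .config import PAPER_COMMUNITY_LABELS, PAPER_CUTOFFS, SCORED_MARKERS
from .ephys import UnitRecord, UnitTypeModel, features_table
from .motifs import CommunityModel, MotifSequence
from .phenoscore import DScoreModel, MarkerDirection
from .synthetic import (
    MotifGenSpec,
    PhysioGenSpec,
    UnitGenSpec,
    gen_motif_sequences,
    gen_physio_cohort,
    gen_units,
)

logger = logging.getLogger(__name__)

__all__ = [
    "PipelineConfig",
    "RunManifest",
    "validate_config",
    "run_pipeline",
    "write_units_csv",
    "read_units_csv",
    "write_sequences_csv",
    "read_sequences_csv",
]

STAGES = ("simulate", "phenoscore", "ephys", "motifs")


@dataclass
class PipelineConfig:
    """Validated pipeline configuration with defaults for every field."""

    stages: tuple[str, ...] = STAGES
    seed: int = 0
    out_dir: str = "results"
    # phenoscore
    cohort_csv: str | None = None          # input; None -> use simulated cohort
    cutoff_mode: str = "auto"              # "auto" | "frozen"
    frozen_cutoffs: dict[str, float] = field(default_factory=lambda: dict(PAPER_CUTOFFS))
    # ephys
    units_csv: str | None = None           # input prefix; None -> use simulated units
    mixture_seed: int = 0
    mixture_restarts: int = 10
    # motifs
    labels_csv: str | None = None          # input; None -> use simulated sequences
    n_motifs: int = 38
    n_communities: int = 8
    collapse_runs: bool = True
    community_labels: dict[int, str] = field(default_factory=lambda: dict(PAPER_COMMUNITY_LABELS))
    # simulate-stage sizes (None -> generator defaults)
    sim: dict[str, Any] = field(default_factory=dict)


_KNOWN_KEYS = {f.name for f in dataclasses.fields(PipelineConfig)}


def validate_config(source: str | Path | Mapping[str, Any] | None) -> tuple[PipelineConfig | None, list[str]]:
    """Parse, default and validate a config; all errors reported at once.

    ``source`` may be a path to a YAML/JSON file, a mapping, or None/empty
    (full defaults). Returns ``(config, errors)``; ``config`` is None when
    any error was found.
    """
    errors: list[str] = []
    if source is None:
        raw: dict = {}
    elif isinstance(source, Mapping):
        raw = dict(source)
    else:
        path = Path(source)
        if not path.exists():
            return None, [f"config file not found: {path}"]
        text = path.read_text()
        raw = yaml.safe_load(text) or {}
        if not isinstance(raw, dict):
            return None, [f"config root must be a mapping, got {type(raw).__name__}"]

    unknown = set(raw) - _KNOWN_KEYS
    for key in sorted(unknown):
        errors.append(f"unknown config key: {key!r}")
    kwargs = {k: v for k, v in raw.items() if k in _KNOWN_KEYS}

    if "stages" in kwargs:
        stages = tuple(kwargs["stages"])
        bad = [s for s in stages if s not in STAGES]
        if bad:
            errors.append(f"unknown stages: {bad}")
        kwargs["stages"] = stages
    for key in ("seed", "mixture_seed"):
        if key in kwargs and (not isinstance(kwargs[key], int) or kwargs[key] < 0):
            errors.append(f"{key} must be a non-negative integer")
    for key in ("n_motifs", "n_communities", "mixture_restarts"):
        if key in kwargs and (not isinstance(kwargs[key], int) or kwargs[key] < 1):
            errors.append(f"{key} must be a positive integer")
    if kwargs.get("cutoff_mode", "auto") not in ("auto", "frozen"):
        errors.append("cutoff_mode must be 'auto' or 'frozen'")
    if kwargs.get("cutoff_mode") == "frozen":
        frozen = kwargs.get("frozen_cutoffs", dict(PAPER_CUTOFFS))
        missing = {m.name for m in SCORED_MARKERS} - set(frozen)
        if missing:
            errors.append(f"frozen_cutoffs missing markers: {sorted(missing)}")
    if "community_labels" in kwargs:
        kwargs["community_labels"] = {int(k): str(v) for k, v in kwargs["community_labels"].items()}
    stages = kwargs.get("stages", STAGES)
    for key, stage in (("cohort_csv", "phenoscore"), ("labels_csv", "motifs")):
        p = kwargs.get(key)
        if p is not None and stage in stages and not Path(p).exists():
            errors.append(f"{key} does not exist: {p}")

    if errors:
        return None, errors
    return PipelineConfig(**kwargs), []


# ---------------------------------------------------------------------------
# plain-text unit / sequence containers


def write_units_csv(units: list[UnitRecord], prefix: Path) -> list[Path]:
    """Write a unit collection as three CSVs: waveforms, spikes, metadata."""
    prefix = Path(prefix)
    wf_rows, sp_rows, meta_rows = [], [], []
    for u in units:
        wf_rows.append(
            {"unit_id": u.unit_id, **{f"s{i}": v for i, v in enumerate(u.waveform_uv)}}
        )
        sp_rows.extend({"unit_id": u.unit_id, "t_s": t} for t in u.spike_times_s)
        meta_rows.append(
            {
                "unit_id": u.unit_id,
                "mouse_id": u.mouse_id,
                "group": u.group,
                "duration_s": u.duration_s,
                "rate_hz": u.sampling_rate_hz,
                "true_class": u.true_class if u.true_class is not None else "",
            }
        )
    paths = [prefix.with_name(prefix.name + s) for s in ("_waveforms.csv", "_spikes.csv", "_meta.csv")]
    pd.DataFrame(wf_rows).to_csv(paths[0], index=False)
    pd.DataFrame(sp_rows, columns=["unit_id", "t_s"]).to_csv(paths[1], index=False)
    pd.DataFrame(meta_rows).to_csv(paths[2], index=False)
    return paths


def read_units_csv(prefix: Path) -> list[UnitRecord]:
    prefix = Path(prefix)
    wf = pd.read_csv(prefix.with_name(prefix.name + "_waveforms.csv"))
    sp = pd.read_csv(prefix.with_name(prefix.name + "_spikes.csv"))
    meta = pd.read_csv(prefix.with_name(prefix.name + "_meta.csv"), keep_default_na=False)
    spikes = {uid: g["t_s"].to_numpy() for uid, g in sp.groupby("unit_id")}
    sample_cols = [c for c in wf.columns if c.startswith("s")]
    units = []
    for _, m in meta.iterrows():
        row = wf.loc[wf["unit_id"] == m["unit_id"], sample_cols].to_numpy()[0]
        units.append(
            UnitRecord(
                unit_id=str(m["unit_id"]),
                mouse_id=str(m["mouse_id"]),
                group=str(m["group"]),
                waveform_uv=row,
                sampling_rate_hz=float(m["rate_hz"]),
                spike_times_s=np.sort(spikes.get(m["unit_id"], np.empty(0))),
                duration_s=float(m["duration_s"]),
                true_class=str(m["true_class"]) or None,
            )
        )
    return units


def write_sequences_csv(seqs: list[MotifSequence], path: Path) -> Path:
    rows = []
    for s in seqs:
        rows.append(
            pd.DataFrame(
                {
                    "mouse_id": s.mouse_id,
                    "group": s.group,
                    "condition": s.condition,
                    "frame": np.arange(s.labels.size),
                    "motif": s.labels,
                }
            )
        )
    pd.concat(rows, ignore_index=True).to_csv(path, index=False)
    return Path(path)


def read_sequences_csv(path: Path, frame_rate: float = 60.0) -> list[MotifSequence]:
    df = pd.read_csv(path)
    seqs = []
    for (mouse, group, cond), sub in df.groupby(["mouse_id", "group", "condition"]):
        sub = sub.sort_values("frame")
        seqs.append(MotifSequence(str(mouse), str(group), str(cond), sub["motif"].to_numpy(), frame_rate))
    return seqs


# ---------------------------------------------------------------------------
# run


@dataclass
class RunManifest:
    """Reproducibility record of one pipeline run."""

    config: dict
    version: str
    started: float
    finished: float | None = None
    outputs: dict[str, str] = field(default_factory=dict)  # relpath -> sha256
    stages_completed: list[str] = field(default_factory=list)
    failed_stage: str | None = None

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, default=str)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _register(manifest: RunManifest, out_dir: Path, *paths: Path) -> None:
    for p in paths:
        manifest.outputs[str(Path(p).relative_to(out_dir))] = _sha256(Path(p))


def _sub_seed(seed: int, offset: int) -> int:
    return (seed * 1000 + offset) % (2**31 - 1)


def run_pipeline(config: PipelineConfig, out_dir: str | Path | None = None) -> RunManifest:
    """Execute the selected stages in order and write outputs + manifest."""
    out = Path(out_dir if out_dir is not None else config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config=dataclasses.asdict(config), version=__version__, started=time.time())
    sim = dict(config.sim)

    cohort_df = None
    units = None
    seqs = None
    try:
        if "simulate" in config.stages:
            physio = PhysioGenSpec(
                seed=_sub_seed(config.seed, 1), **sim.get("physio", {})
            )
            cohort_df = gen_physio_cohort(physio)
            cohort_path = out / "synthetic_cohort.csv"
            cohort_df.to_csv(cohort_path, index=False)

            unit_kwargs = sim.get("units", {})
            units = []
            for gi, group in enumerate(("control", "stress")):
                kw = dict(unit_kwargs.get(group, unit_kwargs.get("both", {})))
                spec = UnitGenSpec(
                    group=group,
                    mouse_id=f"{group[:1]}sim",
                    seed=_sub_seed(config.seed, 2 + gi),
                    **kw,
                )
                units.extend(gen_units(spec))
            unit_paths = write_units_csv(units, out / "synthetic_units")

            motif_kwargs = sim.get("motifs", {})
            seqs = []
            si = 0
            for group in ("control", "stress"):
                for condition in ("saline", "CNO"):
                    kw = dict(motif_kwargs.get(f"{group}_{condition}", motif_kwargs.get("all", {})))
                    spec = MotifGenSpec(
                        group=group,
                        condition=condition,
                        seed=_sub_seed(config.seed, 10 + si),
                        **kw,
                    )
                    seqs.extend(gen_motif_sequences(spec))
                    si += 1
            seq_path = write_sequences_csv(seqs, out / "synthetic_motifs.csv")
            _register(manifest, out, cohort_path, *unit_paths, seq_path)
            manifest.stages_completed.append("simulate")

        if "phenoscore" in config.stages:
            if config.cohort_csv is not None:
                cohort_df = pd.read_csv(config.cohort_csv)
            if cohort_df is None:
                raise RuntimeError("phenoscore stage needs cohort_csv or the simulate stage")
            model = DScoreModel(cohort_df)
            cutoffs = "auto" if config.cutoff_mode == "auto" else config.frozen_cutoffs
            res = model.fit(cutoffs=cutoffs)
            scores_path = out / "dscores.csv"
            res.scores.to_csv(scores_path, index=False)
            roc_paths = []
            for name, roc in res.roc.items():
                p = out / f"roc_{name}.csv"
                pd.DataFrame(
                    {"threshold": roc.thresholds, "tpr": roc.tpr, "fpr": roc.fpr, "j": roc.j}
                ).to_csv(p, index=False)
                roc_paths.append(p)
            extra = []
            if "cort" in cohort_df.columns:
                extra = [MarkerDirection("cort", "stress_higher")]
            summary = {
                "cutoff_source": res.cutoff_source,
                "cutoffs": res.cutoffs,
                "retention": res.retention(),
                "predictiveness": res.predictiveness(extra).to_dict(orient="records"),
            }
            summary_path = out / "phenoscore_summary.json"
            summary_path.write_text(json.dumps(summary, indent=2))
            _register(manifest, out, scores_path, *roc_paths, summary_path)
            manifest.stages_completed.append("phenoscore")

        if "ephys" in config.stages:
            if config.units_csv is not None:
                units = read_units_csv(Path(config.units_csv))
            if units is None:
                raise RuntimeError("ephys stage needs units_csv or the simulate stage")
            model = UnitTypeModel.from_units(units)
            res = model.fit(seed=config.mixture_seed, n_init=config.mixture_restarts)
            cls_path = out / "unit_classes.csv"
            res.classification.to_csv(cls_path, index=False)
            summary = {
                "mixture": {
                    "means": res.mixture.means.tolist(),
                    "weights": res.mixture.weights.tolist(),
                    "msn_component": res.mixture.msn_component,
                    "seed": res.mixture.seed,
                    "n_init": res.mixture.n_init,
                },
                "rates": res.rate_report(),
            }
            summary_path = out / "ephys_summary.json"
            summary_path.write_text(json.dumps(summary, indent=2))
            _register(manifest, out, cls_path, summary_path)
            manifest.stages_completed.append("ephys")

        if "motifs" in config.stages:
            if config.labels_csv is not None:
                seqs = read_sequences_csv(Path(config.labels_csv))
            if seqs is None:
                raise RuntimeError("motifs stage needs labels_csv or the simulate stage")
            model = CommunityModel(seqs, config.n_motifs, collapse=config.collapse_runs)
            res = model.fit(config.n_communities, labels=config.community_labels)
            paths = []
            p = out / "transition_matrix.csv"
            pd.DataFrame(res.transition.probs).to_csv(p, index=False)
            paths.append(p)
            p = out / "community_tree.json"
            p.write_text(
                json.dumps(
                    {
                        "n_leaves": res.tree.n_leaves,
                        "merges": res.tree.merges,
                        "partition": res.tree.partition,
                        "labels": res.tree.labels,
                    },
                    indent=2,
                )
            )
            paths.append(p)
            p = out / "motif_usage.csv"
            res.motif_usage_table().to_csv(p, index=False)
            paths.append(p)
            p = out / "community_usage.csv"
            res.community_usage_table().to_csv(p, index=False)
            paths.append(p)
            p = out / "community_comparisons.csv"
            res.compare().to_csv(p, index=False)
            paths.append(p)
            _register(manifest, out, *paths)
            manifest.stages_completed.append("motifs")
    except Exception:
        manifest.failed_stage = next(
            (s for s in config.stages if s not in manifest.stages_completed), None
        )
        manifest.finished = time.time()
        (out / "manifest.json").write_text(manifest.to_json())
        raise

    manifest.finished = time.time()
    (out / "manifest.json").write_text(manifest.to_json())
    return manifest
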