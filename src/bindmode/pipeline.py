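"""Configuration-driven end-to-end analysis pipeline.

Stage order: load -> per-replica interaction fingerprints -> pooled fraction
table -> water-site occupancy and exchange -> side-chain state traces ->
state-conditional occupancy -> affinity-propagation clustering ->
representative-frame export. Each replica is isolated: an error voids only
that replica and is recorded in the run manifest.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import yaml

from . import __version__
from .cluster import (affinity_propagation, pairwise_rmsd_matrix,
                      select_representative, subsample_by_time)
from .errors import BindmodeError, ConfigError
from .fingerprints import (InteractionCriteria, aggregate_fractions,
                           detect_all, events_to_jsonl)
from .geometry import rmsd_trace
from .states import (StateBoundary, classify_states, density_grid,
                     flip_descriptors, traces_to_csv as states_to_csv)
from .structure_io import (Frame, Selection, load_topology, load_trajectory,
                           select, write_frames_pdb)
from .synthetic import GeneratorConfig, simulate
from .water import (WaterSite, conditional_occupancy, occupancy_summary,
                    occupancy_trace, sidechain_anchor,
                    traces_to_csv as occupancy_to_csv)

log = logging.getLogger("bindmode")

REPORT_FILES = ("fractions.csv", "events.jsonl", "occupancy.csv",
                "occupancy_summary.json", "states.csv",
                "conditional_occupancy.json", "clusters.json")


@dataclass
class PipelineConfig:
    """Everything one analysis run needs; defaults follow the study design."""

    topology: str | None = None
    trajectories: tuple[str, ...] = ()
    ligand_sidecar: str | None = None
    synthetic: GeneratorConfig | None = None
    criteria: InteractionCriteria = field(default_factory=InteractionCriteria)
    stride_ns: float = 1.0
    water_site_residues: tuple[int, ...] = (58, 10)
    water_site_radius: float = 3.0
    state_donor_residue: int = 58
    state_reference_residue: int = 10
    state_boundary: StateBoundary = field(default_factory=StateBoundary)
    cluster_max_frames: int = 300
    cluster_damping: float = 0.5
    cluster_preference: float | None = None
    key_residues: tuple[int, ...] | None = None   # default: from fractions

    def __post_init__(self):
        if self.stride_ns <= 0:
            raise ConfigError("stride_ns must be positive")
        if self.synthetic is None and self.topology is None:
            raise ConfigError("either input files or a synthetic source "
                              "must be given")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        kwargs = dict(raw)
        if "criteria" in kwargs:
            kwargs["criteria"] = InteractionCriteria(**kwargs["criteria"])
        if "state_boundary" in kwargs:
            sb = kwargs["state_boundary"]
            if "angle_window" in sb:
                sb["angle_window"] = tuple(sb["angle_window"])
            kwargs["state_boundary"] = StateBoundary(**sb)
        if "synthetic" in kwargs and kwargs["synthetic"] is not None:
            syn = dict(kwargs["synthetic"])
            if "state_schedule" in syn:
                from .synthetic import StateSchedule
                syn["state_schedule"] = StateSchedule(**syn["state_schedule"])
            kwargs["synthetic"] = GeneratorConfig(**syn)
        for key in ("trajectories", "water_site_residues", "key_residues"):
            if key in kwargs and kwargs[key] is not None:
                kwargs[key] = tuple(kwargs[key])
        return cls(**kwargs)

    def to_jsonable(self) -> dict:
        def conv(obj):
            if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
                return {k: conv(v)
                        for k, v in dataclasses.asdict(obj).items()}
            if isinstance(obj, (tuple, list)):
                return [conv(v) for v in obj]
            return obj
        return {f.name: conv(getattr(self, f.name))
                for f in dataclasses.fields(self)}


def _config_hash(config: PipelineConfig) -> str:
    blob = json.dumps(config.to_jsonable(), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def _replica_sources(config: PipelineConfig):
    """Yield (replica_id, topology, frame iterator)."""
    if config.synthetic is not None:
        traj = simulate(config.synthetic)
        topo = traj.topology
        for r in range(config.synthetic.n_replicas):
            yield r, topo, traj.replica(r)
        return
    topo = load_topology(config.topology, config.ligand_sidecar)
    for r, path in enumerate(config.trajectories):
        yield r, topo, load_trajectory(topo, path, stride_ns=config.stride_ns)


def run_pipeline(config: PipelineConfig, outdir: str | Path,
                 seed: int | None = None) -> dict:
    """Execute the full analysis and write the report bundle.

    Returns the manifest (also written as ``manifest.json``). ``seed``
    overrides the synthetic generator seed when a synthetic source is used.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(outdir / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s "
                                           "%(message)s"))
    log.addHandler(handler)
    if not any(isinstance(h, logging.StreamHandler)
               and h.stream is sys.stderr for h in log.handlers):
        log.addHandler(logging.StreamHandler(sys.stderr))
    log.setLevel(logging.INFO)

    if seed is not None and config.synthetic is not None:
        config = dataclasses.replace(
            config, synthetic=dataclasses.replace(config.synthetic,
                                                  seed=seed))

    all_events = []
    occ_traces = []
    state_traces = []
    kept_frames: list[Frame] = []
    kept_ids: list[tuple[int, int]] = []
    frames_per_replica: dict[int, int] = {}
    failures: dict[int, str] = {}
    topo = None
    n_sources = (config.synthetic.n_replicas if config.synthetic is not None
                 else len(config.trajectories))
    keep_per_replica = max(2, config.cluster_max_frames
                           // max(n_sources, 1))

    site = None
    for r, topo, frames in _replica_sources(config):
        try:
            if site is None:
                anchors = tuple(sidechain_anchor(topo, num)
                                for num in config.water_site_residues)
                site = WaterSite(anchor_selections=anchors,
                                 radius=config.water_site_radius)
            frames = list(frames)
            if config.synthetic is not None and config.stride_ns > \
                    config.synthetic.frame_spacing_ns:
                step = int(round(config.stride_ns
                                 / config.synthetic.frame_spacing_ns))
                frames = frames[::step]
            n = len(frames)
            events = []
            for k, fr in enumerate(frames):
                events.extend(detect_all(fr, topo, config.criteria,
                                         frame_index=k, replica=r))
            occ = occupancy_trace(iter(frames), topo, site, replica_id=r)
            st = classify_states(
                flip_descriptors(iter(frames), topo,
                                 config.state_donor_residue,
                                 config.state_reference_residue,
                                 replica_id=r),
                config.state_boundary)
            keep = subsample_by_time(n, keep_per_replica)
            all_events.extend(events)
            occ_traces.append(occ)
            state_traces.append(st)
            frames_per_replica[r] = n
            for k in keep:
                kept_frames.append(frames[int(k)])
                kept_ids.append((r, int(k)))
            log.info("replica %d: %d frames, %d events", r, n, len(events))
        except (BindmodeError, OSError) as exc:
            failures[r] = f"{type(exc).__name__}: {exc}"
            log.error("replica %d failed: %s", r, exc)

    if not frames_per_replica:
        raise BindmodeError("every replica failed; nothing to report")

    frames_analyzed = sum(frames_per_replica.values())
    fractions = aggregate_fractions(all_events, frames_analyzed)
    fractions.to_csv(outdir / "fractions.csv")
    events_to_jsonl(all_events, outdir / "events.jsonl")

    occupancy_to_csv(occ_traces, outdir / "occupancy.csv")
    summary = occupancy_summary(occ_traces)
    (outdir / "occupancy_summary.json").write_text(
        json.dumps(summary, indent=1, sort_keys=True))

    states_to_csv(state_traces, outdir / "states.csv")
    cond = {}
    for occ, st in zip(occ_traces, state_traces):
        for lab, frac in conditional_occupancy(occ, st.labels).items():
            cond.setdefault(lab, []).append(frac)
    # pooled conditionals computed over all replicas at once
    pooled_labels = np.concatenate([st.labels for st in state_traces])
    pooled_occ = np.concatenate([occ.occupied for occ in occ_traces])
    pooled = {lab: float(np.mean(pooled_occ[pooled_labels == lab]))
              for lab in sorted(set(pooled_labels))}
    (outdir / "conditional_occupancy.json").write_text(
        json.dumps({"pooled": pooled,
                    "per_replica": {k: v for k, v in cond.items()}},
                   indent=1, sort_keys=True))

    # clustering on the merged, evenly subsampled frame set
    key_residues = (list(config.key_residues) if config.key_residues
                    else [num for num, _, _ in fractions.key_residues()])
    rep_info: dict = {"selected_frame": None}
    if len(kept_frames) >= 2:
        fit_sel = select(topo, "backbone")
        if key_residues:
            res_expr = " ".join(str(k) for k in key_residues)
            measure = select(topo, f"ligand or residue {res_expr}")
        else:
            log.warning("no key residues above threshold; measuring over "
                        "the ligand only")
            measure = select(topo, "ligand")
        measure = _strip_hydrogens(topo, measure)
        sim = pairwise_rmsd_matrix(kept_frames, fit_sel, measure,
                                   max_frames=config.cluster_max_frames)
        clusters = affinity_propagation(sim,
                                        preference=config.cluster_preference,
                                        damping=config.cluster_damping)
        clusters.to_json(outdir / "clusters.json")
        id_map = {rk: g for g, rk in enumerate(kept_ids)}
        global_events = []
        for ev in all_events:
            g = id_map.get((ev.replica, ev.frame_index))
            if g is not None:
                global_events.append(dataclasses.replace(
                    ev, replica=0, frame_index=g))
        if key_residues:
            rep_frame = select_representative(clusters, global_events,
                                              key_residues)
            rep_info = {"selected_frame": int(rep_frame),
                        "replica_frame": kept_ids[int(rep_frame)],
                        "key_residues": key_residues}
            write_frames_pdb(topo, [kept_frames[int(rep_frame)]],
                             outdir / "representative.pdb")
    else:
        (outdir / "clusters.json").write_text(json.dumps(
            {"labels": [], "note": "too few frames to cluster"}))

    manifest = {
        "version": __version__,
        "config_hash": _config_hash(config),
        "config": config.to_jsonable(),
        "seed": (config.synthetic.seed if config.synthetic is not None
                 else seed),
        "frames_per_replica": frames_per_replica,
        "frames_analyzed": frames_analyzed,
        "failures": failures,
        "representative": rep_info,
        "reports": list(REPORT_FILES),
    }
    (outdir / "manifest.json").write_text(
        json.dumps(manifest, indent=1, sort_keys=True, default=str))
    log.removeHandler(handler)
    handler.close()
    return manifest


def _strip_hydrogens(topo, sel: Selection) -> Selection:
    idx = [i for i in sel.indices if topo.elements[i] != "H"]
    return Selection(indices=tuple(idx),
                     provenance=sel.provenance + " (heavy atoms)")
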