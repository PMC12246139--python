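"""Side-chain flip-state descriptors, two-state classification and masked
density grids.

The canonical use is the threonine-58 side chain of the KRAS switch-II
pocket: its orientation relative to the glycine-10 amide is summarised by
the distance from the side-chain oxygen (OG1) to the Gly10 amide hydrogen
and the interior angle OG1-CB-H. The "native" orientation points the
hydroxyl toward the amide (short distance); the "flipped" orientation
carries it away. The partition boundary is configuration, not a constant.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .errors import AnnotationError, ConfigError, StatisticsError
from .geometry import angle, pbc_displacement
from .structure_io import Frame, Topology

NATIVE = "native"
FLIPPED = "flipped"


@dataclass
class StateTrace:
    """Per-frame (distance, angle) descriptors and optional state labels."""

    times: np.ndarray
    distances: np.ndarray     # Å
    angles: np.ndarray        # deg in [0, 180]
    labels: np.ndarray | None = None
    replica_id: int = 0

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.distances = np.asarray(self.distances, dtype=float)
        self.angles = np.asarray(self.angles, dtype=float)
        n = len(self.times)
        if not (len(self.distances) == len(self.angles) == n):
            raise StatisticsError("state trace arrays differ in length")
        if np.any(self.distances < 0):
            raise StatisticsError("negative descriptor distance")
        if np.any((self.angles < 0) | (self.angles > 180)):
            raise StatisticsError("descriptor angle outside [0, 180]")
        if self.labels is not None:
            self.labels = np.asarray(self.labels, dtype=object)
            if len(self.labels) != n:
                raise StatisticsError("labels differ in length")

    def label_fractions(self) -> dict[str, float]:
        if self.labels is None:
            raise StatisticsError("trace is unlabelled")
        return {str(lab): float(np.mean(self.labels == lab))
                for lab in sorted(set(self.labels))}


@dataclass(frozen=True)
class StateBoundary:
    """Closed native region: distance <= distance_max and angle in window."""

    distance_max: float = 4.0
    angle_window: tuple[float, float] = (60.0, 180.0)

    def __post_init__(self):
        if self.distance_max <= 0:
            raise ConfigError("distance_max must be positive")
        lo, hi = self.angle_window
        if not (0 <= lo < hi <= 180):
            raise ConfigError("angle window must satisfy 0 <= lo < hi <= 180")


def flip_descriptors(traj: Iterable[Frame], topology: Topology,
                     donor_residue: int = 58, reference_residue: int = 10,
                     replica_id: int = 0) -> StateTrace:
    """Per-frame (|OG1 - H|, angle OG1-CB-H) descriptors of the flip.

    ``donor_residue`` must carry OG1 and CB; ``reference_residue`` must carry
    a backbone amide hydrogen named H.
    """
    og1 = topology.atom_index(donor_residue, "OG1")
    cb = topology.atom_index(donor_residue, "CB")
    try:
        amide_h = topology.atom_index(reference_residue, "H")
    except AnnotationError:
        raise AnnotationError(
            f"residue {reference_residue} lacks a backbone amide hydrogen "
            "named H")
    times, dists, angs = [], [], []
    for fr in traj:
        xyz = fr.coordinates
        d = float(np.linalg.norm(
            pbc_displacement(xyz[og1], xyz[amide_h], fr.box)))
        a = angle(xyz[og1], xyz[cb], xyz[amide_h])
        times.append(fr.time_ns)
        dists.append(d)
        angs.append(a)
    return StateTrace(times=np.array(times), distances=np.array(dists),
                      angles=np.array(angs), replica_id=replica_id)


def classify_states(trace: StateTrace,
                    boundary: StateBoundary = StateBoundary()) -> StateTrace:
    """Label each frame native or flipped; the boundary itself is native."""
    lo, hi = boundary.angle_window
    native = ((trace.distances <= boundary.distance_max)
              & (trace.angles >= lo) & (trace.angles <= hi))
    labels = np.where(native, NATIVE, FLIPPED).astype(object)
    return StateTrace(times=trace.times, distances=trace.distances,
                      angles=trace.angles, labels=labels,
                      replica_id=trace.replica_id)


@dataclass
class DensityGrid:
    """Masked 2-D histogram of (distance, angle) normalized to fractions.

    Normalization is by the total frame count, so masked mass is retained:
    masked + unmasked fractions sum to 1. Frames falling in masked cells are
    echoed back as raw points (the scatter overlay convention).
    """

    distance_edges: np.ndarray
    angle_edges: np.ndarray
    fractions: np.ndarray          # (n_dist_bins, n_angle_bins)
    mask: np.ndarray               # True where fraction < threshold
    mask_threshold: float
    masked_points: np.ndarray      # (m, 2) raw (distance, angle) pairs

    def to_json(self, path) -> None:
        import json
        with open(path, "w") as fh:
            json.dump({
                "distance_edges": self.distance_edges.tolist(),
                "angle_edges": self.angle_edges.tolist(),
                "fractions": self.fractions.tolist(),
                "mask": self.mask.tolist(),
                "mask_threshold": self.mask_threshold,
                "masked_points": self.masked_points.tolist(),
            }, fh, indent=1)


def density_grid(traces: Sequence[StateTrace] | StateTrace,
                 distance_bins: np.ndarray,
                 angle_bins: np.ndarray,
                 mask_threshold: float = 0.05) -> DensityGrid:
    """2-D density of flip descriptors with sparse cells masked out."""
    if isinstance(traces, StateTrace):
        traces = [traces]
    distance_bins = np.asarray(distance_bins, dtype=float)
    angle_bins = np.asarray(angle_bins, dtype=float)
    for edges, name in ((distance_bins, "distance"), (angle_bins, "angle")):
        if len(edges) < 2 or np.any(np.diff(edges) <= 0):
            raise ConfigError(f"{name} bin edges must be strictly increasing")
    d = np.concatenate([t.distances for t in traces])
    a = np.concatenate([t.angles for t in traces])
    if len(d) == 0:
        raise StatisticsError("no frames to histogram")
    counts, _, _ = np.histogram2d(d, a, bins=(distance_bins, angle_bins))
    fractions = counts / len(d)
    mask = fractions < mask_threshold
    di = np.clip(np.searchsorted(distance_bins, d, side="right") - 1,
                 0, len(distance_bins) - 2)
    ai = np.clip(np.searchsorted(angle_bins, a, side="right") - 1,
                 0, len(angle_bins) - 2)
    in_range = ((d >= distance_bins[0]) & (d <= distance_bins[-1])
                & (a >= angle_bins[0]) & (a <= angle_bins[-1]))
    pts = np.column_stack([d, a])[in_range & mask[di, ai]]
    return DensityGrid(distance_edges=distance_bins, angle_edges=angle_bins,
                       fractions=fractions, mask=mask,
                       mask_threshold=mask_threshold, masked_points=pts)


def traces_to_csv(traces: Sequence[StateTrace], path) -> None:
    import pandas as pd
    rows = []
    for tr in traces:
        labels = tr.labels if tr.labels is not None else [""] * len(tr.times)
        for t, d, a, lab in zip(tr.times, tr.distances, tr.angles, labels):
            rows.append({"replica": tr.replica_id, "time_ns": t,
                         "distance": d, "angle": a, "state": lab})
    pd.DataFrame(rows, columns=["replica", "time_ns", "distance", "angle",
                                "state"]).to_csv(path, index=False,
                                                 float_format="%.4f")
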