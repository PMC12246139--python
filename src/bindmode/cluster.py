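"""Representative binding-mode selection: pairwise key-residue RMSD matrix,
affinity-propagation clustering, and exemplar choice.

The similarity between two frames is the negative squared RMSD over a
measured atom set (key residues plus ligand heavy atoms) after superposing
on the protein backbone. Affinity propagation is implemented directly (the
responsibility/availability messages of Frey & Dueck) so the result is fully
deterministic: no noise is injected and ties resolve toward the lower frame
index.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .errors import ConfigError, SelectionError
from .fingerprints import InteractionEvent
from .geometry import rmsd_between, superpose
from .structure_io import Frame, Selection


@dataclass
class SimilarityMatrix:
    """Symmetric n x n frame similarities (negative squared RMSD, Å²)."""

    matrix: np.ndarray
    frame_indices: np.ndarray      # original (global) frame ids per row
    fit_provenance: str = ""
    measure_provenance: str = ""


@dataclass
class ClusterResult:
    """Affinity-propagation output on a SimilarityMatrix."""

    labels: np.ndarray             # per clustered frame, cluster id 0..k-1
    exemplars: np.ndarray          # per cluster, row index into the matrix
    exemplar_frames: np.ndarray    # per cluster, original frame id
    populations: np.ndarray        # per cluster, member count
    frame_indices: np.ndarray      # original frame ids per row
    iterations: int = 0
    converged: bool = True

    def __post_init__(self):
        for k, ex in enumerate(self.exemplars):
            if self.labels[ex] != k:
                raise ConfigError("exemplar does not belong to its cluster")
        if self.populations.sum() != len(self.labels):
            raise ConfigError("cluster populations do not partition frames")

    def to_json(self, path) -> None:
        import json
        with open(path, "w") as fh:
            json.dump({
                "labels": self.labels.tolist(),
                "exemplars": self.exemplars.tolist(),
                "exemplar_frames": self.exemplar_frames.tolist(),
                "populations": self.populations.tolist(),
                "frame_indices": self.frame_indices.tolist(),
                "iterations": self.iterations,
                "converged": self.converged,
            }, fh, indent=1)


def subsample_by_time(n: int, max_frames: int) -> np.ndarray:
    """Evenly spaced frame indices when a trajectory exceeds the cap."""
    if n <= max_frames:
        return np.arange(n)
    return np.unique(np.linspace(0, n - 1, max_frames).round().astype(int))


def pairwise_rmsd_matrix(frames: Sequence[Frame], fit_sel: Selection,
                         measure_sel: Selection,
                         max_frames: int = 2000,
                         frame_indices: Sequence[int] | None = None,
                         ) -> SimilarityMatrix:
    """Similarity S(i,j) = -RMSD(i,j)^2 over measure_sel after backbone fit.

    Frame j is superposed on frame i over fit_sel, the measured set follows
    without re-fitting, and the two directions are averaged so S is exactly
    symmetric.
    """
    if len(fit_sel) == 0 or len(measure_sel) == 0:
        raise SelectionError("fit and measure selections must be non-empty")
    frames = list(frames)
    if len(frames) < 2:
        raise ConfigError("pairwise RMSD needs at least 2 frames")
    if frame_indices is None:
        frame_indices = np.arange(len(frames))
    frame_indices = np.asarray(frame_indices, dtype=int)
    keep = subsample_by_time(len(frames), max_frames)
    frames = [frames[k] for k in keep]
    frame_indices = frame_indices[keep]

    fit_idx = fit_sel.as_array()
    meas_idx = measure_sel.as_array()
    n = len(frames)
    fit = np.array([fr.coordinates[fit_idx] for fr in frames])
    meas = np.array([fr.coordinates[meas_idx] for fr in frames])
    fit_c = fit - fit.mean(axis=1, keepdims=True)
    fit_means = fit.mean(axis=1)
    meas_rel = meas - fit_means[:, None, :]

    s = np.zeros((n, n))
    for i in range(n):
        # batched Kabsch of every frame onto frame i
        h = np.einsum("njk,jl->nkl", fit_c, fit_c[i])
        u, _, vt = np.linalg.svd(h)
        det = np.linalg.det(np.einsum("nij,njk->nik",
                                      vt.transpose(0, 2, 1),
                                      u.transpose(0, 2, 1)))
        d = np.repeat(np.eye(3)[None], n, axis=0)
        d[:, 2, 2] = np.sign(det)
        rot = np.einsum("nij,njk,nkl->nil", vt.transpose(0, 2, 1), d,
                        u.transpose(0, 2, 1))
        moved = np.einsum("nak,njk->naj", meas_rel, rot) + fit_means[i]
        diff = moved - meas[i]
        s[i] = -np.mean(np.sum(diff * diff, axis=2), axis=1)
    s = 0.5 * (s + s.T)
    return SimilarityMatrix(matrix=s, frame_indices=frame_indices,
                            fit_provenance=fit_sel.provenance,
                            measure_provenance=measure_sel.provenance)


def affinity_propagation(sim: SimilarityMatrix | np.ndarray,
                         preference: float | None = None,
                         damping: float = 0.5,
                         max_iter: int = 1000,
                         convergence_window: int = 50,
                         escalate_damping: bool = True) -> ClusterResult:
    """Deterministic affinity propagation on a precomputed similarity matrix.

    ``preference`` defaults to the median off-diagonal similarity. Exemplars
    are the points whose self responsibility + availability is positive at
    convergence. Message oscillation (common when many frames are nearly
    identical) is handled the way the method's authors prescribe: on
    non-convergence the damping is escalated (0.7, then 0.9) and the run
    repeated — still fully deterministic. If every attempt fails a result is
    returned with ``converged=False`` and a warning.
    """
    dampings = [damping]
    if escalate_damping:
        dampings += [d for d in (0.7, 0.9) if d > damping]
    result = None
    for d in dampings:
        result = _affinity_propagation_once(sim, preference, d, max_iter,
                                            convergence_window)
        if result.converged:
            return result
    warnings.warn("affinity propagation did not converge within "
                  f"{max_iter} iterations at damping "
                  f"{', '.join(str(d) for d in dampings)}", RuntimeWarning)
    return result


def _affinity_propagation_once(sim, preference, damping, max_iter,
                               convergence_window) -> ClusterResult:
    if isinstance(sim, SimilarityMatrix):
        s = np.array(sim.matrix, dtype=float)
        frame_indices = sim.frame_indices
    else:
        s = np.array(sim, dtype=float)
        frame_indices = np.arange(len(s))
    if not np.all(np.isfinite(s)):
        raise ConfigError("similarity matrix contains non-finite entries")
    if not 0.5 <= damping < 1.0:
        raise ConfigError("damping must lie in [0.5, 1)")
    n = len(s)
    off = s[~np.eye(n, dtype=bool)]
    if preference is None:
        preference = float(np.median(off)) if len(off) else 0.0
    np.fill_diagonal(s, preference)
    # exactly degenerate similarities make the messages oscillate; break the
    # symmetry with a deterministic, index-derived micro-jitter (~1e-9 of the
    # similarity range) instead of random noise, keeping runs reproducible
    span = float(s.max() - s.min()) or 1.0
    idx_pattern = ((np.arange(n)[:, None] * 2654435761
                    + np.arange(n)[None, :] * 40503) % 9973) / 9973.0
    s = s + 1e-9 * span * idx_pattern

    r = np.zeros((n, n))
    a = np.zeros((n, n))
    idx = np.arange(n)
    stable = 0
    last_exemplars: np.ndarray | None = None
    it = 0
    for it in range(1, max_iter + 1):
        # responsibilities
        asum = a + s
        first = np.argmax(asum, axis=1)
        fmax = asum[idx, first]
        asum[idx, first] = -np.inf
        smax = np.max(asum, axis=1)
        rnew = s - fmax[:, None]
        rnew[idx, first] = s[idx, first] - smax
        r = damping * r + (1 - damping) * rnew
        # availabilities
        rp = np.maximum(r, 0)
        np.fill_diagonal(rp, r.diagonal())
        colsums = rp.sum(axis=0)
        anew = np.minimum(0, colsums[None, :] - rp)
        np.fill_diagonal(anew, colsums - r.diagonal())
        a = damping * a + (1 - damping) * anew
        exemplars = np.flatnonzero((r.diagonal() + a.diagonal()) > 0)
        if last_exemplars is not None and np.array_equal(exemplars,
                                                         last_exemplars):
            stable += 1
            if stable >= convergence_window and len(exemplars) > 0:
                break
        else:
            stable = 0
        last_exemplars = exemplars
    converged = stable >= convergence_window and len(exemplars) > 0
    if len(exemplars) == 0:
        exemplars = np.array([int(np.argmax(r.diagonal() + a.diagonal()))])

    # assign members to the most similar exemplar (argmax -> lowest index
    # on ties), then refine each cluster's exemplar once
    labels = np.argmax(s[:, exemplars], axis=1)
    labels[exemplars] = np.arange(len(exemplars))
    refined = []
    for k in range(len(exemplars)):
        members = np.flatnonzero(labels == k)
        within = s[np.ix_(members, members)].sum(axis=0)
        refined.append(int(members[np.argmax(within)]))
    refined = np.array(sorted(set(refined)))
    labels = np.argmax(s[:, refined], axis=1)
    labels[refined] = np.arange(len(refined))
    populations = np.bincount(labels, minlength=len(refined))
    return ClusterResult(labels=labels, exemplars=refined,
                         exemplar_frames=frame_indices[refined],
                         populations=populations,
                         frame_indices=frame_indices,
                         iterations=it, converged=converged)


def select_representative(clusters: ClusterResult,
                          events: Iterable[InteractionEvent],
                          key_residues: Sequence[int | tuple],
                          ) -> int:
    """Exemplar of the most populated cluster showing every key interaction.

    Clusters are visited in order of decreasing population (lower exemplar
    frame id first on ties); the first one whose exemplar frame has at least
    one event with every key residue wins. If none qualifies the largest
    cluster's exemplar is returned with a warning.
    """
    key = list(key_residues)
    if not key:
        raise ConfigError("key residue list must not be empty")
    key_numbers = {k[0] if isinstance(k, tuple) else int(k) for k in key}

    frame_residues: dict[tuple[int, int], set[int]] = {}
    for ev in events:
        frame_residues.setdefault((ev.replica, ev.frame_index),
                                  set()).add(ev.residue[0])
    # clustered frames are identified by global frame id; events from a
    # merged trajectory carry replica 0 with global frame indices
    by_frame: dict[int, set[int]] = {}
    for (rep, fi), residues in frame_residues.items():
        by_frame.setdefault(fi, set()).update(residues)

    order = sorted(range(len(clusters.populations)),
                   key=lambda k: (-clusters.populations[k],
                                  clusters.exemplar_frames[k]))
    for k in order:
        frame_id = int(clusters.exemplar_frames[k])
        if key_numbers <= by_frame.get(frame_id, set()):
            return frame_id
    warnings.warn("no cluster exemplar exhibits all key interactions; "
                  "falling back to the most populated cluster",
                  RuntimeWarning)
    return int(clusters.exemplar_frames[order[0]])
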