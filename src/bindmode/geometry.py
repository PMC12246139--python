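"""Geometric primitives: minimum-image distances, angles, Kabsch
superposition, RMSD/RMSF traces and minimum-distance monitoring.

Conventions: coordinates and distances in Å, angles in degrees, times in ns.
Minimum image is implemented for triclinic boxes by fractional-coordinate
rounding refined over the 27 neighbouring images, which is exact for any
reasonably reduced box.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .errors import GeometryError, SelectionError, StatisticsError
from .structure_io import Frame, Selection

_SHIFTS = np.array(
    [(i, j, k) for i in (-1, 0, 1) for j in (-1, 0, 1) for k in (-1, 0, 1)],
    dtype=float)  # (27, 3)


@dataclass
class SuperpositionResult:
    """Optimal rigid-body superposition: x_fit = x_mobile @ rotation.T + translation."""

    rotation: np.ndarray     # (3, 3), det = +1
    translation: np.ndarray  # (3,)
    rmsd: float              # Å, over the fitted points

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation


@dataclass
class TraceSeries:
    """A per-frame scalar series (RMSD, minimum distance, ...)."""

    times: np.ndarray
    values: np.ndarray
    label: str = ""
    unit: str = "angstrom"

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if len(self.times) != len(self.values):
            raise StatisticsError("times and values differ in length")
        if len(self.times) > 1 and np.any(np.diff(self.times) < 0):
            raise StatisticsError("times must be non-decreasing")

    def to_csv(self, path) -> None:
        import pandas as pd
        pd.DataFrame({"time_ns": self.times, "value": self.values}).to_csv(
            path, index=False)


# ---------------------------------------------------------------------------
# distances and angles
# ---------------------------------------------------------------------------

def _check_box(box: np.ndarray) -> np.ndarray:
    box = np.asarray(box, dtype=float)
    if box.shape != (3, 3) or abs(np.linalg.det(box)) < 1e-9:
        raise GeometryError("degenerate periodic box")
    return box


def pbc_displacement(a: np.ndarray, b: np.ndarray,
                     box: np.ndarray | None) -> np.ndarray:
    """Minimum-image displacement(s) b - a; broadcasts over leading axes."""
    d = np.asarray(b, dtype=float) - np.asarray(a, dtype=float)
    if box is None:
        return d
    box = _check_box(box)
    inv = np.linalg.inv(box)
    frac = d @ inv
    frac -= np.round(frac)
    base = frac @ box
    # refine over the 27 neighbouring images (exact for reduced boxes)
    cand = base[..., None, :] + _SHIFTS @ box  # (..., 27, 3)
    norms = np.einsum("...ij,...ij->...i", cand, cand)
    pick = np.argmin(norms, axis=-1)
    return np.take_along_axis(cand, pick[..., None, None],
                              axis=-2).squeeze(-2)


def pbc_distance(a, b, box: np.ndarray | None = None) -> float | np.ndarray:
    """Minimum-image distance between points (Euclidean when box is None)."""
    d = pbc_displacement(a, b, box)
    return np.sqrt(np.einsum("...i,...i->...", d, d))


def angle(a, b, c) -> float:
    """Interior angle at vertex b, in degrees within [0, 180]."""
    u = np.asarray(a, float) - np.asarray(b, float)
    v = np.asarray(c, float) - np.asarray(b, float)
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu < 1e-12 or nv < 1e-12:
        raise GeometryError("zero-length arm in angle computation")
    cosang = np.clip(np.dot(u, v) / (nu * nv), -1.0, 1.0)
    return float(np.degrees(np.arccos(cosang)))


def angles_batch(a: np.ndarray, b: np.ndarray, c: np.ndarray) -> np.ndarray:
    """Vectorized interior angles at b for stacked point triples."""
    u = a - b
    v = c - b
    nu = np.linalg.norm(u, axis=-1)
    nv = np.linalg.norm(v, axis=-1)
    cosang = np.einsum("...i,...i->...", u, v) / np.maximum(nu * nv, 1e-300)
    return np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))


# ---------------------------------------------------------------------------
# superposition
# ---------------------------------------------------------------------------

def superpose(mobile: np.ndarray, reference: np.ndarray) -> SuperpositionResult:
    """Least-squares rigid superposition of mobile onto reference (Kabsch).

    Reflections are excluded; requires >= 3 non-degenerate points.
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if mobile.shape != reference.shape or mobile.ndim != 2:
        raise GeometryError("point sets must have identical (n, 3) shapes")
    n = mobile.shape[0]
    if n < 3:
        raise GeometryError("superposition requires at least 3 points")
    mc = mobile.mean(axis=0)
    rc = reference.mean(axis=0)
    h = (mobile - mc).T @ (reference - rc)
    u, s, vt = np.linalg.svd(h)
    sign = np.sign(np.linalg.det(vt.T @ u.T))
    d = np.diag([1.0, 1.0, sign])
    rot = vt.T @ d @ u.T
    trans = rc - rot @ mc
    fitted = mobile @ rot.T + trans
    rmsd = float(np.sqrt(np.mean(np.sum((fitted - reference) ** 2, axis=1))))
    return SuperpositionResult(rotation=rot, translation=trans, rmsd=rmsd)


def rmsd_between(a: np.ndarray, b: np.ndarray) -> float:
    """Plain coordinate RMSD without fitting."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    return float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1))))


# ---------------------------------------------------------------------------
# trajectory statistics
# ---------------------------------------------------------------------------

def _sel_array(sel: Selection, what: str) -> np.ndarray:
    if len(sel) == 0:
        raise SelectionError(f"empty {what} selection")
    return sel.as_array()


def rmsd_trace(traj: Iterable[Frame], fit_sel: Selection,
               measure_sel: Selection, reference: Frame,
               refit_measure: bool = False,
               label: str = "rmsd") -> TraceSeries:
    """Per-frame RMSD over measure_sel after superposing each frame on the
    reference over fit_sel.

    With ``refit_measure=False`` (default) the measured set is *not* re-fit:
    this is the ligand-RMSD-after-protein-fit convention. With
    ``refit_measure=True`` the measured set is superposed directly.
    """
    fit_idx = _sel_array(fit_sel, "fit")
    meas_idx = _sel_array(measure_sel, "measure")
    ref_fit = reference.coordinates[fit_idx]
    ref_meas = reference.coordinates[meas_idx]
    times, values = [], []
    for fr in traj:
        if refit_measure:
            sup = superpose(fr.coordinates[meas_idx], ref_meas)
            val = sup.rmsd
        else:
            sup = superpose(fr.coordinates[fit_idx], ref_fit)
            moved = sup.apply(fr.coordinates[meas_idx])
            val = rmsd_between(moved, ref_meas)
        times.append(fr.time_ns)
        values.append(val)
    return TraceSeries(times=np.array(times), values=np.array(values),
                       label=label)


def rmsf(traj: Sequence[Frame], fit_sel: Selection,
         measure_sel: Selection,
         reference: str = "mean") -> np.ndarray:
    """Per-atom root-mean-square fluctuation over measure_sel.

    Frames are first fit on fit_sel to the first frame, averaged, then re-fit
    to the average structure (two-pass iterated-mean reference). With
    ``reference='first'`` the second pass is skipped and fluctuations are
    measured about the mean of first-frame-fitted coordinates.
    """
    traj = list(traj)
    if len(traj) < 2:
        raise StatisticsError("RMSF requires at least 2 frames")
    fit_idx = _sel_array(fit_sel, "fit")
    meas_idx = _sel_array(measure_sel, "measure")

    def fitted_coords(ref_fit_coords):
        out = np.empty((len(traj), len(meas_idx), 3))
        fits = np.empty((len(traj), len(fit_idx), 3))
        for k, fr in enumerate(traj):
            sup = superpose(fr.coordinates[fit_idx], ref_fit_coords)
            out[k] = sup.apply(fr.coordinates[meas_idx])
            fits[k] = sup.apply(fr.coordinates[fit_idx])
        return out, fits

    ref_fit = traj[0].coordinates[fit_idx]
    meas1, fits1 = fitted_coords(ref_fit)
    if reference == "mean":
        meas1, _ = fitted_coords(fits1.mean(axis=0))
    mean_pos = meas1.mean(axis=0)
    dev = meas1 - mean_pos
    return np.sqrt(np.mean(np.sum(dev ** 2, axis=2), axis=0))


def min_distance_trace(traj: Iterable[Frame], sel_a: Selection,
                       sel_b: Selection,
                       label: str = "min_distance") -> TraceSeries:
    """Per-frame minimum (PBC-aware) distance between two selections."""
    ia = _sel_array(sel_a, "first")
    ib = _sel_array(sel_b, "second")
    times, values = [], []
    for fr in traj:
        pa = fr.coordinates[ia]
        pb = fr.coordinates[ib]
        d = pbc_distance(pa[:, None, :], pb[None, :, :], fr.box)
        times.append(fr.time_ns)
        values.append(float(np.min(d)))
    return TraceSeries(times=np.array(times), values=np.array(values),
                       label=label)
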