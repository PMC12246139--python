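"""Synthetic protein-ligand-solvent trajectories with planted ground truth.

The generator emulates the statistical structure of a multi-replica
binding-mode study of a KRAS-like switch-II pocket: a mini receptor with the
pocket's named residues (Gly10, Cys12, Lys16, Thr58, Glu62, Glu63, Tyr64,
Asp69, His95, Tyr96), a ligand carrying donors, acceptors, an aromatic
ring, charged amines and apolar carbons, a conserved-water site anchored
between Thr58 and Gly10, and explicit waters exchanging through it.

It is a statistical emulator, not molecular dynamics: every planted contact
is switched on (geometry placed deep inside its criterion) or off (parked
far outside) by per-frame schedules, the site water follows a two-state
Markov chain with fresh water identities on re-entry, and the Thr58 side
chain follows a native/flipped schedule. Gaussian positional noise is
truncated at four standard deviations so planted geometries can never cross
a detection boundary; a generation-time check runs the real detectors on
noise-free template frames and asserts the planted event set exactly.
Contact probabilities therefore translate into *exactly* recoverable
per-frame ground truth, recorded in a ledger.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np

from .errors import ConfigError
from .fingerprints import InteractionCriteria, detect_all
from .structure_io import (
    Frame,
    Topology,
    _annotate_standard,
    _assemble_topology,
    apply_ligand_annotations,
)

# maximum noise sigma for which the +-4 sigma truncation keeps every planted
# geometry on its side of the criterion boundaries (margins >= 0.53 Å / 25 deg)
_MAX_NOISE_SIGMA = 0.05

BOX_EDGE = 80.0
_CENTER = np.array([40.0, 40.0, 40.0])
_RING_RADIUS6 = 1.39
_RING_RADIUS5 = 1.17


@dataclass(frozen=True)
class PlantedContact:
    name: str
    itype: str                 # detector event type
    residue: int               # author residue number
    fragment: tuple[str, ...]  # ligand atom names moved by the schedule


CONTACTS: tuple[PlantedContact, ...] = (
    PlantedContact("hbond_asp69", "hbond", 69, ("N1", "H1A", "H1B")),
    PlantedContact("hbond_lys16", "hbond", 16, ("O1", "C9")),
    PlantedContact("hbond_glu63", "hbond", 63, ("N2", "C10")),
    PlantedContact("water_bridge_cys12", "water_bridge", 12, ("O2", "C8")),
    PlantedContact("pipi_tyr96", "pi_pi", 96,
                   ("C1", "C2", "C3", "C4", "C5", "C6")),
    PlantedContact("pication_his95", "pi_cation", 95,
                   ("N3", "H3A", "H3B", "H3C")),
    PlantedContact("ionic_glu62", "ionic", 62, ("N4",)),
    PlantedContact("hydrophobic_tyr64", "hydrophobic", 64, ("C7",)),
)

LIGAND_SIDECAR: dict = {
    "name": "LIG",
    "donors": {"N1": ["H1A", "H1B"]},
    "acceptors": ["O1", "N2", "O2"],
    "aromatic_rings": [["C1", "C2", "C3", "C4", "C5", "C6"]],
    "charged_groups": [{"atoms": ["N3"], "charge": 1},
                       {"atoms": ["N4"], "charge": 1}],
    "hydrophobic": ["C7"],
}

_LIGAND_BONDS = [
    ("N1", "H1A"), ("N1", "H1B"), ("C9", "O1"), ("N2", "C10"),
    ("O2", "C8"), ("N3", "H3A"), ("N3", "H3B"), ("N3", "H3C"),
    ("C1", "C2"), ("C2", "C3"), ("C3", "C4"), ("C4", "C5"), ("C5", "C6"),
    ("C6", "C1"),
    # linkers making the ligand one molecule
    ("C1", "C9"), ("C4", "C10"), ("C5", "C7"), ("C6", "N1"), ("C3", "C8"),
    ("N3", "C7"), ("N4", "C10"),
]


@dataclass(frozen=True)
class StateSchedule:
    """Two-state flip schedule: stationary native fraction and mean dwell.

    ``mean_dwell_frames = 1`` gives independent per-frame draws (the study
    conditions used for statistical recovery checks); larger dwells give
    persistent excursions.
    """
    fraction_native: float = 0.7
    mean_dwell_frames: float = 1.0


@dataclass(frozen=True)
class GeneratorConfig:
    n_replicas: int = 20
    n_frames: int = 1000
    frame_spacing_ns: float = 1.0
    hbond_occupancy_targets: dict = field(default_factory=lambda: {
        "hbond_asp69": 1.0, "hbond_lys16": 0.7, "hbond_glu63": 0.2})
    other_contact_targets: dict = field(default_factory=lambda: {
        "water_bridge_cys12": 0.3, "pipi_tyr96": 0.6,
        "pication_his95": 0.5, "ionic_glu62": 0.4,
        "hydrophobic_tyr64": 0.8})
    water_site_occupancy: float = 0.8
    water_exchange_rate: float = 30.0   # expected distinct waters / replica
    water_occupancy_by_state: dict | None = None  # e.g. {"native": .9, ...}
    state_schedule: StateSchedule = StateSchedule()
    geometry_noise_sigma: float = 0.03
    n_waters: int = 60
    seed: int = 0

    def __post_init__(self):
        if self.n_replicas < 1 or self.n_frames < 1:
            raise ConfigError("replica and frame counts must be >= 1")
        if self.geometry_noise_sigma < 0:
            raise ConfigError("noise sigma must be non-negative")
        if self.geometry_noise_sigma > _MAX_NOISE_SIGMA:
            raise ConfigError(
                f"noise sigma {self.geometry_noise_sigma} could cross a "
                f"criterion boundary (max {_MAX_NOISE_SIGMA})")
        for d in (self.hbond_occupancy_targets, self.other_contact_targets):
            for k, p in d.items():
                if not 0 <= p <= 1:
                    raise ConfigError(f"probability of {k} outside [0,1]")
        if not 0 <= self.water_site_occupancy <= 1:
            raise ConfigError("water_site_occupancy outside [0,1]")
        if not 0 < self.state_schedule.fraction_native < 1:
            raise ConfigError("fraction_native must lie in (0,1)")
        if self.n_waters < 2:
            raise ConfigError("need at least 2 waters")

    def contact_probability(self, name: str) -> float:
        if name in self.hbond_occupancy_targets:
            return self.hbond_occupancy_targets[name]
        return self.other_contact_targets.get(name, 0.0)


# ---------------------------------------------------------------------------
# geometry construction (all positions relative to the pocket center)
# ---------------------------------------------------------------------------

def _unit(v):
    return v / np.linalg.norm(v)


def _rotz(v, deg):
    th = np.radians(deg)
    c, s = np.cos(th), np.sin(th)
    return np.array([c * v[0] - s * v[1], s * v[0] + c * v[1], v[2]])


_Z = np.array([0.0, 0.0, 1.0])

_RESIDUE_ANGLES = {10: 0.0, 58: 30.0, 12: 67.0, 16: 104.0, 62: 141.0,
                   63: 178.0, 64: 215.0, 69: 252.0, 95: 289.0, 96: 326.0}
_RESIDUES = [(10, "GLY"), (12, "CYS"), (16, "LYS"), (58, "THR"),
             (62, "GLU"), (63, "GLU"), (64, "TYR"), (69, "ASP"),
             (95, "HIS"), (96, "TYR")]
_RADIUS = 16.0


def _build_geometry() -> dict:
    """Nominal (noise-free) positions of every atom plus plant metadata."""
    pos: dict[str, np.ndarray] = {}   # "resnum:name" or "LIG:name"

    def u_t(resnum):
        th = np.radians(_RESIDUE_ANGLES[resnum])
        u = np.array([np.cos(th), np.sin(th), 0.0])
        t = np.array([-np.sin(th), np.cos(th), 0.0])
        return u, t

    def backbone(resnum):
        u, t = u_t(resnum)
        ca = _RADIUS * u
        n = ca + 1.45 * t
        pos[f"{resnum}:N"] = n
        pos[f"{resnum}:H"] = n - 1.0 * u
        pos[f"{resnum}:CA"] = ca
        pos[f"{resnum}:C"] = ca - 1.5 * t
        pos[f"{resnum}:O"] = ca - 1.5 * t + 1.23 * u
        return u, t, ca

    def hexagon(center, u, t, radius):
        out = []
        for k in range(6):
            th = np.radians(180.0 - 60.0 * k)
            out.append(center + radius * (np.cos(th) * u + np.sin(th) * t))
        return out  # CG CD1 CE1 CZ CE2 CD2 order

    # GLY10 (anchor; no side chain)
    backbone(10)

    # CYS12 (water-bridge anchor via its backbone carbonyl)
    u, t, ca = backbone(12)
    pos["12:CB"] = ca + 1.5 * u + 0.5 * _Z
    pos["12:SG"] = ca + 3.0 * u + 0.5 * _Z

    # LYS16 (side-chain ammonium donates to the ligand carbonyl O1)
    u, t, ca = backbone(16)
    for k, name in enumerate(("CB", "CG", "CD", "CE"), start=1):
        pos[f"16:{name}"] = ca + 1.5 * k * u
    nz = ca + 7.5 * u
    pos["16:NZ"] = nz
    pos["16:HZ1"] = nz + 1.0 * u
    d2 = -0.334 * u + 0.943 * _Z
    d3 = -0.334 * u - 0.943 * _Z
    pos["16:HZ2"] = nz + d2
    pos["16:HZ3"] = nz + d3
    pos["LIG:O1"] = nz + 2.9 * u          # H...O = 1.9 Å, linear
    pos["LIG:C9"] = nz + 4.13 * u

    # THR58 (flip states relative to the Gly10 amide hydrogen)
    u, t, ca = backbone(58)
    h10 = pos["10:H"]
    m = _unit(ca - h10)
    cb = h10 + 3.1 * m
    pos["58:CB"] = cb
    pos["58:CG2"] = cb + 1.5 * t
    og1_native = cb + 1.43 * _Z
    og1_flipped = cb + 1.8 * m
    pos["58:OG1"] = og1_native
    pos["58:HG1"] = og1_native + 0.96 * _Z
    state_positions = {
        "native": {"58:OG1": og1_native, "58:HG1": og1_native + 0.96 * _Z},
        "flipped": {"58:OG1": og1_flipped, "58:HG1": og1_flipped + 0.96 * m},
    }

    # GLU62 (side-chain carboxylate paired ionically with ligand N4)
    u, t, ca = backbone(62)
    pos["62:CB"] = ca + 1.5 * u
    pos["62:CG"] = ca + 3.0 * u
    cd = ca + 4.5 * u
    pos["62:CD"] = cd
    r1, r2 = _rotz(u, 55), _rotz(u, -55)
    oe1 = cd + 1.25 * r1
    pos["62:OE1"] = oe1
    pos["62:OE2"] = cd + 1.25 * r2
    pos["LIG:N4"] = oe1 + 3.0 * r1

    # GLU63 (backbone amide donates to the ligand pyridine-like N2)
    u, t, ca = backbone(63)
    pos["63:CB"] = ca + 1.5 * u
    pos["63:CG"] = ca + 3.0 * u
    cd = ca + 4.5 * u
    pos["63:CD"] = cd
    pos["63:OE1"] = cd + 1.25 * _rotz(u, 55)
    pos["63:OE2"] = cd + 1.25 * _rotz(u, -55)
    h63 = pos["63:H"]
    pos["LIG:N2"] = h63 - 1.9 * u
    pos["LIG:C10"] = h63 - 3.3 * u

    # TYR64 (apolar contact to ligand C7)
    u, t, ca = backbone(64)
    cb = ca + 1.5 * u
    pos["64:CB"] = cb
    ring = hexagon(ca + 3.5 * u, u, t, _RING_RADIUS6)
    for name, p in zip(("CG", "CD1", "CE1", "CZ", "CE2", "CD2"), ring):
        pos[f"64:{name}"] = p
    pos["64:OH"] = pos["64:CZ"] + 1.36 * u
    pos["64:HH"] = pos["64:OH"] + 0.96 * u
    pos["LIG:C7"] = cb + 3.0 * (-0.5 * u + 0.866 * _Z)

    # ASP69 (side-chain carboxylate accepts the ligand amine N1)
    u, t, ca = backbone(69)
    pos["69:CB"] = ca + 1.5 * u
    cg = ca + 3.0 * u
    pos["69:CG"] = cg
    a1, a2 = _rotz(u, 50), _rotz(u, -50)
    od1 = cg + 1.25 * a1
    pos["69:OD1"] = od1
    pos["69:OD2"] = cg + 1.25 * a2
    pos["LIG:H1A"] = od1 + 1.9 * a1
    n1 = od1 + 2.86 * a1
    pos["LIG:N1"] = n1
    pos["LIG:H1B"] = n1 + (-0.334 * a1 + 0.943 * _Z)

    # HIS95 (imidazole ring under the ligand charged amine N3)
    u, t, ca = backbone(95)
    pos["95:CB"] = ca + 1.5 * u
    q = ca + 3.2 * u
    for name, deg in zip(("CG", "ND1", "CE1", "NE2", "CD2"),
                         (180.0, 108.0, 36.0, -36.0, -108.0)):
        th = np.radians(deg)
        pos[f"95:{name}"] = q + _RING_RADIUS5 * (np.cos(th) * u
                                                 + np.sin(th) * t)
    pos["95:HE2"] = pos["95:NE2"] + 1.0 * _unit(pos["95:NE2"] - q)
    n3 = q + 3.5 * _Z
    pos["LIG:N3"] = n3
    for k, name in enumerate(("H3A", "H3B", "H3C")):
        th = np.radians(120.0 * k)
        horiz = np.cos(th) * u + np.sin(th) * t
        pos[f"LIG:{name}"] = n3 + (0.334 * _Z + 0.943 * horiz)

    # TYR96 (stacked ligand six-ring)
    u, t, ca = backbone(96)
    pos["96:CB"] = ca + 1.5 * u
    ring = hexagon(ca + 3.5 * u, u, t, _RING_RADIUS6)
    for name, p in zip(("CG", "CD1", "CE1", "CZ", "CE2", "CD2"), ring):
        pos[f"96:{name}"] = p
    pos["96:OH"] = pos["96:CZ"] + 1.36 * u
    pos["96:HH"] = pos["96:OH"] + 0.96 * u
    for k, name in enumerate(("C1", "C2", "C3", "C4", "C5", "C6")):
        th = np.radians(180.0 - 60.0 * k)
        pos[f"LIG:{name}"] = (ca + 3.5 * u + 3.8 * _Z
                              + _RING_RADIUS6 * (np.cos(th) * u
                                                 + np.sin(th) * t))

    # bridge water at the CYS12 backbone carbonyl; ligand ether O2 beyond it
    u, t = u_t(12)
    o12 = pos["12:O"]
    wo = o12 + 2.86 * u
    d2 = 0.2504 * u + 0.9681 * _Z          # 104.5 deg from the first O-H
    bridge = {"O": wo, "H1": o12 + 1.9 * u, "H2": wo + 0.96 * d2}
    pos["LIG:O2"] = wo + 2.86 * d2
    pos["LIG:C8"] = wo + 4.26 * d2

    # site-water placement: 2 Å below the per-state anchor centroid
    anchors = {
        "native": [pos["58:CB"], og1_native, pos["58:CG2"], pos["10:CA"]],
        "flipped": [pos["58:CB"], og1_flipped, pos["58:CG2"], pos["10:CA"]],
    }
    site_water = {
        state: np.mean(pts, axis=0) - 2.0 * _Z
        for state, pts in anchors.items()
    }

    # parking slots for switched-off ligand fragments (pocket axis, high z)
    slots = {}
    for k, contact in enumerate(CONTACTS):
        slots[contact.name] = np.array([2.5 * (k % 3 - 1),
                                        2.5 * ((k // 3) % 3 - 1),
                                        8.0 + 3.0 * (k // 9)])

    return {"pos": pos, "state_positions": state_positions,
            "bridge_water": bridge, "site_water": site_water,
            "park_slots": slots}


# ---------------------------------------------------------------------------
# topology assembly
# ---------------------------------------------------------------------------

_RESIDUE_ATOMS = {
    "GLY": ["N", "H", "CA", "C", "O"],
    "CYS": ["N", "H", "CA", "C", "O", "CB", "SG"],
    "LYS": ["N", "H", "CA", "C", "O", "CB", "CG", "CD", "CE", "NZ",
            "HZ1", "HZ2", "HZ3"],
    "THR": ["N", "H", "CA", "C", "O", "CB", "OG1", "HG1", "CG2"],
    "GLU": ["N", "H", "CA", "C", "O", "CB", "CG", "CD", "OE1", "OE2"],
    "TYR": ["N", "H", "CA", "C", "O", "CB", "CG", "CD1", "CD2", "CE1",
            "CE2", "CZ", "OH", "HH"],
    "ASP": ["N", "H", "CA", "C", "O", "CB", "CG", "OD1", "OD2"],
    "HIS": ["N", "H", "CA", "C", "O", "CB", "CG", "ND1", "CD2", "CE1",
            "NE2", "HE2"],
}

_LIGAND_ATOMS = ["N1", "H1A", "H1B", "C9", "O1", "N2", "C10",
                 "C1", "C2", "C3", "C4", "C5", "C6",
                 "N3", "H3A", "H3B", "H3C", "N4", "O2", "C8", "C7"]


def build_system(config: GeneratorConfig = GeneratorConfig()
                 ) -> tuple[Topology, Frame]:
    """Mini receptor + annotated ligand + waters, with a reference frame.

    The reference frame has every planted contact switched on, Thr58 native
    and the conserved-water site occupied, with no noise. Deterministic for
    a fixed config.
    """
    geo = _build_geometry()
    names, elements, resnames, resnums, chains = [], [], [], [], []
    coords = []

    def add(name, resname, resnum, xyz):
        names.append(name)
        elements.append("H" if name.startswith("H") else name[0])
        resnames.append(resname)
        resnums.append(resnum)
        chains.append("A")
        coords.append(np.asarray(xyz) + _CENTER)

    for resnum, resname in _RESIDUES:
        for aname in _RESIDUE_ATOMS[resname]:
            add(aname, resname, resnum, geo["pos"][f"{resnum}:{aname}"])
    for aname in _LIGAND_ATOMS:
        add(aname, "LIG", 150, geo["pos"][f"LIG:{aname}"])
    # bridge water then the exchange pool (parked in the far corner)
    bw = geo["bridge_water"]
    for aname, key in (("O", "O"), ("H1", "H1"), ("H2", "H2")):
        add(aname, "HOH", 200, bw[key])
    for j in range(config.n_waters):
        base = _park_water(j)
        add("O", "HOH", 201 + j, base)
        add("H1", "HOH", 201 + j, base + np.array([0.7, 0.7, 0.0]))
        add("H2", "HOH", 201 + j, base + np.array([-0.7, 0.7, 0.0]))

    names = np.array(names, dtype=object)
    elements = np.array(elements, dtype=object)
    resnames_a = np.array(resnames, dtype=object)
    resnums_a = np.array(resnums, dtype=int)
    chains_a = np.array(chains, dtype=object)
    is_water = np.array([r == "HOH" for r in resnames])
    is_ligand = np.array([r == "LIG" for r in resnames])

    # ligand CONECT-equivalent bonds by name
    lig_local = {n: i for i, n in enumerate(names)
                 if is_ligand[i]}
    extra = [(lig_local[a], lig_local[b]) for a, b in _LIGAND_BONDS]
    topo = _assemble_topology(names, elements, resnames_a, resnums_a,
                              chains_a, is_water, is_ligand, extra)
    _annotate_standard(topo)
    apply_ligand_annotations(topo, LIGAND_SIDECAR)
    topo.validate()

    ref = Frame(coordinates=np.array(coords),
                box=np.eye(3) * BOX_EDGE, time_ns=0.0)
    # the reference has the site occupied by the first pool water
    site = geo["site_water"]["native"] + _CENTER
    w0 = _water_atom_indices(topo)[1]
    ref.coordinates[w0[0]] = site
    ref.coordinates[w0[1]] = site + np.array([0.0, 0.7, -0.7])
    ref.coordinates[w0[2]] = site + np.array([0.0, -0.7, -0.7])
    return topo, ref


def _park_water(j: int) -> np.ndarray:
    # far-corner grid, >= 18 Å (minimum image) from pocket and site
    return (np.array([22.0, 22.0, 22.0])
            + 4.0 * np.array([j % 4, (j // 4) % 4, j // 16]))


def _water_atom_indices(topo: Topology) -> list[tuple[int, int, int]]:
    """Per water molecule (O, H1, H2) atom indices, in file order."""
    out = []
    widx = np.flatnonzero(topo.is_water)
    for k in range(0, len(widx), 3):
        out.append((int(widx[k]), int(widx[k + 1]), int(widx[k + 2])))
    return out


# ---------------------------------------------------------------------------
# ledger and simulation
# ---------------------------------------------------------------------------

@dataclass
class ReplicaLedger:
    contact_flags: dict[str, np.ndarray]
    site_occupied: np.ndarray
    site_water_id: np.ndarray      # topology molecule id, -1 when empty
    state_labels: np.ndarray       # 'native' / 'flipped'

    def unique_waters(self) -> int:
        ids = self.site_water_id[self.site_water_id >= 0]
        return len(set(int(i) for i in ids))


@dataclass
class GroundTruthLedger:
    """Planted per-frame truth plus exactly recomputable totals."""

    replicas: list[ReplicaLedger]
    frame_spacing_ns: float
    targets: dict[str, float]

    @property
    def n_frames_total(self) -> int:
        return sum(len(r.site_occupied) for r in self.replicas)

    def contact_fraction(self, name: str) -> float:
        hits = sum(int(r.contact_flags[name].sum()) for r in self.replicas)
        return hits / self.n_frames_total

    def site_occupancy_fraction(self) -> float:
        return (sum(int(r.site_occupied.sum()) for r in self.replicas)
                / self.n_frames_total)

    def unique_waters_per_replica(self) -> list[int]:
        return [r.unique_waters() for r in self.replicas]

    def native_fraction(self) -> float:
        return (sum(int((r.state_labels == "native").sum())
                    for r in self.replicas) / self.n_frames_total)

    def conditional_occupancy(self) -> dict[str, float]:
        out = {}
        for lab in ("native", "flipped"):
            num = den = 0
            for r in self.replicas:
                mask = r.state_labels == lab
                den += int(mask.sum())
                num += int(r.site_occupied[mask].sum())
            out[lab] = num / den if den else float("nan")
        return out

    def to_json(self, path) -> None:
        payload = {
            "frame_spacing_ns": self.frame_spacing_ns,
            "targets": self.targets,
            "replicas": [{
                "contact_flags": {k: v.astype(int).tolist()
                                  for k, v in r.contact_flags.items()},
                "site_occupied": r.site_occupied.astype(int).tolist(),
                "site_water_id": r.site_water_id.tolist(),
                "state_labels": r.state_labels.tolist(),
            } for r in self.replicas],
        }
        Path(path).write_text(json.dumps(payload))


class SyntheticTrajectory:
    """Lazily materialized replica trajectories bound to a ledger."""

    def __init__(self, config: GeneratorConfig, topology: Topology,
                 ledger: GroundTruthLedger, noise_seeds: list):
        self.config = config
        self.topology = topology
        self.ledger = ledger
        self._noise_seeds = noise_seeds
        self._geo = _build_geometry()
        self._base, self._meta = _frame_template(topology, self._geo)

    def replica(self, r: int) -> Iterator[Frame]:
        """Deterministically regenerate the frames of replica r."""
        cfg = self.config
        led = self.ledger.replicas[r]
        rng = np.random.default_rng(self._noise_seeds[r])
        sigma = cfg.geometry_noise_sigma
        for k in range(cfg.n_frames):
            coords = _frame_coordinates(
                self._base, self._meta, self._geo,
                {name: bool(led.contact_flags[name][k]) for name in
                 led.contact_flags},
                str(led.state_labels[k]),
                int(led.site_water_id[k]))
            if sigma > 0:
                noise = rng.normal(0.0, sigma, coords.shape)
                np.clip(noise, -4 * sigma, 4 * sigma, out=noise)
                coords = coords + noise
            yield Frame(coordinates=coords, box=np.eye(3) * BOX_EDGE,
                        time_ns=k * cfg.frame_spacing_ns)

    def all_replicas(self) -> Iterator[tuple[int, Iterator[Frame]]]:
        for r in range(self.config.n_replicas):
            yield r, self.replica(r)


def _frame_template(topo: Topology, geo: dict):
    """Static base coordinates plus index metadata for fast frame assembly."""
    n = topo.n_atoms
    base = np.zeros((n, 3))
    name_of = {}
    for i in range(n):
        resnum = int(topo.resnums[i])
        aname = str(topo.names[i])
        if topo.is_ligand[i]:
            key = f"LIG:{aname}"
        elif topo.is_water[i]:
            key = None
        else:
            key = f"{resnum}:{aname}"
        if key is not None:
            base[i] = geo["pos"][key] + _CENTER
        name_of[i] = (resnum, aname)

    waters = _water_atom_indices(topo)
    bridge = waters[0]
    bw = geo["bridge_water"]
    base[bridge[0]] = bw["O"] + _CENTER
    base[bridge[1]] = bw["H1"] + _CENTER
    base[bridge[2]] = bw["H2"] + _CENTER
    pool = waters[1:]
    for j, (o, h1, h2) in enumerate(pool):
        p = _park_water(j) + _CENTER
        base[o] = p
        base[h1] = p + np.array([0.7, 0.7, 0.0])
        base[h2] = p + np.array([-0.7, 0.7, 0.0])

    lig_index = {str(topo.names[i]): i
                 for i in np.flatnonzero(topo.is_ligand)}
    frag_idx = {c.name: np.array([lig_index[a] for a in c.fragment])
                for c in CONTACTS}
    frag_on = {c.name: np.array([geo["pos"][f"LIG:{a}"] + _CENTER
                                 for a in c.fragment])
               for c in CONTACTS}
    frag_park = {}
    for c in CONTACTS:
        on = frag_on[c.name]
        frag_park[c.name] = on - on.mean(axis=0) \
            + geo["park_slots"][c.name] + _CENTER
    thr = {name: topo.atom_index(58, name) for name in ("OG1", "HG1")}
    pool_mol_ids = [int(topo.molecule_ids[o]) for o, _, _ in pool]
    meta = {"pool": pool, "pool_mol_ids": pool_mol_ids,
            "mol_to_pool": {m: j for j, m in enumerate(pool_mol_ids)},
            "frag_idx": frag_idx, "frag_on": frag_on,
            "frag_park": frag_park, "thr": thr}
    return base, meta


def _frame_coordinates(base: np.ndarray, meta: dict, geo: dict,
                       flags: dict[str, bool], state: str,
                       site_mol_id: int) -> np.ndarray:
    coords = base.copy()
    for name, on in flags.items():
        idx = meta["frag_idx"][name]
        coords[idx] = meta["frag_on"][name] if on else meta["frag_park"][name]
    for aname, p in geo["state_positions"][state].items():
        coords[meta["thr"][aname.split(":")[1]]] = p + _CENTER
    if site_mol_id >= 0:
        j = meta["mol_to_pool"][site_mol_id]
        o, h1, h2 = meta["pool"][j]
        site = geo["site_water"][state] + _CENTER
        coords[o] = site
        coords[h1] = site + np.array([0.0, 0.7, -0.7])
        coords[h2] = site + np.array([0.0, -0.7, -0.7])
    return coords


def _verify_templates(topo: Topology, tr: SyntheticTrajectory) -> None:
    """Run the real detectors on noise-free template frames and require the
    planted (residue, type) set exactly; a failure means the construction
    itself is unsafe and generation must stop."""
    expected_all = {(c.residue, c.itype) for c in CONTACTS}
    for state in ("native", "flipped"):
        for site_mol in (-1, tr._meta["pool_mol_ids"][0]):
            for on in (True, False):
                coords = _frame_coordinates(
                    tr._base, tr._meta, tr._geo,
                    {c.name: on for c in CONTACTS}, state, site_mol)
                frame = Frame(coordinates=coords,
                              box=np.eye(3) * BOX_EDGE, time_ns=0.0)
                events = detect_all(frame, topo, InteractionCriteria())
                got = {(ev.residue[0], ev.type) for ev in events}
                want = expected_all if on else set()
                if got != want:
                    raise ConfigError(
                        "planted-geometry self-check failed: template frame "
                        f"(state={state}, all_on={on}) detected {got}, "
                        f"expected {want}")


def simulate(config: GeneratorConfig = GeneratorConfig(),
             topology: Topology | None = None,
             write_dir: str | Path | None = None,
             verify: bool = True) -> SyntheticTrajectory:
    """Draw the planted schedules, build the ledger, and return lazily
    generated replica trajectories.

    With ``write_dir`` the topology (PDB), ligand sidecar (YAML), per-replica
    trajectories (multi-model PDB and DCD) and the ledger (JSON) are written
    out as well.
    """
    if topology is None:
        topology, _ = build_system(config)
    ss = np.random.SeedSequence(config.seed)
    replica_seeds = ss.spawn(config.n_replicas)
    pool_mol_ids = None

    # water pool molecule ids (bridge water excluded from the pool)
    waters = _water_atom_indices(topology)
    pool_mol_ids = [int(topology.molecule_ids[o]) for o, _, _ in waters[1:]]

    sched = config.state_schedule
    f_nat = sched.fraction_native
    dwell = max(sched.mean_dwell_frames, 1.0)
    p_nf = min(1.0, (1 - f_nat) / dwell)
    p_fn = min(1.0, f_nat / dwell)

    p_occ = config.water_site_occupancy
    n = config.n_frames
    if config.water_occupancy_by_state is None:
        if not 0 < p_occ < 1:
            p01 = p10 = 0.0
        else:
            p01 = config.water_exchange_rate / (n * (1 - p_occ))
            p10 = config.water_exchange_rate / (n * p_occ)
            if p01 > 1 or p10 > 1:
                raise ConfigError(
                    "water_exchange_rate too high for the requested "
                    "occupancy and frame count")

    replicas = []
    noise_seeds = []
    for r in range(config.n_replicas):
        streams = replica_seeds[r].spawn(4)
        rng_c = np.random.default_rng(streams[0])
        rng_w = np.random.default_rng(streams[1])
        rng_s = np.random.default_rng(streams[2])
        noise_seeds.append(streams[3])

        flags = {}
        for c in CONTACTS:
            p = config.contact_probability(c.name)
            flags[c.name] = rng_c.random(n) < p

        labels = np.empty(n, dtype=object)
        state = "native" if rng_s.random() < f_nat else "flipped"
        for k in range(n):
            labels[k] = state
            flip_p = p_nf if state == "native" else p_fn
            if rng_s.random() < flip_p:
                state = "flipped" if state == "native" else "native"

        occupied = np.zeros(n, dtype=bool)
        water_id = np.full(n, -1, dtype=int)
        next_pool = 0
        if config.water_occupancy_by_state is not None:
            probs = config.water_occupancy_by_state
            prev = False
            for k in range(n):
                occ = rng_w.random() < probs[str(labels[k])]
                if occ and not prev:
                    next_pool = next_pool  # fresh id on entry
                    wid = pool_mol_ids[next_pool % len(pool_mol_ids)]
                    next_pool += 1
                if occ:
                    occupied[k] = True
                    water_id[k] = wid
                prev = occ
        else:
            occ = rng_w.random() < p_occ
            wid = -1
            if occ:
                wid = pool_mol_ids[0]
                next_pool = 1
            for k in range(n):
                if occ:
                    occupied[k] = True
                    water_id[k] = wid
                stay = rng_w.random()
                if occ and stay < p10:
                    occ = False
                elif not occ and stay < p01:
                    occ = True
                    wid = pool_mol_ids[next_pool % len(pool_mol_ids)]
                    next_pool += 1
        replicas.append(ReplicaLedger(contact_flags=flags,
                                      site_occupied=occupied,
                                      site_water_id=water_id,
                                      state_labels=labels))

    targets = dict(config.hbond_occupancy_targets)
    targets.update(config.other_contact_targets)
    targets["water_site_occupancy"] = p_occ
    targets["fraction_native"] = f_nat
    ledger = GroundTruthLedger(replicas=replicas,
                               frame_spacing_ns=config.frame_spacing_ns,
                               targets=targets)
    traj = SyntheticTrajectory(config, topology, ledger, noise_seeds)
    if verify:
        _verify_templates(topology, traj)
    if write_dir is not None:
        _export(traj, Path(write_dir))
    return traj


def _export(traj: SyntheticTrajectory, out: Path) -> None:
    import warnings

    import MDAnalysis as mda
    import yaml as _yaml

    from .structure_io import write_frames_pdb

    out.mkdir(parents=True, exist_ok=True)
    topo = traj.topology
    _, ref = build_system(traj.config)
    write_frames_pdb(topo, [ref], out / "topology.pdb")
    (out / "ligand.yaml").write_text(_yaml.safe_dump(LIGAND_SIDECAR))
    traj.ledger.to_json(out / "ledger.json")
    for r in range(traj.config.n_replicas):
        frames = list(traj.replica(r))
        write_frames_pdb(topo, frames, out / f"replica_{r:02d}.pdb")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            with mda.Writer(str(out / f"replica_{r:02d}.dcd"),
                            topo.n_atoms,
                            dt=traj.config.frame_spacing_ns * 1000.0) as w:
                u = mda.Universe.empty(topo.n_atoms, trajectory=True)
                for fr in frames:
                    u.atoms.positions = fr.coordinates
                    u.dimensions = [BOX_EDGE, BOX_EDGE, BOX_EDGE,
                                    90.0, 90.0, 90.0]
                    w.write(u.atoms)


# ---------------------------------------------------------------------------
# engineered conformational basins (for clustering validation)
# ---------------------------------------------------------------------------

def simulate_basins(n_frames: int = 120, populations: Sequence[float] =
                    (0.5, 0.3, 0.2), separation: float = 12.0,
                    noise_sigma: float = 0.1, seed: int = 0,
                    config: GeneratorConfig | None = None):
    """Trajectory with well-separated ligand-placement basins.

    All planted contacts stay on; the whole ligand is rigidly offset along z
    by ``separation`` per basin with small intra-basin jitter, so inter-basin
    RMSD over any measured set containing the ligand far exceeds intra-basin
    spread. Returns (topology, frames, basin_labels).
    """
    if config is None:
        config = GeneratorConfig(n_replicas=1, n_frames=n_frames,
                                 n_waters=4, seed=seed)
    topo, ref = build_system(config)
    rng = np.random.default_rng(seed)
    pops = np.asarray(populations, dtype=float)
    pops = pops / pops.sum()
    labels = rng.choice(len(pops), size=n_frames, p=pops)
    lig = np.flatnonzero(topo.is_ligand)
    frames = []
    for k in range(n_frames):
        coords = ref.coordinates.copy()
        coords[lig, 2] += separation * labels[k]
        coords += rng.normal(0.0, noise_sigma, coords.shape)
        frames.append(Frame(coordinates=coords, box=np.eye(3) * BOX_EDGE,
                            time_ns=float(k)))
    return topo, frames, labels
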