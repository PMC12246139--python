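"""Geometric protein-ligand interaction fingerprints.

Per-frame detection of hydrogen bonds, water bridges, pi-stacking, pi-cation,
ionic and hydrophobic contacts, followed by aggregation into per-residue
interaction fractions over pooled replicas.

Criteria defaults: H-bond = hydrogen...acceptor distance <= 2.5 Å with
donor angle (D-H...A) >= 120 deg and acceptor angle (H...A-X) >= 90 deg;
water bridge = the same geometry at 2.8 Å / 110 deg / 90 deg simultaneously
to protein and ligand through one water; pi-cation = centroid separation
<= 4.5 Å. The distance threshold is deliberately the H...A distance: a
2.5 Å donor-acceptor cutoff would reject virtually every real hydrogen bond
(typical D-A separations are 2.8-3.2 Å). pi-pi and nonpolar thresholds are
conventional fingerprinting values; everything is configurable.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import AnnotationError, ConfigError, StatisticsError
from .geometry import angles_batch, pbc_displacement
from .structure_io import BACKBONE_NAMES, Frame, Topology

INTERACTION_TYPES = ("hbond", "water_bridge", "pi_pi", "pi_cation",
                     "ionic", "hydrophobic")


@dataclass(frozen=True)
class InteractionCriteria:
    """Geometric thresholds for every interaction class (Å / degrees)."""

    hbond_distance: float = 2.5
    hbond_donor_angle_min: float = 120.0
    hbond_acceptor_angle_min: float = 90.0
    wbridge_distance: float = 2.8
    wbridge_donor_angle_min: float = 110.0
    wbridge_acceptor_angle_min: float = 90.0
    pication_distance: float = 4.5
    pipi_f2f_centroid_max: float = 4.4
    pipi_e2f_centroid_max: float = 5.5
    pipi_f2f_plane_angle_max: float = 30.0
    pipi_e2f_plane_angle_window: tuple[float, float] = (60.0, 120.0)
    hydrophobic_distance: float = 3.6
    ionic_distance: float = 3.7

    def __post_init__(self):
        for name in ("hbond_distance", "wbridge_distance", "pication_distance",
                     "pipi_f2f_centroid_max", "pipi_e2f_centroid_max",
                     "hydrophobic_distance", "ionic_distance"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        for name in ("hbond_donor_angle_min", "hbond_acceptor_angle_min",
                     "wbridge_donor_angle_min", "wbridge_acceptor_angle_min",
                     "pipi_f2f_plane_angle_max"):
            v = getattr(self, name)
            if not 0 < v <= 180:
                raise ConfigError(f"{name} must lie in (0, 180]")

    def with_overrides(self, **kwargs) -> "InteractionCriteria":
        return replace(self, **kwargs)


@dataclass(frozen=True)
class InteractionEvent:
    """One detected protein-ligand contact in one frame."""

    frame_index: int
    type: str
    residue: tuple[int, str, str]      # (number, name, chain)
    residue_part: str                  # backbone | sidechain
    ligand_atoms: tuple[int, ...]
    water_molecule_id: int | None = None
    direction: str | None = None       # donor side: protein | ligand | water
    replica: int = 0

    def __post_init__(self):
        if (self.type == "water_bridge") != (self.water_molecule_id is not None):
            raise AnnotationError(
                "water_molecule_id must be present exactly for water bridges")

    def identity(self):
        """Hashable identity used for event-set comparisons."""
        return (self.type, self.residue, self.residue_part,
                tuple(sorted(self.ligand_atoms)), self.water_molecule_id,
                self.direction)


def _residue_part(topology: Topology, atom: int) -> str:
    name = str(topology.names[atom])
    if name in BACKBONE_NAMES or name in ("H", "HN", "HA"):
        return "backbone"
    return "sidechain"


# ---------------------------------------------------------------------------
# hydrogen bonds
# ---------------------------------------------------------------------------

def _hbond_geometry_ok(frame: Frame, topology: Topology,
                       donor: int, hydrogen: int, acceptor: int,
                       dist_max: float, donor_angle_min: float,
                       acceptor_angle_min: float) -> bool:
    """Literal evaluation of the three-part hydrogen-bond criterion."""
    box = frame.box
    xyz = frame.coordinates
    ha = pbc_displacement(xyz[hydrogen], xyz[acceptor], box)
    if np.linalg.norm(ha) > dist_max:
        return False
    hd = pbc_displacement(xyz[hydrogen], xyz[donor], box)
    cosd = np.dot(hd, ha) / max(np.linalg.norm(hd) * np.linalg.norm(ha),
                                1e-300)
    # donor angle D-H...A is at the hydrogen; linear bond -> 180 deg
    if np.degrees(np.arccos(np.clip(cosd, -1, 1))) < donor_angle_min:
        return False
    heavies = topology.heavy_neighbors(acceptor)
    if not heavies:
        return True  # no reference substituent: criterion is vacuous
    ah = -ha
    best = -np.inf
    for x in heavies:
        ax = pbc_displacement(xyz[acceptor], xyz[x], box)
        cosx = np.dot(ah, ax) / max(
            np.linalg.norm(ah) * np.linalg.norm(ax), 1e-300)
        best = max(best, np.degrees(np.arccos(np.clip(cosx, -1, 1))))
    return best >= acceptor_angle_min


def _donor_triples(topology: Topology, mask: np.ndarray):
    """(donor, hydrogen) pairs whose donor heavy atom lies in mask."""
    out = []
    for heavy, hs in topology.annotations.donor_hydrogens.items():
        if mask[heavy]:
            if not hs:
                raise AnnotationError(
                    f"donor atom {heavy} has no attached hydrogen")
            out.extend((heavy, h) for h in hs)
    return out


def detect_hbonds(frame: Frame, topology: Topology,
                  criteria: InteractionCriteria = InteractionCriteria(),
                  frame_index: int = 0, replica: int = 0,
                  ) -> list[InteractionEvent]:
    """Protein-ligand hydrogen bonds in one frame (both donor directions)."""
    ann = topology.annotations
    prot = topology.is_protein
    lig = topology.is_ligand
    events: list[InteractionEvent] = []
    directions = (
        ("protein", _donor_triples(topology, prot),
         [a for a in ann.acceptors if lig[a]]),
        ("ligand", _donor_triples(topology, lig),
         [a for a in ann.acceptors if prot[a]]),
    )
    for direction, donors, acceptors in directions:
        if not donors or not acceptors:
            continue
        xyz = frame.coordinates
        hpos = np.array([xyz[h] for _, h in donors])
        apos = np.array([xyz[a] for a in acceptors])
        d = pbc_displacement(hpos[:, None, :], apos[None, :, :], frame.box)
        dist = np.linalg.norm(d, axis=-1)
        for i, j in zip(*np.nonzero(dist <= criteria.hbond_distance)):
            donor, hydrogen = donors[i]
            acceptor = acceptors[j]
            if _hbond_geometry_ok(frame, topology, donor, hydrogen, acceptor,
                                  criteria.hbond_distance,
                                  criteria.hbond_donor_angle_min,
                                  criteria.hbond_acceptor_angle_min):
                prot_atom = donor if direction == "protein" else acceptor
                lig_atom = acceptor if direction == "protein" else donor
                events.append(InteractionEvent(
                    frame_index=frame_index, type="hbond",
                    residue=topology.residue_key(prot_atom),
                    residue_part=_residue_part(topology, prot_atom),
                    ligand_atoms=(int(lig_atom),),
                    direction=direction, replica=replica))
    return events


# ---------------------------------------------------------------------------
# water bridges
# ---------------------------------------------------------------------------

def _partner_bonds(frame, topology, criteria, water_ox, water_hs, mask):
    """Atoms of `mask` H-bonded to this water under water-bridge thresholds.

    Returns (partner atom, donor side) with donor side 'water' when the
    water donates and 'partner' when the partner donates.
    """
    out = []
    for acc in topology.annotations.acceptors:
        if not mask[acc]:
            continue
        for h in water_hs:
            if _hbond_geometry_ok(frame, topology, water_ox, h, acc,
                                  criteria.wbridge_distance,
                                  criteria.wbridge_donor_angle_min,
                                  criteria.wbridge_acceptor_angle_min):
                out.append((acc, "water"))
                break
    for donor, hs in topology.annotations.donor_hydrogens.items():
        if not mask[donor]:
            continue
        for h in hs:
            if _hbond_geometry_ok(frame, topology, donor, h, water_ox,
                                  criteria.wbridge_distance,
                                  criteria.wbridge_donor_angle_min,
                                  criteria.wbridge_acceptor_angle_min):
                out.append((donor, "partner"))
                break
    return out


def detect_water_bridges(frame: Frame, topology: Topology,
                         criteria: InteractionCriteria = InteractionCriteria(),
                         frame_index: int = 0, replica: int = 0,
                         ) -> list[InteractionEvent]:
    """Single-water bridges: one water H-bonded to protein and ligand at once.

    One event per (residue, water, ligand atom) per frame; the reported
    direction is the donor side of the ligand-side hydrogen bond.
    """
    ann = topology.annotations
    if not np.any(topology.is_water):
        raise AnnotationError("topology contains no annotated waters")
    prot = topology.is_protein
    lig = topology.is_ligand
    xyz = frame.coordinates
    adj = topology._adj

    # candidate waters: oxygen within reach of any polar ligand atom
    lig_polar = sorted({a for a in ann.acceptors if lig[a]}
                       | {d for d in ann.donor_hydrogens if lig[d]})
    if not lig_polar:
        return []
    water_ox = [i for i in np.flatnonzero(topology.is_water)
                if topology.elements[i] == "O"]
    wpos = xyz[water_ox]
    lpos = xyz[lig_polar]
    reach = criteria.wbridge_distance + 1.2  # O-H offset slack
    dmin = np.linalg.norm(
        pbc_displacement(wpos[:, None, :], lpos[None, :, :], frame.box),
        axis=-1).min(axis=1)
    events = []
    for k in np.flatnonzero(dmin <= reach):
        ox = water_ox[k]
        whs = sorted(h for h in adj[ox] if topology.elements[h] == "H")
        prot_partners = _partner_bonds(frame, topology, criteria, ox, whs, prot)
        if not prot_partners:
            continue
        lig_partners = _partner_bonds(frame, topology, criteria, ox, whs, lig)
        for prot_atom, _ in prot_partners:
            for lig_atom, lig_side in lig_partners:
                direction = "water" if lig_side == "water" else "ligand"
                events.append(InteractionEvent(
                    frame_index=frame_index, type="water_bridge",
                    residue=topology.residue_key(prot_atom),
                    residue_part=_residue_part(topology, prot_atom),
                    ligand_atoms=(int(lig_atom),),
                    water_molecule_id=int(topology.molecule_ids[ox]),
                    direction=direction, replica=replica))
    return events


# ---------------------------------------------------------------------------
# aromatic interactions
# ---------------------------------------------------------------------------

def ring_centroid_normal(frame: Frame, ring: Sequence[int]):
    """Ring centroid and unit normal (smallest singular vector of the
    centered ring coordinates)."""
    if len(ring) < 5:
        raise AnnotationError(f"ring {ring} has fewer than 5 atoms")
    pts = frame.coordinates[list(ring)]
    centroid = pts.mean(axis=0)
    _, _, vt = np.linalg.svd(pts - centroid)
    return centroid, vt[2]


def detect_pi_interactions(frame: Frame, topology: Topology,
                           criteria: InteractionCriteria = InteractionCriteria(),
                           frame_index: int = 0, replica: int = 0,
                           ) -> list[InteractionEvent]:
    """pi-pi stacking (face-to-face / edge-to-face) and pi-cation contacts.

    The interplanar angle is taken between ring normals in [0, 180] deg;
    face-to-face accepts angles near 0 or 180 (normal sign is arbitrary),
    edge-to-face accepts the configured window around 90 deg.
    """
    ann = topology.annotations
    prot = topology.is_protein
    lig = topology.is_ligand
    events: list[InteractionEvent] = []

    prot_rings = [r for r in ann.aromatic_rings if prot[r[0]]]
    lig_rings = [r for r in ann.aromatic_rings if lig[r[0]]]

    def interplanar(n1, n2):
        c = np.clip(abs(np.dot(n1, n2)), 0, 1)  # fold to [0, 90]
        return np.degrees(np.arccos(c))

    f2f_lim = min(criteria.pipi_f2f_plane_angle_max,
                  180 - criteria.pipi_f2f_plane_angle_max)
    lo, hi = criteria.pipi_e2f_plane_angle_window
    e2f_lo = min(lo, 180 - hi)

    for pr in prot_rings:
        c1, n1 = ring_centroid_normal(frame, pr)
        for lr in lig_rings:
            c2, n2 = ring_centroid_normal(frame, lr)
            sep = np.linalg.norm(pbc_displacement(c1, c2, frame.box))
            ang = interplanar(n1, n2)
            hit = ((sep <= criteria.pipi_f2f_centroid_max and ang <= f2f_lim)
                   or (sep <= criteria.pipi_e2f_centroid_max
                       and ang >= e2f_lo))
            if hit:
                events.append(InteractionEvent(
                    frame_index=frame_index, type="pi_pi",
                    residue=topology.residue_key(pr[0]),
                    residue_part="sidechain",
                    ligand_atoms=tuple(int(a) for a in sorted(lr)),
                    replica=replica))

    prot_cations = [(g, s) for g, s in ann.charged_groups
                    if s > 0 and prot[g[0]]]
    lig_cations = [(g, s) for g, s in ann.charged_groups
                   if s > 0 and lig[g[0]]]
    pairs = ([(pr, g, "ligand") for pr in prot_rings for g, _ in lig_cations]
             + [(lr, g, "protein") for lr in lig_rings
                for g, _ in prot_cations])
    for ring, group, cation_side in pairs:
        c_ring, _ = ring_centroid_normal(frame, ring)
        c_grp = frame.coordinates[list(group)].mean(axis=0)
        sep = np.linalg.norm(pbc_displacement(c_ring, c_grp, frame.box))
        if sep <= criteria.pication_distance:
            prot_atoms = group if cation_side == "protein" else ring
            lig_atoms = ring if cation_side == "protein" else group
            events.append(InteractionEvent(
                frame_index=frame_index, type="pi_cation",
                residue=topology.residue_key(prot_atoms[0]),
                residue_part="sidechain",
                ligand_atoms=tuple(int(a) for a in sorted(lig_atoms)),
                replica=replica))
    return events


# ---------------------------------------------------------------------------
# nonpolar and ionic
# ---------------------------------------------------------------------------

def detect_nonpolar_and_ionic(frame: Frame, topology: Topology,
                              criteria: InteractionCriteria = InteractionCriteria(),
                              frame_index: int = 0, replica: int = 0,
                              ) -> list[InteractionEvent]:
    """Hydrophobic carbon-carbon contacts and ionic closest-atom contacts."""
    ann = topology.annotations
    prot = topology.is_protein
    lig = topology.is_ligand
    xyz = frame.coordinates
    events: list[InteractionEvent] = []

    pc = sorted(a for a in ann.hydrophobic if prot[a])
    lc = sorted(a for a in ann.hydrophobic if lig[a])
    if pc and lc:
        d = np.linalg.norm(
            pbc_displacement(xyz[pc][:, None, :], xyz[lc][None, :, :],
                             frame.box), axis=-1)
        seen = set()
        for i, j in zip(*np.nonzero(d <= criteria.hydrophobic_distance)):
            key = (topology.residue_key(pc[i]), lc[j])
            if key in seen:
                continue
            seen.add(key)
            events.append(InteractionEvent(
                frame_index=frame_index, type="hydrophobic",
                residue=key[0],
                residue_part=_residue_part(topology, pc[i]),
                ligand_atoms=(int(lc[j]),), replica=replica))

    prot_groups = [(g, s) for g, s in ann.charged_groups if prot[g[0]]]
    lig_groups = [(g, s) for g, s in ann.charged_groups if lig[g[0]]]
    for pg, ps in prot_groups:
        for lg, ls in lig_groups:
            if ps * ls >= 0:
                continue
            d = np.linalg.norm(
                pbc_displacement(xyz[list(pg)][:, None, :],
                                 xyz[list(lg)][None, :, :], frame.box),
                axis=-1)
            if d.min() <= criteria.ionic_distance:
                events.append(InteractionEvent(
                    frame_index=frame_index, type="ionic",
                    residue=topology.residue_key(pg[0]),
                    residue_part=_residue_part(topology, pg[0]),
                    ligand_atoms=tuple(int(a) for a in sorted(lg)),
                    replica=replica))
    return events


def detect_all(frame: Frame, topology: Topology,
               criteria: InteractionCriteria = InteractionCriteria(),
               frame_index: int = 0, replica: int = 0,
               include_water_bridges: bool = True) -> list[InteractionEvent]:
    """All interaction detectors on one frame."""
    events = detect_hbonds(frame, topology, criteria, frame_index, replica)
    if include_water_bridges and np.any(topology.is_water):
        events += detect_water_bridges(frame, topology, criteria,
                                       frame_index, replica)
    events += detect_pi_interactions(frame, topology, criteria,
                                     frame_index, replica)
    events += detect_nonpolar_and_ionic(frame, topology, criteria,
                                        frame_index, replica)
    return events


# ---------------------------------------------------------------------------
# aggregation
# ---------------------------------------------------------------------------

@dataclass
class FractionTable:
    """Per-(residue, interaction type) fractions plus per-residue totals.

    A residue is *displayed* when its total fraction exceeds 0.2 and *key*
    when it exceeds 0.5 (strict inequalities). Because a residue can engage
    through several interaction types at once, totals may exceed 1.
    """

    table: pd.DataFrame
    totals: pd.DataFrame
    frames_analyzed: int
    displayed_threshold: float = 0.2
    key_threshold: float = 0.5

    def key_residues(self) -> list[tuple[int, str, str]]:
        rows = self.totals[self.totals["key"]]
        return [(int(r.residue_number), r.residue_name, r.chain)
                for r in rows.itertuples()]

    def fraction(self, residue_number: int, itype: str) -> float:
        t = self.table
        hit = t[(t.residue_number == residue_number) & (t.type == itype)]
        return float(hit.fraction.iloc[0]) if len(hit) else 0.0

    def to_csv(self, path) -> None:
        merged = self.table.merge(
            self.totals[["residue_number", "residue_name", "chain", "total",
                         "displayed", "key"]],
            on=["residue_number", "residue_name", "chain"], how="left")
        merged.to_csv(path, index=False)


def aggregate_fractions(events: Iterable[InteractionEvent],
                        frames_analyzed: int,
                        displayed_threshold: float = 0.2,
                        key_threshold: float = 0.5) -> FractionTable:
    """Pool events over replicas into per-(residue, type) fractions.

    A residue-type pair counts at most once per (replica, frame): multiple
    same-type contacts in one frame contribute a single occupied frame.
    """
    if frames_analyzed <= 0:
        raise StatisticsError("frames_analyzed must be positive")
    seen: dict[tuple, set] = {}
    for ev in events:
        seen.setdefault((ev.residue, ev.type), set()).add(
            (ev.replica, ev.frame_index))
    rows = [{"residue_number": res[0], "residue_name": res[1],
             "chain": res[2], "type": itype,
             "fraction": len(frames) / frames_analyzed}
            for (res, itype), frames in sorted(seen.items())]
    table = pd.DataFrame(rows, columns=["residue_number", "residue_name",
                                        "chain", "type", "fraction"])
    if len(table):
        totals = (table.groupby(["residue_number", "residue_name", "chain"],
                                as_index=False)["fraction"].sum()
                  .rename(columns={"fraction": "total"}))
    else:
        totals = pd.DataFrame(columns=["residue_number", "residue_name",
                                       "chain", "total"])
    totals["displayed"] = totals.get("total", pd.Series(dtype=float)) \
        > displayed_threshold
    totals["key"] = totals.get("total", pd.Series(dtype=float)) > key_threshold
    return FractionTable(table=table, totals=totals,
                         frames_analyzed=frames_analyzed,
                         displayed_threshold=displayed_threshold,
                         key_threshold=key_threshold)


def events_to_jsonl(events: Iterable[InteractionEvent], path) -> None:
    import json
    with open(path, "w") as fh:
        for ev in events:
            fh.write(json.dumps({
                "replica": ev.replica, "frame_index": ev.frame_index,
                "type": ev.type,
                "residue": {"number": ev.residue[0], "name": ev.residue[1],
                            "chain": ev.residue[2]},
                "residue_part": ev.residue_part,
                "ligand_atoms": list(ev.ligand_atoms),
                "water_molecule_id": ev.water_molecule_id,
                "direction": ev.direction}) + "\n")
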