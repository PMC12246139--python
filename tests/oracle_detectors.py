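"""Literal brute-force reference implementation of the interaction criteria.

Deliberately independent of the package internals: explicit Python loops,
minimum image by enumerating all 27 periodic translations, plane normals
from the covariance eigendecomposition. Used as the oracle that the
vectorized detectors must match event-for-event.
"""

from __future__ import annotations

import itertools

import numpy as np


def oracle_min_image(a, b, box):
    """Minimum-image displacement by enumerating all 27 translations."""
    d = np.asarray(b, float) - np.asarray(a, float)
    if box is None:
        return d
    # fold into the central cell once, then enumerate every neighbour image
    frac = d @ np.linalg.inv(box)
    d = (frac - np.round(frac)) @ box
    best = None
    best_n = np.inf
    for i, j, k in itertools.product((-1, 0, 1), repeat=3):
        cand = d + i * box[0] + j * box[1] + k * box[2]
        n = np.linalg.norm(cand)
        if n < best_n:
            best_n = n
            best = cand
    return best


def oracle_dist(a, b, box):
    return float(np.linalg.norm(oracle_min_image(a, b, box)))


def _angle_deg(u, v):
    c = np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v))
    return float(np.degrees(np.arccos(np.clip(c, -1, 1))))


def oracle_hbond_ok(xyz, box, topo, donor, hydrogen, acceptor,
                    dist_max, donor_min, acceptor_min):
    ha = oracle_min_image(xyz[hydrogen], xyz[acceptor], box)
    if np.linalg.norm(ha) > dist_max:
        return False
    hd = oracle_min_image(xyz[hydrogen], xyz[donor], box)
    if _angle_deg(hd, ha) < donor_min:
        return False
    heavies = [j for j in _neighbors(topo, acceptor)
               if topo.elements[j] != "H"]
    if not heavies:
        return True
    angles = [_angle_deg(oracle_min_image(xyz[acceptor], xyz[hydrogen], box),
                         oracle_min_image(xyz[acceptor], xyz[x], box))
              for x in heavies]
    return max(angles) >= acceptor_min


def _neighbors(topo, i):
    out = []
    for a, b in topo.bonds:
        if a == i:
            out.append(b)
        if b == i:
            out.append(a)
    return out


def _donors(topo, mask):
    out = []
    for heavy, hs in topo.annotations.donor_hydrogens.items():
        if mask[heavy]:
            out.extend((heavy, h) for h in hs)
    return out


def oracle_hbond_events(frame, topo, c):
    xyz, box = frame.coordinates, frame.box
    prot = topo.is_protein
    lig = topo.is_ligand
    acc = topo.annotations.acceptors
    out = set()
    for direction, dmask, amask in (("protein", prot, lig),
                                    ("ligand", lig, prot)):
        for donor, h in _donors(topo, dmask):
            for a in acc:
                if not amask[a]:
                    continue
                if oracle_hbond_ok(xyz, box, topo, donor, h, a,
                                   c.hbond_distance,
                                   c.hbond_donor_angle_min,
                                   c.hbond_acceptor_angle_min):
                    patom = donor if direction == "protein" else a
                    latom = a if direction == "protein" else donor
                    out.add(("hbond", topo.residue_key(patom), (latom,),
                             None, direction))
    return out


def oracle_water_bridge_events(frame, topo, c):
    xyz, box = frame.coordinates, frame.box
    prot = topo.is_protein
    lig = topo.is_ligand
    acc = topo.annotations.acceptors
    out = set()
    water_ox = [i for i in np.flatnonzero(topo.is_water)
                if topo.elements[i] == "O"]
    for ox in water_ox:
        whs = [j for j in _neighbors(topo, ox) if topo.elements[j] == "H"]

        def bonds_to(mask):
            partners = []
            for a in acc:
                if mask[a] and any(
                        oracle_hbond_ok(xyz, box, topo, ox, h, a,
                                        c.wbridge_distance,
                                        c.wbridge_donor_angle_min,
                                        c.wbridge_acceptor_angle_min)
                        for h in whs):
                    partners.append((a, "water"))
            for d, h in _donors(topo, mask):
                if oracle_hbond_ok(xyz, box, topo, d, h, ox,
                                   c.wbridge_distance,
                                   c.wbridge_donor_angle_min,
                                   c.wbridge_acceptor_angle_min):
                    partners.append((d, "partner"))
            return partners

        pp = bonds_to(prot)
        if not pp:
            continue
        lp = bonds_to(lig)
        for pa, _ in pp:
            for la, side in lp:
                direction = "water" if side == "water" else "ligand"
                out.add(("water_bridge", topo.residue_key(pa), (la,),
                         int(topo.molecule_ids[ox]), direction))
    return out


def _plane_normal(pts):
    centered = pts - pts.mean(axis=0)
    cov = centered.T @ centered
    w, v = np.linalg.eigh(cov)
    return v[:, 0]


def oracle_pi_events(frame, topo, c):
    xyz, box = frame.coordinates, frame.box
    prot = topo.is_protein
    lig = topo.is_ligand
    rings = topo.annotations.aromatic_rings
    charged = topo.annotations.charged_groups
    out = set()
    prot_rings = [r for r in rings if prot[r[0]]]
    lig_rings = [r for r in rings if lig[r[0]]]
    for pr in prot_rings:
        c1 = xyz[list(pr)].mean(axis=0)
        n1 = _plane_normal(xyz[list(pr)])
        for lr in lig_rings:
            c2 = xyz[list(lr)].mean(axis=0)
            n2 = _plane_normal(xyz[list(lr)])
            sep = oracle_dist(c1, c2, box)
            ang = _angle_deg(n1, n2)
            folded = min(ang, 180 - ang)
            f2f = (sep <= c.pipi_f2f_centroid_max
                   and folded <= min(c.pipi_f2f_plane_angle_max,
                                     180 - c.pipi_f2f_plane_angle_max))
            lo, hi = c.pipi_e2f_plane_angle_window
            e2f = (sep <= c.pipi_e2f_centroid_max
                   and folded >= min(lo, 180 - hi))
            if f2f or e2f:
                out.add(("pi_pi", topo.residue_key(pr[0]),
                         tuple(sorted(lr)), None, None))
    for ring, group, cation_side in (
            [(pr, g, "ligand") for pr in prot_rings
             for g, s in charged if s > 0 and lig[g[0]]]
            + [(lr, g, "protein") for lr in lig_rings
               for g, s in charged if s > 0 and prot[g[0]]]):
        cr = xyz[list(ring)].mean(axis=0)
        cg = xyz[list(group)].mean(axis=0)
        if oracle_dist(cr, cg, box) <= c.pication_distance:
            patoms = group if cation_side == "protein" else ring
            latoms = ring if cation_side == "protein" else group
            out.add(("pi_cation", topo.residue_key(patoms[0]),
                     tuple(sorted(latoms)), None, None))
    return out


def oracle_nonpolar_ionic_events(frame, topo, c):
    xyz, box = frame.coordinates, frame.box
    prot = topo.is_protein
    lig = topo.is_ligand
    hyd = topo.annotations.hydrophobic
    charged = topo.annotations.charged_groups
    out = set()
    for i in sorted(hyd):
        if not prot[i]:
            continue
        for j in sorted(hyd):
            if not lig[j]:
                continue
            if oracle_dist(xyz[i], xyz[j], box) <= c.hydrophobic_distance:
                out.add(("hydrophobic", topo.residue_key(i), (j,),
                         None, None))
    for pg, ps in charged:
        if not prot[pg[0]]:
            continue
        for lg, ls in charged:
            if not lig[lg[0]] or ps * ls >= 0:
                continue
            dmin = min(oracle_dist(xyz[i], xyz[j], box)
                       for i in pg for j in lg)
            if dmin <= c.ionic_distance:
                out.add(("ionic", topo.residue_key(pg[0]),
                         tuple(sorted(lg)), None, None))
    return out


def oracle_all_events(frame, topo, criteria):
    return (oracle_hbond_events(frame, topo, criteria)
            | oracle_water_bridge_events(frame, topo, criteria)
            | oracle_pi_events(frame, topo, criteria)
            | oracle_nonpolar_ionic_events(frame, topo, criteria))


def event_identity_set(events):
    """Reduce package events to the oracle's identity tuples."""
    return {(ev.type, ev.residue, tuple(sorted(ev.ligand_atoms)),
             ev.water_molecule_id,
             ev.direction if ev.type in ("hbond", "water_bridge") else None)
            for ev in events}
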