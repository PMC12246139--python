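"""Shared fixtures: tiny PDB texts, micro-topologies and synthetic runs."""

from __future__ import annotations

import numpy as np
import pytest

from bindmode.structure_io import (Annotations, Frame, Topology,
                                   _annotate_standard, _assemble_topology)

WATER_PDB = """\
HETATM    1  O   HOH A   1       0.000   0.000   0.000  1.00  0.00           O
HETATM    2  H1  HOH A   1       0.960   0.000   0.000  1.00  0.00           H
HETATM    3  H2  HOH A   1      -0.240   0.930   0.000  1.00  0.00           H
CONECT    1    2
CONECT    1    3
END
"""


def _pdb_line(serial, name, resname, chain, resnum, xyz, element,
              record="ATOM  "):
    fmt_name = name if len(name) == 4 else f" {name:<3s}"
    x, y, z = xyz
    return (f"{record}{serial:5d} {fmt_name:<4s} {resname:<3s} {chain}"
            f"{resnum:4d}    {x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00"
            f"          {element:>2s}")


def make_pdb(atoms, conect=()):
    """atoms: (name, resname, resnum, xyz) tuples; returns PDB text."""
    lines = []
    for k, (name, resname, resnum, xyz) in enumerate(atoms, start=1):
        element = "H" if name.startswith("H") else name[0]
        record = "HETATM" if resname in ("HOH", "LIG") else "ATOM  "
        lines.append(_pdb_line(k, name, resname, "A", resnum, xyz, element,
                               record))
    for i, j in conect:
        lines.append(f"CONECT{i:5d}{j:5d}")
    lines.append("END")
    return "\n".join(lines) + "\n"


TRIPEPTIDE_ATOMS = [
    # Gly1
    ("N", "GLY", 1, (0.0, 0.0, 0.0)), ("H", "GLY", 1, (-0.9, 0.3, 0.0)),
    ("CA", "GLY", 1, (1.4, 0.0, 0.0)), ("C", "GLY", 1, (2.1, 1.3, 0.0)),
    ("O", "GLY", 1, (1.5, 2.4, 0.0)),
    # Thr2
    ("N", "THR", 2, (3.4, 1.3, 0.0)), ("H", "THR", 2, (3.9, 0.5, 0.0)),
    ("CA", "THR", 2, (4.2, 2.5, 0.0)), ("CB", "THR", 2, (5.1, 2.5, 1.2)),
    ("OG1", "THR", 2, (6.0, 3.6, 1.2)), ("HG1", "THR", 2, (6.6, 3.5, 2.0)),
    ("CG2", "THR", 2, (5.9, 2.5, 2.5)),
    ("C", "THR", 2, (5.0, 2.6, -1.3)), ("O", "THR", 2, (4.5, 3.1, -2.3)),
    # Asp3
    ("N", "ASP", 3, (6.3, 2.2, -1.3)), ("H", "ASP", 3, (6.7, 1.8, -0.5)),
    ("CA", "ASP", 3, (7.2, 2.3, -2.4)), ("CB", "ASP", 3, (8.5, 3.0, -2.0)),
    ("CG", "ASP", 3, (9.5, 3.1, -3.1)),
    ("OD1", "ASP", 3, (9.2, 3.7, -4.2)), ("OD2", "ASP", 3, (10.7, 2.6, -2.9)),
    ("C", "ASP", 3, (7.5, 0.9, -2.9)), ("O", "ASP", 3, (7.2, -0.1, -2.2)),
]


@pytest.fixture()
def water_pdb(tmp_path):
    p = tmp_path / "water.pdb"
    p.write_text(WATER_PDB)
    return p


@pytest.fixture()
def tripeptide_pdb(tmp_path):
    p = tmp_path / "tripeptide.pdb"
    p.write_text(make_pdb(TRIPEPTIDE_ATOMS))
    return p


def micro_topology(atoms, bonds=(), donors=None, acceptors=(),
                   rings=(), charged=(), hydrophobic=()):
    """Hand-annotated topology for controlled detector geometry.

    atoms: (name, element, resname, resnum, is_water, is_ligand) tuples.
    Annotation arguments use atom indices directly.
    """
    n = len(atoms)
    names = np.array([a[0] for a in atoms], dtype=object)
    elements = np.array([a[1] for a in atoms], dtype=object)
    resnames = np.array([a[2] for a in atoms], dtype=object)
    resnums = np.array([a[3] for a in atoms], dtype=int)
    chains = np.array(["A"] * n, dtype=object)
    is_water = np.array([a[4] for a in atoms], dtype=bool)
    is_ligand = np.array([a[5] for a in atoms], dtype=bool)
    mol = np.zeros(n, dtype=int)
    for i in range(n):
        mol[i] = resnums[i]
    topo = Topology(names=names, elements=elements, resnames=resnames,
                    resnums=resnums, chain_ids=chains, is_water=is_water,
                    is_ligand=is_ligand, molecule_ids=mol,
                    bonds=[tuple(b) for b in bonds])
    ann = topo.annotations
    for heavy, hs in (donors or {}).items():
        ann.donor_hydrogens[heavy] = list(hs)
    ann.acceptors.update(acceptors)
    for ring in rings:
        ann.aromatic_rings.append(list(ring))
    for group, sign in charged:
        ann.charged_groups.append((list(group), sign))
    ann.hydrophobic.update(hydrophobic)
    return topo


@pytest.fixture(scope="session")
def small_run():
    """Small synthetic run shared across tests (3 replicas x 80 frames)."""
    import bindmode as bm
    cfg = bm.GeneratorConfig(n_replicas=3, n_frames=80, n_waters=16,
                             water_exchange_rate=4.0, seed=42)
    traj = bm.simulate(cfg)
    return traj


@pytest.fixture(scope="session")
def small_frames(small_run):
    return {r: list(small_run.replica(r))
            for r in range(small_run.config.n_replicas)}
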