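"""Topology/trajectory reading, chemical annotation and atom selection.

File parsing is delegated to MDAnalysis (multi-model PDB, DCD, XTC).
Chemical annotation of standard residues and water comes from the built-in
template table; ligand chemistry comes from a YAML sidecar (preferred) or,
as a fallback, RDKit bond-order/aromaticity perception.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
import yaml

from . import templates as T
from .errors import (
    AnnotationError,
    FormatError,
    ParseError,
    TopologyError,
)

_KNOWN_ELEMENTS = {
    "H", "C", "N", "O", "S", "P", "F", "CL", "BR", "I", "NA", "K", "MG",
    "CA", "ZN", "FE", "SE", "B",
}

BACKBONE_NAMES = {"N", "CA", "C", "O", "OXT"}


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class Annotations:
    """Per-atom and per-group chemical annotation of a topology."""

    donor_hydrogens: dict[int, list[int]] = field(default_factory=dict)
    acceptors: set[int] = field(default_factory=set)
    formal_charges: dict[int, int] = field(default_factory=dict)
    aromatic_rings: list[list[int]] = field(default_factory=list)
    charged_groups: list[tuple[list[int], int]] = field(default_factory=list)
    hydrophobic: set[int] = field(default_factory=set)


@dataclass
class Topology:
    """Atoms, bonds and chemistry of one simulated system.

    Residue numbers follow author (1-based) numbering; atom indices are
    0-based throughout.
    """

    names: np.ndarray          # (n,) str
    elements: np.ndarray       # (n,) str, upper-case symbols
    resnames: np.ndarray       # (n,) str
    resnums: np.ndarray        # (n,) int
    chain_ids: np.ndarray      # (n,) str
    is_water: np.ndarray       # (n,) bool
    is_ligand: np.ndarray      # (n,) bool
    molecule_ids: np.ndarray   # (n,) int
    bonds: list[tuple[int, int]]
    annotations: Annotations = field(default_factory=Annotations)
    source_path: str | None = None

    @property
    def n_atoms(self) -> int:
        return len(self.names)

    @property
    def is_protein(self) -> np.ndarray:
        return ~self.is_water & ~self.is_ligand

    def adjacency(self) -> list[set[int]]:
        adj: list[set[int]] = [set() for _ in range(self.n_atoms)]
        for i, j in self.bonds:
            adj[i].add(j)
            adj[j].add(i)
        return adj

    def heavy_neighbors(self, i: int) -> list[int]:
        return [j for j in self._adj[i] if self.elements[j] != "H"]

    def __post_init__(self):
        self._adj = self.adjacency()

    def rebuild_adjacency(self) -> None:
        self._adj = self.adjacency()

    def residue_key(self, i: int) -> tuple[int, str, str]:
        """(residue number, residue name, chain) of atom i."""
        return (int(self.resnums[i]), str(self.resnames[i]),
                str(self.chain_ids[i]))

    def atom_index(self, resnum: int, name: str) -> int:
        hits = np.flatnonzero((self.resnums == resnum) & (self.names == name))
        if len(hits) == 0:
            raise AnnotationError(
                f"atom {name!r} of residue {resnum} not found in topology")
        return int(hits[0])

    def validate(self) -> None:
        """Check structural invariants; raise on violation."""
        n = self.n_atoms
        for i, j in self.bonds:
            if not (0 <= i < n and 0 <= j < n):
                raise TopologyError(f"bond ({i},{j}) references invalid atoms")
        for mol in np.unique(self.molecule_ids[self.is_water]):
            sel = (self.molecule_ids == mol) & self.is_water
            n_ox = int(np.sum(self.elements[sel] == "O"))
            if n_ox != 1:
                raise TopologyError(
                    f"water molecule {mol} has {n_ox} oxygens (expected 1)")
        bondset = {frozenset(b) for b in self.bonds}
        for ring in self.annotations.aromatic_rings:
            if len(ring) < 5:
                raise AnnotationError(
                    f"aromatic ring {ring} has fewer than 5 members")
            for a, b in zip(ring, ring[1:] + ring[:1]):
                if frozenset((a, b)) not in bondset:
                    raise AnnotationError(
                        f"ring {ring} is not cyclic under the bond list")
        ann = self.annotations
        for idx in list(ann.acceptors) + list(ann.hydrophobic):
            if not 0 <= idx < n:
                raise AnnotationError(f"annotation references atom {idx}")
        for heavy, hs in ann.donor_hydrogens.items():
            if not 0 <= heavy < n or any(not 0 <= h < n for h in hs):
                raise AnnotationError("donor annotation references bad atom")


@dataclass
class Frame:
    """One trajectory frame: coordinates in Å, optional periodic box, time."""

    coordinates: np.ndarray            # (n, 3) float, Å
    box: np.ndarray | None = None      # (3, 3) box vectors, Å
    time_ns: float = 0.0

    def __post_init__(self):
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        if self.box is not None:
            self.box = np.asarray(self.box, dtype=float)
            if abs(np.linalg.det(self.box)) < 1e-9:
                raise TopologyError("box vectors are linearly dependent")
        if self.time_ns < 0:
            raise TopologyError("negative frame timestamp")


@dataclass(frozen=True)
class Selection:
    """Sorted, unique 0-based atom indices plus the expression that made them."""

    indices: tuple[int, ...]
    provenance: str = ""

    def __len__(self) -> int:
        return len(self.indices)

    def as_array(self) -> np.ndarray:
        return np.asarray(self.indices, dtype=int)


# ---------------------------------------------------------------------------
# topology loading
# ---------------------------------------------------------------------------

def _guess_element(name: str) -> str:
    stripped = name.strip().lstrip("0123456789")
    if not stripped:
        raise AnnotationError(f"cannot infer element for atom named {name!r}")
    two = stripped[:2].upper()
    if two in {"CL", "BR", "NA", "MG", "ZN", "FE", "SE"} and len(name) > 1:
        return two
    return stripped[0].upper()


def load_topology(path: str | Path,
                  ligand_template: str | Path | None = None) -> Topology:
    """Read a PDB topology (CONECT honored) and annotate its chemistry.

    Standard residues and waters are annotated from the built-in template
    table; ligand chemistry comes from the YAML sidecar ``ligand_template``
    or, when absent, from RDKit perception of the ligand's bond graph.
    """
    import MDAnalysis as mda

    path = Path(path)
    if not path.exists():
        raise FormatError(f"cannot read topology file: {path}")
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            u = mda.Universe(str(path))
    except Exception as exc:  # pragma: no cover - MDA raises various types
        raise FormatError(f"unreadable topology {path}: {exc}") from exc

    n = len(u.atoms)
    names = np.array([a.name for a in u.atoms], dtype=object)
    resnames = np.array([a.resname.strip().upper() for a in u.atoms],
                        dtype=object)
    resnums = np.array([a.resid for a in u.atoms], dtype=int)
    try:
        chain_ids = np.array(
            [(a.chainID if a.chainID.strip() else "A") for a in u.atoms],
            dtype=object)
    except mda.exceptions.NoDataError:
        chain_ids = np.array(["A"] * n, dtype=object)

    elements = np.empty(n, dtype=object)
    try:
        file_elems = [e.strip().upper() for e in u.atoms.elements]
    except mda.exceptions.NoDataError:
        file_elems = [""] * n
    for i in range(n):
        elem = file_elems[i] or _guess_element(str(names[i]))
        if elem not in _KNOWN_ELEMENTS:
            raise AnnotationError(
                f"unknown element {elem!r} for atom {names[i]} "
                f"in residue {resnames[i]}{resnums[i]}")
        elements[i] = elem

    is_water = np.array([T.is_water_resname(r) for r in resnames])
    is_ligand = np.array(
        [not w and not T.is_standard_resname(r)
         for w, r in zip(is_water, resnames)])

    conect_bonds: list[tuple[int, int]] = []
    if hasattr(u, "bonds"):
        conect_bonds = [(int(b[0].index), int(b[1].index)) for b in u.bonds]

    topo = _assemble_topology(names, elements, resnames, resnums, chain_ids,
                              is_water, is_ligand, conect_bonds)
    topo.source_path = str(path)
    _annotate_standard(topo)
    if np.any(topo.is_ligand):
        if ligand_template is not None:
            _annotate_ligand_from_sidecar(topo, ligand_template)
        else:
            _annotate_ligand_by_perception(topo)
    topo.validate()
    return topo


def _assemble_topology(names, elements, resnames, resnums, chain_ids,
                       is_water, is_ligand, extra_bonds) -> Topology:
    """Merge CONECT bonds with template bonds and assign molecule ids."""
    n = len(names)
    bonds: set[frozenset[int]] = {frozenset(b) for b in extra_bonds
                                  if b[0] != b[1]}

    # group atoms into residues in file order
    residues: list[list[int]] = []
    last_key = None
    for i in range(n):
        key = (resnums[i], resnames[i], chain_ids[i])
        if key != last_key:
            residues.append([])
            last_key = key
        residues[-1].append(i)

    for res_atoms in residues:
        rname = T.canonical_resname(str(resnames[res_atoms[0]]))
        local = {str(names[i]): i for i in res_atoms}
        heavy_names = [str(names[i]) for i in res_atoms
                       if elements[i] != "H"]
        if T.is_water_resname(rname):
            ox = [i for i in res_atoms if elements[i] == "O"]
            for i in res_atoms:
                if elements[i] == "H" and ox:
                    bonds.add(frozenset((i, ox[0])))
            continue
        if rname in T.SIDECHAIN_BONDS:
            for a, b in T.BACKBONE_BONDS + T.SIDECHAIN_BONDS[rname]:
                if a in local and b in local:
                    bonds.add(frozenset((local[a], local[b])))
            if "OXT" in local and "C" in local:
                bonds.add(frozenset((local["OXT"], local["C"])))
            for i in res_atoms:
                if elements[i] == "H":
                    parent = T.hydrogen_parent(str(names[i]), heavy_names)
                    if parent is not None:
                        bonds.add(frozenset((i, local[parent])))

    # peptide bonds between consecutive standard residues on one chain
    for prev, cur in zip(residues, residues[1:]):
        pname = str(resnames[prev[0]])
        cname = str(resnames[cur[0]])
        if (T.is_standard_resname(pname) and T.is_standard_resname(cname)
                and chain_ids[prev[0]] == chain_ids[cur[0]]):
            pl = {str(names[i]): i for i in prev}
            cl = {str(names[i]): i for i in cur}
            if "C" in pl and "N" in cl:
                bonds.add(frozenset((pl["C"], cl["N"])))

    bond_list = sorted(tuple(sorted(b)) for b in bonds)

    # molecule ids: connected components, but force each residue's atoms
    # together and keep all standard residues of a chain in one molecule
    molecule_ids = np.full(n, -1, dtype=int)
    mol = 0
    for res_atoms in residues:
        if molecule_ids[res_atoms[0]] >= 0:
            continue
        # flood fill over bonds restricted to unassigned atoms
        stack = list(res_atoms)
        adj: dict[int, set[int]] = {}
        for a, b in bond_list:
            adj.setdefault(a, set()).add(b)
            adj.setdefault(b, set()).add(a)
        while stack:
            i = stack.pop()
            if molecule_ids[i] >= 0:
                continue
            molecule_ids[i] = mol
            stack.extend(adj.get(i, ()))
        mol += 1

    return Topology(names=names, elements=elements, resnames=resnames,
                    resnums=resnums, chain_ids=chain_ids, is_water=is_water,
                    is_ligand=is_ligand, molecule_ids=molecule_ids,
                    bonds=[tuple(b) for b in bond_list])


def _annotate_standard(topo: Topology) -> None:
    """Template-driven annotation of standard residues and waters."""
    ann = topo.annotations
    n = topo.n_atoms
    attached_h: dict[int, list[int]] = {}
    for i, j in topo.bonds:
        if topo.elements[i] == "H":
            attached_h.setdefault(j, []).append(i)
        if topo.elements[j] == "H":
            attached_h.setdefault(i, []).append(j)

    # group by residue
    res_groups: dict[tuple, list[int]] = {}
    for i in range(n):
        res_groups.setdefault(topo.residue_key(i), []).append(i)

    for (resnum, resname, chain), atoms in res_groups.items():
        rname = T.canonical_resname(resname)
        local = {str(topo.names[i]): i for i in atoms}
        if T.is_water_resname(rname):
            ox = [i for i in atoms if topo.elements[i] == "O"]
            if ox:
                ann.acceptors.add(ox[0])
                hs = attached_h.get(ox[0], [])
                if hs:
                    ann.donor_hydrogens[ox[0]] = sorted(hs)
            continue
        if rname not in T.SIDECHAIN_BONDS:
            continue  # ligand handled elsewhere
        # backbone
        if "O" in local:
            ann.acceptors.add(local["O"])
        if "OXT" in local:
            ann.acceptors.add(local["OXT"])
        if rname != "PRO" and "N" in local:
            hs = attached_h.get(local["N"], [])
            if hs:
                ann.donor_hydrogens[local["N"]] = sorted(hs)
        # side chain
        for dname in T.POTENTIAL_DONORS.get(rname, []):
            if dname in local:
                hs = attached_h.get(local[dname], [])
                if hs:
                    ann.donor_hydrogens[local[dname]] = sorted(hs)
        for aname in T.ACCEPTORS.get(rname, []):
            if aname in local:
                idx = local[aname]
                # an N acceptor is vetoed by an attached hydrogen (it donates)
                if topo.elements[idx] == "N" and attached_h.get(idx):
                    continue
                ann.acceptors.add(idx)
        if rname in T.CHARGED_GROUPS:
            group_names, sign = T.CHARGED_GROUPS[rname]
            group = [local[g] for g in group_names if g in local]
            if group:
                ann.charged_groups.append((sorted(group), sign))
                ann.formal_charges[group[-1]] = sign
        for ring_names in T.AROMATIC_RINGS.get(rname, []):
            if all(r in local for r in ring_names):
                ann.aromatic_rings.append([local[r] for r in ring_names])
        for cname in T.HYDROPHOBIC_CARBONS.get(rname, []):
            if cname in local:
                ann.hydrophobic.add(local[cname])


def _annotate_ligand_from_sidecar(topo: Topology,
                                  sidecar: str | Path) -> None:
    """Apply the YAML ligand annotation sidecar (the preferred source)."""
    sidecar = Path(sidecar)
    if not sidecar.exists():
        raise FormatError(f"ligand sidecar not found: {sidecar}")
    apply_ligand_annotations(topo, yaml.safe_load(sidecar.read_text()))


def apply_ligand_annotations(topo: Topology, mapping: dict) -> None:
    """Annotate ligand chemistry from a sidecar-style mapping.

    Keys: ``donors`` (heavy atom name -> hydrogen names), ``acceptors``,
    ``aromatic_rings`` (lists of atom names), ``charged_groups``
    (``{atoms: [...], charge: +-1}``), ``hydrophobic``.
    """
    lig_idx = np.flatnonzero(topo.is_ligand)
    local = {str(topo.names[i]): int(i) for i in lig_idx}

    def resolve(name: str) -> int:
        if name not in local:
            raise AnnotationError(
                f"sidecar references unknown ligand atom {name!r}")
        return local[name]

    ann = topo.annotations
    for heavy, hs in (mapping.get("donors") or {}).items():
        ann.donor_hydrogens[resolve(heavy)] = sorted(resolve(h) for h in hs)
    for a in mapping.get("acceptors") or []:
        ann.acceptors.add(resolve(a))
    for ring in mapping.get("aromatic_rings") or []:
        ann.aromatic_rings.append([resolve(a) for a in ring])
    for grp in mapping.get("charged_groups") or []:
        atoms = sorted(resolve(a) for a in grp["atoms"])
        sign = int(grp["charge"])
        ann.charged_groups.append((atoms, sign))
        ann.formal_charges[atoms[-1]] = sign
    for c in mapping.get("hydrophobic") or []:
        ann.hydrophobic.add(resolve(c))


def _annotate_ligand_by_perception(topo: Topology) -> None:
    """Fallback ligand annotation via RDKit perception of the bond graph.

    Less reliable than a sidecar (no bond orders in PDB): aromaticity is
    perceived from ring geometry/valence after sanitization, donors are N/O
    with attached hydrogens, acceptors are N/O without full substitution.
    """
    try:
        from rdkit import Chem
    except ImportError as exc:  # pragma: no cover
        raise AnnotationError(
            "no ligand sidecar given and RDKit is unavailable for "
            "perception") from exc

    lig_idx = [int(i) for i in np.flatnonzero(topo.is_ligand)]
    pos = {g: k for k, g in enumerate(lig_idx)}
    mol = Chem.RWMol()
    for g in lig_idx:
        mol.AddAtom(Chem.Atom(str(topo.elements[g]).capitalize()))
    for i, j in topo.bonds:
        if i in pos and j in pos:
            mol.AddBond(pos[i], pos[j], Chem.BondType.SINGLE)
    try:
        Chem.SanitizeMol(mol)
    except Exception as exc:
        raise AnnotationError(
            f"RDKit perception of the ligand failed ({exc}); "
            "provide a sidecar annotation file") from exc

    ann = topo.annotations
    adj = topo.adjacency()
    for g in lig_idx:
        elem = str(topo.elements[g])
        hs = sorted(j for j in adj[g] if topo.elements[j] == "H")
        if elem in ("N", "O"):
            if hs:
                ann.donor_hydrogens[g] = hs
            ann.acceptors.add(g)
        if elem == "C" and not any(
                topo.elements[j] in ("N", "O") for j in adj[g]):
            ann.hydrophobic.add(g)
    ri = mol.GetRingInfo()
    for ring in ri.AtomRings():
        if len(ring) >= 5:
            ann.aromatic_rings.append([lig_idx[k] for k in ring])


# ---------------------------------------------------------------------------
# trajectory loading / writing
# ---------------------------------------------------------------------------

def _box_from_dimensions(dimensions) -> np.ndarray | None:
    from MDAnalysis.lib.mdamath import triclinic_vectors
    if dimensions is None or not np.any(dimensions[:3]):
        return None
    return np.asarray(triclinic_vectors(dimensions), dtype=float)


def load_trajectory(topology: Topology, path: str | Path,
                    stride_ns: float = 1.0,
                    frame_spacing_ns: float | None = None,
                    ) -> Iterator[Frame]:
    """Iterate frames of a multi-model PDB, DCD or XTC file.

    The stride is applied by *time*, not by frame index: a frame is emitted
    when its timestamp reaches the next multiple of ``stride_ns`` past the
    previously emitted frame. Formats without reliable embedded times
    (PDB, and DCD files of unknown provenance when ``frame_spacing_ns`` is
    given) are assigned timestamps ``index * frame_spacing_ns``
    (default spacing 1 ns).
    """
    import MDAnalysis as mda

    path = Path(path)
    if not path.exists():
        raise FormatError(f"cannot read trajectory file: {path}")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u = mda.Universe.empty(topology.n_atoms, trajectory=True)
        try:
            u.load_new(str(path))
        except ValueError as exc:
            # MDA raises ValueError on atom-count mismatch
            raise TopologyError(
                f"trajectory {path} does not match topology "
                f"({topology.n_atoms} topology atoms): {exc}") from exc

    is_pdb = path.suffix.lower() in (".pdb", ".ent")
    use_file_time = frame_spacing_ns is None and not is_pdb
    spacing = 1.0 if frame_spacing_ns is None else float(frame_spacing_ns)

    next_emit = None
    for k, ts in enumerate(u.trajectory):
        if ts.n_atoms != topology.n_atoms:
            raise TopologyError(
                f"frame has {ts.n_atoms} atoms, topology has "
                f"{topology.n_atoms}")
        if use_file_time:
            time_ns = float(ts.time) / 1000.0  # MDAnalysis time unit is ps
        else:
            time_ns = k * spacing
        if next_emit is None:
            next_emit = time_ns
        if time_ns + 1e-9 >= next_emit:
            yield Frame(coordinates=np.array(ts.positions, dtype=float),
                        box=_box_from_dimensions(ts.dimensions),
                        time_ns=time_ns)
            next_emit = time_ns + stride_ns


def write_frames_pdb(topology: Topology, frames: Iterable[Frame],
                     path: str | Path) -> None:
    """Write frames as a multi-model PDB (MODEL/ENDMDL, CONECT, element col)."""
    path = Path(path)
    lines: list[str] = []
    hetero = topology.is_water | topology.is_ligand
    for m, fr in enumerate(frames, start=1):
        if fr.coordinates.shape[0] != topology.n_atoms:
            raise TopologyError(
                f"frame has {fr.coordinates.shape[0]} atoms, topology has "
                f"{topology.n_atoms}")
        lines.append(f"MODEL     {m:4d}")
        lines.append(f"REMARK 250 TIME_NS {fr.time_ns:.6f}")
        if fr.box is not None:
            a, b, c, al, be, ga = _box_to_lengths_angles(fr.box)
            lines.append(
                f"CRYST1{a:9.3f}{b:9.3f}{c:9.3f}"
                f"{al:7.2f}{be:7.2f}{ga:7.2f} P 1           1")
        for i in range(topology.n_atoms):
            rec = "HETATM" if hetero[i] else "ATOM  "
            name = str(topology.names[i])
            fmt_name = name if len(name) == 4 else f" {name:<3s}"
            x, y, z = fr.coordinates[i]
            elem = str(topology.elements[i])
            lines.append(
                f"{rec}{(i % 99999) + 1:5d} {fmt_name:<4s} "
                f"{str(topology.resnames[i]):<3s} "
                f"{str(topology.chain_ids[i])[:1]}"
                f"{int(topology.resnums[i]) % 10000:4d}    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}"
                f"          {elem:>2s}")
        lines.append("ENDMDL")
    # CONECT for hetero atoms only (standard residues are template-bonded)
    for i, j in topology.bonds:
        if hetero[i] or hetero[j]:
            lines.append(f"CONECT{i + 1:5d}{j + 1:5d}")
    lines.append("END")
    path.write_text("\n".join(lines) + "\n")


def _box_to_lengths_angles(box: np.ndarray):
    a, b, c = (np.linalg.norm(v) for v in box)

    def ang(u, v):
        return float(np.degrees(np.arccos(
            np.clip(np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v)),
                    -1, 1))))

    return a, b, c, ang(box[1], box[2]), ang(box[0], box[2]), ang(box[0], box[1])


# ---------------------------------------------------------------------------
# selection mini-language
# ---------------------------------------------------------------------------

_KEYWORDS = {"backbone", "calpha", "water", "ligand", "protein",
             "and", "or", "not", "residue", "name", "chain", "resname"}


def _tokenize(expr: str) -> list[tuple[str, int]]:
    tokens: list[tuple[str, int]] = []
    i = 0
    while i < len(expr):
        ch = expr[i]
        if ch.isspace():
            i += 1
            continue
        if ch in "()":
            tokens.append((ch, i))
            i += 1
            continue
        j = i
        while j < len(expr) and not expr[j].isspace() and expr[j] not in "()":
            j += 1
        tokens.append((expr[i:j], i))
        i = j
    return tokens


class _SelParser:
    """Recursive-descent parser for the selection mini-grammar."""

    def __init__(self, topology: Topology, expr: str):
        self.topo = topology
        self.expr = expr
        self.tokens = _tokenize(expr)
        self.pos = 0

    def peek(self):
        return self.tokens[self.pos] if self.pos < len(self.tokens) else None

    def take(self):
        tok = self.peek()
        if tok is None:
            raise ParseError(f"unexpected end of expression {self.expr!r}",
                             len(self.expr))
        self.pos += 1
        return tok

    def parse(self) -> np.ndarray:
        if not self.tokens:
            raise ParseError("empty selection expression", 0)
        mask = self.parse_or()
        if self.peek() is not None:
            tok, at = self.peek()
            raise ParseError(f"unexpected token {tok!r}", at)
        return mask

    def parse_or(self) -> np.ndarray:
        mask = self.parse_and()
        while self.peek() and self.peek()[0].lower() == "or":
            self.take()
            mask = mask | self.parse_and()
        return mask

    def parse_and(self) -> np.ndarray:
        mask = self.parse_unary()
        while self.peek() and self.peek()[0].lower() == "and":
            self.take()
            mask = mask & self.parse_unary()
        return mask

    def parse_unary(self) -> np.ndarray:
        tok = self.peek()
        if tok and tok[0].lower() == "not":
            self.take()
            return ~self.parse_unary()
        return self.parse_primary()

    def _is_value_token(self, tok: str) -> bool:
        return tok.lower() not in _KEYWORDS and tok not in "()"

    def parse_primary(self) -> np.ndarray:
        topo = self.topo
        tok, at = self.take()
        low = tok.lower()
        if tok == "(":
            mask = self.parse_or()
            nxt = self.take()
            if nxt[0] != ")":
                raise ParseError(f"expected ')', got {nxt[0]!r}", nxt[1])
            return mask
        if low == "backbone":
            return (np.isin(topo.names.astype(str), list(BACKBONE_NAMES))
                    & topo.is_protein)
        if low == "calpha":
            return (topo.names.astype(str) == "CA") & topo.is_protein
        if low == "water":
            return topo.is_water.copy()
        if low == "ligand":
            return topo.is_ligand.copy()
        if low == "protein":
            return topo.is_protein.copy()
        if low in ("residue", "name", "chain", "resname"):
            values = []
            while self.peek() and self._is_value_token(self.peek()[0]):
                values.append(self.take()[0])
            if not values:
                raise ParseError(f"{tok!r} requires at least one value", at)
            return self._match_values(low, values, at)
        raise ParseError(f"unknown token {tok!r}", at)

    def _match_values(self, kind: str, values: Sequence[str],
                      at: int) -> np.ndarray:
        topo = self.topo
        mask = np.zeros(topo.n_atoms, dtype=bool)
        for v in values:
            if kind == "residue":
                if "-" in v[1:]:
                    lo_s, hi_s = v.split("-", 1) if not v.startswith("-") \
                        else (v[0] + v[1:].split("-", 1)[0],
                              v[1:].split("-", 1)[1])
                    try:
                        lo, hi = int(lo_s), int(hi_s)
                    except ValueError:
                        raise ParseError(f"bad residue range {v!r}", at)
                    mask |= (topo.resnums >= lo) & (topo.resnums <= hi)
                elif v.lstrip("-").isdigit():
                    mask |= topo.resnums == int(v)
                else:
                    mask |= topo.resnames.astype(str) == v.upper()
            elif kind == "name":
                mask |= topo.names.astype(str) == v
            elif kind == "chain":
                mask |= topo.chain_ids.astype(str) == v
            elif kind == "resname":
                mask |= topo.resnames.astype(str) == v.upper()
        return mask


def select(topology: Topology, expr: str) -> Selection:
    """Resolve a selection expression to a deterministic, sorted Selection.

    Grammar: ``residue <num|lo-hi|NAME>...``, ``name <ATOM>...``,
    ``chain <ID>...``, ``resname <NAME>...``, keywords ``backbone``,
    ``calpha``, ``water``, ``ligand``, ``protein``, combined with
    ``and`` / ``or`` / ``not`` and parentheses. An empty result is a valid
    empty Selection, not an error.
    """
    mask = _SelParser(topology, expr).parse()
    idx = tuple(int(i) for i in np.flatnonzero(mask))
    return Selection(indices=idx, provenance=expr)
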