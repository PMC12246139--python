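"""Interaction detectors against constructed geometries and a literal
brute-force oracle, plus fraction aggregation rules."""

import dataclasses

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

import bindmode as bm
from bindmode.fingerprints import InteractionCriteria, aggregate_fractions
from bindmode.structure_io import Frame
from conftest import micro_topology
from oracle_detectors import event_identity_set, oracle_all_events


# ---------------------------------------------------------------------------
# constructed single-interaction systems
# ---------------------------------------------------------------------------

def _nh_co_system(h_to_o: float):
    """Protein N-H donor pointing at a ligand O=C acceptor, linear."""
    topo = micro_topology(
        atoms=[("N", "N", "GLY", 1, False, False),
               ("H", "H", "GLY", 1, False, False),
               ("O1", "O", "LIG", 9, False, True),
               ("C9", "C", "LIG", 9, False, True)],
        bonds=[(0, 1), (2, 3)],
        donors={0: [1]}, acceptors=[2])
    coords = np.array([[0, 0, 0], [1.0, 0, 0],
                       [1.0 + h_to_o, 0, 0], [2.23 + h_to_o, 0, 0]])
    return topo, Frame(coordinates=coords, time_ns=0)


class TestHbonds:
    def test_ideal_linear_geometry(self):
        topo, frame = _nh_co_system(1.9)
        events = bm.detect_hbonds(frame, topo)
        assert len(events) == 1
        ev = events[0]
        assert ev.type == "hbond" and ev.direction == "protein"
        assert ev.residue == (1, "GLY", "A")

    def test_too_far(self):
        topo, frame = _nh_co_system(3.5)
        assert bm.detect_hbonds(frame, topo) == []

    def test_donor_angle_vetoes(self):
        topo, frame = _nh_co_system(1.9)
        # bend the hydrogen so D-H...A drops below 120 deg
        frame.coordinates[1] = [0.2, 0.98, 0]
        assert bm.detect_hbonds(frame, topo) == []

    def test_donor_without_hydrogen_raises(self):
        topo, frame = _nh_co_system(1.9)
        topo.annotations.donor_hydrogens[0] = []
        with pytest.raises(bm.AnnotationError):
            bm.detect_hbonds(frame, topo)


def _bridge_system():
    """Water ideally H-bonded to a protein carbonyl and a ligand ether."""
    topo = micro_topology(
        atoms=[("O", "O", "GLY", 1, False, False),
               ("C", "C", "GLY", 1, False, False),
               ("O2", "O", "LIG", 9, False, True),
               ("C8", "C", "LIG", 9, False, True),
               ("OW", "O", "HOH", 50, True, False),
               ("H1", "H", "HOH", 50, True, False),
               ("H2", "H", "HOH", 50, True, False)],
        bonds=[(0, 1), (2, 3), (4, 5), (4, 6)],
        acceptors=[0, 2])
    u = np.array([1.0, 0, 0])
    d2 = np.array([0.2504, 0.9681, 0.0])
    o_prot = np.zeros(3)
    wh1 = o_prot + 1.9 * u
    wo = o_prot + 2.86 * u
    wh2 = wo + 0.96 * d2
    o_lig = wo + 2.86 * d2
    coords = np.stack([o_prot, o_prot - 1.23 * u, o_lig, o_lig + 1.4 * d2,
                       wo, wh1, wh2])
    return topo, Frame(coordinates=coords, time_ns=0)


class TestWaterBridges:
    def test_ideal_bridge(self):
        topo, frame = _bridge_system()
        events = bm.detect_water_bridges(frame, topo)
        assert len(events) == 1
        ev = events[0]
        assert ev.type == "water_bridge"
        assert ev.water_molecule_id == 50
        assert ev.residue == (1, "GLY", "A")

    def test_protein_only_is_no_bridge(self):
        topo, frame = _bridge_system()
        frame.coordinates[2] += [0, 8.0, 0]  # pull the ligand ether away
        frame.coordinates[3] += [0, 8.0, 0]
        assert bm.detect_water_bridges(frame, topo) == []


def _ring_pair(separation, tilt_deg):
    topo = micro_topology(
        atoms=[(f"C{k}", "C", "TYR", 1, False, False) for k in range(6)]
        + [(f"D{k}", "C", "LIG", 9, False, True) for k in range(6)],
        bonds=[(k, (k + 1) % 6) for k in range(6)]
        + [(6 + k, 6 + (k + 1) % 6) for k in range(6)],
        rings=[list(range(6)), list(range(6, 12))])
    ring = np.array([[1.39 * np.cos(np.radians(60 * k)),
                      1.39 * np.sin(np.radians(60 * k)), 0.0]
                     for k in range(6)])
    rot = Rotation.from_euler("x", tilt_deg, degrees=True).as_matrix()
    other = ring @ rot.T + np.array([0, 0, separation])
    return topo, Frame(coordinates=np.vstack([ring, other]), time_ns=0)


class TestPiInteractions:
    def test_face_to_face(self):
        topo, frame = _ring_pair(3.8, 0)
        events = bm.detect_pi_interactions(frame, topo)
        assert [ev.type for ev in events] == ["pi_pi"]

    def test_edge_to_face(self):
        topo, frame = _ring_pair(5.0, 90)
        events = bm.detect_pi_interactions(frame, topo)
        assert [ev.type for ev in events] == ["pi_pi"]

    def test_tilted_midrange_is_rejected(self):
        topo, frame = _ring_pair(5.0, 45)
        assert bm.detect_pi_interactions(frame, topo) == []

    def test_pication_distance(self):
        topo = micro_topology(
            atoms=[(f"C{k}", "C", "HIS", 1, False, False)
                   for k in range(6)]
            + [("N3", "N", "LIG", 9, False, True)],
            bonds=[(k, (k + 1) % 6) for k in range(6)],
            rings=[list(range(6))],
            charged=[([6], +1)])
        ring = np.array([[1.2 * np.cos(np.radians(60 * k)),
                          1.2 * np.sin(np.radians(60 * k)), 0.0]
                         for k in range(6)])
        for z, expected in ((3.5, 1), (5.0, 0)):
            coords = np.vstack([ring, [[0, 0, z]]])
            events = bm.detect_pi_interactions(
                Frame(coordinates=coords, time_ns=0), topo)
            assert len(events) == expected


class TestNonpolarIonic:
    def _system(self, cc: float, charge_sep: float):
        topo = micro_topology(
            atoms=[("CB", "C", "TYR", 1, False, False),
                   ("OD1", "O", "ASP", 2, False, False),
                   ("CM", "C", "LIG", 9, False, True),
                   ("NP", "N", "LIG", 9, False, True)],
            charged=[([1], -1), ([3], +1)],
            hydrophobic=[0, 2])
        coords = np.array([[0, 0, 0], [0, 10, 0],
                           [cc, 0, 0], [charge_sep, 10, 0]], float)
        return topo, Frame(coordinates=coords, time_ns=0)

    def test_hydrophobic_within_default(self):
        topo, frame = self._system(3.5, 20.0)
        events = bm.detect_nonpolar_and_ionic(frame, topo)
        assert [ev.type for ev in events] == ["hydrophobic"]

    def test_distant_charges_no_ionic(self):
        topo, frame = self._system(10.0, 10.0)
        assert bm.detect_nonpolar_and_ionic(frame, topo) == []

    def test_ionic_close(self):
        topo, frame = self._system(10.0, 3.2)
        events = bm.detect_nonpolar_and_ionic(frame, topo)
        assert [ev.type for ev in events] == ["ionic"]


# ---------------------------------------------------------------------------
# randomized oracle equivalence
# ---------------------------------------------------------------------------

def random_micro_system():
    """Micro-topology with every feature class, for randomized placement."""
    atoms = [
        ("N", "N", "SER", 10, False, False),     # 0 protein donor
        ("H", "H", "SER", 10, False, False),     # 1
        ("O", "O", "SER", 10, False, False),     # 2 protein acceptor
        ("C", "C", "SER", 10, False, False),     # 3 its substituent
    ]
    atoms += [(f"C{k}", "C", "PHE", 11, False, False) for k in range(6)]
    atoms += [("NZ", "N", "LYS", 12, False, False),   # 10 cation + donor
              ("HZ1", "H", "LYS", 12, False, False),  # 11
              ("CG", "C", "ASP", 13, False, False),   # 12
              ("OD1", "O", "ASP", 13, False, False),  # 13
              ("OD2", "O", "ASP", 13, False, False)]  # 14
    atoms += [("N1", "N", "LIG", 99, False, True),    # 15 ligand donor
              ("H1", "H", "LIG", 99, False, True),    # 16
              ("O1", "O", "LIG", 99, False, True),    # 17 ligand acceptor
              ("C9", "C", "LIG", 99, False, True)]    # 18
    atoms += [(f"D{k}", "C", "LIG", 99, False, True) for k in range(6)]
    atoms += [("NP", "N", "LIG", 99, False, True),    # 25 ligand cation
              ("CM", "C", "LIG", 99, False, True)]    # 26 ligand apolar
    atoms += [("OW", "O", "HOH", 100, True, False),
              ("H1", "H", "HOH", 100, True, False),
              ("H2", "H", "HOH", 100, True, False),
              ("OW", "O", "HOH", 101, True, False),
              ("H1", "H", "HOH", 101, True, False),
              ("H2", "H", "HOH", 101, True, False)]
    bonds = [(0, 1), (2, 3), (10, 11), (12, 13), (12, 14), (15, 16),
             (17, 18), (27, 28), (27, 29), (30, 31), (30, 32)]
    bonds += [(4 + k, 4 + (k + 1) % 6) for k in range(6)]
    bonds += [(19 + k, 19 + (k + 1) % 6) for k in range(6)]
    return micro_topology(
        atoms, bonds,
        donors={0: [1], 10: [11], 15: [16]},
        acceptors=[2, 13, 14, 17],
        rings=[list(range(4, 10)), list(range(19, 25))],
        charged=[([10], +1), ([12, 13, 14], -1), ([25], +1)],
        hydrophobic=[5, 6, 26, 19])


_RIGID_GROUPS = [
    [0, 1], [2, 3], list(range(4, 10)), [10, 11], [12, 13, 14],
    [15, 16], [17, 18], list(range(19, 25)), [25], [26],
    [27, 28, 29], [30, 31, 32],
]

_LOCAL = {
    2: np.array([[0, 0, 0], [1.0, 0, 0]]),                 # X-H / X-C pairs
    3: np.array([[0, 0, 0], [1.0, 0, 0], [-0.25, 0.97, 0]]),
    6: np.array([[1.39 * np.cos(np.radians(60 * k)),
                  1.39 * np.sin(np.radians(60 * k)), 0.0]
                 for k in range(6)]),
    1: np.array([[0.0, 0.0, 0.0]]),
}


def random_micro_frame(topo, rng, box_edge=12.0):
    coords = np.zeros((topo.n_atoms, 3))
    for group in _RIGID_GROUPS:
        local = _LOCAL[3 if len(group) == 3 else min(len(group), 6)]
        local = local[:len(group)]
        rot = Rotation.random(rng=rng).as_matrix()
        origin = rng.uniform(0, box_edge, 3)
        coords[group] = local @ rot.T + origin
    return Frame(coordinates=coords, box=np.eye(3) * box_edge, time_ns=0)


class TestOracleEquivalence:
    def test_random_micro_frames_match_bruteforce(self):
        """Vectorized detectors reproduce the literal criteria verbatim."""
        topo = random_micro_system()
        rng = np.random.default_rng(2024)
        criteria = InteractionCriteria()
        checked_nonempty = 0
        for _ in range(60):
            frame = random_micro_frame(topo, rng)
            got = event_identity_set(bm.detect_all(frame, topo, criteria))
            want = oracle_all_events(frame, topo, criteria)
            assert got == want
            checked_nonempty += bool(want)
        assert checked_nonempty > 5  # placements actually produce contacts

    def test_monotonicity_under_loosened_thresholds(self):
        topo = random_micro_system()
        rng = np.random.default_rng(77)
        tight = InteractionCriteria()
        loose = InteractionCriteria(
            hbond_distance=3.2, hbond_donor_angle_min=100,
            hbond_acceptor_angle_min=60, wbridge_distance=3.4,
            wbridge_donor_angle_min=90, pication_distance=6.0,
            pipi_f2f_centroid_max=5.5, pipi_e2f_centroid_max=6.5,
            hydrophobic_distance=4.5, ionic_distance=5.0)
        for _ in range(25):
            frame = random_micro_frame(topo, rng)
            a = event_identity_set(bm.detect_all(frame, topo, tight))
            b = event_identity_set(bm.detect_all(frame, topo, loose))
            assert a <= b

    def test_determinism(self):
        topo = random_micro_system()
        rng = np.random.default_rng(5)
        frame = random_micro_frame(topo, rng)
        a = [ev.identity() for ev in bm.detect_all(frame, topo)]
        b = [ev.identity() for ev in bm.detect_all(frame, topo)]
        assert a == b


# ---------------------------------------------------------------------------
# aggregation
# ---------------------------------------------------------------------------

def _event(frame_index, residue=69, itype="hbond", replica=0):
    return bm.InteractionEvent(
        frame_index=frame_index, type=itype,
        residue=(residue, "ASP", "A"), residue_part="sidechain",
        ligand_atoms=(1,), replica=replica)


class TestAggregateFractions:
    def test_event_every_frame_gives_one(self):
        events = [_event(k) for k in range(10)]
        table = aggregate_fractions(events, 10)
        assert table.fraction(69, "hbond") == 1.0

    def test_per_frame_binarization(self):
        """Duplicate same-type contacts in one frame count once."""
        events = [_event(0), _event(0), _event(1)]
        table = aggregate_fractions(events, 4)
        assert table.fraction(69, "hbond") == 0.5

    def test_key_rule_strict_inequality(self):
        events = [_event(k) for k in range(51)]
        table = aggregate_fractions(events, 100)
        assert table.key_residues() == [(69, "ASP", "A")]
        table = aggregate_fractions([_event(k) for k in range(50)], 100)
        assert table.key_residues() == []

    def test_totals_sum_over_types(self):
        events = ([_event(k, itype="hbond") for k in range(6)]
                  + [_event(k, itype="hydrophobic") for k in range(8)])
        table = aggregate_fractions(events, 10)
        row = table.totals[table.totals.residue_number == 69]
        assert float(row["total"].iloc[0]) == pytest.approx(1.4)
        assert bool(row["displayed"].iloc[0])

    def test_replica_pooling(self):
        events = [_event(0, replica=r) for r in range(4)]
        table = aggregate_fractions(events, 8)
        assert table.fraction(69, "hbond") == 0.5

    def test_zero_frames_raises(self):
        with pytest.raises(bm.StatisticsError):
            aggregate_fractions([], 0)
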