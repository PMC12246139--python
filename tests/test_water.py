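"""Conserved-water-site occupancy, exchange and conditional statistics."""

import numpy as np
import pytest

import bindmode as bm
from bindmode.structure_io import Frame, Selection
from bindmode.water import (OccupancyTrace, WaterSite, occupancy_summary,
                            sidechain_anchor)


def _site(*atom_indices, radius=3.0):
    sels = tuple(Selection(indices=(i,), provenance=f"atom {i}")
                 for i in atom_indices)
    return WaterSite(anchor_selections=sels, radius=radius)


class TestSiteCentroid:
    def test_two_anchor_mean(self):
        frame = Frame(coordinates=np.array([[0, 0, 0], [2, 0, 0]], float),
                      time_ns=0)
        c = bm.site_centroid(frame, _site(0, 1))
        assert np.allclose(c, [1, 0, 0])

    def test_coincident_anchors(self):
        frame = Frame(coordinates=np.array([[1, 2, 3], [1, 2, 3]], float),
                      time_ns=0)
        assert np.allclose(bm.site_centroid(frame, _site(0, 1)), [1, 2, 3])

    def test_matches_arithmetic_mean(self):
        rng = np.random.default_rng(0)
        coords = rng.uniform(-10, 10, (8, 3))
        frame = Frame(coordinates=coords, time_ns=0)
        c = bm.site_centroid(frame, _site(*range(8)))
        assert np.allclose(c, coords.mean(axis=0), atol=1e-9)

    def test_glycine_anchor_falls_back_to_calpha(self, small_run):
        topo = small_run.topology
        anchor = sidechain_anchor(topo, 10)
        assert [str(topo.names[i]) for i in anchor.indices] == ["CA"]
        thr = sidechain_anchor(topo, 58)
        assert set(str(topo.names[i]) for i in thr.indices) == \
            {"CB", "OG1", "CG2"}


class TestOccupancyTrace:
    def test_pinned_water_full_occupancy(self, small_run, small_frames):
        """A water pinned at the centroid every frame gives fraction 1."""
        topo = small_run.topology
        site = WaterSite(anchor_selections=(
            sidechain_anchor(topo, 58), sidechain_anchor(topo, 10)))
        water_ox = int(np.flatnonzero(
            topo.is_water & (topo.elements.astype(str) == "O"))[2])
        frames = []
        for fr in small_frames[0][:20]:
            c = fr.coordinates.copy()
            c[water_ox] = bm.site_centroid(fr, site)
            frames.append(Frame(coordinates=c, box=fr.box,
                                time_ns=fr.time_ns))
        trace = bm.occupancy_trace(iter(frames), topo, site)
        assert trace.fraction == 1.0

    def test_fraction_matches_ledger_exactly(self, small_run, small_frames):
        topo = small_run.topology
        site = WaterSite(anchor_selections=(
            sidechain_anchor(topo, 58), sidechain_anchor(topo, 10)))
        for r in range(small_run.config.n_replicas):
            led = small_run.ledger.replicas[r]
            trace = bm.occupancy_trace(iter(small_frames[r]), topo, site,
                                       replica_id=r)
            assert np.array_equal(trace.occupied, led.site_occupied)
            for k, ids in enumerate(trace.water_ids):
                want = ({int(led.site_water_id[k])}
                        if led.site_occupied[k] else set())
                assert set(ids) == want

    def test_occupancy_plus_absence_is_one(self, small_run, small_frames):
        topo = small_run.topology
        site = WaterSite(anchor_selections=(sidechain_anchor(topo, 58),
                                            sidechain_anchor(topo, 10)))
        trace = bm.occupancy_trace(iter(small_frames[0]), topo, site)
        assert trace.fraction + trace.absence_fraction == 1.0

    def test_radius_monotonicity(self, small_run, small_frames):
        """Shrinking the radius can never increase occupancy."""
        topo = small_run.topology
        anchors = (sidechain_anchor(topo, 58), sidechain_anchor(topo, 10))
        fracs = []
        for radius in (4.0, 3.0, 2.0, 1.0):
            site = WaterSite(anchor_selections=anchors, radius=radius)
            fracs.append(bm.occupancy_trace(
                iter(small_frames[1]), topo, site).fraction)
        assert all(a >= b for a, b in zip(fracs, fracs[1:]))

    def test_no_waters_raises(self, tripeptide_pdb):
        topo = bm.load_topology(tripeptide_pdb)
        site = _site(0, 5)
        frame = Frame(coordinates=np.zeros((topo.n_atoms, 3)), time_ns=0)
        with pytest.raises(bm.AnnotationError):
            bm.occupancy_trace(iter([frame]), topo, site)


def _trace(occ_ids, replica_id=0):
    occupied = np.array([bool(ids) for ids in occ_ids])
    return OccupancyTrace(times=np.arange(len(occ_ids), dtype=float),
                          occupied=occupied,
                          water_ids=[frozenset(i) for i in occ_ids],
                          replica_id=replica_id)


class TestUniqueWaters:
    def test_single_resident_water(self):
        counts, med = bm.unique_waters([_trace([{5}] * 10)])
        assert counts == {0: 1} and med == 1

    def test_scripted_exchange_counts_exactly(self, small_run, small_frames):
        topo = small_run.topology
        site = WaterSite(anchor_selections=(sidechain_anchor(topo, 58),
                                            sidechain_anchor(topo, 10)))
        traces = [bm.occupancy_trace(iter(small_frames[r]), topo, site,
                                     replica_id=r)
                  for r in range(small_run.config.n_replicas)]
        counts, _ = bm.unique_waters(traces)
        assert list(counts.values()) == \
            small_run.ledger.unique_waters_per_replica()

    def test_even_replica_count_median(self):
        traces = [_trace([set(range(100, 100 + k + 1))], replica_id=k)
                  for k in range(20)]
        _, med = bm.unique_waters(traces)
        assert med == 10.5

    def test_bounded_by_topology(self, small_run, small_frames):
        topo = small_run.topology
        site = WaterSite(anchor_selections=(sidechain_anchor(topo, 58),
                                            sidechain_anchor(topo, 10)))
        trace = bm.occupancy_trace(iter(small_frames[0]), topo, site)
        n_waters = len(np.unique(topo.molecule_ids[topo.is_water]))
        assert 1 <= len(trace.distinct_waters()) <= n_waters


class TestConditionalOccupancy:
    def test_independence_gives_equal_conditionals(self):
        rng = np.random.default_rng(1)
        n = 4000
        occ = rng.random(n) < 0.5
        labels = np.where(rng.random(n) < 0.5, "native", "flipped")
        trace = _trace([{1} if o else set() for o in occ])
        cond = bm.conditional_occupancy(trace, labels)
        for v in cond.values():
            assert abs(v - 0.5) < 0.03  # inside a generous binomial CI

    def test_total_probability_identity(self):
        rng = np.random.default_rng(2)
        n = 500
        occ = rng.random(n) < 0.7
        labels = np.where(rng.random(n) < 0.3, "native", "flipped")
        trace = _trace([{1} if o else set() for o in occ])
        cond = bm.conditional_occupancy(trace, labels)
        weighted = sum(cond[lab] * np.mean(labels == lab)
                       for lab in cond)
        assert weighted == pytest.approx(np.mean(occ), abs=1e-12)

    def test_coupled_generator_recovery(self):
        cfg = bm.GeneratorConfig(
            n_replicas=2, n_frames=400, n_waters=16, seed=9,
            water_occupancy_by_state={"native": 0.9, "flipped": 0.1})
        traj = bm.simulate(cfg)
        led = traj.ledger
        cond = led.conditional_occupancy()
        assert abs(cond["native"] - 0.9) < 0.06
        assert abs(cond["flipped"] - 0.1) < 0.06
        # analysis recovers the ledger's realized conditionals exactly
        topo = traj.topology
        site = WaterSite(anchor_selections=(sidechain_anchor(topo, 58),
                                            sidechain_anchor(topo, 10)))
        num = {"native": 0, "flipped": 0}
        den = {"native": 0, "flipped": 0}
        for r in range(2):
            frames = list(traj.replica(r))
            occ = bm.occupancy_trace(iter(frames), topo, site, replica_id=r)
            st = bm.classify_states(bm.flip_descriptors(iter(frames), topo))
            for lab in num:
                mask = st.labels == lab
                den[lab] += int(mask.sum())
                num[lab] += int(occ.occupied[mask].sum())
        for lab in num:
            assert num[lab] / den[lab] == pytest.approx(cond[lab], abs=1e-12)

    def test_misaligned_traces_raise(self):
        trace = _trace([{1}, set()])
        with pytest.raises(bm.AlignmentError):
            bm.conditional_occupancy(trace, ["native"] * 3)


def test_summary_roundtrip(small_run, small_frames, tmp_path):
    topo = small_run.topology
    site = WaterSite(anchor_selections=(sidechain_anchor(topo, 58),
                                        sidechain_anchor(topo, 10)))
    traces = [bm.occupancy_trace(iter(small_frames[r]), topo, site,
                                 replica_id=r) for r in range(3)]
    summary = occupancy_summary(traces)
    assert summary["occupancy_fraction"] + summary["absence_fraction"] == 1.0
    assert summary["frames"] == 240
    from bindmode.water import traces_to_csv
    traces_to_csv(traces, tmp_path / "occ.csv")
    assert (tmp_path / "occ.csv").read_text().startswith(
        "replica,time_ns,occupied")
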