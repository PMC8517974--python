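"""CN matrices, event detection, pathway classification, species ledger."""

import numpy as np
import pytest

from znmt.colvars import switching
from znmt.errors import ValidationError
from znmt.pathways import (
    CNMatrix,
    DissociationPathway,
    build_cn_matrix,
    classify_pathways,
    detect_events,
    species_ledger,
)
from znmt.synthetic import DissociationScript, gen_dissociation_runs
from znmt.trajio import AtomLabel, Trajectory


class TestBuildCnMatrix:
    def test_matches_scripted_profile(self, star_topology, znS_params):
        script = DissociationScript(events=[("Zn3", 40)], n_frames=80)
        trajs, _ = gen_dissociation_runs(script, 1, star_topology)
        cn = build_cn_matrix(trajs[0], star_topology)
        expect = script.cn_profile("Zn3")
        j = cn.metal_ids.index("Zn3")
        assert np.abs(cn.values[:, j] - expect).max() < 1e-5
        # undissociated metals stay at full coordination
        other = [k for k in range(len(cn.metal_ids)) if k != j]
        assert np.abs(cn.values[:, other] - 4.0).max() < 1e-5

    def test_all_ligands_distant_gives_zero_row(self, star_topology):
        atoms = ([AtomLabel(m, i + 1, "Zn")
                  for i, m in enumerate(star_topology.metal_ids)]
                 + [AtomLabel(l, star_topology.residue_index_of[l], "S")
                    for l in star_topology.ligand_ids])
        coords = np.zeros((1, len(atoms), 3))
        for i in range(len(atoms)):
            coords[0, i] = [0, 0, 1000.0 + 50.0 * i]
        cn = build_cn_matrix(Trajectory(atoms=atoms, coords=coords),
                             star_topology)
        assert np.abs(cn.values).max() < 1e-6

    def test_brute_force_oracle_on_random_frame(self, star_topology,
                                                znS_params, rng):
        atoms = ([AtomLabel(m, i + 1, "Zn")
                  for i, m in enumerate(star_topology.metal_ids)]
                 + [AtomLabel(l, star_topology.residue_index_of[l], "S")
                    for l in star_topology.ligand_ids])
        coords = rng.normal(0, 4, (1, len(atoms), 3))
        traj = Trajectory(atoms=atoms, coords=coords)
        cn = build_cn_matrix(traj, star_topology)
        n_m = len(star_topology.metal_ids)
        for j, m in enumerate(star_topology.metal_ids):
            expect = 0.0
            for li, _ in enumerate(star_topology.ligand_ids):
                r = np.linalg.norm(coords[0, j] - coords[0, n_m + li])
                expect += switching(float(r), znS_params)
            assert cn.values[0, j] == pytest.approx(expect, rel=1e-10)

    def test_missing_atom_rejected(self, star_topology, rng):
        traj = Trajectory(atoms=[AtomLabel("Zn1", 1, "Zn")],
                          coords=rng.normal(0, 1, (2, 1, 3)))
        with pytest.raises(ValidationError):
            build_cn_matrix(traj, star_topology)


def _matrix(col_values):
    """Single-metal CN matrix from a list of values."""
    v = np.asarray(col_values, dtype=float)[:, None]
    return CNMatrix(values=v, metal_ids=["Zn1"])


class TestDetectEvents:
    def test_monotone_decay_first_crossing(self):
        values = np.concatenate([np.full(100, 4.0), np.full(100, 0.1)])
        path = detect_events(_matrix(values), window=10)
        assert path.events == [("Zn1", 100)]

    def test_transient_dip_ignored_with_persistence(self):
        values = np.full(200, 4.0)
        values[50] = 0.85
        assert detect_events(_matrix(values), window=2).events == []
        assert detect_events(_matrix(values), window=1).events == [("Zn1", 50)]

    def test_two_metals_ordered_by_frame(self):
        v = np.full((400, 2), 4.0)
        v[100:, 0] = 0.0
        v[300:, 1] = 0.0
        cn = CNMatrix(values=v, metal_ids=["Zn1", "Zn2"])
        assert detect_events(cn, window=10).events == [("Zn1", 100),
                                                       ("Zn2", 300)]

    def test_tie_broken_by_metal_id_and_flagged(self):
        v = np.full((50, 2), 4.0)
        v[20:, :] = 0.0
        cn = CNMatrix(values=v, metal_ids=["Zn2", "Zn1"])
        path = detect_events(cn, window=5)
        assert path.events == [("Zn1", 20), ("Zn2", 20)]
        assert path.tied_frames == [20]

    def test_widening_window_never_adds_events(self, rng):
        values = np.clip(4.0 * rng.random(300), 0, 4)
        counts = [len(detect_events(_matrix(values), window=w).events)
                  for w in (1, 3, 10, 30)]
        assert counts == sorted(counts, reverse=True)

    def test_empty_matrix_rejected(self):
        with pytest.raises(ValidationError):
            detect_events(CNMatrix(values=np.empty((0, 1)),
                                   metal_ids=["Zn1"]))


class TestClassifyPathways:
    def test_single_pathway(self):
        runs = [DissociationPathway(events=[("Zn1", 10), ("Zn2", 20)],
                                    run_id=i) for i in range(5)]
        assert classify_pathways(runs) == {("Zn1", "Zn2"): 1.0}

    def test_seventy_thirty_split(self):
        runs = ([DissociationPathway(events=[("Zn1", 10 + i), ("Zn2", 90)],
                                     run_id=i) for i in range(70)]
                + [DissociationPathway(events=[("Zn2", 5), ("Zn1", 80 + i)],
                                       run_id=70 + i) for i in range(30)])
        probs = classify_pathways(runs)
        assert probs[("Zn1", "Zn2")] == 0.70
        assert probs[("Zn2", "Zn1")] == 0.30

    def test_twelve_distinct_orders(self, rng):
        metals = [f"Zn{i}" for i in range(1, 8)]
        orders = set()
        while len(orders) < 12:
            orders.add(tuple(rng.permutation(metals)))
        runs = []
        for i, order in enumerate(sorted(orders)):
            for rep in range(1 + i % 3):
                runs.append(DissociationPathway(
                    events=[(m, 10 * (k + 1)) for k, m in enumerate(order)],
                    run_id=f"{i}:{rep}"))
        probs = classify_pathways(runs)
        assert len(probs) == 12
        assert sum(probs.values()) == pytest.approx(1.0)

    def test_probabilities_sum_to_one_and_order_invariant(self, rng):
        runs = ([DissociationPathway(events=[("Zn1", 1)], run_id=i)
                 for i in range(3)]
                + [DissociationPathway(events=[("Zn2", 1)], run_id=9 + i)
                   for i in range(7)])
        ref = classify_pathways(runs)
        shuffled = list(runs)
        rng.shuffle(shuffled)
        assert classify_pathways(shuffled) == ref
        assert sum(ref.values()) == pytest.approx(1.0)


class TestSpeciesLedger:
    def test_beta_first_event_gives_zn6_4a_2b(self, mt2_topology):
        path = DissociationPathway(events=[("Zn1", 100)])  # a beta metal
        ledger = species_ledger(path, mt2_topology)
        assert ledger[0] == (7, 4, 3)
        assert ledger[1] == (6, 4, 2)

    def test_empty_pathway_full_occupancy(self, mt2_topology):
        assert species_ledger(DissociationPathway(events=[]),
                              mt2_topology) == [(7, 4, 3)]

    def test_full_dissociation_ends_empty(self, mt2_topology):
        events = [(m, 10 * (i + 1))
                  for i, m in enumerate(mt2_topology.metal_ids)]
        ledger = species_ledger(DissociationPathway(events=events),
                                mt2_topology)
        assert ledger[-1] == (0, 0, 0)
        assert len(ledger) == 8
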