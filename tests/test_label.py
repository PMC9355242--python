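import numpy as np
import pytest

from spinsight import (
    DistanceDistribution,
    default_r_grid,
    find_modes,
    generate_ensemble,
    interlabel_distribution,
    label_to_atom_distances,
    make_toy_structure,
    mean_label_position,
)
from spinsight.errors import BuriedSiteError, EmptySelectionError, GridRangeError
from spinsight.label import DEFAULT_CLASH_TOLERANCE, build_conformer

from conftest import make_atom, point_ensemble
from spinsight.structure import Structure


@pytest.fixture(scope="module")
def helix_ensemble(exposed_helix):
    return generate_ensemble(exposed_helix.structure, exposed_helix.sites[0], n=60, seed=7)


class TestConformerGeometry:
    def test_internal_bond_lengths_match_template(self):
        conf = build_conformer(
            np.array([0.0, 0.0, 0.0]),
            np.array([1.458, 0.0, 0.0]),
            np.array([2.0, -0.8, 1.2]),
            np.array([60.0, 180.0, -65.0, 120.0, 10.0]),
        )
        pos = {n: p for n, p in zip(conf.atom_names, conf.atom_positions)}
        cb = np.array([2.0, -0.8, 1.2])
        expected = {
            ("SG",): 1.81,
            ("SG", "SD"): 2.03,
            ("SD", "CE"): 1.81,
            ("CE", "C3"): 1.50,
            ("C3", "C4"): 1.34,
            ("N1", "O1"): 1.28,
        }
        assert np.linalg.norm(pos["SG"] - cb) == pytest.approx(1.81, abs=0.01)
        for pair, length in expected.items():
            if len(pair) == 2:
                d = np.linalg.norm(pos[pair[0]] - pos[pair[1]])
                assert d == pytest.approx(length, abs=0.01)

    def test_no_midpoint_on_n_o_segment(self):
        conf = build_conformer(
            np.zeros(3), np.array([1.458, 0, 0]), np.array([2.0, -0.8, 1.2]),
            np.array([10.0, 20.0, 30.0, 40.0, 50.0]),
        )
        n1 = conf.position_of("N1")
        o1 = conf.position_of("O1")
        assert np.allclose(conf.no_midpoint, 0.5 * (n1 + o1))
        # collinearity: midpoint lies on the N-O segment
        assert np.linalg.norm(conf.no_midpoint - n1) + np.linalg.norm(
            conf.no_midpoint - o1
        ) == pytest.approx(np.linalg.norm(o1 - n1))


class TestGenerateEnsemble:
    def test_exposed_site_fills_request(self, helix_ensemble):
        assert len(helix_ensemble) == 60
        assert helix_ensemble.n_attempted >= 60

    def test_buried_cage_raises(self):
        toy = make_toy_structure("buried-cage", seed=0)
        with pytest.raises(BuriedSiteError):
            generate_ensemble(toy.structure, toy.sites[0], n=10, seed=1)

    def test_deterministic_for_fixed_seed(self, exposed_helix):
        a = generate_ensemble(exposed_helix.structure, exposed_helix.sites[0], n=20, seed=3)
        b = generate_ensemble(exposed_helix.structure, exposed_helix.sites[0], n=20, seed=3)
        for ca, cb in zip(a.conformers, b.conformers):
            assert (ca.atom_positions == cb.atom_positions).all()

    def test_prefix_property_when_growing_n(self, exposed_helix):
        small = generate_ensemble(exposed_helix.structure, exposed_helix.sites[0], n=15, seed=3)
        large = generate_ensemble(exposed_helix.structure, exposed_helix.sites[0], n=40, seed=3)
        assert len(large) == 40
        for cs, cl in zip(small.conformers, large.conformers):
            assert (cs.atom_positions == cl.atom_positions).all()

    def test_accepted_conformers_clash_free_by_brute_force(self, exposed_helix, helix_ensemble):
        site = exposed_helix.sites[0]
        from spinsight.structure import substitute_to_cys

        st = substitute_to_cys(exposed_helix.structure, site.chain, site.residue_number)
        env = st.heavy_positions(exclude_residue=(site.chain, site.residue_number))
        for conf in helix_ensemble.conformers:
            diffs = conf.atom_positions[:, None, :] - env[None, :, :]
            dmin = np.sqrt((diffs**2).sum(axis=2)).min()
            assert dmin >= DEFAULT_CLASH_TOLERANCE


class TestMeanLabelPosition:
    def test_single_conformer_identity(self):
        ens = point_ensemble([(1.0, 2.0, 3.0)])
        assert np.allclose(mean_label_position(ens), [1, 2, 3])

    def test_two_conformer_mean(self):
        ens = point_ensemble([(0, 0, 0), (2, 0, 0)])
        assert np.allclose(mean_label_position(ens), [1, 0, 0])

    def test_empty_ensemble_rejected(self):
        ens = point_ensemble([(0, 0, 0)])
        ens.conformers = []
        with pytest.raises(ValueError):
            mean_label_position(ens)


class TestLabelToAtomDistances:
    def test_single_reporter_at_known_distance(self):
        reporter = make_atom("CD1", "ILE", "R", 1, (10.0, 0.0, 0.0), "C")
        st = Structure(atoms=[reporter], identifier="reporter-only")
        ens = point_ensemble([(0.0, 0.0, 0.0)])
        table = label_to_atom_distances(ens, st)
        assert len(table) == 1
        assert table.loc[0, "distance_A"] == pytest.approx(10.0)

    def test_reporter_on_toy_helix(self):
        toy = make_toy_structure("exposed-helix", seed=0, reporter_distance_A=12.0)
        ens = generate_ensemble(toy.structure, toy.sites[0], n=40, seed=5)
        table = label_to_atom_distances(ens, toy.structure)
        # the label arm extends ~6-9 A beyond CB, so the mean-center distance
        # differs from the CB-reporter distance but stays within arm reach
        assert len(table) == 1
        assert 2.0 < table.loc[0, "distance_A"] < 25.0

    def test_empty_selection_raises(self, exposed_helix):
        ens = point_ensemble([(0, 0, 0)])
        with pytest.raises(EmptySelectionError):
            label_to_atom_distances(ens, exposed_helix.structure, "TRP", "NE1")


class TestInterlabelDistribution:
    def test_two_singletons_give_delta_at_separation(self):
        a = point_ensemble([(0.0, 0.0, 0.0)])
        b = point_ensemble([(40.0, 0.0, 0.0)], site=("A", 2))
        dist = interlabel_distribution(a, b)
        modes = find_modes(dist)
        assert len(modes) == 1
        assert modes[0] == pytest.approx(4.0, abs=0.02)

    def test_symmetric_in_arguments(self):
        rng = np.random.default_rng(0)
        a = point_ensemble(rng.normal(0, 2, (20, 3)))
        b = point_ensemble(rng.normal((35, 0, 0), 2, (20, 3)), site=("A", 2))
        d1 = interlabel_distribution(a, b)
        d2 = interlabel_distribution(b, a)
        assert (d1.p == d2.p).all()

    def test_normalized_and_mean_consistent(self):
        rng = np.random.default_rng(1)
        a = point_ensemble(rng.normal(0, 3, (30, 3)))
        b = point_ensemble(rng.normal((45, 0, 0), 3, (30, 3)), site=("A", 2))
        dist = interlabel_distribution(a, b)
        assert np.sum(dist.p * dist.widths) == pytest.approx(1.0, abs=1e-9)
        # histogram mean within one grid step of the exact pairwise mean
        assert dist.mean() == pytest.approx(dist.metadata["mean_pairwise_nm"], abs=0.02)

    def test_narrow_grid_raises(self):
        a = point_ensemble([(0.0, 0.0, 0.0)])
        b = point_ensemble([(40.0, 0.0, 0.0)], site=("A", 2))
        with pytest.raises(GridRangeError):
            interlabel_distribution(a, b, r_grid=default_r_grid(1.0, 3.0))


class TestFindModes:
    def test_single_gaussian(self):
        dist = DistanceDistribution.from_gaussians([(4.5, 0.2, 1.0)])
        assert find_modes(dist) == pytest.approx([4.5], abs=0.02)

    def test_two_equal_gaussians(self):
        dist = DistanceDistribution.from_gaussians([(2.5, 0.15, 0.5), (3.5, 0.15, 0.5)])
        assert find_modes(dist) == pytest.approx([2.5, 3.5], abs=0.02)

    def test_uniform_has_no_modes(self):
        r = default_r_grid()
        dist = DistanceDistribution(r=r, p=np.ones_like(r))
        assert find_modes(dist) == []

    def test_small_side_peak_suppressed_by_threshold(self):
        dist = DistanceDistribution.from_gaussians([(3.0, 0.15, 0.99), (6.0, 0.15, 0.01)])
        assert find_modes(dist, min_rel_height=0.05) == pytest.approx([3.0], abs=0.02)
        assert len(find_modes(dist, min_rel_height=0.001)) == 2
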