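import numpy as np
import pandas as pd
import pytest

from lectevo.hbnet import (
    BinnedRates,
    GroupAssignment,
    HBondDefinition,
    OccupancyMatrix,
    assign_groups,
    bin_formation_rates,
    detect_hbonds,
    filter_informative_bonds,
    group_average_correlation,
    overall_formation_rate,
    pairwise_correlation,
)
from lectevo.synthetic import ToyTrajectorySpec, gen_toy_trajectory

LOOPS = {"L2": (25, 31), "L3": (36, 42), "L4": (46, 52), "L5": (69, 77), "L6": (85, 92)}


def occ_from_rows(rows, interval=10.0, labels=None):
    data = np.asarray(rows, dtype=np.uint8)
    labels = labels or tuple(f"b{i}" for i in range(len(data)))
    return OccupancyMatrix(tuple(labels), data, interval)


def protein_bond(res_a, res_b, label_suffix=""):
    return HBondDefinition(
        donor_resid=res_a, donor_atom="N", donor_chain="A",
        acceptor_resid=res_b, acceptor_atom="O", acceptor_chain="A",
        donor_resname="ALA", acceptor_resname="GLY",
    )


class TestDetection:
    def test_close_collinear_pair_present(self):
        frames, _ = gen_toy_trajectory(ToyTrajectorySpec(np.array([[2.8]])))
        bonds, occ = detect_hbonds(frames)
        assert len(bonds) == 1
        assert occ.data.tolist() == [[1]]

    def test_far_pair_absent(self):
        frames, _ = gen_toy_trajectory(ToyTrajectorySpec(np.array([[5.0]])))
        bonds, occ = detect_hbonds(frames)
        assert bonds == [] and occ.data.shape == (0, 1)

    def test_square_wave_schedule(self):
        sched = np.array([[2.8, 5.0, 2.8, 5.0, 2.8, 2.8]])
        frames, truth = gen_toy_trajectory(ToyTrajectorySpec(sched))
        _, occ = detect_hbonds(frames)
        assert np.array_equal(occ.data, truth)

    def test_randomised_schedules_match_truth_exactly(self):
        rng = np.random.default_rng(42)
        sched = rng.uniform(2.6, 6.0, size=(50, 30))
        frames, truth = gen_toy_trajectory(ToyTrajectorySpec(sched))
        bonds, occ = detect_hbonds(frames)
        assert np.array_equal(occ.data, truth[truth.sum(axis=1) > 0])

    def test_angle_criterion_rejects_bent_geometry(self):
        # donor N at origin, H perpendicular to the D->A axis: angle ~45 deg
        atoms = pd.DataFrame(
            [
                {"name": "N", "element": "N", "resid": 1, "resname": "DON", "chain": "A"},
                {"name": "H", "element": "H", "resid": 1, "resname": "DON", "chain": "A"},
                {"name": "O", "element": "O", "resid": 2, "resname": "ACC", "chain": "A"},
            ]
        )
        coords = np.array([[[0.0, 0, 0], [0.0, 1.0, 0], [2.8, 0, 0]]])
        from lectevo.hbnet import TrajectoryFrames

        frames = TrajectoryFrames(coords, atoms, 10.0)
        bonds, occ = detect_hbonds(frames, distance_only=True)
        assert len(bonds) == 2  # distance alone accepts it (both directions)
        bonds_geo, _ = detect_hbonds(frames, angle_cut=120.0)
        assert bonds_geo == []  # bent geometry rejected by the angle criterion

    def test_distance_only_mode_on_hydrogen_free_input(self):
        atoms = pd.DataFrame(
            [
                {"name": "N", "element": "N", "resid": 1, "resname": "X", "chain": "A"},
                {"name": "O", "element": "O", "resid": 2, "resname": "Y", "chain": "A"},
            ]
        )
        coords = np.array([[[0.0, 0, 0], [3.0, 0, 0]]])
        from lectevo.hbnet import TrajectoryFrames

        frames = TrajectoryFrames(coords, atoms, 10.0)
        bonds, occ = detect_hbonds(frames, distance_only=True)
        assert {(b.donor_resid, b.acceptor_resid) for b in bonds} == {(1, 2), (2, 1)}


class TestRatesAndFiltering:
    def test_all_ones_rate(self):
        occ = occ_from_rows([[1, 1, 1, 1]])
        assert overall_formation_rate(occ, "b0") == 1.0

    def test_alternating_rate(self):
        occ = occ_from_rows([[1, 0] * 50])
        assert overall_formation_rate(occ, "b0") == 0.5

    def test_bernoulli_law_of_large_numbers(self):
        rng = np.random.default_rng(0)
        occ = occ_from_rows([rng.binomial(1, 0.3, size=3000)])
        assert overall_formation_rate(occ, "b0") == pytest.approx(0.3, abs=0.02)

    def test_filter_keeps_mid_band_only(self):
        rows = [
            [1] + [0] * 19,   # 0.05
            [1] * 10 + [0] * 10,  # 0.50
            [1] * 19 + [0],   # 0.95
        ]
        kept = filter_informative_bonds(occ_from_rows(rows))
        assert kept.bonds == ("b1",)

    def test_filter_bounds_inclusive(self):
        rows = [[1] + [0] * 9, [1] * 9 + [0]]  # exactly 0.10 and 0.90
        kept = filter_informative_bonds(occ_from_rows(rows))
        assert kept.bonds == ("b0", "b1")

    def test_filter_empty_input(self):
        occ = OccupancyMatrix((), np.zeros((0, 5), dtype=np.uint8), 10.0)
        assert filter_informative_bonds(occ).bonds == ()

    def test_filter_identity_when_all_inside(self):
        occ = occ_from_rows([[1, 0, 1, 0], [0, 1, 1, 0]])
        kept = filter_informative_bonds(occ)
        assert np.array_equal(kept.data, occ.data)


class TestBinning:
    def test_bin_count_semantics(self):
        occ = occ_from_rows([np.ones(60, dtype=int)])
        rates = bin_formation_rates(occ, bin_width_ps=200, analysis_span_ps=600)
        assert rates.n_bins == 3 and rates.snapshots_per_bin == 20

    def test_constant_bond_all_bins_one(self):
        occ = occ_from_rows([np.ones(300, dtype=int)])
        rates = bin_formation_rates(occ)
        assert np.all(rates.rates == 1.0) and rates.n_bins == 15

    def test_block_mean_oracle(self):
        rng = np.random.default_rng(7)
        data = rng.integers(0, 2, size=(5, 317))
        occ = occ_from_rows(data)
        rates = bin_formation_rates(occ, bin_width_ps=200, analysis_span_ps=3000)
        # independent brute-force block averaging
        expected = np.array(
            [[data[i, 20 * b : 20 * (b + 1)].mean() for b in range(15)] for i in range(5)]
        )
        assert np.allclose(rates.rates, expected)

    def test_trailing_partial_bin_dropped(self):
        occ = occ_from_rows([np.ones(30, dtype=int)])
        rates = bin_formation_rates(occ, bin_width_ps=200, analysis_span_ps=3000)
        assert rates.n_bins == 1

    def test_span_shorter_than_bin_raises(self):
        occ = occ_from_rows([[1, 0, 1]])
        with pytest.raises(ValueError):
            bin_formation_rates(occ, bin_width_ps=200, analysis_span_ps=30)

    def test_bin_width_must_divide_interval(self):
        occ = occ_from_rows([np.ones(100, dtype=int)], interval=7.0)
        with pytest.raises(ValueError):
            bin_formation_rates(occ, bin_width_ps=200)

    def test_relabelling_within_bin_invariant(self):
        rng = np.random.default_rng(3)
        data = rng.integers(0, 2, size=(4, 300))
        shuffled = data.copy()
        for b in range(15):
            rng.shuffle(shuffled[:, 20 * b : 20 * (b + 1)].T)
        r1 = bin_formation_rates(occ_from_rows(data))
        r2 = bin_formation_rates(occ_from_rows(shuffled))
        assert np.allclose(r1.rates, r2.rates)


def corr_oracle(x, y):
    """Textbook product-moment formula, coded independently of the package."""
    xb, yb = sum(x) / len(x), sum(y) / len(y)
    num = sum((xi - xb) * (yi - yb) for xi, yi in zip(x, y))
    den = (
        sum((xi - xb) ** 2 for xi in x) * sum((yi - yb) ** 2 for yi in y)
    ) ** 0.5
    return num / den


class TestPairwiseCorrelation:
    def rates(self, matrix):
        m = np.asarray(matrix, dtype=float)
        return BinnedRates(tuple(f"b{i}" for i in range(len(m))), m, 200.0, 20)

    def test_self_correlation_unity(self):
        corr = pairwise_correlation(self.rates([[0.1, 0.5, 0.9, 0.2]]))
        assert corr.loc["b0", "b0"] == pytest.approx(1.0)

    def test_antiphase_minus_one(self):
        x = np.array([0.1, 0.4, 0.8, 0.3])
        corr = pairwise_correlation(self.rates([x, 1.0 - x]))
        assert corr.loc["b0", "b1"] == pytest.approx(-1.0)

    def test_matches_brute_force_oracle_to_1e12(self):
        rng = np.random.default_rng(11)
        m = rng.uniform(0, 1, size=(10, 15))
        corr = pairwise_correlation(self.rates(m))
        for i in range(10):
            for j in range(10):
                assert corr.iloc[i, j] == pytest.approx(
                    corr_oracle(m[i], m[j]), abs=1e-12
                )

    def test_symmetry_and_bounds(self):
        rng = np.random.default_rng(5)
        m = rng.uniform(0, 1, size=(8, 15))
        corr = pairwise_correlation(self.rates(m)).to_numpy()
        assert np.allclose(corr, corr.T)
        assert np.nanmax(np.abs(corr)) <= 1.0

    def test_zero_variance_flagged_undefined(self):
        corr = pairwise_correlation(self.rates([[0.5, 0.5, 0.5], [0.1, 0.5, 0.9]]))
        assert np.isnan(corr.loc["b0", "b1"]) and np.isnan(corr.loc["b0", "b0"])
        assert corr.loc["b1", "b1"] == pytest.approx(1.0)

    def test_too_few_bins_rejected(self):
        with pytest.raises(ValueError):
            pairwise_correlation(self.rates([[0.1, 0.9]]))

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(9)
        m = rng.uniform(0, 1, size=(6, 15))
        corr = pairwise_correlation(self.rates(m))
        perm = [3, 1, 5, 0, 2, 4]
        permuted = BinnedRates(
            tuple(f"b{i}" for i in perm), m[perm], 200.0, 20
        )
        corr_p = pairwise_correlation(permuted)
        for a in range(6):
            for b in range(6):
                assert corr_p.loc[f"b{perm[a]}", f"b{perm[b]}"] == pytest.approx(
                    corr.loc[f"b{perm[a]}", f"b{perm[b]}"]
                )

    def test_filter_then_correlate_commutes_with_restrict(self):
        rng = np.random.default_rng(13)
        data = rng.integers(0, 2, size=(6, 300))
        data[0] = 1  # permanently formed, filtered out
        occ = occ_from_rows(data)
        kept = filter_informative_bonds(occ)
        path_a = pairwise_correlation(bin_formation_rates(kept))
        full = pairwise_correlation(bin_formation_rates(occ))
        path_b = full.loc[list(kept.bonds), list(kept.bonds)]
        assert np.allclose(path_a.to_numpy(), path_b.to_numpy(), equal_nan=True)


def lac_bond(resid):
    return HBondDefinition(
        donor_resid=900, donor_atom="O3", donor_chain="A",
        acceptor_resid=resid, acceptor_atom="NH1", acceptor_chain="A",
        donor_resname="LAC", acceptor_resname="ARG",
    )


class TestGrouping:
    def test_intra_loop(self):
        a = assign_groups([protein_bond(37, 40)], LOOPS)
        assert list(a.groups.values()) == ["L3"]

    def test_inter_loop_pair(self):
        a = assign_groups([protein_bond(26, 90)], LOOPS)
        assert list(a.groups.values()) == ["L2-L6"]

    def test_ligand_bond_to_r28(self):
        a = assign_groups([lac_bond(28)], LOOPS)
        assert list(a.groups.values()) == ["Lac-R28"]

    def test_ligand_bond_to_r47(self):
        a = assign_groups([lac_bond(47)], LOOPS)
        assert list(a.groups.values()) == ["Lac-R47"]

    def test_unmatched_bond_unassigned(self):
        a = assign_groups([protein_bond(5, 100)], LOOPS)
        assert a.groups == {} and len(a.unassigned) == 1

    def test_overlapping_ranges_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            assign_groups([protein_bond(37, 40)], {"L3": (36, 42), "L4": (40, 50)})


class TestGroupAveraging:
    def test_two_singleton_groups_single_edge(self):
        corr = pd.DataFrame(
            [[1.0, 0.42], [0.42, 1.0]], index=["x", "y"], columns=["x", "y"]
        )
        net = group_average_correlation(corr, {"x": "A", "y": "B"})
        assert net.edge_r("A", "B") == pytest.approx(0.42)
        assert net.graph.edges["A", "B"]["n_pairs"] == 1

    def test_within_group_self_edge(self):
        corr = pd.DataFrame(
            np.array([[1.0, 0.6, 0.2], [0.6, 1.0, 0.4], [0.2, 0.4, 1.0]]),
            index=list("xyz"), columns=list("xyz"),
        )
        net = group_average_correlation(corr, {"x": "A", "y": "A", "z": "B"})
        assert net.edge_r("A", "A") == pytest.approx(0.6)
        assert net.edge_r("A", "B") == pytest.approx(0.3)

    def test_undefined_pairs_counted_and_excluded(self):
        corr = pd.DataFrame(
            [[1.0, np.nan], [np.nan, 1.0]], index=["x", "y"], columns=["x", "y"]
        )
        net = group_average_correlation(corr, {"x": "A", "y": "B"})
        assert net.n_undefined_pairs == 1
        assert not net.graph.has_edge("A", "B")

    def test_empty_group_rejected(self):
        corr = pd.DataFrame([[1.0]], index=["x"], columns=["x"])
        with pytest.raises(ValueError):
            group_average_correlation(corr, {"y": "A"})
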