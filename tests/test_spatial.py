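"""Geodesic grid, MST extent, pruning, windows, SQS and correlations."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from ammodiv import spatial
from tests.conftest import make_occurrences


class TestGrid:
    @pytest.mark.parametrize("f,expected", [(1, 12), (2, 42), (4, 162), (7, 492)])
    def test_cell_count_follows_closed_form(self, f, expected):
        grid = spatial.build_grid(f)
        assert grid.n_cells == expected == 10 * f * f + 2

    def test_invalid_frequency(self):
        with pytest.raises(ValueError):
            spatial.build_grid(0)

    def test_every_point_maps_to_one_cell(self, rng):
        grid = spatial.build_grid(3)
        lon = rng.uniform(-180, 180, 200)
        lat = np.degrees(np.arcsin(rng.uniform(-1, 1, 200)))
        occ = spatial.assign_cells(lon, lat, grid)
        assert occ.counts.sum() == 200
        assert (occ.counts > 0).all()

    def test_repeated_point_single_cell(self):
        grid = spatial.build_grid(2)
        occ = spatial.assign_cells([12.0] * 9, [45.0] * 9, grid)
        assert len(occ.counts) == 1
        assert occ.counts.iloc[0] == 9

    def test_empty_and_out_of_range(self):
        grid = spatial.build_grid(1)
        assert len(spatial.assign_cells([], [], grid).counts) == 0
        with pytest.raises(ValueError):
            spatial.assign_cells([200.0], [0.0], grid)

    def test_points_at_two_centroids(self):
        grid = spatial.build_grid(2)
        a = grid.centroids.iloc[0]
        b = grid.centroids.iloc[-1]
        occ = spatial.assign_cells([a["lon"], b["lon"], b["lon"]],
                                   [a["lat"], b["lat"], b["lat"]], grid)
        assert sorted(occ.counts.to_list()) == [1, 2]


def brute_force_mst(vectors, radius=spatial.EARTH_RADIUS_KM):
    """Minimum total length over all spanning trees by exhaustive enumeration."""
    n = len(vectors)
    dist = spatial._pairwise_km(vectors, radius)
    edges = [(i, j) for i in range(n) for j in range(i + 1, n)]
    best = math.inf
    for subset in itertools.combinations(edges, n - 1):
        parent = list(range(n))

        def find(a):
            while parent[a] != a:
                parent[a] = parent[parent[a]]
                a = parent[a]
            return a

        ok = True
        for i, j in subset:
            ri, rj = find(i), find(j)
            if ri == rj:
                ok = False
                break
            parent[ri] = rj
        if ok:
            best = min(best, sum(dist[i, j] for i, j in subset))
    return best


class TestMST:
    def test_single_cell_zero_length(self):
        grid = spatial.build_grid(1)
        occ = spatial.assign_cells([grid.centroids["lon"][0]],
                                   [grid.centroids["lat"][0]], grid)
        tree = spatial.mst_length(occ, grid)
        assert tree.total_length_km == 0.0
        assert tree.edges == []

    def test_quarter_circumference(self):
        d = spatial.great_circle_km(0.0, 0.0, 90.0, 0.0)
        assert d == pytest.approx(math.pi * spatial.EARTH_RADIUS_KM / 2, abs=1e-6)

    def test_matches_exhaustive_enumeration(self, rng):
        grid = spatial.build_grid(4)
        for _ in range(25):
            k = rng.integers(2, 7)
            ids = rng.choice(grid.n_cells, size=k, replace=False)
            occ = spatial.CellOccupancy(pd.Series(1, index=np.sort(ids)))
            tree = spatial.mst_length(occ, grid)
            oracle = brute_force_mst(grid._vectors[np.sort(ids)])
            assert tree.total_length_km == pytest.approx(oracle, rel=1e-9)

    def test_empty_occupancy_rejected(self):
        grid = spatial.build_grid(1)
        with pytest.raises(ValueError):
            spatial.mst_length(spatial.CellOccupancy(pd.Series(dtype=int)), grid)


def prune_oracle(occupancy, grid, target):
    """Follow the deterministic removal path; first state at minimal gap."""
    counts = occupancy.counts.copy()
    states = []
    while True:
        occ = spatial.CellOccupancy(counts)
        tree = spatial.mst_length(occ, grid)
        states.append((counts.copy(), tree.total_length_km))
        if len(counts) == 1:
            break
        degree = pd.Series(0, index=counts.index)
        for a, b, _ in tree.edges:
            degree[a] += 1
            degree[b] += 1
        tips = sorted(degree.index[degree <= 1], key=lambda c: (counts[c], c))
        counts = counts.drop(tips[0])
    gaps = [abs(length - target) for _, length in states]
    best = int(np.argmin(gaps))
    return states[best]


class TestPrune:
    def test_target_at_or_above_current_unchanged(self, rng):
        grid = spatial.build_grid(3)
        ids = np.sort(rng.choice(grid.n_cells, 6, replace=False))
        occ = spatial.CellOccupancy(pd.Series(rng.integers(1, 9, 6), index=ids))
        before = spatial.mst_length(occ, grid)
        pruned, tree = spatial.prune_to_target(occ, grid, before.total_length_km + 500)
        pd.testing.assert_series_equal(pruned.counts, occ.counts)

    def test_path_tie_break_removes_fewest_occurrences(self):
        """Three nearly collinear cells: the sparse end tip is removed first."""
        grid = spatial.build_grid(6)
        # pick three cells along the equator
        eq = grid.centroids[np.abs(grid.centroids["lat"]) < 8].sort_values("lon")
        ids = eq["cell_id"].iloc[[3, 4, 5]].to_numpy()
        counts = pd.Series([1, 5, 2], index=ids).sort_index()
        occ = spatial.CellOccupancy(counts)
        full = spatial.mst_length(occ, grid)
        # target: the MST length of the two best-occupied cells
        keep = counts.drop(counts.idxmin())
        target = spatial.mst_length(spatial.CellOccupancy(keep), grid).total_length_km
        pruned, tree = spatial.prune_to_target(occ, grid, target)
        assert set(pruned.cell_ids) == set(keep.index)
        assert tree.total_length_km == pytest.approx(target)
        assert tree.total_length_km < full.total_length_km

    def test_target_zero_reaches_single_cell_on_uniform_path(self, rng):
        grid = spatial.build_grid(4)
        ids = np.sort(rng.choice(grid.n_cells, 5, replace=False))
        occ = spatial.CellOccupancy(pd.Series(1, index=ids))
        pruned, tree = spatial.prune_to_target(occ, grid, 0.0)
        assert len(pruned.counts) == 1
        assert tree.total_length_km == 0.0

    def test_matches_removal_path_oracle(self, rng):
        grid = spatial.build_grid(4)
        for _ in range(20):
            k = int(rng.integers(3, 9))
            ids = np.sort(rng.choice(grid.n_cells, k, replace=False))
            occ = spatial.CellOccupancy(
                pd.Series(rng.integers(1, 20, k), index=ids)
            )
            full = spatial.mst_length(occ, grid).total_length_km
            target = float(rng.uniform(0, full * 1.1))
            counts_o, length_o = prune_oracle(occ, grid, target)
            pruned, tree = spatial.prune_to_target(occ, grid, target)
            assert set(pruned.cell_ids) == set(counts_o.index)
            assert tree.total_length_km == pytest.approx(length_o, rel=1e-9)

    def test_length_non_increasing_along_path(self, rng):
        grid = spatial.build_grid(4)
        ids = np.sort(rng.choice(grid.n_cells, 8, replace=False))
        occ = spatial.CellOccupancy(pd.Series(rng.integers(1, 5, 8), index=ids))
        lengths = [l for _, l in [prune_oracle(occ, grid, t)
                                  for t in [1e9]]]  # full state only
        # walk the whole path explicitly
        counts = occ.counts.copy()
        prev = math.inf
        while len(counts) >= 1:
            tree = spatial.mst_length(spatial.CellOccupancy(counts), grid)
            assert tree.total_length_km <= prev + 1e-9
            prev = tree.total_length_km
            if len(counts) == 1:
                break
            degree = pd.Series(0, index=counts.index)
            for a, b, _ in tree.edges:
                degree[a] += 1
                degree[b] += 1
            tips = sorted(degree.index[degree <= 1], key=lambda c: (counts[c], c))
            counts = counts.drop(tips[0])


class TestWindows:
    def _drifting_table(self, step_lon=2.0, n_stages=5, jitter=0.0, rng=None):
        rows = []
        for s in range(n_stages):
            for i in range(12):
                lon = 10.0 + s * step_lon + (rng.uniform(-jitter, jitter) if jitter else 0)
                lat = 20.0 + (rng.uniform(-jitter, jitter) if jitter else 0)
                rows.append(
                    (f"o{s}_{i}", f"l{s}_{i}", "SubA", "SF01", "G", "",
                     100.0 - 5 * s, 95.0 - 5 * s, lon, lat, f"st{s}")
                )
        return make_occurrences(rows)

    def test_stationary_cluster_prefers_zero_step(self):
        table = self._drifting_table(step_lon=0.0)
        track, masks = spatial.slide_windows(table, (20.0, 20.0))
        assert track.step_deg == 0.0
        assert track.total_retained == len(table)

    def test_drifting_cluster_recovered(self, rng):
        # narrow window over many stages: only the true drift keeps everything
        table = self._drifting_table(step_lon=2.0, n_stages=9, jitter=0.2, rng=rng)
        track, masks = spatial.slide_windows(
            table, (3.0, 3.0),
            step_candidates=np.arange(0.0, 4.01, 0.5),
        )
        assert track.step_deg == pytest.approx(2.0, abs=0.51)
        assert abs(track.bearing_deg - 90.0) <= 15.0
        assert track.total_retained == len(table)

    def test_unreachable_occurrences_warn(self, caplog):
        rows = [
            ("o1", "l1", "SubA", "SF01", "G", "", 90.0, 85.0, -170.0, -60.0, "a"),
            ("o2", "l2", "SubA", "SF01", "G", "", 80.0, 75.0, 170.0, 60.0, "b"),
        ]
        table = make_occurrences(rows)
        with caplog.at_level("WARNING"):
            track, _ = spatial.slide_windows(
                table, (1.0, 1.0), step_candidates=[0.0],
                anchor_offsets=(40.0,),
            )
        assert track.total_retained == 0

    def test_invalid_window(self, toy_table):
        with pytest.raises(ValueError):
            spatial.slide_windows(toy_table, (0.0, 5.0))


def sqs_oracle(abundances, quorum):
    """Exhaustive-expectation rarefaction oracle.

    Enumerates every subsample (as index subsets of the individual list) for
    each size m, averages richness and full-sample-share coverage, rescales
    the coverage curve to the Chao-Jost full-sample estimate, and linearly
    interpolates richness at the quorum.  Independent of the analytic
    hypergeometric route used by the implementation.
    """
    individuals = []
    for taxon, count in enumerate(abundances):
        individuals.extend([taxon] * count)
    n = len(individuals)
    x = np.asarray(abundances, float)
    f1 = int(np.sum(x == 1))
    f2 = int(np.sum(x == 2))
    if f1 == 0 or n <= 1:
        c_full = 1.0
    elif f2 > 0:
        c_full = 1.0 - (f1 / n) * ((n - 1) * f1 / ((n - 1) * f1 + 2 * f2))
    else:
        c_full = 1.0 - (f1 / n) * ((n - 1) * (f1 - 1) / ((n - 1) * (f1 - 1) + 2))
    rich, cov = [], []
    for m in range(1, n + 1):
        r_tot = c_tot = k = 0
        for subset in itertools.combinations(range(n), m):
            taxa = {individuals[i] for i in subset}
            r_tot += len(taxa)
            c_tot += sum(x[t] for t in taxa) / n
            k += 1
        rich.append(r_tot / k)
        cov.append(c_full * c_tot / k)
    if quorum <= cov[0]:
        return rich[0]
    return float(np.interp(quorum, cov, rich))


class TestSQS:
    def test_single_taxon_any_quorum(self):
        for quorum in (0.1, 0.5, 0.9, 1.0):
            assert spatial.sqs_diversity([7], quorum).richness == pytest.approx(1.0)

    def test_quorum_at_full_coverage_returns_observed_richness(self):
        ab = [6, 3, 2, 2, 1]
        c_full = spatial.sqs_diversity(ab, 0.5).coverage_full
        res = spatial.sqs_diversity(ab, c_full)
        assert not res.extrapolated
        assert res.richness == pytest.approx(len(ab), abs=1e-9)

    def test_reference_vector_matches_oracle(self):
        got = spatial.sqs_diversity([4, 2, 1, 1], 0.5)
        assert got.richness == pytest.approx(sqs_oracle([4, 2, 1, 1], 0.5), abs=1e-9)

    def test_all_small_vectors_match_oracle(self):
        """Every abundance vector with n <= 12 individuals matches the
        exhaustive-expectation oracle at quorum 0.5."""

        def partitions(n, max_part=None):
            if max_part is None:
                max_part = n
            if n == 0:
                yield []
                return
            for first in range(min(n, max_part), 0, -1):
                for rest in partitions(n - first, first):
                    yield [first] + rest

        for n in range(1, 13):
            for vec in partitions(n):
                res = spatial.sqs_diversity(vec, 0.5)
                if res.extrapolated:
                    continue
                assert res.richness == pytest.approx(
                    sqs_oracle(vec, 0.5), abs=1e-9
                ), vec

    def test_monotone_in_quorum(self):
        ab = [9, 5, 3, 2, 1, 1, 1]
        prev = 0.0
        c_full = spatial.sqs_diversity(ab, 0.5).coverage_full
        for q in np.linspace(0.05, c_full, 25):
            r = spatial.sqs_diversity(ab, q).richness
            assert r >= prev - 1e-9
            assert r <= len(ab) + 1e-9
            prev = r

    def test_extrapolation_flagged(self):
        res = spatial.sqs_diversity([2, 1, 1, 1], 0.99)
        assert res.extrapolated
        assert res.richness >= 4

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            spatial.sqs_diversity([], 0.5)
        with pytest.raises(ValueError):
            spatial.sqs_diversity([3, 2], 0.0)

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.lists(st.integers(1, 9), min_size=1, max_size=8))
    def test_interpolated_richness_bounded_by_observed(self, vec):
        res = spatial.sqs_diversity(vec, 0.5)
        if not res.extrapolated:
            assert res.richness <= len(vec) + 1e-9


class TestExtentCorrelations:
    def test_perfect_linearity(self):
        out = spatial.extent_correlations([2, 4, 6], {"mst": [1, 2, 3]})
        assert out["pearson_r"].iloc[0] == pytest.approx(1.0)

    def test_spearman_exact_permutation(self):
        out = spatial.extent_correlations([3, 5, 4], {"mst": [1, 2, 3]})
        # rho = 0.5; permutations of 3 ranks give rho >= 0.5 in 3 of 6 cases
        assert out["spearman_p"].iloc[0] == pytest.approx(3 / 6)

    def test_zero_variance_errors(self):
        with pytest.raises(ValueError):
            spatial.extent_correlations([1.0, 1.0, 1.0], {"mst": [1, 2, 3]})
        with pytest.raises(ValueError):
            spatial.extent_correlations([1, 2, 3], {"mst": [2.0, 2.0, 2.0]})
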