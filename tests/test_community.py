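"""Community comparison: Bray-Curtis, fold changes, Ward clustering, top-N."""

import itertools

import numpy as np
import pandas as pd
import pytest

import epsdigest as ed
from epsdigest.community import DEFAULT_ABUNDANCE_FLOOR, load_abundance_table


class TestBrayCurtis:
    def test_identical_vectors(self):
        assert ed.bray_curtis([0.5, 0.3, 0.2], [0.5, 0.3, 0.2]) == 0.0

    def test_disjoint_supports(self):
        assert ed.bray_curtis([0.6, 0.4, 0.0], [0.0, 0.0, 1.0]) == pytest.approx(1.0)

    def test_worked_example(self):
        assert ed.bray_curtis([0.7, 0.3, 0.0], [0.2, 0.3, 0.5]) == pytest.approx(0.5)

    def test_symmetry_and_bounds(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            u, v = rng.uniform(0, 1, (2, 8))
            d = ed.bray_curtis(u, v)
            assert d == pytest.approx(ed.bray_curtis(v, u))
            assert 0.0 <= d <= 1.0
            # independent arithmetic check of sum|u-v| / sum(u+v)
            assert d == pytest.approx(np.abs(u - v).sum() / (u + v).sum())

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            ed.bray_curtis([0.0, 0.0], [0.0, 0.0])


class TestFoldChanges:
    @staticmethod
    def table():
        return pd.DataFrame(
            {
                "inoculum": [0.01, 0.25, 0.74, 0.0],
                "eps1": [0.07, 0.25, 0.58, 0.10],
                "eps2": [0.22, 0.0, 0.70, 0.08],
            },
            index=["V. gigantis", "sp2", "sp3", "sp4"],
        )

    def test_sevenfold_enrichment(self):
        fc = ed.fold_changes(self.table(), "inoculum")
        assert fc.values.loc["V. gigantis", "eps1"] == pytest.approx(2.807, abs=1e-3)

    def test_equal_abundance_gives_zero(self):
        fc = ed.fold_changes(self.table(), "inoculum")
        assert fc.values.loc["sp2", "eps1"] == 0.0

    def test_absent_species_masked_not_zeroed(self):
        fc = ed.fold_changes(self.table(), "inoculum")
        assert fc.mask.loc["sp2", "eps2"]
        assert np.isnan(fc.values.loc["sp2", "eps2"])

    def test_species_absent_from_inoculum_uses_floor(self):
        fc = ed.fold_changes(self.table(), "inoculum")
        expected = np.log2(0.10 / DEFAULT_ABUNDANCE_FLOOR)
        assert fc.values.loc["sp4", "eps1"] == pytest.approx(expected)

    def test_unknown_inoculum_rejected(self):
        with pytest.raises(KeyError):
            ed.fold_changes(self.table(), "nope")

    def test_invariant_to_uniform_rescaling(self):
        t = self.table()
        fc1 = ed.fold_changes(t, "inoculum", floor=1e-6)
        fc2 = ed.fold_changes(t * 2, "inoculum", floor=2e-6)
        pd.testing.assert_frame_equal(fc1.values, fc2.values)


def brute_force_ward(X):
    """Exhaustive minimum-variance agglomeration.

    At each step merge the cluster pair whose union minimally increases the
    within-cluster sum of squares; ties broken by lowest member index.
    Returns the merge sequence as frozensets of original row indices.
    """
    clusters = [frozenset([i]) for i in range(len(X))]
    merges = []
    while len(clusters) > 1:
        best = None
        for a, b in itertools.combinations(range(len(clusters)), 2):
            A = np.array(sorted(clusters[a]))
            B = np.array(sorted(clusters[b]))
            ca, cb = X[A].mean(axis=0), X[B].mean(axis=0)
            delta = len(A) * len(B) / (len(A) + len(B)) * np.sum((ca - cb) ** 2)
            key = (delta, min(clusters[a] | clusters[b]))
            if best is None or key < best[0]:
                best = (key, a, b)
        _, a, b = best
        merged = clusters[a] | clusters[b]
        merges.append(merged)
        clusters = [c for i, c in enumerate(clusters) if i not in (a, b)] + [merged]
    return merges


def scipy_merge_sets(Z, n):
    members = {i: frozenset([i]) for i in range(n)}
    out = []
    for step, (a, b, _, _) in enumerate(Z):
        merged = members[int(a)] | members[int(b)]
        members[n + step] = merged
        out.append(merged)
    return out


class TestWardCluster:
    def test_identical_rows_merge_first(self):
        vals = pd.DataFrame(
            [[1.0, 2.0], [5.0, -3.0], [1.0, 2.0], [-4.0, 0.5]],
            index=["a", "b", "c", "d"],
        )
        Z, _ = ed.ward_cluster(vals)
        first = scipy_merge_sets(Z, 4)[0]
        assert first == frozenset([0, 2])

    @pytest.mark.parametrize("n_rows", [4, 6, 8])
    def test_matches_exhaustive_minimum_variance_oracle(self, n_rows):
        rng = np.random.default_rng(n_rows)
        X = rng.normal(size=(n_rows, 5))
        Z, _ = ed.ward_cluster(pd.DataFrame(X))
        assert scipy_merge_sets(Z, n_rows) == brute_force_ward(X)

    def test_merge_heights_non_decreasing(self):
        rng = np.random.default_rng(9)
        Z, _ = ed.ward_cluster(pd.DataFrame(rng.normal(size=(12, 4))))
        heights = Z[:, 2]
        assert (np.diff(heights) >= -1e-12).all()

    def test_row_permutation_preserves_topology(self):
        rng = np.random.default_rng(4)
        df = pd.DataFrame(rng.normal(size=(7, 3)), index=list("abcdefg"))
        perm = df.sample(frac=1, random_state=1)
        sets1 = {
            frozenset(df.index[i] for i in s)
            for s in scipy_merge_sets(ed.ward_cluster(df)[0], 7)
        }
        sets2 = {
            frozenset(perm.index[i] for i in s)
            for s in scipy_merge_sets(ed.ward_cluster(perm)[0], 7)
        }
        assert sets1 == sets2

    def test_masked_cells_imputed_at_matrix_minimum(self):
        vals = pd.DataFrame(
            [[1.0, np.nan], [1.0, -6.0], [4.0, 2.0]], index=["a", "b", "c"]
        )
        fc = ed.FoldChangeMatrix(vals, vals.isna(), "inoc", 1e-4)
        Z, _ = ed.ward_cluster(fc)
        # nan -> -6 makes rows a and b identical, so they merge first
        assert scipy_merge_sets(Z, 3)[0] == frozenset([0, 1])

    def test_fully_masked_row_rejected(self):
        vals = pd.DataFrame([[np.nan, np.nan], [1.0, 2.0]], index=["a", "b"])
        fc = ed.FoldChangeMatrix(vals, vals.isna(), "inoc", 1e-4)
        with pytest.raises(ValueError):
            ed.ward_cluster(fc)


class TestTopN:
    @staticmethod
    def community(n_species=10, seed=0):
        rng = np.random.default_rng(seed)
        raw = rng.dirichlet(np.ones(n_species), size=2).T
        return pd.DataFrame(
            raw, index=[f"sp{i:02d}" for i in range(n_species)], columns=["s1", "s2"]
        )

    def test_remainder_completes_the_composition(self):
        table = self.community()
        out = ed.top_n(table, n=6)
        np.testing.assert_allclose(out.sum(axis=0), 1.0, atol=1e-12)
        assert out.index[-1] == "other"

    def test_n_at_least_species_count_leaves_no_remainder(self):
        table = self.community(n_species=5)
        out = ed.top_n(table, n=8)
        np.testing.assert_allclose(out.loc["other"], 0.0, atol=1e-12)

    def test_ties_broken_lexicographically(self):
        table = pd.DataFrame(
            {"s1": [0.25, 0.25, 0.25, 0.25]}, index=["d", "b", "a", "c"]
        )
        out = ed.top_n(table, n=2)
        assert set(out.index[:-1]) == {"a", "b"}


class TestLoadAbundanceTable:
    def test_renormalizes_columns(self):
        df = pd.DataFrame({"s1": [0.2, 0.2], "s2": [0.5, 0.25]}, index=["a", "b"])
        out = load_abundance_table(df)
        np.testing.assert_allclose(out.sum(axis=0), 1.0)

    def test_negative_abundance_rejected(self):
        df = pd.DataFrame({"s1": [-0.1, 0.5]}, index=["a", "b"])
        with pytest.raises(ValueError):
            load_abundance_table(df)

    def test_empty_sample_rejected(self):
        df = pd.DataFrame({"s1": [0.0, 0.0]}, index=["a", "b"])
        with pytest.raises(ValueError):
            load_abundance_table(df)
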