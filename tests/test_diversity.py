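"""Alpha/beta diversity, batch correction, PCoA, PERMANOVA, Holm pairwise tests."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.spatial.distance import pdist, squareform
from skbio import DistanceMatrix
from skbio.stats.distance import permanova as skbio_permanova
from skbio.stats.ordination import pcoa as skbio_pcoa

import lungbiota as lb
from lungbiota.community import relative_abundance


class TestAlpha:
    def test_shannon_values(self):
        assert lb.shannon([1, 1, 1, 1]) == pytest.approx(np.log(4))
        assert lb.shannon([7]) == 0.0
        assert lb.shannon([2, 1, 1]) == pytest.approx(1.0397, abs=1e-4)

    def test_shannon_scale_invariant_and_base(self):
        counts = [5, 3, 9, 1]
        assert lb.shannon(counts) == pytest.approx(lb.shannon([10 * c for c in counts]))
        assert lb.shannon(counts, base=2) == pytest.approx(lb.shannon(counts) / np.log(2))

    def test_inverse_simpson_values(self):
        assert lb.inverse_simpson([1] * 5) == pytest.approx(5.0)
        assert lb.inverse_simpson([9]) == pytest.approx(1.0)
        assert lb.inverse_simpson([3, 1]) == pytest.approx(1.6)

    def test_inverse_simpson_bounded_by_richness(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            counts = rng.integers(0, 30, size=12)
            counts[0] += 1
            val = lb.inverse_simpson(counts)
            assert 1.0 <= val <= np.count_nonzero(counts) + 1e-9

    def test_all_zero_errors(self):
        with pytest.raises(ValueError):
            lb.shannon([0, 0])
        with pytest.raises(ValueError):
            lb.inverse_simpson([0])


class TestBrayCurtis:
    def test_examples(self):
        x = np.array([[6, 2], [0, 2], [2, 0]])
        dm = lb.bray_curtis(x, ["a", "b"])
        assert dm["a", "b"] == pytest.approx(8 / 12)
        same = lb.bray_curtis(np.array([[3, 3], [1, 1]]), ["a", "b"])
        assert same["a", "b"] == 0.0
        disjoint = lb.bray_curtis(np.array([[5, 0], [0, 7]]), ["a", "b"])
        assert disjoint["a", "b"] == pytest.approx(1.0)

    @settings(derandomize=True, max_examples=25, deadline=None)
    @given(st.integers(min_value=0, max_value=2**31 - 1))
    def test_matches_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        mat = rng.integers(0, 30, size=(10, 8)).astype(float)
        mat[0, :] += 1
        dm = lb.bray_curtis(mat, [f"s{j}" for j in range(8)])
        for i in range(8):
            for j in range(8):
                x, y = mat[:, i], mat[:, j]
                expected = np.abs(x - y).sum() / (x + y).sum()
                assert dm.data[i, j] == pytest.approx(expected, abs=1e-12)
        assert np.allclose(dm.data, dm.data.T)
        assert (dm.data >= 0).all() and (dm.data <= 1).all()
        assert np.allclose(np.diag(dm.data), 0)

    def test_zero_sum_column_errors(self):
        with pytest.raises(ValueError):
            lb.bray_curtis(np.array([[1, 0], [1, 0]]), ["a", "b"])


class TestBatchCorrect:
    def test_single_batch_is_identity(self, toy_table):
        table, _ = toy_table
        meta = lb.SampleMetadata(
            pd.DataFrame(
                {
                    "sample_id": table.sample_ids,
                    "subject_id": ["A", "A", "B", "B"],
                    "site": ["oral", "lung", "oral", "lung"],
                    "batch": ["run1"] * 4,
                }
            )
        )
        rel = relative_abundance(table)
        out = lb.batch_correct(rel, table.sample_ids, meta)
        assert np.allclose(out, rel)

    def test_saturated_two_group_model_gives_grand_mean(self):
        # taxon proportions constant within batch: residuals are zero, so the
        # corrected value is the taxon grand mean in every sample
        props = np.array([[0.2, 0.2, 0.4, 0.4], [0.8, 0.8, 0.6, 0.6]])
        meta = lb.SampleMetadata(
            pd.DataFrame(
                {
                    "sample_id": ["a", "b", "c", "d"],
                    "subject_id": ["S1", "S2", "S3", "S4"],
                    "site": ["oral"] * 4,
                    "batch": ["run1", "run1", "run2", "run2"],
                }
            )
        )
        out = lb.batch_correct(props, ["a", "b", "c", "d"], meta)
        assert np.allclose(out[0], 0.3)
        assert np.allclose(out[1], 0.7)

    def test_columns_sum_to_one(self, default_cohort):
        table, metadata, _ = default_cohort
        subj = table.select_samples(
            [s for s in table.sample_ids if metadata.site_of(s) != "control"]
        )
        out = lb.batch_correct(relative_abundance(subj), subj.sample_ids, metadata)
        assert np.allclose(out.sum(axis=0), 1.0, atol=1e-9)

    @pytest.mark.parametrize("seed", [0, 3])
    def test_reduces_between_batch_distance(self, seed):
        table, metadata, _ = lb.simulate_cohort(lb.CohortConfig(seed=seed))
        subj = table.select_samples(
            [s for s in table.sample_ids if metadata.site_of(s) != "control"]
        )
        rel = relative_abundance(subj)
        corrected = lb.batch_correct(rel, subj.sample_ids, metadata)

        def between_batch_mean(mat):
            dm = lb.bray_curtis(mat, subj.sample_ids)
            batch = {s: metadata.batch_of(s) for s in subj.sample_ids}
            vals = [
                dm[a, b]
                for i, a in enumerate(subj.sample_ids)
                for b in subj.sample_ids[i + 1:]
                if batch[a] != batch[b]
            ]
            return np.mean(vals)

        assert between_batch_mean(corrected) < between_batch_mean(rel)


class TestPcoa:
    def test_collinear_points_recovered_on_first_axis(self):
        xs = np.array([0.0, 3.0, 5.0])
        D = np.abs(xs[:, None] - xs[None, :])
        res = lb.pcoa(DistanceMatrix(D, ids=["a", "b", "c"]), n_axes=3)
        coords = res.coordinates
        for i in range(3):
            for j in range(3):
                got = abs(coords[i, 0] - coords[j, 0])
                assert got == pytest.approx(D[i, j], abs=1e-9)
        assert len(res.eigenvalues) == 1  # remaining eigenvalues are ~0

    def test_identical_samples_identical_coordinates(self):
        D = np.array([[0, 0, 1.0], [0, 0, 1.0], [1.0, 1.0, 0]])
        res = lb.pcoa(DistanceMatrix(D, ids=list("abc")), n_axes=2)
        assert np.allclose(res.coordinates[0], res.coordinates[1], atol=1e-9)

    def test_plane_distances_and_trace_identity(self):
        rng = np.random.default_rng(8)
        pts = rng.normal(size=(7, 2))
        D = squareform(pdist(pts))
        dm = DistanceMatrix(D, ids=[f"s{i}" for i in range(7)])
        res = lb.pcoa(dm, n_axes=7)
        # all pairwise distances reproduced by the positive axes
        rec = squareform(pdist(res.coordinates))
        assert np.allclose(rec, D, atol=1e-9)
        # Gower-centering trace identity for Euclidean input
        assert res.eigenvalues.sum() == pytest.approx((D**2).sum() / (2 * 7), abs=1e-9)
        assert (np.diff(res.eigenvalues) <= 1e-12).all()
        assert res.proportion_explained.sum() <= 1 + 1e-12

    def test_agrees_with_skbio(self):
        rng = np.random.default_rng(12)
        pts = rng.normal(size=(6, 3))
        dm = DistanceMatrix(squareform(pdist(pts)), ids=[f"s{i}" for i in range(6)])
        mine = lb.pcoa(dm, n_axes=3)
        ref = skbio_pcoa(dm, number_of_dimensions=3)
        assert np.allclose(
            np.abs(mine.coordinates), np.abs(ref.samples.values[:, :3]), atol=1e-6
        )

    def test_invalid_axes(self):
        dm = DistanceMatrix(np.array([[0, 1.0], [1.0, 0]]), ids=["a", "b"])
        with pytest.raises(ValueError):
            lb.pcoa(dm, n_axes=0)


class TestPermanova:
    def _separated(self):
        D = np.ones((4, 4)) - np.eye(4)
        D[0, 1] = D[1, 0] = 0.0
        D[2, 3] = D[3, 2] = 0.0
        return DistanceMatrix(D, ids=list("abcd")), {"a": "g1", "b": "g1", "c": "g2", "d": "g2"}

    def test_perfect_separation_r2_is_one(self):
        dm, groups = self._separated()
        res = lb.permanova(dm, groups, n_permutations=99, seed=0)
        assert res.r_squared == pytest.approx(1.0)

    def test_constant_distances_give_p_one(self):
        D = np.ones((6, 6)) - np.eye(6)
        dm = DistanceMatrix(D, ids=list("abcdef"))
        groups = dict(zip("abcdef", ["x", "x", "x", "y", "y", "y"]))
        res = lb.permanova(dm, groups, n_permutations=199, seed=1)
        assert res.p_value == pytest.approx(1.0)

    def test_seeded_reproducibility_and_r2_stability(self):
        rng = np.random.default_rng(5)
        pts = rng.normal(size=(12, 4))
        dm = DistanceMatrix(squareform(pdist(pts)), ids=[f"s{i}" for i in range(12)])
        groups = {f"s{i}": f"g{i % 3}" for i in range(12)}
        a = lb.permanova(dm, groups, n_permutations=199, seed=7)
        b = lb.permanova(dm, groups, n_permutations=199, seed=7)
        c = lb.permanova(dm, groups, n_permutations=499, seed=3)
        assert a.p_value == b.p_value and a.pseudo_F == b.pseudo_F
        assert a.r_squared == pytest.approx(c.r_squared)

    def test_pseudo_f_matches_skbio(self):
        rng = np.random.default_rng(6)
        pts = rng.normal(size=(10, 3))
        dm = DistanceMatrix(squareform(pdist(pts)), ids=[f"s{i}" for i in range(10)])
        labels = ["g1"] * 5 + ["g2"] * 5
        mine = lb.permanova(dm, dict(zip(dm.ids, labels)), n_permutations=99, seed=0)
        ref = skbio_permanova(dm, grouping=labels, permutations=99)
        assert mine.pseudo_F == pytest.approx(ref["test statistic"], rel=1e-9)

    def test_type_I_error_within_binomial_bounds(self):
        # random labels on structureless data: rejection rate at alpha=0.05
        # should match alpha over replicates
        rng = np.random.default_rng(2024)
        rejections = 0
        n_rep = 200
        for _ in range(n_rep):
            pts = rng.normal(size=(12, 3))
            dm = DistanceMatrix(
                squareform(pdist(pts)), ids=[f"s{i}" for i in range(12)]
            )
            labels = rng.permutation(["g1"] * 4 + ["g2"] * 4 + ["g3"] * 4)
            res = lb.permanova(
                dm, dict(zip(dm.ids, labels)), n_permutations=199,
                seed=int(rng.integers(2**31 - 1)),
            )
            rejections += res.p_value <= 0.05
        lo = 0.05 - 1.96 * np.sqrt(0.05 * 0.95 / n_rep)
        hi = 0.05 + 1.96 * np.sqrt(0.05 * 0.95 / n_rep)
        assert lo <= rejections / n_rep <= hi

    def test_single_group_errors(self):
        D = np.ones((3, 3)) - np.eye(3)
        dm = DistanceMatrix(D, ids=list("abc"))
        with pytest.raises(ValueError):
            lb.permanova(dm, {"a": "g", "b": "g", "c": "g"}, seed=0)


class TestPairwiseHolm:
    def _metadata(self, n_subjects=6, sites=("oral", "nasal", "lung")):
        rows = []
        for i in range(n_subjects):
            for site in sites:
                rows.append(
                    {
                        "sample_id": f"S{i}_{site}",
                        "subject_id": f"S{i}",
                        "site": site,
                        "batch": "run1",
                    }
                )
        return lb.SampleMetadata(pd.DataFrame(rows))

    def test_holm_adjustment_matches_step_down_definition(self):
        meta = self._metadata()
        rng = np.random.default_rng(3)
        values = {
            f"S{i}_{site}": rng.normal(loc={"oral": 0, "nasal": 1, "lung": 0.5}[site])
            for i in range(6)
            for site in ("oral", "nasal", "lung")
        }
        out = lb.pairwise_tests_holm(values, meta, sites=("oral", "nasal", "lung"))
        raw = out["p_raw"].to_numpy()
        m = len(raw)
        order = np.argsort(raw)
        expected = np.empty(m)
        running = 0.0
        for rank, idx in enumerate(order):
            running = max(running, min(1.0, (m - rank) * raw[idx]))
            expected[idx] = running
        assert np.allclose(out["p_holm"].to_numpy(), expected)
        assert (np.diff(out.sort_values("p_raw")["p_holm"]) >= -1e-12).all()

    def test_single_pair_adjusted_equals_raw(self):
        meta = self._metadata(sites=("oral", "lung"))
        rng = np.random.default_rng(4)
        values = {s: rng.normal() for s in meta.sample_ids}
        out = lb.pairwise_tests_holm(values, meta, sites=("oral", "lung"))
        assert len(out) == 1
        assert out["p_holm"].iloc[0] == pytest.approx(out["p_raw"].iloc[0])

    def test_zero_variance_reports_p_one(self):
        meta = self._metadata(sites=("oral", "lung"))
        values = {s: 1.0 for s in meta.sample_ids}
        out = lb.pairwise_tests_holm(values, meta, sites=("oral", "lung"))
        assert out["p_raw"].iloc[0] == 1.0

    def test_insufficient_pairs_not_testable(self):
        meta = self._metadata(n_subjects=1, sites=("oral", "lung"))
        values = {s: 1.0 for s in meta.sample_ids}
        out = lb.pairwise_tests_holm(values, meta, sites=("oral", "lung"))
        assert not out["testable"].iloc[0]
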