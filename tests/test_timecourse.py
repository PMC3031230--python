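"""PCC matrices, phase segmentation, PCA, gene trees and spike flags."""

import numpy as np
import pandas as pd
import pytest

from fieldtx import io, timecourse


def _frame(arr, prefix="s"):
    arr = np.asarray(arr, dtype=float)
    return pd.DataFrame(arr, index=[f"g{i}" for i in range(arr.shape[0])],
                        columns=[f"{prefix}{j}" for j in range(arr.shape[1])])


class TestPccMatrix:
    def test_duplicated_column_correlates_perfectly(self, rng):
        col = rng.normal(size=50)
        mat = _frame(np.column_stack([col, col, rng.normal(size=50)]))
        pcc = timecourse.pcc_matrix(mat)
        assert pcc.iloc[0, 1] == pytest.approx(1.0, abs=1e-12)

    def test_negated_column_gives_minus_one(self, rng):
        col = rng.normal(size=50)
        pcc = timecourse.pcc_matrix(_frame(np.column_stack([col, -col])))
        assert pcc.iloc[0, 1] == pytest.approx(-1.0, abs=1e-12)

    def test_matches_covariance_oracle(self, rng):
        mat = _frame(rng.normal(size=(500, 6)))
        pcc = timecourse.pcc_matrix(mat).to_numpy()
        arr = mat.to_numpy()
        for i in range(6):
            for j in range(6):
                x, y = arr[:, i], arr[:, j]
                expected = (((x - x.mean()) * (y - y.mean())).mean()
                            / (x.std() * y.std()))
                assert pcc[i, j] == pytest.approx(expected, abs=1e-12)
        np.testing.assert_array_equal(pcc, pcc.T)

    def test_constant_column_rejected_by_name(self, rng):
        mat = _frame(rng.normal(size=(20, 2)))
        mat["s2"] = 3.0
        with pytest.raises(ValueError, match="s2"):
            timecourse.pcc_matrix(mat)


def _block_pcc(sizes, within=0.95, between=0.3):
    n = sum(sizes)
    r = np.full((n, n), between)
    start = 0
    for size in sizes:
        r[start:start + size, start:start + size] = within
        start += size
    np.fill_diagonal(r, 1.0)
    labels = [f"t{i}" for i in range(n)]
    return pd.DataFrame(r, index=labels, columns=labels)


class TestSegmentPhases:
    def test_block_structure_recovered_exactly(self):
        pcc = _block_pcc([5, 7, 5])
        seg = timecourse.segment_phases(pcc, k=3)
        np.testing.assert_array_equal(
            seg.phase_labels, [1] * 5 + [2] * 7 + [3] * 5)
        assert seg.boundaries == [("t4", "t5"), ("t11", "t12")]

    def test_k_equal_n_gives_singleton_phases(self):
        pcc = _block_pcc([2, 2])
        seg = timecourse.segment_phases(pcc, k=4)
        np.testing.assert_array_equal(seg.phase_labels, [1, 2, 3, 4])

    def test_k_below_two_rejected(self):
        with pytest.raises(ValueError, match="k"):
            timecourse.segment_phases(_block_pcc([3, 3]), k=1)

    def test_labels_are_contiguous_and_nondecreasing(self, rng):
        # noisy correlation matrices must still yield contiguous labels
        for _ in range(10):
            base = _block_pcc([6, 5, 6]).to_numpy()
            noise = rng.normal(0, 0.05, size=base.shape)
            noise = (noise + noise.T) / 2
            r = np.clip(base + noise, -1, 1)
            np.fill_diagonal(r, 1.0)
            pcc = pd.DataFrame(r, index=[f"t{i}" for i in range(17)],
                               columns=[f"t{i}" for i in range(17)])
            seg = timecourse.segment_phases(pcc, k=3)
            assert (np.diff(seg.phase_labels) >= 0).all()
            assert len(np.unique(seg.phase_labels)) == 3

    def test_invariant_to_constant_shift_of_expression(self, rng):
        mat = _frame(rng.normal(size=(200, 9)))
        seg1 = timecourse.segment_phases(timecourse.pcc_matrix(mat), k=3)
        seg2 = timecourse.segment_phases(
            timecourse.pcc_matrix(mat + 5.0), k=3)
        np.testing.assert_array_equal(seg1.phase_labels, seg2.phase_labels)


class TestPCA:
    def test_two_point_geometry(self, rng):
        a, b = rng.normal(size=100), rng.normal(size=100)
        mat = _frame(np.column_stack([a, a, b, b]))
        res = timecourse.pca(mat)
        assert res.variance_ratio[0] == pytest.approx(1.0, abs=1e-10)
        scores = res.scores["PC1"]
        assert scores.iloc[0] == pytest.approx(scores.iloc[1], abs=1e-8)
        assert abs(scores.iloc[0] - scores.iloc[2]) > 1.0

    def test_variance_fractions_sum_to_one(self, rng):
        res = timecourse.pca(_frame(rng.normal(size=(80, 7))))
        assert res.variance_ratio.sum() == pytest.approx(1.0, abs=1e-12)

    def test_reconstruction_identity(self, rng):
        mat = _frame(rng.normal(size=(40, 6)))
        res = timecourse.pca(mat)
        recon = (res.scores.to_numpy() @ res.loadings.to_numpy().T
                 + res.means.to_numpy())
        np.testing.assert_allclose(recon, mat.to_numpy().T, atol=1e-10)

    def test_sign_convention_deterministic(self, rng):
        mat = _frame(rng.normal(size=(30, 5)))
        res = timecourse.pca(mat)
        for c in res.loadings.columns:
            col = res.loadings[c].to_numpy()
            assert col[np.argmax(np.abs(col))] > 0


def _naive_average_linkage(d):
    """O(n^3) agglomeration oracle: merge order and heights."""
    active = {i: [i] for i in range(d.shape[0])}
    heights = []
    merges = []
    nxt = d.shape[0]
    dd = {(i, j): d[i, j] for i in range(d.shape[0])
          for j in range(i + 1, d.shape[0])}
    while len(active) > 1:
        (i, j), h = min(dd.items(), key=lambda kv: kv[1])
        heights.append(h)
        merges.append(frozenset(active[i] + active[j]))
        members = active[i] + active[j]
        del active[i], active[j]
        for k in list(active):
            dd[(min(k, nxt), max(k, nxt))] = np.mean(
                [d[a, b] for a in members for b in active[k]])
        active[nxt] = members
        nxt += 1
        dd = {key: v for key, v in dd.items()
              if key[0] in active and key[1] in active}
    return merges, heights


class TestHclustGenes:
    def test_uncentered_distance_is_scale_invariant(self, rng):
        x = rng.normal(size=8)
        mat = _frame(np.vstack([x, 2 * x]))
        tree = timecourse.hclust_genes(mat, distance="uncentered",
                                       linkage="average")
        assert tree.linkage[0, 2] == pytest.approx(0.0, abs=1e-12)

    def test_orthogonal_profiles_at_distance_one(self):
        mat = _frame([[1.0, 0.0, 1.0, 0.0], [0.0, 1.0, 0.0, 1.0]])
        tree = timecourse.hclust_genes(mat, distance="uncentered",
                                       linkage="average")
        assert tree.linkage[0, 2] == pytest.approx(1.0, abs=1e-12)

    def test_merge_sequence_matches_naive_oracle(self, rng):
        mat = _frame(rng.normal(size=(8, 10)))
        tree = timecourse.hclust_genes(mat, distance="uncentered",
                                       linkage="average")
        X = mat.to_numpy()
        ss = (X ** 2).sum(axis=1)
        d = 1 - (X @ X.T) / np.sqrt(np.outer(ss, ss))
        np.fill_diagonal(d, 0.0)
        _, heights = _naive_average_linkage(d)
        np.testing.assert_allclose(tree.linkage[:, 2], heights, atol=1e-10)

    def test_centroid_inversions_are_recorded_not_hidden(self, rng):
        # centroid linkage on correlation-type distances can invert;
        # over many random draws at least one inversion must be caught
        found = False
        for seed in range(30):
            r = np.random.default_rng(seed)
            mat = _frame(r.normal(size=(12, 6)))
            tree = timecourse.hclust_genes(mat, distance="uncentered",
                                           linkage="centroid")
            heights = tree.linkage[:, 2]
            has_inversion = any(np.diff(heights) < 0)
            if tree.inversions:
                found = True
            if has_inversion:
                assert tree.inversions
        assert found

    def test_zero_profile_warns(self):
        mat = _frame([[0.0, 0.0, 0.0], [1.0, 2.0, 3.0]])
        with pytest.warns(UserWarning, match="zero"):
            timecourse.hclust_genes(mat, distance="uncentered",
                                    linkage="average")


class TestRefineDEByCluster:
    @staticmethod
    def _series(rng, n_step=30, n_blip=10, n_t=10, step=2.0):
        rows, kinds = [], []
        for _ in range(n_step):
            sign = 1 if rng.random() < 0.5 else -1
            prof = np.zeros(n_t)
            prof[5:] += sign * step
            rows.append(prof + rng.normal(0, 0.1, n_t))
            kinds.append("step_up" if sign > 0 else "step_down")
        for _ in range(n_blip):
            prof = np.zeros(n_t)
            prof[5] += 6.0
            rows.append(prof + rng.normal(0, 0.1, n_t))
            kinds.append("blip")
        mat = pd.DataFrame(rows, index=[f"g{i:02d}" for i in range(len(rows))],
                           columns=[f"t{j}" for j in range(n_t)])
        return mat, kinds

    def test_single_pattern_returns_full_set(self, rng):
        mat, _ = self._series(rng, n_step=20, n_blip=0)
        mat.iloc[:, :] = np.abs(mat.to_numpy())  # all upward steps
        prof = np.zeros(10)
        prof[5:] = 2.0
        mat = pd.DataFrame(prof + np.random.default_rng(0).normal(0, 0.1, (20, 10)),
                           index=[f"g{i}" for i in range(20)],
                           columns=[f"t{j}" for j in range(10)])
        tree = timecourse.hclust_genes(mat, distance="correlation",
                                       linkage="average")
        up, down = timecourse.refine_de_by_cluster(tree, mat, ("t4", "t5"),
                                                   n_cut=3)
        assert len(up) == 20 and len(down) == 0

    def test_blip_cluster_excluded_steps_kept(self, rng):
        mat, kinds = self._series(rng)
        tree = timecourse.hclust_genes(mat, distance="correlation",
                                       linkage="average")
        up, down = timecourse.refine_de_by_cluster(tree, mat, ("t4", "t5"),
                                                   n_cut=6)
        kept = set(up) | set(down)
        steps = {g for g, k in zip(mat.index, kinds) if k.startswith("step")}
        blips = {g for g, k in zip(mat.index, kinds) if k == "blip"}
        assert len(kept & steps) >= 0.9 * len(steps)
        assert not kept & blips

    def test_empty_input_gives_empty_output(self):
        empty = pd.DataFrame(columns=["t0", "t1"])
        up, down = timecourse.refine_de_by_cluster(None, empty, ("t0", "t1"))
        assert len(up) == 0 and len(down) == 0

    def test_n_cut_larger_than_gene_count_rejected(self, rng):
        mat, _ = self._series(rng, n_step=4, n_blip=0)
        tree = timecourse.hclust_genes(mat, distance="correlation",
                                       linkage="average")
        with pytest.raises(ValueError, match="n_cut"):
            timecourse.refine_de_by_cluster(tree, mat, ("t4", "t5"), n_cut=99)


class TestDetectTransientSpike:
    def test_monotone_profile_not_flagged(self):
        mat = _frame([np.linspace(0, 10, 9)], prefix="t")
        report = timecourse.detect_transient_spike(mat)
        assert len(report.all_flagged) == 0

    def test_planted_hundredfold_spike_flagged(self, rng):
        prof = rng.normal(0, 0.2, size=9)
        prof[4] += np.log2(100)
        mat = _frame([prof], prefix="t")
        report = timecourse.detect_transient_spike(mat, min_ratio=32)
        assert report.modal_timepoint == "t4"
        assert "g0" in report.flagged["t4"]

    def test_planted_spikes_in_generated_series(self, timecourse_small):
        raw, meta, truth = timecourse_small
        keep = io.filter_by_raw_intensity(raw)
        log2 = io.percentile_normalize(io.RawMatrix(raw.values.loc[keep]))
        means = io.average_replicates(log2, meta)
        report = timecourse.detect_transient_spike(means, min_ratio=32)
        planted = set(truth["spike"]) & set(means.index)
        assert planted <= set(report.all_flagged)
        assert len(set(report.all_flagged) - set(truth["spike"])) <= 1
        assert report.modal_timepoint == f"T{truth['spike_timepoint_dat']}"

    def test_too_few_timepoints_rejected(self):
        with pytest.raises(ValueError, match="3 timepoints"):
            timecourse.detect_transient_spike(_frame([[1.0, 2.0]]))
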