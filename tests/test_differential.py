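"""t-tests, BH adjustment, DE extraction, ANOVA and contrasts."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import integrate, special

from fieldtx import differential, io


def _mat(rows, columns):
    arr = np.asarray(rows, dtype=float)
    return pd.DataFrame(arr, index=[f"g{i}" for i in range(arr.shape[0])],
                        columns=columns)


class TestGeneTTest:
    def test_identical_groups_give_p_one(self):
        mat = _mat([[1.0, 2.0, 3.0, 1.0, 2.0, 3.0]], list("abcdef"))
        res = differential.gene_t_test(mat, ["a", "b", "c"], ["d", "e", "f"])
        assert res.loc["g0", "p"] == pytest.approx(1.0)
        assert res.loc["g0", "log2fc"] == 0.0

    def test_degenerate_zero_variance_unequal_means(self):
        mat = _mat([[0.0, 0.0, 0.0, 1.0, 1.0, 1.0]], list("abcdef"))
        res = differential.gene_t_test(mat, ["a", "b", "c"], ["d", "e", "f"],
                                       variant="pooled")
        assert res.loc["g0", "p"] == 0.0
        assert res.loc["g0", "log2fc"] == 1.0

    def test_welch_p_matches_numerical_integration_oracle(self, rng):
        a = rng.normal(0, 1, size=(200, 4))
        b = rng.normal(0.5, 2, size=(200, 5))
        mat = pd.DataFrame(np.hstack([a, b]),
                           index=[f"g{i}" for i in range(200)],
                           columns=[f"s{j}" for j in range(9)])
        ga, gb = [f"s{j}" for j in range(4)], [f"s{j}" for j in range(4, 9)]
        res = differential.gene_t_test(mat, ga, gb, variant="welch")

        def t_pdf(x, df):
            return (special.gamma((df + 1) / 2)
                    / (np.sqrt(df * np.pi) * special.gamma(df / 2))
                    * (1 + x * x / df) ** (-(df + 1) / 2))

        for i in rng.choice(200, size=12, replace=False):
            xa, xb = a[i], b[i]
            va, vb = xa.var(ddof=1), xb.var(ddof=1)
            na, nb = len(xa), len(xb)
            se2 = va / na + vb / nb
            t = (xb.mean() - xa.mean()) / np.sqrt(se2)
            df = se2 ** 2 / ((va / na) ** 2 / (na - 1)
                             + (vb / nb) ** 2 / (nb - 1))
            tail, _ = integrate.quad(t_pdf, abs(t), np.inf, args=(df,))
            assert res["p"].iloc[i] == pytest.approx(2 * tail, abs=1e-10)

    def test_groups_must_be_disjoint(self):
        mat = _mat([[1.0] * 4], list("abcd"))
        with pytest.raises(ValueError, match="disjoint"):
            differential.gene_t_test(mat, ["a", "b"], ["b", "c"])


def _bh_oracle(p):
    m = len(p)
    order = np.argsort(p, kind="stable")
    q = np.empty(m)
    for rank_idx, i in enumerate(order):
        # min over j >= rank of (m / (j+1)) * p_(j)
        q[i] = min((m / (j + 1)) * p[order[j]] for j in range(rank_idx, m))
    return np.minimum(q, 1.0)


class TestBHAdjust:
    def test_all_equal_p_unchanged(self):
        q = differential.bh_adjust([0.2] * 7)
        np.testing.assert_allclose(q, 0.2)

    def test_arithmetic_from_definition(self):
        q = differential.bh_adjust([0.01, 0.02, 0.03, 0.04])
        np.testing.assert_allclose(q, [0.04, 0.04, 0.04, 0.04])

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(40):
            p = rng.uniform(size=rng.integers(1, 60))
            np.testing.assert_allclose(differential.bh_adjust(p),
                                       _bh_oracle(p), atol=1e-12)

    @settings(deadline=None, max_examples=30)
    @given(st.lists(st.floats(min_value=0.0, max_value=1.0),
                    min_size=2, max_size=30))
    def test_permutation_equivariant(self, p):
        p = np.array(p)
        perm = np.random.default_rng(1).permutation(len(p))
        np.testing.assert_allclose(differential.bh_adjust(p)[perm],
                                   differential.bh_adjust(p[perm]),
                                   atol=1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            differential.bh_adjust([0.1, 1.5])


class TestExtractDE:
    @staticmethod
    def _planted(rng, n_bg=900, n_up=50, n_down=50, effect=2.0, sd=0.25,
                 n_rep=3):
        n = n_bg + n_up + n_down
        base = rng.normal(8, 1, size=n)
        a = base[:, None] + rng.normal(0, sd, size=(n, n_rep))
        b = base[:, None] + rng.normal(0, sd, size=(n, n_rep))
        b[n_bg:n_bg + n_up] += effect
        b[n_bg + n_up:] -= effect
        genes = [f"g{i}" for i in range(n)]
        mat = pd.DataFrame(np.hstack([a, b]), index=genes,
                           columns=[f"a{j}" for j in range(n_rep)]
                           + [f"b{j}" for j in range(n_rep)])
        return (mat, set(genes[n_bg:n_bg + n_up]), set(genes[n_bg + n_up:]))

    def test_planted_four_fold_recovery(self, rng):
        # contrast over the planted 50 up + 50 down genes (4-fold,
        # n=3/group, sigma=0.25 log2) with a modest null background
        mat, up_truth, down_truth = self._planted(rng, n_bg=100)
        ga = [c for c in mat.columns if c.startswith("a")]
        gb = [c for c in mat.columns if c.startswith("b")]
        res = differential.extract_de(mat, ga, gb, fdr_max=0.05, fc_min=3.0)
        recall = (len(set(res.up) & up_truth)
                  + len(set(res.down) & down_truth)) / 100
        false_pos = len(set(res.selected) - up_truth - down_truth)
        assert recall >= 0.9
        assert false_pos <= 2

    def test_sets_shrink_with_stricter_thresholds(self, rng):
        mat, _, _ = self._planted(rng, n_bg=300, n_up=30, n_down=30)
        ga = [c for c in mat.columns if c.startswith("a")]
        gb = [c for c in mat.columns if c.startswith("b")]
        loose = differential.extract_de(mat, ga, gb, 0.10, 2.0)
        tight = differential.extract_de(mat, ga, gb, 0.01, 4.0)
        assert set(tight.selected) <= set(loose.selected)

    def test_swapping_groups_exchanges_up_and_down(self, rng):
        mat, _, _ = self._planted(rng, n_bg=200, n_up=20, n_down=20)
        ga = [c for c in mat.columns if c.startswith("a")]
        gb = [c for c in mat.columns if c.startswith("b")]
        fwd = differential.extract_de(mat, ga, gb)
        rev = differential.extract_de(mat, gb, ga)
        assert set(fwd.up) == set(rev.down)
        assert set(fwd.down) == set(rev.up)

    def test_fc_equals_two_to_abs_log2fc(self, rng):
        mat, _, _ = self._planted(rng, n_bg=100, n_up=10, n_down=10)
        ga = [c for c in mat.columns if c.startswith("a")]
        gb = [c for c in mat.columns if c.startswith("b")]
        table = differential.extract_de(mat, ga, gb).table
        np.testing.assert_array_equal(
            table["fc"].to_numpy(),
            np.exp2(np.abs(table["log2fc"].to_numpy())))

    def test_empty_group_rejected(self):
        mat = _mat([[1.0] * 4], list("abcd"))
        with pytest.raises(ValueError, match="empty"):
            differential.extract_de(mat, [], ["a", "b"])


class TestDiurnalExtraction:
    def test_planted_leaf_blade_fraction(self, field_small, field_small_norm):
        raw, meta, truth = field_small
        log2, _ = field_small_norm
        keep = io.filter_by_raw_intensity(raw)
        res = differential.diurnal_extraction(log2.values.loc[keep], meta,
                                              "leaf blade")
        fraction = len(res.selected) / len(keep)
        planted_fraction = sum(
            1 for v in truth["diurnal"].values()
            if v["organ"] == "leaf blade") / len(keep)
        assert abs(fraction - planted_fraction) < 0.02

    def test_no_planted_diurnal_in_root(self, field_small, field_small_norm):
        raw, meta, _ = field_small
        log2, _ = field_small_norm
        keep = io.filter_by_raw_intensity(raw)
        res = differential.diurnal_extraction(log2.values.loc[keep], meta,
                                              "root")
        assert len(res.selected) <= 2

    def test_missing_timepoint_rejected(self, field_small, field_small_norm):
        _, meta, _ = field_small
        log2, _ = field_small_norm
        with pytest.raises(ValueError, match="12:00 or 24:00"):
            differential.diurnal_extraction(log2.values, meta, "anther")


class TestUniversalIntersection:
    @staticmethod
    def _result(up, down):
        table = pd.DataFrame(index=pd.Index(list(up) + list(down)))
        return differential.DEResult(table=table, up=pd.Index(list(up)),
                                     down=pd.Index(list(down)))

    def test_disjoint_sets_empty_intersection(self):
        venn = differential.universal_intersection({
            "x": self._result({"a"}, set()),
            "y": self._result({"b"}, set())})
        assert venn.universal == set()
        assert venn.region("x") == {"a"}

    def test_identical_sets(self):
        venn = differential.universal_intersection({
            "x": self._result({"a", "b"}, set()),
            "y": self._result({"a", "b"}, set())})
        assert venn.universal == {"a", "b"}
        assert all(venn.concordant.values())

    def test_direction_discordance_flagged(self):
        venn = differential.universal_intersection({
            "x": self._result({"a"}, set()),
            "y": self._result(set(), {"a"})})
        assert venn.universal == {"a"}
        assert venn.concordant["a"] is False

    def test_regions_match_brute_force(self, rng):
        names = ["t1", "t2", "t3"]
        genes = [f"g{i}" for i in range(40)]
        member = {n: set(rng.choice(genes, size=15, replace=False))
                  for n in names}
        venn = differential.universal_intersection(
            {n: self._result(member[n], set()) for n in names})
        total = 0
        for combo, region in venn.regions.items():
            for g in region:
                assert all(g in member[n] for n in combo)
                assert all(g not in member[n] for n in names
                           if n not in combo)
            total += len(region)
        assert total == len(set.union(*member.values()))


class TestTwoWayAnova:
    @staticmethod
    def _design(n_rep=3):
        samples, fa, fb = [], {}, {}
        for t in ("lemma", "palea"):
            for s in ("s1", "s2", "s3"):
                for r in range(n_rep):
                    sid = f"{t}_{s}_{r}"
                    samples.append(sid)
                    fa[sid] = t
                    fb[sid] = s
        return samples, pd.Series(fa), pd.Series(fb)

    def test_matches_statsmodels_oracle(self, rng):
        import statsmodels.api as sm
        from statsmodels.formula.api import ols
        samples, fa, fb = self._design()
        mat = pd.DataFrame(rng.normal(size=(5, len(samples))),
                           index=[f"g{i}" for i in range(5)],
                           columns=samples)
        res = differential.two_way_anova(mat, fa, fb)
        for g in mat.index:
            df = pd.DataFrame({"y": mat.loc[g],
                               "tissue": fa[samples].to_numpy(),
                               "stage": fb[samples].to_numpy()})
            fit = ols("y ~ C(tissue) * C(stage)", data=df).fit()
            tab = sm.stats.anova_lm(fit, typ=1)
            assert res.loc[g, "p_tissue"] == pytest.approx(
                tab.loc["C(tissue)", "PR(>F)"], rel=1e-8)
            assert res.loc[g, "p_stage"] == pytest.approx(
                tab.loc["C(stage)", "PR(>F)"], rel=1e-8)
            assert res.loc[g, "p_interaction"] == pytest.approx(
                tab.loc["C(tissue):C(stage)", "PR(>F)"], rel=1e-8)

    def test_null_p_values_uniform(self, rng):
        from scipy import stats
        samples, fa, fb = self._design()
        mat = pd.DataFrame(rng.normal(size=(2000, len(samples))),
                           index=[f"g{i}" for i in range(2000)],
                           columns=samples)
        res = differential.two_way_anova(mat, fa, fb)
        for col in ("p_tissue", "p_stage", "p_interaction"):
            assert stats.kstest(res[col], "uniform").pvalue > 0.01

    def test_pure_tissue_shift_detected(self, rng):
        samples, fa, fb = self._design()
        vals = rng.normal(scale=0.25, size=(1, len(samples)))
        shift = np.array([2.0 if fa[s] == "lemma" else 0.0 for s in samples])
        mat = pd.DataFrame(vals + shift, index=["g"], columns=samples)
        res = differential.two_way_anova(mat, fa, fb)
        assert res.loc["g", "p_tissue"] < 1e-6
        assert res.loc["g", "p_interaction"] > 0.001

    def test_factor_order_invariance(self, rng):
        samples, fa, fb = self._design()
        mat = pd.DataFrame(rng.normal(size=(10, len(samples))),
                           index=[f"g{i}" for i in range(10)],
                           columns=samples)
        res1 = differential.two_way_anova(mat, fa, fb)
        res2 = differential.two_way_anova(mat, fb, fa)
        np.testing.assert_allclose(res1["p_tissue"], res2["p_stage"],
                                   rtol=1e-10)
        np.testing.assert_allclose(res1["p_interaction"],
                                   res2["p_interaction"], rtol=1e-10)

    def test_unbalanced_design_rejected(self, rng):
        samples, fa, fb = self._design()
        samples = samples[:-1]  # drop one replicate
        mat = pd.DataFrame(rng.normal(size=(2, len(samples))),
                           columns=samples)
        with pytest.raises(ValueError, match="balanced|>= 2"):
            differential.two_way_anova(mat, fa, fb)


class TestFertileSterileContrast:
    def test_divergence_grows_with_week(self, fertile_sterile_small):
        raw, meta, _ = fertile_sterile_small
        keep = io.filter_by_raw_intensity(raw)
        log2 = io.percentile_normalize(io.RawMatrix(raw.values.loc[keep]))
        sizes = [len(differential.fertile_sterile_contrast(
            log2.values, meta, week=w).selected) for w in (0, 1, 2, 3)]
        assert sizes[0] <= 2  # no divergence planted at heading
        assert sizes[1] < sizes[2] < sizes[3]

    def test_label_swap_antisymmetry(self, fertile_sterile_small):
        raw, meta, _ = fertile_sterile_small
        log2 = io.percentile_normalize(raw)
        res = differential.fertile_sterile_contrast(log2.values, meta, week=3)
        fertile = meta.select(genotype="fertile", week=3)
        sterile = meta.select(genotype="sterile", week=3)
        swapped = differential.extract_de(log2.values, fertile, sterile,
                                          fdr_max=0.05, fc_min=2.0)
        assert set(res.up) == set(swapped.down)
        assert set(res.down) == set(swapped.up)

    def test_missing_genotype_rejected(self, field_small, field_small_norm):
        _, meta, _ = field_small
        log2, _ = field_small_norm
        with pytest.raises((ValueError, KeyError)):
            differential.fertile_sterile_contrast(log2.values, meta, week=0)
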