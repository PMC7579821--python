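import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from holosplit.expression import (
    CountMatrix,
    benjamini_hochberg,
    cpm,
    de_test,
    detect_outliers,
    normalize,
    overlap_sets,
    phase_specific_sets,
    remove_outliers,
    tmm_factors,
    zscore_rows,
)
from holosplit.synthetic import SimulationConfig, gen_counts
from _oracles import bh_brute


@pytest.fixture
def random_counts(rng):
    counts = pd.DataFrame(
        rng.poisson(50, size=(300, 6)),
        index=[f"g{i}" for i in range(300)],
        columns=[f"s{i}" for i in range(6)],
    )
    return counts + 1  # keep all genes expressed


class TestTmm:
    def test_pure_depth_difference_gives_unit_factors(self, random_counts):
        counts = random_counts.copy()
        counts["s1"] = 2 * counts["s0"]
        f = tmm_factors(counts)
        assert f["s0"] == pytest.approx(f["s1"], rel=1e-9)

    def test_identical_columns_give_unit_factors(self, random_counts):
        counts = pd.concat([random_counts["s0"]] * 4, axis=1)
        counts.columns = list("abcd")
        f = tmm_factors(counts)
        assert np.allclose(f, 1.0)

    def test_partial_inflation_lowers_factor(self, rng):
        """Composition bias: a sample where 5% of genes are 8-fold
        inflated consumes sequencing depth, so the unchanged majority of
        its genes look under-expressed after library-size adjustment and
        the trimmed mean of M pushes its factor below 1 (the direction
        the published normalization scheme produces)."""
        counts = pd.DataFrame(
            rng.poisson(100, size=(1000, 4)) + 1, columns=list("abcd")
        )
        inflated = counts.copy()
        inflated.loc[: int(0.05 * 1000), "d"] *= 8  # 5% of genes 8-fold up
        f = tmm_factors(inflated)
        assert f["d"] < 1.0
        assert np.allclose(f[["a", "b", "c"]], f[["a", "b", "c"]].mean(), atol=0.02)
        assert (f[["a", "b", "c"]] > f["d"]).all()

    def test_scale_invariance_up_to_weighting(self, random_counts):
        """Rescaling a column's depth leaves factors essentially
        unchanged.  Invariance is not exact: the inverse-variance weights
        of the published scheme depend weakly on absolute depth."""
        f1 = tmm_factors(random_counts)
        scaled = random_counts.copy()
        scaled["s2"] = scaled["s2"] * 7
        f2 = tmm_factors(scaled)
        assert np.allclose(f1, f2, atol=0.01)

    def test_geometric_mean_is_one(self, random_counts):
        f = tmm_factors(random_counts)
        assert np.exp(np.mean(np.log(f))) == pytest.approx(1.0)

    def test_all_zero_sample_named_in_error(self, random_counts):
        counts = random_counts.copy()
        counts["s3"] = 0
        with pytest.raises(ValueError, match="s3"):
            tmm_factors(counts)

    def test_matches_edger_calcnormfactors(self, rng, tmp_path):
        """Cross-check against the reference R implementation on a small
        fixed matrix (skipped silently only if Rscript is unavailable)."""
        import shutil
        import subprocess

        if shutil.which("Rscript") is None:
            pytest.skip("Rscript not on PATH")
        counts = pd.DataFrame(
            rng.poisson(80, size=(500, 5)) + 1, columns=list("abcde")
        )
        counts.loc[:40, "e"] *= 6
        csv = tmp_path / "counts.csv"
        counts.to_csv(csv, index=False)
        script = tmp_path / "tmm.R"
        script.write_text(
            "suppressMessages(library(edgeR));"
            f"x <- as.matrix(read.csv('{csv}'));"
            "cat(calcNormFactors(x, method='TMM'), sep='\\n')"
        )
        out = subprocess.run(
            ["Rscript", str(script)], capture_output=True, text=True, check=True
        )
        expected = np.array([float(v) for v in out.stdout.split()])
        ours = tmm_factors(counts).to_numpy()
        assert np.allclose(ours, expected, atol=1e-4)


class TestCpm:
    def test_single_sample_values(self):
        counts = pd.DataFrame({"s": [1, 1, 2]})
        norm = cpm(counts)
        assert list(norm.cpm["s"]) == [250000.0, 250000.0, 500000.0]

    def test_columns_sum_to_one_million_with_unit_factors(self, random_counts):
        norm = cpm(random_counts)
        assert np.allclose(norm.cpm.sum(axis=0), 1e6)

    def test_depth_invariance(self, random_counts):
        norm1 = cpm(random_counts)
        doubled = random_counts.copy()
        doubled["s0"] = 2 * doubled["s0"]
        norm2 = cpm(doubled)
        assert np.allclose(norm1.cpm["s0"], norm2.cpm["s0"])

    def test_nonpositive_factor_rejected(self, random_counts):
        bad = pd.Series(0.0, index=random_counts.columns)
        with pytest.raises(ValueError):
            cpm(random_counts, bad)


def _null_counts(seed, **kwargs):
    cfg = SimulationConfig(
        seed=seed,
        n_planted_per_sex=0,
        n_moderate_per_sex=0,
        n_outliers_per_sex=0,
        **kwargs,
    )
    cm, _ = gen_counts(cfg)
    return cm


class TestDetectOutliers:
    def test_homogeneous_samples_rarely_flagged(self):
        """Per-sample false-positive rate < 5% under the null."""
        flags = samples = 0
        for seed in range(10):
            cm = _null_counts(seed)
            for _, sub in cm.split_by_sex().items():
                rep = detect_outliers(normalize(sub))
                flags += len(rep.flagged)
                samples += len(sub.counts.columns)
        assert flags / samples < 0.05

    def test_permuted_profile_sample_is_flagged(self):
        cfg = SimulationConfig(seed=3)
        cm, truth = gen_counts(cfg)
        for _, sub in cm.split_by_sex().items():
            rep = detect_outliers(normalize(sub))
            planted = set(truth.outlier_samples) & set(sub.counts.columns)
            assert planted <= set(rep.flagged)

    def test_duplicated_sample_not_flagged(self):
        cm = _null_counts(1)
        sub = next(iter(cm.split_by_sex().values()))
        counts = sub.counts.copy()
        counts["dup"] = counts.iloc[:, 0]
        meta = sub.meta.copy()
        meta.loc["dup"] = meta.iloc[0]
        rep = detect_outliers(normalize(CountMatrix(counts, meta)))
        assert "dup" not in rep.flagged

    def test_too_few_samples_rejected(self, random_counts):
        norm = cpm(random_counts.iloc[:, :3])
        with pytest.raises(ValueError):
            detect_outliers(norm)

    def test_removal_never_breaks_replication(self):
        cfg = SimulationConfig(seed=5)
        cm, _ = gen_counts(cfg)
        for _, sub in cm.split_by_sex().items():
            rep = detect_outliers(normalize(sub))
            cleaned = remove_outliers(sub, rep)
            assert cleaned.meta["phase"].value_counts().min() >= 2


class TestDeTest:
    def test_constant_expression_not_de(self):
        cm = _null_counts(2)
        sub = next(iter(cm.split_by_sex().values()))
        # identical columns: every gene has constant CPM across samples
        counts = pd.concat([sub.counts.iloc[:, 0]] * len(sub.counts.columns), axis=1)
        counts.columns = sub.counts.columns
        de = de_test(cpm(counts, meta=sub.meta))
        assert (de.table["p"] == 1.0).all()
        assert not de.table["is_de"].any()

    def test_planted_strong_effects_detected(self):
        cfg = SimulationConfig(seed=11)
        cm, truth = gen_counts(cfg)
        sub = cm.split_by_sex()["F"]
        rep = detect_outliers(normalize(sub))
        de = de_test(normalize(remove_outliers(sub, rep)))
        strong = truth.high_fc_truth("F", 4.0)
        sens = len(strong & de.de_genes) / len(strong)
        assert sens >= 0.9

    def test_q_at_least_p_and_specific_only_when_de(self):
        cfg = SimulationConfig(seed=11)
        cm, _ = gen_counts(cfg)
        de = de_test(normalize(cm.split_by_sex()["M"]))
        assert (de.table["q"] >= de.table["p"] - 1e-12).all()
        has_phase = de.table["specific_phase"].notna()
        assert (has_phase <= de.table["is_de"]).all()

    def test_underreplicated_phase_rejected(self):
        cm = _null_counts(2)
        sub = next(iter(cm.split_by_sex().values()))
        early = [s for s in sub.counts.columns if sub.meta.loc[s, "phase"] == "early"]
        keep = [s for s in sub.counts.columns if s not in early[1:]]
        with pytest.raises(ValueError, match="early"):
            de_test(normalize(sub.subset_samples(keep)))


class TestBenjaminiHochberg:
    @given(
        st.lists(
            st.floats(min_value=1e-12, max_value=1.0, allow_nan=False),
            min_size=1,
            max_size=100,
        )
    )
    def test_matches_step_up_brute_force(self, pvals):
        ours = benjamini_hochberg(np.array(pvals))
        expected = bh_brute(pvals)
        assert np.allclose(ours, np.minimum(expected, 1.0))


class TestPhaseSpecificSets:
    def _de_with_means(self, means_rows, is_de=True):
        genes = [f"g{i}" for i in range(len(means_rows))]
        phase_means = pd.DataFrame(
            means_rows, index=genes, columns=["early", "middle", "late", "mature"]
        )
        table = pd.DataFrame(
            {
                "F": 10.0,
                "p": 1e-6,
                "q": 1e-6 if is_de else 1.0,
                "is_de": is_de,
                "specific_phase": None,
            },
            index=genes,
        )
        means = phase_means.to_numpy()
        for i, g in enumerate(genes):
            order = np.argsort(means[i])
            if is_de and means[i][order[-1]] > means[i][order[-2]]:
                table.loc[g, "specific_phase"] = phase_means.columns[order[-1]]
        from holosplit.expression import DETable

        return DETable(table=table, phase_means=phase_means, alpha=0.05)

    def test_hundredfold_gene_passes_ovary_filter(self):
        de = self._de_with_means([[1, 1, 1, 100]])
        specific, high = phase_specific_sets(de, 5.0)
        # min log2((100+1)/(1+1)) = log2(50.5) ~ 5.66 > 5
        assert specific["mature"] == {"g0"} and high["mature"] == {"g0"}

    def test_two_hundredfold_gene_fails_testis_filter(self):
        de = self._de_with_means([[1, 1, 1, 200]])
        specific, high = phase_specific_sets(de, 8.0)
        # log2(201/2) ~ 6.65 < 8
        assert specific["mature"] == {"g0"} and high["mature"] == set()

    def test_tied_maximal_phases_specific_to_neither(self):
        de = self._de_with_means([[1, 5, 5, 1]])
        specific, _ = phase_specific_sets(de, 5.0)
        assert all(not s for s in specific.values())

    def test_non_de_gene_excluded(self):
        de = self._de_with_means([[1, 1, 1, 100]], is_de=False)
        specific, high = phase_specific_sets(de, 5.0)
        assert all(not s for s in specific.values())

    def test_high_fc_subset_of_specific(self, default_report):
        for res in default_report["_internals"]["expression"]["per_sex"].values():
            for phase in res["_specific"]:
                assert res["_high_fc"][phase] <= res["_specific"][phase]
                assert res["_specific"][phase] <= res["_de_table"].de_genes


class TestOverlapAndZscore:
    def _mini_de(self, de_ids, universe):
        from holosplit.expression import DETable

        table = pd.DataFrame(
            {
                "F": 1.0,
                "p": 0.5,
                "q": [0.01 if g in de_ids else 0.9 for g in universe],
                "is_de": [g in de_ids for g in universe],
                "specific_phase": None,
            },
            index=universe,
        )
        means = pd.DataFrame(1.0, index=universe, columns=["early", "mature"])
        return DETable(table=table, phase_means=means, alpha=0.05)

    def test_disjoint_sets_share_nothing(self):
        uni = ["a", "b", "c"]
        out = overlap_sets(self._mini_de({"a", "b"}, uni), self._mini_de({"c"}, uni))
        assert out["shared"] == 0 and out["female_only"] == 2

    def test_identical_sets_fully_shared(self):
        uni = ["a", "b", "c"]
        out = overlap_sets(self._mini_de({"a", "b"}, uni), self._mini_de({"a", "b"}, uni))
        assert out["shared"] == 2

    def test_mismatched_universes_rejected(self):
        with pytest.raises(ValueError):
            overlap_sets(self._mini_de(set(), ["a"]), self._mini_de(set(), ["b"]))

    def test_planted_overlap_recovered(self):
        uni = [f"g{i}" for i in range(100)]
        f = set(uni[:30])
        m = set(uni[27:40])
        out = overlap_sets(self._mini_de(f, uni), self._mini_de(m, uni))
        assert out["shared"] == 3

    def test_zscore_closed_form(self):
        z = zscore_rows(pd.DataFrame([[1.0, 2.0, 3.0]]))
        assert np.allclose(z.to_numpy(), [[-1.2247, 0.0, 1.2247]], atol=1e-4)

    def test_zscore_constant_row_is_zero(self):
        z = zscore_rows(pd.DataFrame([[5.0, 5.0, 5.0]]))
        assert np.allclose(z.to_numpy(), 0.0)

    def test_zscore_rows_standardized(self, rng):
        mat = pd.DataFrame(rng.normal(size=(10, 8)))
        z = zscore_rows(mat)
        assert np.allclose(z.mean(axis=1), 0.0, atol=1e-12)
        assert np.allclose(z.std(axis=1, ddof=0), 1.0)
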