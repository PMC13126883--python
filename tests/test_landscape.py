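"""Chromosome scans, PCA, metaprofiles and correlation analyses."""

import warnings

import numpy as np
import pandas as pd
import pytest

from polymeth import landscape

from conftest import make_records


def _regions(n, chrom="chr1A", spacing=1000, start0=0):
    return pd.DataFrame({
        "gene_id": [f"g{i}" for i in range(n)],
        "anchor_type": "TSS",
        "chrom": chrom,
        "start": start0 + np.arange(n) * spacing,
        "end": start0 + np.arange(n) * spacing + 300,
        "subgenome": chrom[-1] if chrom[-1] in "ABD" else "unknown",
        "strand": "+",
        "multi_utr": False,
    })


class TestChromosomeScan:
    def test_window_count_on_5mb_chromosome(self):
        regions = _regions(5, spacing=1_000_000)
        df = make_records([("chr1A", int(r.start) + 10, "+", 2, 8, "CpG")
                           for r in regions.itertuples()])
        track = landscape.chromosome_scan(df, regions, {"chr1A": 5_000_000})
        assert len(track) == 4
        assert list(track["start"]) == [0, 1_000_000, 2_000_000, 3_000_000]

    def test_uniform_level_gives_flat_track(self):
        regions = _regions(40, spacing=100_000)
        df = make_records([("chr1A", int(r.start) + 10, "+", 2, 8, "CpG")
                           for r in regions.itertuples()])
        track = landscape.chromosome_scan(df, regions, {"chr1A": 4_000_000})
        filled = track["weighted_level"].dropna()
        assert np.allclose(filled, 0.2)

    def test_empty_window_is_gap(self):
        regions = _regions(1)
        df = make_records([("chr1A", 10, "+", 2, 8, "CpG")])
        track = landscape.chromosome_scan(df, regions, {"chr1A": 6_000_000})
        assert np.isnan(track["weighted_level"].iloc[-1])

    def test_centromere_gradient_peaks_at_centromere(self, small_cohort):
        regions = small_cohort.annotation.regions
        lengths = small_cohort.annotation.chrom_lengths
        df = small_cohort.methylomes[("Recital", 1)]
        track = landscape.chromosome_scan(df, regions, lengths)
        sub = track[track["chrom"] == "chr1A"].dropna(subset=["weighted_level"])
        peak = sub.loc[sub["weighted_level"].idxmax()]
        centromere = 20_000_000
        assert abs((peak["start"] + peak["end"]) / 2 - centromere) <= 4_000_000


class TestTrackSimilarity:
    @staticmethod
    def _track(levels):
        return pd.DataFrame({"chrom": "chr1A",
                             "start": np.arange(len(levels)) * 1_000_000,
                             "end": np.arange(len(levels)) * 1_000_000 + 2_000_000,
                             "weighted_level": levels})

    def test_identical_tracks(self):
        t = self._track(np.linspace(0.1, 0.5, 25))
        r, p = landscape.track_similarity({"a": t, "b": t})
        assert r.loc["a", "b"] == pytest.approx(1.0)
        assert p.loc["a", "b"] == pytest.approx(1.0)

    def test_constant_offset_detected_by_signed_rank(self):
        base = np.linspace(0.1, 0.5, 25)
        r, p = landscape.track_similarity({"a": self._track(base),
                                           "b": self._track(base + 0.05)})
        assert r.loc["a", "b"] == pytest.approx(1.0)
        assert p.loc["a", "b"] < 0.05

    def test_independent_tracks_uncorrelated(self):
        rng = np.random.default_rng(0)
        rs = []
        for _ in range(20):
            r, _ = landscape.track_similarity(
                {"a": self._track(rng.uniform(size=40)),
                 "b": self._track(rng.uniform(size=40))})
            rs.append(r.loc["a", "b"])
        assert abs(np.mean(rs)) < 0.1

    def test_too_few_windows_undefined(self):
        r, p = landscape.track_similarity({"a": self._track([0.1, 0.2]),
                                           "b": self._track([0.1, 0.3])})
        assert np.isnan(r.loc["a", "b"])


class TestPca:
    @staticmethod
    def _matrix(seed=0, n_sites=300, n_obs=6):
        rng = np.random.default_rng(seed)
        X = rng.uniform(size=(n_sites, n_obs))
        return pd.DataFrame(X, columns=[f"s{i}" for i in range(n_obs)])

    def test_duplicated_columns_identical_coordinates(self):
        m = self._matrix()
        m["dup"] = m["s0"]
        coords, _ = landscape.pca_methylomes(m)
        assert np.allclose(coords.loc["s0"], coords.loc["dup"], atol=1e-8)

    def test_variance_explained_is_a_fraction(self):
        _, var = landscape.pca_methylomes(self._matrix())
        assert var.sum() <= 1.0 + 1e-9
        assert (var >= 0).all()

    def test_invariant_to_site_reordering_up_to_sign(self):
        m = self._matrix(seed=3)
        coords1, _ = landscape.pca_methylomes(m)
        shuffled = m.sample(frac=1.0, random_state=1)
        coords2, _ = landscape.pca_methylomes(shuffled)
        for col in coords1.columns:
            same = np.allclose(coords1[col], coords2[col], atol=1e-6)
            flipped = np.allclose(coords1[col], -coords2[col], atol=1e-6)
            assert same or flipped

    def test_single_observation_rejected(self):
        with pytest.raises(ValueError):
            landscape.pca_methylomes(self._matrix(n_obs=1))


class TestMetaprofile:
    def test_thirty_bins_and_across_gene_sd(self):
        regions = _regions(3)
        rows = []
        for r in regions.itertuples():
            for j in range(0, 300, 10):
                rows.append(("chr1A", int(r.start) + j + 1, "+", 2, 8, "CpG"))
        df = make_records(rows)
        expr = pd.Series("expressed", index=regions["gene_id"],
                         name="expr_class")
        profile, per_gene = landscape.metaprofile({"s1": df}, regions, expr)
        cpg = profile[profile["context"] == "CpG"]
        assert sorted(cpg["bin"]) == list(range(30))
        assert cpg["bin_start"].min() == -150
        # a single sample: across-sample SD undefined -> NaN
        assert cpg["sd_samples"].isna().all()
        sd_genes = per_gene.groupby("bin")["level"].std()
        assert np.allclose(sd_genes.dropna(), 0.0)

    def test_minus_strand_bins_flipped(self):
        regions = _regions(1)
        regions.loc[0, "strand"] = "-"
        # one site at the left edge of the window = 3' end for minus strand
        df = make_records([("chr1A", 1, "+", 5, 5, "CpG")])
        expr = pd.Series("expressed", index=regions["gene_id"])
        profile, _ = landscape.metaprofile({"s1": df}, regions, expr)
        assert profile["bin"].iloc[0] == 29

    def test_double_average_equals_mean_of_per_sample_profiles(self):
        regions = _regions(2)
        expr = pd.Series("expressed", index=regions["gene_id"])
        # sample 2 has 10x the coverage: pooled-count averaging would be
        # dominated by it; the double average must weight samples equally
        s1 = make_records([("chr1A", 5, "+", 1, 9, "CpG"),
                           ("chr1A", 1005, "+", 9, 1, "CpG")])
        s2 = make_records([("chr1A", 5, "+", 80, 20, "CpG"),
                           ("chr1A", 1005, "+", 60, 40, "CpG")])
        profile, per_gene = landscape.metaprofile({"s1": s1, "s2": s2}, regions,
                                                  expr)
        row = profile[(profile["context"] == "CpG") & (profile["bin"] == 0)]
        per_sample = (per_gene[per_gene["bin"] == 0]
                      .groupby("sample")["level"].mean())
        assert row["mean_level"].iloc[0] == pytest.approx(per_sample.mean())
        assert per_sample["s1"] == pytest.approx((0.1 + 0.9) / 2)
        assert per_sample["s2"] == pytest.approx((0.8 + 0.6) / 2)

    def test_multi_utr_genes_dropped_from_tss_set(self):
        regions = _regions(2)
        regions.loc[1, "multi_utr"] = True
        df = make_records([("chr1A", 5, "+", 5, 5, "CpG"),
                           ("chr1A", 1005, "+", 5, 5, "CpG")])
        expr = pd.Series("expressed", index=regions["gene_id"])
        _, per_gene = landscape.metaprofile({"s1": df}, regions, expr)
        assert set(per_gene["gene_id"]) == {"g0"}


class TestCorrelations:
    @staticmethod
    def _inputs(n=80, seed=0, slope=-0.1):
        rng = np.random.default_rng(seed)
        level = rng.uniform(0, 0.6, size=n)
        log_tpm = 2 + slope * 20 * level + rng.normal(0, 1.0, size=n)
        tpm = pd.Series(10 ** log_tpm - 1, index=[f"g{i}" for i in range(n)])
        tpm = tpm.clip(lower=0)
        meth = pd.DataFrame({
            "region_idx": np.arange(n),
            "gene_id": [f"g{i}" for i in range(n)],
            "anchor_type": "TSS",
            "chrom": "chr1A",
            "start": np.arange(n) * 1000,
            "end": np.arange(n) * 1000 + 300,
            "context": "CpG",
            "weighted_level": level,
            "n_covered_cytosines": 10,
            "total_meth": 1, "total_cov": 10,
        })
        centromeres = pd.DataFrame({"chrom": ["chr1A"], "position": [40_000],
                                    "chrom_length": [80_000]})
        return meth, tpm, centromeres

    def test_matches_brute_force_covariance(self):
        meth, tpm, cen = self._inputs()
        res = landscape.methylation_expression_correlations(meth, tpm, cen, "CpG")
        x = meth["weighted_level"].to_numpy()
        y = np.log10(tpm.to_numpy() + 1)
        r_oracle = (np.mean((x - x.mean()) * (y - y.mean()))
                    / (x.std() * y.std()))
        assert res["meth_expression"].r == pytest.approx(r_oracle, abs=1e-9)
        assert res["meth_expression"].r2 == pytest.approx(r_oracle ** 2, abs=1e-9)
        assert res["meth_expression"].r < 0

    def test_permuted_expression_kills_correlation(self):
        meth, tpm, cen = self._inputs(n=200)
        rng = np.random.default_rng(1)
        r2s = []
        for _ in range(10):
            perm = pd.Series(rng.permutation(tpm.to_numpy()), index=tpm.index)
            res = landscape.methylation_expression_correlations(meth, perm,
                                                                cen, "CpG")
            r2s.append(res["meth_expression"].r2)
        assert np.mean(r2s) < 0.02

    def test_constant_level_warns_undefined(self):
        meth, tpm, cen = self._inputs()
        meth["weighted_level"] = 0.3
        with pytest.warns(UserWarning):
            res = landscape.methylation_expression_correlations(meth, tpm,
                                                                cen, "CpG")
        assert np.isnan(res["meth_expression"].r)

    def test_too_few_genes_undefined(self):
        meth, tpm, cen = self._inputs(n=5)
        with pytest.warns(UserWarning):
            res = landscape.methylation_expression_correlations(meth, tpm,
                                                                cen, "CpG")
        assert np.isnan(res["meth_expression"].r)


class TestSubgenomeMeans:
    def test_identical_subgenomes_no_difference(self):
        rng = np.random.default_rng(2)
        rows = []
        for chrom in ("chr1A", "chr1B"):
            for i in range(200):
                m = int(rng.integers(0, 15))
                rows.append((chrom, i + 1, "+", m, 15 - m, "CpG"))
        # same counts duplicated on A and B
        df = make_records(rows)
        df.loc[df["chrom"] == "chr1B", ["count_meth", "count_unmeth"]] = (
            df.loc[df["chrom"] == "chr1A", ["count_meth", "count_unmeth"]].to_numpy())
        means, tests = landscape.subgenome_means({"s1": df}, "CpG")
        ab = tests[tests["pair"] == "A-B"]
        assert ab["p"].iloc[0] > 0.9

    def test_offset_subgenome_detected(self):
        rng = np.random.default_rng(3)
        rows = []
        for chrom, level in (("chr1A", 0.2), ("chr1B", 0.3)):
            cov = rng.integers(10, 40, size=5000)
            meth = rng.binomial(cov, level)
            rows += [(chrom, i + 1, "+", int(m), int(c - m), "CpG")
                     for i, (m, c) in enumerate(zip(meth, cov))]
        means, tests = landscape.subgenome_means({"s1": make_records(rows)},
                                                 "CpG")
        m = means.set_index("subgenome")["mean_level"]
        assert m["B"] > m["A"]
        assert tests.set_index("pair").loc["A-B", "p"] < 0.001
        assert tests.set_index("pair").loc["A-B", "stars"] == "***"

    def test_single_site_test_skipped(self):
        df = make_records([("chr1A", 1, "+", 5, 5, "CpG"),
                           ("chr1B", 1, "+", 5, 5, "CpG")])
        with pytest.warns(UserWarning, match="too few"):
            means, tests = landscape.subgenome_means({"s1": df}, "CpG")
        assert len(tests) == 0


class TestOutlierGenes:
    def test_simultaneity_rule(self):
        genes = ["a", "b", "c"]
        cpg = pd.Series([0.4, 0.4, 0.1], index=genes)
        chg = pd.Series([0.2, 0.10, 0.2], index=genes)
        tpm = pd.Series([300.0, 300.0, 300.0], index=genes)
        sets = landscape.flag_outlier_genes(cpg, chg, tpm)
        assert sets["high_tpm_methylated"] == {"a"}

    def test_double_percentile_set_small_under_independence(self):
        rng = np.random.default_rng(4)
        n = 4000
        genes = [f"g{i}" for i in range(n)]
        cpg = pd.Series(rng.uniform(size=n), index=genes)
        chg = pd.Series(rng.uniform(size=n), index=genes)
        tpm = pd.Series(rng.uniform(0, 100, size=n), index=genes)
        sets = landscape.flag_outlier_genes(cpg, chg, tpm)
        # independent uniforms: P(both above p95) = 0.25 %
        frac = len(sets["double_p95"]) / n
        assert frac == pytest.approx(0.0025, abs=0.003)


def test_classify_expression_status_threshold():
    expr = pd.DataFrame({
        "gene_id": ["g1"] * 3 + ["g2"] * 3,
        "sample_id": "s",
        "library": [1, 2, 3] * 2,
        "tpm": [0.5, 0.2, 0.0, 0.5, 0.05, 0.05],
    })
    status = landscape.classify_expression_status(expr)
    assert status["g1"] == "expressed"
    assert status["g2"] == "silent"
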