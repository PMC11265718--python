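"""Per-site distributions, CWG strand symmetry, and metaplots."""

import numpy as np
import pandas as pd
import pytest

import methylsensor as ms
from methylsensor.profiles import symmetry_summary


class TestPerSiteLevels:
    def _df(self, rows):
        df = pd.DataFrame(rows, columns=["mc", "cov"])
        df["context_class"] = "CHG"
        df["called"] = df["mc"] >= 2
        return df

    def test_inclusion_rules(self):
        levels = ms.per_site_levels(self._df([(2, 3), (1, 2), (0, 10)]))
        # (2,3) kept; (1,2) below coverage 3; (0,10) has no methylated read
        assert levels == pytest.approx([2 / 3])

    def test_called_only_mode_is_stricter(self):
        df = self._df([(1, 10), (5, 10)])
        assert len(ms.per_site_levels(df)) == 2
        assert ms.per_site_levels(df, inclusion="called") == pytest.approx([0.5])

    def test_bimodal_methylome_recovers_both_modes(self):
        rng = np.random.default_rng(4)
        n = 20_000
        true = np.where(rng.random(n) < 0.5, 0.9, 0.05)
        cov = np.maximum(rng.poisson(10, n), 3)
        mc = rng.binomial(cov, true)
        df = pd.DataFrame({"mc": mc, "cov": cov, "context_class": "CHG", "called": True})
        levels = ms.per_site_levels(df)
        hi = levels[levels > 0.5]
        lo = levels[levels <= 0.5]
        assert np.median(hi) == pytest.approx(0.9, abs=0.05)
        # low mode: sites at 0.05 that show >= 1 read cluster near 1/cov ~ 0.1
        assert np.median(lo) == pytest.approx(0.1, abs=0.05)


class TestPairCwgSites:
    def _allc(self, rows):
        df = pd.DataFrame(rows, columns=["chrom", "pos", "strand", "trinucleotide", "mc", "cov"])
        ctx = df["trinucleotide"].map(ms.classify_context)
        df["context_class"] = [c[0] for c in ctx]
        df["called"] = None
        return df

    def test_palindromic_pair_found(self):
        #        123456789
        seq = {"chr1": "TTCAGTTTT"}  # CAG at 3-5; minus-strand C at pos 5 reads CTG
        allc = self._allc([("chr1", 3, "+", "CAG", 4, 5), ("chr1", 5, "-", "CTG", 3, 6)])
        pairs = ms.pair_cwg_sites(allc, seq)
        assert len(pairs) == 1
        assert pairs.iloc[0]["pos"] == 3

    def test_ccg_sites_never_paired(self):
        seq = {"chr1": "TTCCGTTTT"}
        allc = self._allc([("chr1", 3, "+", "CCG", 4, 5), ("chr1", 5, "-", "CGG", 3, 6)])
        assert len(ms.pair_cwg_sites(allc, seq)) == 0

    def test_low_coverage_strand_drops_pair(self):
        seq = {"chr1": "TTCAGTTTT"}
        allc = self._allc([("chr1", 3, "+", "CAG", 4, 5), ("chr1", 5, "-", "CTG", 2, 2)])
        assert len(ms.pair_cwg_sites(allc, seq)) == 0

    def test_unmethylated_pair_excluded(self):
        seq = {"chr1": "TTCAGTTTT"}
        allc = self._allc([("chr1", 3, "+", "CAG", 0, 5), ("chr1", 5, "-", "CTG", 0, 6)])
        assert len(ms.pair_cwg_sites(allc, seq)) == 0

    def test_reference_mismatch_raises(self):
        seq = {"chr1": "TTCAGTTTT"}
        allc = self._allc([("chr1", 3, "+", "CCG", 4, 5), ("chr1", 5, "-", "CTG", 3, 6)])
        with pytest.raises(ValueError, match="disagrees"):
            ms.pair_cwg_sites(allc, seq)


class TestSymmetrySummary:
    def test_classes_partition_and_fractions_sum_to_one(self):
        cfg = ms.SimulationConfig(seed=2, cwg_regime="independent", cwg_level=0.4,
                                  n_cwg_pairs=2000)
        pairs, _ = ms.simulate_cwg(cfg)
        table, summary = symmetry_summary(pairs, p0=cfg.p0)
        assert summary["n"].sum() == len(table)
        assert summary["fraction"].sum() == pytest.approx(1.0)

    def test_one_called_strand_classes(self):
        pairs = pd.DataFrame({
            "plus_mc": [5, 0], "plus_cov": [6, 8],
            "minus_mc": [0, 5], "minus_cov": [8, 6],
        })
        table, _ = symmetry_summary(pairs, p0=0.005)
        assert list(table["symmetry_class"]) == ["plus_only", "minus_only"]

    def test_coupled_regime_is_predominantly_symmetric(self):
        fracs = []
        for seed in range(10):
            cfg = ms.SimulationConfig(seed=seed, cwg_regime="coupled", cwg_level=0.8)
            pairs, _ = ms.simulate_cwg(cfg)
            _, summary = symmetry_summary(pairs, p0=cfg.p0)
            fracs.append(summary.set_index("symmetry_class").loc["symmetric", "fraction"])
        assert min(fracs) >= 0.9

    def test_independent_regime_is_predominantly_asymmetric(self):
        fracs = []
        for seed in range(10):
            cfg = ms.SimulationConfig(seed=seed, cwg_regime="independent", cwg_level=0.3)
            pairs, _ = ms.simulate_cwg(cfg)
            _, summary = symmetry_summary(pairs, p0=cfg.p0)
            fracs.append(summary.set_index("symmetry_class").loc["symmetric", "fraction"])
        assert max(fracs) < 0.5

    def test_empty_pair_set(self):
        pairs = pd.DataFrame(columns=["plus_mc", "plus_cov", "minus_mc", "minus_cov"])
        table, summary = symmetry_summary(pairs, p0=0.005)
        assert len(table) == 0 and summary["n"].sum() == 0


class TestMetaplot:
    def _uniform(self, seed=0, level=0.3, n_features=300, flen=2000, depth=10):
        rng = np.random.default_rng(seed)
        feats, rows = [], []
        for i in range(n_features):
            start = i * (flen + 2200) + 1100
            strand = "+" if i % 2 == 0 else "-"
            feats.append(("chr1", start, start + flen, strand))
            pos = np.arange(start - 1000, start + flen + 1000, 25)
            cov = rng.poisson(depth, len(pos))
            mc = rng.binomial(cov, level)
            for p, m, c in zip(pos, mc, cov):
                rows.append(("chr1", p + 1, m, c))
        df = pd.DataFrame(rows, columns=["chrom", "pos", "mc", "cov"])
        df["context_class"] = "CG"
        return df, feats

    def test_uniform_methylome_is_flat(self):
        df, feats = self._uniform()
        mat = ms.metaplot(df, feats, context="CG")
        assert np.all(np.abs(mat["pooled_level"] - 0.3) < 0.02)
        assert np.all(np.abs(mat["mean_level"] - 0.3) < 0.02)

    def test_window_pooled_ratio(self):
        feats = [("chr1", 0, 2000, "+")]
        df = pd.DataFrame({
            "chrom": "chr1", "pos": [10, 20], "mc": [2, 3], "cov": [4, 6],
            "context_class": "CG",
        })
        mat = ms.metaplot(df, feats, context="CG")
        body0 = mat[(mat["region"] == "body") & (mat["window"] == 20)]
        assert body0["pooled_level"].iloc[0] == pytest.approx(0.5)

    def test_minus_strand_feature_is_reversed(self):
        feats = [("chr1", 0, 2000, "-")]
        df = pd.DataFrame({
            "chrom": "chr1", "pos": [1999], "mc": [5], "cov": [5],  # genomic right end
            "context_class": "CG",
        })
        mat = ms.metaplot(df, feats, context="CG")
        hit = mat[mat["cov"] > 0]
        assert list(hit["window"]) == [20]  # first body window (5' end of the feature)

    def test_pooling_identity_body_windows_vs_whole_body(self):
        df, feats = self._uniform(seed=5, n_features=50)
        mat = ms.metaplot(df, feats, context="CG")
        body = mat[mat["region"] == "body"]
        pooled = body["mc"].sum() / body["cov"].sum()
        # whole-body weighted level computed directly from the sites
        total_mc = total_cov = 0
        for chrom, s, e, _ in feats:
            sub = df[(df["pos"] >= s + 1) & (df["pos"] <= e)]
            total_mc += sub["mc"].sum()
            total_cov += sub["cov"].sum()
        assert pooled == pytest.approx(total_mc / total_cov, abs=1e-12)

    def test_short_features_skipped(self):
        feats = [("chr1", 0, 10, "+"), ("chr1", 100, 2100, "+")]
        df = pd.DataFrame({"chrom": "chr1", "pos": [150], "mc": [1], "cov": [2],
                           "context_class": "CG"})
        mat = ms.metaplot(df, feats, context="CG", n_windows=20)
        assert mat["cov"].sum() == 2  # only the long feature contributes
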