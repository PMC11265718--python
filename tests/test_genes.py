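"""gbM classification: CDS summaries, background, gene tests, gbM ratio."""

import numpy as np
import pandas as pd
import pytest

import methylsensor as ms


def _summary_frame(rows):
    """rows: gene_id -> dict of (n_meth, n_sites) per context + cg counts."""
    recs = {}
    for gid, d in rows.items():
        rec = {}
        for c in ("CG", "CHG", "CHH"):
            n_meth, n_sites = d.get(c, (0, 0))
            rec[f"n_meth_{c}"] = n_meth
            rec[f"n_sites_{c}"] = n_sites
            rec[f"mc_sum_{c}"] = n_meth * 5
            rec[f"cov_sum_{c}"] = max(n_sites, 1) * 10
            rec[f"weighted_m{c}"] = rec[f"mc_sum_{c}"] / rec[f"cov_sum_{c}"]
        rec["n_cg_total"] = d.get("n_cg_total", d.get("CG", (0, 0))[1])
        rec["n_cg_cov1"] = d.get("n_cg_cov1", rec["n_cg_total"])
        rec["n_cg_cov3"] = d.get("n_cg_cov3", rec["n_cg_total"])
        recs[gid] = rec
    df = pd.DataFrame.from_dict(recs, orient="index")
    df.index.name = "gene_id"
    return df


class TestSummarizeGeneCds:
    def _called(self, rows):
        df = pd.DataFrame(rows, columns=["chrom", "pos", "strand", "trinucleotide", "mc", "cov"])
        df["context_class"] = df["trinucleotide"].map(lambda t: ms.classify_context(t)[0])
        df["eligible"] = df["cov"] >= 3
        df["called"] = df["eligible"] & (df["mc"] > 0)
        return df

    def test_weighted_level_is_pooled_ratio(self):
        gene = ms.GeneModel("g1", "chr1", "+", exons=[(0, 100)], cds=[(0, 100)])
        called = self._called([("chr1", 10, "+", "CGA", 2, 4), ("chr1", 20, "+", "CGA", 3, 6)])
        s = ms.summarize_gene_cds(called, gene)
        assert s["weighted_mCG"] == pytest.approx(0.5)
        assert s["n_sites_CG"] == 2 and s["n_meth_CG"] == 2

    def test_sites_outside_cds_not_counted(self):
        gene = ms.GeneModel("g1", "chr1", "+", exons=[(0, 100), (200, 300)],
                            cds=[(0, 100), (200, 300)])
        called = self._called([("chr1", 150, "+", "CGA", 5, 5)])  # in the intron
        s = ms.summarize_gene_cds(called, gene)
        assert s["n_sites_CG"] == 0

    def test_minus_strand_site_inside_cds_counted(self):
        gene = ms.GeneModel("g1", "chr1", "+", exons=[(0, 100)], cds=[(0, 100)])
        called = self._called([("chr1", 50, "-", "CGA", 4, 4), ("chr1", 60, "+", "CGA", 0, 4)])
        s = ms.summarize_gene_cds(called, gene)
        assert s["n_sites_CG"] == 2 and s["n_meth_CG"] == 1

    def test_gene_without_cds_gives_empty_summary(self):
        gene = ms.GeneModel("g1", "chr1", "+", exons=[(0, 100)], cds=[])
        called = self._called([("chr1", 50, "+", "CGA", 4, 4)])
        s = ms.summarize_gene_cds(called, gene)
        assert s["n_sites_CG"] == 0 and s["n_cg_total"] == 0


class TestEstimateBackground:
    def test_pooled_over_genes(self):
        df = _summary_frame({"a": {"CG": (10, 50), "CHG": (1, 50), "CHH": (1, 50)},
                             "b": {"CG": (30, 50), "CHG": (1, 50), "CHH": (1, 50)}})
        bg = ms.estimate_background(df)
        assert bg["CG"] == pytest.approx(0.4)

    def test_order_invariant(self):
        df = _summary_frame({"a": {"CG": (10, 50), "CHG": (1, 9), "CHH": (1, 9)},
                             "b": {"CG": (30, 70), "CHG": (2, 11), "CHH": (0, 11)}})
        bg1 = ms.estimate_background(df)
        bg2 = ms.estimate_background(df.iloc[::-1])
        assert bg1.p_bg == bg2.p_bg

    def test_zero_eligible_sites_errors(self):
        df = _summary_frame({"a": {"CG": (1, 10)}})
        with pytest.raises(ValueError):
            ms.estimate_background(df)


class TestClassifyGbm:
    def test_clear_gbm_gene(self):
        rows = {"hot": {"CG": (20, 25), "CHG": (0, 25), "CHH": (0, 25)}}
        for i in range(40):  # background genes
            rows[f"bg{i:02d}"] = {"CG": (3, 25), "CHG": (0, 25), "CHH": (0, 25)}
        cls = ms.classify_genes(_summary_frame(rows))
        assert cls.loc["hot", "label"] == "gbM"
        assert cls.loc["hot", "q_CHG"] > 0.95 and cls.loc["hot", "q_CHH"] > 0.95

    def test_under_20_cg_sites_is_never_gbm(self):
        rows = {"small": {"CG": (10, 10), "CHG": (0, 10), "CHH": (0, 10)}}
        for i in range(40):
            rows[f"bg{i:02d}"] = {"CG": (3, 25), "CHG": (0, 25), "CHH": (0, 25)}
        cls = ms.classify_genes(_summary_frame(rows))
        assert cls.loc["small", "label"] == "non-gbM"
        assert cls.loc["small", "q_CG"] < 0.05  # significant, yet excluded by the site floor

    def test_coverage_fraction_below_40pct_is_unclassified(self):
        rows = {"thin": {"CG": (30, 39), "CHG": (0, 30), "CHH": (0, 30),
                         "n_cg_total": 100, "n_cg_cov1": 90, "n_cg_cov3": 39}}
        for i in range(40):
            rows[f"bg{i:02d}"] = {"CG": (3, 25), "CHG": (0, 25), "CHH": (0, 25)}
        cls = ms.classify_genes(_summary_frame(rows))
        assert cls.loc["thin", "label"] == "unclassified"
        assert np.isnan(cls.loc["thin", "q_CG"])

    def test_chg_methylated_gene_is_not_gbm(self):
        rows = {"tem": {"CG": (20, 25), "CHG": (15, 25), "CHH": (0, 25)}}
        for i in range(40):
            rows[f"bg{i:02d}"] = {"CG": (3, 25), "CHG": (0, 25), "CHH": (0, 25)}
        cls = ms.classify_genes(_summary_frame(rows))
        assert cls.loc["tem", "label"] == "non-gbM"
        assert bool(cls.loc["tem", "tem_like"])


class TestGbmRatio:
    def test_excludes_unclassified_from_denominator(self):
        labels = ["gbM"] * 300 + ["non-gbM"] * 700 + ["unclassified"] * 500
        assert ms.gbm_ratio(pd.DataFrame({"label": labels})) == pytest.approx(0.30)

    def test_all_unclassified_is_missing_not_zero(self):
        assert np.isnan(ms.gbm_ratio(pd.DataFrame({"label": ["unclassified"] * 5})))

    def test_order_invariant(self):
        labels = ["gbM", "non-gbM", "unclassified", "gbM"]
        assert ms.gbm_ratio(pd.Series(labels)) == ms.gbm_ratio(pd.Series(labels[::-1]))


class TestPlantedRecovery:
    """Planted-gbM simulation: sensitivity, specificity, and ratio recovery."""

    def test_sensitivity_and_fpr_on_planted_genes(self):
        cfg = ms.SimulationConfig(seed=10, n_genes=1000)
        sites, truth = ms.simulate_gene_sites(cfg)
        called = ms.call_sites(sites, p0=cfg.p0)
        cls = ms.classify_genes(ms.summarize_genes(called))
        merged = cls.join(truth.set_index("gene_id"))
        sens = np.mean(merged.loc[merged["is_gbm"], "label"] == "gbM")
        fpr = np.mean(merged.loc[~merged["is_gbm"], "label"] == "gbM")
        assert sens >= 0.95
        assert fpr <= 0.01

    @pytest.mark.parametrize("f", [0.1, 0.5])
    def test_gbm_ratio_recovers_planted_fraction(self, f):
        cfg = ms.SimulationConfig(seed=20, n_genes=1000, gbm_fraction=f)
        sites, _ = ms.simulate_gene_sites(cfg)
        called = ms.call_sites(sites, p0=cfg.p0)
        cls = ms.classify_genes(ms.summarize_genes(called))
        assert ms.gbm_ratio(cls) == pytest.approx(f, abs=0.03)

    def test_gene_binomial_tail_matches_bruteforce(self, oracles):
        rng = np.random.default_rng(3)
        for _ in range(50):
            n = int(rng.integers(1, 501))
            k = int(rng.integers(0, n + 1))
            bg = float(rng.uniform(0.001, 0.5))
            assert ms.binom_sf(k, n, bg) == pytest.approx(oracles["binom_tail"](k, n, bg), abs=1e-10)
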