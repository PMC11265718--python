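"""Intronic mCHG-enrichment detection (the heterochromatin-sensor screen)."""

import numpy as np
import pandas as pd
import pytest

import methylsensor as ms
from methylsensor.introns import assign_intron_sites, intron_enrichment_tests


def _two_exon_gene(gid, start, intron_len, chrom="chr1", strand="+"):
    e1 = (start, start + 200)
    e2 = (e1[1] + intron_len, e1[1] + intron_len + 200)
    return ms.GeneModel(gid, chrom, strand, [e1, e2], cds=[e1, e2])


def _sites_in(interval, chrom, n, mc, cov, tri="CAG", rng=None, spacing=4):
    s, e = interval
    pos = np.arange(s, s + n * spacing, spacing)[:n] + 1
    return pd.DataFrame({
        "chrom": chrom, "pos": pos, "strand": "+", "trinucleotide": tri,
        "mc": mc, "cov": cov,
    })


def _prep(df):
    df = df.copy()
    ctx = df["trinucleotide"].map(ms.classify_context)
    df["context_class"] = [c[0] for c in ctx]
    df["subcontext"] = [c[1] for c in ctx]
    df["eligible"] = df["cov"] >= 3
    df["called"] = df["eligible"] & (df["mc"] >= 2)
    return df


@pytest.fixture
def toy_genome():
    """3 genes; geneA's intron is mCHG-dense, the others' are clean."""
    genes = {
        "geneA": _two_exon_gene("geneA", 0, 1200),
        "geneB": _two_exon_gene("geneB", 3000, 1200),
        "geneC": _two_exon_gene("geneC", 6000, 1200),
    }
    ann = ms.GenomeAnnotation(genes=genes)
    frames = []
    for gid, g in genes.items():
        intron = g.introns[0]
        dense = gid == "geneA"
        mc = 8 if dense else 0
        frames.append(_sites_in(intron, "chr1", 100, mc, 10))
        frames.append(_sites_in(g.cds[0], "chr1", 20, 9, 10, tri="CGA"))
    return ann, _prep(pd.concat(frames, ignore_index=True))


class TestIntronBackground:
    def test_pooled_ratio_over_introns(self, toy_genome):
        ann, called = toy_genome
        bg = ms.intron_background(called, ann)
        # 100 methylated of 300 intronic CHG sites
        assert bg["CHG"] == pytest.approx(100 / 300)
        assert bg.scope == "intron"

    def test_cds_sites_never_contribute(self, toy_genome):
        ann, called = toy_genome
        # CDS sites are heavily mCG; intronic CG background must not see them
        sites = assign_intron_sites(called, ann)
        assert (sites["context_class"] == "CG").sum() == 0

    def test_matches_cds_background_machinery_on_intron_scope(self, toy_genome):
        ann, called = toy_genome
        sites = assign_intron_sites(called, ann).rename(columns={"intron_key": "gene_id"})
        summaries = ms.summarize_genes(sites)
        assert ms.intron_background(called, ann)["CHG"] == pytest.approx(
            summaries["n_meth_CHG"].sum() / summaries["n_sites_CHG"].sum())


class TestTestIntron:
    def test_dense_intron_is_enriched(self, toy_genome):
        ann, called = toy_genome
        res = ms.screen_sensor_candidates(ann, called, min_len=1000)
        enriched = res[res["enriched"]]
        assert list(enriched["gene_id"]) == ["geneA"]
        assert res.iloc[0]["gene_id"] == "geneA"  # ranked first

    def test_zero_methylated_intron_has_p_one(self, toy_genome):
        ann, called = toy_genome
        res = ms.screen_sensor_candidates(ann, called, min_len=1000).set_index("gene_id")
        assert res.loc["geneB", "p_CHG"] == pytest.approx(1.0)
        assert not res.loc["geneB", "enriched"]

    def test_identical_introns_get_identical_qvalues(self, toy_genome):
        ann, called = toy_genome
        res = ms.screen_sensor_candidates(ann, called, min_len=1000).set_index("gene_id")
        assert res.loc["geneB", "q_CHG"] == res.loc["geneC", "q_CHG"]

    def test_invariant_to_record_order(self, toy_genome):
        ann, called = toy_genome
        res1 = ms.screen_sensor_candidates(ann, called, min_len=1000)
        res2 = ms.screen_sensor_candidates(ann, called.sample(frac=1, random_state=0), min_len=1000)
        pd.testing.assert_frame_equal(res1, res2)

    def test_untestable_intron_flagged(self):
        g = _two_exon_gene("g1", 0, 1200)
        ann = ms.GenomeAnnotation(genes={"g1": g})
        called = _prep(_sites_in(g.introns[0], "chr1", 5, 0, 1))  # all below min_cov
        with pytest.raises(ValueError):
            ms.intron_background(called, ann)  # no eligible sites at all
        bg = ms.BackgroundModel(p_bg={"CG": 0.01, "CHG": 0.01, "CHH": 0.01}, scope="intron")
        res = intron_enrichment_tests(called, ann, background=bg)
        assert not res["testable"].iloc[0] and not res["enriched"].iloc[0]

    def test_short_planted_intron_absent_at_default_min_len(self):
        genes = {"short": _two_exon_gene("short", 0, 999),
                 "long": _two_exon_gene("long", 3000, 1000)}
        ann = ms.GenomeAnnotation(genes=genes)
        called = _prep(pd.concat([
            _sites_in(genes["short"].introns[0], "chr1", 50, 8, 10),
            _sites_in(genes["long"].introns[0], "chr1", 50, 0, 10),
        ], ignore_index=True))
        res = ms.screen_sensor_candidates(ann, called)
        assert list(res["gene_id"]) == ["long"]

    def test_no_long_introns_gives_empty_report(self):
        ann = ms.GenomeAnnotation(genes={"g": _two_exon_gene("g", 0, 100)})
        res = ms.screen_sensor_candidates(ann, _prep(_sites_in((0, 100), "chr1", 5, 0, 10)))
        assert len(res) == 0


class TestScreenRecovery:
    def test_planted_dense_intron_among_clean_ones(self):
        """One mCHG-dense long intron among 200 clean ones is the sole hit."""
        hits_per_seed = []
        for seed in range(5):
            rng = np.random.default_rng(seed)
            genes, frames = {}, []
            for i in range(201):
                g = _two_exon_gene(f"g{i:03d}", i * 3000, 1200)
                genes[g.gene_id] = g
                level = 0.4 if i == 17 else 0.01
                n = 60
                cov = rng.poisson(10, n)
                mc = rng.binomial(cov, level + (1 - level) * 0.005)
                s, _ = g.introns[0]
                frames.append(pd.DataFrame({
                    "chrom": "chr1", "pos": np.arange(s, s + n * 4, 4)[:n] + 1,
                    "strand": "+", "trinucleotide": "CAG", "mc": mc, "cov": cov,
                }))
            ann = ms.GenomeAnnotation(genes=genes)
            allc = pd.concat(frames, ignore_index=True)
            ctx = allc["trinucleotide"].map(ms.classify_context)
            allc["context_class"] = [c[0] for c in ctx]
            allc["subcontext"] = [c[1] for c in ctx]
            called = ms.call_sites(allc, p0=0.005)
            res = ms.screen_sensor_candidates(ann, called)
            hits_per_seed.append(set(res.loc[res["enriched"], "gene_id"]))
        assert sum(h == {"g017"} for h in hits_per_seed) >= 4

    def test_null_introns_rarely_flagged(self):
        """All-background introns: flagged fraction respects FDR control."""
        fracs = []
        for seed in range(20):
            rng = np.random.default_rng(100 + seed)
            genes, frames = {}, []
            for i in range(50):
                g = _two_exon_gene(f"g{i:03d}", i * 3000, 1200)
                genes[g.gene_id] = g
                n = 50
                cov = rng.poisson(10, n)
                mc = rng.binomial(cov, 0.01)
                s, _ = g.introns[0]
                frames.append(pd.DataFrame({
                    "chrom": "chr1", "pos": np.arange(s, s + n * 4, 4)[:n] + 1,
                    "strand": "+", "trinucleotide": "CAG", "mc": mc, "cov": cov,
                }))
            ann = ms.GenomeAnnotation(genes=genes)
            allc = pd.concat(frames, ignore_index=True)
            allc["context_class"] = "CHG"
            allc["subcontext"] = "CWG"
            called = ms.call_sites(allc, p0=0.005)
            res = ms.screen_sensor_candidates(ann, called)
            fracs.append(res["enriched"].mean())
        assert np.mean(fracs) <= 0.05
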