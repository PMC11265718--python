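"""Gene-body methylation (gbM) classification.

gbM genes carry CG-only methylation in their coding sequence.  For each
gene we count called-methylated and eligible cytosines per context over the
CDS of the primary transcript, estimate a species background probability
per context (pooled fraction of methylated sites across all CDS), and test
each gene's counts with an upper-tail binomial against that background.
After Benjamini-Hochberg adjustment across genes (per context), a gene is
gbM when its mCG q-value is below 0.05 while both non-CG q-values exceed
0.95, it has reads on at least 20 CG sites, and at least 40% of its CG
sites reach three reads of coverage.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .calling import bh_fdr, binom_sf
from .io import GeneModel, GenomeAnnotation
from .regions import assign_sites

CONTEXTS = ("CG", "CHG", "CHH")

DEFAULT_Q_LO = 0.05
DEFAULT_Q_HI = 0.95
DEFAULT_MIN_CG = 20
DEFAULT_MIN_COV_FRAC = 0.40


@dataclass
class BackgroundModel:
    """Per-context pooled background methylation probability.

    ``p_bg[c]`` = (sum of called-methylated sites) / (sum of eligible
    sites) over the stated scope (CDS or introns) for context ``c``.
    """

    p_bg: dict[str, float]
    scope: str = "CDS"

    def __getitem__(self, context: str) -> float:
        return self.p_bg[context]


def assign_cds_sites(called: pd.DataFrame, annotation: GenomeAnnotation) -> pd.DataFrame:
    """Restrict called sites to CDS intervals, labelling each with its gene.

    Both strands count: a minus-strand cytosine inside a CDS interval
    belongs to that gene.
    """
    intervals = [
        (g.chrom, s, e, g.gene_id)
        for g in annotation.genes.values()
        for (s, e) in g.cds
    ]
    gene_ids = assign_sites(called, intervals)
    out = called.copy()
    out["gene_id"] = gene_ids
    return out[out["gene_id"].notna()]


def summarize_genes(gene_sites: pd.DataFrame, min_cov: int = 3) -> pd.DataFrame:
    """Per-gene, per-context counts and weighted levels from a gene-site table.

    ``gene_sites`` needs columns gene_id, context_class, mc, cov and (after
    site calling) eligible, called.  Returns one row per gene with, for
    each context: n_sites (eligible sites), n_meth (called methylated),
    pooled mc/cov sums and the weighted level mc/cov; plus the CG coverage
    eligibility counts n_cg_total (all CG sites), n_cg_cov1 (>= 1 read) and
    n_cg_cov3 (>= min_cov reads).
    """
    df = gene_sites
    called = df["called"].fillna(False).to_numpy(dtype=bool)
    eligible = df["eligible"].to_numpy(dtype=bool) if "eligible" in df else df["cov"].to_numpy() >= min_cov
    work = pd.DataFrame(
        {
            "gene_id": df["gene_id"].to_numpy(),
            "context": df["context_class"].to_numpy(),
            "mc": df["mc"].to_numpy(),
            "cov": df["cov"].to_numpy(),
            "eligible": eligible.astype(np.int64),
            "meth": (called & eligible).astype(np.int64),
        }
    )
    g = work.groupby(["gene_id", "context"], sort=True)
    agg = g.agg(
        n_sites=("eligible", "sum"),
        n_meth=("meth", "sum"),
        mc_sum=("mc", "sum"),
        cov_sum=("cov", "sum"),
    )
    wide = agg.unstack("context")
    genes = wide.index
    out = pd.DataFrame(index=genes)
    for c in CONTEXTS:
        for col in ("n_sites", "n_meth", "mc_sum", "cov_sum"):
            key = (col, c)
            vals = wide[key] if key in wide.columns else pd.Series(0, index=genes)
            out[f"{col}_{c}"] = vals.fillna(0).astype(np.int64)
        covs = out[f"cov_sum_{c}"].to_numpy().astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            out[f"weighted_m{c}"] = np.where(covs > 0, out[f"mc_sum_{c}"] / np.where(covs > 0, covs, 1), np.nan)
    cg = work[work["context"] == "CG"]
    cov_by_gene = cg.groupby("gene_id")["cov"]
    out["n_cg_total"] = cov_by_gene.size().reindex(genes).fillna(0).astype(np.int64)
    out["n_cg_cov1"] = cg.assign(x=(cg["cov"] >= 1).astype(int)).groupby("gene_id")["x"].sum().reindex(genes).fillna(0).astype(np.int64)
    out["n_cg_cov3"] = cg.assign(x=(cg["cov"] >= min_cov).astype(int)).groupby("gene_id")["x"].sum().reindex(genes).fillna(0).astype(np.int64)
    out.index.name = "gene_id"
    return out


def summarize_gene_cds(called: pd.DataFrame, gene: GeneModel, min_cov: int = 3) -> pd.Series:
    """Summary row for one gene's CDS (empty CDS gives all-zero counts)."""
    ann = GenomeAnnotation(genes={gene.gene_id: gene})
    sites = assign_cds_sites(called, ann)
    if not len(sites):
        empty = {f"{col}_{c}": 0 for c in CONTEXTS for col in ("n_sites", "n_meth", "mc_sum", "cov_sum")}
        empty.update({f"weighted_m{c}": np.nan for c in CONTEXTS})
        empty.update(n_cg_total=0, n_cg_cov1=0, n_cg_cov3=0)
        return pd.Series(empty, name=gene.gene_id)
    return summarize_genes(sites, min_cov=min_cov).loc[gene.gene_id]


def estimate_background(summaries: pd.DataFrame, scope: str = "CDS") -> BackgroundModel:
    """Pooled per-context background: sum(n_meth) / sum(n_sites) over genes."""
    p_bg = {}
    for c in CONTEXTS:
        n_sites = int(summaries[f"n_sites_{c}"].sum())
        if n_sites == 0:
            raise ValueError(f"no eligible {c} sites to estimate background from")
        p_bg[c] = summaries[f"n_meth_{c}"].sum() / n_sites
    return BackgroundModel(p_bg=p_bg, scope=scope)


def classify_genes(
    summaries: pd.DataFrame,
    background: BackgroundModel | None = None,
    q_lo: float = DEFAULT_Q_LO,
    q_hi: float = DEFAULT_Q_HI,
    min_cg: int = DEFAULT_MIN_CG,
    min_cov_frac: float = DEFAULT_MIN_COV_FRAC,
) -> pd.DataFrame:
    """Attach per-context p/q-values and a gbM label to each gene summary.

    Coverage eligibility: a gene is ``unclassified`` unless at least
    ``min_cov_frac`` of its CG sites have >= 3 reads.  BH adjustment runs
    per context across the coverage-eligible genes.  ``gbM`` additionally
    requires reads mapping to at least ``min_cg`` CG sites (cov >= 1),
    q_CG < q_lo, and q_CHG and q_CHH > q_hi; everything else eligible is
    ``non-gbM``.  A ``tem_like`` flag (q_CHG < q_lo) is annotated but plays
    no part in the label.
    """
    out = summaries.copy()
    if background is None:
        background = estimate_background(out)
    n = len(out)
    total = out["n_cg_total"].to_numpy().astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(total > 0, out["n_cg_cov3"] / np.where(total > 0, total, 1), 0.0)
    eligible = frac >= min_cov_frac
    out["cg_cov_frac"] = frac
    out["coverage_eligible"] = eligible
    for c in CONTEXTS:
        p = np.full(n, np.nan)
        q = np.full(n, np.nan)
        has = eligible & (out[f"n_sites_{c}"].to_numpy() > 0)
        p[has] = binom_sf(out[f"n_meth_{c}"].to_numpy()[has], out[f"n_sites_{c}"].to_numpy()[has], background[c])
        # genes with zero eligible sites in this context cannot reject: p = 1
        p[eligible & ~has] = 1.0
        q[eligible] = bh_fdr(p[eligible])
        out[f"p_{c}"] = p
        out[f"q_{c}"] = q
    is_gbm = (
        eligible
        & (out["n_cg_cov1"].to_numpy() >= min_cg)
        & (out["q_CG"].to_numpy() < q_lo)
        & (out["q_CHG"].to_numpy() > q_hi)
        & (out["q_CHH"].to_numpy() > q_hi)
    )
    label = np.where(~eligible, "unclassified", np.where(is_gbm, "gbM", "non-gbM"))
    out["label"] = label
    out["tem_like"] = eligible & (out["q_CHG"].to_numpy() < q_lo)
    return out


def gbm_ratio(classified: pd.DataFrame | pd.Series) -> float:
    """Fraction of coverage-eligible genes labelled gbM (NaN when none)."""
    labels = classified["label"] if isinstance(classified, pd.DataFrame) else classified
    labels = np.asarray(labels)
    n_eligible = int(np.sum(labels != "unclassified"))
    if n_eligible == 0:
        return float("nan")
    return float(np.sum(labels == "gbM") / n_eligible)
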