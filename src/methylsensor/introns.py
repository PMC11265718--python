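"""Intronic mCHG-enrichment testing — the heterochromatin-sensor detector.

Long introns that carry dense CHG methylation (like the 7th intron of
IBM1) act as heterochromatin sensors: their methylation level couples the
gene's isoform output to the cell's heterochromatin machinery.  An intron
is called mCHG-enriched when an upper-tail binomial test of its
called-methylated CHG sites against the species-wide intronic background,
BH-adjusted across the set of introns screened, gives q < 0.05.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .calling import bh_fdr, binom_sf
from .genes import CONTEXTS, BackgroundModel
from .io import GenomeAnnotation, select_long_introns
from .regions import assign_sites

DEFAULT_Q_ENRICH = 0.05


def assign_intron_sites(called: pd.DataFrame, annotation: GenomeAnnotation) -> pd.DataFrame:
    """Label called sites with (gene_id, intron_index) for sites in introns.

    Intron indices are 1-based in transcript orientation.
    """
    intervals = [
        (g.chrom, s, e, (g.gene_id, idx))
        for g in annotation.genes.values()
        for idx, (s, e) in enumerate(g.introns_transcript_order(), start=1)
    ]
    labels = assign_sites(called, intervals)
    out = called.copy()
    out["intron_key"] = labels
    return out[out["intron_key"].notna()]


def intron_background(called: pd.DataFrame, annotation: GenomeAnnotation, min_cov: int = 3) -> BackgroundModel:
    """Per-context background over all introns: pooled methylated/eligible ratio.

    Contexts with no eligible intronic site get a NaN background (and are
    skipped by the tests); if no context has any eligible site the
    annotation carries no usable intronic data and an error is raised.
    """
    sites = assign_intron_sites(called, annotation)
    eligible = sites["cov"].to_numpy() >= min_cov
    meth = sites["called"].fillna(False).to_numpy(dtype=bool) & eligible
    p_bg = {}
    for c in CONTEXTS:
        in_ctx = sites["context_class"].to_numpy() == c
        n = int(np.sum(eligible & in_ctx))
        p_bg[c] = float(np.sum(meth & in_ctx) / n) if n else float("nan")
    if all(np.isnan(v) for v in p_bg.values()):
        raise ValueError("no eligible intronic sites in any context")
    return BackgroundModel(p_bg=p_bg, scope="intron")


def _intron_counts(sites: pd.DataFrame, min_cov: int) -> pd.DataFrame:
    eligible = sites["cov"].to_numpy() >= min_cov
    called = sites["called"].fillna(False).to_numpy(dtype=bool) & eligible
    work = pd.DataFrame(
        {
            "intron_key": sites["intron_key"].to_numpy(),
            "context": sites["context_class"].to_numpy(),
            "subcontext": sites["subcontext"].to_numpy() if "subcontext" in sites else None,
            "mc": sites["mc"].to_numpy(),
            "cov": sites["cov"].to_numpy(),
            "eligible": eligible.astype(np.int64),
            "meth": called.astype(np.int64),
        }
    )
    agg = work.groupby(["intron_key", "context"], sort=True).agg(
        n_sites=("eligible", "sum"), n_meth=("meth", "sum"),
        mc_sum=("mc", "sum"), cov_sum=("cov", "sum"),
    ).unstack("context")
    keys = agg.index
    out = pd.DataFrame(index=keys)
    for c in CONTEXTS:
        for col in ("n_sites", "n_meth", "mc_sum", "cov_sum"):
            key = (col, c)
            vals = agg[key] if key in agg.columns else pd.Series(0, index=keys)
            out[f"{col}_{c}"] = vals.fillna(0).astype(np.int64)
        covs = out[f"cov_sum_{c}"].to_numpy().astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            out[f"weighted_m{c}"] = np.where(covs > 0, out[f"mc_sum_{c}"] / np.where(covs > 0, covs, 1), np.nan)
    # CWG/CCG subcontext breakdown of CHG methylation
    chg = work[work["context"] == "CHG"]
    for sub in ("CWG", "CCG"):
        s = chg[chg["subcontext"] == sub]
        grp = s.groupby("intron_key")
        mc = grp["mc"].sum().reindex(keys).fillna(0)
        cov = grp["cov"].sum().reindex(keys).fillna(0)
        with np.errstate(invalid="ignore", divide="ignore"):
            out[f"weighted_m{sub}"] = np.where(cov > 0, mc / cov.where(cov > 0, 1), np.nan)
    return out


def intron_enrichment_tests(
    called: pd.DataFrame,
    annotation: GenomeAnnotation,
    introns: list | None = None,
    background: BackgroundModel | None = None,
    q_enrich: float = DEFAULT_Q_ENRICH,
    min_cov: int = 3,
) -> pd.DataFrame:
    """Test a set of introns for per-context methylation enrichment.

    The BH family is exactly the set of introns supplied (or every intron
    in the annotation when ``introns`` is None).  Introns with zero
    eligible CHG sites are flagged ``testable = False`` and excluded from
    the CHG family.  Returns one row per intron with counts, p/q per
    context, the enriched flag (q_CHG < q_enrich) and CWG/CCG levels,
    ranked by (q_CHG, -weighted_mCHG).
    """
    if background is None:
        background = intron_background(called, annotation, min_cov=min_cov)
    sites = assign_intron_sites(called, annotation)
    if introns is not None:
        wanted = {(g, i) for g, i, _, _ in introns}
        sites = sites[sites["intron_key"].isin(wanted)]
        all_keys = sorted(wanted)
    else:
        all_keys = sorted(sites["intron_key"].unique())
    counts = _intron_counts(sites, min_cov) if len(sites) else pd.DataFrame()
    counts = counts.reindex(all_keys)
    for c in CONTEXTS:
        for col in ("n_sites", "n_meth", "mc_sum", "cov_sum"):
            counts[f"{col}_{c}"] = counts.get(f"{col}_{c}", pd.Series(index=counts.index)).fillna(0).astype(np.int64)
    out = counts
    out.index.name = "intron_key"
    for c in CONTEXTS:
        n_sites = out[f"n_sites_{c}"].to_numpy()
        p = np.full(len(out), np.nan)
        q = np.full(len(out), np.nan)
        has = n_sites > 0
        if np.isnan(background[c]):
            has = np.zeros(len(out), dtype=bool)
        p[has] = binom_sf(out[f"n_meth_{c}"].to_numpy()[has], n_sites[has], background[c])
        q[has] = bh_fdr(p[has])
        out[f"p_{c}"] = p
        out[f"q_{c}"] = q
    out["testable"] = out["n_sites_CHG"].to_numpy() > 0
    out["enriched"] = out["testable"] & (out["q_CHG"].to_numpy() < q_enrich)
    out = out.reset_index()
    out["gene_id"] = [k[0] for k in out["intron_key"]]
    out["intron_index"] = [k[1] for k in out["intron_key"]]
    out = out.drop(columns=["intron_key"])
    out = out.sort_values(
        ["q_CHG", "weighted_mCHG"], ascending=[True, False], na_position="last", kind="mergesort"
    ).reset_index(drop=True)
    return out


def screen_sensor_candidates(
    annotation: GenomeAnnotation,
    called: pd.DataFrame,
    min_len: int = 1000,
    background: BackgroundModel | None = None,
    q_enrich: float = DEFAULT_Q_ENRICH,
    min_cov: int = 3,
) -> pd.DataFrame:
    """Genome-wide screen: test every long intron for mCHG enrichment."""
    long_introns = select_long_introns(annotation, min_len=min_len)
    if not long_introns:
        return pd.DataFrame()
    return intron_enrichment_tests(called, annotation, introns=long_introns,
                                   background=background, q_enrich=q_enrich, min_cov=min_cov)
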