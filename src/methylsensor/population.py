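"""Population-scale ectopic non-CG methylation scans.

Across an accession panel, a normally-gbM gene that shows significant CHG
and/or CHH methylation in a particular accession is an "ectopic non-CG"
gene there — the signature of a failing IBM1 pathway.  Accessions with
more than 120 such genes are flagged ibm1-like.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

log = logging.getLogger(__name__)

DEFAULT_Q_ECTOPIC = 0.05
DEFAULT_GBM_FREQ = 0.90
DEFAULT_IBM1_THRESHOLD = 120
DEFAULT_SENSOR_MCHG_MAX = 0.035
DEFAULT_GAIN_DELTA = 0.02


@dataclass
class AccessionPanel:
    """Long-format per-accession gene classification table.

    ``table`` has one row per (accession, gene_id) with at least columns
    label, q_CHG, q_CHH, weighted_mCHG.  gbM frequency per gene is the
    fraction of accessions calling the gene gbM among those where it is
    classified (unclassified accessions drop out of the denominator).
    """

    table: pd.DataFrame

    @classmethod
    def from_classifications(cls, classified_by_accession: dict[str, pd.DataFrame]) -> "AccessionPanel":
        frames = []
        for acc, df in classified_by_accession.items():
            sub = df.reset_index()[["gene_id", "label", "q_CHG", "q_CHH", "weighted_mCHG"]].copy()
            sub.insert(0, "accession", acc)
            frames.append(sub)
        return cls(pd.concat(frames, ignore_index=True))

    def gbm_frequency(self) -> pd.Series:
        classified = self.table[self.table["label"] != "unclassified"]
        freq = classified.groupby("gene_id")["label"].agg(lambda s: np.mean(s == "gbM"))
        freq.name = "gbm_frequency"
        return freq


def call_ectopic_genes(
    panel: AccessionPanel,
    q_alpha: float = DEFAULT_Q_ECTOPIC,
    gbm_freq_min: float = DEFAULT_GBM_FREQ,
) -> pd.DataFrame:
    """Per-accession ectopic gene calls.

    A gene is ectopic in an accession when (q_CHG < q_alpha or
    q_CHH < q_alpha) and its population gbM frequency is strictly greater
    than ``gbm_freq_min``.  Returns the long table of ectopic
    (accession, gene_id) rows.
    """
    freq = panel.gbm_frequency()
    t = panel.table.merge(freq, on="gene_id", how="left")
    sig = (t["q_CHG"] < q_alpha) | (t["q_CHH"] < q_alpha)
    candidate = t["gbm_frequency"] > gbm_freq_min
    hits = t[sig.fillna(False) & candidate.fillna(False) & (t["label"] != "unclassified")]
    return hits[["accession", "gene_id", "q_CHG", "q_CHH", "weighted_mCHG", "gbm_frequency"]].reset_index(drop=True)


def ectopic_counts(panel: AccessionPanel, **kwargs) -> pd.DataFrame:
    """Number of ectopic genes per accession (all accessions, zeros kept)."""
    hits = call_ectopic_genes(panel, **kwargs)
    accessions = panel.table["accession"].unique()
    counts = hits.groupby("accession").size().reindex(accessions).fillna(0).astype(int)
    return pd.DataFrame({"accession": accessions, "n_ectopic": counts.to_numpy()})


def flag_ibm1_like(
    counts: pd.DataFrame,
    threshold: int = DEFAULT_IBM1_THRESHOLD,
    strict: bool = True,
) -> pd.DataFrame:
    """Flag accessions with an unusually high ectopic-gene count.

    Strict (default) uses ``n_ectopic > threshold``; ``strict=False`` uses
    ``>=`` for the "at least 120" reading.
    """
    out = counts.copy()
    n = out["n_ectopic"].to_numpy()
    out["ibm1_like"] = (n > threshold) if strict else (n >= threshold)
    return out


def mchg_gain_genes(
    reference: pd.DataFrame,
    sample: pd.DataFrame,
    delta: float = DEFAULT_GAIN_DELTA,
    candidates: pd.Index | None = None,
) -> pd.DataFrame:
    """Genes whose CDS weighted mCHG rose by strictly more than ``delta``.

    ``reference``/``sample`` are classified gene tables indexed by gene_id
    with a weighted_mCHG column.  ``candidates`` defaults to the reference
    sample's gbM genes.  Genes missing from either table are skipped (a
    count is logged).
    """
    if candidates is None:
        candidates = reference.index[reference["label"] == "gbM"]
    common = candidates.intersection(reference.index).intersection(sample.index)
    n_skip = len(candidates) - len(common)
    if n_skip:
        log.info("mchg_gain_genes: %d candidate genes missing from one sample", n_skip)
    gain = sample.loc[common, "weighted_mCHG"] - reference.loc[common, "weighted_mCHG"]
    hit = gain > delta
    return pd.DataFrame(
        {
            "gene_id": common[hit.fillna(False)],
            "mCHG_reference": reference.loc[common, "weighted_mCHG"][hit.fillna(False)].to_numpy(),
            "mCHG_sample": sample.loc[common, "weighted_mCHG"][hit.fillna(False)].to_numpy(),
            "gain": gain[hit.fillna(False)].to_numpy(),
        }
    ).reset_index(drop=True)


def ectopic_vs_sensor_table(
    counts: pd.DataFrame,
    sensor_mchg: pd.Series,
    expression: pd.Series | None = None,
    isoform_ratio: pd.Series | None = None,
    mchg_max: float = DEFAULT_SENSOR_MCHG_MAX,
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Join per-accession ectopic counts with sensor-intron mCHG and expression.

    Spearman rank correlations between sensor mCHG and expression (and,
    when given, the short/long isoform ratio) are computed on the subset of
    accessions with sensor mCHG <= ``mchg_max`` — the low-methylation range
    where the sensor responds.  Accessions missing from any input are
    excluded (and logged).
    """
    t = counts.set_index("accession").copy()
    t["sensor_mCHG"] = sensor_mchg
    if expression is not None:
        t["expression"] = expression
    if isoform_ratio is not None:
        t["isoform_ratio"] = isoform_ratio
    n_before = len(t)
    t = t.dropna(subset=["sensor_mCHG"])
    if len(t) < n_before:
        log.info("ectopic_vs_sensor_table: %d accessions lacked sensor mCHG", n_before - len(t))
    sub = t[t["sensor_mCHG"] <= mchg_max]
    corr: dict[str, float] = {"n_subset": float(len(sub))}
    for col in ("expression", "isoform_ratio"):
        if col in t.columns:
            s = sub.dropna(subset=[col])
            if len(s) >= 3:
                rho = stats.spearmanr(s["sensor_mCHG"], s[col]).statistic
            else:
                rho = float("nan")
            corr[f"rho_{col}"] = float(rho)
    return t.reset_index(), corr
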