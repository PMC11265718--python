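"""Binomial methylation calling against a bisulfite non-conversion control.

A fully unmethylated control sequence (chloroplast or lambda) gives the
non-conversion rate p0 — the fraction of unmethylated cytosines that escape
bisulfite conversion.  Each cytosine with coverage >= 3 is then tested with
an upper-tail binomial test of its methylated-read count against p0, and
p-values are adjusted with Benjamini-Hochberg FDR (stratified by context
class, since CG, CHG and CHH background rates differ by orders of
magnitude).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

log = logging.getLogger(__name__)

DEFAULT_MIN_COV = 3
DEFAULT_ALPHA = 0.05
DEFAULT_P0_FLOOR = 1e-4


@dataclass
class ConversionControl:
    """Pooled non-conversion estimate from unmethylated control sequences."""

    control_seq_ids: tuple[str, ...]
    mc_total: int
    cov_total: int
    rate: float  # p0, floored

    @property
    def raw_rate(self) -> float:
        return self.mc_total / self.cov_total


@dataclass
class SiteCallResult:
    chrom: str
    pos: int
    strand: str
    p_value: float | None
    q_value: float | None
    eligible: bool
    called: bool | None


def estimate_nonconversion(
    allc: pd.DataFrame,
    control_seq_ids,
    floor: float = DEFAULT_P0_FLOOR,
) -> ConversionControl:
    """Estimate p0 by pooling counts over all control cytosines.

    Counts are pooled (sum mc / sum cov) across sequences and contexts, not
    averaged per sequence, so deeper sequences carry proportionally more
    weight.  A floor (default 1e-4) keeps p0 positive when the finite
    control shows zero non-conversion.
    """
    ids = tuple(control_seq_ids) if not isinstance(control_seq_ids, str) else (control_seq_ids,)
    sub = allc[allc["chrom"].isin(ids)]
    cov_total = int(sub["cov"].sum())
    if cov_total == 0:
        raise ValueError(f"no coverage on control sequences {ids}")
    mc_total = int(sub["mc"].sum())
    raw = mc_total / cov_total
    if raw > 0.5:
        log.warning("control non-conversion rate %.3f > 0.5; control likely mislabelled", raw)
    return ConversionControl(ids, mc_total, cov_total, max(raw, floor))


def binom_sf(mc, cov, p0):
    """Upper-tail binomial probability P(X >= mc | n=cov, p=p0).

    Vectorised over mc/cov.  mc=0 gives exactly 1.
    """
    mc = np.asarray(mc)
    if np.any((np.asarray(p0) < 0) | (np.asarray(p0) > 1)):
        raise ValueError("p0 must be in [0, 1]")
    return stats.binom.sf(mc - 1, cov, p0)


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg q-values, in the input order, clipped at 1."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must be in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def call_site(mc: int, cov: int, p0: float, min_cov: int = DEFAULT_MIN_COV) -> SiteCallResult:
    """Single-site binomial test (p-value only; no FDR across sites).

    Sites below the minimum coverage (default 3 reads) are ineligible and
    receive no call.
    """
    if not 0 <= mc <= cov:
        raise ValueError(f"require 0 <= mc <= cov, got mc={mc}, cov={cov}")
    eligible = cov >= min_cov
    p = float(binom_sf(mc, cov, p0)) if eligible else None
    return SiteCallResult("", 0, "+", p, None, eligible, None)


def call_sites(
    allc: pd.DataFrame,
    p0: float,
    alpha: float = DEFAULT_ALPHA,
    min_cov: int = DEFAULT_MIN_COV,
    stratify_by_context: bool = True,
) -> pd.DataFrame:
    """Call every eligible site; returns a copy with p/q/eligible/called columns.

    ``called = eligible and q < alpha``.  Ineligible sites (cov < min_cov)
    are retained with ``called`` unset so downstream coverage-eligibility
    rules can still see them.  BH-FDR runs within each context class when
    ``stratify_by_context`` (the default), else genome-wide.
    """
    df = allc.copy()
    n = len(df)
    eligible = df["cov"].to_numpy() >= min_cov
    p = np.full(n, np.nan)
    q = np.full(n, np.nan)
    if eligible.any():
        p[eligible] = binom_sf(df["mc"].to_numpy()[eligible], df["cov"].to_numpy()[eligible], p0)
        if stratify_by_context and "context_class" in df.columns:
            ctx = df["context_class"].to_numpy()
            for c in pd.unique(ctx[eligible]):
                m = eligible & (ctx == c)
                q[m] = bh_fdr(p[m])
        else:
            q[eligible] = bh_fdr(p[eligible])
    df["p_value"] = p
    df["q_value"] = q
    df["eligible"] = eligible
    called = pd.array([pd.NA] * n, dtype="boolean")
    called[eligible] = q[eligible] < alpha
    df["called"] = called
    return df


def call_methylome(
    allc: pd.DataFrame,
    control: ConversionControl,
    alpha: float = DEFAULT_ALPHA,
    min_cov: int = DEFAULT_MIN_COV,
    stratify_by_context: bool = True,
) -> pd.DataFrame:
    """Call the whole methylome against an estimated conversion control."""
    return call_sites(allc, control.rate, alpha=alpha, min_cov=min_cov,
                      stratify_by_context=stratify_by_context)
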