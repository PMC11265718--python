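"""Per-site level distributions, CWG strand symmetry, and metaplots.

CWG triplets (W = A or T) are strand-symmetric: the plus-strand cytosine
at position i pairs with the minus-strand cytosine at i+2.  CMT3 maintains
methylation on both strands of such sites, so strand-coupled (symmetric)
mCWG is the fingerprint of active CMT3, while strand-independent mCWG
marks its absence.  CWG is analysed instead of all CHG to exclude MET1's
influence on CCG sites.

Metaplots divide each gene body into 20 equal windows and the 1 kb flanks
into 20 windows each, compute the weighted methylation level (sum mc / sum
cov) per window per gene, and average the window values across genes.
"""

from __future__ import annotations

import logging
import re

import numpy as np
import pandas as pd

from .calling import DEFAULT_ALPHA, DEFAULT_MIN_COV, bh_fdr, binom_sf

log = logging.getLogger(__name__)

_CWG = re.compile(r"(?=C[AT]G)")

SYMMETRY_CLASSES = ("symmetric", "plus_only", "minus_only", "neither")


def per_site_levels(
    called: pd.DataFrame,
    context: str = "CHG",
    min_cov: int = DEFAULT_MIN_COV,
    inclusion: str = "mc_ge1",
) -> np.ndarray:
    """Distribution of per-site methylation ratios mc/cov for one context.

    A site is included when cov >= min_cov and it shows methylation:
    ``inclusion='mc_ge1'`` (default) requires at least one methylated read,
    ``'called'`` requires the site to be called methylated.
    """
    df = called[called["context_class"] == context]
    keep = df["cov"].to_numpy() >= min_cov
    if inclusion == "mc_ge1":
        keep &= df["mc"].to_numpy() >= 1
    elif inclusion == "called":
        keep &= df["called"].fillna(False).to_numpy(dtype=bool)
    else:
        raise ValueError(f"unknown inclusion rule {inclusion!r}")
    sub = df[keep]
    return (sub["mc"] / sub["cov"]).to_numpy()


def pair_cwg_sites(
    called: pd.DataFrame,
    sequences,
    min_cov: int = DEFAULT_MIN_COV,
) -> pd.DataFrame:
    """Pair plus/minus cytosines of palindromic CWG triplets.

    ``sequences`` maps chrom -> sequence string (a dict or a pyfaidx.Fasta
    works).  Only pairs where both strands have cov >= min_cov and at least
    one methylated read on either strand are returned.  A record whose
    trinucleotide contradicts the reference sequence raises ValueError.
    Positions in the output are the 1-based plus-strand C.
    """
    chg = called[called["context_class"] == "CHG"]
    by_key: dict[tuple[str, int, str], tuple] = {}
    for r in chg.itertuples():
        by_key[(r.chrom, r.pos, r.strand)] = (
            r.mc, r.cov, r.trinucleotide,
            None if pd.isna(r.called) else bool(r.called),
        )
    rows = []
    for chrom in {c for c, _, _ in by_key}:
        seq = str(sequences[chrom][:]) if hasattr(sequences[chrom], "__getitem__") and not isinstance(sequences[chrom], str) else str(sequences[chrom])
        seq = seq.upper()
        for m in _CWG.finditer(seq):
            i = m.start()
            if i + 2 >= len(seq) or seq[i + 2] != "G":
                continue
            plus = by_key.get((chrom, i + 1, "+"))
            minus = by_key.get((chrom, i + 3, "-"))
            if plus is None or minus is None:
                continue
            for rec, strand, base in ((plus, "+", i), (minus, "-", i + 2)):
                tri = rec[2]
                if tri[0] != "C":
                    raise ValueError(f"{chrom}:{base + 1}{strand}: record trinucleotide {tri} is not a cytosine")
            if plus[2][1] not in "AT":
                raise ValueError(
                    f"{chrom}:{i + 1}+: record trinucleotide {plus[2]} disagrees with reference CWG"
                )
            if plus[1] < min_cov or minus[1] < min_cov:
                continue
            if plus[0] + minus[0] < 1:
                continue
            rows.append((chrom, i + 1, plus[0], plus[1], plus[3], minus[0], minus[1], minus[3]))
    return pd.DataFrame(
        rows,
        columns=["chrom", "pos", "plus_mc", "plus_cov", "plus_called",
                 "minus_mc", "minus_cov", "minus_called"],
    )


def symmetry_summary(
    pairs: pd.DataFrame,
    p0: float | None = None,
    alpha: float = DEFAULT_ALPHA,
    min_cov: int = DEFAULT_MIN_COV,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Classify each CWG pair and tabulate symmetry-class fractions.

    If the pairs lack per-strand call flags, ``p0`` must be given and each
    strand is called with the binomial test plus BH across all strands of
    the pair set.  Classes: symmetric (both strands called), plus_only /
    minus_only (exactly one), neither.  Returns (per-pair table with
    levels and class, summary with counts and fractions over included
    pairs).
    """
    df = pairs.copy()
    df = df[(df["plus_cov"] >= min_cov) & (df["minus_cov"] >= min_cov)]
    df = df[(df["plus_mc"] + df["minus_mc"]) >= 1]
    if len(df) and ("plus_called" not in df.columns or df["plus_called"].isna().any()):
        if p0 is None:
            raise ValueError("pairs lack call flags; pass p0 to call strands")
        p = np.concatenate([
            binom_sf(df["plus_mc"].to_numpy(), df["plus_cov"].to_numpy(), p0),
            binom_sf(df["minus_mc"].to_numpy(), df["minus_cov"].to_numpy(), p0),
        ])
        q = bh_fdr(p)
        n = len(df)
        df["plus_called"] = q[:n] < alpha
        df["minus_called"] = q[n:] < alpha
    if len(df):
        plus = df["plus_called"].to_numpy(dtype=bool)
        minus = df["minus_called"].to_numpy(dtype=bool)
        cls = np.where(plus & minus, "symmetric",
                       np.where(plus, "plus_only", np.where(minus, "minus_only", "neither")))
        df["symmetry_class"] = cls
        df["plus_level"] = df["plus_mc"] / df["plus_cov"]
        df["minus_level"] = df["minus_mc"] / df["minus_cov"]
    else:
        df["symmetry_class"] = pd.Series(dtype=object)
        df["plus_level"] = df["minus_level"] = pd.Series(dtype=float)
    counts = {c: int(np.sum(df["symmetry_class"] == c)) for c in SYMMETRY_CLASSES}
    total = sum(counts.values())
    summary = pd.DataFrame(
        {
            "symmetry_class": SYMMETRY_CLASSES,
            "n": [counts[c] for c in SYMMETRY_CLASSES],
            "fraction": [counts[c] / total if total else np.nan for c in SYMMETRY_CLASSES],
        }
    )
    return df.reset_index(drop=True), summary


# ---------------------------------------------------------------------------
# metaplots


def metaplot(
    called: pd.DataFrame,
    features,
    context: str = "CG",
    n_windows: int = 20,
    flank: int = 1000,
    mode: str = "per_feature_mean",
) -> pd.DataFrame:
    """Weighted-methylation metaplot over features and their flanks.

    ``features`` is an iterable of (chrom, start, end, strand) with 0-based
    half-open body coordinates (GeneModel objects also work).  Windows are
    an equal-width real-valued partition: 20 upstream-flank windows, 20
    body windows, 20 downstream windows, oriented 5'->3' (minus-strand
    features are reversed, so window 0 is always the distal 5' flank).

    Returns one row per window with pooled mc/cov and two levels: the
    pooled ratio and the per-feature mean of window-weighted levels (the
    default ``mode`` picks which goes in the ``level`` column).  Features
    shorter than ``n_windows`` bases are skipped (count logged).
    """
    feats = []
    for f in features:
        if hasattr(f, "gene_id"):
            feats.append((f.chrom, f.start, f.end, f.strand))
        else:
            feats.append(tuple(f))
    n_short = sum(1 for _, s, e, _ in feats if e - s < n_windows)
    if n_short:
        log.info("metaplot: skipped %d features shorter than %d bp", n_short, n_windows)
    feats = [f for f in feats if f[2] - f[1] >= n_windows]

    df = called[called["context_class"] == context]
    pos0 = df["pos"].to_numpy() - 1
    chroms = df["chrom"].to_numpy()
    mc = df["mc"].to_numpy().astype(np.int64)
    cov = df["cov"].to_numpy().astype(np.int64)

    total_windows = 3 * n_windows
    # pooled counts per window, and per-(feature, window) counts for averaging
    pooled_mc = np.zeros(total_windows, dtype=np.int64)
    pooled_cov = np.zeros(total_windows, dtype=np.int64)
    feat_levels: list[list[float]] = [[] for _ in range(total_windows)]

    order = np.lexsort((pos0, chroms))
    pos_sorted = pos0[order]
    chrom_sorted = chroms[order]
    for chrom, start, end, strand in feats:
        lo = np.searchsorted(chrom_sorted, chrom, side="left")
        hi = np.searchsorted(chrom_sorted, chrom, side="right")
        cpos = pos_sorted[lo:hi]
        a = np.searchsorted(cpos, start - flank, side="left")
        b = np.searchsorted(cpos, end + flank, side="left")
        idx = order[lo + a: lo + b]
        p = pos0[idx]
        w = np.empty(len(p), dtype=np.int64)
        up = p < start
        down = p >= end
        body = ~up & ~down
        w[up] = np.floor((p[up] - (start - flank)) / flank * n_windows).astype(np.int64)
        w[body] = n_windows + np.minimum(
            np.floor((p[body] - start) / (end - start) * n_windows).astype(np.int64), n_windows - 1
        )
        w[down] = 2 * n_windows + np.minimum(
            np.floor((p[down] - end) / flank * n_windows).astype(np.int64), n_windows - 1
        )
        w = np.clip(w, 0, total_windows - 1)
        if strand == "-":
            w = total_windows - 1 - w
        np.add.at(pooled_mc, w, mc[idx])
        np.add.at(pooled_cov, w, cov[idx])
        fm = np.bincount(w, weights=mc[idx], minlength=total_windows)
        fc = np.bincount(w, weights=cov[idx], minlength=total_windows)
        for wi in np.nonzero(fc > 0)[0]:
            feat_levels[wi].append(fm[wi] / fc[wi])

    with np.errstate(invalid="ignore", divide="ignore"):
        pooled_level = np.where(pooled_cov > 0, pooled_mc / np.where(pooled_cov > 0, pooled_cov, 1), np.nan)
    mean_level = np.array([np.mean(v) if v else np.nan for v in feat_levels])
    region = (["upstream"] * n_windows + ["body"] * n_windows + ["downstream"] * n_windows)
    out = pd.DataFrame(
        {
            "window": np.arange(total_windows),
            "region": region,
            "mc": pooled_mc,
            "cov": pooled_cov,
            "pooled_level": pooled_level,
            "mean_level": mean_level,
        }
    )
    out["level"] = out["mean_level"] if mode == "per_feature_mean" else out["pooled_level"]
    return out
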