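"""Interval assignment of cytosine sites to annotation features."""

from __future__ import annotations

import numpy as np
import pandas as pd


def assign_sites(allc: pd.DataFrame, intervals) -> np.ndarray:
    """Map each site to the interval containing it.

    ``intervals`` is an iterable of ``(chrom, start, end, label)`` with
    0-based half-open coordinates, assumed non-overlapping within a
    chromosome.  Returns an object array of labels (None where the site
    falls in no interval).  Sites are matched by position regardless of
    strand, so both cytosines of a CG/CWG pair land in the same feature.
    """
    labels = np.full(len(allc), None, dtype=object)
    if not len(allc):
        return labels
    by_chrom: dict[str, list[tuple[int, int, object]]] = {}
    for chrom, s, e, lab in intervals:
        by_chrom.setdefault(chrom, []).append((s, e, lab))
    pos0 = allc["pos"].to_numpy() - 1  # allc positions are 1-based
    chroms = allc["chrom"].to_numpy()
    for chrom, ivs in by_chrom.items():
        ivs.sort()
        starts = np.array([s for s, _, _ in ivs])
        ends = np.array([e for _, e, _ in ivs])
        labs = np.empty(len(ivs), dtype=object)
        labs[:] = [lab for _, _, lab in ivs]
        mask = chroms == chrom
        if not mask.any():
            continue
        p = pos0[mask]
        idx = np.searchsorted(starts, p, side="right") - 1
        ok = (idx >= 0) & (p < ends[np.clip(idx, 0, None)])
        out = np.full(p.shape, None, dtype=object)
        out[ok] = labs[idx[ok]]
        labels[mask] = out
    return labels
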