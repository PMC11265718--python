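"""Truncated short-isoform references and short/long isoform ratios.

Genes whose long intron carries heterochromatic methylation can terminate
transcription at that intron, producing a truncated ("short") isoform.  To
quantify both forms, a truncated reference transcript is built from the
exonic sequence (UTR + CDS) 5' of the long intron and added to the
transcriptome used for abundance estimation; the short/long abundance
ratio then measures how often transcription fails to read through.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd

from .io import GeneModel, reverse_complement

log = logging.getLogger(__name__)

DEFAULT_SHIFT_DELTA = 2.0


@dataclass
class TranscriptPair:
    gene_id: str
    long_tx: str
    long_seq: str
    short_tx: str
    short_seq: str
    truncation_point: int  # transcript coordinate of the intron's 5' boundary

    def __post_init__(self) -> None:
        if not self.long_seq.startswith(self.short_seq):
            raise ValueError(f"{self.gene_id}: short sequence is not a prefix of the long transcript")


def _fetch(sequences, chrom: str, start: int, end: int) -> str:
    seq = sequences[chrom]
    return str(seq[start:end]).upper()


def spliced_sequence(gene: GeneModel, sequences) -> str:
    """mRNA-orientation spliced sequence (exons joined, revcomp on minus)."""
    parts = [_fetch(sequences, gene.chrom, s, e) for s, e in gene.exons]
    seq = "".join(parts)
    return reverse_complement(seq) if gene.strand == "-" else seq


def make_truncated_transcript(gene: GeneModel, intron_index: int, sequences) -> TranscriptPair:
    """Build the short-isoform reference truncated at a given intron.

    ``intron_index`` is 1-based in transcript orientation (the gene's "7th
    intron" is index 7).  The short sequence is the exonic sequence
    strictly 5' of that intron — the first ``intron_index`` exons in
    transcript order — so it is always a prefix of the full spliced
    transcript.  The intron itself is excluded.
    """
    n_introns = len(gene.introns)
    if not 1 <= intron_index <= n_introns:
        raise ValueError(f"{gene.gene_id}: intron {intron_index} does not exist ({n_introns} introns)")
    exon_order = gene.exons[::-1] if gene.strand == "-" else gene.exons
    kept = exon_order[:intron_index]
    kept_genomic = sorted(kept)
    seq = "".join(_fetch(sequences, gene.chrom, s, e) for s, e in kept_genomic)
    if gene.strand == "-":
        seq = reverse_complement(seq)
    long_seq = spliced_sequence(gene, sequences)
    if gene.cds:
        first_kept = set(kept_genomic)
        cds_in_kept = any(
            s < ke and e > ks for (s, e) in gene.cds for (ks, ke) in first_kept
        )
        if not cds_in_kept:
            log.warning("%s: intron %d precedes all CDS; short transcript is UTR only",
                        gene.gene_id, intron_index)
    tx = gene.transcript_id or gene.gene_id
    return TranscriptPair(
        gene_id=gene.gene_id,
        long_tx=tx,
        long_seq=long_seq,
        short_tx=f"{tx}.short",
        short_seq=seq,
        truncation_point=len(seq),
    )


def write_transcript_fasta(pairs, path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for p in pairs:
            for name, seq in ((p.long_tx, p.long_seq), (p.short_tx, p.short_seq)):
                fh.write(f">{name}\n")
                for i in range(0, len(seq), width):
                    fh.write(seq[i:i + width] + "\n")


def isoform_ratio(
    abundance: pd.DataFrame,
    pairing: pd.DataFrame,
    condition_of_sample: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Short/long abundance ratio per gene per condition.

    ``abundance`` is long-format (transcript_id, sample, abundance);
    ``pairing`` has columns (gene_id, short_tx, long_tx).  Replicates of a
    condition are averaged per transcript first, then the ratio of the
    averages is taken; the ratio is left missing when the long isoform's
    average abundance is zero.  Genes with a transcript absent from the
    table are skipped (count logged).
    """
    ab = abundance.copy()
    if condition_of_sample:
        ab["condition"] = ab["sample"].map(condition_of_sample)
    elif "condition" not in ab.columns:
        ab["condition"] = "all"
    means = ab.groupby(["transcript_id", "condition"])["abundance"].mean()
    rows = []
    n_skipped = 0
    for rec in pairing.itertuples():
        for cond in ab["condition"].unique():
            try:
                short = means.loc[(rec.short_tx, cond)]
                long = means.loc[(rec.long_tx, cond)]
            except KeyError:
                n_skipped += 1
                continue
            ratio = short / long if long > 0 else float("nan")
            rows.append((rec.gene_id, cond, short, long, ratio))
    if n_skipped:
        log.info("isoform_ratio: skipped %d (gene, condition) pairs with missing transcripts", n_skipped)
    return pd.DataFrame(rows, columns=["gene_id", "condition", "short", "long", "ratio"])


def ratio_shift_genes(
    ratios_a: pd.DataFrame,
    ratios_b: pd.DataFrame,
    delta: float = DEFAULT_SHIFT_DELTA,
) -> list[str]:
    """Genes whose short/long ratio rose by strictly more than ``delta``.

    ``ratios_b`` is the perturbed (e.g. hypomethylated-mutant) condition;
    the shift is the arithmetic difference ratio_b - ratio_a.  Genes with a
    missing ratio in either condition are skipped.
    """
    a = ratios_a.set_index("gene_id")["ratio"]
    b = ratios_b.set_index("gene_id")["ratio"]
    common = a.index.intersection(b.index)
    diff = (b.loc[common] - a.loc[common]).dropna()
    return sorted(diff.index[diff > delta])
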