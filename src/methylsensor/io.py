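"""Per-cytosine methylation tables, genome annotation and context classification.

The per-cytosine table ("allc" dialect) is a 7-column TSV:
``chrom  pos  strand  trinucleotide  mc  cov  call`` with 1-based positions
and the trinucleotide read 5'->3' on the cytosine's own strand (i.e. the
reverse complement of the reference for minus-strand sites).

All intervals held in memory are 0-based half-open; conversion to and from
1-based inclusive coordinates happens only while reading/writing GFF3, BED
and allc files.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import gffutils
import pandas as pd

log = logging.getLogger(__name__)

ALLC_COLUMNS = ["chrom", "pos", "strand", "trinucleotide", "mc", "cov", "call"]

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


class AllcParseError(ValueError):
    """Raised when a per-cytosine table line cannot be parsed or is invalid."""


def classify_context(trinucleotide: str) -> tuple[str, str | None]:
    """Classify a cytosine trinucleotide into (context_class, subcontext).

    CG if the second base is G; CHG if the second base is A/C/T and the
    third is G, with subcontext CWG (W = A or T) or CCG; everything else
    is CHH.  The subcontext is defined only for CHG; CWG sites are the
    strand-symmetric triplets preferred by CMT3, while CCG methylation
    additionally depends on MET1.
    """
    tri = trinucleotide.upper()
    if len(tri) != 3 or any(b not in "ACGT" for b in tri):
        raise ValueError(f"trinucleotide must be a 3-mer over ACGT, got {trinucleotide!r}")
    if tri[0] != "C":
        raise ValueError(f"trinucleotide must start with C, got {trinucleotide!r}")
    if tri[1] == "G":
        return "CG", None
    if tri[2] == "G":
        return "CHG", ("CWG" if tri[1] in "AT" else "CCG")
    return "CHH", None


@dataclass
class CytosineSiteRecord:
    """One cytosine's counts and call status.

    ``pos`` is 1-based; ``mc_reads``/``total_reads`` are the methylated and
    total read counts of the binomial methylation call.
    """

    chrom: str
    pos: int
    strand: str
    trinucleotide: str
    mc_reads: int
    total_reads: int
    called: bool | None = None

    def __post_init__(self) -> None:
        if self.mc_reads < 0 or self.total_reads < 0:
            raise AllcParseError(f"negative read count at {self.chrom}:{self.pos}")
        if self.mc_reads > self.total_reads:
            raise AllcParseError(
                f"mc_reads ({self.mc_reads}) exceeds total_reads "
                f"({self.total_reads}) at {self.chrom}:{self.pos}"
            )
        if self.strand not in "+-":
            raise AllcParseError(f"bad strand {self.strand!r} at {self.chrom}:{self.pos}")

    @property
    def context_class(self) -> str:
        return classify_context(self.trinucleotide)[0]

    @property
    def subcontext(self) -> str | None:
        return classify_context(self.trinucleotide)[1]


def read_allc(path: str | Path) -> Iterator[CytosineSiteRecord]:
    """Stream records from an allc file, validating each line.

    The context class is always recomputed from the trinucleotide rather
    than trusted from the file.  Malformed lines raise
    :class:`AllcParseError` naming the line number.
    """
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 7:
                raise AllcParseError(f"{path}:{lineno}: expected 7 fields, got {len(fields)}")
            chrom, pos_s, strand, tri, mc_s, cov_s, call_s = fields
            try:
                pos, mc, cov = int(pos_s), int(mc_s), int(cov_s)
            except ValueError as exc:
                raise AllcParseError(f"{path}:{lineno}: non-integer field ({exc})") from exc
            called: bool | None
            if call_s in ("", ".", "NA"):
                called = None
            else:
                called = bool(int(call_s))
            try:
                rec = CytosineSiteRecord(chrom, pos, strand, tri, mc, cov, called)
                rec.context_class  # validates the trinucleotide
            except (AllcParseError, ValueError) as exc:
                raise AllcParseError(f"{path}:{lineno}: {exc}") from exc
            yield rec


def load_allc(path: str | Path) -> pd.DataFrame:
    """Load an allc file into a DataFrame with derived context columns."""
    records = list(read_allc(path))
    return records_to_frame(records)


def records_to_frame(records: Iterable[CytosineSiteRecord]) -> pd.DataFrame:
    rows = [
        (r.chrom, r.pos, r.strand, r.trinucleotide, r.mc_reads, r.total_reads, r.called)
        for r in records
    ]
    df = pd.DataFrame(rows, columns=["chrom", "pos", "strand", "trinucleotide", "mc", "cov", "called"])
    if len(df):
        ctx = df["trinucleotide"].map(lambda t: classify_context(t))
        df["context_class"] = [c[0] for c in ctx]
        df["subcontext"] = [c[1] for c in ctx]
    else:
        df["context_class"] = pd.Series(dtype=object)
        df["subcontext"] = pd.Series(dtype=object)
    return df


def write_allc(records, path: str | Path, header: bool = False) -> None:
    """Write records (iterable of records or a DataFrame) as an allc TSV.

    Output is sorted by (chrom, pos, strand) with deterministic formatting;
    the call column is '1'/'0' or '.' when unset.
    """
    if isinstance(records, pd.DataFrame):
        df = records
        rows = [
            (r.chrom, int(r.pos), r.strand, r.trinucleotide, int(r.mc), int(r.cov),
             None if pd.isna(r.called) else bool(r.called))
            for r in df.itertuples()
        ]
    else:
        rows = [
            (r.chrom, r.pos, r.strand, r.trinucleotide, r.mc_reads, r.total_reads, r.called)
            for r in records
        ]
    try:
        rows.sort(key=lambda r: (r[0], r[1], r[2]))
    except TypeError as exc:
        raise ValueError(f"unsortable chromosome names: {exc}") from exc
    with open(path, "w") as fh:
        if header:
            fh.write("#" + "\t".join(ALLC_COLUMNS) + "\n")
        for chrom, pos, strand, tri, mc, cov, called in rows:
            call_s = "." if called is None else ("1" if called else "0")
            fh.write(f"{chrom}\t{pos}\t{strand}\t{tri}\t{mc}\t{cov}\t{call_s}\n")


# ---------------------------------------------------------------------------
# annotation

Interval = tuple[int, int]  # 0-based half-open


@dataclass
class GeneModel:
    """Strand-aware exon/CDS/UTR structure of one gene's primary transcript.

    Intervals are 0-based half-open, sorted in genomic order.  Introns are
    the gaps between consecutive exons.
    """

    gene_id: str
    chrom: str
    strand: str
    exons: list[Interval]
    cds: list[Interval] = field(default_factory=list)
    utr5: list[Interval] = field(default_factory=list)
    utr3: list[Interval] = field(default_factory=list)
    transcript_id: str | None = None

    def __post_init__(self) -> None:
        self.exons = sorted(self.exons)
        self.cds = sorted(self.cds)
        for a, b in zip(self.exons, self.exons[1:]):
            if a[1] > b[0]:
                raise ValueError(f"{self.gene_id}: overlapping exons {a} and {b}")

    @property
    def introns(self) -> list[Interval]:
        return [(a[1], b[0]) for a, b in zip(self.exons, self.exons[1:])]

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    def introns_transcript_order(self) -> list[Interval]:
        """Introns ordered 5'->3' along the transcript (reversed on minus strand)."""
        ivs = self.introns
        return ivs[::-1] if self.strand == "-" else ivs


@dataclass
class GenomeAnnotation:
    genes: dict[str, GeneModel]
    te_features: list[tuple[str, int, int, str]] = field(default_factory=list)
    chrom_lengths: dict[str, int] = field(default_factory=dict)


def _spliced_length(intervals: list[Interval]) -> int:
    return sum(e - s for s, e in intervals)


def read_gff(path: str | Path, te_types: tuple[str, ...] = ("transposable_element",)) -> GenomeAnnotation:
    """Read GFF3 into a :class:`GenomeAnnotation`.

    One :class:`GeneModel` is built per gene from its primary transcript,
    defined as the mRNA with the longest spliced (exonic) length; ties are
    broken by the lexicographically smallest transcript id.  GFF3 1-based
    inclusive coordinates become 0-based half-open.
    """
    db = gffutils.create_db(
        str(path), ":memory:", merge_strategy="create_unique", keep_order=True
    )
    genes: dict[str, GeneModel] = {}
    for gene in db.features_of_type("gene"):
        mrnas = list(db.children(gene, featuretype="mRNA"))
        if not mrnas:
            log.warning("gene %s has no mRNA children; skipped", gene.id)
            continue

        def key(m):
            exons = [(e.start - 1, e.end) for e in db.children(m, featuretype="exon")]
            return (-_spliced_length(exons) if exons else -(m.end - m.start + 1), m.id)

        primary = min(mrnas, key=key)
        exons = sorted((e.start - 1, e.end) for e in db.children(primary, featuretype="exon"))
        if not exons:
            exons = [(primary.start - 1, primary.end)]
        cds = sorted((c.start - 1, c.end) for c in db.children(primary, featuretype="CDS"))
        utr5 = sorted((u.start - 1, u.end) for u in db.children(primary, featuretype="five_prime_UTR"))
        utr3 = sorted((u.start - 1, u.end) for u in db.children(primary, featuretype="three_prime_UTR"))
        gene_span = (gene.start - 1, gene.end)
        for s, e in exons:
            if s < gene_span[0] or e > gene_span[1]:
                raise ValueError(f"exon ({s},{e}) outside span of gene {gene.id}")
        genes[gene.id] = GeneModel(
            gene_id=gene.id,
            chrom=gene.seqid,
            strand=gene.strand,
            exons=exons,
            cds=cds,
            utr5=utr5,
            utr3=utr3,
            transcript_id=primary.id,
        )
    tes = [
        (f.seqid, f.start - 1, f.end, f.featuretype)
        for t in te_types
        for f in db.features_of_type(t)
    ]
    return GenomeAnnotation(genes=genes, te_features=tes)


def select_long_introns(
    annotation: GenomeAnnotation, min_len: int = 1000, strict: bool = False
) -> list[tuple[str, int, str, Interval]]:
    """Return (gene_id, intron_index, chrom, interval) for long introns.

    ``intron_index`` is 1-based in transcript orientation, so a minus-strand
    gene's "7th intron" is counted from its 5' end.  Length comparison is
    inclusive (``>= min_len``) by default; ``strict=True`` uses ``>``.
    Results are ordered by genomic position.
    """
    hits = []
    for gene in annotation.genes.values():
        for idx, (s, e) in enumerate(gene.introns_transcript_order(), start=1):
            length = e - s
            keep = length > min_len if strict else length >= min_len
            if keep:
                hits.append((gene.gene_id, idx, gene.chrom, (s, e)))
    hits.sort(key=lambda h: (h[2], h[3][0]))
    return hits


def write_intron_bed(introns, path: str | Path) -> None:
    """Write select_long_introns output as BED (0-based half-open)."""
    with open(path, "w") as fh:
        for gene_id, idx, chrom, (s, e) in introns:
            fh.write(f"{chrom}\t{s}\t{e}\t{gene_id}.intron{idx}\n")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]
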