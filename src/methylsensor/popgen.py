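"""Region-stratified SNP density, Tajima's D, and pairwise divergence.

Methylated cytosines deaminate at elevated rates, so a methylated intron
should accumulate more SNPs than the surrounding coding sequence.  These
statistics compare polymorphism between region classes (CDS, methylated
intron, unmethylated intron) of one gene or locus.

Haplotypes are treated as haploid (inbred accessions), the 1,001-Genomes
convention.  Tajima's D follows the standard estimator: D = (pi - S/a1) /
sqrt(e1*S + e2*S*(S-1)) with the usual Watterson constants; pi is the mean
pairwise difference count over haplotype pairs, counted pairwise-complete
at sites where both members are genotyped.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MISSING = -1

REGION_CLASSES = ("CDS", "methylated_intron", "unmethylated_intron", "other")


@dataclass
class SnpMatrix:
    """Biallelic genotypes: positions x haplotypes, 0/1 with -1 missing."""

    positions: np.ndarray  # 1-based, shape (S_raw,)
    genotypes: np.ndarray  # shape (S_raw, n), int8
    haplotype_ids: list[str]

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions)
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        if self.genotypes.shape != (len(self.positions), len(self.haplotype_ids)):
            raise ValueError("genotype matrix shape mismatch")

    @property
    def n(self) -> int:
        return len(self.haplotype_ids)

    def restrict(self, positions_keep) -> "SnpMatrix":
        mask = np.isin(self.positions, np.asarray(list(positions_keep)))
        return SnpMatrix(self.positions[mask], self.genotypes[mask], self.haplotype_ids)

    @classmethod
    def read_tsv(cls, path) -> "SnpMatrix":
        """Genotype TSV: first column 'pos', one column per haplotype; '.' missing."""
        df = pd.read_csv(path, sep="\t")
        pos = df["pos"].to_numpy()
        hap_ids = [c for c in df.columns if c != "pos"]
        geno = df[hap_ids].replace(".", MISSING).to_numpy(dtype=np.int8)
        return cls(pos, geno, hap_ids)

    def write_tsv(self, path) -> None:
        df = pd.DataFrame(self.genotypes, columns=self.haplotype_ids)
        df.insert(0, "pos", self.positions)
        df.to_csv(path, sep="\t", index=False)


@dataclass
class RegionPartition:
    """Maps 1-based positions to disjoint region classes.

    ``regions`` maps class name -> list of (start, end) 0-based half-open
    intervals.  The surveyed length of a class is the total span of its
    intervals.
    """

    regions: dict[str, list[tuple[int, int]]]

    def length(self, cls: str) -> int:
        return sum(e - s for s, e in self.regions.get(cls, []))

    def positions_in(self, cls: str, positions: np.ndarray) -> np.ndarray:
        mask = np.zeros(len(positions), dtype=bool)
        p0 = np.asarray(positions) - 1
        for s, e in self.regions.get(cls, []):
            mask |= (p0 >= s) & (p0 < e)
        return mask

    def class_of_columns(self, n_columns: int) -> np.ndarray:
        """Class label per alignment column (0-based); 'other' where unassigned."""
        out = np.full(n_columns, "other", dtype=object)
        for cls, ivs in self.regions.items():
            for s, e in ivs:
                out[s:e] = cls
        return out


@dataclass
class PopGenStats:
    region_class: str
    L: int
    S: int
    pi: float
    n: int
    constants: dict[str, float] = field(default_factory=dict)
    D: float = float("nan")
    snp_density: float = float("nan")


def segregating_mask(genotypes: np.ndarray) -> np.ndarray:
    """True for sites with >= 2 alleles among non-missing haplotypes."""
    g = np.asarray(genotypes)
    present = g != MISSING
    ones = ((g == 1) & present).sum(axis=1)
    nz = present.sum(axis=1)
    return (ones > 0) & (ones < nz)


def snp_density(matrix: SnpMatrix, partition: RegionPartition, region_class: str) -> float:
    """Proportion of surveyed sites in the class that are polymorphic (S/L)."""
    L = partition.length(region_class)
    if L == 0:
        return float("nan")
    in_cls = partition.positions_in(region_class, matrix.positions)
    S = int(segregating_mask(matrix.genotypes[in_cls]).sum())
    return S / L


def _tajima_constants(n: int) -> dict[str, float]:
    i = np.arange(1, n)
    a1 = float(np.sum(1.0 / i))
    a2 = float(np.sum(1.0 / i**2))
    b1 = (n + 1) / (3 * (n - 1))
    b2 = 2 * (n**2 + n + 3) / (9 * n * (n - 1))
    c1 = b1 - 1 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return {"a1": a1, "a2": a2, "b1": b1, "b2": b2, "c1": c1, "c2": c2, "e1": e1, "e2": e2}


def mean_pairwise_differences(genotypes: np.ndarray) -> float:
    """Mean over all haplotype pairs of difference counts, pairwise-complete.

    A pair's difference count at a site is 1 when both are genotyped and
    their alleles differ, else 0; the mean is over all C(n,2) pairs.  For
    biallelic 0/1 data this equals sum_s k_s (m_s - k_s) / C(n,2) with k_s
    derived-allele count and m_s genotyped haplotypes at site s.
    """
    g = np.asarray(genotypes)
    n = g.shape[1]
    if n < 2:
        raise ValueError("need >= 2 haplotypes")
    present = g != MISSING
    k = ((g == 1) & present).sum(axis=1)
    m = present.sum(axis=1)
    diff_pairs = (k * (m - k)).sum()
    return float(diff_pairs) / (n * (n - 1) / 2)


def tajimas_d(
    matrix: SnpMatrix,
    partition: RegionPartition | None = None,
    region_class: str | None = None,
) -> PopGenStats:
    """Tajima's D for the sites of one region class (or the whole matrix).

    D is left missing when S = 0.  Requires n >= 4 haplotypes.
    """
    g = matrix.genotypes
    pos = matrix.positions
    L = len(pos)
    cls = region_class or "all"
    if partition is not None and region_class is not None:
        mask = partition.positions_in(region_class, pos)
        g = g[mask]
        L = partition.length(region_class)
    n = matrix.n
    if n < 4:
        raise ValueError(f"need >= 4 haplotypes, got {n}")
    seg = segregating_mask(g)
    S = int(seg.sum())
    consts = _tajima_constants(n)
    pi = mean_pairwise_differences(g[seg]) if S else 0.0
    stats = PopGenStats(region_class=cls, L=L, S=S, pi=pi, n=n, constants=consts)
    stats.snp_density = S / L if L else float("nan")
    if S > 0:
        var = consts["e1"] * S + consts["e2"] * S * (S - 1)
        stats.D = (pi - S / consts["a1"]) / np.sqrt(var)
    return stats


def pairwise_difference(seq_a: str, seq_b: str, partition: RegionPartition) -> dict[str, float]:
    """Per-class divergence of a 2-sequence alignment: 1 - identical/compared.

    Columns with a gap ('-') in either sequence are excluded from both the
    numerator and the denominator.  Classes with no comparable columns get
    NaN.
    """
    if len(seq_a) != len(seq_b):
        raise ValueError(f"aligned sequences differ in length ({len(seq_a)} vs {len(seq_b)})")
    a = np.frombuffer(seq_a.upper().encode(), dtype="S1")
    b = np.frombuffer(seq_b.upper().encode(), dtype="S1")
    comparable = (a != b"-") & (b != b"-")
    identical = comparable & (a == b)
    classes = partition.class_of_columns(len(a))
    out = {}
    for cls in dict.fromkeys(classes):
        in_cls = classes == cls
        n_comp = int((comparable & in_cls).sum())
        if n_comp == 0:
            out[cls] = float("nan")
        else:
            out[cls] = 1.0 - int((identical & in_cls).sum()) / n_comp
    return out
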