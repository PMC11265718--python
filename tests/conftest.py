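import math

import numpy as np
import pytest

import methylsensor as ms


# ---------------------------------------------------------------------------
# independent oracles (kept deliberately naive)


def binom_upper_tail_bruteforce(mc: int, cov: int, p: float) -> float:
    """P(X >= mc) by direct summation of the binomial pmf."""
    return sum(
        math.comb(cov, k) * p**k * (1 - p) ** (cov - k) for k in range(mc, cov + 1)
    )


def bh_bruteforce(pvals):
    """Benjamini-Hochberg by the definition: sort, scale, cummin from the top."""
    p = list(pvals)
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    q = [0.0] * m
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * m / rank)
        q[i] = min(running, 1.0)
    return q


def tajimas_d_bruteforce(genotypes):
    """Tajima's D with pi counted pair by pair (missing = -1 skipped)."""
    g = np.asarray(genotypes)
    S_count = 0
    for row in g:
        alleles = {a for a in row if a != -1}
        if len(alleles) > 1:
            S_count += 1
    n = g.shape[1]
    diffs = []
    for a in range(n):
        for b in range(a + 1, n):
            d = sum(
                1
                for s in range(g.shape[0])
                if g[s, a] != -1 and g[s, b] != -1 and g[s, a] != g[s, b]
            )
            diffs.append(d)
    pi = sum(diffs) / len(diffs)
    a1 = sum(1 / i for i in range(1, n))
    a2 = sum(1 / i**2 for i in range(1, n))
    b1 = (n + 1) / (3 * (n - 1))
    b2 = 2 * (n**2 + n + 3) / (9 * n * (n - 1))
    c1 = b1 - 1 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    if S_count == 0:
        return float("nan")
    return (pi - S_count / a1) / math.sqrt(e1 * S_count + e2 * S_count * (S_count - 1))


@pytest.fixture
def oracles():
    return {
        "binom_tail": binom_upper_tail_bruteforce,
        "bh": bh_bruteforce,
        "tajimas_d": tajimas_d_bruteforce,
    }


# ---------------------------------------------------------------------------
# toy data


TOY_GFF = """##gff-version 3
chr1\t.\tgene\t1\t300\t.\t+\t.\tID=geneA
chr1\t.\tmRNA\t1\t300\t.\t+\t.\tID=geneA.t1;Parent=geneA
chr1\t.\texon\t1\t100\t.\t+\t.\tID=geneA.t1.e1;Parent=geneA.t1
chr1\t.\texon\t201\t300\t.\t+\t.\tID=geneA.t1.e2;Parent=geneA.t1
chr1\t.\tCDS\t21\t100\t.\t+\t.\tID=geneA.t1.c1;Parent=geneA.t1
chr1\t.\tCDS\t201\t280\t.\t+\t.\tID=geneA.t1.c2;Parent=geneA.t1
chr1\t.\tfive_prime_UTR\t1\t20\t.\t+\t.\tID=geneA.t1.u5;Parent=geneA.t1
chr1\t.\tthree_prime_UTR\t281\t300\t.\t+\t.\tID=geneA.t1.u3;Parent=geneA.t1
chr1\t.\tgene\t1001\t1500\t.\t-\t.\tID=geneB
chr1\t.\tmRNA\t1001\t1300\t.\t-\t.\tID=geneB.t2;Parent=geneB
chr1\t.\texon\t1001\t1300\t.\t-\t.\tID=geneB.t2.e1;Parent=geneB.t2
chr1\t.\tCDS\t1001\t1300\t.\t-\t.\tID=geneB.t2.c1;Parent=geneB.t2
chr1\t.\tmRNA\t1001\t1500\t.\t-\t.\tID=geneB.t1;Parent=geneB
chr1\t.\texon\t1001\t1200\t.\t-\t.\tID=geneB.t1.e1;Parent=geneB.t1
chr1\t.\texon\t1301\t1500\t.\t-\t.\tID=geneB.t1.e2;Parent=geneB.t1
chr1\t.\tCDS\t1001\t1200\t.\t-\t.\tID=geneB.t1.c1;Parent=geneB.t1
chr1\t.\tCDS\t1301\t1400\t.\t-\t.\tID=geneB.t1.c2;Parent=geneB.t1
"""


@pytest.fixture
def toy_gff(tmp_path):
    path = tmp_path / "toy.gff3"
    path.write_text(TOY_GFF)
    return path


@pytest.fixture
def toy_annotation(toy_gff):
    return ms.read_gff(toy_gff)


def random_gene_model(rng, gene_id="g", chrom="chr1", max_exons=6):
    """Random multi-exon GeneModel for property tests."""
    n_exons = int(rng.integers(1, max_exons + 1))
    pos = int(rng.integers(0, 50))
    exons = []
    for _ in range(n_exons):
        length = int(rng.integers(20, 200))
        exons.append((pos, pos + length))
        pos += length + int(rng.integers(30, 300))
    strand = "+" if rng.random() < 0.5 else "-"
    return ms.GeneModel(gene_id=gene_id, chrom=chrom, strand=strand, exons=exons,
                        cds=list(exons), transcript_id=f"{gene_id}.t1")
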