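"""Synthetic methylomes, accession panels, genomes and genotype matrices.

Every generator is a pure function of its configuration (seed included),
so repeated calls with the same config are identical.  The count model at
each cytosine is

    cov ~ Poisson(depth),   mc ~ Binomial(cov, level + (1 - level) * p0)

which folds the bisulfite non-conversion rate p0 into the observed
methylated-read probability; at a true level of 0 the site caller's null
is then exactly correct.

Two tiers are provided: gene-site tables (counts keyed by gene, for
classifier- and panel-scale simulations) and full coordinate genomes
(FASTA + GFF3 + allc, for end-to-end pipeline runs).  Truth is returned as
separate tables, never embedded in the data formats.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import GeneModel, GenomeAnnotation
from .popgen import RegionPartition, SnpMatrix

CONTEXT_TRI = {"CG": "CGA", "CHG": "CAG", "CHH": "CAT"}


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic generators.

    Defaults follow the simulation conditions the analyses are validated
    under: per-gene site counts of 30 CG / 30 CHG / 20 CHH, sequencing
    depth Poisson(10), non-conversion 0.005, gbM-gene CG level 0.8 against
    a 0.02 genic background and ~0.01 non-CG background.
    """

    seed: int = 0
    # gene-site simulations
    n_genes: int = 2000
    n_cg_sites: int = 30
    n_chg_sites: int = 30
    n_chh_sites: int = 20
    gbm_fraction: float = 0.3
    gbm_cg_level: float = 0.8
    background_cg_level: float = 0.02
    chg_level: float = 0.01
    chh_level: float = 0.005
    depth: float = 10.0
    p0: float = 0.005
    # accession panel
    n_accessions: int = 50
    n_ibm1_like: int = 5
    n_ectopic_genes: int = 150
    n_ectopic_background: int = 10
    ectopic_chg_level: float = 0.3
    sensor_chg_level: float = 0.12
    sensor_reduction: float = 0.2  # ibm1-like sensor level = level * reduction
    sensor_n_sites: int = 100
    sensor_depth: float = 20.0
    # CWG symmetry
    cwg_regime: str = "coupled"  # or "independent"
    cwg_level: float = 0.8  # coupled: shared per-site level; independent: per-strand methylation prob
    cwg_meth_level: float = 0.8  # read-level of a methylated strand in the independent regime
    n_cwg_pairs: int = 5000
    cwg_depth: float = 20.0
    # SNP matrices
    n_haplotypes: int = 20
    region_lengths: dict = field(default_factory=lambda: {
        "CDS": 2000, "methylated_intron": 1000, "unmethylated_intron": 1000})
    snp_rates: dict = field(default_factory=lambda: {
        "CDS": 0.002, "methylated_intron": 0.006, "unmethylated_intron": 0.002})
    # abundance tables
    n_abund_genes: int = 500
    n_shifted_genes: int = 10
    shift_size: float = 5.0
    shift_noise_sd: float = 0.3
    n_replicates: int = 3
    # coordinate genomes
    n_genome_genes: int = 60
    long_intron_fraction: float = 0.2
    long_intron_len: int = 1500
    sensor_intron_chg_level: float = 0.4
    tem_fraction: float = 0.1
    te_cg_level: float = 0.9
    te_chg_level: float = 0.7
    te_chh_level: float = 0.1


def _counts(rng, n, depth, level, p0):
    cov = rng.poisson(depth, size=n)
    p = np.asarray(level) + (1 - np.asarray(level)) * p0
    mc = rng.binomial(cov, np.broadcast_to(p, cov.shape))
    return mc, cov


# ---------------------------------------------------------------------------
# gene-site tier


def simulate_gene_sites(cfg: SimulationConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Gene-keyed site count table with planted gbM genes.

    Returns (sites, truth): ``sites`` has one row per cytosine with columns
    gene_id, context_class, mc, cov; ``truth`` lists each gene's planted
    class.  The number of gbM genes is exactly
    ``round(n_genes * gbm_fraction)``.
    """
    rng = np.random.default_rng(cfg.seed)
    n_gbm = round(cfg.n_genes * cfg.gbm_fraction)
    gene_ids = np.array([f"g{i:05d}" for i in range(cfg.n_genes)])
    is_gbm = np.zeros(cfg.n_genes, dtype=bool)
    is_gbm[rng.choice(cfg.n_genes, size=n_gbm, replace=False)] = True

    frames = []
    for context, n_sites in (("CG", cfg.n_cg_sites), ("CHG", cfg.n_chg_sites), ("CHH", cfg.n_chh_sites)):
        if context == "CG":
            levels = np.where(is_gbm, cfg.gbm_cg_level, cfg.background_cg_level)
        elif context == "CHG":
            levels = np.full(cfg.n_genes, cfg.chg_level)
        else:
            levels = np.full(cfg.n_genes, cfg.chh_level)
        lv = np.repeat(levels, n_sites)
        mc, cov = _counts(rng, cfg.n_genes * n_sites, cfg.depth, lv, cfg.p0)
        frames.append(pd.DataFrame({
            "gene_id": np.repeat(gene_ids, n_sites),
            "context_class": context,
            "mc": mc,
            "cov": cov,
        }))
    sites = pd.concat(frames, ignore_index=True)
    truth = pd.DataFrame({"gene_id": gene_ids, "is_gbm": is_gbm})
    return sites, truth


def simulate_panel(cfg: SimulationConfig) -> tuple[dict[str, pd.DataFrame], pd.DataFrame, pd.DataFrame]:
    """Accession panel with a minority of ibm1-like accessions.

    A fixed ``gbm_fraction`` of genes are gbM in every accession (gbM is
    population-stable); the rest sit at the unmethylated background.
    Each ibm1-like accession carries ectopic mCHG (level
    ``ectopic_chg_level``) in ``n_ectopic_genes`` random gbM genes and a
    sensor intron whose mCHG is reduced by ``sensor_reduction``; normal
    accessions carry ``n_ectopic_background`` ectopic gbM genes and the
    full sensor level.

    Returns (sites_by_accession, accession_truth, ectopic_truth).
    ``accession_truth`` has per-accession ibm1_like flags, true and
    observed sensor mCHG, and expression / isoform-ratio columns coupled
    to the sensor level (expression rises, the short/long ratio falls, as
    sensor methylation rises).
    """
    rng = np.random.default_rng(cfg.seed)
    if cfg.n_ibm1_like > cfg.n_accessions:
        raise ValueError("n_ibm1_like exceeds n_accessions")
    gene_ids = np.array([f"g{i:05d}" for i in range(cfg.n_genes)])
    accessions = [f"acc{i:03d}" for i in range(cfg.n_accessions)]
    ibm1_idx = rng.choice(cfg.n_accessions, size=cfg.n_ibm1_like, replace=False)
    ibm1_like = np.zeros(cfg.n_accessions, dtype=bool)
    ibm1_like[ibm1_idx] = True
    n_gbm = round(cfg.n_genes * cfg.gbm_fraction)
    if max(cfg.n_ectopic_genes, cfg.n_ectopic_background) > n_gbm:
        raise ValueError("more ectopic genes requested than gbM genes exist")
    gbm_idx = rng.choice(cfg.n_genes, size=n_gbm, replace=False)
    cg_levels = np.full(cfg.n_genes, cfg.background_cg_level)
    cg_levels[gbm_idx] = cfg.gbm_cg_level

    sites_by_acc: dict[str, pd.DataFrame] = {}
    ectopic_rows = []
    truth_rows = []
    for a, acc in enumerate(accessions):
        n_ect = cfg.n_ectopic_genes if ibm1_like[a] else cfg.n_ectopic_background
        ect_idx = rng.choice(gbm_idx, size=n_ect, replace=False)
        chg_levels = np.full(cfg.n_genes, cfg.chg_level)
        chg_levels[ect_idx] = cfg.ectopic_chg_level
        for g in ect_idx:
            ectopic_rows.append((acc, gene_ids[g]))
        frames = []
        for context, n_sites, levels in (
            ("CG", cfg.n_cg_sites, cg_levels),
            ("CHG", cfg.n_chg_sites, chg_levels),
            ("CHH", cfg.n_chh_sites, np.full(cfg.n_genes, cfg.chh_level)),
        ):
            mc, cov = _counts(rng, cfg.n_genes * n_sites, cfg.depth, np.repeat(levels, n_sites), cfg.p0)
            frames.append(pd.DataFrame({
                "gene_id": np.repeat(gene_ids, n_sites),
                "context_class": context,
                "mc": mc,
                "cov": cov,
            }))
        sites_by_acc[acc] = pd.concat(frames, ignore_index=True)

        sensor_true = cfg.sensor_chg_level * (cfg.sensor_reduction if ibm1_like[a] else 1.0)
        # per-accession jitter so sensor levels vary within each group
        sensor_true = max(0.0, sensor_true * float(rng.uniform(0.7, 1.3)))
        s_mc, s_cov = _counts(rng, cfg.sensor_n_sites, cfg.sensor_depth, sensor_true, cfg.p0)
        sensor_obs = s_mc.sum() / max(s_cov.sum(), 1)
        expression = 5.0 + 40.0 * sensor_true + rng.normal(0, 0.25)
        iso_ratio = max(0.0, 2.0 - 12.0 * sensor_true + rng.normal(0, 0.05))
        truth_rows.append((acc, bool(ibm1_like[a]), sensor_true, sensor_obs,
                           int(s_mc.sum()), int(s_cov.sum()), expression, iso_ratio))

    accession_truth = pd.DataFrame(
        truth_rows,
        columns=["accession", "ibm1_like", "sensor_mCHG_true", "sensor_mCHG",
                 "sensor_mc", "sensor_cov", "expression", "isoform_ratio"],
    )
    ectopic_truth = pd.DataFrame(ectopic_rows, columns=["accession", "gene_id"])
    return sites_by_acc, accession_truth, ectopic_truth


def gene_sites_to_allc(sites: pd.DataFrame, gene_block: int = 10_000, chrom: str = "chr1") -> pd.DataFrame:
    """Assign deterministic coordinates to a gene-site table (allc columns).

    Gene i occupies a ``gene_block``-sized block; sites are laid out in
    order on the plus strand with a context-consistent trinucleotide.
    """
    df = sites.copy().reset_index(drop=True)
    gene_idx = df["gene_id"].str.extract(r"(\d+)$")[0].astype(int).to_numpy()
    offset = df.groupby("gene_id").cumcount().to_numpy()
    df["chrom"] = chrom
    df["pos"] = gene_idx * gene_block + offset * 5 + 1
    df["strand"] = "+"
    df["trinucleotide"] = df["context_class"].map(CONTEXT_TRI)
    df["called"] = None
    return df[["chrom", "pos", "strand", "trinucleotide", "mc", "cov", "called",
               "context_class", "gene_id"]]


# ---------------------------------------------------------------------------
# CWG symmetry tier


def simulate_cwg(cfg: SimulationConfig) -> tuple[pd.DataFrame, dict]:
    """Strand-paired CWG count table under a coupled or independent regime.

    ``coupled``: one per-site methylation level (``cwg_level``) shared by
    both strands — the CMT3-maintained situation.  ``independent``: each
    strand is independently methylated with probability ``cwg_level``, and
    a methylated strand reads at ``cwg_meth_level`` — the CMT3-absent
    situation where strands decouple.
    """
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_cwg_pairs
    if cfg.cwg_regime == "coupled":
        plus_level = minus_level = np.full(n, cfg.cwg_level)
    elif cfg.cwg_regime == "independent":
        plus_level = np.where(rng.random(n) < cfg.cwg_level, cfg.cwg_meth_level, 0.0)
        minus_level = np.where(rng.random(n) < cfg.cwg_level, cfg.cwg_meth_level, 0.0)
    else:
        raise ValueError(f"unknown regime {cfg.cwg_regime!r}")
    p_mc, p_cov = _counts(rng, n, cfg.cwg_depth, plus_level, cfg.p0)
    m_mc, m_cov = _counts(rng, n, cfg.cwg_depth, minus_level, cfg.p0)
    pairs = pd.DataFrame({
        "chrom": "chr1",
        "pos": np.arange(1, 5 * n, 5),
        "plus_mc": p_mc, "plus_cov": p_cov,
        "minus_mc": m_mc, "minus_cov": m_cov,
    })
    truth = {"regime": cfg.cwg_regime, "plus_level": plus_level, "minus_level": minus_level}
    return pairs, truth


# ---------------------------------------------------------------------------
# SNP tier


def simulate_snp_matrix(cfg: SimulationConfig) -> tuple[SnpMatrix, RegionPartition, dict]:
    """Genotype matrix with region-dependent polymorphism rates.

    Regions are laid out consecutively in the order of
    ``cfg.region_lengths``.  Each position is polymorphic with its class
    rate; the derived-allele count at a polymorphic site is drawn from the
    neutral-like spectrum P(i) proportional to 1/i (i = 1 .. n-1), which
    keeps Tajima's D near zero in expectation.
    """
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_haplotypes
    if n < 4:
        raise ValueError("need >= 4 haplotypes")
    regions = {}
    start = 0
    for cls, length in cfg.region_lengths.items():
        regions[cls] = [(start, start + length)]
        start += length
    partition = RegionPartition(regions=regions)
    i = np.arange(1, n)
    sfs = (1.0 / i) / np.sum(1.0 / i)
    positions, genotypes = [], []
    for cls, ivs in regions.items():
        rate = cfg.snp_rates.get(cls, 0.0)
        for s, e in ivs:
            poly = np.nonzero(rng.random(e - s) < rate)[0]
            for p in poly:
                k = int(rng.choice(i, p=sfs))
                row = np.zeros(n, dtype=np.int8)
                row[rng.choice(n, size=k, replace=False)] = 1
                positions.append(s + p + 1)  # 1-based
                genotypes.append(row)
    if positions:
        order = np.argsort(positions)
        positions = np.asarray(positions)[order]
        genotypes = np.asarray(genotypes)[order]
    else:
        positions = np.empty(0, dtype=int)
        genotypes = np.empty((0, n), dtype=np.int8)
    matrix = SnpMatrix(positions, genotypes, [f"hap{j:03d}" for j in range(n)])
    return matrix, partition, {"rates": dict(cfg.snp_rates)}


# ---------------------------------------------------------------------------
# abundance tier


def simulate_abundance(cfg: SimulationConfig) -> tuple[pd.DataFrame, pd.DataFrame, dict[str, str], list[str]]:
    """Abundance table with planted short/long ratio shifts.

    Baseline short/long ratios are mildly positive; between conditions
    "wt" and "mut", unshifted genes move by Normal(0, shift_noise_sd)
    while ``n_shifted_genes`` planted genes move by ``shift_size``.
    Returns (abundance, pairing, condition_of_sample, shifted_gene_ids).
    """
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_abund_genes
    gene_ids = [f"ag{i:04d}" for i in range(n)]
    shifted = sorted(rng.choice(n, size=cfg.n_shifted_genes, replace=False))
    shifted_ids = [gene_ids[i] for i in shifted]
    base_ratio = np.abs(rng.normal(0.5, 0.2, size=n))
    delta = rng.normal(0.0, cfg.shift_noise_sd, size=n)
    delta[shifted] = cfg.shift_size
    long_ab = rng.uniform(2.0, 10.0, size=n)
    rows = []
    cond_of_sample = {}
    for cond, ratios in (("wt", base_ratio), ("mut", np.maximum(base_ratio + delta, 0.0))):
        for r in range(cfg.n_replicates):
            sample = f"{cond}_{r + 1}"
            cond_of_sample[sample] = cond
            noise_l = rng.normal(1.0, 0.02, size=n)
            noise_s = rng.normal(1.0, 0.02, size=n)
            for i, g in enumerate(gene_ids):
                rows.append((f"{g}.t1", sample, long_ab[i] * noise_l[i]))
                rows.append((f"{g}.t1.short", sample, ratios[i] * long_ab[i] * noise_s[i]))
    abundance = pd.DataFrame(rows, columns=["transcript_id", "sample", "abundance"])
    pairing = pd.DataFrame({
        "gene_id": gene_ids,
        "short_tx": [f"{g}.t1.short" for g in gene_ids],
        "long_tx": [f"{g}.t1" for g in gene_ids],
    })
    return abundance, pairing, cond_of_sample, shifted_ids


# ---------------------------------------------------------------------------
# coordinate-genome tier


_BASES = np.array(list("ACGT"))


def simulate_genome(cfg: SimulationConfig) -> tuple[dict[str, str], GenomeAnnotation, pd.DataFrame]:
    """Random genome with genes, introns, TEs and an unmethylated control contig.

    Genes alternate strand and have three exons; a ``long_intron_fraction``
    of genes get a long (``long_intron_len``) second intron, the first of
    which is the planted heterochromatin-sensor intron.  Gene classes
    (gbM / teM / unmethylated) are planted in the truth table.  The
    control contig ``chrC`` stands in for the chloroplast.
    """
    rng = np.random.default_rng(cfg.seed)
    exon_lens = (300, 200, 300)
    short_intron, spacer = 150, 300
    genes: dict[str, GeneModel] = {}
    truth_rows = []
    tes = []
    pos = spacer
    n_long = max(1, round(cfg.n_genome_genes * cfg.long_intron_fraction))
    long_genes = set(rng.choice(cfg.n_genome_genes, size=n_long, replace=False))
    sensor_gene = min(long_genes)
    n_gbm = round(cfg.n_genome_genes * cfg.gbm_fraction)
    n_tem = round(cfg.n_genome_genes * cfg.tem_fraction)
    classes = np.array(["unmethylated"] * cfg.n_genome_genes, dtype=object)
    order = rng.permutation(cfg.n_genome_genes)
    classes[order[:n_gbm]] = "gbM"
    classes[order[n_gbm:n_gbm + n_tem]] = "teM"
    classes[sensor_gene] = "gbM"  # the sensor gene is a gbM gene with a methylated intron

    for i in range(cfg.n_genome_genes):
        intron2 = cfg.long_intron_len if i in long_genes else short_intron
        strand = "+" if i % 2 == 0 else "-"
        e1 = (pos, pos + exon_lens[0])
        e2 = (e1[1] + short_intron, e1[1] + short_intron + exon_lens[1])
        e3 = (e2[1] + intron2, e2[1] + intron2 + exon_lens[2])
        utr_len = 100
        if strand == "+":
            cds = [(e1[0] + utr_len, e1[1]), e2, (e3[0], e3[1] - utr_len)]
            utr5, utr3 = [(e1[0], e1[0] + utr_len)], [(e3[1] - utr_len, e3[1])]
        else:
            cds = [(e1[0] + utr_len, e1[1]), e2, (e3[0], e3[1] - utr_len)]
            utr5, utr3 = [(e3[1] - utr_len, e3[1])], [(e1[0], e1[0] + utr_len)]
        gid = f"gene{i:04d}"
        genes[gid] = GeneModel(gene_id=gid, chrom="chr1", strand=strand,
                               exons=[e1, e2, e3], cds=cds, utr5=utr5, utr3=utr3,
                               transcript_id=f"{gid}.t1")
        truth_rows.append((gid, classes[i], i in long_genes, i == sensor_gene))
        pos = e3[1] + spacer
        if i % 5 == 4:  # a TE between every fifth gene pair
            tes.append(("chr1", pos, pos + 400, "transposable_element"))
            pos += 400 + spacer
    chr1_len = pos + spacer
    chr1 = "".join(rng.choice(_BASES, size=chr1_len))
    chrc = "".join(rng.choice(_BASES, size=20_000))
    sequences = {"chr1": chr1, "chrC": chrc}
    annotation = GenomeAnnotation(
        genes=genes, te_features=tes,
        chrom_lengths={"chr1": chr1_len, "chrC": len(chrc)},
    )
    truth = pd.DataFrame(truth_rows, columns=["gene_id", "gene_class", "has_long_intron", "is_sensor"])
    return sequences, annotation, truth


def _cytosine_sites(seq: str, chrom: str) -> pd.DataFrame:
    """All cytosines on both strands with their own-strand trinucleotides."""
    arr = np.frombuffer(seq.upper().encode(), dtype="S1")
    rows = []
    plus = np.nonzero(arr == b"C")[0]
    minus = np.nonzero(arr == b"G")[0]
    comp = str.maketrans("ACGT", "TGCA")
    for i in plus:
        tri = seq[i:i + 3].upper()
        if len(tri) == 3 and all(b in "ACGT" for b in tri):
            rows.append((chrom, i + 1, "+", tri))
    for i in minus:
        if i >= 2:
            ref = seq[i - 2:i + 1].upper()
            if all(b in "ACGT" for b in ref):
                rows.append((chrom, i + 1, "-", ref.translate(comp)[::-1]))
    return pd.DataFrame(rows, columns=["chrom", "pos", "strand", "trinucleotide"])


def simulate_methylome(
    sequences: dict[str, str],
    annotation: GenomeAnnotation,
    truth: pd.DataFrame,
    cfg: SimulationConfig,
) -> pd.DataFrame:
    """Per-cytosine counts over a simulated genome (allc-shaped DataFrame).

    Compartment levels: gbM genes get ``gbm_cg_level`` mCG over their
    span; teM genes and TEs get TE-like levels in all contexts; the sensor
    gene's long intron gets ``sensor_intron_chg_level`` mCHG; everything
    else (and the whole control contig) sits at the unmethylated
    background.  The ``true_level`` column carries the planted level.
    """
    from .io import classify_context

    rng = np.random.default_rng(cfg.seed + 1)
    frames = []
    class_of = dict(zip(truth["gene_id"], truth["gene_class"]))
    sensor_ivs = []
    for rec in truth[truth["is_sensor"]].itertuples():
        g = annotation.genes[rec.gene_id]
        longest = max(g.introns, key=lambda iv: iv[1] - iv[0])
        sensor_ivs.append((g.chrom, longest[0], longest[1]))
    for chrom, seq in sequences.items():
        sites = _cytosine_sites(seq, chrom)
        ctx = sites["trinucleotide"].map(lambda t: classify_context(t)[0]).to_numpy()
        level = np.zeros(len(sites))
        cidx = {"CG": 0, "CHG": 1, "CHH": 2}
        lv_bg = np.array([cfg.background_cg_level, cfg.chg_level, cfg.chh_level])
        lv_gbm = np.array([cfg.gbm_cg_level, cfg.chg_level, cfg.chh_level])
        lv_te = np.array([cfg.te_cg_level, cfg.te_chg_level, cfg.te_chh_level])
        ctx_i = np.array([cidx[c] for c in ctx])
        level[:] = lv_bg[ctx_i]
        if chrom != "chrC":
            pos0 = sites["pos"].to_numpy() - 1
            for g in annotation.genes.values():
                if g.chrom != chrom:
                    continue
                m = (pos0 >= g.start) & (pos0 < g.end)
                gene_class = class_of[g.gene_id]
                if gene_class == "gbM":
                    level[m] = lv_gbm[ctx_i[m]]
                elif gene_class == "teM":
                    level[m] = lv_te[ctx_i[m]]
            for c, s, e, _ in annotation.te_features:
                if c != chrom:
                    continue
                m = (pos0 >= s) & (pos0 < e)
                level[m] = lv_te[ctx_i[m]]
            for c, s, e in sensor_ivs:
                if c != chrom:
                    continue
                m = (pos0 >= s) & (pos0 < e)
                sensor_lv = np.array([cfg.gbm_cg_level, cfg.sensor_intron_chg_level, cfg.chh_level])
                level[m] = sensor_lv[ctx_i[m]]
        else:
            level[:] = 0.0  # unmethylated control
        mc, cov = _counts(rng, len(sites), cfg.depth, level, cfg.p0)
        sites["mc"] = mc
        sites["cov"] = cov
        sites["called"] = None
        sites["context_class"] = ctx
        sites["subcontext"] = sites["trinucleotide"].map(lambda t: classify_context(t)[1])
        sites["true_level"] = level
        frames.append(sites)
    return pd.concat(frames, ignore_index=True)


def write_fasta(sequences: dict[str, str], path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def write_gff(annotation: GenomeAnnotation, path) -> None:
    """Write the annotation as GFF3 (1-based inclusive)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in annotation.genes.values():
            tx = g.transcript_id or f"{g.gene_id}.t1"
            fh.write(f"{g.chrom}\t.\tgene\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\tID={g.gene_id}\n")
            fh.write(f"{g.chrom}\t.\tmRNA\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\tID={tx};Parent={g.gene_id}\n")
            for kind, ivs in (("exon", g.exons), ("CDS", g.cds),
                              ("five_prime_UTR", g.utr5), ("three_prime_UTR", g.utr3)):
                for j, (s, e) in enumerate(ivs, 1):
                    fh.write(f"{g.chrom}\t.\t{kind}\t{s + 1}\t{e}\t.\t{g.strand}\t.\t"
                             f"ID={tx}.{kind}{j};Parent={tx}\n")
        for c, s, e, kind in annotation.te_features:
            fh.write(f"{c}\t.\t{kind}\t{s + 1}\t{e}\t.\t+\t.\tID=te_{c}_{s}\n")
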