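# Methods

## Site-level methylation calls

Bisulfite conversion leaves a residual error: a fraction *p₀* of truly
unmethylated cytosines read as methylated. *p₀* is estimated by pooling
counts over every cytosine of one or more unmethylated control sequences
(chloroplast or lambda), `p₀ = Σmc / Σcov`, pooled rather than averaged per
sequence so depth weights the estimate. When a finite control shows zero
non-conversion, *p₀* is floored at 1e-4 (configurable) so downstream
p-values are never degenerate zeros. A control rate above 0.5 triggers a
warning (mislabelled control).

Each cytosine with coverage ≥ 3 reads (`min_cov`, default 3) is tested
with the exact upper-tail binomial `P(X ≥ mc | n = cov, p = p₀)`
(`scipy.stats.binom.sf`). Sites below the coverage floor are retained with
the call unset so coverage-eligibility rules downstream can still count
them. p-values are Benjamini–Hochberg adjusted and a site is called
methylated at *q* < α (default 0.05).

**FDR families.** Site-level BH runs separately within each context class
(CG, CHG, CHH) because their background rates differ by orders of
magnitude; a pooled mode is available (`stratify_by_context=False`).
Whether the original population analyses corrected site-level tests is not
derivable from their description, so the choice is explicit in the API and
recorded in pipeline logs.

## Gene classification (gbM)

For each gene, methylated and total cytosines per context are counted over
the CDS of the *primary transcript* — defined here as the mRNA with the
longest spliced length, ties broken by lexicographically smallest
transcript id. Both strands count. The species background per context is
the pooled fraction of called-methylated among eligible sites across all
CDS; each gene's counts are then tested with the same upper-tail binomial
against that background and BH-adjusted per context across genes (the BH
family is the coverage-eligible genes of one sample).

Label rules, with the standard constants:

- *unclassified* unless ≥ 40% of the gene's CG sites have ≥ 3 reads;
- *gbM* iff reads map to ≥ 20 CG sites (interpreted as ≥ 20 CG sites with
  ≥ 1 read; the 40%-at-3× rule is a separate filter, both apply), and
  *q*₍CG₎ < 0.05 and *q*₍CHG₎ > 0.95 and *q*₍CHH₎ > 0.95;
- otherwise *non-gbM*. A `tem_like` flag (*q*₍CHG₎ < 0.05) is annotated
  but not part of the label vocabulary.

Genes with coverage but zero eligible sites in a non-CG context get
*p* = 1 there (cannot reject the background), which keeps them inside the
BH family rather than dropping them. The gbM ratio divides gbM genes by
all non-unclassified genes and is reported missing (not 0) when no gene is
eligible.

## Intron mCHG enrichment

The intronic background is the pooled methylated/eligible ratio per
context over *all* introns of the annotation; the binomial test and BH
adjustment mirror the gene tests, with the BH family being the set of
introns screened in one invocation (the genome-wide ≥ 1 kb screen by
default, or a supplied list). An intron is *enriched* at *q*₍CHG₎ < 0.05.
Introns with zero eligible CHG sites are flagged untestable and excluded
from the family. Contexts absent from all introns get a NaN background and
are skipped rather than aborting the screen. CWG/CCG weighted levels are
reported alongside because CCG methylation carries a MET1 dependence that
can mask CMT3 loss. Results are ranked by (*q*₍CHG₎, −weighted mCHG) with a
stable sort, so identical introns tie deterministically.

The long-intron threshold is inclusive (≥ 1000 bp) by default with a
strict (>) switch, since both conventions appear in practice. Intron
indices are 1-based in transcript orientation, so "the 7th intron" of a
minus-strand gene counts from its 5′ end.

## Population ectopic scan

The accession panel is a long table of per-accession gene classifications.
A gene's population gbM frequency is the fraction of accessions calling it
gbM among those where it is classified — coverage-failed accessions leave
the denominator, since a missing classification is not evidence against
gbM. A gene is ectopic in an accession when (*q*₍CHG₎ < 0.05 or
*q*₍CHH₎ < 0.05) and its gbM frequency exceeds 0.90 strictly. Accessions
are flagged ibm1-like at n_ectopic > 120 (strict by default; a ≥ reading
is available because both appear in common usage). mCHG-gain comparisons
between paired samples list genes whose CDS weighted mCHG rises by
strictly more than 0.02, with candidates defaulting to the reference
sample's gbM genes. The sensor-coupling table joins per-accession ectopic
counts, sensor-intron mCHG, expression and isoform ratio, and computes
Spearman correlations on the subset with sensor mCHG ≤ 0.035 — the
low-methylation range where the sensor responds approximately linearly.

## CWG symmetry

Palindromic CWG/CWG pairs are located from the genome sequence; a pair
enters the analysis when both strands have ≥ 3 reads and the pair carries
at least one methylated read. Strand calls reuse the binomial test with BH
across all strands of the pair set. Classes partition included pairs:
symmetric (both called), plus_only / minus_only, neither. A record whose
trinucleotide contradicts the reference raises an error rather than being
silently dropped.

## Metaplots

Windows are an equal-width real-valued partition: 20 windows over the
body, 20 over each 1 kb flank, a site belonging to the half-open window
containing its position; minus-strand features are reversed so window 0 is
always the distal 5′ flank. Two summaries are computed per window: pooled
counts (Σmc/Σcov over all features — the coverage-weighted mean of the 20
body windows then equals the whole-body weighted level exactly) and the
per-feature mean of window levels (the default `level` column, matching
the convention of averaging each gene's window value across genes).
Features shorter than the window count are skipped and counted in the log.

## Population genetics

Haplotypes are haploid (inbred accessions). S counts sites with ≥ 2
alleles among non-missing genotypes. π is the mean pairwise difference
count over all C(n,2) haplotype pairs, counted pairwise-complete: a pair
contributes at a site only when both members are genotyped (for biallelic
0/1 data this is Σₛ kₛ(mₛ−kₛ)/C(n,2)). D uses the standard constants
(a₁…e₂) with the full sample size n; D is reported missing at S = 0 and
n < 4 is an error. SNP density is S/L with L the full surveyed span of the
region class (a genotyped-sites denominator is the documented alternative).
Pairwise divergence between two aligned sequences is 1 − identical/compared
per region class, columns with a gap in either sequence excluded from both
numerator and denominator.

## Truncated transcripts and isoform ratios

The short-isoform reference is the concatenated exonic sequence strictly
5′ of the target intron, in mRNA orientation — by construction a prefix of
the full spliced transcript; the intron's first base is excluded. Introns
positioned 5′ of all CDS produce a UTR-only short transcript with a
warning. Abundances are averaged across replicates per condition before
the short/long ratio is taken; a zero long-isoform average leaves the
ratio missing rather than infinite. Ratio-shift genes satisfy
ratio(mutant) − ratio(wild type) > 2, an arithmetic difference, not a fold
change.

## Synthetic data

The count model at every cytosine is cov ~ Poisson(depth),
mc ~ Binomial(cov, level + (1 − level)·p₀), which folds non-conversion
into the observed probability so the caller's null is exactly correct at
level 0. Default study conditions: 30 CG / 30 CHG / 20 CHH sites per gene,
depth 10, p₀ = 0.005, gbM CG level 0.8 against a 0.02 CG background and
~0.01 non-CG background; panels of 50 accessions × 2,000 genes with 30%
gbM, 5 ibm1-like accessions carrying ectopic mCHG (level 0.3) in 150 gbM
genes each and 10 background-ectopic genes elsewhere; sensor-intron mCHG
0.12, reduced 5-fold in ibm1-like accessions with ±30% per-accession
jitter. Gene counts and planted fractions are exact (round(n·f)), so ratio
recovery is tested against a known denominator.

Two tiers exist deliberately. The gene-site tier keys counts by gene and
skips coordinates, which is what classifier- and panel-scale statistics
need; `gene_sites_to_allc` lays the same counts onto deterministic
coordinates when the file-facing path is wanted. The coordinate tier
builds a FASTA + GFF3 genome (three-exon genes, alternating strands,
planted long introns, TEs, a gbM/teM/unmethylated gene-class mix, an
unmethylated control contig) and derives every cytosine from the actual
sequence, exercising I/O, interval assignment and strand handling
end-to-end.

CWG regimes: *coupled* gives both strands one shared per-site level — the
CMT3-maintained case; *independent* methylates each strand independently
with probability equal to the level parameter (methylated strands read at
0.8) — the CMT3-absent case where a fixed common level would not decouple
the strands. SNP matrices draw derived-allele counts from the neutral-like
spectrum P(i) ∝ 1/i, anchoring Tajima's D near zero so departures are
attributable to the region-dependent rates being tested.

What the generators do not emulate: linkage and genealogy (sites are
independent), sequence composition biases and mappability, TE sequence
evolution, overdispersed coverage, partial methylation heterogeneity
within compartments, and read-level artifacts. Passing recovery tests
therefore demonstrates the statistical machinery under its stated model,
not robustness to those real-data effects.

## Problem sizes and numerics

The validation suite uses 2,000-gene methylomes (10 replicate seeds × 3
planted fractions), 50-accession panels (10 seeds), 1e5-site null
methylomes, 20 null-intron replicates, 5,000-pair symmetry tables and
100-matrix popgen oracle sweeps; `scripts/acceptance.py` reruns the same
analyses at 5 seeds per recovery block. Oracle agreement is required to
1e-10 (binomial tail), 1e-12 (BH) and 1e-9 (Tajima's D). All internal
intervals are 0-based half-open with conversion only at I/O boundaries;
BH is `statsmodels.stats.multitest.multipletests(method="fdr_bh")`, with
independent brute-force implementations living in the tests and the
acceptance script.

## Known limitations

No beta-binomial overdispersion at the site level; no differential
methylation tests between samples beyond the mCHG-gain rule; no
genotype-aware exclusion of deleted regions in the panel scan; the
minimal VCF/TSV genotype reader assumes biallelic sites; plotting is left
to the caller (outputs are tidy tables).
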