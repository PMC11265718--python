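"""End-to-end pipeline over a synthetic genome: simulate -> call -> classify
-> intron screen -> symmetry -> popgen -> isoform ratios.

Every stage writes a TSV into the output directory and the headline
numbers land in ``summary.json`` (schema_version 1).  Thresholds in use
are logged as machine-readable key=value lines so a run can be audited
against the defaults.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import numpy as np

from . import calling, genes, introns, isoforms, popgen, profiles
from .simulate import (SimulationConfig, simulate_abundance, simulate_genome,
                       simulate_methylome, simulate_snp_matrix, write_fasta, write_gff)
from .io import write_allc

log = logging.getLogger(__name__)

SCHEMA_VERSION = 1


@dataclasses.dataclass
class RunConfig:
    """Pipeline thresholds (defaults are the analysis' standard values)."""

    simulation: SimulationConfig = dataclasses.field(default_factory=SimulationConfig)
    alpha: float = 0.05
    min_cov: int = 3
    q_lo: float = 0.05
    q_hi: float = 0.95
    min_cg: int = 20
    min_cov_frac: float = 0.40
    min_intron_len: int = 1000
    q_enrich: float = 0.05
    shift_delta: float = 2.0
    write_inputs: bool = True

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        sim = SimulationConfig(**d.pop("simulation", {}))
        return cls(simulation=sim, **d)


def run_pipeline(config: RunConfig, outdir: str | Path) -> dict:
    """Run every stage on one synthetic genome; returns the summary dict."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    cfg = config.simulation
    for key in ("alpha", "min_cov", "q_lo", "q_hi", "min_cg", "min_cov_frac",
                "min_intron_len", "q_enrich", "shift_delta"):
        log.info("threshold %s=%s", key, getattr(config, key))

    def stage(name):
        log.info("stage=%s", name)

    try:
        stage("simulate")
        sequences, annotation, truth = simulate_genome(cfg)
        allc = simulate_methylome(sequences, annotation, truth, cfg)
        if config.write_inputs:
            write_fasta(sequences, out / "genome.fa")
            write_gff(annotation, out / "annotation.gff3")
            write_allc(allc.drop(columns=["true_level"]), out / "methylome.allc")
            truth.to_csv(out / "truth_genes.tsv", sep="\t", index=False)
    except Exception as exc:
        raise RuntimeError(f"stage 'simulate' failed: {exc}") from exc

    try:
        stage("call")
        control = calling.estimate_nonconversion(allc, ["chrC"])
        called = calling.call_methylome(allc, control, alpha=config.alpha, min_cov=config.min_cov)
    except Exception as exc:
        raise RuntimeError(f"stage 'call' failed: {exc}") from exc

    try:
        stage("classify")
        cds_sites = genes.assign_cds_sites(called, annotation)
        summaries = genes.summarize_genes(cds_sites, min_cov=config.min_cov)
        classified = genes.classify_genes(
            summaries, q_lo=config.q_lo, q_hi=config.q_hi,
            min_cg=config.min_cg, min_cov_frac=config.min_cov_frac,
        )
        classified.to_csv(out / "genes.tsv", sep="\t")
        ratio = genes.gbm_ratio(classified)
    except Exception as exc:
        raise RuntimeError(f"stage 'classify' failed: {exc}") from exc

    try:
        stage("intron-screen")
        screen = introns.screen_sensor_candidates(
            annotation, called, min_len=config.min_intron_len,
            q_enrich=config.q_enrich, min_cov=config.min_cov,
        )
        screen.to_csv(out / "intron_tests.tsv", sep="\t", index=False)
        enriched = screen[screen["enriched"]] if len(screen) else screen
    except Exception as exc:
        raise RuntimeError(f"stage 'intron-screen' failed: {exc}") from exc

    try:
        stage("symmetry")
        chg_called = called[called["chrom"] == "chr1"]
        pairs = profiles.pair_cwg_sites(chg_called, sequences, min_cov=config.min_cov)
        pair_table, symmetry = profiles.symmetry_summary(pairs, p0=control.rate, alpha=config.alpha)
        symmetry.to_csv(out / "symmetry.tsv", sep="\t", index=False)
    except Exception as exc:
        raise RuntimeError(f"stage 'symmetry' failed: {exc}") from exc

    try:
        stage("popgen")
        matrix, partition, _ = simulate_snp_matrix(cfg)
        pop_rows = []
        for cls in partition.regions:
            st = popgen.tajimas_d(matrix, partition, cls)
            pop_rows.append({"region_class": cls, "L": st.L, "S": st.S, "pi": st.pi,
                             "snp_density": st.snp_density, "tajimas_d": st.D})
        import pandas as pd
        pd.DataFrame(pop_rows).to_csv(out / "popgen.tsv", sep="\t", index=False)
    except Exception as exc:
        raise RuntimeError(f"stage 'popgen' failed: {exc}") from exc

    try:
        stage("isoform")
        abundance, pairing, cond_of, shifted = simulate_abundance(cfg)
        ratios = isoforms.isoform_ratio(abundance, pairing, cond_of)
        ratios.to_csv(out / "isoform_ratios.tsv", sep="\t", index=False)
        wt = ratios[ratios["condition"] == "wt"]
        mut = ratios[ratios["condition"] == "mut"]
        shift_hits = isoforms.ratio_shift_genes(wt, mut, delta=config.shift_delta)
    except Exception as exc:
        raise RuntimeError(f"stage 'isoform' failed: {exc}") from exc

    summary = {
        "schema_version": SCHEMA_VERSION,
        "seed": cfg.seed,
        "nonconversion_rate": control.rate,
        "n_genes": int(len(classified)),
        "gbm_ratio": None if np.isnan(ratio) else float(ratio),
        "n_gbm": int((classified["label"] == "gbM").sum()),
        "n_long_introns": int(len(screen)),
        "n_enriched_introns": int(len(enriched)),
        "enriched_introns": [f"{r.gene_id}.intron{r.intron_index}" for r in enriched.itertuples()],
        "symmetry_fractions": dict(zip(symmetry["symmetry_class"], symmetry["fraction"])),
        "n_cwg_pairs": int(len(pair_table)),
        "popgen": pop_rows,
        "n_ratio_shift_genes": len(shift_hits),
    }
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, default=float)
    return summary
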