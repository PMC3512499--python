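"""End-to-end train -> classify -> smooth pipeline over files on disk."""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from . import hmm_smoothing as hmm
from . import svm_ancestry as svm
from .haplotype_io import (
    GeneticMap,
    HaplotypePanel,
    WindowPartition,
    encode_major_minor,
    fixed_rate_map,
    partition_windows,
    read_genetic_map,
    read_phased_panel,
    write_partition_bed,
)
from .hmm_smoothing import AncestryCall

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline", "write_calls_bed", "read_calls_bed",
           "intersect_panels"]


@dataclass
class RunConfig:
    """All user-facing parameters of one inference run."""

    ancestral_vcf: str
    query_vcf: str
    pop_table: str
    out_dir: str
    genetic_map: str | None = None
    fixed_rate_cM_per_Mb: float | None = None
    w: int = 100
    g: float = 5.0
    C: float = 1.0
    seed: int = 0
    subsample_per_pop: int | None = None
    write_posteriors: bool = True

    def __post_init__(self) -> None:
        if self.w < 1:
            raise ValueError("window size w must be >= 1")
        if self.g <= 0:
            raise ValueError("generations g must be positive")
        if self.C <= 0:
            raise ValueError("penalty C must be positive")
        if (self.genetic_map is None) == (self.fixed_rate_cM_per_Mb is None):
            raise ValueError(
                "exactly one of genetic_map and fixed_rate_cM_per_Mb required")


def intersect_panels(ancestral: HaplotypePanel, query: HaplotypePanel
                     ) -> tuple[HaplotypePanel, HaplotypePanel]:
    """Restrict both panels to shared SNPs, in the ancestral column order."""
    qpos = {sid: j for j, sid in enumerate(query.snp_ids)}
    anc_cols = [j for j, sid in enumerate(ancestral.snp_ids) if sid in qpos]
    if not anc_cols:
        raise ValueError("ancestral and query panels share no SNPs")
    qry_cols = [qpos[ancestral.snp_ids[j]] for j in anc_cols]
    return ancestral.take_columns(anc_cols), query.take_columns(qry_cols)


def _subsample(panel: HaplotypePanel, per_pop: int, seed: int) -> HaplotypePanel:
    rng = np.random.default_rng(seed)
    keep: list[int] = []
    for name in panel.population_names:
        rows = panel.rows_for_population(name)
        if len(rows) > per_pop:
            rows = np.sort(rng.choice(rows, size=per_pop, replace=False))
        keep.extend(rows.tolist())
    return panel.take_rows(sorted(keep))


def write_calls_bed(calls: list[AncestryCall], partition: WindowPartition,
                    panel: HaplotypePanel, path: str | Path) -> None:
    """Write per-haplotype window calls as BED-like TSV."""
    rows = []
    for call in calls:
        names = call.population_names
        for j, win in enumerate(partition.windows):
            label = int(call.labels[j])
            rows.append({
                "chrom": win.chrom,
                "window_start_bp": int(panel.bp_pos[win.start]),
                "window_end_bp": int(panel.bp_pos[win.end - 1]),
                "haplotype_id": call.haplotype_id,
                "called_population": names[label - 1] if names else str(label),
                "max_posterior": f"{call.posterior[j, label - 1]:.6f}",
            })
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_calls_bed(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"chrom": str})


def _checksum(path: str) -> str:
    h = hashlib.md5()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Run the full two-level inference and write call files + manifest.

    Stages: read panels, intersect SNPs, encode alleles against the
    ancestral panel, annotate genetic positions, partition into windows,
    train per-window SVM ensembles with cross-validated success rates,
    classify the query windows, smooth with the HMM, and serialize calls,
    posteriors, the window partition, and a reproducibility manifest.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    logger.info("reading ancestral panel %s", config.ancestral_vcf)
    ancestral = read_phased_panel(config.ancestral_vcf, config.pop_table)
    logger.info("reading query panel %s", config.query_vcf)
    query = read_phased_panel(config.query_vcf)

    ancestral, query = intersect_panels(ancestral, query)
    logger.info("%d shared SNPs after intersection", ancestral.n_snps)

    if config.subsample_per_pop is not None:
        ancestral = _subsample(ancestral, config.subsample_per_pop, config.seed)

    # joint encoding: ancestral panel defines major/minor polarity
    n_anc = ancestral.n_haplotypes
    stacked = np.vstack([ancestral.alleles, query.alleles])
    encoded = encode_major_minor(stacked, np.arange(n_anc))
    ancestral.alleles = encoded[:n_anc]
    ancestral.encoded = True
    query.alleles = encoded[n_anc:]
    query.encoded = True

    gmap: GeneticMap = (read_genetic_map(config.genetic_map)
                        if config.genetic_map is not None
                        else fixed_rate_map(config.fixed_rate_cM_per_Mb))
    ancestral.annotate_genetic_positions(gmap)
    query.gen_pos = ancestral.gen_pos

    partition = partition_windows(ancestral, config.w)
    logger.info("training %d window ensembles (k'=%d)", partition.n_windows,
                ancestral.n_populations)
    ensembles = svm.train_window_ensemble(ancestral, partition,
                                          C=config.C, cv_seed=config.seed)
    rates = [e.success_rate for e in ensembles]
    logger.info("cross-validated success rate: mean %.3f, min %.3f "
                "(low values suggest increasing w)",
                float(np.mean(rates)), float(np.min(rates)))

    svm.check_alignment(ancestral, query)
    raw = svm.classify_panel(ensembles, query, partition)
    calls = hmm.smooth_panel(raw, rates, partition, config.g,
                             k_prime=ancestral.n_populations,
                             haplotype_ids=list(query.sample_ids),
                             population_names=ancestral.population_names)

    calls_path = out / "calls.bed"
    write_calls_bed(calls, partition, ancestral, calls_path)
    write_partition_bed(partition, ancestral, out / "windows.bed")
    svm.save_ensembles(ensembles, out / "ensembles.json", window_size=config.w)
    if config.write_posteriors:
        post = np.vstack([c.posterior for c in calls])
        hap_col = np.repeat([c.haplotype_id for c in calls],
                            partition.n_windows)
        df = pd.DataFrame(post, columns=ancestral.population_names)
        df.insert(0, "window_index",
                  np.tile(np.arange(partition.n_windows), len(calls)))
        df.insert(0, "haplotype_id", hap_col)
        df.to_csv(out / "posteriors.tsv", sep="\t", index=False,
                  float_format="%.6g")

    manifest = {
        "version": __version__,
        "parameters": {
            "w": config.w, "g": config.g, "C": config.C, "seed": config.seed,
            "subsample_per_pop": config.subsample_per_pop,
            "fixed_rate_cM_per_Mb": config.fixed_rate_cM_per_Mb,
        },
        "inputs": {
            "ancestral_vcf": {"path": config.ancestral_vcf,
                              "md5": _checksum(config.ancestral_vcf)},
            "query_vcf": {"path": config.query_vcf,
                          "md5": _checksum(config.query_vcf)},
            "pop_table": {"path": config.pop_table,
                          "md5": _checksum(config.pop_table)},
            "genetic_map": None if config.genetic_map is None else {
                "path": config.genetic_map,
                "md5": _checksum(config.genetic_map)},
        },
        "n_shared_snps": ancestral.n_snps,
        "n_windows": partition.n_windows,
        "populations": ancestral.population_names,
        "mean_success_rate": float(np.mean(rates)),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
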