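"""End-to-end orchestration: QC -> additive scan -> independence screen ->
pair screen -> exact tests -> conditional tests -> significance calls ->
replication, with audit logging of every filtered record."""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import yaml

from . import additive_scan, exact_epistasis, genotype_io, pair_screen
from .additive_scan import AdditiveBackground, AdditiveHit, MarkerQC
from .exact_epistasis import EpistasisResult, SignificanceCall
from .genotype_io import CohortTable, GenotypeMatrix
from .pair_screen import PairCandidate

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    bfile: str = ""
    covar: str = ""
    replication_bfile: str = ""
    replication_covar: str = ""
    out_dir: str = "episcan_out"
    entry_p: float = 5e-8
    keep_p: float = 0.05
    screen_p: float = 1e-10
    screen_r2: float = 0.2
    genome_wide_p: float = 1e-13
    chip_wide_p: float = 1.1e-8
    replication_p: float = 0.05
    hwe_p: float = 1e-6
    maf: float = 1e-5
    mhc_chrom: str = "6"
    mhc_start: int = 28_700_000
    mhc_end: int = 34_000_000
    reuse_discovery_background: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("entry_p", "keep_p", "screen_p", "screen_r2",
                     "genome_wide_p", "chip_wide_p", "replication_p",
                     "hwe_p", "maf"):
            if getattr(self, name) < 0:
                raise ValueError(f"threshold {name} must be non-negative")
        if self.genome_wide_p > self.chip_wide_p:
            raise ValueError("genome-wide threshold must not exceed chip-wide")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        bad = set(raw) - known
        if bad:
            raise ValueError(f"unknown config keys: {sorted(bad)}")
        return cls(**raw)


@dataclass
class DiscoveryOutput:
    qc_report: list[MarkerQC]
    hits: list[AdditiveHit]
    background: AdditiveBackground
    candidates: list[PairCandidate]
    results: list[EpistasisResult]
    calls: list[SignificanceCall]
    significant: list[EpistasisResult]
    counts: dict[str, int] = field(default_factory=dict)


def in_mhc(genotypes: GenotypeMatrix, marker: str, config: RunConfig) -> bool:
    j = genotypes.marker_index(marker)
    row = genotypes.markers.iloc[j]
    return (str(row["chrom"]) == str(config.mhc_chrom)
            and config.mhc_start <= int(row["pos"]) <= config.mhc_end)


def run_discovery(
    genotypes: GenotypeMatrix, cohort: CohortTable, config: RunConfig
) -> DiscoveryOutput:
    """Full discovery-cohort protocol; stage counts are logged in protocol
    order (markers after QC, genome-wide markers, independent markers,
    screened pairs, significant pairs)."""
    gm, qc_report = additive_scan.qc_filter(
        genotypes, hwe_threshold=config.hwe_p, maf_threshold=config.maf
    )
    log.info("QC: %d of %d markers retained", gm.n_markers, genotypes.n_markers)

    hits = additive_scan.single_snp_scan(gm, cohort)
    n_gw = sum(1 for h in hits if h.testable and h.p < config.entry_p)
    log.info("scan: %d genome-wide significant markers (P < %g)", n_gw, config.entry_p)

    background = additive_scan.independence_screen(
        hits, gm, cohort, entry_threshold=config.entry_p,
        keep_threshold=config.keep_p,
    )
    log.info("independence screen: %d independent markers", len(background))

    candidates = pair_screen.screen_all_pairs(
        gm, cohort, p_threshold=config.screen_p, r2_threshold=config.screen_r2
    )
    log.info("pair screen: %d candidate pairs", len(candidates))

    results = [
        exact_epistasis.test_pair(gm, cohort, (c.snp1, c.snp2),
                                  background.markers, cohort_label="discovery")
        for c in candidates
    ]
    calls = exact_epistasis.call_significance(
        results, genome_wide_p=config.genome_wide_p,
        chip_wide_p=config.chip_wide_p,
    )
    significant = [r for r, c in zip(results, calls) if c.chip_wide]
    log.info("exact stage: %d significant pairs (conditional P < %g)",
             len(significant), config.chip_wide_p)

    counts = {
        "markers_input": genotypes.n_markers,
        "markers_after_qc": gm.n_markers,
        "genome_wide_markers": n_gw,
        "independent_markers": len(background),
        "candidate_pairs": len(candidates),
        "significant_pairs": len(significant),
    }
    return DiscoveryOutput(qc_report, hits, background, candidates, results,
                           calls, significant, counts)


def _scan_p(hits: Sequence[AdditiveHit], marker: str) -> float:
    for h in hits:
        if h.marker == marker:
            return h.p
    return math.nan


def run_replication(
    discovery: DiscoveryOutput,
    discovery_genotypes: GenotypeMatrix,
    rep_genotypes: GenotypeMatrix,
    rep_cohort: CohortTable,
    config: RunConfig,
) -> list[dict]:
    """Re-test the discovery-significant pairs in the replication cohort and
    assemble the combined per-pair report (results-TSV dialect rows)."""
    overlap = set(discovery_genotypes.samples) & set(rep_genotypes.samples)
    if overlap:
        raise ValueError(
            f"replication cohort shares {len(overlap)} samples with discovery"
        )
    rep_gm, _ = additive_scan.qc_filter(
        rep_genotypes, hwe_threshold=config.hwe_p, maf_threshold=config.maf
    )
    rep_hits = additive_scan.single_snp_scan(rep_gm, rep_cohort)
    if config.reuse_discovery_background:
        rep_background = AdditiveBackground(
            [m for m in discovery.background.markers if m in set(rep_gm.marker_ids)],
            dict(discovery.background.joint_p),
        )
    else:
        rep_background = additive_scan.independence_screen(
            rep_hits, rep_gm, rep_cohort,
            entry_threshold=config.entry_p, keep_threshold=config.keep_p,
        )

    pairs = [(r.snp1, r.snp2) for r in discovery.significant]
    testable = [p for p in pairs
                if p[0] in set(rep_gm.marker_ids) and p[1] in set(rep_gm.marker_ids)]
    rep_results = exact_epistasis.replicate(
        testable, rep_gm, rep_cohort, rep_background.markers,
        replication_p=config.replication_p,
    )
    rep_by_pair = {(r.snp1, r.snp2): (r, flag) for r, flag in rep_results}

    report = []
    disc_hits = {h.marker: h for h in discovery.hits}
    for res in discovery.significant:
        pair = (res.snp1, res.snp2)
        row: dict = {
            "SNP1": res.snp1,
            "Pos1": int(discovery_genotypes.markers.iloc[
                discovery_genotypes.marker_index(res.snp1)]["pos"]),
            "Gene1": "",
            "SNP2": res.snp2,
            "Pos2": int(discovery_genotypes.markers.iloc[
                discovery_genotypes.marker_index(res.snp2)]["pos"]),
            "Gene2": "",
            "LD": pair_screen.dosage_r2(discovery_genotypes, res.snp1, res.snp2),
            "P_SNP1": disc_hits[res.snp1].p if res.snp1 in disc_hits else math.nan,
            "P_SNP2": disc_hits[res.snp2].p if res.snp2 in disc_hits else math.nan,
            "P_SNP1xSNP2": res.p,
            "P_SNP1xSNP2_Cond": res.cond_p,
            "InMHC": (in_mhc(discovery_genotypes, res.snp1, config)
                      and in_mhc(discovery_genotypes, res.snp2, config)),
        }
        if pair in rep_by_pair:
            rep_res, flag = rep_by_pair[pair]
            row.update({
                "P_SNP1_rep": _scan_p(rep_hits, res.snp1),
                "P_SNP2_rep": _scan_p(rep_hits, res.snp2),
                "P_SNP1xSNP2_rep": rep_res.p,
                "P_SNP1xSNP2_Cond_rep": rep_res.cond_p,
                "Replicated": flag,
            })
        else:
            row.update({
                "P_SNP1_rep": math.nan, "P_SNP2_rep": math.nan,
                "P_SNP1xSNP2_rep": math.nan, "P_SNP1xSNP2_Cond_rep": math.nan,
                "Replicated": False,
            })
        report.append(row)
    return report


def write_discovery_outputs(out_dir: str | Path, disc: DiscoveryOutput) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "qc_report.tsv", "w") as fh:
        fh.write("marker\thwe_p\tmaf\tpassed\treasons\n")
        for q in disc.qc_report:
            fh.write(f"{q.marker}\t{q.hwe_p:.4g}\t{q.maf:.6g}\t"
                     f"{int(q.passed)}\t{','.join(q.reasons)}\n")
    with open(out / "scan.tsv", "w") as fh:
        fh.write("marker\tbeta\tse\tp\tn\tflag\n")
        for h in disc.hits:
            fh.write(f"{h.marker}\t{h.beta:.6g}\t{h.se:.6g}\t{h.p:.4E}\t"
                     f"{h.n}\t{h.flag}\n")
    with open(out / "background.tsv", "w") as fh:
        fh.write("marker\tjoint_p\n")
        for m in disc.background.markers:
            fh.write(f"{m}\t{disc.background.joint_p[m]:.4E}\n")
    with open(out / "background_dropped.tsv", "w") as fh:
        fh.write("marker\treason\n")
        for m, reason in disc.background.dropped:
            fh.write(f"{m}\t{reason}\n")
    with open(out / "candidates.tsv", "w") as fh:
        fh.write("snp1\tsnp2\tstatistic\tp\tr2\n")
        for c in disc.candidates:
            fh.write(f"{c.snp1}\t{c.snp2}\t{c.statistic:.6g}\t"
                     f"{c.p:.4E}\t{c.r2:.4f}\n")
    (out / "counts.json").write_text(json.dumps(disc.counts, indent=1))


def run_full(config: RunConfig) -> list[dict]:
    """Load inputs per config, run discovery and replication, write outputs."""
    gm, fam = genotype_io.read_plink(config.bfile)
    cohort = genotype_io.read_covariates(config.covar, fam)
    disc = run_discovery(gm, cohort, config)
    write_discovery_outputs(config.out_dir, disc)

    if not config.replication_bfile:
        report = []
        disc_hits = {h.marker: h for h in disc.hits}
        for res in disc.significant:
            report.append({
                "SNP1": res.snp1, "SNP2": res.snp2,
                "Pos1": int(gm.markers.iloc[gm.marker_index(res.snp1)]["pos"]),
                "Pos2": int(gm.markers.iloc[gm.marker_index(res.snp2)]["pos"]),
                "Gene1": "", "Gene2": "",
                "LD": pair_screen.dosage_r2(gm, res.snp1, res.snp2),
                "P_SNP1": disc_hits[res.snp1].p,
                "P_SNP2": disc_hits[res.snp2].p,
                "P_SNP1xSNP2": res.p,
                "P_SNP1xSNP2_Cond": res.cond_p,
                "InMHC": (in_mhc(gm, res.snp1, config)
                          and in_mhc(gm, res.snp2, config)),
            })
    else:
        rep_gm, rep_fam = genotype_io.read_plink(config.replication_bfile)
        rep_cohort = genotype_io.read_covariates(config.replication_covar, rep_fam)
        report = run_replication(disc, gm, rep_gm, rep_cohort, config)

    genotype_io.write_results(report, Path(config.out_dir) / "results.tsv")
    return report
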