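"""Synthetic case-control cohorts with known additive and epistatic truth.

Genotypes are built from correlated latent Gaussian signals, two haplotypes
per sample, which gives exact Hardy-Weinberg marginals and tunable LD that
decays with distance inside each block.  Case status follows a logistic
model whose intercept is solved numerically so the realized case fraction
matches the requested design; cases and controls are then sampled
retrospectively from the simulated population.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit, ndtri

from . import genotype_io
from .genotype_io import CohortTable, GenotypeMatrix

_CHROM = "6"
_POS_START = 25_000_000
_POS_STEP = 10_000
_INTERCEPT_BOUND = 30.0


class SimulationError(RuntimeError):
    pass


@dataclass
class SimulationConfig:
    n_cases: int
    n_controls: int
    n_markers: int
    block_structure: list[tuple[int, float]] = field(default_factory=list)
    maf_range: tuple[float, float] = (0.05, 0.5)
    additive_effects: list[tuple[int, float]] = field(default_factory=list)
    epistatic_effects: list[tuple[tuple[int, int], np.ndarray]] = field(default_factory=list)
    n_batches: int = 1
    batch_effect_sd: float = 0.0
    n_subpops: int = 1
    fst_like_divergence: float = 0.0
    subpop_effect_sd: float = 0.0
    missing_rate: float = 0.0
    n_pcs: int = 5
    # (target, src1, src2): the target marker's allele on each haplotype is
    # the AND of the two source alleles, producing haplotype-driven LD with
    # both sources (the classic generator of pseudo-interactions at the
    # source pair when the target carries a main effect).
    haplotype_and_markers: list[tuple[int, int, int]] = field(default_factory=list)
    seed: int = 0

    def validate(self) -> None:
        if self.n_cases <= 0 or self.n_controls <= 0 or self.n_markers <= 0:
            raise ValueError("cohort and marker counts must be positive")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must lie in (0, 0.5]")
        if sum(l for l, _ in self.block_structure) > self.n_markers:
            raise ValueError("block lengths exceed n_markers")
        for _, rho in self.block_structure:
            if not 0.0 <= rho < 1.0:
                raise ValueError("block correlation must be in [0, 1)")
        for idx, _ in self.additive_effects:
            if not 0 <= idx < self.n_markers:
                raise ValueError(f"additive effect index {idx} out of range")
        for (i, j), mat in self.epistatic_effects:
            if i == j:
                raise ValueError("epistatic pair members must be distinct")
            if not (0 <= i < self.n_markers and 0 <= j < self.n_markers):
                raise ValueError(f"epistatic pair ({i},{j}) out of range")
            if np.asarray(mat).shape != (3, 3):
                raise ValueError("epistatic effect must be a 3x3 log-odds matrix")
        if not 0.0 <= self.missing_rate <= 0.1:
            raise ValueError("missing_rate must be in [0, 0.1]")
        if not 0.0 <= self.fst_like_divergence < 0.5:
            raise ValueError("fst_like_divergence must be in [0, 0.5)")
        if self.n_batches < 1 or self.n_subpops < 1:
            raise ValueError("need at least one batch and one subpopulation")
        for t, i, j in self.haplotype_and_markers:
            if len({t, i, j}) != 3:
                raise ValueError("haplotype AND marker indices must be distinct")
            for idx in (t, i, j):
                if not 0 <= idx < self.n_markers:
                    raise ValueError(f"haplotype AND index {idx} out of range")


@dataclass
class TruthRecord:
    additive: list[tuple[str, float]]
    epistatic: list[tuple[str, str, list[list[float]]]]
    intercept: float
    batch_labels: np.ndarray
    subpop_labels: np.ndarray
    batch_effects: np.ndarray
    subpop_effects: np.ndarray

    def to_json(self) -> str:
        d = asdict(self)
        for k in ("batch_labels", "subpop_labels", "batch_effects", "subpop_effects"):
            d[k] = np.asarray(d[k]).tolist()
        return json.dumps(d, indent=1)


def _block_rhos(config: SimulationConfig) -> np.ndarray:
    """Per-marker AR(1) correlation with the previous marker (0 at block starts)."""
    rho = np.zeros(config.n_markers)
    pos = 0
    for length, r in config.block_structure:
        rho[pos + 1: pos + length] = r
        pos += length
    return rho


def _simulate_haplotypes(
    rng: np.random.Generator, n: int, thresholds: np.ndarray, rho: np.ndarray,
    and_markers: Sequence[tuple[int, int, int]] = (),
) -> np.ndarray:
    """Dosage matrix from two latent AR(1) Gaussian haplotypes per sample.

    ``thresholds``: (n, m) per-sample latent thresholds (subpop-specific
    allele frequencies); allele present iff latent < threshold.  Entries of
    ``and_markers`` overwrite the target marker's allele with the AND of the
    two source alleles on the same haplotype.
    """
    m = rho.size
    dosage = np.zeros((n, m), dtype=np.int8)
    for _hap in range(2):
        z = np.empty((n, m))
        eps = rng.standard_normal((n, m))
        z[:, 0] = eps[:, 0]
        for j in range(1, m):
            z[:, j] = rho[j] * z[:, j - 1] + np.sqrt(1.0 - rho[j] ** 2) * eps[:, j]
        allele = z < thresholds
        for t, i, j in and_markers:
            allele[:, t] = allele[:, i] & allele[:, j]
        dosage += allele.astype(np.int8)
    return dosage


def compute_pcs(dosages: np.ndarray, k: int = 5) -> np.ndarray:
    """Top-k principal-component scores of the centered, scaled dosage
    matrix (missing calls mean-imputed), each standardized to unit variance."""
    X = dosages.astype(float)
    X[dosages < 0] = np.nan
    mean = np.nanmean(X, axis=0)
    inds = np.where(np.isnan(X))
    X[inds] = np.take(mean, inds[1])
    X -= mean
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    X /= sd
    u, s, _ = np.linalg.svd(X, full_matrices=False)
    k = min(k, (s > 1e-9).sum())
    pcs = u[:, :k] * s[:k]
    pcs /= pcs.std(axis=0)
    return pcs


def _risk_scores(dosage: np.ndarray, config: SimulationConfig,
                 batch_eff: np.ndarray, batch_labels: np.ndarray,
                 subpop_eff: np.ndarray, subpop_labels: np.ndarray) -> np.ndarray:
    risk = np.zeros(dosage.shape[0])
    for idx, beta in config.additive_effects:
        risk += beta * dosage[:, idx]
    for (i, j), mat in config.epistatic_effects:
        mat = np.asarray(mat, dtype=float)
        risk += mat[dosage[:, i], dosage[:, j]]
    risk += batch_eff[batch_labels]
    risk += subpop_eff[subpop_labels]
    return risk


def simulate_cohort(
    config: SimulationConfig,
) -> tuple[GenotypeMatrix, CohortTable, TruthRecord]:
    """Simulate a retrospective case-control cohort.

    A population pool larger than the requested cohort is generated; the
    logistic intercept is solved so the population case fraction equals
    n_cases / (n_cases + n_controls); the requested numbers of cases and
    controls are then drawn from the pool.  Identical config and seed give
    bit-identical output.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    total = config.n_cases + config.n_controls
    target = config.n_cases / total
    pool_n = int(total * 1.4) + 500
    m = config.n_markers

    lo, hi = config.maf_range
    p_anc = rng.uniform(lo, hi, size=m)
    F = config.fst_like_divergence
    if config.n_subpops > 1 and F > 0:
        c = (1.0 - F) / F
        p_sub = rng.beta(np.maximum(p_anc * c, 1e-3),
                         np.maximum((1.0 - p_anc) * c, 1e-3),
                         size=(config.n_subpops, m))
        p_sub = np.clip(p_sub, 1e-4, 1.0 - 1e-4)
    else:
        p_sub = np.tile(p_anc, (config.n_subpops, 1))

    subpop_labels = rng.integers(0, config.n_subpops, size=pool_n)
    batch_labels = rng.integers(0, config.n_batches, size=pool_n)
    batch_eff = (rng.normal(0.0, config.batch_effect_sd, size=config.n_batches)
                 if config.batch_effect_sd > 0 else np.zeros(config.n_batches))
    subpop_eff = (rng.normal(0.0, config.subpop_effect_sd, size=config.n_subpops)
                  if config.subpop_effect_sd > 0 else np.zeros(config.n_subpops))

    thresholds = ndtri(p_sub)[subpop_labels]  # (pool_n, m)
    rho = _block_rhos(config)
    dosage = _simulate_haplotypes(rng, pool_n, thresholds, rho,
                                  config.haplotype_and_markers)

    risk = _risk_scores(dosage, config, batch_eff, batch_labels,
                        subpop_eff, subpop_labels)

    def case_fraction(intercept: float) -> float:
        return float(expit(intercept + risk).mean()) - target

    b = _INTERCEPT_BOUND
    if case_fraction(-b) > 0 or case_fraction(b) < 0:
        raise SimulationError(
            f"cannot reach case fraction {target:.3f} with intercept in "
            f"[-{b}, {b}]: planted effects too extreme"
        )
    intercept = brentq(case_fraction, -b, b, xtol=1e-10)

    y_pool = (rng.uniform(size=pool_n) < expit(intercept + risk)).astype(np.int8)
    case_idx = np.flatnonzero(y_pool == 1)
    ctrl_idx = np.flatnonzero(y_pool == 0)
    if case_idx.size < config.n_cases or ctrl_idx.size < config.n_controls:
        raise SimulationError(
            f"pool of {pool_n} yielded {case_idx.size} cases / {ctrl_idx.size} "
            f"controls; need {config.n_cases}/{config.n_controls} — "
            "increase pool margin or weaken effects"
        )
    chosen = np.sort(np.concatenate([
        rng.choice(case_idx, config.n_cases, replace=False),
        rng.choice(ctrl_idx, config.n_controls, replace=False),
    ]))

    dosage = dosage[chosen]
    status = y_pool[chosen]
    batch_labels = batch_labels[chosen]
    subpop_labels = subpop_labels[chosen]

    if config.missing_rate > 0:
        miss = rng.uniform(size=dosage.shape) < config.missing_rate
        dosage[miss] = -1

    marker_ids = [f"snp{j + 1}" for j in range(m)]
    markers = pd.DataFrame({
        "id": marker_ids,
        "chrom": _CHROM,
        "pos": _POS_START + _POS_STEP * np.arange(m),
        "a1": "A",
        "a2": "B",
    })
    samples = [f"ind{i + 1}" for i in range(total)]
    gm = GenotypeMatrix(dosage, markers, samples)

    covars = {}
    if config.n_pcs > 0:
        pcs = compute_pcs(dosage, config.n_pcs)
        covars.update({f"PC{k + 1}": pcs[:, k] for k in range(pcs.shape[1])})
    for b_ in range(1, config.n_batches):
        covars[f"batch{b_ + 1}"] = (batch_labels == b_).astype(float)
    cohort = CohortTable(samples, status,
                         pd.DataFrame(covars, index=range(total)))

    truth = TruthRecord(
        additive=[(marker_ids[i], float(b)) for i, b in config.additive_effects],
        epistatic=[(marker_ids[i], marker_ids[j], np.asarray(mat, float).tolist())
                   for (i, j), mat in config.epistatic_effects],
        intercept=float(intercept),
        batch_labels=batch_labels,
        subpop_labels=subpop_labels,
        batch_effects=batch_eff,
        subpop_effects=subpop_eff,
    )
    return gm, cohort, truth


def split_cohort(
    genotypes: GenotypeMatrix,
    cohort: CohortTable,
    fraction: float,
    seed: int,
    recompute_pcs_per_half: bool = True,
) -> tuple[tuple[GenotypeMatrix, CohortTable], tuple[GenotypeMatrix, CohortTable]]:
    """Stratified random split into discovery and replication halves.

    ``fraction`` of cases and ``fraction`` of controls (rounded to the
    nearest sample) go to the first half; the partition is disjoint and
    exhaustive.  Principal-component covariates are recomputed within each
    half by default.
    """
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    first: list[np.ndarray] = []
    second: list[np.ndarray] = []
    for stratum in (1, 0):
        idx = np.flatnonzero(cohort.status == stratum)
        if idx.size == 0:
            name = "case" if stratum == 1 else "control"
            raise ValueError(f"cannot split: {name} stratum is empty")
        take = int(round(fraction * idx.size))
        perm = rng.permutation(idx)
        first.append(perm[:take])
        second.append(perm[take:])
    i1 = np.sort(np.concatenate(first))
    i2 = np.sort(np.concatenate(second))

    halves = []
    for idx in (i1, i2):
        gm = genotypes.subset_samples(idx)
        ct = cohort.subset(idx)
        if recompute_pcs_per_half:
            pc_cols = [c for c in ct.covariates.columns if c.startswith("PC")]
            if pc_cols:
                pcs = compute_pcs(gm.dosages, len(pc_cols))
                cov = ct.covariates.copy()
                cov = cov.drop(columns=pc_cols)
                for k in range(pcs.shape[1]):
                    cov.insert(k, f"PC{k + 1}", pcs[:, k])
                ct = CohortTable(ct.samples, ct.status, cov, ct.excluded)
        halves.append((gm, ct))
    return halves[0], halves[1]


def write_cohort(prefix: str | Path, genotypes: GenotypeMatrix,
                 cohort: CohortTable, truth: TruthRecord | None = None) -> None:
    """Write PLINK bed/bim/fam, a tab-separated covariate file, and the
    truth record JSON next to them."""
    prefix = Path(prefix)
    genotype_io.write_plink(prefix, genotypes, status=cohort.status)
    genotype_io.write_covariates(prefix.with_suffix(".covar"), cohort)
    if truth is not None:
        prefix.with_suffix(".truth.json").write_text(truth.to_json())


def interaction_only_matrix(strength: float) -> np.ndarray:
    """A 3x3 log-odds matrix with pure interaction: zero additive and
    dominance content in both margins (checkerboard +/- strength)."""
    sign = np.array([[1, -1, 1], [-1, 1, -1], [1, -1, 1]], dtype=float)
    return strength * sign


def multiplicative_matrix(beta1: float, beta2: float) -> np.ndarray:
    """A 3x3 log-odds matrix that is purely additive in the two dosages
    (the null of the 4-df interaction test)."""
    g = np.arange(3, dtype=float)
    return beta1 * g[:, None] + beta2 * g[None, :]
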