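"""Stage 1: exhaustive approximate interaction screening over marker pairs.

Genotypes are packed into per-class bit planes so that every status x
genotype x genotype contingency count is a word-level popcount.  The
screening statistic compares the saturated three-way distribution with its
Kirkwood superposition approximation (a normalized product of the three
two-way margins divided by one-way margins); it upper-bounds the exact
no-covariate 4-df likelihood-ratio statistic, so the screen never discards
a pair that the exact test would call significant at the same threshold.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy.stats import chi2

from .genotype_io import CohortTable, GenotypeMatrix

log = logging.getLogger(__name__)

SCREEN_P = 1e-10
SCREEN_R2 = 0.2


@dataclass
class PairCandidate:
    snp1: str
    snp2: str
    statistic: float
    p: float
    r2: float


@dataclass
class BitPlanes:
    """Per-marker genotype-class bit vectors packed into uint64 words.

    ``planes[j, g]`` has bit ``s`` set iff sample ``s`` has dosage ``g`` at
    marker ``j``; ``valid[j]`` is the union of the three planes (non-missing
    calls).  AND-ing planes and popcounting reproduces contingency counts
    exactly.
    """

    planes: np.ndarray  # (n_markers, 3, n_words) uint64
    valid: np.ndarray   # (n_markers, n_words) uint64
    n_samples: int
    marker_ids: list[str]

    @property
    def n_words(self) -> int:
        return self.planes.shape[2]


def pack_bits(mask: np.ndarray) -> np.ndarray:
    """Pack a boolean vector into little-endian uint64 words."""
    mask = np.asarray(mask, dtype=bool)
    pad = (-mask.size) % 64
    if pad:
        mask = np.concatenate([mask, np.zeros(pad, dtype=bool)])
    return np.packbits(mask, bitorder="little").view(np.uint64)


def popcount(words: np.ndarray) -> int:
    return int(np.bitwise_count(words).sum())


def encode_bit_planes(genotypes: GenotypeMatrix) -> BitPlanes:
    n, m = genotypes.n_samples, genotypes.n_markers
    n_words = (n + 63) // 64
    planes = np.zeros((m, 3, n_words), dtype=np.uint64)
    for g in range(3):
        mask = genotypes.dosages == g  # (n, m)
        for j in range(m):
            planes[j, g] = pack_bits(mask[:, j])
    valid = planes[:, 0] | planes[:, 1] | planes[:, 2]
    return BitPlanes(planes, valid, n, genotypes.marker_ids)


def status_planes(cohort: CohortTable) -> tuple[np.ndarray, np.ndarray]:
    """Packed (controls, cases) bit vectors."""
    return pack_bits(cohort.status == 0), pack_bits(cohort.status == 1)


def pair_table(
    planes: BitPlanes, i: int, j: int, status: tuple[np.ndarray, np.ndarray]
) -> np.ndarray:
    """2x3x3 counts n[y, g1, g2] on pairwise-complete samples."""
    if i == j:
        raise ValueError("pair members must be distinct")
    table = np.zeros((2, 3, 3), dtype=np.int64)
    for y, sy in enumerate(status):
        for g1 in range(3):
            v = planes.planes[i, g1] & sy
            for g2 in range(3):
                table[y, g1, g2] = popcount(v & planes.planes[j, g2])
    return table


def ksa_statistic(table: np.ndarray) -> tuple[float, float]:
    """Kirkwood-superposition screening statistic and its chi2(4 df) upper
    tail P.

    statistic = 2 * [loglik(saturated) - loglik(KSA)], where the KSA cell
    probabilities are proportional to
    p(g1,g2) * p(g1,y) * p(g2,y) / (p(g1) * p(g2) * p(y)),
    normalized over all 18 cells.  Empty cells contribute zero (0*log 0 = 0);
    genotype classes absent from the table drop out of both likelihoods.
    """
    n = np.asarray(table, dtype=float)
    N = n.sum()
    if N <= 0:
        raise ValueError("empty table")
    p = n / N
    p12 = p.sum(axis=0)          # (g1, g2)
    p1y = p.sum(axis=2)          # (y, g1)
    p2y = p.sum(axis=1)          # (y, g2)
    p1 = p12.sum(axis=1)         # (g1,)
    p2 = p12.sum(axis=0)         # (g2,)
    py = p1y.sum(axis=1)         # (y,)

    num = p12[None, :, :] * p1y[:, :, None] * p2y[:, None, :]
    den = p1[None, :, None] * p2[None, None, :] * py[:, None, None]
    with np.errstate(divide="ignore", invalid="ignore"):
        q = np.where(den > 0, num / np.where(den > 0, den, 1.0), 0.0)
    q_sum = q.sum()
    if q_sum <= 0:
        return 0.0, 1.0
    q /= q_sum

    mask = n > 0
    ll_sat = float(np.sum(n[mask] * np.log(p[mask])))
    ll_ksa = float(np.sum(n[mask] * np.log(q[mask])))
    stat = max(0.0, 2.0 * (ll_sat - ll_ksa))
    return stat, float(chi2.sf(stat, 4))


def _ksa_statistics_batch(tables: np.ndarray) -> np.ndarray:
    """Vectorized KSA statistic over an array of 2x3x3 tables (k,2,3,3)."""
    n = tables.astype(float)
    N = n.sum(axis=(1, 2, 3), keepdims=True)
    N = np.where(N > 0, N, 1.0)
    p = n / N
    p12 = p.sum(axis=1)
    p1y = p.sum(axis=3)
    p2y = p.sum(axis=2)
    p1 = p12.sum(axis=2)
    p2 = p12.sum(axis=1)
    py = p1y.sum(axis=2)

    num = p12[:, None, :, :] * p1y[:, :, :, None] * p2y[:, :, None, :]
    den = p1[:, None, :, None] * p2[:, None, None, :] * py[:, :, None, None]
    with np.errstate(divide="ignore", invalid="ignore"):
        q = np.where(den > 0, num / np.where(den > 0, den, 1.0), 0.0)
    q_sum = q.sum(axis=(1, 2, 3), keepdims=True)
    q = np.where(q_sum > 0, q / np.where(q_sum > 0, q_sum, 1.0), 0.0)

    mask = n > 0
    with np.errstate(divide="ignore", invalid="ignore"):
        ll_sat = np.where(mask, n * np.log(np.where(mask, p, 1.0)), 0.0).sum(axis=(1, 2, 3))
        ll_ksa = np.where(mask, n * np.log(np.where(mask & (q > 0), q, 1.0)), 0.0).sum(axis=(1, 2, 3))
    return np.maximum(0.0, 2.0 * (ll_sat - ll_ksa))


def dosage_r2(genotypes: GenotypeMatrix, marker_i: str | int, marker_j: str | int) -> float:
    """Squared Pearson correlation of dosages on pairwise-complete samples.

    NaN when either marker has zero variance on the shared subset.
    """
    di = genotypes.dosage(marker_i)
    dj = genotypes.dosage(marker_j)
    ok = (di >= 0) & (dj >= 0)
    a, b = di[ok].astype(float), dj[ok].astype(float)
    if a.size < 2 or a.std() == 0 or b.std() == 0:
        return math.nan
    r = float(np.corrcoef(a, b)[0, 1])
    return r * r


def screen_all_pairs(
    genotypes: GenotypeMatrix,
    cohort: CohortTable,
    p_threshold: float = SCREEN_P,
    r2_threshold: float = SCREEN_R2,
) -> list[PairCandidate]:
    """Evaluate every unordered marker pair; retain those with approximate
    interaction P below ``p_threshold`` and dosage r2 below ``r2_threshold``.

    Covariates are deliberately ignored at this stage.  Output is sorted by
    ascending approximate P, ties by identifiers.
    """
    planes = encode_bit_planes(genotypes)
    s0, s1 = status_planes(cohort)
    m = genotypes.n_markers
    stat_threshold = float(chi2.isf(p_threshold, 4)) if p_threshold > 0 else math.inf
    ids = genotypes.marker_ids

    candidates: list[PairCandidate] = []
    excluded_r2 = 0
    undefined_r2 = 0
    for i in range(m - 1):
        rest = planes.planes[i + 1:]  # (m', 3, W)
        tables = np.empty((m - i - 1, 2, 3, 3), dtype=np.int64)
        for y, sy in enumerate((s0, s1)):
            for g1 in range(3):
                v = planes.planes[i, g1] & sy
                tables[:, y, g1, :] = np.bitwise_count(v[None, None, :] & rest).sum(axis=2)
        stats = _ksa_statistics_batch(tables)
        for off in np.flatnonzero(stats > stat_threshold):
            j = i + 1 + int(off)
            stat = float(stats[off])
            p = float(chi2.sf(stat, 4))
            if not p < p_threshold:
                continue
            r2 = dosage_r2(genotypes, i, j)
            if math.isnan(r2):
                undefined_r2 += 1
                log.info("pair (%s,%s): r2 undefined on complete pairs; excluded",
                         ids[i], ids[j])
                continue
            if r2 >= r2_threshold:
                excluded_r2 += 1
                continue
            candidates.append(PairCandidate(ids[i], ids[j], stat, p, r2))

    candidates.sort(key=lambda c: (c.p, c.snp1, c.snp2))
    log.info(
        "pair screen: %d pairs evaluated, %d candidates retained "
        "(%d removed by r2 filter, %d undefined r2)",
        m * (m - 1) // 2, len(candidates), excluded_r2, undefined_r2,
    )
    return candidates
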