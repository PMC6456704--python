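"""Marker QC, single-marker association scan, and independence screening.

The independence screen defines the "additive background": the subset of
marginally significant markers that stay individually significant in one
joint logistic model.  Conditional interaction tests later adjust for this
set.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.special import gammaln

from .exact_epistasis import FitError, drop_collinear_columns, logistic_fit
from .genotype_io import CohortTable, GenotypeMatrix

log = logging.getLogger(__name__)

HWE_THRESHOLD = 1e-6
MAF_THRESHOLD = 1e-5
ENTRY_THRESHOLD = 5e-8
KEEP_THRESHOLD = 0.05


@dataclass
class MarkerQC:
    marker: str
    hwe_p: float
    maf: float
    passed: bool
    reasons: list[str] = field(default_factory=list)


@dataclass
class AdditiveHit:
    marker: str
    beta: float
    se: float
    p: float
    n: int
    flag: str = ""  # "", "not_testable", "separation", "not_converged"

    @property
    def testable(self) -> bool:
        return self.flag == ""


@dataclass
class AdditiveBackground:
    """Ordered markers retained as independent additive signals."""

    markers: list[str]
    joint_p: dict[str, float]
    dropped: list[tuple[str, str]] = field(default_factory=list)  # (marker, reason)

    def __len__(self) -> int:
        return len(self.markers)


def hwe_exact_test(n_hom1: int, n_het: int, n_hom2: int) -> float:
    """Two-sided exact Hardy-Weinberg test (conditional enumeration).

    Sums, over all heterozygote counts compatible with the observed allele
    counts, the probabilities of tables no more likely than the observed
    one.
    """
    if min(n_hom1, n_het, n_hom2) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_hom1 + n_het + n_hom2
    if n == 0:
        raise ValueError("all genotype counts are zero")
    n1 = 2 * n_hom1 + n_het  # copies of allele 1
    n2 = 2 * n_hom2 + n_het
    rare = min(n1, n2)
    if rare == 0:
        return 1.0

    hets = np.arange(rare % 2, rare + 1, 2)
    hom_rare = (rare - hets) // 2
    hom_common = (max(n1, n2) - hets) // 2
    # log P(het = h | allele counts), up to a shared constant
    logp = (
        hets * math.log(2.0)
        - gammaln(hets + 1)
        - gammaln(hom_rare + 1)
        - gammaln(hom_common + 1)
    )
    logp -= logp.max()
    probs = np.exp(logp)
    probs /= probs.sum()
    observed = probs[np.flatnonzero(hets == n_het)[0]]
    return float(min(1.0, probs[probs <= observed * (1.0 + 1e-12)].sum()))


def marker_qc(
    genotypes: GenotypeMatrix,
    hwe_threshold: float = HWE_THRESHOLD,
    maf_threshold: float = MAF_THRESHOLD,
    sample_mask: np.ndarray | None = None,
) -> list[MarkerQC]:
    """Per-marker HWE exact P and minor-allele frequency with pass flags."""
    out = []
    D = genotypes.dosages if sample_mask is None else genotypes.dosages[sample_mask]
    for j, marker in enumerate(genotypes.marker_ids):
        d = D[:, j]
        ok = d >= 0
        n0 = int((d[ok] == 0).sum())
        n1 = int((d[ok] == 1).sum())
        n2 = int((d[ok] == 2).sum())
        total = n0 + n1 + n2
        if total == 0:
            out.append(MarkerQC(marker, math.nan, math.nan, False, ["all_missing"]))
            continue
        freq2 = (2 * n2 + n1) / (2 * total)
        maf = min(freq2, 1.0 - freq2)
        hwe_p = hwe_exact_test(n0, n1, n2)
        reasons = []
        if hwe_p < hwe_threshold:
            reasons.append("hwe")
        if maf < maf_threshold:
            reasons.append("maf")
        out.append(MarkerQC(marker, hwe_p, maf, not reasons, reasons))
    return out


def qc_filter(
    genotypes: GenotypeMatrix,
    hwe_threshold: float = HWE_THRESHOLD,
    maf_threshold: float = MAF_THRESHOLD,
    controls_only: bool = False,
    cohort: CohortTable | None = None,
) -> tuple[GenotypeMatrix, list[MarkerQC]]:
    """Remove markers failing the HWE or MAF threshold.

    With ``controls_only`` the statistics are computed in controls, which
    requires a cohort table; the default uses all samples.
    """
    mask = None
    if controls_only:
        if cohort is None:
            raise ValueError("controls_only QC requires a cohort table")
        mask = cohort.status == 0
    report = marker_qc(genotypes, hwe_threshold, maf_threshold, mask)
    keep = np.flatnonzero([q.passed for q in report])
    return genotypes.subset_markers(keep), report


def single_snp_scan(
    genotypes: GenotypeMatrix, cohort: CohortTable
) -> list[AdditiveHit]:
    """Additive logistic scan: status ~ dosage + covariates, Wald P on the
    dosage coefficient, complete cases per marker.

    Non-converged or separated fits are flagged, never silently dropped.
    """
    C = cohort.covariate_matrix()
    cov_ok = np.isfinite(C).all(axis=1)
    y_all = cohort.status.astype(float)
    hits = []
    for j, marker in enumerate(genotypes.marker_ids):
        d = genotypes.dosages[:, j]
        ok = (d >= 0) & cov_ok
        n = int(ok.sum())
        dj = d[ok].astype(float)
        y = y_all[ok]
        if n == 0 or dj.min() == dj.max() or y.min() == y.max():
            hits.append(AdditiveHit(marker, math.nan, math.nan, math.nan, n,
                                    "not_testable"))
            continue
        X0 = np.column_stack([np.ones(n), C[ok], dj])
        dosage_col = X0.shape[1] - 1
        X, kept, _ = drop_collinear_columns(X0)
        if kept[-1] != dosage_col:
            hits.append(AdditiveHit(marker, math.nan, math.nan, math.nan, n,
                                    "not_testable"))
            continue
        try:
            fit = logistic_fit(X, y)
        except FitError:
            hits.append(AdditiveHit(marker, math.nan, math.nan, math.nan, n,
                                    "not_testable"))
            continue
        jdx = X.shape[1] - 1
        flag = ""
        if fit.separated:
            flag = "separation"
        elif not fit.converged:
            flag = "not_converged"
        hits.append(AdditiveHit(marker, float(fit.beta[jdx]), fit.se(jdx),
                                fit.wald_p(jdx), n, flag))
    return hits


def independence_screen(
    hits: Sequence[AdditiveHit],
    genotypes: GenotypeMatrix,
    cohort: CohortTable,
    entry_threshold: float = ENTRY_THRESHOLD,
    keep_threshold: float = KEEP_THRESHOLD,
) -> AdditiveBackground:
    """Pool markers with scan P below ``entry_threshold``, drop perfect
    duplicates, refit one joint logistic model, and keep markers whose joint
    Wald P stays below ``keep_threshold``.

    Duplicates and rank-deficient columns are resolved greedily by ascending
    scan P (ties by identifier), so only one of any fully correlated set
    survives.
    """
    selected = sorted(
        (h for h in hits if h.testable and math.isfinite(h.p) and h.p < entry_threshold),
        key=lambda h: (h.p, h.marker),
    )
    dropped: list[tuple[str, str]] = []
    if not selected:
        log.info("independence screen: no marker reached P < %g", entry_threshold)
        return AdditiveBackground([], {}, dropped)

    C = cohort.covariate_matrix()
    ok = np.isfinite(C).all(axis=1)
    for h in selected:
        ok &= genotypes.dosage(h.marker) >= 0
    y = cohort.status[ok].astype(float)
    if y.size == 0 or y.min() == y.max():
        raise FitError("independence screen: degenerate complete-case subset")

    # drop exact duplicates first (pairwise |r| == 1 on complete cases)
    D = np.column_stack([genotypes.dosage(h.marker)[ok].astype(float) for h in selected])
    kept_idx: list[int] = []
    for i, h in enumerate(selected):
        dup_of = None
        for k in kept_idx:
            a, b = D[:, i], D[:, k]
            sa, sb = a.std(), b.std()
            if sa == 0 or sb == 0:
                continue
            r = float(np.corrcoef(a, b)[0, 1])
            if abs(r) >= 1.0 - 1e-12:
                dup_of = selected[k].marker
                break
        if dup_of is None:
            kept_idx.append(i)
        else:
            dropped.append((h.marker, f"duplicate_of:{dup_of}"))

    # greedy forward pass in ascending scan P resolves remaining collinearity
    base = np.column_stack([np.ones(int(ok.sum())), C[ok]])
    design_cols, names = [], []
    for i in kept_idx:
        cand = np.column_stack([base] + design_cols + [D[:, i][:, None]])
        _, kept_cols, dropped_names = drop_collinear_columns(cand)
        if len(kept_cols) == cand.shape[1]:
            design_cols.append(D[:, i][:, None])
            names.append(selected[i].marker)
        else:
            dropped.append((selected[i].marker, "collinear_in_joint_fit"))

    if not names:
        return AdditiveBackground([], {}, dropped)

    X = np.column_stack([base] + design_cols)
    fit = logistic_fit(X, y)
    if not fit.converged:
        raise FitError(
            f"joint refit did not converge in {fit.n_iter} iterations "
            f"(separated={fit.separated})"
        )
    offset = base.shape[1]
    joint_p = {m: fit.wald_p(offset + i) for i, m in enumerate(names)}
    retained = [m for m in names if joint_p[m] < keep_threshold]
    for m in names:
        if m not in retained:
            dropped.append((m, f"joint_p>={keep_threshold}"))
    log.info("independence screen: %d entered, %d retained", len(selected), len(retained))
    return AdditiveBackground(retained, {m: joint_p[m] for m in retained}, dropped)
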