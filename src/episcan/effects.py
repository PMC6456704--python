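"""Orthogonal effect decomposition and observed-scale variance accounting.

Each marker gets frequency-dependent additive and dominance scores that are
orthogonal under Hardy-Weinberg genotype weights; a pair contributes eight
genetic terms (A1, A2, D1, D2 and the four products), fit jointly on the
log-odds scale.  Variance explained is the squared correlation between the
binary status and fitted probabilities, differenced across nested models.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .exact_epistasis import drop_collinear_columns, logistic_fit
from .genotype_io import CohortTable, GenotypeMatrix

EFFECT_TERMS = ["A1", "A2", "D1", "D2", "A1xA2", "A1xD2", "D1xA2", "D1xD2"]


@dataclass
class OrthogonalCoding:
    """Additive score a(g) and dominance score d(g) for g in {0, 1, 2}.

    a(g) = g - 2p; d is the heterozygote indicator orthogonalized against
    {1, a} under HWE weights ((1-p)^2, 2p(1-p), p^2), where p is the
    frequency of the counted allele.
    """

    p: float
    a: np.ndarray
    d: np.ndarray

    def hwe_weights(self) -> np.ndarray:
        q = 1.0 - self.p
        return np.array([q * q, 2 * self.p * q, self.p * self.p])

    def score(self, dosage: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        d = np.asarray(dosage)
        return self.a[d], self.d[d]


def orthogonal_coding(p: float) -> OrthogonalCoding:
    if not 0.0 < p < 1.0:
        raise ValueError(f"allele frequency must be in (0, 1); got {p}")
    g = np.array([0.0, 1.0, 2.0])
    a = g - 2.0 * p
    het = np.array([0.0, 1.0, 0.0])
    # Gram-Schmidt of the het indicator against {1, a} under HWE weights:
    # E[het] = 2p(1-p); cov(het, a)/var(a) = 1 - 2p
    d = het - 2.0 * p * (1.0 - p) - (1.0 - 2.0 * p) * a
    return OrthogonalCoding(p, a, d)


@dataclass
class EffectDecomposition:
    snp1: str
    snp2: str
    coefficients: dict[str, float]
    standard_errors: dict[str, float]
    n: int
    converged: bool
    cohort: str = ""


def pair_design(
    genotypes: GenotypeMatrix, pair: tuple[str, str], mask: np.ndarray
) -> tuple[np.ndarray, list[str]]:
    """The eight orthogonal columns for one pair on the masked samples.

    Allele frequencies are estimated from the masked subset of the analysis
    cohort.
    """
    id1, id2 = pair
    d1 = genotypes.dosage(id1)[mask]
    d2 = genotypes.dosage(id2)[mask]
    c1 = orthogonal_coding(float(d1.mean() / 2.0))
    c2 = orthogonal_coding(float(d2.mean() / 2.0))
    a1, dd1 = c1.score(d1)
    a2, dd2 = c2.score(d2)
    cols = np.column_stack(
        [a1, a2, dd1, dd2, a1 * a2, a1 * dd2, dd1 * a2, dd1 * dd2]
    )
    names = [f"{t}:{id1}:{id2}" for t in EFFECT_TERMS]
    return cols, names


def decompose_pair(
    genotypes: GenotypeMatrix,
    cohort: CohortTable,
    pair: tuple[str, str],
    extra_covariates: Sequence[str] = (),
    cohort_label: str = "",
) -> EffectDecomposition:
    """Fit status ~ covariates (+ background dosages) + 8 orthogonal terms."""
    id1, id2 = pair
    C = cohort.covariate_matrix()
    extras = [m for m in extra_covariates if m not in pair]
    ok = (genotypes.dosage(id1) >= 0) & (genotypes.dosage(id2) >= 0)
    ok &= np.isfinite(C).all(axis=1)
    for m in extras:
        ok &= genotypes.dosage(m) >= 0

    terms, _ = pair_design(genotypes, pair, ok)
    base = [np.ones((int(ok.sum()), 1)), C[ok]]
    if extras:
        base.append(np.column_stack(
            [genotypes.dosage(m)[ok].astype(float) for m in extras]))
    X = np.column_stack([*base, terms])
    fit = logistic_fit(X, cohort.status[ok].astype(float))
    offset = X.shape[1] - 8
    coef = {t: float(fit.beta[offset + k]) for k, t in enumerate(EFFECT_TERMS)}
    se = {t: fit.se(offset + k) for k, t in enumerate(EFFECT_TERMS)}
    return EffectDecomposition(id1, id2, coef, se, fit.n, fit.converged, cohort_label)


@dataclass
class VarianceReport:
    """Observed-scale variance explained, in percent."""

    joint_pct: float                # covariates excluded: background + pairs
    pairs_beyond_background_pct: float
    interaction_only_pct: float
    per_pair_avg_pct: float
    single_pair_pcts: dict[str, float] = field(default_factory=dict)


def _observed_r2(y: np.ndarray, fitted: np.ndarray) -> float:
    if fitted.std() == 0:
        return 0.0
    r = float(np.corrcoef(y, fitted)[0, 1])
    return r * r


def variance_explained(
    genotypes: GenotypeMatrix,
    cohort: CohortTable,
    background: Sequence[str],
    pairs: Sequence[tuple[str, str]],
) -> VarianceReport:
    """Nested-model R2 accounting.

    M0 = covariates + background dosages; M1 = M0 + pair main-effect terms;
    M2 = M1 + pair interaction terms.  Reports R2(M2) as the joint figure,
    M2-M0 as "pairs beyond background", M2-M1 as "interactions only", and
    (M2-M0)/n_pairs as the per-pair average; single-pair contributions
    (M0 + one full pair vs M0) are reported alongside.
    """
    if not pairs:
        return VarianceReport(0.0, 0.0, 0.0, 0.0, {})

    C = cohort.covariate_matrix()
    ok = np.isfinite(C).all(axis=1)
    involved = sorted({m for pr in pairs for m in pr})
    for m in set(background) | set(involved):
        ok &= genotypes.dosage(m) >= 0
    y = cohort.status[ok].astype(float)
    nrow = int(ok.sum())

    base_cols = [np.ones((nrow, 1)), C[ok]]
    if background:
        base_cols.append(np.column_stack(
            [genotypes.dosage(m)[ok].astype(float) for m in background]))
    M0 = np.column_stack(base_cols)

    main_blocks, int_blocks, per_pair_blocks = [], [], {}
    for pr in pairs:
        terms, _ = pair_design(genotypes, pr, ok)
        main_blocks.append(terms[:, :4])
        int_blocks.append(terms[:, 4:])
        per_pair_blocks[f"{pr[0]}:{pr[1]}"] = terms
    M1 = np.column_stack([M0] + main_blocks)
    M2 = np.column_stack([M1] + int_blocks)

    def fit_r2(X: np.ndarray) -> float:
        Xr, _, _ = drop_collinear_columns(X)
        fit = logistic_fit(Xr, y)
        from scipy.special import expit
        return _observed_r2(y, expit(Xr @ fit.beta))

    r2_0, r2_1, r2_2 = fit_r2(M0), fit_r2(M1), fit_r2(M2)
    tol = 1e-10
    if r2_1 < r2_0 - tol or r2_2 < r2_1 - tol:
        raise RuntimeError(
            f"nested R2 not monotone: M0={r2_0:.6g} M1={r2_1:.6g} M2={r2_2:.6g}"
        )
    r2_1 = max(r2_1, r2_0)
    r2_2 = max(r2_2, r2_1)

    singles = {
        key: max(0.0, fit_r2(np.column_stack([M0, terms])) - r2_0) * 100.0
        for key, terms in per_pair_blocks.items()
    }
    beyond = (r2_2 - r2_0) * 100.0
    return VarianceReport(
        joint_pct=r2_2 * 100.0,
        pairs_beyond_background_pct=beyond,
        interaction_only_pct=(r2_2 - r2_1) * 100.0,
        per_pair_avg_pct=beyond / len(pairs),
        single_pair_pcts=singles,
    )
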