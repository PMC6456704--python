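"""Exact covariate-adjusted interaction tests.

Stage 2 of the pair search: a 4-df likelihood-ratio test comparing a
logistic model with full genotype-factor coding for both markers plus all
four indicator products against the same model without the products.
Conditional tests add an independently derived set of additive-background
markers as dosage covariates to both nested models.

Also hosts the shared IRLS fitting engine and the iterative-proportional-
fitting oracle for the covariate-free reduced model.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.special import expit
from scipy.stats import chi2

from .genotype_io import CohortTable, GenotypeMatrix

log = logging.getLogger(__name__)

MAX_ITER = 100
LL_TOL = 1e-10
BETA_TOL = 1e-8
SEPARATION_BOUND = 15.0

GENOME_WIDE_P = 1e-13
CHIP_WIDE_P = 1.1e-8
REPLICATION_P = 0.05


class FitError(RuntimeError):
    """Raised for degenerate outcomes or unusable designs."""


@dataclass
class LogisticFit:
    loglik: float
    beta: np.ndarray
    cov: np.ndarray
    converged: bool
    separated: bool
    n_iter: int
    n: int
    column_names: list[str] = field(default_factory=list)

    def wald_p(self, j: int) -> float:
        se = math.sqrt(self.cov[j, j])
        if se <= 0 or not math.isfinite(se):
            return math.nan
        z = self.beta[j] / se
        return float(chi2.sf(z * z, 1))

    def se(self, j: int) -> float:
        return float(math.sqrt(self.cov[j, j]))


def _loglik(y: np.ndarray, eta: np.ndarray) -> float:
    # sum y*eta - log(1 + exp(eta)), computed stably
    return float(np.sum(y * eta) - np.sum(np.logaddexp(0.0, eta)))


def logistic_fit(X: np.ndarray, y: np.ndarray,
                 column_names: Sequence[str] | None = None) -> LogisticFit:
    """Maximum-likelihood logistic regression by IRLS with step halving.

    ``X`` must contain the intercept column and be full rank on the rows
    provided (use :func:`drop_collinear_columns` first when unsure).
    Convergence requires both a log-likelihood change below 1e-10 and a
    maximum coefficient change below 1e-8 within 100 iterations.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.ndim != 2 or X.shape[0] != y.shape[0]:
        raise ValueError("design/response shape mismatch")
    n = X.shape[0]
    if n == 0:
        raise FitError("empty design")
    if y.min() == y.max():
        raise FitError("degenerate outcome: all responses identical")

    names = list(column_names) if column_names is not None else [
        f"x{j}" for j in range(X.shape[1])
    ]
    beta = np.zeros(X.shape[1])
    eta = X @ beta
    ll = _loglik(y, eta)
    converged = False
    it = 0
    for it in range(1, MAX_ITER + 1):
        mu = expit(eta)
        w = np.clip(mu * (1.0 - mu), 1e-12, None)
        z = eta + (y - mu) / w
        Xw = X * w[:, None]
        xtwx = X.T @ Xw
        xtwz = Xw.T @ z
        try:
            beta_new = np.linalg.solve(xtwx, xtwz)
        except np.linalg.LinAlgError:
            beta_new = np.linalg.lstsq(xtwx, xtwz, rcond=None)[0]
        # step-halve to keep the likelihood non-decreasing
        step = beta_new - beta
        ll_new = _loglik(y, X @ beta_new)
        halvings = 0
        while ll_new < ll - 1e-12 and halvings < 30:
            step *= 0.5
            beta_new = beta + step
            ll_new = _loglik(y, X @ beta_new)
            halvings += 1
        delta = float(np.max(np.abs(beta_new - beta)))
        dll = abs(ll_new - ll)
        beta, ll = beta_new, ll_new
        eta = X @ beta
        if dll < LL_TOL and delta < BETA_TOL:
            converged = True
            break

    separated = bool(np.max(np.abs(beta)) > SEPARATION_BOUND)
    mu = expit(eta)
    w = np.clip(mu * (1.0 - mu), 1e-12, None)
    xtwx = X.T @ (X * w[:, None])
    try:
        cov = np.linalg.inv(xtwx)
    except np.linalg.LinAlgError:
        cov = np.linalg.pinv(xtwx)
    return LogisticFit(ll, beta, cov, converged, separated, it, n, names)


def drop_collinear_columns(
    X: np.ndarray, names: Sequence[str] | None = None, tol: float = 1e-8
) -> tuple[np.ndarray, list[int], list[str]]:
    """Greedy left-to-right removal of columns that are (near) linear
    combinations of earlier ones.  Returns (reduced X, kept indices, dropped
    names).  Deterministic: earlier columns always win."""
    X = np.asarray(X, dtype=float)
    names = list(names) if names is not None else [f"x{j}" for j in range(X.shape[1])]
    kept: list[int] = []
    dropped: list[str] = []
    # incremental Gram-Schmidt against the kept basis
    basis = np.empty((X.shape[0], 0))
    for j in range(X.shape[1]):
        v = X[:, j].astype(float)
        scale = np.linalg.norm(v)
        if scale <= tol:
            dropped.append(names[j])
            continue
        r = v - basis @ (basis.T @ v)
        if np.linalg.norm(r) <= tol * max(scale, 1.0):
            dropped.append(names[j])
            continue
        kept.append(j)
        basis = np.concatenate([basis, (r / np.linalg.norm(r))[:, None]], axis=1)
    return X[:, kept], kept, dropped


# ---------------------------------------------------------------------------
# Interaction LRT
# ---------------------------------------------------------------------------

@dataclass
class InteractionLRT:
    statistic: float
    p: float
    df: int
    n: int
    converged: bool
    separated: bool
    standard_df: bool
    note: str = ""


@dataclass
class EpistasisResult:
    """Unconditional and conditional 4-df interaction test for one pair."""

    snp1: str
    snp2: str
    statistic: float
    p: float
    cond_statistic: float
    cond_p: float
    df: int
    cond_df: int
    n: int
    converged: bool
    separated: bool
    cohort: str = ""
    note: str = ""


@dataclass
class SignificanceCall:
    snp1: str
    snp2: str
    genome_wide: bool
    chip_wide: bool
    replicated: bool | None = None
    note: str = ""


def _factor_columns(d: np.ndarray, label: str) -> tuple[np.ndarray, list[str]]:
    """Two indicator columns per marker; reference = homozygous-major class.

    Classes absent from the data yield no column (df shrinks accordingly).
    """
    freq2 = d.mean() / 2.0
    ref = 2 if freq2 > 0.5 else 0
    cols, names = [], []
    for g in (0, 1, 2):
        if g == ref:
            continue
        ind = (d == g).astype(float)
        if ind.any():
            cols.append(ind)
            names.append(f"{label}_g{g}")
    if not cols:
        return np.empty((d.shape[0], 0)), []
    return np.column_stack(cols), names


def interaction_lrt(
    genotypes: GenotypeMatrix,
    cohort: CohortTable,
    pair: tuple[str, str],
    extra_covariates: Sequence[str] = (),
) -> InteractionLRT:
    """4-df LRT for the pair, adjusted for cohort covariates and optional
    extra additive-dosage covariates (the additive background).

    Pair members appearing in ``extra_covariates`` are excluded from the
    extras (they already enter through the factor coding).  Both nested
    models are fit on the identical complete-case subset.
    """
    id1, id2 = pair
    if id1 == id2:
        raise ValueError("pair members must be distinct")
    d1 = genotypes.dosage(id1)
    d2 = genotypes.dosage(id2)
    extras = [m for m in extra_covariates if m not in (id1, id2)]
    extra_d = [genotypes.dosage(m) for m in extras]

    C = cohort.covariate_matrix()
    ok = (d1 >= 0) & (d2 >= 0) & np.isfinite(C).all(axis=1)
    for ed in extra_d:
        ok &= ed >= 0
    y = cohort.status[ok].astype(float)
    if ok.sum() == 0 or y.min() == y.max():
        return InteractionLRT(math.nan, math.nan, 0, int(ok.sum()), False, False,
                              False, "degenerate complete-case subset")

    f1, n1 = _factor_columns(d1[ok], id1)
    f2, n2 = _factor_columns(d2[ok], id2)
    if f1.shape[1] == 0 or f2.shape[1] == 0:
        return InteractionLRT(math.nan, math.nan, 0, int(ok.sum()), False, False,
                              False, "monomorphic pair member")

    prod_cols, prod_names = [], []
    for a in range(f1.shape[1]):
        for b in range(f2.shape[1]):
            prod_cols.append(f1[:, a] * f2[:, b])
            prod_names.append(f"{n1[a]}x{n2[b]}")
    products = np.column_stack(prod_cols)

    base = [np.ones((int(ok.sum()), 1)), C[ok]]
    base_names = ["intercept"] + list(cohort.covariates.columns)
    if extra_d:
        base.append(np.column_stack([ed[ok].astype(float) for ed in extra_d]))
        base_names += list(extras)
    reduced_X = np.column_stack([*base, f1, f2])
    reduced_names = base_names + n1 + n2
    reduced_X, kept_r, dropped_r = drop_collinear_columns(reduced_X, reduced_names)

    full_X = np.column_stack([reduced_X, products])
    full_names = [reduced_names[k] for k in kept_r] + prod_names
    full_X, kept_f, dropped_f = drop_collinear_columns(full_X, full_names)
    df = full_X.shape[1] - reduced_X.shape[1]
    if df <= 0:
        return InteractionLRT(math.nan, math.nan, 0, int(ok.sum()), False, False,
                              False, "interaction columns collinear with main effects")

    fit_r = logistic_fit(reduced_X, y)
    fit_f = logistic_fit(full_X, y)
    stat = max(0.0, 2.0 * (fit_f.loglik - fit_r.loglik))
    p = float(chi2.sf(stat, df))
    standard = df == 4
    note = "" if standard else f"reduced df={df} (absent genotype class or collinearity)"
    if dropped_r or dropped_f:
        log.debug("pair (%s,%s): dropped collinear columns %s", id1, id2,
                  dropped_r + dropped_f)
    return InteractionLRT(stat, p, df, int(ok.sum()),
                          fit_r.converged and fit_f.converged,
                          fit_r.separated or fit_f.separated, standard, note)


def interaction_logp(statistic: float, df: int) -> float:
    """log10 of the chi-square upper tail; safe far below float underflow."""
    return float(chi2.logsf(statistic, df) / math.log(10.0))


def test_pair(
    genotypes: GenotypeMatrix,
    cohort: CohortTable,
    pair: tuple[str, str],
    background: Sequence[str],
    cohort_label: str = "",
) -> EpistasisResult:
    """Unconditional + conditional LRT for one pair in one cohort."""
    uncond = interaction_lrt(genotypes, cohort, pair)
    cond = interaction_lrt(genotypes, cohort, pair, extra_covariates=background)
    note = "; ".join(s for s in (uncond.note, cond.note) if s)
    return EpistasisResult(
        pair[0], pair[1],
        uncond.statistic, uncond.p, cond.statistic, cond.p,
        uncond.df, cond.df, cond.n,
        uncond.converged and cond.converged,
        uncond.separated or cond.separated,
        cohort_label, note,
    )


# ---------------------------------------------------------------------------
# IPF oracle for the covariate-free reduced model
# ---------------------------------------------------------------------------

def ipf_homogeneous_fit(
    table: np.ndarray, tol: float = 1e-9, max_sweeps: int = 4000
) -> tuple[np.ndarray, float]:
    """Fit the log-linear model with all three two-way margins and no
    three-way term to a 2x3x3 table by iterative proportional fitting.

    Returns the fitted table (same total) and its multinomial log-likelihood
    at the observed counts.  Cells in margins with zero observed totals are
    structural zeros.  When the MLE lies on the boundary (sampling zeros
    force some fitted cells to zero), plain IPF converges only as O(1/t);
    such cells are detected by stalling, removed from the support, and the
    fit restarted, which restores geometric convergence.
    """
    n = np.asarray(table, dtype=float)
    if n.shape != (2, 3, 3):
        raise ValueError("table must be 2x3x3")
    N = n.sum()
    if N <= 0:
        raise ValueError("empty table")

    m_yg1 = n.sum(axis=2)  # (2,3)
    m_yg2 = n.sum(axis=1)  # (2,3)
    m_g1g2 = n.sum(axis=0)  # (3,3)
    margins = ((2, m_yg1), (1, m_yg2), (0, m_g1g2))

    support = ((m_yg1 > 0)[:, :, None]
               & (m_yg2 > 0)[:, None, :]
               & (m_g1g2 > 0)[None, :, :])
    if not support.any():
        raise ValueError("no supported cells")

    zero_cells = int(((n == 0) & support).sum())
    for _round in range(zero_cells + 1):
        fit = support.astype(float)
        fit *= N / fit.sum()
        disc = math.inf
        for sweep in range(max_sweeps):
            for axis, obs in margins:
                cur = fit.sum(axis=axis)
                with np.errstate(divide="ignore", invalid="ignore"):
                    ratio = np.where(cur > 0, obs / np.where(cur > 0, cur, 1.0), 0.0)
                fit *= np.expand_dims(ratio, axis)
            if sweep % 50 == 49 or sweep == max_sweeps - 1:
                disc = max(
                    np.abs(fit.sum(axis=2) - m_yg1).max(),
                    np.abs(fit.sum(axis=1) - m_yg2).max(),
                    np.abs(fit.sum(axis=0) - m_g1g2).max(),
                )
                if disc < tol:
                    break
        if disc < tol:
            mask = n > 0
            ll = float(np.sum(n[mask] * np.log(fit[mask] / N)))
            return fit, ll
        # stalled: the smallest fitted observed-zero cell is heading to the
        # boundary; remove it from the support and refit
        candidates = support & (n == 0)
        if not candidates.any():
            raise RuntimeError("IPF did not converge and no boundary cell found")
        idx = np.unravel_index(
            np.argmin(np.where(candidates, fit, np.inf)), fit.shape
        )
        support[idx] = False
    raise RuntimeError("IPF did not converge")


def saturated_loglik(table: np.ndarray) -> float:
    n = np.asarray(table, dtype=float)
    N = n.sum()
    mask = n > 0
    return float(np.sum(n[mask] * np.log(n[mask] / N)))


# ---------------------------------------------------------------------------
# Significance calls and replication
# ---------------------------------------------------------------------------

def call_significance(
    results: Sequence[EpistasisResult],
    genome_wide_p: float = GENOME_WIDE_P,
    chip_wide_p: float = CHIP_WIDE_P,
) -> list[SignificanceCall]:
    """Apply the fixed thresholds to the conditional P of each result."""
    calls = []
    for r in results:
        p = r.cond_p
        usable = p is not None and math.isfinite(p)
        gw = bool(usable and p < genome_wide_p)
        cw = bool(usable and p < chip_wide_p)
        calls.append(SignificanceCall(r.snp1, r.snp2, gw, cw,
                                      note="" if usable else "untestable"))
    return calls


def replicate(
    pairs: Sequence[tuple[str, str]],
    genotypes: GenotypeMatrix,
    cohort: CohortTable,
    background: Sequence[str],
    replication_p: float = REPLICATION_P,
) -> list[tuple[EpistasisResult, bool]]:
    """Rerun the conditional test in the replication cohort.

    A pair replicates iff its conditional interaction P < ``replication_p``.
    Untestable pairs are reported as not replicated with a diagnostic note.
    """
    out = []
    for pair in pairs:
        res = test_pair(genotypes, cohort, pair, background, cohort_label="replication")
        ok = math.isfinite(res.cond_p) and res.converged
        replicated = bool(ok and res.cond_p < replication_p)
        if not ok and not res.note:
            res.note = "untestable in replication"
        out.append((res, replicated))
    return out
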