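"""Genotype and cohort I/O: PLINK bed/bim/fam, covariate tables, results TSV.

Dosages count copies of allele2 (the second allele column of the .bim),
matching PLINK binary semantics.  Missing calls are stored as -1 in an
``int8`` matrix.  Only SNP-major .bed files are supported.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

MISSING = np.int8(-1)

_BED_MAGIC = bytes([0x6C, 0x1B])
_SNP_MAJOR = 0x01

# 2-bit PLINK code -> dosage of allele2 (-1 = missing)
_CODE_TO_DOSAGE = np.array([0, -1, 1, 2], dtype=np.int8)
_DOSAGE_TO_CODE = {0: 0b00, -1: 0b01, 1: 0b10, 2: 0b11}

#: canonical column order of the results dialect
RESULT_COLUMNS = [
    "SNP1", "Pos1", "Gene1", "SNP2", "Pos2", "Gene2", "LD",
    "P_SNP1", "P_SNP2", "P_SNP1xSNP2", "P_SNP1xSNP2_Cond",
    "P_SNP1_rep", "P_SNP2_rep", "P_SNP1xSNP2_rep", "P_SNP1xSNP2_Cond_rep",
    "Replicated", "InMHC",
]
_P_COLUMNS = {c for c in RESULT_COLUMNS if c.startswith("P_")}


class GenotypeFileError(ValueError):
    """Raised for malformed PLINK triplets or covariate files."""


@dataclass
class GenotypeMatrix:
    """samples x markers dosage matrix plus marker metadata.

    dosages: int8 array of shape (n_samples, n_markers); values {0,1,2,-1}.
    markers: DataFrame with columns id, chrom, pos, a1, a2.
    samples: sample identifiers (IID), aligned to dosage rows.
    """

    dosages: np.ndarray
    markers: pd.DataFrame
    samples: list[str]
    counted_allele: str = "a2"

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=np.int8)
        if self.dosages.ndim != 2:
            raise ValueError("dosages must be 2-D (samples x markers)")
        n, m = self.dosages.shape
        if len(self.samples) != n:
            raise ValueError("sample identifiers do not match dosage rows")
        if len(self.markers) != m:
            raise ValueError("marker table does not match dosage columns")
        ids = self.markers["id"]
        if ids.duplicated().any():
            dup = ids[ids.duplicated()].iloc[0]
            raise ValueError(f"duplicate marker identifier: {dup}")
        if (self.markers["pos"].to_numpy() < 0).any():
            raise ValueError("marker positions must be non-negative")
        self.markers = self.markers.reset_index(drop=True)
        self._index: dict[str, int] = {s: i for i, s in enumerate(ids)}

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_markers(self) -> int:
        return self.dosages.shape[1]

    @property
    def marker_ids(self) -> list[str]:
        return list(self.markers["id"])

    def marker_index(self, marker_id: str) -> int:
        try:
            return self._index[marker_id]
        except KeyError:
            raise KeyError(f"unknown marker identifier: {marker_id}") from None

    def dosage(self, marker: str | int) -> np.ndarray:
        j = marker if isinstance(marker, (int, np.integer)) else self.marker_index(marker)
        return self.dosages[:, j]

    def subset_markers(self, index: Sequence[int] | np.ndarray) -> "GenotypeMatrix":
        index = np.asarray(index)
        return GenotypeMatrix(
            self.dosages[:, index],
            self.markers.iloc[index].reset_index(drop=True),
            list(self.samples),
            self.counted_allele,
        )

    def subset_samples(self, index: Sequence[int] | np.ndarray) -> "GenotypeMatrix":
        index = np.asarray(index)
        return GenotypeMatrix(
            self.dosages[index, :],
            self.markers.copy(),
            [self.samples[i] for i in index],
            self.counted_allele,
        )

    def allele2_frequency(self, marker: str | int) -> float:
        """Frequency of the counted allele among non-missing calls."""
        d = self.dosage(marker)
        ok = d >= 0
        if not ok.any():
            return math.nan
        return float(d[ok].mean() / 2.0)


@dataclass
class CohortTable:
    """Per-sample binary status and numeric covariates, aligned to a GenotypeMatrix."""

    samples: list[str]
    status: np.ndarray
    covariates: pd.DataFrame
    excluded: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.status = np.asarray(self.status, dtype=np.int8)
        if self.status.shape != (len(self.samples),):
            raise ValueError("status length does not match samples")
        bad = set(np.unique(self.status)) - {0, 1}
        if bad:
            raise ValueError(f"status must be 0/1; found {sorted(bad)}")
        if len(self.covariates) != len(self.samples):
            raise ValueError("covariate rows do not match samples")
        self.covariates = self.covariates.reset_index(drop=True)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def covariate_matrix(self) -> np.ndarray:
        return self.covariates.to_numpy(dtype=float)

    def subset(self, index: Sequence[int] | np.ndarray) -> "CohortTable":
        index = np.asarray(index)
        return CohortTable(
            [self.samples[i] for i in index],
            self.status[index],
            self.covariates.iloc[index].reset_index(drop=True),
            list(self.excluded),
        )


# ---------------------------------------------------------------------------
# PLINK bed/bim/fam
# ---------------------------------------------------------------------------

def read_plink(prefix: str | Path) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Read a PLINK bed/bim/fam triplet.

    Returns the genotype matrix and the fam table
    (columns fid, iid, father, mother, sex, phenotype).
    """
    prefix = Path(prefix)
    bed_path = prefix.with_suffix(".bed")
    bim_path = prefix.with_suffix(".bim")
    fam_path = prefix.with_suffix(".fam")
    for p in (bed_path, bim_path, fam_path):
        if not p.exists():
            raise GenotypeFileError(f"missing file: {p}")

    fam = pd.read_csv(
        fam_path, sep=r"\s+", header=None,
        names=["fid", "iid", "father", "mother", "sex", "phenotype"],
        dtype={"fid": str, "iid": str},
    )
    bim = pd.read_csv(
        bim_path, sep=r"\s+", header=None,
        names=["chrom", "id", "cm", "pos", "a1", "a2"],
        dtype={"chrom": str, "id": str, "a1": str, "a2": str},
    )
    n, m = len(fam), len(bim)

    raw = bed_path.read_bytes()
    if len(raw) < 3 or raw[:2] != _BED_MAGIC:
        raise GenotypeFileError(f"bad magic bytes in {bed_path}")
    if raw[2] != _SNP_MAJOR:
        raise GenotypeFileError(
            f"unsupported bed mode 0x{raw[2]:02x} in {bed_path}: only SNP-major supported"
        )
    bytes_per_marker = (n + 3) // 4
    expected = 3 + bytes_per_marker * m
    if len(raw) != expected:
        raise GenotypeFileError(
            f"truncated or oversized bed file {bed_path}: "
            f"expected {expected} bytes for {n} samples x {m} markers, got {len(raw)}"
        )

    body = np.frombuffer(raw, dtype=np.uint8, offset=3).reshape(m, bytes_per_marker)
    # expand each byte into four 2-bit codes (sample k uses bits 2k..2k+1)
    codes = np.empty((m, bytes_per_marker * 4), dtype=np.uint8)
    for k in range(4):
        codes[:, k::4] = (body >> (2 * k)) & 0b11
    dosages = _CODE_TO_DOSAGE[codes[:, :n]].T.copy()

    gm = GenotypeMatrix(
        dosages,
        bim[["id", "chrom", "pos", "a1", "a2"]].copy(),
        list(fam["iid"]),
    )
    return gm, fam


def write_plink(
    prefix: str | Path,
    genotypes: GenotypeMatrix,
    status: np.ndarray | None = None,
    fid: Sequence[str] | None = None,
) -> None:
    """Write bed/bim/fam.  Phenotype column is 1/2 if status given, else -9."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    n, m = genotypes.n_samples, genotypes.n_markers

    fids = list(fid) if fid is not None else list(genotypes.samples)
    pheno = (np.asarray(status) + 1) if status is not None else np.full(n, -9, dtype=int)
    fam = pd.DataFrame(
        {"fid": fids, "iid": genotypes.samples, "father": 0, "mother": 0,
         "sex": 0, "phenotype": pheno}
    )
    fam.to_csv(prefix.with_suffix(".fam"), sep="\t", header=False, index=False)

    mk = genotypes.markers
    bim = pd.DataFrame(
        {"chrom": mk["chrom"], "id": mk["id"], "cm": 0, "pos": mk["pos"],
         "a1": mk["a1"], "a2": mk["a2"]}
    )
    bim.to_csv(prefix.with_suffix(".bim"), sep="\t", header=False, index=False)

    code_lut = np.zeros(4, dtype=np.uint8)
    for dosage, code in _DOSAGE_TO_CODE.items():
        code_lut[dosage % 4] = code  # -1 wraps to index 3
    codes = code_lut[genotypes.dosages.T % 4]  # (m, n)
    pad = (-n) % 4
    if pad:
        codes = np.concatenate(
            [codes, np.zeros((m, pad), dtype=np.uint8)], axis=1
        )
    packed = np.zeros((m, codes.shape[1] // 4), dtype=np.uint8)
    for k in range(4):
        packed |= codes[:, k::4] << (2 * k)
    with open(prefix.with_suffix(".bed"), "wb") as fh:
        fh.write(_BED_MAGIC + bytes([_SNP_MAJOR]))
        fh.write(packed.tobytes())


# ---------------------------------------------------------------------------
# Covariate tables
# ---------------------------------------------------------------------------

def read_covariates(path: str | Path, fam: pd.DataFrame) -> CohortTable:
    """Read a whitespace/tab-delimited covariate file with FID+IID keys.

    Rows are aligned to the fam sample order; samples without covariate rows
    are kept but flagged in ``excluded`` (their covariates are NaN and drop
    out of complete-case fits).  Case/control status is taken from the fam
    phenotype column (1=control, 2=case; anything else is treated as missing
    and excluded).
    """
    path = Path(path)
    tab = pd.read_csv(path, sep=r"\s+", dtype={0: str, 1: str})
    cols = list(tab.columns)
    if len(cols) < 2 or cols[0].upper() != "FID" or cols[1].upper() != "IID":
        raise GenotypeFileError(f"{path}: first two columns must be FID and IID")
    if tab["IID" if "IID" in tab.columns else cols[1]].duplicated().any():
        dup = tab[cols[1]][tab[cols[1]].duplicated()].iloc[0]
        raise GenotypeFileError(f"{path}: duplicated IID {dup}")
    covar_cols = cols[2:]
    for c in covar_cols:
        coerced = pd.to_numeric(tab[c], errors="coerce")
        bad = coerced.isna() & tab[c].notna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise GenotypeFileError(
                f"{path}: non-numeric value {tab[c].iloc[row]!r} "
                f"in column {c}, row {row + 2}"
            )
        tab[c] = coerced

    tab = tab.set_index(cols[1])
    aligned = tab.reindex(fam["iid"])
    excluded = [iid for iid in fam["iid"] if iid not in tab.index]

    pheno = fam["phenotype"].to_numpy()
    status = np.where(pheno == 2, 1, 0).astype(np.int8)
    covariates = aligned[covar_cols].reset_index(drop=True)
    for iid in np.asarray(fam["iid"])[~np.isin(pheno, (1, 2))]:
        if iid not in excluded:
            excluded.append(iid)
            covariates.loc[list(fam["iid"]).index(iid)] = np.nan
    return CohortTable(list(fam["iid"]), status, covariates, excluded)


def write_covariates(path: str | Path, cohort: CohortTable,
                     fid: Sequence[str] | None = None) -> None:
    fids = list(fid) if fid is not None else list(cohort.samples)
    out = cohort.covariates.copy()
    out.insert(0, "IID", cohort.samples)
    out.insert(0, "FID", fids)
    out.to_csv(Path(path), sep="\t", index=False)


# ---------------------------------------------------------------------------
# Results TSV (the dialect of the final pair report)
# ---------------------------------------------------------------------------

def _format_cell(column: str, value) -> str:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return "NA"
    if column in _P_COLUMNS:
        return f"{float(value):.2E}"
    if column == "LD":
        return f"{float(value):.3f}"
    if isinstance(value, (bool, np.bool_)):
        return "yes" if value else "no"
    if isinstance(value, float) and value.is_integer():
        return str(int(value))
    return str(value)


def write_results(records: Iterable[Mapping], path: str | Path) -> None:
    """Write pair results as TSV.

    One header line; P-values rendered in scientific notation with three
    significant digits; rows ordered by discovery conditional P ascending,
    ties broken by (SNP1, SNP2).
    """
    records = [dict(r) for r in records]
    present = [c for c in RESULT_COLUMNS if any(c in r for r in records)]
    if not present:
        present = RESULT_COLUMNS[:11]

    def sort_key(r: Mapping):
        p = r.get("P_SNP1xSNP2_Cond")
        p = math.inf if p is None or (isinstance(p, float) and math.isnan(p)) else float(p)
        return (p, str(r.get("SNP1", "")), str(r.get("SNP2", "")))

    lines = ["\t".join(present)]
    for r in sorted(records, key=sort_key):
        lines.append("\t".join(_format_cell(c, r.get(c)) for c in present))
    Path(path).write_text("\n".join(lines) + "\n")


def read_results(path: str | Path) -> pd.DataFrame:
    """Read a results TSV written by :func:`write_results` (or hand-built in
    the same dialect).  P columns and LD become floats."""
    df = pd.read_csv(Path(path), sep="\t", dtype=str, na_values=["NA"])
    for c in df.columns:
        if c in _P_COLUMNS or c in ("LD",):
            df[c] = pd.to_numeric(df[c])
        elif c in ("Pos1", "Pos2"):
            df[c] = pd.to_numeric(df[c]).astype("Int64")
    return df
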