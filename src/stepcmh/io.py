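"""Reading and writing genotype/phenotype tables.

Two genotype formats are supported:

* ``delimited`` — header row of SNP ids, first column the sample id, cells
  the minor-allele counts 0/1/2 with ``NA`` or ``-9`` for missing calls
  (TSV or CSV; the delimiter is sniffed);
* ``plink_raw`` — a PLINK additive-recode text table (``--recode A``): the
  six leading columns FID IID PAT MAT SEX PHENOTYPE followed by one
  ``SNP_allele`` column per marker counting the coded allele.
"""

from __future__ import annotations

import csv
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import ParseError, ValidationError
from .genotypes import GenotypeMatrix

__all__ = [
    "read_genotypes",
    "write_genotypes",
    "read_phenotype",
    "write_phenotype",
]

_PLINK_META = ("FID", "IID", "PAT", "MAT", "SEX", "PHENOTYPE")
_MISSING_TOKENS = {"NA", "-9", "", "NAN"}


def _sniff_sep(path: Path) -> str:
    with open(path, newline="") as fh:
        sample = fh.read(4096)
    try:
        return csv.Sniffer().sniff(sample, delimiters="\t,; ").delimiter
    except csv.Error:
        return "\t"


def _validate_codes(df: pd.DataFrame, path) -> np.ndarray:
    raw = df.to_numpy()
    codes = np.full(raw.shape, -1.0)
    for val, out in (("0", 0), ("1", 1), ("2", 2)):
        codes[raw == val] = out
    bad = np.array(
        [str(v).strip().upper() not in _MISSING_TOKENS for v in raw.ravel()]
    ).reshape(raw.shape) & (codes == -1.0)
    if bad.any():
        i, j = map(int, np.argwhere(bad)[0])
        raise ValidationError(
            f"{path}: invalid genotype code {raw[i, j]!r} for sample "
            f"{df.index[i]!r}, SNP {df.columns[j]!r}"
        )
    return codes


def read_genotypes(path, format: str = "delimited") -> GenotypeMatrix:
    """Read a genotype table into a :class:`GenotypeMatrix`."""
    path = Path(path)
    if not path.exists():
        raise ParseError(f"no such file: {path}")
    sep = _sniff_sep(path)
    try:
        df = pd.read_csv(path, sep=sep, dtype=str, index_col=0)
    except Exception as exc:
        raise ParseError(f"could not parse {path}: {exc}") from exc
    if format == "plink_raw":
        missing_meta = [c for c in _PLINK_META[1:] if c not in df.columns]
        if missing_meta:
            raise ParseError(
                f"{path}: not a PLINK .raw table (missing {missing_meta})"
            )
        df = df.drop(columns=list(_PLINK_META[1:]), errors="ignore")
        # Strip the counted-allele suffix PLINK appends (e.g. rs123_A).
        df.columns = [c.rsplit("_", 1)[0] if "_" in c else c for c in df.columns]
    elif format != "delimited":
        raise ValidationError(f"unknown genotype format {format!r}")
    if df.shape[1] == 0:
        raise ParseError(f"{path}: no SNP columns found")
    df = df.astype(str).apply(lambda s: s.str.strip())
    codes = _validate_codes(df, path)
    return GenotypeMatrix(codes, list(df.columns), [str(s) for s in df.index])


def write_genotypes(genos: GenotypeMatrix, path, sep: str = "\t") -> None:
    """Write the delimited genotype format (missing calls as NA)."""
    df = genos.to_frame()
    df.index.name = "sample_id"
    df.to_csv(path, sep=sep, na_rep="NA")


def read_phenotype(path, samples: list[str] | None = None) -> np.ndarray:
    """Read a two-column sample/trait table; returns float codes (NaN missing).

    Trait values must be non-negative integer level codes; when ``samples``
    is given the result is aligned to that order.
    """
    path = Path(path)
    if not path.exists():
        raise ParseError(f"no such file: {path}")
    try:
        df = pd.read_csv(path, sep=_sniff_sep(path), dtype=str)
    except Exception as exc:
        raise ParseError(f"could not parse {path}: {exc}") from exc
    if df.shape[1] < 2:
        raise ParseError(f"{path}: expected sample and trait columns")
    ids = df.iloc[:, 0].astype(str)
    vals = df.iloc[:, 1].astype(str).str.strip()
    out = pd.Series(np.nan, index=ids, dtype=float)
    ok = ~vals.str.upper().isin(_MISSING_TOKENS)
    try:
        out[ok.to_numpy()] = vals[ok].astype(float).to_numpy()
    except ValueError as exc:
        raise ValidationError(f"{path}: non-numeric trait value ({exc})") from exc
    codes = out.to_numpy()
    finite = codes[~np.isnan(codes)]
    if finite.size and (np.any(finite < 0) or np.any(finite != finite.astype(int))):
        raise ValidationError(f"{path}: trait codes must be integers >= 0")
    if samples is not None:
        out = out.reindex([str(s) for s in samples])
        codes = out.to_numpy()
    return codes


def write_phenotype(pheno: np.ndarray, samples: list[str], path,
                    sep: str = "\t") -> None:
    vals = pd.Series(pheno, index=samples, name="trait")
    frame = vals.map(lambda v: "NA" if pd.isna(v) else str(int(v))).to_frame()
    frame.index.name = "sample_id"
    frame.to_csv(path, sep=sep)
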