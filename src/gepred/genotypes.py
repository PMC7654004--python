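"""SNP dosage matrix container and plain-text genotype I/O.

Dosages count copies of the reference allele (0/1/2); missing calls are
stored as NaN so the matrix stays a single float array.  Two text dialects
are supported: PLINK ``.raw``-style (header ``FID IID PAT MAT SEX PHENOTYPE``
followed by one column per SNP, ``NA`` for missing) and a bare delimited
matrix with a header row of marker names and an ``id`` column.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["GenotypeMatrix", "read_raw", "write_raw", "read_matrix", "write_matrix",
           "read_genotypes"]


@dataclass
class GenotypeMatrix:
    """Individuals x markers dosage matrix with missing mask.

    Parameters
    ----------
    ids : array-like of str
        Individual identifiers, one per row.
    dosages : ndarray, shape (n, m)
        Reference-allele counts in {0, 1, 2}; NaN marks a missing call.
        After mean imputation entries may be real-valued.
    marker_names : array-like of str, optional
        One name per column; generated as ``snp0001`` ... if omitted.
    """

    ids: np.ndarray
    dosages: np.ndarray
    marker_names: np.ndarray = field(default=None)

    def __post_init__(self):
        self.ids = np.asarray(self.ids, dtype=str)
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.ndim != 2:
            raise ValueError("dosages must be a 2-D matrix")
        if len(self.ids) != self.dosages.shape[0]:
            raise ValueError("ids length does not match dosage rows")
        if self.marker_names is None:
            width = max(4, len(str(self.dosages.shape[1])))
            self.marker_names = np.array(
                [f"snp{j + 1:0{width}d}" for j in range(self.dosages.shape[1])]
            )
        else:
            self.marker_names = np.asarray(self.marker_names, dtype=str)
        if len(self.marker_names) != self.dosages.shape[1]:
            raise ValueError("marker_names length does not match dosage columns")

    @property
    def n(self) -> int:
        return self.dosages.shape[0]

    @property
    def m(self) -> int:
        return self.dosages.shape[1]

    @property
    def missing_mask(self) -> np.ndarray:
        return np.isnan(self.dosages)

    @property
    def allele_freqs(self) -> np.ndarray:
        """Observed frequency of the counted allele per marker (missing ignored)."""
        with np.errstate(invalid="ignore"):
            freq = np.nanmean(self.dosages, axis=0) / 2.0
        return freq

    def subset_markers(self, keep: np.ndarray) -> "GenotypeMatrix":
        return GenotypeMatrix(self.ids, self.dosages[:, keep],
                              self.marker_names[keep])

    def subset_individuals(self, keep_ids) -> "GenotypeMatrix":
        keep_ids = np.asarray(keep_ids, dtype=str)
        pos = {iid: i for i, iid in enumerate(self.ids)}
        rows = np.array([pos[i] for i in keep_ids])
        return GenotypeMatrix(keep_ids, self.dosages[rows], self.marker_names)


def write_raw(G: GenotypeMatrix, path, sex=None) -> None:
    """Write PLINK .raw-style whitespace-delimited text."""
    n = G.n
    df = pd.DataFrame({
        "FID": np.repeat("0", n),
        "IID": G.ids,
        "PAT": np.repeat("0", n),
        "MAT": np.repeat("0", n),
        "SEX": np.zeros(n, dtype=int) if sex is None else np.asarray(sex),
        "PHENOTYPE": np.repeat(-9, n),
    })
    dos = pd.DataFrame(G.dosages, columns=G.marker_names)
    # integral dosages print as integers, imputed reals keep decimals
    for c in dos.columns:
        col = dos[c]
        if np.all(np.isnan(col) | (col == np.round(col))):
            dos[c] = col.astype("Int64")
    out = pd.concat([df, dos], axis=1)
    out.to_csv(path, sep=" ", index=False, na_rep="NA")


def read_raw(path) -> GenotypeMatrix:
    df = pd.read_csv(path, sep=r"\s+", na_values=["NA"])
    meta = ["FID", "IID", "PAT", "MAT", "SEX", "PHENOTYPE"]
    missing_cols = [c for c in meta if c not in df.columns]
    if missing_cols:
        raise ValueError(f"not a .raw file: missing columns {missing_cols}")
    snps = [c for c in df.columns if c not in meta]
    return GenotypeMatrix(df["IID"].astype(str).to_numpy(),
                          df[snps].to_numpy(dtype=float),
                          np.array(snps))


def write_matrix(G: GenotypeMatrix, path, sep=",") -> None:
    df = pd.DataFrame(G.dosages, columns=G.marker_names)
    df.insert(0, "id", G.ids)
    df.to_csv(path, sep=sep, index=False, na_rep="NA")


def read_matrix(path, sep=",") -> GenotypeMatrix:
    df = pd.read_csv(path, sep=sep, na_values=["NA"])
    if "id" not in df.columns:
        raise ValueError("delimited genotype matrix needs an 'id' column")
    snps = [c for c in df.columns if c != "id"]
    return GenotypeMatrix(df["id"].astype(str).to_numpy(),
                          df[snps].to_numpy(dtype=float),
                          np.array(snps))


def read_genotypes(path) -> GenotypeMatrix:
    """Auto-detect the dialect from the header line."""
    with open(path) as fh:
        header = fh.readline()
    if header.split()[:2] == ["FID", "IID"]:
        return read_raw(path)
    return read_matrix(path)
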