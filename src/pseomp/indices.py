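"""Physicochemical amino-acid index tables.

An index assigns one real value to each of the 20 standard amino acids
(a hydropathy scale, a polarity scale, ...).  Before entering the
sequence-order correlation of the pseudo amino acid composition each
index is standardized to zero mean and unit standard deviation over the
20 amino acids, which removes units and makes scales commensurable.

A small registry of named scales ships with the package, keyed by their
AAindex accessions; the default trio covers hydropathy, polarity and
solvation free energy.  Values are data, not algorithm: any table can be
replaced by a user-supplied TSV (rows = amino acids, columns = indices).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .seq_io import AMINO_ACIDS

# Registry of built-in scales.  Values listed in the alphabetical
# amino-acid order A C D E F G H I K L M N P Q R S T V W Y.
BUILTIN_INDICES: dict[str, dict[str, float]] = {
    # Kyte & Doolittle (1982) hydropathy
    "KYTJ820101": dict(
        zip(
            AMINO_ACIDS,
            [1.8, 2.5, -3.5, -3.5, 2.8, -0.4, -3.2, 4.5, -3.9, 3.8,
             1.9, -3.5, -1.6, -3.5, -4.5, -0.8, -0.7, 4.2, -0.9, -1.3],
        )
    ),
    # Grantham (1974) polarity
    "GRAR740102": dict(
        zip(
            AMINO_ACIDS,
            [8.1, 5.5, 13.0, 12.3, 5.2, 9.0, 10.4, 5.2, 11.3, 4.9,
             5.7, 11.6, 8.0, 10.5, 10.5, 9.2, 8.6, 5.9, 5.4, 6.2],
        )
    ),
    # Eisenberg & McLachlan (1986) solvation free energy (kcal/mol)
    "EISD860101": dict(
        zip(
            AMINO_ACIDS,
            [0.67, 0.38, -1.2, -0.76, 2.3, 0.0, 0.64, 1.9, -0.57, 1.9,
             2.4, -0.6, 1.2, -0.22, -2.1, 0.01, 0.52, 1.5, 2.6, 1.6],
        )
    ),
}

#: Default hydropathy / polarity / solvation trio.
DEFAULT_INDEX_NAMES = ("KYTJ820101", "GRAR740102", "EISD860101")


@dataclass(frozen=True)
class AminoAcidIndexTable:
    """Ordered set of named physicochemical indices over the 20 amino acids.

    ``values`` has shape (n_indices, 20), columns in the alphabetical
    amino-acid order of :data:`pseomp.seq_io.AMINO_ACIDS`.
    """

    names: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        if vals.ndim != 2 or vals.shape[1] != 20:
            raise ValueError(f"index table must be (Gamma, 20), got {vals.shape}")
        if len(self.names) != vals.shape[0]:
            raise ValueError("number of names must match number of index rows")
        if vals.shape[0] < 1:
            raise ValueError("need at least one index")
        if not np.all(np.isfinite(vals)):
            raise ValueError("index table contains non-finite values")
        object.__setattr__(self, "values", vals)

    @property
    def n_indices(self) -> int:
        return self.values.shape[0]

    def standardized(self) -> "AminoAcidIndexTable":
        """Return the table with each index at mean 0, SD 1 over the 20 AAs.

        SD is the population standard deviation (ddof=0).  A constant
        index has no information and is rejected.
        """
        mu = self.values.mean(axis=1, keepdims=True)
        sd = self.values.std(axis=1, keepdims=True)
        for k, s in enumerate(sd.ravel()):
            if s == 0.0:
                raise ValueError(
                    f"index {self.names[k]!r} is constant over the 20 amino acids"
                )
        return AminoAcidIndexTable(self.names, (self.values - mu) / sd)

    def content_hash(self) -> str:
        """Stable hash of names + values, for model-file provenance."""
        import hashlib

        h = hashlib.sha256()
        h.update(",".join(self.names).encode())
        h.update(np.ascontiguousarray(self.values).tobytes())
        return h.hexdigest()[:16]


def default_index_table() -> AminoAcidIndexTable:
    """The built-in hydropathy/polarity/solvation trio (raw values)."""
    return index_table_from_registry(DEFAULT_INDEX_NAMES)


def index_table_from_registry(names: tuple[str, ...] | list[str]) -> AminoAcidIndexTable:
    rows = []
    for name in names:
        if name not in BUILTIN_INDICES:
            raise KeyError(
                f"unknown index {name!r}; built-ins: {sorted(BUILTIN_INDICES)}"
            )
        scale = BUILTIN_INDICES[name]
        rows.append([scale[aa] for aa in AMINO_ACIDS])
    return AminoAcidIndexTable(tuple(names), np.array(rows, dtype=float))


def read_index_tsv(path: str | Path) -> AminoAcidIndexTable:
    """Read an index table from TSV.

    Layout: header row ``aa<TAB>name1<TAB>name2...``, then one row per
    amino acid (single-letter code) with one value per index.  All 20
    amino acids must be present exactly once.
    """
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if len(header) < 2:
            raise ValueError(f"{path}: header must have an aa column plus >=1 index")
        names = tuple(header[1:])
        rows: dict[str, list[float]] = {}
        for lineno, line in enumerate(fh, 2):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != len(header):
                raise ValueError(f"{path}:{lineno}: expected {len(header)} columns")
            aa = parts[0].upper()
            if aa not in AMINO_ACIDS:
                raise ValueError(f"{path}:{lineno}: unknown amino acid {parts[0]!r}")
            if aa in rows:
                raise ValueError(f"{path}:{lineno}: duplicate amino acid {aa!r}")
            rows[aa] = [float(x) for x in parts[1:]]
    missing = sorted(set(AMINO_ACIDS) - set(rows))
    if missing:
        raise ValueError(f"{path}: missing amino acid rows {missing}")
    values = np.array([[rows[aa][k] for aa in AMINO_ACIDS] for k in range(len(names))])
    return AminoAcidIndexTable(names, values)


def write_index_tsv(table: AminoAcidIndexTable, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("aa\t" + "\t".join(table.names) + "\n")
        for j, aa in enumerate(AMINO_ACIDS):
            vals = "\t".join(repr(float(v)) for v in table.values[:, j])
            fh.write(f"{aa}\t{vals}\n")
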