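"""Amino-acid composition and type-I pseudo amino acid composition.

A sequence of length L is encoded as a (20 + λ)-vector

    x_u     = f_u / (1 + ω Σ_τ θ_τ)          u = 1..20
    x_{20+τ} = ω θ_τ / (1 + ω Σ_τ θ_τ)        τ = 1..λ

where f_u are the residue fractions (the classic composition), and the
tier correlation factor

    θ_τ = (1/(L−τ)) Σ_{i=1}^{L−τ} Θ(R_i, R_{i+τ}),
    Θ(R_i, R_j) = (1/Γ) Σ_k [H_k(R_j) − H_k(R_i)]²

averages the squared differences of Γ standardized physicochemical
indices H_k over all residue pairs at lag τ.  The components are
non-negative and sum to one; with λ = 0 the encoding reduces exactly to
the plain composition.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .indices import AminoAcidIndexTable, default_index_table
from .seq_io import AMINO_ACIDS, DatasetManifest

_AA_TO_IDX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}

NORMALIZATION_TOL = 1e-9


@dataclass(frozen=True)
class PseAACConfig:
    """Encoding parameters: λ sequence-order tiers, weight ω, index set."""

    lam: int = 5
    weight: float = 0.5
    index_table: AminoAcidIndexTable = field(default_factory=default_index_table)

    def __post_init__(self) -> None:
        if self.lam < 0:
            raise ValueError(f"lam must be >= 0, got {self.lam}")
        if not self.weight > 0:
            raise ValueError(f"weight must be > 0, got {self.weight}")

    @property
    def n_features(self) -> int:
        return 20 + self.lam


def _encode_indices(sequence: str) -> np.ndarray:
    try:
        return np.array([_AA_TO_IDX[c] for c in sequence], dtype=np.intp)
    except KeyError as exc:
        raise ValueError(f"non-standard residue {exc.args[0]!r} in sequence") from None


def compute_aac(sequence: str) -> np.ndarray:
    """Residue-fraction 20-vector in alphabetical amino-acid order."""
    if not sequence:
        raise ValueError("cannot compute composition of an empty sequence")
    idx = _encode_indices(sequence)
    counts = np.bincount(idx, minlength=20).astype(float)
    return counts / len(sequence)


def correlation_factor(
    sequence: str, tau: int, table: AminoAcidIndexTable
) -> float:
    """Tier correlation factor θ_τ over standardized indices.

    Requires L > τ (at least one residue pair at lag τ).  θ_τ ≥ 0 and is
    invariant under sequence reversal.
    """
    if tau < 1:
        raise ValueError(f"tau must be >= 1, got {tau}")
    L = len(sequence)
    if L <= tau:
        raise ValueError(f"sequence shorter than lag: L={L}, tau={tau}")
    H = table.standardized().values  # (Gamma, 20)
    idx = _encode_indices(sequence)
    diffs = H[:, idx[tau:]] - H[:, idx[:-tau]]  # (Gamma, L-tau)
    theta_pairs = np.mean(diffs**2, axis=0)  # mean over indices
    return float(np.mean(theta_pairs))  # mean over pairs


def compute_pseaac(sequence: str, config: PseAACConfig) -> np.ndarray:
    """Full (20 + λ)-component pseudo amino acid composition vector."""
    L = len(sequence)
    if L <= config.lam:
        raise ValueError(
            f"sequence length {L} must exceed lam={config.lam} for encoding"
        )
    f = compute_aac(sequence)
    if config.lam == 0:
        return f
    H = config.index_table.standardized().values
    idx = _encode_indices(sequence)
    thetas = np.empty(config.lam)
    for t in range(1, config.lam + 1):
        diffs = H[:, idx[t:]] - H[:, idx[:-t]]
        thetas[t - 1] = np.mean(np.mean(diffs**2, axis=0))
    denom = 1.0 + config.weight * thetas.sum()
    out = np.concatenate([f / denom, config.weight * thetas / denom])
    assert abs(out.sum() - 1.0) <= NORMALIZATION_TOL
    return out


def encode_dataset(
    manifest: DatasetManifest, config: PseAACConfig
) -> tuple[np.ndarray, np.ndarray]:
    """Encode every record; rows follow manifest order.

    Returns ``(X, y)`` with X of shape (n, 20+λ) and y the 0/1 labels.
    Fails fast, listing every record too short for the requested λ —
    rows are never silently dropped.
    """
    too_short = [r.id for r in manifest if len(r) <= config.lam]
    if too_short:
        raise ValueError(
            f"sequences shorter than lam+1={config.lam + 1} cannot be encoded: "
            + ", ".join(too_short)
        )
    X = np.empty((len(manifest), config.n_features))
    for i, rec in enumerate(manifest):
        X[i] = compute_pseaac(rec.sequence, config)
    y = np.asarray(manifest.labels(), dtype=int)
    return X, y


def write_features_tsv(
    manifest: DatasetManifest, X: np.ndarray, path, lam: int
) -> None:
    """Feature table as TSV: id, label, x1..x{20+λ}."""
    header = ["id", "label"] + [f"x{u}" for u in range(1, 21 + lam)]
    with open(path, "w") as fh:
        fh.write("\t".join(header) + "\n")
        for rec, row in zip(manifest, X):
            vals = "\t".join(repr(float(v)) for v in row)
            fh.write(f"{rec.id}\t{rec.label.value}\t{vals}\n")


def write_features_libsvm(X: np.ndarray, y: np.ndarray, path) -> None:
    """Sparse ``label idx:val`` format (1-based indices), LIBSVM-compatible."""
    with open(path, "w") as fh:
        for label, row in zip(y, X):
            parts = [f"{int(label)}"]
            for j, v in enumerate(row, start=1):
                if v != 0.0:
                    parts.append(f"{j}:{v:.17g}")
            fh.write(" ".join(parts) + "\n")
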