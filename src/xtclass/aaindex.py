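"""Embedded AAindex amino-acid property scales.

The package ships a block of 531 complete AAindex property tables (20
numeric values each, one per standard residue) so that descriptor
extraction needs no downloads.  Values are keyed by the canonical AAindex
accession (e.g. ``DAYM780201`` — Dayhoff relative mutability,
``BIGC670101`` — Bigelow residue volume).

Properties are standardized (z-score over the 20 residues) before use in
correlation-type descriptors, which is the convention of the protr-style
descriptor toolkits this module mirrors.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, replace

import numpy as np

#: The 20 standard residues in AAindex order.
AAINDEX_ORDER = "ARNDCQEGHILKMFPSTWYV"

#: The 20 standard residues in alphabetical order (feature-name order).
ALPHABET = "ACDEFGHIKLMNPQRSTVWY"

#: Hydrophobicity / hydrophilicity accessions used by the amphiphilic
#: pseudo-amino-acid composition.
HYDROPHOBICITY = "ARGP820101"
HYDROPHILICITY = "HOPT810101"


@dataclass(frozen=True)
class PropertyTable:
    """One AAindex property: a numeric value for each standard residue."""

    accession: str
    values: dict[str, float]
    standardized: bool = False

    def __post_init__(self) -> None:
        if sorted(self.values) != sorted(ALPHABET):
            raise ValueError(
                f"property {self.accession!r} must key exactly the 20 "
                f"standard residues"
            )
        if self.standardized:
            arr = np.array([self.values[a] for a in ALPHABET])
            if abs(arr.mean()) > 1e-9 or abs(arr.std() - 1.0) > 1e-9:
                raise ValueError(
                    f"property {self.accession!r} marked standardized but "
                    f"mean/sd are {arr.mean():.3g}/{arr.std():.3g}"
                )

    def standardize(self) -> "PropertyTable":
        """Return a z-scored copy (mean 0, sd 1 over the 20 residues)."""
        if self.standardized:
            return self
        arr = np.array([self.values[a] for a in ALPHABET], dtype=float)
        sd = arr.std()
        if sd == 0:
            raise ValueError(f"property {self.accession!r} is constant")
        arr = (arr - arr.mean()) / sd
        return replace(
            self,
            values=dict(zip(ALPHABET, arr.tolist())),
            standardized=True,
        )

    def as_array(self) -> np.ndarray:
        """Values as a vector in :data:`ALPHABET` order."""
        return np.array([self.values[a] for a in ALPHABET], dtype=float)


def _read_block() -> dict[str, PropertyTable]:
    path = importlib.resources.files("xtclass.data") / "aaindex_block.tsv"
    tables: dict[str, PropertyTable] = {}
    for line in path.read_text().splitlines():
        if not line.strip():
            continue
        parts = line.split("\t")
        acc, vals = parts[0], [float(x) for x in parts[1:]]
        if len(vals) != 20:
            raise ValueError(f"malformed AAindex row for {acc!r}")
        tables[acc] = PropertyTable(acc, dict(zip(AAINDEX_ORDER, vals)))
    return tables


_BLOCK: dict[str, PropertyTable] | None = None


def all_tables() -> dict[str, PropertyTable]:
    """All embedded property tables, keyed by accession (unstandardized)."""
    global _BLOCK
    if _BLOCK is None:
        _BLOCK = _read_block()
    return _BLOCK


def get_table(accession: str, standardize: bool = True) -> PropertyTable:
    """Look up one embedded property table by AAindex accession."""
    try:
        t = all_tables()[accession]
    except KeyError:
        raise KeyError(f"unknown AAindex accession {accession!r}") from None
    return t.standardize() if standardize else t


def property_matrix(accessions: list[str] | None = None) -> tuple[np.ndarray, list[str]]:
    """Standardized property values as a (n_properties, 20) matrix.

    Columns follow :data:`ALPHABET` order.  Returns the matrix and the
    accession list in row order.
    """
    block = all_tables()
    accs = list(accessions) if accessions is not None else sorted(block)
    mat = np.stack([block[a].standardize().as_array() for a in accs])
    return mat, accs


def principal_scales(k: int = 5) -> np.ndarray:
    """Per-residue scores on the top *k* principal components of the block.

    The 20 residues are treated as observations described by the 531
    standardized properties; the returned (k, 20) matrix holds each
    residue's score on the first k components, centred per component over
    the 20 residues.  Component sign is fixed so the largest-magnitude
    loading is positive, making the scales deterministic.
    """
    mat, _ = property_matrix()           # (P, 20)
    X = mat.T                            # residues as rows
    X = X - X.mean(axis=0)
    u, s, vt = np.linalg.svd(X, full_matrices=False)
    scores = (u[:, :k] * s[:k]).T        # (k, 20)
    for i in range(scores.shape[0]):
        j = np.argmax(np.abs(scores[i]))
        if scores[i, j] < 0:
            scores[i] = -scores[i]
    return scores - scores.mean(axis=1, keepdims=True)
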