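"""Alignment-free protein sequence descriptors.

Implements the descriptor families behind the classifier's feature
matrix: amino-acid / dipeptide / tripeptide composition, AAindex
property autocorrelation (Moreau-Broto, Moran, Geary), Chou's
amphiphilic pseudo-amino-acid composition (APAAC, the ``Pc1.*`` /
``Pc2.*`` features), and auto-cross covariance of principal-component
property scales (the ``scl<i>.<j>lag.<d>`` features).

Positions holding ``X`` (unknown residue) are excluded from composition
denominators and skipped pairwise in all correlation sums, since no
property value is defined for them.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

import numpy as np
import pandas as pd

from . import aaindex
from .aaindex import ALPHABET, PropertyTable
from .seqio import LabeledDataset, SequenceRecord, XtclassError

_IDX = {a: i for i, a in enumerate(ALPHABET)}


@dataclass(frozen=True)
class DescriptorConfig:
    """Parameters of the descriptor inventory.

    lags        maximum lag d for property autocorrelation
    lambda_     λ of the amphiphilic pseudo-composition
    weight      w of the pseudo-composition (weight of the τ terms)
    n_components  number of principal-component property scales k
    acc_lag     maximum lag of the scales auto-cross covariance
    blocks      descriptor blocks to compute, in output order
    autocorrelation_accessions  AAindex accessions to autocorrelate
                (None = every embedded property)
    autocorrelation_types       subset of {moreau_broto, moran, geary}
    count_kmers  extra raw k-mer count features (overlapping counts)
    """

    lags: int = 30
    lambda_: int = 30
    weight: float = 0.05
    n_components: int = 5
    acc_lag: int = 13
    blocks: tuple[str, ...] = (
        "aac",
        "dipeptide",
        "tripeptide",
        "autocorrelation",
        "apaac",
        "scales",
    )
    autocorrelation_accessions: tuple[str, ...] | None = None
    autocorrelation_types: tuple[str, ...] = ("moreau_broto", "moran", "geary")
    count_kmers: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.lags < 1:
            raise XtclassError("lags must be >= 1")
        if self.lambda_ < 0:
            raise XtclassError("lambda must be >= 0")
        if self.weight <= 0:
            raise XtclassError("weight must be > 0")
        if self.n_components < 1:
            raise XtclassError("n_components must be >= 1")
        if self.acc_lag < 1:
            raise XtclassError("acc_lag must be >= 1")
        unknown = set(self.blocks) - {
            "aac", "dipeptide", "tripeptide", "autocorrelation",
            "apaac", "scales",
        }
        if unknown:
            raise XtclassError(f"unknown descriptor blocks {sorted(unknown)}")

    @classmethod
    def compact(cls) -> "DescriptorConfig":
        """Small inventory (~100 columns) for model-training runs.

        Keeps one representative of each family the classifier's most
        informative features come from, including the paper-relevant
        accessions (relative mutability, residue volume) and the GFV
        tripeptide count.
        """
        return cls(
            lags=5,
            lambda_=5,
            acc_lag=3,
            blocks=("aac", "autocorrelation", "apaac", "scales"),
            autocorrelation_accessions=("DAYM780201", "BIGC670101"),
            autocorrelation_types=("moreau_broto", "moran"),
            count_kmers=("GFV",),
        )

    def to_dict(self) -> dict:
        return {
            "lags": self.lags,
            "lambda": self.lambda_,
            "weight": self.weight,
            "n_components": self.n_components,
            "acc_lag": self.acc_lag,
            "blocks": list(self.blocks),
            "autocorrelation_accessions": (
                None
                if self.autocorrelation_accessions is None
                else list(self.autocorrelation_accessions)
            ),
            "autocorrelation_types": list(self.autocorrelation_types),
            "count_kmers": list(self.count_kmers),
        }

    @classmethod
    def from_dict(cls, doc: dict) -> "DescriptorConfig":
        doc = dict(doc)
        if "lambda" in doc:
            doc["lambda_"] = doc.pop("lambda")
        for key in (
            "blocks", "autocorrelation_accessions",
            "autocorrelation_types", "count_kmers",
        ):
            if doc.get(key) is not None:
                doc[key] = tuple(doc[key])
        return cls(**doc)


# ---------------------------------------------------------------------------
# elementary descriptors


def _standard_positions(seq: SequenceRecord) -> np.ndarray:
    """Residue indices into ALPHABET; -1 marks X positions."""
    return np.array([_IDX.get(ch, -1) for ch in seq.residues], dtype=np.int64)


def aac(seq: SequenceRecord) -> np.ndarray:
    """Amino-acid composition: 20 fractions over the standard residues."""
    idx = _standard_positions(seq)
    idx = idx[idx >= 0]
    if idx.size == 0:
        raise XtclassError(f"sequence {seq.id!r} has no standard residues")
    counts = np.bincount(idx, minlength=20).astype(float)
    return counts / counts.sum()


def kmer_count(seq: SequenceRecord, kmer: str) -> int:
    """Overlapping occurrence count of *kmer* in the sequence."""
    if not (1 <= len(kmer) <= len(seq)):
        raise XtclassError(
            f"k-mer {kmer!r} longer than sequence {seq.id!r}"
        )
    s, n = seq.residues, 0
    start = 0
    while True:
        i = s.find(kmer, start)
        if i < 0:
            return n
        n += 1
        start = i + 1


def _kmer_composition(seq: SequenceRecord, k: int) -> np.ndarray:
    if len(seq) < k:
        raise XtclassError(f"sequence {seq.id!r} shorter than k={k}")
    idx = _standard_positions(seq)
    windows = np.lib.stride_tricks.sliding_window_view(idx, k)
    valid = (windows >= 0).all(axis=1)
    codes = windows[valid] @ (20 ** np.arange(k - 1, -1, -1))
    counts = np.bincount(codes, minlength=20 ** k).astype(float)
    return counts / (len(seq) - k + 1)


def dipeptide_composition(seq: SequenceRecord) -> np.ndarray:
    """400 overlapping 2-mer fractions (÷ L−1)."""
    return _kmer_composition(seq, 2)


def tripeptide_composition(seq: SequenceRecord) -> np.ndarray:
    """8000 overlapping 3-mer fractions (÷ L−2); names are raw 3-mers."""
    return _kmer_composition(seq, 3)


def _property_values(seq: SequenceRecord, prop: PropertyTable) -> np.ndarray:
    if not prop.standardized:
        raise XtclassError(
            f"property {prop.accession!r} must be standardized first"
        )
    table = prop.as_array()
    idx = _standard_positions(seq)
    vals = np.where(idx >= 0, table[np.clip(idx, 0, 19)], np.nan)
    return vals


def moreau_broto(seq: SequenceRecord, prop: PropertyTable, d: int) -> float:
    """Moreau-Broto autocorrelation at lag d.

    ATS_d = mean over i of P(r_i)·P(r_{i+d}); pairs touching an X
    position are skipped (the mean runs over the remaining pairs).
    """
    vals = _property_values(seq, prop)
    L = int(np.sum(~np.isnan(vals)))
    if d >= L or d >= vals.size:
        raise XtclassError(f"lag {d} >= sequence length for {seq.id!r}")
    prod = vals[:-d] * vals[d:]
    if np.all(np.isnan(prod)):
        raise XtclassError(f"no valid lag-{d} pairs in {seq.id!r}")
    return float(np.nanmean(prod))


def moran(seq: SequenceRecord, prop: PropertyTable, d: int) -> float:
    """Moran autocorrelation at lag d (centred, variance-normalized)."""
    vals = _property_values(seq, prop)
    L = int(np.sum(~np.isnan(vals)))
    if d >= L or d >= vals.size:
        raise XtclassError(f"lag {d} >= sequence length for {seq.id!r}")
    pbar = np.nanmean(vals)
    den = np.nanmean((vals - pbar) ** 2)
    if den == 0:
        return 0.0
    num = np.nanmean((vals[:-d] - pbar) * (vals[d:] - pbar))
    return float(num / den)


def geary(seq: SequenceRecord, prop: PropertyTable, d: int) -> float:
    """Geary autocorrelation at lag d (squared-difference form)."""
    vals = _property_values(seq, prop)
    L = int(np.sum(~np.isnan(vals)))
    if d >= L or d >= vals.size:
        raise XtclassError(f"lag {d} >= sequence length for {seq.id!r}")
    pbar = np.nanmean(vals)
    den = np.nansum((vals - pbar) ** 2) / (L - 1)
    if den == 0:
        return 0.0
    num = np.nanmean((vals[:-d] - vals[d:]) ** 2) / 2.0
    return float(num / den)


_AUTOCORR_FUNCS = {"moreau_broto": moreau_broto, "moran": moran, "geary": geary}


def apaac(
    seq: SequenceRecord,
    config: DescriptorConfig,
    h1: PropertyTable | None = None,
    h2: PropertyTable | None = None,
) -> np.ndarray:
    """Amphiphilic pseudo-amino-acid composition (20 + 2λ values).

    τ_{2j−1} is the mean lag-j product of hydrophobicity values,
    τ_{2j} of hydrophilicity values (j = 1..λ); the composition
    fractions and the weighted τ terms are jointly normalized by
    Σf + w·Στ.  λ = 0 reduces exactly to the plain composition.
    """
    h1 = h1 if h1 is not None else aaindex.get_table(aaindex.HYDROPHOBICITY)
    h2 = h2 if h2 is not None else aaindex.get_table(aaindex.HYDROPHILICITY)
    lam, w = config.lambda_, config.weight
    vals1 = _property_values(seq, h1)
    vals2 = _property_values(seq, h2)
    L = int(np.sum(~np.isnan(vals1)))
    if L <= lam:
        raise XtclassError(
            f"sequence {seq.id!r} has {L} standard residues, need > λ={lam}"
        )
    taus = np.empty(2 * lam)
    for j in range(1, lam + 1):
        taus[2 * j - 2] = np.nanmean(vals1[:-j] * vals1[j:])
        taus[2 * j - 1] = np.nanmean(vals2[:-j] * vals2[j:])
    f = aac(seq)
    denom = f.sum() + w * taus.sum()
    if abs(denom) < 1e-9:
        raise XtclassError(
            f"degenerate APAAC normalization for {seq.id!r}"
        )
    return np.concatenate([f / denom, w * taus / denom])


def scales_acc(
    seq: SequenceRecord, scales: np.ndarray, acc_lag: int
) -> np.ndarray:
    """Auto-cross covariance of per-residue scale scores.

    *scales* is a (k, 20) matrix of per-residue component scores,
    centred per component over the 20 residues.  Output is the
    k·k·acc_lag vector ACC_{i,j}(d) = mean_t s_i(t)·s_j(t+d), ordered
    by (i, j, d) to match the ``scl<i>.<j>lag.<d>`` naming.
    """
    k = scales.shape[0]
    if scales.shape != (k, 20):
        raise XtclassError("scales must be a (k, 20) matrix")
    idx = _standard_positions(seq)
    L = int(np.sum(idx >= 0))
    if acc_lag >= L:
        raise XtclassError(
            f"acc_lag {acc_lag} >= length of {seq.id!r}"
        )
    s = np.where(idx >= 0, scales[:, np.clip(idx, 0, 19)], np.nan)  # (k, L)
    out = np.empty(k * k * acc_lag)
    pos = 0
    for i in range(k):
        for j in range(k):
            for d in range(1, acc_lag + 1):
                out[pos] = np.nanmean(s[i, :-d] * s[j, d:])
                pos += 1
    return out


# ---------------------------------------------------------------------------
# whole-inventory extraction


def _autocorr_block_names(config: DescriptorConfig, accs: list[str]) -> list[str]:
    names = []
    for typ in config.autocorrelation_types:
        prefix = "" if typ == "moreau_broto" else typ.capitalize() + "."
        for acc in accs:
            for d in range(1, config.lags + 1):
                names.append(f"{prefix}{acc}.lag.{d}")
    return names


def _autocorr_block(
    seq: SequenceRecord, config: DescriptorConfig, mat: np.ndarray
) -> np.ndarray:
    """Vectorized autocorrelation over all properties at once.

    *mat* is the (P, 20) standardized property matrix.
    """
    idx = _standard_positions(seq)
    L = int(np.sum(idx >= 0))
    if config.lags >= L:
        raise XtclassError(
            f"autocorrelation lags={config.lags} >= length of {seq.id!r}"
        )
    V = np.where(idx >= 0, mat[:, np.clip(idx, 0, 19)], np.nan)  # (P, L)
    P = mat.shape[0]
    pbar = np.nanmean(V, axis=1, keepdims=True)
    var_moran = np.nanmean((V - pbar) ** 2, axis=1)
    var_geary = np.nansum((V - pbar) ** 2, axis=1) / (L - 1)
    blocks = []
    for typ in config.autocorrelation_types:
        out = np.empty((P, config.lags))
        for d in range(1, config.lags + 1):
            A, B = V[:, :-d], V[:, d:]
            if typ == "moreau_broto":
                out[:, d - 1] = np.nanmean(A * B, axis=1)
            elif typ == "moran":
                num = np.nanmean((A - pbar) * (B - pbar), axis=1)
                out[:, d - 1] = np.divide(
                    num, var_moran,
                    out=np.zeros(P), where=var_moran != 0,
                )
            else:
                num = np.nanmean((A - B) ** 2, axis=1) / 2.0
                out[:, d - 1] = np.divide(
                    num, var_geary,
                    out=np.zeros(P), where=var_geary != 0,
                )
        blocks.append(out.reshape(-1))
    return np.concatenate(blocks)


def feature_names(config: DescriptorConfig) -> list[str]:
    """Ordered descriptor column names for *config* (profile blocks excluded)."""
    accs = (
        list(config.autocorrelation_accessions)
        if config.autocorrelation_accessions is not None
        else sorted(aaindex.all_tables())
    )
    names: list[str] = []
    for block in config.blocks:
        if block == "aac":
            names += [f"AAC.{a}" for a in ALPHABET]
        elif block == "dipeptide":
            names += ["".join(p) for p in product(ALPHABET, repeat=2)]
        elif block == "tripeptide":
            names += ["".join(p) for p in product(ALPHABET, repeat=3)]
        elif block == "autocorrelation":
            names += _autocorr_block_names(config, accs)
        elif block == "apaac":
            names += [f"Pc1.{a}" for a in ALPHABET]
            names += [f"Pc2.{j}" for j in range(1, 2 * config.lambda_ + 1)]
        elif block == "scales":
            names += [
                f"scl{i}.{j}lag.{d}"
                for i in range(1, config.n_components + 1)
                for j in range(1, config.n_components + 1)
                for d in range(1, config.acc_lag + 1)
            ]
    names += [kmer for kmer in config.count_kmers]
    return names


def extract_descriptors(
    seq: SequenceRecord,
    config: DescriptorConfig,
    *,
    _mat: np.ndarray | None = None,
    _scales: np.ndarray | None = None,
) -> np.ndarray:
    """All descriptor values for one sequence, in feature_names order."""
    accs = (
        list(config.autocorrelation_accessions)
        if config.autocorrelation_accessions is not None
        else sorted(aaindex.all_tables())
    )
    mat = _mat if _mat is not None else aaindex.property_matrix(accs)[0]
    scales = (
        _scales
        if _scales is not None
        else aaindex.principal_scales(config.n_components)
    )
    parts: list[np.ndarray] = []
    for block in config.blocks:
        if block == "aac":
            parts.append(aac(seq))
        elif block == "dipeptide":
            parts.append(dipeptide_composition(seq))
        elif block == "tripeptide":
            parts.append(tripeptide_composition(seq))
        elif block == "autocorrelation":
            parts.append(_autocorr_block(seq, config, mat))
        elif block == "apaac":
            parts.append(apaac(seq, config))
        elif block == "scales":
            parts.append(scales_acc(seq, scales, config.acc_lag))
    if config.count_kmers:
        parts.append(
            np.array(
                [kmer_count(seq, km) for km in config.count_kmers],
                dtype=float,
            )
        )
    return np.concatenate(parts) if parts else np.empty(0)


def extract_all(
    dataset: LabeledDataset | list[SequenceRecord],
    config: DescriptorConfig | None = None,
    profile_features: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Feature matrix for a sequence set: descriptors + profile features.

    *profile_features*, if given, is a per-sequence DataFrame (indexed by
    id) of PROSITE/PSSM/HMM features appended after the descriptor
    blocks.  The result is deterministic for identical input.
    """
    config = config if config is not None else DescriptorConfig()
    records = dataset.records if isinstance(dataset, LabeledDataset) else dataset
    accs = (
        list(config.autocorrelation_accessions)
        if config.autocorrelation_accessions is not None
        else sorted(aaindex.all_tables())
    )
    mat = aaindex.property_matrix(accs)[0]
    scales = aaindex.principal_scales(config.n_components)
    names = feature_names(config)
    rows = np.empty((len(records), len(names)))
    for i, rec in enumerate(records):
        try:
            rows[i] = extract_descriptors(rec, config, _mat=mat, _scales=scales)
        except XtclassError:
            raise
        except Exception as exc:  # annotate with the offending sequence
            raise XtclassError(
                f"descriptor extraction failed for {rec.id!r}: {exc}"
            ) from exc
    out = pd.DataFrame(rows, index=[r.id for r in records], columns=names)
    out.index.name = "id"
    if profile_features is not None:
        missing = [i for i in out.index if i not in profile_features.index]
        if missing:
            raise XtclassError(
                f"profile features missing for ids: {missing[:5]}"
            )
        out = pd.concat([out, profile_features.loc[out.index]], axis=1)
    return out
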