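"""Shared fixtures and independent brute-force oracles.

The oracle functions here deliberately re-derive every quantity with
naive loops / exhaustive enumeration, independent of the package's
vectorized implementations.
"""

from __future__ import annotations

import random

import numpy as np
import pytest

from xtclass.aaindex import ALPHABET
from xtclass.synthetic import SynthConfig, generate


def random_sequence(rng: random.Random, length: int) -> str:
    return "".join(rng.choice(ALPHABET) for _ in range(length))


@pytest.fixture
def rng() -> random.Random:
    return random.Random(1234)


@pytest.fixture(scope="session")
def small_fixture():
    """A compact labelled set for fast end-to-end tests."""
    return generate(
        SynthConfig(
            n_pos=12,
            n_neg=60,
            length_range=(120, 160),
            motif_region=(41, 90),
            mutation_rate=0.1,
            seed=7,
        )
    )


# ---------------------------------------------------------------------------
# oracles


def oracle_aac(residues: str) -> dict[str, float]:
    counts = {a: 0 for a in ALPHABET}
    for ch in residues:
        if ch in counts:
            counts[ch] += 1
    total = sum(counts.values())
    return {a: c / total for a, c in counts.items()}


def oracle_kmer_count(residues: str, kmer: str) -> int:
    return sum(
        residues[i : i + len(kmer)] == kmer
        for i in range(len(residues) - len(kmer) + 1)
    )


def oracle_moreau_broto(residues: str, table: dict[str, float], d: int) -> float:
    pairs = [
        table[residues[i]] * table[residues[i + d]]
        for i in range(len(residues) - d)
        if residues[i] in table and residues[i + d] in table
    ]
    return sum(pairs) / len(pairs)


def oracle_moran(residues: str, table: dict[str, float], d: int) -> float:
    vals = [table[ch] for ch in residues if ch in table]
    mean = sum(vals) / len(vals)
    den = sum((v - mean) ** 2 for v in vals) / len(vals)
    num_terms = [
        (table[residues[i]] - mean) * (table[residues[i + d]] - mean)
        for i in range(len(residues) - d)
        if residues[i] in table and residues[i + d] in table
    ]
    return (sum(num_terms) / len(num_terms)) / den


def oracle_geary(residues: str, table: dict[str, float], d: int) -> float:
    vals = [table[ch] for ch in residues if ch in table]
    mean = sum(vals) / len(vals)
    den = sum((v - mean) ** 2 for v in vals) / (len(vals) - 1)
    terms = [
        (table[residues[i]] - table[residues[i + d]]) ** 2
        for i in range(len(residues) - d)
        if residues[i] in table and residues[i + d] in table
    ]
    return (sum(terms) / (2 * len(terms))) / den


def oracle_apaac(
    residues: str,
    h1: dict[str, float],
    h2: dict[str, float],
    lam: int,
    w: float,
) -> list[float]:
    taus = []
    for j in range(1, lam + 1):
        t1 = [
            h1[residues[i]] * h1[residues[i + j]]
            for i in range(len(residues) - j)
        ]
        t2 = [
            h2[residues[i]] * h2[residues[i + j]]
            for i in range(len(residues) - j)
        ]
        taus += [sum(t1) / len(t1), sum(t2) / len(t2)]
    comp = oracle_aac(residues)
    f = [comp[a] for a in ALPHABET]
    denom = sum(f) + w * sum(taus)
    return [x / denom for x in f] + [w * t / denom for t in taus]


def oracle_scales_acc(
    residues: str, scales: np.ndarray, acc_lag: int
) -> list[float]:
    idx = {a: i for i, a in enumerate(ALPHABET)}
    out = []
    k = scales.shape[0]
    for i in range(k):
        for j in range(k):
            for d in range(1, acc_lag + 1):
                terms = [
                    scales[i, idx[residues[t]]] * scales[j, idx[residues[t + d]]]
                    for t in range(len(residues) - d)
                ]
                out.append(sum(terms) / len(terms))
    return out


def oracle_auc_pair_count(y, scores) -> float:
    """AUC by exhaustive positive-negative pair comparison."""
    pos = [s for s, lab in zip(scores, y) if lab == 1]
    neg = [s for s, lab in zip(scores, y) if lab == 0]
    total = 0.0
    for p in pos:
        for n in neg:
            if p > n:
                total += 1.0
            elif p == n:
                total += 0.5
    return total / (len(pos) * len(neg))


def oracle_average_precision(y, scores) -> float:
    """AP by walking thresholds at every distinct score."""
    npos = sum(y)
    thresholds = sorted(set(scores), reverse=True)
    ap, prev_recall = 0.0, 0.0
    for thr in thresholds:
        tp = sum(1 for s, lab in zip(scores, y) if s >= thr and lab == 1)
        pp = sum(1 for s in scores if s >= thr)
        recall = tp / npos
        precision = tp / pp
        ap += (recall - prev_recall) * precision
        prev_recall = recall
    return ap


def oracle_hmm_enumerate(hmm, residues: str) -> float:
    """Total sequence probability by explicit state-path enumeration."""
    from xtclass.aaindex import ALPHABET as _AB

    idx = {a: i for i, a in enumerate(_AB)}
    k = hmm.n_match
    out_m = (hmm.amm, hmm.ami, hmm.amd)
    out_i = (hmm.aim, hmm.aii, hmm.aid)
    out_d = (hmm.adm, hmm.adi, hmm.add)
    total = 0.0

    def step(state: str, layer: int, pos: int, prob: float) -> None:
        nonlocal total
        if prob == 0.0:
            return
        a_m, a_i, a_d = {"M": out_m, "I": out_i, "D": out_d}[state]
        if pos == len(residues) and layer == k:
            total += prob * a_m[k]
        if pos < len(residues):
            ch = residues[pos]
            if layer < k:
                e = hmm.match_emissions[layer, idx[ch]]
                step("M", layer + 1, pos + 1, prob * a_m[layer] * e)
            eb = hmm.background[idx[ch]]
            step("I", layer, pos + 1, prob * a_i[layer] * eb)
        if layer < k:
            step("D", layer + 1, pos, prob * a_d[layer])

    step("M", 0, 0, 1.0)
    return total
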