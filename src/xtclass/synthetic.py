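"""Synthetic labelled sequence sets with an implanted domain motif.

The generator emulates the statistical shape of a curated transporter
training set: a small positive class carrying a conserved motif inside
a designated "non-cytoplasmic" region, and a large background negative
class.  Everything is seeded and deterministic, and the positives'
motif-region alignment is produced by construction (the implant offset
is fixed, so region substrings align column-for-column without running
an aligner).

``default_paper_shape`` yields the standard fixture: 25 positives /
371 negatives (396 sequences), lengths 400-600, a 15-residue motif at
10% per-site mutation — the class imbalance the classifier is designed
around.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .aaindex import ALPHABET
from .seqio import (
    LabeledDataset,
    Msa,
    RegionAnnotation,
    SequenceRecord,
    XtclassError,
)

#: Robinson-Robinson amino-acid frequencies (selectable background).
ROBINSON_FREQUENCIES = {
    "A": 0.0780, "C": 0.0192, "D": 0.0536, "E": 0.0629, "F": 0.0386,
    "G": 0.0737, "H": 0.0219, "I": 0.0514, "K": 0.0574, "L": 0.0901,
    "M": 0.0224, "N": 0.0448, "P": 0.0520, "Q": 0.0426, "R": 0.0512,
    "S": 0.0712, "T": 0.0584, "V": 0.0644, "W": 0.0132, "Y": 0.0321,
}


@dataclass(frozen=True)
class SynthConfig:
    """Generator parameters.

    n_pos / n_neg      class sizes
    length_range       inclusive (min, max) sequence length
    background         per-residue frequencies (None = uniform)
    motif              residue string implanted in every positive
    motif_region       1-based inclusive interval simulating the
                       non-cytoplasmic domain (the motif sits at a
                       fixed offset inside it)
    mutation_rate      per-site substitution probability on the motif
    seed               RNG seed
    """

    n_pos: int = 25
    n_neg: int = 371
    length_range: tuple[int, int] = (400, 600)
    background: dict[str, float] | None = None
    motif: str = "WQNRFGYDWPTKQAC"
    motif_region: tuple[int, int] = (151, 200)
    mutation_rate: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_pos < 2:
            raise XtclassError("need at least 2 positives")
        if self.n_neg < 1:
            raise XtclassError("need at least 1 negative")
        lo, hi = self.length_range
        if not (0 < lo <= hi):
            raise XtclassError("bad length range")
        start, end = self.motif_region
        if not (1 <= start <= end):
            raise XtclassError("bad motif region")
        if end > lo:
            raise XtclassError(
                "motif region must fit inside the minimum sequence length"
            )
        width = end - start + 1
        if len(self.motif) > width:
            raise XtclassError("motif does not fit in motif_region")
        if set(self.motif) - set(ALPHABET):
            raise XtclassError("motif must use the 20 standard residues")
        if not (0 <= self.mutation_rate < 0.5):
            raise XtclassError("mutation_rate must lie in [0, 0.5)")


@dataclass
class SyntheticFixture:
    """One generated study set."""

    dataset: LabeledDataset
    msa: Msa
    annotation: RegionAnnotation
    config: SynthConfig = field(repr=False, default=None)

    @property
    def positives(self) -> list[SequenceRecord]:
        return [r for r in self.dataset.records if self.dataset.labels[r.id]]


def _background_probs(cfg: SynthConfig) -> np.ndarray:
    if cfg.background is None:
        return np.full(20, 1 / 20)
    probs = np.array([cfg.background.get(a, 0.0) for a in ALPHABET])
    if probs.min() < 0 or probs.sum() <= 0:
        raise XtclassError("invalid background frequencies")
    return probs / probs.sum()


def generate(cfg: SynthConfig) -> SyntheticFixture:
    """Generate a labelled set, the positives' region alignment, and
    the region annotation naming the first positive as reference."""
    rng = np.random.default_rng(cfg.seed)
    probs = _background_probs(cfg)
    alphabet = np.frombuffer(ALPHABET.encode(), dtype=np.uint8)
    lo, hi = cfg.length_range
    start, end = cfg.motif_region
    offset = start - 1 + (end - start + 1 - len(cfg.motif)) // 2

    def draw(length: int) -> np.ndarray:
        return alphabet[rng.choice(20, size=length, p=probs)]

    records: list[SequenceRecord] = []
    labels: dict[str, int] = {}
    motif_arr = np.frombuffer(cfg.motif.encode(), dtype=np.uint8)
    region_rows: list[tuple[str, str]] = []
    for i in range(cfg.n_pos):
        L = int(rng.integers(lo, hi + 1))
        seq = draw(L)
        implant = motif_arr.copy()
        mutate = rng.random(len(implant)) < cfg.mutation_rate
        if mutate.any():
            # substitute with a uniformly drawn *different* residue
            shift = rng.integers(1, 20, size=int(mutate.sum()))
            cur = np.array(
                [ALPHABET.index(chr(c)) for c in implant[mutate]]
            )
            implant[mutate] = alphabet[(cur + shift) % 20]
        seq[offset : offset + len(implant)] = implant
        rid = f"pos{i + 1:03d}"
        rec = SequenceRecord(rid, seq.tobytes().decode())
        records.append(rec)
        labels[rid] = 1
        region_rows.append((rid, rec.residues))
    for i in range(cfg.n_neg):
        L = int(rng.integers(lo, hi + 1))
        rid = f"neg{i + 1:03d}"
        records.append(SequenceRecord(rid, draw(L).tobytes().decode()))
        labels[rid] = 0

    # positives align by construction: the implant offset is absolute, so
    # left-aligned rows with right gap padding put every motif column in
    # register and keep the annotation's reference coordinates valid
    reference = records[0].id
    width = max(len(s) for _, s in region_rows)
    msa = Msa(
        [(rid, s + "-" * (width - len(s))) for rid, s in region_rows],
        reference_id=reference,
    )
    annotation = RegionAnnotation(
        reference, [(start, end, "non_cytoplasmic")]
    )
    return SyntheticFixture(
        dataset=LabeledDataset(records, labels),
        msa=msa,
        annotation=annotation,
        config=cfg,
    )


def default_paper_shape(seed: int = 0) -> SyntheticFixture:
    """The standard fixture: 25 positives vs 371 negatives."""
    return generate(SynthConfig(seed=seed))
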