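"""Greedy redundancy removal at a sequence-identity threshold.

Mirrors the CD-HIT convention: sequences are processed in order of
decreasing length, each either joins the first existing representative
it matches at >= threshold identity or founds a new cluster.  Identity
is the number of identical positions in a global BLOSUM62 alignment
(gap open 10, extend 1) divided by the length of the shorter sequence.

Known positives can be *protected*: any protected sequence absorbed
into a cluster is re-added to the output afterwards, so curated
transporters are never lost to the filter.

A cheap, exact-safe prescreen avoids most alignments: for any global
alignment with M identical positions and unit-cost edit distance d,
M <= (len(a) + len(b) - d) / 2, so pairs whose edit-distance bound
falls below the threshold can be skipped without changing the result.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import edlib
from Bio import Align
from Bio.Align import substitution_matrices

from .seqio import LabeledDataset, SequenceRecord, XtclassError


def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -10.0
    aligner.extend_gap_score = -1.0
    aligner.mode = "global"
    return aligner


_ALIGNER = _make_aligner()


def pairwise_identity(a: SequenceRecord, b: SequenceRecord) -> float:
    """Fraction of identical aligned positions over the shorter length."""
    if not a.residues or not b.residues:
        raise XtclassError("cannot align an empty sequence")
    aln = _ALIGNER.align(a.residues, b.residues)[0]
    ident = aln.counts().identities
    return ident / min(len(a), len(b))


def _identity_upper_bound(a: str, b: str) -> float:
    """Sound upper bound on pairwise_identity from edit distance."""
    d = edlib.align(a, b, mode="NW", task="distance")["editDistance"]
    return (len(a) + len(b) - d) / (2 * min(len(a), len(b)))


@dataclass
class ClusterResult:
    """Outcome of greedy clustering."""

    representatives: list[str]
    members: dict[str, list[str]]
    protected: set[str] = field(default_factory=set)

    @property
    def output_ids(self) -> list[str]:
        """Representatives plus protected re-additions, input-stable order."""
        out = list(self.representatives)
        seen = set(out)
        for p in sorted(self.protected):
            if p not in seen:
                out.append(p)
                seen.add(p)
        return out


def greedy_cluster(
    data: LabeledDataset,
    threshold: float = 0.8,
    protected: set[str] | None = None,
) -> ClusterResult:
    """Cluster at *threshold* identity; re-add protected ids afterwards."""
    if not (0 < threshold < 1):
        raise XtclassError("threshold must lie strictly between 0 and 1")
    protected = set(protected or ())
    known = {r.id for r in data.records}
    unknown = protected - known
    if unknown:
        raise XtclassError(f"protected ids not in dataset: {sorted(unknown)}")

    by_id = {r.id: r for r in data.records}
    order = sorted(data.records, key=lambda r: (-len(r), r.id))
    reps: list[str] = []
    members: dict[str, list[str]] = {}
    for rec in order:
        home = None
        for rep in reps:
            rrec = by_id[rep]
            if _identity_upper_bound(rec.residues, rrec.residues) < threshold:
                continue
            if pairwise_identity(rec, rrec) >= threshold:
                home = rep
                break
        if home is None:
            reps.append(rec.id)
            members[rec.id] = [rec.id]
        else:
            members[home].append(rec.id)
    return ClusterResult(reps, members, protected=protected)
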