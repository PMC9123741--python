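"""Sequence, label, alignment and region-annotation I/O.

All annotation coordinates are 1-based inclusive, in the coordinate
system of the UNGAPPED reference sequence (the Uniprot/InterPro
convention).  Nonstandard residues B/Z/U/O are mapped to ``X`` on read;
gaps are only legal in alignments.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import pandas as pd
from Bio import SeqIO as _BioSeqIO

from .aaindex import ALPHABET

GAP = "-"
_AMBIGUOUS = {"B": "X", "Z": "X", "U": "X", "O": "X", "J": "X"}
_VALID = set(ALPHABET) | {"X"}


class XtclassError(Exception):
    """Base class for user-facing errors."""


@dataclass(frozen=True)
class SequenceRecord:
    """A protein sequence over the 20 standard residues plus ``X``."""

    id: str
    residues: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise XtclassError("sequence record with empty id")
        if not self.residues:
            raise XtclassError(f"sequence {self.id!r} is empty")
        bad = set(self.residues) - _VALID
        if bad:
            raise XtclassError(
                f"sequence {self.id!r} contains illegal characters "
                f"{sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.residues)


def normalize_residues(raw: str, *, allow_gaps: bool = False) -> str:
    """Uppercase, map ambiguity codes to X, strip ``*`` stops.

    Gap characters (``-`` and ``.``) raise unless *allow_gaps*, in which
    case ``.`` is normalized to ``-``.
    """
    out = []
    for ch in raw.upper():
        if ch == "*":
            continue
        if ch in ".-":
            if not allow_gaps:
                raise XtclassError("gap character in ungapped sequence")
            out.append(GAP)
            continue
        out.append(_AMBIGUOUS.get(ch, ch))
    return "".join(out)


@dataclass
class LabeledDataset:
    """Sequences with binary xylose-transport labels (1 = transporter)."""

    records: list[SequenceRecord]
    labels: dict[str, int]

    def __post_init__(self) -> None:
        ids = [r.id for r in self.records]
        if len(ids) != len(set(ids)):
            raise XtclassError("duplicate sequence ids in dataset")
        missing = [i for i in ids if i not in self.labels]
        if missing:
            raise XtclassError(f"missing labels for ids: {missing[:5]}")
        bad = {i: l for i, l in self.labels.items() if l not in (0, 1)}
        if bad:
            raise XtclassError(f"labels outside {{0,1}}: {bad}")

    @property
    def ids(self) -> list[str]:
        return [r.id for r in self.records]

    def class_counts(self) -> tuple[int, int]:
        """(n_positive, n_negative) over the records present."""
        pos = sum(self.labels[r.id] for r in self.records)
        return pos, len(self.records) - pos

    def subset(self, ids: list[str]) -> "LabeledDataset":
        keep = set(ids)
        recs = [r for r in self.records if r.id in keep]
        return LabeledDataset(recs, {r.id: self.labels[r.id] for r in recs})


@dataclass
class Msa:
    """A gapped multiple sequence alignment."""

    rows: list[tuple[str, str]]
    reference_id: str | None = None

    def __post_init__(self) -> None:
        if not self.rows:
            raise XtclassError("empty alignment")
        widths = {len(s) for _, s in self.rows}
        if len(widths) != 1:
            raise XtclassError("ragged alignment: unequal row lengths")
        ids = [i for i, _ in self.rows]
        if len(ids) != len(set(ids)):
            raise XtclassError("duplicate row ids in alignment")
        if self.reference_id is not None and self.reference_id not in ids:
            raise XtclassError(
                f"reference id {self.reference_id!r} not among alignment rows"
            )
        for rid, s in self.rows:
            SequenceRecord(rid, s.replace(GAP, "") or "X")  # alphabet check
            if not s.replace(GAP, ""):
                raise XtclassError(f"alignment row {rid!r} is all gaps")

    @property
    def width(self) -> int:
        return len(self.rows[0][1])

    def row(self, rid: str) -> str:
        for i, s in self.rows:
            if i == rid:
                return s
        raise XtclassError(f"no alignment row {rid!r}")

    def degap(self, rid: str) -> SequenceRecord:
        return SequenceRecord(rid, self.row(rid).replace(GAP, ""))


REGION_KINDS = ("non_cytoplasmic", "binding_site")


@dataclass
class RegionAnnotation:
    """Intervals (1-based inclusive) on an ungapped reference sequence."""

    reference_id: str
    regions: list[tuple[int, int, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.regions:
            raise XtclassError("region annotation with no regions")
        for start, end, kind in self.regions:
            if kind not in REGION_KINDS:
                raise XtclassError(f"unknown region kind {kind!r}")
            if not (1 <= start <= end):
                raise XtclassError(f"bad region coordinates ({start},{end})")
        srt = sorted(self.regions)
        for (s1, e1, _), (s2, _, _) in zip(srt, srt[1:]):
            if s2 <= e1:
                raise XtclassError("overlapping regions in annotation")

    def validate_against(self, reference_length: int) -> None:
        for start, end, _ in self.regions:
            if end > reference_length:
                raise XtclassError(
                    f"region ({start},{end}) exceeds reference length "
                    f"{reference_length}"
                )


# ---------------------------------------------------------------------------
# readers / writers


def read_fasta(path, gapped: bool = False):
    """Read a FASTA file into records, or an :class:`Msa` when *gapped*.

    Residues are normalized (uppercase, ambiguity codes to X, ``*``
    stripped).  Duplicate ids, empty files, illegal characters and — for
    alignments — ragged rows are errors.
    """
    entries = []
    for rec in _BioSeqIO.parse(str(path), "fasta"):
        entries.append((rec.id, rec.description, str(rec.seq)))
    if not entries:
        raise XtclassError(f"no FASTA records in {path}")
    ids = [e[0] for e in entries]
    if len(ids) != len(set(ids)):
        dup = sorted({i for i in ids if ids.count(i) > 1})
        raise XtclassError(f"duplicate ids in {path}: {dup}")
    if gapped:
        rows = [
            (rid, normalize_residues(seq, allow_gaps=True))
            for rid, _, seq in entries
        ]
        return Msa(rows)
    return [
        SequenceRecord(rid, normalize_residues(seq), description=desc)
        for rid, desc, seq in entries
    ]


def write_fasta(records, path, width: int = 60) -> None:
    """Write records (or Msa rows) as FASTA."""
    with open(path, "w") as fh:
        items = records.rows if isinstance(records, Msa) else [
            (r.id, r.residues) for r in records
        ]
        for rid, seq in items:
            fh.write(f">{rid}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def load_labels(path, records, logger=None) -> LabeledDataset:
    """Attach binary labels from a two-column ``id\\tlabel`` TSV."""
    df = pd.read_csv(path, sep="\t", dtype={"id": str})
    if not {"id", "label"}.issubset(df.columns):
        raise XtclassError("label TSV must have columns 'id' and 'label'")
    if df["id"].duplicated().any():
        raise XtclassError("duplicate ids in label TSV")
    lab = dict(zip(df["id"], df["label"].astype(int)))
    missing = [r.id for r in records if r.id not in lab]
    if missing:
        raise XtclassError(f"no label for ids: {missing[:5]}")
    ds = LabeledDataset(list(records), {r.id: lab[r.id] for r in records})
    pos, neg = ds.class_counts()
    if logger is not None:
        logger.info("labels loaded: %d positive / %d negative", pos, neg)
    return ds


def write_labels(dataset: LabeledDataset, path) -> None:
    pd.DataFrame(
        {"id": dataset.ids, "label": [dataset.labels[i] for i in dataset.ids]}
    ).to_csv(path, sep="\t", index=False)


def write_features(matrix: pd.DataFrame, path, float_format: str = "%.12g") -> None:
    """Write a feature matrix as TSV (header = feature names, index = ids)."""
    import numpy as np

    vals = matrix.to_numpy()
    if not np.isfinite(vals).all():
        bad = matrix.columns[~np.isfinite(vals).all(axis=0)].tolist()
        raise XtclassError(f"non-finite feature values in columns {bad[:5]}")
    matrix.to_csv(path, sep="\t", index_label="id", float_format=float_format)


def read_features(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="id")


def read_regions_json(path) -> RegionAnnotation:
    """Read a region annotation: ``{"reference_id": ..., "regions": [...]}``.

    Each region object has 1-based inclusive ``start``/``end`` and a
    ``kind`` of ``non_cytoplasmic`` or ``binding_site``.
    """
    with open(path) as fh:
        doc = json.load(fh)
    try:
        regions = [
            (int(r["start"]), int(r["end"]), str(r["kind"]))
            for r in doc["regions"]
        ]
        return RegionAnnotation(str(doc["reference_id"]), regions)
    except (KeyError, TypeError) as exc:
        raise XtclassError(f"malformed region JSON {path}: {exc}") from exc


def write_regions_json(ann: RegionAnnotation, path) -> None:
    doc = {
        "reference_id": ann.reference_id,
        "regions": [
            {"start": s, "end": e, "kind": k} for s, e, k in ann.regions
        ],
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1)


def read_regions_bed(path, reference_id: str, kind: str = "non_cytoplasmic") -> RegionAnnotation:
    """Read regions from a BED file (0-based half-open → 1-based inclusive).

    The optional 4th BED column overrides *kind* per line.
    """
    regions = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise XtclassError(f"malformed BED line: {line!r}")
            start, end = int(parts[1]), int(parts[2])
            k = parts[3] if len(parts) > 3 and parts[3] in REGION_KINDS else kind
            regions.append((start + 1, end, k))
    return RegionAnnotation(reference_id, regions)
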