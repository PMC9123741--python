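"""Position-specific profile features.

Three feature sources built from curated knowledge of the positive
class (known xylose transporters):

* PROSITE signature patterns, compiled locally and scanned with
  overlapping matches (count + presence per pattern);
* a position-specific scoring matrix (PSSM) estimated from the
  known-positives alignment, summarized per query into 23 features;
* a Krogh-style profile hidden Markov model built from the alignment
  columns of annotated regions (non-cytoplasmic domains / binding
  sites), scored with the forward algorithm as a log-odds score in
  bits — the pipeline's signature feature.

All log scores are base 2.  Alignment column indices are 1-based at
this module's surface, matching the 1-based region coordinates.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .aaindex import ALPHABET
from .redundancy import _make_aligner
from .seqio import Msa, RegionAnnotation, SequenceRecord, XtclassError


def _make_semiglobal_aligner():
    """BLOSUM62 aligner with free end gaps: profiles are region-sized,
    queries are whole sequences, so terminal gaps carry no signal."""
    aligner = _make_aligner()
    aligner.end_gap_score = 0.0
    return aligner


_SEMIGLOBAL_ALIGNER = _make_semiglobal_aligner()

_IDX = {a: i for i, a in enumerate(ALPHABET)}

FORMAT_VERSION = 1

UNIFORM_BACKGROUND = np.full(20, 1 / 20)


# ---------------------------------------------------------------------------
# PROSITE patterns


_ELEMENT_RE = re.compile(
    r"^(?P<base>[A-Za-z]|\[[A-Z]+\]|\{[A-Z]+\})"
    r"(?:\((?P<n>\d+)(?:,(?P<m>\d+))?\))?$"
)


@dataclass(frozen=True)
class PrositePattern:
    """A compiled PROSITE-syntax pattern."""

    raw: str
    regex: str = field(compare=False)

    def finditer(self, residues: str):
        """1-based start positions of overlapping matches."""
        return [
            m.start() + 1
            for m in re.finditer(f"(?=({self.regex}))", residues)
        ]

    def count(self, seq: SequenceRecord) -> int:
        return len(self.finditer(seq.residues))


def compile_prosite(raw: str) -> PrositePattern:
    """Compile a PROSITE pattern (elements, [..], {..}, x, (n)/(n,m), <, >)."""
    pattern = raw.strip().rstrip(".")
    if not pattern:
        raise XtclassError("empty PROSITE pattern")
    anchored_start = pattern.startswith("<")
    anchored_end = pattern.endswith(">")
    pattern = pattern.removeprefix("<").removesuffix(">")
    parts = pattern.split("-")
    out = []
    for part in parts:
        m = _ELEMENT_RE.match(part)
        if m is None:
            raise XtclassError(f"malformed PROSITE element {part!r} in {raw!r}")
        base = m.group("base")
        if base in ("x", "X"):
            rx = "."
        elif base.startswith("["):
            rx = base
        elif base.startswith("{"):
            rx = "[^" + base[1:-1] + "]"
        elif base.isalpha() and base.isupper():
            rx = base
        else:
            raise XtclassError(f"malformed PROSITE element {part!r} in {raw!r}")
        if m.group("n"):
            rx += (
                f"{{{m.group('n')},{m.group('m')}}}"
                if m.group("m")
                else f"{{{m.group('n')}}}"
            )
        out.append(rx)
    regex = "".join(out)
    if anchored_start:
        regex = "^" + regex
    if anchored_end:
        regex += "$"
    return PrositePattern(raw=raw, regex=regex)


def prosite_features(
    seq: SequenceRecord, patterns: list[PrositePattern]
) -> dict[str, float]:
    """Per-pattern overlapping match count and presence flag."""
    out: dict[str, float] = {}
    for i, pat in enumerate(patterns, start=1):
        n = pat.count(seq)
        out[f"PROSITE.{i}.count"] = float(n)
        out[f"PROSITE.{i}.presence"] = float(n > 0)
    return out


# ---------------------------------------------------------------------------
# region → column mapping


def map_regions_to_columns(msa: Msa, ann: RegionAnnotation) -> list[int]:
    """Alignment columns (1-based) holding the annotated reference residues.

    Reference gap columns are never selected; the result is sorted and
    unique.
    """
    row = msa.row(ann.reference_id)
    reflen = len(row) - row.count("-")
    ann.validate_against(reflen)
    wanted = set()
    for start, end, _ in ann.regions:
        wanted.update(range(start, end + 1))
    cols = []
    pos = 0
    for col, ch in enumerate(row, start=1):
        if ch == "-":
            continue
        pos += 1
        if pos in wanted:
            cols.append(col)
    return cols


def columns_for_kind(msa: Msa, ann: RegionAnnotation, kind: str) -> list[int]:
    sub = [r for r in ann.regions if r[2] == kind]
    if not sub:
        return []
    return map_regions_to_columns(
        msa, RegionAnnotation(ann.reference_id, sub)
    )


# ---------------------------------------------------------------------------
# PSSM


@dataclass
class Pssm:
    """Per-column residue probabilities and log2 odds from an alignment."""

    probs: np.ndarray          # (width, 20)
    log_odds: np.ndarray       # (width, 20)
    background: np.ndarray     # (20,)
    alpha: float
    consensus: str

    def __post_init__(self) -> None:
        if self.probs.ndim != 2 or self.probs.shape[1] != 20:
            raise XtclassError("PSSM probabilities must be (width, 20)")
        if np.abs(self.probs.sum(axis=1) - 1).max() > 1e-9:
            raise XtclassError("PSSM columns must sum to 1")

    @property
    def width(self) -> int:
        return self.probs.shape[0]

    def to_json(self, path) -> None:
        doc = {
            "format": "xtclass-pssm",
            "version": FORMAT_VERSION,
            "alpha": self.alpha,
            "background": self.background.tolist(),
            "probs": self.probs.tolist(),
            "consensus": self.consensus,
        }
        with open(path, "w") as fh:
            json.dump(doc, fh)

    @classmethod
    def from_json(cls, path) -> "Pssm":
        with open(path) as fh:
            doc = json.load(fh)
        if doc.get("format") != "xtclass-pssm" or doc.get("version") != FORMAT_VERSION:
            raise XtclassError(f"unsupported PSSM file {path}")
        probs = np.array(doc["probs"])
        q = np.array(doc["background"])
        return cls(
            probs=probs,
            log_odds=np.log2(probs / q),
            background=q,
            alpha=doc["alpha"],
            consensus=doc["consensus"],
        )


def _column_counts(msa: Msa, columns: list[int]) -> np.ndarray:
    """(n_columns, 20) residue counts; gaps and X excluded."""
    counts = np.zeros((len(columns), 20))
    for _, rowseq in msa.rows:
        for ci, col in enumerate(columns):
            ch = rowseq[col - 1]
            j = _IDX.get(ch)
            if j is not None:
                counts[ci, j] += 1
    return counts


def build_pssm(
    msa: Msa,
    columns: list[int] | None = None,
    alpha: float = 1.0,
    background: np.ndarray | None = None,
) -> Pssm:
    """Estimate a PSSM from alignment columns.

    p(a|col) = (count_a + α) / (n_nongap + 20α); log-odds are log2(p/q).
    *columns* defaults to every column with >= 50% residue occupancy.
    """
    if alpha < 0:
        raise XtclassError("pseudocount must be >= 0")
    q = background if background is not None else UNIFORM_BACKGROUND
    if columns is None:
        nrows = len(msa.rows)
        columns = [
            c
            for c in range(1, msa.width + 1)
            if sum(r[c - 1] != "-" for _, r in msa.rows) >= 0.5 * nrows
        ]
    if not columns:
        raise XtclassError("no columns to build a PSSM from")
    for c in columns:
        if not (1 <= c <= msa.width):
            raise XtclassError(f"column {c} outside alignment width {msa.width}")
    counts = _column_counts(msa, columns)
    n = counts.sum(axis=1, keepdims=True)
    if alpha == 0 and (n == 0).any():
        raise XtclassError(
            "all-gap column with zero pseudocount; raise alpha"
        )
    probs = (counts + alpha) / (n + 20 * alpha)
    with np.errstate(divide="ignore"):
        log_odds = np.log2(probs / q)
    consensus = "".join(
        ALPHABET[int(np.argmax(p))] for p in probs
    )
    return Pssm(
        probs=probs, log_odds=log_odds, background=q.copy(),
        alpha=alpha, consensus=consensus,
    )


PSSM_FEATURE_NAMES = (
    [f"PSSM.mean.{a}" for a in ALPHABET]
    + ["PSSM.mean", "PSSM.max", "PSSM.coverage"]
)


def pssm_features(seq: SequenceRecord, pssm: Pssm) -> dict[str, float]:
    """23 summary features from aligning the query to the PSSM consensus.

    The query is globally aligned (BLOSUM62) to the profile consensus;
    each aligned query residue takes that column's log-odds for its
    letter.  Summaries: mean score per residue class (0 when the class
    is absent), overall mean, max, and the fraction of profile columns
    covered.
    """
    aln = _SEMIGLOBAL_ALIGNER.align(pssm.consensus, seq.residues)[0]
    scores: list[float] = []
    classes: list[int] = []
    ncols = 0
    for (t0, t1), (q0, q1) in zip(*aln.aligned):
        for k in range(t1 - t0):
            col = t0 + k
            ch = seq.residues[q0 + k]
            j = _IDX.get(ch)
            ncols += 1
            if j is None:
                continue
            scores.append(float(pssm.log_odds[col, j]))
            classes.append(j)
    if not scores:
        raise XtclassError(
            f"query {seq.id!r} has no alignable overlap with the profile"
        )
    scores_arr = np.array(scores)
    classes_arr = np.array(classes)
    out: dict[str, float] = {}
    for j, a in enumerate(ALPHABET):
        sel = scores_arr[classes_arr == j]
        out[f"PSSM.mean.{a}"] = float(sel.mean()) if sel.size else 0.0
    out["PSSM.mean"] = float(scores_arr.mean())
    out["PSSM.max"] = float(scores_arr.max())
    out["PSSM.coverage"] = ncols / pssm.width
    return out


def read_ascii_pssm(path) -> Pssm:
    """Read a PSI-BLAST-style ASCII PSSM (first 20 log-odds columns).

    The file's per-position log-odds (base-2-ish integers, columns in
    A R N D C Q E G H I L K M F P S T W Y V order) are converted back to
    probabilities against a uniform background so the result behaves
    like a locally built :class:`Pssm`.
    """
    order = "ARNDCQEGHILKMFPSTWYV"
    perm = [order.index(a) for a in ALPHABET]
    rows = []
    consensus = []
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if len(parts) >= 22 and parts[0].isdigit() and parts[1].isalpha():
                vals = [float(x) for x in parts[2:22]]
                rows.append([vals[k] for k in perm])
                consensus.append(parts[1] if parts[1] in ALPHABET else "A")
    if not rows:
        raise XtclassError(f"no PSSM rows parsed from {path}")
    log_odds = np.array(rows)
    probs = UNIFORM_BACKGROUND * np.exp2(log_odds)
    probs = probs / probs.sum(axis=1, keepdims=True)
    return Pssm(
        probs=probs,
        log_odds=log_odds,
        background=UNIFORM_BACKGROUND.copy(),
        alpha=0.0,
        consensus="".join(consensus),
    )


# ---------------------------------------------------------------------------
# profile HMM


@dataclass
class ProfileHmm:
    """Krogh-style profile HMM (match/insert/delete) over 20 residues.

    Transition arrays are indexed by source layer j = 0..k, where layer
    0 is the begin state and transitions from layer k lead to the end
    state (no delete k+1 exists, so ``a?d[k]`` is 0).  Insert emissions
    are the background distribution.
    """

    match_emissions: np.ndarray       # (k, 20)
    background: np.ndarray            # (20,)
    amm: np.ndarray                   # (k+1,) M_j -> M_{j+1} (M_0 = begin)
    ami: np.ndarray                   # M_j -> I_j
    amd: np.ndarray                   # M_j -> D_{j+1}
    aim: np.ndarray                   # I_j -> M_{j+1}
    aii: np.ndarray                   # I_j -> I_j
    aid: np.ndarray                   # I_j -> D_{j+1}
    adm: np.ndarray                   # D_j -> M_{j+1}
    add: np.ndarray                   # D_j -> D_{j+1}
    adi: np.ndarray                   # D_j -> I_j
    alpha: float = 1.0

    def __post_init__(self) -> None:
        k = self.n_match
        if k < 1:
            raise XtclassError("profile HMM needs at least one match state")
        if np.abs(self.match_emissions.sum(axis=1) - 1).max() > 1e-9:
            raise XtclassError("match emissions must sum to 1")
        for name, (a, b, c) in {
            "M": (self.amm, self.ami, self.amd),
            "I": (self.aim, self.aii, self.aid),
            "D": (self.adm, self.add, self.adi),
        }.items():
            tot = a + b + c
            lo = 1 if name == "D" else 0
            if np.abs(tot[lo:] - 1).max() > 1e-9:
                raise XtclassError(
                    f"outgoing {name}-state transitions must sum to 1"
                )

    @property
    def n_match(self) -> int:
        return self.match_emissions.shape[0]

    def to_json(self, path) -> None:
        doc = {
            "format": "xtclass-hmm",
            "version": FORMAT_VERSION,
            "alpha": self.alpha,
            "log_base": 2,
            "background": self.background.tolist(),
            "match_emissions": self.match_emissions.tolist(),
            "transitions": {
                n: getattr(self, n).tolist()
                for n in (
                    "amm", "ami", "amd", "aim", "aii", "aid",
                    "adm", "add", "adi",
                )
            },
        }
        with open(path, "w") as fh:
            json.dump(doc, fh)

    @classmethod
    def from_json(cls, path) -> "ProfileHmm":
        with open(path) as fh:
            doc = json.load(fh)
        if doc.get("format") != "xtclass-hmm" or doc.get("version") != FORMAT_VERSION:
            raise XtclassError(f"unsupported HMM file {path}")
        tr = {k: np.array(v) for k, v in doc["transitions"].items()}
        return cls(
            match_emissions=np.array(doc["match_emissions"]),
            background=np.array(doc["background"]),
            alpha=doc["alpha"],
            **tr,
        )


def _state_path(rowseq: str, columns: list[int], is_match: list[bool]):
    """Yield (state, layer, residue|None) along one alignment row."""
    layer = 0
    for col, m in zip(columns, is_match):
        ch = rowseq[col - 1]
        if m:
            layer += 1
            if ch == "-":
                yield ("D", layer, None)
            else:
                yield ("M", layer, ch)
        else:
            if ch != "-":
                yield ("I", layer, ch)


def build_profile_hmm(
    msa: Msa,
    columns: list[int],
    alpha: float = 1.0,
    background: np.ndarray | None = None,
    occupancy: float = 0.5,
) -> ProfileHmm:
    """Estimate a profile HMM from selected alignment columns.

    Columns with at least *occupancy* residue occupancy become match
    states; the remaining selected columns feed insert states.
    Emissions and transitions are maximum-likelihood counts with
    Laplace pseudocount *alpha* added to every allowed outcome.
    """
    if alpha < 0:
        raise XtclassError("pseudocount must be >= 0")
    if not columns:
        raise XtclassError("no columns selected for the profile HMM")
    columns = sorted(set(columns))
    for c in columns:
        if not (1 <= c <= msa.width):
            raise XtclassError(f"column {c} outside alignment width {msa.width}")
    q = background if background is not None else UNIFORM_BACKGROUND
    nrows = len(msa.rows)
    occ = [
        sum(r[c - 1] != "-" for _, r in msa.rows) / nrows for c in columns
    ]
    is_match = [o >= occupancy for o in occ]
    k = sum(is_match)
    if k == 0:
        raise XtclassError(
            "no match states: all selected columns fall below the "
            f"{occupancy:.0%} occupancy rule"
        )

    emit = np.zeros((k, 20))
    # transition counts per source layer
    cnt = {
        key: np.zeros(k + 1)
        for key in ("mm", "mi", "md", "im", "ii", "id", "dm", "dd", "di")
    }
    for _, rowseq in msa.rows:
        prev = ("M", 0)  # begin
        for state, layer, ch in _state_path(rowseq, columns, is_match):
            if state == "M" and ch is not None:
                j = _IDX.get(ch)
                if j is not None:
                    emit[layer - 1, j] += 1
            key = prev[0].lower() + state.lower()
            cnt[key][prev[1]] += 1
            prev = (state, layer)
        key = prev[0].lower() + "m"  # transition into the end state
        cnt[key][prev[1]] += 1

    def _normalize(a, b, c):
        """Normalize (→M, →I, →D) counts per layer with pseudocount α."""
        out_a, out_b, out_c = (
            a + alpha, b + alpha, c.astype(float).copy()
        )
        out_c[:-1] += alpha          # D_{k+1} does not exist
        out_c[-1] = 0.0
        tot = out_a + out_b + out_c
        bad = tot == 0
        if bad.any():
            # unreachable layer with alpha=0: pin mass on ->M
            out_a = out_a.copy()
            out_a[bad] = 1.0
            tot = out_a + out_b + out_c
        return out_a / tot, out_b / tot, out_c / tot

    # argument order is (→M, →I, →D) counts per source layer
    amm, ami, amd = _normalize(cnt["mm"], cnt["mi"], cnt["md"])
    aim, aii, aid = _normalize(cnt["im"], cnt["ii"], cnt["id"])
    adm, adi, add = _normalize(cnt["dm"], cnt["di"], cnt["dd"])

    esum = emit.sum(axis=1, keepdims=True)
    if alpha == 0 and (esum == 0).any():
        raise XtclassError(
            "match state with no observed residues and zero pseudocount"
        )
    match_emissions = (emit + alpha) / (esum + 20 * alpha)

    return ProfileHmm(
        match_emissions=match_emissions,
        background=q.copy(),
        amm=amm, ami=ami, amd=amd,
        aim=aim, aii=aii, aid=aid,
        adm=adm, add=add, adi=adi,
        alpha=alpha,
    )


def flank_calibrated(hmm: ProfileHmm, length: int) -> ProfileHmm:
    """Copy of *hmm* with length-calibrated flank insert self-loops.

    A region-restricted profile sees no flanking residues in training,
    so the self-transitions of its first and last insert states (the de
    facto N-/C-flank states when a whole sequence is scored glocally)
    are estimated from pseudocounts alone and punish every flank
    residue heavily, burying the region signal under a length-
    proportional cost.  Resetting those two self-loops to L/(L+2) — the
    geometric expectation for a query of length L, as profile-search
    tools do — makes the flank cost O(1) while leaving every path that
    stays inside the core model untouched.
    """
    k = hmm.n_match
    loop = length / (length + 2)
    aim, aii, aid = hmm.aim.copy(), hmm.aii.copy(), hmm.aid.copy()
    for j in (0, k):
        rest = aim[j] + aid[j]
        if rest > 0:
            scale = (1 - loop) / rest
            aim[j] *= scale
            aid[j] *= scale
        else:
            aim[j] = 1 - loop
        aii[j] = loop
    return ProfileHmm(
        match_emissions=hmm.match_emissions,
        background=hmm.background,
        amm=hmm.amm, ami=hmm.ami, amd=hmm.amd,
        aim=aim, aii=aii, aid=aid,
        adm=hmm.adm, add=hmm.add, adi=hmm.adi,
        alpha=hmm.alpha,
    )


def hmm_forward_log2(hmm: ProfileHmm, seq: SequenceRecord) -> float:
    """log2 of the total (all-paths) probability of the sequence."""
    k = hmm.n_match
    q = hmm.background
    # residue emission lookups; X gets a flat 1/20 under every model
    def emis_m(ch: str) -> np.ndarray:
        j = _IDX.get(ch)
        if j is None:
            return np.full(k, 1 / 20)
        return hmm.match_emissions[:, j]

    def emis_i(ch: str) -> float:
        j = _IDX.get(ch)
        return 1 / 20 if j is None else float(q[j])

    # scaled probability-space forward.  fM/fD indexed 1..k, fI indexed 0..k
    fM = np.zeros(k + 1)
    fI = np.zeros(k + 1)
    fD = np.zeros(k + 1)
    fM[0] = 1.0  # begin state
    # deletes reachable before any emission: B->D1->D2->...
    fD[1] = fM[0] * hmm.amd[0]
    for j in range(2, k + 1):
        fD[j] = fD[j - 1] * hmm.add[j - 1]
    log2_total = 0.0

    for ch in seq.residues:
        em = emis_m(ch)
        ei = emis_i(ch)
        newM = np.zeros(k + 1)
        newM[1:] = em * (
            fM[:-1] * hmm.amm[:-1]
            + fI[:-1] * hmm.aim[:-1]
            + fD[:-1] * hmm.adm[:-1]
        )
        newI = ei * (fM * hmm.ami + fI * hmm.aii + fD * hmm.adi)
        newD = np.zeros(k + 1)
        c = newM[:-1] * hmm.amd[:-1] + newI[:-1] * hmm.aid[:-1]  # into D_{j+1}
        acc = 0.0
        for j in range(1, k + 1):
            acc = acc * (hmm.add[j - 1] if j > 1 else 0.0) + c[j - 1]
            newD[j] = acc
        fM, fI, fD = newM, newI, newD
        scale = max(fM.max(), fI.max(), fD.max())
        if scale <= 0:
            return float("-inf")
        fM /= scale
        fI /= scale
        fD /= scale
        log2_total += np.log2(scale)

    p_end = fM[k] * hmm.amm[k] + fI[k] * hmm.aim[k] + fD[k] * hmm.adm[k]
    if p_end <= 0:
        return float("-inf")
    return log2_total + float(np.log2(p_end))


def hmm_score(
    hmm: ProfileHmm, seq: SequenceRecord, length_calibrated: bool = True
) -> float:
    """Forward log-odds score in bits vs. the i.i.d. background model.

    With *length_calibrated* (the default) the flank insert self-loops
    are set per query via :func:`flank_calibrated`, so whole sequences
    can be scored against a region-restricted profile.  Poor matches
    give low scores, never errors.
    """
    if length_calibrated:
        hmm = flank_calibrated(hmm, len(seq))
    fwd = hmm_forward_log2(hmm, seq)
    null = 0.0
    for ch in seq.residues:
        j = _IDX.get(ch)
        null += np.log2(1 / 20 if j is None else hmm.background[j])
    return fwd - null


# ---------------------------------------------------------------------------
# combined profile feature extraction


@dataclass
class ProfileFeatureSet:
    """Bundle of profile models producing per-sequence named features.

    Sequences that are themselves rows of the source alignment are
    scored against jackknifed models (their own row left out of the
    counts): a sequence contributing to a profile matches it partly
    because of itself, and that self-match bias would leak optimism
    into every feature computed for the training positives.
    """

    patterns: list[PrositePattern] = field(default_factory=list)
    pssm: Pssm | None = None
    hmms: dict[str, ProfileHmm] = field(default_factory=dict)
    source_msa: Msa | None = None
    source_columns: dict[str, list[int]] = field(default_factory=dict)
    pssm_columns: list[int] | None = None
    alpha: float = 1.0
    background: np.ndarray | None = None

    def feature_names(self) -> list[str]:
        names: list[str] = []
        for i in range(1, len(self.patterns) + 1):
            names += [f"PROSITE.{i}.count", f"PROSITE.{i}.presence"]
        if self.pssm is not None:
            names += PSSM_FEATURE_NAMES
        names += [f"HMM.{kind}" for kind in sorted(self.hmms)]
        return names

    def _jackknifed(self, rid: str) -> tuple[Pssm | None, dict[str, ProfileHmm]]:
        reduced = Msa([r for r in self.source_msa.rows if r[0] != rid])
        pssm = None
        if self.pssm is not None:
            pssm = build_pssm(
                reduced, columns=self.pssm_columns,
                alpha=self.alpha, background=self.background,
            )
        hmms = {
            kind: build_profile_hmm(
                reduced, cols, alpha=self.alpha, background=self.background
            )
            for kind, cols in self.source_columns.items()
        }
        return pssm, hmms

    def _models_for(self, seq: SequenceRecord):
        if (
            self.source_msa is not None
            and len(self.source_msa.rows) > 2
            and any(rid == seq.id for rid, _ in self.source_msa.rows)
        ):
            return self._jackknifed(seq.id)
        return self.pssm, self.hmms

    def features_for(self, seq: SequenceRecord) -> dict[str, float]:
        out = prosite_features(seq, self.patterns) if self.patterns else {}
        pssm, hmms = self._models_for(seq)
        if pssm is not None:
            out.update(pssm_features(seq, pssm))
        for kind in sorted(self.hmms):
            out[f"HMM.{kind}"] = hmm_score(hmms[kind], seq)
        return out

    def features(self, records: list[SequenceRecord]) -> pd.DataFrame:
        rows = [self.features_for(r) for r in records]
        df = pd.DataFrame(rows, index=[r.id for r in records])
        df.index.name = "id"
        return df[self.feature_names()]


def build_profile_features(
    msa: Msa,
    annotation: RegionAnnotation | None = None,
    patterns: list[str] | None = None,
    alpha: float = 1.0,
    background: np.ndarray | None = None,
) -> ProfileFeatureSet:
    """Build the full profile feature set from the positives alignment.

    All position-specific features are computed on the curated regions:
    when an annotation is given, the PSSM is built from the annotated
    columns (all region kinds combined) and one profile HMM is built
    per region kind.  Without an annotation the PSSM falls back to
    every alignment column with >= 50% occupancy.
    """
    compiled = [compile_prosite(p) for p in (patterns or [])]
    columns = (
        map_regions_to_columns(msa, annotation)
        if annotation is not None else None
    )
    pssm = build_pssm(msa, columns=columns, alpha=alpha, background=background)
    hmms: dict[str, ProfileHmm] = {}
    source_columns: dict[str, list[int]] = {}
    if annotation is not None:
        for kind in sorted({k for _, _, k in annotation.regions}):
            cols = columns_for_kind(msa, annotation, kind)
            if cols:
                hmms[kind] = build_profile_hmm(
                    msa, cols, alpha=alpha, background=background
                )
                source_columns[kind] = cols
    return ProfileFeatureSet(
        patterns=compiled, pssm=pssm, hmms=hmms,
        source_msa=msa, source_columns=source_columns,
        pssm_columns=columns, alpha=alpha, background=background,
    )
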