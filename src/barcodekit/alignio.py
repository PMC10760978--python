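"""Species-labeled FASTA I/O and reference-anchored alignment.

Barcode analyses start from collections of near-identical sequences (one
barcode locus, one genus).  Instead of a progressive MSA, every record is
globally aligned to a designated reference accession and projected onto the
reference coordinate system; insertions relative to the reference are dropped
(the downstream de-gapping would delete those columns anyway) and logged.
Coordinates are 1-based throughout, in the reference frame.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as BioSeqRecord

DNA_BASES = frozenset("ACGT")
#: characters that count as an observed, unambiguous base
_ACGT_CODES = np.frombuffer(b"ACGT", dtype=np.uint8)
GAP = "-"


@dataclass(frozen=True)
class SeqRecord:
    """One barcode sequence with its species label.

    ``id`` is the full FASTA header; ``species`` is the part before the first
    ``|`` (or ``"unknown"`` when the header carries no label).
    """

    id: str
    species: str
    sequence: str

    def __post_init__(self):
        if not self.sequence:
            raise ValueError(f"record {self.id!r} has an empty sequence")


@dataclass
class LabeledSequenceSet:
    """Ordered collection of species-labeled records; ids are unique."""

    records: list[SeqRecord]

    def __post_init__(self):
        if not self.records:
            raise ValueError("sequence set must contain at least one record")
        seen = set()
        for rec in self.records:
            if rec.id in seen:
                raise ValueError(f"duplicate record id {rec.id!r}")
            seen.add(rec.id)

    def __len__(self):
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    @property
    def ids(self) -> list[str]:
        return [r.id for r in self.records]

    @property
    def species_map(self) -> dict[str, str]:
        return {r.id: r.species for r in self.records}

    def get(self, record_id: str) -> SeqRecord:
        for rec in self.records:
            if rec.id == record_id:
                return rec
        raise KeyError(f"no record with id {record_id!r}")


def parse_header(header: str) -> tuple[str, str]:
    """Split a ``species|individual`` header; no ``|`` means species unknown."""
    if "|" in header:
        species = header.split("|", 1)[0]
        return species, header
    return "unknown", header


def load_labeled_fasta(path) -> LabeledSequenceSet:
    """Read a multi-FASTA whose headers follow the ``species|individual`` grammar.

    Sequences are upper-cased and RNA ``U`` is mapped to ``T``.  Headers
    without a ``|`` fall back to species ``"unknown"`` with the whole header
    as the id.  Duplicate ids and empty files are rejected.
    """
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        species, rid = parse_header(rec.description.strip())
        seq = str(rec.seq).upper().replace("U", "T")
        records.append(SeqRecord(id=rid, species=species, sequence=seq))
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    return LabeledSequenceSet(records)


def write_fasta(seqset: LabeledSequenceSet, path) -> None:
    recs = [
        BioSeqRecord(Seq(r.sequence), id=r.id, description="") for r in seqset
    ]
    SeqIO.write(recs, str(path), "fasta")


@dataclass(frozen=True)
class Scoring:
    """Global-alignment scoring; a gap of length k costs open + (k-1)*extend."""

    match: float = 2.0
    mismatch: float = -1.0
    gap_open: float = -4.0
    gap_extend: float = -1.0


@dataclass(frozen=True)
class PairAlignment:
    aligned_a: str
    aligned_b: str
    score: float

    def __post_init__(self):
        if len(self.aligned_a) != len(self.aligned_b):
            raise ValueError("aligned strings differ in length")


def align_pair(a: str, b: str, scoring: Scoring = Scoring()) -> PairAlignment:
    """Optimal global (end-to-end) pairwise alignment with affine gaps.

    Gotoh three-state dynamic programming.  Ties are broken deterministically
    during traceback: substitution is preferred over a gap in ``b``, which is
    preferred over a gap in ``a``.
    """
    if not a or not b:
        raise ValueError("align_pair requires two non-empty sequences")
    n, m = len(a), len(b)
    go, ge = scoring.gap_open, scoring.gap_extend
    av = np.frombuffer(a.encode(), dtype=np.uint8)
    bv = np.frombuffer(b.encode(), dtype=np.uint8)
    neg = -np.inf

    # state matrices: M ends in a substitution column, X ends in a gap in b
    # (a-char over '-'), Y ends in a gap in a ('-' over b-char)
    M = np.full((n + 1, m + 1), neg)
    X = np.full((n + 1, m + 1), neg)
    Y = np.full((n + 1, m + 1), neg)
    M[0, 0] = 0.0
    if n:
        X[1:, 0] = go + ge * np.arange(n)
    if m:
        Y[0, 1:] = go + ge * np.arange(m)

    jj = np.arange(1, m + 1)
    for i in range(1, n + 1):
        sub = np.where(bv == av[i - 1], scoring.match, scoring.mismatch)
        prev_best = np.maximum(np.maximum(M[i - 1, :-1], X[i - 1, :-1]), Y[i - 1, :-1])
        M[i, 1:] = prev_best + sub
        X[i, 1:] = np.maximum(
            np.maximum(M[i - 1, 1:], Y[i - 1, 1:]) + go, X[i - 1, 1:] + ge
        )
        # Y has an in-row dependency; solve the running max in closed form:
        # Y[i,j] = ge*(j-1) + max_{k<j} (max(M,X)[i,k] + go - ge*k)
        w = np.maximum(M[i, :-1], X[i, :-1]) + go - ge * np.arange(m)
        Y[i, 1:] = ge * (jj - 1) + np.maximum.accumulate(w)

    # traceback with the fixed state preference M > X > Y
    out_a, out_b = [], []
    i, j = n, m
    best = max(M[n, m], X[n, m], Y[n, m])
    if M[n, m] == best:
        state = "M"
    elif X[n, m] == best:
        state = "X"
    else:
        state = "Y"
    score = float(best)
    while i > 0 or j > 0:
        if state == "M":
            out_a.append(a[i - 1])
            out_b.append(b[j - 1])
            i, j = i - 1, j - 1
            if i == 0 and j == 0:
                break
            here = max(M[i, j], X[i, j], Y[i, j])
            state = "M" if M[i, j] == here else ("X" if X[i, j] == here else "Y")
        elif state == "X":
            out_a.append(a[i - 1])
            out_b.append(GAP)
            val = X[i, j]
            i -= 1
            if val == M[i, j] + go:
                state = "M"
            elif val == X[i, j] + ge:
                state = "X"
            else:
                state = "Y"
        else:
            out_a.append(GAP)
            out_b.append(b[j - 1])
            val = Y[i, j]
            j -= 1
            if val == M[i, j] + go:
                state = "M"
            elif val == X[i, j] + go:
                state = "X"
            else:
                state = "Y"
    return PairAlignment("".join(reversed(out_a)), "".join(reversed(out_b)), score)


@dataclass
class Alignment:
    """Reference-anchored character matrix.

    ``rows`` maps record id to an aligned string; all rows share the width of
    the reference.  ``column_map[c]`` gives the original 1-based reference
    position of current column ``c+1``; it is strictly increasing.
    ``insertions`` logs bases of non-reference records that fell between
    reference positions and were discarded, as ``(record id, reference
    position after which, length)``.
    """

    reference_id: str
    ids: list[str]
    rows: dict[str, str]
    column_map: tuple[int, ...]
    trimmed: bool = False
    insertions: list[tuple[str, int, int]] = field(default_factory=list)

    def __post_init__(self):
        widths = {len(r) for r in self.rows.values()}
        if len(widths) > 1:
            raise ValueError("alignment rows differ in length")
        if self.rows and len(self.column_map) != widths.pop():
            raise ValueError("column_map length must equal alignment width")
        if any(b <= a for a, b in zip(self.column_map, self.column_map[1:])):
            raise ValueError("column_map must be strictly increasing")
        if self.reference_id not in self.rows:
            raise ValueError(f"reference {self.reference_id!r} missing from rows")

    @property
    def width(self) -> int:
        return len(self.column_map)

    def matrix(self) -> np.ndarray:
        """Rows as a (n, width) uint8 array of ASCII codes, in ``ids`` order."""
        return np.vstack(
            [np.frombuffer(self.rows[i].encode(), dtype=np.uint8) for i in self.ids]
        )

    def comparable_mask(self) -> np.ndarray:
        """Boolean (n, width): True where a cell holds an unambiguous A/C/G/T."""
        return np.isin(self.matrix(), _ACGT_CODES)


def build_reference_msa(
    seqset: LabeledSequenceSet, reference_id: str, scoring: Scoring = Scoring()
) -> Alignment:
    """Anchor every record to the reference by pairwise global alignment.

    The result has exactly one column per reference position.  Record bases
    that align between reference positions (insertions) are dropped and
    logged; reference positions a record does not cover hold ``-``.
    """
    try:
        ref = seqset.get(reference_id)
    except KeyError:
        raise ValueError(f"reference id {reference_id!r} not in sequence set")
    rows: dict[str, str] = {reference_id: ref.sequence}
    insertions: list[tuple[str, int, int]] = []
    for rec in seqset:
        if rec.id == reference_id:
            continue
        pal = align_pair(rec.sequence, ref.sequence, scoring)
        row = []
        ref_pos = 0
        ins_run = 0
        for ca, cr in zip(pal.aligned_a, pal.aligned_b):
            if cr == GAP:  # insertion in the record relative to the reference
                ins_run += 1
                continue
            if ins_run:
                insertions.append((rec.id, ref_pos, ins_run))
                ins_run = 0
            ref_pos += 1
            row.append(ca)
        if ins_run:
            insertions.append((rec.id, ref_pos, ins_run))
        rows[rec.id] = "".join(row)
    return Alignment(
        reference_id=reference_id,
        ids=list(seqset.ids),
        rows=rows,
        column_map=tuple(range(1, len(ref.sequence) + 1)),
        trimmed=False,
        insertions=insertions,
    )


def alignment_from_seqset(
    seqset: LabeledSequenceSet, reference_id: str | None = None
) -> Alignment:
    """Treat an equal-length, indel-free set as an alignment directly.

    The simulator emits such sets; skipping the pairwise-alignment step for
    them is exact, not an approximation.
    """
    lengths = {len(r.sequence) for r in seqset}
    if len(lengths) > 1:
        raise ValueError("sequences differ in length; run build_reference_msa")
    ref = reference_id if reference_id is not None else seqset.records[0].id
    return Alignment(
        reference_id=ref,
        ids=list(seqset.ids),
        rows={r.id: r.sequence for r in seqset},
        column_map=tuple(range(1, lengths.pop() + 1)),
        trimmed=False,
    )


def trim_and_degap(alignment: Alignment) -> Alignment:
    """Cut unreliable alignment ends and remove every gapped column.

    Head/tail trimming keeps the interval between the first and last column
    at which every row holds a real base (non-gap, non-N); interior columns
    containing a gap in any row are then removed.  Interior ``N`` columns are
    kept — ``N`` is missing data, handled downstream, whereas a gap makes a
    column non-comparable.  The returned alignment carries an updated
    ``column_map`` and is idempotent under re-trimming.
    """
    mat = alignment.matrix()
    covered = (mat != ord("-")) & (mat != ord("N"))
    complete = covered.all(axis=0)
    if not complete.any():
        raise ValueError("no comparable region: no column is covered by every row")
    first = int(np.argmax(complete))
    last = int(len(complete) - 1 - np.argmax(complete[::-1]))
    keep = np.zeros(mat.shape[1], dtype=bool)
    keep[first : last + 1] = True
    keep &= (mat != ord("-")).all(axis=0)
    idx = np.flatnonzero(keep)
    rows = {i: "".join(alignment.rows[i][c] for c in idx) for i in alignment.ids}
    column_map = tuple(alignment.column_map[c] for c in idx)
    return Alignment(
        reference_id=alignment.reference_id,
        ids=list(alignment.ids),
        rows=rows,
        column_map=column_map,
        trimmed=True,
        insertions=list(alignment.insertions),
    )


def write_alignment_fasta(alignment: Alignment, path) -> None:
    recs = [
        BioSeqRecord(Seq(alignment.rows[i]), id=i, description="")
        for i in alignment.ids
    ]
    SeqIO.write(recs, str(path), "fasta")


def load_alignment_fasta(path, reference_id: str | None = None) -> Alignment:
    """Read an aligned FASTA (``-`` as gap) back into an Alignment.

    The alignment is marked trimmed when it contains no gap character, which
    is what the pipeline's own aligned output satisfies after trimming.
    """
    seqs: list[tuple[str, str]] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seqs.append((rec.description.strip(), str(rec.seq).upper()))
    if not seqs:
        raise ValueError(f"no FASTA records found in {path}")
    ids = [h for h, _ in seqs]
    ref = reference_id if reference_id is not None else ids[0]
    width = len(seqs[0][1])
    aln = Alignment(
        reference_id=ref,
        ids=ids,
        rows=dict(seqs),
        column_map=tuple(range(1, width + 1)),
        trimmed=all(GAP not in s for _, s in seqs),
    )
    return aln


def run_report(alignment: Alignment) -> str:
    """TSV report of trim boundaries and dropped insertion columns."""
    buf = io.StringIO()
    buf.write("key\tvalue\n")
    buf.write(f"reference_id\t{alignment.reference_id}\n")
    buf.write(f"trimmed\t{alignment.trimmed}\n")
    buf.write(f"width\t{alignment.width}\n")
    if alignment.column_map:
        buf.write(f"first_reference_position\t{alignment.column_map[0]}\n")
        buf.write(f"last_reference_position\t{alignment.column_map[-1]}\n")
    buf.write(f"dropped_insertions\t{len(alignment.insertions)}\n")
    for rid, pos, length in alignment.insertions:
        buf.write(f"insertion\t{rid}:after_ref_pos={pos}:len={length}\n")
    return buf.getvalue()
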