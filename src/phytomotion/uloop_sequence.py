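"""Sequence-level detection of histidine-phosphatase signature motifs and
classification of U-loop insertions.

Clade 2 histidine phosphatases carry an RHGXRXh motif (h hydrophobic)
holding the nucleophilic histidine, and either an HD proton-donor motif or,
in multiple inositol polyphosphate phosphatases (MINPPs), an HAE triplet.
A subset of bacterial MINPPs additionally carries a large polypeptide
insertion in the alpha-domain — the U-loop — followed downstream by a
characteristic DAAM tetrapeptide.  U-loops are classified by length and
cysteine content: type A (long, with two cysteines able to form a
disulfide), type B (medium) and type C (short).

The motif scanner is a direct position-by-position pattern matcher rather
than a regular-expression engine, so that regex-based checks remain an
independent verification route.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

from Bio import AlignIO, SeqIO

__all__ = [
    "ProteinSequence",
    "MotifHit",
    "ULoopAnnotation",
    "HYDROPHOBIC",
    "MOTIF_PATTERNS",
    "scan_motifs",
    "detect_uloop",
    "classify_uloop",
    "pairwise_identity",
    "read_sequences",
    "read_alignment",
]

AMINO_ACIDS = set("ACDEFGHIKLMNPQRSTVWY")
HYDROPHOBIC = frozenset("AVLIMFWY")
GAP_CHARS = set("-.")


@dataclass(frozen=True)
class ProteinSequence:
    id: str
    residues: str
    numbering_offset: int = 1  # author number of the first residue

    def __post_init__(self) -> None:
        bad = set(self.residues.upper()) - AMINO_ACIDS - {"X"}
        if bad:
            raise ValueError(f"{self.id}: invalid residue letters {sorted(bad)}")
        object.__setattr__(self, "residues", self.residues.upper())

    def author_number(self, index: int) -> int:
        return self.numbering_offset + index

    def index(self, author_number: int) -> int:
        return author_number - self.numbering_offset


@dataclass(frozen=True)
class MotifHit:
    motif_name: str
    start: int  # author numbering, inclusive
    end: int
    matched: str


@dataclass
class ULoopAnnotation:
    start: int | None
    end: int | None
    loop_type: str = "none"  # A | B | C | none
    cys_positions: list[int] = field(default_factory=list)
    daam_position: int | None = None
    evidence: str = "alignment"  # alignment | motif_anchored

    @property
    def length(self) -> int:
        if self.start is None or self.end is None:
            return 0
        return self.end - self.start + 1


# pattern tokens: a literal residue, "X" for any, "h" for hydrophobic, or a
# bracketed class like [ST]
def _compile(pattern: str) -> list[frozenset]:
    tokens: list[frozenset] = []
    i = 0
    while i < len(pattern):
        ch = pattern[i]
        if ch == "[":
            j = pattern.index("]", i)
            tokens.append(frozenset(pattern[i + 1 : j]))
            i = j + 1
        elif ch == "X":
            tokens.append(frozenset(AMINO_ACIDS | {"X"}))
            i += 1
        elif ch == "h":
            tokens.append(HYDROPHOBIC)
            i += 1
        else:
            tokens.append(frozenset(ch))
            i += 1
    return tokens


MOTIF_PATTERNS: dict[str, list[frozenset]] = {
    "RHGXRXh": _compile("RHGXRXh"),
    "HD": _compile("HD"),
    "HAE": _compile("HAE"),
    "GXLTX2G": _compile("GXLTXXG"),
    "DAAM": _compile("DAAM"),
    "RHGXRXL_ST_SXK": _compile("RHGXRXL[ST]SXK"),
}


def scan_motifs(
    seq: ProteinSequence, motifs: list[str] | None = None
) -> list[MotifHit]:
    """All matches of the signature patterns, in author numbering.

    Overlapping matches of different motifs are all reported (e.g. every
    RHGXRXL(S/T)SXK hit is also an RHGXRXh hit).
    """
    if not seq.residues:
        raise ValueError("empty sequence")
    names = motifs or list(MOTIF_PATTERNS)
    s = seq.residues
    hits: list[MotifHit] = []
    for name in names:
        tokens = MOTIF_PATTERNS[name]
        m = len(tokens)
        for i in range(len(s) - m + 1):
            if all(s[i + k] in tokens[k] for k in range(m)):
                hits.append(
                    MotifHit(
                        motif_name=name,
                        start=seq.author_number(i),
                        end=seq.author_number(i + m - 1),
                        matched=s[i : i + m],
                    )
                )
    hits.sort(key=lambda h: (h.start, h.motif_name))
    return hits


def _first_hit(hits: list[MotifHit], name: str) -> MotifHit | None:
    for h in hits:
        if h.motif_name == name:
            return h
    return None


def _cys_in(seq: ProteinSequence, start: int, end: int) -> list[int]:
    return [
        seq.author_number(i)
        for i in range(seq.index(start), seq.index(end) + 1)
        if 0 <= i < len(seq.residues) and seq.residues[i] == "C"
    ]


def detect_uloop(
    seq: ProteinSequence,
    mode: str = "alignment",
    reference: str | ProteinSequence | None = None,
    alignment: list[tuple[str, str]] | None = None,
    min_insert: int = 8,
) -> ULoopAnnotation:
    """Detect an alpha-domain insertion (U-loop) in a MINPP sequence.

    ``alignment`` mode takes a precomputed alignment containing ``seq`` and
    a non-loop ``reference`` (rows as ``(id, aligned string)``; Biopython
    alignments are accepted via :func:`read_alignment`).  The U-loop is the
    longest block of >= ``min_insert`` columns between the RHGXRXh and DAAM
    anchors where the reference is gapped and the query is not, reported in
    the query's author numbering.

    ``motif_anchored`` mode needs no reference: the loop window ends at the
    conserved block immediately preceding the DAAM motif, and its start is
    taken from the first of the conserved cysteines upstream (this mode can
    only anchor cysteine-bearing loops and may underestimate the length;
    the ``evidence`` field records which mode produced the annotation).
    """
    hits = scan_motifs(seq, ["RHGXRXh", "DAAM"])
    rhg = _first_hit(hits, "RHGXRXh")
    daam = _first_hit(hits, "DAAM")
    if mode == "alignment":
        if alignment is None or reference is None:
            raise ValueError("alignment mode needs alignment and reference")
        ref_id = reference.id if isinstance(reference, ProteinSequence) else reference
        rows = dict(alignment)
        if seq.id not in rows or ref_id not in rows:
            raise ValueError(
                f"alignment must contain rows {seq.id!r} and {ref_id!r}"
            )
        return _detect_by_alignment(
            seq, rows[seq.id], rows[ref_id], rhg, daam, min_insert
        )
    if mode == "motif_anchored":
        return _detect_by_motifs(seq, rhg, daam, min_insert)
    raise ValueError(f"unknown detection mode {mode!r}")


def _detect_by_alignment(
    seq: ProteinSequence,
    row: str,
    ref_row: str,
    rhg: MotifHit | None,
    daam: MotifHit | None,
    min_insert: int,
) -> ULoopAnnotation:
    if len(row) != len(ref_row):
        raise ValueError("aligned rows differ in length")
    # map query residue index -> alignment column
    col_of: dict[int, int] = {}
    qi = 0
    for col, ch in enumerate(row):
        if ch not in GAP_CHARS:
            col_of[qi] = col
            qi += 1
    if qi != len(seq.residues):
        raise ValueError(
            f"aligned row of {seq.id!r} does not match its sequence length"
        )
    lo_col = col_of[seq.index(rhg.end)] if rhg else 0
    hi_col = col_of[seq.index(daam.start)] if daam else len(row)
    if rhg is None and daam is None:
        return ULoopAnnotation(None, None, evidence="alignment")

    # insertion blocks: reference gapped, query not
    blocks: list[tuple[int, int]] = []
    start = None
    for col in range(lo_col, hi_col):
        ins = ref_row[col] in GAP_CHARS and row[col] not in GAP_CHARS
        if ins and start is None:
            start = col
        elif not ins and start is not None:
            blocks.append((start, col - 1))
            start = None
    if start is not None:
        blocks.append((start, hi_col - 1))
    blocks = [b for b in blocks if b[1] - b[0] + 1 >= min_insert]
    if not blocks:
        return ULoopAnnotation(
            None, None, daam_position=daam.start if daam else None,
            evidence="alignment",
        )
    b0, b1 = max(blocks, key=lambda b: b[1] - b[0])
    idx_of_col = {c: i for i, c in col_of.items()}
    start_auth = seq.author_number(idx_of_col[b0])
    end_auth = seq.author_number(idx_of_col[b1])
    ann = ULoopAnnotation(
        start=start_auth,
        end=end_auth,
        cys_positions=_cys_in(seq, start_auth, end_auth),
        daam_position=daam.start if daam else None,
        evidence="alignment",
    )
    ann.loop_type = classify_uloop(ann, seq, min_insert=min_insert)
    return ann


def _detect_by_motifs(
    seq: ProteinSequence,
    rhg: MotifHit | None,
    daam: MotifHit | None,
    min_insert: int,
    scan_window: int = 70,
) -> ULoopAnnotation:
    if rhg is None or daam is None or daam.start <= rhg.end:
        return ULoopAnnotation(None, None, evidence="motif_anchored")
    end = daam.start - 1
    lo = max(rhg.end + 1, daam.start - scan_window)
    cys = _cys_in(seq, lo, end)
    if len(cys) < 2:
        return ULoopAnnotation(
            None, None, daam_position=daam.start, evidence="motif_anchored"
        )
    ann = ULoopAnnotation(
        start=cys[0],
        end=end,
        cys_positions=cys,
        daam_position=daam.start,
        evidence="motif_anchored",
    )
    ann.loop_type = classify_uloop(ann, seq, min_insert=min_insert)
    return ann


def classify_uloop(
    ann: ULoopAnnotation,
    seq: ProteinSequence,
    long_threshold: int = 35,
    medium_threshold: int = 20,
    min_insert: int = 8,
) -> str:
    """Type A: long (>= ``long_threshold``) with >= 2 cysteines inside;
    type B: medium length (or long without the cysteine pair); type C:
    short.  Total over annotations; sub-threshold lengths give "none"."""
    if ann.start is None or ann.end is None:
        return "none"
    n_cys = len(_cys_in(seq, ann.start, ann.end))
    length = ann.length
    if length >= long_threshold:
        return "A" if n_cys >= 2 else "B"
    if length >= medium_threshold:
        return "B"
    if length >= min_insert:
        return "C"
    return "none"


def pairwise_identity(aln_seq_a: str, aln_seq_b: str) -> float:
    """Fraction of identical residue pairs over mutually non-gap columns."""
    if len(aln_seq_a) != len(aln_seq_b):
        raise ValueError("aligned rows differ in length")
    both = [
        (a, b)
        for a, b in zip(aln_seq_a.upper(), aln_seq_b.upper())
        if a not in GAP_CHARS and b not in GAP_CHARS
    ]
    if not both:
        return 0.0
    return sum(a == b for a, b in both) / len(both)


# ---------------------------------------------------------------------------
# file I/O (Biopython-backed)


def read_sequences(
    path: str | Path, numbering_offset: int = 1
) -> list[ProteinSequence]:
    return [
        ProteinSequence(rec.id, str(rec.seq), numbering_offset)
        for rec in SeqIO.parse(str(path), "fasta")
    ]


_ALN_FORMATS = {
    ".fasta": "fasta",
    ".fa": "fasta",
    ".afa": "fasta",
    ".aln": "clustal",
    ".clustal": "clustal",
    ".sto": "stockholm",
    ".stk": "stockholm",
}


def read_alignment(
    path: str | Path, format: str | None = None
) -> list[tuple[str, str]]:
    """Read a FASTA/Clustal/Stockholm alignment into (id, row) pairs."""
    path = Path(path)
    fmt = format or _ALN_FORMATS.get(path.suffix.lower(), "fasta")
    aln = AlignIO.read(str(path), fmt)
    return [(rec.id, str(rec.seq)) for rec in aln]
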