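"""Motif scanning, U-loop detection/classification and alignment metrics."""

import re

import numpy as np
import pytest

from phytomotion.synthetic_data import SyntheticSeqSpec, make_uloop_family
from phytomotion.uloop_sequence import (
    MotifHit,
    ProteinSequence,
    ULoopAnnotation,
    classify_uloop,
    detect_uloop,
    pairwise_identity,
    read_alignment,
    read_sequences,
    scan_motifs,
)

#: regex equivalents of the scanner's patterns, used as an independent
#: oracle (the scanner itself is a token matcher, not a regex engine)
_REGEX_ORACLE = {
    "RHGXRXh": r"RHG[A-Z]R[A-Z][AVLIMFWY]",
    "HD": r"HD",
    "HAE": r"HAE",
    "GXLTX2G": r"G[A-Z]LT[A-Z]{2}G",
    "DAAM": r"DAAM",
    "RHGXRXL_ST_SXK": r"RHG[A-Z]R[A-Z]L[ST]S[A-Z]K",
}


def _oracle_hits(seq: ProteinSequence):
    hits = set()
    for name, pattern in _REGEX_ORACLE.items():
        for m in re.finditer(f"(?=({pattern}))", seq.residues):
            hits.add((name, seq.author_number(m.start()), m.group(1)))
    return hits


def test_polyalanine_has_no_hits():
    seq = ProteinSequence("polyA", "A" * 200)
    assert scan_motifs(seq) == []


def test_planted_anchor_positions_in_author_numbering():
    """On a family member without the loop, the planted anchors scan at
    their canonical MINPP positions: catalytic His at 45 (inside RHGXRXh
    starting at 44), GXLTX2G at 98, HAE at 399."""
    seqs, _, _ = make_uloop_family(SyntheticSeqSpec(), n=2)
    sid, parent = seqs[1]  # loop-free member
    seq = ProteinSequence(sid, parent, numbering_offset=33)
    hits = {h.motif_name: h for h in scan_motifs(seq)}
    assert hits["RHGXRXh"].start == 44
    assert seq.residues[seq.index(45)] == "H"
    assert hits["GXLTX2G"].start == 98
    assert hits["HAE"].start == 399
    assert hits["RHGXRXL_ST_SXK"].start == 44


def test_scan_matches_regex_oracle_on_random_sequence():
    rng = np.random.default_rng(40)
    letters = rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=10_000)
    seq = ProteinSequence("rand10k", "".join(letters))
    got = {(h.motif_name, h.start, h.matched) for h in scan_motifs(seq)}
    assert got == _oracle_hits(seq)


def test_scan_shift_equivariance():
    rng = np.random.default_rng(41)
    s = "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=2000))
    base = scan_motifs(ProteinSequence("s", s, numbering_offset=1))
    shifted = scan_motifs(ProteinSequence("s", s, numbering_offset=101))
    assert [(h.motif_name, h.start + 100, h.matched) for h in base] == [
        (h.motif_name, h.start, h.matched) for h in shifted
    ]


def test_matched_substring_equals_sequence_slice():
    seqs, _, _ = make_uloop_family(SyntheticSeqSpec(), n=2)
    seq = ProteinSequence(seqs[0][0], seqs[0][1], 33)
    for h in scan_motifs(seq):
        assert h.matched == seq.residues[seq.index(h.start): seq.index(h.end) + 1]


def test_empty_sequence_rejected():
    with pytest.raises(ValueError):
        scan_motifs(ProteinSequence("e", ""))


# --- U-loop detection ------------------------------------------------------


@pytest.fixture(scope="module")
def family():
    spec = SyntheticSeqSpec(loop_length=44, loop_cys_count=2)
    seqs, aligned, truths = make_uloop_family(spec, n=6)
    return spec, seqs, aligned, truths


def test_alignment_mode_recovers_planted_span(family):
    spec, seqs, aligned, truths = family
    ref_id = next(t.seq_id for t in truths if not t.has_loop)
    for (sid, s), truth in zip(seqs, truths):
        if not truth.has_loop:
            continue
        seq = ProteinSequence(sid, s, spec.numbering_offset)
        ann = detect_uloop(seq, "alignment", reference=ref_id,
                           alignment=aligned)
        assert (ann.start, ann.end) == (truth.loop_start, truth.loop_end)
        assert ann.length == 44
        assert ann.cys_positions == truth.cys_positions
        assert ann.evidence == "alignment"


def test_loop_free_parent_detects_nothing(family):
    spec, seqs, aligned, truths = family
    loop_free = [
        (sid, s) for (sid, s), t in zip(seqs, truths) if not t.has_loop
    ]
    seq = ProteinSequence(loop_free[0][0], loop_free[0][1],
                          spec.numbering_offset)
    ann = detect_uloop(seq, "alignment", reference=loop_free[1][0],
                       alignment=aligned)
    assert ann.loop_type == "none"
    assert ann.start is None


def test_alignment_mode_invariant_to_extra_rows(family):
    spec, seqs, aligned, truths = family
    ref_id = next(t.seq_id for t in truths if not t.has_loop)
    sid, s = seqs[0]
    seq = ProteinSequence(sid, s, spec.numbering_offset)
    base = detect_uloop(seq, "alignment", reference=ref_id, alignment=aligned)
    ncol = len(aligned[0][1])
    padded = aligned + [("unrelated", "G" * ncol)]
    again = detect_uloop(seq, "alignment", reference=ref_id, alignment=padded)
    assert (base.start, base.end, base.loop_type) == (
        again.start, again.end, again.loop_type
    )


def test_motif_anchored_mode_finds_cys_anchored_window(family):
    spec, seqs, aligned, truths = family
    sid, s = seqs[0]
    truth = truths[0]
    seq = ProteinSequence(sid, s, spec.numbering_offset)
    ann = detect_uloop(seq, "motif_anchored")
    assert ann.evidence == "motif_anchored"
    # the heuristic window sits inside the loop/conserved-block region
    assert truth.loop_start <= ann.start <= ann.end
    assert ann.end < ann.daam_position


def test_motif_anchored_without_anchors_is_none():
    seq = ProteinSequence("plain", "AGGSTVK" * 30)
    ann = detect_uloop(seq, "motif_anchored")
    assert ann.loop_type == "none" and ann.start is None


def test_alignment_mode_requires_rows(family):
    spec, seqs, aligned, _ = family
    seq = ProteinSequence("ghost", "ARNDC" * 20, 1)
    with pytest.raises(ValueError):
        detect_uloop(seq, "alignment", reference="nope", alignment=aligned)


# --- classification --------------------------------------------------------


@pytest.mark.parametrize(
    "length,n_cys,expected",
    [
        (44, 2, "A"),
        (44, 0, "B"),  # length alone is insufficient for type A
        (35, 2, "A"),
        (35, 1, "B"),
        (34, 2, "B"),
        (25, 0, "B"),
        (20, 0, "B"),
        (19, 0, "C"),
        (12, 0, "C"),
        (8, 0, "C"),
        (7, 0, "none"),
    ],
)
def test_classification_rule_table(length, n_cys, expected):
    body = ["G"] * length
    for i in range(n_cys):
        body[2 * i] = "C"
    seq = ProteinSequence("x", "A" * 10 + "".join(body) + "A" * 10, 1)
    ann = ULoopAnnotation(start=11, end=10 + length)
    assert classify_uloop(ann, seq) == expected


def test_classification_total_over_empty_annotation():
    seq = ProteinSequence("x", "AAAA", 1)
    assert classify_uloop(ULoopAnnotation(None, None), seq) == "none"


# --- pairwise identity -----------------------------------------------------


def test_identity_of_identical_and_disjoint_rows():
    assert pairwise_identity("ACDEFG", "ACDEFG") == 1.0
    assert pairwise_identity("AAAAAA", "CCCCCC") == 0.0


def test_identity_counts_only_mutually_ungapped_columns():
    # 10 columns, 8 mutually non-gap, 4 identities -> 0.5
    a = "ACDEFGHIK-"
    b = "ACDE-YQLMW"
    # identities A,C,D,E at columns 1-4; mutually non-gap columns are
    # 1,2,3,4,6,7,8,9 -> 4 / 8
    assert pairwise_identity(a, b) == pytest.approx(4 / 8)


def test_identity_length_mismatch_errors():
    with pytest.raises(ValueError):
        pairwise_identity("AAA", "AA")


# --- file I/O --------------------------------------------------------------


def test_fasta_and_alignment_round_trip(tmp_path, family):
    from phytomotion.synthetic_data import write_fasta

    spec, seqs, aligned, truths = family
    fasta = tmp_path / "family.fasta"
    aln = tmp_path / "family_aligned.fasta"
    write_fasta(seqs, fasta)
    write_fasta(aligned, aln)
    back = read_sequences(fasta, numbering_offset=spec.numbering_offset)
    assert [(s.id, s.residues) for s in back] == [
        (sid, s) for sid, s in seqs
    ]
    rows = read_alignment(aln)
    assert rows == aligned
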