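"""Sequence-primitive tests: translation, seed-and-extend searches against
exhaustive dynamic-programming oracles, variable-metric alignment, consensus."""

import numpy as np
import pytest
from Bio.Seq import Seq
from hypothesis import given, settings
from hypothesis import strategies as st

from mobilome.seqcore import (
    PipelineConfig,
    SequenceRecord,
    align_pair_vm,
    build_consensus,
    find_tir,
    longest_orf,
    revcomp,
    search_nt,
    search_translated,
    translate_six_frames,
)

# ---------------------------------------------------------------------------
# oracles
# ---------------------------------------------------------------------------


def translate_oracle(nt: str) -> str:
    """Codon-by-codon translation using Biopython's single-codon translator."""
    out = []
    for i in range(0, len(nt) - 2, 3):
        codon = nt[i : i + 3]
        if "N" in codon:
            out.append("X")
        else:
            out.append(str(Seq(codon).translate()))
    return "".join(out)


def gotoh_local(q: str, s: str, score_fn, gap_open: float, gap_extend: float):
    """Exhaustive affine-gap Smith-Waterman.  Gap of length L costs
    gap_open + (L-1)*gap_extend, matching Bio.Align.PairwiseAligner.
    Returns (best score, (q_start, q_end), (s_start, s_end))."""
    n, m = len(q), len(s)
    H = np.zeros((n + 1, m + 1))
    E = np.full((n + 1, m + 1), -np.inf)  # gap in q (moving along s)
    F = np.full((n + 1, m + 1), -np.inf)  # gap in s
    ptr = {}
    best, best_cell = 0.0, (0, 0)
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            E[i, j] = max(H[i, j - 1] + gap_open, E[i, j - 1] + gap_extend)
            F[i, j] = max(H[i - 1, j] + gap_open, F[i - 1, j] + gap_extend)
            diag = H[i - 1, j - 1] + score_fn(q[i - 1], s[j - 1])
            H[i, j] = max(0.0, diag, E[i, j], F[i, j])
            if H[i, j] > best:
                best, best_cell = H[i, j], (i, j)
    # traceback for the interval only (any co-optimal path is fine)
    i, j = best_cell
    qi, sj = i, j
    while H[i, j] > 0:
        if H[i, j] == H[i - 1, j - 1] + score_fn(q[i - 1], s[j - 1]):
            i, j = i - 1, j - 1
        elif H[i, j] == E[i, j]:
            # walk the gap back
            jj = j
            while jj > 1 and E[i, jj] == E[i, jj - 1] + gap_extend:
                jj -= 1
            j = jj - 1
        else:
            ii = i
            while ii > 1 and F[ii, j] == F[ii - 1, j] + gap_extend:
                ii -= 1
            i = ii - 1
    return best, (i, qi), (j, sj)


def nw_vm_oracle(a: str, b: str, w: float) -> float:
    """Exhaustive global alignment minimising mismatches + w*gaps, then
    normalised by aligned columns (tracks columns along the optimal path)."""
    from functools import lru_cache

    @lru_cache(maxsize=None)
    def go(i: int, j: int) -> tuple[float, int]:
        if i == len(a) and j == len(b):
            return 0.0, 0
        opts = []
        if i < len(a) and j < len(b):
            c, n = go(i + 1, j + 1)
            opts.append((c + (a[i] != b[j]), n + 1))
        if i < len(a):
            c, n = go(i + 1, j)
            opts.append((c + w, n + 1))
        if j < len(b):
            c, n = go(i, j + 1)
            opts.append((c + w, n + 1))
        # the pipeline minimises raw cost with a fewest-columns tie-break
        return min(opts, key=lambda cn: (cn[0], cn[1]))

    cost, cols = go(0, 0)
    return cost / cols


def _nt_score(match=2.0, mismatch=-3.0):
    return lambda a, b: match if (a == b and a != "N") else mismatch


def random_dna(rng, n):
    return "".join(rng.choice(list("ACGT"), size=n))


# ---------------------------------------------------------------------------
# translation
# ---------------------------------------------------------------------------


def test_translate_trivial_codons():
    frames = dict(translate_six_frames(SequenceRecord("x", "ATGGCT")))
    assert frames[1] == "MA"
    frames = dict(translate_six_frames(SequenceRecord("y", "TTA")))
    assert frames[-1] == "*"  # revcomp is TAA


def test_translate_matches_codon_oracle():
    rng = np.random.default_rng(11)
    nt = random_dna(rng, 300)
    nt = nt[:100] + "N" + nt[101:]
    rec = SequenceRecord("r", nt)
    frames = dict(translate_six_frames(rec))
    for off in range(3):
        assert frames[off + 1] == translate_oracle(nt[off:])
        assert frames[-(off + 1)] == translate_oracle(revcomp(nt)[off:])


# ---------------------------------------------------------------------------
# nucleotide search
# ---------------------------------------------------------------------------


def test_search_nt_exact_substring_and_strand():
    rng = np.random.default_rng(5)
    subject = random_dna(rng, 3000)
    q = subject[700:950]
    hits = search_nt(SequenceRecord("q", q), SequenceRecord("s", subject))
    assert [(h.s_interval, h.strand) for h in hits] == [((700, 950), "+")]
    assert hits[0].identity == 1.0
    rc_hits = search_nt(SequenceRecord("q", revcomp(q)), SequenceRecord("s", subject))
    assert [(h.s_interval, h.strand) for h in rc_hits] == [((700, 950), "-")]


def test_search_nt_short_query_raises():
    with pytest.raises(ValueError):
        search_nt(SequenceRecord("q", "ACGTA"), SequenceRecord("s", "ACGT" * 100))


def test_search_nt_matches_sw_oracle_on_mutated_copy():
    rng = np.random.default_rng(17)
    subject = random_dna(rng, 5000)
    q = list(subject[2000:2200])
    for i in rng.choice(200, size=10, replace=False):
        q[i] = rng.choice([b for b in "ACGT" if b != q[i]])
    q = "".join(q)
    hits = search_nt(SequenceRecord("q", q), SequenceRecord("s", subject))
    assert len(hits) == 1
    oracle_score, _, (ss, se) = gotoh_local(q, subject, _nt_score(), -5.0, -2.0)
    assert hits[0].score == pytest.approx(oracle_score)
    assert abs(hits[0].s_interval[0] - ss) <= 5
    assert abs(hits[0].s_interval[1] - se) <= 5


def test_search_nt_strand_symmetry_property():
    rng = np.random.default_rng(23)
    subject = random_dna(rng, 2000)
    q = subject[500:700]
    fwd = search_nt(SequenceRecord("q", q), SequenceRecord("s", subject))
    rev = search_nt(SequenceRecord("q", revcomp(q)), SequenceRecord("s", subject))
    assert [h.s_interval for h in fwd] == [h.s_interval for h in rev]
    assert {h.strand for h in fwd} == {"+"} and {h.strand for h in rev} == {"-"}


# ---------------------------------------------------------------------------
# translated search
# ---------------------------------------------------------------------------


def _encode_protein(prot: str) -> str:
    from Bio.Data import CodonTable

    table = CodonTable.unambiguous_dna_by_id[1]
    codon_for = {}
    for codon, aa in sorted(table.forward_table.items()):
        codon_for.setdefault(aa, codon)
    return "".join(codon_for[a] for a in prot)


def test_search_translated_exact_encoding_full_cover():
    rng = np.random.default_rng(31)
    prot = "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=50))
    nt = _encode_protein(prot)
    genome = random_dna(rng, 1000) + nt + random_dna(rng, 900)
    hits = search_translated(SequenceRecord("p", prot), SequenceRecord("g", genome))
    assert len(hits) == 1
    h = hits[0]
    assert h.q_interval == (0, 50)
    assert h.s_interval == (1000, 1150)
    assert h.identity == 1.0 and h.strand == "+" and h.frame != 0


def test_search_translated_no_hit_in_random_sequence():
    rng = np.random.default_rng(37)
    prot = "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=50))
    genome = random_dna(rng, 3000)
    assert search_translated(SequenceRecord("p", prot), SequenceRecord("g", genome)) == []


def test_search_translated_matches_six_frame_sw_oracle():
    from Bio.Align import substitution_matrices

    blosum = substitution_matrices.load("BLOSUM62")

    def aa_score(a, b):
        return float(blosum[a, b])

    rng = np.random.default_rng(41)
    prot = "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=50))
    nt = list(_encode_protein(prot))
    for i in rng.choice(len(nt), size=8, replace=False):  # nt-level noise
        nt[i] = rng.choice([b for b in "ACGT" if b != nt[i]])
    genome = random_dna(rng, 800) + "".join(nt) + random_dna(rng, 700)
    rec = SequenceRecord("g", genome)
    hits = search_translated(SequenceRecord("p", prot), rec)
    assert hits, "planted homology must be found"
    best_hit = max(h.score for h in hits)
    oracle_best = max(
        gotoh_local(prot, frame_prot, aa_score, -11.0, -1.0)[0]
        for _, frame_prot in translate_six_frames(rec)
        if frame_prot
    )
    assert best_hit == pytest.approx(oracle_best)


def test_search_translated_minus_strand_coordinates():
    rng = np.random.default_rng(43)
    prot = "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=50))
    nt = _encode_protein(prot)
    genome = random_dna(rng, 600) + revcomp(nt) + random_dna(rng, 500)
    hits = search_translated(SequenceRecord("p", prot), SequenceRecord("g", genome))
    assert len(hits) == 1
    assert hits[0].strand == "-" and hits[0].frame < 0
    assert hits[0].s_interval == (600, 750)


# ---------------------------------------------------------------------------
# variable-metric alignment
# ---------------------------------------------------------------------------


@pytest.mark.parametrize("w", [0.0, 0.25, 0.5, 1.0])
def test_vm_identical_sequences_distance_zero(w):
    assert align_pair_vm("ACGT", "ACGT", w).vm_distance == 0.0


def test_vm_single_gap_fifth_nucleotide():
    assert align_pair_vm("ACGT", "ACG", 1.0).vm_distance == pytest.approx(0.25)
    assert align_pair_vm("ACGT", "ACG", 0.0).vm_distance == 0.0


@pytest.mark.parametrize("w", [0.3, 0.6, 1.0])
def test_vm_matches_exhaustive_nw_oracle(w):
    rng = np.random.default_rng(47)
    for _ in range(4):
        a = random_dna(rng, 14)
        b = random_dna(rng, rng.integers(9, 15))
        assert align_pair_vm(a, b, w).vm_distance == pytest.approx(nw_vm_oracle(a, b, w))


def test_vm_symmetry_and_monotone_in_w():
    rng = np.random.default_rng(53)
    a, b = random_dna(rng, 30), random_dna(rng, 26)
    for w in [0.0, 0.2, 0.5, 0.8, 1.0]:
        d_ab = align_pair_vm(a, b, w).vm_distance
        d_ba = align_pair_vm(b, a, w).vm_distance
        assert d_ab == pytest.approx(d_ba)
    # fixed-alignment monotonicity: recompute the w=1 alignment at lower w
    aln = align_pair_vm(a, b, 1.0)
    gaps = sum(1 for x, y in zip(aln.aligned_a, aln.aligned_b) if "-" in (x, y))
    mism = len(aln.aligned_a) - gaps - sum(
        1 for x, y in zip(aln.aligned_a, aln.aligned_b) if x == y and x != "-")
    cols = len(aln.aligned_a)
    assert (mism + 0.5 * gaps) / cols <= aln.vm_distance


def test_vm_alignment_recovers_inputs():
    aln = align_pair_vm("ACGTACGT", "ACGACGT", 0.5)
    assert aln.aligned_a.replace("-", "") == "ACGTACGT"
    assert aln.aligned_b.replace("-", "") == "ACGACGT"


# ---------------------------------------------------------------------------
# consensus
# ---------------------------------------------------------------------------


def test_consensus_tie_rules():
    assert build_consensus(["AC-T", "ACGT", "ACGT"]).residues == "ACGT"
    # {A, A, -} keeps the base; {-, -, A} drops the column
    assert build_consensus(["A--", "AA-", "-AA"]).residues == "AA"
    # base ties resolve A < C < G < T
    assert build_consensus(["AC", "CC", "GA", "TA"]).residues == "AA"


def test_consensus_unequal_lengths_error():
    with pytest.raises(ValueError):
        build_consensus(["ACGT", "ACG"])


def test_consensus_recovers_ancestor_from_mutated_copies():
    rng = np.random.default_rng(59)
    ancestor = random_dna(rng, 600)
    copies = []
    for _ in range(20):
        c = list(ancestor)
        for i in rng.choice(600, size=12, replace=False):  # 2% divergence
            c[i] = rng.choice([b for b in "ACGT" if b != c[i]])
        copies.append("".join(c))
    cons = build_consensus(copies).residues
    ident = sum(1 for a, b in zip(cons, ancestor) if a == b) / len(ancestor)
    assert ident >= 0.99


@given(st.text(alphabet="ACGT", min_size=5, max_size=40), st.integers(2, 6))
@settings(max_examples=30, deadline=None)
def test_consensus_of_identical_copies_property(seq, n):
    assert build_consensus([seq] * n).residues == seq


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------


@given(st.text(alphabet="ACGTN", min_size=1, max_size=60))
@settings(max_examples=50, deadline=None)
def test_revcomp_involution(seq):
    assert revcomp(revcomp(seq)) == seq


def test_find_tir_recovers_planted_tir():
    rng = np.random.default_rng(61)
    tir = "CGAGGGTCGTTTGAAAAGTCCGTGCAAA"
    elem = tir + random_dna(rng, 500) + revcomp(tir)
    assert find_tir(elem) == tir


def test_find_tir_absent_in_random_sequence():
    rng = np.random.default_rng(67)
    assert find_tir(random_dna(rng, 400)) == ""


def test_longest_orf_simple():
    orf = "ATG" + _encode_protein("HELLDWKRMAN") + "TAA"
    nt = "CCGT" + orf + "GGAC"
    length, prot = longest_orf(nt)
    assert length == 3 + 3 * 11
    assert prot.startswith("M") and "*" not in prot


def test_pipeline_config_roundtrip(tmp_path):
    cfg = PipelineConfig(cluster_identity=0.85, mite_min_copies=12)
    path = tmp_path / "c.cfg"
    path.write_text("cluster_identity = 0.85\nmite_min_copies = 12  # floor\n")
    assert PipelineConfig.from_file(path) == cfg
    with pytest.raises(ValueError):
        PipelineConfig(min_copy_len_bp=0)
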