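"""Shared sequence primitives for the mobilome pipeline.

This module provides the low-level machinery every other stage builds on:

* FASTA I/O (thin wrappers around :mod:`Bio.SeqIO`);
* deterministic seed-and-extend local searches at the nucleotide and the
  translated (six-frame) level — in-package stand-ins for BLASTN / TBLASTN;
* global pairwise alignment with a tunable gap weight, where an alignment
  gap can be scored anywhere between "ignored" (w = 0) and "a fifth
  nucleotide", i.e. exactly like a mismatch (w = 1);
* majority-rule consensus construction biased toward the longest elements;
* small helpers shared by the annotation stages: ORF scanning, terminal
  inverted repeat (TIR) detection, center-star multiple alignment.

Coordinates are 0-based, half-open everywhere in memory.  Minus-strand hits
are stored on plus-strand subject coordinates with a strand flag.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, fields, replace
from pathlib import Path
from typing import Iterable, Sequence

import edlib
import numpy as np
from Bio import SeqIO
from Bio.Align import PairwiseAligner, substitution_matrices
from Bio.Data import CodonTable
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

# ---------------------------------------------------------------------------
# Records and configuration
# ---------------------------------------------------------------------------

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")
DNA_ALPHABET = frozenset("ACGTN")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (N stays N)."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class SequenceRecord:
    """A named sequence.  ``residues`` is DNA for genomic records and amino
    acids for protein queries; DNA validity can be checked with
    :meth:`validate_dna`."""

    id: str
    residues: str
    description: str = ""

    def __len__(self) -> int:
        return len(self.residues)

    def validate_dna(self) -> None:
        if not self.residues:
            raise ValueError(f"empty sequence for record {self.id!r}")
        bad = set(self.residues.upper()) - DNA_ALPHABET
        if bad:
            raise ValueError(f"record {self.id!r} has non-ACGTN symbols: {sorted(bad)}")


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read a (wrapped or unwrapped, CRLF-tolerant) multi-record FASTA file."""
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        records.append(SequenceRecord(rec.id, str(rec.seq).upper(), rec.description))
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path, width: int = 70) -> None:
    bio = [
        _BioSeqRecord(Seq(r.residues), id=r.id, description=r.description or "")
        for r in records
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(bio)


@dataclass
class PipelineConfig:
    """All numeric thresholds used by the pipeline, in one place.

    Defaults follow the published Tc1-mariner mining protocol: hits closer
    than 1 kb are chained into one copy, copies under 400 bp are discarded,
    500 bp flanks are kept for segmental-duplication detection, clustering
    uses 80% identity testing both orientations, and lineages need at least
    5 independent clean copies.  MITE discovery uses >= 11 bp inverted seeds
    spanning <= 750 bp with 60 bp flanks and a 10-copy floor; horizontal
    transfer screening uses the 75% identity / 90% coverage rule.
    """

    chain_max_gap_bp: int = 1000
    min_copy_len_bp: int = 400
    flank_len_bp: int = 500
    cluster_identity: float = 0.80
    cluster_rev: bool = True
    min_lineage_copies: int = 5
    tir_seed_min_bp: int = 11
    mite_max_span_bp: int = 750
    mite_flank_bp: int = 60
    mite_min_copies: int = 10
    partner_min_len_bp: int = 1000
    ht_min_identity: float = 0.75
    ht_min_coverage: float = 0.90
    synteny_window_bp: int = 50000
    active_orf_min_bp: int = 1000
    mariner_tsd: str = "TA"
    rearranged_size_line_bp: int = 938
    # operational knobs not fixed by the protocol (documented in docs/methods.md)
    mite_homogeneity_min: float = 0.70
    flank_dup_identity: float = 0.90
    deleted_length_frac: float = 0.80
    tir_max_mismatch_frac: float = 0.20
    tir_min_len: int = 10
    novelty_threshold: float = 0.45
    recent_epsilon: float = 0.005

    def __post_init__(self) -> None:
        for name in ("chain_max_gap_bp", "min_copy_len_bp", "flank_len_bp",
                     "tir_seed_min_bp", "mite_max_span_bp", "mite_flank_bp",
                     "partner_min_len_bp", "synteny_window_bp", "active_orf_min_bp"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("cluster_identity", "ht_min_identity", "ht_min_coverage"):
            v = getattr(self, name)
            if not 0.0 < v <= 1.0:
                raise ValueError(f"{name} must be in (0, 1]")

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        """Parse a ``key = value`` config file (``#`` comments allowed)."""
        kwargs: dict = {}
        types = {f.name: f.type for f in fields(cls)}
        for line in Path(path).read_text().splitlines():
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            key, _, value = line.partition("=")
            key, value = key.strip(), value.strip()
            if key not in types:
                raise KeyError(f"unknown config key {key!r}")
            current = getattr(cls(), key)
            if isinstance(current, bool):
                kwargs[key] = value.lower() in ("1", "true", "yes")
            elif isinstance(current, int):
                kwargs[key] = int(value)
            elif isinstance(current, float):
                kwargs[key] = float(value)
            else:
                kwargs[key] = value
        return cls(**kwargs)


# ---------------------------------------------------------------------------
# Translation
# ---------------------------------------------------------------------------

_STANDARD = CodonTable.unambiguous_dna_by_id[1]
_CODON_MAP: dict[str, str] = dict(_STANDARD.forward_table)
for _stop in _STANDARD.stop_codons:
    _CODON_MAP[_stop] = "*"


def translate_frame(nt: str, offset: int) -> str:
    """Translate one reading frame.  N-containing codons give 'X', stops '*'."""
    out = []
    for i in range(offset, len(nt) - 2, 3):
        codon = nt[i : i + 3]
        out.append(_CODON_MAP.get(codon, "X"))
    return "".join(out)


def translate_six_frames(seq: SequenceRecord) -> list[tuple[int, str]]:
    """All six reading frames as ``(frame, protein)`` with frames in
    {+1,+2,+3,-1,-2,-3}; negative frames read off the reverse complement."""
    if not seq.residues:
        raise ValueError("cannot translate an empty sequence")
    fwd = seq.residues.upper()
    rev = revcomp(fwd)
    frames = []
    for off in range(3):
        frames.append((off + 1, translate_frame(fwd, off)))
    for off in range(3):
        frames.append((-(off + 1), translate_frame(rev, off)))
    return frames


# ---------------------------------------------------------------------------
# Local hits and seed-and-extend search
# ---------------------------------------------------------------------------


@dataclass
class LocalHit:
    """A local alignment hit.  ``s_interval`` is always on plus-strand subject
    coordinates; ``frame`` is 0 for nucleotide-level hits."""

    query_id: str
    subject_id: str
    q_interval: tuple[int, int]
    s_interval: tuple[int, int]
    strand: str
    frame: int
    score: float
    identity: float

    def __post_init__(self) -> None:
        if self.q_interval[0] >= self.q_interval[1] or self.s_interval[0] >= self.s_interval[1]:
            raise ValueError("hit intervals must satisfy start < end")
        if not 0.0 <= self.identity <= 1.0:
            raise ValueError("identity must be in [0, 1]")


HIT_TSV_HEADER = ["query_id", "subject_id", "q_start", "q_end", "s_start", "s_end",
                  "strand", "frame", "score", "identity"]


def write_hits_tsv(hits: Sequence[LocalHit], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(HIT_TSV_HEADER) + "\n")
        for h in hits:
            fh.write("\t".join(map(str, [
                h.query_id, h.subject_id, h.q_interval[0], h.q_interval[1],
                h.s_interval[0], h.s_interval[1], h.strand, h.frame,
                f"{h.score:g}", f"{h.identity:.4f}"])) + "\n")


_NT_CODE = np.full(256, 4, dtype=np.int64)
for _i, _b in enumerate("ACGT"):
    _NT_CODE[ord(_b)] = _i
    _NT_CODE[ord(_b.lower())] = _i

_AA_ALPHABET = "ARNDCQEGHILKMFPSTWYVBZX*"
_AA_CODE = np.full(256, len(_AA_ALPHABET), dtype=np.int64)
for _i, _a in enumerate(_AA_ALPHABET):
    _AA_CODE[ord(_a)] = _i

_BLOSUM62 = substitution_matrices.load("BLOSUM62")
# plain-dict view of BLOSUM62 for the (hot) ungapped x-drop extensions
_BLOSUM_DICT: dict[tuple[str, str], float] = {
    (a, b): float(_BLOSUM62[a, b]) for a in _AA_ALPHABET for b in _AA_ALPHABET
}


def _encode(seq: str, table: np.ndarray) -> np.ndarray:
    return table[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def _kmer_hashes(codes: np.ndarray, k: int, base: int) -> tuple[np.ndarray, np.ndarray]:
    """Rolling k-mer hashes and a validity mask (False where the window
    contains an out-of-alphabet symbol such as N)."""
    n = len(codes) - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=bool)
    h = np.zeros(n, dtype=np.int64)
    valid = np.ones(n, dtype=bool)
    for j in range(k):
        window = codes[j : j + n]
        h = h * base + np.where(window >= base, 0, window)
        valid &= window < base
    return h, valid


def _find_seeds(q_codes: np.ndarray, s_codes: np.ndarray, k: int, base: int,
                max_seeds: int = 500_000) -> list[tuple[int, int]]:
    qh, qv = _kmer_hashes(q_codes, k, base)
    sh, sv = _kmer_hashes(s_codes, k, base)
    if len(qh) == 0 or len(sh) == 0:
        return []
    qpos_by_hash: dict[int, list[int]] = {}
    for qpos in np.nonzero(qv)[0]:
        qpos_by_hash.setdefault(int(qh[qpos]), []).append(int(qpos))
    mask = sv & np.isin(sh, np.fromiter(qpos_by_hash, dtype=np.int64, count=len(qpos_by_hash)))
    seeds: list[tuple[int, int]] = []
    for spos in np.nonzero(mask)[0]:
        for qpos in qpos_by_hash[int(sh[spos])]:
            seeds.append((qpos, int(spos)))
            if len(seeds) >= max_seeds:
                return seeds
    return seeds


def _group_seeds(seeds: list[tuple[int, int]], qlen: int, band: int = 24,
                 s_gap: int | None = None) -> list[list[tuple[int, int]]]:
    """Group seeds into diagonal bands; each group triggers one DP extension."""
    if s_gap is None:
        s_gap = max(2 * qlen, 200)
    seeds = sorted(seeds, key=lambda qs: (qs[1] - qs[0], qs[1]))
    groups: list[list[tuple[int, int]]] = []
    for qpos, spos in seeds:
        d = spos - qpos
        placed = False
        if groups:
            lq, ls = groups[-1][-1]
            if abs(d - (ls - lq)) <= band and abs(spos - ls) <= s_gap:
                groups[-1].append((qpos, spos))
                placed = True
        if not placed:
            groups.append([(qpos, spos)])
    return groups


def _ungapped_score(q: str, s: str, qpos: int, spos: int, k: int,
                    score_fn, xdrop: float) -> float:
    """X-drop ungapped extension of an exact seed match, both directions."""
    best = total = sum(score_fn(q[qpos + j], s[spos + j]) for j in range(k))
    i, j = qpos + k, spos + k
    run = total
    while i < len(q) and j < len(s):
        run += score_fn(q[i], s[j])
        if run > best:
            best = run
        if best - run > xdrop:
            break
        i += 1
        j += 1
    fwd_best = best
    run = best = 0.0
    i, j = qpos - 1, spos - 1
    while i >= 0 and j >= 0:
        run += score_fn(q[i], s[j])
        if run > best:
            best = run
        if best - run > xdrop:
            break
        i -= 1
        j -= 1
    return fwd_best + best


def _nt_matrix(match: float, mismatch: float):
    mat = substitution_matrices.Array("ACGTN", dims=2)
    for a in "ACGTN":
        for b in "ACGTN":
            # N never matches anything, including itself
            mat[a, b] = match if (a == b and a != "N") else mismatch
    return mat


def _alignment_stats(alignment, query: str, subject: str,
                     never_match: str = "") -> tuple[int, int, int, int, int, int]:
    """(q_start, q_end, s_start, s_end, matches, columns) of a local alignment."""
    qblocks, sblocks = alignment.aligned
    qs, qe = int(qblocks[0][0]), int(qblocks[-1][1])
    ss, se = int(sblocks[0][0]), int(sblocks[-1][1])
    matches = aligned = 0
    for (qb0, qb1), (sb0, sb1) in zip(qblocks, sblocks):
        aligned += qb1 - qb0
        for a, b in zip(query[qb0:qb1], subject[sb0:sb1]):
            if a == b and a not in never_match:
                matches += 1
    columns = aligned + ((qe - qs) - aligned) + ((se - ss) - aligned)
    return qs, qe, ss, se, matches, columns


def _search_one_orientation(query: str, subject: str, *, k: int, base: int,
                            table: np.ndarray, aligner: PairwiseAligner,
                            score_fn, min_score: float, ungapped_min: float,
                            xdrop: float, never_match: str = "") -> list[tuple[int, int, int, int, float, float]]:
    """Seed, group, DP-extend.  Returns (qs, qe, ss, se, score, identity)."""
    seeds = _find_seeds(_encode(query, table), _encode(subject, table), k, base)
    results = []
    seen: set[tuple[int, int, int, int]] = set()
    for group in _group_seeds(seeds, len(query)):
        # gate every group on cheap x-drop extensions before paying for a
        # DP: chance seed clusters die here, genuine homology segments
        # extend far beyond the seed (deletions are bridged later, at the
        # hit-chaining level, so no group has to span them)
        reps = {0, len(group) // 2, len(group) - 1}
        if not any(_ungapped_score(query, subject, *group[r], k, score_fn, xdrop)
                   >= ungapped_min for r in sorted(reps)):
            continue
        s_lo = max(0, min(s for _, s in group) - len(query) - 50)
        s_hi = min(len(subject), max(s for _, s in group) + k + len(query) + 50)
        window = subject[s_lo:s_hi]
        alns = aligner.align(query, window)
        if alns.score < min_score:
            continue
        aln = alns[0]
        qs, qe, ws, we, matches, columns = _alignment_stats(aln, query, window, never_match)
        key = (qs, qe, s_lo + ws, s_lo + we)
        if key in seen or columns == 0:
            continue
        seen.add(key)
        results.append((qs, qe, s_lo + ws, s_lo + we, float(alns.score), matches / columns))
    return results


def search_nt(query: SequenceRecord, subject: SequenceRecord, *, min_word: int = 11,
              both_strands: bool = True, match: float = 2.0, mismatch: float = -3.0,
              gap_open: float = -5.0, gap_extend: float = -2.0,
              min_score: float = 60.0) -> list[LocalHit]:
    """Nucleotide seed-and-extend local search (BLASTN stand-in).

    Exact ``min_word``-mers seed a banded group, each group is extended with a
    full local DP over a subject window.  Subject coordinates are always on
    the plus strand; minus-strand hits carry ``strand='-'`` with the query
    interval mapped back to the input query orientation.
    """
    if min_word < 4:
        raise ValueError("min_word must be >= 4")
    if len(query.residues) < min_word:
        raise ValueError(
            f"query {query.id!r} ({len(query.residues)} bp) shorter than min_word={min_word}")
    if not subject.residues:
        return []
    aligner = PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = _nt_matrix(match, mismatch)
    aligner.open_gap_score = gap_open
    aligner.extend_gap_score = gap_extend

    def score_fn(a: str, b: str) -> float:
        return match if (a == b and a != "N") else mismatch

    hits: list[LocalHit] = []
    orientations = [("+", query.residues.upper())]
    if both_strands:
        orientations.append(("-", revcomp(query.residues.upper())))
    subj = subject.residues.upper()
    qlen = len(query.residues)
    for strand, qseq in orientations:
        for qs, qe, ss, se, score, ident in _search_one_orientation(
                qseq, subj, k=min_word, base=4, table=_NT_CODE, aligner=aligner,
                score_fn=score_fn, min_score=min_score,
                ungapped_min=min(min_score, 0.8 * min_score + 4), xdrop=20.0,
                never_match="N"):
            if strand == "-":
                qs, qe = qlen - qe, qlen - qs
            hits.append(LocalHit(query.id, subject.id, (qs, qe), (ss, se),
                                 strand, 0, score, ident))
    hits.sort(key=lambda h: (h.s_interval, h.strand, h.q_interval))
    return hits


def search_translated(query_protein: SequenceRecord, genome: SequenceRecord, *,
                      seed_len: int = 4, min_score: float = 100.0,
                      gap_open: float = -11.0, gap_extend: float = -1.0,
                      frames: Sequence[tuple[int, str]] | None = None) -> list[LocalHit]:
    """Translated seed-and-extend search of a protein query against all six
    frames of a genome (TBLASTN stand-in).

    Exact ``seed_len``-mer amino-acid seeds are extended with BLOSUM62-scored
    gapped DP; the default raw-score threshold is low enough that any 50-aa
    exact match passes (BLOSUM62 diagonal >= 4).  Hit subject intervals are
    reported in plus-strand nucleotide coordinates.
    """
    if len(query_protein.residues) < seed_len:
        raise ValueError("query shorter than the seed word size")
    if not genome.residues:
        return []
    if frames is None:
        frames = translate_six_frames(genome)
    aligner = PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = _BLOSUM62
    aligner.open_gap_score = gap_open
    aligner.extend_gap_score = gap_extend

    def score_fn(a: str, b: str) -> float:
        return _BLOSUM_DICT.get((a, b), -4.0)

    qseq = query_protein.residues.upper()
    L = len(genome.residues)
    hits: list[LocalHit] = []
    for frame, prot in frames:
        if not prot:
            continue
        for qs, qe, ps, pe, score, ident in _search_one_orientation(
                qseq, prot, k=seed_len, base=len(_AA_ALPHABET), table=_AA_CODE,
                aligner=aligner, score_fn=score_fn, min_score=min_score,
                ungapped_min=0.5 * min_score, xdrop=16.0):
            off = abs(frame) - 1
            nt_s, nt_e = off + 3 * ps, off + 3 * pe
            if frame > 0:
                s_interval = (nt_s, nt_e)
                strand = "+"
            else:
                s_interval = (L - nt_e, L - nt_s)
                strand = "-"
            hits.append(LocalHit(query_protein.id, genome.id, (qs, qe),
                                 s_interval, strand, frame, score, ident))
    hits.sort(key=lambda h: (h.s_interval, h.strand, h.q_interval))
    return hits


def search_translated_many(queries: Sequence[SequenceRecord], genome: SequenceRecord,
                           **kwargs) -> list[LocalHit]:
    """Search several protein queries, translating the genome only once."""
    frames = translate_six_frames(genome) if genome.residues else []
    hits: list[LocalHit] = []
    for q in queries:
        hits.extend(search_translated(q, genome, frames=frames, **kwargs))
    return hits


# ---------------------------------------------------------------------------
# Variable-metric global alignment
# ---------------------------------------------------------------------------


@dataclass
class PairwiseAlignment:
    """A global alignment scored under the variable gap metric: each mismatch
    column costs 1 and each gap column costs ``gap_weight`` (w = 1 treats a
    gap as a fifth nucleotide, w = 0 ignores gap columns)."""

    aligned_a: str
    aligned_b: str
    identity: float
    vm_distance: float
    gap_weight: float


def align_pair_vm(a: str, b: str, gap_weight: float) -> PairwiseAlignment:
    """Global alignment minimising ``mismatches + w * gap_columns``.

    The DP is exact (Needleman-Wunsch over the weighted edit costs).  Among
    equal-cost alignments the shortest one (fewest columns) is canonical —
    enforced by an infinitesimal per-column charge — which makes the
    normalised distance well defined and symmetric in the inputs.
    """
    if not a or not b:
        raise ValueError("align_pair_vm requires non-empty sequences")
    if not 0.0 <= gap_weight <= 1.0:
        raise ValueError("gap_weight must be in [0, 1]")
    a, b = a.upper(), b.upper()
    n, m = len(a), len(b)
    w = float(gap_weight)
    col_eps = 1e-8  # column tie-break charge, far below any real cost step
    gw = w + col_eps
    arr_a = np.frombuffer(a.encode("ascii"), dtype=np.uint8)
    arr_b = np.frombuffer(b.encode("ascii"), dtype=np.uint8)
    D = np.empty((n + 1, m + 1), dtype=np.float64)
    D[0, :] = gw * np.arange(m + 1)
    jw = gw * np.arange(m + 1)
    for i in range(1, n + 1):
        sub = (arr_a[i - 1] != arr_b).astype(np.float64) + col_eps
        diag = D[i - 1, :-1] + sub
        up = D[i - 1, 1:] + gw
        M = np.minimum(diag, up)
        base = np.concatenate(([D[i - 1, 0] + gw], M))  # base[0] covers D[i,0]
        D[i] = np.minimum.accumulate(base - jw) + jw
        D[i, 0] = D[i - 1, 0] + gw
    # traceback (prefer diagonal, then up, then left)
    out_a: list[str] = []
    out_b: list[str] = []
    i, j = n, m
    eps = 1e-10
    while i > 0 or j > 0:
        here = D[i, j]
        if i > 0 and j > 0 and abs(here - (D[i - 1, j - 1] + (a[i - 1] != b[j - 1]) + col_eps)) < eps:
            out_a.append(a[i - 1])
            out_b.append(b[j - 1])
            i -= 1
            j -= 1
        elif i > 0 and abs(here - (D[i - 1, j] + gw)) < eps:
            out_a.append(a[i - 1])
            out_b.append("-")
            i -= 1
        else:
            out_a.append("-")
            out_b.append(b[j - 1])
            j -= 1
    aligned_a = "".join(reversed(out_a))
    aligned_b = "".join(reversed(out_b))
    cols = len(aligned_a)
    matches = sum(1 for x, y in zip(aligned_a, aligned_b) if x == y and x != "-")
    gaps = sum(1 for x, y in zip(aligned_a, aligned_b) if x == "-" or y == "-")
    mism = cols - matches - gaps
    return PairwiseAlignment(aligned_a, aligned_b, matches / cols,
                             (mism + w * gaps) / cols, w)


def _parse_cigar(cigar: str) -> list[tuple[int, str]]:
    return [(int(n), op) for n, op in re.findall(r"(\d+)([=XIDM])", cigar)]


def nw_identity(a: str, b: str) -> float:
    """Global-alignment identity = matches / aligned columns, via edlib."""
    if not a or not b:
        return 0.0
    res = edlib.align(a.upper(), b.upper(), mode="NW", task="path")
    ops = _parse_cigar(res["cigar"])
    cols = sum(n for n, _ in ops)
    dist = res["editDistance"]
    if cols == 0:
        return 0.0
    return (cols - dist) / cols


def vm_distance_w1(a: str, b: str) -> float:
    """Fast w = 1 variable-metric distance: (mismatches + gaps) / columns."""
    res = edlib.align(a.upper(), b.upper(), mode="NW", task="path")
    cols = sum(n for n, _ in _parse_cigar(res["cigar"]))
    return res["editDistance"] / cols if cols else 0.0


# ---------------------------------------------------------------------------
# Consensus and multiple alignment
# ---------------------------------------------------------------------------


def build_consensus(aligned_copies: Sequence[str], record_id: str = "consensus") -> SequenceRecord:
    """Per-column majority-rule consensus, keeping the longest elements.

    Ties between a base and '-' resolve toward the base (so the consensus
    keeps the longest version of the element); ties among bases resolve by
    alphabet order A < C < G < T.  All-majority-gap columns are dropped.
    """
    if len(aligned_copies) < 2:
        raise ValueError("need at least 2 aligned copies")
    length = len(aligned_copies[0])
    if any(len(s) != length for s in aligned_copies):
        raise ValueError("aligned copies must have equal length")
    out = []
    order = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4, "-": 5}
    for col in range(length):
        counts: dict[str, int] = {}
        for s in aligned_copies:
            c = s[col].upper()
            counts[c] = counts.get(c, 0) + 1
        # pick max count; '-' loses all ties, bases tie-break alphabetically
        best = max(counts.items(), key=lambda kv: (kv[1], kv[0] != "-", -order.get(kv[0], 9)))
        if best[0] != "-":
            out.append(best[0])
    if not out:
        raise ValueError("consensus is empty (all columns gap-majority)")
    return SequenceRecord(record_id, "".join(out))


def star_align(seqs: Sequence[str], center_index: int | None = None) -> list[str]:
    """Center-star multiple alignment in the coordinates of the longest
    sequence.  Each sequence is globally aligned to the center with edlib and
    projected onto the center's columns (insertions relative to the center
    are dropped).  Adequate for clusters whose members differ by
    substitutions and deletions, which is the regime of this pipeline."""
    if not seqs:
        return []
    if center_index is None:
        center_index = max(range(len(seqs)), key=lambda i: (len(seqs[i]), -i))
    center = seqs[center_index].upper()
    rows = []
    for idx, s in enumerate(seqs):
        if idx == center_index:
            rows.append(center)
            continue
        s = s.upper()
        res = edlib.align(s, center, mode="NW", task="path")
        row = []
        qi = ti = 0
        for n, op in _parse_cigar(res["cigar"]):
            if op in ("=", "X", "M"):
                row.append(s[qi : qi + n])
                qi += n
                ti += n
            elif op == "D":  # gap in query relative to center: center consumes
                row.append("-" * n)
                ti += n
            else:  # 'I': insertion relative to center -> dropped
                qi += n
        rows.append("".join(row))
    return rows


# ---------------------------------------------------------------------------
# ORF scanning and TIR detection
# ---------------------------------------------------------------------------


def longest_orf(nt: str) -> tuple[int, str]:
    """Longest ATG-initiated open reading frame over all six frames.

    Returns ``(orf_length_nt, protein)``; the length counts nucleotides from
    ATG up to (not including) the stop codon, or to the frame end when no
    stop follows.  Returns ``(0, "")`` when no ATG exists.
    """
    best_len, best_prot = 0, ""
    for strand_seq in (nt.upper(), revcomp(nt.upper())):
        for off in range(3):
            prot = translate_frame(strand_seq, off)
            start = None
            for i, aa in enumerate(prot + "*"):
                if aa == "M" and start is None:
                    start = i
                elif aa == "*" and start is not None:
                    span = (i - start) * 3
                    if span > best_len:
                        best_len, best_prot = span, prot[start:i]
                    start = None
    return best_len, best_prot


def find_tir(seq: str, min_len: int = 10, max_mismatch_frac: float = 0.2,
             max_len: int | None = None) -> str:
    """Longest terminal inverted repeat of ``seq``.

    Compares the prefix against the reverse complement of the suffix and
    returns the longest prefix whose mismatch fraction stays within
    ``max_mismatch_frac``.  Empty string when nothing >= ``min_len`` exists.
    """
    seq = seq.upper()
    half = len(seq) // 2
    cap = min(half, max_len) if max_len else half
    prefix = seq[:cap]
    suffix_rc = revcomp(seq[-cap:])
    best, best_score = 0, 0.0
    mism = 0
    score = 0.0
    for i in range(cap):
        if prefix[i] != suffix_rc[i] or prefix[i] == "N":
            mism += 1
            score -= 2.0
        else:
            score += 1.0
        length = i + 1
        # candidate ends must land on a match and stay within the tolerance;
        # among candidates the score (match - 2*mismatch) picks the end,
        # which keeps random sequence beyond the true TIR from stretching it
        if (length >= min_len and mism <= max_mismatch_frac * length
                and prefix[i] == suffix_rc[i] and score >= best_score):
            best, best_score = length, score
    return prefix[:best]
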