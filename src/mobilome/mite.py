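"""De novo MITE discovery from terminal inverted repeats.

Miniature inverted-repeat transposable elements carry no coding sequence, so
homology mining misses them.  This module finds them structurally: the
genome is compared against itself for short inverted matches (>= 11 bp) at
most 750 bp apart; each such TIR pair plus the intervening sequence and
60 bp flanks becomes a candidate; candidates are clustered, copies with
similar flanking sequences removed (same locus / segmental duplications, not
transposition), and only clusters with at least ten independent copies, a
minimum internal homogeneity and bona fide terminal inverted repeats are
kept.  For each surviving cluster the target-site duplication is inferred
from the flanks, a putative autonomous partner (> 1 kb element sharing the
same TIRs) is searched in the genome, and the superfamily is assigned by
translated homology of the partner and consensus against a protein library
with a guard against nested insertions.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field

import numpy as np

from .mine import TECopy, _trim_flank_at_n, clean_cluster, cluster_copies
from .seqcore import (
    PipelineConfig,
    SequenceRecord,
    _kmer_hashes,
    _NT_CODE,
    _encode,
    build_consensus,
    nw_identity,
    revcomp,
    search_translated_many,
    star_align,
)

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}

# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass
class TIRSeedPair:
    contig: str
    left_interval: tuple[int, int]
    right_interval: tuple[int, int]
    seed_len: int
    internal_span: int

    def __post_init__(self) -> None:
        if self.right_interval[0] < self.left_interval[1]:
            raise ValueError("TIR blocks must not overlap")


@dataclass
class MITECluster:
    name: str
    members: list[TECopy]
    sublineages: list[list[str]]
    consensus: SequenceRecord
    tsd: str
    tir: str
    partner: tuple[str, int, int, str] | None   # (contig, start, end, sequence)
    superfamily: str
    bona_fide: bool
    independent_count: int = 0
    member_coverage: list[float] = field(default_factory=list)
    all_member_intervals: list[tuple[str, tuple[int, int]]] = field(default_factory=list)
    notes: str = ""


# ---------------------------------------------------------------------------
# Inverted-repeat seeding
# ---------------------------------------------------------------------------


def find_inverted_repeats(genome: SequenceRecord, min_word: int = 11,
                          max_span: int = 750, extend: bool = True) -> list[TIRSeedPair]:
    """All pairs of exact inverted matches >= ``min_word`` whose intervening
    span is at most ``max_span``, with non-overlapping blocks.

    With ``extend`` (default) seed matches are grown to maximal inverted
    matches and deduplicated; with ``extend=False`` the raw seed pairs are
    returned (one per window pair), which is the form compared against the
    exhaustive oracle in tests.
    """
    seq = genome.residues.upper()
    L = len(seq)
    k = min_word
    if L < 2 * k:
        return []
    codes = _encode(seq, _NT_CODE)
    h, valid = _kmer_hashes(codes, k, 4)
    rc_codes = _encode(revcomp(seq), _NT_CODE)
    h_rc, valid_rc = _kmer_hashes(rc_codes, k, 4)
    # hash of revcomp(window starting at i) = h_rc[L - k - i]
    rh = h_rc[::-1]
    rv = valid_rc[::-1]
    pairs: list[tuple[int, int]] = []
    n = len(h)
    for d in range(k, k + max_span + 1):
        if d >= n:
            break
        m = (h[d:] == rh[: n - d]) & valid[d:] & rv[: n - d]
        for i in np.nonzero(m)[0]:
            pairs.append((int(i), int(i) + d))
    if not extend:
        return [TIRSeedPair(genome.id, (i, i + k), (j, j + k), k, j - (i + k))
                for i, j in sorted(pairs)]
    seen: set[tuple[int, int, int]] = set()
    out: list[TIRSeedPair] = []
    for i, j in sorted(pairs):
        length = k
        # outer growth: left of block A pairs with right of block B
        while i > 0 and j + length < L and seq[i - 1] == _COMP.get(seq[j + length], "?"):
            i -= 1
            length += 1
        # inner growth: right of A pairs with left of B
        while j - 1 >= i + length and seq[i + length] == _COMP.get(seq[j - 1], "?"):
            j -= 1
            length += 1
        if j < i + length:
            continue
        key = (i, j, length)
        if key in seen:
            continue
        seen.add(key)
        out.append(TIRSeedPair(genome.id, (i, i + length), (j, j + length),
                               length, j - (i + length)))
    out.sort(key=lambda p: (p.left_interval, p.right_interval))
    return out


def _tsd_trim(seq: str, start: int, end: int, max_trim: int = 8) -> tuple[int, int]:
    """Shrink a maximal inverted-match candidate back to the element.

    The target-site duplication flanking a real element is itself an
    inverted-match continuation (TA against TA), so maximal extension
    systematically overshoots the boundary.  The smallest symmetric trim that
    exposes a duplicated flanking k-mer (k = 8 down to 2, preferring longer
    duplications) is taken as the boundary; no trim when nothing is exposed.
    """
    for t in range(0, max_trim + 1):
        s, e = start + t, end - t
        if e - s < 50:
            break
        for k in range(8, 1, -1):
            if s - k < 0 or e + k > len(seq):
                continue
            left, right = seq[s - k : s], seq[e : e + k]
            if left == right and "N" not in left:
                return s, e
    return start, end


def extract_candidates(pairs: list[TIRSeedPair], genome: SequenceRecord,
                       flank: int = 60) -> list[TECopy]:
    """Candidate = left TIR + intervening sequence + right TIR, with
    ``flank`` bp stored on each side (trimmed at contig edges / N-runs).
    Candidate boundaries are pulled back to the position exposing the
    target-site duplication when the inverted match overshot into it."""
    seq = genome.residues.upper()
    out: list[TECopy] = []
    seen: set[tuple[int, int]] = set()
    for p in pairs:
        start, end = _tsd_trim(seq, p.left_interval[0], p.right_interval[1])
        if (start, end) in seen:
            continue
        seen.add((start, end))
        left = _trim_flank_at_n(seq[max(0, start - flank):start], "left")
        right = _trim_flank_at_n(seq[end:end + flank], "right")
        out.append(TECopy(
            copy_id=f"{genome.id}:{start}-{end}", contig=genome.id,
            interval=(start, end), strand="+", core_seq=seq[start:end],
            left_flank=left, right_flank=right, has_n="N" in seq[start:end],
            assembly_truncated=len(left) < flank or len(right) < flank))
    out.sort(key=lambda c: c.interval)
    return out


# ---------------------------------------------------------------------------
# Clustering and filtering
# ---------------------------------------------------------------------------


def _terminal_tir(seq: str, min_len: int = 11, max_mismatch: int = 2) -> str:
    """Bona fide TIR test: longest terminal inverted match with at most
    ``max_mismatch`` mismatches, empty when shorter than ``min_len``."""
    cap = len(seq) // 2
    best = 0
    mism = 0
    for i in range(cap):
        if seq[i] != _COMP.get(seq[-(i + 1)], "?"):
            mism += 1
            if mism > max_mismatch:
                break
        else:
            if i + 1 >= min_len:
                best = i + 1
    return seq[:best]


def _mean_pairwise_identity(seqs: list[str], rng_cap: int = 15) -> float:
    sub = seqs[:rng_cap]
    if len(sub) < 2:
        return 1.0
    idents = [nw_identity(sub[i], sub[j])
              for i in range(len(sub)) for j in range(i + 1, len(sub))]
    return float(np.mean(idents))


def infer_cluster_tsd(members: list[TECopy], k_max: int = 8) -> str:
    """Target-site duplication of a cluster.

    For each member and k = 2..8, a k-mer duplicated immediately on both
    sides of the copy is TSD evidence.  If one literal k-mer is duplicated in
    a majority of members it is returned (e.g. "TA" for Tc1-mariner);
    otherwise, if one *length* k dominates (hAT-style TSDs duplicate random
    host sequence), a TSD of unknown bases ("N" * k) is reported; otherwise
    "unclear".
    """
    intact = [m for m in members if len(m.left_flank) >= k_max and len(m.right_flank) >= k_max]
    if len(intact) < 3:
        return "unclear"
    literal: Counter = Counter()
    lengths: Counter = Counter()
    for m in intact:
        for k in range(k_max, 1, -1):
            l, r = m.left_flank[-k:], m.right_flank[:k]
            if l == r and "N" not in l:
                literal[l] += 1
                lengths[k] += 1
                break  # longest duplication per member
    half = len(intact) / 2.0
    if literal:
        tsd, votes = literal.most_common(1)[0]
        if votes >= half:
            return tsd
    if lengths:
        k, votes = lengths.most_common(1)[0]
        if votes >= half:
            return "N" * k
    return "unclear"


def _sublineages(members: list[TECopy], identity: float = 0.95,
                 len_spread: float = 0.05) -> list[list[str]]:
    """Connected components of near-identical, near-equal-length members."""
    n = len(members)
    parent = list(range(n))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i in range(n):
        for j in range(i + 1, n):
            a, b = members[i], members[j]
            la, lb = len(a.core_seq), len(b.core_seq)
            if abs(la - lb) > len_spread * max(la, lb):
                continue
            if nw_identity(a.core_seq, b.core_seq) >= identity:
                parent[find(i)] = find(j)
    comps: dict[int, list[str]] = defaultdict(list)
    for i, m in enumerate(members):
        comps[find(i)].append(m.copy_id)
    groups = [sorted(v) for v in comps.values() if len(v) >= 2]
    groups.sort(key=lambda g: (-len(g), g[0]))
    return groups


def cluster_filter_mites(candidates: list[TECopy], config: PipelineConfig | None = None
                         ) -> tuple[list[MITECluster], list[tuple[str, str]]]:
    """Cluster candidates and apply the MITE filters; returns the surviving
    clusters and a discard log of (cluster id, reason)."""
    config = config or PipelineConfig()
    discards: list[tuple[str, str]] = []
    clusters: list[MITECluster] = []
    if not candidates:
        return clusters, discards
    raw = cluster_copies(candidates, config.cluster_identity, config.cluster_rev)
    idx = 0
    for cl in raw:
        cid = cl.centroid.copy_id
        clean_cluster(cl, config.flank_dup_identity)
        members = cl.clean_members
        if cl.clean_independent_count < config.mite_min_copies:
            discards.append((cid, f"copy number ({cl.clean_independent_count} "
                                  f"< {config.mite_min_copies} independent)"))
            continue
        homog = _mean_pairwise_identity([m.core_seq for m in members])
        if homog < config.mite_homogeneity_min:
            discards.append((cid, f"homogeneity {homog:.2f} < {config.mite_homogeneity_min}"))
            continue
        aligned = star_align([m.core_seq for m in members])
        consensus = build_consensus(aligned, record_id=f"MITE_{idx}")
        coverage = [sum(1 for r in aligned if r[c] != "-") / len(aligned)
                    for c in range(len(aligned[0]))]
        tir = _terminal_tir(consensus.residues, min_len=config.tir_seed_min_bp)
        if not tir:
            discards.append((cid, "no bona fide terminal inverted repeat"))
            continue
        tsd = infer_cluster_tsd(members)
        clusters.append(MITECluster(
            name=f"MITE_{idx}", members=members,
            sublineages=_sublineages(members), consensus=consensus, tsd=tsd,
            tir=tir, partner=None, superfamily="unknown",
            bona_fide=tsd != "unclear",
            independent_count=cl.clean_independent_count,
            member_coverage=coverage,
            all_member_intervals=[(m.contig, m.interval) for m in cl.members]))
        idx += 1
    return clusters, discards


# ---------------------------------------------------------------------------
# Autonomous partner search and superfamily assignment
# ---------------------------------------------------------------------------


def _tir_occurrences(tir: str, seq: str, max_mismatch: int = 2) -> list[int]:
    """Positions where ``tir`` occurs with at most ``max_mismatch``
    mismatches (seeded on its first 8 exact bases for speed)."""
    out = []
    seed = tir[:8]
    start = 0
    while True:
        i = seq.find(seed, start)
        if i < 0:
            break
        window = seq[i : i + len(tir)]
        if len(window) == len(tir) and sum(a != b for a, b in zip(window, tir)) <= max_mismatch:
            out.append(i)
        start = i + 1
    return out


def find_partner(cluster: MITECluster, contigs: list[SequenceRecord],
                 min_len: int = 1000, max_len: int = 8000
                 ) -> tuple[str, int, int, str] | None:
    """Search for a putative autonomous partner: a locus > ``min_len`` where
    the cluster's TIRs occur in inverted orientation and that does not
    overlap any cluster candidate.  Among qualifying loci the shortest span
    is returned (an autonomous element, not a chance pairing of distant TIR
    occurrences).  Returns (contig, start, end, sequence) or None."""
    tir = cluster.tir
    if not tir:
        return None
    member_loci = cluster.all_member_intervals or [
        (m.contig, m.interval) for m in cluster.members]
    best: tuple[str, int, int, str] | None = None
    for rec in contigs:
        seq = rec.residues.upper()
        starts = _tir_occurrences(tir, seq)
        rc = revcomp(tir)
        ends = _tir_occurrences(rc, seq)
        for i in starts:
            for j in ends:
                end = j + len(rc)
                span = end - i
                if span <= min_len or span > max_len:
                    continue
                overlaps_member = any(
                    rec.id == mc and not (end <= ms or i >= me)
                    for mc, (ms, me) in member_loci)
                if overlaps_member:
                    continue
                if best is None or span < best[2] - best[1]:
                    best = (rec.id, i, end, seq[i:end])
    return best


def classify_cluster(cluster: MITECluster, protein_db: list[SequenceRecord],
                     min_score: float = 100.0) -> str:
    """Superfamily of the best translated hit of the partner (if any) and the
    consensus against the protein library.

    Hits confined to consensus regions present in fewer than half of the
    members are ignored: such homology comes from a nested insertion in one
    copy, not from the MITE itself.  Protein records may carry their
    superfamily as ``superfamily=<name>`` in the description.
    """
    if not protein_db:
        raise ValueError("protein_db must not be empty")

    def label_of(rec_id: str) -> str:
        for p in protein_db:
            if p.id == rec_id:
                for tok in p.description.split():
                    if tok.startswith("superfamily="):
                        return tok.split("=", 1)[1]
                return p.id
        return rec_id

    best_label, best_score = "unknown", min_score
    targets = [("consensus", cluster.consensus)]
    if cluster.partner is not None:
        targets.append(("partner", SequenceRecord("partner", cluster.partner[3])))
    for kind, target in targets:
        hits = search_translated_many(protein_db, target, min_score=min_score)
        for h in hits:
            if kind == "consensus" and cluster.member_coverage:
                s, e = h.s_interval
                cov = cluster.member_coverage[s:e]
                if cov and float(np.mean(cov)) < 0.5:
                    continue  # nested-insertion guard
            if h.score > best_score or (h.score == best_score and best_label == "unknown"):
                best_label, best_score = label_of(h.query_id), h.score
    cluster.superfamily = best_label
    return best_label


# ---------------------------------------------------------------------------
# Driver and reporting
# ---------------------------------------------------------------------------


def discover_mites(contigs: list[SequenceRecord], protein_db: list[SequenceRecord] | None = None,
                   config: PipelineConfig | None = None
                   ) -> tuple[list[MITECluster], list[tuple[str, str]]]:
    """Full de novo MITE pipeline over an assembly."""
    config = config or PipelineConfig()
    candidates: list[TECopy] = []
    for rec in contigs:
        pairs = find_inverted_repeats(rec, config.tir_seed_min_bp, config.mite_max_span_bp)
        candidates.extend(extract_candidates(pairs, rec, config.mite_flank_bp))
    clusters, discards = cluster_filter_mites(candidates, config)
    for cl in clusters:
        cl.partner = find_partner(cl, contigs, config.partner_min_len_bp)
        if protein_db:
            classify_cluster(cl, protein_db)
        if cl.superfamily == "unknown" and cl.tsd == "TA":
            cl.notes = "TSD compatible with Tc1-mariner"
    return clusters, discards


def mite_table(clusters: list[MITECluster]):
    """Summary table mirroring the classic MITE characterisation columns."""
    import pandas as pd

    rows = []
    for cl in clusters:
        sizes = [len(m.core_seq) for m in cl.members]
        rows.append({
            "Clusters": cl.name,
            "Copy number": cl.independent_count,
            "Sublineages": len(cl.sublineages),
            "Confirmed family": cl.superfamily,
            "Partner": f"{cl.partner[0]}:{cl.partner[1]}-{cl.partner[2]}" if cl.partner else "No",
            "Size": f"{min(sizes)}-{max(sizes)}",
            "TSD and TIRs": f"{cl.tsd} {cl.tir}",
            "Remarks": cl.notes,
        })
    return pd.DataFrame(rows)
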