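"""Library-based Tc1-mariner mining: from transposase protein queries and a
genome assembly to characterised element lineages.

The pipeline mirrors the classic homology-based protocol:

i.   translated search of each transposase query against the genome;
ii.  chaining of co-linear hits closer than 1 kb into copy candidates;
iii. discarding candidates shorter than 400 bp and extracting each copy with
     up to 500 bp of flanking sequence on each side (minus-strand copies are
     reverse-complement-normalised to element orientation);
iv.  greedy centroid clustering of the copies at 80% identity, testing both
     orientations;
v.   per-cluster alignment (center-star) of the members;
vi.  cleaning: copies containing N, assembly-truncated copies, and
     segmental-duplication twins (both flanks >= 90% identical to another
     member's) are excluded from the clean independent set;
vii. consensus building (majority rule keeping the longest elements), TIR
     and TSD inference, and activity assessment (an uninterrupted ORF longer
     than 1 kb in at least one member).
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field

import networkx as nx

from .seqcore import (
    LocalHit,
    PipelineConfig,
    SequenceRecord,
    build_consensus,
    find_tir,
    longest_orf,
    nw_identity,
    revcomp,
    search_translated_many,
    star_align,
)

# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass
class CopyCandidate:
    contig: str
    interval: tuple[int, int]
    strand: str
    supporting_hits: list[LocalHit]
    best_query: str

    @property
    def score(self) -> float:
        return sum(h.score for h in self.supporting_hits)


@dataclass
class TECopy:
    copy_id: str
    contig: str
    interval: tuple[int, int]
    strand: str
    core_seq: str
    left_flank: str
    right_flank: str
    has_n: bool
    assembly_truncated: bool
    tsd: str | None = None


@dataclass
class Lineage:
    name: str
    members: list[TECopy]
    total_copy_number: int
    clean_independent_count: int
    clean_members: list[TECopy]
    consensus_nt: SequenceRecord
    consensus_aa: str
    tir: str
    tsd: str
    potentially_active: bool
    status: set[str] = field(default_factory=set)
    subfamily: str = "unassigned"


@dataclass
class MiningResult:
    lineages: list[Lineage]
    copies: list[TECopy]
    candidates: list[CopyCandidate]
    discards: list[tuple[str, str]]   # (cluster description, reason)


# ---------------------------------------------------------------------------
# Step i-ii: hit chaining
# ---------------------------------------------------------------------------


def _compatible(h1: LocalHit, h2: LocalHit, max_gap: int) -> bool:
    """Can h2 follow h1 in one copy?  Requires subject order, subject gap
    below the threshold, and query offsets co-linear with the strand."""
    if h2.s_interval[0] < h1.s_interval[0]:
        return False
    if h2.s_interval[0] - h1.s_interval[1] >= max_gap:
        return False
    if h1.strand == "+":
        return h2.q_interval[0] >= h1.q_interval[0] and h2.q_interval[1] >= h1.q_interval[1]
    return h2.q_interval[0] <= h1.q_interval[0] and h2.q_interval[1] <= h1.q_interval[1]


def chain_hits(hits: list[LocalHit], max_gap: int = 1000) -> list[CopyCandidate]:
    """Merge co-linear hits of one query closer than ``max_gap`` into copy
    candidates (minimum chain partition of the compatibility DAG, so each
    hit lands in exactly one candidate and the number of candidates is
    minimal)."""
    if max_gap <= 0:
        raise ValueError("max_gap must be positive")
    groups: dict[tuple[str, str, str], list[LocalHit]] = defaultdict(list)
    for h in hits:
        groups[(h.subject_id, h.query_id, h.strand)].append(h)
    candidates: list[CopyCandidate] = []
    for (contig, query, strand), ghits in sorted(groups.items()):
        ghits.sort(key=lambda h: (h.s_interval, h.q_interval))
        n = len(ghits)
        graph = nx.Graph()
        left = [("L", i) for i in range(n)]
        graph.add_nodes_from(left, bipartite=0)
        graph.add_nodes_from((("R", j) for j in range(n)), bipartite=1)
        for i in range(n):
            for j in range(i + 1, n):
                if _compatible(ghits[i], ghits[j], max_gap):
                    graph.add_edge(("L", i), ("R", j))
        matching = nx.bipartite.hopcroft_karp_matching(graph, top_nodes=left)
        succ = {i: j for (side, i), (_, j) in matching.items() if side == "L"}
        has_pred = set(succ.values())
        for i in range(n):
            if i in has_pred:
                continue
            chain = [ghits[i]]
            k = i
            while k in succ:
                k = succ[k]
                chain.append(ghits[k])
            start = min(h.s_interval[0] for h in chain)
            end = max(h.s_interval[1] for h in chain)
            candidates.append(CopyCandidate(contig, (start, end), strand, chain, query))
    candidates.sort(key=lambda c: (c.contig, c.interval, c.strand))
    return candidates


def merge_candidates(candidates: list[CopyCandidate], min_overlap: float = 0.5) -> list[CopyCandidate]:
    """Collapse candidates found by different queries at the same locus,
    keeping the best-scoring one per locus."""
    out: list[CopyCandidate] = []
    by_contig: dict[str, list[CopyCandidate]] = defaultdict(list)
    for c in candidates:
        by_contig[c.contig].append(c)
    for contig in sorted(by_contig):
        cands = sorted(by_contig[contig], key=lambda c: c.interval)
        current: list[CopyCandidate] = []
        for c in cands:
            if current:
                last = max(x.interval[1] for x in current)
                ov = last - c.interval[0]
                shorter = min(c.interval[1] - c.interval[0],
                              min(x.interval[1] - x.interval[0] for x in current))
                if ov < min_overlap * shorter:
                    out.append(max(current, key=lambda x: x.score))
                    current = []
            current.append(c)
        if current:
            out.append(max(current, key=lambda x: x.score))
    out.sort(key=lambda c: (c.contig, c.interval, c.strand))
    return out


# ---------------------------------------------------------------------------
# Step iii: filtering and extraction
# ---------------------------------------------------------------------------


def _trim_flank_at_n(flank: str, side: str, min_run: int = 5) -> str:
    """Cut a flank at the N-run nearest the copy (assembly gap)."""
    run = "N" * min_run
    if side == "left":
        idx = flank.rfind(run)
        return flank[idx + min_run:].lstrip("N") if idx >= 0 else flank
    idx = flank.find(run)
    return flank[:idx].rstrip("N") if idx >= 0 else flank


def filter_and_extract(candidates: list[CopyCandidate], contigs: dict[str, SequenceRecord],
                       min_len: int = 400, flank: int = 500) -> list[TECopy]:
    """Drop candidates below ``min_len`` and extract copies with flanks.

    Minus-strand copies are reverse-complement-normalised: the core is
    flipped to element orientation and the flanks swap sides (each reverse
    complemented).  Flanks shortened by a contig edge or an N-run mark the
    copy as assembly-truncated.
    """
    copies: list[TECopy] = []
    for c in candidates:
        start, end = c.interval
        if end - start < min_len:
            continue
        seq = contigs[c.contig].residues
        core = seq[start:end]
        left = _trim_flank_at_n(seq[max(0, start - flank):start], "left")
        right = _trim_flank_at_n(seq[end:end + flank], "right")
        truncated = len(left) < flank or len(right) < flank
        if c.strand == "-":
            core = revcomp(core)
            left, right = revcomp(right), revcomp(left)
        copies.append(TECopy(
            copy_id=f"{c.contig}:{start}-{end}({c.strand})",
            contig=c.contig, interval=(start, end), strand=c.strand,
            core_seq=core, left_flank=left, right_flank=right,
            has_n="N" in core, assembly_truncated=truncated))
    copies.sort(key=lambda cp: (cp.contig, cp.interval))
    return copies


# ---------------------------------------------------------------------------
# Step iv: clustering
# ---------------------------------------------------------------------------


@dataclass
class CopyCluster:
    centroid: TECopy
    members: list[TECopy]                 # co-oriented with the centroid
    clean_members: list[TECopy] = field(default_factory=list)
    clean_independent_count: int = 0


def _flip(copy: TECopy) -> TECopy:
    return TECopy(copy.copy_id, copy.contig, copy.interval,
                  "-" if copy.strand == "+" else "+",
                  revcomp(copy.core_seq), revcomp(copy.right_flank),
                  revcomp(copy.left_flank), copy.has_n, copy.assembly_truncated,
                  copy.tsd)


def cluster_copies(copies: list[TECopy], identity: float = 0.80,
                   rev: bool = True) -> list[CopyCluster]:
    """Greedy centroid clustering: copies sorted by decreasing length; each
    copy joins the first centroid it matches at >= ``identity`` (testing the
    reverse complement too when ``rev``), else founds a new centroid."""
    if not copies:
        raise ValueError("no copies to cluster")
    clusters: list[CopyCluster] = []
    ordered = sorted(copies, key=lambda c: (-len(c.core_seq), c.copy_id))
    for cp in ordered:
        placed = False
        for cl in clusters:
            ident = nw_identity(cp.core_seq, cl.centroid.core_seq)
            if ident >= identity:
                cl.members.append(cp)
                placed = True
                break
            if rev:
                ident_rc = nw_identity(revcomp(cp.core_seq), cl.centroid.core_seq)
                if ident_rc >= identity:
                    cl.members.append(_flip(cp))
                    placed = True
                    break
        if not placed:
            clusters.append(CopyCluster(cp, [cp]))
    clusters.sort(key=lambda cl: (-len(cl.members), cl.centroid.copy_id))
    return clusters


# ---------------------------------------------------------------------------
# Step v: boundary refinement on the cluster alignment
# ---------------------------------------------------------------------------


def _position_map(member: str, center: str) -> list[int]:
    """For every position in ``center`` (0..len inclusive), the corresponding
    position in ``member`` under the optimal global alignment."""
    import edlib

    res = edlib.align(member, center, mode="NW", task="path")
    import re as _re

    out = [0] * (len(center) + 1)
    qi = ti = 0
    for n, op in _re.findall(r"(\d+)([=XIDM])", res["cigar"]):
        n = int(n)
        if op in ("=", "X", "M"):
            for _ in range(n):
                out[ti] = qi
                qi += 1
                ti += 1
        elif op == "I":  # extra member sequence
            qi += n
        else:            # gap in member
            for _ in range(n):
                out[ti] = qi
                ti += 1
    out[len(center)] = len(member)
    return out


def refine_cluster_boundaries(cluster: CopyCluster, tsd_len: int = 2,
                              max_members: int = 40,
                              contigs: dict[str, SequenceRecord] | None = None,
                              flank: int = 500) -> CopyCluster:
    """Extend homology-region copies to full element boundaries.

    Translated hits only cover the transposase region; the element proper
    (TIRs and UTRs) continues into the extracted flanks.  Aligning members
    with their flanks, element columns stay conserved across copies while
    true flank columns are unrelated background.  The approximate boundary
    from that conservation profile is then refined to the base by maximising
    the target-site-duplication vote (identical ``tsd_len``-mers immediately
    outside both boundaries) plus a terminal-inverted-repeat bonus.
    Members' core sequences, intervals and flanks are updated in place.
    """
    members = cluster.members
    ext = [m.left_flank + m.core_seq + m.right_flank for m in members]
    lefts = [len(m.left_flank) for m in members]
    sample = list(range(len(members)))
    if len(sample) > max_members:
        sample = sample[:: len(sample) // max_members + 1]
    center = max(sample, key=lambda i: (len(members[i].core_seq), -i))
    rows = star_align([ext[i] for i in sample],
                      center_index=sample.index(center))
    ncols = len(rows[0])
    agree = [0.0] * ncols
    for col in range(ncols):
        counts: dict[str, int] = {}
        for r in rows:
            counts[r[col]] = counts.get(r[col], 0) + 1
        best = max(counts.values())
        agree[col] = best / len(rows)
    # smoothed conservation profile; block = contiguous conserved run
    # containing the centre's homology region
    win = 15
    import numpy as _np

    # random flanks still project at ~0.6 agreement (gap-rich edit paths);
    # element columns sit at >= ~0.85 even for 10%-diverged families
    sm = _np.convolve(_np.array(agree), _np.ones(win) / win, mode="same")
    conserved = sm >= 0.75
    c_lo, c_hi = lefts[center], lefts[center] + len(members[center].core_seq)
    bs = c_lo
    while bs > 0 and conserved[bs - 1]:
        bs -= 1
    be = c_hi
    while be < ncols and conserved[be]:
        be += 1

    # exact per-member coordinate maps (cigar walk; star rows only provided
    # the conservation profile, their projection loses member insertions)
    pos_maps = {mi: _position_map(ext[mi], ext[center]) for mi in sample}

    def outside_conserved(s: int, e: int) -> bool:
        # just beyond the implied TSD of a true boundary members are
        # unrelated background (low column agreement); beyond the "TSD" of a
        # spurious inner boundary they still share element sequence (the
        # real TSD and TIR head), which stays conserved
        win = 5
        left = agree[max(0, s - tsd_len - win) : max(0, s - tsd_len)]
        right = agree[min(ncols, e + tsd_len) : min(ncols, e + tsd_len + win)]
        window = list(left) + list(right)
        return bool(window) and sum(window) / len(window) > 0.75

    def boundary_score(ds: int, de: int) -> tuple[int, int]:
        s, e = bs + ds, be + de
        if s < tsd_len or e > ncols - tsd_len or e - s < 100:
            return (-1, 0)
        if outside_conserved(s, e):
            return (-1, 0)
        votes = 0
        for mi in sample:
            ps, pe = pos_maps[mi][s], pos_maps[mi][e]
            seq = ext[mi]
            if ps < tsd_len or pe + tsd_len > len(seq):
                continue
            l2, r2 = seq[ps - tsd_len : ps], seq[pe : pe + tsd_len]
            if l2 == r2 and "N" not in l2:
                votes += 1
        tir_bonus = 0
        cseq = ext[center][s:e]
        if len(cseq) >= 24:
            head, tail = cseq[:12], revcomp(cseq[-12:])
            if sum(a != b for a, b in zip(head, tail)) <= 2:
                tir_bonus = 2
        return (votes + tir_bonus, votes)

    # near-ties broken toward the longest element: a symmetric inset landing
    # on a complementary dinucleotide inside the TIR votes as well as the
    # true boundary (give or take boundary-mapping noise), and "keeping the
    # longest elements" resolves it
    scored: list[tuple[int, int, int, int]] = []
    for ds in range(-30, 31):
        for de in range(-30, 31):
            sc, _v = boundary_score(ds, de)
            if sc >= 0:
                scored.append((sc, (be + de) - (bs + ds), ds, de))
    if scored:
        max_score = max(sc for sc, _l, _ds, _de in scored)
        tol = max(2, len(sample) // 10)
        near = [t for t in scored if t[0] >= max_score - tol]
        _sc, _length, best_ds, best_de = max(near, key=lambda t: (t[1], t[0], -abs(t[2]), -abs(t[3])))
    else:
        best_ds = best_de = 0
    s, e = bs + best_ds, be + best_de
    # project the refined boundary onto every member
    for idx, m in enumerate(members):
        pmap = pos_maps.get(idx) or _position_map(ext[idx], ext[center])
        ps, pe = pmap[s], pmap[e]
        ps = max(0, min(ps, len(ext[idx])))
        pe = max(ps + 1, min(pe, len(ext[idx])))
        l = lefts[idx]
        core_len = len(m.core_seq)
        if m.strand == "+":
            g_start = m.interval[0] - (l - ps)
            g_end = m.interval[1] + (pe - (l + core_len))
        else:
            g_end = m.interval[1] + (l - ps)
            g_start = m.interval[0] - (pe - (l + core_len))
        m.core_seq = ext[idx][ps:pe]
        m.interval = (g_start, g_end)
        if contigs is not None:
            # re-extract flanks relative to the refined element boundary so
            # truncation (contig edge / N-run within `flank` bp) is judged
            # against the element, not the homology region
            seq = contigs[m.contig].residues
            left = _trim_flank_at_n(seq[max(0, g_start - flank):g_start], "left")
            right = _trim_flank_at_n(seq[g_end:g_end + flank], "right")
            m.assembly_truncated = len(left) < flank or len(right) < flank
            if m.strand == "-":
                left, right = revcomp(right), revcomp(left)
            m.left_flank, m.right_flank = left, right
        else:
            m.left_flank = ext[idx][max(0, ps - flank):ps]
            m.right_flank = ext[idx][pe:pe + flank]
        m.tsd = (m.left_flank[-tsd_len:]
                 if len(m.left_flank) >= tsd_len
                 and m.left_flank[-tsd_len:] == m.right_flank[:tsd_len]
                 else None)
        m.has_n = "N" in m.core_seq
    return cluster


# ---------------------------------------------------------------------------
# Step vi: cleaning
# ---------------------------------------------------------------------------


def clean_cluster(cluster: CopyCluster, flank_dup_identity: float = 0.90) -> CopyCluster:
    """Flag the clean independent member set.

    Copies with N and assembly-truncated copies are excluded; members whose
    BOTH flanks match another member's flanks at >= ``flank_dup_identity``
    are segmental-duplication twins (not transposition) and count once.
    """
    clean = [m for m in cluster.members if not m.has_n and not m.assembly_truncated]
    clean.sort(key=lambda m: m.copy_id)
    parent = list(range(len(clean)))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i in range(len(clean)):
        for j in range(i + 1, len(clean)):
            a, b = clean[i], clean[j]
            if not a.left_flank or not b.left_flank or not a.right_flank or not b.right_flank:
                continue
            if (nw_identity(a.left_flank, b.left_flank) >= flank_dup_identity
                    and nw_identity(a.right_flank, b.right_flank) >= flank_dup_identity):
                parent[find(i)] = find(j)
    reps: dict[int, TECopy] = {}
    for i, m in enumerate(clean):
        reps.setdefault(find(i), m)
    cluster.clean_members = clean
    cluster.clean_independent_count = len(reps)
    return cluster


# ---------------------------------------------------------------------------
# Step vii: characterisation
# ---------------------------------------------------------------------------


def _infer_tsd(members: list[TECopy]) -> str:
    votes = Counter()
    for m in members:
        left2, right2 = m.left_flank[-2:], m.right_flank[:2]
        if len(left2) == 2 and left2 == right2 and "N" not in left2:
            votes[left2] += 1
    if not votes:
        return ""
    tsd, count = votes.most_common(1)[0]
    return tsd if count * 2 >= len(members) else ""


def characterize_lineage(cluster: CopyCluster, config: PipelineConfig,
                         name: str = "lineage") -> Lineage | None:
    """Build the lineage record (consensus, TIR, TSD, activity) for a cleaned
    cluster; returns None when the cluster has fewer than
    ``min_lineage_copies`` clean independent members."""
    if cluster.clean_independent_count < config.min_lineage_copies:
        return None
    cores = [m.core_seq for m in cluster.clean_members]
    aligned = star_align(cores)
    consensus = build_consensus(aligned, record_id=name)
    orf_len, orf_prot = longest_orf(consensus.residues)
    tir = find_tir(consensus.residues, min_len=config.tir_min_len,
                   max_mismatch_frac=config.tir_max_mismatch_frac)
    tsd = _infer_tsd(cluster.clean_members)
    active = any(longest_orf(m.core_seq)[0] > config.active_orf_min_bp
                 for m in cluster.clean_members)
    status: set[str] = set()
    if len(tir) >= 80:
        # long terminal inverted blocks are the signature of 5'->3' replacement
        status.add("rearranged")
    return Lineage(
        name=name, members=cluster.members, total_copy_number=len(cluster.members),
        clean_independent_count=cluster.clean_independent_count,
        clean_members=cluster.clean_members, consensus_nt=consensus,
        consensus_aa=orf_prot, tir=tir, tsd=tsd,
        potentially_active=active, status=status)


def finalize_statuses(lineages: list[Lineage], config: PipelineConfig) -> None:
    """Mark lineages 'deleted' when their consensus is shorter than 80% of
    the longest consensus among lineages of the same subfamily (falling back
    to sequence-similarity groups when no subfamily labels are set)."""
    groups: dict[str, list[Lineage]] = defaultdict(list)
    unassigned: list[Lineage] = []
    for lin in lineages:
        if lin.subfamily != "unassigned":
            groups[lin.subfamily].append(lin)
        else:
            unassigned.append(lin)
    # similarity groups for unlabeled lineages (>= 65% consensus identity)
    for lin in unassigned:
        placed = False
        for key, members in groups.items():
            if key.startswith("simgroup") and members:
                if nw_identity(lin.consensus_nt.residues,
                               members[0].consensus_nt.residues) >= 0.65:
                    members.append(lin)
                    placed = True
                    break
        if not placed:
            groups[f"simgroup{len(groups)}"].append(lin)
    for members in groups.values():
        longest = max(len(l.consensus_nt.residues) for l in members)
        for lin in members:
            if len(lin.consensus_nt.residues) < config.deleted_length_frac * longest:
                lin.status.add("deleted")


# ---------------------------------------------------------------------------
# End-to-end driver and reporting
# ---------------------------------------------------------------------------


def mine_genome(contigs: list[SequenceRecord], queries: list[SequenceRecord],
                config: PipelineConfig | None = None) -> MiningResult:
    """Run the full mining pipeline on an assembly."""
    config = config or PipelineConfig()
    contig_map = {c.id: c for c in contigs}
    hits: list[LocalHit] = []
    for contig in contigs:
        hits.extend(search_translated_many(queries, contig))
    candidates = merge_candidates(chain_hits(hits, config.chain_max_gap_bp))
    copies = filter_and_extract(candidates, contig_map,
                                config.min_copy_len_bp, config.flank_len_bp)
    discards: list[tuple[str, str]] = []
    lineages: list[Lineage] = []
    if copies:
        clusters = cluster_copies(copies, config.cluster_identity, config.cluster_rev)
        idx = 0
        for cl in clusters:
            if len(cl.members) >= 3:
                refine_cluster_boundaries(cl, tsd_len=len(config.mariner_tsd),
                                          contigs=contig_map, flank=config.flank_len_bp)
            clean_cluster(cl, config.flank_dup_identity)
            lin = characterize_lineage(cl, config, name=f"lineage{idx:03d}")
            if lin is None:
                discards.append((cl.centroid.copy_id,
                                 f"only {cl.clean_independent_count} clean independent copies "
                                 f"(minimum {config.min_lineage_copies})"))
                continue
            lineages.append(lin)
            idx += 1
    finalize_statuses(lineages, config)
    return MiningResult(lineages, copies, candidates, discards)


def lineage_table(lineages: list[Lineage]):
    """Per-lineage summary mirroring the classic characterisation table.
    Exported coordinates elsewhere are 0-based half-open; this table has no
    coordinates, only per-lineage descriptors."""
    import pandas as pd

    rows = []
    for lin in lineages:
        rows.append({
            "Cluster": lin.name,
            "Total Copy Number": lin.total_copy_number,
            "Clean Independent Copy Number": lin.clean_independent_count,
            "Subfamily": lin.subfamily,
            "Length": len(lin.consensus_nt.residues),
            "TIR length": len(lin.tir),
            "TIR sequence": lin.tir,
            "TSD": lin.tsd,
            "Potentially Active": "Yes" if lin.potentially_active else "No",
            "Remarks": "/".join(sorted(lin.status)) or "",
        })
    return pd.DataFrame(rows)
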