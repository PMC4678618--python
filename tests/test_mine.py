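"""Mining pipeline tests: hit chaining against an exhaustive oracle,
extraction edge cases, clustering semantics, cleaning, and end-to-end
recovery of planted families."""

from itertools import combinations

import numpy as np
import pytest

from mobilome import mine
from mobilome import simulate as sim
from mobilome.seqcore import LocalHit, PipelineConfig, SequenceRecord, nw_identity, revcomp


def H(q_s, q_e, s_s, s_e, strand="+", query="q", subject="c"):
    return LocalHit(query, subject, (q_s, q_e), (s_s, s_e), strand, 1, 100.0, 0.9)


# ---------------------------------------------------------------------------
# chaining
# ---------------------------------------------------------------------------


def min_chain_count_oracle(hits, max_gap):
    """Exhaustive minimum chain partition: recursively peel off every chain
    that can start at the lowest-index hit (consecutive-pair compatibility)
    and take the best completion of the rest."""
    hits = sorted(hits, key=lambda h: (h.s_interval, h.q_interval))
    from functools import lru_cache

    def compat(i, j):
        return mine._compatible(hits[i], hits[j], max_gap)

    def chains(last, pool, acc):
        yield acc
        for j in sorted(pool):
            if compat(last, j):
                yield from chains(j, pool - {j}, acc | {j})

    @lru_cache(maxsize=None)
    def solve(remaining: frozenset) -> int:
        if not remaining:
            return 0
        first = min(remaining)
        pool = remaining - {first}
        return 1 + min(solve(frozenset(pool - used))
                       for used in chains(first, pool, frozenset()))

    return solve(frozenset(range(len(hits))))


def test_chain_hits_gap_threshold():
    near = [H(0, 100, 1000, 1300), H(100, 200, 2200, 2500)]   # gap 900
    far = [H(0, 100, 1000, 1300), H(100, 200, 3500, 3800)]    # gap 1200
    assert len(mine.chain_hits(near, 1000)) == 1
    assert len(mine.chain_hits(far, 1000)) == 2


def test_chain_hits_strand_colinearity():
    # minus-strand copy: query positions decrease along the subject
    ok = [H(100, 200, 1000, 1300, "-"), H(0, 100, 1400, 1700, "-")]
    assert len(mine.chain_hits(ok, 1000)) == 1
    bad = [H(0, 100, 1000, 1300, "-"), H(100, 200, 1400, 1700, "-")]
    assert len(mine.chain_hits(bad, 1000)) == 2


def test_chain_hits_each_hit_in_exactly_one_candidate():
    rng = np.random.default_rng(13)
    hits = [H(int(q), int(q) + 50, int(s), int(s) + 150)
            for q, s in zip(rng.integers(0, 300, 10), rng.integers(0, 6000, 10))]
    cands = mine.chain_hits(hits, 1000)
    flat = [id(h) for c in cands for h in c.supporting_hits]
    assert sorted(flat) == sorted(id(h) for h in hits)


@pytest.mark.parametrize("seed", [0, 1, 2, 3, 4, 5, 6, 7])
def test_chain_hits_minimal_against_exhaustive_oracle(seed):
    rng = np.random.default_rng(seed)
    n = int(rng.integers(4, 11))
    hits = []
    for _ in range(n):
        q = int(rng.integers(0, 250))
        s = int(rng.integers(0, 5000))
        hits.append(H(q, q + int(rng.integers(30, 80)), s, s + int(rng.integers(100, 400))))
    got = len(mine.chain_hits(hits, 1000))
    assert got == min_chain_count_oracle(hits, 1000)


# ---------------------------------------------------------------------------
# extraction
# ---------------------------------------------------------------------------


def test_filter_and_extract_length_boundary():
    rng = np.random.default_rng(17)
    contig = SequenceRecord("c", "".join(rng.choice(list("ACGT"), size=5000)))
    cands = [
        mine.CopyCandidate("c", (1000, 1399), "+", [H(0, 100, 1000, 1399)], "q"),
        mine.CopyCandidate("c", (2000, 2400), "+", [H(0, 100, 2000, 2400)], "q"),
    ]
    copies = mine.filter_and_extract(cands, {"c": contig}, min_len=400, flank=500)
    assert [c.interval for c in copies] == [(2000, 2400)]


def test_filter_and_extract_contig_edge_truncation():
    rng = np.random.default_rng(19)
    contig = SequenceRecord("c", "".join(rng.choice(list("ACGT"), size=2000)))
    cands = [mine.CopyCandidate("c", (100, 600), "+", [H(0, 100, 100, 600)], "q")]
    (copy,) = mine.filter_and_extract(cands, {"c": contig})
    assert copy.assembly_truncated and len(copy.left_flank) == 100


def test_filter_and_extract_minus_strand_normalisation():
    rng = np.random.default_rng(23)
    seq = "".join(rng.choice(list("ACGT"), size=3000))
    contig = SequenceRecord("c", seq)
    cands = [mine.CopyCandidate("c", (1000, 1600), "-", [H(0, 100, 1000, 1600, "-")], "q")]
    (copy,) = mine.filter_and_extract(cands, {"c": contig})
    assert copy.core_seq == revcomp(seq[1000:1600])
    assert copy.left_flank == revcomp(seq[1600:2100])
    assert copy.right_flank == revcomp(seq[500:1000])


# ---------------------------------------------------------------------------
# clustering
# ---------------------------------------------------------------------------


def _copy(seq, cid="x"):
    return mine.TECopy(cid, "c", (0, len(seq)), "+", seq, "", "", "N" in seq, False)


def test_cluster_copies_identical_and_revcomp():
    rng = np.random.default_rng(29)
    seq = "".join(rng.choice(list("ACGT"), size=600))
    a, b = _copy(seq, "a"), _copy(seq, "b")
    assert len(mine.cluster_copies([a, b])) == 1
    rc = _copy(revcomp(seq), "rc")
    assert len(mine.cluster_copies([_copy(seq, "a"), rc], rev=True)) == 1
    assert len(mine.cluster_copies([_copy(seq, "a"), rc], rev=False)) == 2


def test_cluster_copies_matches_single_linkage_oracle():
    """On well-separated planted families, greedy centroid clustering yields
    the same partition as brute-force single linkage at the same cutoff."""
    rng = np.random.default_rng(31)
    ancestors = ["".join(rng.choice(list("ACGT"), size=500)) for _ in range(3)]
    copies = []
    for fi, anc in enumerate(ancestors):
        for ci in range(6):
            copies.append(_copy(sim.mutate_copy(anc, 0.05, 1.0, rng), f"f{fi}c{ci}"))
    clusters = mine.cluster_copies(copies, identity=0.8)
    got = sorted(sorted(m.copy_id for m in cl.members) for cl in clusters)
    # single-linkage oracle
    ids = [c.copy_id for c in copies]
    parent = {i: i for i in ids}

    def find(x):
        while parent[x] != x:
            x = parent[x]
        return x

    for a, b in combinations(copies, 2):
        if nw_identity(a.core_seq, b.core_seq) >= 0.8:
            parent[find(a.copy_id)] = find(b.copy_id)
    groups = {}
    for i in ids:
        groups.setdefault(find(i), []).append(i)
    want = sorted(sorted(g) for g in groups.values())
    assert got == want


# ---------------------------------------------------------------------------
# cleaning and characterisation
# ---------------------------------------------------------------------------


def test_clean_cluster_excludes_n_and_collapses_twins():
    rng = np.random.default_rng(37)
    seq = "".join(rng.choice(list("ACGT"), size=600))
    flank_a = "".join(rng.choice(list("ACGT"), size=500))
    flank_b = "".join(rng.choice(list("ACGT"), size=500))
    shared_l = "".join(rng.choice(list("ACGT"), size=500))
    shared_r = "".join(rng.choice(list("ACGT"), size=500))
    members = [
        mine.TECopy("a", "c", (0, 600), "+", seq, flank_a, flank_b, False, False),
        mine.TECopy("twin1", "c", (0, 600), "+", seq, shared_l, shared_r, False, False),
        mine.TECopy("twin2", "c", (0, 600), "+", seq, shared_l, shared_r, False, False),
        mine.TECopy("n", "c", (0, 600), "+", seq[:300] + "N" * 10 + seq[310:],
                    flank_a, flank_b, True, False),
        mine.TECopy("trunc", "c", (0, 600), "+", seq, flank_a[:100], flank_b, False, True),
    ]
    cl = mine.CopyCluster(members[0], members)
    mine.clean_cluster(cl)
    assert len(cl.members) == 5                       # total keeps everything
    assert {m.copy_id for m in cl.clean_members} == {"a", "twin1", "twin2"}
    assert cl.clean_independent_count == 2            # twins count once


def test_characterize_rejects_small_clusters(mined_small):
    cfg = PipelineConfig()
    rng = np.random.default_rng(41)
    seq = "".join(rng.choice(list("ACGT"), size=600))
    members = [mine.TECopy(f"m{i}", "c", (0, 600), "+", seq,
                           "".join(rng.choice(list("ACGT"), size=500)),
                           "".join(rng.choice(list("ACGT"), size=500)), False, False)
               for i in range(4)]
    cl = mine.CopyCluster(members[0], members)
    mine.clean_cluster(cl)
    assert mine.characterize_lineage(cl, cfg) is None


# ---------------------------------------------------------------------------
# end-to-end on the shared small genome
# ---------------------------------------------------------------------------


def test_end_to_end_recovers_planted_families(small_genome, mined_small):
    genome, specs = small_genome
    res = mined_small
    assert len(res.lineages) == len(specs)
    for lin in res.lineages:
        spec = max(specs, key=lambda s: nw_identity(lin.consensus_nt.residues,
                                                    s.ancestor.residues))
        truth_clean = sum(1 for t in genome.truth
                          if t.family == spec.name and t.independent
                          and not t.has_n and not t.assembly_truncated)
        assert lin.tsd == "TA"
        assert lin.clean_independent_count == truth_clean
        assert nw_identity(lin.consensus_nt.residues, spec.ancestor.residues) >= 0.99
        assert lin.potentially_active


def test_copy_counts_invariant_to_contig_order_and_revcomp(small_genome, small_queries):
    genome, _specs = small_genome
    res_fwd = mine.mine_genome(genome.contigs, small_queries)
    res_perm = mine.mine_genome(genome.contigs[::-1], small_queries)
    counts = lambda r: sorted(len(l.members) for l in r.lineages)
    assert counts(res_fwd) == counts(res_perm)
    rc_contigs = [SequenceRecord(c.id, revcomp(c.residues)) for c in genome.contigs]
    res_rc = mine.mine_genome(rc_contigs, small_queries)
    assert counts(res_fwd) == counts(res_rc)


def test_lineage_table_columns(mined_small):
    df = mine.lineage_table(mined_small.lineages)
    assert list(df.columns)[:3] == ["Cluster", "Total Copy Number",
                                    "Clean Independent Copy Number"]
    assert len(df) == len(mined_small.lineages)
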