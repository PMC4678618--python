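"""UPGM-VM classification and subfamily assignment.

UPGM-VM is an ascending hierarchical classification of nucleotide element
sequences that differs from classical UPGMA in two ways: there is no
arithmetic mean — cluster-to-cluster distance is the minimum over pairwise
alignments, recomputed per round — and the metric varies as the
classification ascends.  Early rounds score an alignment gap like a fifth
nucleotide (weight 1); the gap weight then decays rapidly to zero, which
lets a complete element join its internally deleted derivatives (MITEs,
truncated copies) late in the clustering without distorting the early,
substitution-driven groups.

Subfamily assignment places a lineage consensus with the reference group of
minimal average distance at full gap weight, or calls it "novel" beyond a
distance threshold.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

from .seqcore import SequenceRecord, align_pair_vm, vm_distance_w1

# ---------------------------------------------------------------------------
# Types
# ---------------------------------------------------------------------------


@dataclass
class VMDendrogram:
    leaves: list[str]
    # (cluster_a leaf ids, cluster_b leaf ids, height, gap weight at merge)
    merges: list[tuple[tuple[str, ...], tuple[str, ...], float, float]]

    def newick(self) -> str:
        """Newick with branch lengths = difference of merge heights (heights
        need not increase because the metric changes between rounds, so
        negative branch lengths are possible and kept as recorded)."""
        sub: dict[tuple[str, ...], tuple[str, float]] = {
            (leaf,): (leaf, 0.0) for leaf in self.leaves}
        for a, b, h, _w in self.merges:
            (na, ha), (nb, hb) = sub.pop(a), sub.pop(b)
            merged = tuple(sorted(a + b))
            sub[merged] = (f"({na}:{h - ha:.6f},{nb}:{h - hb:.6f})", h)
        (root, _h), = sub.values()
        return root + ";"

    def partition_at(self, round_index: int) -> list[tuple[str, ...]]:
        """Cluster composition after the first ``round_index`` merges."""
        clusters: list[tuple[str, ...]] = [(leaf,) for leaf in self.leaves]
        for a, b, _h, _w in self.merges[:round_index]:
            clusters.remove(a)
            clusters.remove(b)
            clusters.append(tuple(sorted(a + b)))
        return sorted(clusters)


@dataclass
class SubfamilyAssignment:
    lineage_name: str
    label: str
    distance: float
    support: float        # margin: second-nearest group distance minus nearest


# ---------------------------------------------------------------------------
# UPGM-VM
# ---------------------------------------------------------------------------


def default_weight_schedule(merges_done: int, n_leaves: int) -> float:
    """Gap weight 2^-k with k = floor(6 * merges_done / (n - 1)), clamped to
    zero from k = 6: starts at 1 ("a fifth nucleotide") and is progressively
    and rapidly set to zero as the classification ascends."""
    k = (6 * merges_done) // max(1, n_leaves - 1)
    return 0.0 if k >= 6 else 2.0 ** (-k)


def upgm_vm(seqs: Sequence[SequenceRecord],
            weight_schedule: Callable[[int, int], float] | None = None) -> VMDendrogram:
    """Variable-metric ascending hierarchical classification.

    At each round the gap weight is taken from the schedule, all
    cluster-to-cluster distances are recomputed as the minimum pairwise
    variable-metric alignment distance at that weight, and the closest pair
    merges (ties broken lexicographically by leaf id).
    """
    if len(seqs) < 2:
        raise ValueError("upgm_vm needs at least 2 sequences")
    ids = [s.id for s in seqs]
    if len(set(ids)) != len(ids):
        raise ValueError("sequence ids must be unique")
    schedule = weight_schedule or default_weight_schedule
    n = len(seqs)
    seq_of = {s.id: s.residues for s in seqs}
    clusters: list[tuple[str, ...]] = sorted((s.id,) for s in seqs)
    cache: dict[tuple[str, str, float], float] = {}

    def pair_dist(a: str, b: str, w: float) -> float:
        key = (a, b, w) if a < b else (b, a, w)
        if key not in cache:
            cache[key] = align_pair_vm(seq_of[a], seq_of[b], w).vm_distance
        return cache[key]

    merges: list[tuple[tuple[str, ...], tuple[str, ...], float, float]] = []
    for round_idx in range(n - 1):
        w = schedule(round_idx, n)
        best: tuple[float, tuple[str, ...], tuple[str, ...]] | None = None
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                a, b = clusters[i], clusters[j]
                d = min(pair_dist(x, y, w) for x in a for y in b)
                cand = (d, a, b)
                if best is None or cand < best:
                    best = cand
        d, a, b = best
        merges.append((a, b, d, w))
        clusters.remove(a)
        clusters.remove(b)
        clusters.append(tuple(sorted(a + b)))
        clusters.sort()
    return VMDendrogram(sorted(ids), merges)


# ---------------------------------------------------------------------------
# Subfamily assignment
# ---------------------------------------------------------------------------


def reference_groups(references: Sequence[SequenceRecord]) -> dict[str, list[SequenceRecord]]:
    """Group labelled references; the label is the ``subfamily=<name>`` token
    of the description."""
    groups: dict[str, list[SequenceRecord]] = {}
    for rec in references:
        label = None
        for tok in rec.description.split():
            if tok.startswith("subfamily="):
                label = tok.split("=", 1)[1]
        if label is None:
            raise ValueError(f"reference {rec.id!r} lacks a subfamily=<name> label")
        groups.setdefault(label, []).append(rec)
    return groups


def assign_subfamily(consensus: SequenceRecord, references: Sequence[SequenceRecord],
                     novelty_threshold: float = 0.45) -> SubfamilyAssignment:
    """Label of the reference group with minimal average variable-metric
    distance at full gap weight; "novel" when even the nearest group is
    farther than ``novelty_threshold``."""
    groups = reference_groups(references)
    if len(groups) < 2:
        raise ValueError("references must span at least 2 subfamily labels")
    means = []
    for label in sorted(groups):
        ds = [vm_distance_w1(consensus.residues, r.residues) for r in groups[label]]
        means.append((sum(ds) / len(ds), label))
    means.sort()
    (d1, label1), (d2, _label2) = means[0], means[1]
    if d1 > novelty_threshold:
        return SubfamilyAssignment(consensus.id, "novel", d1, d2 - d1)
    return SubfamilyAssignment(consensus.id, label1, d1, d2 - d1)


def assign_lineages(lineages, references: Sequence[SequenceRecord],
                    novelty_threshold: float = 0.45) -> list[SubfamilyAssignment]:
    """Assign every mined lineage's consensus and stamp the label back onto
    the lineage records."""
    out = []
    for lin in lineages:
        a = assign_subfamily(lin.consensus_nt, references, novelty_threshold)
        lin.subfamily = a.label
        out.append(a)
    return out
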