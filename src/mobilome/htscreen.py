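"""Horizontal-transfer screening, rearranged-copy breakpoint analysis, and
mobilome masking reports.

Horizontal transfer (HT) of a transposon between reproductively isolated
species shows up as anomalously high sequence identity: a lineage consensus
matching a foreign genome at more than 75% nucleotide identity over more
than 90% of its length is an HT candidate, provided the locus sits inside a
conserved synteny block of the recipient genome (which excludes sequencing
contamination, typically short orphan contigs with no conserved context).

The breakpoint analysis characterises copies produced by the
5'-replaced-by-3' rearrangement: such copies hit the full-length reference
on both the plus and the minus strand, and the two block starts in
reference coordinates are the rearrangement breakpoints.

The masking report measures how much of a genome a consensus library covers
(a RepeatMasker-style accounting by superfamily).
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field

import numpy as np

from .mine import chain_hits
from .seqcore import LocalHit, PipelineConfig, SequenceRecord, search_nt

# ---------------------------------------------------------------------------
# Types
# ---------------------------------------------------------------------------


@dataclass
class HTCandidate:
    query_lineage: str
    foreign_genome_id: str
    identity: float
    query_coverage: float
    copy_count_in_foreign: int
    synteny_pass: bool
    verdict: str                      # candidate | rejected_identity | ...
    best_locus: tuple[str, int, int] | None = None


@dataclass
class BreakpointRecord:
    copy_id: str
    a_breakpoint: int                 # 0-based, full-length-element coordinates
    b_breakpoint: int
    copy_length: int
    extra_deletions: bool


@dataclass
class MaskReport:
    genome_bp: int
    per_superfamily: dict[str, int]   # merged masked bp
    total_masked_bp: int

    def fraction(self, superfamily: str) -> float:
        return self.per_superfamily.get(superfamily, 0) / self.genome_bp

    @property
    def total_fraction(self) -> float:
        return self.total_masked_bp / self.genome_bp


# ---------------------------------------------------------------------------
# Loci from nucleotide hits
# ---------------------------------------------------------------------------


def _hit_loci(consensus: SequenceRecord, contigs: list[SequenceRecord],
              max_gap: int = 1000, min_score: float = 60.0) -> list[dict]:
    """Chain nucleotide hits of the consensus into loci and score each locus
    by merged query coverage and column-weighted identity."""
    hits: list[LocalHit] = []
    for rec in contigs:
        hits.extend(search_nt(consensus, rec, min_score=min_score))
    loci = []
    for cand in chain_hits(hits, max_gap=max_gap):
        spans = sorted(h.q_interval for h in cand.supporting_hits)
        covered = 0
        last_end = -1
        for qs, qe in spans:
            covered += max(0, qe - max(qs, last_end))
            last_end = max(last_end, qe)
        weights = [(h.q_interval[1] - h.q_interval[0]) for h in cand.supporting_hits]
        ident = (sum(h.identity * w for h, w in zip(cand.supporting_hits, weights))
                 / sum(weights))
        loci.append({
            "contig": cand.contig, "interval": cand.interval,
            "strand": cand.strand, "identity": ident,
            "coverage": covered / len(consensus.residues),
            "score": cand.score})
    loci.sort(key=lambda l: (-l["coverage"] * l["identity"], l["contig"], l["interval"]))
    return loci


# ---------------------------------------------------------------------------
# HT screening
# ---------------------------------------------------------------------------


def check_synteny(locus: tuple[str, int, int], recipient_contigs: list[SequenceRecord],
                  reference_contigs: list[SequenceRecord], window: int = 5000
                  ) -> tuple[bool, str]:
    """Conserved-synteny test of an HT candidate locus.

    The ``window`` bp on each side of the locus must both match the same
    donor-free reference contig, in the same orientation and order.  A locus
    too close to a contig edge fails with reason "edge" (short orphan
    contigs — the contamination signature — always do).
    """
    if window <= 0:
        raise ValueError("window must be positive")
    contig_id, start, end = locus
    contig = next((c for c in recipient_contigs if c.id == contig_id), None)
    if contig is None:
        raise KeyError(contig_id)
    if start - window < 0 or end + window > len(contig.residues):
        return False, "edge"
    # the windows are inspected through short probes (cheap local searches
    # rather than one window-long alignment); any probe anchoring a side on
    # the reference carries the synteny information of that side
    probe_len = min(500, window)
    offsets = sorted({0, max(0, window // 2 - probe_len // 2), window - probe_len})
    probes = []
    for off in offsets:
        lseq = contig.residues[start - window + off : start - window + off + probe_len]
        rseq = contig.residues[end + off : end + off + probe_len]
        probes.append(SequenceRecord(f"left_flank_{off}", lseq))
        probes.append(SequenceRecord(f"right_flank_{off}", rseq))
    best: dict[str, LocalHit | None] = {"left_flank": None, "right_flank": None}
    for ref in reference_contigs:
        for q in probes:
            side = "left_flank" if q.id.startswith("left") else "right_flank"
            for h in search_nt(q, ref, min_score=100.0):
                cur = best[side]
                if cur is None or h.score > cur.score:
                    best[side] = h
    lh, rh = best["left_flank"], best["right_flank"]
    if lh is None or rh is None:
        return False, "no conserved flank match"
    if lh.subject_id != rh.subject_id:
        return False, "flanks match different reference contigs"
    if lh.strand != rh.strand:
        return False, "flanks match in opposite orientations"
    ordered = (lh.s_interval[0] <= rh.s_interval[1] if lh.strand == "+"
               else rh.s_interval[0] <= lh.s_interval[1])
    if not ordered:
        return False, "flank order not conserved"
    return True, "ok"


def screen_ht(consensus: SequenceRecord, foreign_genomes, config: PipelineConfig | None = None
              ) -> list[HTCandidate]:
    """Screen a lineage consensus against foreign genomes.

    ``foreign_genomes`` is an iterable of objects with ``genome_id``,
    ``contigs`` and optionally ``reference_contigs`` (donor-free genomes for
    the synteny check; when absent the synteny test is vacuous and passes).
    """
    config = config or PipelineConfig()
    if len(consensus.residues) < 200:
        raise ValueError("consensus too short for HT screening (min 200 bp)")
    out: list[HTCandidate] = []
    window = min(config.synteny_window_bp, 5000)
    for fg in foreign_genomes:
        loci = _hit_loci(consensus, fg.contigs)
        passing = [l for l in loci if l["identity"] > config.ht_min_identity
                   and l["coverage"] > config.ht_min_coverage]
        if not loci:
            out.append(HTCandidate(consensus.id, fg.genome_id, 0.0, 0.0, 0,
                                   False, "rejected_identity"))
            continue
        best = loci[0]
        locus = (best["contig"], *best["interval"])
        identity, coverage = best["identity"], best["coverage"]
        references = getattr(fg, "reference_contigs", None)
        if identity <= config.ht_min_identity:
            verdict, syn = "rejected_identity", False
        elif coverage <= config.ht_min_coverage:
            verdict, syn = "rejected_coverage", False
        else:
            if references:
                syn, _reason = check_synteny(locus, fg.contigs, references, window)
            else:
                syn = True
            verdict = "candidate" if syn else "rejected_synteny"
        out.append(HTCandidate(consensus.id, fg.genome_id, identity, coverage,
                               len(passing), syn, verdict, locus))
    return out


def ht_table(candidates: list[HTCandidate]):
    """Summary table of HT screening results (one row per foreign genome)."""
    import pandas as pd

    return pd.DataFrame([{
        "TE": c.query_lineage,
        "Foreign genome": c.foreign_genome_id,
        "Copy number": c.copy_count_in_foreign,
        "Nucleotide similarity": f"{100 * c.identity:.0f} %",
        "Query coverage": f"{100 * c.query_coverage:.0f} %",
        "Synteny": "pass" if c.synteny_pass else "fail",
        "Verdict": c.verdict,
    } for c in candidates])


# ---------------------------------------------------------------------------
# Rearranged copies (plus+minus strand hit structure)
# ---------------------------------------------------------------------------


def detect_rearranged_copies(full_length_ref: SequenceRecord,
                             contigs: list[SequenceRecord],
                             junction_tol: int = 10,
                             min_score: float = 100.0) -> list[BreakpointRecord]:
    """Find copies made of a reverse-complemented 3' block replacing the 5'
    part of the reference element.

    A rearranged copy yields exactly one plus-strand and one minus-strand
    hit of the reference that together tile the copy; the two hit starts in
    reference coordinates are the breakpoints (a = plus-part, b =
    reversed-part).  Copies with junction gaps or missing reference ends
    beyond ``junction_tol`` carry additional deletions: they are reported
    flagged and excluded from the clean set by the caller.
    """
    if len(full_length_ref.residues) < 500:
        raise ValueError("reference must be at least 500 bp")
    L = len(full_length_ref.residues)
    hits: list[LocalHit] = []
    for rec in contigs:
        hits.extend(search_nt(full_length_ref, rec, min_score=min_score))
    # group hits into loci by subject position regardless of strand
    by_contig: dict[str, list[LocalHit]] = defaultdict(list)
    for h in hits:
        by_contig[h.subject_id].append(h)
    records: list[BreakpointRecord] = []
    for contig in sorted(by_contig):
        chits = sorted(by_contig[contig], key=lambda h: h.s_interval)
        loci: list[list[LocalHit]] = []
        for h in chits:
            if loci and h.s_interval[0] - max(x.s_interval[1] for x in loci[-1]) <= 50:
                loci[-1].append(h)
            else:
                loci.append([h])
        for locus in loci:
            plus = [h for h in locus if h.strand == "+"]
            minus = [h for h in locus if h.strand == "-"]
            if len(plus) != 1 or len(minus) != 1:
                continue
            p, m = plus[0], minus[0]
            s_start = min(p.s_interval[0], m.s_interval[0])
            s_end = max(p.s_interval[1], m.s_interval[1])
            copy_len = s_end - s_start
            a_bp = min(p.q_interval[0], m.q_interval[0])
            b_bp = max(p.q_interval[0], m.q_interval[0])
            # junction tiling: blocks must abut within tolerance
            inner = sorted([p.s_interval, m.s_interval])
            junction_gap = abs(inner[1][0] - inner[0][1])
            # both blocks must reach the reference 3' end
            ref_end_ok = (p.q_interval[1] >= L - junction_tol
                          and m.q_interval[1] >= L - junction_tol)
            expected_len = (L - a_bp) + (L - b_bp)
            extra = (junction_gap > junction_tol or not ref_end_ok
                     or abs(copy_len - expected_len) > 3 * junction_tol)
            records.append(BreakpointRecord(
                copy_id=f"{contig}:{s_start}-{s_end}",
                a_breakpoint=a_bp, b_breakpoint=b_bp,
                copy_length=copy_len, extra_deletions=extra))
    records.sort(key=lambda r: r.copy_id)
    return records


def breakpoint_profile(records: list[BreakpointRecord], ref_len: int,
                       size_line_bp: int = 938, bins: int = 40) -> dict:
    """Histograms of breakpoint positions, copy-size distribution, A-vs-B
    scatter pairs, and the fraction of copies below the size line."""
    clean = [r for r in records if not r.extra_deletions]
    if not clean:
        raise ValueError("no clean rearranged copies")
    a = np.array([r.a_breakpoint for r in clean])
    b = np.array([r.b_breakpoint for r in clean])
    sizes = np.array([r.copy_length for r in clean])
    return {
        "n_clean": len(clean),
        "n_flagged": len(records) - len(clean),
        "a_hist": np.histogram(a, bins=bins, range=(0, ref_len)),
        "b_hist": np.histogram(b, bins=bins, range=(0, ref_len)),
        "sizes": sizes,
        "pairs": np.column_stack([a, b]),
        "fraction_below_size_line": float(np.mean(sizes < size_line_bp)),
    }


# ---------------------------------------------------------------------------
# Masking report
# ---------------------------------------------------------------------------


def _superfamily_of(rec: SequenceRecord) -> str:
    for tok in rec.description.split():
        if tok.startswith("superfamily="):
            return tok.split("=", 1)[1]
    return rec.id


def _merge_intervals(intervals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    merged: list[tuple[int, int]] = []
    for s, e in sorted(intervals):
        if merged and s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged


def mask_genome(consensus_library: list[SequenceRecord], contigs: list[SequenceRecord],
                min_score: float = 60.0) -> MaskReport:
    """RepeatMasker-style coverage accounting.

    Every consensus is searched against the genome on both strands; hit
    intervals are assigned to superfamilies with overlaps resolved by best
    score, then merged per superfamily.  The report is invariant to library
    order (hits are globally sorted by score before assignment).
    """
    if not consensus_library:
        raise ValueError("consensus library must not be empty")
    genome_bp = sum(len(c.residues) for c in contigs)
    scored: list[tuple[float, str, str, int, int]] = []
    for cons in consensus_library:
        fam = _superfamily_of(cons)
        for rec in contigs:
            for h in search_nt(cons, rec, min_score=min_score):
                scored.append((h.score, fam, rec.id, *h.s_interval))
    scored.sort(key=lambda t: (-t[0], t[1], t[2], t[3], t[4]))
    taken: dict[str, list[tuple[int, int]]] = defaultdict(list)
    assigned: dict[tuple[str, str], list[tuple[int, int]]] = defaultdict(list)
    for score, fam, contig, s, e in scored:
        free = [(s, e)]
        for ts, te in taken[contig]:
            nxt = []
            for fs, fe in free:
                if te <= fs or ts >= fe:
                    nxt.append((fs, fe))
                    continue
                if fs < ts:
                    nxt.append((fs, ts))
                if te < fe:
                    nxt.append((te, fe))
            free = nxt
            if not free:
                break
        for fs, fe in free:
            if fe - fs > 0:
                assigned[(fam, contig)].append((fs, fe))
                taken[contig].append((fs, fe))
        taken[contig] = _merge_intervals(taken[contig])
    per_fam: dict[str, int] = {}
    for (fam, _contig), iv in sorted(assigned.items()):
        per_fam[fam] = per_fam.get(fam, 0) + sum(e - s for s, e in _merge_intervals(iv))
    return MaskReport(genome_bp, per_fam, sum(per_fam.values()))
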