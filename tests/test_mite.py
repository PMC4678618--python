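"""MITE discovery tests: inverted-repeat seeding against a brute-force
oracle, TSD-aware boundary trimming, filtering semantics, TSD inference,
partner search and superfamily assignment."""

import numpy as np
import pytest

from mobilome import mite
from mobilome import simulate as sim
from mobilome.seqcore import SequenceRecord, revcomp


def random_dna(rng, n):
    return "".join(rng.choice(list("ACGT"), size=n))


# ---------------------------------------------------------------------------
# inverted-repeat seeding
# ---------------------------------------------------------------------------


def test_find_inverted_repeats_constructed_pair():
    rng = np.random.default_rng(1)
    s = random_dna(rng, 15)
    genome = SequenceRecord("g", random_dna(rng, 200) + s + random_dna(rng, 300)
                            + revcomp(s) + random_dna(rng, 200))
    pairs = mite.find_inverted_repeats(genome, min_word=11, max_span=750)
    # chance matching bases adjacent to the planted blocks may extend the
    # maximal match by a base or two
    assert any(abs(p.left_interval[0] - 200) <= 3 and p.seed_len >= 15 for p in pairs)


def test_find_inverted_repeats_ignores_direct_repeats():
    rng = np.random.default_rng(2)
    unit = random_dna(rng, 40)
    genome = SequenceRecord("g", random_dna(rng, 100) + unit + random_dna(rng, 100)
                            + unit + random_dna(rng, 100))
    pairs = mite.find_inverted_repeats(genome, min_word=11, max_span=750)
    covered = [p for p in pairs
               if p.left_interval[0] >= 100 and p.right_interval[1] <= 240 + 100]
    assert covered == []


def brute_force_seed_pairs(seq, k, max_span):
    """Independent exhaustive enumeration of inverted k-mer seed pairs."""
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    by_word = {}
    for i in range(len(seq) - k + 1):
        by_word.setdefault(seq[i:i + k], []).append(i)
    out = set()
    for i in range(len(seq) - k + 1):
        w = seq[i:i + k]
        if "N" in w:
            continue
        rc = "".join(comp[c] for c in reversed(w))
        for j in by_word.get(rc, []):
            if j >= i + k and j - (i + k) <= max_span:
                out.add((i, j))
    return out


def test_find_inverted_repeats_matches_exhaustive_oracle():
    rng = np.random.default_rng(3)
    parts = [random_dna(rng, 20_000)]
    for _ in range(8):  # plant some real inverted pairs
        t = random_dna(rng, 14)
        parts.append(t + random_dna(rng, int(rng.integers(50, 700))) + revcomp(t))
        parts.append(random_dna(rng, 3000))
    genome = SequenceRecord("g", "".join(parts))
    raw = mite.find_inverted_repeats(genome, min_word=11, max_span=750, extend=False)
    got = {(p.left_interval[0], p.right_interval[0]) for p in raw}
    want = brute_force_seed_pairs(genome.residues, 11, 750)
    assert got == want


def test_tsd_trim_pulls_back_overshoot():
    rng = np.random.default_rng(4)
    elem = "CGAGG" + random_dna(rng, 100) + revcomp("CGAGG")
    seq = random_dna(rng, 50) + "TA" + elem + "TA" + random_dna(rng, 50)
    start, end = 50, 50 + 2 + len(elem) + 2   # maximal match includes both TAs
    s, e = mite._tsd_trim(seq, start, end)
    assert (s, e) == (52, 52 + len(elem))


# ---------------------------------------------------------------------------
# cluster-level TSD inference
# ---------------------------------------------------------------------------


def _member(core, lf, rf, cid="m"):
    from mobilome.mine import TECopy

    return TECopy(cid, "c", (0, len(core)), "+", core, lf, rf, False, False)


def test_infer_tsd_ta_and_hat_style_and_unclear():
    rng = np.random.default_rng(5)
    core = random_dna(rng, 200)
    ta = [_member(core, random_dna(rng, 58) + "TA", "TA" + random_dna(rng, 58), f"a{i}")
          for i in range(6)]
    assert mite.infer_cluster_tsd(ta) == "TA"
    hat = []
    for i in range(6):
        t8 = random_dna(rng, 8)
        hat.append(_member(core, random_dna(rng, 52) + t8, t8 + random_dna(rng, 52), f"h{i}"))
    assert mite.infer_cluster_tsd(hat) == "N" * 8
    rnd = [_member(core, random_dna(rng, 60), random_dna(rng, 60), f"r{i}")
           for i in range(6)]
    assert mite.infer_cluster_tsd(rnd) == "unclear"
    assert mite.infer_cluster_tsd(ta[:2]) == "unclear"  # too few intact flanks


# ---------------------------------------------------------------------------
# end-to-end discovery on the standard fixture
# ---------------------------------------------------------------------------


@pytest.fixture(scope="module")
def discovered(mite_fixture):
    rng = np.random.default_rng(3)
    prot = sim.family_query_protein(mite_fixture["specs"][1], rng)
    prot.description = "superfamily=Tc1-mariner"
    clusters, discards = mite.discover_mites(mite_fixture["genome"].contigs,
                                             protein_db=[prot])
    return clusters, discards


def test_planted_family_recovered_bona_fide(mite_fixture, discovered):
    clusters, _discards = discovered
    bona = [c for c in clusters if c.bona_fide]
    assert len(bona) == 1
    cl = bona[0]
    assert cl.tsd == "TA"
    assert cl.tir == mite_fixture["tir"]
    assert cl.independent_count >= 0.9 * len(mite_fixture["mite_truth"])
    assert cl.superfamily == "Tc1-mariner"


def test_partner_found_at_planted_locus(mite_fixture, discovered):
    clusters, _ = discovered
    cl = [c for c in clusters if c.bona_fide][0]
    assert cl.partner is not None
    contig, start, end, seq = cl.partner
    planted = {(t.contig, t.interval) for t in mite_fixture["partner_truth"]}
    assert any(contig == pc and abs(start - ps) <= 5 and abs(end - pe) <= 5
               for pc, (ps, pe) in planted)
    assert end - start > 1000


def test_small_family_and_decoys_rejected_with_reasons(mite_fixture, discovered):
    clusters, discards = discovered
    # the 9-copy family is logged as a copy-number discard (the logged id is
    # the cluster centroid, whose boundaries may differ by a few bases)
    small = {(t.contig, t.interval) for t in mite_fixture["genome"].truth
             if t.family == "small_fam"}

    def overlaps_small(cid: str) -> bool:
        contig, _, coords = cid.rpartition(":")
        s, e = map(int, coords.split("-"))
        return any(contig == tc and s < te and e > ts for tc, (ts, te) in small)

    assert any(overlaps_small(cid) and "copy number" in reason
               for cid, reason in discards)
    # no bona fide cluster overlaps a decoy region (precision vs decoys)
    for cl in clusters:
        if not cl.bona_fide:
            continue
        for m in cl.members:
            for dc, ds, de in mite_fixture["decoys"]:
                assert not (m.contig == dc and m.interval[0] < de and m.interval[1] > ds)


def test_no_partner_when_none_planted():
    rng = np.random.default_rng(7)
    anc, tir = sim.make_mite_ancestor(rng, "m", length=280, tir_len=24)
    spec = sim.FamilySpec("m", "mite", anc, tir, target_copies=20,
                          dynamics_model="L", dynamics_params={"T": 0.01},
                          n_active_copies=0)
    g = sim.plant_genome([spec], 120_000, rng_seed=8)
    clusters, _ = mite.discover_mites(g.contigs)
    bona = [c for c in clusters if c.bona_fide]
    assert len(bona) == 1 and bona[0].partner is None


def test_partner_below_min_length_rejected():
    """A locus sharing the TIRs but spanning < 1 kb is not a partner."""
    rng = np.random.default_rng(9)
    anc, tir = sim.make_mite_ancestor(rng, "m", length=280, tir_len=24)
    spec = sim.FamilySpec("m", "mite", anc, tir, target_copies=20,
                          dynamics_model="L", dynamics_params={"T": 0.01},
                          n_active_copies=0)
    g = sim.plant_genome([spec], 120_000, rng_seed=10)
    # append a 900 bp pseudo-element sharing the TIRs on its own contig
    pseudo = tir + random_dna(rng, 900 - 2 * len(tir)) + revcomp(tir)
    g.contigs.append(SequenceRecord("extra", random_dna(rng, 2000) + pseudo
                                    + random_dna(rng, 2000)))
    clusters, _ = mite.discover_mites(g.contigs)
    bona = [c for c in clusters if c.bona_fide]
    assert len(bona) == 1 and bona[0].partner is None


def test_nested_insertion_does_not_drive_superfamily(mite_fixture):
    """Homology confined to a nested mariner insert in one copy must not
    label the host MITE cluster."""
    rng = np.random.default_rng(11)
    anc, tir = sim.make_mite_ancestor(rng, "host", length=300, tir_len=25)
    spec = sim.FamilySpec("host", "mite", anc, tir, target_copies=25,
                          dynamics_model="L", dynamics_params={"T": 0.01},
                          n_active_copies=0)
    g = sim.plant_genome([spec], 150_000, rng_seed=12)
    mar_anc, _mt, orf = sim.make_ancestor(rng, "mar", length=1310)
    mar_spec = sim.FamilySpec("mar", "mariner", mar_anc, _mt, target_copies=1,
                              orf_interval=orf)
    prot = sim.family_query_protein(mar_spec, rng)
    prot.description = "superfamily=Tc1-mariner"
    # nest a short mariner fragment inside ONE host copy
    host = next(t for t in g.truth if t.family == "host")
    contig = g.contig(host.contig)
    mid = (host.interval[0] + host.interval[1]) // 2
    frag = mar_anc.residues[orf[0]:orf[0] + 240]
    contig.residues = contig.residues[:mid] + frag + contig.residues[mid:]
    clusters, _ = mite.discover_mites(g.contigs, protein_db=[prot])
    bona = [c for c in clusters if c.bona_fide]
    assert bona and all(c.superfamily == "unknown" for c in bona)


def test_pipeline_invariant_to_revcomp(mite_fixture):
    genome = mite_fixture["genome"]
    fwd, _ = mite.discover_mites(genome.contigs)
    rc = [SequenceRecord(c.id, revcomp(c.residues)) for c in genome.contigs]
    rev, _ = mite.discover_mites(rc)
    key = lambda cls: sorted((c.independent_count, c.tsd, len(c.consensus.residues))
                             for c in cls if c.bona_fide)
    assert key(fwd) == key(rev)
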