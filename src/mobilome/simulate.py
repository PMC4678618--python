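"""Truth-bearing synthetic genome generator.

Plants transposable-element families with controlled amplification dynamics
into random background contigs, so that every downstream stage (mining, MITE
discovery, classification, dynamics, HT screening) can be scored against a
complete ground-truth ledger.

The emulated biology, in brief: a family descends from one ancestral element
bounded by terminal inverted repeats (TIRs); each insertion duplicates its
target site (a TA dinucleotide for mariner-style families); a copy inserted
`age` divergence units ago has accumulated substitutions according to a
Jukes-Cantor clock; some copies suffer internal deletions, 5'-replaced-by-3'
rearrangements, N-runs (assembly artifacts) or are duplicated segmentally
together with their flanks (which does not represent transposition).  Copy
ages are drawn from one of four amplification-dynamics models:

* ``E`` (exponential): constant per-copy transposition rate — event density
  grows toward the present, ages pile up near 0;
* ``L`` (linear): constant events per unit time — uniform ages;
* ``S`` (S-shaped): logistic event density, slow start, burst, slow-down;
* ``C`` (concave): high initial rate decaying toward the present — ages pile
  up near the origin.

Substitutions are the only point-mutation process; deletions and
rearrangements are explicit structured events.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .seqcore import SequenceRecord, revcomp, translate_frame

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_STOPS = {"TAA", "TAG", "TGA"}

# ---------------------------------------------------------------------------
# Specs and records
# ---------------------------------------------------------------------------


@dataclass
class FamilySpec:
    """Blueprint of one planted TE family."""

    name: str
    subfamily: str
    ancestor: SequenceRecord
    tir: str
    target_copies: int
    dynamics_model: str = "L"            # one of S, E, L, C
    dynamics_params: dict = field(default_factory=lambda: {"T": 0.05})
    deletion_prob: float = 0.0
    deletion_len_range: tuple[int, int] = (100, 400)
    rearrangement_prob: float = 0.0
    rearrangement_a_window: tuple[int, int] = (190, 250)
    rearrangement_b_offset: int = 0      # b = len - (a + offset); 0 keeps length
    mutation_rate: float = 1.0           # substitutions/site per divergence unit
    tsd: str = "TA"                      # literal site, or an int-like length
    tsd_len: int | None = None           # if set, random TSD of this length per copy
    n_active_copies: int = 2             # copies whose ORF is protected from stops
    orf_interval: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        if self.target_copies < 1:
            raise ValueError("target_copies must be >= 1")
        anc = self.ancestor.residues.upper()
        if self.tir and not (anc.startswith(self.tir) and anc.endswith(revcomp(self.tir))):
            raise ValueError(f"ancestor of {self.name} must start with tir and end with revcomp(tir)")


@dataclass
class TruthRecord:
    """Ground truth for one planted copy (final assembly coordinates)."""

    copy_id: str
    family: str
    subfamily: str
    contig: str
    interval: tuple[int, int]
    strand: str
    age: float
    has_intact_orf: bool
    deletion_intervals: list[tuple[int, int]] = field(default_factory=list)
    rearranged: bool = False
    breakpoints: tuple[int, int] | None = None
    tsd: str = "TA"
    independent: bool = True             # False for segmental-duplication twins
    has_n: bool = False
    assembly_truncated: bool = False
    nested: bool = False


@dataclass
class SyntheticGenome:
    contigs: list[SequenceRecord]
    truth: list[TruthRecord]
    seed: int

    def contig(self, name: str) -> SequenceRecord:
        for c in self.contigs:
            if c.id == name:
                return c
        raise KeyError(name)


@dataclass
class ForeignPlant:
    """A foreign genome carrying a (possibly) horizontally transferred copy,
    plus a matched donor-free reference genome for synteny checking."""

    genome_id: str
    contigs: list[SequenceRecord]
    reference_contigs: list[SequenceRecord]
    identity: float
    syntenic: bool
    insert_interval: tuple[str, int, int]


# ---------------------------------------------------------------------------
# Amplification-dynamics age models
# ---------------------------------------------------------------------------


def _model_T(params: dict) -> float:
    T = float(params.get("T", 0.05))
    if T <= 0:
        raise ValueError("dynamics duration T must be > 0")
    return T


def sample_copy_ages(model: str, params: dict, n: int, rng) -> np.ndarray:
    """Draw ``n`` copy insertion ages (divergence units before present) from
    one of the four amplification-dynamics models.

    ``E``: truncated exponential toward the present (pure birth at per-copy
    rate ``rate``); ``L``: uniform on [0, T]; ``C``: mirror of E (burst at the
    origin); ``S``: ages T - t with t truncated-logistic around T/2 with
    scale ``scale``.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    if n < 0:
        raise ValueError("n must be >= 0")
    if n == 0:
        return np.empty(0)
    T = _model_T(params)
    u = rng.random(n)
    if model == "L":
        return u * T
    if model == "E":
        r = float(params.get("rate", 6.0 / T))
        return -np.log1p(-u * (1.0 - math.exp(-r * T))) / r
    if model == "C":
        r = float(params.get("rate", 6.0 / T))
        return T + np.log1p(-u * (1.0 - math.exp(-r * T))) / r
    if model == "S":
        s = float(params.get("scale", T / 10.0))
        mu = T / 2.0
        lo = 1.0 / (1.0 + math.exp(mu / s))          # logistic CDF at t=0
        hi = 1.0 / (1.0 + math.exp(-(T - mu) / s))   # at t=T
        p = lo + u * (hi - lo)
        t = mu + s * np.log(p / (1.0 - p))
        return T - t
    raise ValueError(f"unknown dynamics model {model!r}")


def age_cdf(model: str, params: dict, ages: np.ndarray) -> np.ndarray:
    """Closed-form CDF of the age distribution (for calibration tests)."""
    T = _model_T(params)
    a = np.clip(np.asarray(ages, dtype=float), 0.0, T)
    if model == "L":
        return a / T
    if model == "E":
        r = float(params.get("rate", 6.0 / T))
        return (1.0 - np.exp(-r * a)) / (1.0 - math.exp(-r * T))
    if model == "C":
        r = float(params.get("rate", 6.0 / T))
        return 1.0 - (1.0 - np.exp(-r * (T - a))) / (1.0 - math.exp(-r * T))
    if model == "S":
        s = float(params.get("scale", T / 10.0))
        mu = T / 2.0
        lo = 1.0 / (1.0 + np.exp(mu / s))
        hi = 1.0 / (1.0 + np.exp(-(T - mu) / s))
        ft = 1.0 / (1.0 + np.exp(-((T - a) - mu) / s))
        return (hi - ft) / (hi - lo)
    raise ValueError(f"unknown dynamics model {model!r}")


def true_median_age(model: str, params: dict) -> float:
    """Median of the age distribution, in closed form."""
    T = _model_T(params)
    if model in ("L", "S"):
        return T / 2.0
    r = float(params.get("rate", 6.0 / T))
    med_e = -math.log1p(-0.5 * (1.0 - math.exp(-r * T))) / r
    return med_e if model == "E" else T - med_e


# ---------------------------------------------------------------------------
# Sequence-level events
# ---------------------------------------------------------------------------


def mutate_copy(ancestor: str, age: float, rate: float, rng,
                protect_orf: tuple[int, int] | None = None) -> str:
    """Apply i.i.d. Jukes-Cantor substitutions for ``age`` divergence units.

    The per-site substitution probability is the JC transition probability
    3/4 (1 - e^(-4 d / 3)) at branch length d = rate * age, so the expected
    observed divergence matches the JC closed form.  When ``protect_orf`` is
    given, substitutions that create an in-frame stop codon inside that
    interval are reverted (used for copies planted as potentially active).
    """
    d = rate * age
    if d >= 0.75:
        raise ValueError("rate * age must stay below 0.75")
    seq = np.frombuffer(ancestor.upper().encode("ascii"), dtype=np.uint8).copy()
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    p = 0.75 * (1.0 - math.exp(-4.0 * d / 3.0))
    hit = np.nonzero(rng.random(len(seq)) < p)[0]
    if len(hit):
        shift = rng.integers(1, 4, size=len(hit))
        codes = np.searchsorted(_BASES, seq[hit])  # ACGT are sorted bytes
        seq[hit] = _BASES[(codes + shift) % 4]
    out = seq.tobytes().decode("ascii")
    if protect_orf is not None:
        s, e = protect_orf
        orf = list(out[s:e])
        anc_orf = ancestor[s:e]
        for c0 in range(0, len(orf) - 2, 3):
            if "".join(orf[c0 : c0 + 3]) in _STOPS:
                orf[c0 : c0 + 3] = anc_orf[c0 : c0 + 3]
        out = out[:s] + "".join(orf) + out[e:]
    return out


def apply_rearrangement(copy: str, a_pos: int, b_pos: int) -> str:
    """Replace the 5' part of an element (up to ``a_pos``) by the reverse
    complement of its 3' part (from ``b_pos``), the abortive-gap-repair
    rearrangement that yields elements whose two ends are long inverted
    copies of the same 3' block."""
    if not (0 < a_pos < len(copy)) or not (0 < b_pos < len(copy)):
        raise ValueError("breakpoints must fall strictly inside the element")
    return revcomp(copy[b_pos:]) + copy[a_pos:]


# ---------------------------------------------------------------------------
# Ancestor construction
# ---------------------------------------------------------------------------


def _random_dna(rng, n: int) -> str:
    return rng.choice(_BASES, size=n).tobytes().decode("ascii")


def _random_orf(rng, n_codons: int) -> str:
    """ATG + random non-stop codons + TAA."""
    codons = ["ATG"]
    while len(codons) < n_codons - 1:
        c = _random_dna(rng, 3)
        if c not in _STOPS and c != "ATG":
            codons.append(c)
    codons.append("TAA")
    return "".join(codons)


def make_ancestor(rng, name: str = "anc", length: int = 1310, tir: str | None = None,
                  tir_len: int = 28, orf_len_nt: int = 1041) -> tuple[SequenceRecord, str, tuple[int, int]]:
    """Build a mariner-style ancestral element: TIR + 5' UTR + transposase
    ORF + 3' UTR + revcomp(TIR).  Returns (record, tir, orf_interval)."""
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    if tir is None:
        tir = _random_dna(rng, tir_len)
    orf = _random_orf(rng, orf_len_nt // 3)
    pad = length - 2 * len(tir) - len(orf)
    if pad < 2:
        raise ValueError("length too small for TIRs and ORF")
    left = pad // 2
    seq = tir + _random_dna(rng, left) + orf + _random_dna(rng, pad - left) + revcomp(tir)
    orf_start = len(tir) + left
    return SequenceRecord(name, seq), tir, (orf_start, orf_start + len(orf))


def family_query_protein(spec: FamilySpec, rng, divergence: float = 0.05) -> SequenceRecord:
    """A transposase query related to (not identical to) the family ancestor,
    emulating a library protein from a sister lineage."""
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    if spec.orf_interval is None:
        raise ValueError(f"family {spec.name} has no recorded ORF")
    s, e = spec.orf_interval
    mutated = mutate_copy(spec.ancestor.residues, divergence, 1.0, rng, protect_orf=(s, e))
    prot = translate_frame(mutated[s:e], 0).rstrip("*")
    return SequenceRecord(f"{spec.name}_tpase", prot, f"transposase query for {spec.name}")


# ---------------------------------------------------------------------------
# Genome assembly
# ---------------------------------------------------------------------------


@dataclass
class _Insert:
    bg_pos: int
    text: str                 # full inserted block (tsd + element + tsd, or segdup block)
    elem_offset: int          # element start within text
    elem_len: int
    truth: TruthRecord


def _sample_sites(rng, contig_lens: list[int], count: int, margin: int,
                  slot: int) -> list[tuple[int, int]]:
    """Deterministic non-overlapping insertion sites: shuffled grid slots with
    jitter, guaranteeing >= slot - 200 bp between neighbouring sites."""
    slots: list[tuple[int, int]] = []
    for ci, ln in enumerate(contig_lens):
        for pos in range(margin, ln - margin, slot):
            slots.append((ci, pos))
    if count > len(slots):
        raise ValueError(f"background too small: {count} insertions, {len(slots)} slots")
    order = rng.permutation(len(slots))[:count]
    return [(slots[i][0], slots[i][1] + int(rng.integers(0, 100))) for i in sorted(order)]


def plant_genome(specs: Sequence[FamilySpec], background_len: int, contig_count: int = 1,
                 extras: dict | None = None, rng_seed: int = 0) -> SyntheticGenome:
    """Assemble a synthetic genome with all families planted.

    Each copy is inserted at a site whose target sequence (the family TSD,
    "TA" for mariner-style families) is duplicated on both sides.  The
    ``extras`` dict may set ``n_run_prob`` (per-copy probability of an N-run
    in the copy or its flank), ``segdup_count`` (segmental duplications of a
    planted copy together with >= 500 bp of flanks) and ``nested_count``
    (copies inserted inside another planted copy).
    """
    extras = {"n_run_prob": 0.0, "segdup_count": 0, "nested_count": 0,
              "flank_margin": 600, **(extras or {})}
    rng = np.random.default_rng(rng_seed)
    base = max(1, background_len // contig_count)
    contig_lens = [base] * contig_count
    backgrounds = [_random_dna(rng, ln) for ln in contig_lens]
    total = sum(s.target_copies for s in specs)
    margin = extras["flank_margin"]
    sites = _sample_sites(rng, contig_lens, total, margin, slot=1400)
    inserts: list[list[_Insert]] = [[] for _ in contig_lens]

    site_iter = iter(sites)
    for spec in specs:
        ages = np.sort(sample_copy_ages(spec.dynamics_model, spec.dynamics_params,
                                        spec.target_copies, rng))[::-1]
        anc = spec.ancestor.residues.upper()
        active_idx = set()
        if spec.n_active_copies and spec.orf_interval is not None:
            # youngest copies are the plausibly active ones
            active_idx = set(range(spec.target_copies - spec.n_active_copies,
                                   spec.target_copies))
        for i in range(spec.target_copies):
            ci, pos = next(site_iter)
            age = float(ages[i])
            protect = spec.orf_interval if i in active_idx else None
            elem = mutate_copy(anc, age, spec.mutation_rate, rng, protect_orf=protect)
            deletions: list[tuple[int, int]] = []
            breakpoints = None
            rearranged = False
            if spec.rearrangement_prob and rng.random() < spec.rearrangement_prob:
                a = int(rng.integers(*spec.rearrangement_a_window))
                b = len(elem) - a - spec.rearrangement_b_offset
                elem = apply_rearrangement(elem, a, b)
                breakpoints = (a, b)
                rearranged = True
            elif spec.deletion_prob and rng.random() < spec.deletion_prob:
                dlen = int(rng.integers(*spec.deletion_len_range))
                dstart = int(rng.integers(60, len(elem) - 60 - dlen))
                elem = elem[:dstart] + elem[dstart + dlen:]
                deletions.append((dstart, dstart + dlen))
            strand = "+" if rng.random() < 0.5 else "-"
            placed = elem if strand == "+" else revcomp(elem)
            tsd = spec.tsd if spec.tsd_len is None else _random_dna(rng, spec.tsd_len)
            has_n = False
            truncated = False
            if extras["n_run_prob"] and rng.random() < extras["n_run_prob"]:
                if rng.random() < 0.5 and len(placed) > 200:  # N-run inside the copy
                    npos = int(rng.integers(50, len(placed) - 90))
                    placed = placed[:npos] + "N" * 40 + placed[npos + 40:]
                    has_n = True
                else:  # N-run in the left flank, inside the 500 bp window
                    cut = pos - int(rng.integers(100, 400))
                    backgrounds[ci] = (backgrounds[ci][:cut] + "N" * 30
                                       + backgrounds[ci][cut + 30:])
                    truncated = True
            has_orf = protect is not None and not rearranged and not deletions and not has_n
            rec = TruthRecord(
                copy_id=f"{spec.name}_c{i:04d}", family=spec.name,
                subfamily=spec.subfamily, contig=f"contig{ci}", interval=(0, 0),
                strand=strand, age=age, has_intact_orf=has_orf,
                deletion_intervals=deletions, rearranged=rearranged,
                breakpoints=breakpoints, tsd=tsd, has_n=has_n,
                assembly_truncated=truncated)
            inserts[ci].append(_Insert(pos, tsd + placed + tsd, len(tsd), len(placed), rec))

    # nested insertions: a fresh copy of the first family inside a planted copy
    for k in range(extras["nested_count"]):
        hosts = [ins for lst in inserts for ins in lst
                 if not ins.truth.has_n and ins.elem_len > 600]
        if not hosts or not specs:
            break
        host = hosts[int(rng.integers(0, len(hosts)))]
        spec = specs[int(rng.integers(0, len(specs)))]
        elem = mutate_copy(spec.ancestor.residues.upper(), 0.01, spec.mutation_rate, rng)
        tsd = spec.tsd if spec.tsd_len is None else _random_dna(rng, spec.tsd_len)
        off = host.elem_offset + int(rng.integers(100, host.elem_len - 100))
        host.text = host.text[:off] + tsd + elem + tsd + host.text[off:]
        host.truth.nested = True  # host interval now contains a nested element

    # segmental duplications: copy an insertion together with its flanks
    segdup_donors = [ins for lst in inserts for ins in lst
                     if ins.truth.independent and not ins.truth.has_n
                     and not ins.truth.assembly_truncated and not ins.truth.nested]
    donor_order = rng.permutation(len(segdup_donors))
    flank = 550
    for k in range(min(extras["segdup_count"], len(segdup_donors))):
        donor = segdup_donors[int(donor_order[k])]
        ci = int(donor.truth.contig.removeprefix("contig"))
        left = backgrounds[ci][donor.bg_pos - flank : donor.bg_pos]
        right = backgrounds[ci][donor.bg_pos : donor.bg_pos + flank]
        block = left + donor.text + right
        # append the twin past the last contig's regular slots
        tci = len(contig_lens) - 1
        twin_truth = TruthRecord(
            copy_id=donor.truth.copy_id + "_segdup", family=donor.truth.family,
            subfamily=donor.truth.subfamily, contig=f"contig{tci}", interval=(0, 0),
            strand=donor.truth.strand, age=donor.truth.age,
            has_intact_orf=donor.truth.has_intact_orf, tsd=donor.truth.tsd,
            independent=False)
        inserts[tci].append(_Insert(len(backgrounds[tci]) - 1,
                                    block, len(left) + donor.elem_offset,
                                    donor.elem_len, twin_truth))

    contigs: list[SequenceRecord] = []
    truth: list[TruthRecord] = []
    for ci, bg in enumerate(backgrounds):
        parts: list[str] = []
        cursor = 0
        offset = 0
        for ins in sorted(inserts[ci], key=lambda x: x.bg_pos):
            parts.append(bg[cursor : ins.bg_pos])
            offset += ins.bg_pos - cursor
            start = offset + ins.elem_offset
            ins.truth.interval = (start, start + ins.elem_len)
            parts.append(ins.text)
            offset += len(ins.text)
            cursor = ins.bg_pos
            truth.append(ins.truth)
        parts.append(bg[cursor:])
        contigs.append(SequenceRecord(f"contig{ci}", "".join(parts),
                                      f"synthetic contig {ci}"))
    truth.sort(key=lambda t: (t.contig, t.interval))
    return SyntheticGenome(contigs, truth, int(rng_seed))


def plant_foreign_genomes(donor_consensus: SequenceRecord, recipients: int,
                          identity_levels: Sequence[float], syntenic: Sequence[bool],
                          rng_seed: int = 0, contig_len: int = 30000) -> list[ForeignPlant]:
    """Foreign genomes for horizontal-transfer screening.

    Each recipient carries one copy of the donor consensus mutated to an
    exact identity level.  Syntenic copies sit mid-contig in a background
    shared with the donor-free reference genome; non-syntenic copies sit on a
    short orphan contig absent from the reference (a contamination mimic).
    """
    if len(identity_levels) != recipients or len(syntenic) != recipients:
        raise ValueError("identity_levels and syntenic must have length == recipients")
    rng = np.random.default_rng(rng_seed)
    donor = donor_consensus.residues.upper()
    out: list[ForeignPlant] = []
    for k in range(recipients):
        ident = float(identity_levels[k])
        if not 0.0 < ident <= 1.0:
            raise ValueError("identity levels must be in (0, 1]")
        n_mut = round((1.0 - ident) * len(donor))
        seq = np.frombuffer(donor.encode("ascii"), dtype=np.uint8).copy()
        if n_mut:
            pos = rng.choice(len(donor), size=n_mut, replace=False)
            codes = np.searchsorted(_BASES, seq[pos])
            seq[pos] = _BASES[(codes + rng.integers(1, 4, size=n_mut)) % 4]
        copy = seq.tobytes().decode("ascii")
        bg = _random_dna(rng, contig_len)
        gid = f"foreign{k}"
        if syntenic[k]:
            mid = contig_len // 2
            carrier = SequenceRecord(f"{gid}_chr", bg[:mid] + "TA" + copy + "TA" + bg[mid:])
            contigs = [carrier]
            interval = (carrier.id, mid + 2, mid + 2 + len(copy))
        else:
            orphan = SequenceRecord(f"{gid}_orphan",
                                    _random_dna(rng, 700) + copy + _random_dna(rng, 700))
            contigs = [SequenceRecord(f"{gid}_chr", bg), orphan]
            interval = (orphan.id, 700, 700 + len(copy))
        reference = [SequenceRecord(f"{gid}_chr", bg)]
        out.append(ForeignPlant(gid, contigs, reference, ident, bool(syntenic[k]), interval))
    return out


def default_mining_panel(rng_seed: int = 0) -> tuple[list[FamilySpec], list[SequenceRecord]]:
    """The standard mining test panel: eight mariner-style families spanning
    the study conditions — 8 to 200 copies per family, amplification ages up
    to 10% divergence across the four dynamics models, TA target sites —
    plus one related transposase query per family (a 5%-diverged sister
    protein, emulating a library of known transposases)."""
    rng = np.random.default_rng(rng_seed)
    layout = [  # (copies, model, duration in divergence units)
        (200, "E", 0.10), (100, "S", 0.06), (60, "L", 0.05), (45, "C", 0.08),
        (30, "E", 0.04), (20, "L", 0.05), (12, "S", 0.06), (8, "L", 0.03),
    ]
    subfamilies = ["irritans", "irritans", "mellifera", "mellifera",
                   "cecropia", "cecropia", "mauritiana", "mauritiana"]
    specs: list[FamilySpec] = []
    queries: list[SequenceRecord] = []
    for fi, (copies, model, T) in enumerate(layout):
        anc, tir, orf = make_ancestor(rng, f"fam{fi}", length=int(rng.integers(1285, 1345)))
        spec = FamilySpec(f"fam{fi}", subfamilies[fi], anc, tir, target_copies=copies,
                          dynamics_model=model, dynamics_params={"T": T},
                          orf_interval=orf)
        specs.append(spec)
        queries.append(family_query_protein(spec, rng))
    return specs, queries


def build_rearrangement_fixture(rng_seed: int = 0, n_clean: int = 100,
                                n_deleted: int = 15, n_full: int = 5,
                                background_len: int = 400_000) -> dict:
    """Genome of rearranged copies for breakpoint analysis.

    ``n_clean`` copies carry only the 5'-replaced-by-3' rearrangement with
    breakpoints uniform over 60 bp windows (a around 221, b = len - a) at
    <= 5% divergence; ``n_deleted`` copies additionally lose an internal
    100 bp block (must be flagged and excluded downstream); ``n_full``
    unrearranged copies are negative controls.  Returns the contigs, the
    full-length reference and the truth list of (a, b, extra_deletion).
    """
    rng = np.random.default_rng(rng_seed)
    anc, tir, orf = make_ancestor(rng, "ref", length=1319)
    L = len(anc.residues)
    inserts: list[tuple[str, tuple | None]] = []
    for _ in range(n_clean):
        a = int(rng.integers(191, 251))
        b = L - a
        copy = apply_rearrangement(mutate_copy(anc.residues, float(rng.uniform(0, 0.05)),
                                               1.0, rng), a, b)
        inserts.append((copy, (a, b, False)))
    for _ in range(n_deleted):
        a = int(rng.integers(191, 251))
        b = L - a
        copy = apply_rearrangement(mutate_copy(anc.residues, float(rng.uniform(0, 0.05)),
                                               1.0, rng), a, b)
        dstart = int(rng.integers(300, len(copy) - 400))
        copy = copy[:dstart] + copy[dstart + 100:]
        inserts.append((copy, (a, b, True)))
    for _ in range(n_full):
        inserts.append((mutate_copy(anc.residues, float(rng.uniform(0, 0.05)), 1.0, rng),
                        None))
    order = rng.permutation(len(inserts))
    bg = _random_dna(rng, background_len)
    spacing = background_len // (len(inserts) + 1)
    parts = []
    cursor = 0
    out_len = 0
    truth = []
    for k, oi in enumerate(order):
        copy, info = inserts[int(oi)]
        pos = (k + 1) * spacing
        parts.append(bg[cursor:pos])
        out_len += pos - cursor
        strand = "+" if rng.random() < 0.5 else "-"
        block = "TA" + (copy if strand == "+" else revcomp(copy)) + "TA"
        if info is not None:
            a, b, deleted = info
            truth.append({"a": a, "b": b, "extra_deletion": deleted,
                          "interval": (out_len + 2, out_len + 2 + len(copy))})
        parts.append(block)
        out_len += len(block)
        cursor = pos
    parts.append(bg[cursor:])
    contig = SequenceRecord("rcontig", "".join(parts))
    return {"contigs": [contig], "reference": anc, "truth": truth,
            "n_clean": n_clean, "n_deleted": n_deleted, "n_full": n_full}


def make_mite_ancestor(rng, name: str = "mite", length: int = 300,
                       tir: str | None = None, tir_len: int = 25) -> tuple[SequenceRecord, str]:
    """A miniature element: TIR + non-coding internal sequence + revcomp(TIR)."""
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    if tir is None:
        tir = _random_dna(rng, tir_len)
    internal = _random_dna(rng, length - 2 * len(tir))
    return SequenceRecord(name, tir + internal + revcomp(tir)), tir


def inject_tandem_decoys(genome: SyntheticGenome, count: int, rng_seed: int = 0,
                         unit_len: int = 60, n_units: int = 8,
                         palindrome_len: int = 13) -> list[tuple[str, int, int]]:
    """Overwrite TE-free background stretches with tandem repeat arrays whose
    unit contains a short internal inverted repeat — hard negatives for MITE
    discovery (they seed inverted matches but every candidate shares flanks
    within the array).  Returns the decoy intervals."""
    rng = np.random.default_rng(rng_seed)
    placed: list[tuple[str, int, int]] = []
    array_len = unit_len * n_units
    for _ in range(count):
        for _try in range(200):
            ci = int(rng.integers(0, len(genome.contigs)))
            contig = genome.contigs[ci]
            pos = int(rng.integers(1000, len(contig.residues) - array_len - 1000))
            clear = all(t.contig != contig.id
                        or pos - 2000 > t.interval[1] or pos + array_len + 2000 < t.interval[0]
                        for t in genome.truth)
            clear = clear and all(c != contig.id or pos - 2000 > e or pos + array_len + 2000 < s
                                  for c, s, e in placed)
            if clear:
                break
        else:
            raise ValueError("could not place decoy away from planted copies")
        p = _random_dna(rng, palindrome_len)
        unit = p + revcomp(p) + _random_dna(rng, unit_len - 2 * palindrome_len)
        contig.residues = (contig.residues[:pos] + unit * n_units
                           + contig.residues[pos + array_len:])
        placed.append((contig.id, pos, pos + array_len))
    return placed


def build_mite_fixture(rng_seed: int = 0, background_len: int = 400_000,
                       mite_copies: int = 150, small_copies: int = 9,
                       decoys: int = 3) -> dict:
    """The standard MITE-discovery test genome: one abundant 300 bp MITE
    family (25 bp TIRs, TA TSD), an autonomous > 1 kb partner sharing its
    TIRs, one family below the ten-copy floor, and tandem-repeat decoys.
    Returns a dict with the genome and the planted specs."""
    rng = np.random.default_rng(rng_seed)
    mite_anc, tir = make_mite_ancestor(rng, "mite_fam", length=300, tir_len=25)
    partner_anc, _, orf = make_ancestor(rng, "partner_fam", length=1310, tir=tir)
    small_anc, small_tir = make_mite_ancestor(rng, "small_fam", length=320, tir_len=22)
    specs = [
        FamilySpec("mite_fam", "mite", mite_anc, tir, target_copies=mite_copies,
                   dynamics_model="E", dynamics_params={"T": 0.03},
                   n_active_copies=0),
        FamilySpec("partner_fam", "mariner", partner_anc, tir, target_copies=2,
                   dynamics_model="L", dynamics_params={"T": 0.01},
                   orf_interval=orf),
        FamilySpec("small_fam", "mite", small_anc, small_tir, target_copies=small_copies,
                   dynamics_model="L", dynamics_params={"T": 0.01},
                   n_active_copies=0),
    ]
    genome = plant_genome(specs, background_len, contig_count=2,
                          rng_seed=int(rng.integers(0, 2**31)))
    decoy_intervals = inject_tandem_decoys(genome, decoys,
                                           rng_seed=int(rng.integers(0, 2**31)))
    return {"genome": genome, "specs": specs, "tir": tir,
            "decoys": decoy_intervals,
            "partner_truth": [t for t in genome.truth if t.family == "partner_fam"],
            "mite_truth": [t for t in genome.truth if t.family == "mite_fam"]}


# ---------------------------------------------------------------------------
# Copy genealogies (for tree-based dynamics validation)
# ---------------------------------------------------------------------------


class _GenNode:
    __slots__ = ("label", "age", "children")

    def __init__(self, label: str, age: float, children=None):
        self.label = label
        self.age = age
        self.children = children or []

    def newick(self) -> str:
        if not self.children:
            return self.label
        inner = ",".join(f"{c.newick()}:{self.age - c.age:.6f}" for c in self.children)
        return f"({inner})"


def simulate_copy_genealogy(event_ages: Sequence[float], root_seq: str, rate: float,
                            rng) -> tuple[dict[str, str], str]:
    """Evolve sequences down an explicit transposition genealogy.

    Events (ages, divergence units before present) are processed oldest
    first; each event picks a uniformly random extant lineage as template and
    splits it.  All lineages keep accumulating substitutions to the present,
    so the genealogy is ultrametric with internal nodes at the event ages.
    Returns (leaf label -> sequence, newick of the true topology).
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    ages = sorted((float(a) for a in event_ages), reverse=True)
    if not ages:
        raise ValueError("need at least one event")
    counter = [0]

    def fresh() -> str:
        counter[0] += 1
        return f"copy{counter[0]:03d}"

    root_age = ages[0]
    # extant lineages: (sequence at `age`, age of last update, tip node)
    first = _GenNode(fresh(), 0.0)
    lineages: list[list] = [[root_seq, root_age, first]]
    root = first
    for a in ages:
        idx = int(rng.integers(0, len(lineages)))
        seq, since, tip = lineages[idx]
        seq = mutate_copy(seq, since - a, rate, rng)
        new_tip = _GenNode(fresh(), 0.0)
        internal = _GenNode("", a)
        # splice the internal node where the old tip hung
        internal.children = [_GenNode(tip.label, 0.0), new_tip]
        tip.label, tip.age, tip.children = "", a, internal.children
        lineages[idx] = [seq, a, tip.children[0]]
        lineages.append([seq, a, new_tip])
    leaves: dict[str, str] = {}
    for seq, since, tip in lineages:
        leaves[tip.label] = mutate_copy(seq, since, rate, rng)
    return leaves, root.newick() + ";"


# ---------------------------------------------------------------------------
# Truth ledger I/O and evaluation helpers
# ---------------------------------------------------------------------------


def write_truth_json(genome: SyntheticGenome, path: str | Path) -> None:
    payload = {
        "seed": genome.seed,
        "contigs": {c.id: len(c.residues) for c in genome.contigs},
        "copies": [t.__dict__ | {"interval": list(t.interval),
                                 "breakpoints": list(t.breakpoints) if t.breakpoints else None,
                                 "deletion_intervals": [list(d) for d in t.deletion_intervals]}
                   for t in genome.truth],
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def write_truth_tsv(genome: SyntheticGenome, path: str | Path) -> None:
    cols = ["contig", "start", "end", "strand", "family", "copy_id", "age",
            "independent", "has_n", "assembly_truncated", "rearranged"]
    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for t in genome.truth:
            fh.write("\t".join(map(str, [
                t.contig, t.interval[0], t.interval[1], t.strand, t.family,
                t.copy_id, f"{t.age:.5f}", int(t.independent), int(t.has_n),
                int(t.assembly_truncated), int(t.rearranged)])) + "\n")


def match_to_truth(found: Iterable[tuple[str, int, int]], truth: Sequence[TruthRecord],
                   min_overlap: float = 0.5) -> list[int | None]:
    """Greedy interval matching of found copies to truth records.  Returns,
    per found copy, the index of the truth record covering >= ``min_overlap``
    of the shorter interval (or None)."""
    out: list[int | None] = []
    for contig, start, end in found:
        best, best_ov = None, 0.0
        for ti, t in enumerate(truth):
            if t.contig != contig:
                continue
            ov = min(end, t.interval[1]) - max(start, t.interval[0])
            denom = min(end - start, t.interval[1] - t.interval[0])
            if denom > 0 and ov / denom > best_ov:
                best, best_ov = ti, ov / denom
        out.append(best if best_ov >= min_overlap else None)
    return out
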