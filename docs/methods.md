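# Methods

`mobilome` annotates Tc1-mariner transposons and their non-autonomous
derivatives (MITEs) in genome assemblies, reconstructs the amplification
history of each lineage, and screens for horizontal transfer.  Because the
interesting quantitative claims (copy recall, boundary accuracy, clean-copy
accounting, dynamics classification) can only be judged against a known
answer, the package ships a first-class simulator that plants TE families
with full ground truth; every pipeline stage is validated against that
truth and against exhaustive dynamic-programming oracles.

## Search primitives

Nucleotide and translated searches are deterministic seed-and-extend local
aligners (in-package stand-ins for BLASTN/TBLASTN):

* exact word seeds — 11-mers for DNA, 4-mer amino acids for translated
  search over all six reading frames;
* seeds are grouped into diagonal bands; each group must survive an
  ungapped x-drop extension (BLOSUM62 for protein, +2/−3 for DNA) before a
  full affine-gap local DP (`Bio.Align.PairwiseAligner`; gap open/extend
  −11/−1 protein, −5/−2 DNA) is run on a subject window around the group;
* default raw-score thresholds: 100 (translated; any 50-aa exact match
  passes, since the BLOSUM62 diagonal is ≥ 4) and 60 (nucleotide; ≈ 30
  matching bases, below which local hits in random sequence are common).
* `N` never matches anything, including itself; identity is defined as
  matches / aligned columns with gap columns in the denominator — this
  definition is what makes the 0.80 clustering and 0.75 HT thresholds
  meaningful.

Coordinates are 0-based half-open internally; minus-strand hits are stored
on plus-strand subject coordinates with a strand flag.  On all fixtures the
searches reproduce the scores and intervals of exhaustive affine-gap
Smith–Waterman oracles (see `tests/test_seqcore.py` and the acceptance
suite); deletions inside copies do not need to be bridged by the aligner
because co-linear hits are chained downstream.

## Variable-metric alignment

`align_pair_vm(a, b, w)` is an exact global DP minimising
`mismatches + w × gap_columns`, normalised by aligned columns.  At `w = 1` a
gap column costs exactly like a mismatch (the "fifth nucleotide" regime);
at `w = 0` gap columns are free.  Among equal-cost alignments the shortest
(fewest columns) is canonical, enforced by an infinitesimal per-column
charge (1e-8, far below any real cost step); this makes the normalised
distance well defined and symmetric.  The optimal normalised distance need
not be monotone in `w` (the minimising alignment changes); monotonicity
holds for any fixed alignment, and that is the property tested.

## Simulator

The generator's defaults are the study conditions, not tuning knobs:

* **Families.** A mariner-style ancestor is TIR + 5' UTR + transposase ORF
  (> 1000 bp, stop-free) + 3' UTR + revcomp(TIR), 1285–1345 bp total with
  22–35 bp TIRs; MITE ancestors are TIR + non-coding internal sequence
  (≈ 300 bp).  Every insertion duplicates its target site — the literal
  "TA" for mariner-style families, a random k-mer of configurable length
  for other superfamilies (hAT-style 8-mers).
* **Ages and divergence.** Copy ages are drawn from one of four
  amplification-dynamics models over a duration `T` in divergence units:
  `E` truncated-exponential toward the present (default rate 6/T), `L`
  uniform, `C` the mirror of E, `S` truncated-logistic around T/2 with
  scale T/10.  The rate 6/T makes the early-half event fraction ≈ 0.05
  (clearly shifted), and scale T/10 keeps the S-curve's deviation from the
  diagonal ≈ 0.17 at the quartiles, comfortably above sampling noise at
  n = 200 events; both are operational definitions, the source protocol
  publishes none.  Divergence follows a single global clock: a copy of age
  `a` receives i.i.d. substitutions with the Jukes-Cantor transition
  probability at branch length `rate × a` (substitutions only; deletions
  and rearrangements are explicit structured events).
* **Structured events.**  Internal deletions remove 100–400 bp; the
  5'-replaced-by-3' rearrangement builds
  `revcomp(copy[b:]) + copy[a:]` — the two ends of the product are long
  inverted copies of the same 3' block, so the product hits the intact
  element on both strands; N-runs are written either into the copy or into
  its flank (assembly-gap mimics); segmental duplications copy an insertion
  together with 550 bp of both flanks and mark the twin non-independent;
  nested insertions place one element inside another.
* **Placement.**  Background is i.i.d. uniform ACGT.  Insertion sites come
  from a shuffled grid with ≥ 1.3 kb spacing, which keeps each copy's
  500 bp flanks private — that separation is what makes flank-based
  segmental-duplication detection a clean signal.  Tandem-repeat decoys
  (direct arrays whose unit contains a short internal inverted repeat) can
  be injected as hard negatives for MITE discovery.
* **Genealogies.**  For tree-based validation an explicit transposition
  genealogy is simulated (each event copies a uniformly chosen extant
  lineage; all lineages keep evolving to the present), giving an
  ultrametric true tree with internal nodes at the event ages.

What the simulator does **not** emulate: indel point mutations, nucleotide
composition bias, low-complexity and satellite background, nested TE
landscapes of real genomes, or assembly collapse of near-identical copies.
Passing tests therefore demonstrate correctness of the pipeline's logic
under its stated model, not performance on real assemblies.

## Mining (library-based)

Hits of each transposase query are chained when co-linear, on one strand,
and closer than 1 kb; the chain partition is the minimum one (bipartite
matching), so each hit belongs to exactly one copy candidate and the number
of candidates is minimal.  Candidates shorter than 400 bp are discarded;
survivors are extracted with up to 500 bp flanks, minus-strand copies
reverse-complement-normalised.  Copies are clustered greedily (length
sorted, first centroid at ≥ 80% identity, both orientations) — the stated
reading of the classic Usearch call, bounded against a single-linkage
oracle in tests.

Because translated hits cover only the transposase region, full element
boundaries are recovered on the cluster alignment: element columns stay
conserved across members while true flanks are unrelated background
(≥ 0.85 versus ≈ 0.6 column agreement — random flanks projected through a
center-star alignment agree more often than naive intuition suggests,
because unit-cost edit paths between unrelated sequences still match ≈ 60%
of columns).  The approximate conserved block is then refined to the base
by maximising the target-site-duplication vote (identical dinucleotides
immediately outside both boundaries across members) plus a terminal
inverted-repeat bonus.  Two systematic traps and their resolutions:

* a symmetric inset landing on a self-complementary dinucleotide inside the
  TIR votes exactly as well as the true boundary — near-maximal vote counts
  (within max(2, members/10)) are treated as ties and resolved toward the
  longest element, the same convention the consensus uses;
* the immediate outside of a spurious boundary is still conserved element
  sequence, so candidates whose beyond-TSD columns stay above 0.75
  agreement are disqualified.

Cleaning excludes copies containing N and assembly-truncated copies
(flank shortened by a contig edge or an N-run of ≥ 5), and collapses
members whose **both** flanks match another member's at ≥ 90% identity —
segmental duplications, which do not represent transposition.  The
consensus is per-column majority with ties toward bases over gaps ("keeping
the longest elements") and A < C < G < T among bases; the lineage TSD is
the majority duplicated dinucleotide, the TIR the longest terminal inverted
match under a 20% mismatch tolerance (score-based end selection, so random
sequence beyond the true TIR cannot stretch it), and a lineage is
potentially active when at least one clean member carries an uninterrupted
ATG-initiated ORF longer than 1 kb.  Lineages with fewer than 5 clean
independent copies are logged and discarded.  "Deleted" status marks
consensuses shorter than 80% of the longest consensus among same-subfamily
lineages; "rearranged" marks TIRs ≥ 80 bp (the signature of 5'→3'
replacement).  Cluster alignment is an in-package center-star projection
(edlib global alignments onto the longest member) — exact for
substitution-and-deletion divergence, which is the simulator's regime, and
fully deterministic.

## MITE discovery

Inverted exact matches ≥ 11 bp at most 750 bp apart seed candidates; maximal
extension systematically overshoots the element because the TA duplication
itself continues the inverted match, so candidates are pulled back to the
smallest symmetric trim exposing a duplicated flanking k-mer (k = 8 down
to 2).  Candidates cluster as in mining; same-locus duplicates and
segmental copies are removed by the flank rule scaled to the 60 bp windows.
Clusters survive only with ≥ 10 independent copies, mean pairwise identity
≥ 0.70 (the protocol's unquantified "certain level of homogeneity"), and a
bona fide terminal inverted repeat (≥ 11 bp, ≤ 2 mismatches).  The cluster
TSD is the majority duplicated k-mer; when only the *length* of the
duplication is shared (hAT-style random target sites) the TSD is reported
as `N×k`, and mariner compatibility requires the literal "TA".  Sublineages
are connected components at ≥ 95% identity and ≤ 5% length spread.  The
partner search finds loci > 1 kb (≤ 8 kb) where both TIRs occur in inverted
orientation (≤ 2 mismatches each) without overlapping any cluster
candidate, preferring the shortest qualifying span — an autonomous element,
not a chance pairing of distant TIR occurrences.  Superfamily assignment
searches the partner and the consensus against a labelled protein library;
consensus hits confined to regions carried by fewer than half of the
members are ignored (nested-insertion guard).

## UPGM-VM classification

Ascending hierarchical classification with no arithmetic mean:
cluster-to-cluster distance is the minimum pairwise variable-metric
alignment distance, recomputed each round at the current gap weight.  The
schedule is `w = 2^-k` with `k = floor(6 · merges_done / (n − 1))`, clamped
to 0 from `k = 6` — weight 1 ("fifth nucleotide") for the first sixth of
the ascent, then a rapid decay that lets internally deleted derivatives
join their full-length parents before unrelated elements.  Ties break
lexicographically by leaf id, so the dendrogram is input-order invariant.
Merge heights are recorded as computed; they are **not** monotone (the
metric changes between rounds), which is why partitions are read off merge
order rather than by cutting at a height gap.  Subfamily assignment uses
the mean `w = 1` distance to each labelled reference group (edlib edit
distance over alignment columns — within ≈ 3% of the canonical
variable-metric value, a negligible difference against the ≥ 20-point
margins between groups), with a novelty threshold of 0.45: between-subfamily
mariner distances exceed this while evolved members of a known subfamily
stay well below.

## Amplification dynamics

Copy trees are UPGMA on Jukes-Cantor-corrected pairwise distances (clock
reading: node age = half the corrected distance at the merge); lineages
above 500 copies are subsampled with a fixed seed.  Each internal node is
one duplicative transposition event; the LTT curve is the cumulative event
count against age.  The summary reports the time span, the age at which
half of the events have accumulated, and activity (an event within 0.5%
divergence of the present).  Shape classification normalises ages and
counts to [0, 1] and compares the curve with the constant-rate diagonal:

* `L` when the sup-norm deviation stays below the 5% Kolmogorov–Smirnov
  critical value `1.358/√n`.  An n-adaptive bound is used deliberately: a
  fixed sup-norm cutoff of 0.08 would misclassify a genuinely uniform
  200-event history about 15% of the time (closed-form KS distribution),
  which no fixed constant fixes across n;
* otherwise the early-half event fraction decides: < 0.35 → `E` (median
  shifted recent), > 0.65 → `C` (median shifted ancient), else `S`;
* fewer than 10 events → "undetermined".

Generator-recovery tests (50 replicates × 4 models × 200 events) recover
each class in well over 80% of replicates and the median event age within
15% of the closed-form truth.

## Horizontal-transfer screening

A lineage consensus is searched against each foreign genome; co-linear hits
are chained into loci, scored by merged query coverage (old copies
fragment — the 90% rule concerns the query overall, not one HSP) and
column-weighted identity.  A candidate needs identity > 0.75, coverage
> 0.90, and a conserved synteny context: the windows flanking the locus
(5 kb at desk scale; the rule is structural, not scale-dependent) must
match the same donor-free reference contig in conserved orientation and
order, inspected through 500 bp probes.  Loci too close to a contig edge
fail with reason "edge" — which is exactly how short orphan-contig
contamination is rejected.

Rearranged copies are detected as loci with exactly one plus- and one
minus-strand hit of the full-length reference that tile the copy with
junction gap ≤ 10 bp and both blocks reaching the reference 3' end; the two
hit starts in reference coordinates are the breakpoints.  Copies violating
the tiling (junction gaps, missing ends, length deficit > 30 bp) are
flagged as carrying additional deletions and excluded from the clean set.
The profile reports breakpoint histograms, the copy-size distribution, the
A-versus-B scatter and the fraction of copies below a configurable size
line (default 938 bp).

Masking searches every library consensus on both strands, resolves
overlaps by best score globally (so the report is library-order invariant),
merges per superfamily and reports masked base pairs and genome fractions.

## Problem sizes and determinism

The standard validation genome is 2 Mb with eight families of 8–200 copies
(≈ 480 copies, ≈ 30% at ≤ 10% divergence), which exercises every cleaning
rule while keeping a full pipeline run around half a minute; MITE and
breakpoint fixtures use 0.4–0.9 Mb.  All randomness flows through
`numpy.random.default_rng` seeds; identical seeds give byte-identical
genomes, ledgers and pipeline outputs, and copy counts are invariant to
contig order and to global reverse complementation.

## Known limitations

* Boundary refinement needs ≥ 3 cluster members; singleton copies keep
  homology-region coordinates and no TSD call.
* The center-star cluster alignment drops insertions relative to the
  longest member; with insertion-generating mutation processes a proper
  progressive MSA would be needed.
* The greedy centroid clustering can split a family whose copies straddle
  the 80% identity radius around the first (longest) centroid — the same
  behaviour as the tool it emulates; very old families may fragment.
* Exact published genome-scale numbers (total copy counts, masked
  megabases) are assembly- and library-dependent and are not reproduction
  targets; the acceptance metrics are recall/accuracy measures against
  simulated truth.
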