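# Methods

This note documents the models, parameter choices, and numerical conventions
behind `tmmotif`, and what the synthetic generators do and do not emulate.

## Structures and membrane regions

Chains are read from PDB text (Bio.PDB underneath, with an added
pre-validation pass so malformed ATOM records raise an error naming the
line).  Internally every residue has a 0-based `seq_index`; original PDB
residue numbers are metadata only, which keeps window arithmetic uniform.

Region labels come from one of two sources:

- an annotation table of intervals `(chain, start, end, label)` with labels
  from {Cytoplasmic, Extracellular, Helix core, Reentrant}.  *Interface* is
  never annotated — it is derived at the fragment level.  The two membrane
  sides are supplied explicitly by the caller (annotation databases usually
  record only "side 1 / side 2"; mapping them to cytoplasmic/extracellular
  requires external topology knowledge we do not guess at).
- a slab-geometry fallback: membrane normal along z, residues with CA
  |z| ≤ half-thickness (default 15 Å) are Helix core, the rest get the side
  labels; an in-slab run of ≥ 3 residues flanked by the same side label is
  relabeled Reentrant (the chain dipped into the bilayer without crossing).

Dataset filtering removes chains at resolution ≥ 3.5 Å, then reduces
redundancy by greedy incremental clustering at 90 % ungapped identity over
the shorter sequence, longest chain first; each cluster keeps its
best-resolution member.  The greedy order is a choice (the tie-break used by
external redundancy reducers is not documented anywhere); it is deterministic
and idempotent, and tests assert no two survivors reach the threshold.

## Fragments

Sliding windows of 3–14 residues.  Torsions are computed from backbone
dihedrals, in (−180, 180]; Φ is undefined at the chain start, Ψ at the end,
and both angles are undefined next to missing backbone atoms.  Fragments
with undefined torsions are kept for hydrogen-bond clustering but excluded
from torsion clustering — the two measures therefore see slightly different
fragment populations.

Hydrogen bonds are detected from heavy atoms only (no hydrogen placement):
donors are backbone N plus N/O-bearing side-chain atoms with polar
hydrogens, acceptors are backbone O plus side-chain O/N lone-pair carriers.
Criteria: donor–acceptor distance ≤ 3.6 Å (configurable up to 4.2 Å —
membrane hydrogen bonds are commonly counted out to ~4 Å) and, when the
donor's antecedent atom is present, antecedent–donor–acceptor angle ≥ 90°.
Main-chain/main-chain pairs between residues fewer than two positions apart
are excluded as covalent-geometry artifacts.  This detector is deliberately
permissive; on an ideal helix it reports the i→i+4 ladder plus some
i→i+2/i+3 contacts, which is acceptable because bonds act as shared/unshared
tokens in the similarity, not as an energy model.

A fragment's region label collapses its residues' labels with the
precedence: uniform label → itself; any Reentrant residue → Reentrant
(reentrant fragments are the scarcest class and must not be diluted);
Helix core mixed with an aqueous side → Interface; otherwise majority, ties
→ Interface.  A fragment mixing the two aqueous sides without core is
physically implausible and falls through to the majority rule.

## Distances and normalization

All three pairwise measures are min–max normalized over the full pair set
being clustered (one region × one window length × one measure — the unit at
which clustering happens).  Degenerate spread (all pairwise values equal) is
mapped to all-1 distances for the hydrogen-bond measure (shared-bond
similarity carries no information there) but to all-0 distances for the
torsion and sequence measures, where the degenerate case typically means
"all fragments identical" and all-1 would call identical fragments maximally
distant.

Torsion differences are circular (|Δ| folded into [0, 180]°); naive
differences would misrank fragments near ±180°.  Sequence distance is the
negative mean BLOSUM50 score (the matrix ships as an NCBI-format text file);
identical sequences attain the set minimum.  Mixed-class hydrogen bonds are
canonicalized so donor→acceptor order does not matter: S→M and M→S both
weigh w_SM.  Backbone RMSD uses a from-scratch Kabsch superposition
(SVD with determinant correction).

## Tree cuts

Average-linkage trees (scipy agglomeration; an independent O(n³)
agglomerator cross-checks it in the tests) are cut horizontally — one height
for the whole tree — so both cut objectives can be enumerated exhaustively
over the O(n) candidate heights, and the tests do exactly that.

**Structural cut.** J = (pooled mean intra-cluster pairwise RMSD)
− λ·(fraction of correctly positioned fragments), minimized over candidate
heights; ties prefer fewer clusters, then the lower cut.  "Correctly
positioned" means: the fragment is in a cluster of size ≥ 2, its RMSD to the
cluster medoid is ≤ 1.5 Å (configurable), and that medoid is the nearest of
all cluster medoids.  The last two conditions are essential, not cosmetic:
if singletons counted as positioned, the all-singleton partition would
always attain the unbeatable J = −λ; and without the nearest-medoid
condition any partition that splits true groups without creating singletons
would beat the true partition, because the RMSD term decreases monotonically
with finer cuts while the fraction term saturates.  λ defaults to 2 so that
a fully-positioned partition is preferred over an empty one by a wide margin
against RMSD values on the 0–2 Å scale of backbone fragments.

**Sequence cut.** Minimizes (#singleton clusters + #clusters of size < 5);
ties prefer *more* clusters, then the lower height.  The finer-tie rule
matters: the root cut trivially scores 0 on any tree of ≥ 5 leaves, and the
point of this cut is to isolate specific sequence families, so among
zero-cost cuts the finest is taken.

## Pattern induction

Fragments in a cluster are fixed-length windows, hence inherently aligned;
induction is positional (this replaces an unaligned-input pattern-discovery
tool with an identical contract).  Per-column residue sets are built from
the members; a column whose *full* observed set exceeds `max_set_size`
(default 4, keeping patterns in the conventional `[AS]`/`[FIV]` style)
becomes a wildcard permanently.  The remaining columns are then greedily
sharpened, dropping rarest residues first while the pattern still matches
the required fraction of members (80 % after structural clustering, 100 %
after the sequence fallback).  The result is `None` when only an
all-wildcard pattern remains.  The coverage contract is verified by actually
scanning the member sequences, and tests assert it on noisy families.

Scanning compiles the dialect to a Python regex with a look-ahead so
overlapping hits are reported, at most one per start position (greedy
longest span for variable-length patterns).  Occurrence counts N_M count
hits, not hit sequences; the hit-sequence id set is retained so either
statistic is available.

## Pattern comparison and novelty

Repetition ranges are expanded into fixed-length instances (Cartesian
product, smallest repetitions first, capped at 512 with an "approximate"
flag).  For each instance pair the shorter is slid along the longer;
the default requires the shorter to be fully contained (an optional
`min_overlap` relaxes this to scored partial overlaps).  Position pairs
score |s₁∩s₂|/(|s₁|·|s₂|); a segment scores the positional mean; the pattern
similarity is the maximum over offsets and instance pairs.  The novelty
cutoff defaults to 0.86.  A randomized null — symbol-order shuffles of the
library patterns — supports cutoff selection; the shuffle preserves each
pattern's symbol multiset so composition effects cancel.

## Statistics

The permutation null shuffles residues *within* each database sequence
(lengths and compositions preserved — the standard null for motif
occurrence), 100 times by default.  The reported p-value is the upper tail
of a normal fitted to the null counts (no continuity correction); the exact
empirical tail (add-one corrected) is reported alongside, since a normal
tail on 100 draws is an extrapolation.  The odds ratio divides N_M by the
null mean and is flagged undefined when that mean is zero.  Hypergeometric
tails (TM specificity, GO enrichment) use scipy's survival function and are
tested against exhaustive enumeration of all draws for small universes.
The Bonferroni divisor for GO defaults to the number of distinct terms in
the supplied annotation table; the reference count 24 287 can be passed to
reproduce the conventional threshold.  GO coverage is k/n (carriers
annotated with the term over all carriers).

The transmembrane classifier counts distinct motifs with false positive
rate < 40 % hitting a sequence and calls TM strictly above 5; it never
asserts "globular" — library coverage is too sparse for a negative call,
so the alternative outcome is an abstention.

## Synthetic world

The generators state one fixed world; none of their defaults were chosen by
looking at test outcomes.  Helical chains are grown from ideal bond
lengths/angles with caller-supplied torsions (so the noise-free helix
reproduces Φ = −57°, Ψ = −47° exactly and exhibits the i→i+4 bond ladder),
with Gaussian torsion noise (default sd 3°) and a 20 % chance of a
4-residue extended-torsion irregularity per chain.  Sequence databases
default to 60 TM + 60 globular sequences of 80–160 residues drawn from a
hydrophobic-enriched composition (a uniform alternative is available),
with motifs planted at 30 % of TM and 0 % of globular sequences — the
operating point at which the significance/specificity machinery is
expected to have full power — and a GO term attached to 90 % of carriers
vs 5 % background.  The structure fixture plants one heptad verbatim at the
core of five 36-residue membrane-spanning helices.

What the generators do **not** emulate: real side-chain rotamers (side
chains exist only as idealized CB; side-chain hydrogen-bond tests construct
coordinates explicitly), experimental coordinate error, homology structure
between database sequences, GO-hierarchy structure, and the size of real
sequence databases.  A green test therefore establishes formula and
algorithm correctness and power at the stated operating point — not
headline counts on the historical data, which depended on database
snapshots that no longer exist at that state.

## Known limitations

- Horizontal cuts cannot express per-branch cut heights; gnarled trees may
  admit better non-horizontal partitions.
- The normal-tail permutation p-value is anti-conservative in the extreme
  tail; use the empirical p when 1/(n_perm+1) resolution suffices.
- Instance expansion of patterns with many wide repetition ranges is capped;
  comparisons involving the cap are flagged approximate rather than exact.
- The hydrogen-bond detector trades physical strictness for parameter
  transparency; do not interpret its output as an energy-ranked bond list.
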