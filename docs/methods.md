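# Methods

This note records the models, parameter choices and numerical conventions
behind `levitax`, and what the synthetic benchmarks do and do not establish.

## ORF annotation

Maximal start→stop ORFs are called in all six frames (reverse strand
optional but on by default, since metagenomic contigs arrive in either
orientation), under genetic code 11. Start codons default to {ATG, GTG,
TTG} because leviviricete genes use alternative starts; the minimum ORF
length is a parameter (default 30 aa — short enough to keep every plausible
CP). Within one frame an ORF opens at the first start codon after the
previous stop, so no reported ORF nests inside a longer same-frame ORF;
overlapping ORFs in different frames are retained (the MS2 lysis gene
overlaps CP and replicase). ORFs running off the contig end without an
in-frame stop are reported with a `runoff` flag — the downstream length
filters (MP ≥ 350 aa, RdRP ≥ 500 aa, both inclusive) already guard
completeness. Internally all coordinates are 0-based half-open on the
forward strand; GFF3 output is 1-based inclusive.

## Profile HMMs

Profiles are Plan7-style: M match nodes with 20-letter emissions, insert and
delete states, begin/end. The exact generative model is

    B → M1 | D1;   Mk → M(k+1) | Ik | D(k+1);   Ik → M(k+1) | Ik;
    Dk → M(k+1) | D(k+1);   M_M → E and D_M → E with probability 1,

scored as log2-odds against fixed Robinson–Robinson background frequencies.
Alignment is local in the sequence (unmatched query prefix/suffix residues
contribute zero) and global in the model. `X` emits exactly the background
(zero log-odds). There is no null2 bias correction and no E-value
calibration: acceptance is a per-profile bit-score threshold, default
25 bits. With the profile sizes in play (130–540 match states) true family
members score hundreds of bits and unrelated sequences score at or below
zero, so the threshold is not delicate; it is configurable per profile for
borderline real-data libraries.

Profile estimation: a column becomes a match state when ≥ 50 % of rows are
non-gap (`match_fraction`, the standard heuristic). Match emissions are
(counts + w·background) normalized with pseudocount weight w = 1; insert
emissions are the background itself; transitions are counted from per-row
state walks and Laplace-smoothed with the same w. Sequence weights are
uniform (tree weighting is an extension point). Insert residues before the
first or after the last match column count as flanking sequence. The I→D
and D→I moves that a raw gap pattern can imply are not Plan7 moves; they are
folded into I→M and treated as flanking, respectively — with pre-clustered,
mostly gapless training families this affects only smoothing-scale mass.

Viterbi and forward are exact dynamic programs over this model (verified
against exhaustive path enumeration for all small profiles in the test
suite); forward sums over all paths *and* all free prefix/suffix
placements, which is also what the enumeration oracle counts. Profiles
serialize to HMMER3/f ASCII (−ln probability, `*` for zero); files written
here are parseable by HMMER's own reader (checked via pyhmmer), and
hmmbuild-produced files are readable, with their extra annotation columns
and header lines ignored.

## Pairwise alignment and PAAI

Global alignment is Needleman–Wunsch with affine gaps, BLOSUM62, gap open
11 / extend 1 (a gap of length k costs 11 + k, matching BLAST's protein
defaults). Ties break deterministically: residue pair over gap-in-a over
gap-in-b. PAAI is 100 × identical columns / aligned columns, where aligned
columns are those between the first and last residue–residue pair — terminal
gap overhangs are excluded so truncated contig ends are not penalized. This
denominator choice matters near the 50/80 thresholds and is therefore
stated prominently: a sequence that is a perfect substring of another has
PAAI 100 under this rule. The similarity graphs for clustering use
Smith–Waterman local scores in bits (BLOSUM62 is in half-bit units, so the
raw optimum is halved), with edges below 30 bits dropped as noise.

Both DP kernels are compiled (numba) with two-row score recurrences and
packed traceback pointers; scores are exact sums of integer substitution
scores and integer gap costs, so the compiled and reference implementations
agree bit-for-bit (cross-checked against Bio.Align.PairwiseAligner in the
tests).

## Protein clustering (MCL)

All-vs-all local-alignment scores (symmetric, so one direction is computed)
form the graph; Markov clustering iterates expansion (matrix square) and
inflation (elementwise power, column renormalization, pruning of entries
< 1e-5) on the column-stochastic matrix with unit self-loops, until the
largest column change falls below 1e-6 or 100 iterations. Clusters are the
connected components of the attractor support. Defaults: inflation 2.0.
Plain MCL is used rather than a full orthology pipeline — the inputs are one
pooled protein set, so inter-species normalizations have nothing to act on.
Cluster labels come from anchor sequences when provided (e.g. known CP_A
members); otherwise clusters get deterministic `novel_<role>_<k>` names.

## Genus/species demarcation

Genera are connected components of the RdRP PAAI graph thresholded at
≥ 50 %; species are components at ≥ 80 % computed *within* each genus.
Single-linkage is the one clustering rule under which "PAAI ≥ cutoff" is
itself the demarcation criterion, and it guarantees that species nest inside
genera for any matrix (property-tested on random matrices). Thresholds are
inclusive. Exemplars per cluster follow the priority ladder ICTV-archived >
GenBank-deposited > longest contig, ties by contig length then id.

## Phylogeny

Trees are Saitou–Nei neighbor joining on d = 1 − PAAI/100, a deterministic
distance-based stand-in for likelihood phylogenetics: exact on additive
matrices (property-tested over random trees of 4–12 taxa at 1e-9), with
lexicographic tie-breaking on equal Q and negative branch estimates clamped
to zero with the deficit moved to the sibling. Clade concordance tests each
label's leaves against the tree's bipartitions (so it is re-rooting
invariant); for a non-monophyletic label the minimal leaf-removal set is
found by exhaustive search over increasing subset sizes (intruder leaves
tried first, exact for labels of ≤ 20 leaves and pools of ≤ 16 candidates)
and greedily beyond. The disagreement count is the number of distinct
leaves across all removal sets.

## End-to-end classification

Per genome: ORF calling → profile scan → for each role (MP/CP/RdRP) the
highest-scoring passing ORF wins (ties by longer ORF, then smaller start) →
completeness filter → order from the RdRP cluster → family from the CP
cluster with the incongruence rule (mismatched parent order blanks both
order and family) → genus/species adoption against a demarcated reference:
the query joins the genus of its best reference match at ≥ 50 % PAAI, then
the species of its best within-genus match at ≥ 80 %, founding
deterministically-named novel taxa otherwise. Incongruent genomes keep
their genus/species — the demarcation runs off the RdRP whenever one was
confidently found on a complete genome, mirroring how order/family-
unassigned viruses still hold genus and species ranks. Order and family are
reported (flagged) for incomplete genomes so partial evidence is surfaced,
but such genomes never enter genus/species demarcation. The whole chain is
deterministic: identical inputs give byte-identical output tables.

## Synthetic data generator

The generator emulates the structure of a leviviricete reference corpus:
every genome is MP (400 aa) – CP (130 aa) – RdRP (540 aa) with short random
spacers, satisfying the completeness filter by construction. Protein
families evolve star-wise from random ancestors with per-branch substitution
rates chosen so *pairwise* identities hit the planted ladder: ~40 % between
genus ancestors within a family, ~70 % between species ancestors within a
genus, ~90 % between members of a species (each branch mutates at
1 − √(target/100)). The ladder brackets the 50/80 thresholds with ≥ 10-point
margins so recovery tests are not flaky; realized RdRP identities are
asserted against those margins at generation time and the dataset is
regenerated from a derived seed (at most 5 attempts) on violation.
Substitutions are BLOSUM62-weighted replacement draws; default generation
uses no indels, which keeps per-cluster training "alignments" trivially
column-aligned. Back-translation uses uniformly random synonymous codons of
genetic code 11 (no codon-usage model — downstream stages are
protein-level). Two deliberate constructions make ORF calling exact: the
initiator methionine is never mutated, and an in-frame stop codon directly
precedes each CDS, so the called ORFs coincide with the planted proteins.
MP and RdRP clusters span an order (family-level ancestors diverge at 60 %
inside them), CP clusters coincide with families, matching how the real
clusters map onto ranks.

What this does *not* emulate: insertions/deletions between relatives,
codon-usage and RNA-structure constraints, fragmented or chimeric contigs,
and sequencing error. Perfect recovery on synthetic corpora therefore
demonstrates the correctness of the decision logic and the stability of the
thresholds under the stated margins — not expected accuracy on real
metatranscriptomic data, where cluster counts and borderline memberships
depend on alignment parameters the original analysis did not publish.

## Problem sizes and determinism

The benchmark corpus is 2 orders × 3 families × 4 genera × 3 species ×
2 members = 144 genomes (≈ 3.3 kb each), classified end to end in about a
minute per seed on one CPU; the recovery test repeats this over 5 seeds.
All randomness flows through explicit seeds; hypothesis-based property
tests run derandomized. Known limitations beyond the generator's scope:
the star-anchored multiple alignment used by `build-hmms` on raw protein
sets is a simplification of progressive alignment (adequate for
pre-clustered families, not for deeply diverged ones); bit-score thresholds
substitute for the unpublished acceptance criteria of the original HMM
screening; and MP clusters carry no taxonomic rank, so they contribute only
to role detection and completeness.
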