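# Methods

This note records the models, parameter choices, numerical conventions and
known limitations behind `paleomt`.

## Damage model and the consistency predicate

Post-mortem cytosine deamination is modelled as a per-base Bernoulli event
on the molecule strand with probability

p(i) = δ · exp(−λ·i) + c

at distance *i* (0-based) from the relevant terminus: C→T from the 5′ end
and, in the default double-stranded library model, G→A from the 3′ end (a
single-stranded mode puts C→T at both ends instead). Defaults δ = 0.3,
λ = 0.3, c = 0.01 describe a well-damaged Pleistocene bone library;
δ is the terminal amplitude (probability at the very first base), λ the
per-base decay into the fragment, and c a position-independent baseline.

The caller's predicate `is_damage_consistent` is deliberately binary: an
observation is discounted iff it matches the deamination pattern within a
window of *d* bases from the terminus (default *d* = 5, where the
single-stranded overhangs concentrate the lesions). Distances are always
measured in the molecule's own orientation — for a reverse-strand read the
5′ terminus sits at the highest reference coordinate, and the reference
and observed bases are complemented before the test. No probabilistic
rescaling of base qualities is attempted; that is declared out of scope.

Profiling (`compute_damage_profile`) uses a window of 25 positions per
terminus, the conventional width for terminal-misincorporation plots.
Positions whose reference base is not an unmasked A/C/G/T are excluded
from denominators. The package reports profiles and fitted parameters; it
deliberately does not decide "authentic vs contaminated" — no published
threshold exists, so that judgement is left to the user.

## Consensus calling

Each reference position is called independently from its adjusted counts:
depth below `c_min` (default 5) masks the position as `LOW_COV`; a winning
allele below `f_min` (default 0.75) masks as `LOW_FREQ`; an exact count
tie between distinct bases masks as `LOW_FREQ` (there is no principled way
to pick a winner); zero depth is `NO_DATA`. Both thresholds are
*inclusive*: "minimum coverage 5" and "minimal frequency 75%" name
accepted boundaries, so depth 5 and frequency 0.75 are called. With
`d = 0` the caller reduces exactly to a plain coverage/frequency caller.

"Coverage of the miscoding base is artificially reduced" is
operationalised per read: each damage-consistent observation is removed
both from its allele's count and from the position's depth, preserving
`adjusted depth + removed = raw depth` at every column. This is the only
reading computable from the stated inputs that keeps the two thresholds
meaningful.

Indels come from a VCF (they carry no terminus information, so no damage
adjustment); an event is applied iff its supporting depth ≥ `c_min` and
its allele fraction ≥ `f_min`. Deletions shorten the consensus and emit
`INDEL_DEL` CCF rows; insertions anchor at the preceding position as
`INDEL_INS` rows. Overlapping accepted events are an error rather than a
silent priority rule. Two input modes exist: reads mode (canonical;
alignment + reference, VCFs as optional site restriction) and a VCF-only
mode in which, lacking terminus distances, damage handling degrades to
*flagging* reference-C/alt-T and reference-G/alt-A sites when a damage
profile is supplied — an approximation, clearly surfaced as a flagged-site
set rather than an adjustment.

`completeness` is the fraction of non-N positions before indel editing;
`nucleotide support` — needed by the strict QC category but nowhere given
a published definition — is interpreted as the fraction of called
positions whose winning-allele frequency is ≥ 0.90, and is documented as
an interpretation. Similarly, whether published capture-efficiency ranges
are post/pre ratios or simply post-capture percentages is ambiguous in
print, so `screening_stats` reports both numbers and their ratio.

## Parsimony and homoplasy counting

The small-parsimony step is exact unit-cost dynamic programming over
{A,C,G,T} (Sankoff's algorithm with a unit cost matrix; equivalently
Hartigan's generalisation of Fitch). It is exact on multifurcating trees,
which matters because the three-clade ingroup is modelled as a
trifurcation — on a strictly binary ingroup, identical mutations on two
*sister* stems are mathematically indistinguishable from one inherited
mutation, so pairwise homoplasy counting is only well-posed when no clade
pair is forced into sisterhood. N and `-` are missing data: such leaves
constrain nothing and never add cost.

Top-down resolution prefers the parent's state whenever it is among the
optimal states; root ties are broken toward the outgroup's observed state;
any remaining choice is arbitrary, flagged ambiguous, and excluded from
derived counting. Columns with more than 50% missing leaves are excluded
from counts (and reported via the assignment's `countable` mask) to avoid
artefactual derived calls.

Definitions: with the tree rooted on the outgroup, the *ingroup root* is
the MRCA of all non-outgroup leaves. A column is **derived** for clade X
iff the state at MRCA(X) is unambiguous and differs from the unambiguous
ingroup-root state. It is **shared derived** for clades A and B iff both
derived states agree and that state is *not* present at MRCA(A∪B) —
presence there means the allele was inherited from a common stem rather
than acquired twice. Shared counts are symmetric and bounded by
min(|derived(A)|, |derived(B)|) by construction.

Coding effects reconstruct the codon containing a column from the
ingroup-root states, substitute the derived state, complement for
reverse-strand genes, and translate with the annotation's genetic code
(NCBI table 2, vertebrate mitochondrial, by default); codons touching
missing or ambiguous states return `unresolved`. D-loop trimming removes
the alignment columns aligned to a reference interval (default
15422–16770, the hypervariable control region, which mixed reconstruction
protocols make unalignable); columns that are insertions relative to the
reference are removed when strictly inside the interval.

Production tree inference is an input, not a responsibility of this
package: the `nj_tree` helper (neighbour joining on uncorrected
p-distances, label-sorted for determinism, via scikit-bio) exists only to
build test-scale trees.

## Simulator

`simulate_clade_dataset` generates an ancestral random genome (default
16 kb, the mitogenome scale), three clades of ladder topology hanging from
a trifurcating ingroup root plus one outgroup leaf, and places mutations
under infinite sites (every mutation in its own column, recorded in the
ground truth):

- per-clade **total** derived budgets, default {I: 65, II: 70, III: 50} —
  shared columns count inside both members' totals, so the private stem
  mutations are 24/19/6;
- pairwise homoplasies, default {II–I: 24, II–III: 27, I–III: 17}: one
  column mutated to the *same* state independently on two clade stems;
- 5 private mutations per non-founder leaf and 400 outgroup-branch
  mutations (roughly the few-percent divergence expected of a congeneric
  outgroup at this genome size).

Under these conditions the counting operations must recover the injected
numbers exactly, for every seed, and the tests assert exactly that.

`simulate_reads` draws lognormal fragment lengths (mean 75 bp, sd 15 bp,
minimum 30 bp — matching per-sample mean fragment lengths of 68–90 bp in
well-preserved Late Pleistocene bone), uniform strands, and start
positions that are *marginally* uniform but stratified by default (an
evenly spaced grid with random jitter). Two deliberate idealisations:

1. **Circularity.** Mitogenomes are circular, so fragments may wrap the
   origin; wrapped fragments are emitted as two SAM records sharing a read
   id, with hard-clip CIGARs preserving each base's distance to the true
   molecule termini.
2. **Stratified starts.** With independent uniform starts, depth is
   Poisson-distributed and a 16 kb genome at 20× is expected to contain a
   sub-threshold position every few runs, making "exact recovery at 20×"
   a property of the sampler's tail rather than of the caller.  Local
   coverage fluctuation is not what these simulations study, so starts
   are evened out by default; `start_mode="iid"` restores independent
   starts for experiments where the fluctuation itself matters.

Damage is applied per molecule, in molecule orientation, *before*
sequencing error (uniform per-base miscall, default 10⁻³), matching the
biochemistry: deamination happens to the template, sequencing error to
the readout. Reads are emitted as perfectly mapped alignments so that
calling is isolated from mapping; alignment, adapter trimming and
duplicate removal are upstream concerns. Identical config and seed give
byte-identical FASTA/SAM output.

What the simulator does **not** emulate: contamination mixtures, indel
evolution, rate heterogeneity along the genome, selection, reference
bias, mapping error. Tests passing on these simulations therefore show
that the algorithms are correct under their stated model, not that real
libraries are free of those effects.

## Verification experiments and their scales

The test suite and `scripts/acceptance.py` compute, at these problem
sizes (chosen to keep the full run in seconds on one CPU):

- **Noiseless recovery** — 16 kb genome, damage and error off, 20×:
  consensus equals the truth at every position, completeness 100%.
- **Damage suppression** — δ = 0.3, 20 seeds, 2× coverage with permissive
  thresholds (`c_min=1`, `f_min=0.51`): the damage-aware caller (d = 5)
  makes strictly fewer false deamination-allele calls than the identical
  caller with d = 0 on every seed. The sparse regime is used because at
  the default thresholds a false deamination call needs ≥75% of ≥5
  independent reads damaged at one site (probability ~10⁻⁶ per site), so
  both callers sit at zero and the comparison is vacuous; with single
  reads dominating calls, the adjusted caller's false-call sites are a
  provable subset of the unadjusted caller's.
- **Parsimony exactness** — 200 random binary and multifurcating trees of
  up to 6 leaves with random (partly missing) columns against exhaustive
  enumeration of internal labelings.
- **Homoplasy recovery** — the default injection (65/70/50; 24/27/17)
  recovered exactly.
- **Damage-parameter recovery** — δ refit from a 100× profile to within
  ±20% (observed errors are typically ~1–3%).
- **QC categorisation** — the bundled 20-sample capture summary table:
  all 20 meet the relaxed criteria; 15 are strict-eligible on coverage and
  completeness alone (per-sample nucleotide support values were never
  published, so the published strict count of 13 — two samples failing
  support — cannot be re-derived and no support values are invented).

## Known limitations

- The shared-derived count is a single MRCA-based statistic; published
  counts described as "averages" over an unspecified procedure may differ
  in detail, and derived counts on real alignments are sensitive to
  alignment, missing-data masks and tie-breaking choices.
- The binary damage window is a filter, not a likelihood model; at
  extreme damage it discards real terminal variation (visible as a small
  completeness cost in the examples).
- VCF-only mode cannot adjust counts, only flag suspect sites.
- BAM/CRAM, BCF and indexed access are out of scope; SAM/VCF text is the
  interchange surface.
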