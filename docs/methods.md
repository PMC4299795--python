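# Methods

This note documents the models and procedures paleoerv implements, the
parameters that matter, what the bundled simulator does and does not
emulate, and the numerical choices made where the design was genuinely
open.

## The synthetic genomes

Background sequence is i.i.d. with a configurable GC fraction (default
0.44, a typical amniote value). Proviruses are assembled as
`LTR5 + internal + LTR3` where the internal region carries four genes
(*gag*, *pro*, *pol*, *env*) as ATG-initiated, stop-terminated ORFs padded
by neutral spacers to a configurable internal length (default 6 kb,
matching reported mean proviral chain lengths of ~7.2 kb once 400-bp LTRs
and the TSD are added; the LTR default is shorter than the 1.5-kb solo-LTR
averages reported for real crocodilian data purely to keep desk-scale
runtimes, and both lengths are configurable).

Because no reference sequences ship with the package, each gene embeds
short fixed amino-acid signature blocks inside otherwise random ORFs: a
capsid block present in every class, the CCHC zinc-finger cassette
(C-x2-C-x4-H-x4-C; one copy in class I, two in class II, none in
III/IV), the D(T/S)G protease motif, an RT core containing the LPQG and
Y(V)DD boxes, RNase H and DDE-integrase blocks, a GPY/F module downstream
of integrase (classes I/II only), a dUTPase cassette (within *pro* in
class II, downstream of integrase in class III), and an *env* block
(class IV keeps a relatively intact *env*; so, here, do the others —
*env* presence is deliberately not a discriminating feature). Class
identity lives in variable regions: four class centroids are derived once,
from a fixed internal seed, by mutating a common ancestor at 40% of
variable-region residues; families within a class mutate their centroid at
a further 5%. The same fixed seed generates the packaged RT reference
panel (three representatives per class plus two deeply diverged
Gypsy-like outgroups) and the synthetic host protein set (a KIT-ligand-like
and a nectin3-like protein plus decoys) used for capture tests — all of
these are synthetic stand-ins, swappable for real FASTA references.

Age is encoded as LTR–LTR divergence *d*: each LTR accumulates
Poisson(*d*/2) substitution events per site under a Kimura two-parameter
process (transition:transversion event ratio 2:1), so homoplasy is
possible and the K2P estimator recovers *d* without bias (checked by a
paired t-test over 50 replicates). Copy decay applies single-hit
substitutions (and optionally geometric-length indels, p = 0.5, capped at
30 bp) along the whole element; decay on the LTRs adds to the age signal
and the truth ledger records the total. `force_nonsense` writes a TAA at a
random internal *pol* codon so that every copy is individually broken.

Planting duplicates the class-specific number of bases at the insertion
site (4/6/5/5 bp) on both sides of the element; TSDs are exact at planting
time. Species pairs are built on one ancestral background: shared
insertions are composed at homologous coordinates, then each species'
genome receives single-hit substitutions at half the configured flank
divergence. Single-hit (rather than Poisson) divergence is used here so
that "25% flank divergence" yields ~76% expected flank identity, safely
below the 80% orthology threshold; with homoplasy the expectation would
sit at ~79% and chance acceptances would blur the designed negative
control.

What the simulator does **not** emulate: nested insertions, assembly gaps
and sequencing error, PBS/PPT biology, CpG-elevated mutation, rate
heterogeneity among sites, and non-LTR repeats. Tests passing on this
generator therefore demonstrate the pipeline's logic and calibration, not
its robustness to assembly artefacts or to repeat landscapes denser than
the planted one.

## Detection

Candidate LTR pairs are exact 12-mer seed pairs at a start-to-start
separation of 1–15 kb, clustered along diagonals, extended ungapped with
an X-drop rule, and verified by global-alignment identity (edlib; accept
≥60% over ≥200 bp, both configurable). Overlapping candidates resolve
greedily by identity × length.

Outer LTR boundaries carry an irreducible one-base ambiguity: whenever a
genomic base adjacent to the repeat happens to match the corresponding
repeat-edge base (probability 1/4 per junction), a shorter-TSD and a
longer-TSD reading of the locus are *exactly* equally consistent with the
local sequence. Per element, `snap_boundaries` scores candidate edge
offsets by a changepoint likelihood along the LTR5/LTR3 correspondence
plus a per-base bonus for exact duplication, with the bonus equal to the
cost of reclassifying one matching repeat base — so the unidentifiable
case scores an exact tie, which is split by position parity to spread the
unavoidable one-off errors symmetrically rather than biasing every
ambiguous element toward the same wrong TSD length. When three or more
detected elements share an LTR (≥75% identity), `refine_boundaries_by_family`
resolves the ambiguity properly: members of a family carry near-identical
LTRs but sit in unrelated flanks, so stacking their edge windows and
locating the column where mean pairwise identity collapses to background
pins the true edge; this is what makes per-element TSD calls essentially
exact on family data.

TSD calling itself is an exact-match rule: the longest k ∈ [3, 8] with the
k bases 5′ of the 5′ LTR equal to the k bases 3′ of the 3′ LTR; degraded
TSDs simply return none.

Domain scanning translates the internal region in six frames and takes the
best sliding-window identity against each signature block (threshold 0.55
— random 20-letter windows reach this with probability < 10⁻⁶, while 5%
nucleotide decay leaves ~90% amino-acid identity). The chain score is
transparent and additive: each motif scores 0–100 (percent identity), an
LTR pair adds 50, a TSD adds 25, with the conventional thresholds kept as
anchors (detect at 250, report at 300). "Complete" calls have a gag
signature (capsid or zinc finger), protease, RT and integrase, *env*, both
LTRs, and no run of more than five ambiguous residues in the *pol*
translation. Solo LTRs are reported only when they match a library of
called or consensus LTRs (≥70% identity over ≥50% of length): without a
library hit a lone LTR cannot be attributed to an ERV rather than a
Gypsy-like element, so unmatched repeats stay unreported.

## Consensus and repair

Majority-rule consensus per column; gap-majority columns are omitted; ties
resolve gap < A < C < G < T. Repair is the deterministic stand-in for
manual curation: inside annotated ORF spans only, each premature stop
substitutes the highest-count alternative column state that removes it,
and a span whose length breaks frame flips its most nearly tied indel
column between kept and omitted. Every edit is logged with column,
states, and reason; sites with no resolving alternative are left and, when
they fall in RT, clear the `rt_intact` flag. The built-in aligner is
center-star progressive (the minimum-total-edit-distance sequence anchors
pairwise alignments merged column-wise); pairwise steps use affine gap
costs (match 1, mismatch −1, open −4, extend −1) because unit-cost edit
alignments open spurious indel pairs between equal-length diverged copies
and a single such pair garbles every downstream codon. Any external
aligner's FASTA output is accepted in its place.

## Groups, classes, ages

Group definition works on the *pol* amino-acid translations of complete
calls: uncorrected p-distances with pairwise deletion of gapped or
ambiguous columns, neighbor joining, and column-resampling bootstrap
(replicate r seeded with seed + r, so supports are reproducible and
independent of execution order). NJ ties on the Q criterion break on the
lexicographically smallest pair of cluster labels — deterministic and
invariant to input row order, which a matrix-index tie-break is not;
negative branch lengths clamp to zero with the deficit moved to the sister
branch. Clades with support strictly above 0.70 (both sides of each edge;
the tree is unrooted) seed the partition; fragments merge back
agglomeratively while the distance between them is at most twice their
internal diversity (the factor 2 operationalises "more similar to each
other than to other lineages"; accepted groups always satisfy mean
within-group distance < distance to the nearest other group). Singletons
are legal groups; a group whose only consensus lacks an intact RT is
flagged unrepresented.

Structural classification scores the feature vector (TSD length,
zinc-finger count, GPY/F, dUTPase location, *env*) against the four class
columns, one point per match; dUTPase *absence* is uninformative (lineages
lose it) and scores nothing, which correctly leaves the III-vs-IV
structural comparison tied and deferred to phylogeny. RT placement joins
the query to the labelled panel by NJ + bootstrap and returns the class of
the smallest supported (>0.70) clade containing the query and a single
panel class, else "intermediate". The final label is the phylogenetic one
unless unresolved, then the structural one unless ambiguous, else
"unclassified".

Dating aligns each LTR pair globally (match +1, mismatch −1, gap open −5,
extend −1) and rejects pairs with more than 20% gapped columns or under
60% identity — the operational form of "could not be aligned due to
indels". K2P distance d = −½ ln[(1 − 2P − Q)√(1 − 2Q)] over ungapped
columns; saturated pairs (either logarithm argument ≤ 0) are flagged
undefined and dropped from group means, with used/dropped counts reported
(dropping, rather than zeroing, is a declared choice). T = d/(2r); r is
configurable and defaults to 3.9 × 10⁻¹⁰ s/s/y.

Orthology takes 500 bp of flank outside the TSD on each side, discards
flanks truncated by scaffold edges, >5% ambiguous, or matching the
ERV/LTR library, and pairs calls one-to-one by reciprocal-best combined
flank identity, accepting only when *both* flanks reach 80% global
identity (stricter than averaging, declared). Group species distributions
are cross-checked against a divergence-time table (defaults: alligator
lineage vs crocodile/gharial 97 My, crocodile vs gharial 47 My — the lower
bounds of the published ranges): a group spanning species older than its
LTR-based age gets flagged, the expected signature of LTR-clock
underestimation.

## Captures and selection

ORFs of ≥80 codons that do not overlap retroviral domain hits are aligned
locally (BLOSUM62, open −11, extend −1) against the host protein set;
hits at ≥40% identity over ≥60% of the host protein are capture events
(thresholds are package choices). Mode is `replacing_env` when the
provirus lacks an *env* hit, otherwise `between_pol_env`. Captured ORFs
are codon-aligned via their translations; gap runs whose length is a
multiple of three are reported as in-frame indels with flanking peptide
context, others logged as frame-disrupting.

dN/dS follows the Nei–Gojobori proportion method: per-codon potential
sites from single-mutation neighbourhoods with stop neighbours excluded
(so S + N = 3 × (1 − stop-neighbour fraction)); observed differences
averaged over all minimal mutational pathways that avoid stops (all
pathways if every one is blocked, renormalised to the observed difference
count); pairwise Nd/N and Sd/S averaged over all sequence pairs; no
distance correction. The Z test uses Z = (dS − dN)/√(Var(dS) + Var(dN))
with variances from a codon-site bootstrap (default 1000 resamples,
multinomial column weights), one-tailed against the purifying alternative
by default; positive-selection and two-tailed alternatives are available,
and an analytical check of the calibration is part of the test suite
(type-I error 0.042–0.060 at α = 0.05 over 500 neutral replicates of 10
sequences × 300 codons).

## Problem sizes and determinism

The package-level checks run at desk scale by design: detection accuracy
and TSD recovery on 1.5-Mb genomes with 20 insertions per class; dating
recovery on 100 pairs of 2-kb LTRs per divergence level; consensus repair
on 20 replicate families of 10 copies with 3-kb internal regions; NJ
correctness on 200 random additive matrices of up to 8 taxa;
orthology on ~0.9-Mb species pairs with 6 shared insertions. Genome-scale
figures (thousands of chains, hundreds of thousands of solo LTRs) require
real assemblies and are out of scope for the bundled data.

Every stochastic component takes an explicit seed; a fixed config + seed
reproduces byte-identical FASTA/GFF3/TSV outputs (verified by manifest
hashing in the pipeline tests).

## Known limitations

- Solo-LTR sensitivity is bounded by the LTR library: families with no
  detected provirus contribute no library entry and their solo LTRs go
  unreported.
- Single-element TSD calls retain the one-base ambiguity described above
  (~20% of isolated elements report ±1 bp); family evidence removes it.
- The detector assumes colinear, unnested proviruses; nested insertions
  split or mask chains.
- K2P dating inherits the usual LTR-clock caveats (gene conversion between
  LTRs, rate variation); the distribution-vs-age cross-check is the
  built-in sanity valve.
- The codon Z test's bootstrap treats codon sites as exchangeable;
  pervasive site-wise rate variation would make it conservative.
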