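# Methods

This note documents the models, algorithms, parameter choices and known
limitations of `circfuse`, in the order the pipeline applies them.

## Scope and model

`circfuse` detects transcripts of *known* fusion gene pairs only: a curated
pair table defines the entire search space, which is what gives the method
its specificity and speed. It makes no attempt to discover novel fusion
partners, genomic (DNA-level) breakpoints, or circRNAs outside the
reconstructed fusion sequences, and it does not model expression levels or
circular-to-linear ratios.

Coordinates are 0-based half-open throughout the library; SAM output
converts to 1-based on emission. `bp5` is one past the last fused base of
the 5′ gene, `bp3` the first fused base of the 3′ gene, so the fusion
sequence is `seq5[:bp5] + seq3[bp3:]` with the junction at `bp5`.

## Bipartite partition (sets U and V)

Fusion partner genes and curated pairs form a graph; 2-coloring it yields
the two alignment reference sets. Each connected component is colored
breadth-first with neighbours visited in sorted order; the seed (placed in
U) is the component's lexicographically smallest gene that occurs as a 5′
partner, so U collects the 5′ side where orientation allows. The result is
deterministic and invariant to pair-list order.

Curated catalogues are bipartite in practice, but user-supplied tables may
contain odd cycles. Every gene of an odd cycle — computed exactly as the
vertex set of non-bipartite biconnected blocks, since in a 2-connected
non-bipartite graph every vertex lies on an odd cycle — is placed in *both*
sets (`dual`) with a logged warning, so all of its known partners remain
searchable. Failing open here keeps real catalogues usable.

## The soft-clip local aligner

The aligner is an exact affine-gap dynamic program whose objective adds a
flat, low penalty for clipped read ends: alignments start and end on an
aligned base pair, reference ends are free, and each clipped read base
costs 1. Defaults: match +2, mismatch −4 (N counts as mismatch), gap open
−5, gap extend −3 per base, clip −1/base; alignments scoring below
`score_min(L) = 0 − 0.8·L` are discarded. The clip and minimum-score
settings are what make chimeric reads align as clean `M/S` patterns instead
of being forced through one reference; the match/mismatch/gap values are
ordinary local-alignment defaults and nothing downstream depends on their
exact magnitudes. Score ties between extending through a mismatch-heavy run
and clipping are resolved toward clipping (canonical boundary); remaining
end ties go to the smallest read end, then reference end, so output is
deterministic.

The kernel is numba-compiled and exact — no seeding heuristics live inside
`local_align`, which keeps it bit-identical to a brute-force DP oracle.
Speed at pipeline scale comes from a separate k-mer prefilter (below).

### Boundary cleanup around junctions

With a clip cost of 1/base, an exhaustive DP will extend an alignment past
a junction whenever the partner sequence happens to agree: pure-match
extensions (micro-homology), mixed match/mismatch runs where matches
outnumber mismatches, and gap-separated chance blocks (e.g. `81M1D11M`
instead of `81M19S`) all score at least as well as clipping. These
extensions are *deterministic per sequence pair*, so every read's
breakpoint vote shifts identically and majority voting cannot repair them.
Three cleanup passes run after the DP, none of which alters the raw score:

1. **Gap-block trimming** — terminal match blocks separated from the rest
   of the alignment by an indel are folded into the soft clip when shorter
   than 12 bases or below 85% identity (with the reference in hand).
   Contiguous segments are never touched.
2. **Exact re-extension** — trimmed ends are greedily re-extended over
   exact matches, restoring bases a junk gap path had stolen from the true
   terminal run. Extension stops at the first mismatch, so it can only add
   homology-equivalent bases.
3. **Mismatch-tail cutting** — each junction-facing segment end is cut back
   past any mismatch within its terminal 12 aligned bases (PCC detection,
   back-splice detection and verification). What survives is either exact
   or pure homology, which canonicalization resolves.

## PCC signals and breakpoint inference

Two alignments of one read form a paired chiastic clipping signal when they
sit on different partner genes, on the same strand, with complementary clip
patterns: the left segment starts within 3 bases of the read start, the
right segment ends within 3 bases of the read end, both segments are at
least `min_clip` = 8 bases, and the in-read boundaries leave a gap of at
most 3 bases. The boundaries may *overlap* by up to 12 bases, because
junctional micro-homology extends both segments across the junction; the
signal is canonicalised to the boundary implied by the 5′ segment.

Junctional micro-homology also makes the breakpoint itself ambiguous: every
`(bp5 − j, bp3 − j)` inside the homology run reconstructs the identical
fusion sequence. Caller and simulator truth therefore agree on the
left-most representative (`canonicalize_breakpoint`). The same convention
applies to back-splice junctions, where each rotation `(s − j, e − j)` with
`F[s−i] == F[e−i]` describes the same circle.

Breakpoints are the modal `(bp5, bp3)` tuple over a pair's signals; ties go
to the tuple whose signals cover more aligned bases, then to the smaller
coordinates. Tuples within 2 bases of a winner are absorbed (clip jitter
from single-base chance matches); remaining distinct tuples are isoform
candidates, but a secondary candidate needs at least 2 split-read votes
before reconstruction — recalibrated support cannot discriminate between
reconstructions a few bases apart, so a lone error-bearing read must not
spawn its own call.

Reads back-spliced across a circle that spans the fusion point mimic a
fusion in the *opposite* orientation. When the catalogued orientation is
itself observed, such reversed signal groups are attributed to the
catalogued call (they are exactly the reads the back-splice stage
consumes); a reversed group without an observed catalogued counterpart is
still reported, annotated `catalogue_orientation = False`.

## Recalibration and the balance test

All reads touching either partner gene (and their mates) are re-aligned to
the reconstructed fusion. A read supports the junction when its matched
interval covers `junction_pos ± min_overlap` (default 5 — a read barely
touching the junction is uninformative); a read pair counts once. For each
supporting read the left/right fragment lengths around the junction feed a
two-sided Wilcoxon signed-rank test. Fragment lengths tie constantly, so
the exact null (n ≤ 25) is computed by counting-polynomial convolution over
doubled midranks, which stays exact under ties; larger samples use the
normal approximation with tie and continuity corrections. Zero differences
are dropped; a degenerate sample returns p = 1. The p-value *annotates*
calls — uniform junction coverage is an assumption worth surfacing, not a
hard filter — though `balance_alpha` enables filtering.

Reporting requires `min_support` = 3 junction-spanning reads. With genomic
gene coordinates supplied, same-chromosome pairs closer than 100,000 bp are
flagged as read-through transcripts and dropped in benchmark mode; without
coordinates the flag is unknown and nothing is dropped on it.

## Back-splice detection

On each reconstructed fusion, a candidate back-spliced read is one whose
best contiguous alignment leaves a soft clip of at least `circ_anchor` = 12
bases while the clipped fragment aligns *near-fully* (each edge within 3
bases, positive score) strictly upstream of the main segment. The anchor is
deliberately larger than the PCC `min_clip`: an 8–11 base fragment matches
a 2–3 kb reference by chance often enough to mint spurious support-1
circles, which would break the guarantee that linear-only data yields zero
circles. The read is then rotated at its split offset
(`read[k:] + read[:k]`) and both parts are re-aligned: verification
requires forward order at the candidate's loci (within 2 bases), near-full
part coverage, positive part scores and a combined score above
`score_min`. Verified junctions are canonicalised, clustered with a 2-base
tolerance (modal coordinates win), and reported with their support;
`min_circ_support` defaults to 1, and raising it to 2 removes most
error-induced single-read isoforms — the same cutoff sensitivity seen in
real data. Circles not containing the fusion point are flagged
`spans_fusion = False` and excluded from the default table view: they are
ordinary single-gene circRNAs, outside the tool's claim. For paired-end
data the mate of a back-splice read is checked for consistency with the
circle and the call is flagged, not dropped, on disagreement.

## Pipeline-level seeding

The exact DP is quadratic, so the pipeline screens reads against the
reference sets with exact k-mers (k = 14, both strands, vectorised) and
runs the DP only on seeded (read, gene, strand) triples, restricted to a
reference window around the seed matches — the role a spliced aligner's
multiseed stage plays in comparable workflows. A fusion segment shorter
than k cannot seed; if the other segment seeds with a clip, the partner
genes are aligned in full, so segments down to `min_clip` still contribute.
Recalibration seeds against the fusion sequence the same way. With
background sequences sharing no 30-mer with any fusion (a simulator
guarantee), a background read seeds only by chance (~1% at k = 14).

## The simulator

`simulate` emulates a spike-in style evaluation design on seeded random
sequences: gene lengths are drawn from 1–3 kb (always leaving 200 nt beyond
any designed breakpoint), fusions are reconstructed from designed
`(bp5, bp3)`, and circles are intervals on the fusion sequence. Reads are
uniform: single-end reads take a random strand; paired-end fragments
(250 ± 30 nt, FR orientation) yield mate 1 forward and mate 2 reverse
complemented. Circular reads are drawn from the doubled circle sequence so
that reads crossing the seam carry the back-splice junction. Errors are
independent substitutions (default 0.001/base) at constant Q30 — enough to
exercise clip-boundary jitter; indels, quality trajectories, GC and
positional bias, and duplicate reads are deliberately not modelled, so
passing tests demonstrate algorithmic correctness on idealised reads, not
robustness to every real-library artefact. Real transcript sequence content
is also absent; the pipeline is sequence-content-agnostic, which this
design exploits.

Read counts: each circle gets `ceil(coverage × circle_len / read_len)`
records; a fusion with circles gets 2.5× its circular count as linear
fusion reads (the linear:circular ratio), otherwise coverage-scaled linear
reads; background fills in at 20× the total fusion read count, spread over
transcripts by length, with every background transcript rejection-sampled
until it shares no 30-mer with any fusion sequence (either strand). The
bundled `default_design()` carries 4 fusion pairs (EML4–ALK, EWSR1–FLI1,
KMT2A–MLLT3, PML–RARA) with 2 fusion-point-spanning circles each (lengths
400–600 nt, summing to 1000 per fusion so counts divide evenly across the
20/50/100× × 50/100 nt grid). `benchmark_design(n)` provides a linear-only
design with deterministic breakpoints for precision/recall runs. Truth
coordinates are stored in canonical (left-most equivalent) form, read names
encode their origin, and identical configs reproduce byte-identical output.

## Problem sizes used in the shipped evaluation

The acceptance suite runs the full design at 100×/100 nt paired-end
(~294k read records), the linear-only control across the whole condition
grid with 20 seeds, a 10-fusion benchmark at 50× over 3 seeds (~254k
records each), and breakpoint-exactness over 2-fusion datasets at 25× for
20 seeds per error rate — sizes chosen so the complete evaluation
regenerates and analyses every dataset from scratch in a few minutes on a
single core while keeping per-call support in the tens of reads.

## Known limitations

- Fusions whose partners are absent from the catalogue are invisible by
  design, and genes missing from the reference FASTA are skipped with a
  warning.
- Breakpoints and circle coordinates are reported on the supplied
  transcript sequences; mapping to genomic coordinates (and hence the
  read-through filter) requires user-provided gene coordinates.
- The aligner supports substitutions and short indels but no spliced (N)
  alignment outside the two-segment back-splice chain, so fusions whose
  junction-spanning reads cross additional introns relative to the supplied
  transcript sequences will lose support.
- Micro-homology at a junction makes the breakpoint a class of equivalent
  coordinates; all output is the left-most representative, which may differ
  from an annotation that uses a different convention.
- At `min_circ_support` = 1, sequencing errors near a back-splice seam can
  emit isolated support-1 isoform calls a few bases off a true circle;
  cutoff 2 suppresses them at the cost of sensitivity to genuinely rare
  isoforms.
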