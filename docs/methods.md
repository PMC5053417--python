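# Methods

This note records the models, parameter choices and numerical decisions
behind pavscape, and what the synthetic experiments do and do not show.

## The ZCR → PAV/HDR model

The analysis assumes two high-quality assemblies of closely related,
effectively homozygous genomes (a selfing plant is the motivating case)
and deep short-read data for both. Reads of accession A are mapped onto
assembly B under a strict acceptance contract — at least `length_fraction`
(default 0.9) of the read aligned at identity ≥ `similarity_fraction`
(default 0.95) — with non-specific reads placed uniformly at random among
their co-optimal loci. Under this contract, sequence private to B receives
no A-reads; sequence shared but diverged beyond ~5% also receives none;
duplicated-but-shared sequence still receives its share through random
placement. Maximal zero-depth runs ≥ `min_zcr_len` (5 bp) are recorded as
ZCRs, runs with more than `max_ambiguity` (10%) non-ACGT characters are
discarded (assembly gaps masquerade as ZCRs), and only runs ≥
`report_min_len` (100 bp) are classified — the 100 bp floor separates
structural variation from ordinary InDels and absorbs small anchor
placement inaccuracies. The 5–99 bp runs are retained in raw outputs but
excluded from PAV/HDR statistics.

Classification anchors the 1 kbp ZCR flanks in the read-source assembly by
local alignment and asks whether the anchors are directly adjacent: same
subject sequence, same strand, flank order preserved under that strand,
and a signed inner-end distance within tolerance. The tolerance is
`base_adjacency_tol` (100 bp) up to 1 kbp and `rel_tol` (10%) of the ZCR
length beyond that. Adjacent anchors mean the ZCR sequence is absent from
the read source: a PAV, reported simultaneously as a deletion in the read
source and an insertion in the mapping target. Non-adjacent anchors leave
an HDR. ZCRs at sequence edges, or with clipped or unanchorable flanks,
are labelled unresolved rather than HDR: absence cannot be distinguished
from assembly truncation there. Anchor ties are broken deterministically
(highest score, then lowest subject id, then lowest coordinate); inner-end
distances are signed, so anchors overlapping beyond tolerance (mis-anchored
repeats) disqualify a PAV rather than sneaking in as |distance| ≈ 0.

PAV candidates are validated against the mate-distance signal: pairs with
one mate on each side of the ZCR should deviate from the library-wide mean
inner distance by more than `pair_dev_cutoff` (100 bp). The test is
two-sided and is run in the calling direction only; fewer than 3 spanning
pairs leaves a candidate indeterminate. Reported size-bin summaries use
doubling bins 100–200 … 12,801–25,600, >25,600 bp.

## Read mapper

The mapper is a desk-scale seed-and-extend design: exact 15-mer seeds at
four fixed read offsets against a sorted k-mer index, diagonal voting, an
exact-match fast path, and edlib (edit-distance, extended CIGAR) extension
of the full read against the best candidate windows. Identity is matches
over aligned columns. Two deliberate simplifications:

- **No soft clipping.** The whole read must align, so an accepted
  placement always has aligned_fraction 1.0; reads that would need
  clipping (e.g. spanning an insertion junction) are left unmapped. This
  sharpens ZCR boundaries — clipped alignments would erode the edges of
  zero-coverage runs — at the cost of slightly lower mapped fractions
  near junctions.
- Only the two acceptance fractions are treated as normative; seed length,
  gap penalties and candidate limits are implementation choices and are
  exposed as parameters.

Mate inner distance is the gap between the inner ends of the two
placements (negative when they overlap), computed identically for
paired-end (inward, FR) and mate-pair (outward, RF) layouts after
orientation normalization.

## Flank anchoring and protein scoring

Pairwise DP alignment is delegated to Bio.Align.PairwiseAligner:
nucleotide local alignment at match +1 / mismatch −2 with affine gaps
costing 5 + 2 per gap column; protein alignment with BLOSUM62 and gaps
costing 11 + 1 per column. For large targets, exact-seed diagonal voting
selects candidate windows (~2× query length) and only those are aligned;
targets ≤ 20 kbp are aligned whole, so results there equal exhaustive
local alignment (the test suite checks this against an independent Gotoh
implementation). The protein e-value surrogate is the Karlin–Altschul form
E = m·n·2^(−bit) with λ = 0.267, K = 0.041 (ungapped BLOSUM62 constants)
and m, n the total residue counts; only the ≤ 0.001 cutoff is meaningful,
absolute calibration is not.

## RBH synteny

Best hits require E ≤ 0.001; ties break by e-value then lexicographic
subject id, making reruns deterministic. Ranks are 0-based positions in
each assembly's position-sorted list of RBH genes. Outlier candidates are
pairs whose rank offset (rank_b − rank_a) deviates from the median offset
of their `outlier_window` (5) nearest neighbours by more than
`outlier_rank_dev` (20) ranks; offsets rather than raw ranks keep the test
exact at the ends of the gene list where neighbourhoods are one-sided.
Outliers with ≥ 2 near-best hits (score ≥ 0.95 × best) for either member
are typed *random* (ambiguous pairing, typically gene families), otherwise
*real*. Both knobs are configurable; outlier counts are sensitive to them
and are not comparable across parameterizations.

Split hints fall between consecutive genes on one scaffold whose
counterparts change chromosome or jump more than `outlier_rank_dev` ranks,
each side backed by a consistent run of ≥ 2 genes. Chromosome anchoring
takes the bp-weighted evidence majority (≥ 60%, else unplaced with a
reason), orientation from the sign of the Spearman correlation between
scaffold and chromosome positions, order from the median counterpart
coordinate, and emits AGP v2.0 with 100 bp unknown-size gaps. Genic
coverage flags use the median mean-depth of RBH genes as the single-copy
reference level; a non-RBH gene at ≥ 2× that level is a
collapsed-duplicate candidate.

## Genome composition estimators

Genome size comes from the canonical 25-mer multiplicity histogram of raw
reads: the error-tail boundary is the first multiplicity after which the
3-bin-smoothed histogram rises again (smoothing uses edge-replicated
padding; zero padding manufactures a dip at multiplicity 1), and the size
is the total k-mer observations above the boundary divided by the
coverage-peak depth. The peak depth is the count-weighted centroid of the
single-copy peak region, multiplicities within [0.5×, 1.75×] of the modal
bin: on sampled histograms the bare mode jitters by one or two bins and
narrow windows inherit per-bin counting noise (several percent of the
estimate), while a window covering essentially the whole single-copy peak
— but staying below the two-copy repeat peak at 2× — averages that noise
out and tracks the peak centre to < 1% on 30× simulations. All
multiplicities above the boundary are
included, so high-copy repeats count toward the estimate. Heterozygosity
is not modelled — the intended data are from a selfing accession — and no
mixture model is fitted.

Repeat copy number is pure depth arithmetic: reads are mapped to a short
reference of a few adjacent repeat units and copies = (mean depth ×
reference length / unit length) / single-copy depth, with the single-copy
level taken from genic (RBH) coverage. Composition reconciliation splits
estimate − assembly into the rDNA (NOR) array and five equal centromeres;
inputs where assembly + NOR exceed the estimate are rejected.

Completeness filters: an exon (> 50 bp) is present when its best assembly
hit reaches 50% of its self-score under a greedy one-hit-per-region
assignment (highest score first; claimed regions close); an EST maps when
some hit covers ≥ 95% of it at ≥ 90% identity; terminal-2 kbp windows of
scaffolds > 4 kbp are anchored to the counterpart and intersected with
transposable-element annotation.

## Synthetic data: what it does and does not emulate

The generator produces an ancestor (i.i.d. background at target GC,
default 0.36, with exact tandem arrays at recorded positions) and derives
a second accession from it. Defaults are the measured divergence of two
natural accessions of a selfing plant: SNPs at 1/292 bp, small InDels
(1–20 bp, truncated-geometric lengths) at ~1/1,500 bp, large events
log-uniform over 100 bp–25.6 kbp so every doubling bin is exercised. HDR
blocks are modelled as locally multiplied SNP/InDel density (default 10×)
— the operational definition of an HDR is mapping failure from
accumulated differences, not alien sequence. Note that at 10× the default
background, within-block identity (~96.6%) still exceeds the 95% mapping
threshold, so default HDR blocks need not become ZCRs; tests that require
HDR-driven ZCRs raise the multiplier. Large events are placed ≥ 2 kbp
apart and ≥ 3 kbp from sequence ends so 1 kbp flanks never touch a second
event; the collapsed-duplicate locus writes two identical copies in the
derived accession and one in the ancestor, mirroring a known
reference-collapse case. Every edit is recorded in a TruthRegistry whose
replay onto the ancestor must reproduce the derived sequence exactly; HDR
entries are annotations (their edits are recorded individually).

Read simulation: uniform fragment starts; the *inner* (between-mate)
distance is Normal(insert_mean, insert_sd) truncated at ≥ 0 — the two
worked recovery checks (library-mean recovery, spanning-pair deviation)
are defined on inner distances, so the generator parametrizes them
directly; the sequenced fragment is inner + 2 × read length. Paired-end
reads face inward, mate-pair reads outward. Errors are i.i.d.
substitutions; there are no quality models, PCR duplicates, chimeras,
contaminants or coverage biases. Consequently, passing recovery tests
shows the logic is correct under clean, uniform coverage; it does not
bound performance on real libraries with coverage dips, adapter chatter
or repeat-rich breakpoints.

## Problem sizes and determinism

The benchmark suite uses a 1 Mbp accession pair with 20 implanted
deletions and 20 insertions (100 bp–10 kbp) at 30× error-free 2×250 nt
coverage for recovery; a 200 kbp identical pair at 20× for the null
control; 100 kbp at 30× for genome-size recovery; and a 60 kbp genome with
a 50-copy 180 bp array for copy-number recovery — sizes chosen so the full
suite and the acceptance script each run in minutes on one CPU while every
size bin up to 10 kbp is represented. One global seed fans out to
per-stage seeds through a SeedSequence-based counter derivation; every
random choice (event placement, read sampling, multi-mapper resolution)
descends from it, and identical configurations reproduce byte-identical
reports.

## Known limitations

- No soft clipping or split-read alignment: breakpoints are resolved only
  to anchor inner ends; events at scaffold ends stay unresolved.
- CNV is deliberately out of calling scope (only the ≥ 2× genic coverage
  flag addresses collapsed duplicates); SNP/InDel calling is out of scope.
- The coverage-titration helper maps the full read set once and filters
  placements per nested subsample — valid because per-read placements are
  independent of the rest of the read set, but it would not capture
  effects of read-set-dependent mappers.
- The e-value surrogate is uncalibrated; RBH results depend only on the
  relative cutoff.
- Outlier and split-hint counts depend on invented, configurable knobs
  (window 5 / deviation 20) and are not comparable across settings.
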