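# Methods

`hashalign` is a reference-guided short-read mapper built around four
stages — k-mer seeding against a hashed reference, diagonal clustering
of seed hits, banded Smith-Waterman-Gotoh polishing, and paired-end
resolution with mate rescue — plus a neural-network scheme that turns
alignment evidence into calibrated Phred mapping qualities, and a
simulation/evaluation harness that reproduces the standard accuracy
experiments for such a mapper at desk scale.

## Reference hashing

The reference (one or more FASTA sequences, IUPAC alphabet) is packed
into a single coordinate space; every overlapping window of length
`hs` (hash size, 4–32, default 15) that contains no `N`/`X` is stored
in a k-mer → positions table (CSR layout over sorted packed codes).
Windows containing other ambiguity codes are expanded into all
compatible A/C/G/T k-mers so that reads carrying either allele of a
dbSNP-masked site seed identically; expansion is capped at 64
combinations per window to bound table growth, and `N`/`X` windows are
never hashed. Lookups return at most `mhp` (default 100) positions per
k-mer, keeping the first in global coordinate order.

Special references (user-supplied insertion sequences such as mobile
elements) are placed at the *lowest* global coordinates. Ascending
position order therefore reports special-reference hits before genome
hits, which is how "alignment to the insertion sequences is attempted
first" is realised: in lookup order, in the `mhp` cap, and in
candidate-region tie-breaking. Only the reverse complement of the
*read* is queried; the reference is indexed on one strand.

## Seeding and clustering

A read of length L contributes its L−k+1 overlapping k-mers (windows
containing non-ACGT bases are skipped; reads shorter than k stay
unaligned). Each hit is characterised by its diagonal
(`ref_pos − read_offset`). Same-strand hits whose diagonals differ by
at most one and whose positions lie within one read length merge —
transitively — into one alignment candidate region, which is what lets
a region survive sequencing errors, SNPs and single-base INDELs in the
read; larger INDELs split the seeds into nearby regions that the
polishing stage re-unifies (overlapping polished placements are
deduplicated, keeping the best score). Regions are ranked by
`covered` — the number of distinct read bases under at least one
seed — then by seed count, with special-reference regions ahead of
equally ranked genome regions and leftmost position breaking remaining
ties (a stable sort keeps everything deterministic). Regions covering
fewer than `act` bases (alignment candidate threshold, default 55) are
dropped, and at most `max_loci` (default 200) regions are polished.
The `act` unit is *read bases covered by seeds*, consistent with the
default 55 being meaningful for 76–100 bp reads.

The hot path (seed collection, union-find clustering, coverage
counting, selection, score-only polishing) is compiled with numba; a
pure-Python implementation of the same rule (`seedcluster.cluster_hits`
et al.) provides the reference semantics, and the test suite checks
the two against each other and against a naive all-pairs grouping
oracle on small references. Per-read seed hits are buffered up to
4096 per strand; beyond that (extremely repetitive reads under a
generous `mhp`) later windows stop contributing, which parallels the
candidate cap's purpose.

## Polishing

Each selected region is aligned with local affine-gap dynamic
programming (Gotoh): a gap of length g costs `gap_open + (g−1) ×
gap_extend`. Default scores are match +10, mismatch −9, gap open 15,
gap extend 4, chosen so one substitution (19 below a match) is cheaper
than a 1 bp gap (25) but a long gap is cheaper than many scattered
mismatches — the usual balance between SNP and INDEL calls; all four
are configuration-exposed. The DP is banded around the region's seed
diagonals with half-width `band` (default 19, enough for the 14 bp
INDELs the INDEL experiment plants, plus slack); the banded result is
identical to the unbanded one whenever the optimal path stays inside
the band. Candidate scoring is a two-row, score-only pass that also
propagates the path origin (so the reference start is known without a
traceback); a full traceback runs only for placements actually
reported. Traceback ties prefer diagonal over deletion over insertion;
the best cell is the first maximal cell in row-major order — CIGARs
are deterministic. Read ends outside the local path become soft
clips, so M+I+S lengths always sum to the read length. A reference
ambiguity code that includes the read base scores as a match.

A placement is accepted when `mismatches + inserted + deleted bases ≤
mmp × L` (maximum mismatch proportion, default 0.15). Candidates are
pre-filtered at the score bound `L·match − mmp·L·(match+mismatch)` —
the best score attainable at the ceiling — and the exact rule is
enforced at traceback; if the top candidate fails it (possible when a
long gap is score-cheap but base-expensive), the next candidate is
tried. A PacBio-style preset (`hs 10, mmp 0.5, act 15`) covers
high-error long reads.

## Paired-end resolution and rescue

Mates are aligned independently. The fragment model (mean, spread) is
estimated per run from uniquely both-mapped forward-reverse pairs
using median and 1.4826×MAD (robust to the multimapping tail), falling
back to a configured model when fewer than 100 such pairs exist. The
resolver picks the fragment-consistent combination (same sequence,
opposite strands, forward before reverse, fragment within mean ±
4×spread) maximising the summed alignment score; it also records
whether several consistent combinations tie at that score — the pair
is then *proper but ambiguous*. When no consistent combination
exists, each aligned mate anchors a bounded Smith-Waterman search for
its partner over the window the model implies (anchor-side start ±
(mean + 4×spread) plus a read length); a hit passing the mismatch
ceiling with consistent strand, orientation and length is *rescued*.
Remaining pairs are classed discordant (both aligned, inconsistent),
one-end, or neither. `discordant` extends the basic status set
because both-aligned-but-inconsistent pairs (e.g. one mate inside an
element insertion) are a distinct, downstream-relevant outcome.
Mapping quality plays no role in combination selection — it is
computed afterwards — avoiding circularity with the fragment feature.

## Mapping qualities

`Q = −10·log10(P)` with P the probability the placement is wrong,
clipped to [0, 60] via a probability floor of 1e-6. P is estimated by
a small feed-forward network (one hidden layer of 8 logistic units,
standardised inputs, Adam, fixed seed) over six features: best and
second-best alignment score (each normalised by `L × match`), read
mononucleotide Shannon entropy, number of candidate loci polished,
number of seed hash hits (both counts as `log1p`), and the observed
fragment-length deviation in spread units (0 for single-end reads,
capped at 10; set to the cap for discordant pairs). One network
serves single-end and paired reads.

Two design points matter for calibration:

* **Ambiguity propagation.** When a read's best and second-best loci
  tie exactly, alignment evidence alone cannot place it and Q is
  forced to 0 — *unless* a unique fragment-consistent pair
  combination disambiguates it (the tie-ambiguity of the pair, not
  just the read, decides). Without the exemption, repeat reads that
  pairing places confidently would all be zeroed, which empirically
  produced a Q=0 bin whose actual quality was 25–40.
* **Probability calibration.** The raw network ranks alignments well
  but its tail probabilities are over-smoothed, so network scores are
  recalibrated on out-of-fold predictions with an error-count-adaptive
  histogram: bins accumulate (from the low-confidence end) until they
  hold at least 10 misaligned examples and 500 reads, the entire
  high-confidence remainder forms one pooled bin, and
  pool-adjacent-violators enforces monotonicity. The calibrated P for
  the best reads is therefore bounded by what the training set can
  measure (~the pseudocount rate of the pooled bin) — the assigned
  ceiling rises with training size instead of overclaiming certainty.

Training is simulate → align → label → fit: reads simulated from the
genome under study are aligned back to it and labelled by the 20 bp
tolerance rule (correct iff same reference, same strand, start within
20 bp). Reads whose quality the tie override will force to zero are
excluded from training — their labels are the coin flips the override
already accounts for, and keeping them makes the network hedge
everything with tie-like features (if exclusion leaves a single
class, training falls back to the full set). The whole pipeline is
deterministic given a seed and can be re-run for any genome
(`hashalign train-mapq`); the saved network carries the reference
digest and `align` warns on mismatch.

## Output

Primary SAM/BAM (via pysam/htslib) with standard flags, 1-based
positions, soft-clip CIGARs, AS/NM tags, and the ZA annotation
`ZA:Z:<mate_ref>;<mate_pos>;<mate_mq>;<mate_nloci>;<special>` carrying
the mate's location, mapping quality, mapping-location count and any
special-reference hit (the tag grammar is this package's own; the
content is what a structural-variant caller needs to avoid extra BAM
sweeps). Reads best explained by a special reference are reported on
it; reads with both genome and special placements report the genome
coordinate and flag the special hit in the mate's ZA. An optional
multi-mapping stream writes one position-sorted record per accepted
locus with SEQ/QUAL stripped and names replaced by per-read ordinals;
all but one representative are flagged secondary with MQ 0.

## Colorspace (SOLiD) support

Reads arrive as a primer base plus di-base transition colors
(identical pairs → 0; A↔C, G↔T → 1; A↔G, C↔T → 2; A↔T, C↔G → 3 —
equivalently XOR of the 2-bit base codes). Alignment happens in color
space; decoding back to basespace is reference-anchored: within each
aligned segment the observed colors are compared with the colors the
reference implies, a lone discrepancy is treated as a sequencing error
(the reference base stands), and a run of two or more discrepancies is
decoded through the chain as a real substitution. Basespace qualities
take the minimum of the two colors overlapping each base; the final
base, covered by one color, inherits that color's quality (the paper
trail for this boundary is silent; this is our convention, as is the
first-segment anchor on the primer).

## Synthetic data

The generator reproduces the study design used to benchmark the
mapper, scaled to a desk:

* **Genome**: 1 Mb i.i.d. uniform ACGT plus planted repeat families
  chosen to emulate the repeat landscape that makes real genomes hard
  to map — Alu-like 300 bp elements at 0.3/1/3% divergence (80/60/40
  copies), L1-like 1.5–6 kb elements (beyond the fragment length, so
  pairing cannot always disambiguate), and six identical 1.5 kb
  duplications (truly ambiguous); ~10% of the genome. Without
  elements longer than the fragment, misalignment is essentially
  unobservable at this scale and calibration cannot be measured.
* **Haplotype**: SNP count ~ Binomial(L, rate) (default rate 0.1%),
  INDELs in exact per-length counts, events ≥ 200 bp apart, with a
  piecewise-monotone coordinate map back to the original genome.
* **Reads**: 100 bp forward-reverse pairs, fragment ~ N(300, 30),
  random fragment strand, substitution errors on a linear
  quality-dependent ramp from 0.1% to 1% along the read (qualities are
  the Phred transform of the positional rate); read-level indel errors
  are off by default. Truth (reference, original-coordinate start,
  strand, spanned events) travels in a TSV sidecar, not in read names.
* **Spanning reads** for the INDEL experiment cover their event with
  at least 10 bp on each side — the anchor sequence a local aligner
  needs on both sides of a gap before "spanning" is meaningful.
* **Element insertions**: 50 copies of two synthetic 300 bp elements
  at uniform positions (≥ 2 kb apart, random orientation) in a donor
  genome; reads simulated from the donor are aligned against the
  original genome plus the elements as special references.

What the simulation does *not* model: base-composition bias, indel
sequencing errors, quality-dependent miscall spectra, chimeric
fragments, and a real genome's full repeat complexity. Passing the
acceptance experiments shows the pipeline reproduces the *structure*
of the published results under a comparable difficulty profile, not
performance on real data.

## Evaluation statistics

Correctness uses the 20 bp tolerance window (same reference, same
strand, |mapped − true start| ≤ 20). PPV per MQ cutoff is
correct/mapped among records at or above the cutoff; ROC points are
(total mapped, incorrect) per descending threshold. INDEL sensitivity
is per event length over spanning reads: the strict criterion
additionally requires the CIGAR to place an I/D of the true length
within ±2 bp of the true site (the containment tolerance is our
operationalisation); the relaxed criterion requires the position only.
Calibration bins by assigned Q (bins ≥ 30 reads), computes each bin's
actual quality as the Phred transform of its misalignment fraction
with a +0.5 pseudocount, and reports the Pearson correlation — note a
zero-error bin's "actual" is a lower bound set by the bin size, so at
desk scale bins beyond ~Q50 cannot confirm their assigned value, only
fail to contradict it. The element-insertion caller clusters
confidently mapped genome anchors (MQ ≥ 20, primary, non-special)
whose ZA reports a special-reference mate, within 500 bp and with
support ≥ 2, and counts a planted site recovered when a candidate lies
within 500 bp.

## Problem sizes and runtime

The reproduction (`scripts/acceptance.py`, also backing the acceptance
test suite) uses: 120,000 training pairs (~236k labelled alignments),
50,000 evaluation pairs (100k reads), 100 INDEL events per length
1–14 bp with 8 spanning pairs per event (~11k spanning reads), and
30,000 pairs over the 50-site donor genome. These sizes were chosen
so a full run completes in a few minutes on one CPU while every
reported statistic rests on enough events to be meaningful; the
training set is smaller than the ~500k alignments of the full-scale
design, which mainly lowers the measurable quality ceiling of the
calibrated network.

## Known limitations

* Alignment works chromosome-resident: no low-memory
  chromosome-by-chromosome mode, no SIMD inner loop.
* Legacy read container formats are out of scope; FASTA/FASTQ only.
* The overall (MQ ≥ 0) PPV on the default synthetic genome is ~98.7%:
  the planted identical duplications produce ~1.2% of reads whose
  placement is a reported-at-MQ-0 coin flip. This repeat load is
  heavier than the human-genome benchmark the published 99.5% figure
  comes from; high-confidence PPV (MQ ≥ 20) is unaffected.
* Mate-pair (reverse-forward) libraries are not modelled; pairing
  assumes forward-reverse short-insert data.
* Colorspace decoding is reference-anchored and heuristic rather than
  a joint DP re-decoding; adjacent color errors can decode as a
  spurious substitution.
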