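# hashalign

A hash-clustering short-read aligner with calibrated mapping
qualities, for people who need accurate read placement *and* an honest
statement of how confident each placement is — reference-guided
mapping for variant discovery, structural-variant support, and mapper
benchmarking on simulated data.

## How it works

Mapping proceeds in four stages:

1. **Seeding** — the reference is split into overlapping k-mers
   (`-hs`, default 15) stored in a hash table; IUPAC ambiguity codes
   are expanded so reads carrying either allele of a masked SNP seed
   identically. Read k-mers are looked up on both strands.
2. **Clustering** — seed hits with diagonals (ref&thinsp;pos − read
   offset) within ±1 and positions within a read length consolidate
   into alignment candidate regions, tolerant of sequencing errors,
   SNPs and single-base INDELs; regions covering fewer than `-act`
   (default 55) read bases are dropped and at most `--max-loci`
   (default 200) are kept.
3. **Polishing** — each region is aligned with banded local
   affine-gap DP (Smith-Waterman-Gotoh; gap of length g costs
   open + (g−1)·extend), and kept if
   mismatches + gap bases ≤ `-mmp`·L (default 0.15).
4. **Pairing** — mates are resolved against a fragment-length model
   (median/MAD-estimated per run); unresolved mates are rescued by a
   bounded Smith-Waterman search next to their anchored partner.

Mapping quality is the Phred-scaled misalignment probability,
Q = −10·log₁₀ P, with P estimated by a small neural network over
alignment evidence (best/second-best score, read entropy, locus and
seed-hit counts, fragment deviation), recalibrated on out-of-fold
predictions so Q is faithful. The network retrains for any genome
with one command. Special references (e.g. mobile-element sequences)
can ride along with the genome: hits to them are prioritized and
reported through the `ZA` tag
(`ZA:Z:<mate_ref>;<mate_pos>;<mate_mq>;<mate_nloci>;<special>`), which
is all a downstream insertion detector needs.

The package also ships the simulation harness used to validate all of
this: seeded genomes with planted repeat families, SNP/INDEL
haplotypes with truth tracking, Illumina-like paired reads, element
insertions, and the evaluation statistics (PPV by MQ cutoff under a
20 bp tolerance window, ROC, per-length INDEL sensitivity,
calibration curves, insertion-site recovery).

## Worked example

Simulate a small study, train the quality network, align, evaluate:

```bash
hashalign simulate genome --length 200000 --seed 7 -o genome.fa
hashalign simulate reads genome.fa --n-pairs 2000 --seed 8 --out-prefix sim
hashalign train-mapq genome.fa --n-pairs 20000 --seed 9 -o mapq.net
hashalign align genome.fa -q sim_1.fastq -q2 sim_2.fastq \
    --mapq-net mapq.net -o out.sam
hashalign evaluate out.sam sim_truth.tsv
```

which prints

```json
{
  "ppv_by_cutoff": {
    "0": 93.55,
    "10": 99.51456310679612,
    "20": 99.85242030696575,
    "30": 99.93773349937733
  },
  "calibration_r": 0.9864839659705584
}
```

Reading this: of all mapped reads, 93.6% landed within 20 bp of their
true origin — the 200 kb toy genome carries the generator's full
repeat load, so many reads are genuinely ambiguous — but restricted
to reads the aligner itself marks confident (MQ ≥ 10, ≥ 20, ≥ 30) the
positive predictive value climbs to 99.5–99.9%. That separation is
the point of calibrated qualities, and `calibration_r` ≈ 0.99 says
assigned and observed quality agree across the scale. The same
library is importable directly (`hashalign.ReadAligner`,
`hashalign.simeval`, `hashalign.pipelines`) for scripted studies.

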