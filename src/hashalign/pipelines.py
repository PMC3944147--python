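"""High-level experiment pipelines shared by the CLI, the tests and the
reproduction script: train the mapping-quality network on one seeded
simulation, evaluate accuracy on an independent one, run the INDEL and
element-insertion experiments.

Problem sizes default to a desk-scale replica of the published study
design: a 1 Mb genome with planted repeat families, a 0.1% SNP
haplotype, 100 bp paired forward-reverse reads at fragment length
300 +/- 30, and 100 INDEL events per length 1-14 bp.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .aligner import ReadAligner, records_to_frame
from .mapq import MapqNetwork, train_network
from .pairing import FragmentModel
from .refindex import AlignerConfig, ReferenceSet
from . import simeval

#: repeat families planted into the synthetic genome, mimicking the
#: repeat landscape that makes real genomes hard to map: short
#: high-identity interspersed elements (Alu-like), longer elements that
#: exceed the fragment length so pairing cannot always disambiguate
#: (L1-like), and identical recent duplications (truly ambiguous).
#: Roughly 8% of a 1 Mb genome.
DEFAULT_REPEAT_SPEC = [
    {"length": 300, "copies": 80, "divergence": 0.003},
    {"length": 300, "copies": 60, "divergence": 0.01},
    {"length": 300, "copies": 40, "divergence": 0.03},
    {"length": 1500, "copies": 12, "divergence": 0.005},
    {"length": 1500, "copies": 6, "divergence": 0.0},
    {"length": 6000, "copies": 4, "divergence": 0.01},
]

DEFAULT_GENOME_LENGTH = 1_000_000
DEFAULT_SNP_RATE = 0.001


def _sub_seed(seed: int, salt: int) -> int:
    return int((seed * 1_000_003 + salt) % (2 ** 31 - 1))


def make_genome(seed: int, length: int = DEFAULT_GENOME_LENGTH,
                repeat_spec=DEFAULT_REPEAT_SPEC) -> ReferenceSet:
    return simeval.generate_genome(length, _sub_seed(seed, 11), repeat_spec)


def _default_model() -> FragmentModel:
    return FragmentModel(simeval.DEFAULT_FRAGMENT_MEAN,
                         simeval.DEFAULT_FRAGMENT_SD)


def align_simulation(aligner: ReadAligner, sim: simeval.SimulatedReads
                     ) -> tuple[list, pd.DataFrame]:
    """Align simulated pairs; returns (records, truth-labelled frame)."""
    pairs = aligner.align_pairs(sim.reads1, sim.reads2,
                                fallback_model=_default_model())
    df = simeval.attach_truth(records_to_frame(pairs), sim.truth)
    return pairs, df


def features_and_labels(pairs, df: pd.DataFrame,
                        exclude_overridden: bool = True
                        ) -> tuple[np.ndarray, np.ndarray]:
    """Feature matrix and misalignment labels for network training.

    Reads whose quality the exact-tie override will force to zero at
    prediction time (tied loci without unambiguous pairing evidence) are
    excluded by default: their correctness is a coin flip the override
    already accounts for, and training on them makes the network hedge
    every read with tie-like features.
    """
    from .pairing import STATUS_PROPER, STATUS_RESCUED
    lab = {(row.name, row.mate): not row.correct
           for row in df.itertuples(index=False)
           if row.mapped}
    rows = []
    y = []
    for pair in pairs:
        for r in pair:
            if not r.mapped:
                continue
            if exclude_overridden:
                tie = r.second_score >= r.score > 0
                exempt = (r.status in (STATUS_PROPER, STATUS_RESCUED)
                          and not r.pair_tied)
                if tie and not exempt:
                    continue
            denom = r.read_length * r.match_reward
            rows.append((min(max(r.score / denom, 0.0), 1.0),
                         min(max(r.second_score / denom, 0.0), 1.0),
                         r.entropy, r.n_loci, r.n_hits, r.frag_dev))
            y.append(int(lab[(r.name, r.mate)]))
    return np.array(rows, float), np.array(y, int)


def train_mapq_pipeline(refset: ReferenceSet, n_pairs: int = 60_000,
                        snp_rate: float = DEFAULT_SNP_RATE, seed: int = 1,
                        config: AlignerConfig | None = None
                        ) -> tuple[MapqNetwork, dict]:
    """Simulate -> align -> label -> train, for the given genome."""
    hap, ms = simeval.mutate_genome(refset.seqs[0], snp_rate, None,
                                    _sub_seed(seed, 23))
    sim = simeval.simulate_reads(hap, n_pairs, _sub_seed(seed, 29),
                                 mutset=ms, ref_name=refset.names[0],
                                 name_prefix="trn")
    aligner = ReadAligner(refset, config or AlignerConfig())
    pairs, df = align_simulation(aligner, sim)
    X, y = features_and_labels(pairs, df)
    if len(np.unique(y)) < 2:
        # not enough non-overridden misalignments: keep every read
        X, y = features_and_labels(pairs, df, exclude_overridden=False)
    net, report = train_network(X, y, seed=_sub_seed(seed, 31),
                                ref_digest=refset.digest())
    report["n_alignments"] = int(len(y))
    return net, report


def accuracy_experiment(refset: ReferenceSet, net: MapqNetwork,
                        n_pairs: int = 50_000,
                        snp_rate: float = DEFAULT_SNP_RATE, seed: int = 2,
                        config: AlignerConfig | None = None
                        ) -> pd.DataFrame:
    """Align an independent simulation with mapping qualities assigned;
    returns the truth-labelled result frame."""
    hap, ms = simeval.mutate_genome(refset.seqs[0], snp_rate, None,
                                    _sub_seed(seed, 41))
    sim = simeval.simulate_reads(hap, n_pairs, _sub_seed(seed, 43),
                                 mutset=ms, ref_name=refset.names[0],
                                 name_prefix="acc")
    aligner = ReadAligner(refset, config or AlignerConfig(), mapq_net=net)
    _, df = align_simulation(aligner, sim)
    return df


def indel_experiment(refset: ReferenceSet, net: MapqNetwork | None,
                     events_per_length: int = 100,
                     reads_per_event: int = 8, seed: int = 3,
                     max_length: int = 14,
                     config: AlignerConfig | None = None) -> pd.DataFrame:
    """INDEL-spanning read experiment: events of each length 1-14 are
    planted, ~``reads_per_event`` spanning pairs simulated per event."""
    spec = {ln: events_per_length for ln in range(1, max_length + 1)}
    hap, ms = simeval.mutate_genome(refset.seqs[0], 0.0, spec,
                                    _sub_seed(seed, 53))
    sim = simeval.simulate_spanning_reads(hap, ms, reads_per_event,
                                          _sub_seed(seed, 59),
                                          ref_name=refset.names[0])
    aligner = ReadAligner(refset, config or AlignerConfig(), mapq_net=net)
    _, df = align_simulation(aligner, sim)
    return df


def overall_sensitivity(sens: pd.DataFrame) -> float:
    return float(100.0 * sens["n_correct"].sum() / sens["n_spanning"].sum())


def reproduce(seed: int = 1, workdir=None,
              n_train_pairs: int = 120_000,
              n_eval_pairs: int = 50_000) -> dict:
    """Run the full desk-scale study once and collect its headline
    numbers.

    One synthetic 1 Mb genome; the mapping-quality network is trained on
    one seeded simulation and every evaluation uses independent seeds:
    paired-read accuracy (PPV by MQ cutoff + calibration), the INDEL
    sensitivity experiment, and the element-insertion recovery
    experiment.  Returns a dict of scalar results plus the calibration
    table.
    """
    import tempfile
    from .mapq import calibration_curve

    refset = make_genome(seed)
    net, train_report = train_mapq_pipeline(refset, n_pairs=n_train_pairs,
                                            seed=seed)
    df = accuracy_experiment(refset, net, n_pairs=n_eval_pairs,
                             seed=seed + 1)
    ppv = simeval.evaluate_ppv(df, mq_cutoffs=(0, 10, 20, 30))
    mapped = df[df["mapped"]]
    table, r = calibration_curve(mapped["mapq"].to_numpy(),
                                 mapped["correct"].to_numpy())

    idf = indel_experiment(refset, net, seed=seed + 2)
    strict = simeval.indel_sensitivity(idf, "strict")
    partial = simeval.indel_sensitivity(idf, "partial")

    if workdir is None:
        workdir = tempfile.mkdtemp(prefix="hashalign-mei-")
    sam_path = f"{workdir}/mei.sam"
    cands, mei_truth = mei_experiment(refset, net, sam_path, seed=seed + 3)
    mei_sens = simeval.mei_sensitivity(cands, mei_truth["site"].tolist())

    return {
        "seed": seed,
        "train_report": train_report,
        "ppv_by_cutoff": ppv,
        "n_eval_records": int(len(df)),
        "n_eval_mapped": int(len(mapped)),
        "calibration_table": table,
        "calibration_r": float(r),
        "indel_strict_pct": overall_sensitivity(strict),
        "indel_partial_pct": overall_sensitivity(partial),
        "indel_table_strict": strict,
        "indel_table_partial": partial,
        "n_spanning_reads": int(strict["n_spanning"].sum()),
        "mei_sensitivity_pct": float(mei_sens),
        "n_mei_sites": int(len(mei_truth)),
        "mei_sam": sam_path,
    }


def mei_experiment(refset: ReferenceSet, net: MapqNetwork | None,
                   sam_path, n_sites: int = 50, n_pairs: int = 30_000,
                   n_elements: int = 2, element_len: int = 300,
                   seed: int = 4) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Plant element insertions, align donor reads against the original
    genome plus the elements as special references, write the ZA-tagged
    alignment file, call candidates.

    Returns (candidates, insertion truth).
    """
    from .samio import write_primary
    rng = np.random.default_rng(_sub_seed(seed, 61))
    elements = []
    for e in range(n_elements):
        eseq = "".join("ACGT"[int(b)]
                       for b in rng.integers(0, 4, element_len))
        elements.append((f"ELT{e}", eseq))
    donor, truth = simeval.insert_elements(refset.seqs[0], elements,
                                           n_sites, _sub_seed(seed, 67))
    sim = simeval.simulate_reads(donor, n_pairs, _sub_seed(seed, 71),
                                 ref_name=refset.names[0],
                                 name_prefix="mei")
    aug = ReferenceSet.from_sequences(
        [(n, s, True) for n, s in elements]
        + [(n, s, False) for n, s in zip(refset.names, refset.seqs)])
    aligner = ReadAligner(aug, AlignerConfig(), mapq_net=net)
    pairs = aligner.align_pairs(sim.reads1, sim.reads2,
                                fallback_model=_default_model())
    write_primary(pairs, aug, sam_path)
    cands = simeval.mei_candidates(sam_path)
    return cands, truth
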