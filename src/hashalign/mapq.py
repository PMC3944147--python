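"""Mapping-quality calibration via a small feed-forward network.

The mapping quality of an alignment is the Phred-scaled probability that
the reported placement is wrong: ``Q = -10 * log10(P)``.  The aligner
cannot compute P analytically, so a small neural network is trained to
approximate it from alignment evidence: best and second-best local
alignment scores (normalised by the perfect-match score), read entropy,
the number of candidate loci polished, the number of seed hash hits, and
the fragment-length deviation for paired reads.

The full retraining pipeline (simulate reads from the genome under
study, align them, label each alignment against the simulation truth,
train the network) lives in :mod:`hashalign.simeval`; this module holds
the feature extraction, the network and the calibration diagnostics.
"""

from __future__ import annotations

import math
import pickle
import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.model_selection import cross_val_predict
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler

QMAX = 60
PROB_FLOOR = 1e-6
CORRECTNESS_TOLERANCE_BP = 20

FEATURE_NAMES = ("best_norm", "second_norm", "entropy",
                 "n_loci", "n_hits", "frag_dev")


def phred_from_prob(p: float, qmax: int = QMAX) -> int:
    """Phred score of a misalignment probability, clipped to [0, qmax].

    P <= 0 clips to qmax (better than measurable); P > 1 is an error.
    """
    if p > 1:
        raise ValueError(f"probability {p} > 1")
    if p <= 0:
        return qmax
    return int(min(max(round(-10.0 * math.log10(p)), 0), qmax))


def prob_from_phred(q: float) -> float:
    return 10.0 ** (-q / 10.0)


def read_entropy(seq: str) -> float:
    """Shannon entropy of mononucleotide frequencies (bits per base)."""
    from .readio import entropy_bits_per_base
    return entropy_bits_per_base(seq)


@dataclass
class AlignmentFeatures:
    """Evidence vector mapped to a misalignment probability.

    Scores are normalised by ``read length * match reward`` so a perfect
    full-length alignment has ``best_norm == 1``; ``second_norm`` is zero
    when no second locus was accepted.  ``frag_dev`` is the observed
    fragment-length deviation in units of the model spread (0 for
    single-end reads).
    """

    best_norm: float
    second_norm: float
    entropy: float
    n_loci: int
    n_hits: int
    frag_dev: float = 0.0

    def as_array(self) -> np.ndarray:
        return np.array([self.best_norm, self.second_norm, self.entropy,
                         self.n_loci, self.n_hits, self.frag_dev], float)


def extract_features(record) -> AlignmentFeatures:
    """Features from a resolved alignment record.

    ``record`` needs attributes ``score``, ``second_score``, ``seq`` (or
    ``entropy``), ``n_loci``, ``n_hits``, ``frag_dev``, ``read_length``
    and ``match_reward``.
    """
    denom = record.read_length * record.match_reward
    best = min(max(record.score / denom, 0.0), 1.0)
    second = min(max(record.second_score / denom, 0.0), 1.0)
    ent = getattr(record, "entropy", None)
    if ent is None:
        ent = read_entropy(record.seq)
    return AlignmentFeatures(best, second, ent, record.n_loci,
                             record.n_hits, record.frag_dev)


class _BinnedCalibrator:
    """Histogram calibration of classifier scores with monotone pooling.

    Out-of-fold scores are sorted and grouped, starting from the
    low-confidence end, into bins that each contain enough misaligned
    examples (and enough examples overall) for their error rate to be
    measurable; the entire high-confidence remainder forms one pooled
    bin, so the calibrated probability never claims more certainty than
    the training data can support.  Pool-adjacent-violators enforces
    that the calibrated rate is non-decreasing in the raw score.
    """

    def __init__(self, min_wrong: int = 10, min_n: int = 500):
        self.min_wrong = min_wrong
        self.min_n = min_n
        self.thresholds_: np.ndarray | None = None
        self.rates_: np.ndarray | None = None

    def fit(self, p: np.ndarray, y: np.ndarray) -> "_BinnedCalibrator":
        order = np.argsort(p, kind="mergesort")[::-1]  # worst first
        ps, ys = p[order], y[order]
        n = len(ps)
        edges = []      # lower raw-score edge of each bin (exclusive)
        stats = []      # (n, wrong)
        start = 0
        while start < n:
            end = start
            wrong = 0
            while end < n and (wrong < self.min_wrong
                               or end - start < self.min_n):
                wrong += int(ys[end])
                end += 1
            # never split identical raw scores across bins
            while end < n and ps[end] == ps[end - 1]:
                wrong += int(ys[end])
                end += 1
            if end >= n or (wrong < self.min_wrong):
                # fold an unfinished tail into the previous bin
                end = n
                wrong = int(ys[start:end].sum())
            stats.append((end - start, wrong))
            edges.append(ps[end - 1])
            start = end
        rates = np.array([(w + 0.5) / (m + 1.0) for m, w in stats])
        weights = np.array([m for m, _ in stats], float)
        rates = _pava_decreasing(rates, weights)
        # bins were built worst-first: reverse so rates increase with p
        self.thresholds_ = np.array(edges[::-1][1:])  # ascending
        self.rates_ = rates[::-1]
        return self

    def predict(self, p: np.ndarray) -> np.ndarray:
        i = np.searchsorted(self.thresholds_, p, side="right")
        return self.rates_[i]


def _pava_decreasing(rates: np.ndarray, weights: np.ndarray) -> np.ndarray:
    """Pool adjacent violators: make ``rates`` non-increasing."""
    vals = list(rates)
    wts = list(weights)
    idx = [[i] for i in range(len(vals))]
    out_v, out_w, out_i = [], [], []
    for v, w, ii in zip(vals, wts, idx):
        out_v.append(v)
        out_w.append(w)
        out_i.append(list(ii))
        while len(out_v) > 1 and out_v[-1] > out_v[-2]:
            v2, w2, i2 = out_v.pop(), out_w.pop(), out_i.pop()
            v1, w1, i1 = out_v.pop(), out_w.pop(), out_i.pop()
            m = (v1 * w1 + v2 * w2) / (w1 + w2)
            out_v.append(m)
            out_w.append(w1 + w2)
            out_i.append(i1 + i2)
    res = np.empty(len(vals))
    for v, ii in zip(out_v, out_i):
        for i in ii:
            res[i] = v
    return res


class MapqNetwork:
    """One-hidden-layer sigmoid network: features -> P(misaligned).

    The counts (``n_loci``, ``n_hits``) enter as ``log1p`` and all
    features are standardised; a single network serves single-end and
    paired reads, with the fragment feature zeroed for single-end.  The
    raw network output is recalibrated on out-of-fold predictions (see
    :class:`_BinnedCalibrator`) so the Phred transform is faithful.
    """

    FORMAT_VERSION = 1

    def __init__(self, hidden_layer_sizes=(8,), seed: int = 0,
                 max_iter: int = 300, ref_digest: str = "",
                 calibrate: bool = True):
        self.hidden_layer_sizes = tuple(hidden_layer_sizes)
        self.seed = int(seed)
        self.ref_digest = ref_digest
        self.calibrate = calibrate
        self._calib: _BinnedCalibrator | None = None
        self._pipe = Pipeline([
            ("scale", StandardScaler()),
            ("net", MLPClassifier(
                hidden_layer_sizes=self.hidden_layer_sizes,
                activation="logistic", solver="adam",
                alpha=1e-4, max_iter=max_iter, random_state=self.seed,
                tol=1e-6)),
        ])
        self.trained = False

    @staticmethod
    def _transform(X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, float).copy()
        if X.ndim == 1:
            X = X[None, :]
        X[:, 3] = np.log1p(X[:, 3])
        X[:, 4] = np.log1p(X[:, 4])
        X[:, 5] = np.minimum(X[:, 5], 10.0)
        return X

    def fit(self, X: np.ndarray, y: np.ndarray) -> "MapqNetwork":
        """Train on features X and labels y (1 = misaligned)."""
        y = np.asarray(y, int)
        if len(np.unique(y)) < 2:
            raise ValueError(
                "training labels contain a single class; need both "
                "correct and incorrect alignments")
        if len(y) < 100_000:
            warnings.warn(
                f"training on {len(y)} labeled alignments; calibration "
                f"is typically trained on >= 1e5", stacklevel=2)
        Xt = self._transform(X)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # convergence chatter
            if self.calibrate:
                oof = cross_val_predict(self._pipe, Xt, y, cv=3,
                                        method="predict_proba")[:, 1]
                self._calib = _BinnedCalibrator().fit(oof, y)
            self._pipe.fit(Xt, y)
        self.trained = True
        return self

    def predict_prob(self, X: np.ndarray) -> np.ndarray:
        """P(misaligned) per row, floored at PROB_FLOOR."""
        if not self.trained:
            raise RuntimeError("network is not trained")
        p = self._pipe.predict_proba(self._transform(X))[:, 1]
        if self._calib is not None:
            p = self._calib.predict(p)
        return np.maximum(p, PROB_FLOOR)

    def predict_q(self, X: np.ndarray,
                  tie_exempt: np.ndarray | None = None) -> np.ndarray:
        """Phred qualities with the exact-tie override.

        Reads whose best and second-best loci share the maximal score are
        indistinguishable on alignment evidence alone and are forced to
        Q = 0, unless ``tie_exempt`` marks them as disambiguated by
        independent pairing evidence (a unique fragment-consistent pair
        combination).
        """
        p = self.predict_prob(X)
        q = np.clip(np.round(-10.0 * np.log10(p)), 0, QMAX).astype(int)
        X = np.asarray(X, float)
        if X.ndim == 1:
            X = X[None, :]
        tie = (X[:, 1] >= X[:, 0] - 1e-12) & (X[:, 1] > 0)
        if tie_exempt is not None:
            tie &= ~np.asarray(tie_exempt, bool)
        q[tie] = 0
        return q

    def save(self, path) -> None:
        with open(path, "wb") as fh:
            pickle.dump({
                "format_version": self.FORMAT_VERSION,
                "hidden_layer_sizes": self.hidden_layer_sizes,
                "seed": self.seed,
                "ref_digest": self.ref_digest,
                "pipe": self._pipe,
                "calib": self._calib,
                "trained": self.trained,
            }, fh)

    @classmethod
    def load(cls, path) -> "MapqNetwork":
        with open(path, "rb") as fh:
            st = pickle.load(fh)
        net = cls(st["hidden_layer_sizes"], st["seed"],
                  ref_digest=st["ref_digest"])
        net._pipe = st["pipe"]
        net._calib = st.get("calib")
        net.trained = st["trained"]
        return net


def predict_mapq(net: MapqNetwork, features: AlignmentFeatures) -> int:
    """Phred mapping quality for one alignment's features."""
    return int(net.predict_q(features.as_array()[None, :])[0])


def train_network(X: np.ndarray, y: np.ndarray, seed: int = 0,
                  hidden_layer_sizes=(8,), holdout: float = 0.2,
                  ref_digest: str = "") -> tuple[MapqNetwork, dict]:
    """Train the mapping-quality network and report held-out calibration.

    Deterministic given ``seed``.  Returns (network, report) where the
    report carries held-out accuracy, Brier score and class prior.
    """
    X = np.asarray(X, float)
    y = np.asarray(y, int)
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(y))
    n_hold = max(int(len(y) * holdout), 1)
    hold, train = order[:n_hold], order[n_hold:]
    if len(np.unique(y[train])) < 2:  # tiny inputs: train on everything
        train = order
        hold = order
    net = MapqNetwork(hidden_layer_sizes, seed=seed, ref_digest=ref_digest)
    net.fit(X[train], y[train])
    p = net.predict_prob(X[hold])
    report = {
        "n_train": int(len(train)),
        "n_holdout": int(len(hold)),
        "holdout_accuracy": float(np.mean((p > 0.5) == (y[hold] == 1))),
        "holdout_brier": float(np.mean((p - y[hold]) ** 2)),
        "class_prior": float(np.mean(y)),
    }
    return net, report


def label_correctness(aln_ref, aln_pos, aln_strand, truth_ref, truth_pos,
                      truth_strand,
                      tolerance: int = CORRECTNESS_TOLERANCE_BP) -> bool:
    """An alignment is correct when it hits the true reference and strand
    with its start within the tolerance window (default 20 bp)."""
    if truth_ref is None:
        raise ValueError("missing simulation truth for alignment")
    return (aln_ref == truth_ref and aln_strand == truth_strand
            and abs(int(aln_pos) - int(truth_pos)) <= tolerance)


def calibration_curve(assigned_q: np.ndarray, correct: np.ndarray,
                      min_bin: int = 30):
    """Assigned-vs-actual mapping-quality table and Pearson correlation.

    Bins alignments by assigned Q; the actual quality of a bin is the
    Phred transform of its observed misalignment fraction (with a +0.5
    pseudocount so empty-error bins stay finite).  Returns (table,
    pearson_r); raises when fewer than 3 bins survive ``min_bin`` or the
    assigned qualities have no variance.
    """
    assigned_q = np.asarray(assigned_q, int)
    correct = np.asarray(correct, bool)
    rows = []
    for q in np.unique(assigned_q):
        sel = assigned_q == q
        n = int(sel.sum())
        if n < min_bin:
            continue
        wrong = int((~correct[sel]).sum())
        p = (wrong + 0.5) / (n + 1.0)
        rows.append((int(q), n, wrong, phred_from_prob(p)))
    if len(rows) < 3:
        raise ValueError(f"only {len(rows)} usable bins (need >= 3)")
    arr = np.array(rows, float)
    aq, actual = arr[:, 0], arr[:, 3]
    if np.std(aq) == 0 or np.std(actual) == 0:
        raise ValueError("zero variance in binned qualities; "
                         "correlation undefined")
    r = float(np.corrcoef(aq, actual)[0, 1])
    import pandas as pd
    table = pd.DataFrame(rows, columns=["assigned_q", "n", "wrong",
                                        "actual_q"])
    return table, r
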