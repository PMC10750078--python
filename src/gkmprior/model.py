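"""Training and evaluation of the gapped k-mer SVM TF-binding classifier.

The positive training set is the top-N ChIP-seq peaks by signal; negatives
are unbound sequences sampled from the same genome matched for length,
chromosome and GC content. The classifier is a soft-margin SVM over the
normalized gkm kernel; any convergent dual solver satisfies the contract
(KKT conditions at the configured tolerance) — here scikit-learn's SVC with
a precomputed kernel. Performance is summarized by cross-validated AUROC
(tie-aware rank statistic) and AUPRC (step-wise average precision).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.metrics import average_precision_score, roc_auc_score
from sklearn.svm import SVC

from . import dna
from .gkm import GkmFeaturizer, ModelConfig


def _chromosomes(genome) -> dict:
    return genome.chromosomes if hasattr(genome, "chromosomes") else dict(genome)


@dataclass
class TrainingSet:
    """Labelled sequences: positives are TF-bound, negatives unbound."""

    positives: list[tuple[str, str]]
    negatives: list[tuple[str, str]]

    def __post_init__(self):
        if not self.positives or not self.negatives:
            raise ValueError("both classes must be nonempty")
        for _id, seq in self.positives + self.negatives:
            if not dna.is_valid(seq):
                raise ValueError(f"sequence {_id!r} contains non-ACGT characters")

    @property
    def ids(self) -> list[str]:
        return [i for i, _ in self.positives] + [i for i, _ in self.negatives]

    @property
    def sequences(self) -> list[str]:
        return [s for _, s in self.positives] + [s for _, s in self.negatives]

    @property
    def labels(self) -> np.ndarray:
        return np.concatenate(
            [np.ones(len(self.positives), dtype=int), -np.ones(len(self.negatives), dtype=int)]
        )


@dataclass
class GkmModel:
    """A trained gkm-SVM: support sequences, dual coefficients and bias.

    ``dual_coefficients[i]`` is alpha_i * y_i for support sequence i; the
    decision value of a sequence x is sum_i dual_i * K(s_i, x) + bias.
    Positive decision values predict TF-DNA binding.
    """

    config: ModelConfig
    support_sequences: list[str]
    dual_coefficients: np.ndarray
    bias: float
    support_ids: list[str] = field(default_factory=list)
    _featurizer: GkmFeaturizer | None = field(default=None, repr=False, compare=False)
    _support_matrix=None

    def __post_init__(self):
        self.dual_coefficients = np.asarray(self.dual_coefficients, dtype=np.float64)
        if len(self.support_sequences) != self.dual_coefficients.size:
            raise ValueError("one dual coefficient per support sequence required")
        if np.any(np.abs(self.dual_coefficients) > self.config.C * (1 + 1e-6)):
            raise ValueError("dual coefficients exceed the box constraint C")

    @property
    def featurizer(self) -> GkmFeaturizer:
        if self._featurizer is None:
            self._featurizer = GkmFeaturizer(self.config.l, self.config.k)
        return self._featurizer

    def _sv_matrix(self):
        if self._support_matrix is None:
            self._support_matrix = self.featurizer.feature_matrix(
                self.support_sequences, normalize=True
            )
        return self._support_matrix

    def decision_values(self, sequences) -> np.ndarray:
        """SVM decision values for a batch of sequences (strand-invariant)."""
        X = self.featurizer.feature_matrix(list(sequences), normalize=True)
        K = np.asarray((X @ self._sv_matrix().T).todense())
        return K @ self.dual_coefficients + self.bias

    def save(self, prefix: str | Path) -> None:
        """Serialize as JSON header + TSV of coefficients + FASTA of supports."""
        prefix = Path(prefix)
        header = {
            "config": {
                "l": self.config.l,
                "k": self.config.k,
                "d": self.config.d,
                "C": self.config.C,
                "eps": self.config.eps,
                "cv_folds": self.config.cv_folds,
                "kernel_variant": self.config.kernel_variant,
            },
            "bias": self.bias,
            "n_support": len(self.support_sequences),
        }
        prefix.with_suffix(".model.json").write_text(json.dumps(header, indent=2))
        ids = self.support_ids or [f"sv{i}" for i in range(len(self.support_sequences))]
        with open(prefix.with_suffix(".coefs.tsv"), "w") as fh:
            fh.write("id\tdual_coefficient\n")
            for i, c in zip(ids, self.dual_coefficients):
                fh.write(f"{i}\t{c:.17g}\n")
        with open(prefix.with_suffix(".support.fa"), "w") as fh:
            for i, s in zip(ids, self.support_sequences):
                fh.write(f">{i}\n{s}\n")

    @classmethod
    def load(cls, prefix: str | Path) -> "GkmModel":
        from Bio import SeqIO

        prefix = Path(prefix)
        header = json.loads(prefix.with_suffix(".model.json").read_text())
        coefs = pd.read_csv(prefix.with_suffix(".coefs.tsv"), sep="\t")
        recs = list(SeqIO.parse(prefix.with_suffix(".support.fa"), "fasta"))
        return cls(
            config=ModelConfig(**header["config"]),
            support_sequences=[str(r.seq) for r in recs],
            dual_coefficients=coefs["dual_coefficient"].to_numpy(),
            bias=header["bias"],
            support_ids=[r.id for r in recs],
        )


@dataclass
class CvReport:
    """Cross-validation metrics with the fold assignment that produced them."""

    fold_auroc: list[float]
    fold_auprc: list[float]
    fold_assignments: dict[str, int]
    seed: int

    @property
    def mean_auroc(self) -> float:
        return float(np.mean(self.fold_auroc))

    @property
    def mean_auprc(self) -> float:
        return float(np.mean(self.fold_auprc))


def select_top_peaks(peaks: pd.DataFrame, n: int = 1000) -> pd.DataFrame:
    """Top-``n`` peaks by signal, the positive-set selection rule.

    Sorts descending by score with ties broken by (chromosome, start) so the
    selected set is deterministic; returns min(n, available) rows.
    """
    ordered = peaks.sort_values(
        ["score", "chrom", "start"], ascending=[False, True, True], kind="mergesort"
    )
    return ordered.head(n).reset_index(drop=True)


def extract_sequences(genome, intervals: pd.DataFrame):
    """Extract interval sequences from the genome (uppercased).

    Returns ``(records, excluded)`` where records are (id, sequence) pairs
    and excluded lists (id, reason) for intervals containing non-ACGT
    characters. Intervals beyond chromosome ends raise.
    """
    chroms = _chromosomes(genome)
    records, excluded = [], []
    for row in intervals.itertuples(index=False):
        name = getattr(row, "name", None) or f"{row.chrom}:{row.start}-{row.end}"
        if row.chrom not in chroms:
            raise KeyError(f"chromosome {row.chrom!r} not in genome")
        seq = chroms[row.chrom]
        if row.end > len(seq) or row.start < 0:
            raise ValueError(f"interval {name} outside chromosome bounds")
        sub = seq[row.start : row.end].upper()
        if dna.is_valid(sub):
            records.append((name, sub))
        else:
            excluded.append((name, "non-ACGT characters"))
    return records, excluded


def _overlaps(chrom, start, end, table) -> bool:
    sub = table.get(chrom)
    if sub is None:
        return False
    starts, ends = sub
    i = np.searchsorted(starts, end)
    return bool((ends[:i] > start).any())


def generate_null_set(
    genome,
    positives: pd.DataFrame,
    gc_tolerance: float = 0.02,
    excluded: pd.DataFrame | None = None,
    max_attempts: int = 2000,
    seed: int = 0,
) -> pd.DataFrame:
    """GC-, length- and chromosome-matched unbound intervals.

    For each positive peak, draws random same-length windows on the same
    chromosome until one matches the peak's GC content within
    ``gc_tolerance`` and overlaps neither the positives, the ``excluded``
    intervals, nor a previously selected negative. Deterministic under
    ``seed``; raises listing the unmatched positives if ``max_attempts`` is
    exhausted for any peak.
    """
    chroms = _chromosomes(genome)
    rng = np.random.default_rng(seed)

    def _index(df):
        table = {}
        if df is None:
            return table
        for c, sub in df.groupby("chrom"):
            s = sub.sort_values("start")
            table[c] = (s["start"].to_numpy(), s["end"].to_numpy())
        return table

    pos_tab = _index(positives)
    exc_tab = _index(excluded)
    chosen: list[dict] = []
    failures = []
    for row in positives.itertuples(index=False):
        length = row.end - row.start
        target_gc = dna.gc_fraction(chroms[row.chrom][row.start : row.end].upper())
        limit = len(chroms[row.chrom]) - length
        found = None
        for _ in range(max_attempts):
            start = int(rng.integers(0, limit + 1))
            end = start + length
            if _overlaps(row.chrom, start, end, pos_tab) or _overlaps(row.chrom, start, end, exc_tab):
                continue
            if any(c["chrom"] == row.chrom and c["start"] < end and start < c["end"] for c in chosen):
                continue
            sub = chroms[row.chrom][start:end].upper()
            if not dna.is_valid(sub):
                continue
            if abs(dna.gc_fraction(sub) - target_gc) <= gc_tolerance:
                found = {"chrom": row.chrom, "start": start, "end": end,
                         "name": f"null_{row.chrom}_{start}", "score": 0.0, "strand": "+"}
                break
        if found is None:
            failures.append(f"{row.chrom}:{row.start}-{row.end}")
        else:
            chosen.append(found)
    if failures:
        raise RuntimeError(
            f"could not GC-match negatives for {len(failures)} positives: {failures[:5]}"
        )
    return pd.DataFrame(chosen, columns=["chrom", "start", "end", "name", "score", "strand"])


def build_training_set(
    genome,
    peaks: pd.DataFrame,
    n_top: int = 1000,
    gc_tolerance: float = 0.02,
    excluded: pd.DataFrame | None = None,
    seed: int = 0,
) -> TrainingSet:
    """Top-peak positives plus GC/length/chromosome-matched null negatives."""
    top = select_top_peaks(peaks, n_top)
    positives, _ = extract_sequences(genome, top)
    negatives_bed = generate_null_set(genome, top, gc_tolerance, excluded, seed=seed)
    negatives, _ = extract_sequences(genome, negatives_bed)
    return TrainingSet(positives=positives, negatives=negatives)


def _fit_svc(K: np.ndarray, y: np.ndarray, config: ModelConfig):
    svc = SVC(kernel="precomputed", C=config.C, tol=config.eps)
    svc.fit(K, y)
    return svc


def train_gkm_svm(train_set: TrainingSet, config: ModelConfig | None = None,
                  seed: int = 0, kernel: np.ndarray | None = None) -> GkmModel:
    """Train the soft-margin gkm-SVM on a labelled sequence set.

    ``kernel`` may pass a precomputed training kernel matrix (in
    ``train_set`` order) to avoid recomputation; otherwise it is built here.
    """
    config = config or ModelConfig()
    seqs = train_set.sequences
    if any(len(s) < config.l for s in seqs):
        raise ValueError(f"all training sequences must have length >= l={config.l}")
    feat = GkmFeaturizer(config.l, config.k)
    if kernel is None:
        kernel = feat.kernel_matrix(seqs)
    y = train_set.labels
    svc = _fit_svc(kernel, y, config)
    sv = svc.support_
    ids = train_set.ids
    model = GkmModel(
        config=config,
        support_sequences=[seqs[i] for i in sv],
        dual_coefficients=svc.dual_coef_.ravel(),
        bias=float(svc.intercept_[0]),
        support_ids=[ids[i] for i in sv],
    )
    model._featurizer = feat
    return model


def _stable_hash(text: str) -> int:
    return int.from_bytes(hashlib.sha256(text.encode()).digest()[:8], "big")


def assign_folds(ids, labels, folds: int, seed: int) -> np.ndarray:
    """Stratified fold assignment by stable hash of sequence id.

    Within each class, ids are ordered by the hash of ``"{seed}:{id}"`` and
    dealt round-robin, so assignments depend on ids and seed only — never on
    input order.
    """
    labels = np.asarray(labels)
    out = np.empty(len(ids), dtype=int)
    for cls in np.unique(labels):
        idx = np.nonzero(labels == cls)[0]
        order = sorted(idx, key=lambda i: (_stable_hash(f"{seed}:{ids[i]}"), ids[i]))
        for rank, i in enumerate(order):
            out[i] = rank % folds
    return out


def cross_validate(train_set: TrainingSet, config: ModelConfig | None = None,
                   seed: int = 0, kernel: np.ndarray | None = None) -> CvReport:
    """Stratified k-fold cross-validation of the gkm-SVM.

    Each sequence is scored exactly once by a model not trained on it.
    Raises if any fold ends up single-class (use fewer folds).
    """
    config = config or ModelConfig()
    seqs = train_set.sequences
    ids = train_set.ids
    y = train_set.labels
    if kernel is None:
        kernel = GkmFeaturizer(config.l, config.k).kernel_matrix(seqs)
    fold_of = assign_folds(ids, y, config.cv_folds, seed)
    scores = np.empty(len(seqs))
    for f in range(config.cv_folds):
        test = fold_of == f
        train = ~test
        if len(np.unique(y[train])) < 2 or not test.any():
            raise ValueError(f"fold {f} is degenerate; use fewer folds")
        svc = _fit_svc(kernel[np.ix_(train, train)], y[train], config)
        scores[test] = svc.decision_function(kernel[np.ix_(test, train)])
    fold_auroc, fold_auprc = [], []
    for f in range(config.cv_folds):
        test = fold_of == f
        if len(np.unique(y[test])) < 2:
            raise ValueError(f"fold {f} contains a single class; use fewer folds")
        fold_auroc.append(float(roc_auc_score(y[test], scores[test])))
        fold_auprc.append(float(average_precision_score(y[test], scores[test])))
    return CvReport(
        fold_auroc=fold_auroc,
        fold_auprc=fold_auprc,
        fold_assignments={ids[i]: int(fold_of[i]) for i in range(len(ids))},
        seed=seed,
    )
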