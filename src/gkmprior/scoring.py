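"""Exhaustive k-mer scoring, region scoring and PWM reconstruction.

A trained gkm-SVM induces a weight over every possible word of its length l:
the decision value the model assigns to that word as a sequence. Because
feature counting is double-stranded, a word and its reverse complement score
identically, so the table is keyed by canonical l-mers (lexicographic min of
the pair) — 4^l / 2 keys for odd l. The table turns the kernel model into a
fast additive scorer: a region's score is the sum of its l-window weights
(the construction deltaSVM builds on), and the top-scoring words align into
a position weight matrix that summarizes the learned motif.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import dna
from .gkm import GkmFeaturizer
from .model import GkmModel, _chromosomes

MAX_TABLE_L = 13  # 4^l memory guard


def enumerate_canonical_kmers(l: int, as_strings: bool = False):
    """All canonical l-mers (every word or its reverse complement, once).

    Canonical representative is the lexicographic minimum of the pair, which
    on base-4 codes is the numeric minimum. Returns sorted integer codes, or
    fixed-width byte strings when ``as_strings``. Count is 4^l/2 for odd l
    (no reverse-complement palindromes exist); even l keeps palindromes once.
    """
    if l < 1:
        raise ValueError("l must be >= 1")
    if l > MAX_TABLE_L:
        raise MemoryError(f"refusing to enumerate 4^{l} k-mers (guard at l <= {MAX_TABLE_L})")
    codes = np.arange(4**l, dtype=np.int64)
    rc = dna.revcomp_codes(codes, l)
    canon = codes[codes <= rc]
    return dna.codes_to_kmers(canon, l) if as_strings else canon


@dataclass
class KmerWeightTable:
    """Model decision value for every l-mer, keyed canonically.

    ``weights`` is indexed by the base-4 code of *any* l-mer (a word and its
    reverse complement hold the same value), which makes sliding-window
    lookups allocation-free.
    """

    l: int
    weights: np.ndarray  # shape (4**l,), weights[c] == weights[revcomp(c)]
    provenance: str = ""

    def __post_init__(self):
        if self.weights.shape != (4**self.l,):
            raise ValueError("weights must have shape (4**l,)")

    def weight_of(self, kmer: str) -> float:
        if len(kmer) != self.l:
            raise ValueError(f"expected a {self.l}-mer")
        return float(self.weights[dna.kmer_to_code(kmer)])

    def canonical_codes(self) -> np.ndarray:
        return enumerate_canonical_kmers(self.l)

    def top(self, n: int) -> tuple[np.ndarray, np.ndarray]:
        """Top-``n`` canonical codes by weight, ties broken lexicographically.

        Entries absent from a partially loaded table (NaN) are excluded.
        """
        canon = self.canonical_codes()
        w = self.weights[canon]
        present = np.isfinite(w)
        canon, w = canon[present], w[present]
        order = np.lexsort((canon, -w))
        sel = order[: min(n, canon.size)]
        return canon[sel], w[sel]

    def save(self, path: str | Path, top_n: int | None = None) -> None:
        """Write a (kmer, weight) TSV, optionally only the top-``top_n``."""
        codes, w = self.top(top_n if top_n is not None else 4**self.l)
        kmers = dna.codes_to_kmers(codes, self.l)
        with open(path, "w") as fh:
            fh.write("kmer\tweight\n")
            for kmer, wt in zip(kmers, w):
                fh.write(f"{kmer.decode()}\t{wt:.17g}\n")

    @classmethod
    def load(cls, path: str | Path, l: int | None = None) -> "KmerWeightTable":
        """Load a (kmer, weight) TSV; absent k-mers become NaN.

        A table saved with ``top_n`` is partial: it supports ``top`` and
        ``weight_of`` on stored words, but not whole-region scoring.
        """
        df = pd.read_csv(path, sep="\t")
        l = l or len(df["kmer"].iloc[0])
        weights = np.full(4**l, np.nan)
        codes = np.array([dna.kmer_to_code(k) for k in df["kmer"]])
        weights[codes] = df["weight"].to_numpy()
        weights[dna.revcomp_codes(codes, l)] = df["weight"].to_numpy()
        return cls(l=l, weights=weights, provenance=str(path))


def score_sequence(model: GkmModel, sequence: str) -> float:
    """SVM decision value of one sequence; positive predicts TF binding."""
    if len(sequence) < model.config.l:
        raise ValueError(f"sequence shorter than l={model.config.l}")
    return float(model.decision_values([sequence])[0])


def build_kmer_weight_table(model: GkmModel, l: int | None = None) -> KmerWeightTable:
    """Score every l-mer with the model, vectorized over the full code space.

    Exploits the structure of single-word feature vectors: one forward
    window contributes one count per gap pattern (norm^2 = C(l,k) per
    strand) plus the strand cross-term where the word and its reverse
    complement read identically at a pattern. Agrees with
    :func:`score_sequence` on every word to float precision.
    """
    l = l or model.config.l
    if l != model.config.l:
        raise ValueError("weight table word length must equal the model's l")
    if l > MAX_TABLE_L:
        raise MemoryError(f"4^{l} weight table exceeds the l <= {MAX_TABLE_L} guard")
    k = model.config.k
    feat = model.featurizer
    # w = sum_i dual_i * phi(s_i)/|phi(s_i)| as a dense feature-space vector
    Xsv = model._sv_matrix()
    w = np.asarray(Xsv.T @ model.dual_coefficients).ravel()

    n = 4**l
    digits = dna.codes_to_digits(np.arange(n, dtype=np.int64), l)
    rc = dna.revcomp_codes(np.arange(n, dtype=np.int64), l)
    pow4 = 4 ** np.arange(k - 1, -1, -1, dtype=np.int64)
    fwd_score = np.zeros(n)
    strand_overlap = np.zeros(n, dtype=np.int64)
    for p_idx, pattern in enumerate(feat.patterns):
        word_codes = digits[:, pattern].astype(np.int64) @ pow4
        fwd_score += w[p_idx * 4**k + word_codes]
        strand_overlap += word_codes == word_codes[rc]
    numerator = fwd_score + fwd_score[rc]
    norm = np.sqrt(2 * feat.n_patterns + 2 * strand_overlap)
    weights = numerator / norm + model.bias
    return KmerWeightTable(l=l, weights=weights, provenance="gkm-svm model")


@dataclass
class RegionScore:
    chrom: str
    start: int
    end: int
    score: float
    best_window: int  # offset of the max-scoring l-window within the region
    name: str = ""


def score_regions(
    table: KmerWeightTable,
    genome,
    regions: pd.DataFrame,
    mode: str = "sliding_sum",
    window: int = 18,
) -> tuple[list[RegionScore], list[tuple[str, str]]]:
    """Score genomic intervals with the k-mer weight table.

    ``sliding_sum`` adds the weights of every l-window in the region (the
    deltaSVM-compatible additive score); ``center_window`` scores only the
    central ``window`` bp the same way. Regions shorter than l are skipped
    and reported. Strand of the reference is irrelevant by canonicalization.
    """
    if mode not in ("sliding_sum", "center_window"):
        raise ValueError(f"unknown mode {mode!r}")
    chroms = _chromosomes(genome)
    results, skipped = [], []
    for row in regions.itertuples(index=False):
        name = str(getattr(row, "name", "") or f"{row.chrom}:{row.start}-{row.end}")
        seq = chroms[row.chrom][row.start : row.end].upper()
        if mode == "center_window" and len(seq) > window:
            off = (len(seq) - window) // 2
            seq = seq[off : off + window]
        if len(seq) < table.l or not dna.is_valid(seq):
            skipped.append((name, "shorter than l" if len(seq) < table.l else "non-ACGT"))
            continue
        codes = dna.window_codes(seq, table.l)
        per_window = table.weights[codes]
        results.append(
            RegionScore(
                chrom=row.chrom, start=row.start, end=row.end,
                score=float(per_window.sum()),
                best_window=int(np.argmax(per_window)),
                name=name,
            )
        )
    return results, skipped


@dataclass
class Pwm:
    """Position probability matrix (columns A, C, G, T; rows sum to 1)."""

    matrix: np.ndarray
    n_contributing_kmers: int = 0
    name: str = "motif"

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=np.float64)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != 4:
            raise ValueError("PWM must be L x 4")
        if not np.allclose(self.matrix.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("PWM rows must sum to 1")

    def __len__(self):
        return self.matrix.shape[0]

    @property
    def consensus(self) -> str:
        return dna.decode(self.matrix.argmax(axis=1).astype(np.uint8))

    def reverse_complement(self) -> "Pwm":
        return Pwm(self.matrix[::-1, ::-1], self.n_contributing_kmers, self.name + "_rc")

    def log_odds(self, seq: str, background: float = 0.25) -> float:
        arr = dna.encode(seq)
        if arr.size != len(self):
            raise ValueError("sequence length must equal PWM length")
        p = self.matrix[np.arange(arr.size), arr]
        return float(np.log2(np.maximum(p, 1e-12) / background).sum())

    def to_meme(self, path: str | Path) -> None:
        """Write MEME minimal motif format."""
        lines = [
            "MEME version 4", "", "ALPHABET= ACGT", "", "strands: + -", "",
            "Background letter frequencies", "A 0.25 C 0.25 G 0.25 T 0.25", "",
            f"MOTIF {self.name}",
            f"letter-probability matrix: alength= 4 w= {len(self)} nsites= "
            f"{max(self.n_contributing_kmers, 1)} E= 0",
        ]
        for row in self.matrix:
            lines.append(" ".join(f"{p:.6f}" for p in row))
        Path(path).write_text("\n".join(lines) + "\n")

    def to_tsv(self, path: str | Path) -> None:
        pd.DataFrame(self.matrix, columns=list("ACGT")).to_csv(path, sep="\t", index=False)


def build_pwm_from_top_kmers(
    table: KmerWeightTable, top_n: int = 1000, max_shift: int = 2,
    pseudocount: float = 0.25,
) -> Pwm:
    """PWM from the top-scoring k-mers by seed-anchored ungapped alignment.

    The highest-weight canonical k-mer acts as the seed; every other top
    k-mer is oriented (forward or reverse complement) and shifted within
    ±``max_shift`` to maximize identity with the seed, then its bases are
    added to the position counts over the overlap. Counts get a
    ``pseudocount`` per base before row normalization. This replaces
    EM-based motif discovery: for fixed-length words an anchored alignment
    already determines the register.
    """
    canon = table.canonical_codes()
    if top_n > canon.size:
        import warnings

        warnings.warn(f"top_n={top_n} exceeds table size {canon.size}; clamping")
        top_n = canon.size
    codes, _ = table.top(top_n)
    l = table.l
    seed = dna.codes_to_digits(codes[:1], l)[0]
    counts = np.zeros((l, 4))
    for code in codes:
        fwd = dna.codes_to_digits(np.array([code]), l)[0]
        best = (-1, None, None)  # identity, digits, shift
        for digs in (fwd, (3 - fwd)[::-1]):
            for shift in range(-max_shift, max_shift + 1):
                # kmer position j aligns to seed position j + shift
                lo, hi = max(0, -shift), min(l, l - shift)
                ident = int((digs[lo:hi] == seed[lo + shift : hi + shift]).sum())
                if ident > best[0]:
                    best = (ident, digs, shift)
        _, digs, shift = best
        lo, hi = max(0, -shift), min(l, l - shift)
        np.add.at(counts, (np.arange(lo + shift, hi + shift), digs[lo:hi].astype(int)), 1.0)
    counts += pseudocount
    return Pwm(counts / counts.sum(axis=1, keepdims=True), n_contributing_kmers=len(codes))


def pwm_information_content(pwm: Pwm) -> np.ndarray:
    """Per-position information content in bits, uniform background.

    IC(pos) = 2 + sum_b p log2 p; 0 for a uniform row, 2 for a point mass.
    """
    p = pwm.matrix
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(p > 0, p * np.log2(p), 0.0)
    return 2.0 + plogp.sum(axis=1)
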