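"""Gapped k-mer feature maps and the gkm kernel.

A gapped k-mer feature is a pair (gap pattern, k-letter word): the gap
pattern chooses k "informative" positions out of a length-l window, and the
word is the string read at those positions. A sequence's feature vector
counts every such pair over all l-windows of the sequence *and* of its
reverse complement, so double-stranded DNA is represented strand-invariantly.

The kernel between two sequences is the cosine similarity (normalized inner
product) of their feature count vectors. Two equivalent computations are
provided:

* an explicit sparse feature expansion (:class:`GkmFeaturizer`), efficient
  for batches of sequences, and
* a window-pair combinatorial identity: the unnormalized inner product
  equals sum over window pairs (u, v) of C(m(u, v), k), where m is the
  number of matching positions — because a gap pattern contributes exactly
  when all k of its positions match. The truncated variant zeroes the
  contribution of window pairs with more than d mismatches, mirroring the
  mismatch cutoff used by large-scale gkm-SVM implementations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from math import comb

import numpy as np
import scipy.sparse as sp

from . import dna


@dataclass(frozen=True)
class ModelConfig:
    """Hyperparameters of the gapped k-mer SVM.

    Defaults follow the standard gkm-SVM training setup for TF ChIP-seq
    peaks: word length l=11, k=7 informative positions, mismatch cutoff
    d=3 (truncated variant only), soft-margin C=1, stopping tolerance
    eps=0.005, 5-fold cross-validation.
    """

    l: int = 11
    k: int = 7
    d: int = 3
    C: float = 1.0
    eps: float = 0.005
    cv_folds: int = 5
    kernel_variant: str = "exact_gkm"

    def __post_init__(self):
        if not (0 < self.k <= self.l):
            raise ValueError(f"require 0 < k <= l, got l={self.l} k={self.k}")
        if self.d > self.l - self.k:
            raise ValueError(f"require d <= l - k, got d={self.d}")
        if self.C <= 0 or self.eps <= 0:
            raise ValueError("C and eps must be positive")
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")
        if self.kernel_variant not in ("exact_gkm", "truncated_gkm"):
            raise ValueError(f"unknown kernel_variant {self.kernel_variant!r}")


class GkmFeaturizer:
    """Explicit gapped k-mer count vectors and kernels.

    Feature ids are ``pattern_index * 4**k + word_code`` over the
    C(l, k) * 4**k dimensional space. Counts include both strands.
    """

    def __init__(self, l: int = 11, k: int = 7):
        if not (0 < k <= l):
            raise ValueError("require 0 < k <= l")
        self.l = l
        self.k = k
        self.patterns = np.array(list(combinations(range(l), k)), dtype=np.int64)
        self.n_patterns = len(self.patterns)  # C(l, k)
        self._pow4 = 4 ** np.arange(k - 1, -1, -1, dtype=np.int64)
        self._offsets = (np.arange(self.n_patterns, dtype=np.int64) * 4**k)[None, :]
        self.n_features = self.n_patterns * 4**k

    def _strand_feature_ids(self, arr: np.ndarray) -> np.ndarray:
        """Feature ids of all windows of one strand; shape (n_windows, P)."""
        n = arr.size - self.l + 1
        if n <= 0:
            return np.empty((0, self.n_patterns), dtype=np.int64)
        win = np.lib.stride_tricks.sliding_window_view(arr, self.l)
        sel = win[:, self.patterns].astype(np.int64)  # (n, P, k)
        codes = sel @ self._pow4
        return codes + self._offsets

    def feature_counts(self, seq: str) -> tuple[np.ndarray, np.ndarray]:
        """Sorted unique feature ids and their counts, both strands."""
        fwd = dna.encode(seq)
        rev = (3 - fwd)[::-1]
        ids = np.concatenate(
            [self._strand_feature_ids(fwd).ravel(), self._strand_feature_ids(rev).ravel()]
        )
        return np.unique(ids, return_counts=True)

    def feature_matrix(self, seqs, normalize: bool = False) -> sp.csr_matrix:
        """Sparse (n_seqs, n_features) count matrix; optionally L2-normalized rows.

        Sequences shorter than l produce all-zero rows (flagged by callers).
        """
        seqs = list(seqs)
        indptr = [0]
        indices: list[np.ndarray] = []
        data: list[np.ndarray] = []
        for s in seqs:
            ids, counts = self.feature_counts(s)
            indices.append(ids)
            data.append(counts.astype(np.float64))
            indptr.append(indptr[-1] + ids.size)
        X = sp.csr_matrix(
            (
                np.concatenate(data) if data else np.empty(0),
                np.concatenate(indices) if indices else np.empty(0, dtype=np.int64),
                np.array(indptr, dtype=np.int64),
            ),
            shape=(len(seqs), self.n_features),
        )
        if normalize:
            norms = np.sqrt(X.multiply(X).sum(axis=1)).A1
            norms[norms == 0] = 1.0
            X = sp.diags(1.0 / norms) @ X
        return X.tocsr()

    def kernel_matrix(self, seqs_a, seqs_b=None) -> np.ndarray:
        """Normalized gkm kernel matrix between two sequence batches.

        K(a, b) = <phi(a), phi(b)> / (|phi(a)| |phi(b)|); rows with zero
        feature norm (sequence shorter than l) give 0 against everything.
        """
        Xa = self.feature_matrix(seqs_a, normalize=True)
        Xb = Xa if seqs_b is None else self.feature_matrix(seqs_b, normalize=True)
        return np.asarray((Xa @ Xb.T).todense())


def _window_code_digits(seq: str, l: int) -> np.ndarray:
    """Digit matrix (n_windows_both_strands, l) of all l-windows, both strands."""
    fwd = dna.encode(seq)
    rev = (3 - fwd)[::-1]
    mats = []
    for arr in (fwd, rev):
        if arr.size >= l:
            mats.append(np.lib.stride_tricks.sliding_window_view(arr, l))
    if not mats:
        return np.empty((0, l), dtype=np.uint8)
    return np.concatenate(mats, axis=0)


def gkm_inner_product_bruteforce(
    seq_a: str, seq_b: str, l: int, k: int, d: int | None = None
) -> float:
    """Unnormalized gkm inner product via the window-pair match identity.

    Sum over all window pairs of C(matches, k); with a mismatch cutoff d,
    pairs with more than d mismatching positions contribute 0.
    """
    wa = _window_code_digits(seq_a, l).astype(np.int16)
    wb = _window_code_digits(seq_b, l).astype(np.int16)
    if wa.size == 0 or wb.size == 0:
        return 0.0
    matches = (wa[:, None, :] == wb[None, :, :]).sum(axis=2)
    weights = np.array([comb(m, k) for m in range(l + 1)], dtype=np.float64)
    if d is not None:
        weights[: l - d] = 0.0
    return float(weights[matches].sum())


def gkm_kernel(seq_a: str, seq_b: str, config: ModelConfig) -> float:
    """Normalized gkm kernel between two sequences under ``config``.

    Returns 0 (by convention) when either sequence is shorter than l.
    """
    d = config.d if config.kernel_variant == "truncated_gkm" else None
    ab = gkm_inner_product_bruteforce(seq_a, seq_b, config.l, config.k, d)
    aa = gkm_inner_product_bruteforce(seq_a, seq_a, config.l, config.k, d)
    bb = gkm_inner_product_bruteforce(seq_b, seq_b, config.l, config.k, d)
    if aa == 0.0 or bb == 0.0:
        return 0.0
    return ab / np.sqrt(aa * bb)
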