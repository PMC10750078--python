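"""deltaSVM allele-effect scoring and variant prioritization.

The deltaSVM score of a single-base variant is the change in the model's
additive sequence score caused by substituting the alternate allele: both
alleles are embedded in the (2l-1) bp genomic window centered on the
variant (every l-window covering the position), each window is scored by
canonical k-mer weight lookup, and delta = alt_score - ref_score. Negative
deltas predict loss of TF binding, positive deltas gain.

Prioritization combines allele effect with regulatory evidence: a candidate
must carry at least one heart-tissue eQTL pair AND pass the delta-magnitude
criterion for at least one TF model; candidates rank by max |delta| across
models.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import dna
from .catalog import EqtlPair, VariantRecord
from .model import _chromosomes
from .scoring import KmerWeightTable


@dataclass
class DeltaSvmResult:
    variant: VariantRecord
    ref_score: float
    alt_score: float
    delta: float  # alt_score - ref_score, exactly
    window_sequence_ref: str
    window_sequence_alt: str


@dataclass
class PrioritizedVariant:
    variant: VariantRecord
    delta_per_model: dict[str, float]
    eqtl_pairs: list[EqtlPair]
    rank: int
    rationale_flags: dict[str, bool] = field(default_factory=dict)

    @property
    def max_abs_delta(self) -> float:
        return max(abs(d) for d in self.delta_per_model.values())


def _sliding_score(table: KmerWeightTable, seq: str) -> float:
    return float(table.weights[dna.window_codes(seq, table.l)].sum())


def delta_svm(table: KmerWeightTable, genome, variant: VariantRecord) -> DeltaSvmResult:
    """deltaSVM of one variant against the reference genome.

    Raises if the variant sits within l-1 bases of a chromosome edge
    (insufficient window context) or if the genome base at the position is
    not the recorded reference allele (coordinate-bug guard).
    """
    chroms = _chromosomes(genome)
    l = table.l
    seq = chroms[variant.chromosome]
    center = variant.position - 1  # to 0-based
    if center - (l - 1) < 0 or center + l > len(seq):
        raise ValueError(
            f"{variant.rsid}: position within {l - 1} bp of a chromosome edge"
        )
    window = seq[center - (l - 1) : center + l].upper()
    if window[l - 1] != variant.ref_allele:
        raise ValueError(
            f"{variant.rsid}: genome base {window[l - 1]!r} at "
            f"{variant.chromosome}:{variant.position} does not match ref allele "
            f"{variant.ref_allele!r}"
        )
    alt_window = window[: l - 1] + variant.alt_allele + window[l:]
    ref_score = _sliding_score(table, window)
    alt_score = _sliding_score(table, alt_window)
    return DeltaSvmResult(
        variant=variant,
        ref_score=ref_score,
        alt_score=alt_score,
        delta=alt_score - ref_score,
        window_sequence_ref=window,
        window_sequence_alt=alt_window,
    )


def delta_svm_batch(
    table: KmerWeightTable, genome, variants: list[VariantRecord]
) -> tuple[list[DeltaSvmResult], list[tuple[str, str]], dict]:
    """deltaSVM over a variant batch with a distribution summary.

    Unsuitable variants (edge-proximal, reference mismatch, unknown
    chromosome) are reported with reasons rather than aborting the batch.
    """
    results, unsuitable = [], []
    chroms = _chromosomes(genome)
    for v in variants:
        if v.chromosome not in chroms:
            unsuitable.append((v.rsid, f"unknown chromosome {v.chromosome}"))
            continue
        try:
            results.append(delta_svm(table, genome, v))
        except ValueError as exc:
            unsuitable.append((v.rsid, str(exc)))
    deltas = np.array([r.delta for r in results])
    summary = {
        "n_scored": len(results),
        "n_unsuitable": len(unsuitable),
        "mean": float(deltas.mean()) if deltas.size else float("nan"),
        "sd": float(deltas.std(ddof=1)) if deltas.size > 1 else float("nan"),
        "quantiles": {
            q: float(np.quantile(deltas, q)) for q in (0.01, 0.25, 0.5, 0.75, 0.99)
        }
        if deltas.size
        else {},
    }
    return results, unsuitable, summary


def prioritize(
    delta_results: dict[str, list[DeltaSvmResult]],
    eqtl_pairs: list[EqtlPair],
    selection: str = "abs_delta_threshold",
    top_k: int = 5,
    abs_delta_quantile: float = 0.99,
    abs_delta_threshold: float | None = None,
) -> list[PrioritizedVariant]:
    """Rank variants by predicted binding change, gated on cardiac eQTLs.

    ``delta_results`` maps TF model name to its batch of deltaSVM results.
    A candidate needs >=1 eQTL pair and, in ``abs_delta_threshold`` mode, a
    |delta| for some TF strictly above the threshold (default: the
    ``abs_delta_quantile`` quantile of that TF's |delta| batch); in
    ``top_k`` mode the k eQTL-supported candidates with largest max |delta|
    are kept. Ranks are contiguous from 1, ordered by max |delta|
    descending with ties broken by rsid.
    """
    if selection not in ("top_k", "abs_delta_threshold"):
        raise ValueError(f"unknown selection mode {selection!r}")
    if not eqtl_pairs:
        import warnings

        warnings.warn("no eQTL pairs supplied; prioritized list is empty")
        return []
    eqtl_by_rsid: dict[str, list[EqtlPair]] = {}
    for p in eqtl_pairs:
        eqtl_by_rsid.setdefault(p.variant_rsid, []).append(p)

    per_variant: dict[str, dict] = {}
    thresholds = {}
    for tf, results in delta_results.items():
        if selection == "abs_delta_threshold":
            if abs_delta_threshold is not None:
                thresholds[tf] = abs_delta_threshold
            else:
                absd = np.abs([r.delta for r in results])
                thresholds[tf] = float(np.quantile(absd, abs_delta_quantile)) if absd.size else np.inf
        for r in results:
            entry = per_variant.setdefault(
                r.variant.rsid, {"variant": r.variant, "delta": {}}
            )
            entry["delta"][tf] = r.delta

    candidates = []
    for rsid, entry in per_variant.items():
        pairs = eqtl_by_rsid.get(rsid, [])
        if not pairs:
            continue
        if selection == "abs_delta_threshold":
            if not any(abs(d) > thresholds[tf] for tf, d in entry["delta"].items()):
                continue
        candidates.append((entry, pairs))

    candidates.sort(key=lambda c: (-max(abs(d) for d in c[0]["delta"].values()), c[0]["variant"].rsid))
    if selection == "top_k":
        candidates = candidates[:top_k]
    out = []
    for rank, (entry, pairs) in enumerate(candidates, start=1):
        out.append(
            PrioritizedVariant(
                variant=entry["variant"],
                delta_per_model=dict(entry["delta"]),
                eqtl_pairs=pairs,
                rank=rank,
                rationale_flags={"large_delta": True, "heart_eqtl": True},
            )
        )
    return out


def delta_results_to_frame(results_per_tf: dict[str, list[DeltaSvmResult]]) -> pd.DataFrame:
    rows = []
    for tf, results in results_per_tf.items():
        for r in results:
            rows.append(
                {"rsid": r.variant.rsid, "tf": tf, "ref_score": r.ref_score,
                 "alt_score": r.alt_score, "delta": r.delta}
            )
    return pd.DataFrame(rows, columns=["rsid", "tf", "ref_score", "alt_score", "delta"])
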