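"""Synthetic inputs for every stage of the prioritization pipeline.

Real runs of this workflow consume TF ChIP-seq peaks on a reference genome,
a GWAS-catalog association table, enhancer and DNase-footprint tracks, LD
proxy tables and tissue eQTL tables. The generators here emulate each of
those inputs with the statistical structure the analysis assumes — a small
i.i.d. background genome, peaks carrying a planted motif whose strength
drives peak signal, association tables mixing cardiovascular and unrelated
traits with indels and incomplete rows, footprints nested in enhancers plus
orphans, block-structured LD with exponential r^2 decay, heart-tissue eQTLs
with planted significant pairs, and noisy saturation-binding gel
intensities — so the whole pipeline is testable without downloads.

Every generator is deterministic under its seed: one global seed fans out
to per-generator subseeds by stable hashing of the generator name, so
adding a generator never perturbs the others. Each generated "observed"
file is accompanied by ground-truth sidecar data; downstream checks read
truth only from sidecars.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import dna, io
from .catalog import DEFAULT_POPULATIONS, HEART_TISSUES, VariantRecord

CVD_TRAITS = (
    "Atrial fibrillation",
    "Coronary artery disease",
    "Stroke",
    "Myocardial infarction",
    "Heart failure",
    "Aortic aneurysm",
    "Cardiomyopathy",
    "Left ventricular mass",
    "Heart rate variability",
    "Coronary artery calcification",
)

NON_CVD_TRAITS = (
    "Height",
    "Body mass index",
    "Type 2 diabetes",
    "Educational attainment",
    "Crohn's disease",
    "Schizophrenia",
    "Bone mineral density",
    "Serum urate levels",
)


def subseed(seed: int, name: str) -> int:
    """Per-generator subseed: stable hash of the generator name mixed with seed."""
    h = hashlib.sha256(f"{seed}:{name}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31)


@dataclass
class SyntheticGenome:
    """A small artificial genome standing in for real sequence context."""

    chromosomes: dict[str, str]
    gc_content: float
    seed: int

    def __post_init__(self):
        for name, seq in self.chromosomes.items():
            if not seq:
                raise ValueError(f"chromosome {name} is empty")
            if not dna.is_valid(seq):
                raise ValueError(f"chromosome {name} contains non-ACGT characters")

    def with_edit(self, chrom: str, start: int, replacement: str) -> "SyntheticGenome":
        """Copy of the genome with ``replacement`` written at ``start`` (0-based)."""
        seq = self.chromosomes[chrom]
        if start < 0 or start + len(replacement) > len(seq):
            raise ValueError("edit outside chromosome bounds")
        new = dict(self.chromosomes)
        new[chrom] = seq[:start] + replacement + seq[start + len(replacement) :]
        return SyntheticGenome(new, self.gc_content, self.seed)


@dataclass
class PlantedMotifSpec:
    """The motif planted into positive peaks (emulating a cardiac TF's site)."""

    pwm: np.ndarray  # L x 4 probabilities, columns A C G T
    name: str = "motif"
    planting_probability: float = 1.0
    strand_policy: str = "both"  # forward | both

    def __post_init__(self):
        self.pwm = np.asarray(self.pwm, dtype=np.float64)
        if self.pwm.ndim != 2 or self.pwm.shape[1] != 4:
            raise ValueError("pwm must be L x 4")
        if self.pwm.shape[0] < 6:
            raise ValueError("motif length must be >= 6")
        if not np.allclose(self.pwm.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("pwm rows must sum to 1")
        if not (0.0 <= self.planting_probability <= 1.0):
            raise ValueError("planting_probability must lie in [0, 1]")
        if self.strand_policy not in ("forward", "both"):
            raise ValueError("strand_policy must be 'forward' or 'both'")

    def __len__(self):
        return self.pwm.shape[0]

    @property
    def consensus(self) -> str:
        return dna.decode(self.pwm.argmax(axis=1).astype(np.uint8))

    def sample(self, rng: np.random.Generator) -> str:
        bases = [int(rng.choice(4, p=row)) for row in self.pwm]
        return dna.decode(np.array(bases, dtype=np.uint8))

    def log_odds(self, seq: str, background: float = 0.25) -> float:
        arr = dna.encode(seq)
        p = self.pwm[np.arange(arr.size), arr]
        return float(np.log2(np.maximum(p, 1e-12) / background).sum())


def default_motif(planting_probability: float = 1.0) -> PlantedMotifSpec:
    """A strong 9 bp homeodomain-like motif (consensus GCACTTAAT).

    Mimics the information content of an NKX2-5-class binding site: a
    near-deterministic 7 bp core (~1.7 bits/position) with softer flanks,
    the "strong motif" regime a well-trained TF classifier operates in.
    """
    consensus = "GCACTTAAT"
    strong, soft = 0.97, 0.85
    rows = []
    for i, b in enumerate(dna.encode(consensus)):
        p_major = soft if i in (0, len(consensus) - 1) else strong
        row = np.full(4, (1 - p_major) / 3)
        row[b] = p_major
        rows.append(row)
    return PlantedMotifSpec(np.array(rows), name="NKX-like", planting_probability=planting_probability)


def generate_genome(
    n_chromosomes: int, length_per_chromosome: int, gc_content: float, seed: int
) -> SyntheticGenome:
    """I.i.d. (order-0) background genome with P(G)+P(C) = gc_content."""
    if n_chromosomes <= 0 or length_per_chromosome <= 0:
        raise ValueError("sizes must be positive")
    if not (0.0 <= gc_content <= 1.0):
        raise ValueError("gc_content must lie in [0, 1]")
    rng = np.random.default_rng(subseed(seed, "genome"))
    p = np.array([(1 - gc_content) / 2, gc_content / 2, gc_content / 2, (1 - gc_content) / 2])
    chroms = {
        f"chr{i + 1}": dna.decode(rng.choice(4, size=length_per_chromosome, p=p).astype(np.uint8))
        for i in range(n_chromosomes)
    }
    return SyntheticGenome(chroms, gc_content, seed)


def _slot_positions(lo: int, hi: int, item_length: int, slot_length: int,
                    n_items: int, rng: np.random.Generator) -> list[int]:
    """Non-overlapping random starts: choose slots, jitter within each slot."""
    n_slots = (hi - lo) // slot_length
    if n_slots < n_items:
        raise ValueError(f"region [{lo},{hi}) too small for {n_items} items of {item_length} bp")
    slots = rng.choice(n_slots, size=n_items, replace=False)
    slack = slot_length - item_length
    offs = rng.integers(0, slack + 1, size=n_items)
    return sorted(int(lo + s * slot_length + o) for s, o in zip(slots, offs))


def _regions_or_whole(genome: SyntheticGenome, regions, margin: int = 0):
    if regions is not None:
        return dict(regions)
    return {c: (margin, len(s) - margin) for c, s in genome.chromosomes.items()}


def generate_peaks(
    genome: SyntheticGenome,
    motif: PlantedMotifSpec,
    n_peaks: int,
    peak_length: int,
    seed: int,
    base_signal: float = 10.0,
    gain: float = 1.0,
    noise_sd: float = 1.0,
    regions: dict | None = None,
):
    """Non-overlapping peaks with planted motif instances and correlated signal.

    With probability ``planting_probability`` a peak receives one motif
    instance sampled from the PWM (written into the returned genome copy) at
    a random offset and strand; its signal is
    ``base_signal + noise + gain * log-odds(instance)`` so signal ranks
    correlate with motif strength. Returns ``(peaks, truth, genome)`` with
    peaks sorted by signal descending; truth records every planted
    placement.
    """
    if peak_length < len(motif):
        raise ValueError("peak_length must be >= motif length")
    rng = np.random.default_rng(subseed(seed, "peaks"))
    regions = _regions_or_whole(genome, regions)
    slot = int(peak_length * 1.5)
    capacity = {c: (hi - lo) // slot for c, (lo, hi) in regions.items()}
    total = sum(capacity.values())
    if total < n_peaks:
        raise ValueError("genome too small for the requested number of peaks")
    # allocate peaks across chromosomes proportionally to capacity
    alloc = {c: int(round(n_peaks * cap / total)) for c, cap in capacity.items()}
    while sum(alloc.values()) < n_peaks:
        alloc[max(capacity, key=lambda x: capacity[x] - alloc[x])] += 1
    while sum(alloc.values()) > n_peaks:
        alloc[max(alloc, key=alloc.get)] -= 1

    chrom_edit = {c: bytearray(s.encode()) for c, s in genome.chromosomes.items()}
    rows, truth_rows = [], []
    for chrom, (lo, hi) in regions.items():
        if alloc.get(chrom, 0) == 0:
            continue
        starts = _slot_positions(lo, hi, peak_length, slot, alloc[chrom], rng)
        for start in starts:
            planted = rng.random() < motif.planting_probability
            offset = strand = instance = None
            logodds = 0.0
            if planted:
                instance = motif.sample(rng)
                strand = "+" if motif.strand_policy == "forward" or rng.random() < 0.5 else "-"
                logodds = motif.log_odds(instance)
                placed = instance if strand == "+" else dna.revcomp(instance)
                offset = int(rng.integers(0, peak_length - len(motif) + 1))
                chrom_edit[chrom][start + offset : start + offset + len(motif)] = placed.encode()
            signal = base_signal + rng.normal(0.0, noise_sd) + (gain * logodds if planted else 0.0)
            rows.append({"chrom": chrom, "start": start, "end": start + peak_length,
                         "score": signal})
            truth_rows.append({"chrom": chrom, "start": start, "end": start + peak_length,
                               "signal": signal, "planted": planted, "offset": offset,
                               "strand": strand, "instance": instance, "log_odds": logodds})
    peaks = pd.DataFrame(rows).sort_values(
        ["score", "chrom", "start"], ascending=[False, True, True], kind="mergesort"
    ).reset_index(drop=True)
    peaks["name"] = [f"peak_{i + 1:05d}" for i in range(len(peaks))]
    peaks["strand"] = "+"
    peaks = peaks[["chrom", "start", "end", "name", "score", "strand"]]
    truth = pd.DataFrame(truth_rows)
    key = peaks.set_index(["chrom", "start"])["name"]
    truth["name"] = [key.loc[(r.chrom, r.start)] for r in truth.itertuples(index=False)]
    out_genome = SyntheticGenome(
        {c: b.decode() for c, b in chrom_edit.items()}, genome.gc_content, genome.seed
    )
    return peaks, truth, out_genome


def generate_gwas_catalog(
    genome: SyntheticGenome,
    n_associations: int,
    fraction_cvd: float = 0.5,
    fraction_indel: float = 0.1,
    fraction_malformed: float = 0.1,
    seed: int = 0,
    site_provider=None,
):
    """A GWAS-catalog-dialect association table with planted row classes.

    Exactly ``round(n * fraction)`` rows are CVD-trait, indel and malformed
    (indel/malformed are mutually exclusive; their fractions must sum to
    <= 1). Malformed rows alternate between an empty CHR_POS and empty
    allele fields — the two concrete readings of "incomplete entries".
    ``site_provider(n_clean_cvd, rng)`` may supply (chrom, pos, alt) sites
    for the clean CVD single-base rows, in order; remaining positions are
    sampled uniformly away from chromosome edges. Returns (table, truth).
    """
    if fraction_indel + fraction_malformed > 1.0:
        raise ValueError("indel + malformed fractions exceed 1 (classes are exclusive)")
    if not (0.0 <= fraction_cvd <= 1.0):
        raise ValueError("fraction_cvd must lie in [0, 1]")
    rng = np.random.default_rng(subseed(seed, "gwas"))
    n = n_associations
    n_cvd = int(round(n * fraction_cvd))
    n_indel = int(round(n * fraction_indel))
    n_malformed = int(round(n * fraction_malformed))

    order = rng.permutation(n)
    is_indel = np.zeros(n, bool)
    is_indel[order[:n_indel]] = True
    is_malformed = np.zeros(n, bool)
    is_malformed[order[n_indel : n_indel + n_malformed]] = True
    is_cvd = np.zeros(n, bool)
    is_cvd[rng.permutation(n)[:n_cvd]] = True

    clean_cvd_rows = np.nonzero(is_cvd & ~is_indel & ~is_malformed)[0]
    sites = list(site_provider(len(clean_cvd_rows), rng)) if site_provider else []
    if len(sites) > len(clean_cvd_rows):
        raise ValueError("site provider returned more sites than clean CVD rows")
    site_for_row = dict(zip(clean_cvd_rows, sites))

    chrom_names = list(genome.chromosomes)
    used_positions = {(c, p) for c, p, _ in sites}

    def random_site():
        while True:
            c = chrom_names[int(rng.integers(len(chrom_names)))]
            p = int(rng.integers(1000, len(genome.chromosomes[c]) - 1000))  # 1-based
            if (c, p) not in used_positions:
                used_positions.add((c, p))
                return c, p

    rows, truth_rows = [], []
    malformed_toggle = 0
    for i in range(n):
        rsid = f"rs{1000000 + i}"
        trait = str(rng.choice(CVD_TRAITS if is_cvd[i] else NON_CVD_TRAITS))
        kind = ""
        if is_malformed[i]:
            kind = "missing_position" if malformed_toggle % 2 == 0 else "missing_allele"
            malformed_toggle += 1
        if i in site_for_row:
            chrom, pos, alt = site_for_row[i]
            ref = genome.chromosomes[chrom][pos - 1]
            if alt is None:
                alt = dna.ALPHABET[(dna.ALPHABET.index(ref) + 1 + int(rng.integers(3))) % 4]
        else:
            chrom, pos = random_site()
            ref = genome.chromosomes[chrom][pos - 1]
            alt = dna.ALPHABET[(dna.ALPHABET.index(ref) + 1 + int(rng.integers(3))) % 4]
        if is_indel[i]:
            extra = dna.decode(rng.integers(0, 4, size=int(rng.integers(1, 4))).astype(np.uint8))
            if rng.random() < 0.5:
                alt = ref + extra  # insertion
            else:
                ref, alt = ref + extra, ref  # deletion
        pos_text, ref_text, alt_text = str(pos), ref, alt
        if kind == "missing_position":
            pos_text = ""
        elif kind == "missing_allele":
            ref_text = alt_text = ""
        rows.append({
            "SNPS": rsid, "CHR_ID": chrom, "CHR_POS": pos_text, "DISEASE/TRAIT": trait,
            "STRONGEST SNP-RISK ALLELE": f"{rsid}-{alt_text or '?'}",
            "REF_ALLELE": ref_text, "ALT_ALLELE": alt_text,
        })
        truth_rows.append({
            "rsid": rsid, "chrom": chrom, "pos": pos, "trait": trait,
            "is_cvd": bool(is_cvd[i]), "is_indel": bool(is_indel[i]),
            "is_malformed": bool(is_malformed[i]), "malformed_kind": kind,
            "ref": ref, "alt": alt,
        })
    return pd.DataFrame(rows), pd.DataFrame(truth_rows)


def generate_regulatory_tracks(
    genome: SyntheticGenome,
    n_enhancers: int,
    enhancer_length: int,
    dgfs_per_enhancer: int,
    dgf_length: int,
    orphan_dgf_fraction: float = 0.0,
    seed: int = 0,
    regions: dict | None = None,
):
    """Enhancer intervals with nested DNase footprints, plus orphan footprints.

    All intervals are 0-based half-open BED6. ``dgfs_per_enhancer``
    footprints are placed wholly inside each enhancer; an orphan fraction of
    the total footprint count falls outside every enhancer. Returns
    ``(enhancers, footprints)``; footprint names carry a ``nested``/
    ``orphan`` label suffix.
    """
    if dgf_length > enhancer_length:
        raise ValueError("dgf_length must be <= enhancer_length")
    if not (0.0 <= orphan_dgf_fraction < 1.0):
        raise ValueError("orphan_dgf_fraction must lie in [0, 1)")
    rng = np.random.default_rng(subseed(seed, "tracks"))
    regions = _regions_or_whole(genome, regions, margin=1000)
    slot = int(enhancer_length * 1.4) + 1
    capacity = {c: (hi - lo) // slot for c, (lo, hi) in regions.items()}
    total = sum(capacity.values())
    if total < n_enhancers:
        raise ValueError("regions too small for the requested enhancers")
    alloc = {c: int(round(n_enhancers * cap / total)) for c, cap in capacity.items()}
    while sum(alloc.values()) < n_enhancers:
        alloc[max(capacity, key=lambda x: capacity[x] - alloc[x])] += 1
    while sum(alloc.values()) > n_enhancers:
        alloc[max(alloc, key=alloc.get)] -= 1

    enh_rows, fp_rows = [], []
    orphan_gaps = []  # space between enhancer slots for orphan placement
    for chrom, (lo, hi) in regions.items():
        if alloc.get(chrom, 0) == 0:
            continue
        starts = _slot_positions(lo, hi, enhancer_length, slot, alloc[chrom], rng)
        for start in starts:
            enh_rows.append({"chrom": chrom, "start": start, "end": start + enhancer_length,
                             "name": f"enh_{chrom}_{start}", "score": 0.0, "strand": "."})
            # partition the enhancer into footprint slots
            fp_slot = enhancer_length // max(dgfs_per_enhancer, 1)
            for j in range(dgfs_per_enhancer):
                off = int(rng.integers(0, fp_slot - dgf_length + 1))
                s = start + j * fp_slot + off
                fp_rows.append({"chrom": chrom, "start": s, "end": s + dgf_length,
                                "name": f"dgf_{chrom}_{s}_nested", "score": 0.0, "strand": "."})
        # gaps between consecutive enhancers (and region edges) host orphans
        edges = [lo]
        for s in starts:
            edges.extend([s, s + enhancer_length])
        edges.append(hi)
        for a, b in zip(edges[::2], edges[1::2]):
            if b - a > dgf_length + 2:
                orphan_gaps.append((chrom, a + 1, b - 1))

    n_inside = len(fp_rows)
    n_orphans = int(round(n_inside * orphan_dgf_fraction / (1.0 - orphan_dgf_fraction)))
    taken: dict[str, list] = {}
    made = 0
    gap_idx = 0
    while made < n_orphans:
        if not orphan_gaps:
            raise ValueError("no room outside enhancers for orphan footprints")
        chrom, a, b = orphan_gaps[gap_idx % len(orphan_gaps)]
        gap_idx += 1
        s = int(rng.integers(a, b - dgf_length))
        if any(s < e and t < s + dgf_length for t, e in taken.get(chrom, [])):
            continue
        taken.setdefault(chrom, []).append((s, s + dgf_length))
        fp_rows.append({"chrom": chrom, "start": s, "end": s + dgf_length,
                        "name": f"dgf_{chrom}_{s}_orphan", "score": 0.0, "strand": "."})
        made += 1
    enhancers = pd.DataFrame(enh_rows, columns=io.BED6_COLUMNS).sort_values(
        ["chrom", "start"]).reset_index(drop=True)
    footprints = pd.DataFrame(fp_rows, columns=io.BED6_COLUMNS).sort_values(
        ["chrom", "start"]).reset_index(drop=True)
    return enhancers, footprints


def generate_ld_table(
    lead_variants: list[VariantRecord],
    populations=DEFAULT_POPULATIONS,
    block_size: int = 5000,
    r2_decay: float = 1.5,
    seed: int = 0,
    genome: SyntheticGenome | None = None,
    n_high_ld_per_lead: int | None = None,
    n_low_ld_per_lead: tuple[int, int] = (1, 3),
    avoid_positions: set | None = None,
):
    """Block-structured LD proxy table with exponential r^2 distance decay.

    Every lead links to itself at r^2 = 1 in every population. Linked
    variants get per-population r^2 values of ``exp(-r2_decay * d /
    block_size)`` times population jitter; r^2 is zero outside the block
    (no rows emitted). When ``n_high_ld_per_lead`` is set, exactly that
    many proxies per lead are guaranteed above r^2 = 0.8 in at least one
    population (short distances) while the low-LD proxies stay below 0.8
    in every population (long distances) — the planned in/out contrast the
    expansion step must detect. Returns (table, truth) where truth lists
    the proxies qualifying at r^2 > 0.8.
    """
    if not populations:
        raise ValueError("population list must be nonempty")
    rng = np.random.default_rng(subseed(seed, "ld"))
    avoid = set(avoid_positions or ())
    rows, truth_rows = [], []
    counter = 0
    for lead in lead_variants:
        chrom_len = len(genome.chromosomes[lead.chromosome]) if genome else None
        for pop in populations:
            rows.append({"lead_rsid": lead.rsid, "linked_rsid": lead.rsid, "population": pop,
                         "r2": 1.0, "distance": 0, "LINKED_CHR": lead.chromosome,
                         "LINKED_POS": lead.position, "LINKED_REF": lead.ref_allele,
                         "LINKED_ALT": lead.alt_allele})
        n_high = n_high_ld_per_lead if n_high_ld_per_lead is not None else 0
        n_low = int(rng.integers(n_low_ld_per_lead[0], n_low_ld_per_lead[1] + 1))
        plans = [("high", None)] * n_high + [("low", None)] * n_low
        if n_high_ld_per_lead is None:
            # purely decay-driven distances across the block
            plans = [("free", None)] * n_low
        for kind, _ in plans:
            if kind == "high":
                dist = int(rng.integers(30, max(31, int(0.05 * block_size))))
            elif kind == "low":
                dist = int(rng.integers(int(0.35 * block_size), block_size))
            else:
                dist = int(rng.integers(30, block_size))
            for _attempt in range(200):
                sign = -1 if rng.random() < 0.5 else 1
                pos = lead.position + sign * dist
                if chrom_len is not None and not (1000 < pos < chrom_len - 1000):
                    dist = max(30, dist // 2)
                    continue
                if (lead.chromosome, pos) in avoid:
                    dist += 7
                    continue
                break
            avoid.add((lead.chromosome, pos))
            counter += 1
            rsid = f"rs{9000000 + counter}"
            if genome is not None:
                ref = genome.chromosomes[lead.chromosome][pos - 1]
            else:
                ref = dna.ALPHABET[int(rng.integers(4))]
            alt = dna.ALPHABET[(dna.ALPHABET.index(ref) + 1 + int(rng.integers(3))) % 4]
            base = float(np.exp(-r2_decay * dist / block_size))
            r2s = {}
            for pop in populations:
                r2 = base * float(rng.uniform(0.90, 1.08))
                if kind == "low":
                    r2 = min(r2, 0.78)
                r2s[pop] = float(np.clip(r2, 0.0, 0.99))
            if kind == "high" and max(r2s.values()) <= 0.8:
                boost_pop = populations[int(rng.integers(len(populations)))]
                r2s[boost_pop] = float(rng.uniform(0.82, 0.98))
            for pop in populations:
                rows.append({"lead_rsid": lead.rsid, "linked_rsid": rsid, "population": pop,
                             "r2": r2s[pop], "distance": dist, "LINKED_CHR": lead.chromosome,
                             "LINKED_POS": pos, "LINKED_REF": ref, "LINKED_ALT": alt})
            truth_rows.append({"lead_rsid": lead.rsid, "linked_rsid": rsid,
                               "max_r2": max(r2s.values()),
                               "qualifies": max(r2s.values()) > 0.8})
    table = pd.DataFrame(rows, columns=["lead_rsid", "linked_rsid", "population", "r2",
                                        "distance", "LINKED_CHR", "LINKED_POS",
                                        "LINKED_REF", "LINKED_ALT"])
    truth = pd.DataFrame(truth_rows, columns=["lead_rsid", "linked_rsid", "max_r2", "qualifies"])
    return table, truth


def generate_eqtl_table(
    variants: list[VariantRecord],
    n_genes: int = 50,
    tissues=("heart atrial appendage", "heart left ventricle", "Liver", "Lung"),
    effect_size_sd: float = 0.4,
    fraction_significant: float = 0.1,
    seed: int = 0,
    p_threshold: float = 0.1,
    heart_tissues=HEART_TISSUES,
    significant_rsids: list[str] | None = None,
    vocabulary: tuple | None = None,
):
    """Tissue eQTL pair table with planted significant heart-tissue pairs.

    A chosen set of variants (``significant_rsids`` or a
    ``fraction_significant`` random draw) gets one heart-tissue pair each
    with p-value strictly below ``p_threshold``; every other emitted pair
    has a p-value at or above it (heart tissues) or any p-value (non-heart,
    exercising the tissue filter). Returns (table, truth) where truth lists
    the planted significant pairs.
    """
    if vocabulary is not None:
        unknown = [t for t in tissues if t not in vocabulary]
        if unknown:
            raise ValueError(f"unknown tissue names: {unknown}")
    rng = np.random.default_rng(subseed(seed, "eqtl"))
    genes = [f"GENE{g:04d}" for g in range(n_genes)]
    heart = [t for t in tissues if t in heart_tissues]
    non_heart = [t for t in tissues if t not in heart_tissues]
    if significant_rsids is None:
        k = int(round(fraction_significant * len(variants)))
        significant_rsids = list(rng.permutation([v.rsid for v in variants]))[:k]
    sig_set = set(significant_rsids)
    missing = sig_set - {v.rsid for v in variants}
    if missing:
        raise ValueError(f"significant rsids not among the variants: {sorted(missing)[:5]}")
    rows, truth_rows = [], []
    for v in variants:
        if v.rsid in sig_set:
            if not heart:
                raise ValueError("no heart tissue in the configured tissues")
            tissue = heart[int(rng.integers(len(heart)))]
            gene = genes[int(rng.integers(n_genes))]
            pval = float(10 ** rng.uniform(-8, np.log10(p_threshold * 0.5)))
            slope = float(rng.normal(0.0, effect_size_sd))
            rows.append({"variant_id": v.rsid, "gene_id": gene, "tissue": tissue,
                         "slope": slope, "pval": pval})
            truth_rows.append({"variant_id": v.rsid, "gene_id": gene, "tissue": tissue,
                               "slope": slope, "pval": pval})
        # decoy pairs: heart but non-significant, or non-heart any p
        for _ in range(int(rng.integers(1, 3))):
            if non_heart and rng.random() < 0.5:
                tissue = non_heart[int(rng.integers(len(non_heart)))]
                pval = float(10 ** rng.uniform(-6, 0))
            else:
                tissue = heart[int(rng.integers(len(heart)))] if heart else tissues[0]
                pval = float(rng.uniform(p_threshold * 1.01, 1.0))
            rows.append({"variant_id": v.rsid, "gene_id": genes[int(rng.integers(n_genes))],
                         "tissue": tissue, "slope": float(rng.normal(0.0, effect_size_sd)),
                         "pval": pval})
    cols = ["variant_id", "gene_id", "tissue", "slope", "pval"]
    return pd.DataFrame(rows, columns=cols), pd.DataFrame(truth_rows, columns=cols)


def generate_emsa_data(
    kd: float,
    bmax: float,
    concentrations=(50.0, 100.0, 500.0, 1000.0, 2000.0),
    noise_sd: float = 0.02,
    n_replicates: int = 3,
    seed: int = 0,
    total_intensity: float = 10000.0,
    background_range: tuple[float, float] = (50.0, 150.0),
) -> pd.DataFrame:
    """Saturation-binding lane intensities under the one-site model.

    The true bound fraction at concentration X is ``bmax * X / (kd + X)``;
    observed fractions add Gaussian noise (sd ``noise_sd``, clipped to
    [0, 1]) and the emitted bound/unbound intensities carry a positive
    per-lane background offset, so background subtraction followed by the
    bound/(bound+unbound) ratio recovers the noisy fraction exactly.
    """
    if kd <= 0:
        raise ValueError("kd must be positive")
    if any(x <= 0 for x in concentrations):
        raise ValueError("concentrations must be positive")
    rng = np.random.default_rng(subseed(seed, "emsa"))
    rows = []
    lane = 0
    for rep in range(1, n_replicates + 1):
        for x in concentrations:
            lane += 1
            frac = bmax * x / (kd + x)
            obs = float(np.clip(frac + rng.normal(0.0, noise_sd) if noise_sd > 0 else frac, 0.0, 1.0))
            bg = float(rng.uniform(*background_range))
            rows.append({"lane": f"L{lane:02d}", "replicate": f"r{rep}",
                         "concentration_nM": float(x),
                         "bound": obs * total_intensity + bg,
                         "unbound": (1.0 - obs) * total_intensity + bg,
                         "background": bg})
    return pd.DataFrame(rows, columns=["lane", "replicate", "concentration_nM",
                                       "bound", "unbound", "background"])


def plant_motif_instances(
    genome: SyntheticGenome,
    motif: PlantedMotifSpec,
    positions: list[tuple[str, int]],
    seed: int = 0,
    use_consensus: bool = False,
):
    """Write motif instances into a genome copy at given (chrom, 0-based start).

    Returns ``(genome, placements)`` with the planted instance sequence per
    site (consensus or PWM-sampled).
    """
    rng = np.random.default_rng(subseed(seed, "plant"))
    placements = []
    g = genome
    for chrom, start in positions:
        inst = motif.consensus if use_consensus else motif.sample(rng)
        g = g.with_edit(chrom, start, inst)
        placements.append({"chrom": chrom, "start": start, "instance": inst})
    return g, placements


def motif_destroying_variants(
    genome: SyntheticGenome,
    motif: PlantedMotifSpec,
    n: int,
    seed: int = 0,
    regions: dict | None = None,
):
    """Plant ``n`` motif instances and return SNVs that disrupt their cores.

    Each instance is PWM-sampled and written into a genome copy at a
    non-overlapping random location; the paired variant substitutes the
    lowest-probability base at the instance's highest-information position.
    Returns ``(genome, variants)``.
    """
    rng = np.random.default_rng(subseed(seed, "destroy"))
    regions = _regions_or_whole(genome, regions, margin=1000)
    L = len(motif)
    ic = 2.0 + np.where(motif.pwm > 0, motif.pwm * np.log2(np.maximum(motif.pwm, 1e-12)), 0).sum(axis=1)
    hot = int(np.argmax(ic))
    chrom_list = list(regions)
    sites: list[tuple[str, int]] = []
    used: set[tuple[str, int]] = set()
    while len(sites) < n:
        chrom = chrom_list[int(rng.integers(len(chrom_list)))]
        lo, hi = regions[chrom]
        start = int(rng.integers(lo, hi - L))
        if any(c == chrom and abs(start - s) < L + 25 for c, s in used):
            continue
        used.add((chrom, start))
        sites.append((chrom, start))
    g, placements = plant_motif_instances(genome, motif, sites, seed=seed)
    variants = []
    for i, pl in enumerate(placements):
        inst = pl["instance"]
        ref = inst[hot]
        worst = dna.ALPHABET[int(np.argmin(motif.pwm[hot]))]
        if worst == ref:
            order = np.argsort(motif.pwm[hot])
            worst = dna.ALPHABET[int(order[1])]
        variants.append(VariantRecord(
            rsid=f"rsX{i:04d}", chromosome=pl["chrom"],
            position=pl["start"] + hot + 1, ref_allele=ref, alt_allele=worst,
        ))
    return g, variants


@dataclass
class SyntheticStudyConfig:
    """Parameters of the fully coordinated synthetic study."""

    n_peaks: int = 500
    peak_length: int = 100
    n_associations: int = 800
    fraction_cvd_traits: float = 0.6
    fraction_indel: float = 0.08
    fraction_malformed: float = 0.07
    n_populations: int = 5
    ld_block_size: int = 5000
    eqtl_tissues: tuple = ("heart atrial appendage", "heart left ventricle", "Liver", "Lung")
    seed: int = 0
    # layout and planting details
    chromosome_length: int = 300_000
    n_enhancers: int = 150
    enhancer_length: int = 500
    dgfs_per_enhancer: int = 2
    dgf_length: int = 21
    orphan_dgf_fraction: float = 0.2
    n_prioritized: int = 5
    n_nested_extra: int = 220
    n_enhancer_only: int = 60
    n_orphan_sites: int = 40
    n_eqtl_genes: int = 60
    n_extra_eqtl_variants: int = 25

    def __post_init__(self):
        for name in ("n_peaks", "peak_length", "n_associations", "n_populations",
                     "ld_block_size"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not (0.0 <= self.fraction_cvd_traits <= 1.0):
            raise ValueError("fraction_cvd_traits must lie in [0, 1]")


@dataclass
class SyntheticStudy:
    """Every pipeline input plus the ground truth that generated it."""

    config: SyntheticStudyConfig
    genome: SyntheticGenome
    motif: PlantedMotifSpec
    peaks: pd.DataFrame
    peak_truth: pd.DataFrame
    enhancers: pd.DataFrame
    footprints: pd.DataFrame
    gwas: pd.DataFrame
    gwas_truth: pd.DataFrame
    ld_table: pd.DataFrame
    ld_truth: pd.DataFrame
    eqtl_table: pd.DataFrame
    eqtl_truth: pd.DataFrame
    emsa: dict
    ground_truth: dict

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        io.write_fasta(self.genome.chromosomes, out / "genome.fa")
        io.write_bed(self.peaks, out / "peaks.bed")
        io.write_tsv(self.peak_truth, out / "peaks_truth.tsv")
        io.write_bed(self.enhancers, out / "enhancers.bed")
        io.write_bed(self.footprints, out / "footprints.bed")
        io.write_tsv(self.gwas, out / "gwas_catalog.tsv")
        io.write_tsv(self.gwas_truth, out / "gwas_truth.tsv")
        io.write_tsv(self.ld_table, out / "ld_pairs.tsv")
        io.write_tsv(self.ld_truth, out / "ld_truth.tsv")
        io.write_tsv(self.eqtl_table, out / "eqtl_pairs.tsv")
        io.write_tsv(self.eqtl_truth, out / "eqtl_truth.tsv")
        for rsid, tables in self.emsa.items():
            for allele, df in tables.items():
                df.to_csv(out / f"emsa_{rsid}_{allele}.csv", index=False)
        (out / "ground_truth.json").write_text(json.dumps(self.ground_truth, indent=2))


def simulate_study(config: SyntheticStudyConfig | None = None, seed: int | None = None) -> SyntheticStudy:
    """Generate the full coordinated synthetic study.

    Plants ``n_prioritized`` consensus motif instances inside footprints
    nested in enhancers, pairs each with a core-disrupting CVD-trait SNV
    and a significant heart-tissue eQTL, and books per-stage ground-truth
    counts by construction, so the catalog -> model -> deltaSVM ->
    prioritize chain can be checked end to end against the sidecar.
    """
    config = config or SyntheticStudyConfig()
    if seed is not None:
        config.seed = seed
    seed = config.seed
    rng = np.random.default_rng(subseed(seed, "study"))
    motif = default_motif()
    L = config.chromosome_length
    genome = generate_genome(2, L, 0.41, seed)

    peak_zone = {"chr1": (1000, 155_000)}
    reg_zone = {"chr1": (160_000, L - 4000), "chr2": (1000, 200_000)}
    background_zone = ("chr2", 205_000, L - 4000)

    peaks, peak_truth, genome = generate_peaks(
        genome, motif, config.n_peaks, config.peak_length, seed, regions=peak_zone
    )
    enhancers, footprints = generate_regulatory_tracks(
        genome, config.n_enhancers, config.enhancer_length, config.dgfs_per_enhancer,
        config.dgf_length, config.orphan_dgf_fraction, seed, regions=reg_zone,
    )
    nested = footprints[footprints["name"].str.endswith("nested")]
    orphans = footprints[footprints["name"].str.endswith("orphan")]

    # --- plant consensus motif instances in chr2 nested footprints ---
    ml = len(motif)
    nested2 = nested[nested["chrom"] == "chr2"].reset_index(drop=True)
    pick = rng.choice(len(nested2), size=config.n_prioritized, replace=False)
    ic = 2.0 + np.where(motif.pwm > 0, motif.pwm * np.log2(np.maximum(motif.pwm, 1e-12)), 0).sum(axis=1)
    hot = int(np.argmax(ic))
    worst_base = dna.ALPHABET[int(np.argmin(motif.pwm[hot]))]
    if worst_base == motif.consensus[hot]:
        worst_base = dna.ALPHABET[int(np.argsort(motif.pwm[hot])[1])]
    plant_sites, prioritized_sites = [], []
    for idx in sorted(int(i) for i in pick):
        fp = nested2.iloc[idx]
        start = int(fp["start"]) + (config.dgf_length - ml) // 2
        plant_sites.append((fp["chrom"], start))
        prioritized_sites.append({"chrom": fp["chrom"], "motif_start": start,
                                  "pos": start + hot + 1,
                                  "ref": motif.consensus[hot], "alt": worst_base})
    genome, _ = plant_motif_instances(genome, motif, plant_sites, seed=seed, use_consensus=True)

    # --- site plan for the clean CVD rows of the association table ---
    used = {(s["chrom"], s["pos"]) for s in prioritized_sites}

    def _in_motif_window(chrom, pos):
        return any(c == chrom and abs(pos - (s + hot + 1)) <= ml + 10 for c, s in plant_sites)

    def _sample_in_intervals(frame, count, label, rng, forbidden_frames=()):
        sites = []
        rows = frame.reset_index(drop=True)
        trees = []
        for ff in forbidden_frames:
            trees.append({(r.chrom, p) for r in ff.itertuples(index=False)
                          for p in range(r.start + 1, r.end + 1)})
        attempts = 0
        while len(sites) < count:
            attempts += 1
            if attempts > 100 * count + 1000:
                raise RuntimeError(f"could not place {count} {label} sites")
            r = rows.iloc[int(rng.integers(len(rows)))]
            pos = int(rng.integers(r["start"] + 1, r["end"] + 1))  # 1-based within interval
            key = (r["chrom"], pos)
            if key in used or _in_motif_window(*key):
                continue
            if any(key in t for t in trees):
                continue
            used.add(key)
            sites.append({"chrom": r["chrom"], "pos": pos, "alt": None, "category": label})
        return sites

    nested_sites = _sample_in_intervals(nested, config.n_nested_extra, "nested", rng)
    enh_only_sites = _sample_in_intervals(enhancers, config.n_enhancer_only, "enhancer_only",
                                          rng, forbidden_frames=(footprints,))
    orphan_sites = _sample_in_intervals(orphans, config.n_orphan_sites, "orphan", rng)

    site_plan_holder: dict = {}

    def site_provider(n_clean_cvd: int, _rng) -> list:
        base = (
            [{"chrom": s["chrom"], "pos": s["pos"], "alt": s["alt"], "category": "prioritized"}
             for s in prioritized_sites]
            + nested_sites + enh_only_sites + orphan_sites
        )
        if n_clean_cvd < len(base):
            raise ValueError(
                f"only {n_clean_cvd} clean CVD rows for {len(base)} planted sites; "
                "raise n_associations or fraction_cvd_traits"
            )
        c, lo, hi = background_zone
        outside = []
        while len(outside) < n_clean_cvd - len(base):
            pos = int(rng.integers(lo, hi))
            if (c, pos) in used:
                continue
            used.add((c, pos))
            outside.append({"chrom": c, "pos": pos, "alt": None, "category": "outside"})
        plan = base + outside
        site_plan_holder["plan"] = plan
        return [(s["chrom"], s["pos"], s["alt"]) for s in plan]

    gwas, gwas_truth = generate_gwas_catalog(
        genome, config.n_associations, config.fraction_cvd_traits, config.fraction_indel,
        config.fraction_malformed, seed, site_provider=site_provider,
    )
    plan = site_plan_holder["plan"]
    # attach categories to the truth rows of clean CVD sites
    cat_by_pos = {(s["chrom"], s["pos"]): s["category"] for s in plan}
    gwas_truth["category"] = [
        cat_by_pos.get((r.chrom, r.pos), "") if (r.is_cvd and not r.is_indel and not r.is_malformed)
        else "" for r in gwas_truth.itertuples(index=False)
    ]

    # --- stage-count bookkeeping, by construction ---
    t = gwas_truth
    clean = t["is_cvd"] & ~t["is_indel"] & ~t["is_malformed"]
    n_parse_rejected = int((t["malformed_kind"] == "missing_position").sum())
    n_after_parse = len(t) - n_parse_rejected
    n_cvd_after_trait = int((t["is_cvd"] & (t["malformed_kind"] != "missing_position")).sum())
    n_snv = int(clean.sum())
    surviving_mask = clean & t["category"].isin(["prioritized", "nested"])
    n_in_regulatory = int(surviving_mask.sum())

    # --- LD on the intersect survivors ---
    survivors = [
        VariantRecord(r.rsid, r.chrom, r.pos, r.ref, r.alt)
        for r in t[surviving_mask].itertuples(index=False)
    ]
    populations = DEFAULT_POPULATIONS[: config.n_populations]
    ld_table, ld_truth = generate_ld_table(
        survivors, populations, config.ld_block_size, seed=seed, genome=genome,
        n_high_ld_per_lead=1, avoid_positions=used,
    )
    n_expanded = len(survivors) + int(ld_truth["qualifies"].sum())

    # --- eQTL over the expanded set ---
    proxies = []
    qual = set(ld_truth.loc[ld_truth["qualifies"], "linked_rsid"])
    seen = set()
    for row in ld_table.itertuples(index=False):
        if row.linked_rsid in qual and row.linked_rsid not in seen:
            seen.add(row.linked_rsid)
            proxies.append(VariantRecord(row.linked_rsid, str(row.LINKED_CHR),
                                         int(row.LINKED_POS), str(row.LINKED_REF),
                                         str(row.LINKED_ALT)))
    expanded = survivors + proxies
    prioritized_rsids = [
        r.rsid for r in t[clean & (t["category"] == "prioritized")].itertuples(index=False)
    ]
    non_prio = [v.rsid for v in expanded if v.rsid not in prioritized_rsids]
    extra_sig = list(rng.permutation(non_prio))[: config.n_extra_eqtl_variants]
    heart = tuple(x for x in config.eqtl_tissues if x in HEART_TISSUES)
    eqtl_table, eqtl_truth = generate_eqtl_table(
        expanded, config.n_eqtl_genes, config.eqtl_tissues, seed=seed,
        significant_rsids=prioritized_rsids + extra_sig, heart_tissues=heart,
    )

    # --- EMSA lane tables for the prioritized variants ---
    emsa = {}
    emsa_truth = {}
    for i, rsid in enumerate(prioritized_rsids):
        kd_ref = float(rng.uniform(150, 300))
        decreased = i % 2 == 0
        kd_alt = kd_ref * 4 if decreased else kd_ref / 4
        emsa[rsid] = {
            "ref": generate_emsa_data(kd_ref, 0.95, seed=subseed(seed, f"emsa-{rsid}-ref")),
            "alt": generate_emsa_data(kd_alt, 0.95, seed=subseed(seed, f"emsa-{rsid}-alt")),
        }
        emsa_truth[rsid] = {"kd_ref": kd_ref, "kd_alt": kd_alt,
                            "direction": "decreased" if decreased else "increased"}

    ground_truth = {
        "seed": seed,
        "motif": {"name": motif.name, "consensus": motif.consensus,
                  "pwm": motif.pwm.tolist(), "hot_position": hot},
        "catalog": {
            "n_rows": len(t),
            "n_parse_rejected": n_parse_rejected,
            "n_after_parse": n_after_parse,
            "n_cvd_after_trait": n_cvd_after_trait,
            "n_snv": n_snv,
            "n_in_regulatory": n_in_regulatory,
            "n_ld_expanded": n_expanded,
            "eqtl": {
                "n_pairs": len(eqtl_truth),
                "n_unique_genes": int(eqtl_truth["gene_id"].nunique()),
                "n_unique_variants": int(eqtl_truth["variant_id"].nunique()),
            },
        },
        "prioritized_rsids": sorted(prioritized_rsids),
        "prioritized_sites": prioritized_sites,
        "emsa": emsa_truth,
    }
    return SyntheticStudy(
        config=config, genome=genome, motif=motif, peaks=peaks, peak_truth=peak_truth,
        enhancers=enhancers, footprints=footprints, gwas=gwas, gwas_truth=gwas_truth,
        ld_table=ld_table, ld_truth=ld_truth, eqtl_table=eqtl_table, eqtl_truth=eqtl_truth,
        emsa=emsa, ground_truth=ground_truth,
    )
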