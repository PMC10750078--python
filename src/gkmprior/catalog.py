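"""GWAS-catalog variant identification: filter, intersect, LD-expand, eQTL-join.

Implements the variant-identification stage of the prioritization workflow:
parse a GWAS-catalog-format association table, keep cardiovascular disease
and trait associations, drop indels and incomplete entries, keep variants
lying inside both a DNase footprint and a putative cardiac enhancer, expand
the surviving set with linkage-disequilibrium proxies (r^2 strictly > 0.8
in at least one population), and join the expanded set to tissue eQTLs
(heart atrial appendage / left ventricle, p < 0.1).

Coordinate conventions: variant positions are 1-based (catalog convention);
interval tracks are 0-based half-open (BED convention). A 1-based position
p falls in half-open [start, end) iff start < p <= end. All conversions
happen in the readers here, nowhere else.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from intervaltree import IntervalTree

# The trait filter applied to the DISEASE/TRAIT column ("cardio" appears
# twice in the published pattern; duplicated alternation terms are harmless).
CVD_TRAIT_PATTERN = (
    "heart|cardiac|aortic|atrial|ventric|cardio|vascular|artery|coronary|"
    "myocardial|valve|cardio|cardium|stroke"
)

DEFAULT_POPULATIONS = ("EUR", "AFR", "SAS", "EAS", "AMR")
HEART_TISSUES = ("heart atrial appendage", "heart left ventricle")

REQUIRED_GWAS_COLUMNS = ("SNPS", "CHR_ID", "CHR_POS", "DISEASE/TRAIT")

_BASES = {"A", "C", "G", "T"}


@dataclass(frozen=True)
class GwasAssociation:
    rsid: str
    chromosome: str
    position: int  # 1-based
    trait: str
    ref_allele: str | None = None
    alt_allele: str | None = None


@dataclass(frozen=True)
class VariantRecord:
    """A biallelic single-base substitution."""

    rsid: str
    chromosome: str
    position: int  # 1-based
    ref_allele: str
    alt_allele: str

    def __post_init__(self):
        if self.ref_allele not in _BASES or self.alt_allele not in _BASES:
            raise ValueError(f"{self.rsid}: alleles must be single bases in ACGT")
        if self.ref_allele == self.alt_allele:
            raise ValueError(f"{self.rsid}: ref and alt alleles must differ")


@dataclass(frozen=True)
class GenomicInterval:
    chromosome: str
    start: int  # 0-based inclusive
    end: int  # exclusive
    label: str = ""

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise ValueError("require 0 <= start < end")


@dataclass(frozen=True)
class LDPair:
    lead_rsid: str
    linked_rsid: str
    population: str
    r2: float
    distance: int


@dataclass(frozen=True)
class EqtlPair:
    variant_rsid: str
    gene_id: str
    tissue: str
    slope: float
    pval: float

    def __post_init__(self):
        if not (0 < self.pval <= 1):
            raise ValueError("pval must lie in (0, 1]")


@dataclass
class CatalogConfig:
    """Tunable thresholds of the variant-identification stage."""

    trait_pattern: str = CVD_TRAIT_PATTERN
    case_sensitive: bool = False
    r2_threshold: float = 0.8  # strict >
    p_threshold: float = 0.1  # strict <
    tissues: tuple = HEART_TISSUES
    populations: tuple = DEFAULT_POPULATIONS
    require_footprint_in_enhancer: bool = False  # both-containment by default
    refilter_ld_proxies: bool = False

    def __post_init__(self):
        if not (0 < self.r2_threshold <= 1):
            raise ValueError("r2_threshold must be in (0, 1]")
        if not (0 < self.p_threshold <= 1):
            raise ValueError("p_threshold must be in (0, 1]")


@dataclass
class RejectionReport:
    rejected: list = field(default_factory=list)  # (row_index, rsid, reason)

    def add(self, idx, rsid, reason):
        self.rejected.append((idx, rsid, reason))

    def __len__(self):
        return len(self.rejected)


def parse_gwas_catalog(path: str | Path) -> tuple[list[GwasAssociation], RejectionReport]:
    """Parse a GWAS-catalog-dialect TSV into associations plus rejects.

    Rows with a missing or non-numeric chromosome position, or a missing
    rsid/chromosome, go to the rejection report rather than being silently
    dropped. Missing required columns raise, naming them. Allele columns
    (REF_ALLELE/ALT_ALLELE, an extension of the catalog dialect) are carried
    through when present; absent or empty alleles leave the fields None.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in REQUIRED_GWAS_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"GWAS catalog file lacks required columns: {missing}")
    out, report = [], RejectionReport()
    col = {c: df.columns.get_loc(c) for c in df.columns}
    for idx, row in enumerate(df.itertuples(index=False, name=None)):
        rsid = row[col["SNPS"]] or ""
        chrom = row[col["CHR_ID"]] or ""
        pos_text = row[col["CHR_POS"]] or ""
        trait = row[col["DISEASE/TRAIT"]]
        if not rsid.strip():
            report.add(idx, rsid, "missing rsid")
            continue
        if not chrom.strip():
            report.add(idx, rsid, "missing chromosome")
            continue
        if not pos_text.strip():
            report.add(idx, rsid, "missing position")
            continue
        try:
            pos = int(pos_text)
        except ValueError:
            report.add(idx, rsid, "non-numeric position")
            continue
        if pos < 1:
            report.add(idx, rsid, "non-positive position")
            continue
        ref = (row[col["REF_ALLELE"]] if "REF_ALLELE" in col else "") or None
        alt = (row[col["ALT_ALLELE"]] if "ALT_ALLELE" in col else "") or None
        out.append(
            GwasAssociation(rsid=rsid, chromosome=chrom, position=pos, trait=trait,
                            ref_allele=ref or None, alt_allele=alt or None)
        )
    return out, report


def filter_cvd_traits(
    associations: list[GwasAssociation],
    pattern: str = CVD_TRAIT_PATTERN,
    case_sensitive: bool = False,
) -> list[GwasAssociation]:
    """Keep associations whose trait matches the CVD pattern; order preserved.

    Matching is substring (regex search), case-insensitive by default since
    catalog trait strings are mixed-case while the published pattern is
    lowercase.
    """
    rx = re.compile(pattern, flags=0 if case_sensitive else re.IGNORECASE)
    return [a for a in associations if rx.search(a.trait or "")]


def drop_non_snv(associations: list[GwasAssociation]) -> list[VariantRecord]:
    """Remove insertions, deletions and incomplete entries.

    Only biallelic single-base substitutions with both alleles present
    survive; each output record carries single-base ref/alt alleles.
    """
    out = []
    for a in associations:
        if not a.ref_allele or not a.alt_allele:
            continue
        ref, alt = a.ref_allele.upper(), a.alt_allele.upper()
        if ref in _BASES and alt in _BASES and ref != alt:
            out.append(VariantRecord(a.rsid, a.chromosome, a.position, ref, alt))
    return out


def _build_trees(intervals: pd.DataFrame) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for row in intervals.itertuples(index=False):
        trees.setdefault(row.chrom, IntervalTree()).addi(row.start, row.end)
    return trees


def _contains_point(trees: dict[str, IntervalTree], chrom: str, pos_1based: int) -> bool:
    tree = trees.get(chrom)
    # 1-based p is inside half-open [start, end) iff start <= p-1 < end
    return bool(tree is not None and tree.overlaps_point(pos_1based - 1))


def intersect_with_regulatory(
    variants: list[VariantRecord],
    enhancers: pd.DataFrame,
    footprints: pd.DataFrame,
    require_footprint_in_enhancer: bool = False,
) -> list[VariantRecord]:
    """Keep variants inside a DNase footprint AND inside an enhancer.

    Both containment tests apply to the variant point; the footprint need
    not be nested in the enhancer unless ``require_footprint_in_enhancer``.
    Variants on chromosomes absent from both tracks are dropped with a
    warning.
    """
    enh_trees = _build_trees(enhancers)
    fp_source = footprints
    if require_footprint_in_enhancer:
        keep = []
        for row in footprints.itertuples(index=False):
            tree = enh_trees.get(row.chrom)
            if tree is not None and any(
                iv.begin <= row.start and row.end <= iv.end for iv in tree.overlap(row.start, row.end)
            ):
                keep.append(row)
        fp_source = pd.DataFrame(keep, columns=footprints.columns)
    fp_trees = _build_trees(fp_source)
    out = []
    missing_chroms = set()
    for v in variants:
        if v.chromosome not in enh_trees and v.chromosome not in fp_trees:
            missing_chroms.add(v.chromosome)
            continue
        if _contains_point(fp_trees, v.chromosome, v.position) and _contains_point(
            enh_trees, v.chromosome, v.position
        ):
            out.append(v)
    if missing_chroms:
        warnings.warn(
            f"variants on chromosomes absent from both tracks were dropped: {sorted(missing_chroms)}"
        )
    return out


def expand_ld(
    variants: list[VariantRecord],
    ld_table: pd.DataFrame,
    r2_threshold: float = 0.8,
    populations: tuple = DEFAULT_POPULATIONS,
) -> tuple[list[VariantRecord], pd.DataFrame]:
    """Add LD proxies with r^2 strictly above threshold in >=1 population.

    Returns the deduplicated union (input leads first, then new proxies in
    rsid order) and a provenance table (linked_rsid, lead_rsid, population,
    r2). Unknown population codes in ``populations`` raise. Proxy
    coordinates/alleles come from the LINKED_* columns of the LD table.
    """
    known = set(ld_table["population"].unique()) | set(DEFAULT_POPULATIONS)
    unknown = [p for p in populations if p not in known]
    if unknown:
        raise ValueError(f"unknown population codes: {unknown}")
    lead_rsids = {v.rsid for v in variants}
    prov_rows = []
    proxies: dict[str, VariantRecord] = {}
    if len(ld_table):
        sub = ld_table[
            ld_table["lead_rsid"].isin(lead_rsids)
            & ld_table["population"].isin(populations)
            & (ld_table["r2"] > r2_threshold)
        ]
        for row in sub.itertuples(index=False):
            prov_rows.append(
                {"linked_rsid": row.linked_rsid, "lead_rsid": row.lead_rsid,
                 "population": row.population, "r2": float(row.r2)}
            )
            if row.linked_rsid in lead_rsids or row.linked_rsid in proxies:
                continue
            proxies[row.linked_rsid] = VariantRecord(
                rsid=row.linked_rsid,
                chromosome=str(row.LINKED_CHR),
                position=int(row.LINKED_POS),
                ref_allele=str(row.LINKED_REF),
                alt_allele=str(row.LINKED_ALT),
            )
    expanded = list(variants) + [proxies[r] for r in sorted(proxies)]
    # keep leads unique too, in case callers passed duplicates
    seen, deduped = set(), []
    for v in expanded:
        if v.rsid not in seen:
            seen.add(v.rsid)
            deduped.append(v)
    prov = pd.DataFrame(prov_rows, columns=["linked_rsid", "lead_rsid", "population", "r2"])
    return deduped, prov


def join_eqtl(
    variants: list[VariantRecord],
    eqtl_table: pd.DataFrame,
    tissues: tuple = HEART_TISSUES,
    p_threshold: float = 0.1,
) -> tuple[list[EqtlPair], dict]:
    """SNP-gene pairs with genotype-dependent expression in the tissues.

    A pair is kept iff its variant is in the input set, its tissue is
    requested, and pval < p_threshold (strict). The summary reports pair,
    unique-gene and unique-variant counts.
    """
    rsids = {v.rsid for v in variants}
    pairs = []
    for row in eqtl_table.itertuples(index=False):
        if (
            row.variant_id in rsids
            and row.tissue in tissues
            and float(row.pval) < p_threshold
        ):
            pairs.append(
                EqtlPair(row.variant_id, row.gene_id, row.tissue,
                         float(row.slope), float(row.pval))
            )
    summary = {
        "n_pairs": len(pairs),
        "n_unique_genes": len({p.gene_id for p in pairs}),
        "n_unique_variants": len({p.variant_rsid for p in pairs}),
    }
    return pairs, summary


@dataclass
class CatalogResult:
    """Outcome of the full filter -> intersect -> expand -> join pipeline."""

    associations: list
    rejects: RejectionReport
    cvd_associations: list
    snvs: list
    in_regulatory: list
    expanded: list
    ld_provenance: pd.DataFrame
    eqtl_pairs: list
    eqtl_summary: dict

    @property
    def stage_counts(self) -> dict:
        return {
            "parsed": len(self.associations),
            "rejected": len(self.rejects),
            "cvd_traits": len(self.cvd_associations),
            "snvs": len(self.snvs),
            "in_regulatory": len(self.in_regulatory),
            "ld_expanded": len(self.expanded),
            "eqtl_pairs": self.eqtl_summary["n_pairs"],
            "eqtl_unique_genes": self.eqtl_summary["n_unique_genes"],
            "eqtl_unique_variants": self.eqtl_summary["n_unique_variants"],
        }


def run_catalog(
    gwas_path,
    enhancers: pd.DataFrame,
    footprints: pd.DataFrame,
    ld_table: pd.DataFrame,
    eqtl_table: pd.DataFrame,
    config: CatalogConfig | None = None,
) -> CatalogResult:
    """Run the whole variant-identification stage on file/table inputs."""
    config = config or CatalogConfig()
    associations, rejects = parse_gwas_catalog(gwas_path)
    cvd = filter_cvd_traits(associations, config.trait_pattern, config.case_sensitive)
    snvs = drop_non_snv(cvd)
    surviving = intersect_with_regulatory(
        snvs, enhancers, footprints, config.require_footprint_in_enhancer
    )
    expanded, prov = expand_ld(surviving, ld_table, config.r2_threshold, config.populations)
    if config.refilter_ld_proxies:
        leads = {v.rsid for v in surviving}
        refiltered = intersect_with_regulatory(
            [v for v in expanded if v.rsid not in leads], enhancers, footprints,
            config.require_footprint_in_enhancer,
        )
        expanded = list(surviving) + refiltered
    pairs, summary = join_eqtl(expanded, eqtl_table, config.tissues, config.p_threshold)
    return CatalogResult(
        associations=associations, rejects=rejects, cvd_associations=cvd, snvs=snvs,
        in_regulatory=surviving, expanded=expanded, ld_provenance=prov,
        eqtl_pairs=pairs, eqtl_summary=summary,
    )


def variants_to_frame(variants: list[VariantRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [(v.rsid, v.chromosome, v.position, v.ref_allele, v.alt_allele) for v in variants],
        columns=["rsid", "chrom", "pos", "ref", "alt"],
    )
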