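"""Positional classification of eCpG-transcript pairs.

Broad categories: *cis* (CpG within 50 kb of the associated gene's span),
*distal* (same chromosome, ≥ 50 kb) and *trans* (different chromosome). Cis
pairs are refined into detailed categories describing where the CpG sits
relative to the associated gene and its neighbors: near the promoter
(±2500 bp of the TSS), in the gene body (> 2500 bp past the TSS, before the
TES), the associated gene being the closest gene up- or downstream, or one of
the non-canonical configurations (another gene's TSS is closer on the
opposite side, another gene's TES is closer, a gene lies between, the CpG is
inside a different gene) — with ``multiple_closer_between`` when more than
one non-canonical condition holds. All upstream/downstream logic is
strand-aware; canonical roles are near_promoter, in_gene_body,
closest_upstream_gene and closest_downstream_gene.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .genome import AnnotationError, CpGSite, GeneModel

CIS_WINDOW = 50_000
PROMOTER_WINDOW = 2_500

CANONICAL = frozenset(
    {"near_promoter", "in_gene_body", "closest_upstream_gene", "closest_downstream_gene"}
)
DETAILED_CATEGORIES = (
    "near_promoter", "in_gene_body", "closest_upstream_gene",
    "closest_downstream_gene", "closer_5prime", "closer_3prime",
    "gene_between", "in_different_gene", "multiple_closer_between",
    "distal", "trans",
)


@dataclass(frozen=True)
class PairClassification:
    broad: str       # cis | distal | trans
    detailed: str    # one of DETAILED_CATEGORIES
    canonical: bool
    signed_distance: int  # bp from CpG to gene span; negative = upstream of TSS


@dataclass(frozen=True)
class GeneBodySubcategory:
    sub: str              # intronic | exonic
    first_exon: bool
    last_exon: bool


@dataclass(frozen=True)
class ProbeLocation:
    """An expression probe with one or more candidate genomic matches.

    Candidates are ``(chrom, start, end, match_rank, gene_id-or-None)``
    tuples with ``match_rank`` in {"primary", "secondary", "other"}.
    """

    probe_id: str
    candidates: tuple

    def __post_init__(self) -> None:
        if not self.candidates:
            raise AnnotationError(f"{self.probe_id}: no candidate locations")


_RANK_ORDER = {"primary": 0, "secondary": 1, "other": 2}


def resolve_probe_location(probe: ProbeLocation, cpg: CpGSite):
    """Pick one genomic location for a multi-mapping expression probe.

    Preference order: candidates annotatable to a gene (when any exist), then
    proximity to the CpG (same-chromosome distance; other chromosomes sort
    last), then match rank primary > secondary > other, then lowest start.
    """
    cands = list(probe.candidates)
    annotatable = [c for c in cands if c[4] is not None]
    if annotatable:
        cands = annotatable

    def distance(c):
        chrom, start, end = c[0], c[1], c[2]
        if chrom != cpg.chrom:
            return float("inf")
        if start <= cpg.pos <= end:
            return 0
        return min(abs(cpg.pos - start), abs(cpg.pos - end))

    cands.sort(key=lambda c: (distance(c), _RANK_ORDER[c[3]], c[1]))
    return cands[0][:3]


def _is_upstream(pos: int, gene: GeneModel) -> bool:
    """True when the point lies on the 5' (TSS) side of the gene span."""
    return pos < gene.start if gene.strand == "+" else pos > gene.end


def _is_downstream(pos: int, gene: GeneModel) -> bool:
    """True when the point lies past the TES (3' side of the span)."""
    return pos > gene.end if gene.strand == "+" else pos < gene.start


def signed_distance(cpg: CpGSite, gene: GeneModel) -> int:
    """Distance from CpG to the gene span: 0 inside, negative upstream of the
    TSS, positive downstream of the TES (strand-aware)."""
    d = gene.distance_to(cpg.pos)
    if d == 0:
        return 0
    return -d if _is_upstream(cpg.pos, gene) else d


def _in_body(pos: int, gene: GeneModel) -> bool:
    """> 2500 bp downstream of the TSS and upstream of the TES."""
    if gene.strand == "+":
        return gene.tss + PROMOTER_WINDOW < pos < gene.tes
    return gene.tes < pos < gene.tss - PROMOTER_WINDOW


def classify_pair(cpg: CpGSite, gene: GeneModel, all_genes) -> PairClassification:
    """Assign the broad and detailed positional category for one pair.

    ``all_genes`` is the full gene complement used for the neighbor-dependent
    categories; the associated gene itself is excluded from the "next closest
    gene" comparisons.
    """
    if gene.start >= gene.end:
        raise AnnotationError(f"{gene.gene_id}: malformed gene (tss=tes)")

    if cpg.chrom != gene.chrom:
        return PairClassification("trans", "trans", False, 0)

    dist = gene.distance_to(cpg.pos)
    sdist = signed_distance(cpg, gene)
    if dist >= CIS_WINDOW:
        return PairClassification("distal", "distal", False, sdist)

    def done(detailed):
        return PairClassification("cis", detailed, detailed in CANONICAL, sdist)

    pos = cpg.pos
    if abs(pos - gene.tss) <= PROMOTER_WINDOW:
        return done("near_promoter")
    if _in_body(pos, gene):
        return done("in_gene_body")

    others = [
        g for g in all_genes
        if g.gene_id != gene.gene_id and g.chrom == cpg.chrom
    ]
    min_other = min((g.distance_to(pos) for g in others), default=None)

    if _is_upstream(pos, gene):
        # ties go to the downstream (TSS-side) gene, i.e. the associated gene
        if min_other is None or abs(pos - gene.tss) <= min_other:
            return done("closest_downstream_gene")
    elif _is_downstream(pos, gene):
        if min_other is None or abs(pos - gene.tes) < min_other:
            return done("closest_upstream_gene")

    d_tss = abs(pos - gene.tss)
    d_tes = abs(pos - gene.tes)
    side = np.sign(gene.tss - pos)

    closer_5 = any(
        np.sign(g.tss - pos) == -side and abs(pos - g.tss) < d_tss
        for g in others
        if np.sign(g.tss - pos) != 0
    )
    closer_3 = any(abs(pos - g.tes) < min(d_tss, d_tes) for g in others)
    between = any(
        min(pos, gene.tss) < g.tss < max(pos, gene.tss) for g in others
    )
    in_other = any(g.contains(pos) for g in others)

    hits = [
        name for name, hit in (
            ("closer_5prime", closer_5), ("closer_3prime", closer_3),
            ("gene_between", between), ("in_different_gene", in_other),
        ) if hit
    ]
    if len(hits) > 1:
        return done("multiple_closer_between")
    if len(hits) == 1:
        return done(hits[0])
    # no non-canonical condition holds (tie edge cases): fall back to the
    # canonical side label
    if _is_downstream(pos, gene):
        return done("closest_upstream_gene")
    return done("closest_downstream_gene")


def genebody_subcategory(cpg: CpGSite, gene: GeneModel) -> GeneBodySubcategory:
    """Exonic/intronic placement of a gene-body CpG, strand-aware.

    Exon membership is by half-open interval overlap; first/last exon refer to
    transcription order.
    """
    if not _in_body(cpg.pos, gene):
        raise ValueError(
            f"{cpg.cpg_id} is not in the body of {gene.gene_id}; "
            "classify_pair must return in_gene_body first"
        )
    tx_exons = gene.exons_transcription_order()
    hit = [i for i, (s, e) in enumerate(tx_exons) if s <= cpg.pos < e]
    if not hit:
        return GeneBodySubcategory("intronic", False, False)
    i = hit[0]
    return GeneBodySubcategory("exonic", i == 0, i == len(tx_exons) - 1)


def relative_proportion_by_distance(ecpg_distances, all_cpg_distances, bins):
    """Per-bin ratio (eCpGs in bin / all eCpGs) / (CpGs in bin / all CpGs).

    Bins with zero array CpGs are reported as NaN (undefined), not zero.
    """
    e = np.asarray(ecpg_distances, dtype=float)
    a = np.asarray(all_cpg_distances, dtype=float)
    if e.size == 0 or a.size == 0:
        raise ValueError("need non-empty distance lists")
    bins = np.asarray(bins, dtype=float)
    if e.min() < bins[0] or e.max() > bins[-1] or a.min() < bins[0] or a.max() > bins[-1]:
        raise ValueError("bins must cover all observations")
    ce, _ = np.histogram(e, bins=bins)
    ca, _ = np.histogram(a, bins=bins)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = (ce / e.size) / (ca / a.size)
    return np.where(ca == 0, np.nan, ratio)


def classify_records(records, genes, cpgs, significant_only=True):
    """Classify every (significant) association record.

    ``records`` is a scan results frame that carries cpg_id, transcript_id,
    effect and tier columns plus a transcript→gene mapping supplied as a
    ``gene_id`` column. Returns a copy with broad/detailed/canonical/
    signed_distance/sign columns appended.
    """
    gene_by_id = {g.gene_id: g for g in genes}
    cpg_by_id = {c.cpg_id: c for c in cpgs}
    gene_list = list(genes)
    out = records.copy()
    if significant_only and "tier" in out.columns:
        out = out[out["tier"] == "significant"].copy()
    broads, details, canonicals, sdists = [], [], [], []
    for cpg_id, gene_id in zip(out["cpg_id"], out["gene_id"]):
        cls = classify_pair(cpg_by_id[cpg_id], gene_by_id[gene_id], gene_list)
        broads.append(cls.broad)
        details.append(cls.detailed)
        canonicals.append(cls.canonical)
        sdists.append(cls.signed_distance)
    out["broad"] = broads
    out["detailed"] = details
    out["canonical"] = canonicals
    out["signed_distance"] = sdists
    out["sign"] = np.where(out["effect"] >= 0, "+", "-")
    return out.reset_index(drop=True)


def find_overlapping_gene_pairs(classified, genes=None):
    """eCpGs significant for two genes: promoter of one, body of the other.

    ``classified`` must carry cpg_id, gene_id, detailed and sign columns
    (significant records only). Returns a list of
    ``(cpg_id, promoter_gene, body_gene, promoter_sign, body_sign)``.
    """
    rows = []
    for cpg_id, sub in classified.groupby("cpg_id", sort=True):
        promoters = sub[sub["detailed"] == "near_promoter"]
        bodies = sub[sub["detailed"] == "in_gene_body"]
        for _, pr in promoters.iterrows():
            for _, br in bodies.iterrows():
                if pr["gene_id"] != br["gene_id"]:
                    rows.append(
                        (cpg_id, pr["gene_id"], br["gene_id"], pr["sign"], br["sign"])
                    )
    return rows
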