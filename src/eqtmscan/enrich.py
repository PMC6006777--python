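"""Interval annotation of CpGs and enrichment statistics.

Covers: CpG-island shore/shelf construction (1.5 kb bands), point-in-interval
annotation of CpGs against arbitrary tracks (ChromHMM states, CGI, TFBS,
lincRNA, sno/miRNA), Fisher 2×2 enrichment in the two designs used for
chromatin features (against all tested CpGs, and within significant pairs),
intermediate-methylation enrichment (mean β in [0.2, 0.8]), gene-body
sign enrichment, and generic hypergeometric term enrichment with
Benjamini–Hochberg FDR.

Intervals are 0-based half-open and every track is merged (sorted,
non-overlapping) on construction, so point membership is a binary search.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

SHORE_WIDTH = 1_500
SHELF_WIDTH = 1_500

#: ChromHMM state groupings used by the enrichment analyses.
PROMOTER_STATES = (1, 2, 3)
STRONG_ENHANCER_STATES = (4, 5)
WEAK_ENHANCER_STATES = (6, 7)
INSULATOR_STATES = (8,)
#: The gene-body sign analysis pools enhancer states 4-8.
GENEBODY_ENHANCER_STATES = (4, 5, 6, 7, 8)


def _merge(intervals):
    """Sort and merge possibly-overlapping half-open intervals per chrom."""
    by_chrom: dict = {}
    for chrom, start, end in intervals:
        if end <= start:
            raise ValueError(f"empty interval {chrom}:{start}-{end}")
        by_chrom.setdefault(chrom, []).append((int(start), int(end)))
    merged = {}
    for chrom, ivals in by_chrom.items():
        ivals.sort()
        out = [list(ivals[0])]
        for s, e in ivals[1:]:
            if s <= out[-1][1]:
                out[-1][1] = max(out[-1][1], e)
            else:
                out.append([s, e])
        merged[chrom] = np.asarray(out, dtype=np.int64)
    return merged


@dataclass
class AnnotationTrack:
    """A named set of genomic intervals, merged on construction."""

    name: str
    intervals: list  # input: iterable of (chrom, start, end)
    _merged: dict = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self._merged = _merge(self.intervals)
        self.intervals = [
            (chrom, int(s), int(e))
            for chrom in sorted(self._merged)
            for s, e in self._merged[chrom]
        ]

    def contains(self, chrom: str, pos: int) -> bool:
        arr = self._merged.get(chrom)
        if arr is None:
            return False
        i = np.searchsorted(arr[:, 0], pos, side="right") - 1
        return i >= 0 and pos < arr[i, 1]

    def total_width(self) -> int:
        return int(sum(e - s for _, s, e in self.intervals))

    def _expanded(self, pad: int, bounds=None) -> list:
        out = []
        for chrom, s, e in self.intervals:
            lo = max(0, s - pad)
            hi = e + pad
            if bounds and chrom in bounds:
                hi = min(hi, bounds[chrom])
            out.append((chrom, lo, hi))
        return out

    def subtract(self, other: "AnnotationTrack", name: str) -> "AnnotationTrack":
        out = []
        for chrom, s, e in self.intervals:
            cuts = other._merged.get(chrom)
            if cuts is None:
                out.append((chrom, s, e))
                continue
            cur = s
            for cs, ce in cuts:
                if ce <= cur or cs >= e:
                    continue
                if cs > cur:
                    out.append((chrom, cur, cs))
                cur = max(cur, ce)
                if cur >= e:
                    break
            if cur < e:
                out.append((chrom, cur, e))
        return AnnotationTrack(name, out)


def build_shores_shelves(cgi: AnnotationTrack, chrom_bounds=None):
    """Shores: 1.5 kb flanks of CpG islands; shelves: the next 1.5 kb.

    Both are clipped at chromosome bounds (``chrom_bounds`` maps chromosome →
    length) and subtracted from the inner layers, so CGI, shore and shelf are
    pairwise disjoint.
    """
    ring1 = AnnotationTrack("_ring1", cgi._expanded(SHORE_WIDTH, chrom_bounds))
    shore = ring1.subtract(cgi, "shore")
    ring2 = AnnotationTrack(
        "_ring2", cgi._expanded(SHORE_WIDTH + SHELF_WIDTH, chrom_bounds)
    )
    shelf = ring2.subtract(ring1, "shelf")
    return shore, shelf


def annotate_cpgs(cpgs, tracks) -> pd.DataFrame:
    """Boolean CpG × track membership matrix (point in half-open interval).

    CpGs on chromosomes absent from every track are kept (all-False rows);
    membership of a point ``pos`` in ``[start, end)`` is start-inclusive.
    """
    data = {
        t.name: [t.contains(c.chrom, c.pos) for c in cpgs] for t in tracks
    }
    return pd.DataFrame(data, index=[c.cpg_id for c in cpgs])


@dataclass(frozen=True)
class EnrichmentResult:
    odds_ratio: float
    ci_low: float
    ci_high: float
    p_value: float
    test_design: str = ""
    table: tuple = ()
    zero_cell: bool = False


def fisher_enrichment(a: int, b: int, c: int, d: int,
                      test_design: str = "") -> EnrichmentResult:
    """Two-sided Fisher exact test on the 2×2 table [[a, b], [c, d]].

    The p-value is computed on the raw counts; the odds ratio is the
    cross-product ratio ad/bc with a Haldane–Anscombe +0.5 correction applied
    to every cell when any cell is zero, and the 95% CI is
    exp(log OR ± 1.96·SE(log OR)) on the (possibly corrected) cells.
    """
    cells = (a, b, c, d)
    if any(x < 0 for x in cells):
        raise ValueError("counts must be non-negative")
    if sum(cells) == 0:
        raise ValueError("all-zero contingency table")
    _, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    zero = any(x == 0 for x in cells)
    aa, bb, cc, dd = ((x + 0.5 for x in cells) if zero else cells)
    orr = (aa * dd) / (bb * cc)
    se = np.sqrt(1 / aa + 1 / bb + 1 / cc + 1 / dd)
    lo, hi = np.exp(np.log(orr) - 1.96 * se), np.exp(np.log(orr) + 1.96 * se)
    return EnrichmentResult(float(orr), float(lo), float(hi), float(p),
                            test_design, cells, zero)


def intermediate_methylation_enrichment(mean_beta, is_significant,
                                        lo: float = 0.2, hi: float = 0.8
                                        ) -> EnrichmentResult:
    """Enrichment of intermediate methylation (``lo ≤ mean β ≤ hi``,
    boundaries inclusive) among significant eCpGs vs the rest."""
    mb = np.asarray(mean_beta, dtype=float)
    sig = np.asarray(is_significant, dtype=bool)
    if mb.min() < 0 or mb.max() > 1:
        raise ValueError("mean β-values must lie in [0, 1]")
    inter = (mb >= lo) & (mb <= hi)
    a = int((inter & sig).sum())
    b = int((~inter & sig).sum())
    c = int((inter & ~sig).sum())
    d = int((~inter & ~sig).sum())
    return fisher_enrichment(a, b, c, d, test_design="all_cpgs")


def genebody_sign_enrichment(records: pd.DataFrame, tracks) -> dict:
    """Negative-vs-positive gene-body eCpG enrichment in each track.

    ``records`` carries gene-body classified associations with columns chrom,
    pos and sign. Returns ``{track_name: EnrichmentResult}`` where each 2×2
    is sign (− / +) × track membership.
    """
    if len(records) == 0:
        raise ValueError("no gene-body records")
    neg = records["sign"].to_numpy() == "-"
    out = {}
    for t in tracks:
        member = np.array(
            [t.contains(ch, p) for ch, p in zip(records["chrom"], records["pos"])]
        )
        a = int((neg & member).sum())
        b = int((neg & ~member).sum())
        c = int((~neg & member).sum())
        d = int((~neg & ~member).sum())
        out[t.name] = fisher_enrichment(a, b, c, d, test_design="within_significant")
    return out


def sign_fractions_by_subregion(records: pd.DataFrame) -> pd.DataFrame:
    """Fraction of negatively correlated gene-body eCpGs per subregion.

    Expects boolean columns intronic/exonic/first_exon/last_exon plus sign;
    the "gene_body" row covers all records.
    """
    rows = []
    masks = {"gene_body": np.ones(len(records), dtype=bool)}
    for col in ("intronic", "exonic", "first_exon", "last_exon"):
        if col in records.columns:
            masks[col] = records[col].to_numpy(dtype=bool)
    neg = records["sign"].to_numpy() == "-"
    for name, mask in masks.items():
        n = int(mask.sum())
        rows.append((name, n, float(neg[mask].mean()) if n else float("nan")))
    return pd.DataFrame(rows, columns=["subregion", "n", "frac_negative"])


@dataclass(frozen=True)
class TermEnrichment:
    term_id: str
    odds_ratio: float
    p_value: float
    fdr: float
    k: int  # selected genes in term
    K: int  # universe genes in term


def term_enrichment(selected, universe, term_map) -> list:
    """One-sided hypergeometric (upper tail) enrichment per term, BH FDR.

    ``selected`` ⊆ ``universe``; ``term_map`` maps term_id → gene set. Terms
    with no gene in the universe are skipped.
    """
    selected = set(selected)
    universe = set(universe)
    if not selected:
        raise ValueError("empty gene selection")
    if not selected <= universe:
        raise ValueError("selected genes must be a subset of the universe")
    N, n = len(universe), len(selected)
    results = []
    for term_id in sorted(term_map):
        term_genes = set(term_map[term_id]) & universe
        K = len(term_genes)
        if K == 0:
            continue
        k = len(term_genes & selected)
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        a, b = k, n - k
        c, d = K - k, (N - n) - (K - k)
        if 0 in (a, b, c, d):
            a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
        results.append((term_id, (a * d) / (b * c), p, k, K))
    if not results:
        return []
    pvals = [r[2] for r in results]
    fdr = multipletests(pvals, method="fdr_bh")[1]
    return [
        TermEnrichment(t, float(orr), p, float(q), k, K)
        for (t, orr, p, k, K), q in zip(results, fdr)
    ]
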