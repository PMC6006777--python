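"""Corroboration of eCpG-transcript pairs between and within studies.

*Between-study*: a pair replicates when CpG ID, expression probe ID, probe
location and direction of correlation all match exactly; the chance level is
estimated by shuffling probe IDs (with their locations) within each study and
broad category.

*Within-study*: for windows of increasing half-width, three nested congruence
fractions over eCpGs having at least one neighboring eCpG in the window —
sharing an associated gene, sharing a gene with the same correlation sign,
and having *all* neighbors share both gene and sign.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass

import numpy as np
import pandas as pd

NEIGHBOR_WINDOWS = (100, 500, 1000, 1500, 2000)


@dataclass(frozen=True)
class EcpgPairKey:
    cpg_id: str
    probe_id: str
    probe_location: tuple  # (chrom, start, end)
    sign: str              # '+' or '-'
    category: str          # cis | distal | trans

    def match_key(self):
        return (self.cpg_id, self.probe_id, self.probe_location, self.sign)


@dataclass(frozen=True)
class CongruenceReport:
    window: int
    frac_share_gene: float
    frac_share_gene_and_sign: float
    frac_all_congruent: float
    n_with_neighbor: int


def match_pairs(study_a, study_b) -> dict:
    """Per-category fraction of study-A pairs with an exact match in study B."""
    b_keys = {k.match_key() for k in study_b}
    counts: dict = defaultdict(lambda: [0, 0])
    for k in study_a:
        c = counts[k.category]
        c[1] += 1
        if k.match_key() in b_keys:
            c[0] += 1
    return {cat: hit / tot for cat, (hit, tot) in counts.items()}


def _shuffled(study, rng) -> list:
    """Shuffle (probe_id, probe_location) jointly within each category."""
    by_cat: dict = defaultdict(list)
    for i, k in enumerate(study):
        by_cat[k.category].append(i)
    out = list(study)
    for idx in by_cat.values():
        perm = rng.permutation(len(idx))
        for slot, src in zip(idx, (idx[j] for j in perm)):
            s = study[src]
            t = study[slot]
            out[slot] = EcpgPairKey(
                cpg_id=t.cpg_id, probe_id=s.probe_id,
                probe_location=s.probe_location, sign=t.sign,
                category=t.category,
            )
    return out


def permutation_null(study_a, study_b, n_perm: int, seed: int) -> pd.DataFrame:
    """Null distribution of per-category overlap under probe-ID shuffling.

    Each permutation independently shuffles probe IDs (carrying their
    locations) within each study and category, then recomputes the overlap
    fractions. Returns a DataFrame with one row per permutation and one
    column per category present in study A.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = np.random.default_rng(seed)
    cats = sorted({k.category for k in study_a})
    rows = []
    for _ in range(n_perm):
        fa = match_pairs(_shuffled(study_a, rng), _shuffled(study_b, rng))
        rows.append([fa.get(c, 0.0) for c in cats])
    return pd.DataFrame(rows, columns=cats)


def neighbor_congruence(ecpgs: pd.DataFrame, windows=NEIGHBOR_WINDOWS) -> list:
    """Congruence of neighboring eCpGs at each window half-width.

    ``ecpgs`` carries one row per significant association with columns
    cpg_id, chrom, pos, gene_id, sign; a CpG may appear in several rows
    (several associated genes). The unit of analysis is the eCpG site; its
    gene set and (gene, sign) set aggregate over its rows. Windows are
    inclusive of the boundary distance and the query site is not its own
    neighbor.
    """
    windows = list(windows)
    if any(w <= 0 for w in windows) or windows != sorted(windows):
        raise ValueError("windows must be positive and sorted")

    sites = (
        ecpgs.groupby("cpg_id", sort=True)
        .agg(chrom=("chrom", "first"), pos=("pos", "first"))
        .reset_index()
    )
    genes_of = ecpgs.groupby("cpg_id")["gene_id"].agg(set).to_dict()
    gene_sign_of = (
        ecpgs.groupby("cpg_id")[["gene_id", "sign"]]
        .apply(lambda df: set(map(tuple, df.values)))
        .to_dict()
    )

    by_chrom: dict = defaultdict(list)
    for row in sites.itertuples(index=False):
        by_chrom[row.chrom].append((row.pos, row.cpg_id))
    for v in by_chrom.values():
        v.sort()

    reports = []
    for w in windows:
        n_with = n_share = n_share_sign = n_all = 0
        for chrom, sited in by_chrom.items():
            positions = [p for p, _ in sited]
            for i, (pos, cid) in enumerate(sited):
                lo = np.searchsorted(positions, pos - w, side="left")
                hi = np.searchsorted(positions, pos + w, side="right")
                neighbors = [sited[j][1] for j in range(lo, hi) if j != i]
                if not neighbors:
                    continue
                n_with += 1
                g = genes_of[cid]
                gs = gene_sign_of[cid]
                share = [bool(g & genes_of[nb]) for nb in neighbors]
                share_sign = [bool(gs & gene_sign_of[nb]) for nb in neighbors]
                if any(share):
                    n_share += 1
                if any(share_sign):
                    n_share_sign += 1
                if all(share_sign):
                    n_all += 1
        if n_with:
            reports.append(CongruenceReport(
                w, n_share / n_with, n_share_sign / n_with, n_all / n_with, n_with,
            ))
        else:
            reports.append(CongruenceReport(w, float("nan"), float("nan"),
                                            float("nan"), 0))
    return reports
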