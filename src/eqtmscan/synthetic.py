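"""Synthetic toy genomes and cohorts with known ground truth.

The generator emulates the statistical structure the association scan assumes:

* bimodal methylation β-values (most CpGs sit near 0 or near 1 across samples,
  a minority are intermediately methylated),
* per-transcript log-expression driven by covariates (age, sex), shared latent
  confounders (cellular heterogeneity acting on both assays), planted
  CpG → transcript effects at a requested variance explained, and Gaussian
  noise,
* a toy genome whose gene/CpG placement instantiates every detailed
  CpG-gene positional category used by the classifier.

All randomness flows through one ``numpy.random.default_rng(seed)``; identical
inputs and seed give bit-identical output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genome import CpGSite, GeneModel, ToyGenome


class SizingError(ValueError):
    """Requested genome cannot be hosted (too many genes / too few chromosomes)."""


class ConfigError(ValueError):
    """Invalid generator configuration."""


# Layout constants for the toy genome (bp). Genes are placed on a regular
# grid with jitter so inter-gene gaps, flanks and a long gene-free tail exist
# on every chromosome; the tail guarantees >50 kb ("distal") placements. The
# first chromosome hosts a long anchor gene with a second gene nested inside
# it (the nested gene's promoter lies in the anchor's body), which
# instantiates the overlapping-gene and CpG-in-different-gene configurations.
_GENE_SPAN = 10_000
_ANCHOR_SPAN = 40_000
_GENE_PITCH = 30_000
_LEAD = 60_000
_CHR1_GAP = 90_000  # distance from anchor start to the chr1 grid genes
_TAIL = 150_000


@dataclass(frozen=True)
class PlantedEffect:
    """Ground truth for one simulated CpG → transcript effect."""

    cpg_id: str
    transcript_id: str
    effect_size: float  # log-expression units per unit β
    variance_explained: float
    sign: str  # '+' or '-'


@dataclass
class SyntheticCohort:
    methylation: pd.DataFrame   # samples × CpGs, β in [0, 1]
    expression: pd.DataFrame    # transcripts × samples, log scale
    covariates: pd.DataFrame    # samples × (age, sex)
    confounder_loadings: np.ndarray  # samples × K
    truth: list = field(default_factory=list)
    transcript_gene: dict = field(default_factory=dict)


def transcript_id_for(gene_id: str) -> str:
    return f"t_{gene_id}"


def generate_genome(
    n_chrom: int,
    genes_per_chrom: int,
    cpg_density: float,
    seed: int,
    chrom_length: int | None = None,
) -> ToyGenome:
    """Build a deterministic toy genome.

    Genes sit on a jittered grid; one pair of genes on the first chromosome
    overlaps (a gene whose promoter lies inside another gene's body) whenever
    ``genes_per_chrom >= 2``. A set of anchor CpGs is placed around the first
    gene so that promoter, gene-body, first-exon, last-exon, intronic,
    near-flank (<50 kb), distal (>50 kb) and trans placements all exist;
    ``cpg_density`` (sites/kb) controls the additional uniform CpG fill.
    """
    if n_chrom < 2:
        raise SizingError("n_chrom must be >= 2: trans pairs require a second chromosome")
    if genes_per_chrom < 1:
        raise SizingError("need at least one gene per chromosome")
    if cpg_density < 0:
        raise ConfigError("cpg_density must be >= 0")

    needed = _LEAD + _CHR1_GAP + max(genes_per_chrom - 2, 0) * _GENE_PITCH + _TAIL
    length = needed if chrom_length is None else int(chrom_length)
    if length < needed:
        raise SizingError(
            f"chromosome length {length} too short for {genes_per_chrom} genes "
            f"(needs >= {needed} bp)"
        )

    rng = np.random.default_rng(seed)
    chromosomes = [(f"chr{i + 1}", length) for i in range(n_chrom)]
    genes: list[GeneModel] = []
    cpgs: list[CpGSite] = []
    positions: dict[str, set] = {c: set() for c, _ in chromosomes}

    def add_cpg(chrom: str, pos: int) -> None:
        pos = int(min(max(pos, 1), length - 1))
        while pos in positions[chrom]:
            pos += 1
        positions[chrom].add(pos)
        cpgs.append(CpGSite(f"cg_{chrom}_{pos:08d}", chrom, pos))

    for ci, (chrom, _) in enumerate(chromosomes):
        for gi in range(genes_per_chrom):
            jitter = int(rng.integers(-2000, 2001))
            if ci == 0 and gi == 0:
                # long anchor gene, fixed orientation for the anchor CpGs below
                strand, s = "+", _LEAD + jitter
                e = s + _ANCHOR_SPAN
                exons = ((s, s + 3000), (s + 4500, s + 6000), (s + 8000, e))
            elif ci == 0 and gi == 1:
                # gene nested in the anchor: its promoter is in the anchor's
                # body, and mid-anchor CpGs sit in a *different* gene than the
                # one they associate with
                s = genes[0].start + 5000
                e = s + 7000
                strand = "+"
                exons = ((s, s + 1500), (s + 3000, e))
            else:
                strand = "+" if (ci + gi) % 2 == 0 else "-"
                offset = _CHR1_GAP + (gi - 2) * _GENE_PITCH if ci == 0 \
                    else gi * _GENE_PITCH
                s = _LEAD + offset + jitter
                e = s + _GENE_SPAN
                # exon layout (genome order): long first block, middle, last
                exons = ((s, s + 3000), (s + 4500, s + 6000), (s + 8000, e))
            genes.append(
                GeneModel(f"g{ci + 1}_{gi + 1}", chrom, strand, s, e, exons)
            )

    # anchor CpGs around the first (+ strand) gene
    a = genes[0]
    chrom = a.chrom
    for pos in (
        a.start - 1000,        # promoter window
        a.start + 2800,        # gene body, inside first exon
        a.start + 9200,        # gene body, inside last exon
        a.start + 3800,        # gene body, intronic
        a.start + 7000,        # gene body, intronic (between middle and last exon)
        a.end + 20_000,        # < 50 kb flank (cis, outside gene)
        length - 2000,         # > 50 kb from every gene on the chromosome
        a.start + 5100,        # promoter of the nested gene, body of the anchor
        a.start + 15_000,      # inside the anchor, past the nested gene's TES
    ):
        add_cpg(chrom, pos)
    add_cpg(chromosomes[1][0], _LEAD // 2)  # different chromosome (trans anchor)

    # uniform fill at cpg_density sites per kb
    n_fill = int(round(cpg_density * length / 1000.0))
    for chrom, _ in chromosomes:
        for pos in sorted(rng.integers(1, length - 1, size=n_fill).tolist()):
            add_cpg(chrom, int(pos))

    cpgs.sort(key=lambda c: (c.chrom, c.pos))
    return ToyGenome(chromosomes, genes, cpgs)


def _draw_beta_matrix(
    rng: np.random.Generator,
    n_samples: int,
    cpg_ids: list,
    bimodal_fraction: float,
    intermediate_ids: set,
) -> pd.DataFrame:
    """β-value mixture giving a bimodal distribution of per-CpG average
    methylation: each bimodal CpG is hypo- or hyper-methylated (coin flip per
    CpG) with samples ~ Beta(0.5, 10) or its reflection, so its average β
    sits near 0 or near 1; intermediate CpGs draw samples ~ Beta(5, 5). CpGs
    listed in ``intermediate_ids`` (planted eCpGs) are always intermediate."""
    p = len(cpg_ids)
    is_bimodal = rng.random(p) < bimodal_fraction
    for i, cid in enumerate(cpg_ids):
        if cid in intermediate_ids:
            is_bimodal[i] = False
    hyper = rng.random(p) < 0.5
    beta = np.empty((n_samples, p))
    for i in range(p):
        if is_bimodal[i]:
            draw = rng.beta(0.5, 10.0, size=n_samples)
            beta[:, i] = 1.0 - draw if hyper[i] else draw
        else:
            beta[:, i] = rng.beta(5.0, 5.0, size=n_samples)
    return pd.DataFrame(beta, columns=cpg_ids)


def generate_cohort(
    genome: ToyGenome,
    n_samples: int,
    n_confounders: int,
    planted: list,
    bimodal_fraction: float = 0.8,
    seed: int = 0,
    confounder_meth_sd: float = 0.05,
    noise_sd: float = 1.0,
) -> SyntheticCohort:
    """Simulate a methylation + expression cohort over a toy genome.

    ``planted`` is a list of ``(cpg_id, transcript_id, variance_explained,
    sign)``; each planted effect's coefficient is calibrated against the
    realized variances so the requested fraction of that transcript's
    expression variance is explained by the CpG's β (within Monte-Carlo
    tolerance). Shared latent confounders load on expression (per-transcript
    weights ~ N(0,1)) and, weakly, on methylation (per-CpG weights ~
    N(0, ``confounder_meth_sd``)), mimicking cellular heterogeneity visible
    in both assays.
    """
    if n_samples < 2:
        raise ConfigError("n_samples must be >= 2")
    if not 0 <= bimodal_fraction <= 1:
        raise ConfigError("bimodal_fraction must be in [0, 1]")

    cpg_ids = [c.cpg_id for c in genome.cpgs]
    gene_ids = [g.gene_id for g in genome.genes]
    transcript_ids = [transcript_id_for(g) for g in gene_ids]
    tx_index = {t: i for i, t in enumerate(transcript_ids)}
    cpg_index = {c: i for i, c in enumerate(cpg_ids)}

    planted_norm = []
    for cpg_id, tx_id, ve, sign in planted:
        if cpg_id not in cpg_index:
            raise ConfigError(f"planted CpG {cpg_id!r} not in genome")
        if tx_id not in tx_index:
            raise ConfigError(f"planted transcript {tx_id!r} not in genome")
        if not 0 <= ve < 1:
            raise ConfigError(f"variance_explained must be in [0, 1): got {ve}")
        if sign not in ("+", "-"):
            raise ConfigError(f"sign must be '+' or '-': got {sign!r}")
        planted_norm.append((cpg_id, tx_id, float(ve), sign))

    rng = np.random.default_rng(seed)
    sample_ids = [f"S{i + 1:04d}" for i in range(n_samples)]

    age = rng.uniform(18.0, 78.0, size=n_samples)
    sex = rng.integers(0, 2, size=n_samples).astype(float)
    covars = pd.DataFrame({"age": age, "sex": sex}, index=sample_ids)

    # methylation
    meth = _draw_beta_matrix(
        rng, n_samples, cpg_ids, bimodal_fraction,
        intermediate_ids={c for c, _, _, _ in planted_norm},
    )
    meth.index = sample_ids

    loadings = rng.standard_normal((n_samples, n_confounders))
    if n_confounders > 0:
        cpg_weights = rng.normal(0.0, confounder_meth_sd, size=(n_confounders, len(cpg_ids)))
        meth.loc[:, :] = np.clip(meth.values + loadings @ cpg_weights, 0.0, 1.0)

    # expression: intercept + covariates + confounders + noise (planted added after)
    m = len(transcript_ids)
    baseline = rng.normal(7.0, 1.0, size=m)
    expr = np.tile(baseline[:, None], (1, n_samples))
    affected = rng.random(m) < 0.10
    age_coef = np.where(affected, rng.normal(0.0, 0.01, size=m), 0.0)
    sex_coef = np.where(affected, rng.normal(0.0, 0.3, size=m), 0.0)
    expr += age_coef[:, None] * age[None, :] + sex_coef[:, None] * sex[None, :]
    if n_confounders > 0:
        tx_weights = rng.standard_normal((n_confounders, m))
        expr += (loadings @ tx_weights).T
    expr += rng.normal(0.0, noise_sd, size=(m, n_samples))

    truth: list[PlantedEffect] = []
    for cpg_id, tx_id, ve, sign in planted_norm:
        k = tx_index[tx_id]
        b = meth[cpg_id].to_numpy()
        v_rest = float(np.var(expr[k], ddof=1))
        v_b = float(np.var(b, ddof=1))
        if v_b <= 0:
            raise ConfigError(f"planted CpG {cpg_id!r} has zero β variance")
        a = 0.0 if ve == 0 else math.sqrt(ve / (1.0 - ve) * v_rest / v_b)
        if sign == "-":
            a = -a
        expr[k] = expr[k] + a * b
        truth.append(PlantedEffect(cpg_id, tx_id, a, ve, sign))

    expression = pd.DataFrame(expr, index=transcript_ids, columns=sample_ids)
    return SyntheticCohort(
        methylation=meth,
        expression=expression,
        covariates=covars,
        confounder_loadings=loadings,
        truth=truth,
        transcript_gene=dict(zip(transcript_ids, gene_ids)),
    )
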