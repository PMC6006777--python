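"""File formats, pipeline configuration and the end-to-end driver.

Formats: TSV matrices (methylation samples × CpGs, expression transcripts ×
samples, covariates samples × columns), BED (3+ columns, 0-based half-open)
for annotation tracks, BED12-like gene models, a CpG position TSV and a UCSC
custom track for eCpGs. Every writer emits a header (BED excepted), stable
column order and deterministic row order; write → read round-trips are
identity.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import classify as _classify
from . import corroborate as _corroborate
from . import enrich as _enrich
from . import lmm as _lmm
from . import synthetic as _synthetic
from .genome import CpGSite, GeneModel, ToyGenome

log = logging.getLogger("eqtmscan")


class BedParseError(ValueError):
    pass


# ---------------------------------------------------------------- readers

def read_bed(path, name: str | None = None) -> _enrich.AnnotationTrack:
    """Read a BED (≥3 columns) file into a merged AnnotationTrack."""
    intervals = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise BedParseError(f"{path}: line {lineno}: expected >=3 columns")
            try:
                intervals.append((parts[0], int(parts[1]), int(parts[2])))
            except ValueError as exc:
                raise BedParseError(f"{path}: line {lineno}: {exc}") from exc
    return _enrich.AnnotationTrack(name or Path(path).stem, intervals)


def read_chromhmm_bed(path) -> dict:
    """Read a ChromHMM segmentation BED; returns {state_number: track}.

    The name column is expected to look like ``4_Strong_Enhancer`` (leading
    integer state number).
    """
    by_state: dict = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise BedParseError(f"{path}: line {lineno}: need a name column")
            state = int(parts[3].split("_")[0])
            by_state.setdefault(state, []).append(
                (parts[0], int(parts[1]), int(parts[2]))
            )
    return {
        s: _enrich.AnnotationTrack(f"chromhmm_state_{s}", iv)
        for s, iv in sorted(by_state.items())
    }


def read_gene_models(path) -> list:
    """Read BED12-like gene models (strand-aware TSS/TES, exon blocks)."""
    genes = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            p = line.split("\t")
            if len(p) < 12:
                raise BedParseError(f"{path}: line {lineno}: expected 12 columns")
            chrom, start, end, gene_id, _, strand = p[0], int(p[1]), int(p[2]), p[3], p[4], p[5]
            if strand not in ("+", "-"):
                raise BedParseError(f"{path}: line {lineno}: bad strand {strand!r}")
            sizes = [int(x) for x in p[10].rstrip(",").split(",")]
            starts = [int(x) for x in p[11].rstrip(",").split(",")]
            exons = tuple((start + s, start + s + sz) for s, sz in zip(starts, sizes))
            genes.append(GeneModel(gene_id, chrom, strand, start, end, exons))
    return genes


def write_gene_models(genes, path) -> None:
    with open(path, "w") as fh:
        for g in sorted(genes, key=lambda g: (g.chrom, g.start, g.gene_id)):
            sizes = ",".join(str(e - s) for s, e in g.exons)
            starts = ",".join(str(s - g.start) for s, e in g.exons)
            fh.write(
                "\t".join(map(str, [
                    g.chrom, g.start, g.end, g.gene_id, 0, g.strand,
                    g.start, g.end, "0,0,0", len(g.exons), sizes, starts,
                ])) + "\n"
            )


def write_bed(track: _enrich.AnnotationTrack, path) -> None:
    with open(path, "w") as fh:
        for chrom, s, e in track.intervals:
            fh.write(f"{chrom}\t{s}\t{e}\t{track.name}\n")


def read_cpg_table(path) -> list:
    df = pd.read_csv(path, sep="\t")
    return [CpGSite(r.cpg_id, r.chrom, int(r.pos)) for r in df.itertuples()]


def write_cpg_table(cpgs, path) -> None:
    pd.DataFrame(
        [(c.cpg_id, c.chrom, c.pos) for c in cpgs],
        columns=["cpg_id", "chrom", "pos"],
    ).sort_values(["chrom", "pos"]).to_csv(path, sep="\t", index=False)


def write_genome(genome: ToyGenome, outdir) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_gene_models(genome.genes, outdir / "genes.bed12")
    write_cpg_table(genome.cpgs, outdir / "cpgs.tsv")
    with open(outdir / "chromosomes.tsv", "w") as fh:
        fh.write("chrom\tlength\n")
        for name, length in genome.chromosomes:
            fh.write(f"{name}\t{length}\n")


def read_matrix(path, index_col=0) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=index_col)


def write_matrix(df: pd.DataFrame, path, index_label: str) -> None:
    df.to_csv(path, sep="\t", index_label=index_label, float_format="%.10g")


def write_cohort(cohort: _synthetic.SyntheticCohort, outdir) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_matrix(cohort.methylation, outdir / "methylation.tsv", "sample_id")
    write_matrix(cohort.expression, outdir / "expression.tsv", "transcript_id")
    write_matrix(cohort.covariates, outdir / "covariates.tsv", "sample_id")
    pd.DataFrame(
        [dataclasses.asdict(t) for t in cohort.truth],
        columns=["cpg_id", "transcript_id", "effect_size",
                 "variance_explained", "sign"],
    ).to_csv(outdir / "truth.tsv", sep="\t", index=False)
    pd.DataFrame(
        sorted(cohort.transcript_gene.items()),
        columns=["transcript_id", "gene_id"],
    ).to_csv(outdir / "transcript_gene.tsv", sep="\t", index=False)


def write_ucsc_track(classified: pd.DataFrame, cpgs, path,
                     track_name: str = "eCpGs") -> None:
    """UCSC custom BED track: one line per significant eCpG association.

    name = associated gene, score = min(1000, −10·log10 p), strand = sign of
    the correlation.
    """
    pos_of = {c.cpg_id: (c.chrom, c.pos) for c in cpgs}
    with open(path, "w") as fh:
        fh.write(f'track name="{track_name}" visibility=2\n')
        for row in classified.sort_values(["cpg_id", "gene_id"]).itertuples():
            chrom, pos = pos_of[row.cpg_id]
            score = int(min(1000, -10.0 * np.log10(max(row.p, 1e-300))))
            fh.write(
                f"{chrom}\t{pos}\t{pos + 1}\t{row.gene_id}\t{score}\t{row.sign}\n"
            )


# ------------------------------------------------------------ configuration

@dataclass
class PipelineConfig:
    """All pipeline thresholds and simulation parameters in one place.

    Defaults are the scan's reference values: suggestive 1e-5 / significant
    1e-11 p-value tiers, GIF cap 2, 50 kb cis window, 2.5 kb promoter window,
    1.5 kb shore/shelf bands, neighbor windows 100–2000 bp.
    """

    outdir: str = "eqtm_run"
    seed: int = 1
    # simulation
    simulate: bool = True
    n_chrom: int = 2
    genes_per_chrom: int = 5
    cpg_density: float = 0.3
    n_samples: int = 100
    n_confounders: int = 2
    bimodal_fraction: float = 0.8
    planted: list = field(default_factory=list)  # (cpg_id, tx_id, ve, sign)
    n_planted_auto: int = 3
    planted_ve: float = 0.4
    # input paths (used when simulate is False)
    methylation: str | None = None
    expression: str | None = None
    covariates: str | None = None
    genes: str | None = None
    cpgs: str | None = None
    transcript_gene: str | None = None
    # thresholds
    alpha_suggestive: float = 1e-5
    alpha_significant: float = 1e-11
    gif_max: float = 2.0
    cis_window: int = 50_000
    promoter_window: int = 2_500
    shore_width: int = 1_500
    neighbor_windows: tuple = _corroborate.NEIGHBOR_WINDOWS
    n_perm: int = 1000

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def validate(self) -> None:
        for name in ("alpha_suggestive", "alpha_significant", "gif_max",
                     "cis_window", "promoter_window", "shore_width"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


# ---------------------------------------------------------------- pipeline

def _auto_planted(genome: ToyGenome, cfg: PipelineConfig):
    """Plant effects on the first few genes, each from a mid-gene-body CpG."""
    planted = []
    for g in genome.genes[: cfg.n_planted_auto]:
        body = [c for c in genome.cpgs
                if c.chrom == g.chrom and g.start < c.pos < g.end]
        near = body or sorted(
            (c for c in genome.cpgs if c.chrom == g.chrom),
            key=lambda c: g.distance_to(c.pos),
        )
        sign = "-" if len(planted) % 2 == 0 else "+"
        planted.append(
            (near[0].cpg_id, _synthetic.transcript_id_for(g.gene_id),
             cfg.planted_ve, sign)
        )
    return planted


def run_pipeline(cfg: PipelineConfig) -> Path:
    """simulate (optional) → scan → GIF filter → classify → enrich → reports.

    Writes all outputs under ``cfg.outdir`` plus a ``run_log.json`` with the
    seed, thresholds and per-stage record counts. Deterministic for a fixed
    config + seed.
    """
    cfg.validate()
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    counts: dict = {}

    if cfg.simulate:
        log.info("stage simulate: generating toy genome and cohort")
        genome = _synthetic.generate_genome(
            cfg.n_chrom, cfg.genes_per_chrom, cfg.cpg_density, cfg.seed
        )
        planted = list(cfg.planted) or _auto_planted(genome, cfg)
        cohort = _synthetic.generate_cohort(
            genome, cfg.n_samples, cfg.n_confounders, planted,
            cfg.bimodal_fraction, cfg.seed + 1,
        )
        write_genome(genome, outdir / "genome")
        write_cohort(cohort, outdir / "cohort")
        meth, expr, covars = cohort.methylation, cohort.expression, cohort.covariates
        genes, cpgs = genome.genes, genome.cpgs
        tx_gene = cohort.transcript_gene
    else:
        for name in ("methylation", "expression", "covariates", "genes",
                     "cpgs", "transcript_gene"):
            if getattr(cfg, name) is None:
                raise ValueError(f"config requires {name!r} when simulate is off")
        meth = read_matrix(cfg.methylation)
        expr = read_matrix(cfg.expression)
        covars = read_matrix(cfg.covariates)
        genes = read_gene_models(cfg.genes)
        cpgs = read_cpg_table(cfg.cpgs)
        tx_gene = dict(
            pd.read_csv(cfg.transcript_gene, sep="\t").to_numpy()
        )
    counts["samples"] = len(meth.index)
    counts["cpgs_in"] = meth.shape[1]
    counts["transcripts_in"] = expr.shape[0]

    log.info("stage scan: %d transcripts x %d CpGs", expr.shape[0], meth.shape[1])
    results = _lmm.scan(meth, expr, covars,
                        suggestive=cfg.alpha_suggestive,
                        significant=cfg.alpha_significant)
    gifs = _lmm.gif_table(results, cfg.gif_max)
    gifs.to_csv(outdir / "gif.tsv", sep="\t", index=False)
    filtered = _lmm.filter_by_gif(results, cfg.gif_max)
    counts["pairs_tested"] = len(results)
    counts["transcripts_gif_pass"] = int(gifs["passed"].sum())
    counts["pairs_after_gif"] = len(filtered)
    filtered.to_csv(outdir / "results.tsv", sep="\t", index=False,
                    float_format="%.6g")

    log.info("stage classify")
    pos_of = {c.cpg_id: c for c in cpgs}
    filtered = filtered.assign(
        gene_id=[tx_gene[t] for t in filtered["transcript_id"]]
    )
    classified = _classify.classify_records(filtered, genes, cpgs)
    classified["chrom"] = [pos_of[c].chrom for c in classified["cpg_id"]]
    classified["pos"] = [pos_of[c].pos for c in classified["cpg_id"]]
    counts["significant_pairs"] = len(classified)
    classified.to_csv(outdir / "classified.tsv", sep="\t", index=False,
                      float_format="%.6g")
    if len(classified):
        write_ucsc_track(classified, cpgs, outdir / "ecpgs_track.bed")
    else:
        log.info("stage classify: no significant pairs; downstream "
                 "enrichment/corroboration skipped")

    log.info("stage enrich")
    if len(classified):
        mean_beta = meth.mean(axis=0)
        sig_cpgs = set(classified["cpg_id"])
        res = _enrich.intermediate_methylation_enrichment(
            mean_beta.to_numpy(),
            mean_beta.index.isin(sig_cpgs),
        )
        pd.DataFrame([{
            "analysis": "intermediate_methylation",
            "odds_ratio": res.odds_ratio, "ci_low": res.ci_low,
            "ci_high": res.ci_high, "p": res.p_value,
        }]).to_csv(outdir / "enrichment.tsv", sep="\t", index=False,
                   float_format="%.6g")

        log.info("stage corroborate (within-study congruence)")
        reports = _corroborate.neighbor_congruence(
            classified, cfg.neighbor_windows
        )
        pd.DataFrame([dataclasses.asdict(r) for r in reports]).to_csv(
            outdir / "congruence.tsv", sep="\t", index=False,
            float_format="%.6g",
        )

    counts["thresholds"] = {
        "alpha_suggestive": cfg.alpha_suggestive,
        "alpha_significant": cfg.alpha_significant,
        "gif_max": cfg.gif_max, "cis_window": cfg.cis_window,
        "promoter_window": cfg.promoter_window,
    }
    counts["seed"] = cfg.seed
    with open(outdir / "run_log.json", "w") as fh:
        json.dump(counts, fh, indent=2, sort_keys=True)
    return outdir
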