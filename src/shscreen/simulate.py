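"""Synthetic inputs with known ground truth for every pipeline stage.

Three generators cover the pipeline's inputs end to end:

* :func:`simulate_screen` — hairpin count tables over an erythroid
  differentiation time course (days 4..16, three donor replicates) in which
  each gene carries a true per-day dropout/enrichment slope ``gamma_g``
  (log2 units per day) and each hairpin a slope deviation ``delta_h``
  modelling knockdown efficiency and off-target drift. Counts are drawn
  negative-binomially (gamma-Poisson; dispersion 0 degrades to Poisson).
* :func:`simulate_genome_toy` — a toy chromosome with LD blocks built by
  construction (within-block dosages are noisy copies of a latent
  haplotype), recombination hotspots between blocks, gene models and one
  sentinel SNP per block, for exercising locus-to-gene nomination.
* :func:`simulate_annotations` — external validation axes (essentiality
  scores, stage expression, coding-variant flags, a gold-standard list)
  wired to the simulated truth so that enrichment is present exactly when
  true effects exist.

All randomness flows from a single :func:`numpy.random.default_rng` stream
per call; identical seeds give byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .enrich import AnnotationBundle
from .preprocess import CountMatrix, sample_name

DEFAULT_TIME_GRID = (4, 6, 9, 12, 14, 16)


@dataclass
class SimConfig:
    """Parameters of the screen simulator.

    Slopes are in log2 fold change per day. ``dispersion`` is the
    negative-binomial overdispersion phi in Var = mu + phi * mu^2.
    ``sigma_hairpin`` is the SD of the per-hairpin slope deviation delta_h;
    ``sigma_resid`` the SD of residual log2-abundance noise per
    hairpin x sample. Control genes (positive/erythroid/negative controls,
    mirroring a real library's composition) are off by default.
    """

    n_loci: int = 50
    n_genes: int = 200
    hairpins_per_gene: tuple[int, int] = (5, 7)
    n_replicates: int = 3
    time_grid: tuple[int, ...] = DEFAULT_TIME_GRID
    depth_per_sample: float = 1e7
    dispersion: float = 0.05
    sigma_hairpin: float = 0.05
    sigma_resid: float = 0.1
    effect_fraction: float = 0.1
    effect_range: tuple[float, float] = (0.15, 0.3)
    baseline_log_sd: float = 0.5
    n_essential: int = 0
    n_erythroid: int = 0
    n_negcon: int = 0
    seed: int = 0

    def validate(self) -> None:
        grid = list(self.time_grid)
        if len(grid) < 2 or any(b <= a for a, b in zip(grid, grid[1:])):
            raise ValueError("time_grid must be strictly increasing with >= 2 days")
        if self.depth_per_sample <= 0:
            raise ValueError("depth_per_sample must be positive")
        if self.dispersion < 0 or self.sigma_hairpin < 0 or self.sigma_resid < 0:
            raise ValueError("dispersion and SDs must be >= 0")
        if not 0 <= self.effect_fraction <= 1:
            raise ValueError("effect_fraction must be in [0, 1]")
        lo, hi = self.hairpins_per_gene
        if lo < 1 or hi < lo:
            raise ValueError("invalid hairpins_per_gene range")
        if self.n_loci < 1 or self.n_genes < 1:
            raise ValueError("need at least one locus and one gene")


@dataclass
class SimTruth:
    """Ground truth of a simulated screen (for recovery tests)."""

    gene_slopes: pd.Series  # gene -> gamma_g, log2/day
    hairpin_dev: pd.Series  # hairpin -> delta_h, log2/day
    depths: pd.Series  # sample -> realized total reads
    seed: int

    def effect_genes(self, threshold: float = 0.0) -> list[str]:
        return sorted(self.gene_slopes.index[np.abs(self.gene_slopes) > threshold])

    def to_tsv(self, path) -> None:
        df = self.gene_slopes.rename("gamma").to_frame()
        df.to_csv(path, sep="\t", index_label="gene")


def simulate_screen(cfg: SimConfig) -> tuple[CountMatrix, pd.DataFrame, SimTruth]:
    """Simulate a pooled shRNA dropout screen with known gene effects.

    Expected log2 abundance of hairpin h of gene g at day t is
    ``log2(a_h0) + (gamma_g + delta_h) * (t - t0)``; per-sample counts are
    negative binomial around ``depth * proportion`` with overdispersion
    ``cfg.dispersion``. Returns (counts, library table, truth).
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    grid = list(cfg.time_grid)
    t0 = grid[0]

    genes = [f"G{i + 1:04d}" for i in range(cfg.n_genes)]
    categories = {g: "gwas" for g in genes}
    gamma = pd.Series(0.0, index=genes)
    n_eff = int(round(cfg.effect_fraction * cfg.n_genes))
    if n_eff > 0:
        eff = rng.choice(cfg.n_genes, size=n_eff, replace=False)
        lo, hi = cfg.effect_range
        mag = rng.uniform(lo, hi, size=n_eff)
        sign = rng.choice([-1.0, 1.0], size=n_eff)
        gamma.iloc[eff] = sign * mag

    # optional control genes with fixed, category-typical behaviour
    ctrl = [("ESS", cfg.n_essential, "essential", -0.25),
            ("ERY", cfg.n_erythroid, "erythroid", -0.2),
            ("NEG", cfg.n_negcon, "negcon", 0.0)]
    for prefix, n, cat, slope in ctrl:
        for i in range(n):
            g = f"{prefix}{i + 1:03d}"
            genes.append(g)
            categories[g] = cat
            gamma.loc[g] = slope

    # contiguous locus assignment for the GWAS genes; controls get their own
    loci = {}
    gwas = [g for g in genes if categories[g] == "gwas"]
    for k, chunk in enumerate(np.array_split(np.asarray(gwas, dtype=object), cfg.n_loci)):
        for g in chunk:
            loci[g] = f"L{k + 1:03d}"
    for g in genes:
        loci.setdefault(g, "control")

    lo_h, hi_h = cfg.hairpins_per_gene
    hp_counts = rng.integers(lo_h, hi_h + 1, size=len(genes))
    hairpins, hp_gene = [], []
    for g, n in zip(genes, hp_counts):
        for j in range(n):
            hairpins.append(f"{g}_h{j + 1}")
            hp_gene.append(g)
    library = pd.DataFrame(
        {
            "gene": hp_gene,
            "category": [categories[g] for g in hp_gene],
            "locus": [loci[g] for g in hp_gene],
        },
        index=pd.Index(hairpins, name="hairpin"),
    )

    H = len(hairpins)
    delta = rng.normal(0.0, cfg.sigma_hairpin, size=H)
    slope_h = gamma.loc[hp_gene].to_numpy() + delta
    a0 = rng.lognormal(mean=0.0, sigma=cfg.baseline_log_sd * np.log(2), size=H)

    cols, col_counts, depths = [], [], []
    for r in range(cfg.n_replicates):
        rep = f"rep{r + 1}"
        for day in grid:
            eps = rng.normal(0.0, cfg.sigma_resid, size=H)
            log2_abund = np.log2(a0) + slope_h * (day - t0) + eps
            prop = np.exp2(log2_abund)
            prop /= prop.sum()
            mu = cfg.depth_per_sample * prop
            if cfg.dispersion > 0:
                lam = rng.gamma(1.0 / cfg.dispersion, cfg.dispersion * mu)
            else:
                lam = mu
            counts = rng.poisson(lam)
            cols.append(sample_name(rep, day))
            col_counts.append(counts)
            depths.append(counts.sum())

    counts_df = pd.DataFrame(
        np.column_stack(col_counts), index=library.index, columns=cols
    )
    truth = SimTruth(
        gene_slopes=gamma.rename("gamma"),
        hairpin_dev=pd.Series(delta, index=library.index, name="delta"),
        depths=pd.Series(depths, index=cols, name="depth", dtype=float),
        seed=cfg.seed,
    )
    return CountMatrix(counts_df), library, truth


@dataclass
class BlockStructure:
    """Layout knobs for the toy chromosome."""

    n_samples: int = 100
    snps_per_block: int = 8
    snp_spacing: int = 2_000
    locus_span: int = 250_000
    hotspot_width: int = 2_000
    flip_prob: float = 0.02
    maf_range: tuple[float, float] = (0.2, 0.5)
    gene_length_range: tuple[int, int] = (5_000, 30_000)
    gene_scatter: int = 80_000
    margin: int = 50_000


@dataclass
class GenomeToy:
    """Toy chromosome with LD blocks, hotspots, genes, and sentinel SNPs."""

    chrom: str
    chrom_length: int
    genes: pd.DataFrame  # index gene id; strand, txStart, txEnd, locus
    hotspots: pd.DataFrame  # start, end (sorted, non-overlapping)
    snps: pd.DataFrame  # index snp id; pos, locus
    dosages: pd.DataFrame  # samples x snps, values in {0,1,2}
    sentinels: list[str]

    def __post_init__(self) -> None:
        if (self.genes["txEnd"] > self.chrom_length).any():
            raise ValueError("gene model outside chromosome")
        if (self.hotspots["end"] > self.chrom_length).any():
            raise ValueError("hotspot outside chromosome")
        d = self.dosages.to_numpy()
        if not np.isin(d, [0, 1, 2]).all():
            raise ValueError("dosages must be in {0,1,2}")
        if not set(self.sentinels) <= set(self.snps.index):
            raise ValueError("sentinels must be a subset of SNP ids")


def simulate_genome_toy(
    n_loci: int,
    genes_per_locus: int = 4,
    block_structure: BlockStructure | None = None,
    seed: int = 0,
    chrom: str = "chr1",
) -> GenomeToy:
    """Build a toy panel in which LD blocks exist by construction.

    Each locus contributes one block of SNPs whose dosages are per-haplotype
    noisy copies (flip probability ``block_structure.flip_prob``) of a latent
    biallelic haplotype, so within-block r2 is high and cross-block r2 is at
    the independence floor. One hotspot sits before every block and one
    after the last; the middle SNP of each block is its sentinel.
    """
    if n_loci < 1 or genes_per_locus < 1:
        raise ValueError("n_loci and genes_per_locus must be positive")
    bs = block_structure or BlockStructure()
    rng = np.random.default_rng(seed)
    chrom_length = 2 * bs.margin + n_loci * bs.locus_span
    block_width = bs.snps_per_block * bs.snp_spacing
    if block_width + 2 * bs.hotspot_width + 20_000 > bs.locus_span:
        raise ValueError("locus_span too small for requested block layout")

    hotspots, snp_rows, gene_rows, sentinels = [], [], [], []
    dosage_cols = {}
    for i in range(n_loci):
        origin = bs.margin + i * bs.locus_span
        hotspots.append((origin, origin + bs.hotspot_width))
        block_start = origin + bs.locus_span // 3
        f = rng.uniform(*bs.maf_range)
        hapA = (rng.random(bs.n_samples) < f).astype(np.int8)
        hapB = (rng.random(bs.n_samples) < f).astype(np.int8)
        ids = []
        for j in range(bs.snps_per_block):
            pos = block_start + j * bs.snp_spacing
            sid = f"rs{i + 1:03d}_{j + 1:02d}"
            ids.append(sid)
            flipA = rng.random(bs.n_samples) < bs.flip_prob
            flipB = rng.random(bs.n_samples) < bs.flip_prob
            dosage_cols[sid] = (hapA ^ flipA).astype(np.int8) + (hapB ^ flipB).astype(np.int8)
            snp_rows.append((sid, pos, f"L{i + 1:03d}"))
        sentinels.append(ids[bs.snps_per_block // 2])
        for k in range(genes_per_locus):
            length = int(rng.integers(*bs.gene_length_range))
            lo = max(0, block_start - bs.gene_scatter)
            hi = min(chrom_length - length - 1, block_start + block_width + bs.gene_scatter)
            if hi <= lo:
                raise ValueError("no room to place gene within chromosome")
            start = int(rng.integers(lo, hi))
            gene_rows.append(
                (f"GENE_L{i + 1:03d}_{k + 1}", "+" if rng.random() < 0.5 else "-",
                 start, start + length, f"L{i + 1:03d}")
            )
    hotspots.append((bs.margin + n_loci * bs.locus_span - bs.hotspot_width,
                     bs.margin + n_loci * bs.locus_span))

    genes = pd.DataFrame(
        gene_rows, columns=["gene", "strand", "txStart", "txEnd", "locus"]
    ).set_index("gene")
    snps = pd.DataFrame(snp_rows, columns=["snp", "pos", "locus"]).set_index("snp")
    dosages = pd.DataFrame(
        dosage_cols, index=[f"S{i + 1:03d}" for i in range(bs.n_samples)]
    )
    hotspots_df = pd.DataFrame(hotspots, columns=["start", "end"]).sort_values(
        "start", ignore_index=True
    )
    return GenomeToy(
        chrom=chrom,
        chrom_length=chrom_length,
        genes=genes,
        hotspots=hotspots_df,
        snps=snps,
        dosages=dosages,
        sentinels=sentinels,
    )


def simulate_annotations(
    truth: SimTruth,
    n_stages: int = 5,
    seed: int = 0,
    essentiality_scale: float = 5.0,
    expression_boost: float = 8.0,
    coding_base_rate: float = 0.05,
    coding_effect_rate: float = 0.25,
    n_genome_extra: int = 600,
    n_gold: int = 5,
) -> AnnotationBundle:
    """Annotation tables wired to the simulated truth.

    Essentiality is a monotone function of |gamma| plus unit normal noise;
    expression gets a boost proportional to |gamma| at one designated active
    stage; coding-variant flags have an elevated rate among effect genes;
    the gold list is the ``n_gold`` genes of largest |gamma| (ties broken by
    gene id). A disjoint set of ``n_genome_extra`` null genes widens the
    library universe into a genome-like universe.
    """
    if n_stages < 2:
        raise ValueError("need at least 2 stages")
    if len(truth.gene_slopes) == 0:
        raise ValueError("truth is empty")
    rng = np.random.default_rng(seed)
    genes = list(truth.gene_slopes.index)
    absg = truth.gene_slopes.abs()

    extra = [f"X{i + 1:04d}" for i in range(n_genome_extra)]
    genome = genes + extra
    ess = pd.Series(
        np.concatenate(
            [
                essentiality_scale * absg.to_numpy() + rng.normal(0, 1, len(genes)),
                rng.normal(0, 1, len(extra)),
            ]
        ),
        index=genome,
        name="essentiality",
    )

    stages = [f"stage{i + 1}" for i in range(n_stages)]
    active = stages[n_stages // 2]
    expr = pd.DataFrame(
        rng.normal(0, 1, (len(genes), n_stages)), index=genes, columns=stages
    )
    expr[active] += expression_boost * absg

    is_effect = (absg > 0).to_numpy()
    rate = np.where(is_effect, coding_effect_rate, coding_base_rate)
    coding = pd.Series(
        (rng.random(len(genes)) < rate).astype(int), index=genes, name="coding_flag"
    )

    order = sorted(genes, key=lambda g: (-absg[g], g))
    gold = order[:n_gold]

    alt_panels = {
        f"alt_panel{k + 1}": sorted(
            rng.choice(np.asarray(genome, dtype=object), size=min(300, len(genome)),
                       replace=False)
        )
        for k in range(2)
    }
    universes = {"library": list(genes), "genome": list(genome), **alt_panels}
    return AnnotationBundle(
        essentiality=ess,
        expression=expr,
        coding_flag=coding,
        gold_genes=gold,
        universes=universes,
        active_stage=active,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# plain-text writers

def write_library(library: pd.DataFrame, path) -> None:
    library.to_csv(path, sep="\t", index_label="hairpin")


def write_genome_toy(toy: GenomeToy, outdir) -> dict:
    """Write the toy panel as BED (genes, hotspots) + TSV dosages + VCF."""
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "genes": outdir / "genes.bed",
        "hotspots": outdir / "hotspots.bed",
        "dosages": outdir / "genotypes.tsv",
        "vcf": outdir / "snps.vcf",
        "sentinels": outdir / "sentinels.txt",
    }
    with open(paths["genes"], "w") as fh:
        for g, row in toy.genes.iterrows():
            fh.write(
                f"{toy.chrom}\t{row.txStart}\t{row.txEnd}\t{g}\t0\t{row.strand}\n"
            )
    with open(paths["hotspots"], "w") as fh:
        for _, row in toy.hotspots.iterrows():
            fh.write(f"{toy.chrom}\t{row.start}\t{row.end}\n")
    toy.dosages.to_csv(paths["dosages"], sep="\t", index_label="sample")
    with open(paths["vcf"], "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##contig=<ID={toy.chrom},length={toy.chrom_length}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        samples = "\t".join(toy.dosages.index)
        fh.write(f"#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{samples}\n")
        gt = {0: "0/0", 1: "0/1", 2: "1/1"}
        for sid, row in toy.snps.iterrows():
            calls = "\t".join(gt[int(d)] for d in toy.dosages[sid])
            fh.write(f"{toy.chrom}\t{row.pos + 1}\t{sid}\tA\tG\t.\tPASS\t.\tGT\t{calls}\n")
    with open(paths["sentinels"], "w") as fh:
        fh.write("\n".join(toy.sentinels) + "\n")
    return {k: str(v) for k, v in paths.items()}
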