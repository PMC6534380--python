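"""Locus-to-gene nomination from trait-associated sentinel SNPs.

A sentinel SNP is expanded to the interval spanning all panel SNPs in high
LD with it (r2 >= 0.8 by default), the interval is extended outward to the
inner edges of the nearest flanking recombination hotspots, and every gene
whose regulatory "wingspan" (110 kb upstream of the transcription start,
40 kb downstream of the transcription end, strand-aware) overlaps the
extended window is nominated as a candidate for that locus.

All coordinates are 0-based half-open (BED convention).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)


@dataclass
class GeneModel:
    """A gene's transcribed interval, 0-based half-open."""

    gene: str
    chrom: str
    strand: str
    txStart: int
    txEnd: int

    def __post_init__(self) -> None:
        if self.strand not in {"+", "-"}:
            raise ValueError(f"strand must be + or -, got {self.strand!r}")
        if not 0 <= self.txStart < self.txEnd:
            raise ValueError(f"invalid gene interval for {self.gene}")

    def wingspan(self, up_kb: float = 110, down_kb: float = 40,
                 strand_aware: bool = True) -> tuple[int, int]:
        """Regulatory reach: up_kb beyond the TSS, down_kb beyond the TES.

        With ``strand_aware=False`` both extensions are applied on both
        sides (the more permissive, strand-agnostic reading).
        """
        up = int(round(up_kb * 1000))
        down = int(round(down_kb * 1000))
        if not strand_aware:
            ext = max(up, down)
            return max(0, self.txStart - ext), self.txEnd + ext
        if self.strand == "+":
            return max(0, self.txStart - up), self.txEnd + down
        return max(0, self.txStart - down), self.txEnd + up


@dataclass
class LocusWindow:
    """Sentinel-anchored genomic window, before and after hotspot extension."""

    locus: str
    chrom: str
    sentinel: str
    sentinel_pos: int
    ld_start: int
    ld_end: int
    ext_start: int | None = None
    ext_end: int | None = None
    trait: str = ""

    def __post_init__(self) -> None:
        if not self.ld_start <= self.sentinel_pos < self.ld_end:
            raise ValueError(f"sentinel outside LD window at {self.locus}")
        if self.ext_start is not None and self.ext_end is not None:
            if not (self.ext_start <= self.ld_start and self.ld_end <= self.ext_end):
                raise ValueError(f"extended window does not contain LD window at {self.locus}")

    @property
    def window(self) -> tuple[int, int]:
        if self.ext_start is None or self.ext_end is None:
            return self.ld_start, self.ld_end
        return self.ext_start, self.ext_end


def compute_r2(dosages_a, dosages_b) -> float:
    """Squared Pearson correlation of two unphased dosage vectors.

    Composite LD; works without phase. A monomorphic vector has no defined
    correlation: returns NaN (never silently 0).
    """
    a = np.asarray(dosages_a, dtype=float)
    b = np.asarray(dosages_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or len(a) < 3:
        raise ValueError("dosage vectors must be 1-D, equal length >= 3")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        logger.warning("monomorphic SNP in r2 computation; returning NaN")
        return float("nan")
    r = np.corrcoef(a, b)[0, 1]
    return float(r * r)


def ld_block(sentinel: str, panel, r2_threshold: float = 0.8) -> tuple[int, int]:
    """Interval spanning all panel SNPs with r2(sentinel, .) >= threshold.

    Half-open: end = max qualifying position + 1. The sentinel always
    qualifies. ``panel`` is a GenomeToy-like object with ``snps`` (pos per
    SNP id) and ``dosages`` (samples x SNPs).
    """
    if sentinel not in panel.snps.index:
        raise KeyError(f"sentinel {sentinel!r} not in panel")
    s = panel.dosages[sentinel].to_numpy(dtype=float)
    if np.ptp(s) == 0:
        raise ValueError(f"sentinel {sentinel!r} is monomorphic")
    dos = panel.dosages.to_numpy(dtype=float)
    # vectorized Pearson r against the sentinel; monomorphic columns -> NaN
    sc = s - s.mean()
    dc = dos - dos.mean(axis=0)
    denom = np.sqrt((sc ** 2).sum() * (dc ** 2).sum(axis=0))
    with np.errstate(invalid="ignore", divide="ignore"):
        r2 = np.where(denom > 0, (dc.T @ sc) / np.where(denom == 0, 1, denom), np.nan) ** 2
    keep = pd.Index(panel.dosages.columns)[np.nan_to_num(r2) >= r2_threshold]
    pos = panel.snps.loc[keep.union([sentinel]), "pos"]
    return int(pos.min()), int(pos.max()) + 1


def extend_to_hotspots(block: tuple[int, int], hotspots: pd.DataFrame,
                       chrom_length: int) -> tuple[int, int]:
    """Extend an interval outward to the inner edges of flanking hotspots.

    ext_start is the end of the nearest hotspot entirely at or left of the
    block (0 if none); ext_end the start of the nearest hotspot at or right
    of it (chrom_length if none). The hotspot interval itself is excluded:
    a hotspot delimits an association block rather than belonging to it.
    """
    start, end = block
    if start < 0 or end > chrom_length or start >= end:
        raise ValueError("block outside chromosome")
    hs = hotspots.sort_values("start")
    if (hs["start"].shift(-1) < hs["end"]).any():
        raise ValueError("hotspots must be non-overlapping")
    left = hs.loc[hs["end"] <= start, "end"]
    right = hs.loc[hs["start"] >= end, "start"]
    ext_start = int(left.max()) if len(left) else 0
    ext_end = int(right.min()) if len(right) else int(chrom_length)
    return ext_start, ext_end


def _overlaps(a_start, a_end, b_start, b_end) -> bool:
    return a_start < b_end and b_start < a_end


def nominate_genes(window: LocusWindow, genes, up_kb: float = 110,
                   down_kb: float = 40, strand_aware: bool = True) -> list[str]:
    """Genes whose wingspan overlaps the locus window (half-open overlap)."""
    w_start, w_end = window.window
    out = []
    for g in genes:
        if g.chrom != window.chrom:
            raise ValueError(f"gene {g.gene} on {g.chrom}, window on {window.chrom}")
        s, e = g.wingspan(up_kb, down_kb, strand_aware=strand_aware)
        if _overlaps(s, e, w_start, w_end):
            out.append(g.gene)
    return sorted(out)


@dataclass
class CandidateGeneSet:
    """Per-locus nominated genes plus summary statistics."""

    assignments: dict[str, list[str]]

    @property
    def genes(self) -> list[str]:
        return sorted({g for gs in self.assignments.values() for g in gs})

    def summary(self) -> dict:
        per_locus = {k: len(v) for k, v in self.assignments.items()}
        counts = np.array(list(per_locus.values())) if per_locus else np.array([0])
        return {
            "n_loci": len(self.assignments),
            "n_genes": len(self.genes),
            "genes_per_locus_median": float(np.median(counts)),
            "loci_with_candidates": int((counts > 0).sum()),
        }

    def to_frame(self) -> pd.DataFrame:
        rows = [(loc, g) for loc, gs in sorted(self.assignments.items()) for g in gs]
        return pd.DataFrame(rows, columns=["locus", "gene"])


def nominate_all(
    panel,
    r2_threshold: float = 0.8,
    up_kb: float = 110,
    down_kb: float = 40,
    strand_aware: bool = True,
    overrides: dict[str, tuple[int, int]] | None = None,
) -> tuple[list[LocusWindow], CandidateGeneSet]:
    """Run sentinel -> LD block -> hotspot extension -> wingspan nomination.

    ``overrides`` maps locus id to an explicit (start, end) extended window,
    for manual per-locus expansions (gene deserts, unusual structures);
    they replace the computed extension and are never inferred.
    """
    genes = [
        GeneModel(g, panel.chrom, row.strand, int(row.txStart), int(row.txEnd))
        for g, row in panel.genes.iterrows()
    ]
    windows, assignments = [], {}
    for i, sid in enumerate(panel.sentinels):
        locus = f"L{i + 1:03d}"
        ld_start, ld_end = ld_block(sid, panel, r2_threshold)
        if overrides and locus in overrides:
            ext_start, ext_end = overrides[locus]
            if not (ext_start <= ld_start and ld_end <= ext_end):
                raise ValueError(f"override for {locus} does not contain its LD block")
        else:
            ext_start, ext_end = extend_to_hotspots(
                (ld_start, ld_end), panel.hotspots, panel.chrom_length
            )
        w = LocusWindow(
            locus=locus, chrom=panel.chrom, sentinel=sid,
            sentinel_pos=int(panel.snps.loc[sid, "pos"]),
            ld_start=ld_start, ld_end=ld_end,
            ext_start=ext_start, ext_end=ext_end,
        )
        windows.append(w)
        assignments[locus] = nominate_genes(w, genes, up_kb, down_kb,
                                            strand_aware=strand_aware)
    return windows, CandidateGeneSet(assignments)


def pad_window_to_fixed(start: int, end: int, width_bp: int = 100_000) -> tuple[int, int]:
    """Symmetrically resize an interval about its midpoint to a fixed width."""
    mid = (start + end) // 2
    half = width_bp // 2
    new_start = max(0, mid - half)
    return new_start, new_start + width_bp


def eqtl_window_comparison(
    windows,
    genes,
    eqtl_genes,
    hit_genes,
    pad_to_kb: float = 100,
) -> dict:
    """Compare screen hits with genes an eQTL-window approach would nominate.

    Each LD window is resized to a fixed width about its midpoint (small
    windows are not otherwise comparable); a universe gene is
    "eQTL-nominated" if its transcribed interval overlaps any padded window.
    The universe is the eQTL gene set; the 2x2 table crosses hit status with
    nomination status and is tested with a two-sided Fisher exact test.
    """
    eqtl_genes = set(eqtl_genes)
    if not eqtl_genes:
        raise ValueError("empty eQTL gene universe")
    hit_genes = set(hit_genes)
    width = int(round(pad_to_kb * 1000))
    padded = [pad_window_to_fixed(w.ld_start, w.ld_end, width) for w in windows]
    nominated = set()
    for g in genes:
        if any(_overlaps(g.txStart, g.txEnd, s, e) for s, e in padded):
            nominated.add(g.gene)
    nominated &= eqtl_genes
    table = np.zeros((2, 2), dtype=int)
    for g in eqtl_genes:
        table[0 if g in hit_genes else 1, 0 if g in nominated else 1] += 1
    p = float(stats.fisher_exact(table, alternative="two-sided")[1])
    return {
        "table": table,
        "p_value": p,
        "n_eqtl_genes": len(eqtl_genes),
        "n_nominated": int(table[:, 0].sum()),
        "n_hits_in_universe": int(table[0, :].sum()),
        "padded_windows": padded,
    }


# ---------------------------------------------------------------------------
# file readers (BED / minimal GFF3 / dosage TSV / minimal VCF)

def read_genes_bed(path, chrom: str | None = None) -> list[GeneModel]:
    genes = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 6:
                raise ValueError("gene BED needs 6 columns (incl. name, strand)")
            if chrom is not None and f[0] != chrom:
                continue
            genes.append(GeneModel(f[3], f[0], f[5], int(f[1]), int(f[2])))
    return genes


def read_genes_gff3(path, chrom: str | None = None,
                    feature: str = "gene") -> list[GeneModel]:
    """Minimal GFF3 subset: gene features with an ID attribute (1-based
    inclusive coordinates converted to 0-based half-open)."""
    genes = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 9 or f[2] != feature:
                continue
            if chrom is not None and f[0] != chrom:
                continue
            attrs = dict(
                kv.split("=", 1) for kv in f[8].split(";") if "=" in kv
            )
            name = attrs.get("ID") or attrs.get("Name")
            if name is None:
                raise ValueError("GFF3 gene without ID/Name attribute")
            genes.append(GeneModel(name, f[0], f[6], int(f[3]) - 1, int(f[4])))
    return genes


def read_intervals_bed(path, chrom: str | None = None) -> pd.DataFrame:
    rows = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            f = line.rstrip("\n").split("\t")
            if chrom is not None and f[0] != chrom:
                continue
            rows.append((int(f[1]), int(f[2])))
    return pd.DataFrame(rows, columns=["start", "end"]).sort_values(
        "start", ignore_index=True
    )


def read_dosages_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def read_vcf_dosages(path) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Minimal VCF reader: GT fields parsed to dosage. Returns (snps, dosages)."""
    snp_rows, dosage_cols, samples = [], {}, None
    with open(path) as fh:
        for line in fh:
            if line.startswith("##"):
                continue
            f = line.rstrip("\n").split("\t")
            if line.startswith("#CHROM"):
                samples = f[9:]
                continue
            if samples is None:
                raise ValueError("VCF missing #CHROM header line")
            fmt = f[8].split(":")
            gi = fmt.index("GT")
            dose = []
            for cell in f[9:]:
                gt = cell.split(":")[gi].replace("|", "/")
                dose.append(sum(int(a) for a in gt.split("/") if a != "."))
            snp_rows.append((f[2], int(f[1]) - 1, f[0]))
            dosage_cols[f[2]] = np.asarray(dose, dtype=np.int8)
    snps = pd.DataFrame(snp_rows, columns=["snp", "pos", "chrom"]).set_index("snp")
    dosages = pd.DataFrame(dosage_cols, index=samples)
    return snps, dosages
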