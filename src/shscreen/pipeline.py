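"""End-to-end orchestration: simulate -> nominate -> preprocess -> fit ->
call hits -> enrich, with a JSON run manifest and a plain-text summary.

Every run is driven by a single :class:`RunConfig` (loadable from a YAML
key-value file with CLI overrides) and a single seed; identical config and
seed give byte-identical stage outputs. Each output table carries a header
comment with the run id (a checksum of the configuration), and the manifest
records per-stage row counts, wall times, and output checksums. The
manifest is written even when a stage fails, with the failing stage
recorded.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .enrich import (
    overlap_enrichment,
    rank_sum_enrichment,
    score_sum_enrichment,
    stage_expression_enrichment,
)
from .model import call_hits, fit_all_genes
from .nominate import nominate_all
from .preprocess import (
    CountMatrix,
    fold_change_vs_baseline,
    log2_cpm,
    representation_qc,
)
from .simulate import (
    SimConfig,
    simulate_annotations,
    simulate_genome_toy,
    simulate_screen,
    write_genome_toy,
)

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """All knobs of a pipeline run, with reproducibility contract."""

    outdir: str = "shscreen_run"
    seed: int = 0
    # inputs; when counts/library are None the screen is simulated
    counts_path: str | None = None
    library_path: str | None = None
    simulate: dict = field(default_factory=dict)  # SimConfig overrides
    run_nomination: bool = True
    n_toy_loci: int = 10
    genes_per_locus: int = 4
    # preprocessing
    baseline_day: int = 4
    pseudocount: float = 1.0
    qc_threshold_log2cpm: float = 5.0
    min_baseline_log2cpm: float | None = None
    # nomination
    r2_threshold: float = 0.8
    up_kb: float = 110.0
    down_kb: float = 40.0
    pad_to_kb: float = 100.0
    strand_aware: bool = True
    # model / hit calling
    re_mode: str = "per_day"
    slope_mode: str = "cumulative"
    slope_threshold: float = 0.1
    q_threshold: float = 0.1
    # enrichment
    n_perm: int = 100_000
    n_stages: int = 5

    def __post_init__(self) -> None:
        if self.slope_threshold < 0 or self.q_threshold < 0:
            raise ValueError("thresholds must be non-negative")
        if self.n_perm < 1:
            raise ValueError("n_perm must be >= 1")
        for p in (self.counts_path, self.library_path):
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(p)

    @classmethod
    def from_yaml(cls, path, **overrides) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def run_id(self) -> str:
        """Checksum of the analysis configuration (output location excluded,
        so identical analyses in different directories share an id)."""
        cfg = {k: v for k, v in asdict(self).items() if k != "outdir"}
        blob = json.dumps(cfg, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _write_table(df: pd.DataFrame, path: Path, run_id: str, index=True,
                 index_label=None) -> None:
    with open(path, "w") as fh:
        fh.write(f"# run_id: {run_id}\n")
        df.to_csv(fh, sep="\t", index=index, index_label=index_label)


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute all stages; return the manifest (also written to disk)."""
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    run_id = cfg.run_id()
    manifest: dict = {
        "run_id": run_id,
        "version": __version__,
        "config": asdict(cfg),
        "stages": {},
        "outputs": {},
        "status": "running",
    }

    def finish_stage(name: str, t0: float, **info) -> None:
        manifest["stages"][name] = {
            "wall_time_s": round(time.time() - t0, 3), **info,
        }
        logger.info("stage %s done (%.2fs)", name, time.time() - t0)

    def register(name: str, path: Path) -> None:
        manifest["outputs"][name] = {
            "path": str(path), "sha256": _sha256(path),
        }

    def write_manifest() -> None:
        with open(outdir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True, default=str)

    try:
        # stage 1: inputs (simulated or loaded)
        t0 = time.time()
        if cfg.counts_path is None:
            sim_cfg = SimConfig(**{"seed": cfg.seed, **cfg.simulate})
            counts, library, truth = simulate_screen(sim_cfg)
            _write_table(counts.counts, outdir / "counts.tsv", run_id,
                         index_label="hairpin")
            _write_table(library, outdir / "library.tsv", run_id,
                         index_label="hairpin")
            _write_table(truth.gene_slopes.to_frame(), outdir / "truth.tsv",
                         run_id, index_label="gene")
            register("counts", outdir / "counts.tsv")
            register("library", outdir / "library.tsv")
            register("truth", outdir / "truth.tsv")
            finish_stage("simulate", t0, n_hairpins=len(counts.counts),
                         n_genes=int(library["gene"].nunique()))
        else:
            counts = CountMatrix.from_tsv(cfg.counts_path)
            if cfg.library_path is None:
                raise ValueError("library_path required with counts_path")
            library = pd.read_csv(cfg.library_path, sep="\t", index_col=0,
                                  comment="#")
            truth = None
            finish_stage("load", t0, n_hairpins=len(counts.counts))

        # stage 2: locus nomination on a toy genome panel
        if cfg.run_nomination:
            t0 = time.time()
            toy = simulate_genome_toy(cfg.n_toy_loci, cfg.genes_per_locus,
                                      seed=cfg.seed + 1)
            write_genome_toy(toy, outdir / "genome")
            windows, cand = nominate_all(
                toy, r2_threshold=cfg.r2_threshold, up_kb=cfg.up_kb,
                down_kb=cfg.down_kb, strand_aware=cfg.strand_aware,
            )
            _write_table(cand.to_frame(), outdir / "candidates.tsv", run_id,
                         index=False)
            register("candidates", outdir / "candidates.tsv")
            wdf = pd.DataFrame(
                [
                    (w.locus, w.chrom, w.sentinel, w.sentinel_pos,
                     w.ld_start, w.ld_end, w.ext_start, w.ext_end)
                    for w in windows
                ],
                columns=["locus", "chrom", "sentinel", "sentinel_pos",
                         "ld_start", "ld_end", "ext_start", "ext_end"],
            )
            _write_table(wdf, outdir / "windows.tsv", run_id, index=False)
            register("windows", outdir / "windows.tsv")
            finish_stage("nominate", t0, **cand.summary())

        # stage 3: preprocess
        t0 = time.time()
        norm = log2_cpm(counts, cfg.pseudocount)
        qc = representation_qc(norm, counts.samples, cfg.baseline_day,
                               cfg.qc_threshold_log2cpm)
        with open(outdir / "qc.json", "w") as fh:
            json.dump(qc, fh, indent=2, sort_keys=True)
        register("qc", outdir / "qc.json")
        fc = fold_change_vs_baseline(norm, counts.samples, cfg.baseline_day,
                                     library=library)
        if cfg.min_baseline_log2cpm is not None:
            base_cols = counts.samples.index[
                counts.samples["day"] == cfg.baseline_day
            ]
            ok = norm[base_cols].mean(axis=1) >= cfg.min_baseline_log2cpm
            fc = fc[fc["hairpin"].isin(ok.index[ok])].reset_index(drop=True)
        _write_table(fc, outdir / "fold_changes.tsv", run_id, index=False)
        register("fold_changes", outdir / "fold_changes.tsv")
        finish_stage("preprocess", t0, n_rows=len(fc),
                     qc_fraction=qc["fraction"])

        # stage 4: model fits
        t0 = time.time()
        fits = fit_all_genes(fc, re_mode=cfg.re_mode)
        _write_table(fits, outdir / "fits.tsv", run_id, index=False)
        register("fits", outdir / "fits.tsv")
        finish_stage("fit", t0, n_genes=int(fits["gene"].nunique()),
                     n_failed=int((fits.groupby("gene")["status"].first()
                                   == "failed").sum()))

        # stage 5: hit calling
        t0 = time.time()
        gene_loci = library.groupby("gene")["locus"].first()
        result = call_hits(
            fits, slope_threshold=cfg.slope_threshold,
            q_threshold=cfg.q_threshold, slope_mode=cfg.slope_mode,
            baseline_day=cfg.baseline_day, gene_loci=gene_loci,
        )
        _write_table(result.gene_effects, outdir / "gene_effects.tsv", run_id,
                     index_label="gene")
        _write_table(result.day_table, outdir / "fits_with_q.tsv", run_id,
                     index=False)
        register("gene_effects", outdir / "gene_effects.tsv")
        register("fits_with_q", outdir / "fits_with_q.tsv")
        with open(outdir / "locus_summary.json", "w") as fh:
            json.dump(result.locus_summary, fh, indent=2, sort_keys=True)
        register("locus_summary", outdir / "locus_summary.json")
        finish_stage("call_hits", t0, n_hits=len(result.hits),
                     loci_with_hit=result.locus_summary.get("loci_with_hit"))

        # stage 6: enrichment (only meaningful on simulated annotations)
        t0 = time.time()
        enr: dict = {}
        if truth is not None and len(result.hits) > 0:
            ann = simulate_annotations(truth, n_stages=cfg.n_stages,
                                       seed=cfg.seed + 2)
            ann.write(outdir / "annotations")
            hits = result.hits
            enr["essentiality_library"] = score_sum_enrichment(
                hits, ann.essentiality, ann.universes["library"],
                n_perm=cfg.n_perm, seed=cfg.seed + 3, keep_null=False,
            ).summary()
            genome_hits = [g for g in hits if g in set(ann.universes["genome"])]
            enr["essentiality_genome"] = score_sum_enrichment(
                genome_hits, ann.essentiality, ann.universes["genome"],
                n_perm=cfg.n_perm, seed=cfg.seed + 4, keep_null=False,
            ).summary()
            gene_q = result.gene_effects["min_q"]
            enr["gold_rank_sum"] = rank_sum_enrichment(
                ann.gold_genes, gene_q,
                [g for g in ann.universes["library"] if g in gene_q.index],
                n_perm=cfg.n_perm, seed=cfg.seed + 5, keep_null=False,
            ).summary()
            enr["coding_overlap"] = overlap_enrichment(
                hits, ann.coding_flag.index[ann.coding_flag == 1],
                ann.universes["library"], n_perm=cfg.n_perm,
                seed=cfg.seed + 6, keep_null=False,
            ).summary()
            stage_res = stage_expression_enrichment(
                hits, ann.expression, ann.universes["library"],
                n_perm=min(cfg.n_perm, 20_000), seed=cfg.seed + 7,
            )
            enr["stage_expression"] = {k: v.summary()
                                       for k, v in stage_res.items()}
        with open(outdir / "enrichment.json", "w") as fh:
            json.dump(enr, fh, indent=2, sort_keys=True)
        register("enrichment", outdir / "enrichment.json")
        finish_stage("enrich", t0, n_tests=len(enr))

        manifest["status"] = "ok"
    except Exception as exc:  # manifest is written even on failure
        manifest["status"] = "failed"
        manifest["error"] = f"{type(exc).__name__}: {exc}"
        write_manifest()
        raise
    write_manifest()
    return manifest


def summary_report(outdir) -> str:
    """Human-readable run summary, recomputed from the written outputs."""
    outdir = Path(outdir)
    effects = pd.read_csv(outdir / "gene_effects.tsv", sep="\t", comment="#",
                          index_col=0)
    with open(outdir / "locus_summary.json") as fh:
        locus = json.load(fh)
    with open(outdir / "qc.json") as fh:
        qc = json.load(fh)
    hits = effects[effects["hit"]]
    lines = [
        "shscreen run summary",
        "====================",
        f"genes tested:        {len(effects)}",
        f"hit genes:           {len(hits)}"
        f" ({(hits['direction'] == 'depleted').sum()} depleted,"
        f" {(hits['direction'] == 'enriched').sum()} enriched)",
    ]
    if locus:
        lines.append(
            f"loci with >=1 hit:   {locus['loci_with_hit']} / {locus['n_loci']}"
        )
        hist = ", ".join(f"{k} hit(s): {v} loci"
                         for k, v in sorted(locus["histogram"].items(),
                                            key=lambda kv: int(kv[0]))
                         if int(k) > 0)
        lines.append(f"hits per locus:      {hist or 'none'}")
    lines.append(
        f"day-{qc['day']} representation: "
        f"{qc['fraction']:.1%} of {qc['n_hairpins']} hairpins >= "
        f"{qc['threshold_log2cpm']} log2 CPM"
    )
    enr_path = outdir / "enrichment.json"
    if enr_path.exists():
        with open(enr_path) as fh:
            enr = json.load(fh)
        for name, res in enr.items():
            if name == "stage_expression":
                for stage, r in res.items():
                    lines.append(f"enrichment {stage}: p = {r['p_value']:.4g}")
            else:
                lines.append(f"enrichment {name}: p = {res['p_value']:.4g}")
    return "\n".join(lines) + "\n"
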