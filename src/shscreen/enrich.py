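"""Permutation-null enrichment statistics for validating a screen hit set.

Four validation axes, all sharing one resampling engine: the observed
statistic over the hit set is compared with the same statistic over
uniformly drawn, identically sized gene sets from a stated universe
(the screened library, a genome-wide set, or alternative GWAS panels).

Empirical p values use the add-one estimator ``(n_extreme + 1) /
(n_perm + 1)`` with ties counted as extreme, so a permutation p is never 0
and is valid (conservative) at any number of permutations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

_CHUNK = 50_000


@dataclass
class PermutationResult:
    """Observed statistic, its permutation null, and the empirical p value."""

    statistic: str
    observed: float
    n_permutations: int
    n_extreme: int
    p_value: float
    tail: str
    seed: int
    null: np.ndarray | None = field(default=None, repr=False)
    exact_p: float | None = None
    extra: dict = field(default_factory=dict)

    def summary(self) -> dict:
        out = {
            "statistic": self.statistic,
            "observed": float(self.observed),
            "n_permutations": int(self.n_permutations),
            "n_extreme": int(self.n_extreme),
            "p_value": float(self.p_value),
            "tail": self.tail,
            "seed": int(self.seed),
        }
        if self.exact_p is not None:
            out["exact_p"] = float(self.exact_p)
        out.update(self.extra)
        return out


@dataclass
class AnnotationBundle:
    """External validation annotations keyed to gene ids.

    ``universes`` holds named gene sets ("library", "genome", alternative
    panels); ``essentiality`` must cover at least the library universe,
    ``expression`` is gene x stage, ``gold_genes`` a short list of
    positive-control genes with established causal links.
    """

    essentiality: pd.Series
    expression: pd.DataFrame
    coding_flag: pd.Series
    gold_genes: list[str]
    universes: dict[str, list[str]]
    active_stage: str | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.expression.shape[1] < 2:
            raise ValueError("expression needs >= 2 stages")
        lib = set(self.universes.get("library", []))
        if lib and not set(self.gold_genes) <= lib:
            raise ValueError("gold genes must belong to the library universe")

    def write(self, outdir) -> dict:
        from pathlib import Path

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "essentiality": outdir / "essentiality.tsv",
            "expression": outdir / "expression.tsv",
            "coding": outdir / "coding_flags.tsv",
            "gold": outdir / "gold_genes.txt",
            "universes": outdir / "universes.tsv",
        }
        self.essentiality.to_frame().to_csv(paths["essentiality"], sep="\t",
                                            index_label="gene")
        self.expression.to_csv(paths["expression"], sep="\t", index_label="gene")
        self.coding_flag.to_frame().to_csv(paths["coding"], sep="\t",
                                           index_label="gene")
        paths["gold"].write_text("\n".join(self.gold_genes) + "\n")
        rows = [(name, g) for name, gs in self.universes.items() for g in gs]
        pd.DataFrame(rows, columns=["universe", "gene"]).to_csv(
            paths["universes"], sep="\t", index=False
        )
        return {k: str(v) for k, v in paths.items()}


def _check_sets(hits, universe) -> tuple[list, list]:
    hits = list(hits)
    universe = list(universe)
    if len(set(hits)) != len(hits) or len(set(universe)) != len(universe):
        raise ValueError("duplicate gene ids")
    if not set(hits) <= set(universe):
        raise ValueError("hits must be a subset of the universe")
    if len(hits) > len(universe):
        raise ValueError("more hits than universe members")
    return hits, universe


def _restrict_to_annotated(hits, universe, annotated, missing: str):
    """Handle universe members without an annotation: drop them or score 0."""
    annotated = set(annotated)
    absent = [g for g in universe if g not in annotated]
    if not absent:
        return hits, universe, {}
    if missing == "drop":
        logger.warning("%d universe genes lack annotation; dropped", len(absent))
        universe = [g for g in universe if g in annotated]
        hits = [g for g in hits if g in annotated]
        return hits, universe, {"n_dropped_unannotated": len(absent)}
    if missing == "zero":
        return hits, universe, {"n_zero_filled": len(absent)}
    raise ValueError(f"unknown missing policy {missing!r}")


def _null_sums(rng, values: np.ndarray, k: int, n_perm: int) -> np.ndarray:
    """Sums of `values` over `n_perm` uniform draws of k items w/o replacement.

    Vectorized k-subset sampling: the k smallest of i.i.d. uniform keys per
    row are a uniform k-subset. Chunked to bound memory.
    """
    n = len(values)
    if k == n:
        return np.full(n_perm, values.sum())
    out = np.empty(n_perm)
    done = 0
    while done < n_perm:
        b = min(_CHUNK, n_perm - done)
        keys = rng.random((b, n))
        idx = np.argpartition(keys, k, axis=1)[:, :k]
        out[done:done + b] = values[idx].sum(axis=1)
        done += b
    return out


def _tail_counts(null: np.ndarray, observed: float, tail: str) -> int:
    # ties count as extreme; the epsilon absorbs summation-order noise so a
    # null draw of exactly the observed subset is never missed
    eps = 1e-9 * max(1.0, abs(observed))
    if tail == "greater":
        return int((null >= observed - eps).sum())
    if tail == "less":
        return int((null <= observed + eps).sum())
    if tail == "two-sided":
        return min(
            2 * min((null >= observed - eps).sum(),
                    (null <= observed + eps).sum()),
            len(null),
        )
    raise ValueError(f"unknown tail {tail!r}")


def _result(name, observed, null, tail, seed, keep_null=True, **extra):
    n_ext = _tail_counts(null, observed, tail)
    p = (n_ext + 1) / (len(null) + 1)
    return PermutationResult(
        statistic=name,
        observed=float(observed),
        n_permutations=len(null),
        n_extreme=n_ext,
        p_value=float(p),
        tail=tail,
        seed=seed,
        null=null if keep_null else None,
        extra=extra,
    )


def score_sum_enrichment(
    hits,
    scores: pd.Series,
    universe,
    n_perm: int = 1_000_000,
    tail: str = "greater",
    seed: int = 0,
    missing: str = "drop",
    keep_null: bool = True,
) -> PermutationResult:
    """Is the sum of per-gene scores over the hit set extreme?

    The null resamples |hits| genes uniformly without replacement from the
    universe. Used for essentiality enrichment against the library, the
    genome, or alternative GWAS panels (same code path, different universe).
    """
    hits, universe = _check_sets(hits, universe)
    hits, universe, extra = _restrict_to_annotated(
        hits, universe, scores.dropna().index, missing
    )
    if not hits:
        raise ValueError("no annotated hits left")
    vals = scores.reindex(universe).fillna(0.0).to_numpy(dtype=float)
    observed = float(scores.reindex(hits).fillna(0.0).sum())
    rng = np.random.default_rng(seed)
    null = _null_sums(rng, vals, len(hits), n_perm)
    return _result("score_sum", observed, null, tail, seed,
                   keep_null=keep_null, n_hits=len(hits),
                   n_universe=len(universe), **extra)


def rank_sum_enrichment(
    target_genes,
    gene_ranking: pd.Series,
    universe,
    n_perm: int = 1_000_000,
    seed: int = 0,
    keep_null: bool = True,
) -> PermutationResult:
    """Rank-sum test of a short target list against random same-size sets.

    ``gene_ranking`` scores the universe with lower = stronger evidence
    (e.g. the model's min q per gene); genes are ranked ascending with
    average ranks for ties. Low rank sums are extreme (tail = less).
    """
    targets, universe = _check_sets(target_genes, universe)
    ranking = gene_ranking.reindex(universe)
    if ranking.isna().any():
        missing = ranking.index[ranking.isna()].tolist()[:5]
        raise ValueError(f"ranking does not cover the universe (e.g. {missing})")
    ranks = pd.Series(stats.rankdata(ranking.to_numpy()), index=universe)
    observed = float(ranks.loc[targets].sum())
    rng = np.random.default_rng(seed)
    null = _null_sums(rng, ranks.to_numpy(), len(targets), n_perm)
    return _result("rank_sum", observed, null, "less", seed,
                   keep_null=keep_null, n_targets=len(targets),
                   n_universe=len(universe))


def overlap_enrichment(
    hits,
    flagged,
    universe,
    n_perm: int = 100_000,
    seed: int = 0,
    keep_null: bool = True,
) -> PermutationResult:
    """Overlap of the hit set with a flagged gene set (e.g. coding variants).

    Reports the permutation p (uniform same-size draws) alongside the exact
    upper hypergeometric tail P(X >= observed).
    """
    hits, universe = _check_sets(hits, universe)
    flagged = [g for g in set(flagged) if g in set(universe)]
    ind = pd.Series(0.0, index=universe)
    ind.loc[flagged] = 1.0
    observed = float(ind.loc[hits].sum())
    rng = np.random.default_rng(seed)
    null = _null_sums(rng, ind.to_numpy(), len(hits), n_perm)
    exact = float(stats.hypergeom.sf(observed - 1, len(universe),
                                     len(flagged), len(hits)))
    res = _result("overlap", observed, null, "greater", seed,
                  keep_null=keep_null, n_hits=len(hits),
                  n_flagged=len(flagged), n_universe=len(universe))
    res.exact_p = exact
    return res


def zscore_by_gene(expression: pd.DataFrame) -> pd.DataFrame:
    """z-score each gene's expression across stages (ddof=1; SD 0 -> 0)."""
    if expression.shape[1] < 2:
        raise ValueError("need >= 2 stages")
    mu = expression.mean(axis=1)
    sd = expression.std(axis=1, ddof=1)
    z = expression.sub(mu, axis=0).div(sd.replace(0.0, np.nan), axis=0)
    return z.fillna(0.0)


def stage_expression_enrichment(
    hits,
    expression: pd.DataFrame,
    library_universe,
    n_perm: int = 100_000,
    seed: int = 0,
    keep_null: bool = False,
) -> dict[str, PermutationResult]:
    """Per-stage enrichment of hit-gene expression (z-scored within gene).

    One permutation draw is shared across stages (a drawn gene set yields a
    per-stage sum vector), mirroring a gene-set permutation across a
    multi-stage expression matrix. Returns one result per stage
    (tail = greater).
    """
    hits, universe = _check_sets(hits, library_universe)
    hits, universe, extra = _restrict_to_annotated(
        hits, universe, expression.dropna().index, "drop"
    )
    if not hits:
        raise ValueError("no annotated hits left")
    z = zscore_by_gene(expression.reindex(universe))
    zmat = z.to_numpy()
    k = len(hits)
    observed = z.loc[hits].sum(axis=0)
    rng = np.random.default_rng(seed)
    n = len(universe)
    nulls = np.empty((n_perm, z.shape[1]))
    done = 0
    while done < n_perm:
        b = min(_CHUNK // max(1, z.shape[1]), n_perm - done)
        if k == n:
            nulls[done:done + b] = zmat.sum(axis=0)
        else:
            keys = rng.random((b, n))
            idx = np.argpartition(keys, k, axis=1)[:, :k]
            nulls[done:done + b] = zmat[idx].sum(axis=1)
        done += b
    out = {}
    for j, stage in enumerate(z.columns):
        out[stage] = _result(
            f"stage_expression[{stage}]", float(observed.iloc[j]), nulls[:, j],
            "greater", seed, keep_null=keep_null, n_hits=k, n_universe=n, **extra
        )
    return out
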