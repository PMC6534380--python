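"""Per-gene longitudinal mixed model, multiple testing, and hit calling.

For each gene the response is the log2 fold change ``y`` of its hairpins
versus the day-4 baseline, pooled across donor replicates. The model is

    y = beta_day + b_{h,day} + eps,
    b_{h,day} ~ N(0, sigma2_hairpin) i.i.d. per hairpin x day,
    eps ~ N(0, sigma2)

with ``day`` a categorical fixed effect (no intercept; one coefficient per
post-baseline day, in cumulative log2FC units) and a per-day random effect
per hairpin absorbing knockdown-efficiency and off-target deviations.
Treating the random time term as categorical mirrors the categorical fixed
effect; a single diagonal variance keeps it identifiable with 5-7 hairpins
per gene. The alternative reading — one random slope per hairpin on
elapsed days (``re_mode="slope"``) — is selectable; it assumes hairpin
deviations grow linearly from the baseline and therefore assigns almost no
hairpin-level uncertainty to the earliest day. Variance
components are estimated by REML; each coefficient gets a Wald chi-square
test (1 df), adjusted jointly across all gene x day tests by
Benjamini-Hochberg. A gene is a hit when some day clears both the
effect-size gate (|slope| > 0.1 log2FC/day) and the confidence gate
(q < 0.1).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.regression.mixed_linear_model import MixedLM
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

_FIT_METHODS = ("powell", "lbfgs", "nm")  # bounded restarts, in order
_DEGENERATE_TOL = 1e-10


@dataclass
class GeneModelFit:
    """Fixed-effect estimates and variance components for one gene."""

    gene: str
    days: list[int]
    beta: np.ndarray
    se: np.ndarray
    wald: np.ndarray
    p: np.ndarray
    sigma2_hairpin: float
    sigma2_resid: float
    status: str  # converged | degenerate | failed
    n_hairpins: int
    n_obs: int

    @property
    def converged(self) -> bool:
        return self.status in ("converged", "degenerate")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "gene": self.gene,
                "day": self.days,
                "beta": self.beta,
                "se": self.se,
                "wald": self.wald,
                "p": self.p,
                "sigma2_hairpin": self.sigma2_hairpin,
                "sigma2_resid": self.sigma2_resid,
                "status": self.status,
                "n_hairpins": self.n_hairpins,
                "n_obs": self.n_obs,
            }
        )


def _ols_day_means(fc: pd.DataFrame) -> tuple[list[int], np.ndarray, float]:
    grouped = fc.groupby("day")["y"]
    days = sorted(grouped.groups)
    means = grouped.mean().loc[days].to_numpy()
    sse = float(((fc["y"] - fc["day"].map(grouped.mean())) ** 2).sum())
    return [int(d) for d in days], means, sse


def fit_gene(fc: pd.DataFrame, gene: str | None = None,
             re_mode: str = "per_day") -> GeneModelFit:
    """Fit the mixed model on one gene's fold-change rows.

    ``fc`` needs columns hairpin, day, elapsed_days, y (post-baseline rows
    only). ``re_mode`` selects the random term: "per_day" (default; i.i.d.
    random per-day effects per hairpin, one shared variance) or "slope"
    (one random slope on elapsed days per hairpin).

    A gene whose day-mean fit is exact (zero residual variance, e.g.
    noiseless input) is returned with status "degenerate": the fixed
    effects are the per-day means and no Wald test is defined. Genes
    failing all optimizer restarts come back with status "failed" and are
    excluded from hit calling downstream (never silently dropped).
    """
    if gene is None:
        gene = str(fc["gene"].iloc[0]) if "gene" in fc.columns else "?"
    n_hairpins = fc["hairpin"].nunique()
    days, means, sse = _ols_day_means(fc)
    if n_hairpins < 2:
        raise ValueError(f"{gene}: need >= 2 hairpins")
    if len(days) < 2:
        raise ValueError(f"{gene}: need >= 2 post-baseline days")
    nan = np.full(len(days), np.nan)
    if sse <= _DEGENERATE_TOL * max(1.0, float((fc["y"] ** 2).sum())):
        return GeneModelFit(gene, days, means, np.zeros(len(days)), nan, nan,
                            0.0, 0.0, "degenerate", n_hairpins, len(fc))

    exog = pd.get_dummies(fc["day"].astype("category")).to_numpy(dtype=float)
    groups = fc["hairpin"].to_numpy()
    y = fc["y"].to_numpy(dtype=float)
    if re_mode not in ("slope", "per_day"):
        raise ValueError(f"unknown re_mode {re_mode!r}")

    result = None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for method in _FIT_METHODS:
            try:
                if re_mode == "slope":
                    model = MixedLM(
                        y, exog, groups=groups,
                        exog_re=fc["elapsed_days"].to_numpy(dtype=float)[:, None],
                    )
                else:
                    model = MixedLM.from_formula(
                        "y ~ 0 + C(day)", data=fc, groups="hairpin",
                        vc_formula={"day": "0 + C(day)"},
                        re_formula="0",
                    )
                r = model.fit(reml=True, method=method, maxiter=500)
            except (np.linalg.LinAlgError, ValueError):
                continue
            if r.converged and np.isfinite(r.bse[: len(days)]).all():
                result = r
                break
    if result is None:
        logger.warning("%s: mixed model failed to converge", gene)
        return GeneModelFit(gene, days, means, nan, nan, nan, np.nan, np.nan,
                            "failed", n_hairpins, len(fc))
    beta = np.asarray(result.fe_params)[: len(days)]
    se = np.asarray(result.bse)[: len(days)]
    wald = (beta / se) ** 2
    # floor at the smallest positive double so p stays in (0, 1]
    p = np.maximum(stats.chi2.sf(wald, df=1), np.finfo(float).tiny)
    if re_mode == "slope":
        s2h = float(np.asarray(result.cov_re)[0, 0])
    else:
        s2h = float(list(result.vcomp)[0]) if len(result.vcomp) else 0.0
    return GeneModelFit(gene, days, beta, se, wald, p, s2h,
                        float(result.scale), "converged", n_hairpins, len(fc))


def fit_all_genes(fc: pd.DataFrame, re_mode: str = "per_day",
                  min_hairpins: int = 2) -> pd.DataFrame:
    """Fit every gene in a fold-change table; long gene x day output."""
    if "gene" not in fc.columns:
        raise ValueError("fold-change table needs a 'gene' column")
    frames, skipped = [], []
    for gene, sub in fc.groupby("gene", sort=True):
        if sub["hairpin"].nunique() < min_hairpins or sub["day"].nunique() < 2:
            skipped.append(gene)
            continue
        frames.append(fit_gene(sub, gene=str(gene), re_mode=re_mode).to_frame())
    if skipped:
        logger.warning("skipped %d genes with too few hairpins/days", len(skipped))
    if not frames:
        raise ValueError("no genes could be fitted")
    return pd.concat(frames, ignore_index=True)


def slope_per_day(fits: pd.DataFrame, mode: str = "cumulative",
                  baseline_day: int = 4) -> pd.Series:
    """Per-day slopes from cumulative log2FC coefficients.

    cumulative: beta_k / (t_k - t0) — the average rate since baseline;
    incremental: (beta_k - beta_{k-1}) / (t_k - t_{k-1}) with beta_0 = 0 —
    the rate within each interval.
    """
    if mode == "cumulative":
        return fits["beta"] / (fits["day"] - baseline_day)
    if mode == "incremental":
        out = np.empty(len(fits))
        for _, idx in fits.groupby("gene", sort=False).groups.items():
            sub = fits.loc[idx].sort_values("day")
            prev_b = np.concatenate([[0.0], sub["beta"].to_numpy()[:-1]])
            prev_t = np.concatenate([[baseline_day], sub["day"].to_numpy()[:-1]])
            out[sub.index] = (sub["beta"].to_numpy() - prev_b) / (
                sub["day"].to_numpy() - prev_t
            )
        return pd.Series(out, index=fits.index)
    raise ValueError(f"unknown slope mode {mode!r}")


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q values; NaN p -> NaN q, excluded from m."""
    p = np.asarray(p_values, dtype=float)
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p values must lie in [0, 1]")
    q = np.full(p.shape, np.nan)
    ok = np.isfinite(p)
    if ok.sum():
        q[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return q


@dataclass
class HitCallResult:
    """Gene-level effects, the per-day table with q values, locus summary."""

    gene_effects: pd.DataFrame
    day_table: pd.DataFrame
    locus_summary: dict = field(default_factory=dict)
    thresholds: dict = field(default_factory=dict)

    @property
    def hits(self) -> list[str]:
        ge = self.gene_effects
        return sorted(ge.index[ge["hit"]])


def call_hits(
    fits: pd.DataFrame,
    slope_threshold: float = 0.1,
    q_threshold: float = 0.1,
    slope_mode: str = "cumulative",
    baseline_day: int = 4,
    gene_loci: pd.Series | None = None,
) -> HitCallResult:
    """Dual-threshold hit calling over fitted gene x day effects.

    BH adjustment is applied jointly across every gene x day Wald p value
    (control genes included when present). A gene is a hit iff some day has
    |slope per day| > slope_threshold AND q < q_threshold; its direction is
    the sign at the best (minimum-q) qualifying day. ``gene_loci``
    (gene -> locus) adds a per-locus summary: loci with >= 1 hit and the
    hits-per-locus histogram.
    """
    day_table = fits.copy()
    day_table["q"] = bh_fdr(day_table["p"])
    day_table["slope_per_day"] = slope_per_day(day_table, slope_mode, baseline_day)

    records = []
    for gene, sub in day_table.groupby("gene", sort=True):
        status = sub["status"].iloc[0]
        qualifying = sub[
            (sub["slope_per_day"].abs() > slope_threshold)
            & (sub["q"] < q_threshold)
            & (status == "converged")
        ]
        hit = len(qualifying) > 0
        if hit:
            best = qualifying.loc[qualifying["q"].idxmin()]
            direction = "depleted" if best["slope_per_day"] < 0 else "enriched"
            best_day = int(best["day"])
        else:
            direction = ""
            best_day = (
                int(sub.loc[sub["q"].idxmin(), "day"])
                if sub["q"].notna().any()
                else -1
            )
        records.append(
            {
                "gene": gene,
                "status": status,
                "min_q": float(sub["q"].min()) if sub["q"].notna().any() else np.nan,
                "best_day": best_day,
                "max_abs_slope": float(sub["slope_per_day"].abs().max()),
                "hit": hit,
                "direction": direction,
            }
        )
    gene_effects = pd.DataFrame(records).set_index("gene")

    locus_summary: dict = {}
    if gene_loci is not None:
        loci = gene_loci.reindex(gene_effects.index)
        hits_per_locus = (
            gene_effects["hit"].groupby(loci).sum().astype(int).sort_index()
        )
        hist = hits_per_locus.value_counts().sort_index()
        locus_summary = {
            "n_loci": int(loci.nunique()),
            "loci_with_hit": int((hits_per_locus > 0).sum()),
            "hits_per_locus": hits_per_locus.to_dict(),
            "histogram": {int(k): int(v) for k, v in hist.items()},
        }
    return HitCallResult(
        gene_effects=gene_effects,
        day_table=day_table,
        locus_summary=locus_summary,
        thresholds={
            "slope_threshold": slope_threshold,
            "q_threshold": q_threshold,
            "slope_mode": slope_mode,
            "baseline_day": baseline_day,
        },
    )
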