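"""Turn raw hairpin counts into the model response and compute representation QC.

The screen measures hairpin abundance by deep sequencing at several days of
an erythroid differentiation culture. Counts are normalized per sample to
log2 counts-per-million (after a pseudocount of 1 on every hairpin), and the
model's response variable is the log2 fold change of each hairpin, replicate
and day relative to the same replicate's baseline (day 4) sample.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

SAMPLE_RE = re.compile(r"^(?P<rep>.+)_d(?P<day>\d+)$")


def sample_name(replicate: str, day: int) -> str:
    return f"{replicate}_d{day}"


@dataclass
class CountMatrix:
    """Non-negative integer hairpin x sample abundances with sample metadata.

    ``counts`` is hairpins x samples; ``samples`` is indexed by sample name
    with columns ``replicate`` and ``day``. Column names follow the
    ``<replicate>_d<day>`` convention.
    """

    counts: pd.DataFrame
    samples: pd.DataFrame = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.counts.shape[0] == 0 or self.counts.shape[1] == 0:
            raise ValueError("count matrix must be non-empty")
        if self.samples is None:
            self.samples = self._metadata_from_columns(self.counts.columns)
        if not self.counts.columns.equals(pd.Index(self.samples.index)):
            raise ValueError("sample metadata does not match count columns")
        vals = self.counts.to_numpy()
        if np.isnan(vals).any():
            raise ValueError("count matrix contains missing cells")
        if (vals < 0).any():
            raise ValueError("counts must be non-negative")

    @staticmethod
    def _metadata_from_columns(columns) -> pd.DataFrame:
        recs = []
        for c in columns:
            m = SAMPLE_RE.match(str(c))
            if m is None:
                raise ValueError(
                    f"sample column {c!r} does not follow '<replicate>_d<day>'"
                )
            recs.append((c, m.group("rep"), int(m.group("day"))))
        return pd.DataFrame(
            recs, columns=["sample", "replicate", "day"]
        ).set_index("sample")

    @property
    def hairpins(self) -> pd.Index:
        return self.counts.index

    @property
    def days(self) -> list[int]:
        return sorted(self.samples["day"].unique())

    @property
    def replicates(self) -> list[str]:
        return sorted(self.samples["replicate"].unique())

    def to_tsv(self, path) -> None:
        self.counts.to_csv(path, sep="\t", index_label="hairpin")

    @classmethod
    def from_tsv(cls, path) -> "CountMatrix":
        counts = pd.read_csv(path, sep="\t", index_col=0, comment="#")
        return cls(counts)


def log2_cpm(counts: CountMatrix, pseudocount: float = 1.0) -> pd.DataFrame:
    """Per-sample log2 counts-per-million after pseudocounting.

    The pseudocount is added to every hairpin count *before* the library
    size is computed, so each column back-transforms to exactly 1e6:
    ``value = log2((c + pc) / sum_h (c_h + pc) * 1e6)``.
    """
    c = counts.counts.to_numpy(dtype=float) + pseudocount
    libsize = c.sum(axis=0)
    if (libsize <= 0).any():
        bad = counts.counts.columns[libsize <= 0].tolist()
        raise ValueError(f"non-positive library size in samples {bad}")
    vals = np.log2(c / libsize * 1e6)
    return pd.DataFrame(vals, index=counts.counts.index, columns=counts.counts.columns)


def fold_change_vs_baseline(
    norm: pd.DataFrame,
    samples: pd.DataFrame | None = None,
    baseline_day: int = 4,
    library: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Long-format log2 fold changes of each hairpin vs its replicate baseline.

    Returns rows (hairpin[, gene], replicate, day, elapsed_days, y) for every
    post-baseline sample; baseline rows (y = 0 identically) are dropped.
    ``library`` optionally maps hairpin -> gene (index = hairpin id).
    """
    if samples is None:
        samples = CountMatrix._metadata_from_columns(norm.columns)
    if baseline_day not in set(samples["day"]):
        raise ValueError(f"baseline day {baseline_day} absent from samples")
    frames = []
    for rep, meta in samples.groupby("replicate"):
        base = meta.index[meta["day"] == baseline_day]
        if len(base) == 0:
            raise ValueError(f"replicate {rep!r} has no day-{baseline_day} baseline")
        base_vals = norm[base[0]]
        for samp, row in meta.iterrows():
            if row["day"] == baseline_day:
                continue
            y = norm[samp] - base_vals
            frames.append(
                pd.DataFrame(
                    {
                        "hairpin": norm.index,
                        "replicate": rep,
                        "day": int(row["day"]),
                        "elapsed_days": int(row["day"]) - baseline_day,
                        "y": y.to_numpy(),
                    }
                )
            )
    fc = pd.concat(frames, ignore_index=True)
    if library is not None:
        gene = library["gene"] if "gene" in library.columns else library.iloc[:, 0]
        fc.insert(1, "gene", fc["hairpin"].map(gene))
        missing = fc["gene"].isna()
        if missing.any():
            n = fc.loc[missing, "hairpin"].nunique()
            logger.warning("%d hairpins missing from library annotation; dropped", n)
            fc = fc[~missing].reset_index(drop=True)
    if not np.isfinite(fc["y"]).all():
        raise ValueError("non-finite fold changes")
    return fc


def representation_qc(
    norm: pd.DataFrame,
    samples: pd.DataFrame | None = None,
    day: int = 4,
    threshold_log2cpm: float = 5.0,
) -> dict:
    """Fraction of hairpins represented at >= threshold log2 CPM at a day.

    The headline number uses the mean across replicates at the given day;
    per-replicate fractions are reported alongside.
    """
    if samples is None:
        samples = CountMatrix._metadata_from_columns(norm.columns)
    cols = samples.index[samples["day"] == day]
    if len(cols) == 0:
        raise ValueError(f"day {day} not present")
    mean_vals = norm[cols].mean(axis=1)
    per_rep = {
        str(samples.loc[c, "replicate"]): float((norm[c] >= threshold_log2cpm).mean())
        for c in cols
    }
    return {
        "day": day,
        "threshold_log2cpm": threshold_log2cpm,
        "fraction": float((mean_vals >= threshold_log2cpm).mean()),
        "per_replicate": per_rep,
        "n_hairpins": int(norm.shape[0]),
    }
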