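"""Preprocessing of raw UHPLC glycan peak areas.

Fixed stage order: total-area normalisation -> natural-log transform ->
empirical-Bayes batch correction -> 3-SD outlier removal -> rank-based
inverse-normal transform.  Each stage checks it receives the stage it
expects and stamps its output, so analyses downstream can assert they are
looking at the right scale.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from ._combat import combat

PEAKS = [f"GP{i}" for i in range(1, 40)]

META_COLUMNS = ["sample_id", "patient_id", "batch", "days_from_ici_start"]

STAGES = ("relative", "log", "batch_corrected", "inverse_normal")


@dataclass
class NormalizedGlycome:
    """Samples-by-peaks matrix plus sample metadata and a processing-stage marker."""

    values: pd.DataFrame  # index sample_id, one column per peak/trait
    meta: pd.DataFrame  # index sample_id: patient_id, batch, days_from_ici_start
    stage: str
    removed: dict = field(default_factory=dict)  # column -> n outliers masked

    def copy_with(self, values: pd.DataFrame, stage: str, removed: dict | None = None):
        return NormalizedGlycome(
            values=values, meta=self.meta, stage=stage, removed=removed or dict(self.removed)
        )

    def pretreatment(self) -> "NormalizedGlycome":
        """Subset to the (single) pre-treatment sample of each patient."""
        mask = self.meta["days_from_ici_start"] <= 0
        return NormalizedGlycome(
            values=self.values.loc[mask[mask].index],
            meta=self.meta.loc[mask[mask].index],
            stage=self.stage,
            removed=dict(self.removed),
        )

    def _require(self, stage: str):
        if self.stage != stage:
            raise ValueError(f"expected stage {stage!r}, got {self.stage!r}")


def _split_table(table: pd.DataFrame, peak_columns=None):
    if peak_columns is None:
        peak_columns = [c for c in table.columns if c.startswith("GP")]
    meta_cols = [c for c in META_COLUMNS if c in table.columns]
    meta = table[meta_cols].set_index(table["sample_id"].values)
    values = table[peak_columns].copy()
    values.index = table["sample_id"].values
    return values, meta


def total_area_normalize(table: pd.DataFrame, peak_columns=None) -> NormalizedGlycome:
    """Divide each peak area by its sample's total chromatogram area.

    Rows with any non-positive peak are rejected with a diagnostic listing
    the offending sample ids.
    """
    values, meta = _split_table(table, peak_columns)
    bad = values.index[(values <= 0).any(axis=1) | values.isna().any(axis=1)]
    if len(bad):
        raise ValueError(
            "non-positive or missing peak areas for samples: " + ", ".join(map(str, bad[:10]))
        )
    rel = values.div(values.sum(axis=1), axis=0)
    return NormalizedGlycome(values=rel, meta=meta, stage="relative")


def log_transform(g: NormalizedGlycome, pseudo_fraction: bool = False) -> NormalizedGlycome:
    """Natural log of relative abundances.

    Zero fractions are not expected from chromatogram areas; if present and
    ``pseudo_fraction`` is set, they are replaced with half the smallest
    positive value of their column, otherwise an error is raised.
    """
    g._require("relative")
    vals = g.values.copy()
    if (vals <= 0).any().any():
        if not pseudo_fraction:
            raise ValueError(
                "zero relative abundances present; pass pseudo_fraction=True to "
                "replace them with half the column minimum positive value"
            )
        for col in vals.columns:
            zero = vals[col] <= 0
            if zero.any():
                vals.loc[zero, col] = vals.loc[~zero, col].min() / 2.0
    return g.copy_with(np.log(vals), "log")


def combat_correct(g: NormalizedGlycome, batch=None) -> NormalizedGlycome:
    """Empirical-Bayes location/scale batch correction of log abundances."""
    g._require("log")
    if batch is None:
        batch = g.meta["batch"]
    batch = pd.Series(np.asarray(batch), index=g.values.index)
    corrected = combat(g.values.to_numpy(), batch.to_numpy())
    out = pd.DataFrame(corrected, index=g.values.index, columns=g.values.columns)
    return g.copy_with(out, "batch_corrected")


def remove_outliers(g: NormalizedGlycome, n_sd: float = 3.0) -> NormalizedGlycome:
    """Mask values more than ``n_sd`` sample SDs from their column mean.

    Mean and SD are computed once on the incoming values (no iteration).
    """
    g._require("batch_corrected")
    vals = g.values.copy()
    removed = {}
    for col in vals.columns:
        x = vals[col]
        sd = x.std(ddof=1)
        if not np.isfinite(sd) or sd == 0:
            warnings.warn(f"column {col} has zero SD; no outliers removed")
            removed[col] = 0
            continue
        mask = (x - x.mean()).abs() > n_sd * sd
        removed[col] = int(mask.sum())
        vals.loc[mask, col] = np.nan
    return g.copy_with(vals, "batch_corrected", removed=removed)


def _blom(x: pd.Series) -> pd.Series:
    ok = x.notna()
    n = int(ok.sum())
    ranks = stats.rankdata(x[ok])
    q = (ranks - 3.0 / 8.0) / (n + 0.25)
    out = pd.Series(np.nan, index=x.index)
    out[ok] = stats.norm.ppf(q)
    return out


def inverse_normal(g: NormalizedGlycome) -> NormalizedGlycome:
    """Rank-based inverse-normal transform, Blom offset, average ranks for ties.

    Columns with fewer than 3 non-missing values are dropped with a warning.
    """
    g._require("batch_corrected")
    cols = {}
    for col in g.values.columns:
        x = g.values[col]
        if x.notna().sum() < 3:
            warnings.warn(f"column {col} has <3 non-missing values; dropped")
            continue
        cols[col] = _blom(x)
    return g.copy_with(pd.DataFrame(cols, index=g.values.index), "inverse_normal")


def preprocess_chain(
    table: pd.DataFrame,
    peak_columns=None,
    stop_after: str = "inverse_normal",
    outlier_sd: float = 3.0,
    pseudo_fraction: bool = False,
) -> NormalizedGlycome:
    """Run the full fixed-order preprocessing chain up to ``stop_after``."""
    if stop_after not in STAGES:
        raise ValueError(f"unknown stage {stop_after!r}")
    g = total_area_normalize(table, peak_columns)
    if stop_after == "relative":
        return g
    g = log_transform(g, pseudo_fraction=pseudo_fraction)
    if stop_after == "log":
        return g
    g = combat_correct(g)
    if stop_after == "batch_corrected":
        return g
    g = remove_outliers(g, n_sd=outlier_sd)
    return inverse_normal(g)


def transform_values_like_peaks(
    values: pd.DataFrame,
    meta: pd.DataFrame,
    stop_after: str = "inverse_normal",
    outlier_sd: float = 3.0,
) -> NormalizedGlycome:
    """Send an arbitrary relative-abundance matrix (e.g. derived traits)
    through the log -> batch -> outlier -> inverse-normal chain."""
    g = NormalizedGlycome(values=values, meta=meta, stage="relative")
    g = log_transform(g, pseudo_fraction=True)
    if stop_after == "log":
        return g
    g = combat_correct(g)
    if stop_after == "batch_corrected":
        return g
    g = remove_outliers(g, n_sd=outlier_sd)
    if stop_after == "inverse_normal":
        g = inverse_normal(g)
    return g


def write_processed(g: NormalizedGlycome, path) -> None:
    """Write the matrix as TSV with a ``# stage=...`` metadata header line."""
    with open(path, "w") as fh:
        fh.write(f"# stage={g.stage}\n")
        g.values.join(g.meta, how="left").to_csv(fh, sep="\t", index_label="sample_id", na_rep="NA")
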