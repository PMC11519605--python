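"""Heavy/light MS1 ratio aggregation and ligandability calling.

Row-level rules: methionine-oxidized peptide rows are excluded; rows
with both channels give log2(H/L); unpaired rows are kept at the caps
log2(20) (heavy-only) or log2(1/20) (light-only). A zero-intensity
channel counts as absent. Site-level aggregation takes the median log2
ratio over peptide rows per replicate, then the mean (and sample SD,
n-1) across replicates; sites pass when quantified in at least two
replicates with SD <= 1 (the SD filter can be disabled for ratio-skew
benchmarking). A passing site with mean log2 ratio strictly greater
than 2 is called ligandable.

Channel orientation: DMSO = heavy, compound = light, so a competed
(ligandable) cysteine shows an elevated H:L ratio; ``swap_channels``
covers the inverse design.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

LOG2_CAP = float(np.log2(20.0))
LIGANDABLE_THRESHOLD = 2.0

QUANT_COLUMNS = [
    "modified_peptide",
    "site_id",
    "replicate_id",
    "heavy_intensity",
    "light_intensity",
    "has_met_oxidation",
]


class InvalidQuantRow(ValueError):
    """Both channels absent: the row quantifies nothing."""


def row_ratio(
    heavy: float | None,
    light: float | None,
    has_met_oxidation: bool = False,
    swap_channels: bool = False,
) -> float | None:
    """Log2 H:L ratio for one quantified peptide row, or None if excluded."""
    if has_met_oxidation:
        return None
    h = None if heavy is None or not np.isfinite(heavy) or heavy <= 0 else float(heavy)
    l = None if light is None or not np.isfinite(light) or light <= 0 else float(light)
    if swap_channels:
        h, l = l, h
    if h is None and l is None:
        raise InvalidQuantRow("row has neither heavy nor light intensity")
    if h is None:
        return -LOG2_CAP
    if l is None:
        return LOG2_CAP
    return float(np.clip(np.log2(h / l), -LOG2_CAP, LOG2_CAP))


def row_ratios(table: pd.DataFrame, swap_channels: bool = False) -> pd.DataFrame:
    """Apply :func:`row_ratio` to a quant table; excluded rows are dropped."""
    out = table.copy()
    ratios = []
    for r in out.itertuples():
        h = getattr(r, "heavy_intensity", None)
        l = getattr(r, "light_intensity", None)
        ratios.append(
            row_ratio(
                None if pd.isna(h) else h,
                None if pd.isna(l) else l,
                bool(getattr(r, "has_met_oxidation", False)),
                swap_channels,
            )
        )
    out["log2_ratio"] = ratios
    return out[out["log2_ratio"].notna()].reset_index(drop=True)


def aggregate_site(
    rows: pd.DataFrame,
    min_replicates: int = 2,
    sd_max: float | None = 1.0,
    ligandable_threshold: float = LIGANDABLE_THRESHOLD,
) -> pd.DataFrame:
    """Per-site quantification from row-level log2 ratios.

    ``rows`` needs columns site_id, replicate_id, log2_ratio (see
    :func:`row_ratios`). Median over rows within each (site, replicate)
    — midpoint convention for even counts — then mean and sample SD across
    replicate medians. Aggregation is independent of row order.
    """
    per_rep = (
        rows.groupby(["site_id", "replicate_id"], sort=True)["log2_ratio"]
        .median()
        .reset_index()
    )
    grouped = per_rep.groupby("site_id", sort=True)["log2_ratio"]
    out = grouped.agg(
        mean_log2_ratio="mean",
        ratio_sd=lambda s: s.std(ddof=1),
        n_replicates="count",
    ).reset_index()
    out["passes_filters"] = (out["n_replicates"] >= min_replicates) & (
        True if sd_max is None else (out["ratio_sd"] <= sd_max)
    )
    out["is_ligandable"] = out["passes_filters"] & (
        out["mean_log2_ratio"] > ligandable_threshold
    )
    return out


def call_ligandable(
    site: pd.Series, threshold: float = LIGANDABLE_THRESHOLD
) -> bool:
    """Ligandable iff the site passes filters and mean log2 ratio > threshold
    (strict inequality: a site at exactly the threshold is not called)."""
    return bool(site["passes_filters"] and site["mean_log2_ratio"] > threshold)


def read_quant_table(path, replicate_id: str | int | None = None) -> pd.DataFrame:
    """Read one replicate quant TSV (modified_peptide_label_quant dialect)."""
    df = pd.read_csv(path, sep="\t")
    missing = {"heavy_intensity", "light_intensity"} - set(df.columns)
    if missing:
        raise ValueError(f"quant table missing columns: {sorted(missing)}")
    if "site_id" not in df.columns:
        df["site_id"] = df["modified_peptide"]
    if "has_met_oxidation" not in df.columns:
        df["has_met_oxidation"] = False
    if replicate_id is not None:
        df["replicate_id"] = replicate_id
    return df


def quantify(
    tables: list[pd.DataFrame],
    min_replicates: int = 2,
    sd_max: float | None = 1.0,
    ligandable_threshold: float = LIGANDABLE_THRESHOLD,
    swap_channels: bool = False,
) -> pd.DataFrame:
    """Full row→site pipeline over replicate tables."""
    frames = []
    for i, t in enumerate(tables):
        t = t.copy()
        if "replicate_id" not in t.columns:
            t["replicate_id"] = i + 1
        frames.append(t)
    rows = row_ratios(pd.concat(frames, ignore_index=True), swap_channels)
    return aggregate_site(rows, min_replicates, sd_max, ligandable_threshold)


def recover_design_ratio(
    tables: list[pd.DataFrame],
    sd_max: float | None = None,
    swap_channels: bool = False,
) -> float:
    """Median recovered H:L fold across sites — the benchmark surface.

    Runs the row→site pipeline without the SD filter (the ratio-skew
    benchmark mode) and returns the median of 2**mean_log2_ratio.
    """
    sites = quantify(tables, min_replicates=2, sd_max=sd_max,
                     swap_channels=swap_channels)
    kept = sites[sites["passes_filters"]]
    if kept.empty:
        raise ValueError("no site passed the replicate filter")
    return float(np.median(np.power(2.0, kept["mean_log2_ratio"])))
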