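"""Food-web analysis on per-compound delta-2H tables.

Two operations: area-weighted pooling of compounds into fatty-acid classes
(SFA/MUFA, n-6 PUFA, n-3 PUFA) per sample, and site-specific ordinary
least-squares regression of consumer delta-2H on potential-diet delta-2H.
Diet values are averaged per (site, compound) before pairing; consumers
enter as individual records.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import linregress

__all__ = ["DietConsumerFit", "pool_weighted", "diet_consumer_fit"]

_RECORD_COLUMNS = {"compound", "delta_fa", "area2"}


@dataclass(frozen=True)
class DietConsumerFit:
    consumer: str
    diet: str
    intercept: float   # per mil
    slope: float
    r_squared: float
    n_pairs: int


def pool_weighted(
    records: pd.DataFrame,
    class_map: dict[str, str],
    by: tuple[str, ...] = ("sample",),
) -> pd.DataFrame:
    """Peak-area-weighted class-level delta-2H per sample.

    ``records`` needs columns ``compound``, ``delta_fa``, ``area2`` (plus
    the grouping columns in ``by``; an optional ``u`` column is pooled by
    area-weighted quadrature).  Compounds absent from ``class_map`` and
    empty classes are omitted, not reported as zero.
    """
    missing = _RECORD_COLUMNS - set(records.columns)
    if missing:
        raise ValueError(f"records table lacks column(s) {sorted(missing)}")
    if (records["area2"] <= 0).any():
        raise ValueError("all peak areas must be positive")
    df = records[records["compound"].isin(class_map)].copy()
    df["fa_class"] = df["compound"].map(class_map)
    rows = []
    for key, grp in df.groupby([*by, "fa_class"], sort=True):
        w = grp["area2"].to_numpy(dtype=float)
        w = w / w.sum()
        delta = float(np.sum(w * grp["delta_fa"].to_numpy(dtype=float)))
        row = dict(zip([*by, "fa_class"], key if isinstance(key, tuple) else (key,)))
        row["delta_fa"] = delta
        row["n_compounds"] = len(grp)
        if "u" in grp.columns:
            row["u"] = float(np.sqrt(np.sum((w * grp["u"].to_numpy(dtype=float)) ** 2)))
        rows.append(row)
    return pd.DataFrame(rows)


def diet_consumer_fit(
    consumer: pd.DataFrame,
    diet: pd.DataFrame,
    consumer_name: str = "consumer",
    diet_name: str = "diet",
    tissue: str | None = "muscle",
) -> DietConsumerFit:
    """Site-specific OLS of consumer delta-2H on potential-diet delta-2H.

    Both tables need columns ``site``, ``compound``, ``delta_fa`` (consumer
    additionally ``tissue`` when a tissue filter applies).  Diet values are
    averaged per (site, compound); each consumer record is then paired with
    the diet mean for its (site, compound).  Refuses to fit fewer than 3
    pairs.
    """
    for name, df in (("consumer", consumer), ("diet", diet)):
        missing = {"site", "compound", "delta_fa"} - set(df.columns)
        if missing:
            raise ValueError(f"{name} table lacks column(s) {sorted(missing)}")
    if tissue is not None and "tissue" in consumer.columns:
        consumer = consumer[consumer["tissue"] == tissue]
    diet_means = (
        diet.groupby(["site", "compound"], as_index=False)["delta_fa"]
        .mean()
        .rename(columns={"delta_fa": "delta_diet"})
    )
    paired = consumer.merge(diet_means, on=["site", "compound"], how="inner")
    if len(paired) < 3:
        raise ValueError(
            f"only {len(paired)} shared (site, compound) pairs between "
            f"{consumer_name} and {diet_name}; at least 3 are required"
        )
    fit = linregress(paired["delta_diet"].to_numpy(float), paired["delta_fa"].to_numpy(float))
    return DietConsumerFit(
        consumer=consumer_name,
        diet=diet_name,
        intercept=float(fit.intercept),
        slope=float(fit.slope),
        r_squared=float(fit.rvalue ** 2),
        n_pairs=int(len(paired)),
    )
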