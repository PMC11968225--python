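"""Caliper morphometry: implant volumes and fold changes.

Volumes come from external caliper length/width/height. The default formula
is the ellipsoid V = (pi/6) l w h, which suits the lenticular shape of a
subcutaneous injection; a rectangular-box formula is available. Because the
primary readouts are fold changes relative to implantation (timepoint 0),
the formula constant cancels and the choice does not affect them.

Outlier handling: an optional median-absolute-deviation (MAD) flagging of
fold changes is provided (off by default) and flagged ids are recorded
rather than silently dropped.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

VOLUME_FORMULAS = ("ellipsoid", "box")


def implant_volume(
    length_mm: float | np.ndarray,
    width_mm: float | np.ndarray,
    height_mm: float | np.ndarray,
    formula: str = "ellipsoid",
) -> float | np.ndarray:
    """Implant volume (mm^3) from caliper dimensions.

    ``ellipsoid``: V = (pi/6) l w h;  ``box``: V = l w h.
    """
    l = np.asarray(length_mm, dtype=float)
    w = np.asarray(width_mm, dtype=float)
    h = np.asarray(height_mm, dtype=float)
    if (l <= 0).any() or (w <= 0).any() or (h <= 0).any():
        raise ValueError("all caliper dimensions must be positive")
    if formula == "ellipsoid":
        v = np.pi / 6 * l * w * h
    elif formula == "box":
        v = l * w * h
    else:
        raise ValueError(f"unknown formula {formula!r}; expected {VOLUME_FORMULAS}")
    return float(v) if v.ndim == 0 else v


def fold_change(records: pd.DataFrame, formula: str = "ellipsoid") -> pd.DataFrame:
    """Volume and height fold change per implant relative to timepoint 0.

    ``records`` needs columns implant_id, timepoint, length_mm, width_mm,
    height_mm (extra metadata columns are carried through). Raises
    ``ValueError`` naming any implant without a timepoint-0 baseline.
    """
    df = records.copy()
    df["volume_mm3"] = implant_volume(
        df["length_mm"], df["width_mm"], df["height_mm"], formula
    )
    baselines = df[df["timepoint"] == 0].set_index("implant_id")
    missing = sorted(set(df["implant_id"]) - set(baselines.index))
    if missing:
        raise ValueError(f"no timepoint-0 baseline for implant(s): {missing}")
    v0 = baselines["volume_mm3"]
    h0 = baselines["height_mm"]
    out = df.copy()
    out["volume_fold"] = df["volume_mm3"].to_numpy() / v0.loc[df["implant_id"]].to_numpy()
    out["height_fold"] = df["height_mm"].to_numpy() / h0.loc[df["implant_id"]].to_numpy()
    return out


def summarize_folds(folds: pd.DataFrame, by: tuple[str, ...] = ("group", "timepoint")
                    ) -> pd.DataFrame:
    """Group-level mean +/- SD of fold changes, plus percent volume decrease
    (100 * (1 - mean volume fold))."""
    by_cols = [c for c in by if c in folds.columns]
    g = folds.groupby(by_cols, sort=True)
    out = g.agg(
        n=("volume_fold", "size"),
        volume_fold_mean=("volume_fold", "mean"),
        volume_fold_sd=("volume_fold", "std"),
        height_fold_mean=("height_fold", "mean"),
        height_fold_sd=("height_fold", "std"),
    ).reset_index()
    out["volume_pct_decrease"] = 100.0 * (1.0 - out["volume_fold_mean"])
    return out


def flag_outliers_mad(
    folds: pd.DataFrame, column: str = "volume_fold", n_mads: float = 3.5
) -> pd.DataFrame:
    """Flag records whose fold deviates from the per-timepoint median by more
    than ``n_mads`` scaled MADs. Returns the table with an ``outlier``
    column; nothing is dropped."""
    out = folds.copy()
    out["outlier"] = False
    for _, idx in out.groupby("timepoint").groups.items():
        vals = out.loc[idx, column].to_numpy(dtype=float)
        med = np.median(vals)
        mad = np.median(np.abs(vals - med)) * 1.4826
        if mad == 0:
            continue
        out.loc[idx, "outlier"] = np.abs(vals - med) > n_mads * mad
    return out
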