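"""Use-report cleaning: outlier fence, label-error filter, rate selection.

Large self-reported pesticide/adjuvant use registries contain entry and
unit errors.  This module turns raw per-application records into a
defensible per-chemical maximum application rate:

1. harmonize rate units to kg a.i./ha;
2. flag rates above the IQR upper fence (Q3 + 1.5 × IQR) as outliers and
   remove them;
3. on the remainder, flag rates more than one order of magnitude above
   the highest commercial label rate as likely data errors and remove
   them;
4. select the exposure rate: the maximum over records of neat (unblended)
   products when any exist, otherwise the 90th percentile of all rates as
   a conservative stand-in for the neat-material maximum.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import InsufficientDataError
from .exposure import convert_rate

__all__ = [
    "CleanSummary",
    "iqr_upper_fence",
    "harmonize_units",
    "flag_records",
    "select_exposure_rate",
    "clean_use_records",
]

#: Accepted unit spellings -> canonical unit.
_UNIT_ALIASES = {
    "kg_per_ha": "kg_per_ha",
    "kg/ha": "kg_per_ha",
    "lb_per_acre": "lb_per_acre",
    "lb/acre": "lb_per_acre",
    "lbs/acre": "lb_per_acre",
}


@dataclass
class CleanSummary:
    """Audit record of one cleaning pass over a chemical's records."""

    chemical_id: str
    n_total: int
    n_unparseable_units: int
    n_outliers: int
    n_errors: int
    upper_fence: float
    max_rate_neat: float | None
    p90_rate: float
    selected_rate: float
    provenance: str  # neat_max | p90_mixture

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)


def iqr_upper_fence(
    rates: Sequence[float], method: str = "linear"
) -> float:
    """Upper outlier fence Q3 + 1.5 × (Q3 − Q1).

    ``method`` is the quantile estimator passed to numpy (default linear
    interpolation between order statistics).  Requires at least four
    finite positive rates.
    """
    arr = np.asarray(list(rates), dtype=float)
    arr = arr[np.isfinite(arr) & (arr > 0)]
    if arr.size < 4:
        raise InsufficientDataError(
            f"IQR fence needs >= 4 finite positive rates, got {arr.size}"
        )
    q1, q3 = np.quantile(arr, [0.25, 0.75], method=method)
    return float(q3 + 1.5 * (q3 - q1))


def harmonize_units(df: pd.DataFrame) -> tuple[pd.DataFrame, int]:
    """Convert the ``rate``/``unit`` columns to kg/ha in ``rate_kg_ha``.

    Records with unrecognised units are dropped; the drop count is
    returned alongside the harmonized frame.
    """
    unit = df["unit"].astype(str).str.strip().str.lower().map(_UNIT_ALIASES)
    ok = unit.notna()
    out = df.loc[ok].copy()
    unit = unit.loc[ok]
    rate = out["rate"].astype(float).to_numpy()
    lb = unit.to_numpy() == "lb_per_acre"
    rate = np.where(lb, [convert_rate(r, "lb_per_acre", "kg_per_ha") for r in rate], rate)
    out["rate_kg_ha"] = rate
    return out, int((~ok).sum())


def flag_records(
    df: pd.DataFrame, fence: float, max_label_rate: float
) -> pd.DataFrame:
    """Add ``outlier`` and ``likely_error`` flags to harmonized records.

    A record is an outlier iff its rate strictly exceeds the fence, and a
    likely error iff it strictly exceeds 10 × the highest label rate
    (both flags may co-occur).  Removal is two-pass: outliers first, then
    error review on the remainder — ``removed_as`` records which pass
    removed each record.
    """
    if fence <= 0 or max_label_rate <= 0:
        raise ValueError("fence and max_label_rate must be > 0")
    out = df.copy()
    rate = out["rate_kg_ha"].astype(float)
    out["outlier"] = rate > fence
    out["likely_error"] = rate > 10.0 * max_label_rate
    removed = np.where(
        out["outlier"], "outlier", np.where(out["likely_error"], "likely_error", "")
    )
    out["removed_as"] = removed
    return out


def select_exposure_rate(df: pd.DataFrame, chemical_id: str = "") -> tuple[float, str]:
    """Pick the exposure rate from cleaned records.

    Maximum over neat-product records when any exist; otherwise the 90th
    percentile (linear interpolation) of all cleaned rates.
    """
    if len(df) == 0:
        raise InsufficientDataError("cannot select an exposure rate from no records")
    rates = df["rate_kg_ha"].astype(float).to_numpy()
    if "neat" in df.columns and bool(df["neat"].astype(bool).any()):
        return float(rates[df["neat"].astype(bool).to_numpy()].max()), "neat_max"
    return float(np.quantile(rates, 0.9, method="linear")), "p90_mixture"


def clean_use_records(
    df: pd.DataFrame,
    max_label_rate: float,
    quantile_method: str = "linear",
    group_by: str | None = None,
) -> tuple[pd.DataFrame, list[CleanSummary]]:
    """Full cleaning pass: harmonize, fence, flag, remove, select.

    The fence and percentiles are computed per chemical over all crops
    pooled by default; pass ``group_by="crop"`` to fence within each
    chemical × crop group instead.  Returns the cleaned records (flagged
    rows removed) and one :class:`CleanSummary` per chemical.
    """
    harmonized, n_dropped = harmonize_units(df)
    cleaned_parts: list[pd.DataFrame] = []
    summaries: list[CleanSummary] = []
    for chem, chem_df in harmonized.groupby("chemical_id", sort=True):
        if group_by == "crop":
            flagged = pd.concat(
                [
                    flag_records(g, iqr_upper_fence(g["rate_kg_ha"], quantile_method),
                                 max_label_rate)
                    for _, g in chem_df.groupby("crop")
                ]
            )
            fence = float("nan")
        else:
            fence = iqr_upper_fence(chem_df["rate_kg_ha"], quantile_method)
            flagged = flag_records(chem_df, fence, max_label_rate)
        kept = flagged[flagged["removed_as"] == ""]
        n_out = int((flagged["removed_as"] == "outlier").sum())
        n_err = int((flagged["removed_as"] == "likely_error").sum())
        selected, provenance = select_exposure_rate(kept, str(chem))
        neat_max = None
        if "neat" in kept.columns and bool(kept["neat"].astype(bool).any()):
            neat_max = float(
                kept.loc[kept["neat"].astype(bool), "rate_kg_ha"].max()
            )
        summaries.append(
            CleanSummary(
                chemical_id=str(chem),
                n_total=len(chem_df),
                n_unparseable_units=n_dropped,
                n_outliers=n_out,
                n_errors=n_err,
                upper_fence=fence,
                max_rate_neat=neat_max,
                p90_rate=float(
                    np.quantile(kept["rate_kg_ha"], 0.9, method=quantile_method)
                ),
                selected_rate=selected,
                provenance=provenance,
            )
        )
        cleaned_parts.append(kept)
    cleaned = pd.concat(cleaned_parts) if cleaned_parts else harmonized.iloc[:0]
    return cleaned, summaries
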