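"""Injury-clearance kinetics: within-animal normalized fluorescence.

After unilateral antennal ablation, GFP-labeled axonal debris on the injured
side is cleared by ensheathing glia over days 1-4 while the uninjured side of
the same animal serves as an endogenous control. The readout per fly and day
is the ratio injured / uninjured; group summaries are means over flies.

Records with a non-positive uninjured intensity cannot be normalized; they
are flagged (not silently dropped) so the usable n stays auditable.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

REQUIRED_COLUMNS = (
    "fly_id", "diet_group", "day_post_injury",
    "injured_intensity", "uninjured_intensity",
)


@dataclasses.dataclass(frozen=True)
class ClearanceRecord:
    fly_id: str
    diet_group: str
    day_post_injury: int
    injured_intensity: float
    uninjured_intensity: float
    normalized_ratio: float | None
    usable: bool


def normalize_record(injured: float, uninjured: float) -> float:
    """injured / uninjured; requires a positive uninjured intensity."""
    if injured < 0:
        raise ValueError("injured intensity must be >= 0")
    if uninjured <= 0:
        raise ValueError("uninjured intensity must be positive to normalize")
    return injured / uninjured


def normalize_table(table: pd.DataFrame) -> pd.DataFrame:
    """Add ``normalized_ratio`` and ``usable`` columns to a record table."""
    missing = [c for c in REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"clearance table missing columns: {missing}")
    out = table.copy()
    usable = (out["uninjured_intensity"] > 0) & (out["injured_intensity"] >= 0)
    out["usable"] = usable
    out["normalized_ratio"] = np.where(
        usable,
        out["injured_intensity"] / out["uninjured_intensity"].where(usable, other=np.nan),
        np.nan,
    )
    return out


def summarize_timecourse(table: pd.DataFrame) -> pd.DataFrame:
    """Per (diet_group, day) mean ratio, SD, and usable/unusable counts.

    Group x day cells with no usable record appear with n = 0 and NaN
    summaries rather than vanishing.
    """
    if len(table) == 0:
        raise ValueError("empty clearance table")
    norm = table if "normalized_ratio" in table.columns else normalize_table(table)
    rows = []
    groups = sorted(norm["diet_group"].unique())
    days = sorted(norm["day_post_injury"].unique())
    for group in groups:
        for day in days:
            cell = norm[(norm["diet_group"] == group) & (norm["day_post_injury"] == day)]
            ok = cell[cell["usable"]] if "usable" in cell.columns else cell
            n = len(ok)
            rows.append({
                "diet_group": group,
                "day_post_injury": day,
                "mean_ratio": float(ok["normalized_ratio"].mean()) if n else float("nan"),
                "sd_ratio": (float(ok["normalized_ratio"].std(ddof=1))
                             if n > 1 else float("nan")),
                "n": n,
                "n_unusable": int(len(cell) - n),
            })
    return pd.DataFrame(rows)
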