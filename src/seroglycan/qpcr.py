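"""Relative quantification of target taxa by qPCR via the 2^-dCt method.

A target amplicon (e.g. a genus- or species-specific 16S primer pair) is
quantified relative to a total-bacteria amplicon run on the same plate:
relative quantity = 2^-(Ct_target - Ct_total).  Assumes doubling per cycle
(amplification efficiency 2); technical replicates are averaged on the Ct
scale before the difference is taken.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .stats import GroupTestResult

TOTAL_TARGET = "total_bacteria"

__all__ = [
    "QPCRRecord",
    "read_ct_table",
    "relative_quantity",
    "relative_quantity_table",
    "compare_fractions",
]


@dataclass(frozen=True)
class QPCRRecord:
    """One qPCR well: sample, target amplicon, threshold cycle, plate."""

    sample_id: str
    target: str
    ct: float
    plate_id: str = "plate1"

    def __post_init__(self) -> None:
        if not (self.ct > 0 and math.isfinite(self.ct)):
            raise ValueError(f"Ct must be a positive finite number, got {self.ct}")


def read_ct_table(path) -> pd.DataFrame:
    """Read a Ct table TSV (sample_id, target, ct, plate_id)."""
    frame = pd.read_csv(path, sep="\t")
    required = {"sample_id", "target", "ct"}
    missing = required - set(frame.columns)
    if missing:
        raise ValueError(f"Ct table lacks columns: {sorted(missing)}")
    if "plate_id" not in frame.columns:
        frame["plate_id"] = "plate1"
    frame["ct"] = frame["ct"].astype(float)
    if (frame["ct"] <= 0).any():
        raise ValueError("Ct values must be positive")
    return frame


def relative_quantity(ct_target: float, ct_total: float) -> float:
    """2^-(Ct_target - Ct_total); equals the target:total template ratio
    under perfect efficiency."""
    if ct_target is None or ct_total is None:
        raise ValueError("both target and total Ct are required")
    return float(2.0 ** -(float(ct_target) - float(ct_total)))


def relative_quantity_table(records: pd.DataFrame) -> pd.DataFrame:
    """Per (sample, target) relative quantity versus the same-plate total.

    Technical replicates are averaged on the Ct scale first.  A sample
    whose plate lacks the total-bacteria amplicon is an error.
    """
    means = (
        records.groupby(["plate_id", "sample_id", "target"], sort=True)["ct"]
        .mean()
        .reset_index()
    )
    totals = means[means["target"] == TOTAL_TARGET].set_index(
        ["plate_id", "sample_id"]
    )["ct"]
    targets = means[means["target"] != TOTAL_TARGET]
    rows = []
    for row in targets.itertuples(index=False):
        key = (row.plate_id, row.sample_id)
        if key not in totals.index:
            raise ValueError(
                f"sample {row.sample_id!r} on plate {row.plate_id!r} has no "
                f"{TOTAL_TARGET} amplicon"
            )
        rows.append(
            {
                "sample_id": row.sample_id,
                "target": row.target,
                "ct": row.ct,
                "ct_total": float(totals[key]),
                "relative_quantity": relative_quantity(row.ct, totals[key]),
            }
        )
    return pd.DataFrame(rows)


def compare_fractions(
    values_by_group: Mapping[str, Sequence[float]],
) -> GroupTestResult:
    """Classic two-sided Student's t-test (equal variance) on two groups of
    relative quantities, e.g. IgG-positive versus unsorted samples."""
    if len(values_by_group) != 2:
        raise ValueError("compare_fractions expects exactly two groups")
    (name_a, a), (name_b, b) = [
        (k, np.asarray(v, dtype=float)) for k, v in values_by_group.items()
    ]
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs >= 2 values")
    degenerate = np.ptp(a) == 0 and np.ptp(b) == 0
    if degenerate and a.mean() == b.mean():
        t_stat, p = 0.0, 1.0
    else:
        t_stat, p = sps.ttest_ind(a, b, equal_var=True)
        degenerate = False
    return GroupTestResult(
        comparison=f"{name_a}_vs_{name_b}",
        method="t_test",
        statistic=float(t_stat),
        p_raw=float(p),
        p_adjusted=float(p),
        n_per_group={name_a: len(a), name_b: len(b)},
        degenerate=degenerate,
    )
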