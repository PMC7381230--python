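"""Glycan-array spot processing: background subtraction, replicate averaging,
clamping and the per-sample log2 reactivity matrix.

The processing contract mirrors standard scanner-export handling for serum
antibody arrays: background (the mean signal of an annulus around each spot)
is subtracted per spot, replicate net signals are averaged, non-positive
means are clamped to 1 RFU, and all downstream analysis runs on log2(RFU).
Cells are therefore never negative.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .glycans import LibraryPartition, partition_library

logger = logging.getLogger(__name__)

#: Non-positive replicate means are set to this RFU value before log2.
DEFAULT_CLAMP_VALUE = 1.0
#: Arrays are printed with this many replicate spots per glycan.
DEFAULT_EXPECTED_REPLICATES = 4
#: Spot and local-background geometry (microns), descriptive metadata only.
DEFAULT_SPOT_DIAMETER_UM = 110.0
DEFAULT_BACKGROUND_DIAMETER_UM = 330.0

REQUIRED_SPOT_COLUMNS = (
    "sample_id",
    "isotype",
    "glycan_id",
    "replicate_index",
    "foreground_mean",
    "background_mean",
)

__all__ = [
    "SpotRecord",
    "ReactivityMatrix",
    "read_spot_table",
    "net_signal",
    "aggregate_replicates",
    "build_reactivity_matrix",
]


@dataclass(frozen=True)
class SpotRecord:
    """One scanned spot: foreground and local-background mean fluorescence."""

    sample_id: str
    isotype: str
    glycan_id: str
    replicate_index: int
    foreground_mean: float
    background_mean: float
    spot_diameter_um: float = DEFAULT_SPOT_DIAMETER_UM
    background_diameter_um: float = DEFAULT_BACKGROUND_DIAMETER_UM

    def __post_init__(self) -> None:
        if self.foreground_mean < 0 or self.background_mean < 0:
            raise ValueError(
                f"negative mean fluorescence for spot {self.sample_id}/"
                f"{self.glycan_id} replicate {self.replicate_index}"
            )


@dataclass
class ReactivityMatrix:
    """Samples x glycans log2(RFU) with sample and glycan annotations.

    ``values`` is a complete DataFrame (index sample_id, columns glycan_id);
    every cell is log2 of a clamped RFU >= 1 and hence >= 0.
    """

    values: pd.DataFrame
    isotype: str
    sample_groups: pd.Series
    igg_concentration: pd.Series | None = None
    library: LibraryPartition | None = None
    clamp_value: float = DEFAULT_CLAMP_VALUE

    @property
    def samples(self) -> list[str]:
        return list(self.values.index)

    @property
    def glycans(self) -> list[str]:
        return list(self.values.columns)

    def group_samples(self, group: str) -> list[str]:
        return list(self.sample_groups.index[self.sample_groups == group])

    def to_tsv(self, path) -> None:
        self.values.to_csv(path, sep="\t", index_label="sample_id")


def read_spot_table(path) -> list[SpotRecord]:
    """Read a tab-separated spot-level export into validated records.

    The header must contain ``sample_id, isotype, glycan_id,
    replicate_index, foreground_mean, background_mean``; extra columns are
    ignored.  Rows with non-numeric fluorescence are rejected with a
    warning; a missing required column is fatal.
    """
    frame = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in REQUIRED_SPOT_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"spot table {path} lacks required columns: {missing}")

    records: list[SpotRecord] = []
    n_rejected = 0
    for row in frame.itertuples(index=False):
        try:
            fg = float(getattr(row, "foreground_mean"))
            bg = float(getattr(row, "background_mean"))
            rep = int(getattr(row, "replicate_index"))
            if not (math.isfinite(fg) and math.isfinite(bg)):
                raise ValueError("non-finite fluorescence")
            records.append(
                SpotRecord(
                    sample_id=str(getattr(row, "sample_id")),
                    isotype=str(getattr(row, "isotype")),
                    glycan_id=str(getattr(row, "glycan_id")),
                    replicate_index=rep,
                    foreground_mean=fg,
                    background_mean=bg,
                )
            )
        except (TypeError, ValueError) as exc:
            n_rejected += 1
            logger.warning("rejected spot row %r: %s", tuple(row), exc)
    logger.info(
        "read %d spot records from %s (%d rejected)", len(records), path, n_rejected
    )
    return records


def net_signal(spot: SpotRecord) -> float:
    """Background-subtracted spot signal; may be negative at spot level."""
    return spot.foreground_mean - spot.background_mean


def aggregate_replicates(
    nets: Sequence[float],
    clamp_value: float = DEFAULT_CLAMP_VALUE,
    expected_replicates: int = DEFAULT_EXPECTED_REPLICATES,
) -> float:
    """Mean of replicate net signals, clamped to ``clamp_value`` if <= 0.

    Positive means below the clamp value are kept as-is here; flooring to
    the clamp value happens at the log2 step so matrix cells stay
    non-negative.
    """
    if len(nets) == 0:
        raise ValueError("aggregate_replicates needs at least one replicate")
    if len(nets) != expected_replicates:
        logger.warning(
            "expected %d replicates, got %d", expected_replicates, len(nets)
        )
    mean = float(np.mean(nets))
    return clamp_value if mean <= 0 else mean


def _records_to_frame(records: Iterable[SpotRecord] | pd.DataFrame) -> pd.DataFrame:
    if isinstance(records, pd.DataFrame):
        missing = [c for c in REQUIRED_SPOT_COLUMNS if c not in records.columns]
        if missing:
            raise ValueError(f"spot frame lacks required columns: {missing}")
        return records
    return pd.DataFrame(
        {
            "sample_id": [r.sample_id for r in records],
            "isotype": [r.isotype for r in records],
            "glycan_id": [r.glycan_id for r in records],
            "replicate_index": [r.replicate_index for r in records],
            "foreground_mean": [r.foreground_mean for r in records],
            "background_mean": [r.background_mean for r in records],
        }
    )


def build_reactivity_matrix(
    records: Iterable[SpotRecord] | pd.DataFrame,
    metadata: pd.DataFrame,
    isotype: str = "IgG",
    library: LibraryPartition | Mapping[str, str] | None = None,
    clamp_value: float = DEFAULT_CLAMP_VALUE,
    expected_replicates: int = DEFAULT_EXPECTED_REPLICATES,
) -> ReactivityMatrix:
    """Assemble the complete samples x glycans log2 reactivity matrix.

    Parameters
    ----------
    records
        Spot records (or an equivalent DataFrame) covering one or more
        isotype channels; only ``isotype`` is used.
    metadata
        Per-sample table with columns ``sample_id``, ``group`` and
        optionally ``igg_concentration``.
    library
        Optional ``glycan_id -> composition_label`` mapping (or an already
        computed partition) used to annotate glycans.

    A (sample, glycan) pair with zero replicates in the selected channel is
    fatal and the offending identifiers are listed.
    """
    frame = _records_to_frame(records)
    channel = frame[frame["isotype"] == isotype]
    if channel.empty:
        raise ValueError(f"no spot records for isotype {isotype!r}")

    net = channel["foreground_mean"].astype(float) - channel[
        "background_mean"
    ].astype(float)
    work = pd.DataFrame(
        {
            "sample_id": channel["sample_id"].astype(str),
            "glycan_id": channel["glycan_id"].astype(str),
            "net": net.to_numpy(),
        }
    )
    rep_counts = work.groupby(["sample_id", "glycan_id"], sort=True).size()
    if (rep_counts != expected_replicates).any():
        bad = rep_counts[rep_counts != expected_replicates]
        logger.warning(
            "%d (sample, glycan) pairs deviate from %d replicates (e.g. %s)",
            len(bad),
            expected_replicates,
            bad.index[0],
        )

    means = work.groupby(["sample_id", "glycan_id"], sort=True)["net"].mean()
    grid = means.unstack("glycan_id")
    if grid.isna().any().any():
        holes = [
            (s, g)
            for s, g in zip(*np.nonzero(grid.isna().to_numpy()))
        ]
        labels = [
            f"{grid.index[s]}/{grid.columns[g]}" for s, g in holes[:10]
        ]
        raise ValueError(
            f"{len(holes)} (sample, glycan) pairs have no replicates: {labels}"
        )

    clamped = grid.to_numpy(dtype=float)
    clamped[clamped <= 0] = clamp_value
    # cells in (0, clamp_value) are floored at the log2 step
    values = pd.DataFrame(
        np.log2(np.maximum(clamped, clamp_value)),
        index=grid.index,
        columns=grid.columns,
    )

    meta = metadata.set_index(metadata["sample_id"].astype(str))
    missing_meta = [s for s in values.index if s not in meta.index]
    if missing_meta:
        raise ValueError(f"samples without metadata: {missing_meta}")
    groups = meta.loc[values.index, "group"].astype(str)
    conc = None
    if "igg_concentration" in meta.columns:
        conc = meta.loc[values.index, "igg_concentration"].astype(float)

    part: LibraryPartition | None
    if library is None or isinstance(library, LibraryPartition):
        part = library
    else:
        part = partition_library(library)

    return ReactivityMatrix(
        values=values,
        isotype=isotype,
        sample_groups=groups,
        igg_concentration=conc,
        library=part,
        clamp_value=clamp_value,
    )
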