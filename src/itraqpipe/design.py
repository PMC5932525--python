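"""Experimental design for multiplexed isobaric-labeling cohorts.

A *batch* is one multiplexed iTRAQ run: several samples labeled with
distinct reporter channels, pooled and acquired together.  The cohort
design maps every (batch, channel) pair to a sample and its clinical
group.  The blocking structure this package assumes — every group
contributes the same number of samples to every batch, with channels
assigned at random within the batch — is what lets cross-batch
normalization work without an internal reference channel.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

DESIGN_COLUMNS = ("batch", "channel", "sample_id", "group")

#: Reporter-ion mass labels conventionally used for iTRAQ channels.
ITRAQ_CHANNELS = ("113", "114", "115", "116", "117", "118", "119", "121")


class DesignError(ValueError):
    """Raised when a cohort design violates the balanced-block structure."""


@dataclass(frozen=True)
class BatchDesign:
    """Balanced mapping of (batch, channel) to (sample, group).

    Parameters
    ----------
    table
        DataFrame with columns ``batch, channel, sample_id, group``,
        one row per labeled sample.

    Invariants (checked on construction): channel labels are unique
    within a batch, sample ids are globally unique, and within every
    batch each group contributes the same number of samples.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        t = self.table
        missing = [c for c in DESIGN_COLUMNS if c not in t.columns]
        if missing:
            raise DesignError(f"design table lacks columns: {missing}")
        object.__setattr__(self, "table", t.loc[:, list(DESIGN_COLUMNS)].reset_index(drop=True))
        t = self.table
        dup = t.duplicated(subset=["batch", "channel"])
        if dup.any():
            rows = t.loc[dup, ["batch", "channel"]].to_records(index=False).tolist()
            raise DesignError(f"duplicate (batch, channel) assignments: {rows}")
        if t["sample_id"].duplicated().any():
            dups = t.loc[t["sample_id"].duplicated(), "sample_id"].tolist()
            raise DesignError(f"sample ids assigned more than once: {dups}")
        sizes = t.groupby(["batch", "group"], sort=False).size().unstack(fill_value=0)
        if sizes.to_numpy().std() != 0 or (sizes.to_numpy() == 0).any():
            raise DesignError(
                "unbalanced design: per-batch group counts differ\n" + sizes.to_string()
            )

    # -- accessors ---------------------------------------------------------

    @property
    def batches(self) -> list[str]:
        return list(dict.fromkeys(self.table["batch"]))

    @property
    def groups(self) -> list[str]:
        return list(dict.fromkeys(self.table["group"]))

    @property
    def samples(self) -> list[str]:
        return list(self.table["sample_id"])

    def channels(self, batch: str) -> list[str]:
        sub = self.table[self.table["batch"] == batch]
        if sub.empty:
            raise KeyError(f"unknown batch {batch!r}")
        return list(sub["channel"])

    @property
    def sample_groups(self) -> pd.Series:
        """Series mapping sample_id -> group label, in design order."""
        return self.table.set_index("sample_id")["group"]

    @property
    def sample_batches(self) -> pd.Series:
        """Series mapping sample_id -> batch id, in design order."""
        return self.table.set_index("sample_id")["batch"]

    def group_sizes(self) -> pd.Series:
        return self.table.groupby("group", sort=False).size()

    def sample_of(self, batch: str, channel: str) -> str:
        t = self.table
        hit = t[(t["batch"] == batch) & (t["channel"] == channel)]
        if hit.empty:
            raise KeyError(f"no sample assigned to batch {batch!r} channel {channel!r}")
        return str(hit["sample_id"].iloc[0])

    def channel_map(self, batch: str) -> dict[str, str]:
        """channel -> sample_id for one batch."""
        sub = self.table[self.table["batch"] == batch]
        return dict(zip(sub["channel"], sub["sample_id"]))


def generate_design(
    n_batches: int,
    channels_per_batch: int,
    groups: Sequence[str],
    seed: int,
    channels: Sequence[str] | None = None,
) -> BatchDesign:
    """Build a balanced randomized-block design.

    Each batch receives ``channels_per_batch / len(groups)`` samples
    from every group, and the group-to-channel assignment within each
    batch is a seeded random permutation (emulating random reporter-ion
    assignment at labeling time).  The same seed reproduces the same
    design exactly.

    Raises
    ------
    DesignError
        If ``channels_per_batch`` is not divisible by the number of
        groups, so no balanced assignment exists.
    """
    groups = list(groups)
    if n_batches < 1 or channels_per_batch < 1:
        raise DesignError("n_batches and channels_per_batch must be >= 1")
    if len(set(groups)) != len(groups) or not groups:
        raise DesignError(f"group labels must be non-empty and distinct: {groups}")
    if channels_per_batch % len(groups) != 0:
        raise DesignError(
            f"{channels_per_batch} channels cannot be split evenly over "
            f"{len(groups)} groups"
        )
    per_group = channels_per_batch // len(groups)
    if channels is None:
        if channels_per_batch <= len(ITRAQ_CHANNELS):
            channels = list(ITRAQ_CHANNELS[:channels_per_batch])
        else:
            channels = [f"ch{i + 1:02d}" for i in range(channels_per_batch)]
    elif len(set(channels)) != channels_per_batch:
        raise DesignError("channel labels must be distinct and match channels_per_batch")

    rng = np.random.default_rng(seed)
    counters = {g: 0 for g in groups}
    rows = []
    for b in range(n_batches):
        batch_id = f"B{b + 1}"
        membership = np.repeat(groups, per_group)
        membership = membership[rng.permutation(channels_per_batch)]
        for channel, group in zip(channels, membership):
            counters[group] += 1
            rows.append((batch_id, channel, f"{group}-{counters[group]:02d}", group))
    return BatchDesign(pd.DataFrame(rows, columns=list(DESIGN_COLUMNS)))
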