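"""Reference-free two-step normalization of reporter-ion intensities.

Step 1 (within protein): each protein's raw reporter intensities in a
batch are expressed as percent shares of that protein's channel sum, so
every present row sums to 100 %.  Any additive protein-level offset that
is common to all channels of a batch — e.g. run-to-run identification
efficiency, a per-batch abundance shift — cancels exactly at this step,
which is why an identical blocked design across batches removes batch
effects without an internal standard channel.

Step 2 (equal loading): under the assumptions that (a) samples within a
batch were equally loaded and (b) most proteins are not differentially
expressed, every channel's mean share over identified proteins should be
100/6 % (for 6-plex).  Each channel is rescaled multiplicatively so its
mean share equals exactly that value, correcting unequal protein input.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd

from .design import BatchDesign

log = logging.getLogger(__name__)


class NormalizationError(ValueError):
    """Raised when a batch cannot be normalized (e.g. empty channel)."""


@dataclass(frozen=True)
class ReporterTable:
    """Protein-level reporter-ion intensities for one multiplexed batch.

    ``intensities`` is indexed by protein id with one column per channel
    label.  A protein unidentified in the batch is simply absent from the
    index (iTRAQ missingness is at the protein-per-batch level: no
    identification means no reporter ions in any channel).
    """

    batch: str
    intensities: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.intensities
        if df.index.has_duplicates:
            dups = df.index[df.index.duplicated()].tolist()
            raise NormalizationError(f"batch {self.batch}: duplicate protein ids {dups}")
        values = df.to_numpy(dtype=float)
        if not np.all(np.isfinite(values)):
            raise NormalizationError(f"batch {self.batch}: non-finite intensities")
        if (values < 0).any():
            raise NormalizationError(f"batch {self.batch}: negative intensities")

    @property
    def channels(self) -> list[str]:
        return list(self.intensities.columns)

    @property
    def proteins(self) -> pd.Index:
        return self.intensities.index


def normalize_within_protein(table: ReporterTable) -> ReporterTable:
    """Convert each protein row to percent shares of its channel sum.

    Rows whose channel sum is zero carry no quantitative information and
    are reclassified as missing (dropped, with a log message) rather
    than raising.
    """
    df = table.intensities
    sums = df.sum(axis=1)
    dead = sums <= 0
    if dead.any():
        log.info(
            "batch %s: %d all-zero protein rows reclassified as missing",
            table.batch,
            int(dead.sum()),
        )
        df = df.loc[~dead]
        sums = sums.loc[~dead]
    shares = df.div(sums, axis=0) * 100.0
    return ReporterTable(table.batch, shares)


def correct_loading(table: ReporterTable) -> ReporterTable:
    """Rescale each channel so its mean share over proteins is 100/6 %.

    The target is ``100 / n_channels`` percent; the per-channel factor is
    ``target / observed_channel_mean``, a single multiplicative pass.
    Rows are not re-normalized afterwards, so row sums may drift slightly
    from 100 % — only the channel-mean condition is enforced.  Applying
    the correction twice is a no-op (the factors become 1).
    """
    df = table.intensities
    if df.empty:
        raise NormalizationError(f"batch {table.batch}: no observed proteins")
    target = 100.0 / df.shape[1]
    means = df.mean(axis=0)
    if (means <= 0).any():
        bad = means.index[means <= 0].tolist()
        raise NormalizationError(
            f"batch {table.batch}: channels {bad} have zero mean over observed proteins"
        )
    corrected = df.mul(target / means, axis=1)
    return ReporterTable(table.batch, corrected)


def normalize_batch(table: ReporterTable) -> ReporterTable:
    """Within-protein normalization followed by equal-loading correction."""
    return correct_loading(normalize_within_protein(table))


def assemble_matrix(tables: "Iterable[ReporterTable]", design: BatchDesign) -> pd.DataFrame:
    """Stack corrected batch tables into one protein x sample matrix.

    Each cell (protein, sample) holds the corrected percent share from
    the sample's (batch, channel); proteins absent from a batch yield
    NaN for all that batch's samples.  Columns follow design sample
    order, so the result is independent of the order batches are passed.
    """
    blocks = []
    for table in tables:
        chan_map = design.channel_map(table.batch)
        unknown = [c for c in table.channels if c not in chan_map]
        if unknown:
            raise NormalizationError(
                f"batch {table.batch}: channels {unknown} not present in the design"
            )
        blocks.append(table.intensities.rename(columns=chan_map))
    if not blocks:
        raise NormalizationError("no reporter tables to assemble")
    matrix = pd.concat(blocks, axis=1)
    proteins = sorted(matrix.index)
    matrix = matrix.reindex(index=proteins, columns=design.samples)
    matrix.index.name = "protein_id"
    matrix.columns.name = "sample_id"
    return matrix
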