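"""Synthetic cohorts with the statistical structure the pipeline assumes.

The generator emulates a 36-sample, 6-batch isobaric-labeling study:
log-normal protein abundances, group effects on the log2 scale,
per-protein-per-batch offsets (batch effects), per-channel multiplicative
loading imbalance, and protein-per-batch missingness.  It emits the same
tables the pipeline reads plus a ground-truth table, so every downstream
stage — normalization, presence filtering, differential expression,
clustering QC, MRM concordance — can be tested end to end without any
external data.

Model for the raw reporter intensity of protein *p* in channel *c* of
batch *b* (channel *c* carries sample *s* of group *g*)::

    I[p, b, c] = 2 ** (a_p + d_{p,g} + u_{p,b} + e_{p,s}) * L[b, c]

with ``a_p ~ N(baseline_mean, baseline_sd)`` the log2 baseline,
``d_{p,g}`` the injected group effect (0 for non-DE proteins and for the
reference group), ``u_{p,b} ~ N(0, batch_effect_sd)``,
``e ~ N(0, within_group_sd)`` i.i.d. per cell, and ``L[b, c]`` the
loading multiplier of channel *c* in batch *b*.  A protein is dropped
from a whole batch with probability ``missing_rate``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .design import BatchDesign, DesignError, generate_design
from .normalize import ReporterTable


class ParameterError(ValueError):
    """Raised for invalid generator parameters."""


def parse_comparison(comparison: str | tuple[str, str]) -> tuple[str, str]:
    """Split ``"A-B"`` (or pass through ``(A, B)``) into group labels."""
    if isinstance(comparison, tuple):
        a, b = comparison
        return str(a), str(b)
    parts = comparison.split("-")
    if len(parts) != 2 or not all(parts):
        raise ParameterError(f"cannot parse comparison label {comparison!r}; expected 'A-B'")
    return parts[0], parts[1]


@dataclass(frozen=True)
class GeneratorParams:
    """Knobs of the synthetic cohort generator.

    ``effect_sizes`` maps comparison labels of the form ``"<group>-<ref>"``
    (the reference group is the last entry of ``groups``) to signed log2
    effects applied to differentially expressed proteins.  Effects for
    other pairwise comparisons follow by subtraction, exactly as group
    offsets imply them.  ``loading_factors`` is either one multiplier
    per channel (applied identically in every batch) or a ``(lo, hi)``
    range from which a multiplier is drawn log-uniformly for every
    (batch, channel).
    """

    n_proteins: int = 2000
    n_batches: int = 6
    channels_per_batch: int = 6
    groups: Sequence[str] = ("G1", "G2", "Ctrl")
    de_fraction: float = 0.1
    effect_sizes: Mapping[str, float] = field(
        default_factory=lambda: {"G1-Ctrl": 1.0, "G2-Ctrl": 0.5}
    )
    within_group_sd: float = 0.5
    batch_effect_sd: float = 0.25
    loading_factors: Sequence[float] | tuple[float, float] = (0.5, 2.0)
    missing_rate: float = 0.1
    baseline_mean: float = 10.0
    baseline_sd: float = 2.0
    random_sign: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_proteins < 1 or self.n_batches < 1 or self.channels_per_batch < 1:
            raise ParameterError("counts must be >= 1")
        if not (0.0 <= self.de_fraction <= 1.0) or not (0.0 <= self.missing_rate <= 1.0):
            raise ParameterError("de_fraction and missing_rate must lie in [0, 1]")
        if self.within_group_sd < 0 or self.batch_effect_sd < 0 or self.baseline_sd < 0:
            raise ParameterError("standard deviations must be >= 0")
        lf = np.asarray(self.loading_factors, dtype=float)
        if (lf <= 0).any():
            raise ParameterError("loading multipliers must be > 0")
        if len(lf) not in (2, self.channels_per_batch):
            raise ParameterError(
                "loading_factors must be a (lo, hi) range or one multiplier per channel"
            )
        ref = self.reference_group
        for comp in self.effect_sizes:
            a, b = parse_comparison(comp)
            if b != ref or a == ref or a not in self.groups:
                raise ParameterError(
                    f"effect_sizes keys must compare a non-reference group against the "
                    f"reference group {ref!r}; got {comp!r}"
                )

    @property
    def reference_group(self) -> str:
        return list(self.groups)[-1]

    @property
    def comparisons(self) -> list[str]:
        """All pairwise comparisons, non-reference pairs first-vs-second."""
        gs = list(self.groups)
        ref = self.reference_group
        out = [f"{g}-{ref}" for g in gs if g != ref]
        non_ref = [g for g in gs if g != ref]
        out += [f"{a}-{b}" for i, a in enumerate(non_ref) for b in non_ref[i + 1:]]
        return out


@dataclass(frozen=True)
class SyntheticTruth:
    """Ground truth emitted with a synthetic cohort.

    ``table`` is indexed by protein id with columns ``baseline``,
    ``effect_<comparison>`` (true log2 effect, 0 for null proteins) and
    ``de_<comparison>`` (exactly ``effect != 0``) for every pairwise
    comparison, plus a global ``de`` flag.
    """

    table: pd.DataFrame
    comparisons: tuple[str, ...]

    def effects(self, comparison: str) -> pd.Series:
        return self.table[f"effect_{comparison}"]

    def de_labels(self, comparison: str) -> pd.Series:
        return self.table[f"de_{comparison}"]


def _loading_matrix(params: GeneratorParams, rng: np.random.Generator) -> np.ndarray:
    lf = np.asarray(params.loading_factors, dtype=float)
    shape = (params.n_batches, params.channels_per_batch)
    if len(lf) == params.channels_per_batch and len(lf) != 2:
        return np.tile(lf, (params.n_batches, 1))
    lo, hi = lf  # a (lo, hi) range, sampled log-uniformly per (batch, channel)
    if lo == hi:
        return np.full(shape, lo)
    return np.exp(rng.uniform(np.log(lo), np.log(hi), size=shape))


def generate_cohort(
    design: BatchDesign, params: GeneratorParams
) -> tuple[list[ReporterTable], SyntheticTruth]:
    """Generate per-batch raw reporter tables plus their ground truth.

    The design must use the same groups (and per-batch channel count) as
    ``params``.  All randomness flows from ``params.seed`` through a
    single generator, so identical inputs give bit-identical output.
    """
    if set(design.groups) != set(params.groups):
        raise DesignError(
            f"design groups {design.groups} do not match generator groups {list(params.groups)}"
        )
    rng = np.random.default_rng(params.seed)
    n = params.n_proteins
    proteins = [f"P{i + 1:05d}" for i in range(n)]
    groups = list(params.groups)
    ref = params.reference_group

    baseline = rng.normal(params.baseline_mean, params.baseline_sd, size=n)
    n_de = int(round(params.de_fraction * n))
    de_mask = np.zeros(n, dtype=bool)
    de_mask[rng.choice(n, size=n_de, replace=False)] = True

    # per-protein log2 offset of each group relative to the reference
    offsets = {g: np.zeros(n) for g in groups}
    for comp, effect in params.effect_sizes.items():
        g = parse_comparison(comp)[0]
        signs = rng.choice([-1.0, 1.0], size=n) if params.random_sign else np.ones(n)
        offsets[g] = np.where(de_mask, signs * float(effect), 0.0)

    loading = _loading_matrix(params, rng)

    batches = design.batches
    if len(batches) != params.n_batches:
        raise DesignError(
            f"design has {len(batches)} batches but params expect {params.n_batches}"
        )
    tables: list[ReporterTable] = []
    for bi, batch_id in enumerate(batches):
        channels = design.channels(batch_id)
        if len(channels) != params.channels_per_batch:
            raise DesignError(f"batch {batch_id} has {len(channels)} channels")
        batch_fx = rng.normal(0.0, params.batch_effect_sd, size=n)
        chan_groups = [design.sample_groups[design.sample_of(batch_id, c)] for c in channels]
        log2_int = np.empty((n, len(channels)))
        for ci, g in enumerate(chan_groups):
            noise = rng.normal(0.0, params.within_group_sd, size=n)
            log2_int[:, ci] = baseline + offsets[g] + batch_fx + noise
        raw = np.exp2(log2_int) * loading[bi]
        observed = rng.random(n) >= params.missing_rate
        df = pd.DataFrame(raw[observed], index=pd.Index(np.asarray(proteins)[observed],
                                                        name="protein_id"), columns=channels)
        tables.append(ReporterTable(batch_id, df))

    truth = pd.DataFrame({"baseline": baseline}, index=pd.Index(proteins, name="protein_id"))
    comps = tuple(params.comparisons)
    for comp in comps:
        a, b = parse_comparison(comp)
        eff = offsets[a] - offsets[b]
        truth[f"effect_{comp}"] = eff
        truth[f"de_{comp}"] = eff != 0.0
    truth["de"] = de_mask
    return tables, SyntheticTruth(truth, comps)


def generate_synthetic_study(
    params: GeneratorParams,
) -> tuple[BatchDesign, list[ReporterTable], SyntheticTruth]:
    """Design + cohort in one call (design seeded from ``params.seed``)."""
    design = generate_design(
        params.n_batches, params.channels_per_batch, params.groups, params.seed
    )
    tables, truth = generate_cohort(design, params)
    return design, tables, truth


MRM_COLUMNS = ("protein_id", "peptide", "transition", "isotope", "group", "area")


def generate_mrm_toy(
    protein_l2r: Mapping[str, float],
    n_transitions: int = 3,
    seed: int = 0,
    noise_sd: float = 0.0,
    groups: tuple[str, str] = ("G1", "Ctrl"),
) -> pd.DataFrame:
    """Toy targeted-MS (MRM) export encoding known group ratios.

    Per protein, 1-3 proteotypic peptides are simulated; each peptide
    contributes ``n_transitions`` light-transition peak areas per group
    whose *sum* carries the group ratio ``2**l2r`` times a log-normal
    peptide-level noise factor (sd ``noise_sd`` in log2 units), plus
    matching heavy-standard rows (identity confirmation only, equal in
    both groups).  With ``noise_sd=0`` the light transition sums are in
    the exact injected ratio.

    Raises
    ------
    ParameterError
        If ``n_transitions < 3`` — peptides quantified from fewer than
        three transitions are not acceptable MRM quantifications.
    """
    if n_transitions < 3:
        raise ParameterError("MRM quantification requires at least 3 transitions per peptide")
    if noise_sd < 0:
        raise ParameterError("noise_sd must be >= 0")
    a, b = groups
    rng = np.random.default_rng(seed)
    rows = []
    for protein, l2r in protein_l2r.items():
        n_pep = int(rng.integers(1, 4))
        for pi in range(n_pep):
            peptide = f"{protein}_pep{pi + 1}"
            total = float(np.exp2(rng.normal(16.0, 1.0)))
            weights = rng.dirichlet(np.full(n_transitions, 5.0))
            ratio = float(np.exp2(l2r + rng.normal(0.0, noise_sd))) if noise_sd > 0 \
                else float(np.exp2(l2r))
            for ti in range(n_transitions):
                area_b = total * weights[ti]
                tid = f"y{ti + 3}"
                rows.append((protein, peptide, tid, "light", a, area_b * ratio))
                rows.append((protein, peptide, tid, "light", b, area_b))
                # heavy standards co-elute at a fixed spike level
                rows.append((protein, peptide, tid, "heavy", a, area_b * 0.8))
                rows.append((protein, peptide, tid, "heavy", b, area_b * 0.8))
    return pd.DataFrame(rows, columns=list(MRM_COLUMNS))
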