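"""MRM (multiple reaction monitoring) quantitation and cross-platform
sign concordance.

Targeted validation in this pipeline follows the transition-sum rule: a
peptide is quantified in a (pooled) group sample as the sum of the peak
areas of at least three light (endogenous) transitions; peptides with
fewer transitions are excluded, not zero-filled.  Heavy-isotope rows are
accepted and validated — they confirm peptide identity by co-elution —
but never enter quantification.  Protein-level group ratios are the
mean of peptide quantities per group, and agreement with the discovery
platform is scored as fold-change sign concordance ("k out of n
proteins"), the weakest reading of per-protein positive correlation;
the per-protein detail rows allow stricter definitions downstream.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .synthdata import MRM_COLUMNS

log = logging.getLogger(__name__)

MIN_TRANSITIONS = 3


class MrmError(ValueError):
    """Raised for malformed MRM tables or impossible concordance requests."""


def validate_mrm(table: pd.DataFrame) -> pd.DataFrame:
    """Check an MRM export and average technical replicates.

    Requires the canonical columns, finite non-negative areas and
    isotope labels in {light, heavy}.  Replicate rows of the same
    (protein, peptide, transition, isotope, group) are averaged.
    """
    missing = [c for c in MRM_COLUMNS if c not in table.columns]
    if missing:
        raise MrmError(f"MRM table lacks columns: {missing}")
    table = table.loc[:, list(MRM_COLUMNS)].copy()
    bad_iso = set(table["isotope"]) - {"light", "heavy"}
    if bad_iso:
        raise MrmError(f"unknown isotope labels: {sorted(bad_iso)}")
    areas = pd.to_numeric(table["area"], errors="coerce")
    if areas.isna().any() or not np.isfinite(areas).all():
        raise MrmError("non-numeric or non-finite peak areas")
    if (areas < 0).any():
        raise MrmError("negative peak areas")
    table["area"] = areas
    keys = ["protein_id", "peptide", "transition", "isotope", "group"]
    return table.groupby(keys, as_index=False, sort=False)["area"].mean()


def quantify_peptides(table: pd.DataFrame) -> pd.DataFrame:
    """Transition-sum quantification of every (peptide, group).

    Returns columns ``protein_id, peptide, group, quant`` where quant is
    the sum of the light-transition areas.  (peptide, group) pairs with
    fewer than three light transitions are excluded (logged), and pairs
    whose areas are all zero yield no quantity.
    """
    table = validate_mrm(table)
    light = table[table["isotope"] == "light"]
    grouped = light.groupby(["protein_id", "peptide", "group"], sort=False)["area"]
    counts = grouped.count()
    sums = grouped.sum()
    too_few = counts < MIN_TRANSITIONS
    if too_few.any():
        log.info(
            "%d (peptide, group) pairs excluded: fewer than %d light transitions",
            int(too_few.sum()), MIN_TRANSITIONS,
        )
    all_zero = (sums == 0) & ~too_few
    if all_zero.any():
        log.info("%d (peptide, group) pairs had all-zero areas; quantity missing",
                 int(all_zero.sum()))
    quant = sums[~too_few & ~all_zero]
    out = quant.rename("quant").reset_index()
    return out


def protein_group_l2r(
    peptide_quants: pd.DataFrame, group_a: str, group_b: str
) -> pd.Series:
    """Protein-level log2 ratio of two groups from peptide quantities.

    The protein value in a group is the mean of its quantified peptides;
    the result is ``log2(value_A / value_B)``.  Proteins lacking a
    quantified peptide in either group, or with a zero denominator, are
    excluded (logged).
    """
    per_group = (
        peptide_quants.groupby(["protein_id", "group"], sort=False)["quant"].mean().unstack()
    )
    for g in (group_a, group_b):
        if g not in per_group.columns:
            per_group[g] = np.nan
    a, b = per_group[group_a], per_group[group_b]
    valid = a.notna() & b.notna() & (b > 0) & (a > 0)
    n_bad = int((~valid).sum())
    if n_bad:
        log.info("%d proteins excluded from MRM ratio %s/%s", n_bad, group_a, group_b)
    out = np.log2(a[valid] / b[valid])
    out.name = "mrm_l2r"
    out.index.name = "protein_id"
    return out


@dataclass(frozen=True)
class ConcordanceResult:
    """Sign agreement between two per-protein log2-ratio vectors."""

    n: int
    k: int
    detail: pd.DataFrame

    def __str__(self) -> str:  # the field's reporting idiom
        return f"{self.k} out of {self.n} proteins concordant"


def sign_concordance(itraq_l2r: pd.Series, mrm_l2r: pd.Series) -> ConcordanceResult:
    """Count proteins whose fold-change sign agrees across platforms.

    Zeros only match zeros.  Symmetric in the two platforms and
    invariant to any positive rescaling of either vector.  Raises if
    the two vectors share no proteins.
    """
    shared = itraq_l2r.index.intersection(mrm_l2r.index)
    if len(shared) == 0:
        raise MrmError("no proteins shared between the iTRAQ and MRM ratio vectors")
    a = itraq_l2r.loc[shared].astype(float)
    b = mrm_l2r.loc[shared].astype(float)
    concordant = np.sign(a) == np.sign(b)
    detail = pd.DataFrame(
        {"itraq_l2r": a, "mrm_l2r": b, "concordant": concordant.astype(bool)}
    )
    detail.index.name = "protein_id"
    result = ConcordanceResult(n=len(shared), k=int(concordant.sum()), detail=detail)
    log.info("MRM concordance: %s", result)
    return result
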