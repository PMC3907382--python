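"""Relative copy-number quantification from qPCR Ct values by the
2^-ddCt method, and concordance scoring against array calls.

Each measurement carries triplicate crossing-threshold (Ct) values for the
target amplicon and for a reference gene (e.g. GAPDH) in the same sample.
With dCt = mean Ct(target) - mean Ct(reference gene) and
ddCt = dCt(test sample) - dCt(calibrator sample), the relative copy number
is RCN = 2^-ddCt: 1 for no change, ~1.5 for a single-copy gain on a diploid
background, ~0.5 for a single-copy loss.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import pandas as pd

from .cnvr import CNVR, _overlaps

#: RCN thresholds: midpoints between diploid (1.0) and one-copy change
#: (1.5 / 0.5), with margin.
GAIN_RCN_THRESHOLD = 1.4
LOSS_RCN_THRESHOLD = 0.6

#: Replicate QC: flag triplicates whose Ct range exceeds this many cycles.
CT_RANGE_QC_LIMIT = 0.5


@dataclass(frozen=True)
class QPCRMeasurement:
    """Triplicate Ct values for one sample x assay (target CNVR primer pair)
    plus the reference-gene triplicate from the same reaction plate."""

    sample_id: str
    assay_id: str
    ct_target: tuple[float, float, float]
    ct_refgene: tuple[float, float, float]

    def __post_init__(self):
        for name, trip in (("ct_target", self.ct_target),
                           ("ct_refgene", self.ct_refgene)):
            if len(trip) != 3:
                raise ValueError(f"{name} must have exactly 3 replicates")
            if not all(math.isfinite(c) and c > 0 for c in trip):
                raise ValueError(f"{name} values must be finite and positive")


@dataclass(frozen=True)
class RelativeCopyNumber:
    sample_id: str
    assay_id: str
    delta_delta_ct: float
    rcn: float
    inferred_status: str


def mean_ct(replicates) -> float:
    """Arithmetic mean of a Ct triplicate; warns when the replicate range
    exceeds 0.5 cycles (poor technical reproducibility)."""
    reps = tuple(float(c) for c in replicates)
    if len(reps) != 3:
        raise ValueError("expected exactly 3 replicate Ct values")
    if not all(math.isfinite(c) for c in reps):
        raise ValueError("non-finite Ct value")
    if max(reps) - min(reps) > CT_RANGE_QC_LIMIT:
        warnings.warn(
            f"Ct replicate range {max(reps) - min(reps):.2f} exceeds "
            f"{CT_RANGE_QC_LIMIT} cycles (QC flag)")
    return sum(reps) / 3.0


def ddct_rcn(test: QPCRMeasurement, calibrator: QPCRMeasurement,
             gain_threshold: float = GAIN_RCN_THRESHOLD,
             loss_threshold: float = LOSS_RCN_THRESHOLD) -> RelativeCopyNumber:
    """Relative copy number of the test sample versus the calibrator.

    ddCt = (mean target - mean refgene) of the test minus the same
    difference of the calibrator; RCN = 2^-ddCt.  The reference-gene
    normalization makes the result invariant to a constant shift of all
    Ct values.
    """
    if test.assay_id != calibrator.assay_id:
        raise ValueError(
            f"assay mismatch: {test.assay_id!r} vs {calibrator.assay_id!r}")
    dct_test = mean_ct(test.ct_target) - mean_ct(test.ct_refgene)
    dct_cal = mean_ct(calibrator.ct_target) - mean_ct(calibrator.ct_refgene)
    ddct = dct_test - dct_cal
    rcn = 2.0 ** (-ddct)
    if rcn >= gain_threshold:
        status = "gain"
    elif rcn <= loss_threshold:
        status = "loss"
    else:
        status = "unchanged"
    return RelativeCopyNumber(sample_id=test.sample_id, assay_id=test.assay_id,
                              delta_delta_ct=ddct, rcn=rcn,
                              inferred_status=status)


def concordance(array_calls: pd.DataFrame, rcn_table: list[RelativeCopyNumber],
                assay_map: dict[str, CNVR]) -> float:
    """Fraction of qPCR results whose inferred status matches the array.

    ``assay_map`` maps each assay_id to the CNVR its primers target.  The
    array status for a sample x CNVR is the status of that sample's call
    overlapping the CNVR (>= 1 bp); a sample with no overlapping call is
    "unchanged".
    """
    if not rcn_table:
        raise ValueError("empty RCN table")
    missing = sorted({r.assay_id for r in rcn_table} - set(assay_map))
    if missing:
        raise ValueError(f"assays not mapped to a CNVR: {missing}")
    n_match = 0
    for r in rcn_table:
        region = assay_map[r.assay_id]
        sub = array_calls[(array_calls["sample_id"] == r.sample_id)
                          & (array_calls["chrom"] == region.chrom)]
        array_status = "unchanged"
        for c in sub.itertuples(index=False):
            if _overlaps(c.start, c.end, region.start, region.end):
                array_status = c.status
                break
        if array_status == r.inferred_status:
            n_match += 1
    return n_match / len(rcn_table)
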