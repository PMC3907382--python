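"""CNV calling from segments: retention and classification thresholds,
the end-to-end per-sample pipeline, the self-self false-positive check, and
recovery benchmarking against planted truth.

A segment becomes a call iff |mean log2 ratio| >= threshold (default 0.5)
AND it spans at least ``min_probes`` consecutive probes (default 5).  The
boundary is inclusive: a mean of exactly +0.5 is a gain, -0.5 a loss.
"""

from __future__ import annotations

import math

import pandas as pd

from . import preprocess, segment as seg

CALL_COLUMNS = ["sample_id", "chrom", "start", "end", "status", "mean_log2", "n_probes"]

GAIN = "gain"
LOSS = "loss"
UNCHANGED = "unchanged"


def classify_segment(mean_log2: float, threshold: float = 0.5) -> str:
    """Classify a segment mean as gain / loss / unchanged (inclusive at the
    threshold)."""
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    if not math.isfinite(mean_log2):
        raise ValueError("non-finite segment mean")
    if mean_log2 >= threshold:
        return GAIN
    if mean_log2 <= -threshold:
        return LOSS
    return UNCHANGED


def call_cnvs(results: list[seg.SegmentationResult], sample_id: str,
              threshold: float = 0.5, min_probes: int = 5) -> pd.DataFrame:
    """Retain exactly the segments passing both the magnitude and the probe
    count filter as CNV calls, sorted by (chromosome order, start)."""
    frame = seg.segments_to_frame(results)
    return call_segments_frame(frame, sample_id, threshold, min_probes)


def call_segments_frame(segments: pd.DataFrame, sample_id: str,
                        threshold: float = 0.5, min_probes: int = 5) -> pd.DataFrame:
    """Apply the retention/classification rules to a segments table
    (``chrom, start, end, n_probes, mean_log2``), e.g. one re-imported from
    TSV for re-calling with new thresholds."""
    rows = []
    for s in segments.itertuples(index=False):
        status = classify_segment(float(s.mean_log2), threshold)
        if status == UNCHANGED or s.n_probes < min_probes:
            continue
        rows.append((sample_id, s.chrom, int(s.start), int(s.end), status,
                     float(s.mean_log2), int(s.n_probes)))
    calls = pd.DataFrame(rows, columns=CALL_COLUMNS)
    order = {c: i for i, c in enumerate(dict.fromkeys(segments["chrom"]))}
    calls = calls.sort_values(
        ["chrom", "start"],
        key=lambda s_: s_.map(order) if s_.name == "chrom" else s_,
        kind="stable")
    return calls.reset_index(drop=True)


def stitch_calls(calls: pd.DataFrame, max_gap_bp: int = 20000,
                 gap_fraction: float = 0.05) -> pd.DataFrame:
    """Merge consecutive same-status calls of one sample separated by a
    small gap: at most ``max_gap_bp``, or at most ``gap_fraction`` of the
    combined span (gap included).

    Optimal segmentation occasionally isolates a short run of outlier probes
    inside a long CNV; the flanking pieces pass the retention filters while
    the outlier run is dropped, splitting one event into adjacent calls.
    Stitching re-joins such pieces (the analogue of the outlier smoothing /
    adjacent-segment merging steps of standard CNV callers; the fractional
    rule follows the convention of joining pieces whose gap is a minor share
    of the joined event).  The gap cap is deliberately small relative to a
    segment of genuinely diploid probes, so two distinct nearby CNVs of the
    same status are not fused.  The merged call spans the union, sums probe
    counts, and carries the probe-count-weighted mean; calls never overlap
    afterwards.
    """
    if len(calls) == 0:
        return calls.copy()
    rows = []
    for (sample, chrom), grp in calls.groupby(["sample_id", "chrom"], sort=False):
        grp = grp.sort_values("start", kind="stable")
        cur = None
        for r in grp.itertuples(index=False):
            gap = r.start - cur["end"] - 1 if cur is not None else None
            if (cur is not None and r.status == cur["status"]
                    and (gap <= max_gap_bp
                         or gap <= gap_fraction
                         * (r.end - cur["start"] + 1))):
                w = cur["n_probes"] + r.n_probes
                cur["mean_log2"] = (cur["mean_log2"] * cur["n_probes"]
                                    + r.mean_log2 * r.n_probes) / w
                cur["n_probes"] = w
                cur["end"] = max(cur["end"], int(r.end))
            else:
                if cur is not None:
                    rows.append(cur)
                cur = {"sample_id": sample, "chrom": chrom,
                       "start": int(r.start), "end": int(r.end),
                       "status": r.status, "mean_log2": float(r.mean_log2),
                       "n_probes": int(r.n_probes)}
        rows.append(cur)
    return pd.DataFrame(rows, columns=CALL_COLUMNS)


def run_sample_pipeline(intensities: pd.DataFrame, design: pd.DataFrame,
                        sample_id: str = "sample", *, span: float = 0.3,
                        n_anchors: int = 100, k_max_per_mb: float = 10.0,
                        penalty_lambda: float | None = None,
                        threshold: float = 0.5, min_probes: int = 5,
                        stitch_gap_bp: int = 20000,
                        do_spatial: bool = True, do_qspline: bool = True) -> pd.DataFrame:
    """Full per-sample chain: spatial correction -> q-spline normalization ->
    log2 track -> DP segmentation -> calling -> stitching of adjacent
    same-status calls.  The two preprocessing steps can be disabled
    individually for ablation studies; ``stitch_gap_bp=0`` disables
    stitching of non-book-ended pieces."""
    x = intensities
    if do_spatial:
        x = preprocess.spatial_correct(x, span=span)
    if do_qspline:
        x = preprocess.qspline_normalize(x, n_anchors=n_anchors)
    track = preprocess.to_log2_track(x, design)
    results = seg.segment_track(track, k_max_per_mb=k_max_per_mb,
                                penalty_lambda=penalty_lambda)
    calls = call_cnvs(results, sample_id, threshold=threshold, min_probes=min_probes)
    return stitch_calls(calls, max_gap_bp=stitch_gap_bp)


def false_positive_check(self_self: pd.DataFrame, design: pd.DataFrame,
                         params: dict | None = None) -> int:
    """Run the full pipeline on a self-self hybridization and return the
    number of retained CNV calls (every one a false positive; expected 0 at
    default noise and thresholds)."""
    params = dict(params or {})
    calls = run_sample_pipeline(self_self, design, sample_id="self_self", **params)
    return len(calls)


# ---------------------------------------------------------------------------
# Recovery benchmarking against planted truth
# ---------------------------------------------------------------------------

def reciprocal_overlap(a_start: int, a_end: int, b_start: int, b_end: int) -> float:
    """Minimum of the two overlap fractions of two 1-based inclusive
    intervals (0 if disjoint)."""
    ov = min(a_end, b_end) - max(a_start, b_start) + 1
    if ov <= 0:
        return 0.0
    return min(ov / (a_end - a_start + 1), ov / (b_end - b_start + 1))


def benchmark_recovery(calls: pd.DataFrame, truth: pd.DataFrame,
                       design: pd.DataFrame, min_frac: float = 0.5,
                       min_probes: int = 5, threshold: float = 0.5) -> dict:
    """Sensitivity/precision of calls against a planted truth set.

    A truth CNV is *eligible* if >= ``min_probes`` probe midpoints fall
    inside it and |log2(copies/2)| >= ``threshold`` (0-copy counts as
    unbounded loss); sensitivity is the fraction of eligible truth CNVs
    matched by a call at reciprocal ``min_frac`` overlap.  Precision is the
    fraction of calls matching *any* truth CNV (eligible or not) at the same
    criterion.
    """
    mid = (design["start"].to_numpy() + design["end"].to_numpy()) // 2
    chrom = design["chrom"].to_numpy()
    eligible = []
    for t in truth.itertuples(index=False):
        n_cov = int(((chrom == t.chrom) & (mid >= t.start) & (mid <= t.end)).sum())
        effect = math.inf if t.copies == 0 else abs(math.log2(t.copies / 2.0))
        eligible.append(n_cov >= min_probes and effect >= threshold)
    n_eligible = sum(eligible)
    recovered = 0
    for is_el, t in zip(eligible, truth.itertuples(index=False)):
        if not is_el:
            continue
        sub = calls[calls["chrom"] == t.chrom]
        if any(reciprocal_overlap(t.start, t.end, c.start, c.end) >= min_frac
               for c in sub.itertuples(index=False)):
            recovered += 1
    matched_calls = 0
    for c in calls.itertuples(index=False):
        sub = truth[truth["chrom"] == c.chrom]
        if any(reciprocal_overlap(c.start, c.end, t.start, t.end) >= min_frac
               for t in sub.itertuples(index=False)):
            matched_calls += 1
    return {
        "n_truth": len(truth),
        "n_eligible": n_eligible,
        "n_recovered": recovered,
        "n_calls": len(calls),
        "n_matched_calls": matched_calls,
        "sensitivity": recovered / n_eligible if n_eligible else float("nan"),
        "precision": matched_calls / len(calls) if len(calls) else float("nan"),
    }
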