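"""End-to-end benchmark scenarios: planted-CNV recovery, self-self false
positives, segmentation oracle agreement, and merge conservation.

The recovery scenario uses a scaled-down genome of 56 scaffolds x 3 Mb
(168 Mb) tiled at the full 1650-bp probe density, with 30 planted CNVs per
replicate drawn from the default size range, so that CNVs occupy ~5% of the
genome.  (On a real ~2.2 Gb autosome complement the same CNV load fills
~0.6%; scaffold count, not length, is scaled down because segmentation cost
grows cubically with chromosome length.)  Truth CNVs covered by at least 5
probes and with |log2(copies/2)| at or beyond the calling threshold count
as recoverable; matching is reciprocal 50% overlap.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import calling
from .cnvr import merge_to_cnvrs
from .segment import breakpoints, brute_force_segment, dp_segment
from .simulate import (GenomeSpec, SimulationConfig, design_probes,
                       plant_cnvs, simulate_self_self, simulate_array)

RECOVERY_N_SCAFFOLDS = 56
SELF_SELF_N_SCAFFOLDS = 16
SCAFFOLD_LENGTH_BP = 3_000_000
RECOVERY_N_CNVS = 30


def _scaffold_genome(n: int) -> GenomeSpec:
    return GenomeSpec(tuple((f"s{i:02d}", SCAFFOLD_LENGTH_BP) for i in range(n)))


def recovery_replicate(seed: int, normalized: bool = True,
                       n_scaffolds: int = RECOVERY_N_SCAFFOLDS,
                       n_cnvs: int = RECOVERY_N_CNVS) -> dict:
    """One simulate -> preprocess -> segment -> call -> score replicate.

    ``normalized=False`` switches off both spatial correction and q-spline
    normalization (ablation arm); dye bias and the spatial gradient stay on.
    """
    genome = _scaffold_genome(n_scaffolds)
    design = design_probes(genome, seed=seed * 10 + 1)
    truth = plant_cnvs(genome, n_cnvs, seed=seed * 10 + 2)
    arr = simulate_array(design, truth, SimulationConfig(seed=seed * 10 + 3))
    calls = calling.run_sample_pipeline(arr, design, f"rep{seed}",
                                        do_spatial=normalized,
                                        do_qspline=normalized)
    return calling.benchmark_recovery(calls, truth, design)


def pooled_recovery(seeds, normalized: bool = True) -> dict:
    """Pool recovery counts over replicates; returns sensitivity/precision
    plus the raw pooled counts."""
    tot = {"n_eligible": 0, "n_recovered": 0, "n_calls": 0, "n_matched_calls": 0}
    for s in seeds:
        rep = recovery_replicate(int(s), normalized=normalized)
        for k in tot:
            tot[k] += rep[k]
    tot["sensitivity"] = tot["n_recovered"] / tot["n_eligible"]
    tot["precision"] = tot["n_matched_calls"] / tot["n_calls"]
    return tot


def self_self_false_positives(seeds, design_seed: int = 101) -> list[int]:
    """Retained CNV calls per self-self replicate at default parameters
    (expected all zero)."""
    genome = _scaffold_genome(SELF_SELF_N_SCAFFOLDS)
    design = design_probes(genome, seed=design_seed)
    counts = []
    for s in seeds:
        ss = simulate_self_self(design, SimulationConfig(seed=int(s)))
        counts.append(calling.false_positive_check(ss, design))
    return counts


def dp_oracle_agreement(n_tracks: int = 200, seed: int = 7,
                        n_max: int = 20, k_max: int = 4) -> float:
    """Fraction of random tracks on which dp_segment matches the exhaustive
    enumeration oracle in both cost and breakpoints."""
    rng = np.random.default_rng(seed)
    agree = 0
    for _ in range(n_tracks):
        n = int(rng.integers(3, n_max + 1))
        k = int(rng.integers(1, min(k_max, n) + 1))
        x = rng.standard_normal(n)
        res = dp_segment(x, k_max=k, penalty_lambda=0.0)
        cost, cuts = brute_force_segment(x, k)
        ok = (abs(res.sse_by_k[k - 1] - cost) <= 1e-9 * max(1.0, abs(cost))
              and breakpoints(res) == cuts)
        agree += ok
    return agree / n_tracks


def merge_conservation_trials(n_sets: int = 100, seed: int = 5) -> dict:
    """Random call sets on a 1 Mb toy genome: exact union length via per-bp
    marking vs the sum of merged CNVR lengths, idempotence, and the
    |CNVRs| <= |CNVs| contraction."""
    rng = np.random.default_rng(seed)
    ok_length = ok_idempotent = ok_contraction = 0
    for _ in range(n_sets):
        n_calls = int(rng.integers(1, 60))
        rows = []
        for i in range(n_calls):
            start = int(rng.integers(1, 950_000))
            end = start + int(rng.integers(1, 50_000))
            rows.append((f"s{i % 5}", f"c{i % 2}", start, end,
                         "gain" if rng.random() < 0.5 else "loss", 1.0, 10))
        calls = pd.DataFrame(rows, columns=calling.CALL_COLUMNS)
        cnvrs = merge_to_cnvrs(calls)
        marked = {}
        for r in rows:
            mask = marked.setdefault(r[1], np.zeros(1_000_002, dtype=bool))
            mask[r[2]:r[3] + 1] = True
        union = sum(int(m.sum()) for m in marked.values())
        ok_length += sum(r.length for r in cnvrs) == union
        as_calls = pd.DataFrame(
            [("m", r.chrom, r.start, r.end, "gain", 1.0, 1) for r in cnvrs],
            columns=calling.CALL_COLUMNS)
        again = merge_to_cnvrs(as_calls)
        ok_idempotent += ([(r.chrom, r.start, r.end) for r in again]
                          == [(r.chrom, r.start, r.end) for r in cnvrs])
        ok_contraction += len(cnvrs) <= len(calls)
    return {"n_sets": n_sets, "length_ok": ok_length,
            "idempotent_ok": ok_idempotent, "contraction_ok": ok_contraction}
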