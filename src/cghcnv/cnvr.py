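"""Cross-sample CNV region (CNVR) analysis: merging overlapping calls,
status and sharing classification, gene annotation, and population summary
tables.

All interval arithmetic is 1-based inclusive (length = end - start + 1);
overlap requires at least one shared base pair, so book-ended intervals do
not merge.  A CNVR is the union span of a connected component of overlapping
calls across samples; its status is gain or loss when all members agree and
"both" otherwise.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .simulate import GenomeSpec

ANNOTATION_COLUMNS = ["gene_id", "chrom", "start", "end", "biotype"]

SIZE_BIN_LABELS = ["1-10 Kb", "10-50 Kb", "50-100 Kb", "100-500 Kb", ">500 Kb"]
_SIZE_BIN_EDGES_BP = [0, 10_000, 50_000, 100_000, 500_000]  # half-open [lo, hi)


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Round half away from zero at ``ndigits`` decimals (table convention)."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class CNVR:
    """A copy-number-variable region: the union of overlapping CNV calls."""

    chrom: str
    start: int
    end: int
    status: str
    samples: frozenset[str]
    members: pd.DataFrame = field(repr=False, default=None)

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    @property
    def n_members(self) -> int:
        return 0 if self.members is None else len(self.members)


def _overlaps(a_start, a_end, b_start, b_end) -> bool:
    return a_start <= b_end and b_start <= a_end


def cnvr_status(member_statuses) -> str:
    """All-gain -> gain; all-loss -> loss; mixed -> both."""
    statuses = set(member_statuses)
    if not statuses:
        raise ValueError("empty CNVR membership")
    if statuses == {"gain"}:
        return "gain"
    if statuses == {"loss"}:
        return "loss"
    return "both"


def _chrom_order(chroms) -> dict[str, int]:
    return {c: i for i, c in enumerate(dict.fromkeys(chroms))}


def merge_to_cnvrs(calls: pd.DataFrame) -> list[CNVR]:
    """Merge CNV calls across samples into CNVRs by transitive >=1 bp
    overlap per chromosome.

    Each CNVR spans min(start)..max(end) of its component calls.  Merging is
    idempotent: re-merging the resulting regions is a fixed point.
    """
    if len(calls) == 0:
        return []
    if (calls["end"] < calls["start"]).any():
        raise ValueError("invalid call intervals (end < start)")
    out: list[CNVR] = []
    for chrom in dict.fromkeys(calls["chrom"]):
        sub = calls[calls["chrom"] == chrom].sort_values(
            ["start", "end"], kind="stable")
        component: list[int] = []
        cur_start = cur_end = None
        for idx, row in zip(sub.index, sub.itertuples(index=False)):
            if cur_end is None or row.start > cur_end:
                if component:
                    out.append(_build_cnvr(chrom, cur_start, cur_end,
                                           calls.loc[component]))
                component = [idx]
                cur_start, cur_end = int(row.start), int(row.end)
            else:
                component.append(idx)
                cur_end = max(cur_end, int(row.end))
        if component:
            out.append(_build_cnvr(chrom, cur_start, cur_end, calls.loc[component]))
    return out


def _build_cnvr(chrom, start, end, members: pd.DataFrame) -> CNVR:
    samples = frozenset(members["sample_id"]) if "sample_id" in members else frozenset()
    return CNVR(chrom=str(chrom), start=int(start), end=int(end),
                status=cnvr_status(members["status"]), samples=samples,
                members=members.reset_index(drop=True))


def cnvrs_to_frame(cnvrs: list[CNVR]) -> pd.DataFrame:
    """Tabular view: chrom, start, end, length, status, n_members, n_samples,
    samples (comma-joined, sorted)."""
    rows = [(c.chrom, c.start, c.end, c.length, c.status, c.n_members,
             len(c.samples), ",".join(sorted(c.samples))) for c in cnvrs]
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "length",
                                       "status", "n_members", "n_samples",
                                       "samples"])


def label_sharing(calls: pd.DataFrame) -> pd.DataFrame:
    """Label each call breed-specific or shared.

    A call is *shared* when it overlaps (>= 1 bp) a call from at least one
    other sample; shared calls are annotated with the number of distinct
    samples in their overlap connected component (so a chain A-B, B-C makes
    all three shared among 3 samples even if A and C are disjoint).  Returns
    a copy of ``calls`` with columns ``sharing`` and ``n_shared_samples``.
    """
    out = calls.copy()
    out["sharing"] = "breed_specific"
    out["n_shared_samples"] = 1
    for region in merge_to_cnvrs(calls):
        members = region.members
        comp_samples = len(region.samples)
        for i, row in enumerate(members.itertuples(index=False)):
            others = members.drop(members.index[i])
            shared = any(
                o.sample_id != row.sample_id
                and _overlaps(row.start, row.end, o.start, o.end)
                for o in others.itertuples(index=False))
            if shared:
                mask = ((out["sample_id"] == row.sample_id)
                        & (out["chrom"] == row.chrom)
                        & (out["start"] == row.start) & (out["end"] == row.end))
                out.loc[mask, "sharing"] = "shared"
                out.loc[mask, "n_shared_samples"] = comp_samples
    return out


def common_in_all(cnvrs: list[CNVR], all_samples) -> list[CNVR]:
    """CNVRs whose member samples cover every experimental sample."""
    wanted = set(all_samples)
    if not wanted:
        raise ValueError("all_samples must be non-empty")
    return [c for c in cnvrs if wanted <= set(c.samples)]


def compare_sets(a: list[CNVR], b: list[CNVR]) -> tuple[int, list[tuple[int, int]]]:
    """Count CNVRs of ``a`` overlapping (>= 1 bp) any CNVR of ``b``.

    Returns ``(count, pairs)`` where pairs are (index in a, index in b).
    """
    trees: dict[str, IntervalTree] = {}
    for j, r in enumerate(b):
        trees.setdefault(r.chrom, IntervalTree()).addi(r.start, r.end + 1, j)
    pairs = []
    hit = set()
    for i, r in enumerate(a):
        tree = trees.get(r.chrom)
        if tree is None:
            continue
        for iv in sorted(tree.overlap(r.start, r.end + 1)):
            pairs.append((i, iv.data))
            hit.add(i)
    return len(hit), pairs


def genes_overlapping(cnvrs: list[CNVR], annotation: pd.DataFrame,
                      genome: GenomeSpec | None = None
                      ) -> tuple[list[list[str]], int]:
    """Genes sharing >= 1 bp with each CNVR, plus the deduplicated global
    gene count.  Genes on chromosomes absent from ``genome`` (when given)
    are skipped with a warning."""
    ann = annotation
    if genome is not None:
        known = set(genome.names)
        bad = set(ann["chrom"]) - known
        if bad:
            warnings.warn(
                f"annotation chromosomes not in genome skipped: {sorted(bad)}")
            ann = ann[ann["chrom"].isin(known)]
    trees: dict[str, IntervalTree] = {}
    for g in ann.itertuples(index=False):
        if g.end < g.start:
            raise ValueError(f"invalid gene interval for {g.gene_id}")
        trees.setdefault(g.chrom, IntervalTree()).addi(g.start, g.end + 1, g.gene_id)
    per_cnvr: list[list[str]] = []
    seen: set[str] = set()
    for r in cnvrs:
        tree = trees.get(r.chrom)
        hits = sorted({iv.data for iv in tree.overlap(r.start, r.end + 1)}) if tree else []
        per_cnvr.append(hits)
        seen.update(hits)
    return per_cnvr, len(seen)


def chromosome_summary(cnvrs: list[CNVR], genome: GenomeSpec,
                       annotation: pd.DataFrame | None = None) -> pd.DataFrame:
    """Per-chromosome CNVR distribution plus a totals row.

    Columns: chrom, n_cnvrs, n_genes, total_cnvr_bp, chrom_length_bp,
    percent_of_chrom, mean_cnvr_kb.  Percent is 100 * total/chrom length and
    mean size total/n/1000 Kb, both rounded half-up to 2 decimals.

    The totals row reports the full genome length but computes the genome
    coverage percent over AUTOSOMES ONLY (X/Y excluded from the
    denominator), matching the convention of surveys that call CNVs on
    autosomes while listing the sex chromosome for completeness.
    """
    by_chrom: dict[str, list[CNVR]] = {}
    for r in cnvrs:
        by_chrom.setdefault(r.chrom, []).append(r)
    unknown = set(by_chrom) - set(genome.names)
    if unknown:
        raise ValueError(f"CNVR chromosomes absent from genome: {sorted(unknown)}")
    gene_lists, n_genes_total = (None, 0)
    if annotation is not None:
        gene_lists, n_genes_total = genes_overlapping(cnvrs, annotation, genome)
        genes_by_chrom: dict[str, set[str]] = {}
        for r, genes in zip(cnvrs, gene_lists):
            genes_by_chrom.setdefault(r.chrom, set()).update(genes)
    rows = []
    for chrom, length in genome.chromosomes:
        regs = by_chrom.get(chrom, [])
        total_bp = sum(r.length for r in regs)
        n = len(regs)
        ngenes = len(genes_by_chrom.get(chrom, set())) if annotation is not None else 0
        rows.append({
            "chrom": chrom,
            "n_cnvrs": n,
            "n_genes": ngenes,
            "total_cnvr_bp": total_bp,
            "chrom_length_bp": length,
            "percent_of_chrom": round_half_up(100.0 * total_bp / length),
            "mean_cnvr_kb": round_half_up(total_bp / n / 1000.0) if n else 0.0,
        })
    total_bp = sum(r["total_cnvr_bp"] for r in rows)
    total_n = sum(r["n_cnvrs"] for r in rows)
    rows.append({
        "chrom": "total",
        "n_cnvrs": total_n,
        "n_genes": n_genes_total,
        "total_cnvr_bp": total_bp,
        "chrom_length_bp": genome.total_length,
        "percent_of_chrom": round_half_up(100.0 * total_bp / genome.autosome_length),
        "mean_cnvr_kb": round_half_up(total_bp / total_n / 1000.0) if total_n else 0.0,
    })
    return pd.DataFrame(rows)


def size_bins(cnvrs: list[CNVR]) -> pd.Series:
    """CNVR counts over half-open size bins [1,10), [10,50), [50,100),
    [100,500), [500,inf) Kb; size = end - start + 1.  Every CNVR falls in
    exactly one bin."""
    counts = dict.fromkeys(SIZE_BIN_LABELS, 0)
    edges = _SIZE_BIN_EDGES_BP + [np.inf]
    for r in cnvrs:
        for label, lo, hi in zip(SIZE_BIN_LABELS, edges[:-1], edges[1:]):
            if lo <= r.length < hi:
                counts[label] += 1
                break
    return pd.Series(counts, name="n_cnvrs")


def status_summary(cnvrs: list[CNVR]) -> pd.DataFrame:
    """Per-status (gain/loss/both) counts, total bp, mean size (Kb) and
    percent of the total CNVR length (both rounded half-up, 2 decimals)."""
    grand_total = sum(r.length for r in cnvrs)
    rows = []
    for status in ("gain", "loss", "both"):
        regs = [r for r in cnvrs if r.status == status]
        total = sum(r.length for r in regs)
        rows.append({
            "status": status,
            "n_cnvrs": len(regs),
            "total_bp": total,
            "mean_kb": round_half_up(total / len(regs) / 1000.0) if regs else 0.0,
            "percent_of_total_length":
                round_half_up(100.0 * total / grand_total) if grand_total else 0.0,
        })
    return pd.DataFrame(rows)
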