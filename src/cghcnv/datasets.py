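"""Bundled example data: summary statistics of a published six-breed horse
aCGH CNV survey (EquCab2 autosomes plus X).

These tables are *inputs* for the summary operations — per-chromosome CNVR
counts, gene counts and total lengths, per-status CNVR totals, and per-breed
CNV counts from five test mares hybridized against a Thoroughbred reference.
:func:`cnvrs_matching_chrom_table` and :func:`cnvrs_matching_status_totals`
expand them into synthetic interval sets whose per-chromosome (or
per-status) totals equal the published columns, so the arithmetic of the
summary tables can be reproduced end-to-end without the original microarray
data.  The intervals themselves are synthetic placeholders; only their
counts and length sums are meaningful.
"""

from __future__ import annotations

import pandas as pd

from .cnvr import CNVR, merge_to_cnvrs
from .simulate import GenomeSpec

#: EquCab2 chromosome lengths (bp), autosomes 1..31 then X.
HORSE_CHROM_LENGTHS_BP: dict[str, int] = {
    "1": 185838109, "2": 120857687, "3": 119479920, "4": 108569075,
    "5": 99680356, "6": 84719076, "7": 98542428, "8": 94057673,
    "9": 83561422, "10": 83980604, "11": 61308211, "12": 33091231,
    "13": 42578167, "14": 93904894, "15": 91571448, "16": 87365405,
    "17": 80757907, "18": 82527541, "19": 59975221, "20": 64166202,
    "21": 57723302, "22": 49946797, "23": 55726280, "24": 46749900,
    "25": 39536964, "26": 41866177, "27": 39960074, "28": 46177339,
    "29": 33672925, "30": 30062385, "31": 24984650, "X": 124114077,
}

#: Published chromosome distribution of CNVRs:
#: chrom -> (n_cnvrs, n_genes, total_cnvr_bp).
HORSE_CNVR_CHROM_TABLE: dict[str, tuple[int, int, int]] = {
    "1": (22, 59, 1486385), "2": (12, 11, 471323), "3": (14, 8, 339820),
    "4": (23, 11, 685515), "5": (12, 12, 407652), "6": (13, 8, 188057),
    "7": (22, 48, 940910), "8": (24, 30, 1034813), "9": (6, 3, 142125),
    "10": (17, 18, 338576), "11": (9, 12, 161560), "12": (6, 171, 2611353),
    "13": (9, 13, 196374), "14": (9, 4, 291428), "15": (6, 1, 77346),
    "16": (7, 3, 131240), "17": (17, 2, 194530), "18": (14, 8, 410207),
    "19": (7, 6, 138162), "20": (37, 48, 1526667), "21": (2, 3, 78028),
    "22": (9, 4, 265150), "23": (12, 3, 173586), "24": (5, 1, 89110),
    "25": (8, 10, 271071), "26": (10, 8, 251810), "27": (9, 6, 176564),
    "28": (7, 4, 469128), "29": (5, 3, 38069), "30": (0, 0, 0),
    "31": (0, 0, 0),
}

#: Published per-status CNVR totals: status -> (n_cnvrs, total_bp).
HORSE_CNVR_STATUS_TOTALS: dict[str, tuple[int, int]] = {
    "gain": (109, 5005156),
    "loss": (234, 7924489),
    "both": (10, 656914),
}

#: Published per-breed CNV counts of the five test mares.
HORSE_PER_BREED_CNV_COUNTS: dict[str, int] = {
    "Mongolia": 82, "Abaga": 112, "Hequ": 211, "Kazakh": 157, "Debao": 138,
}


def horse_genome() -> GenomeSpec:
    """EquCab2 chromosome backbone (autosomes 1..31 plus X)."""
    return GenomeSpec(tuple(HORSE_CHROM_LENGTHS_BP.items()))


def _spread_intervals(chrom: str, n: int, total_bp: int, gap: int = 1000):
    """n disjoint 1-based intervals on one chromosome whose lengths sum to
    ``total_bp``: n-1 unit-length intervals then one interval carrying the
    remainder."""
    assert total_bp >= n
    sizes = [1] * (n - 1) + [total_bp - (n - 1)]
    pos = 1
    out = []
    for size in sizes:
        out.append((chrom, pos, pos + size - 1))
        pos += size + gap
    return out


def cnvrs_matching_chrom_table() -> tuple[list[CNVR], pd.DataFrame]:
    """Synthetic CNVRs and gene annotation whose per-chromosome counts,
    total lengths and gene counts equal the published chromosome
    distribution.  Returns ``(cnvrs, annotation)``."""
    call_rows = []
    gene_rows = []
    for chrom, (n, n_genes, total_bp) in HORSE_CNVR_CHROM_TABLE.items():
        if n == 0:
            continue
        intervals = _spread_intervals(chrom, n, total_bp)
        for chrom_, start, end in intervals:
            call_rows.append(("S1", chrom_, start, end, "loss", -1.0, 10))
        # genes placed inside the last (largest) interval, one bp each
        _, gstart, gend = intervals[-1]
        assert gend - gstart + 1 >= n_genes
        for g in range(n_genes):
            gene_rows.append((f"GENE_{chrom}_{g + 1}", chrom, gstart + g,
                              gstart + g, "protein_coding"))
    calls = pd.DataFrame(call_rows, columns=[
        "sample_id", "chrom", "start", "end", "status", "mean_log2", "n_probes"])
    annotation = pd.DataFrame(gene_rows, columns=[
        "gene_id", "chrom", "start", "end", "biotype"])
    return merge_to_cnvrs(calls), annotation


def cnvrs_matching_status_totals() -> list[CNVR]:
    """Synthetic CNVRs whose per-status counts and total lengths equal the
    published status table (gain/loss/both)."""
    out = []
    pos = 1
    gap = 1000
    for status, (n, total_bp) in HORSE_CNVR_STATUS_TOTALS.items():
        sizes = [1] * (n - 1) + [total_bp - (n - 1)]
        for size in sizes:
            out.append(CNVR(chrom="1", start=pos, end=pos + size - 1,
                            status=status, samples=frozenset({"S1"})))
            pos += size + gap
    return out
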