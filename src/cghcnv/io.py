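"""File formats and run configuration.

Native interchange is TSV with a header row and 1-based inclusive
coordinates.  BED is used only at the boundary and is 0-based half-open;
:func:`internal_to_bed` / :func:`bed_to_internal` are exact inverses.  Gene
annotation is read from BED (name column = gene id) or GFF3 (``gene``
features, via gffutils).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .cnvr import ANNOTATION_COLUMNS, CNVR, cnvrs_to_frame
from .simulate import (GenomeSpec, INTENSITY_COLUMNS, PROBE_COLUMNS,
                       TRUTH_COLUMNS)
from .preprocess import TRACK_COLUMNS
from .segment import SEGMENT_COLUMNS
from .calling import CALL_COLUMNS


def internal_to_bed(start: int, end: int) -> tuple[int, int]:
    """1-based inclusive -> 0-based half-open."""
    return start - 1, end


def bed_to_internal(start0: int, end0: int) -> tuple[int, int]:
    """0-based half-open -> 1-based inclusive."""
    return start0 + 1, end0


def _read_tsv(path, required: list[str], kind: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(
            f"{path}: malformed {kind} table, missing columns {missing}")
    return df


def _write_tsv(df: pd.DataFrame, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False)


# -- probe design -----------------------------------------------------------

def write_probe_design(design: pd.DataFrame, path) -> None:
    _write_tsv(design[PROBE_COLUMNS], path)


def read_probe_design(path) -> pd.DataFrame:
    df = _read_tsv(path, PROBE_COLUMNS, "probe design")
    if (df["end"] < df["start"]).any():
        raise ValueError(f"{path}: probe end < start")
    return df[PROBE_COLUMNS]


def write_probe_design_bed(design: pd.DataFrame, path) -> None:
    """Optional BED export of the probe design (0-based half-open)."""
    bed = pd.DataFrame({
        "chrom": design["chrom"],
        "start": design["start"] - 1,
        "end": design["end"],
        "name": design["probe_id"],
    })
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    bed.to_csv(path, sep="\t", index=False, header=False)


# -- intensities, truth, tracks, segments -----------------------------------

def write_intensities(intensities: pd.DataFrame, path) -> None:
    _write_tsv(intensities[INTENSITY_COLUMNS], path)


def read_intensities(path) -> pd.DataFrame:
    df = _read_tsv(path, ["probe_id", "test_intensity", "ref_intensity"],
                   "intensity")
    if (df["test_intensity"] <= 0).any() or (df["ref_intensity"] <= 0).any():
        raise ValueError(f"{path}: non-positive intensities")
    return df


def write_truth(truth: pd.DataFrame, path) -> None:
    _write_tsv(truth[TRUTH_COLUMNS], path)


def read_truth(path) -> pd.DataFrame:
    return _read_tsv(path, TRUTH_COLUMNS, "truth")


def write_track(track: pd.DataFrame, path) -> None:
    _write_tsv(track[TRACK_COLUMNS], path)


def read_track(path) -> pd.DataFrame:
    return _read_tsv(path, TRACK_COLUMNS, "log2-ratio track")


def write_segments(segments: pd.DataFrame, path) -> None:
    _write_tsv(segments[SEGMENT_COLUMNS], path)


def read_segments(path) -> pd.DataFrame:
    return _read_tsv(path, SEGMENT_COLUMNS, "segments")


# -- calls and CNVRs --------------------------------------------------------

def write_calls(calls: pd.DataFrame, path) -> None:
    _write_tsv(calls[CALL_COLUMNS], path)


def read_calls(path) -> pd.DataFrame:
    return _read_tsv(path, CALL_COLUMNS, "CNV calls")


def write_calls_bed(calls: pd.DataFrame, path) -> None:
    """BED export: 0-based half-open, name = status,
    score = round(1000 * |mean log2|)."""
    bed = pd.DataFrame({
        "chrom": calls["chrom"],
        "start": calls["start"] - 1,
        "end": calls["end"],
        "name": calls["status"],
        "score": (1000 * calls["mean_log2"].abs()).round().astype(int),
    })
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    bed.to_csv(path, sep="\t", index=False, header=False)


def write_cnvrs(cnvrs: list[CNVR], path) -> None:
    _write_tsv(cnvrs_to_frame(cnvrs), path)


def write_cnvrs_bed(cnvrs: list[CNVR], path) -> None:
    frame = cnvrs_to_frame(cnvrs)
    bed = pd.DataFrame({
        "chrom": frame["chrom"],
        "start": frame["start"] - 1,
        "end": frame["end"],
        "name": frame["status"],
        "score": frame["n_samples"],
    })
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    bed.to_csv(path, sep="\t", index=False, header=False)


def read_regions_bed(path) -> list[CNVR]:
    """Read a BED file as a plain CNVR list (e.g. a comparison set from
    another study); name column, when present, is taken as the status."""
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(
                    f"{path}:{lineno}: BED line has fewer than 3 columns")
            start, end = bed_to_internal(int(parts[1]), int(parts[2]))
            status = parts[3] if len(parts) > 3 else "unknown"
            rows.append(CNVR(chrom=parts[0], start=start, end=end,
                             status=status, samples=frozenset()))
    return rows


# -- gene annotation --------------------------------------------------------

def read_annotation(path) -> pd.DataFrame:
    """Gene annotation from BED (name = gene id) or GFF3 (``gene`` features
    only; gene id from the ID/gene_id/Name attribute, biotype from
    gene_biotype/biotype when present).  Returns columns
    ``gene_id, chrom, start, end, biotype`` with 1-based coordinates."""
    suffix = Path(path).suffix.lower()
    if suffix in (".gff", ".gff3"):
        return _read_annotation_gff3(path)
    return _read_annotation_bed(path)


def _read_annotation_bed(path) -> pd.DataFrame:
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(
                    f"{path}:{lineno}: BED line has fewer than 3 columns")
            start, end = bed_to_internal(int(parts[1]), int(parts[2]))
            gene_id = parts[3] if len(parts) > 3 else f"gene_{lineno}"
            rows.append((gene_id, parts[0], start, end, ""))
    return pd.DataFrame(rows, columns=ANNOTATION_COLUMNS)


def _read_annotation_gff3(path) -> pd.DataFrame:
    import gffutils

    db = gffutils.create_db(str(path), ":memory:", force=True,
                            keep_order=True, merge_strategy="create_unique")
    rows = []
    for feat in db.features_of_type("gene"):
        gene_id = (feat.attributes.get("gene_id", [None])[0]
                   or feat.attributes.get("Name", [None])[0]
                   or feat.id)
        biotype = (feat.attributes.get("gene_biotype", [""])[0]
                   or feat.attributes.get("biotype", [""])[0])
        rows.append((gene_id, feat.seqid, feat.start, feat.end, biotype))
    return pd.DataFrame(rows, columns=ANNOTATION_COLUMNS)


# -- qPCR tables ------------------------------------------------------------

QPCR_COLUMNS = ["sample_id", "assay_id", "role", "ct1", "ct2", "ct3"]


def write_qpcr_table(df: pd.DataFrame, path) -> None:
    _write_tsv(df[QPCR_COLUMNS], path)


def read_qpcr_table(path) -> pd.DataFrame:
    df = _read_tsv(path, QPCR_COLUMNS, "qPCR Ct")
    bad = set(df["role"]) - {"target", "refgene"}
    if bad:
        raise ValueError(f"{path}: unknown qPCR roles {sorted(bad)}")
    return df


def qpcr_measurements(df: pd.DataFrame):
    """Pair target/refgene triplicates per (sample, assay) into
    :class:`~cghcnv.qpcr.QPCRMeasurement` objects."""
    from .qpcr import QPCRMeasurement

    out = []
    for (sample, assay), grp in df.groupby(["sample_id", "assay_id"], sort=True):
        tgt = grp[grp["role"] == "target"]
        ref = grp[grp["role"] == "refgene"]
        if len(tgt) != 1 or len(ref) != 1:
            raise ValueError(
                f"sample {sample!r} assay {assay!r}: need exactly one target "
                "and one refgene row")
        out.append(QPCRMeasurement(
            sample_id=str(sample), assay_id=str(assay),
            ct_target=tuple(tgt.iloc[0][["ct1", "ct2", "ct3"]].astype(float)),
            ct_refgene=tuple(ref.iloc[0][["ct1", "ct2", "ct3"]].astype(float))))
    return out


# -- run configuration ------------------------------------------------------

@dataclass
class RunConfig:
    """All pipeline tunables; the defaults reproduce the published filters
    (|mean log2 ratio| >= 0.5, at least 5 consecutive probes)."""

    chromosomes: list[tuple[str, int]] = field(
        default_factory=lambda: [(f"chr{i}", 3_000_000) for i in range(1, 7)])
    n_samples: int = 5
    n_cnvs_per_sample: int = 5
    cnv_size_range: tuple[int, int] = (6100, 570000)
    mean_spacing: float = 1650.0
    probe_length: int = 60
    jitter_fraction: float = 0.2
    baseline_intensity: float = 1000.0
    noise_sd: float = 0.15
    probe_effect_sd: float = 1.0
    dye_bias: tuple[float, float] = (1.2, 0.95)
    gradient_amplitude: float = 0.3
    span: float = 0.3
    n_anchors: int = 100
    k_max_per_mb: float = 10.0
    penalty_lambda: float | None = None
    threshold: float = 0.5
    min_probes: int = 5
    qpcr_gain_threshold: float = 1.4
    qpcr_loss_threshold: float = 0.6
    seed: int = 0

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = json.load(fh)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"{path}: unknown config keys {sorted(unknown)}")
        cfg = cls(**raw)
        cfg.chromosomes = [(str(n), int(l)) for n, l in cfg.chromosomes]
        cfg.cnv_size_range = tuple(cfg.cnv_size_range)
        cfg.dye_bias = tuple(cfg.dye_bias)
        return cfg

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2, sort_keys=True)
            fh.write("\n")

    def genome(self) -> GenomeSpec:
        return GenomeSpec(tuple(self.chromosomes))
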