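"""Synthetic aCGH data: tiling probe designs, planted CNV truth sets, and
two-channel hybridization simulation.

The simulator emulates a NimbleGen-style whole-genome tiling CGH experiment:
a test genome and a diploid reference genome are co-hybridized to a probe
array, and each probe reports one fluorescence intensity per channel.  The
generative model, per probe ``p`` with array position ``(row, col)``::

    log2 T_p = log2(B) + b_p + log2(c_p / 2) + g(row, col) + e_p^T
    log2 R_p = log2(B) + b_p +                 g(row, col) + e_p^R
    T_p      -> a * T_p ** beta          (test-channel dye bias, linear scale)

where ``B`` is the baseline intensity, ``b_p ~ N(0, probe_effect_sd^2)`` is a
probe-specific hybridization efficiency shared by both channels (sequence/GC
effects -- the dominant source of spread on real arrays), ``c_p`` is the test
copy number at the probe midpoint (2 outside planted CNVs), ``g`` is a smooth
spatial artifact surface over the array grid, and ``e ~ N(0, noise_sd^2)``
are independent per-channel noise terms.  Zero-copy probes retain a small
residual hybridization signal (``deletion_residual`` copies) so intensities
stay positive, mirroring background cross-hybridization.

Random draws per :func:`simulate_array` call, in order, from one seeded
generator: (1) probe effects ``b`` (n values), (2) test-channel noise
(n values), (3) reference-channel noise (n values).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

PROBE_COLUMNS = ["probe_id", "chrom", "start", "end", "row", "col"]
TRUTH_COLUMNS = ["chrom", "start", "end", "copies"]
INTENSITY_COLUMNS = ["probe_id", "test_intensity", "ref_intensity", "row", "col"]

SEX_CHROM_NAMES = {"x", "y", "chrx", "chry"}


def is_autosome(name: str) -> bool:
    """Whether a chromosome name denotes an autosome (not X/Y)."""
    return name.lower() not in SEX_CHROM_NAMES


@dataclass(frozen=True)
class GenomeSpec:
    """An ordered set of chromosomes with lengths in base pairs."""

    chromosomes: tuple[tuple[str, int], ...]

    def __post_init__(self):
        object.__setattr__(self, "chromosomes", tuple(
            (str(n), int(l)) for n, l in self.chromosomes))
        names = [n for n, _ in self.chromosomes]
        if len(set(names)) != len(names):
            raise ValueError("chromosome names must be unique")
        for n, l in self.chromosomes:
            if l <= 0:
                raise ValueError(f"chromosome {n!r} has non-positive length {l}")

    @property
    def names(self) -> list[str]:
        return [n for n, _ in self.chromosomes]

    @property
    def lengths(self) -> dict[str, int]:
        return dict(self.chromosomes)

    @property
    def total_length(self) -> int:
        return sum(l for _, l in self.chromosomes)

    @property
    def autosome_length(self) -> int:
        """Total length of autosomes only (X/Y excluded)."""
        return sum(l for n, l in self.chromosomes if is_autosome(n))


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the two-channel hybridization simulation.

    Attributes
    ----------
    baseline_intensity:
        Mean linear-scale intensity of a diploid probe before probe and
        spatial effects (arbitrary fluorescence units).
    noise_sd:
        Standard deviation of the independent per-channel Gaussian noise on
        log2 intensity.
    probe_effect_sd:
        Standard deviation of the probe-specific efficiency term shared by
        both channels (log2 units).  This shared spread is what makes the two
        channel distributions comparable and quantile normalization well
        posed.
    dye_bias:
        ``(a, b)`` of the monotone power distortion ``test' = a * test**b``
        applied to the test channel on the linear scale.  ``(1.0, 1.0)``
        disables it.
    gradient_amplitude:
        Peak-to-peak swing, in log2 units, of the spatial artifact surface
        across the array diagonal.
    gradient_shape:
        ``"planar_sine"`` (default), ``"planar"`` or ``"none"``.
    deletion_residual:
        Effective copy number floor for 0-copy probes, modelling residual
        background / cross-hybridization signal.  The default 0.4 puts
        homozygous deletions at log2(0.4/2) = -2.3, the magnitude range
        short-oligo aCGH typically reports for two-copy loss (arrays never
        observe the -inf a literal zero would imply).
    seed:
        Seed of the single generator used for all draws.
    """

    baseline_intensity: float = 1000.0
    noise_sd: float = 0.15
    probe_effect_sd: float = 1.0
    dye_bias: tuple[float, float] = (1.2, 0.95)
    gradient_amplitude: float = 0.3
    gradient_shape: str = "planar_sine"
    deletion_residual: float = 0.4
    seed: int = 0

    def __post_init__(self):
        if self.baseline_intensity <= 0:
            raise ValueError("baseline_intensity must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.probe_effect_sd < 0:
            raise ValueError("probe_effect_sd must be >= 0")
        if self.gradient_amplitude < 0:
            raise ValueError("gradient_amplitude must be >= 0")
        if self.gradient_shape not in ("planar_sine", "planar", "none"):
            raise ValueError(f"unknown gradient_shape {self.gradient_shape!r}")
        if self.deletion_residual <= 0:
            raise ValueError("deletion_residual must be positive")


def design_probes(genome: GenomeSpec, mean_spacing: float = 1650.0,
                  probe_length: int = 60, jitter_fraction: float = 0.2,
                  seed: int = 0) -> pd.DataFrame:
    """Tile every chromosome with probes at jittered regular spacing.

    Start-to-start gaps are drawn uniformly (integer bp) in
    ``mean_spacing * (1 +/- jitter_fraction)``; one gap is drawn per placed
    probe from a single seeded generator, chromosomes in genome order.
    Array ``(row, col)`` positions are assigned row-major over a near-square
    grid following genomic order.

    Returns a DataFrame with columns ``probe_id, chrom, start, end, row, col``
    (1-based inclusive coordinates).
    """
    if not mean_spacing > probe_length:
        raise ValueError("mean_spacing must exceed probe_length")
    if not 0 <= jitter_fraction < 1:
        raise ValueError("jitter_fraction must be in [0, 1)")
    rng = np.random.default_rng(seed)
    lo = int(math.ceil(mean_spacing * (1 - jitter_fraction)))
    hi = int(math.floor(mean_spacing * (1 + jitter_fraction)))
    rows: list[tuple[str, int, int]] = []
    for chrom, length in genome.chromosomes:
        if length < mean_spacing:
            warnings.warn(
                f"chromosome {chrom!r} shorter than mean_spacing; no probes placed")
            continue
        pos = 1
        while pos + probe_length - 1 <= length:
            rows.append((chrom, pos, pos + probe_length - 1))
            pos += int(rng.integers(lo, hi + 1))
    n = len(rows)
    ncol = max(1, int(math.ceil(math.sqrt(n))))
    df = pd.DataFrame(rows, columns=["chrom", "start", "end"])
    df.insert(0, "probe_id", [f"P{i + 1:07d}" for i in range(n)])
    df["row"] = np.arange(n) // ncol
    df["col"] = np.arange(n) % ncol
    return df


def plant_cnvs(genome: GenomeSpec, n_cnvs: int,
               size_range: tuple[int, int] = (6100, 570000),
               copy_choices: tuple[int, ...] = (0, 1, 3, 4),
               seed: int = 0, max_tries: int = 1000) -> pd.DataFrame:
    """Plant non-overlapping CNV intervals with non-diploid test copy numbers.

    Sizes are uniform integers in ``size_range``; chromosomes are chosen with
    probability proportional to length; copies are sampled uniformly from
    ``copy_choices``.  Returns a DataFrame ``chrom, start, end, copies``
    sorted by (chromosome order, start).
    """
    lo, hi = int(size_range[0]), int(size_range[1])
    if lo <= 0 or hi < lo:
        raise ValueError("invalid size_range")
    if 2 in copy_choices:
        raise ValueError("copy_choices must exclude the diploid state 2")
    if n_cnvs > 0 and hi > max(l for _, l in genome.chromosomes):
        raise ValueError("size_range exceeds every chromosome length")
    rng = np.random.default_rng(seed)
    names = genome.names
    lengths = np.array([l for _, l in genome.chromosomes], dtype=float)
    weights = lengths / lengths.sum()
    placed: dict[str, list[tuple[int, int]]] = {n: [] for n in names}
    out = []
    for _ in range(int(n_cnvs)):
        last_chrom = names[0]
        for attempt in range(max_tries):
            size = int(rng.integers(lo, hi + 1))
            ci = int(rng.choice(len(names), p=weights))
            chrom, clen = names[ci], int(lengths[ci])
            last_chrom = chrom
            if clen < size:
                continue
            start = int(rng.integers(1, clen - size + 2))
            end = start + size - 1
            if any(start <= e and s <= end for s, e in placed[chrom]):
                continue
            copies = int(copy_choices[int(rng.integers(0, len(copy_choices)))])
            placed[chrom].append((start, end))
            out.append((chrom, start, end, copies))
            break
        else:
            raise RuntimeError(
                f"could not place CNV without overlap after {max_tries} tries "
                f"(last attempt on chromosome {last_chrom!r})")
    df = pd.DataFrame(out, columns=TRUTH_COLUMNS)
    order = {n: i for i, n in enumerate(names)}
    df = df.sort_values(["chrom", "start"],
                        key=lambda s: s.map(order) if s.name == "chrom" else s)
    return df.reset_index(drop=True)


def spatial_gradient(row: np.ndarray, col: np.ndarray, amplitude: float,
                     shape: str = "planar_sine") -> np.ndarray:
    """Smooth log2 artifact surface over array grid coordinates.

    ``planar`` is a pure tilt whose swing across the diagonal equals
    ``amplitude``; ``planar_sine`` adds one low-frequency sinusoid.
    """
    if shape == "none" or amplitude == 0:
        return np.zeros(len(row))
    u = _unit_scale(np.asarray(row, dtype=float))
    v = _unit_scale(np.asarray(col, dtype=float))
    plane = 0.5 * (u + v - 1.0)
    if shape == "planar":
        return amplitude * plane
    if shape == "planar_sine":
        return amplitude * (plane + 0.25 * np.sin(2 * np.pi * u) * np.cos(2 * np.pi * v))
    raise ValueError(f"unknown gradient shape {shape!r}")


def _unit_scale(x: np.ndarray) -> np.ndarray:
    span = x.max() - x.min() if len(x) else 0.0
    if span == 0:
        return np.full_like(x, 0.5, dtype=float)
    return (x - x.min()) / span


def probe_copy_numbers(design: pd.DataFrame, truth: pd.DataFrame) -> np.ndarray:
    """Test copy number per probe: a probe is inside a CNV iff its midpoint
    ``floor((start+end)/2)`` falls within the truth interval; otherwise 2."""
    copies = np.full(len(design), 2, dtype=int)
    if len(truth) == 0:
        return copies
    known = set(design["chrom"])
    bad = set(truth["chrom"]) - known
    if bad:
        raise ValueError(f"truth chromosomes absent from design: {sorted(bad)}")
    mid = (design["start"].to_numpy() + design["end"].to_numpy()) // 2
    chrom = design["chrom"].to_numpy()
    for t in truth.itertuples(index=False):
        mask = (chrom == t.chrom) & (mid >= t.start) & (mid <= t.end)
        copies[mask] = t.copies
    return copies


def simulate_array(design: pd.DataFrame, truth: pd.DataFrame,
                   config: SimulationConfig) -> pd.DataFrame:
    """Simulate one two-channel hybridization against a diploid reference.

    Deterministic for a fixed ``config.seed``.  Returns a DataFrame with
    columns ``probe_id, test_intensity, ref_intensity, row, col`` aligned to
    the design.
    """
    n = len(design)
    copies = probe_copy_numbers(design, truth)
    eff = np.where(copies == 0, config.deletion_residual, copies).astype(float)
    log2_copy = np.log2(eff / 2.0)
    g = spatial_gradient(design["row"].to_numpy(), design["col"].to_numpy(),
                         config.gradient_amplitude, config.gradient_shape)
    rng = np.random.default_rng(config.seed)
    b = rng.normal(0.0, config.probe_effect_sd, n)
    noise_t = rng.normal(0.0, config.noise_sd, n)
    noise_r = rng.normal(0.0, config.noise_sd, n)
    shared = math.log2(config.baseline_intensity) + b + g
    test = np.exp2(shared + log2_copy + noise_t)
    ref = np.exp2(shared + noise_r)
    a, p = config.dye_bias
    test = a * test ** p
    return pd.DataFrame({
        "probe_id": design["probe_id"].to_numpy(),
        "test_intensity": test,
        "ref_intensity": ref,
        "row": design["row"].to_numpy(),
        "col": design["col"].to_numpy(),
    })


def simulate_self_self(design: pd.DataFrame, config: SimulationConfig) -> pd.DataFrame:
    """Hybridize the reference against itself: empty truth and no dye-bias
    asymmetry, so the expected log2 ratio is 0 genome-wide and every call
    made downstream is by construction a false positive."""
    cfg = replace(config, dye_bias=(1.0, 1.0))
    truth = pd.DataFrame(columns=TRUTH_COLUMNS)
    return simulate_array(design, truth, cfg)
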