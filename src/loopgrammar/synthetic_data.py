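"""Ground-truth scenario generator.

Emulates the statistical structure the analysis modules assume so the
whole pipeline can be exercised, and its recovery quantified, without any
sequencing data: an i.i.d. background genome with CTCF-class 19-bp and
MAZ-class GGGAGGG motif instances planted at loop anchors (strands set by
each loop's orientation class, MAZ at a configurable signed offset from
CTCF), ChIP-like peaks around the planted instances, loop sets with a
chosen convergent/tandem/divergent mixture and a sub-2-Mb-concentrated
distance law, and Poisson-sampled contact matrices with power-law distance
decay, block-TAD enrichment and corner-peak loop enrichment.  A "KO"
condition attenuates a configured fraction of loops, mirroring the
direction of a cofactor knockout.

Everything derives from one seeded generator with a fixed draw order
(TAD tiling, loops, perturbed-loop choice, genome background, motif
planting, peaks, then matrices WT replicates before KO replicates), so a
scenario is fully reproducible from its seed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field, replace

import numpy as np

from .io_formats import (
    ContactMatrix,
    GenomicInterval,
    Loop,
    PositionWeightMatrix,
)
from .motif_scan import reverse_complement

logger = logging.getLogger(__name__)

CLASS_NAMES = ("convergent", "tandem", "divergent")

CTCF_CONSENSUS = "TGGCCACCAGGGGGCGCTA"  # 19-bp CTCF-class core, non-palindromic
MAZ_CONSENSUS = "GGGAGGG"


def default_ctcf_pwm() -> PositionWeightMatrix:
    """Sharp 19-bp CTCF-class PWM (synthetic; consensus base prob 0.94)."""
    return _consensus_pwm("CTCF", CTCF_CONSENSUS, 0.94)


def default_maz_pwm() -> PositionWeightMatrix:
    """GGGAGGG-class MAZ PWM (synthetic; consensus base prob 0.97)."""
    return _consensus_pwm("MAZ", MAZ_CONSENSUS, 0.97)


def _consensus_pwm(
    name: str, consensus: str, p: float
) -> PositionWeightMatrix:
    q = (1.0 - p) / 3.0
    idx = {"A": 0, "C": 1, "G": 2, "T": 3}
    probs = np.full((len(consensus), 4), q)
    for k, base in enumerate(consensus):
        probs[k, idx[base]] = p
    return PositionWeightMatrix(name=name, probs=probs)


@dataclass
class ScenarioConfig:
    """Parameters of one synthetic study.

    Distances and sizes are in bp; ``class_mixture`` orders
    (convergent, tandem, divergent); ``maz_offset_mode`` is one of
    ``uniform_range`` (magnitude uniform in [lo, hi], placed loop-ward of
    the CTCF strand), ``fixed`` (constant offset), ``window_uniform``
    (uniform over the feasible part of the spacing window, the
    no-preferred-spacing null) or ``none``.
    """

    seed: int = 0
    chrom: str = "chrS"
    chrom_size: int = 30_000_000
    gc: float = 0.42
    n_loops: int = 300
    class_mixture: tuple[float, float, float] = (0.60, 0.30, 0.10)
    loop_min_distance: int = 100_000
    loop_mean_distance: int = 500_000
    loop_max_distance: int = 3_000_000
    maz_offset_mode: str = "uniform_range"
    maz_offset_lo: float = 70.0
    maz_offset_hi: float = 140.0
    maz_offset_fixed: float = 85.0
    maz_fraction: float = 1.0
    spacing_window_bp: int = 500
    bin_size: int = 20_000
    decay_alpha: float = 1.0
    tad_min_size: int = 400_000
    tad_max_size: int = 1_200_000
    tad_enrichment: float = 2.5
    loop_enrichment: float = 3.0
    depth: int = 10_000_000
    n_replicates: int = 2
    ko_fraction: float = 0.0
    ko_factor: float = 1.0
    peak_width: int = 200
    peak_signal_mean: float = 10.0
    peak_decoy_rate: float = 0.0

    def __post_init__(self) -> None:
        if abs(sum(self.class_mixture) - 1.0) > 1e-9:
            raise ValueError("class mixture must sum to 1")
        if self.tad_enrichment < 1 or self.loop_enrichment < 1:
            raise ValueError("enrichments must be >= 1")
        if self.depth <= 0:
            raise ValueError("depth must be positive")
        if self.n_loops > 0 and self.chrom_size < 10 * self.loop_max_distance:
            raise ValueError(
                "chromosome must be >= 10x the maximum loop distance"
            )

    def pwms(self) -> dict[str, PositionWeightMatrix]:
        return {"CTCF": default_ctcf_pwm(), "MAZ": default_maz_pwm()}


@dataclass
class PlantedMotif:
    factor: str
    chrom: str
    start: int
    end: int
    strand: str

    @property
    def midpoint(self) -> float:
        return 0.5 * (self.start + self.end)


@dataclass
class TruthTable:
    """Everything the generator planted, for recovery scoring."""

    config: ScenarioConfig
    motifs: list[PlantedMotif] = field(default_factory=list)
    loops: list[Loop] = field(default_factory=list)
    loop_classes: list[str] = field(default_factory=list)
    tad_boundaries: list[int] = field(default_factory=list)  # bin indices
    perturbed: list[bool] = field(default_factory=list)

    def loop_pixels(self) -> list[tuple[int, int]]:
        bs = self.config.bin_size
        return [
            (
                int(lp.anchor5.midpoint // bs),
                int(lp.anchor3.midpoint // bs),
            )
            for lp in self.loops
        ]

    def to_json(self, path) -> None:
        payload = {
            "config": asdict(self.config),
            "motifs": [asdict(m) for m in self.motifs],
            "loops": [
                {
                    "chrom": lp.chrom,
                    "start1": lp.anchor5.start,
                    "end1": lp.anchor5.end,
                    "start2": lp.anchor3.start,
                    "end2": lp.anchor3.end,
                }
                for lp in self.loops
            ],
            "loop_classes": self.loop_classes,
            "tad_boundaries": self.tad_boundaries,
            "perturbed": self.perturbed,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)
            fh.write("\n")

    @classmethod
    def from_json(cls, path) -> "TruthTable":
        with open(path) as fh:
            payload = json.load(fh)
        cfg_dict = payload["config"]
        cfg_dict["class_mixture"] = tuple(cfg_dict["class_mixture"])
        cfg = ScenarioConfig(**cfg_dict)
        truth = cls(config=cfg)
        truth.motifs = [PlantedMotif(**m) for m in payload["motifs"]]
        truth.loops = [
            Loop(
                GenomicInterval(d["chrom"], d["start1"], d["end1"]),
                GenomicInterval(d["chrom"], d["start2"], d["end2"]),
            )
            for d in payload["loops"]
        ]
        truth.loop_classes = list(payload["loop_classes"])
        truth.tad_boundaries = [int(b) for b in payload["tad_boundaries"]]
        truth.perturbed = [bool(p) for p in payload["perturbed"]]
        return truth


@dataclass
class Scenario:
    config: ScenarioConfig
    truth: TruthTable
    genome: dict[str, str]
    peaks: dict[str, list[GenomicInterval]]
    matrices: dict[str, list[ContactMatrix]]


# ---------------------------------------------------------------------------
# generation steps (draw order is part of the protocol; see module docstring)
# ---------------------------------------------------------------------------


def _plant_tads(config: ScenarioConfig, rng: np.random.Generator) -> list[int]:
    """Tile the chromosome with TADs; return interior boundary bins."""
    if config.tad_enrichment <= 1.0:
        return []
    n_bins = config.chrom_size // config.bin_size
    boundaries: list[int] = []
    pos = 0
    while True:
        size_bp = rng.uniform(config.tad_min_size, config.tad_max_size)
        pos += int(round(size_bp / config.bin_size))
        if pos >= n_bins:
            break
        boundaries.append(pos)
    return boundaries


def make_loops(
    config: ScenarioConfig, rng: np.random.Generator
) -> tuple[list[Loop], list[str]]:
    """Loops with bin-snapped, non-overlapping anchors and i.i.d. classes.

    Distances follow a truncated shifted exponential so that the bulk of
    loops falls below 2 Mb, as observed for real Hi-C loop sets.
    """
    bs = config.bin_size
    n_bins = config.chrom_size // bs
    min_b = max(1, int(round(config.loop_min_distance / bs)))
    max_b = int(round(config.loop_max_distance / bs))
    scale = max(config.loop_mean_distance - config.loop_min_distance, bs)
    if config.n_loops * 2 > n_bins * 0.8:
        raise ValueError("chromosome too small for the requested loop count")
    used: set[int] = set()
    loops: list[Loop] = []
    classes: list[str] = []
    attempts = 0
    while len(loops) < config.n_loops:
        attempts += 1
        if attempts > 200 * config.n_loops:
            raise RuntimeError("could not place loops without anchor overlap")
        d_bp = config.loop_min_distance + rng.exponential(scale)
        d_bins = int(np.clip(round(d_bp / bs), min_b, max_b))
        b5 = int(rng.integers(1, n_bins - d_bins - 1))
        b3 = b5 + d_bins
        if b5 in used or b3 in used:
            continue
        used.add(b5)
        used.add(b3)
        loops.append(
            Loop(
                GenomicInterval(config.chrom, b5 * bs, (b5 + 1) * bs),
                GenomicInterval(config.chrom, b3 * bs, (b3 + 1) * bs),
            )
        )
        classes.append(
            CLASS_NAMES[int(rng.choice(3, p=list(config.class_mixture)))]
        )
    order = np.argsort([lp.anchor5.start for lp in loops], kind="stable")
    loops = [loops[i] for i in order]
    classes = [classes[i] for i in order]
    return loops, classes


def _draw_maz_offset(
    config: ScenarioConfig, rng: np.random.Generator
) -> float | None:
    mode = config.maz_offset_mode
    if mode == "none":
        return None
    if config.maz_fraction < 1.0 and rng.random() >= config.maz_fraction:
        return None
    if mode == "uniform_range":
        return float(rng.uniform(config.maz_offset_lo, config.maz_offset_hi))
    if mode == "fixed":
        return float(config.maz_offset_fixed)
    if mode == "window_uniform":
        half = config.spacing_window_bp / 2.0
        margin = len(MAZ_CONSENSUS) / 2.0
        return float(rng.uniform(-half + margin, half - margin))
    raise ValueError(f"unknown maz_offset_mode {mode!r}")


def make_genome(
    config: ScenarioConfig,
    loops: list[Loop],
    classes: list[str],
    rng: np.random.Generator,
    max_retries: int = 50,
) -> tuple[dict[str, str], list[PlantedMotif]]:
    """Background genome with motif instances planted at loop anchors.

    CTCF consensus instances sit at anchor-bin centers with strands
    dictated by the loop class; MAZ consensus instances sit at a signed
    center-to-center offset from CTCF, placed loop-ward of the CTCF
    strand ('+' CTCF: MAZ downstream).  Overlapping plants are re-drawn
    a bounded number of times, then rejected.
    """
    gc = config.gc
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    codes = rng.choice(4, size=config.chrom_size, p=p).astype(np.uint8)
    seq = np.frombuffer(b"ACGT", dtype=np.uint8)[codes]

    occupied: list[tuple[int, int]] = []

    def collides(start: int, end: int) -> bool:
        return any(start < e and s < end for s, e in occupied)

    def plant(word: str, start: int) -> None:
        arr = np.frombuffer(word.encode("ascii"), dtype=np.uint8)
        seq[start : start + len(word)] = arr
        occupied.append((start, start + len(word)))

    motifs: list[PlantedMotif] = []
    kc = len(CTCF_CONSENSUS)
    km = len(MAZ_CONSENSUS)
    for lp, cls in zip(loops, classes):
        if cls == "convergent":
            strands = ("+", "-")
        elif cls == "divergent":
            strands = ("-", "+")
        else:
            s = "+" if rng.random() < 0.5 else "-"
            strands = (s, s)
        for anchor, strand in zip((lp.anchor5, lp.anchor3), strands):
            center = int(anchor.midpoint)
            c_start = center - kc // 2
            word = (
                CTCF_CONSENSUS if strand == "+"
                else reverse_complement(CTCF_CONSENSUS)
            )
            if collides(c_start, c_start + kc):
                raise RuntimeError("CTCF plant collision at fixed anchor center")
            plant(word, c_start)
            motifs.append(
                PlantedMotif("CTCF", lp.chrom, c_start, c_start + kc, strand)
            )
            offset = _draw_maz_offset(config, rng)
            if offset is None:
                continue
            sign = 1.0 if strand == "+" else -1.0
            ctcf_mid = c_start + kc / 2.0
            placed = False
            for _ in range(max_retries):
                m_mid = ctcf_mid + sign * offset
                m_start = int(round(m_mid - km / 2.0))
                if (
                    m_start < 0
                    or m_start + km > config.chrom_size
                    or collides(m_start, m_start + km)
                ):
                    offset = _draw_maz_offset(config, rng)
                    if offset is None:
                        break
                    continue
                m_strand = "+" if rng.random() < 0.5 else "-"
                m_word = (
                    MAZ_CONSENSUS if m_strand == "+"
                    else reverse_complement(MAZ_CONSENSUS)
                )
                plant(m_word, m_start)
                motifs.append(
                    PlantedMotif("MAZ", lp.chrom, m_start, m_start + km, m_strand)
                )
                placed = True
                break
            else:
                raise RuntimeError(
                    "could not place a MAZ instance after bounded retries"
                )
            del placed
    genome = {config.chrom: seq.tobytes().decode("ascii")}
    return genome, motifs


def make_peaks(
    config: ScenarioConfig,
    motifs: list[PlantedMotif],
    rng: np.random.Generator,
) -> dict[str, list[GenomicInterval]]:
    """One ChIP-like peak per planted instance, with log-normal signal.

    With a nonzero decoy rate, extra motif-free peaks are added at random
    positions (re-drawn when they would cover a planted instance).
    """
    if config.peak_width < len(MAZ_CONSENSUS):
        raise ValueError("peak width must be >= motif length")
    by_factor: dict[str, list[GenomicInterval]] = {}
    mu = np.log(config.peak_signal_mean)
    planted = [(m.start, m.end) for m in motifs]
    for m in motifs:
        half = config.peak_width // 2
        start = max(0, int(m.midpoint) - half)
        end = min(config.chrom_size, start + config.peak_width)
        signal = float(rng.lognormal(mu, 0.5))
        by_factor.setdefault(m.factor, []).append(
            GenomicInterval(m.chrom, start, end, signal=signal)
        )
    if config.peak_decoy_rate > 0:
        for factor in list(by_factor):
            n_decoy = int(round(config.peak_decoy_rate * len(by_factor[factor])))
            for _ in range(n_decoy):
                for _ in range(100):
                    start = int(
                        rng.integers(0, config.chrom_size - config.peak_width)
                    )
                    end = start + config.peak_width
                    if not any(start < e and s < end for s, e in planted):
                        break
                by_factor[factor].append(
                    GenomicInterval(
                        config.chrom, start, end,
                        name="decoy",
                        signal=float(rng.lognormal(mu, 0.5)),
                    )
                )
    for peaks in by_factor.values():
        peaks.sort(key=lambda p: (p.start, p.end))
    return by_factor


def _expected_grid(
    config: ScenarioConfig,
    truth: TruthTable,
    attenuate: bool,
) -> np.ndarray:
    """Per-pixel expected weights: decay x TAD block x loop corner peak."""
    n = config.chrom_size // config.bin_size
    d = np.abs(np.arange(n)[:, None] - np.arange(n)[None, :])
    W = (d + 1.0) ** (-config.decay_alpha)
    cuts = [0] + list(truth.tad_boundaries) + [n]
    if config.tad_enrichment > 1.0:
        for lo, hi in zip(cuts[:-1], cuts[1:]):
            W[lo:hi, lo:hi] *= config.tad_enrichment
    for (b1, b2), hit in zip(truth.loop_pixels(), truth.perturbed):
        f = config.loop_enrichment
        if attenuate and hit:
            f *= config.ko_factor
        halo = 1.0 + (f - 1.0) / 2.0
        lo1, hi1 = max(0, b1 - 1), min(n, b1 + 2)
        lo2, hi2 = max(0, b2 - 1), min(n, b2 + 2)
        W[lo1:hi1, lo2:hi2] *= halo
        W[lo2:hi2, lo1:hi1] *= halo
        W[b1, b2] *= f / halo
        W[b2, b1] *= f / halo
    return W


def make_contact_maps(
    config: ScenarioConfig,
    truth: TruthTable,
    rng: np.random.Generator,
) -> dict[str, list[ContactMatrix]]:
    """Poisson-sampled contact matrices per replicate and condition.

    The WT expectation is scaled so its upper-triangle total equals
    ``depth``; the KO expectation keeps the same per-pixel scale with the
    perturbed loops' enrichment multiplied by ``ko_factor``, so the
    planted KO/WT expected ratio at a perturbed pixel is exactly
    ``ko_factor``.
    """
    n = config.chrom_size // config.bin_size
    W_wt = _expected_grid(config, truth, attenuate=False)
    iu, ju = np.triu_indices(n)
    scale = config.depth / W_wt[iu, ju].sum()
    conditions = {"WT": W_wt}
    if config.ko_fraction > 0 and config.ko_factor != 1.0:
        conditions["KO"] = _expected_grid(config, truth, attenuate=True)
    out: dict[str, list[ContactMatrix]] = {}
    for cond, W in conditions.items():
        mats = []
        mu = scale * W[iu, ju]
        for _ in range(config.n_replicates):
            sampled = rng.poisson(mu)
            mat = np.zeros((n, n))
            mat[iu, ju] = sampled
            mat[ju, iu] = sampled
            mats.append(
                ContactMatrix(
                    chrom=config.chrom, bin_size=config.bin_size, counts=mat
                )
            )
        out[cond] = mats
    return out


def generate_scenario(
    config: ScenarioConfig, with_matrices: bool = True
) -> Scenario:
    """Run the full generation protocol from the configured seed."""
    rng = np.random.default_rng(config.seed)
    truth = TruthTable(config=config)
    truth.tad_boundaries = _plant_tads(config, rng)
    truth.loops, truth.loop_classes = make_loops(config, rng)
    n_pert = int(round(config.ko_fraction * config.n_loops))
    perturbed = np.zeros(config.n_loops, dtype=bool)
    if n_pert:
        perturbed[
            rng.choice(config.n_loops, size=n_pert, replace=False)
        ] = True
    truth.perturbed = perturbed.tolist()
    genome, truth.motifs = make_genome(
        config, truth.loops, truth.loop_classes, rng
    )
    peaks = make_peaks(config, truth.motifs, rng)
    matrices = (
        make_contact_maps(config, truth, rng) if with_matrices else {}
    )
    return Scenario(
        config=config, truth=truth, genome=genome, peaks=peaks,
        matrices=matrices,
    )


PRESETS = ("maz_ko_like", "null", "spacing_only", "apa_like", "tad_like")


def scenario_preset(name: str, seed: int = 0) -> ScenarioConfig:
    """Named study conditions.

    * ``maz_ko_like`` — 300 loops, mixture (0.60, 0.30, 0.10), MAZ offsets
      uniform in 70-140 bp, planted TADs, 30% of loops attenuated 4-fold
      in the KO condition.
    * ``null`` — zero loops, zero TADs: pure decay.
    * ``spacing_only`` — 500 CTCF sites with MAZ at a fixed +85 bp offset
      for 70% of sites; no contact structure of interest.
    * ``apa_like`` — 200 loops at 3.0-fold corner enrichment over a plain
      decay background, 5-kb bins.
    * ``tad_like`` — TADs of 0.4-1.2 Mb at 2.5-fold intra enrichment on a
      10-Mb chromosome, no loops.
    """
    if name == "maz_ko_like":
        return ScenarioConfig(
            seed=seed,
            chrom_size=30_000_000,
            n_loops=300,
            ko_fraction=0.30,
            ko_factor=0.25,
        )
    if name == "null":
        return ScenarioConfig(
            seed=seed,
            chrom_size=10_000_000,
            n_loops=0,
            tad_enrichment=1.0,
            maz_offset_mode="none",
            depth=1_000_000,
        )
    if name == "spacing_only":
        return ScenarioConfig(
            seed=seed,
            chrom_size=3_000_000,
            bin_size=2_000,
            n_loops=250,
            loop_min_distance=20_000,
            loop_mean_distance=100_000,
            loop_max_distance=300_000,
            maz_offset_mode="fixed",
            maz_fraction=0.70,
            tad_enrichment=1.0,
            depth=100_000,
        )
    if name == "apa_like":
        return ScenarioConfig(
            seed=seed,
            chrom_size=10_000_000,
            bin_size=5_000,
            n_loops=200,
            loop_min_distance=150_000,
            loop_mean_distance=500_000,
            loop_max_distance=1_000_000,
            tad_enrichment=1.0,
            depth=3_000_000,
        )
    if name == "tad_like":
        return ScenarioConfig(
            seed=seed,
            chrom_size=10_000_000,
            n_loops=0,
            maz_offset_mode="none",
            depth=2_000_000,
        )
    raise ValueError(f"unknown preset {name!r}; choose from {PRESETS}")
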