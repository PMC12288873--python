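"""Seeded simulator of phased haplotype populations with block-structured LD.

Haplotypes are mosaics of a small founder pool: each haplotype copies one
founder along the chromosome and may switch founders at known recombination
hotspot positions, after which per-site flip noise is applied.  Variants inside
a hotspot-delimited block are therefore strongly correlated (they trace the
same founders) while correlation across blocks decays with the crossover
probability — the structure the segmentation and compression stages exploit in
real data.  The matching recombination map emitted alongside exceeds the
hotspot rate threshold exactly at the simulated hotspot positions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .io_formats import HaplotypeMatrix, RecombMap, write_phased_vcf

__all__ = ["SimConfig", "SimResult", "simulate_population", "write_fixture"]

HOTSPOT_RATE = 10.0  # cM/Mb written to the emitted map at hotspots
BACKGROUND_RATE = 0.0
_HOTSPOT_HALF_WIDTH = 50  # bp; interval centre equals the hotspot position


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the simulated population.

    Founder allele frequencies follow a Beta(maf_alpha, maf_beta) truncated to
    [maf_min, maf_max]: U-shaped like a real site-frequency spectrum but
    bounded away from 0 so fixture variants survive the minimum-carrier
    filter.  ``crossover_prob`` is the per-hotspot probability that a
    haplotype switches to a uniformly chosen founder.
    """

    n_founders: int = 20
    n_haplotypes: int = 500
    n_variants: int = 600
    hotspot_positions: tuple[int, ...] = ()
    crossover_prob: float = 0.5
    mutation_flip_prob: float = 0.01
    maf_alpha: float = 0.5
    maf_beta: float = 0.5
    maf_min: float = 0.05
    maf_max: float = 0.95
    position_spacing: int = 100
    chrom: str = "chr1"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_founders < 2:
            raise ValueError("need at least 2 founders")
        for p in (self.crossover_prob, self.mutation_flip_prob):
            if not (0.0 <= p <= 1.0):
                raise ValueError("probabilities must lie in [0, 1]")
        span = self.n_variants * self.position_spacing
        if any(not (1 <= h <= span) for h in self.hotspot_positions):
            raise ValueError("hotspot_positions must lie within the simulated span")
        if list(self.hotspot_positions) != sorted(self.hotspot_positions):
            raise ValueError("hotspot_positions must be sorted")


@dataclass
class SimResult:
    haplotypes: HaplotypeMatrix
    recomb_map: RecombMap
    founders: np.ndarray  # n_founders x n_variants binary matrix
    founder_freqs: np.ndarray
    block_bounds: list[tuple[int, int]]  # variant-index blocks between hotspots
    assignments: np.ndarray = field(repr=False)  # n_haplotypes x n_blocks founder index


def _truncated_beta(rng: np.random.Generator, alpha: float, beta: float,
                    lo: float, hi: float, size: int) -> np.ndarray:
    out = np.empty(size)
    filled = 0
    while filled < size:
        draw = rng.beta(alpha, beta, size=size)
        ok = draw[(draw >= lo) & (draw <= hi)]
        take = min(len(ok), size - filled)
        out[filled:filled + take] = ok[:take]
        filled += take
    return out


def simulate_population(cfg: SimConfig = SimConfig()) -> SimResult:
    """Simulate a phased population plus its recombination map and truth record."""
    rng = np.random.default_rng(cfg.seed)
    m = cfg.n_variants
    positions = np.arange(1, m + 1, dtype=np.int64) * cfg.position_spacing - (cfg.position_spacing - 1)
    freqs = _truncated_beta(rng, cfg.maf_alpha, cfg.maf_beta, cfg.maf_min, cfg.maf_max, m)
    founders = (rng.random((cfg.n_founders, m)) < freqs).astype(np.uint8)
    # variant-index blocks delimited by hotspot positions (hotspot on a variant
    # position falls after that variant, matching the segmentation convention)
    cuts = [int(np.searchsorted(positions, h, side="right")) for h in cfg.hotspot_positions]
    bounds = []
    prev = 0
    for c in cuts:
        if c > prev:
            bounds.append((prev, c))
            prev = c
    if prev < m:
        bounds.append((prev, m))
    n_blocks = len(bounds)
    assignments = np.empty((cfg.n_haplotypes, n_blocks), dtype=np.int64)
    assignments[:, 0] = rng.integers(0, cfg.n_founders, cfg.n_haplotypes)
    for b in range(1, n_blocks):
        switch = rng.random(cfg.n_haplotypes) < cfg.crossover_prob
        assignments[:, b] = np.where(switch,
                                     rng.integers(0, cfg.n_founders, cfg.n_haplotypes),
                                     assignments[:, b - 1])
    data = np.empty((cfg.n_haplotypes, m), dtype=np.uint8)
    for b, (lo, hi) in enumerate(bounds):
        data[:, lo:hi] = founders[assignments[:, b], lo:hi]
    if cfg.mutation_flip_prob > 0:
        flips = rng.random(data.shape) < cfg.mutation_flip_prob
        data ^= flips.astype(np.uint8)
    n_donors = cfg.n_haplotypes // 2
    sample_ids = [f"S{i}_{s}" for i in range(n_donors) for s in ("A", "B")]
    sample_ids += [f"S{n_donors}_A"] * (cfg.n_haplotypes - 2 * n_donors)  # odd-N edge
    hm = HaplotypeMatrix(chrom=cfg.chrom, positions=positions,
                         variant_ids=[f"v{i}" for i in range(m)],
                         sample_ids=sample_ids, data=data)
    starts, ends, rates = [], [], []
    prev_end = 1
    for h in cfg.hotspot_positions:
        if h - _HOTSPOT_HALF_WIDTH > prev_end:
            starts.append(prev_end)
            ends.append(h - _HOTSPOT_HALF_WIDTH)
            rates.append(BACKGROUND_RATE)
        starts.append(h - _HOTSPOT_HALF_WIDTH)
        ends.append(h + _HOTSPOT_HALF_WIDTH)  # centre (start+end)//2 == h
        rates.append(HOTSPOT_RATE)
        prev_end = h + _HOTSPOT_HALF_WIDTH
    span_end = int(positions[-1]) + cfg.position_spacing
    if span_end > prev_end:
        starts.append(prev_end)
        ends.append(span_end)
        rates.append(BACKGROUND_RATE)
    rmap = RecombMap(chrom=cfg.chrom, starts=np.asarray(starts, dtype=np.int64),
                     ends=np.asarray(ends, dtype=np.int64), rates=np.asarray(rates))
    return SimResult(haplotypes=hm, recomb_map=rmap, founders=founders,
                     founder_freqs=freqs, block_bounds=bounds, assignments=assignments)


def write_fixture(directory: str | Path, sim: SimResult) -> tuple[Path, Path]:
    """Write the simulated population as a phased VCF plus a recombination-map TSV.

    The map is written in the internal one-based convention (read back with
    ``coords="one-based"``); both files round-trip bit-exactly through the
    readers in :mod:`haplogen.io_formats`.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    vcf_path = directory / "population.vcf"
    map_path = directory / "recomb_map.tsv"
    write_phased_vcf(sim.haplotypes, vcf_path)
    rmap = sim.recomb_map
    with open(map_path, "w") as fh:
        fh.write("chrom\tstart\tend\trate_cM_Mb\n")
        for s, e, r in zip(rmap.starts, rmap.ends, rmap.rates):
            fh.write(f"{rmap.chrom}\t{s}\t{e}\t{r}\n")
    return vcf_path, map_path
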