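"""Synthetic genotype cohorts with planted autozygosity (ground truth included).

The generator emulates reduced-representation SNP data from a single pig
population: 18 autosomes totalling 2.26 Gb, roughly one SNP per 12.4 kb
(~182k markers genome-wide), cohort allele frequencies drawn uniformly from
[0.05, 0.5], background genotypes in Hardy-Weinberg proportions, and
per-individual autozygous tracts planted directly (no coalescent machinery).
Tract lengths are exponential with mean 100/(2g) cM where g is the
generations-to-common-ancestor parameter, using the 1 cM ~ 1 Mb
correspondence; within a tract the individual is homozygous for one sampled
haplotype, with a small het-error rate mimicking genotyping error.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io import MISSING, GenotypeMatrix, MarkerMap, Pedigree

# Sscrofa11.1-like autosome lengths (Mb), summing to exactly 2260 Mb
DEFAULT_CHROM_LENGTHS_BP: dict[str, int] = {
    "1": 274, "2": 151, "3": 133, "4": 131, "5": 104, "6": 171, "7": 121,
    "8": 139, "9": 139, "10": 69, "11": 79, "12": 61, "13": 208, "14": 141,
    "15": 140, "16": 80, "17": 63, "18": 56,
}
DEFAULT_CHROM_LENGTHS_BP = {c: mb * 1_000_000 for c, mb in DEFAULT_CHROM_LENGTHS_BP.items()}


@dataclass(frozen=True)
class TruthTract:
    """A planted autozygous interval (ground truth for recovery tests)."""

    sample: str
    chrom: str
    start_bp: int
    end_bp: int
    generations: float

    @property
    def length_bp(self) -> int:
        return self.end_bp - self.start_bp


@dataclass
class SimulationConfig:
    """Study-shaped cohort parameters; the seed is mandatory for reproducibility."""

    seed: int
    n_individuals: int = 93
    n_males: int = 17
    n_females: int = 76
    chrom_lengths_bp: Mapping[str, int] = field(
        default_factory=lambda: dict(DEFAULT_CHROM_LENGTHS_BP))
    snp_spacing_bp: int = 12_400
    maf_range: tuple[float, float] = (0.05, 0.5)
    het_error_rate: float = 0.001
    missing_rate: float = 0.02
    autozygosity: float | Sequence[float] = 0.0
    generations_to_ancestor: float = 5.0
    min_tract_bp: int = 1_000_000

    def __post_init__(self) -> None:
        for r in (self.het_error_rate, self.missing_rate):
            if not (0 <= r <= 1):
                raise ValueError("rates must be in [0, 1]")
        f = np.atleast_1d(np.asarray(self.autozygosity, dtype=float))
        if ((f < 0) | (f > 0.95)).any():
            raise ValueError("autozygosity targets must be in [0, 0.95]")
        if not (0 < self.maf_range[0] <= self.maf_range[1] <= 0.5):
            raise ValueError("maf_range must satisfy 0 < lo <= hi <= 0.5")
        if self.snp_spacing_bp <= 0 or self.generations_to_ancestor <= 0:
            raise ValueError("snp_spacing_bp and generations_to_ancestor must be positive")

    @property
    def genome_length_bp(self) -> int:
        return int(sum(self.chrom_lengths_bp.values()))

    def f_targets(self) -> np.ndarray:
        f = np.atleast_1d(np.asarray(self.autozygosity, dtype=float))
        if f.size == 1:
            return np.full(self.n_individuals, float(f[0]))
        if f.size != self.n_individuals:
            raise ValueError("autozygosity must be a scalar or one value per individual")
        return f

    def mean_tract_bp(self) -> float:
        # tract length ~ Exp(mean 100/(2g) cM), 1 cM ~ 1 Mb
        return 100.0 / (2.0 * self.generations_to_ancestor) * 1e6


def _build_map(cfg: SimulationConfig) -> MarkerMap:
    rows = []
    chroms = tuple(str(c) for c in cfg.chrom_lengths_bp)
    for chrom, length in cfg.chrom_lengths_bp.items():
        pos = np.arange(cfg.snp_spacing_bp, length + 1, cfg.snp_spacing_bp, dtype=np.int64)
        rows.append(pd.DataFrame({
            "snp_id": [f"snp_{chrom}_{k}" for k in range(len(pos))],
            "chrom": str(chrom), "pos": pos}))
    return MarkerMap(pd.concat(rows, ignore_index=True), autosomes=chroms)


def _sample_tracts(cfg: SimulationConfig, rng: np.random.Generator, sample: str,
                   target_bp: float, max_retries: int = 1000) -> list[TruthTract]:
    """Non-overlapping tracts totalling ~target_bp (last tract truncated to fit)."""
    if target_bp <= 0:
        return []
    chroms = list(cfg.chrom_lengths_bp)
    lengths = np.array([cfg.chrom_lengths_bp[c] for c in chroms], dtype=float)
    weights = lengths / lengths.sum()
    placed: dict[str, list[tuple[int, int]]] = {c: [] for c in chroms}
    tracts: list[TruthTract] = []
    total = 0.0
    retries = 0
    while total < target_bp:
        want = target_bp - total
        tract_len = rng.exponential(cfg.mean_tract_bp())
        tract_len = max(tract_len, cfg.min_tract_bp)
        if tract_len > want:  # truncate the final tract to hit the target
            tract_len = max(want, cfg.min_tract_bp)
        tract_len = int(round(tract_len))
        ci = rng.choice(len(chroms), p=weights)
        chrom, clen = chroms[ci], int(lengths[ci])
        if tract_len >= clen:
            tract_len = clen - 1
        start = int(rng.integers(1, clen - tract_len + 1))
        end = start + tract_len
        if any(start <= e and end >= s for s, e in placed[chrom]):
            retries += 1
            if retries > max_retries:
                raise RuntimeError(
                    f"could not place tracts for {sample}: target autozygosity "
                    "unreachable with this tract-length distribution")
            continue
        placed[chrom].append((start, end))
        tracts.append(TruthTract(sample, chrom, start, end, cfg.generations_to_ancestor))
        total += tract_len
    return tracts


def simulate_cohort(cfg: SimulationConfig) -> tuple[GenotypeMatrix, list[TruthTract]]:
    """Generate a cohort with planted autozygous tracts; identical seed, identical output."""
    rng = np.random.default_rng(cfg.seed)
    markers = _build_map(cfg)
    n_snps = markers.n_snps
    n = cfg.n_individuals
    samples = [f"LW{i + 1:03d}" for i in range(n)]
    p_alt = rng.uniform(cfg.maf_range[0], cfg.maf_range[1], size=n_snps)
    calls = rng.binomial(2, p_alt, size=(n, n_snps)).astype(np.int8)

    slices = markers.chrom_slices()
    positions = markers.table["pos"].to_numpy()
    truth: list[TruthTract] = []
    for i, (sample, f_i) in enumerate(zip(samples, cfg.f_targets())):
        tracts = _sample_tracts(cfg, rng, sample, f_i * cfg.genome_length_bp)
        truth.extend(tracts)
        for t in tracts:
            sl = slices[t.chrom]
            pos = positions[sl]
            i0 = sl.start + int(np.searchsorted(pos, t.start_bp, side="left"))
            i1 = sl.start + int(np.searchsorted(pos, t.end_bp, side="right"))
            if i1 <= i0:
                continue
            hap = rng.binomial(1, p_alt[i0:i1])
            g = (2 * hap).astype(np.int8)
            err = rng.random(i1 - i0) < cfg.het_error_rate
            g[err] = 1
            calls[i, i0:i1] = g
    if cfg.missing_rate > 0:
        calls[rng.random(calls.shape) < cfg.missing_rate] = MISSING
    gm = GenotypeMatrix(samples, calls, markers, cfg.genome_length_bp)
    gm.io_stats = {"n_males": cfg.n_males, "n_females": cfg.n_females}
    return gm, truth


def simulate_island_cohort(cfg: SimulationConfig, chrom: str, start_bp: int, end_bp: int,
                           carrier_fraction: float, seed: int | None = None
                           ) -> tuple[GenotypeMatrix, list[TruthTract], list[str]]:
    """Cohort with one shared homozygous region planted in a fraction of individuals.

    All carriers receive the same haplotype over the region (a hard selective
    sweep caricature); the background is simulate_cohort. Returns the cohort,
    all truth tracts (background + island copies) and the carrier ids.
    """
    if not (0 < carrier_fraction <= 1):
        raise ValueError("carrier_fraction must be in (0, 1]")
    chrom = str(chrom)
    if chrom not in cfg.chrom_lengths_bp:
        raise ValueError(f"unknown chromosome {chrom!r}")
    if end_bp > cfg.chrom_lengths_bp[chrom] or start_bp < 1 or start_bp >= end_bp:
        raise ValueError("island region does not fit on the chromosome")
    gm, truth = simulate_cohort(cfg)
    rng = np.random.default_rng(seed if seed is not None else cfg.seed + 1)
    n = gm.n_samples
    k = max(1, int(round(carrier_fraction * n)))
    carrier_idx = rng.choice(n, size=k, replace=False)
    sl = gm.markers.chrom_slices()[chrom]
    pos = gm.markers.table["pos"].to_numpy()[sl]
    i0 = sl.start + int(np.searchsorted(pos, start_bp, side="left"))
    i1 = sl.start + int(np.searchsorted(pos, end_bp, side="right"))
    p_alt = np.clip(gm.allele_freq()[i0:i1], 0.05, 0.95)
    shared_hap = rng.binomial(1, p_alt)
    base = (2 * shared_hap).astype(np.int8)
    for i in carrier_idx:
        g = base.copy()
        g[rng.random(i1 - i0) < cfg.het_error_rate] = 1
        g[rng.random(i1 - i0) < cfg.missing_rate] = MISSING
        gm.calls[i, i0:i1] = g
        truth.append(TruthTract(gm.samples[i], chrom, start_bp, end_bp,
                                cfg.generations_to_ancestor))
    carriers = [gm.samples[i] for i in sorted(carrier_idx)]
    return gm, truth, carriers


# ---------------------------------------------------------------------------
# pedigrees with known F
# ---------------------------------------------------------------------------

def full_sib_line_f(t: int) -> float:
    """Expected F in generation t of repeated full-sib mating:
    F_t = 1/4 (1 + 2 F_{t-1} + F_{t-2}), F_0 = F_{-1} = 0."""
    f_prev2, f_prev1 = 0.0, 0.0
    for _ in range(t):
        f_prev2, f_prev1 = f_prev1, 0.25 * (1 + 2 * f_prev1 + f_prev2)
    return f_prev1


def simulate_pedigree(n_founders: int = 16, n_generations: int = 2,
                      scheme: str = "random", seed: int = 0) -> Pedigree:
    """Pedigree with analytically known inbreeding for the named schemes.

    * ``full_sib_line``: a founder pair, then repeated full-sib mating;
      generation t offspring have F = full_sib_line_f(t).
    * ``half_sib_line``: one sire, two dams; the half-sib pair's offspring
      have F = 0.125; subsequent generations continue by full-sib mating.
    * ``random``: founder pairs crossed hierarchically (families merged
      pairwise each generation), so with n_founders >= 2^(n_generations+1)
      no mates share an ancestor and every F is exactly 0.
    """
    records: list[tuple[str, str | None, str | None]] = []
    if scheme == "full_sib_line":
        records += [("M", None, None), ("F", None, None)]
        prev = ("S0a", "S0b")
        records += [(prev[0], "M", "F"), (prev[1], "M", "F")]
        for t in range(1, n_generations + 1):
            cur = (f"G{t}a", f"G{t}b")
            records += [(cur[0], prev[0], prev[1]), (cur[1], prev[0], prev[1])]
            prev = cur
        return Pedigree(records)
    if scheme == "half_sib_line":
        records += [("SIRE", None, None), ("D1", None, None), ("D2", None, None)]
        prev = ("H1", "H2")
        records += [("H1", "SIRE", "D1"), ("H2", "SIRE", "D2")]
        for t in range(1, n_generations + 1):
            cur = (f"G{t}a", f"G{t}b")
            records += [(cur[0], prev[0], prev[1]), (cur[1], prev[0], prev[1])]
            prev = cur
        return Pedigree(records)
    if scheme == "random":
        rng = np.random.default_rng(seed)
        founders = [f"F{i:03d}" for i in range(n_founders)]
        records += [(f, None, None) for f in founders]
        order = list(rng.permutation(founders))
        gen = order
        for t in range(1, n_generations + 1):
            nxt = []
            for k in range(0, len(gen) - 1, 2):
                child = f"G{t}_{k // 2:03d}"
                records.append((child, gen[k], gen[k + 1]))
                nxt.append(child)
            gen = nxt
            if len(gen) < 2:
                break
        return Pedigree(records)
    raise ValueError(f"unknown scheme {scheme!r}")
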