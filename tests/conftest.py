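from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from rohscan import MarkerMap, GenotypeMatrix, MISSING


@pytest.fixture
def small_map() -> MarkerMap:
    """Two chromosomes, 10-kb spacing, 1,200 + 800 SNPs."""
    rows = []
    for chrom, n in (("1", 1200), ("2", 800)):
        pos = np.arange(1, n + 1) * 10_000
        rows.append(pd.DataFrame({
            "snp_id": [f"s{chrom}_{i}" for i in range(n)],
            "chrom": chrom, "pos": pos}))
    return MarkerMap(pd.concat(rows, ignore_index=True))


def make_matrix(calls: np.ndarray, spacing_bp: int = 10_000, chrom: str = "1",
                genome_length_bp: int | None = None) -> GenotypeMatrix:
    """Wrap a (samples x snps) array on a single uniformly spaced chromosome."""
    calls = np.atleast_2d(np.asarray(calls, dtype=np.int8))
    n = calls.shape[1]
    mm = MarkerMap(pd.DataFrame({
        "snp_id": [f"s{i}" for i in range(n)],
        "chrom": chrom,
        "pos": np.arange(1, n + 1) * spacing_bp}))
    return GenotypeMatrix([f"I{i}" for i in range(calls.shape[0])], calls, mm,
                          genome_length_bp or n * spacing_bp)


def random_fixture(rng: np.random.Generator, n_snps: int = 2000,
                   n_chroms: int = 2, spacing_bp: int = 10_000):
    """Random genotype vector with planted homozygous stretches for scan tests.

    Returns (calls, chroms, positions) lists suitable for both the package
    scanner and the brute-force oracle. Mixes HWE background, planted runs of
    assorted lengths/densities, missingness, and occasional large gaps.
    """
    calls = np.empty(n_snps, dtype=np.int8)
    chrom_labels = [str(c + 1) for c in range(n_chroms)]
    bounds = np.sort(rng.choice(np.arange(1, n_snps), size=n_chroms - 1, replace=False)) \
        if n_chroms > 1 else np.array([], dtype=int)
    starts = np.concatenate([[0], bounds])
    stops = np.concatenate([bounds, [n_snps]])
    chroms: list[str] = []
    positions: list[int] = []
    for lab, a, b in zip(chrom_labels, starts, stops):
        m = b - a
        gaps = rng.integers(spacing_bp // 2, spacing_bp * 2, size=m)
        big = rng.random(m) < 0.002  # occasional gaps beyond max_gap_bp
        gaps[big] = rng.integers(1_200_000, 3_000_000, size=int(big.sum()))
        pos = np.cumsum(gaps)
        chroms.extend([lab] * m)
        positions.extend(pos.tolist())
    p = rng.uniform(0.05, 0.5, size=n_snps)
    calls[:] = rng.binomial(2, p, size=n_snps)
    # plant homozygous stretches of assorted sizes, some near filter boundaries
    for _ in range(rng.integers(1, 5)):
        ln = int(rng.integers(60, 400))
        s = int(rng.integers(0, max(1, n_snps - ln)))
        calls[s:s + ln] = np.where(rng.random(ln) < 0.5, 0, 2)
        flip = rng.random(ln) < 0.005
        calls[s:s + ln][flip] = 1
    miss = rng.random(n_snps) < 0.02
    calls[miss] = MISSING
    return calls.tolist(), chroms, positions
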