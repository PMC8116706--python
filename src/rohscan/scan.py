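"""Sliding-window detection of runs of homozygosity (ROH).

The detector mirrors the PLINK ``--homozyg`` approach: windows of a fixed
number of SNPs slide along each chromosome; a window is called homozygous if
it carries at most ``window_het_max`` heterozygous and ``window_missing_max``
missing calls; a SNP is eligible when the fraction of windows covering it
that are homozygous reaches ``window_hit_fraction``. Maximal runs of
eligible SNPs are trimmed so they neither start nor end on a het/missing
call, split at large inter-SNP gaps, and finally filtered on SNP count,
physical length and SNP density.

Segment length is ``end_bp - start_bp`` (simple difference), consistent with
the island-length convention used downstream; ``inclusive_length=True``
switches to ``end - start + 1``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .io import MISSING, GenotypeMatrix, MarkerMap


@dataclass(frozen=True)
class ROHSegment:
    """One homozygous run: positions of first/last SNP, 1-based inclusive."""

    sample: str
    chrom: str
    start_bp: int
    end_bp: int
    n_snps: int

    @property
    def length_bp(self) -> int:
        return self.end_bp - self.start_bp


@dataclass
class ScanParams:
    """Detection parameters; defaults follow PLINK's --homozyg defaults."""

    window_snp: int = 50
    window_het_max: int = 1
    window_missing_max: int = 5
    window_hit_fraction: float = 0.05
    min_snp: int = 100
    min_length_bp: int = 1_000_000
    density_bp_per_snp: int = 50_000
    max_gap_bp: int = 1_000_000
    length_class_bounds_mb: tuple[float, ...] = (1.0, 5.0, 10.0)
    inclusive_length: bool = False

    def __post_init__(self) -> None:
        for name in ("window_snp", "window_het_max", "window_missing_max",
                     "window_hit_fraction", "min_snp", "min_length_bp",
                     "density_bp_per_snp", "max_gap_bp"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.window_snp <= 0 or self.window_snp > self.min_snp:
            raise ValueError("require 0 < window_snp <= min_snp")
        b = self.length_class_bounds_mb
        if any(b[i] >= b[i + 1] for i in range(len(b) - 1)):
            raise ValueError("length_class_bounds_mb must be strictly increasing")


def _segment_length(start: int, end: int, p: ScanParams) -> int:
    return end - start + (1 if p.inclusive_length else 0)


def _eligible_mask(het: np.ndarray, miss: np.ndarray, p: ScanParams) -> np.ndarray:
    """Per-SNP window-eligibility on one chromosome (vectorised)."""
    n = het.size
    w = p.window_snp
    if n < w:
        return np.zeros(n, dtype=bool)
    het_c = np.concatenate([[0], np.cumsum(het)])
    mis_c = np.concatenate([[0], np.cumsum(miss)])
    win_het = het_c[w:] - het_c[:-w]
    win_mis = mis_c[w:] - mis_c[:-w]
    win_ok = (win_het <= p.window_het_max) & (win_mis <= p.window_missing_max)
    ok_c = np.concatenate([[0], np.cumsum(win_ok)])
    n_win = n - w + 1
    idx = np.arange(n)
    lo = np.maximum(0, idx - w + 1)
    hi = np.minimum(idx, n_win - 1)
    hits = ok_c[hi + 1] - ok_c[lo]
    return hits / (hi - lo + 1) >= p.window_hit_fraction


def _true_runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Inclusive (start, end) index pairs of maximal True runs."""
    if not mask.any():
        return []
    padded = np.concatenate([[False], mask, [False]])
    d = np.diff(padded.astype(np.int8))
    starts = np.flatnonzero(d == 1)
    ends = np.flatnonzero(d == -1) - 1
    return list(zip(starts.tolist(), ends.tolist()))


def scan_individual(calls: np.ndarray, markers: MarkerMap, params: ScanParams | None = None,
                    sample: str = "sample") -> list[ROHSegment]:
    """Detect ROH for one individual; ``calls`` aligned with ``markers``."""
    p = params or ScanParams()
    calls = np.asarray(calls)
    if calls.shape != (markers.n_snps,):
        raise ValueError("calls must be a 1-D array aligned with the marker map")
    out: list[ROHSegment] = []
    positions = markers.table["pos"].to_numpy()
    for chrom, sl in markers.chrom_slices().items():
        c = calls[sl]
        pos = positions[sl]
        het = c == 1
        miss = c == MISSING
        bad = het | miss
        eligible = _eligible_mask(het, miss, p)
        for s0, e0 in _true_runs(eligible):
            # split at gaps > max_gap_bp, trimming het/missing ends of each piece
            pieces = [(s0, e0)]
            gap_idx = np.flatnonzero(np.diff(pos[s0:e0 + 1]) > p.max_gap_bp)
            if gap_idx.size:
                pieces = []
                a = s0
                for gi in gap_idx:
                    pieces.append((a, s0 + int(gi)))
                    a = s0 + int(gi) + 1
                pieces.append((a, e0))
            for s, e in pieces:
                while s <= e and bad[s]:
                    s += 1
                while e >= s and bad[e]:
                    e -= 1
                if s > e:
                    continue
                n_snps = e - s + 1
                length = _segment_length(int(pos[s]), int(pos[e]), p)
                if (n_snps >= p.min_snp and length >= p.min_length_bp
                        and length / n_snps <= p.density_bp_per_snp):
                    out.append(ROHSegment(sample, chrom, int(pos[s]), int(pos[e]), n_snps))
    _assert_valid(out, p)
    return out


def scan_population(g: GenotypeMatrix, params: ScanParams | None = None) -> list[ROHSegment]:
    """Run scan_individual over every sample; deterministic (sample, chrom, start) order."""
    p = params or ScanParams()
    out: list[ROHSegment] = []
    for i, s in enumerate(g.samples):
        out.extend(scan_individual(g.calls[i], g.markers, p, sample=s))
    return out


def _assert_valid(segments: Sequence[ROHSegment], p: ScanParams) -> None:
    by_key: dict[tuple[str, str], list[ROHSegment]] = {}
    for s in segments:
        if s.n_snps < p.min_snp:
            raise AssertionError(f"segment with {s.n_snps} SNPs < min_snp")
        length = _segment_length(s.start_bp, s.end_bp, p)
        if length < p.min_length_bp:
            raise AssertionError("segment shorter than min_length_bp")
        if length / s.n_snps > p.density_bp_per_snp:
            raise AssertionError("segment violates density bound")
        by_key.setdefault((s.sample, s.chrom), []).append(s)
    for segs in by_key.values():
        segs = sorted(segs, key=lambda x: x.start_bp)
        for a, b in zip(segs, segs[1:]):
            if b.start_bp <= a.end_bp:
                raise AssertionError("overlapping segments for one individual")


def segments_to_frame(segments: Sequence[ROHSegment]) -> pd.DataFrame:
    df = pd.DataFrame(
        [(s.sample, s.chrom, s.start_bp, s.end_bp, s.n_snps, s.length_bp) for s in segments],
        columns=["sample", "chrom", "start_bp", "end_bp", "n_snps", "length_bp"])
    return df


def class_labels(bounds_mb: Sequence[float]) -> list[str]:
    labels = []
    for i in range(len(bounds_mb) - 1):
        labels.append(f"{bounds_mb[i]:g}-{bounds_mb[i + 1]:g}")
    labels.append(f">{bounds_mb[-1]:g}")
    return labels


def class_of(length_bp: int, bounds_mb: Sequence[float]) -> int:
    """Index of the left-closed right-open length class; -1 if below the first bound."""
    mb = length_bp / 1e6
    if mb < bounds_mb[0]:
        return -1
    for i in range(len(bounds_mb) - 1, -1, -1):
        if mb >= bounds_mb[i]:
            return i
    return -1


def classify_segments(segments: Sequence[ROHSegment], *, n_individuals: int,
                      genome_length_bp: int,
                      bounds_mb: Sequence[float] = (1.0, 5.0, 10.0)) -> pd.DataFrame:
    """Length-class summary table (counts, percents, mean/SD length, coverage).

    Classes are left-closed right-open ([1,5), [5,10), [10,inf) Mb by
    default) plus a total row. Genome coverage of a class is the summed
    segment length over all individuals divided by
    ``n_individuals * genome_length_bp``, as a percent.
    """
    labels = class_labels(bounds_mb)
    lengths_by_class: list[list[float]] = [[] for _ in labels]
    for s in segments:
        k = class_of(s.length_bp, bounds_mb)
        if k < 0:
            raise ValueError(
                f"segment of {s.length_bp / 1e6:.3f} Mb below the first class bound "
                f"{bounds_mb[0]} Mb (scan should have filtered it)")
        lengths_by_class[k].append(s.length_bp / 1e6)
    total = len(segments)
    denom_mb = n_individuals * genome_length_bp / 1e6
    rows = []
    for lab, ls in zip(labels, lengths_by_class):
        arr = np.array(ls)
        rows.append({
            "class": lab,
            "count": len(ls),
            "percent": (100.0 * len(ls) / total) if total else 0.0,
            "mean_length_mb": arr.mean() if len(ls) else np.nan,
            "sd_length_mb": arr.std(ddof=1) if len(ls) > 1 else np.nan,
            "coverage_percent": 100.0 * arr.sum() / denom_mb,
        })
    all_mb = np.array([s.length_bp / 1e6 for s in segments])
    rows.append({
        "class": f"Total (>{bounds_mb[0]:g})",
        "count": total,
        "percent": 100.0 if total else 0.0,
        "mean_length_mb": all_mb.mean() if total else np.nan,
        "sd_length_mb": all_mb.std(ddof=1) if total > 1 else np.nan,
        "coverage_percent": 100.0 * all_mb.sum() / denom_mb,
    })
    return pd.DataFrame(rows)


def per_chromosome_summary(segments: Sequence[ROHSegment],
                           chrom_lengths: Mapping[str, int],
                           n_individuals: int) -> pd.DataFrame:
    """Per-chromosome segment count and coverage percent.

    Coverage = summed segment length on the chromosome over all individuals
    divided by ``n_individuals * chromosome length``, as a percent.
    """
    counts = {c: 0 for c in chrom_lengths}
    lensum = {c: 0 for c in chrom_lengths}
    for s in segments:
        if s.chrom not in counts:
            raise ValueError(f"segment on chromosome {s.chrom!r} missing from chrom_lengths")
        counts[s.chrom] += 1
        lensum[s.chrom] += s.length_bp
    rows = [{"chrom": c,
             "count": counts[c],
             "coverage_percent": 100.0 * lensum[c] / (n_individuals * chrom_lengths[c])}
            for c in chrom_lengths]
    return pd.DataFrame(rows)
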