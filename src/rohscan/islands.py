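"""ROH islands: per-SNP ROH incidence, top-percentile calling, annotation overlap.

An island is a maximal run of consecutively-mapped SNPs whose ROH incidence
(the fraction of individuals with at least one ROH covering the SNP) reaches
the empirical (1 - top_fraction) quantile of the incidence track. The
quantile is an order statistic of the observed incidences and ties at the
threshold are all selected, so at least ``ceil(top_fraction * n_snps)`` SNPs
are always picked. Island length is ``end - start`` (simple difference).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .io import AnnotationIntervals, MarkerMap
from .scan import ROHSegment

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class IslandRegion:
    """Merged run of selected SNPs: span of first to last SNP, 1-based inclusive."""

    chrom: str
    start_bp: int
    end_bp: int
    n_snps: int
    max_incidence: float
    annotations: tuple[str, ...] = ()

    @property
    def length_bp(self) -> int:
        return self.end_bp - self.start_bp


def incidence(segments: Sequence[ROHSegment], markers: MarkerMap,
              n_individuals: int) -> pd.DataFrame:
    """Per-SNP ROH incidence track (chrom, pos, incidence), in map order.

    A SNP covered by two segments of the same individual counts once.
    """
    if n_individuals < 1:
        raise ValueError("n_individuals must be >= 1")
    slices = markers.chrom_slices()
    positions = markers.table["pos"].to_numpy()
    counts = np.zeros(markers.n_snps, dtype=np.int64)
    by_sample: dict[str, list[ROHSegment]] = {}
    for s in segments:
        if s.chrom not in slices:
            raise ValueError(f"segment on chromosome {s.chrom!r} absent from the marker map")
        by_sample.setdefault(s.sample, []).append(s)
    for segs in by_sample.values():
        covered = np.zeros(markers.n_snps, dtype=bool)
        for s in segs:
            sl = slices[s.chrom]
            pos = positions[sl]
            i0 = int(np.searchsorted(pos, s.start_bp, side="left"))
            i1 = int(np.searchsorted(pos, s.end_bp, side="right"))
            covered[sl.start + i0: sl.start + i1] = True
        counts += covered
    track = markers.table[["chrom", "pos"]].copy()
    track["incidence"] = counts / n_individuals
    return track


def call_islands(track: pd.DataFrame, top_fraction: float = 0.01,
                 max_gap_bp: int | None = None) -> list[IslandRegion]:
    """Call ROH islands from an incidence track ordered like the marker map.

    SNPs with incidence >= the (1 - top_fraction) order-statistic quantile
    are selected (ties included); maximal runs of consecutive selected SNPs
    on one chromosome are merged into islands. ``max_gap_bp`` optionally
    breaks runs at large physical gaps (no limit by default).
    """
    if not (0 < top_fraction < 1):
        raise ValueError("top_fraction must be in (0, 1)")
    vals = track["incidence"].to_numpy(dtype=float)
    if vals.size == 0:
        warnings.warn("empty incidence track; no islands")
        return []
    threshold = float(np.quantile(vals, 1.0 - top_fraction, method="higher"))
    selected = vals >= threshold
    if not selected.any():
        warnings.warn("no SNP reached the incidence threshold; no islands")
        return []
    if selected.all():
        warnings.warn("incidence threshold is degenerate (all SNPs tie the quantile); "
                      "one island per chromosome will be reported")
    chroms = track["chrom"].to_numpy()
    pos = track["pos"].to_numpy()
    out: list[IslandRegion] = []
    i, n = 0, len(track)
    while i < n:
        if not selected[i]:
            i += 1
            continue
        j = i
        while (j + 1 < n and selected[j + 1] and chroms[j + 1] == chroms[i]
               and (max_gap_bp is None or pos[j + 1] - pos[j] <= max_gap_bp)):
            j += 1
        region = IslandRegion(str(chroms[i]), int(pos[i]), int(pos[j]), j - i + 1,
                              float(vals[i:j + 1].max()))
        if region.n_snps == 1:
            log.info("single-SNP island at %s:%d (length 0)", region.chrom, region.start_bp)
        out.append(region)
        i = j + 1
    return out


def island_length(island: IslandRegion) -> int:
    """Island length in bp (end - start, matching the reporting convention)."""
    return island.length_bp


def overlap_annotations(islands: Sequence[IslandRegion],
                        annotations: AnnotationIntervals) -> list[IslandRegion]:
    """Attach names of intervals sharing >= 1 bp with each island.

    Partial containment counts. Names are tagged 'category:name' unless the
    category is 'gene'. Existing annotations on the islands are preserved.
    """
    trees: dict[str, IntervalTree] = {}
    for r in annotations.table.itertuples():
        label = r.name if r.category == "gene" else f"{r.category}:{r.name}"
        # internal 1-based inclusive -> half-open tree interval
        trees.setdefault(str(r.chrom), IntervalTree()).addi(r.start_bp, r.end_bp + 1, label)
    out = []
    for isl in islands:
        tree = trees.get(isl.chrom)
        hits = sorted(tree.overlap(isl.start_bp, isl.end_bp + 1),
                      key=lambda iv: (iv.begin, iv.data)) if tree is not None else []
        names = list(isl.annotations) + [iv.data for iv in hits]
        out.append(IslandRegion(isl.chrom, isl.start_bp, isl.end_bp, isl.n_snps,
                                isl.max_incidence, tuple(names)))
    return out


def islands_to_frame(islands: Sequence[IslandRegion]) -> pd.DataFrame:
    return pd.DataFrame(
        [(i.chrom, i.start_bp, i.end_bp, i.length_bp, i.n_snps, i.max_incidence,
          ",".join(i.annotations)) for i in islands],
        columns=["chrom", "start_bp", "end_bp", "length_bp", "n_snps",
                 "max_incidence", "annotations"])
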