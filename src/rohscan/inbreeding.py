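"""Pedigree-, ROH-, and SNP-based inbreeding coefficients and diversity stats.

Estimators
----------
* ``f_ped`` — Wright's coefficient via the tabular additive-relationship
  recursion (founders non-inbred and unrelated; an unknown parent is a founder).
* ``f_roh`` — fraction of the autosomal genome covered by ROH
  (``sum of segment lengths / L_auto``), optionally split by length class.
* ``f_snp`` — three marker-based estimators: variance of additive genotypes
  (F_SNP1), homozygosity excess (F_SNP2), and correlation of uniting gametes
  (F_SNP3). Allele frequencies are cohort sample frequencies; monomorphic
  SNPs are excluded (their 2p(1-p) denominator is zero) and an individual's
  missing calls reduce that individual's SNP count.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io import MISSING, GenotypeMatrix, Pedigree
from .scan import ROHSegment, class_labels, class_of

log = logging.getLogger(__name__)

F_ROH_COLUMNS = ("F_ROH_1_5", "F_ROH_5_10", "F_ROH_gt10")


def f_ped(ped: Pedigree) -> pd.Series:
    """Per-individual pedigree inbreeding coefficient F = a(sire, dam) / 2."""
    order = ped.topological()
    idx = {ind: k for k, ind in enumerate(order)}
    n = len(order)
    A = np.zeros((n, n))
    for k, ind in enumerate(order):
        sire, dam = ped.parents_of(ind)
        si = idx[sire] if sire is not None else None
        di = idx[dam] if dam is not None else None
        for j in range(k):
            a = 0.0
            if si is not None:
                a += 0.5 * A[j, si]
            if di is not None:
                a += 0.5 * A[j, di]
            A[k, j] = A[j, k] = a
        A[k, k] = 1.0 + (0.5 * A[si, di] if si is not None and di is not None else 0.0)
    listed = [r[0] for r in ped.records]
    return pd.Series({ind: A[idx[ind], idx[ind]] - 1.0 for ind in listed}, name="F_PED")


def f_roh(segments: Sequence[ROHSegment], l_auto: int,
          bounds_mb: Sequence[float] = (1.0, 5.0, 10.0)) -> tuple[float, tuple[float, ...]]:
    """F_ROH for one individual's segments: total and per-length-class components.

    Components sum to the total exactly by construction. Overlapping segments
    indicate an upstream bug and raise.
    """
    if l_auto <= 0:
        raise ValueError("l_auto must be positive")
    by_chrom: dict[str, list[ROHSegment]] = {}
    for s in segments:
        by_chrom.setdefault(s.chrom, []).append(s)
    for segs in by_chrom.values():
        segs = sorted(segs, key=lambda x: x.start_bp)
        for a, b in zip(segs, segs[1:]):
            if b.start_bp <= a.end_bp:
                raise ValueError("overlapping ROH segments for one individual")
    comps = [0.0] * len(bounds_mb)
    for s in segments:
        k = class_of(s.length_bp, bounds_mb)
        if k < 0:
            raise ValueError("segment below first class bound")
        comps[k] += s.length_bp / l_auto
    return sum(comps), tuple(comps)


def f_roh_table(segments: Sequence[ROHSegment], samples: Sequence[str], l_auto: int,
                bounds_mb: Sequence[float] = (1.0, 5.0, 10.0)) -> pd.DataFrame:
    """Per-individual F_ROH components for a cohort (zero rows for ROH-free samples)."""
    by_sample: dict[str, list[ROHSegment]] = {s: [] for s in samples}
    for seg in segments:
        if seg.sample not in by_sample:
            raise ValueError(f"segment for unknown sample {seg.sample!r}")
        by_sample[seg.sample].append(seg)
    labels = [f"F_ROH_{lab.replace('-', '_').replace('>', 'gt').replace('.', '_')}"
              for lab in class_labels(bounds_mb)]
    rows = {}
    for s in samples:
        total, comps = f_roh(by_sample[s], l_auto, bounds_mb)
        rows[s] = dict(zip(labels, comps), F_ROH_all=total)
    return pd.DataFrame.from_dict(rows, orient="index")[labels + ["F_ROH_all"]]


def f_snp(g: GenotypeMatrix, estimator: int) -> pd.Series:
    """One of the three SNP-based inbreeding estimators (1, 2 or 3)."""
    if estimator not in (1, 2, 3):
        raise ValueError("estimator must be 1, 2 or 3")
    return f_snp_all(g)[f"F_SNP{estimator}"]


def f_snp_all(g: GenotypeMatrix) -> pd.DataFrame:
    """All three SNP-based estimators per individual.

    SNPs monomorphic in the cohort are excluded from the sums; individuals
    with no usable SNP get NaN (flagged with a warning).
    """
    p = g.allele_freq()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        usable = (p > 0) & (p < 1)
    n_mono = int(np.sum(~usable & ~np.isnan(p)))
    if n_mono:
        log.info("F_SNP: excluded %d monomorphic SNPs", n_mono)
    y = g.calls.astype(float)
    y[g.calls == MISSING] = np.nan
    y = y[:, usable]
    pu = p[usable]
    h = 2.0 * pu * (1.0 - pu)
    obs = ~np.isnan(y)
    n_used = obs.sum(axis=1).astype(float)
    y0 = np.where(obs, y, 0.0)

    def _row_mean(terms: np.ndarray) -> np.ndarray:
        s = np.where(obs, terms, 0.0).sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            return s / n_used

    f1 = _row_mean((y0 - 2 * pu) ** 2 / h) - 1.0
    f2 = 1.0 - _row_mean(y0 * (2 - y0) / h)
    f3 = _row_mean((y0 ** 2 - y0 * (1 + 2 * pu) + 2 * pu ** 2) / h)
    for f in (f1, f2, f3):
        f[n_used == 0] = np.nan
    if (n_used == 0).any():
        bad = [g.samples[i] for i in np.flatnonzero(n_used == 0)]
        warnings.warn(f"no usable SNPs for individuals {bad}; F_SNP undefined (NaN)")
    return pd.DataFrame({"F_SNP1": f1, "F_SNP2": f2, "F_SNP3": f3}, index=list(g.samples))


@dataclass
class DiversityStats:
    ho: float
    he: float
    ne: float | None = None
    n_males: int | None = None
    n_females: int | None = None


def diversity(g: GenotypeMatrix, n_males: int | None = None,
              n_females: int | None = None) -> DiversityStats:
    """Observed/expected heterozygosity (means over SNPs); Ne if sex counts given.

    Ho = mean fraction of heterozygotes among non-missing calls;
    He = mean of 2p(1-p) with cohort sample frequency p.
    """
    obs = g.calls != MISSING
    het = g.calls == 1
    with np.errstate(invalid="ignore", divide="ignore"):
        ho_snp = het.sum(axis=0) / obs.sum(axis=0)
    p = g.allele_freq()
    he_snp = 2.0 * p * (1.0 - p)
    ho = float(np.nanmean(ho_snp))
    he = float(np.nanmean(he_snp))
    ne_val = ne(n_males, n_females) if n_males is not None and n_females is not None else None
    return DiversityStats(ho=ho, he=he, ne=ne_val, n_males=n_males, n_females=n_females)


def ne(n_males: int, n_females: int, classical: bool = False) -> float:
    """Effective population size under equalised family sizes: 16NmNf/(Nm+Nf).

    ``classical=True`` computes the standard unequal-sex-ratio formula
    4NmNf/(Nm+Nf) for comparison.
    """
    if n_males < 1 or n_females < 1:
        raise ValueError("need at least one male and one female")
    k = 4.0 if classical else 16.0
    return k * n_males * n_females / (n_males + n_females)


def estimator_correlations(table: pd.DataFrame, bonferroni: bool = False
                           ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise Pearson r and two-sided p-values between estimator columns.

    Pairwise-complete observations; zero-variance columns give NaN with a
    warning. ``bonferroni=True`` multiplies p-values by the number of
    distinct pairs (clipped at 1).
    """
    cols = list(table.columns)
    r = pd.DataFrame(np.eye(len(cols)), index=cols, columns=cols)
    p = pd.DataFrame(np.zeros((len(cols), len(cols))), index=cols, columns=cols)
    n_pairs = len(cols) * (len(cols) - 1) // 2
    for i, a in enumerate(cols):
        for j in range(i):
            b = cols[j]
            sub = table[[a, b]].dropna()
            if len(sub) < 3 or sub[a].nunique() < 2 or sub[b].nunique() < 2:
                warnings.warn(f"correlation {a} vs {b} undefined "
                              "(fewer than 3 pairs or zero variance)")
                rv, pv = np.nan, np.nan
            else:
                rv, pv = stats.pearsonr(sub[a], sub[b])
                if bonferroni:
                    pv = min(1.0, pv * n_pairs)
            r.loc[a, b] = r.loc[b, a] = rv
            p.loc[a, b] = p.loc[b, a] = pv
    return r, p


def correlation_report(table: pd.DataFrame, alpha: float = 0.01,
                       bonferroni: bool = False) -> pd.DataFrame:
    """Lower-triangular text report; '**' marks p < alpha (0.01 by default)."""
    r, p = estimator_correlations(table, bonferroni=bonferroni)
    cols = list(table.columns)
    out = pd.DataFrame("", index=cols, columns=cols, dtype=object)
    for i, a in enumerate(cols):
        out.loc[a, a] = "1"
        for j in range(i):
            b = cols[j]
            rv, pv = r.loc[a, b], p.loc[a, b]
            if np.isnan(rv):
                out.loc[a, b] = "NA"
            else:
                out.loc[a, b] = f"{rv:.3f}" + ("**" if pv < alpha else "")
    return out


def inbreeding_table(g: GenotypeMatrix, segments: Sequence[ROHSegment],
                     pedigree: Pedigree | None = None,
                     l_auto: int | None = None,
                     bounds_mb: Sequence[float] = (1.0, 5.0, 10.0)) -> pd.DataFrame:
    """Per-individual table of all estimators (F_PED, F_ROH by class, F_SNP1-3)."""
    l_auto = l_auto if l_auto is not None else g.genome_length_bp
    tab = f_roh_table(segments, g.samples, l_auto, bounds_mb)
    tab = tab.join(f_snp_all(g))
    if pedigree is not None:
        tab.insert(0, "F_PED", f_ped(pedigree).reindex(tab.index))
    return tab


def summarize_estimators(table: pd.DataFrame) -> pd.DataFrame:
    """Mean/min/max/SD per estimator column (cohort descriptive statistics)."""
    return pd.DataFrame({
        "mean": table.mean(),
        "min": table.min(),
        "max": table.max(),
        "sd": table.std(ddof=1),
    })
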