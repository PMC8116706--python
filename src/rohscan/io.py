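"""Genotype, marker-map, pedigree and interval I/O plus cohort-level QC.

Internal conventions
--------------------
* Genotype codes: ``0`` hom-ref, ``1`` het, ``2`` hom-alt, ``-1`` missing
  (half-missing calls are treated as missing).
* Coordinates are 1-based inclusive throughout the package; BED files are
  converted from/to 0-based half-open at the I/O boundary.
* Only chromosomes in a declared ordered autosome list are kept (18 pig
  autosomes by default); everything else is skipped with a warning.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

MISSING = -1
PIG_AUTOSOMES: tuple[str, ...] = tuple(str(i) for i in range(1, 19))
DEFAULT_GENOME_BP = 2_260_000_000

_UNKNOWN_PARENT = {"0", "", ".", "na", "nan", "none", "unknown"}


def normalize_chrom(label: str) -> str:
    """Strip common chromosome prefixes ('chr', 'SSC') from a label."""
    s = str(label).strip()
    for prefix in ("chr", "CHR", "Chr", "SSC", "ssc"):
        if s.startswith(prefix):
            s = s[len(prefix):]
            break
    return s


class FormatError(ValueError):
    """Raised for malformed input files."""


@dataclass
class MarkerMap:
    """Ordered SNP map: one row per marker with columns snp_id, chrom, pos.

    Rows are sorted by (autosome order, position) on construction; positions
    must be strictly increasing within each chromosome and snp_ids unique.
    ``order`` records the permutation applied, so callers holding a genotype
    matrix aligned to the *input* row order can re-align columns.
    """

    table: pd.DataFrame
    autosomes: tuple[str, ...] = PIG_AUTOSOMES
    order: np.ndarray = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        required = {"snp_id", "chrom", "pos"}
        if not required.issubset(self.table.columns):
            raise FormatError(f"marker map needs columns {sorted(required)}")
        tbl = self.table.copy()
        tbl["chrom"] = tbl["chrom"].astype(str)
        tbl["pos"] = tbl["pos"].astype(np.int64)
        unknown = set(tbl["chrom"]) - set(self.autosomes)
        if unknown:
            raise FormatError(f"chromosome labels not in the declared autosome set: {sorted(unknown)}")
        if tbl["snp_id"].duplicated().any():
            dups = tbl.loc[tbl["snp_id"].duplicated(), "snp_id"].iloc[0]
            raise FormatError(f"duplicate snp_id: {dups!r}")
        if (tbl["pos"] < 1).any():
            raise FormatError("positions must be >= 1 (1-based)")
        rank = {c: i for i, c in enumerate(self.autosomes)}
        key = tbl["chrom"].map(rank).to_numpy() * np.int64(2**40) + tbl["pos"].to_numpy()
        order = np.argsort(key, kind="stable")
        if not np.array_equal(order, np.arange(len(tbl))):
            warnings.warn("marker map was not sorted; sorting by (chromosome, position)")
        tbl = tbl.iloc[order].reset_index(drop=True)
        for _, grp in tbl.groupby("chrom", sort=False):
            d = np.diff(grp["pos"].to_numpy())
            if (d <= 0).any():
                raise FormatError("duplicate position within a chromosome")
        object.__setattr__(self, "table", tbl)
        object.__setattr__(self, "order", order)

    @property
    def n_snps(self) -> int:
        return len(self.table)

    def chrom_slices(self) -> dict[str, slice]:
        """Contiguous row slice for each chromosome present, in map order."""
        out: dict[str, slice] = {}
        chroms = self.table["chrom"].to_numpy()
        if len(chroms) == 0:
            return out
        change = np.flatnonzero(chroms[1:] != chroms[:-1]) + 1
        starts = np.concatenate([[0], change])
        stops = np.concatenate([change, [len(chroms)]])
        for a, b in zip(starts, stops):
            out[chroms[a]] = slice(int(a), int(b))
        return out

    def positions(self, chrom: str) -> np.ndarray:
        sl = self.chrom_slices().get(str(chrom))
        if sl is None:
            return np.empty(0, dtype=np.int64)
        return self.table["pos"].to_numpy()[sl]

    def chrom_lengths(self) -> dict[str, int]:
        """Chromosome extent taken as the last mapped position."""
        return {c: int(self.table["pos"].to_numpy()[sl][-1]) for c, sl in self.chrom_slices().items()}


@dataclass
class GenotypeMatrix:
    """Cohort genotypes: samples x SNPs int8 matrix aligned with a MarkerMap."""

    samples: list[str]
    calls: np.ndarray
    markers: MarkerMap
    genome_length_bp: int = DEFAULT_GENOME_BP
    io_stats: dict = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.shape != (len(self.samples), self.markers.n_snps):
            raise ValueError(
                f"calls shape {self.calls.shape} != "
                f"({len(self.samples)} samples, {self.markers.n_snps} SNPs)"
            )
        bad = ~np.isin(self.calls, (0, 1, 2, MISSING))
        if bad.any():
            raise ValueError(f"invalid genotype codes present: {np.unique(self.calls[bad])}")
        if self.genome_length_bp <= 0:
            raise ValueError("genome_length_bp must be positive")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def allele_freq(self) -> np.ndarray:
        """Per-SNP alternate-allele frequency from non-missing calls (NaN if none)."""
        c = self.calls.astype(float)
        c[self.calls == MISSING] = np.nan
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            return np.nanmean(c, axis=0) / 2.0

    def call_rate(self) -> np.ndarray:
        return (self.calls != MISSING).mean(axis=0)

    def subset_snps(self, keep: np.ndarray) -> "GenotypeMatrix":
        mm = MarkerMap(self.markers.table.loc[np.asarray(keep)].reset_index(drop=True),
                       autosomes=self.markers.autosomes)
        return GenotypeMatrix(list(self.samples), self.calls[:, keep], mm, self.genome_length_bp)


@dataclass
class Pedigree:
    """Three-column pedigree (individual, sire, dam); None marks unknown parents.

    Parents referenced but never listed as individuals are treated as unknown
    founders. Construction fails on cycles.
    """

    records: list[tuple[str, str | None, str | None]]

    def __post_init__(self) -> None:
        ids = [r[0] for r in self.records]
        if len(set(ids)) != len(ids):
            raise FormatError("duplicate individual id in pedigree")
        self._parents = {r[0]: (r[1], r[2]) for r in self.records}
        self.topological()  # raises on cycles

    def topological(self) -> list[str]:
        """All ids (listed individuals + referenced parents), parents first."""
        known = set(self._parents)
        all_ids = set(known)
        for s, d in self._parents.values():
            all_ids.update(x for x in (s, d) if x is not None)
        parents = {i: tuple(x for x in self._parents.get(i, (None, None)) if x is not None)
                   for i in all_ids}
        indeg = {i: 0 for i in all_ids}
        children: dict[str, list[str]] = {i: [] for i in all_ids}
        for child, ps in parents.items():
            for p in ps:
                children[p].append(child)
                indeg[child] += 1
        queue = sorted(i for i in all_ids if indeg[i] == 0)
        out: list[str] = []
        while queue:
            i = queue.pop(0)
            out.append(i)
            for ch in sorted(children[i]):
                indeg[ch] -= 1
                if indeg[ch] == 0:
                    queue.append(ch)
        if len(out) != len(all_ids):
            raise FormatError("pedigree contains a cycle (an individual is its own ancestor)")
        return out

    def parents_of(self, ind: str) -> tuple[str | None, str | None]:
        return self._parents.get(ind, (None, None))


@dataclass
class AnnotationIntervals:
    """Named intervals (genes, QTL, ...) in 1-based inclusive coordinates."""

    table: pd.DataFrame  # chrom, start_bp, end_bp, name, category

    def __post_init__(self) -> None:
        required = {"chrom", "start_bp", "end_bp", "name", "category"}
        if not required.issubset(self.table.columns):
            raise FormatError(f"annotation table needs columns {sorted(required)}")
        t = self.table
        if (t["start_bp"] > t["end_bp"]).any():
            raise FormatError("interval with start_bp > end_bp")


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

def read_genotypes(path: str | Path, format_flag: str = "vcf", *,
                   autosomes: Sequence[str] = PIG_AUTOSOMES,
                   genome_length_bp: int = DEFAULT_GENOME_BP) -> GenotypeMatrix:
    """Read a genotype matrix from VCF ('vcf') or PLINK text PED/MAP ('plink_text').

    Multiallelic and non-SNP records are skipped with a logged count, as are
    records on chromosomes outside ``autosomes``. Phased and unphased
    heterozygotes are coded identically.
    """
    path = Path(path)
    if format_flag == "vcf":
        return _read_vcf(path, tuple(str(a) for a in autosomes), genome_length_bp)
    if format_flag == "plink_text":
        return _read_plink_text(path, tuple(str(a) for a in autosomes), genome_length_bp)
    raise ValueError(f"unknown format_flag {format_flag!r} (use 'vcf' or 'plink_text')")


def _read_vcf(path: Path, autosomes: tuple[str, ...], genome_length_bp: int) -> GenotypeMatrix:
    from cyvcf2 import VCF

    if not path.exists():
        raise FileNotFoundError(path)
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    ids: list[str] = []
    chroms: list[str] = []
    poss: list[int] = []
    cols: list[np.ndarray] = []
    skipped_non_snp = 0
    skipped_chrom = 0
    for var in vcf:
        if (not var.is_snp) or len(var.ALT) != 1:
            skipped_non_snp += 1
            continue
        chrom = normalize_chrom(var.CHROM)
        if chrom not in autosomes:
            skipped_chrom += 1
            warnings.warn(f"skipping record on unlisted chromosome {var.CHROM!r}")
            continue
        alleles = var.genotype.array()  # (n, ploidy+1); last col = phased flag
        a, b = alleles[:, 0].astype(np.int64), alleles[:, 1].astype(np.int64)
        g = (a + b).astype(np.int8)
        g[(a < 0) | (b < 0)] = MISSING
        ids.append(var.ID if var.ID not in (None, ".") else f"{chrom}:{var.POS}")
        chroms.append(chrom)
        poss.append(int(var.POS))
        cols.append(g)
    vcf.close()
    if skipped_non_snp or skipped_chrom:
        log.info("VCF read: skipped %d non-SNP/multiallelic and %d off-autosome records",
                 skipped_non_snp, skipped_chrom)
    mm = MarkerMap(pd.DataFrame({"snp_id": ids, "chrom": chroms, "pos": poss}),
                   autosomes=autosomes)
    calls = (np.column_stack(cols) if cols
             else np.empty((len(samples), 0), dtype=np.int8))[:, mm.order]
    g = GenotypeMatrix(samples, calls, mm, genome_length_bp)
    g.io_stats = {"skipped_non_snp": skipped_non_snp, "skipped_unknown_chrom": skipped_chrom}
    return g


def _read_plink_text(path: Path, autosomes: tuple[str, ...], genome_length_bp: int) -> GenotypeMatrix:
    """PED/MAP reader. ``path`` may be the file-set prefix or the .ped file."""
    prefix = path.with_suffix("") if path.suffix in (".ped", ".map") else path
    ped_path, map_path = prefix.with_suffix(".ped"), prefix.with_suffix(".map")
    for p in (ped_path, map_path):
        if not p.exists():
            raise FileNotFoundError(p)

    mp = pd.read_csv(map_path, sep=r"\s+", header=None,
                     names=["chrom", "snp_id", "cm", "pos"], dtype=str)
    mp["chrom"] = mp["chrom"].map(normalize_chrom)
    keep = mp["chrom"].isin(autosomes).to_numpy()
    skipped_chrom = int((~keep).sum())
    if skipped_chrom:
        warnings.warn(f"skipping {skipped_chrom} MAP records on unlisted chromosomes")

    samples: list[str] = []
    allele_rows: list[np.ndarray] = []
    n_snps_in = len(mp)
    with open(ped_path) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            if len(parts) != 6 + 2 * n_snps_in:
                raise FormatError(
                    f"PED line for {parts[1] if len(parts) > 1 else '?'} has "
                    f"{len(parts) - 6} allele fields, expected {2 * n_snps_in}")
            samples.append(parts[1])
            allele_rows.append(np.array(parts[6:], dtype=object))
    if allele_rows:
        alleles = np.stack(allele_rows)
        a1, a2 = alleles[:, 0::2], alleles[:, 1::2]
    else:
        a1 = a2 = np.empty((0, n_snps_in), dtype=object)

    calls = np.full((len(samples), n_snps_in), MISSING, dtype=np.int8)
    for j in range(n_snps_in):
        col1, col2 = a1[:, j], a2[:, j]
        present = (col1 != "0") & (col2 != "0")
        seen = sorted(set(col1[present]) | set(col2[present]))
        if len(seen) > 2:
            raise FormatError(f"more than two alleles at SNP index {j}")
        if not seen:
            continue
        # alphabetically first allele is coded as ref: deterministic, and
        # round-trips with write_plink_text's A/G coding
        ref = seen[0]
        calls[present, j] = ((col1[present] != ref).astype(np.int8)
                             + (col2[present] != ref).astype(np.int8))

    mm = MarkerMap(mp.loc[keep, ["snp_id", "chrom", "pos"]].reset_index(drop=True),
                   autosomes=autosomes)
    calls = calls[:, keep.nonzero()[0]][:, mm.order]
    g = GenotypeMatrix(samples, calls, mm, genome_length_bp)
    g.io_stats = {"skipped_non_snp": 0, "skipped_unknown_chrom": skipped_chrom}
    return g


def read_pedigree(path: str | Path) -> Pedigree:
    """Read a 3-column (individual, sire, dam) pedigree; whitespace or comma separated."""
    records: list[tuple[str, str | None, str | None]] = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.replace(",", " ").split()
            if len(parts) < 3:
                raise FormatError(f"{path}:{ln}: expected 3 columns, got {len(parts)}")
            ind, sire, dam = parts[:3]

            def _norm(x: str) -> str | None:
                return None if x.lower() in _UNKNOWN_PARENT else x

            records.append((ind, _norm(sire), _norm(dam)))
    return Pedigree(records)


def read_intervals(path: str | Path, category: str = "gene",
                   autosomes: Sequence[str] = PIG_AUTOSOMES) -> AnnotationIntervals:
    """Read BED4 (0-based half-open) into 1-based inclusive intervals."""
    rows = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            if len(parts) < 3:
                raise FormatError(f"{path}:{ln}: BED line has fewer than 3 columns")
            try:
                start0, end0 = int(parts[1]), int(parts[2])
            except ValueError as e:
                raise FormatError(f"{path}:{ln}: non-integer BED coordinates") from e
            if start0 >= end0:
                raise FormatError(f"{path}:{ln}: BED start must be < end")
            chrom = normalize_chrom(parts[0])
            if chrom not in autosomes:
                warnings.warn(f"{path}:{ln}: skipping interval on unlisted chromosome {parts[0]!r}")
                continue
            name = parts[3] if len(parts) > 3 else f"interval_{ln}"
            rows.append((chrom, start0 + 1, end0, name, category))
    return AnnotationIntervals(pd.DataFrame(
        rows, columns=["chrom", "start_bp", "end_bp", "name", "category"]))


# ---------------------------------------------------------------------------
# QC
# ---------------------------------------------------------------------------

def qc_filter(g: GenotypeMatrix, maf_min: float = 0.05,
              call_rate_min: float = 0.30) -> GenotypeMatrix:
    """Drop SNPs failing MAF or call-rate thresholds (defaults 0.05 and 0.30).

    MAF is computed on non-missing calls only. Removal counts per filter are
    stored in ``io_stats`` and logged. Raises if nothing survives.
    """
    if not (0 <= maf_min < 0.5):
        raise ValueError("maf_min must be in [0, 0.5)")
    if not (0 < call_rate_min <= 1):
        raise ValueError("call_rate_min must be in (0, 1]")
    p = g.allele_freq()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        maf = np.minimum(p, 1 - p)
    fail_maf = ~(maf >= maf_min)  # NaN (no calls) fails
    fail_cr = g.call_rate() < call_rate_min
    keep = ~(fail_maf | fail_cr)
    if not keep.any():
        stricter = "maf" if fail_maf.sum() >= fail_cr.sum() else "call_rate"
        raise ValueError(f"QC removed every SNP; the stricter filter was {stricter!r}")
    out = g.subset_snps(keep)
    out.io_stats = dict(g.io_stats)
    out.io_stats.update(removed_maf=int(fail_maf.sum()), removed_call_rate=int(fail_cr.sum()),
                        removed_total=int((~keep).sum()))
    log.info("QC: removed %d SNPs (MAF<%g: %d, call rate<%g: %d); %d retained",
             int((~keep).sum()), maf_min, int(fail_maf.sum()),
             call_rate_min, int(fail_cr.sum()), int(keep.sum()))
    return out


# ---------------------------------------------------------------------------
# writers (all round-trip with the readers above / in scan & islands modules)
# ---------------------------------------------------------------------------

def write_segments(segments: Iterable, path: str | Path) -> None:
    from .scan import segments_to_frame

    df = segments_to_frame(list(segments))
    df["length_kb"] = df["length_bp"] / 1000.0
    df[["sample", "chrom", "start_bp", "end_bp", "n_snps", "length_kb"]].to_csv(
        path, sep="\t", index=False)


def read_segments(path: str | Path) -> list:
    from .scan import ROHSegment

    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    return [ROHSegment(r.sample, str(r.chrom), int(r.start_bp), int(r.end_bp), int(r.n_snps))
            for r in df.itertuples()]


def write_inbreeding(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index=True, index_label="sample")


def read_inbreeding(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="sample")


def write_islands(islands: Iterable, path: str | Path) -> None:
    from .islands import islands_to_frame

    islands_to_frame(list(islands)).to_csv(path, sep="\t", index=False)


def read_islands(path: str | Path) -> list:
    from .islands import IslandRegion

    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    out = []
    for r in df.itertuples():
        ann = () if pd.isna(r.annotations) or r.annotations == "" \
            else tuple(str(r.annotations).split(","))
        out.append(IslandRegion(str(r.chrom), int(r.start_bp), int(r.end_bp),
                                int(r.n_snps), float(r.max_incidence), ann))
    return out


def write_intervals(ann: AnnotationIntervals, path: str | Path) -> None:
    """Write intervals back to BED4 (convert to 0-based half-open)."""
    t = ann.table
    with open(path, "w") as fh:
        for r in t.itertuples():
            fh.write(f"{r.chrom}\t{r.start_bp - 1}\t{r.end_bp}\t{r.name}\n")


def write_pedigree(ped: Pedigree, path: str | Path) -> None:
    with open(path, "w") as fh:
        for ind, sire, dam in ped.records:
            fh.write(f"{ind}\t{sire or '0'}\t{dam or '0'}\n")


def write_vcf(g: GenotypeMatrix, path: str | Path) -> None:
    """Write a minimal VCF 4.2 (GT only; synthetic REF=A, ALT=G)."""
    gt_str = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
    lengths = g.markers.chrom_lengths()
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for c in g.markers.autosomes:
            if c in lengths:
                fh.write(f"##contig=<ID={c},length={lengths[c]}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(g.samples) + "\n")
        tbl = g.markers.table
        chroms = tbl["chrom"].to_numpy()
        poss = tbl["pos"].to_numpy()
        sids = tbl["snp_id"].to_numpy()
        for j in range(g.markers.n_snps):
            gts = "\t".join(gt_str[int(x)] for x in g.calls[:, j])
            fh.write(f"{chroms[j]}\t{poss[j]}\t{sids[j]}\tA\tG\t.\tPASS\t.\tGT\t{gts}\n")


def write_plink_text(g: GenotypeMatrix, prefix: str | Path) -> None:
    """Write PLINK text PED/MAP (alleles A/G, missing '0 0')."""
    prefix = Path(prefix)
    tbl = g.markers.table
    with open(prefix.with_suffix(".map"), "w") as fh:
        for r in tbl.itertuples():
            fh.write(f"{r.chrom}\t{r.snp_id}\t0\t{r.pos}\n")
    pair = {0: "A A", 1: "A G", 2: "G G", MISSING: "0 0"}
    with open(prefix.with_suffix(".ped"), "w") as fh:
        for i, s in enumerate(g.samples):
            fields = [s, s, "0", "0", "0", "-9"]
            fields += [pair[int(x)] for x in g.calls[i]]
            fh.write(" ".join(fields) + "\n")
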