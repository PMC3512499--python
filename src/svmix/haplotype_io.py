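"""Phased haplotype panels, genetic maps, and SNP windowing.

A :class:`HaplotypePanel` holds phased haploid genomes as a matrix over
shared biallelic SNPs.  After major/minor encoding the matrix contains only
``+1`` (major allele in the reference panel) and ``-1`` (minor allele).
Genetic maps provide cumulative genetic positions (Morgans) by linear
interpolation of HapMap-format tables, or at a fixed recombination rate.
:func:`partition_windows` tiles each chromosome's SNP columns into windows
of ``w`` consecutive SNPs, recording the genetic distance between
consecutive windows (midpoint to midpoint) that parameterizes the HMM
smoother downstream.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "HaplotypePanel",
    "GeneticMap",
    "FixedRateMap",
    "WindowPartition",
    "Window",
    "read_phased_panel",
    "read_population_table",
    "encode_major_minor",
    "encode_panel",
    "read_genetic_map",
    "genetic_position",
    "fixed_rate_map",
    "partition_windows",
    "write_phased_vcf",
    "write_partition_bed",
    "write_genetic_map",
]


# ---------------------------------------------------------------------------
# Haplotype panels


@dataclass
class HaplotypePanel:
    """Phased haploid genomes over a shared set of biallelic SNPs.

    ``alleles`` is ``(n_haplotypes, n_snps)``; raw panels straight from a
    VCF hold REF/ALT indicators in ``{0, 1}``, encoded panels hold
    major/minor codes in ``{-1, +1}``.  ``labels`` (population index,
    1-based, dense over ``population_names``) is present for ancestral
    panels and absent for admixed query panels.
    """

    alleles: np.ndarray
    sample_ids: list[str]
    snp_ids: np.ndarray
    chrom: np.ndarray
    bp_pos: np.ndarray
    gen_pos: np.ndarray | None = None
    labels: np.ndarray | None = None
    population_names: list[str] | None = None
    encoded: bool = False
    # Polarity bookkeeping set by encode_panel: True where ALT is the major
    # allele.  Needed to serialize encoded panels back to REF/ALT space.
    alt_is_major: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.alleles = np.asarray(self.alleles, dtype=np.int8)
        self.snp_ids = np.asarray(self.snp_ids, dtype=object)
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.bp_pos = np.asarray(self.bp_pos, dtype=np.int64)
        if self.gen_pos is not None:
            self.gen_pos = np.asarray(self.gen_pos, dtype=float)
        if self.labels is not None:
            self.labels = np.asarray(self.labels, dtype=np.int64)
        self._validate()

    def _validate(self) -> None:
        if self.alleles.ndim != 2:
            raise ValueError("alleles must be 2-D (haplotypes x SNPs)")
        n_hap, n_snp = self.alleles.shape
        if len(self.sample_ids) != n_hap:
            raise ValueError("sample_ids length does not match allele rows")
        for arr, name in ((self.snp_ids, "snp_ids"), (self.chrom, "chrom"),
                          (self.bp_pos, "bp_pos")):
            if len(arr) != n_snp:
                raise ValueError(f"{name} length does not match allele columns")
        for c in self.chromosomes:
            pos = self.bp_pos[self.chrom == c]
            if np.any(np.diff(pos) <= 0):
                raise ValueError(f"bp_pos not strictly increasing on chromosome {c}")
        if self.labels is not None:
            if len(self.labels) != n_hap:
                raise ValueError("labels length does not match allele rows")
            k = self.n_populations
            if len(self.labels) and (self.labels.min() < 1
                                     or self.labels.max() > k):
                raise ValueError("labels must be dense 1..k'")

    @property
    def n_haplotypes(self) -> int:
        return self.alleles.shape[0]

    @property
    def n_snps(self) -> int:
        return self.alleles.shape[1]

    @property
    def n_populations(self) -> int:
        if self.population_names is None:
            return 0
        return len(self.population_names)

    @property
    def chromosomes(self) -> list:
        """Chromosomes in order of first appearance."""
        return list(pd.unique(self.chrom))

    def rows_for_population(self, name: str) -> np.ndarray:
        if self.labels is None or self.population_names is None:
            raise ValueError("panel has no population labels")
        try:
            idx = self.population_names.index(name) + 1
        except ValueError:
            raise KeyError(f"population {name!r} not in panel") from None
        return np.flatnonzero(self.labels == idx)

    def take_rows(self, rows: Sequence[int]) -> "HaplotypePanel":
        rows = np.asarray(rows, dtype=np.int64)
        return replace(
            self,
            alleles=self.alleles[rows],
            sample_ids=[self.sample_ids[i] for i in rows],
            labels=None if self.labels is None else self.labels[rows],
        )

    def take_columns(self, cols: Sequence[int]) -> "HaplotypePanel":
        cols = np.asarray(cols, dtype=np.int64)
        return replace(
            self,
            alleles=self.alleles[:, cols],
            snp_ids=self.snp_ids[cols],
            chrom=self.chrom[cols],
            bp_pos=self.bp_pos[cols],
            gen_pos=None if self.gen_pos is None else self.gen_pos[cols],
            alt_is_major=None if self.alt_is_major is None else self.alt_is_major[cols],
        )

    def annotate_genetic_positions(self, gmap: "GeneticMap") -> None:
        """Fill ``gen_pos`` (Morgans) from a genetic map, per column."""
        gp = np.empty(self.n_snps, dtype=float)
        for c in self.chromosomes:
            mask = self.chrom == c
            gp[mask] = gmap.positions(c, self.bp_pos[mask])
        self.gen_pos = gp


def read_population_table(path: str | Path) -> dict[str, str]:
    """Read a 2-column TSV mapping sample id to population name."""
    df = pd.read_csv(path, sep="\t", header=None, names=["sample", "population"],
                     dtype=str, comment="#")
    if df.empty:
        raise ValueError(f"empty population table: {path}")
    return dict(zip(df["sample"], df["population"]))


def read_phased_panel(vcf_path: str | Path,
                      pop_table_path: str | Path | None = None) -> HaplotypePanel:
    """Read a phased VCF into a raw (REF/ALT coded) haplotype panel.

    Each diploid sample contributes two haplotype rows (suffixes ``|0`` and
    ``|1``).  Only biallelic SNPs with fully phased, non-missing genotypes
    for all samples are accepted; multiallelic records are skipped with a
    logged count, an unphased or missing genotype is an error.  When a
    population table is given, every sample must appear in it; population
    names are mapped to dense indices 1..k' in lexicographic order.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(vcf_path))
    samples = list(vcf.samples)
    if not samples:
        raise ValueError(f"VCF {vcf_path} contains no samples")

    pop_of: dict[str, str] | None = None
    if pop_table_path is not None:
        pop_of = read_population_table(pop_table_path)
        missing = [s for s in samples if s not in pop_of]
        if missing:
            raise ValueError(
                f"samples missing from population table: {', '.join(missing)}")

    cols_alleles: list[np.ndarray] = []
    snp_ids, chroms, positions = [], [], []
    n_multi = 0
    for var in vcf:
        if len(var.ALT) != 1:
            n_multi += 1
            continue
        gts = var.genotypes  # [a0, a1, phased] per sample
        col = np.empty(2 * len(samples), dtype=np.int8)
        for i, (a0, a1, phased) in enumerate(gts):
            if a0 < 0 or a1 < 0:
                raise ValueError(
                    f"missing genotype for sample {samples[i]} at "
                    f"{var.CHROM}:{var.POS}")
            if not phased:
                raise ValueError(
                    f"unphased genotype for sample {samples[i]} at "
                    f"{var.CHROM}:{var.POS}")
            col[2 * i] = a0
            col[2 * i + 1] = a1
        cols_alleles.append(col)
        snp_ids.append(var.ID if var.ID not in (None, ".") else
                       f"{var.CHROM}:{var.POS}")
        chroms.append(var.CHROM)
        positions.append(var.POS)
    if n_multi:
        logger.info("skipped %d multiallelic sites in %s", n_multi, vcf_path)
    if not cols_alleles:
        raise ValueError(f"no usable biallelic SNPs in {vcf_path}")

    alleles = np.stack(cols_alleles, axis=1)
    hap_ids = [f"{s}|{h}" for s in samples for h in (0, 1)]

    labels = None
    pop_names: list[str] | None = None
    if pop_of is not None:
        pop_names = sorted(set(pop_of[s] for s in samples))
        index_of = {name: i + 1 for i, name in enumerate(pop_names)}
        labels = np.array([index_of[pop_of[s]] for s in samples
                           for _ in (0, 1)], dtype=np.int64)

    return HaplotypePanel(
        alleles=alleles, sample_ids=hap_ids, snp_ids=np.array(snp_ids, dtype=object),
        chrom=np.array(chroms, dtype=object), bp_pos=np.array(positions),
        labels=labels, population_names=pop_names,
    )


def encode_major_minor(raw_alleles: np.ndarray,
                       reference_rows: np.ndarray) -> np.ndarray:
    """Encode REF/ALT indicators as major (+1) / minor (-1) codes.

    Major/minor status is defined per column by allele frequency among
    ``reference_rows`` (the ancestral panel); the encoding is then applied
    to every row so queries share the ancestral polarity.  A frequency tie
    at exactly 0.5, and columns monomorphic for REF, declare REF major.
    """
    raw = np.asarray(raw_alleles)
    ref_rows = np.asarray(reference_rows)
    if ref_rows.dtype == bool:
        ref = raw[ref_rows]
    else:
        ref = raw[np.asarray(ref_rows, dtype=np.int64)]
    if ref.shape[0] == 0:
        raise ValueError("reference_rows selects no haplotypes")
    alt_freq = ref.mean(axis=0)
    alt_major = alt_freq > 0.5  # tie -> REF is major
    encoded = np.where(raw == 1, 1, -1).astype(np.int8)
    encoded[:, ~alt_major] *= -1
    return encoded


def encode_panel(panel: HaplotypePanel,
                 reference_rows: np.ndarray | None = None) -> HaplotypePanel:
    """Return a copy of ``panel`` with alleles in major/minor (+1/-1) code."""
    if panel.encoded:
        return panel
    if reference_rows is None:
        reference_rows = np.ones(panel.n_haplotypes, dtype=bool)
    ref_rows = np.asarray(reference_rows)
    if ref_rows.dtype == bool:
        ref = panel.alleles[ref_rows]
    else:
        ref = panel.alleles[np.asarray(ref_rows, dtype=np.int64)]
    alt_major = ref.mean(axis=0) > 0.5
    return replace(
        panel,
        alleles=encode_major_minor(panel.alleles, reference_rows),
        encoded=True,
        alt_is_major=alt_major,
    )


# ---------------------------------------------------------------------------
# Genetic maps


class GeneticMap:
    """Cumulative genetic positions per chromosome, linearly interpolated.

    Stores, per chromosome, ordered knots of (bp position, cumulative cM).
    Queries outside the mapped range use constant extrapolation (the first
    or last knot's value).  Positions are returned in Morgans.
    """

    def __init__(self, tables: dict[str, tuple[np.ndarray, np.ndarray]]):
        self._tables: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        for chrom, (bp, cm) in tables.items():
            bp = np.asarray(bp, dtype=np.int64)
            cm = np.asarray(cm, dtype=float)
            if bp.size == 0:
                raise ValueError(f"no map entries for chromosome {chrom}")
            if np.any(np.diff(bp) <= 0):
                raise ValueError(f"map bp positions not strictly increasing on {chrom}")
            if np.any(np.diff(cm) < 0):
                raise ValueError(f"cumulative cM decreases on chromosome {chrom}")
            self._tables[str(chrom)] = (bp, cm)

    @property
    def chromosomes(self) -> list[str]:
        return list(self._tables)

    def positions(self, chrom, bp) -> np.ndarray:
        """Genetic position(s) in Morgans for physical position(s) on chrom."""
        key = str(chrom)
        if key not in self._tables:
            raise KeyError(f"chromosome {chrom} absent from genetic map")
        knots_bp, knots_cm = self._tables[key]
        # np.interp clamps to end values: constant extrapolation as required
        return np.interp(np.asarray(bp, dtype=float), knots_bp, knots_cm) / 100.0

    def position(self, chrom, bp) -> float:
        return float(self.positions(chrom, np.array([bp]))[0])


class FixedRateMap(GeneticMap):
    """Uniform-recombination map: ``bp * rate_cM_per_Mb`` cM everywhere."""

    def __init__(self, rate_cM_per_Mb: float):
        if rate_cM_per_Mb <= 0:
            raise ValueError("recombination rate must be positive")
        self.rate = float(rate_cM_per_Mb)
        self._tables = {}

    @property
    def chromosomes(self) -> list[str]:
        return []

    def positions(self, chrom, bp) -> np.ndarray:
        return np.asarray(bp, dtype=float) * self.rate * 1e-8


def fixed_rate_map(rate_cM_per_Mb: float) -> FixedRateMap:
    """Genetic-map provider at a single genome-wide recombination rate."""
    return FixedRateMap(rate_cM_per_Mb)


def read_genetic_map(path: str | Path) -> GeneticMap:
    """Parse a HapMap-format genetic map (header + 4 whitespace columns).

    Columns: chromosome, physical position (bp), local rate (cM/Mb, unused),
    cumulative map position (cM).
    """
    tables: dict[str, tuple[list, list]] = {}
    with open(path) as fh:
        lines = fh.read().splitlines()
    if not lines:
        raise ValueError(f"no map entries in {path}")
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        parts = line.split()
        if len(parts) < 4:
            raise ValueError(f"{path}:{lineno}: expected 4 columns")
        chrom, bp, _rate, cm = parts[0], int(parts[1]), parts[2], float(parts[3])
        tab = tables.setdefault(chrom, ([], []))
        if tab[0] and bp <= tab[0][-1]:
            raise ValueError(f"{path}:{lineno}: bp position not increasing")
        if tab[1] and cm < tab[1][-1]:
            raise ValueError(f"{path}:{lineno}: cumulative cM decreases")
        tab[0].append(bp)
        tab[1].append(cm)
    if not tables:
        raise ValueError(f"no map entries in {path}")
    return GeneticMap({c: (np.array(b), np.array(m)) for c, (b, m) in tables.items()})


def genetic_position(gmap: GeneticMap, chrom, bp) -> float:
    """Genetic position in Morgans of ``bp`` on ``chrom`` under ``gmap``."""
    return gmap.position(chrom, bp)


# ---------------------------------------------------------------------------
# Windowing


@dataclass(frozen=True)
class Window:
    chrom: str
    start: int  # global column index, inclusive
    end: int    # global column index, exclusive

    @property
    def n_snps(self) -> int:
        return self.end - self.start

    @property
    def mid(self) -> int:
        return (self.start + self.end - 1) // 2


@dataclass
class WindowPartition:
    """Tiling of a panel's SNP columns into windows of ``w`` SNPs.

    ``gaps[j]`` is the genetic distance (Morgans) between window ``j`` and
    window ``j+1`` when both lie on the same chromosome, else ``None``
    (chains restart across chromosomes).
    """

    w: int
    windows: list[Window]
    gaps: list[float | None] = field(default_factory=list)

    @property
    def n_windows(self) -> int:
        return len(self.windows)

    def column_of_window(self) -> np.ndarray:
        """Map each SNP column to its window index."""
        total = self.windows[-1].end if self.windows else 0
        out = np.empty(total, dtype=np.int64)
        for j, win in enumerate(self.windows):
            out[win.start:win.end] = j
        return out

    def chromosome_chains(self) -> list[list[int]]:
        """Consecutive window-index runs sharing a chromosome."""
        chains: list[list[int]] = []
        for j, win in enumerate(self.windows):
            if chains and self.windows[chains[-1][-1]].chrom == win.chrom:
                chains[-1].append(j)
            else:
                chains.append([j])
        return chains


def partition_windows(panel: HaplotypePanel, w: int) -> WindowPartition:
    """Tile each chromosome's columns into windows of ``w`` SNPs.

    Each chromosome with ``n`` SNPs yields ``floor(n/w)`` windows, the last
    absorbing the remainder; a chromosome with fewer than ``w`` SNPs forms a
    single short window (logged).  Gap distances between consecutive windows
    on a chromosome are measured between window midpoint SNPs in ``gen_pos``.
    """
    if w < 1:
        raise ValueError("window size w must be >= 1")
    if panel.n_snps == 0:
        raise ValueError("panel has no SNPs")
    if panel.gen_pos is None:
        raise ValueError("panel lacks genetic positions; annotate from a map first")

    windows: list[Window] = []
    offset = 0
    for c in panel.chromosomes:
        n_c = int(np.sum(panel.chrom == c))
        if n_c < w:
            logger.warning("chromosome %s has %d SNPs < window size %d; "
                           "using one short window", c, n_c, w)
            windows.append(Window(str(c), offset, offset + n_c))
        else:
            n_win = n_c // w
            for j in range(n_win):
                start = offset + j * w
                end = offset + (j + 1) * w if j < n_win - 1 else offset + n_c
                windows.append(Window(str(c), start, end))
        offset += n_c

    gaps: list[float | None] = []
    for a, b in zip(windows[:-1], windows[1:]):
        if a.chrom != b.chrom:
            gaps.append(None)
        else:
            d = float(panel.gen_pos[b.mid] - panel.gen_pos[a.mid])
            gaps.append(max(d, 0.0))
    return WindowPartition(w=w, windows=windows, gaps=gaps)


# ---------------------------------------------------------------------------
# Serialization


def write_phased_vcf(panel: HaplotypePanel, path: str | Path,
                     ref_allele: str = "A", alt_allele: str = "T") -> None:
    """Write a panel as an uncompressed phased VCF.

    Haplotype rows are paired in order into diploid samples.  For encoded
    panels the recorded ``alt_is_major`` polarity restores REF/ALT codes, so
    a write/read/encode round trip is exact.
    """
    if panel.n_haplotypes % 2 != 0:
        raise ValueError("panel must contain an even number of haplotypes")
    if panel.encoded:
        if panel.alt_is_major is None:
            raise ValueError("encoded panel lacks polarity information")
        # +1 = major; column polarity says whether major is ALT
        raw = (panel.alleles == 1).astype(np.int8)
        raw[:, ~panel.alt_is_major] = 1 - raw[:, ~panel.alt_is_major]
    else:
        raw = panel.alleles

    sample_names = [sid.rsplit("|", 1)[0] for sid in panel.sample_ids[::2]]
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for c in panel.chromosomes:
            end = int(panel.bp_pos[panel.chrom == c].max())
            fh.write(f"##contig=<ID={c},length={end + 1}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(sample_names) + "\n")
        for j in range(panel.n_snps):
            gts = "\t".join(
                f"{raw[2 * i, j]}|{raw[2 * i + 1, j]}"
                for i in range(len(sample_names)))
            fh.write(f"{panel.chrom[j]}\t{panel.bp_pos[j]}\t{panel.snp_ids[j]}\t"
                     f"{ref_allele}\t{alt_allele}\t.\tPASS\t.\tGT\t{gts}\n")


def write_genetic_map(gmap: GeneticMap, path: str | Path) -> None:
    """Write a knot-based genetic map back to HapMap text format."""
    if not gmap.chromosomes:
        raise ValueError("map has no explicit knots to serialize")
    with open(path, "w") as fh:
        fh.write("chr\tposition\trate(cM/Mb)\tmap(cM)\n")
        for chrom in gmap.chromosomes:
            bp, cm = gmap._tables[chrom]
            for i in range(len(bp)):
                if i < len(bp) - 1:
                    rate = (cm[i + 1] - cm[i]) / (bp[i + 1] - bp[i]) * 1e6
                else:
                    rate = 0.0
                fh.write(f"{chrom}\t{bp[i]}\t{rate:.6f}\t{cm[i]:.6f}\n")


def write_partition_bed(partition: WindowPartition, panel: HaplotypePanel,
                        path: str | Path) -> None:
    """Serialize a window partition as BED-like TSV."""
    rows = []
    for j, win in enumerate(partition.windows):
        d = partition.gaps[j] if j < len(partition.gaps) else None
        rows.append({
            "chrom": win.chrom,
            "start_bp": int(panel.bp_pos[win.start]),
            "end_bp": int(panel.bp_pos[win.end - 1]),
            "window_index": j,
            "n_snps": win.n_snps,
            "d_to_next_morgans": "" if d is None else f"{d:.8g}",
        })
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
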