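"""In-silico admixture and synthetic ancestral panels.

Admixed haploid genomes are generated by "mating" one donor haplotype per
ancestral population: recombination breakpoints fall as a homogeneous
Poisson process of rate ``g`` per Morgan (so run lengths between
breakpoints follow the CDF ``1 - exp(-g d)``), the initial origin is drawn
from the mixing proportions ``alpha``, and at every breakpoint the origin
is independently redrawn from ``alpha``.  Redraws may land on the current
origin; such self-transitions are merged when reporting ground-truth
tracts, since the origin population is what is scored.

Ancestral panels themselves can be generated under the Balding-Nichols
model at a target divergence F, so the full train/classify/smooth pipeline
is testable without any external genotype data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .haplotype_io import GeneticMap, HaplotypePanel, encode_panel

__all__ = [
    "AdmixtureSpec",
    "Tract",
    "TractSet",
    "SyntheticPanelSpec",
    "sample_breakpoints",
    "simulate_admixed_haplotype",
    "simulate_admixed_population",
    "generate_synthetic_panels",
    "generate_panels_with_relatives",
]


@dataclass
class AdmixtureSpec:
    """Parameters of one simulated admixed population."""

    population_ids: list[str]
    alpha: tuple[float, ...]
    g: float
    n_offspring: int = 4
    seed: int = 0

    def __post_init__(self) -> None:
        self.alpha = tuple(float(a) for a in self.alpha)
        if len(self.alpha) != len(self.population_ids):
            raise ValueError("alpha must have one entry per population")
        if any(a <= 0 for a in self.alpha):
            raise ValueError("all mixing proportions must be positive")
        if abs(sum(self.alpha) - 1.0) > 1e-12:
            raise ValueError("mixing proportions must sum to 1")
        if self.g <= 0:
            raise ValueError("generations g must be positive")
        if self.n_offspring < 1:
            raise ValueError("n_offspring must be at least 1")


@dataclass(frozen=True)
class Tract:
    chrom: str
    start_col: int  # inclusive
    end_col: int    # exclusive
    origin: int     # 1-based population index of the source panel


@dataclass
class TractSet:
    """Ground-truth ancestry segments of one simulated haplotype."""

    haplotype_id: str
    tracts: list[Tract] = field(default_factory=list)

    def column_origins(self, n_snps: int) -> np.ndarray:
        """Per-SNP-column true origin (1-based)."""
        out = np.zeros(n_snps, dtype=np.int64)
        for t in self.tracts:
            out[t.start_col:t.end_col] = t.origin
        if np.any(out == 0):
            raise ValueError("tracts do not tile all SNP columns")
        return out


def sample_breakpoints(length_morgans: float, g: float,
                       rng: np.random.Generator | int) -> np.ndarray:
    """Breakpoint positions of a rate-``g`` Poisson process on (0, length).

    Inter-breakpoint distances are Exponential(mean 1/g Morgans), so run
    lengths have CDF ``1 - exp(-g d)``.
    """
    if g <= 0:
        raise ValueError("generations g must be positive")
    if length_morgans < 0:
        raise ValueError("length must be non-negative")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    points = []
    pos = 0.0
    while True:
        pos += rng.exponential(1.0 / g)
        if pos >= length_morgans:
            break
        points.append(pos)
    return np.asarray(points, dtype=float)


def _merge_runs(origins: np.ndarray, chrom: str, col_offset: int,
                pop_index_of: np.ndarray) -> list[Tract]:
    """Merge consecutive equal origins into tracts (column space)."""
    tracts: list[Tract] = []
    start = 0
    for i in range(1, len(origins) + 1):
        if i == len(origins) or origins[i] != origins[start]:
            tracts.append(Tract(chrom, col_offset + start, col_offset + i,
                                int(pop_index_of[origins[start]])))
            start = i
    return tracts


def simulate_admixed_haplotype(donor_haps: np.ndarray, alpha: tuple[float, ...],
                               g: float, gen_pos: np.ndarray,
                               chrom: np.ndarray,
                               rng: np.random.Generator,
                               pop_index_of: np.ndarray | None = None,
                               haplotype_id: str = "sim") -> tuple[np.ndarray, TractSet]:
    """Mosaic one haplotype from one donor per population.

    ``donor_haps`` is ``(n_populations, n_snps)``; ``pop_index_of`` maps the
    donor row to the 1-based population index recorded in the ground truth
    (defaults to ``row + 1``).  Chromosomes are simulated independently:
    each starts with a fresh draw from ``alpha``.
    """
    donor_haps = np.asarray(donor_haps)
    n_pops, n_snps = donor_haps.shape
    if len(gen_pos) != n_snps or len(chrom) != n_snps:
        raise ValueError("map does not cover all donor columns")
    if pop_index_of is None:
        pop_index_of = np.arange(1, n_pops + 1)
    alpha_arr = np.asarray(alpha, dtype=float)

    hap = np.empty(n_snps, dtype=donor_haps.dtype)
    tracts: list[Tract] = []
    offset = 0
    import pandas as pd
    for c in pd.unique(np.asarray(chrom, dtype=object)):
        mask = np.asarray(chrom, dtype=object) == c
        gp = np.asarray(gen_pos, dtype=float)[mask]
        n_c = len(gp)
        local = gp - gp[0]
        breaks = sample_breakpoints(local[-1], g, rng) if n_c > 1 else np.array([])
        # segment index of each SNP; draws: initial origin + one per breakpoint
        seg = np.searchsorted(breaks, local, side="right")
        draws = rng.choice(n_pops, size=len(breaks) + 1, p=alpha_arr)
        origins = draws[seg]
        hap[offset:offset + n_c] = donor_haps[origins, np.flatnonzero(mask)]
        tracts.extend(_merge_runs(origins, str(c), offset, pop_index_of))
        offset += n_c
    return hap, TractSet(haplotype_id=haplotype_id, tracts=tracts)


def simulate_admixed_population(panel: HaplotypePanel, spec: AdmixtureSpec
                                ) -> tuple[HaplotypePanel, list[TractSet],
                                           HaplotypePanel]:
    """Simulate an admixed sample and return it with truth and clean panel.

    For each offspring one donor haplotype is sampled (without replacement)
    from every mixed population and the donors are paired by sampling
    index.  All used donors are removed from the returned ancestral panel
    so training never sees a simulated haplotype's source.
    """
    if panel.gen_pos is None:
        raise ValueError("panel lacks genetic positions")
    rng = np.random.default_rng(spec.seed)
    donor_rows = {}
    for name in spec.population_ids:
        rows = panel.rows_for_population(name)
        if len(rows) < spec.n_offspring:
            raise ValueError(
                f"population {name!r} has {len(rows)} haplotypes; "
                f"{spec.n_offspring} donors required")
        donor_rows[name] = rng.choice(rows, size=spec.n_offspring, replace=False)

    pop_index_of = np.array(
        [panel.population_names.index(name) + 1 for name in spec.population_ids])

    haps, truths = [], []
    for i in range(spec.n_offspring):
        donors = np.stack([panel.alleles[donor_rows[name][i]]
                           for name in spec.population_ids])
        hid = f"adm{i // 2}|{i % 2}"
        hap, tracts = simulate_admixed_haplotype(
            donors, spec.alpha, spec.g, panel.gen_pos, panel.chrom, rng,
            pop_index_of=pop_index_of, haplotype_id=hid)
        haps.append(hap)
        truths.append(tracts)

    admixed = HaplotypePanel(
        alleles=np.stack(haps),
        sample_ids=[t.haplotype_id for t in truths],
        snp_ids=panel.snp_ids, chrom=panel.chrom, bp_pos=panel.bp_pos,
        gen_pos=panel.gen_pos, encoded=panel.encoded,
        alt_is_major=panel.alt_is_major,
    )
    used = np.concatenate(list(donor_rows.values()))
    keep = np.setdiff1d(np.arange(panel.n_haplotypes), used)
    reduced = panel.take_rows(keep)
    return admixed, truths, reduced


def write_tracts_bed(truths: list[TractSet], panel: HaplotypePanel,
                     path) -> None:
    """Write ground-truth tracts as BED-like TSV (bp coordinates)."""
    import pandas as pd

    names = panel.population_names
    rows = []
    for ts in truths:
        for t in ts.tracts:
            rows.append({
                "chrom": t.chrom,
                "start_bp": int(panel.bp_pos[t.start_col]),
                "end_bp": int(panel.bp_pos[t.end_col - 1]),
                "haplotype_id": ts.haplotype_id,
                "origin_population": names[t.origin - 1] if names else str(t.origin),
            })
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Synthetic ancestral panels (Balding-Nichols)


@dataclass
class SyntheticPanelSpec:
    """Balding-Nichols panel: populations diverged at target F."""

    n_pops: int = 2
    haplotypes_per_pop: int = 50
    n_snps: int = 5000
    fst_target: float = 0.15
    chrom_length_morgans: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.fst_target < 1.0):
            raise ValueError("fst_target must lie in (0, 1)")
        if min(self.n_pops, self.haplotypes_per_pop, self.n_snps) < 1:
            raise ValueError("all counts must be at least 1")
        if self.chrom_length_morgans <= 0:
            raise ValueError("chromosome length must be positive")


def _bn_frequencies(ancestral_freq: np.ndarray, fst: float, n_pops: int,
                    rng: np.random.Generator) -> np.ndarray:
    """Per-population allele frequencies under Balding-Nichols drift."""
    q = np.clip(ancestral_freq, 1e-3, 1 - 1e-3)
    shape_a = q * (1.0 - fst) / fst
    shape_b = (1.0 - q) * (1.0 - fst) / fst
    return rng.beta(shape_a, shape_b, size=(n_pops, len(q)))


def _assemble_panel(freqs: np.ndarray, pop_names: list[str],
                    haps_per_pop: int, chrom_length_morgans: float,
                    rng: np.random.Generator
                    ) -> tuple[HaplotypePanel, GeneticMap]:
    n_pops, n_snps = freqs.shape
    order = np.argsort(pop_names)  # dense labels in lexicographic name order
    names_sorted = [pop_names[i] for i in order]
    alleles = np.concatenate([
        (rng.random((haps_per_pop, n_snps)) < freqs[i]).astype(np.int8)
        for i in order])
    labels = np.repeat(np.arange(1, n_pops + 1), haps_per_pop)
    sample_ids = [f"{names_sorted[(i // haps_per_pop)]}_s{(i % haps_per_pop) // 2}"
                  f"|{i % 2}" for i in range(n_pops * haps_per_pop)]
    bp = 1 + np.arange(n_snps, dtype=np.int64) * 1000
    total_cm = chrom_length_morgans * 100.0
    gmap = GeneticMap({"1": (np.array([bp[0], bp[-1]]),
                             np.array([0.0, total_cm]))})
    panel = HaplotypePanel(
        alleles=alleles, sample_ids=sample_ids,
        snp_ids=np.array([f"snp{j}" for j in range(n_snps)], dtype=object),
        chrom=np.array(["1"] * n_snps, dtype=object), bp_pos=bp,
        labels=labels, population_names=names_sorted,
    )
    panel.annotate_genetic_positions(gmap)
    return encode_panel(panel), gmap


def generate_synthetic_panels(spec: SyntheticPanelSpec
                              ) -> tuple[HaplotypePanel, GeneticMap]:
    """Generate a labelled ancestral panel plus its (uniform) genetic map.

    Ancestral allele frequencies are Uniform(0.05, 0.95) per SNP
    (mirroring a 5% MAF filter); each population's frequency drifts from
    the ancestral one under a Beta distribution parameterized by the
    target F.  SNPs are evenly spaced on a single chromosome whose total
    genetic length is ``chrom_length_morgans``.
    """
    rng = np.random.default_rng(spec.seed)
    q = rng.uniform(0.05, 0.95, size=spec.n_snps)
    freqs = _bn_frequencies(q, spec.fst_target, spec.n_pops, rng)
    names = [f"POP{i + 1:02d}" for i in range(spec.n_pops)]
    return _assemble_panel(freqs, names, spec.haplotypes_per_pop,
                           spec.chrom_length_morgans, rng)


def generate_panels_with_relatives(spec: SyntheticPanelSpec,
                                   relatives_per_pop: int,
                                   relative_fst: float,
                                   n_unrelated: int = 0
                                   ) -> tuple[HaplotypePanel, GeneticMap,
                                              dict[str, str]]:
    """Ancestor populations plus close relatives, with a grouping map.

    Each of the ``spec.n_pops`` ancestor populations additionally spawns
    ``relatives_per_pop`` populations diverged from it at ``relative_fst``
    (a second round of Balding-Nichols drift); ``n_unrelated`` extra
    decoy populations drift independently from the ancestral frequencies
    at ``spec.fst_target``.  The returned group map assigns an ancestor
    and its relatives to one group (unrelated decoys get singleton
    groups), for group-collapsed accuracy scoring.
    """
    if not (0.0 < relative_fst < 1.0):
        raise ValueError("relative_fst must lie in (0, 1)")
    rng = np.random.default_rng(spec.seed)
    q = rng.uniform(0.05, 0.95, size=spec.n_snps)
    anc_freqs = _bn_frequencies(q, spec.fst_target, spec.n_pops, rng)
    freqs, names, groups = [], [], {}
    for i in range(spec.n_pops):
        anc_name, group = f"POP{i + 1:02d}", f"G{i + 1:02d}"
        freqs.append(anc_freqs[i])
        names.append(anc_name)
        groups[anc_name] = group
        if relatives_per_pop:
            rel = _bn_frequencies(anc_freqs[i], relative_fst,
                                  relatives_per_pop, rng)
            for r in range(relatives_per_pop):
                rel_name = f"POP{i + 1:02d}r{r + 1}"
                freqs.append(rel[r])
                names.append(rel_name)
                groups[rel_name] = group
    if n_unrelated:
        dec = _bn_frequencies(q, spec.fst_target, n_unrelated, rng)
        for u in range(n_unrelated):
            name = f"OUT{u + 1:02d}"
            freqs.append(dec[u])
            names.append(name)
            groups[name] = f"GX{u + 1:02d}"
    panel, gmap = _assemble_panel(np.stack(freqs), names,
                                  spec.haplotypes_per_pop,
                                  spec.chrom_length_morgans, rng)
    return panel, gmap, groups
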