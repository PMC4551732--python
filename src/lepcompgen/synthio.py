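"""Synthetic-data generators with known ground truth.

Every downstream stage of the pipeline is exercised on data produced here, so
each generator records the truth needed to score recovery:

* :func:`simulate_diploid` — a diploid genome whose per-block SNP rate is
  drawn from a two-component Gaussian mixture, plus SNP-free
  identity-by-descent blocks;
* :func:`simulate_reads` — uniform-coverage error-free reads alternating
  between the two haplotypes;
* :func:`simulate_split_assembly` — an assembly in which highly heterozygous
  blocks appear twice: once embedded in a long scaffold and once as a
  standalone half-coverage haplotig;
* :func:`simulate_gene_orders` — gene orders evolved along a known species
  tree by segmental inversions, translocations and duplications;
* :func:`simulate_sub_profiles` — per-protein substitution counts with a
  planted enriched subset and disordered regions.

All generators are deterministic given their seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import numpy as np

from lepcompgen.io import ScaffoldRecord, revcomp

__all__ = [
    "DiploidTruth",
    "GeneOrderTruth",
    "SubProfileTruth",
    "GenePlacement",
    "SplitAssembly",
    "simulate_diploid",
    "simulate_reads",
    "simulate_split_assembly",
    "simulate_gene_orders",
    "simulate_sub_profiles",
]

_BASES = np.frombuffer(b"ACGT", dtype="S1")


def _random_dna(rng: np.random.Generator, length: int) -> np.ndarray:
    return _BASES[rng.integers(0, 4, size=length)]


@dataclass
class DiploidTruth:
    """Two haplotypes plus the block structure that generated their SNPs."""

    hap1: str
    hap2: str
    snp_positions: set[int]
    #: (start, end, rate_class) with rate_class in {"free", "low", "high"}
    block_table: list[tuple[int, int, str]]
    #: per-block realized per-site SNP probability (0.0 for free blocks)
    block_rates: list[float] = field(default_factory=list)

    @property
    def length(self) -> int:
        return len(self.hap1)


def simulate_diploid(
    length_bp: int,
    mix_weights: tuple[float, ...] = (0.5, 0.5),
    mix_means: tuple[float, ...] = (0.0035, 0.025),
    mix_sds: tuple[float, ...] = (0.001, 0.004),
    free_fraction: float = 0.1,
    block_len_mean: int = 5000,
    seed: int = 0,
) -> DiploidTruth:
    """Simulate a diploid genome with block-structured heterozygosity.

    The genome is tiled by blocks of geometric length (mean ``block_len_mean``).
    With probability ``free_fraction`` a block is SNP-free (identical
    haplotypes, emulating identity-by-descent segments); otherwise its
    per-site SNP probability is drawn from the named Gaussian mixture,
    truncated at 0 by resampling.  SNPs are then placed by independent
    Bernoulli trials per site.  Default mixture centers follow the
    low/high-heterozygosity regime seen in skipper butterflies: a component
    near 0.35 % and a second near 2.5 %.
    """
    if length_bp <= 0:
        raise ValueError("length_bp must be positive")
    if not 0 <= free_fraction < 1:
        raise ValueError("free_fraction must be in [0, 1)")
    weights = np.asarray(mix_weights, dtype=float)
    means = np.asarray(mix_means, dtype=float)
    sds = np.asarray(mix_sds, dtype=float)
    if not np.isclose(weights.sum(), 1.0):
        raise ValueError("mix_weights must sum to 1")
    if (means <= 0).any() or (sds <= 0).any():
        raise ValueError("mixture means and sds must be positive")

    rng = np.random.default_rng(seed)
    hap1 = _random_dna(rng, length_bp)
    hap2 = hap1.copy()

    block_table: list[tuple[int, int, str]] = []
    block_rates: list[float] = []
    snp_positions: set[int] = set()
    pos = 0
    while pos < length_bp:
        blen = int(rng.geometric(1.0 / block_len_mean))
        end = min(pos + blen, length_bp)
        if rng.random() < free_fraction:
            block_table.append((pos, end, "free"))
            block_rates.append(0.0)
        else:
            comp = int(rng.choice(len(weights), p=weights))
            rate = float(rng.normal(means[comp], sds[comp]))
            while rate <= 0:  # truncate at 0 by resampling
                rate = float(rng.normal(means[comp], sds[comp]))
            cls = "high" if comp == int(np.argmax(means)) and len(weights) > 1 else "low"
            block_table.append((pos, end, cls))
            block_rates.append(rate)
            hit = np.nonzero(rng.random(end - pos) < rate)[0] + pos
            for p in hit:
                ref = hap2[p]
                alts = _BASES[_BASES != ref]
                hap2[p] = alts[rng.integers(0, 3)]
                snp_positions.add(int(p))
        pos = end

    return DiploidTruth(
        hap1=hap1.tobytes().decode(),
        hap2=hap2.tobytes().decode(),
        snp_positions=snp_positions,
        block_table=block_table,
        block_rates=block_rates,
    )


def simulate_reads(
    truth: DiploidTruth, depth: float, read_len: int, seed: int = 0
) -> list[str]:
    """Draw error-free reads uniformly from the two haplotypes.

    Each read picks a haplotype with probability 1/2 and a start uniform on
    the valid range, so the expected per-haplotype depth is ``depth / 2``.
    Reads from the reverse strand are emitted reverse-complemented.
    """
    if depth <= 0:
        raise ValueError("depth must be positive")
    glen = truth.length
    if read_len > glen:
        raise ValueError("read_len exceeds genome length")
    n_reads = int(round(depth * glen / read_len))
    rng = np.random.default_rng(seed)
    starts = rng.integers(0, glen - read_len + 1, size=n_reads)
    hap_choice = rng.random(n_reads) < 0.5
    strand_rev = rng.random(n_reads) < 0.5
    reads = []
    for s, use_h2, rev in zip(starts, hap_choice, strand_rev):
        src = truth.hap2 if use_h2 else truth.hap1
        r = src[s : s + read_len]
        reads.append(revcomp(r) if rev else r)
    return reads


@dataclass
class SplitAssembly:
    """An assembly with standalone haplotigs plus the coverage evidence."""

    assembly: list[ScaffoldRecord]
    #: per-scaffold length-weighted mean read depth
    scaffold_depths: dict[str, float]
    #: per-window depth track: (scaffold, start, end, depth)
    coverage: list[tuple[str, int, int, float]]
    #: (haplotig_id, target_id, (start, end) on the target)
    truth_merges: list[tuple[str, str, tuple[int, int]]]


def simulate_split_assembly(
    truth: DiploidTruth,
    het_split_threshold: float = 0.015,
    depth: float = 60.0,
    window: int = 100,
    min_split_len: int = 1000,
    seed: int = 0,
) -> SplitAssembly:
    """Build an assembly in which high-heterozygosity blocks split in two.

    Blocks whose realized SNP rate exceeds ``het_split_threshold`` are emitted
    twice: the hap1 copy stays embedded in the long primary scaffold, and the
    hap2 copy becomes a standalone scaffold ("haplotig").  Because reads from
    the diverged haplotype map to their own copy, both the embedded region and
    the haplotig sit at roughly half the diploid read depth; all other regions
    are emitted once from hap1 at full depth.  Window depths carry Poisson
    read-sampling noise (base-count variance = depth x window length).

    Blocks shorter than ``min_split_len`` never split: an assembler does not
    emit scaffolds below the contig scale (draft assemblies conventionally
    report scaffolds of at least 1 kb).
    """
    rng = np.random.default_rng(seed)
    primary_id = "scaffold_1"
    assembly = [ScaffoldRecord(primary_id, truth.hap1)]
    truth_merges = []
    half_depth_regions: list[tuple[int, int]] = []
    n = 0
    snp_sorted = np.array(sorted(truth.snp_positions), dtype=np.int64)
    for (start, end, _cls) in truth.block_table:
        n_snps = int(np.searchsorted(snp_sorted, end) - np.searchsorted(snp_sorted, start))
        rate = n_snps / (end - start)  # realized, not drawn, block rate
        if rate > het_split_threshold and end - start >= min_split_len:
            n += 1
            hid = f"haplotig_{n}"
            assembly.append(ScaffoldRecord(hid, truth.hap2[start:end]))
            truth_merges.append((hid, primary_id, (start, end)))
            half_depth_regions.append((start, end))

    coverage: list[tuple[str, int, int, float]] = []
    scaffold_depths: dict[str, float] = {}
    for rec in assembly:
        total = 0.0
        for ws in range(0, rec.length, window):
            we = min(ws + window, rec.length)
            if rec.id == primary_id:
                half = any(s <= ws and we <= e for s, e in half_depth_regions)
                base = depth / 2 if half else depth
            else:
                base = depth / 2
            d = float(rng.poisson(base * (we - ws)) / (we - ws))
            coverage.append((rec.id, ws, we, d))
            total += d * (we - ws)
        scaffold_depths[rec.id] = total / rec.length
    return SplitAssembly(assembly, scaffold_depths, coverage, truth_merges)


# ---------------------------------------------------------------------------
# Gene orders


@dataclass
class GenePlacement:
    gene_id: str
    family_id: str
    scaffold: str
    index: int  # dense rank along the scaffold
    strand: str


@dataclass
class GeneOrderTruth:
    species_tree: dendropy.Tree
    #: species code -> list of placements (dense indices per scaffold)
    tables: dict[str, list[GenePlacement]]
    #: (branch head label, event type, description)
    event_log: list[tuple[str, str, str]]


def _apply_inversion(genes: list[GenePlacement], i: int, j: int) -> None:
    """Reverse the order of genes[i:j] in place and flip their strands."""
    seg = genes[i:j][::-1]
    for g in seg:
        g.strand = "-" if g.strand == "+" else "+"
    genes[i:j] = seg


def _reindex(by_scaffold: dict[str, list[GenePlacement]]) -> None:
    for placements in by_scaffold.values():
        for idx, g in enumerate(placements):
            g.index = idx


def simulate_gene_orders(
    species_tree: dendropy.Tree,
    n_families: int = 1200,
    n_scaffolds: int = 8,
    inversion_rate: float = 5.0,
    transloc_rate: float = 1.0,
    dup_rate: float = 0.5,
    seed: int = 0,
    max_copies: int = 5,
    inversions_per_branch: tuple[int, int] | None = (3, 8),
) -> GeneOrderTruth:
    """Evolve gene orders along a species tree by rearrangement events.

    The ancestral genome places families ``fam0001..famN`` in shuffled order
    across ``n_scaffolds`` scaffolds with random strands.  Along each branch
    events are applied: an *inversion* reverses a contiguous segment's order
    and flips strands; a *translocation* moves a segment to another scaffold
    position; a *duplication* copies one gene in place.  Family copy number
    is capped at ``max_copies``.

    By default every branch receives a uniform number of inversions in the
    inclusive ``inversions_per_branch`` range, so no internal branch is left
    without rearrangement signal; translocation and duplication counts are
    ``Poisson(rate * branch_length)``.  Passing ``inversions_per_branch=None``
    makes inversions Poisson as well, with ``inversion_rate`` per
    branch-length unit (branch lengths default to 1 when absent).
    """
    leaves = [l.taxon.label for l in species_tree.leaf_node_iter()]
    if len(leaves) < 3:
        raise ValueError("species tree must have at least 3 leaves")
    if n_families < 4:
        raise ValueError("need at least 4 families")
    for r in (inversion_rate, transloc_rate, dup_rate):
        if r < 0:
            raise ValueError("rates must be non-negative")

    rng = np.random.default_rng(seed)

    # ancestral order
    fam_ids = [f"fam{i + 1:04d}" for i in range(n_families)]
    order = rng.permutation(n_families)
    scaff_of = rng.integers(0, n_scaffolds, size=n_families)
    ancestor: dict[str, list[GenePlacement]] = {f"scf{s + 1}": [] for s in range(n_scaffolds)}
    gene_counter = [0]

    def new_gene(fam: str, scf: str, strand: str) -> GenePlacement:
        gene_counter[0] += 1
        return GenePlacement(f"g{gene_counter[0]:06d}", fam, scf, 0, strand)

    for k in order:
        scf = f"scf{scaff_of[k] + 1}"
        strand = "+" if rng.random() < 0.5 else "-"
        ancestor[scf].append(new_gene(fam_ids[k], scf, strand))
    _reindex(ancestor)

    event_log: list[tuple[str, str, str]] = []
    tables: dict[str, list[GenePlacement]] = {}

    def clone(gmap: dict[str, list[GenePlacement]]) -> dict[str, list[GenePlacement]]:
        return {
            scf: [GenePlacement(g.gene_id, g.family_id, g.scaffold, g.index, g.strand) for g in gs]
            for scf, gs in gmap.items()
        }

    def evolve(gmap: dict[str, list[GenePlacement]], node_label: str, blen: float) -> None:
        fam_counts: dict[str, int] = {}
        for gs in gmap.values():
            for g in gs:
                fam_counts[g.family_id] = fam_counts.get(g.family_id, 0) + 1
        if inversions_per_branch is not None:
            lo, hi = inversions_per_branch
            n_inv = int(rng.integers(lo, hi + 1)) if inversion_rate > 0 else 0
        else:
            n_inv = rng.poisson(inversion_rate * blen)
        n_tra = rng.poisson(transloc_rate * blen)
        n_dup = rng.poisson(dup_rate * blen)
        events = ["inv"] * n_inv + ["tra"] * n_tra + ["dup"] * n_dup
        rng.shuffle(events)
        for ev in events:
            scaffs = [s for s, gs in gmap.items() if gs]
            if not scaffs:
                break
            scf = scaffs[rng.integers(len(scaffs))]
            genes = gmap[scf]
            if ev == "inv":
                i = int(rng.integers(0, len(genes)))
                j = int(rng.integers(i + 1, min(i + 1 + 10, len(genes)) + 1))
                _apply_inversion(genes, i, j)
                event_log.append((node_label, "inversion", f"{scf}[{i}:{j}]"))
            elif ev == "tra":
                i = int(rng.integers(0, len(genes)))
                j = int(rng.integers(i + 1, min(i + 1 + 5, len(genes)) + 1))
                seg = genes[i:j]
                del genes[i:j]
                dest = scaffs[rng.integers(len(scaffs))]
                dgenes = gmap[dest]
                at = int(rng.integers(0, len(dgenes) + 1))
                for g in seg:
                    g.scaffold = dest
                dgenes[at:at] = seg
                event_log.append((node_label, "translocation", f"{scf}[{i}:{j}]->{dest}@{at}"))
            else:  # duplication in place
                i = int(rng.integers(0, len(genes)))
                g = genes[i]
                if fam_counts.get(g.family_id, 0) >= max_copies:
                    continue
                dup = new_gene(g.family_id, g.scaffold, g.strand)
                genes.insert(i + 1, dup)
                fam_counts[g.family_id] = fam_counts.get(g.family_id, 0) + 1
                event_log.append((node_label, "duplication", f"{scf}@{i}:{g.family_id}"))
        _reindex(gmap)

    def recurse(node: dendropy.Node, gmap: dict[str, list[GenePlacement]]) -> None:
        for child in node.child_nodes():
            cmap = clone(gmap)
            blen = child.edge.length if child.edge.length is not None else 1.0
            label = child.taxon.label if child.is_leaf() else (child.label or "internal")
            evolve(cmap, label, blen)
            if child.is_leaf():
                tables[child.taxon.label] = [g for gs in cmap.values() for g in gs]
            else:
                recurse(child, cmap)

    recurse(species_tree.seed_node, ancestor)
    return GeneOrderTruth(species_tree=species_tree, tables=tables, event_log=event_log)


# ---------------------------------------------------------------------------
# Substitution profiles


@dataclass
class SubProfileTruth:
    """Per-protein substitution profiles with planted enrichment labels."""

    #: (protein_id, length_aa, disorder_mask (bool array, True = disordered),
    #:  substitution positions (aa indices))
    profiles: list[tuple[str, int, np.ndarray, np.ndarray]]
    enriched_ids: set[str]


def simulate_sub_profiles(
    n_proteins: int = 2000,
    mean_len: int = 400,
    p0: float = 0.007,
    enriched_fraction: float = 0.05,
    effect_mult: float = 5.0,
    disorder_fraction: float = 0.2,
    disorder_mult: float = 2.0,
    len_sigma: float = 0.0,
    seed: int = 0,
) -> SubProfileTruth:
    """Simulate per-protein substitution counts with a planted enriched subset.

    Protein lengths are ``mean_len`` aa, or lognormal around it (log-scale
    ``len_sigma``, floored at 50 aa) when length spread is wanted.  A
    contiguous disordered segment covers ``disorder_fraction`` of each
    protein.  Per-site substitution probability is ``p0`` for ordered sites
    of non-enriched proteins, times ``effect_mult`` for enriched proteins,
    times ``disorder_mult`` extra in disordered sites.  The default ``p0``
    of 0.007 substitutions per aa corresponds to a coding SNP rate just
    under 1 % of which about a quarter are non-synonymous (3 nt per codon).
    """
    rng = np.random.default_rng(seed)
    profiles = []
    enriched_ids: set[str] = set()
    n_enriched = int(round(enriched_fraction * n_proteins))
    mu = float(np.log(mean_len)) - len_sigma**2 / 2
    for i in range(n_proteins):
        pid = f"prot{i + 1:05d}"
        if len_sigma > 0:
            length = max(50, int(rng.lognormal(mu, len_sigma)))
        else:
            length = mean_len
        mask = np.zeros(length, dtype=bool)
        dis_len = int(round(disorder_fraction * length))
        if dis_len > 0:
            start = int(rng.integers(0, length - dis_len + 1))
            mask[start : start + dis_len] = True
        enriched = i < n_enriched
        if enriched:
            enriched_ids.add(pid)
        rate = np.full(length, p0 * (effect_mult if enriched else 1.0))
        rate[mask] *= disorder_mult
        subs = np.nonzero(rng.random(length) < rate)[0]
        profiles.append((pid, length, mask, subs))
    return SubProfileTruth(profiles=profiles, enriched_ids=enriched_ids)
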