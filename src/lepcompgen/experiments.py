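"""End-to-end validation experiments on synthetic data with known truth.

Each function runs one self-contained study — generation, analysis,
scoring — and returns plain numbers, so the same code backs both the test
suite and the reproduction script.  Problem sizes are desk-scale versions of
the real analyses (see ``docs/methods.md``).
"""

from __future__ import annotations

import numpy as np

from lepcompgen import hapmerge, kmercov, rearrphylo, snpdist, subenrich, synthio
from lepcompgen.io import parse_newick
from lepcompgen.snpdist import CODON_TABLE, SubstitutionProfile
from lepcompgen.io import GeneModel, ScaffoldRecord, SnpRecord

__all__ = [
    "column_grouping_summary",
    "orientation_state_count",
    "tree_recovery_experiment",
    "bionj_additive_experiment",
    "mixture_recovery_experiment",
    "enrichment_calibration_experiment",
    "hapmerge_recovery_experiment",
    "codon_classification_oracle",
    "kmer_peak_experiment",
]


def column_grouping_summary(n_columns: int = 570_686, n_groups: int = 100, seed: int = 0):
    """Sizes of the near-equal random column groups at full scale."""
    groups = rearrphylo.sample_column_groups(n_columns, n_groups=n_groups, n_reps=1, seed=seed)
    sizes = [len(g) for g in groups]
    return {
        "max_size": max(sizes),
        "min_size": min(sizes),
        "n_max_sized": sizes.count(max(sizes)),
    }


def orientation_state_count() -> int:
    """Brute-force enumeration of strand combinations for an ordered pair."""
    states = set()
    for sa in "+-":
        for sb in "+-":
            states.add(
                rearrphylo.orientation_state(("a", "s", 0, sa), ("b", "s", 100, sb))
            )
    return len(states)


def tree_recovery_experiment(seed: int = 0, n_replicates: int = 50) -> dict:
    """Fraction of replicates where the rearrangement pipeline recovers the
    7-taxon reference topology (RF = 0) from simulated gene orders."""
    reference = parse_newick(rearrphylo.TRADITIONAL_NEWICK)
    hits = 0
    min_pairs = None
    for i in range(n_replicates):
        truth = synthio.simulate_gene_orders(reference, seed=seed * 10_000 + i)
        fams = rearrphylo.families_from_tables(truth.tables)
        tree, matrix = rearrphylo.rearrangement_tree(fams, sorted(truth.tables))
        if min_pairs is None or len(matrix.pairs) < min_pairs:
            min_pairs = len(matrix.pairs)
        hits += rearrphylo.rf_distance(tree, reference) == 0
    return {"recovery_fraction": hits / n_replicates, "min_pairs": min_pairs,
            "n": n_replicates}


def random_tree_with_lengths(rng: np.random.Generator, n_taxa: int):
    """Random binary unrooted topology with branch lengths uniform in [0.5, 2]."""
    frags = [f"T{i}:{rng.uniform(0.5, 2):.6f}" for i in range(n_taxa)]
    while len(frags) > 3:
        i, j = sorted(rng.choice(len(frags), size=2, replace=False))
        b = frags.pop(j)
        a = frags.pop(i)
        frags.append(f"({a},{b}):{rng.uniform(0.5, 2):.6f}")
    return parse_newick(f"({frags[0]},{frags[1]},{frags[2]});")


def additive_matrix(tree):
    """Path-length (additive) distance matrix of a tree, labels sorted."""
    pdm = tree.phylogenetic_distance_matrix()
    taxa = sorted(tree.taxon_namespace, key=lambda t: t.label)
    n = len(taxa)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            d[i, j] = pdm.distance(taxa[i], taxa[j])
    return d, [t.label for t in taxa]


def bionj_additive_experiment(seed: int = 0, n_matrices: int = 20) -> dict:
    """BioNJ on additive matrices from random 5-8 taxon trees: worst RF and
    worst absolute branch-length error across matrices."""
    rng = np.random.default_rng(seed)
    worst_rf = 0
    worst_len_err = 0.0
    for _ in range(n_matrices):
        n_taxa = int(rng.integers(5, 9))
        t = random_tree_with_lengths(rng, n_taxa)
        d, labels = additive_matrix(t)
        bt = rearrphylo.bionj(d, labels)
        worst_rf = max(worst_rf, rearrphylo.rf_distance(bt, t))
        db, lb = additive_matrix(bt)
        order = [lb.index(x) for x in labels]
        worst_len_err = max(worst_len_err, float(np.abs(db[np.ix_(order, order)] - d).max()))
    return {"worst_rf": worst_rf, "worst_pathlen_err": worst_len_err, "n": n_matrices}


def mixture_recovery_experiment(seed: int = 0, n: int = 5000) -> dict:
    """Two-component fit on window rates in the low/high heterozygosity
    regime (components at 0.35 % and 2.5 %), plus a one-component control."""
    rng = np.random.default_rng(seed)
    two = np.concatenate(
        [rng.normal(0.0035, 0.001, n // 2), rng.normal(0.025, 0.004, n - n // 2)]
    )
    f1, f2 = snpdist.fit_mixture(two, 1), snpdist.fit_mixture(two, 2)
    chosen = snpdist.select_model(f1, f2)
    one = rng.normal(0.024, 0.004, n)
    g1, g2 = snpdist.fit_mixture(one, 1), snpdist.fit_mixture(one, 2)
    return {
        "selected_k_two_component": chosen.n_components,
        "mean_low": float(f2.means[0]),
        "mean_high": float(f2.means[1]),
        "selected_k_one_component": snpdist.select_model(g1, g2).n_components,
        "n": n,
    }


def enrichment_calibration_experiment(
    seed: int = 0,
    n_null_replicates: int = 200,
    n_proteins_null: int = 400,
    n_effect_replicates: int = 5,
) -> dict:
    """FDR calibration under the complete null and sensitivity to a 5x
    planted effect."""
    def profiles(truth):
        return [
            SubstitutionProfile(pid, L, mask, len(subs), int((~mask[subs]).sum()))
            for pid, L, mask, subs in truth.profiles
        ]

    false_rates = []
    for i in range(n_null_replicates):
        truth = synthio.simulate_sub_profiles(
            n_proteins=n_proteins_null, enriched_fraction=0.0,
            seed=seed * 100_000 + i,
        )
        res = subenrich.test_proteins(profiles(truth), mode="ordered_only")
        n_flagged = sum(r.enriched for r in res)
        false_rates.append(1.0 if n_flagged else 0.0)  # all flags are false
    false_rates = np.array(false_rates)

    sens = []
    for i in range(n_effect_replicates):
        truth = synthio.simulate_sub_profiles(
            n_proteins=2000, enriched_fraction=0.05, effect_mult=5.0,
            disorder_fraction=0.0, disorder_mult=1.0, seed=seed * 100_000 + 777 + i,
        )
        res = subenrich.test_proteins(profiles(truth), mode="all")
        flagged = {r.unit_id for r in res if r.enriched}
        sens.append(len(flagged & truth.enriched_ids) / len(truth.enriched_ids))
    return {
        "null_mean_fdr": float(false_rates.mean()),
        "null_fdr_se": float(false_rates.std(ddof=1) / np.sqrt(len(false_rates))),
        "sensitivity": float(np.mean(sens)),
        "n_null_replicates": n_null_replicates,
    }


def hapmerge_recovery_experiment(seed: int = 0, n_replicates: int = 10) -> dict:
    """Precision/recall of haplotig merging against planted truth."""
    tp = fp = fn = 0
    for i in range(n_replicates):
        s = seed * 10_000 + i
        truth = synthio.simulate_diploid(
            150_000, mix_weights=(0.85, 0.15), free_fraction=0.1, seed=s
        )
        sa = synthio.simulate_split_assembly(truth, depth=60, seed=s)
        _, report = hapmerge.find_merges(
            sa.assembly, sa.scaffold_depths, sa.coverage, hom_depth=60
        )
        T = {(h, t) for h, t, _ in sa.truth_merges}
        F = {(h, t) for h, t, _ in report}
        tp += len(T & F)
        fp += len(F - T)
        fn += len(T - F)
    return {
        "precision": tp / (tp + fp) if tp + fp else 1.0,
        "recall": tp / (tp + fn) if tp + fn else 1.0,
        "n_planted": tp + fn,
    }


def codon_classification_oracle() -> dict:
    """All 576 single-base codon changes vs brute-force translation."""
    mismatches = total = 0
    for codon in CODON_TABLE:
        for off in range(3):
            for alt in "ACGT":
                if alt == codon[off]:
                    continue
                total += 1
                seq = codon + "AAA"
                gene = GeneModel("g", "s", 0, 6, "+", [(0, 6)])
                snp = SnpRecord("s", off, codon[off], alt)
                got = snpdist.classify_snp_effect(snp, gene, seq)
                mutant = codon[:off] + alt + codon[off + 1 :]
                want = (
                    "synonymous"
                    if CODON_TABLE[codon] == CODON_TABLE[mutant]
                    else "nonsynonymous"
                )
                mismatches += got != want
    return {"n_changes": total, "mismatches": mismatches}


def kmer_peak_experiment(
    seed: int = 0,
    n_replicates: int = 10,
    depth: float = 60.0,
    genome_len: int = 60_000,
    read_len: int = 250,
    het: float = 0.016,
) -> dict:
    """Peak recovery from simulated diploid reads plus the het/hom height
    ratio across three heterozygosity levels.

    Reads of length L contribute L-k+1 k-mers, so the histogram peaks sit at
    ``depth * (L-k+1)/L`` and half of it; reported depths are rescaled to
    read depth for comparison against the nominal 60x/30x.
    """
    k = 17
    kmer_factor = (read_len - k + 1) / read_len
    hom, hetd = [], []
    for i in range(n_replicates):
        s = seed * 10_000 + i
        truth = synthio.simulate_diploid(
            genome_len, mix_weights=(1.0,), mix_means=(het,), mix_sds=(0.002,),
            free_fraction=0.0, seed=s,
        )
        reads = synthio.simulate_reads(truth, depth=depth, read_len=read_len, seed=s)
        pk = kmercov.detect_peaks(kmercov.kmer_histogram(reads, k=k))
        hom.append(pk.hom_depth / kmer_factor)
        hetd.append(pk.het_depth / kmer_factor)

    ratios = []
    for level in (0.005, 0.016, 0.023):
        truth = synthio.simulate_diploid(
            genome_len, mix_weights=(1.0,), mix_means=(level,), mix_sds=(0.001,),
            free_fraction=0.0, seed=seed * 10_000 + 99,
        )
        reads = synthio.simulate_reads(truth, depth=depth, read_len=read_len,
                                       seed=seed * 10_000 + 99)
        pk = kmercov.detect_peaks(kmercov.kmer_histogram(reads, k=k))
        ratios.append(pk.height_ratio)
    return {
        "hom_depth_mean": float(np.mean(hom)),
        "het_depth_mean": float(np.mean(hetd)),
        "hom_depth_worst_rel_err": float(max(abs(h - depth) / depth for h in hom)),
        "het_depth_worst_rel_err": float(max(abs(h - depth / 2) / (depth / 2) for h in hetd)),
        "height_ratios": [float(r) for r in ratios],
        "n": n_replicates,
    }
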