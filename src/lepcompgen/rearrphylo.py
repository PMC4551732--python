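"""Gene-order rearrangement phylogeny and alignment-sampling machinery.

The rearrangement phylogeny encodes, for every pair of ortholog families
that is co-located on one scaffold in every species, the relative strand
orientation of the two genes as one of four states::

    A = (+, +)   B = (-, -)   C = (+, -)   D = (-, +)

read in canonical family order (``fam_a < fam_b``).  An inversion that
captures exactly one gene of a pair flips its state (A<->C or B<->D when the
second gene flips; A<->D, B<->C for the first), so Hamming distances between
the per-species state strings count rearrangement events and feed a BioNJ
tree.  Families with more than 4 copies in any species are removed first,
and each family participates in at most one pair.

The module also carries the column-consistency, column-sampling and
majority-rule consensus utilities used by sequence-based analyses of the
same species set, plus Robinson–Foulds distances and a three-way topology
classifier for the butterfly data set.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from lepcompgen.io import ParseError, parse_newick
import dendropy

__all__ = [
    "OrthologFamily",
    "FamilyPair",
    "OrientationMatrix",
    "families_from_tables",
    "read_family_table",
    "filter_families",
    "orientation_state",
    "resolvable_pairs",
    "select_disjoint_pairs",
    "orientation_matrix",
    "hamming_distances",
    "bionj",
    "export_character_matrix",
    "read_character_matrix",
    "consistent_columns",
    "sample_column_groups",
    "majority_consensus",
    "tree_splits",
    "rf_distance",
    "topology_report",
    "rearrangement_tree",
    "TRADITIONAL_NEWICK",
    "ALTERNATE_NEWICK",
]

#: The two reference resolutions of the 7-taxon butterfly phylogeny: the
#: morphology-based ("traditional") topology places skippers (Lac) outside
#: the other butterflies; the DNA-based ("alternate") topology swaps Pgl and
#: Lac.
TRADITIONAL_NEWICK = "(((((Mci,Hme),Dpl),Pgl),Lac),Bmo,Pxy);"
ALTERNATE_NEWICK = "(((((Mci,Hme),Dpl),Lac),Pgl),Bmo,Pxy);"

STATE_BY_STRANDS = {("+", "+"): "A", ("-", "-"): "B", ("+", "-"): "C", ("-", "+"): "D"}


@dataclass
class OrthologFamily:
    """Per-species gene placements of one orthologous group."""

    family_id: str
    #: species -> list of (gene_id, scaffold, start_bp, strand)
    members: dict[str, list[tuple[str, str, int, str]]] = field(default_factory=dict)

    def copies(self, species: str) -> int:
        return len(self.members.get(species, ()))


@dataclass
class FamilyPair:
    fam_a: str
    fam_b: str
    #: species -> state letter, or None when undetermined
    states: dict[str, str | None]

    def __post_init__(self) -> None:
        if not self.fam_a < self.fam_b:
            raise ValueError("fam_a must sort before fam_b")

    @property
    def fully_determined(self) -> bool:
        return all(s is not None for s in self.states.values())


@dataclass
class OrientationMatrix:
    species: list[str]
    pairs: list[tuple[str, str]]
    #: species -> state string over {A,B,C,D}, aligned with ``pairs``
    strings: dict[str, str]


def families_from_tables(
    tables: dict[str, list],
) -> dict[str, OrthologFamily]:
    """Build :class:`OrthologFamily` objects from per-species gene tables.

    ``tables`` maps a species code to gene placements with ``gene_id``,
    ``family_id``, ``scaffold``, ``index`` and ``strand`` attributes (as
    produced by the gene-order simulator).
    """
    fams: dict[str, OrthologFamily] = {}
    for sp, genes in tables.items():
        for g in genes:
            fam = fams.setdefault(g.family_id, OrthologFamily(g.family_id))
            fam.members.setdefault(sp, []).append(
                (g.gene_id, g.scaffold, g.index, g.strand)
            )
    return fams


def read_family_table(path: str | Path) -> dict[str, OrthologFamily]:
    """Read a TSV of (species, gene_id, family_id, scaffold, start, strand)."""
    fams: dict[str, OrthologFamily] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\r\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 6:
                raise ParseError(f"{path}: expected 6 columns at line {lineno}")
            species, gene_id, fam_id, scaffold, start, strand = cols
            fam = fams.setdefault(fam_id, OrthologFamily(fam_id))
            fam.members.setdefault(species, []).append(
                (gene_id, scaffold, int(start), strand)
            )
    return fams


def filter_families(
    families: dict[str, OrthologFamily], species: list[str], max_copies: int = 4
) -> dict[str, OrthologFamily]:
    """Keep families present in every species with at most ``max_copies`` copies."""
    return {
        fid: fam
        for fid, fam in families.items()
        if all(1 <= fam.copies(sp) <= max_copies for sp in species)
    }


def orientation_state(
    gene_a: tuple[str, str, int, str], gene_b: tuple[str, str, int, str]
) -> str | None:
    """Orientation state of an ordered gene pair, or None across scaffolds.

    ``gene_*`` are (gene_id, scaffold, start, strand) with the pair already
    in canonical family order.
    """
    if gene_a[0] == gene_b[0]:
        raise ValueError("cannot pair a gene with itself")
    if gene_a[1] != gene_b[1]:
        return None
    return STATE_BY_STRANDS[(gene_a[3], gene_b[3])]


def _consistent_locus(
    placements: list[tuple[str, str, int, str]]
) -> tuple[str, str] | None:
    """(scaffold, strand) when all copies agree on both; None otherwise."""
    scaffolds = {p[1] for p in placements}
    strands = {p[3] for p in placements}
    if len(scaffolds) == 1 and len(strands) == 1:
        return next(iter(scaffolds)), next(iter(strands))
    return None


def resolvable_pairs(
    families: dict[str, OrthologFamily], species: list[str]
) -> list[FamilyPair]:
    """All family pairs whose orientation is determined in every species.

    A family is single-locus-resolvable in a species when all of its copies
    lie on one scaffold with one consistent strand.  A pair qualifies when
    both families resolve in every species and share the scaffold there.
    """
    loci: dict[str, dict[str, tuple[str, str]]] = {}
    for fid, fam in families.items():
        per_sp = {}
        for sp in species:
            locus = _consistent_locus(fam.members.get(sp, []))
            if locus is None:
                break
            per_sp[sp] = locus
        else:
            loci[fid] = per_sp

    # group resolvable families by scaffold per species to limit pair tests
    out: list[FamilyPair] = []
    fids = sorted(loci)
    for fam_a, fam_b in itertools.combinations(fids, 2):
        states: dict[str, str | None] = {}
        for sp in species:
            sa, stra = loci[fam_a][sp]
            sb, strb = loci[fam_b][sp]
            if sa != sb:
                break
            states[sp] = STATE_BY_STRANDS[(stra, strb)]
        else:
            out.append(FamilyPair(fam_a, fam_b, states))
    return out


def select_disjoint_pairs(pairs: list[FamilyPair]) -> list[FamilyPair]:
    """Greedy matching so each family participates in only one pair.

    Pairs are scanned in (fam_a, fam_b) sort order; a pair is accepted iff
    neither family has been used yet.  Deterministic.
    """
    used: set[str] = set()
    out = []
    for pair in sorted(pairs, key=lambda p: (p.fam_a, p.fam_b)):
        if pair.fam_a in used or pair.fam_b in used:
            continue
        used.update((pair.fam_a, pair.fam_b))
        out.append(pair)
    return out


def orientation_matrix(pairs: list[FamilyPair], species: list[str]) -> OrientationMatrix:
    """Encode fully determined pairs as one state string per species."""
    det = [p for p in pairs if all(p.states.get(sp) for sp in species)]
    det.sort(key=lambda p: (p.fam_a, p.fam_b))
    strings = {
        sp: "".join(p.states[sp] for p in det) for sp in species  # type: ignore[misc]
    }
    return OrientationMatrix(
        species=list(species),
        pairs=[(p.fam_a, p.fam_b) for p in det],
        strings=strings,
    )


def hamming_distances(matrix: OrientationMatrix) -> tuple[np.ndarray, list[str]]:
    """Pairwise Hamming distances between the species state strings."""
    sp = matrix.species
    n = len(sp)
    arr = np.array(
        [np.frombuffer(matrix.strings[s].encode(), dtype=np.uint8) for s in sp]
    )
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = int((arr[i] != arr[j]).sum())
    return d, list(sp)


# ---------------------------------------------------------------------------
# BioNJ


def bionj(dist: np.ndarray, labels: list[str]) -> dendropy.Tree:
    """BioNJ tree from a distance matrix.

    Standard neighbor joining with the variance-weighted reduction of
    Gascuel (1997): pairs are chosen by the NJ Q-criterion (ties broken by
    lexicographic taxon-pair order), branch lengths use the NJ two-point
    formulas, and the reduction of the distance and variance matrices uses
    the weight ``lambda`` that minimizes the variance of the reduced matrix,
    clamped to [0, 1].  The variance matrix is initialized to the distance
    matrix.  Returns an unrooted dendropy tree.
    """
    d = np.asarray(dist, dtype=float).copy()
    n = d.shape[0]
    if n < 3:
        raise ValueError("need at least 3 taxa")
    if d.shape != (n, n) or not np.allclose(d, d.T) or not np.allclose(np.diag(d), 0):
        raise ValueError("distance matrix must be symmetric with zero diagonal")
    if len(labels) != n:
        raise ValueError("labels must match matrix size")

    v = d.copy()
    # node subtrees as (newick fragment, canonical smallest label)
    nodes = [(lbl, lbl) for lbl in labels]
    active = list(range(n))

    while len(active) > 3:
        r = len(active)
        sub = d[np.ix_(active, active)]
        S = sub.sum(axis=1)
        best = None
        for ai in range(r):
            for aj in range(ai + 1, r):
                q = (r - 2) * sub[ai, aj] - S[ai] - S[aj]
                key = tuple(sorted((nodes[active[ai]][1], nodes[active[aj]][1])))
                if best is None or q < best[0] - 1e-12 or (abs(q - best[0]) <= 1e-12 and key < best[1]):
                    best = (q, key, ai, aj)
        _, _, ai, aj = best
        i, j = active[ai], active[aj]
        dij = d[i, j]
        bi = dij / 2 + (S[ai] - S[aj]) / (2 * (r - 2))
        bj = dij - bi

        others = [a for a in active if a not in (i, j)]
        # BioNJ lambda: minimize variance of the reduced matrix
        vij = v[i, j]
        if vij > 0 and r > 2:
            lam = 0.5 + sum(v[j, k] - v[i, k] for k in others) / (2 * (r - 2) * vij)
            lam = min(1.0, max(0.0, lam))
        else:
            lam = 0.5

        # new node index = len(nodes)
        u = len(nodes)
        frag = f"({nodes[i][0]}:{bi:.10g},{nodes[j][0]}:{bj:.10g})"
        nodes.append((frag, min(nodes[i][1], nodes[j][1])))
        d = np.pad(d, ((0, 1), (0, 1)))
        v = np.pad(v, ((0, 1), (0, 1)))
        for k in others:
            duk = lam * (d[i, k] - bi) + (1 - lam) * (d[j, k] - bj)
            vuk = lam * v[i, k] + (1 - lam) * v[j, k] - lam * (1 - lam) * vij
            d[u, k] = d[k, u] = duk
            v[u, k] = v[k, u] = vuk
        active = others + [u]

    a, b, c = active
    # three-point closed form
    la = (d[a, b] + d[a, c] - d[b, c]) / 2
    lb = (d[a, b] + d[b, c] - d[a, c]) / 2
    lc = (d[a, c] + d[b, c] - d[a, b]) / 2
    newick = (
        f"({nodes[a][0]}:{la:.10g},{nodes[b][0]}:{lb:.10g},{nodes[c][0]}:{lc:.10g});"
    )
    tree = parse_newick(newick)
    tree.is_rooted = False
    return tree


def rearrangement_tree(
    families: dict[str, OrthologFamily], species: list[str], max_copies: int = 4
) -> tuple[dendropy.Tree, OrientationMatrix]:
    """Full pipeline: filter -> pairs -> disjoint -> Hamming -> BioNJ."""
    kept = filter_families(families, species, max_copies=max_copies)
    pairs = resolvable_pairs(kept, species)
    disjoint = select_disjoint_pairs(pairs)
    matrix = orientation_matrix(disjoint, species)
    if len(matrix.pairs) == 0:
        raise ValueError("no fully determined pairs; cannot build a tree")
    d, labels = hamming_distances(matrix)
    return bionj(d, labels), matrix


# ---------------------------------------------------------------------------
# character-matrix export (relaxed PHYLIP)


def export_character_matrix(matrix: OrientationMatrix, path: str | Path) -> None:
    """Write the state strings as relaxed PHYLIP (A-D as amino-acid states)."""
    n_chars = len(matrix.pairs)
    with open(path, "w") as fh:
        fh.write(f"{len(matrix.species)} {n_chars}\n")
        for sp in matrix.species:
            fh.write(f"{sp} {matrix.strings[sp]}\n")


def read_character_matrix(path: str | Path) -> dict[str, str]:
    with open(path) as fh:
        header = fh.readline().split()
        if len(header) != 2:
            raise ParseError(f"{path}: bad PHYLIP header")
        n_sp, n_chars = int(header[0]), int(header[1])
        out = {}
        for _ in range(n_sp):
            name, string = fh.readline().split()
            if len(string) != n_chars:
                raise ParseError(f"{path}: row {name} has wrong length")
            out[name] = string
    return out


# ---------------------------------------------------------------------------
# alignment-column machinery


def consistent_columns(
    msa_global: dict[str, str],
    aln_local: dict[str, str] | set[frozenset[tuple[str, int]]],
) -> list[int]:
    """Columns of a global MSA confirmed by a second alignment.

    A column asserts that the residues it contains (one per non-gap
    sequence) are mutually homologous.  The column is kept iff every such
    assertion also holds in the second input: in MSA mode, all its residues
    must fall into one common column of the second MSA; in pairwise mode
    (a set of ``frozenset{(seq, residue_index), (seq, residue_index)}``
    pairs), every within-column residue pair must appear in the set.
    Columns asserting no pairs (at most one non-gap residue) are kept
    vacuously.
    """
    names = sorted(msa_global)
    length = {len(s) for s in msa_global.values()}
    if len(length) != 1:
        raise ValueError("global MSA rows have unequal lengths")
    ncol = length.pop()

    # residue index per (sequence, column) of the global MSA
    res_idx: dict[str, list[int | None]] = {}
    for name in names:
        idx, out = 0, []
        for ch in msa_global[name]:
            if ch == "-":
                out.append(None)
            else:
                out.append(idx)
                idx += 1
        res_idx[name] = out

    msa_mode = isinstance(aln_local, dict)
    if msa_mode:
        second_col: dict[str, dict[int, int]] = {}
        for name, seq in aln_local.items():
            idx = 0
            cols = {}
            for c, ch in enumerate(seq):
                if ch != "-":
                    cols[idx] = c
                    idx += 1
            second_col[name] = cols
        if set(second_col) != set(names):
            raise ValueError("alignments contain different sequence sets")

    kept = []
    for c in range(ncol):
        residues = [(n, res_idx[n][c]) for n in names if res_idx[n][c] is not None]
        if len(residues) <= 1:
            kept.append(c)
            continue
        if msa_mode:
            cols2 = {second_col[n][ri] for n, ri in residues}
            if len(cols2) == 1:
                kept.append(c)
        else:
            ok = all(
                frozenset((pa, pb)) in aln_local
                for pa, pb in itertools.combinations(residues, 2)
            )
            if ok:
                kept.append(c)
    return kept


def sample_column_groups(
    n_columns: int, n_groups: int = 100, n_reps: int = 10, seed: int = 0
) -> list[np.ndarray]:
    """Randomly split column indices into near-equal groups, repeatedly.

    Per repetition a fresh uniform permutation of ``0..n_columns-1`` is cut
    into ``n_groups`` contiguous chunks whose sizes differ by at most one
    (the first ``n_columns mod n_groups`` chunks get the extra column), so
    within a repetition the groups partition all columns.  Returns
    ``n_groups * n_reps`` index arrays.
    """
    if n_columns < n_groups:
        raise ValueError("more groups than columns")
    rng = np.random.default_rng(seed)
    base, extra = divmod(n_columns, n_groups)
    sizes = [base + 1] * extra + [base] * (n_groups - extra)
    out = []
    for _ in range(n_reps):
        perm = rng.permutation(n_columns)
        pos = 0
        for sz in sizes:
            out.append(np.sort(perm[pos : pos + sz]))
            pos += sz
    return out


# ---------------------------------------------------------------------------
# consensus, RF distance, topology classification


def tree_splits(tree: dendropy.Tree) -> set[frozenset[str]]:
    """Non-trivial splits of an unrooted tree, normalized to the side not
    containing the lexicographically smallest leaf label."""
    leaves = sorted(l.taxon.label for l in tree.leaf_node_iter())
    ref = leaves[0]
    all_leaves = set(leaves)
    splits: set[frozenset[str]] = set()
    for node in tree.preorder_node_iter():
        if node.is_leaf() or node.parent_node is None:
            continue
        side = {l.taxon.label for l in node.leaf_iter()}
        if ref in side:
            side = all_leaves - side
        if 1 < len(side) < len(all_leaves) - 1:
            splits.add(frozenset(side))
    return splits


def rf_distance(t1: dendropy.Tree, t2: dendropy.Tree) -> int:
    """Robinson–Foulds distance: splits present in exactly one tree."""
    l1 = {l.taxon.label for l in t1.leaf_node_iter()}
    l2 = {l.taxon.label for l in t2.leaf_node_iter()}
    if l1 != l2:
        raise ValueError("trees have different leaf sets")
    return len(tree_splits(t1) ^ tree_splits(t2))


def majority_consensus(trees: list[dendropy.Tree], threshold: float = 0.5) -> dendropy.Tree:
    """Majority-rule consensus: splits in strictly more than ``threshold``
    of the input trees, with occurrence fractions as supports."""
    if not trees:
        raise ValueError("no input trees")
    leaf_sets = [{l.taxon.label for l in t.leaf_node_iter()} for t in trees]
    if any(ls != leaf_sets[0] for ls in leaf_sets):
        raise ValueError("trees have different leaf sets")
    taxa = sorted(leaf_sets[0])
    counts: dict[frozenset[str], int] = {}
    for t in trees:
        for sp in tree_splits(t):
            counts[sp] = counts.get(sp, 0) + 1
    n = len(trees)
    majority = [
        (sp, c / n) for sp, c in counts.items() if c / n > threshold
    ]
    # splits above 0.5 are pairwise compatible; build by nesting larger first
    majority.sort(key=lambda x: (-len(x[0]), sorted(x[0])))

    # start from a star tree; insert each split as a new internal node
    root: dict = {"children": [], "support": None}
    leaf_nodes = {t: {"label": t, "children": [], "support": None} for t in taxa}
    root["children"] = [leaf_nodes[t] for t in taxa]

    def leafset(node: dict) -> set[str]:
        if not node["children"]:
            return {node["label"]}
        return set().union(*(leafset(c) for c in node["children"]))

    for sp, support in majority:
        target = root
        while True:
            for child in target["children"]:
                ls = leafset(child)
                if sp <= ls and len(ls) > len(sp):
                    target = child
                    break
            else:
                break
        grouped = [c for c in target["children"] if leafset(c) <= sp]
        if set().union(*(leafset(c) for c in grouped)) != set(sp):
            continue  # incompatible with an already-inserted split
        for c in grouped:
            target["children"].remove(c)
        target["children"].append({"label": None, "children": grouped, "support": support})

    def to_newick(node: dict) -> str:
        if not node["children"]:
            return node["label"]
        inner = ",".join(to_newick(c) for c in node["children"])
        sup = f"{node['support']:.4g}" if node["support"] is not None else ""
        return f"({inner}){sup}"

    tree = parse_newick(to_newick(root) + ";")
    tree.is_rooted = False
    return tree


def topology_report(tree: dendropy.Tree) -> str:
    """Classify a 7-taxon butterfly tree as traditional, alternate or other."""
    trad = tree_splits(parse_newick(TRADITIONAL_NEWICK))
    alt = tree_splits(parse_newick(ALTERNATE_NEWICK))
    splits = tree_splits(tree)
    if splits == trad:
        return "traditional"
    if splits == alt:
        return "alternate"
    return "other"
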