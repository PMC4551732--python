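"""Ortholog-family merging and the gene-expansion criterion.

Families produced by a clustering tool sometimes split one biological family
in two; when two families share the same closest reference-proteome homolog
they are merged (connected components of the shared-closest-hit graph).  A
focal species is called *expanded* in a family when both its copy number and
its total protein length exceed 1.5 times the averages over the other
species.  A small report utility assigns every family to one ortholog
category (1:1:1, N:N:N, clade-specific, patchy, species-specific,
unclustered).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import networkx as nx

__all__ = [
    "ExpansionVerdict",
    "merge_families_by_closest_hit",
    "expansion_test",
    "ortholog_categories",
]


@dataclass
class ExpansionVerdict:
    family_id: str
    focal_species: str
    focal_count: int
    focal_total_len: float
    other_mean_count: float
    other_mean_len: float
    ratio: float = 1.5

    @property
    def count_ratio(self) -> float:
        return self.focal_count / self.other_mean_count

    @property
    def length_ratio(self) -> float:
        return self.focal_total_len / self.other_mean_len

    @property
    def expanded(self) -> bool:
        return self.count_ratio > self.ratio and self.length_ratio > self.ratio


def merge_families_by_closest_hit(
    families: dict[str, list[str]],
    closest_hit: dict[str, str],
) -> dict[str, list[str]]:
    """Merge families that share a closest reference homolog.

    ``families`` maps family id to member protein ids; ``closest_hit`` maps
    a protein to its closest reference-proteome entry.  Each family's hit is
    the modal entry over its members (ties broken by lexicographically
    smallest entry; members without a hit are ignored).  Families whose
    modal entries coincide are joined into connected components; merged
    families are named by joining the sorted constituent ids with ``+``.
    Proteins listed in ``closest_hit`` but in no family are ignored.
    """
    family_hit: dict[str, str] = {}
    for fid, members in families.items():
        hits = [closest_hit[m] for m in members if m in closest_hit]
        if not hits:
            continue
        counts = Counter(hits)
        top = max(counts.values())
        family_hit[fid] = min(h for h, c in counts.items() if c == top)

    g = nx.Graph()
    g.add_nodes_from(families)
    by_hit: dict[str, list[str]] = {}
    for fid, hit in family_hit.items():
        by_hit.setdefault(hit, []).append(fid)
    for fids in by_hit.values():
        for a, b in zip(fids, fids[1:]):
            g.add_edge(a, b)

    merged: dict[str, list[str]] = {}
    for comp in nx.connected_components(g):
        fids = sorted(comp)
        merged["+".join(fids)] = sorted(m for fid in fids for m in families[fid])
    return merged


def expansion_test(
    counts: dict[str, int],
    total_lengths: dict[str, float],
    focal_species: str,
    family_id: str = "",
    ratio: float = 1.5,
) -> ExpansionVerdict:
    """Apply the expansion criterion to one family.

    ``counts``/``total_lengths`` give, per species, the number of family
    members and their summed protein length.  Both the count ratio and the
    length ratio against the mean over non-focal species must strictly
    exceed ``ratio`` for the verdict to be *expanded*.
    """
    others = [sp for sp in counts if sp != focal_species]
    if len(others) < 2:
        raise ValueError("need members in at least 2 non-focal species")
    return ExpansionVerdict(
        family_id=family_id,
        focal_species=focal_species,
        focal_count=counts.get(focal_species, 0),
        focal_total_len=total_lengths.get(focal_species, 0.0),
        other_mean_count=sum(counts[sp] for sp in others) / len(others),
        other_mean_len=sum(total_lengths[sp] for sp in others) / len(others),
        ratio=ratio,
    )


def ortholog_categories(
    family_counts: dict[str, dict[str, int]],
    species: list[str],
    clades: dict[str, list[str]] | None = None,
    n_unclustered: int = 0,
) -> dict[str, int]:
    """Count families per ortholog category.

    Categories are evaluated in order for each family: ``1:1:1`` (single
    copy in every species), ``N:N:N`` (present in every species, multiple
    copies somewhere), one category per configured clade (present in exactly
    that clade's species), ``species-specific`` (members in exactly one
    species), ``patchy`` (anything else shared by >1 species).  The
    ``unclustered`` count (proteins outside any family) is passed through.
    """
    clades = clades or {}
    out = {cat: 0 for cat in ["1:1:1", "N:N:N", *clades, "patchy", "species-specific"]}
    out["unclustered"] = n_unclustered
    all_sp = set(species)
    for counts in family_counts.values():
        present = {sp for sp, c in counts.items() if c > 0}
        if present == all_sp:
            out["1:1:1" if all(counts[sp] == 1 for sp in species) else "N:N:N"] += 1
            continue
        for clade, members in clades.items():
            if present == set(members):
                out[clade] += 1
                break
        else:
            if len(present) == 1:
                out["species-specific"] += 1
            else:
                out["patchy"] += 1
    return out
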