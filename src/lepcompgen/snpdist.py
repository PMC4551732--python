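"""SNP-rate distributions in a diploid genome.

Given called SNPs, gene models, repeat annotation and a BED of
diploid-coverage regions, this module partitions the genome into region
classes (exon > intron > repeat > intergenic), computes SNP rates in
overlapping 1000-bp windows, extracts SNP-free segments, fits one- and
two-component Gaussian mixtures to the window rates by EM (BIC model
selection), and classifies coding SNPs as synonymous or non-synonymous.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from lepcompgen.io import GeneModel, ScaffoldRecord, SnpRecord, revcomp

__all__ = [
    "RegionPartition",
    "MixtureFit",
    "SubstitutionProfile",
    "partition_regions",
    "window_rates",
    "snp_free_segments",
    "fit_mixture",
    "select_model",
    "classify_snp_effect",
    "substitution_profiles",
    "CODON_TABLE",
]

Interval = tuple[int, int]

# standard genetic code, DNA codons
_AAS = "FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG"
_B = "TCAG"
CODON_TABLE: dict[str, str] = {
    a + b + c: _AAS[16 * i + 4 * j + k]
    for i, a in enumerate(_B)
    for j, b in enumerate(_B)
    for k, c in enumerate(_B)
}


# ---------------------------------------------------------------------------
# interval arithmetic (sorted, half-open, per scaffold)


def _merge(intervals: list[Interval]) -> list[Interval]:
    out: list[Interval] = []
    for s, e in sorted(intervals):
        if out and s <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out


def _subtract(a: list[Interval], b: list[Interval]) -> list[Interval]:
    """a \\ b, both sorted merged lists."""
    out: list[Interval] = []
    bi = 0
    for s, e in a:
        cur = s
        while bi < len(b) and b[bi][1] <= cur:
            bi += 1
        k = bi
        while k < len(b) and b[k][0] < e:
            bs, be = b[k]
            if bs > cur:
                out.append((cur, bs))
            cur = max(cur, be)
            k += 1
        if cur < e:
            out.append((cur, e))
    return out


def _intersect(a: list[Interval], b: list[Interval]) -> list[Interval]:
    out: list[Interval] = []
    i = j = 0
    while i < len(a) and j < len(b):
        s = max(a[i][0], b[j][0])
        e = min(a[i][1], b[j][1])
        if s < e:
            out.append((s, e))
        if a[i][1] < b[j][1]:
            i += 1
        else:
            j += 1
    return out


def _total(intervals: list[Interval]) -> int:
    return sum(e - s for s, e in intervals)


@dataclass
class RegionPartition:
    """Disjoint per-scaffold interval lists for the four region classes."""

    classes: dict[str, dict[str, list[Interval]]]  # class -> scaffold -> intervals

    CLASS_ORDER = ("exon", "intron", "repeat", "intergenic")

    def total_length(self, cls: str) -> int:
        return sum(_total(iv) for iv in self.classes[cls].values())


def partition_regions(
    genes: list[GeneModel],
    repeats: list[tuple[str, int, int]],
    scaffolds: list[ScaffoldRecord],
    diploid_bed: list[tuple[str, int, int]],
) -> RegionPartition:
    """Partition diploid-coverage regions into exon/intron/repeat/intergenic.

    Precedence where annotations overlap: exon > intron > repeat >
    intergenic.  Every class is intersected with the diploid-coverage BED, so
    the class lengths sum exactly to the diploid BED length.
    """
    known = {rec.id for rec in scaffolds}
    for g in genes:
        if g.scaffold not in known:
            raise ValueError(f"gene {g.gene_id} on unknown scaffold {g.scaffold!r}")

    exon: dict[str, list[Interval]] = {}
    genebody: dict[str, list[Interval]] = {}
    for g in genes:
        exon.setdefault(g.scaffold, []).extend(g.cds_intervals or [(g.start, g.end)])
        genebody.setdefault(g.scaffold, []).append((g.start, g.end))
    rep: dict[str, list[Interval]] = {}
    for scf, s, e in repeats:
        rep.setdefault(scf, []).append((s, e))
    dip: dict[str, list[Interval]] = {}
    for scf, s, e in diploid_bed:
        dip.setdefault(scf, []).append((s, e))

    classes: dict[str, dict[str, list[Interval]]] = {c: {} for c in RegionPartition.CLASS_ORDER}
    for rec in scaffolds:
        scf = rec.id
        d = _merge(dip.get(scf, []))
        if not d:
            continue
        ex = _merge(exon.get(scf, []))
        intron = _subtract(_merge(genebody.get(scf, [])), ex)
        repeat = _subtract(_subtract(_merge(rep.get(scf, [])), ex), intron)
        everything = [(0, rec.length)]
        intergenic = _subtract(_subtract(_subtract(everything, ex), intron), repeat)
        for cls, ivs in (
            ("exon", ex),
            ("intron", intron),
            ("repeat", repeat),
            ("intergenic", intergenic),
        ):
            clipped = _intersect(ivs, d)
            if clipped:
                classes[cls][scf] = clipped
    return RegionPartition(classes=classes)


def window_rates(
    snps: list[SnpRecord],
    partition: RegionPartition,
    window: int = 1000,
    step: int = 100,
) -> list[tuple[str, int, float, str]]:
    """SNP rates in overlapping windows, per region class.

    Windows are anchored every ``step`` bp within each region-class interval
    of length >= ``window``; a window inherits the class of its anchor
    interval and never straddles interval boundaries.  Returns
    ``(scaffold, start, rate, region_class)`` entries with
    ``rate = SNPs in window / window``.
    """
    pos_by_scf: dict[str, np.ndarray] = {}
    for scf in {s.scaffold for s in snps}:
        pos_by_scf[scf] = np.sort(
            np.array([s.pos for s in snps if s.scaffold == scf], dtype=np.int64)
        )
    out = []
    for cls in RegionPartition.CLASS_ORDER:
        for scf, ivs in partition.classes[cls].items():
            pos = pos_by_scf.get(scf, np.empty(0, dtype=np.int64))
            for s, e in ivs:
                if e - s < window:
                    continue
                starts = np.arange(s, e - window + 1, step)
                lo = np.searchsorted(pos, starts, side="left")
                hi = np.searchsorted(pos, starts + window, side="left")
                for st, c in zip(starts, hi - lo):
                    out.append((scf, int(st), c / window, cls))
    return out


def snp_free_segments(
    snps: list[SnpRecord],
    diploid_bed: list[tuple[str, int, int]],
    min_len: int = 1000,
) -> tuple[list[tuple[str, int, int]], int]:
    """Maximal SNP-free sub-intervals of the diploid regions.

    A SNP at position p splits its interval into [start, p) and [p+1, end).
    Returns segments of length >= ``min_len`` plus the global maximum length
    (0 when no segment qualifies).
    """
    by_scf: dict[str, list[Interval]] = {}
    for scf, s, e in diploid_bed:
        by_scf.setdefault(scf, []).append((s, e))
    pos_by_scf: dict[str, np.ndarray] = {}
    for s_rec in snps:
        pos_by_scf.setdefault(s_rec.scaffold, [])
    for scf in pos_by_scf:
        pos_by_scf[scf] = np.sort(
            np.array([s.pos for s in snps if s.scaffold == scf], dtype=np.int64)
        )
    segments = []
    max_len = 0
    for scf, ivs in sorted(by_scf.items()):
        pos = pos_by_scf.get(scf)
        if pos is None:
            pos = np.empty(0, dtype=np.int64)
        for s, e in _merge(ivs):
            inside = pos[(pos >= s) & (pos < e)]
            cur = s
            bounds = list(inside) + [e]
            for p in bounds:
                seg_end = int(p) if p != e else e
                if seg_end - cur > 0:
                    max_len = max(max_len, seg_end - cur)
                    if seg_end - cur >= min_len:
                        segments.append((scf, cur, seg_end))
                cur = int(p) + 1
    return segments, max_len


# ---------------------------------------------------------------------------
# Gaussian mixture by EM


@dataclass
class MixtureFit:
    n_components: int
    weights: np.ndarray
    means: np.ndarray
    sds: np.ndarray
    loglik: float
    bic: float
    n_iter: int
    converged: bool


def _normal_logpdf(x: np.ndarray, mu: float, sd: float) -> np.ndarray:
    return -0.5 * np.log(2 * np.pi) - np.log(sd) - 0.5 * ((x - mu) / sd) ** 2


def fit_mixture(
    rates: np.ndarray,
    k: int,
    tol: float = 1e-8,
    max_iter: int = 500,
    min_sd: float = 1e-12,
) -> MixtureFit:
    """Fit a k-component (k in {1, 2}) Gaussian mixture to window SNP rates.

    Deterministic quantile initialization: component j starts at the
    (2j-1)/(2k) quantile with equal weights and the pooled SD.  EM runs to a
    relative log-likelihood tolerance of ``tol`` or ``max_iter`` iterations;
    the log-likelihood is non-decreasing by construction.  BIC =
    -2 loglik + n_params ln n with n_params = 3k - 1.
    """
    x = np.asarray(rates, dtype=float)
    n = x.size
    if n < 50:
        raise ValueError("need at least 50 rates to fit a mixture")
    if k not in (1, 2):
        raise ValueError("k must be 1 or 2")
    if np.allclose(x, x[0]):
        if k == 2:
            raise ValueError("degenerate input: all rates identical")
        mu, sd = float(x[0]), min_sd
    if k == 1:
        mu = float(x.mean())
        sd = float(max(x.std(), min_sd))
        loglik = float(_normal_logpdf(x, mu, sd).sum())
        bic = -2 * loglik + 2 * np.log(n)
        return MixtureFit(1, np.array([1.0]), np.array([mu]), np.array([sd]), loglik, bic, 0, True)

    qs = [(2 * j + 1) / (2 * k) for j in range(k)]
    means = np.quantile(x, qs)
    sds = np.full(k, max(x.std(), min_sd))
    weights = np.full(k, 1.0 / k)

    prev_ll = -np.inf
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        logp = np.stack(
            [np.log(weights[j]) + _normal_logpdf(x, means[j], sds[j]) for j in range(k)]
        )
        mx = logp.max(axis=0)
        lse = mx + np.log(np.exp(logp - mx).sum(axis=0))
        ll = float(lse.sum())
        resp = np.exp(logp - lse)
        nk = resp.sum(axis=1)
        weights = nk / n
        means = (resp @ x) / nk
        sds = np.sqrt(np.maximum((resp * (x[None, :] - means[:, None]) ** 2).sum(axis=1) / nk, min_sd**2))
        if ll < prev_ll - 1e-9:
            raise AssertionError("EM log-likelihood decreased")
        if abs(ll - prev_ll) <= tol * (1 + abs(ll)):
            converged = True
            prev_ll = ll
            break
        prev_ll = ll
    order = np.argsort(means)
    bic = -2 * prev_ll + (3 * k - 1) * np.log(n)
    return MixtureFit(
        k, weights[order], means[order], sds[order], prev_ll, bic, it, converged
    )


def select_model(fit1: MixtureFit, fit2: MixtureFit) -> MixtureFit:
    """Choose between the 1- and 2-component fits by lower BIC."""
    return fit1 if fit1.bic <= fit2.bic else fit2


# ---------------------------------------------------------------------------
# synonymous / non-synonymous classification


def classify_snp_effect(
    snp: SnpRecord, gene: GeneModel, scaffold_seq: str
) -> str:
    """Classify a SNP as synonymous, nonsynonymous or noncoding.

    The SNP's CDS coordinate is found by summing CDS interval lengths up to
    its position; for minus-strand genes the CDS is read reverse-complemented
    so codons are always in coding orientation.  The reference base must
    agree with the scaffold sequence.
    """
    if not gene.coding or gene.cds_total_length % 3 != 0:
        raise ValueError(f"gene {gene.gene_id} is not a valid coding model")
    inside = any(s <= snp.pos < e for s, e in gene.cds_intervals)
    if not inside:
        return "noncoding"
    if scaffold_seq[snp.pos] != snp.ref:
        raise ValueError(
            f"SNP ref {snp.ref} at {snp.scaffold}:{snp.pos} disagrees with scaffold "
            f"base {scaffold_seq[snp.pos]}"
        )
    # position within the concatenated plus-strand CDS
    cds_pos = 0
    for s, e in gene.cds_intervals:
        if snp.pos < s:
            break
        if snp.pos < e:
            cds_pos += snp.pos - s
            break
        cds_pos += e - s
    cds_seq = "".join(scaffold_seq[s:e] for s, e in gene.cds_intervals)
    L = len(cds_seq)
    if gene.strand == "-":
        coding = revcomp(cds_seq)
        coding_pos = L - 1 - cds_pos
        ref_c, alt_c = revcomp(snp.ref), revcomp(snp.alt)
    else:
        coding = cds_seq
        coding_pos = cds_pos
        ref_c, alt_c = snp.ref, snp.alt
    ci = coding_pos // 3
    off = coding_pos % 3
    codon = coding[3 * ci : 3 * ci + 3]
    assert codon[off] == ref_c
    mutant = codon[:off] + alt_c + codon[off + 1 :]
    return "synonymous" if CODON_TABLE[codon] == CODON_TABLE[mutant] else "nonsynonymous"


@dataclass
class SubstitutionProfile:
    """Per-protein substitution load with a disorder mask."""

    protein_id: str
    length: int  # aa
    disorder_mask: np.ndarray  # bool, True = disordered
    substitution_count: int  # all nonsynonymous SNPs
    ordered_count: int  # nonsynonymous SNPs at ordered positions

    @property
    def ordered_length(self) -> int:
        return int((~self.disorder_mask).sum())

    @property
    def disordered_length(self) -> int:
        return int(self.disorder_mask.sum())


def substitution_profiles(
    snps: list[SnpRecord],
    genes: list[GeneModel],
    scaffold_seqs: dict[str, str],
    disorder_masks: dict[str, list[tuple[int, int]]] | None = None,
) -> list[SubstitutionProfile]:
    """Per-protein substitution profiles from nonsynonymous SNPs.

    ``disorder_masks`` maps a gene id to aa-coordinate half-open intervals of
    predicted disorder; positions inside the mask count toward the total but
    not the ordered-region count.
    """
    disorder_masks = disorder_masks or {}
    by_scf: dict[str, list[SnpRecord]] = {}
    for s in snps:
        by_scf.setdefault(s.scaffold, []).append(s)
    out = []
    for g in genes:
        if not g.coding or not g.cds_intervals:
            continue
        aa_len = g.cds_total_length // 3
        mask = np.zeros(aa_len, dtype=bool)
        for s, e in disorder_masks.get(g.gene_id, []):
            mask[s:e] = True
        total = ordered = 0
        seq = scaffold_seqs[g.scaffold]
        for snp in by_scf.get(g.scaffold, []):
            if not any(s <= snp.pos < e for s, e in g.cds_intervals):
                continue
            if classify_snp_effect(snp, g, seq) != "nonsynonymous":
                continue
            cds_pos = 0
            for s, e in g.cds_intervals:
                if snp.pos < e:
                    cds_pos += max(0, snp.pos - s)
                    break
                cds_pos += e - s
            if g.strand == "-":
                cds_pos = g.cds_total_length - 1 - cds_pos
            aa_pos = cds_pos // 3
            total += 1
            if not mask[aa_pos]:
                ordered += 1
        out.append(SubstitutionProfile(g.gene_id, aa_len, mask, total, ordered))
    return out
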