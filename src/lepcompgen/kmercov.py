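"""k-mer frequency histograms, heterozygosity peaks and coverage classes.

A diploid genome sequenced at depth *c* yields a bimodal k-mer multiplicity
histogram: k-mers from homozygous regions occur on both haplotypes and pile
up near *c*, while k-mers spanning a heterozygous site are haplotype-specific
and pile up near *c/2*.  The relative height of the two peaks indicates the
heterozygosity level.  The same logic applies to read-depth tracks: scaffolds
at roughly half the modal depth are candidate haplotype duplicates, and
windows far above it are candidate repeats.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import numpy as np

__all__ = [
    "KmerHistogram",
    "PeakCall",
    "kmer_histogram",
    "detect_peaks",
    "scaffold_coverage",
    "flag_high_coverage",
]

# 2-bit base codes; anything else (N, lowercase) maps to 4 = invalid
_CODE = np.full(256, 4, dtype=np.int64)
for i, b in enumerate("ACGT"):
    _CODE[ord(b)] = i


@dataclass
class KmerHistogram:
    """Counts of distinct canonical k-mers per multiplicity."""

    k: int
    counts: dict[int, int]

    @property
    def total_instances(self) -> int:
        """Total number of counted k-mer instances (sum multiplicity*count)."""
        return sum(m * c for m, c in self.counts.items())


@dataclass
class PeakCall:
    """Heterozygous (left) and homozygous (right) peaks of a k-mer histogram.

    ``het_depth``/``het_height`` are None for an effectively homozygous
    sample whose histogram shows a single peak.
    """

    hom_depth: int
    hom_height: float
    het_depth: int | None = None
    het_height: float | None = None

    @property
    def height_ratio(self) -> float | None:
        if self.het_height is None:
            return None
        return self.het_height / self.hom_height


def _kmer_codes(seq: str, k: int) -> np.ndarray:
    """Canonical integer codes of all k-mers of ``seq`` (N-containing skipped)."""
    codes = _CODE[np.frombuffer(seq.encode(), dtype=np.uint8)]
    n = len(codes) - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64)
    # rolling 2-bit encoding via cumulative polynomial trick
    valid = codes < 4
    window_valid = (
        np.convolve(valid.astype(np.int64), np.ones(k, dtype=np.int64), "valid") == k
    )
    safe = np.where(valid, codes, 0)
    weights = 4 ** np.arange(k - 1, -1, -1, dtype=np.int64)
    fwd = np.convolve(safe, weights[::-1], "valid")  # big-endian k-mer codes
    comp = np.where(valid, 3 - codes, 0)
    rev = np.convolve(comp, weights, "valid")  # reverse-complement codes
    canon = np.minimum(fwd, rev)
    return canon[window_valid]


def kmer_histogram(reads: list[str], k: int = 17) -> KmerHistogram:
    """Histogram of canonical k-mer multiplicities across a read set.

    k-mers are canonicalized to the lexicographic minimum of the k-mer and
    its reverse complement (hence ``k`` must be odd, so no k-mer is its own
    reverse complement); k-mers containing N are skipped.
    """
    if k % 2 == 0:
        raise ValueError("k must be odd (even k makes canonicalization ambiguous)")
    if not 3 <= k <= 31:
        raise ValueError("k must be in [3, 31]")
    counter: Counter[int] = Counter()
    chunk: list[np.ndarray] = []
    size = 0
    for read in reads:
        codes = _kmer_codes(read.upper(), k)
        if codes.size:
            chunk.append(codes)
            size += codes.size
        if size > 2_000_000:
            vals, cnts = np.unique(np.concatenate(chunk), return_counts=True)
            counter.update(dict(zip(vals.tolist(), cnts.tolist())))
            chunk, size = [], 0
    if chunk:
        vals, cnts = np.unique(np.concatenate(chunk), return_counts=True)
        counter.update(dict(zip(vals.tolist(), cnts.tolist())))
    hist: Counter[int] = Counter(counter.values())
    return KmerHistogram(k=k, counts=dict(hist))


def detect_peaks(
    hist: KmerHistogram,
    min_depth: int = 3,
    smooth_window: int = 3,
    min_rel_height: float = 0.05,
    min_separation: float = 0.3,
) -> PeakCall:
    """Locate the heterozygous and homozygous peaks of a k-mer histogram.

    The histogram is smoothed with a centered moving average (window
    ``smooth_window``), multiplicities below ``min_depth`` are ignored as
    sequencing-error k-mers, and the two largest local maxima are returned
    with the lower-multiplicity one as the heterozygous peak.  Two guards
    keep the caller honest on real-shaped histograms: a secondary maximum
    below ``min_rel_height`` times the main peak is treated as noise, and
    maxima whose multiplicities differ by less than ``min_separation``
    (relative) are jaggedness within one broad peak, so only the tallest
    survives.  The true het/hom peaks sit a factor 2 apart and are never
    suppressed.  With fewer than two surviving maxima the het fields are
    None.
    """
    if not hist.counts:
        raise ValueError("empty histogram")
    max_mult = max(hist.counts)
    y = np.zeros(max_mult + 1)
    for m, c in hist.counts.items():
        y[m] = c
    kernel = np.ones(smooth_window) / smooth_window
    ys = np.convolve(y, kernel, mode="same")

    # local maxima at multiplicity >= min_depth
    peaks: list[tuple[float, int]] = []
    for m in range(max(1, min_depth), max_mult + 1):
        left = ys[m - 1] if m - 1 >= 0 else -np.inf
        right = ys[m + 1] if m + 1 <= max_mult else -np.inf
        if ys[m] > left and ys[m] >= right and ys[m] > 0:
            peaks.append((ys[m], m))
    if not peaks:
        raise ValueError("no peaks found at multiplicity >= min_depth")
    peaks.sort(reverse=True)
    main_height = peaks[0][0]
    accepted: list[tuple[float, int]] = []
    for h, m in peaks:
        if h < min_rel_height * main_height:
            continue
        if all(abs(m - m0) / m0 >= min_separation for _, m0 in accepted):
            accepted.append((h, m))
    top = sorted(accepted[:2], key=lambda p: p[1])  # order by multiplicity
    if len(top) == 1:
        h, m = top[0]
        return PeakCall(hom_depth=m, hom_height=float(h))
    (hh, hm), (oh, om) = top
    return PeakCall(hom_depth=om, hom_height=float(oh), het_depth=hm, het_height=float(hh))


def scaffold_coverage(
    track: list[tuple[str, int, int, float]],
    diploid_bracket: tuple[float, float] = (0.75, 1.25),
) -> tuple[dict[str, float], tuple[float, float], float]:
    """Per-scaffold mean depth plus the diploid-coverage interval.

    The modal window depth (argmax of the rounded depth histogram) is taken
    as the expected diploid coverage; the diploid interval defaults to
    ``[0.75, 1.25]`` times the mode, a symmetric bracket that excludes the
    half-coverage peak of haplotype duplicates.  Per-scaffold means are
    length-weighted over windows.

    Returns ``(scaffold_means, (lo, hi), modal_depth)``.
    """
    if not track:
        raise ValueError("empty coverage track")
    depths = np.array([d for _, _, _, d in track])
    lens = np.array([e - s for _, s, e, _ in track], dtype=float)
    rounded = np.round(depths).astype(int)
    mode = int(np.bincount(rounded, weights=lens).argmax())
    interval = (diploid_bracket[0] * mode, diploid_bracket[1] * mode)

    sums: dict[str, float] = {}
    total: dict[str, float] = {}
    for (scf, s, e, d) in track:
        sums[scf] = sums.get(scf, 0.0) + d * (e - s)
        total[scf] = total.get(scf, 0.0) + (e - s)
    means = {scf: sums[scf] / total[scf] for scf in sums}
    return means, interval, float(mode)


def flag_high_coverage(
    track: list[tuple[str, int, int, float]], factor: float = 4.0
) -> list[tuple[str, int, int]]:
    """Repeat candidates: maximal runs of windows above ``factor`` x modal depth.

    Adjacent qualifying windows are merged; intervals are 0-based half-open.
    """
    _, _, mode = scaffold_coverage(track)
    threshold = factor * mode
    out: list[tuple[str, int, int]] = []
    for (scf, s, e, d) in sorted(track, key=lambda w: (w[0], w[1])):
        if d > threshold:
            if out and out[-1][0] == scf and out[-1][2] == s:
                out[-1] = (scf, out[-1][1], e)
            else:
                out.append((scf, s, e))
    return out
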