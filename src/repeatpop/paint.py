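"""In silico chromosome painting with cluster-diagnostic k-mers.

For a repeat cluster: count canonical 12-mers over its reads, keep the 100
most abundant, map them exactly (both strands) onto a genome, count hit
starts in 200 kb windows stepped by 100 kb, min/max-scale per cluster
across the whole genome, loess-smooth per chromosome for display, and
correlate the scaled track with windowed gene density.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats as sps

from ._utils import encode_seq, revcomp
from .simulate import ReadSet

DEFAULT_K = 12
DEFAULT_TOP = 100
DEFAULT_WINDOW = 200_000
DEFAULT_STEP = 100_000
DEFAULT_SPAN = 0.1


@dataclass(frozen=True)
class KmerProfile:
    """Top canonical k-mers of a cluster, counts non-increasing."""

    cluster_id: int
    k: int
    entries: tuple[tuple[str, int], ...]

    def kmers(self) -> list[str]:
        return [kmer for kmer, _ in self.entries]


@dataclass
class WindowTrack:
    """Windowed signal along one chromosome (0-based half-open windows)."""

    chrom: str
    windows: list[tuple[int, int]]
    raw: np.ndarray
    scaled: np.ndarray | None = None
    smoothed: np.ndarray | None = None
    gene_density: np.ndarray | None = None

    def midpoints(self) -> np.ndarray:
        return np.array([(s + e) / 2.0 for s, e in self.windows])


@dataclass(frozen=True)
class CorrelationResult:
    cluster_id: int
    genome_id: str
    pearson_r: float | None
    pearson_p: float | None
    spearman_rho: float | None
    spearman_p: float | None
    n_windows: int
    defined: bool = True


def canonical_kmer(kmer: str) -> str:
    """Lexicographic minimum of a k-mer and its reverse complement."""
    rc = revcomp(kmer)
    return kmer if kmer <= rc else rc


def _powers(k: int) -> np.ndarray:
    return 4 ** np.arange(k - 1, -1, -1, dtype=np.int64)


def _window_codes(codes: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """(k-mer integer codes per position, validity mask excluding N)."""
    n = len(codes)
    if n < k:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=bool)
    windows = np.lib.stride_tricks.sliding_window_view(codes, k)
    valid = ~(windows == 4).any(axis=1)
    safe = np.where(windows == 4, 0, windows).astype(np.int64)
    return safe @ _powers(k), valid


def _code_of(kmer: str) -> int:
    codes = encode_seq(kmer)
    if (codes > 3).any():
        raise ValueError(f"k-mer contains non-ACGT base: {kmer}")
    return int(codes.astype(np.int64) @ _powers(len(kmer)))


def top_kmers(
    reads: ReadSet | Sequence[str],
    k: int = DEFAULT_K,
    top: int = DEFAULT_TOP,
    cluster_id: int = 0,
) -> KmerProfile:
    """Exact canonical k-mer counts over cluster reads, top `top` kept.

    Ties at equal count are broken lexicographically. k-mers containing N
    are skipped. Errors if no read is at least k long.
    """
    seqs = [r.sequence for r in reads] if isinstance(reads, ReadSet) else list(reads)
    if not seqs:
        raise ValueError("no reads")
    chunks = []
    for seq in seqs:
        seq = seq.upper()
        codes_f, valid_f = _window_codes(encode_seq(seq), k)
        codes_r, valid_r = _window_codes(encode_seq(revcomp(seq)), k)
        if len(codes_f) == 0:
            continue
        # revcomp codes, reversed, align with forward positions
        codes_r = codes_r[::-1]
        valid_r = valid_r[::-1]
        canon = np.minimum(codes_f, codes_r)
        chunks.append(canon[valid_f & valid_r])
    if not chunks:
        raise ValueError(f"k={k} exceeds every read length")
    allc = np.concatenate(chunks)
    uniq, counts = np.unique(allc, return_counts=True)
    # sort by count desc then code asc (code order == lexicographic order)
    order = np.lexsort((uniq, -counts))[:top]
    basemap = np.frombuffer(b"ACGT", dtype=np.uint8)
    entries = []
    for idx in order:
        code = int(uniq[idx])
        digits = [(code >> (2 * (k - 1 - j))) & 3 for j in range(k)]
        entries.append((basemap[digits].tobytes().decode(), int(counts[idx])))
    return KmerProfile(cluster_id=cluster_id, k=k, entries=tuple(entries))


def map_kmers(
    profile: KmerProfile, genome: Mapping[str, str]
) -> dict[str, np.ndarray]:
    """Forward-strand start positions of every exact occurrence per chromosome.

    Each profile k-mer and its reverse complement are searched; overlapping
    occurrences all count. Hits from all k-mers are pooled.
    """
    k = profile.k
    targets = set()
    for kmer, _ in profile.entries:
        targets.add(_code_of(kmer))
        targets.add(_code_of(revcomp(kmer)))
    target_arr = np.fromiter(targets, dtype=np.int64)
    out: dict[str, np.ndarray] = {}
    for chrom, seq in genome.items():
        codes, valid = _window_codes(encode_seq(seq.upper()), k)
        if len(codes) == 0:
            out[chrom] = np.empty(0, dtype=np.int64)
            continue
        hit = np.isin(codes, target_arr) & valid
        out[chrom] = np.flatnonzero(hit).astype(np.int64)
    return out


def make_windows(
    length: int, width: int = DEFAULT_WINDOW, step: int = DEFAULT_STEP
) -> list[tuple[int, int]]:
    """Sliding windows: starts 0, step, ... while start < length.

    Ends truncate at the chromosome end (bedtools makewindows-compatible).
    """
    if width <= 0 or step <= 0:
        raise ValueError("width and step must be > 0")
    if length <= 0:
        raise ValueError("length must be > 0")
    return [(s, min(s + width, length)) for s in range(0, length, step)]


def window_counts(
    positions: np.ndarray, windows: Sequence[tuple[int, int]]
) -> np.ndarray:
    """Hit-start count per half-open window (overlap zones count twice)."""
    pos = np.sort(np.asarray(positions, dtype=np.int64))
    starts = np.array([w[0] for w in windows])
    ends = np.array([w[1] for w in windows])
    return (
        np.searchsorted(pos, ends, side="left")
        - np.searchsorted(pos, starts, side="left")
    ).astype(np.int64)


def scale_values(values: np.ndarray) -> np.ndarray:
    """Min/max scale to [0, 1]; a constant vector maps to zeros."""
    v = np.asarray(values, dtype=float)
    lo, hi = v.min(), v.max()
    if hi == lo:
        return np.zeros_like(v)
    return (v - lo) / (hi - lo)


def scale_tracks(tracks: Mapping[str, WindowTrack]) -> None:
    """Per-cluster genome-wide min/max scaling across all chromosomes."""
    raw = np.concatenate([t.raw for t in tracks.values()])
    lo, hi = raw.min(), raw.max()
    for t in tracks.values():
        if hi == lo:
            t.scaled = np.zeros(len(t.raw))
        else:
            t.scaled = (t.raw - lo) / (hi - lo)


def loess_smooth(
    values: np.ndarray, positions: np.ndarray | None = None, span: float = DEFAULT_SPAN
) -> np.ndarray:
    """Local linear regression with tricube weights at each input position.

    The neighborhood of each point is the ceil(span*n) nearest points, with
    weights (1-(d/h)^3)^3 for h the neighborhood radius. Fewer than 3
    points pass through unchanged. Exact on linear inputs.
    """
    if not 0 < span <= 1:
        raise ValueError("span must be in (0, 1]")
    y = np.asarray(values, dtype=float)
    n = len(y)
    if n < 3:
        return y.copy()
    x = np.arange(n, dtype=float) if positions is None else np.asarray(positions, float)
    r = max(2, int(np.ceil(span * n)))
    out = np.empty(n)
    for i in range(n):
        d = np.abs(x - x[i])
        idx = np.argpartition(d, min(r, n - 1))[: min(r + 1, n)]
        h = np.partition(d, min(r, n - 1))[min(r, n - 1)]
        if h == 0:
            out[i] = y[np.isclose(d, 0)].mean()
            continue
        w = np.clip(1 - (d / h) ** 3, 0, None) ** 3
        sw = w.sum()
        xm = (w * x).sum() / sw
        ym = (w * y).sum() / sw
        sxx = (w * (x - xm) ** 2).sum()
        if sxx <= 1e-12 * max(1.0, xm * xm):
            out[i] = ym
            continue
        beta = (w * (x - xm) * (y - ym)).sum() / sxx
        out[i] = ym + beta * (x[i] - xm)
    return out


def _merge_intervals(intervals: Sequence[tuple[int, int]]) -> list[tuple[int, int]]:
    merged: list[tuple[int, int]] = []
    for s, e in sorted(intervals):
        if merged and s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged


def gene_density(
    intervals: Sequence[tuple[int, int]],
    windows: Sequence[tuple[int, int]],
    chrom_length: int | None = None,
) -> np.ndarray:
    """Fraction of each window covered by the union of gene intervals."""
    for s, e in intervals:
        if s < 0 or e <= s:
            raise ValueError(f"invalid interval ({s}, {e})")
        if chrom_length is not None and e > chrom_length:
            raise ValueError(f"interval ({s}, {e}) beyond chromosome end {chrom_length}")
    merged = _merge_intervals(intervals)
    out = np.zeros(len(windows))
    for i, (ws, we) in enumerate(windows):
        cov = sum(max(0, min(ge, we) - max(gs, ws)) for gs, ge in merged)
        out[i] = cov / (we - ws)
    return out


def correlate(
    kmer_track: np.ndarray,
    density_track: np.ndarray,
    cluster_id: int = 0,
    genome_id: str = "genome",
) -> CorrelationResult:
    """Pearson and Spearman correlation over pooled windows.

    Zero variance in either track makes the correlation undefined, which is
    reported explicitly rather than propagated as NaN.
    """
    x = np.asarray(kmer_track, dtype=float)
    y = np.asarray(density_track, dtype=float)
    if len(x) != len(y):
        raise ValueError("tracks must cover the same windows")
    if len(x) < 3:
        raise ValueError("need >= 3 windows to correlate")
    if x.std() == 0 or y.std() == 0:
        return CorrelationResult(
            cluster_id, genome_id, None, None, None, None, len(x), defined=False
        )
    pr = sps.pearsonr(x, y)
    sr = sps.spearmanr(x, y)
    return CorrelationResult(
        cluster_id=cluster_id,
        genome_id=genome_id,
        pearson_r=float(pr.statistic),
        pearson_p=float(pr.pvalue),
        spearman_rho=float(sr.statistic),
        spearman_p=float(sr.pvalue),
        n_windows=len(x),
    )


@dataclass
class PaintResult:
    cluster_id: int
    genome_id: str
    profile: KmerProfile
    tracks: dict[str, WindowTrack]
    correlation: CorrelationResult
    per_chromosome: dict[str, CorrelationResult] = field(default_factory=dict)


def paint_cluster(
    reads: ReadSet | Sequence[str],
    genome: Mapping[str, str],
    genes: Sequence[tuple[str, int, int]],
    cluster_id: int = 0,
    genome_id: str = "genome",
    k: int = DEFAULT_K,
    top: int = DEFAULT_TOP,
    width: int = DEFAULT_WINDOW,
    step: int = DEFAULT_STEP,
    span: float = DEFAULT_SPAN,
    per_chromosome: bool = False,
) -> PaintResult:
    """Full painting of one cluster onto one genome.

    Correlation uses scaled-but-unsmoothed values pooled genome-wide;
    smoothing is for display. Multi-genome runs reuse the same profile and
    differ only in the mapping target.
    """
    profile = top_kmers(reads, k=k, top=top, cluster_id=cluster_id)
    return paint_profile(
        profile, genome, genes, genome_id=genome_id,
        width=width, step=step, span=span, per_chromosome=per_chromosome,
    )


def paint_profile(
    profile: KmerProfile,
    genome: Mapping[str, str],
    genes: Sequence[tuple[str, int, int]],
    genome_id: str = "genome",
    width: int = DEFAULT_WINDOW,
    step: int = DEFAULT_STEP,
    span: float = DEFAULT_SPAN,
    per_chromosome: bool = False,
) -> PaintResult:
    """Map an existing k-mer profile onto a genome and build all tracks."""
    hits = map_kmers(profile, genome)
    genes_by_chrom: dict[str, list[tuple[int, int]]] = {}
    for chrom, s, e in genes:
        genes_by_chrom.setdefault(chrom, []).append((s, e))
    tracks: dict[str, WindowTrack] = {}
    for chrom, seq in genome.items():
        windows = make_windows(len(seq), width, step)
        raw = window_counts(hits[chrom], windows)
        track = WindowTrack(chrom=chrom, windows=windows, raw=raw)
        track.gene_density = gene_density(
            genes_by_chrom.get(chrom, []), windows, chrom_length=len(seq)
        )
        tracks[chrom] = track
    scale_tracks(tracks)
    for track in tracks.values():
        track.smoothed = loess_smooth(track.scaled, track.midpoints(), span=span)
    pooled_x = np.concatenate([t.scaled for t in tracks.values()])
    pooled_y = np.concatenate([t.gene_density for t in tracks.values()])
    corr = correlate(pooled_x, pooled_y, profile.cluster_id, genome_id)
    result = PaintResult(
        cluster_id=profile.cluster_id,
        genome_id=genome_id,
        profile=profile,
        tracks=tracks,
        correlation=corr,
    )
    if per_chromosome:
        for chrom, t in tracks.items():
            if len(t.scaled) >= 3 and t.scaled.std() > 0 and t.gene_density.std() > 0:
                result.per_chromosome[chrom] = correlate(
                    t.scaled, t.gene_density, profile.cluster_id, f"{genome_id}:{chrom}"
                )
    return result
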