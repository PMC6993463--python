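"""Pairwise read similarity: seeded ungapped alignment scored in bits.

A desk-scale stand-in for an all-vs-all megablast run. For every diagonal
sharing at least one exact seed word on either strand, the scorer finds the
maximum-scoring ungapped segment containing a seed (exact, via prefix
sums), converts the best raw score to a bit-score with the Karlin-Altschul
formula, and discards hits below the reporting threshold. An import path
accepts externally computed BLAST tabular hits instead.
"""

from __future__ import annotations

import math
from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable, NamedTuple

from ._utils import revcomp
from .simulate import ReadSet


class SimilarityHit(NamedTuple):
    """Unordered read pair with the best bit-score (read_a < read_b)."""

    read_a: str
    read_b: str
    bitscore: float


@dataclass(frozen=True)
class ScoringParams:
    """Scorer parameters; defaults mimic megablast (+1/-2, 16 bp words)."""

    match: int = 1
    mismatch: int = -2
    seed_length: int = 16
    lam: float = 1.28
    k_const: float = 0.46
    min_report_bits: float = 100.0

    def __post_init__(self) -> None:
        if not (self.match > 0 > self.mismatch):
            raise ValueError("need match > 0 > mismatch")
        if self.seed_length < 8:
            raise ValueError("seed_length must be >= 8")
        if self.lam <= 0:
            raise ValueError("lambda must be > 0")
        if not 0 < self.k_const < 1:
            raise ValueError("K must be in (0, 1)")


DEFAULT_PARAMS = ScoringParams()


def bitscore(raw_score: float, params: ScoringParams = DEFAULT_PARAMS) -> float:
    """Karlin-Altschul bit-score: (lambda*S - ln K) / ln 2."""
    if raw_score < 0:
        raise ValueError("raw_score must be >= 0")
    return (params.lam * raw_score - math.log(params.k_const)) / math.log(2)


def _canonical(id_a: str, id_b: str, bits: float) -> SimilarityHit:
    if id_a <= id_b:
        return SimilarityHit(id_a, id_b, bits)
    return SimilarityHit(id_b, id_a, bits)


def seed_kmers(seq: str, k: int) -> dict[str, list[int]]:
    """Positions of each N-free k-mer in seq."""
    out: dict[str, list[int]] = defaultdict(list)
    for i in range(len(seq) - k + 1):
        kmer = seq[i : i + k]
        if "N" not in kmer:
            out[kmer].append(i)
    return out


def _best_raw_one_strand(
    a: str, b: str, index_a: dict[str, list[int]], params: ScoringParams
) -> int:
    """Best ungapped raw score over diagonals sharing a seed with b.

    Per diagonal the score is the maximum-scoring segment that fully
    contains at least one shared seed word: with prefix sums P, a seed at
    a-offset s gives max_{r >= s+k} P_r - min_{l <= s} P_l, answerable in
    O(1) per seed after one pass. Exact and mirror-symmetric.
    """
    k = params.seed_length
    match, mismatch = params.match, params.mismatch
    diags: dict[int, set[int]] = defaultdict(set)
    for j in range(len(b) - k + 1):
        kmer = b[j : j + k]
        if "N" in kmer:
            continue
        for i in index_a.get(kmer, ()):
            diags[i - j].add(i)
    best = 0
    for diag, ipos in diags.items():
        lo = max(0, diag)  # a-coordinates of the diagonal overlap
        hi = min(len(a), len(b) + diag)
        n = hi - lo
        prefix = [0] * (n + 1)
        for t in range(n):
            ca = a[lo + t]
            cb = b[lo + t - diag]
            prefix[t + 1] = prefix[t] + (
                match if (ca == cb and ca != "N") else mismatch
            )
        prefix_min = [0] * (n + 1)
        for t in range(1, n + 1):
            prefix_min[t] = min(prefix_min[t - 1], prefix[t])
        suffix_max = [0] * (n + 2)
        suffix_max[n] = prefix[n]
        for t in range(n - 1, -1, -1):
            suffix_max[t] = max(suffix_max[t + 1], prefix[t])
        for i in sorted(ipos):
            s = i - lo
            score = suffix_max[s + k] - prefix_min[s]
            if score > best:
                best = score
    return best


def score_pair(
    seq_a: str,
    seq_b: str,
    params: ScoringParams = DEFAULT_PARAMS,
    ids: tuple[str, str] = ("a", "b"),
) -> SimilarityHit | None:
    """Best seeded ungapped hit between two reads on either strand.

    Symmetric in its arguments; returns None when no shared seed exists or
    the best alignment scores below min_report_bits.
    """
    if not seq_a or not seq_b:
        raise ValueError("empty sequence")
    seq_a, seq_b = seq_a.upper(), seq_b.upper()
    index_a = seed_kmers(seq_a, params.seed_length)
    best = _best_raw_one_strand(seq_a, seq_b, index_a, params)
    best = max(best, _best_raw_one_strand(seq_a, revcomp(seq_b), index_a, params))
    if best <= 0:
        return None
    bits = bitscore(best, params)
    if bits < params.min_report_bits:
        return None
    return _canonical(ids[0], ids[1], bits)


def all_vs_all(
    reads: ReadSet, params: ScoringParams = DEFAULT_PARAMS
) -> list[SimilarityHit]:
    """All-pairs similarity, restricted to pairs sharing at least one seed.

    Equivalent to score_pair over every unordered pair: a pair with no
    shared seed on either strand cannot align at all under the seeded
    scorer, so only seed-sharing candidates are evaluated. Output is
    canonical (read_a < read_b), self-hit free, and at most one hit per
    pair (the maximum bit-score).
    """
    if len(reads) < 2:
        return []
    k = params.seed_length
    ids = reads.ids()
    seqs = [r.sequence.upper() for r in reads]
    bucket: dict[str, list[int]] = defaultdict(list)
    for idx, seq in enumerate(seqs):
        seen: set[str] = set()
        for strand_seq in (seq, revcomp(seq)):
            for i in range(len(strand_seq) - k + 1):
                kmer = strand_seq[i : i + k]
                if "N" in kmer:
                    continue
                canon = min(kmer, revcomp(kmer))
                if canon not in seen:
                    seen.add(canon)
                    bucket[canon].append(idx)
    candidates: set[tuple[int, int]] = set()
    for members in bucket.values():
        if len(members) < 2:
            continue
        for x in range(len(members)):
            for y in range(x + 1, len(members)):
                candidates.add((members[x], members[y]))
    hits: list[SimilarityHit] = []
    for x, y in sorted(candidates):
        hit = score_pair(seqs[x], seqs[y], params, ids=(ids[x], ids[y]))
        if hit is not None:
            hits.append(hit)
    return sorted(hits)


def import_hits(lines: Iterable[str]) -> list[SimilarityHit]:
    """Parse BLAST outfmt-6 rows into canonical deduplicated hits.

    Keeps the maximum bit-score per unordered pair and drops self-hits.
    Malformed rows raise with their line number.
    """
    best: dict[tuple[str, str], float] = {}
    for lineno, line in enumerate(lines, start=1):
        line = line.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) == 1:
            fields = line.split()
        if len(fields) < 12:
            raise ValueError(
                f"line {lineno}: expected >= 12 tab-separated fields, got {len(fields)}"
            )
        qid, sid = fields[0], fields[1]
        try:
            bits = float(fields[11])
        except ValueError as exc:
            raise ValueError(f"line {lineno}: bad bitscore {fields[11]!r}") from exc
        if qid == sid:
            continue
        key = (qid, sid) if qid <= sid else (sid, qid)
        if bits > best.get(key, float("-inf")):
            best[key] = bits
    return [SimilarityHit(a, b, s) for (a, b), s in sorted(best.items())]
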