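"""Internal k-mer seeded exact/near-exact matching primitives.

Shared by the repeat finder, the assembly merger, the isoform block
decomposition and the plastid-insertion scanner.  The strategy everywhere is
the same: exact k-mer seeds, grouped per diagonal into maximal exact runs,
then (optionally) runs merged across small mismatch gaps on the same diagonal
while the combined identity stays above a floor, and finally co-linear runs
on nearby diagonals chained into one local hit (tolerating short indels).
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass

from .genome_io import reverse_complement_seq

DEFAULT_K = 24


@dataclass
class Segment:
    """An (approximately) gap-free match q[q_start:q_end] ~ t[t_start:t_end]
    on one diagonal: equal lengths, ``mismatches`` differing positions."""

    q_start: int
    t_start: int
    length: int
    mismatches: int = 0

    @property
    def q_end(self) -> int:
        return self.q_start + self.length

    @property
    def t_end(self) -> int:
        return self.t_start + self.length

    @property
    def identity(self) -> float:
        return (self.length - self.mismatches) / self.length

    @property
    def diagonal(self) -> int:
        return self.t_start - self.q_start


@dataclass
class Hit:
    """A chained local similarity (may contain short indels between segments)."""

    q_start: int
    q_end: int
    t_start: int
    t_end: int
    matches: int

    @property
    def q_length(self) -> int:
        return self.q_end - self.q_start

    @property
    def t_length(self) -> int:
        return self.t_end - self.t_start

    @property
    def identity(self) -> float:
        return self.matches / max(self.q_length, self.t_length)


def kmer_index(t: str, k: int) -> dict[str, list[int]]:
    """Positions of every k-mer (k-mers containing N are skipped)."""
    idx: dict[str, list[int]] = defaultdict(list)
    for i in range(len(t) - k + 1):
        kmer = t[i:i + k]
        if "N" not in kmer:
            idx[kmer].append(i)
    return idx


def exact_segments(
    q: str,
    t: str,
    k: int = DEFAULT_K,
    index: dict | None = None,
    seed_filter=None,
    max_occ: int = 200,
) -> list[Segment]:
    """All maximal exact matches of length >= k between q and t (forward).

    ``seed_filter(qp, tp)``, if given, drops individual seeds (e.g. the
    trivial self-diagonal when q is t).  k-mers occurring more than
    ``max_occ`` times in t are skipped to bound worst-case cost.
    """
    idx = kmer_index(t, k) if index is None else index
    by_diag: dict[int, list[int]] = defaultdict(list)
    for qp in range(len(q) - k + 1):
        kmer = q[qp:qp + k]
        if "N" in kmer:
            continue
        positions = idx.get(kmer)
        if not positions or len(positions) > max_occ:
            continue
        for tp in positions:
            if seed_filter is None or seed_filter(qp, tp):
                by_diag[tp - qp].append(qp)

    segments = []
    for diag, qps in by_diag.items():
        qps.sort()
        run_start = prev = qps[0]
        for qp in qps[1:]:
            if qp == prev + 1:
                prev = qp
                continue
            segments.append(Segment(run_start, run_start + diag, prev - run_start + k))
            run_start = prev = qp
        segments.append(Segment(run_start, run_start + diag, prev - run_start + k))
    return segments


def merge_codiagonal(segments: list[Segment], min_identity: float,
                     max_gap: int = 500) -> list[Segment]:
    """Greedily join consecutive segments on one diagonal across mismatch-only
    gaps while the combined identity stays >= min_identity."""
    if min_identity >= 1.0:
        return list(segments)
    by_diag: dict[int, list[Segment]] = defaultdict(list)
    for s in segments:
        by_diag[s.diagonal].append(s)
    merged = []
    for diag, segs in by_diag.items():
        segs.sort(key=lambda s: s.q_start)
        cur = segs[0]
        for nxt in segs[1:]:
            gap = nxt.q_start - cur.q_end
            if 0 <= gap <= max_gap:
                total = nxt.q_end - cur.q_start
                mm = cur.mismatches + nxt.mismatches + gap
                if (total - mm) / total >= min_identity:
                    cur = Segment(cur.q_start, cur.t_start, total, mm)
                    continue
            merged.append(cur)
            cur = nxt
        merged.append(cur)
    return merged


def chain_colinear(segments: list[Segment], max_gap: int = 100) -> list[Hit]:
    """Chain co-linear segments whose q and t gaps are both within max_gap
    (short indels allowed) into local hits."""
    segs = sorted(segments, key=lambda s: (s.q_start, s.t_start))
    hits: list[Hit] = []
    used = [False] * len(segs)
    for i, s in enumerate(segs):
        if used[i]:
            continue
        used[i] = True
        hit = Hit(s.q_start, s.q_end, s.t_start, s.t_end,
                  s.length - s.mismatches)
        for j in range(i + 1, len(segs)):
            if used[j]:
                continue
            n = segs[j]
            qg = n.q_start - hit.q_end
            tg = n.t_start - hit.t_end
            if n.q_start > hit.q_end + max_gap:
                break
            if -max_gap <= qg <= max_gap and -max_gap <= tg <= max_gap:
                used[j] = True
                hit = Hit(hit.q_start, max(hit.q_end, n.q_end),
                          hit.t_start, max(hit.t_end, n.t_end),
                          hit.matches + n.length - n.mismatches)
        hits.append(hit)
    return hits


def local_hits(
    q: str,
    t: str,
    k: int = DEFAULT_K,
    min_len: int = 50,
    min_identity: float = 0.85,
    both_strands: bool = True,
    chain_gap: int = 100,
) -> list[tuple[Hit, str]]:
    """Local similarity hits between q and t, as (Hit, strand) with the hit's
    t coordinates always on the forward strand of t."""
    out: list[tuple[Hit, str]] = []
    strands = ["+", "-"] if both_strands else ["+"]
    for strand in strands:
        target = t if strand == "+" else reverse_complement_seq(t)
        segs = merge_codiagonal(exact_segments(q, target, k), min_identity)
        for hit in chain_colinear(segs, max_gap=chain_gap):
            if hit.q_length >= min_len and hit.identity >= min_identity:
                if strand == "-":
                    ts, te = len(t) - hit.t_end, len(t) - hit.t_start
                    hit = Hit(hit.q_start, hit.q_end, ts, te, hit.matches)
                out.append((hit, strand))
    return out


def hamming(a: str, b: str) -> int:
    if len(a) != len(b):
        raise ValueError("hamming requires equal lengths")
    return sum(x != y for x, y in zip(a, b))


def longest_common_exact(a: str, b: str, k: int = DEFAULT_K) -> Segment | None:
    """Longest maximal exact match between two strings, or None."""
    segs = exact_segments(a, b, k)
    return max(segs, key=lambda s: s.length, default=None)
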