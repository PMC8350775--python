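"""Discovery and naming of repeated sequence pairs in (circular) genomes.

Pairs are found by exact k-mer seeding on the doubled circular sequence with
co-diagonal merging across mismatch gaps down to an identity floor, reported
maximal, sorted by descending length and named R01..Rn.  Homologous repeats
in other genomes inherit the reference names via reciprocal best matching.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

from .genome_io import CircularGenome, Interval
from .seqmatch import DEFAULT_K, exact_segments, kmer_index, local_hits, merge_codiagonal


@dataclass
class RepeatPair:
    """Two near-identical genome intervals; the recombination substrate."""

    copy_a: Interval
    copy_b: Interval
    orientation: str  # "direct" | "inverted"
    length: int
    identity: float
    name: str = ""
    family: int = -1  # copies sharing >=80% span are grouped into one family
    seq: str = ""     # representative sequence (copy_a)

    def copies(self) -> tuple[Interval, Interval]:
        return self.copy_a, self.copy_b


def _circ_overlap(s1: int, l1: int, s2: int, l2: int, L: int) -> int:
    """Overlap in bp of two (possibly wrapping) intervals on a circle."""
    o = 0
    d = (s2 - s1) % L
    if d < l1:
        o = max(o, min(l1 - d, l2))
    d = (s1 - s2) % L
    if d < l2:
        o = max(o, min(l2 - d, l1))
    return o


def _interval(start: int, length: int, L: int) -> Interval:
    start %= L
    end = start + length
    return Interval(start, end if end <= L else end - L)


def _contained(inner_s: int, inner_l: int, outer_s: int, outer_l: int, L: int) -> bool:
    return (inner_s - outer_s) % L + inner_l <= outer_l


def find_repeats(
    genome: CircularGenome,
    min_len: int = 50,
    min_identity: float = 0.99,
    k: int = DEFAULT_K,
) -> list[RepeatPair]:
    """All maximal repeated pairs >= min_len at >= min_identity, both
    orientations, respecting circular topology.  Sorted by length descending.
    Tandem self-overlaps (copies sharing >50% of their span) are suppressed.
    """
    if min_len < k:
        raise ValueError(
            f"min_len={min_len} is below the seed size k={k}; pass a smaller k"
        )
    L = len(genome)
    circular = genome.topology == "circular"
    S = genome.seq + genome.seq if circular else genome.seq

    raw: list[tuple[int, int, int, int, str]] = []  # (sa, sb, length, mismatches, orient)

    # direct pairs: S vs S, above the main diagonal, excluding the trivial
    # self-image diagonals (offset == 0 mod L)
    idx = kmer_index(S, k)
    if circular:
        filt = lambda qp, tp: tp > qp and (tp - qp) % L != 0 and qp < L
    else:
        filt = lambda qp, tp: tp > qp
    segs = merge_codiagonal(exact_segments(S, S, k, index=idx, seed_filter=filt),
                            min_identity)
    for s in segs:
        raw.append((s.q_start, s.t_start, s.length, s.mismatches, "direct"))

    # inverted pairs: S vs revcomp(S); a match at (qp, tp) of length l puts the
    # second copy, in forward coordinates, at len(S) - tp - l
    from .genome_io import reverse_complement_seq

    T = reverse_complement_seq(S)
    segs = merge_codiagonal(exact_segments(S, T, k), min_identity)
    for s in segs:
        sb = len(S) - s.t_end
        if circular and s.q_start >= L:
            continue
        raw.append((s.q_start, sb, s.length, s.mismatches, "inverted"))

    pairs: list[RepeatPair] = []
    seen: set = set()
    for sa, sb, length, mm, orient in raw:
        if length < min_len or length > L:
            continue
        am, bm = sa % L, sb % L
        if am == bm:  # same genome locus (palindrome onto itself)
            continue
        key = (frozenset({(am, length), (bm, length)}), orient)
        if key in seen:
            continue
        seen.add(key)
        if _circ_overlap(am, length, bm, length, L) > 0.5 * length:
            continue  # tandem / self-overlapping
        a, b = sorted([am, bm])
        pairs.append(
            RepeatPair(
                copy_a=_interval(a, length, L),
                copy_b=_interval(b, length, L),
                orientation=orient,
                length=length,
                identity=(length - mm) / length,
            )
        )

    # drop pairs wholly contained in a longer pair of the same orientation at
    # a consistent offset (edge-truncated duplicates from the doubled string)
    pairs.sort(key=lambda p: -p.length)
    kept: list[RepeatPair] = []
    for p in pairs:
        pa, pb, pl = p.copy_a.start, p.copy_b.start, p.length
        redundant = False
        for q in kept:
            if q.orientation != p.orientation:
                continue
            qa, qb, ql = q.copy_a.start, q.copy_b.start, q.length
            for (xa, xb) in ((qa, qb), (qb, qa)):
                if not (_contained(pa, pl, xa, ql, L) and _contained(pb, pl, xb, ql, L)):
                    continue
                off_a = (pa - xa) % L
                if p.orientation == "direct":
                    if (pb - xb) % L == off_a:
                        redundant = True
                else:
                    if (ql - off_a - pl) % L == (pb - xb) % L:
                        redundant = True
            if redundant:
                break
        if not redundant:
            p.seq = genome.slice(p.copy_a)
            kept.append(p)

    _assign_families(kept, L)
    kept.sort(key=lambda p: (-p.length, p.copy_a.start, p.copy_b.start))
    return kept


def _assign_families(pairs: list[RepeatPair], L: int) -> None:
    """Union-find over copies: copies overlapping >=80% of the shorter one are
    the same copy; pairs link their two copies into one family."""
    copies: list[tuple[int, int]] = []  # (start, length)
    parent: list[int] = []

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i, j):
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[rj] = ri

    def copy_id(iv: Interval, length: int) -> int:
        for i, (s, l) in enumerate(copies):
            ov = _circ_overlap(iv.start, length, s, l, L)
            if ov >= 0.8 * length and ov >= 0.8 * l:  # reciprocal
                return i
        copies.append((iv.start, length))
        parent.append(len(copies) - 1)
        return len(copies) - 1

    links = []
    for p in pairs:
        ia = copy_id(p.copy_a, p.length)
        ib = copy_id(p.copy_b, p.length)
        links.append((p, ia, ib))
        union(ia, ib)

    roots: dict[int, int] = {}
    for p, ia, _ in links:
        r = find(ia)
        p.family = roots.setdefault(r, len(roots))


def name_repeats(pairs: list[RepeatPair], start: int = 1) -> list[RepeatPair]:
    """Assign names R01, R02, ... strictly by descending length; ties broken
    by the smaller copy_a.start."""
    ordered = sorted(pairs, key=lambda p: (-p.length, p.copy_a.start, p.copy_b.start))
    width = max(2, len(str(len(ordered) + start - 1)))
    return [replace(p, name=f"R{i + start:0{width}d}") for i, p in enumerate(ordered)]


def count_repeat_pairs(genome: CircularGenome, min_len: int = 50,
                       min_identity: float = 0.99) -> int:
    return len(find_repeats(genome, min_len=min_len, min_identity=min_identity))


def map_repeats_across_genomes(
    reference_named: list[RepeatPair],
    other_genome: CircularGenome,
    other_pairs: list[RepeatPair],
) -> list[RepeatPair]:
    """Give each other-genome pair the name of its reciprocal best reference
    match (>=80% identity over >=50% of the shorter length); the rest get
    fresh names continuing the reference series."""
    if any(not p.name for p in reference_named):
        raise ValueError("reference pairs must be named (run name_repeats first)")

    def matched_bases(a: str, b: str) -> int:
        hits = local_hits(a, b, min_len=24, min_identity=0.8)
        return max((h.matches for h, _ in hits), default=0)

    other = [
        p if p.seq else replace(p, seq=other_genome.slice(p.copy_a))
        for p in other_pairs
    ]
    n_ref, n_oth = len(reference_named), len(other)
    score = [[0] * n_ref for _ in range(n_oth)]
    for i, op in enumerate(other):
        for j, rp in enumerate(reference_named):
            m = matched_bases(rp.seq, op.seq)
            if m >= 0.5 * min(rp.length, op.length) and m > 0:
                score[i][j] = m

    best_for_other = [max(range(n_ref), key=lambda j: score[i][j], default=None)
                      if n_ref else None for i in range(n_oth)]
    best_for_ref = [max(range(n_oth), key=lambda i: score[i][j], default=None)
                    if n_oth else None for j in range(n_ref)]

    import re as _re

    used_indices = [int(m.group(1)) for p in reference_named
                    if (m := _re.match(r"R(\d+)$", p.name))]
    next_idx = max(used_indices, default=0) + 1
    width = max(2, len(str(next_idx)))

    out = []
    for i, p in enumerate(other):
        j = best_for_other[i]
        if j is not None and score[i][j] > 0 and best_for_ref[j] == i:
            out.append(replace(p, name=reference_named[j].name))
        else:
            out.append(replace(p, name=f"R{next_idx:0{width}d}"))
            next_idx += 1
    return out
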