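"""Block decomposition of circular genome pairs and the repeat-mediated
recombination equivalence test ("are these two circles isoforms?").

Two genomes are decomposed into maximal co-linear blocks of shared unique
k-mer anchors lying outside repeat copies.  Each genome then becomes a
circular signed sequence over block identifiers and repeat-family identifiers.
Recombination moves on such arrangements are:

  inversion  — crossover at two copies of one family in inverted relative
               orientation on one circle: the segment between them flips;
  fission    — crossover at two direct-orientation copies on one circle:
               the circle splits into two, one copy each;
  fusion     — crossover at one copy on each of two circles: they join
               (the second circle is reflected first if orientations oppose).

Equivalence is decided by breadth-first search over canonical states; states
may pass through multi-circle (subgenomic) intermediates but the endpoints
are single circles.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field

import numpy as np

from .genome_io import CircularGenome, Interval, reverse_complement_seq
from .repeat_finder import (RepeatPair, _circ_overlap, find_repeats,
                            map_repeats_across_genomes, name_repeats)
from .seqmatch import kmer_index, local_hits

ANCHOR_K = 31


@dataclass
class Block:
    """A maximal shared unique segment; one occurrence per genome."""

    id: str
    sequence: str
    occ_a: tuple[Interval, int]  # (interval, sign); sign is +1 in genome a
    occ_b: tuple[Interval, int]

    @property
    def length(self) -> int:
        return len(self.sequence)


Circle = tuple[tuple[str, int], ...]  # circular signed symbol sequence


@dataclass(frozen=True)
class BlockArrangement:
    """One or more circles of signed block/repeat-family symbols."""

    circles: tuple[Circle, ...]
    repeat_symbols: frozenset = frozenset()

    def canonical(self) -> "BlockArrangement":
        return BlockArrangement(
            tuple(sorted(_canon_circle(c) for c in self.circles)),
            self.repeat_symbols,
        )

    def symbol_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for c in self.circles:
            for sym, _ in c:
                counts[sym] = counts.get(sym, 0) + 1
        return counts


@dataclass
class IsoformVerdict:
    equivalent: bool | None  # None = undecided (search caps hit)
    moves: list = field(default_factory=list)  # (family, move type)
    differences: list = field(default_factory=list)
    status: str = "equivalent"
    path: list = field(default_factory=list)  # canonical states along the moves


def _canon_circle(c: Circle) -> Circle:
    """Lexicographically minimal rotation of the circle or of its reflection
    (reversed order, flipped signs)."""
    n = len(c)
    if n == 0:
        return c
    reflected = tuple((s, -g) for s, g in reversed(c))
    best = None
    for base in (c, reflected):
        for r in range(n):
            v = base[r:] + base[:r]
            if best is None or v < best:
                best = v
    return best


def _block_id(i: int) -> str:
    if i < 26:
        return chr(ord("A") + i)
    return f"B{i:02d}"


# ---------------------------------------------------------------------------
# anchors

def _unique_anchors(genome: CircularGenome, k: int) -> dict[str, tuple[int, int]]:
    """canonical k-mer -> (position, sign) for k-mers occurring exactly once
    on the circle counting both strands.  Palindromic k-mers are skipped."""
    L = len(genome)
    S = genome.seq + genome.seq[:k - 1] if genome.topology == "circular" else genome.seq
    occ: dict[str, list[tuple[int, int]]] = {}
    for p in range(L if genome.topology == "circular" else L - k + 1):
        f = S[p:p + k]
        if "N" in f:
            continue
        r = reverse_complement_seq(f)
        if f == r:
            continue
        canon, sign = (f, 1) if f < r else (r, -1)
        lst = occ.get(canon)
        if lst is None:
            occ[canon] = [(p, sign)]
        elif len(lst) < 3:
            lst.append((p, sign))
    return {c: lst[0] for c, lst in occ.items() if len(lst) == 1}


def _repeat_mask(L: int, copies) -> np.ndarray:
    mask = np.zeros(L, dtype=bool)
    for iv, _sym, _sign in copies:
        for p in iv.positions(L):
            mask[p] = True
    return mask


def _mask_any(csum: np.ndarray, L: int, start: int, end: int) -> bool:
    """Any masked position in circular range [start, end) (end may exceed L)."""
    start %= L
    end = start + (end - start)
    if end <= L:
        return bool(csum[end] - csum[start])
    return bool((csum[L] - csum[start]) or csum[end - L])


# ---------------------------------------------------------------------------
# repeat copies with family symbols and signs

def _distinct_copies(pairs: list[RepeatPair], L: int):
    """Distinct (interval, length) copies from a pair list, merged at >=80%
    overlap, each tagged with the family symbol (smallest pair name in the
    connected family) and the list of pairs touching it."""
    fam_name: dict[int, str] = {}
    for p in pairs:
        cur = fam_name.get(p.family)
        if cur is None or p.name < cur:
            fam_name[p.family] = p.name
    copies: list[list] = []  # [start, length, symbol]
    for p in pairs:
        sym = fam_name[p.family]
        for iv in p.copies():
            length = p.length
            for c in copies:
                ov = _circ_overlap(iv.start, length, c[0], c[1], L)
                if c[2] == sym and ov >= 0.8 * length and ov >= 0.8 * c[1]:
                    break
            else:
                copies.append([iv.start, length, sym])
    out = []
    for s, l, sym in copies:
        e = s + l
        out.append((Interval(s, e if e <= L else e - L), sym, 0))
    return out


def _copy_sign(genome: CircularGenome, iv: Interval, rep_seq: str, k: int = 24) -> int:
    """+1 if the copy reads in the representative's orientation, else -1,
    decided by shared k-mer counts."""
    c = genome.slice(iv)
    idx = kmer_index(rep_seq, k)
    fwd = sum(1 for i in range(0, max(1, len(c) - k + 1), k) if c[i:i + k] in idx)
    rc = reverse_complement_seq(c)
    rev = sum(1 for i in range(0, max(1, len(rc) - k + 1), k) if rc[i:i + k] in idx)
    return 1 if fwd >= rev else -1


# ---------------------------------------------------------------------------
# decomposition

class UnrelatedGenomes(ValueError):
    pass


@dataclass
class Decomposition:
    blocks: list[Block]
    arrangement_a: BlockArrangement
    arrangement_b: BlockArrangement
    private_a: list[Interval]
    private_b: list[Interval]
    families: dict[str, dict]  # symbol -> {"len_a", "len_b", "copies_a", "copies_b"}


def decompose_blocks(
    a: CircularGenome,
    b: CircularGenome,
    repeats_a: list[RepeatPair] | None = None,
    repeats_b: list[RepeatPair] | None = None,
    min_repeat: int = 500,
    k: int = ANCHOR_K,
) -> tuple[list[Block], BlockArrangement, BlockArrangement]:
    dec = decompose(a, b, repeats_a, repeats_b, min_repeat, k)
    return dec.blocks, dec.arrangement_a, dec.arrangement_b


def decompose(
    a: CircularGenome,
    b: CircularGenome,
    repeats_a: list[RepeatPair] | None = None,
    repeats_b: list[RepeatPair] | None = None,
    min_repeat: int = 500,
    k: int = ANCHOR_K,
) -> Decomposition:
    La, Lb = len(a), len(b)
    if repeats_a is None:
        repeats_a = find_repeats(a, min_len=min_repeat)
    if repeats_b is None:
        repeats_b = find_repeats(b, min_len=min_repeat)
    ra = name_repeats([p for p in repeats_a if p.length >= min_repeat])
    rb_raw = [p for p in repeats_b if p.length >= min_repeat]
    rb = map_repeats_across_genomes(ra, b, rb_raw) if ra or rb_raw else []

    rep_seqs: dict[str, str] = {}
    for p in ra:
        rep_seqs.setdefault(_family_symbol(ra, p), p.seq or a.slice(p.copy_a))
    for p in rb:
        rep_seqs.setdefault(_family_symbol(rb, p), p.seq or b.slice(p.copy_a))

    copies_a = [(iv, sym, _copy_sign(a, iv, rep_seqs[sym])) for iv, sym, _ in _distinct_copies(ra, La)]
    copies_b = [(iv, sym, _copy_sign(b, iv, rep_seqs[sym])) for iv, sym, _ in _distinct_copies(rb, Lb)]

    mask_a = _repeat_mask(La, copies_a)
    mask_b = _repeat_mask(Lb, copies_b)
    csum_a = np.concatenate([[0], np.cumsum(mask_a)])
    csum_b = np.concatenate([[0], np.cumsum(mask_b)])

    ua = _unique_anchors(a, k)
    ub = _unique_anchors(b, k)
    anchors = []
    for canon, (pa, sa) in ua.items():
        hit = ub.get(canon)
        if hit is None:
            continue
        pb, sb = hit
        if _mask_any(csum_a, La, pa, pa + k) or _mask_any(csum_b, Lb, pb, pb + k):
            continue
        anchors.append((pa, pb, sa * sb))
    if not anchors:
        raise UnrelatedGenomes(f"{a.id} and {b.id} share no unique anchors")
    anchors.sort()

    chains = _chain_anchors(anchors, csum_a, csum_b, La, Lb, k)
    blocks, occ_b_order = _chains_to_blocks(chains, a, b, La, Lb, k)

    arr_a = _build_arrangement(
        [(blk.occ_a[0], blk.id, blk.occ_a[1]) for blk in blocks] + copies_a,
        {sym for _, sym, _ in copies_a} | {sym for _, sym, _ in copies_b},
    )
    arr_b = _build_arrangement(
        [(blk.occ_b[0], blk.id, blk.occ_b[1]) for blk in blocks] + copies_b,
        {sym for _, sym, _ in copies_a} | {sym for _, sym, _ in copies_b},
    )

    private_a = _uncovered(La, [blk.occ_a[0] for blk in blocks] + [iv for iv, _, _ in copies_a])
    private_b = _uncovered(Lb, [blk.occ_b[0] for blk in blocks] + [iv for iv, _, _ in copies_b])

    families: dict[str, dict] = {}
    for sym in {s for _, s, _ in copies_a} | {s for _, s, _ in copies_b}:
        ca = [iv for iv, s, _ in copies_a if s == sym]
        cb = [iv for iv, s, _ in copies_b if s == sym]
        families[sym] = {
            "len_a": max((iv.length(La) for iv in ca), default=0),
            "len_b": max((iv.length(Lb) for iv in cb), default=0),
            "copies_a": len(ca),
            "copies_b": len(cb),
        }
    return Decomposition(blocks, arr_a, arr_b, private_a, private_b, families)


def _family_symbol(pairs: list[RepeatPair], p: RepeatPair) -> str:
    return min(q.name for q in pairs if q.family == p.family)


def _chain_anchors(anchors, csum_a, csum_b, La, Lb, k, slack: int = 100):
    """Group anchors (sorted by position in a) into maximal co-linear chains,
    breaking on sign changes, offset jumps, or intervening repeat copies."""

    def compatible(prev, nxt):
        pa0, pb0, s0 = prev
        pa1, pb1, s1 = nxt
        if s0 != s1:
            return False
        da = (pa1 - pa0) % La
        db = (pb1 - pb0) % Lb if s0 == 1 else (pb0 - pb1) % Lb
        if da == 0 or abs(db - da) > slack:
            return False
        if _mask_any(csum_a, La, pa0 + 1, pa0 + 1 + da):
            return False
        if s0 == 1:
            if _mask_any(csum_b, Lb, pb0 + 1, pb0 + 1 + db):
                return False
        else:
            if _mask_any(csum_b, Lb, pb1 + 1, pb1 + 1 + db):
                return False
        return True

    chains = [[anchors[0]]]
    for nxt in anchors[1:]:
        if compatible(chains[-1][-1], nxt):
            chains[-1].append(nxt)
        else:
            chains.append([nxt])
    # circular closure: merge last chain into first when they connect
    if len(chains) > 1 and compatible(chains[-1][-1], chains[0][0]):
        chains[0] = chains.pop() + chains[0]
    return chains


def _chains_to_blocks(chains, a, b, La, Lb, k):
    def iv(start, end, L):
        start %= L
        end = end % L if end % L != 0 else L if end >= L else end
        return Interval(start, end)

    raw = []
    for ch in chains:
        pa0, pb0, sign = ch[0]
        pa1, pb1, _ = ch[-1]
        span_a = (pa1 - pa0) % La + k
        span_b = ((pb1 - pb0) % Lb if sign == 1 else (pb0 - pb1) % Lb) + k
        if span_a >= La:  # one block covering the whole circle
            raw.append((Interval(0, La), Interval(0, Lb), sign))
            continue
        a_iv = iv(pa0, pa0 + span_a, La)
        if sign == 1:
            b_iv = iv(pb0, pb0 + span_b, Lb)
        else:
            b_iv = iv(pb1, pb1 + span_b, Lb)
        raw.append((a_iv, b_iv, sign))
    raw.sort(key=lambda r: -r[0].length(La))
    blocks = []
    for i, (a_iv, b_iv, sign) in enumerate(raw):
        blocks.append(Block(_block_id(i), a.slice(a_iv), (a_iv, 1), (b_iv, sign)))
    return blocks, None


def _build_arrangement(items, repeat_symbols) -> BlockArrangement:
    """items: (Interval, symbol, sign); one circle ordered by start position."""
    ordered = sorted(items, key=lambda t: (t[0].start, t[0].end))
    circle = tuple((sym, sign if sign != 0 else 1) for _, sym, sign in ordered)
    return BlockArrangement((circle,), frozenset(repeat_symbols))


def _uncovered(L: int, intervals: list[Interval], min_run: int = 100) -> list[Interval]:
    covered = np.zeros(L, dtype=bool)
    for iv in intervals:
        for p in iv.positions(L):
            covered[p] = True
    out = []
    run_start = None
    for p in range(L):
        if not covered[p] and run_start is None:
            run_start = p
        elif covered[p] and run_start is not None:
            if p - run_start >= min_run:
                out.append(Interval(run_start, p))
            run_start = None
    if run_start is not None and L - run_start >= min_run:
        # may continue across the origin into the first uncovered run
        end = L
        if out and out[0].start == 0:
            first = out.pop(0)
            out.append(Interval(run_start, first.end))
        else:
            out.append(Interval(run_start, end))
    return out


# ---------------------------------------------------------------------------
# moves

def _neighbors(state: tuple[Circle, ...], repeat_symbols: frozenset):
    """Yield (canonical successor state, (family, move_type))."""
    circles = list(state)
    for ci, c in enumerate(circles):
        pos: dict[str, list[int]] = {}
        for idx, (sym, _) in enumerate(c):
            if sym in repeat_symbols:
                pos.setdefault(sym, []).append(idx)
        for sym, idxs in pos.items():
            for x in range(len(idxs)):
                for y in range(x + 1, len(idxs)):
                    i, j = idxs[x], idxs[y]
                    si, sj = c[i][1], c[j][1]
                    if si != sj:  # inverted relative orientation -> inversion
                        seg = tuple((s, -g) for s, g in reversed(c[i + 1:j]))
                        new_c = c[:i + 1] + seg + c[j:]
                        yield _canon_state(circles[:ci] + [new_c] + circles[ci + 1:]), (sym, "inversion")
                    else:  # direct orientation -> fission into two circles
                        c1 = c[i:j]
                        c2 = c[j:] + c[:i]
                        yield _canon_state(circles[:ci] + [c1, c2] + circles[ci + 1:]), (sym, "fission")
    # fusion between circle pairs
    for ci in range(len(circles)):
        for cj in range(ci + 1, len(circles)):
            c1, c2 = circles[ci], circles[cj]
            syms1 = {s for s, _ in c1 if s in repeat_symbols}
            syms2 = {s for s, _ in c2 if s in repeat_symbols}
            for sym in syms1 & syms2:
                for i, (s1, g1) in enumerate(c1):
                    if s1 != sym:
                        continue
                    for j, (s2, g2) in enumerate(c2):
                        if s2 != sym:
                            continue
                        r1 = c1[i:] + c1[:i]
                        r2 = c2[j:] + c2[:j]
                        if g1 != g2:  # reflect second circle to match orientation
                            r2 = tuple((s, -g) for s, g in reversed(r2))
                            jj = next(idx for idx, (s, _) in enumerate(r2) if s == sym)
                            r2 = r2[jj:] + r2[:jj]
                        rest = [circles[x] for x in range(len(circles)) if x not in (ci, cj)]
                        yield _canon_state(rest + [r1 + r2]), (sym, "fusion")


def _canon_state(circles) -> tuple[Circle, ...]:
    return tuple(sorted(_canon_circle(tuple(c)) for c in circles))


def recombination_moves(state: BlockArrangement, repeats=None) -> set[BlockArrangement]:
    syms = state.repeat_symbols if repeats is None else frozenset(repeats)
    start = _canon_state(list(state.circles))
    out = set()
    for nxt, _label in _neighbors(start, syms):
        if nxt != start:
            out.add(BlockArrangement(nxt, syms))
    return out


# ---------------------------------------------------------------------------
# equivalence

def are_isoforms(
    a: CircularGenome,
    b: CircularGenome,
    min_repeat: int = 500,
    max_moves: int = 6,
    max_states: int = 100_000,
    repeats_a=None,
    repeats_b=None,
) -> IsoformVerdict:
    dec = decompose(a, b, repeats_a, repeats_b, min_repeat)
    differences = []
    for iv in dec.private_a:
        differences.append({"type": "private_segment", "genome": a.id,
                            "interval": (iv.start, iv.end)})
    for iv in dec.private_b:
        differences.append({"type": "private_segment", "genome": b.id,
                            "interval": (iv.start, iv.end)})
    ca = dec.arrangement_a.symbol_counts()
    cb = dec.arrangement_b.symbol_counts()
    for sym in sorted(set(ca) | set(cb)):
        if ca.get(sym, 0) != cb.get(sym, 0):
            differences.append({"type": "copy_number", "symbol": sym,
                                "count_a": ca.get(sym, 0), "count_b": cb.get(sym, 0)})
    if differences:
        return IsoformVerdict(False, [], differences, status="different")

    syms = dec.arrangement_a.repeat_symbols
    start = _canon_state(list(dec.arrangement_a.circles))
    goal = _canon_state(list(dec.arrangement_b.circles))
    if start == goal:
        return IsoformVerdict(True, [], [], status="equivalent", path=[start])

    visited = {start}
    parents: dict = {start: (None, None)}
    frontier = deque([(start, 0)])
    truncated = False
    while frontier:
        state, depth = frontier.popleft()
        if depth >= max_moves:
            truncated = True
            continue
        for nxt, label in _neighbors(state, syms):
            if nxt in visited:
                continue
            visited.add(nxt)
            parents[nxt] = (state, label)
            if nxt == goal:
                moves, path = [], [nxt]
                cur = nxt
                while parents[cur][0] is not None:
                    cur, lab = parents[cur]
                    moves.append(lab)
                    path.append(cur)
                moves.reverse()
                path.reverse()
                return IsoformVerdict(True, moves, [], status="equivalent", path=path)
            if len(visited) > max_states:
                truncated = True
                frontier.clear()
                break
            frontier.append((nxt, depth + 1))
    if truncated:
        return IsoformVerdict(None, [], [], status="undecided")
    return IsoformVerdict(
        False, [],
        [{"type": "order", "detail": "same content, not connected by repeat-mediated moves"}],
        status="different",
    )


# ---------------------------------------------------------------------------
# structural diff

def structural_diff(
    a: CircularGenome,
    b: CircularGenome,
    min_repeat: int = 500,
    repeats_a=None,
    repeats_b=None,
) -> dict:
    """Per-block placement table, private segments, repeat-length and
    copy-number differences, and candidate mediating families."""
    dec = decompose(a, b, repeats_a, repeats_b, min_repeat)
    La, Lb = len(a), len(b)

    def order_index(arr: BlockArrangement):
        return {(is_sym := sym): i for i, (sym, _) in enumerate(arr.circles[0])}

    oa, ob = order_index(dec.arrangement_a), order_index(dec.arrangement_b)
    block_rows = []
    for blk in dec.blocks:
        block_rows.append({
            "block": blk.id,
            "length": blk.length,
            "a_interval": (blk.occ_a[0].start, blk.occ_a[0].end),
            "a_sign": blk.occ_a[1],
            "a_order": oa.get(blk.id),
            "b_interval": (blk.occ_b[0].start, blk.occ_b[0].end),
            "b_sign": blk.occ_b[1],
            "b_order": ob.get(blk.id),
        })

    repeat_rows = []
    mediating = []
    for sym, info in sorted(dec.families.items()):
        row = {"family": sym, **info}
        if info["copies_a"] != info["copies_b"]:
            # a family with extra copies in one genome may have a single-copy
            # homolog in the other that the pair finder cannot see; count it
            other = b if info["copies_b"] < info["copies_a"] else a
            rep = _family_rep_seq(a, b, dec, sym)
            if rep:
                n = _count_occurrences(other, rep)
                key = "copies_b" if other is b else "copies_a"
                row[key + "_sequence_level"] = n
            mediating.append(sym)
        if info["len_a"] and info["len_b"] and info["len_a"] != info["len_b"]:
            row["length_difference"] = info["len_b"] - info["len_a"]
        repeat_rows.append(row)

    # families whose block context differs between genomes also mediate moves
    ctx_a = _family_context(dec.arrangement_a)
    ctx_b = _family_context(dec.arrangement_b)
    for sym in dec.families:
        if ctx_a.get(sym) != ctx_b.get(sym) and sym not in mediating:
            mediating.append(sym)

    return {
        "identical": not dec.private_a and not dec.private_b
                     and dec.arrangement_a.canonical() == dec.arrangement_b.canonical()
                     and len(dec.blocks) <= 1,
        "blocks": block_rows,
        "private_a": [(iv.start, iv.end) for iv in dec.private_a],
        "private_b": [(iv.start, iv.end) for iv in dec.private_b],
        "repeats": repeat_rows,
        "mediating_families": sorted(mediating),
    }


def _family_rep_seq(a, b, dec: Decomposition, sym: str) -> str:
    for g, arr in ((a, dec.arrangement_a), (b, dec.arrangement_b)):
        pass
    # blocks do not store family seqs; re-find from genome a or b
    for g in (a, b):
        pairs = name_repeats(find_repeats(g, min_len=50))
        for p in pairs:
            if p.name == sym:
                return p.seq
    return ""


def _count_occurrences(genome: CircularGenome, seq: str) -> int:
    S = genome.seq + genome.seq if genome.topology == "circular" else genome.seq
    hits = [h for h, _ in local_hits(seq, S, min_len=max(24, int(0.8 * len(seq))),
                                     min_identity=0.9)]
    # dedupe doubled-string images and overlapping hits
    L = len(genome)
    starts = sorted({h.t_start % L for h in hits if h.q_length >= 0.8 * len(seq)})
    merged = []
    for s in starts:
        if not merged or (s - merged[-1]) % L >= 0.5 * len(seq):
            merged.append(s)
    return len(merged)


def _family_context(arr: BlockArrangement) -> dict[str, frozenset]:
    """Multiset of signed neighbour symbols around each repeat-family copy."""
    ctx: dict[str, list] = {}
    for c in arr.circles:
        n = len(c)
        for i, (sym, sign) in enumerate(c):
            if sym not in arr.repeat_symbols:
                continue
            prev = c[(i - 1) % n]
            nxt = c[(i + 1) % n]
            if sign == -1:
                prev, nxt = (nxt[0], -nxt[1]), (prev[0], -prev[1])
            ctx.setdefault(sym, []).append((prev, nxt))
    return {sym: frozenset(v) for sym, v in ctx.items()}
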