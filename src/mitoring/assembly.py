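"""Post-assembler structural logic: repeat-contig flagging, circularization
of linear contigs, and merging of circular chromosomes by recombination-like
events at shared repeats."""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field

from .genome_io import CircularGenome, reverse_complement_seq
from .seqmatch import exact_segments, hamming, merge_codiagonal


class NoTerminalOverlap(ValueError):
    """Contig ends do not overlap above the requested thresholds."""


class NoSharedRepeat(ValueError):
    """The two circles share no repeat long enough to recombine at."""


class AnchorError(ValueError):
    """Contig extremities do not anchor consistently in the repeat."""


@dataclass
class AssemblyContig:
    id: str
    seq: str
    source: str = ""

    def __post_init__(self):
        self.seq = self.seq.upper()
        if not self.seq:
            raise ValueError(f"contig {self.id!r}: empty sequence")

    def __len__(self) -> int:
        return len(self.seq)


@dataclass
class ContigOverlapGraph:
    """Edges connect contig extremities: ends are 'L' (5') or 'R' (3')."""

    nodes: set[str] = field(default_factory=set)
    edges: list[tuple[tuple[str, str], tuple[str, str], int]] = field(default_factory=list)

    def add_edge(self, a: str, a_end: str, b: str, b_end: str, overlap: int = 0) -> None:
        for end in (a_end, b_end):
            if end not in ("L", "R"):
                raise ValueError(f"contig end must be 'L' or 'R', got {end!r}")
        self.nodes.update((a, b))
        self.edges.append(((a, a_end), (b, b_end), overlap))


def flag_repeat_contigs(graph: ContigOverlapGraph) -> list[str]:
    """Contigs with >=2 distinct neighbours on the left end AND >=2 on the
    right end — the signature of a repeat that links four other contigs."""
    neighbours: dict[tuple[str, str], set[str]] = defaultdict(set)
    for (a, a_end), (b, b_end), _ in graph.edges:
        neighbours[(a, a_end)].add(b)
        neighbours[(b, b_end)].add(a)
    return sorted(
        n for n in graph.nodes
        if len(neighbours[(n, "L")]) >= 2 and len(neighbours[(n, "R")]) >= 2
    )


def circularize_by_terminal_overlap(
    contig: AssemblyContig,
    min_overlap: int = 1000,
    min_identity: float = 0.99,
    seed: int = 24,
) -> CircularGenome:
    """Circularize a contig whose start overlaps its end.

    The overlap is the longest prefix~suffix match >= min_overlap at
    >= min_identity (gap-free); the circle keeps the prefix copy's bases at
    the junction and has length len(contig) - overlap.
    """
    s = contig.seq
    n = len(s)
    max_over = n - 1
    candidates: set[int] = set()
    # seeds taken from several prefix offsets so a mismatch in the first few
    # bases cannot hide the overlap
    for j in range(0, min(5 * seed, max(1, n - seed)), seed):
        probe = s[j:j + seed]
        start = 0
        while True:
            p = s.find(probe, max(start, j + 1))
            if p == -1:
                break
            start = p + 1
            o = n - (p - j)
            if min_overlap <= o <= max_over:
                candidates.add(o)
    best = None
    for o in sorted(candidates, reverse=True):
        mism = hamming(s[:o], s[n - o:])
        if (o - mism) / o >= min_identity:
            best = o
            break
    if best is None:
        raise NoTerminalOverlap(
            f"{contig.id}: no terminal overlap >= {min_overlap} bp at "
            f">= {min_identity:.2%} identity"
        )
    return CircularGenome(contig.id, s[: n - best], "circular")


def _max_anchor(fixed: str, movable: str, min_anchor: int, mode: str) -> int:
    """Longest exact anchor between a contig extremity and a repeat flank.

    mode 'prefix_vs_suffix': longest a with movable[:a] == fixed[-a:]
    mode 'suffix_vs_prefix': longest b with movable[-b:] == fixed[:b]
    """
    limit = min(len(fixed), len(movable))
    if mode == "prefix_vs_suffix":
        probe = movable[:min_anchor]
        best = 0
        start = 0
        while True:
            p = fixed.find(probe, start)
            if p == -1:
                break
            start = p + 1
            a = len(fixed) - p
            if a <= limit and movable[:a] == fixed[-a:]:
                best = max(best, a)
        return best
    probe = movable[-min_anchor:]
    best = 0
    start = 0
    while True:
        p = fixed.find(probe, start)
        if p == -1:
            break
        start = p + 1
        b = p + min_anchor
        if b <= limit and movable[-b:] == fixed[:b]:
            best = max(best, b)
    return best


def circularize_via_repeat(
    contig: AssemblyContig,
    repeat_sequence: str,
    min_anchor: int = 50,
) -> CircularGenome:
    """Circularize a contig whose two ends are partial copies of one repeat:
    contig = suffix(R, a) + U + prefix(R, b)  ->  circle = U + R.

    Resulting length = len(contig) - a - b + len(R).
    """
    R = repeat_sequence.upper()
    s = contig.seq
    if min_anchor < 12:
        raise ValueError("min_anchor must be >= 12")
    a = _max_anchor(R, s, min_anchor, "prefix_vs_suffix")     # contig start ~ R suffix
    b = _max_anchor(R, s, min_anchor, "suffix_vs_prefix")     # contig end ~ R prefix
    if a < min_anchor or b < min_anchor:
        # diagnose the same-flank situation for a clearer error
        wrong_a = s[:min_anchor] == R[:min_anchor]
        wrong_b = s[-min_anchor:] == R[-min_anchor:]
        if wrong_a or wrong_b:
            raise AnchorError(
                f"{contig.id}: contig extremities anchor the same repeat flank"
            )
        raise AnchorError(
            f"{contig.id}: extremities do not both anchor in the repeat "
            f"(anchors {a} and {b} bp, need >= {min_anchor})"
        )
    if a + b > len(R):
        raise AnchorError(
            f"{contig.id}: end anchors overlap inconsistently inside the repeat "
            f"({a} + {b} > {len(R)} bp)"
        )
    if a + b > len(s):
        raise AnchorError(f"{contig.id}: anchors longer than the contig")
    circle = s[a: len(s) - b] + R
    return CircularGenome(contig.id, circle, "circular")


def _longest_shared_segment(a: CircularGenome, b: CircularGenome, min_len: int,
                            k: int = 24):
    """Longest shared (near-)exact segment between two circles, searching both
    strands of b on doubled sequences.  Returns (a_start, b_start, length,
    strand) in forward genome coordinates, or None."""
    La, Lb = len(a), len(b)
    Sa = a.seq + a.seq if a.topology == "circular" else a.seq
    best = None
    for strand in ("+", "-"):
        sb = b.seq if strand == "+" else reverse_complement_seq(b.seq)
        Sb = sb + sb if b.topology == "circular" else sb
        segs = merge_codiagonal(exact_segments(Sa, Sb, k), 0.99)
        for s in segs:
            if s.q_start >= La or s.t_start >= Lb:
                continue
            length = min(s.length, La, Lb)
            if length < min_len:
                continue
            if best is None or length > best[2]:
                # b coordinate stays in the strand-matched frame: for '-' that
                # is the reverse complement of b, which the merge then rotates
                best = (s.q_start % La, s.t_start % Lb, length, strand)
    return best


def merge_circles_by_repeat(
    a: CircularGenome,
    b: CircularGenome,
    family=None,
    min_len: int = 50,
    report: dict | None = None,
) -> CircularGenome:
    """Fuse two circles by a recombination-like event at a shared repeat.

    ``family`` may be None (auto: the longest shared segment >= min_len) or a
    tuple (a_start, b_start, length, strand) giving the copy coordinates.
    The crossover is placed at the repeat midpoint; the product has length
    len(a) + len(b) and carries two copies of the shared repeat.
    """
    if a.topology != "circular" or b.topology != "circular":
        raise ValueError("merge requires two circular genomes")
    hit = family if family is not None else _longest_shared_segment(a, b, min_len)
    if hit is None:
        raise NoSharedRepeat(
            f"{a.id} and {b.id} share no repeat >= {min_len} bp"
        )
    sa, sb, length, strand = hit
    b_oriented = b if strand == "+" else b.reverse_complement()
    a_rot = a.rotate(sa)
    b_rot = b_oriented.rotate(sb)
    Ra, X = a_rot.seq[:length], a_rot.seq[length:]
    Rb, Y = b_rot.seq[:length], b_rot.seq[length:]
    m = length // 2
    merged = Ra[:m] + Rb[m:] + Y + Rb[:m] + Ra[m:] + X
    if report is not None:
        report.update({
            "a": a.id, "b": b.id,
            "a_copy_start": sa, "b_copy_start": sb,
            "repeat_length": length, "strand": strand,
            "crossover_offset": m,
            "merged_length": len(merged),
        })
    return CircularGenome(f"{a.id}+{b.id}", merged, "circular")
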