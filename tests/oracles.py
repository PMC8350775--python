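"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's seeded/chained matching machinery:
repeats are enumerated from full-length seed words with direct character
extension, and recombination reachability is enumerated at the raw sequence
level (string surgery), so they can arbitrate the package's answers.
"""

from collections import defaultdict, deque

_COMP = str.maketrans("ACGTN", "TGCAN")


def rc(s: str) -> str:
    return s.translate(_COMP)[::-1]


# ---------------------------------------------------------------------------
# exhaustive maximal repeated pairs (exact matches, circular)

def oracle_repeats(seq: str, min_len: int) -> set[tuple[int, int, int, str]]:
    """All maximal exact repeated pairs >= min_len on a circle, as
    (start_a, start_b, length, orientation) with start_a < start_b, tandem
    pairs (copies sharing >50% of their span) excluded."""
    L = len(seq)
    S = seq + seq
    m = min_len

    def char(p):
        return seq[p % L]

    idx = defaultdict(list)
    for i in range(L):
        idx[S[i:i + m]].append(i)

    results = set()

    def overlap(a, b, length):
        o = 0
        d = (b - a) % L
        if d < length:
            o = max(o, length - d)
        d = (a - b) % L
        if d < length:
            o = max(o, length - d)
        return o

    def add(a, b, length, orient):
        a, b = a % L, b % L
        if a == b:
            return
        if a > b:
            if orient == "direct":
                a, b = b, a
            else:
                a, b = b, a
        if overlap(a, b, length) > 0.5 * length:
            return
        results.add((a, b, length, orient))

    # direct
    for positions in idx.values():
        for x in range(len(positions)):
            for y in range(x + 1, len(positions)):
                i, j = positions[x], positions[y]
                if (j - i) % L == 0:
                    continue
                # extend left
                a, b, length = i, j, m
                steps = 0
                while length < L and char(a - 1) == char(b - 1) and steps < L:
                    a, b, length, steps = a - 1, b - 1, length + 1, steps + 1
                steps = 0
                while length < L and char(a + length) == char(b + length) and steps < L:
                    length, steps = length + 1, steps + 1
                add(a, b, length, "direct")

    # inverted: seq[i:i+m] == rc(seq[j:j+m])
    for i in range(L):
        word = rc(S[i:i + m])
        for j in idx.get(word, ()):
            if (j - i) % L == 0 and m % 2 == 1:
                continue
            a, b, length = i, j, m
            # left of copy A pairs with right of copy B
            steps = 0
            while length < L and char(a - 1) == rc(char(b + length)) and steps < L:
                a, length, steps = a - 1, length + 1, steps + 1
            steps = 0
            while length < L and char(a + length) == rc(char(b - 1)) and steps < L:
                b, length, steps = b - 1, length + 1, steps + 1
            if (a - b) % L == 0:
                continue
            add(a, b, length, "inverted")

    return results


def pairs_as_tuples(pairs, L) -> set[tuple[int, int, int, str]]:
    """RepeatPair list -> oracle tuple representation."""
    out = set()
    for p in pairs:
        a, b = p.copy_a.start, p.copy_b.start
        out.add((min(a, b), max(a, b), p.length, p.orientation))
    return out


# ---------------------------------------------------------------------------
# sequence-level recombination reachability

def seq_canon(s: str) -> str:
    best = None
    for base in (s, rc(s)):
        for i in range(len(base)):
            v = base[i:] + base[:i]
            if best is None or v < best:
                best = v
    return best


def _copies(circle: str, repeat: str):
    """(start, orientation) of every full copy of the repeat on the circle."""
    L = len(circle)
    D = circle + circle
    out = []
    for word, orient in ((repeat, 1), (rc(repeat), -1)):
        start = 0
        while True:
            p = D.find(word, start)
            if p == -1 or p >= L:
                break
            out.append((p, orient))
            start = p + 1
    return sorted(set(out))


def seq_neighbors(state: tuple[str, ...], repeats: list[str]) -> set[tuple[str, ...]]:
    """States one recombination away, at the raw sequence level."""
    out = set()
    circles = list(state)
    for ci, c in enumerate(circles):
        L = len(c)
        D = c + c
        for R in repeats:
            r = len(R)
            cops = _copies(c, R)
            for x in range(len(cops)):
                for y in range(x + 1, len(cops)):
                    (p1, o1), (p2, o2) = cops[x], cops[y]
                    if (p2 - p1) < r or (p1 + L - p2) < r:
                        continue  # overlapping copies
                    rest = circles[:ci] + circles[ci + 1:]
                    if o1 == o2:  # fission
                        c1, c2 = D[p1:p2], D[p2:p1 + L]
                        out.add(_canon_state(rest + [c1, c2]))
                    else:  # inversion of the in-between segment
                        new = D[p1:p1 + r] + rc(D[p1 + r:p2]) + D[p2:p1 + L]
                        out.add(_canon_state(rest + [new]))
    for ci in range(len(circles)):
        for cj in range(ci + 1, len(circles)):
            c1, c2 = circles[ci], circles[cj]
            for R in repeats:
                for p, o1 in _copies(c1, R):
                    for q, o2 in _copies(c2, R):
                        r1 = c1[p:] + c1[:p]
                        if o1 == o2:
                            r2 = c2[q:] + c2[:q]
                        else:
                            flipped = rc(c2)
                            q2 = len(c2) - q - len(R)
                            r2 = flipped[q2:] + flipped[:q2]
                        rest = [circles[x] for x in range(len(circles))
                                if x not in (ci, cj)]
                        out.add(_canon_state(rest + [r1 + r2]))
    out.discard(_canon_state(circles))
    return out


def _canon_state(circles) -> tuple[str, ...]:
    return tuple(sorted(seq_canon(c) for c in circles))


def seq_reachable(start: str, repeats: list[str], max_depth: int) -> dict[tuple[str, ...], int]:
    """BFS over raw-sequence states; returns state -> depth."""
    s0 = _canon_state([start])
    seen = {s0: 0}
    frontier = deque([s0])
    while frontier:
        state = frontier.popleft()
        d = seen[state]
        if d >= max_depth:
            continue
        for nxt in seq_neighbors(state, repeats):
            if nxt not in seen:
                seen[nxt] = d + 1
                frontier.append(nxt)
    return seen


def oracle_isoforms(a: str, b: str, repeats: list[str], max_depth: int = 4):
    """(equivalent, n_moves) by exhaustive sequence-level enumeration,
    judged at single-circle endpoints."""
    goal = _canon_state([b])
    reach = seq_reachable(a, repeats, max_depth)
    if goal in reach:
        return True, reach[goal]
    return False, None
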