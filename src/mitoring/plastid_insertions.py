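"""Detection and cross-genome classification of plastid-derived insertions
(MTPTs) in mitochondrial genomes."""

from __future__ import annotations

from dataclasses import dataclass, field

from .genome_io import CircularGenome, Interval
from .repeat_finder import find_repeats
from .seqmatch import kmer_index, local_hits


@dataclass
class InsertionCall:
    """A mitochondrial interval matched to a plastid interval."""

    mt_interval: Interval
    cp_interval: Interval
    strand: str
    identity: float
    length: int            # mt-side length (primary)
    cp_length: int = 0
    cp_genes: list[str] = field(default_factory=list)
    mt_id: str = ""
    cp_id: str = ""


def _largest_inverted_repeat(cp: CircularGenome, min_len: int = 1000):
    """The plastid inverted-repeat pair (IRa/IRb), if present."""
    pairs = [p for p in find_repeats(cp, min_len=min_len, min_identity=0.99)
             if p.orientation == "inverted"]
    return max(pairs, key=lambda p: p.length, default=None)


def find_insertions(
    mt: CircularGenome,
    cp: CircularGenome,
    min_len: int = 50,
    min_identity: float = 0.85,
    collapse_ir: bool = True,
    k: int = 24,
) -> list[InsertionCall]:
    """Plastid-similar segments of the mt genome, both strands, co-linear
    fragments within 100 bp merged, sorted by mt position.

    With ``collapse_ir`` hits falling in the second copy of the plastid
    inverted repeat are remapped onto the first copy, and duplicate calls
    sharing >90% of their mt span are collapsed.
    """
    Lm, Lc = len(mt), len(cp)
    Sm = mt.seq + mt.seq if mt.topology == "circular" else mt.seq
    Sc = cp.seq + cp.seq if cp.topology == "circular" else cp.seq

    calls: list[InsertionCall] = []
    for hit, strand in local_hits(Sm, Sc, k=k, min_len=min_len,
                                  min_identity=min_identity):
        if hit.q_start >= Lm or hit.q_length > Lm:
            continue  # doubled-string image
        ts = hit.t_start % Lc
        if hit.t_start >= Lc and strand == "+":
            continue
        if strand == "-" and hit.t_end > Lc and ts + hit.t_length > Lc and hit.t_start >= Lc:
            continue
        ms, me = hit.q_start % Lm, (hit.q_start + hit.q_length) % Lm or Lm
        if hit.q_start + hit.q_length <= Lm:
            me = hit.q_start + hit.q_length
        ce = ts + hit.t_length
        calls.append(InsertionCall(
            mt_interval=Interval(ms, me if me <= Lm else me - Lm),
            cp_interval=Interval(ts, ce if ce <= Lc else ce - Lc),
            strand=strand,
            identity=hit.identity,
            length=hit.q_length,
            cp_length=hit.t_length,
            mt_id=mt.id,
            cp_id=cp.id,
        ))

    calls = _dedupe_mt(calls, Lm)

    if collapse_ir:
        ir = _largest_inverted_repeat(cp)
        if ir is not None:
            calls = [_collapse_to_first_ir(c, ir, Lc) for c in calls]
            calls = _dedupe_mt(calls, Lm)

    for c in calls:
        c.cp_genes = sorted({
            a.name for a in cp.annotations
            if a.feature_type in ("gene", "CDS", "rRNA", "tRNA")
            and any(p.overlap(c.cp_interval, Lc) > 0 for p in a.parts)
        })
    calls.sort(key=lambda c: (c.mt_interval.start, c.mt_interval.end))
    return calls


def _dedupe_mt(calls: list[InsertionCall], Lm: int) -> list[InsertionCall]:
    """Keep calls disjoint on the mt side: among overlapping calls retain the
    longest (ties: highest identity, then smaller cp start)."""
    kept: list[InsertionCall] = []
    for c in sorted(calls, key=lambda c: (-c.length, -c.identity, c.cp_interval.start)):
        if all(c.mt_interval.overlap(k.mt_interval, Lm) == 0 for k in kept):
            kept.append(c)
    return kept


def _collapse_to_first_ir(call: InsertionCall, ir, Lc: int) -> InsertionCall:
    a, b = ir.copy_a, ir.copy_b  # a is the first copy (smaller start)
    civ = call.cp_interval
    if (civ.start - b.start) % Lc + civ.length(Lc) <= ir.length:
        off = (civ.start - b.start) % Lc
        # mirror within the inverted second copy onto the first copy
        new_end = a.start + (ir.length - off)
        new_start = new_end - civ.length(Lc)
        call.cp_interval = Interval(new_start % Lc, new_end % Lc or new_end)
        call.strand = "-" if call.strand == "+" else "+"
    return call


def classify_insertions(
    calls_per_genome: dict[str, list[InsertionCall]],
    genomes: dict[str, CircularGenome] | None = None,
    cp_length: int | None = None,
    flank: int = 300,
    locus_gap: int = 100,
) -> list[dict]:
    """Cluster insertions across genomes and label them shared or variable.

    Within each genome, calls within ``locus_gap`` bp on the mt side are first
    grouped into one insertion locus (a locus may comprise several plastid
    fragments).  Loci cluster across genomes when any member calls overlap
    reciprocally >=50% on the cp side, or — when ``genomes`` are supplied —
    when the mt sequences flanking the loci match, so mutually exclusive
    variants at one flanked locus land in the same cluster.
    """
    if len(calls_per_genome) < 2:
        raise ValueError("classification needs calls from >=2 genomes")

    loci: list[tuple[str, list[InsertionCall]]] = []
    for gid, cs in calls_per_genome.items():
        cur: list[InsertionCall] = []
        for c in sorted(cs, key=lambda c: c.mt_interval.start):
            if cur and c.mt_interval.start - cur[-1].mt_interval.end <= locus_gap:
                cur.append(c)
            else:
                if cur:
                    loci.append((gid, cur))
                cur = [c]
        if cur:
            loci.append((gid, cur))

    if cp_length is None:
        cp_length = max((max(c.cp_interval.start, c.cp_interval.end)
                         for _, ls in loci for c in ls), default=0) + 1

    n = len(loci)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i, j):
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[rj] = ri

    def cp_overlaps(ls1, ls2) -> bool:
        for c1 in ls1:
            for c2 in ls2:
                ov = c1.cp_interval.overlap(c2.cp_interval, cp_length)
                if ov >= 0.5 * c1.cp_interval.length(cp_length) and \
                   ov >= 0.5 * c2.cp_interval.length(cp_length):
                    return True
        return False

    for i in range(n):
        for j in range(i + 1, n):
            if loci[i][0] != loci[j][0] and cp_overlaps(loci[i][1], loci[j][1]):
                union(i, j)

    if genomes:
        flanks = [_locus_flanks(genomes[gid], ls, flank) for gid, ls in loci]
        for i in range(n):
            for j in range(i + 1, n):
                if find(i) == find(j) or loci[i][0] == loci[j][0]:
                    continue
                if _flanks_match(flanks[i], flanks[j]):
                    union(i, j)

    clusters: dict[int, list[int]] = {}
    for i in range(n):
        clusters.setdefault(find(i), []).append(i)

    all_genomes = sorted(calls_per_genome)
    rows = []
    for _, members in sorted(clusters.items(), key=lambda kv: min(kv[1])):
        per_genome: dict[str, list[dict]] = {}
        keys: dict[str, tuple] = {}
        for i in members:
            gid, ls = loci[i]
            per_genome.setdefault(gid, []).extend({
                "mt_interval": (c.mt_interval.start, c.mt_interval.end),
                "cp_interval": (c.cp_interval.start, c.cp_interval.end),
                "length": c.length,
                "genes": c.cp_genes,
            } for c in ls)
        for gid, vs in per_genome.items():
            keys[gid] = tuple(sorted(v["cp_interval"] for v in vs))
        absent = [g for g in all_genomes if g not in per_genome]
        variant_keys = set(keys.values())
        shared = not absent and len(variant_keys) == 1
        rows.append({
            "cluster": len(rows),
            "status": "shared" if shared else "variable",
            "genomes": per_genome,
            "absent": absent,
            "mutually_exclusive": len(variant_keys) > 1,
        })
    return rows


def _locus_flanks(genome: CircularGenome, locus: list[InsertionCall], flank: int):
    L = len(genome)
    start = min(c.mt_interval.start for c in locus)
    end = max(c.mt_interval.end for c in locus)
    left = Interval((start - flank) % L, start)
    right = Interval(end % L, (end + flank) % L or (end + flank))
    return genome.slice(left), genome.slice(right)


def _flanks_match(f1, f2, k: int = 24, min_frac: float = 0.5) -> bool:
    def share(a: str, b: str) -> float:
        if len(a) < k or len(b) < k:
            return 0.0
        idx = kmer_index(b, k)
        probes = range(0, len(a) - k + 1, k)
        hits = sum(1 for i in probes if a[i:i + k] in idx)
        return hits / max(1, len(list(probes)))

    return share(f1[0], f2[0]) >= min_frac and share(f1[1], f2[1]) >= min_frac
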