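"""Seeded generators for circular genomes with known ground truth: planted
repeat families, genes, plastid-derived insertions, partial editing sites,
isoform shuffles, terminal-overlap contigs and simulated pileups.

The background sequence is i.i.d. at the requested GC with a post-pass that
breaks any emergent repeat above half the planted minimum by point
substitution, so the planted truth is the complete truth.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .assembly import AssemblyContig
from .genome_io import (Annotation, CircularGenome, Interval, PileupColumn,
                        reverse_complement_seq)
from .repeat_finder import find_repeats


class UnsatisfiableSpec(ValueError):
    pass


@dataclass
class RepeatSpec:
    length: int
    orientation: str = "direct"  # direct | inverted
    copies: int = 2
    name: str = ""
    positions: list[int] | None = None  # optional fixed start positions
    nested_in: str | None = None        # embed inside this family's copies


@dataclass
class GeneSpec:
    name: str
    length: int
    strand: str = "+"
    feature_type: str = "CDS"


@dataclass
class InsertionSpec:
    length: int = 0
    cp_interval: tuple[int, int] | None = None  # slice of the cp genome
    name: str = ""
    strand: str = "+"


@dataclass
class EditingSpec:
    gene: str
    offset: int  # 0-based offset within the spliced CDS
    extent: float


# a generic mitochondrial gene complement: ~33 protein genes + 3 rRNAs
MITO_GENE_TEMPLATE: list[tuple[str, int, str]] = (
    [(f"nad{i}", 900 + 60 * i, "+" if i % 2 else "-") for i in range(1, 10)]
    + [(f"cox{i}", 780 + 90 * i, "+") for i in range(1, 4)]
    + [("cob", 1182, "-"), ("atp1", 1524, "+"), ("atp4", 594, "-"),
       ("atp6", 780, "+"), ("atp8", 480, "-"), ("atp9", 225, "+"),
       ("ccmB", 621, "+"), ("ccmC", 720, "-"), ("ccmFc", 1320, "+"),
       ("ccmFn", 1740, "-"), ("matR", 1968, "+"), ("mttB", 804, "-"),
       ("rpl5", 558, "+"), ("rpl16", 537, "+"), ("rps3", 1678 // 3 * 3, "+"),
       ("rps4", 1059, "-"), ("rps12", 378, "+"), ("rps13", 351, "-"),
       ("rpl2", 1029, "+"), ("rps7", 447, "-"), ("rps1", 570, "+")]
)
MITO_RRNA_TEMPLATE: list[tuple[str, int, str]] = [
    ("rrn18", 1935, "+"), ("rrn26", 3169, "+"), ("rrn5", 118, "+"),
]


@dataclass
class GenomeSpec:
    length: int
    gc: float = 0.45
    repeat_specs: list[RepeatSpec] = field(default_factory=list)
    gene_specs: list[GeneSpec] | str | None = None  # None, list, or "template"
    insertion_specs: list[InsertionSpec] = field(default_factory=list)
    editing_specs: list[EditingSpec] = field(default_factory=list)
    seed: int = 0
    id: str = "synthetic"
    cp_genome: CircularGenome | None = None  # source for cp-derived inserts
    break_emergent_below: int | None = None  # default: 25


def random_dna(rng: np.random.Generator, n: int, gc: float = 0.45) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(np.array(list("ACGT"))[rng.choice(4, size=n, p=p)])


_STOPS = {"TAA", "TAG", "TGA"}


def random_cds(rng: np.random.Generator, length: int, gc: float = 0.45) -> str:
    """ATG + non-stop codons + TAA, total = length (rounded up to codons)."""
    n_codons = max(3, (length + 2) // 3)
    codons = ["ATG"]
    while len(codons) < n_codons - 1:
        c = random_dna(rng, 3, gc)
        if c not in _STOPS and c != "ATG":
            codons.append(c)
    codons.append("TAA")
    return "".join(codons)


def generate_mitogenome(spec: GenomeSpec) -> tuple[CircularGenome, dict]:
    """Build the genome and a machine-readable truth record listing every
    planted repeat, gene, insertion and editing site with exact coordinates."""
    rng = np.random.default_rng(spec.seed)
    L = spec.length
    seq = list(random_dna(rng, L, spec.gc))

    gene_specs: list[GeneSpec] = []
    if spec.gene_specs == "template":
        gene_specs = [GeneSpec(n, l, s) for n, l, s in MITO_GENE_TEMPLATE]
        gene_specs += [GeneSpec(n, l, s, "rRNA") for n, l, s in MITO_RRNA_TEMPLATE]
    elif spec.gene_specs:
        gene_specs = list(spec.gene_specs)

    # ---- build the planted fragments -------------------------------------
    repeat_seqs: dict[str, str] = {}
    for i, rs in enumerate(spec.repeat_specs):
        if not rs.name:
            rs.name = f"P{i + 1:02d}"
        repeat_seqs[rs.name] = random_dna(rng, rs.length, spec.gc)
    # nesting: overwrite a window of the host family's sequence so every host
    # copy automatically carries the nested sequence
    for rs in spec.repeat_specs:
        if rs.nested_in:
            host = repeat_seqs.get(rs.nested_in)
            if host is None or rs.length > len(host):
                raise UnsatisfiableSpec(
                    f"repeat {rs.name}: cannot nest in {rs.nested_in!r}")
            off = int(rng.integers(0, len(host) - rs.length + 1))
            repeat_seqs[rs.nested_in] = (
                host[:off] + repeat_seqs[rs.name] + host[off + rs.length:]
            )
            repeat_seqs[rs.name + "__host_offset"] = str(off)

    gene_seqs: dict[str, str] = {}
    for gs in gene_specs:
        if gs.feature_type == "CDS":
            gene_seqs[gs.name] = random_cds(rng, gs.length, spec.gc)
        else:
            gene_seqs[gs.name] = random_dna(rng, gs.length, spec.gc)

    editing_by_gene: dict[str, list[EditingSpec]] = {}
    for es in spec.editing_specs:
        if es.gene not in gene_seqs:
            raise UnsatisfiableSpec(f"editing spec names unknown gene {es.gene!r}")
        s = gene_seqs[es.gene]
        if es.offset >= len(s):
            raise UnsatisfiableSpec(f"editing offset beyond gene {es.gene}")
        # the edited base must be a C in the coding orientation
        gene_seqs[es.gene] = s[:es.offset] + "C" + s[es.offset + 1:]
        editing_by_gene.setdefault(es.gene, []).append(es)

    insert_seqs: list[tuple[InsertionSpec, str]] = []
    for i, ins in enumerate(spec.insertion_specs):
        if not ins.name:
            ins.name = f"cp_insert{i + 1}"
        if ins.cp_interval is not None:
            if spec.cp_genome is None:
                raise UnsatisfiableSpec("insertion references cp_interval but no cp_genome given")
            frag = spec.cp_genome.slice(Interval(*ins.cp_interval))
        else:
            frag = random_dna(rng, ins.length, spec.gc)
        if ins.strand == "-":
            frag = reverse_complement_seq(frag)
        insert_seqs.append((ins, frag))

    # ---- placement --------------------------------------------------------
    fragments: list[tuple[str, str, object]] = []  # (kind, seq, spec)
    for rs in spec.repeat_specs:
        if rs.nested_in:
            extra = rs.copies - 2 * sum(
                1 for h in spec.repeat_specs if h.name == rs.nested_in
            )  # host pairs carry two embedded copies each
            for _ in range(max(0, extra if extra > 0 else rs.copies - 2)):
                fragments.append(("repeat_copy", repeat_seqs[rs.name], rs))
            continue
        r = repeat_seqs[rs.name]
        for ci in range(rs.copies):
            s = r if rs.orientation == "direct" or ci == 0 else reverse_complement_seq(r)
            fragments.append(("repeat_copy", s, rs))
    for gs in gene_specs:
        s = gene_seqs[gs.name]
        fragments.append(("gene", s if gs.strand == "+" else reverse_complement_seq(s), gs))
    for ins, frag in insert_seqs:
        fragments.append(("cp_insert", frag, ins))

    total = sum(len(s) for _, s, _ in fragments)
    if total > 0.8 * L:
        raise UnsatisfiableSpec(
            f"planted features ({total} bp) exceed 80% of genome length {L}")

    placed: list[tuple[int, int]] = []
    placements: list[tuple[str, int, str, object, int]] = []  # kind,start,seq,spec,copy_idx
    copy_counters: dict[int, int] = {}

    def fits(start: int, length: int) -> bool:
        end = start + length
        if end > L:
            return False
        return all(end <= s or start >= e for s, e in placed)

    fixed_iter: dict[int, int] = {}
    for kind, s, sp in fragments:
        length = len(s)
        start = None
        if isinstance(sp, RepeatSpec) and sp.positions:
            idx = fixed_iter.get(id(sp), 0)
            if idx < len(sp.positions):
                start = sp.positions[idx]
                fixed_iter[id(sp)] = idx + 1
                if not fits(start, length):
                    raise UnsatisfiableSpec(
                        f"fixed position {start} for {sp.name} collides or overflows")
        if start is None:
            for _ in range(2000):
                cand = int(rng.integers(0, L - length))
                if fits(cand, length):
                    start = cand
                    break
            else:
                raise UnsatisfiableSpec("could not place all features (genome too full)")
        placed.append((start, start + length))
        ci = copy_counters.get(id(sp), 0)
        copy_counters[id(sp)] = ci + 1
        placements.append((kind, start, s, sp, ci))
        seq[start:start + length] = s

    genome_seq = "".join(seq)

    # ---- annotations and truth -------------------------------------------
    annotations: list[Annotation] = []
    truth: dict = {"id": spec.id, "length": L, "seed": spec.seed,
                   "repeats": [], "genes": [], "insertions": [],
                   "editing_sites": []}
    rep_copies: dict[str, list[tuple[int, int, int]]] = {}
    for kind, start, s, sp, ci in placements:
        end = start + len(s)
        if kind == "repeat_copy":
            sign = 1 if (sp.orientation == "direct" or ci == 0) else -1
            rep_copies.setdefault(sp.name, []).append((start, end, sign))
            annotations.append(Annotation("repeat", [Interval(start, end)],
                                          "+" if sign == 1 else "-", sp.name))
        elif kind == "gene":
            annotations.append(Annotation(sp.feature_type, [Interval(start, end)],
                                          sp.strand, sp.name))
            truth["genes"].append({"name": sp.name, "start": start, "end": end,
                                   "strand": sp.strand, "type": sp.feature_type})
            for es in editing_by_gene.get(sp.name, []):
                if sp.strand == "+":
                    gpos = start + es.offset
                else:
                    gpos = end - 1 - es.offset
                truth["editing_sites"].append({
                    "gene": sp.name, "position": gpos, "strand": sp.strand,
                    "extent": es.extent, "cds_offset": es.offset,
                })
        elif kind == "cp_insert":
            annotations.append(Annotation("cp_insert", [Interval(start, end)],
                                          sp.strand, sp.name))
            truth["insertions"].append({
                "name": sp.name, "start": start, "end": end,
                "strand": sp.strand, "length": len(s),
                "cp_interval": list(sp.cp_interval) if sp.cp_interval else None,
            })

    # nested families also occur inside every host copy
    for rs in spec.repeat_specs:
        if not rs.nested_in:
            continue
        off = int(repeat_seqs[rs.name + "__host_offset"])
        for hs, he, hsign in rep_copies.get(rs.nested_in, []):
            if hsign == 1:
                s0 = hs + off
            else:
                s0 = he - off - rs.length
            rep_copies.setdefault(rs.name, []).append(
                (s0, s0 + rs.length, hsign))

    for name, copies in rep_copies.items():
        rs = next(r for r in spec.repeat_specs if r.name == name)
        truth["repeats"].append({
            "family": name, "length": rs.length, "orientation": rs.orientation,
            "copies": sorted(copies),
        })

    genome_seq = _divorce_flanks(genome_seq, rep_copies, placed, rng)
    genome_seq = _divorce_insertion_flanks(genome_seq, truth["insertions"],
                                           spec.cp_genome, placed, rng)
    genome = CircularGenome(spec.id, genome_seq, "circular", annotations)
    threshold = spec.break_emergent_below or 25
    genome = _break_emergent_repeats(genome, truth, rng, threshold)
    return genome, truth


_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


def _divorce_flanks(genome_seq: str, rep_copies: dict, placed: list,
                    rng: np.random.Generator) -> str:
    """Break chance base matches just outside planted repeat copies so each
    planted pair is maximal exactly at its planted boundaries."""
    seq = list(genome_seq)
    L = len(seq)

    def in_feature(p: int) -> bool:
        return any(s <= p < e for s, e in placed)

    def divorce(p1: int, p2: int, complemented: bool) -> bool:
        p1, p2 = p1 % L, p2 % L
        want_diff = (_COMP[seq[p1]] if complemented else seq[p1])
        if seq[p2] != want_diff:
            return False
        for target, ref in ((p2, p1), (p1, p2)):
            if not in_feature(target):
                avoid = {_COMP[seq[ref]] if complemented else seq[ref]}
                seq[target] = rng.choice([b for b in "ACGT" if b not in avoid])
                return True
        return False

    # with >2 copies a later fix can re-collide an earlier pair: iterate
    for _ in range(10):
        changed = False
        for copies in rep_copies.values():
            for i in range(len(copies)):
                for j in range(i + 1, len(copies)):
                    (s1, e1, g1), (s2, e2, g2) = copies[i], copies[j]
                    if g1 == g2:  # co-oriented: left~left, right~right
                        changed |= divorce(s1 - 1, s2 - 1, False)
                        changed |= divorce(e1, e2, False)
                    else:  # opposite: left of one ~ complement of right of other
                        changed |= divorce(s1 - 1, e2, True)
                        changed |= divorce(e1, s2 - 1, True)
        if not changed:
            break
    return "".join(seq)


def _divorce_insertion_flanks(genome_seq: str, insertions: list[dict],
                              cp: CircularGenome | None,
                              placed: list, rng: np.random.Generator) -> str:
    """Make the mt bases flanking each cp-derived insertion differ from the
    bases flanking its plastid source, so call boundaries are exact."""
    if cp is None:
        return genome_seq
    seq = list(genome_seq)
    L = len(seq)
    Lc = len(cp)

    def fix(mt_pos: int, cp_base: str):
        mt_pos %= L
        if any(s <= mt_pos < e for s, e in placed):
            return
        if seq[mt_pos] == cp_base:
            seq[mt_pos] = rng.choice([b for b in "ACGT" if b != cp_base])

    for rec in insertions:
        if not rec.get("cp_interval"):
            continue
        cs, ce = rec["cp_interval"]
        left_cp = cp.seq[(cs - 1) % Lc]
        right_cp = cp.seq[ce % Lc]
        if rec["strand"] == "+":
            fix(rec["start"] - 1, left_cp)
            fix(rec["end"], right_cp)
        else:
            fix(rec["start"] - 1, _COMP[right_cp])
            fix(rec["end"], _COMP[left_cp])
    return "".join(seq)


def _break_emergent_repeats(genome: CircularGenome, truth: dict,
                            rng: np.random.Generator, threshold: int,
                            max_rounds: int = 40) -> CircularGenome:
    """Point-substitute away repeats >= threshold not part of the plant."""
    L = len(genome)
    planted: list[tuple[int, int]] = []
    for rec in truth["repeats"]:
        planted.extend((s, e) for s, e, _ in rec["copies"])

    def is_planted(iv: Interval) -> bool:
        length = iv.length(L)
        return any(
            max(0, min(iv.end if not iv.wraps else L, e) - max(iv.start, s)) >= 0.5 * length
            for s, e in planted
        )

    protected = set()
    for rec in truth["editing_sites"]:
        protected.update(range(rec["position"] - 1, rec["position"] + 2))

    seq = list(genome.seq)
    k = min(24, threshold)
    for _ in range(max_rounds):
        g = CircularGenome(genome.id, "".join(seq), "circular")
        emergent = [p for p in find_repeats(g, min_len=threshold, min_identity=1.0, k=k)
                    if not (is_planted(p.copy_a) and is_planted(p.copy_b))]
        if not emergent:
            genome = CircularGenome(genome.id, "".join(seq), "circular",
                                    genome.annotations)
            return genome
        for p in emergent:
            for iv in (p.copy_b, p.copy_a):
                positions = [q for q in iv.positions(L)
                             if q not in protected and not any(s <= q < e for s, e in planted)]
                if positions:
                    q = positions[len(positions) // 2]
                    cur = seq[q]
                    seq[q] = rng.choice([b for b in "ACGT" if b != cur])
                    break
    raise UnsatisfiableSpec("could not eliminate emergent repeats")


def generate_plastid(
    length: int,
    genes: list[tuple[str, int, int, str]],  # (name, start, glen, strand)
    ir: tuple[int, int, int] | None = None,  # (start_a, start_b, ir_len)
    seed: int = 0,
    gc: float = 0.37,
    id: str = "cp",
) -> CircularGenome:
    """A plastid-like genome with gene annotations and an optional inverted
    repeat (the second copy is the reverse complement of the first)."""
    rng = np.random.default_rng(seed)
    seq = list(random_dna(rng, length, gc))
    if ir:
        sa, sb, il = ir
        core = random_dna(rng, il, gc)
        seq[sa:sa + il] = core
        seq[sb:sb + il] = reverse_complement_seq(core)
    anns = [Annotation("gene", [Interval(s, s + gl)], strand, name)
            for name, s, gl, strand in genes]
    return CircularGenome(id, "".join(seq), "circular", anns)


# ---------------------------------------------------------------------------
# isoform shuffling

class NoEligibleFamily(ValueError):
    pass


def shuffle_isoform(
    genome: CircularGenome,
    truth: dict,
    n_moves: int,
    seed: int = 0,
    min_repeat: int = 500,
) -> tuple[CircularGenome, list]:
    """Apply n random inversion moves at inverted repeat pairs, keeping a
    single circle; returns the shuffled genome and a replayable move log."""
    rng = np.random.default_rng(seed)
    copies = {
        rec["family"]: [list(c) for c in rec["copies"]]
        for rec in truth["repeats"] if rec["length"] >= min_repeat
    }
    seq = genome.seq
    L = len(seq)
    log = []
    for _ in range(n_moves):
        eligible = []
        for fam, cs in copies.items():
            for i in range(len(cs)):
                for j in range(i + 1, len(cs)):
                    if cs[i][2] != cs[j][2]:  # opposite signs -> inversion
                        eligible.append((fam, i, j))
        if not eligible:
            raise NoEligibleFamily(
                f"no repeat family >= {min_repeat} bp with inverted copies")
        fam, i, j = eligible[int(rng.integers(0, len(eligible)))]
        c1, c2 = sorted((copies[fam][i], copies[fam][j]), key=lambda c: c[0])
        e1, s2 = c1[1], c2[0]
        seq = seq[:e1] + reverse_complement_seq(seq[e1:s2]) + seq[s2:]
        # remap every copy lying inside the inverted window
        for cs in copies.values():
            for c in cs:
                if e1 <= c[0] and c[1] <= s2:
                    c[0], c[1] = e1 + (s2 - c[1]), e1 + (s2 - c[0])
                    c[2] = -c[2]
        log.append({"family": fam, "type": "inversion",
                    "window": [e1, s2]})
    return CircularGenome(genome.id + "_iso", seq, "circular"), log


# ---------------------------------------------------------------------------
# inverse assembly operations

def fragment_with_overlap(genome: CircularGenome, cut: int, overlap: int) -> AssemblyContig:
    """Linearize a circle at ``cut`` duplicating the first ``overlap`` bases
    at the end; circularizing the result recovers a rotation of the input."""
    if overlap >= len(genome):
        raise ValueError("overlap must be shorter than the genome")
    if genome.topology != "circular":
        raise ValueError("fragment_with_overlap needs a circular genome")
    rotated = genome.rotate(cut).seq
    return AssemblyContig(genome.id + "_contig", rotated + rotated[:overlap])


def split_by_direct_repeat(
    genome: CircularGenome,
    family: str,
    truth: dict,
) -> tuple[CircularGenome, CircularGenome]:
    """Fission at two direct copies of a family: two circles whose lengths
    sum to the original."""
    rec = next((r for r in truth["repeats"] if r["family"] == family), None)
    if rec is None:
        raise KeyError(f"family {family!r} not in truth record")
    direct = [(s, e, g) for s, e, g in rec["copies"]]
    same_sign = [
        (a, b) for i, a in enumerate(direct) for b in direct[i + 1:]
        if a[2] == b[2]
    ]
    if not same_sign:
        raise ValueError(f"family {family!r} has no two direct-orientation copies")
    (s1, e1, _), (s2, e2, _) = sorted(same_sign[0], key=lambda c: c[0])
    seq = genome.seq
    c1 = CircularGenome(genome.id + "_sub1", seq[s1:s2], "circular")
    c2 = CircularGenome(genome.id + "_sub2", seq[s2:] + seq[:s1], "circular")
    return c1, c2


# ---------------------------------------------------------------------------
# pileup simulation

def simulate_pileups(
    genome: CircularGenome,
    annotations,
    editing_sites: list[dict],
    depth: int = 100,
    seed: int = 0,
    error_rate: float = 0.002,
    region: Interval | None = None,
) -> list[PileupColumn]:
    """Binomial sampling of edited-base counts at planted sites, uniform
    error rate elsewhere; every position gets a column (reference-only
    outside planted sites)."""
    if depth <= 0:
        raise ValueError("depth must be positive")
    rng = np.random.default_rng(seed)
    L = len(genome)
    by_pos = {rec["position"]: rec for rec in editing_sites}
    positions = range(L) if region is None else region.positions(L)
    bases = "ACGT"
    cols = []
    for p in positions:
        ref = genome.seq[p]
        if ref == "N":
            continue
        counts = [0, 0, 0, 0]
        rec = by_pos.get(p)
        if rec is not None:
            edited_base = "T" if rec["strand"] == "+" else "A"
            n_ed = int(rng.binomial(depth, rec["extent"]))
            counts[bases.index(edited_base)] += n_ed
            counts[bases.index(ref)] += depth - n_ed
        else:
            counts[bases.index(ref)] = depth
        if error_rate > 0:
            new = [0, 0, 0, 0]
            for bi in range(4):
                n = counts[bi]
                if n == 0:
                    continue
                errs = int(rng.binomial(n, error_rate))
                new[bi] += n - errs
                for _ in range(errs):
                    other = [x for x in range(4) if x != bi]
                    new[other[int(rng.integers(0, 3))]] += 1
            counts = new
        cols.append(PileupColumn(genome.id, p, ref, tuple(counts)))
    return cols


def truth_to_json(truth: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(truth, fh, indent=1)
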