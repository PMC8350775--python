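"""Data model for circular genomes plus FASTA/GFF3/BED/pileup/newick readers and writers.

Internal coordinates are 0-based half-open everywhere.  Conversion to the
1-based inclusive conventions of GFF3 (and 1-based positions in reports)
happens only at file boundaries.  Features spanning the origin of a circular
sequence are stored with ``start > end`` and an explicit flag; in GFF3 they
are encoded as two-part features sharing an ``ID``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

VALID_RESIDUES = frozenset("ACGTN")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

GENE_LIKE = frozenset({"gene", "CDS", "rRNA", "tRNA", "orf", "dpo", "rpo"})
FEATURE_TYPES = GENE_LIKE | {"cp_insert", "repeat"}


class GenomeIOError(ValueError):
    """Malformed input file or invalid coordinate."""


def reverse_complement_seq(s: str) -> str:
    return s.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class Interval:
    """0-based half-open interval.  ``start > end`` means origin-spanning
    (only meaningful on a circular sequence)."""

    start: int
    end: int

    @property
    def wraps(self) -> bool:
        return self.start > self.end

    def length(self, genome_length: int | None = None) -> int:
        if not self.wraps:
            return self.end - self.start
        if genome_length is None:
            raise ValueError("origin-spanning interval needs the genome length")
        return genome_length - self.start + self.end

    def positions(self, genome_length: int):
        """Yield every genome position covered, in 5'->3' order."""
        if not self.wraps:
            yield from range(self.start, self.end)
        else:
            yield from range(self.start, genome_length)
            yield from range(0, self.end)

    def contains(self, pos: int, genome_length: int | None = None) -> bool:
        if not self.wraps:
            return self.start <= pos < self.end
        return pos >= self.start or pos < self.end

    def overlap(self, other: "Interval", genome_length: int) -> int:
        """Number of shared positions on a circle of the given length."""
        mine = set(self.positions(genome_length))
        return sum(1 for p in other.positions(genome_length) if p in mine)


@dataclass
class Annotation:
    """A genome feature.  ``parts`` holds one interval per exon/segment in
    annotation (5'->3' transcript) order; simple features have one part."""

    feature_type: str
    parts: list[Interval]
    strand: str = "+"
    name: str = ""
    qualifiers: dict = field(default_factory=dict)

    @property
    def interval(self) -> Interval:
        return self.parts[0]

    def span_length(self, genome_length: int) -> int:
        return sum(p.length(genome_length) for p in self.parts)

    def contains(self, pos: int, genome_length: int) -> bool:
        return any(p.contains(pos, genome_length) for p in self.parts)


@dataclass
class CircularGenome:
    """A DNA sequence with circular or linear topology and annotations."""

    id: str
    seq: str
    topology: str = "circular"
    annotations: list[Annotation] = field(default_factory=list)

    def __post_init__(self):
        self.seq = self.seq.upper()
        if not self.seq:
            raise GenomeIOError(f"record {self.id!r}: empty sequence")
        bad = re.search(r"[^ACGTN]", self.seq)
        if bad:
            raise GenomeIOError(
                f"record {self.id!r}: invalid residue {bad.group()!r} at offset {bad.start()}"
            )
        if self.topology not in ("circular", "linear"):
            raise GenomeIOError(f"record {self.id!r}: bad topology {self.topology!r}")

    def __len__(self) -> int:
        return len(self.seq)

    @property
    def length(self) -> int:
        return len(self.seq)

    def slice(self, interval: Interval) -> str:
        """Extract residues, resolving origin-spanning intervals."""
        if not interval.wraps:
            return self.seq[interval.start:interval.end]
        if self.topology != "circular":
            raise GenomeIOError("origin-spanning interval on a linear sequence")
        return self.seq[interval.start:] + self.seq[:interval.end]

    def feature_seq(self, ann: Annotation) -> str:
        """Spliced feature sequence: parts joined in order, minus strand
        reverse-complemented."""
        s = "".join(self.slice(p) for p in ann.parts)
        return reverse_complement_seq(s) if ann.strand == "-" else s

    def rotate(self, offset: int) -> "CircularGenome":
        """New genome starting at ``offset`` of this one; annotations remapped."""
        if self.topology != "circular":
            raise GenomeIOError("cannot rotate a linear sequence")
        L = len(self.seq)
        offset %= L
        seq = self.seq[offset:] + self.seq[:offset]

        def shift(iv: Interval) -> Interval:
            s = (iv.start - offset) % L
            e = (iv.end - offset) % L
            if iv.length(L) == L:  # full-circle feature
                return Interval(s, s + L) if s == 0 else Interval(s, s)
            if e == 0 and not (s == 0 and iv.length(L) == 0):
                e = L
            if s >= e and iv.length(L) > 0 and e != L:
                return Interval(s, e)  # wraps after shift
            return Interval(s, e)

        anns = [replace(a, parts=[shift(p) for p in a.parts]) for a in self.annotations]
        return CircularGenome(self.id, seq, self.topology, anns)

    def reverse_complement(self) -> "CircularGenome":
        L = len(self.seq)
        seq = reverse_complement_seq(self.seq)

        def flip(iv: Interval) -> Interval:
            if not iv.wraps:
                return Interval(L - iv.end, L - iv.start)
            # wrapping [s, L) + [0, e) maps to wrapping [L-e, L) + [0, L-s)
            return Interval((L - iv.end) % L, L - iv.start)

        anns = []
        for a in self.annotations:
            strand = {"+": "-", "-": "+"}.get(a.strand, a.strand)
            anns.append(replace(a, strand=strand, parts=[flip(p) for p in reversed(a.parts)]))
        return CircularGenome(self.id, seq, self.topology, anns)


@dataclass(frozen=True)
class PileupColumn:
    """Per-position base counts of reads reported on the reference forward
    strand.  ``position`` is 0-based internally."""

    seq_id: str
    position: int
    ref_base: str
    counts: tuple[int, int, int, int]  # A, C, G, T

    @property
    def depth(self) -> int:
        return sum(self.counts)

    def count(self, base: str) -> int:
        return self.counts["ACGT".index(base)]

    def fraction(self, base: str) -> float:
        d = self.depth
        if d == 0:
            raise ZeroDivisionError(f"zero depth at position {self.position + 1}")
        return self.count(base) / d


# ---------------------------------------------------------------------------
# FASTA

def read_fasta(path, default_topology: str = "circular") -> list[CircularGenome]:
    """Read FASTA records.  Topology comes from a ``topology=`` header token,
    falling back to ``default_topology``."""
    genomes = []
    for rec in SeqIO.parse(str(path), "fasta"):
        topo = default_topology
        for token in rec.description.split()[1:]:
            if token.startswith("topology="):
                topo = token.split("=", 1)[1]
        genomes.append(CircularGenome(rec.id, str(rec.seq), topo))
    if not genomes:
        raise GenomeIOError(f"{path}: no FASTA records")
    return genomes


def write_fasta(genomes, path) -> None:
    records = [
        SeqRecord(Seq(g.seq), id=g.id, description=f"topology={g.topology}")
        for g in genomes
    ]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# GFF3

def read_gff3(path, genome: CircularGenome) -> list[Annotation]:
    """Parse GFF3 (1-based inclusive) into 0-based half-open annotations.
    Rows sharing an ID become one multi-part annotation; a two-part feature
    whose parts abut the origin is collapsed into a single wrapping interval."""
    L = len(genome)
    groups: dict[str, Annotation] = {}
    order: list[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise GenomeIOError(f"{path}:{lineno}: expected 9 columns")
            seqid, _src, ftype, start, end, _score, strand, _phase, attrs = cols
            if seqid != genome.id:
                raise GenomeIOError(f"{path}:{lineno}: unknown seq_id {seqid!r}")
            start_i, end_i = int(start), int(end)
            if not (1 <= start_i <= end_i <= L):
                raise GenomeIOError(f"{path}:{lineno}: coordinates out of range")
            attr_map = dict(
                kv.split("=", 1) for kv in attrs.split(";") if "=" in kv
            )
            fid = attr_map.get("ID", f"_anon{lineno}")
            name = attr_map.get("Name", attr_map.get("gene", fid))
            iv = Interval(start_i - 1, end_i)
            if fid in groups:
                groups[fid].parts.append(iv)
            else:
                quals = {k: v for k, v in attr_map.items() if k not in ("ID", "Name")}
                groups[fid] = Annotation(ftype, [iv], strand, name, quals)
                order.append(fid)

    anns = []
    for fid in order:
        a = groups[fid]
        if len(a.parts) == 2:
            p1, p2 = a.parts
            if p1.end == L and p2.start == 0:
                a.parts = [Interval(p1.start, p2.end)]
            elif p2.end == L and p1.start == 0:
                a.parts = [Interval(p2.start, p1.end)]
        anns.append(a)
    return anns


def write_gff3(genome: CircularGenome, path, annotations=None) -> None:
    L = len(genome)
    anns = genome.annotations if annotations is None else annotations
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        fh.write(f"##sequence-region {genome.id} 1 {L}\n")
        for i, a in enumerate(anns):
            fid = a.qualifiers.get("_id", f"{a.feature_type}{i:05d}")
            parts = []
            for p in a.parts:
                if p.wraps:
                    parts.extend([Interval(p.start, L), Interval(0, p.end)])
                else:
                    parts.append(p)
            for p in parts:
                attrs = f"ID={fid};Name={a.name}" if a.name else f"ID={fid}"
                for k, v in a.qualifiers.items():
                    if not k.startswith("_"):
                        attrs += f";{k}={v}"
                fh.write(
                    f"{genome.id}\tmitoring\t{a.feature_type}\t{p.start + 1}\t{p.end}"
                    f"\t.\t{a.strand}\t.\t{attrs}\n"
                )


# ---------------------------------------------------------------------------
# BED (BED4, 0-based half-open — identical to internal convention)

def read_bed(path) -> list[tuple[str, Interval, str]]:
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            cols = line.split("\t")
            if len(cols) < 3:
                raise GenomeIOError(f"{path}:{lineno}: expected >=3 BED columns")
            chrom, start, end = cols[0], int(cols[1]), int(cols[2])
            name = cols[3] if len(cols) > 3 else ""
            if start < 0:
                raise GenomeIOError(f"{path}:{lineno}: negative start")
            out.append((chrom, Interval(start, end), name))
    return out


def write_bed(records, path) -> None:
    """``records``: iterable of (chrom, Interval, name)."""
    with open(path, "w") as fh:
        for chrom, iv, name in records:
            fh.write(f"{chrom}\t{iv.start}\t{iv.end}\t{name}\n")


# ---------------------------------------------------------------------------
# Pileup TSV:  seq_id  pos(1-based)  ref_base  count_A  count_C  count_G  count_T

PILEUP_HEADER = ["seq_id", "pos", "ref_base", "count_A", "count_C", "count_G", "count_T"]


def read_pileup_tsv(path, genome: CircularGenome | None = None) -> list[PileupColumn]:
    cols = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if fields[0] == "seq_id":  # header row
                continue
            if len(fields) != 7:
                raise GenomeIOError(f"{path}:{lineno}: expected 7 columns")
            seq_id, pos, ref = fields[0], int(fields[1]), fields[2].upper()
            counts = tuple(int(x) for x in fields[3:7])
            if genome is not None:
                if seq_id != genome.id:
                    raise GenomeIOError(f"{path}:{lineno}: unknown seq_id {seq_id!r}")
                if not (1 <= pos <= len(genome)):
                    raise GenomeIOError(f"{path}:{lineno}: position out of range")
            cols.append(PileupColumn(seq_id, pos - 1, ref, counts))
    return cols


def write_pileup_tsv(columns, path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(PILEUP_HEADER) + "\n")
        for c in columns:
            fh.write(
                f"{c.seq_id}\t{c.position + 1}\t{c.ref_base}\t"
                + "\t".join(str(x) for x in c.counts)
                + "\n"
            )


# ---------------------------------------------------------------------------
# newick

def write_newick(tree, path) -> None:
    """Write a tree (anything exposing ``.newick()``, or a newick string)."""
    text = tree if isinstance(tree, str) else tree.newick()
    if not text.endswith(";"):
        text += ";"
    with open(path, "w") as fh:
        fh.write(text + "\n")
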