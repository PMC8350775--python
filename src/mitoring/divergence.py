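"""Coding-sequence extraction, pairwise alignment, SNP/gap counting,
p-distance matrices and neighbor-joining trees."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from Bio import Align

from .genome_io import CircularGenome, reverse_complement_seq


@dataclass
class PairwiseAlignment:
    id_a: str
    id_b: str
    aligned_a: str
    aligned_b: str
    score: float
    parameters: dict = field(default_factory=dict)

    def __post_init__(self):
        if len(self.aligned_a) != len(self.aligned_b):
            raise ValueError("aligned rows differ in length")
        # removing gaps must recover the inputs; enforced by construction


@dataclass
class DistanceMatrix:
    taxa: list[str]
    d: np.ndarray

    def __post_init__(self):
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.taxa)
        if self.d.shape != (n, n):
            raise ValueError("matrix shape does not match taxa")
        if not np.allclose(self.d, self.d.T):
            raise ValueError("matrix is not symmetric")
        if not np.allclose(np.diag(self.d), 0):
            raise ValueError("diagonal must be zero")


class TreeNode:
    """A node of an unrooted tree serialized from an arbitrary trifurcating
    root; leaves carry labels, edges carry lengths."""

    __slots__ = ("label", "children")

    def __init__(self, label: str | None = None):
        self.label = label
        self.children: list[tuple["TreeNode", float]] = []

    def is_leaf(self) -> bool:
        return not self.children

    def newick(self) -> str:
        if self.is_leaf():
            return self.label or ""
        inner = ",".join(f"{c.newick()}:{bl:.6g}" for c, bl in self.children)
        return f"({inner})"


@dataclass
class Tree:
    root: TreeNode
    taxa: list[str]

    def newick(self) -> str:
        return self.root.newick() + ";"

    def leaf_neighbors(self) -> set[frozenset]:
        """Pairs of taxa that are cherries (share an internal node)."""
        out = set()

        def walk(node):
            leaf_children = [c.label for c, _ in node.children if c.is_leaf()]
            for i in range(len(leaf_children)):
                for j in range(i + 1, len(leaf_children)):
                    if len(node.children) == 2 or True:
                        pass
            if len(leaf_children) >= 2 and len(node.children) == len(leaf_children) == 2:
                out.add(frozenset(leaf_children))
            for c, _ in node.children:
                walk(c)

        walk(self.root)
        return out

    def bipartitions(self) -> set[frozenset]:
        """Non-trivial splits of the taxon set, for topology comparison."""
        taxa = frozenset(self.taxa)
        splits = set()

        def walk(node) -> frozenset:
            if node.is_leaf():
                return frozenset([node.label])
            below = frozenset().union(*(walk(c) for c, _ in node.children))
            if 1 < len(below) < len(taxa) - 1:
                splits.add(min(below, taxa - below, key=lambda s: (len(s), sorted(s))))
            return below

        for c, _ in self.root.children:
            walk(c)
        return splits


# ---------------------------------------------------------------------------
# CDS extraction

def extract_concatenated_cds(
    genome: CircularGenome,
    annotations,
    gene_set: list[str],
) -> str:
    """Concatenate spliced CDS sequences of the genes in ``gene_set`` in
    alphabetical gene-name order; minus-strand genes reverse-complemented,
    multi-exon genes joined in annotation part order.  A missing gene is an
    error, never silently skipped."""
    by_name: dict[str, list] = {}
    for a in annotations:
        if a.feature_type == "CDS":
            by_name.setdefault(a.name, []).append(a)
    chunks = []
    for gene in sorted(set(gene_set)):
        anns = by_name.get(gene)
        if not anns:
            raise KeyError(f"gene {gene!r} is not annotated as CDS in {genome.id}")
        for ann in anns:
            chunks.append(genome.feature_seq(ann))
    return "".join(chunks)


# ---------------------------------------------------------------------------
# alignment

DEFAULT_ALIGN_PARAMS = {"match": 1, "mismatch": -2, "gap_open": -5, "gap_extend": -1}
ANCHORED_THRESHOLD = 50_000
_ANCHOR_K = 31


def _aligner(params: dict) -> Align.PairwiseAligner:
    al = Align.PairwiseAligner()
    al.mode = "global"
    al.match_score = params["match"]
    al.mismatch_score = params["mismatch"]
    # a gap of length g costs -(|gap_open| + g*|gap_extend|)
    al.open_gap_score = params["gap_open"] + params["gap_extend"]
    al.extend_gap_score = params["gap_extend"]
    return al


def align_pair(
    a: str,
    b: str,
    params: dict | None = None,
    id_a: str = "a",
    id_b: str = "b",
    anchored: bool | None = None,
) -> PairwiseAlignment:
    """Optimal global affine-gap alignment; inputs above 50 kb switch to
    anchored mode (shared unique 31-mer chaining, optimal alignment between
    anchors) with the same contract on the anchored segments."""
    if not a or not b:
        raise ValueError("align_pair requires non-empty sequences")
    p = dict(DEFAULT_ALIGN_PARAMS, **(params or {}))
    if anchored is None:
        anchored = max(len(a), len(b)) > ANCHORED_THRESHOLD
    if anchored:
        ra, rb, score = _anchored_align(a, b, p)
    else:
        aln = _aligner(p).align(a, b)[0]
        ra, rb, score = str(aln[0]), str(aln[1]), aln.score
    out = PairwiseAlignment(id_a, id_b, ra, rb, score, p)
    assert out.aligned_a.replace("-", "") == a
    assert out.aligned_b.replace("-", "") == b
    return out


def _unique_kmers(s: str, k: int) -> dict[str, int]:
    seen: dict[str, int] = {}
    dup = set()
    for i in range(len(s) - k + 1):
        km = s[i:i + k]
        if km in dup:
            continue
        if km in seen:
            del seen[km]
            dup.add(km)
        else:
            seen[km] = i
    return seen


def _anchored_align(a: str, b: str, params: dict):
    k = _ANCHOR_K
    ua, ub = _unique_kmers(a, k), _unique_kmers(b, k)
    shared = sorted((ua[km], ub[km]) for km in ua.keys() & ub.keys())
    # longest chain increasing in both coordinates (offsets near-diagonal)
    chain: list[tuple[int, int]] = []
    for pa, pb in shared:
        if not chain or (pa >= chain[-1][0] + k and pb >= chain[-1][1] + k):
            chain.append((pa, pb))
    if not chain:
        aln = _aligner(params).align(a, b)[0]
        return str(aln[0]), str(aln[1]), aln.score

    al = _aligner(params)
    ra, rb, score = [], [], 0.0
    prev_a = prev_b = 0
    for pa, pb in chain + [(len(a), len(b))]:
        seg_a, seg_b = a[prev_a:pa], b[prev_b:pb]
        if seg_a or seg_b:
            if not seg_a:
                ra.append("-" * len(seg_b)); rb.append(seg_b)
                score += params["gap_open"] + params["gap_extend"] * len(seg_b)
            elif not seg_b:
                ra.append(seg_a); rb.append("-" * len(seg_a))
                score += params["gap_open"] + params["gap_extend"] * len(seg_a)
            else:
                sub = al.align(seg_a, seg_b)[0]
                ra.append(str(sub[0])); rb.append(str(sub[1]))
                score += sub.score
        if pa < len(a):
            ra.append(a[pa:pa + k]); rb.append(b[pb:pb + k])
            score += params["match"] * k
            prev_a, prev_b = pa + k, pb + k
    return "".join(ra), "".join(rb), score


def count_snps_gaps(alignment: PairwiseAlignment) -> tuple[int, int]:
    """SNPs = columns with two distinct non-gap residues; gaps = maximal runs
    of gap characters (indel events), each run counted once."""
    a, b = alignment.aligned_a, alignment.aligned_b
    snps = sum(1 for x, y in zip(a, b) if x != "-" and y != "-" and x != y)
    gaps = 0
    for row in (a, b):
        in_gap = False
        for ch in row:
            if ch == "-" and not in_gap:
                gaps += 1
                in_gap = True
            elif ch != "-":
                in_gap = False
    return snps, gaps


def gap_columns(alignment: PairwiseAlignment) -> int:
    return sum(1 for x, y in zip(alignment.aligned_a, alignment.aligned_b)
               if x == "-" or y == "-")


def conserved_positions(msa: list[str]) -> tuple[int, int]:
    """(alignment length, columns where all rows share one residue);
    a gap breaks conservation."""
    if not msa:
        raise ValueError("empty alignment")
    length = len(msa[0])
    if any(len(row) != length for row in msa):
        raise ValueError("ragged alignment rows")
    conserved = 0
    for col in zip(*msa):
        first = col[0]
        if first != "-" and all(c == first for c in col):
            conserved += 1
    return length, conserved


# ---------------------------------------------------------------------------
# distances and neighbor joining

def p_distance(row_a: str, row_b: str) -> float:
    """Proportion of differing residues over columns without a gap in either row."""
    pairs = [(x, y) for x, y in zip(row_a, row_b) if x != "-" and y != "-"
             and x != "N" and y != "N"]
    if not pairs:
        return 0.0
    return sum(1 for x, y in pairs if x != y) / len(pairs)


def distance_matrix(
    seqs: dict[str, str],
    model: str = "p",
    params: dict | None = None,
) -> DistanceMatrix:
    """Pairwise p-distances.  Equal-length inputs are treated as aligned MSA
    rows; otherwise each pair is globally aligned first."""
    taxa = list(seqs)
    n = len(taxa)
    lengths = {len(s) for s in seqs.values()}
    aligned = len(lengths) == 1
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            if aligned:
                ra, rb = seqs[taxa[i]], seqs[taxa[j]]
            else:
                aln = align_pair(seqs[taxa[i]], seqs[taxa[j]], params)
                ra, rb = aln.aligned_a, aln.aligned_b
            d[i, j] = d[j, i] = p_distance(ra, rb)
    return DistanceMatrix(taxa, d)


def nj_tree(dm: DistanceMatrix) -> Tree:
    """Classic neighbor joining (Q criterion).  Ties in Q are broken by the
    smallest taxon-index pair; negative branch lengths are clamped to zero
    with the remainder moved to the sister edge."""
    n = len(dm.taxa)
    if n < 3:
        raise ValueError("neighbor joining requires >= 3 taxa")
    nodes: list[TreeNode] = [TreeNode(t) for t in dm.taxa]
    d = dm.d.astype(float).copy()
    active = list(range(n))

    def clamp(li: float, lj: float) -> tuple[float, float]:
        if li < 0:
            lj += li
            li = 0.0
        if lj < 0:
            li += lj
            lj = 0.0
        return max(li, 0.0), max(lj, 0.0)

    while len(active) > 3:
        m = len(active)
        r = {i: sum(d[i, j] for j in active if j != i) for i in active}
        best = None
        for ai in range(m):
            for aj in range(ai + 1, m):
                i, j = active[ai], active[aj]
                q = (m - 2) * d[i, j] - r[i] - r[j]
                if best is None or q < best[0] - 1e-12:
                    best = (q, i, j)
        _, i, j = best
        li = d[i, j] / 2 + (r[i] - r[j]) / (2 * (m - 2))
        lj = d[i, j] - li
        li, lj = clamp(li, lj)
        u = TreeNode()
        u.children = [(nodes[i], li), (nodes[j], lj)]
        new_idx = d.shape[0]
        d = np.pad(d, ((0, 1), (0, 1)))
        for kx in active:
            if kx in (i, j):
                continue
            duk = (d[i, kx] + d[j, kx] - d[i, j]) / 2
            d[new_idx, kx] = d[kx, new_idx] = duk
        nodes.append(u)
        active = [x for x in active if x not in (i, j)] + [new_idx]

    i, j, k = active
    li = (d[i, j] + d[i, k] - d[j, k]) / 2
    lj = (d[i, j] + d[j, k] - d[i, k]) / 2
    lk = (d[i, k] + d[j, k] - d[i, j]) / 2
    root = TreeNode()
    root.children = [(nodes[i], max(li, 0.0)), (nodes[j], max(lj, 0.0)),
                     (nodes[k], max(lk, 0.0))]
    return Tree(root, list(dm.taxa))


def bootstrap_support(
    msa: dict[str, str],
    n_replicates: int = 100,
    seed: int = 0,
) -> dict[frozenset, float]:
    """Column-resampling bootstrap over an aligned MSA: fraction of replicate
    NJ trees containing each bipartition of the full-data tree."""
    rng = np.random.default_rng(seed)
    taxa = list(msa)
    cols = np.array([list(msa[t]) for t in taxa])
    base = nj_tree(distance_matrix(msa))
    target = base.bipartitions()
    counts = {bp: 0 for bp in target}
    ncol = cols.shape[1]
    for _ in range(n_replicates):
        idx = rng.integers(0, ncol, size=ncol)
        rep = {t: "".join(cols[i, idx]) for i, t in enumerate(taxa)}
        rep_tree = nj_tree(distance_matrix(rep))
        for bp in rep_tree.bipartitions():
            if bp in counts:
                counts[bp] += 1
    return {bp: c / n_replicates for bp, c in counts.items()}
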