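"""C-to-U RNA-editing site calling from per-site base counts, functional
effect annotation, and the m1A misincorporation diagnostic.

A site is called when, at sufficient depth inside an annotated coding region,
the reference base is C with a T read fraction above threshold on a plus
strand gene, or G with an A fraction above threshold on a minus strand gene
(the same C-to-U event seen from the other strand).  All other variant
classes are discarded.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from Bio.Seq import Seq

from .genome_io import Annotation, CircularGenome, PileupColumn


@dataclass
class EffectRecord:
    gene: str
    strand: str
    codon_position: int  # 1|2|3
    codon_before: str
    codon_after: str
    effect: str  # silent | missense | start_gain | stop_gain | stop_loss | other


@dataclass
class EditingSite:
    position: int  # 0-based internal; reported 1-based externally
    gene: str
    strand: str
    extent: float
    depth: int
    codon_position: int = 0
    effect: str = ""
    effects: list[EffectRecord] = field(default_factory=list)


class PileupMismatch(ValueError):
    """Pileup reference bases disagree with the genome sequence."""


def _cds_annotations(annotations) -> list[Annotation]:
    return [a for a in annotations if a.feature_type == "CDS"]


def call_editing_sites(
    pileups: list[PileupColumn],
    cds: list[Annotation],
    genome: CircularGenome | None = None,
    min_depth: int = 10,
    min_fraction: float = 0.1,
    annotate: bool = True,
) -> list[EditingSite]:
    """Threshold caller for C-to-U editing restricted to coding regions."""
    cds = _cds_annotations(cds) or list(cds)
    if genome is not None:
        bad = [c.position + 1 for c in pileups
               if genome.seq[c.position] != c.ref_base]
        if bad:
            raise PileupMismatch(
                f"pileup reference base disagrees with genome at 1-based "
                f"positions {bad[:10]}{'...' if len(bad) > 10 else ''}"
            )
    L = len(genome) if genome is not None else max(c.position for c in pileups) + 1

    sites: list[EditingSite] = []
    for col in pileups:
        if col.depth < min_depth:
            continue
        covering = [a for a in cds if a.contains(col.position, L)]
        if not covering:
            continue
        for ann in covering:
            if ann.strand == "+" and col.ref_base == "C":
                extent = col.count("T") / col.depth
            elif ann.strand == "-" and col.ref_base == "G":
                extent = col.count("A") / col.depth
            else:
                continue
            if extent >= min_fraction:
                site = EditingSite(col.position, ann.name, ann.strand,
                                   extent, col.depth)
                if annotate and genome is not None:
                    annotate_effect(site, genome, covering)
                sites.append(site)
                break  # one site record; effects cover all frames
    sites.sort(key=lambda s: s.position)
    return sites


def annotate_effect(
    site: EditingSite,
    genome: CircularGenome,
    cds: list[Annotation],
) -> EditingSite:
    """Compute the functional effect by editing the codon in silico
    (translation table 1), for every CDS covering the site — overlapping
    reading frames each get their own effect record."""
    L = len(genome)
    covering = [a for a in _cds_annotations(cds) or cds
                if a.contains(site.position, L)]
    if not covering:
        raise ValueError(f"site at position {site.position + 1} lies outside every CDS")
    site.effects = []
    for ann in covering:
        coords = []
        for part in ann.parts:
            coords.extend(part.positions(L))
        if ann.strand == "-":
            coords = coords[::-1]
        try:
            idx = coords.index(site.position)
        except ValueError:
            continue
        spliced = genome.feature_seq(ann)
        codon_i = idx // 3
        codon_pos = idx % 3 + 1
        codon = spliced[3 * codon_i: 3 * codon_i + 3]
        if len(codon) < 3:
            continue
        edited = codon[: codon_pos - 1] + "T" + codon[codon_pos:]
        aa_before = str(Seq(codon).translate(table=1))
        aa_after = str(Seq(edited).translate(table=1))
        if codon_i == 0 and codon == "ACG" and edited == "ATG":
            effect = "start_gain"
        elif aa_after == "*" and aa_before != "*":
            effect = "stop_gain"
        elif aa_before == "*" and aa_after != "*":
            effect = "stop_loss"
        elif aa_before == aa_after:
            effect = "silent"
        elif aa_before != aa_after:
            effect = "missense"
        else:
            effect = "other"
        site.effects.append(EffectRecord(ann.name, ann.strand, codon_pos,
                                         codon, edited, effect))
    if site.effects:
        primary = next((e for e in site.effects if e.gene == site.gene),
                       site.effects[0])
        site.codon_position = primary.codon_position
        site.effect = primary.effect
    return site


def misincorporation_fraction(
    pileups: list[PileupColumn],
    position: int,
) -> tuple[float, bool]:
    """T-read fraction at a 0-based position; flagged as an m1A candidate when
    the reference is A and the fraction falls in [0.3, 0.7]."""
    col = next((c for c in pileups if c.position == position), None)
    if col is None:
        raise ValueError(f"no pileup column at position {position + 1}")
    if col.depth == 0:
        raise ZeroDivisionError(f"zero depth at position {position + 1}")
    frac = col.count("T") / col.depth
    flagged = col.ref_base == "A" and 0.3 <= frac <= 0.7
    return frac, flagged
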