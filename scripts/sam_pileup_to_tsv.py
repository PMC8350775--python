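#!/usr/bin/env python
"""Convert `samtools mpileup` text output into the per-site base-count TSV
consumed by `mitoring editing` (columns: seq_id, pos 1-based, ref_base,
count_A, count_C, count_G, count_T).

Counts are read bases reported on the reference forward strand: '.' and ','
count as the reference base, explicit base letters (either case) as
themselves.  Indels, read starts/ends, deletions ('*') and reference skips
are ignored.

Usage:
    samtools mpileup -f ref.fasta aln.bam | python scripts/sam_pileup_to_tsv.py > pileup.tsv
"""

import re
import sys

_INDEL = re.compile(r"[+-](\d+)")


def parse_bases(ref: str, bases: str) -> dict[str, int]:
    counts = {"A": 0, "C": 0, "G": 0, "T": 0}
    i = 0
    n = len(bases)
    while i < n:
        ch = bases[i]
        if ch == "^":          # read start: skip mapping-quality char
            i += 2
            continue
        if ch in "+-":         # indel: skip its length and sequence
            m = _INDEL.match(bases, i)
            length = int(m.group(1))
            i = m.end() + length
            continue
        if ch in ".,":
            if ref in counts:
                counts[ref] += 1
        elif ch.upper() in counts:
            counts[ch.upper()] += 1
        # '$', '*', '>', '<', 'N' and anything else: ignored
        i += 1
    return counts


def main() -> int:
    out = sys.stdout
    out.write("seq_id\tpos\tref_base\tcount_A\tcount_C\tcount_G\tcount_T\n")
    for line in sys.stdin:
        cols = line.rstrip("\n").split("\t")
        if len(cols) < 5:
            continue
        seq_id, pos, ref = cols[0], cols[1], cols[2].upper()
        counts = parse_bases(ref, cols[4])
        out.write(f"{seq_id}\t{pos}\t{ref}\t{counts['A']}\t{counts['C']}"
                  f"\t{counts['G']}\t{counts['T']}\n")
    return 0


if __name__ == "__main__":
    raise SystemExit(main())
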