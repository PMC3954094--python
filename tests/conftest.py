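"""Shared fixtures and independent brute-force oracles.

The oracles here deliberately avoid the package's index/assembly code paths:
multiplicity is counted by scanning every start position with string slicing,
and the brute-force assembler re-applies the connection rules with that naive
scanner, so agreement between the two routes is a meaningful check.
"""

from __future__ import annotations

import numpy as np
import pytest

from asmsim import MappedFragment, ReferenceGenome, reverse_complement


def naive_count_forward(ref: ReferenceGenome, s: str) -> int:
    """Overlapping forward-strand occurrence count by direct string search."""
    count = 0
    for seq in ref.sequences.values():
        i = seq.find(s)
        while i != -1:
            count += 1
            i = seq.find(s, i + 1)
    return count


def naive_multiplicity(ref: ReferenceGenome, s: str) -> int:
    """Both-strand occurrence count; palindromic queries counted once per locus."""
    rc = reverse_complement(s)
    if s == rc:
        return naive_count_forward(ref, s)
    return naive_count_forward(ref, s) + naive_count_forward(ref, rc)


def brute_force_assemble(fragments, ref: ReferenceGenome, min_overlap: int = 1):
    """Independent re-implementation of the connection rules.

    Returns (contig intervals, break causes) per the same conventions as the
    package: contigs as (seq_name, start, end, member_ids).
    """
    contigs = []
    causes = []
    by_seq: dict[str, list] = {}
    for f in fragments:
        by_seq.setdefault(f.seq_name, []).append(f)
    for name in ref.sequences:
        frags = by_seq.get(name)
        if not frags:
            continue
        frags = sorted(frags, key=lambda f: (f.start, -f.end, f.fragment_id))
        kept = []
        max_end = -1
        for f in frags:
            if f.end > max_end:
                kept.append(f)
                max_end = f.end
        run = [kept[0]]
        for a, b in zip(kept, kept[1:]):
            overlap = a.end - b.start
            if overlap <= 0:
                cause = "gap"
            elif overlap < min_overlap:
                cause = "short_overlap"
            else:
                s = ref.sequences[name][b.start:a.end]
                cause = "repeat" if naive_multiplicity(ref, s) >= 2 else None
            if cause is None:
                run.append(b)
            else:
                contigs.append((name, run[0].start, max(f.end for f in run),
                                [f.fragment_id for f in run]))
                causes.append(cause)
                run = [b]
        contigs.append((name, run[0].start, max(f.end for f in run),
                        [f.fragment_id for f in run]))
    return contigs, causes


def tiled_fragments(seq_name: str, seq_len: int, read_len: int, step: int,
                    offset: int = 0) -> list[MappedFragment]:
    return [MappedFragment(f"t{i}", seq_name, s, s + read_len)
            for i, s in enumerate(range(offset, seq_len - read_len + 1, step))]


@pytest.fixture
def rng():
    return np.random.default_rng(20260919)


@pytest.fixture
def small_random_ref():
    from asmsim import random_reference
    return random_reference(2000, seed=7, name="chr")
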