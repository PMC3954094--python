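"""Assembly metrics: per-site N50, coverage fractions, reference N statistics.

The N50 here is a per-site variant computed against the reference rather than
against the contig set alone: every reference site is scored with the length
of the longest contig covering it (0 if uncovered), and N50 is the largest
value v such that at least half of all sites score >= v. For non-overlapping
contigs covering the whole reference this coincides with the classical
length-weighted median contig length; because neighbouring contigs may share
short overlaps it can be slightly larger. Scaffolded (unsequenced) interiors
of mate-pair contigs count as covered, matching the contig/scaffold
conflation of the simulation.
"""

from __future__ import annotations

import bisect
import json
import re
from dataclasses import asdict, dataclass

import numpy as np

from .assembly import Contig
from .reference import ReferenceGenome


@dataclass
class AssemblyReport:
    """Summary of one simulated assembly."""

    n_contigs: int
    longest: int
    n50: int
    covered_fraction: float
    known_fraction: float
    n50_known: int
    total_length: int

    #: alias used in diploid phase experiments, where coverage of the combined
    #: homologs is the "sequenced fraction" of the genome
    @property
    def sequenced_fraction(self) -> float:
        return self.covered_fraction

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)

    def one_line(self) -> str:
        return (f"contigs={self.n_contigs} longest={self.longest} n50={self.n50} "
                f"covered={100 * self.covered_fraction:.2f}% "
                f"known_covered={100 * self.known_fraction:.2f}%")


class _IntervalUnion:
    """Disjoint sorted interval set supporting add-with-new-length accounting."""

    def __init__(self) -> None:
        self.starts: list[int] = []
        self.ends: list[int] = []

    def add(self, start: int, end: int) -> list[tuple[int, int]]:
        """Insert [start, end); return the newly covered subintervals."""
        new: list[tuple[int, int]] = []
        i = bisect.bisect_right(self.ends, start)
        cur = start
        j = i
        while j < len(self.starts) and self.starts[j] < end:
            if self.starts[j] > cur:
                new.append((cur, self.starts[j]))
            cur = max(cur, self.ends[j])
            j += 1
        if cur < end:
            new.append((cur, end))
        merged_start = min(start, self.starts[i]) if i < j else start
        merged_end = max(end, self.ends[j - 1]) if i < j else end
        self.starts[i:j] = [merged_start]
        self.ends[i:j] = [merged_end]
        return new

    def total(self) -> int:
        return sum(e - s for s, e in zip(self.starts, self.ends))


def _n_prefix(seq: str) -> np.ndarray:
    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    pref = np.zeros(len(seq) + 1, dtype=np.int64)
    np.cumsum(arr == ord("N"), out=pref[1:])
    return pref


def _score_weights(contigs: list[Contig], n_pref: dict[str, np.ndarray] | None):
    """(length, site_count[, non_N_site_count]) accounting by sweeping contigs
    longest-first and crediting each newly covered site to that contig."""
    unions: dict[str, _IntervalUnion] = {}
    rows: list[tuple[int, int, int]] = []
    for c in sorted(contigs, key=lambda c: c.length, reverse=True):
        union = unions.setdefault(c.seq_name, _IntervalUnion())
        new = union.add(c.start, c.end)
        sites = sum(e - s for s, e in new)
        if n_pref is None:
            rows.append((c.length, sites, sites))
        else:
            pref = n_pref[c.seq_name]
            known = sites - sum(int(pref[e] - pref[s]) for s, e in new)
            rows.append((c.length, sites, known))
    return rows


def _n50_from_rows(rows, total_sites: int, which: int) -> int:
    """Largest score v with at least half the sites scoring >= v (0 if none)."""
    if total_sites <= 0:
        raise ValueError("reference has zero length")
    cum = 0
    for length, *counts in sorted(rows, key=lambda r: r[0], reverse=True):
        cum += counts[which]
        if 2 * cum >= total_sites:
            return length
    return 0


def per_site_n50(contigs: list[Contig], ref_total_length: int) -> int:
    """Per-site N50 over all reference sites (N sites included, scored 0 when
    uncovered), computed by weighted counting over contig-length classes."""
    rows = _score_weights(contigs, None)
    return _n50_from_rows(rows, ref_total_length, 0)


def coverage_fractions(contigs: list[Contig], ref: ReferenceGenome) -> tuple[float, float]:
    """(fraction of all sites inside >= 1 contig, same over non-N sites only)."""
    total = ref.total_length
    if total == 0:
        raise ValueError("reference has zero length")
    n_pref = {name: _n_prefix(seq) for name, seq in ref.sequences.items()}
    covered = 0
    covered_known = 0
    unions: dict[str, _IntervalUnion] = {}
    for c in contigs:
        union = unions.setdefault(c.seq_name, _IntervalUnion())
        for s, e in union.add(c.start, c.end):
            covered += e - s
            covered_known += (e - s) - int(n_pref[c.seq_name][e] - n_pref[c.seq_name][s])
    total_known = total - sum(int(p[-1]) for p in n_pref.values())
    known_fraction = covered_known / total_known if total_known else 0.0
    return covered / total, known_fraction


def reference_stats(ref: ReferenceGenome, min_block: int = 1) -> tuple[float, int]:
    """(fraction of N characters, number of maximal N runs of length >= min_block)."""
    total = ref.total_length
    if total == 0:
        return 0.0, 0
    n_chars = 0
    n_runs = 0
    for seq in ref.sequences.values():
        for m in re.finditer(r"N+", seq):
            n_chars += m.end() - m.start()
            if m.end() - m.start() >= min_block:
                n_runs += 1
    return n_chars / total, n_runs


def summarize(contigs: list[Contig], ref: ReferenceGenome) -> AssemblyReport:
    """Full report: contig count, longest, both N50 variants, coverage fractions."""
    total = ref.total_length
    n_pref = {name: _n_prefix(seq) for name, seq in ref.sequences.items()}
    total_known = total - sum(int(p[-1]) for p in n_pref.values())
    rows = _score_weights(contigs, n_pref)
    covered_fraction, known_fraction = coverage_fractions(contigs, ref)
    return AssemblyReport(
        n_contigs=len(contigs),
        longest=max((c.length for c in contigs), default=0),
        n50=_n50_from_rows(rows, total, 0),
        covered_fraction=covered_fraction,
        known_fraction=known_fraction,
        n50_known=_n50_from_rows(rows, total_known, 1) if total_known else 0,
        total_length=total,
    )
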