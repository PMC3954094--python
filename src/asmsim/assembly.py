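"""Reference-guided optimal assembly simulation.

Given truth (or imported) read mappings, compute the best de novo assembly
theoretically possible: fragments are sorted by start, contained fragments are
dropped, qualifying mate pairs become single long fragments, and consecutive
fragments are connected unless the junction is ambiguous. A junction breaks
when

* the fragments do not overlap at all (coverage gap),
* the overlap is shorter than ``min_overlap`` (the De Bruijn word-size effect:
  connection requires an overlap of at least word size - 1), or
* the overlapping reference substring occurs more than once in the multiplicity
  scope (a repeat: the join is ambiguous).

The multiplicity *scope* need not equal the coordinate reference: assembling
reads of one chromosome, one BAC clone, or one clone pool against that subset
is what implements chromosome sorting and BAC strategies.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .reference import DiploidReference, ReferenceGenome
from .repeats import RepeatIndex

BREAK_GAP = "gap"
BREAK_SHORT = "short_overlap"
BREAK_REPEAT = "repeat"
BREAK_UNKNOWN = "unknown_base"


@dataclass(slots=True)
class MappedFragment:
    """A half-open interval on one reference sequence.

    ``kind`` is ``read``, ``pair_span`` (a mate pair treated as one long
    fragment) or ``stage1_contig`` (BAC two-stage assembly). ``sequenced``
    lists the subintervals actually covered by read bases; ``None`` means the
    whole interval is sequenced.
    """

    fragment_id: str
    seq_name: str
    start: int
    end: int
    strand: str = "+"
    kind: str = "read"
    sequenced: list[tuple[int, int]] | None = None

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"fragment {self.fragment_id}: start must be < end")

    @property
    def length(self) -> int:
        return self.end - self.start

    def sequenced_intervals(self) -> list[tuple[int, int]]:
        return self.sequenced if self.sequenced is not None else [(self.start, self.end)]


@dataclass
class AssemblyOptions:
    """Connection rules for the assembly simulation.

    ``min_overlap`` models a De Bruijn word size w as w - 1; pair distance
    limits gate :func:`pairs_to_fragments`; ``demote_discarded_pairs`` keeps
    the mates of a rejected pair as unpaired reads instead of dropping them.
    """

    min_overlap: int = 1
    pair_distance_min: int | None = None
    pair_distance_max: int | None = None
    drop_nonunique_pairs: bool = True
    demote_discarded_pairs: bool = False

    def __post_init__(self) -> None:
        if self.min_overlap < 1:
            raise ValueError("min_overlap must be >= 1")


@dataclass
class Contig:
    """A maximal run of connected fragments, as a reference interval.

    ``gaps`` are the scaffolded (unsequenced) subintervals inside the contig,
    i.e. mate-pair interiors not covered by any member's read bases.
    """

    seq_name: str
    start: int
    end: int
    member_count: int
    member_ids: list[str] | None = None
    gaps: list[tuple[int, int]] = field(default_factory=list)

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class Breakpoint:
    seq_name: str
    position: int  # start of the failed junction (next fragment's start)
    cause: str
    left_id: str | None = None
    right_id: str | None = None
    overlap: int = 0
    multiplicity: int | None = None


@dataclass
class PairReport:
    kept: int = 0
    discarded_nonunique: int = 0
    discarded_distance: int = 0
    discarded_cross_sequence: int = 0


@dataclass
class AssemblyResult:
    contigs: list[Contig]
    breakpoints: list[Breakpoint]
    pair_report: PairReport | None = None


# ---------------------------------------------------------------------------
# pairs


def pairs_to_fragments(pairs, ref: ReferenceGenome, index: RepeatIndex,
                       options: AssemblyOptions) -> tuple[list[MappedFragment], PairReport]:
    """Turn mate pairs into single long fragments.

    A pair is accepted iff both mate substrings are unique in the index scope
    and the inner distance lies within the configured limits; rejected pairs
    are dropped entirely (both mates), unless ``demote_discarded_pairs`` turns
    them back into unpaired read fragments. The unsequenced interior is
    recorded so it can later be reported as a scaffold gap.

    ``pairs`` is an iterable of 2-tuples of objects with ``seq_name``,
    ``start``, ``end`` and optionally ``read_id``/``fragment_id`` attributes
    (SimulatedRead mates or imported mapping records).
    """
    out: list[MappedFragment] = []
    report = PairReport()

    def _demote(m1, m2, tag):
        if options.demote_discarded_pairs:
            for j, m in enumerate((m1, m2)):
                out.append(MappedFragment(f"{_frag_id(m)}:{tag}", m.seq_name,
                                          m.start, m.end, kind="read"))

    for i, (m1, m2) in enumerate(pairs):
        if m1.seq_name != m2.seq_name:
            report.discarded_cross_sequence += 1
            _demote(m1, m2, "xseq")
            continue
        left, right = (m1, m2) if m1.start <= m2.start else (m2, m1)
        if options.drop_nonunique_pairs:
            s1 = ref.substring(left.seq_name, left.start, left.end)
            s2 = ref.substring(right.seq_name, right.start, right.end)
            if "N" in s1 or "N" in s2 or not index.is_unique_fragment(s1) \
                    or not index.is_unique_fragment(s2):
                report.discarded_nonunique += 1
                _demote(m1, m2, "rep")
                continue
        inner = right.start - left.end
        if (options.pair_distance_min is not None and inner < options.pair_distance_min) or \
           (options.pair_distance_max is not None and inner > options.pair_distance_max):
            report.discarded_distance += 1
            _demote(m1, m2, "dist")
            continue
        sequenced = [(left.start, left.end), (right.start, right.end)]
        if inner <= 0:  # mates touch or overlap: fully sequenced
            sequenced = [(left.start, max(left.end, right.end))]
        out.append(MappedFragment(f"pair_{_frag_id(left)}", left.seq_name,
                                  left.start, right.end, kind="pair_span",
                                  sequenced=sequenced))
        report.kept += 1
    return out, report


def _frag_id(obj) -> str:
    return getattr(obj, "read_id", None) or getattr(obj, "fragment_id", "anon")


# ---------------------------------------------------------------------------
# sorting / containment


def sort_and_filter(fragments: list[MappedFragment]) -> list[MappedFragment]:
    """Sort by start and drop contained fragments.

    Output is sorted by start (ties: longer first, then id) and keeps only
    fragments whose end exceeds the running maximum end, so both starts and
    ends strictly increase.
    """
    ordered = sorted(fragments, key=lambda f: (f.start, -f.end, f.fragment_id))
    out: list[MappedFragment] = []
    max_end = -1
    for f in ordered:
        if f.end > max_end:
            out.append(f)
            max_end = f.end
    return out


# ---------------------------------------------------------------------------
# assembly proper


def _finish_contig(members: list[MappedFragment], keep_ids: bool) -> Contig:
    start = members[0].start
    end = max(m.end for m in members)
    # scaffold gaps: complement of the union of sequenced subintervals
    pieces: list[tuple[int, int]] = []
    for m in members:
        pieces.extend(m.sequenced_intervals())
    pieces.sort()
    gaps: list[tuple[int, int]] = []
    cur = start
    for s, e in pieces:
        if s > cur:
            gaps.append((cur, s))
        cur = max(cur, e)
    if cur < end:  # cannot happen for well-formed members, kept for safety
        gaps.append((cur, end))
    return Contig(members[0].seq_name, start, end, len(members),
                  member_ids=[m.fragment_id for m in members] if keep_ids else None,
                  gaps=gaps)


def assemble(fragments: list[MappedFragment], ref: ReferenceGenome, index: RepeatIndex,
             options: AssemblyOptions | None = None, keep_member_ids: bool = True) -> AssemblyResult:
    """Assemble mapped fragments into optimal contigs.

    ``ref`` supplies coordinates and overlap substrings; ``index`` answers
    multiplicity queries and may be built over a smaller scope (a chromosome,
    clone, or pool). Fragments are grouped per sequence and sorted/filtered
    internally, so pre-sorted input is not required.
    """
    options = options or AssemblyOptions()
    per_seq: dict[str, list[MappedFragment]] = {}
    for f in fragments:
        if f.end > len(ref.sequences[f.seq_name]):
            raise ValueError(f"fragment {f.fragment_id} exceeds {f.seq_name!r} bounds")
        per_seq.setdefault(f.seq_name, []).append(f)
    contigs: list[Contig] = []
    breaks: list[Breakpoint] = []
    for name in ref.sequences:
        if name not in per_seq:
            continue
        kept = sort_and_filter(per_seq[name])
        members: list[MappedFragment] = [kept[0]]
        for a, b in zip(kept, kept[1:]):
            cause = None
            mult = None
            overlap = a.end - b.start
            if overlap <= 0:
                cause = BREAK_GAP
            elif overlap < options.min_overlap:
                cause = BREAK_SHORT
            else:
                s = ref.substring(name, b.start, a.end)
                if "N" in s:
                    cause = BREAK_UNKNOWN
                else:
                    mult = index.multiplicity(s)
                    if mult >= 2:
                        cause = BREAK_REPEAT
            if cause is None:
                members.append(b)
            else:
                contigs.append(_finish_contig(members, keep_member_ids))
                breaks.append(Breakpoint(name, b.start, cause, a.fragment_id,
                                         b.fragment_id, max(0, overlap), mult))
                members = [b]
        contigs.append(_finish_contig(members, keep_member_ids))
    return AssemblyResult(contigs, breaks)


def assemble_read_starts(seq_name: str, starts: np.ndarray, read_length: int,
                         ref: ReferenceGenome, index: RepeatIndex,
                         options: AssemblyOptions | None = None) -> AssemblyResult:
    """Vectorized assembly of equal-length unpaired reads given by start position.

    Equivalent to :func:`assemble` on read fragments ``[s, s + read_length)``
    (covered by a dedicated test), but operates on numpy arrays throughout:
    for equal-length reads containment reduces to duplicate removal, gap and
    short-overlap tests vectorize, and repeat tests run through the index's
    batch query. Used by the strategy drivers for deep simulations.
    """
    options = options or AssemblyOptions()
    starts = np.unique(np.asarray(starts, dtype=np.int64))
    if len(starts) == 0:
        return AssemblyResult([], [])
    ends = starts + read_length
    if ends[-1] > len(ref.sequences[seq_name]):
        raise ValueError("read interval exceeds sequence bounds")
    overlap = ends[:-1] - starts[1:]
    cause = np.full(len(overlap), 0, dtype=np.int8)  # 0 connect, 1 gap, 2 short, 3 repeat
    cause[overlap <= 0] = 1
    cause[(overlap > 0) & (overlap < options.min_overlap)] = 2
    candidates = np.flatnonzero(cause == 0)
    if len(candidates):
        mult = index.multiplicities_at(seq_name, starts[candidates + 1], overlap[candidates])
        cause[candidates[mult >= 2]] = 3
    break_idx = np.flatnonzero(cause)
    contigs: list[Contig] = []
    breaks: list[Breakpoint] = []
    names = {1: BREAK_GAP, 2: BREAK_SHORT, 3: BREAK_REPEAT}
    run_start = 0
    for j in break_idx:
        contigs.append(Contig(seq_name, int(starts[run_start]), int(ends[j]),
                              member_count=int(j - run_start + 1)))
        breaks.append(Breakpoint(seq_name, int(starts[j + 1]), names[int(cause[j])],
                                 overlap=max(0, int(overlap[j]))))
        run_start = j + 1
    contigs.append(Contig(seq_name, int(starts[run_start]), int(ends[-1]),
                          member_count=int(len(starts) - run_start)))
    return AssemblyResult(contigs, breaks)


# ---------------------------------------------------------------------------
# diploid / phase


@dataclass
class PhaseBlock:
    """Het sites co-phased by one contig."""

    seq_name: str
    contig_start: int
    contig_end: int
    het_positions: list[int]


def assemble_diploid(diploid: DiploidReference, fragments: list[MappedFragment],
                     options: AssemblyOptions | None = None,
                     index: RepeatIndex | None = None,
                     keep_member_ids: bool = True) -> tuple[AssemblyResult, list[PhaseBlock]]:
    """Assembly simulation on both homologs of a diploid, for phase determination.

    The scope reference is the two homologs side by side, so any fragment or
    overlap not covering a heterozygous site occurs in both copies, has
    multiplicity >= 2, and is treated exactly like a repeat: fragments whose
    substring is non-unique are discarded (they map to either homolog), and
    overlaps without a het site break. The returned phase blocks list, per
    contig, the heterozygous sites it covers — the phased haplotype blocks.
    """
    combined = diploid.combined()
    if index is None:
        index = RepeatIndex(combined)
    unique: list[MappedFragment] = []
    for f in fragments:
        s = combined.substring(f.seq_name, f.start, f.end)
        if "N" not in s and index.is_unique_fragment(s):
            unique.append(f)
    result = assemble(unique, combined, index, options, keep_member_ids=keep_member_ids)
    het = diploid.het_positions()
    blocks: list[PhaseBlock] = []
    for c in result.contigs:
        positions = het.get(c.seq_name)
        if positions is None:
            continue
        lo, hi = np.searchsorted(positions, [c.start, c.end])
        blocks.append(PhaseBlock(c.seq_name, c.start, c.end,
                                 [int(p) for p in positions[lo:hi]]))
    return result, blocks


# ---------------------------------------------------------------------------
# BAC two-stage assembly


def _scope_for_clones(clones, full_ref: ReferenceGenome) -> ReferenceGenome:
    return ReferenceGenome({c.clone_id: full_ref.substring(c.seq_name, c.start, c.end)
                            for c in clones})


def contigs_to_fragments(contigs: list[Contig], prefix: str = "s1") -> list[MappedFragment]:
    """Re-present contigs as fragments (for the second BAC assembly stage),
    preserving their scaffold gaps as unsequenced subintervals."""
    out = []
    for i, c in enumerate(contigs):
        sequenced: list[tuple[int, int]] = []
        cur = c.start
        for gs, ge in sorted(c.gaps):
            if gs > cur:
                sequenced.append((cur, gs))
            cur = ge
        if cur < c.end:
            sequenced.append((cur, c.end))
        out.append(MappedFragment(f"{prefix}_{i}", c.seq_name, c.start, c.end,
                                  kind="stage1_contig",
                                  sequenced=sequenced if c.gaps else None))
    return out


def two_stage_assemble(layout, reads_by_clone: dict[str, list[MappedFragment]],
                       full_ref: ReferenceGenome, options: AssemblyOptions | None = None,
                       mode: str = "barcoded",
                       full_index: RepeatIndex | None = None) -> AssemblyResult:
    """BAC sequencing/pooling: assemble per clone (or pool), then across clones.

    Stage 1 assembles each clone's reads with multiplicity scope restricted to
    the clone sequence (``barcoded``) or to all clone sequences of its pool
    (``pooled``); read coordinates stay on the full genome, so stage 2 simply
    assembles the stage-1 contigs against the whole-genome scope.
    """
    if mode not in ("barcoded", "pooled"):
        raise ValueError("mode must be 'barcoded' or 'pooled'")
    options = options or AssemblyOptions()
    by_id = layout.clones_by_id()
    missing = set(reads_by_clone) - set(by_id)
    if missing:
        raise ValueError(f"reads reference unknown clone ids: {sorted(missing)[:3]}")
    stage1: list[Contig] = []
    if mode == "barcoded":
        groups = [[cid] for pool in layout.pools.values() for cid in pool]
    else:
        groups = [list(pool) for pool in layout.pools.values()]
    for group in groups:
        frags = [f for cid in group for f in reads_by_clone.get(cid, [])]
        if not frags:
            continue
        scope = _scope_for_clones([by_id[cid] for cid in group], full_ref)
        scope_index = RepeatIndex(scope)
        res = assemble(frags, full_ref, scope_index, options, keep_member_ids=False)
        stage1.extend(res.contigs)
    if full_index is None:
        full_index = RepeatIndex(full_ref)
    return assemble(contigs_to_fragments(stage1), full_ref, full_index, options,
                    keep_member_ids=False)
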