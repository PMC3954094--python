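"""Readers and writers for standard formats (FASTA/FASTQ/SAM/BED, csfasta).

SAM is the single mapping-interchange format: simulated truth mappings are
emitted as SAM (reads placed at their true coordinates with mate fields set),
and externally mapped reads are imported from SAM, so the assembly module
consumes one representation for both. All coordinates in memory are 0-based,
half-open; conversion to/from SAM's 1-based positions happens only here.
"""

from __future__ import annotations

from dataclasses import dataclass

import pysam

from .assembly import Contig, MappedFragment
from .reads import SimulatedRead, reverse_complement
from .reference import ReferenceGenome


@dataclass
class MappingRecord:
    """One mapped primary alignment, losslessly convertible to a MappedFragment."""

    read_id: str
    seq_name: str
    start: int
    strand: str
    ref_span: int  # reference bases consumed (M/=/X/D/N), clipped bases excluded
    mate_seq_name: str | None = None
    mate_start: int | None = None
    is_paired: bool = False
    is_first: bool = True
    source: str = "imported"

    @property
    def end(self) -> int:
        return self.start + self.ref_span

    def to_fragment(self) -> MappedFragment:
        return MappedFragment(self.read_id, self.seq_name, self.start, self.end,
                              strand=self.strand, kind="read")


# ---------------------------------------------------------------------------
# reads out


def write_reads_fasta(reads: list[SimulatedRead], path) -> None:
    with open(path, "w") as fh:
        for r in reads:
            fh.write(f">{r.read_id}\n{r.observed}\n")


def write_reads_fastq(reads: list[SimulatedRead], path, phred: int = 30) -> None:
    """FASTQ with a constant quality (configurable Phred value)."""
    qchar = chr(phred + 33)
    with open(path, "w") as fh:
        for r in reads:
            fh.write(f"@{r.read_id}\n{r.observed}\n+\n{qchar * len(r.observed)}\n")


def write_reads_csfasta(reads: list[SimulatedRead], path) -> None:
    """csfasta-style color output for SOLiD-mode reads."""
    with open(path, "w") as fh:
        for r in reads:
            if r.colors is None:
                raise ValueError(f"read {r.read_id} has no color string (not colorspace)")
            fh.write(f">{r.read_id}\n{r.first_base}{r.colors}\n")


# ---------------------------------------------------------------------------
# SAM


def _truth_cigar(read: SimulatedRead) -> str:
    """CIGAR for a truth placement, reconstructed from the error records."""
    span = read.end - read.start
    indels = [(kind, off) for kind, off in read.errors if kind in ("ins", "del")]
    if not indels:
        return f"{len(read.observed)}M"
    # offsets are in the coordinates of the strand-oriented template; walk the
    # template emitting M runs split by I/D, then orient for SAM (forward strand)
    ops: list[tuple[str, int]] = []
    cur = 0
    for kind, off in sorted(indels, key=lambda t: t[1]):
        if off > cur:
            ops.append(("M", off - cur))
        ops.append(("I", 1) if kind == "ins" else ("D", 1))
        cur = off if kind == "ins" else off + 1
    if cur < span:
        ops.append(("M", span - cur))
    if read.strand == "-":
        ops.reverse()
    merged: list[tuple[str, int]] = []
    for op, n in ops:
        if merged and merged[-1][0] == op:
            merged[-1] = (op, merged[-1][1] + n)
        else:
            merged.append((op, n))
    return "".join(f"{n}{op}" for op, n in merged)


def write_truth_sam(reads: list[SimulatedRead], ref: ReferenceGenome, path) -> None:
    """Emit truth mappings: each read aligned at its origin interval."""
    header = {"HD": {"VN": "1.6", "SO": "unsorted"},
              "SQ": [{"SN": name, "LN": length} for name, length in ref.lengths.items()]}
    tids = {name: i for i, name in enumerate(ref.sequences)}
    by_id = {r.read_id: r for r in reads}
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for r in reads:
            a = pysam.AlignedSegment()
            paired = r.mate_id is not None
            qname = r.read_id
            if paired and qname.endswith(("/1", "/2")):
                qname = qname[:-2]
            a.query_name = qname
            a.reference_id = tids[r.seq_name]
            a.reference_start = r.start
            seq = r.observed if r.strand == "+" else reverse_complement(r.observed)
            a.query_sequence = seq
            a.cigarstring = _truth_cigar(r)
            flag = 0
            if r.strand == "-":
                flag |= 0x10
            if paired:
                mate = by_id[r.mate_id]
                flag |= 0x1 | 0x2 | (0x40 if r.read_id.endswith("/1") else 0x80)
                if mate.strand == "-":
                    flag |= 0x20
                a.next_reference_id = tids[mate.seq_name]
                a.next_reference_start = mate.start
                outer = max(r.end, mate.end) - min(r.start, mate.start)
                a.template_length = outer if r.start <= mate.start else -outer
            a.flag = flag
            a.mapping_quality = 60
            out.write(a)


def read_sam(path, ref: ReferenceGenome | None = None) -> tuple[list[MappingRecord], int]:
    """Parse mapped primary alignments; returns (records, n_skipped).

    Secondary/supplementary and unmapped records are skipped and counted.
    SAM's 1-based positions arrive 0-based through pysam; the reference span is
    the sum of M/=/X/D/N CIGAR lengths, so clipped bases are excluded.
    """
    records: list[MappingRecord] = []
    skipped = 0
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as fh:
        if ref is not None:
            for sq in fh.header.get("SQ", []):
                name, length = sq["SN"], sq["LN"]
                if name not in ref.sequences or len(ref.sequences[name]) != length:
                    raise ValueError(f"SAM header sequence {name!r} (LN={length}) "
                                     "does not match the reference")
        for a in fh:
            if a.is_unmapped or a.is_secondary or a.is_supplementary:
                skipped += 1
                continue
            read_id = a.query_name
            if a.is_paired:
                read_id += "/1" if a.is_read1 else "/2"
            records.append(MappingRecord(
                read_id=read_id,
                seq_name=a.reference_name,
                start=a.reference_start,
                strand="-" if a.is_reverse else "+",
                ref_span=a.reference_length,
                mate_seq_name=a.next_reference_name if a.is_paired else None,
                mate_start=a.next_reference_start if a.is_paired else None,
                is_paired=a.is_paired,
                is_first=not a.is_paired or a.is_read1,
            ))
    return records, skipped


def pair_records(records: list[MappingRecord]) -> tuple[list[tuple[MappingRecord, MappingRecord]],
                                                        list[MappingRecord]]:
    """Group paired records by query name; singletons are returned separately."""
    first: dict[str, MappingRecord] = {}
    second: dict[str, MappingRecord] = {}
    unpaired: list[MappingRecord] = []
    for rec in records:
        if not rec.is_paired:
            unpaired.append(rec)
        elif rec.is_first:
            first[rec.read_id[:-2]] = rec
        else:
            second[rec.read_id[:-2]] = rec
    pairs = [(first[q], second[q]) for q in first if q in second]
    unpaired.extend(first[q] for q in first if q not in second)
    unpaired.extend(second[q] for q in second if q not in first)
    return pairs, unpaired


# ---------------------------------------------------------------------------
# contigs / reports out


def write_contigs(contigs: list[Contig], ref: ReferenceGenome, bed_path,
                  fasta_path=None) -> None:
    """BED (0-based half-open) plus optional FASTA with scaffold gaps as N runs."""
    with open(bed_path, "w") as bed:
        for i, c in enumerate(contigs):
            bed.write(f"{c.seq_name}\t{c.start}\t{c.end}\tcontig_{i}\t{c.member_count}\n")
    if fasta_path is None:
        return
    with open(fasta_path, "w") as fa:
        for i, c in enumerate(contigs):
            seq = list(ref.substring(c.seq_name, c.start, c.end))
            for gs, ge in c.gaps:
                for p in range(gs - c.start, ge - c.start):
                    seq[p] = "N"
            fa.write(f">contig_{i} {c.seq_name}:{c.start}-{c.end}\n{''.join(seq)}\n")


def write_breakpoints(breakpoints, path) -> None:
    """Tab-separated breakpoint report with the certified cause of each break."""
    with open(path, "w") as fh:
        fh.write("seq_name\tposition\tcause\tleft\tright\toverlap\tmultiplicity\n")
        for b in breakpoints:
            mult = "" if b.multiplicity is None else b.multiplicity
            fh.write(f"{b.seq_name}\t{b.position}\t{b.cause}\t{b.left_id or ''}\t"
                     f"{b.right_id or ''}\t{b.overlap}\t{mult}\n")


def write_bac_layout(layout, bed_path) -> None:
    """BED-style clone intervals annotated with their pool."""
    pool_of = {cid: pid for pid, ids in layout.pools.items() for cid in ids}
    with open(bed_path, "w") as fh:
        for c in layout.clones:
            fh.write(f"{c.seq_name}\t{c.start}\t{c.end}\t{c.clone_id}\t{pool_of[c.clone_id]}\n")


def write_het_sites(diploid, bed_path) -> None:
    with open(bed_path, "w") as fh:
        for name, pos, a, b in diploid.het_sites:
            fh.write(f"{name}\t{pos}\t{pos + 1}\t{a}/{b}\n")
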