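"""Reference genomes: loading, random generation, planted repeats, diploids, BAC layouts.

All coordinates are 0-based, half-open. Sequences are plain Python strings over
the alphabet {A, C, G, T, N}; every generator takes an explicit integer seed or
a :class:`numpy.random.Generator` so runs are bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from Bio import SeqIO

BASES = "ACGT"
ALPHABET = frozenset("ACGTN")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
_BASE_ARR = np.frombuffer(b"ACGT", dtype=np.uint8)


def reverse_complement(seq: str) -> str:
    """Reverse complement of a sequence over {A,C,G,T,N}."""
    return seq.translate(_COMPLEMENT)[::-1]


def as_rng(seed) -> np.random.Generator:
    """Coerce an int seed (or an existing Generator) to a Generator."""
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


@dataclass
class ReferenceGenome:
    """A named collection of chromosome-like sequences, the ground truth of a simulation.

    Parameters
    ----------
    sequences
        Ordered mapping of sequence name to sequence string over {A,C,G,T,N}.
    """

    sequences: dict[str, str]

    def __post_init__(self) -> None:
        for name, seq in self.sequences.items():
            bad = set(seq) - ALPHABET
            if bad:
                raise ValueError(f"sequence {name!r} has characters outside ACGTN: {sorted(bad)}")

    @property
    def names(self) -> list[str]:
        return list(self.sequences)

    @property
    def lengths(self) -> dict[str, int]:
        return {name: len(seq) for name, seq in self.sequences.items()}

    @property
    def total_length(self) -> int:
        return sum(len(s) for s in self.sequences.values())

    def substring(self, name: str, start: int, end: int) -> str:
        seq = self.sequences[name]
        if not (0 <= start <= end <= len(seq)):
            raise ValueError(f"[{start}, {end}) out of bounds for {name!r} (length {len(seq)})")
        return seq[start:end]

    def subset(self, names) -> "ReferenceGenome":
        """A new genome restricted to the given sequence names (order preserved)."""
        return ReferenceGenome({n: self.sequences[n] for n in names})


@dataclass
class RepeatCopy:
    """Coordinates of one planted repeat copy."""

    seq_name: str
    start: int
    end: int
    strand: str = "+"


@dataclass
class DiploidReference:
    """Two structurally identical homologs differing only at recorded heterozygous sites.

    ``het_sites`` entries are ``(seq_name, position, base_a, base_b)`` with
    ``base_a != base_b``; positions refer to both homologs (substitution-only
    heterozygosity preserves coordinates).
    """

    homolog_a: ReferenceGenome
    homolog_b: ReferenceGenome
    het_sites: list[tuple[str, int, str, str]]
    SUFFIX_A = "_hapA"
    SUFFIX_B = "_hapB"

    def combined(self) -> ReferenceGenome:
        """Both homologs as one genome, sequence names suffixed _hapA/_hapB."""
        seqs: dict[str, str] = {}
        for name, seq in self.homolog_a.sequences.items():
            seqs[name + self.SUFFIX_A] = seq
        for name, seq in self.homolog_b.sequences.items():
            seqs[name + self.SUFFIX_B] = seq
        return ReferenceGenome(seqs)

    def het_positions(self) -> dict[str, np.ndarray]:
        """Sorted het-site positions per combined-genome sequence name."""
        per_base: dict[str, list[int]] = {n: [] for n in self.homolog_a.sequences}
        for name, pos, _a, _b in self.het_sites:
            per_base[name].append(pos)
        out: dict[str, np.ndarray] = {}
        for name, positions in per_base.items():
            arr = np.asarray(sorted(positions), dtype=np.int64)
            out[name + self.SUFFIX_A] = arr
            out[name + self.SUFFIX_B] = arr
        return out


@dataclass
class BACClone:
    clone_id: str
    seq_name: str
    start: int
    end: int


@dataclass
class BACLayout:
    """A simulated BAC library: clone intervals on the reference plus a pool partition."""

    clones: list[BACClone]
    pools: dict[str, list[str]]  # pool id -> clone ids
    clone_length: int
    bac_coverage: float

    def clones_by_id(self) -> dict[str, BACClone]:
        return {c.clone_id: c for c in self.clones}


# ---------------------------------------------------------------------------
# loading / generation


def load_fasta(path) -> ReferenceGenome:
    """Load a FASTA file; lowercase is folded and IUPAC ambiguity codes become N."""
    seqs: dict[str, str] = {}
    n_records = 0
    for rec in SeqIO.parse(str(path), "fasta"):
        n_records += 1
        if rec.id in seqs:
            raise ValueError(f"duplicate sequence name {rec.id!r} in {path}")
        seq = str(rec.seq).upper()
        cleaned = "".join(c if c in "ACGT" else "N" for c in seq)
        seqs[rec.id] = cleaned
    if n_records == 0:
        raise ValueError(f"no FASTA records found in {path}")
    return ReferenceGenome(seqs)


def random_sequence(length: int, rng: np.random.Generator, base_freqs=(0.25, 0.25, 0.25, 0.25)) -> str:
    freqs = np.asarray(base_freqs, dtype=float)
    if freqs.shape != (4,) or abs(freqs.sum() - 1.0) > 1e-9 or (freqs < 0).any():
        raise ValueError("base_freqs must be 4 non-negative probabilities summing to 1")
    if length < 1:
        raise ValueError("length must be >= 1")
    idx = rng.choice(4, size=length, p=freqs)
    return _BASE_ARR[idx].tobytes().decode()


def random_reference(length: int, base_freqs=(0.25, 0.25, 0.25, 0.25), seed=0,
                     name: str = "random") -> ReferenceGenome:
    """A single random sequence with i.i.d. bases at the given frequencies."""
    rng = as_rng(seed)
    return ReferenceGenome({name: random_sequence(length, rng, base_freqs)})


def plant_repeats(unique_segment_lengths, repeat_unit: str, orientations=None, seed=0,
                  name: str = "planted",
                  distinct_copy_flanks: bool = False) -> tuple[ReferenceGenome, list[RepeatCopy]]:
    """Build U1 R U2 R ... Un with exact repeat copies between random unique segments.

    ``orientations`` gives '+'/'-' per copy ('-' plants the reverse complement);
    default is all forward. At least two copies (three unique segments) are
    required — a single copy is not a repeat.

    With ``distinct_copy_flanks`` (at most 4 copies, forward orientations) the
    base immediately before and after each copy is forced to differ across
    copies, so any substring extending even one base past a copy boundary is
    guaranteed unique — otherwise a chance flank coincidence (probability
    ~4^-f for an f-base flank match) could create an extra repeated junction.
    """
    lengths = list(unique_segment_lengths)
    n_copies = len(lengths) - 1
    if n_copies < 2:
        raise ValueError("need at least 3 unique segments (>= 2 repeat copies)")
    if orientations is None:
        orientations = ["+"] * n_copies
    if len(orientations) != n_copies:
        raise ValueError("one orientation per repeat copy required")
    if distinct_copy_flanks and n_copies > 4:
        raise ValueError("distinct_copy_flanks supports at most 4 copies")
    rng = as_rng(seed)
    segments = [random_sequence(ulen, rng) for ulen in lengths]
    if distinct_copy_flanks:
        for i in range(n_copies):
            segments[i] = segments[i][:-1] + BASES[i]          # base before copy i
            segments[i + 1] = BASES[(i + 1) % 4] + segments[i + 1][1:]  # base after
    parts: list[str] = []
    copies: list[RepeatCopy] = []
    pos = 0
    for i, seg in enumerate(segments):
        parts.append(seg)
        pos += len(seg)
        if i < n_copies:
            unit = repeat_unit if orientations[i] == "+" else reverse_complement(repeat_unit)
            parts.append(unit)
            copies.append(RepeatCopy(name, pos, pos + len(unit), orientations[i]))
            pos += len(unit)
    return ReferenceGenome({name: "".join(parts)}), copies


def scatter_repeats(length: int, repeat_unit: str, n_copies: int, seed=0,
                    name: str = "planted") -> tuple[ReferenceGenome, list[RepeatCopy]]:
    """Random genome of exactly ``length`` with ``n_copies`` of a unit written at
    random non-overlapping positions (background bases overwritten)."""
    if n_copies < 2:
        raise ValueError("need >= 2 copies to form a repeat")
    unit_len = len(repeat_unit)
    if n_copies * unit_len > length:
        raise ValueError("copies do not fit in the requested length")
    rng = as_rng(seed)
    seq = np.frombuffer(random_sequence(length, rng).encode(), dtype=np.uint8).copy()
    placed: list[int] = []
    unit_bytes = np.frombuffer(repeat_unit.encode(), dtype=np.uint8)
    while len(placed) < n_copies:
        start = int(rng.integers(0, length - unit_len + 1))
        if all(start + unit_len <= p or p + unit_len <= start for p in placed):
            placed.append(start)
    placed.sort()
    for start in placed:
        seq[start:start + unit_len] = unit_bytes
    genome = ReferenceGenome({name: seq.tobytes().decode()})
    return genome, [RepeatCopy(name, s, s + unit_len) for s in placed]


def make_diploid(ref: ReferenceGenome, het_rate: float, seed=0) -> DiploidReference:
    """Introduce substitution heterozygosity at rate ``het_rate`` per non-N site.

    Each heterozygous site keeps the reference base on homolog A and gets a
    uniformly chosen different base on homolog B; N sites are never mutated.
    """
    if not 0.0 <= het_rate <= 1.0:
        raise ValueError("het_rate must be in [0, 1]")
    rng = as_rng(seed)
    b_seqs: dict[str, str] = {}
    het_sites: list[tuple[str, int, str, str]] = []
    for name, seq in ref.sequences.items():
        arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
        eligible = arr != ord("N")
        hits = np.flatnonzero(eligible & (rng.random(len(arr)) < het_rate))
        for pos in hits:
            base_a = chr(arr[pos])
            alt = [b for b in BASES if b != base_a]
            base_b = alt[int(rng.integers(0, 3))]
            arr[pos] = ord(base_b)
            het_sites.append((name, int(pos), base_a, base_b))
        b_seqs[name] = arr.tobytes().decode()
    return DiploidReference(
        homolog_a=ReferenceGenome(dict(ref.sequences)),
        homolog_b=ReferenceGenome(b_seqs),
        het_sites=het_sites,
    )


def simulate_bac_layout(ref: ReferenceGenome, clone_length: int, bac_coverage: float,
                        pool_size: int, seed=0) -> BACLayout:
    """Sample a BAC clone library and partition it into pools.

    The clone count is round(bac_coverage * total_length / clone_length); starts
    are uniform and independent over positions where a full clone fits (clones
    may overlap, as in shotgun-style library construction). Clones are assigned
    to pools by a random partition into groups of ``pool_size``.
    """
    eligible = [(n, len(s)) for n, s in ref.sequences.items() if len(s) >= clone_length]
    if not eligible:
        raise ValueError("clone_length exceeds every reference sequence length")
    rng = as_rng(seed)
    n_clones = int(round(bac_coverage * ref.total_length / clone_length))
    names = [n for n, _ in eligible]
    weights = np.array([length - clone_length + 1 for _, length in eligible], dtype=float)
    weights /= weights.sum()
    clones: list[BACClone] = []
    seq_choice = rng.choice(len(names), size=n_clones, p=weights)
    for i in range(n_clones):
        name, length = eligible[seq_choice[i]]
        start = int(rng.integers(0, length - clone_length + 1))
        clones.append(BACClone(f"clone_{i:05d}", name, start, start + clone_length))
    order = rng.permutation(n_clones)
    pools: dict[str, list[str]] = {}
    for j in range(0, n_clones, pool_size):
        pool_id = f"pool_{j // pool_size:04d}"
        pools[pool_id] = [clones[idx].clone_id for idx in order[j:j + pool_size]]
    return BACLayout(clones=clones, pools=pools, clone_length=clone_length,
                     bac_coverage=bac_coverage)
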