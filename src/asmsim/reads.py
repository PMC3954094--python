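"""Shotgun read simulation: unpaired/paired reads with configurable errors.

Reads are drawn uniformly from both strands of the reference, restricted to
windows free of N so that unknown regions behave as forced coverage gaps.
Each read retains its true origin interval, which downstream assembly uses as
the (errorless) truth mapping; sequencing errors change the observed sequence
but never the truth interval.

Paired protocols specify the relative orientation and a [min, max] range for
the intervening (inner) distance between the facing mate ends; sampled
distances follow a normal distribution whose 95% central interval equals the
range. SOLiD-style data is emulated in color space: each color encodes a base
transition, and a single miscalled color corrupts every naively decoded base
downstream of it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .reference import ReferenceGenome, as_rng, reverse_complement

#: two-sided 95% standard-normal quantile used to convert a range to an SD
Z_95 = 1.959963984540054

_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}
_BASE = "ACGT"


@dataclass
class ErrorModel:
    """Per-base error probabilities. In color space, errors are color miscalls
    only and nucleotide insertion/deletion rates are ignored."""

    sub_rate: float = 0.0
    ins_rate: float = 0.0
    del_rate: float = 0.0
    colorspace: bool = False
    color_miscall_rate: float = 0.0

    def __post_init__(self) -> None:
        for rate in (self.sub_rate, self.ins_rate, self.del_rate, self.color_miscall_rate):
            if not 0.0 <= rate <= 1.0:
                raise ValueError("error rates must lie in [0, 1]")


@dataclass
class PairedProtocol:
    """Mate-pair geometry.

    ``distance_min``/``distance_max`` bound the intervening distance between
    the facing ends of the two mates (95% of sampled distances fall inside).
    With ``range_is_outer_span`` the range is interpreted as the outer
    fragment span instead, i.e. inner distance = span - 2 * read_length.
    """

    distance_min: int
    distance_max: int
    orientation: str = "fr"  # fr | rf | ff
    range_is_outer_span: bool = False

    def __post_init__(self) -> None:
        if not 0 <= self.distance_min <= self.distance_max:
            raise ValueError("require 0 <= distance_min <= distance_max")
        if self.orientation not in ("fr", "rf", "ff"):
            raise ValueError("orientation must be one of fr, rf, ff")

    def inner_limits(self, read_length: int) -> tuple[int, int]:
        if self.range_is_outer_span:
            return (max(0, self.distance_min - 2 * read_length),
                    max(0, self.distance_max - 2 * read_length))
        return self.distance_min, self.distance_max


@dataclass
class SimulatedRead:
    """One simulated read with its ground-truth origin.

    ``start``/``end`` are the origin interval on the reference (0-based,
    half-open); ``observed`` is the read sequence in read orientation with
    errors applied. ``errors`` holds ``(kind, offset)`` records where offset
    is in read coordinates ('sub'/'ins') or reference-window coordinates
    ('del', 'color').
    """

    read_id: str
    seq_name: str
    start: int
    end: int
    strand: str
    observed: str
    errors: list[tuple[str, int]] = field(default_factory=list)
    mate_id: str | None = None
    pair_distance: int | None = None
    first_base: str | None = None
    colors: str | None = None

    @property
    def span(self) -> int:
        return self.end - self.start


# ---------------------------------------------------------------------------
# counts and distances


def read_count_for_coverage(total_length: int, read_length: int, coverage: float,
                            paired: bool = False) -> int:
    """Number of reads (or pairs) needed for a target fold-coverage.

    Coverage counts sequenced bases only, so a pair contributes two read
    lengths, never its intervening gap.
    """
    if total_length <= 0 or read_length <= 0 or coverage <= 0:
        raise ValueError("arguments must be positive")
    if read_length > total_length:
        raise ValueError("read_length exceeds the reference length")
    denom = 2 * read_length if paired else read_length
    return int(round(coverage * total_length / denom))


def sample_pair_distance(protocol: PairedProtocol, rng: np.random.Generator,
                         read_length: int | None = None) -> int:
    """One inner distance draw: Normal with 95% mass inside the protocol range,
    rounded to the nearest integer and clamped at 0."""
    lo, hi = (protocol.inner_limits(read_length) if protocol.range_is_outer_span
              else (protocol.distance_min, protocol.distance_max))
    mean = (lo + hi) / 2.0
    sd = (hi - lo) / (2.0 * Z_95)
    d = rng.normal(mean, sd) if sd > 0 else mean
    return max(0, int(round(d)))


# ---------------------------------------------------------------------------
# color space


def encode_colorspace(seq: str) -> tuple[str, str]:
    """SOLiD two-base encoding: color_i = code(base_i) XOR code(base_{i+1})."""
    if not seq or not set(seq) <= set("ACGT"):
        raise ValueError("colorspace encoding requires a non-empty ACGT sequence")
    codes = [_CODE[c] for c in seq]
    colors = "".join(str(codes[i] ^ codes[i + 1]) for i in range(len(codes) - 1))
    return seq[0], colors


def decode_colorspace(first_base: str, colors: str) -> str:
    """Invert :func:`encode_colorspace` (naive decode: errors propagate)."""
    if first_base not in _CODE:
        raise ValueError("first base must be one of ACGT")
    out = [_CODE[first_base]]
    for c in colors:
        out.append(out[-1] ^ int(c))
    return "".join(_BASE[v] for v in out)


def apply_color_errors(read: SimulatedRead, rate: float, rng: np.random.Generator) -> SimulatedRead:
    """Miscall each color independently with probability ``rate`` (uniform among
    the three wrong colors) and re-decode; the observed nucleotides therefore
    carry the full downstream corruption of each miscall."""
    first, colors = encode_colorspace(read.observed)
    color_arr = np.frombuffer(colors.encode(), dtype=np.uint8) - ord("0")
    hits = np.flatnonzero(rng.random(len(color_arr)) < rate)
    color_arr = color_arr.copy()
    for i in hits:
        wrong = [c for c in range(4) if c != color_arr[i]]
        color_arr[i] = wrong[int(rng.integers(0, 3))]
        read.errors.append(("color", int(i)))
    miscalled = "".join(str(int(c)) for c in color_arr)
    read.first_base = first
    read.colors = miscalled
    read.observed = decode_colorspace(first, miscalled)
    return read


# ---------------------------------------------------------------------------
# sampling machinery


class _WindowSampler:
    """Uniform sampling of N-free windows across the sequences of a genome."""

    def __init__(self, ref: ReferenceGenome, window: int):
        self.ref = ref
        self.window = window
        self.names: list[str] = []
        self._n_prefix: dict[str, np.ndarray] = {}
        counts = []
        for name, seq in ref.sequences.items():
            if len(seq) < window:
                continue
            arr = np.frombuffer(seq.encode(), dtype=np.uint8)
            pref = np.zeros(len(seq) + 1, dtype=np.int64)
            np.cumsum(arr == ord("N"), out=pref[1:])
            n_valid = int(np.count_nonzero(pref[window:] - pref[:-window] == 0))
            if n_valid > 0:
                self.names.append(name)
                self._n_prefix[name] = pref
                counts.append(n_valid)
        if not self.names:
            raise ValueError(f"no N-free window of length {window} exists in the reference")
        self._weights = np.asarray(counts, dtype=float) / sum(counts)
        self._n_free = all(self._n_prefix[name][-1] == 0 for name in self.names)

    def window_is_clean(self, name: str, start: int, length: int) -> bool:
        pref = self._n_prefix[name]
        return pref[start + length] - pref[start] == 0

    def sample_array(self, n: int, rng: np.random.Generator) -> dict[str, np.ndarray]:
        """``n`` draws as unsorted start arrays per sequence (vectorized)."""
        seq_idx = (np.zeros(n, dtype=np.int64) if len(self.names) == 1
                   else rng.choice(len(self.names), size=n, p=self._weights))
        out: dict[str, np.ndarray] = {}
        for k, name in enumerate(self.names):
            count = int(np.count_nonzero(seq_idx == k))
            if count == 0:
                continue
            hi = len(self.ref.sequences[name]) - self.window + 1
            if self._n_free:
                out[name] = rng.integers(0, hi, size=count)
            else:
                starts = np.empty(0, dtype=np.int64)
                pref = self._n_prefix[name]
                while len(starts) < count:
                    draw = rng.integers(0, hi, size=2 * (count - len(starts)) + 16)
                    clean = draw[pref[draw + self.window] - pref[draw] == 0]
                    starts = np.concatenate([starts, clean])
                out[name] = starts[:count]
        return out

    def sample(self, n: int, rng: np.random.Generator) -> list[tuple[str, int]]:
        """``n`` (name, start) draws; windows containing N are rejected and redrawn."""
        out: list[tuple[str, int]] = []
        while len(out) < n:
            batch = min(4096, 2 * (n - len(out)) + 16)
            picks = rng.choice(len(self.names), size=batch, p=self._weights)
            for k in picks:
                if len(out) == n:
                    break
                name = self.names[k]
                hi = len(self.ref.sequences[name]) - self.window + 1
                start = int(rng.integers(0, hi))
                if self.window_is_clean(name, start, self.window):
                    out.append((name, start))
        return out


def sample_read_starts(ref: ReferenceGenome, read_length: int, count: int,
                       rng: np.random.Generator) -> dict[str, np.ndarray]:
    """Truth intervals only (no sequences): sorted start arrays per sequence.

    This is the high-throughput path for unpaired simulations where only the
    origin intervals matter to the assembly; it draws from the same window
    distribution as :func:`simulate_reads`.
    """
    sampler = _WindowSampler(ref, read_length)
    return {name: np.sort(starts.astype(np.int64))
            for name, starts in sampler.sample_array(count, rng).items()}


def _apply_nucleotide_errors(observed: str, model: ErrorModel,
                             rng: np.random.Generator) -> tuple[str, list[tuple[str, int]]]:
    errors: list[tuple[str, int]] = []
    chars = list(observed)
    if model.sub_rate > 0:
        for i in np.flatnonzero(rng.random(len(chars)) < model.sub_rate):
            wrong = [b for b in _BASE if b != chars[i]]
            chars[i] = wrong[int(rng.integers(0, 3))]
            errors.append(("sub", int(i)))
    # indels: evaluated per original position, applied right-to-left so offsets
    # recorded in reference-window coordinates stay meaningful
    if model.ins_rate > 0 or model.del_rate > 0:
        n = len(chars)
        ins_hits = set(np.flatnonzero(rng.random(n) < model.ins_rate).tolist()) if model.ins_rate > 0 else set()
        del_hits = set(np.flatnonzero(rng.random(n) < model.del_rate).tolist()) if model.del_rate > 0 else set()
        for i in range(n - 1, -1, -1):
            if i in del_hits:
                del chars[i]
                errors.append(("del", i))
            elif i in ins_hits:
                chars.insert(i, _BASE[int(rng.integers(0, 4))])
                errors.append(("ins", i))
        errors.reverse()
    return "".join(chars), errors


def simulate_reads(ref: ReferenceGenome, read_length: int, *, coverage: float | None = None,
                   count: int | None = None, error_model: ErrorModel | None = None,
                   paired: PairedProtocol | None = None, seed=0) -> list[SimulatedRead]:
    """Simulate reads (or mate pairs) with ground-truth origins.

    Exactly one of ``coverage`` and ``count`` must be given; ``count`` is the
    number of reads (unpaired) or pairs (paired). Start positions are uniform
    over N-free windows on both strands; with a paired protocol the whole
    fragment (two mates plus the sampled inner distance) must be N-free, and
    draws that fail are rejected and resampled so the requested count is met.
    """
    if read_length < 1:
        raise ValueError("read_length must be >= 1")
    if (coverage is None) == (count is None):
        raise ValueError("give exactly one of coverage= or count=")
    model = error_model or ErrorModel()
    rng = as_rng(seed)
    if count is None:
        count = read_count_for_coverage(ref.total_length, read_length, coverage,
                                        paired=paired is not None)
    reads: list[SimulatedRead] = []
    if paired is None:
        sampler = _WindowSampler(ref, read_length)
        for n, (name, start) in enumerate(sampler.sample(count, rng)):
            strand = "+" if rng.random() < 0.5 else "-"
            reads.append(_make_read(ref, f"sim_{n}", name, start, read_length, strand,
                                    model, rng))
        return reads

    lo, hi = paired.inner_limits(read_length)
    max_span = 2 * read_length + hi
    sampler = _WindowSampler(ref, min(max_span, max(2 * read_length, read_length)))
    # fragment placement: left mate start uniform, full span must fit and be N-free
    made = 0
    attempts = 0
    limit = 1000 * count + 1000
    while made < count:
        attempts += 1
        if attempts > limit:
            raise ValueError("could not place the requested number of pairs "
                             "(fragments do not fit in any N-free window)")
        distance = sample_pair_distance(paired, rng, read_length)
        span = 2 * read_length + distance
        name = sampler.names[int(rng.choice(len(sampler.names), p=sampler._weights))]
        seq_len = len(ref.sequences[name])
        if span > seq_len:
            continue
        start = int(rng.integers(0, seq_len - span + 1))
        if not sampler.window_is_clean(name, start, span):
            continue
        flip = rng.random() < 0.5  # fragment as a whole sits on either strand
        s1 = "+" if not flip else "-"
        if paired.orientation == "fr":
            s2 = "-" if s1 == "+" else "+"
        elif paired.orientation == "rf":
            s1, s2 = ("-", "+") if not flip else ("+", "-")
        else:  # ff
            s2 = s1
        r1 = _make_read(ref, f"sim_{made}/1", name, start, read_length, s1, model, rng)
        r2 = _make_read(ref, f"sim_{made}/2", name, start + read_length + distance,
                        read_length, s2, model, rng)
        r1.mate_id, r2.mate_id = r2.read_id, r1.read_id
        r1.pair_distance = r2.pair_distance = distance
        reads.extend((r1, r2))
        made += 1
    return reads


def _make_read(ref: ReferenceGenome, read_id: str, name: str, start: int, length: int,
               strand: str, model: ErrorModel, rng: np.random.Generator) -> SimulatedRead:
    template = ref.substring(name, start, start + length)
    if strand == "-":
        template = reverse_complement(template)
    read = SimulatedRead(read_id=read_id, seq_name=name, start=start, end=start + length,
                         strand=strand, observed=template)
    if model.colorspace:
        if model.color_miscall_rate > 0:
            apply_color_errors(read, model.color_miscall_rate, rng)
        else:
            read.first_base, read.colors = encode_colorspace(read.observed)
    elif model.sub_rate or model.ins_rate or model.del_rate:
        read.observed, read.errors = _apply_nucleotide_errors(read.observed, model, rng)
    return read
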