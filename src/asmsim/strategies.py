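"""Strategy drivers: shotgun, chromosome sorting, BAC sequencing/pooling, phase.

Each driver composes the generators, the read simulator, the assembly
simulator and the metrics into one reproducible experiment. The strategies
differ (almost) only in the multiplicity scope used for the repeat predicate:

* shotgun               — scope is the whole genome;
* chromosome sorting    — each chromosome is assembled with scope restricted
                          to that chromosome (sorting thins out repeats);
* BAC sequencing/pooling— two-stage assembly with scope = one clone
                          (barcoded) or one clone pool (pooled);
* phase                 — both homologs of a diploid form the scope, so
                          homozygous stretches behave as repeats and only
                          het-site-covering reads assemble.

A master seed derives per-stage child seeds deterministically, so whole runs
are reproducible end to end.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from . import reference as refmod
from .assembly import (AssemblyOptions, AssemblyResult, MappedFragment, assemble,
                       assemble_diploid, assemble_read_starts, pairs_to_fragments,
                       two_stage_assemble, PhaseBlock)
from .metrics import AssemblyReport, summarize
from .reads import ErrorModel, PairedProtocol, read_count_for_coverage, sample_pair_distance, sample_read_starts
from .reference import BACLayout, DiploidReference, ReferenceGenome
from .repeats import RepeatIndex

STRATEGIES = ("shotgun", "chromosome_sorting", "bac", "phase")


@dataclass
class StrategyConfig:
    """Declarative description of one simulation experiment.

    ``reference`` may be a ReferenceGenome/DiploidReference instance or a spec
    dict (kind: fasta|random|planted, plus parameters) resolved at run time.
    ``coverage`` is fold-coverage in sequenced bases; for the phase strategy it
    is the *total* depth over both homologs (half per homolog). BAC fields are
    only legal with the ``bac`` strategy.
    """

    strategy: str
    reference: object
    read_length: int
    coverage: float
    seed: int
    paired: PairedProtocol | None = None
    error_model: ErrorModel | None = None
    min_overlap: int = 1
    het_rate: float | None = None          # phase: diploidize the base reference
    clone_length: int | None = None        # bac
    bac_coverage: float | None = None      # bac
    pool_size: int | None = None           # bac
    barcoded: bool = False                 # bac
    label: str | None = None

    def validate(self) -> None:
        if self.strategy not in STRATEGIES:
            raise ValueError(f"unknown strategy {self.strategy!r}")
        bac_fields = (self.clone_length, self.bac_coverage, self.pool_size)
        if self.strategy == "bac":
            if any(v is None for v in bac_fields):
                raise ValueError("bac strategy requires clone_length, bac_coverage, pool_size")
        elif any(v is not None for v in bac_fields) or (self.strategy != "bac" and self.barcoded):
            raise ValueError("BAC parameters are only valid with strategy='bac'")
        if self.strategy == "phase":
            if self.het_rate is None and not isinstance(self.reference, DiploidReference):
                raise ValueError("phase strategy needs het_rate or a DiploidReference")
        elif self.het_rate is not None:
            raise ValueError("het_rate is only valid with strategy='phase'")


@dataclass
class StrategyResult:
    config: StrategyConfig
    report: AssemblyReport
    assembly: AssemblyResult
    phase_blocks: list[PhaseBlock] | None = None
    extra: dict = field(default_factory=dict)


def _child_rngs(seed: int, n: int) -> list[np.random.Generator]:
    return [np.random.default_rng(c) for c in np.random.SeedSequence(seed).spawn(n)]


def build_reference(spec, rng: np.random.Generator):
    """Resolve a reference spec (instance or dict) into a genome object."""
    if isinstance(spec, (ReferenceGenome, DiploidReference)):
        return spec
    if not isinstance(spec, dict) or "kind" not in spec:
        raise ValueError("reference spec must be a genome object or a dict with 'kind'")
    kind = spec["kind"]
    if kind == "fasta":
        return refmod.load_fasta(spec["path"])
    if kind == "random":
        return refmod.random_reference(spec["length"],
                                       tuple(spec.get("base_freqs", (0.25,) * 4)), rng)
    if kind == "planted":
        genome, _ = refmod.scatter_repeats(spec["length"], spec["repeat_unit"],
                                           spec["n_copies"], rng)
        return genome
    raise ValueError(f"unknown reference kind {kind!r}")


# ---------------------------------------------------------------------------
# per-strategy runners


def _simulate_unpaired_starts(ref: ReferenceGenome, read_length: int, coverage: float,
                              rng: np.random.Generator) -> dict[str, np.ndarray]:
    n = read_count_for_coverage(ref.total_length, read_length, coverage)
    return sample_read_starts(ref, read_length, n, rng)


def _assemble_unpaired(ref: ReferenceGenome, starts_by_seq: dict[str, np.ndarray],
                       read_length: int, options: AssemblyOptions,
                       index_for: dict[str, RepeatIndex]) -> AssemblyResult:
    contigs, breaks = [], []
    for name, starts in starts_by_seq.items():
        res = assemble_read_starts(name, starts, read_length, ref, index_for[name], options)
        contigs.extend(res.contigs)
        breaks.extend(res.breakpoints)
    return AssemblyResult(contigs, breaks)


def _simulate_pair_fragments(ref: ReferenceGenome, read_length: int, coverage: float,
                             protocol: PairedProtocol, index: RepeatIndex,
                             options: AssemblyOptions,
                             rng: np.random.Generator) -> tuple[list[MappedFragment], object]:
    """Sample pairs as truth intervals and convert them to span fragments.

    Vectorized variant of simulate_reads + pairs_to_fragments for deep runs:
    only the two mate intervals matter to the assembly, so observed sequences
    are never materialized.
    """
    n_pairs = read_count_for_coverage(ref.total_length, read_length, coverage, paired=True)
    lo, hi = protocol.inner_limits(read_length)
    opts = AssemblyOptions(min_overlap=options.min_overlap,
                           pair_distance_min=lo, pair_distance_max=hi,
                           demote_discarded_pairs=options.demote_discarded_pairs)

    class _Mate:
        __slots__ = ("read_id", "seq_name", "start", "end")

        def __init__(self, read_id, seq_name, start, end):
            self.read_id, self.seq_name, self.start, self.end = read_id, seq_name, start, end

    pairs = []
    names = list(ref.sequences)
    lengths = np.array([len(ref.sequences[n]) for n in names], dtype=float)
    weights = lengths / lengths.sum()
    made = 0
    while made < n_pairs:
        batch = min(n_pairs - made, 65536)
        d = np.maximum(0, np.round(rng.normal((lo + hi) / 2,
                                              (hi - lo) / (2 * 1.959963984540054) if hi > lo else 0,
                                              size=batch))).astype(np.int64)
        seq_idx = rng.choice(len(names), size=batch, p=weights)
        for k in range(batch):
            name = names[seq_idx[k]]
            span = 2 * read_length + int(d[k])
            seq_len = len(ref.sequences[name])
            if span > seq_len:
                continue
            s = int(rng.integers(0, seq_len - span + 1))
            m1 = _Mate(f"p{made}/1", name, s, s + read_length)
            m2 = _Mate(f"p{made}/2", name, s + read_length + int(d[k]), s + span)
            pairs.append((m1, m2))
            made += 1
            if made == n_pairs:
                break
    return pairs_to_fragments(pairs, ref, index, opts)


def run_strategy(config: StrategyConfig) -> StrategyResult:
    """Execute one experiment: generate -> simulate -> assemble -> measure."""
    config.validate()
    ref_rng, read_rng, aux_rng = _child_rngs(config.seed, 3)
    options = AssemblyOptions(min_overlap=config.min_overlap)
    base_ref = build_reference(config.reference, ref_rng)

    if config.strategy == "phase":
        return _run_phase(config, base_ref, options, ref_rng, read_rng)
    if config.strategy == "bac":
        return _run_bac(config, base_ref, options, read_rng, aux_rng)

    ref: ReferenceGenome = base_ref
    if config.strategy == "chromosome_sorting":
        index_for = {name: RepeatIndex(ref.subset([name])) for name in ref.sequences}
    else:
        whole = RepeatIndex(ref)
        index_for = {name: whole for name in ref.sequences}

    pair_report = None
    if config.paired is None:
        starts = _simulate_unpaired_starts(ref, config.read_length, config.coverage, read_rng)
        result = _assemble_unpaired(ref, starts, config.read_length, options, index_for)
    else:
        if config.strategy == "chromosome_sorting":
            # pair uniqueness and assembly both against the per-chromosome scope
            contigs, breaks = [], []
            for name in ref.sequences:
                sub = ref.subset([name])
                frags, _ = _simulate_pair_fragments(sub, config.read_length,
                                                    config.coverage, config.paired,
                                                    index_for[name], options, read_rng)
                res = assemble(frags, sub, index_for[name], options, keep_member_ids=False)
                contigs.extend(res.contigs)
                breaks.extend(res.breakpoints)
            result = AssemblyResult(contigs, breaks)
        else:
            frags, pair_report = _simulate_pair_fragments(ref, config.read_length,
                                                          config.coverage, config.paired,
                                                          index_for[next(iter(ref.sequences))],
                                                          options, read_rng)
            result = assemble(frags, ref, index_for[next(iter(ref.sequences))], options,
                              keep_member_ids=False)
    report = summarize(result.contigs, ref)
    return StrategyResult(config, report, result,
                          extra={"pair_report": pair_report} if pair_report else {})


def _run_phase(config: StrategyConfig, base_ref, options, ref_rng, read_rng) -> StrategyResult:
    if isinstance(base_ref, DiploidReference):
        diploid = base_ref
    else:
        diploid = refmod.make_diploid(base_ref, config.het_rate, ref_rng)
    combined = diploid.combined()
    index = RepeatIndex(combined)
    if config.paired is None:
        # total depth over both homologs: per-site coverage of the combined genome
        starts = _simulate_unpaired_starts(combined, config.read_length,
                                           config.coverage / 2, read_rng)
        fragments = [MappedFragment(f"r_{name}_{i}", name, int(s),
                                    int(s) + config.read_length)
                     for name, arr in starts.items() for i, s in enumerate(arr)]
    else:
        pair_frags, _ = _simulate_pair_fragments(combined, config.read_length,
                                                 config.coverage / 2, config.paired,
                                                 index, options, read_rng)
        fragments = pair_frags
    result, blocks = assemble_diploid(diploid, fragments, options, index=index,
                                      keep_member_ids=False)
    report = summarize(result.contigs, combined)
    multi = [b for b in blocks if len(b.het_positions) >= 2]
    extra = {
        "n_het_sites": len(diploid.het_sites),
        "n_phase_blocks": len(multi),
        "n_sites_in_multi_blocks": sum(len(b.het_positions) for b in multi),
    }
    return StrategyResult(config, report, result, phase_blocks=blocks, extra=extra)


def _run_bac(config: StrategyConfig, ref: ReferenceGenome, options,
             read_rng, aux_rng) -> StrategyResult:
    layout = refmod.simulate_bac_layout(ref, config.clone_length, config.bac_coverage,
                                        config.pool_size, aux_rng)
    reads_by_clone: dict[str, list[MappedFragment]] = {}
    for clone in layout.clones:
        n = read_count_for_coverage(clone.end - clone.start, config.read_length,
                                    config.coverage)
        clone_ref = ReferenceGenome({clone.seq_name:
                                     ref.substring(clone.seq_name, clone.start, clone.end)})
        starts = sample_read_starts(clone_ref, config.read_length, n, read_rng)
        frags = [MappedFragment(f"{clone.clone_id}_r{j}", clone.seq_name,
                                clone.start + int(s), clone.start + int(s) + config.read_length)
                 for j, s in enumerate(starts.get(clone.seq_name, []))]
        reads_by_clone[clone.clone_id] = frags
    mode = "barcoded" if config.barcoded else "pooled"
    full_index = RepeatIndex(ref)
    result = two_stage_assemble(layout, reads_by_clone, ref, options, mode=mode,
                                full_index=full_index)
    report = summarize(result.contigs, ref)
    return StrategyResult(config, report, result, extra={"n_clones": len(layout.clones),
                                                         "n_pools": len(layout.pools)})


# ---------------------------------------------------------------------------
# sweeps


def sweep(configs: list[StrategyConfig]) -> pd.DataFrame:
    """Run several configs and tabulate one report row per config."""
    rows = []
    for cfg in configs:
        res = run_strategy(cfg)
        row = {
            "label": cfg.label or cfg.strategy,
            "strategy": cfg.strategy,
            "read_length": cfg.read_length,
            "coverage": cfg.coverage,
            "min_overlap": cfg.min_overlap,
            "seed": cfg.seed,
            "paired": cfg.paired is not None,
        }
        row.update({k: v for k, v in asdict(res.report).items()})
        rows.append(row)
    return pd.DataFrame(rows)
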