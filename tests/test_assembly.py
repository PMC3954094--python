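"""Assembly simulator: sorting/containment, breakpoint rules, pairs, diploid, BAC."""

import numpy as np
import pytest

from asmsim import (AssemblyOptions, MappedFragment, RepeatIndex, ReferenceGenome,
                    assemble, assemble_diploid, assemble_read_starts, make_diploid,
                    pairs_to_fragments, plant_repeats, random_reference,
                    simulate_bac_layout, sort_and_filter, two_stage_assemble)

from conftest import brute_force_assemble, tiled_fragments


def frag(fid, start, end, name="chr"):
    return MappedFragment(fid, name, start, end)


class TestSortAndFilter:
    def test_contained_fragment_dropped(self):
        out = sort_and_filter([frag("a", 0, 100), frag("b", 50, 150), frag("c", 60, 90)])
        assert [(f.start, f.end) for f in out] == [(0, 100), (50, 150)]

    def test_duplicate_interval_kept_once(self):
        out = sort_and_filter([frag("a", 10, 60), frag("b", 10, 60)])
        assert len(out) == 1

    def test_empty_input(self):
        assert sort_and_filter([]) == []

    def test_starts_and_ends_strictly_increase(self, rng):
        frags = [frag(f"f{i}", int(s), int(s) + int(l))
                 for i, (s, l) in enumerate(zip(rng.integers(0, 500, 100),
                                                rng.integers(10, 80, 100)))]
        out = sort_and_filter(frags)
        starts = [f.start for f in out]
        ends = [f.end for f in out]
        assert starts == sorted(starts) and len(set(starts)) == len(starts)
        assert ends == sorted(ends) and len(set(ends)) == len(ends)


class TestBreakRules:
    def test_full_tiling_of_repeat_free_reference_is_one_contig(self):
        ref = random_reference(3000, seed=1, name="chr")
        idx = RepeatIndex(ref)
        res = assemble(tiled_fragments("chr", 3000, 100, 50), ref, idx)
        assert len(res.contigs) == 1
        assert (res.contigs[0].start, res.contigs[0].end) == (0, 3000)
        assert res.breakpoints == []

    def test_planted_repeats_break_inside_copies(self):
        # tiling offset chosen so each 100-base copy admits exactly one
        # fully-interior overlap -> exactly one break per copy
        unit = random_reference(100, seed=2).sequences["random"]
        genome, copies = plant_repeats([500, 500, 500], unit, seed=3, name="chr",
                                       distinct_copy_flanks=True)
        idx = RepeatIndex(genome)
        frags = tiled_fragments("chr", genome.total_length, 100, 10, offset=5)
        res = assemble(frags, genome, idx)
        assert len(res.contigs) == 3
        for b in res.breakpoints:
            assert b.cause == "repeat"
            assert any(c.start <= b.position < c.end for c in copies)

    def test_min_overlap_short_overlap_breaks(self):
        ref = random_reference(1000, seed=4, name="chr")
        idx = RepeatIndex(ref)
        frags = [frag("a", 0, 100), frag("b", 80, 200)]  # overlap 20
        ok = assemble(frags, ref, idx, AssemblyOptions(min_overlap=20))
        broken = assemble(frags, ref, idx, AssemblyOptions(min_overlap=21))
        assert len(ok.contigs) == 1
        assert len(broken.contigs) == 2
        assert broken.breakpoints[0].cause == "short_overlap"

    def test_gap_breaks(self):
        ref = random_reference(1000, seed=5, name="chr")
        idx = RepeatIndex(ref)
        res = assemble([frag("a", 0, 100), frag("b", 100, 200)], ref, idx)
        assert len(res.contigs) == 2
        assert res.breakpoints[0].cause == "gap"

    def test_fragment_out_of_bounds_rejected(self):
        ref = random_reference(100, seed=6, name="chr")
        with pytest.raises(ValueError):
            assemble([frag("a", 50, 150)], ref, RepeatIndex(ref))

    def test_min_overlap_monotonicity(self, rng):
        unit = random_reference(40, seed=7).sequences["random"]
        genome, _ = plant_repeats([300, 300, 300], unit, seed=8, name="chr")
        idx = RepeatIndex(genome)
        starts = np.unique(rng.integers(0, genome.total_length - 100, size=60))
        frags = [frag(f"r{i}", int(s), int(s) + 100) for i, s in enumerate(starts)]
        counts = [len(assemble(frags, genome, idx, AssemblyOptions(min_overlap=w)).contigs)
                  for w in range(1, 64)]
        assert counts == sorted(counts)
        assert counts[-1] > counts[0]  # random gaps make some overlaps short


class TestFastPathEquivalence:
    def test_array_path_matches_object_path(self, rng):
        unit = random_reference(80, seed=9).sequences["random"]
        genome, _ = plant_repeats([400, 400, 400, 400], unit,
                                  orientations=["+", "-", "+"], seed=10, name="chr")
        idx = RepeatIndex(genome)
        for min_overlap in (1, 15, 40):
            starts = np.unique(rng.integers(0, genome.total_length - 100, size=400))
            frags = [frag(f"r{i}", int(s), int(s) + 100) for i, s in enumerate(starts)]
            opts = AssemblyOptions(min_overlap=min_overlap)
            a = assemble(frags, genome, idx, opts)
            b = assemble_read_starts("chr", starts, 100, genome, idx, opts)
            assert [(c.start, c.end, c.member_count) for c in a.contigs] == \
                   [(c.start, c.end, c.member_count) for c in b.contigs]
            assert [(x.position, x.cause) for x in a.breakpoints] == \
                   [(x.position, x.cause) for x in b.breakpoints]


class TestBruteForceOracle:
    def test_assembly_matches_independent_implementation(self, rng):
        for trial in range(20):
            unit = random_reference(int(rng.integers(30, 90)), seed=trial).sequences["random"]
            genome, _ = plant_repeats([250, 250, 250], unit, seed=100 + trial, name="chr")
            idx = RepeatIndex(genome)
            n = int(rng.integers(30, 70))
            frags = []
            for i in range(n):
                length = int(rng.integers(40, 120))
                start = int(rng.integers(0, genome.total_length - length))
                frags.append(frag(f"r{i}", start, start + length))
            res = assemble(frags, genome, idx)
            expected_contigs, expected_causes = brute_force_assemble(frags, genome)
            got = [(c.seq_name, c.start, c.end, c.member_ids) for c in res.contigs]
            assert got == expected_contigs
            assert [b.cause for b in res.breakpoints] == expected_causes


class TestPairs:
    @staticmethod
    def _scaffold_ref():
        """unique(600) R(100) x3 unique(600); with 100-base reads tiled every 10
        at offset 5, each copy admits exactly one fully-interior overlap, so the
        read baseline alone gives exactly 4 contigs (one break per copy)."""
        unit = random_reference(100, seed=11).sequences["random"]
        genome, copies = plant_repeats([600, 600, 600, 600], unit, seed=12, name="chr",
                                       distinct_copy_flanks=True)
        return genome, copies

    @staticmethod
    def _baseline(genome):
        return tiled_fragments("chr", genome.total_length, 100, 10, offset=5)

    def test_pair_spanning_repeat_joins_contigs(self):
        genome, copies = self._scaffold_ref()
        idx = RepeatIndex(genome)
        baseline = self._baseline(genome)
        assert len(assemble(baseline, genome, idx).contigs) == 4
        pair = (frag("p/1", 450, 550), frag("p/2", 850, 950))  # spans copy 1 [600,700)
        spans, report = pairs_to_fragments([pair], genome, idx, AssemblyOptions())
        assert report.kept == 1
        res = assemble(baseline + spans, genome, idx)
        assert len(res.contigs) == 3

    def test_pair_with_mate_in_repeat_is_discarded_whole(self):
        genome, copies = self._scaffold_ref()
        idx = RepeatIndex(genome)
        c = copies[0]
        pair = (frag("p/1", c.start, c.end), frag("p/2", 1500, 1600))
        spans, report = pairs_to_fragments([pair], genome, idx, AssemblyOptions())
        assert spans == [] and report.discarded_nonunique == 1

    def test_demotion_flag_keeps_mates_as_reads(self):
        genome, copies = self._scaffold_ref()
        idx = RepeatIndex(genome)
        c = copies[0]
        pair = (frag("p/1", c.start, c.end), frag("p/2", 1500, 1600))
        spans, _ = pairs_to_fragments([pair], genome, idx,
                                      AssemblyOptions(demote_discarded_pairs=True))
        assert len(spans) == 2 and all(f.kind == "read" for f in spans)

    def test_distance_limits_discard(self):
        genome, _ = self._scaffold_ref()
        idx = RepeatIndex(genome)
        pair = (frag("p/1", 0, 100), frag("p/2", 2200, 2300))  # inner distance 2100
        opts = AssemblyOptions(pair_distance_min=100, pair_distance_max=500)
        spans, report = pairs_to_fragments([pair], genome, idx, opts)
        assert spans == [] and report.discarded_distance == 1

    def test_cross_sequence_pairs_counted(self):
        ref = ReferenceGenome({"c1": "ACGT" * 100, "c2": "TTGG" * 100})
        idx = RepeatIndex(ref)
        pair = (MappedFragment("p/1", "c1", 0, 50), MappedFragment("p/2", "c2", 0, 50))
        spans, report = pairs_to_fragments([pair], ref, idx, AssemblyOptions())
        assert spans == [] and report.discarded_cross_sequence == 1

    def test_scaffold_gap_recorded_and_interior_counts_as_covered(self):
        genome, _ = self._scaffold_ref()
        idx = RepeatIndex(genome)
        pair = (frag("p/1", 100, 200), frag("p/2", 400, 500))
        spans, _ = pairs_to_fragments([pair], genome, idx, AssemblyOptions())
        res = assemble(spans, genome, idx)
        assert res.contigs[0].gaps == [(200, 400)]
        assert res.contigs[0].length == 400


class TestDiploid:
    def test_all_homozygous_limit_has_no_contigs(self):
        ref = random_reference(5000, seed=13, name="chr")
        dip = make_diploid(ref, 0.0, seed=14)
        frags = [MappedFragment(f"r{i}", "chr_hapA", s, s + 100)
                 for i, s in enumerate(range(0, 4900, 50))]
        res, blocks = assemble_diploid(dip, frags)
        assert res.contigs == []  # every read maps to both homologs

    def test_het_sites_enable_contigs_and_phase_blocks(self):
        ref = random_reference(4000, seed=15, name="chr")
        dip = make_diploid(ref, 0.01, seed=16)
        assert len(dip.het_sites) > 10
        frags = []
        for hap in ("chr_hapA", "chr_hapB"):
            frags += [MappedFragment(f"{hap}_{i}", hap, s, s + 400)
                      for i, s in enumerate(range(0, 3600, 100))]
        res, blocks = assemble_diploid(dip, frags)
        assert len(res.contigs) > 0
        covered = {p for b in blocks for p in b.het_positions}
        # every contig covers at least one het site, else it would be a repeat
        assert all(b.het_positions for b in blocks)
        assert covered <= {pos for _, pos, _, _ in dip.het_sites}

    def test_overlap_without_het_site_breaks(self):
        # two reads overlapping only in a homozygous stretch stay unconnected
        ref = random_reference(2000, seed=17, name="chr")
        dip = make_diploid(ref, 0.0, seed=18)
        # plant one het site manually at position 100 and one at 1500
        seq_b = list(dip.homolog_b.sequences["chr"])
        for pos in (100, 1500):
            seq_b[pos] = "A" if seq_b[pos] != "A" else "C"
            dip.het_sites.append(("chr", pos, dip.homolog_a.sequences["chr"][pos], seq_b[pos]))
        dip.homolog_b.sequences["chr"] = "".join(seq_b)
        frags = [MappedFragment("r1", "chr_hapA", 50, 450),
                 MappedFragment("r2", "chr_hapA", 400, 800),   # overlap [400,450) has no het
                 MappedFragment("r3", "chr_hapA", 1400, 1800)]
        res, _ = assemble_diploid(dip, frags)
        # r2 covers no het site -> discarded; r1 and r3 each their own contig
        assert sorted((c.start, c.end) for c in res.contigs) == [(50, 450), (1400, 1800)]


class TestTwoStageBAC:
    @staticmethod
    def _bac_fixture(seed):
        # genome U(1000) R(150) U(1000) R(150) U(1000); clone c0 carries only
        # copy 1, clone c1 only copy 2, and the clones overlap in unique U1
        from asmsim.reference import BACClone, BACLayout
        unit = random_reference(150, seed=seed).sequences["random"]
        genome, copies = plant_repeats([1000, 1000, 1000], unit, seed=seed + 1, name="chr")
        clones = [BACClone("c0", "chr", 0, 1400), BACClone("c1", "chr", 1200, 2450)]
        reads = {
            cid: [MappedFragment(f"{cid}_r{i}", "chr", s, s + 100)
                  for i, s in enumerate(range(c.start, c.end - 100 + 1, 40))]
            for cid, c in (("c0", clones[0]), ("c1", clones[1]))
        }
        return genome, clones, reads, BACClone, BACLayout

    def test_clone_with_single_repeat_copy_assembles_through_it(self):
        genome, clones, reads, _, BACLayout = self._bac_fixture(19)
        layout = BACLayout(clones, {"p0": ["c0"], "p1": ["c1"]}, 1400, 1.0)
        res = two_stage_assemble(layout, reads, genome, mode="barcoded")
        # whole-genome shotgun on the same reads breaks inside both copies;
        # clone-scoped stage 1 bridges them, stage 2 joins the clone contigs
        # through their unique overlap
        idx = RepeatIndex(genome)
        shotgun = assemble([f for fs in reads.values() for f in fs], genome, idx)
        assert len(shotgun.contigs) > 1
        assert len(res.contigs) == 1

    def test_pooled_vs_barcoded_scope(self):
        # the two clones of one pool jointly carry both repeat copies:
        # pooled scope breaks inside the copies, barcoded scope does not
        genome, clones, reads, _, BACLayout = self._bac_fixture(21)
        pooled_layout = BACLayout(clones, {"p0": ["c0", "c1"]}, 1400, 1.0)
        pooled = two_stage_assemble(pooled_layout, reads, genome, mode="pooled")
        barcoded = two_stage_assemble(pooled_layout, reads, genome, mode="barcoded")
        assert len(barcoded.contigs) < len(pooled.contigs)

    def test_nonoverlapping_clones_leave_gap(self):
        ref = random_reference(5000, seed=23, name="chr")
        from asmsim.reference import BACClone, BACLayout
        clones = [BACClone("c0", "chr", 0, 1000), BACClone("c1", "chr", 2000, 3000)]
        layout = BACLayout(clones, {"p0": ["c0"], "p1": ["c1"]}, 1000, 0.4)
        reads = {cid: [MappedFragment(f"{cid}_r{i}", "chr", s, s + 100)
                       for i, s in enumerate(range(c.start, c.end - 100 + 1, 50))]
                 for cid, c in (("c0", clones[0]), ("c1", clones[1]))}
        res = two_stage_assemble(layout, reads, ref, mode="barcoded")
        assert len(res.contigs) == 2
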