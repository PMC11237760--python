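"""Simulator: determinism, planted-structure fidelity, fragmentation."""

import pytest

from crisprcensus.sequtil import gc_fraction, hamming, revcomp, \
    ungapped_identity
from crisprcensus.simulate import (ArraySpec, ConfigError, PlacementError,
                                   SimConfig, TruthTable, fragment_assembly,
                                   generate_host_genome, generate_mge)


class TestHostGenome:
    def test_deterministic_for_equal_seeds(self):
        cfg = SimConfig(seed=1, n_arrays=3)
        rec1, t1 = generate_host_genome(cfg)
        rec2, t2 = generate_host_genome(SimConfig(seed=1, n_arrays=3))
        assert str(rec1.seq) == str(rec2.seq)
        assert [(a.start, a.end, a.spacer_seqs) for a in t1.arrays] == \
               [(a.start, a.end, a.spacer_seqs) for a in t2.arrays]

    def test_different_seeds_differ(self):
        rec1, _ = generate_host_genome(SimConfig(seed=1))
        rec2, _ = generate_host_genome(SimConfig(seed=2))
        assert str(rec1.seq) != str(rec2.seq)

    def test_c_type_template_ends_with_terminal_motif(self):
        cfg = SimConfig(seed=3, n_arrays=3,
                        array_specs=[ArraySpec(repeat_type="C")])
        _, truth = generate_host_genome(cfg)
        assert len(truth.arrays) == 3
        for arr in truth.arrays:
            assert arr.repeat_template.endswith("TTGAAAC")

    @pytest.mark.parametrize("rtype,motif", [
        ("G", "TTGAAGC"), ("B", "TTGAGCAC")])
    def test_other_terminal_motifs(self, rtype, motif):
        length = 36
        cfg = SimConfig(seed=4, n_arrays=1, array_specs=[
            ArraySpec(repeat_type=rtype, repeat_length=length)])
        _, truth = generate_host_genome(cfg)
        assert truth.arrays[0].repeat_template.endswith(motif)

    def test_spacer_count_is_units_minus_one(self):
        cfg = SimConfig(seed=5, n_arrays=2,
                        array_specs=[ArraySpec(n_units=5)])
        _, truth = generate_host_genome(cfg)
        for arr in truth.arrays:
            assert len(arr.spacer_seqs) == 4
            assert len(arr.unit_coords) == 5

    def test_truth_coordinates_match_sequence(self, mixed_genome):
        _, rec, truth = mixed_genome
        seq = str(rec.seq)
        for arr in truth.arrays:
            assert 0 <= arr.start < arr.end <= len(seq)
            for i, (s, e) in enumerate(arr.unit_coords[:-1]):
                sp = seq[e:arr.unit_coords[i + 1][0]]
                assert sp == arr.spacer_seqs[i]

    def test_spacers_pairwise_dissimilar(self, mixed_genome):
        _, _, truth = mixed_genome
        spacers = [s for a in truth.arrays for s in a.spacer_seqs]
        for i in range(0, 40):
            for j in range(i + 1, 40):
                assert ungapped_identity(spacers[i], spacers[j]) < 0.60

    def test_background_gc_close_to_config(self):
        cfg = SimConfig(seed=6, n_arrays=1, genome_length=100_000)
        rec, truth = generate_host_genome(cfg)
        arr = truth.arrays[0]
        background = str(rec.seq)[:arr.start]
        assert abs(gc_fraction(background) - 0.69) < 0.02

    def test_arrays_too_big_for_genome_raise(self):
        cfg = SimConfig(seed=7, n_arrays=10, genome_length=5000)
        with pytest.raises(PlacementError):
            generate_host_genome(cfg)

    def test_invalid_specs_rejected(self):
        with pytest.raises(ConfigError):
            ArraySpec(repeat_length=60)
        with pytest.raises(ConfigError):
            ArraySpec(n_units=1)
        with pytest.raises(ConfigError):
            SimConfig(pam="TT")


class TestMge:
    def test_zero_mismatch_protospacer_equals_spacer(self):
        cfg = SimConfig(seed=8, n_protospacers=5, planted_mismatches=0)
        spacers = ["ACGTGGCCGTTGACGGCATCGGCAGTCCAGGTCA"]
        rec, truth = generate_mge(cfg, spacers)
        seq = str(rec.seq)
        for p in truth.protospacers:
            proto = seq[p.start:p.end]
            if p.strand == "-":
                proto = revcomp(proto)
            assert proto == spacers[0]

    def test_planted_mismatch_count_is_exact(self):
        cfg = SimConfig(seed=9, n_protospacers=8, planted_mismatches=2)
        spacers = ["ACGTGGCCGTTGACGGCATCGGCAGTCCAGGTCA",
                   "TTTTCGCGCAAGGCCGGAAGCTGCGTACGATCCA"]
        rec, truth = generate_mge(cfg, spacers)
        seq = str(rec.seq)
        for p in truth.protospacers:
            proto = seq[p.start:p.end]
            if p.strand == "-":
                proto = revcomp(proto)
            src = spacers[int(p.spacer_id.removeprefix("spacer"))]
            assert hamming(proto, src) == 2 == p.mismatches

    def test_pam_planted_5prime_of_protospacer(self):
        cfg = SimConfig(seed=10, n_protospacers=10, pam="TTC",
                        planted_mismatches=0)
        spacers = ["ACGTGGCCGTTGACGGCATCGGCAGTCCAGGTCA"]
        rec, truth = generate_mge(cfg, spacers)
        seq = str(rec.seq)
        for p in truth.protospacers:
            if p.strand == "+":
                assert seq[p.start - 3:p.start] == "TTC"
            else:
                assert revcomp(seq[p.end:p.end + 3]) == "TTC"

    def test_too_many_protospacers_raise(self):
        cfg = SimConfig(seed=11, n_protospacers=1000, element_length=5000)
        with pytest.raises(PlacementError):
            generate_mge(cfg, ["ACGT" * 9])

    def test_empty_spacers_rejected(self):
        with pytest.raises(ValueError):
            generate_mge(SimConfig(seed=1), [])


class TestFragmentation:
    def test_single_contig_is_identity(self, small_genome):
        cfg, rec, truth = small_genome
        contigs, t2 = fragment_assembly(rec, truth, cfg)
        assert len(contigs) == 1
        assert str(contigs[0].seq) == str(rec.seq)
        assert not any(a.truncated for a in t2.arrays)

    def test_bases_conserved_for_any_split(self, small_genome):
        cfg0, rec, truth = small_genome
        for n in (2, 5, 9):
            cfg = SimConfig(seed=cfg0.seed, fragmentation=(n, 1000))
            contigs, _ = fragment_assembly(rec, truth, cfg)
            assert len(contigs) == n
            assert "".join(str(c.seq) for c in contigs) == str(rec.seq)

    def test_breakpoint_inside_array_flags_truncated(self, small_genome):
        cfg, rec, truth = small_genome
        arr = truth.arrays[1]
        mid = (arr.start + arr.end) // 2
        contigs, t2 = fragment_assembly(rec, truth, cfg, breakpoints=[mid])
        parts = [a for a in t2.arrays if a.array_id.startswith(arr.array_id)]
        assert parts and all(p.truncated for p in parts)
        intact = [a for a in t2.arrays
                  if not a.truncated]
        assert len(intact) == len(truth.arrays) - 1

    def test_remapped_truth_measurable_from_fragments(self, small_genome):
        cfg, rec, truth = small_genome
        contigs, t2 = fragment_assembly(rec, truth, cfg,
                                        breakpoints=[20000, 40000])
        by_id = {c.id: str(c.seq) for c in contigs}
        for arr in t2.arrays:
            seq = by_id[arr.contig_id]
            for s, e in arr.unit_coords:
                assert 0 <= s < e <= len(seq)

    def test_infeasible_fragmentation_raises(self, small_genome):
        cfg0, rec, truth = small_genome
        cfg = SimConfig(seed=1, fragmentation=(100, 10_000))
        with pytest.raises(ConfigError):
            fragment_assembly(rec, truth, cfg)


def test_truth_table_tsv_roundtrip(tmp_path, small_genome):
    cfg, rec, truth = small_genome
    _, mtruth = generate_mge(cfg, truth.arrays[0].spacer_seqs)
    table = TruthTable(arrays=list(truth.arrays),
                       protospacers=list(mtruth.protospacers))
    path = tmp_path / "truth.tsv"
    table.to_tsv(path)
    loaded = TruthTable.from_tsv(path)
    assert [(a.array_id, a.start, a.end, a.unit_coords, a.spacer_seqs)
            for a in loaded.arrays] == \
           [(a.array_id, a.start, a.end, a.unit_coords, a.spacer_seqs)
            for a in table.arrays]
    assert [(p.start, p.end, p.strand, p.mismatches, p.pam)
            for p in loaded.protospacers] == \
           [(p.start, p.end, p.strand, p.mismatches, p.pam)
            for p in table.protospacers]
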