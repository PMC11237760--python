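"""Target tracing: scoring identity, oracle equivalence, flanks, dedupe."""

import pytest

from crisprcensus.sequtil import random_dna, revcomp
from crisprcensus.simulate import SimConfig, generate_mge
from crisprcensus.trace import (TraceConfig, brute_force_trace,
                                dedupe_targets, extract_flanks, score_hit,
                                trace_all, trace_spacer)


def _plant(rng, subject, spacer, pos, mismatches, strand):
    proto = list(spacer)
    for p in rng.choice(len(proto), size=mismatches, replace=False):
        proto[p] = [b for b in "ACGT" if b != proto[p]][int(rng.integers(3))]
    proto = "".join(proto)
    ins = proto if strand == "+" else revcomp(proto)
    return subject[:pos] + ins + subject[pos + len(ins):]


class TestScore:
    def test_perfect_match(self):
        s = "ACGT" * 5
        assert score_hit(s, s) == (20, 0)

    def test_score_is_length_minus_twice_mismatches(self, rng):
        for _ in range(20):
            L = int(rng.integers(20, 45))
            spacer = random_dna(rng, L, 0.5)
            m = int(rng.integers(0, L // 2))
            window = _plant(rng, spacer, spacer, 0, m, "+")
            score, got_m = score_hit(spacer, window)
            assert got_m == m
            assert score == L - 2 * m

    def test_threshold_boundary_cases(self, rng):
        cfg = TraceConfig()
        # 36-nt spacer with 8 mismatches scores exactly 20: reported
        assert cfg.max_mismatches(36) == 8
        # 34-nt spacer with 8 mismatches scores 18: below threshold
        assert cfg.max_mismatches(34) == 7

    def test_unequal_lengths_rejected(self):
        with pytest.raises(ValueError):
            score_hit("ACGT", "ACG")

    def test_n_counts_as_mismatch(self):
        assert score_hit("ACGT", "ACNT")[1] == 1
        assert score_hit("ACNT", "ACNT")[1] == 1


class TestTraceVsOracle:
    def test_planted_minus_strand_hit_found_exactly(self, rng):
        spacer = random_dna(rng, 34, 0.65)
        subject = random_dna(rng, 5000, 0.69)
        subject = _plant(rng, subject, spacer, 1234, 0, "-")
        hits = trace_spacer(spacer, subject)
        assert len(hits) == 1
        h = hits[0]
        assert (h.start, h.end, h.strand, h.mismatches) == (1234, 1268, "-", 0)

    def test_absent_spacer_yields_nothing(self, rng):
        spacer = random_dna(rng, 34, 0.3)
        subject = random_dna(rng, 20_000, 0.69)
        assert trace_spacer(spacer, subject) == \
            brute_force_trace(spacer, subject) == []

    def test_equivalent_to_brute_force_on_planted_corpus(self, rng):
        """Seeded search finds exactly what the exhaustive scan finds."""
        cfg = TraceConfig()
        for trial in range(50):
            L = int(rng.integers(24, 45))
            spacer = random_dna(rng, L, 0.6)
            subject = random_dna(rng, 8000, 0.69)
            n_plant = int(rng.integers(0, 4))
            for _ in range(n_plant):
                pos = int(rng.integers(0, len(subject) - L))
                m = int(rng.integers(0, max(1, cfg.max_mismatches(L) + 2)))
                strand = "+-"[int(rng.integers(2))]
                subject = _plant(rng, subject, spacer, pos, min(m, L - 1),
                                 strand)
            fast = trace_spacer(spacer, subject, cfg)
            slow = brute_force_trace(spacer, subject, cfg)
            key = lambda h: (h.start, h.end, h.strand, h.mismatches, h.score)
            assert sorted(map(key, fast)) == sorted(map(key, slow))

    def test_oracle_scans_every_window(self, rng):
        spacer = random_dna(rng, 30, 0.5)
        subject = _plant(rng, random_dna(rng, 400, 0.5), spacer, 100, 0, "+")
        hits = brute_force_trace(spacer, subject)
        assert all(0 <= h.start and h.end <= 400 for h in hits)
        assert any(h.start == 100 for h in hits)

    def test_strand_mirror_symmetry(self, rng):
        spacer = random_dna(rng, 34, 0.6)
        subject = _plant(rng, random_dna(rng, 3000, 0.69), spacer, 500, 2, "+")
        fwd = trace_spacer(spacer, subject)
        mirrored = trace_spacer(spacer, revcomp(subject))
        n = len(subject)
        assert {(n - h.end, n - h.start, h.mismatches) for h in mirrored} == \
               {(h.start, h.end, h.mismatches) for h in fwd}


class TestFlanks:
    def test_planted_pam_read_from_flank5_both_strands(self):
        cfg = SimConfig(seed=51, n_protospacers=20, pam="TTC",
                        planted_mismatches=0)
        spacers = ["ACGTGGCCGTTGACGGCATCGGCAGTCCAGGTCA",
                   "GGTTACGCGCAAGGCCGGAAGCTGCGTACGATCC"]
        rec, truth = generate_mge(cfg, spacers)
        strands = {p.strand for p in truth.protospacers}
        assert strands == {"+", "-"}  # both orientations exercised
        hits = trace_all({f"s{i}": s for i, s in enumerate(spacers)},
                         {"mge": str(rec.seq)})
        planted = {(p.start, p.end) for p in truth.protospacers}
        matched = [h for h in hits if (h.start, h.end) in planted]
        assert len(matched) == len(truth.protospacers)
        for h in matched:
            assert h.flank5 is not None and h.flank5.endswith("TTC")

    def test_flank_unavailable_near_subject_edge(self):
        subject = "GGACGTACGTACGTACGTACGTAA"
        f5, f3 = extract_flanks(2, 22, "+", subject, flank_len=8)
        assert f5 is None
        assert f3 is None  # only 2 bases right of the interval

    def test_minus_strand_flank_is_revcomp_of_right_side(self):
        subject = "AAAATTTTGGGGCCCCACGTACGTAAGGCCTTAACCGGTT"
        start, end = 16, 24
        f5, f3 = extract_flanks(start, end, "-", subject, flank_len=8)
        assert f5 == revcomp(subject[end:end + 8])
        assert f3 == revcomp(subject[start - 8:start])


class TestDedupe:
    def test_identical_protospacer_and_flanks_collapse(self, rng):
        spacer = random_dna(rng, 34, 0.6)
        block = random_dna(rng, 8, 0.5) + spacer + random_dna(rng, 8, 0.5)
        subject = ("T" * 30) + block + ("A" * 30) + block + ("G" * 30)
        hits = trace_spacer(spacer, subject)
        assert len(hits) == 2
        assert len(dedupe_targets(hits)) == 1

    def test_different_flank5_stays_separate(self, rng):
        spacer = random_dna(rng, 34, 0.6)
        b1 = "AAAAAAAA" + spacer + "CCCCCCCC"
        b2 = "GGGGGGGG" + spacer + "CCCCCCCC"
        subject = ("T" * 30) + b1 + ("T" * 30) + b2 + ("T" * 30)
        hits = trace_spacer(spacer, subject)
        assert len(dedupe_targets(hits)) == 2

    def test_lowest_mismatch_representative_kept(self, rng):
        spacer = random_dna(rng, 34, 0.6)
        sub = random_dna(rng, 2000, 0.69)
        sub = _plant(rng, sub, spacer, 100, 0, "+")
        sub = _plant(rng, sub, spacer, 900, 2, "+")
        nonred = dedupe_targets(trace_spacer(spacer, sub))
        assert min(h.mismatches for h in nonred) == 0


def test_self_hits_flagged_but_emitted(small_genome):
    from crisprcensus.detect import detect
    from crisprcensus.spacers import dedupe_spacers, extract_spacers
    _, rec, _ = small_genome
    arrays = detect([rec])
    unique, _ = dedupe_spacers(extract_spacers(arrays))
    spacer_map = {r.spacer_id: r.sequence for r in unique[:5]}
    loci = {rec.id: [(a.start, a.end) for a in arrays]}
    hits = trace_all(spacer_map, {rec.id: str(rec.seq)}, crispr_loci=loci)
    assert hits and all(h.self_hit for h in hits
                        if any(s <= h.start < e for s, e in loci[rec.id]))
    assert any(h.self_hit for h in hits)
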