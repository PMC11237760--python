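"""Synteny anchoring: alignment statistics, context comparison, locus state."""

import numpy as np
import pytest
from Bio.Align import substitution_matrices

from crisprcensus.synteny import (FlankLibrary, GeneRecord,
                                  align_proteins, compare_contexts,
                                  extract_flank_genes, infer_locus_state)

AA = "ACDEFGHIKLMNPQRSTVWY"
_B62 = substitution_matrices.load("BLOSUM62")


def random_protein(rng, n):
    return "".join(AA[i] for i in rng.integers(0, 20, size=n))


def gotoh_local_score(a, b, open_pen=11, ext_pen=1):
    """Quadratic affine-gap Smith-Waterman; independent scoring oracle."""
    n, m = len(a), len(b)
    NEG = -1e9
    H = np.zeros((n + 1, m + 1))
    E = np.full((n + 1, m + 1), NEG)
    F = np.full((n + 1, m + 1), NEG)
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            E[i, j] = max(H[i, j - 1] - open_pen, E[i, j - 1] - ext_pen)
            F[i, j] = max(H[i - 1, j] - open_pen, F[i - 1, j] - ext_pen)
            diag = H[i - 1, j - 1] + _B62[a[i - 1], b[j - 1]]
            H[i, j] = max(0.0, diag, E[i, j], F[i, j])
            best = max(best, H[i, j])
    return best


def _genome(rng, contig="ctg", n_genes=26, prot_len=120, start0=100,
            id_prefix="g"):
    """Annotation of evenly spaced genes with random proteins."""
    genes = []
    for k in range(n_genes):
        s = start0 + k * 1500
        genes.append(GeneRecord(
            gene_id=f"{id_prefix}{k}", contig_id=contig, start=s,
            end=s + 900, strand="+" if k % 2 else "-",
            protein=random_protein(rng, prot_len)))
    return genes


class TestAlignProteins:
    def test_identical_proteins(self, rng):
        p = random_protein(rng, 100)
        pident, coverage, evalue = align_proteins(p, p)
        assert pident == 100.0
        assert coverage == 1.0
        assert evalue < 1e-10

    def test_thirty_substitutions_give_seventy_percent(self, rng):
        p = list(random_protein(rng, 100))
        mutant = list(p)
        # isolated internal substitutions: full-length alignment retained
        positions = range(3, 93, 3)
        for i in list(positions)[:30]:
            mutant[i] = AA[(AA.index(mutant[i]) + 7) % 20]
        pident, coverage, _ = align_proteins("".join(p), "".join(mutant))
        assert pident == pytest.approx(70.0, abs=1.0)
        assert coverage > 0.95

    def test_unrelated_proteins_fail_filter(self, rng):
        a = random_protein(rng, 100)
        b = random_protein(rng, 100)
        pident, coverage, evalue = align_proteins(a, b)
        assert pident < 70.0

    def test_invalid_residues_rejected(self):
        with pytest.raises(ValueError):
            align_proteins("ACDEF1", "ACDEF")

    def test_score_matches_gotoh_oracle(self, rng):
        from crisprcensus.synteny import _aligner
        aligner = _aligner()
        for _ in range(6):
            a = random_protein(rng, int(rng.integers(40, 120)))
            b = random_protein(rng, int(rng.integers(40, 120)))
            assert aligner.score(a, b) == pytest.approx(
                gotoh_local_score(a, b))


class TestFlankExtraction:
    def test_full_windows_both_sides(self, rng):
        genes = _genome(rng)
        locus = (genes[12].end + 10, genes[13].start - 10)
        lib = extract_flank_genes(genes, "ctg", locus, w=10)
        assert len(lib.upstream) == 10
        assert len(lib.downstream) == 10
        assert not lib.up_truncated and not lib.down_truncated

    def test_contig_end_truncates_flank(self, rng):
        genes = _genome(rng)
        locus = (genes[22].end + 10, genes[23].start - 10)
        lib = extract_flank_genes(genes, "ctg", locus, w=10)
        assert len(lib.downstream) == 3
        assert lib.down_truncated

    def test_zero_window_gives_empty_libraries(self, rng):
        genes = _genome(rng)
        lib = extract_flank_genes(genes, "ctg", (5000, 6000), w=0)
        assert lib.upstream == [] and lib.downstream == []

    def test_unknown_contig_raises(self, rng):
        with pytest.raises(ValueError):
            extract_flank_genes(_genome(rng), "missing", (0, 10))


class TestCompareContexts:
    def test_self_comparison_all_pass_at_full_identity(self, rng):
        genes = _genome(rng, n_genes=14)
        locus = (genes[6].end + 10, genes[7].start - 10)
        lib = extract_flank_genes(genes, "ctg", locus, w=4)
        matches = compare_contexts(lib, genes)
        assert all(m.passed and m.pident == 100.0 for m in matches)
        assert all(m.reciprocal_best for m in matches)

    def test_deleted_locus_leaves_flank_anchors(self, rng):
        ref = _genome(rng, n_genes=20)
        locus_genes = {f"g{k}" for k in range(8, 12)}
        query = [g for g in ref if g.gene_id not in locus_genes]
        lib = FlankLibrary(upstream=ref[4:8], downstream=ref[12:16],
                           up_truncated=False, down_truncated=False)
        matches = compare_contexts(lib, query)
        assert all(m.passed for m in matches)

    def test_empty_query_yields_no_passes(self, rng):
        ref = _genome(rng, n_genes=10)
        lib = FlankLibrary(upstream=ref[:3], downstream=ref[7:],
                           up_truncated=False, down_truncated=False)
        matches = compare_contexts(lib, [])
        assert all(not m.passed and m.query_gene_id is None for m in matches)


class TestLocusState:
    def _setup(self, rng):
        ref = _genome(rng, n_genes=20)
        locus = (ref[9].end + 50, ref[10].start - 50)
        lib = extract_flank_genes(ref, "ctg", locus, w=4)
        return ref, locus, lib

    def test_intact_genome_present(self, rng):
        ref, locus, lib = self._setup(rng)
        matches = compare_contexts(lib, ref)
        state = infer_locus_state(matches, ref, [("ctg", *locus)])
        assert state == "present"

    def test_excised_locus_absent_with_context(self, rng):
        ref, locus, lib = self._setup(rng)
        matches = compare_contexts(lib, ref)
        state = infer_locus_state(matches, ref, [])
        assert state == "absent_with_context"

    def test_split_flanks_unresolved(self, rng):
        ref, locus, lib = self._setup(rng)
        split = []
        for g in ref:
            contig = "left" if g.end <= locus[0] else "right"
            split.append(GeneRecord(
                gene_id=g.gene_id, contig_id=contig, start=g.start,
                end=g.end, strand=g.strand, protein=g.protein))
        matches = compare_contexts(lib, split)
        state = infer_locus_state(matches, split, [])
        assert state == "unresolved"

    def test_too_few_anchors_unresolved(self, rng):
        ref, locus, lib = self._setup(rng)
        matches = compare_contexts(lib, ref[:2])
        assert infer_locus_state(matches, ref[:2], []) == "unresolved"

    def test_state_invariant_under_contig_rename_and_reorder(self, rng):
        ref, locus, lib = self._setup(rng)
        renamed = [GeneRecord(g.gene_id, "zzz", g.start, g.end, g.strand,
                              g.protein) for g in reversed(ref)]
        matches = compare_contexts(lib, renamed)
        state = infer_locus_state(matches, renamed,
                                  [("zzz", *locus)])
        assert state == "present"
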