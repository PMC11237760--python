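"""Gene-neighborhood comparison around CRISPR-Cas loci.

To decide whether an incomplete assembly carries, lacks, or cannot
resolve a CRISPR-Cas locus, the proteins encoded by the genes flanking a
reference locus are collected as an anchor library and matched against a
query genome's proteome. Anchors are matched by Smith-Waterman local
alignment under BLOSUM62 with affine gaps (open 11, extend 1) — the
library sizes here are tens of proteins, so exact alignment is
affordable — and filtered like a BLAST tabular run: e-value <= 1 and
percent identity >= 70, plus a coverage guard (>= 50% of the shorter
protein aligned) against short spurious local hits. E-values use the
Karlin-Altschul formula with standard ungapped BLOSUM62 constants
(K = 0.041, lambda = 0.267), an approximation of gapped statistics; the
identity filter dominates in practice.

Locus states: ``present`` (enough anchors pass on both sides and a
CRISPR locus lies between them), ``absent_with_context`` (both flanks
anchor contiguously with no locus between) or ``unresolved`` (flanks on
different contigs, near contig ends, or too few anchors).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from Bio import Align
from Bio.Align import substitution_matrices

KARLIN_K = 0.041
KARLIN_LAMBDA = 0.267

_BLOSUM62 = substitution_matrices.load("BLOSUM62")
_VALID_RESIDUES = set(str(_BLOSUM62.alphabet))


@dataclass(frozen=True)
class GeneRecord:
    gene_id: str
    contig_id: str
    start: int  # 0-based half-open
    end: int
    strand: str
    protein: str

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"empty interval for gene {self.gene_id}")
        if not self.protein:
            raise ValueError(f"empty protein for gene {self.gene_id}")


@dataclass
class AnchorMatch:
    ref_gene_id: str
    query_gene_id: str | None
    pident: float  # percent identity over aligned columns
    coverage: float  # fraction of the shorter protein aligned
    evalue: float
    score: float
    passed: bool
    reciprocal_best: bool = False
    side: str = ""  # 'up' or 'down' when produced by compare_contexts


@dataclass
class FlankLibrary:
    upstream: list[GeneRecord]
    downstream: list[GeneRecord]
    up_truncated: bool  # fewer than w genes available on that side
    down_truncated: bool


def _aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = _BLOSUM62
    aligner.open_gap_score = -11
    aligner.extend_gap_score = -1
    return aligner


def extract_flank_genes(annotation: list[GeneRecord], contig_id: str,
                        locus: tuple[int, int], w: int = 10) -> FlankLibrary:
    """Up to w genes on each side of a locus, in genomic order."""
    genes = sorted((g for g in annotation if g.contig_id == contig_id),
                   key=lambda g: g.start)
    if not any(g.contig_id == contig_id for g in annotation) and annotation:
        raise ValueError(f"contig {contig_id!r} absent from annotation")
    start, end = locus
    upstream = [g for g in genes if g.end <= start][-w:] if w else []
    downstream = [g for g in genes if g.start >= end][:w] if w else []
    return FlankLibrary(
        upstream=upstream, downstream=downstream,
        up_truncated=w > 0 and len(upstream) < w,
        down_truncated=w > 0 and len(downstream) < w,
    )


def align_proteins(a: str, b: str) -> tuple[float, float, float]:
    """(pident, coverage, evalue) of a local protein alignment.

    pident: identities over aligned columns (gaps included), in percent.
    coverage: aligned residues of the shorter protein / its length.
    evalue: K * m * n * exp(-lambda * S) with ungapped BLOSUM62 constants.
    """
    a, b = a.upper().rstrip("*"), b.upper().rstrip("*")
    for seq in (a, b):
        if not seq or any(r not in _VALID_RESIDUES for r in seq):
            raise ValueError(f"invalid protein sequence: {seq[:30]!r}...")
    aligner = _aligner()
    alignments = aligner.align(a, b)
    if len(alignments) == 0:
        return 0.0, 0.0, math.inf
    aln = alignments[0]
    counts = aln.counts()
    columns = counts.identities + counts.mismatches + counts.gaps
    pident = 100.0 * counts.identities / columns if columns else 0.0
    shorter = min(len(a), len(b))
    blocks_a, _ = aln.aligned
    aligned_a = sum(int(e - s) for s, e in blocks_a)
    # blocks are reported on the first sequence; for coverage of the
    # shorter protein this equals the aligned-residue count of either
    # sequence up to gaps, which the 0.5 guard tolerates
    coverage = aligned_a / shorter
    evalue = KARLIN_K * len(a) * len(b) * math.exp(-KARLIN_LAMBDA * aln.score)
    return pident, coverage, evalue


def _match_filter(pident: float, coverage: float, evalue: float,
                  min_pident: float = 70.0, max_evalue: float = 1.0,
                  min_coverage: float = 0.5) -> bool:
    return evalue <= max_evalue and pident >= min_pident \
        and coverage >= min_coverage


def compare_contexts(ref_library: FlankLibrary,
                     query_genes: list[GeneRecord]) -> list[AnchorMatch]:
    """Best query match per reference anchor, with pass/fail flags.

    Scans every reference anchor against every query protein (best hit by
    alignment score) and records whether the hit passes the e-value <= 1,
    pident >= 70, coverage >= 0.5 filter, plus a reciprocal-best flag.
    """
    anchors = [("up", g) for g in ref_library.upstream] + \
              [("down", g) for g in ref_library.downstream]
    if not anchors:
        raise ValueError("reference flank library is empty")
    matches: list[AnchorMatch] = []
    best_for_query: dict[str, tuple[float, str]] = {}
    for side, ref in anchors:
        best: tuple[float, GeneRecord, tuple[float, float, float]] | None = None
        for q in query_genes:
            pident, coverage, evalue = align_proteins(ref.protein, q.protein)
            score = -math.log10(evalue) if evalue > 0 else math.inf
            if best is None or score > best[0]:
                best = (score, q, (pident, coverage, evalue))
        if best is None:
            matches.append(AnchorMatch(
                ref_gene_id=ref.gene_id, query_gene_id=None, pident=0.0,
                coverage=0.0, evalue=math.inf, score=0.0, passed=False,
                side=side))
            continue
        score, q, (pident, coverage, evalue) = best
        passed = _match_filter(pident, coverage, evalue)
        matches.append(AnchorMatch(
            ref_gene_id=ref.gene_id, query_gene_id=q.gene_id, pident=pident,
            coverage=coverage, evalue=evalue, score=score, passed=passed,
            side=side))
        prev = best_for_query.get(q.gene_id)
        if prev is None or score > prev[0]:
            best_for_query[q.gene_id] = (score, ref.gene_id)
    for m in matches:
        if m.query_gene_id is not None:
            m.reciprocal_best = \
                best_for_query[m.query_gene_id][1] == m.ref_gene_id
    return matches


def infer_locus_state(matches: list[AnchorMatch],
                      query_genes: list[GeneRecord],
                      query_loci: list[tuple[str, int, int]],
                      contig_lengths: dict[str, int] | None = None,
                      min_anchors: int = 3,
                      edge_margin: int = 200) -> str:
    """present / absent_with_context / unresolved for one reference locus.

    ``query_loci`` are CRISPR loci of the query (detected arrays or
    provided annotations) as (contig_id, start, end). The state is
    ``present`` when >= min_anchors pass on each side and a locus lies in
    the interval spanned by the innermost passing anchors on one contig;
    ``absent_with_context`` when both flanks anchor that interval with no
    locus inside; ``unresolved`` when flanks land on different contigs,
    within edge_margin of a contig end, or too few anchors pass.
    """
    gene_by_id = {g.gene_id: g for g in query_genes}
    passed = [(m, gene_by_id[m.query_gene_id]) for m in matches
              if m.passed and m.query_gene_id in gene_by_id]
    up = [g for m, g in passed if m.side == "up"]
    down = [g for m, g in passed if m.side == "down"]
    if len(up) < min_anchors or len(down) < min_anchors:
        return "unresolved"
    up_contigs = {g.contig_id for g in up}
    down_contigs = {g.contig_id for g in down}
    shared = up_contigs & down_contigs
    if not shared:
        return "unresolved"
    for contig in sorted(shared):
        up_here = [g for g in up if g.contig_id == contig]
        down_here = [g for g in down if g.contig_id == contig]
        if len(up_here) < min_anchors or len(down_here) < min_anchors:
            continue
        lo = min(min(g.start for g in up_here),
                 min(g.start for g in down_here))
        hi = max(max(g.end for g in up_here), max(g.end for g in down_here))
        # innermost span between the two anchor groups
        inner_lo = min(max(g.end for g in up_here),
                       max(g.end for g in down_here))
        inner_hi = max(min(g.start for g in up_here),
                       min(g.start for g in down_here))
        if contig_lengths is not None:
            clen = contig_lengths.get(contig)
            if clen is not None and (lo < edge_margin
                                     or clen - hi < edge_margin):
                return "unresolved"
        if inner_lo > inner_hi:  # anchor groups interleave: no clean gap
            inner_lo, inner_hi = inner_hi, inner_lo
        has_locus = any(c == contig and s < inner_hi and e > inner_lo
                        for c, s, e in query_loci)
        return "present" if has_locus else "absent_with_context"
    return "unresolved"
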