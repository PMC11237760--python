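"""Spacer → protospacer target tracing with ungapped CRISPRTarget scoring.

Every ungapped window on either strand of a subject sequence is scored
+1 per match and -1 per mismatch (so score = L - 2m for a spacer of
length L with m mismatches) and reported when the score reaches the
threshold (default 20, the setting used for spacer target searches in
host-invader studies). Gaps are not modelled: this keeps the score/
mismatch bookkeeping exact and mirrors the default penalty rule of
CRISPRTarget. The 8 nt flanking each protospacer are extracted in
protospacer orientation for downstream PAM inference.

`trace_spacer` uses exact word seeding with an adaptive word length: the
word is shortened to the pigeonhole bound ceil((L - m_max)/(m_max + 1))
whenever the configured seed word could miss a reportable hit, so the
seeded search provably finds everything the exhaustive scan
(`brute_force_trace`) finds.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from .sequtil import encode, revcomp


@dataclass(frozen=True)
class TraceConfig:
    match_reward: int = 1
    mismatch_penalty: int = -1
    score_threshold: int = 20
    max_mismatches_report: int = 10
    flank_len: int = 8
    seed_word: int = 11

    def __post_init__(self) -> None:
        if self.score_threshold <= 0:
            raise ValueError("score_threshold must be > 0")
        if self.flank_len < 3:
            raise ValueError("flank_len must be >= 3")

    def max_mismatches(self, spacer_len: int) -> int:
        """Largest m with L - 2m >= threshold, capped by the report limit."""
        by_score = (spacer_len - self.score_threshold) // 2
        return min(by_score, self.max_mismatches_report)


@dataclass
class TargetHit:
    spacer_id: str
    subject_id: str
    start: int  # 0-based half-open, forward strand of the subject
    end: int
    strand: str  # strand carrying the protospacer ('+' or '-')
    mismatches: int
    score: int
    proto_seq: str  # protospacer in protospacer orientation
    flank5: str | None  # flank_len bases 5' of the protospacer, its strand
    flank3: str | None
    self_hit: bool = False  # hit overlapping a CRISPR locus of the subject


class _EncodedSubject:
    """Cache of the numeric encoding of a subject sequence."""

    def __init__(self, seq: str):
        self.seq = seq.upper()
        self.arr = encode(self.seq)


def score_hit(spacer: str, subject_window: str,
              cfg: TraceConfig | None = None) -> tuple[int, int]:
    """(score, mismatches) of an ungapped spacer/window comparison.

    N in either sequence counts as a mismatch. Raises on unequal lengths.
    """
    cfg = cfg or TraceConfig()
    if len(spacer) != len(subject_window):
        raise ValueError(
            f"spacer ({len(spacer)}) and window ({len(subject_window)}) "
            "must have equal lengths")
    spacer = spacer.upper()
    subject_window = subject_window.upper()
    m = sum(1 for a, b in zip(spacer, subject_window)
            if a != b or a not in "ACGT")
    score = (len(spacer) - m) * cfg.match_reward + m * cfg.mismatch_penalty
    return score, m


def extract_flanks(start: int, end: int, strand: str, subject: str,
                   flank_len: int = 8) -> tuple[str | None, str | None]:
    """Flanks of a protospacer interval, read in protospacer orientation.

    For minus-strand hits the 5' flank is the reverse complement of the
    bases 3' of the interval on the forward strand. A flank is None when
    fewer than flank_len bases exist on that side.
    """
    left = subject[start - flank_len:start] if start >= flank_len else None
    right = subject[end:end + flank_len]
    if len(right) < flank_len:
        right = None
    if strand == "+":
        return left, right
    return (revcomp(right) if right is not None else None,
            revcomp(left) if left is not None else None)


def _mismatch_counts(spacer_arr: np.ndarray, subj_arr: np.ndarray) -> np.ndarray:
    """Hamming distance of the spacer against every window of the subject."""
    L = len(spacer_arr)
    n_win = len(subj_arr) - L + 1
    if n_win <= 0:
        return np.empty(0, dtype=np.int32)
    mism = np.zeros(n_win, dtype=np.int32)
    ambiguous = subj_arr >= 4
    for i in range(L):
        col = subj_arr[i:i + n_win]
        # spacer N encodes as 4, which never equals an ACGT code, and
        # subject ambiguity is OR-ed in: N mismatches everything
        mism += (col != spacer_arr[i]) | ambiguous[i:i + n_win]
    return mism


def _hits_from_positions(spacer_id: str, spacer: str, subject_id: str,
                         subject: str, positions, mismatches, strand: str,
                         cfg: TraceConfig) -> list[TargetHit]:
    hits = []
    L = len(spacer)
    for pos, m in zip(positions, mismatches):
        score = L - 2 * int(m)
        proto = subject[pos:pos + L]
        if strand == "-":
            proto = revcomp(proto)
        f5, f3 = extract_flanks(pos, pos + L, strand, subject, cfg.flank_len)
        hits.append(TargetHit(
            spacer_id=spacer_id, subject_id=subject_id, start=int(pos),
            end=int(pos + L), strand=strand, mismatches=int(m), score=score,
            proto_seq=proto, flank5=f5, flank3=f3))
    return hits


def _sorted_hits(hits: list[TargetHit]) -> list[TargetHit]:
    hits.sort(key=lambda h: (-h.score, h.subject_id, h.start, h.strand))
    return hits


def brute_force_trace(spacer: str, subject, cfg: TraceConfig | None = None,
                      spacer_id: str = "spacer",
                      subject_id: str = "subject") -> list[TargetHit]:
    """Exhaustive scan of every window on both strands (testing oracle)."""
    cfg = cfg or TraceConfig()
    spacer = spacer.upper()
    seq = subject.seq if isinstance(subject, _EncodedSubject) else subject.upper()
    sub_arr = encode(seq)
    hits: list[TargetHit] = []
    for strand, probe in (("+", spacer), ("-", revcomp(spacer))):
        mism = _mismatch_counts(encode(probe), sub_arr)
        max_m = cfg.max_mismatches(len(spacer))
        keep = np.nonzero(mism <= max_m)[0]
        hits.extend(_hits_from_positions(
            spacer_id, spacer, subject_id, seq, keep, mism[keep], strand, cfg))
    return _sorted_hits(hits)


def _build_word_index(seq: str, word: int) -> dict[str, list[int]]:
    index: dict[str, list[int]] = {}
    for i in range(len(seq) - word + 1):
        index.setdefault(seq[i:i + word], []).append(i)
    return index


def _seed_candidates(probe: str, index: dict[str, list[int]], word: int,
                     n_win: int) -> np.ndarray:
    """Window starts sharing at least one exact `word`-mer with the probe."""
    starts: set[int] = set()
    for off in range(len(probe) - word + 1):
        for pos in index.get(probe[off:off + word], ()):
            s = pos - off
            if 0 <= s < n_win:
                starts.add(s)
    return np.fromiter(sorted(starts), dtype=np.int64, count=len(starts))


def trace_spacer(spacer: str, subject, cfg: TraceConfig | None = None,
                 spacer_id: str = "spacer", subject_id: str = "subject",
                 _index_cache: dict | None = None) -> list[TargetHit]:
    """All above-threshold ungapped hits of one spacer in one subject.

    Seed word length is min(cfg.seed_word, pigeonhole bound), which makes
    the seeded search complete for every reportable mismatch count.
    Hits sorted by score (desc), then subject position. ``_index_cache``
    lets repeated calls against the same subject reuse the word index.
    """
    cfg = cfg or TraceConfig()
    spacer = spacer.upper()
    seq = subject.upper()
    L = len(spacer)
    max_m = cfg.max_mismatches(L)
    if max_m < 0 or len(seq) < L:
        return []
    # pigeonhole: m mismatches leave an exact run of ceil((L-m)/(m+1))
    bound = math.ceil((L - max_m) / (max_m + 1))
    word = max(1, min(cfg.seed_word, bound, L))
    cache = _index_cache if _index_cache is not None else {}
    if word not in cache:
        cache[word] = _build_word_index(seq, word)
    index = cache[word]
    sub_arr = encode(seq)
    n_win = len(seq) - L + 1
    hits: list[TargetHit] = []
    offsets = np.arange(L)
    for strand, probe in (("+", spacer), ("-", revcomp(spacer))):
        cand = _seed_candidates(probe, index, word, n_win)
        if cand.size == 0:
            continue
        probe_arr = encode(probe)
        windows = sub_arr[cand[:, None] + offsets]
        mism = np.count_nonzero(
            (windows != probe_arr) | (windows >= 4) | (probe_arr >= 4),
            axis=1)
        keep = mism <= max_m
        hits.extend(_hits_from_positions(
            spacer_id, spacer, subject_id, seq, cand[keep], mism[keep],
            strand, cfg))
    return _sorted_hits(hits)


def trace_all(spacers: dict[str, str], subjects: dict[str, str],
              cfg: TraceConfig | None = None,
              crispr_loci: dict[str, list[tuple[int, int]]] | None = None,
              ) -> list[TargetHit]:
    """Trace every spacer against every subject record.

    ``crispr_loci`` maps subject ids to detected array intervals; hits
    overlapping one are flagged self_hit (spacers always match the array
    they came from) but are still emitted.
    """
    cfg = cfg or TraceConfig()
    loci = crispr_loci or {}
    caches: dict[str, dict] = {tid: {} for tid in subjects}
    out: list[TargetHit] = []
    for sid, sseq in spacers.items():
        for tid, tseq in subjects.items():
            for hit in trace_spacer(sseq, tseq, cfg, spacer_id=sid,
                                    subject_id=tid,
                                    _index_cache=caches[tid]):
                if any(hit.start < e and hit.end > s
                       for s, e in loci.get(tid, ())):
                    hit = replace(hit, self_hit=True)
                out.append(hit)
    out.sort(key=lambda h: (h.spacer_id, -h.score, h.subject_id, h.start,
                            h.strand))
    return out


def dedupe_targets(hits: list[TargetHit]) -> list[TargetHit]:
    """Collapse hits to non-redundant targets.

    Identity of a target is the triple (protospacer sequence, flank5,
    flank3), all in protospacer orientation; the lowest-mismatch
    representative is kept (ties: first by subject id, then position).
    """
    best: dict[tuple, TargetHit] = {}
    ordered = sorted(hits, key=lambda h: (h.mismatches, h.subject_id,
                                          h.start, h.strand))
    for hit in ordered:
        key = (hit.proto_seq, hit.flank5, hit.flank3)
        if key not in best:
            best[key] = hit
    return sorted(best.values(),
                  key=lambda h: (h.subject_id, h.start, h.strand))
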