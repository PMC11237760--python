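"""De-novo CRISPR array detection in contigs.

A CRISPR array is a run of near-identical direct repeats (23-55 bp)
separated by unique spacers (18-60 bp). Detection is seed-and-extend:

1. exact k-mer seeds (default k=9) recurring at spacings compatible with
   one repeat + one spacer define candidate chains;
2. each chain is extended to full repeat units by maximizing a per-column
   log-likelihood of "conserved column" against the contig's own base
   composition (GC-rich backgrounds make naive majority voting
   over-extend, so the null model matters);
3. missed units (seed k-mers destroyed by mutation) are recovered by
   scanning flanking/interior windows against the running consensus;
4. confidence filters keep only high-evidence arrays: >= 4 units, repeat
   conservation >= 0.80, and maximum pairwise spacer identity <= 0.60
   (rejects tandem repeats, whose "spacers" are all alike).

Coordinates are 0-based half-open on the forward strand; detection is
strand-agnostic (a reverse-complemented contig yields the mirrored array).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from Bio import SeqIO

from .sequtil import ungapped_identity


class InputError(ValueError):
    """Unreadable or empty input."""


@dataclass(frozen=True)
class ScanConfig:
    k_seed: int = 9
    repeat_len_range: tuple[int, int] = (23, 55)
    spacer_len_range: tuple[int, int] = (18, 60)
    min_units: int = 4
    min_repeat_conservation: float = 0.80
    max_spacer_pairwise_identity: float = 0.60
    permissive: bool = False  # keep 3-unit arrays

    def __post_init__(self) -> None:
        if self.k_seed > self.repeat_len_range[0]:
            raise ValueError("k_seed must not exceed the minimum repeat length")
        if self.repeat_len_range[0] > self.repeat_len_range[1]:
            raise ValueError("empty repeat length range")
        if self.spacer_len_range[0] > self.spacer_len_range[1]:
            raise ValueError("empty spacer length range")

    @property
    def min_period(self) -> int:
        return self.repeat_len_range[0] + self.spacer_len_range[0]

    @property
    def max_period(self) -> int:
        return self.repeat_len_range[1] + self.spacer_len_range[1]

    @property
    def effective_min_units(self) -> int:
        return 3 if self.permissive else self.min_units


@dataclass
class CrisprArray:
    """One detected array (all coordinates 0-based half-open, forward)."""

    contig_id: str
    start: int
    end: int
    unit_coords: list[tuple[int, int]]
    repeat_seqs: list[str]
    spacer_seqs: list[str]
    consensus_repeat: str
    conservation: float
    orientation: str = "?"  # +, - or ? (assigned later from the repeat motif)
    truncated: bool = False

    @property
    def n_units(self) -> int:
        return len(self.repeat_seqs)

    def max_spacer_identity(self) -> float:
        sp = self.spacer_seqs
        best = 0.0
        for i in range(len(sp)):
            for j in range(i + 1, len(sp)):
                best = max(best, ungapped_identity(sp[i], sp[j]))
        return best


@dataclass
class SeedChain:
    kmer: str
    positions: list[int] = field(default_factory=list)

    @property
    def start(self) -> int:
        return self.positions[0]

    @property
    def end(self) -> int:
        return self.positions[-1] + len(self.kmer)


# ---------------------------------------------------------------------------
# stage 1: seeding


def find_seed_repeats(contig: str, cfg: ScanConfig | None = None) -> list[SeedChain]:
    """Maximal chains of an identical k-mer recurring at array-like spacings.

    Low-complexity seeds (< 3 distinct bases) are ignored, which keeps
    homopolymer and dinucleotide tracts from flooding the index. Chains
    describing the same locus at different k-mer offsets are collapsed to
    the longest (ties: leftmost). Returned ordered by position.
    """
    cfg = cfg or ScanConfig()
    contig = contig.upper()
    k = cfg.k_seed
    index: dict[str, list[int]] = {}
    for i in range(len(contig) - k + 1):
        word = contig[i:i + k]
        if len(set(word)) < 3 or "N" in word:
            continue
        index.setdefault(word, []).append(i)

    chains: list[SeedChain] = []
    for word, positions in index.items():
        if len(positions) < 2:
            continue
        current = [positions[0]]
        for p in positions[1:]:
            gap = p - current[-1]
            if gap < cfg.min_period:
                continue  # overlapping / intra-repeat recurrence
            if gap <= cfg.max_period:
                current.append(p)
            else:
                if len(current) >= 2:
                    chains.append(SeedChain(word, current))
                current = [p]
        if len(current) >= 2:
            chains.append(SeedChain(word, current))

    # collapse offset-shifted chains of the same locus
    chains.sort(key=lambda c: (-len(c.positions), c.start))
    kept: list[SeedChain] = []
    for ch in chains:
        redundant = False
        for acc in kept:
            if ch.start >= acc.start - cfg.repeat_len_range[1] and \
                    ch.end <= acc.end + cfg.repeat_len_range[1] and \
                    all(any(abs(p - q) < cfg.repeat_len_range[1]
                            for q in acc.positions) for p in ch.positions):
                redundant = True
                break
        if not redundant:
            kept.append(ch)
    kept.sort(key=lambda c: c.start)
    return kept


# ---------------------------------------------------------------------------
# stage 2: extension to full repeat units


def _base_log_odds(contig: str) -> dict[str, float]:
    """log background probability per base, floored at 5%."""
    n = max(1, len(contig))
    return {b: math.log(max(contig.count(b) / n, 0.05)) for b in "ACGT"}


# conserved-column model: each unit matches the consensus base with
# probability 1 - r (r ~ 2% per-copy substitution), else one of the three
# other bases uniformly
_MATCH_LP = math.log(0.98)
_MISMATCH_LP = math.log(0.02 / 3)


def _column_score(contig: str, anchors: list[int], d: int,
                  log_bg: dict[str, float]) -> float:
    """Log-likelihood ratio (conserved column vs background) at offset d."""
    bases = []
    for p in anchors:
        q = p + d
        if q < 0 or q >= len(contig):
            return -math.inf
        bases.append(contig[q])
    if any(b not in "ACGT" for b in bases):
        return -math.inf
    counts = {b: bases.count(b) for b in set(bases)}
    maj = max(sorted(counts), key=counts.get)
    score = 0.0
    for b in bases:
        score += (_MATCH_LP if b == maj else _MISMATCH_LP) - log_bg[b]
    return score


def _consensus(seqs: list[str]) -> str:
    cons = []
    for col in zip(*seqs):
        counts = {b: col.count(b) for b in set(col)}
        cons.append(max(sorted(counts), key=counts.get))
    return "".join(cons)


def _conservation(seqs: list[str], cons: str) -> float:
    if not seqs:
        return 0.0
    per = [sum(1 for a, b in zip(s, cons) if a == b) / len(cons) for s in seqs]
    return sum(per) / len(per)


def _extend_chain(contig: str, chain: SeedChain, cfg: ScanConfig,
                  log_bg: dict[str, float]) -> tuple[int, int] | None:
    """Choose (left_ext a, right_ext b): repeat = [p - a, p + k + b).

    Maximizes the summed column log-likelihood over the repeat window,
    subject to the repeat length range and to every inter-unit gap landing
    in the spacer length range. Ties prefer the leftmost start, then the
    shortest repeat.
    """
    k = len(chain.kmer)
    pos = chain.positions
    periods = [b - a for a, b in zip(pos, pos[1:])]
    rmin, rmax = cfg.repeat_len_range
    smin, smax = cfg.spacer_len_range
    # gap_i = period_i - repeat_len must lie in [smin, smax]
    len_lo = max(rmin, max(periods) - smax, k)
    len_hi = min(rmax, min(periods) - smin)
    if len_lo > len_hi:
        return None
    max_ext = len_hi - k
    offsets = range(-max_ext, k + max_ext)
    col = {d: _column_score(contig, pos, d, log_bg) for d in offsets}
    BAD = -1e9  # sentinel for out-of-bounds columns (prefix-sum friendly)
    cum = {}  # cum[d] = sum of column scores over (-max_ext .. d)
    run = 0.0
    for d in offsets:
        run += col[d] if col[d] != -math.inf else BAD
        cum[d] = run
    cum[-max_ext - 1] = 0.0
    best = None
    for a in range(0, max_ext + 1):
        for b in range(0, max_ext + 1):
            length = a + k + b
            if not len_lo <= length <= len_hi:
                continue
            total = cum[k + b - 1] - cum[-a - 1]
            if total < BAD / 2:
                continue
            key = (total, a, -length)  # prefer leftmost start, then shortest
            if best is None or key > best[0]:
                best = (key, a, b)
    if best is None:
        return None
    return best[1], best[2]


def _try_add_unit(contig: str, cons: str, lo: int, hi: int,
                  min_ident: float) -> tuple[int, int] | None:
    """Best consensus-matching window starting in [lo, hi]; None if < min_ident."""
    L = len(cons)
    best = None
    for s in range(max(0, lo), min(hi, len(contig) - L) + 1):
        ident = ungapped_identity(contig[s:s + L], cons)
        if ident >= min_ident and (best is None or ident > best[0]):
            best = (ident, s)
    if best is None:
        return None
    return best[1], best[1] + L


def build_arrays(chains: list[SeedChain], contig: str,
                 cfg: ScanConfig | None = None,
                 contig_id: str = "contig") -> list[CrisprArray]:
    """Extend seed chains to full arrays with refined unit boundaries.

    After boundary selection the consensus is computed by per-column
    majority (ties to the alphabetically first base) and units whose seed
    k-mer was destroyed by mutation are recovered by consensus scanning,
    outward from the array ends and inside over-long gaps.
    """
    cfg = cfg or ScanConfig()
    contig = contig.upper()
    log_bg = _base_log_odds(contig)

    candidates: list[CrisprArray] = []
    for chain in chains:
        arr = _best_chain_variant(contig, chain, cfg, log_bg, contig_id)
        if arr is not None:
            candidates.append(arr)

    # resolve overlaps: prefer arrays that pass the confidence filters,
    # then most units, then conservation
    def _passes(a: CrisprArray) -> bool:
        return (a.n_units >= cfg.effective_min_units
                and a.conservation >= cfg.min_repeat_conservation
                and a.max_spacer_identity() <= cfg.max_spacer_pairwise_identity)

    candidates.sort(key=lambda x: (-_passes(x), -x.n_units, -x.conservation,
                                   x.start))
    kept: list[CrisprArray] = []
    for arr in candidates:
        if all(arr.end <= other.start or arr.start >= other.end
               for other in kept):
            kept.append(arr)
    kept.sort(key=lambda x: x.start)
    return kept


def _realign_units(contig: str, units: list[tuple[int, int]],
                   min_ident: float) -> list[tuple[int, int]]:
    """Snap units that disagree with the consensus to their best local fit.

    Repeat templates can contain internal near-duplications of the seed
    k-mer; when a seed copy is mutated, the chain may anchor that unit at
    the wrong intra-repeat offset. Units below the identity bar are
    re-searched within one repeat length of their anchor.
    """
    if len(units) < 3:
        return units
    L = units[0][1] - units[0][0]
    cons = _consensus([contig[s:e] for s, e in units])
    moved = []
    for s, e in units:
        ident = ungapped_identity(contig[s:e], cons)
        if ident >= min_ident:
            moved.append((s, e))
            continue
        best_i, best_s = ident, s
        for c in range(max(0, s - L), min(len(contig) - L, s + L) + 1):
            i2 = ungapped_identity(contig[c:c + L], cons)
            if i2 > best_i:
                best_i, best_s = i2, c
        moved.append((best_s, best_s + L))
    moved = sorted(set(moved))
    out: list[tuple[int, int]] = []
    for u in moved:
        if out and u[0] < out[-1][1]:
            prev = out[-1]
            if ungapped_identity(contig[u[0]:u[1]], cons) > \
                    ungapped_identity(contig[prev[0]:prev[1]], cons):
                out[-1] = u
        else:
            out.append(u)
    return out


def _array_from_positions(contig: str, positions: list[int], k: int,
                          cfg: ScanConfig, log_bg: dict[str, float],
                          contig_id: str) -> CrisprArray | None:
    """Boundary extension + unit recovery for one set of seed anchors."""
    smin, smax = cfg.spacer_len_range
    ext = _extend_chain(contig, SeedChain("N" * k, positions), cfg, log_bg)
    if ext is None:
        return None
    a, b = ext
    L = a + k + b
    units = [(p - a, p - a + L) for p in positions]
    if units[0][0] < 0 or units[-1][1] > len(contig):
        return None
    # acceptance bar for recovered/realigned units: random windows match a
    # consensus at ~0.3 per base even in GC-rich sequence, true units sit
    # near 1 - substitution rate, so the conservation threshold separates
    # them cleanly
    min_ident = cfg.min_repeat_conservation
    units = _realign_units(contig, units, min_ident)
    repeats = [contig[s:e] for s, e in units]
    cons = _consensus(repeats)

    # recover units the seeding missed: outward, then in over-long gaps
    changed = True
    while changed:
        changed = False
        s0 = units[0][0]
        cand = _try_add_unit(contig, cons, s0 - smax - L, s0 - smin - L,
                             min_ident)
        if cand and cand[1] <= s0 - smin:
            units.insert(0, cand)
            changed = True
        e_last = units[-1][1]
        cand = _try_add_unit(contig, cons, e_last + smin, e_last + smax,
                             min_ident)
        if cand and cand[0] >= e_last + smin:
            units.append(cand)
            changed = True
        for i in range(len(units) - 1):
            gap = units[i + 1][0] - units[i][1]
            if gap > smax:
                cand = _try_add_unit(contig, cons, units[i][1] + smin,
                                     units[i + 1][0] - smin - L, min_ident)
                if cand:
                    units.insert(i + 1, cand)
                    changed = True
                    break
        if changed:
            repeats = [contig[s:e] for s, e in units]
            cons = _consensus(repeats)

    # prune divergent terminal units (spurious seed recurrences at the ends)
    while len(units) > 2:
        repeats = [contig[s:e] for s, e in units]
        cons = _consensus(repeats)
        if ungapped_identity(repeats[0], cons) < min_ident:
            units = units[1:]
        elif ungapped_identity(repeats[-1], cons) < min_ident:
            units = units[:-1]
        else:
            break
    repeats = [contig[s:e] for s, e in units]
    cons = _consensus(repeats)
    spacers = [contig[units[i][1]:units[i + 1][0]]
               for i in range(len(units) - 1)]
    return CrisprArray(
        contig_id=contig_id, start=units[0][0], end=units[-1][1],
        unit_coords=units, repeat_seqs=repeats, spacer_seqs=spacers,
        consensus_repeat=cons, conservation=_conservation(repeats, cons),
    )


def _best_chain_variant(contig: str, chain: SeedChain, cfg: ScanConfig,
                        log_bg: dict[str, float],
                        contig_id: str) -> CrisprArray | None:
    """Build the chain and, if needed, end-trimmed variants of it.

    A chance recurrence of the seed k-mer just outside a real array can
    corrupt the inferred unit geometry (the shortest inter-seed period
    caps the repeat length), so when the full chain yields a low-evidence
    array, variants with up to two seeds dropped from either end are
    tried; the best candidate wins (filter pass, then unit count, then
    conservation).
    """
    k = len(chain.kmer)
    pos = chain.positions
    variants = []
    for t0 in range(0, 3):
        for t1 in range(0, 3):
            if len(pos) - t0 - t1 < 2:
                continue
            trimmed = pos[t0:len(pos) - t1] if t1 else pos[t0:]
            arr = _array_from_positions(contig, trimmed, k, cfg, log_bg,
                                        contig_id)
            if arr is not None:
                passes = (arr.n_units >= cfg.effective_min_units
                          and arr.conservation >= cfg.min_repeat_conservation
                          and arr.max_spacer_identity()
                          <= cfg.max_spacer_pairwise_identity)
                variants.append((passes, arr.n_units, arr.conservation, -arr.start, arr))
            if t0 == 0 and t1 == 0 and variants and variants[0][0]:
                return variants[0][4]  # untrimmed chain already high-evidence
    if not variants:
        return None
    variants.sort(key=lambda v: v[:4], reverse=True)
    return variants[0][4]


# ---------------------------------------------------------------------------
# stage 3: confidence filters


def filter_arrays(arrays: list[CrisprArray],
                  cfg: ScanConfig | None = None) -> list[CrisprArray]:
    """High-evidence filter: unit count, repeat conservation, spacer diversity."""
    cfg = cfg or ScanConfig()
    out = []
    for arr in arrays:
        if arr.n_units < cfg.effective_min_units:
            continue
        if arr.conservation < cfg.min_repeat_conservation:
            continue
        if arr.max_spacer_identity() > cfg.max_spacer_pairwise_identity:
            continue
        out.append(arr)
    return out


# ---------------------------------------------------------------------------
# orchestration


def _flag_truncated(arr: CrisprArray, contig_len: int, cfg: ScanConfig) -> None:
    """Arrays abutting a contig edge may continue off-contig."""
    if arr.start < cfg.max_period or contig_len - arr.end < cfg.max_period:
        arr.truncated = True


def detect_contig(contig: str, cfg: ScanConfig | None = None,
                  contig_id: str = "contig") -> list[CrisprArray]:
    cfg = cfg or ScanConfig()
    if len(contig) < 2 * cfg.repeat_len_range[0]:
        return []
    chains = find_seed_repeats(contig, cfg)
    arrays = filter_arrays(build_arrays(chains, contig, cfg, contig_id), cfg)
    for arr in arrays:
        _flag_truncated(arr, len(contig), cfg)
    return arrays


def detect(assembly, cfg: ScanConfig | None = None) -> list[CrisprArray]:
    """Detect arrays in a FASTA path or an iterable of SeqRecords.

    Output is sorted by (contig id, start), so it does not depend on the
    record order of the input.
    """
    cfg = cfg or ScanConfig()
    if isinstance(assembly, (str, bytes)) or hasattr(assembly, "read"):
        try:
            records = list(SeqIO.parse(assembly, "fasta"))
        except (OSError, ValueError) as exc:
            raise InputError(f"cannot read FASTA {assembly!r}: {exc}") from exc
    else:
        records = list(assembly)
    if not records:
        raise InputError(f"no FASTA records in {assembly!r}")
    out: list[CrisprArray] = []
    for rec in records:
        out.extend(detect_contig(str(rec.seq), cfg, contig_id=rec.id))
    out.sort(key=lambda a: (a.contig_id, a.start))
    return out
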