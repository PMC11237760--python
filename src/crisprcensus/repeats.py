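"""Repeat-based CRISPR type classification (C / B / G / E / U).

Direct-repeat sequences are strongly conserved within a CRISPR-Cas
lineage and carry diagnostic features at fixed positions: a short
3'-terminal motif (C: -TTGAAAC, G: -TTGAAGC, B: -TTGAGCAC), a
characteristic length, and an inverted-repeat hairpin (the E family lacks
a tail motif but carries an internal palindrome, CCCCGC-NNNN-GCGGGG).
Typing an array from its consensus repeat alone therefore works even in
fragmented assemblies where the cas cluster is missing — which is the
point of this module. Repeats matching no rule are labelled U
(unclassified).

Rules are applied in precedence order B, G, C, E (longest terminal motif
first); C and G differ by a single base (TTGA-A-AC vs TTGA-G-C), so the
default motif tolerance is 0 mismatches.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

from .sequtil import revcomp

IUPAC_SETS = {
    "N": set("ACGT"), "A": {"A"}, "C": {"C"}, "G": {"G"}, "T": {"T"},
    "R": set("AG"), "Y": set("CT"), "S": set("CG"), "W": set("AT"),
    "K": set("GT"), "M": set("AC"), "B": set("CGT"), "D": set("AGT"),
    "H": set("ACT"), "V": set("ACG"),
}


@dataclass(frozen=True)
class TypeRule:
    label: str
    terminal_motif: str | None  # matched at the 3' end (C, B, G)
    internal_pattern: str | None  # IUPAC pattern anywhere (E)
    length_range: tuple[int, int]


DEFAULT_RULES = [
    TypeRule("B", "TTGAGCAC", None, (34, 38)),
    TypeRule("G", "TTGAAGC", None, (34, 38)),
    TypeRule("C", "TTGAAAC", None, (35, 39)),
    TypeRule("E", None, "CCCCGCNNNNGCGGGG", (27, 33)),
]


@dataclass
class RepeatTypeCall:
    label: str  # C, B, G, E or U
    oriented_consensus: str
    strand_flipped: bool
    matched_motif: str | None
    motif_mismatches: int
    hairpin: tuple[int, int, int, int]  # (stem_len, loop_len, i, j)


def _check_dna(seq: str) -> str:
    seq = seq.upper()
    if not seq or any(b not in "ACGTN" for b in seq):
        raise ValueError(f"not a DNA (ACGTN) string: {seq!r}")
    return seq


def _motif_mismatches(seq: str, motif: str) -> int:
    """Mismatches of the 3'-terminal window against an IUPAC motif."""
    if len(seq) < len(motif):
        return len(motif)
    tail = seq[-len(motif):]
    return sum(1 for b, m in zip(tail, motif) if b not in IUPAC_SETS[m])


def _best_terminal(seq: str, rules: list[TypeRule]) -> int:
    """Fewest mismatches of any terminal motif at the 3' end of seq."""
    best = min(
        (_motif_mismatches(seq, r.terminal_motif)
         for r in rules if r.terminal_motif), default=10 ** 6)
    return best


def canonical_orientation(repeat: str, rules: list[TypeRule] | None = None,
                          tolerance: int = 2) -> tuple[str, bool]:
    """Orient a repeat 5'→3' by its terminal motif.

    Returns the strand on which a terminal type motif matches with fewest
    mismatches (within ``tolerance``); if neither strand carries a motif,
    the lexicographically smaller of sequence/reverse-complement is
    returned. Deterministic and an involution: feeding the reverse
    complement restores the same output.
    """
    rules = rules or DEFAULT_RULES
    fwd = _check_dna(repeat)
    rev = revcomp(fwd)
    mf, mr = _best_terminal(fwd, rules), _best_terminal(rev, rules)
    if min(mf, mr) <= tolerance:
        if mf < mr:
            return fwd, False
        if mr < mf:
            return rev, True
    # no motif evidence (or a dead tie): lexicographic canonical form
    if fwd <= rev:
        return fwd, False
    return rev, True


def hairpin_stem(seq: str, min_loop: int = 3) -> tuple[int, int, int, int]:
    """Longest inverted repeat within the sequence (crRNA hairpin proxy).

    Finds the longest L with seq[i:i+L] reverse-complementary to
    seq[j:j+L] and j >= i + L + min_loop; ties resolved to the smallest i,
    then the smallest j. Returns (stem_len, loop_len, i, j);
    (0, 0, -1, -1) if no complementary pair exists.
    """
    seq = _check_dna(seq)
    n = len(seq)
    rc = revcomp(seq)  # revcomp(seq[j:j+L]) == rc[n-j-L : n-j]
    max_l = (n - min_loop) // 2
    for L in range(max_l, 0, -1):
        for i in range(0, n - 2 * L - min_loop + 1):
            left = seq[i:i + L]
            for j in range(i + L + min_loop, n - L + 1):
                if left == rc[n - j - L:n - j]:
                    return L, j - (i + L), i, j
    return 0, 0, -1, -1


def _pattern_search(seq: str, pattern: str) -> bool:
    regex = "".join("." if b == "N" else b for b in pattern)
    return re.search(regex, seq) is not None


def assign_type(consensus: str, rules: list[TypeRule] | None = None,
                max_motif_mismatches: int = 0,
                fuzzy: bool = False) -> RepeatTypeCall:
    """Classify a consensus repeat into C/B/G/E, or U if no rule fits.

    The repeat is first oriented canonically; the first rule (precedence
    order of ``rules``) whose terminal motif matches the 3' end within the
    mismatch budget *and* whose length range contains the repeat length
    wins. The E family is matched by its internal palindrome instead.
    With ``fuzzy`` one motif mismatch is allowed; a resulting C/G tie is
    resolved by the discriminating base (TTGA[A]AC vs TTGA[A][G]C).
    Strand-invariant: assign_type(revcomp(x)) == assign_type(x).
    """
    rules = rules or DEFAULT_RULES
    consensus = _check_dna(consensus)
    if not 23 <= len(consensus) <= 55:
        raise ValueError(f"consensus length {len(consensus)} outside [23, 55]")
    oriented, flipped = canonical_orientation(consensus, rules)
    budget = max(max_motif_mismatches, 1 if fuzzy else 0)
    n = len(oriented)

    label, motif, mism = "U", None, 0
    terminal_hits = []
    for rule in rules:
        if not rule.length_range[0] <= n <= rule.length_range[1]:
            continue
        if rule.terminal_motif:
            m = _motif_mismatches(oriented, rule.terminal_motif)
            if m <= budget:
                terminal_hits.append((rule, m))
        elif rule.internal_pattern:
            if _pattern_search(oriented, rule.internal_pattern) or \
                    _pattern_search(revcomp(oriented), rule.internal_pattern):
                terminal_hits.append((rule, 0))
    if terminal_hits:
        exact = [h for h in terminal_hits if h[1] == 0]
        if exact:
            rule, mism = exact[0]
        elif fuzzy and {h[0].label for h in terminal_hits} >= {"C", "G"}:
            # one-mismatch C/G ambiguity: read the discriminating base
            disc = oriented[-3]  # TTGAA[A]C vs TTGAA[G]C
            pick = "C" if disc == "A" else "G" if disc == "G" else None
            if pick is None:
                rule, mism = terminal_hits[0]
            else:
                rule, mism = next(h for h in terminal_hits
                                  if h[0].label == pick)
        else:
            rule, mism = terminal_hits[0]
        label = rule.label
        motif = rule.terminal_motif or rule.internal_pattern

    return RepeatTypeCall(
        label=label, oriented_consensus=oriented, strand_flipped=flipped,
        matched_motif=motif, motif_mismatches=mism,
        hairpin=hairpin_stem(oriented),
    )


# ---------------------------------------------------------------------------
# repeat clustering


@dataclass
class RepeatCluster:
    member_indices: list[int]
    members: list[str]
    consensus: str
    conservation: float


def _anchored_identity(a: str, b: str) -> float:
    """Ungapped identity with sequences aligned at their 3' ends.

    The terminal motif sits at the 3' end, so right-anchoring compares
    homologous positions even when repeat lengths differ slightly.
    """
    n = min(len(a), len(b))
    if n == 0:
        return 0.0
    return sum(1 for x, y in zip(a[-n:], b[-n:]) if x == y) / n


def cluster_repeats(repeats: list[str], id_threshold: float = 0.90,
                    ) -> list[RepeatCluster]:
    """Single-linkage clusters of strand-normalized repeats.

    Pairs with 3'-anchored ungapped identity >= id_threshold are linked;
    per-cluster consensus is the per-column majority (right-anchored, over
    the modal length) and conservation the mean identity to it.
    """
    if not repeats:
        raise ValueError("repeats must be non-empty")
    n = len(repeats)
    parent = list(range(n))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i in range(n):
        for j in range(i + 1, n):
            if _anchored_identity(repeats[i], repeats[j]) >= id_threshold:
                parent[find(i)] = find(j)

    groups: dict[int, list[int]] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(i)

    clusters = []
    for idxs in groups.values():
        members = [repeats[i] for i in idxs]
        width = max(len(m) for m in members)
        cols = []
        for d in range(width):  # d counted from the 3' end
            col = [m[len(m) - 1 - d] for m in members if d < len(m)]
            counts = {b: col.count(b) for b in set(col)}
            cols.append(max(sorted(counts), key=counts.get))
        consensus = "".join(reversed(cols))
        conservation = sum(_anchored_identity(m, consensus)
                           for m in members) / len(members)
        clusters.append(RepeatCluster(
            member_indices=sorted(idxs), members=members,
            consensus=consensus, conservation=conservation))
    clusters.sort(key=lambda c: c.member_indices[0])
    return clusters
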