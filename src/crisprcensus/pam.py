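"""PAM inference from protospacer flanks.

The protospacer adjacent motif is read from the 8-nt 5' flank of each
non-redundant target, stratified by how well the target matches its
spacer: perfect (0 mismatches), high-confidence (<= 3), extended (<= 6)
and all. For each stratum this module produces

* trinucleotide counts/ratios of the PAM window (the 3 nt immediately
  5' of the protospacer, i.e. the last 3 of the flank);
* the preferred-PAM list at the >= 10% ratio rule;
* an 8 x 4 per-position base-frequency matrix (logo data);
* a degenerate IUPAC consensus built from perfectly matched targets
  (per position, the set of bases with frequency >= 15%), with the
  fraction of perfect PAMs the motif covers.

Aged targets accumulate mutations in both protospacer and PAM, which is
why degenerate consensus building is restricted to the perfect stratum.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass

import pandas as pd

from .trace import TargetHit

logger = logging.getLogger(__name__)

STRATA = (("perfect", 0), ("high_confidence", 3), ("extended", 6),
          ("all", None))

_IUPAC_BY_SET = {
    frozenset("A"): "A", frozenset("C"): "C", frozenset("G"): "G",
    frozenset("T"): "T", frozenset("AG"): "R", frozenset("CT"): "Y",
    frozenset("CG"): "S", frozenset("AT"): "W", frozenset("GT"): "K",
    frozenset("AC"): "M", frozenset("CGT"): "B", frozenset("AGT"): "D",
    frozenset("ACT"): "H", frozenset("ACG"): "V", frozenset("ACGT"): "N",
}
IUPAC_SETS = {v: set(k) for k, v in _IUPAC_BY_SET.items()}


@dataclass
class PamProfile:
    stratum: str
    n_targets: int
    n_excluded: int  # hits without a usable 5' flank
    tri_counts: dict[str, int]
    tri_ratios: dict[str, float]
    preferred: list[tuple[str, float]]  # ratio >= 0.10, sorted desc
    position_matrix: pd.DataFrame | None  # 8 positions x ACGT, rows sum to 1
    degenerate: str | None = None  # filled for the perfect stratum
    degenerate_coverage: float | None = None

    def to_dict(self) -> dict:
        return {
            "stratum": self.stratum, "n_targets": self.n_targets,
            "n_excluded": self.n_excluded, "tri_counts": self.tri_counts,
            "tri_ratios": self.tri_ratios,
            "preferred": [list(p) for p in self.preferred],
            "position_matrix": (self.position_matrix.to_dict("index")
                                if self.position_matrix is not None else None),
            "degenerate": self.degenerate,
            "degenerate_coverage": self.degenerate_coverage,
        }


def pam_of(hit: TargetHit) -> str | None:
    """The 3 nt immediately 5' of the protospacer, on its strand."""
    if hit.flank5 is None or len(hit.flank5) < 3:
        return None
    return hit.flank5[-3:]


def stratify_hits(hits: list[TargetHit],
                  strata: tuple[int, ...] = (0, 3, 6),
                  ) -> dict[str, list[TargetHit]]:
    """Nested mismatch strata: perfect ⊆ high_confidence ⊆ extended ⊆ all."""
    names = ["perfect", "high_confidence", "extended"][:len(strata)]
    out = {name: [h for h in hits if h.mismatches <= bound]
           for name, bound in zip(names, strata)}
    out["all"] = list(hits)
    return out


def pam_counts(hits: list[TargetHit],
               ) -> tuple[dict[str, int], dict[str, float], int]:
    """Trinucleotide PAM counts and ratios; flankless hits are excluded."""
    counts: Counter[str] = Counter()
    excluded = 0
    for h in hits:
        pam = pam_of(h)
        if pam is None:
            excluded += 1
            continue
        counts[pam] += 1
    if excluded:
        logger.info("pam_counts: %d hit(s) without usable 5' flank excluded",
                    excluded)
    total = sum(counts.values())
    ratios = {k: v / total for k, v in counts.items()} if total else {}
    return dict(counts), ratios, excluded


def preferred_pams(ratios: dict[str, float],
                   min_ratio: float = 0.10) -> list[tuple[str, float]]:
    """PAMs at or above the ratio threshold, sorted by ratio descending.

    The threshold is inclusive: a PAM at exactly 10% is listed.
    """
    out = [(k, v) for k, v in ratios.items() if v >= min_ratio]
    out.sort(key=lambda kv: (-kv[1], kv[0]))
    return out


def position_profile(hits: list[TargetHit],
                     flank_len: int = 8) -> pd.DataFrame | None:
    """Per-position base frequencies over the 5' flank (rows sum to 1).

    Rows are positions -flank_len .. -1 relative to the protospacer start;
    columns A, C, G, T. None when no hit has a usable flank.
    """
    flanks = [h.flank5 for h in hits
              if h.flank5 is not None and len(h.flank5) == flank_len]
    if not flanks:
        return None
    mat = pd.DataFrame(0.0, index=range(-flank_len, 0), columns=list("ACGT"))
    for f in flanks:
        for pos, base in zip(mat.index, f):
            if base in "ACGT":
                mat.loc[pos, base] += 1
    return mat.div(mat.sum(axis=1), axis=0)


def degenerate_consensus(perfect_hits: list[TargetHit],
                         pos_threshold: float = 0.15,
                         ) -> tuple[str | None, float]:
    """Degenerate IUPAC PAM from perfectly matched targets.

    Per PAM position, the set of bases observed at frequency >=
    pos_threshold is encoded as an IUPAC letter; coverage is the fraction
    of perfect-hit PAMs the motif matches. (None, 0.0) with a warning
    when no perfect hit has a flank.
    """
    pams = [p for p in (pam_of(h) for h in perfect_hits) if p is not None]
    if not pams:
        logger.warning("degenerate_consensus: no perfectly matched targets "
                       "with flanks; no consensus")
        return None, 0.0
    n = len(pams)
    letters = []
    sets = []
    for pos in range(3):
        freqs = Counter(p[pos] for p in pams)
        allowed = {b for b, c in freqs.items() if c / n >= pos_threshold
                   and b in "ACGT"}
        if not allowed:  # pathological spread: fall back to N
            allowed = set("ACGT")
        sets.append(allowed)
        letters.append(_IUPAC_BY_SET[frozenset(allowed)])
    coverage = sum(1 for p in pams
                   if all(p[i] in sets[i] for i in range(3))) / n
    return "".join(letters), coverage


def build_profiles(hits: list[TargetHit],
                   strata: tuple[int, ...] = (0, 3, 6),
                   min_ratio: float = 0.10,
                   pos_threshold: float = 0.15) -> dict[str, PamProfile]:
    """All per-stratum PAM profiles for one set of non-redundant targets."""
    out: dict[str, PamProfile] = {}
    layers = stratify_hits(hits, strata)
    for name, subset in layers.items():
        counts, ratios, excluded = pam_counts(subset)
        profile = PamProfile(
            stratum=name, n_targets=sum(counts.values()),
            n_excluded=excluded, tri_counts=counts, tri_ratios=ratios,
            preferred=preferred_pams(ratios, min_ratio),
            position_matrix=position_profile(subset),
        )
        if name == "perfect":
            profile.degenerate, profile.degenerate_coverage = \
                degenerate_consensus(subset, pos_threshold)
        out[name] = profile
    return out
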