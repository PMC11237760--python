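"""Census summary report: per-type array/spacer counts and tracing rate.

The headline number is the traced fraction: the percentage of unique
spacers with at least one target hit, rounded half-up to two decimals
(e.g. 13,429 of 19,178 → 70.02). Totals are always recomputed from their
parts, never stored independently.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

from . import __version__

TYPE_LABELS = ("C", "B", "G", "E", "U")


def pct_traced(n_traced: int, n_total: int) -> float | None:
    """100 * traced / total, rounded half-up to 2 decimals; None if no spacers."""
    if n_total == 0:
        return None
    if not 0 <= n_traced <= n_total:
        raise ValueError(f"traced ({n_traced}) outside [0, total={n_total}]")
    frac = Decimal(100 * n_traced) / Decimal(n_total)
    return float(frac.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


@dataclass
class CensusReport:
    n_arrays_by_type: dict[str, int] = field(default_factory=dict)
    n_spacers_by_type: dict[str, int] = field(default_factory=dict)
    n_spacers_total: int = 0
    n_spacers_unique: int = 0
    n_spacers_traced: int = 0
    pct_traced: float | None = None
    n_targets_nonredundant: int | None = None
    pam_profiles: dict | None = None  # per type → per stratum dicts
    seed: int | None = None
    config_hash: str | None = None
    version: str = __version__

    @property
    def n_arrays_total(self) -> int:
        return sum(self.n_arrays_by_type.values())

    def to_json(self, path=None) -> str:
        payload = dataclasses.asdict(self)
        payload["n_arrays_total"] = self.n_arrays_total
        text = json.dumps(payload, indent=2, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text


def config_hash(config: dict) -> str:
    return hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()).hexdigest()[:16]


def summary_report(arrays, type_calls: dict[str, str], spacer_records,
                   unique_spacers, hits, seed: int | None = None,
                   config: dict | None = None,
                   pam_profiles: dict | None = None,
                   n_targets_nonredundant: int | None = None) -> CensusReport:
    """Aggregate stage outputs into a census report.

    ``type_calls`` maps array_id → label; every array and every spacer
    record must be covered (inconsistent ids raise). Tracing is counted
    on unique spacers: a spacer is traced when any hit carries its id.
    """
    from .spacers import array_id_of

    n_arrays: dict[str, int] = {t: 0 for t in TYPE_LABELS}
    for arr in arrays:
        aid = array_id_of(arr)
        if aid not in type_calls:
            raise ValueError(f"array {aid!r} has no type call")
        n_arrays[type_calls[aid]] += 1

    n_spacers: dict[str, int] = {t: 0 for t in TYPE_LABELS}
    for rec in spacer_records:
        if rec.array_id not in type_calls:
            raise ValueError(f"spacer {rec.spacer_id!r}: unknown array "
                             f"{rec.array_id!r}")
        n_spacers[type_calls[rec.array_id]] += 1

    traced_ids = {h.spacer_id for h in hits}
    n_traced = sum(1 for rec in unique_spacers
                   if rec.spacer_id in traced_ids)
    return CensusReport(
        n_arrays_by_type=n_arrays,
        n_spacers_by_type=n_spacers,
        n_spacers_total=sum(n_spacers.values()),
        n_spacers_unique=len(unique_spacers),
        n_spacers_traced=n_traced,
        pct_traced=pct_traced(n_traced, len(unique_spacers)),
        n_targets_nonredundant=n_targets_nonredundant,
        pam_profiles=pam_profiles,
        seed=seed,
        config_hash=config_hash(config) if config is not None else None,
    )
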