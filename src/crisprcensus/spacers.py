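"""Spacer extraction, deduplication and per-type summary statistics.

Spacers are the inter-repeat intervals of a detected array. They are
catalogued in array order (index 0 = the leader-proximal end when the
array orientation is known, else the leftmost), deduplicated on exact
sequence after strand normalization, and profiled per repeat type:
counts, length distribution, GC quartiles and per-array spacer numbers.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .detect import CrisprArray
from .sequtil import gc_fraction, revcomp


@dataclass(frozen=True)
class SpacerRecord:
    spacer_id: str
    array_id: str
    index: int  # 0 = leader-proximal as detected
    sequence: str
    length: int
    gc: float


def array_id_of(arr: CrisprArray) -> str:
    return f"{arr.contig_id}:{arr.start}-{arr.end}"


def extract_spacers(arrays: list[CrisprArray]) -> list[SpacerRecord]:
    """One record per inter-repeat interval, order preserved.

    Sequences are uppercase forward-strand as detected. For minus-oriented
    arrays the index runs from the right end (the leader-proximal side),
    which affects only reporting, not the sequences.
    """
    records: list[SpacerRecord] = []
    for arr in arrays:
        aid = array_id_of(arr)
        n = len(arr.spacer_seqs)
        for i, seq in enumerate(arr.spacer_seqs):
            idx = (n - 1 - i) if arr.orientation == "-" else i
            seq = seq.upper()
            records.append(SpacerRecord(
                spacer_id=f"{aid}|{idx}", array_id=aid, index=idx,
                sequence=seq, length=len(seq), gc=gc_fraction(seq)))
    return records


def dedupe_spacers(records: list[SpacerRecord],
                   ) -> tuple[list[SpacerRecord], dict[str, int]]:
    """Unique spacers (exact sequence, strand-normalized) + multiplicities.

    Strand normalization keeps the lexicographically smaller of the
    sequence and its reverse complement, so a spacer and its reverse
    complement collapse. The first record of each class is the
    representative; multiplicities are keyed by the normalized sequence.
    """
    reps: dict[str, SpacerRecord] = {}
    mult: dict[str, int] = {}
    for rec in records:
        key = min(rec.sequence, revcomp(rec.sequence))
        mult[key] = mult.get(key, 0) + 1
        reps.setdefault(key, rec)
    return list(reps.values()), mult


def spacer_stats(records: list[SpacerRecord],
                 type_calls: dict[str, str]) -> pd.DataFrame:
    """Per-type summary: counts, length distribution, GC quartiles.

    ``type_calls`` maps array_id → type label (C/B/G/E/U); every record's
    array must have a call. Returns a DataFrame indexed by type with
    columns: n_spacers, mean_length, length_ratios (dict length→ratio,
    summing to 1), gc_q1, gc_median, gc_q3 (linear interpolation),
    max_per_array.
    """
    for rec in records:
        if rec.array_id not in type_calls:
            raise ValueError(f"no type call for array {rec.array_id!r}")
    rows = []
    by_type: dict[str, list[SpacerRecord]] = {}
    for rec in records:
        by_type.setdefault(type_calls[rec.array_id], []).append(rec)
    for label in sorted(by_type):
        recs = by_type[label]
        lengths = np.array([r.length for r in recs])
        gcs = np.array([r.gc for r in recs])
        counts = pd.Series(lengths).value_counts().sort_index()
        ratios = (counts / counts.sum()).to_dict()
        per_array = pd.Series([r.array_id for r in recs]).value_counts()
        q1, med, q3 = np.percentile(gcs, [25, 50, 75])  # linear interpolation
        rows.append({
            "type": label, "n_spacers": len(recs),
            "mean_length": float(lengths.mean()),
            "length_ratios": ratios,
            "gc_q1": float(q1), "gc_median": float(med), "gc_q3": float(q3),
            "max_per_array": int(per_array.max()),
        })
    return pd.DataFrame(rows).set_index("type")
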