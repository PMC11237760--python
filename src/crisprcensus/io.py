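"""Plain-file input/output: FASTA, GFF3, TSV.

All stage artifacts are text files so any stage can be rerun in
isolation. GFF3 output follows the usual CRISPR convention: a
``repeat_region`` feature per array with ``direct_repeat`` and
``binding_site``-free ``spacer`` children; GFF3 coordinates are 1-based
inclusive (internal coordinates are 0-based half-open).
"""

from __future__ import annotations

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqIO.FastaIO import FastaWriter
from Bio.SeqRecord import SeqRecord

from .detect import CrisprArray
from .spacers import SpacerRecord
from .trace import TargetHit

FASTA_WRAP = 70

HITS_COLUMNS = ["spacer_id", "subject_id", "start", "end", "strand",
                "mismatches", "score", "proto_seq", "flank5", "flank3",
                "self_hit"]


def write_fasta(records, path) -> None:
    with open(path, "w") as fh:
        FastaWriter(fh, wrap=FASTA_WRAP).write_file(records)


def read_fasta(path) -> list[SeqRecord]:
    return list(SeqIO.parse(path, "fasta"))


def arrays_to_gff3(arrays: list[CrisprArray], path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for n, arr in enumerate(arrays, 1):
            aid = f"crispr{n}"
            attrs = (f"ID={aid};n_units={arr.n_units};"
                     f"conservation={arr.conservation:.4f};"
                     f"consensus={arr.consensus_repeat};"
                     f"orientation={arr.orientation};"
                     f"truncated={'true' if arr.truncated else 'false'}")
            fh.write("\t".join([
                arr.contig_id, "crisprcensus", "repeat_region",
                str(arr.start + 1), str(arr.end), ".", ".", ".", attrs,
            ]) + "\n")
            for i, (s, e) in enumerate(arr.unit_coords):
                fh.write("\t".join([
                    arr.contig_id, "crisprcensus", "direct_repeat",
                    str(s + 1), str(e), ".", ".", ".",
                    f"ID={aid}.dr{i};Parent={aid}",
                ]) + "\n")
            for i in range(len(arr.unit_coords) - 1):
                s = arr.unit_coords[i][1]
                e = arr.unit_coords[i + 1][0]
                fh.write("\t".join([
                    arr.contig_id, "crisprcensus", "spacer",
                    str(s + 1), str(e), ".", ".", ".",
                    f"ID={aid}.sp{i};Parent={aid}",
                ]) + "\n")


def arrays_to_tsv(arrays: list[CrisprArray], path) -> None:
    cols = ["contig_id", "start", "end", "n_units", "conservation",
            "consensus_repeat", "orientation", "truncated"]
    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for a in arrays:
            fh.write("\t".join(map(str, [
                a.contig_id, a.start, a.end, a.n_units,
                f"{a.conservation:.4f}", a.consensus_repeat, a.orientation,
                int(a.truncated)])) + "\n")


def spacers_to_fasta(records: list[SpacerRecord], path) -> None:
    write_fasta([SeqRecord(Seq(r.sequence), id=r.spacer_id, description="")
                 for r in records], path)


def hits_to_tsv(hits: list[TargetHit], path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(HITS_COLUMNS) + "\n")
        for h in hits:
            fh.write("\t".join(map(str, [
                h.spacer_id, h.subject_id, h.start, h.end, h.strand,
                h.mismatches, h.score, h.proto_seq,
                h.flank5 or ".", h.flank3 or ".", int(h.self_hit)])) + "\n")


def hits_from_tsv(path) -> list[TargetHit]:
    hits = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != HITS_COLUMNS:
            raise ValueError(f"unexpected hit table columns in {path}")
        for line in fh:
            f = line.rstrip("\n").split("\t")
            hits.append(TargetHit(
                spacer_id=f[0], subject_id=f[1], start=int(f[2]),
                end=int(f[3]), strand=f[4], mismatches=int(f[5]),
                score=int(f[6]), proto_seq=f[7],
                flank5=None if f[8] == "." else f[8],
                flank3=None if f[9] == "." else f[9],
                self_hit=bool(int(f[10]))))
    return hits
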