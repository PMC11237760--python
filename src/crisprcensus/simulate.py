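"""Synthetic genomes and mobile elements with planted CRISPR ground truth.

Emulates the kind of corpus the census pipeline is aimed at: high-GC host
contigs (background GC defaults to 0.69, typical of myxobacterial
assemblies) carrying CRISPR arrays of a defined repeat type, length, copy
number and per-copy substitution rate; mobile-element sequences carrying
protospacers with planted PAMs and controlled mismatch counts; and assembly
fragmentation into contigs. Every planted feature is recorded in a
:class:`TruthTable` so downstream stages can be validated without any
external download.

All randomness flows through one ``numpy.random.Generator`` (PCG64) seeded
from ``SimConfig.seed``; equal seeds give byte-identical outputs.
Coordinates are 0-based half-open on the forward strand throughout.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .sequtil import DNA, hamming, random_dna, revcomp, ungapped_identity

# 3'-terminal motifs of the C/B/G repeat families and the internal
# palindrome of the E family (N = any base).
TERMINAL_MOTIFS = {"C": "TTGAAAC", "G": "TTGAAGC", "B": "TTGAGCAC"}
E_PALINDROME = "CCCCGCNNNNGCGGGG"

MIN_GAP = 200  # bp of background between planted arrays / around them
MGE_MIN_GAP = 20  # bp of background around planted protospacers


class PlacementError(ValueError):
    """Planted features cannot be placed without violating a constraint."""


class ConfigError(ValueError):
    """Simulator configuration violates an invariant."""


@dataclass(frozen=True)
class ArraySpec:
    """One planted CRISPR array: type, geometry and mutational load."""

    repeat_type: str = "C"  # C, B, G or E
    repeat_length: int = 37
    n_units: int = 10  # arrays in the study system typically carry tens of spacers
    sub_rate: float = 0.02  # per-base substitution probability per copy
    spacer_length: int = 34
    spacer_gc: float = 0.65
    motif_ablated: bool = False  # if True, mutations may hit the typing motif

    def __post_init__(self) -> None:
        if not 23 <= self.repeat_length <= 55:
            raise ConfigError(f"repeat_length {self.repeat_length} outside [23, 55]")
        if self.n_units < 2:
            raise ConfigError("n_units must be >= 2")
        if not 0.0 <= self.sub_rate <= 1.0:
            raise ConfigError("sub_rate outside [0, 1]")
        if self.repeat_type not in ("C", "B", "G", "E"):
            raise ConfigError(f"unknown repeat_type {self.repeat_type!r}")
        if self.repeat_type == "E" and self.repeat_length < len(E_PALINDROME) + 4:
            raise ConfigError("E-type repeat too short for its internal palindrome")

    @property
    def span(self) -> int:
        return self.n_units * self.repeat_length + (self.n_units - 1) * self.spacer_length


def _default_specs() -> list[ArraySpec]:
    return [ArraySpec()]


@dataclass(frozen=True)
class SimConfig:
    """Knobs of the synthetic corpus.

    Defaults reflect the study system: GC-rich hosts (0.69), C-type arrays
    of 37-bp repeats with 34-bp spacers, a 2% per-copy repeat substitution
    rate, and the C-type 5'-TTC-3' PAM on planted protospacers.
    """

    seed: int = 0
    gc_background: float = 0.69
    n_arrays: int = 3
    array_specs: list[ArraySpec] = field(default_factory=_default_specs)
    genome_length: int = 60_000
    n_protospacers: int = 10
    pam: str = "TTC"
    planted_mismatches: int = 0
    element_length: int = 20_000
    fragmentation: tuple[int, int] = (1, 1000)  # (n_contigs, min_contig bp)

    def __post_init__(self) -> None:
        if not 0.0 <= self.gc_background <= 1.0:
            raise ConfigError("gc_background outside [0, 1]")
        if len(self.pam) != 3 or any(b not in DNA for b in self.pam):
            raise ConfigError("pam must be a 3-nt ACGT string")
        if self.fragmentation[0] < 1 or self.fragmentation[1] < 1:
            raise ConfigError("fragmentation requires n_contigs >= 1 and min_contig >= 1")

    def spec_for(self, i: int) -> ArraySpec:
        """Spec of the i-th planted array (specs cycle if fewer given)."""
        return self.array_specs[i % len(self.array_specs)]

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


@dataclass
class TruthArray:
    array_id: str
    contig_id: str
    start: int
    end: int
    repeat_type: str
    unit_coords: list[tuple[int, int]]
    spacer_seqs: list[str]
    repeat_template: str
    truncated: bool = False


@dataclass
class TruthProtospacer:
    element_id: str
    start: int
    end: int
    strand: str  # '+' or '-'
    spacer_id: str
    mismatches: int
    pam: str


@dataclass
class TruthTable:
    """Planted features emitted by the simulator, for validation."""

    arrays: list[TruthArray] = field(default_factory=list)
    protospacers: list[TruthProtospacer] = field(default_factory=list)

    ARRAY_COLS = (
        "kind array_id contig_id start end repeat_type unit_coords "
        "spacer_seqs repeat_template truncated"
    ).split()

    def to_tsv(self, path) -> None:
        cols = [
            "kind", "id", "contig_id", "start", "end", "repeat_type_or_strand",
            "unit_coords_or_spacer_id", "spacer_seqs_or_mismatches",
            "repeat_template_or_pam", "truncated",
        ]
        with open(path, "w") as fh:
            fh.write("\t".join(cols) + "\n")
            for a in self.arrays:
                units = ",".join(f"{s}-{e}" for s, e in a.unit_coords)
                fh.write(
                    f"array\t{a.array_id}\t{a.contig_id}\t{a.start}\t{a.end}\t"
                    f"{a.repeat_type}\t{units}\t{','.join(a.spacer_seqs)}\t"
                    f"{a.repeat_template}\t{int(a.truncated)}\n"
                )
            for p in self.protospacers:
                fh.write(
                    f"protospacer\t{p.element_id}\t{p.element_id}\t{p.start}\t"
                    f"{p.end}\t{p.strand}\t{p.spacer_id}\t{p.mismatches}\t"
                    f"{p.pam}\t0\n"
                )

    @classmethod
    def from_tsv(cls, path) -> "TruthTable":
        tt = cls()
        with open(path) as fh:
            next(fh)  # header
            for line in fh:
                f = line.rstrip("\n").split("\t")
                if f[0] == "array":
                    units = []
                    if f[6]:
                        for u in f[6].split(","):
                            s, e = u.split("-")
                            units.append((int(s), int(e)))
                    tt.arrays.append(TruthArray(
                        array_id=f[1], contig_id=f[2], start=int(f[3]),
                        end=int(f[4]), repeat_type=f[5], unit_coords=units,
                        spacer_seqs=f[7].split(",") if f[7] else [],
                        repeat_template=f[8], truncated=bool(int(f[9])),
                    ))
                else:
                    tt.protospacers.append(TruthProtospacer(
                        element_id=f[1], start=int(f[3]), end=int(f[4]),
                        strand=f[5], spacer_id=f[6], mismatches=int(f[7]),
                        pam=f[8],
                    ))
        return tt


# ---------------------------------------------------------------------------
# repeat templates and spacers


def make_repeat_template(rng: np.random.Generator, spec: ArraySpec, gc: float) -> str:
    """Random repeat of the requested family.

    C/B/G templates end with the family's terminal motif and carry a 6-bp
    stem / 4-nt loop inverted repeat in the body (the crRNA hairpin). E
    templates embed the 16-nt internal palindrome with random bases at its
    four N positions.
    """
    L = spec.repeat_length
    if spec.repeat_type == "E":
        pat = "".join(
            rng.choice(list(DNA)) if b == "N" else b for b in E_PALINDROME
        )
        pre = max(2, (L - len(pat)) // 2)
        body = random_dna(rng, pre, gc) + pat + random_dna(rng, L - pre - len(pat), gc)
        return body
    motif = TERMINAL_MOTIFS[spec.repeat_type]
    body_len = L - len(motif)
    stem = random_dna(rng, 6, gc)
    loop = random_dna(rng, 4, gc)
    hairpin = stem + loop + revcomp(stem)
    pre = max(1, (body_len - len(hairpin)) // 2)
    post = body_len - pre - len(hairpin)
    if post < 0:
        # short repeat: drop the hairpin, keep the motif
        body = random_dna(rng, body_len, gc)
    else:
        body = random_dna(rng, pre, gc) + hairpin + random_dna(rng, post, gc)
    return body + motif


_TYPE_DEFAULT_LENGTH = {"C": 37, "B": 36, "G": 36, "E": 29}


def make_typed_consensus(rng: np.random.Generator, label: str,
                         max_other_mutations: int = 0,
                         gc: float = 0.69) -> str:
    """Random motif-intact consensus repeat of one type.

    Up to ``max_other_mutations`` substitutions are applied outside the
    typing motif (useful for testing classifier robustness).
    """
    spec = ArraySpec(repeat_type=label,
                     repeat_length=_TYPE_DEFAULT_LENGTH[label])
    template = make_repeat_template(rng, spec, gc)
    protected = _protected_positions(spec, template)
    out = list(template)
    free = [i for i in range(len(out)) if i not in protected]
    n_mut = int(rng.integers(0, max_other_mutations + 1))
    for i in rng.choice(free, size=min(n_mut, len(free)), replace=False):
        out[i] = rng.choice([b for b in DNA if b != out[i]])
    return "".join(out)


def _protected_positions(spec: ArraySpec, template: str) -> set[int]:
    """Positions never mutated (the typing motif), unless motif_ablated."""
    if spec.motif_ablated:
        return set()
    L = len(template)
    if spec.repeat_type == "E":
        core = E_PALINDROME.replace("N", ".")
        import re
        m = re.search(core, template)
        if m:
            return set(range(m.start(), m.end()))
        return set()
    return set(range(L - 8, L))


def mutate_copy(rng: np.random.Generator, template: str, rate: float,
                protected: set[int]) -> str:
    out = list(template)
    for i in range(len(out)):
        if i in protected:
            continue
        if rng.random() < rate:
            out[i] = rng.choice([b for b in DNA if b != out[i]])
    return "".join(out)


def sample_spacers(rng: np.random.Generator, n: int, length: int, gc: float,
                   existing: list[str] | None = None,
                   max_identity: float = 0.60, max_tries: int = 2000) -> list[str]:
    """i.i.d. spacers with pairwise ungapped identity < max_identity.

    Rejection against every previously accepted spacer (including
    ``existing``) guarantees planted arrays pass the detector's
    tandem-repeat filter.
    """
    pool: list[str] = list(existing or [])
    out: list[str] = []
    for _ in range(n):
        for _try in range(max_tries):
            cand = random_dna(rng, length, gc)
            if all(ungapped_identity(cand, s) < max_identity for s in pool):
                pool.append(cand)
                out.append(cand)
                break
        else:
            raise PlacementError(
                f"could not sample a spacer with pairwise identity < {max_identity}")
    return out


# ---------------------------------------------------------------------------
# operations


def _partition_gaps(rng: np.random.Generator, total: int, n_gaps: int,
                    min_gap: int) -> list[int]:
    """Random composition of `total` into n_gaps parts, each >= min_gap."""
    free = total - n_gaps * min_gap
    if free < 0:
        raise PlacementError(
            f"cannot fit {n_gaps} gaps of >= {min_gap} bp into {total} bp "
            f"of background (constraint: features + gaps <= sequence length)")
    if n_gaps == 1:
        return [total]
    cuts = np.sort(rng.integers(0, free + 1, size=n_gaps - 1))
    parts = np.diff(np.concatenate([[0], cuts, [free]]))
    return [int(p) + min_gap for p in parts]


def generate_host_genome(cfg: SimConfig, contig_id: str = "sim_contig_1",
                         rng: np.random.Generator | None = None,
                         ) -> tuple[SeqRecord, TruthTable]:
    """One host contig of cfg.genome_length with cfg.n_arrays planted arrays.

    Each array is n_units repeat copies (independently mutated at the
    spec's substitution rate, typing motif protected) interleaved with
    n_units - 1 distinct random spacers. Arrays are separated by at least
    200 bp of background.
    """
    rng = cfg.rng() if rng is None else rng
    specs = [cfg.spec_for(i) for i in range(cfg.n_arrays)]
    total_arr = sum(s.span for s in specs)
    background = cfg.genome_length - total_arr
    gaps = _partition_gaps(rng, background, cfg.n_arrays + 1, MIN_GAP)

    truth = TruthTable()
    pieces: list[str] = []
    pos = 0
    all_spacers: list[str] = []
    for i, spec in enumerate(specs):
        gap = random_dna(rng, gaps[i], cfg.gc_background)
        pieces.append(gap)
        pos += gaps[i]
        template = make_repeat_template(rng, spec, cfg.gc_background)
        protected = _protected_positions(spec, template)
        spacers = sample_spacers(rng, spec.n_units - 1, spec.spacer_length,
                                 spec.spacer_gc, existing=all_spacers)
        all_spacers.extend(spacers)
        start = pos
        unit_coords = []
        arr_pieces = []
        for u in range(spec.n_units):
            unit = mutate_copy(rng, template, spec.sub_rate, protected)
            unit_coords.append((pos, pos + len(unit)))
            arr_pieces.append(unit)
            pos += len(unit)
            if u < spec.n_units - 1:
                arr_pieces.append(spacers[u])
                pos += len(spacers[u])
        pieces.append("".join(arr_pieces))
        truth.arrays.append(TruthArray(
            array_id=f"{contig_id}|array{i}", contig_id=contig_id,
            start=start, end=pos, repeat_type=spec.repeat_type,
            unit_coords=unit_coords, spacer_seqs=spacers,
            repeat_template=template,
        ))
    pieces.append(random_dna(rng, gaps[-1], cfg.gc_background))
    seq = "".join(pieces)
    assert len(seq) == cfg.genome_length
    rec = SeqRecord(Seq(seq), id=contig_id, description="synthetic host contig")
    return rec, truth


def generate_mge(cfg: SimConfig, spacers: list[str],
                 element_id: str = "sim_mge_1",
                 rng: np.random.Generator | None = None,
                 ) -> tuple[SeqRecord, TruthTable]:
    """Mobile element carrying protospacers derived from ``spacers``.

    For each of the first cfg.n_protospacers spacers (cycled if fewer), a
    protospacer with exactly cfg.planted_mismatches substitutions is
    planted on a random strand, with cfg.pam immediately 5' of it on the
    protospacer strand. Spacer ids recorded as ``spacer<i>`` by input index.
    """
    if not spacers:
        raise ValueError("spacers must be non-empty")
    if cfg.planted_mismatches >= min(len(s) for s in spacers):
        raise ConfigError("planted_mismatches must be < spacer length")
    rng = cfg.rng() if rng is None else rng
    chosen = [(i % len(spacers), spacers[i % len(spacers)])
              for i in range(cfg.n_protospacers)]
    unit_len = [len(s) + 3 for _, s in chosen]  # protospacer + PAM
    background = cfg.element_length - sum(unit_len)
    gaps = _partition_gaps(rng, background, len(chosen) + 1, MGE_MIN_GAP)

    truth = TruthTable()
    pieces = []
    pos = 0
    for k, (idx, spacer) in enumerate(chosen):
        pieces.append(random_dna(rng, gaps[k], cfg.gc_background))
        pos += gaps[k]
        proto = list(spacer)
        mut_pos = rng.choice(len(proto), size=cfg.planted_mismatches, replace=False)
        for p in mut_pos:
            proto[p] = rng.choice([b for b in DNA if b != proto[p]])
        proto = "".join(proto)
        strand = "+" if rng.random() < 0.5 else "-"
        if strand == "+":
            unit = cfg.pam + proto
            start = pos + 3
        else:
            unit = revcomp(cfg.pam + proto)
            start = pos
        pieces.append(unit)
        end = start + len(proto)
        pos += len(unit)
        assert hamming(proto, spacer) == cfg.planted_mismatches
        truth.protospacers.append(TruthProtospacer(
            element_id=element_id, start=start, end=end, strand=strand,
            spacer_id=f"spacer{idx}", mismatches=cfg.planted_mismatches,
            pam=cfg.pam,
        ))
    pieces.append(random_dna(rng, gaps[-1], cfg.gc_background))
    seq = "".join(pieces)
    assert len(seq) == cfg.element_length
    rec = SeqRecord(Seq(seq), id=element_id, description="synthetic mobile element")
    return rec, truth


def fragment_assembly(record: SeqRecord, truth: TruthTable, cfg: SimConfig,
                      breakpoints: list[int] | None = None,
                      rng: np.random.Generator | None = None,
                      ) -> tuple[list[SeqRecord], TruthTable]:
    """Partition the contig into fragments; truth coordinates are remapped.

    Fragments cover the source with no base duplicated or lost. Arrays cut
    by a breakpoint are split; each retained part keeps only the repeat
    units fully inside its fragment and is flagged truncated. Explicit
    ``breakpoints`` (sorted cut positions) override random fragmentation.
    """
    n_contigs, min_contig = cfg.fragmentation
    L = len(record.seq)
    if breakpoints is None:
        if n_contigs * min_contig > L:
            raise ConfigError(
                f"min_contig ({min_contig}) x n_contigs ({n_contigs}) "
                f"exceeds sequence length ({L})")
        rng = cfg.rng() if rng is None else rng
        lens = _partition_gaps(rng, L, n_contigs, min_contig)
        breakpoints = list(np.cumsum(lens)[:-1])
    breakpoints = sorted(breakpoints)
    bounds = [0] + [int(b) for b in breakpoints] + [L]
    seq = str(record.seq)

    contigs = []
    new_truth = TruthTable(protospacers=list(truth.protospacers))
    for ci in range(len(bounds) - 1):
        s, e = bounds[ci], bounds[ci + 1]
        cid = f"{record.id}.frag{ci + 1}"
        contigs.append(SeqRecord(Seq(seq[s:e]), id=cid,
                                 description=f"fragment {s}-{e} of {record.id}"))
        for arr in truth.arrays:
            if arr.end <= s or arr.start >= e:
                continue
            intact = arr.start >= s and arr.end <= e
            units = [(us - s, ue - s) for us, ue in arr.unit_coords
                     if us >= s and ue <= e]
            if not units:
                continue
            # spacers between consecutive retained units only
            kept_idx = [i for i, (us, ue) in enumerate(arr.unit_coords)
                        if us >= s and ue <= e]
            spacer_seqs = [arr.spacer_seqs[i] for i in kept_idx[:-1]
                           if i + 1 in kept_idx]
            # an array always starts at its first unit and ends at its last
            new_truth.arrays.append(TruthArray(
                array_id=arr.array_id if intact else f"{arr.array_id}.part{ci + 1}",
                contig_id=cid, start=units[0][0], end=units[-1][1],
                repeat_type=arr.repeat_type, unit_coords=units,
                spacer_seqs=list(arr.spacer_seqs) if intact else spacer_seqs,
                repeat_template=arr.repeat_template,
                truncated=not intact,
            ))
    return contigs, new_truth
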