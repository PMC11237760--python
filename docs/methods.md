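# Methods

This note documents the models, parameter choices and known limitations
behind `crisprcensus`. Nothing here states an empirical result that the
test suite or `scripts/acceptance.py` does not itself compute.

## Synthetic corpus

The simulator is the package's ground-truth instrument: it emulates the
kind of data the census targets and emits a truth table for every
planted feature. Defaults describe the study system it was designed
around:

| knob | default | rationale |
|---|---|---|
| background GC | 0.69 | high-GC hosts (myxobacteria-like); spacer and background GC both sit well above 0.6 in such genomes |
| repeat types | C 37 bp, B 36 bp, G 36 bp, E 29 bp | the four repeat families' printed lengths; the E length is not published and 29 bp is this package's choice, sized to hold the 16-nt internal palindrome with margin |
| units per array | 10 | arrays in this clade typically carry tens of spacers (corpus mean ≈ 38 per array; maxima in the hundreds); 10 keeps simulations small while giving the consensus real support |
| per-copy substitution rate | 0.02 | matches the ≥ 95 % repeat conservation observed across the four families |
| spacer length / GC | 34 bp / 0.65 | around the C-type means; per-type specs override (B 35, G 36, E 31) |
| PAM | TTC | the preferred C-type PAM |

Mechanics worth knowing:

* One PCG64 stream (`numpy.random.default_rng(seed)`) drives a whole
  run; equal seeds give byte-identical FASTA and truth tables.
* Spacers are i.i.d. per base at the configured GC, with rejection
  sampling enforcing pairwise ungapped identity < 0.60 — planted arrays
  therefore always clear the detector's tandem-repeat filter, by
  construction.
* Repeat copies are mutated independently; the typing motif (the final
  8 nt for C/B/G, the internal palindrome for E) is protected unless
  `motif_ablated` is set, so typing robustness and motif damage can be
  tested separately.
* Protospacers are planted with an exact Hamming distance and the PAM
  immediately 5′ on the protospacer strand; truth records re-measure
  from the emitted sequence exactly.
* Fragmentation partitions the sequence (no bases duplicated or lost);
  an array cut by a breakpoint is re-emitted per fragment with only the
  units fully inside, flagged truncated.

What the simulator does **not** model: indels (in repeats or anywhere),
repeat age gradients (real arrays diversify away from the *cas*-proximal
end; the single per-copy rate is a simplification), leader sequences,
*cas* genes, real phage sequence composition, and read-level sequencing
error. Passing tests therefore demonstrate correctness of the machinery
on realistic composition and mutation load — not performance on real
assemblies with indel-rich or highly degenerate arrays.

## Array detection

Seed-and-extend, in the spirit of CRT-class detectors:

1. **Seeding.** Exact 9-mers recurring at spacings in
   [min repeat + min spacer, max repeat + max spacer] = [41, 115] bp form
   chains. Words with < 3 distinct bases are ignored (homopolymer
   guard). Chains describing one locus at different k-mer offsets are
   collapsed to the longest.
2. **Boundary extension.** For a chain with anchors at one repeat
   offset, the repeat window is chosen to maximize the summed per-column
   log-likelihood ratio of a conserved-column model (each copy matches
   the column consensus with probability 0.98, else one of the three
   other bases uniformly) against the contig's own base composition
   (floored at 5 % per base). The background term is essential in
   GC-rich sequence: under a uniform null, a mostly-G column just
   outside the repeat looks conserved and boundaries creep outward.
   Constraints: repeat length within [23, 55] and every inter-unit gap
   within [18, 60]. Ties prefer the leftmost start, then the shortest
   repeat.
3. **Unit recovery and repair.** Units whose seed word was destroyed by
   mutation are recovered by scanning outward and inside over-long gaps
   for windows matching the consensus at ≥ the conservation threshold;
   units anchored at the wrong intra-repeat offset (possible when the
   repeat contains an internal near-duplication of the seed word) are
   realigned to their best local fit; divergent terminal units (chance
   seed recurrences just outside the array) are pruned. When a chain
   still yields a low-evidence array, end-trimmed variants of the chain
   are tried and the best candidate wins.
4. **Filters.** ≥ 4 units (3 under `--permissive`), mean per-column
   identity to the majority consensus ≥ 0.80, maximum pairwise spacer
   identity ≤ 0.60. The 4-unit floor approximates the high-evidence tier
   of the standard online detectors whose top evidence level defined the
   original census.

Consensus ties go to the alphabetically first base; conservation is
ungapped (indel-tolerant alignment is out of scope). Arrays whose ends
fall within one maximal period (115 bp) of a contig edge are flagged
truncated. Coordinates are 0-based half-open internally; GFF3 output is
1-based inclusive.

Residual boundary error is dominated by single columns immediately
outside a repeat that happen to be near-unanimous across copies; with
10 copies at 2 % substitution this occurs in roughly 1–2 % of arrays
and is the intrinsic ambiguity of column-wise evidence, not a bug the
thresholds can remove without trading under- for over-extension.

## Repeat typing

Rules are (precedence order, longest terminal motif first):

| label | signature | length range |
|---|---|---|
| B | 3′ `-TTGAGCAC` | 34–38 |
| G | 3′ `-TTGAAGC` | 34–38 |
| C | 3′ `-TTGAAAC` | 35–39 |
| E | internal `CCCCGCNNNNGCGGGG` | 27–33 |

Length ranges are the printed lengths ± 2; the E range is this package's
placeholder (no published length). Orientation is chosen as the strand
whose 3′ end carries a terminal motif with fewest mismatches (≤ 2);
motif-free repeats fall back to the lexicographically smaller strand,
which makes orientation — and therefore typing — a deterministic
involution: `assign_type(revcomp(x)) == assign_type(x)`.

The motif mismatch budget is 0 by default: C and G motifs differ by a
single base, so any tolerance would merge them. Under `--fuzzy` one
mismatch is allowed and a C/G tie is resolved by the discriminating
base. E is matched by its internal palindrome because the family has no
conserved tail. B deliberately covers both of the two closely related
subtype lineages that share the `-TTGAGCAC` repeat.

`hairpin_stem` returns the longest internal inverted repeat (min loop
3 nt; ties to smallest 5′ start) as a proxy for crRNA secondary
structure — no thermodynamic folding. Repeat clustering is
single-linkage under 3′-anchored ungapped identity (the motif end is the
alignment anchor), threshold 0.90.

## Spacer catalog

GC counts G+C over A+C+G+T with N excluded from both numerator and
denominator. Quartiles use linear interpolation (numpy default). Spacer
index 0 is the leader-proximal end when orientation is known, else the
leftmost; this affects reporting only. Deduplication is per input set
(typically per genome) on exact sequence after strand normalization
(lexicographically smaller of sequence/reverse complement).

## Target tracing

The gapless CRISPRTarget default model: +1 match, −1 mismatch, no gaps,
threshold 20. This is the package's single largest simplification — an
indel in a protospacer breaks the hit entirely — and is kept because it
preserves the exact `score = L − 2m` bookkeeping the census statistics
are built on. N counts as a mismatch. Seeding uses one exact shared
word; the word length is `min(11, ⌈(L − m_max)/(m_max + 1)⌉)`, the
pigeonhole bound that guarantees the seeded search reports exactly the
exhaustive scan's hit set (property-tested against `brute_force_trace`
on every build). Hits overlapping a known CRISPR locus of the subject
are flagged `self_hit` but still emitted. Non-redundant targets collapse
on (protospacer sequence, 5′ flank, 3′ flank) keeping the
lowest-mismatch representative.

## PAM inference

The PAM window is positions −3..−1 of the 8-nt 5′ flank (both the
trinucleotide tables and the full 8×4 position matrix are produced).
Strata are nested on mismatch count: perfect (0) ⊆ high-confidence (≤ 3)
⊆ extended (≤ 6) ⊆ all, computed on non-redundant targets; ratios use
the per-stratum target count as denominator. The preferred threshold is
inclusive ≥ 10 %. The degenerate consensus uses perfect targets only
(aged targets accumulate PAM mutations); per position, bases at
frequency ≥ 0.15 are merged into an IUPAC letter. The 0.15 default is
the smallest value that keeps genuinely minor bases (single outlier
observations) out of the code while admitting real second and third
bases of degenerate positions; it is exposed in the API.

## Synteny context

BLAST is replaced by exact Smith–Waterman (Biopython `PairwiseAligner`,
BLOSUM62, gap open 11 / extend 1) — anchor libraries are tens of
proteins, so quadratic alignment is cheap and removes an external binary
dependency. E-values use Karlin–Altschul with ungapped constants
K = 0.041, λ = 0.267, an acknowledged approximation of gapped
statistics; the pident ≥ 70 filter dominates in practice. A coverage
guard (≥ 50 % of the shorter protein aligned) suppresses short spurious
local hits. The flank window is 10 genes per side (the source procedure
names no count) and `present` requires ≥ 3 passing anchors per side —
a conservative floor chosen so that a single conserved housekeeping gene
cannot fake a context.

## Pipeline and report

Percentages round half-up to 2 decimals via `decimal.Decimal`
(locale-independent); totals are always recomputed from their parts.
The traced percentage is counted over unique spacers. All artifacts are
plain text (FASTA wrapped at 70 columns, GFF3, TSV, JSON) and a config
hash plus seed are recorded, so identical config+seed reproduce
identical reports.

## Problem sizes in the validation suite

The test suite and acceptance script validate on: 100 planted arrays
(10 genomes × 10 arrays, 120 kb contigs, all four types) for detector
recall; 200 motif-intact consensus repeats (50 per type) for typing; 50
random spacer/subject pairs (10 kb subjects, planted near-matches) for
tracer equivalence; 100 planted perfect protospacers (60 kb element)
for PAM recovery. These sizes give the statistics real support while a
full run stays in the seconds-to-a-minute range.
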