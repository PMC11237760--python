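"""End-to-end orchestration: simulate → detect → type → spacers → trace → pam → report.

Every stage reads and writes plain files (FASTA/GFF3/TSV/JSON) inside a
run directory, so any stage can be rerun in isolation; a fixed seed and
config give byte-identical outputs.
"""

from __future__ import annotations

import logging
from pathlib import Path

import yaml

from . import io as cio
from .detect import CrisprArray, ScanConfig, detect
from .pam import build_profiles
from .repeats import assign_type
from .report import CensusReport, summary_report
from .simulate import ArraySpec, SimConfig, TruthTable, fragment_assembly, \
    generate_host_genome, generate_mge
from .spacers import array_id_of, dedupe_spacers, extract_spacers, \
    spacer_stats
from .trace import TraceConfig, dedupe_targets, trace_all

logger = logging.getLogger(__name__)


class StageError(RuntimeError):
    """A pipeline stage failed; partial outputs are preserved."""


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError(f"config {path} is not a mapping")
    return cfg


def _sim_config(config: dict, seed: int) -> SimConfig:
    sim = dict(config.get("simulate", {}))
    specs = [ArraySpec(**s) for s in sim.pop("array_specs", [])] or None
    sim.pop("n_genomes", None)
    kwargs = {k: v for k, v in sim.items()
              if k in SimConfig.__dataclass_fields__}
    if specs:
        kwargs["array_specs"] = specs
    kwargs["seed"] = seed
    if "fragmentation" in kwargs:
        kwargs["fragmentation"] = tuple(kwargs["fragmentation"])
    return SimConfig(**kwargs)


def simulate_stage(config: dict, seed: int, outdir: Path) -> tuple[Path, Path | None]:
    """Write a synthetic assembly (+ optional mobile-element db) and truth."""
    sim = config.get("simulate", {})
    n_genomes = int(sim.get("n_genomes", 1))
    cfg = _sim_config(config, seed)
    rng = cfg.rng()
    contigs, truth = [], TruthTable()
    all_spacers: list[str] = []
    for g in range(n_genomes):
        rec, tt = generate_host_genome(cfg, contig_id=f"sim_contig_{g + 1}",
                                       rng=rng)
        n_frag = cfg.fragmentation[0]
        if n_frag > 1:
            frags, tt = fragment_assembly(rec, tt, cfg, rng=rng)
            contigs.extend(frags)
        else:
            contigs.append(rec)
        truth.arrays.extend(tt.arrays)
        truth.protospacers.extend(tt.protospacers)
        for arr in tt.arrays:
            all_spacers.extend(arr.spacer_seqs)
    assembly = outdir / "assembly.fasta"
    cio.write_fasta(contigs, assembly)
    targets = None
    if cfg.n_protospacers > 0 and all_spacers:
        mge, mtruth = generate_mge(cfg, all_spacers, rng=rng)
        targets = outdir / "targets.fasta"
        cio.write_fasta([mge], targets)
        truth.protospacers.extend(mtruth.protospacers)
    truth.to_tsv(outdir / "truth.tsv")
    logger.info("stage=simulate contigs=%d arrays=%d protospacers=%d",
                len(contigs), len(truth.arrays), len(truth.protospacers))
    return assembly, targets


def type_arrays(arrays: list[CrisprArray]) -> dict[str, str]:
    """Type every array from its consensus repeat; sets array orientation."""
    calls = {}
    for arr in arrays:
        call = assign_type(arr.consensus_repeat)
        calls[array_id_of(arr)] = call.label
        if call.label != "U":
            arr.orientation = "-" if call.strand_flipped else "+"
    return calls


def run_pipeline(config: dict | str | Path, outdir: str | Path,
                 seed: int | None = None) -> CensusReport:
    """Run all stages; returns the census report (also written as JSON)."""
    if not isinstance(config, dict):
        config = load_config(config)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0)) if seed is None else int(seed)

    inputs = config.get("inputs", {})
    stage = "simulate"
    try:
        if "assembly" in inputs:
            assembly = Path(inputs["assembly"])
            targets = Path(inputs["targets"]) if "targets" in inputs else None
        else:
            assembly, targets = simulate_stage(config, seed, outdir)

        stage = "detect"
        scan = ScanConfig(**config.get("detect", {}))
        arrays = detect(str(assembly), scan)
        stage = "type"
        calls = type_arrays(arrays)
        cio.arrays_to_gff3(arrays, outdir / "arrays.gff3")
        cio.arrays_to_tsv(arrays, outdir / "arrays.tsv")
        with open(outdir / "types.tsv", "w") as fh:
            fh.write("array_id\tlabel\n")
            for aid, label in sorted(calls.items()):
                fh.write(f"{aid}\t{label}\n")
        logger.info("stage=detect arrays=%d", len(arrays))

        stage = "spacers"
        records = extract_spacers(arrays)
        unique, mult = dedupe_spacers(records)
        cio.spacers_to_fasta(unique, outdir / "spacers.fasta")
        if records:
            spacer_stats(records, calls).to_csv(
                outdir / "spacer_stats.tsv", sep="\t")
        logger.info("stage=spacers total=%d unique=%d", len(records),
                    len(unique))

        hits = []
        profiles = None
        n_nonred = None
        if targets is not None:
            stage = "trace"
            tcfg = TraceConfig(**config.get("trace", {}))
            subjects = {r.id: str(r.seq) for r in cio.read_fasta(targets)}
            spacer_map = {r.spacer_id: r.sequence for r in unique}
            hits = trace_all(spacer_map, subjects, tcfg)
            cio.hits_to_tsv(hits, outdir / "hits.tsv")
            logger.info("stage=trace spacers=%d hits=%d", len(spacer_map),
                        len(hits))

            stage = "pam"
            by_type: dict[str, list] = {}
            type_of_spacer = {r.spacer_id: calls[r.array_id] for r in unique}
            nonred = dedupe_targets(hits)
            n_nonred = len(nonred)
            for h in nonred:
                by_type.setdefault(type_of_spacer[h.spacer_id], []).append(h)
            profiles = {
                label: {name: prof.to_dict()
                        for name, prof in build_profiles(subset).items()}
                for label, subset in sorted(by_type.items())
            }
            import json
            with open(outdir / "pam.json", "w") as fh:
                json.dump(profiles, fh, indent=2, sort_keys=True)
            logger.info("stage=pam nonredundant_targets=%d", n_nonred)

        stage = "report"
        report = summary_report(arrays, calls, records, unique, hits,
                                seed=seed, config=config,
                                pam_profiles=profiles,
                                n_targets_nonredundant=n_nonred)
        report.to_json(outdir / "report.json")
        logger.info("stage=report arrays=%d spacers=%d pct_traced=%s",
                    report.n_arrays_total, report.n_spacers_total,
                    report.pct_traced)
        return report
    except Exception as exc:
        raise StageError(f"stage {stage!r} failed: {exc}") from exc


def dump_config(config: dict, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config, fh, sort_keys=True)
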