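"""Pipeline orchestration: config validation, staged runs, run manifests.

Stages run in dependency order: simulate -> scan -> consensus/assign ->
coexpr -> ea-compare -> survival.  Each stage writes its own outputs into
the report directory plus entries in a JSON run manifest (seed, parameters,
input checksums), so any result file can be traced to the exact inputs that
produced it.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .alu_consensus import (
    build_msa,
    call_consensus,
    collapse_redundancy,
    nj_tree,
    p_distance_matrix,
)
from .io_formats import (
    read_fasta,
    read_repeat_annotations,
    read_tss_bed,
    reverse_complement,
    write_hits,
    write_table,
)
from .promoter_scan import (
    ConfigurationGrammar,
    genome_scan_similar,
    matches_to_frame,
)
from .synthetic_data import (
    ExpressionParams,
    MutationParams,
    SimulationConfig,
    SurvivalParams,
    builtin_alu_library,
    generate_expression_pair,
    generate_genome_with_annotations,
    generate_mutation_sets,
    generate_survival_cohort,
    random_score_table,
)
from .cancer_stats import (
    correlate_by_cancer,
    km_curve_frame,
    ks_two_sample,
    subgroup_survival,
)

logger = logging.getLogger(__name__)

KNOWN_CLASSES = {"SINE/Alu", "LINE/L1", "Low_complexity", "Simple_repeat",
                 "SINE/MIR", "LINE/L2"}

ALL_STAGES = ("simulate", "scan", "consensus", "coexpr", "ea-compare", "survival")


@dataclass
class PipelineConfig:
    """Everything a full run needs; CLI flags override file values."""

    outdir: str = "pprealu_report"
    seed: int = 0
    window_length: int = 2000
    grammar: str = "SINE/Alu,SINE/Alu,Low_complexity,LINE/L1"
    max_gap: int = 500
    motif: str = "TGACCTC"
    identity_threshold: float = 0.95
    genome: str | None = None   # None => simulate
    repeats: str | None = None
    tss: str | None = None
    stages: tuple[str, ...] = ALL_STAGES
    n_genes: int = 50
    n_planted_configs: int = 10
    alu_mutation_rate: float = 0.05

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        raw.update({k: v for k, v in overrides.items() if v is not None})
        if "stages" in raw and not isinstance(raw["stages"], tuple):
            raw["stages"] = tuple(raw["stages"])
        return cls(**raw)


def validate_config(config: PipelineConfig) -> list[str]:
    """Collect every structural error at once; an empty list means valid."""
    errors = []
    if config.max_gap < 0:
        errors.append("max_gap must be >= 0")
    if config.window_length <= 0:
        errors.append("window_length must be positive")
    if not config.motif:
        errors.append("motif must be non-empty")
    if not 0 < config.identity_threshold <= 1:
        errors.append("identity_threshold must be in (0, 1]")
    for term in (t.strip() for t in config.grammar.split(",")):
        if not term:
            errors.append("grammar contains an empty term")
        elif term not in KNOWN_CLASSES:
            errors.append(f"unknown repeat class in grammar: {term!r}")
    for name in ("genome", "repeats", "tss"):
        p = getattr(config, name)
        if p is not None and not Path(p).exists():
            errors.append(f"{name} path does not exist: {p}")
    externals = [getattr(config, n) for n in ("genome", "repeats", "tss")]
    if any(e is not None for e in externals) and not all(e is not None for e in externals):
        errors.append("genome, repeats and tss must be given together (or none, to simulate)")
    for st in config.stages:
        if st not in ALL_STAGES:
            errors.append(f"unknown stage {st!r}")
    return errors


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> Path:
    """Run the configured stages; returns the report directory.

    Raises ``ValueError`` on config errors before any stage runs; a stage
    failure propagates and aborts everything downstream.
    """
    errors = validate_config(config)
    if errors:
        raise ValueError("invalid configuration:\n" + "\n".join(f"  - {e}" for e in errors))
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "tool": "pprealu",
        "version": __version__,
        "seed": config.seed,
        "parameters": dataclasses.asdict(config),
        "inputs": {},
        "outputs": {},
        "started": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }

    sim_cfg = SimulationConfig(
        seed=config.seed,
        n_genes=config.n_genes,
        n_planted_configs=config.n_planted_configs,
        alu_mutation_rate=config.alu_mutation_rate,
        max_gap=min(config.max_gap, 500),
    )
    library = builtin_alu_library()

    if config.genome is None:
        logger.info("[simulate] generating synthetic genome and annotations")
        syn = generate_genome_with_annotations(sim_cfg, library)
        simdir = outdir / "inputs"
        paths = syn.write_outputs(simdir)
        genome_path, repeats_path, tss_path = paths["genome"], paths["repeats"], paths["tss"]
        manifest["outputs"]["planted_truth"] = str(paths["truth"])
    else:
        genome_path, repeats_path, tss_path = (
            Path(config.genome), Path(config.repeats), Path(config.tss)
        )
    for name, p in (("genome", genome_path), ("repeats", repeats_path), ("tss", tss_path)):
        manifest["inputs"][name] = {"path": str(p), "sha256": _sha256(p)}

    genomes = {g.chrom_id: g for g in read_fasta(genome_path)}
    dialect = "rmsk_out" if str(repeats_path).endswith(".out") else "bed"
    repeats = read_repeat_annotations(repeats_path, dialect)
    tss = read_tss_bed(tss_path)

    if "scan" in config.stages:
        logger.info("[scan] scanning %d promoters", len(tss))
        grammar = ConfigurationGrammar.from_string(config.grammar, config.max_gap)
        genes, report, matches, hits = genome_scan_similar(
            genomes, tss, repeats, grammar, config.motif,
            window_length=config.window_length, consensus_library=library,
        )
        write_table(report, outdir / "scan_report.tsv")
        write_table(matches_to_frame(matches), outdir / "matches.tsv")
        write_hits(hits, outdir / "hits.tsv", "tsv")
        write_hits(hits, outdir / "hits.bed", "bed")
        (outdir / "genes.txt").write_text("".join(g + "\n" for g in genes))
        manifest["outputs"]["qualifying_genes"] = genes

    if "consensus" in config.stages:
        logger.info("[consensus] rebuilding subfamily consensi from genomic copies")
        by_subfamily: dict[str, list[str]] = {}
        for r in repeats:
            if r.class_family != "SINE/Alu":
                continue
            s = genomes[r.chrom].seq[r.start:r.end]
            if r.strand == "-":
                s = reverse_complement(s)
            by_subfamily.setdefault(r.name, []).append(s)
        cons_rows = []
        rebuilt = {}
        for name in sorted(by_subfamily):
            copies = collapse_redundancy(by_subfamily[name], config.identity_threshold)
            if len(copies) >= 2:
                res = call_consensus(build_msa(copies))
                rebuilt[name] = res.consensus
            else:
                rebuilt[name] = copies[0]
            cons_rows.append({"subfamily": name, "n_copies": len(by_subfamily[name]),
                              "n_representatives": len(copies),
                              "consensus_length": len(rebuilt[name])})
        write_table(pd.DataFrame(cons_rows), outdir / "consensus_summary.tsv")
        with open(outdir / "consensus.fa", "w") as fh:
            for name, seq in sorted(rebuilt.items()):
                fh.write(f">{name}\n{seq}\n")
        if len(rebuilt) >= 3:
            dm = p_distance_matrix([rebuilt[k] for k in sorted(rebuilt)], sorted(rebuilt))
            (outdir / "subfamilies.nwk").write_text(nj_tree(dm).newick() + "\n")

    if "coexpr" in config.stages:
        logger.info("[coexpr] tumor/control co-expression")
        expr = generate_expression_pair(sim_cfg)
        write_table(expr, outdir / "expression.tsv")
        corr = correlate_by_cancer(expr)
        write_table(corr, outdir / "correlation.tsv")
        manifest["outputs"]["correlation"] = str(outdir / "correlation.tsv")

    if "ea-compare" in config.stages:
        logger.info("[ea-compare] observed vs all-missense score distributions")
        cds = "ATG" + "GCTTGGAAGCTGCGTCCA" * 20 + "TAA"
        table = random_score_table(cds, seed=sim_cfg.seed + 7)
        observed, null = generate_mutation_sets(sim_cfg, cds, table)
        res = ks_two_sample(observed["ea_score"], null["ea_score"])
        write_table(observed, outdir / "mutations_observed.tsv")
        write_table(null, outdir / "mutations_null.tsv")
        write_table(
            pd.DataFrame([{"D": res.D, "p": res.p, "n_obs": res.n_obs, "n_null": res.n_null}]),
            outdir / "ks_result.tsv",
        )

    if "survival" in config.stages:
        logger.info("[survival] median-split Kaplan-Meier with chr3 subgroups")
        cohort = generate_survival_cohort(sim_cfg)
        cohort.to_csv(outdir / "survival_cohort.csv", index=False)
        rows = []
        curves = []
        for flt in ("all", "disomy3", "monosomy3"):
            try:
                res = subgroup_survival(cohort, flt)
            except ValueError as exc:
                logger.warning("survival subgroup %s skipped: %s", flt, exc)
                continue
            rows.append({
                "subgroup": flt, "n_high": res["n_high"], "n_low": res["n_low"],
                "chi_square": res["logrank"].chi_square, "p": res["logrank"].p,
            })
            curves.append(km_curve_frame(res["km_high"], f"{flt}/high"))
            curves.append(km_curve_frame(res["km_low"], f"{flt}/low"))
        write_table(pd.DataFrame(rows), outdir / "survival_summary.tsv")
        write_table(pd.concat(curves, ignore_index=True), outdir / "km_curves.tsv")

    manifest["finished"] = time.strftime("%Y-%m-%dT%H:%M:%S")
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return outdir
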