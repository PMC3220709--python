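"""End-to-end pipeline: profiles -> harvest -> classify -> architecture
-> phylo -> synteny, driven by one YAML config.

All stage outputs and the JSON report are timestamp-free so a rerun with
the same config and seeds is byte-identical; the plain-text log carries
timestamps and is excluded from that contract.
"""

from __future__ import annotations

import json
import time
import traceback
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import architecture as arch_mod
from . import classify as classify_mod
from . import harvest as harvest_mod
from . import phylo as phylo_mod
from . import synteny as synteny_mod
from .classify import TaxonomyMap
from .harvest import SequenceDB
from .msa import read_msa
from .profile import build_profile, write_profile
from .scoring import calibrate


class ConfigurationError(ValueError):
    pass


@dataclass
class PipelineConfig:
    db_fasta: str
    seed_msas: dict[str, str]  # family name -> aligned FASTA/Stockholm path
    harvest_family: str  # which seed profile scans the database
    output_dir: str
    taxonomy_tsv: str | None = None
    gene_tables_tsv: str | None = None
    tree_msa: str | None = None
    subclade_seeds: list[str] = field(default_factory=list)
    n_family: str | None = None  # architecture stage profile names
    c_family: str | None = None
    evalue_cutoff: float = 0.01
    min_support: float = 70.0
    window_span: int = 7
    min_distinct: int = 2
    bootstrap_B: int = 100
    calibration_samples: int = 300
    calibration_len: int = 200
    calibration_seed: int = 0
    bootstrap_seed: int = 0
    max_overlap_frac: float = 0.2
    gap_threshold: float = 0.5
    pseudocount_weight: float = 1.0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        try:
            return cls(**raw)
        except TypeError as exc:
            raise ConfigurationError(str(exc)) from exc

    def validate(self) -> None:
        required = {"db_fasta": self.db_fasta, **{
            f"seed_msas[{k}]": v for k, v in self.seed_msas.items()
        }}
        for opt in ("taxonomy_tsv", "gene_tables_tsv", "tree_msa"):
            val = getattr(self, opt)
            if val is not None:
                required[opt] = val
        missing = [f"{k}: {v}" for k, v in required.items() if not Path(v).exists()]
        if missing:
            raise ConfigurationError("missing input files: " + "; ".join(missing))
        if self.harvest_family not in self.seed_msas:
            raise ConfigurationError(
                f"harvest_family {self.harvest_family!r} not among seed MSAs"
            )
        for fam in (self.n_family, self.c_family):
            if fam is not None and fam not in self.seed_msas:
                raise ConfigurationError(f"architecture family {fam!r} not among seed MSAs")
        if not (0 < self.evalue_cutoff):
            raise ConfigurationError("evalue_cutoff must be positive")
        if self.window_span < 2 or self.min_distinct < 2:
            raise ConfigurationError("window_span and min_distinct must be >= 2")
        if self.bootstrap_B < 0:
            raise ConfigurationError("bootstrap_B must be >= 0")


class _Log:
    def __init__(self, path: Path):
        self.path = path
        self.lines: list[str] = []

    def write(self, msg: str) -> None:
        self.lines.append(f"[{time.strftime('%Y-%m-%d %H:%M:%S')}] {msg}")
        self.path.write_text("\n".join(self.lines) + "\n")


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all configured stages, returning the machine-readable report.

    The report (also written to ``<output_dir>/report.json``) contains a
    section per stage; a failed stage is recorded with its error and
    later stages that depend on it are skipped.
    """
    config.validate()
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    log = _Log(outdir / "pipeline.log")
    report: dict = {
        "parameters": {
            "evalue_cutoff": config.evalue_cutoff,
            "min_support": config.min_support,
            "window_span": config.window_span,
            "min_distinct": config.min_distinct,
            "bootstrap_B": config.bootstrap_B,
            "calibration_samples": config.calibration_samples,
            "calibration_len": config.calibration_len,
            "seeds": {
                "calibration": config.calibration_seed,
                "bootstrap": config.bootstrap_seed,
            },
        },
        "stages": {},
    }

    def run_stage(name: str, fn) -> bool:
        log.write(f"stage {name}: start")
        try:
            report["stages"][name] = fn()
            log.write(f"stage {name}: done")
            return True
        except Exception as exc:  # noqa: BLE001 - stage isolation
            report["stages"][name] = {"failed": True, "error": str(exc)}
            log.write(f"stage {name}: FAILED: {exc}\n{traceback.format_exc()}")
            return False

    profiles: dict[str, object] = {}

    def stage_profiles() -> dict:
        profdir = outdir / "profiles"
        profdir.mkdir(exist_ok=True)
        section = {}
        for fam, msa_path in sorted(config.seed_msas.items()):
            prof = build_profile(
                read_msa(msa_path),
                name=fam,
                gap_threshold=config.gap_threshold,
                pseudocount_weight=config.pseudocount_weight,
            )
            calib = calibrate(
                prof,
                n_samples=config.calibration_samples,
                sample_len=config.calibration_len,
                seed=config.calibration_seed,
            )
            prof = prof.with_calibration(calib)
            write_profile(prof, profdir / f"{fam}.hmm")
            profiles[fam] = prof
            section[fam] = {
                "n_match": prof.n_match,
                "calibration": {"mu": calib.mu, "lam": calib.lam},
            }
        return section

    harvest_result: dict = {}

    def stage_harvest() -> dict:
        db = SequenceDB.from_fasta(config.db_fasta)
        result = harvest_mod.harvest_domains(
            db, profiles[config.harvest_family], config.evalue_cutoff
        )
        harvest_mod.write_hits_tsv(result.hits, outdir / "harvest_hits.tsv")
        harvest_mod.write_domains_fasta(result.domains, outdir / "harvest_domains.fasta")
        harvest_result["domains"] = result.domains
        harvest_result["db"] = db
        return {
            "profile": config.harvest_family,
            "db_size": result.db_size,
            "n_hits": len(result.hits),
        }

    def stage_classify() -> dict:
        domains = harvest_result["domains"]
        assignments = classify_mod.classify_competitive(
            domains, list(profiles.values()), config.evalue_cutoff
        )
        classify_mod.write_assignments_tsv(assignments, outdir / "assignments.tsv")
        taxmap = (
            TaxonomyMap.from_tsv(config.taxonomy_tsv)
            if config.taxonomy_tsv
            else TaxonomyMap()
        )
        tp = classify_mod.build_taxon_profile(assignments, taxmap)
        classify_mod.write_taxon_profile_tsv(tp, outdir / "taxon_matrix.tsv")
        per_family = {
            fam: int(tp.counts[fam].sum()) for fam in tp.counts.columns
        }
        return {
            "n_domains": len(domains),
            "per_family": per_family,
            "unclassified": tp.unclassified,
            "unknown_taxon": tp.unknown_taxon,
        }

    def stage_architecture() -> dict:
        db: SequenceDB = harvest_result["db"]
        seqs = [(sid, seq) for sid, _, seq in db.records]
        calls = arch_mod.detect_architectures(
            seqs,
            profiles[config.n_family],
            profiles[config.c_family],
            config.evalue_cutoff,
            max_overlap_frac=config.max_overlap_frac,
        )
        arch_mod.write_calls_tsv(calls, outdir / "architecture_calls.tsv")
        taxmap = (
            TaxonomyMap.from_tsv(config.taxonomy_tsv)
            if config.taxonomy_tsv
            else TaxonomyMap()
        )
        summary = arch_mod.summarize_architectures(calls, taxmap)
        summary.to_csv(outdir / "architecture_summary.tsv", sep="\t")
        return {lbl: int(summary.loc[lbl].sum()) for lbl in summary.index}

    def stage_phylo() -> dict:
        msa = read_msa(config.tree_msa)
        tree = phylo_mod.bootstrap_supports(
            msa, B=config.bootstrap_B, seed=config.bootstrap_seed
        )
        phylo_mod.write_newick(tree, outdir / "tree.nwk")
        section: dict = {"n_leaves": len(tree.leaf_labels), "B": config.bootstrap_B}
        if config.subclade_seeds:
            sc = phylo_mod.extract_subclade(
                tree, set(config.subclade_seeds), config.min_support
            )
            phylo_mod.write_subclades_tsv([sc], outdir / "subclades.tsv")
            section["subclade"] = {
                "n_leaves": len(sc.leaves),
                "support": sc.support,
                "low_support": sc.low_support,
            }
        return section

    def stage_synteny() -> dict:
        tables = synteny_mod.read_gene_table_tsv(config.gene_tables_tsv)
        all_calls = []
        for t in tables:
            all_calls.extend(
                synteny_mod.synteny_scan(t, config.window_span, config.min_distinct)
            )
        synteny_mod.write_calls_tsv(all_calls, outdir / "synteny_calls.tsv")
        n_with, n_total, frac = synteny_mod.genome_fraction(
            tables, config.window_span, config.min_distinct
        )
        return {
            "n_calls": len(all_calls),
            "genomes_with_call": n_with,
            "genomes_total": n_total,
            "fraction": frac,
        }

    ok = run_stage("profiles", stage_profiles)
    if ok:
        ok_harvest = run_stage("harvest", stage_harvest)
        if ok_harvest:
            run_stage("classify", stage_classify)
        if config.n_family and config.c_family and ok_harvest:
            run_stage("architecture", stage_architecture)
    if config.tree_msa:
        run_stage("phylo", stage_phylo)
    if config.gene_tables_tsv:
        run_stage("synteny", stage_synteny)

    (outdir / "report.json").write_text(
        json.dumps(report, indent=2, sort_keys=True) + "\n"
    )
    return report
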