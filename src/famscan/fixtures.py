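"""Write a complete on-disk synthetic fixture runnable by the pipeline."""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import yaml

from .classify import TAXON_GROUPS
from .simulate import (
    SyntheticSpec,
    family_msa_rows,
    make_families,
    make_fusions,
    make_genomes,
    mutate,
)
from .synteny import write_gene_table_tsv


def _write_fasta(path: Path, records: list[tuple[str, str]]) -> None:
    with open(path, "w") as fh:
        for sid, seq in records:
            fh.write(f">{sid}\n{seq}\n")


def write_fixture(
    outdir: Path,
    seed: int = 0,
    n_families: int = 5,
    n_per_family: int = 20,
    divergence: float = 0.05,
    n_fusions: int = 10,
    msa_rows: int = 8,
) -> Path:
    """Generate all pipeline inputs plus a ready config; returns the config path.

    Deterministic in (arguments, seed): reruns produce identical bytes.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    spec = SyntheticSpec(
        seed=seed,
        n_families=n_families,
        n_per_family=n_per_family,
        divergence=divergence,
    )
    fam = make_families(spec)
    rng = np.random.default_rng(seed + 1)

    msa_dir = outdir / "seed_msas"
    msa_dir.mkdir(exist_ok=True)
    seed_msas = {}
    for prof in fam.profiles:
        rows = family_msa_rows(prof, msa_rows, divergence, rng)
        path = msa_dir / f"{prof.name}.fasta"
        _write_fasta(path, [(f"{prof.name}_seed{i}", r) for i, r in enumerate(rows)])
        seed_msas[prof.name] = str(path)

    records = list(fam.sequences)
    n_fam_name = c_fam_name = None
    if len(fam.profiles) >= 2 and n_fusions > 0:
        n_fam_name, c_fam_name = fam.profiles[0].name, fam.profiles[1].name
        fusions, fusion_truth = make_fusions(
            fam.profiles[0],
            fam.profiles[1],
            linker_len=spec.linker_len,
            n=n_fusions,
            seed=seed + 2,
            divergence=divergence,
        )
        records.extend(fusions)
        fusion_truth.to_csv(outdir / "fusion_truth.tsv", sep="\t", index=False)
    db_path = outdir / "db.fasta"
    _write_fasta(db_path, records)
    fam.truth.to_csv(outdir / "family_truth.tsv", sep="\t", index=False)

    tax_path = outdir / "taxonomy.tsv"
    with open(tax_path, "w") as fh:
        for i, (sid, _) in enumerate(records):
            fh.write(f"{sid}\t{TAXON_GROUPS[i % len(TAXON_GROUPS)]}\n")

    tables, genome_truth = make_genomes(spec)
    genes_path = outdir / "genes.tsv"
    write_gene_table_tsv(tables, genes_path)
    genome_truth.to_csv(outdir / "genome_truth.tsv", sep="\t", index=False)

    # two-block alignment for the tree stage: one family at low divergence
    # against a heavily diverged copy of its consensus
    prof = fam.profiles[0]
    consensus = prof.consensus()
    block_a = family_msa_rows(prof, 4, divergence, rng)
    block_b = [mutate(consensus, 0.6, rng) for _ in range(4)]
    block_b = [mutate(block_b[0], divergence, rng) for _ in range(4)]
    tree_msa_path = outdir / "tree_msa.fasta"
    _write_fasta(
        tree_msa_path,
        [(f"blockA_{i}", r) for i, r in enumerate(block_a)]
        + [(f"blockB_{i}", r) for i, r in enumerate(block_b)],
    )

    config = {
        "db_fasta": str(db_path),
        "seed_msas": seed_msas,
        "harvest_family": fam.profiles[0].name,
        "taxonomy_tsv": str(tax_path),
        "gene_tables_tsv": str(genes_path),
        "tree_msa": str(tree_msa_path),
        "subclade_seeds": ["blockA_0", "blockA_1"],
        "n_family": n_fam_name,
        "c_family": c_fam_name,
        "output_dir": str(outdir / "out"),
        "calibration_samples": 200,
        "calibration_len": 150,
        "calibration_seed": seed,
        "bootstrap_seed": seed,
        "bootstrap_B": 50,
    }
    config_path = outdir / "config.yaml"
    config_path.write_text(yaml.safe_dump(config, sort_keys=True))

    manifest = {
        "spec": dataclasses.asdict(spec),
        "seed": seed,
        "n_fusions": n_fusions,
        "msa_rows": msa_rows,
    }
    (outdir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n"
    )
    return config_path
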