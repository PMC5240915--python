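from __future__ import annotations

from pathlib import Path

import numpy as np
import pytest

from episub.cli_report import RunConfig, run_pipeline
from episub.synthetic import (
    PlantedEpitope,
    SimulationConfig,
    generate_dataset,
    write_fasta,
    write_peptide_table,
)

EPITOPE = (36, 43)


def planted_config(seed: int, **overrides) -> SimulationConfig:
    """Standard planted-epitope design: 80-mer protein, one 8-residue
    epitope, effect 0.1, CV 0.1, 5 native copies, full coverage."""
    defaults = dict(
        protein_length=80,
        epitopes=(PlantedEpitope(*EPITOPE, effect=0.1),),
        noise_cv=0.1,
        native_copies=5,
        seed=seed,
    )
    defaults.update(overrides)
    return SimulationConfig(**defaults)


def run_synthetic(tmp_path: Path, seed: int, scale: float = 1.0,
                  alpha: float = 1e-4, **sim_overrides):
    """Generate a planted dataset, optionally rescale intensities, and run
    the full pipeline.  Returns (dataset, PipelineResult, outdir)."""
    config = planted_config(seed, **sim_overrides)
    dataset = generate_dataset(config)
    table = dataset.peptides
    if scale != 1.0:
        table = table.assign(intensity=table["intensity"] * scale)
    fasta = tmp_path / f"protein_{seed}_{scale}.fasta"
    peptides = tmp_path / f"peptides_{seed}_{scale}.tsv"
    outdir = tmp_path / f"out_{seed}_{scale}"
    write_fasta(dataset.protein, fasta)
    write_peptide_table(table, peptides)
    result = run_pipeline(
        RunConfig(fasta=fasta, peptides=peptides, outdir=outdir,
                  alpha=alpha, seed=seed)
    )
    return dataset, result, outdir


@pytest.fixture(scope="session")
def planted_runs(tmp_path_factory):
    """Twenty seeded planted-epitope pipeline runs (shared: they back the
    recovery, logo-normalization and determinism checks)."""
    tmp = tmp_path_factory.mktemp("planted")
    runs = []
    for seed in range(1, 21):
        runs.append(run_synthetic(tmp, seed))
    return runs


def null_pssm_values(rng: np.random.Generator, length: int = 15, cv: float = 0.1):
    """A complete-scan PSSM of i.i.d. multiplicative noise around 1
    (mean-one log-normal), 19 present cells per column."""
    sigma = np.sqrt(np.log(1.0 + cv * cv))
    values = np.exp(sigma * rng.standard_normal((20, length)) - 0.5 * sigma**2)
    return values
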