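"""Shared fixtures: one synthetic study per session, plus small helpers."""

import random

import pytest

from brocmir import pipeline as pl
from brocmir import synthdata as sd


@pytest.fixture(scope="session")
def study(tmp_path_factory):
    """Default synthetic study (seed 42), generated once per session."""
    outdir = tmp_path_factory.mktemp("study42")
    config = sd.SimulationConfig(seed=42)
    genome, features, reference, truth = sd.simulate_reference(config)
    control, treated = sd.simulate_libraries(truth, config, genome)
    transcripts = sd.simulate_transcripts(truth, config)
    sd.write_fasta(genome, outdir / "genome.fa")
    sd.write_gff3(features, outdir / "annotation.gff3")
    sd.write_reference_fasta(reference, outdir / "reference_mirnas.fa")
    sd.write_fastq(control, outdir / "control.fastq")
    sd.write_fastq(treated, outdir / "treated.fastq")
    sd.write_fasta(transcripts, outdir / "transcripts.fa")
    return {
        "dir": outdir, "config": config, "genome": genome,
        "features": features, "reference": reference, "truth": truth,
        "control": control, "treated": treated, "transcripts": transcripts,
    }


@pytest.fixture(scope="session")
def run_config(study):
    d = study["dir"]
    return pl.RunConfig(
        control_fastq=str(d / "control.fastq"),
        treated_fastq=str(d / "treated.fastq"),
        genome_fasta=str(d / "genome.fa"),
        annotation_gff3=str(d / "annotation.gff3"),
        reference_fasta=str(d / "reference_mirnas.fa"),
        transcripts_fasta=str(d / "transcripts.fa"),
        outdir=str(d / "run"), seed=42)


@pytest.fixture(scope="session")
def pipeline_state(study, run_config):
    """One full pipeline run on the default study, with recovery scores."""
    import json
    summary = pl.run_all(run_config, truth=study["truth"])
    return summary


def random_dna(rng: random.Random, n: int) -> str:
    return "".join(rng.choice("ACGT") for _ in range(n))
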