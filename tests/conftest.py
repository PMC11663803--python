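"""Shared fixtures: a small noise-free synthetic dataset and one pipeline run."""

from __future__ import annotations

import pytest

from diphase import pipeline, simulate
from diphase.fastaio import read_fasta


FIXTURE_PARAMS = dict(length=400_000, n_contigs=2, het_rate=0.002,
                      block_len_mean=60_000, switch_count=0, pairs_n=15_000,
                      cis_trans_ratio=4.0, noise=False, seed=7,
                      insert_range=(1000, 60_000))


@pytest.fixture(scope="session")
def fixture_dir(tmp_path_factory):
    out = tmp_path_factory.mktemp("fixture")
    simulate.write_fixture(out, **FIXTURE_PARAMS)
    return out


@pytest.fixture(scope="session")
def pipeline_config(fixture_dir, tmp_path_factory):
    out = tmp_path_factory.mktemp("run")
    return dict(primary=str(fixture_dir / "primary.fasta"),
                alternate=str(fixture_dir / "alternate.fasta"),
                paf=str(fixture_dir / "aln.paf"),
                primary_vcf=str(fixture_dir / "primary.vcf"),
                alternate_vcf=str(fixture_dir / "alternate.vcf"),
                hic_sam=str(fixture_dir / "hic.sam"),
                out_dir=str(out), seed=3)


@pytest.fixture(scope="session")
def pipeline_report(pipeline_config):
    return pipeline.run_pipeline(pipeline_config)


@pytest.fixture(scope="session")
def truth(fixture_dir):
    import json
    with open(fixture_dir / "truth.json") as fh:
        payload = json.load(fh)
    return simulate.TruthSet.from_json(
        payload,
        read_fasta(fixture_dir / "truth_hap_a.fasta"),
        read_fasta(fixture_dir / "truth_hap_b.fasta"))
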