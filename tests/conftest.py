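import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # makes oracle.py importable

from allelesplice.alignment_io import SplicedAlignment
from allelesplice.pipeline import RunConfig, run_pipeline
from allelesplice.synthetic_data import SimConfig, simulate


def make_aln(
    est_id="est1",
    chrom="chr1",
    strand="+",
    blocks=((100, 200), (300, 400)),
    coverage=1.0,
    identity=1.0,
    **kw,
):
    return SplicedAlignment(
        est_id=est_id,
        chrom=chrom,
        strand=strand,
        blocks=tuple(tuple(b) for b in blocks),
        coverage=coverage,
        identity=identity,
        **kw,
    )


@pytest.fixture(scope="session")
def sim_small(tmp_path_factory):
    """A 40-gene, error-free simulation shared across pipeline-level tests."""
    out = tmp_path_factory.mktemp("sim_small")
    cfg = SimConfig(n_genes=40, seed=101, est_error_rate=0.0)
    return simulate(cfg, out_dir=str(out))


@pytest.fixture(scope="session")
def pipeline_small(sim_small, tmp_path_factory):
    out = tmp_path_factory.mktemp("pipe_small")
    cfg = RunConfig(
        alignments=sim_small.paths["alignments"],
        genome=sim_small.paths["genome"],
        est_fasta=sim_small.paths["ests"],
        gene_models=sim_small.paths["gene_models"],
        out_dir=str(out),
    )
    return run_pipeline(cfg)
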