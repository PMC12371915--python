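import numpy as np
import pytest

from amplimeth.calling import assign_reads, call_methylation
from amplimeth.synthetic import make_fixture

TINY_SEED = 7
PAPER_SEED = 3


@pytest.fixture(scope="session")
def tiny_run(tmp_path_factory):
    """Tiny fixture with reads on disk, assignments and called matrix."""
    out = tmp_path_factory.mktemp("tiny")
    fx = make_fixture("tiny", TINY_SEED, out_dir=out, depth=120)
    assignments = assign_reads(fx.reads.fastq_paths, fx.panel)
    matrix = call_methylation(assignments, fx.panel)
    return fx, assignments, matrix


@pytest.fixture(scope="session")
def paper_fixture():
    """paper_like cohort truth (no reads; statistics-level studies)."""
    return make_fixture("paper_like", PAPER_SEED)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
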