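import numpy as np
import pytest

import mnrseq as m


@pytest.fixture(scope="session")
def study_design():
    """The study's 56-sample design: 8+8 at 90/165 dG, 6+6 at 120/140 dG."""
    return m.mnr_study_design()


@pytest.fixture(scope="session")
def small_design():
    """A reduced 24-sample version of the same layout, for fast unit tests."""
    return m.mnr_study_design(group_sizes={90: 3, 120: 3, 140: 3, 165: 3})


@pytest.fixture
def tiny_matrix():
    return m.TranscriptCountMatrix(
        transcript_ids=["T1", "T2", "T3"],
        gene_symbols=["GA", "GA", "GB"],
        sample_ids=["s1", "s2"],
        counts=np.array([[5, 0], [2, 7], [0, 3]]),
    )


@pytest.fixture(scope="session")
def default_sim():
    """One seeded draw at the default study conditions (signals included)."""
    spec = m.SimulationSpec(n_genes=400, seed=11)
    return m.simulate_counts(spec)


@pytest.fixture(scope="session")
def null_sim():
    """A no-signal draw at the default study conditions."""
    spec = m.SimulationSpec(n_genes=400, frac_de=0.0, frac_splice=0.0, seed=12)
    return m.simulate_counts(spec)
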