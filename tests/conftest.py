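import pytest

from indexswap.index_sets import IndexConstraints, design_index_set
from indexswap.simulate import SimulationConfig, mixture_halves_organisms


@pytest.fixture(scope="session")
def sheet6():
    """A 6-sample non-redundant sheet (the Fig-5b-style pool size)."""
    return design_index_set(6, IndexConstraints(), seed=101)


@pytest.fixture(scope="session")
def sheet24():
    """A 24-sample sheet for the two-organism mixture design."""
    return design_index_set(24, IndexConstraints(), seed=202)


@pytest.fixture(scope="session")
def organisms24(sheet24):
    return mixture_halves_organisms(sheet24)


def make_config(sheet, n_reads, seed=0, **kw):
    """Noise-free baseline config; tests opt into each noise source."""
    defaults = dict(
        p_swap_i7=0.0,
        p_swap_i5=0.0,
        index_error_rate=0.0,
        swap_length_coeff=0.0,
        swap_gc_coeff=0.0,
    )
    defaults.update(kw)
    return SimulationConfig(
        samplesheet=sheet, n_reads=n_reads, seed=seed, **defaults
    )
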