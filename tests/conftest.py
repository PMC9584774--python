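import numpy as np
import pytest

from grmhor import HORSimParams, make_monomer_consensuses
from grmhor.synthetic import simulate_genome_with_cset


@pytest.fixture(scope="session")
def small_params():
    """Scaled-down simulation regime for fast unit tests: same divergence
    structure, shorter monomers and fewer copies."""
    # length spread mirrors the real regime's ~4% relative spread; a larger
    # spread would make the +-2-point divergence band unreachable because the
    # deletion component alone would dominate
    return HORSimParams(
        monomer_lengths=(325, 318, 311),
        array_sizes=(6, 4, 3),
        inter_array_gap=800,
        flank_length=1500,
        seed=7,
    )


@pytest.fixture(scope="session")
def small_sim(small_params):
    """(consensus set, genome, truth) for the scaled-down regime."""
    rng = np.random.default_rng(small_params.seed)
    cset = make_monomer_consensuses(small_params, rng)
    genome, truth = simulate_genome_with_cset(cset, small_params, rng)
    return cset, genome, truth


@pytest.fixture(scope="session")
def default_sim():
    """(consensus set, genome, truth) at the full default regime:
    ~1.6-kb monomers at ~18% mutual divergence, four arrays of
    19/13/11/7 HOR copies at 0.8% per-copy substitutions."""
    params = HORSimParams(seed=1)
    rng = np.random.default_rng(params.seed)
    cset = make_monomer_consensuses(params, rng)
    genome, truth = simulate_genome_with_cset(cset, params, rng)
    return params, cset, genome, truth
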