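import numpy as np
import pytest

from conformoscope.mutagenesis import Q5HQ64_REGISTRY, Template
from conformoscope.synthetic import EnsembleConfig, generate_ensemble

H3_G_POSITIONS = (127, 133, 138, 141)


@pytest.fixture(scope="session")
def truth():
    """Default noiseless rocking-bundle ensemble with ground truth."""
    return generate_ensemble(EnsembleConfig())


@pytest.fixture(scope="session")
def noisy_truth():
    """30 conformers at sigma = 0.5 A with uniform transition coordinates."""
    rng = np.random.default_rng(7)
    ts = tuple(np.round(rng.uniform(0, 1, 30), 3))
    return generate_ensemble(EnsembleConfig(t_values=ts, noise_sigma=0.5, seed=11))


@pytest.fixture(scope="session")
def carrier_template():
    """Synthetic carrier template matching the Q5HQ64 registry numbering.

    The sequence is a stand-in (the real accession is not bundled): it
    carries the registry's wild-type letters at every synapomorphic site
    and non-glycine residues at the four h3 outgroup-glycine positions.
    """
    seq = ["L"] * 460
    for site in Q5HQ64_REGISTRY.sites:
        seq[site.position - 1] = site.wt_aa
    for pos in H3_G_POSITIONS:
        seq[pos - 1] = "S"
    template = Template("Q5HQ64-like", "".join(seq))
    aliases = Q5HQ64_REGISTRY.alias_table(h3_outgroup_g_positions=H3_G_POSITIONS)
    return template, aliases
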