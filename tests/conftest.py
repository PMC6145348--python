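import numpy as np
import pytest

from lakeredox.reaction_network import default_network
from lakeredox.synthetic import default_scenario, make_community


@pytest.fixture(scope="session")
def network():
    return default_network()


@pytest.fixture(scope="session")
def baseline_result():
    """One default-season run shared by read-only tests."""
    return default_scenario().run()


@pytest.fixture(scope="session")
def community():
    return make_community(seed=0)


@pytest.fixture(scope="session")
def community_match_inputs(community):
    """Dual-L1 matrices and control-trained tolerances for matching."""
    from lakeredox.community import (
        AbundanceMatrix,
        bin_abundance_table,
        combined_distance,
        dual_l1_normalize,
        taxonomy_fraction,
        train_tolerance,
    )

    amp = dual_l1_normalize(community.otu_amplicon)
    met = dual_l1_normalize(community.otu_metagenomic)
    mags = dual_l1_normalize(
        AbundanceMatrix(
            table=bin_abundance_table(
                community.contigs, community.sample_ids, community.library_reads
            )
        )
    )
    ta, tm = [], []
    for otu, mag in community.control_pairs:
        f = taxonomy_fraction(community.taxonomies[otu], community.taxonomies[mag])
        ta.append(combined_distance(amp.row(otu), mags.row(mag), f))
        tm.append(combined_distance(met.row(otu), mags.row(mag), f))
    return amp, met, mags, train_tolerance(ta), train_tolerance(tm)
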