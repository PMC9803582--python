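import numpy as np
import pytest

import mtpnet as m


@pytest.fixture
def toy_net() -> m.MTPNetwork:
    """Small hand-built MTP network: 2 miRNAs, 3 targets, 2 pathways."""
    return m.MTPNetwork.from_triples(
        [
            ("m1", "MT", "g1"),
            ("m1", "MT", "g2"),
            ("m2", "MT", "g2"),
            ("m2", "MT", "g3"),
            ("g1", "TT", "g2"),
            ("g2", "TT", "g3"),
            ("g1", "TP", "p1"),
            ("g2", "TP", "p1"),
            ("g3", "TP", "p2"),
        ]
    )


@pytest.fixture
def synthetic_net():
    """Planted-community MTP network used across modules (seed 7)."""
    net, t_labels, p_labels, truth = m.simulate_mtp(seed=7)
    return net, t_labels, p_labels, truth


@pytest.fixture
def small_expr():
    expr, truth = m.simulate_expression(
        n_case=20, n_control=20, n_mirna=40, n_modules=4, seed=11
    )
    return expr, truth
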