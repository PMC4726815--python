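"""Shared independent oracles for the test suite."""

import numpy as np

from amparcycle.dynamics import evaluate_rate


def naive_rhs(net, p, y):
    """Brute-force derivative oracle: loop over reactions, evaluate each flux
    with the scalar rate evaluator, accumulate stoichiometry."""
    amounts = dict(zip(net.species.names, y))
    dy = np.zeros(len(net.species))
    idx = net.species.index
    for r in net.reactions:
        f = evaluate_rate(r, amounts, p)
        for name in r.reactants:
            dy[idx(name)] -= f
        for name in r.products:
            dy[idx(name)] += f
    return dy
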