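"""Independent oracle implementations used by multiple test modules."""

import numpy as np

from cphylo.dec import branch_probability, cladogenesis_table


def brute_force_likelihood(tree, tip_ranges, hypothesis, d, e, space, time_scale=1.0):
    """Independent oracle: explicit enumeration over root states,
    cladogenetic scenarios, and per-branch state transitions."""
    ages = {n: a / time_scale for n, a in tree.node_ages().items()}

    def transition(t_start, t_end):
        return branch_probability(space, hypothesis, d, e, t_start, t_end)

    def below(node, state):
        """P(data below node | node in `state` just before splitting)."""
        if node.is_leaf():
            raise AssertionError("below() called on a leaf")
        total = 0.0
        for left_state, right_state, p in cladogenesis_table(state):
            term = p
            for child, child_state in zip(node.child_nodes(), (left_state, right_state)):
                P = transition(ages[node], ages[child])
                if child.is_leaf():
                    term *= P[space.state_index(child_state), space.state_index(tip_ranges[child.taxon.label])]
                else:
                    inner = 0.0
                    for s in space.living_states:
                        inner += P[space.state_index(child_state), space.state_index(s)] * below(child, s)
                    term *= inner
            total += term
        return total

    root = tree.tree.seed_node
    lik = np.mean([below(root, s) for s in space.living_states])
    return -np.log(lik)
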