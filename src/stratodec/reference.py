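"""Reference likelihood by exhaustive enumeration.

Sums the probability of the tip data over every joint assignment of
cladogenetic events to internal nodes (each event fixes the node's
ancestor state and both daughter states), with branch transition
probabilities taken from directly composed matrix exponentials.  This is
exponential in the number of internal nodes and exists purely as a slow,
transparent cross-check of the pruning implementation on tiny problems
(a handful of tips and areas).
"""

from __future__ import annotations

from itertools import product

import numpy as np
import scipy.linalg

from .geography import Geography, build_state_space, stratum_state_mask
from .models import ModelSpec, build_clado_table, build_generator
from .tree_io import TimeTree

__all__ = ["enumeration_loglik"]


def _branch_matrix(child_age, parent_age, geography, Qs, space):
    """P(child state | parent state) composed segment by segment, with
    disallowed states zeroed on entry into each older stratum."""
    cuts = [child_age] + geography.boundaries_between(child_age, parent_age) + [parent_age]
    P = np.eye(len(space))
    prev = None
    for lo, hi in zip(cuts[:-1], cuts[1:]):
        if hi <= lo:
            continue
        s_idx = geography.stratum_index_at((lo + hi) / 2.0)
        if prev is not None and s_idx != prev:
            mask = np.array(stratum_state_mask(space, geography.strata[s_idx]), dtype=float)
            P = mask[:, None] * P
        P = scipy.linalg.expm(Qs[s_idx] * (hi - lo)) @ P
        prev = s_idx
    return P


def enumeration_loglik(
    tree: TimeTree,
    tip_ranges: dict[str, int],
    spec: ModelSpec,
    geography: Geography,
    max_range_size: int | None = None,
) -> float:
    """Log-likelihood by explicit summation over joint event assignments.

    Only feasible for trees with a few internal nodes; intended for
    validating the pruning algorithm, never for real data.
    """
    space = build_state_space(geography.n_areas, max_range_size)
    Qs = [build_generator(space, geography, s, spec.d, spec.e) for s in geography.strata]
    tables = [
        build_clado_table(space, spec.family, spec.plus_j, spec.j, s) for s in geography.strata
    ]
    # per internal node: list of (anc, left, right, prob)
    internal = tree.internal_ids
    node_events = {}
    for n in internal:
        t = tables[geography.stratum_index_at(tree.ages[n])]
        node_events[n] = list(zip(t.anc.tolist(), t.left.tolist(), t.right.tolist(), t.prob.tolist()))
    branch_P = {
        i: _branch_matrix(tree.ages[i], tree.ages[tree.parent[i]], geography, Qs, space)
        for i in range(tree.n_nodes - 1)
    }
    prior = np.array(
        stratum_state_mask(space, geography.stratum_at(tree.root_age)), dtype=float
    )
    prior[0] = 0.0
    prior /= prior.sum()
    tip_state = {i: space.index(tip_ranges[tree.labels[i]]) for i in tree.tip_ids}

    total = 0.0
    for combo in product(*(node_events[n] for n in internal)):
        ev = dict(zip(internal, combo))
        p = prior[ev[tree.root][0]]
        if p == 0.0:
            continue
        for n in internal:
            anc, left, right, prob = ev[n]
            p *= prob
            for side, child in zip((left, right), tree.children[n]):
                target = tip_state[child] if tree.children[child] is None else ev[child][0]
                p *= branch_P[child][side, target]
            if p == 0.0:
                break
        total += p
    if total <= 0.0:
        return -np.inf
    return float(np.log(total))
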