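"""Independent brute-force oracles used by the test suite.

Deliberately naive: a truncated-series matrix exponential and full
enumeration over internal-node states.  They share no code with the
pruning/eigendecomposition machinery they validate.
"""

from itertools import product

import numpy as np

from karyoevol.chromnum import build_rate_matrix


def series_expm(Q: np.ndarray, t: float, terms: int = 80) -> np.ndarray:
    """exp(Qt) by the plain Taylor series (fine for the tiny test matrices)."""
    P = np.eye(Q.shape[0])
    term = np.eye(Q.shape[0])
    for k in range(1, terms):
        term = term @ (Q * t) / k
        P = P + term
    return P


def enumerate_joint(tree, counts, model):
    """Joint probability of every internal-state assignment.

    Returns (list of internal node indices, dict assignment -> probability).
    Tips must all be observed.
    """
    Q = build_rate_matrix(model)
    P = {v: series_expm(Q, float(tree.length[v])) for v in range(tree.n_nodes)}
    internals = [v for v in range(tree.n_nodes) if not tree.is_tip[v]]
    prior = model.root_prior_vector()
    tip_state = {
        v: counts.data[tree.node_id[v]] for v in tree.tip_indices
    }
    out = {}
    for assign in product(range(1, model.nmax + 1), repeat=len(internals)):
        state = dict(zip(internals, assign))
        state.update(tip_state)
        p = prior[state[tree.root] - 1]
        for v in range(tree.n_nodes):
            if v == tree.root:
                continue
            p *= P[v][state[tree.parent[v]] - 1, state[v] - 1]
        out[assign] = p
    return internals, out


def enumerate_loglik(tree, counts, model) -> float:
    _, joint = enumerate_joint(tree, counts, model)
    return float(np.log(sum(joint.values())))


def enumerate_posteriors(tree, counts, model):
    """Marginal posterior vector per internal node by direct summation."""
    internals, joint = enumerate_joint(tree, counts, model)
    total = sum(joint.values())
    post = {v: np.zeros(model.nmax) for v in internals}
    for assign, p in joint.items():
        for v, s in zip(internals, assign):
            post[v][s - 1] += p
    return {tree.node_id[v]: post[v] / total for v in internals}
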