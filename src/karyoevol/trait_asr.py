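"""Brownian-motion ancestral reconstruction of continuous karyotype traits.

A continuous trait (genome size in pg/1C, asymmetry index) is modelled as
Brownian motion on the fixed phylogram: the tip vector x is multivariate
normal with mean root * 1 and covariance sigma^2 * C, where C[i, j] is the
branch-length distance from the root to the most recent common ancestor of
tips i and j.  The root state and sigma^2 have generalized-least-squares
closed forms:

    root    = (1' C^-1 x) / (1' C^-1 1)
    sigma^2 = (x - root)' C^-1 (x - root) / n        (ML; n-1 for REML)

Ancestral states at internal nodes are the conditional expectations of the
same Gaussian process given the tips, which coincide with the joint ML
estimates; each estimate therefore lies within the range of the observed
tip values.  Taxa with missing trait values are pruned from the tree before
fitting.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import linalg

from .phylo_io import Phylogram, TraitTable, check_tree_table

logger = logging.getLogger("karyoevol")

#: Lower bound on the ML variance rate, used for degenerate (constant) data.
SIGMA2_FLOOR = 1e-12


class BMError(ValueError):
    pass


def _mrca_depths(tree: Phylogram) -> np.ndarray:
    """Depth of the MRCA for every pair of nodes (full node set)."""
    n = tree.n_nodes
    depths = tree.depths()
    # ancestor list (including self) per node, root first
    anc: list[list[int]] = [[] for _ in range(n)]
    for v in tree.preorder():
        if v == tree.root:
            anc[v] = [v]
        else:
            anc[v] = anc[tree.parent[v]] + [v]
    anc_sets = [set(a) for a in anc]
    M = np.empty((n, n))
    for i in range(n):
        for j in range(i, n):
            if i == j:
                m = i
            else:
                m = i if i in anc_sets[j] else (j if j in anc_sets[i] else None)
                if m is None:
                    # deepest shared ancestor on the two root paths
                    shared = anc_sets[i] & anc_sets[j]
                    m = max(shared, key=lambda v: depths[v])
            M[i, j] = M[j, i] = depths[m]
    return M


@dataclass
class BMFit:
    """Fitted Brownian-motion model on a (possibly pruned) phylogram."""

    sigma2: float
    root_state: float
    logL: float
    method: str
    tree: Phylogram
    trait_name: str = "trait"
    tip_values: dict[str, float] = field(default_factory=dict)
    _C: np.ndarray = field(default=None, repr=False)
    _M: np.ndarray = field(default=None, repr=False)


def fit_bm(
    tree: Phylogram,
    trait: TraitTable,
    method: str = "ML",
    zero_length_floor: Optional[float] = None,
) -> BMFit:
    """GLS closed-form ML (or REML) fit of Brownian motion to tip data.

    Taxa with missing values are pruned.  A singular tip covariance
    (duplicate zero-length tips) raises unless ``zero_length_floor`` is
    given, in which case zero terminal branches are floored at that length
    (in units of tree height) and the flooring is logged loudly.
    """
    if method not in ("ML", "REML"):
        raise BMError("method must be 'ML' or 'REML'")
    values = trait.non_missing()
    if len(values) < 2:
        raise BMError("need at least 2 non-missing trait values")
    check_tree_table(tree, trait)
    if set(values) != set(tree.tip_labels):
        tree = tree.prune_to_taxa(values)
    if tree.height() <= 0:
        raise BMError("tree has no branch length information")
    if zero_length_floor:
        floor = zero_length_floor * tree.height()
        lengths = tree.length.copy()
        zero_tips = [
            v for v in tree.tip_indices if lengths[v] < floor and v != tree.root
        ]
        if zero_tips:
            logger.warning(
                "flooring %d zero-length terminal branches at %g", len(zero_tips), floor
            )
            for v in zero_tips:
                lengths[v] = floor
            tree = Phylogram(tree.parent, lengths, tree.label)
    M = _mrca_depths(tree)
    tips = tree.tip_indices
    x = np.array([values[tree.node_id[i]] for i in tips])
    C = M[np.ix_(tips, tips)]
    n = x.size
    try:
        cf = linalg.cho_factor(C)
    except linalg.LinAlgError as exc:
        raise BMError(
            "singular tip covariance (duplicate zero-length tips?); "
            "consider zero_length_floor=1e-8"
        ) from exc
    one = np.ones(n)
    Cinv_x = linalg.cho_solve(cf, x)
    Cinv_1 = linalg.cho_solve(cf, one)
    root = float(one @ Cinv_x / (one @ Cinv_1))
    e = x - root
    quad = float(e @ linalg.cho_solve(cf, e))
    dof = n if method == "ML" else n - 1
    sigma2 = max(quad / dof, SIGMA2_FLOOR)
    logdetC = 2.0 * float(np.sum(np.log(np.diag(cf[0]))))
    logL = -0.5 * (
        n * math.log(2 * math.pi) + n * math.log(sigma2) + logdetC + quad / sigma2
    )
    return BMFit(
        sigma2=sigma2,
        root_state=root,
        logL=logL,
        method=method,
        tree=tree,
        trait_name=trait.name,
        tip_values={tree.node_id[i]: float(v) for i, v in zip(tips, x)},
        _C=C,
        _M=M,
    )


def ancestral_states_bm(
    tree: Phylogram,
    trait: TraitTable,
    fit: Optional[BMFit] = None,
) -> dict[str, tuple[float, float]]:
    """Conditional (estimate, variance) per node under the fitted BM model.

    Tips return their observed value with variance 0.  Internal estimates
    are GLS conditional expectations: root + c_a' C^-1 (x - root), with
    variance sigma^2 (C_aa - c_a' C^-1 c_a).
    """
    if fit is None:
        fit = fit_bm(tree, trait)
    tree = fit.tree
    M, C = fit._M, fit._C
    tips = tree.tip_indices
    x = np.array([fit.tip_values[tree.node_id[i]] for i in tips])
    cf = linalg.cho_factor(C)
    resid = linalg.cho_solve(cf, x - fit.root_state)
    out: dict[str, tuple[float, float]] = {}
    for v in range(tree.n_nodes):
        nid = tree.node_id[v]
        if tree.is_tip[v]:
            out[nid] = (fit.tip_values[nid], 0.0)
            continue
        c_a = M[v, tips]
        est = fit.root_state + float(c_a @ resid)
        var = fit.sigma2 * float(M[v, v] - c_a @ linalg.cho_solve(cf, c_a))
        out[nid] = (est, max(var, 0.0))
    return out


def asr_table(estimates: dict[str, tuple[float, float]]) -> pd.DataFrame:
    rows = [
        {"node": nid, "estimate": est, "variance": var}
        for nid, (est, var) in estimates.items()
    ]
    return pd.DataFrame(rows)
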