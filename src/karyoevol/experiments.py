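"""Simulation experiments: parameter recovery and model selection.

These are the calibration checks run by the test suite and the
reproduction script: simulate data under known parameters on Yule trees,
re-fit with the corresponding estimator, and score how often the estimates
land within stated tolerances.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .chromnum import ChromModel, fit_model
from .synthetic import simulate_bm_trait, simulate_chrom_counts, simulate_yule_tree
from .trait_asr import fit_bm

#: Birth rate used for recovery experiments.  At 200 tips this gives a tree
#: height near 1 and a few dozen dysploidy events per tree under the
#: simulated rates -- enough signal without saturating the state space.
RECOVERY_BIRTH_RATE = 5.0

#: Birth rate for the Brownian-motion recovery experiment.  The resulting
#: tree height (~0.2) matches the depth of empirical plastid phylograms in
#: substitutions per site, the scale on which the trait models are run.
BM_BIRTH_RATE = 25.0


@dataclass
class RecoveryResult:
    table: pd.DataFrame
    success_fraction: float


def rate_recovery_experiment(
    n_replicates: int = 20,
    n_tips: int = 200,
    gain: float = 0.5,
    loss: float = 1.0,
    root_state: int = 10,
    rel_tol: float = 0.5,
    seed_base: int = 1,
    n_starts: int = 2,
) -> RecoveryResult:
    """Gain/loss rate recovery for the dysploidy-only CTMC.

    For seeds ``seed_base .. seed_base + n_replicates - 1``: simulate counts
    under CONST_RATE_NO_DUPL with the given rates on a fresh Yule tree, re-fit
    the same model, and call a replicate a success when both fitted rates are
    within ``rel_tol`` relative error of the truth.
    """
    rows = []
    for i in range(n_replicates):
        seed = seed_base + i
        tree = simulate_yule_tree(n_tips, RECOVERY_BIRTH_RATE, seed=seed)
        nmax = max(root_state + 10, 2 * root_state)
        model = ChromModel("CONST_RATE_NO_DUPL", gain=gain, loss=loss, nmax=nmax)
        counts, _ = simulate_chrom_counts(tree, model, root_state, seed=seed)
        fit = fit_model(
            tree, counts, "CONST_RATE_NO_DUPL", n_starts=n_starts, seed=seed
        )
        g, l = fit.model.gain, fit.model.loss
        ok = abs(g - gain) <= rel_tol * gain and abs(l - loss) <= rel_tol * loss
        rows.append(
            {"seed": seed, "gain_hat": g, "loss_hat": l, "logL": fit.logL, "ok": ok}
        )
    table = pd.DataFrame(rows)
    return RecoveryResult(table, float(table["ok"].mean()))


def model_selection_experiment(
    n_replicates: int = 10,
    n_tips: int = 100,
    gain: float = 0.5,
    loss: float = 1.0,
    dupl: float = 0.15,
    root_state: int = 10,
    seed_base: int = 1,
    n_starts: int = 2,
) -> RecoveryResult:
    """AIC choice between CONST_RATE and CONST_RATE_DEMI on data simulated
    with no demiduplication.  Success = CONST_RATE wins (lower AIC; ties go
    to it as both models have the same parameter count)."""
    rows = []
    for i in range(n_replicates):
        seed = seed_base + i
        tree = simulate_yule_tree(n_tips, RECOVERY_BIRTH_RATE, seed=seed)
        nmax = 3 * root_state
        truth = ChromModel("CONST_RATE", gain=gain, loss=loss, dupl=dupl, nmax=nmax)
        counts, _ = simulate_chrom_counts(tree, truth, root_state, seed=seed)
        fits = {
            name: fit_model(tree, counts, name, n_starts=n_starts, seed=seed)
            for name in ("CONST_RATE", "CONST_RATE_DEMI")
        }
        ok = fits["CONST_RATE"].aic <= fits["CONST_RATE_DEMI"].aic
        rows.append(
            {
                "seed": seed,
                "aic_const_rate": fits["CONST_RATE"].aic,
                "aic_const_rate_demi": fits["CONST_RATE_DEMI"].aic,
                "ok": ok,
            }
        )
    table = pd.DataFrame(rows)
    return RecoveryResult(table, float(table["ok"].mean()))


def bm_recovery_experiment(
    n_replicates: int = 20,
    n_tips: int = 200,
    sigma2: float = 1.0,
    root: float = 5.0,
    root_tol: float = 0.5,
    sigma2_rel_tol: float = 0.3,
    seed_base: int = 1,
) -> RecoveryResult:
    """Root and sigma^2 recovery for Brownian motion on Yule trees."""
    rows = []
    for i in range(n_replicates):
        seed = seed_base + i
        tree = simulate_yule_tree(n_tips, BM_BIRTH_RATE, seed=seed)
        trait = simulate_bm_trait(tree, sigma2, root, seed=seed)
        fit = fit_bm(tree, trait)
        ok = (
            abs(fit.root_state - root) <= root_tol
            and abs(fit.sigma2 - sigma2) <= sigma2_rel_tol * sigma2
        )
        rows.append(
            {"seed": seed, "root_hat": fit.root_state, "sigma2_hat": fit.sigma2, "ok": ok}
        )
    table = pd.DataFrame(rows)
    return RecoveryResult(table, float(table["ok"].mean()))
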