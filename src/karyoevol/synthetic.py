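"""Seeded generators for every input the pipeline consumes.

The generators emulate the statistical structure the analyses assume: pure
birth (Yule) phylograms, chromosome counts evolved forward under the same
dysploidy/polyploidy CTMC the inference fits, Brownian-motion continuous
traits, arm-length measurement tables realizing a target karyotype formula
with multiplicative measurement noise, and flow-cytometry peak pairs with a
stated coefficient of variation.

Every generator is a pure function of (parameters, seed).  Substreams are
derived from the run seed and a generator-specific name, so adding one
generator to a pipeline never perturbs the draws of another.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .chromnum import ChromModel
from .karyo_metrics import ChromosomeMeasurement, parse_formula
from .genome_size import FlowMeasurement
from .phylo_io import CountsTable, Phylogram, TraitTable

#: Default arm-ratio templates, one per Levan class, placed mid-interval so
#: moderate measurement noise does not cross a class boundary.
CLASS_TEMPLATE_RATIOS = {"m": 1.3, "sm": 2.2, "st": 4.5, "t": 8.5}


def substream(seed: Optional[int], name: str) -> np.random.Generator:
    """Named, decorrelated child stream of the run seed."""
    tag = zlib.crc32(name.encode())
    return np.random.default_rng(np.random.SeedSequence([0 if seed is None else seed, tag]))


@dataclass
class SimulationConfig:
    """Defaults mirroring the study scale: ~50 tips, haploid counts 3..11,
    genome sizes 1-7.5 pg, measurement noise of a few percent."""

    seed: int = 1436
    n_tips: int = 50
    birth_rate: float = 1.0
    gain: float = 0.1
    loss: float = 0.4
    dupl: float = 0.05
    demi: float = 0.05
    root_state: int = 6
    sigma2: float = 1.0
    bm_root: float = 3.5
    measurement_cv: float = 2.0
    flow_cv: float = 2.0
    n_cells: int = 10
    n_replicates: int = 3


def simulate_yule_tree(
    n_tips: int, birth_rate: float = 1.0, seed: Optional[int] = None
) -> Phylogram:
    """Pure-birth ultrametric tree with ``n_tips`` labelled tips.

    With k extant lineages the waiting time to the next split is
    Exp(k * birth_rate); the process is stopped when the (n+1)-th split
    would occur, so the expected root height at rate 1 is sum_{k=2..n} 1/k.
    Tips are labelled ``t1..tn`` in their order of creation.
    """
    if n_tips < 2:
        raise ValueError("need at least 2 tips")
    if birth_rate <= 0:
        raise ValueError("birth rate must be positive")
    rng = substream(seed, "yule")
    parent = [-1, 0, 0]
    pending = [0.0, 0.0, 0.0]  # time since the node's branch started
    active = [1, 2]
    while True:
        k = len(active)
        dt = rng.exponential(1.0 / (k * birth_rate))
        for v in active:
            pending[v] += dt
        if k == n_tips:
            break
        split = active[rng.integers(k)]
        for _ in range(2):
            parent.append(split)
            pending.append(0.0)
        active.remove(split)
        active.extend([len(parent) - 2, len(parent) - 1])
    labels: list[Optional[str]] = [None] * len(parent)
    for i, v in enumerate(sorted(active), 1):
        labels[v] = f"t{i}"
    return Phylogram(parent, pending, labels)


def simulate_chrom_counts(
    tree: Phylogram,
    model: ChromModel,
    root_state: int,
    seed: Optional[int] = None,
) -> tuple[CountsTable, pd.DataFrame]:
    """Forward Gillespie simulation of the chromosome-number CTMC.

    Returns the tip counts and a per-branch log of the true numbers of
    events of each type (the oracle against which stochastic-mapping
    expectations can be validated).
    """
    if not 1 <= root_state <= model.nmax:
        raise ValueError(f"root state must lie in 1..{model.nmax}")
    rng = substream(seed, "chrom-counts")
    states = np.empty(tree.n_nodes, dtype=int)
    states[tree.root] = root_state
    log_rows = []
    for v in tree.preorder():
        if v == tree.root:
            continue
        s = int(states[tree.parent[v]])
        t_left = float(tree.length[v])
        events = {"gain": 0, "loss": 0, "duplication": 0, "demiduplication": 0}
        while True:
            channels = model.event_channels(s)
            total = sum(r for _, r, _ in channels)
            if total <= 0:
                break
            wait = rng.exponential(1.0 / total)
            if wait >= t_left:
                break
            t_left -= wait
            rates = np.array([r for _, r, _ in channels])
            idx = rng.choice(len(channels), p=rates / rates.sum())
            target, _, ev = channels[idx]
            events[ev] += 1
            s = target
        states[v] = s
        log_rows.append({"branch": tree.node_id[v], **events, "end_state": s})
    counts = CountsTable(
        {tree.node_id[i]: int(states[i]) for i in tree.tip_indices}
    )
    return counts, pd.DataFrame(log_rows).set_index("branch")


def simulate_bm_trait(
    tree: Phylogram,
    sigma2: float,
    root: float,
    seed: Optional[int] = None,
    name: str = "trait",
) -> TraitTable:
    """Brownian motion along the tree: normal increments with variance
    sigma2 * branch length."""
    if sigma2 < 0:
        raise ValueError("sigma2 must be >= 0")
    rng = substream(seed, "bm-trait")
    vals = np.empty(tree.n_nodes)
    vals[tree.root] = root
    for v in tree.preorder():
        if v == tree.root:
            continue
        sd = np.sqrt(sigma2 * tree.length[v])
        vals[v] = vals[tree.parent[v]] + (rng.normal(0.0, sd) if sd > 0 else 0.0)
    return TraitTable(
        {tree.node_id[i]: float(vals[i]) for i in tree.tip_indices}, name=name
    )


def simulate_karyotype_measurements(
    formula: str,
    n_cells: int = 10,
    noise_cv: float = 2.0,
    seed: Optional[int] = None,
    longest_um: float = 12.0,
    shortest_um: float = 6.0,
) -> list[ChromosomeMeasurement]:
    """Arm-length measurement set realizing a target karyotype formula.

    Each homologue pair gets a template: an arm ratio in the middle of its
    Levan class interval and a total length on a decreasing ramp from
    ``longest_um`` to ``shortest_um``.  Per cell, each arm is perturbed
    multiplicatively with the given CV (percent).  Homologues share their
    pair's template, and at ``noise_cv = 0`` rebuilding the karyotype
    recovers the formula exactly.
    """
    if n_cells < 1:
        raise ValueError("need at least one cell")
    if noise_cv < 0:
        raise ValueError("noise CV must be >= 0")
    two_n, _, class_counts = parse_formula(formula)
    if any(c % 2 for c in class_counts.values()):
        raise ValueError(f"formula {formula!r} has odd class counts; homologues pair")
    rng = substream(seed, "karyotype")
    pair_classes: list[str] = []
    for cls in ("m", "sm", "st", "t"):
        pair_classes.extend([cls] * (class_counts.get(cls, 0) // 2))
    n_pairs = two_n // 2
    totals = np.linspace(longest_um, shortest_um, n_pairs)
    measurements = []
    for cell in range(1, n_cells + 1):
        chrom = 0
        for p, cls in enumerate(pair_classes):
            r = CLASS_TEMPLATE_RATIOS[cls]
            long_t = totals[p] * r / (1.0 + r)
            short_t = totals[p] / (1.0 + r)
            for _ in range(2):  # the two homologues
                chrom += 1
                noise = rng.normal(1.0, noise_cv / 100.0, size=2) if noise_cv else np.ones(2)
                measurements.append(
                    ChromosomeMeasurement(
                        cell_id=f"cell{cell}",
                        chrom_id=f"chr{chrom}",
                        long_um=float(long_t * max(noise[0], 0.05)),
                        short_um=float(short_t * max(noise[1], 0.05)),
                    )
                )
    return measurements


def simulate_flow_peaks(
    true_2c: float,
    standard_2c: float,
    cv: float = 2.0,
    n_replicates: int = 3,
    seed: Optional[int] = None,
    standard_peak: float = 200.0,
    sample_id_prefix: str = "run",
    taxon: str = "",
    standard_name: str = "standard",
) -> list[FlowMeasurement]:
    """Flow-cytometry peak pairs whose ratio is normally perturbed with the
    stated CV (percent); the per-run reported CV equals that setting."""
    if min(true_2c, standard_2c, standard_peak) <= 0:
        raise ValueError("2C values and peak means must be positive")
    if cv < 0 or n_replicates < 1:
        raise ValueError("cv must be >= 0 and n_replicates >= 1")
    rng = substream(seed, "flow")
    out = []
    for i in range(1, n_replicates + 1):
        ratio = true_2c / standard_2c
        noisy = ratio * (1.0 + rng.normal(0.0, cv / 100.0)) if cv else ratio
        out.append(
            FlowMeasurement(
                sample_id=f"{sample_id_prefix}{i}",
                sample_peak=standard_peak * max(noisy, 1e-6),
                standard_peak=standard_peak,
                standard_2c_pg=standard_2c,
                cv_pct=cv,
                taxon=taxon,
                standard_name=standard_name,
            )
        )
    return out
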