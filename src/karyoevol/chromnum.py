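"""Chromosome-number evolution as a continuous-time Markov chain.

The haploid chromosome number evolves on the state space 1..Nmax under four
elementary event types with constant per-lineage rates:

* gain (ascending dysploidy), i -> i+1, rate ``gain``;
* loss (descending dysploidy), i -> i-1, rate ``loss``;
* duplication (polyploidization), i -> 2i, rate ``dupl``;
* demiduplication (triploidy-mediated), i -> 1.5i, rate ``demi``; odd
  states split the demiduplication mass equally between floor and ceiling.

Targets beyond Nmax are truncated to Nmax.  Four model flavours restrict
the free rates: CONST_RATE (no demiduplication), CONST_RATE_DEMI
(demiduplication rate tied to the duplication rate), CONST_RATE_DEMI_EST
(free demiduplication rate), and CONST_RATE_NO_DUPL (dysploidy only).

The likelihood of tip counts on a rooted phylogram is computed by
Felsenstein pruning with per-branch transition matrices P(t) = exp(Qt);
rates are fitted by bounded multi-start maximum likelihood, models are
compared by AIC, marginal ancestral states come from a standard up-down
pass, and per-branch expected numbers of events of each type are estimated
by stochastic mapping (simulating histories conditional on the tip data).
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import linalg, optimize

from .phylo_io import CountsTable, Phylogram, check_tree_table

logger = logging.getLogger("karyoevol")

MODEL_NAMES = (
    "CONST_RATE",
    "CONST_RATE_DEMI",
    "CONST_RATE_DEMI_EST",
    "CONST_RATE_NO_DUPL",
)

EVENTS = ("gain", "loss", "duplication", "demiduplication")


class ChromModelError(ValueError):
    pass


def _demi_targets(i: int, nmax: int) -> list[tuple[int, float]]:
    """(target state, fraction of the demiduplication rate) pairs for state i.

    Even i goes to 3i/2; odd i splits equally between floor(1.5i) and
    ceil(1.5i).  Targets are capped at Nmax; self-targets (possible for
    i = 1 or at the cap) are dropped.
    """
    if i % 2 == 0:
        raw = [(3 * i // 2, 1.0)]
    else:
        raw = [(math.floor(1.5 * i), 0.5), (math.ceil(1.5 * i), 0.5)]
    out: dict[int, float] = {}
    for j, frac in raw:
        j = min(j, nmax)
        if j != i:
            out[j] = out.get(j, 0.0) + frac
    return sorted(out.items())


@dataclass
class ChromModel:
    """Rates and state space of the chromosome-number CTMC."""

    name: str
    gain: float
    loss: float
    dupl: float = 0.0
    demi: float = 0.0
    nmax: int = 50
    root_prior: str | np.ndarray = "uniform"

    def __post_init__(self):
        if self.name not in MODEL_NAMES:
            raise ChromModelError(f"unknown model {self.name!r}; use one of {MODEL_NAMES}")
        for r in (self.gain, self.loss, self.dupl, self.demi):
            if not (math.isfinite(r) and r >= 0):
                raise ChromModelError("rates must be finite and >= 0")
        if self.nmax < 1:
            raise ChromModelError("Nmax must be >= 1")
        if self.name == "CONST_RATE" and self.demi != 0:
            raise ChromModelError("CONST_RATE fixes the demiduplication rate to 0")
        if self.name == "CONST_RATE_DEMI" and self.demi != self.dupl:
            raise ChromModelError("CONST_RATE_DEMI ties demi = dupl")
        if self.name == "CONST_RATE_NO_DUPL" and (self.dupl != 0 or self.demi != 0):
            raise ChromModelError("CONST_RATE_NO_DUPL fixes dupl = demi = 0")
        if isinstance(self.root_prior, np.ndarray):
            if self.root_prior.size != self.nmax:
                raise ChromModelError("root prior length must equal Nmax")
            if not np.isclose(self.root_prior.sum(), 1.0):
                raise ChromModelError("root prior must sum to 1")

    @property
    def free_param_names(self) -> tuple[str, ...]:
        return {
            "CONST_RATE": ("gain", "loss", "dupl"),
            "CONST_RATE_DEMI": ("gain", "loss", "dupl"),
            "CONST_RATE_DEMI_EST": ("gain", "loss", "dupl", "demi"),
            "CONST_RATE_NO_DUPL": ("gain", "loss"),
        }[self.name]

    @property
    def k(self) -> int:
        """Number of free rate parameters (the root prior is fixed)."""
        return len(self.free_param_names)

    def with_rates(self, values: Sequence[float]) -> "ChromModel":
        names = self.free_param_names
        if len(values) != len(names):
            raise ChromModelError("wrong number of free rates")
        rates = {"gain": self.gain, "loss": self.loss, "dupl": self.dupl, "demi": self.demi}
        rates.update(dict(zip(names, map(float, values))))
        if self.name == "CONST_RATE_DEMI":
            rates["demi"] = rates["dupl"]
        return ChromModel(self.name, nmax=self.nmax, root_prior=self.root_prior, **rates)

    def root_prior_vector(self) -> np.ndarray:
        if isinstance(self.root_prior, np.ndarray):
            return self.root_prior
        if self.root_prior == "uniform":
            return np.full(self.nmax, 1.0 / self.nmax)
        raise ChromModelError(f"unknown root prior {self.root_prior!r}")

    def event_channels(self, i: int) -> list[tuple[int, float, str]]:
        """(target state, rate, event name) channels out of state ``i``
        (1-based states)."""
        ch: list[tuple[int, float, str]] = []
        if self.gain > 0 and i + 1 <= self.nmax:
            ch.append((i + 1, self.gain, "gain"))
        if self.loss > 0 and i - 1 >= 1:
            ch.append((i - 1, self.loss, "loss"))
        if self.dupl > 0:
            j = min(2 * i, self.nmax)
            if j != i:
                ch.append((j, self.dupl, "duplication"))
        if self.demi > 0:
            for j, frac in _demi_targets(i, self.nmax):
                ch.append((j, self.demi * frac, "demiduplication"))
        return ch


def build_rate_matrix(model: ChromModel) -> np.ndarray:
    """Instantaneous rate matrix Q over states 1..Nmax (row index i-1)."""
    n = model.nmax
    Q = np.zeros((n, n))
    for i in range(1, n + 1):
        for j, rate, _ in model.event_channels(i):
            Q[i - 1, j - 1] += rate
    np.fill_diagonal(Q, Q.diagonal() - Q.sum(axis=1))
    return Q


class Propagator:
    """Transition matrices P(t) = exp(Qt), cached per branch length.

    Uses the eigendecomposition of the (small, dense) truncated Q when it is
    well conditioned, falling back to scaling-and-squaring otherwise.  Tiny
    negative entries from round-off are clipped to 0.
    """

    def __init__(self, Q: np.ndarray):
        self.Q = Q
        self._cache: dict[float, np.ndarray] = {}
        self._eig = None
        try:
            w, V = linalg.eig(Q)
            if np.linalg.cond(V) < 1e8:
                self._eig = (w, V, linalg.inv(V))
        except linalg.LinAlgError:  # pragma: no cover - expm fallback
            pass

    def __call__(self, t: float) -> np.ndarray:
        if t < 0:
            raise ChromModelError("branch length must be >= 0")
        P = self._cache.get(t)
        if P is not None:
            return P
        if t == 0.0:
            P = np.eye(self.Q.shape[0])
        elif self._eig is not None:
            w, V, Vinv = self._eig
            P = (V * np.exp(w * t)) @ Vinv
            P = np.real(P)
        else:  # pragma: no cover - ill-conditioned eigenbasis
            P = linalg.expm(self.Q * t)
        np.clip(P, 0.0, None, out=P)
        self._cache[t] = P
        return P


def _tip_partial(count: Optional[int], nmax: int) -> np.ndarray:
    if count is None:
        return np.ones(nmax)
    if count > nmax:
        raise ChromModelError(f"tip count {count} exceeds Nmax = {nmax}")
    v = np.zeros(nmax)
    v[count - 1] = 1.0
    return v


def _down_pass(
    tree: Phylogram, counts: CountsTable, model: ChromModel
) -> tuple[np.ndarray, np.ndarray, Propagator]:
    """Scaled conditional likelihoods of the data below each node.

    Returns (partials[n_nodes, nmax], log scale factor per node accumulated
    over its subtree, propagator).  Partials are rescaled by their maximum
    at every internal node to avoid underflow.
    """
    check_tree_table(tree, counts)
    nmax = model.nmax
    prop = Propagator(build_rate_matrix(model))
    partials = np.empty((tree.n_nodes, nmax))
    logscale = np.zeros(tree.n_nodes)
    for v in tree.postorder():
        if tree.is_tip[v]:
            count = counts.data.get(tree.node_id[v])
            partials[v] = _tip_partial(count, nmax)
            continue
        part = np.ones(nmax)
        acc = 0.0
        for c in tree.children[v]:
            part = part * (prop(float(tree.length[c])) @ partials[c])
            acc += logscale[c]
        m = part.max()
        if m <= 0:
            raise ChromModelError(
                f"all-zero partial at node {tree.node_id[v]!r} "
                "(data impossible under the model)"
            )
        partials[v] = part / m
        logscale[v] = acc + math.log(m)
    return partials, logscale, prop


def likelihood(tree: Phylogram, counts: CountsTable, model: ChromModel) -> float:
    """Log-likelihood of tip counts under the model (Felsenstein pruning)."""
    partials, logscale, _ = _down_pass(tree, counts, model)
    root = tree.root
    lik = float(model.root_prior_vector() @ partials[root])
    if lik <= 0 or not math.isfinite(lik):
        raise ChromModelError("non-finite likelihood at the root")
    return math.log(lik) + float(logscale[root])


@dataclass
class ChromModelFit:
    """Fitted model with log-likelihood, AIC and the optimizer trace."""

    model: ChromModel
    logL: float
    trace: list[dict] = field(default_factory=list)
    data_key: tuple = ()

    @property
    def k(self) -> int:
        return self.model.k

    @property
    def aic(self) -> float:
        return 2.0 * self.k - 2.0 * self.logL

    @property
    def rates(self) -> dict[str, float]:
        m = self.model
        return {"gain": m.gain, "loss": m.loss, "dupl": m.dupl, "demi": m.demi}


def _data_key(tree: Phylogram, counts: CountsTable) -> tuple:
    return (
        tuple(tree.parent.tolist()),
        tuple(np.round(tree.length, 12).tolist()),
        tuple(sorted(counts.data.items())),
    )


def fit_model(
    tree: Phylogram,
    counts: CountsTable,
    model_name: str = "CONST_RATE",
    n_starts: int = 5,
    bounds: tuple[float, float] = (1e-8, 100.0),
    seed: Optional[int] = None,
    nmax: Optional[int] = None,
    nmax_pad: int = 10,
    root_prior: str | np.ndarray = "uniform",
    maxiter: int = 200,
) -> ChromModelFit:
    """Bounded multi-start ML estimation of the free rates.

    Rates are optimized on the log scale with L-BFGS-B.  The first start is
    a data-scaled guess (two expected events over the whole tree per
    channel); the remaining starts are log-uniform draws from the seeded
    generator.  Nmax defaults to the largest observed count plus
    ``nmax_pad``.
    """
    non_missing = counts.non_missing()
    if len(non_missing) < 2:
        raise ChromModelError("need at least 2 non-missing tip counts")
    if nmax is None:
        nmax = counts.max_count() + nmax_pad
    if nmax < counts.max_count():
        raise ChromModelError(
            f"Nmax = {nmax} is below the largest observed count {counts.max_count()}"
        )
    template = ChromModel(model_name, 0.0, 0.0, nmax=nmax, root_prior=root_prior)
    names = template.free_param_names
    lo, hi = math.log(bounds[0]), math.log(bounds[1])
    rng = np.random.default_rng(seed)

    def objective(theta: np.ndarray) -> float:
        model = template.with_rates(np.exp(theta))
        try:
            return -likelihood(tree, counts, model)
        except (ChromModelError, FloatingPointError):
            return 1e10

    total_len = max(tree.total_length(), 1e-8)
    first = np.full(len(names), math.log(min(max(2.0 / total_len, bounds[0]), bounds[1])))
    starts = [first]
    for _ in range(max(n_starts - 1, 0)):
        starts.append(rng.uniform(math.log(1e-3), math.log(10.0), size=len(names)))
    best = None
    trace = []
    for x0 in starts:
        res = optimize.minimize(
            objective,
            np.clip(x0, lo, hi),
            method="L-BFGS-B",
            bounds=[(lo, hi)] * len(names),
            options={"maxiter": maxiter},
        )
        trace.append(
            {"x0": np.exp(x0), "rates": np.exp(res.x), "logL": -res.fun,
             "success": bool(res.success), "message": str(res.message)}
        )
        if math.isfinite(res.fun) and res.fun < 1e9 and (best is None or res.fun < best.fun):
            best = res
    if best is None:
        raise ChromModelError(f"optimizer failed on all starts: {trace}")
    fitted = template.with_rates(np.exp(best.x))
    return ChromModelFit(
        model=fitted,
        logL=-float(best.fun),
        trace=trace,
        data_key=_data_key(tree, counts),
    )


def select_model(fits: Iterable[ChromModelFit]) -> ChromModelFit:
    """Minimum-AIC fit; exact ties break toward fewer free parameters."""
    fits = list(fits)
    if not fits:
        raise ChromModelError("no fits to select from")
    keys = {f.data_key for f in fits}
    if len(keys) > 1:
        raise ChromModelError("fits were computed on different data")
    best_aic = min(f.aic for f in fits)
    candidates = [f for f in fits if abs(f.aic - best_aic) <= 1e-9]
    return min(candidates, key=lambda f: f.k)


@dataclass
class NodePosterior:
    """Marginal posterior state probabilities ('pp') per node."""

    probs: dict[str, np.ndarray]
    states: np.ndarray  # 1..Nmax

    def map_state(self, node_id: str) -> tuple[int, float]:
        """(most probable state, its posterior probability)."""
        p = self.probs[node_id]
        i = int(np.argmax(p))
        return int(self.states[i]), float(p[i])

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for nid, p in self.probs.items():
            state, pp = self.map_state(nid)
            rows.append({"node": nid, "map_state": state, "pp": pp})
        return pd.DataFrame(rows)


def _up_pass(
    tree: Phylogram,
    model: ChromModel,
    partials: np.ndarray,
    prop: Propagator,
) -> np.ndarray:
    """'Above' partials: likelihood of everything outside each node's
    subtree, as a function of the node's state.  Normalized per node (the
    scale cancels in posteriors)."""
    nmax = model.nmax
    above = np.empty((tree.n_nodes, nmax))
    above[tree.root] = model.root_prior_vector()
    for u in tree.preorder():
        if tree.is_tip[u]:
            continue
        # S[c] = P_c @ D_c as a function of the parent state
        S = {c: prop(float(tree.length[c])) @ partials[c] for c in tree.children[u]}
        for v in tree.children[u]:
            contrib = above[u].copy()
            for w in tree.children[u]:
                if w != v:
                    contrib *= S[w]
            a = contrib @ prop(float(tree.length[v]))
            m = a.max()
            if m <= 0:
                raise ChromModelError(
                    f"zero above-partial at node {tree.node_id[v]!r}"
                )
            above[v] = a / m
    return above


def marginal_ancestral_states(
    tree: Phylogram, counts: CountsTable, fit: ChromModelFit
) -> NodePosterior:
    """Marginal posterior over states for every node (up-down algorithm)."""
    model = fit.model
    partials, _, prop = _down_pass(tree, counts, model)
    above = _up_pass(tree, model, partials, prop)
    probs: dict[str, np.ndarray] = {}
    for v in range(tree.n_nodes):
        joint = above[v] * partials[v]
        s = joint.sum()
        if s <= 0 or not math.isfinite(s):
            raise ChromModelError(f"cannot normalize posterior at {tree.node_id[v]!r}")
        probs[tree.node_id[v]] = joint / s
    return NodePosterior(probs=probs, states=np.arange(1, model.nmax + 1))


# ------------------------------------------------------------------ mapping
@dataclass
class EventExpectation:
    """Per-branch expected event counts from stochastic mapping."""

    expectations: pd.DataFrame  # index: child-node id; columns: EVENTS
    threshold: float
    nsim: int
    seed: Optional[int]

    def flagged(self) -> list[tuple[str, str]]:
        """(branch, event) pairs whose expectation exceeds the threshold."""
        out = []
        for branch, row in self.expectations.iterrows():
            for ev in EVENTS:
                if row[ev] > self.threshold:
                    out.append((str(branch), ev))
        return out

    def n_flagged(self, event: str) -> int:
        return sum(1 for _, ev in self.flagged() if ev == event)

    def total_expected(self, event: str) -> float:
        return float(self.expectations[event].sum())


class _BranchSimulator:
    """Samples CTMC paths on a branch conditional on both endpoint states.

    Rejection sampling (forward simulation until the endpoint matches) with
    a per-path attempt cap; branches where rejection keeps failing switch to
    uniformization, which samples the number of (possibly virtual) jumps
    from its exact conditional distribution and then the jump chain as a
    bridge.
    """

    def __init__(self, model: ChromModel, prop: Propagator, rng: np.random.Generator,
                 max_attempts: int = 1000):
        self.model = model
        self.prop = prop
        self.rng = rng
        self.max_attempts = max_attempts
        self.Q = prop.Q
        self.n_uniformized = 0
        lam = float(np.max(-np.diag(self.Q)))
        self.lam = lam
        n = self.Q.shape[0]
        self.R = np.eye(n) + (self.Q / lam if lam > 0 else 0.0 * self.Q)
        self._Rpow: list[np.ndarray] = [np.eye(n), self.R.copy()]
        # per-state event channels and total exit rates
        self.channels = [model.event_channels(i) for i in range(1, model.nmax + 1)]
        self.exit = np.array([sum(r for _, r, _ in ch) for ch in self.channels])

    def _pick_event(self, a: int, b: int) -> str:
        """Attribute a realized jump a->b to an event type, proportional to
        the rate contributions of the channels that produce it."""
        opts = [(ev, r) for j, r, ev in self.channels[a - 1] if j == b]
        if not opts:
            raise ChromModelError(f"impossible jump {a}->{b}")
        if len(opts) == 1:
            return opts[0][0]
        rates = np.array([r for _, r in opts])
        idx = self.rng.choice(len(opts), p=rates / rates.sum())
        return opts[idx][0]

    def _forward(self, a: int, t: float) -> tuple[int, list[tuple[int, int]]]:
        """Unconditional Gillespie path from state a for duration t."""
        s = a
        now = 0.0
        jumps: list[tuple[int, int]] = []
        while True:
            rate = self.exit[s - 1]
            if rate <= 0:
                return s, jumps
            now += self.rng.exponential(1.0 / rate)
            if now >= t:
                return s, jumps
            ch = self.channels[s - 1]
            rates = np.array([r for _, r, _ in ch])
            idx = self.rng.choice(len(ch), p=rates / rates.sum())
            nxt = ch[idx][0]
            jumps.append((s, nxt))
            s = nxt

    def _Rpow_upto(self, n: int) -> None:
        while len(self._Rpow) <= n:
            self._Rpow.append(self._Rpow[-1] @ self.R)

    def _uniformized(self, a: int, b: int, t: float) -> list[tuple[int, int]]:
        lam = self.lam
        if lam <= 0:
            return []
        Pab = float(self.prop(t)[a - 1, b - 1])
        if Pab <= 0:
            raise ChromModelError(f"endpoint pair {a}->{b} has probability 0")
        # sample the number of uniformized jumps
        u = self.rng.uniform() * Pab
        acc = 0.0
        n = -1
        log_pois = -lam * t
        while acc < u:
            n += 1
            self._Rpow_upto(n)
            term = math.exp(log_pois + n * math.log(lam * t) - math.lgamma(n + 1)) if lam * t > 0 else (1.0 if n == 0 else 0.0)
            acc += term * float(self._Rpow[n][a - 1, b - 1])
            if n > 10000:  # pragma: no cover - numerical safety valve
                break
        # sample the jump chain as a bridge from a to b in n steps
        jumps: list[tuple[int, int]] = []
        s = a
        for step in range(n, 0, -1):
            self._Rpow_upto(step - 1)
            w = self.R[s - 1, :] * self._Rpow[step - 1][:, b - 1]
            w_sum = w.sum()
            if w_sum <= 0:
                raise ChromModelError("uniformization bridge failed")
            nxt = int(self.rng.choice(w.size, p=w / w_sum)) + 1
            if nxt != s:
                jumps.append((s, nxt))
            s = nxt
        return jumps

    def sample(self, a: int, b: int, t: float) -> list[tuple[str, int, int]]:
        """One conditional path as a list of (event, from, to) jumps."""
        if t == 0.0:
            if a != b:
                raise ChromModelError("state change across a 0-length branch")
            return []
        jumps = None
        for _ in range(self.max_attempts):
            end, js = self._forward(a, t)
            if end == b:
                jumps = js
                break
        if jumps is None:
            self.n_uniformized += 1
            jumps = self._uniformized(a, b, t)
        return [(self._pick_event(x, y), x, y) for x, y in jumps]


def expected_events(
    tree: Phylogram,
    counts: CountsTable,
    fit: ChromModelFit,
    nsim: int = 10_000,
    threshold: float = 0.5,
    seed: Optional[int] = None,
) -> EventExpectation:
    """Expected per-branch event counts via stochastic mapping.

    Joint node states are sampled exactly (root from its marginal
    posterior, then each child conditional on its sampled parent and the
    data below), and each branch history is simulated conditional on its
    endpoints.  Means over ``nsim`` replicates estimate the expected number
    of gains, losses, duplications and demiduplications per branch; events
    with expectation above ``threshold`` are flagged for reporting.
    """
    model = fit.model
    rng = np.random.default_rng(seed)
    partials, _, prop = _down_pass(tree, counts, model)
    root = tree.root
    root_post = model.root_prior_vector() * partials[root]
    root_post /= root_post.sum()
    sim = _BranchSimulator(model, prop, rng)
    n = tree.n_nodes
    totals = {ev: np.zeros(n) for ev in EVENTS}
    preorder = [v for v in tree.preorder()]
    states = np.empty(n, dtype=int)
    for _ in range(nsim):
        states[root] = rng.choice(model.nmax, p=root_post) + 1
        for v in preorder:
            if v == root:
                continue
            p = prop(float(tree.length[v]))[states[tree.parent[v]] - 1, :] * partials[v]
            psum = p.sum()
            if psum <= 0:
                raise ChromModelError(
                    f"cannot sample state at node {tree.node_id[v]!r}"
                )
            states[v] = rng.choice(model.nmax, p=p / psum) + 1
            for ev, _, _ in sim.sample(
                int(states[tree.parent[v]]), int(states[v]), float(tree.length[v])
            ):
                totals[ev][v] += 1.0
    if sim.n_uniformized:
        warnings.warn(
            f"rejection sampling hit the attempt cap on {sim.n_uniformized} "
            "branch draws; uniformization was used for those",
            stacklevel=2,
        )
    branch_ids = [tree.node_id[v] for v in range(n) if v != root]
    df = pd.DataFrame(
        {ev: [totals[ev][tree.index_of(b)] / nsim for b in branch_ids] for ev in EVENTS},
        index=pd.Index(branch_ids, name="branch"),
    )
    return EventExpectation(expectations=df, threshold=threshold, nsim=nsim, seed=seed)
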