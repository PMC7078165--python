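"""Generators for timetrees, branch-rate processes, substitution data, and
fossil calibrations with the statistical structure the downstream analyses
assume.

Three tree generators are provided:

* :func:`simulate_bd_tree` with a target tip count draws the reconstructed
  constant-rate birth-death tree by the coalescent-point-process
  construction — tip-separating node depths are iid from the conditioned
  depth distribution and the tree is the Cartesian (max-at-top) tree over
  the depth sequence — which is exactly the distribution of the extant
  reconstructed tree conditioned on the number of sampled tips.
* :func:`simulate_bd_tree` with a stopping age runs a forward simulation
  from a single origin lineage, prunes extinct lineages, and subsamples
  tips with probability rho.
* :func:`simulate_episodic_tree` runs the same forward simulator with
  piecewise-constant rates switching at bin boundaries; with a single bin
  it is definitionally identical to the constant-rate stopping-age case
  (same code path, same random stream).

Branch rates follow a strict clock, an uncorrelated gamma-multiplier
process (UGAM), or an autocorrelated mean-reverting square-root diffusion
(CIR) sampled by its exact noncentral-chi-square transition law.
Substitution data is generated as Poisson branch-length noise or as an
amino-acid alignment under a single exchangeable (equal-rates) model.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .diversify import EpisodicRates
from .trees import Calibration, PhyloTree, TimeTree

AA_ALPHABET = "ARNDCQEGHILKMFPSTWYV"
N_AA = 20


def _rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class BDParams:
    """Constant-rate birth-death simulation parameters.

    Rates are events per lineage per My; stop either at ``n`` sampled tips
    or at origin age ``T`` (Ma).  ``rho`` is the tip sampling fraction.
    """

    lam: float
    mu: float = 0.0
    n: int | None = None
    T: float | None = None
    rho: float = 1.0
    retry_cap: int = 1000

    def __post_init__(self):
        if self.lam <= 0:
            raise ValueError("lam must be positive")
        if self.mu < 0:
            raise ValueError("mu must be non-negative")
        if not 0 < self.rho <= 1:
            raise ValueError("rho must be in (0, 1]")
        if (self.n is None) == (self.T is None):
            raise ValueError("set exactly one of n (tip count) or T (origin age)")
        if self.n is not None and self.n < 2:
            raise ValueError("tip-count mode needs n >= 2")
        if self.n is not None and self.mu >= self.lam:
            raise ValueError("tip-count mode requires a supercritical process "
                             "(lam > mu)")


@dataclass
class ClockParams:
    """Branch-rate process parameters.

    ``model`` is ``strict``, ``cir``, or ``ugam``.  ``mean_rate`` m is in
    subst/site/My.  For CIR, ``v`` is the stationary variance of the
    instantaneous rate and ``theta`` its mean-reversion (decorrelation)
    rate per My; for UGAM, ``v`` is the variance of the gamma multiplier.
    """

    model: str = "strict"
    mean_rate: float = 1e-3
    v: float = 0.25
    theta: float = 0.05

    def __post_init__(self):
        if self.model not in ("strict", "cir", "ugam"):
            raise ValueError(f"unknown clock model {self.model!r}")
        if self.mean_rate <= 0:
            raise ValueError("mean_rate must be positive")
        if self.model in ("cir", "ugam") and self.v <= 0:
            raise ValueError("v must be positive")
        if self.model == "cir" and self.theta <= 0:
            raise ValueError("theta must be positive")


@dataclass
class BranchRates:
    """Per-branch substitution rates keyed by child node id.

    ``rates[i]`` is the rate on the branch above node i (NaN at the root).
    """

    rates: np.ndarray
    node_rates: np.ndarray | None = None  # CIR instantaneous rates, if any

    def __post_init__(self):
        self.rates = np.asarray(self.rates, float)
        if np.any(self.rates[1:] <= 0):
            raise ValueError("branch rates must be strictly positive")

    @classmethod
    def unchecked(cls, rates, node_rates=None) -> "BranchRates":
        """Wrap estimated rates that may legitimately contain zeros."""
        obj = cls.__new__(cls)
        obj.rates = np.asarray(rates, float)
        obj.node_rates = node_rates
        return obj


@dataclass
class SubstData:
    """Per-branch substitution observations.

    ``lengths`` mode: estimated branch lengths in subst/site (index =
    child node id, NaN at the root) with standard errors and the site
    count L they were estimated from.  ``alignment`` mode: an amino-acid
    alignment over the tree's leaves.
    """

    mode: str
    L: int
    lengths: np.ndarray | None = None
    se: np.ndarray | None = None
    sequences: dict[str, str] | None = None

    def __post_init__(self):
        if self.mode not in ("lengths", "alignment"):
            raise ValueError(f"unknown SubstData mode {self.mode!r}")
        if self.L < 1:
            raise ValueError("L must be >= 1")
        if self.mode == "lengths":
            self.lengths = np.asarray(self.lengths, float)
            if np.any(self.lengths[1:] < 0):
                raise ValueError("branch lengths must be non-negative")
        else:
            lens = {len(s) for s in self.sequences.values()}
            if lens != {self.L}:
                raise ValueError("all sequences must have length L")

    def encoded(self, leaf_names: list[str]) -> np.ndarray:
        """Integer-encoded alignment matrix (n_leaves, L); -1 marks gaps."""
        idx = {a: i for i, a in enumerate(AA_ALPHABET)}
        mat = np.full((len(leaf_names), self.L), -1, dtype=np.int8)
        missing = [nm for nm in leaf_names if nm not in self.sequences]
        if missing:
            raise ValueError(f"alignment lacks sequences for {missing}")
        for r, nm in enumerate(leaf_names):
            for c, ch in enumerate(self.sequences[nm]):
                mat[r, c] = idx.get(ch, -1)
        return mat


def to_fasta(seqs: dict[str, str]) -> str:
    return "".join(f">{nm}\n{s}\n" for nm, s in seqs.items())


# ---------------------------------------------------------------------------
# Conditioned birth-death depth distribution (coalescent point process)
# ---------------------------------------------------------------------------

def bd_depth_cdf(t, lam: float, mu: float, rho: float = 1.0):
    """CDF of a tip-separating node depth under the reconstructed
    birth-death process with present-day sampling fraction rho.

    Proper for supercritical processes (lam > mu): F(inf) = 1.
    """
    t = np.asarray(t, float)
    c = lam - mu
    if abs(c) < 1e-12 * max(lam, mu, 1.0):
        return rho * lam * t / (1.0 + rho * lam * t)
    a = lam * (1 - rho) - mu
    e = np.exp(-c * t)
    return rho * lam * (1.0 - e) / (rho * lam + a * e)


def bd_depth_ppf(u, lam: float, mu: float, rho: float = 1.0):
    """Inverse of :func:`bd_depth_cdf` (closed form)."""
    u = np.asarray(u, float)
    c = lam - mu
    if abs(c) < 1e-12 * max(lam, mu, 1.0):
        return u / (rho * lam * (1.0 - u))
    a = lam * (1 - rho) - mu
    return -np.log(rho * lam * (1.0 - u) / (u * a + rho * lam)) / c


def _cartesian_timetree(depths: np.ndarray, rng: np.random.Generator
                        ) -> TimeTree:
    """Build the coalescent-point-process tree over tip-separating depths."""
    n = len(depths) + 1
    parent, names, ages = [], [], []

    def build(lo, hi, par):
        i = len(parent)
        parent.append(par)
        if hi - lo == 1:
            names.append(f"t{lo + 1}")
            ages.append(0.0)
            return
        j = lo + int(np.argmax(depths[lo:hi - 1]))
        names.append(None)
        ages.append(float(depths[j]))
        build(lo, j + 1, i)
        build(j + 1, hi, i)

    import sys
    old = sys.getrecursionlimit()
    sys.setrecursionlimit(max(old, 10 * n + 100))
    try:
        build(0, n, -1)
    finally:
        sys.setrecursionlimit(old)
    return TimeTree(PhyloTree(parent, names), np.asarray(ages))


# ---------------------------------------------------------------------------
# Forward simulation (piecewise-constant rates)
# ---------------------------------------------------------------------------

def _forward_piecewise_bd(edges, lam_bins, mu_bins, origin_age: float,
                          rho: float, rng: np.random.Generator,
                          min_tips: int = 2, retry_cap: int = 1000
                          ) -> TimeTree:
    """Forward birth-death from one origin lineage; rates switch at bin
    boundaries; extinct lineages pruned; tips kept independently w.p. rho.

    Retries on failure to reach ``min_tips`` sampled tips, up to
    ``retry_cap`` attempts.
    """
    edges = np.asarray(edges, float)
    for attempt in range(retry_cap):
        node_parent = [-1]
        node_age = [origin_age]       # speciation age (0 for extant tips)
        node_children: list[list[int]] = [[]]
        active = [0]
        t = origin_age
        while active and t > 0:
            b = max(min(int(np.searchsorted(edges, t, side="left")) - 1,
                        len(lam_bins) - 1), 0)
            lam, mu = lam_bins[b], mu_bins[b]
            total = len(active) * (lam + mu)
            wait = rng.exponential(1.0 / total)
            lower = edges[b]
            if t - wait < lower:
                t = lower            # redraw in the next (younger) bin
                if t <= 0:
                    break
                continue
            t -= wait
            k = int(rng.integers(len(active)))
            node = active[k]
            if rng.random() < lam / (lam + mu):
                for _ in range(2):
                    cid = len(node_parent)
                    node_parent.append(node)
                    node_age.append(0.0)
                    node_children.append([])
                    node_children[node].append(cid)
                node_age[node] = t
                active[k] = node_children[node][0]
                active.append(node_children[node][1])
            else:
                node_age[node] = np.nan   # dead
                active.pop(k)
        sampled = [i for i in active if rng.random() < rho]
        if len(sampled) >= min_tips:
            return _reconstruct(node_parent, node_age, node_children, sampled)
    raise RuntimeError(
        f"forward simulation failed to reach {min_tips} sampled tips in "
        f"{retry_cap} attempts")


def _reconstruct(node_parent, node_age, node_children, sampled) -> TimeTree:
    """Prune to sampled tips, suppress unifurcations, return the TimeTree."""
    keep = set()
    for tip in sampled:
        i = tip
        while i >= 0 and i not in keep:
            keep.add(i)
            i = node_parent[i]
    sampled_set = set(sampled)

    def kept_children(i):
        return [c for c in node_children[i] if c in keep]

    # reconstructed root: descend through single-kept-child chains
    root = 0
    while root not in sampled_set and len(kept_children(root)) == 1:
        root = kept_children(root)[0]

    parent, names, ages = [], [], []
    counter = [0]

    def build(i, par):
        # skip chains of unifurcations
        while i not in sampled_set and len(kept_children(i)) == 1:
            i = kept_children(i)[0]
        me = len(parent)
        parent.append(par)
        if i in sampled_set:
            counter[0] += 1
            names.append(f"t{counter[0]}")
            ages.append(0.0)
        else:
            names.append(None)
            ages.append(float(node_age[i]))
            for c in kept_children(i):
                build(c, me)

    import sys
    old = sys.getrecursionlimit()
    sys.setrecursionlimit(max(old, 10 * len(node_parent) + 100))
    try:
        build(root, -1)
    finally:
        sys.setrecursionlimit(old)
    return TimeTree(PhyloTree(parent, names), np.asarray(ages))


# ---------------------------------------------------------------------------
# Public tree simulators
# ---------------------------------------------------------------------------

def simulate_bd_tree(params: BDParams, seed=0,
                     root_age: float | None = None,
                     min_tips: int = 2) -> TimeTree:
    """Simulate a reconstructed extant birth-death timetree.

    Tip-count mode draws node depths from the conditioned depth
    distribution (coalescent point process); if ``root_age`` is given the
    root depth is fixed there and placed at a uniform position, matching
    the root-conditioned process.  Stopping-age mode runs the forward
    simulator from one origin lineage at age ``T``.
    """
    rng = _rng(seed)
    if params.n is not None:
        n = params.n
        if root_age is None:
            u = rng.uniform(size=n - 1)
            depths = bd_depth_ppf(u, params.lam, params.mu, params.rho)
        else:
            inner = bd_depth_ppf(
                rng.uniform(size=n - 2) * bd_depth_cdf(root_age, params.lam,
                                                       params.mu, params.rho),
                params.lam, params.mu, params.rho)
            pos = int(rng.integers(n - 1))
            depths = np.insert(inner, pos, root_age)
        return _cartesian_timetree(np.asarray(depths, float), rng)
    return _forward_piecewise_bd(
        [0.0, params.T], [params.lam], [params.mu], params.T, params.rho,
        rng, min_tips=min_tips, retry_cap=params.retry_cap)


def simulate_episodic_tree(bins: EpisodicRates, rho: float = 1.0, seed=0,
                           min_tips: int = 2, retry_cap: int = 1000
                           ) -> TimeTree:
    """Forward birth-death whose rates switch at the episodic bin edges.

    The origin lineage starts at the oldest bin edge.  With a single bin
    this is exactly :func:`simulate_bd_tree` in stopping-age mode under
    the same seed (shared code path and random stream).
    """
    return _forward_piecewise_bd(
        bins.edges, bins.lam, bins.mu, float(bins.edges[-1]), rho,
        _rng(seed), min_tips=min_tips, retry_cap=retry_cap)


# ---------------------------------------------------------------------------
# Branch-rate processes
# ---------------------------------------------------------------------------

def cir_transition_sample(r0, dt, m, v, theta, rng) -> float:
    """Exact CIR transition: r(t+dt) | r(t)=r0 via noncentral chi-square.

    Parameterized by stationary mean m, stationary variance v, and
    mean-reversion rate theta (sigma^2 = 2*theta*v/m).
    """
    df = 2.0 * m * m / v
    fac = v * (1.0 - math.exp(-theta * dt)) / (2.0 * m)
    if fac <= 0:
        return float(r0)
    nonc = r0 * math.exp(-theta * dt) / fac
    return float(fac * rng.noncentral_chisquare(df, nonc))


def cir_stationary_sample(m, v, rng, size=None):
    """Stationary CIR distribution: Gamma(shape m^2/v, scale v/m)."""
    return rng.gamma(m * m / v, v / m, size=size)


def simulate_rates(tree: TimeTree, params: ClockParams, seed=0) -> BranchRates:
    """Draw per-branch substitution rates under the chosen clock model.

    CIR: the instantaneous rate evolves root-to-tips by its exact
    transition law; the branch rate is the arithmetic mean of the parent-
    and child-node instantaneous rates (standard discretization for
    autocorrelated clocks).  UGAM: independent gamma multipliers with
    mean 1 and variance v.  Strict: all branches at the mean rate.
    """
    rng = _rng(seed)
    n = tree.tree.n_nodes
    rates = np.full(n, np.nan)
    if params.model == "strict":
        rates[1:] = params.mean_rate
        return BranchRates(rates)
    if params.model == "ugam":
        shape = 1.0 / params.v
        mult = rng.gamma(shape, params.v, size=n - 1)
        rates[1:] = params.mean_rate * mult
        return BranchRates(rates)
    node_rates = np.empty(n)
    node_rates[0] = cir_stationary_sample(params.mean_rate, params.v, rng)
    for i in tree.tree.preorder():
        if i == 0:
            continue
        dt = tree.ages[tree.tree.parent[i]] - tree.ages[i]
        node_rates[i] = cir_transition_sample(
            node_rates[tree.tree.parent[i]], dt, params.mean_rate, params.v,
            params.theta, rng)
        node_rates[i] = max(node_rates[i], 1e-300)
    rates[1:] = 0.5 * (node_rates[tree.tree.parent[1:]] + node_rates[1:])
    return BranchRates(rates, node_rates=node_rates)


# ---------------------------------------------------------------------------
# Substitution data
# ---------------------------------------------------------------------------

def simulate_subst_data(tree: TimeTree, rates: BranchRates, L: int = 1000,
                        mode: str = "lengths", seed=0) -> SubstData:
    """Generate substitution data from rate x duration branch expectations.

    ``lengths`` mode: observed length = Poisson(L * rate * duration) / L
    per branch, SE = sqrt(length / L).  ``alignment`` mode: amino-acid
    sites evolved under the 20-state equal-exchangeability model with
    branch length rate * duration.
    """
    rng = _rng(seed)
    if L < 1:
        raise ValueError("L must be >= 1")
    dur = tree.durations()
    expected = rates.rates * dur     # NaN at root
    if mode == "lengths":
        n = tree.tree.n_nodes
        lengths = np.full(n, np.nan)
        se = np.full(n, np.nan)
        counts = rng.poisson(L * expected[1:])
        lengths[1:] = counts / L
        se[1:] = np.sqrt(lengths[1:] / L)
        return SubstData(mode="lengths", L=L, lengths=lengths, se=se)
    if mode != "alignment":
        raise ValueError(f"unknown mode {mode!r}")
    seqs_int = {0: rng.integers(N_AA, size=L)}
    for i in tree.tree.preorder():
        if i == 0:
            continue
        b = expected[i]
        parent_seq = seqs_int[tree.tree.parent[i]]
        q = 1.0 - math.exp(-(N_AA / (N_AA - 1.0)) * b)
        hit = rng.random(L) < q
        child = parent_seq.copy()
        child[hit] = rng.integers(N_AA, size=int(hit.sum()))
        seqs_int[i] = child
    seqs = {tree.tree.names[i]: "".join(AA_ALPHABET[s] for s in seqs_int[i])
            for i in tree.tree.leaf_ids()}
    return SubstData(mode="alignment", L=L, sequences=seqs)


def anchor_calibrations_to_tree(tree_or_timetree, cals,
                                ages: np.ndarray | None = None
                                ) -> list[Calibration]:
    """Re-anchor a calibration table onto an arbitrary rooted topology.

    The packaged calibration fixture names clades, not the leaves of any
    particular tree; this maps each calibration to a distinct internal
    node — older constraints to deeper nodes — and rewrites its MRCA leaf
    pair accordingly.  Useful for exercising a full calibration set on a
    synthetic topology.
    """
    tt = tree_or_timetree
    tree = tt.tree if isinstance(tt, TimeTree) else tt
    if ages is None:
        if isinstance(tt, TimeTree):
            ages = tt.ages
        else:
            # no ages: use node depth as a proxy for relative antiquity
            ages = -tree.depths().astype(float)
    internal = sorted(tree.internal_ids(), key=lambda i: -ages[i])
    if len(cals) > len(internal):
        raise ValueError(f"{len(cals)} calibrations but only "
                         f"{len(internal)} internal nodes")

    def cal_age(c):
        if c.min_age is not None and c.max_age is not None:
            return 0.5 * (c.min_age + c.max_age)
        return c.min_age if c.min_age is not None else c.max_age

    out = []
    ranked = sorted(cals, key=lambda c: -cal_age(c))
    for cal, node in zip(ranked, internal):
        kids = tree.children[node]
        a = tree.names[tree.clade_leaves(kids[0])[0]]
        b = tree.names[tree.clade_leaves(kids[-1])[0]]
        out.append(Calibration(cal.label, a, b, cal.min_age, cal.max_age,
                               cal.soft_mass))
    return out


# ---------------------------------------------------------------------------
# Calibration generation
# ---------------------------------------------------------------------------

def make_calibrations(tree: TimeTree, nodes, style: str = "interval",
                      slack: float = 0.1, seed=0,
                      soft_mass: float = 0.05) -> list[Calibration]:
    """Generate fossil-like calibrations bracketing true node ages.

    min_age ~ U[(1-slack) * age, age]; interval style adds
    max_age ~ U[age, (1+slack) * age].  Every calibration is consistent
    (the true age lies inside its bounds).  With slack = 0 both bounds
    coincide with the true age exactly.
    """
    if style not in ("min-only", "interval"):
        raise ValueError(f"unknown calibration style {style!r}")
    rng = _rng(seed)
    cals = []
    for node in nodes:
        if tree.tree.is_leaf(node):
            raise ValueError(f"node {node} is a leaf; calibrations anchor "
                             "to internal nodes")
        kids = tree.tree.children[node]
        leaf_a = tree.tree.names[tree.tree.clade_leaves(kids[0])[0]]
        leaf_b = tree.tree.names[tree.tree.clade_leaves(kids[1])[0]]
        age = float(tree.ages[node])
        mn = float(rng.uniform((1.0 - slack) * age, age)) if slack > 0 else age
        mx = None
        if style == "interval":
            mx = float(rng.uniform(age, (1.0 + slack) * age)) if slack > 0 else age
        cals.append(Calibration(f"cal_{node}", leaf_a, leaf_b, mn, mx,
                                soft_mass))
    return cals
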