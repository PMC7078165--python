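"""Per-branch absolute substitution-rate estimators and their aggregation
into a rate-versus-time curve.

Two estimators of the branch-wise rate of molecular evolution, expected to
agree closely on clock-like data:

1. relative branch lengths (subst/site) divided by branch durations (My);
2. gross amino-acid changes between marginally reconstructed ancestral
   sequences at the branch's endpoints, divided by sites x duration.

The curve aggregates branch rates into contiguous time bins; each branch
contributes to every bin it overlaps, weighted by the overlapping
duration, so the duration-weighted mean of the curve equals the
duration-weighted mean of the branch rates exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dating import alignment_loglik
from .simulate import BranchRates, SubstData, N_AA
from .trees import PhyloTree, TimeTree


@dataclass
class RateCurve:
    """Duration-weighted mean rate per time bin (subst/site/My)."""

    edges: np.ndarray        # bin edges, Ma, increasing from 0
    rates: np.ndarray        # per-bin weighted mean rate (NaN if empty bin)
    branch_counts: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "bin_start_Ma": self.edges[:-1],
            "bin_end_Ma": self.edges[1:],
            "weighted_mean_rate": self.rates,
            "branch_count": self.branch_counts,
        })


def rates_from_branch_lengths(relative: np.ndarray, timetree: TimeTree
                              ) -> BranchRates:
    """Absolute rates: relative branch length / branch duration.

    ``relative[i]`` is the substitution length (subst/site) of the branch
    above node i.  Units of the result: subst/site/My.
    """
    relative = np.asarray(relative, float)
    dur = timetree.durations()
    n = timetree.tree.n_nodes
    rates = np.full(n, np.nan)
    for i in range(1, n):
        if dur[i] <= 0:
            raise ValueError(f"zero duration on branch above node {i}")
        rates[i] = relative[i] / dur[i]
    return BranchRates.unchecked(rates)


def _marginal_asr(tree: PhyloTree, blens: np.ndarray, mat: np.ndarray
                  ) -> dict[int, np.ndarray]:
    """Marginal ancestral-state posterior at every node, per site.

    Returns node -> (L, 20) posterior probabilities.  Uses the 20-state
    equal-exchangeability model: P(b) has diagonal e + (1-e)/20 and
    off-diagonal (1-e)/20 with e = exp(-20/19 b), so matrix products
    reduce to scaled sums.
    """
    L = mat.shape[1]
    nu = N_AA / (N_AA - 1.0)
    leaf_row = {leaf: r for r, leaf in enumerate(tree.leaf_ids())}

    up = {}
    for i in tree.postorder():
        if tree.is_leaf(i):
            P = np.zeros((L, N_AA))
            states = mat[leaf_row[i]]
            gap = states < 0
            P[np.arange(L), np.clip(states, 0, N_AA - 1)] = 1.0
            P[gap] = 1.0
            up[i] = P
            continue
        acc = np.ones((L, N_AA))
        for c in tree.children[i]:
            e = math.exp(-nu * blens[c])
            pc = up[c]
            acc *= (1.0 - e) / N_AA * pc.sum(axis=1, keepdims=True) + e * pc
        mx = acc.max(axis=1, keepdims=True)
        mx[mx == 0] = 1.0
        up[i] = acc / mx

    down = {0: np.ones((L, N_AA))}
    post = {}
    for i in tree.preorder():
        marg = up[i] * down[i]
        tot = marg.sum(axis=1, keepdims=True)
        tot[tot == 0] = 1.0
        post[i] = marg / tot
        for c in tree.children[i]:
            sibs = np.ones((L, N_AA))
            for s in tree.children[i]:
                if s is c:
                    continue
                e = math.exp(-nu * blens[s])
                ps = up[s]
                sibs *= (1.0 - e) / N_AA * ps.sum(axis=1, keepdims=True) + e * ps
            msg = down[i] * sibs
            e = math.exp(-nu * blens[c])
            dc = (1.0 - e) / N_AA * msg.sum(axis=1, keepdims=True) + e * msg
            mx = dc.max(axis=1, keepdims=True)
            mx[mx == 0] = 1.0
            down[c] = dc / mx
    return post


def _fit_global_rate(tree: PhyloTree, dur: np.ndarray, mat: np.ndarray
                     ) -> float:
    """ML global rate for branch lengths proportional to durations."""
    from scipy.optimize import minimize_scalar

    def nll(logm):
        b = math.exp(logm) * dur
        b[0] = 0.0
        return -alignment_loglik(tree, b, mat)

    res = minimize_scalar(nll, bounds=(-14, 2), method="bounded",
                          options={"xatol": 1e-4})
    return math.exp(res.x)


def rates_from_ancestral_changes(alignment: SubstData, tree: PhyloTree,
                                 timetree: TimeTree) -> BranchRates:
    """Per-branch rates from gross changes between reconstructed ancestors.

    Marginal ancestral reconstruction at every internal node under the
    equal-exchangeability amino-acid model (branch lengths = duration x a
    globally fitted rate); per branch, gross changes = number of positions
    whose most-probable states differ between parent and child; rate =
    changes / (effective sites x duration).  Ties in the child posterior
    are broken in fixed alphabet order and count as no change when the
    parent state is among the tied set.  Gap positions at a leaf are
    excluded from that branch's change count and its effective site count.
    """
    if alignment.mode != "alignment":
        raise ValueError("ancestral-change rates need alignment data")
    leaf_names = [tree.names[i] for i in tree.leaf_ids()]
    mat = alignment.encoded(leaf_names)
    dur = timetree.durations()
    m_hat = _fit_global_rate(tree, np.nan_to_num(dur), mat)
    blens = np.nan_to_num(dur) * m_hat
    post = _marginal_asr(tree, blens, mat)

    L = alignment.L
    leaf_row = {leaf: r for r, leaf in enumerate(tree.leaf_ids())}
    best = {}
    for i in range(tree.n_nodes):
        if tree.is_leaf(i):
            best[i] = mat[leaf_row[i]].astype(int)  # -1 marks gaps
        else:
            best[i] = np.argmax(post[i], axis=1)

    n = tree.n_nodes
    rates = np.full(n, np.nan)
    for i in range(1, n):
        p = tree.parent[i]
        bp, bc = best[p], best[i]
        valid = bc >= 0
        L_eff = int(valid.sum())
        if L_eff == 0 or dur[i] <= 0:
            raise ValueError(f"no usable sites or zero duration on branch "
                             f"above node {i}")
        differ = (bp != bc) & valid
        if not tree.is_leaf(i):
            # tie rule: no change if the parent state attains the child max
            pmax = post[i].max(axis=1)
            parent_prob = post[i][np.arange(L), bp]
            differ &= ~np.isclose(parent_prob, pmax)
        changes = int(differ.sum())
        rates[i] = changes / (L_eff * dur[i])
    return BranchRates.unchecked(rates)


def rate_curve(rates: BranchRates, timetree: TimeTree, bins: int = 10
               ) -> RateCurve:
    """Aggregate branch rates into a duration-weighted binned time series.

    Bins are equal-width over [0, root age]; each branch contributes to
    every bin it overlaps, weighted by the overlapping duration.
    """
    if bins < 1:
        raise ValueError("need at least one bin")
    edges = np.linspace(0.0, timetree.root_age, bins + 1)
    ages = timetree.ages
    parent = timetree.tree.parent
    wsum = np.zeros(bins)
    rsum = np.zeros(bins)
    counts = np.zeros(bins, dtype=int)
    for i in range(1, timetree.tree.n_nodes):
        t_c, t_p = ages[i], ages[parent[i]]
        r = rates.rates[i]
        for b in range(bins):
            ov = min(t_p, edges[b + 1]) - max(t_c, edges[b])
            if ov > 0:
                wsum[b] += ov
                rsum[b] += r * ov
                counts[b] += 1
    with np.errstate(invalid="ignore"):
        mean = np.where(wsum > 0, rsum / np.maximum(wsum, 1e-300), np.nan)
    return RateCurve(edges=edges, rates=mean, branch_counts=counts)
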