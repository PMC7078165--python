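"""Rooted-tree data model, time trees, calibrations, and phylogenetic file IO.

The package works on *fixed* rooted topologies.  ``PhyloTree`` stores the
topology plus optional branch lengths in expected substitutions per site;
``TimeTree`` adds node ages in millions of years (Ma) before present, with
leaves at age 0 and every parent strictly older than its children.  Branch
durations are always derived from ages, never stored separately.

Newick/nexus parsing and serialization are delegated to :mod:`dendropy`;
this module owns the array-based tree representation used by the samplers,
the calibration and diversity tables, and posterior-trace summaries
(mean, 95% highest-posterior-density intervals, ESS, relative differences).
"""

from __future__ import annotations

import io
import math
import warnings
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd


class TreeError(ValueError):
    """Invalid tree structure or tree-file content."""


class CalibrationError(ValueError):
    """Invalid calibration table content."""


# ---------------------------------------------------------------------------
# PhyloTree
# ---------------------------------------------------------------------------

class PhyloTree:
    """Rooted phylogeny with stable integer node ids (preorder, root = 0).

    Parameters
    ----------
    parent : sequence of int
        Parent id per node; -1 for the root (node 0).
    names : sequence of str or None
        Leaf names (internal nodes may be None or carry a label).
    blen : sequence of float or None, optional
        Branch length (subst/site) above each node; NaN/None for the root.
    """

    def __init__(self, parent, names, blen=None):
        self.parent = np.asarray(parent, dtype=int)
        self.names = list(names)
        n = len(self.parent)
        if len(self.names) != n:
            raise TreeError("names and parent arrays differ in length")
        if blen is None:
            self.blen = np.full(n, np.nan)
        else:
            self.blen = np.asarray(blen, dtype=float)
        self.children: list[list[int]] = [[] for _ in range(n)]
        roots = []
        for i, p in enumerate(self.parent):
            if p < 0:
                roots.append(i)
            else:
                self.children[p].append(i)
        if roots != [0]:
            raise TreeError(f"expected exactly one root with id 0, found {roots}")
        self._validate()

    # -- construction ------------------------------------------------------

    @classmethod
    def from_newick(cls, text: str, resolve_polytomies: bool = False) -> "PhyloTree":
        """Parse a rooted newick string.

        Raises :class:`TreeError` with the character offset for malformed
        input and for duplicate leaf names.  Polytomies are rejected unless
        ``resolve_polytomies`` is set, in which case they are resolved
        deterministically in input order with zero-length edges.
        """
        try:
            dtree = dendropy.Tree.get(
                data=text, schema="newick",
                suppress_internal_node_taxa=True,
                preserve_underscores=True,
            )
        except Exception as exc:  # dendropy raises several parse error types
            offset = getattr(exc, "column", None)
            loc = f" near character {offset}" if offset is not None else ""
            raise TreeError(f"malformed newick{loc}: {exc}") from exc
        return cls.from_dendropy(dtree, resolve_polytomies=resolve_polytomies)

    @classmethod
    def from_dendropy(cls, dtree: "dendropy.Tree",
                      resolve_polytomies: bool = False) -> "PhyloTree":
        if resolve_polytomies:
            # deterministic: dendropy resolves in child order with 0-length edges
            dtree.resolve_polytomies(limit=2, update_bipartitions=False)
        parent, names, blen = [], [], []
        index = {}
        for node in dtree.preorder_node_iter():
            i = len(parent)
            index[node] = i
            parent.append(index[node.parent_node] if node.parent_node else -1)
            label = node.taxon.label if node.taxon else node.label
            names.append(label)
            el = node.edge.length
            blen.append(np.nan if el is None else float(el))
        return cls(parent, names, blen)

    # -- validation / basic accessors --------------------------------------

    def _validate(self):
        leaves = self.leaf_ids()
        seen = {}
        for i in leaves:
            nm = self.names[i]
            if not nm:
                raise TreeError(f"leaf {i} has an empty name")
            if nm in seen:
                raise TreeError(f"duplicate leaf name {nm!r} (nodes {seen[nm]}, {i})")
            seen[nm] = i
        self._name_to_id = seen
        if self.n_leaves == 1:
            warnings.warn("degenerate single-leaf tree", stacklevel=3)
        for i, kids in enumerate(self.children):
            if len(kids) > 2:
                raise TreeError(
                    f"polytomy at node {i} ({len(kids)} children); "
                    "resolve with resolve_polytomies=True")
            if len(kids) == 1 and i != 0:
                raise TreeError(f"unifurcation at internal node {i}")

    @property
    def n_nodes(self) -> int:
        return len(self.parent)

    @property
    def n_leaves(self) -> int:
        return len(self.leaf_ids())

    def leaf_ids(self) -> list[int]:
        return [i for i, kids in enumerate(self.children) if not kids]

    def internal_ids(self) -> list[int]:
        return [i for i, kids in enumerate(self.children) if kids]

    def is_leaf(self, i: int) -> bool:
        return not self.children[i]

    def leaf_names(self) -> list[str]:
        return [self.names[i] for i in self.leaf_ids()]

    def id_of(self, name: str) -> int:
        try:
            return self._name_to_id[name]
        except KeyError:
            raise TreeError(f"unknown leaf name {name!r}") from None

    def postorder(self) -> list[int]:
        order = []
        stack = [0]
        while stack:
            i = stack.pop()
            order.append(i)
            stack.extend(self.children[i])
        order.reverse()
        return order

    def preorder(self) -> list[int]:
        order = []
        stack = [0]
        while stack:
            i = stack.pop()
            order.append(i)
            stack.extend(reversed(self.children[i]))
        return order

    def depths(self) -> np.ndarray:
        """Number of edges from the root to each node."""
        d = np.zeros(self.n_nodes, dtype=int)
        for i in self.preorder():
            if self.parent[i] >= 0:
                d[i] = d[self.parent[i]] + 1
        return d

    def mrca(self, a: str, b: str) -> int:
        """Most recent common ancestor of leaves named ``a`` and ``b``."""
        i, j = self.id_of(a), self.id_of(b)
        d = self.depths()
        while i != j:
            if d[i] >= d[j]:
                i = self.parent[i]
            else:
                j = self.parent[j]
        return int(i)

    def clade_leaves(self, node: int) -> list[int]:
        """Leaf ids in the clade rooted at ``node``."""
        out, stack = [], [node]
        while stack:
            i = stack.pop()
            if self.is_leaf(i):
                out.append(i)
            else:
                stack.extend(self.children[i])
        return out

    # -- serialization -----------------------------------------------------

    def to_newick(self, lengths=None, digits: int = 10) -> str:
        """Newick string; ``lengths`` overrides stored branch lengths."""
        bl = self.blen if lengths is None else np.asarray(lengths, float)
        fmt = f"%.{digits}g"

        def render(i):
            if self.is_leaf(i):
                s = self.names[i]
            else:
                s = "(" + ",".join(render(c) for c in self.children[i]) + ")"
            if self.parent[i] >= 0 and np.isfinite(bl[i]):
                s += ":" + fmt % bl[i]
            return s

        import sys
        old = sys.getrecursionlimit()
        sys.setrecursionlimit(max(old, 10 * self.n_nodes + 100))
        try:
            return render(0) + ";"
        finally:
            sys.setrecursionlimit(old)

    def copy(self) -> "PhyloTree":
        return PhyloTree(self.parent.copy(), list(self.names), self.blen.copy())


def read_newick(text: str, resolve_polytomies: bool = False) -> PhyloTree:
    """Parse a rooted newick string into a :class:`PhyloTree`."""
    return PhyloTree.from_newick(text, resolve_polytomies=resolve_polytomies)


def write_newick(tree: PhyloTree, digits: int = 10) -> str:
    return tree.to_newick(digits=digits)


# ---------------------------------------------------------------------------
# TimeTree
# ---------------------------------------------------------------------------

@dataclass
class TimeTree:
    """A phylogeny with node ages in Ma before present (leaves at 0).

    Branch durations are derived: duration(child) = age(parent) - age(child),
    strictly positive on every edge.
    """

    tree: PhyloTree
    ages: np.ndarray

    def __post_init__(self):
        self.ages = np.asarray(self.ages, dtype=float)
        if self.ages.shape != (self.tree.n_nodes,):
            raise TreeError("ages must have one entry per node")
        self.validate()

    def validate(self):
        for i in self.tree.leaf_ids():
            if abs(self.ages[i]) > 1e-9:
                raise TreeError(f"leaf {self.tree.names[i]!r} has nonzero age "
                                f"{self.ages[i]}")
        if self.tree.n_leaves > 1 and self.ages[0] <= 0:
            raise TreeError("root age must be positive")
        for i in range(1, self.tree.n_nodes):
            if self.ages[self.tree.parent[i]] <= self.ages[i]:
                raise TreeError(
                    f"age(parent) must exceed age(child) at node {i}: "
                    f"{self.ages[self.tree.parent[i]]} <= {self.ages[i]}")

    @property
    def root_age(self) -> float:
        return float(self.ages[0])

    def durations(self) -> np.ndarray:
        """Branch duration above each node (NaN for the root), in My."""
        d = np.full(self.tree.n_nodes, np.nan)
        p = self.tree.parent
        d[1:] = self.ages[p[1:]] - self.ages[1:]
        return d

    def to_newick(self, digits: int = 10) -> str:
        """Chronogram newick: branch lengths are durations in My."""
        return self.tree.to_newick(lengths=self.durations(), digits=digits)

    def total_tree_length(self) -> float:
        return float(np.nansum(self.durations()))


def timetree_from_newick(text: str) -> TimeTree:
    """Read an ultrametric newick chronogram (branch lengths = durations)."""
    tree = read_newick(text)
    ages = np.zeros(tree.n_nodes)
    # distance from root, then convert to age = root_height - dist
    dist = np.zeros(tree.n_nodes)
    for i in tree.preorder():
        if tree.parent[i] >= 0:
            bl = tree.blen[i]
            if not np.isfinite(bl):
                raise TreeError(f"missing branch length above node {i}")
            dist[i] = dist[tree.parent[i]] + bl
    height = max(dist[i] for i in tree.leaf_ids())
    for i in tree.leaf_ids():
        if abs(dist[i] - height) > 1e-6 * max(height, 1.0):
            raise TreeError(f"tree is not ultrametric at leaf {tree.names[i]!r}")
        dist[i] = height
    ages = height - dist
    ages[tree.leaf_ids()] = 0.0
    return TimeTree(tree, ages)


# ---------------------------------------------------------------------------
# Calibrations
# ---------------------------------------------------------------------------

@dataclass
class Calibration:
    """An MRCA-anchored age constraint with soft bounds.

    ``soft_mass`` is the fraction of prior probability outside the stated
    interval (default 0.05, i.e. 5% of the mass lies outside the bounds).
    """

    label: str
    leaf_a: str
    leaf_b: str
    min_age: float | None = None
    max_age: float | None = None
    soft_mass: float = 0.05

    def __post_init__(self):
        if self.min_age is None and self.max_age is None:
            raise CalibrationError(f"{self.label}: neither min nor max age set")
        # equality permitted: a point calibration pins the age exactly
        if (self.min_age is not None and self.max_age is not None
                and self.max_age < self.min_age):
            raise CalibrationError(
                f"{self.label}: max age {self.max_age} < min age {self.min_age}")
        if not 0 <= self.soft_mass < 1:
            raise CalibrationError(
                f"{self.label}: soft_mass {self.soft_mass} outside [0, 1)")


def read_calibrations(text: str, soft_mass: float = 0.05) -> list[Calibration]:
    """Parse a delimited calibration table.

    Expected columns: ``label``, ``leafA``, ``leafB``, ``min``, ``max``
    (min and max optional per row, but at least one must be present).
    Tab- and comma-delimited files are both accepted.
    """
    df = pd.read_csv(io.StringIO(text), sep=None, engine="python",
                     dtype={"label": str, "leafA": str, "leafB": str})
    if df.empty:
        warnings.warn("empty calibration table", stacklevel=2)
        return []
    required = {"label", "leafA", "leafB"}
    if not required.issubset(df.columns):
        raise CalibrationError(
            f"calibration table needs columns {sorted(required)}, "
            f"got {list(df.columns)}")
    out = []
    for _, row in df.iterrows():
        mn = row.get("min")
        mx = row.get("max")
        mn = None if mn is None or (isinstance(mn, float) and math.isnan(mn)) else float(mn)
        mx = None if mx is None or (isinstance(mx, float) and math.isnan(mx)) else float(mx)
        if mn is not None and mx is not None and mx <= mn:
            raise CalibrationError(
                f"{row['label']}: max age {mx} <= min age {mn}")
        out.append(Calibration(str(row["label"]), str(row["leafA"]),
                               str(row["leafB"]), mn, mx, soft_mass))
    return out


def calibrations_to_phylobayes(cals: list[Calibration]) -> str:
    """Export calibrations as a PhyloBayes-style calibration block.

    Each line: ``label  upper  lower`` with -1 for an unset bound.
    """
    lines = [str(len(cals))]
    for c in cals:
        up = -1 if c.max_age is None else c.max_age
        lo = -1 if c.min_age is None else c.min_age
        lines.append(f"{c.label}\t{up}\t{lo}")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# Diversity table
# ---------------------------------------------------------------------------

@dataclass
class DiversitySpec:
    """Described extant species counts and sampled tip counts per clade."""

    clades: dict[str, tuple[int, int]] = field(default_factory=dict)

    def add(self, label: str, described: int, sampled: int = 0):
        if described < 1:
            raise ValueError(f"{label}: described count must be >= 1")
        if not 0 <= sampled <= described:
            raise ValueError(
                f"{label}: sampled count {sampled} outside [0, {described}]")
        self.clades[label] = (int(described), int(sampled))

    def total_described(self) -> int:
        return sum(d for d, _ in self.clades.values())

    def total_sampled(self) -> int:
        return sum(s for _, s in self.clades.values())


def read_diversity(text: str) -> DiversitySpec:
    """Parse a delimited diversity table with columns clade, described[, sampled]."""
    df = pd.read_csv(io.StringIO(text), sep=None, engine="python")
    spec = DiversitySpec()
    for _, row in df.iterrows():
        sampled = int(row["sampled"]) if "sampled" in df.columns and not pd.isna(row.get("sampled")) else 0
        spec.add(str(row["clade"]), int(row["described"]), sampled)
    return spec


def load_default_calibrations() -> list[Calibration]:
    """The packaged fossil-calibration fixture.

    28 constraints on arthropod clades: 27 carry a minimum age (five of
    those also a maximum) and one (Mandibulata) is a maximum-only
    constraint.  The anchor leaf names are ``<Clade>_rep1/2`` placeholders:
    the table constrains named clades, and mapping the anchors onto a
    user-supplied topology (whose taxon sampling the table cannot know)
    is the caller's responsibility.  The Lobopodia minimum is stored at
    its tabulated precision, 528.82 Ma.
    """
    from importlib.resources import files
    text = files("chronodiv.data").joinpath("calibrations_default.tsv").read_text()
    return read_calibrations(text)


def load_default_diversity() -> DiversitySpec:
    """Described extant species counts for 12 chelicerate/pycnogonid clades."""
    from importlib.resources import files
    text = files("chronodiv.data").joinpath("diversity_default.tsv").read_text()
    return read_diversity(text)


# ---------------------------------------------------------------------------
# Posterior traces and HPD summaries
# ---------------------------------------------------------------------------

def hpd_interval(samples, mass: float = 0.95) -> tuple[float, float]:
    """Highest-posterior-density interval over stored samples.

    The smallest-width window containing ``ceil(mass * N)`` of the sorted
    samples.  Degenerate (constant) samples give a zero-width interval.
    """
    x = np.sort(np.asarray(samples, dtype=float))
    n = x.size
    if n == 0:
        raise ValueError("no samples")
    k = int(math.ceil(mass * n))
    k = min(max(k, 1), n)
    widths = x[k - 1:] - x[:n - k + 1]
    j = int(np.argmin(widths))
    return float(x[j]), float(x[j + k - 1])


def trace_rel_diff(a, b) -> float:
    """Relative difference between two traces of one parameter.

    ``2|mean_a - mean_b| / (sd_a + sd_b)`` — the tracecomp-style statistic;
    0 for identical traces, below 1 indicates agreement.
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    denom = a.std() + b.std()
    if denom == 0:
        return 0.0 if a.mean() == b.mean() else np.inf
    return float(2 * abs(a.mean() - b.mean()) / denom)


def effective_sample_size(samples) -> float:
    """ESS via autocorrelation-time estimation (arviz)."""
    import arviz
    x = np.asarray(samples, float)
    if x.size < 4 or x.std() == 0:
        return float(x.size)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return float(arviz.ess(x[None, :]))


class PosteriorTrace:
    """Ordered MCMC samples of a named parameter vector with summaries."""

    def __init__(self, samples: dict[str, np.ndarray]):
        self.samples = {k: np.asarray(v, float) for k, v in samples.items()}
        sizes = {v.shape[0] for v in self.samples.values()}
        if len(sizes) > 1:
            raise ValueError("all parameters must have the same sample count")
        self.n_samples = sizes.pop() if sizes else 0
        if self.n_samples < 1:
            raise ValueError("trace must contain at least one sample")

    def names(self) -> list[str]:
        return list(self.samples)

    def __getitem__(self, name: str) -> np.ndarray:
        return self.samples[name]

    def ess(self) -> dict[str, float]:
        return {k: effective_sample_size(v) for k, v in self.samples.items()}

    def rel_diff(self, other: "PosteriorTrace | None" = None) -> dict[str, float]:
        """Per-parameter relative difference vs. another chain (or chain halves)."""
        out = {}
        for k, v in self.samples.items():
            if other is None:
                h = v.shape[0] // 2
                out[k] = trace_rel_diff(v[:h], v[h:])
            else:
                out[k] = trace_rel_diff(v, other.samples[k])
        return out

    def summary(self, mass: float = 0.95) -> pd.DataFrame:
        rows = []
        for k, v in self.samples.items():
            lo, hi = hpd_interval(v, mass)
            rows.append({"parameter": k, "mean": float(v.mean()),
                         "hpd_lower": lo, "hpd_upper": hi})
        return pd.DataFrame(rows).set_index("parameter")


# ---------------------------------------------------------------------------
# Chronogram sample files ("datedist"-like) and annotated nexus
# ---------------------------------------------------------------------------

def write_chronogram_samples(age_samples: np.ndarray, tree: PhyloTree,
                             mass: float = 0.95) -> tuple[str, pd.DataFrame]:
    """Serialize posterior age samples as one newick timetree per line.

    ``age_samples`` is (n_samples, n_nodes) of node ages in Ma.  Returns the
    sample-file text plus a per-node summary table (mean, 95% HPD).  Refuses
    to serialize a sample violating age(parent) > age(child).
    """
    age_samples = np.atleast_2d(np.asarray(age_samples, float))
    if age_samples.shape[1] != tree.n_nodes:
        raise ValueError("age samples must have one column per node")
    p = tree.parent
    lines = []
    for s, ages in enumerate(age_samples):
        bad = np.where(ages[p[1:]] <= ages[1:])[0]
        if bad.size:
            raise TreeError(
                f"sample {s}: age(parent) <= age(child) at node {bad[0] + 1}")
        durations = np.full(tree.n_nodes, np.nan)
        durations[1:] = ages[p[1:]] - ages[1:]
        lines.append(tree.to_newick(lengths=durations))
    rows = []
    for i in range(tree.n_nodes):
        lo, hi = hpd_interval(age_samples[:, i], mass)
        rows.append({"node": i, "name": tree.names[i] or "",
                     "mean_age": float(age_samples[:, i].mean()),
                     "hpd_lower": lo, "hpd_upper": hi})
    return "\n".join(lines) + "\n", pd.DataFrame(rows).set_index("node")


def write_annotated_nexus(summary: pd.DataFrame, tree: PhyloTree) -> str:
    """Summary chronogram in nexus with figtree-style 95% HPD comments."""
    ages = summary["mean_age"].to_numpy()
    durations = np.full(tree.n_nodes, np.nan)
    durations[1:] = ages[tree.parent[1:]] - ages[1:]
    durations = np.maximum(durations, 0.0)

    def render(i):
        if tree.is_leaf(i):
            s = tree.names[i]
        else:
            s = "(" + ",".join(render(c) for c in tree.children[i]) + ")"
        lo, hi = summary.loc[i, "hpd_lower"], summary.loc[i, "hpd_upper"]
        s += f"[&age_mean={ages[i]:.6g},age_95%HPD={{{lo:.6g},{hi:.6g}}}]"
        if tree.parent[i] >= 0:
            s += ":%.10g" % durations[i]
        return s

    names = tree.leaf_names()
    taxa = "\n".join(f"\t\t{nm}" for nm in names)
    return ("#NEXUS\nbegin taxa;\n\tdimensions ntax=%d;\n\ttaxlabels\n%s\n;\nend;\n"
            "begin trees;\n\ttree SUMMARY = [&R] %s;\nend;\n"
            % (len(names), taxa, render(0)))
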