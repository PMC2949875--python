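"""I/O and containers for time-scaled trees, tip-area tables and MCMC traces.

Trees are rooted, strictly bifurcating, ultrametric chronograms with branch
lengths in million years (Ma).  Node ages are measured backward from the
present: every tip sits at age 0 (within tolerance) and the root age equals
the maximum tip-to-root path length.  Newick parsing and writing go through
dendropy; the in-memory representation is a flat array-based structure that
the likelihood code can traverse cheaply.

Tip-area tables map taxon labels to geographic ranges over the four-area
coding used throughout the package: A = Indian Subcontinent, B = Southeast
Asia (including the Sunda shelf), C = Philippines, D = east of the Wallace
Line.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd

AREA_CODES = "ABCD"

#: Relative ultrametricity tolerance (fraction of root age).
DEFAULT_ULTRAMETRIC_TOL = 1e-6


class PhyloError(ValueError):
    """Malformed tree, tip table or trace input."""


class Phylogeny:
    """Rooted bifurcating ultrametric tree with branch lengths in Ma.

    Nodes are integer ids ``0..n_nodes-1``.  ``parent[v]`` is -1 at the
    root; ``children[v]`` is a pair of child ids for internal nodes and
    ``(-1, -1)`` for tips; ``blen[v]`` is the length of the branch above
    ``v`` (0 at the root); ``labels[v]`` is the taxon label for tips and
    ``None`` (or an optional name) for internal nodes.
    """

    __slots__ = ("parent", "children", "blen", "labels", "_post", "_ages")

    def __init__(self, parent, children, blen, labels):
        self.parent = np.asarray(parent, dtype=np.int64)
        self.children = np.asarray(children, dtype=np.int64)
        self.blen = np.asarray(blen, dtype=float)
        self.labels = list(labels)
        self._post = None
        self._ages = None
        self._validate_shape()

    # -- structure ---------------------------------------------------------

    def _validate_shape(self):
        n = self.parent.shape[0]
        if self.children.shape != (n, 2) or self.blen.shape != (n,):
            raise PhyloError("inconsistent node arrays")
        roots = np.flatnonzero(self.parent < 0)
        if roots.size != 1:
            raise PhyloError("tree must have exactly one root")
        if np.any(self.blen < 0):
            raise PhyloError("negative branch length")

    @property
    def n_nodes(self) -> int:
        return self.parent.shape[0]

    @property
    def root(self) -> int:
        return int(np.flatnonzero(self.parent < 0)[0])

    def is_tip(self, v: int) -> bool:
        return self.children[v, 0] < 0

    @property
    def tips(self) -> list[int]:
        return [v for v in range(self.n_nodes) if self.is_tip(v)]

    @property
    def n_tips(self) -> int:
        return len(self.tips)

    @property
    def tip_labels(self) -> list[str]:
        return [self.labels[v] for v in self.tips]

    def postorder(self) -> tuple[int, ...]:
        """Node ids, children always before parents (cached)."""
        if self._post is None:
            order, stack = [], [self.root]
            while stack:
                v = stack.pop()
                order.append(v)
                if not self.is_tip(v):
                    stack.extend(self.children[v])
            self._post = tuple(reversed(order))
        return self._post

    # -- ages --------------------------------------------------------------

    @property
    def ages(self) -> np.ndarray:
        """Node ages in Ma before present (root = root_age, tips ~ 0)."""
        if self._ages is None:
            depth = np.zeros(self.n_nodes)
            for v in reversed(self.postorder()):  # preorder
                p = self.parent[v]
                if p >= 0:
                    depth[v] = depth[p] + self.blen[v]
            self._ages = depth.max() - depth
        return self._ages

    @property
    def root_age(self) -> float:
        return float(self.ages[self.root])

    def is_ultrametric(self, tol_rel: float = DEFAULT_ULTRAMETRIC_TOL) -> bool:
        tol = tol_rel * max(self.root_age, 1.0 if self.root_age == 0 else self.root_age)
        tip_ages = self.ages[self.tips]
        return bool(np.all(np.abs(tip_ages) <= max(tol, 1e-12)))

    def assert_ultrametric(self, tol_rel: float = DEFAULT_ULTRAMETRIC_TOL):
        if not self.is_ultrametric(tol_rel):
            raise PhyloError("tree is not ultrametric: tip ages differ")

    # -- queries -----------------------------------------------------------

    def tip_id(self, label: str) -> int:
        for v in self.tips:
            if self.labels[v] == label:
                return v
        raise PhyloError(f"unknown tip label: {label!r}")

    def mrca(self, *tip_labels: str) -> int:
        """Most recent common ancestor of the named tips."""
        if len(tip_labels) < 2:
            raise PhyloError("mrca needs at least two tip labels")
        paths = []
        for lab in tip_labels:
            v, path = self.tip_id(lab), []
            while v >= 0:
                path.append(v)
                v = self.parent[v]
            paths.append(set(path))
        common = set.intersection(*paths)
        # deepest common ancestor = smallest age among common
        return min(common, key=lambda v: self.ages[v])

    def rescaled(self, target_root_age: float) -> "Phylogeny":
        """Copy with all branch lengths scaled so the root age hits target."""
        if self.root_age <= 0:
            raise PhyloError("cannot rescale a zero-depth tree")
        f = target_root_age / self.root_age
        return Phylogeny(self.parent, self.children, self.blen * f, self.labels)

    def relabeled(self, mapping: dict[str, str]) -> "Phylogeny":
        labels = [mapping.get(l, l) if l is not None else None for l in self.labels]
        return Phylogeny(self.parent, self.children, self.blen, labels)


# -- Newick ---------------------------------------------------------------


def parse_newick(
    text: str,
    *,
    ultrametric_tol: float = DEFAULT_ULTRAMETRIC_TOL,
    require_ultrametric: bool = True,
) -> Phylogeny:
    """Parse a Newick string into a :class:`Phylogeny`.

    Rejects non-binary nodes, missing branch lengths on non-root edges and
    (by default) non-ultrametric trees.
    """
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises assorted reader errors
        raise PhyloError(f"malformed Newick: {exc}") from exc

    dnodes = list(dtree.preorder_node_iter())
    if not dnodes:
        raise PhyloError("empty tree")
    index = {id(nd): i for i, nd in enumerate(dnodes)}
    n = len(dnodes)
    parent = np.full(n, -1, dtype=np.int64)
    children = np.full((n, 2), -1, dtype=np.int64)
    blen = np.zeros(n)
    labels: list[str | None] = [None] * n

    for nd in dnodes:
        i = index[id(nd)]
        kids = nd.child_nodes()
        if len(kids) not in (0, 2):
            raise PhyloError(
                f"non-binary node with {len(kids)} children; trees must be bifurcating"
            )
        for j, kid in enumerate(kids):
            children[i, j] = index[id(kid)]
            parent[index[id(kid)]] = i
        if nd.parent_node is not None:
            if nd.edge.length is None:
                raise PhyloError("missing branch length on a non-root edge")
            blen[i] = float(nd.edge.length)
        else:
            blen[i] = float(nd.edge.length or 0.0)
        if nd.taxon is not None:
            labels[i] = nd.taxon.label
        elif nd.label:
            labels[i] = nd.label

    for v in range(n):
        if children[v, 0] < 0 and labels[v] is None:
            raise PhyloError("unlabeled tip")

    tree = Phylogeny(parent, children, blen, labels)
    if len(set(tree.tip_labels)) != tree.n_tips:
        raise PhyloError("duplicate tip labels")
    if require_ultrametric:
        tree.assert_ultrametric(ultrametric_tol)
    return tree


def write_newick(tree: Phylogeny) -> str:
    """Serialize with full float precision (round-trips through parse_newick)."""

    def fmt(v: int) -> str:
        if tree.is_tip(v):
            body = tree.labels[v]
        else:
            l, r = tree.children[v]
            body = f"({fmt(l)},{fmt(r)})"
        if tree.parent[v] < 0:
            return body
        return f"{body}:{float(tree.blen[v])!r}"

    return fmt(tree.root) + ";"


# -- tip-area tables -------------------------------------------------------


def read_tip_areas(tsv_text: str, *, area_codes: str = AREA_CODES) -> dict[str, frozenset[str]]:
    """Parse a two-column TSV ``taxon<TAB>areas`` into a tip-area table.

    ``areas`` is a string over the area alphabet (e.g. ``A`` or ``AB`` for a
    widespread tip).  A single header row beginning with ``taxon`` is
    skipped if present.
    """
    table: dict[str, frozenset[str]] = {}
    for lineno, raw in enumerate(tsv_text.splitlines(), 1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise PhyloError(f"line {lineno}: expected 2 tab-separated columns")
        taxon, areas = parts[0].strip(), parts[1].strip()
        if lineno == 1 and taxon.lower() in ("taxon", "tip", "label", "species"):
            continue
        if taxon in table:
            raise PhyloError(f"duplicate tip {taxon!r}")
        bad = [a for a in areas if a not in area_codes]
        if bad or not areas:
            raise PhyloError(
                f"line {lineno}: unknown area code {bad[0]!r}" if bad
                else f"line {lineno}: empty area set for {taxon!r}"
            )
        table[taxon] = frozenset(areas)
    if not table:
        raise PhyloError("empty tip-area table")
    return table


def write_tip_areas(table: dict[str, frozenset[str]]) -> str:
    lines = ["taxon\tareas"]
    for taxon in sorted(table):
        lines.append(f"{taxon}\t{''.join(sorted(table[taxon]))}")
    return "\n".join(lines) + "\n"


def validate_tip_areas(table: dict[str, frozenset[str]], tree: Phylogeny):
    """Check the table keys exactly match the tree's tips."""
    tips = set(tree.tip_labels)
    keys = set(table)
    missing = tips - keys
    extra = keys - tips
    if missing:
        raise PhyloError(f"tips missing from area table: {sorted(missing)}")
    if extra:
        raise PhyloError(f"area-table entries not in tree: {sorted(extra)}")


# -- MCMC traces -----------------------------------------------------------


@dataclass
class MCMCTrace:
    """Ordered MCMC samples with a log-likelihood column (nats).

    ``burn_in`` counts leading samples excluded from all estimators.
    """

    samples: pd.DataFrame
    burn_in: int = 0

    def __post_init__(self):
        if "lnL" not in self.samples.columns:
            raise PhyloError("trace has no lnL column")
        n = len(self.samples)
        if self.burn_in < 0 or self.burn_in >= n:
            raise PhyloError(f"burn-in {self.burn_in} >= {n} samples")
        if n - self.burn_in < 2:
            raise PhyloError("fewer than 2 post-burn-in samples")
        lnl = self.samples["lnL"].to_numpy(dtype=float)
        if not np.all(np.isfinite(lnl)):
            raise PhyloError("non-finite lnL in trace")

    @property
    def lnl(self) -> np.ndarray:
        """Post-burn-in log-likelihood samples."""
        return self.samples["lnL"].to_numpy(dtype=float)[self.burn_in:]

    @property
    def n_post(self) -> int:
        return len(self.samples) - self.burn_in


def read_trace(tsv_text: str, burn_in: int = 0) -> MCMCTrace:
    """Parse a TSV trace with a header naming an ``lnL`` column.

    Column matching is case-insensitive (``lnL``, ``lnl``, ``likelihood``
    and Tracer-style ``lnlikelihood`` are all accepted).
    """
    try:
        df = pd.read_csv(io.StringIO(tsv_text), sep="\t")
    except Exception as exc:
        raise PhyloError(f"unreadable trace: {exc}") from exc
    lnl_col = None
    for col in df.columns:
        if str(col).lower() in ("lnl", "likelihood", "lnlikelihood", "loglik", "lnlik"):
            lnl_col = col
            break
    if lnl_col is None:
        raise PhyloError("no lnL column in trace header")
    df = df.rename(columns={lnl_col: "lnL"})
    return MCMCTrace(samples=df, burn_in=burn_in)


def write_trace(trace: MCMCTrace) -> str:
    df = trace.samples.copy()
    if "state" not in df.columns:
        df.insert(0, "state", np.arange(len(df)))
    return df.to_csv(sep="\t", index=False)
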