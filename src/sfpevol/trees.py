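"""Rooted phylogenies with branch lengths and per-tip mating-system labels.

A :class:`Phylogeny` is a lightweight array representation (parent pointers
in postorder) built from newick via dendropy.  Each non-root node owns the
branch above it, so "branch b" is identified by its child node index.
"""

from __future__ import annotations

import dendropy
import numpy as np

UNI = "uni"
MULTI = "multi"
MATING_LABELS = (UNI, MULTI)


class TreeError(ValueError):
    pass


class Phylogeny:
    """Rooted tree stored as parent pointers in postorder (root is last).

    Attributes
    ----------
    parent : int array, -1 for the root
    blen : float array, branch length above each node (0 for the root)
    names : list of tip name or None for internal nodes
    mating : dict tip name -> "uni" | "multi" (may be empty)
    """

    def __init__(self, parent, blen, names, mating=None):
        self.parent = np.asarray(parent, dtype=int)
        self.blen = np.asarray(blen, dtype=float)
        self.names = list(names)
        self.mating = dict(mating or {})
        n = self.parent.size
        if self.blen.size != n or len(self.names) != n:
            raise TreeError("parent/blen/names size mismatch")
        self.children: list[list[int]] = [[] for _ in range(n)]
        root = None
        for v, p in enumerate(self.parent):
            if p < 0:
                if root is not None:
                    raise TreeError("more than one root")
                root = v
            else:
                if p <= v:
                    raise TreeError("nodes must be numbered in postorder")
                self.children[p].append(v)
        if root != n - 1:
            raise TreeError("root must be the last node")
        self.root = n - 1
        self.tip_ids = np.array(
            [v for v in range(n) if not self.children[v]], dtype=int
        )
        self.internal_postorder = [v for v in range(n) if self.children[v]]
        tip_names = [self.names[v] for v in self.tip_ids]
        if any(nm is None for nm in tip_names):
            raise TreeError("every tip needs a name")
        if len(set(tip_names)) != len(tip_names):
            raise TreeError("tip names must be unique")
        if np.any(self.blen[: self.root] < 0) or not np.all(np.isfinite(self.blen)):
            raise TreeError("branch lengths must be finite and non-negative")
        self.tip_index = {self.names[v]: v for v in self.tip_ids}
        for name, lab in self.mating.items():
            if name not in self.tip_index:
                raise TreeError(f"mating label for unknown tip {name!r}")
            if lab not in MATING_LABELS:
                raise TreeError(f"mating label must be one of {MATING_LABELS}")

    # ------------------------------------------------------------------ io
    @classmethod
    def from_newick(cls, source: str, mating=None) -> "Phylogeny":
        """Parse a rooted newick string (or text of a file)."""
        try:
            dt = dendropy.Tree.get(
                data=source, schema="newick", preserve_underscores=True
            )
        except Exception as exc:  # dendropy raises several parse error types
            raise TreeError(f"newick syntax error: {exc}") from exc
        index = {}
        parent, blen, names = [], [], []
        for i, nd in enumerate(dt.postorder_node_iter()):
            index[nd] = i
            parent.append(-1)
            blen.append(nd.edge.length if nd.edge.length is not None else 0.0)
            names.append(nd.taxon.label if nd.taxon is not None else None)
        for nd in dt.postorder_node_iter():
            for ch in nd.child_nodes():
                parent[index[ch]] = index[nd]
        return cls(parent, blen, names, mating=mating)

    def to_newick(self) -> str:
        def fmt(v: int) -> str:
            if not self.children[v]:
                core = self.names[v]
            else:
                core = "(" + ",".join(fmt(c) for c in self.children[v]) + ")"
            if v == self.root:
                return core
            return f"{core}:{self.blen[v]:.12g}"

        return fmt(self.root) + ";"

    # ----------------------------------------------------------- accessors
    @property
    def n_nodes(self) -> int:
        return self.parent.size

    @property
    def n_tips(self) -> int:
        return self.tip_ids.size

    @property
    def tip_names(self) -> list[str]:
        return [self.names[v] for v in self.tip_ids]

    def with_branch_lengths(self, blen) -> "Phylogeny":
        return Phylogeny(self.parent.copy(), blen, list(self.names), dict(self.mating))

    def scaled(self, factor: float) -> "Phylogeny":
        return self.with_branch_lengths(self.blen * factor)

    def descendant_tips(self) -> list[list[int]]:
        """Per node, indices of descendant tips (a tip descends from itself)."""
        out: list[list[int]] = [[] for _ in range(self.n_nodes)]
        for v in range(self.n_nodes):
            if not self.children[v]:
                out[v] = [v]
            else:
                for c in self.children[v]:
                    out[v].extend(out[c])
        return out

    def require_mating_labels(self) -> None:
        missing = [nm for nm in self.tip_names if nm not in self.mating]
        if missing:
            raise TreeError(f"tips without mating label: {missing}")

    def foreground_mask(self, foreground: str = MULTI) -> np.ndarray:
        """Boolean mask over nodes marking foreground branches.

        A tip branch is foreground iff the tip carries the foreground label;
        an internal branch is foreground iff *all* of its descendant tips do
        (parsimony-style assignment).  The root entry is always False.
        """
        if foreground not in MATING_LABELS:
            raise TreeError(f"foreground must be one of {MATING_LABELS}")
        self.require_mating_labels()
        desc = self.descendant_tips()
        mask = np.zeros(self.n_nodes, dtype=bool)
        for v in range(self.n_nodes):
            if v == self.root:
                continue
            mask[v] = all(self.mating[self.names[t]] == foreground for t in desc[v])
        return mask

    def node_label(self, v: int) -> str:
        if self.names[v] is not None:
            return self.names[v]
        desc = self.descendant_tips()[v]
        return "mrca(" + "+".join(sorted(self.names[t] for t in desc)) + ")"
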