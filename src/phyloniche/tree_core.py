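"""Rooted phylogenies: Newick I/O, validation, and patristic distances.

The tree is the substrate for every downstream computation — patristic
distances feed the community-structure indices, and the node/edge structure
feeds ancestral-state reconstruction.  Trees are stored as :class:`Phylogeny`,
a thin validated wrapper around a :class:`dendropy.Tree` that fixes the
conventions used throughout the package:

* the tree is rooted exactly as written; no re-rooting is ever performed;
* tip labels are unique, non-empty strings;
* branch lengths are non-negative; a missing length defaults to 1.0 with a
  logged warning (Mesquite-style unit branches);
* internal node labels / support values are parsed and kept but ignored by
  all computations.
"""

from __future__ import annotations

import io
import logging
import warnings
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "Phylogeny",
    "TreeFormatError",
    "read_newick",
    "write_newick",
    "patristic_distances",
]


class TreeFormatError(ValueError):
    """Raised when a Newick string violates the tree invariants."""


@dataclass
class Phylogeny:
    """A rooted phylogeny with branch lengths.

    Parameters
    ----------
    tree
        The underlying dendropy tree (rooted; every edge has a finite
        non-negative length after validation).

    Attributes
    ----------
    tip_labels : list of str
        Tip labels in a stable (leaf-iteration) order.
    """

    tree: dendropy.Tree
    tip_labels: list[str] = field(init=False)

    def __post_init__(self) -> None:
        self.tip_labels = [lf.taxon.label for lf in self.tree.leaf_node_iter()]
        self._validate()

    # -- invariants ---------------------------------------------------------
    def _validate(self) -> None:
        seen: set[str] = set()
        for label in self.tip_labels:
            if not label:
                raise TreeFormatError("empty tip label")
            if label in seen:
                raise TreeFormatError(f"duplicate tip label {label!r}")
            seen.add(label)
        n_missing = 0
        any_positive = False
        for edge in self.tree.preorder_edge_iter():
            if edge.head_node is self.tree.seed_node:
                continue
            if edge.length is None:
                edge.length = 1.0
                n_missing += 1
            if edge.length < 0:
                raise TreeFormatError(f"negative branch length {edge.length}")
            if edge.length > 0:
                any_positive = True
        if n_missing:
            logger.warning(
                "%d branch lengths missing; defaulted to 1.0", n_missing
            )
        if len(self.tip_labels) >= 2 and not any_positive:
            raise TreeFormatError("all branch lengths are zero")

    # -- convenience --------------------------------------------------------
    @property
    def n_tips(self) -> int:
        return len(self.tip_labels)

    def copy(self) -> "Phylogeny":
        return Phylogeny(self.tree.clone(depth=1))

    def prune_to(self, labels: set[str]) -> "Phylogeny":
        """Restrict to the given tips, re-summing branch lengths along
        retained paths (unary internal nodes are suppressed)."""
        sub = self.tree.clone(depth=1)
        taxa = [t for t in sub.taxon_namespace if t.label in labels]
        missing = labels - {t.label for t in taxa}
        if missing:
            raise KeyError(f"labels not in tree: {sorted(missing)}")
        sub.retain_taxa(taxa)
        return Phylogeny(sub)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"Phylogeny(n_tips={self.n_tips})"


def read_newick(path_or_text: str) -> Phylogeny:
    """Parse a Newick string or file into a validated :class:`Phylogeny`.

    Accepts either a literal Newick string (detected by the presence of
    ``(`` or a trailing ``;``) or a path to a ``.nwk``/``.tre`` file.
    Polytomies are preserved as written.

    Raises
    ------
    TreeFormatError
        On duplicate/empty tip labels or unparseable input.
    """
    text = path_or_text
    if "(" not in text and not text.rstrip().endswith(";"):
        with open(path_or_text, encoding="utf-8") as fh:
            text = fh.read()
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            tree = dendropy.Tree.get(
                data=text,
                schema="newick",
                preserve_underscores=True,
                suppress_internal_node_taxa=True,
            )
    except Exception as exc:  # dendropy raises several error types
        msg = str(exc)
        if "Duplicate taxon labels" in msg:
            dup = msg.rsplit("Duplicate taxon labels:", 1)[1].strip()
            raise TreeFormatError(f"duplicate tip label {dup}") from exc
        raise TreeFormatError(f"cannot parse Newick: {msg}") from exc
    tree.is_rooted = True
    return Phylogeny(tree)


def write_newick(tree: Phylogeny, path: str | None = None) -> str:
    """Serialize to Newick with branch lengths at 6 significant digits.

    Returns the string; also writes to ``path`` when given.
    """
    buf = io.StringIO()
    tree.tree.write(
        file=buf,
        schema="newick",
        suppress_rooting=True,
        unquoted_underscores=True,
        real_value_format_specifier=".6g",
    )
    text = buf.getvalue()
    if path is not None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(text)
    return text


def patristic_distances(tree: Phylogeny) -> pd.DataFrame:
    """Pairwise patristic (path-sum) distances between tips.

    d(i, j) is the sum of branch lengths along the unique path joining tips
    i and j; the result is a symmetric, zero-diagonal DataFrame indexed by
    tip labels in ``tree.tip_labels`` order.

    Raises
    ------
    ValueError
        If the tree has fewer than two tips ("degenerate tree").
    """
    labels = tree.tip_labels
    if len(labels) < 2:
        raise ValueError("degenerate tree: patristic distances need >=2 tips")
    pdm = tree.tree.phylogenetic_distance_matrix()
    taxa = {lf.taxon.label: lf.taxon for lf in tree.tree.leaf_node_iter()}
    n = len(labels)
    mat = np.zeros((n, n))
    for i, a in enumerate(labels):
        for j in range(i + 1, n):
            d = pdm.patristic_distance(taxa[a], taxa[labels[j]])
            mat[i, j] = mat[j, i] = d
    return pd.DataFrame(mat, index=labels, columns=labels)
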