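"""Neighbor-joining trees and support-thresholded monophyly scoring.

The NJ builder is plumbing: it turns a distance matrix into an unrooted
tree so the monophyly machinery can be exercised without an external
maximum-likelihood program. Real analyses typically consume externally
built trees (with bootstrap supports as internal-node labels) through
:func:`barcodekit.seqio.read_newick`.

Monophyly is assessed on unrooted bipartitions: a species with >= 2 tips is
monophyletic iff some edge of the tree separates exactly its tips from all
others, so the verdict cannot depend on where the tree happens to be
rooted. When a support threshold is active, the species additionally needs
the defining split's support to exceed the threshold; a split with no
recorded support counts as unsupported. Singleton species are reported but
excluded from the headline rate by default.
"""

from __future__ import annotations

from dataclasses import dataclass

import dendropy
import numpy as np
import pandas as pd
from skbio import DistanceMatrix as SkbioDistanceMatrix
from skbio.tree import nj as _skbio_nj

from barcodekit.distmat import DistanceMatrix
from barcodekit.seqio import read_newick


@dataclass
class MonophylyReport:
    """Per-species monophyly verdicts and the headline conspecific-cluster rate."""

    per_species: pd.DataFrame  # species, n_tips, monophyletic, support, supported
    rate: float  # percent of multi-tip species forming supported clades
    n_singletons: int
    support_threshold: float
    include_singletons: bool


def nj_tree(matrix: DistanceMatrix) -> dendropy.Tree:
    """Neighbor-joining tree from a fully applicable distance matrix.

    For an additive input matrix the tree's tip-to-tip path lengths
    reproduce the input exactly. Negative branch-length estimates are
    clamped to zero (standard NJ practice).
    """
    if len(matrix) < 3:
        raise ValueError("NJ requires >= 3 samples")
    if np.isnan(matrix.values).any():
        iu = np.triu_indices(len(matrix), k=1)
        bad = [
            (matrix.ids[i], matrix.ids[j])
            for i, j in zip(*iu)
            if np.isnan(matrix.values[i, j])
        ]
        raise ValueError(f"inapplicable distances for pairs: {bad}")
    sk = SkbioDistanceMatrix(matrix.values, ids=matrix.ids)
    tree = _skbio_nj(sk)
    return read_newick(str(tree))


def path_distance_matrix(tree: dendropy.Tree) -> pd.DataFrame:
    """Tip-to-tip path-length matrix of a tree."""
    pdm = tree.phylogenetic_distance_matrix()
    taxa = sorted(tree.taxon_namespace, key=lambda t: t.label)
    labels = [t.label for t in taxa]
    n = len(labels)
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            out[i, j] = out[j, i] = pdm.patristic_distance(taxa[i], taxa[j])
    return pd.DataFrame(out, index=labels, columns=labels)


def _splits(tree: dendropy.Tree) -> list[tuple[frozenset, float | None]]:
    """(tip set below edge, support) for every internal edge."""
    all_tips = frozenset(leaf.taxon.label for leaf in tree.leaf_node_iter())
    out = []
    for node in tree.preorder_node_iter():
        if node.is_leaf() or node.parent_node is None:
            continue
        below = frozenset(leaf.taxon.label for leaf in node.leaf_iter())
        if len(below) < 2 or len(below) > len(all_tips) - 2:
            continue  # trivial split
        out.append((below, getattr(node, "support", None)))
    return out


def species_monophyly(
    tree: dendropy.Tree,
    taxonomy: pd.DataFrame,
    support_threshold: float = 95.0,
    include_singletons: bool = False,
) -> MonophylyReport:
    """Score conspecific clustering of every species on an unrooted tree.

    Parameters
    ----------
    support_threshold : supports must strictly exceed this value for a
        clade to count as supported; 0 disables gating only in the sense
        that any positive recorded support passes, while a threshold of
        ``None``-like behaviour (no supports in the tree at all) treats
        monophyly alone as success when ``support_threshold == 0`` and the
        tree carries no supports.
    include_singletons : count single-tip species (trivially monophyletic)
        in the headline rate's denominator.
    """
    species_of = taxonomy.set_index("sample_id")["species"]
    tips = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    missing = [t for t in tips if t not in species_of.index]
    if missing:
        raise KeyError(f"tips missing from taxonomy: {missing}")
    all_tips = frozenset(tips)
    by_species: dict[str, set] = {}
    for t in tips:
        by_species.setdefault(species_of[t], set()).add(t)
    splits = _splits(tree)
    tree_has_supports = any(s is not None for _, s in splits)
    rows = []
    for sp, sp_tips in sorted(by_species.items()):
        sp_tips = frozenset(sp_tips)
        if len(sp_tips) == 1:
            rows.append(
                {
                    "species": sp,
                    "n_tips": 1,
                    "monophyletic": True,
                    "support": float("nan"),
                    "supported": True,
                    "singleton": True,
                }
            )
            continue
        if sp_tips == all_tips or len(all_tips - sp_tips) == 1:
            # the species spans (almost) the whole tree: trivially exclusive
            mono, support = True, None
        else:
            mono, support = False, None
            # prefer the edge subtending the species' own clade; only fall
            # back to a complement match (rooting artefact) if none exists
            for below, sup in splits:
                if below == sp_tips:
                    mono, support = True, sup
                    break
            else:
                for below, sup in splits:
                    if (all_tips - below) == sp_tips:
                        mono, support = True, sup
                        break
        if not mono:
            supported = False
        elif support_threshold <= 0 and not tree_has_supports:
            supported = True
        elif support is None:
            supported = support_threshold <= 0
        else:
            supported = support > support_threshold
        rows.append(
            {
                "species": sp,
                "n_tips": len(sp_tips),
                "monophyletic": mono,
                "support": float("nan") if support is None else float(support),
                "supported": bool(supported),
                "singleton": False,
            }
        )
    per_species = pd.DataFrame(rows)
    scored = per_species if include_singletons else per_species[~per_species["singleton"]]
    rate = 100.0 * scored["supported"].mean() if len(scored) else float("nan")
    return MonophylyReport(
        per_species=per_species,
        rate=float(rate),
        n_singletons=int(per_species["singleton"].sum()),
        support_threshold=support_threshold,
        include_singletons=include_singletons,
    )
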