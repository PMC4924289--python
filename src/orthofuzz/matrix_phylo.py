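"""Presence/absence evidence matrix, Dollo gain/loss mapping, tree collapse.

The evidence matrix records, per (seed gene, species), the best case
among the evidence streams under the order

    published_ok > minor_refinement > major_refinement > read_only > absent

where a positive fuzzy reciprocal best-hit call contributes
``published_ok``, reconciliation tiers contribute their own level, and a
supported read-depth verdict contributes ``read_only``.

Gain/loss histories are reconstructed under Dollo parsimony: a character
(gene) is gained exactly once — at the most recent common ancestor of
the species carrying it — and may subsequently be lost any number of
times; the loss set is the set of maximal all-absent subtrees under the
gain node, which minimises the number of losses under the single-gain
constraint.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import dendropy
import pandas as pd

from .errors import ValidationError
from .formats_io import SupportTree
from .frb import HomologyCall
from .model_reconciliation import RefinementTier
from .read_evidence import ConsistencyVerdict


class CellTier(enum.Enum):
    PUBLISHED_OK = "published_ok"
    MINOR_REFINEMENT = "minor_refinement"
    MAJOR_REFINEMENT = "major_refinement"
    READ_ONLY = "read_only"
    ABSENT = "absent"

    @property
    def rank(self) -> int:
        return {
            "published_ok": 4,
            "minor_refinement": 3,
            "major_refinement": 2,
            "read_only": 1,
            "absent": 0,
        }[self.value]

    @property
    def present(self) -> bool:
        return self is not CellTier.ABSENT


# short codes used in matrix TSVs
TIER_CODES = {
    CellTier.PUBLISHED_OK: "PUB",
    CellTier.MINOR_REFINEMENT: "MIN",
    CellTier.MAJOR_REFINEMENT: "MAJ",
    CellTier.READ_ONLY: "RD",
    CellTier.ABSENT: "ABS",
}
CODE_TIERS = {v: k for k, v in TIER_CODES.items()}

_REFINEMENT_TO_CELL = {
    RefinementTier.PUBLISHED_OK: CellTier.PUBLISHED_OK,
    RefinementTier.MINOR_REFINEMENT: CellTier.MINOR_REFINEMENT,
    RefinementTier.MAJOR_REFINEMENT: CellTier.MAJOR_REFINEMENT,
    # a model at a locus with no published annotation is still genome-level
    # evidence; in the matrix it lands in the major-improvement band
    RefinementTier.NOVEL: CellTier.MAJOR_REFINEMENT,
}


def _collect_stream(items: Iterable[tuple[tuple[str, str], CellTier]], name: str) -> dict:
    out: dict[tuple[str, str], CellTier] = {}
    for key, tier in items:
        if key in out and out[key] is not tier:
            raise ValidationError(f"conflicting duplicate key {key} in {name} stream")
        out[key] = tier
    return out


def build_matrix(
    calls: Iterable[HomologyCall],
    tiers: Mapping[tuple[str, str], RefinementTier] | Iterable[tuple[tuple[str, str], RefinementTier]],
    verdicts: Iterable[ConsistencyVerdict],
    genes: Sequence[str],
    species: Sequence[str],
) -> pd.DataFrame:
    """Assemble the per-(gene, species) best-case evidence matrix.

    Row/column order follows ``genes`` and ``species``; the result is
    invariant to the order of the evidence streams themselves.
    """
    call_stream = _collect_stream(
        (
            ((c.seed_gene, c.species), CellTier.PUBLISHED_OK)
            for c in calls
            if c.positive
        ),
        "homology-call",
    )
    tier_items = tiers.items() if isinstance(tiers, Mapping) else tiers
    tier_stream = _collect_stream(
        ((key, _REFINEMENT_TO_CELL[t]) for key, t in tier_items), "refinement"
    )
    verdict_stream = _collect_stream(
        (
            ((v.seed_gene, v.species), CellTier.READ_ONLY)
            for v in verdicts
            if v.supported
        ),
        "read-verdict",
    )
    data = {}
    for sp in species:
        col = []
        for g in genes:
            key = (g, sp)
            best = CellTier.ABSENT
            for stream in (call_stream, tier_stream, verdict_stream):
                t = stream.get(key)
                if t is not None and t.rank > best.rank:
                    best = t
            col.append(best)
        data[sp] = col
    return pd.DataFrame(data, index=list(genes), columns=list(species))


def write_matrix(matrix: pd.DataFrame, path) -> None:
    coded = matrix.map(lambda t: TIER_CODES[t])
    coded.to_csv(path, sep="\t", index_label="gene")


def read_matrix(path) -> pd.DataFrame:
    coded = pd.read_csv(path, sep="\t", index_col="gene")
    return coded.map(lambda c: CODE_TIERS[c])


# ---------------------------------------------------------------------------
# Dollo parsimony


@dataclass
class GainLossReconstruction:
    """Single-gain/any-loss history for one gene on a species tree.

    The gain node and loss edges are identified by the leaf sets below
    them, which is stable across tree copies and serialisation.
    """

    gain_leaves: frozenset[str] | None
    loss_edges: tuple[frozenset[str], ...]

    @property
    def n_losses(self) -> int:
        return len(self.loss_edges)


def dollo_reconstruct(presence: Mapping[str, int], tree: SupportTree) -> GainLossReconstruction:
    """Map a presence/absence leaf pattern onto the tree under Dollo parsimony.

    The gain is placed at the MRCA of all presence leaves; losses are the
    maximal all-absent subtrees under the gain node (one loss edge each),
    which is the minimum-loss single-gain explanation.  With no presence
    leaf the result is an empty history.
    """
    leaves = set(tree.leaf_labels())
    unknown = set(presence) - leaves
    if unknown:
        raise ValidationError(f"presence pattern names unknown leaves: {sorted(unknown)}")
    present = {lf for lf in leaves if presence.get(lf, 0)}
    if not present:
        return GainLossReconstruction(gain_leaves=None, loss_edges=())
    gain_node = tree.mrca(present)
    losses: list[frozenset[str]] = []

    def visit(node: dendropy.Node) -> None:
        for child in node.child_nodes():
            below = tree.leaf_set(child)
            if below & present:
                visit(child)
            else:
                losses.append(below)

    visit(gain_node)
    losses.sort(key=lambda s: (len(s), sorted(s)))
    return GainLossReconstruction(
        gain_leaves=tree.leaf_set(gain_node), loss_edges=tuple(losses)
    )


def forward_simulate(recon: GainLossReconstruction, tree: SupportTree) -> dict[str, int]:
    """Replay a gain/loss history into the leaf pattern it implies."""
    pattern = {lf: 0 for lf in tree.leaf_labels()}
    if recon.gain_leaves is None:
        return pattern
    lost: set[str] = set()
    for edge in recon.loss_edges:
        lost |= edge
    for lf in recon.gain_leaves - lost:
        pattern[lf] = 1
    return pattern


# ---------------------------------------------------------------------------
# support-based collapse


def collapse_low_support(tree: SupportTree, threshold: float) -> SupportTree:
    """Contract internal edges whose support falls below ``threshold``.

    Edges with support >= threshold, or without a support value, are
    retained; the leaf set is unchanged.  Supports are assumed on the
    0-100 scale; when every numeric support is <= 1 they are taken as
    fractions and rescaled with a warning.
    """
    if not 0.0 <= threshold <= 100.0:
        raise ValidationError("threshold must lie in [0, 100]")
    out = tree.clone()
    supports = [
        s
        for node in out.dtree.preorder_node_iter()
        if (s := SupportTree.node_support(node)) is not None and node.parent_node is not None
    ]
    scale = 1.0
    if supports and all(s <= 1.0 for s in supports):
        scale = 100.0
        warnings.warn("support values all <= 1; interpreting as fractions of 1 and rescaling to 0-100")
    to_collapse = [
        node
        for node in out.dtree.preorder_node_iter()
        if node.parent_node is not None
        and not node.is_leaf()
        and (s := SupportTree.node_support(node)) is not None
        and s * scale < threshold
    ]
    for node in to_collapse:
        node.edge.collapse()
    return out


# ---------------------------------------------------------------------------
# summaries


def summarize_matrix(
    matrix: pd.DataFrame,
    groups: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Per species-group counts and fractions of cells at each tier.

    Also reports, per group, the fraction of *present* cells whose best
    evidence sits below ``published_ok`` — the share of homologues whose
    detection required genome-level search or read mapping rather than
    the published gene models alone.
    """
    groups = groups or {sp: "all" for sp in matrix.columns}
    missing = set(matrix.columns) - set(groups)
    if missing:
        raise ValidationError(f"species without group assignment: {sorted(missing)}")
    rows = []
    for group in sorted(set(groups.values())):
        cols = [sp for sp in matrix.columns if groups[sp] == group]
        cells = [matrix.at[g, sp] for sp in cols for g in matrix.index]
        n = len(cells)
        present = [c for c in cells if c.present]
        row: dict[str, object] = {"group": group, "n_cells": n, "n_present": len(present)}
        for tier in CellTier:
            k = sum(1 for c in cells if c is tier)
            row[f"n_{TIER_CODES[tier].lower()}"] = k
            row[f"frac_{TIER_CODES[tier].lower()}"] = k / n if n else 0.0
        below = sum(1 for c in present if c is not CellTier.PUBLISHED_OK)
        row["frac_genome_dependent"] = below / len(present) if present else 0.0
        rows.append(row)
    return pd.DataFrame(rows).set_index("group")
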