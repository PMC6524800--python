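"""Simplified jackknife: one removal per family/subfamily unit.

For each unit (subfamily where defined, else family) one member is
removed, the whole pipeline (core identification, distance matrix,
Fitch-Margoliash tree) is rerun on the remaining structures, and the
stability of each named group is the fraction of replicate trees in
which its remaining members form a clade under unrooted bipartition
semantics.
"""

from __future__ import annotations

import json
import os
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from skbio.tree import TreeNode

from corecluster.core_builder import build_hierarchy, core_average_rmsd
from corecluster.distance_tree import build_distance_matrix, fitch_margoliash_tree
from corecluster.pairwise_align import AlignParams
from corecluster.structure_io import StructureModel

__all__ = ["JackknifeReplicate", "JackknifeReport", "run_jackknife", "clade_stability"]


@dataclass
class JackknifeReplicate:
    removed_id: str
    unit: str
    core_size: int
    avg_rmsd: float
    tree: TreeNode


@dataclass
class JackknifeReport:
    """Replicate outcomes plus per-group clade stability fractions."""

    replicates: list[JackknifeReplicate]
    stability: dict[str, float]
    n_replicates: int

    def write(self, out_dir: str | os.PathLike) -> None:
        os.makedirs(out_dir, exist_ok=True)
        summary = {
            "n_replicates": self.n_replicates,
            "replicates": [
                {
                    "removed_id": r.removed_id,
                    "unit": r.unit,
                    "core_size": r.core_size,
                    "avg_rmsd": round(r.avg_rmsd, 6),
                }
                for r in self.replicates
            ],
            "stability": {k: round(v, 6) for k, v in sorted(self.stability.items())},
        }
        with open(os.path.join(out_dir, "jackknife.json"), "w") as fh:
            json.dump(summary, fh, indent=1, sort_keys=True)
        for r in self.replicates:
            r.tree.write(os.path.join(out_dir, f"replicate_{r.removed_id}.nwk"))
        with open(os.path.join(out_dir, "stability.tsv"), "w") as fh:
            fh.write("group\tfraction\tn_replicates\n")
            for g, f in sorted(self.stability.items()):
                fh.write(f"{g}\t{f:.4f}\t{self.n_replicates}\n")


def _bipartition_sets(tree: TreeNode) -> tuple[frozenset, set[frozenset]]:
    leaves = frozenset(t.name for t in tree.tips())
    clades = set()
    for node in tree.postorder(include_self=False):
        if node.children:
            clades.add(frozenset(t.name for t in node.tips()))
    return leaves, clades


def _forms_clade(tree_leaves: frozenset, clades: set[frozenset], group: frozenset) -> bool:
    present = group & tree_leaves
    if len(present) < 2 or len(tree_leaves - present) < 2:
        return True  # trivial bipartition (pendant edge or near-whole set)
    return present in clades or (tree_leaves - present) in clades


def clade_stability(trees: Sequence[TreeNode], group: Iterable[str]) -> float:
    """Fraction of trees in which ``group`` forms an unrooted clade.

    A group forms a clade when some edge splits exactly its present
    members from the rest; groups reduced to fewer than two present
    members count as trivially stable.  Invariant to leaf order and to
    rooting.
    """
    group = frozenset(group)
    if not group:
        raise ValueError("empty group")
    if len(trees) < 1:
        raise ValueError("need at least one tree")
    infos = [_bipartition_sets(t) for t in trees]
    if all(not (group & leaves) for leaves, _ in infos):
        raise ValueError(f"group {sorted(group)} absent from every tree")
    hits = sum(_forms_clade(leaves, clades, group) for leaves, clades in infos)
    return hits / len(trees)


def _units(models: Sequence[StructureModel]) -> dict[str, list[str]]:
    units: dict[str, list[str]] = {}
    for m in models:
        unit = m.subfamily_label or m.family_label
        if not unit:
            raise ValueError(f"{m.model_id}: missing family/subfamily label")
        units.setdefault(unit, []).append(m.model_id)
    for ids in units.values():
        ids.sort()
    return dict(sorted(units.items()))


def run_jackknife(
    models: Sequence[StructureModel],
    params: AlignParams | None = None,
    *,
    seed: int | None = None,
    distance_weights: tuple[float, float] = (1.0, 1.0),
) -> JackknifeReport:
    """One replicate per multi-member family/subfamily unit.

    By default the lexicographically first member of each unit is
    removed; with ``seed`` the removed member is drawn at random
    (deterministically for a fixed seed).  Units with a single member
    are skipped with a warning, since removing their member would empty
    the unit.  Stability is reported for every unit and for every
    family label.
    """
    units = _units(models)
    if len(units) < 2:
        raise ValueError("need at least 2 family/subfamily units")
    rng = np.random.default_rng(seed) if seed is not None else None
    by_id = {m.model_id: m for m in models}

    replicates: list[JackknifeReplicate] = []
    for unit, ids in units.items():
        if len(ids) < 2:
            warnings.warn(f"unit {unit!r} has a single member; skipped")
            continue
        removed = ids[int(rng.integers(len(ids)))] if rng is not None else ids[0]
        remaining = [m for m in models if m.model_id != removed]
        root = build_hierarchy(remaining, params)
        core = root.payload
        dm = build_distance_matrix(core, distance_weights)
        tree = fitch_margoliash_tree(dm)
        replicates.append(
            JackknifeReplicate(
                removed_id=removed,
                unit=unit,
                core_size=core.n_columns,
                avg_rmsd=core_average_rmsd(core),
                tree=tree,
            )
        )
    if not replicates:
        raise ValueError("no multi-member units; nothing to jackknife")

    trees = [r.tree for r in replicates]
    groups: dict[str, set[str]] = {}
    for m in models:
        if m.family_label:
            groups.setdefault(m.family_label, set()).add(m.model_id)
        if m.subfamily_label:
            groups.setdefault(m.subfamily_label, set()).add(m.model_id)
    stability = {g: clade_stability(trees, ids) for g, ids in sorted(groups.items())}
    return JackknifeReport(
        replicates=replicates, stability=stability, n_replicates=len(replicates)
    )
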