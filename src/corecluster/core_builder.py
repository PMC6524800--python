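"""Agglomerative identification of a clan-wide common structural core.

All structures are aligned pairwise; the most similar pair (largest
``merge_score``) is merged into a :class:`StructuralCore` that represents
the pair in later iterations, and the new core is re-aligned against the
remaining active nodes.  Merging continues until a single core spans
every input structure.

Column semantics are strict intersection: a column of a merged core
survives only if every member of both children contributes a residue to
it.  Column counts are therefore non-increasing toward the root of the
guide tree, and the final core holds positions equivalent across the
whole input set.
"""

from __future__ import annotations

import json
import os
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from corecluster.pairwise_align import (
    AlignParams,
    ChainView,
    EquivalenceMap,
    Superposition,
    align_pair,
    as_view,
    kabsch_superpose,
    merge_score,
)
from corecluster.structure_io import StructureModel

__all__ = [
    "UnalignableError",
    "CoreColumn",
    "StructuralCore",
    "GuideTreeNode",
    "build_hierarchy",
    "merge_cores",
    "core_average_rmsd",
    "parameter_scan",
    "write_core_tsv",
    "guide_tree_newick",
]


class UnalignableError(RuntimeError):
    """Raised when a structure aligns with nothing else in the dataset."""


@dataclass(frozen=True)
class CoreColumn:
    """One homologous position: a residue index in every member."""

    member_index: dict[str, int]
    rep_xyz: np.ndarray


@dataclass
class StructuralCore:
    """Ordered homologous columns spanning a set of member structures.

    ``col_index[m][c]`` is the 0-based residue index of member ``m`` at
    column ``c``; indices are strictly increasing along the columns for
    every member.  ``view`` holds representative (mean) coordinates and
    properties in the core frame (the frame of the first-merged member),
    so a core can be re-aligned by the same machinery as a chain.
    """

    members: list[str]
    col_index: dict[str, np.ndarray]
    per_member_superposition: dict[str, Superposition]
    view: ChainView
    models: dict[str, StructureModel]

    def __len__(self) -> int:
        return self.n_columns

    @property
    def n_columns(self) -> int:
        return len(self.view.coords)

    @property
    def columns(self) -> list[CoreColumn]:
        return [
            CoreColumn(
                member_index={m: int(self.col_index[m][c]) for m in self.members},
                rep_xyz=self.view.coords[c],
            )
            for c in range(self.n_columns)
        ]

    def validate(self) -> None:
        for m in self.members:
            idx = self.col_index[m]
            if len(idx) != self.n_columns:
                raise AssertionError(f"member {m}: column count mismatch")
            if len(idx) > 1 and not np.all(np.diff(idx) > 0):
                raise AssertionError(f"member {m}: column indices not strictly increasing")
        shortest = min(len(self.models[m]) for m in self.members)
        if self.n_columns > shortest:
            raise AssertionError("core has more columns than its shortest member")


@dataclass
class GuideTreeNode:
    """Binary merge history; leaves carry models, internal nodes cores."""

    payload: StructureModel | StructuralCore
    children: tuple["GuideTreeNode", "GuideTreeNode"] | None = None
    merge_score: float | None = None

    @property
    def is_leaf(self) -> bool:
        return self.children is None

    @property
    def members(self) -> list[str]:
        if isinstance(self.payload, StructuralCore):
            return list(self.payload.members)
        return [self.payload.model_id]

    @property
    def key(self) -> str:
        """Deterministic node identity: lexicographically smallest member."""
        return min(self.members)

    @property
    def n_columns(self) -> int:
        if isinstance(self.payload, StructuralCore):
            return self.payload.n_columns
        return len(self.payload)

    def leaves(self) -> list["GuideTreeNode"]:
        if self.is_leaf:
            return [self]
        return self.children[0].leaves() + self.children[1].leaves()


def _as_core(payload: StructureModel | StructuralCore) -> StructuralCore:
    """Wrap a single model as a trivial one-member core (its own frame)."""
    if isinstance(payload, StructuralCore):
        return payload
    view = as_view(payload)
    return StructuralCore(
        members=[payload.model_id],
        col_index={payload.model_id: np.arange(len(payload))},
        per_member_superposition={payload.model_id: Superposition.identity()},
        view=view,
        models={payload.model_id: payload},
    )


def _circular_mean_deg(values: np.ndarray) -> np.ndarray:
    """Column-wise circular mean of angle arrays in degrees, NaN-aware."""
    rad = np.radians(values)
    with np.errstate(invalid="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        s = np.nanmean(np.sin(rad), axis=0)
        c = np.nanmean(np.cos(rad), axis=0)
    out = np.degrees(np.arctan2(s, c))
    all_nan = np.all(np.isnan(values), axis=0)
    out[all_nan] = np.nan
    return out


def _rebuild_view(core: StructuralCore) -> None:
    """Recompute representative coordinates/properties from the members.

    Each member is first superposed into the core frame with its stored
    transform; the transform is then refreshed by one Kabsch refit of the
    member's column coordinates onto the current representative trace,
    which keeps the frame stable as cores deepen.
    """
    n_cols = len(next(iter(core.col_index.values())))
    member_views = {m: as_view(core.models[m]) for m in core.members}

    rep = np.zeros((n_cols, 3))
    for m in core.members:
        sup = core.per_member_superposition[m]
        rep += sup.apply(member_views[m].coords[core.col_index[m]])
    rep /= len(core.members)

    for m in core.members:
        coords = member_views[m].coords[core.col_index[m]]
        core.per_member_superposition[m] = kabsch_superpose(rep, coords)

    coords_stack, prof, theta, tau, dirs, ncnt = [], [], [], [], [], []
    for m in core.members:
        v = member_views[m]
        idx = core.col_index[m]
        sup = core.per_member_superposition[m]
        coords_stack.append(sup.apply(v.coords[idx]))
        prof.append(v.aa_profile[idx])
        theta.append(v.theta[idx])
        tau.append(v.tau[idx])
        dirs.append(v.direction[idx] @ sup.rotation.T)
        ncnt.append(v.neighbor_count[idx])
    rep_xyz = np.mean(coords_stack, axis=0)
    with np.errstate(invalid="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean_dir = np.nanmean(dirs, axis=0)
        norms = np.linalg.norm(mean_dir, axis=1, keepdims=True)
        mean_dir = np.where(norms > 1e-12, mean_dir / norms, np.nan)
    core.view = ChainView(
        coords=rep_xyz,
        aa_profile=np.mean(prof, axis=0),
        theta=_circular_mean_deg(np.stack(theta)),
        tau=_circular_mean_deg(np.stack(tau)),
        direction=mean_dir,
        neighbor_count=np.nanmean(np.stack(ncnt), axis=0),
    )


def merge_cores(
    m: EquivalenceMap,
    a: StructureModel | StructuralCore,
    b: StructureModel | StructuralCore,
) -> StructuralCore:
    """Merge two payloads along an equivalence map of their views.

    Only matched positions survive (intersection semantics), so the
    merged core never exceeds the smaller child.  The merged frame is the
    frame of ``a``; members of ``b`` enter through the map's
    superposition composed with their previous transforms.
    """
    if m.n_eq == 0 or m.superposition is None:
        raise ValueError("cannot merge along an empty equivalence map")
    core_a, core_b = _as_core(a), _as_core(b)
    overlap = set(core_a.members) & set(core_b.members)
    if overlap:
        raise ValueError(f"children share members: {sorted(overlap)}")
    ia = np.array([p[0] for p in m.pairs], dtype=int)
    ib = np.array([p[1] for p in m.pairs], dtype=int)
    col_index: dict[str, np.ndarray] = {}
    sups: dict[str, Superposition] = {}
    for mem in core_a.members:
        col_index[mem] = core_a.col_index[mem][ia]
        sups[mem] = core_a.per_member_superposition[mem]
    for mem in core_b.members:
        col_index[mem] = core_b.col_index[mem][ib]
        sups[mem] = m.superposition.compose(core_b.per_member_superposition[mem])
    merged = StructuralCore(
        members=core_a.members + core_b.members,
        col_index=col_index,
        per_member_superposition=sups,
        view=core_a.view,  # placeholder, rebuilt below
        models={**core_a.models, **core_b.models},
    )
    _rebuild_view(merged)
    merged.validate()
    return merged


def build_hierarchy(
    models: Sequence[StructureModel], params: AlignParams | None = None
) -> GuideTreeNode:
    """Agglomeratively cluster structures into a single clan-wide core.

    At each step the active pair with the highest ``merge_score`` is
    merged (ties broken on the lexicographically smallest pair of node
    keys) and the new core is re-aligned against every remaining node.
    Deterministic and invariant to input order.

    Raises :class:`UnalignableError` if some structure scores 0 against
    every other.
    """
    if len(models) < 2:
        raise ValueError("need at least 2 models")
    p = params if params is not None else AlignParams()
    ids = [m.model_id for m in models]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate model_ids")

    nodes: dict[str, GuideTreeNode] = {}
    for m in sorted(models, key=lambda x: x.model_id):
        nodes[m.model_id] = GuideTreeNode(payload=m)

    maps: dict[tuple[str, str], EquivalenceMap] = {}

    def _pair_key(k1: str, k2: str) -> tuple[str, str]:
        return (k1, k2) if k1 < k2 else (k2, k1)

    def _align(k1: str, k2: str) -> None:
        ka, kb = _pair_key(k1, k2)
        maps[(ka, kb)] = align_pair(nodes[ka].payload, nodes[kb].payload, p)

    keys = sorted(nodes)
    for i, k1 in enumerate(keys):
        for k2 in keys[i + 1 :]:
            _align(k1, k2)

    orphans = [
        k
        for k in keys
        if all(merge_score(maps[_pair_key(k, other)]) == 0.0 for other in keys if other != k)
    ]
    if orphans:
        raise UnalignableError(f"structures align with nothing else: {orphans}")

    while len(nodes) > 1:
        best = None
        for (ka, kb), em in maps.items():
            s = merge_score(em)
            cand = (-s, ka, kb)
            if best is None or cand < best:
                best = cand
        neg_s, ka, kb = best
        score = -neg_s
        if score == 0.0:
            raise UnalignableError(
                f"remaining nodes are mutually unalignable: {sorted(nodes)}"
            )
        em = maps.pop((ka, kb))
        na, nb = nodes.pop(ka), nodes.pop(kb)
        core = merge_cores(em, na.payload, nb.payload)
        if core.n_columns > min(na.n_columns, nb.n_columns):
            raise AssertionError("merged core exceeds smaller child (intersection violated)")
        new = GuideTreeNode(payload=core, children=(na, nb), merge_score=score)
        stale = [pk for pk in maps if ka in pk or kb in pk]
        for pk in stale:
            del maps[pk]
        nodes[new.key] = new
        for other in sorted(nodes):
            if other != new.key:
                _align(new.key, other)
    return next(iter(nodes.values()))


def core_average_rmsd(core: StructuralCore, models: Mapping[str, StructureModel] | None = None) -> float:
    """Mean pairwise rmsd of members superposed on the core columns."""
    if models is None:
        models = core.models
    members = list(core.members)
    if len(members) < 2:
        raise ValueError("need at least 2 members")
    total, npairs = 0.0, 0
    for i, ma in enumerate(members):
        xa = models[ma].ca_coords[core.col_index[ma]]
        for mb in members[i + 1 :]:
            xb = models[mb].ca_coords[core.col_index[mb]]
            total += kabsch_superpose(xa, xb).rmsd
            npairs += 1
    return total / npairs


def parameter_scan(
    models: Sequence[StructureModel], grid: Sequence[AlignParams]
) -> pd.DataFrame:
    """Build a hierarchy per parameter set and rank the outcomes.

    Ranking: core size descending, then average rmsd ascending -- the
    largest, tightest core wins.  Failing grid points are kept in the
    table flagged as failed rather than silently dropped.
    """
    if len(grid) == 0:
        raise ValueError("empty parameter grid")
    rows = []
    for k, p in enumerate(grid):
        row = {"grid_index": k, "params": repr(p)}
        try:
            root = build_hierarchy(models, p)
            core = root.payload
            row.update(
                core_size=core.n_columns,
                avg_rmsd=core_average_rmsd(core),
                failed=False,
                error="",
            )
        except Exception as exc:  # per-point failures become flagged rows
            row.update(core_size=np.nan, avg_rmsd=np.nan, failed=True, error=str(exc))
        rows.append(row)
    df = pd.DataFrame(rows)
    ok = df[~df["failed"]].sort_values(
        ["core_size", "avg_rmsd", "grid_index"], ascending=[False, True, True]
    )
    bad = df[df["failed"]]
    out = pd.concat([ok, bad]).reset_index(drop=True)
    out["rank"] = [i + 1 if not f else -1 for i, f in enumerate(out["failed"])]
    return out


# ---------------------------------------------------------------------------
# serialization


def write_core_tsv(core: StructuralCore, path: str | os.PathLike) -> None:
    """Core columns as TSV: column index x member residue indices
    (author numbering, res_seq plus insertion code)."""
    members = list(core.members)
    with open(path, "w") as fh:
        fh.write("column\t" + "\t".join(members) + "\n")
        for c in range(core.n_columns):
            cells = []
            for m in members:
                rec = core.models[m].residues[int(core.col_index[m][c])]
                cells.append(f"{rec.res_seq}{rec.icode}")
            fh.write(f"{c}\t" + "\t".join(cells) + "\n")


def write_core_superpositions(core: StructuralCore, path: str | os.PathLike) -> None:
    data = {
        m: {
            "rotation": np.round(s.rotation, 9).tolist(),
            "translation": np.round(s.translation, 6).tolist(),
            "rmsd": round(float(s.rmsd), 6),
        }
        for m, s in core.per_member_superposition.items()
    }
    with open(path, "w") as fh:
        json.dump(data, fh, indent=1, sort_keys=True)


def guide_tree_newick(root: GuideTreeNode) -> str:
    """Guide tree as Newick with merge scores as internal labels."""

    def _fmt(node: GuideTreeNode) -> str:
        if node.is_leaf:
            return node.payload.model_id
        left = _fmt(node.children[0])
        right = _fmt(node.children[1])
        return f"({left},{right}){node.merge_score:.4f}"

    return _fmt(root) + ";"
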