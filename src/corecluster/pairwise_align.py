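"""Property-based pairwise structural alignment of C-alpha traces.

Two chains (or cores) are aligned by iterating two steps until the set of
equivalent residue pairs stabilizes:

1. rigid-body superposition (Kabsch) on the current equivalences;
2. a global dynamic-programming alignment (affine gaps, free end gaps)
   over a position-pair score that combines amino-acid similarity, local
   backbone geometry (pseudo bond and dihedral angles over consecutive
   C-alphas), backbone direction, and the post-superposition C-alpha
   distance.  The distance term turns negative beyond the cut-off
   ``d_cut``, so remote pairs are increasingly penalized during the
   iteration (a hard ban would pin the alignment to the neighbourhood of
   the seed on elongated chains); the final equivalence set is pruned so
   that every reported pair satisfies ``d_cut`` under the superposition
   fitted on the reported pairs themselves.

The iteration is seeded from the best-superposing pair of gapless
windows, which makes the whole procedure deterministic and free of any
dependence on input order.

Amino acids are represented as profile vectors over a 21-letter alphabet
(20 standard + X) so that merged cores, whose columns hold several
residues, score through the same machinery as single chains: the
similarity of two profiles is their bilinear form under a BLOSUM62 matrix
rescaled to [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from Bio.Align import substitution_matrices
from numba import njit

__all__ = [
    "DegenerateGeometryError",
    "PropertyVector",
    "ChainView",
    "Superposition",
    "AlignParams",
    "EquivalenceMap",
    "compute_properties",
    "kabsch_superpose",
    "align_pair",
    "merge_score",
]

ALPHABET = "ACDEFGHIKLMNPQRSTVWYX"
_NEG = -1.0e15  # DP ban value; large but safe under addition

NEIGHBOR_RADIUS = 10.0  # A; contact sphere for the burial count
NEIGHBOR_SEQ_EXCLUDE = 2  # exclude i-2..i+2 from the count
SEED_RMSD_MAX = 5.0  # A; structures with no window pair below this are unalignable


class DegenerateGeometryError(ValueError):
    """Raised when a superposition problem has no unique solution."""


def _blosum_unit() -> np.ndarray:
    """BLOSUM62 over ALPHABET rescaled to [0, 1] with unit self-similarity.

    Scores are shifted positive and cross-normalized
    (``s_ij / sqrt(s_ii * s_jj)``), so identical residues score exactly 1
    and the amino-acid dissimilarity of an identical pair is exactly 0.
    """
    raw = substitution_matrices.load("BLOSUM62")
    n = len(ALPHABET)
    m = np.empty((n, n), dtype=float)
    for i, a in enumerate(ALPHABET):
        for j, b in enumerate(ALPHABET):
            m[i, j] = raw[a, b]
    m -= m.min()
    diag = np.sqrt(np.diag(m))
    m = m / np.outer(diag, diag)
    m = (m + m.T) / 2.0  # exact symmetry despite rounding
    np.fill_diagonal(m, 1.0)
    return np.clip(m, 0.0, 1.0)


BLOSUM_UNIT = _blosum_unit()


@dataclass(frozen=True)
class PropertyVector:
    """Properties of one residue; angle fields are NaN where undefined."""

    aa_profile: np.ndarray  # (21,) distribution over ALPHABET
    pseudo_angle: float  # theta over Ca(i-1), Ca(i), Ca(i+1), degrees
    pseudo_dihedral: float  # tau over Ca(i-1..i+2), degrees
    direction: np.ndarray  # unit vector Ca(i) -> Ca(i+1); NaN at C-terminus
    neighbor_count: float


@dataclass
class ChainView:
    """Vectorized per-position properties of a chain or core.

    The uniform interface consumed by the aligner: plain chains and
    merged cores both reduce to coordinates plus property arrays.
    """

    coords: np.ndarray  # (N, 3)
    aa_profile: np.ndarray  # (N, 21)
    theta: np.ndarray  # (N,) degrees, NaN undefined
    tau: np.ndarray  # (N,) degrees, NaN undefined
    direction: np.ndarray  # (N, 3), NaN rows undefined
    neighbor_count: np.ndarray  # (N,)

    def __len__(self) -> int:
        return len(self.coords)

    def __getitem__(self, i: int) -> PropertyVector:
        return PropertyVector(
            aa_profile=self.aa_profile[i],
            pseudo_angle=float(self.theta[i]),
            pseudo_dihedral=float(self.tau[i]),
            direction=self.direction[i],
            neighbor_count=float(self.neighbor_count[i]),
        )


@dataclass(frozen=True)
class Superposition:
    """Proper rigid transform x -> R x + t fitting one point set onto another."""

    rotation: np.ndarray  # (3, 3), orthonormal, det = +1
    translation: np.ndarray  # (3,)
    rmsd: float

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation

    @staticmethod
    def identity() -> "Superposition":
        return Superposition(np.eye(3), np.zeros(3), 0.0)

    def compose(self, inner: "Superposition") -> "Superposition":
        """Transform equal to applying ``inner`` first, then ``self``."""
        return Superposition(
            rotation=self.rotation @ inner.rotation,
            translation=self.rotation @ inner.translation + self.translation,
            rmsd=self.rmsd,
        )


@dataclass(frozen=True)
class AlignParams:
    """Tunable parameters of the pairwise aligner.

    ``d_cut`` is the equivalence cut-off between matched C-alphas after
    superposition (default 3.8 A, one C-alpha-C-alpha bond).  The four
    weights set the relative influence of the amino-acid, geometry,
    direction, and distance terms of the position score; each term lies
    in [0, 1] before weighting.
    """

    w_aa: float = 1.0
    w_geo: float = 1.0
    w_dir: float = 1.0
    w_dist: float = 1.0
    d_cut: float = 3.8
    gap_open: float = 2.0
    gap_extend: float = 0.2
    seed_window: int = 8
    max_iter: int = 50

    def __post_init__(self) -> None:
        if self.d_cut <= 0:
            raise ValueError("d_cut must be positive")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")
        for w in (self.w_aa, self.w_geo, self.w_dir, self.w_dist):
            if w < 0:
                raise ValueError("weights must be non-negative")


@dataclass
class EquivalenceMap:
    """Result of a pairwise structural alignment.

    ``pairs`` is strictly increasing in both columns (sequential,
    colinear alignment); every pair is within ``d_cut`` after applying
    ``superposition`` (which maps b onto a).  An empty map (score 0)
    marks a pair of structures deemed unalignable.
    """

    pairs: list[tuple[int, int]]
    superposition: Superposition | None
    score: float
    d_cut: float

    @property
    def n_eq(self) -> int:
        return len(self.pairs)

    @property
    def rmsd(self) -> float:
        if self.superposition is None:
            return float("nan")
        return self.superposition.rmsd

    @staticmethod
    def empty(d_cut: float) -> "EquivalenceMap":
        return EquivalenceMap(pairs=[], superposition=None, score=0.0, d_cut=d_cut)


# ---------------------------------------------------------------------------
# properties


def _pseudo_angles(xyz: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Pseudo bond angle theta and pseudo dihedral tau along a Ca trace."""
    n = len(xyz)
    theta = np.full(n, np.nan)
    tau = np.full(n, np.nan)
    if n >= 3:
        b1 = xyz[:-2] - xyz[1:-1]  # Ca(i) -> Ca(i-1)
        b2 = xyz[2:] - xyz[1:-1]  # Ca(i) -> Ca(i+1)
        cosang = np.einsum("ij,ij->i", b1, b2) / (
            np.linalg.norm(b1, axis=1) * np.linalg.norm(b2, axis=1)
        )
        theta[1:-1] = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
    if n >= 4:
        b0 = xyz[1:-2] - xyz[:-3]
        b1 = xyz[2:-1] - xyz[1:-2]
        b2 = xyz[3:] - xyz[2:-1]
        n1 = np.cross(b0, b1)
        n2 = np.cross(b1, b2)
        m1 = np.cross(n1, b1 / np.linalg.norm(b1, axis=1, keepdims=True))
        x = np.einsum("ij,ij->i", n1, n2)
        y = np.einsum("ij,ij->i", m1, n2)
        ang = np.degrees(np.arctan2(y, x))
        # convention: tau assigned to residue i of the quad (i-1, i, i+1, i+2)
        ang = np.where(ang <= -180.0, ang + 360.0, ang)
        tau[1:-2] = ang
    return theta, tau


def sequence_profile(sequence: str) -> np.ndarray:
    """One-hot profile rows over ALPHABET for a plain sequence."""
    idx = np.array([ALPHABET.index(c) for c in sequence])
    prof = np.zeros((len(sequence), len(ALPHABET)))
    prof[np.arange(len(sequence)), idx] = 1.0
    return prof


def compute_properties(model) -> ChainView:
    """Per-residue property vectors for a :class:`StructureModel`.

    Entries undefined at the termini (angles, direction) are NaN and are
    excluded from scoring rather than zero-filled.
    """
    xyz = model.ca_coords
    n = len(xyz)
    if n < 2:
        raise ValueError(f"{model.model_id}: need at least 2 residues for properties")
    theta, tau = _pseudo_angles(xyz)
    direction = np.full((n, 3), np.nan)
    diffs = xyz[1:] - xyz[:-1]
    direction[:-1] = diffs / np.linalg.norm(diffs, axis=1, keepdims=True)
    d2 = np.sum((xyz[:, None, :] - xyz[None, :, :]) ** 2, axis=-1)
    mask = d2 < NEIGHBOR_RADIUS**2
    ij = np.abs(np.arange(n)[:, None] - np.arange(n)[None, :])
    mask &= ij > NEIGHBOR_SEQ_EXCLUDE
    neighbor_count = mask.sum(axis=1).astype(float)
    return ChainView(
        coords=xyz,
        aa_profile=sequence_profile(model.sequence),
        theta=theta,
        tau=tau,
        direction=direction,
        neighbor_count=neighbor_count,
    )


def as_view(obj) -> ChainView:
    """Coerce a StructureModel, StructuralCore or ChainView to a ChainView."""
    if isinstance(obj, ChainView):
        return obj
    view = getattr(obj, "view", None)
    if isinstance(view, ChainView):
        return view
    cached = getattr(obj, "_view", None)
    if cached is None:
        cached = compute_properties(obj)
        try:
            obj._view = cached
        except AttributeError:
            pass
    return cached


# ---------------------------------------------------------------------------
# superposition


def kabsch_superpose(coords_a: np.ndarray, coords_b: np.ndarray) -> Superposition:
    """Least-squares proper rotation + translation of b onto a.

    Reflections are excluded (det = +1).  Raises
    :class:`DegenerateGeometryError` for fewer than 3 points or collinear
    input, where the optimal rotation is not unique.
    """
    a = np.asarray(coords_a, dtype=float)
    b = np.asarray(coords_b, dtype=float)
    if a.shape != b.shape or a.ndim != 2 or a.shape[1] != 3:
        raise ValueError("coordinate arrays must both be (N, 3)")
    n = len(a)
    if n < 3:
        raise DegenerateGeometryError(f"need >= 3 points for a unique superposition, got {n}")
    ca, cb = a.mean(axis=0), b.mean(axis=0)
    ac, bc = a - ca, b - cb
    for name, x in (("first", ac), ("second", bc)):
        s = np.linalg.svd(x, compute_uv=False)
        if s[1] <= 1e-8 * max(s[0], 1.0):
            raise DegenerateGeometryError(f"collinear {name} point set: rotation not unique")
    h = bc.T @ ac
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.diag([1.0, 1.0, d])
    rot = vt.T @ corr @ u.T
    t = ca - rot @ cb
    fitted = b @ rot.T + t
    rmsd = float(np.sqrt(np.mean(np.sum((fitted - a) ** 2, axis=1))))
    if rmsd < 1e-12:  # identity/translation cases: exact zero, not SVD dust
        rmsd = 0.0
    return Superposition(rotation=rot, translation=t, rmsd=rmsd)


def _window_rmsd_scan(ca: np.ndarray, cb: np.ndarray, w: int) -> np.ndarray:
    """Superposition rmsd of every gapless window pair (exhaustive).

    Uses the closed-form Kabsch rmsd from batched 3x3 SVDs of the
    cross-covariance of every window pair; returns an
    (a-windows, b-windows) matrix.
    """
    from numpy.lib.stride_tricks import sliding_window_view

    wa = sliding_window_view(ca, (w, 3)).reshape(-1, w, 3)
    wb = sliding_window_view(cb, (w, 3)).reshape(-1, w, 3)
    wa = wa - wa.mean(axis=1, keepdims=True)
    wb = wb - wb.mean(axis=1, keepdims=True)
    ea = np.sum(wa**2, axis=(1, 2))
    eb = np.sum(wb**2, axis=(1, 2))
    # cross-covariance for every (b-window, a-window) pair
    h = np.einsum("iwa,jwb->ijab", wb, wa)
    na, nb = len(wa), len(wb)
    hs = h.reshape(na * nb, 3, 3)
    sv = np.linalg.svd(hs, compute_uv=False)
    det = np.linalg.det(hs)
    ssum = sv[:, 0] + sv[:, 1] + np.where(det < 0, -sv[:, 2], sv[:, 2])
    msd = (eb[:, None] + ea[None, :]).reshape(-1) - 2.0 * ssum
    msd = np.maximum(msd, 0.0) / w
    return np.sqrt(msd.reshape(nb, na).T)  # [a-window, b-window] rmsd


def _seed_windows(ca: np.ndarray, cb: np.ndarray, w: int, n_seeds: int) -> list[tuple[int, int, float]]:
    """Up to ``n_seeds`` best mutually non-overlapping seed window pairs.

    Several restarts guard against spurious seeds in internally symmetric
    or repetitive structures, where the single best-superposing window
    pair can sit in a wrong registration.
    """
    rmsd = _window_rmsd_scan(ca, cb, w)
    out: list[tuple[int, int, float]] = []
    masked = rmsd.copy()
    while len(out) < n_seeds and np.isfinite(masked).any():
        k = int(np.argmin(masked))
        i, j = divmod(k, masked.shape[1])
        r = float(masked[i, j])
        if r > SEED_RMSD_MAX:
            break
        out.append((i, j, r))
        masked[max(0, i - w) : i + w, :] = np.inf
        masked[:, max(0, j - w) : j + w] = np.inf
    return out


# ---------------------------------------------------------------------------
# dynamic programming (Gotoh, affine gaps, free end gaps)


@njit(cache=False)
def _gotoh(S, gap_open, gap_extend):  # pragma: no cover - numba
    n, m = S.shape
    NEG = -1.0e15
    M = np.full((n + 1, m + 1), NEG)
    X = np.full((n + 1, m + 1), NEG)  # gap in b (moving down rows of a)
    Y = np.full((n + 1, m + 1), NEG)  # gap in a
    TM = np.zeros((n + 1, m + 1), dtype=np.int8)
    TX = np.zeros((n + 1, m + 1), dtype=np.int8)
    TY = np.zeros((n + 1, m + 1), dtype=np.int8)
    M[0, 0] = 0.0
    for i in range(1, n + 1):
        X[i, 0] = 0.0  # free end gaps
        TX[i, 0] = 1
    for j in range(1, m + 1):
        Y[0, j] = 0.0
        TY[0, j] = 2
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            # M: match i-1, j-1
            best = M[i - 1, j - 1]
            tb = 0
            if X[i - 1, j - 1] > best:
                best = X[i - 1, j - 1]
                tb = 1
            if Y[i - 1, j - 1] > best:
                best = Y[i - 1, j - 1]
                tb = 2
            M[i, j] = best + S[i - 1, j - 1]
            TM[i, j] = tb
            # X: gap in b, consume a[i-1]
            ox = M[i - 1, j] - gap_open
            ex = X[i - 1, j] - gap_extend
            oy = Y[i - 1, j] - gap_open
            best = ox
            tb = 0
            if ex > best:
                best = ex
                tb = 1
            if oy > best:
                best = oy
                tb = 2
            X[i, j] = best
            TX[i, j] = tb
            # Y: gap in a, consume b[j-1]
            oy2 = M[i, j - 1] - gap_open
            ey = Y[i, j - 1] - gap_extend
            ox2 = X[i, j - 1] - gap_open
            best = oy2
            tb = 0
            if ey > best:
                best = ey
                tb = 2
            if ox2 > best:
                best = ox2
                tb = 1
            Y[i, j] = best
            TY[i, j] = tb
    # free trailing gaps: best over last row / column
    best = M[n, m]
    bi, bj, bstate = n, m, 0
    if X[n, m] > best:
        best = X[n, m]
        bstate = 1
    if Y[n, m] > best:
        best = Y[n, m]
        bstate = 2
    for i in range(n + 1):
        if M[i, m] > best:
            best = M[i, m]
            bi, bj, bstate = i, m, 0
    for j in range(m + 1):
        if M[n, j] > best:
            best = M[n, j]
            bi, bj, bstate = n, j, 0
    # traceback
    pairs = np.empty((n + m, 2), dtype=np.int64)
    k = 0
    i, j, state = bi, bj, bstate
    while i > 0 or j > 0:
        if state == 0:
            if i == 0 or j == 0:
                break
            pairs[k, 0] = i - 1
            pairs[k, 1] = j - 1
            k += 1
            state = TM[i, j]
            i -= 1
            j -= 1
        elif state == 1:
            if i == 0:
                break
            state = TX[i, j]
            i -= 1
        else:
            if j == 0:
                break
            state = TY[i, j]
            j -= 1
    return best, pairs[:k][::-1].copy()


# ---------------------------------------------------------------------------
# scoring


def _circular_abs_diff(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """|a - b| on a 360-degree circle, result in [0, 180]."""
    d = np.abs(a[:, None] - b[None, :]) % 360.0
    return np.where(d > 180.0, 360.0 - d, d)


def _score_matrix(va: ChainView, vb: ChainView, rot: np.ndarray, d: np.ndarray, p: AlignParams) -> np.ndarray:
    """Position-pair score; NaN property terms are dropped and the
    remaining weighted sum rescaled to the full weight budget."""
    sim_aa = va.aa_profile @ BLOSUM_UNIT @ vb.aa_profile.T

    dth = np.abs(va.theta[:, None] - vb.theta[None, :])
    dta = _circular_abs_diff(va.tau, vb.tau)
    sim_geo = 1.0 - (dth + dta / 2.0) / 270.0
    geo_ok = ~np.isnan(sim_geo)

    dir_b = vb.direction @ rot.T
    cosang = va.direction @ dir_b.T
    sim_dir = (1.0 + cosang) / 2.0
    dir_ok = ~np.isnan(sim_dir)

    sim_dist = 1.0 - d / p.d_cut

    total_w = p.w_aa + p.w_geo + p.w_dir + p.w_dist
    num = p.w_aa * sim_aa + p.w_dist * sim_dist
    den = np.full(d.shape, p.w_aa + p.w_dist)
    num += np.where(geo_ok, p.w_geo * np.nan_to_num(sim_geo), 0.0)
    den += np.where(geo_ok, p.w_geo, 0.0)
    num += np.where(dir_ok, p.w_dir * np.nan_to_num(sim_dir), 0.0)
    den += np.where(dir_ok, p.w_dir, 0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        s = np.where(den > 0, num / den * total_w, 0.0)
    return s


def _fit_pairs(ca: np.ndarray, cb: np.ndarray, pairs: np.ndarray) -> Superposition:
    return kabsch_superpose(ca[pairs[:, 0]], cb[pairs[:, 1]])


def _iterate_from_seed(va, vb, seed: tuple[int, int], p: AlignParams) -> tuple[float, np.ndarray]:
    """Superpose/realign iteration from one seed window pair."""
    ca, cb = va.coords, vb.coords
    i0, j0 = seed
    pairs = np.array([(i0 + k, j0 + k) for k in range(p.seed_window)], dtype=np.int64)
    best_score = -np.inf
    best_pairs = pairs
    seen: set[bytes] = set()
    for _ in range(p.max_iter):
        try:
            sup = _fit_pairs(ca, cb, pairs)
        except DegenerateGeometryError:
            break
        tb = sup.apply(cb)
        d = np.sqrt(np.sum((ca[:, None, :] - tb[None, :, :]) ** 2, axis=-1))
        s = _score_matrix(va, vb, sup.rotation, d, p)
        score, new_pairs = _gotoh(s, p.gap_open, p.gap_extend)
        if len(new_pairs) < 3:
            break
        if score > best_score:
            best_score = score
            best_pairs = new_pairs
        key = new_pairs.tobytes()
        if key in seen:
            break
        seen.add(key)
        pairs = new_pairs
    return best_score, best_pairs


N_SEED_RESTARTS = 3


def align_pair(a, b, params: AlignParams | None = None) -> EquivalenceMap:
    """Align two structures (or cores) into an :class:`EquivalenceMap`.

    The iteration is restarted from up to three non-overlapping seed
    window pairs and the best-scoring result kept, which makes the
    registration robust to internal symmetry.  Deterministic for fixed
    inputs and parameters.  If no pair of gapless seed windows
    superposes below 5 A rmsd the structures are deemed unalignable and
    an empty map with score 0 is returned.
    """
    p = params if params is not None else AlignParams()
    va, vb = as_view(a), as_view(b)
    w = p.seed_window
    if len(va) < w or len(vb) < w:
        raise ValueError(f"inputs must have at least seed_window={w} positions")
    ca, cb = va.coords, vb.coords

    seeds = _seed_windows(ca, cb, w, N_SEED_RESTARTS)
    if not seeds:
        return EquivalenceMap.empty(p.d_cut)

    best_score = -np.inf
    best_pairs = None
    for i0, j0, _ in seeds:
        score, pairs = _iterate_from_seed(va, vb, (i0, j0), p)
        if score > best_score:
            best_score = score
            best_pairs = pairs

    if best_pairs is None or not np.isfinite(best_score):
        return EquivalenceMap.empty(p.d_cut)

    # final pruning: every reported pair must satisfy d_cut under the
    # superposition fitted on the reported pairs themselves
    pairs = best_pairs
    sup = None
    for _ in range(100):
        if len(pairs) < 3:
            return EquivalenceMap.empty(p.d_cut)
        sup = _fit_pairs(ca, cb, pairs)
        dist = np.sqrt(np.sum((ca[pairs[:, 0]] - sup.apply(cb[pairs[:, 1]])) ** 2, axis=1))
        if np.all(dist <= p.d_cut):
            break
        pairs = pairs[dist <= p.d_cut]
    return EquivalenceMap(
        pairs=[(int(i), int(j)) for i, j in pairs],
        superposition=sup,
        score=float(best_score),
        d_cut=p.d_cut,
    )


def merge_score(m: EquivalenceMap) -> float:
    """Similarity used to rank merge candidates: n_eq / (1 + rmsd).

    Rewards both a large number of equivalent residues and a low rmsd;
    zero for empty (unalignable) maps.
    """
    if m.n_eq == 0 or m.superposition is None:
        return 0.0
    return m.n_eq / (1.0 + m.superposition.rmsd)
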