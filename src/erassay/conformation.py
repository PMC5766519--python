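"""Superposition, RMSD/RMSF, equilibration detection, Daura clustering and
α-helix content tracking.

Clustering follows the greedy neighbour-count algorithm of Daura et al.:
compute all pairwise post-fit RMSDs, repeatedly take the frame with the most
neighbours within the cutoff (ties broken by lowest frame index) together
with its neighbours as a cluster, remove them, and continue until no frames
remain.  The production cutoff used throughout is 2.75 Å on per-monomer Cα
coordinates.

Helix assignment is the α-helical i→i+4 backbone hydrogen-bond criterion
(C=O(i−4)···H−N(i), d(O,N) ≤ 3.5 Å, N−H···O within 40° of linear); a residue
is helical in a frame when it participates in such a bond as donor or
acceptor.  This deliberately tracks helical-versus-not content only, not the
full 8-class secondary-structure alphabet.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import CA, Selection, Topology, Trajectory

__all__ = [
    "ClusterParams",
    "ClusterResult",
    "HelixAssignment",
    "kabsch_superpose",
    "pairwise_min_rmsd",
    "rmsd_series",
    "detect_equilibration",
    "rmsf",
    "daura_cluster",
    "representative_structure",
    "assign_helix",
]


# --------------------------------------------------------------------------
# Kabsch superposition
# --------------------------------------------------------------------------

def kabsch_superpose(
    mobile: np.ndarray, reference: np.ndarray
) -> tuple[np.ndarray, np.ndarray, float]:
    """Least-squares optimal rigid superposition of ``mobile`` onto
    ``reference`` (both (n, 3), n ≥ 3, non-collinear).

    Returns (R, t, rmsd) with the proper rotation R (det = +1) and
    translation t such that ``mobile @ R.T + t`` best fits ``reference``.
    """
    mobile = np.asarray(mobile, float)
    reference = np.asarray(reference, float)
    if mobile.shape != reference.shape or mobile.ndim != 2 or mobile.shape[1] != 3:
        raise ValueError("mobile and reference must both have shape (n, 3)")
    n = mobile.shape[0]
    if n < 3:
        raise ValueError("superposition needs at least 3 atoms")
    mc = mobile.mean(axis=0)
    rc = reference.mean(axis=0)
    X = mobile - mc
    Y = reference - rc
    sx = np.linalg.svd(X, compute_uv=False)
    sy = np.linalg.svd(Y, compute_uv=False)
    if sx[1] < 1e-8 or sy[1] < 1e-8:
        raise ValueError("degenerate (collinear) atom selection")
    H = X.T @ Y
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = rc - R @ mc
    diff = X @ R.T - Y
    rmsd = float(np.sqrt(np.mean(np.sum(diff**2, axis=1))))
    return R, t, rmsd


def pairwise_min_rmsd(coords: np.ndarray, chunk: int = 256) -> np.ndarray:
    """All-pairs minimum (post-fit) RMSD matrix for frames (n, atoms, 3).

    Uses the closed-form Kabsch RMSD: for centred frames X_i, X_j with
    squared norms G_i, G_j and cross-covariance H = X_iᵀX_j,
    rmsd² = (G_i + G_j − 2(σ₁+σ₂±σ₃)) / n_atoms, the sign following det(H).
    """
    X = np.asarray(coords, float)
    n, natoms, _ = X.shape
    X = X - X.mean(axis=1, keepdims=True)
    G = np.sum(X**2, axis=(1, 2))
    out = np.zeros((n, n))
    for i0 in range(0, n, chunk):
        i1 = min(i0 + chunk, n)
        # H[a, b] = X[i0+a].T @ X[b]
        H = np.einsum("iak,jal->ijkl", X[i0:i1], X)
        S = np.linalg.svd(H, compute_uv=False)
        det = np.linalg.det(H)
        trace = S[..., 0] + S[..., 1] + np.sign(det) * S[..., 2]
        sq = (G[i0:i1, None] + G[None, :] - 2.0 * trace) / natoms
        out[i0:i1] = np.sqrt(np.maximum(sq, 0.0))
    np.fill_diagonal(out, 0.0)
    return out


# --------------------------------------------------------------------------
# RMSD / equilibration / RMSF
# --------------------------------------------------------------------------

def rmsd_series(
    traj: Trajectory,
    reference: np.ndarray,
    top: Topology,
    sel: Selection = CA,
) -> np.ndarray:
    """Per-frame minimum RMSD (Å) to a reference structure over ``sel``."""
    idx = sel.resolve(top)
    ref = np.asarray(reference, float)[idx]
    out = np.empty(traj.n_frames)
    for t in range(traj.n_frames):
        _, _, out[t] = kabsch_superpose(traj.coordinates[t, idx, :], ref)
    return out


def detect_equilibration(
    series: np.ndarray,
    times: np.ndarray,
    tol: float = 0.5,
    min_plateau: float = 0.95,
    min_tail_frames: int = 10,
    min_tail_fraction: float = 0.2,
) -> float | None:
    """Earliest time from which the running mean of ``series`` has settled.

    A start index k qualifies when, over the tail series[k:], the cumulative
    running mean stays within ``tol`` of the tail's final running mean for at
    least ``min_plateau`` of the tail's frames.  Tails shorter than
    ``min_tail_frames`` or ``min_tail_fraction`` of the series are not
    considered (a two-frame tail is trivially "settled"), so a monotonically
    drifting series reports not-converged (None) rather than a spurious late
    start.
    """
    x = np.asarray(series, float)
    times = np.asarray(times, float)
    n = len(x)
    if n < 10:
        raise ValueError("equilibration detection needs at least 10 frames")
    min_tail = max(int(min_tail_frames), int(np.ceil(min_tail_fraction * n)))
    for k in range(n - min_tail + 1):
        tail = x[k:]
        running = np.cumsum(tail) / np.arange(1, len(tail) + 1)
        frac = np.mean(np.abs(running - running[-1]) <= tol)
        if frac >= min_plateau:
            return float(times[k])
    return None


def rmsf(
    traj: Trajectory,
    top: Topology,
    sel: Selection = CA,
    window: slice | None = None,
) -> pd.Series:
    """Per-atom root mean square fluctuation about the window-mean position.

    RMSF_i = sqrt(<|r_i − <r_i>|²>); the trajectory must already be in a
    common frame (superposed).
    """
    idx = sel.resolve(top)
    X = traj.coordinates[window if window is not None else slice(None), :, :][:, idx, :]
    if X.shape[0] < 2:
        raise ValueError("RMSF needs at least 2 frames in the window")
    dev = X - X.mean(axis=0, keepdims=True)
    vals = np.sqrt(np.mean(np.sum(dev**2, axis=2), axis=0))
    labels = [
        f"{top.chain_id[k]}:{top.residue_number[k]}:{top.atom_name[k]}" for k in idx
    ]
    return pd.Series(vals, index=labels, name="rmsf_A")


# --------------------------------------------------------------------------
# Daura clustering
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class ClusterParams:
    rmsd_cutoff: float = 2.75  # Å
    selection: Selection = CA

    def __post_init__(self):
        if self.rmsd_cutoff <= 0:
            raise ValueError("rmsd cutoff must be > 0")


@dataclass(frozen=True)
class ClusterResult:
    """Cluster assignment by descending population.

    ``assignment[f]`` is the cluster id of windowed frame f; ``centers[c]``
    is the frame index of cluster c's centre; ``populations`` are percentages
    summing to 100.
    """

    assignment: np.ndarray
    centers: tuple[int, ...]
    populations: tuple[float, ...]

    def __post_init__(self):
        if abs(sum(self.populations) - 100.0) > 1e-9:
            raise ValueError("populations must sum to 100%")
        for c, center in enumerate(self.centers):
            if self.assignment[center] != c:
                raise ValueError("cluster centre must belong to its cluster")

    @property
    def n_clusters(self) -> int:
        return len(self.centers)


def daura_cluster(
    traj: Trajectory,
    top: Topology,
    params: ClusterParams = ClusterParams(),
    window: slice | None = None,
) -> ClusterResult:
    """Greedy neighbour-count clustering under a pairwise-RMSD cutoff.

    Each round picks the unassigned frame with the most unassigned
    neighbours within the cutoff (ties → lowest frame index) as a cluster
    centre; the centre and its neighbours form the cluster.  Clusters are
    reported by descending population (ties → lower centre index).
    """
    idx = params.selection.resolve(top)
    frames = traj.coordinates[window if window is not None else slice(None), :, :]
    X = frames[:, idx, :]
    n = X.shape[0]
    if n == 0:
        raise ValueError("empty frame window")
    D = pairwise_min_rmsd(X)
    neighbours = D <= params.rmsd_cutoff
    active = np.ones(n, bool)
    raw_clusters: list[tuple[int, np.ndarray]] = []
    while active.any():
        counts = (neighbours & active[None, :]).sum(axis=1)
        counts[~active] = -1
        center = int(np.argmax(counts))  # argmax takes the lowest index on ties
        members = np.flatnonzero(neighbours[center] & active)
        raw_clusters.append((center, members))
        active[members] = False
    order = sorted(
        range(len(raw_clusters)),
        key=lambda c: (-len(raw_clusters[c][1]), raw_clusters[c][0]),
    )
    assignment = np.empty(n, int)
    centers, pops = [], []
    for rank, c in enumerate(order):
        center, members = raw_clusters[c]
        assignment[members] = rank
        centers.append(center)
        pops.append(100.0 * len(members) / n)
    # force exact 100% despite float summation
    pops[-1] = 100.0 - sum(pops[:-1])
    return ClusterResult(
        assignment=assignment, centers=tuple(centers), populations=tuple(pops)
    )


def representative_structure(result: ClusterResult, rank: int = 0) -> int:
    """Frame index of the centre of the rank-th most populated cluster."""
    if not 0 <= rank < result.n_clusters:
        raise IndexError(
            f"cluster rank {rank} out of range (have {result.n_clusters} clusters)"
        )
    return result.centers[rank]


# --------------------------------------------------------------------------
# helix assignment
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class HelixAssignment:
    """Per-frame × per-residue helicity plus content summaries."""

    columns: tuple[tuple[str, int], ...]  # (chain, resnum) per column
    helical: np.ndarray                   # (n_frames, n_residues) bool

    @property
    def content(self) -> pd.Series:
        """Per-residue helical content, % of frames."""
        labels = [f"{ch}:{rn}" for ch, rn in self.columns]
        return pd.Series(100.0 * self.helical.mean(axis=0), index=labels,
                         name="helical_content_pct")

    def segment_content(self, chain: str, first: int, last: int) -> float:
        """Mean helical content (%) over the segment's member residues."""
        cols = [
            k for k, (ch, rn) in enumerate(self.columns)
            if ch == chain and first <= rn <= last
        ]
        if not cols:
            raise ValueError(f"no residues in segment {chain}:{first}-{last}")
        return float(100.0 * self.helical[:, cols].mean())


_HELIX_D_MAX = 3.5    # Å, O···N heavy-atom distance
_HELIX_DEV_MAX = 40.0  # degrees off N-H···O linearity


def assign_helix(
    traj: Trajectory,
    top: Topology,
    window: slice | None = None,
) -> HelixAssignment:
    """α-helix assignment from i→i+4 backbone hydrogen bonds.

    Residue i is helical in a frame when C=O(i−4)···H−N(i) or
    C=O(i)···H−N(i+4) satisfies d(O, N) ≤ 3.5 Å and an N−H···O deviation
    from linearity ≤ 40°.
    """
    frames = traj.coordinates[window if window is not None else slice(None), :, :]
    if frames.shape[0] == 0:
        raise ValueError("empty frame window")
    columns: list[tuple[str, int]] = []
    helical_cols: list[np.ndarray] = []
    for chain in top.chains:
        resnums = top.residues(chain)
        coords = {}
        missing = []
        for name in ("N", "H", "O"):
            idx = np.full(len(resnums), -1)
            for j, rn in enumerate(resnums):
                hit = np.flatnonzero(
                    (top.chain_id == chain)
                    & (top.residue_number == rn)
                    & (top.atom_name == name)
                )
                if hit.size:
                    idx[j] = hit[0]
                else:
                    missing.append(f"{chain}:{rn}:{name}")
            coords[name] = idx
        if missing:
            raise ValueError(
                "missing backbone atoms for helix assignment: " + ", ".join(missing)
            )
        O = frames[:, coords["O"], :]
        N = frames[:, coords["N"], :]
        H = frames[:, coords["H"], :]
        nres = len(resnums)
        # bond[t, j] for j >= 4: O(j-4) ... H-N(j)
        bond = np.zeros((frames.shape[0], nres), bool)
        if nres > 4:
            Ow = O[:, :-4, :]
            Nw = N[:, 4:, :]
            Hw = H[:, 4:, :]
            d = np.linalg.norm(Ow - Nw, axis=2)
            v1 = Nw - Hw
            v2 = Ow - Hw
            cosang = np.sum(v1 * v2, axis=2) / (
                np.linalg.norm(v1, axis=2) * np.linalg.norm(v2, axis=2)
            )
            ang = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
            bond[:, 4:] = (d <= _HELIX_D_MAX) & ((180.0 - ang) <= _HELIX_DEV_MAX)
        donor = bond
        acceptor = np.zeros_like(bond)
        acceptor[:, :-4] = bond[:, 4:]
        hel = donor | acceptor
        for j, rn in enumerate(resnums):
            columns.append((str(chain), int(rn)))
            helical_cols.append(hel[:, j])
    return HelixAssignment(
        columns=tuple(columns), helical=np.stack(helical_cols, axis=1)
    )
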