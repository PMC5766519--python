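import numpy as np
import pytest

from erassay.core import Topology, Trajectory
from erassay.synthetic import build_reference_dimer


def make_ca_topology(n: int, chain: str = "A", start: int = 303) -> Topology:
    """Minimal Cα-only topology of n consecutive residues on one chain."""
    return Topology(
        atom_name=np.array(["CA"] * n, dtype="U6"),
        element=np.array(["C"] * n, dtype="U2"),
        residue_number=np.arange(start, start + n),
        residue_name=np.array(["ALA"] * n, dtype="U5"),
        chain_id=np.array([chain] * n, dtype="U4"),
    )


def make_trajectory(coords: np.ndarray, dt_ns: float = 0.1) -> Trajectory:
    coords = np.asarray(coords, float)
    return Trajectory(coords, np.arange(coords.shape[0]) * dt_ns)


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random proper rotation matrix."""
    q = rng.standard_normal(4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - z * w), 2 * (x * z + y * w)],
            [2 * (x * y + z * w), 1 - 2 * (x * x + z * z), 2 * (y * z - x * w)],
            [2 * (x * z - y * w), 2 * (y * z + x * w), 1 - 2 * (x * x + y * y)],
        ]
    )


def horn_quaternion_rmsd(mobile: np.ndarray, reference: np.ndarray) -> float:
    """Independent optimal-superposition RMSD via Horn's quaternion method."""
    X = mobile - mobile.mean(axis=0)
    Y = reference - reference.mean(axis=0)
    Sxx, Sxy, Sxz = (X[:, 0] * Y[:, 0]).sum(), (X[:, 0] * Y[:, 1]).sum(), (X[:, 0] * Y[:, 2]).sum()
    Syx, Syy, Syz = (X[:, 1] * Y[:, 0]).sum(), (X[:, 1] * Y[:, 1]).sum(), (X[:, 1] * Y[:, 2]).sum()
    Szx, Szy, Szz = (X[:, 2] * Y[:, 0]).sum(), (X[:, 2] * Y[:, 1]).sum(), (X[:, 2] * Y[:, 2]).sum()
    K = np.array(
        [
            [Sxx + Syy + Szz, Syz - Szy, Szx - Sxz, Sxy - Syx],
            [Syz - Szy, Sxx - Syy - Szz, Sxy + Syx, Szx + Sxz],
            [Szx - Sxz, Sxy + Syx, -Sxx + Syy - Szz, Syz + Szy],
            [Sxy - Syx, Szx + Sxz, Syz + Szy, -Sxx - Syy + Szz],
        ]
    )
    lam = np.linalg.eigvalsh(K)[-1]
    sq = (np.sum(X**2) + np.sum(Y**2) - 2.0 * lam) / len(X)
    return float(np.sqrt(max(sq, 0.0)))


def daura_oracle(D: np.ndarray, cutoff: float):
    """Exhaustive greedy clustering: recount neighbours from scratch each
    round; ties broken by lowest frame index.  Returns (assignment, centers,
    populations) ordered by descending population."""
    n = D.shape[0]
    active = set(range(n))
    raw = []
    while active:
        best, best_count = None, -1
        for i in sorted(active):
            count = sum(1 for j in active if D[i, j] <= cutoff)
            if count > best_count:
                best, best_count = i, count
        members = sorted(j for j in active if D[best, j] <= cutoff)
        raw.append((best, members))
        active -= set(members)
    order = sorted(range(len(raw)), key=lambda c: (-len(raw[c][1]), raw[c][0]))
    assignment = np.empty(n, int)
    centers, pops = [], []
    for rank, c in enumerate(order):
        center, members = raw[c]
        assignment[list(members)] = rank
        centers.append(center)
        pops.append(100.0 * len(members) / n)
    return assignment, centers, pops


@pytest.fixture(scope="session")
def ref_dimer():
    return build_reference_dimer()
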