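"""Seeded synthetic dimer trajectories with planted statistical structure.

No deposited trajectories exist for the µs-scale ERα LBD simulations this
assay was designed around, so every downstream stage is validated against
trajectories generated here, where the ground truth is known by construction:

* **Inter-region correlations** — Cα displacements are drawn, independently
  per Cartesian component, from a zero-mean multivariate normal whose
  correlation matrix is assembled from shared latent factors: a plant
  (region A, region B, ρ) contributes loadings ±√|ρ| to the member residues,
  so every cross-region pair has correlation exactly ρ and the matrix is
  positive semi-definite by construction (a literal pairwise-only covariance
  is indefinite as soon as |ρ|·√(n_A·n_B) > 1).  Within-region pairs of a
  planted region pick up correlation |ρ| as a side effect; see
  docs/methods.md.
* **H-bond occupancy** — per frame, with probability p the acceptor atom is
  placed 2.8-3.1 Å from the donor with a D-H···A deviation from linearity
  ≤ 10°; otherwise it is parked ≥ 4.8 Å away.
* **Conformer mixtures** — each frame's base geometry is drawn from a
  weighted set of reference conformers (rigid segment shifts of the
  reference dimer) plus the correlated noise.
* **Helicity** — a planted segment uses ideal α-helix backbone geometry in a
  fraction q of frames and a displaced extended-strand geometry otherwise;
  the segment's backbone N/H/C/O follow that choice exactly (the Cα keeps
  the correlated noise), so planted helical content is an exact Bernoulli
  fraction.

The reference dimer is metrically valid but deliberately non-physical: two
continuous ideal α-helices (chains A and B, residues 303-552 each) carrying
named side-chain pseudo-atoms only for the residues whose interactions the
assay monitors (E380, H377, D351, N348, K529/K531, W383, 536-540, ...).
"""

from __future__ import annotations

import dataclasses
import json
import os
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import (
    Topology,
    Trajectory,
    default_region_scheme,
    write_topology_pdb,
    write_trajectory_dcd,
    write_trajectory_pdb,
)

__all__ = [
    "CorrelationPlant",
    "HBondPlant",
    "Conformer",
    "HelicityPlant",
    "SyntheticSpec",
    "GroundTruth",
    "build_reference_dimer",
    "generate_trajectory",
    "write_fixture",
    "CovarianceError",
]

FIRST_RESIDUE = 303
LAST_RESIDUE = 552

# ideal backbone internal coordinates (Å, degrees)
_B_N_CA, _B_CA_C, _B_C_N, _B_C_O, _B_N_H = 1.458, 1.525, 1.329, 1.231, 1.01
_A_N_CA_C, _A_CA_C_N, _A_C_N_CA, _A_CA_C_O = 111.2, 116.2, 121.7, 120.5
HELIX_PHI, HELIX_PSI = -57.0, -47.0
EXTENDED_PHI, EXTENDED_PSI = -139.0, 135.0


class CovarianceError(ValueError):
    """Planted correlations exceed a valid (positive semi-definite) model."""


# --------------------------------------------------------------------------
# plant specifications
# --------------------------------------------------------------------------

RegionRef = "str | tuple[int, int]"


@dataclass(frozen=True)
class CorrelationPlant:
    """Plant DCCM correlation ρ between every Cα pair of two residue sets.

    Regions may be named (default 14-region scheme) or explicit inclusive
    residue ranges ``(first, last)``.
    """

    region_a: object  # region name or (first, last)
    region_b: object
    rho: float
    chain_a: str = "A"
    chain_b: str = "A"

    def __post_init__(self):
        if not -1.0 <= self.rho <= 1.0:
            raise ValueError(f"|rho| must be <= 1, got {self.rho}")

    @property
    def label(self) -> str:
        def fmt(r):
            return r if isinstance(r, str) else f"{r[0]}-{r[1]}"

        return (
            f"{fmt(self.region_a)}@{self.chain_a}~{fmt(self.region_b)}"
            f"@{self.chain_b}"
        )


@dataclass(frozen=True)
class HBondPlant:
    """Plant an H-bond with given occupancy; atoms as (chain, resnum, name)."""

    label: str
    donor: tuple[str, int, str]
    hydrogen: tuple[str, int, str]
    acceptor: tuple[str, int, str]
    occupancy: float

    def __post_init__(self):
        if not 0.0 <= self.occupancy <= 1.0:
            raise ValueError("occupancy must be in [0, 1]")


@dataclass(frozen=True)
class Conformer:
    """A reference conformation: the base dimer with rigid segment shifts.

    ``shifts`` is a tuple of (chain, first_res, last_res, (dx, dy, dz)).
    """

    label: str
    weight: float
    shifts: tuple = ()


@dataclass(frozen=True)
class HelicityPlant:
    """A backbone segment that is helical in a fraction q of frames."""

    label: str
    chain: str
    first: int
    last: int
    fraction: float

    def __post_init__(self):
        if not 0.0 <= self.fraction <= 1.0:
            raise ValueError("fraction must be in [0, 1]")


@dataclass(frozen=True)
class SyntheticSpec:
    """Full recipe for one synthetic system.

    Defaults emulate one production run of the study design: 500 ns sampled
    every 0.1 ns (5000 frames) with ~1 Å per-coordinate Cα fluctuations.
    """

    seed: int
    n_frames: int = 5000
    dt_ns: float = 0.1
    sigma: float = 1.0
    variant: str = "WT"
    correlations: tuple = ()
    hbond_plants: tuple = ()
    conformers: tuple = (Conformer("ref", 1.0),)
    helicity_plants: tuple = ()
    ca_only: bool = False

    def __post_init__(self):
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")
        w = sum(c.weight for c in self.conformers)
        if abs(w - 1.0) > 1e-9:
            raise ValueError(f"conformer weights must sum to 1, got {w}")
        if self.ca_only and (self.hbond_plants or self.helicity_plants):
            raise ValueError("ca_only topologies cannot carry H-bond/helicity plants")


@dataclass
class GroundTruth:
    """Per-frame latent labels recorded by the generator."""

    frame_times: np.ndarray
    conformer: np.ndarray                    # (n,) conformer labels
    hbond_formed: dict[str, np.ndarray]      # label -> (n,) bool
    helical: dict[str, np.ndarray]           # label -> (n,) bool
    ca_displacements: np.ndarray             # (n, n_residues_total, 3), σ units of Å
    ca_columns: list[tuple[str, int]]        # (chain, resnum) per displacement column

    def displacement(self, chain: str, resnum: int) -> np.ndarray:
        return self.ca_displacements[:, self.ca_columns.index((chain, int(resnum))), :]

    def to_dataframe(self) -> pd.DataFrame:
        data = {
            "frame": np.arange(len(self.frame_times)),
            "time_ns": self.frame_times,
            "conformer": self.conformer,
        }
        for label, arr in self.hbond_formed.items():
            data[f"hbond_{label}"] = arr.astype(int)
        for label, arr in self.helical.items():
            data[f"helical_{label}"] = arr.astype(int)
        return pd.DataFrame(data)


# --------------------------------------------------------------------------
# geometry builders
# --------------------------------------------------------------------------

def _nerf(a, b, c, r, theta_deg, chi_deg):
    """Place atom d from three predecessors by internal coordinates."""
    theta = np.deg2rad(theta_deg)
    chi = np.deg2rad(chi_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d2 = r * np.array(
        [-np.cos(theta), np.sin(theta) * np.cos(chi), np.sin(theta) * np.sin(chi)]
    )
    return c + d2[0] * bc + d2[1] * m + d2[2] * n


def _build_backbone(n_res: int, phi: float, psi: float,
                    seed_atoms: tuple | None = None) -> dict[str, np.ndarray]:
    """Backbone N/CA/C/O/H coordinates for a poly-residue chain with uniform
    (phi, psi).  Returns arrays of shape (n_res, 3); H[0] duplicates N[0]+offset
    along the first N-CA bond (no preceding carbonyl exists)."""
    N = np.zeros((n_res, 3))
    CA = np.zeros((n_res, 3))
    C = np.zeros((n_res, 3))
    O = np.zeros((n_res, 3))
    H = np.zeros((n_res, 3))
    if seed_atoms is None:
        N[0] = (0.0, 0.0, 0.0)
        CA[0] = (_B_N_CA, 0.0, 0.0)
        ang = np.deg2rad(180.0 - _A_N_CA_C)
        C[0] = CA[0] + _B_CA_C * np.array([np.cos(ang), np.sin(ang), 0.0])
    else:
        N[0], CA[0], C[0] = seed_atoms
    O[0] = _nerf(N[0], CA[0], C[0], _B_C_O, _A_CA_C_O, psi + 180.0)
    H[0] = N[0] + _B_N_H * (N[0] - CA[0]) / np.linalg.norm(N[0] - CA[0])
    for i in range(1, n_res):
        N[i] = _nerf(N[i - 1], CA[i - 1], C[i - 1], _B_C_N, _A_CA_C_N, psi)
        CA[i] = _nerf(CA[i - 1], C[i - 1], N[i], _B_N_CA, _A_C_N_CA, 180.0)
        C[i] = _nerf(C[i - 1], N[i], CA[i], _B_CA_C, _A_N_CA_C, phi)
        O[i] = _nerf(N[i], CA[i], C[i], _B_C_O, _A_CA_C_O, psi + 180.0)
        hdir = C[i - 1] - O[i - 1]
        H[i] = N[i] + _B_N_H * hdir / np.linalg.norm(hdir)
    return {"N": N, "CA": CA, "C": C, "O": O, "H": H}


# side-chain pseudo-atom offsets in the residue's local frame
# (x outward from backbone, y/z spanning the perpendicular plane)
def _pentagon(center_x, radius, names):
    out = []
    for k, name in enumerate(names):
        a = np.deg2rad(90.0 + 72.0 * k)
        out.append((name, (center_x + radius * np.cos(a), radius * np.sin(a), 0.0)))
    return out


def _hexagon(center_x, radius, names):
    out = []
    for k, name in enumerate(names):
        a = np.deg2rad(60.0 * k)
        out.append((name, (center_x + radius * np.cos(a), radius * np.sin(a), 0.0)))
    return out


def _his_sidechain():
    ring = _pentagon(2.8, 1.13, ["CG", "ND1", "CE1", "NE2", "CD2"])
    atoms = dict(ring)
    out = list(ring)
    for nname, hname in (("ND1", "HD1"), ("NE2", "HE2")):
        x, y, z = atoms[nname]
        v = np.array([x - 2.8, y, z])
        v = 1.01 * v / np.linalg.norm(v)
        out.append((hname, (x + v[0], y + v[1], z + v[2])))
    return out


def _tyr_sidechain():
    ring = _hexagon(3.0, 1.39, ["CG", "CD1", "CE1", "CZ", "CE2", "CD2"])
    atoms = dict(ring)
    x, y, z = atoms["CZ"]
    return ring + [("OH", (x + 1.36, y, z))]


_SIDECHAINS: dict[str, list] = {
    "GLU": [("OE1", (3.2, 0.6, 0.0)), ("OE2", (3.2, -0.6, 0.0))],
    "ASP": [("OD1", (2.6, 0.6, 0.0)), ("OD2", (2.6, -0.6, 0.0))],
    "HIS": _his_sidechain(),
    "TYR": _tyr_sidechain(),
    "SER": [("OG", (2.0, 0.0, 0.0)), ("HG", (2.62, 0.81, 0.0))],
    "ASN": [
        ("OD1", (2.5, 0.7, 0.0)),
        ("ND2", (2.5, -0.7, 0.0)),
        ("HD21", (3.32, -1.31, 0.0)),
        ("HD22", (3.32, -0.09, 0.0)),
    ],
    "GLN": [
        ("OE1", (3.2, 0.7, 0.0)),
        ("NE2", (3.2, -0.7, 0.0)),
        ("HE21", (4.02, -1.31, 0.0)),
        ("HE22", (4.02, -0.09, 0.0)),
    ],
    "LEU": [("CD1", (2.9, 0.8, 0.0)), ("CD2", (2.9, -0.8, 0.0))],
    "LYS": [
        ("NZ", (3.9, 0.0, 0.0)),
        ("HZ1", (4.52, 0.81, 0.0)),
        ("HZ2", (4.52, -0.81, 0.0)),
        ("HZ3", (3.9, 0.0, 1.02)),
    ],
    "TRP": [("CZ2", (3.6, 1.0, 0.0)), ("CZ3", (3.6, -1.0, 0.0)), ("CH2", (4.3, 0.0, 0.0))],
    "GLY": [],
    "ALA": [],
}

# residues carrying explicit side-chain pseudo-atoms (both chains); everything
# else is an ALA-like backbone stub
_SIGNATURE_RESIDUES: dict[int, str] = {
    346: "LEU",
    348: "ASN",
    351: "ASP",
    377: "HIS",
    380: "GLU",
    383: "TRP",
    529: "LYS",
    530: "ALA",  # C530 stub; cysteine side chain not needed geometrically
    531: "LYS",
    539: "LEU",
    540: "LEU",
}

#: residue names at the mutation site per isoform (536, 537, 538)
VARIANT_SITE: dict[str, tuple[str, str, str]] = {
    "WT": ("LEU", "TYR", "ASP"),
    "L536Q": ("GLN", "TYR", "ASP"),
    "Y537S": ("LEU", "SER", "ASP"),
    "Y537N": ("LEU", "ASN", "ASP"),
    "D538G": ("LEU", "TYR", "GLY"),
}


def _residue_names(variant: str) -> dict[int, str]:
    if variant not in VARIANT_SITE:
        raise ValueError(
            f"unknown variant {variant!r}; known: {', '.join(VARIANT_SITE)}"
        )
    names = dict(_SIGNATURE_RESIDUES)
    names[536], names[537], names[538] = VARIANT_SITE[variant]
    return names


def _local_frame(n, ca, c):
    u = n - ca
    u /= np.linalg.norm(u)
    v = c - ca
    v /= np.linalg.norm(v)
    x = -(u + v)
    x /= np.linalg.norm(x)
    z = np.cross(u, v)
    z /= np.linalg.norm(z)
    y = np.cross(z, x)
    return np.stack([x, y, z], axis=1)  # columns are local axes


def build_reference_dimer(
    variant: str = "WT", ca_only: bool = False
) -> tuple[Topology, np.ndarray]:
    """Ideal-helix LBD dimer: chains A and B, residues 303-552 each.

    Chain B is chain A translated by 30 Å along x.  Backbone is a continuous
    ideal α-helix; signature residues carry named side-chain pseudo-atoms in
    the residue's local frame.  Minimum interatomic distance >= 1.0 Å.
    """
    res_names = _residue_names(variant)
    n_res = LAST_RESIDUE - FIRST_RESIDUE + 1
    bb = _build_backbone(n_res, HELIX_PHI, HELIX_PSI)

    names, elems, resnums, resnames, chains, coords = [], [], [], [], [], []
    for chain, offset in (("A", np.zeros(3)), ("B", np.array([30.0, 0.0, 0.0]))):
        for i in range(n_res):
            resnum = FIRST_RESIDUE + i
            rname = res_names.get(resnum, "ALA")
            frame = _local_frame(bb["N"][i], bb["CA"][i], bb["C"][i])
            if ca_only:
                atom_list = [("CA", bb["CA"][i])]
            else:
                atom_list = [
                    ("N", bb["N"][i]),
                    ("H", bb["H"][i]),
                    ("CA", bb["CA"][i]),
                    ("C", bb["C"][i]),
                    ("O", bb["O"][i]),
                ]
                for aname, local in _SIDECHAINS[rname]:
                    atom_list.append((aname, bb["CA"][i] + frame @ np.asarray(local)))
            for aname, pos in atom_list:
                names.append(aname)
                elems.append(aname[0] if aname[0] in "CNOSH" else "C")
                resnums.append(resnum)
                resnames.append(rname)
                chains.append(chain)
                coords.append(pos + offset)
    top = Topology(
        atom_name=np.array(names, dtype="U6"),
        element=np.array(elems, dtype="U2"),
        residue_number=np.array(resnums, dtype=int),
        residue_name=np.array(resnames, dtype="U5"),
        chain_id=np.array(chains, dtype="U4"),
    )
    return top, np.array(coords, float)


def _extended_segment(base_bb: dict[str, np.ndarray], first_i: int, last_i: int):
    """Extended-strand backbone for segment residues, displaced 8 Å outward so
    neither within-segment nor cross-boundary i->i+4 H-bond geometry survives."""
    n_seg = last_i - first_i + 1
    seg = _build_backbone(n_seg, EXTENDED_PHI, EXTENDED_PSI)
    # anchor the strand at the segment's first Cα, then push it away
    shift = base_bb["CA"][first_i] - seg["CA"][0] + np.array([8.0, 0.0, 0.0])
    return {k: v + shift for k, v in seg.items()}


# --------------------------------------------------------------------------
# correlated-noise model
# --------------------------------------------------------------------------

def _resolve_region(region, chain, ca_columns):
    scheme = default_region_scheme()
    if isinstance(region, str):
        lo, hi = scheme.range(region)
    else:
        lo, hi = int(region[0]), int(region[1])
    idx = [
        k for k, (ch, rn) in enumerate(ca_columns) if ch == chain and lo <= rn <= hi
    ]
    if not idx:
        raise ValueError(f"region {region!r} on chain {chain!r} has no residues")
    return np.array(idx)


def _factor_loadings(correlations, ca_columns) -> np.ndarray:
    """(n_residues, n_plants) loading matrix; cross-region correlation of
    plant p is exactly rho_p."""
    n = len(ca_columns)
    cols = []
    for plant in correlations:
        if plant.rho == 0.0:
            cols.append(np.zeros(n))
            continue
        lam = np.zeros(n)
        ia = _resolve_region(plant.region_a, plant.chain_a, ca_columns)
        ib = _resolve_region(plant.region_b, plant.chain_b, ca_columns)
        root = np.sqrt(abs(plant.rho))
        lam[ia] = root
        lam[ib] = np.sign(plant.rho) * root
        if np.intersect1d(ia, ib).size and set(ia) != set(ib):
            raise ValueError(
                f"correlation plant {plant.label} has partially overlapping regions"
            )
        cols.append(lam)
    if not cols:
        return np.zeros((n, 0))
    lam = np.column_stack(cols)
    resid = 1.0 - np.sum(lam**2, axis=1)
    if np.any(resid < -1e-12):
        bad = [ca_columns[k] for k in np.flatnonzero(resid < -1e-12)][:5]
        raise CovarianceError(
            "planted correlations are not jointly realisable (residual variance "
            f"negative at residues {bad}); reduce |rho| or the number of "
            "overlapping plants"
        )
    return lam


# --------------------------------------------------------------------------
# generator
# --------------------------------------------------------------------------

def generate_trajectory(
    spec: SyntheticSpec,
) -> tuple[Topology, Trajectory, GroundTruth]:
    """Generate a seeded trajectory with the planted structure of ``spec``.

    All randomness flows from one counter-based (Philox) stream keyed by
    ``spec.seed``; a fixed spec therefore reproduces the trajectory
    bit-identically.
    """
    rng = np.random.Generator(np.random.Philox(key=int(spec.seed)))
    top, base = build_reference_dimer(spec.variant, ca_only=spec.ca_only)
    n = spec.n_frames

    # per-residue bookkeeping
    ca_columns: list[tuple[str, int]] = []
    col_of: dict[tuple[str, int], int] = {}
    for ch, rn, an in zip(top.chain_id, top.residue_number, top.atom_name):
        if an == "CA":
            col_of[(str(ch), int(rn))] = len(ca_columns)
            ca_columns.append((str(ch), int(rn)))
    atom_res_col = np.array(
        [col_of[(str(ch), int(rn))] for ch, rn in zip(top.chain_id, top.residue_number)]
    )
    atom_index: dict[tuple[str, int, str], int] = {
        (str(ch), int(rn), str(an)): k
        for k, (ch, rn, an) in enumerate(
            zip(top.chain_id, top.residue_number, top.atom_name)
        )
    }

    # conformer library
    conf_coords = []
    for conf in spec.conformers:
        c = base.copy()
        for chain, first, last, vec in conf.shifts:
            mask = (top.chain_id == chain) & (
                (top.residue_number >= first) & (top.residue_number <= last)
            )
            c[mask] += np.asarray(vec, float)
        conf_coords.append(c)
    weights = np.array([c.weight for c in spec.conformers], float)
    conf_draw = rng.choice(len(spec.conformers), size=n, p=weights / weights.sum())
    conf_labels = np.array([spec.conformers[k].label for k in conf_draw])

    # correlated Cα noise: disp[t, residue, axis], each axis iid with the
    # factor-model correlation matrix, marginal sd = sigma
    lam = _factor_loadings(spec.correlations, ca_columns)
    resid_sd = np.sqrt(np.clip(1.0 - np.sum(lam**2, axis=1), 0.0, None))
    factors = rng.standard_normal((n, lam.shape[1], 3))
    eps = rng.standard_normal((n, len(ca_columns), 3))
    disp = spec.sigma * (
        np.einsum("kp,tpc->tkc", lam, factors) + eps * resid_sd[None, :, None]
    )

    coords = conf_coords[0][None].repeat(n, axis=0) if len(spec.conformers) == 1 \
        else np.stack([conf_coords[k] for k in conf_draw])
    coords = coords + disp[:, atom_res_col, :]

    # helicity plants: backbone N/H/C/O of the segment follow the chosen
    # conformation exactly (Cα keeps the correlated noise)
    helical: dict[str, np.ndarray] = {}
    if spec.helicity_plants:
        n_res = LAST_RESIDUE - FIRST_RESIDUE + 1
        helix_bb = _build_backbone(n_res, HELIX_PHI, HELIX_PSI)
        for plant in spec.helicity_plants:
            is_helical = rng.random(n) < plant.fraction
            helical[plant.label] = is_helical
            fi, li = plant.first - FIRST_RESIDUE, plant.last - FIRST_RESIDUE
            ext_bb = _extended_segment(helix_bb, fi, li)
            offset = np.array([30.0, 0.0, 0.0]) if plant.chain == "B" else np.zeros(3)
            for j, resnum in enumerate(range(plant.first, plant.last + 1)):
                for aname in ("N", "H", "C", "O"):
                    k = atom_index.get((plant.chain, resnum, aname))
                    if k is None:
                        raise ValueError(
                            f"backbone atom {aname} missing for residue "
                            f"{plant.chain}:{resnum}"
                        )
                    hp = helix_bb[aname][fi + j] + offset
                    ep = ext_bb[aname][j] + offset
                    coords[:, k, :] = np.where(
                        is_helical[:, None], hp[None, :], ep[None, :]
                    )

    # H-bond plants: acceptor placed relative to the (noisy) donor geometry
    hbond_formed: dict[str, np.ndarray] = {}
    for plant in spec.hbond_plants:
        try:
            di = atom_index[plant.donor]
            hi = atom_index[plant.hydrogen]
            ai = atom_index[plant.acceptor]
        except KeyError as exc:
            raise ValueError(f"H-bond plant {plant.label}: atom {exc} not in topology")
        formed = rng.random(n) < plant.occupancy
        hbond_formed[plant.label] = formed
        dev = np.deg2rad(rng.uniform(0.0, 10.0, size=n))
        azim = rng.uniform(0.0, 2.0 * np.pi, size=n)
        d_target = rng.uniform(2.8, 3.1, size=n)
        d_far = rng.uniform(4.8, 6.0, size=n)

        D = coords[:, di, :]
        Hc = coords[:, hi, :]
        u = Hc - D
        d_dh = np.linalg.norm(u, axis=1, keepdims=True)
        u = u / d_dh
        # orthonormal complement of u, rotation by the sampled deviation
        ref = np.where(np.abs(u[:, [0]]) < 0.9, [[1.0, 0.0, 0.0]], [[0.0, 1.0, 0.0]])
        p1 = np.cross(u, ref)
        p1 /= np.linalg.norm(p1, axis=1, keepdims=True)
        p2 = np.cross(u, p1)
        w = (
            np.cos(dev)[:, None] * u
            + np.sin(dev)[:, None]
            * (np.cos(azim)[:, None] * p1 + np.sin(azim)[:, None] * p2)
        )
        dh = d_dh[:, 0]
        r = -dh * np.cos(dev) + np.sqrt(
            np.maximum(d_target**2 - (dh * np.sin(dev)) ** 2, 0.0)
        )
        a_formed = Hc + r[:, None] * w
        a_far = D + d_far[:, None] * u
        coords[:, ai, :] = np.where(formed[:, None], a_formed, a_far)

    times = np.arange(n, dtype=float) * float(spec.dt_ns)
    truth = GroundTruth(
        frame_times=times,
        conformer=conf_labels,
        hbond_formed=hbond_formed,
        helical=helical,
        ca_displacements=disp.astype(np.float32),
        ca_columns=ca_columns,
    )
    return top, Trajectory(coordinates=coords, frame_times=times), truth


# --------------------------------------------------------------------------
# fixture writer
# --------------------------------------------------------------------------

def write_fixture(
    top: Topology,
    traj: Trajectory,
    outdir: str | os.PathLike,
    truth: GroundTruth | None = None,
    spec: SyntheticSpec | None = None,
) -> dict[str, str]:
    """Write topology.pdb, traj.pdb, traj.dcd (+ truth.csv, config.json).

    Deterministic output: rerunning with the same inputs overwrites every
    file with identical bytes.
    """
    outdir = str(outdir)
    os.makedirs(outdir, exist_ok=True)
    paths = {
        "topology": os.path.join(outdir, "topology.pdb"),
        "traj_pdb": os.path.join(outdir, "traj.pdb"),
        "traj_dcd": os.path.join(outdir, "traj.dcd"),
    }
    write_topology_pdb(top, traj.coordinates[0], paths["topology"])
    write_trajectory_pdb(top, traj, paths["traj_pdb"])
    write_trajectory_dcd(traj, paths["traj_dcd"])
    if truth is not None:
        paths["truth"] = os.path.join(outdir, "truth.csv")
        truth.to_dataframe().to_csv(paths["truth"], index=False)
    if spec is not None:
        paths["config"] = os.path.join(outdir, "config.json")
        with open(paths["config"], "w") as fh:
            json.dump(dataclasses.asdict(spec), fh, indent=2, sort_keys=True,
                      default=list)
            fh.write("\n")
    return paths
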