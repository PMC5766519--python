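"""Geometric interaction detection and persistence statistics.

Hydrogen bonds use the donor-acceptor heavy-atom distance / linearity
criterion d(D, A) ≤ 3.3 Å and a D−H···A deviation from 180° of at most 35°
(i.e. an angle at the hydrogen of ≥ 145°); salt bridges are H-bonds between
charged groups under the same rule.  Hydrophobic contacts use a minimum
heavy-atom cross-distance cutoff (default 4.5 Å); π-stacking uses ring
centroid distance plus the acute angle between best-fit ring planes
(defaults 5.0 Å / 30°).  Persistence is the percentage of analysed frames in
which the interaction is present.

Multi-atom alternative sites (Oδ1/Oδ2 of a carboxylate, Nδ1/Nε2 of an
imidazole) are OR-combined into one labelled interaction, mirroring the
"Oδ1/Oδ2@D351" style of notation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import EmptySelectionError, Selection, Topology, Trajectory

__all__ = [
    "HBondParams",
    "InteractionSpec",
    "InteractionSeries",
    "MissingHydrogenError",
    "detect_hbond_frame",
    "hbond_series",
    "persistence",
    "contact_persistence",
    "pi_stacking",
    "signature_panel",
]


class MissingHydrogenError(ValueError):
    """Donor hydrogen cannot be resolved; suggests distance-only mode."""


@dataclass(frozen=True)
class HBondParams:
    """H-bond geometry cutoffs: heavy-atom distance and angular deviation."""

    d_max: float = 3.3       # Å, donor-acceptor heavy-atom distance
    theta_max: float = 35.0  # degrees, deviation of D-H...A from linearity
    distance_only: bool = False  # heavy-atom fallback when no H is present

    def __post_init__(self):
        if self.d_max <= 0:
            raise ValueError("d_max must be > 0")
        if not 0 < self.theta_max < 90:
            raise ValueError("theta_max must be in (0, 90) degrees")


@dataclass(frozen=True)
class InteractionSpec:
    """A named interaction with the selections its kind requires.

    kind == "hbond" / "salt_bridge": donor, hydrogen, acceptor selections
    (each may resolve to several alternative atoms; all triplets are
    OR-combined).  kind == "hydrophobic_contact": group_a, group_b heavy-atom
    selections.  kind == "pi_stack": ring_a, ring_b selections of ≥ 3 atoms.
    """

    kind: str
    label: str
    donor: Selection | None = None
    hydrogen: Selection | None = None
    acceptor: Selection | None = None
    group_a: Selection | None = None
    group_b: Selection | None = None

    def __post_init__(self):
        kinds = ("hbond", "salt_bridge", "hydrophobic_contact", "pi_stack")
        if self.kind not in kinds:
            raise ValueError(f"kind must be one of {kinds}")
        if self.kind in ("hbond", "salt_bridge"):
            if self.donor is None or self.acceptor is None:
                raise ValueError(f"{self.kind} spec needs donor and acceptor")
        elif self.group_a is None or self.group_b is None:
            raise ValueError(f"{self.kind} spec needs group_a and group_b")


@dataclass(frozen=True)
class InteractionSeries:
    """Per-frame presence of one labelled interaction."""

    label: str
    kind: str
    present: np.ndarray  # (n_frames,) bool

    @property
    def n_frames(self) -> int:
        return len(self.present)

    @property
    def persistence(self) -> float:
        """Percent of analysed frames in which the interaction is present."""
        return float(100.0 * np.mean(self.present)) if self.n_frames else 0.0


# --------------------------------------------------------------------------
# frame-level geometry
# --------------------------------------------------------------------------

def _hbond_geometry(D, H, A, params: HBondParams):
    d = np.linalg.norm(np.asarray(D) - np.asarray(A))
    if d > params.d_max:
        return False
    if params.distance_only or H is None:
        return True
    v1 = np.asarray(D) - np.asarray(H)
    v2 = np.asarray(A) - np.asarray(H)
    cosang = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
    angle = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
    return (180.0 - angle) <= params.theta_max


def _resolve_triplets(top: Topology, spec: InteractionSpec, params: HBondParams):
    donors = spec.donor.resolve(top)
    acceptors = spec.acceptor.resolve(top)
    if params.distance_only:
        hydros: np.ndarray | None = None
    else:
        if spec.hydrogen is None:
            raise MissingHydrogenError(
                f"{spec.label}: no hydrogen selection; use "
                "HBondParams(distance_only=True) for a heavy-atom-only rule"
            )
        try:
            hydros = spec.hydrogen.resolve(top)
        except EmptySelectionError as exc:
            raise MissingHydrogenError(
                f"{spec.label}: hydrogen selection resolves to no atoms; use "
                "HBondParams(distance_only=True) for a heavy-atom-only rule"
            ) from exc
    return donors, hydros, acceptors


def detect_hbond_frame(
    frame: np.ndarray,
    top: Topology,
    spec: InteractionSpec,
    params: HBondParams = HBondParams(),
) -> bool:
    """True iff any expanded (donor, H, acceptor) triplet satisfies the rule
    d(D, A) ≤ d_max and (180° − angle(D, H, A)) ≤ θ_max in this frame."""
    donors, hydros, acceptors = _resolve_triplets(top, spec, params)
    for di in donors:
        for ai in acceptors:
            if di == ai:
                continue
            if hydros is None:
                if _hbond_geometry(frame[di], None, frame[ai], params):
                    return True
            else:
                for hi in hydros:
                    if _hbond_geometry(frame[di], frame[hi], frame[ai], params):
                        return True
    return False


# --------------------------------------------------------------------------
# series / persistence
# --------------------------------------------------------------------------

def _frames(traj: Trajectory, window: slice | None) -> np.ndarray:
    out = traj.coordinates[window if window is not None else slice(None), :, :]
    if out.shape[0] == 0:
        raise ValueError("empty frame window")
    return out


def hbond_series(
    traj: Trajectory,
    top: Topology,
    spec: InteractionSpec,
    params: HBondParams = HBondParams(),
    window: slice | None = None,
) -> InteractionSeries:
    """Vectorised per-frame H-bond presence (OR over expanded triplets)."""
    frames = _frames(traj, window)
    donors, hydros, acceptors = _resolve_triplets(top, spec, params)
    present = np.zeros(frames.shape[0], bool)
    for di in donors:
        D = frames[:, di, :]
        for ai in acceptors:
            if di == ai:
                continue
            A = frames[:, ai, :]
            d = np.linalg.norm(D - A, axis=1)
            ok = d <= params.d_max
            if hydros is None:
                present |= ok
                continue
            for hi in hydros:
                Hc = frames[:, hi, :]
                v1 = D - Hc
                v2 = A - Hc
                cosang = np.sum(v1 * v2, axis=1) / (
                    np.linalg.norm(v1, axis=1) * np.linalg.norm(v2, axis=1)
                )
                ang = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
                present |= ok & ((180.0 - ang) <= params.theta_max)
    return InteractionSeries(label=spec.label, kind=spec.kind, present=present)


def persistence(
    traj: Trajectory,
    top: Topology,
    spec: InteractionSpec,
    params: HBondParams = HBondParams(),
    window: slice | None = None,
) -> InteractionSeries:
    """Per-frame detection over the window for any interaction kind."""
    if spec.kind in ("hbond", "salt_bridge"):
        return hbond_series(traj, top, spec, params, window)
    if spec.kind == "hydrophobic_contact":
        return contact_persistence(traj, top, spec.group_a, spec.group_b,
                                   window=window, label=spec.label)
    return pi_stacking(traj, top, spec.group_a, spec.group_b, window=window,
                       label=spec.label)


def contact_persistence(
    traj: Trajectory,
    top: Topology,
    group_a: Selection,
    group_b: Selection,
    cutoff: float = 4.5,
    window: slice | None = None,
    label: str = "contact",
) -> InteractionSeries:
    """Contact present in a frame iff the minimum heavy-atom cross-distance
    between the two groups is ≤ cutoff (Å)."""
    frames = _frames(traj, window)
    ia = group_a.resolve(top)
    ib = group_b.resolve(top)
    A = frames[:, ia, :]
    B = frames[:, ib, :]
    d = np.linalg.norm(A[:, :, None, :] - B[:, None, :, :], axis=3)
    present = d.min(axis=(1, 2)) <= cutoff
    return InteractionSeries(label=label, kind="hydrophobic_contact",
                             present=present)


def _ring_planes(P: np.ndarray):
    """Centroids and unit normals of ring atom sets per frame (n, m, 3)."""
    centroid = P.mean(axis=1)
    Q = P - centroid[:, None, :]
    # smallest right singular vector = best-fit plane normal
    _, s, Vt = np.linalg.svd(Q)
    if np.any(s[:, 1] < 1e-8):
        raise ValueError("collinear ring atoms: plane normal undefined")
    return centroid, Vt[:, 2, :]


def pi_stacking(
    traj: Trajectory,
    top: Topology,
    ring_a: Selection,
    ring_b: Selection,
    d_centroid: float = 5.0,
    angle_max: float = 30.0,
    window: slice | None = None,
    label: str = "pi_stack",
) -> InteractionSeries:
    """Stacking present iff ring-centroid distance ≤ d_centroid and the acute
    angle between best-fit ring planes is ≤ angle_max (degrees)."""
    frames = _frames(traj, window)
    ia = ring_a.resolve(top)
    ib = ring_b.resolve(top)
    if ia.size < 3 or ib.size < 3:
        raise ValueError("each ring needs at least 3 atoms")
    ca, na = _ring_planes(frames[:, ia, :])
    cb, nb = _ring_planes(frames[:, ib, :])
    d = np.linalg.norm(ca - cb, axis=1)
    cosang = np.abs(np.sum(na * nb, axis=1))
    angle = np.degrees(np.arccos(np.clip(cosang, 0.0, 1.0)))
    present = (d <= d_centroid) & (angle <= angle_max)
    return InteractionSeries(label=label, kind="pi_stack", present=present)


# --------------------------------------------------------------------------
# signature panel
# --------------------------------------------------------------------------

def _sel(chain, res, names):
    return Selection.of(chains=[chain], residues=[res], names=names)


def _builtin_signatures(chain: str, variant_537: str) -> list[dict]:
    """The mechanistic signature set monitored per monomer.

    E380-H377 stabilises the antagonist H12 pose; the D351···L11-12 backbone
    family and D351···S537 mark mutant self-activation; K529/K531 salt
    bridges anchor elongated SERD tails; the L536 hydrophobic pocket hosts
    the fulvestrant tail; Y537-H377 stacking reports the wild-type pose.
    """
    sigs: list[dict] = [
        dict(kind="hbond", label="E380-H377",
             donor=_sel(chain, 377, ["ND1", "NE2"]),
             hydrogen=_sel(chain, 377, ["HD1", "HE2"]),
             acceptor=_sel(chain, 380, ["OE1", "OE2"])),
        dict(kind="hbond", label="N348-L536bb",
             donor=_sel(chain, 348, ["ND2"]),
             hydrogen=_sel(chain, 348, ["HD21", "HD22"]),
             acceptor=_sel(chain, 536, ["O"])),
    ]
    for res in (538, 539, 540):
        sigs.append(
            dict(kind="hbond", label=f"D351-{res}bb",
                 donor=_sel(chain, res, ["N"]),
                 hydrogen=_sel(chain, res, ["H"]),
                 acceptor=_sel(chain, 351, ["OD1", "OD2"]))
        )
    sigs.append(
        dict(kind="hbond", label="D351-S537",
             donor=_sel(chain, 537, ["OG"]),
             hydrogen=_sel(chain, 537, ["HG"]),
             acceptor=_sel(chain, 351, ["OD1", "OD2"]))
    )
    sigs.append(
        dict(kind="hbond", label="E380-537side",
             donor=_sel(chain, 537, ["OG", "ND2", "OH"]),
             hydrogen=_sel(chain, 537, ["HG", "HD21", "HD22"]),
             acceptor=_sel(chain, 380, ["OE1", "OE2"]))
    )
    for lys in (529, 531):
        sigs.append(
            dict(kind="salt_bridge", label=f"LIG-K{lys}",
                 donor=_sel(chain, lys, ["NZ"]),
                 hydrogen=_sel(chain, lys, ["HZ1", "HZ2", "HZ3"]),
                 acceptor=Selection.of(chains=[chain], residues=[900],
                                       names=["O1", "O2"]))
        )
    sigs.append(
        dict(kind="hydrophobic_contact", label="L536-pocket",
             group_a=_sel(chain, 536, ["CD1", "CD2", "OE1", "NE2"]),
             group_b=Selection.of(chains=[chain], residues=[383, 539, 540],
                                  names=["CZ2", "CZ3", "CH2", "CD1", "CD2"]))
    )
    sigs.append(
        dict(kind="pi_stack", label="Y537-H377",
             group_a=_sel(chain, 537, ["CG", "CD1", "CD2", "CE1", "CE2", "CZ"]),
             group_b=_sel(chain, 377, ["CG", "ND1", "CD2", "CE1", "NE2"]))
    )
    return sigs


def signature_panel(
    top: Topology,
    traj: Trajectory,
    isoform: str = "WT",
    ligand: str = "apo",
    params: HBondParams = HBondParams(),
    window: slice | None = None,
    chains: tuple[str, ...] | None = None,
    extra_specs: tuple[InteractionSpec, ...] = (),
) -> pd.DataFrame:
    """Persistence table of the built-in signature set, one row per
    (signature, monomer); rows whose atoms are absent from the topology
    (e.g. S537 Oγ in the wild type, or ligand atoms in an apo system) are
    reported as not applicable rather than silently dropped."""
    if chains is None:
        chains = top.chains
    n_frames = _frames(traj, window).shape[0]
    rows = []
    for chain in chains:
        specs = [
            InteractionSpec(**{k: v for k, v in sig.items()})
            for sig in _builtin_signatures(chain, isoform)
        ] + [s for s in extra_specs]
        for spec in specs:
            try:
                series = persistence(traj, top, spec, params, window)
                rows.append(
                    dict(isoform=isoform, ligand=ligand, chain=chain,
                         label=spec.label, kind=spec.kind,
                         persistence_pct=round(series.persistence, 4),
                         n_frames=series.n_frames, applicable=True)
                )
            except (EmptySelectionError, MissingHydrogenError):
                rows.append(
                    dict(isoform=isoform, ligand=ligand, chain=chain,
                         label=spec.label, kind=spec.kind,
                         persistence_pct=np.nan, n_frames=n_frames,
                         applicable=False)
                )
    return pd.DataFrame(rows)
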