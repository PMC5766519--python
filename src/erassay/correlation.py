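"""Dynamic cross-correlation analysis and H12 activation scoring.

The dynamic cross-correlation matrix (DCCM) over Cα atoms,

    C_ij = <Δr_i · Δr_j> / sqrt(<|Δr_i|²> <|Δr_j|²>),   Δr_i = r_i − <r_i>,

is aggregated two ways:

* a 14×14 **region score map**: for regions A, B the score is the sum of
  C_ij over residue pairs whose |C_ij| reaches the threshold τ (default
  0.6), optionally divided by the pair count (``per_pair_mean``);
* a per-residue **H12 profile**: for each H12 residue i and target region R,
  s_i(R) = Σ_{j∈R} C_ij·1[|C_ij| ≥ τ] (raw sum), with region totals
  Σ_i s_i(R).

The H12↔H3 (or H5) total is the activation metric: the estradiol-bound
wild-type receptor scores 4, taken as the reference for the agonist-like
state, so a monomer is classified *high* (≥ 4, active / drug ineffective),
*intermediate* ([2, 4)), or *low* (< 2).  A drug is called effective only if
both monomers stay below the activation threshold.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .conformation import kabsch_superpose
from .core import CA, RegionScheme, Selection, Topology, Trajectory

__all__ = [
    "CorrelationMatrix",
    "ScoreParams",
    "ActivationParams",
    "ActivationVerdict",
    "H12Profile",
    "superpose_to_mean",
    "compute_dccm",
    "aggregate_region_scores",
    "h12_profile",
    "classify_activation",
]


@dataclass(frozen=True)
class CorrelationMatrix:
    """Residue-labelled normalized covariance matrix (entries in [-1, 1])."""

    residues: tuple[tuple[str, int], ...]  # (chain, resnum) per row
    C: np.ndarray

    def __post_init__(self):
        n = len(self.residues)
        if self.C.shape != (n, n):
            raise ValueError("matrix shape inconsistent with residue labels")

    def index_of(self, chain: str, resnum: int) -> int:
        return self.residues.index((chain, int(resnum)))

    def block(self, rows: np.ndarray, cols: np.ndarray) -> np.ndarray:
        return self.C[np.ix_(rows, cols)]

    def to_dataframe(self) -> pd.DataFrame:
        labels = [f"{ch}:{rn}" for ch, rn in self.residues]
        return pd.DataFrame(self.C, index=labels, columns=labels)


@dataclass(frozen=True)
class ScoreParams:
    """Aggregation parameters: threshold τ and normalization mode."""

    threshold: float = 0.6
    normalization: str = "raw_sum"  # or "per_pair_mean"

    def __post_init__(self):
        if self.threshold < 0:
            raise ValueError("threshold must be >= 0")
        if self.normalization not in ("raw_sum", "per_pair_mean"):
            raise ValueError("normalization must be raw_sum or per_pair_mean")


@dataclass(frozen=True)
class ActivationParams:
    """Activation threshold (default 4) and intermediate band [2, 4)."""

    activation_threshold: float = 4.0
    intermediate_floor: float = 2.0

    def __post_init__(self):
        if self.activation_threshold <= 0:
            raise ValueError("activation threshold must be > 0")
        if not 0 <= self.intermediate_floor <= self.activation_threshold:
            raise ValueError("intermediate floor must lie in [0, threshold]")


@dataclass(frozen=True)
class H12Profile:
    """Per-H12-residue thresholded correlation sums against each other region."""

    chain: str
    table: pd.DataFrame  # rows: H12 residues; columns: target regions

    @property
    def totals(self) -> pd.Series:
        return self.table.sum(axis=0)

    def score(self, region: str) -> float:
        return float(self.totals[region])


@dataclass(frozen=True)
class ActivationVerdict:
    """Per-monomer H12-H3/H5 scores and tier, plus the overall efficacy flag."""

    scores: dict  # chain -> {"H3": float, "H5": float}
    tiers: dict   # chain -> "high" | "intermediate" | "low"
    effective: bool
    params: ActivationParams = field(default_factory=ActivationParams)

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for chain in self.scores:
            rows.append(
                {
                    "chain": chain,
                    "H12_H3_score": self.scores[chain]["H3"],
                    "H12_H5_score": self.scores[chain]["H5"],
                    "tier": self.tiers[chain],
                    "drug_effective": self.effective,
                }
            )
        return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# superposition to the converged mean
# --------------------------------------------------------------------------

def superpose_to_mean(
    traj: Trajectory,
    top: Topology,
    sel: Selection = CA,
    max_iter: int = 10,
    tol: float = 1e-6,
) -> tuple[Trajectory, np.ndarray]:
    """Iteratively superpose all frames onto their mean structure.

    Fits on ``sel`` (default Cα) but transforms all atoms.  Iterates
    fit → recompute mean until the mean moves less than ``tol`` (Å, RMS) or
    ``max_iter`` is reached.  Returns the aligned trajectory and the
    converged mean coordinates of the fit selection.
    """
    if traj.n_frames < 2:
        raise ValueError("superposition needs at least 2 frames")
    idx = sel.resolve(top)
    if idx.size < 3:
        raise ValueError("superposition under-determined: fewer than 3 fit atoms")
    coords = traj.coordinates.copy()
    mean = coords[:, idx, :].mean(axis=0)
    for _ in range(max_iter):
        for t in range(coords.shape[0]):
            R, tvec, _ = kabsch_superpose(coords[t, idx, :], mean)
            coords[t] = coords[t] @ R.T + tvec
        new_mean = coords[:, idx, :].mean(axis=0)
        shift = np.sqrt(np.mean(np.sum((new_mean - mean) ** 2, axis=1)))
        mean = new_mean
        if shift < tol:
            break
    return Trajectory(coords, traj.frame_times), mean


# --------------------------------------------------------------------------
# DCCM
# --------------------------------------------------------------------------

def compute_dccm(
    traj: Trajectory, top: Topology, sel: Selection = CA
) -> CorrelationMatrix:
    """Normalized covariance of per-residue displacement vectors.

    The trajectory is assumed to be in a common frame (superposed).  Residues
    with zero positional variance get NaN rows/columns and a warning; a fully
    static trajectory is an error.
    """
    if traj.n_frames < 2:
        raise ValueError("DCCM needs at least 2 frames")
    idx = sel.resolve(top)
    X = traj.coordinates[:, idx, :]
    X = X - X.mean(axis=0, keepdims=True)
    n = X.shape[0]
    cov = np.einsum("tia,tja->ij", X, X) / n
    var = np.diag(cov).copy()
    if np.all(var <= 0):
        raise ValueError("degenerate trajectory: all residues have zero variance")
    zero = var <= 0
    if np.any(zero):
        labels = [
            f"{top.chain_id[idx[k]]}:{top.residue_number[idx[k]]}"
            for k in np.flatnonzero(zero)
        ]
        warnings.warn(
            "zero-variance residues excluded from correlation (NaN): "
            + ", ".join(labels),
            stacklevel=2,
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        denom = np.sqrt(np.outer(var, var))
        C = np.where(denom > 0, cov / np.where(denom > 0, denom, 1.0), np.nan)
    C[zero, :] = np.nan
    C[:, zero] = np.nan
    residues = tuple(
        (str(top.chain_id[k]), int(top.residue_number[k])) for k in idx
    )
    return CorrelationMatrix(residues=residues, C=C)


# --------------------------------------------------------------------------
# region aggregation
# --------------------------------------------------------------------------

def _region_indices(
    cm: CorrelationMatrix, scheme: RegionScheme, chain: str
) -> dict[str, np.ndarray]:
    res_arr = np.array([rn for _, rn in cm.residues])
    ch_arr = np.array([ch for ch, _ in cm.residues])
    out = {}
    for name in scheme.names:
        lo, hi = scheme.range(name)
        idx = np.flatnonzero((ch_arr == chain) & (res_arr >= lo) & (res_arr <= hi))
        if idx.size == 0:
            raise ValueError(
                f"region {name} has no resolvable residues on chain {chain}"
            )
        out[name] = idx
    return out


def _thresholded(C: np.ndarray, tau: float) -> np.ndarray:
    with np.errstate(invalid="ignore"):
        keep = np.abs(C) >= tau
    return np.where(keep & np.isfinite(C), C, 0.0)


def aggregate_region_scores(
    cm: CorrelationMatrix,
    scheme: RegionScheme,
    params: ScoreParams = ScoreParams(normalization="per_pair_mean"),
    chain_a: str = "A",
    chain_b: str = "A",
) -> pd.DataFrame:
    """14×14 region score map for one (monomer, monomer) block.

    S(A,B) = Σ_{i∈A, j∈B} C_ij over pairs with |C_ij| ≥ τ (inclusive);
    self-pairs (i = j) are excluded on the diagonal blocks.  In
    ``per_pair_mean`` mode the sum is divided by the number of residue pairs
    (the convention behind map-style displays).  NaN entries never count.
    """
    ra = _region_indices(cm, scheme, chain_a)
    rb = _region_indices(cm, scheme, chain_b)
    names = list(scheme.names)
    T = _thresholded(cm.C, params.threshold)
    out = np.zeros((len(names), len(names)))
    for i, na in enumerate(names):
        for j, nb in enumerate(names):
            ia, ib = ra[na], rb[nb]
            block = T[np.ix_(ia, ib)].copy()
            n_pairs = ia.size * ib.size
            if chain_a == chain_b and na == nb:
                np.fill_diagonal(block, 0.0)
                n_pairs -= ia.size
            s = block.sum()
            if params.normalization == "per_pair_mean":
                s = s / n_pairs if n_pairs else 0.0
            out[i, j] = s
    return pd.DataFrame(out, index=names, columns=names)


def h12_profile(
    cm: CorrelationMatrix,
    scheme: RegionScheme,
    params: ScoreParams = ScoreParams(normalization="raw_sum"),
    chain: str = "A",
) -> H12Profile:
    """Per-residue thresholded correlation sums of H12 against each region.

    Raw sums by construction (the activation metric reaches its reference
    value of 4 only unnormalized).
    """
    regions = _region_indices(cm, scheme, chain)
    h12 = regions["H12"]
    T = _thresholded(cm.C, params.threshold)
    targets = [n for n in scheme.names if n != "H12"]
    res_labels = [cm.residues[k][1] for k in h12]
    table = pd.DataFrame(
        {name: T[np.ix_(h12, regions[name])].sum(axis=1) for name in targets},
        index=res_labels,
    )
    return H12Profile(chain=chain, table=table)


def classify_activation(
    profiles: dict[str, H12Profile],
    params: ActivationParams = ActivationParams(),
) -> ActivationVerdict:
    """Tier each monomer by max(H12-H3, H12-H5) and flag drug efficacy.

    Values exactly at the activation threshold classify as *high* (and the
    drug as ineffective): the threshold is inclusive.
    """
    if not profiles:
        raise ValueError("no monomer profiles supplied")
    scores, tiers = {}, {}
    for chain, prof in profiles.items():
        for region in ("H3", "H5"):
            if region not in prof.table.columns:
                raise ValueError(f"profile for chain {chain} lacks {region} scores")
        s3, s5 = prof.score("H3"), prof.score("H5")
        m = max(s3, s5)
        if m >= params.activation_threshold:
            tier = "high"
        elif m >= params.intermediate_floor:
            tier = "intermediate"
        else:
            tier = "low"
        scores[chain] = {"H3": s3, "H5": s5}
        tiers[chain] = tier
    effective = all(
        max(s["H3"], s["H5"]) < params.activation_threshold
        for s in scores.values()
    )
    return ActivationVerdict(
        scores=scores, tiers=tiers, effective=effective, params=params
    )
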