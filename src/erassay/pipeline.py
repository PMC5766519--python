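"""Study-design enumeration and end-to-end assay orchestration.

The study design matrix crosses receptor isoforms (wild type plus the four
recurrent resistance variants L536Q, Y537S, Y537N, D538G) with two
agonist-state conditions (apo, estradiol-bound) and three antagonist-state
ligands (endoxifen, AZD-9496, fulvestrant): 5 × (2 + 3) = 25 systems at
500 ns each, 12.5 µs cumulative.  Production analysis windows drop the
equilibration phase: the default is the final 60 % of frames, the
length-relative form of analysing the last 300 ns of a 500 ns run.

``run_assay`` drives every stage per system and per monomer — windowing,
joint dimer superposition, DCCM, region score maps, H12 profile and
activation verdict, interaction signature panel, Daura clustering, helical
content and RMSF — and ``write_report`` emits deterministic CSV tables
(fixed column order, no timestamps), so identical configs reproduce
byte-identical reports.
"""

from __future__ import annotations

import dataclasses
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .conformation import ClusterParams, daura_cluster, rmsf
from .core import (
    CA,
    Selection,
    Topology,
    Trajectory,
    default_region_scheme,
    load_topology,
    load_trajectory,
    split_monomers,
)
from .correlation import (
    ActivationParams,
    ActivationVerdict,
    ScoreParams,
    aggregate_region_scores,
    classify_activation,
    compute_dccm,
    h12_profile,
    superpose_to_mean,
)
from .interactions import HBondParams, signature_panel
from .synthetic import (
    Conformer,
    CorrelationPlant,
    HBondPlant,
    HelicityPlant,
    SyntheticSpec,
    generate_trajectory,
)

__all__ = [
    "SystemDescriptor",
    "SystemDesign",
    "AssayParams",
    "SystemResult",
    "AssayReport",
    "ConfigError",
    "enumerate_design",
    "apply_window",
    "run_assay",
    "write_report",
]


class ConfigError(ValueError):
    """Configuration file violates the expected schema."""


# --------------------------------------------------------------------------
# study design
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class SystemDescriptor:
    isoform: str
    state: str   # "agonist" or "antagonist"
    ligand: str
    length_ns: float

    @property
    def name(self) -> str:
        return f"{self.isoform}_{self.ligand}"


@dataclass(frozen=True)
class SystemDesign:
    isoforms: tuple[str, ...] = ("WT", "L536Q", "Y537S", "Y537N", "D538G")
    agonist_ligands: tuple[str, ...] = ("apo", "EST")
    antagonist_ligands: tuple[str, ...] = ("END", "AZD-9496", "FULV")
    length_ns: float = 500.0


def enumerate_design(
    design: SystemDesign = SystemDesign(),
) -> tuple[list[SystemDescriptor], float]:
    """Deterministic system enumeration (isoform-major, agonist state first)
    plus the cumulative simulated time in ns."""
    if not design.isoforms:
        raise ValueError("design needs at least one isoform")
    out: list[SystemDescriptor] = []
    seen = set()
    for iso in design.isoforms:
        for state, ligands in (
            ("agonist", design.agonist_ligands),
            ("antagonist", design.antagonist_ligands),
        ):
            for lig in ligands:
                desc = SystemDescriptor(iso, state, lig, design.length_ns)
                if (iso, lig) in seen:
                    raise ValueError(f"duplicate system descriptor {iso}/{lig}")
                seen.add((iso, lig))
                out.append(desc)
    return out, len(out) * design.length_ns


# --------------------------------------------------------------------------
# windowing
# --------------------------------------------------------------------------

def apply_window(traj: Trajectory, mode: str, value: float) -> Trajectory:
    """Production-window view of a trajectory.

    mode "fraction": keep the last ``value`` fraction of frames.
    mode "absolute": keep frames with time ≥ ``value`` ns.
    """
    if mode == "fraction":
        if not 0 < value <= 1:
            raise ValueError("fraction must be in (0, 1]")
        keep = int(round(value * traj.n_frames))
        if keep < 1:
            raise ValueError("window retains no frames")
        return traj.frame_subset(slice(traj.n_frames - keep, None))
    if mode == "absolute":
        mask = traj.frame_times >= value
        if not mask.any():
            raise ValueError(
                f"window start {value} ns is beyond the trajectory span "
                f"[{traj.frame_times[0]}, {traj.frame_times[-1]}] ns"
            )
        start = int(np.argmax(mask))
        return traj.frame_subset(slice(start, None))
    raise ValueError("window mode must be 'fraction' or 'absolute'")


# --------------------------------------------------------------------------
# configuration
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class AssayParams:
    """All numeric analysis parameters, echoed verbatim into the report."""

    threshold: float = 0.6
    map_normalization: str = "per_pair_mean"
    activation_threshold: float = 4.0
    intermediate_floor: float = 2.0
    hbond_d_max: float = 3.3
    hbond_theta_max: float = 35.0
    cluster_cutoff: float = 2.75
    window_mode: str = "fraction"
    window_value: float = 0.6
    helix_segment: tuple[int, int] = (527, 552)  # H11/H12 edge incl. L11-12


def _build_synthetic_spec(d: dict) -> SyntheticSpec:
    def tup(x):
        return tuple(x) if isinstance(x, (list, tuple)) else x

    corr = tuple(
        CorrelationPlant(
            region_a=tup(c["region_a"]), region_b=tup(c["region_b"]),
            rho=float(c["rho"]),
            chain_a=c.get("chain_a", "A"), chain_b=c.get("chain_b", "A"),
        )
        for c in d.get("correlations", [])
    )
    hb = tuple(
        HBondPlant(
            label=h["label"], donor=tuple(h["donor"]),
            hydrogen=tuple(h["hydrogen"]), acceptor=tuple(h["acceptor"]),
            occupancy=float(h["occupancy"]),
        )
        for h in d.get("hbond_plants", [])
    )
    hel = tuple(
        HelicityPlant(label=p["label"], chain=p["chain"], first=int(p["first"]),
                      last=int(p["last"]), fraction=float(p["fraction"]))
        for p in d.get("helicity_plants", [])
    )
    confs = tuple(
        Conformer(
            label=c["label"], weight=float(c["weight"]),
            shifts=tuple(
                (s[0], int(s[1]), int(s[2]), tuple(float(v) for v in s[3]))
                for s in c.get("shifts", [])
            ),
        )
        for c in d.get("conformers", [])
    ) or (Conformer("ref", 1.0),)
    return SyntheticSpec(
        seed=int(d["seed"]), n_frames=int(d.get("n_frames", 5000)),
        dt_ns=float(d.get("dt_ns", 0.1)), sigma=float(d.get("sigma", 1.0)),
        variant=d.get("variant", "WT"), correlations=corr, hbond_plants=hb,
        conformers=confs, helicity_plants=hel,
    )


def _validate_config(cfg: dict) -> None:
    if not isinstance(cfg, dict):
        raise ConfigError("config root must be a mapping")
    systems = cfg.get("systems")
    if not isinstance(systems, list) or not systems:
        raise ConfigError("config must list at least one system under 'systems'")
    for i, sys_cfg in enumerate(systems):
        if not isinstance(sys_cfg, dict) or "name" not in sys_cfg:
            raise ConfigError(f"system #{i} must be a mapping with a 'name'")
        has_syn = "synthetic" in sys_cfg
        has_files = "topology" in sys_cfg and "trajectory" in sys_cfg
        if not (has_syn or has_files):
            raise ConfigError(
                f"system {sys_cfg.get('name')!r} needs either 'synthetic' or "
                "'topology'+'trajectory'"
            )
        if has_syn and "seed" not in sys_cfg["synthetic"]:
            raise ConfigError(
                f"system {sys_cfg['name']!r}: synthetic spec needs a 'seed'"
            )
        if has_files and "dt_ns" not in sys_cfg:
            raise ConfigError(
                f"system {sys_cfg['name']!r}: file-based input needs 'dt_ns'"
            )
    params = cfg.get("params", {})
    if not isinstance(params, dict):
        raise ConfigError("'params' must be a mapping")
    known = {f.name for f in dataclasses.fields(AssayParams)}
    unknown = set(params) - known
    if unknown:
        raise ConfigError(f"unknown params: {sorted(unknown)}; known: {sorted(known)}")


# --------------------------------------------------------------------------
# results
# --------------------------------------------------------------------------

@dataclass
class SystemResult:
    name: str
    isoform: str
    ligand: str
    status: str  # "ok" or an error marker
    verdict: ActivationVerdict | None = None
    region_scores: dict = field(default_factory=dict)  # (cA, cB) -> DataFrame
    h12_tables: dict = field(default_factory=dict)     # chain -> DataFrame
    panel: pd.DataFrame | None = None
    cluster_populations: dict = field(default_factory=dict)  # chain -> tuple
    helix_content: dict = field(default_factory=dict)        # chain -> float
    rmsf_profiles: dict = field(default_factory=dict)        # chain -> Series


@dataclass
class AssayReport:
    params: AssayParams
    systems: list[SystemResult]

    def summary(self) -> pd.DataFrame:
        rows = []
        for res in self.systems:
            if res.status != "ok":
                rows.append(
                    dict(system=res.name, isoform=res.isoform, ligand=res.ligand,
                         chain="", status=res.status, H12_H3_score=np.nan,
                         H12_H5_score=np.nan, tier="", drug_effective="",
                         top_cluster_pct=np.nan, helix_content_pct=np.nan)
                )
                continue
            for chain in res.verdict.scores:
                rows.append(
                    dict(
                        system=res.name, isoform=res.isoform, ligand=res.ligand,
                        chain=chain, status="ok",
                        H12_H3_score=round(res.verdict.scores[chain]["H3"], 6),
                        H12_H5_score=round(res.verdict.scores[chain]["H5"], 6),
                        tier=res.verdict.tiers[chain],
                        drug_effective=res.verdict.effective,
                        top_cluster_pct=round(res.cluster_populations[chain][0], 6),
                        helix_content_pct=round(res.helix_content[chain], 6),
                    )
                )
        return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# orchestration
# --------------------------------------------------------------------------

def _load_system(sys_cfg: dict) -> tuple[Topology, Trajectory]:
    if "synthetic" in sys_cfg:
        spec = _build_synthetic_spec(sys_cfg["synthetic"])
        top, traj, _ = generate_trajectory(spec)
        return top, traj
    top, _ = load_topology(sys_cfg["topology"])
    traj = load_trajectory(sys_cfg["trajectory"], top, float(sys_cfg["dt_ns"]))
    return top, traj


def _analyse_system(
    top: Topology, traj: Trajectory, params: AssayParams,
    isoform: str, ligand: str,
) -> dict:
    scheme = default_region_scheme()
    windowed = apply_window(traj, params.window_mode, params.window_value)
    aligned, _ = superpose_to_mean(windowed, top, CA)
    cm = compute_dccm(aligned, top, CA)
    chains = top.chains
    score_params = ScoreParams(params.threshold, params.map_normalization)
    profile_params = ScoreParams(params.threshold, "raw_sum")
    region_scores = {
        (ca, cb): aggregate_region_scores(cm, scheme, score_params, ca, cb)
        for ca in chains for cb in chains
    }
    profiles = {c: h12_profile(cm, scheme, profile_params, c) for c in chains}
    verdict = classify_activation(
        profiles,
        ActivationParams(params.activation_threshold, params.intermediate_floor),
    )
    hb = HBondParams(params.hbond_d_max, params.hbond_theta_max)
    panel = signature_panel(top, windowed, isoform=isoform, ligand=ligand,
                            params=hb)
    cluster_pops, helix, rmsf_profiles = {}, {}, {}
    monomers = split_monomers(top, windowed)
    has_backbone = "N" in set(top.atom_name) and "O" in set(top.atom_name)
    for chain, (mtop, mtraj) in monomers.items():
        aligned_m, _ = superpose_to_mean(mtraj, mtop, CA)
        result = daura_cluster(
            mtraj, mtop, ClusterParams(rmsd_cutoff=params.cluster_cutoff)
        )
        cluster_pops[chain] = result.populations
        rmsf_profiles[chain] = rmsf(aligned_m, mtop, CA)
        if has_backbone:
            from .conformation import assign_helix

            ha = assign_helix(mtraj, mtop)
            lo, hi = params.helix_segment
            helix[chain] = ha.segment_content(chain, lo, hi)
        else:
            helix[chain] = np.nan
    return dict(
        verdict=verdict, region_scores=region_scores,
        h12_tables={c: p.table for c, p in profiles.items()},
        panel=panel, cluster_populations=cluster_pops, helix_content=helix,
        rmsf_profiles=rmsf_profiles,
    )


def run_assay(config: dict | str | os.PathLike) -> AssayReport:
    """Run the full assay for every system in the configuration.

    Config schema violations abort before any work; per-system failures are
    recorded in that system's status and the run continues.
    """
    if not isinstance(config, dict):
        with open(config) as fh:
            config = yaml.safe_load(fh)
    _validate_config(config)
    params = AssayParams(**{
        k: (tuple(v) if isinstance(v, list) else v)
        for k, v in config.get("params", {}).items()
    })
    systems: list[SystemResult] = []
    for sys_cfg in config["systems"]:
        name = sys_cfg["name"]
        isoform = sys_cfg.get("isoform", "WT")
        ligand = sys_cfg.get("ligand", "apo")
        try:
            top, traj = _load_system(sys_cfg)
        except FileNotFoundError as exc:
            systems.append(SystemResult(name, isoform, ligand,
                                        status=f"missing input: {exc}"))
            continue
        except Exception as exc:
            systems.append(SystemResult(name, isoform, ligand,
                                        status=f"load failed: {exc}"))
            continue
        try:
            parts = _analyse_system(top, traj, params, isoform, ligand)
        except Exception as exc:
            systems.append(SystemResult(name, isoform, ligand,
                                        status=f"analysis failed: {exc}"))
            continue
        systems.append(SystemResult(name, isoform, ligand, status="ok", **parts))
    return AssayReport(params=params, systems=systems)


def write_report(report: AssayReport, outdir: str | os.PathLike) -> dict[str, str]:
    """Write summary + per-system CSV tables with stable column order.

    The run log echoes every numeric parameter and the package version (no
    timestamps), so reruns with identical inputs are byte-identical.
    """
    outdir = str(outdir)
    os.makedirs(outdir, exist_ok=True)
    paths: dict[str, str] = {}
    summary = report.summary()
    paths["summary"] = os.path.join(outdir, "summary.csv")
    summary.to_csv(paths["summary"], index=False)
    log_lines = [f"erassay {__version__}", "parameters:"]
    for f in dataclasses.fields(AssayParams):
        log_lines.append(f"  {f.name} = {getattr(report.params, f.name)}")
    paths["run_log"] = os.path.join(outdir, "run_log.txt")
    with open(paths["run_log"], "w") as fh:
        fh.write("\n".join(log_lines) + "\n")
    for res in report.systems:
        sdir = os.path.join(outdir, res.name)
        os.makedirs(sdir, exist_ok=True)
        if res.status != "ok":
            with open(os.path.join(sdir, "STATUS.txt"), "w") as fh:
                fh.write(res.status + "\n")
            continue
        res.verdict.to_dataframe().to_csv(
            os.path.join(sdir, "verdict.csv"), index=False
        )
        for (ca, cb), df in res.region_scores.items():
            df.to_csv(os.path.join(sdir, f"region_scores_{ca}{cb}.csv"))
        for chain, df in res.h12_tables.items():
            df.to_csv(os.path.join(sdir, f"h12_profile_{chain}.csv"))
        res.panel.to_csv(os.path.join(sdir, "signature_panel.csv"), index=False)
        pops = pd.DataFrame(
            [
                dict(chain=c, cluster=k, population_pct=p)
                for c, pop in res.cluster_populations.items()
                for k, p in enumerate(pop)
            ]
        )
        pops.to_csv(os.path.join(sdir, "cluster_populations.csv"), index=False)
        for chain, series in res.rmsf_profiles.items():
            series.to_csv(os.path.join(sdir, f"rmsf_{chain}.csv"))
    return paths
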