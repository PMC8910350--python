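"""Config-driven orchestration of the full ectodomain analysis.

``run_analysis`` executes the enabled stages — per-frame metrics (RMSD, Rg,
H-bonds, SASA), interdomain hinge angles, pooled essential-dynamics PCA
with reference-structure projection, and linker dihedral clustering — over
one or more trajectories, and writes every result as a machine-readable
TSV plus a JSON metadata block that records the seed, versions and the
analysis conventions in effect, so each report is self-describing and
reproducible.

Summary rows follow the conventional table schema for ensemble properties:
mean +/- sd of Ca-RMSD (Angstrom), Rg (nm), intramolecular H-bond count and
SASA (nm^2) per trajectory, with single-row entries (no sd) for reference
crystal structures.
"""

from __future__ import annotations

import json
import platform
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

import ectodyn
from ectodyn.clustering import circular_features, cluster_report, select_k
from ectodyn.io import (
    DomainMap,
    Structure,
    Trajectory,
    read_pdb,
    read_trajectory,
    select_atoms,
    write_pdb,
)
from ectodyn.metrics import (
    backbone_dihedrals,
    hinge_series,
    radius_of_gyration,
    rmsd_series,
)
from ectodyn.pca import EssentialDynamics
from ectodyn.surface import HBondCriteria, count_hbonds, sasa

__all__ = ["AnalysisConfig", "ReportBundle", "run_analysis", "summarize_table"]

_BACKBONE = ("N", "CA", "C")


@dataclass
class AnalysisConfig:
    """Declarative description of one analysis run."""

    trajectories: list[dict[str, str]]  # each {"path": ..., "label": ...}
    domain_map: DomainMap
    out_dir: str = "ectodyn-report"
    reference: str | None = None  # PDB path of the reference crystal
    reference_chains: list[str] | None = None
    stride: int = 1
    seed: int = 0
    time_stride_ps: float = 60.0
    pca_components: int = 4
    cluster_k_min: int = 2
    cluster_k_max: int = 10
    sasa_probe_radius: float = 1.4
    sasa_n_points: int = 960
    hbond_max_distance: float = 3.5
    property_stride: int = 50  # frames between SASA / H-bond evaluations
    hinge_plane: str | None = None  # e.g. "xy" for membrane-plane projection
    run_metrics: bool = True
    run_hinge: bool = True
    run_pca: bool = True
    run_clustering: bool = True
    min_cluster_fraction: float = 0.05

    def __post_init__(self) -> None:
        if self.stride < 1:
            raise ValueError("stride must be >= 1")
        if self.cluster_k_min < 2 or self.cluster_k_max < self.cluster_k_min:
            raise ValueError("invalid cluster k range")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        raw = yaml.safe_load(Path(path).read_text())
        raw["domain_map"] = DomainMap.from_dict(raw["domain_map"])
        return cls(**raw)

    def to_metadata(self) -> dict[str, Any]:
        d = asdict(self)
        d["domain_map"] = self.domain_map.to_dict()
        return d

    def validate_paths(self) -> None:
        missing = [t["path"] for t in self.trajectories
                   if not Path(t["path"]).exists()]
        if self.reference and not Path(self.reference).exists():
            missing.append(self.reference)
        if missing:
            raise FileNotFoundError(f"input paths do not exist: {missing}")


@dataclass
class ReportBundle:
    """All artifacts of one run (also written under ``out_dir``)."""

    summary: pd.DataFrame
    hinge: dict[str, pd.DataFrame] = field(default_factory=dict)
    projections: pd.DataFrame | None = None
    reference_projections: pd.DataFrame | None = None
    cluster_table: pd.DataFrame | None = None
    silhouette_table: pd.DataFrame | None = None
    medoid_paths: list[Path] = field(default_factory=list)
    metadata: dict[str, Any] = field(default_factory=dict)
    errors: dict[str, str] = field(default_factory=dict)
    out_dir: Path = Path(".")


def _plane_axes(name: str | None) -> tuple[int, int] | None:
    if name is None:
        return None
    axes = {"x": 0, "y": 1, "z": 2}
    name = name.lower()
    if len(name) != 2 or any(c not in axes for c in name):
        raise ValueError(f"invalid plane {name!r}; use e.g. 'xy'")
    return axes[name[0]], axes[name[1]]


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def run_analysis(config: AnalysisConfig) -> ReportBundle:
    """Execute all enabled stages; optional-stage failures are recorded,
    not fatal.  Outputs are deterministic for a fixed config and seed."""
    config.validate_paths()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    bundle = ReportBundle(summary=pd.DataFrame(), out_dir=out)

    trajs: list[Trajectory] = []
    for spec in config.trajectories:
        t = read_trajectory(spec["path"], time_stride=config.time_stride_ps,
                            label=spec.get("label", Path(spec["path"]).stem))
        if config.stride > 1:
            t = Trajectory(topology=t.topology,
                           frames=t.frames[::config.stride],
                           time_stride=t.time_stride * config.stride,
                           label=t.label)
        trajs.append(t)
    config.domain_map.validate_against(trajs[0].topology)

    reference = None
    if config.reference:
        reference = read_pdb(config.reference,
                             chain_filter=config.reference_chains)

    # ---- stage: per-frame metrics + summary table -----------------------
    per_traj: dict[str, pd.DataFrame] = {}
    if config.run_metrics:
        try:
            for t in trajs:
                per_traj[t.label] = _metric_table(t, reference, config)
                _write_tsv(per_traj[t.label], out / f"metrics_{t.label}.tsv")
        except Exception as exc:
            bundle.errors["metrics"] = str(exc)
    ref_rows = _reference_rows(reference, config) if reference is not None else None
    bundle.summary = summarize_table(per_traj, ref_rows)
    _write_tsv(bundle.summary, out / "summary.tsv")

    # ---- stage: hinge angles --------------------------------------------
    if config.run_hinge:
        try:
            plane = _plane_axes(config.hinge_plane)
            for t in trajs:
                for pair in (("D1", "D3"), ("D2", "D3")):
                    hs = hinge_series(t, config.domain_map, *pair, plane=plane)
                    df = hs.to_frame()
                    key = f"{t.label}_{pair[0]}-{pair[1]}"
                    bundle.hinge[key] = df
                    _write_tsv(df, out / f"hinge_{key}.tsv")
        except Exception as exc:
            bundle.errors["hinge"] = str(exc)

    # ---- stage: essential dynamics --------------------------------------
    if config.run_pca:
        try:
            sel = select_atoms(trajs[0], atom_names=_BACKBONE)
            model = EssentialDynamics(selection=sel,
                                      n_components=config.pca_components)
            model.fit(trajs)
            rows = []
            for t in trajs:
                proj = model.transform(t)
                for f in range(proj.shape[0]):
                    rows.append([t.label, f] + proj[f].tolist())
            cols = ["trajectory", "frame"] + [
                f"PC{i + 1}" for i in range(config.pca_components)]
            bundle.projections = pd.DataFrame(rows, columns=cols)
            _write_tsv(bundle.projections, out / "pc_projections.tsv")
            var_df = pd.DataFrame({
                "component": np.arange(1, config.pca_components + 1),
                "eigenvalue_A2": model.eigenvalues_[:config.pca_components],
                "variance_fraction": [model.variance_fraction(i + 1) -
                                      (model.variance_fraction(i) if i else 0.0)
                                      for i in range(config.pca_components)],
            })
            _write_tsv(var_df, out / "pc_variance.tsv")
            if reference is not None:
                try:
                    rproj = model.transform(reference)
                    bundle.reference_projections = pd.DataFrame(
                        [[reference.identifier] + rproj[0].tolist()],
                        columns=["structure"] + [f"PC{i + 1}" for i in
                                                 range(config.pca_components)])
                    _write_tsv(bundle.reference_projections,
                               out / "reference_projections.tsv")
                except Exception as exc:
                    bundle.errors["pca_reference"] = str(exc)
        except Exception as exc:
            bundle.errors["pca"] = str(exc)

    # ---- stage: linker clustering ----------------------------------------
    if config.run_clustering:
        try:
            tables = []
            for t in trajs:
                d = backbone_dihedrals(t, config.domain_map["linker"])
                d["frame"] = d["frame"] + sum(
                    tr.n_frames for tr in trajs[:trajs.index(t)])
                tables.append(d)
            dihedrals = pd.concat(tables, ignore_index=True)
            _write_tsv(dihedrals, out / "linker_dihedrals.tsv")
            feats = circular_features(dihedrals)
            result = select_k(feats,
                              range(config.cluster_k_min, config.cluster_k_max + 1),
                              random_state=config.seed)
            bundle.silhouette_table = result.table
            _write_tsv(result.table, out / "silhouette_vs_k.tsv")
            table, _ = cluster_report(result.model, feats,
                                      min_fraction=config.min_cluster_fraction)
            bundle.cluster_table = table
            _write_tsv(table, out / "cluster_populations.tsv")
            # medoid structure export (frame ids are pooled indices)
            offsets = np.cumsum([0] + [t.n_frames for t in trajs])
            for rank, mf in enumerate(table["medoid_frame"], start=1):
                ti = int(np.searchsorted(offsets, int(mf), side="right") - 1)
                local = int(mf) - int(offsets[ti])
                s = trajs[ti].frame(local)
                p = out / f"medoid_cluster{rank}.pdb"
                write_pdb(s, p)
                bundle.medoid_paths.append(p)
        except Exception as exc:
            bundle.errors["clustering"] = str(exc)

    bundle.metadata = {
        "package": "ectodyn",
        "version": ectodyn.__version__,
        "python": platform.python_version(),
        "seed": config.seed,
        "config": config.to_metadata(),
        "conventions": {
            "hinge_vertex": "linker center of mass",
            "hinge_plane": config.hinge_plane or "none (3D angle)",
            "superposition": "unweighted Kabsch on Ca atoms",
            "rg_sasa_units": "nm / nm^2 in summary table; Angstrom internally",
            "hbond_mode": "heavy-atom-only (distance criterion)",
            "dihedral_scaling": "none (sin/cos features)",
            "sd": "sample standard deviation (n-1)",
        },
        "stage_errors": bundle.errors,
    }
    (out / "metadata.json").write_text(json.dumps(bundle.metadata, indent=2))
    return bundle


def _metric_table(traj: Trajectory, reference: Structure | None,
                  config: AnalysisConfig) -> pd.DataFrame:
    ref = reference if reference is not None else traj.frame(0)
    rmsd = rmsd_series(traj, ref)
    rg = np.array([
        radius_of_gyration(traj.frames[f], traj.topology.mass)
        for f in range(traj.n_frames)
    ])
    hb = np.full(traj.n_frames, np.nan)
    sa = np.full(traj.n_frames, np.nan)
    crit = HBondCriteria(donor_acceptor_max=config.hbond_max_distance,
                         mode="heavy-atom-only")
    for f in range(0, traj.n_frames, config.property_stride):
        frame = traj.frame(f)
        hb[f] = count_hbonds(frame, crit)[0]
        sa[f] = sasa(frame, probe_radius=config.sasa_probe_radius,
                     n_sphere_points=config.sasa_n_points).total
    return pd.DataFrame({
        "time_ps": traj.times,
        "rmsd_A": rmsd,
        "rg_nm": rg / 10.0,
        "hb_intra": hb,
        "sasa_nm2": sa / 100.0,
    })


def _reference_rows(reference: Structure,
                    config: AnalysisConfig) -> dict[str, dict[str, float]]:
    rg = radius_of_gyration(reference.coords, reference.mass) / 10.0
    hb = count_hbonds(reference, HBondCriteria(
        donor_acceptor_max=config.hbond_max_distance, mode="heavy-atom-only"))[0]
    sa = sasa(reference, probe_radius=config.sasa_probe_radius,
              n_sphere_points=config.sasa_n_points).total_nm2
    return {reference.identifier: {
        "rg_nm": rg, "hb_intra": float(hb), "sasa_nm2": sa}}


def summarize_table(per_traj: Mapping[str, pd.DataFrame],
                    references: Mapping[str, Mapping[str, float]] | None = None
                    ) -> pd.DataFrame:
    """Mean +/- sd summary per trajectory (the ensemble-properties schema).

    sd is the sample standard deviation (n-1).  Reference-structure rows
    are single observations: their sd fields are left empty (NaN).
    """
    rows = []
    if references:
        for name, vals in references.items():
            rows.append({
                "system": name,
                "rmsd_mean_A": np.nan, "rmsd_sd_A": np.nan,
                "rg_mean_nm": vals.get("rg_nm", np.nan), "rg_sd_nm": np.nan,
                "hb_mean": vals.get("hb_intra", np.nan), "hb_sd": np.nan,
                "sasa_mean_nm2": vals.get("sasa_nm2", np.nan),
                "sasa_sd_nm2": np.nan,
            })
    for label, df in per_traj.items():
        def ms(col):
            v = df[col].dropna()
            if v.empty:
                return np.nan, np.nan
            sd = float(v.std(ddof=1)) if len(v) > 1 else 0.0
            return float(v.mean()), sd
        rmsd_m, rmsd_s = ms("rmsd_A")
        rg_m, rg_s = ms("rg_nm")
        hb_m, hb_s = ms("hb_intra")
        sa_m, sa_s = ms("sasa_nm2")
        rows.append({
            "system": label,
            "rmsd_mean_A": rmsd_m, "rmsd_sd_A": rmsd_s,
            "rg_mean_nm": rg_m, "rg_sd_nm": rg_s,
            "hb_mean": hb_m, "hb_sd": hb_s,
            "sasa_mean_nm2": sa_m, "sasa_sd_nm2": sa_s,
        })
    return pd.DataFrame(rows)
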