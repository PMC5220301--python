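"""Config-driven end-to-end run: pose ensemble -> clustering -> viability
filters -> interface characterization -> alanine scan (-> thermodynamics
when a mean-force profile is supplied)."""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import yaml
from pydantic import BaseModel, ConfigDict

from . import __version__
from .alascan import scan_interface
from .interface import characterize
from .posefilter import (
    PoseEnsemble,
    apply_filters,
    audit_rows,
    cluster_poses,
    pairwise_pose_rmsd,
)
from .sasa import delta_sasa
from .structure import DimerModel, read_structure
from .thermo import MeanForceProfile, integrate_mean_force, kd_from_pmf

logger = logging.getLogger("dimerscope")


class RunConfig(BaseModel):
    """All pipeline thresholds; defaults follow the conventional values
    (probe 0.14 nm; HB 0.3 nm / 20 deg; HC 0.38 nm; 5% enrichment; score
    2.0; exposure 0.25; 300 K; reference beyond 4.6 nm). Unknown keys are
    rejected."""

    model_config = ConfigDict(extra="forbid")

    poses: str                       # multi-model PDB, chains A and B per model
    output_dir: str = "run"
    hotspots_file: str | None = None
    reactive_file: str | None = None
    ss_file: str | None = None       # lines: chain resid label
    mean_force_file: str | None = None
    seed: int = 0

    probe_radius_nm: float = 0.14
    n_sphere_points: int = 240
    hb_distance_nm: float = 0.30
    hb_angle_deg: float = 20.0
    hc_distance_nm: float = 0.38
    cluster_radius_nm: float = 0.40
    min_enrichment: float = 0.05
    score_cutoff: float = 2.0
    exposure_cutoff: float = 0.25
    effector_range: tuple[int, int] = (25, 40)
    anchor_residue: int | None = None
    promote_minor: list[int] = []
    temperature_k: float = 300.0
    reference_distance_nm: float = 4.6

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls(**yaml.safe_load(Path(path).read_text()))

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.model_dump(), sort_keys=True))

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(self.model_dump(), sort_keys=True, default=str)
            .encode()).hexdigest()[:16]


def _read_residue_list(path: str | Path) -> list[int]:
    return [int(line.split()[0])
            for line in Path(path).read_text().splitlines()
            if line.strip() and not line.startswith("#")]


def _read_ss_file(path: str | Path) -> dict[tuple[str, int], str]:
    out = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        chain, resid, label = line.split()[:3]
        out[(chain, int(resid))] = label
    return out


def load_pose_ensemble(path: str | Path) -> PoseEnsemble:
    """Load poses from a multi-model PDB (chains A and B per MODEL)."""
    st = read_structure(path, frame_policy="all")
    poses = []
    for k in range(st.n_frames):
        st.set_frame(k)
        poses.append(DimerModel(st.copy(), ["A"], ["B"],
                                provenance=f"model{k + 1}"))
    return PoseEnsemble(poses=poses)


def _write_tsv(rows: list[dict], path: Path) -> None:
    if not rows:
        path.write_text("")
        return
    cols = list(rows[0].keys())
    for r in rows[1:]:
        for c in r:
            if c not in cols:
                cols.append(c)
    lines = ["\t".join(cols)]
    lines += ["\t".join(str(r.get(c, "")) for c in cols) for r in rows]
    path.write_text("\n".join(lines) + "\n")


def run_pipeline(config: RunConfig) -> dict:
    """Run the full pipeline; writes audit TSVs, JSON reports and a log to
    the output directory and returns a summary dict. Deterministic for a
    given config."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    summary: dict = {"config_digest": config.digest(),
                     "version": __version__, "seed": config.seed}
    config.to_yaml(out / "config.yaml")
    sasa_kwargs = dict(probe_radius=config.probe_radius_nm,
                       n_sphere_points=config.n_sphere_points)
    try:
        stage = "load"
        ensemble = load_pose_ensemble(config.poses)
        logger.info("loaded %d poses", len(ensemble))
        ss = _read_ss_file(config.ss_file) if config.ss_file else {}
        for pose in ensemble.poses:
            for r in pose.structure.residues():
                if (r.chain_id, r.index) in ss:
                    r.secondary_structure = ss[(r.chain_id, r.index)]
        hotspots = _read_residue_list(config.hotspots_file) \
            if config.hotspots_file else []
        reactive = _read_residue_list(config.reactive_file) \
            if config.reactive_file else []

        stage = "cluster"
        matrix = pairwise_pose_rmsd(ensemble)
        clusters = cluster_poses(matrix, config.cluster_radius_nm,
                                 config.min_enrichment)
        summary["n_clusters"] = len(clusters.clusters)
        summary["n_major_clusters"] = sum(
            1 for c in clusters.clusters if not c.minor)

        stage = "filter"
        survivors, audit = apply_filters(
            clusters, ensemble, hotspots, reactive,
            effector_range=tuple(config.effector_range),
            anchor_residue=config.anchor_residue,
            exposure_cut=config.exposure_cutoff,
            promote_minor=config.promote_minor, **sasa_kwargs)
        _write_tsv(audit_rows(audit), out / "filter_audit.tsv")
        summary["survivors"] = survivors
        summary["n_survivors"] = len(survivors)

        stage = "characterize"
        reports = {}
        for idx in survivors:
            pose = ensemble.poses[idx]
            rep = characterize(pose, probe_radius=config.probe_radius_nm,
                               n_sphere_points=config.n_sphere_points,
                               hb_d_cut=config.hb_distance_nm,
                               hb_angle_cut=config.hb_angle_deg,
                               hc_d_cut=config.hc_distance_nm)
            reports[idx] = {
                "hb_count": rep.hb_count, "hc_count": rep.hc_count,
                "d_com_nm": rep.d_com, "delta_sasa_nm2": rep.delta_sasa,
                "quasi_symmetry": rep.quasi_symmetry,
                "salt_bridges": [list(map(str, sb)) for sb in rep.salt_bridges],
                "pi_stacks": [list(map(str, ps)) for ps in rep.pi_stacks],
                "interfacial_residues_a": rep.interfacial_residues_a,
                "interfacial_residues_b": rep.interfacial_residues_b,
            }
        (out / "interface_reports.json").write_text(
            json.dumps(reports, indent=1, default=str))
        summary["interface_reports"] = reports

        stage = "alascan"
        scans = {}
        for idx in survivors:
            pose = ensemble.poses[idx]
            dsr = delta_sasa(pose, **sasa_kwargs)
            targets = [("A", i) for i in dsr.interfacial_residues_a] + \
                      [("B", i) for i in dsr.interfacial_residues_b]
            rows = [{"chain": s.chain_id, "resid": s.residue_index,
                     "name": s.residue_name, "dde_kcal": round(s.dde, 4),
                     "dde_coulomb": round(s.dde_coulomb, 4),
                     "dde_lj": round(s.dde_lj, 4), "rank": s.rank,
                     "skipped": s.skipped or ""}
                    for s in scan_interface(pose, targets)]
            _write_tsv(rows, out / f"alascan_pose{idx}.tsv")
            scans[idx] = rows
        summary["alascan"] = {k: v[:5] for k, v in scans.items()}

        if config.mean_force_file:
            stage = "thermodynamics"
            profile = MeanForceProfile.from_tsv(config.mean_force_file)
            pmf = integrate_mean_force(
                profile, reference=(config.reference_distance_nm, np.inf))
            pmf.to_tsv(out / "pmf.tsv")
            est = kd_from_pmf(pmf, temperature=config.temperature_k)
            binding = {"kd_molar": est.kd, "dg_bind_kcal_mol": est.dg_bind,
                       "temperature_k": est.temperature,
                       "bound_window_nm": list(est.bound_window),
                       "minima": est.minima}
            (out / "binding.json").write_text(json.dumps(binding, indent=1))
            summary["binding"] = binding
    except Exception as exc:
        logger.error("stage %s failed: %s", stage, exc)
        (out / "summary.json").write_text(
            json.dumps({"error": str(exc), "stage": stage}, indent=1))
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
    finally:
        logger.removeHandler(handler)
        handler.close()
    (out / "summary.json").write_text(json.dumps(summary, indent=1, default=str))
    return summary
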