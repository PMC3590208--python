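"""End-to-end orchestration: dock -> cluster -> filter -> rerank -> evaluate.

Every stage's output is persisted as plain text (pose TSV, YAML report),
the effective configuration is echoed into the report, and independent
per-rotation scorings / per-pose filter evaluations run through a work
queue whose results merge in input order, so single-worker and
multi-worker runs produce identical outputs.
"""

from __future__ import annotations

import json
import time
from concurrent.futures import ThreadPoolExecutor
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import cluster as cluster_mod
from . import evalmetrics, fftscore, gbrerank, molio
from .cdr import detect_complex_type
from .fftscore import DockParams, Pose, params_for_type
from .filters import FilterConfig, FilterContext, apply_filters
from .molio import Molecule, SkinParams, build_skin_core, detect_surface_atoms
from .params import load_params
from .rotsamp import Rotation, sample_rotations


class TaskQueue:
    """Balanced work queue with a deterministic-merge contract.

    Workers pull one task at a time; results are merged in task order
    regardless of completion order, so the output is independent of the
    worker count.
    """

    def __init__(self, n_workers: int = 1):
        self.n_workers = max(int(n_workers), 1)

    def run(self, fn, items):
        items = list(items)
        if self.n_workers == 1 or len(items) <= 1:
            return [fn(x) for x in items]
        with ThreadPoolExecutor(max_workers=self.n_workers) as ex:
            return list(ex.map(fn, items))


@dataclass
class RunConfig:
    """Configuration of a full docking run."""

    receptor: str = ""
    ligand: str = ""
    native_ligand: str = ""          # optional, enables evaluation
    complex_type: str = "auto"       # antibody | enzyme | other | auto
    delta: float = 15.0              # rotational sampling interval, deg
    skin_mode: str = "improved"
    do_cluster: bool = True
    do_filter: bool = True
    do_rerank: str = "auto"          # on | off | auto (skip for enzymes)
    rerank_top: int = 20
    n_workers: int = 1
    outdir: str = "dock_out"
    dock: DockParams = field(default_factory=DockParams)
    skin: SkinParams = field(default_factory=SkinParams)
    filters: FilterConfig = field(default_factory=FilterConfig)
    clustering: cluster_mod.ClusterParams = field(
        default_factory=cluster_mod.ClusterParams)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cfg = cls()
        for key, value in raw.items():
            if not hasattr(cfg, key):
                raise KeyError(f"unknown config key {key!r}")
            current = getattr(cfg, key)
            if hasattr(current, "__dataclass_fields__") and isinstance(value, dict):
                for k2, v2 in value.items():
                    setattr(current, k2, v2)
            else:
                setattr(cfg, key, value)
        return cfg


POSE_COLUMNS = ["rank", "rotation_index",
                "r00", "r01", "r02", "r10", "r11", "r12", "r20", "r21", "r22",
                "tx", "ty", "tz", "SC", "EL", "IP", "dGsol", "penalties",
                "total"]


def poses_to_frame(poses: list[Pose], rotations: list[Rotation]) -> pd.DataFrame:
    rotmap = {r.index: r.matrix for r in rotations}
    rows = []
    for p in poses:
        m = rotmap.get(p.rotation_index, np.eye(3))
        rows.append({
            "rank": p.rank, "rotation_index": p.rotation_index,
            **{f"r{i}{j}": m[i, j] for i in range(3) for j in range(3)},
            "tx": p.translation[0], "ty": p.translation[1],
            "tz": p.translation[2],
            "SC": p.scores.get("SC", 0.0), "EL": p.scores.get("EL", 0.0),
            "IP": p.scores.get("IP", 0.0),
            "dGsol": p.scores.get("dGsol", np.nan),
            "penalties": json.dumps(p.penalties),
            "total": p.total})
    return pd.DataFrame(rows, columns=POSE_COLUMNS)


def write_poses(poses: list[Pose], rotations: list[Rotation],
                path: str | Path) -> None:
    poses_to_frame(poses, rotations).to_csv(path, sep="\t", index=False,
                                            float_format="%.6f")


def read_poses(path: str | Path) -> list[Pose]:
    df = pd.read_csv(path, sep="\t")
    poses = []
    for _, row in df.iterrows():
        p = Pose(rotation_index=int(row["rotation_index"]),
                 translation=np.array([row["tx"], row["ty"], row["tz"]]),
                 scores={k: float(row[k]) for k in ("SC", "EL", "IP")},
                 penalties=[tuple(x) for x in json.loads(row["penalties"])],
                 total=float(row["total"]), rank=int(row["rank"]))
        if not np.isnan(row.get("dGsol", np.nan)):
            p.scores["dGsol"] = float(row["dGsol"])
        poses.append(p)
    return poses


@dataclass
class RunResult:
    poses: list[Pose]
    rotations: list[Rotation]
    complex_type: str
    report: dict
    receptor: Molecule
    ligand: Molecule
    evaluation: pd.DataFrame | None = None


def _log(report: dict, outdir: Path, stage: str, t0: float, **info) -> None:
    entry = {"stage": stage, "seconds": round(time.time() - t0, 2), **info}
    report.setdefault("stages", []).append(entry)


def run(config: RunConfig,
        receptor: Molecule | None = None,
        ligand: Molecule | None = None,
        native_ligand: Molecule | None = None) -> RunResult:
    """Execute the docking pipeline per the configuration.

    Molecules may be passed directly (e.g. from the fixture generator)
    instead of file paths.  Raises with the failing stage's name; outputs
    of completed stages are already persisted under ``config.outdir``.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    queue = TaskQueue(config.n_workers)
    report: dict = {"config": _config_echo(config)}
    stage = "load"
    try:
        t0 = time.time()
        if receptor is None:
            receptor = molio.read_structure(config.receptor, label="receptor")
        if ligand is None:
            ligand = molio.read_structure(config.ligand, label="ligand")
        if native_ligand is None and config.native_ligand:
            native_ligand = molio.read_structure(config.native_ligand,
                                                 label="native")
        _log(report, outdir, stage, t0,
             receptor_atoms=len(receptor), ligand_atoms=len(ligand))

        stage = "prepare"
        t0 = time.time()
        receptor = detect_surface_atoms(receptor, config.skin.probe)
        ligand = detect_surface_atoms(ligand, config.skin.probe)
        ctype = config.complex_type
        if ctype == "auto":
            ctype = detect_complex_type(receptor, ligand)
        receptor, ligand = build_skin_core(receptor, ligand,
                                           mode=config.skin_mode,
                                           params=config.skin)
        report["complex_type"] = ctype
        _log(report, outdir, stage, t0, complex_type=ctype)

        stage = "dock"
        t0 = time.time()
        type_key = {"antibody": "A", "enzyme": "E", "other": "O"}[ctype]
        params = params_for_type(type_key, config.dock)
        params.skin_mode = config.skin_mode
        rotations = sample_rotations(config.delta)
        pre = fftscore.prepare_receptor(receptor, ligand, params)
        poses = fftscore.search(receptor, ligand, rotations, params, pre,
                                task_runner=queue.run)
        write_poses(poses, rotations, outdir / "poses_fft.tsv")
        _log(report, outdir, stage, t0, rotations=len(rotations),
             poses=len(poses), grid_dim=pre.spec.dim)

        if config.do_cluster:
            stage = "cluster"
            t0 = time.time()
            poses = cluster_mod.proximity_cluster(
                poses, ligand.geometric_center, config.clustering)
            write_poses(poses, rotations, outdir / "poses_clustered.tsv")
            _log(report, outdir, stage, t0)

        if config.do_filter:
            stage = "filter"
            t0 = time.time()
            ctx = FilterContext(receptor=receptor, ligand=ligand,
                                params=load_params(), config=config.filters,
                                complex_type=ctype)
            ctx.set_rotations(rotations)
            poses = apply_filters(poses, ctx, task_runner=queue.run)
            write_poses(poses, rotations, outdir / "poses_filtered.tsv")
            _log(report, outdir, stage, t0)

        do_rr = config.do_rerank == "on" or (
            config.do_rerank == "auto" and ctype != "enzyme")
        if do_rr and config.rerank_top > 0:
            stage = "rerank"
            t0 = time.time()
            model = gbrerank.SolvationModel(receptor, ligand)
            poses = gbrerank.rerank(poses, model, config.rerank_top,
                                    rotations=rotations,
                                    task_runner=queue.run)
            write_poses(poses, rotations, outdir / "poses_reranked.tsv")
            _log(report, outdir, stage, t0, reranked=min(config.rerank_top,
                                                         len(poses)))

        evaluation = None
        if native_ligand is not None:
            stage = "evaluate"
            t0 = time.time()
            evaluation = evaluate_poses(poses, rotations, receptor,
                                        native_ligand)
            evaluation.to_csv(outdir / "evaluation.tsv", sep="\t", index=False)
            _log(report, outdir, stage, t0)

        write_poses(poses, rotations, outdir / "poses_final.tsv")
        with open(outdir / "report.yaml", "w") as fh:
            yaml.safe_dump(report, fh, sort_keys=False)
        return RunResult(poses=poses, rotations=rotations, complex_type=ctype,
                         report=report, receptor=receptor, ligand=ligand,
                         evaluation=evaluation)
    except Exception as exc:
        with open(outdir / "report.yaml", "w") as fh:
            yaml.safe_dump({**report, "failed_stage": stage,
                            "error": str(exc)}, fh, sort_keys=False)
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc


def evaluate_poses(poses: list[Pose], rotations: list[Rotation],
                   receptor: Molecule, native_ligand: Molecule,
                   max_poses: int = 1000) -> pd.DataFrame:
    rotmap = {r.index: r.matrix for r in rotations}
    iface = evalmetrics.interface_backbone_set(receptor, native_ligand)
    rows = []
    for p in poses[:max_poses]:
        res = evalmetrics.evaluate_pose(
            p, receptor, native_ligand, iface,
            rotation=rotmap.get(p.rotation_index))
        rows.append({"rank": p.rank, "irmsd": res.irmsd, "fnat": res.fnat,
                     "capri": res.capri, "is_hit": res.is_hit})
    return pd.DataFrame(rows)


def _config_echo(config: RunConfig) -> dict:
    def clean(obj):
        if hasattr(obj, "__dataclass_fields__"):
            return {k: clean(v) for k, v in asdict(obj).items()}
        if isinstance(obj, (np.floating, np.integer)):
            return obj.item()
        if isinstance(obj, (list, tuple)):
            return [clean(v) for v in obj]
        if isinstance(obj, dict):
            return {k: clean(v) for k, v in obj.items()}
        return obj
    return clean(config)
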