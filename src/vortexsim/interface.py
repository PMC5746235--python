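"""Configuration loading, output serialization and run manifests.

Config documents are TOML (or JSON) with sections ``mesh``, ``params``,
``phase``, ``integrator`` and ``run``; every key defaults to the standard
simulation values, and unknown keys are rejected by name.
"""

from __future__ import annotations

import dataclasses
import json
import tomllib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .biology import ModelState, Params, PhaseConfig
from .integrators import IntegratorConfig
from .mesh import MeshSpec, VRLMesh
from .scenarios import Diagnostics, Scenario, make_scenario, scenario_names

__all__ = [
    "RunConfig",
    "load_config",
    "write_outputs",
    "write_mesh_csv",
    "read_mesh_csv",
    "write_vtk",
]


@dataclass(frozen=True)
class RunConfig:
    """One document holding everything a run needs."""

    mesh: MeshSpec = field(default_factory=MeshSpec)
    params: Params = field(default_factory=Params)
    phase: PhaseConfig | None = None
    integrator: IntegratorConfig = field(default_factory=IntegratorConfig)
    scenario: str = "mixed"
    horizon: float = 20.0
    record_every: int = 50
    snapshot_times: tuple[float, ...] = ()
    out_dir: str = "out"

    def build_scenario(self) -> Scenario:
        return make_scenario(
            self.scenario,
            params=self.params,
            phase_cfg=self.phase,
            horizon=self.horizon,
            snapshot_times=tuple(self.snapshot_times),
        )

    def to_dict(self) -> dict:
        def enc(obj):
            if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
                return {k: enc(v) for k, v in dataclasses.asdict(obj).items()}
            if isinstance(obj, tuple):
                return list(obj)
            return obj

        return {
            "mesh": enc(self.mesh),
            "params": enc(self.params),
            "phase": enc(self.phase) if self.phase else None,
            "integrator": enc(self.integrator),
            "scenario": self.scenario,
            "horizon": self.horizon,
            "record_every": self.record_every,
            "snapshot_times": list(self.snapshot_times),
            "out_dir": self.out_dir,
        }


_SECTION_TYPES = {
    "mesh": MeshSpec,
    "params": Params,
    "phase": PhaseConfig,
    "integrator": IntegratorConfig,
}
_RUN_KEYS = {"scenario", "horizon", "record_every", "snapshot_times", "out_dir"}


def _build_section(cls, data: dict, section: str):
    valid = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - valid
    if unknown:
        raise ValueError(f"unknown key(s) in [{section}]: {sorted(unknown)}")
    try:
        return cls(**data)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"invalid [{section}] configuration: {exc}") from exc


def load_config(path: str | Path) -> RunConfig:
    """Read and validate a TOML or JSON run configuration.

    Missing sections and keys take the standard defaults; an empty file
    yields the all-defaults configuration.  Validation errors name the
    offending key.
    """
    path = Path(path)
    text = path.read_bytes()
    if path.suffix.lower() == ".json":
        doc = json.loads(text.decode()) if text.strip() else {}
    else:
        doc = tomllib.loads(text.decode())

    known_sections = set(_SECTION_TYPES) | {"run"}
    unknown = set(doc) - known_sections
    if unknown:
        raise ValueError(f"unknown section(s): {sorted(unknown)}")

    kwargs = {}
    for section, cls in _SECTION_TYPES.items():
        if section in doc:
            data = dict(doc[section])
            if section == "params" and "literal_algae_diffusion" in data:
                data["literal_algae_diffusion"] = bool(data["literal_algae_diffusion"])
            kwargs[section] = _build_section(cls, data, section)
    run = dict(doc.get("run", {}))
    unknown = set(run) - _RUN_KEYS
    if unknown:
        raise ValueError(f"unknown key(s) in [run]: {sorted(unknown)}")
    if run.get("scenario") and run["scenario"] not in scenario_names():
        raise ValueError(
            f"unknown scenario {run['scenario']!r}; choose from {scenario_names()}"
        )
    if "snapshot_times" in run:
        run["snapshot_times"] = tuple(float(t) for t in run["snapshot_times"])
    return RunConfig(**kwargs, **run)


def save_config(cfg: RunConfig, path: str | Path) -> None:
    """Write a config as JSON (round-trips through :func:`load_config`)."""
    doc = cfg.to_dict()
    out = {k: v for k, v in doc.items() if k in _SECTION_TYPES and v is not None}
    out["run"] = {
        "scenario": doc["scenario"],
        "horizon": doc["horizon"],
        "record_every": doc["record_every"],
        "snapshot_times": doc["snapshot_times"],
        "out_dir": doc["out_dir"],
    }
    Path(path).write_text(json.dumps(out, indent=2))


# --------------------------------------------------------------------------
# mesh / field serialization

def write_mesh_csv(mesh: VRLMesh, out_dir: str | Path, extra_node_columns: dict | None = None) -> tuple[Path, Path]:
    """Write the node table (id, cell_i, cell_j, x, y, A, boundary, ...) and
    edge table (i, j, f, l) as CSV."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    nodes = pd.DataFrame(
        {
            "id": np.arange(mesh.n_nodes),
            "cell_i": mesh.cell_index[:, 0],
            "cell_j": mesh.cell_index[:, 1],
            "x": mesh.nodes[:, 0],
            "y": mesh.nodes[:, 1],
            "A": mesh.A,
            "boundary": mesh.boundary.astype(int),
        }
    )
    for name, col in (extra_node_columns or {}).items():
        nodes[name] = col
    edges = pd.DataFrame(
        {"i": mesh.edges[:, 0], "j": mesh.edges[:, 1], "f": mesh.f, "l": mesh.l}
    )
    npath, epath = out_dir / "nodes.csv", out_dir / "edges.csv"
    nodes.to_csv(npath, index=False, float_format="%.17g")
    edges.to_csv(epath, index=False, float_format="%.17g")
    return npath, epath


def read_mesh_csv(out_dir: str | Path, spec: MeshSpec) -> VRLMesh:
    """Rebuild a geometric mesh from the node/edge CSV tables."""
    out_dir = Path(out_dir)
    nodes = pd.read_csv(out_dir / "nodes.csv", float_precision="round_trip")
    edges = pd.read_csv(out_dir / "edges.csv", float_precision="round_trip")
    mesh = VRLMesh(
        spec=spec,
        nodes=nodes[["x", "y"]].to_numpy(),
        cell_index=nodes[["cell_i", "cell_j"]].to_numpy(),
        edges=edges[["i", "j"]].to_numpy(),
        f=edges["f"].to_numpy(),
        l=edges["l"].to_numpy(),
        A=nodes["A"].to_numpy(),
        boundary=nodes["boundary"].to_numpy().astype(bool),
    )
    return mesh


def write_vtk(
    mesh: VRLMesh, point_data: dict[str, np.ndarray], path: str | Path
) -> Path:
    """Legacy ASCII VTK unstructured grid of the Delaunay triangulation with
    per-node scalar fields."""
    from scipy.spatial import Delaunay

    path = Path(path)
    tri = Delaunay(mesh.nodes)
    cells = tri.simplices
    lines = [
        "# vtk DataFile Version 3.0",
        "vortexsim snapshot",
        "ASCII",
        "DATASET UNSTRUCTURED_GRID",
        f"POINTS {mesh.n_nodes} double",
    ]
    lines += [f"{x:.10g} {y:.10g} 0" for x, y in mesh.nodes]
    lines.append(f"CELLS {len(cells)} {4 * len(cells)}")
    lines += [f"3 {a} {b} {c}" for a, b, c in cells]
    lines.append(f"CELL_TYPES {len(cells)}")
    lines += ["5"] * len(cells)  # VTK_TRIANGLE
    lines.append(f"POINT_DATA {mesh.n_nodes}")
    for name, vals in point_data.items():
        lines.append(f"SCALARS {name} double 1")
        lines.append("LOOKUP_TABLE default")
        lines += [f"{v:.10g}" for v in np.asarray(vals)]
    path.write_text("\n".join(lines) + "\n")
    return path


def read_vtk_point_data(path: str | Path) -> dict[str, np.ndarray]:
    """Minimal reader for the files written by :func:`write_vtk` (round-trip
    checks)."""
    tokens = Path(path).read_text().split("\n")
    data: dict[str, np.ndarray] = {}
    i = 0
    npoints = 0
    while i < len(tokens):
        line = tokens[i]
        if line.startswith("POINT_DATA"):
            npoints = int(line.split()[1])
        elif line.startswith("SCALARS"):
            name = line.split()[1]
            vals = [float(v) for v in tokens[i + 2 : i + 2 + npoints]]
            data[name] = np.asarray(vals)
            i += 1 + npoints
        i += 1
    return data


def write_outputs(
    diag: Diagnostics,
    mesh: VRLMesh,
    cfg: RunConfig,
    out_dir: str | Path | None = None,
    vtk: bool = True,
) -> Path:
    """Write diagnostics CSV, node/edge CSVs, snapshot CSV (+VTK) files and
    a JSON manifest with the fully resolved configuration."""
    out_dir = Path(out_dir or cfg.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    pd.DataFrame(
        {
            "t": diag.times,
            "radius": diag.radius,
            "bbar": diag.bbar,
            "phase": diag.phase,
            "n_components": diag.n_components,
            "clipped_mass": diag.clipped_mass,
        }
    ).to_csv(out_dir / "diagnostics.csv", index=False, float_format="%.17g")

    final = diag.final_state.species_fields()
    write_mesh_csv(mesh, out_dir, extra_node_columns=final)

    for t, fields in diag.snapshots.items():
        tag = f"{t:.4f}".replace(".", "p")
        pd.DataFrame({"id": np.arange(mesh.n_nodes), **fields}).to_csv(
            out_dir / f"snapshot_t{tag}.csv", index=False, float_format="%.17g"
        )
        if vtk:
            write_vtk(mesh, fields, out_dir / f"snapshot_t{tag}.vtk")

    import platform

    manifest = {
        "config": cfg.to_dict(),
        "scenario": diag.scenario,
        "n_steps": int(round(cfg.horizon / cfg.integrator.dt)),
        "phase_switch_times": list(map(float, diag.phase_switch_times)),
        "versions": {
            "python": platform.python_version(),
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return out_dir
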