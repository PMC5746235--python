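"""Initial conditions, experiment catalogue and run diagnostics.

Every simulation variant ships as a named :class:`Scenario`: single-species
controls, the mixed colony that develops growth rings, two separated
colonies that synchronize on contact, a half-plane antibiotic gradient, the
three-species (algae) system, the parameter-sensitivity sweep and the
combined-density switching rule.

Length scale: Table-style rate constants are calibrated to reference-cell
units, so scenarios default to ``h = 1`` (domain side = nx).  The initial
colony radius is ``r0`` times the domain size.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable

import numpy as np

from .biology import (
    BUILDER,
    EXPLORER,
    ModelState,
    Params,
    PhaseConfig,
    SUPPORT_THRESHOLD,
    advance,
    mean_colony_density,
)
from .integrators import IntegratorConfig
from .mesh import MeshSpec, VRLMesh, build_mesh
from .operators import Field

__all__ = [
    "Scenario",
    "Diagnostics",
    "smoothed_disk",
    "smoothed_half_plane",
    "make_scenario",
    "scenario_names",
    "colony_radius",
    "footprint_radius",
    "cross_section",
    "radial_profile",
    "count_alternating_bands",
    "run_scenario",
    "component_count",
    "sensitivity_cases",
]

DEFAULT_BAND_CELLS = 2.0  # smoothing band width in units of h


def _smoothstep(t: np.ndarray) -> np.ndarray:
    """C^2 quintic ramp: 0 at t<=0, 1 at t>=1, 6t^5 - 15t^4 + 10t^3 between.

    First and second derivatives vanish at both ends, so indicator profiles
    built from it are twice continuously differentiable.
    """
    t = np.clip(t, 0.0, 1.0)
    return t * t * t * (t * (6.0 * t - 15.0) + 10.0)


def smoothed_disk(
    mesh: VRLMesh,
    center: tuple[float, float],
    r0: float,
    band: float | None = None,
    amplitude: float = 1.0,
    name: str = "",
) -> Field:
    """Smoothed disk indicator: ``amplitude`` for r < r0 - band, 0 for
    r > r0, with a C^2 monotone ramp in between."""
    if band is None:
        band = DEFAULT_BAND_CELLS * mesh.spec.h
    r = np.hypot(mesh.nodes[:, 0] - center[0], mesh.nodes[:, 1] - center[1])
    vals = amplitude * _smoothstep((r0 - r) / band)
    return Field(vals, mesh, name)


def smoothed_half_plane(
    mesh: VRLMesh, x_edge: float, band: float | None = None, amplitude: float = 1.0,
    name: str = "",
) -> Field:
    """Smoothed indicator of the half-plane x < x_edge."""
    if band is None:
        band = DEFAULT_BAND_CELLS * mesh.spec.h
    vals = amplitude * _smoothstep((x_edge - mesh.nodes[:, 0]) / band)
    return Field(vals, mesh, name)


@dataclass(frozen=True)
class Scenario:
    """A named experiment: initial-condition builder plus run settings."""

    name: str
    initial: Callable[[VRLMesh, "Params"], ModelState]
    params: Params = field(default_factory=Params)
    phase_cfg: PhaseConfig | None = None
    horizon: float = 20.0
    center: tuple[float, float] | None = None  # colony center for radius readout
    snapshot_times: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        if self.horizon <= 0:
            raise ValueError("horizon must be positive")

    def build_state(self, mesh: VRLMesh) -> ModelState:
        state = self.initial(mesh, self.params)
        for arr in (state.b1, state.b2, state.n, state.a):
            if np.any(arr < 0):
                raise ValueError("initial densities must be non-negative")
        return state

    def resolved_phase_cfg(self) -> PhaseConfig:
        return self.phase_cfg or PhaseConfig.from_params(self.params)

    def colony_center(self, mesh: VRLMesh) -> tuple[float, float]:
        if self.center is not None:
            return self.center
        Lx, Ly = mesh.spec.domain
        return (0.5 * Lx, 0.5 * Ly)


@dataclass
class Diagnostics:
    """Time series and snapshots collected by :func:`run_scenario`."""

    scenario: str
    times: np.ndarray
    radius: np.ndarray
    radius_footprint: np.ndarray
    bbar: np.ndarray
    phase: np.ndarray  # dominant phase per record
    n_components: np.ndarray
    clipped_mass: np.ndarray
    snapshots: dict[float, dict[str, np.ndarray]]
    final_state: ModelState
    phase_switch_times: list[float]

    def n_phase_alternations(self) -> int:
        """Number of recorded phase changes."""
        return len(self.phase_switch_times)


def _disk_state(
    mesh: VRLMesh,
    params: Params,
    centers: list[tuple[float, float]],
    with_b1: bool = True,
    with_b2: bool = True,
    with_algae: bool = False,
    antibiotic: str = "uniform",
) -> ModelState:
    Lx, Ly = mesh.spec.domain
    size = min(Lx, Ly)
    r0 = params.r0 * size
    zeros = np.zeros(mesh.n_nodes)
    b1 = zeros.copy()
    b2 = zeros.copy()
    X = zeros.copy() if with_algae else None
    for c in centers:
        disk = smoothed_disk(mesh, c, r0).values
        if with_b1:
            b1 = np.maximum(b1, disk)
        if with_b2:
            b2 = np.maximum(b2, disk)
        if with_algae:
            X = np.maximum(X, disk)
    n = np.full(mesh.n_nodes, params.n0)
    if antibiotic == "uniform":
        a = np.full(mesh.n_nodes, params.a0)
    elif antibiotic == "half_plane":
        # literal unit amplitude on the left half, smoothed over ~2h
        a = smoothed_half_plane(mesh, 0.5 * Lx).values
    else:
        raise ValueError(f"unknown antibiotic layout {antibiotic!r}")
    return ModelState(mesh=mesh, b1=b1, b2=b2, n=n, a=a, X=X)


def _center(mesh_frac: tuple[float, float]) -> Callable[[VRLMesh], tuple[float, float]]:
    def fn(mesh: VRLMesh) -> tuple[float, float]:
        Lx, Ly = mesh.spec.domain
        return (mesh_frac[0] * Lx, mesh_frac[1] * Ly)

    return fn


def make_scenario(name: str, params: Params | None = None, **overrides) -> Scenario:
    """Build a catalogue scenario by name.

    Names: ``pv_only``, ``ec_only``, ``mixed``, ``two_colonies``,
    ``half_plane_antibiotic``, ``three_species``, ``s2_rule``.
    ``overrides`` replace Scenario fields (e.g. ``horizon=10``).
    """
    p = params or Params()
    mid = (0.5, 0.5)

    def centered(mesh, frac=mid):
        Lx, Ly = mesh.spec.domain
        return (frac[0] * Lx, frac[1] * Ly)

    if name == "pv_only":
        sc = Scenario(
            name=name,
            initial=lambda mesh, pp: _disk_state(mesh, pp, [centered(mesh)], with_b2=False),
            params=p,
        )
    elif name == "ec_only":
        sc = Scenario(
            name=name,
            initial=lambda mesh, pp: _disk_state(mesh, pp, [centered(mesh)], with_b1=False),
            params=p,
        )
    elif name == "mixed":
        sc = Scenario(
            name=name,
            initial=lambda mesh, pp: _disk_state(mesh, pp, [centered(mesh)]),
            params=p,
        )
    elif name == "two_colonies":
        sc = Scenario(
            name=name,
            initial=lambda mesh, pp: _disk_state(
                mesh, pp, [centered(mesh, (0.3, 0.5)), centered(mesh, (0.7, 0.5))]
            ),
            params=p,
            phase_cfg=PhaseConfig(
                rule="b1_only",
                bbar_min=p.bbar_min,
                bbar_max=p.bbar_max,
                track_components=True,
            ),
        )
    elif name == "half_plane_antibiotic":
        sc = Scenario(
            name=name,
            initial=lambda mesh, pp: _disk_state(
                mesh, pp, [centered(mesh)], antibiotic="half_plane"
            ),
            params=p,
        )
    elif name == "three_species":
        p3 = p.three_species_defaults()
        sc = Scenario(
            name=name,
            initial=lambda mesh, pp: _disk_state(mesh, pp, [centered(mesh)], with_algae=True),
            params=p3,
        )
    elif name == "s2_rule":
        sc = Scenario(
            name=name,
            initial=lambda mesh, pp: _disk_state(mesh, pp, [centered(mesh)]),
            params=p,
            phase_cfg=PhaseConfig.from_params(p, rule="b1_plus_b2"),
        )
    else:
        raise ValueError(f"unknown scenario {name!r}; choose from {scenario_names()}")
    return replace(sc, **overrides) if overrides else sc


def scenario_names() -> list[str]:
    return [
        "pv_only",
        "ec_only",
        "mixed",
        "two_colonies",
        "half_plane_antibiotic",
        "three_species",
        "s2_rule",
    ]


def sensitivity_cases(base: Params | None = None) -> dict[str, Params]:
    """Parameter perturbations of the sensitivity sweep: a0 and n0 +-50%,
    bbar_max +-20%, C2 +-50%, D2 +-20%."""
    p = base or Params()
    cases: dict[str, Params] = {}
    for sgn, tag in ((0.5, "-50%"), (1.5, "+50%")):
        cases[f"a0{tag}"] = replace(p, a0=p.a0 * sgn)
        cases[f"n0{tag}"] = replace(p, n0=p.n0 * sgn)
        cases[f"C2{tag}"] = replace(p, C2=p.C2 * sgn)
    for sgn, tag in ((0.8, "-20%"), (1.2, "+20%")):
        cases[f"bbar_max{tag}"] = replace(p, bbar_max=p.bbar_max * sgn)
        cases[f"D2{tag}"] = replace(p, D2=p.D2 * sgn)
    return cases


# --------------------------------------------------------------------------
# diagnostics

def colony_radius(
    state: ModelState,
    center: tuple[float, float],
    threshold: float = SUPPORT_THRESHOLD,
    percentile: float = 95.0,
) -> float:
    """Robust colony radius: the given percentile of distances from the
    (fixed) inoculation center over nodes with live density above the
    threshold.  Zero for an empty colony.  For disjoint colonies this spans
    both (documented behavior)."""
    live = state.b1 + state.b2
    return _radius_of(live, state.mesh, center, threshold, percentile)


def footprint_radius(
    state: ModelState,
    center: tuple[float, float],
    threshold: float = 0.01,
    percentile: float = 95.0,
) -> float:
    """Radius of the visible colony footprint: live plus dead density above
    a visibility threshold (dead cells remain part of the observed colony,
    so this is the quantity radius-vs-time plots track)."""
    acc = state.b1 + state.s1 + state.b2 + state.s2
    if state.has_algae:
        acc = acc + state.X + state.sX
    return _radius_of(acc, state.mesh, center, threshold, percentile)


def _radius_of(density, mesh, center, threshold, percentile) -> float:
    sel = density > threshold
    if not sel.any():
        return 0.0
    r = np.hypot(mesh.nodes[sel, 0] - center[0], mesh.nodes[sel, 1] - center[1])
    return float(np.percentile(r, percentile))


def cross_section(
    values: np.ndarray,
    mesh: VRLMesh,
    center: tuple[float, float],
    angle: float = 0.0,
    width: float | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Values of nodes within ``width`` of the line through ``center`` at
    ``angle`` (radians), against signed along-line coordinate."""
    if width is None:
        width = 1.5 * mesh.spec.h
    d = mesh.nodes - np.asarray(center)
    u = np.array([math.cos(angle), math.sin(angle)])
    along = d @ u
    across = d @ np.array([-u[1], u[0]])
    sel = np.abs(across) <= 0.5 * width
    order = np.argsort(along[sel])
    return along[sel][order], np.asarray(values)[sel][order]


def radial_profile(
    values: np.ndarray,
    mesh: VRLMesh,
    center: tuple[float, float],
    nbins: int = 40,
    rmax: float | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Area-weighted radial average on equal-width annuli."""
    r = np.hypot(mesh.nodes[:, 0] - center[0], mesh.nodes[:, 1] - center[1])
    if rmax is None:
        rmax = float(r.max())
    bins = np.linspace(0.0, rmax, nbins + 1)
    idx = np.clip(np.digitize(r, bins) - 1, 0, nbins - 1)
    wsum = np.bincount(idx, mesh.A * np.asarray(values), nbins)
    asum = np.bincount(idx, mesh.A, nbins)
    with np.errstate(invalid="ignore", divide="ignore"):
        prof = np.where(asum > 0, wsum / np.maximum(asum, 1e-300), np.nan)
    centers = 0.5 * (bins[:-1] + bins[1:])
    return centers, prof


def count_alternating_bands(profile: np.ndarray, rel_prominence: float = 0.05) -> int:
    """Number of alternating high-density bands (rings) in a radial profile.

    Counts local maxima whose prominence exceeds ``rel_prominence`` times
    the peak's own height, so successively weaker outer rings of a decaying
    ring train still register.  An elevated center plateau counts as the
    innermost band."""
    from scipy.signal import find_peaks, peak_prominences

    prof = np.asarray(profile, dtype=float)
    prof = prof[np.isfinite(prof)]
    if prof.size < 3 or prof.max() <= prof.min():
        return 0
    peaks, _ = find_peaks(prof)
    if len(peaks):
        prominences = peak_prominences(prof, peaks)[0]
        keep = prominences >= rel_prominence * prof[peaks]
        count = int(keep.sum())
    else:
        count = 0
    if prof[0] > prof[1]:
        count += 1
    return count


def component_count(state: ModelState, cfg: PhaseConfig) -> int:
    from .biology import _support_components

    n, _, _ = _support_components(state, cfg)
    return n


def run_scenario(
    scenario: Scenario,
    mesh: VRLMesh | MeshSpec | None = None,
    cfg: IntegratorConfig | None = None,
    record_every: int = 50,
    snapshot_fields: tuple[str, ...] | None = None,
    progress: bool = False,
) -> Diagnostics:
    """Integrate a scenario to its horizon, recording the colony radius,
    mean density, dominant phase and support-component count every
    ``record_every`` steps, plus full-field snapshots at the scenario's
    snapshot times.  Deterministic for a fixed mesh seed."""
    if mesh is None:
        mesh = MeshSpec(nx=64, ny=64, h=1.0, seed=0)
    if isinstance(mesh, MeshSpec):
        mesh = build_mesh(mesh)
    if cfg is None:
        cfg = IntegratorConfig()
    phase_cfg = scenario.resolved_phase_cfg()
    state = scenario.build_state(mesh)
    center = scenario.colony_center(mesh)
    n_steps = int(round(scenario.horizon / cfg.dt))
    snap_steps = sorted(
        {min(n_steps, max(0, int(round(ts / cfg.dt)))) for ts in scenario.snapshot_times}
    )

    times, radius, bbar_series, phase_series, ncomp_series, clipped = [], [], [], [], [], []
    radius_fp = []
    snapshots: dict[float, dict[str, np.ndarray]] = {}
    switch_times: list[float] = []
    prev_phase = state.global_phase

    def record(st: ModelState) -> None:
        times.append(st.t)
        radius.append(colony_radius(st, center, phase_cfg.support_threshold))
        radius_fp.append(footprint_radius(st, center))
        bbar_series.append(
            mean_colony_density(st.b1, st.b2, phase_cfg, mesh=st.mesh)
        )
        phase_series.append(st.global_phase)
        ncomp_series.append(
            component_count(st, phase_cfg) if phase_cfg.track_components else 1
        )
        clipped.append(st.clipped_mass)

    def snapshot(st: ModelState) -> None:
        fields = st.species_fields()
        keep = snapshot_fields or tuple(fields)
        snapshots[round(st.t, 9)] = {k: fields[k].copy() for k in keep}
        snapshots[round(st.t, 9)]["accumulated"] = (st.b1 + st.s1 + st.b2 + st.s2).copy()

    record(state)
    if 0 in snap_steps:
        snapshot(state)
    for step in range(1, n_steps + 1):
        state = advance(state, scenario.params, cfg, phase_cfg)
        gp = state.global_phase
        if gp != prev_phase:
            switch_times.append(state.t)
            prev_phase = gp
        if step % record_every == 0 or step == n_steps:
            record(state)
            if progress and (step % (20 * record_every) == 0):
                print(
                    f"[{scenario.name}] t={state.t:.2f} radius={radius[-1]:.2f} "
                    f"bbar={bbar_series[-1]:.4f} phase={gp}"
                )
        if step in snap_steps:
            snapshot(state)

    return Diagnostics(
        scenario=scenario.name,
        times=np.asarray(times),
        radius=np.asarray(radius),
        radius_footprint=np.asarray(radius_fp),
        bbar=np.asarray(bbar_series),
        phase=np.asarray(phase_series),
        n_components=np.asarray(ncomp_series),
        clipped_mass=np.asarray(clipped),
        snapshots=snapshots,
        final_state=state,
        phase_switch_times=switch_times,
    )
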