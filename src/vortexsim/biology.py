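"""Model content for the cooperating-colony simulator.

Species and fields
------------------
b1  swarming species (P. vortex-like): porous-medium self-diffusion with a
    colony-wide builder/explorer motility switch, nutrient-dependent growth
    and an antibiotic kill rate mu1(n, a) proportional to a (growth-coupled
    by default; see Params.nutrient_shielded_mortality).
b2  carried species (E. coli-like): weak self-diffusion, advection along
    grad(b1), growth beta2*n, death mu2(n) = 1/(1 + 4 n), degrades the
    antibiotic at rate p*a per unit b2.
X   optional algal species: carried like b2, boosts bacterial growth by the
    factor (1 + rX*X), consumes nutrients, dies at constant rate muX.
n   nutrient; a antibiotic.  s1, s2, sX accumulate dead mass
    (ds_i/dt = mu_i b_i), so s_i + b_i is the live-plus-dead density whose
    spatial pattern shows the growth rings.

Reproduction, nutrient-consumption and antibiotic-degradation rates are
proportional: beta(n) = beta*n, lambda(n) = lambda*n, p(a) = p*a.

The global phase switches by hysteresis on the mean colony density
(area-weighted mean of b1 — or b1+b2 — over its support {density > 1e-6}):
builder -> explorer when the mean exceeds bbar_max, explorer -> builder when
it falls below bbar_min.  Each connected component of the support carries
its own phase, so spatially separate colonies switch independently and
synchronize when they merge.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .mesh import VRLMesh
from .operators import Field, divergence_values

__all__ = [
    "Params",
    "PhaseConfig",
    "ModelState",
    "BUILDER",
    "EXPLORER",
    "mortality_pvortex",
    "mortality_ecoli",
    "linear_rate",
    "rhs_single",
    "rhs_two_species",
    "rhs_three_species",
    "mean_colony_density",
    "phase_update",
    "accumulate_dead",
    "advance",
]

BUILDER = 0
EXPLORER = 1

SUPPORT_THRESHOLD = 1e-6


@dataclass(frozen=True)
class Params:
    """All model rate/diffusion/threshold constants (simulation units)."""

    D1_explore: float = 0.35
    D1_build: float = 0.0125
    D2: float = 0.0001
    C2: float = 6.0
    Dn: float = 0.25
    Da: float = 0.25
    beta1_explore: float = 0.7
    beta1_build: float = 0.9
    beta2: float = 0.5
    k_explore: int = 0
    k_build: int = 1
    lambda1: float = 0.9
    lambda2: float = 0.9
    n0: float = 2.0
    p: float = 0.6
    a0: float = 2.0
    bbar_max: float = 0.033
    bbar_min: float = 0.007
    r0: float = 0.15  # initial colony radius as a fraction of domain size
    # three-species extras
    rX: float = 1.0
    DX: float = 0.25
    CX: float = 10.0
    betaX: float = 0.25
    muX: float = 0.1
    lambdaX: float = 0.9
    literal_algae_diffusion: bool = False  # diffuse b2 instead of X in the X equation
    # Antibiotic kill-rate form for the swarming species.  False (default):
    # mu1 = 0.3*a*(1 + 4n) — the kill rate scales with growth activity, as
    # for beta-lactams, which act on dividing cells.  This is the only form
    # under which a single-species colony collapses without expanding while
    # the mixed colony expands (nutrient-rich fronts are lethal until the
    # carried species degrades the antibiotic).  True: mu1 = 0.3*a/(1 + 4n)
    # (nutrient shields against the antibiotic), under which the swarming
    # species outgrows the antibiotic at any nutrient-rich front on its own.
    nutrient_shielded_mortality: bool = False

    def __post_init__(self) -> None:
        numeric = {
            k: v
            for k, v in self.__dict__.items()
            if isinstance(v, (int, float)) and not isinstance(v, bool)
        }
        bad = [k for k, v in numeric.items() if v < 0]
        if bad:
            raise ValueError(f"negative parameter(s): {bad}")
        if not self.bbar_min < self.bbar_max:
            raise ValueError("bbar_min must be smaller than bbar_max")
        if self.D2 > 0.1 * self.D1_explore or self.D2 > 0.1 * self.C2:
            warnings.warn(
                "D2 should be much smaller than D1 and C2 for the carried "
                "species to move mainly by advection",
                stacklevel=2,
            )

    def three_species_defaults(self) -> "Params":
        """Overrides used for the three-species runs (shifted n0 and
        phase thresholds)."""
        return replace(self, n0=0.5, bbar_max=0.04, bbar_min=0.02)

    def motility(self, phase: int) -> tuple[float, float, int]:
        """(D1, beta1, k) for a phase; the three switch jointly."""
        if phase == EXPLORER:
            return self.D1_explore, self.beta1_explore, self.k_explore
        return self.D1_build, self.beta1_build, self.k_build


@dataclass(frozen=True)
class PhaseConfig:
    """Hysteresis rule for the builder/explorer transition."""

    support_threshold: float = SUPPORT_THRESHOLD
    rule: Literal["b1_only", "b1_plus_b2"] = "b1_only"
    bbar_min: float = 0.007
    bbar_max: float = 0.033
    track_components: bool = False  # per-connected-component phases (multi-colony)

    def __post_init__(self) -> None:
        if not 0 < self.bbar_min < self.bbar_max:
            raise ValueError("need 0 < bbar_min < bbar_max")
        if self.rule not in ("b1_only", "b1_plus_b2"):
            raise ValueError(f"unknown phase rule {self.rule!r}")

    @classmethod
    def from_params(cls, params: Params, rule: str = "b1_only") -> "PhaseConfig":
        if rule == "b1_plus_b2":
            # shifted thresholds for the combined-density rule
            return cls(rule=rule, bbar_min=0.029, bbar_max=0.066)
        return cls(rule=rule, bbar_min=params.bbar_min, bbar_max=params.bbar_max)


@dataclass
class ModelState:
    """Fields, dead-mass accumulators, per-node phase and simulation time."""

    mesh: VRLMesh
    b1: np.ndarray
    b2: np.ndarray
    n: np.ndarray
    a: np.ndarray
    X: np.ndarray | None = None
    s1: np.ndarray = None
    s2: np.ndarray = None
    sX: np.ndarray | None = None
    phase: np.ndarray = None  # int8 per node, BUILDER or EXPLORER
    t: float = 0.0
    clipped_mass: float = 0.0  # cumulative mass removed by negativity clipping

    def __post_init__(self) -> None:
        N = self.mesh.n_nodes
        for name in ("b1", "b2", "n", "a"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != (N,):
                raise ValueError(f"{name} must have one value per node")
            setattr(self, name, arr)
        if self.X is not None:
            self.X = np.asarray(self.X, dtype=float)
        if self.s1 is None:
            self.s1 = np.zeros(N)
        if self.s2 is None:
            self.s2 = np.zeros(N)
        if self.X is not None and self.sX is None:
            self.sX = np.zeros(N)
        if self.phase is None:
            self.phase = np.full(N, BUILDER, dtype=np.int8)  # all start as builders
        else:
            self.phase = np.asarray(self.phase, dtype=np.int8)

    @property
    def has_algae(self) -> bool:
        return self.X is not None

    @property
    def global_phase(self) -> int:
        """Phase of the majority of support nodes (diagnostic)."""
        sup = (self.b1 + self.b2) > SUPPORT_THRESHOLD
        if not sup.any():
            return int(np.round(self.phase.mean()))
        return int(np.round(self.phase[sup].mean()))

    def species_fields(self) -> dict[str, np.ndarray]:
        out = {"b1": self.b1, "b2": self.b2, "n": self.n, "a": self.a,
               "s1": self.s1, "s2": self.s2}
        if self.has_algae:
            out["X"] = self.X
            out["sX"] = self.sX
        return out

    def copy(self) -> "ModelState":
        return ModelState(
            mesh=self.mesh,
            b1=self.b1.copy(), b2=self.b2.copy(), n=self.n.copy(), a=self.a.copy(),
            X=None if self.X is None else self.X.copy(),
            s1=self.s1.copy(), s2=self.s2.copy(),
            sX=None if self.sX is None else self.sX.copy(),
            phase=self.phase.copy(), t=self.t, clipped_mass=self.clipped_mass,
        )


# --------------------------------------------------------------------------
# rate functions

def mortality_pvortex(n, a, nutrient_shielded: bool = False):
    """Antibiotic kill rate of the swarming species.

    Default (growth-coupled): mu1(n, a) = 0.3 a (1 + 4 n) — more nutrient
    means more division and a higher beta-lactam kill rate.  With
    ``nutrient_shielded=True``: mu1(n, a) = 0.3 a / (1 + 4 n).  Both are
    zero without antibiotic and proportional to ``a``.
    """
    n = np.asarray(n)
    a = np.asarray(a)
    if nutrient_shielded:
        return 0.3 * a / (1.0 + 4.0 * n)
    return 0.3 * a * (1.0 + 4.0 * n)


def mortality_ecoli(n):
    """mu2(n) = 1 / (1 + 4 n): starvation mortality, decreasing in n."""
    return 1.0 / (1.0 + 4.0 * np.asarray(n))


def linear_rate(x, coefficient):
    """Proportional rate law used for reproduction (beta*n), nutrient
    consumption (lambda*n) and antibiotic degradation (p*a)."""
    return coefficient * np.asarray(x)


# --------------------------------------------------------------------------
# right-hand sides

def _phase_coefficients(params: Params, phase: np.ndarray):
    """Per-node (D1, beta1, k) from the per-node phase; scalars when the
    phase is colony-wide uniform (the common case)."""
    first = phase[0]
    if np.all(phase == first):
        return params.motility(int(first))
    explorer = phase == EXPLORER
    D1 = np.where(explorer, params.D1_explore, params.D1_build)
    beta1 = np.where(explorer, params.beta1_explore, params.beta1_build)
    k = np.where(explorer, params.k_explore, params.k_build).astype(float)
    return D1, beta1, k


def _b1_psi(b1: np.ndarray, D1, k) -> np.ndarray:
    """Mobility D1 * b1^k with the convention 0^0 = 1."""
    if np.ndim(k) == 0:
        if k == 0:
            return np.full(b1.shape, float(D1))
        if k == 1:
            return D1 * b1
        return D1 * b1**k
    return D1 * np.power(b1, k)


def rhs_single(state: ModelState, params: Params) -> dict[str, np.ndarray]:
    """Single-species model: nonlinear self-diffusion, growth beta1(n),
    death mu1(n, a), and a diffusing, consumed nutrient."""
    mesh = state.mesh
    D1, beta1, k = _phase_coefficients(params, state.phase)
    mu1 = mortality_pvortex(state.n, state.a, params.nutrient_shielded_mortality)
    db1 = (
        divergence_values(mesh, state.b1, _b1_psi(state.b1, D1, k))
        + linear_rate(state.n, beta1) * state.b1
        - mu1 * state.b1
    )
    dn = (
        params.Dn * divergence_values(mesh, state.n, None)
        - linear_rate(state.n, params.lambda1) * state.b1
    )
    return {"b1": db1, "n": dn}


def rhs_two_species(state: ModelState, params: Params) -> dict[str, np.ndarray]:
    """Two-species model with antibiotic.

    Adds the carried species b2 (weak diffusion plus advection along
    grad(b1) with mobility C2*b2) and the antibiotic field degraded by b2.
    """
    mesh = state.mesh
    out = rhs_single(state, params)
    mu2 = mortality_ecoli(state.n)
    db2 = (
        params.D2 * divergence_values(mesh, state.b2, None)
        + divergence_values(mesh, state.b1, params.C2 * state.b2)
        + linear_rate(state.n, params.beta2) * state.b2
        - mu2 * state.b2
    )
    out["b2"] = db2
    out["n"] = out["n"] - linear_rate(state.n, params.lambda2) * state.b2
    out["a"] = (
        params.Da * divergence_values(mesh, state.a, None)
        - linear_rate(state.a, params.p) * state.b2
    )
    return out


def rhs_three_species(state: ModelState, params: Params) -> dict[str, np.ndarray]:
    """Three-species model: algae X carried like b2, boosting growth of both
    bacteria by (1 + rX*X) and consuming nutrients.

    The algal transport terms act on X by default (so the model nests
    exactly into the two-species one at X = 0); set
    ``params.literal_algae_diffusion`` to use b2 in both terms of the X
    equation instead (the equation as printed, which advects and diffuses
    the carrier rather than the algae).
    """
    if state.X is None:
        raise ValueError("state has no algae field X")
    mesh = state.mesh
    out = rhs_two_species(state, params)
    boost = params.rX * state.X
    D1, beta1, _ = _phase_coefficients(params, state.phase)
    out["b1"] = out["b1"] + linear_rate(state.n, beta1) * boost * state.b1
    out["b2"] = out["b2"] + linear_rate(state.n, params.beta2) * boost * state.b2
    carried = state.b2 if params.literal_algae_diffusion else state.X
    dX = (
        params.DX * divergence_values(mesh, carried, None)
        + divergence_values(mesh, state.b1, params.CX * carried)
        + linear_rate(state.n, params.betaX) * state.X
        - params.muX * state.X
    )
    out["X"] = dX
    out["n"] = out["n"] - linear_rate(state.n, params.lambdaX) * state.X
    return out


def model_rhs(state: ModelState, params: Params) -> dict[str, np.ndarray]:
    """Dispatch on the state's species content."""
    if state.has_algae:
        return rhs_three_species(state, params)
    return rhs_two_species(state, params)


# --------------------------------------------------------------------------
# phase controller

def mean_colony_density(
    b1: Field | np.ndarray,
    b2: Field | np.ndarray | None = None,
    cfg: PhaseConfig | None = None,
    mesh: VRLMesh | None = None,
    mask: np.ndarray | None = None,
) -> float:
    """Area-weighted mean of the phase-rule density over its own support.

    Returns 0 when the support is empty.  ``mask`` restricts the support to
    a node subset (used for per-component phase bookkeeping).
    """
    if cfg is None:
        cfg = PhaseConfig()
    if isinstance(b1, Field):
        mesh = b1.mesh
        b1 = b1.values
    if isinstance(b2, Field):
        b2 = b2.values
    if mesh is None:
        raise ValueError("mesh required when passing raw arrays")
    density = b1 if (cfg.rule == "b1_only" or b2 is None) else b1 + b2
    support = density > cfg.support_threshold
    if mask is not None:
        support = support & mask
    if not support.any():
        return 0.0
    A = mesh.A[support]
    return float(np.dot(A, density[support]) / A.sum())


def phase_update(bbar: float, phase: int, cfg: PhaseConfig) -> int:
    """Hysteresis: builder -> explorer above bbar_max, explorer -> builder
    below bbar_min, otherwise unchanged."""
    if phase == BUILDER and bbar > cfg.bbar_max:
        return EXPLORER
    if phase == EXPLORER and bbar < cfg.bbar_min:
        return BUILDER
    return phase


def accumulate_dead(s: np.ndarray, b: np.ndarray, mu: np.ndarray, dt: float) -> np.ndarray:
    """s += dt * mu * b (explicit, mu evaluated at the start of the step)."""
    return s + dt * mu * b


def _support_components(state: ModelState, cfg: PhaseConfig) -> tuple[int, np.ndarray, np.ndarray]:
    """Connected components (natural-neighbor adjacency) of the support of
    the phase-rule density.  Returns (n_components, labels, support_mask);
    labels are -1 off support."""
    density = state.b1 if cfg.rule == "b1_only" else state.b1 + state.b2
    support = density > cfg.support_threshold
    mesh = state.mesh
    n = mesh.n_nodes
    labels = np.full(n, -1, dtype=np.int64)
    if not support.any():
        return 0, labels, support
    i, j = mesh.edges[:, 0], mesh.edges[:, 1]
    keep = support[i] & support[j]
    sub = csr_matrix(
        (np.ones(int(keep.sum())), (i[keep], j[keep])), shape=(n, n)
    )
    ncomp_all, lab_all = connected_components(sub, directed=False)
    # renumber only the support components
    sup_labels = lab_all[support]
    uniq, renum = np.unique(sup_labels, return_inverse=True)
    labels[support] = renum
    return len(uniq), labels, support


def update_phase_field(state: ModelState, cfg: PhaseConfig) -> list[tuple[int, float, int]]:
    """Re-evaluate the builder/explorer phase.

    With ``cfg.track_components`` False (the default) the colony is treated
    as a single unit: one mean density, one hysteresis decision, broadcast
    to every node.  Returns [(0, bbar, phase)].
    """
    if not cfg.track_components:
        prev = state.global_phase
        bbar = mean_colony_density(state.b1, state.b2, cfg, mesh=state.mesh)
        new = phase_update(bbar, prev, cfg)
        state.phase[:] = new
        return [(0, bbar, new)]
    return _update_phase_per_component(state, cfg)


def _update_phase_per_component(state: ModelState, cfg: PhaseConfig) -> list[tuple[int, float, int]]:
    """Re-evaluate the builder/explorer phase per support component.

    Each component's phase is advanced by the hysteresis rule from the
    majority phase of its members, then written back to every member (so
    merged colonies immediately share one phase).  Returns a list of
    (component, bbar, phase) records.
    """
    ncomp, labels, support = _support_components(state, cfg)
    records: list[tuple[int, float, int]] = []
    for comp in range(ncomp):
        members = labels == comp
        prev = int(np.round(state.phase[members].mean()))
        bbar = mean_colony_density(
            state.b1, state.b2, cfg, mesh=state.mesh, mask=members
        )
        new = phase_update(bbar, prev, cfg)
        state.phase[members] = new
        records.append((comp, bbar, new))
    if ncomp:
        # off-support nodes adopt the phase of the largest component so that
        # newly colonized territory starts in the colony's current phase
        sizes = np.bincount(labels[support], minlength=ncomp)
        state.phase[~support] = state.phase[labels == int(np.argmax(sizes))][0]
    return records


# --------------------------------------------------------------------------
# coupled stepping

def advance(state: ModelState, params: Params, cfg, phase_cfg: PhaseConfig | None = None) -> ModelState:
    """One explicit step of the full model (reactions, advection and
    diffusion forward-Euler), dead-mass accumulation, negativity clipping
    and the phase update.

    With ``cfg.scheme == 'crank_nicolson'`` the self-diffusion of every
    field is advanced implicitly (reactions and advection stay explicit).
    """
    if phase_cfg is None:
        phase_cfg = PhaseConfig.from_params(params)
    dt = cfg.dt
    mesh = state.mesh
    new = state.copy()

    mu1 = mortality_pvortex(state.n, state.a, params.nutrient_shielded_mortality)
    mu2 = mortality_ecoli(state.n)

    if cfg.scheme == "forward_euler":
        derivs = model_rhs(state, params)
        for name, d in derivs.items():
            arr = getattr(new, name) + dt * d
            if not np.all(np.isfinite(arr)):
                raise FloatingPointError(
                    f"non-finite values in field '{name}' at t={state.t + dt:.4f}; "
                    "reduce dt"
                )
            setattr(new, name, arr)
    else:
        _advance_cn(state, new, params, cfg)

    # dead mass, with mu at the start of the step
    new.s1 = accumulate_dead(state.s1, state.b1, mu1, dt)
    new.s2 = accumulate_dead(state.s2, state.b2, mu2, dt)
    if state.has_algae:
        new.sX = accumulate_dead(state.sX, state.X, params.muX, dt)

    # clip negative densities (explicit reactions can undershoot)
    for name in ("b1", "b2", "n", "a") + (("X",) if state.has_algae else ()):
        arr = getattr(new, name)
        neg = arr < 0
        if neg.any():
            new.clipped_mass += float(-np.dot(mesh.A[neg], arr[neg]))
            arr[neg] = 0.0

    new.t = state.t + dt
    update_phase_field(new, phase_cfg)
    return new


def _advance_cn(state: ModelState, new: ModelState, params: Params, cfg) -> None:
    """Crank-Nicolson self-diffusion + explicit reactions/advection."""
    from .integrators import cn_diffusion_step

    mesh = state.mesh
    dt = cfg.dt
    # explicit part: full RHS minus the self-diffusion terms
    derivs = model_rhs(state, params)
    D1, _, k = _phase_coefficients(params, state.phase)
    explicit = {
        "b1": derivs["b1"] - divergence_values(mesh, state.b1, _b1_psi(state.b1, D1, k)),
        "b2": derivs["b2"] - params.D2 * divergence_values(mesh, state.b2, None),
        "n": derivs["n"] - params.Dn * divergence_values(mesh, state.n, None),
        "a": derivs["a"] - params.Da * divergence_values(mesh, state.a, None),
    }
    diffusion = {"b2": (0, params.D2), "n": (0, params.Dn), "a": (0, params.Da)}
    if state.has_algae:
        DXfield = state.b2 if params.literal_algae_diffusion else state.X
        explicit["X"] = derivs["X"] - params.DX * divergence_values(mesh, DXfield, None)
        diffusion["X"] = (0, params.DX)
    # b1: phase is colony-wide in practice; use the dominant phase's (D1, k)
    dom = state.global_phase
    D1g, _, kg = params.motility(dom)
    for name, (kk, DD) in {"b1": (kg, D1g), **diffusion}.items():
        phi = Field(getattr(state, name), mesh, name)
        stepped, _ = cn_diffusion_step(phi, kk, DD, dt, cfg)
        arr = stepped.values + dt * explicit[name]
        if not np.all(np.isfinite(arr)):
            raise FloatingPointError(f"non-finite values in field '{name}' (CN step)")
        setattr(new, name, arr)
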