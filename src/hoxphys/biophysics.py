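"""Pulling-force model of Hox cluster extrusion and gene activation.

The model couples two scales.  Macroscopically, a morphogen gradient
M(x) = M0·exp(-(axis_length-x)/lambda) rises toward the posterior end of
the embryo axis; concentration thresholds T1 < T2 < ... carve nested
expression domains S_k = {x : M(x) >= T_k} that all share the posterior
end.  Microscopically, the transduced signal accumulates pulling molecules
whose capacity P(x,t) = alpha·M(x)·t grows linearly in time, and the
cluster carries a 'charge' N proportional to its fiber extent, giving the
extruding force

    F = P · N.

The force decondenses the cluster like an expanding elastic spring whose
anterior (3') end is loose and whose posterior (5') end is anchored:
quasi-static work balance against a position-dependent stiffness s(u)
determines the extruded fiber length E.  A gene g sitting L_g Kbp from the
anterior end is out of the chromosome territory once delta_g = E - L_g >= 0,
and its activation intensity follows a triangular kernel peaked near the
CT/ICD border (the transcription-factory side): genes still inside the CT
are silent, the most recently extruded gene is activated most strongly,
and genes that have traveled far past the factory fade — which yields
spatial, temporal and quantitative collinearity at once.

All units are arbitrary (Kbp on the fiber, dimensionless force); only
orderings and comparisons carry meaning.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .cluster import HoxCluster, HoxValidationError, cluster_span

__all__ = [
    "MorphogenField",
    "ThresholdSchedule",
    "ChargeModel",
    "ElasticityProfile",
    "ActivationKernel",
    "ExtrusionState",
    "CollinearityReport",
    "morphogen_at",
    "expression_domain",
    "pull_force",
    "extrusion_length",
    "activation_intensity",
    "simulate_expression",
    "collinearity_report",
    "DEFAULTS",
]

# Default parameter set (arbitrary units). axis_length/decay_lambda shape the
# gradient; alpha and kappa_N scale force accumulation so that a posterior
# cell extrudes the whole 94-Kbp mouse cluster within the default time grid;
# the kernel width exceeds the cluster span so extruded genes stay weakly
# active while intensity still falls off with distance from the factory.
DEFAULTS: dict[str, float] = {
    "axis_length": 100.0,
    "decay_lambda": 30.0,
    "peak_value": 1.0,
    "alpha": 60.0,
    "kappa_N": 0.01,
    "stiffness": 1.0,
    "rho": 0.5,
    "tf_offset": 0.0,
    "width": 130.0,
    "peak_intensity": 1.0,
    "t_max": 2.0,
}


@dataclass(frozen=True)
class MorphogenField:
    """Exponential morphogen gradient peaking at the posterior end."""

    axis_length: float = DEFAULTS["axis_length"]
    decay_lambda: float = DEFAULTS["decay_lambda"]
    peak_value: float = DEFAULTS["peak_value"]

    def __post_init__(self) -> None:
        if self.axis_length <= 0 or self.decay_lambda <= 0 or self.peak_value <= 0:
            raise HoxValidationError("field parameters must be positive")


@dataclass(frozen=True)
class ThresholdSchedule:
    """Strictly increasing thresholds T_k paired with activation times t_k."""

    thresholds: tuple[float, ...]
    times: tuple[float, ...]

    def __post_init__(self) -> None:
        T, t = tuple(self.thresholds), tuple(self.times)
        object.__setattr__(self, "thresholds", T)
        object.__setattr__(self, "times", t)
        if len(T) != len(t):
            raise HoxValidationError("thresholds and times must have equal length")
        if any(b <= a for a, b in zip(T, T[1:])) or any(
            b <= a for a, b in zip(t, t[1:])
        ):
            raise HoxValidationError("thresholds and times must be strictly increasing")


@dataclass(frozen=True)
class ChargeModel:
    """Force bookkeeping: F = P·N with P(x,t) = alpha·M(x)·t, N = kappa_N·span."""

    alpha: float = DEFAULTS["alpha"]
    kappa_N: float = DEFAULTS["kappa_N"]
    N: float = 0.0

    @classmethod
    def for_cluster(
        cls,
        cluster: HoxCluster,
        alpha: float = DEFAULTS["alpha"],
        kappa_N: float = DEFAULTS["kappa_N"],
    ) -> "ChargeModel":
        return cls(alpha=alpha, kappa_N=kappa_N, N=kappa_N * cluster_span(cluster))


@dataclass(frozen=True)
class ElasticityProfile:
    """Positive step-function stiffness s(u) along the fiber from the 3' end.

    ``edges`` are the breakpoints (starting at 0, strictly increasing) and
    ``stiffness`` the per-interval values; beyond the last edge the final
    stiffness extends indefinitely (the fiber continues into the anchor
    region), so extrusion is defined for any finite force.
    """

    edges: tuple[float, ...]
    stiffness: tuple[float, ...]

    def __post_init__(self) -> None:
        edges = tuple(float(e) for e in self.edges)
        s = tuple(float(v) for v in self.stiffness)
        object.__setattr__(self, "edges", edges)
        object.__setattr__(self, "stiffness", s)
        if len(edges) < 2 or edges[0] != 0.0:
            raise HoxValidationError("profile edges must start at 0 with >= 1 segment")
        if any(b <= a for a, b in zip(edges, edges[1:])):
            raise HoxValidationError("profile edges must be strictly increasing")
        if len(s) != len(edges) - 1:
            raise HoxValidationError("need one stiffness value per interval")
        if any(v <= 0 for v in s):
            raise HoxValidationError("stiffness must be positive everywhere")

    @classmethod
    def uniform(cls, length: float, stiffness: float = 1.0) -> "ElasticityProfile":
        return cls(edges=(0.0, float(length)), stiffness=(float(stiffness),))

    @property
    def length(self) -> float:
        return self.edges[-1]

    def work(self, e: float | np.ndarray) -> np.ndarray | float:
        """Quasi-static work to extrude fiber length ``e``: ∫0^e s(u) du."""
        edges = np.asarray(self.edges)
        s = np.asarray(self.stiffness)
        cum = np.concatenate([[0.0], np.cumsum(s * np.diff(edges))])
        e_arr = np.asarray(e, dtype=float)
        idx = np.clip(np.searchsorted(edges, e_arr, side="right") - 1, 0, s.size - 1)
        w = cum[idx] + s[idx] * (e_arr - edges[idx])
        return w if w.ndim else float(w)

    def extrusion(self, F: float | np.ndarray) -> np.ndarray | float:
        """Inverse of :meth:`work`: the largest e with ∫0^e s(u)du <= F."""
        edges = np.asarray(self.edges)
        s = np.asarray(self.stiffness)
        cum = np.concatenate([[0.0], np.cumsum(s * np.diff(edges))])
        F_arr = np.asarray(F, dtype=float)
        idx = np.clip(np.searchsorted(cum, F_arr, side="right") - 1, 0, s.size - 1)
        e = edges[idx] + (F_arr - cum[idx]) / s[idx]
        return e if e.ndim else float(e)

    def excise(self, start: float, end: float) -> "ElasticityProfile":
        """Profile of the fiber after deleting the interval [start, end]."""
        if not (0.0 <= start < end <= self.length):
            raise HoxValidationError(
                f"cannot excise [{start}, {end}] from fiber of length {self.length}"
            )
        new_edges: list[float] = [0.0]
        new_s: list[float] = []
        D = end - start
        for a, b, v in zip(self.edges, self.edges[1:], self.stiffness):
            lo, hi = max(a, start), min(b, end)
            kept = (b - a) - max(0.0, hi - lo)
            if kept <= 0:
                continue
            edge = new_edges[-1] + kept
            if new_s and math.isclose(new_s[-1], v):
                new_edges[-1] = edge
            else:
                new_edges.append(edge)
                new_s.append(v)
        if not new_s:
            raise HoxValidationError("excision removed the whole fiber")
        assert math.isclose(new_edges[-1], self.length - D)
        return ElasticityProfile(edges=tuple(new_edges), stiffness=tuple(new_s))


@dataclass(frozen=True)
class ActivationKernel:
    """Triangular activation intensity around the transcription factory.

    Intensity peaks at delta = tf_offset (the factory position inside the
    ICD, measured from the CT/ICD border) and reaches zero at
    tf_offset ± width; genes with delta < 0 are still sequestered in the CT
    and silent.
    """

    tf_offset: float = DEFAULTS["tf_offset"]
    width: float = DEFAULTS["width"]
    peak_intensity: float = DEFAULTS["peak_intensity"]
    inverted: bool = field(default=False, compare=False)  # diagnostic misuse knob

    def __post_init__(self) -> None:
        if self.tf_offset < 0 or self.width <= 0 or self.peak_intensity <= 0:
            raise HoxValidationError("kernel needs tf_offset >= 0, width > 0, I0 > 0")

    def intensity(self, delta: float | np.ndarray) -> np.ndarray | float:
        d = np.asarray(delta, dtype=float)
        if self.inverted:  # deliberately broken kernel for report diagnostics
            out = np.where(d < 0, 0.0, self.peak_intensity * np.minimum(d / self.width, 1.0))
        else:
            out = np.where(
                d < 0,
                0.0,
                self.peak_intensity
                * np.maximum(0.0, 1.0 - np.abs(d - self.tf_offset) / self.width),
            )
        return out if out.ndim else float(out)


@dataclass(frozen=True)
class ExtrusionState:
    """Snapshot of the cluster under force F: extruded length and per-gene state."""

    force: float
    extruded_length: float
    gene_positions: dict[int, float]   # L_g, anterior end -> gene
    deltas: dict[int, float]           # E - L_g
    intensities: dict[int, float]


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------

def morphogen_at(field: MorphogenField, x: float | np.ndarray) -> float | np.ndarray:
    """M(x) = M0·exp(-(axis_length - x)/lambda); strictly increasing in x."""
    x_arr = np.asarray(x, dtype=float)
    if np.any(x_arr < 0) or np.any(x_arr > field.axis_length):
        raise HoxValidationError(
            f"position outside the axis [0, {field.axis_length}]"
        )
    m = field.peak_value * np.exp(-(field.axis_length - x_arr) / field.decay_lambda)
    return m if m.ndim else float(m)


def expression_domain(
    field: MorphogenField, schedule: ThresholdSchedule, k: int
) -> tuple[float, float] | None:
    """Domain S_k = {x : M(x) >= T_k}, or None when T_k exceeds the peak.

    Domains are nested (S1 ⊇ S2 ⊇ ...) and all share the posterior end.
    """
    if not 1 <= k <= len(schedule.thresholds):
        raise HoxValidationError(f"gene rank {k} out of range")
    T = schedule.thresholds[k - 1]
    if T > field.peak_value:
        return None
    boundary = field.axis_length - field.decay_lambda * math.log(field.peak_value / T)
    return (max(0.0, boundary), field.axis_length)


def pull_force(
    charges: ChargeModel,
    field: MorphogenField,
    x: float | np.ndarray,
    t: float | np.ndarray,
) -> float | np.ndarray:
    """F = P·N with P(x,t) = alpha·M(x)·t (linear accumulation of P-molecules)."""
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0):
        raise HoxValidationError("time must be nonnegative")
    f = charges.alpha * np.asarray(morphogen_at(field, x)) * t_arr * charges.N
    return f if f.ndim else float(f)


def extrusion_length(
    F: float,
    profile: ElasticityProfile,
    fixed_end_intact: bool = True,
    loose_end_gain: float | None = None,
) -> float:
    """Extruded fiber length E under force F on a stepwise stiffness profile.

    E is the largest e with ∫0^e s(u)du <= F_eff.  When the 5' anchor is
    removed the spring is loose at both ends and decondenses with abnormally
    smaller forces: the effective force becomes F/rho with 0 < rho < 1.
    """
    if F < 0:
        raise HoxValidationError("force must be nonnegative")
    if fixed_end_intact:
        F_eff = F
    else:
        rho = loose_end_gain
        if rho is None or not (0.0 < rho < 1.0):
            raise HoxValidationError(
                "removing the fixed end requires a loose-end gain rho in (0, 1)"
            )
        F_eff = F / rho
    return float(profile.extrusion(F_eff))


def activation_intensity(
    state: ExtrusionState, kernel: ActivationKernel, gene_number: int
) -> float:
    """Activation intensity of one gene given its extrusion offset delta."""
    if gene_number not in state.deltas:
        raise HoxValidationError(f"gene {gene_number} not in extrusion state")
    return float(kernel.intensity(state.deltas[gene_number]))


def simulate_expression(
    cluster: HoxCluster,
    field: MorphogenField,
    schedule: ThresholdSchedule | None,
    charges: ChargeModel,
    profile: ElasticityProfile,
    kernel: ActivationKernel,
    x: float,
    t: float,
    rho: float = DEFAULTS["rho"],
) -> ExtrusionState:
    """Compose pull_force -> extrusion_length -> activation at one (x, t).

    The threshold schedule is accepted for interface parity with the
    macroscopic picture but the force pathway generates the expression
    pattern itself.  At t = 0 no P-molecules have been apposed: the cluster
    sits in its ground state and every gene is silent.
    """
    del schedule  # macroscopic description only; see expression_domain
    F = float(pull_force(charges, field, x, t))
    if F == 0.0:
        E = 0.0
    else:
        E = extrusion_length(
            F,
            profile,
            fixed_end_intact=cluster.fixed_posterior_end,
            loose_end_gain=None if cluster.fixed_posterior_end else rho,
        )
    positions = {g.number: cluster.gene_position_kbp(g.number) for g in cluster.genes}
    deltas = {n: E - L for n, L in positions.items()}
    if F == 0.0:  # ground state: nothing extruded, nothing active
        intensities = {n: 0.0 for n in positions}
    else:
        intensities = {n: float(kernel.intensity(d)) for n, d in deltas.items()}
    return ExtrusionState(
        force=F,
        extruded_length=E,
        gene_positions=positions,
        deltas=deltas,
        intensities=intensities,
    )


# ---------------------------------------------------------------------------
# Collinearity regression surface
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CollinearityReport:
    """Pass/fail verdicts for the three collinearities, with witnesses."""

    spatial: bool
    temporal: bool
    quantitative: bool
    witnesses: dict

    @property
    def all_pass(self) -> bool:
        return self.spatial and self.temporal and self.quantitative


def _intensity_grid(
    cluster: HoxCluster,
    field: MorphogenField,
    charges: ChargeModel,
    profile: ElasticityProfile,
    kernel: ActivationKernel,
    x_grid: np.ndarray,
    t_grid: np.ndarray,
    rho: float,
) -> tuple[np.ndarray, np.ndarray]:
    """(intensity[g, x, t], E[x, t]) over the grid, vectorized."""
    M = np.asarray(morphogen_at(field, x_grid))
    F = charges.alpha * charges.N * np.outer(M, t_grid)  # (x, t)
    F_eff = F if cluster.fixed_posterior_end else F / rho
    E = np.asarray(profile.extrusion(F_eff))
    L = np.array([cluster.gene_position_kbp(g.number) for g in cluster.genes])
    delta = E[None, :, :] - L[:, None, None]
    inten = np.asarray(kernel.intensity(delta))
    inten[:, F == 0.0] = 0.0  # ground state
    return inten, E


def collinearity_report(
    cluster: HoxCluster,
    field: MorphogenField,
    charges: ChargeModel,
    profile: ElasticityProfile,
    kernel: ActivationKernel,
    x_grid: np.ndarray | None = None,
    t_grid: np.ndarray | None = None,
    schedule: ThresholdSchedule | None = None,
    rho: float = DEFAULTS["rho"],
) -> CollinearityReport:
    """Check spatial, temporal and quantitative collinearity on a grid.

    (i) spatial: a gene's expression domain is taken cumulatively (expression
    persists once triggered); its anterior boundary must move posteriorly
    with gene rank, and any gene never expressed must lie posterior (in
    rank) to every expressed gene.
    (ii) temporal: at the posterior end of the axis, first-activation times
    are nondecreasing in rank, again with never-activated genes forming a
    posterior suffix.
    (iii) quantitative: at every instant and position where several genes are
    simultaneously active, the most posterior active gene has the highest
    intensity.
    Witness coordinates are recorded for every failure.
    """
    del schedule
    if x_grid is None:
        x_grid = np.linspace(0.0, field.axis_length, 101)
    if t_grid is None:
        t_grid = np.linspace(0.0, DEFAULTS["t_max"], 201)
    x_grid = np.asarray(x_grid, dtype=float)
    t_grid = np.asarray(t_grid, dtype=float)
    if x_grid.size < 2 or t_grid.size < 2:
        raise HoxValidationError("degenerate grid: need >= 2 points per axis")

    inten, _ = _intensity_grid(
        cluster, field, charges, profile, kernel, x_grid, t_grid, rho
    )
    active = inten > 0.0
    n_genes = len(cluster.genes)
    witnesses: dict = {}

    # (i) spatial ordering of cumulative expression domains
    spatial = True
    ever = active.any(axis=2)  # gene expressed at x at some t <= t_max
    boundaries: list[float | None] = [
        float(x_grid[row.argmax()]) if row.any() else None for row in ever
    ]
    seen_gap = False
    prev = -np.inf
    for g, b in enumerate(boundaries):
        if b is None:
            seen_gap = True
            continue
        if seen_gap or b < prev:
            spatial = False
            witnesses["spatial"] = {
                "gene": cluster.genes[g].label,
                "anterior_boundary_x": b,
                "previous_boundary_x": None if prev == -np.inf else prev,
            }
            break
        prev = b
    witnesses.setdefault("spatial_boundaries", boundaries)

    # (ii) temporal ordering at the posterior end
    temporal = True
    at_post = active[:, -1, :]
    first_t: list[float | None] = [
        float(t_grid[row.argmax()]) if row.any() else None for row in at_post
    ]
    seen_gap = False
    prev = -np.inf
    for g, ft in enumerate(first_t):
        if ft is None:
            seen_gap = True
            continue
        if seen_gap or ft < prev:
            temporal = False
            witnesses["temporal"] = {
                "gene": cluster.genes[g].label,
                "first_activation_t": ft,
                "previous_first_t": None if prev == -np.inf else prev,
            }
            break
        prev = ft
    witnesses.setdefault("first_activation_times", first_t)

    # (iii) quantitative: most posterior active gene is strongest
    quantitative = True
    counts = active.sum(axis=0)
    # rank index of the most posterior active gene at each (x, t)
    rank = np.arange(n_genes)[:, None, None]
    last_active = np.where(active, rank, -1).max(axis=0)
    max_int = inten.max(axis=0)
    last_int = np.take_along_axis(
        inten, np.maximum(last_active, 0)[None, :, :], axis=0
    )[0]
    bad = (counts >= 2) & (last_int < max_int - 1e-12)
    if bad.any():
        quantitative = False
        xi, ti = np.argwhere(bad)[0]
        witnesses["quantitative"] = {
            "x": float(x_grid[xi]),
            "t": float(t_grid[ti]),
            "posterior_active_gene": cluster.genes[int(last_active[xi, ti])].label,
            "posterior_intensity": float(last_int[xi, ti]),
            "max_intensity": float(max_int[xi, ti]),
        }

    if n_genes == 1:  # vacuously collinear
        spatial = temporal = quantitative = True
    return CollinearityReport(
        spatial=spatial,
        temporal=temporal,
        quantitative=quantitative,
        witnesses=witnesses,
    )
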