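"""Validation experiments and procedure-quality scoring.

The mechanical validations are the two classic middle-ear checks: the
frequency response of the stapes under an acoustic pressure on the tympanic
membrane (a virtual audiometry), and a high static pressure on the membrane
in nominal and pathological (fixed-footplate) configurations.

The procedure score aggregates four criteria into one number:

    E = alpha/S + beta/F + gamma/VF + delta * TF_after/TF_before

with S the distance to the expert target (smaller is better), F a functional
of the force applied to the anatomy, F = max_t |mu df/dt + lambda int f dt|,
VF the visual-obstruction time, and the TF ratio the frequency-averaged
stapes response ratio after/before the intervention.  Higher E is better;
the weights and the normalizing reference values are configuration choices.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.integrate import cumulative_trapezoid

from . import fem
from .geometry import Scene, TriShell

logger = logging.getLogger(__name__)

__all__ = ["TFResult", "ScoreWeights", "ForceTrace", "transfer_function",
           "static_pressure_test", "force_functional", "quality_score",
           "visual_obstruction_time"]


@dataclass
class TFResult:
    """Stapes frequency response to tympanic-membrane pressure."""

    frequencies: np.ndarray    # Hz
    magnitude: np.ndarray      # m (response at the driven amplitude)
    phase: np.ndarray          # rad
    pressure: float            # Pa, driving amplitude

    def __post_init__(self) -> None:
        self.frequencies = np.asarray(self.frequencies, float)
        self.magnitude = np.asarray(self.magnitude, float)
        self.phase = np.asarray(self.phase, float)
        if len(self.frequencies) != len(self.magnitude):
            raise ValueError("frequency/magnitude length mismatch")
        if np.any(self.magnitude < 0):
            raise ValueError("magnitudes must be nonnegative")

    @property
    def magnitude_per_pa(self) -> np.ndarray:
        """Response per unit pressure (m/Pa); requires nonzero drive."""
        return self.magnitude / self.pressure


@dataclass
class ScoreWeights:
    """Constants of the quality score and the force functional."""

    alpha: float = 1.0
    beta: float = 1.0
    gamma: float = 1.0
    delta: float = 1.0
    mu: float = 1.0
    lam: float = 1.0

    def __post_init__(self) -> None:
        for name in ("alpha", "beta", "gamma", "delta", "mu", "lam"):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"weight {name} must be finite")


@dataclass
class ForceTrace:
    """Force magnitude on a named structure over time."""

    times: np.ndarray      # s, strictly increasing
    values: np.ndarray     # N
    structure: str = ""

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, float)
        self.values = np.asarray(self.values, float)
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")


def _membrane_pressure_force(scene: Scene, sys: fem.SystemMatrices,
                             pressure: float) -> np.ndarray:
    """Consistent nodal load of a uniform pressure on the tympanic membrane
    (each triangle spreads p * area over its three nodes, along its normal)."""
    body = scene.bodies["membrane"]
    mesh = body.mesh
    if not isinstance(mesh, TriShell):
        raise ValueError("membrane body must be a triangle shell")
    f = np.zeros(sys.ndof)
    off = sys.node_offsets["membrane"]
    a, b, c = (mesh.nodes[mesh.triangles[:, i]] for i in range(3))
    area_vec = 0.5 * np.cross(b - a, c - a)       # oriented normals
    for tri, av in zip(mesh.triangles, area_vec):
        load = pressure * av / 3.0
        for v in tri:
            f[3 * (off + v):3 * (off + v) + 3] += load
    return f


def transfer_function(scene: Scene, freqs: np.ndarray,
                      pressure: float = 1.0) -> TFResult:
    """Steady-state harmonic stapes response per frequency.

    Solves (K + i w C - w^2 M) u = f with f the membrane pressure load, and
    reads the displacement at the stapes output node on the footplate.
    Linear in the pressure amplitude.
    """
    freqs = np.asarray(freqs, float)
    sys = fem.assemble_system(scene)
    f = _membrane_pressure_force(scene, sys, pressure)
    free = sys.free
    Kf = sys.K[np.ix_(free, free)]
    Cf = sys.C[np.ix_(free, free)]
    Mf = sys.M[free]
    u = fem.harmonic_response(Mf, Kf, Cf, f[free], 2 * np.pi * freqs)
    out_dofs_full = sys.dof_indices(*scene.named_nodes["stapes_output"])
    full_to_free = -np.ones(sys.ndof, int)
    full_to_free[free] = np.arange(free.sum())
    od = full_to_free[out_dofs_full]
    if np.any(od < 0):
        raise ValueError("stapes output node is fixed")
    resp = u[:, od]
    magnitude = np.linalg.norm(np.abs(resp), axis=1)
    phase = np.angle(resp[:, 2])       # lateral-medial (piston) component
    return TFResult(freqs, magnitude, phase, pressure)


def static_pressure_test(scene: Scene, pressure: float):
    """Static response to a (possibly high) pressure on the membrane.

    Pathological variants (e.g. otosclerotic footplate fixation) are built by
    configuration switches such as springs.annular_fixation_factor before
    calling.  Returns (displacement field, per-body peak displacement in m).
    """
    if not np.isfinite(pressure):
        raise ValueError("pressure must be finite")
    sys = fem.assemble_system(scene)
    f = _membrane_pressure_force(scene, sys, pressure)
    u = fem.static_solve(sys, f)
    disp = u.reshape(-1, 3)
    peaks = {}
    for name in scene.bodies:
        off = sys.node_offsets[name]
        cnt = sys.node_counts[name]
        peaks[name] = float(np.linalg.norm(disp[off:off + cnt], axis=1).max())
    return u, peaks


def force_functional(trace: ForceTrace, mu: float = 1.0,
                     lam: float = 1.0):
    """Force functional F(t) = mu df/dt + lambda int_0^t f dtau and its
    scalar reduction F = max_t |F(t)|.

    The derivative uses central differences, the integral the trapezoid
    rule.  Returns (F scalar, F(t) array).
    """
    if trace.times.size < 2:
        raise ValueError("force functional needs at least 2 samples")
    dfdt = np.gradient(trace.values, trace.times)
    integ = cumulative_trapezoid(trace.values, trace.times, initial=0.0)
    Ft = mu * dfdt + lam * integ
    return float(np.max(np.abs(Ft))), Ft


def quality_score(S: float, F: float, VF: float, tf_before: TFResult,
                  tf_after: TFResult, weights: ScoreWeights | None = None
                  ) -> float:
    """Procedure quality E = alpha/S + beta/F + gamma/VF + delta * ratio.

    The transfer-function ratio is the mean magnitude ratio over the shared
    frequency grid.  A zero S, F or VF leaves its term undefined; it is
    omitted with a logged note.
    """
    w = weights or ScoreWeights()
    if not np.array_equal(tf_before.frequencies, tf_after.frequencies):
        raise ValueError("transfer functions must share a frequency grid")
    ratio = float(np.mean(tf_after.magnitude_per_pa
                          / tf_before.magnitude_per_pa))
    E = w.delta * ratio
    for name, weight, val in (("S", w.alpha, S), ("F", w.beta, F),
                              ("VF", w.gamma, VF)):
        if val == 0:
            logger.info("quality_score: %s = 0, reciprocal term omitted", name)
            continue
        E += weight / val
    return float(E)


def visual_obstruction_time(times: np.ndarray, tool_positions,
                            target: np.ndarray,
                            speculum_diameter: float,
                            speculum_depth: float = 6e-3,
                            view_axis=(0.0, 0.0, -1.0)) -> float:
    """Total simulated time during which any tool point lies inside the
    viewing cone from the target through the speculum aperture.

    The cone apex sits at the target, opens along the microscope view axis
    (lateral, out of the ear), and passes through the speculum rim:
    half-angle = atan((speculum radius) / (speculum depth)).
    """
    times = np.asarray(times, float)
    axis = np.asarray(view_axis, float)
    axis = axis / np.linalg.norm(axis)
    tan_half = (speculum_diameter / 2.0) / speculum_depth
    if isinstance(tool_positions, dict):
        stacks = list(tool_positions.values())
    else:
        stacks = [tool_positions]
    inside_any = np.zeros(len(times), bool)
    for pos in stacks:
        rel = np.atleast_2d(pos) - np.asarray(target, float)
        s = rel @ axis
        lat = np.linalg.norm(rel - np.outer(s, axis), axis=1)
        inside_any |= (s > 0) & (lat < s * tan_half)
    if len(times) < 2:
        return 0.0
    dt = np.diff(times)
    # a sample obstructing counts its following interval
    return float(np.sum(dt[inside_any[:-1]]))
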