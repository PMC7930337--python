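"""2D cross-section body: rigid rods joined by damped-spring elements.

The ~1 mm body is divided into ``n_seg`` variable-width segments, each
bounded by two rigid rods. Rod endpoints connect to their neighbors via
damped-spring *lateral* elements (cuticle stretch resistance) and to the
opposite endpoints of adjacent rods via damped-spring *diagonal*
elements (internal-pressure compression resistance). Each rod carries
two translational and one rotational degree of freedom, 3*(n_seg+1) in
total. Locomotion happens at low Reynolds number, so inertia is dropped
and the medium exerts linear drag F = -C v with strongly anisotropic
tangential/normal coefficients (agar).
"""
from __future__ import annotations

import dataclasses
import warnings

import numpy as np

from . import _kernels
from .config import BodyConstants, load_body_constants


class BodyIntegrationError(RuntimeError):
    """Raised when the implicit body solve fails or an element degenerates."""


def dof_count(n_seg: int) -> int:
    """Degrees of freedom of an n_seg-segment body: 3*(n_seg+1)."""
    if n_seg < 1:
        raise ValueError("n_seg must be >= 1")
    return 3 * (n_seg + 1)


@dataclasses.dataclass
class BodyGeometry:
    """Element topology, rest lengths and material constants of the body.

    Elements are ordered per segment: lateral dorsal, lateral ventral,
    diagonal dorsal->ventral, diagonal ventral->dorsal.
    """

    constants: BodyConstants
    half_width: np.ndarray          # (n_rod,)
    elem_rod: np.ndarray            # (n_el,) anterior rod index
    elem_side_a: np.ndarray         # (n_el,) +1 dorsal / -1 ventral at rod a
    elem_side_b: np.ndarray
    elem_k: np.ndarray
    elem_c: np.ndarray
    elem_rest: np.ndarray
    elem_kind: np.ndarray           # 0 latD, 1 latV, 2 diag d->v, 3 diag v->d

    @property
    def n_seg(self) -> int:
        return self.constants.n_seg

    @property
    def n_rod(self) -> int:
        return self.constants.n_seg + 1

    @property
    def seg_length(self) -> float:
        return self.constants.body_length / self.constants.n_seg

    @classmethod
    def from_constants(cls, constants: BodyConstants | None = None) -> "BodyGeometry":
        c = constants or load_body_constants()
        n_seg = c.n_seg
        n_rod = n_seg + 1
        i = np.arange(n_rod)
        t = (i - n_seg / 2.0) / c.half_width_taper
        half_width = c.half_width_max * np.sqrt(np.clip(1.0 - t * t, 0.0, None))
        ell0 = c.body_length / n_seg

        n_el = 4 * n_seg
        elem_rod = np.repeat(np.arange(n_seg), 4).astype(np.int64)
        elem_kind = np.tile(np.arange(4), n_seg).astype(np.int64)
        side_a = np.where((elem_kind == 0) | (elem_kind == 2), 1.0, -1.0)
        side_b = np.where((elem_kind == 0) | (elem_kind == 3), 1.0, -1.0)
        is_lateral = elem_kind < 2
        elem_k = np.where(is_lateral, c.k_lateral, c.k_diagonal)
        elem_c = np.where(is_lateral, c.c_lateral, c.c_diagonal)
        wa = half_width[elem_rod]
        wb = half_width[elem_rod + 1]
        dy = side_b * wb - side_a * wa
        elem_rest = np.hypot(ell0, dy)
        assert elem_rest.shape == (n_el,)
        return cls(
            constants=c,
            half_width=half_width,
            elem_rod=elem_rod,
            elem_side_a=side_a,
            elem_side_b=side_b,
            elem_k=elem_k,
            elem_c=elem_c,
            elem_rest=elem_rest,
            elem_kind=elem_kind,
        )


@dataclasses.dataclass
class BodyState:
    """Rod centers (x, y), orientations phi and their time derivatives.

    phi is the angle of the rod's dorsal unit vector; in the straight
    rest posture the midline lies along +x (head at the origin, tail at
    +L) with all rods at phi = pi/2 (dorsal side toward +y).
    """

    x: np.ndarray
    y: np.ndarray
    phi: np.ndarray
    vx: np.ndarray
    vy: np.ndarray
    vphi: np.ndarray

    @classmethod
    def straight(cls, geometry: BodyGeometry) -> "BodyState":
        n_rod = geometry.n_rod
        return cls(
            x=np.arange(n_rod) * geometry.seg_length,
            y=np.zeros(n_rod),
            phi=np.full(n_rod, np.pi / 2),
            vx=np.zeros(n_rod),
            vy=np.zeros(n_rod),
            vphi=np.zeros(n_rod),
        )

    def copy(self) -> "BodyState":
        return BodyState(*(np.array(getattr(self, f.name)) for f in dataclasses.fields(self)))

    @property
    def midline(self) -> np.ndarray:
        """(n_rod, 2) rod-center coordinates."""
        return np.column_stack([self.x, self.y])

    @property
    def com(self) -> np.ndarray:
        return np.array([self.x.mean(), self.y.mean()])


@dataclasses.dataclass(frozen=True)
class EnvironmentDrag:
    """Linear agar drag coefficients per rod (tangential, normal)."""

    c_par: float = 3.2e-3
    c_perp: float = 128e-3

    def __post_init__(self):
        if self.c_par <= 0 or self.c_perp <= 0:
            raise ValueError("drag coefficients must be positive")


def midline_tangents(state: BodyState) -> np.ndarray:
    """Unit midline tangent at each rod (central differences, one-sided ends)."""
    tx = np.zeros_like(state.x)
    ty = np.zeros_like(state.y)
    _kernels._midline_tangents(state.x, state.y, tx, ty)
    return np.column_stack([tx, ty])


def drag_forces(state: BodyState, drag: EnvironmentDrag | None = None) -> np.ndarray:
    """Per-rod drag force -C_par v_t - C_perp v_n in the rod's local frame.

    The tangential direction is the body-midline tangent at the rod. Only
    the rod-center translational component is reported here; the
    integrator additionally applies the endpoint-split version, which
    adds rotational damping.
    """
    drag = drag or EnvironmentDrag()
    t = midline_tangents(state)
    v = np.column_stack([state.vx, state.vy])
    vt = np.sum(v * t, axis=1)
    n = np.column_stack([-t[:, 1], t[:, 0]])
    vn = np.sum(v * n, axis=1)
    return -(drag.c_par * vt[:, None] * t + drag.c_perp * vn[:, None] * n)


def _muscle_zeros(geometry: BodyGeometry) -> np.ndarray:
    return np.zeros(geometry.n_seg)


def internal_forces(
    state: BodyState,
    geometry: BodyGeometry,
    act_dorsal: np.ndarray | None = None,
    act_ventral: np.ndarray | None = None,
) -> np.ndarray:
    """Generalized (fx, fy, torque) per rod from all elements and muscles.

    Damped-spring element force along the element: f = -k (l - l0) - c dl/dt,
    resolved to the rod centers; muscle tensions (if activations given)
    contract lateral elements with Hill force-length/velocity scaling.
    """
    c = geometry.constants
    fgen = np.zeros((geometry.n_rod, 3))
    status = _kernels.element_forces(
        state.x, state.y, state.phi, state.vx, state.vy, state.vphi,
        geometry.half_width,
        geometry.elem_rod, geometry.elem_side_a, geometry.elem_side_b,
        geometry.elem_k, geometry.elem_c, geometry.elem_rest, geometry.elem_kind,
        act_dorsal if act_dorsal is not None else _muscle_zeros(geometry),
        act_ventral if act_ventral is not None else _muscle_zeros(geometry),
        c.f_max, c.fl_width, c.fv_vmax, c.fv_curvature,
        fgen,
    )
    if status == 2:
        raise BodyIntegrationError("degenerate element (zero length)")
    return fgen


def body_step(
    state: BodyState,
    geometry: BodyGeometry,
    act_dorsal: np.ndarray | None = None,
    act_ventral: np.ndarray | None = None,
    drag: EnvironmentDrag | None = None,
    dt: float = 1e-4,
    n_sub: int = 1,
) -> BodyState:
    """Advance the overdamped body by ``n_sub`` semi-implicit steps of dt.

    Muscle activations are held constant across the substeps. Returns a
    new state; raises :class:`BodyIntegrationError` on solver failure.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    drag = drag or EnvironmentDrag()
    c = geometry.constants
    new = state.copy()
    status = _kernels.body_substeps(
        new.x, new.y, new.phi, new.vx, new.vy, new.vphi,
        geometry.half_width,
        geometry.elem_rod, geometry.elem_side_a, geometry.elem_side_b,
        geometry.elem_k, geometry.elem_c, geometry.elem_rest, geometry.elem_kind,
        act_dorsal if act_dorsal is not None else _muscle_zeros(geometry),
        act_ventral if act_ventral is not None else _muscle_zeros(geometry),
        c.f_max, c.fl_width, c.fv_vmax, c.fv_curvature,
        drag.c_par, drag.c_perp, dt, n_sub,
    )
    if status == 1:
        raise BodyIntegrationError("implicit body solve failed (singular system)")
    if status == 2:
        raise BodyIntegrationError("degenerate element (zero length)")
    return new


def check_self_intersection(midline: np.ndarray, half_width: np.ndarray) -> bool:
    """Warn (and return True) if non-adjacent midline points overlap.

    Self-intersection is not penalized by the model; extreme genotypes
    may self-cross, which this cheap overlap check merely reports.
    """
    pts = np.asarray(midline)
    n = len(pts)
    d2 = np.sum((pts[:, None, :] - pts[None, :, :]) ** 2, axis=-1)
    ii, jj = np.triu_indices(n, k=5)
    wsum = half_width[ii] + half_width[jj]
    crossed = d2[ii, jj] < wsum**2
    if np.any(crossed):
        warnings.warn("body midline self-intersection detected", RuntimeWarning, stacklevel=2)
        return True
    return False
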