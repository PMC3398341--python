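"""Adaptation of a population-to-reference deformation field into a
population-to-test field from six channel edge shifts.

Each node's longitudinal (y) displacement is rescaled by a proximity-
weighted blend of the superior and inferior channel ratios
``(Delta_NC + shift_NC) / Delta_NC``; its lateral (x) displacement by a
linear blend of the two same-row channels in the upper and lower regions
and a bilinear blend of all four lateral channels in the middle region.
Anterior-posterior (z) displacements pass through unchanged: no lateral
film exists to constrain them.

Two conventions are fixed here (the printed formulations are internally
inconsistent about both):

* a channel's weight is one minus its normalized distance to the node, so
  the nearer channel always dominates;
* which of NC5/NC6 is the superior channel is configuration
  (``superior_role``), defaulting to NC5.

When a channel's predicted displacement ``Delta_NC`` is below ``eps`` the
multiplicative ratio is replaced by an additive correction (the node
displacement gains the weighted shift directly) -- the unique finite limit
that preserves the zero-shift identity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ConfigurationError, GeometryError, ParameterError
from .geometry_core import DeformationField, SurfaceMesh, apply_field
from .navigator import CHANNEL_ROLES

__all__ = [
    "ChannelState",
    "NodeWeights",
    "RegionPartition",
    "compute_node_weights",
    "adapt_longitudinal",
    "adapt_lateral",
    "partition_regions",
    "adapt_field",
    "reconstruct",
]

#: lateral channel placement: (x side, row) per role
LATERAL_LAYOUT = {
    "NC1": ("right", "lower"),
    "NC2": ("left", "lower"),
    "NC3": ("right", "upper"),
    "NC4": ("left", "upper"),
}

DEFAULT_EPS = 1e-6


@dataclass(frozen=True)
class ChannelState:
    """Per-channel (predicted displacement, detected shift) pair, cm."""

    role: str
    delta: float  # population -> reference displacement at the channel
    shift: float  # reference -> test edge shift

    def __post_init__(self):
        if self.role not in CHANNEL_ROLES:
            raise ParameterError(f"unknown channel role {self.role!r}")
        if not (np.isfinite(self.delta) and np.isfinite(self.shift)):
            raise ParameterError(f"{self.role}: delta/shift must be finite")


@dataclass(frozen=True)
class NodeWeights:
    """Normalized node position in the heart bbox; clamped to [0, 1].

    ``k_x``: 0 = right-most edge (smallest x), 1 = left-most.
    ``k_y``: 0 = most superior (smallest y), 1 = most inferior.
    """

    k_x: float
    k_y: float


@dataclass
class RegionPartition:
    upper_boundary_y: float  # NC3/NC4 row center
    lower_boundary_y: float  # NC1/NC2 row center
    labels: np.ndarray  # per-node 'upper' | 'middle' | 'lower'


def _correction(delta_node, ch: ChannelState, eps: float):
    """Channel contribution before weighting: ``delta_node * shift / Delta_NC``,
    or the bare shift when the denominator degenerates."""
    if abs(ch.delta) < eps:
        return ch.shift
    return delta_node * ch.shift / ch.delta


def compute_node_weights(vertex, heart_bbox) -> NodeWeights:
    """``heart_bbox`` is (x_min, x_max, y_min, y_max) of the reference-deformed
    model projected into the radiograph plane."""
    x_min, x_max, y_min, y_max = heart_bbox
    if not (x_max > x_min and y_max > y_min):
        raise GeometryError(f"degenerate heart bbox {heart_bbox}")
    v = np.asarray(vertex, dtype=float)
    k_x = float(np.clip((v[0] - x_min) / (x_max - x_min), 0.0, 1.0))
    k_y = float(np.clip((v[1] - y_min) / (y_max - y_min), 0.0, 1.0))
    return NodeWeights(k_x=k_x, k_y=k_y)


def adapt_longitudinal(
    delta_y: float,
    w: NodeWeights,
    ch_superior: ChannelState,
    ch_inferior: ChannelState,
    eps: float = DEFAULT_EPS,
) -> float:
    """Test-specific y-displacement from the superior/inferior channel pair.

    The superior channel is weighted ``1 - k_y`` and the inferior ``k_y``
    (nearer channel dominates; weights sum to 1).
    """
    w_sup = 1.0 - w.k_y
    w_inf = w.k_y
    return delta_y + w_sup * _correction(delta_y, ch_superior, eps) \
        + w_inf * _correction(delta_y, ch_inferior, eps)


def adapt_lateral(
    delta_x: float,
    w: NodeWeights,
    region: str,
    channels: dict,
    k_y_lateral: float | None = None,
    eps: float = DEFAULT_EPS,
) -> float:
    """Test-specific x-displacement.

    ``channels`` maps NC1..NC4 roles to :class:`ChannelState`.  For the
    middle region ``k_y_lateral`` is the node's normalized position between
    the upper and lower channel rows (0 at the NC3/NC4 row, 1 at the
    NC1/NC2 row); it defaults to ``w.k_y``.  Right-side channels are
    weighted ``1 - k_x`` and left-side ``k_x``, so the bilinear quadruple
    sums to 1.
    """
    if region not in ("upper", "middle", "lower"):
        raise ConfigurationError(f"unknown region {region!r}")
    wx = {"right": 1.0 - w.k_x, "left": w.k_x}
    if region == "upper":
        pair = ("NC3", "NC4")
        return delta_x + sum(
            wx[LATERAL_LAYOUT[r][0]] * _correction(delta_x, channels[r], eps)
            for r in pair
        )
    if region == "lower":
        pair = ("NC1", "NC2")
        return delta_x + sum(
            wx[LATERAL_LAYOUT[r][0]] * _correction(delta_x, channels[r], eps)
            for r in pair
        )
    kyl = w.k_y if k_y_lateral is None else float(np.clip(k_y_lateral, 0.0, 1.0))
    wy = {"upper": 1.0 - kyl, "lower": kyl}
    out = delta_x
    for role in ("NC1", "NC2", "NC3", "NC4"):
        side, row = LATERAL_LAYOUT[role]
        out += wx[side] * wy[row] * _correction(delta_x, channels[role], eps)
    return out


def partition_regions(mesh: SurfaceMesh, channels) -> RegionPartition:
    """Label nodes upper/middle/lower by the two lateral channel row centers."""
    by_role = {c.role: c for c in channels}
    for role in ("NC1", "NC2", "NC3", "NC4"):
        if role not in by_role:
            raise ConfigurationError(f"missing lateral channel {role}")
    upper_y = (by_role["NC3"].center[1] + by_role["NC4"].center[1]) / 2.0
    lower_y = (by_role["NC1"].center[1] + by_role["NC2"].center[1]) / 2.0
    if not upper_y < lower_y:
        raise ConfigurationError(
            f"NC3/NC4 row (y={upper_y:.2f}) must lie superior to NC1/NC2 row "
            f"(y={lower_y:.2f})"
        )
    y = mesh.vertices[:, 1]
    labels = np.where(y < upper_y, "upper", np.where(y > lower_y, "lower", "middle"))
    return RegionPartition(upper_boundary_y=upper_y, lower_boundary_y=lower_y,
                           labels=labels)


def _states_by_role(channel_states):
    if isinstance(channel_states, dict):
        by_role = dict(channel_states)
    else:
        by_role = {c.role: c for c in channel_states}
    missing = [r for r in CHANNEL_ROLES if r not in by_role]
    if missing:
        raise ConfigurationError(f"missing channel states: {', '.join(missing)}")
    return by_role


def adapt_field(
    field: DeformationField,
    mesh: SurfaceMesh,
    channel_states,
    nc_geom,
    superior_role: str = "NC5",
    eps: float = DEFAULT_EPS,
) -> DeformationField:
    """Adapt every node of the population->reference field.

    ``mesh`` is the reference-deformed model (population plus ``field``)
    whose radiograph-plane bbox defines the node weights; ``nc_geom`` are
    the channel rectangles that define the region rows.
    """
    if len(field) != mesh.n_vertices:
        raise ConfigurationError(
            f"field length {len(field)} != mesh vertex count {mesh.n_vertices}"
        )
    states = _states_by_role(channel_states)
    if superior_role not in ("NC5", "NC6"):
        raise ConfigurationError(f"superior_role must be NC5 or NC6, not {superior_role!r}")
    inferior_role = "NC6" if superior_role == "NC5" else "NC5"
    part = partition_regions(mesh, nc_geom)

    lo, hi = mesh.bbox()
    bbox = (lo[0], hi[0], lo[1], hi[1])
    row_span = part.lower_boundary_y - part.upper_boundary_y

    disp = field.displacements
    out = disp.copy()
    for n in range(len(disp)):
        v = mesh.vertices[n]
        w = compute_node_weights(v, bbox)
        out[n, 1] = adapt_longitudinal(
            disp[n, 1], w, states[superior_role], states[inferior_role], eps
        )
        kyl = (v[1] - part.upper_boundary_y) / row_span
        out[n, 0] = adapt_lateral(
            disp[n, 0], w, str(part.labels[n]), states, k_y_lateral=kyl, eps=eps
        )
        # z untouched
    return DeformationField(out, source_mesh=field.source_mesh)


def reconstruct(population: SurfaceMesh, adapted: DeformationField) -> SurfaceMesh:
    """Apply the adapted field to the population model's nodes."""
    mesh = apply_field(population, adapted)
    return SurfaceMesh(mesh.vertices, mesh.triangles, name="reconstructed")
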