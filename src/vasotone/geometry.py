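"""Two-layer quasi-circular arterial cross-section meshes.

The reference (unloaded) cross section is an annulus split into an inner
media layer and an outer adventitia layer.  The mesh is a structured
polar-product grid of bilinear quadrilaterals: ``n_circ`` circumferential
sectors times radial layers.  Quasi-circularity is realised by perturbing
the layer interface radii with a low-order Fourier series whose amplitude
is bounded by ``eta`` times the minimum layer thickness; ``eta = 0``
(the default everywhere) gives the nominally circular section.

Regions are tagged per element (media / adventitia / calcified) and the
three boundaries are tagged per edge (intima, media-adventitia interface,
outer).  A calcified sub-region of the media, spanning a contiguous
angular sector through a configurable fraction of the media thickness,
can be tagged after construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

MEDIA = 0
ADVENTITIA = 1
CALCIFIED = 2

REGION_NAMES = {MEDIA: "media", ADVENTITIA: "adventitia", CALCIFIED: "calcified"}


class MeshError(RuntimeError):
    """Raised when mesh construction produces an invalid (inverted) element."""


@dataclass(frozen=True)
class CrossSectionGeometry:
    """Geometric description of the unloaded cross section.

    Parameters
    ----------
    R_i0 : mean unloaded internal radius (mm)
    d_IM : unloaded intima-media thickness (mm)
    d_A : unloaded adventitia thickness (mm)
    eta : quasi-circularity perturbation fraction, 0 <= eta < 1
    ell_S : segment length (mm)
    lambda_z : axial pre-stretch (-)
    """

    R_i0: float = 5.55
    d_IM: float = 0.8
    d_A: float = 0.4
    eta: float = 0.0
    ell_S: float = 300.0
    lambda_z: float = 1.3

    def __post_init__(self):
        if self.R_i0 <= 0 or self.d_IM <= 0 or self.d_A <= 0:
            raise ValueError("geometry dimensions must be positive")
        if not 0.0 <= self.eta < 1.0:
            raise ValueError("eta must satisfy 0 <= eta < 1")

    @property
    def R_m(self) -> float:
        """Media-adventitia interface radius (mm)."""
        return self.R_i0 + self.d_IM

    @property
    def R_o(self) -> float:
        """Outer radius (mm)."""
        return self.R_i0 + self.d_IM + self.d_A


@dataclass
class Mesh:
    """Structured quadrilateral mesh of the reference cross section.

    Attributes
    ----------
    nodes : (n_nodes, 2) reference coordinates (mm), vessel centre at origin
    elems : (n_el, 4) connectivity, counter-clockwise
    region : (n_el,) element region tag (MEDIA / ADVENTITIA / CALCIFIED)
    inner_edges, interface_edges, outer_edges : (n, 2) node pairs on the
        tagged boundaries, ordered counter-clockwise along each loop
    n_circ, n_rad_media, n_rad_adv : grid resolution
    geom : the generating :class:`CrossSectionGeometry`
    """

    nodes: np.ndarray
    elems: np.ndarray
    region: np.ndarray
    inner_edges: np.ndarray
    interface_edges: np.ndarray
    outer_edges: np.ndarray
    n_circ: int
    n_rad_media: int
    n_rad_adv: int
    geom: CrossSectionGeometry
    _theta: np.ndarray = field(default=None, repr=False)

    @property
    def n_nodes(self) -> int:
        return self.nodes.shape[0]

    @property
    def n_elements(self) -> int:
        return self.elems.shape[0]

    @property
    def inner_loop(self) -> np.ndarray:
        """Node indices of the inner (intima) boundary loop, CCW order."""
        return self.inner_edges[:, 0]

    @property
    def outer_loop(self) -> np.ndarray:
        return self.outer_edges[:, 0]

    def element_centroids(self, coords: np.ndarray | None = None) -> np.ndarray:
        xy = self.nodes if coords is None else coords
        return xy[self.elems].mean(axis=1)

    def element_areas(self, coords: np.ndarray | None = None) -> np.ndarray:
        """Signed quadrilateral areas by the shoelace formula."""
        xy = self.nodes if coords is None else coords
        q = xy[self.elems]  # (n_el, 4, 2)
        x, y = q[..., 0], q[..., 1]
        xn, yn = np.roll(x, -1, axis=1), np.roll(y, -1, axis=1)
        return 0.5 * np.sum(x * yn - xn * y, axis=1)

    def region_area(self, tag: int) -> float:
        return float(self.element_areas()[self.region == tag].sum())


def polygon_area(loop_xy: np.ndarray) -> float:
    """Signed shoelace area of a closed polygon given its vertices in order."""
    x, y = loop_xy[:, 0], loop_xy[:, 1]
    xn, yn = np.roll(x, -1), np.roll(y, -1)
    return 0.5 * float(np.sum(x * yn - xn * y))


def _boundary_radius(theta: np.ndarray, R: float, amplitude: float,
                     rng: np.random.Generator) -> np.ndarray:
    """Quasi-circular boundary: R plus a low-order Fourier perturbation."""
    if amplitude == 0.0:
        return np.full_like(theta, R)
    modes = (2, 3, 4)
    coeff = rng.uniform(-1.0, 1.0, size=(len(modes), 2))
    pert = np.zeros_like(theta)
    for (m, (ac, as_)) in zip(modes, coeff):
        pert += ac * np.cos(m * theta) + as_ * np.sin(m * theta)
    norm = np.abs(pert).max()
    if norm > 0:
        pert *= amplitude / norm
    return R + pert


def build_cross_section_mesh(geom: CrossSectionGeometry,
                             n_radial_media: int = 10,
                             n_radial_adventitia: int = 5,
                             n_circ: int = 96,
                             seed: int = 0) -> Mesh:
    """Build the structured annular mesh of the reference cross section.

    Radial node lines are placed at ``n_radial_media`` equal steps through
    the media and ``n_radial_adventitia`` through the adventitia, at
    ``n_circ`` equally spaced angles.  With ``geom.eta > 0`` the three
    boundary radii are perturbed by a smooth periodic function of amplitude
    ``eta * min(d_IM, d_A)`` (seeded); interior node lines interpolate
    linearly between the perturbed boundaries.
    """
    if n_radial_media < 2 or n_radial_adventitia < 2 or n_circ < 4:
        raise ValueError("insufficient mesh resolution (counts >= 2, n_circ >= 4)")

    rng = np.random.default_rng(seed)
    theta = np.linspace(0.0, 2.0 * np.pi, n_circ, endpoint=False)
    amp = geom.eta * min(geom.d_IM, geom.d_A)
    r_i = _boundary_radius(theta, geom.R_i0, amp, rng)
    r_m = _boundary_radius(theta, geom.R_m, amp, rng)
    r_o = _boundary_radius(theta, geom.R_o, amp, rng)

    n_rad = n_radial_media + n_radial_adventitia  # element layers
    radii = np.empty((n_rad + 1, n_circ))
    for k in range(n_radial_media + 1):
        s = k / n_radial_media
        radii[k] = (1 - s) * r_i + s * r_m
    for k in range(1, n_radial_adventitia + 1):
        s = k / n_radial_adventitia
        radii[n_radial_media + k] = (1 - s) * r_m + s * r_o

    nodes = np.empty(((n_rad + 1) * n_circ, 2))
    for k in range(n_rad + 1):
        nodes[k * n_circ:(k + 1) * n_circ, 0] = radii[k] * np.cos(theta)
        nodes[k * n_circ:(k + 1) * n_circ, 1] = radii[k] * np.sin(theta)

    def nid(k, j):
        return k * n_circ + (j % n_circ)

    elems = np.empty((n_rad * n_circ, 4), dtype=np.int64)
    region = np.empty(n_rad * n_circ, dtype=np.int64)
    e = 0
    for k in range(n_rad):
        for j in range(n_circ):
            # CCW: inner-j, outer-j, outer-j+1, inner-j+1
            elems[e] = (nid(k, j), nid(k + 1, j), nid(k + 1, j + 1), nid(k, j + 1))
            region[e] = MEDIA if k < n_radial_media else ADVENTITIA
            e += 1

    mesh = Mesh(
        nodes=nodes, elems=elems, region=region,
        inner_edges=np.array([[nid(0, j), nid(0, j + 1)] for j in range(n_circ)]),
        interface_edges=np.array([[nid(n_radial_media, j), nid(n_radial_media, j + 1)]
                                  for j in range(n_circ)]),
        outer_edges=np.array([[nid(n_rad, j), nid(n_rad, j + 1)] for j in range(n_circ)]),
        n_circ=n_circ, n_rad_media=n_radial_media, n_rad_adv=n_radial_adventitia,
        geom=geom, _theta=theta,
    )
    if np.any(mesh.element_areas() <= 0.0):
        raise MeshError("mesh construction produced an inverted element")
    return mesh


def tag_calcification(mesh: Mesh, angular_fraction: float = 1.0 / 3.0,
                      radial_extent: float = 1.0,
                      center_angle: float = 0.0) -> Mesh:
    """Re-tag a contiguous angular sector of the media as calcified.

    The sector is centred at ``center_angle`` and spans ``angular_fraction``
    of the full circle, through ``radial_extent`` of the media thickness
    measured from the intima outward.  Returns a new :class:`Mesh` sharing
    node/element arrays except for the region tags.
    """
    if not 0.0 <= angular_fraction <= 1.0:
        raise ValueError("angular_fraction must lie in [0, 1]")
    if not 0.0 <= radial_extent <= 1.0:
        raise ValueError("radial_extent must lie in [0, 1]")
    region = mesh.region.copy()
    if angular_fraction > 0.0:
        n_sector = int(round(angular_fraction * mesh.n_circ))
        n_layers = int(round(radial_extent * mesh.n_rad_media))
        half = np.pi * angular_fraction
        cent = mesh.element_centroids()
        ang = np.arctan2(cent[:, 1], cent[:, 0])
        dang = np.angle(np.exp(1j * (ang - center_angle)))
        # element index -> (layer k, sector j) from the structured layout
        k_of = np.arange(mesh.n_elements) // mesh.n_circ
        sel = (np.abs(dang) <= half + 1e-12) & (k_of < n_layers) & (region == MEDIA)
        # enforce exactly n_sector contiguous sectors per layer
        j_of = np.arange(mesh.n_elements) % mesh.n_circ
        for k in range(n_layers):
            in_layer = np.where(sel & (k_of == k))[0]
            if len(in_layer) > n_sector:
                # drop the elements angularly farthest from the centre
                order = np.argsort(np.abs(dang[in_layer]))
                sel[in_layer[order[n_sector:]]] = False
        region[sel] = CALCIFIED
    out = Mesh(nodes=mesh.nodes, elems=mesh.elems, region=region,
               inner_edges=mesh.inner_edges, interface_edges=mesh.interface_edges,
               outer_edges=mesh.outer_edges, n_circ=mesh.n_circ,
               n_rad_media=mesh.n_rad_media, n_rad_adv=mesh.n_rad_adv,
               geom=mesh.geom, _theta=mesh._theta)
    return out


def circumferential_directions(points: np.ndarray) -> np.ndarray:
    """Unit circumferential vectors e_theta at given reference points."""
    ang = np.arctan2(points[:, 1], points[:, 0])
    return np.stack([-np.sin(ang), np.cos(ang)], axis=-1)
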