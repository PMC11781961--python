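"""Parametric 3D geometry of a vein segment with a bicuspid valve.

The reference configuration is an idealised straight vein of luminal
diameter ``d`` whose wall bulges into a sinus pocket of axial depth ``ls``
around the valve.  Two semilunar leaflets of depth ``lv`` attach to the
inner wall along half-elliptic curves that meet at two commissures; their
free edges are parabolic and leave a small gap ``g`` at the symmetry plane
so the valve can initialise its opening.  All lengths are in cm and the
vein axis is the z axis.

The mesh is a conformal linear-tetrahedral mesh: wall, sinus and leaflets
share nodes along their junction curves.  It is built from structured hex
grids (wall: radial x angular x axial; leaflet: thickness x arc x depth)
that are split into tetrahedra with a translation-invariant Kuhn
decomposition, which guarantees matching face diagonals between neighbouring
cells.  The axial grid lines of the wall are warped column-by-column so that
one grid ring follows the leaflet attachment curve exactly; the leaflet
meshes then reuse those wall nodes.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, replace
from typing import Optional

import numpy as np

REGIONS = ("wall", "sinus", "leaflet")
REGION_ID = {name: i for i, name in enumerate(REGIONS)}


class ParameterDomainError(ValueError):
    """Surface parameter outside its domain."""


class MeshingError(ValueError):
    """Requested resolution cannot resolve the geometry."""


class InvertedElementError(ValueError):
    """One or more tetrahedra have non-positive signed volume."""

    def __init__(self, element_ids):
        self.element_ids = np.asarray(element_ids)
        super().__init__(
            f"{len(self.element_ids)} inverted element(s): "
            f"{self.element_ids[:20].tolist()}")


@dataclass(frozen=True)
class GeometryParams:
    """Dimensions of the vein/sinus/valve model (cm).

    Defaults are the bovine-saphenous-vein dimensions used throughout:
    wall length 3.2, luminal diameter 0.691, wall thickness 0.020, valve
    depth 0.500, valve thickness 0.020, sinus depth 1.000, sinus thickness
    0.015.  ``sinus_bulge_ratio`` (max sinus inner radius over lumen
    radius) and the free-edge gap ``g`` are gap-filling parameters with
    configurable defaults; ``axial_position_of_valve`` is the z coordinate
    of the free-edge plane (``None`` = centred on the tube).
    """

    l: float = 3.2
    d: float = 0.691
    tw: float = 0.020
    lv: float = 0.500
    tv: float = 0.020
    ls: float = 1.000
    ts: float = 0.015
    sinus_bulge_ratio: float = 1.4
    g: float = 0.01
    axial_position_of_valve: Optional[float] = None

    def __post_init__(self) -> None:
        for name in ("l", "d", "tw", "lv", "tv", "ls", "ts", "g"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be > 0")
        if not (self.lv < self.ls < self.l):
            raise ValueError("need valve depth lv < sinus depth ls < length l")
        if not self.g < self.d / 10.0:
            raise ValueError("free-edge gap g must be < d/10")
        if not (1.0 < self.sinus_bulge_ratio <= 2.0):
            raise ValueError("sinus_bulge_ratio must lie in (1, 2]")

    # -- derived axial landmarks ------------------------------------------
    @property
    def valve_top(self) -> float:
        """z of the free-edge plane."""
        if self.axial_position_of_valve is not None:
            return self.axial_position_of_valve
        return 0.5 * self.l + 0.5 * self.lv

    @property
    def valve_apex(self) -> float:
        """z of the deepest (distal) point of the attachment curve."""
        return self.valve_top - self.lv

    @property
    def sinus_window(self) -> tuple:
        """Axial extent (z0, z1) of the sinus bulge, centred on the valve."""
        mid = self.valve_top - 0.5 * self.lv
        return (mid - 0.5 * self.ls, mid + 0.5 * self.ls)

    def truncated(self, length: float) -> "GeometryParams":
        """Copy with the tube truncated to ``length`` (valve position kept
        centred if it was defaulted)."""
        zt = None if self.axial_position_of_valve is None else \
            self.axial_position_of_valve
        return replace(self, l=length, axial_position_of_valve=zt)


def _bump(params: GeometryParams, z):
    """Smooth sinus bulge shape in [0, 1] over the sinus window."""
    z0, z1 = params.sinus_window
    xi = (np.asarray(z, dtype=float) - z0) / (z1 - z0)
    out = np.where((xi > 0.0) & (xi < 1.0),
                   np.sin(np.pi * np.clip(xi, 0.0, 1.0)) ** 2, 0.0)
    return out


def inner_radius(params: GeometryParams, z):
    """Inner (luminal) wall radius at axial position z (cm)."""
    r0 = 0.5 * params.d
    return r0 * (1.0 + (params.sinus_bulge_ratio - 1.0) * _bump(params, z))


def wall_thickness(params: GeometryParams, z):
    """Local wall thickness, blending tw -> ts over the sinus bulge."""
    return params.tw + (params.ts - params.tw) * _bump(params, z)


def commissure_offset(params: GeometryParams) -> float:
    """Azimuthal half-offset of the commissures from the symmetry plane.

    Each leaflet (and its commissures on the wall) keeps a transverse
    clearance of g/2 from the inter-leaflet symmetry plane, so the
    commissure azimuths are pulled in by ``asin((g/2)/r)`` from +-pi/2.
    """
    rt = float(inner_radius(params, params.valve_top))
    return float(np.arcsin(0.5 * params.g / rt))


def leaflet_midsurface(params: GeometryParams, s, t, side: int = +1):
    """Point on the leaflet midsurface (cm).

    ``s`` in [0, 1] runs along the arc from one commissure to the other;
    ``t`` in [0, 1] runs from the attachment curve on the sinus wall (t=0)
    to the free edge (t=1).  ``side`` selects the leaflet (+1: x > 0 half,
    -1: mirror).  The attachment is a half-ellipse in the unrolled wall
    plane, dipping by the valve depth lv at the leaflet midline; the free
    edge is the straight coaptation chord at transverse distance g/2 from
    the symmetry plane; the belly is the parabola-like ruled blend between
    them.  Both commissures (s=0, s=1, any t) lie on the wall.
    """
    s = np.asarray(s, dtype=float)
    t = np.asarray(t, dtype=float)
    if np.any((s < 0) | (s > 1)) or np.any((t < 0) | (t > 1)):
        raise ParameterDomainError("s and t must lie in [0, 1]")
    if side not in (+1, -1):
        raise ValueError("side must be +1 or -1")
    zt = params.valve_top
    rt = inner_radius(params, zt)
    delta = commissure_offset(params)
    if side == +1:
        theta = -(0.5 * np.pi - delta) + s * (np.pi - 2.0 * delta)
    else:
        theta = (0.5 * np.pi + delta) + s * (np.pi - 2.0 * delta)
    za = zt - params.lv * np.sin(np.pi * s)
    ra = inner_radius(params, za)
    attach = np.stack([ra * np.cos(theta), ra * np.sin(theta),
                       za * np.ones_like(s)], axis=-1)
    yc = np.sqrt(rt ** 2 - (0.5 * params.g) ** 2)
    edge = np.stack([np.full_like(s, side * 0.5 * params.g),
                     -side * yc * (1.0 - 2.0 * s),
                     np.full_like(s, zt)], axis=-1)
    t = np.asarray(t)[..., None]
    return (1.0 - t) * attach + t * edge


@dataclass
class StructuralMesh:
    """Conformal tetrahedral reference mesh of wall + sinus + leaflets."""

    X: np.ndarray                 # (N, 3) reference coordinates, cm
    elements: np.ndarray          # (E, 4) int connectivity
    region: np.ndarray            # (E,) int8, index into REGIONS
    fixed_nodes: np.ndarray       # node ids of the tube end rings
    free_edges: tuple             # per-leaflet ordered free-edge node ids
    params: GeometryParams
    meta: dict

    @property
    def n_nodes(self) -> int:
        return self.X.shape[0]

    @property
    def n_elements(self) -> int:
        return self.elements.shape[0]

    def element_volumes(self, x: Optional[np.ndarray] = None) -> np.ndarray:
        """Signed tetrahedron volumes for coordinates ``x`` (default ref)."""
        pts = self.X if x is None else x
        v = pts[self.elements]
        e = v[:, 1:] - v[:, :1]
        return np.linalg.det(e) / 6.0

    def region_volume(self, name: str, x: Optional[np.ndarray] = None) -> float:
        vol = self.element_volumes(x)
        return float(vol[self.region == REGION_ID[name]].sum())

    def total_volume(self, x: Optional[np.ndarray] = None) -> float:
        return float(self.element_volumes(x).sum())

    def wall_ring(self, z: float) -> np.ndarray:
        """Node ids of the wall ring (all radial layers) nearest plane z."""
        wall_ids = self.meta["wall_ids"]           # (nr+1, ntheta, nz+1)
        zmean = self.X[wall_ids, 2].mean(axis=(0, 1))
        k = int(np.argmin(np.abs(zmean - z)))
        return wall_ids[:, :, k].ravel()


# --------------------------------------------------------------------------
# Kuhn decomposition of a hexahedron into six tetrahedra.  Corner bit order
# is (b0, b1, b2) along the three local axes; the split is the same in every
# cell, so shared faces of neighbouring cells carry matching diagonals.
_KUHN_PATHS = []
for _perm in itertools.permutations(range(3)):
    bits = [0, 0, 0]
    path = [tuple(bits)]
    for ax in _perm:
        bits[ax] = 1
        path.append(tuple(bits))
    _KUHN_PATHS.append(path)


def _hex_to_tets(corner_ids: np.ndarray) -> np.ndarray:
    """corner_ids: (..., 2, 2, 2) global node ids -> (M, 4) tets.

    Degenerate tetrahedra (repeated nodes from collapsed hex corners) are
    dropped, which turns collapsed hexes into wedges/pyramids correctly.
    """
    tets = []
    for path in _KUHN_PATHS:
        t = np.stack([corner_ids[..., b0, b1, b2] for (b0, b1, b2) in path],
                     axis=-1).reshape(-1, 4)
        tets.append(t)
    tets = np.concatenate(tets, axis=0)
    s = np.sort(tets, axis=1)
    ok = np.all(np.diff(s, axis=1) != 0, axis=1)
    return tets[ok]


def _orient_positive(tets: np.ndarray, X: np.ndarray) -> np.ndarray:
    v = X[tets]
    vol = np.linalg.det(v[:, 1:] - v[:, :1]) / 6.0
    flip = vol < 0
    tets[flip, 1], tets[flip, 2] = tets[flip, 2].copy(), tets[flip, 1].copy()
    return tets


def build_structural_mesh(params: GeometryParams, resolution: float,
                          include_leaflets: bool = True) -> StructuralMesh:
    """Generate the conformal reference mesh at a target in-plane edge
    length ``resolution`` (cm).

    Thin dimensions (wall, sinus and leaflet thickness) are always meshed
    with at least one element through the thickness regardless of
    ``resolution``; the target edge length controls the angular, axial and
    leaflet-depth spacing.
    """
    if resolution > params.lv / 2 or resolution > params.d:
        raise MeshingError(
            f"resolution {resolution} cm too coarse for valve depth "
            f"{params.lv} cm / diameter {params.d} cm")
    z0s, z1s = params.sinus_window
    if not (0.0 < z0s and z1s < params.l):
        raise MeshingError("sinus window does not fit inside the tube; "
                           "adjust axial_position_of_valve or l")

    r0 = 0.5 * params.d
    nu = 4 * max(2, int(np.ceil(np.pi * params.d / (4.0 * resolution))))
    nz = max(12, int(np.ceil(params.l / resolution)))
    nr = max(1, int(round(params.tw / resolution)))
    chord = np.hypot(params.lv, r0)
    nt = max(3, int(np.ceil(chord / resolution)))

    # Angular grid: uniform, except that the columns at +-pi/2 are each
    # split into two at the commissure azimuths (offset +-delta), so the
    # commissures of both leaflets are exact wall nodes.  Without
    # leaflets there is nothing to attach, so the grid stays uniform.
    delta = commissure_offset(params)
    theta = []
    for j in range(nu):
        th = 2.0 * np.pi * j / nu
        if include_leaflets and (j == nu // 4 or j == 3 * nu // 4):
            theta.extend([th - delta, th + delta])
        else:
            theta.append(th)
    theta = np.asarray(theta)
    ntheta = theta.size                           # nu + 2 (or nu)
    # leaflet spans: side +1 wraps through theta=0, side -1 through pi
    i_lo = nu // 4 + 1        # index of pi/2 + delta
    i_hi = 3 * nu // 4 + 1    # index of 3*pi/2 - delta
    ns = i_hi - i_lo          # intervals per leaflet
    span_cols = {+1: (np.arange(i_hi + 1, i_hi + 1 + ns + 1)) % ntheta,
                 -1: np.arange(i_lo, i_hi + 1)}

    zbase = np.linspace(0.0, params.l, nz + 1)

    # -- warp each axial column so one ring follows the attachment curve --
    zt_ = params.valve_top
    z_att = np.full(ntheta, zt_)
    s_of_col = {}
    if include_leaflets:
        for side, jcols in span_cols.items():
            s = np.arange(jcols.size) / ns
            z_att[jcols] = zt_ - params.lv * np.sin(np.pi * s)
            s_of_col[side] = s
    k_att = np.clip(np.argmin(np.abs(zbase[None, :] - z_att[:, None]),
                              axis=1), 2, nz - 2)
    zcol = np.empty((ntheta, nz + 1))
    for j in range(ntheta):
        ka, za = k_att[j], z_att[j]
        lo = zbase[:ka + 1] * (za / zbase[ka])
        hi = params.l - (params.l - zbase[ka:]) * \
            (params.l - za) / (params.l - zbase[ka])
        zcol[j] = np.concatenate([lo, hi[1:]])

    # -- wall nodes --------------------------------------------------------
    # The split commissure columns are needed only where the leaflets
    # attach; outside the sinus window the two columns of each pair are
    # merged back into a single column at the uniform azimuth, so the
    # narrow sliver elements stay local to the valve region.
    n_wall = (nr + 1) * ntheta * (nz + 1)
    wall_ids = np.arange(n_wall).reshape(nr + 1, ntheta, nz + 1).copy()
    theta2d = np.repeat(theta[:, None], nz + 1, axis=1)
    if include_leaflets:
        for c1, c2, target in ((nu // 4, nu // 4 + 1, 0.5 * np.pi),
                               (3 * nu // 4 + 1, 3 * nu // 4 + 2,
                                1.5 * np.pi)):
            outside = (zcol[c1] < z0s) | (zcol[c1] > z1s)
            theta2d[c1, outside] = target
            theta2d[c2, outside] = target
            wall_ids[:, c2, outside] = wall_ids[:, c1, outside]
    zz = np.broadcast_to(zcol, (nr + 1, ntheta, nz + 1))
    rin = inner_radius(params, zz)
    thick = wall_thickness(params, zz)
    frac = (np.arange(nr + 1) / nr)[:, None, None]
    rr = rin + frac * thick
    tt = np.broadcast_to(theta2d[None, :, :], zz.shape)
    Xw = np.stack([rr * np.cos(tt), rr * np.sin(tt), zz], axis=-1)
    nodes = [Xw.reshape(-1, 3)]
    next_id = n_wall

    # -- wall hexes -> tets ------------------------------------------------
    ir, jj, kk = np.meshgrid(np.arange(nr), np.arange(ntheta),
                             np.arange(nz), indexing="ij")
    corners = np.empty(ir.shape + (2, 2, 2), dtype=np.int64)
    for b0, b1, b2 in itertools.product((0, 1), repeat=3):
        corners[..., b0, b1, b2] = wall_ids[ir + b0, (jj + b1) % ntheta,
                                            kk + b2]
    wall_tets = _hex_to_tets(corners)

    # -- leaflets ----------------------------------------------------------
    leaflet_tets = []
    free_edges = []
    if include_leaflets:
        zt = params.valve_top
        rt = float(inner_radius(params, zt))
        yc = np.sqrt(rt ** 2 - (0.5 * params.g) ** 2)
        for side in (+1, -1):
            jcols = span_cols[side]
            s = s_of_col[side]
            attach_ids = wall_ids[0, jcols, k_att[jcols]]      # (ns+1,)
            A = nodes[0][attach_ids]                           # (ns+1, 3)
            E = np.stack([np.full(ns + 1, side * 0.5 * params.g),
                          -side * yc * (1.0 - 2.0 * s),
                          np.full(ns + 1, zt)], axis=-1)
            tm = np.arange(nt + 1) / nt
            P = (1.0 - tm[None, :, None]) * A[:, None, :] + \
                tm[None, :, None] * E[:, None, :]              # (ns+1, nt+1, 3)
            # midsurface normals from parametric tangents, oriented so the
            # +offset layer points radially outward (toward the wall) to
            # match the inner/outer wall-layer attachment below
            dPda = np.gradient(P, axis=0)
            dPdm = np.gradient(P, axis=1)
            nrm = np.cross(dPda, dPdm)
            ln = np.linalg.norm(nrm, axis=-1, keepdims=True)
            nrm = np.divide(nrm, ln, out=np.zeros_like(nrm), where=ln > 1e-14)
            radial = (nrm[..., 0] * P[..., 0] + nrm[..., 1] * P[..., 1])
            if radial[1:-1, 1].mean() < 0.0:
                nrm = -nrm
            half = 0.5 * params.tv
            # Thickness tapers to zero over a fixed physical length at the
            # collapsed boundaries (attachment row, sharp free edge and
            # commissures), so the leaflet shape -- hence its volume -- is
            # independent of the mesh resolution.
            taper_len = 5.0 * params.tv
            L_depth = np.linalg.norm(E - A, axis=1)            # (ns+1,)
            L_arc = (np.pi - 2.0 * delta) * rt
            tm_col = tm[None, :] * L_depth[:, None]
            f_t = np.minimum(tm_col, L_depth[:, None] - tm_col) / taper_len
            f_s = np.minimum(s, 1.0 - s)[:, None] * L_arc / taper_len
            # floor keeps the free-edge taper from producing
            # inversion-fragile slivers
            f = np.clip(np.minimum(f_t, f_s), 0.35, 1.0)       # (ns+1, nt+1)
            # node ids: layer q in {0,1}.  The attachment row and the
            # commissure columns anchor the two leaflet layers to the
            # inner and outer wall node layers (the leaflet is a fold of
            # the full wall thickness, so no zero-thickness elements form
            # at the load-bearing junctions); only the free edge (m=nt)
            # collapses to a sharp midsurface row, which keeps the
            # coaptation gap exact.
            attach_out = wall_ids[nr, jcols, k_att[jcols]]
            lids = np.full((2, ns + 1, nt + 1), -1, dtype=np.int64)
            lids[0, :, 0] = attach_ids
            lids[1, :, 0] = attach_out
            lids[0, 0, :] = attach_ids[0]
            lids[1, 0, :] = attach_out[0]
            lids[0, -1, :] = attach_ids[-1]
            lids[1, -1, :] = attach_out[-1]
            new_pts = []
            for q, sgn in enumerate((-1.0, +1.0)):
                for a in range(1, ns):
                    for m in range(1, nt + 1):
                        if m == nt and q == 1:
                            lids[1, a, m] = lids[0, a, m]
                            continue
                        off = 0.0 if m == nt else sgn * half * f[a, m]
                        new_pts.append(P[a, m] + off * nrm[a, m])
                        lids[q, a, m] = next_id
                        next_id += 1
            if new_pts:
                nodes.append(np.asarray(new_pts))
            qa, aa, mm = np.meshgrid(np.arange(1), np.arange(ns),
                                     np.arange(nt), indexing="ij")
            corners = np.empty(qa.shape + (2, 2, 2), dtype=np.int64)
            for b0, b1, b2 in itertools.product((0, 1), repeat=3):
                corners[..., b0, b1, b2] = lids[qa + b0, aa + b1, mm + b2]
            leaflet_tets.append(_hex_to_tets(corners))
            free_edges.append(lids[0, :, nt].copy())

    X = np.concatenate(nodes, axis=0)
    tet_blocks = [wall_tets] + leaflet_tets
    elements = np.concatenate(tet_blocks, axis=0)
    region = np.empty(elements.shape[0], dtype=np.int8)

    # wall vs sinus by element centroid; leaflets tagged directly
    nwt = wall_tets.shape[0]
    zc = X[wall_tets, 2].mean(axis=1)
    region[:nwt] = np.where((zc > z0s) & (zc < z1s),
                            REGION_ID["sinus"], REGION_ID["wall"])
    region[nwt:] = REGION_ID["leaflet"]

    elements = _orient_positive(elements, X)
    vol = np.linalg.det(X[elements][:, 1:] - X[elements][:, :1]) / 6.0
    keep = vol > 1e-9 * resolution ** 3
    # drop sub-scale leaflet slivers (taper/commissure corner fragments):
    # their faces are too small to exert meaningful restoring forces and
    # they invert under sub-cell differential motion
    leaf = region == REGION_ID["leaflet"]
    if np.any(leaf):
        floor = 0.1 * np.median(vol[leaf & keep])
        keep &= ~(leaf & (vol < floor))
        # never orphan a free-edge node: restore its largest element
        must_keep = np.unique(np.concatenate(free_edges)) \
            if free_edges else np.array([], dtype=np.int64)
        used = np.unique(elements[keep])
        for node in np.setdiff1d(must_keep, used):
            cand = np.flatnonzero((elements == node).any(axis=1))
            keep[cand[np.argmax(vol[cand])]] = True
    elements, region = elements[keep], region[keep]

    fixed = np.unique(np.concatenate([wall_ids[:, :, 0].ravel(),
                                      wall_ids[:, :, nz].ravel()]))

    # -- compact away unused node ids (merged duplicates) ------------------
    used = np.unique(elements)
    remap = np.full(X.shape[0], -1, dtype=np.int64)
    remap[used] = np.arange(used.size)
    X = X[used]
    elements = remap[elements]
    fixed = remap[fixed]
    free_edges = [remap[fe] for fe in free_edges]
    wall_ids = remap[wall_ids]
    meta = dict(ntheta=ntheta, nz=nz, nr=nr, nt=nt, resolution=resolution,
                k_att=k_att, wall_ids=wall_ids,
                valve_top=params.valve_top, sinus_window=params.sinus_window)
    return StructuralMesh(X=X, elements=elements, region=region,
                          fixed_nodes=fixed, free_edges=tuple(free_edges),
                          params=params, meta=meta)


def mesh_quality_report(mesh: StructuralMesh) -> dict:
    """Element/node counts, volume extrema, worst aspect ratio and
    per-region counts.  Raises :class:`InvertedElementError` if any element
    has non-positive signed volume."""
    v = mesh.X[mesh.elements]
    vol = np.linalg.det(v[:, 1:] - v[:, :1]) / 6.0
    bad = np.flatnonzero(vol <= 0.0)
    if bad.size:
        raise InvertedElementError(bad)
    # aspect ratio: longest edge over smallest altitude
    pairs = [(0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3)]
    edges = np.stack([np.linalg.norm(v[:, a] - v[:, b], axis=1)
                      for a, b in pairs], axis=1)
    faces = [(1, 2, 3), (0, 2, 3), (0, 1, 3), (0, 1, 2)]
    areas = np.stack(
        [0.5 * np.linalg.norm(np.cross(v[:, f[1]] - v[:, f[0]],
                                       v[:, f[2]] - v[:, f[0]]), axis=1)
         for f in faces], axis=1)
    h_min = 3.0 * vol / areas.max(axis=1)
    aspect = edges.max(axis=1) / h_min
    used = np.unique(mesh.elements)
    report = {
        "n_elements": int(mesh.n_elements),
        "n_nodes": int(mesh.n_nodes),
        "n_orphan_nodes": int(mesh.n_nodes - used.size),
        "min_volume": float(vol.min()),
        "max_volume": float(vol.max()),
        "total_volume": float(vol.sum()),
        "worst_aspect_ratio": float(aspect.max()),
        "region_counts": {name: int((mesh.region == i).sum())
                          for i, name in enumerate(REGIONS)},
    }
    return report
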