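"""2D cross-section geometry of the valve and its disassembled optical parts.

Coordinate convention: x is the propagation axis (the plane wave travels in
+x), y is transverse (the apical axis of the valve in longitudinal CSs).
Lengths are in µm.  The CS leading (external) face sits at ``face_x``
(default 4 µm from the input boundary).

A cross-section is assembled from a small set of optical components:

* a thin-slab element (the valve face, thickness ``D_v``),
* curved, tilted mantle edges (fibre-like, width ``W_M_CS``),
* a grid-like element (costae/striae or areolae rows) of pitch ``d`` whose
  units are plano-convex (flat side external, curved side internal),
* lens-like thickenings (nodule, sternum) on the internal face,
* raphe slits cutting through the slab,
* girdle bands (rectangular fibre-like hoops) and, for the complete
  frustule, a mirrored and slightly scaled hypovalve.

All silica corners are smoothed with circular fillets (radius 0.02 µm by
default), emulating the smoothing of cross-sectioning artifacts against the
reconstructed volume data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import shapely
from shapely import affinity
from shapely.geometry import LineString, Polygon, box as shapely_box
from shapely.ops import unary_union

from .params import CrossSectionSpec, OpticalConstants, ValveParameters

FILLET_RADIUS = 0.02     # µm, convex-corner smoothing
DEFAULT_FACE_X = 4.0     # µm, leading face position from the input boundary
GRID_UNITS_LONG4 = 11    # grid units in CS_long,4 (13 striae minus sternum zone)
GRID_UNITS_LONG6 = 9
DEFAULT_FF = 0.70        # grid fill factor ≈ 1 − diam_a_int/d_str
LENS_SAG = 0.07          # µm, sag of the costa lens out of D_v


class SceneError(ValueError):
    pass


@dataclass
class GeometryScene:
    """Closed silica polygons in a medium, with optical constants.

    ``silica`` is a list of disjoint shapely polygons (after union); the
    medium fills everything else.  ``meta`` carries builder bookkeeping
    (leading/exit face positions, grid bounding box, unit centres ...).
    """

    silica: list[Polygon]
    optics: OpticalConstants
    label: str = ""
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for p in self.silica:
            if not p.is_valid:
                raise SceneError(f"invalid (self-intersecting?) polygon in {self.label}")

    @property
    def union(self):
        return unary_union(self.silica)

    @property
    def area(self) -> float:
        return self.union.area

    @property
    def bounds(self) -> tuple[float, float, float, float]:
        if not self.silica:
            return (0.0, 0.0, 0.0, 0.0)
        return self.union.bounds

    def with_optics(self, optics: OpticalConstants) -> "GeometryScene":
        return GeometryScene(list(self.silica), optics, self.label, dict(self.meta))


@dataclass
class IndexGrid:
    """Regular raster of the refractive index n(x, y).

    ``n[i, j]`` lives at cell centre (origin_x + (i+½)h, origin_y + (j+½)h).
    Anti-aliased cells carry the permittivity-averaged index, so values lie
    in [n_m, n_v].
    """

    n: np.ndarray
    origin: tuple[float, float]
    spacing: float
    optics: OpticalConstants

    @property
    def shape(self) -> tuple[int, int]:
        return self.n.shape

    def x_centers(self) -> np.ndarray:
        return self.origin[0] + (np.arange(self.n.shape[0]) + 0.5) * self.spacing

    def y_centers(self) -> np.ndarray:
        return self.origin[1] + (np.arange(self.n.shape[1]) + 0.5) * self.spacing

    def silica_area(self) -> float:
        """Silica area implied by the raster (µm²), via permittivity coverage."""
        o = self.optics
        cov = (self.n**2 - o.n_m**2) / (o.n_v**2 - o.n_m**2)
        return float(cov.sum()) * self.spacing**2


# ---------------------------------------------------------------------------
# component primitives


def _fillet(geom, radius: float = FILLET_RADIUS):
    """Round convex silica corners with circular fillets of the given radius."""
    if radius <= 0 or geom.is_empty:
        return geom
    return geom.buffer(-radius, quad_segs=8).buffer(radius, quad_segs=8)


def _plano_convex_unit(x0: float, y_lo: float, width: float, thickness: float,
                       sag: float, n_arc: int = 17) -> Polygon:
    """Plano-convex unit: flat external face at x0, convex cap on the internal
    side with the given sag (cap apex at x0 + thickness)."""
    base = thickness - sag
    half = width / 2.0
    yc = y_lo + half
    if sag <= 0:
        return shapely_box(x0, y_lo, x0 + thickness, y_lo + width)
    # circular arc through (base, ±half) and apex (base+sag, 0), local coords
    R = (half**2 + sag**2) / (2.0 * sag)
    xc = x0 + base + sag - R
    t_max = math.asin(half / R)
    ts = np.linspace(-t_max, t_max, n_arc)
    arc = [(xc + R * math.cos(t), yc + R * math.sin(t)) for t in ts]
    pts = [(x0, y_lo), (x0, y_lo + width)] + arc[::-1]
    return Polygon(pts)


def _mantle_arc(params: ValveParameters, face_x: float, y_edge: float,
                side: int, W_M_CS: float) -> tuple[Polygon, tuple[float, float]]:
    """Curved, tilted mantle edge at one transverse end of the slab.

    The centreline starts at the slab mid-plane and sweeps ``theta_M``
    degrees from the face plane towards +x (downstream); the radius is set so
    the rim elevation along x equals ``h_M``.  Returns (polygon, tip point).
    """
    theta = math.radians(params.theta_M)
    R = params.h_M / (1.0 - math.cos(theta))
    x_start = face_x + params.D_v / 2.0
    ts = np.linspace(0.0, theta, 24)
    pts = [(x_start + R * (1.0 - math.cos(t)),
            y_edge + side * R * math.sin(t)) for t in ts]
    line = LineString(pts)
    poly = line.buffer(W_M_CS / 2.0, cap_style="flat", quad_segs=8)
    return poly, pts[-1]


def _grid_units(x0: float, centers: np.ndarray, width: float, D: float,
                sag: float) -> list[Polygon]:
    return [_plano_convex_unit(x0, c - width / 2.0, width, D, sag)
            for c in centers]


def _sternum(params: ValveParameters, face_x: float, y_center: float = 0.0,
             slit: bool = False) -> Polygon:
    """Thickened sternum element on the internal side, optional raphe slit."""
    w = 2.0 * params.half_W_s
    poly = _plano_convex_unit(face_x, y_center - w / 2.0, w, params.D_S,
                              params.D_S - params.D_v)
    if slit:
        cut = shapely_box(face_x - 0.1, y_center - params.W_ra / 2.0,
                          face_x + params.D_S + 0.1, y_center + params.W_ra / 2.0)
        poly = poly.difference(cut)
    return poly


def _nodule_lens(params: ValveParameters, face_x: float,
                 y_center: float) -> Polygon:
    return _plano_convex_unit(face_x, y_center - params.W_nod / 2.0,
                              params.W_nod, params.D_nod,
                              params.D_nod - params.D_v)


# ---------------------------------------------------------------------------
# cross-section builders


def _w_m_cs_default(params: ValveParameters, index: str) -> float:
    lo, hi = params.W_M_CS_range
    return {"5": lo, "7": hi, "6": 0.5 * (lo + hi)}.get(index, lo)


def _slab_with_mantle(params: ValveParameters, face_x: float, half_span: float,
                      W_M_CS: float) -> tuple[list[Polygon], dict]:
    """Thin slab of thickness D_v between two curved mantle edges.

    A zero mantle width degenerates to the bare slab (straight edges)."""
    slab = shapely_box(face_x, -half_span, face_x + params.D_v, half_span)
    if W_M_CS <= 0:
        return [slab], {"mantle_tips": []}
    top, tip_top = _mantle_arc(params, face_x, half_span, +1, W_M_CS)
    bot, tip_bot = _mantle_arc(params, face_x, -half_span, -1, W_M_CS)
    meta = {"mantle_tips": [tip_top, tip_bot]}
    return [slab, top, bot], meta


def build_longitudinal_cs(params: ValveParameters,
                          spec: CrossSectionSpec,
                          face_x: float = DEFAULT_FACE_X,
                          ff: float = DEFAULT_FF,
                          n_units: int | None = None,
                          fillet_radius: float = FILLET_RADIUS) -> GeometryScene:
    """Build a longitudinal cross-section CS_long,index.

    Index 5/7: plain thin slab with mantle edges (differing length and
    mantle width).  4/6: adds the grid-like costae element of pitch
    d_str_min+ / d_str_max with plano-convex units; 4* displaces one unit
    (the shortened-stria defect).  3: grid interrupted by the off-centre
    nodule lens.  2: sternum thickening, no grid.  1: slab cut by the two
    raphe slits with the central lens in between.
    """
    if spec.family != "long":
        raise SceneError("spec.family must be 'long'")
    idx = spec.index
    W_M_CS = spec.W_M_CS if spec.W_M_CS is not None \
        else _w_m_cs_default(params, idx)
    theta = math.radians(params.theta_M)
    R = params.h_M / (1.0 - math.cos(theta))
    edge_growth = (R * math.sin(theta) + W_M_CS / 2.0) if W_M_CS > 0 else 0.0

    lengths = {"5": params.L_v, "7": 5.0, "4": params.L_v, "4*": params.L_v,
               "6": 6.0, "3": params.L_v, "2": params.L_v, "1": params.L_v}
    half_span = max(lengths[idx] / 2.0 - edge_growth, 1.0)

    meta: dict = {"face_x": face_x, "exit_x": face_x + params.D_v,
                  "cs": f"CS_long,{idx}", "W_M_CS": W_M_CS}
    d = None
    if idx in ("4", "4*"):
        d, N = 0.500, (n_units or GRID_UNITS_LONG4)
    elif idx == "6":
        d, N = 0.565, (n_units or GRID_UNITS_LONG6)
    elif idx == "3":
        d, N = params.d_str_min, (n_units or GRID_UNITS_LONG4)

    if d is not None:
        span_needed = ((N - 1) * d + ff * d) / 2.0 + 0.15
        half_span = max(half_span, span_needed)

    polys, m = _slab_with_mantle(params, face_x, half_span, W_M_CS)
    meta.update(m)
    slab, mantles = polys[0], polys[1:]

    if d is not None:
        w = ff * d
        centers = (np.arange(N) - (N - 1) / 2.0) * d
        if idx == "3":
            # off-centre nodule lens interrupts the grid
            y_nod = params.nodule_offset
            keep = np.abs(centers - y_nod) > (params.W_nod + w) / 2.0
            centers = centers[keep]
        units = _grid_units(face_x, centers, w, params.D_v, LENS_SAG)
        if idx == "4*":
            # shortened-stria defect: displace one unit to close a gap,
            # leaving the total silica area unchanged
            j = N // 2 + 1
            units[j] = affinity.translate(units[j], yoff=(1.0 - ff) * d)
        # open the grid window in the slab, then insert the units
        y_lo = centers.min() - w / 2.0
        y_hi = centers.max() + w / 2.0
        if idx == "3":
            y_lo = min(y_lo, params.nodule_offset - params.W_nod / 2.0)
            y_hi = max(y_hi, params.nodule_offset + params.W_nod / 2.0)
        window = shapely_box(face_x - 0.1, y_lo, face_x + params.D_v + 0.1, y_hi)
        slab = slab.difference(window)
        polys = [slab, *mantles, *units]
        meta["grid"] = {"d": d, "ff": ff, "n_units": int(len(centers)),
                       "unit_centers": [float(c) for c in centers]}
        meta["grid_bbox"] = (face_x, y_lo, face_x + params.D_v, y_hi)
        if idx == "3":
            polys.append(_nodule_lens(params, face_x, params.nodule_offset))
    elif idx == "2":
        polys.append(_sternum(params, face_x))
    elif idx == "1":
        half_gap = params.d_ra / 2.0
        lens_w = params.d_ra - params.W_ra
        for sgn in (+1, -1):
            cut = shapely_box(face_x - 0.1, sgn * half_gap - params.W_ra / 2.0,
                              face_x + params.D_v + 0.1,
                              sgn * half_gap + params.W_ra / 2.0)
            slab = slab.difference(cut)
        polys = [slab, *mantles,
                 _plano_convex_unit(face_x, -lens_w / 2.0, lens_w,
                                    params.D_nod, params.D_nod - params.D_v)]

    return _finish(polys, spec, meta, fillet_radius, f"CS_long,{idx}")


def build_vertical_cs(params: ValveParameters,
                      spec: CrossSectionSpec,
                      face_x: float = DEFAULT_FACE_X,
                      fillet_radius: float = FILLET_RADIUS) -> GeometryScene:
    """Build a vertical cross-section CS_ver,index (across the valve width).

    4/5: slab split by the raphe/sternum element with (4) or without (5) the
    23 nm slit; 2: triangular nodule element; 1/3: additionally divided by
    the areolae grid of pitch d_a (1: nodule variant, 3: raphe variant).
    """
    if spec.family != "ver":
        raise SceneError("spec.family must be 'ver'")
    idx = spec.index
    W_M_CS = spec.W_M_CS if spec.W_M_CS is not None \
        else params.W_M_CS_range[0]
    theta = math.radians(params.theta_M)
    R = params.h_M / (1.0 - math.cos(theta))
    edge_growth = R * math.sin(theta) + W_M_CS / 2.0
    half_span = params.W_v / 2.0 - edge_growth

    polys, m = _slab_with_mantle(params, face_x, half_span, W_M_CS)
    meta = {"face_x": face_x, "exit_x": face_x + params.D_v,
            "cs": f"CS_ver,{idx}", "W_M_CS": W_M_CS}
    meta.update(m)
    slab, mantles = polys[0], polys[1:]

    central_halfwidth = 0.0
    extras: list[Polygon] = []
    if idx in ("4", "3"):
        extras.append(_sternum(params, face_x, slit=True))
        central_halfwidth = params.half_W_s
        if idx == "4":
            cut = shapely_box(face_x - 0.1, -params.W_ra / 2.0,
                              face_x + params.D_S + 0.1, params.W_ra / 2.0)
            slab = slab.difference(cut)
    elif idx == "5":
        extras.append(_sternum(params, face_x, slit=False))
        central_halfwidth = params.half_W_s
    elif idx in ("2", "1"):
        tri = Polygon([(face_x + params.D_v, -params.W_nod / 2.0),
                       (face_x + params.D_v, params.W_nod / 2.0),
                       (face_x + params.D_nod, 0.0)])
        if tri.area > 0:
            extras.append(tri)
        central_halfwidth = params.W_nod / 2.0
    if idx == "4":
        # ver,4: raphe slit also cuts the sternum element (built with slit=True);
        # the slab cut above opens the same 23 nm gap in the face
        extras = [_sternum(params, face_x, slit=True)]
    if idx == "3":
        cut = shapely_box(face_x - 0.1, -params.W_ra / 2.0,
                          face_x + params.D_S + 0.1, params.W_ra / 2.0)
        slab = slab.difference(cut)

    if idx in ("1", "3"):
        # areolae grid of pitch d_a on both sides of the central element
        d = params.d_a
        ff = 1.0 - params.diam_a_int / d
        w = ff * d
        units = []
        y0 = central_halfwidth + d / 2.0
        n_side = int((half_span - 0.2 - y0) // d) + 1
        centers = []
        for k in range(n_side):
            centers.extend([y0 + k * d, -(y0 + k * d)])
        centers = np.sort(np.array(centers))
        units = _grid_units(face_x, centers, w, params.D_v, 0.0)
        for sgn in (+1, -1):
            lo = sgn * y0 - sgn * d / 2.0 - (w / 2.0 if sgn < 0 else 0)
            window = shapely_box(face_x - 0.1,
                                 min(sgn * y0, sgn * (y0 + (n_side - 1) * d)) - w / 2.0,
                                 face_x + params.D_v + 0.1,
                                 max(sgn * y0, sgn * (y0 + (n_side - 1) * d)) + w / 2.0)
            slab = slab.difference(window)
        extras.extend(units)
        meta["grid"] = {"d": d, "ff": ff, "n_units": len(centers),
                        "unit_centers": [float(c) for c in centers]}
        meta["grid_bbox"] = (face_x, float(centers.min() - w / 2),
                             face_x + params.D_v, float(centers.max() + w / 2))

    polys = [slab, *mantles, *extras]
    return _finish(polys, spec, meta, fillet_radius, f"CS_ver,{idx}")


def build_analytic_component(kind: str, dims: dict,
                             optics: OpticalConstants | None = None,
                             face_x: float = DEFAULT_FACE_X) -> GeometryScene:
    """Analytic stand-ins: straight-edged slab, rectangular-groove grating,
    mantle-equivalent strip, or a single plano-convex lens.

    dims (µm): slab → L, D; grid → d, ff, D, N; mantle → W, h, tilt (deg);
    lens → width, D, sag.
    """
    optics = optics or OpticalConstants()
    meta: dict = {"face_x": face_x}
    if kind == "slab":
        L, D = dims["L"], dims["D"]
        if L <= 0 or D <= 0:
            raise SceneError("slab dims must be positive")
        polys = [shapely_box(face_x, -L / 2.0, face_x + D, L / 2.0)]
        meta["exit_x"] = face_x + D
        label = f"S_ana,slab(L={L},D={D})"
    elif kind == "grid":
        d, ff, D, N = dims["d"], dims.get("ff", DEFAULT_FF), dims["D"], dims["N"]
        if not 0 < ff <= 1:
            raise SceneError("fill factor must lie in (0, 1]")
        w = ff * d
        centers = (np.arange(N) - (N - 1) / 2.0) * d
        polys = [shapely_box(face_x, c - w / 2.0, face_x + D, c + w / 2.0)
                 for c in centers]
        meta.update(exit_x=face_x + D,
                    grid={"d": d, "ff": ff, "n_units": int(N),
                          "unit_centers": [float(c) for c in centers]},
                    grid_bbox=(face_x, float(centers.min() - w / 2),
                               face_x + D, float(centers.max() + w / 2)))
        label = f"G_ana(d={d},ff={ff},N={N})"
    elif kind == "mantle":
        W, h = dims["W"], dims["h"]
        tilt = dims.get("tilt", 0.0)
        poly = shapely_box(face_x, -W / 2.0, face_x + h, W / 2.0)
        if tilt:
            poly = affinity.rotate(poly, tilt, origin="centroid")
        polys = [poly]
        meta["exit_x"] = poly.bounds[2]
        label = f"S_ana,M(W={W},h={h})"
    elif kind == "lens":
        w, D = dims["width"], dims["D"]
        sag = dims.get("sag", D / 2.0)
        polys = [_plano_convex_unit(face_x, -w / 2.0, w, D, sag)]
        meta["exit_x"] = face_x + D
        label = f"lens(w={w},D={D})"
    else:
        raise SceneError(f"unknown analytic component kind {kind!r}")
    return GeometryScene(_as_list(unary_union(polys)), optics, label, meta)


def add_girdle_bands(scene: GeometryScene, params: ValveParameters,
                     toward_hypovalve: bool = True) -> GeometryScene:
    """Append four girdle-band rectangles (two per side) behind the mantle.

    Bands are W_girdle × H_girdle fibres along x, consecutive bands separated
    by d_girdle on x and stepped one band-width inward on y.
    """
    tips = scene.meta.get("mantle_tips")
    if not tips:
        raise SceneError("scene has no mantle edges to attach girdle bands to")
    bands = []
    x_anchor = scene.bounds[2]   # downstream silica extent (mantle rim)
    for (tx, ty) in tips:
        side = 1.0 if ty > 0 else -1.0
        for k in range(2):
            x0 = x_anchor + params.d_girdle + k * (params.H_girdle + params.d_girdle)
            y_out = ty - side * k * params.W_girdle
            band = shapely_box(x0, min(y_out, y_out - side * params.W_girdle),
                               x0 + params.H_girdle,
                               max(y_out, y_out - side * params.W_girdle))
            bands.append(band)
    silica_union = scene.union
    for b in bands:
        if b.intersects(silica_union) and b.intersection(silica_union).area > 1e-12:
            raise SceneError("girdle band overlaps existing silica")
    meta = dict(scene.meta)
    meta["girdle_end_x"] = max(b.bounds[2] for b in bands)
    return GeometryScene(list(scene.silica) + bands, scene.optics,
                         scene.label + "+girdles", meta)


def assemble_frustule(epivalve_scene: GeometryScene, params: ValveParameters,
                      scale_hypovalve: float = 0.97) -> GeometryScene:
    """Complete frustule: epivalve + girdle bands + mirrored, smaller hypovalve.

    The hypovalve is the epivalve mirrored about a mid-plane downstream and
    scaled by ``scale_hypovalve`` (< 1, the hypovalve nests inside the
    epivalve's girdle); four girdle bands bridge the two valves.  The medium
    fills the interior.
    """
    if scale_hypovalve >= 1.0:
        raise SceneError("hypovalve scale must be < 1")
    if epivalve_scene.meta.get("frustule"):
        raise SceneError("scene already contains a hypovalve")
    with_girdles = add_girdle_bands(epivalve_scene, params)
    tips = epivalve_scene.meta["mantle_tips"]
    tip_x = max(t[0] for t in tips)
    girdle_end = with_girdles.meta["girdle_end_x"]
    mid_x = 0.5 * (tip_x + girdle_end + params.d_girdle)
    epi = epivalve_scene.union
    hypo = affinity.scale(epi, xfact=scale_hypovalve, yfact=scale_hypovalve,
                          origin="centroid")
    hypo = affinity.scale(hypo, xfact=-1.0, yfact=1.0,
                          origin=(mid_x, 0.0))
    # push the mirrored valve so its (now leading) mantle tips clear the bands
    shift = girdle_end + params.d_girdle - hypo.bounds[0]
    hypo = affinity.translate(hypo, xoff=shift)
    meta = dict(with_girdles.meta)
    meta.update(frustule=True, hypovalve_scale=scale_hypovalve,
                hypovalve_exit_x=hypo.bounds[2])
    polys = list(with_girdles.silica) + _as_list(hypo)
    return GeometryScene(polys, epivalve_scene.optics,
                         epivalve_scene.label + ",frustule", meta)


def transform_scene(scene: GeometryScene, rotate_180: bool = False,
                    tilt_deg: float = 0.0) -> GeometryScene:
    """Rigid rotation of the whole scene about the silica centroid."""
    geom = scene.union
    c = geom.centroid
    if rotate_180:
        geom = affinity.rotate(geom, 180.0, origin=c)
    if tilt_deg:
        geom = affinity.rotate(geom, tilt_deg, origin=c)
    meta = dict(scene.meta)
    meta["rotated_180"] = bool(rotate_180) ^ bool(meta.get("rotated_180", False))
    meta["tilt_deg"] = meta.get("tilt_deg", 0.0) + tilt_deg
    return GeometryScene(_as_list(geom), scene.optics, scene.label, meta)


# ---------------------------------------------------------------------------
# rasterization


def rasterize(scene: GeometryScene, resolution: float,
              box: tuple[float, float, float, float] | None = None,
              lam_min_nm: float | None = None) -> IndexGrid:
    """Rasterize a scene to a refractive-index grid with sub-pixel coverage.

    ``box`` is (x0, y0, x1, y1) in µm; defaults to the silica bounds plus a
    1 µm margin.  Cells wholly inside/outside silica get n_v/n_m; cells cut
    by a boundary are supersampled 8×8 and carry the permittivity-averaged
    index.  If ``lam_min_nm`` is given, the resolution is required to satisfy
    resolution ≤ λ_min/(15·n_v).
    """
    o = scene.optics
    if lam_min_nm is not None:
        max_res = lam_min_nm * 1e-3 / (15.0 * o.n_v)
        if resolution > max_res * (1 + 1e-9):
            raise SceneError(
                f"resolution {resolution:.4g} µm too coarse for λ_min="
                f"{lam_min_nm:g} nm; need <= {max_res:.4g} µm")
    if box is None:
        x0, y0, x1, y1 = scene.bounds
        box = (x0 - 1.0, y0 - 1.0, x1 + 1.0, y1 + 1.0)
    x0, y0, x1, y1 = box
    h = resolution
    nx = max(int(round((x1 - x0) / h)), 1)
    ny = max(int(round((y1 - y0) / h)), 1)
    n = np.full((nx, ny), o.n_m, dtype=float)
    geom = scene.union
    if geom.is_empty:
        return IndexGrid(n, (x0, y0), h, o)

    shapely.prepare(geom)
    xc = x0 + (np.arange(nx) + 0.5) * h
    yc = y0 + (np.arange(ny) + 0.5) * h
    XX, YY = np.meshgrid(xc, yc, indexing="ij")
    inside = shapely.contains_xy(geom, XX.ravel(), YY.ravel()).reshape(nx, ny)

    # mixed cells: neighbourhood disagreement plus cells crossed by the
    # boundary (catches features thinner than one cell, e.g. the raphe slit)
    from scipy.ndimage import binary_dilation
    grown = binary_dilation(inside)
    shrunk = ~binary_dilation(~inside)
    mixed = grown & ~shrunk
    bnd = geom.boundary
    length = bnd.length
    if length > 0:
        step = h / 4.0
        n_pts = max(int(length / step), 8)
        pts = [bnd.interpolate(s) for s in np.linspace(0, length, n_pts)] \
            if bnd.geom_type == "LineString" else None
        if pts is None:
            pts = []
            for part in getattr(bnd, "geoms", [bnd]):
                k = max(int(part.length / step), 4)
                pts.extend(part.interpolate(s)
                           for s in np.linspace(0, part.length, k))
        bx = np.array([p.x for p in pts])
        by = np.array([p.y for p in pts])
        ix = np.clip(((bx - x0) / h).astype(int), 0, nx - 1)
        iy = np.clip(((by - y0) / h).astype(int), 0, ny - 1)
        crossed = np.zeros((nx, ny), dtype=bool)
        crossed[ix, iy] = True
        mixed |= binary_dilation(crossed)

    n[inside] = o.n_v
    mi, mj = np.nonzero(mixed)
    if len(mi):
        S = 8
        offs = (np.arange(S) + 0.5) / S
        ox, oy = np.meshgrid(offs, offs, indexing="ij")
        sx = (x0 + (mi[:, None] + ox.ravel()[None, :]) * h).ravel()
        sy = (y0 + (mj[:, None] + oy.ravel()[None, :]) * h).ravel()
        hit = shapely.contains_xy(geom, sx, sy).reshape(len(mi), S * S)
        frac = hit.mean(axis=1)
        n[mi, mj] = np.sqrt(frac * o.n_v**2 + (1.0 - frac) * o.n_m**2)
    return IndexGrid(n, (x0, y0), h, o)


def vectorize(grid: IndexGrid) -> list[Polygon]:
    """Reconstruct silica polygons from a raster (marching squares at 50%
    permittivity coverage); the inverse of :func:`rasterize` up to aliasing."""
    from skimage import measure
    o = grid.optics
    cov = (grid.n**2 - o.n_m**2) / (o.n_v**2 - o.n_m**2)
    padded = np.pad(cov, 1, constant_values=0.0)
    contours = measure.find_contours(padded, 0.5)
    polys = []
    for c in contours:
        if len(c) < 4:
            continue
        xs = grid.origin[0] + (c[:, 0] - 1 + 0.5) * grid.spacing
        ys = grid.origin[1] + (c[:, 1] - 1 + 0.5) * grid.spacing
        p = Polygon(np.column_stack([xs, ys]))
        if p.is_valid and p.area > 0:
            polys.append(p)
    # marching squares yields outer shells and holes; combine by even-odd area
    return polys


def _as_list(geom) -> list[Polygon]:
    if geom.is_empty:
        return []
    if geom.geom_type == "Polygon":
        return [geom]
    return [g for g in geom.geoms if g.geom_type == "Polygon"]


def _finish(polys, spec: CrossSectionSpec, meta: dict, fillet_radius: float,
            label: str) -> GeometryScene:
    geom = unary_union([p for p in polys if not p.is_empty and p.area > 0])
    geom = _fillet(geom, fillet_radius)
    scene = GeometryScene(_as_list(geom), OpticalConstants(), label, meta)
    if spec.orientation == "internal_first" or spec.tilt_deg:
        scene = transform_scene(scene,
                                rotate_180=(spec.orientation == "internal_first"),
                                tilt_deg=spec.tilt_deg)
    return scene
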