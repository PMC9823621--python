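"""Extraction of optical observables from simulated field maps.

* reflectance/transmittance intensities of slab-like cross-sections
  (standing-wave envelope upstream, mean transmitted amplitude downstream,
  both squared to intensities),
* diffraction-driven focusing spots (position Z_f, axial length L_f,
  strength E_Norm,f),
* photonic-jet metrics (peak, distance, waist, axis angle),
* the Talbot length Z_T with its uncertainty from the spacing of the
  self-image planes,
* guided-mode-resonance position λ_GMR via a coarse-then-fine wavelength
  sweep of the interior field of the grid-like element.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.signal import find_peaks
from skimage import measure

from .geometry import GeometryScene, rasterize
from .solver import FieldMap, SimulationConfig, cutline, solve

UM_PER_NM = 1e-3
SPOT_THRESHOLD = 1.1     # × E_input; below this a bright feature is ignored


class FeatureError(RuntimeError):
    pass


@dataclass
class FocusSpot:
    Z_f: float               # axial distance from the CS exit face, µm
    L_f: float               # axial FWHM, µm
    E_Norm_f: float          # peak field, V/m
    centroid: tuple[float, float]
    peak_xy: tuple[float, float]


@dataclass
class PhotonicJet:
    E_Norm_PJ: float
    distance: float          # exit face to peak, µm
    waist: float             # transverse FWHM at the peak, µm
    angle_deg: float         # beam axis angle from the incident axis


@dataclass
class TalbotMeasurement:
    Z_T: float
    uncertainty: float
    plane_positions: list[float]


@dataclass
class GmrResonance:
    lam_nm: float
    E_Norm_GMR: float
    mode_index: int
    sweep: list[tuple[float, float]]    # (λ, interior metric) pairs examined


# ---------------------------------------------------------------------------


def extract_RT(fieldmap: FieldMap, scene: GeometryScene,
               y_line: float = 0.0, margin: float = 1.0) -> tuple[float, float]:
    """Reflected and transmitted intensities (E²) of a slab-like scene.

    Upstream the reflected wave forms a standing wave with the incident one;
    the reflected amplitude r is half the peak-to-peak excursion of |E| on an
    axial cutline (window of ≥ 2 spatial periods λ/(2 n_m), ending ``margin``
    µm before the face).  Downstream the transmitted amplitude is the mean
    |E| on a short transverse segment behind the slab centre, away from the
    edge-fringe lobes.  Both are squared to intensities.
    """
    face_x = scene.meta.get("face_x")
    exit_x = scene.meta.get("exit_x")
    if face_x is None or exit_x is None:
        raise FeatureError("scene lacks face/exit metadata (not slab-like?)")
    E0 = fieldmap.config.E_input
    h = fieldmap.spacing
    period = fieldmap.lam_nm * UM_PER_NM / (2.0 * fieldmap.n_m)
    win = max(2.5 * period, 5 * h)
    x_hi = face_x - margin
    x_lo = x_hi - win
    p = fieldmap.pml_cells
    lo_x = fieldmap.origin[0] + (p + 3) * h
    if x_lo < lo_x:
        raise FeatureError(
            f"standing-wave window [{x_lo:.2f}, {x_hi:.2f}] µm does not fit "
            f"upstream of the face; need >= {win + margin:.2f} µm of open "
            "space before the structure")
    # standing-wave envelope on the axial line: the complex field there is
    # a·e^{ikx} + b·e^{-ikx}, so (env_max − env_min)/2 = |b|; recover |b| by
    # least-squares demodulation against the two discrete plane waves
    xc = fieldmap.x_centers()
    yc = fieldmap.y_centers()
    j = int(np.argmin(np.abs(yc - y_line)))
    im = (xc >= x_lo) & (xc <= x_hi)
    xs = xc[im]
    Ec = fieldmap.field[im, j]
    k0 = 2.0 * math.pi / (fieldmap.lam_nm * UM_PER_NM)
    k_eff = k0 * fieldmap.n_m   # exact with the dispersion-corrected stencil
    basis = np.column_stack([np.exp(1j * k_eff * xs),
                             np.exp(-1j * k_eff * xs)])
    coef, *_ = np.linalg.lstsq(basis, Ec, rcond=None)
    r = abs(coef[1]) / E0
    R = min(r, 1.0) ** 2

    # transmitted amplitude: transverse segment behind the slab centre,
    # clipped to the interior (outside PML) and away from the edges
    interior_half = (yc[-1] - yc[0]) / 2.0 - (p + 2) * h
    half_w = min(_slab_halfwidth(scene) * 0.5, interior_half * 0.7)
    x_t = min(exit_x + 0.5, xc[-1] - (p + 2) * h)
    prof_t = cutline(fieldmap, (x_t, y_line - half_w), (x_t, y_line + half_w),
                     120, warn_pml=False)[:, 2]
    T = (prof_t.mean() / E0) ** 2
    return float(R), float(T)


def _slab_halfwidth(scene: GeometryScene) -> float:
    x0, y0, x1, y1 = scene.bounds
    return (y1 - y0) / 2.0


def detect_focus_spots(fieldmap: FieldMap, exit_face_x: float) -> list[FocusSpot]:
    """Bright interference spots downstream of the exit face.

    Connected components of E_Norm ≥ 1.1·E_input beyond ``exit_face_x``;
    per component the peak strength, intensity-weighted centroid, axial gap
    Z_f to the exit face (at the peak) and axial FWHM L_f through the peak.
    Sorted by strength (descending), ties by smaller Z_f.
    """
    E = fieldmap.E_norm
    E0 = fieldmap.config.E_input
    h = fieldmap.spacing
    p = fieldmap.pml_cells
    xc = fieldmap.x_centers()
    i_exit = int(np.searchsorted(xc, exit_face_x))
    mask = np.zeros_like(E, dtype=bool)
    inner = (slice(p, E.shape[0] - p), slice(p, E.shape[1] - p))
    mask[inner] = E[inner] >= SPOT_THRESHOLD * E0
    mask[:i_exit + 1, :] = False
    labels = measure.label(mask, connectivity=2)
    spots: list[FocusSpot] = []
    yc = fieldmap.y_centers()
    for region in measure.regionprops(labels, intensity_image=E):
        ii, jj = region.coords[:, 0], region.coords[:, 1]
        vals = E[ii, jj]
        k = int(np.argmax(vals))
        pi, pj = int(ii[k]), int(jj[k])
        peak = float(vals[k])
        wsum = vals.sum()
        cx = float((xc[ii] * vals).sum() / wsum)
        cy = float((yc[jj] * vals).sum() / wsum)
        L_f = _axial_fwhm(E, xc, pi, pj, peak, E0)
        spots.append(FocusSpot(Z_f=float(xc[pi] - exit_face_x), L_f=L_f,
                               E_Norm_f=peak, centroid=(cx, cy),
                               peak_xy=(float(xc[pi]), float(yc[pj]))))
    spots.sort(key=lambda s: (-s.E_Norm_f, s.Z_f))
    return spots


def _axial_fwhm(E: np.ndarray, xc: np.ndarray, pi: int, pj: int,
                peak: float, E0: float) -> float:
    """FWHM along x through (pi, pj): half level midway between peak and E0."""
    level = E0 + (peak - E0) / 2.0
    prof = E[:, pj]
    i_lo = pi
    while i_lo > 0 and prof[i_lo] > level:
        i_lo -= 1
    i_hi = pi
    while i_hi < len(prof) - 1 and prof[i_hi] > level:
        i_hi += 1
    return float(xc[i_hi] - xc[i_lo])


def track_spot(spot_lists: list[list[FocusSpot]],
               start: FocusSpot | None = None) -> list[FocusSpot]:
    """Follow one spot across a wavelength sweep by centroid continuity.

    Starts from ``start`` (default: the strongest spot of the first list)
    and at each subsequent wavelength picks the spot with the nearest
    centroid.  The transverse position dominates the match: a spot keeps
    its fringe index (y) while sliding along the axis as λ changes, so
    axial displacement is discounted.
    """
    if not spot_lists or not spot_lists[0]:
        raise FeatureError("no spots to track")
    tracked = [start if start is not None else spot_lists[0][0]]
    for spots in spot_lists[1:]:
        if not spots:
            raise FeatureError("spot lost during tracking")
        cx, cy = tracked[-1].centroid
        dists = [abs(s.centroid[1] - cy) + 0.1 * abs(s.centroid[0] - cx)
                 for s in spots]
        tracked.append(spots[int(np.argmin(dists))])
    return tracked


def characterize_pj(fieldmap: FieldMap,
                    structure_bbox: tuple[float, float, float, float]
                    ) -> PhotonicJet:
    """Photonic jet: the brightest downstream feature contiguous with the
    structure's shadow axis."""
    x0, y0, x1, y1 = structure_bbox
    y_axis = 0.5 * (y0 + y1)
    E = fieldmap.E_norm
    E0 = fieldmap.config.E_input
    p = fieldmap.pml_cells
    xc, yc = fieldmap.x_centers(), fieldmap.y_centers()
    i_exit = int(np.searchsorted(xc, x1))
    mask = np.zeros_like(E, dtype=bool)
    inner = (slice(p, E.shape[0] - p), slice(p, E.shape[1] - p))
    mask[inner] = E[inner] >= SPOT_THRESHOLD * E0
    mask[:i_exit + 1, :] = False
    labels = measure.label(mask, connectivity=2)
    best = None
    for region in measure.regionprops(labels, intensity_image=E):
        jj = region.coords[:, 1]
        ys = yc[jj]
        # contiguous with the shadow axis: the component crosses it
        if ys.min() - fieldmap.spacing > y_axis or ys.max() + fieldmap.spacing < y_axis:
            continue
        if best is None or region.intensity_max > best.intensity_max:
            best = region
    if best is None:
        raise FeatureError("no downstream feature above the PJ threshold")
    ii, jj = best.coords[:, 0], best.coords[:, 1]
    vals = E[ii, jj]
    k = int(np.argmax(vals))
    pi, pj = int(ii[k]), int(jj[k])
    peak = float(vals[k])
    waist = _transverse_fwhm(E, yc, pi, pj, peak, E0)
    angle = math.degrees(math.atan2(yc[pj] - y_axis, xc[pi] - x1))
    return PhotonicJet(E_Norm_PJ=peak, distance=float(xc[pi] - x1),
                       waist=waist, angle_deg=angle)


def _transverse_fwhm(E: np.ndarray, yc: np.ndarray, pi: int, pj: int,
                     peak: float, E0: float) -> float:
    level = E0 + (peak - E0) / 2.0
    prof = E[pi, :]
    j_lo = pj
    while j_lo > 0 and prof[j_lo] > level:
        j_lo -= 1
    j_hi = pj
    while j_hi < len(prof) - 1 and prof[j_hi] > level:
        j_hi += 1
    return float(yc[j_hi] - yc[j_lo])


def extract_talbot(fieldmap: FieldMap, d: float,
                   scene: GeometryScene | None = None,
                   exit_x: float | None = None,
                   unit_centers: np.ndarray | None = None) -> TalbotMeasurement:
    """Talbot length from the self-image planes behind a grating.

    For each axial position the transverse E_Norm profile (restricted to the
    central part of the grating span) is correlated with a grating-registered
    cosine template of period d and zero lateral shift; integer Talbot planes
    are the local maxima of this correlation (the d/2-shifted half-planes
    correlate negatively and are excluded).  Z_T is the mean spacing of
    consecutive planes and the uncertainty their standard deviation.
    """
    if scene is not None:
        g = scene.meta.get("grid")
        if g is None:
            raise FeatureError("scene has no grid-like element")
        exit_x = exit_x if exit_x is not None else scene.meta["exit_x"]
        unit_centers = np.asarray(g["unit_centers"])
    if exit_x is None or unit_centers is None:
        raise FeatureError("need a grating scene or explicit exit/centres")
    y_ref = float(np.median(unit_centers))
    span = unit_centers.max() - unit_centers.min()
    half = max(span / 2.0 - d, d)          # drop the outermost unit each side
    E = fieldmap.E_norm
    xc, yc = fieldmap.x_centers(), fieldmap.y_centers()
    p = fieldmap.pml_cells
    jm = (yc >= y_ref - half) & (yc <= y_ref + half)
    template = np.cos(2.0 * np.pi * (yc[jm] - y_ref) / d)
    i0 = int(np.searchsorted(xc, exit_x + 0.25 * d))
    i1 = E.shape[0] - p - 1
    corr = (E[i0:i1, :][:, jm] * template[None, :]).mean(axis=1)
    # planes repeat every Z_T >= paraxial-limit fraction; keep peaks separated
    min_sep = max(int(0.5 * d / fieldmap.spacing), 3)
    peaks, _ = find_peaks(corr, distance=min_sep,
                          prominence=0.05 * (corr.max() - corr.min()))
    peaks = peaks[corr[peaks] > 0]
    # parabolic sub-cell refinement of each plane position
    h = fieldmap.spacing
    planes = []
    for k in peaks:
        if 0 < k < len(corr) - 1:
            denom = corr[k - 1] - 2 * corr[k] + corr[k + 1]
            shift = 0.5 * (corr[k - 1] - corr[k + 1]) / denom if denom else 0.0
            planes.append(xc[i0 + k] + np.clip(shift, -1, 1) * h)
        else:
            planes.append(xc[i0 + k])
    planes = np.asarray(planes)
    if len(planes) < 2:
        raise FeatureError("fewer than 2 Talbot planes in the box; extend "
                           "the simulation domain downstream")
    spacings = np.diff(planes)
    # uncertainty: scatter of consecutive spacings, plus the fringe
    # deformation of the planes themselves — the per-fringe spread of the
    # bright-fringe maxima around each plane (edge diffraction warps the
    # self-images of a finite grating), floored at one grid cell
    deform = _plane_deformation(E, xc, yc, unit_centers, planes,
                                float(np.mean(spacings)))
    unc = max(float(spacings.std(ddof=0)), math.sqrt(2.0) * deform, h)
    return TalbotMeasurement(Z_T=float(spacings.mean()),
                             uncertainty=unc,
                             plane_positions=[float(v) for v in planes])


def _plane_deformation(E: np.ndarray, xc: np.ndarray, yc: np.ndarray,
                       unit_centers: np.ndarray, planes: np.ndarray,
                       z_est: float) -> float:
    """Median per-plane spread of bright-fringe maxima across the grating."""
    centers = unit_centers[1:-1] if len(unit_centers) > 4 else unit_centers
    spreads = []
    for plane in planes:
        xs = []
        for c in centers:
            j = int(np.argmin(np.abs(yc - c)))
            lo = int(np.searchsorted(xc, plane - 0.35 * z_est))
            hi = int(np.searchsorted(xc, plane + 0.35 * z_est))
            if hi - lo < 3:
                continue
            prof = E[lo:hi, j]
            xs.append(xc[lo + int(np.argmax(prof))])
        if len(xs) >= 3:
            spreads.append(np.std(xs))
    return float(np.median(spreads)) if spreads else 0.0


def find_gmr(scene: GeometryScene, lam_window: tuple[float, float],
             config: SimulationConfig,
             coarse_step: float = 10.0,
             fine_halfwidth: float | None = None,
             box: tuple[float, float, float, float] | None = None,
             mode_index: int = 0) -> GmrResonance:
    """Guided-mode resonance of a grid-like element in a wavelength window.

    A coarse sweep (default 10 nm) of the mean E_Norm inside the silica of
    the grid region locates the resonance; a 1 nm fine sweep around the
    coarse maximum refines λ_GMR.  E_Norm,GMR is the maximum interior field
    at resonance.
    """
    if "grid" not in scene.meta:
        raise FeatureError("scene has no grid-like element")
    lo, hi = lam_window
    if not (250.0 <= lo < hi <= 800.0):
        raise FeatureError("window must lie inside 250-800 nm")
    if box is None:
        box = (0.0, -config.box_height_y / 2.0,
               config.box_width_x, config.box_height_y / 2.0)
    examined: list[tuple[float, float]] = []
    cache: dict[float, tuple[float, float]] = {}

    def metric(lam: float) -> float:
        lam = round(float(lam), 3)
        if lam in cache:
            return cache[lam][0]
        res = config.resolution_for(lam, scene.optics.n_v)
        grid = rasterize(scene, res, box=box, lam_min_nm=lam)
        fm = solve(grid, lam, config)
        o = scene.optics
        gx0, gy0, gx1, gy1 = scene.meta["grid_bbox"]
        xc, yc = fm.x_centers(), fm.y_centers()
        im = (xc >= gx0) & (xc <= gx1)
        jm = (yc >= gy0) & (yc <= gy1)
        sub_n = grid.n[np.ix_(im, jm)]
        sub_E = fm.E_norm[np.ix_(im, jm)]
        silica = sub_n >= 0.5 * (o.n_v + o.n_m)
        mean_E = float(sub_E[silica].mean())
        max_E = float(sub_E[silica].max())
        cache[lam] = (mean_E, max_E)
        examined.append((lam, mean_E))
        return mean_E

    coarse = np.arange(lo, hi + 1e-9, coarse_step)
    vals = [metric(l) for l in coarse]
    lam_best = float(coarse[int(np.argmax(vals))])
    hw = fine_halfwidth if fine_halfwidth is not None else coarse_step / 2.0 + 2.0
    fine = np.arange(math.ceil(max(lo, lam_best - hw)),
                     math.floor(min(hi, lam_best + hw)) + 0.5, 1.0)
    fvals = [metric(l) for l in fine]
    lam_star = float(fine[int(np.argmax(fvals))])
    mean_E, max_E = cache[round(lam_star, 3)]
    if max_E < 1.2 * config.E_input:
        raise FeatureError(
            f"no resonance found in [{lo:g}, {hi:g}] nm: interior field "
            f"never exceeds 1.2×E_input (max {max_E:.3f})")
    return GmrResonance(lam_nm=lam_star, E_Norm_GMR=max_E,
                        mode_index=mode_index, sweep=sorted(examined))
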