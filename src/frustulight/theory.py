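"""Closed-form optical predictors for the valve's integrated optical components.

These are the analytic ground truths against which the numerical field maps
are compared:

* single-slab (thin-film) reflectance/transmittance spectra from the
  transfer-matrix method at normal incidence,
* interference extrema wavelengths of a thin slab, 2·n_sl·D_sl = m·λ
  (destructive reflection) and (m + ½)·λ (constructive reflection, carrying
  the π phase shift of the thin-to-thick reflection),
* the Talbot self-imaging length of a small-period transmission grating,
* the allowed diffraction orders of a grating from the grating equation,
* mode cutoffs of the fibre-like (mantle / girdle band) slab waveguides.

Wavelengths are in nm, transverse dimensions in µm.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

UM_PER_NM = 1e-3


class NoTalbotRegime(ValueError):
    """Raised when λ ≥ n_m·d and the ±1 diffraction orders do not propagate."""


@dataclass
class SlabSpec:
    """A thin homogeneous slab: thickness D_sl (µm), index n_sl, in medium n_m."""

    D_sl: float
    n_sl: float = 1.46
    n_m: float = 1.00
    L_sl: float = float("inf")

    def __post_init__(self) -> None:
        if self.D_sl <= 0:
            raise ValueError("slab thickness must be positive")


@dataclass
class GratingSpec:
    """1D transmission grating: pitch d (µm), fill factor ff, thickness D (µm)."""

    d: float
    ff: float = 0.7
    D: float = 0.17
    N_units: int = 11
    n_v: float = 1.46
    n_m: float = 1.00

    def __post_init__(self) -> None:
        if not 0.0 < self.ff <= 1.0:
            raise ValueError("fill factor must lie in (0, 1]")
        if self.N_units < 2:
            raise ValueError("a grating needs at least 2 units")

    @property
    def span(self) -> float:
        """Total transverse span: (N−1) pitches plus one unit width (µm)."""
        return (self.N_units - 1) * self.d + self.ff * self.d


@dataclass
class WaveguideSpec:
    """Symmetric slab waveguide: core width W_wg (µm), indices n_core > n_clad."""

    W_wg: float
    n_core: float = 1.46
    n_clad: float = 1.00

    def __post_init__(self) -> None:
        if self.n_core <= self.n_clad:
            raise ValueError("guiding requires n_core > n_clad")


def fresnel_slab_spectrum(slab: SlabSpec, wavelengths_nm) -> pd.DataFrame:
    """Reflected/transmitted intensity of a single lossless slab vs wavelength.

    Single-layer transfer-matrix (Airy) result at normal incidence; the slab
    is embedded in the same medium on both sides, so R + T = 1 exactly.

    Returns a DataFrame indexed by ``wavelength_nm`` with columns ``R``, ``T``.
    """
    lam = np.asarray(wavelengths_nm, dtype=float)
    if np.any(lam <= 0):
        raise ValueError("wavelengths must be positive")
    r01 = (slab.n_m - slab.n_sl) / (slab.n_m + slab.n_sl)
    delta = 2.0 * np.pi * slab.n_sl * slab.D_sl / (lam * UM_PER_NM)
    phase = np.exp(2j * delta)
    r = (r01 - r01 * phase) / (1.0 - r01**2 * phase)
    R = np.abs(r) ** 2
    return pd.DataFrame({"R": R, "T": 1.0 - R},
                        index=pd.Index(lam, name="wavelength_nm"))


def thin_film_extrema(slab: SlabSpec, lam_window_nm: tuple[float, float]) -> dict:
    """Wavelengths of constructive/destructive reflection inside a window.

    Constructive reflection (destructive transmission) at
    λ = 2·n_sl·D_sl/(m + ½) and destructive reflection at λ = 2·n_sl·D_sl/m,
    m ≥ 1, rounded to the nearest nm.  The positions depend on n_sl and D_sl
    only — not on the surrounding medium.
    """
    lo, hi = lam_window_nm
    if not (0 < lo < hi):
        raise ValueError("wavelength window must satisfy 0 < lo < hi")
    opd_nm = 2.0 * slab.n_sl * slab.D_sl / UM_PER_NM  # 2 n D in nm
    constructive, destructive = [], []
    m = 1
    while True:
        lam_c = opd_nm / (m - 0.5)
        lam_d = opd_nm / m
        if lo <= lam_c <= hi:
            constructive.append(round(lam_c))
        if lo <= lam_d <= hi:
            destructive.append(round(lam_d))
        if max(lam_c, lam_d) < lo:
            break
        m += 1
    return {"constructive_reflection_nm": sorted(constructive),
            "destructive_reflection_nm": sorted(destructive)}


def talbot_length(lam_vacc_nm: float, n_m: float, d_um: float) -> float:
    """Talbot length Z_T (µm) of a small-period grating.

    Z_T = (λ/n_m) / (1 − sqrt(1 − (λ/(n_m·d))²)); valid only while the ±1
    diffraction orders propagate, i.e. λ < n_m·d.  Reduces to the paraxial
    2·d²·n_m/λ when d ≫ λ.
    """
    lam_um = lam_vacc_nm * UM_PER_NM
    ratio = lam_um / (n_m * d_um)
    if ratio >= 1.0:
        raise NoTalbotRegime(
            f"no Talbot regime: λ={lam_vacc_nm:g} nm >= n_m*d="
            f"{n_m * d_um / UM_PER_NM:g} nm (±1 orders evanescent)")
    lam_medium = lam_um / n_m
    return lam_medium / (1.0 - np.sqrt(1.0 - ratio**2))


def grating_orders(lam_vacc_nm: float, n_m: float, d_um: float) -> set[int]:
    """Propagating diffraction orders m of a grating: |m|·λ < n_m·d.

    Follows sin θ_m = m·λ/(n_m·d); order m propagates while |sin θ_m| < 1.
    Always contains 0; symmetric in ±m.
    """
    lam_um = lam_vacc_nm * UM_PER_NM
    x = n_m * d_um / lam_um
    m_max = max(int(np.ceil(x - 1e-12)) - 1, 0)  # largest m with m < x, strict
    return set(range(-m_max, m_max + 1))


def waveguide_cutoff(wg: WaveguideSpec, mode_index: int) -> float:
    """Cutoff vacuum wavelength (nm) of mode m of a fibre-like component.

    Uses the mode-count ratio 2·W_wg·n_core/λ_vacc: mode m is supported for
    λ < 2·W_wg·n_core/m.  The fundamental (m = 0) is supported at every
    wavelength, signalled by returning ``inf``.
    """
    if mode_index < 0:
        raise ValueError("mode index must be >= 0")
    if mode_index == 0:
        return float("inf")
    return 2.0 * wg.W_wg * wg.n_core / mode_index / UM_PER_NM


def waveguide_cutoff_exact(wg: WaveguideSpec, mode_index: int) -> float:
    """Exact symmetric-slab TE cutoff (nm): λ_c = 2·W·sqrt(n_core²−n_clad²)/m.

    Alternative to :func:`waveguide_cutoff`, which uses the simplified
    mode-count ratio; kept clearly separate because the two differ whenever
    n_clad > 0 contributes.
    """
    if mode_index < 0:
        raise ValueError("mode index must be >= 0")
    if mode_index == 0:
        return float("inf")
    na = np.sqrt(wg.n_core**2 - wg.n_clad**2)
    return 2.0 * wg.W_wg * na / mode_index / UM_PER_NM
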