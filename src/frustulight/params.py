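"""Structural parameters of the *Gomphonema parvulum* valve and optical constants.

All lengths are in micrometres (µm); wavelengths elsewhere in the package are
quoted in nanometres (nm).  The defaults of :class:`ValveParameters` are the
weighted means of the statistical structural analysis of the valve (SEM /
FIB-SEM measurement campaign): valve face thickness ``D_v``, striae spacing
``d_str``, areolae spacing ``d_a``, mantle dimensions, sternum and nodule
dimensions, raphe slit geometry, and the girdle-band envelope.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Literal


@dataclass
class OpticalConstants:
    """Refractive indices of the valve silica and the surrounding medium.

    n_v : refractive index of the amorphous biosilica (default 1.46).
    n_m : refractive index of the medium; 1.00 for air, 1.33 for water.
    """

    n_v: float = 1.46
    n_m: float = 1.00

    def __post_init__(self) -> None:
        if self.n_m < 1.0:
            raise ValueError(f"n_m must be >= 1.0, got {self.n_m}")
        if self.n_v <= 0:
            raise ValueError(f"n_v must be positive, got {self.n_v}")

    @property
    def contrast(self) -> float:
        """Index contrast Δn = n_v − n_m."""
        return self.n_v - self.n_m


AIR = OpticalConstants(n_v=1.46, n_m=1.00)
WATER = OpticalConstants(n_v=1.46, n_m=1.33)


@dataclass
class ValveParameters:
    """Weighted-mean structural parameters of the valve (µm unless noted).

    The valve face is a thin silica slab (thickness ``D_v``) rimmed by a
    curved, tilted mantle (height ``h_M``, width ``W_M``, tilt ``theta_M``
    degrees from the face plane).  Rows of areolae (pores) with spacing
    ``d_a`` form striae; the solid costae between consecutive striae repeat
    with spacing ``d_str_min``..``d_str_max``.  The sternum is a thickened rib
    (max thickness ``D_S``, half-width ``half_W_s``) carrying the raphe slits
    (width ``W_ra``, separated by ``d_ra`` at the central nodule).  The nodule
    is a dome (thickness ``D_nod``, width ``W_nod``, length ``L_nod``) shifted
    ``nodule_offset`` along the apical axis; a single stria there is shortened
    by ``shortened_stria_by``.  Girdle bands are rectangles ``W_girdle`` ×
    ``H_girdle`` stacked with gap ``d_girdle``.
    """

    L_v: float = 7.1            # valve length
    W_v: float = 4.59           # valve width
    D_v: float = 0.17           # valve face thickness
    D_nod: float = 0.38         # nodule-zone thickness
    W_nod: float = 0.86         # nodule-zone width
    L_nod: float = 1.568        # nodule-zone length
    D_S: float = 0.26           # sternum max thickness
    half_W_s: float = 0.32      # sternum half-width
    L_ra: float = 5.8           # raphe slit length
    W_ra: float = 0.023         # raphe slit width
    d_ra: float = 0.54          # raphe slit spacing at nodule
    d_str_min: float = 0.49     # min striae spacing (centre to centre)
    d_str_max: float = 0.57     # max striae spacing (centre to centre)
    d_a: float = 0.214          # areolae spacing (centre to centre)
    diam_a_ext: float = 0.100   # areola diameter, external face
    diam_a_int: float = 0.15    # areola diameter, internal face
    h_M: float = 0.58           # mantle height
    W_M: float = 0.184          # mantle width
    W_occ: float = 0.017        # pore-occlusion slit width
    D_occ: float = 0.02         # pore-occlusion thickness
    n_striae: int = 13          # visible striae per valve
    nodule_offset: float = 0.18     # apical shift of the nodule
    shortened_stria_by: float = 1.0  # shortening of the single defect stria
    theta_M: float = 70.0       # mantle tilt, degrees from face plane
    W_girdle: float = 0.184     # girdle band width (= W_M)
    H_girdle: float = 2.84      # girdle band height
    d_girdle: float = 0.01      # girdle band spacing
    W_M_CS_range: tuple[float, float] = (0.184, 0.334)  # per-CS mantle width

    def __post_init__(self) -> None:
        for name, value in asdict(self).items():
            if name in ("W_M_CS_range", "n_striae"):
                continue
            if isinstance(value, (int, float)) and value <= 0:
                raise ValueError(f"{name} must be strictly positive, got {value}")
        if self.d_str_min > self.d_str_max:
            raise ValueError("d_str_min must not exceed d_str_max")
        if self.diam_a_ext > self.diam_a_int:
            raise ValueError("external areola diameter exceeds internal")
        if self.diam_a_int >= min(self.d_str_min, self.L_v, self.W_v):
            raise ValueError("areola diameter must be smaller than the striae "
                             "spacing and valve extents")
        if not (self.D_v <= self.D_S <= self.D_nod):
            raise ValueError("expected D_v <= D_S <= D_nod")

    @classmethod
    def from_dict(cls, d: dict) -> "ValveParameters":
        known = {k: v for k, v in d.items() if k in cls.__dataclass_fields__}
        if "W_M_CS_range" in known and isinstance(known["W_M_CS_range"], list):
            known["W_M_CS_range"] = tuple(known["W_M_CS_range"])
        return cls(**known)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["W_M_CS_range"] = list(self.W_M_CS_range)
        return d


Orientation = Literal["external_first", "internal_first"]


@dataclass
class CrossSectionSpec:
    """Selector for one 2D cross-section (CS) of the valve.

    family : ``"long"`` (longitudinal, indices 1–7 plus the defect variant
        ``"4*"``), ``"ver"`` (vertical, indices 1–5), or ``"analytic"``.
    orientation : ``external_first`` (wave hits the flat external face, the
        default) or ``internal_first`` (CS rotated 180°).
    tilt_deg : rigid tilt θ_inc of the whole CS, in [-30, 30] degrees.
    W_M_CS : mantle width for this slicing position, within the per-CS range.
    """

    family: Literal["long", "ver", "analytic"] = "long"
    index: str = "5"
    orientation: Orientation = "external_first"
    tilt_deg: float = 0.0
    include_occlusions: bool = False
    include_girdle_bands: bool = False
    include_hypovalve: bool = False
    W_M_CS: float | None = None

    _LONG = ("1", "2", "3", "4", "4*", "5", "6", "7")
    _VER = ("1", "2", "3", "4", "5")

    def __post_init__(self) -> None:
        self.index = str(self.index)
        if self.family == "long" and self.index not in self._LONG:
            raise ValueError(f"unknown longitudinal CS index {self.index!r}")
        if self.family == "ver" and self.index not in self._VER:
            raise ValueError(f"unknown vertical CS index {self.index!r}")
        if not -30.0 <= self.tilt_deg <= 30.0:
            raise ValueError("tilt_deg must lie in [-30, 30] degrees")
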