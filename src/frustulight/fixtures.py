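"""Synthetic fixtures for every pipeline stage, each with an attached
closed-form ground truth.

Fixtures are deterministic per (kind, parameters, seed) and carry their
oracle in ``ground_truth`` so that tests compare the numerical pipeline
against an independent analytic value: the transfer-matrix spectrum for the
uniform slab, the Talbot-length formula for the analytic grating, and the
generating parameters for the synthetic measurement tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import theory
from .geometry import GeometryScene, build_analytic_component
from .params import OpticalConstants
from .stats import MeasurementTable, build_table_from_synthetic

KINDS = ("homogeneous", "uniform_slab", "analytic_grid", "two_slit",
         "measurement_table")


@dataclass
class FixtureSpec:
    kind: str
    parameters: dict = field(default_factory=dict)
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ValueError(f"unknown fixture kind {self.kind!r}; "
                             f"choose from {KINDS}")
        if self.kind == "measurement_table" and self.seed is None:
            raise ValueError("measurement_table fixtures require a seed")


@dataclass
class Fixture:
    spec: FixtureSpec
    scene: GeometryScene | None
    table: MeasurementTable | None
    ground_truth: dict


def make_fixture(spec: FixtureSpec) -> Fixture:
    """Build one synthetic fixture with its documented ground truth."""
    p = dict(spec.parameters)
    if spec.kind == "homogeneous":
        optics = OpticalConstants(n_v=p.get("n_v", 1.46), n_m=p.get("n_m", 1.0))
        scene = GeometryScene([], optics, "homogeneous", {"face_x": 4.0})
        return Fixture(spec, scene, None,
                       {"E_norm": 1.0, "R": 0.0, "T": 1.0})

    if spec.kind == "uniform_slab":
        D = p.get("D", 0.17)
        L = p.get("L", 30.0)
        optics = OpticalConstants(n_v=p.get("n_v", 1.46), n_m=p.get("n_m", 1.0))
        scene = build_analytic_component("slab", {"L": L, "D": D}, optics,
                                         face_x=p.get("face_x", 4.0))
        slab = theory.SlabSpec(D_sl=D, n_sl=optics.n_v, n_m=optics.n_m)
        lam = np.arange(300.0, 801.0, 50.0)
        spectrum = theory.fresnel_slab_spectrum(slab, lam)
        return Fixture(spec, scene, None,
                       {"oracle": "single-layer transfer matrix",
                        "slab": slab, "spectrum": spectrum})

    if spec.kind == "analytic_grid":
        d = p.get("d", 0.5)
        ff = p.get("ff", 0.7)
        D = p.get("D", 0.17)
        N = p.get("N", 11)
        optics = OpticalConstants(n_v=p.get("n_v", 1.46), n_m=p.get("n_m", 1.0))
        scene = build_analytic_component(
            "grid", {"d": d, "ff": ff, "D": D, "N": N}, optics,
            face_x=p.get("face_x", 4.0))
        zt = {}
        for lam in p.get("wavelengths_nm", (330.0, 350.0, 400.0)):
            try:
                zt[lam] = theory.talbot_length(lam, optics.n_m, d)
            except theory.NoTalbotRegime:
                zt[lam] = None
        return Fixture(spec, scene, None,
                       {"oracle": "small-period Talbot-length formula",
                        "Z_T_um": zt, "d": d})

    if spec.kind == "two_slit":
        # a slab pierced by two symmetric slits: a minimal scene whose
        # downstream pattern splits into two interference patches
        from shapely.geometry import box as shapely_box
        from shapely.ops import unary_union
        L = p.get("L", 8.0)
        D = p.get("D", 0.17)
        slit_w = p.get("slit_width", 0.4)
        sep = p.get("separation", 2.0)
        face_x = p.get("face_x", 4.0)
        optics = OpticalConstants(n_v=p.get("n_v", 1.46), n_m=p.get("n_m", 1.0))
        slab = shapely_box(face_x, -L / 2, face_x + D, L / 2)
        for sgn in (+1, -1):
            slab = slab.difference(shapely_box(
                face_x - 0.1, sgn * sep / 2 - slit_w / 2,
                face_x + D + 0.1, sgn * sep / 2 + slit_w / 2))
        scene = GeometryScene(
            [g for g in getattr(slab, "geoms", [slab])], optics, "two_slit",
            {"face_x": face_x, "exit_x": face_x + D,
             "slit_centers": [-sep / 2, sep / 2]})
        return Fixture(spec, scene, None, {"n_patches": 2})

    # measurement_table
    truth = p.get("truth", 0.17)
    table = build_table_from_synthetic(
        n_valves=p.get("n_valves", 6), truth=truth,
        within_sd=p.get("within_sd", 0.01), between_sd=p.get("between_sd", 0.004),
        seed=spec.seed, parameter=p.get("parameter", "D_v"),
        n_per_valve=p.get("n_per_valve", 10))
    return Fixture(spec, None, table,
                   {"truth": truth, "within_sd": p.get("within_sd", 0.01),
                    "between_sd": p.get("between_sd", 0.004)})
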