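"""Serialization: GeoJSON scenes, SVG previews, VTK rasters/fields, CSV tables."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
from shapely.geometry import mapping, shape

from .geometry import GeometryScene, IndexGrid
from .params import OpticalConstants
from .solver import FieldMap


def scene_to_geojson(scene: GeometryScene, path: str | Path) -> None:
    features = [{
        "type": "Feature",
        "properties": {"material": "silica"},
        "geometry": mapping(p),
    } for p in scene.silica]
    doc = {
        "type": "FeatureCollection",
        "properties": {
            "label": scene.label,
            "n_v": scene.optics.n_v,
            "n_m": scene.optics.n_m,
            "meta": _jsonable(scene.meta),
        },
        "features": features,
    }
    Path(path).write_text(json.dumps(doc))


def scene_from_geojson(path: str | Path) -> GeometryScene:
    doc = json.loads(Path(path).read_text())
    props = doc.get("properties", {})
    optics = OpticalConstants(n_v=props.get("n_v", 1.46),
                              n_m=props.get("n_m", 1.0))
    polys = [shape(f["geometry"]) for f in doc["features"]
             if f.get("properties", {}).get("material", "silica") == "silica"]
    return GeometryScene(polys, optics, props.get("label", ""),
                         props.get("meta", {}))


def scene_to_svg(scene: GeometryScene, path: str | Path,
                 size: int = 640) -> None:
    x0, y0, x1, y1 = scene.bounds
    pad = 0.05 * max(x1 - x0, y1 - y0, 1e-6)
    x0, y0, x1, y1 = x0 - pad, y0 - pad, x1 + pad, y1 + pad
    w, hgt = x1 - x0, y1 - y0
    scale = size / max(w, hgt)
    paths = []
    for p in scene.silica:
        rings = [p.exterior, *p.interiors]
        d = ""
        for ring in rings:
            pts = [f"{(x - x0) * scale:.2f},{(y1 - y) * scale:.2f}"
                   for x, y in ring.coords]
            d += "M" + " L".join(pts) + " Z "
        paths.append(f'<path d="{d}" fill="#8bb" fill-rule="evenodd" '
                     'stroke="#246" stroke-width="0.5"/>')
    svg = (f'<svg xmlns="http://www.w3.org/2000/svg" '
           f'width="{w * scale:.0f}" height="{hgt * scale:.0f}">'
           + "".join(paths) + "</svg>")
    Path(path).write_text(svg)


def grid_to_vtk(grid: IndexGrid, path: str | Path,
                name: str = "refractive_index") -> None:
    _write_vtk_scalar(grid.n, grid.origin, grid.spacing, path, name)


def fieldmap_to_vtk(fm: FieldMap, path: str | Path) -> None:
    _write_vtk_scalar(fm.E_norm, fm.origin, fm.spacing, path, "E_Norm")


def _write_vtk_scalar(arr: np.ndarray, origin, spacing: float,
                      path: str | Path, name: str) -> None:
    nx, ny = arr.shape
    lines = [
        "# vtk DataFile Version 3.0", name, "ASCII",
        "DATASET STRUCTURED_POINTS",
        f"DIMENSIONS {nx} {ny} 1",
        f"ORIGIN {origin[0] + spacing / 2:.6g} {origin[1] + spacing / 2:.6g} 0",
        f"SPACING {spacing:.6g} {spacing:.6g} 1",
        f"POINT_DATA {nx * ny}",
        f"SCALARS {name} float 1",
        "LOOKUP_TABLE default",
    ]
    # VTK structured points iterate x fastest
    vals = arr.T.ravel()
    lines.extend(" ".join(f"{v:.6g}" for v in vals[i:i + 9])
                 for i in range(0, len(vals), 9))
    Path(path).write_text("\n".join(lines) + "\n")


def fieldmap_to_png(fm: FieldMap, path: str | Path,
                    vmin: float = 0.0, vmax: float = 2.0) -> None:
    """Blue-white-red E_Norm rendering (white at E_input)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    fig, ax = plt.subplots(figsize=(6, 6 * fm.field.shape[1] / fm.field.shape[0]))
    x = fm.x_centers()
    y = fm.y_centers()
    im = ax.imshow(fm.E_norm.T, origin="lower", cmap="bwr_r",
                   vmin=vmin, vmax=vmax,
                   extent=(x[0], x[-1], y[0], y[-1]), aspect="equal")
    ax.set_xlabel("x (µm)")
    ax.set_ylabel("y (µm)")
    fig.colorbar(im, ax=ax, label="E_Norm (V/m)")
    fig.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(fig)


def cutline_to_csv(samples: np.ndarray, path: str | Path) -> None:
    import pandas as pd
    pd.DataFrame(samples, columns=["x", "y", "E_Norm"]).to_csv(path, index=False)


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj
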