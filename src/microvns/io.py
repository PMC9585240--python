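"""Output writers: legacy-ASCII VTK structured grids, CSV, manifests."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import yaml


def write_vtk_structured(path, field_map, name: str = "field") -> None:
    """Write a FieldMap as a legacy ASCII VTK structured-points file."""
    g = field_map.grid
    v = field_map.values
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\n")
        fh.write(f"{field_map.quantity}\nASCII\nDATASET STRUCTURED_POINTS\n")
        fh.write(f"DIMENSIONS {g.shape[0]} {g.shape[1]} {g.shape[2]}\n")
        fh.write(
            "ORIGIN "
            + " ".join(f"{g.origin[i] + 0.5 * g.spacing[i]:.9e}" for i in range(3))
            + "\n"
        )
        fh.write("SPACING " + " ".join(f"{s:.9e}" for s in g.spacing) + "\n")
        n = g.shape[0] * g.shape[1] * g.shape[2]
        fh.write(f"POINT_DATA {n}\n")
        fh.write(f"VECTORS {name} float\n")
        # VTK expects x fastest
        flat = np.transpose(v, (2, 1, 0, 3)).reshape(-1, 3)
        np.savetxt(fh, flat, fmt="%.6e")


def write_vtk_polyline(path, current_path) -> None:
    """Write a CurrentPath as a legacy ASCII VTK polyline."""
    pts = current_path.points
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\n")
        fh.write("coil\nASCII\nDATASET POLYDATA\n")
        fh.write(f"POINTS {len(pts)} float\n")
        np.savetxt(fh, pts, fmt="%.9e")
        fh.write(f"LINES 1 {len(pts) + 1}\n")
        fh.write(str(len(pts)) + " " + " ".join(map(str, range(len(pts)))) + "\n")


def config_hash(config: dict) -> str:
    return hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def write_manifest(outdir, config: dict, seeds) -> None:
    from . import __version__

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "package_version": __version__,
        "config_hash": config_hash(config),
        "seeds": seeds,
        "config": config,
    }
    with open(outdir / "manifest.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=False)
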