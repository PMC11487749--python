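"""Standard-format I/O: GIFTI and PLY surfaces, per-vertex fields, CSV tables.

Stage outputs are plain text (CSV, GIFTI XML, PLY) so external tooling can
consume them; every table written by the pipeline carries a provenance
comment line with the config hash and seed.
"""

from __future__ import annotations

import io as _io
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import trimesh
import yaml

__all__ = [
    "write_surface_gifti",
    "read_surface_gifti",
    "write_surface_ply",
    "read_surface",
    "write_vertex_field_gifti",
    "read_vertex_field_gifti",
    "write_labels_text",
    "read_labels_text",
    "write_cohort_csv",
    "read_cohort_csv",
    "write_config_yaml",
    "read_config_yaml",
]


def write_surface_gifti(mesh: trimesh.Trimesh, path) -> None:
    img = nib.gifti.GiftiImage(
        darrays=[
            nib.gifti.GiftiDataArray(
                np.asarray(mesh.vertices, dtype=np.float32),
                intent="NIFTI_INTENT_POINTSET",
            ),
            nib.gifti.GiftiDataArray(
                np.asarray(mesh.faces, dtype=np.int32),
                intent="NIFTI_INTENT_TRIANGLE",
            ),
        ]
    )
    nib.save(img, str(path))


def read_surface_gifti(path) -> trimesh.Trimesh:
    img = nib.load(str(path))
    verts, faces = img.agg_data(("pointset", "triangle"))
    return trimesh.Trimesh(vertices=np.asarray(verts), faces=np.asarray(faces), process=False)


def write_surface_ply(mesh: trimesh.Trimesh, path) -> None:
    Path(path).write_bytes(mesh.export(file_type="ply", encoding="ascii"))


def read_surface(path) -> trimesh.Trimesh:
    """Read a surface from GIFTI (.gii) or anything trimesh loads (e.g. PLY)."""
    p = str(path)
    if p.endswith(".gii"):
        return read_surface_gifti(p)
    loaded = trimesh.load(p, process=False)
    return trimesh.Trimesh(vertices=loaded.vertices, faces=loaded.faces, process=False)


def write_vertex_field_gifti(values: np.ndarray, path) -> None:
    img = nib.gifti.GiftiImage(
        darrays=[
            nib.gifti.GiftiDataArray(
                np.asarray(values, dtype=np.float32), intent="NIFTI_INTENT_NONE"
            )
        ]
    )
    nib.save(img, str(path))


def read_vertex_field_gifti(path) -> np.ndarray:
    return np.asarray(nib.load(str(path)).darrays[0].data, dtype=float)


def write_labels_text(labels: np.ndarray, path) -> None:
    """One integer label per line, aligned to the mesh vertex order."""
    np.savetxt(str(path), np.asarray(labels, dtype=int), fmt="%d")


def read_labels_text(path) -> np.ndarray:
    return np.loadtxt(str(path), dtype=int).ravel()


def write_cohort_csv(table: pd.DataFrame, path, provenance: dict | None = None) -> None:
    """Write a cohort/results table; optional provenance header comment."""
    buf = _io.StringIO()
    if provenance:
        items = " ".join(f"{k}={v}" for k, v in sorted(provenance.items()))
        buf.write(f"# {items}\n")
    table.to_csv(buf, index=False)
    Path(path).write_text(buf.getvalue())


def read_cohort_csv(path) -> pd.DataFrame:
    return pd.read_csv(str(path), comment="#")


def write_config_yaml(obj: dict, path) -> None:
    Path(path).write_text(yaml.safe_dump(obj, sort_keys=True))


def read_config_yaml(path) -> dict:
    return yaml.safe_load(Path(path).read_text())
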