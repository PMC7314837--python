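"""Readers and writers for every format the pipeline touches.

Native interchange format: delimited (tab-separated) tables with a key-value
metadata header in ``# key = value`` comment lines — robust, diffable and
language-neutral. Images and masks travel as TIFF; MAT-file import/export is
provided for compatibility with the public island datasets, whose per-island
folders contain particle stacks (c1_island#.tif), cell stacks
(c2_island#.tif), a traction-free reference (c1_tryp_island#.tif), a
boundary mask (domain.tif) and processed .mat results.
"""
from __future__ import annotations

import glob
import os
from dataclasses import dataclass, field as _dc_field
from typing import Optional

import numpy as np
import tifffile

from .domain import IslandDomain, domain_from_mask
from .fields import GriddedVectorField, StressField

__all__ = [
    "write_field", "read_field", "write_stress", "read_stress",
    "write_mask_tiff", "read_mask_tiff", "write_image_tiff", "read_image_tiff",
    "write_mat_fields", "read_mat_fields", "IslandRecord",
    "read_island_record", "write_synthetic_bundle", "read_metadata",
    "write_metadata",
]


# ---------------------------------------------------------------------------
# key-value metadata

def write_metadata(path: str, meta: dict) -> None:
    with open(path, "w") as fh:
        for k, v in meta.items():
            fh.write(f"{k} = {v}\n")


def read_metadata(path: str) -> dict:
    meta: dict = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or "=" not in line:
                continue
            k, v = line.split("=", 1)
            meta[k.strip()] = _coerce(v.strip())
    return meta


def _coerce(s: str):
    for cast in (int, float):
        try:
            return cast(s)
        except ValueError:
            pass
    if s in ("True", "False"):
        return s == "True"
    return s


# ---------------------------------------------------------------------------
# gridded tables

_SAFE_META = (str, int, float, bool)


def _write_table(path: str, columns: dict[str, np.ndarray],
                 x: np.ndarray, y: np.ndarray, meta: dict) -> None:
    X, Y = np.meshgrid(x, y)
    data = [X.ravel(), Y.ravel()] + [np.asarray(c).ravel() for c in columns.values()]
    header_meta = {k: v for k, v in meta.items() if isinstance(v, _SAFE_META)}
    with open(path, "w") as fh:
        for k, v in header_meta.items():
            fh.write(f"# {k} = {v}\n")
        fh.write("# columns: x, y in um; y increases downward (image "
                 "convention)\n")
        fh.write("x\ty\t" + "\t".join(columns) + "\n")
        np.savetxt(fh, np.column_stack(data), delimiter="\t", fmt="%.10g")


def _read_table(path: str):
    meta: dict = {}
    names: list[str] = []
    rows: list[list[float]] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line[1:].strip()
                if "=" in body:
                    k, v = body.split("=", 1)
                    meta[k.strip()] = _coerce(v.strip())
            elif not names:
                names = line.split()
            else:
                rows.append([float(t) for t in line.split()])
    values = np.asarray(rows, dtype=float)
    x = np.unique(values[:, 0])
    y = np.unique(values[:, 1])
    grids = {}
    nx, ny = x.size, y.size
    order = np.lexsort((values[:, 0], values[:, 1]))
    values = values[order]
    for k, name in enumerate(names[2:], start=2):
        grids[name] = values[:, k].reshape(ny, nx)
    return x, y, grids, meta


def write_field(path: str, field: GriddedVectorField) -> None:
    """Write a vector field as a TSV table with a metadata header."""
    cols = {"u": field.u, "v": field.v}
    if field.quality is not None:
        cols["quality"] = field.quality
    meta = dict(field.meta, units=field.units)
    if field.time_index is not None:
        meta["time_index"] = field.time_index
    _write_table(path, cols, field.x, field.y, meta)


def read_field(path: str) -> GriddedVectorField:
    x, y, grids, meta = _read_table(path)
    units = str(meta.pop("units", "um"))
    time_index = meta.pop("time_index", None)
    return GriddedVectorField(x, y, grids["u"], grids["v"], units=units,
                              quality=grids.get("quality"),
                              time_index=time_index, meta=meta)


def write_stress(path: str, stress: StressField) -> None:
    cols = {"sxx": stress.sxx, "syy": stress.syy, "sxy": stress.sxy}
    for name in ("s1", "s2", "theta"):
        val = getattr(stress, name)
        if val is not None:
            cols[name] = val
    _write_table(path, cols, stress.x, stress.y,
                 dict(stress.meta, units=stress.units))


def read_stress(path: str) -> StressField:
    x, y, grids, meta = _read_table(path)
    units = str(meta.pop("units", "Pa"))
    return StressField(x, y, grids["sxx"], grids["syy"], grids["sxy"],
                       s1=grids.get("s1"), s2=grids.get("s2"),
                       theta=grids.get("theta"), units=units, meta=meta)


# ---------------------------------------------------------------------------
# TIFF

def write_mask_tiff(path: str, mask: np.ndarray) -> None:
    tifffile.imwrite(path, (np.asarray(mask, bool) * np.uint8(255)))


def read_mask_tiff(path: str) -> np.ndarray:
    return np.asarray(tifffile.imread(path)) > 0


def write_image_tiff(path: str, images, bit_depth: int = 16) -> None:
    """Write one image or a stack as 8/16-bit TIFF, scaled to full range."""
    arr = np.asarray(images, dtype=float)
    if arr.ndim == 2:
        arr = arr[None]
    lo, hi = arr.min(), arr.max()
    scale = (2 ** bit_depth - 1) / (hi - lo) if hi > lo else 1.0
    dtype = np.uint16 if bit_depth == 16 else np.uint8
    out = ((arr - lo) * scale).astype(dtype)
    # grayscale pages, never RGB: a 3-frame stack must stay a 3-page stack
    tifffile.imwrite(path, out.squeeze(), photometric="minisblack")


def read_image_tiff(path: str) -> np.ndarray:
    """Read a single- or multi-page TIFF as float; stacks come back (nt, ny, nx)."""
    return np.asarray(tifffile.imread(path), dtype=float)


# ---------------------------------------------------------------------------
# MAT files

_MAT_SYNONYMS = {
    "displacements": {"u": ("u", "ux", "dx", "disp_x", "displ_x"),
                      "v": ("v", "uy", "dy", "disp_y", "displ_y")},
    "tractions": {"u": ("tx", "tract_x", "Tx", "traction_x", "u"),
                  "v": ("ty", "tract_y", "Ty", "traction_y", "v")},
    "stresses": {"sxx": ("sxx", "Sxx", "sigma_xx", "stress_xx"),
                 "syy": ("syy", "Syy", "sigma_yy", "stress_yy"),
                 "sxy": ("sxy", "Sxy", "sigma_xy", "stress_xy")},
}


def _find_var(data: dict, names: tuple[str, ...], kind: str):
    for n in names:
        if n in data:
            return np.asarray(data[n], dtype=float)
    found = sorted(k for k in data if not k.startswith("__"))
    raise ValueError(f"no variable matching {names} for kind '{kind}' in "
                     f"MAT file; found: {found}")


def write_mat_fields(path: str, fields, kind: str,
                     x: Optional[np.ndarray] = None,
                     y: Optional[np.ndarray] = None) -> None:
    """Export a field sequence to a MAT file using this package's names."""
    from scipy.io import savemat
    if kind not in _MAT_SYNONYMS:
        raise ValueError(f"kind must be one of {sorted(_MAT_SYNONYMS)}")
    if not isinstance(fields, (list, tuple)):
        fields = [fields]
    f0 = fields[0]
    out = {"x": f0.x if x is None else x, "y": f0.y if y is None else y}
    if kind == "stresses":
        out["sxx"] = np.stack([f.sxx for f in fields])
        out["syy"] = np.stack([f.syy for f in fields])
        out["sxy"] = np.stack([f.sxy for f in fields])
    else:
        key_u, key_v = ("u", "v") if kind == "displacements" else ("tx", "ty")
        out[key_u] = np.stack([f.u for f in fields])
        out[key_v] = np.stack([f.v for f in fields])
    savemat(path, out)


def read_mat_fields(path: str, kind: str):
    """Read a field sequence from a MAT file, mapping variable names
    defensively.

    Returns a list of :class:`GriddedVectorField` (displacements/tractions,
    one per time point) or :class:`StressField` (stresses). Unknown layouts
    raise an error listing the variable names that were found.
    """
    from scipy.io import loadmat
    if kind not in _MAT_SYNONYMS:
        raise ValueError(f"kind must be one of {sorted(_MAT_SYNONYMS)}")
    data = loadmat(path, squeeze_me=True)
    syn = _MAT_SYNONYMS[kind]
    comps = {k: _find_var(data, names, kind) for k, names in syn.items()}
    first = next(iter(comps.values()))
    if first.ndim == 2:
        comps = {k: v[None] for k, v in comps.items()}
        first = first[None]
    nt, ny, nx = first.shape
    if "x" in data and "y" in data:
        x = np.asarray(data["x"], float).ravel()
        y = np.asarray(data["y"], float).ravel()
        if x.size != nx or y.size != ny:
            x, y = np.arange(nx, dtype=float), np.arange(ny, dtype=float)
    else:
        x, y = np.arange(nx, dtype=float), np.arange(ny, dtype=float)
    out = []
    for t in range(nt):
        if kind == "stresses":
            out.append(StressField(x, y, comps["sxx"][t], comps["syy"][t],
                                   comps["sxy"][t]))
        else:
            units = "um" if kind == "displacements" else "Pa"
            out.append(GriddedVectorField(x, y, comps["u"][t], comps["v"][t],
                                          units=units, time_index=t))
    return out


# ---------------------------------------------------------------------------
# island records

@dataclass
class IslandRecord:
    """Paths and timing metadata for one island's raw data."""

    folder: str
    particle_stack: str          # c1_island#.tif
    reference_image: str         # c1_tryp_island#.tif
    mask_image: str              # domain.tif
    cell_stack: Optional[str] = None   # c2_island#.tif (optional member)
    dt: float = 10.0             # minutes between frames
    treatment_frame: Optional[int] = None  # first post-treatment frame index
    post_treatment_times: Optional[list[float]] = None
    meta: dict = _dc_field(default_factory=dict)

    def frame_times(self, n_frames: int) -> np.ndarray:
        """Time stamps (min, 0 = treatment) covering every frame.

        Pre-treatment frames count back from 0 in steps of dt; post-treatment
        frames use ``post_treatment_times`` when given (drug protocols resume
        imaging some time after dosing), else continue in steps of dt.
        """
        if self.treatment_frame is None:
            return np.arange(n_frames) * self.dt
        k = self.treatment_frame
        pre = (np.arange(k) - k) * self.dt
        n_post = n_frames - k
        if self.post_treatment_times is not None:
            post = np.asarray(self.post_treatment_times, float)[:n_post]
            if post.size != n_post:
                raise ValueError("post_treatment_times does not cover every "
                                 "post-treatment frame")
        else:
            post = np.arange(1, n_post + 1) * self.dt
        return np.concatenate([pre, post])


def _find_one(folder: str, pattern: str, required: bool) -> Optional[str]:
    hits = sorted(glob.glob(os.path.join(folder, pattern)))
    if not hits:
        if required:
            raise FileNotFoundError(
                f"island folder {folder!r} is missing a file matching "
                f"{pattern!r}")
        return None
    return hits[0]


def read_island_record(folder: str, dt: float = 10.0,
                       treatment_frame: Optional[int] = None,
                       post_treatment_times: Optional[list[float]] = None,
                       patterns: Optional[dict] = None) -> IslandRecord:
    """Locate and validate one island's files in a dataset folder.

    Follows the public dataset naming convention (configurable via
    ``patterns``): particle stack ``c1_island*.tif``, cells
    ``c2_island*.tif`` (optional, warns if absent), traction-free reference
    ``c1_tryp_island*.tif`` and mask ``domain.tif``. Image dimensions are
    checked for consistency.
    """
    import warnings
    pat = dict(particles="c1_island*.tif", cells="c2_island*.tif",
               reference="c1_tryp_island*.tif", mask="domain.tif")
    if patterns:
        pat.update(patterns)
    # the reference pattern also matches c1_island*; resolve reference first
    reference = _find_one(folder, pat["reference"], required=True)
    particle_hits = [p for p in sorted(glob.glob(os.path.join(folder, pat["particles"])))
                     if p != reference]
    if not particle_hits:
        raise FileNotFoundError(f"island folder {folder!r} is missing a file "
                                f"matching {pat['particles']!r}")
    particles = particle_hits[0]
    mask = _find_one(folder, pat["mask"], required=True)
    cells = _find_one(folder, pat["cells"], required=False)
    if cells is None:
        warnings.warn(f"island folder {folder!r} has no cell stack "
                      f"({pat['cells']}); velocities will be unavailable",
                      stacklevel=2)

    shapes = {}
    for name, p in (("particles", particles), ("reference", reference),
                    ("mask", mask)) + ((("cells", cells),) if cells else ()):
        arr = tifffile.TiffFile(p).pages[0].shape
        shapes[name] = tuple(arr[-2:])
    if len(set(shapes.values())) != 1:
        raise ValueError(f"inconsistent image dimensions across files: {shapes}")

    meta_path = os.path.join(folder, "metadata.txt")
    meta = read_metadata(meta_path) if os.path.exists(meta_path) else {}
    return IslandRecord(folder=folder, particle_stack=particles,
                        reference_image=reference, mask_image=mask,
                        cell_stack=cells, dt=dt,
                        treatment_frame=treatment_frame,
                        post_treatment_times=post_treatment_times, meta=meta)


# ---------------------------------------------------------------------------
# synthetic bundles

def write_synthetic_bundle(folder: str, island, n_cell_frames: int = 3,
                           cell_dt: float = 10.0) -> str:
    """Write a ground-truthed synthetic island in the island-record layout.

    Produces domain.tif, a particle image pair (reference + deformed), an
    advected cell-texture stack for velocity DIC, per-field ground-truth
    tables and a flat metadata file. Returns the folder path.
    """
    from .synthetic import render_advected_stack
    os.makedirs(folder, exist_ok=True)
    write_mask_tiff(os.path.join(folder, "domain.tif"), island.domain.mask)
    if island.speckle_reference is None:
        raise ValueError("island was synthesized without speckle images")
    write_image_tiff(os.path.join(folder, "c1_tryp_island1.tif"),
                     island.speckle_reference.data)
    write_image_tiff(os.path.join(folder, "c1_island1.tif"),
                     island.speckle_deformed.data)
    cells = render_advected_stack(island.velocity, n_cell_frames, cell_dt,
                                  density=island.params.get("speckle_density", 0.03),
                                  seed=island.params.get("seed", 0) + 1)
    write_image_tiff(os.path.join(folder, "c2_island1.tif"),
                     np.stack([c.data for c in cells]))

    gt = os.path.join(folder, "ground_truth")
    os.makedirs(gt, exist_ok=True)
    write_field(os.path.join(gt, "velocity.tsv"), island.velocity)
    write_field(os.path.join(gt, "traction.tsv"), island.traction)
    write_field(os.path.join(gt, "displacement.tsv"),
                island.substrate_displacement)
    write_stress(os.path.join(gt, "stress.tsv"), island.stress)

    meta = dict(island.params)
    meta.update(youngs_modulus_Pa=island.substrate.youngs_modulus_E,
                poisson_ratio=island.substrate.poisson_ratio,
                substrate_thickness_um=island.substrate.thickness_um,
                monolayer_height_um=island.monolayer.height_h,
                K1=island.monolayer.K1, K2=island.monolayer.K2,
                cell_dt_min=cell_dt, n_cell_frames=n_cell_frames,
                center_x_um=island.domain.center[0],
                center_y_um=island.domain.center[1],
                radius_um=island.domain.radius)
    write_metadata(os.path.join(folder, "metadata.txt"), meta)
    return folder
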