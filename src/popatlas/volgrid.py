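"""Volumetric data model: volumes, label maps, affines, dense warp fields.

All spatial quantities live in world millimetres.  A ``Volume`` couples a 3D
scalar grid with a 4x4 voxel-index-to-world affine (NIfTI sform convention);
a ``WarpField`` stores a per-voxel displacement vector in world mm on a
reference grid, so fields defined on different grids compose consistently.

Transforms follow the *pull* (resampling) convention throughout: a transform
maps a point in the target/output space to the location in the source image
that should be sampled.  Applying a pure translation ``t`` therefore moves
image content by ``-t`` in world space.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
from scipy import ndimage


# --------------------------------------------------------------------------
# data types
# --------------------------------------------------------------------------

@dataclass
class Volume:
    """3D scalar image with voxel-to-world affine."""

    data: np.ndarray
    affine: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        self.affine = np.asarray(self.affine, dtype=np.float64)
        if self.data.ndim != 3:
            raise ValueError(f"Volume data must be 3D, got shape {self.data.shape}")
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if abs(np.linalg.det(self.affine[:3, :3])) < 1e-12:
            raise ValueError("affine is singular")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def voxel_sizes(self) -> np.ndarray:
        """mm per voxel along each grid axis (column norms of the affine)."""
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    @property
    def voxel_volume(self) -> float:
        """Volume of one voxel in mm^3."""
        return float(abs(np.linalg.det(self.affine[:3, :3])))

    def copy(self) -> "Volume":
        return Volume(self.data.copy(), self.affine.copy())

    def same_grid(self, other: "Volume | LabelMap | WarpField") -> bool:
        aff = other.affine if not isinstance(other, WarpField) else other.reference_affine
        shp = other.shape if not isinstance(other, WarpField) else other.displacements.shape[:3]
        return self.shape == tuple(shp) and np.allclose(self.affine, aff, atol=1e-6)


@dataclass
class LabelMap:
    """Integer parcellation sharing the Volume grid model.

    ``table`` maps integer region id -> region name; background (id
    ``background_id``) need not appear in the table.
    """

    data: np.ndarray
    affine: np.ndarray
    table: dict[int, str] = field(default_factory=dict)
    background_id: int = 0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if not np.issubdtype(self.data.dtype, np.integer):
            rounded = np.rint(self.data)
            if not np.allclose(self.data, rounded):
                raise ValueError("label data must be integer-valued")
            self.data = rounded.astype(np.int32)
        self.affine = np.asarray(self.affine, dtype=np.float64)
        missing = set(np.unique(self.data).tolist()) - set(self.table) - {self.background_id}
        if self.table and missing:
            raise ValueError(f"labels present in data but absent from table: {sorted(missing)}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def voxel_volume(self) -> float:
        return float(abs(np.linalg.det(self.affine[:3, :3])))

    def ids(self) -> list[int]:
        """Non-background ids present in the data, sorted."""
        u = np.unique(self.data)
        return [int(i) for i in u if i != self.background_id]


@dataclass
class AffineTransform:
    """World-mm to world-mm homogeneous transform (pull convention)."""

    matrix: np.ndarray

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=np.float64)
        if self.matrix.shape != (4, 4):
            raise ValueError("matrix must be 4x4")
        if not np.allclose(self.matrix[3], [0, 0, 0, 1], atol=1e-9):
            raise ValueError("bottom row must be (0,0,0,1)")
        if abs(np.linalg.det(self.matrix[:3, :3])) < 1e-12:
            raise ValueError("upper-left 3x3 must be invertible")

    @classmethod
    def identity(cls) -> "AffineTransform":
        return cls(np.eye(4))

    @classmethod
    def from_translation(cls, t) -> "AffineTransform":
        m = np.eye(4)
        m[:3, 3] = t
        return cls(m)

    def inverse(self) -> "AffineTransform":
        return AffineTransform(np.linalg.inv(self.matrix))

    def __matmul__(self, other: "AffineTransform") -> "AffineTransform":
        return AffineTransform(self.matrix @ other.matrix)

    def apply_points(self, pts: np.ndarray) -> np.ndarray:
        """Map (3, N) world points through the transform."""
        return self.matrix[:3, :3] @ pts + self.matrix[:3, 3:4]


@dataclass
class WarpField:
    """Dense displacement field u(x) in world mm on a reference grid.

    Applying the warp samples the source at ``x + u(x)`` for each world
    point x of the target grid (pull convention).
    """

    displacements: np.ndarray  # (X, Y, Z, 3)
    reference_affine: np.ndarray

    def __post_init__(self) -> None:
        self.displacements = np.asarray(self.displacements, dtype=np.float64)
        self.reference_affine = np.asarray(self.reference_affine, dtype=np.float64)
        if self.displacements.ndim != 4 or self.displacements.shape[3] != 3:
            raise ValueError("displacements must have shape (X, Y, Z, 3)")
        if not np.all(np.isfinite(self.displacements)):
            raise ValueError("warp field contains non-finite displacements")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.displacements.shape[:3]  # type: ignore[return-value]

    @classmethod
    def zeros(cls, shape, affine) -> "WarpField":
        return cls(np.zeros(tuple(shape) + (3,)), np.asarray(affine))

    def magnitude(self) -> np.ndarray:
        return np.linalg.norm(self.displacements, axis=-1)


# --------------------------------------------------------------------------
# grid helpers
# --------------------------------------------------------------------------

def grid_world_coords(affine: np.ndarray, shape) -> np.ndarray:
    """World coordinates of every voxel centre, as a (3, N) array (C order)."""
    idx = np.indices(shape, dtype=np.float64).reshape(3, -1)
    return np.asarray(affine)[:3, :3] @ idx + np.asarray(affine)[:3, 3:4]


def world_to_voxel(affine: np.ndarray, pts: np.ndarray) -> np.ndarray:
    """Map (3, N) world points into continuous voxel indices."""
    inv = np.linalg.inv(affine)
    return inv[:3, :3] @ pts + inv[:3, 3:4]


# --------------------------------------------------------------------------
# interpolation
# --------------------------------------------------------------------------

_LANCZOS_RADIUS = 3


def _lanczos_kernel(t: np.ndarray) -> np.ndarray:
    a = _LANCZOS_RADIUS
    out = np.sinc(t) * np.sinc(t / a)
    out[np.abs(t) >= a] = 0.0
    return out


def _sample_lanczos(data: np.ndarray, coords: np.ndarray) -> np.ndarray:
    """Lanczos-windowed sinc interpolation (radius 3) at (3, N) voxel coords.

    Weights are renormalised so constants are reproduced exactly; samples
    outside the grid clamp to the edge.
    """
    n = coords.shape[1]
    base = np.floor(coords).astype(np.int64)
    frac = coords - base
    offs = np.arange(-_LANCZOS_RADIUS + 1, _LANCZOS_RADIUS + 1)  # -2..3
    # per-axis weights (6, N) and clipped indices
    w = []
    ind = []
    for ax in range(3):
        t = offs[:, None] - frac[ax][None, :]
        wa = _lanczos_kernel(t)
        wa /= wa.sum(axis=0, keepdims=True)
        w.append(wa)
        ind.append(np.clip(base[ax][None, :] + offs[:, None], 0, data.shape[ax] - 1))
    out = np.zeros(n)
    for i in range(len(offs)):
        wi = w[0][i]
        xi = ind[0][i]
        for j in range(len(offs)):
            wij = wi * w[1][j]
            yj = ind[1][j]
            for k in range(len(offs)):
                out += wij * w[2][k] * data[xi, yj, ind[2][k]]
    return out


def sample_volume(data: np.ndarray, coords: np.ndarray, method: str) -> np.ndarray:
    """Sample ``data`` at continuous (3, N) voxel coordinates.

    method: 'nearest' | 'linear' | 'sinc' (Lanczos-3 windowed sinc).
    Out-of-grid samples are 0 for nearest/linear and edge-clamped for sinc.
    """
    if method == "nearest":
        return ndimage.map_coordinates(data, coords, order=0, mode="constant", cval=0.0)
    if method == "linear":
        return ndimage.map_coordinates(data, coords, order=1, mode="constant", cval=0.0)
    if method == "sinc":
        vals = _sample_lanczos(np.asarray(data, dtype=np.float64), coords)
        # zero outside the field of view, matching the other methods
        inside = np.ones(coords.shape[1], dtype=bool)
        for ax in range(3):
            inside &= (coords[ax] >= -0.5) & (coords[ax] <= data.shape[ax] - 0.5)
        vals[~inside] = 0.0
        return vals
    raise ValueError(f"unknown interpolation method: {method!r}")


# --------------------------------------------------------------------------
# I/O
# --------------------------------------------------------------------------

def _load_canonical(path) -> nib.Nifti1Image:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    img = nib.load(str(path))
    return nib.as_closest_canonical(img)


def read_volume(path) -> Volume:
    """Read a single 3D NIfTI-1 volume, reoriented to canonical axis order.

    Raises on 4D input and on non-finite voxels (reporting their count).
    """
    img = _load_canonical(path)
    data = np.asanyarray(img.dataobj)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 3D volume, got shape {data.shape}")
    data = np.asarray(data, dtype=np.float64)
    bad = int(np.count_nonzero(~np.isfinite(data)))
    if bad:
        raise ValueError(f"{path}: {bad} non-finite voxel(s)")
    return Volume(data, img.affine)


def write_volume(vol: Volume, path) -> None:
    img = nib.Nifti1Image(vol.data.astype(np.float64), vol.affine)
    img.header.set_sform(vol.affine, code=1)
    img.header.set_qform(vol.affine, code=1)
    nib.save(img, str(path))


def read_labelmap(path, table_path=None) -> LabelMap:
    img = _load_canonical(path)
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 3D label map, got shape {data.shape}")
    table = read_label_table(table_path) if table_path else {}
    return LabelMap(np.rint(data).astype(np.int32), img.affine, table)


def write_labelmap(lm: LabelMap, path, table_path=None) -> None:
    img = nib.Nifti1Image(lm.data.astype(np.int32), lm.affine)
    img.header.set_sform(lm.affine, code=1)
    img.header.set_qform(lm.affine, code=1)
    nib.save(img, str(path))
    if table_path:
        write_label_table(lm.table, table_path)


def read_label_table(path) -> dict[int, str]:
    table: dict[int, str] = {}
    with open(path, newline="") as fh:
        for row in csv.reader(fh, delimiter="\t"):
            if not row or row[0].startswith("#"):
                continue
            table[int(row[0])] = row[1]
    return table


def write_label_table(table: dict[int, str], path) -> None:
    with open(path, "w", newline="") as fh:
        wr = csv.writer(fh, delimiter="\t", lineterminator="\n")
        for k in sorted(table):
            wr.writerow([k, table[k]])


def read_warp(path) -> WarpField:
    img = _load_canonical(path)
    data = np.asanyarray(img.dataobj)
    if data.ndim == 5:  # (X, Y, Z, 1, 3): vector stored on a dummy 4th axis
        data = data[:, :, :, 0, :]
    if data.ndim != 4 or data.shape[3] != 3:
        raise ValueError(f"{path}: expected (X, Y, Z, 3) displacement volume")
    return WarpField(np.asarray(data, dtype=np.float64), img.affine)


def write_warp(w: WarpField, path) -> None:
    img = nib.Nifti1Image(w.displacements.astype(np.float64), w.reference_affine)
    img.header.set_sform(w.reference_affine, code=1)
    img.header.set_qform(w.reference_affine, code=1)
    nib.save(img, str(path))


def read_affine(path) -> AffineTransform:
    return AffineTransform(np.loadtxt(path).reshape(4, 4))


def write_affine(xf: AffineTransform, path) -> None:
    np.savetxt(path, xf.matrix, fmt="%.12g")


# --------------------------------------------------------------------------
# resampling and transform application
# --------------------------------------------------------------------------

_METHOD_ALIASES = {"sinc-like": "sinc", "lanczos": "sinc"}


def _canon_method(method: str) -> str:
    m = _METHOD_ALIASES.get(method, method)
    if m not in ("nearest", "linear", "sinc"):
        raise ValueError(f"unknown interpolation method: {method!r}")
    return m


def resample(vol: Volume, target_affine, target_shape, method: str = "linear") -> Volume:
    """Resample a volume onto the target grid (no geometric transform)."""
    target_affine = np.asarray(target_affine, dtype=np.float64)
    if abs(np.linalg.det(target_affine[:3, :3])) < 1e-12:
        raise ValueError("degenerate target affine")
    pts = grid_world_coords(target_affine, target_shape)
    coords = world_to_voxel(vol.affine, pts)
    vals = sample_volume(vol.data, coords, _canon_method(method))
    return Volume(vals.reshape(tuple(target_shape)), target_affine)


def apply_transform(
    vol: Volume,
    xf: AffineTransform | WarpField | None,
    target_affine,
    target_shape,
    method: str = "linear",
) -> Volume:
    """Resample ``vol`` through a transform onto the target grid.

    Pull convention: output(x) = vol(xf(x)) with xf(x) = M x for an affine
    and xf(x) = x + u(x) for a warp field.
    """
    target_affine = np.asarray(target_affine, dtype=np.float64)
    target_shape = tuple(int(s) for s in target_shape)
    pts = grid_world_coords(target_affine, target_shape)
    if xf is None:
        src_pts = pts
    elif isinstance(xf, AffineTransform):
        src_pts = xf.apply_points(pts)
    elif isinstance(xf, WarpField):
        if xf.shape != target_shape or not np.allclose(
            xf.reference_affine, target_affine, atol=1e-6
        ):
            raise ValueError("warp field grid does not match the target grid")
        src_pts = pts + xf.displacements.reshape(-1, 3).T
    else:
        raise TypeError(f"unsupported transform type: {type(xf)}")
    coords = world_to_voxel(vol.affine, src_pts)
    vals = sample_volume(vol.data, coords, _canon_method(method))
    return Volume(vals.reshape(target_shape), target_affine)


def _sample_warp(w: WarpField, pts: np.ndarray, order: int = 3) -> np.ndarray:
    """Sample a warp's displacement vectors at (3, N) world points (cubic
    spline by default — smooth fields resample with far less jitter than
    linear — edge-clamped so extrapolation stays bounded)."""
    coords = world_to_voxel(w.reference_affine, pts)
    out = np.empty((3, pts.shape[1]))
    for c in range(3):
        out[c] = ndimage.map_coordinates(
            w.displacements[..., c], coords, order=order, mode="nearest"
        )
    return out


def compose_transforms(
    outer: AffineTransform | WarpField,
    inner: AffineTransform | WarpField,
    reference_affine=None,
    shape=None,
) -> WarpField | AffineTransform:
    """Compose transforms so that applying the result to an image equals
    applying ``inner`` first, then ``outer``.

    In the pull convention the composed point map is inner_map(outer_map(x)).
    Affine-affine composition stays affine; any other pairing produces a
    dense warp on the outer warp's grid (or on ``reference_affine``/``shape``
    when the outer transform is affine).
    """
    if isinstance(outer, AffineTransform) and isinstance(inner, AffineTransform):
        return AffineTransform(inner.matrix @ outer.matrix)
    if isinstance(outer, WarpField):
        shape = outer.shape
        reference_affine = outer.reference_affine
    elif reference_affine is None or shape is None:
        raise ValueError("affine-outer composition with a warp needs a reference grid")
    shape = tuple(int(s) for s in shape)
    reference_affine = np.asarray(reference_affine, dtype=np.float64)
    pts = grid_world_coords(reference_affine, shape)
    if isinstance(outer, WarpField):
        mid = pts + outer.displacements.reshape(-1, 3).T
    else:
        mid = outer.apply_points(pts)
    if isinstance(inner, AffineTransform):
        src = inner.apply_points(mid)
    elif isinstance(inner, WarpField):
        src = mid + _sample_warp(inner, mid)
    else:
        raise TypeError(f"unsupported inner transform: {type(inner)}")
    disp = (src - pts).T.reshape(shape + (3,))
    return WarpField(disp, reference_affine)


def compose_warps(outer: WarpField, inner: AffineTransform | WarpField) -> WarpField:
    """Warp-outer special case of :func:`compose_transforms`."""
    if not isinstance(outer, WarpField):
        raise TypeError("outer must be a WarpField")
    out = compose_transforms(outer, inner)
    assert isinstance(out, WarpField)
    return out


def affine_to_warp(xf: AffineTransform, reference_affine, shape) -> WarpField:
    """Densify an affine transform onto a reference grid."""
    pts = grid_world_coords(reference_affine, shape)
    disp = (xf.apply_points(pts) - pts).T.reshape(tuple(shape) + (3,))
    return WarpField(disp, np.asarray(reference_affine))


def invert_warp(w: WarpField, iterations: int = 30, tol: float = 0.01) -> WarpField:
    """Approximate inverse displacement field by fixed-point iteration.

    Solves v(x) = -u(x + v(x)).  Stops when the median residual of the
    composition drops below ``tol`` mm or after ``iterations`` sweeps; if the
    tolerance is not reached, a warning is emitted with the residual.
    """
    import warnings

    shape = w.shape
    aff = w.reference_affine
    pts = grid_world_coords(aff, shape)
    v = np.zeros_like(w.displacements).reshape(-1, 3).T
    resid = np.inf
    for _ in range(max(1, iterations)):
        v_new = -_sample_warp(w, pts + v)
        resid = float(np.median(np.linalg.norm(v_new - v, axis=0)))
        v = v_new
        if resid < tol:
            break
    inv = WarpField(v.T.reshape(shape + (3,)), aff)
    comp = compose_warps(inv, w)
    med = float(np.median(comp.magnitude()))
    if med > tol:
        warnings.warn(
            f"warp inversion did not reach tol={tol} mm (median residual {med:.4g} mm)",
            RuntimeWarning,
            stacklevel=2,
        )
    return inv


def jacobian_determinant(w: WarpField) -> np.ndarray:
    """Voxelwise Jacobian determinant of the map x -> x + u(x).

    Positive values indicate a locally invertible, folding-free deformation.
    """
    aff = w.reference_affine[:3, :3]
    inv = np.linalg.inv(aff)
    # displacement gradient in world coords: du/dx = (du/di) (di/dx)
    grads = np.empty(w.shape + (3, 3))
    for c in range(3):
        gi = np.stack(np.gradient(w.displacements[..., c]), axis=-1)  # du_c/di
        grads[..., c, :] = gi @ inv
    jac = grads + np.eye(3)
    return np.linalg.det(jac)
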