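"""Diffusion-tensor estimation and scalar-map derivation.

Per voxel the single-tensor model relates the measured signal to the gradient
scheme through the Stejskal–Tanner monoexponential

    S(b, g) = S0 * exp(-b * g^T D g)

with ``D`` a symmetric positive 3x3 tensor (mm^2/s) and ``g`` a unit gradient
direction.  Taking logs makes the model linear in (ln S0, Dxx, Dyy, Dzz, Dxy,
Dxz, Dyz), so the fit is ordinary or weighted linear least squares on ln S.
From the sorted eigenvalues (l1 >= l2 >= l3) the standard scalar maps follow:

    AD = l1            RD = (l2 + l3) / 2        MD = (l1 + l2 + l3) / 3
    FA = sqrt(3/2) * ||l - mean(l)|| / ||l||

Numerical policy (documented in docs/methods.md): signals are floored at
1e-6 * S0 before the log (count logged), negative eigenvalues are kept for
MD/AD/RD but clamped to zero inside the FA formula only, and eigenvector signs
are fixed so the largest-magnitude component is positive (reproducible
tracking).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import nibabel as nib
import numpy as np

from .errors import ProtocolError, SimulationError

logger = logging.getLogger("tractrr.tensor")

#: floor applied to signals (relative to the voxel's estimated S0) before log
SIGNAL_FLOOR = 1e-6

# index order of the unique tensor components throughout the package
TENSOR_COMPONENTS = ("Dxx", "Dyy", "Dzz", "Dxy", "Dxz", "Dyz")


@dataclass
class DWIVolume:
    """A 4D diffusion-weighted acquisition on an isotropic grid.

    ``data`` has shape (X, Y, Z, m) with one 3D volume per protocol entry.
    """

    data: np.ndarray
    voxel_size_mm: float

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return tuple(self.data.shape[:3])


@dataclass
class TensorField:
    """Per-voxel symmetric diffusion tensors.

    ``tensors`` stores the six unique components in :data:`TENSOR_COMPONENTS`
    order, shape (X, Y, Z, 6), units mm^2/s. ``s0`` is the estimated (or
    simulated) non-diffusion-weighted signal; ``valid`` flags voxels with a
    usable fit — invalid voxels are never silently zeroed.
    """

    tensors: np.ndarray
    s0: np.ndarray
    valid: np.ndarray
    voxel_size_mm: float

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return tuple(self.tensors.shape[:3])

    def matrices(self) -> np.ndarray:
        """Expand the compact storage to full (X, Y, Z, 3, 3) matrices."""
        d = self.tensors
        m = np.empty(d.shape[:-1] + (3, 3), dtype=d.dtype)
        m[..., 0, 0] = d[..., 0]
        m[..., 1, 1] = d[..., 1]
        m[..., 2, 2] = d[..., 2]
        m[..., 0, 1] = m[..., 1, 0] = d[..., 3]
        m[..., 0, 2] = m[..., 2, 0] = d[..., 4]
        m[..., 1, 2] = m[..., 2, 1] = d[..., 5]
        return m

    def eigensystem(self) -> tuple[np.ndarray, np.ndarray]:
        """Eigenvalues sorted descending and matching eigenvectors.

        Returns ``(evals, evecs)`` with shapes (X, Y, Z, 3) and (X, Y, Z, 3, 3);
        ``evecs[..., :, a]`` is the eigenvector of ``evals[..., a]``.  Ties are
        broken by the stable descending sort of ``eigh`` output; each
        eigenvector's sign is fixed so its largest-magnitude component is
        positive.
        """
        mats = self.matrices()
        bad = ~np.isfinite(mats).all(axis=(-2, -1)) | ~self.valid
        mats[bad] = np.eye(3)
        evals, evecs = np.linalg.eigh(mats)
        evals = evals[..., ::-1]
        evecs = evecs[..., ::-1]
        # sign convention: largest-|component| positive
        comp = np.argmax(np.abs(evecs), axis=-2, keepdims=True)
        sign = np.sign(np.take_along_axis(evecs, comp, axis=-2))
        sign[sign == 0] = 1.0
        evecs = evecs * sign
        evals[bad] = np.nan
        return evals, evecs

    def principal_directions(self) -> np.ndarray:
        """Unit principal eigenvector per voxel, shape (X, Y, Z, 3)."""
        _, evecs = self.eigensystem()
        v1 = evecs[..., :, 0]
        return np.nan_to_num(v1, nan=0.0)


@dataclass
class ScalarMaps:
    """FA (unitless) and MD/AD/RD (mm^2/s) volumes with a validity mask."""

    fa: np.ndarray
    md: np.ndarray
    ad: np.ndarray
    rd: np.ndarray
    valid: np.ndarray
    voxel_size_mm: float = field(default=1.0)

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return tuple(self.fa.shape)


def design_matrix(protocol) -> np.ndarray:
    """Log-linear design matrix, one row per volume.

    Row i is [1, -b gx^2, -b gy^2, -b gz^2, -2b gx gy, -2b gx gz, -2b gy gz]
    so that ``X @ (ln S0, Dxx, ..., Dyz) = ln S``.
    """
    b = np.asarray(protocol.bvals, dtype=float)
    g = np.asarray(protocol.bvecs, dtype=float)
    x = np.empty((b.size, 7))
    x[:, 0] = 1.0
    x[:, 1] = -b * g[:, 0] ** 2
    x[:, 2] = -b * g[:, 1] ** 2
    x[:, 3] = -b * g[:, 2] ** 2
    x[:, 4] = -2.0 * b * g[:, 0] * g[:, 1]
    x[:, 5] = -2.0 * b * g[:, 0] * g[:, 2]
    x[:, 6] = -2.0 * b * g[:, 1] * g[:, 2]
    return x


def quadratic_forms(tensors6: np.ndarray, bvecs: np.ndarray) -> np.ndarray:
    """g^T D g for every voxel/direction pair; shapes (..., 6) x (m, 3) -> (..., m)."""
    g = np.asarray(bvecs, dtype=float)
    gxx = g[:, 0] ** 2
    gyy = g[:, 1] ** 2
    gzz = g[:, 2] ** 2
    gxy = 2.0 * g[:, 0] * g[:, 1]
    gxz = 2.0 * g[:, 0] * g[:, 2]
    gyz = 2.0 * g[:, 1] * g[:, 2]
    d = tensors6
    return (
        d[..., 0, None] * gxx
        + d[..., 1, None] * gyy
        + d[..., 2, None] * gzz
        + d[..., 3, None] * gxy
        + d[..., 4, None] * gxz
        + d[..., 5, None] * gyz
    )


def fit_tensor(dwi: DWIVolume, protocol, method: str = "wls") -> TensorField:
    """Fit the diffusion tensor per voxel by log-linear least squares.

    ``method`` is ``"ols"`` or ``"wls"``; WLS weights are the squared model
    signals from an OLS first pass (the usual heteroscedasticity correction
    for log-transformed Rician/Gaussian magnitude data).  All-zero voxels are
    flagged invalid rather than fitted.
    """
    if method not in ("ols", "wls"):
        raise ValueError(f"unknown fit method: {method!r}")
    m = len(protocol.bvals)
    if dwi.data.shape[-1] != m:
        raise ProtocolError(
            f"protocol has {m} volumes but DWI has {dwi.data.shape[-1]}"
        )
    n_dwi = int(np.sum(np.asarray(protocol.bvals) > 0))
    if n_dwi < 6:
        raise ProtocolError("tensor fit requires >= 6 diffusion-weighted volumes")
    x = design_matrix(protocol)
    if np.linalg.matrix_rank(x) < 7:
        raise ProtocolError("rank-deficient design matrix: collinear directions")

    grid = dwi.data.shape[:3]
    signals = np.asarray(dwi.data, dtype=np.float64).reshape(-1, m)
    b0 = np.asarray(protocol.bvals, dtype=float) == 0
    s0_est = signals[:, b0].mean(axis=1)
    valid = s0_est > 0

    nv = signals.shape[0]
    beta = np.zeros((nv, 7))
    if valid.any():
        sig = signals[valid]
        floor = SIGNAL_FLOOR * s0_est[valid, None]
        n_clamped = int(np.sum(sig < floor))
        if n_clamped:
            logger.info("fit_tensor: clamped %d non-positive/low signals", n_clamped)
        y = np.log(np.maximum(sig, floor))
        # OLS: identical normal equations for every voxel
        beta_v = np.linalg.solve(x.T @ x, x.T @ y.T).T
        if method == "wls":
            w = np.exp(2.0 * (beta_v @ x.T))  # squared model signals
            a = np.einsum("vm,mi,mj->vij", w, x, x, optimize=True)
            rhs = np.einsum("vm,mi,vm->vi", w, x, y, optimize=True)
            beta_v = np.linalg.solve(a, rhs[..., None])[..., 0]
        beta[valid] = beta_v

    tensors = beta[:, 1:].reshape(grid + (6,))
    s0_fit = np.exp(beta[:, 0])
    s0_fit[~valid] = 0.0
    return TensorField(
        tensors=tensors,
        s0=s0_fit.reshape(grid),
        valid=valid.reshape(grid),
        voxel_size_mm=dwi.voxel_size_mm,
    )


def fa_from_eigenvalues(evals: np.ndarray) -> np.ndarray:
    """Fractional anisotropy from eigenvalues along the last axis.

    Negative eigenvalues are clamped to zero here (FA only); an all-zero
    eigenvalue set yields FA = 0.
    """
    lam = np.maximum(np.asarray(evals, dtype=float), 0.0)
    n_neg = int(np.sum(np.asarray(evals) < 0))
    if n_neg:
        logger.info("fa_from_eigenvalues: clamped %d negative eigenvalues", n_neg)
    mean = lam.mean(axis=-1, keepdims=True)
    num = np.sqrt(np.sum((lam - mean) ** 2, axis=-1))
    den = np.sqrt(np.sum(lam**2, axis=-1))
    with np.errstate(invalid="ignore", divide="ignore"):
        fa = np.sqrt(1.5) * num / den
    return np.where(den > 0, fa, 0.0)


def tensor_metrics(tfield: TensorField) -> ScalarMaps:
    """Derive FA/MD/AD/RD maps from a fitted tensor field.

    MD/AD/RD use the raw (possibly negative) eigenvalues to stay unbiased;
    FA clamps negatives internally. The validity mask propagates unchanged.
    """
    evals, _ = tfield.eigensystem()
    invalid = ~tfield.valid
    ad = evals[..., 0]
    rd = (evals[..., 1] + evals[..., 2]) / 2.0
    md = evals.sum(axis=-1) / 3.0
    fa = fa_from_eigenvalues(np.nan_to_num(evals, nan=0.0))
    for arr in (ad, rd, md, fa):
        arr[invalid] = np.nan
    fa_valid = fa[tfield.valid]
    if fa_valid.size:
        np.clip(fa, 0.0, 1.0, out=fa)
        fa[invalid] = np.nan
    return ScalarMaps(
        fa=fa, md=md, ad=ad, rd=rd,
        valid=tfield.valid.copy(),
        voxel_size_mm=tfield.voxel_size_mm,
    )


# ---------------------------------------------------------------------------
# NIfTI / gradient-table I/O
# ---------------------------------------------------------------------------

def _affine(voxel_size_mm: float) -> np.ndarray:
    aff = np.diag([voxel_size_mm, voxel_size_mm, voxel_size_mm, 1.0])
    return aff


def write_dwi(path, dwi: DWIVolume) -> None:
    img = nib.Nifti1Image(np.asarray(dwi.data, dtype=np.float32), _affine(dwi.voxel_size_mm))
    nib.save(img, str(path))


def read_dwi(path) -> DWIVolume:
    img = nib.load(str(path))
    vox = float(img.header.get_zooms()[0])
    data = np.asarray(img.dataobj, dtype=np.float64)
    if data.ndim != 4:
        raise SimulationError(f"expected 4D DWI, got shape {data.shape}")
    return DWIVolume(data=data, voxel_size_mm=vox)


def write_scalar_maps(prefix, maps: ScalarMaps) -> dict:
    """Write FA/MD/AD/RD as <prefix>_FA.nii.gz etc.

    Diffusivities are stored in mm^2/s; the header description records the
    unit (reports use the x1e-3 mm^2/s display convention).
    """
    written = {}
    aff = _affine(maps.voxel_size_mm)
    for name, arr, unit in (
        ("FA", maps.fa, "unitless"),
        ("MD", maps.md, "mm^2/s"),
        ("AD", maps.ad, "mm^2/s"),
        ("RD", maps.rd, "mm^2/s"),
    ):
        img = nib.Nifti1Image(np.asarray(arr, dtype=np.float32), aff)
        img.header["descrip"] = f"{name} [{unit}]".encode()
        out = f"{prefix}_{name}.nii.gz"
        nib.save(img, out)
        written[name] = out
    return written


def read_scalar_map(path) -> np.ndarray:
    return np.asarray(nib.load(str(path)).dataobj, dtype=np.float64)
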