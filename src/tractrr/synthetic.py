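"""Synthetic DWI phantoms and two-session test–retest cohorts.

The generator stands in for a real chronic-stroke diffusion study: a cohort of
subjects, each scanned twice a few days apart, with one "ipsilesional"
corticospinal-like tract whose FA is systematically lower than the mirrored
"contralesional" tract.  Every stage downstream (tensor fit, tract extraction,
reliability statistics) can therefore be validated against known ground truth.

The variance model is the classical two-level reliability decomposition: each
subject s draws a tract-FA offset b_s ~ N(0, sigma_between^2) and each session
adds e_st ~ N(0, sigma_session^2).  The true intraclass correlation implied by
the generator is

    ICC_true = sigma_between^2 / (sigma_between^2 + sigma_session^2)

and is reported with the cohort so parameter-recovery tests can target it.
Subject/session FA offsets are realised by jointly scaling the two minor
eigenvalues while re-adjusting the major one to preserve the trace, so FA moves
while MD stays fixed (FA and MD reliability are controllable independently).

Default acquisition mirrors a single-shell protocol: b = 1000 s/mm^2, 56
noncollinear directions, 7 b0 volumes, 1.8 mm isotropic voxels.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import brentq
from scipy.spatial import cKDTree

from .errors import CohortError, PhantomError, ProtocolError, SimulationError
from .tensor import DWIVolume, TensorField, fa_from_eigenvalues, quadratic_forms

logger = logging.getLogger("tractrr.synthetic")

DEFAULT_S0 = 100.0


# ---------------------------------------------------------------------------
# Acquisition protocol
# ---------------------------------------------------------------------------

@dataclass
class DiffusionProtocol:
    """Gradient table: b-values (s/mm^2) and unit b-vectors, b0s included."""

    bvals: np.ndarray
    bvecs: np.ndarray

    def __post_init__(self):
        self.bvals = np.asarray(self.bvals, dtype=float)
        self.bvecs = np.asarray(self.bvecs, dtype=float)
        if self.bvals.ndim != 1 or self.bvecs.shape != (self.bvals.size, 3):
            raise ProtocolError("bvals must be (m,), bvecs (m, 3)")
        if self.bvals.size < 7:
            raise ProtocolError("need >= 7 volumes (6 directions + 1 b0)")
        if self.n_b0 < 1:
            raise ProtocolError("at least one b0 volume is required")
        dw = self.bvals > 0
        norms = np.linalg.norm(self.bvecs[dw], axis=1)
        if dw.any() and np.any(np.abs(norms - 1.0) > 1e-8):
            raise ProtocolError("diffusion-weighted b-vectors must be unit length")

    @property
    def n_b0(self) -> int:
        return int(np.sum(self.bvals == 0))

    @property
    def n_volumes(self) -> int:
        return int(self.bvals.size)


def _fibonacci_hemisphere(n: int) -> np.ndarray:
    """n approximately uniform unit vectors on the upper half-sphere."""
    i = np.arange(n)
    z = (i + 0.5) / n
    r = np.sqrt(1.0 - z**2)
    theta = np.pi * (3.0 - np.sqrt(5.0)) * i
    return np.column_stack([r * np.cos(theta), r * np.sin(theta), z])


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    q, r = np.linalg.qr(rng.normal(size=(3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 2] *= -1
    return q


def make_protocol(
    n_directions: int,
    b_value: float = 1000.0,
    n_b0: int = 7,
    seed: int = 0,
) -> DiffusionProtocol:
    """Build a single-shell protocol with near-uniform half-sphere directions.

    Directions come from a Fibonacci spiral on the half-sphere, rotated by a
    seed-determined random rotation; the table is deterministic per seed. b0
    volumes are placed first with zero b-vectors.
    """
    if n_directions < 6:
        raise ProtocolError("a tensor fit needs at least 6 gradient directions")
    if n_b0 < 1:
        raise ProtocolError("at least one b0 volume is required")
    dirs = _fibonacci_hemisphere(n_directions)
    rot = _random_rotation(np.random.default_rng(seed))
    dirs = dirs @ rot.T
    bvals = np.concatenate([np.zeros(n_b0), np.full(n_directions, float(b_value))])
    bvecs = np.vstack([np.zeros((n_b0, 3)), dirs])
    return DiffusionProtocol(bvals=bvals, bvecs=bvecs)


def write_gradient_table(bval_path, bvec_path, protocol: DiffusionProtocol) -> None:
    """FSL-style plain text: one row of b-values, three rows of components."""
    with open(bval_path, "w") as fh:
        fh.write(" ".join(f"{b:g}" for b in protocol.bvals) + "\n")
    with open(bvec_path, "w") as fh:
        for axis in range(3):
            fh.write(" ".join(f"{v:.10f}" for v in protocol.bvecs[:, axis]) + "\n")


def read_gradient_table(bval_path, bvec_path) -> DiffusionProtocol:
    bvals = np.loadtxt(bval_path)
    bvecs = np.loadtxt(bvec_path)
    if bvecs.shape[0] == 3:
        bvecs = bvecs.T
    return DiffusionProtocol(bvals=np.atleast_1d(bvals), bvecs=bvecs)


# ---------------------------------------------------------------------------
# Phantom geometry
# ---------------------------------------------------------------------------

@dataclass
class PhantomSpec:
    """Geometry of a single synthetic tract in a rectangular grid.

    ``tract_centerline`` is an ordered polyline in mm; voxels whose centre
    lies within ``tract_radius_mm`` of it receive the anisotropic tract tensor
    oriented along the local tangent.  A partial-volume shell of width
    ``pv_width_mm`` just outside the radius blends tract and background
    tensors, emulating voxels that mix white matter with surrounding tissue.
    """

    grid_shape: tuple = (40, 40, 60)
    voxel_size_mm: float = 1.8
    tract_centerline: np.ndarray | None = None
    tract_radius_mm: float = 5.4
    tract_eigenvalues: tuple = (1.4e-3, 0.45e-3, 0.45e-3)
    background_diffusivity: float = 0.8e-3
    pv_width_mm: float = 1.8
    lesion_center_mm: tuple | None = None
    lesion_radius_mm: float = 5.4
    lesion_fa_scale: float = 1.0

    def __post_init__(self):
        if any(s <= 0 for s in self.grid_shape) or len(self.grid_shape) != 3:
            raise PhantomError("grid_shape must be 3 positive integers")
        if self.voxel_size_mm <= 0 or self.tract_radius_mm <= 0:
            raise PhantomError("voxel size and tract radius must be positive")
        l1, l2, l3 = self.tract_eigenvalues
        if not (l1 >= l2 >= l3 > 0):
            raise PhantomError("tract eigenvalues must be descending and positive")
        if not 0.0 <= self.lesion_fa_scale <= 1.0:
            raise PhantomError("lesion_fa_scale must lie in [0, 1]")
        if self.tract_centerline is None:
            self.tract_centerline = default_centerline(self)
        cl = np.asarray(self.tract_centerline, dtype=float)
        if cl.ndim != 2 or cl.shape[1] != 3 or cl.shape[0] < 2:
            raise PhantomError("tract_centerline must be an (n>=2, 3) point list")
        extent = np.asarray(self.grid_shape) * self.voxel_size_mm
        if np.any(cl < 0) or np.any(cl >= extent):
            raise PhantomError("centerline must lie inside the grid")
        self.tract_centerline = cl


def default_centerline(spec: PhantomSpec, lateral_frac: float = 0.27) -> np.ndarray:
    """Gently bowed, mostly vertical centerline in the left hemisphere.

    Spans the central 78% of the axial (z) extent with a small sinusoidal
    lateral bow, so curvature is mild relative to the tracker's default
    curvature threshold.
    """
    nx, ny, nz = spec.grid_shape
    vs = spec.voxel_size_mm
    z = np.linspace(0.11 * nz, 0.89 * nz, 120) * vs
    x0 = lateral_frac * nx * vs
    bow = 1.6 * vs * np.sin(np.pi * (z - z[0]) / (z[-1] - z[0]))
    x = x0 + bow
    y = np.full_like(z, 0.5 * ny * vs)
    return np.column_stack([x, y, z])


def _resample_polyline(points: np.ndarray, spacing: float) -> tuple[np.ndarray, np.ndarray]:
    """Resample a polyline at uniform arclength and return points + unit tangents."""
    seg = np.diff(points, axis=0)
    seglen = np.linalg.norm(seg, axis=1)
    arclen = np.concatenate([[0.0], np.cumsum(seglen)])
    total = arclen[-1]
    if total <= 0:
        raise PhantomError("degenerate centerline with zero length")
    n = max(int(np.ceil(total / spacing)) + 1, 2)
    s = np.linspace(0.0, total, n)
    pts = np.column_stack([np.interp(s, arclen, points[:, a]) for a in range(3)])
    tan = np.gradient(pts, s, axis=0)
    tan /= np.linalg.norm(tan, axis=1, keepdims=True)
    return pts, tan


def _orthonormal_basis(tangents: np.ndarray) -> np.ndarray:
    """Per-point right-handed basis (e1=tangent, e2, e3), shape (n, 3, 3)."""
    e1 = tangents
    ref = np.tile(np.array([1.0, 0.0, 0.0]), (len(e1), 1))
    ref[np.abs(e1[:, 0]) > 0.9] = [0.0, 1.0, 0.0]
    e2 = np.cross(e1, ref)
    e2 /= np.linalg.norm(e2, axis=1, keepdims=True)
    e3 = np.cross(e1, e2)
    return np.stack([e1, e2, e3], axis=-1)


def _tensor6(mat: np.ndarray) -> np.ndarray:
    """Compact (..., 3, 3) symmetric matrices to (..., 6) component storage."""
    return np.stack(
        [mat[..., 0, 0], mat[..., 1, 1], mat[..., 2, 2],
         mat[..., 0, 1], mat[..., 0, 2], mat[..., 1, 2]],
        axis=-1,
    )


class PhantomGeometry:
    """Precomputed voxel membership and tract frames for one tract.

    Splitting geometry (expensive, fixed across a cohort) from eigenvalues
    (cheap, varies per subject/session) lets a cohort rebuild tensor fields
    quickly.
    """

    def __init__(self, spec: PhantomSpec):
        self.spec = spec
        nx, ny, nz = spec.grid_shape
        vs = spec.voxel_size_mm
        pts, tans = _resample_polyline(spec.tract_centerline, 0.4 * vs)
        idx = np.indices(spec.grid_shape).reshape(3, -1).T
        centers = (idx + 0.5) * vs
        dist, nearest = cKDTree(pts).query(centers, workers=-1)
        dist = dist.reshape(spec.grid_shape)
        nearest = nearest.reshape(spec.grid_shape)

        core = dist <= spec.tract_radius_mm
        shell = (dist > spec.tract_radius_mm) & (
            dist <= spec.tract_radius_mm + spec.pv_width_mm
        )
        if not core.any():
            raise PhantomError("tract radius too small: no voxel falls inside the tract")
        self.core = core
        self.shell = shell
        self.shell_frac = np.clip(
            (spec.tract_radius_mm + spec.pv_width_mm - dist[shell]) / spec.pv_width_mm,
            0.0,
            1.0,
        )
        basis = _orthonormal_basis(tans)
        self.core_basis = basis[nearest[core]]
        self.shell_basis = basis[nearest[shell]]
        self.centerline_points = pts
        self.centerline_tangents = tans

        if spec.lesion_center_mm is not None:
            lc = np.asarray(spec.lesion_center_mm, dtype=float)
            self.lesion = (
                np.linalg.norm(centers - lc, axis=1).reshape(spec.grid_shape)
                <= spec.lesion_radius_mm
            )
        else:
            self.lesion = np.zeros(spec.grid_shape, dtype=bool)

    def masks(self) -> dict:
        """Extraction masks: seed patches, waypoint slabs, exclusions, template."""
        spec = self.spec
        nx, ny, nz = spec.grid_shape
        vs = spec.voxel_size_mm
        pts = self.centerline_points
        zvox = pts[:, 2] / vs
        z_lo, z_hi = zvox.min(), zvox.max()
        span = z_hi - z_lo

        def slab(frac: float, thickness: int = 4) -> np.ndarray:
            zc = int(round(z_lo + frac * span))
            z0, z1 = max(zc - thickness // 2, 0), min(zc + (thickness + 1) // 2, nz)
            # box around the centerline at that height
            sel = (pts[:, 2] / vs >= z0) & (pts[:, 2] / vs < z1)
            cx, cy = pts[sel, 0].mean() / vs, pts[sel, 1].mean() / vs
            half = spec.tract_radius_mm / vs + 3.0
            m = np.zeros(spec.grid_shape, dtype=bool)
            xs = np.arange(nx)
            ys = np.arange(ny)
            m[
                np.ix_(
                    np.abs(xs + 0.5 - cx) <= half,
                    np.abs(ys + 0.5 - cy) <= half,
                    np.arange(z0, z1),
                )
            ] = True
            return m

        plic = slab(0.62)
        peduncle = slab(0.10)

        midline = np.zeros(spec.grid_shape, dtype=bool)
        midline[nx // 2, :, :] = True
        inferior = np.zeros(spec.grid_shape, dtype=bool)
        inferior[:, :, 0] = True

        # six small cortical seed patches arranged around the superior end
        top = pts[-2]
        e1 = self.centerline_tangents[-2]
        basis = _orthonormal_basis(e1[None])[0]
        e2, e3 = basis[:, 1], basis[:, 2]
        idx = np.indices(spec.grid_shape).reshape(3, -1).T
        centers = (idx + 0.5) * vs
        patches = []
        core_centers = centers[self.core.reshape(-1)]
        for k in range(6):
            ang = 2.0 * np.pi * k / 6.0
            pc = top + 0.55 * spec.tract_radius_mm * (np.cos(ang) * e2 + np.sin(ang) * e3)
            patch = (
                np.linalg.norm(centers - pc, axis=1) <= 1.2 * vs
            ).reshape(spec.grid_shape) & self.core
            if not patch.any():  # fall back to the nearest in-tract voxel
                j = np.argmin(np.linalg.norm(core_centers - pc, axis=1))
                patch = np.zeros(spec.grid_shape, dtype=bool)
                patch[tuple(np.argwhere(self.core)[j])] = True
            patches.append(patch)
        seeds = np.logical_or.reduce(patches)

        return {
            "tract": self.core.copy(),
            "template": self.core | self.shell,
            "seed_patches": patches,
            "seeds": seeds,
            "plic": plic,
            "peduncle": peduncle,
            "midline_exclusion": midline,
            "inferior_exclusion": inferior,
            "lesion": self.lesion.copy(),
        }

    def tensor6_field(self, eigenvalues=None, lesion_fa_scale=None) -> np.ndarray:
        """Per-voxel compact tensors for given tract eigenvalues (mm^2/s)."""
        spec = self.spec
        lam = np.asarray(
            spec.tract_eigenvalues if eigenvalues is None else eigenvalues, dtype=float
        )
        scale = spec.lesion_fa_scale if lesion_fa_scale is None else lesion_fa_scale
        d_bg = np.zeros(6)
        d_bg[:3] = spec.background_diffusivity
        field6 = np.broadcast_to(d_bg, spec.grid_shape + (6,)).copy()

        d_core = _tensor6(np.einsum("vij,j,vkj->vik", self.core_basis, lam, self.core_basis))
        field6[self.core] = d_core
        if self.shell.any():
            d_sh = _tensor6(
                np.einsum("vij,j,vkj->vik", self.shell_basis, lam, self.shell_basis)
            )
            f = self.shell_frac[:, None]
            field6[self.shell] = f * d_sh + (1.0 - f) * d_bg
        if scale < 1.0 and self.lesion.any():
            d_les = field6[self.lesion]
            md = d_les[:, :3].mean(axis=1, keepdims=True)
            iso = np.zeros_like(d_les)
            iso[:, :3] = md
            field6[self.lesion] = scale * d_les + (1.0 - scale) * iso
        return field6


def build_phantom(spec: PhantomSpec) -> tuple[TensorField, dict]:
    """Materialise a phantom: ground-truth tensor field plus extraction masks."""
    geom = PhantomGeometry(spec)
    field6 = geom.tensor6_field()
    tfield = TensorField(
        tensors=field6,
        s0=np.full(spec.grid_shape, DEFAULT_S0),
        valid=np.ones(spec.grid_shape, dtype=bool),
        voxel_size_mm=spec.voxel_size_mm,
    )
    return tfield, geom.masks()


# ---------------------------------------------------------------------------
# DWI simulation
# ---------------------------------------------------------------------------

def simulate_dwi(
    tensors: TensorField,
    protocol: DiffusionProtocol,
    s0: float = DEFAULT_S0,
    noise_sigma: float = 0.0,
    noise_model: str = "gaussian",
    seed: int = 0,
) -> DWIVolume:
    """Simulate the monoexponential tensor signal, optionally with noise.

    ``noise_sigma`` is expressed relative to ``s0`` (i.e. 1/SNR on the b0
    signal).  ``gaussian`` adds zero-mean noise to the signal; ``rician``
    takes the magnitude of a complex Gaussian perturbation, the standard
    model for MR magnitude images.
    """
    if s0 <= 0:
        raise SimulationError("s0 must be positive")
    if noise_sigma < 0:
        raise SimulationError("noise_sigma must be non-negative")
    if noise_model not in ("gaussian", "rician"):
        raise SimulationError(f"unknown noise model: {noise_model!r}")
    q = quadratic_forms(tensors.tensors, protocol.bvecs)
    signal = s0 * np.exp(-np.asarray(protocol.bvals) * q)
    signal[~tensors.valid] = 0.0
    if noise_sigma > 0:
        rng = np.random.default_rng(seed)
        sd = noise_sigma * s0
        if noise_model == "gaussian":
            signal = signal + rng.normal(0.0, sd, signal.shape)
        else:
            n1 = rng.normal(0.0, sd, signal.shape)
            n2 = rng.normal(0.0, sd, signal.shape)
            signal = np.sqrt((signal + n1) ** 2 + n2**2)
    return DWIVolume(data=signal, voxel_size_mm=tensors.voxel_size_mm)


# ---------------------------------------------------------------------------
# Cohort generation
# ---------------------------------------------------------------------------

@dataclass
class CohortSpec:
    """Two-session cohort with a controlled reliability structure (FA units)."""

    n_subjects: int = 18
    n_sessions: int = 2
    between_subject_sd: float = 0.04
    session_sd: float = 0.007
    ipsi_contra_fa_gap: float = 0.04
    noise_sigma: float = 0.03
    noise_model: str = "gaussian"
    session_mean_shift: float = 0.0
    s0: float = DEFAULT_S0
    seed: int = 0

    def __post_init__(self):
        if self.n_subjects < 2 or self.n_sessions < 2:
            raise CohortError("need n_subjects >= 2 and n_sessions >= 2")
        if min(self.between_subject_sd, self.session_sd, self.noise_sigma) < 0:
            raise CohortError("all SDs must be non-negative")

    @property
    def implied_true_icc(self) -> float:
        b2 = self.between_subject_sd**2
        w2 = self.session_sd**2
        if b2 + w2 == 0:
            return float("nan")
        return b2 / (b2 + w2)


def eigenvalues_for_target_fa(target_fa: float, base_eigenvalues) -> tuple:
    """Eigenvalues hitting a target FA by scaling (l2, l3), preserving MD.

    The two minor eigenvalues are scaled jointly by t and the major one is set
    to trace - t*(l2+l3), so MD is unchanged while FA moves monotonically.
    Requires a cylindrical base tensor (l2 == l3).
    """
    l1, l2, l3 = (float(v) for v in base_eigenvalues)
    if not np.isclose(l2, l3):
        raise CohortError("FA adjustment assumes a cylindrical tensor (l2 == l3)")
    trace = l1 + l2 + l3
    s23 = l2 + l3

    def fa_at(t: float) -> float:
        lam = np.array([trace - t * s23, t * l2, t * l3])
        return float(fa_from_eigenvalues(lam))

    t_iso = 2.0 * trace / (3.0 * s23)  # l1 == mean -> FA == 0
    lo, hi = 1e-9, t_iso - 1e-12
    if not (fa_at(hi) < target_fa < fa_at(lo)):
        raise CohortError(
            f"target FA {target_fa:.4f} outside attainable range "
            f"({fa_at(hi):.4f}, {fa_at(lo):.4f})"
        )
    t = brentq(lambda u: fa_at(u) - target_fa, lo, hi, xtol=1e-14)
    lam = (trace - t * s23, t * l2, t * l3)
    if min(lam) <= 0:
        raise CohortError("adjusted eigenvalues are non-positive")
    return lam


@dataclass
class SubjectSession:
    subject: int
    session: int
    dwi: DWIVolume


HEMISPHERES = ("ipsilesional", "contralesional")
SESSION_LABELS = {0: "day1", 1: "day4"}


def session_label(j: int) -> str:
    return SESSION_LABELS.get(j, f"session{j + 1}")


class Cohort:
    """A simulated two-session cohort with bilateral tracts and ground truth.

    ``truth`` is a long-format table (subject, session, hemisphere, approach
    = "truth", metric, value) of noise-free tract-mean metrics;
    ``implied_true_icc`` is the generator-level ICC.  DWI volumes are built
    lazily (one subject-session at a time) via :meth:`iter_sessions` to keep
    memory flat; :meth:`realize` materialises the full list.
    """

    def __init__(self, phantom: PhantomSpec, spec: CohortSpec, protocol: DiffusionProtocol):
        import pandas as pd

        self.phantom_spec = phantom
        self.spec = spec
        self.protocol = protocol
        self.implied_true_icc = spec.implied_true_icc

        # ipsilesional tract: as specified (with lesion); contralesional:
        # mirrored across the grid's mid-sagittal plane, lesion-free
        contra_spec = mirror_spec(phantom)
        self.geometry = {
            "ipsilesional": PhantomGeometry(phantom),
            "contralesional": PhantomGeometry(contra_spec),
        }

        base_fa = float(fa_from_eigenvalues(np.asarray(phantom.tract_eigenvalues)))
        base = {
            "ipsilesional": base_fa - spec.ipsi_contra_fa_gap,
            "contralesional": base_fa,
        }

        root = np.random.SeedSequence(spec.seed)
        draw_ss, sim_ss = root.spawn(2)
        rng = np.random.default_rng(draw_ss)
        n, k = spec.n_subjects, spec.n_sessions
        b = rng.normal(0.0, spec.between_subject_sd, size=(n, 2))
        e = rng.normal(0.0, spec.session_sd, size=(n, k, 2))
        self._sim_seeds = [
            int(ss.generate_state(1)[0] % (2**31)) for ss in sim_ss.spawn(n * k)
        ]

        self.target_fa = np.empty((n, k, 2))
        self.eigenvalues = np.empty((n, k, 2, 3))
        rows = []
        for h, hemi in enumerate(HEMISPHERES):
            for i in range(n):
                for j in range(k):
                    target = base[hemi] + b[i, h] + e[i, j, h]
                    if j > 0:
                        target += spec.session_mean_shift
                    try:
                        lam = eigenvalues_for_target_fa(target, phantom.tract_eigenvalues)
                    except CohortError as err:
                        raise CohortError(f"subject {i}: {err}") from err
                    self.target_fa[i, j, h] = target
                    self.eigenvalues[i, j, h] = lam
                    metrics = {
                        "FA": target,
                        "MD": sum(lam) / 3.0,
                        "AD": lam[0],
                        "RD": (lam[1] + lam[2]) / 2.0,
                    }
                    for metric, value in metrics.items():
                        rows.append(
                            dict(
                                subject=i,
                                session=session_label(j),
                                hemisphere=hemi,
                                approach="truth",
                                metric=metric,
                                value=value,
                            )
                        )
        self.truth = pd.DataFrame(rows)
        self.truth.attrs["implied_true_icc"] = self.implied_true_icc

    def tensor_field(self, subject: int, session: int) -> TensorField:
        """Noise-free bilateral tensor field for one subject-session."""
        spec = self.phantom_spec
        ipsi = self.geometry["ipsilesional"]
        contra = self.geometry["contralesional"]
        field6 = ipsi.tensor6_field(self.eigenvalues[subject, session, 0])
        contra6 = contra.tensor6_field(self.eigenvalues[subject, session, 1])
        mask = contra.core | contra.shell
        field6[mask] = contra6[mask]
        return TensorField(
            tensors=field6,
            s0=np.full(spec.grid_shape, self.spec.s0),
            valid=np.ones(spec.grid_shape, dtype=bool),
            voxel_size_mm=spec.voxel_size_mm,
        )

    def simulate_session(self, subject: int, session: int) -> SubjectSession:
        tfield = self.tensor_field(subject, session)
        seed = self._sim_seeds[subject * self.spec.n_sessions + session]
        dwi = simulate_dwi(
            tfield,
            self.protocol,
            s0=self.spec.s0,
            noise_sigma=self.spec.noise_sigma,
            noise_model=self.spec.noise_model,
            seed=seed,
        )
        return SubjectSession(subject=subject, session=session, dwi=dwi)

    def iter_sessions(self):
        for i in range(self.spec.n_subjects):
            for j in range(self.spec.n_sessions):
                yield self.simulate_session(i, j)

    def realize(self) -> list[SubjectSession]:
        return list(self.iter_sessions())

    def masks(self, hemisphere: str) -> dict:
        return self.geometry[hemisphere].masks()


def mirror_spec(spec: PhantomSpec) -> PhantomSpec:
    """Reflect a phantom spec across the grid's mid-sagittal (x) plane."""
    extent_x = spec.grid_shape[0] * spec.voxel_size_mm
    cl = np.asarray(spec.tract_centerline).copy()
    cl[:, 0] = extent_x - cl[:, 0]
    return replace(
        spec,
        tract_centerline=cl,
        lesion_center_mm=None,
        lesion_fa_scale=1.0,
    )


def make_cohort(
    phantom: PhantomSpec, cohort: CohortSpec, protocol: DiffusionProtocol
) -> Cohort:
    """Generate a bilateral two-session cohort with known ground truth."""
    return Cohort(phantom, cohort, protocol)
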