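"""Synthetic phantoms with known ground truth for every pipeline stage.

Two forward models are provided:

* ``forward_phase`` solves the variable-coefficient elliptic relation
  div((1/sigma) grad phi) = 2 * omega * mu0 for the transceive phase given a
  conductivity map, using a flux-conservative finite-volume discretization.
  This is deliberately a *different* discretization from the
  convection-reaction inverse solver, so round-trip tests are honest
  (no inverse crime).
* ``forward_dwi`` generates stick + zeppelin two-compartment diffusion
  signals with the tortuosity constraint, optionally with Rician noise.

``make_alps_phantom`` assembles a full synthetic subject (multi-echo phase,
two-shell DWI, masks, ground-truth maps and ALPS values) on a template-like
grid whose ROI centers sit exactly on voxel centers.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .mrept import MU0, MultiEchoPhaseVolume, ReconConfig

DEFAULT_ECHO_TIMES_MS = np.arange(1, 7) * 12.0  # 6 echoes, 12 ms spacing


@dataclass
class Region:
    """One phantom region: geometry plus tissue parameters.

    kind : 'background', 'sphere' or 'box'.
    center_mm / size_mm : world-space geometry (diameter for spheres, edge
        lengths for boxes); ignored for background.
    sigma : conductivity [S/m].
    nu_int : intra-neurite volume fraction.
    d_int : intra-neurite diffusivity [mm^2/s].
    d_ext : extra-neurite mean diffusivity [mm^2/s]; None applies the
        tortuosity constraint d_ext = d_int * (1 + 2*(1 - nu_int)) / 3.
    fiber : unit fiber direction.
    """

    kind: str = "background"
    center_mm: tuple = (0.0, 0.0, 0.0)
    size_mm: tuple | float = 0.0
    sigma: float = 0.6
    nu_int: float = 0.0
    d_int: float = 1.7e-3
    d_ext: float | None = None
    fiber: tuple = (0.0, 0.0, 1.0)

    def d_ext_value(self) -> float:
        if self.d_ext is not None:
            return self.d_ext
        return self.d_int * (1.0 + 2.0 * (1.0 - self.nu_int)) / 3.0


@dataclass
class PhantomSpec:
    """Grid geometry, regions and noise levels of a synthetic phantom."""

    shape: tuple = (64, 64, 3)
    voxel_size_mm: tuple = (2.0, 2.0, 5.0)
    regions: list = field(default_factory=lambda: [Region()])
    phase_noise_sd: float = 0.0
    dwi_snr: float | None = None
    seed: int = 0
    affine: np.ndarray | None = None

    def __post_init__(self):
        if self.affine is None:
            aff = np.diag(list(self.voxel_size_mm) + [1.0])
            # center the grid on the world origin
            aff[:3, 3] = -(np.array(self.shape) - 1) / 2.0 * np.array(
                self.voxel_size_mm
            )
            self.affine = aff
        for r in self.regions:
            n = np.linalg.norm(r.fiber)
            if r.nu_int > 0 and abs(n - 1.0) > 1e-6:
                raise ValueError("fiber direction must be unit norm")

    def voxel_centers_mm(self) -> np.ndarray:
        """(X, Y, Z, 3) world coordinates of voxel centers."""
        ii, jj, kk = np.meshgrid(*(np.arange(s) for s in self.shape), indexing="ij")
        vox = np.stack([ii, jj, kk, np.ones_like(ii)], axis=-1)
        return (vox @ self.affine.T)[..., :3]

    def region_masks(self) -> list[np.ndarray]:
        """Boolean mask per region; later regions override earlier ones and
        the background region covers everything not claimed."""
        xyz = self.voxel_centers_mm()
        masks = []
        claimed = np.zeros(self.shape, dtype=bool)
        bg_index = None
        for i, r in enumerate(self.regions):
            if r.kind == "background":
                masks.append(None)
                bg_index = i
                continue
            c = np.asarray(r.center_mm, dtype=float)
            if r.kind == "sphere":
                m = np.linalg.norm(xyz - c, axis=-1) <= float(r.size_mm) / 2.0
            elif r.kind == "box":
                half = np.asarray(r.size_mm, dtype=float) / 2.0
                m = np.all(np.abs(xyz - c) <= half, axis=-1)
            else:
                raise ValueError(f"unknown region kind {r.kind!r}")
            masks.append(m)
        for i in range(len(masks) - 1, -1, -1):
            if masks[i] is None:
                continue
            masks[i] = masks[i] & ~claimed
            claimed |= masks[i]
        if bg_index is not None:
            masks[bg_index] = ~claimed
        elif not claimed.all():
            raise ValueError("regions do not tile the grid and no background given")
        return masks

    def parameter_maps(self) -> dict[str, np.ndarray]:
        """Ground-truth voxel maps (sigma, nu_int, d_int, d_ext, fiber)."""
        masks = self.region_masks()
        maps = {
            "sigma": np.zeros(self.shape),
            "nu_int": np.zeros(self.shape),
            "d_int": np.zeros(self.shape),
            "d_ext": np.zeros(self.shape),
            "fiber": np.zeros(self.shape + (3,)),
        }
        for r, m in zip(self.regions, masks):
            maps["sigma"][m] = r.sigma
            maps["nu_int"][m] = r.nu_int
            maps["d_int"][m] = r.d_int
            maps["d_ext"][m] = r.d_ext_value()
            maps["fiber"][m] = np.asarray(r.fiber, dtype=float)
        return maps


# ---------------------------------------------------------------------------
# forward phase model
# ---------------------------------------------------------------------------


def _forward_phase_slice(
    sigma: np.ndarray, hx: float, hy: float, omega: float
) -> np.ndarray:
    """Solve div((1/sigma) grad phi) = 2*omega*mu0 on one slice.

    Flux-conservative 5-point scheme with harmonic-mean face conductances
    a = 1/sigma; Dirichlet boundary from the homogeneous-medium quadratic
    phi = omega*mu0*sigma_b*(x^2+y^2)/2 evaluated with the border
    conductivity.
    """
    nx, ny = sigma.shape
    f = 2.0 * omega * MU0
    a = 1.0 / sigma
    # face conductances (harmonic mean of a)
    ax = 2.0 * a[1:, :] * a[:-1, :] / (a[1:, :] + a[:-1, :])  # (nx-1, ny)
    ay = 2.0 * a[:, 1:] * a[:, :-1] / (a[:, 1:] + a[:, :-1])  # (nx, ny-1)

    x = (np.arange(nx) - (nx - 1) / 2.0) * hx
    y = (np.arange(ny) - (ny - 1) / 2.0) * hy
    xx, yy = np.meshgrid(x, y, indexing="ij")
    border = np.zeros((nx, ny), dtype=bool)
    border[0, :] = border[-1, :] = True
    border[:, 0] = border[:, -1] = True
    sigma_b = float(np.mean(sigma[border]))
    phi_bc = omega * MU0 * sigma_b * (xx**2 + yy**2) / 2.0

    interior = ~border
    n = int(interior.sum())
    idx = -np.ones((nx, ny), dtype=int)
    ii, jj = np.nonzero(interior)
    idx[ii, jj] = np.arange(n)

    rows, cols, vals = [], [], []
    b = np.full(n, f)
    diag = np.zeros(n)
    for di, dj in ((1, 0), (-1, 0), (0, 1), (0, -1)):
        ni, nj = ii + di, jj + dj
        if di == 1:
            coef = ax[ii, jj] / hx**2
        elif di == -1:
            coef = ax[ii - 1, jj] / hx**2
        elif dj == 1:
            coef = ay[ii, jj] / hy**2
        else:
            coef = ay[ii, jj - 1] / hy**2
        diag -= coef
        nidx = idx[ni, nj]
        free = nidx >= 0
        rows.append(np.arange(n)[free])
        cols.append(nidx[free])
        vals.append(coef[free])
        fixed = ~free
        b[fixed] -= coef[fixed] * phi_bc[ni[fixed], nj[fixed]]
    rows.append(np.arange(n))
    cols.append(np.arange(n))
    vals.append(diag)
    A = sp.csr_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(n, n),
    )
    phi_int = spla.spsolve(A.tocsc(), b)
    res = np.linalg.norm(A @ phi_int - b) / np.linalg.norm(b)
    if res > 1e-10:
        raise RuntimeError(f"forward phase solve residual {res:.3e} > 1e-10")
    phi = phi_bc.copy()
    phi[ii, jj] = phi_int
    return phi


def forward_phase(
    spec: PhantomSpec,
    cfg: ReconConfig | None = None,
    echo_times_ms: np.ndarray = DEFAULT_ECHO_TIMES_MS,
    t2_ms: float = 80.0,
) -> MultiEchoPhaseVolume:
    """Generate a multi-echo transceive phase volume from the phantom.

    Every echo carries the same transceive phase (spin-echo transceive
    assumption) plus optional independent Gaussian noise; magnitudes follow
    mono-exponential T2 decay exp(-TE/T2).
    """
    cfg = cfg or ReconConfig()
    sigma = spec.parameter_maps()["sigma"]
    hx = spec.voxel_size_mm[0] * 1e-3
    hy = spec.voxel_size_mm[1] * 1e-3
    phi = np.zeros(spec.shape)
    for k in range(spec.shape[2]):
        phi[:, :, k] = _forward_phase_slice(sigma[:, :, k], hx, hy, cfg.omega)
    ne = len(echo_times_ms)
    rng = np.random.default_rng(spec.seed)
    phase = np.repeat(phi[..., None], ne, axis=-1)
    if spec.phase_noise_sd > 0:
        phase = phase + rng.normal(0.0, spec.phase_noise_sd, size=phase.shape)
    mag = np.exp(-np.asarray(echo_times_ms) / t2_ms)[None, None, None, :]
    magnitude = np.broadcast_to(mag, phase.shape).copy()
    return MultiEchoPhaseVolume(
        phase=phase,
        magnitude=magnitude,
        echo_times=np.asarray(echo_times_ms, dtype=float),
        voxel_size=np.asarray(spec.voxel_size_mm, dtype=float),
        affine=spec.affine.copy(),
    )


# ---------------------------------------------------------------------------
# forward diffusion model
# ---------------------------------------------------------------------------


def stick_zeppelin_signal(
    bvals: np.ndarray,
    bvecs: np.ndarray,
    nu_int: float,
    d_int: float,
    fiber: np.ndarray,
) -> np.ndarray:
    """Normalized two-compartment signal S/S0 per acquisition volume.

    Stick (intra-neurite): exp(-b * d_int * (g.n)^2).
    Zeppelin (extra-neurite): axial d_int, radial (1 - nu_int) * d_int
    (tortuosity constraint).
    """
    fiber = np.asarray(fiber, dtype=float)
    dot2 = (bvecs @ fiber) ** 2
    lam_perp = (1.0 - nu_int) * d_int
    stick = np.exp(-bvals * d_int * dot2)
    zeppelin = np.exp(-bvals * (lam_perp + (d_int - lam_perp) * dot2))
    return nu_int * stick + (1.0 - nu_int) * zeppelin


def forward_dwi(
    spec: PhantomSpec,
    bvals: np.ndarray,
    bvecs: np.ndarray,
    s0: float = 1.0,
):
    """Generate a DWI dataset from the phantom on the given scheme.

    Returns a :class:`ctialps.dwi.DwiDataset`.  Rician noise is applied to
    the complex magnitude at SNR = s0 / noise_sd when ``spec.dwi_snr`` is
    set.  Ground-truth maps are available from ``spec.parameter_maps()``.
    """
    from .dwi import DwiDataset

    bvals = np.asarray(bvals, dtype=float)
    bvecs = np.asarray(bvecs, dtype=float)
    maps = spec.parameter_maps()
    masks = spec.region_masks()
    signals = np.zeros(spec.shape + (len(bvals),))
    for r, m in zip(spec.regions, masks):
        if not m.any():
            continue
        sig = stick_zeppelin_signal(
            bvals, bvecs, r.nu_int, r.d_int, np.asarray(r.fiber, dtype=float)
        )
        signals[m] = s0 * sig
    if spec.dwi_snr:
        rng = np.random.default_rng(spec.seed + 1)
        sd = s0 / spec.dwi_snr
        re = signals + rng.normal(0.0, sd, size=signals.shape)
        im = rng.normal(0.0, sd, size=signals.shape)
        signals = np.sqrt(re**2 + im**2)
    return DwiDataset(
        signals=signals,
        bvals=bvals,
        bvecs=bvecs,
        voxel_size=np.asarray(spec.voxel_size_mm, dtype=float),
        affine=spec.affine.copy(),
    )


def fibonacci_sphere(n: int) -> np.ndarray:
    """n unit vectors by the deterministic spherical Fibonacci lattice."""
    i = np.arange(n) + 0.5
    golden = (1.0 + math.sqrt(5.0)) / 2.0
    theta = 2.0 * math.pi * i / golden
    z = 1.0 - 2.0 * i / n
    r = np.sqrt(np.clip(1.0 - z**2, 0.0, 1.0))
    return np.stack([r * np.cos(theta), r * np.sin(theta), z], axis=1)


def repulsion_directions(n: int, n_iter: int = 1000, step: float = 5e-3) -> np.ndarray:
    """n gradient axes by electrostatic repulsion of antipodal point pairs.

    Starts from the deterministic Fibonacci lattice and runs a fixed number
    of projected Coulomb-repulsion steps over the 2n symmetrized points
    (the standard way DWI direction tables are designed, since g and -g
    sample the same axis).  Seedless and bit-reproducible.
    """
    p = fibonacci_sphere(n)
    for _ in range(n_iter):
        force = np.zeros_like(p)
        for q in (p, -p):
            diff = p[:, None, :] - q[None, :, :]
            dist2 = (diff**2).sum(-1)
            np.fill_diagonal(dist2, np.inf)
            dist2[dist2 < 1e-12] = np.inf
            force += (diff / dist2[..., None] ** 1.5).sum(axis=1)
        # project onto the tangent plane and renormalize
        force -= (force * p).sum(-1, keepdims=True) * p
        p = p + step * force
        p /= np.linalg.norm(p, axis=1, keepdims=True)
    # canonical hemisphere orientation for reproducible signs
    flip = p[:, 2] < 0
    p[flip] *= -1.0
    return p


def make_default_scheme() -> tuple[np.ndarray, np.ndarray]:
    """Default two-shell acquisition: 6 b=0 volumes, 16 directions at
    b = 800 s/mm^2 and 32 at b = 2000 s/mm^2 (repulsion-optimized axes)."""
    bvals = np.concatenate([np.zeros(6), np.full(16, 800.0), np.full(32, 2000.0)])
    bvecs = np.concatenate(
        [np.zeros((6, 3)), repulsion_directions(16), repulsion_directions(32)]
    )
    return bvals, bvecs


# ---------------------------------------------------------------------------
# full ALPS phantom
# ---------------------------------------------------------------------------

# template-space ROI centers (mm): projection and association fiber sites,
# left/right, at the level of the lateral-ventricle body
ALPS_ROI_CENTERS = {
    "projection_R": (24.0, -12.0, 24.0),
    "projection_L": (-28.0, -12.0, 24.0),
    "association_R": (36.0, -12.0, 24.0),
    "association_L": (-40.0, -12.0, 24.0),
}


def _alps_affine_and_shape():
    """2 mm isotropic grid whose voxel centers hit every default ROI center."""
    shape = (54, 14, 10)
    aff = np.diag([2.0, 2.0, 2.0, 1.0])
    aff[:3, 3] = (-54.0, -26.0, 14.0)
    return aff, shape


def default_alps_zones() -> dict:
    """Compartment parameters of the two fiber-zone types.

    Both zones carry z-oriented fibers (the axis alignment the closed-form
    index presumes: projection x/y radial, association z axial) and share
    the C_L scalar prefactor (1-nu)/(nu*beta*D_int+(1-nu)*D_ext), so the
    component-ratio and closed-form indices agree at ground truth.
    """
    proj = dict(nu_int=0.6, d_int=1.7e-3, sigma=0.8)

    def prefactor(nu, d_int):
        d_ext = d_int * (1.0 + 2.0 * (1.0 - nu)) / 3.0
        return (1.0 - nu) / (nu * d_int + (1.0 - nu) * d_ext)

    # association zone: nu = 0.5 with D_int chosen so the prefactor matches
    # the projection zone under the tortuosity constraint
    nu_a = 0.5
    f_a = nu_a + (1.0 - nu_a) * (1.0 + 2.0 * (1.0 - nu_a)) / 3.0
    d_int_a = (1.0 - nu_a) / (f_a * prefactor(proj["nu_int"], proj["d_int"]))
    assoc = dict(nu_int=nu_a, d_int=d_int_a, sigma=0.8)
    return {"projection": proj, "association": assoc}


def make_alps_phantom(
    zones: dict | None = None,
    background_sigma: float = 0.6,
    background_adc: float = 0.9e-3,
    zone_size_mm: float = 10.0,
    phase_noise_sd: float = 0.0,
    dwi_snr: float | None = None,
    seed: int = 0,
) -> "AlpsPhantom":
    """Build one synthetic subject for the end-to-end ALPS pipeline.

    Cubic fiber zones are placed around the four template ROI centers:
    projection-type zones at x = +24/-28 mm and association-type zones at
    x = +36/-40 mm (y = -12, z = 24 mm).  The background is isotropic
    (nu_int = 0).  Ground-truth ALPS values are computed from the zone
    parameters via the closed form and via the composed tensor ratio.
    """
    zones = zones or default_alps_zones()
    aff, shape = _alps_affine_and_shape()
    regions = [
        Region(kind="background", sigma=background_sigma, nu_int=0.0,
               d_int=background_adc, d_ext=background_adc),
    ]
    for name, center in ALPS_ROI_CENTERS.items():
        z = zones["projection" if name.startswith("projection") else "association"]
        regions.append(
            Region(
                kind="box",
                center_mm=center,
                size_mm=(zone_size_mm,) * 3,
                sigma=z["sigma"],
                nu_int=z["nu_int"],
                d_int=z["d_int"],
                d_ext=z.get("d_ext"),
                fiber=(0.0, 0.0, 1.0),
            )
        )
    spec = PhantomSpec(
        shape=shape,
        voxel_size_mm=(2.0, 2.0, 2.0),
        regions=regions,
        phase_noise_sd=phase_noise_sd,
        dwi_snr=dwi_snr,
        seed=seed,
        affine=aff,
    )
    return AlpsPhantom(spec=spec, zones=zones)


@dataclass
class AlpsPhantom:
    """A full synthetic subject: spec plus ground-truth index values."""

    spec: PhantomSpec
    zones: dict

    def ground_truth(self, beta: float = 1.0) -> dict:
        """Ground-truth CTI-ALPS (closed form and composed component ratio)
        and DTI-ALPS (from zone tensors fitted on the default scheme)."""
        from .alps import cti_alps_closed_form
        from .conductivity import extra_neurite_eigenvalues, low_frequency_sigma
        from .dti import DiffusionTensorModel
        from .dwi import DwiDataset

        p, a = self.zones["projection"], self.zones["association"]
        d_ext = {
            k: z.get("d_ext")
            or z["d_int"] * (1.0 + 2.0 * (1.0 - z["nu_int"])) / 3.0
            for k, z in (("p", p), ("a", a))
        }
        closed_form = cti_alps_closed_form(
            nu_ip=p["nu_int"], d_ip=p["d_int"],
            nu_ia=a["nu_int"], d_ia=a["d_int"], d_ea=d_ext["a"],
        )
        # composed component ratio from the exact C_L of each zone
        comps = {}
        for key, z, de in (("p", p, d_ext["p"]), ("a", a, d_ext["a"])):
            d1, d2, d3 = extra_neurite_eigenvalues(z["nu_int"], z["d_int"], de)
            sig_l = low_frequency_sigma(z["sigma"], z["nu_int"], z["d_int"], de, beta)
            pref = sig_l / de  # prefactor * eigenvalues gives C_L diag (fiber=z)
            comps[key] = dict(xx=pref * d1, yy=pref * d2, zz=pref * d3)
        component_ratio = (comps["p"]["xx"] + comps["a"]["xx"]) / (
            comps["p"]["yy"] + comps["a"]["zz"]
        )
        # DTI-ALPS truth: fit the zone signal (uniform within a zone) once
        bvals, bvecs = make_default_scheme()
        dti = {}
        for key, z in (("p", p), ("a", a)):
            sig = stick_zeppelin_signal(
                bvals, bvecs, z["nu_int"], z["d_int"], np.array([0.0, 0.0, 1.0])
            )
            dti_truth = {}
            for shell in (800.0, 2000.0):
                sel = (bvals == 0) | (bvals == shell)
                ds = DwiDataset(
                    signals=sig[None, None, None, sel],
                    bvals=bvals[sel],
                    bvecs=bvecs[sel],
                    voxel_size=np.array([2.0, 2.0, 2.0]),
                )
                fitted = DiffusionTensorModel(ds).fit()
                dti_truth[shell] = fitted.tensor[0, 0, 0]
            dti[key] = dti_truth
        dti_alps = {
            shell: (dti["p"][shell][0, 0] + dti["a"][shell][0, 0])
            / (dti["p"][shell][1, 1] + dti["a"][shell][2, 2])
            for shell in (800.0, 2000.0)
        }
        return {
            "cti_alps_closed_form": float(closed_form),
            "cti_alps": float(component_ratio),
            "dti_alps": {k: float(v) for k, v in dti_alps.items()},
        }

    def generate(self, cfg: ReconConfig | None = None):
        """Produce (phase volume, DWI dataset, ground-truth maps)."""
        bvals, bvecs = make_default_scheme()
        phase = forward_phase(self.spec, cfg)
        dwi = forward_dwi(self.spec, bvals, bvecs)
        return phase, dwi, self.spec.parameter_maps()

    def write(self, out_dir: str | Path, cfg: ReconConfig | None = None) -> Path:
        """Write NIfTI volumes, bval/bvec and ground-truth JSON to a
        directory layout the CLI consumes."""
        from . import io as cio

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        phase, dwi, maps = self.generate(cfg)
        aff = self.spec.affine
        cio.save_nifti(out / "phase.nii", phase.phase, aff)
        cio.save_nifti(out / "magnitude.nii", phase.magnitude, aff)
        (out / "echo_times.json").write_text(
            json.dumps({"echo_times_ms": list(map(float, phase.echo_times))})
        )
        cio.save_nifti(out / "dwi.nii", dwi.signals, aff)
        cio.save_bvals_bvecs(out / "dwi.bval", out / "dwi.bvec", dwi.bvals, dwi.bvecs)
        mask = np.ones(self.spec.shape, dtype=np.uint8)
        cio.save_nifti(out / "mask.nii", mask, aff)
        for name in ("sigma", "nu_int", "d_int", "d_ext"):
            cio.save_nifti(out / f"truth_{name}.nii", maps[name], aff)
        (out / "ground_truth.json").write_text(
            json.dumps(self.ground_truth(), indent=2)
        )
        return out
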