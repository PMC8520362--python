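"""Digital phantom of the anal sphincter complex (ASC).

The phantom is an analytic, piecewise-constant 3D intensity field in patient
space (mm; x = patient left, y = anterior, z = cranial) holding the three
structures measured by transperineal 3D ultrasound:

* **IAS** — internal anal sphincter, a full ring around the anal canal over
  its whole length;
* **EAS** — external anal sphincter, a ring abutting the IAS outer wall in a
  band around the *distal* plane only;
* **PRM** — puborectalis muscle, a posterior horseshoe (a sling open
  anteriorly, default arc 210 degrees centered on the posterior axis)
  abutting the IAS outer wall in a band around the *mid* plane.  The arc
  extends past the 3/9 o'clock axis so the sling's free ends stay clear of
  every measurement ray, as they do anatomically.

The three measurement planes sit at fixed fractions 0.8 / 0.5 / 0.2
(proximal / mid / distal) of the canal length along z.  Ground-truth ring
thicknesses are exact by construction (outer minus inner radius), which is
what makes the phantom usable as an end-to-end oracle for reconstruction and
morphometry.

Default dimensions echo the magnitudes reported for primiparous women
(IAS ~2 mm, EAS ~2 mm, PRM ~7 mm walls); intensities span 0-100 arbitrary
ultrasound units with distinct levels per tissue so boundaries between
adjacent structures are well defined.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .errors import DomainError
from .grid import VoxelGrid
from .kernels import PointCloud

PLANE_Z_FRACTION = {"proximal": 0.8, "mid": 0.5, "distal": 0.2}

#: z band (fractions of canal_length) where each optional structure exists
EAS_Z_BAND = (0.1, 0.3)
PRM_Z_BAND = (0.4, 0.6)

#: measurement protocol sites: structure -> {plane: clock positions}
MEASUREMENT_SITES = {
    "IAS": {"proximal": (3, 6, 9, 12), "mid": (3, 6, 9, 12), "distal": (3, 6, 9, 12)},
    "EAS": {"distal": (3, 6, 9, 12)},
    "PRM": {"mid": (4, 8)},
}


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry, intensity and acquisition parameters of the phantom.

    All lengths in mm.  ``margin`` pads the bounding box beyond the outermost
    structure so measurement rays see background on both sides of every wall.
    """

    ias_inner_radius: float = 5.0
    ias_thickness: float = 2.0
    eas_thickness: float = 2.0
    prm_thickness: float = 7.0
    prm_arc_deg: float = 210.0
    canal_length: float = 30.0
    margin: float = 2.0
    intensities: dict = field(
        default_factory=lambda: {"background": 0.0, "EAS": 40.0, "IAS": 70.0, "PRM": 100.0}
    )
    blur_sigma: float = 0.0
    noise_sd: float = 10.0
    seed: int = 0

    def __post_init__(self):
        for name in ("ias_inner_radius", "ias_thickness", "eas_thickness",
                     "prm_thickness", "canal_length"):
            if getattr(self, name) <= 0:
                raise DomainError(f"{name} must be positive")
        if not 0 < self.prm_arc_deg <= 360:
            raise DomainError("prm_arc_deg must be in (0, 360]")
        if self.noise_sd < 0:
            raise DomainError("noise_sd must be non-negative")
        if self.blur_sigma < 0:
            raise DomainError("blur_sigma must be non-negative")

    @property
    def ias_outer_radius(self) -> float:
        return self.ias_inner_radius + self.ias_thickness

    @property
    def box(self) -> tuple[np.ndarray, np.ndarray]:
        """(lower, upper) corners of the phantom bounding box."""
        r = self.ias_outer_radius + self.prm_thickness + self.margin
        lower = np.array([-r, -r, 0.0])
        upper = np.array([r, r, self.canal_length])
        return lower, upper

    @property
    def intensity_range(self) -> float:
        vals = list(self.intensities.values())
        return max(vals) - min(vals)


@dataclass(frozen=True)
class GroundTruth:
    """Analytic phantom: the noiseless field plus exact per-site thicknesses."""

    spec: PhantomSpec

    def field(self, positions) -> np.ndarray:
        """Noiseless intensity at arbitrary positions (n, 3) -> (n,)."""
        p = np.atleast_2d(np.asarray(positions, dtype=float))
        s = self.spec
        x, y, z = p[:, 0], p[:, 1], p[:, 2]
        r = np.hypot(x, y)
        L = s.canal_length
        vals = np.full(len(p), s.intensities["background"])
        in_canal = (z >= 0) & (z <= L)
        ro = s.ias_outer_radius
        ias = in_canal & (r >= s.ias_inner_radius) & (r < ro)
        vals[ias] = s.intensities["IAS"]
        eas = (
            (z >= EAS_Z_BAND[0] * L)
            & (z <= EAS_Z_BAND[1] * L)
            & (r >= ro)
            & (r < ro + s.eas_thickness)
        )
        vals[eas] = s.intensities["EAS"]
        # sling angle measured from the posterior (-y) axis
        phi = np.degrees(np.abs(np.arctan2(x, -y)))
        prm = (
            (z >= PRM_Z_BAND[0] * L)
            & (z <= PRM_Z_BAND[1] * L)
            & (phi <= s.prm_arc_deg / 2.0)
            & (r >= ro)
            & (r < ro + s.prm_thickness)
        )
        vals[prm] = s.intensities["PRM"]
        return vals if np.ndim(positions) == 2 else float(vals[0])

    def expected_thickness(self, structure: str, plane: str, clock: int) -> float:
        """Exact wall thickness (mm) at a protocol site; by ring construction."""
        sites = MEASUREMENT_SITES.get(structure, {})
        if plane not in sites or clock not in sites[plane]:
            raise DomainError(f"{structure} is not measured at {plane} {clock} o'clock")
        return {
            "IAS": self.spec.ias_thickness,
            "EAS": self.spec.eas_thickness,
            "PRM": self.spec.prm_thickness,
        }[structure]

    def thickness_table(self):
        """All 18 protocol sites as (structure, plane, clock, thickness_mm)."""
        rows = []
        for structure, planes in MEASUREMENT_SITES.items():
            for plane, clocks in planes.items():
                for clock in clocks:
                    rows.append(
                        (structure, plane, clock, self.expected_thickness(structure, plane, clock))
                    )
        return rows


def make_phantom(spec: PhantomSpec) -> GroundTruth:
    """Build the analytic ground truth for ``spec`` (deterministic)."""
    return GroundTruth(spec=spec)


def sample_cloud(
    truth: GroundTruth,
    n: int,
    noise_sd: float | None = None,
    seed: int | None = None,
    mode: str = "uniform",
) -> PointCloud:
    """Draw a noisy scattered sampling of the phantom field.

    ``mode="uniform"`` scatters positions uniformly over the phantom box.
    ``mode="sweep"`` emulates a freehand fan acquisition: dense transverse
    (x, y) planes at z positions jittered around a regular sweep from the
    distal end to the anorectal angle.  Values are the noiseless field plus
    i.i.d. Gaussian noise of standard deviation ``noise_sd``.
    """
    if n < 1:
        raise DomainError("n must be >= 1")
    sd = truth.spec.noise_sd if noise_sd is None else float(noise_sd)
    if sd < 0:
        raise DomainError("noise_sd must be non-negative")
    rng = np.random.default_rng(truth.spec.seed if seed is None else seed)
    lower, upper = truth.spec.box
    if mode == "uniform":
        pos = rng.uniform(lower, upper, size=(n, 3))
    elif mode == "sweep":
        n_planes = max(2, int(round(truth.spec.canal_length)))
        z_centers = np.linspace(lower[2], upper[2], n_planes)
        z = rng.choice(z_centers, size=n) + rng.normal(0.0, 0.25, size=n)
        z = np.clip(z, lower[2], upper[2])
        xy = rng.uniform(lower[:2], upper[:2], size=(n, 2))
        pos = np.column_stack([xy, z])
    else:
        raise DomainError(f"unknown sampling mode {mode!r}")
    vals = truth.field(pos) + rng.normal(0.0, sd, size=n)
    return PointCloud(positions=pos, values=vals)


def rasterize_truth(truth: GroundTruth, grid: VoxelGrid) -> VoxelGrid:
    """Evaluate the noiseless field at every voxel center of ``grid``.

    If ``spec.blur_sigma > 0`` the rasterized volume is smoothed with an
    isotropic Gaussian of that physical width (a simple point-spread-function
    stand-in applied in the voxel domain).
    """
    vals = truth.field(grid.voxel_centers()).reshape(grid.shape)
    if truth.spec.blur_sigma > 0:
        vals = ndimage.gaussian_filter(vals, sigma=truth.spec.blur_sigma / grid.spacing)
    return VoxelGrid(data=vals, spacing=grid.spacing, origin=grid.origin)
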