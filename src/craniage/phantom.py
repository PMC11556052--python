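"""Craniovertebral phantom rendering.

Each synthetic subject is rendered into

* a 3D volume containing a stylised atlantoaxial joint: the atlas anterior
  arch as a full bony ring (annulus) in the axial plane and the dens as a
  capped vertical peg on the ring's axis, separated radially by the
  subject's latent gap.  Exostoses appear as small bright bumps at the
  three scored sites.  Voxel intensities are 0–255 with the subject's
  latent bone brightness (an age-falling quantity) on bone and dim noise
  elsewhere; the exact construction coordinates are returned as a landmark
  annotation.
* a 2D sagittal scanogram with dark elliptical frontal/sphenoid sinus
  regions and a clivus region filled with Gaussian bone texture of the
  subject's latent brightness mean/SD, plus the exact region masks.

The phantom's primitives are chosen for analytic ground truth, not visual
realism: every landmark and mask is known by construction, so the
downstream measurement, grading and learning stages can be validated
against exact latents.

Conventions: voxel indices are 0-based, boxes half-open; volume axes are
(X, Y, Z) with Z the cranio-caudal axis; isotropic spacing in mm/voxel.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import nibabel as nib
import numpy as np
from skimage.draw import ellipse as draw_ellipse

from .cohort import ExostosisState, Subject


class GeometryError(ValueError):
    """Phantom or region geometry does not fit the requested canvas."""


class FormatError(ValueError):
    """A volume file is malformed or unreadable."""


@dataclass
class Volume3D:
    """A 3D intensity grid (0–255) with isotropic voxel spacing in mm."""

    intensities: np.ndarray  # shape (nx, ny, nz), float32 in [0, 255]
    spacing: float | tuple[float, float, float] = 0.5

    def __post_init__(self) -> None:
        a = np.asarray(self.intensities)
        if a.ndim != 3:
            raise ValueError("intensities must be a 3D array")
        if min(a.shape) < 32:
            raise ValueError("volume must be at least 32 voxels per axis")
        if float(a.min()) < 0 or float(a.max()) > 255:
            raise ValueError("intensities must lie in [0, 255]")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.intensities.shape

    def spacing_tuple(self) -> tuple[float, float, float]:
        s = self.spacing
        return (s, s, s) if np.isscalar(s) else tuple(s)


@dataclass
class LandmarkAnnotation:
    """The three manually-identifiable landmark quantities of the joint.

    ``atlas_z_max``/``atlas_z_min`` are the voxel Z of the highest and
    lowest atlas points; ``dens_apex`` is the (X0, Y0, Z0) voxel of the
    odontoid apex.
    """

    atlas_z_min: int
    atlas_z_max: int
    dens_apex: tuple[int, int, int]

    def __post_init__(self) -> None:
        if not self.atlas_z_min < self.atlas_z_max:
            raise ValueError("atlas_z_min must be below atlas_z_max")

    def to_dict(self) -> dict:
        return {
            "atlas_z_min": int(self.atlas_z_min),
            "atlas_z_max": int(self.atlas_z_max),
            "dens_apex": [int(v) for v in self.dens_apex],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "LandmarkAnnotation":
        return cls(int(d["atlas_z_min"]), int(d["atlas_z_max"]),
                   tuple(int(v) for v in d["dens_apex"]))


@dataclass
class Scanogram2D:
    """A 2D sagittal projection (0–255) with named boolean region masks."""

    image: np.ndarray
    masks: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        for name, m in self.masks.items():
            if m.shape != self.image.shape:
                raise ValueError(f"mask {name!r} shape differs from image")
            if not m.any():
                raise ValueError(f"mask {name!r} is empty")
        stack = np.stack(list(self.masks.values()))
        if (stack.sum(axis=0) > 1).any():
            raise GeometryError("region masks overlap")


@dataclass(frozen=True)
class PhantomSpec:
    """Physical dimensions (mm) of the rendered joint phantom.

    The arch outer radius is age-constant; involution narrows the joint
    space from the inside (the ring thickens as the gap closes), mirroring
    how the real arch keeps its outer contour while the articular gap
    narrows.
    """

    dens_radius_mm: float = 2.0
    arch_outer_radius_mm: float = 7.0
    arch_height_mm: float = 8.0
    dens_below_arch_mm: float = 2.0
    apex_above_arch_mm: float = 2.0
    exostosis_radius_present_mm: float = 0.6
    exostosis_radius_marked_mm: float = 1.1
    background_mean: float = 20.0
    background_noise_sd: float = 8.0
    bone_noise_sd: float = 4.0


def render_volume(
    subject: Subject,
    shape: tuple[int, int, int] = (96, 96, 96),
    spacing: float = 0.5,
    rng: np.random.Generator | None = None,
    spec: PhantomSpec = PhantomSpec(),
    offset: tuple[int, int, int] = (0, 0, 0),
    center_jitter: float = 1.5,
) -> tuple[Volume3D, LandmarkAnnotation]:
    """Render one subject's joint phantom and its exact landmark annotation.

    With ``rng=None`` the render is noise-free (flat background and bone,
    no centre jitter).  ``offset`` translates the whole phantom in voxels;
    annotations shift with it exactly.
    """
    nx, ny, nz = shape
    sp = spacing
    gap_vox = subject.geometry.gap_mm / sp
    r_in = spec.dens_radius_mm / sp + gap_vox
    r_out = spec.arch_outer_radius_mm / sp
    if r_in >= r_out:
        raise GeometryError(
            f"joint gap {subject.geometry.gap_mm} mm leaves no arch wall "
            f"(inner radius {r_in:.1f} vox >= outer {r_out:.1f} vox)")

    jx = jy = jz = 0.0
    if rng is not None and center_jitter > 0:
        jx, jy, jz = rng.uniform(-center_jitter, center_jitter, size=3)
    cx = nx / 2 + jx + offset[0]
    cy = ny / 2 + jy + offset[1]
    arch_h = spec.arch_height_mm / sp
    z_arch_min = int(round(nz / 2 - arch_h / 2 + jz)) + offset[2]
    z_arch_max = int(round(z_arch_min + arch_h)) - 1  # inclusive top arch voxel
    apex_rise = spec.apex_above_arch_mm / sp
    if subject.geometry.apex_above_arch:
        z_apex = int(round(z_arch_max + apex_rise))
    else:
        z_apex = z_arch_max - 1
    z_dens_min = int(round(z_arch_min - spec.dens_below_arch_mm / sp))

    margin = math.ceil(spec.exostosis_radius_marked_mm / sp) + 1
    if (cx - r_out < 1 or cx + r_out > nx - 2 or cy - r_out < 1 or
            cy + r_out > ny - 2 or z_dens_min < 1 or
            z_apex + margin > nz - 2 or z_arch_min < 1):
        raise GeometryError("phantom does not fit inside the requested volume")

    X, Y = np.meshgrid(np.arange(nx), np.arange(ny), indexing="ij")
    rad = np.hypot(X - cx, Y - cy)
    ring2d = (rad >= r_in) & (rad <= r_out)
    dens2d = rad <= spec.dens_radius_mm / sp

    bone = np.zeros(shape, dtype=bool)
    bone[:, :, z_arch_min : z_arch_max + 1] |= ring2d[:, :, None]
    # dens shaft with a rounded (hemispherical) apex
    cap_start = z_apex - int(round(spec.dens_radius_mm / sp))
    for z in range(z_dens_min, z_apex + 1):
        if z < cap_start:
            bone[:, :, z] |= dens2d
        else:
            # shrink radius along the cap so the apex voxel is the topmost
            frac = (z_apex - z) / max(z_apex - cap_start, 1)
            r_z = spec.dens_radius_mm / sp * math.sqrt(max(frac, 1e-6))
            if z == z_apex:
                r_z = 0.75  # tip: covers exactly the voxel nearest the axis
            bone[:, :, z] |= rad <= r_z

    # exostoses: small bright spheres at the three scored sites
    def add_bump(center: tuple[float, float, float], state: ExostosisState) -> None:
        if state is ExostosisState.ABSENT:
            return
        r_mm = (spec.exostosis_radius_marked_mm if state is ExostosisState.MARKED
                else spec.exostosis_radius_present_mm)
        r = max(r_mm / sp, 1.0)
        x0, y0, z0 = center
        xr = np.arange(max(int(x0 - r) - 1, 0), min(int(x0 + r) + 2, nx))
        yr = np.arange(max(int(y0 - r) - 1, 0), min(int(y0 + r) + 2, ny))
        zr = np.arange(max(int(z0 - r) - 1, 0), min(int(z0 + r) + 2, nz))
        XX, YY, ZZ = np.meshgrid(xr, yr, zr, indexing="ij")
        ball = (XX - x0) ** 2 + (YY - y0) ** 2 + (ZZ - z0) ** 2 <= r**2
        sub = bone[np.ix_(xr, yr, zr)]
        bone[np.ix_(xr, yr, zr)] = sub | ball

    g = subject.geometry
    # superior / inferior arch margin bumps sit on the anterior outer rim
    add_bump((cx, cy - r_out, z_arch_max + 1), g.exostosis_superior)
    add_bump((cx, cy - r_out, z_arch_min - 1), g.exostosis_inferior)
    # the apex bump sits laterally on the dens tip so it cannot raise Z0
    add_bump((cx + spec.dens_radius_mm / sp * 0.6, cy, z_apex), g.exostosis_apex)

    bone_brightness = subject.texture.clivus_brightness_mean
    if rng is None:
        vol = np.full(shape, spec.background_mean, dtype=np.float32)
        vol[bone] = bone_brightness
    else:
        vol = rng.normal(spec.background_mean, spec.background_noise_sd,
                         size=shape).astype(np.float32)
        vol[bone] = rng.normal(bone_brightness, spec.bone_noise_sd,
                               size=int(bone.sum())).astype(np.float32)
    np.clip(vol, 0.0, 255.0, out=vol)

    # topmost bone voxel on the dens axis defines Z0
    axis_col = bone[int(round(cx)), int(round(cy)), :]
    z0 = int(np.nonzero(axis_col)[0].max())
    ann = LandmarkAnnotation(
        atlas_z_min=z_arch_min,
        atlas_z_max=z_arch_max,
        dens_apex=(int(round(cx)), int(round(cy)), z0),
    )
    return Volume3D(vol, spacing=spacing), ann


# ---------------------------------------------------------------------------
# 2D scanogram


def _ellipse_mask(shape: tuple[int, int], params: tuple[float, float, float, float, float]
                  ) -> np.ndarray:
    """Rasterize a (cx, cy, a, b, angle_deg) unit-square ellipse spec."""
    h, w = shape
    cx, cy, a, b, ang = params
    rr, cc = draw_ellipse(cx * h, cy * w, a * h, b * w,
                          shape=shape, rotation=math.radians(ang))
    m = np.zeros(shape, dtype=bool)
    m[rr, cc] = True
    return m


def render_scanogram(
    subject: Subject,
    shape: tuple[int, int] = (256, 256),
    rng: np.random.Generator | None = None,
) -> Scanogram2D:
    """Render the sagittal scanogram with sinus and clivus masks.

    Sinuses are dark air-filled ellipses; the clivus region carries
    Gaussian bone texture with the subject's latent brightness mean/SD
    (``rng=None`` gives the noise-free constant-texture render).  Masks
    match the drawn regions exactly.
    """
    if min(shape) < 256:
        raise ValueError("scanogram must be at least 256x256")
    t = subject.texture
    frontal = _ellipse_mask(shape, t.frontal_ellipse)
    sphenoid = _ellipse_mask(shape, t.sphenoid_ellipse)
    # clivus / clinoid plate: an oblique band running postero-inferiorly
    # from the sphenoid region
    h, w = shape
    X, Y = np.meshgrid(np.arange(h), np.arange(w), indexing="ij")
    u = (X - 0.60 * h) * math.cos(math.radians(35)) + (Y - 0.55 * w) * math.sin(
        math.radians(35))
    v = -(X - 0.60 * h) * math.sin(math.radians(35)) + (Y - 0.55 * w) * math.cos(
        math.radians(35))
    clivus = (np.abs(u) < 0.16 * h) & (np.abs(v) < 0.035 * w)
    clivus &= ~(frontal | sphenoid)
    if (frontal & sphenoid).any():
        raise GeometryError("frontal and sphenoid sinus regions overlap")
    if not clivus.any():
        raise GeometryError("clivus band vanished after removing sinus overlap")

    if rng is None:
        img = np.full(shape, 90.0, dtype=np.float32)
    else:
        img = rng.normal(90.0, 6.0, size=shape).astype(np.float32)
    for m in (frontal, sphenoid):
        img[m] = 25.0 if rng is None else rng.normal(25.0, 4.0, size=int(m.sum()))
    n_cl = int(clivus.sum())
    if rng is None or t.clivus_brightness_sd == 0:
        img[clivus] = t.clivus_brightness_mean
    else:
        img[clivus] = rng.normal(t.clivus_brightness_mean, t.clivus_brightness_sd,
                                 size=n_cl)
    np.clip(img, 0.0, 255.0, out=img)
    return Scanogram2D(image=img, masks={
        "frontal_sinus": frontal, "sphenoid_sinus": sphenoid, "clivus": clivus,
    })


# ---------------------------------------------------------------------------
# I/O


def write_volume(volume: Volume3D, path: str | Path) -> None:
    """Write a volume as NIfTI (.nii / .nii.gz) with spacing in the affine."""
    sx, sy, sz = volume.spacing_tuple()
    affine = np.diag([sx, sy, sz, 1.0])
    nib.save(nib.Nifti1Image(volume.intensities.astype(np.float32), affine), str(path))


def read_volume(path: str | Path) -> Volume3D:
    """Read a NIfTI volume; raises :class:`FormatError` on malformed files."""
    try:
        img = nib.load(str(path))
        data = np.asarray(img.get_fdata(), dtype=np.float32)
    except Exception as exc:
        raise FormatError(f"cannot read NIfTI volume {path}: {exc}") from exc
    if data.ndim != 3:
        raise FormatError(f"expected a 3D volume, got shape {data.shape}")
    zooms = tuple(float(z) for z in img.header.get_zooms()[:3])
    spacing = zooms[0] if len(set(zooms)) == 1 else zooms
    return Volume3D(np.clip(data, 0, 255), spacing=spacing)


def write_scanogram(scan: Scanogram2D, path: str | Path) -> None:
    """Write the scanogram image as 8-bit PNG (or BMP by extension)."""
    iio.imwrite(str(path), np.round(scan.image).astype(np.uint8))


def read_scanogram_image(path: str | Path) -> np.ndarray:
    return np.asarray(iio.imread(str(path)), dtype=np.float32)
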