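"""Seeded generator of synthetic multispectral eardrum image sets.

Real multispectral otoscopy data of the tympanic membrane (TM) is rarely
shareable, so this module renders phantoms that reproduce the *contrast
structure* such data shows rather than its photorealistic appearance: an
elliptical TM with an attached malleus-handle strip and a cone-of-light
wedge, curvilinear blood vessels, and four co-registered illumination
channels (white / red / green / blue) whose per-channel photometry encodes
what matters for segmentation —

* **red**: strong TM-versus-canal contrast, vessels invisible (hemoglobin
  absorbs little red light), malleus at the same intensity as the canal
  wall, and a homogeneous low-noise canal wall;
* **white, green**: small TM/canal separation with overlapping intensity
  histograms and clearly visible dark vessels crossing the TM rim;
* **blue**: dim and heavily noisy (poor illumination of the ear cavity).

Ground-truth masks come from the generating geometry and are independent of
all photometric parameters. Every render is deterministic given (spec, seed).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, replace
from importlib import resources
from pathlib import Path

import numpy as np
import yaml
from scipy import ndimage

from .geometry import Ellipse
from .msio import ChannelImage, write_mask, write_image, read_image

__all__ = [
    "CHANNELS",
    "ChannelPhotometry",
    "MalleusSpec",
    "ConeSpec",
    "PhantomSpec",
    "MultispectralSet",
    "PhantomSpecError",
    "default_phantom_spec",
    "generate_phantom",
    "generate_cohort",
    "derive_cohort_seeds",
    "jitter_spec",
]

CHANNELS = ("white", "red", "green", "blue")

#: reference raster the default geometry is stated at (CCD resolution)
REFERENCE_SIZE = (976, 494)


class PhantomSpecError(ValueError):
    """A phantom spec violates one of its invariants."""


@dataclass(frozen=True)
class ChannelPhotometry:
    """Per-channel rendering parameters, all on the [0, 1] intensity scale."""

    tm_mean: float
    outside_mean: float
    malleus_mean: float
    vessel_contrast: float
    cone_gain: float
    noise_sd: float


@dataclass(frozen=True)
class MalleusSpec:
    """Malleus-handle strip: from the TM ellipse's upper rim to the umbo
    (ellipse center), ``width`` px wide, reaching the rim at image-frame
    angle ``angle`` (radians, y down; negative = upward)."""

    width: float
    angle: float


@dataclass(frozen=True)
class ConeSpec:
    """Cone-of-light wedge: vertex at the umbo, opening ``extent`` radians
    around direction ``angle`` (pointing into the anterior-inferior
    quadrant), reaching out to ``radial_fraction`` of the rim."""

    angle: float
    extent: float
    radial_fraction: float = 0.85


@dataclass(frozen=True)
class PhantomSpec:
    width: int
    height: int
    tm_ellipse: Ellipse
    malleus: MalleusSpec
    cone_of_light: ConeSpec
    n_vessels: int
    vessel_width: float
    photometry: dict[str, ChannelPhotometry]

    def validate(self) -> None:
        """Raise :class:`PhantomSpecError` naming the first violated invariant."""
        e = self.tm_ellipse
        # extent of a rotated ellipse along image axes
        c, s = math.cos(e.theta), math.sin(e.theta)
        ext_x = math.sqrt((e.a * c) ** 2 + (e.b * s) ** 2)
        ext_y = math.sqrt((e.a * s) ** 2 + (e.b * c) ** 2)
        if not (e.cx - ext_x > 0 and e.cx + ext_x < self.width - 1
                and e.cy - ext_y > 0 and e.cy + ext_y < self.height - 1):
            raise PhantomSpecError("tm_ellipse must lie strictly inside the image bounds")
        if self.malleus.width <= 0:
            raise PhantomSpecError("malleus width must be positive")
        if self.n_vessels < 0:
            raise PhantomSpecError("n_vessels must be non-negative")
        if self.vessel_width <= 0:
            raise PhantomSpecError("vessel_width must be positive")
        missing = [ch for ch in CHANNELS if ch not in self.photometry]
        if missing:
            raise PhantomSpecError(f"photometry missing channels: {missing}")
        for ch, p in self.photometry.items():
            for name in ("tm_mean", "outside_mean", "malleus_mean", "noise_sd"):
                v = getattr(p, name)
                if not (0.0 <= v <= 1.0):
                    raise PhantomSpecError(f"{ch}.{name}={v} outside [0, 1]")
            if p.vessel_contrast < 0:
                raise PhantomSpecError(f"{ch}.vessel_contrast must be >= 0")

    # -- (de)serialization ------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "geometry": {
                "width": self.width,
                "height": self.height,
                "tm_ellipse": self.tm_ellipse.to_dict(),
                "malleus": {"width": self.malleus.width, "angle": self.malleus.angle},
                "cone_of_light": {
                    "angle": self.cone_of_light.angle,
                    "extent": self.cone_of_light.extent,
                    "radial_fraction": self.cone_of_light.radial_fraction,
                },
                "n_vessels": self.n_vessels,
                "vessel_width": self.vessel_width,
            },
            "photometry": {ch: vars(p).copy() for ch, p in self.photometry.items()},
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PhantomSpec":
        g = d["geometry"]
        return cls(
            width=int(g["width"]),
            height=int(g["height"]),
            tm_ellipse=Ellipse.from_dict(g["tm_ellipse"]),
            malleus=MalleusSpec(**g["malleus"]),
            cone_of_light=ConeSpec(**g["cone_of_light"]),
            n_vessels=int(g["n_vessels"]),
            vessel_width=float(g["vessel_width"]),
            photometry={ch: ChannelPhotometry(**p) for ch, p in d["photometry"].items()},
        )

    @classmethod
    def from_yaml(cls, path) -> "PhantomSpec":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)


@dataclass
class MultispectralSet:
    """Four co-registered single-channel rasters plus ground truth."""

    channels: dict[str, ChannelImage]
    gt_tm_mask: np.ndarray
    gt_malleus_mask: np.ndarray
    gt_vessel_mask: np.ndarray
    seed: int
    spec: PhantomSpec

    def save(self, out_dir) -> None:
        """Write channels and masks as 8-bit PNGs plus a JSON sidecar
        recording the spec, seed and file manifest."""
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        manifest: dict[str, str] = {}
        for ch, img in self.channels.items():
            name = f"channel_{ch}.png"
            write_image(img.pixels, out_dir / name)
            manifest[ch] = name
        for name, mask in (("gt_tm_mask", self.gt_tm_mask),
                           ("gt_malleus_mask", self.gt_malleus_mask),
                           ("gt_vessel_mask", self.gt_vessel_mask)):
            write_mask(mask, out_dir / f"{name}.png")
            manifest[name] = f"{name}.png"
        sidecar = {"seed": self.seed, "spec": self.spec.to_dict(), "manifest": manifest}
        (out_dir / "phantom.json").write_text(json.dumps(sidecar, indent=2))

    @classmethod
    def load(cls, in_dir) -> "MultispectralSet":
        in_dir = Path(in_dir)
        sidecar = json.loads((in_dir / "phantom.json").read_text())
        spec = PhantomSpec.from_dict(sidecar["spec"])
        channels = {
            ch: ChannelImage(read_image(in_dir / sidecar["manifest"][ch]), ch)
            for ch in CHANNELS
        }
        masks = {
            name: read_image(in_dir / sidecar["manifest"][name]) > 0.5
            for name in ("gt_tm_mask", "gt_malleus_mask", "gt_vessel_mask")
        }
        return cls(channels=channels, seed=int(sidecar["seed"]), spec=spec, **masks)


def default_phantom_spec(width: int = 976, height: int = 494) -> PhantomSpec:
    """The packaged default spec, with geometry scaled from the reference
    976×494 raster when another size is requested."""
    with resources.files("otomsi.data").joinpath("default_phantom.yaml").open() as fh:
        d = yaml.safe_load(fh)
    spec = PhantomSpec.from_dict(d)
    if (width, height) == (spec.width, spec.height):
        spec.validate()
        return spec
    sx, sy = width / spec.width, height / spec.height
    sm = 0.5 * (sx + sy)
    e = spec.tm_ellipse
    spec = replace(
        spec,
        width=width,
        height=height,
        tm_ellipse=Ellipse(e.cx * sx, e.cy * sy, e.a * sx, e.b * sy, e.theta),
        malleus=replace(spec.malleus, width=max(2.0, spec.malleus.width * sm)),
        vessel_width=max(1.0, spec.vessel_width * sm),
    )
    spec.validate()
    return spec


# ---------------------------------------------------------------------------
# rendering


def _disk(radius: float) -> np.ndarray:
    r = max(1, int(round(radius)))
    yy, xx = np.mgrid[-r:r + 1, -r:r + 1]
    return xx * xx + yy * yy <= r * r


def _segment_strip_mask(shape, p0, p1, width) -> np.ndarray:
    """Pixels within width/2 of the segment p0->p1 ((x, y) endpoints)."""
    rows, cols = shape
    yy, xx = np.mgrid[0:rows, 0:cols]
    vx, vy = p1[0] - p0[0], p1[1] - p0[1]
    L2 = vx * vx + vy * vy
    t = np.clip(((xx - p0[0]) * vx + (yy - p0[1]) * vy) / max(L2, 1e-12), 0.0, 1.0)
    dx = xx - (p0[0] + t * vx)
    dy = yy - (p0[1] + t * vy)
    return dx * dx + dy * dy <= (width / 2.0) ** 2


def _malleus_mask(spec: PhantomSpec, tm_mask: np.ndarray) -> np.ndarray:
    e = spec.tm_ellipse
    rim = e.boundary_point_toward(spec.malleus.angle)
    strip = _segment_strip_mask((spec.height, spec.width), (e.cx, e.cy), rim,
                                spec.malleus.width)
    return strip & tm_mask


def _cone_mask(spec: PhantomSpec) -> np.ndarray:
    e, cone = spec.tm_ellipse, spec.cone_of_light
    yy, xx = np.mgrid[0:spec.height, 0:spec.width]
    ang = np.arctan2(yy - e.cy, xx - e.cx)
    dang = np.angle(np.exp(1j * (ang - cone.angle)))
    inside = e.quad_form(xx, yy) <= cone.radial_fraction**2
    return inside & (np.abs(dang) <= cone.extent / 2.0)


def _vessel_mask(spec: PhantomSpec, rng: np.random.Generator) -> np.ndarray:
    """Random smooth curves radiating inward across the canal wall and over
    the TM; geometry is drawn once per phantom and shared by all channels."""
    from scipy.interpolate import CubicSpline

    e = spec.tm_ellipse
    rows, cols = spec.height, spec.width
    mask = np.zeros((rows, cols), dtype=bool)
    border_r = 0.5 * math.hypot(cols, rows)
    for _ in range(spec.n_vessels):
        phi = rng.uniform(0.0, 2.0 * math.pi)
        start = (e.cx + border_r * math.cos(phi), e.cy + border_r * math.sin(phi))
        # end somewhere on the TM interior so some vessels cross the rim
        rho = rng.uniform(0.2, 0.75)
        phi2 = phi + rng.normal(0.0, 0.35)
        end = (e.cx + rho * e.a * math.cos(phi2), e.cy + rho * e.b * math.sin(phi2))
        t = np.linspace(0.0, 1.0, 4)
        px = start[0] + t * (end[0] - start[0])
        py = start[1] + t * (end[1] - start[1])
        length = math.hypot(end[0] - start[0], end[1] - start[1])
        wig = 0.08 * length
        nx, ny = -(end[1] - start[1]) / max(length, 1e-9), (end[0] - start[0]) / max(length, 1e-9)
        for i in (1, 2):
            off = rng.normal(0.0, wig)
            px[i] += off * nx
            py[i] += off * ny
        ts = np.linspace(0.0, 1.0, 400)
        sx, sy = CubicSpline(t, px)(ts), CubicSpline(t, py)(ts)
        ix = np.round(sx).astype(int)
        iy = np.round(sy).astype(int)
        ok = (ix >= 0) & (ix < cols) & (iy >= 0) & (iy < rows)
        mask[iy[ok], ix[ok]] = True
    if spec.vessel_width > 1:
        mask = ndimage.binary_dilation(mask, structure=_disk(spec.vessel_width / 2.0))
    return mask


def generate_phantom(spec: PhantomSpec, seed: int) -> MultispectralSet:
    """Render one multispectral set; deterministic given ``(spec, seed)``.

    Per channel: canal wall at ``outside_mean``, TM ellipse at ``tm_mean``,
    malleus strip at ``malleus_mean``, vessels darkened by
    ``vessel_contrast``, cone-of-light wedge brightened by ``cone_gain``,
    plus i.i.d. Gaussian noise of ``noise_sd``, clipped to [0, 1]. The random
    stream is consumed identically regardless of photometric values, so
    ground truth and vessel geometry are invariant to photometry.
    """
    spec.validate()
    rng = np.random.default_rng(seed)
    shape = (spec.height, spec.width)

    tm_mask = spec.tm_ellipse.rasterize(shape)
    malleus_mask = _malleus_mask(spec, tm_mask)
    cone_mask = _cone_mask(spec)
    vessel_mask = _vessel_mask(spec, rng)

    channels: dict[str, ChannelImage] = {}
    for ch in CHANNELS:
        p = spec.photometry[ch]
        img = np.full(shape, p.outside_mean, dtype=float)
        img[tm_mask] = p.tm_mean
        img[malleus_mask] = p.malleus_mean
        img[vessel_mask] -= p.vessel_contrast
        img[cone_mask] += p.cone_gain
        img += rng.normal(0.0, 1.0, shape) * p.noise_sd
        channels[ch] = ChannelImage(np.clip(img, 0.0, 1.0), ch)

    return MultispectralSet(
        channels=channels,
        gt_tm_mask=tm_mask | malleus_mask,
        gt_malleus_mask=malleus_mask,
        gt_vessel_mask=vessel_mask,
        seed=int(seed),
        spec=spec,
    )


def derive_cohort_seeds(master_seed: int, n: int) -> list[tuple[int, int]]:
    """Per-member (jitter_seed, render_seed) pairs, reproducible from the
    master seed and kept below 2³¹."""
    state = np.random.SeedSequence(master_seed).generate_state(2 * n, dtype=np.uint32)
    vals = (state % np.uint32(2**31)).astype(int)
    return [(vals[2 * i], vals[2 * i + 1]) for i in range(n)]


def jitter_spec(spec: PhantomSpec, seed: int, rel: float = 0.05) -> PhantomSpec:
    """Perturb the TM ellipse within ±``rel`` of each parameter (center
    offsets are relative to the semi-axes), emulating anatomical variation
    across ears."""
    rng = np.random.default_rng(seed)
    e = spec.tm_ellipse
    jittered = Ellipse(
        cx=e.cx + rng.uniform(-rel, rel) * e.a,
        cy=e.cy + rng.uniform(-rel, rel) * e.b,
        a=e.a * (1.0 + rng.uniform(-rel, rel)),
        b=e.b * (1.0 + rng.uniform(-rel, rel)),
        theta=e.theta + rng.uniform(-rel, rel),
    )
    out = replace(spec, tm_ellipse=jittered)
    out.validate()
    return out


def generate_cohort(spec: PhantomSpec, n: int, master_seed: int) -> list[MultispectralSet]:
    """Generate ``n`` phantoms with jittered geometry and distinct derived
    seeds, fully reproducible from ``master_seed``."""
    if n < 1:
        raise ValueError(f"cohort size must be >= 1, got {n}")
    spec.validate()
    cohort = []
    for jitter_seed, render_seed in derive_cohort_seeds(master_seed, n):
        member_spec = jitter_spec(spec, jitter_seed)
        cohort.append(generate_phantom(member_spec, render_seed))
    return cohort
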