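"""Synthetic prostate MRI phantom generator.

Produces 2D axial cases (T2-like reference, multi-b DWI, zone masks and
ground-truth ADC / S0 maps) with the anatomical layout the distortion
simulator assumes: an elliptical prostate whose posterior crescent is the
peripheral zone (PZ), abutting a circular rectal gas region across a small
fat gap. DWI channels follow the mono-exponential model
``S(b) = S0 * exp(-b * ADC)`` with zone-dependent ADC, plus optional Rician
noise (magnitude of a complex Gaussian perturbation — the standard
magnitude-MRI noise model).

All numeric zone defaults live in ``data/phantom_defaults.yaml``; they are
qualitative-realism choices, not measurements.
"""

from __future__ import annotations

import dataclasses
import importlib.resources
import json
import logging
import pathlib
from dataclasses import dataclass, field

import nibabel as nib
import numpy as np
import yaml
from scipy import ndimage

from .image import DwiStack, SliceImage, nifti_to_slice, slice_to_nifti

__all__ = [
    "PhantomSpec",
    "PhantomCase",
    "make_phantom",
    "rectal_adjacent_region",
    "save_case",
    "load_case",
]

logger = logging.getLogger(__name__)

ZONES = ("pz", "tz", "background", "rectum")


def _load_defaults() -> dict:
    ref = importlib.resources.files("dwidistort") / "data" / "phantom_defaults.yaml"
    with ref.open("r") as fh:
        return yaml.safe_load(fh)


@dataclass
class PhantomSpec:
    """Full description of one synthetic case; see ``phantom_defaults.yaml``."""

    image_size_px: tuple[int, int]
    pixel_spacing_mm: tuple[float, float]
    prostate_semi_axes_mm: tuple[float, float]
    pz_thickness_mm: float
    rectum_radius_mm: float
    rectum_gap_mm: float
    zone_adc_mm2_per_s: dict[str, float]
    zone_s0: dict[str, float]
    zone_t2_intensity: dict[str, float]
    noise_sigma: float
    b_values_s_per_mm2: tuple[float, ...]
    seed: int = 0

    @classmethod
    def default(cls, **overrides) -> "PhantomSpec":
        cfg = _load_defaults()
        cfg.update(overrides)
        return cls(
            image_size_px=tuple(cfg["image_size_px"]),
            pixel_spacing_mm=tuple(cfg["pixel_spacing_mm"]),
            prostate_semi_axes_mm=tuple(cfg["prostate_semi_axes_mm"]),
            pz_thickness_mm=float(cfg["pz_thickness_mm"]),
            rectum_radius_mm=float(cfg["rectum_radius_mm"]),
            rectum_gap_mm=float(cfg["rectum_gap_mm"]),
            zone_adc_mm2_per_s={k: float(v) for k, v in cfg["zone_adc_mm2_per_s"].items()},
            zone_s0={k: float(v) for k, v in cfg["zone_s0"].items()},
            zone_t2_intensity={k: float(v) for k, v in cfg["zone_t2_intensity"].items()},
            noise_sigma=float(cfg["noise_sigma"]),
            b_values_s_per_mm2=tuple(float(b) for b in cfg["b_values_s_per_mm2"]),
            seed=int(cfg["seed"]),
        )

    def validate(self) -> None:
        if min(self.image_size_px) < 8:
            raise ValueError("image_size_px too small")
        if min(self.pixel_spacing_mm) <= 0:
            raise ValueError("pixel spacing must be positive")
        bvals = np.asarray(self.b_values_s_per_mm2, float)
        if bvals.size < 1 or bvals[0] < 0:
            raise ValueError("b-values must be nonnegative")
        if np.any(np.diff(bvals) < 0):
            raise ValueError("b-values must be sorted ascending")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be nonnegative")
        if self.pz_thickness_mm <= 0 or self.rectum_radius_mm <= 0:
            raise ValueError("pz_thickness_mm and rectum_radius_mm must be positive")
        for zone in ZONES:
            for mapping, name in (
                (self.zone_adc_mm2_per_s, "zone_adc_mm2_per_s"),
                (self.zone_s0, "zone_s0"),
                (self.zone_t2_intensity, "zone_t2_intensity"),
            ):
                if zone not in mapping:
                    raise ValueError(f"{name} missing zone {zone!r}")
            if self.zone_s0[zone] > 0 and self.zone_adc_mm2_per_s[zone] <= 0:
                raise ValueError(f"zone {zone!r} has nonzero signal but ADC <= 0")
        # Geometric fit: AP extent of prostate + gap + rectum must fit the FOV.
        fov_r = self.image_size_px[0] * self.pixel_spacing_mm[0]
        fov_c = self.image_size_px[1] * self.pixel_spacing_mm[1]
        ap_extent = (
            2 * self.prostate_semi_axes_mm[0]
            + self.rectum_gap_mm
            + 2 * self.rectum_radius_mm
        )
        if ap_extent > fov_r:
            raise ValueError(
                f"anteroposterior extent {ap_extent:.1f} mm (prostate + gap + "
                f"rectum) exceeds the {fov_r:.1f} mm field of view"
            )
        if 2 * self.prostate_semi_axes_mm[1] > fov_c:
            raise ValueError(
                f"prostate left-right extent {2 * self.prostate_semi_axes_mm[1]:.1f} mm "
                f"exceeds the {fov_c:.1f} mm field of view"
            )

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["image_size_px"] = list(self.image_size_px)
        d["pixel_spacing_mm"] = list(self.pixel_spacing_mm)
        d["prostate_semi_axes_mm"] = list(self.prostate_semi_axes_mm)
        d["b_values_s_per_mm2"] = list(self.b_values_s_per_mm2)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PhantomSpec":
        return cls.default(**d)


@dataclass
class PhantomCase:
    """One generated case: images, masks and ground truth on a shared grid."""

    t2: SliceImage
    dwi: DwiStack
    prostate_mask: SliceImage
    pz_mask: SliceImage
    rectum_region_mask: SliceImage
    adc_truth: SliceImage
    s0_truth: SliceImage
    spec: PhantomSpec | None = None

    @property
    def spacing_mm(self) -> tuple[float, float]:
        return self.t2.spacing_mm

    def masks(self) -> dict[str, SliceImage]:
        return {
            "prostate": self.prostate_mask,
            "pz": self.pz_mask,
            "rectum_region": self.rectum_region_mask,
        }


def _pixel_centers_mm(n: int, spacing: float) -> np.ndarray:
    return (np.arange(n) + 0.5) * spacing


def make_phantom(spec: PhantomSpec) -> PhantomCase:
    """Rasterize the phantom geometry and synthesize T2 / DWI signals.

    Deterministic given ``spec.seed``. The prostate ellipse is centred
    left-right and placed so that prostate, gap and rectum are vertically
    centred in the field of view; the PZ is the posterior crescent of depth
    ``pz_thickness_mm``.
    """
    spec.validate()
    nr, nc = spec.image_size_px
    sp_r, sp_c = spec.pixel_spacing_mm
    rows_mm = _pixel_centers_mm(nr, sp_r)[:, None]
    cols_mm = _pixel_centers_mm(nc, sp_c)[None, :]

    a_ap, a_lr = spec.prostate_semi_axes_mm
    fov_r = nr * sp_r
    ap_extent = 2 * a_ap + spec.rectum_gap_mm + 2 * spec.rectum_radius_mm
    margin = (fov_r - ap_extent) / 2.0
    prost_r = margin + a_ap            # prostate centre, mm (row axis)
    prost_c = nc * sp_c / 2.0
    rect_r = prost_r + a_ap + spec.rectum_gap_mm + spec.rectum_radius_mm
    rect_c = prost_c

    prostate = ((rows_mm - prost_r) / a_ap) ** 2 + (
        (cols_mm - prost_c) / a_lr
    ) ** 2 <= 1.0
    inner_ap = max(a_ap - spec.pz_thickness_mm, 1e-6)
    inner_lr = max(a_lr - spec.pz_thickness_mm, 1e-6)
    inner = ((rows_mm - prost_r) / inner_ap) ** 2 + (
        (cols_mm - prost_c) / inner_lr
    ) ** 2 <= 1.0
    pz = prostate & ~inner & (rows_mm > prost_r)
    tz = prostate & ~pz
    rectum = (rows_mm - rect_r) ** 2 + (cols_mm - rect_c) ** 2 <= spec.rectum_radius_mm**2
    rectum &= ~prostate
    background = ~(prostate | rectum)

    zone_masks = {"pz": pz, "tz": tz, "rectum": rectum, "background": background}
    adc = np.zeros((nr, nc))
    s0 = np.zeros((nr, nc))
    t2 = np.zeros((nr, nc))
    for zone, zmask in zone_masks.items():
        adc[zmask] = spec.zone_adc_mm2_per_s[zone]
        s0[zmask] = spec.zone_s0[zone]
        t2[zmask] = spec.zone_t2_intensity[zone]

    bvals = np.asarray(spec.b_values_s_per_mm2, float)
    dwi = s0[None] * np.exp(-bvals[:, None, None] * adc[None])
    if spec.noise_sigma > 0:
        rng = np.random.default_rng(spec.seed)
        n_re = rng.normal(0.0, spec.noise_sigma, dwi.shape)
        n_im = rng.normal(0.0, spec.noise_sigma, dwi.shape)
        dwi = np.sqrt((dwi + n_re) ** 2 + n_im**2)

    spacing = (sp_r, sp_c)
    return PhantomCase(
        t2=SliceImage(t2, spacing),
        dwi=DwiStack(dwi, bvals, spacing),
        prostate_mask=SliceImage(prostate, spacing),
        pz_mask=SliceImage(pz, spacing),
        rectum_region_mask=SliceImage(rectum, spacing),
        adc_truth=SliceImage(adc, spacing),
        s0_truth=SliceImage(s0, spacing),
        spec=spec,
    )


def rectal_adjacent_region(
    case: PhantomCase, margin_mm: float, dilate_mm: float = 2.0
) -> SliceImage:
    """Target region for elastic deformation: posterior prostate tissue near
    the rectum.

    Pixels within ``margin_mm`` of the rectal gas region are dilated by
    ``dilate_mm`` (to include immediately adjacent tissue) and intersected
    with the posterior half of the prostate bounding box, so every returned
    pixel lies at or posterior to the prostate centroid row.
    """
    if margin_mm < 0:
        raise ValueError("margin_mm must be nonnegative")
    sp = case.spacing_mm
    rectum = case.rectum_region_mask.data.astype(bool)
    prostate = case.prostate_mask.data.astype(bool)
    dist = ndimage.distance_transform_edt(~rectum, sampling=sp)
    near = dist <= margin_mm
    if dilate_mm > 0:
        it = max(int(round(dilate_mm / min(sp))), 1)
        near = ndimage.binary_dilation(near, iterations=it)
    rows, cols = np.nonzero(prostate)
    r_lo, r_hi = rows.min(), rows.max()
    c_lo, c_hi = cols.min(), cols.max()
    r_mid = (r_lo + r_hi) / 2.0
    posterior_bbox = np.zeros_like(near)
    posterior_bbox[int(np.ceil(r_mid)) : r_hi + 1, c_lo : c_hi + 1] = True
    region = near & posterior_bbox
    if not region.any():
        logger.warning(
            "rectal_adjacent_region is empty (margin %.1f mm): rectum too far "
            "from the prostate",
            margin_mm,
        )
    return SliceImage(region, sp)


# ---------------------------------------------------------------------------
# Case I/O: one NIfTI per component plus a JSON sidecar (spec + seed).

_COMPONENTS = (
    "t2",
    "prostate_mask",
    "pz_mask",
    "rectum_region_mask",
    "adc_truth",
    "s0_truth",
)


def save_case(case: PhantomCase, out_dir) -> pathlib.Path:
    out = pathlib.Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for name in _COMPONENTS:
        img: SliceImage = getattr(case, name)
        dtype = np.uint8 if name.endswith("mask") else np.float32
        nib.save(slice_to_nifti(img, dtype=dtype), out / f"{name}.nii.gz")
    affine = np.diag([case.spacing_mm[0], case.spacing_mm[1], 1.0, 1.0])
    dwi_arr = np.moveaxis(case.dwi.data.astype(np.float32), 0, -1)
    nib.save(nib.Nifti1Image(dwi_arr, affine), out / "dwi.nii.gz")
    sidecar = {
        "b_values_s_per_mm2": list(map(float, case.dwi.b_values)),
        "pixel_spacing_mm": list(case.spacing_mm),
        "spec": case.spec.to_dict() if case.spec is not None else None,
    }
    (out / "case.json").write_text(json.dumps(sidecar, indent=2))
    return out


def load_case(case_dir) -> PhantomCase:
    d = pathlib.Path(case_dir)
    sidecar = json.loads((d / "case.json").read_text())
    spacing = tuple(sidecar["pixel_spacing_mm"])
    comps = {}
    for name in _COMPONENTS:
        img = nifti_to_slice(nib.load(d / f"{name}.nii.gz"))
        if name.endswith("mask"):
            img = SliceImage(img.data.astype(bool), spacing)
        comps[name] = img
    dwi_arr = np.moveaxis(np.asanyarray(nib.load(d / "dwi.nii.gz").dataobj), -1, 0)
    dwi = DwiStack(dwi_arr, np.asarray(sidecar["b_values_s_per_mm2"]), spacing)
    spec = (
        PhantomSpec.from_dict(sidecar["spec"]) if sidecar.get("spec") is not None else None
    )
    return PhantomCase(dwi=dwi, spec=spec, **comps)
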