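"""Seeded generator of dermoscopy-like image/mask pairs.

Lesions are star-convex blobs: the boundary radius is a truncated radial
Fourier series  r(theta) = r0 * (1 + sum_k a_k cos(k*theta + phi_k))  with
sum_k |a_k| bounded below 1, so every mask is a single connected region
with a controllably irregular boundary.  Images place a color-jittered
lesion on a skin-toned background, apply a linear illumination gradient,
Gaussian pixel noise, then the artifacts real dermoscopy suffers from:
dark curved hair strokes and bright bubble highlights.  Artifacts perturb
the image only — masks are untouched, which is what makes these pairs a
fair robustness fixture.

Everything is reproducible: a master seed splits into per-sample seeds via
a counter, and the manifest records enough to regenerate byte-identical
files.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image

from .errors import DataError


@dataclass
class SyntheticSpec:
    """Parameters of the generator; defaults give 64x64 desk-scale samples."""

    image_size: int = 64
    lesion_radius_range: tuple[float, float] = (0.15, 0.30)   # fraction of side
    boundary_harmonics: int = 4
    boundary_amplitude: float = 0.25          # total relative perturbation sum|a_k|
    lesion_color: tuple[float, float, float] = (0.42, 0.28, 0.22)
    skin_color: tuple[float, float, float] = (0.80, 0.60, 0.50)
    color_jitter: float = 0.04
    illumination_gradient: float = 0.15       # max relative brightness slope
    hair_count_range: tuple[int, int] = (0, 4)
    hair_thickness: float = 1.2               # pixels
    hair_darkness: float = 0.35               # stroke brightness multiplier
    bubble_count_range: tuple[int, int] = (0, 2)
    bubble_brightness: float = 0.5            # blend weight toward white
    noise_sigma: float = 0.02
    seed: int = 0

    def __post_init__(self):
        lo, hi = self.lesion_radius_range
        if not (0 < lo <= hi < 0.5):
            raise DataError(f"lesion radius range must lie in (0, 0.5), got {lo, hi}")
        if not (0 <= self.boundary_amplitude < 1):
            raise DataError(
                f"boundary amplitude {self.boundary_amplitude} would allow a "
                "non-positive radius; must be in [0, 1)")

    def sample_seed(self, master_seed: int, index: int) -> int:
        """Counter-based per-sample seed derivation (independent reproducibility)."""
        ss = np.random.SeedSequence([int(master_seed), int(index)])
        return int(ss.generate_state(1)[0] % (2 ** 31))


def _radius_profile(spec: SyntheticSpec, rng: np.random.Generator):
    """Draw r0 (pixels) and the Fourier coefficients of the boundary."""
    lo, hi = spec.lesion_radius_range
    r0 = rng.uniform(lo, hi) * spec.image_size
    k = np.arange(1, spec.boundary_harmonics + 1)
    raw = rng.standard_normal(spec.boundary_harmonics) / k   # damp high harmonics
    norm = np.abs(raw).sum()
    amps = raw / norm * spec.boundary_amplitude * rng.uniform(0.5, 1.0) \
        if norm > 0 else raw
    phases = rng.uniform(0, 2 * np.pi, spec.boundary_harmonics)
    return r0, amps, phases


def radius_at(theta: np.ndarray, r0: float, amps: np.ndarray,
              phases: np.ndarray) -> np.ndarray:
    k = np.arange(1, len(amps) + 1)
    pert = (amps[:, None] * np.cos(np.outer(k, theta) + phases[:, None])).sum(axis=0)
    return r0 * (1.0 + pert)


def generate_mask(spec: SyntheticSpec, sample_seed: int,
                  return_params: bool = False):
    """Rasterize one star-convex lesion mask by a point-in-region test."""
    rng = np.random.default_rng(sample_seed)
    s = spec.image_size
    r0, amps, phases = _radius_profile(spec, rng)
    if np.abs(amps).sum() >= 1.0:
        raise DataError("boundary amplitude leaves a non-positive radius")
    margin = r0 * (1 + np.abs(amps).sum())
    cx = rng.uniform(margin + 1, s - margin - 1) if s > 2 * margin + 2 else s / 2
    cy = rng.uniform(margin + 1, s - margin - 1) if s > 2 * margin + 2 else s / 2
    yy, xx = np.mgrid[0:s, 0:s]
    dx, dy = xx + 0.5 - cx, yy + 0.5 - cy
    theta = np.arctan2(dy, dx)
    rr = np.hypot(dx, dy)
    mask = (rr <= radius_at(theta.ravel(), r0, amps, phases).reshape(s, s)
            ).astype(np.uint8)
    if return_params:
        return mask, {"r0": r0, "amps": amps, "phases": phases, "center": (cx, cy)}
    return mask


def render_image(mask: np.ndarray, spec: SyntheticSpec, sample_seed: int) -> np.ndarray:
    """Skin background + lesion fill, linear illumination field, Gaussian noise."""
    rng = np.random.default_rng(np.random.SeedSequence([int(sample_seed), 1]))
    s = spec.image_size
    skin = np.asarray(spec.skin_color) + rng.uniform(-1, 1, 3) * spec.color_jitter
    lesion = np.asarray(spec.lesion_color) + rng.uniform(-1, 1, 3) * spec.color_jitter
    img = np.where(mask.astype(bool)[None], lesion[:, None, None], skin[:, None, None])
    if spec.illumination_gradient > 0:
        phi = rng.uniform(0, 2 * np.pi)
        yy, xx = np.mgrid[0:s, 0:s]
        proj = ((xx * np.cos(phi) + yy * np.sin(phi)) / s)
        proj = proj - proj.mean()
        img = img * (1.0 + spec.illumination_gradient * proj)[None]
    if spec.noise_sigma > 0:
        img = img + rng.normal(0, spec.noise_sigma, img.shape)
    return np.clip(img, 0.0, 1.0)


def _stroke_coverage(s: int, p0, p1, p2, thickness: float) -> np.ndarray:
    """Anti-aliased coverage of a quadratic Bezier stroke, values in [0,1]."""
    t = np.linspace(0, 1, 4 * s)[:, None]
    pts = (1 - t) ** 2 * p0 + 2 * (1 - t) * t * p1 + t ** 2 * p2   # (T,2)
    yy, xx = np.mgrid[0:s, 0:s]
    grid = np.stack([xx.ravel(), yy.ravel()], axis=1).astype(float)
    d2 = ((grid[:, None, :] - pts[None]) ** 2).sum(axis=2)
    dist = np.sqrt(d2.min(axis=1)).reshape(s, s)
    return np.clip(1.0 - (dist - thickness / 2.0), 0.0, 1.0)


def add_artifacts(image: np.ndarray, spec: SyntheticSpec, sample_seed: int,
                  return_provenance: bool = False):
    """Overlay dark hair strokes and bright bubbles; the mask is untouched."""
    rng = np.random.default_rng(np.random.SeedSequence([int(sample_seed), 2]))
    img = np.array(image, dtype=np.float64, copy=True)
    s = spec.image_size
    n_hair = int(rng.integers(spec.hair_count_range[0], spec.hair_count_range[1] + 1))
    n_bub = int(rng.integers(spec.bubble_count_range[0], spec.bubble_count_range[1] + 1))
    for _ in range(n_hair):
        edge_pts = rng.uniform(0, s, (2, 2))
        ctrl = rng.uniform(0, s, 2)
        cov = _stroke_coverage(s, edge_pts[0], ctrl, edge_pts[1], spec.hair_thickness)
        img = img * (1.0 - cov[None] * (1.0 - spec.hair_darkness))
    yy, xx = np.mgrid[0:s, 0:s]
    for _ in range(n_bub):
        c = rng.uniform(0.15 * s, 0.85 * s, 2)
        radius = rng.uniform(0.03, 0.08) * s
        dist = np.hypot(xx - c[0], yy - c[1])
        cov = np.clip(1.0 - (dist - radius), 0.0, 1.0)
        w = cov[None] * spec.bubble_brightness
        img = img * (1.0 - w) + w
    img = np.clip(img, 0.0, 1.0)
    if return_provenance:
        return img, {"hairs": n_hair, "bubbles": n_bub}
    return img


def generate_sample(spec: SyntheticSpec, sample_seed: int):
    """One (image 3xSxS in [0,1], mask SxS binary, provenance) triple."""
    mask = generate_mask(spec, sample_seed)
    img = render_image(mask, spec, sample_seed)
    img, prov = add_artifacts(img, spec, sample_seed, return_provenance=True)
    prov["sample_seed"] = int(sample_seed)
    return img, mask, prov


def generate_dataset(spec: SyntheticSpec, n: int, seed: int,
                     out_dir: str | Path) -> dict:
    """Write n image/mask PNG pairs plus a JSON manifest; fully reproducible."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {"spec": asdict(spec), "master_seed": int(seed), "samples": []}
    for i in range(n):
        ss = spec.sample_seed(seed, i)
        img, mask, prov = generate_sample(spec, ss)
        stem = f"img_{i:04d}"
        arr = (np.round(img * 255)).astype(np.uint8).transpose(1, 2, 0)
        Image.fromarray(arr).save(out_dir / f"{stem}.png")
        Image.fromarray((mask * 255).astype(np.uint8)).save(
            out_dir / f"{stem}_segmentation.png")
        prov["stem"] = stem
        manifest["samples"].append(prov)
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest


def generate_arrays(spec: SyntheticSpec, n: int, seed: int):
    """In-memory dataset: (n,3,S,S) float images and (n,S,S) uint8 masks."""
    imgs, masks = [], []
    for i in range(n):
        ss = spec.sample_seed(seed, i)
        img, mask, _ = generate_sample(spec, ss)
        imgs.append(img.astype(np.float32))
        masks.append(mask)
    return np.stack(imgs), np.stack(masks)
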