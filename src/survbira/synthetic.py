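"""Synthetic histology-like cohorts with known risk -> survival structure.

Every stage of the cascade needs image data with a controllable ground
truth, and real lung-adenocarcinoma cohorts are controlled-access.  The
generator emulates the structural features the method depends on, not
histology itself: slides of varying area (so the tile count N varies),
multiple slides per patient, uncensored survival in days, and three
tissue types of which only primary tumor carries signal.

Each patient draws a latent risk r ~ U[0, 1] and a survival time

    t = clip(baseline_days - risk_effect_days * r + Normal(0, noise_sd), 1, inf)

rounded to whole days.  A primary-tumor slide renders "nuclei" (dark
ellipses on pink stroma on a white background) whose density and darkness
increase monotonically with r, so the image's texture statistics encode
the risk; lymph-node and normal/non-neoplastic slides are rendered with a
fixed, risk-independent texture.  An optional heavy-tail contamination
replaces a fraction of survival times with long uniform draws, mimicking
the outlier-laden distributions seen when late-stage patients are mixed in.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
from skimage.draw import ellipse

from survbira.manifest import TISSUE_TYPES

#: Nucleus coverage (fraction of tissue area) at risk 0 and 1 for primary
#: tumor; normal/lymph tissue uses the fixed midpoint regardless of risk.
_COVERAGE_LO, _COVERAGE_HI = 0.05, 0.40
#: Nucleus gray level (pre-tint) at risk 0 and 1; darker = higher risk.
_NUCLEUS_SHADE_LO, _NUCLEUS_SHADE_HI = 0.55, 0.22

_STROMA_RGB = np.array([0.92, 0.72, 0.80])
_NUCLEUS_TINT = np.array([0.75, 0.55, 1.0])  # blue-purple cast


@dataclass
class SyntheticCohortConfig:
    """Study conditions for one synthetic cohort."""

    n_patients: int = 40
    slides_per_patient: tuple[int, int] = (1, 3)
    image_size: int = 1024
    patch_size: int = 64
    baseline_days: float = 800.0
    risk_effect_days: float = 600.0
    noise_sd_days: float = 30.0
    fraction_primary: float = 1.0
    stage_probs: tuple[float, float, float, float] = (0.5, 0.3, 0.15, 0.05)
    outlier_frac: float = 0.0
    outlier_max_days: float = 4000.0
    seed: int = 0
    cohort_tag: str = "synthetic"

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        lo, hi = self.slides_per_patient
        if not 1 <= lo <= hi:
            raise ValueError("slides_per_patient must satisfy 1 <= min <= max")
        if abs(sum(self.stage_probs) - 1.0) > 1e-9:
            raise ValueError("stage_probs must sum to 1")
        if not 0.0 <= self.fraction_primary <= 1.0:
            raise ValueError("fraction_primary must be in [0, 1]")
        if self.baseline_days - self.risk_effect_days - 3 * self.noise_sd_days <= 0:
            raise ValueError(
                "baseline_days - risk_effect_days - 3*noise_sd_days must stay "
                "positive so survival times remain positive"
            )


def _tumor_texture(risk: float, tissue_type: str) -> tuple[float, float]:
    """(nucleus coverage, nucleus shade) for a slide."""
    if tissue_type == "primary_tumor":
        cov = _COVERAGE_LO + (_COVERAGE_HI - _COVERAGE_LO) * risk
        shade = _NUCLEUS_SHADE_LO + (_NUCLEUS_SHADE_HI - _NUCLEUS_SHADE_LO) * risk
    else:
        cov = 0.5 * (_COVERAGE_LO + _COVERAGE_HI)
        shade = 0.5 * (_NUCLEUS_SHADE_LO + _NUCLEUS_SHADE_HI)
    return cov, shade


def generate_slide_image(
    risk: float,
    tissue_type: str,
    size: int,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Render one synthetic slide.

    Returns ``(image, tissue_mask)`` where ``image`` is a (size, size, 3)
    uint8 RGB array (white background, pink stroma, dark elliptic nuclei)
    and ``tissue_mask`` is the exact boolean tissue region used during
    rendering — the ground truth for validating tissue detection.
    """
    if tissue_type not in TISSUE_TYPES:
        raise ValueError(f"unknown tissue_type {tissue_type!r}")
    img = np.ones((size, size, 3), dtype=np.float64)

    # Tissue region: union of a few random ellipses around the center.
    mask = np.zeros((size, size), dtype=bool)
    n_blobs = rng.integers(2, 5)
    for _ in range(n_blobs):
        cy, cx = rng.uniform(0.3 * size, 0.7 * size, size=2)
        ry, rx = rng.uniform(0.18 * size, 0.35 * size, size=2)
        rr, cc = ellipse(cy, cx, ry, rx, shape=(size, size))
        mask[rr, cc] = True

    # Pink stroma with mild multiplicative noise.
    stroma = _STROMA_RGB[None, None, :] + rng.normal(0, 0.02, size=(size, size, 3))
    img[mask] = stroma[mask]

    # Nuclei: dark ellipses at density/darkness set by risk and tissue type.
    coverage, shade = _tumor_texture(risk, tissue_type)
    area = mask.sum()
    mean_r = 4.0
    n_nuclei = int(coverage * area / (np.pi * mean_r**2))
    ys, xs = np.nonzero(mask)
    if len(ys) and n_nuclei:
        centers = rng.integers(0, len(ys), size=n_nuclei)
        for c in centers:
            ry, rx = rng.uniform(2.5, 5.5, size=2)
            angle = rng.uniform(0, np.pi)
            rr, cc = ellipse(
                ys[c], xs[c], ry, rx, shape=(size, size), rotation=angle
            )
            keep = mask[rr, cc]
            rr, cc = rr[keep], cc[keep]
            level = np.clip(shade + rng.normal(0, 0.04), 0.05, 0.9)
            img[rr, cc] = level * _NUCLEUS_TINT[None, :]

    img = np.clip(img, 0.0, 1.0)
    return (img * 255).round().astype(np.uint8), mask


def _slide_tissue_types(
    n_slides: int, fraction_primary: float, rng: np.random.Generator
) -> list[str]:
    # Every patient keeps at least one primary-tumor slide so that a
    # primary-only analysis retains the full patient set.
    types = ["primary_tumor"]
    for _ in range(n_slides - 1):
        if rng.random() < fraction_primary:
            types.append("primary_tumor")
        else:
            types.append(rng.choice(["lymph_node", "normal_nonneoplastic"]))
    return types


def generate_cohort(
    config: SyntheticCohortConfig,
    out_dir: str | Path,
    write_images: bool = True,
) -> dict[str, Path | pd.DataFrame]:
    """Generate a full cohort: PNG slides, manifest.csv, and truth.csv.

    Fully deterministic given ``config.seed``.  The truth table records
    each patient's latent risk so downstream recovery can be quantified.
    Returns the manifest/truth DataFrames and the paths they were written
    to.  ``write_images=False`` skips rendering (the manifest and truth
    tables are unchanged) for analyses that only need the labels.
    """
    out_dir = Path(out_dir)
    (out_dir / "slides").mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)

    manifest_rows, truth_rows = [], []
    lo, hi = config.slides_per_patient
    for i in range(config.n_patients):
        pid = f"P{i:04d}"
        risk = rng.uniform(0.0, 1.0)
        t = config.baseline_days - config.risk_effect_days * risk + rng.normal(
            0.0, config.noise_sd_days
        )
        if config.outlier_frac > 0 and rng.random() < config.outlier_frac:
            t = rng.uniform(config.baseline_days, config.outlier_max_days)
        survival = int(max(1, round(t)))
        stage = int(rng.choice([1, 2, 3, 4], p=config.stage_probs))
        n_slides = int(rng.integers(lo, hi + 1))
        types = _slide_tissue_types(n_slides, config.fraction_primary, rng)
        for j, ttype in enumerate(types):
            sid = f"{pid}_S{j}"
            size = int(round(config.image_size * rng.uniform(0.75, 1.25)))
            # Per-slide stream keyed off the master stream plus a stable
            # slide hash, so slide images are independent draws.
            path = out_dir / "slides" / f"{sid}.png"
            if write_images:
                slide_rng = np.random.default_rng(
                    [config.seed, zlib.crc32(sid.encode()) % (2**31)]
                )
                img, _ = generate_slide_image(risk, ttype, size, slide_rng)
                iio.imwrite(path, img)
            manifest_rows.append(
                {
                    "patient_id": pid,
                    "slide_id": sid,
                    "image_path": str(path),
                    "tissue_type": ttype,
                    "stage": stage,
                    "survival_days": survival,
                    "cohort": config.cohort_tag,
                }
            )
        truth_rows.append(
            {"patient_id": pid, "risk": risk, "survival_days": survival}
        )

    manifest = pd.DataFrame(manifest_rows)
    truth = pd.DataFrame(truth_rows)
    manifest_path = out_dir / "manifest.csv"
    truth_path = out_dir / "truth.csv"
    manifest.to_csv(manifest_path, index=False)
    truth.to_csv(truth_path, index=False)
    return {
        "manifest": manifest,
        "truth": truth,
        "manifest_path": manifest_path,
        "truth_path": truth_path,
    }
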