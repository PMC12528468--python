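"""The full cascade as a fit/predict object.

``SurBiRaPipeline.fit`` tiles the training slides, trains the Survpatch
regressor on the label-broadcast patches, chooses the global bin count
from the training slides' patch predictions, and fits the slide-level
random forest.  ``predict_patients`` runs a held-out cohort through
patches -> binned features -> forest -> per-patient average.  The two
ablated prediction paths (direct patch-mean, and binned-feature mean
without the forest) reuse the same trained patch model.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np

from survbira.aggregate import (
    PredictionRecord,
    SlideRegressor,
    aggregate_patient,
    binned_features,
    choose_global_bin_count,
    fit_slide_regressor,
    predict_slide_survival,
)
from survbira.manifest import PatientRecord, SlideRecord, filter_by_tissue_type
from survbira.survpatch import (
    PatchRegressor,
    SurvpatchConfig,
    build_survpatch,
    train_survpatch,
)
from survbira.tiling import PatchRecord, TilingConfig, normalize_patch, tile_slide

VARIANTS = ("patch_mean", "bin_mean", "full")


@dataclass
class PipelineConfig:
    """Everything needed to run the cascade end to end."""

    tiling: TilingConfig = field(default_factory=TilingConfig)
    survpatch: SurvpatchConfig = field(default_factory=SurvpatchConfig)
    n_trees: int = 10
    seed: int = 0
    tissue_keep: frozenset[str] | None = None  # None = all types
    max_patches_per_slide: int | None = None  # cap (seeded subsample) or None


def _load_image(path: str | Path) -> np.ndarray:
    img = iio.imread(path)
    if img.ndim == 3 and img.shape[2] == 4:
        img = img[:, :, :3]
    return img


class SurBiRaPipeline:
    """Cascaded survival-time predictor: patch CNN -> binning -> forest."""

    def __init__(self, config: PipelineConfig) -> None:
        self.config = config
        self.patch_model: PatchRegressor | None = None
        self.slide_model: SlideRegressor | None = None
        self.m_global: int | None = None
        self.history: list[dict] | None = None

    # -- data preparation ------------------------------------------------

    def _select_slides(self, slides: list[SlideRecord]) -> list[SlideRecord]:
        if self.config.tissue_keep is None:
            return list(slides)
        return filter_by_tissue_type(slides, set(self.config.tissue_keep))

    def _slide_patches(
        self, slide: SlideRecord, label_days: float
    ) -> list[PatchRecord]:
        """Tile one slide into normalized, label-broadcast patches."""
        image = _load_image(slide.image_path)
        patches = tile_slide(
            image,
            self.config.tiling,
            label_days=label_days,
            slide_id=slide.slide_id,
        )
        cap = self.config.max_patches_per_slide
        if cap is not None and len(patches) > cap:
            rng = np.random.default_rng(
                [self.config.seed, zlib.crc32(slide.slide_id.encode()) % (2**31)]
            )
            keep = sorted(rng.choice(len(patches), size=cap, replace=False))
            patches = [patches[i] for i in keep]
        for p in patches:
            p.pixels = normalize_patch(p.pixels)
        return patches

    def _cohort_patches(
        self, patients: list[PatientRecord], slides: list[SlideRecord]
    ) -> dict[str, list[PatchRecord]]:
        """Patches per slide id, for the selected tissue types."""
        survival = {p.patient_id: p.survival_days for p in patients}
        out: dict[str, list[PatchRecord]] = {}
        for slide in self._select_slides(slides):
            if slide.patient_id not in survival:
                continue
            out[slide.slide_id] = self._slide_patches(
                slide, float(survival[slide.patient_id])
            )
        return out

    # -- fitting ---------------------------------------------------------

    def fit(
        self, patients: list[PatientRecord], slides: list[SlideRecord]
    ) -> "SurBiRaPipeline":
        by_slide = self._cohort_patches(patients, slides)
        train_patches = [p for ps in by_slide.values() for p in ps]
        if not train_patches:
            raise ValueError("no tissue patches found in the training slides")
        model = build_survpatch(self.config.survpatch, self.config.tiling.patch_size)
        model, self.history = train_survpatch(model, train_patches)
        self.patch_model = model

        # Patch predictions per training slide (no augmentation at inference).
        slide_preds = {
            sid: model.predict(np.stack([p.pixels for p in ps]).astype(np.float32))
            for sid, ps in by_slide.items()
            if ps
        }
        self.m_global = choose_global_bin_count(list(slide_preds.values()))
        survival = {p.patient_id: p.survival_days for p in patients}
        slide_by_id = {s.slide_id: s for s in slides}
        feats, times = [], []
        for sid, preds in slide_preds.items():
            feats.append(binned_features(preds, self.m_global, slide_id=sid))
            times.append(float(survival[slide_by_id[sid].patient_id]))
        self.slide_model = fit_slide_regressor(
            feats, times, n_trees=self.config.n_trees, seed=self.config.seed
        )
        return self

    # -- prediction ------------------------------------------------------

    def predict_patients(
        self,
        patients: list[PatientRecord],
        slides: list[SlideRecord],
        variant: str = "full",
    ) -> dict[str, PredictionRecord]:
        """Predict survival per patient.

        ``variant`` selects the cascade depth: ``"patch_mean"`` averages
        the raw patch predictions per patient (no binning, no forest);
        ``"bin_mean"`` takes the mean of each slide's binned feature
        vector as its slide prediction; ``"full"`` runs the forest.
        """
        if variant not in VARIANTS:
            raise ValueError(f"variant must be one of {VARIANTS}, got {variant!r}")
        if self.patch_model is None:
            raise RuntimeError("pipeline is not fitted")
        by_slide = self._cohort_patches(patients, slides)
        slide_by_id = {s.slide_id: s for s in slides}

        if variant == "patch_mean":
            pooled: dict[str, list[float]] = {}
            for sid, ps in by_slide.items():
                if not ps:
                    continue
                preds = self.patch_model.predict(
                    np.stack([p.pixels for p in ps]).astype(np.float32)
                )
                pooled.setdefault(slide_by_id[sid].patient_id, []).extend(preds)
            return {
                pid: PredictionRecord(
                    level="patient", id=pid, predicted_days=float(np.mean(v))
                )
                for pid, v in pooled.items()
            }

        slide_sv: dict[str, list[float]] = {}
        for sid, ps in by_slide.items():
            if not ps:
                continue
            preds = self.patch_model.predict(
                np.stack([p.pixels for p in ps]).astype(np.float32)
            )
            feat = binned_features(preds, self.m_global, slide_id=sid)
            if variant == "bin_mean":
                sv = float(np.mean(feat.values))
            else:
                sv = predict_slide_survival(self.slide_model, feat).predicted_days
            slide_sv.setdefault(slide_by_id[sid].patient_id, []).append(sv)
        return {
            pid: aggregate_patient(vals, patient_id=pid)
            for pid, vals in slide_sv.items()
        }
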