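"""End-to-end orchestration: masks, robust statistics, haematoma, oedema.

``run_volumes`` operates on in-memory volumes; ``run_case`` adds file I/O
(NIfTI inputs, NIfTI masks plus a JSON provenance sidecar as outputs).  All
four input volumes must already be co-registered onto one grid — a grid
mismatch is a fatal error, never silently resampled.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import atlas_masks
from .atlas_masks import LabelMap, MaskBundle, build_mask_bundle, load_label_map
from .haematoma_seg import segment_haematoma
from .oedema_seg import segment_oedema
from .robust_outliers import (
    DEFAULT_CUTOFF_QUANTILE,
    DEFAULT_SUBSAMPLE_SIZE,
    DEFAULT_SUPPORT_FRACTION,
    fit_robust_stats,
)
from .volume_core import BinaryMask, IntensityVolume, dice_score, load_volume, save_mask

log = logging.getLogger(__name__)


@dataclass
class PipelineParams:
    """Tunable parameters; defaults: lambda = 15, MCD resisting 40% outliers,
    chi-squared outlier cut-off at the 0.975 quantile."""

    lam: float = 15.0
    mcd_support_fraction: float = DEFAULT_SUPPORT_FRACTION
    mcd_cutoff_quantile: float = DEFAULT_CUTOFF_QUANTILE
    mcd_subsample_size: int = DEFAULT_SUBSAMPLE_SIZE
    eq_variant: str = "linear"  # dynamic-threshold form: "linear" or "squared"
    distance_mode: str = "voxel"  # geodesic step units: "voxel" or "mm"
    susceptibility_labels: frozenset = atlas_masks.SUSCEPTIBILITY_LABELS
    lesion_labels: frozenset = atlas_masks.LESION_LABELS
    ventricle_labels: frozenset = atlas_masks.VENTRICLE_LABELS
    csf_label: int = atlas_masks.CSF_LABEL
    rng_seed: int = 0

    @classmethod
    def from_config(cls, path: str | Path, **overrides) -> "PipelineParams":
        """Load parameters from a YAML config file; keyword overrides win."""
        with open(path) as fh:
            cfg = yaml.safe_load(fh) or {}
        known = {
            "lambda": "lam",
            "lam": "lam",
            "mcd_support_fraction": "mcd_support_fraction",
            "mcd_cutoff_quantile": "mcd_cutoff_quantile",
            "mcd_subsample_size": "mcd_subsample_size",
            "eq_variant": "eq_variant",
            "distance_mode": "distance_mode",
            "susceptibility_labels": "susceptibility_labels",
            "lesion_labels": "lesion_labels",
            "ventricle_labels": "ventricle_labels",
            "csf_label": "csf_label",
            "rng_seed": "rng_seed",
        }
        kwargs = {}
        for key, value in cfg.items():
            if key not in known:
                raise ValueError(f"unknown config key {key!r}")
            attr = known[key]
            if attr.endswith("_labels"):
                value = frozenset(int(v) for v in value)
            kwargs[attr] = value
        kwargs.update(overrides)
        return cls(**kwargs)

    def to_dict(self) -> dict:
        return {
            "lambda": self.lam,
            "mcd_support_fraction": self.mcd_support_fraction,
            "mcd_cutoff_quantile": self.mcd_cutoff_quantile,
            "mcd_subsample_size": self.mcd_subsample_size,
            "eq_variant": self.eq_variant,
            "distance_mode": self.distance_mode,
            "susceptibility_labels": sorted(self.susceptibility_labels),
            "lesion_labels": sorted(self.lesion_labels),
            "ventricle_labels": sorted(self.ventricle_labels),
            "csf_label": self.csf_label,
            "rng_seed": self.rng_seed,
        }


@dataclass
class SegmentationResult:
    haematoma: BinaryMask
    oedema: BinaryMask
    bundle: MaskBundle
    haematoma_volume_ml: float
    oedema_volume_ml: float
    provenance: dict = field(default_factory=dict)

    def check_invariants(self) -> None:
        if np.any(self.haematoma.data & self.oedema.data):
            raise AssertionError("haematoma and oedema masks must be disjoint")


def run_volumes(
    t2s: IntensityVolume,
    flair: IntensityVolume,
    labels: LabelMap,
    svd: IntensityVolume,
    params: PipelineParams | None = None,
) -> SegmentationResult:
    """Run the whole pipeline on in-memory volumes sharing one grid."""
    params = params or PipelineParams()
    shapes = {t2s.shape, flair.shape, labels.shape, svd.shape}
    if len(shapes) != 1:
        raise ValueError(f"input grids do not match: {sorted(shapes)} (registration is upstream)")

    bundle = build_mask_bundle(
        labels,
        t2s,
        flair,
        susceptibility_labels=params.susceptibility_labels,
        lesion_labels=params.lesion_labels,
        ventricle_labels=params.ventricle_labels,
        csf_label=params.csf_label,
    )
    fit_kwargs = dict(
        support_fraction=params.mcd_support_fraction,
        cutoff_quantile=params.mcd_cutoff_quantile,
        subsample_size=params.mcd_subsample_size,
        rng_seed=params.rng_seed,
    )
    stats_t2s = fit_robust_stats(t2s, bundle.wm_gm, **fit_kwargs)
    stats_flair = fit_robust_stats(flair, bundle.wm_gm, **fit_kwargs)

    haematoma, thr, best, haem_prov = segment_haematoma(t2s, flair, bundle, stats_t2s, stats_flair)
    oedema, oedema_prov = segment_oedema(
        flair,
        bundle.brain,
        haematoma,
        stats_flair,
        svd,
        lam=params.lam,
        variant=params.eq_variant,
        spacing_mode=params.distance_mode,
    )
    voxel_ml = float(np.prod(t2s.spacing)) / 1000.0
    result = SegmentationResult(
        haematoma=haematoma,
        oedema=oedema,
        bundle=bundle,
        haematoma_volume_ml=round(haematoma.count * voxel_ml, 2),
        oedema_volume_ml=round(oedema.count * voxel_ml, 2),
        provenance={
            "params": params.to_dict(),
            "robust_stats": {"t2s": stats_t2s.to_dict(), "flair": stats_flair.to_dict()},
            "haematoma": haem_prov,
            "oedema": oedema_prov,
        },
    )
    result.check_invariants()
    return result


def run_case(
    t2s_path, flair_path, labels_path, svd_path, params: PipelineParams | None = None, out_dir=None
) -> SegmentationResult:
    """Load four NIfTI inputs, run the pipeline, optionally write outputs."""
    t2s = load_volume(t2s_path)
    flair = load_volume(flair_path)
    labels = load_label_map(labels_path)
    svd = load_volume(svd_path)
    result = run_volumes(t2s, flair, labels, svd, params)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        save_mask(result.haematoma, out_dir / "haematoma_mask.nii.gz")
        save_mask(result.oedema, out_dir / "oedema_mask.nii.gz")
        prov = dict(result.provenance)
        prov["haematoma_volume_ml"] = result.haematoma_volume_ml
        prov["oedema_volume_ml"] = result.oedema_volume_ml
        with open(out_dir / "provenance.json", "w") as fh:
            json.dump(prov, fh, indent=2)
    return result


def evaluate(pred: SegmentationResult, ref_haematoma: BinaryMask, ref_oedema: BinaryMask) -> dict:
    """Dice for haematoma, oedema, and the union-vs-union combined label."""
    combined_pred = pred.haematoma.like(pred.haematoma.data | pred.oedema.data)
    combined_ref = ref_haematoma.like(ref_haematoma.data | ref_oedema.data)
    return {
        "dice_haematoma": dice_score(pred.haematoma, ref_haematoma),
        "dice_oedema": dice_score(pred.oedema, ref_oedema),
        "dice_combined": dice_score(combined_pred, combined_ref),
    }
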