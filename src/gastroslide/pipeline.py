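"""End-to-end slide-analysis pipeline.

Executes the enabled stages in canonical order inside a working
directory, each stage reading the previous stage's artifacts from
well-known paths so any stage can resume from a prior run:

* ``synth`` - generate demo slides (+ ASAP XML annotations) when no input
  directory is configured;
* ``mask`` - tissue masks per slide (PNG + JSON sidecar);
* ``patch`` - labeled training patches from the training-split slides;
* ``train`` - the reference patch classifier (stain-normalized to the
  first training patch when the stain stage is enabled);
* ``heatmap`` - malignancy heatmap per slide;
* ``featurize`` - the 44-feature row per slide (``features.csv``);
* ``classify`` - slide-level random forest, predictions and test metrics.

Every run writes the resolved config, a ``report.json`` summary and a
``manifest.json`` listing each artifact with its SHA-256 checksum.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from . import heatmap as hm_mod
from . import synthdata
from .config import PipelineConfig, save_config, stage_seed
from .patch_model import (
    NormalizingClassifier,
    ReferenceClassifier,
    train_reference_classifier,
)
from .patching import extract_patches, label_patch
from .slide_io import LESION_CLASSES, SlideImage, parse_annotations, \
    rasterize_annotations, write_annotations
from .stain import estimate_stain_matrix, StainEstimationError
from .tissue_mask import TissueMask, tissue_mask_for_slide
from .wsi_features import (
    FEATURE_NAMES,
    classify_slide,
    extract_feature_vector,
    split_cohort,
    train_slide_classifier,
)

logger = logging.getLogger("gastroslide.pipeline")


class PipelineError(RuntimeError):
    """A stage cannot run; the message names the stage to run first."""


def _json_log(stage: str, **fields) -> None:
    logger.info(json.dumps({"stage": stage, **fields}))


@dataclasses.dataclass
class PipelineResult:
    workdir: Path
    report: dict
    manifest: dict


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Run the enabled stages; see the module docstring for the layout."""
    work = Path(config.workdir)
    work.mkdir(parents=True, exist_ok=True)
    save_config(config, work / "resolved_config.yaml")
    stages = set(config.stages)

    if "synth" in stages and config.input_dir is None:
        _stage_synth(config, work)
    slides_dir = Path(config.input_dir) if config.input_dir else work / "slides"
    if not slides_dir.exists():
        raise PipelineError(
            "no slide inputs found; configure input_dir or enable the "
            "'synth' stage"
        )
    index = _slide_index(slides_dir, config)

    if "mask" in stages:
        _stage_mask(config, work, index)
    if "patch" in stages:
        _stage_patch(config, work, index)
    if "train" in stages:
        _stage_train(config, work)
    if "heatmap" in stages:
        _stage_heatmap(config, work, index)
    if "featurize" in stages:
        _stage_featurize(config, work, index)
    report = {}
    if "classify" in stages:
        report = _stage_classify(config, work, index)

    manifest = _write_manifest(work)
    (work / "report.json").write_text(json.dumps(report, indent=2))
    return PipelineResult(workdir=work, report=report, manifest=manifest)


# -- stage implementations -------------------------------------------------


def _stage_synth(config: PipelineConfig, work: Path) -> None:
    out = work / "slides"
    out.mkdir(exist_ok=True)
    p = config.synth
    rng = np.random.default_rng(stage_seed(config.seed, "synth"))
    rows = []
    for i in range(p.n_slides):
        label = LESION_CLASSES[i % 3]
        size = p.slide_size
        side = int(np.sqrt(p.lesion_fraction) * size)
        x0 = int(rng.integers(0, size - side + 1))
        y0 = int(rng.integers(0, size - side + 1))
        poly = np.array(
            [[x0, y0], [x0 + side, y0], [x0 + side, y0 + side], [x0, y0 + side]],
            dtype=float,
        )
        spec = synthdata.SlideSpec(
            width=size,
            height=size,
            lesion_polygons=[(label, poly)],
            seed=int(rng.integers(0, 2**31)) + p.seed_offset,
        )
        slide, anns, _mask = synthdata.generate_synthetic_slide(spec)
        slide_id = f"slide_{i:03d}"
        slide.slide_id = slide_id
        slide.save(out / f"{slide_id}.png")
        anns.slide_id = slide_id
        write_annotations(anns, out / f"{slide_id}.xml")
        rows.append({"slide_id": slide_id, "label": label})
    pd.DataFrame(rows).to_csv(out / "slides.csv", index=False)
    _json_log("synth", n_slides=p.n_slides)


def _slide_index(slides_dir: Path, config: PipelineConfig) -> pd.DataFrame:
    """Slide ids, labels (from slides.csv or worst annotated class) and
    deterministic train/test/val split."""
    paths = sorted(
        p for p in slides_dir.iterdir()
        if p.suffix.lower() in (".png", ".tif", ".tiff")
    )
    if not paths:
        raise PipelineError(f"no slide rasters found in {slides_dir}")
    truth_csv = slides_dir / "slides.csv"
    labels = {}
    if truth_csv.exists():
        t = pd.read_csv(truth_csv)
        labels = dict(zip(t["slide_id"], t["label"]))
    rows = []
    for path in paths:
        sid = path.stem
        label = labels.get(sid)
        xml = path.with_suffix(".xml")
        if label is None and xml.exists():
            anns = parse_annotations(xml)
            present = {a.label for a in anns}
            for cls in reversed(LESION_CLASSES):  # worst class wins
                if cls in present:
                    label = cls
                    break
        rows.append({"slide_id": sid, "path": str(path), "label": label})
    frame = pd.DataFrame(rows)
    train, test, val = split_cohort(
        list(frame["slide_id"]),
        config.splits,
        seed=stage_seed(config.seed, "split"),
    )
    split = {sid: "train" for sid in train}
    split.update({sid: "test" for sid in test})
    split.update({sid: "val" for sid in val})
    frame["split"] = frame["slide_id"].map(split)
    return frame


def _mask_paths(work: Path, sid: str) -> tuple[Path, Path]:
    d = work / "masks"
    return d / f"{sid}.png", d / f"{sid}.json"


def _load_mask(work: Path, sid: str) -> TissueMask:
    png, meta_path = _mask_paths(work, sid)
    if not png.exists():
        raise PipelineError(
            f"tissue mask for {sid} is missing; run the 'mask' stage first"
        )
    meta = json.loads(meta_path.read_text())
    mask = np.asarray(Image.open(png)) > 0
    return TissueMask(
        mask=mask,
        downsample=meta["downsample"],
        threshold=meta["threshold"],
        close_radius=meta["close_radius"],
        min_area_fraction=meta["min_area_fraction"],
    )


def _stage_mask(config: PipelineConfig, work: Path, index: pd.DataFrame) -> None:
    (work / "masks").mkdir(exist_ok=True)
    for row in index.itertuples():
        slide = SlideImage.open(row.path)
        mask = tissue_mask_for_slide(
            slide,
            downsample=config.mask.downsample,
            close_radius=config.mask.close_radius,
            min_area_fraction=config.mask.min_area_fraction,
        )
        png, meta = _mask_paths(work, row.slide_id)
        Image.fromarray(mask.mask.astype(np.uint8) * 255).save(png)
        meta.write_text(
            json.dumps(
                {
                    "downsample": mask.downsample,
                    "threshold": mask.threshold,
                    "close_radius": mask.close_radius,
                    "min_area_fraction": mask.min_area_fraction,
                }
            )
        )
    _json_log("mask", n_slides=len(index))


def _stage_patch(config: PipelineConfig, work: Path, index: pd.DataFrame) -> None:
    out = work / "patches"
    out.mkdir(exist_ok=True)
    rows = []
    n = 0
    for row in index[index["split"] == "train"].itertuples():
        xml = Path(row.path).with_suffix(".xml")
        if not xml.exists():
            continue
        slide = SlideImage.open(row.path)
        mask = _load_mask(work, row.slide_id)
        anns = parse_annotations(xml)
        label_mask = rasterize_annotations(anns, slide.dimensions, downsample=1)
        for patch in extract_patches(
            slide,
            mask,
            scales=config.patch.training_scales,
            stride_fraction=config.patch.stride_fraction,
            out_side=config.patch.out_side,
            min_tissue_fraction=config.patch.min_tissue_fraction,
        ):
            label = label_patch(
                (patch.x, patch.y, patch.scale),
                label_mask,
                purity_threshold=config.patch.purity_threshold,
            )
            if label is None:
                continue
            name = f"{row.slide_id}_{patch.scale}_{patch.x}_{patch.y}.png"
            Image.fromarray(patch.raster).save(out / name)
            rows.append(
                {
                    "file": name,
                    "slide_id": row.slide_id,
                    "x": patch.x,
                    "y": patch.y,
                    "scale": patch.scale,
                    "label": label,
                }
            )
            n += 1
    pd.DataFrame(
        rows, columns=["file", "slide_id", "x", "y", "scale", "label"]
    ).to_csv(out / "manifest.csv", index=False)
    _json_log("patch", n_patches=n)


def _load_patches(work: Path):
    from .patching import Patch

    manifest = work / "patches" / "manifest.csv"
    if not manifest.exists():
        raise PipelineError(
            "no patch manifest found; run the 'patch' stage first"
        )
    frame = pd.read_csv(manifest)
    patches = []
    for row in frame.itertuples():
        raster = np.asarray(Image.open(work / "patches" / row.file))
        patches.append(
            Patch(
                raster=raster,
                x=row.x,
                y=row.y,
                scale=row.scale,
                label=row.label,
                slide_id=row.slide_id,
            )
        )
    return patches


def _stage_train(config: PipelineConfig, work: Path) -> None:
    patches = _load_patches(work)
    if not patches:
        raise PipelineError("patch stage produced no labeled patches")
    reference_profile = None
    if config.stain.enabled:
        for patch in patches:
            try:
                reference_profile = estimate_stain_matrix(
                    patch.raster,
                    beta=config.stain.beta,
                    alpha=config.stain.alpha,
                    source=patch.slide_id,
                )
                break
            except StainEstimationError:
                continue
    if reference_profile is not None:
        from .stain import normalize_to_reference

        for patch in patches:
            patch.raster = normalize_to_reference(
                patch.raster,
                reference_profile,
                beta=config.stain.beta,
                alpha=config.stain.alpha,
            ).image
    model = train_reference_classifier(
        patches, config.classifier, seed=stage_seed(config.seed, "train")
    )
    (work / "model").mkdir(exist_ok=True)
    model.save(work / "model" / "patch_classifier.npz")
    if reference_profile is not None:
        np.savez(
            work / "model" / "stain_reference.npz",
            matrix=reference_profile.matrix,
            max_concentrations=reference_profile.max_concentrations,
            background_intensity=reference_profile.background_intensity,
        )
    _json_log("train", n_patches=len(patches))


def _load_classifier(config: PipelineConfig, work: Path):
    path = work / "model" / "patch_classifier.npz"
    if not path.exists():
        raise PipelineError(
            "patch classifier is missing; run the 'train' stage first"
        )
    model = ReferenceClassifier.load(path)
    ref_path = work / "model" / "stain_reference.npz"
    if config.stain.enabled and ref_path.exists():
        from .stain import StainProfile

        with np.load(ref_path) as z:
            reference = StainProfile(
                matrix=z["matrix"],
                max_concentrations=z["max_concentrations"],
                background_intensity=float(z["background_intensity"]),
            )
        return NormalizingClassifier(
            model, reference, beta=config.stain.beta, alpha=config.stain.alpha
        )
    return model


def _heatmap_paths(work: Path, sid: str) -> tuple[Path, Path]:
    d = work / "heatmaps"
    return d / f"{sid}.png", d / f"{sid}.json"


def _stage_heatmap(config: PipelineConfig, work: Path, index: pd.DataFrame) -> None:
    classifier = _load_classifier(config, work)
    (work / "heatmaps").mkdir(exist_ok=True)
    for row in index.itertuples():
        slide = SlideImage.open(row.path)
        mask = _load_mask(work, row.slide_id)
        heatmap = hm_mod.predict_heatmap(
            slide,
            classifier,
            mask,
            cell_size=config.heatmap.cell_size,
            min_tissue_fraction=config.heatmap.min_tissue_fraction,
            out_side=config.patch.out_side,
        )
        png, meta = _heatmap_paths(work, row.slide_id)
        hm_mod.save_heatmap(heatmap, png, meta)
    _json_log("heatmap", n_slides=len(index))


def _stage_featurize(config: PipelineConfig, work: Path, index: pd.DataFrame) -> None:
    rows = []
    for row in index.itertuples():
        png, meta = _heatmap_paths(work, row.slide_id)
        if not png.exists():
            raise PipelineError(
                f"heatmap for {row.slide_id} is missing; run the 'heatmap' "
                "stage first"
            )
        heatmap = hm_mod.load_heatmap(png, meta)
        fv = extract_feature_vector(heatmap)
        record = {"slide_id": row.slide_id, "label": row.label, "split": row.split}
        record.update(dict(zip(FEATURE_NAMES, fv.values)))
        rows.append(record)
    frame = pd.DataFrame(rows)
    frame.to_csv(work / "features.csv", index=False, float_format="%.12g")
    _json_log("featurize", n_slides=len(rows))


def _stage_classify(config: PipelineConfig, work: Path, index: pd.DataFrame) -> dict:
    path = work / "features.csv"
    if not path.exists():
        raise PipelineError(
            "features.csv is missing; run the 'featurize' stage first"
        )
    frame = pd.read_csv(path)
    train = frame[frame["split"] == "train"]
    if train["label"].nunique() < 2:
        raise PipelineError(
            "training split has fewer than 2 slide classes; cannot train"
        )
    model = train_slide_classifier(
        train[list(FEATURE_NAMES)],
        train["label"],
        config.forest,
        seed=stage_seed(config.seed, "classify"),
    )
    preds = []
    for row in frame.itertuples():
        vec = frame.loc[row.Index, list(FEATURE_NAMES)].to_numpy(float)
        label, probs = classify_slide(model, vec)
        preds.append(
            {
                "slide_id": row.slide_id,
                "split": row.split,
                "true_label": row.label,
                "predicted": label,
                **{f"p_{c}": probs.get(c, 0.0) for c in LESION_CLASSES},
            }
        )
    out = pd.DataFrame(preds)
    out.to_csv(work / "slide_predictions.csv", index=False, float_format="%.12g")
    test = out[out["split"] == "test"]
    report = {
        "n_slides": int(len(out)),
        "oob_accuracy": model.oob_accuracy,
        "test_accuracy": float((test["predicted"] == test["true_label"]).mean())
        if len(test)
        else None,
        "n_test": int(len(test)),
    }
    _json_log("classify", **report)
    return report


def _write_manifest(work: Path) -> dict:
    artifacts = {}
    for path in sorted(work.rglob("*")):
        if path.is_file() and path.name != "manifest.json":
            digest = hashlib.sha256(path.read_bytes()).hexdigest()
            artifacts[str(path.relative_to(work))] = digest
    manifest = {"artifacts": artifacts}
    (work / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
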