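"""Pixel-wise maps, per-lesion majority voting and metric reports.

Also hosts the cohort-level orchestration used by the CLI: raw pre-processing,
ML pre-processing, CNN training, map prediction, voting and metrics, all
driven by a single seeded configuration.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from hsiderm import mlprep, model as model_mod, photometric, synthdata

NO_PREDICTION = -1

#: tie-break priority: over-calling malignancy is the safer error
MALIGNANCY_PRIORITY = ("MM", "SCC", "BCC", "PN", "ID")

GROUP_CLASSES = {
    "pigmented": list(synthdata.PIGMENTED_CLASSES),
    "nonpigmented": list(synthdata.NONPIGMENTED_CLASSES),
}


@dataclass
class ClassificationMap:
    """Per-pixel predicted class index (NO_PREDICTION outside the valid
    region) and maximum softmax probability."""

    class_map: np.ndarray  # int, NO_PREDICTION where not predicted
    confidence_map: np.ndarray  # float, NaN where not predicted
    class_order: list


@dataclass
class MetricsReport:
    class_order: list
    confusion: np.ndarray  # counts, rows = truth, cols = prediction
    confusion_normalized: np.ndarray  # row-normalized
    per_class: dict  # label -> {sensitivity, specificity, ppv, f1, support}
    weighted: dict  # support-weighted aggregates
    undefined: dict  # label -> list of metric names with zero denominators
    n_samples: int


@dataclass
class LesionResult:
    lesion_id: int
    true_label: str
    majority_label: str
    class_counts: dict  # predicted-label -> count over annotated lesion pixels
    map: ClassificationMap | None = None


# --------------------------------------------------------------------------- #
# maps and voting
# --------------------------------------------------------------------------- #


def classification_map(
    trained: model_mod.TrainedModel,
    cube: mlprep.FeatureCube,
    fov: np.ndarray,
    window: int = mlprep.DEFAULT_WINDOW,
    stride: int = 1,
    region: np.ndarray | None = None,
    batch_size: int = 512,
) -> ClassificationMap:
    """Rolling-window prediction restricted to the field of view (optionally
    to ``region``); class = argmax, confidence = max probability."""
    if not isinstance(trained, model_mod.TrainedModel):
        raise ValueError("a TrainedModel is required")
    mask = np.asarray(fov, dtype=bool)
    if region is not None:
        mask = mask & np.asarray(region, dtype=bool)
    h, w = cube.values.shape[:2]
    class_map = np.full((h, w), NO_PREDICTION, dtype=np.int16)
    confidence = np.full((h, w), np.nan, dtype=np.float32)
    centers, patches = [], []

    def flush():
        if not patches:
            return
        probs = model_mod.predict(trained, np.stack(patches))
        idx = probs.argmax(axis=1)
        for (r, c), k, p in zip(centers, idx, probs.max(axis=1)):
            class_map[r, c] = k
            confidence[r, c] = p
        centers.clear()
        patches.clear()

    for center, patch in mlprep.rolling_windows(cube, mask, window=window, stride=stride):
        centers.append(center)
        patches.append(patch)
        if len(patches) >= batch_size:
            flush()
    flush()
    return ClassificationMap(class_map=class_map, confidence_map=confidence,
                             class_order=list(trained.class_order))


def majority_vote(cmap: ClassificationMap, annotation: np.ndarray, lesion_classes) -> tuple:
    """Majority class over predicted, annotated lesion pixels.

    Healthy-skin predictions are counted for diagnostics but excluded from the
    vote; ties break by malignancy priority (MM > PN, SCC > BCC > ID).
    Returns (label, counts dict over all predicted labels).
    """
    annotation = np.asarray(annotation, dtype=bool)
    predicted = cmap.class_map != NO_PREDICTION
    sel = annotation & predicted
    if not sel.any():
        raise ValueError("annotation contains no predicted pixels")
    votes = cmap.class_map[sel]
    counts = {
        label: int((votes == i).sum()) for i, label in enumerate(cmap.class_order)
    }
    lesion_counts = {c: counts.get(c, 0) for c in lesion_classes}
    if sum(lesion_counts.values()) == 0:
        raise ValueError("no lesion-type predictions inside the annotation")
    priority = {c: MALIGNANCY_PRIORITY.index(c) for c in lesion_classes}
    winner = min(lesion_counts, key=lambda c: (-lesion_counts[c], priority[c]))
    return winner, counts


# --------------------------------------------------------------------------- #
# metrics
# --------------------------------------------------------------------------- #


def pixelwise_metrics(predictions, truth, class_order) -> MetricsReport:
    """One-vs-rest sensitivity/specificity/PPV/F1 per class, support-weighted
    aggregates and the confusion matrix.  Zero-denominator rates are reported
    as 0 and flagged in ``undefined``."""
    pred = np.asarray(predictions)
    true = np.asarray(truth)
    if pred.shape != true.shape:
        raise ValueError(f"length mismatch: {pred.shape} vs {true.shape}")
    order = list(class_order)
    index = {c: i for i, c in enumerate(order)}
    for lab in np.unique(np.concatenate([pred, true])):
        if lab not in index:
            raise ValueError(f"label {lab!r} outside class order {order}")
    k = len(order)
    pi = np.asarray([index[v] for v in pred])
    ti = np.asarray([index[v] for v in true])
    confusion = np.zeros((k, k), dtype=np.int64)
    np.add.at(confusion, (ti, pi), 1)

    n = len(pred)
    per_class, undefined = {}, {}
    supports = confusion.sum(axis=1)
    for i, label in enumerate(order):
        tp = confusion[i, i]
        fn = confusion[i].sum() - tp
        fp = confusion[:, i].sum() - tp
        tn = n - tp - fn - fp
        flags = []

        def rate(num, den, name):
            if den == 0:
                flags.append(name)
                return 0.0
            return num / den

        sens = rate(tp, tp + fn, "sensitivity")
        spec = rate(tn, tn + fp, "specificity")
        ppv = rate(tp, tp + fp, "ppv")
        f1 = rate(2 * ppv * sens, ppv + sens, "f1")
        per_class[label] = {
            "sensitivity": sens,
            "specificity": spec,
            "ppv": ppv,
            "f1": f1,
            "support": int(supports[i]),
        }
        if flags:
            undefined[label] = flags

    weights = supports / max(supports.sum(), 1)
    weighted = {
        m: float(sum(per_class[label][m] * weights[i] for i, label in enumerate(order)))
        for m in ("sensitivity", "specificity", "ppv", "f1")
    }
    row_sums = supports[:, None].astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        normalized = np.where(row_sums > 0, confusion / np.where(row_sums > 0, row_sums, 1), 0.0)
    return MetricsReport(
        class_order=order,
        confusion=confusion,
        confusion_normalized=normalized,
        per_class=per_class,
        weighted=weighted,
        undefined=undefined,
        n_samples=n,
    )


# --------------------------------------------------------------------------- #
# cohort orchestration
# --------------------------------------------------------------------------- #


@dataclass
class PipelineConfig:
    """Every tunable of the end-to-end run, with desk-scale defaults."""

    smoothing_sigma: float = 2.0
    surface_band_nm: float = mlprep.DEFAULT_SURFACE_BAND_NM
    erosion_px: int = 30
    margin_px: int = 60
    annulus_outer_px: int = 200
    window: int = mlprep.DEFAULT_WINDOW
    n_lesion_train: int = mlprep.DEFAULT_N_LESION
    n_healthy_train: int = mlprep.DEFAULT_N_HEALTHY
    n_lesion_test: int = mlprep.DEFAULT_N_LESION
    n_healthy_test: int = mlprep.DEFAULT_N_HEALTHY
    validation_fraction: float = 0.2
    vote_stride: int = 1
    model: model_mod.ModelConfig | None = None
    dtype: str = "float64"

    def desk_scaled(self) -> "PipelineConfig":
        """Defaults scaled to 256 px frames (paper-scale margins are set for
        1605x1640 frames and leave no sampling regions at desk scale)."""
        import dataclasses

        return dataclasses.replace(self, erosion_px=15, margin_px=30, annulus_outer_px=120)


@dataclass
class CohortReport:
    group: str
    class_order: list
    pixel_metrics: MetricsReport
    lesion_results: list
    vote_metrics: MetricsReport
    training_log: list
    seed: int


def prepare_lesion(item: synthdata.CohortItem, config: PipelineConfig):
    """Raw + ML pre-processing for one lesion: returns (train half, test half)."""
    cube = photometric.preprocess_capture(
        item.capture, sigma=config.smoothing_sigma,
        dtype=np.float32 if config.dtype == "float32" else None)
    features = mlprep.prepare_features(cube, item.phantom.fov_mask, config.surface_band_nm)
    masks = mlprep.build_masks(
        item.annotation, item.phantom.fov_mask,
        erosion_px=config.erosion_px, margin_px=config.margin_px,
        annulus_outer_px=config.annulus_outer_px)
    return mlprep.split_vertical(features, masks, label=item.label)


def run_cohort(cohort, classifier_group: str, config: PipelineConfig | None = None,
               seed: int = 0, keep_maps: bool = False) -> CohortReport:
    """preprocess -> mlprep -> train -> maps -> votes -> metrics, fully seeded."""
    if classifier_group not in GROUP_CLASSES:
        raise ValueError(f"classifier_group must be one of {sorted(GROUP_CLASSES)}")
    lesion_classes = GROUP_CLASSES[classifier_group]
    bad = {item.label for item in cohort} - set(lesion_classes)
    if bad:
        raise ValueError(f"cohort labels {sorted(bad)} outside the {classifier_group} group")
    config = config or PipelineConfig()
    class_order = sorted(lesion_classes + [synthdata.HEALTHY])
    model_config = config.model or model_mod.ModelConfig(n_classes=len(class_order), seed=seed)

    seeds = np.random.SeedSequence(seed).spawn(len(cohort) + 2)
    train_samples, test_samples, halves = [], [], []
    for item, ss in zip(cohort, seeds[:-2]):
        train_half, test_half = prepare_lesion(item, config)
        s_train, s_test = ss.generate_state(2)
        train_samples.extend(
            mlprep.sample_windows(train_half, config.n_lesion_train,
                                  config.n_healthy_train, config.window, seed=int(s_train)))
        test_samples.extend(
            mlprep.sample_windows(test_half, config.n_lesion_test,
                                  config.n_healthy_test, config.window, seed=int(s_test)))
        halves.append((train_half, test_half))

    s_split, s_balance = seeds[-2].generate_state(2)
    train_set, val_set = mlprep.make_validation_split(
        train_samples, config.validation_fraction, seed=int(s_split))
    train_set = mlprep.balance_oversample(train_set, seed=int(s_balance))
    train_set = mlprep.augment_flips(train_set)

    net = model_mod.build_model(model_config)
    trained = model_mod.train(net, train_set, val_set, model_config, class_order=class_order)

    probs = model_mod.predict(trained, test_samples)
    pred_labels = [class_order[i] for i in probs.argmax(axis=1)]
    true_labels = [s.label for s in test_samples]
    pixel_metrics = pixelwise_metrics(pred_labels, true_labels, class_order)

    lesion_results, vote_pred, vote_true = [], [], []
    for lesion_id, (item, (_, test_half)) in enumerate(zip(cohort, halves)):
        cmap = classification_map(
            trained, test_half.cube, test_half.masks.fov_mask,
            window=config.window, stride=config.vote_stride,
            region=test_half.masks.annotation)
        label, counts = majority_vote(cmap, test_half.masks.annotation, lesion_classes)
        lesion_results.append(
            LesionResult(lesion_id=lesion_id, true_label=item.label,
                         majority_label=label, class_counts=counts,
                         map=cmap if keep_maps else None))
        vote_pred.append(label)
        vote_true.append(item.label)
    vote_metrics = pixelwise_metrics(vote_pred, vote_true, lesion_classes)

    return CohortReport(
        group=classifier_group,
        class_order=class_order,
        pixel_metrics=pixel_metrics,
        lesion_results=lesion_results,
        vote_metrics=vote_metrics,
        training_log=trained.training_log,
        seed=seed,
    )


# --------------------------------------------------------------------------- #
# report output
# --------------------------------------------------------------------------- #

_MAP_PALETTE = [
    (0, 0, 0),        # no prediction
    (46, 204, 113),   # class 0
    (231, 76, 60),    # class 1
    (52, 152, 219),   # class 2
    (241, 196, 15),   # class 3
    (155, 89, 182),   # class 4
]


def _metrics_frame(report: MetricsReport):
    import pandas as pd

    rows = [dict(label=lab, **vals) for lab, vals in report.per_class.items()]
    rows.append(dict(label="weighted", support=report.n_samples, **report.weighted))
    return pd.DataFrame(rows)


def write_report(report: CohortReport, out_dir) -> None:
    """Metrics and confusion matrices as CSV, votes as JSON, class maps as
    indexed PNG with a colour legend."""
    import pandas as pd
    from PIL import Image

    out = Path(out_dir)
    try:
        out.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise ValueError(f"cannot create report directory {out}: {exc}") from exc

    _metrics_frame(report.pixel_metrics).to_csv(out / "pixel_metrics.csv", index=False)
    _metrics_frame(report.vote_metrics).to_csv(out / "vote_metrics.csv", index=False)
    pd.DataFrame(report.pixel_metrics.confusion,
                 index=report.pixel_metrics.class_order,
                 columns=report.pixel_metrics.class_order).to_csv(out / "pixel_confusion.csv")
    pd.DataFrame(report.vote_metrics.confusion,
                 index=report.vote_metrics.class_order,
                 columns=report.vote_metrics.class_order).to_csv(out / "vote_confusion.csv")

    votes = [
        {
            "lesion_id": r.lesion_id,
            "true_label": r.true_label,
            "majority_label": r.majority_label,
            "class_counts": r.class_counts,
        }
        for r in report.lesion_results
    ]
    (out / "votes.json").write_text(json.dumps(votes, indent=2))

    legend = {"no_prediction": _MAP_PALETTE[0]}
    for i, label in enumerate(report.class_order):
        legend[label] = _MAP_PALETTE[1 + i]
    (out / "map_legend.json").write_text(json.dumps(legend, indent=2))

    for r in report.lesion_results:
        if r.map is None:
            continue
        img = (r.map.class_map + 1).astype(np.uint8)  # 0 = no prediction
        pimg = Image.fromarray(img, mode="P")
        palette = []
        for rgb in _MAP_PALETTE[: len(report.class_order) + 1]:
            palette.extend(rgb)
        pimg.putpalette(palette)
        pimg.save(out / f"map_lesion{r.lesion_id:03d}.png")
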