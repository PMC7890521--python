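"""Fixation ground-truth maps and ROC/AUC scoring of saliency maps.

Ground truth for training and evaluation is built by rasterising recorded
fixation points and convolving with an isotropic 2D Gaussian (truncated at
4 sigma, zero outside the canvas), then dividing by the maximum so values
lie in [0, 1].

Prediction accuracy uses the fixation-ROC convention: pixels containing at
least one fixation are positives, all remaining pixels negatives; the ROC
curve is traced over all unique saliency thresholds and integrated by the
trapezoid rule, which equals the tie-corrected Mann-Whitney statistic — the
probability that a fixated pixel outscores a non-fixated one (0.5 = chance).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage, stats
from sklearn.metrics import roc_auc_score

from .synthetic import FixationRecord

__all__ = [
    "SaliencyMap",
    "FixationMap",
    "make_fixation_map",
    "auc_score",
    "mean_auc",
    "compare_models",
]

TRUNCATE_SIGMAS = 4.0


@dataclass
class SaliencyMap:
    """Single-channel model output map on the canvas, values in [0, 1]."""

    values: np.ndarray
    image_id: int | None = None

    def __post_init__(self):
        v = np.asarray(self.values, dtype=np.float64)
        if v.ndim != 2:
            raise ValueError("saliency map must be 2D (height, width)")
        if not np.all(np.isfinite(v)):
            raise ValueError("saliency map contains non-finite values")
        self.values = v


@dataclass
class FixationMap:
    """Binary fixation raster plus its Gaussian-smoothed ground-truth map."""

    raster: np.ndarray
    smoothed: np.ndarray
    sigma: float


def _rasterize(record: FixationRecord) -> np.ndarray:
    cw, ch = record.canvas_wh
    raster = np.zeros((ch, cw))
    for x, y in record.fixation_points:
        raster[int(y), int(x)] += 1.0
    return raster


def make_fixation_map(record: FixationRecord, sigma: float = 10.0,
                      normalization: str = "max") -> FixationMap:
    """Ground-truth map: fixation raster convolved with a 2D Gaussian.

    The kernel is the sampled separable Gaussian truncated at 4 sigma with
    zero boundary (mass falling outside the canvas is lost, not reflected),
    so outputs are bit-stable across platforms.  ``normalization`` is
    "max" (default; peak value 1, the form used as a training target) or
    "sum" (probability-map normalisation).
    """
    if not record.fixation_points:
        raise ValueError("fixation record has no points")
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    raster = _rasterize(record)
    smoothed = ndimage.gaussian_filter(raster, sigma=sigma, mode="constant",
                                       cval=0.0, truncate=TRUNCATE_SIGMAS)
    if normalization == "max":
        smoothed = smoothed / smoothed.max()
    elif normalization == "sum":
        smoothed = smoothed / smoothed.sum()
    else:
        raise ValueError("normalization must be 'max' or 'sum'")
    return FixationMap(raster=raster, smoothed=smoothed, sigma=float(sigma))


def auc_score(saliency, record: FixationRecord) -> float:
    """ROC AUC of a saliency map against fixated pixels.

    Positives are the pixels containing at least one fixation; negatives
    all other pixels.  Equals the Mann-Whitney probability (ties counted
    1/2) that a fixated pixel receives higher saliency than a non-fixated
    one, and is therefore invariant under strictly monotone transforms of
    the saliency values.
    """
    values = saliency.values if isinstance(saliency, SaliencyMap) else \
        np.asarray(saliency, dtype=np.float64)
    raster = _rasterize(record)
    if values.shape != raster.shape:
        raise ValueError(
            f"saliency shape {values.shape} does not match canvas "
            f"{raster.shape}")
    labels = (raster > 0).ravel()
    n_pos = int(labels.sum())
    if n_pos == 0:
        raise ValueError("no fixated pixel")
    if n_pos == labels.size:
        raise ValueError("all pixels fixated: AUC undefined")
    return float(roc_auc_score(labels, values.ravel()))


def mean_auc(model, dataset) -> dict:
    """Mean AUC (with SEM) of a saliency model over a fixation dataset.

    ``model`` maps an image (H, W, 3) to a saliency map (H, W);
    ``dataset`` is a sequence of (image, FixationRecord).  Returns a dict
    with keys ``mean``, ``sem``, ``per_image`` (DataFrame image_id, auc).
    A single-image dataset reports SEM 0 (flagged in the output).
    """
    dataset = list(dataset)
    if not dataset:
        raise ValueError("empty dataset")
    rows = []
    for image, record in dataset:
        sal = model(image)
        rows.append({"image_id": record.image_id,
                     "auc": auc_score(sal, record)})
    per_image = pd.DataFrame(rows)
    aucs = per_image["auc"].to_numpy()
    m = len(aucs)
    sem = float(aucs.std(ddof=1) / np.sqrt(m)) if m > 1 else 0.0
    return {"mean": float(aucs.mean()), "sem": sem, "n_images": m,
            "sem_defined": m > 1, "per_image": per_image}


def compare_models(auc_tables: dict[str, pd.DataFrame]) -> dict:
    """Descriptive comparison of per-image AUC tables across models.

    ``auc_tables`` maps model name -> DataFrame (image_id, auc) over an
    aligned image set.  Reports mean/SEM per model, pairwise Welch t
    statistics, and a one-way ANOVA F — standard formulas, descriptive
    output only.
    """
    if len(auc_tables) < 2:
        raise ValueError("need >= 2 models to compare")
    names = list(auc_tables)
    ids = [tuple(t["image_id"]) for t in auc_tables.values()]
    if len(set(ids)) != 1:
        raise ValueError("models were scored on different image sets")
    summary = []
    samples = []
    for name in names:
        a = auc_tables[name]["auc"].to_numpy()
        samples.append(a)
        summary.append({"model": name, "mean_auc": float(a.mean()),
                        "sem": float(a.std(ddof=1) / np.sqrt(len(a)))
                        if len(a) > 1 else 0.0, "n_images": len(a)})
    pairs = []
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            t = stats.ttest_ind(samples[i], samples[j], equal_var=False)
            pairs.append({"model_a": names[i], "model_b": names[j],
                          "t": float(t.statistic), "p": float(t.pvalue)})
    anova = stats.f_oneway(*samples)
    return {"summary": pd.DataFrame(summary),
            "pairwise": pd.DataFrame(pairs),
            "anova_F": float(anova.statistic),
            "anova_p": float(anova.pvalue)}
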