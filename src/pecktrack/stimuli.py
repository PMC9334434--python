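"""Stimulus pre-screen: pixelwise-correlation selection of exemplars.

Before training, candidate stimulus renders (e.g. 50 per class of
evolved "digital embryo" objects) are screened so the two classes are
maximally distinguishable: each candidate is scored by the mean Pearson
correlation of its pixel vector with every member of the *other* class,
and the n least cross-class-correlated exemplars per class are kept
(30 per class at the defaults). A confound check then verifies that the
selected classes cannot be told apart by object size (count of
above-threshold pixels) or by the amount of surrounding dark background.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

DEFAULT_BLACK_THRESHOLD = 10  # of 255; renders have near-black backgrounds


@dataclass(frozen=True)
class StimulusImage:
    """One grayscale candidate render with its class label."""

    id: str
    class_label: str
    pixels: np.ndarray  # H x W, intensities 0-255

    def __post_init__(self) -> None:
        if np.asarray(self.pixels).ndim != 2:
            raise ValueError("pixels must be a 2-D grayscale matrix")


@dataclass(frozen=True)
class ConfoundStats:
    """Between-class t-tests on object size and background black area."""

    object_pixels: dict  # id -> count of pixels > threshold
    black_pixels: dict  # id -> count of pixels <= threshold
    t_object: float
    p_object: float
    t_black: float
    p_black: float
    black_threshold: int


@dataclass(frozen=True)
class SelectionReport:
    scores: pd.DataFrame  # columns: id, class_label, mean_cross_correlation, selected
    selected_a: tuple[str, ...]
    selected_b: tuple[str, ...]
    confound: ConfoundStats


def load_image(path: str | Path, class_label: str, id: Optional[str] = None) -> StimulusImage:
    """Load a PNG/PGM image as a grayscale stimulus."""
    from PIL import Image

    path = Path(path)
    with Image.open(path) as im:
        pixels = np.asarray(im.convert("L"), dtype=float)
    return StimulusImage(id=id or path.stem, class_label=class_label, pixels=pixels)


def pixelwise_correlation(a: StimulusImage, b: StimulusImage) -> float:
    """Pearson correlation between two images' flattened pixel vectors."""
    pa = np.asarray(a.pixels, dtype=float).ravel()
    pb = np.asarray(b.pixels, dtype=float).ravel()
    if a.pixels.shape != b.pixels.shape:
        raise ValueError(
            f"image dimensions differ: {a.pixels.shape} vs {b.pixels.shape}"
        )
    if pa.std() == 0 or pb.std() == 0:
        raise ValueError("constant image: pixelwise correlation undefined")
    return float(np.corrcoef(pa, pb)[0, 1])


def _cross_scores(own: Sequence[StimulusImage], other: Sequence[StimulusImage]) -> dict:
    """id -> mean correlation with every member of the other class."""
    other_mat = np.stack([np.asarray(im.pixels, dtype=float).ravel() for im in other])
    other_mat = (other_mat - other_mat.mean(axis=1, keepdims=True)) / other_mat.std(
        axis=1, keepdims=True
    )
    scores = {}
    for im in own:
        v = np.asarray(im.pixels, dtype=float).ravel()
        sd = v.std()
        if sd == 0:
            raise ValueError(f"constant image {im.id!r}")
        v = (v - v.mean()) / sd
        scores[im.id] = float(np.mean(other_mat @ v) / v.size)
    return scores


def confound_check(
    selected: Sequence[StimulusImage],
    black_threshold: int = DEFAULT_BLACK_THRESHOLD,
) -> ConfoundStats:
    """Check that the selected classes differ in neither object size nor
    surrounding black area (two-sample t-tests between classes)."""
    labels = sorted({im.class_label for im in selected})
    if len(labels) < 2:
        raise ValueError("confound check needs stimuli from both classes")
    obj = {im.id: int(np.sum(np.asarray(im.pixels) > black_threshold)) for im in selected}
    blk = {im.id: int(np.sum(np.asarray(im.pixels) <= black_threshold)) for im in selected}
    by_class = {
        lab: [im.id for im in selected if im.class_label == lab] for lab in labels
    }
    a, b = labels[0], labels[1]
    t_obj, p_obj = sps.ttest_ind(
        [obj[i] for i in by_class[a]], [obj[i] for i in by_class[b]]
    )
    t_blk, p_blk = sps.ttest_ind(
        [blk[i] for i in by_class[a]], [blk[i] for i in by_class[b]]
    )

    def _nan0(v: float) -> float:  # identical groups give nan; report t = 0
        return 0.0 if np.isnan(v) else float(v)

    return ConfoundStats(
        object_pixels=obj,
        black_pixels=blk,
        t_object=_nan0(t_obj),
        p_object=1.0 if np.isnan(p_obj) else float(p_obj),
        t_black=_nan0(t_blk),
        p_black=1.0 if np.isnan(p_blk) else float(p_blk),
        black_threshold=black_threshold,
    )


def select_stimuli(
    class_a: Sequence[StimulusImage],
    class_b: Sequence[StimulusImage],
    n_select: int = 30,
    black_threshold: int = DEFAULT_BLACK_THRESHOLD,
) -> SelectionReport:
    """Keep the n least cross-class-correlated exemplars per class.

    Every candidate is scored by the mean Pearson correlation of its
    pixels with all members of the other class; per class the
    ``n_select`` lowest-scoring candidates are kept (ties broken by id).
    The confound check runs on the selected set.
    """
    if len(class_a) < n_select or len(class_b) < n_select:
        raise ValueError(
            f"need at least {n_select} candidates per class, got "
            f"{len(class_a)} and {len(class_b)}"
        )
    shapes = {im.pixels.shape for im in list(class_a) + list(class_b)}
    if len(shapes) > 1:
        raise ValueError(f"all images must share dimensions, found {shapes}")

    scores_a = _cross_scores(class_a, class_b)
    scores_b = _cross_scores(class_b, class_a)

    def _pick(images: Sequence[StimulusImage], scores: dict) -> list[str]:
        ranked = sorted(images, key=lambda im: (scores[im.id], im.id))
        return [im.id for im in ranked[:n_select]]

    sel_a = _pick(class_a, scores_a)
    sel_b = _pick(class_b, scores_b)
    selected_set = set(sel_a) | set(sel_b)

    rows = [
        {
            "id": im.id,
            "class_label": im.class_label,
            "mean_cross_correlation": scores[im.id],
            "selected": im.id in selected_set,
        }
        for images, scores in ((class_a, scores_a), (class_b, scores_b))
        for im in images
    ]
    scores_df = pd.DataFrame(rows).sort_values(
        ["class_label", "mean_cross_correlation", "id"]
    ).reset_index(drop=True)

    selected_imgs = [im for im in list(class_a) + list(class_b) if im.id in selected_set]
    confound = confound_check(selected_imgs, black_threshold=black_threshold)
    return SelectionReport(
        scores=scores_df,
        selected_a=tuple(sel_a),
        selected_b=tuple(sel_b),
        confound=confound,
    )


def synthetic_stimulus_set(
    n_per_class: int = 50,
    shape: tuple[int, int] = (48, 48),
    noise_sd: float = 20.0,
    seed: int = 0,
) -> tuple[list[StimulusImage], list[StimulusImage]]:
    """Synthetic stand-in for a rendered stimulus set (no real renders).

    Each class derives from a template blob at a class-specific location
    on a near-black background; candidates are the template plus
    per-candidate Gaussian pixel noise, clipped to [0, 255]. Useful for
    exercising the selection pipeline end to end.
    """
    rng = np.random.default_rng(seed)
    h, w = shape
    yy, xx = np.mgrid[0:h, 0:w]

    def _template(cx: float, cy: float, sx: float, sy: float) -> np.ndarray:
        blob = 220.0 * np.exp(
            -(((xx - cx) / sx) ** 2 + ((yy - cy) / sy) ** 2)
        )
        return blob

    t_a = _template(w * 0.35, h * 0.45, w * 0.12, h * 0.20)
    t_b = _template(w * 0.65, h * 0.55, w * 0.20, h * 0.12)

    def _make(template: np.ndarray, label: str) -> list[StimulusImage]:
        out = []
        for i in range(n_per_class):
            noisy = np.clip(template + rng.normal(0, noise_sd, size=shape), 0, 255)
            out.append(
                StimulusImage(id=f"{label}{i + 1:02d}", class_label=label, pixels=noisy)
            )
        return out

    return _make(t_a, "X"), _make(t_b, "Y")
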