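"""Grad-CAM saliency and channel-pair attribution.

Grad-CAM weights the final convolutional layer's feature maps by the
spatially averaged gradient of a class logit, sums, rectifies, and
upsamples the result to the input size as a saliency heatmap.  Because the
input image is a channel-wise correlation matrix with a block structure —
the (i, j) block of n_scales x n_scales entries holds the correlations
between channels i and j — averaging the heatmap over each block and
symmetrising yields a score per EEG channel pair, turning pixel saliency
into a statement like "the correlation between Fp2 and P4 drove this
prediction".
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from skimage.transform import resize

from . import nn
from .cwt import CorrelationMatrix


@dataclass
class Heatmap:
    """A [0, 1] saliency map at the model's input resolution."""

    values: np.ndarray
    target_class: int
    source_epoch: str = ""


@dataclass
class PairAttribution:
    """Symmetrised per-channel-pair saliency scores with a ranking.

    ``scores`` covers all C*(C+1)/2 unordered pairs including self-pairs;
    ``ranking`` sorts pairs by descending score, ties broken by channel
    index order.  ``cross_ranking`` restricts the ranking to pairs of
    distinct channels — the reading used when interpreting heatmaps as
    inter-channel correlations, since a channel's own scale-scale block
    (the diagonal) often carries strong within-channel saliency.
    """

    scores: dict[tuple[str, str], float]
    ranking: list[tuple[str, str]]

    @property
    def cross_ranking(self) -> list[tuple[str, str]]:
        return [p for p in self.ranking if p[0] != p[1]]


@dataclass
class SubjectExplanation:
    """Per-epoch attributions plus a consensus over a subject's epochs."""

    attributions: list[PairAttribution]
    consensus_scores: dict[tuple[str, str], float]  # mean rank, lower = better
    ranking: list[tuple[str, str]]

    @property
    def cross_ranking(self) -> list[tuple[str, str]]:
        return [p for p in self.ranking if p[0] != p[1]]


def _resolve_network(model) -> nn.Network:
    if isinstance(model, nn.Network):
        return model
    network = getattr(model, "network_", None)
    if network is None:
        raise ValueError("model must be a Network or a fitted classifier")
    return network


def gradcam(model, image: np.ndarray | CorrelationMatrix, target_class: int,
            upsample: str = "bilinear", target: str = "probability") -> Heatmap:
    """Grad-CAM heatmap of ``target_class`` on the final convolutional layer.

    Channel weights are the spatially averaged gradients of the target
    class score with respect to the final conv feature maps; the weighted
    sum is rectified, upsampled to the input size (bilinear by default)
    and min-max normalised to [0, 1].  An everywhere-zero rectified map is
    returned as all zeros with a warning.

    ``target`` selects the class score differentiated: ``"probability"``
    (default) uses the softmax output, whose gradient is contrastive —
    evidence shared by several classes cancels, which sharpens class-
    specific localisation; ``"logit"`` uses the pre-softmax activation.
    """
    network = _resolve_network(model)
    if isinstance(image, CorrelationMatrix):
        image = image.R
    image = np.asarray(image, dtype=np.float32)
    if image.ndim != 2:
        raise ValueError("image must be a single 2-D correlation matrix")
    conv_idx = network.last_conv_index()
    n_out = network.layers[-1].units

    probs = network.forward(image[None], training=False)
    if not 0 <= target_class < n_out:
        raise ValueError(f"target_class {target_class} outside [0, {n_out})")
    if target == "logit":
        seed = np.zeros_like(probs)
        seed[0, target_class] = 1.0  # d(logit_c)/d(logits)
    elif target == "probability":
        # d(softmax_c)/d(logits) = p_c * (e_c - p)
        p = probs[0]
        onehot = np.zeros_like(p)
        onehot[target_class] = 1.0
        seed = (p[target_class] * (onehot - p))[None]
    else:
        raise ValueError("target must be 'probability' or 'logit'")
    grads = network.backward(seed)

    activations = network.layers[conv_idx].output[0]     # (h, w, c)
    d_activations = grads[conv_idx][0]                   # (h, w, c)
    channel_weights = d_activations.mean(axis=(0, 1))
    cam = np.maximum((activations * channel_weights).sum(axis=-1), 0.0)

    order = 1 if upsample == "bilinear" else 0
    cam = resize(cam, image.shape, order=order, mode="edge",
                 anti_aliasing=False, preserve_range=True)
    peak = cam.max()
    if peak <= 0:
        warnings.warn("Grad-CAM map is all zero after rectification")
        return Heatmap(np.zeros_like(cam), target_class)
    return Heatmap(cam / peak, target_class)


def pair_attribution(heatmap: Heatmap | np.ndarray, montage: Sequence[str],
                     n_scales: int, method: str = "mean") -> PairAttribution:
    """Aggregate a heatmap into per-channel-pair scores via its block grid.

    The score of pair (i, j) is the mean (or max) of the heatmap over the
    n_scales x n_scales block at rows [i*n, (i+1)*n) x cols [j*n, (j+1)*n),
    averaged with the transposed block (j, i).  Ranking is by descending
    score with lexicographic channel-index tie-breaks.
    """
    values = heatmap.values if isinstance(heatmap, Heatmap) else np.asarray(heatmap)
    montage = tuple(montage)
    c = len(montage)
    if values.shape != (c * n_scales, c * n_scales):
        raise ValueError(
            f"heatmap shape {values.shape} does not match "
            f"{c} channels x {n_scales} scales"
        )
    reducer = {"mean": np.mean, "max": np.max}[method]
    blocks = np.empty((c, c))
    for i in range(c):
        for j in range(c):
            blocks[i, j] = reducer(
                values[i * n_scales : (i + 1) * n_scales,
                       j * n_scales : (j + 1) * n_scales]
            )
    scores: dict[tuple[str, str], float] = {}
    for i in range(c):
        for j in range(i, c):
            scores[(montage[i], montage[j])] = float((blocks[i, j] + blocks[j, i]) / 2)
    pairs = [(i, j) for i in range(c) for j in range(i, c)]
    pairs.sort(key=lambda p: (-scores[(montage[p[0]], montage[p[1]])], p[0], p[1]))
    ranking = [(montage[i], montage[j]) for i, j in pairs]
    return PairAttribution(scores, ranking)


def explain_subject(model, images: Sequence[np.ndarray | CorrelationMatrix],
                    target_class: int, montage: Sequence[str], n_scales: int,
                    method: str = "mean", target: str = "probability",
                    rank_aggregation: str = "mean") -> SubjectExplanation:
    """Grad-CAM every epoch of one subject and build a consensus ranking.

    The consensus score of a pair is its mean (default) or median rank
    (0-based) across the per-epoch attributions; the consensus ranking
    sorts pairs by ascending consensus rank with lexicographic
    tie-breaks, so structure that is salient consistently across segments
    rises to the top.

    ``model`` may also be a sequence of trained networks (an ensemble of
    initialisations); ranks are then aggregated over every (model, epoch)
    combination.  With three or more members, ``rank_aggregation=
    "median"`` makes the consensus robust to one member whose learned
    features mislocalise a class.
    """
    if len(images) == 0:
        raise ValueError("need at least one epoch to explain")
    models = model if isinstance(model, (list, tuple)) else [model]
    if len(models) == 0:
        raise ValueError("need at least one model to explain")
    if rank_aggregation not in ("mean", "median"):
        raise ValueError("rank_aggregation must be 'mean' or 'median'")
    attributions = [
        pair_attribution(gradcam(m, img, target_class, target=target),
                         montage, n_scales, method)
        for m in models
        for img in images
    ]
    montage = tuple(montage)
    all_pairs = attributions[0].ranking
    ranks = {pair: [] for pair in all_pairs}
    for attr in attributions:
        for rank, pair in enumerate(attr.ranking):
            ranks[pair].append(rank)
    reduce = np.mean if rank_aggregation == "mean" else np.median
    consensus = {pair: float(reduce(ranks[pair])) for pair in all_pairs}
    index = {ch: i for i, ch in enumerate(montage)}
    ordered = sorted(all_pairs,
                     key=lambda p: (consensus[p], index[p[0]], index[p[1]]))
    return SubjectExplanation(attributions, consensus, ordered)


def render_heatmap(heatmap: Heatmap | np.ndarray, montage: Sequence[str],
                   n_scales: int, path=None, ax=None, cmap: str = "jet"):
    """Plot a heatmap with channel-boundary gridlines and montage labels.

    Returns the matplotlib Axes; saves a PNG when ``path`` is given.
    """
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    values = heatmap.values if isinstance(heatmap, Heatmap) else np.asarray(heatmap)
    montage = tuple(montage)
    created = ax is None
    if created:
        _, ax = plt.subplots(figsize=(6, 5))
    im = ax.imshow(values, cmap=cmap, vmin=0, vmax=1, interpolation="nearest")
    side = len(montage) * n_scales
    for b in range(n_scales, side, n_scales):
        ax.axhline(b - 0.5, color="white", lw=0.5, alpha=0.6)
        ax.axvline(b - 0.5, color="white", lw=0.5, alpha=0.6)
    centers = [i * n_scales + n_scales / 2 for i in range(len(montage))]
    ax.set_xticks(centers, montage, rotation=90, fontsize=7)
    ax.set_yticks(centers, montage, fontsize=7)
    ax.figure.colorbar(im, ax=ax, fraction=0.046)
    if path is not None:
        ax.figure.savefig(path, dpi=150, bbox_inches="tight")
        if created:
            plt.close(ax.figure)
    return ax
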