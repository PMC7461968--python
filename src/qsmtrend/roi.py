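"""ROI susceptibility statistics emulating a manual tracing protocol.

Per nucleus, the protocol pools the bilateral labels, selects the
contiguous axial slices on which the structure is largest (the manual
analogue: slices where the border is well defined), and reports the
mean and population STD of the susceptibility over those voxels,
restricted to the reconstruction mask.  Optional tracing jitter
replicates the repeated manual drawing of each ROI: every replicate
randomly erodes or dilates the ROI by a stated number of voxels and
the replicate means are averaged.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .phantom import LabelVolume

__all__ = ["ROIProtocol", "ROIStats", "extract_roi_stats"]


@dataclass(frozen=True)
class ROIProtocol:
    """Slice count, replicate count and tracing jitter of the ROI protocol."""

    n_slices: int = 3
    n_replicates: int = 5
    jitter: int = 0  # morphological perturbation, voxels; 0 = no jitter
    axial_axis: int = 2

    def __post_init__(self) -> None:
        if self.n_slices < 1:
            raise ValueError("n_slices must be >= 1")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if self.jitter < 0:
            raise ValueError("jitter must be >= 0")


@dataclass
class ROIStats:
    """Mean +/- STD susceptibility of one nucleus over the sampled slices."""

    nucleus: str
    mean_chi: float
    std_chi: float
    n_voxels: int
    slices_used: tuple[int, ...]
    missing: bool = False


def _select_slices(roi: np.ndarray, axis: int, n_slices: int) -> tuple[int, ...]:
    """Contiguous ``n_slices`` window maximizing in-slice ROI area.

    Ties break toward the window centered nearest the ROI centroid.
    """
    other = tuple(a for a in range(roi.ndim) if a != axis)
    counts = roi.sum(axis=other)
    present = np.flatnonzero(counts)
    lo, hi = present[0], present[-1]
    coords = np.nonzero(roi)
    centroid = float(np.mean(coords[axis]))
    n = min(n_slices, hi - lo + 1)
    starts = np.arange(lo, hi - n + 2)
    window_counts = np.array([counts[s : s + n].sum() for s in starts])
    centers = starts + (n - 1) / 2.0
    order = np.lexsort((np.abs(centers - centroid), -window_counts))
    best = starts[order[0]]
    return tuple(range(best, best + n))


def _jittered_roi(roi: np.ndarray, jitter: int, rng: np.random.Generator) -> np.ndarray:
    if jitter == 0:
        return roi
    grow = bool(rng.integers(0, 2))
    if grow:
        return ndimage.binary_dilation(roi, iterations=jitter)
    shrunk = ndimage.binary_erosion(roi, iterations=jitter)
    return shrunk if shrunk.any() else roi


def extract_roi_stats(
    chi,
    labels: LabelVolume,
    protocol: ROIProtocol | None = None,
    rng_seed: int = 0,
) -> list[ROIStats]:
    """Per-nucleus mean/STD susceptibility under the slice-sampling protocol.

    ``chi`` is any volume with ``data`` and ``mask`` attributes (a
    reconstructed map or a ground-truth susceptibility volume).
    Bilateral labels sharing a legend name are pooled before slice
    selection.  A nucleus with no voxels surviving the mask is reported
    with ``missing=True`` rather than dropped.  With jitter = 0 and a
    single replicate the result is the plain masked mean and population
    STD over the selected slices.
    """
    protocol = protocol or ROIProtocol()
    data = np.asarray(chi.data, dtype=np.float64)
    mask = chi.mask.astype(bool)
    lab = labels.data
    if lab.shape != data.shape:
        raise ValueError("label volume does not match the susceptibility grid")
    rng = np.random.default_rng(np.random.SeedSequence([int(rng_seed), 11]))

    names = sorted(set(labels.legend.values()), key=list(labels.legend.values()).index)
    out: list[ROIStats] = []
    for name in names:
        label_ids = [k for k, v in labels.legend.items() if v == name]
        pooled = np.isin(lab, label_ids) & mask
        if not pooled.any():
            out.append(ROIStats(name, float("nan"), float("nan"), 0, (), missing=True))
            continue
        slices = _select_slices(pooled, protocol.axial_axis, protocol.n_slices)
        slab = np.zeros_like(pooled)
        idx = [slice(None)] * 3
        idx[protocol.axial_axis] = list(slices)
        slab[tuple(idx)] = True
        roi = pooled & slab

        means, stds, counts = [], [], []
        for _ in range(protocol.n_replicates):
            rep = _jittered_roi(roi, protocol.jitter, rng) & mask
            if not rep.any():
                continue
            vals = data[rep]
            means.append(vals.mean())
            stds.append(vals.std())  # population STD (divisor N)
            counts.append(vals.size)
        if not means:
            out.append(ROIStats(name, float("nan"), float("nan"), 0, slices, missing=True))
            continue
        out.append(
            ROIStats(
                nucleus=name,
                mean_chi=float(np.mean(means)),
                std_chi=float(np.mean(stds)),
                n_voxels=int(np.round(np.mean(counts))),
                slices_used=slices,
            )
        )
    return out
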