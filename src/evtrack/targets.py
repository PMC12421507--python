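"""Training targets of the dual-branch network.

From an instance label image two per-pixel targets are derived:

* a regression target — the Euclidean distance transform computed per
  instance and normalized by that instance's maximum, so every instance peaks
  at 1 regardless of size (cells and EV puncta differ by two orders of
  magnitude in area, and the network is trained on one aggregated channel);
* a classification target over three classes: 0 background, 1 interior,
  2 border.  Border pixels are instance pixels within ``border_width`` of the
  instance boundary or 8-adjacent to a different instance.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

BACKGROUND, INTERIOR, BORDER = 0, 1, 2


def _instance_slices(labels: np.ndarray):
    labels = np.asarray(labels)
    if labels.ndim != 2:
        raise ValueError("label image must be 2-D")
    if labels.size and labels.min() < 0:
        raise ValueError("labels must be non-negative integers")
    for lab, sl in enumerate(ndimage.find_objects(labels), start=1):
        if sl is None:
            continue
        # expand by 1 px (clipped at the image edge) so the zero ring around
        # the bounding box stands in for the full complement
        r, c = sl
        r = slice(max(r.start - 1, 0), min(r.stop + 1, labels.shape[0]))
        c = slice(max(c.start - 1, 0), min(c.stop + 1, labels.shape[1]))
        yield lab, (r, c)


def distance_target(labels: np.ndarray) -> np.ndarray:
    """Per-instance max-normalized Euclidean distance map in [0, 1].

    For each instance independently: distance of each instance pixel to the
    instance's complement (anything that is not this instance, other
    instances included), divided by the instance's maximum distance.
    Background is exactly 0.
    """
    labels = np.asarray(labels)
    out = np.zeros(labels.shape, dtype=np.float64)
    for lab, sl in _instance_slices(labels):
        mask = labels[sl] == lab
        d = ndimage.distance_transform_edt(mask)
        m = d.max()
        if m > 0:
            np.copyto(out[sl], d / m, where=mask)
    return out


def border_target(labels: np.ndarray, border_width: int = 2) -> np.ndarray:
    """Three-class map: 0 background, 1 interior, 2 border.

    An instance pixel is border when its Euclidean distance to the instance's
    complement is <= ``border_width`` (pixels adjacent to background have
    distance 1) or when it is 8-adjacent to a pixel of a different instance.
    """
    if border_width < 1:
        raise ValueError("border_width must be >= 1")
    labels = np.asarray(labels)
    out = np.zeros(labels.shape, dtype=np.uint8)
    struct8 = ndimage.generate_binary_structure(2, 2)
    for lab, sl in _instance_slices(labels):
        mask = labels[sl] == lab
        d = ndimage.distance_transform_edt(mask)
        border = mask & (d <= border_width)
        other = (labels[sl] != lab) & (labels[sl] > 0)
        if other.any():
            border |= mask & ndimage.binary_dilation(other, structure=struct8)
        region = out[sl]
        region[mask] = INTERIOR
        region[border] = BORDER
    return out
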