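"""Transverse-pelvic-angle (TPA) label schemes.

TPA is 0° supine, negative when lying on the left side and positive on the
right. Classification happens at two granularities: a coarse three-class
label (left / supine / right) and, within each side, equal-width bins over
absolute angles 22.5°–112.5° at 45°, 30° or 15° precision. Angles beyond
112.5° from supine are out of range for the fine schemes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

SUPINE_HALF_WIDTH = 22.5
SIDE_MAX = 112.5

OUT_OF_RANGE = "out_of_range"

#: precision label -> per-side ascending bin edges (absolute degrees)
_SCHEME_EDGES = {
    "bins45": (22.5, 67.5, 112.5),
    "bins30": (22.5, 52.5, 82.5, 112.5),
    "bins15": (22.5, 37.5, 52.5, 67.5, 82.5, 97.5, 112.5),
}


@dataclass(frozen=True)
class BinScheme:
    """Equal-width binning of one side's absolute TPA range."""

    precision: str
    edges: tuple[float, ...] = field(default=())

    def __post_init__(self) -> None:
        if self.precision not in _SCHEME_EDGES:
            raise ValueError(
                f"unknown precision {self.precision!r}; "
                f"expected one of {sorted(_SCHEME_EDGES)}"
            )
        if not self.edges:
            object.__setattr__(self, "edges", _SCHEME_EDGES[self.precision])

    @property
    def n_bins(self) -> int:
        return len(self.edges) - 1

    @property
    def bin_width(self) -> float:
        return self.edges[1] - self.edges[0]


def scheme_edges(precision: str) -> BinScheme:
    """Return the ``BinScheme`` for ``'bins45'``, ``'bins30'`` or ``'bins15'``."""
    return BinScheme(precision)


def coarse_label(tpa: float) -> str:
    """Coarse posture class for one TPA in degrees.

    Supine is the open interval (−22.5°, +22.5°); the boundaries belong to
    the sides, so +22.5° is ``'right'`` and −22.5° is ``'left'``.
    """
    if abs(tpa) > 180.0:
        raise ValueError(f"TPA {tpa} outside (-180, 180]")
    if -SUPINE_HALF_WIDTH < tpa < SUPINE_HALF_WIDTH:
        return "supine"
    return "right" if tpa > 0 else "left"


def coarse_labels(tpa: np.ndarray) -> np.ndarray:
    """Vectorized :func:`coarse_label`."""
    tpa = np.asarray(tpa, dtype=float)
    out = np.where(tpa > 0, "right", "left").astype(object)
    out[np.abs(tpa) < SUPINE_HALF_WIDTH] = "supine"
    return out.astype(str)


def side_bin_label(tpa: float, scheme: BinScheme) -> str:
    """Bin identifier like ``'right_1'`` for a side-lying TPA, or ``'out_of_range'``.

    Bins are half-open [low, high) on |TPA|, with 112.5° folded into the
    outermost bin. Supine input is a caller error: the supine class has a
    fixed width and is never refined.
    """
    if coarse_label(tpa) == "supine":
        raise ValueError(f"supine TPA {tpa} has no side bin")
    mag = abs(tpa)
    if mag > SIDE_MAX:
        return OUT_OF_RANGE
    side = "right" if tpa > 0 else "left"
    idx = int(np.searchsorted(scheme.edges, mag, side="right")) - 1
    idx = min(idx, scheme.n_bins - 1)  # fold 112.5 into the last bin
    return f"{side}_{idx}"


def side_bin_labels(tpa: np.ndarray, scheme: BinScheme) -> np.ndarray:
    """Vectorized :func:`side_bin_label` (raises if any input is supine)."""
    return np.array([side_bin_label(t, scheme) for t in np.asarray(tpa, float)])
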