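"""Pay-off landscape generation.

A landscape is a grid of "solutions", each carrying a fixed integer pay-off.
It is built by superimposing ``n_peaks`` single-peak sub-landscapes: every
sub-landscape is a zero matrix with one uniformly placed impulse of height
``z**2`` (``z ~ N(0, 1)``), smoothed with an isotropic Gaussian filter of
standard deviation 1.  The sub-landscapes are merged by taking the cell-wise
maximum, and the merged surface is linearly rescaled to ``[0, scale_max]``
(``scale_max`` a uniform integer in ``{30, ..., 80}``) and rounded to
integers.  Few peaks (``n_peaks = 32``) give a "poor" landscape with isolated
pay-off islands; many peaks (``n_peaks = 512``) give a "rich" one with a
dense, bumpy surface.

One-dimensional landscapes are a uniformly chosen row of a freshly generated
two-dimensional landscape of the same kind.

Coordinates are 1-based ``(row, col)`` throughout, so the centre of a 63x63
grid is ``(32, 32)``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.ndimage import gaussian_filter

__all__ = [
    "Landscape",
    "generate_sublandscape",
    "generate_landscape",
    "generate_1d_landscape",
    "normalize_payoff",
    "save_landscape",
    "load_landscape",
    "POOR_N_PEAKS",
    "RICH_N_PEAKS",
]

POOR_N_PEAKS = 32
RICH_N_PEAKS = 512

#: Gaussian smoothing width (grid cells) applied to every sub-landscape peak.
FILTER_SIGMA = 1.0
#: Truncation radius of the filter in standard deviations (scipy default).
FILTER_TRUNCATE = 4.0

#: Bounds (inclusive) of the uniform integer draw for the scaling maximum.
SCALE_MAX_RANGE = (30, 80)


class DimensionError(ValueError):
    """Raised for grids too small to host a smoothed peak."""


@dataclass
class Landscape:
    """An integer pay-off grid plus its generation metadata.

    Attributes
    ----------
    payoffs : np.ndarray
        Integer matrix of pay-offs, shape ``(rows, cols)``, values in
        ``[0, scale_max]``.
    n_peaks : int
        Number of sub-landscapes merged into this landscape.
    scale_max : int
        Target of the linear rescaling; equals ``payoffs.max()`` unless the
        landscape is degenerate (all peak heights zero).
    kind : str
        ``"poor"`` (n_peaks=32), ``"rich"`` (n_peaks=512) or ``"custom"``.
    seed : int or None
        Seed the landscape was generated from, if known.
    source_row : int or None
        For 1-D landscapes: the 1-based row index of the 2-D parent this
        vector was extracted from.
    """

    payoffs: np.ndarray
    n_peaks: int
    scale_max: int
    kind: str = "custom"
    seed: int | None = None
    source_row: int | None = field(default=None)

    @property
    def dims(self) -> tuple[int, int]:
        return self.payoffs.shape  # type: ignore[return-value]

    @property
    def max_payoff(self) -> int:
        return int(self.payoffs.max())

    def payoff_at(self, position: tuple[int, int]) -> int:
        """Pay-off at a 1-based ``(row, col)`` position."""
        r, c = position
        return int(self.payoffs[r - 1, c - 1])

    def __post_init__(self) -> None:
        self.payoffs = np.asarray(self.payoffs)
        if self.payoffs.ndim != 2:
            raise DimensionError("payoffs must be a 2-D matrix (1-D landscapes are 1 x N)")


def _kind_for(n_peaks: int) -> str:
    if n_peaks == POOR_N_PEAKS:
        return "poor"
    if n_peaks == RICH_N_PEAKS:
        return "rich"
    return "custom"


def n_peaks_for_kind(kind: str) -> int:
    """Preset peak count for a named landscape kind."""
    presets = {"poor": POOR_N_PEAKS, "rich": RICH_N_PEAKS}
    try:
        return presets[kind]
    except KeyError:
        raise ValueError(f"unknown landscape kind {kind!r}; expected 'poor' or 'rich'") from None


def generate_sublandscape(
    dims: tuple[int, int], rng: np.random.Generator
) -> np.ndarray:
    """Generate one single-peak sub-landscape as a real-valued matrix.

    The matrix is zero except for one uniformly chosen cell holding ``z**2``
    with ``z ~ N(0, 1)``; an isotropic Gaussian filter (sigma=1, zero-padded
    boundaries) then spreads the impulse into a smooth local gradient.
    """
    rows, cols = dims
    if rows < 3 or cols < 3:
        raise DimensionError(f"dims must be at least 3 x 3, got {dims}")
    m = np.zeros((rows, cols), dtype=float)
    r = rng.integers(rows)
    c = rng.integers(cols)
    m[r, c] = rng.normal() ** 2
    return gaussian_filter(m, sigma=FILTER_SIGMA, mode="constant", truncate=FILTER_TRUNCATE)


def _gaussian_patch() -> np.ndarray:
    """Filtered unit impulse: the separable sigma=1 kernel as a square patch."""
    radius = int(FILTER_TRUNCATE * FILTER_SIGMA + 0.5)
    x = np.arange(-radius, radius + 1, dtype=float)
    g = np.exp(-(x**2) / (2.0 * FILTER_SIGMA**2))
    g /= g.sum()
    return np.outer(g, g)


_PATCH = _gaussian_patch()
_PATCH_RADIUS = _PATCH.shape[0] // 2


def _merged_surface(
    dims: tuple[int, int],
    peaks: list[tuple[int, int, float]],
) -> np.ndarray:
    """Cell-wise maximum over single-impulse filtered sub-landscapes.

    Each filtered sub-landscape is the impulse height times the shifted
    filter kernel (zero-padded boundary), so the merge only needs to stamp
    a small kernel patch per peak and keep the running maximum.
    """
    rows, cols = dims
    out = np.zeros((rows, cols), dtype=float)
    rad = _PATCH_RADIUS
    for r, c, h in peaks:
        r0, r1 = max(r - rad, 0), min(r + rad + 1, rows)
        c0, c1 = max(c - rad, 0), min(c + rad + 1, cols)
        patch = _PATCH[r0 - r + rad : r1 - r + rad, c0 - c + rad : c1 - c + rad]
        np.maximum(out[r0:r1, c0:c1], h * patch, out=out[r0:r1, c0:c1])
    return out


def generate_landscape(
    dims: tuple[int, int],
    n_peaks: int,
    rng: np.random.Generator,
    *,
    seed: int | None = None,
) -> Landscape:
    """Generate a landscape by merging ``n_peaks`` sub-landscapes.

    The merged surface is linearly rescaled so its minimum maps to 0 and its
    maximum to ``scale_max`` (uniform integer in 30..80), then rounded to the
    nearest integer.  Scaling precedes rounding so the grid stays integral
    with an exact maximum of ``scale_max``.
    """
    rows, cols = dims
    if rows < 3 or cols < 3:
        raise DimensionError(f"dims must be at least 3 x 3, got {dims}")
    if n_peaks < 1:
        raise ValueError(f"n_peaks must be >= 1, got {n_peaks}")
    peaks = [
        (int(rng.integers(rows)), int(rng.integers(cols)), float(rng.normal() ** 2))
        for _ in range(n_peaks)
    ]
    surface = _merged_surface(dims, peaks)
    scale_max = int(rng.integers(SCALE_MAX_RANGE[0], SCALE_MAX_RANGE[1] + 1))
    lo, hi = surface.min(), surface.max()
    if hi > lo:
        payoffs = np.rint((surface - lo) / (hi - lo) * scale_max).astype(int)
    else:  # all peak heights zero: degenerate flat landscape
        payoffs = np.zeros_like(surface, dtype=int)
    return Landscape(
        payoffs=payoffs,
        n_peaks=n_peaks,
        scale_max=scale_max,
        kind=_kind_for(n_peaks),
        seed=seed,
    )


def generate_1d_landscape(
    n_peaks: int,
    rng: np.random.Generator,
    *,
    dims: tuple[int, int] = (63, 63),
    seed: int | None = None,
) -> Landscape:
    """Generate a 1 x cols landscape as a random row of a fresh 2-D landscape."""
    parent = generate_landscape(dims, n_peaks, rng, seed=seed)
    row = int(rng.integers(dims[0]))
    return Landscape(
        payoffs=parent.payoffs[row : row + 1, :].copy(),
        n_peaks=n_peaks,
        scale_max=parent.scale_max,
        kind=parent.kind,
        seed=seed,
        source_row=row + 1,
    )


def normalize_payoff(landscape: Landscape, payoff: float) -> float:
    """Pay-off divided by the highest pay-off of the landscape."""
    m = landscape.max_payoff
    if m <= 0:
        raise ZeroDivisionError("normalized pay-off is undefined on an all-zero landscape")
    return payoff / m


# ---------------------------------------------------------------------------
# Serialization: plain CSV matrix plus a JSON sidecar with the metadata.

def save_landscape(landscape: Landscape, path: str | Path) -> None:
    """Write the pay-off matrix as integer CSV with a ``.json`` sidecar."""
    path = Path(path)
    np.savetxt(path, landscape.payoffs, fmt="%d", delimiter=",")
    sidecar = {
        "n_peaks": landscape.n_peaks,
        "scale_max": landscape.scale_max,
        "kind": landscape.kind,
        "seed": landscape.seed,
        "dims": list(landscape.dims),
        "source_row": landscape.source_row,
        "coordinate_convention": "1-based",
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))


def load_landscape(path: str | Path) -> Landscape:
    path = Path(path)
    payoffs = np.loadtxt(path, delimiter=",", dtype=int, ndmin=2)
    sidecar = json.loads(path.with_suffix(".json").read_text())
    return Landscape(
        payoffs=payoffs,
        n_peaks=sidecar["n_peaks"],
        scale_max=sidecar["scale_max"],
        kind=sidecar["kind"],
        seed=sidecar["seed"],
        source_row=sidecar.get("source_row"),
    )
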