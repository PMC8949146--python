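"""Potentials of mean force from pair correlations, and barrier extraction.

The reversible-work approximation relates the PMF along the pair distance
to the RDF:  W_AB(r) = -kBT ln g_AB(r).  Working in kBT units this is
simply W = -ln g, defined exactly where g > 0; bins with g = 0 are left
undefined (NaN), never capped.

A binding free-energy barrier is read off W(r) as the difference between
the first local maximum and the preceding first local minimum inside a
search window.  Sampling noise creates spurious extrema, so candidates
must exceed a prominence threshold (default 0.05 kBT); an optional
centred moving average can smooth g first.  Barriers are converted to
kcal/mol with an explicit factor (default 1 kBT = 0.596 kcal/mol) that is
never silently recomputed from temperature.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import find_peaks

from .structure import RDFCurve

__all__ = [
    "KBT_TO_KCAL",
    "PMFCurve",
    "BarrierResult",
    "rdf_to_pmf",
    "extract_barrier",
    "kbt_to_kcal",
]

KBT_TO_KCAL = 0.596  # kcal/mol per kBT, the reporting convention adopted here
DEFAULT_WINDOW = (1.0, 6.0)  # Å — spans the HB first shell and second shell
DEFAULT_PROMINENCE = 0.05  # kBT


@dataclass
class PMFCurve:
    """W(r) in kBT units; NaN marks bins where g = 0 (W undefined)."""

    r_centers: np.ndarray
    W: np.ndarray
    temperature: float = 310.15

    @property
    def defined(self) -> np.ndarray:
        return np.isfinite(self.W)

    def to_csv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# temperature_K={self.temperature}\n")
            fh.write("r,W_kBT,defined\n")
            for r, w in zip(self.r_centers, self.W):
                d = int(np.isfinite(w))
                fh.write(f"{r:.6f},{w:.8g},{d}\n")


@dataclass
class BarrierResult:
    """First-minimum/first-maximum barrier of a PMF curve."""

    r_min: float
    W_min: float
    r_max: float
    W_max: float
    delta_W: float
    delta_W_kcal: float


def rdf_to_pmf(rdf: RDFCurve, temperature: float = 310.15) -> PMFCurve:
    """W(r) = -ln g(r) in kBT units; g = 0 bins become NaN (undefined)."""
    with np.errstate(divide="ignore"):
        W = np.where(rdf.g > 0, -np.log(np.where(rdf.g > 0, rdf.g, 1.0)), np.nan)
    return PMFCurve(r_centers=rdf.r_centers.copy(), W=W, temperature=temperature)


def _smooth(y: np.ndarray, window: int) -> np.ndarray:
    if window <= 1:
        return y
    if window % 2 == 0:
        raise ValueError("smoothing window must be odd")
    kernel = np.ones(window) / window
    out = np.convolve(y, kernel, mode="same")
    # edges of 'same' convolution are biased; keep the raw values there
    h = window // 2
    out[:h], out[-h:] = y[:h], y[-h:]
    return out


def extract_barrier(
    pmf: PMFCurve,
    search_window: tuple[float, float] = DEFAULT_WINDOW,
    prominence: float = DEFAULT_PROMINENCE,
    smooth_window: int = 1,
    conversion_factor: float = KBT_TO_KCAL,
) -> BarrierResult | None:
    """First local minimum and subsequent first local maximum of W(r).

    Searches each contiguous defined (finite-W) run inside the window, in
    order of increasing r; extrema must exceed ``prominence`` (kBT).  Flat
    extrema resolve to their smallest-r edge.  Returns None — the "no
    barrier" outcome, distinct from a zero-height barrier — when no
    interior minimum-then-maximum exists.
    """
    lo, hi = search_window
    if lo >= hi:
        raise ValueError("empty search window")
    in_win = (pmf.r_centers >= lo) & (pmf.r_centers <= hi) & pmf.defined
    if not np.any(in_win):
        return None
    # contiguous defined runs, in order of increasing r
    idx = np.nonzero(in_win)[0]
    breaks = np.nonzero(np.diff(idx) > 1)[0]
    runs = np.split(idx, breaks + 1)
    for run in runs:
        if run.size < 3:
            continue
        W = _smooth(pmf.W[run], smooth_window)
        r = pmf.r_centers[run]
        kw = dict(prominence=prominence, plateau_size=(1, None))
        minima, mprops = find_peaks(-W, **kw)
        maxima, xprops = find_peaks(W, **kw)
        minima = mprops["left_edges"]  # ties toward smaller r
        maxima = xprops["left_edges"]
        if minima.size == 0:
            continue
        m = int(minima[0])
        after = maxima[maxima > m]
        if after.size == 0:
            continue
        M = int(after[0])
        dW = float(W[M] - W[m])
        return BarrierResult(
            r_min=float(r[m]),
            W_min=float(W[m]),
            r_max=float(r[M]),
            W_max=float(W[M]),
            delta_W=dW,
            delta_W_kcal=kbt_to_kcal(dW, conversion_factor),
        )
    return None


def kbt_to_kcal(delta_W: float, factor: float = KBT_TO_KCAL) -> float:
    """Convert a kBT quantity to kcal/mol.  Exact product; round only at
    the presentation layer (tables print one decimal)."""
    if factor <= 0:
        raise ValueError("conversion factor must be > 0")
    return float(delta_W) * factor
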