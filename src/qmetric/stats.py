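"""Archive-wide statistical model of Q-score versus reported resolution.

A cubic least-squares fit Q_mean(d) summarizes how mean model Q-scores fall
with reported resolution d across an archive of map-model entries. Because
the residual distribution is skewed toward low Q (misfitted models), three
vertical offsets of the same curve carry the useful reference positions:

* Q_peak  = Q_mean + o_peak: the modal position, found as the vertical
  offset that maximizes the number of residuals inside a 0.01-wide window;
* Q_low_95% / Q_high_95% = Q_mean + o_low / o_high: offsets such that 95%
  of the residuals on each side of the peak lie between them and Q_peak.

Entries outside the two 95% curves are "not commonly observed" for their
reported resolution — candidate misfits (below) or oversharpened maps /
underestimated resolutions (above). A rolling-window empirical-percentile
alternative is provided for cross-checking the parametric curves.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numpy.polynomial import polynomial as npoly

from .io import ArchiveTable

__all__ = [
    "SingularFitError",
    "RegressionBundle",
    "fit_polynomial",
    "compute_offsets",
    "fit_archive",
    "predict_bounds",
    "rolling_percentiles",
    "classify_entry",
]


class SingularFitError(ValueError):
    """Polynomial fit is rank-deficient (too few distinct resolutions)."""


@dataclass
class RegressionBundle:
    """Fitted cubic Q_mean(d) plus its three vertical offsets.

    ``coeffs`` are ascending polynomial coefficients (c0..c_degree);
    offsets satisfy o_low <= o_peak <= o_high; ``domain`` is the fitted
    resolution range in Angstrom.
    """

    coeffs: np.ndarray
    o_peak: float
    o_low: float
    o_high: float
    r_squared: float
    domain: tuple[float, float]
    n: int
    degree: int = field(default=3)

    def __post_init__(self) -> None:
        self.coeffs = np.asarray(self.coeffs, dtype=float)
        if not (self.o_low <= self.o_peak <= self.o_high):
            raise ValueError("offsets must satisfy o_low <= o_peak <= o_high")
        if not -1e-9 <= self.r_squared <= 1 + 1e-9:
            raise ValueError("r_squared outside [0, 1]")

    def q_mean(self, d) -> np.ndarray:
        return npoly.polyval(np.asarray(d, dtype=float), self.coeffs)

    def q_peak(self, d) -> np.ndarray:
        return self.q_mean(d) + self.o_peak

    def q_low(self, d) -> np.ndarray:
        return self.q_mean(d) + self.o_low

    def q_high(self, d) -> np.ndarray:
        return self.q_mean(d) + self.o_high

    def to_json(self, path=None) -> str:
        payload = {
            "coeffs": list(self.coeffs),
            "o_peak": self.o_peak,
            "o_low": self.o_low,
            "o_high": self.o_high,
            "r_squared": self.r_squared,
            "domain": list(self.domain),
            "n": self.n,
            "degree": self.degree,
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, source) -> "RegressionBundle":
        if isinstance(source, (str, bytes)) and str(source).lstrip().startswith("{"):
            payload = json.loads(source)
        else:
            with open(source) as fh:
                payload = json.load(fh)
        return cls(
            coeffs=np.asarray(payload["coeffs"], dtype=float),
            o_peak=payload["o_peak"],
            o_low=payload["o_low"],
            o_high=payload["o_high"],
            r_squared=payload["r_squared"],
            domain=tuple(payload["domain"]),
            n=payload["n"],
            degree=payload.get("degree", 3),
        )


def fit_polynomial(d, q, degree: int = 3) -> tuple[np.ndarray, float]:
    """Least-squares polynomial fit of q on d.

    Returns ascending coefficients (c0..c_degree) and the coefficient of
    determination R^2 = 1 - SS_res/SS_tot. Requires at least degree + 1
    distinct resolutions.
    """
    d = np.asarray(d, dtype=float)
    q = np.asarray(q, dtype=float)
    if d.shape != q.shape or d.ndim != 1:
        raise ValueError("d and q must be equal-length 1D arrays")
    if len(np.unique(d)) < degree + 1:
        raise SingularFitError(
            f"need at least {degree + 1} distinct resolutions for degree {degree}"
        )
    coeffs = npoly.polyfit(d, q, degree)
    pred = npoly.polyval(d, coeffs)
    ss_res = float(np.sum((q - pred) ** 2))
    ss_tot = float(np.sum((q - q.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    return coeffs, float(np.clip(r2, 0.0, 1.0))


def compute_offsets(
    residuals,
    peak_window: float = 0.01,
    tail_frac: float = 0.05,
    grid_step: float = 0.001,
    mode: str = "per_side",
) -> tuple[float, float, float]:
    """Offsets (o_peak, o_low, o_high) from regression residuals.

    o_peak is the vertical offset that maximizes the number of residuals
    within +/- peak_window/2, searched on a ``grid_step`` grid spanning the
    residual range (ties break to the smallest offset). In the default
    ``per_side`` mode, o_low is the ``tail_frac`` quantile of the residuals
    below the peak (so a 1 - tail_frac fraction of that side lies between
    o_low and o_peak) and o_high is the mirror image for the upper side.
    ``mode="overall"`` instead takes plain lower/upper tail_frac quantiles
    of all residuals.
    """
    r = np.sort(np.asarray(residuals, dtype=float))
    if r.size == 0:
        raise ValueError("no residuals")
    if r[-1] - r[0] == 0.0:
        return float(r[0]), float(r[0]), float(r[0])
    grid = np.arange(r[0], r[-1] + grid_step / 2, grid_step)
    half = peak_window / 2.0
    counts = np.searchsorted(r, grid + half, side="right") - np.searchsorted(
        r, grid - half, side="left"
    )
    o_peak = float(grid[np.argmax(counts)])  # argmax returns first => smallest
    if mode == "per_side":
        below = r[r < o_peak]
        above = r[r > o_peak]
        o_low = float(np.percentile(below, 100 * tail_frac)) if below.size else o_peak
        o_high = (
            float(np.percentile(above, 100 * (1 - tail_frac))) if above.size else o_peak
        )
    elif mode == "overall":
        o_low = float(np.percentile(r, 100 * tail_frac))
        o_high = float(np.percentile(r, 100 * (1 - tail_frac)))
        o_low, o_high = min(o_low, o_peak), max(o_high, o_peak)
    else:
        raise ValueError(f"unknown offsets mode {mode!r}")
    return o_peak, o_low, o_high


def fit_archive(
    table: ArchiveTable,
    degree: int = 3,
    d_range: tuple[float, float] = (1.0, 10.0),
    peak_window: float = 0.01,
    tail_frac: float = 0.05,
    mode: str = "per_side",
) -> RegressionBundle:
    """Fit the regression bundle to an archive table.

    Rows are restricted to ``d_range`` (reported resolutions 1-10 A by
    default) before fitting.
    """
    sub = table.restrict(*d_range)
    if len(sub) == 0:
        raise ValueError(f"no archive rows within resolution range {d_range}")
    coeffs, r2 = fit_polynomial(sub.d, sub.q, degree)
    residuals = sub.q - npoly.polyval(sub.d, coeffs)
    o_peak, o_low, o_high = compute_offsets(
        residuals, peak_window=peak_window, tail_frac=tail_frac, mode=mode
    )
    return RegressionBundle(
        coeffs=coeffs,
        o_peak=o_peak,
        o_low=o_low,
        o_high=o_high,
        r_squared=r2,
        domain=(float(sub.d.min()), float(sub.d.max())),
        n=len(sub),
        degree=degree,
    )


def predict_bounds(bundle: RegressionBundle, d) -> dict[str, np.ndarray]:
    """Evaluate the four curves at resolution(s) d.

    Returns a dict with keys q_mean, q_peak, q_low, q_high (arrays matching
    the shape of d). Resolutions outside the fitted domain trigger an
    extrapolation warning.
    """
    d_arr = np.asarray(d, dtype=float)
    if np.any(d_arr <= 0):
        raise ValueError("resolution must be positive")
    if np.any(d_arr < bundle.domain[0]) or np.any(d_arr > bundle.domain[1]):
        warnings.warn(
            f"resolution outside fitted domain {bundle.domain}; extrapolating",
            stacklevel=2,
        )
    mean = bundle.q_mean(d_arr)
    return {
        "q_mean": mean,
        "q_peak": mean + bundle.o_peak,
        "q_low": mean + bundle.o_low,
        "q_high": mean + bundle.o_high,
    }


def rolling_percentiles(
    table: ArchiveTable,
    window: float = 0.5,
    percentiles=(5.0, 50.0, 95.0),
    grid: np.ndarray | None = None,
    min_rows: int = 20,
) -> pd.DataFrame:
    """Empirical Q percentiles in a rolling resolution window.

    For each grid resolution d, percentiles are taken over entries with
    |d_i - d| <= window/2; grid points with fewer than ``min_rows`` entries
    are reported as NaN (gaps). Percentiles use linear interpolation
    between order statistics.
    """
    d = table.d
    q = table.q
    if grid is None:
        grid = np.arange(np.floor(d.min() * 10) / 10, d.max() + 1e-9, 0.1)
    grid = np.asarray(grid, dtype=float)
    if grid.size == 0:
        raise ValueError("empty evaluation grid")
    order = np.argsort(d)
    d_sorted, q_by_d = d[order], q[order]
    rows = []
    for g in grid:
        lo = np.searchsorted(d_sorted, g - window / 2, side="left")
        hi = np.searchsorted(d_sorted, g + window / 2, side="right")
        sel = q_by_d[lo:hi]
        row = {"d": g, "n": hi - lo}
        for p in percentiles:
            row[f"p{p:g}"] = (
                float(np.percentile(sel, p)) if sel.size >= min_rows else np.nan
            )
        rows.append(row)
    return pd.DataFrame(rows)


def classify_entry(q: float, d: float, bundle: RegressionBundle) -> str:
    """Classify an entry's Q at resolution d against the 95% bounds.

    Strictly below Q_low_95%(d) -> ``below_low``; strictly above
    Q_high_95%(d) -> ``above_high``; otherwise ``typical``.
    """
    bounds = predict_bounds(bundle, d)
    if q < float(bounds["q_low"]):
        return "below_low"
    if q > float(bounds["q_high"]):
        return "above_high"
    return "typical"
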