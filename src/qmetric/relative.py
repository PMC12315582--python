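"""Percentile-based relative Q-scores against an archive of entries.

``q_relative_all`` ranks an entry's mean Q against every archive entry:
the percentage of entries with a strictly lower Q. ``q_relative_resolution``
does the same within a resolution window of total width w centered on the
entry's reported resolution d, answering "how does this entry compare with
others of similar resolution?" — near 50% is "as commonly observed", below
~5% suggests a misfitted model or overestimated quality, above ~95% an
oversharpened map or underestimated reported resolution.
"""

from __future__ import annotations

import numpy as np

from .io import ArchiveTable

__all__ = [
    "EmptyWindowError",
    "q_relative_all",
    "q_relative_resolution",
    "window_entry_counts",
    "window_correlation_scan",
]

# the 12 window sizes used for the correlation scan (A)
SCAN_WINDOWS = (0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9, 1.0, 1.2, 1.5)


class EmptyWindowError(ValueError):
    """No comparator entries fall within the resolution window."""


def _count_lower(qs: np.ndarray, q: float, ties: str) -> int:
    if ties == "strict":
        return int(np.count_nonzero(qs < q))
    if ties == "weak":
        return int(np.count_nonzero(qs <= q))
    raise ValueError(f"unknown ties mode {ties!r}")


def q_relative_all(q: float, table: ArchiveTable, ties: str = "strict") -> float:
    """Percentile rank of Q against the whole archive, in percent.

    ``100 * #{entries with q_i < q} / n``. Ties do not count toward the
    numerator in the default ``strict`` mode (``weak`` counts them).
    """
    if len(table) == 0:
        raise ValueError("archive table is empty")
    return 100.0 * _count_lower(table.q, q, ties) / len(table)


def _window_mask(d_arr: np.ndarray, d: float, w: float, window_mode: str) -> np.ndarray:
    if window_mode == "half":
        return np.abs(d_arr - d) <= w / 2.0
    if window_mode == "full":
        return np.abs(d_arr - d) <= w
    raise ValueError(f"unknown window mode {window_mode!r}")


def q_relative_resolution(
    q: float,
    d: float,
    table: ArchiveTable,
    w: float = 0.5,
    ties: str = "strict",
    window_mode: str = "half",
) -> tuple[float, int]:
    """Percentile rank of Q among entries of similar resolution.

    Comparators are entries with |d_i - d| <= w/2 (window of total width w;
    ``window_mode="full"`` selects |d_i - d| <= w instead). Returns
    ``(percent, n_window)``.
    """
    sel = _window_mask(table.d, d, w, window_mode)
    n = int(sel.sum())
    if n == 0:
        raise EmptyWindowError(f"no entries within window w={w} of d={d}")
    return 100.0 * _count_lower(table.q[sel], q, ties) / n, n


def window_entry_counts(
    table: ArchiveTable,
    w: float,
    d_range: tuple[float, float] = (1.0, 10.0),
    window_mode: str = "half",
) -> tuple[int, float, int]:
    """(min, mean, max) comparator-set size over all entries in d_range.

    For each entry, the comparator set is every entry (itself included)
    within its resolution window.
    """
    sub = table.restrict(*d_range)
    if len(sub) == 0:
        raise ValueError("no entries within d_range")
    d = np.sort(sub.d)
    half = w / 2.0 if window_mode == "half" else w
    counts = np.searchsorted(d, d + half, side="right") - np.searchsorted(
        d, d - half, side="left"
    )
    return int(counts.min()), float(counts.mean()), int(counts.max())


def window_correlation_scan(
    table: ArchiveTable,
    windows=SCAN_WINDOWS,
    split_d: float = 5.0,
    ties: str = "strict",
    window_mode: str = "half",
) -> dict[float, dict[str, float]]:
    """Pearson correlation of q_relative_resolution with d, per window size.

    For each window size w, q_relative_resolution is computed for every
    entry, then correlated with reported resolution separately for the
    d < split_d and d >= split_d strata (the high-/low-resolution halves of
    the archive). Low magnitudes are desirable: they mean the relative
    score is not biased by where an entry sits inside its window.

    Returns ``{w: {"below_split": r, "above_split": r}}``; a stratum with
    fewer than 3 entries or a constant score vector yields NaN.
    """
    d = table.d
    q = table.q
    order = np.argsort(d)
    d_sorted = d[order]
    q_sorted = q[order]
    out: dict[float, dict[str, float]] = {}
    for w in windows:
        half = w / 2.0 if window_mode == "half" else w
        lo = np.searchsorted(d_sorted, d - half, side="left")
        hi = np.searchsorted(d_sorted, d + half, side="right")
        qrr = np.empty(len(d))
        for i in range(len(d)):
            window_q = q_sorted[lo[i] : hi[i]]
            qrr[i] = 100.0 * _count_lower(window_q, q[i], ties) / len(window_q)
        strata = {"below_split": d < split_d, "above_split": d >= split_d}
        res: dict[str, float] = {}
        for name, mask in strata.items():
            if mask.sum() < 3 or np.ptp(qrr[mask]) == 0 or np.ptp(d[mask]) == 0:
                res[name] = float("nan")
            else:
                res[name] = float(np.corrcoef(d[mask], qrr[mask])[0, 1])
        out[float(w)] = res
    return out
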