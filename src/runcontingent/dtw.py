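"""Dynamic time warping with symmetric step patterns and L1 local cost.

DTW aligns two series by a monotone matching of their indices, so that two
spawning phenologies with the same shape but offset in calendar time score
as similar where a lockstep (Euclidean) comparison would not. The distance
is the minimum cumulative cost over all admissible warping paths:

* local cost ``c(i, j) = |a_i - b_j|``;
* step increments (1,0), (0,1), (1,1);
* "symmetric2" (default): a diagonal step contributes ``2 * c``, giving no
  a-priori preference to the diagonal over an off-diagonal detour;
  "symmetric1": every step contributes ``c`` once.

Distances are unnormalised path costs: series are catenated to equal length
upstream, so length normalisation is immaterial here.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ValidationError


@dataclass
class WarpingResult:
    """Minimal-cost alignment of two series.

    ``path`` is the ordered list of matched (i, j) index pairs, 0-based,
    from (0, 0) to (n-1, m-1), with both indices nondecreasing.
    """

    distance: float
    path: list[tuple[int, int]]


def dtw_distance(
    a,
    b,
    step_pattern: str = "symmetric2",
    window_size: int | None = None,
    return_path: bool = True,
) -> WarpingResult:
    """Minimum cumulative warping cost between two numeric series.

    ``window_size``, if given, is a Sakoe-Chiba band: only cells with
    ``|i - j| <= window_size`` are admissible; it must be at least
    ``|len(a) - len(b)|`` for a path to exist.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    n, m = len(a), len(b)
    if n == 0 or m == 0:
        raise ValidationError("dtw_distance requires nonempty series")
    if step_pattern not in ("symmetric2", "symmetric1"):
        raise ValidationError(f"unknown step pattern {step_pattern!r}")
    if window_size is not None and window_size < abs(n - m):
        raise ValidationError(
            f"window_size {window_size} < |len(a)-len(b)| = {abs(n - m)}: "
            "no admissible warping path"
        )
    diag_w = 2.0 if step_pattern == "symmetric2" else 1.0
    cost = np.abs(a[:, None] - b[None, :])
    inf = np.inf
    D = np.full((n, m), inf)
    D[0, 0] = cost[0, 0]
    for j in range(1, m):
        if window_size is None or j <= window_size:
            D[0, j] = D[0, j - 1] + cost[0, j]
    for i in range(1, n):
        ci = cost[i]
        row = D[i]
        prev = D[i - 1]
        j_lo = 0 if window_size is None else max(0, i - window_size)
        j_hi = m - 1 if window_size is None else min(m - 1, i + window_size)
        if j_lo == 0:
            row[0] = prev[0] + ci[0]
            j_lo = 1
        for j in range(j_lo, j_hi + 1):
            best = prev[j - 1] * 1.0 + diag_w * ci[j]
            up = prev[j] + ci[j]
            if up < best:
                best = up
            left = row[j - 1] + ci[j]
            if left < best:
                best = left
            row[j] = best
    if not np.isfinite(D[n - 1, m - 1]):
        raise ValidationError("no admissible warping path under the window")
    path = _backtrack(D, cost, diag_w) if return_path else []
    return WarpingResult(distance=float(D[n - 1, m - 1]), path=path)


def _backtrack(D, cost, diag_w):
    n, m = D.shape
    i, j = n - 1, m - 1
    path = [(i, j)]
    tol = 1e-9
    while (i, j) != (0, 0):
        if i > 0 and j > 0 and abs(D[i, j] - (D[i - 1, j - 1] + diag_w * cost[i, j])) <= tol:
            i, j = i - 1, j - 1
        elif i > 0 and abs(D[i, j] - (D[i - 1, j] + cost[i, j])) <= tol:
            i -= 1
        else:
            j -= 1
        path.append((i, j))
    path.reverse()
    return path


def euclidean_distance(a, b) -> float:
    """L1 lockstep distance (the comparison DTW improves on); equal lengths."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValidationError("lockstep distance requires equal-length series")
    return float(np.abs(a - b).sum())
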