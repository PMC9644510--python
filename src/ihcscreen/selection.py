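"""Stepwise discriminant analysis (SDA) for feature selection.

Classic forward-stepwise selection on Wilks' lambda: at each step the
candidate feature whose inclusion minimizes

    lambda(S) = det(W_S) / det(T_S)

(within-class over total scatter, restricted to the selected set S) is
added if its partial F-to-enter passes the threshold, after which any
included feature whose partial F-to-remove has fallen below the removal
threshold is dropped.  With g classes, n samples and q features already
selected, the partial F for adding feature j is

    F = (n - g - q) / (g - 1) * (lambda_q / lambda_{q+1} - 1)

and the symmetric expression (with q -> q-1) governs removal.  The
procedure is deterministic given the input column order; ties are broken
by the lowest column index.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["SDAResult", "sda_select"]

#: conventional F thresholds (~alpha 0.05 entry / 0.10 removal)
DEFAULT_F_ENTER = 3.84
DEFAULT_F_REMOVE = 2.71


@dataclass
class SDAResult:
    selected: list[int]
    wilks_trajectory: list[float] = field(default_factory=list)
    f_stats: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(set(self.selected)) != len(self.selected):
            raise ValueError("selected indices must be unique")
        lam = self.wilks_trajectory
        if any(not 0.0 < v <= 1.0 + 1e-12 for v in lam):
            raise ValueError("Wilks' lambda must lie in (0, 1]")
        if any(a < b - 1e-12 for a, b in zip(lam, lam[1:])):
            raise ValueError("Wilks' lambda must be non-increasing along the trajectory")


def _scatter_matrices(x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Within-class (W) and total (T) scatter, with a ridge guard on W."""
    grand = x.mean(axis=0)
    xc = x - grand
    t = xc.T @ xc
    w = np.zeros_like(t)
    for cls in np.unique(y):
        xg = x[y == cls]
        d = xg - xg.mean(axis=0)
        w += d.T @ d
    p = x.shape[1]
    ridge = 1e-8 * np.trace(w) / p if np.trace(w) > 0 else 1e-8
    w = w + ridge * np.eye(p)
    t = t + ridge * np.eye(p)
    return w, t


def _wilks(w: np.ndarray, t: np.ndarray, idx: list[int]) -> float:
    """lambda = det(W_S)/det(T_S) for the feature subset S, via slogdet."""
    if not idx:
        return 1.0
    ix = np.ix_(idx, idx)
    sw, lw = np.linalg.slogdet(w[ix])
    st, lt = np.linalg.slogdet(t[ix])
    if sw <= 0 or st <= 0:
        return 1.0
    return float(np.exp(lw - lt))


def sda_select(
    features: np.ndarray,
    labels,
    f_enter: float = DEFAULT_F_ENTER,
    f_remove: float = DEFAULT_F_REMOVE,
    max_features: int | None = None,
) -> SDAResult:
    """Forward-stepwise Wilks' lambda feature selection with removal steps.

    Parameters
    ----------
    features : (n, p) array
    labels : (n,) class labels (any hashable values; >= 2 distinct)
    f_enter, f_remove : partial-F thresholds, ``f_enter >= f_remove``
    max_features : stop after this many selected (default min(p, n-g-1))
    """
    x = np.asarray(features, dtype=float)
    if x.ndim != 2 or x.shape[1] == 0:
        raise ValueError("features must be a non-empty (n, p) table")
    y = np.asarray(labels)
    if y.shape[0] != x.shape[0]:
        raise ValueError("features and labels must be aligned")
    classes = np.unique(y)
    g = classes.size
    if g < 2:
        raise ValueError("labels are constant; discriminant analysis undefined")
    n, p = x.shape
    if n <= g:
        raise ValueError("need more samples than classes")
    if f_enter < f_remove:
        raise ValueError("f_enter must be >= f_remove")
    if max_features is None:
        max_features = min(p, n - g - 1)
    max_features = max(1, min(max_features, p))

    w, t = _scatter_matrices(x, y)
    selected: list[int] = []
    trajectory: list[float] = []
    f_at_entry: dict[int, float] = {}
    lam_cur = 1.0

    while len(selected) < max_features:
        q = len(selected)
        if n - g - q <= 0:
            break
        remaining = [j for j in range(p) if j not in selected]
        if not remaining:
            break
        best_j, best_lam = -1, None
        for j in remaining:
            lam_j = _wilks(w, t, selected + [j])
            if best_lam is None or lam_j < best_lam - 1e-15:
                best_j, best_lam = j, lam_j
        if best_lam is None or best_lam <= 0:
            break
        f_stat = (n - g - q) / (g - 1) * (lam_cur / best_lam - 1.0)
        if f_stat < f_enter:
            break
        selected.append(best_j)
        f_at_entry[best_j] = f_stat
        lam_cur = best_lam

        # backward pass: drop features whose partial F fell below f_remove
        changed = True
        while changed and len(selected) > 1:
            changed = False
            q = len(selected)
            for j in list(selected):
                if j == best_j:
                    continue  # never drop the feature just entered
                lam_without = _wilks(w, t, [i for i in selected if i != j])
                f_rm = (n - g - q + 1) / (g - 1) * (lam_without / lam_cur - 1.0)
                if f_rm < f_remove:
                    selected.remove(j)
                    lam_cur = lam_without
                    changed = True
                    break
        # one trajectory entry per accepted step (entry + consequent removals);
        # f_enter > f_remove keeps this net change decreasing
        trajectory.append(lam_cur)

    if not selected:
        # guarantee at least one feature: take the single best by lambda
        best_j = int(
            np.argmin([_wilks(w, t, [j]) for j in range(p)])
        )
        lam_cur = _wilks(w, t, [best_j])
        f_stat = (n - g - 1) / (g - 1) * (1.0 / lam_cur - 1.0) if lam_cur > 0 else 0.0
        selected = [best_j]
        trajectory = [lam_cur]
        f_at_entry[best_j] = f_stat

    return SDAResult(
        selected=selected,
        wilks_trajectory=trajectory,
        f_stats=[f_at_entry[j] for j in selected],
    )
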