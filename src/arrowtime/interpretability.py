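"""Saliency attribution and temporal-focus statistics.

Integrated gradients assigns each input entry the path integral of the model
output's gradient along the straight line from a baseline to the input,
scaled by the displacement — satisfying completeness (attributions sum to
the output difference) in the limit of many steps. On top of the raw maps
this module provides:

* forward/reverse alignment — reverse-input maps are flipped along time and
  compared with the forward map via Pearson correlation of absolute
  attributions;
* temporal concentration ("spikiness") — the top fraction of salient entries
  is kept, collapsed onto the time axis, normalised to a distribution, and
  scored by 1-D earth mover's distance to a uniform reference: concentrated
  mass scores high, scattered mass scores low;
* submodular pick — greedy coverage-based selection of representative
  subjects from a stack of saliency maps.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.stats import pearsonr

from .model import SequenceClassifier

__all__ = [
    "SaliencyMap",
    "TimeDistribution",
    "DegenerateDistributionError",
    "UndefinedCorrelationError",
    "integrated_gradients",
    "flip_time_saliency",
    "alignment_correlation",
    "top_fraction_mask",
    "time_marginal",
    "emd_1d",
    "emd_spikiness",
    "submodular_pick",
]


class DegenerateDistributionError(ValueError):
    """The masked saliency mass is identically zero; no distribution exists."""


class UndefinedCorrelationError(ValueError):
    """Pearson correlation is undefined (zero variance input)."""


@dataclass
class SaliencyMap:
    """A ``T x N`` attribution matrix tied to a subject and input direction."""

    subject_id: str
    attributions: np.ndarray
    direction: str = "forward"  # "forward" or "reverse"
    aligned: bool = False

    def __post_init__(self) -> None:
        self.attributions = np.asarray(self.attributions, dtype=float)
        if self.attributions.ndim != 2:
            raise ValueError("attributions must be a T x N matrix")
        if not np.all(np.isfinite(self.attributions)):
            raise ValueError("attributions contain NaN or Inf")
        if self.direction not in ("forward", "reverse"):
            raise ValueError("direction must be 'forward' or 'reverse'")


@dataclass
class TimeDistribution:
    """Length-T nonnegative mass vector summing to 1 (unless degenerate)."""

    mass: np.ndarray
    degenerate: bool = False

    def __post_init__(self) -> None:
        self.mass = np.asarray(self.mass, dtype=float)
        if self.mass.ndim != 1:
            raise ValueError("mass must be a 1-D vector")
        if not self.degenerate:
            if np.any(self.mass < 0):
                raise ValueError("mass must be nonnegative")
            if abs(self.mass.sum() - 1.0) > 1e-9:
                raise ValueError("mass must sum to 1")

    def __len__(self) -> int:
        return len(self.mass)


def integrated_gradients(
    model: SequenceClassifier,
    X: np.ndarray,
    baseline: Optional[np.ndarray] = None,
    steps: int = 64,
    subject_id: str = "",
    direction: str = "forward",
) -> SaliencyMap:
    """Integrated-gradients attribution of the model probability for one input.

    Uses the midpoint Riemann rule on the straight path from ``baseline``
    (all zeros by default) to ``X``:

        IG_{t,n} = (X - b)_{t,n} * (1/steps) * sum_k dF/dx_{t,n} |_{b + (k-1/2)/steps * (X-b)}

    where F is the sigmoid probability output in evaluation mode.
    """
    if steps < 1:
        raise ValueError("steps must be >= 1")
    X = np.asarray(X, dtype=float)
    if baseline is None:
        baseline = np.zeros_like(X)
    baseline = np.asarray(baseline, dtype=float)
    if baseline.shape != X.shape:
        raise ValueError("baseline shape must match input shape")
    alphas = (np.arange(steps) + 0.5) / steps
    diff = X - baseline
    # chunk the path batch: BPTT caches for large step counts would exhaust memory
    grad_sum = np.zeros_like(X)
    chunk = 128
    for lo in range(0, steps, chunk):
        a = alphas[lo : lo + chunk]
        interpolants = baseline[None] + a[:, None, None] * diff[None]
        grad_sum += model.input_gradient(interpolants).sum(axis=0)
    avg_grad = grad_sum / steps
    return SaliencyMap(subject_id, diff * avg_grad, direction=direction, aligned=False)


def flip_time_saliency(S: SaliencyMap) -> SaliencyMap:
    """Reverse the time axis of a reverse-direction map, marking it aligned."""
    if S.direction != "reverse":
        raise ValueError("only reverse-direction maps can be flipped")
    if S.aligned:
        raise ValueError("map is already aligned")
    return SaliencyMap(S.subject_id, S.attributions[::-1].copy(), direction="reverse", aligned=True)


def alignment_correlation(S_f: SaliencyMap, S_r: SaliencyMap, signed: bool = False) -> float:
    """Pearson correlation between flattened forward and aligned-reverse maps.

    Compares absolute attributions by default (salience magnitude); set
    ``signed=True`` to correlate raw signed values.
    """
    if S_f.direction != "forward":
        raise ValueError("first argument must be a forward map")
    if not S_r.aligned:
        raise ValueError("reverse map must be aligned (flipped) first")
    if S_f.attributions.shape != S_r.attributions.shape:
        raise ValueError("maps must share one shape")
    a = S_f.attributions.ravel()
    b = S_r.attributions.ravel()
    if not signed:
        a, b = np.abs(a), np.abs(b)
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise UndefinedCorrelationError("zero-variance map; correlation undefined")
    return float(pearsonr(a, b).statistic)


def top_fraction_mask(S: SaliencyMap, fraction: float = 0.05) -> np.ndarray:
    """Boolean mask of the k = ceil(fraction * T * N) largest-|attribution| entries.

    Ties at the cutoff are broken by earlier time index, then lower
    component index, so exactly k entries are selected.
    """
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    A = np.abs(S.attributions)
    T, N = A.shape
    k = int(np.ceil(fraction * T * N))
    flat = A.ravel()  # row-major: index = t*N + n, so index order == (t, n) order
    order = np.lexsort((np.arange(flat.size), -flat))
    mask = np.zeros(flat.size, dtype=bool)
    mask[order[:k]] = True
    return mask.reshape(T, N)


def time_marginal(S: SaliencyMap, mask: np.ndarray) -> TimeDistribution:
    """Collapse masked absolute attributions onto the time axis and normalise."""
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != S.attributions.shape:
        raise ValueError("mask shape must match attributions")
    mass = (np.abs(S.attributions) * mask).sum(axis=1)
    total = mass.sum()
    if total == 0:
        return TimeDistribution(mass, degenerate=True)
    return TimeDistribution(mass / total)


def emd_1d(d1: TimeDistribution, d2: TimeDistribution) -> float:
    """1-Wasserstein distance between two length-T distributions.

    Ground distance is |i - j| in time-index units; on the line the optimal
    transport cost has the closed form  sum_{t<T} |CDF1(t) - CDF2(t)|.
    """
    if len(d1) != len(d2):
        raise ValueError("distributions must have equal length")
    cdf_gap = np.cumsum(d1.mass - d2.mass)
    return float(np.abs(cdf_gap[:-1]).sum())


def uniform_distribution(T: int) -> TimeDistribution:
    return TimeDistribution(np.full(T, 1.0 / T))


def emd_spikiness(S: SaliencyMap, fraction: float = 0.05, normalize: bool = False) -> float:
    """Temporal concentration score of a saliency map.

    EMD between the top-``fraction`` time marginal and the uniform
    distribution over the T time indices: a single spike at an endpoint
    scores the maximum (T-1)/2, perfectly scattered saliency scores 0.
    ``normalize=True`` divides by (T-1) for cross-length comparison.
    """
    marginal = time_marginal(S, top_fraction_mask(S, fraction))
    if marginal.degenerate:
        raise DegenerateDistributionError(
            f"subject {S.subject_id!r}: masked saliency mass is zero"
        )
    T = len(marginal)
    value = emd_1d(marginal, uniform_distribution(T))
    return value / (T - 1) if normalize else value


def submodular_pick(maps: Sequence[SaliencyMap], budget: int) -> list[int]:
    """Greedy coverage-maximising selection of representative maps.

    With W the stack of flattened absolute attributions (rows = subjects)
    and feature importance I_j = sqrt(sum_i W_ij), the coverage of a set V
    is the importance-weighted count of features touched by at least one
    picked subject (W_ij > 0). Greedily adds the map with the largest
    marginal coverage gain, breaking ties by lower index, until ``budget``
    picks (or all maps) are made.
    """
    if len(maps) == 0:
        raise ValueError("no saliency maps given")
    if budget < 1:
        raise ValueError("budget must be >= 1")
    W = np.stack([np.abs(m.attributions).ravel() for m in maps])
    importance = np.sqrt(W.sum(axis=0))
    present = W > 0
    covered = np.zeros(W.shape[1], dtype=bool)
    picked: list[int] = []
    remaining = list(range(len(maps)))
    for _ in range(min(budget, len(maps))):
        gains = [importance[present[i] & ~covered].sum() for i in remaining]
        best_pos = int(np.argmax(gains))  # argmax takes the first max: lower index wins ties
        best = remaining.pop(best_pos)
        picked.append(best)
        covered |= present[best]
    return picked
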