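"""Context-based correction of a raw prediction sequence, and its accuracy model.

Consecutive windows of human activity are strongly autocorrelated, so an
isolated prediction that disagrees with its neighbourhood is most likely a
recognition error.  The smoother corrects each raw label with the mode of the
``2k + 1`` labels centred on it: the centre label is kept when it belongs to
the set of modes, otherwise it is replaced by the primary mode.

Under the assumption that each raw window prediction is independently wrong
with probability ``psi``, the corrected accuracy is the binomial tail

    Accuracy(psi, k) = P(at most k of 2k+1 results are wrong)
                     = sum_{i=0..k} C(2k+1, i) psi^i (1 - psi)^(2k+1-i),

implemented in `majority_accuracy` and used by `choose_k` to pick the
smallest window whose marginal gain no longer justifies the extra reporting
delay of ``k`` windows (the method's one real cost).
"""

from __future__ import annotations

from collections import Counter, deque
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import binom
from sklearn.base import BaseEstimator, TransformerMixin

from .errors import ParameterError

__all__ = [
    "SmootherState",
    "ContextSmoother",
    "smooth_step",
    "smooth_sequence",
    "majority_accuracy",
    "choose_k",
]


def _correct(window, center_idx: int):
    """Mode rule: keep the centre label if it is among the modes, else Mode1.

    Mode1 (the primary mode) under ties is the tied label occurring earliest
    in the buffer — deterministic and order-preserving.
    """
    counts = Counter(window)
    top = max(counts.values())
    center = window[center_idx]
    if counts[center] == top:
        return center
    for lab in window:
        if counts[lab] == top:
            return lab
    raise AssertionError("unreachable")  # pragma: no cover


@dataclass
class SmootherState:
    """Streaming smoother: ring buffer of the last ``2k + 1`` raw labels.

    ``step`` emits the raw label until the buffer first fills (warm-up), then
    the corrected label for the buffer's centre — i.e. the stream is emitted
    with a fixed reporting ``delay`` of ``k`` windows.  ``flush`` emits the
    final ``k`` corrected labels from progressively truncated buffers once
    the stream ends.
    """

    k: int
    buffer: deque = field(init=False)
    n_seen: int = field(default=0, init=False)

    def __post_init__(self) -> None:
        if self.k < 0:
            raise ParameterError("k must be >= 0")
        self.buffer = deque(maxlen=2 * self.k + 1)

    @property
    def delay(self) -> int:
        """Reporting delay in windows once the buffer is full."""
        return self.k

    def step(self, label):
        self.buffer.append(label)
        self.n_seen += 1
        if self.n_seen < 2 * self.k + 1:
            return label  # warm-up: raw pass-through
        return _correct(list(self.buffer), self.k)

    def flush(self) -> list:
        """Corrected labels for the last ``k`` stream positions."""
        buf = list(self.buffer)
        out = []
        for j in range(self.k + 1, len(buf)):
            out.append(_correct(buf[j - self.k :], self.k))
        return out


def smooth_step(state: SmootherState, label):
    """One streaming correction step (see `SmootherState.step`)."""
    return state.step(label)


def smooth_sequence(results, k: int) -> list:
    """Correct a whole label sequence with a centred mode window.

    ``output[t]`` applies the mode rule to ``results[t-k .. t+k]``: the first
    ``k`` positions are emitted raw (no centre-aligned window exists yet) and
    the last ``k`` use progressively truncated buffers, so the output has the
    same length as the input.  ``k = 0`` is the identity.
    """
    if k < 0:
        raise ParameterError("k must be >= 0")
    labels = list(results)
    n = len(labels)
    if k == 0:
        return labels
    out = []
    for t in range(n):
        if t < k:
            out.append(labels[t])
            continue
        window = labels[t - k : min(n, t + k + 1)]
        out.append(_correct(window, k))
    return out


class ContextSmoother(TransformerMixin, BaseEstimator):
    """scikit-learn transformer wrapper around `smooth_sequence`.

    Stateless: ``fit`` only validates ``k``; ``transform`` maps a raw label
    sequence to the corrected sequence of the same length.
    """

    def __init__(self, k: int = 1):
        self.k = k

    def fit(self, X=None, y=None):
        if self.k < 0:
            raise ParameterError("k must be >= 0")
        self.n_features_in_ = 1
        return self

    def transform(self, X):
        return np.asarray(smooth_sequence(list(X), self.k), dtype=object)


def majority_accuracy(psi: float, k: int) -> float:
    """Closed-form post-correction accuracy under i.i.d. errors at rate psi.

    The centre label is reported correctly whenever at most ``k`` of the
    ``2k + 1`` window results are wrong, so the accuracy is the binomial
    tail ``P(Binomial(2k+1, psi) <= k)``.  At ``k = 0`` this is ``1 - psi``.
    """
    if not 0.0 <= psi <= 1.0:
        raise ParameterError(f"psi must lie in [0, 1], got {psi}")
    if k < 0 or int(k) != k:
        raise ParameterError("k must be a non-negative integer")
    return float(binom.cdf(k, 2 * int(k) + 1, psi))


def choose_k(psi: float, min_gain: float = 0.05, k_max: int = 5) -> int:
    """Smallest k whose next increment improves accuracy by less than min_gain.

    Valid for ``0 < psi < 0.5`` (above 0.5 majority voting amplifies errors).
    With ``min_gain = 0`` the gains never fall below threshold (they are
    strictly positive for ``psi < 0.5``) and ``k_max`` is returned.
    """
    if not 0.0 < psi < 0.5:
        raise ParameterError(
            f"psi must lie in (0, 0.5) for majority voting to help, got {psi}"
        )
    for k in range(k_max):
        gain = majority_accuracy(psi, k + 1) - majority_accuracy(psi, k)
        if gain < min_gain:
            return k
    return k_max
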