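"""Discrete probability densities and information-theoretic primitives.

Every quantity in the model — what the agent perceives, which task it is
set for, which response side it leans toward — is represented as a small
labeled discrete probability density.  This module provides the immutable
density value type, its constructors, and the divergence/entropy measures
the rest of the package consumes.

All information quantities are reported in nats (natural logarithm).  A
base-2 conversion, if wanted, is a constant factor applied on output.
"""

from __future__ import annotations

from functools import lru_cache
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "DiscreteDensity",
    "make_density",
    "uniform_density",
    "soft_one_hot",
    "kl_divergence",
    "entropy",
    "expected_cost",
    "total_variation",
    "PROB_FLOOR",
]

#: Floor applied to the reference density inside KL to avoid infinities
#: when a hard one-hot goal is compared against a density with true zeros.
PROB_FLOOR = 1e-12

#: Absolute tolerance for the sum-to-one invariant.
NORM_ATOL = 1e-9


class DiscreteDensity:
    """An immutable labeled probability density over a finite category set.

    Parameters
    ----------
    labels
        Unique, ordered category identifiers.
    weights
        Non-negative probabilities, one per label, summing to 1 within
        ``1e-9``.  The array is copied and frozen.

    Use :func:`make_density` to build a density from unnormalized weights.
    """

    __slots__ = ("labels", "weights")

    def __init__(self, labels: Sequence[str], weights: Iterable[float]):
        labels = tuple(labels)
        w = np.asarray(weights, dtype=float).copy()
        if w.ndim != 1 or len(labels) != w.shape[0]:
            raise ValueError("labels and weights must be 1-D and equally long")
        if len(set(labels)) != len(labels):
            raise ValueError(f"labels must be unique, got {labels}")
        if np.any(w < 0):
            raise ValueError(f"negative weight in {w}")
        if abs(w.sum() - 1.0) > NORM_ATOL:
            raise ValueError(f"weights must sum to 1 (got {w.sum()!r})")
        w.flags.writeable = False
        object.__setattr__(self, "labels", labels)
        object.__setattr__(self, "weights", w)

    def __setattr__(self, name, value):  # immutability
        raise AttributeError("DiscreteDensity is immutable")

    # -- conveniences -------------------------------------------------

    def __len__(self) -> int:
        return len(self.labels)

    def __getitem__(self, label: str) -> float:
        return float(self.weights[self.labels.index(label)])

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, DiscreteDensity)
            and self.labels == other.labels
            and np.array_equal(self.weights, other.weights)
        )

    def __hash__(self):
        return hash((self.labels, self.weights.tobytes()))

    def __repr__(self) -> str:
        items = ", ".join(f"{l}={w:.4g}" for l, w in zip(self.labels, self.weights))
        return f"DiscreteDensity({items})"

    def to_dict(self) -> Mapping[str, float]:
        return dict(zip(self.labels, map(float, self.weights)))

    def argmax_label(self) -> str:
        """Label of the largest weight; ties broken by label order."""
        return self.labels[int(np.argmax(self.weights))]

    def allclose(self, other: "DiscreteDensity", atol: float = 1e-12) -> bool:
        return self.labels == other.labels and np.allclose(
            self.weights, other.weights, rtol=0.0, atol=atol
        )

    def with_weights(self, weights: np.ndarray) -> "DiscreteDensity":
        """New density over the same labels (weights must already be valid)."""
        return DiscreteDensity(self.labels, weights)


def _trusted(labels: tuple, weights: np.ndarray) -> DiscreteDensity:
    """Internal fast path: wrap an already-valid, freshly-owned weight
    array without re-validating.  Callers guarantee normalization."""
    d = DiscreteDensity.__new__(DiscreteDensity)
    weights.flags.writeable = False
    object.__setattr__(d, "labels", labels)
    object.__setattr__(d, "weights", weights)
    return d


def make_density(labels: Sequence[str], weights: Iterable[float]) -> DiscreteDensity:
    """Build a density from non-negative weights, normalizing to sum 1.

    Raises
    ------
    ValueError
        If any weight is negative, lengths mismatch, or all weights are 0.
    """
    w = np.asarray(weights, dtype=float)
    if w.ndim != 1 or w.shape[0] != len(tuple(labels)):
        raise ValueError("labels and weights must be equally long")
    if np.any(w < 0):
        raise ValueError(f"negative weight in {w}")
    total = w.sum()
    if total <= 0:
        raise ValueError("all-zero weights cannot be normalized")
    return DiscreteDensity(labels, w / total)


def uniform_density(labels: Sequence[str]) -> DiscreteDensity:
    """Uniform density: weight ``1/n`` on each of the ``n`` labels."""
    return _uniform_cached(tuple(labels))


@lru_cache(maxsize=512)
def _uniform_cached(labels: tuple) -> DiscreteDensity:
    if not labels:
        raise ValueError("need at least one label")
    return DiscreteDensity(labels, np.full(len(labels), 1.0 / len(labels)))


def soft_one_hot(labels: Sequence[str], target: str, mass: float) -> DiscreteDensity:
    """Density with ``mass`` on ``target``, the rest spread evenly.

    ``mass`` must lie in ``[1/n, 1]``; ``mass = 1/n`` recovers the uniform
    density and ``mass = 1`` a hard one-hot.
    """
    return _soft_one_hot_cached(tuple(labels), target, float(mass))


@lru_cache(maxsize=512)
def _soft_one_hot_cached(labels: tuple, target: str, mass: float) -> DiscreteDensity:
    if target not in labels:
        raise ValueError(f"target {target!r} not among labels {labels}")
    n = len(labels)
    if not (1.0 / n <= mass <= 1.0):
        raise ValueError(f"mass {mass} outside [1/{n}, 1]")
    w = np.full(n, (1.0 - mass) / (n - 1) if n > 1 else 0.0)
    w[labels.index(target)] = mass
    return DiscreteDensity(labels, w / w.sum())


# -- information measures ---------------------------------------------


def _check_same_labels(a: DiscreteDensity, b: DiscreteDensity) -> None:
    if a.labels != b.labels:
        raise ValueError(f"label mismatch: {a.labels} vs {b.labels}")


def kl_array(q: np.ndarray, p: np.ndarray, floor: float = PROB_FLOOR) -> float:
    """KL(q || p) in nats on raw weight arrays; ``p`` floored at ``floor``."""
    p = np.maximum(p, floor)
    mask = q > 0.0
    return float(np.sum(q[mask] * np.log(q[mask] / p[mask])))


def kl_divergence(
    q: DiscreteDensity, p: DiscreteDensity, floor: float = PROB_FLOOR
) -> float:
    """Kullback–Leibler divergence ``KL(q || p)`` in nats.

    Quantifies the information-processing cost of moving the prior ``p``
    to the posterior ``q``.  Terms with ``q_i = 0`` contribute zero; the
    reference ``p`` is floored at ``floor`` so hard one-hot posteriors
    stay finite.  Always >= 0 (up to the floor's perturbation).
    """
    _check_same_labels(q, p)
    return kl_array(q.weights, p.weights, floor)


def entropy(p: DiscreteDensity) -> float:
    """Shannon entropy in nats; 0 <= H <= ln(n), maximal at uniform."""
    w = p.weights[p.weights > 0.0]
    return float(-np.sum(w * np.log(w)))


def expected_cost(
    evidence_weights: Sequence[float],
    conditional_posteriors: Sequence[DiscreteDensity],
    prior: DiscreteDensity,
) -> float:
    """Evidence-weighted mean KL cost: ``sum_e p(e) KL(Q(x|e) || P(x))``.

    When ``prior`` equals the evidence-weighted mixture of the posteriors
    this is exactly the mutual information I(E; X) between evidence and
    state, the information-theoretic price of letting the evidence
    re-focus the state density.
    """
    pe = np.asarray(evidence_weights, dtype=float)
    if np.any(pe < 0) or abs(pe.sum() - 1.0) > NORM_ATOL:
        raise ValueError("evidence weights must form a density")
    if len(pe) != len(conditional_posteriors):
        raise ValueError("one conditional posterior required per evidence value")
    return float(
        sum(w * kl_divergence(q, prior) for w, q in zip(pe, conditional_posteriors))
    )


def total_variation(a: DiscreteDensity, b: DiscreteDensity) -> float:
    """Total-variation distance: half the L1 distance between densities."""
    _check_same_labels(a, b)
    return float(0.5 * np.sum(np.abs(a.weights - b.weights)))
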