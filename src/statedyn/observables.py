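"""The five per-session observables of the state-transition dynamics.

From a 1-based label sequence ``L_1..L_T`` over K states we compute:

* coverage -- fraction of volumes in each state (sums to 1);
* frequency -- number of maximal runs of each state divided by T;
* lifespan -- mean run length of each state, in volumes (TR units);
* transition matrix -- row-normalized counts of changes between *distinct*
  states, zero diagonal, no wraparound;
* centroids are carried over from the partition.

States absent from a session get coverage/frequency 0, lifespan 0 flagged as
absent, and an all-zero transition row.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._errors import ConfigurationError
from .clustering import StatePartition


def _check_labels(labels: np.ndarray, k: int) -> np.ndarray:
    labels = np.asarray(labels, dtype=int)
    if labels.ndim != 1 or labels.size == 0:
        raise ConfigurationError("labels must be a non-empty 1-D sequence")
    if labels.min() < 1 or labels.max() > k:
        raise ConfigurationError(f"labels must lie in 1..{k}")
    return labels


def _run_starts(labels: np.ndarray) -> np.ndarray:
    """Boolean mask marking the first volume of each maximal run."""
    starts = np.empty(labels.size, dtype=bool)
    starts[0] = True
    starts[1:] = labels[1:] != labels[:-1]
    return starts


def coverage(labels, k: int) -> np.ndarray:
    """Fraction of volumes in each state; sums to 1."""
    labels = _check_labels(labels, k)
    return np.bincount(labels - 1, minlength=k) / labels.size


def frequency(labels, k: int) -> np.ndarray:
    """Number of maximal runs of each state divided by T."""
    labels = _check_labels(labels, k)
    starts = labels[_run_starts(labels)]
    return np.bincount(starts - 1, minlength=k) / labels.size


def lifespan(labels, k: int) -> np.ndarray:
    """Mean run length per state in volumes; 0 for absent states."""
    labels = _check_labels(labels, k)
    cov_counts = np.bincount(labels - 1, minlength=k).astype(float)
    starts = labels[_run_starts(labels)]
    run_counts = np.bincount(starts - 1, minlength=k).astype(float)
    out = np.zeros(k)
    present = run_counts > 0
    out[present] = cov_counts[present] / run_counts[present]
    return out


def transition_matrix(labels, k: int) -> np.ndarray:
    """Row-stochastic-or-zero matrix of transitions between distinct states.

    Dwell (self) transitions are excluded; a state with no outgoing
    transitions keeps an all-zero row.
    """
    labels = _check_labels(labels, k)
    counts = transition_counts(labels, k).astype(float)
    row_sums = counts.sum(axis=1)
    p = np.zeros((k, k))
    nz = row_sums > 0
    p[nz] = counts[nz] / row_sums[nz, None]
    return p


def transition_counts(labels, k: int) -> np.ndarray:
    """K x K integer counts n_{ll'} of changes l -> l' with l != l'."""
    labels = _check_labels(labels, k)
    a, b = labels[:-1], labels[1:]
    moved = a != b
    counts = np.zeros((k, k), dtype=int)
    np.add.at(counts, (a[moved] - 1, b[moved] - 1), 1)
    return counts


@dataclass
class SessionObservables:
    """All five observables of one session's state-transition dynamics."""

    centroids: np.ndarray
    coverage: np.ndarray
    frequency: np.ndarray
    lifespan: np.ndarray
    transition_matrix: np.ndarray
    n_transitions: np.ndarray
    K: int
    absent: np.ndarray = field(default=None)  # boolean per state

    def __post_init__(self):
        if self.absent is None:
            self.absent = self.coverage == 0.0

    @classmethod
    def from_labels(
        cls, labels, k: int, centroids: np.ndarray
    ) -> "SessionObservables":
        centroids = np.asarray(centroids, dtype=float)
        if centroids.shape[0] != k:
            raise ConfigurationError("need one centroid per state")
        return cls(
            centroids=centroids,
            coverage=coverage(labels, k),
            frequency=frequency(labels, k),
            lifespan=lifespan(labels, k),
            transition_matrix=transition_matrix(labels, k),
            n_transitions=transition_counts(labels, k),
            K=k,
        )

    @classmethod
    def from_partition(cls, part: StatePartition) -> "SessionObservables":
        return cls.from_labels(part.labels, part.K, part.centroids)

    def permuted(self, perm: np.ndarray) -> "SessionObservables":
        """Reindex states so entry ``l`` refers to old state ``perm[l]``
        (0-based permutation array)."""
        perm = np.asarray(perm, dtype=int)
        return SessionObservables(
            centroids=self.centroids[perm],
            coverage=self.coverage[perm],
            frequency=self.frequency[perm],
            lifespan=self.lifespan[perm],
            transition_matrix=self.transition_matrix[np.ix_(perm, perm)],
            n_transitions=self.n_transitions[np.ix_(perm, perm)],
            K=self.K,
            absent=self.absent[perm],
        )

    def to_dict(self) -> dict:
        return {
            "K": self.K,
            "centroids": self.centroids.tolist(),
            "coverage": self.coverage.tolist(),
            "frequency": self.frequency.tolist(),
            "lifespan": self.lifespan.tolist(),
            "transition_matrix": self.transition_matrix.tolist(),
            "n_transitions": self.n_transitions.tolist(),
        }
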