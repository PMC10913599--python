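"""State matching across sessions and per-observable discrepancy measures.

Two sessions' K states are matched by their centroids, either exhaustively
over all K! permutations (K up to a configurable cutover, default 8) or
greedily.  In cosine mode the matching maximizes the mean pairwise cosine
similarity; in euclidean mode it minimizes the mean squared distance.

The matching is computed once per session pair and reused for every
observable: centroid dissimilarity for the centroids, total variation for
coverage/frequency/lifespan, Frobenius distance for the transition matrix.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import permutations

import numpy as np

from ._errors import ConfigurationError
from .clustering import _cosine_matrix
from .observables import SessionObservables

OBSERVABLES = ("centroid", "coverage", "frequency", "lifespan", "transition")

#: largest K for which the exhaustive K! search is used by default
EXHAUSTIVE_CUTOVER = 8


@dataclass
class StateMatching:
    """Bijection from session-1 states to session-2 states.

    ``permutation[l]`` (0-based) is the session-2 state matched with
    session-1 state ``l``.  ``score`` is the mean matched cosine similarity
    (cosine mode) or the mean matched squared distance (euclidean mode).
    """

    permutation: np.ndarray
    score: float
    mode: str
    search: str

    def __post_init__(self):
        self.permutation = np.asarray(self.permutation, dtype=int)
        k = self.permutation.size
        if sorted(self.permutation.tolist()) != list(range(k)):
            raise ConfigurationError("matching must be a bijection")


@dataclass
class Discrepancy:
    observable: str
    value: float


def _pair_scores(c1: np.ndarray, c2: np.ndarray, mode: str) -> np.ndarray:
    """K x K matrix of pair scores; larger is better in both modes
    (euclidean distances are negated)."""
    c1 = np.asarray(c1, dtype=float)
    c2 = np.asarray(c2, dtype=float)
    if c1.shape != c2.shape:
        raise ConfigurationError("centroid sets must have identical shape")
    if mode == "cosine":
        return _cosine_matrix(c1, c2)
    if mode == "euclidean":
        diff = c1[:, None, :] - c2[None, :, :]
        return -np.einsum("ijn,ijn->ij", diff, diff)
    raise ConfigurationError(f"unknown mode {mode!r}")


def match_exhaustive(
    c1: np.ndarray, c2: np.ndarray, mode: str = "cosine"
) -> StateMatching:
    """Optimal matching by evaluating all K! permutations.

    Ties resolve to the lexicographically smallest permutation (the search
    enumerates permutations in lexicographic order and only strict
    improvements replace the incumbent).
    """
    scores = _pair_scores(c1, c2, mode)
    k = scores.shape[0]
    rows = np.arange(k)
    best_perm = None
    best = -np.inf
    for perm in permutations(range(k)):
        s = scores[rows, perm].sum()
        if s > best:
            best = s
            best_perm = perm
    mean = best / k if mode == "cosine" else -best / k
    return StateMatching(
        permutation=np.array(best_perm), score=mean, mode=mode, search="exhaustive"
    )


def match_greedy(
    c1: np.ndarray, c2: np.ndarray, mode: str = "cosine"
) -> StateMatching:
    """Greedy matching: repeatedly pair the unmatched (l, l') with the best
    score; ties resolve to the smallest (l, l') lexicographically."""
    scores = _pair_scores(c1, c2, mode)
    k = scores.shape[0]
    work = scores.copy()
    perm = np.full(k, -1, dtype=int)
    for _ in range(k):
        flat = int(np.argmax(work))  # first (smallest) flat index on ties
        i, j = divmod(flat, k)
        perm[i] = j
        work[i, :] = -np.inf
        work[:, j] = -np.inf
    total = scores[np.arange(k), perm].sum()
    mean = total / k if mode == "cosine" else -total / k
    return StateMatching(
        permutation=perm, score=mean, mode=mode, search="greedy"
    )


def match_states(
    c1: np.ndarray,
    c2: np.ndarray,
    mode: str = "cosine",
    search: str = "auto",
    cutover: int = EXHAUSTIVE_CUTOVER,
) -> StateMatching:
    """Dispatch to exhaustive search for K <= ``cutover``, else greedy."""
    k = np.asarray(c1).shape[0]
    if search == "auto":
        search = "exhaustive" if k <= cutover else "greedy"
    if search == "exhaustive":
        if k > cutover:
            raise ConfigurationError(
                f"exhaustive matching limited to K <= {cutover}; got K={k}"
            )
        return match_exhaustive(c1, c2, mode)
    if search == "greedy":
        return match_greedy(c1, c2, mode)
    raise ConfigurationError(f"unknown search {search!r}")


def centroid_dissimilarity(
    c1: np.ndarray, c2: np.ndarray, matching: StateMatching
) -> float:
    """1 - mean matched cosine similarity; lies in [0, 2]."""
    scores = _pair_scores(c1, c2, "cosine")
    k = scores.shape[0]
    return float(1.0 - scores[np.arange(k), matching.permutation].mean())


def mean_squared_centroid_distance(
    c1: np.ndarray, c2: np.ndarray, matching: StateMatching
) -> float:
    """Mean matched squared Euclidean centroid distance (euclidean mode)."""
    scores = _pair_scores(c1, c2, "euclidean")
    k = scores.shape[0]
    return float(-scores[np.arange(k), matching.permutation].mean())


def tv_distance(q_i, q_j) -> float:
    """Total variation: max componentwise absolute difference."""
    q_i = np.asarray(q_i, dtype=float)
    q_j = np.asarray(q_j, dtype=float)
    if q_i.shape != q_j.shape:
        raise ConfigurationError("vectors must have equal length")
    return float(np.max(np.abs(q_i - q_j)))


def frobenius_distance(p_i, p_j) -> float:
    """Frobenius norm of the difference of two aligned K x K matrices."""
    p_i = np.asarray(p_i, dtype=float)
    p_j = np.asarray(p_j, dtype=float)
    if p_i.shape != p_j.shape:
        raise ConfigurationError("matrices must have equal shape")
    return float(np.linalg.norm(p_i - p_j))


def session_discrepancy(
    obs_i: SessionObservables,
    obs_j: SessionObservables,
    observable: str,
    mode: str = "cosine",
    search: str = "auto",
) -> Discrepancy:
    """Discrepancy between two sessions for one observable.

    The state matching is computed once from the centroids and applied to all
    of session j's payloads before the observable-specific measure.
    """
    if obs_i.K != obs_j.K:
        raise ConfigurationError("sessions must have the same K")
    matching = match_states(obs_i.centroids, obs_j.centroids, mode, search)
    value = _apply_measure(obs_i, obs_j, matching, observable, mode)
    return Discrepancy(observable=observable, value=value)


def _apply_measure(
    obs_i: SessionObservables,
    obs_j: SessionObservables,
    matching: StateMatching,
    observable: str,
    mode: str,
) -> float:
    aligned = obs_j.permuted(matching.permutation)
    if observable == "centroid":
        if mode == "cosine":
            return centroid_dissimilarity(
                obs_i.centroids, obs_j.centroids, matching
            )
        return mean_squared_centroid_distance(
            obs_i.centroids, obs_j.centroids, matching
        )
    if observable == "coverage":
        return tv_distance(obs_i.coverage, aligned.coverage)
    if observable == "frequency":
        return tv_distance(obs_i.frequency, aligned.frequency)
    if observable == "lifespan":
        return tv_distance(obs_i.lifespan, aligned.lifespan)
    if observable == "transition":
        return frobenius_distance(
            obs_i.transition_matrix, aligned.transition_matrix
        )
    raise ConfigurationError(
        f"unknown observable {observable!r}; expected one of {OBSERVABLES}"
    )


def all_discrepancies(
    obs_i: SessionObservables,
    obs_j: SessionObservables,
    mode: str = "cosine",
    search: str = "auto",
) -> dict[str, float]:
    """All five discrepancies for one session pair, sharing one matching."""
    if obs_i.K != obs_j.K:
        raise ConfigurationError("sessions must have the same K")
    matching = match_states(obs_i.centroids, obs_j.centroids, mode, search)
    return {
        name: _apply_measure(obs_i, obs_j, matching, name, mode)
        for name in OBSERVABLES
    }
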