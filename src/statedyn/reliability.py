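"""Normalized distance (ND) statistic and its permutation test over a study.

ND is the ratio of the mean dissimilarity between sessions of *different*
participants (compared at the same session index) to the mean dissimilarity
between sessions of the *same* participant.  ND > 1 indicates that the
state-transition dynamics are more reproducible within than between
participants.

The permutation test shuffles the observable payloads uniformly across all
participant-session cells, recomputes ND for each of R replicates, and
reports the fraction of replicates with ND at least as large as the
empirical value (one-sided; ties count as exceedances).  All pairwise
dissimilarities are precomputed once per (method, K, observable), so a
replicate only re-indexes the cache.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from ._errors import ConfigurationError, DegenerateNDError
from .clustering import cluster
from .io_manifest import StudyManifest, load_session
from .matching import OBSERVABLES, all_discrepancies
from .observables import SessionObservables
from .preprocessing import SymmetryMap, apply_treatment

logger = logging.getLogger(__name__)

DEFAULT_R = 10_000
DEFAULT_METHODS = ("kmeans", "taahc", "bisecting_kmeans")
DEFAULT_KS = tuple(range(2, 11))


@dataclass
class ObservableGrid:
    """One observable's payloads on the rectangular participant x session grid.

    ``payloads[p][s]`` is the payload of participant ``p``'s session ``s``
    (0-based); payloads are whatever the discrepancy callable consumes.
    """

    payloads: list[list]
    observable: str = ""
    method: str = ""
    K: int = 0

    def __post_init__(self):
        lengths = {len(row) for row in self.payloads}
        if len(lengths) > 1:
            raise ConfigurationError("grid must be rectangular")

    @property
    def n_participants(self) -> int:
        return len(self.payloads)

    @property
    def n_sessions(self) -> int:
        return len(self.payloads[0])

    def flat(self) -> list:
        return [q for row in self.payloads for q in row]


@dataclass
class NDResult:
    """Empirical ND, permutation null sample and p-value for one test cell."""

    nd: float
    null_sample: np.ndarray
    p_value: float
    R: int
    seed: int | None = None
    below_resolution: bool = False  # zero exceedances: report as p < 1/R
    n_degenerate: int = 0
    two_sided: bool = False

    def p_display(self) -> str:
        return f"< {1.0 / self.R:g}" if self.below_resolution else f"{self.p_value:g}"


def pair_indices(n_p: int, n_s: int) -> tuple[np.ndarray, np.ndarray]:
    """Flat-cell index pairs entering the ND denominator and numerator.

    Cells are flattened as ``cell = p * n_s + s``.  Returns
    ``(within, between)`` integer arrays of shape (n_pairs, 2): ``within``
    holds all unordered pairs of distinct sessions of the same participant;
    ``between`` holds all unordered pairs of distinct participants compared
    at a common session index.
    """
    within = [
        (p * n_s + s, p * n_s + s2)
        for p in range(n_p)
        for s in range(n_s)
        for s2 in range(s)
    ]
    between = [
        (p * n_s + s, p2 * n_s + s)
        for s in range(n_s)
        for p in range(n_p)
        for p2 in range(p)
    ]
    return np.array(within, dtype=int), np.array(between, dtype=int)


def pairwise_cache(payloads: list, discrepancy) -> np.ndarray:
    """Symmetric M x M matrix of all pairwise dissimilarities."""
    m = len(payloads)
    d = np.zeros((m, m))
    for i in range(m):
        for j in range(i):
            d[i, j] = d[j, i] = discrepancy(payloads[i], payloads[j])
    return d


def nd_from_cache(
    d: np.ndarray, assignment: np.ndarray, n_p: int, n_s: int
) -> float:
    """ND for one assignment of cached payloads to grid cells."""
    within, between = pair_indices(n_p, n_s)
    a = np.asarray(assignment, dtype=int)
    num = d[a[between[:, 0]], a[between[:, 1]]].mean()
    den = d[a[within[:, 0]], a[within[:, 1]]].mean()
    if den == 0.0:
        raise DegenerateNDError(
            "all within-participant session pairs are identical (ND denominator 0)"
        )
    return float(num / den)


def compute_nd(grid: ObservableGrid, discrepancy) -> float:
    """Empirical ND of an observable grid under a pairwise discrepancy."""
    n_p, n_s = grid.n_participants, grid.n_sessions
    if n_p < 2 or n_s < 2:
        raise ConfigurationError("need at least 2 participants and 2 sessions")
    d = pairwise_cache(grid.flat(), discrepancy)
    return nd_from_cache(d, np.arange(n_p * n_s), n_p, n_s)


def _null_nds(
    d: np.ndarray,
    n_p: int,
    n_s: int,
    r: int,
    rng: np.random.Generator,
) -> tuple[np.ndarray, int]:
    """Vectorized ND for r uniformly random cell permutations.

    Degenerate replicates (zero denominator) come back as +inf; their count
    is returned alongside.
    """
    m = n_p * n_s
    within, between = pair_indices(n_p, n_s)
    perms = rng.permuted(np.tile(np.arange(m), (r, 1)), axis=1)
    num = d[perms[:, between[:, 0]], perms[:, between[:, 1]]].mean(axis=1)
    den = d[perms[:, within[:, 0]], perms[:, within[:, 1]]].mean(axis=1)
    degenerate = den == 0.0
    n_deg = int(degenerate.sum())
    out = np.full(r, np.inf)
    ok = ~degenerate
    out[ok] = num[ok] / den[ok]
    return out, n_deg


def permutation_test_from_cache(
    d: np.ndarray,
    n_p: int,
    n_s: int,
    r: int = DEFAULT_R,
    seed: int | None = None,
    two_sided: bool = False,
) -> NDResult:
    """Permutation test given a precomputed pairwise dissimilarity cache."""
    nd = nd_from_cache(d, np.arange(n_p * n_s), n_p, n_s)
    rng = np.random.default_rng(seed)
    null, n_deg = _null_nds(d, n_p, n_s, r, rng)
    if n_deg:
        logger.warning(
            "%d of %d permutation replicates were degenerate; counted as "
            "exceedances",
            n_deg,
            r,
        )
    if two_sided:
        exceed = np.abs(null - 1.0) >= abs(nd - 1.0)
    else:
        exceed = null >= nd
    n_exceed = int(exceed.sum())
    return NDResult(
        nd=nd,
        null_sample=null,
        p_value=n_exceed / r,
        R=r,
        seed=seed,
        below_resolution=n_exceed == 0,
        n_degenerate=n_deg,
        two_sided=two_sided,
    )


def permutation_test(
    grid: ObservableGrid,
    discrepancy,
    r: int = DEFAULT_R,
    seed: int | None = None,
    two_sided: bool = False,
) -> NDResult:
    """Permutation test of ND for one observable grid."""
    n_p, n_s = grid.n_participants, grid.n_sessions
    if n_p < 2 or n_s < 2:
        raise ConfigurationError("need at least 2 participants and 2 sessions")
    d = pairwise_cache(grid.flat(), discrepancy)
    return permutation_test_from_cache(d, n_p, n_s, r, seed, two_sided)


def _session_seed(master: int | None, index: int, method: str, k: int) -> int:
    """Deterministic per-(session, method, K) clustering seed."""
    m_idx = DEFAULT_METHODS.index(method) if method in DEFAULT_METHODS else 97
    base = 0 if master is None else int(master)
    return int(
        np.random.default_rng([base, index, m_idx, k]).integers(2**31 - 1)
    )


def observable_grids(
    sessions: list[list[np.ndarray]],
    method: str,
    k: int,
    seed: int | None = None,
) -> list[list[SessionObservables]]:
    """Cluster every session and compute its observables.

    ``sessions[p][s]`` is the preprocessed T x N matrix of participant p's
    session s.
    """
    out = []
    idx = 0
    for row in sessions:
        obs_row = []
        for x in row:
            part = cluster(x, k, method, seed=_session_seed(seed, idx, method, k))
            obs_row.append(SessionObservables.from_partition(part))
            idx += 1
        out.append(obs_row)
    return out


def discrepancy_caches(
    obs: list[list[SessionObservables]],
    mode: str = "cosine",
    search: str = "auto",
) -> dict[str, np.ndarray]:
    """One pairwise cache per observable, sharing one matching per pair."""
    flat = [o for row in obs for o in row]
    m = len(flat)
    caches = {name: np.zeros((m, m)) for name in OBSERVABLES}
    for i in range(m):
        for j in range(i):
            vals = all_discrepancies(flat[i], flat[j], mode=mode, search=search)
            for name, v in vals.items():
                caches[name][i, j] = caches[name][j, i] = v
    return caches


def load_study_matrices(
    manifest: StudyManifest,
    treatment: str = "none",
    sym: SymmetryMap | None = None,
) -> list[list[np.ndarray]]:
    """Load and preprocess every session matrix in manifest order."""
    out = []
    for pid in manifest.participants:
        row = []
        for sid, path in manifest.sessions(pid):
            ts = load_session(path, pid, sid)
            row.append(apply_treatment(ts.data, treatment, sym=sym))
        out.append(row)
    return out


@dataclass
class StudyResult:
    records: list[dict] = field(default_factory=list)
    nd_results: dict = field(default_factory=dict)  # (method, K, obs) -> NDResult
    n_comparisons: int = 0
    bonferroni_threshold: float = 0.0


def run_study(
    sessions: list[list[np.ndarray]],
    methods=DEFAULT_METHODS,
    ks=DEFAULT_KS,
    observables=OBSERVABLES,
    mode: str = "cosine",
    search: str = "auto",
    r: int = DEFAULT_R,
    seed: int | None = None,
    n_comparisons: int | None = None,
    alpha: float = 0.05,
    two_sided: bool = False,
) -> StudyResult:
    """Full reliability analysis: one permutation test per (method, K,
    observable) cell, with significance flags at 0.05, 0.001 and the
    Bonferroni-corrected 0.05 threshold.

    ``sessions[p][s]`` are preprocessed T x N matrices (see
    :func:`load_study_matrices`).
    """
    cells = [
        (method, k, name)
        for method in methods
        for k in ks
        for name in observables
    ]
    if n_comparisons is None:
        n_comparisons = len(cells)
    bonf = alpha / n_comparisons

    n_p = len(sessions)
    n_s = len(sessions[0])
    result = StudyResult(
        n_comparisons=n_comparisons, bonferroni_threshold=bonf
    )
    for method in methods:
        for k in ks:
            obs = observable_grids(sessions, method, k, seed=seed)
            caches = discrepancy_caches(obs, mode=mode, search=search)
            for name in observables:
                if (method, k, name) not in cells:  # pragma: no cover
                    continue
                cell_seed = _session_seed(seed, 10_000 + k, method, hash(name) % 1000)
                try:
                    nd_res = permutation_test_from_cache(
                        caches[name], n_p, n_s, r=r, seed=cell_seed, two_sided=two_sided
                    )
                    nd_val, p_val = nd_res.nd, nd_res.p_value
                    result.nd_results[(method, k, name)] = nd_res
                except DegenerateNDError:
                    # e.g. K=2 transition matrices are structurally identical
                    # across sessions; keep the cell, flag it unusable
                    logger.warning(
                        "degenerate ND for (%s, K=%d, %s); recording NaN",
                        method,
                        k,
                        name,
                    )
                    nd_val = p_val = float("nan")
                result.records.append(
                    {
                        "method": method,
                        "K": k,
                        "observable": name,
                        "nd": nd_val,
                        "p_value": p_val,
                        "sig_05": p_val < 0.05,
                        "sig_001": p_val < 0.001,
                        "sig_bonf": p_val < bonf,
                    }
                )
    return result
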