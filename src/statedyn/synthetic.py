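"""Synthetic multi-participant, multi-session ROI time series.

Each participant gets a rotated copy of K shared base state centroids and a
perturbed copy of a shared Markov transition matrix; each session simulates
the participant's chain for T volumes and emits the current state's centroid
plus Gaussian noise.  Every emitted volume is standardized to mean 0 and
population SD 1 across ROIs, so downstream code can assume the
post-global-signal-removal convention (sigma_t = 1).

Participant-specific structure is controlled by two knobs: the rotation
angle scale (``participant_divergence``, radians) acting on centroids, and
the multiplicative log-normal jitter on off-diagonal transition rates
(``transition_jitter``).  With both at 0 all participants share identical
dynamics, which is the null case for calibrating the permutation test.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.linalg import expm

from ._errors import ConfigurationError
from .clustering import cluster
from .io_manifest import (
    RoiTimeSeries,
    StudyManifest,
    write_manifest,
    write_session,
)
from .matching import (
    frobenius_distance,
    match_states,
    tv_distance,
)
from .observables import SessionObservables

logger = logging.getLogger(__name__)

#: attempts to draw base centroids obeying the pairwise-angle floor
_MAX_DRAWS = 5000


@dataclass
class SyntheticSpec:
    """Parameters of one synthetic study."""

    n_participants: int = 4
    n_sessions: int = 4
    t_volumes: int = 300
    n_rois: int = 8
    k_states: int = 4
    dwell_prob: float = 0.6
    participant_divergence: float = 0.0
    noise_sd: float = 0.3
    transition_jitter: float = 0.0
    seed: int | None = 0
    min_angle_deg: float = 60.0

    def __post_init__(self):
        if not (0.0 <= self.dwell_prob < 1.0):
            raise ConfigurationError("dwell_prob must lie in [0, 1)")
        if self.noise_sd <= 0.0:
            raise ConfigurationError("noise_sd must be > 0")
        if self.participant_divergence < 0.0 or self.transition_jitter < 0.0:
            raise ConfigurationError("divergence/jitter must be >= 0")
        if self.k_states < 2:
            raise ConfigurationError("k_states must be >= 2")
        if self.k_states > self.n_rois:
            warnings.warn(
                "k_states exceeds n_rois; state centroids cannot be "
                "linearly independent",
                stacklevel=2,
            )


@dataclass
class GroundTruth:
    """Latent quantities behind one synthetic study."""

    base_centroids: np.ndarray  # K x N, row-standardized
    participant_centroids: np.ndarray  # N_p x K x N, row-standardized
    participant_transitions: np.ndarray  # N_p x K x K, zero diag, rows sum to 1
    dwell_prob: float
    labels: list[list[np.ndarray]] = field(default_factory=list)  # 1-based


@dataclass
class SyntheticStudy:
    spec: SyntheticSpec
    sessions: list[list[RoiTimeSeries]]
    truth: GroundTruth

    def matrices(self) -> list[list[np.ndarray]]:
        return [[ts.data for ts in row] for row in self.sessions]


def _standardize_rows(x: np.ndarray) -> np.ndarray:
    sd = x.std(axis=1, keepdims=True)
    if np.any(sd == 0.0):
        raise ConfigurationError("cannot standardize a constant row")
    return (x - x.mean(axis=1, keepdims=True)) / sd


def _draw_base_centroids(
    k: int, n: int, min_angle_deg: float, rng: np.random.Generator
) -> np.ndarray:
    """Unit vectors with pairwise angle >= the floor, then row-standardized."""
    cos_cap = np.cos(np.deg2rad(min_angle_deg))
    for _ in range(_MAX_DRAWS):
        c = rng.standard_normal((k, n))
        c /= np.linalg.norm(c, axis=1, keepdims=True)
        gram = c @ c.T
        if np.max(gram[~np.eye(k, dtype=bool)]) <= cos_cap:
            return _standardize_rows(c)
    raise ConfigurationError(
        f"cannot place {k} centroids in {n} dims with pairwise angle "
        f">= {min_angle_deg} deg"
    )


def _random_rotation(n: int, angle: float, rng: np.random.Generator) -> np.ndarray:
    """Rotation of magnitude ~ ``angle`` radians via a normalized skew matrix."""
    if angle == 0.0:
        return np.eye(n)
    a = rng.standard_normal((n, n))
    skew = a - a.T
    norm = np.linalg.norm(skew, 2)
    return expm(angle * skew / norm)


def _participant_transition(
    k: int, dwell: float, jitter: float, rng: np.random.Generator
) -> np.ndarray:
    """Full K x K chain matrix: diagonal = dwell, jittered off-diagonals
    renormalized to share 1 - dwell per row."""
    off = np.full((k, k), 1.0)
    if jitter > 0.0:
        off *= np.exp(jitter * rng.standard_normal((k, k)))
    np.fill_diagonal(off, 0.0)
    off *= (1.0 - dwell) / off.sum(axis=1, keepdims=True)
    full = off.copy()
    np.fill_diagonal(full, dwell)
    return full


def _off_diagonal_normalized(full: np.ndarray) -> np.ndarray:
    """Recovery target: zero-diagonal, row-normalized transition matrix."""
    off = full.copy()
    np.fill_diagonal(off, 0.0)
    return off / off.sum(axis=1, keepdims=True)


def _simulate_chain(
    full: np.ndarray, t: int, rng: np.random.Generator
) -> np.ndarray:
    k = full.shape[0]
    labels = np.empty(t, dtype=int)
    state = int(rng.integers(k))
    for i in range(t):
        labels[i] = state
        state = int(rng.choice(k, p=full[state]))
    return labels + 1


def generate_study(spec: SyntheticSpec) -> SyntheticStudy:
    """Generate a full rectangular synthetic study with ground truth."""
    rng = np.random.default_rng(spec.seed)
    k, n = spec.k_states, spec.n_rois
    base = _draw_base_centroids(k, n, spec.min_angle_deg, rng)

    part_centroids = np.empty((spec.n_participants, k, n))
    part_trans_full = np.empty((spec.n_participants, k, k))
    for p in range(spec.n_participants):
        rot = _random_rotation(n, spec.participant_divergence, rng)
        part_centroids[p] = _standardize_rows(base @ rot.T)
        part_trans_full[p] = _participant_transition(
            k, spec.dwell_prob, spec.transition_jitter, rng
        )

    sessions: list[list[RoiTimeSeries]] = []
    truth_labels: list[list[np.ndarray]] = []
    for p in range(spec.n_participants):
        row, label_row = [], []
        for s in range(spec.n_sessions):
            labels = _simulate_chain(part_trans_full[p], spec.t_volumes, rng)
            x = part_centroids[p][labels - 1] + spec.noise_sd * rng.standard_normal(
                (spec.t_volumes, n)
            )
            x = _standardize_rows(x)
            row.append(
                RoiTimeSeries(
                    participant_id=f"p{p + 1:02d}",
                    session_id=f"s{s + 1:02d}",
                    data=x,
                )
            )
            label_row.append(labels)
        sessions.append(row)
        truth_labels.append(label_row)

    truth = GroundTruth(
        base_centroids=base,
        participant_centroids=part_centroids,
        participant_transitions=np.stack(
            [_off_diagonal_normalized(m) for m in part_trans_full]
        ),
        dwell_prob=spec.dwell_prob,
        labels=truth_labels,
    )
    return SyntheticStudy(spec=spec, sessions=sessions, truth=truth)


def write_study(study: SyntheticStudy, out_dir) -> StudyManifest:
    """Write per-session CSVs, the manifest and the ground-truth JSON."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    entries = []
    for row in study.sessions:
        for ts in row:
            name = f"{ts.participant_id}_{ts.session_id}.csv"
            write_session(ts, out_dir / name)
            entries.append((ts.participant_id, ts.session_id, out_dir / name))
    manifest = StudyManifest(entries=entries)
    write_manifest(manifest, out_dir / "manifest.csv")
    truth = study.truth
    payload = {
        "spec": {
            k: v for k, v in vars(study.spec).items() if not k.startswith("_")
        },
        "base_centroids": truth.base_centroids.tolist(),
        "participant_centroids": truth.participant_centroids.tolist(),
        "participant_transitions": truth.participant_transitions.tolist(),
        "dwell_prob": truth.dwell_prob,
        "labels": [[lab.tolist() for lab in row] for row in truth.labels],
    }
    with open(out_dir / "ground_truth.json", "w") as fh:
        json.dump(payload, fh)
    return manifest


@dataclass
class SessionRecovery:
    participant: int
    session: int
    centroid_cosine: float  # mean matched cosine of estimated vs true centroids
    label_accuracy: float
    coverage_tv: float
    frequency_tv: float
    lifespan_tv: float
    transition_frobenius: float  # estimated P vs the generator's target matrix


def recover_parameters(
    study: SyntheticStudy, method: str = "kmeans", seed: int | None = 0
) -> list[SessionRecovery]:
    """Cluster every session with the spec's K and score recovery of the
    ground truth after optimal (cosine, exhaustive) state matching."""
    spec = study.spec
    reports = []
    counter = 0
    for p, row in enumerate(study.sessions):
        true_c = study.truth.participant_centroids[p]
        target_p = study.truth.participant_transitions[p]
        for s, ts in enumerate(row):
            part = cluster(
                ts.data, spec.k_states, method, seed=None if seed is None else seed + counter
            )
            counter += 1
            est = SessionObservables.from_partition(part)
            true_labels = study.truth.labels[p][s]
            true_obs = SessionObservables.from_labels(
                true_labels, spec.k_states, true_c
            )
            # perm[l] = estimated state matched with true state l (0-based)
            matching = match_states(true_c, est.centroids, mode="cosine")
            perm = matching.permutation
            aligned = est.permuted(perm)
            accuracy = float(
                np.mean((perm[true_labels - 1] + 1) == part.labels)
            )
            reports.append(
                SessionRecovery(
                    participant=p,
                    session=s,
                    centroid_cosine=matching.score,
                    label_accuracy=accuracy,
                    coverage_tv=tv_distance(true_obs.coverage, aligned.coverage),
                    frequency_tv=tv_distance(
                        true_obs.frequency, aligned.frequency
                    ),
                    lifespan_tv=tv_distance(true_obs.lifespan, aligned.lifespan),
                    transition_frobenius=frobenius_distance(
                        target_p, aligned.transition_matrix
                    ),
                )
            )
    return reports
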