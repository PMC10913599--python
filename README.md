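# statedyn

Clustering-based estimation of discrete brain states from ROI-level fMRI
time series, and a permutation-based test–retest reliability analysis of the
resulting state-transition dynamics.

The pipeline:

1. **Preprocessing** — per-volume global signal removal (subtract the
   across-ROI mean, divide by the across-ROI population SD), optional
   averaging of symmetric left/right ROI pairs, composed into three standard
   treatments (plus pass-through).
2. **Clustering** — seven methods estimate K discrete states per session:
   `kmeans`, `kmedoids`, `ward`, `aahc`, `taahc`, `bisecting_kmeans`, `gmm`.
   Quality is scored by total global explained variance (GEV, GFP-weighted
   squared cosine similarity) and within-cluster sum of squares (WCSS).
3. **Observables** — per session: state centroids, coverage, frequency of
   appearance, average lifespan, and the zero-diagonal transition
   probability matrix.
4. **Matching & discrepancy** — states of two sessions are matched by
   centroid similarity (exhaustive over K! permutations for K ≤ 8, greedy
   above; cosine or squared-Euclidean mode); discrepancies are centroid
   dissimilarity, total variation (coverage/frequency/lifespan) and the
   Frobenius distance (transition matrix).
5. **Reliability** — the normalized distance ND (mean between-participant /
   mean within-participant session dissimilarity) with a permutation test
   that shuffles observable payloads across all participant–session cells
   (default R = 10⁴), plus significance flags at 0.05, 0.001 and the
   Bonferroni-corrected 0.05 threshold.
6. **Synthetic data** — a seeded generator of rectangular multi-participant,
   multi-session studies with latent Markov state dynamics (participant-
   specific centroid rotations and transition jitter), used by the test
   suite and the acceptance harness.

## Library quick start

```python
import numpy as np
from statedyn import cluster, gev_total, SessionObservables, all_discrepancies
from statedyn.synthetic import SyntheticSpec, generate_study
from statedyn.reliability import run_study

study = generate_study(SyntheticSpec(n_participants=4, n_sessions=4,
                                     participant_divergence=0.5, seed=0))
part = cluster(study.sessions[0][0].data, k=4, method="kmeans", seed=0)
print(gev_total(study.sessions[0][0].data, part, np.ones(part.labels.size)))

result = run_study(study.matrices(), methods=["kmeans"], ks=[4], r=1000, seed=0)
for rec in result.records:
    print(rec["observable"], rec["nd"], rec["p_value"])
```

## CLI

```sh
statedyn simulate --config spec.yaml --out study/          # synthetic study
statedyn preprocess IN.csv OUT.csv --treatment 2 --symmetry-map sym.csv
statedyn cluster IN.csv OUT.labels.csv OUT.centroids.csv --method kmeans --k 4 --seed 0
statedyn observables OUT.labels.csv --k 4 --centroids OUT.centroids.csv
statedyn compare A.labels A.centroids B.labels B.centroids --mode cosine
statedyn reliability --manifest study/manifest.csv --methods kmeans,taahc,bisecting_kmeans \
    --k-min 2 --k-max 10 --permutations 10000 --seed 0 --out results.csv
```

Session matrices are delimited text (rows = volumes, columns = ROIs); the
manifest is a CSV with header `participant,session,file` and must be
rectangular (same number of sessions per participant). Results CSVs have
columns `method,K,observable,nd,p_value,sig_05,sig_001,sig_bonf`.

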