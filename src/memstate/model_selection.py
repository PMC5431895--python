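"""GMRQ cross-validation over featurizations and hyperparameters.

A candidate model (featurization, tICA lag t, ridge strength g, state
count k) is fitted on a random subset of the trajectories and scored on
the held-out remainder with the generalized matrix Rayleigh quotient:
with A the leading m training eigenvectors in the state-indicator
basis,

    score = trace[ (A' S_test A)^+ (A' Cbar_test A) ]

where Cbar_test and S_test are the symmetrized lagged-correlation and
instantaneous-overlap matrices of the test state sequences at the MSM
lag.  Scoring a model on its own training data returns exactly the sum
of its first m eigenvalues (the variational identity), and every score
is bounded above by m.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field

import numpy as np
import scipy.linalg

from .featurize import FeatureSpec
from .msm import (DEFAULT_MSM_LAG, MSMModel, assign, count_transitions,
                  estimate_msm, fit_minibatch_kmeans)
from .tica import fit_tica, transform_all

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SplitSpec:
    """One trajectory-level train/test split."""

    train: tuple[int, ...]
    test: tuple[int, ...]
    repeat: int
    seed: int

    def __post_init__(self) -> None:
        if not self.train or not self.test:
            raise ValueError("train and test sets must both be non-empty")
        if set(self.train) & set(self.test):
            raise ValueError("train and test sets must be disjoint")


def shuffle_split(trajectory_ids, test_fraction: float, n_repeats: int,
                  seed: int = 0) -> list[SplitSpec]:
    """Repeated random trajectory-level splits (reproducible per seed)."""
    ids = list(trajectory_ids)
    if len(ids) < 2:
        raise ValueError("shuffle_split needs at least two trajectories")
    if not 0.0 < test_fraction < 1.0:
        raise ValueError("test_fraction must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    n_test = int(np.clip(round(test_fraction * len(ids)), 1, len(ids) - 1))
    splits = []
    for rep in range(n_repeats):
        perm = rng.permutation(len(ids))
        test = tuple(sorted(ids[i] for i in perm[:n_test]))
        train = tuple(sorted(ids[i] for i in perm[n_test:]))
        splits.append(SplitSpec(train=train, test=test, repeat=rep, seed=seed))
    return splits


def _training_eigenvectors(train_msm: MSMModel, m: int) -> tuple[np.ndarray, np.ndarray]:
    """Leading m eigenpairs of the symmetrized training count matrices.

    Solves ``Csym v = lambda diag(rowsum) v`` on the active set (the
    common scale of the two matrices cancels in the Rayleigh quotient)
    and embeds the S-orthonormal eigenvectors into the full state space
    with zero loadings on trimmed states.
    """
    c = train_msm.counts
    csym = c + c.T
    s = csym.sum(axis=1)
    w, v = scipy.linalg.eigh(csym, np.diag(s))
    order = np.argsort(w)[::-1][:m]
    a = np.zeros((train_msm.n_states_full, len(order)))
    a[train_msm.active_set] = v[:, order]
    return w[order], a


def gmrq_score(train_msm: MSMModel, test_states: list[np.ndarray],
               frame_interval: float, m: int = 6,
               cluster_model=None) -> float:
    """GMRQ of the training eigenvectors evaluated on test state sequences.

    ``test_states`` must be assigned with the training cluster model (the
    nearest-center rule is defined for any point).  Transitions through
    states outside the training active set are ignored; states never
    visited in the test data contribute zero rows and columns, handled
    by a pseudo-inverse with rank logging.
    """
    del cluster_model  # assignment happens upstream; kept for interface clarity
    _, a = _training_eigenvectors(train_msm, m)
    ct_full = count_transitions(test_states, train_msm.lag_time, frame_interval,
                                n_states=train_msm.n_states_full)
    act = train_msm.active_set
    ct = ct_full[np.ix_(act, act)]
    csym = ct + ct.T
    s = csym.sum(axis=1)
    a_act = a[act]
    corr = a_act.T @ csym @ a_act
    overlap = (a_act * s[:, None]).T @ a_act
    rank = np.linalg.matrix_rank(overlap, tol=1e-10)
    if rank < m:
        logger.warning("GMRQ overlap matrix rank %d < m=%d (unvisited test states)", rank, m)
    score = float(np.trace(np.linalg.pinv(overlap, rcond=1e-10) @ corr))
    assert score <= m + 1e-8, f"GMRQ score {score} exceeds the variational bound m={m}"
    return score


@dataclass
class GMRQResult:
    """Cross-validated scores for one (featurization, t, g, k) candidate."""

    spec: FeatureSpec
    lag_time: float  # tICA lag t, ns
    gamma: float
    k: int
    m: int
    train_scores: list[float] = field(default_factory=list)
    test_scores: list[float] = field(default_factory=list)
    errors: list[str] = field(default_factory=list)

    @property
    def mean_test(self) -> float:
        return float(np.mean(self.test_scores)) if self.test_scores else float("nan")

    @property
    def mean_train(self) -> float:
        return float(np.mean(self.train_scores)) if self.train_scores else float("nan")


def _derived_seed(*parts) -> int:
    digest = hashlib.sha256(repr(parts).encode()).digest()
    return int.from_bytes(digest[:4], "little") % (2**31)


def evaluate_candidate(features, splits, lag_time, gamma, k, msm_lag, m,
                       n_tics, seed, spec=None) -> GMRQResult:
    """Fit tICA -> k-means -> MSM on each training split and score both ways."""
    result = GMRQResult(spec=spec, lag_time=lag_time, gamma=gamma, k=k, m=m)
    frame_interval = features[0].frame_interval
    for split in splits:
        try:
            train_f = [features[i] for i in split.train]
            test_f = [features[i] for i in split.test]
            model = fit_tica(train_f, lag_time, gamma, n_components=n_tics)
            tics_train = transform_all(model, train_f)
            tics_test = transform_all(model, test_f)
            km_seed = _derived_seed(seed, spec.label if spec else "", lag_time,
                                    gamma, k, split.repeat)
            km = fit_minibatch_kmeans(tics_train, k, seed=km_seed)
            train_states = assign(km, tics_train)
            test_states = assign(km, tics_test)
            train_msm = estimate_msm(train_states, msm_lag, frame_interval, n_states=k)
            result.train_scores.append(
                gmrq_score(train_msm, train_states, frame_interval, m))
            result.test_scores.append(
                gmrq_score(train_msm, test_states, frame_interval, m))
        except Exception as exc:  # individual fit failures are recorded, not fatal
            result.errors.append(f"repeat {split.repeat}: {exc}")
            logger.warning("GMRQ candidate failed on repeat %d: %s", split.repeat, exc)
    return result


def hyperparameter_search(features_by_spec, t_grid, g_grid, k_grid, splits,
                          msm_lag: float = DEFAULT_MSM_LAG, m: int = 6,
                          n_tics: int = 4, seed: int = 0) -> list[GMRQResult]:
    """Exhaustive grid search, ranked by mean held-out GMRQ score.

    ``features_by_spec`` maps each :class:`FeatureSpec` to its list of
    per-trajectory feature matrices.  Candidates whose every split
    failed are ranked last and carry their failure reasons.
    """
    if not (len(t_grid) and len(g_grid) and len(k_grid)):
        raise ValueError("hyperparameter grids must be non-empty")
    results = []
    for spec, features in features_by_spec.items():
        for t in t_grid:
            for g in g_grid:
                for k in k_grid:
                    results.append(
                        evaluate_candidate(features, splits, t, g, int(k),
                                           msm_lag, m, n_tics, seed, spec=spec)
                    )
    results.sort(key=lambda r: (-(r.mean_test if np.isfinite(r.mean_test) else -np.inf),
                                r.spec or FeatureSpec(protein="dihedrals")))
    return results


def top_featurizations(results: list[GMRQResult], n: int = 5) -> list[FeatureSpec]:
    """Best featurizations: best hyperparameters per spec, then top n specs."""
    if not results:
        raise ValueError("no search results to rank")
    best: dict[FeatureSpec, GMRQResult] = {}
    for r in results:
        if not np.isfinite(r.mean_test):
            continue
        cur = best.get(r.spec)
        if cur is None or r.mean_test > cur.mean_test:
            best[r.spec] = r
    ranked = sorted(best.values(), key=lambda r: (-r.mean_test, r.spec))
    if n > len(ranked):
        logger.warning("requested top %d featurizations but only %d available",
                       n, len(ranked))
    return [r.spec for r in ranked[:n]]


def results_to_records(results: list[GMRQResult]) -> list[dict]:
    """Flatten search results to per-split records (for CSV/JSON output)."""
    records = []
    for r in results:
        for i, (tr, te) in enumerate(zip(r.train_scores, r.test_scores)):
            records.append(
                {
                    "featurization": r.spec.label if r.spec else "",
                    "t_ns": r.lag_time,
                    "gamma": r.gamma,
                    "k": r.k,
                    "split": i,
                    "train_score": tr,
                    "test_score": te,
                    "m": r.m,
                    "eigenvector_convention": "stationary eigenvector included",
                }
            )
    return records
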