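"""Representational similarity analysis across areas.

A condition (cue angle) is summarized by a pattern vector: the
channel-by-channel correlation structure over time of each trial's
potentials, vectorized (upper triangle) and averaged over the trials of
that condition. Conditions are compared within an area by a
representational dissimilarity matrix (RDM) with entries
``1 - Pearson(pattern_i, pattern_j)``; two areas are compared by the
*deviation* ``1 - Spearman`` between their RDMs' vectorized upper
triangles (Spearman because no linear correspondence between the two
matrices is assumed). Significance of an RDM match uses a fixed-effects
randomization test that relabels the conditions of one RDM (rows and
columns permuted together, preserving symmetry) and counts how often the
null association reaches the observed one, with a +1 correction so the
p-value is never exactly zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "RDM",
    "DeviationResult",
    "trial_patterns",
    "condition_pattern",
    "build_rdm",
    "deviation",
    "randomization_test",
    "deviation_stderr",
]


def _pattern_from_trial(trial_data: np.ndarray) -> np.ndarray:
    """Upper triangle of the channels x channels time-correlation matrix."""
    X = np.asarray(trial_data, dtype=float)
    if X.ndim != 2:
        raise ValueError("trial data must be channels x time")
    sd = X.std(axis=1)
    if np.any(sd == 0):
        raise ValueError("constant channel: time correlation undefined (zero variance)")
    corr = np.corrcoef(X)
    iu = np.triu_indices(X.shape[0], k=1)
    return corr[iu]


def trial_patterns(data: np.ndarray) -> np.ndarray:
    """Per-trial pattern vectors from (trials x channels x time) data."""
    data = np.asarray(data, dtype=float)
    if data.ndim != 3:
        raise ValueError("data must be trials x channels x time")
    return np.stack([_pattern_from_trial(tr) for tr in data])


def condition_pattern(rec_or_data, angle: float | None = None) -> np.ndarray:
    """Condition pattern: trial patterns averaged over the condition's trials.

    Accepts an LFPRecording plus a cue angle, or directly a
    (trials x channels x time) array of the condition's trials.
    """
    if angle is not None:
        data = rec_or_data.trials_for_angle(angle)
    else:
        data = np.asarray(rec_or_data, dtype=float)
    if data.shape[0] < 2:
        raise ValueError("need at least 2 trials for a condition pattern")
    return trial_patterns(data).mean(axis=0)


@dataclass
class RDM:
    """Condition-wise representational dissimilarity matrix (1 - Pearson)."""

    matrix: np.ndarray
    condition_labels: np.ndarray
    source: str = "lfp"  # {"field", "activity", "lfp"}
    area: str = ""

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise ValueError("RDM must be square")
        if not np.allclose(m, m.T, atol=1e-12):
            raise ValueError("RDM must be symmetric")
        if not np.allclose(np.diag(m), 0.0, atol=1e-12):
            raise ValueError("RDM diagonal must be zero")
        object.__setattr__(self, "matrix", m)

    @property
    def n_conditions(self) -> int:
        return self.matrix.shape[0]

    def upper(self) -> np.ndarray:
        iu = np.triu_indices(self.n_conditions, k=1)
        return self.matrix[iu]


def build_rdm(
    patterns: dict[float, np.ndarray], source: str = "lfp", area: str = ""
) -> RDM:
    """RDM from per-condition pattern vectors; entry (i, j) = 1 - Pearson."""
    labels = sorted(patterns)
    if len(labels) < 3:
        raise ValueError("need at least 3 conditions")
    P = np.stack([np.asarray(patterns[a], dtype=float).ravel() for a in labels])
    if np.any(P.std(axis=1) == 0):
        raise ValueError("zero-variance pattern: correlation undefined")
    corr = np.corrcoef(P)
    m = 1.0 - corr
    np.fill_diagonal(m, 0.0)
    m = 0.5 * (m + m.T)
    return RDM(m, np.asarray(labels, dtype=float), source=source, area=area)


def _as_matrix(rdm) -> np.ndarray:
    return rdm.matrix if isinstance(rdm, RDM) else np.asarray(rdm, dtype=float)


def deviation(rdm_a, rdm_b) -> float:
    """1 - Spearman rank correlation of the vectorized upper triangles."""
    A, B = _as_matrix(rdm_a), _as_matrix(rdm_b)
    if A.shape != B.shape:
        raise ValueError("RDMs must have matching condition sets")
    n = A.shape[0]
    iu = np.triu_indices(n, k=1)
    if len(iu[0]) < 3:
        raise ValueError("need at least 3 off-diagonal pairs")
    rho = stats.spearmanr(A[iu], B[iu]).statistic
    return float(1.0 - rho)


@dataclass
class DeviationResult:
    """Deviation between two RDMs with its randomization p-value."""

    deviation: float
    p_value: float
    n_relabelings: int
    seed: int
    warning: str | None = field(default=None)


def randomization_test(
    rdm_a, rdm_b, n_relabelings: int = 10_000, seed: int = 0
) -> DeviationResult:
    """Fixed-effects randomization test of RDM correspondence.

    The null distribution is built by jointly permuting the condition
    labels (rows and columns together) of one RDM ``n_relabelings`` times
    and recomputing the rank association each time; the p-value is
    (1 + #{null association >= observed}) / (1 + n_relabelings).
    """
    if n_relabelings < 100:
        raise ValueError("n_relabelings must be >= 100")
    A, B = _as_matrix(rdm_a), _as_matrix(rdm_b)
    if A.shape != B.shape:
        raise ValueError("RDMs must have matching condition sets")
    n = A.shape[0]
    iu = np.triu_indices(n, k=1)
    a_ranks = stats.rankdata(A[iu])
    obs = _rank_assoc(a_ranks, B[iu])
    rng = np.random.default_rng(seed)
    null_entries = np.empty((n_relabelings, len(iu[0])))
    for i in range(n_relabelings):
        perm = rng.permutation(n)
        null_entries[i] = B[np.ix_(perm, perm)][iu]
    null = _rank_assoc_rows(a_ranks, null_entries)
    p = (1.0 + np.count_nonzero(null >= obs)) / (1.0 + n_relabelings)
    warning = None
    if n < 4:
        import math

        warning = f"only {math.factorial(n)} distinct relabelings exist for n={n}"
    return DeviationResult(
        deviation=float(1.0 - obs),
        p_value=float(p),
        n_relabelings=n_relabelings,
        seed=seed,
        warning=warning,
    )


def _rank_assoc(a_ranks: np.ndarray, b: np.ndarray) -> float:
    """Spearman correlation given pre-ranked a."""
    b_ranks = stats.rankdata(b)
    return float(np.corrcoef(a_ranks, b_ranks)[0, 1])


def _rank_assoc_rows(a_ranks: np.ndarray, B_rows: np.ndarray) -> np.ndarray:
    b_ranks = stats.rankdata(B_rows, axis=1)
    a_c = a_ranks - a_ranks.mean()
    b_c = b_ranks - b_ranks.mean(axis=1, keepdims=True)
    num = b_c @ a_c
    den = np.sqrt(np.sum(a_c**2) * np.sum(b_c**2, axis=1))
    return num / den


def deviation_stderr(
    patterns_a: dict[float, np.ndarray],
    patterns_b: dict[float, np.ndarray],
    n_boot: int = 100,
    seed: int = 0,
) -> float:
    """Bootstrap standard error of the deviation between two areas' RDMs.

    ``patterns_a``/``patterns_b`` map each condition to its per-trial
    pattern matrix (n_trials x pattern_dim). Trials are resampled with
    replacement within each condition, condition patterns re-averaged, both
    RDMs rebuilt and the deviation recomputed; the standard deviation over
    ``n_boot`` replicates is returned.
    """
    labels = sorted(patterns_a)
    if sorted(patterns_b) != labels:
        raise ValueError("areas must share the condition set")
    for pats in (patterns_a, patterns_b):
        for a in labels:
            if np.asarray(pats[a]).shape[0] < 2:
                raise ValueError("need >= 2 trials per condition for the bootstrap")
    rng = np.random.default_rng(seed)
    devs = np.empty(n_boot)
    for i in range(n_boot):
        conds_a, conds_b = {}, {}
        for a in labels:
            Pa = np.asarray(patterns_a[a])
            Pb = np.asarray(patterns_b[a])
            conds_a[a] = Pa[rng.integers(0, Pa.shape[0], Pa.shape[0])].mean(axis=0)
            conds_b[a] = Pb[rng.integers(0, Pb.shape[0], Pb.shape[0])].mean(axis=0)
        devs[i] = deviation(build_rdm(conds_a), build_rdm(conds_b))
    return float(devs.std(ddof=1))
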