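"""Single-ROI logistic detection classifiers and probability-summing ensembles.

Each ROI gets one binary classifier per whisker: a logistic model mapping
the single-trial evoked dF/F to the probability that the whisker was
deflected (vs a blank trial).  Performance is repeated stratified 80/20
cross-validation.  Ensembles sum each member's probability pair
(p_stim, 1 - p_stim) across units with equal weight and predict the class
with the larger summed probability (ties go to blank); all members share
the same trial partition on every repeat.

The 2-parameter logistic fit is a Newton (IRLS) iteration with a small
ridge term so separable data converge; scikit-learn's LogisticRegression
reproduces it and serves as a cross-check in the test suite.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .session import BLANK
from .responses import AnalysisWindows, evoked_response_per_trial

DEFAULT_SIZES = (1, 2, 3, 5, 10, 15, 20, 25, 30)


def trial_features(dff, stimulus: pd.DataFrame, windows: AnalysisWindows):
    """Per-(roi, trial) scalar decoding feature.

    Identical to the evoked response used by the tuning analysis: mean
    dF/F in the 1 s window after train onset minus the 0.5 s baseline.
    """
    return evoked_response_per_trial(dff, stimulus, windows)


def _fit_logistic(x: np.ndarray, y: np.ndarray, ridge: float = 1e-6):
    """Ridge-stabilized Newton fit of P(y=1|x) = sigmoid(b0 + b1*x)."""
    X = np.column_stack([np.ones_like(x), x])
    beta = np.zeros(2)
    for _ in range(50):
        eta = X @ beta
        p = 1.0 / (1.0 + np.exp(-np.clip(eta, -35, 35)))
        w = p * (1.0 - p) + 1e-12
        grad = X.T @ (y - p) - ridge * beta
        hess = (X * w[:, None]).T @ X + ridge * np.eye(2)
        step = np.linalg.solve(hess, grad)
        beta = beta + step
        if np.max(np.abs(step)) < 1e-10:
            break
    return beta


def _predict_prob(beta: np.ndarray, x: np.ndarray) -> np.ndarray:
    eta = beta[0] + beta[1] * x
    return 1.0 / (1.0 + np.exp(-np.clip(eta, -35, 35)))


def _stratified_split(y: np.ndarray, test_frac: float, rng: np.random.Generator):
    """Boolean test mask with the class ratio preserved."""
    test = np.zeros(y.size, dtype=bool)
    for cls in (0, 1):
        idx = np.nonzero(y == cls)[0]
        rng.shuffle(idx)
        n_test = max(1, int(round(test_frac * idx.size)))
        test[idx[:n_test]] = True
    return test


@dataclass
class RoiClassifier:
    roi_id: object
    whisker: str
    coefficients: tuple[float, float]
    cv_fraction_correct: float
    n_repeats: int = 500
    k_folds: int = 5


def fit_single_roi_classifier(
    stim_features,
    blank_features,
    roi_id=None,
    whisker: str = "",
    k_folds: int = 5,
    n_repeats: int = 500,
    seed: int = 0,
    ridge: float = 1e-6,
) -> RoiClassifier:
    """Single-ROI detection classifier with repeated 80/20 cross-validation.

    Each repeat holds out a stratified 1/k_folds of trials, fits the
    logistic on the rest, and scores held-out trials (predict stimulus when
    the modeled stimulus probability exceeds 0.5).  Reported coefficients
    are refit on all trials.
    """
    xs = np.asarray(stim_features, dtype=float)
    xb = np.asarray(blank_features, dtype=float)
    if xs.size < 10 or xb.size < 10:
        raise ValueError("need >= 10 trials per class")
    x = np.concatenate([xs, xb])
    y = np.concatenate([np.ones(xs.size), np.zeros(xb.size)])
    rng = np.random.default_rng(seed)
    test_frac = 1.0 / k_folds
    accs = np.empty(n_repeats)
    for r in range(n_repeats):
        test = _stratified_split(y, test_frac, rng)
        beta = _fit_logistic(x[~test], y[~test], ridge)
        pred = _predict_prob(beta, x[test]) > 0.5
        accs[r] = np.mean(pred == (y[test] == 1))
    beta_all = _fit_logistic(x, y, ridge)
    return RoiClassifier(
        roi_id=roi_id,
        whisker=whisker,
        coefficients=(float(beta_all[0]), float(beta_all[1])),
        cv_fraction_correct=float(accs.mean()),
        n_repeats=n_repeats,
        k_folds=k_folds,
    )


def ensemble_predict(prob_matrix: np.ndarray) -> np.ndarray:
    """Probability-summing population prediction.

    ``prob_matrix`` is (n_members, n_trials) of per-unit stimulus
    probabilities.  Class scores are the summed stimulus probabilities vs
    the summed blank probabilities; ties predict blank.
    """
    p = np.atleast_2d(prob_matrix)
    if p.shape[0] == 0:
        raise ValueError("empty ensemble")
    stim_score = p.sum(axis=0)
    blank_score = (1.0 - p).sum(axis=0)
    return stim_score > blank_score


@dataclass
class EnsembleSpec:
    member_roi_ids: tuple
    construction: str  # "random" or "clustered"
    size: int
    reference_whisker: str = ""
    centroid_xy: tuple[float, float] | None = None
    distance_to_reference_um: float = np.nan
    fraction_correct: float = np.nan


class DecoderEvaluator:
    """Shared-partition CV evaluation of single ROIs and ensembles.

    Built from a trial-response table; per whisker it caches, for every CV
    repeat, each ROI's held-out stimulus probabilities on a common trial
    partition, so evaluating an ensemble is a cached sum regardless of how
    many ensembles are requested.
    """

    def __init__(
        self,
        trials: pd.DataFrame,
        roi_ids,
        n_repeats: int = 50,
        k_folds: int = 5,
        seed: int = 0,
        ridge: float = 1e-6,
    ):
        self.roi_ids = list(roi_ids)
        self._index = {rid: i for i, rid in enumerate(self.roi_ids)}
        self.n_repeats = n_repeats
        self.k_folds = k_folds
        self.seed = seed
        self.ridge = ridge
        sub = trials[trials["roi_id"].isin(self.roi_ids)]
        self._features = sub.pivot(
            index="roi_id", columns="trial_id", values="evoked_dff"
        ).loc[self.roi_ids]
        tw = sub.drop_duplicates("trial_id").set_index("trial_id")["whisker"]
        self._trial_whisker = tw.loc[self._features.columns]
        self._cache: dict[str, list] = {}

    def _whisker_cache(self, whisker: str) -> list:
        """Per repeat: (probs (n_rois, n_test), y_test)."""
        if whisker in self._cache:
            return self._cache[whisker]
        sel = (self._trial_whisker == whisker) | (self._trial_whisker == BLANK)
        X = self._features.loc[:, sel.to_numpy()].to_numpy(dtype=float)
        y = (self._trial_whisker[sel.to_numpy()] == whisker).to_numpy().astype(int)
        wk_key = int.from_bytes(whisker.encode(), "little") % (2**31)
        rng = np.random.default_rng(
            np.random.SeedSequence([self.seed % (2**31), wk_key])
        )
        reps = []
        test_frac = 1.0 / self.k_folds
        for _ in range(self.n_repeats):
            test = _stratified_split(y, test_frac, rng)
            probs = np.empty((X.shape[0], int(test.sum())))
            for i in range(X.shape[0]):
                beta = _fit_logistic(X[i, ~test], y[~test], self.ridge)
                probs[i] = _predict_prob(beta, X[i, test])
            reps.append((probs, y[test]))
        self._cache[whisker] = reps
        return reps

    def single_roi_accuracy(self, roi_id, whisker: str) -> float:
        return self.ensemble_accuracy([roi_id], whisker)

    def ensemble_accuracy(self, member_roi_ids, whisker: str) -> float:
        """Mean held-out fraction correct over CV repeats."""
        idx = [self._index[r] for r in member_roi_ids]
        if not idx:
            raise ValueError("empty ensemble")
        accs = []
        for probs, y_test in self._whisker_cache(whisker):
            pred = ensemble_predict(probs[idx])
            accs.append(np.mean(pred == (y_test == 1)))
        return float(np.mean(accs))

    def ensemble_accuracy_cw_set(self, member_roi_ids, member_columns) -> float:
        """Accuracy averaged across the distinct columnar whiskers of the
        members' columns (the random-ensemble evaluation rule)."""
        cws = sorted({c for c in member_columns if c != "SEPTUM"})
        if not cws:
            raise ValueError("ensemble has no barrel-assigned members")
        return float(
            np.mean([self.ensemble_accuracy(member_roi_ids, cw) for cw in cws])
        )


def sample_random_ensembles(
    roi_ids,
    sizes=DEFAULT_SIZES,
    cap: int = 500,
    seed: int = 0,
) -> list[EnsembleSpec]:
    """Random ensembles per size: all C(N, k) when fewer than the cap,
    otherwise ``cap`` distinct random draws.  Sizes exceeding N are skipped."""
    ids = list(roi_ids)
    n = len(ids)
    rng = np.random.default_rng(seed)
    out = []
    for k in sizes:
        if k > n:
            continue
        n_comb = math.comb(n, k)
        if n_comb <= cap:
            combos = [tuple(c) for c in itertools.combinations(ids, k)]
        else:
            seen = set()
            while len(seen) < cap:
                pick = tuple(sorted(rng.choice(n, size=k, replace=False)))
                seen.add(pick)
            combos = [tuple(ids[i] for i in pick) for pick in sorted(seen)]
        out.extend(
            EnsembleSpec(member_roi_ids=c, construction="random", size=k)
            for c in combos
        )
    return out


def cluster_spatial_ensembles(
    roi_ids,
    coords: np.ndarray,
    reference_whisker: str,
    seed: int = 0,
    size_range: tuple[int, int] = (2, 42),
    k_values=None,
    n_init: int = 10,
) -> list[EnsembleSpec]:
    """Spatially clustered ensembles from k-means on reference-frame positions.

    For each k (default 2..N), clusters whose size falls inside
    ``size_range`` become ensembles; the centroid and its distance to the
    reference column center (the origin of the reference frame) are
    recorded.
    """
    ids = np.asarray(list(roi_ids), dtype=object)
    coords = np.asarray(coords, dtype=float)
    n = len(ids)
    if n < 2:
        raise ValueError("need >= 2 responsive ROIs")
    if k_values is None:
        k_values = range(2, n + 1)
    out = []
    for k in k_values:
        if k < 1 or k > n:
            continue
        km = KMeans(n_clusters=int(k), n_init=n_init, random_state=seed).fit(coords)
        for b in range(int(k)):
            sel = km.labels_ == b
            size = int(sel.sum())
            if not size_range[0] <= size <= size_range[1]:
                continue
            centroid = coords[sel].mean(axis=0)
            out.append(
                EnsembleSpec(
                    member_roi_ids=tuple(ids[sel]),
                    construction="clustered",
                    size=size,
                    reference_whisker=reference_whisker,
                    centroid_xy=(float(centroid[0]), float(centroid[1])),
                    distance_to_reference_um=float(np.hypot(*centroid)),
                )
            )
    return out


def distance_binned_performance(
    ensembles: list[EnsembleSpec], bin_width_um: float = 77.0
) -> pd.DataFrame:
    """Mean fraction correct per half-open centroid-distance bin."""
    rows = [
        (e.distance_to_reference_um, e.fraction_correct)
        for e in ensembles
        if np.isfinite(e.distance_to_reference_um) and np.isfinite(e.fraction_correct)
    ]
    if not rows:
        return pd.DataFrame(
            columns=["bin_lo_um", "bin_hi_um", "mean_fraction_correct", "sem", "n"]
        )
    d = np.array([r[0] for r in rows])
    a = np.array([r[1] for r in rows])
    idx = np.floor(d / bin_width_um).astype(int)
    out = []
    for b in sorted(set(idx)):
        vals = a[idx == b]
        out.append(
            {
                "bin_lo_um": b * bin_width_um,
                "bin_hi_um": (b + 1) * bin_width_um,
                "mean_fraction_correct": vals.mean(),
                "sem": vals.std(ddof=1) / np.sqrt(vals.size) if vals.size > 1 else np.nan,
                "n": int(vals.size),
            }
        )
    return pd.DataFrame(out)
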