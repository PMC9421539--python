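"""The dating model.

Converts per-sample temporal-component profiles into predicted dates
(years BP) with a random-forest regression: preprocessing filters,
feature engineering, stratified train/validation/unseen splitting,
10-fold cross-validated training with at most 20 trees, prediction, and
resampling-based per-sample uncertainty.

Feature layout (always 10, fixed order)::

    [c1', c2, c3, c4, c5, m1, m2, m3, f_mean, f_dev]

where c1..c5 are the ancient component fractions (oldest first), m1..m3
the modern ones, f_mean the mean of the five ancient fractions, f_dev the
absolute deviation of c1 from its training-cohort mean mu(c1), and
c1' = c1 + 3 * f_dev substitutes the raw c1. mu(c1) is estimated once in
fit mode and reused verbatim in apply mode, so held-out samples never
leak into it.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestRegressor
from sklearn.model_selection import KFold

from .io_formats import DatingMethod, SampleRecord

__all__ = [
    "FEATURE_NAMES",
    "DEFAULT_ALLOWED_METHODS",
    "PreprocessResult",
    "Split",
    "TrainedModel",
    "Prediction",
    "preprocess",
    "engineer_features",
    "stratified_split",
    "train",
    "predict",
    "predict_with_uncertainty",
]

FEATURE_NAMES: tuple[str, ...] = (
    "c1_adj", "c2", "c3", "c4", "c5", "m1", "m2", "m3", "ancient_mean", "c1_dev",
)

DEFAULT_ALLOWED_METHODS: frozenset[DatingMethod] = frozenset(
    {
        DatingMethod.RADIOCARBON_DIRECT,
        DatingMethod.ARCHAEOLOGICAL_CONTEXT,
        DatingMethod.MODERN,
    }
)


# ---------------------------------------------------------------------------
# Feature engineering
# ---------------------------------------------------------------------------

def engineer_features(
    profiles: pd.DataFrame | np.ndarray,
    mode: str = "fit",
    mu_c1: float | None = None,
    n_ancient: int = 5,
) -> tuple[pd.DataFrame, float]:
    """Build the 10-feature matrix from 8-component profiles.

    ``profiles`` columns must follow the canonical order (ancient oldest
    first, then modern). In ``fit`` mode mu(c1) is computed from this
    cohort and returned for storage; ``apply`` mode requires the stored
    value and never recomputes it.
    """
    if mode not in ("fit", "apply"):
        raise ValueError(f"mode must be fit or apply, got {mode!r}")
    if mode == "apply" and mu_c1 is None:
        raise ValueError("apply mode requires the stored mu(c1)")

    if isinstance(profiles, pd.DataFrame):
        index = profiles.index
        q = profiles.to_numpy(dtype=float)
    else:
        q = np.asarray(profiles, dtype=float)
        index = pd.RangeIndex(q.shape[0])

    c1 = q[:, 0]
    if mode == "fit":
        mu_c1 = float(c1.mean())
    f_mean = q[:, :n_ancient].mean(axis=1)
    f_dev = np.abs(mu_c1 - c1)
    c1_adj = c1 + 3.0 * f_dev

    X = np.column_stack([c1_adj, q[:, 1:], f_mean, f_dev])
    df = pd.DataFrame(X, index=index, columns=list(FEATURE_NAMES))
    return df, float(mu_c1)


# ---------------------------------------------------------------------------
# Preprocessing
# ---------------------------------------------------------------------------

@dataclass
class PreprocessResult:
    retained: list[str]
    ledger: pd.DataFrame          # sample_id, rule
    skew_before: float
    skew_after: float
    mu_c1: float                  # mean of c1 over the z-scored cohort


def preprocess(
    records: Sequence[SampleRecord],
    profiles: pd.DataFrame,
    max_age: float = 10000.0,
    allowed_methods: frozenset[DatingMethod] = DEFAULT_ALLOWED_METHODS,
    z_thresh: float = 3.0,
    max_date_sd: float = 400.0,
    combine: str = "and",
) -> PreprocessResult:
    """Apply the three curation filters and return survivors plus a ledger.

    1. ancient samples older than ``max_age`` years BP are dropped;
    2. ancient samples whose dating method is not allowed are dropped;
    3. features are z-scored over the remaining *ancient* samples
       (population variance; a zero-variance feature scores z = 0) and a
       sample is dropped when it has any \\|z\\| >= ``z_thresh`` AND (default
       conjunction; ``combine="or"`` for disjunction) its date SD exceeds
       ``max_date_sd``.

    Modern samples pass rules 1–3 untouched. Date-distribution skewness is
    reported before and after for the curation audit.
    """
    if combine not in ("and", "or"):
        raise ValueError("combine must be 'and' or 'or'")
    by_id = {r.sample_id: r for r in records}
    ids = [sid for sid in profiles.index if sid in by_id]
    ledger_rows: list[dict] = []

    ancient_dates_before = [by_id[s].date_mean for s in ids if by_id[s].is_ancient]
    skew_before = float(stats.skew(ancient_dates_before)) if len(ancient_dates_before) > 2 else 0.0

    keep: list[str] = []
    for sid in ids:
        r = by_id[sid]
        if r.is_ancient and r.date_mean > max_age:
            ledger_rows.append({"sample_id": sid, "rule": "max_age"})
        elif r.is_ancient and r.dating_method not in allowed_methods:
            ledger_rows.append({"sample_id": sid, "rule": "dating_method"})
        else:
            keep.append(sid)

    ancient_keep = [s for s in keep if by_id[s].is_ancient]
    if ancient_keep:
        X, mu_c1 = engineer_features(profiles.loc[ancient_keep], mode="fit")
        x = X.to_numpy()
        mean = x.mean(axis=0)
        sd = x.std(axis=0)        # population (n) variance
        with np.errstate(invalid="ignore", divide="ignore"):
            z = np.where(sd > 0, (x - mean) / np.where(sd > 0, sd, 1.0), 0.0)
        outlier = (np.abs(z) >= z_thresh).any(axis=1)
    else:
        mu_c1 = float("nan")
        outlier = np.zeros(0, dtype=bool)

    survivors: list[str] = []
    for sid in keep:
        if not by_id[sid].is_ancient:
            survivors.append(sid)
            continue
        i = ancient_keep.index(sid)
        wide_sd = by_id[sid].date_sd > max_date_sd
        drop = (outlier[i] and wide_sd) if combine == "and" else (outlier[i] or wide_sd)
        if drop:
            ledger_rows.append({"sample_id": sid, "rule": "z_outlier"})
        else:
            survivors.append(sid)

    if not survivors:
        raise ValueError("preprocessing removed every sample")

    ancient_after = [by_id[s].date_mean for s in survivors if by_id[s].is_ancient]
    skew_after = float(stats.skew(ancient_after)) if len(ancient_after) > 2 else 0.0
    ledger = pd.DataFrame(ledger_rows, columns=["sample_id", "rule"])
    return PreprocessResult(
        retained=survivors, ledger=ledger,
        skew_before=skew_before, skew_after=skew_after, mu_c1=mu_c1,
    )


# ---------------------------------------------------------------------------
# Stratified split
# ---------------------------------------------------------------------------

@dataclass
class Split:
    train: list[str]
    validation: list[str]
    unseen: list[str]

    def as_dict(self) -> dict[str, list[str]]:
        return {"train": self.train, "validation": self.validation, "unseen": self.unseen}


def _largest_remainder(sizes: np.ndarray, frac: float) -> np.ndarray:
    """Allocate round(frac * total) holdouts across strata proportionally."""
    total = int(round(frac * sizes.sum()))
    quota = frac * sizes
    base = np.floor(quota).astype(int)
    base = np.minimum(base, sizes - 1)       # never empty a stratum entirely
    shortfall = total - base.sum()
    if shortfall > 0:
        remainders = quota - np.floor(quota)
        headroom = sizes - 1 - base
        order = np.argsort(-remainders)
        for idx in order:
            if shortfall == 0:
                break
            give = min(headroom[idx], shortfall)
            if give > 0:
                base[idx] += 1
                shortfall -= 1
    return base


def stratified_split(
    records: Sequence[SampleRecord],
    date_bin: float = 500.0,
    unseen_frac: float = 0.15,
    val_frac: float = 0.10,
    seed: int = 0,
) -> Split:
    """Partition samples into train / validation / unseen sets.

    Ancient samples stratify by (date bin x country), modern by country
    only; single-sample strata go to training. The ancient and modern
    unseen sets are drawn separately (largest-remainder allocation of the
    target count across strata) and merged; the remainder splits again
    into validation (``val_frac``) and training, which is reshuffled.
    """
    if unseen_frac + val_frac >= 1.0:
        raise ValueError("unseen_frac + val_frac must be < 1")
    rng = np.random.default_rng(seed)

    def split_group(group: list[SampleRecord], keyfunc):
        strata: dict = {}
        for r in group:
            strata.setdefault(keyfunc(r), []).append(r.sample_id)
        singletons = [v[0] for v in strata.values() if len(v) == 1]
        multi = [sorted(v) for v in strata.values() if len(v) > 1]
        if not multi:
            return [], [], singletons
        sizes = np.array([len(v) for v in multi])
        counts = _largest_remainder(sizes, unseen_frac)
        unseen, rest = [], []
        for ids, c in zip(multi, counts):
            ids = list(ids)
            rng.shuffle(ids)
            unseen.extend(ids[: int(c)])
            rest.extend(ids[int(c):])
        return unseen, rest, singletons

    ancient = [r for r in records if r.is_ancient]
    modern = [r for r in records if not r.is_ancient]
    unseen_a, rest_a, single_a = split_group(
        ancient, lambda r: (int(r.date_mean // date_bin), r.country)
    )
    unseen_m, rest_m, single_m = split_group(modern, lambda r: r.country)
    unseen = unseen_a + unseen_m
    rest = rest_a + rest_m

    # validation from the multi-strata remainder; singletons train only
    n_val = int(round(val_frac / (1.0 - unseen_frac) * len(rest)))
    rng.shuffle(rest)
    validation = rest[:n_val]
    training = rest[n_val:] + single_a + single_m
    rng.shuffle(training)
    return Split(train=training, validation=validation, unseen=unseen)


# ---------------------------------------------------------------------------
# Training / prediction
# ---------------------------------------------------------------------------

@dataclass
class TrainedModel:
    forest: RandomForestRegressor
    mu_c1: float | None
    date_range: tuple[float, float]
    cv_errors: list[float]
    config: dict
    fingerprint: str
    replica: int

    def __getstate__(self):            # joblib/pickle friendly
        return self.__dict__

    def __setstate__(self, state):
        self.__dict__.update(state)


def _fingerprint(X: np.ndarray, y: np.ndarray) -> str:
    h = hashlib.sha256()
    h.update(np.ascontiguousarray(np.round(X, 9)).tobytes())
    h.update(np.ascontiguousarray(np.round(y, 6)).tobytes())
    return h.hexdigest()[:16]


def train(
    X: pd.DataFrame | np.ndarray,
    dates: Sequence[float] | np.ndarray,
    n_trees: int = 20,
    folds: int = 10,
    seed: int = 0,
    final_model: str = "seeded_random",
    mu_c1: float | None = None,
    rf_params: Mapping | None = None,
) -> TrainedModel:
    """Train the forest with k-fold cross-validation.

    ``folds`` replicas are fitted, each on the complement of one fold, and
    their held-fold median absolute errors retained. The final model is a
    seeded-random replica by default (``final_model="best_validation"``
    picks the lowest CV error instead). Forest hyperparameters beyond the
    tree count follow the library defaults, pinned via ``rf_params``.
    """
    Xa = X.to_numpy(dtype=float) if isinstance(X, pd.DataFrame) else np.asarray(X, dtype=float)
    y = np.asarray(dates, dtype=float)
    n = len(y)
    if folds > n:
        raise ValueError(f"folds={folds} exceeds {n} training samples")
    if final_model not in ("seeded_random", "best_validation"):
        raise ValueError(f"unknown final_model policy {final_model!r}")
    params = dict(rf_params or {})

    rng = np.random.default_rng(seed)
    kf = KFold(n_splits=folds, shuffle=True, random_state=int(rng.integers(2**31)))
    replicas: list[RandomForestRegressor] = []
    cv_errors: list[float] = []
    for k, (tr, va) in enumerate(kf.split(Xa)):
        forest = RandomForestRegressor(
            n_estimators=n_trees, random_state=int(rng.integers(2**31)), **params
        )
        forest.fit(Xa[tr], y[tr])
        cv_errors.append(float(np.median(np.abs(forest.predict(Xa[va]) - y[va]))))
        replicas.append(forest)

    if final_model == "seeded_random":
        pick = int(rng.integers(folds))
    else:
        pick = int(np.argmin(cv_errors))

    return TrainedModel(
        forest=replicas[pick],
        mu_c1=mu_c1,
        date_range=(float(y.min()), float(y.max())),
        cv_errors=cv_errors,
        config={
            "n_trees": n_trees, "folds": folds, "seed": seed,
            "final_model": final_model, "rf_params": params,
        },
        fingerprint=_fingerprint(Xa, y),
        replica=pick,
    )


def predict(model: TrainedModel, X: pd.DataFrame | np.ndarray) -> np.ndarray:
    """Predict dates (years BP); one value per sample.

    Forest predictions are averages of leaf means, so they cannot leave
    the training date range.
    """
    Xa = X.to_numpy(dtype=float) if isinstance(X, pd.DataFrame) else np.asarray(X, dtype=float)
    if Xa.ndim != 2 or Xa.shape[1] != len(FEATURE_NAMES):
        raise ValueError(
            f"expected {len(FEATURE_NAMES)} features, got shape {Xa.shape}"
        )
    return model.forest.predict(Xa)


@dataclass
class Prediction:
    sample_id: str
    date_hat: float
    sd: float
    sem: float
    ci95: tuple[float, float]
    n_repeats: int


def predict_with_uncertainty(
    X_train: pd.DataFrame | np.ndarray,
    y_train: Sequence[float] | np.ndarray,
    x_sample: np.ndarray,
    sample_id: str = "",
    repeats: int = 10,
    frac: float = 0.90,
    seed: int = 0,
    n_trees: int = 20,
    rf_params: Mapping | None = None,
) -> Prediction:
    """Date one unseen sample with resampling-based uncertainty.

    Resamples ``frac`` of the training set (without replacement), retrains,
    and dates the sample ``repeats`` times; reports the mean, SD, standard
    error of the mean, and the normal 95% CI. All repeat seeds derive from
    the master seed.
    """
    if repeats < 2:
        raise ValueError("repeats must be >= 2 for an SD to exist")
    Xa = X_train.to_numpy(dtype=float) if isinstance(X_train, pd.DataFrame) else np.asarray(
        X_train, dtype=float
    )
    y = np.asarray(y_train, dtype=float)
    x = np.asarray(x_sample, dtype=float).reshape(1, -1)
    rng = np.random.default_rng(seed)
    n = len(y)
    k = max(1, int(round(frac * n)))
    estimates = np.empty(repeats)
    for r in range(repeats):
        rows = rng.choice(n, size=k, replace=False)
        forest = RandomForestRegressor(
            n_estimators=n_trees, random_state=int(rng.integers(2**31)),
            **(rf_params or {}),
        )
        forest.fit(Xa[rows], y[rows])
        estimates[r] = forest.predict(x)[0]
    date_hat = float(estimates.mean())
    sd = float(estimates.std(ddof=1))
    sem = sd / np.sqrt(repeats)
    return Prediction(
        sample_id=sample_id,
        date_hat=date_hat,
        sd=sd,
        sem=float(sem),
        ci95=(date_hat - 1.96 * sem, date_hat + 1.96 * sem),
        n_repeats=repeats,
    )
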