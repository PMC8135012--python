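"""Penalized-regression epigenetic clocks and their cross-validated evaluation.

A clock is a sparse linear model of transformed age on probe beta values,
fitted with a combined L1/L2 penalty.  Penalty strength is chosen by
internal 10-fold cross-validation at the minimum mean squared error.
Out-of-sample DNA-methylation age comes from leave-one-sample-out or
k-fold schemes in which the *entire* training procedure, including penalty
selection, is rerun without the held-out samples.

Age acceleration is the residual of cross-validated DNAm age regressed on
chronological age within a tissue, which removes tissue-specific
calibration slope and intercept so accelerations are comparable across
tissues.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import ElasticNetCV

from .datamodel import BetaMatrix, Clock, SampleTable, ValidationError
from .transforms import AgeTransform

DEFAULT_PENALTY_MIX = 0.5
_INTERNAL_FOLDS = 10
_N_ALPHAS = 25


def _response(samples: SampleTable, transform: AgeTransform) -> np.ndarray:
    return np.asarray(
        transform.forward(samples.ages, samples.lifespans), float
    ).ravel()


def train_clock(
    betas: BetaMatrix,
    samples: SampleTable,
    transform: AgeTransform | None = None,
    penalty_mix: float = DEFAULT_PENALTY_MIX,
    seed: int = 0,
) -> Clock:
    """Fit an elastic-net clock on all provided samples.

    Predictors are standardized internally; coefficients are returned on the
    original beta scale.  Probes with zero variance in the training set are
    dropped from the penalized fit (their coefficient is zero).
    """
    transform = transform or AgeTransform("identity")
    if len(samples) < 10:
        raise ValidationError("clock training requires at least 10 samples")
    if not 0.0 <= penalty_mix <= 1.0:
        raise ValidationError("penalty_mix must lie in [0, 1]")
    # canonical sample order so the fit is invariant to input column order
    samples = samples.subset(sample_ids=sorted(samples.sample_ids))
    samples.df.sort_values("sample_id", inplace=True, ignore_index=True)
    X = betas.samples_matrix(samples)
    y = _response(samples, transform)
    if np.ptp(y) == 0:
        raise ValidationError("transformed age is constant; clock is unidentifiable")

    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    keep = sd > 0
    if not keep.any():
        return Clock(
            transform=transform,
            intercept=float(y.mean()),
            coefficients={},
            metadata={"n_training_samples": len(samples), "penalty_mix": penalty_mix,
                      "seed": seed, "note": "all probes constant; intercept-only clock"},
        )
    Xs = (X[:, keep] - mu[keep]) / sd[keep]

    n_folds = min(_INTERNAL_FOLDS, len(samples))
    model = ElasticNetCV(
        l1_ratio=penalty_mix if penalty_mix > 0 else 1e-3,
        alphas=_N_ALPHAS,
        cv=n_folds,
        random_state=seed,
        max_iter=2_000,
        tol=1e-3,
        selection="cyclic",
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        model.fit(Xs, y)

    coef_std = model.coef_
    probe_ids = np.array(betas.probe_ids)[keep]
    nz = coef_std != 0
    coef_orig = coef_std[nz] / sd[keep][nz]
    coefficients = dict(zip(probe_ids[nz], coef_orig))
    intercept = float(model.intercept_ - np.sum(coef_orig * mu[keep][nz]))

    clock = Clock(
        transform=transform,
        intercept=intercept,
        coefficients=coefficients,
        metadata={
            "species": sorted(set(samples.df["species"])),
            "tissues": sorted(set(samples.df["tissue"])),
            "n_training_samples": len(samples),
            "penalty_mix": penalty_mix,
            "alpha": float(model.alpha_),
            "cv_folds": n_folds,
            "seed": seed,
        },
    )
    # self-consistency: stored clock reproduces the fitted values
    refit = clock.linear_response(betas)[samples.sample_ids].to_numpy()
    fitted = model.predict(Xs)
    if not np.allclose(refit, fitted, atol=1e-8):
        raise RuntimeError("stored clock does not reproduce its fitted values")
    return clock


def predict_age(
    clock: Clock, betas: BetaMatrix, samples: SampleTable | None = None
) -> pd.Series:
    """Per-sample DNAm age in years.

    The relative-age clock needs ``samples`` to supply species lifespans for
    back-transformation.  Out-of-range predictions are reported as-is with a
    warning rather than clipped.
    """
    response = clock.linear_response(betas)
    transform: AgeTransform = clock.transform
    if transform.kind == "relative":
        if samples is None:
            raise ValidationError(
                "relative-age clock needs a SampleTable for back-transformation"
            )
        sub = samples.subset(sample_ids=betas.sample_ids)
        lifespan = sub.df.set_index("sample_id")["max_lifespan_years"]
        years = response * lifespan.reindex(response.index).to_numpy(float)
    else:
        years = pd.Series(
            np.asarray(transform.inverse(response.to_numpy()), float),
            index=response.index,
        )
    if (years <= 0).any() or (
        samples is not None
        and (
            years.to_numpy()
            > samples.subset(sample_ids=betas.sample_ids)
            .df.set_index("sample_id")["max_lifespan_years"]
            .reindex(years.index)
            .to_numpy(float)
        ).any()
    ):
        warnings.warn("some DNAm-age predictions fall outside (0, max lifespan]")
    years.name = "dnam_age_years"
    return years


def _estimates_frame(samples: SampleTable, pred: pd.Series, fold: pd.Series) -> pd.DataFrame:
    df = samples.df.set_index("sample_id")
    out = pd.DataFrame(
        {
            "dnam_age_years": pred,
            "fold_id": fold,
            "age_years": df["age_years"],
            "tissue": df["tissue"],
            "species": df["species"],
        }
    )
    out.index.name = "sample_id"
    return out.loc[samples.sample_ids]


def loo_estimates(
    betas: BetaMatrix,
    samples: SampleTable,
    transform: AgeTransform | None = None,
    penalty_mix: float = DEFAULT_PENALTY_MIX,
    seed: int = 0,
) -> pd.DataFrame:
    """Leave-one-sample-out DNAm-age estimates (penalty re-selected per fold)."""
    ids = samples.sample_ids
    pred = pd.Series(index=ids, dtype=float)
    fold = pd.Series(index=ids, dtype=int)
    sub_betas = betas.subset_samples(ids)
    for i, sid in enumerate(ids):
        train = samples.subset(sample_ids=[s for s in ids if s != sid])
        clock = train_clock(sub_betas.subset_samples(train.sample_ids), train,
                            transform, penalty_mix, seed)
        pred[sid] = predict_age(clock, sub_betas.subset_samples([sid]), samples).iloc[0]
        fold[sid] = i
    return _estimates_frame(samples, pred, fold)


def make_folds(
    samples: SampleTable, k: int, group_by_donor: bool = False, seed: int = 0
) -> pd.Series:
    """Fold assignment stratified by (species, tissue); donors never split."""
    if k > len(samples):
        raise ValidationError(f"k={k} exceeds n={len(samples)} samples")
    rng = np.random.default_rng(seed)
    df = samples.df
    fold = pd.Series(index=df["sample_id"], dtype=int, name="fold_id")
    if group_by_donor:
        unit = df["donor_id"].fillna(df["sample_id"]).astype(str)
    else:
        unit = df["sample_id"].astype(str)
    unit_df = pd.DataFrame(
        {"unit": unit.values, "stratum": (df["species"] + "/" + df["tissue"]).values,
         "sample_id": df["sample_id"].values}
    )
    units = unit_df.drop_duplicates("unit")[["unit", "stratum"]]
    pointer = 0
    assignment: dict[str, int] = {}
    for _, grp in units.groupby("stratum", sort=True):
        order = grp["unit"].to_numpy()[rng.permutation(len(grp))]
        for u in order:
            assignment[u] = pointer % k
            pointer += 1
    fold[:] = [assignment[u] for u in unit]
    return fold


def kfold_estimates(
    betas: BetaMatrix,
    samples: SampleTable,
    transform: AgeTransform | None = None,
    penalty_mix: float = DEFAULT_PENALTY_MIX,
    k: int = 10,
    group_by_donor: bool = False,
    seed: int = 0,
) -> pd.DataFrame:
    """k-fold cross-validated DNAm-age estimates."""
    fold = make_folds(samples, k, group_by_donor, seed)
    ids = samples.sample_ids
    pred = pd.Series(index=ids, dtype=float)
    sub_betas = betas.subset_samples(ids)
    for f in range(k):
        test_ids = [s for s in ids if fold[s] == f]
        if not test_ids:
            continue
        train = samples.subset(sample_ids=[s for s in ids if fold[s] != f])
        clock = train_clock(sub_betas.subset_samples(train.sample_ids), train,
                            transform, penalty_mix, seed)
        pred[test_ids] = predict_age(
            clock, sub_betas.subset_samples(test_ids), samples
        )
    return _estimates_frame(samples, pred, fold)


def evaluate(estimates: pd.DataFrame, groups: tuple[str, ...] = ("tissue", "species")) -> pd.DataFrame:
    """Pearson r and median absolute error (years), overall and per group."""
    rows = []

    def one(label: str, sub: pd.DataFrame):
        n = len(sub)
        if n < 3:
            return
        ages = sub["age_years"].to_numpy(float)
        est = sub["dnam_age_years"].to_numpy(float)
        if np.ptp(ages) == 0 or np.ptp(est) == 0:
            r = np.nan
        else:
            r = float(np.corrcoef(ages, est)[0, 1])
        rows.append(
            {
                "group": label,
                "n": n,
                "pearson_r": r,
                "median_abs_error_years": float(np.median(np.abs(est - ages))),
            }
        )

    one("overall", estimates)
    for col in groups:
        if estimates[col].nunique() > 1:
            for value, sub in estimates.groupby(col, sort=True):
                one(f"{col}={value}", sub)
    return pd.DataFrame(rows)


def age_acceleration(estimates: pd.DataFrame, group_by: str = "tissue") -> pd.Series:
    """Residual of DNAm age on chronological age, OLS within each group."""
    accel = pd.Series(index=estimates.index, dtype=float, name="acceleration_years")
    for _, sub in estimates.groupby(group_by, sort=True):
        if len(sub) < 3:
            raise ValidationError(
                f"acceleration needs >=3 samples per {group_by} group"
            )
        x = sub["age_years"].to_numpy(float)
        y = sub["dnam_age_years"].to_numpy(float)
        slope, intercept = np.polyfit(x, y, 1)
        accel[sub.index] = y - (intercept + slope * x)
    return accel


def acceleration_correlation(
    est_blood: pd.DataFrame, est_oocyte: pd.DataFrame, samples: SampleTable
) -> dict:
    """Pearson correlation of donor-paired age acceleration across tissues.

    Returns r, two-sided p, number of pairs and per-tissue acceleration
    summaries (median and IQR).
    """
    acc_b = age_acceleration(est_blood)
    acc_o = age_acceleration(est_oocyte)
    donor = samples.df.set_index("sample_id")["donor_id"]
    pairs = pd.DataFrame(
        {
            "blood": acc_b.groupby(donor.reindex(acc_b.index)).mean(),
            "oocyte": acc_o.groupby(donor.reindex(acc_o.index)).mean(),
        }
    ).dropna()
    if len(pairs) < 3:
        raise ValidationError("fewer than 3 donor pairs with both tissues")
    r, p = stats.pearsonr(pairs["blood"], pairs["oocyte"])

    def summary(acc: pd.Series) -> dict:
        q1, med, q3 = np.percentile(acc, [25, 50, 75])
        return {"median": float(med), "iqr": float(q3 - q1)}

    return {
        "r": float(r),
        "p": float(p),
        "n_pairs": int(len(pairs)),
        "blood_summary": summary(acc_b),
        "oocyte_summary": summary(acc_o),
    }
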