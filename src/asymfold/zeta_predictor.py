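"""Liposome ζ-potential prediction with a boosted-regression-tree ensemble.

The model maps eight physicochemical features of a liposome-in-buffer sample
— monovalent and divalent salt concentration (M), pH, hydrodynamic radius
(nm), temperature (°C), mean lipid headgroup charge (e per lipid), mean
lipid Tm (°C, cholesterol excluded), and cholesterol mole fraction — to its
ζ-potential in mV.  Training uses root-mean-squared-error loss with
per-sample weights derived from each measurement's standard deviation
(smaller error → larger weight, affinely normalized to [0.375, 0.625]),
early stopping on a 25% validation split, and fourfold cross-validation for
reporting.  Prediction averages a 50-member ensemble in which every member
must reach a validation MAE below 5 mV; members that miss the cutoff are
retrained with a fresh seed.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field, asdict
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import xgboost as xgb
from sklearn.model_selection import KFold, train_test_split

from .errors import DomainError, TrainingError
from .liposome_design import BUILTIN_SPECIES, LipidSpecies

__all__ = [
    "FEATURES",
    "TrainingConfig",
    "EnsembleModel",
    "CVReport",
    "ImportanceReport",
    "featurize",
    "weights_from_sd",
    "filter_literature_table",
    "train_ensemble",
    "predict_zeta",
    "importance_and_ablation",
    "save_model",
    "load_model",
]

#: Canonical feature order; matches the training CSV column names.
FEATURES: Tuple[str, ...] = (
    "salt_mono_M",
    "salt_di_M",
    "pH",
    "rh_nm",
    "temp_C",
    "mean_charge",
    "mean_tm_C",
    "chol_frac",
)

TARGET = "zeta_mV"
TARGET_SD = "zeta_sd_mV"


@dataclass
class TrainingConfig:
    """Hyperparameters of the boosted ensemble.

    The boosted-tree knobs mirror the XGBoost names: learning_rate,
    subsample_per_tree → ``subsample`` (row fraction per tree),
    subsample_per_node → ``colsample_bynode`` (feature fraction per split),
    min_child_weight, max_depth.  cv_members and ablation_members bound the
    member count used for the fourfold CV report and the per-feature
    ablation so those diagnostics stay cheap relative to the deployed
    ensemble.
    """

    learning_rate: float = 0.05
    early_stop_patience: int = 25
    validation_fraction: float = 0.25
    subsample_per_node: float = 0.85
    subsample_per_tree: float = 0.85
    min_child_weight: float = 2.5
    max_depth: int = 6
    ensemble_size: int = 50
    member_mae_cutoff: float = 5.0  # mV
    weight_lo: float = 0.375
    weight_hi: float = 0.625
    cv_folds: int = 4
    seed: int = 0
    n_estimators: int = 400
    cv_members: int = 8
    ablation_members: int = 4

    def __post_init__(self):
        if self.weight_lo >= self.weight_hi:
            raise DomainError("weight_lo must be < weight_hi")
        if self.ensemble_size < 1:
            raise DomainError("ensemble_size must be >= 1")


@dataclass
class EnsembleModel:
    members: List[xgb.XGBRegressor]
    member_mae: List[float]
    config: TrainingConfig
    feature_names: Tuple[str, ...] = FEATURES


@dataclass
class CVReport:
    fold_mae: List[float]

    @property
    def mean_mae(self) -> float:
        return float(np.mean(self.fold_mae))


@dataclass
class ImportanceReport:
    """Per-feature gain statistics across members, plus ablation MAEs."""

    gain_stats: pd.DataFrame  # index: feature; columns: min, median, max
    ablation_mae: Dict[str, float]
    baseline_mae: float


# ---------------------------------------------------------------------------
# feature construction


def featurize(
    fractions: Mapping[str, float],
    buffer_record: Mapping[str, float],
    species_table: Optional[Mapping[str, LipidSpecies]] = None,
) -> Dict[str, float]:
    """Build the three composition features and merge the buffer features.

    mean_charge averages headgroup charge over the whole composition
    (cholesterol contributes 0); mean_tm_C averages Tm over non-cholesterol
    lipids only, renormalized; chol_frac is the cholesterol mole fraction.
    buffer_record supplies salt_mono_M, salt_di_M, pH, rh_nm and temp_C.
    """
    table = dict(BUILTIN_SPECIES if species_table is None else species_table)
    unknown = [s for s in fractions if s not in table]
    if unknown:
        raise DomainError(f"unknown lipid species: {unknown}")
    total = sum(fractions.values())
    if total <= 0:
        raise DomainError("empty composition")
    mean_charge = sum(f * table[s].headgroup_charge for s, f in fractions.items()) / total
    chol = sum(f for s, f in fractions.items() if table[s].is_cholesterol) / total
    non_chol = {s: f for s, f in fractions.items() if not table[s].is_cholesterol}
    nc_total = sum(non_chol.values())
    if nc_total <= 0:
        raise DomainError("composition is pure cholesterol; mean Tm undefined")
    mean_tm = sum(f * table[s].tm_celsius for s, f in non_chol.items()) / nc_total
    features = {
        "mean_charge": mean_charge,
        "mean_tm_C": mean_tm,
        "chol_frac": chol,
    }
    for key in ("salt_mono_M", "salt_di_M", "pH", "rh_nm", "temp_C"):
        features[key] = float(buffer_record[key])
    return features


def weights_from_sd(
    sds: Sequence[float], lo: float = 0.375, hi: float = 0.625
) -> np.ndarray:
    """Inverse-error sample weights, affinely mapped to [lo, hi].

    The smallest measurement sd maps to ``hi`` and the largest to ``lo``;
    all-equal sds (or a single sample) map to the midpoint.  NaN sds (no
    reported uncertainty) also get the midpoint.
    """
    sds = np.asarray(sds, dtype=float)
    if np.any(sds[np.isfinite(sds)] < 0):
        raise DomainError("measurement sd cannot be negative")
    mid = (lo + hi) / 2.0
    w = np.full(sds.shape, mid)
    finite = np.isfinite(sds)
    if finite.sum() >= 2:
        smin, smax = sds[finite].min(), sds[finite].max()
        if smax > smin:
            w[finite] = lo + (hi - lo) * (smax - sds[finite]) / (smax - smin)
    return w


def filter_literature_table(df: pd.DataFrame) -> pd.DataFrame:
    """Apply the literature-compilation inclusion criteria.

    Keeps rows with (1) a known mean lipid Tm, (2) NaCl or KCl as the buffer
    salt (column ``salt_species``, when present), and (3) no ethanol in the
    buffer (column ``ethanol``, when present, falsy).  Assembling the table
    itself is the caller's task.
    """
    keep = df["mean_tm_C"].notna()
    if "salt_species" in df.columns:
        keep &= df["salt_species"].isin(["NaCl", "KCl"])
    if "ethanol" in df.columns:
        keep &= ~df["ethanol"].astype(bool)
    return df.loc[keep].reset_index(drop=True)


# ---------------------------------------------------------------------------
# training


def _member_params(config: TrainingConfig, seed: int) -> dict:
    return dict(
        objective="reg:squarederror",
        learning_rate=config.learning_rate,
        n_estimators=config.n_estimators,
        max_depth=config.max_depth,
        min_child_weight=config.min_child_weight,
        subsample=config.subsample_per_tree,
        colsample_bynode=config.subsample_per_node,
        random_state=seed,
        n_jobs=1,
        verbosity=0,
        early_stopping_rounds=config.early_stop_patience,
    )


def _fit_member(
    X: np.ndarray,
    y: np.ndarray,
    w: np.ndarray,
    config: TrainingConfig,
    seed: int,
) -> Tuple[xgb.XGBRegressor, float]:
    Xtr, Xval, ytr, yval, wtr, wval = train_test_split(
        X, y, w, test_size=config.validation_fraction, random_state=seed
    )
    model = xgb.XGBRegressor(**_member_params(config, seed))
    model.fit(
        Xtr,
        ytr,
        sample_weight=wtr,
        eval_set=[(Xval, yval)],
        sample_weight_eval_set=[wval],
        verbose=False,
    )
    mae = float(np.mean(np.abs(model.predict(Xval) - yval)))
    return model, mae


def _matrixize(samples: pd.DataFrame, features: Sequence[str] = FEATURES):
    missing = [f for f in features if f not in samples.columns]
    if missing:
        raise DomainError(f"missing feature column(s): {missing}")
    X = samples[list(features)].to_numpy(dtype=float)
    if not np.all(np.isfinite(X)):
        raise DomainError("non-finite feature value in training table")
    y = samples[TARGET].to_numpy(dtype=float)
    sds = (
        samples[TARGET_SD].to_numpy(dtype=float)
        if TARGET_SD in samples.columns
        else np.full(len(samples), np.nan)
    )
    return X, y, sds


def train_ensemble(
    samples: pd.DataFrame,
    config: Optional[TrainingConfig] = None,
    features: Sequence[str] = FEATURES,
) -> Tuple[EnsembleModel, CVReport]:
    """Train the MAE-filtered ensemble and report fourfold CV MAE.

    Each member is trained on all data minus its own random 25% early-stop
    validation split; members whose validation MAE misses the cutoff are
    retrained with a new seed, up to 10× the ensemble size attempts.  The
    CV report retrains small ensembles per fold and is diagnostic only.
    """
    config = config or TrainingConfig()
    if len(samples) < 20:
        raise DomainError("need at least 20 training samples")
    X, y, sds = _matrixize(samples, features)
    w = weights_from_sd(sds, config.weight_lo, config.weight_hi)

    members: List[xgb.XGBRegressor] = []
    maes: List[float] = []
    rejected: List[float] = []
    attempt = 0
    max_attempts = config.ensemble_size * 10
    while len(members) < config.ensemble_size:
        if attempt >= max_attempts:
            raise TrainingError(
                f"could not assemble {config.ensemble_size} members with "
                f"MAE < {config.member_mae_cutoff} mV in {max_attempts} attempts",
                member_maes=rejected,
            )
        model, mae = _fit_member(X, y, w, config, seed=config.seed + attempt)
        attempt += 1
        if mae < config.member_mae_cutoff:
            members.append(model)
            maes.append(mae)
        else:
            rejected.append(mae)

    # fourfold CV (reporting only)
    kf = KFold(n_splits=config.cv_folds, shuffle=True, random_state=config.seed)
    n_cv = min(config.cv_members, config.ensemble_size)
    fold_mae = []
    for fold_i, (tr, te) in enumerate(kf.split(X)):
        preds = np.zeros(te.size)
        for j in range(n_cv):
            m, _ = _fit_member(
                X[tr], y[tr], w[tr], config, seed=config.seed + 1000 * (fold_i + 1) + j
            )
            preds += m.predict(X[te])
        preds /= n_cv
        fold_mae.append(float(np.mean(np.abs(preds - y[te]))))

    ens = EnsembleModel(
        members=members, member_mae=maes, config=config, feature_names=tuple(features)
    )
    return ens, CVReport(fold_mae=fold_mae)


def predict_zeta(model: EnsembleModel, samples) -> np.ndarray:
    """Mean of the member predictions, in mV.

    ``samples`` may be a DataFrame with the feature columns, a mapping for a
    single sample, or a bare feature array in canonical order.
    """
    if isinstance(samples, Mapping):
        missing = [f for f in model.feature_names if f not in samples]
        if missing:
            raise DomainError(f"missing feature(s): {missing}")
        X = np.array([[float(samples[f]) for f in model.feature_names]])
    elif isinstance(samples, pd.DataFrame):
        missing = [f for f in model.feature_names if f not in samples.columns]
        if missing:
            raise DomainError(f"missing feature column(s): {missing}")
        X = samples[list(model.feature_names)].to_numpy(dtype=float)
    else:
        X = np.atleast_2d(np.asarray(samples, dtype=float))
    preds = np.mean([m.predict(X) for m in model.members], axis=0)
    return preds


# ---------------------------------------------------------------------------
# importance and ablation


def _member_gains(member: xgb.XGBRegressor, feature_names: Sequence[str]) -> np.ndarray:
    booster = member.get_booster()
    booster.feature_names = list(feature_names)
    score = booster.get_score(importance_type="gain")
    return np.array([score.get(f, 0.0) for f in feature_names])


def _cv_mae(
    samples: pd.DataFrame,
    config: TrainingConfig,
    features: Sequence[str],
    n_members: int,
    seed_offset: int,
) -> float:
    X, y, sds = _matrixize(samples, features)
    w = weights_from_sd(sds, config.weight_lo, config.weight_hi)
    kf = KFold(n_splits=config.cv_folds, shuffle=True, random_state=config.seed)
    fold_mae = []
    for fold_i, (tr, te) in enumerate(kf.split(X)):
        preds = np.zeros(te.size)
        for j in range(n_members):
            m, _ = _fit_member(
                X[tr],
                y[tr],
                w[tr],
                config,
                seed=config.seed + seed_offset + 100 * fold_i + j,
            )
            preds += m.predict(X[te])
        preds /= n_members
        fold_mae.append(float(np.mean(np.abs(preds - y[te]))))
    return float(np.mean(fold_mae))


def importance_and_ablation(
    model: EnsembleModel,
    samples: pd.DataFrame,
    run_ablation: bool = True,
) -> ImportanceReport:
    """Gain-based feature importance plus leave-one-feature-out ablation.

    Gain per feature per split is collected from every ensemble member and
    summarized as min/median/max.  Ablation retrains a small CV ensemble
    with each feature dropped and reports the resulting CV MAE next to the
    all-features baseline.
    """
    gains = np.array([_member_gains(m, model.feature_names) for m in model.members])
    stats = pd.DataFrame(
        {
            "min": gains.min(axis=0),
            "median": np.median(gains, axis=0),
            "max": gains.max(axis=0),
        },
        index=list(model.feature_names),
    )
    ablation: Dict[str, float] = {}
    baseline = float("nan")
    if run_ablation:
        cfg = model.config
        baseline = _cv_mae(
            samples, cfg, model.feature_names, cfg.ablation_members, seed_offset=5000
        )
        for i, feat in enumerate(model.feature_names):
            reduced = [f for f in model.feature_names if f != feat]
            ablation[feat] = _cv_mae(
                samples, cfg, reduced, cfg.ablation_members, seed_offset=6000 + 100 * i
            )
    return ImportanceReport(gain_stats=stats, ablation_mae=ablation, baseline_mae=baseline)


# ---------------------------------------------------------------------------
# persistence


def save_model(model: EnsembleModel, directory: str) -> None:
    """Persist the ensemble as a directory of member files plus config JSON."""
    os.makedirs(directory, exist_ok=True)
    meta = {
        "config": asdict(model.config),
        "member_mae": model.member_mae,
        "feature_names": list(model.feature_names),
        "n_members": len(model.members),
    }
    with open(os.path.join(directory, "ensemble.json"), "w") as fh:
        json.dump(meta, fh, indent=2)
    for i, m in enumerate(model.members):
        m.get_booster().save_model(os.path.join(directory, f"member_{i:03d}.ubj"))


def load_model(directory: str) -> EnsembleModel:
    with open(os.path.join(directory, "ensemble.json")) as fh:
        meta = json.load(fh)
    config = TrainingConfig(**meta["config"])
    members = []
    for i in range(meta["n_members"]):
        params = _member_params(config, seed=config.seed + i)
        params.pop("early_stopping_rounds")
        m = xgb.XGBRegressor(**params)
        booster = xgb.Booster()
        booster.load_model(os.path.join(directory, f"member_{i:03d}.ubj"))
        m._Booster = booster
        members.append(m)
    return EnsembleModel(
        members=members,
        member_mae=list(meta["member_mae"]),
        config=config,
        feature_names=tuple(meta["feature_names"]),
    )
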