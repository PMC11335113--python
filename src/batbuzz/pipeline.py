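"""Training and deployment of the recording-level buzz classifier.

Training follows the published procedure: extreme outliers are removed from
the non-buzz window set (SNRvar > 3000 or IPIshannon < -10), all 21
predictors are z-scored, a PCA of the scaled features provides PC1 scores
that are split per class into five quantile strata, 150 windows are sampled
from each (class x stratum) for a balanced set of 1500, and a random forest
is trained on an 80/20 stratified split with an accuracy sweep over decision
thresholds 0.5-1.0 before the final forest is rebuilt on the whole balanced
set.  The shipped default predictors are the three variables that dominate
the first principal component of the field data: IPIsd, duravg and SNRavg.

Deployment runs detection over the seven 5 kHz bands, forms the moving
windows, and labels a recording a buzz when enough windows cross the
decision threshold (one window by default; an optional voting rule requires
more).  An optional prescan skips files without any echolocation-like
signal, and a gap threshold between positive windows separates multiple
buzzes within one recording.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import joblib
import numpy as np
import pandas as pd
import yaml
from sklearn.decomposition import PCA
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import train_test_split

from .audio import FrequencyBand, Recording, compute_spectrogram, read_wav
from .detector import (DetectorParams, default_bands, detect_in_band,
                       enforce_min_dur_tbe, scan_bands)
from .features import FEATURE_NAMES, windows_to_frame

log = logging.getLogger(__name__)

__all__ = [
    "DEFAULT_FEATURES",
    "ScalerParams",
    "BalancedDataset",
    "ClassifierBundle",
    "PipelineConfig",
    "RecordingResult",
    "remove_outliers",
    "fit_apply_scaler",
    "pc1_balance",
    "select_features",
    "train_classifier",
    "predict_windows",
    "prescan_echolocation",
    "classify_recording",
    "count_buzzes",
    "extract_features",
    "train_from_features",
    "classify_files",
]

DEFAULT_FEATURES: tuple[str, ...] = ("IPIsd", "duravg", "SNRavg")
THRESHOLD_GRID = tuple(np.round(np.linspace(0.5, 1.0, 11), 2))
_BUNDLE_VERSION = 1


# --------------------------------------------------------------------------
# scaling

@dataclass
class ScalerParams:
    """Per-feature z-score parameters fitted on training windows."""

    feature_names: tuple[str, ...]
    mean: np.ndarray
    sd: np.ndarray

    @classmethod
    def fit(cls, rows: pd.DataFrame,
            feature_names: Sequence[str] = FEATURE_NAMES) -> "ScalerParams":
        if len(rows) < 2:
            raise ValueError("need at least 2 rows to fit a scaler")
        X = rows[list(feature_names)].to_numpy(dtype=np.float64)
        mean = X.mean(axis=0)
        sd = X.std(axis=0, ddof=1)  # sample sd: scaled training data has sd 1
        dead = np.asarray(feature_names)[sd <= 0]
        if dead.size:
            raise ValueError(f"zero-variance feature(s): {', '.join(dead)}")
        return cls(tuple(feature_names), mean, sd)

    def transform(self, rows: pd.DataFrame) -> pd.DataFrame:
        missing = set(self.feature_names) - set(rows.columns)
        if missing:
            raise KeyError(f"rows lack scaled features: {sorted(missing)}")
        out = rows.copy()
        X = out[list(self.feature_names)].to_numpy(dtype=np.float64)
        out[list(self.feature_names)] = (X - self.mean) / self.sd
        return out


def fit_apply_scaler(
    rows: pd.DataFrame,
    feature_names: Sequence[str] = FEATURE_NAMES,
) -> tuple[ScalerParams, pd.DataFrame]:
    scaler = ScalerParams.fit(rows, feature_names)
    return scaler, scaler.transform(rows)


# --------------------------------------------------------------------------
# outlier removal and balancing

def remove_outliers(
    rows: pd.DataFrame,
    labels: np.ndarray | None = None,
    snrvar_max: float = 3000.0,
    ipishannon_min: float = -10.0,
    mode: str = "any",
) -> tuple[pd.DataFrame, np.ndarray | None]:
    """Drop extreme windows: SNRvar > 3000 or IPIshannon < -10.

    When ``labels`` is given (True = buzz) the rule is applied to non-buzz
    rows only, matching the training procedure.  ``mode='all'`` makes the
    two flags conjunctive instead.
    """
    snrvar_flag = rows["SNRvar"].to_numpy() > snrvar_max
    shannon_flag = rows["IPIshannon"].to_numpy() < ipishannon_min
    flag = (snrvar_flag & shannon_flag) if mode == "all" else (snrvar_flag | shannon_flag)
    if labels is not None:
        labels = np.asarray(labels, dtype=bool)
        flag = flag & ~labels
    keep = ~flag
    kept = rows.loc[keep].reset_index(drop=True)
    return kept, (labels[keep] if labels is not None else None)


@dataclass
class BalancedDataset:
    """PC1-stratified balanced training set."""

    rows: pd.DataFrame
    labels: np.ndarray
    pc1_scores: np.ndarray
    strata: np.ndarray  # quantile index 1-5

    def __post_init__(self) -> None:
        n = len(self.rows)
        if not (n == self.labels.size == self.pc1_scores.size == self.strata.size):
            raise ValueError("balanced dataset arrays disagree in length")


def pc1_balance(
    rows: pd.DataFrame,
    labels: np.ndarray,
    per_stratum: int = 150,
    seed: int = 0,
    feature_names: Sequence[str] = FEATURE_NAMES,
) -> BalancedDataset:
    """Sample ``per_stratum`` windows from each (class x PC1-quintile) stratum.

    PC1 is fitted on the scaled features of all rows; each class's scores are
    cut at their own 20/40/60/80 percentiles.  Defaults yield exactly
    2 x 5 x 150 = 1500 rows.
    """
    labels = np.asarray(labels, dtype=bool)
    X = rows[list(feature_names)].to_numpy(dtype=np.float64)
    pc1 = PCA(n_components=1, random_state=0).fit_transform(X)[:, 0]

    rng = np.random.default_rng(seed)
    chosen: list[np.ndarray] = []
    strata_all = np.zeros(len(rows), dtype=int)
    shortfall: list[str] = []
    for cls in (False, True):
        idx = np.nonzero(labels == cls)[0]
        if idx.size == 0:
            shortfall.append(f"class={'buzz' if cls else 'non-buzz'}: no rows")
            continue
        edges = np.quantile(pc1[idx], [0.2, 0.4, 0.6, 0.8])
        strata = np.searchsorted(edges, pc1[idx], side="right") + 1
        strata_all[idx] = strata
        for q in range(1, 6):
            members = idx[strata == q]
            if members.size < per_stratum:
                shortfall.append(
                    f"class={'buzz' if cls else 'non-buzz'} stratum={q}: "
                    f"{members.size} < {per_stratum}"
                )
                continue
            pick = rng.choice(members, size=per_stratum, replace=False)
            chosen.append(np.sort(pick))
    if shortfall:
        raise ValueError("understocked strata: " + "; ".join(shortfall))
    sel = np.concatenate(chosen)
    return BalancedDataset(
        rows=rows.iloc[sel].reset_index(drop=True),
        labels=labels[sel],
        pc1_scores=pc1[sel],
        strata=strata_all[sel],
    )


def select_features(
    rows: pd.DataFrame,
    corr_cutoff: float = 0.6,
    feature_names: Sequence[str] = FEATURE_NAMES,
) -> list[str]:
    """Greedy feature pruning: rank by |PC1 loading|, skip correlated ones.

    Features are accepted in decreasing loading order unless their absolute
    Pearson correlation with an already-accepted feature exceeds the cutoff.
    """
    if len(rows) < 3:
        raise ValueError("need at least 3 rows for feature selection")
    X = rows[list(feature_names)].to_numpy(dtype=np.float64)
    loadings = PCA(n_components=1, random_state=0).fit(X).components_[0]
    corr = np.abs(np.corrcoef(X, rowvar=False))
    order = np.argsort(-np.abs(loadings), kind="stable")
    accepted: list[int] = []
    for j in order:
        if all(corr[j, a] <= corr_cutoff for a in accepted):
            accepted.append(j)
    return [feature_names[j] for j in accepted]


# --------------------------------------------------------------------------
# classifier bundle

@dataclass
class ClassifierBundle:
    """Deployable model: scaler + feature set + forest + decision threshold."""

    scaler: ScalerParams
    selected_features: tuple[str, ...]
    forest: RandomForestClassifier
    decision_threshold: float = 0.8
    training_seed: int = 0
    threshold_accuracies: dict[float, float] = field(default_factory=dict)
    version: int = _BUNDLE_VERSION

    def __post_init__(self) -> None:
        if not (0.5 <= self.decision_threshold <= 1.0):
            raise ValueError("decision_threshold must lie in [0.5, 1.0]")
        unknown = set(self.selected_features) - set(FEATURE_NAMES)
        if unknown:
            raise ValueError(f"unknown features: {sorted(unknown)}")

    def save(self, path) -> None:
        joblib.dump({"format": "batbuzz-bundle", "version": self.version,
                     "bundle": self}, path)

    @classmethod
    def load(cls, path) -> "ClassifierBundle":
        payload = joblib.load(path)
        if payload.get("format") != "batbuzz-bundle":
            raise ValueError(f"{path}: not a classifier bundle")
        return payload["bundle"]


def train_classifier(
    balanced: BalancedDataset,
    scaler: ScalerParams,
    features: Sequence[str] = DEFAULT_FEATURES,
    split: float = 0.8,
    seed: int = 0,
    n_estimators: int = 500,
    decision_threshold: float = 0.8,
) -> tuple[ClassifierBundle, dict[float, float]]:
    """Train the forest and report held-out accuracy across thresholds.

    A stratified ``split`` fraction trains an evaluation forest whose
    held-out accuracy is measured at each threshold 0.5-1.0 (step 0.05);
    the shipped forest is then rebuilt on the entire balanced dataset.
    """
    X = balanced.rows[list(features)].to_numpy(dtype=np.float64)
    y = balanced.labels.astype(int)
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present for training")
    X_tr, X_te, y_tr, y_te = train_test_split(
        X, y, train_size=split, stratify=y, random_state=seed)
    probe = RandomForestClassifier(n_estimators=n_estimators, random_state=seed,
                                   n_jobs=1).fit(X_tr, y_tr)
    prob_te = probe.predict_proba(X_te)[:, list(probe.classes_).index(1)]
    accuracies = {
        float(thr): float(np.mean((prob_te >= thr).astype(int) == y_te))
        for thr in THRESHOLD_GRID
    }
    final = RandomForestClassifier(n_estimators=n_estimators, random_state=seed,
                                   n_jobs=1).fit(X, y)
    bundle = ClassifierBundle(
        scaler=scaler,
        selected_features=tuple(features),
        forest=final,
        decision_threshold=decision_threshold,
        training_seed=seed,
        threshold_accuracies=accuracies,
    )
    return bundle, accuracies


def predict_windows(bundle: ClassifierBundle, windows: pd.DataFrame) -> pd.DataFrame:
    """Per-window buzz probability (forest vote fraction) and label."""
    if windows.empty:
        return windows.assign(probability=pd.Series(dtype=float),
                              is_buzz=pd.Series(dtype=bool))
    scaled = bundle.scaler.transform(windows)
    X = scaled[list(bundle.selected_features)].to_numpy(dtype=np.float64)
    pos = list(bundle.forest.classes_).index(1)
    prob = bundle.forest.predict_proba(X)[:, pos]
    out = windows.copy()
    out["probability"] = prob
    out["is_buzz"] = prob >= bundle.decision_threshold  # inclusive threshold
    return out


# --------------------------------------------------------------------------
# recording-level pipeline

@dataclass
class PipelineConfig:
    """End-to-end options for classifying recordings."""

    detector_params: DetectorParams = field(default_factory=DetectorParams)
    bands: list[FrequencyBand] = field(default_factory=default_bands)
    prescan_enabled: bool = False
    voting_enabled: bool = False
    voting_min_positive: int = 2
    buzz_gap_threshold: float = 1.0  # s between positive windows starting a new buzz

    def __post_init__(self) -> None:
        if self.voting_min_positive < 1:
            raise ValueError("voting_min_positive must be >= 1")
        if self.buzz_gap_threshold <= 0:
            raise ValueError("buzz_gap_threshold must be positive")

    @property
    def min_positive(self) -> int:
        return self.voting_min_positive if self.voting_enabled else 1

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        det = DetectorParams(**raw.pop("detector_params", {}))
        bands = [FrequencyBand(*b) for b in raw.pop("bands", [])] or default_bands()
        return cls(detector_params=det, bands=bands, **raw)

    def to_yaml(self, path) -> None:
        payload = {
            "detector_params": {k: getattr(self.detector_params, k)
                                for k in self.detector_params.__dataclass_fields__},
            "bands": [[b.f_lo, b.f_hi] for b in self.bands],
            "prescan_enabled": self.prescan_enabled,
            "voting_enabled": self.voting_enabled,
            "voting_min_positive": self.voting_min_positive,
            "buzz_gap_threshold": self.buzz_gap_threshold,
        }
        Path(path).write_text(yaml.safe_dump(payload))


def prescan_echolocation(recording: Recording,
                         params: DetectorParams | None = None) -> bool:
    """True iff one broadband 15-50 kHz pass (min_dur 1 ms) detects anything."""
    params = params or DetectorParams()
    relaxed = replace(params, min_dur=1.0)
    band = FrequencyBand(15_000.0, min(50_000.0, recording.nyquist))
    spec = compute_spectrogram(recording, fft_size=relaxed.fft_size,
                               overlap_fraction=relaxed.fft_overlap,
                               db_floor=relaxed.db_floor)
    dets = enforce_min_dur_tbe(detect_in_band(spec, band, relaxed), relaxed)
    return len(dets) > 0


def count_buzzes(positive_times: Sequence[float], gap_threshold: float = 1.0) -> int:
    """Number of buzz groups: gaps > gap_threshold start a new group."""
    times = np.asarray(list(positive_times), dtype=float)
    if times.size == 0:
        return 0
    if np.any(np.diff(times) < 0):
        raise ValueError("positive window times must be sorted")
    return 1 + int(np.sum(np.diff(times) > gap_threshold))


@dataclass(frozen=True)
class RecordingResult:
    source_id: str
    is_buzz: bool
    n_windows: int
    n_positive_windows: int
    buzz_count: int
    max_probability: float


def classify_recording(
    recording: Recording,
    bundle: ClassifierBundle,
    config: PipelineConfig | None = None,
) -> RecordingResult:
    """Full pipeline on one recording: prescan, detect, window, classify."""
    config = config or PipelineConfig()
    if config.prescan_enabled and not prescan_echolocation(recording,
                                                           config.detector_params):
        return RecordingResult(recording.source_id, False, 0, 0, 0, 0.0)
    per_band = scan_bands(recording, config.bands, config.detector_params)
    windows = windows_to_frame(per_band, source_id=recording.source_id)
    if windows.empty:
        return RecordingResult(recording.source_id, False, 0, 0, 0, 0.0)
    scored = predict_windows(bundle, windows)
    positive = scored.loc[scored["is_buzz"], "window_start_s"].sort_values()
    n_pos = int(len(positive))
    return RecordingResult(
        source_id=recording.source_id,
        is_buzz=n_pos >= config.min_positive,
        n_windows=int(len(scored)),
        n_positive_windows=n_pos,
        buzz_count=count_buzzes(positive.to_numpy(), config.buzz_gap_threshold),
        max_probability=float(scored["probability"].max()),
    )


# --------------------------------------------------------------------------
# corpus-level helpers

def extract_features(
    wav_paths: Sequence, labels: dict[str, str] | None = None,
    params: DetectorParams | None = None,
    bands: Sequence[FrequencyBand] | None = None,
) -> pd.DataFrame:
    """Window-feature table over many WAV files (one row per window)."""
    frames = []
    for p in wav_paths:
        rec = read_wav(p)
        name = Path(p).name
        per_band = scan_bands(rec, bands, params)
        lab = labels.get(name) if labels else None
        frames.append(windows_to_frame(per_band, source_id=name, label=lab))
    frames = [f for f in frames if not f.empty]
    if not frames:
        return pd.DataFrame()
    return pd.concat(frames, ignore_index=True)


def train_from_features(
    windows: pd.DataFrame,
    seed: int = 0,
    per_stratum: int = 150,
    features: Sequence[str] = DEFAULT_FEATURES,
    decision_threshold: float = 0.8,
    n_estimators: int = 500,
) -> tuple[ClassifierBundle, dict[float, float]]:
    """Outlier removal, scaling, PC1 balancing and forest training in one call.

    ``windows`` must carry the 21 features plus a ``label`` column with
    values 'buzz' / 'non-buzz'.
    """
    labels = windows["label"].to_numpy() == "buzz"
    kept, labels = remove_outliers(windows, labels)
    scaler, scaled = fit_apply_scaler(kept)
    balanced = pc1_balance(scaled, labels, per_stratum=per_stratum, seed=seed)
    return train_classifier(balanced, scaler, features=features, seed=seed,
                            decision_threshold=decision_threshold,
                            n_estimators=n_estimators)


def classify_files(
    wav_paths: Sequence,
    bundle: ClassifierBundle,
    config: PipelineConfig | None = None,
    jobs: int = 1,
) -> pd.DataFrame:
    """Classify many WAV files; parallel runs match sequential ones exactly."""
    config = config or PipelineConfig()

    def one(p):
        rec = read_wav(p)
        rec.source_id = Path(p).name
        return classify_recording(rec, bundle, config)

    if jobs == 1:
        results = [one(p) for p in wav_paths]
    else:
        results = joblib.Parallel(n_jobs=jobs)(joblib.delayed(one)(p)
                                               for p in wav_paths)
    return pd.DataFrame([{
        "path": r.source_id,
        "label": "buzz" if r.is_buzz else "non-buzz",
        "n_windows": r.n_windows,
        "n_positive_windows": r.n_positive_windows,
        "buzz_count": r.buzz_count,
        "max_probability": r.max_probability,
    } for r in results])
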