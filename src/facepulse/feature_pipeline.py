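"""Change-from-baseline feature table and fold-safe standardize+PCA.

Each participant contributes 20 indices x 6 clips = 120 features, where a
feature is the index value during clip viewing minus its value during the
preceding 30 s baseline (the phasic autonomic change).  Standardization and
principal-component compression are fitted on training rows only, so a
held-out participant never influences the centers, scales or loadings used
to transform them; fitting on the full table before cross-validation is
available behind a flag for comparison.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .chromophore_separation import separate
from .hrv_indices import INDEX_NAMES, ANSIndexVector, compute_index_vector
from .pulse_extraction import UnusableSegmentError, beats_to_rr, clean_rr, hemoglobin_to_rr
from .synthetic_cohort import CLIP_NAMES, Session

__all__ = [
    "FEATURE_NAMES",
    "delta_features",
    "build_feature_table",
    "feature_table_from_cohort",
    "Standardizer",
    "PCModel",
]

#: The 120 feature names: ``<index>_<clip>`` in index-major order.
FEATURE_NAMES = tuple(
    f"{index}_{clip}" for index in INDEX_NAMES for clip in CLIP_NAMES
)


def delta_features(
    session_vectors: dict,
) -> pd.Series:
    """120 change-from-baseline features for one participant.

    ``session_vectors`` maps clip name -> ``(baseline, clip)`` pair of
    :class:`ANSIndexVector` (either may be ``None`` for an unusable
    segment; the corresponding 20 features are then NaN-masked, never
    silently zero).
    """
    missing = set(CLIP_NAMES) - set(session_vectors)
    if missing:
        raise ValueError(f"missing conditions: {sorted(missing)}")
    values = {}
    for clip in CLIP_NAMES:
        baseline, during = session_vectors[clip]
        for index in INDEX_NAMES:
            name = f"{index}_{clip}"
            if baseline is None or during is None:
                values[name] = np.nan
            else:
                values[name] = getattr(during, index) - getattr(baseline, index)
    return pd.Series(values).reindex(list(FEATURE_NAMES))


def _segment_vector_from_truth(segment) -> ANSIndexVector | None:
    try:
        rr = clean_rr(beats_to_rr(segment.beats))
        return compute_index_vector(rr, segment.hb_truth)
    except (UnusableSegmentError, ValueError, ZeroDivisionError) as exc:
        warnings.warn(f"segment unusable: {exc}", stacklevel=2)
        return None


def _segment_vector_from_trace(segment, ica_seed: int) -> ANSIndexVector | None:
    if segment.trace is None:
        raise ValueError("segment has no rendered trace; generate with render=True")
    try:
        chromo = separate(segment.trace, ica_seed=ica_seed)
        rr = hemoglobin_to_rr(chromo.hemoglobin, chromo.frame_rate)
        return compute_index_vector(rr, chromo.hemoglobin)
    except (UnusableSegmentError, ValueError, ZeroDivisionError) as exc:
        warnings.warn(f"segment unusable: {exc}", stacklevel=2)
        return None


def session_features(
    session: Session, from_truth: bool = False, ica_seed: int = 0
) -> pd.Series:
    """Extract one participant's 120 features from their session.

    ``from_truth=True`` computes indices from the generator's ground-truth
    beat times (no rendering/separation), which is exact and fast;
    otherwise the full RGB -> chromophore -> pulse chain runs per segment.
    """
    vectors = {}
    for clip, cond in session.conditions.items():
        if from_truth:
            pair = (
                _segment_vector_from_truth(cond.baseline),
                _segment_vector_from_truth(cond.clip_segment),
            )
        else:
            pair = (
                _segment_vector_from_trace(cond.baseline, ica_seed),
                _segment_vector_from_trace(cond.clip_segment, ica_seed),
            )
        vectors[clip] = pair
    return delta_features(vectors)


def build_feature_table(rows: list[tuple[str, str, pd.Series]]) -> pd.DataFrame:
    """Assemble (participant, group, features) records into a FeatureTable:
    participant-indexed DataFrame with a ``group`` column and 120 feature
    columns."""
    data = []
    for participant, group, series in rows:
        if group not in ("TD", "ASD"):
            raise ValueError(f"unknown group label {group!r}")
        rec = {"participant": participant, "group": group}
        rec.update(series.to_dict())
        data.append(rec)
    table = pd.DataFrame(data).set_index("participant")
    return table[["group", *FEATURE_NAMES]]


def feature_table_from_cohort(
    cohort: list[Session], from_truth: bool = False, ica_seed: int = 0
) -> pd.DataFrame:
    """Feature table for a whole synthetic cohort (see
    :func:`session_features`)."""
    rows = [
        (s.participant, s.group, session_features(s, from_truth, ica_seed))
        for s in cohort
    ]
    return build_feature_table(rows)


class Standardizer:
    """Per-feature z-scoring with train-row statistics only.

    Constant columns get scale 1 (with a warning) so they standardize to
    zero; NaN entries (masked segments) become 0 after standardization,
    i.e. the train-mean imputation the pipeline documents.
    """

    def __init__(self) -> None:
        self.center_: pd.Series | None = None
        self.scale_: pd.Series | None = None

    def fit(self, train: pd.DataFrame) -> "Standardizer":
        if len(train) < 2:
            raise ValueError("need at least 2 training rows")
        self.center_ = train.mean(axis=0, skipna=True)
        scale = train.std(axis=0, ddof=0, skipna=True)
        constant = ~(scale > 0)
        if constant.any():
            warnings.warn(
                f"{int(constant.sum())} constant feature(s); scale fallback 1",
                stacklevel=2,
            )
            scale = scale.mask(constant, 1.0)
        self.scale_ = scale
        return self

    def transform(self, rows: pd.DataFrame) -> pd.DataFrame:
        if self.center_ is None:
            raise RuntimeError("Standardizer is not fitted")
        z = (rows - self.center_) / self.scale_
        return z.fillna(0.0)

    def fit_transform(self, train: pd.DataFrame) -> pd.DataFrame:
        return self.fit(train).transform(train)


class PCModel:
    """PCA loadings ordered by explained variance, with a fixed sign
    convention (largest-magnitude element of each loading is positive)."""

    def __init__(self) -> None:
        self.loadings_: np.ndarray | None = None  # (n_components, n_features)
        self.explained_variance_ratio_: np.ndarray | None = None
        self.mean_: np.ndarray | None = None

    def fit(self, train: pd.DataFrame | np.ndarray) -> "PCModel":
        X = np.asarray(train, dtype=float)
        pca = PCA(svd_solver="full")
        pca.fit(X)
        loadings = pca.components_.copy()
        for i, row in enumerate(loadings):
            if row[np.argmax(np.abs(row))] < 0:
                loadings[i] = -row
        self.loadings_ = loadings
        self.explained_variance_ratio_ = pca.explained_variance_ratio_
        self.mean_ = pca.mean_
        return self

    @property
    def n_components(self) -> int:
        if self.loadings_ is None:
            raise RuntimeError("PCModel is not fitted")
        return self.loadings_.shape[0]

    def project(self, rows: pd.DataFrame | np.ndarray, n_pcs: int) -> np.ndarray:
        """Scores on the first ``n_pcs`` loadings by explained variance."""
        if self.loadings_ is None:
            raise RuntimeError("PCModel is not fitted")
        if not 1 <= n_pcs <= self.n_components:
            raise ValueError(
                f"n_pcs must be in [1, {self.n_components}], got {n_pcs}"
            )
        X = np.asarray(rows, dtype=float)
        return (X - self.mean_) @ self.loadings_[:n_pcs].T
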