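"""Variance-stabilising transforms and aggregate unit-variance scaling.

Area is log-transformed and circularity logit-transformed, then each feature
is divided by its sample standard deviation over the aggregate of all control
and knockdown structures of one oncogene condition. The two conditions are
processed independently. Features are deliberately *not* mean-centred here:
all location handling happens downstream via control-centering in the RKHS.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .io import ScreenDataset

FEATURES = ("f_area", "f_circularity")


class DegenerateDataError(ValueError):
    """A feature has zero variance over the aggregate; scaling is undefined."""


def transform_features(area, circularity, eps: float = 1e-6):
    """Map raw (area, circularity) to (ln(area), logit(circularity)).

    Circularity is clipped to [eps, 1 - eps] so segmented structures that
    score exactly 0 or 1 stay finite. Accepts scalars or arrays; returns a
    pair of arrays (or floats for scalar input).
    """
    if not 0 < eps < 0.5:
        raise ValueError(f"eps must be in (0, 0.5), got {eps}")
    area = np.asarray(area, dtype=float)
    circ = np.asarray(circularity, dtype=float)
    if np.any(area <= 0):
        raise ValueError("area must be strictly positive")
    if np.any((circ < 0) | (circ > 1)):
        raise ValueError("circularity must lie in [0, 1]")
    c = np.clip(circ, eps, 1 - eps)
    f_area = np.log(area)
    f_circ = np.log(c / (1 - c))
    if f_area.ndim == 0:
        return float(f_area), float(f_circ)
    return f_area, f_circ


@dataclasses.dataclass
class FeatureMatrix:
    """Transformed, aggregate-scaled per-structure feature vectors.

    ``frame`` carries one row per structure with columns set_id,
    population_id, is_control, f_area, f_circularity (scaled). ``feature_sd``
    stores the aggregate standard deviations that were divided out, and
    ``clip_eps`` the logit clipping bound, so the map is reproducible.
    """

    frame: pd.DataFrame
    condition: str
    feature_sd: dict[str, float]
    clip_eps: float

    def populations(self) -> list[tuple[str, str]]:
        seen = self.frame[["set_id", "population_id"]].drop_duplicates()
        return [tuple(r) for r in seen.itertuples(index=False)]

    def knockdowns(self) -> list[tuple[str, str]]:
        sub = self.frame[~self.frame["is_control"]]
        seen = sub[["set_id", "population_id"]].drop_duplicates()
        return [tuple(r) for r in seen.itertuples(index=False)]

    def control_of(self, set_id: str) -> str:
        ctrl = self.frame[(self.frame["set_id"] == set_id) & self.frame["is_control"]][
            "population_id"
        ].unique()
        if len(ctrl) != 1:
            raise ValueError(f"set {set_id!r} has {len(ctrl)} controls; expected 1")
        return ctrl[0]

    def values(self, set_id: str, population_id: str) -> np.ndarray:
        mask = (self.frame["set_id"] == set_id) & (
            self.frame["population_id"] == population_id
        )
        if not mask.any():
            raise KeyError(f"population {population_id!r} not found in set {set_id!r}")
        return self.frame.loc[mask, list(FEATURES)].to_numpy(dtype=float)

    def control_values(self, set_id: str) -> np.ndarray:
        return self.values(set_id, self.control_of(set_id))

    def aggregate(self) -> np.ndarray:
        """All feature vectors of the condition, stacked (n_structures, 2)."""
        return self.frame[list(FEATURES)].to_numpy(dtype=float)


class MorphometryTransformer(TransformerMixin, BaseEstimator):
    """Log/logit transform followed by aggregate unit-variance scaling.

    A scikit-learn transformer over an (n, 2) array of raw ``(area,
    circularity)`` columns (a DataFrame with those columns is also accepted).
    ``fit`` learns one standard deviation per transformed feature over the
    aggregate sample; ``transform`` divides by it.

    Parameters
    ----------
    clip_eps : float, default 1e-6
        Circularity is clipped to ``[clip_eps, 1 - clip_eps]`` before the
        logit.
    ddof : int, default 1
        Delta degrees of freedom of the aggregate standard deviation.

    Attributes
    ----------
    scale_ : ndarray of shape (2,)
        Aggregate standard deviation of (log area, logit circularity).
    n_samples_ : int
        Number of structures the scale was estimated from.
    """

    def __init__(self, clip_eps: float = 1e-6, ddof: int = 1):
        self.clip_eps = clip_eps
        self.ddof = ddof

    @staticmethod
    def _raw_columns(X) -> tuple[np.ndarray, np.ndarray]:
        if isinstance(X, pd.DataFrame):
            return X["area"].to_numpy(float), X["circularity"].to_numpy(float)
        arr = np.asarray(X, dtype=float)
        if arr.ndim != 2 or arr.shape[1] != 2:
            raise ValueError("expected an (n, 2) array of (area, circularity)")
        return arr[:, 0], arr[:, 1]

    def fit(self, X, y=None):
        area, circ = self._raw_columns(X)
        if len(area) < self.ddof + 1:
            raise ValueError("need at least ddof + 1 structures to estimate the scale")
        f_area, f_circ = transform_features(area, circ, self.clip_eps)
        scale = np.array(
            [np.std(f_area, ddof=self.ddof), np.std(f_circ, ddof=self.ddof)]
        )
        if np.any(scale <= 0) or not np.all(np.isfinite(scale)):
            which = FEATURES[int(np.argmin(scale))]
            raise DegenerateDataError(
                f"aggregate variance of {which} is zero; cannot scale to unit variance"
            )
        self.scale_ = scale
        self.n_samples_ = int(len(area))
        return self

    def transform(self, X) -> np.ndarray:
        if not hasattr(self, "scale_"):
            raise RuntimeError("MorphometryTransformer is not fitted")
        area, circ = self._raw_columns(X)
        f_area, f_circ = transform_features(area, circ, self.clip_eps)
        return np.column_stack([f_area, f_circ]) / self.scale_


def scale_unit_variance(
    ds: ScreenDataset, condition: str, eps: float = 1e-6
) -> FeatureMatrix:
    """Build the :class:`FeatureMatrix` for one oncogene condition.

    The scale is estimated on, and applied to, the aggregate of all control
    and knockdown structures of that condition, so each feature has exactly
    unit sample variance over the aggregate afterwards.
    """
    sub = ds.condition_subset(condition)
    if sub.empty:
        raise ValueError(f"no records for oncogene condition {condition!r}")
    tf = MorphometryTransformer(clip_eps=eps).fit(sub)
    scaled = tf.transform(sub)
    frame = sub[["set_id", "population_id", "is_control"]].copy().reset_index(drop=True)
    frame["f_area"] = scaled[:, 0]
    frame["f_circularity"] = scaled[:, 1]
    return FeatureMatrix(
        frame=frame,
        condition=condition,
        feature_sd={"f_area": float(tf.scale_[0]), "f_circularity": float(tf.scale_[1])},
        clip_eps=eps,
    )
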