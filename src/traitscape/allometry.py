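"""Leaf-area allometry: area as a linear function of width x length.

Destructive or optical leaf-area measurement is slow, so area is
predicted from caliper measurements via a single-regressor ordinary
least squares model, ``area = intercept + slope * (width * length)``.
The published *Spartina* calibration (fitted on 10 hybrid and 10
allopolyploid leaves, R^2 >= 0.98) is ``area = 86 + 0.63224 * w * l``;
its coefficients fix the measurement scale, so widths/lengths are
treated as opaque instrument-native units and never converted.
"""

from __future__ import annotations

import json

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin

#: published calibration coefficients
LEAF_AREA_INTERCEPT = 86.0
LEAF_AREA_SLOPE = 0.63224


class LeafAreaModel(RegressorMixin, BaseEstimator):
    """OLS of leaf area on the width*length product, with intercept.

    Fitted attributes: ``intercept_``, ``slope_``, ``r_squared_``.
    ``X`` is an (n, 2) array of ``[width, length]`` columns (or a
    DataFrame with ``width``/``length`` columns).
    """

    @staticmethod
    def _regressor(X) -> np.ndarray:
        if isinstance(X, pd.DataFrame):
            X = X[["width", "length"]].to_numpy(dtype=float)
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != 2:
            raise ValueError("X must have two columns: width, length")
        if (X < 0).any():
            raise ValueError("widths and lengths must be non-negative")
        return X[:, 0] * X[:, 1]

    def fit(self, X, y):
        r = self._regressor(X)
        y = np.asarray(y, dtype=float)
        if len(r) < 3:
            raise ValueError("need at least 3 leaves")
        if np.ptp(r) == 0:
            raise ValueError("width*length is constant; slope is unidentifiable")
        slope, intercept = np.polyfit(r, y, 1)
        self.slope_ = float(slope)
        self.intercept_ = float(intercept)
        fitted = intercept + slope * r
        sse = float(((y - fitted) ** 2).sum())
        sst = float(((y - y.mean()) ** 2).sum())
        self.r_squared_ = 1.0 - sse / sst if sst > 0 else 0.0
        return self

    def predict(self, X) -> np.ndarray:
        if not hasattr(self, "slope_"):
            raise ValueError("model is not fitted")
        return self.intercept_ + self.slope_ * self._regressor(X)

    def to_json(self, path=None) -> str:
        payload = json.dumps({"intercept": self.intercept_, "slope": self.slope_,
                              "r_squared": getattr(self, "r_squared_", None)},
                             indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(payload)
        return payload

    @classmethod
    def from_json(cls, source) -> "LeafAreaModel":
        if isinstance(source, (str, bytes)) and str(source).lstrip().startswith("{"):
            data = json.loads(source)
        else:
            with open(source) as fh:
                data = json.load(fh)
        model = cls()
        model.intercept_ = float(data["intercept"])
        model.slope_ = float(data["slope"])
        if data.get("r_squared") is not None:
            model.r_squared_ = float(data["r_squared"])
        return model


def reference_model() -> LeafAreaModel:
    """The published calibration as a ready-to-predict model."""
    model = LeafAreaModel()
    model.intercept_ = LEAF_AREA_INTERCEPT
    model.slope_ = LEAF_AREA_SLOPE
    model.r_squared_ = 0.98
    return model


def fit_leaf_area(leaves: pd.DataFrame) -> LeafAreaModel:
    """Fit the allometry from a (width, length, area) leaf table."""
    return LeafAreaModel().fit(leaves[["width", "length"]],
                               leaves["area"].to_numpy(dtype=float))


def predict_leaf_area(model: LeafAreaModel, width, length):
    """Predict area for scalar or array width/length measurements."""
    width = np.asarray(width, dtype=float)
    length = np.asarray(length, dtype=float)
    X = np.column_stack([np.atleast_1d(width), np.atleast_1d(length)])
    out = model.predict(X)
    return float(out[0]) if width.ndim == 0 and length.ndim == 0 else out
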