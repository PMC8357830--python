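"""Polynomial gaze regression with progressive calibration.

The gaze mapping is a linear model ``G = V c`` where each row of the
observation matrix ``V`` is a fixed list of monomials evaluated on the 4D
eye-feature vector ``e = (x, y, m, n)`` — relative pupil coordinates
``(x, y)`` and inner eye-corner coordinates ``(m, n)`` — and ``G`` holds the
corresponding known screen targets (one 2D point per row).  The coefficient
matrix ``c`` (N terms x 2 screen coordinates, i.e. 2N unknowns) is the
least-squares solution ``c = (V^T V)^{-1} V^T G``, computed here through a
rank-tolerant pseudo-inverse.

Progressive calibration appends a new ``(e, g)`` row pair every time the
user completes a dwell selection on a known target, and refits.  All rows
are kept forever with equal weight.  Separate models are maintained per eye
and their predictions averaged.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from itertools import combinations_with_replacement

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_array, check_is_fitted

__all__ = [
    "ModelSpec",
    "MODEL_SPECS",
    "DEFAULT_SPEC",
    "get_spec",
    "GazeRegressor",
    "BinocularGazeEstimator",
    "CalibrationSample",
    "NotEnoughSamplesError",
    "combine_eyes",
    "median_fixation_features",
]

_VAR_NAMES = ("x", "y", "m", "n")


class NotEnoughSamplesError(ValueError):
    """Raised when fitting is requested with fewer samples than coefficients."""


def _monomial_name(exponents: tuple[int, int, int, int]) -> str:
    if not any(exponents):
        return "1"
    parts = []
    for var, p in zip(_VAR_NAMES, exponents):
        if p == 1:
            parts.append(var)
        elif p > 1:
            parts.append(f"{var}^{p}")
    return "*".join(parts)


@dataclass(frozen=True)
class ModelSpec:
    """A named monomial basis over the eye features ``(x, y, m, n)``.

    ``terms`` is an ordered tuple of exponent 4-tuples; the term
    ``(1, 0, 0, 0)`` is the monomial ``x``, ``(0, 0, 0, 0)`` the constant.
    The basis must contain the constant term.
    """

    name: str
    terms: tuple[tuple[int, int, int, int], ...]

    def __post_init__(self) -> None:
        if len(self.terms) < 1:
            raise ValueError("a model spec needs at least one term")
        if (0, 0, 0, 0) not in self.terms:
            raise ValueError("the basis must include the constant term")
        if len(set(self.terms)) != len(self.terms):
            raise ValueError("duplicate monomials in basis")

    @property
    def n_terms(self) -> int:
        """Number of basis terms N (the solve has 2N unknowns)."""
        return len(self.terms)

    def term_names(self) -> list[str]:
        return [_monomial_name(t) for t in self.terms]

    def basis_row(self, e) -> np.ndarray:
        """Evaluate the monomials on a single feature vector, in spec order."""
        return self.basis_matrix(np.asarray(e, dtype=float).reshape(1, 4))[0]

    def basis_matrix(self, E) -> np.ndarray:
        """Observation matrix V for a stack of feature vectors (M x 4)."""
        E = np.asarray(E, dtype=float)
        if E.ndim != 2 or E.shape[1] != 4:
            raise ValueError("features must have shape (M, 4)")
        cols = [
            np.prod([E[:, i] ** p for i, p in enumerate(t) if p], axis=0)
            if any(t)
            else np.ones(len(E))
            for t in self.terms
        ]
        return np.column_stack(cols)


def _full_degree2_terms() -> tuple[tuple[int, int, int, int], ...]:
    """All monomials of total degree <= 2 in 4 variables (15 terms)."""
    terms = [(0, 0, 0, 0)]
    for deg in (1, 2):
        for combo in combinations_with_replacement(range(4), deg):
            t = [0, 0, 0, 0]
            for i in combo:
                t[i] += 1
            terms.append(tuple(t))
    return tuple(terms)


_X, _Y, _M, _N = (1, 0, 0, 0), (0, 1, 0, 0), (0, 0, 1, 0), (0, 0, 0, 1)
_ONE = (0, 0, 0, 0)

#: The four model families compared during model selection.  The adopted
#: default is quadratic in relative pupil coordinates with linear eye-corner
#: terms: row [x, y, xy, x^2, y^2, m, n, 1] (8 coefficients per coordinate).
MODEL_SPECS: dict[str, ModelSpec] = {
    "quadratic_pupil": ModelSpec(
        "quadratic_pupil",
        (_X, _Y, (1, 1, 0, 0), (2, 0, 0, 0), (0, 2, 0, 0), _ONE),
    ),
    "quadratic_pupil_linear_corner": ModelSpec(
        "quadratic_pupil_linear_corner",
        (_X, _Y, (1, 1, 0, 0), (2, 0, 0, 0), (0, 2, 0, 0), _M, _N, _ONE),
    ),
    "cubic_pupil_linear_corner": ModelSpec(
        "cubic_pupil_linear_corner",
        (
            _X,
            _Y,
            (1, 1, 0, 0),
            (2, 0, 0, 0),
            (0, 2, 0, 0),
            (3, 0, 0, 0),
            (2, 1, 0, 0),
            (1, 2, 0, 0),
            (0, 3, 0, 0),
            _M,
            _N,
            _ONE,
        ),
    ),
    "full_quadratic": ModelSpec("full_quadratic", _full_degree2_terms()),
}

DEFAULT_SPEC = "quadratic_pupil_linear_corner"


def get_spec(spec) -> ModelSpec:
    """Resolve a spec name, ModelSpec, or explicit monomial list."""
    if isinstance(spec, ModelSpec):
        return spec
    if isinstance(spec, str):
        try:
            return MODEL_SPECS[spec]
        except KeyError:
            raise KeyError(
                f"unknown model spec {spec!r}; known: {sorted(MODEL_SPECS)}"
            ) from None
    return ModelSpec("custom", tuple(tuple(t) for t in spec))


def n_coefficients(spec) -> int:
    """Number of basis terms N of a spec (2N unknowns are solved overall)."""
    return get_spec(spec).n_terms


class GazeRegressor(RegressorMixin, BaseEstimator):
    """Least-squares polynomial gaze model for one eye.

    Maps 4D eye features to 2D normalized screen coordinates using the
    monomial basis of ``spec``.  Fitting solves the normal equations through
    ``numpy.linalg.pinv`` with relative rank tolerance ``rcond``, so a
    near-degenerate observation matrix (e.g. a constant head pose making
    the corner columns collinear with the constant term) yields the
    minimum-norm solution instead of failing.

    Parameters
    ----------
    spec : str or ModelSpec, default "quadratic_pupil_linear_corner"
        Monomial basis. Named families: ``quadratic_pupil`` (6 terms),
        ``quadratic_pupil_linear_corner`` (8, adopted),
        ``cubic_pupil_linear_corner`` (12), ``full_quadratic`` (15).
    rcond : float, default 1e-10
        Relative singular-value cutoff of the pseudo-inverse.

    Attributes
    ----------
    coef_ : ndarray of shape (n_terms, 2)
        Coefficient matrix ``c``.
    V_ : ndarray of shape (M, n_terms)
        Observation matrix accumulated so far.
    G_ : ndarray of shape (M, 2)
        Target matrix accumulated so far.
    n_samples_ : int
        Current number of calibration rows M.
    rank_ : int
        Numerical rank of ``V_`` at the last fit.
    """

    def __init__(self, spec=DEFAULT_SPEC, rcond: float = 1e-10):
        self.spec = spec
        self.rcond = rcond

    # ------------------------------------------------------------------
    def _validate(self, X, y=None):
        X = check_array(X, dtype=float, ensure_min_features=4)
        if X.shape[1] != 4:
            raise ValueError("gaze features must be 4-dimensional (x, y, m, n)")
        if y is None:
            return X
        y = check_array(y, dtype=float, ensure_2d=True)
        if y.shape[1] != 2:
            raise ValueError("gaze targets must be 2-dimensional screen points")
        if len(X) != len(y):
            raise ValueError("X and y have inconsistent lengths")
        return X, y

    def fit(self, X, y):
        """Fit on calibration features X (M, 4) and screen targets y (M, 2)."""
        X, y = self._validate(X, y)
        spec = get_spec(self.spec)
        if len(X) < spec.n_terms:
            raise NotEnoughSamplesError(
                f"need at least {spec.n_terms} samples to fit "
                f"{spec.name!r}, got {len(X)}"
            )
        self.spec_ = spec
        self.V_ = spec.basis_matrix(X)
        self.G_ = y.copy()
        self._solve()
        return self

    def _solve(self) -> None:
        pinv = np.linalg.pinv(self.V_, rcond=self.rcond)
        self.coef_ = pinv @ self.G_
        self.rank_ = int(np.linalg.matrix_rank(self.V_, rtol=self.rcond))
        self.n_samples_ = len(self.V_)
        if self.rank_ < self.spec_.n_terms:
            warnings.warn(
                f"observation matrix is rank deficient "
                f"({self.rank_} < {self.spec_.n_terms}); "
                "using the minimum-norm solution",
                RuntimeWarning,
                stacklevel=3,
            )

    def augment(self, X, y):
        """Append calibration rows and refit (progressive calibration).

        Equivalent to a batch fit on the concatenation of all rows seen so
        far; all prior rows are retained with equal weight.
        """
        X, y = self._validate(np.atleast_2d(X), np.atleast_2d(y))
        spec = get_spec(self.spec)
        rows = spec.basis_matrix(X)
        if not hasattr(self, "V_"):
            self.spec_ = spec
            self.V_ = rows
            self.G_ = y.copy()
        else:
            self.V_ = np.vstack([self.V_, rows])
            self.G_ = np.vstack([self.G_, y])
        if len(self.V_) >= spec.n_terms:
            self._solve()
        return self

    def predict(self, X) -> np.ndarray:
        """Predict normalized screen gaze points for features X (M, 4)."""
        check_is_fitted(self, "coef_")
        X = self._validate(X)
        return self.spec_.basis_matrix(X) @ self.coef_

    # ------------------------------------------------------------------
    def to_json(self) -> str:
        check_is_fitted(self, "coef_")
        return json.dumps(
            {
                "spec_name": self.spec_.name,
                "terms": [list(t) for t in self.spec_.terms],
                "rcond": self.rcond,
                "V": self.V_.tolist(),
                "G": self.G_.tolist(),
                "coef": self.coef_.tolist(),
            }
        )

    @classmethod
    def from_json(cls, payload: str) -> "GazeRegressor":
        d = json.loads(payload)
        spec = ModelSpec(d["spec_name"], tuple(tuple(t) for t in d["terms"]))
        est = cls(spec=spec, rcond=d["rcond"])
        est.spec_ = spec
        est.V_ = np.asarray(d["V"], dtype=float)
        est.G_ = np.asarray(d["G"], dtype=float)
        est.coef_ = np.asarray(d["coef"], dtype=float)
        est.n_samples_ = len(est.V_)
        est.rank_ = int(np.linalg.matrix_rank(est.V_, rtol=est.rcond))
        return est


def combine_eyes(g_left, g_right):
    """Mean of the per-eye gaze predictions, with single-eye fallback.

    An eye's prediction is treated as missing when it is None or contains
    NaN (e.g. that eye's pupil was not detected).  Returns None when both
    are missing.
    """

    def _clean(g):
        if g is None:
            return None
        g = np.asarray(g, dtype=float)
        return None if np.any(np.isnan(g)) else g

    left, right = _clean(g_left), _clean(g_right)
    if left is None and right is None:
        return None
    if left is None:
        return right
    if right is None:
        return left
    return 0.5 * (left + right)


def median_fixation_features(buffer, valid=None, min_valid_fraction: float = 0.5):
    """Component-wise median of buffered per-frame features.

    Fixational eye movements (tremor, drifts, microsaccades) perturb the
    per-frame features even during steady fixation; the median over the
    dwell buffer is robust to these outliers.  Returns None when the buffer
    is empty or fewer than ``min_valid_fraction`` of its frames are valid —
    no calibration sample should be emitted from a mostly-blinked dwell.
    """
    buffer = np.atleast_2d(np.asarray(buffer, dtype=float))
    if buffer.size == 0:
        return None
    if valid is None:
        valid = ~np.any(np.isnan(buffer), axis=1)
    valid = np.asarray(valid, dtype=bool)
    if valid.sum() == 0 or valid.sum() < min_valid_fraction * len(buffer):
        return None
    return np.median(buffer[valid], axis=0)


@dataclass(frozen=True)
class CalibrationSample:
    """A (feature vector, known screen target) pair for one selection.

    Every dwell-triggered selection on a target with a known center yields
    one of these per eye; appending it to the model is what makes the
    calibration progressive.
    """

    t: float
    g: tuple[float, float]
    e_left: tuple[float, float, float, float] | None
    e_right: tuple[float, float, float, float] | None
    source: str = "ui-trigger"  # or "initial-calibration"


@dataclass
class BinocularGazeEstimator:
    """Two per-eye gaze models whose predictions are averaged.

    The two eyes are weighted equally; when one eye's features are missing
    (blink, lost pupil) the other eye's prediction is used alone.
    """

    spec: object = DEFAULT_SPEC
    rcond: float = 1e-10
    left: GazeRegressor = field(init=False)
    right: GazeRegressor = field(init=False)

    def __post_init__(self) -> None:
        self.left = GazeRegressor(spec=self.spec, rcond=self.rcond)
        self.right = GazeRegressor(spec=self.spec, rcond=self.rcond)

    def fit(self, X_left, X_right, y):
        self.left.fit(X_left, y)
        self.right.fit(X_right, y)
        return self

    def augment(self, X_left, X_right, y):
        self.left.augment(X_left, y)
        self.right.augment(X_right, y)
        return self

    def append_sample(self, sample: CalibrationSample):
        """Append one calibration sample (one row per available eye)."""
        g = np.asarray(sample.g, dtype=float).reshape(1, 2)
        if sample.e_left is not None:
            self.left.augment(np.asarray(sample.e_left).reshape(1, 4), g)
        if sample.e_right is not None:
            self.right.augment(np.asarray(sample.e_right).reshape(1, 4), g)
        return self

    @property
    def n_samples_(self) -> tuple[int, int]:
        return (
            getattr(self.left, "n_samples_", 0),
            getattr(self.right, "n_samples_", 0),
        )

    def predict(self, X_left, X_right) -> np.ndarray:
        """Combined gaze prediction; rows with NaN features fall back to
        the other eye, and rows missing both eyes are NaN."""
        X_left = np.atleast_2d(np.asarray(X_left, dtype=float))
        X_right = np.atleast_2d(np.asarray(X_right, dtype=float))
        out = np.full((len(X_left), 2), np.nan)
        for i, (el, er) in enumerate(zip(X_left, X_right)):
            gl = None if np.any(np.isnan(el)) else self.left.predict([el])[0]
            gr = None if np.any(np.isnan(er)) else self.right.predict([er])[0]
            g = combine_eyes(gl, gr)
            if g is not None:
                out[i] = g
        return out
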