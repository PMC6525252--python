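"""Additive protein expression score fitted by component-wise boosting.

The score for a sequence with features x = (x_1, ..., x_K) is

    f(x) = offset + sum_k f_k(x_k),        f_k(x) = sum_b beta_kb B_kb(x)

with cubic P-spline partial functions (B-spline basis, second-order
difference penalty calibrated to ~4 effective degrees of freedom).  Fitting
is least-squares component-wise boosting: each iteration fits every
base-learner to the current residuals, applies the step length nu to the
best one, and repeats; the stopping iteration is chosen by out-of-bag
squared error over nonparametric bootstrap replicates.  Features expected
to act monotonically (current, average elongation rate, log transcript
abundance) are constrained to non-decreasing partials by projecting the
accumulated spline coefficients onto the isotone cone after every update;
the hairpin count enters as a plain linear effect.

The weighted score sum_k v_k f_k(x_k) lets callers emphasise or ignore
features (v_6 = 0 drops the transcript term at sequence-design time, where
transcript abundance is undetermined).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.interpolate import BSpline
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.isotonic import isotonic_regression
from sklearn.utils.validation import check_is_fitted

from .rate_model import CodonRateTable
from .simulator import TranslationSystem, simulate

__all__ = [
    "ExpressionBooster",
    "fit_expression_model",
    "score",
    "explained_variance",
    "SimplifiedScore",
    "fit_simplified",
    "calibrate_initiation_rate",
    "save_model",
    "load_model",
]

logger = logging.getLogger(__name__)

DEFAULT_MONOTONE = ("current", "avg_rate", "log10_transcript")
DEFAULT_LINEAR = ("hairpins",)
SPLINE_DEGREE = 3


def _knots(lo: float, hi: float, n_interior: int) -> np.ndarray:
    if hi <= lo:
        hi = lo + 1.0  # degenerate feature; basis still evaluable
    inner = np.linspace(lo, hi, n_interior + 2)
    return np.concatenate(
        [np.full(SPLINE_DEGREE, lo), inner, np.full(SPLINE_DEGREE, hi)]
    )


def _design(x: np.ndarray, knots: np.ndarray) -> np.ndarray:
    lo, hi = knots[0], knots[-1]
    xc = np.clip(x, lo, hi)
    return BSpline.design_matrix(xc, knots, SPLINE_DEGREE).toarray()


class _SplineLearner:
    """Penalized spline base-learner with fixed smoothing chosen by df."""

    kind = "spline"

    def __init__(self, x: np.ndarray, n_knots: int, df: float, monotone: bool):
        self.lo, self.hi = float(x.min()), float(x.max())
        self.knots = _knots(self.lo, self.hi, n_knots)
        self.monotone = monotone
        B = _design(x, self.knots)
        nb = B.shape[1]
        D = np.diff(np.eye(nb), n=2, axis=0)
        P = D.T @ D
        BtB = B.T @ B + 1e-9 * np.eye(nb)
        # calibrate lambda so the trace of the smoother matrix is ~df:
        # trace = sum_i 1/(1 + lam * e_i) with e_i the generalized
        # eigenvalues of (P, B'B)
        evals = np.clip(np.real(np.linalg.eigvals(np.linalg.solve(BtB, P))), 0, None)
        lam = self._lambda_for_df(evals, df)
        self.M = np.linalg.solve(BtB + lam * P, B.T)
        self.B = B
        self.lam = lam

    @staticmethod
    def _lambda_for_df(evals: np.ndarray, df: float) -> float:
        def trace(lam: float) -> float:
            return float(np.sum(1.0 / (1.0 + lam * evals)))

        lo, hi = 1e-8, 1e12
        if trace(hi) > df:  # penalty null space already exceeds df
            return hi
        for _ in range(100):
            mid = np.sqrt(lo * hi)
            if trace(mid) > df:
                lo = mid
            else:
                hi = mid
        return float(np.sqrt(lo * hi))

    def propose(self, resid: np.ndarray) -> np.ndarray:
        return self.M @ resid

    def design_for(self, x: np.ndarray) -> np.ndarray:
        return _design(x, self.knots)

    def project(self, coef: np.ndarray) -> np.ndarray:
        if not self.monotone:
            return coef
        # non-decreasing B-spline coefficients => non-decreasing function
        return isotonic_regression(coef, increasing=True)


class _LinearLearner:
    """Ordinary least-squares line: exactly two effective parameters."""

    kind = "linear"
    monotone = False

    def __init__(self, x: np.ndarray):
        self.lo, self.hi = float(x.min()), float(x.max())
        X = np.column_stack([np.ones_like(x), x])
        self.M = np.linalg.solve(X.T @ X + 1e-12 * np.eye(2), X.T)
        self.B = X

    def propose(self, resid: np.ndarray) -> np.ndarray:
        return self.M @ resid

    def design_for(self, x: np.ndarray) -> np.ndarray:
        xc = np.clip(np.asarray(x, dtype=float), self.lo, self.hi)
        return np.column_stack([np.ones_like(xc), xc])

    def project(self, coef: np.ndarray) -> np.ndarray:
        return coef


class ExpressionBooster(RegressorMixin, BaseEstimator):
    """Component-wise boosted additive model for log protein abundance.

    Parameters
    ----------
    nu : step length in (0, 1], default 0.1.
    n_knots : interior knots of each P-spline base-learner, default 20.
    df : effective degrees of freedom per spline base-learner, default 4.
    max_iter : boosting iteration budget, default 250.
    mstop : fixed number of boosting iterations; when None it is selected by
        out-of-bag error over ``n_bootstrap`` nonparametric bootstrap
        replicates (the in-bag part fits, the out-of-bag part validates).
    monotone / linear : feature names constrained to non-decreasing partials
        / to plain linear effects.
    random_state : seed for the bootstrap resampling.

    After ``fit``: ``offset_`` (the outcome mean), ``coef_`` (per-feature
    coefficient vectors), ``selected_features_``, ``trace_`` (feature chosen
    at each iteration), ``train_loss_path_``, ``mstop_``.
    """

    def __init__(
        self,
        nu: float = 0.1,
        n_knots: int = 20,
        df: float = 4.0,
        max_iter: int = 250,
        mstop: int | None = None,
        n_bootstrap: int = 25,
        monotone: tuple = DEFAULT_MONOTONE,
        linear: tuple = DEFAULT_LINEAR,
        random_state: int | None = 0,
    ):
        self.nu = nu
        self.n_knots = n_knots
        self.df = df
        self.max_iter = max_iter
        self.mstop = mstop
        self.n_bootstrap = n_bootstrap
        self.monotone = monotone
        self.linear = linear
        self.random_state = random_state

    # -- internals ----------------------------------------------------------

    def _make_learners(self, X: pd.DataFrame) -> dict:
        learners = {}
        for name in X.columns:
            x = X[name].to_numpy(dtype=float)
            if x.std() == 0:
                logger.warning("feature %s is constant; base-learner skipped", name)
                continue
            if name in self.linear:
                learners[name] = _LinearLearner(x)
            else:
                learners[name] = _SplineLearner(
                    x, self.n_knots, self.df, monotone=name in self.monotone
                )
        return learners

    def _boost_path(
        self,
        learners: dict,
        y: np.ndarray,
        n_iter: int,
        val: tuple | None = None,
    ):
        """Run the boosting path; returns (coefs, trace, train losses,
        validation losses).  Stops early when no base-learner improves the
        squared error loss; losses are then padded with their last value."""
        n = y.size
        offset = float(y.mean())
        F = np.full(n, offset)
        coefs = {k: np.zeros(l.B.shape[1]) for k, l in learners.items()}
        trace: list[str] = []
        train_losses: list[float] = []
        if val is not None:
            Xval_designs, yval = val
            Fval = np.full(yval.size, offset)
            val_losses: list[float] = []
        for _ in range(n_iter):
            r = y - F
            best = None
            for name, learner in learners.items():
                u = learner.propose(r)
                new = learner.project(coefs[name] + self.nu * u)
                delta = learner.B @ (new - coefs[name])
                rss = float(np.sum((r - delta) ** 2))
                if best is None or rss < best[0]:
                    best = (rss, name, new, delta)
            rss, name, new, delta = best
            if rss >= np.sum(r**2) - 1e-12:  # no learner improves the loss
                break
            old = coefs[name]
            if val is not None:
                Fval = Fval + Xval_designs[name] @ (new - old)
                val_losses.append(float(np.mean((yval - Fval) ** 2)))
            coefs[name] = new
            F = F + delta
            trace.append(name)
            train_losses.append(rss / n)
        while len(train_losses) < n_iter:
            train_losses.append(train_losses[-1] if train_losses else float(np.var(y)))
            if val is not None:
                val_losses.append(val_losses[-1] if val_losses else float(np.var(yval)))
        if val is not None:
            return coefs, trace, train_losses, val_losses
        return coefs, trace, train_losses, None

    def _select_mstop(self, learners: dict, X: pd.DataFrame, y: np.ndarray) -> int:
        rng = np.random.default_rng(self.random_state)
        n = y.size
        curves = []
        for _ in range(self.n_bootstrap):
            inbag = rng.integers(0, n, size=n)
            oob = np.setdiff1d(np.arange(n), inbag)
            if oob.size == 0:
                continue
            Xi = X.iloc[inbag]
            sub = self._make_learners(Xi)
            designs = {
                k: l.design_for(X[k].to_numpy(dtype=float)[oob])
                for k, l in sub.items()
            }
            _, _, _, vloss = self._boost_path(
                sub, y[inbag], self.max_iter, val=(designs, y[oob])
            )
            curves.append(vloss)
        curves = np.asarray(curves)
        mean_curve = curves.mean(axis=0)
        # one-standard-error rule: the smallest iteration whose mean
        # out-of-bag loss is within one SE of the minimum.  The OOB curve is
        # flat past its optimum, so the plain argmin drifts into iterations
        # that only chase noise.
        am = int(np.argmin(mean_curve))
        se = float(curves[:, am].std(ddof=1) / np.sqrt(curves.shape[0]))
        return int(np.argmax(mean_curve <= mean_curve[am] + se)) + 1

    # -- sklearn API --------------------------------------------------------

    def fit(self, X, y):
        X = self._as_frame(X)
        y = np.asarray(y, dtype=float)
        if X.shape[0] != y.size:
            raise ValueError("X and y disagree in length")
        if X.shape[0] < 20 or X.shape[1] < 2:
            raise ValueError("need at least 20 observations and 2 features")
        if X.isna().any().any() or np.isnan(y).any():
            bad = list(X.columns[X.isna().any()])
            raise ValueError(f"missing values in features {bad} or outcome")
        self.feature_names_in_ = np.asarray(X.columns, dtype=object)
        self.offset_ = float(y.mean())
        learners = self._make_learners(X)
        if not learners or np.var(y) == 0:
            # constant outcome (or all-constant features): offset-only model
            self.learners_ = {}
            self.coef_ = {}
            self.trace_ = []
            self.train_loss_path_ = [float(np.var(y))]
            self.selected_features_ = []
            self.mstop_ = 0
            self.train_range_ = {}
            return self
        mstop = self.mstop if self.mstop is not None else self._select_mstop(
            learners, X, y
        )
        coefs, trace, losses, _ = self._boost_path(learners, y, mstop)
        self.learners_ = learners
        self.coef_ = coefs
        self.trace_ = trace
        self.train_loss_path_ = losses[: len(trace)]
        self.selected_features_ = sorted(set(trace), key=trace.index)
        self.mstop_ = mstop
        self.train_range_ = {k: (l.lo, l.hi) for k, l in learners.items()}
        return self

    @staticmethod
    def _as_frame(X) -> pd.DataFrame:
        if isinstance(X, pd.DataFrame):
            return X
        X = np.asarray(X, dtype=float)
        return pd.DataFrame(X, columns=[f"x{i+1}" for i in range(X.shape[1])])

    def partial_value(self, name: str, x) -> np.ndarray:
        """Evaluate the fitted partial function f_k at x (clamped to the
        training range; unselected features contribute exactly zero)."""
        check_is_fitted(self, "coef_")
        x = np.atleast_1d(np.asarray(x, dtype=float))
        if name not in self.learners_ or name not in set(self.trace_):
            return np.zeros_like(x)
        learner = self.learners_[name]
        lo, hi = self.train_range_[name]
        if np.any((x < lo) | (x > hi)):
            logger.info("feature %s clamped to training range [%g, %g]", name, lo, hi)
        return learner.design_for(np.clip(x, lo, hi)) @ self.coef_[name]

    def predict(self, X) -> np.ndarray:
        check_is_fitted(self, "coef_")
        X = self._as_frame(X)
        out = np.full(X.shape[0], self.offset_)
        for name in self.selected_features_:
            if name not in X.columns:
                raise ValueError(f"feature {name!r} missing at prediction time")
            col = X[name].to_numpy(dtype=float)
            if np.isnan(col).any():
                raise ValueError(f"feature {name!r} contains missing values")
            out = out + self.partial_value(name, col)
        return out

    def score_weighted(self, features, weights: dict | None = None) -> float:
        """Weighted score offset + sum_k v_k f_k(x_k) for one feature vector.

        ``features`` is a mapping / Series / FeatureVector; an absent
        feature is allowed only when its weight is zero.
        """
        check_is_fitted(self, "coef_")
        if hasattr(features, "as_dict"):
            features = features.as_dict()
        elif isinstance(features, pd.Series):
            features = features.to_dict()
        weights = weights or {}
        total = self.offset_
        for name in self.selected_features_:
            v = float(weights.get(name, 1.0))
            if v < 0:
                raise ValueError(f"weight for {name!r} must be nonnegative")
            if v == 0.0:
                continue
            val = features.get(name)
            if val is None or (isinstance(val, float) and np.isnan(val)):
                raise ValueError(
                    f"feature {name!r} absent but has weight {v}; "
                    "set its weight to 0 to ignore it"
                )
            total += v * float(self.partial_value(name, val)[0])
        return float(total)


def fit_expression_model(
    X: pd.DataFrame,
    y,
    *,
    train_fraction: float = 0.7,
    seed: int = 0,
    **booster_kwargs,
):
    """Split 70/30, fit on the training part, report held-out R^2.

    Returns (model, r2_test, train_index, test_index); the split seed is
    recorded on the model (``split_seed_``).
    """
    y = np.asarray(y, dtype=float)
    n = len(X)
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    n_train = int(round(train_fraction * n))
    tr, te = perm[:n_train], perm[n_train:]
    model = ExpressionBooster(**booster_kwargs).fit(X.iloc[tr], y[tr])
    model.split_seed_ = seed
    r2 = explained_variance(model, X.iloc[te], y[te])
    return model, r2, tr, te


def score(model: ExpressionBooster, features, weights: dict | None = None) -> float:
    """Module-level convenience wrapper around ``score_weighted``."""
    return model.score_weighted(features, weights)


def explained_variance(model, X, y) -> float:
    """R^2 = 1 - SS_res / SS_tot on a held-out set."""
    y = np.asarray(y, dtype=float)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0:
        raise ValueError("degenerate held-out outcome: zero total variance")
    pred = model.predict(X)
    return 1.0 - float(np.sum((y - pred) ** 2)) / ss_tot


@dataclass
class SimplifiedScore:
    """Linear score with a quadratic GC3 term (the light-weight variant used
    for interactive sequence design): intercept + sum_k a_k x_k
    + q1*gc3 + q2*gc3**2."""

    intercept: float
    linear: dict
    gc3_quadratic: tuple[float, float] = (0.0, 0.0)

    def __call__(self, features) -> float:
        if hasattr(features, "as_dict"):
            features = features.as_dict()
        elif isinstance(features, pd.Series):
            features = features.to_dict()
        total = self.intercept
        for name, a in self.linear.items():
            val = features.get(name)
            if val is None:
                raise ValueError(f"feature {name!r} absent")
            total += a * float(val)
        q1, q2 = self.gc3_quadratic
        if q1 or q2:
            g = float(features["gc3"])
            total += q1 * g + q2 * g * g
        return float(total)


def fit_simplified(model: ExpressionBooster, X: pd.DataFrame) -> SimplifiedScore:
    """Approximate a fitted additive model by per-feature linear effects
    (quadratic for GC3), least-squares over the observed feature values."""
    check_is_fitted(model, "coef_")
    intercept = model.offset_
    linear: dict[str, float] = {}
    gc3_quad = (0.0, 0.0)
    for name in model.selected_features_:
        x = X[name].to_numpy(dtype=float)
        fx = model.partial_value(name, x)
        if name == "gc3":
            A = np.column_stack([np.ones_like(x), x, x * x])
            c, *_ = np.linalg.lstsq(A, fx, rcond=None)
            intercept += float(c[0])
            gc3_quad = (float(c[1]), float(c[2]))
        else:
            A = np.column_stack([np.ones_like(x), x])
            c, *_ = np.linalg.lstsq(A, fx, rcond=None)
            intercept += float(c[0])
            linear[name] = float(c[1])
    return SimplifiedScore(intercept=intercept, linear=linear, gc3_quadratic=gc3_quad)


def calibrate_initiation_rate(
    sequences: list[str],
    table: CodonRateTable,
    protein_levels,
    alpha_grid,
    *,
    seed: int = 0,
    dropoff_rate: float = 0.0,
    footprint: int = 10,
    simulate_kwargs: dict | None = None,
) -> tuple[float, pd.Series]:
    """Self-consistent initiation rate: the grid value maximizing the
    correlation between simulated currents and observed protein levels.

    Ties resolve to the smallest alpha; a flat correlation profile (all
    within 0.05 of each other) logs a warning.  Returns (alpha, profile).
    """
    from .rate_model import sequence_profiles

    if len(sequences) < 10:
        raise ValueError("need at least 10 sequences to calibrate")
    levels = np.asarray(protein_levels, dtype=float)
    alpha_grid = np.asarray(alpha_grid, dtype=float)
    profiles = [sequence_profiles(s, table)[0] for s in sequences]
    corrs = []
    for ia, alpha in enumerate(alpha_grid):
        currents = []
        for k, rates in enumerate(profiles):
            sys = TranslationSystem(
                rates=rates,
                init_rate=float(alpha),
                dropoff_rate=dropoff_rate,
                footprint=footprint,
            )
            res = simulate(
                sys,
                seed=seed + 10000 * ia + k,
                collect_profile=False,
                **(simulate_kwargs or {}),
            )
            currents.append(res.current)
        currents = np.asarray(currents)
        if currents.std() == 0 or levels.std() == 0:
            corrs.append(np.nan)
        else:
            corrs.append(float(np.corrcoef(currents, levels)[0, 1]))
    profile = pd.Series(corrs, index=alpha_grid, name="correlation")
    if profile.isna().all():
        raise ValueError("correlation undefined for every candidate alpha")
    if float(profile.max() - profile.min()) < 0.05:
        logger.warning("flat correlation profile; initiation rate poorly identified")
    best = float(profile.idxmax())  # idxmax returns the first (smallest) maximizer
    return best, profile


# -- persistence --------------------------------------------------------------


def save_model(model: ExpressionBooster, path: str | Path) -> None:
    """Serialize a fitted model (knots, coefficients, constraints, trace) to
    JSON; reloadable with :func:`load_model` to the identical scores."""
    check_is_fitted(model, "coef_")
    payload = {
        "params": model.get_params(),
        "offset": model.offset_,
        "mstop": model.mstop_,
        "trace": model.trace_,
        "split_seed": getattr(model, "split_seed_", None),
        "features": {},
    }
    for name, learner in model.learners_.items():
        entry = {
            "kind": learner.kind,
            "monotone": bool(getattr(learner, "monotone", False)),
            "range": [learner.lo, learner.hi],
            "coef": model.coef_[name].tolist(),
        }
        if learner.kind == "spline":
            entry["knots"] = learner.knots.tolist()
        payload["features"][name] = entry
    Path(path).write_text(json.dumps(payload, indent=1))


class _FrozenSpline:
    kind = "spline"

    def __init__(self, knots, lo, hi, monotone):
        self.knots = np.asarray(knots)
        self.lo, self.hi = lo, hi
        self.monotone = monotone

    def design_for(self, x):
        return _design(np.asarray(x, dtype=float), self.knots)


class _FrozenLinear:
    kind = "linear"
    monotone = False

    def __init__(self, lo, hi):
        self.lo, self.hi = lo, hi

    def design_for(self, x):
        xc = np.clip(np.asarray(x, dtype=float), self.lo, self.hi)
        return np.column_stack([np.ones_like(xc), xc])


def load_model(path: str | Path) -> ExpressionBooster:
    payload = json.loads(Path(path).read_text())
    model = ExpressionBooster(**payload["params"])
    model.offset_ = payload["offset"]
    model.mstop_ = payload["mstop"]
    model.trace_ = payload["trace"]
    model.selected_features_ = sorted(
        set(model.trace_), key=model.trace_.index
    )
    if payload.get("split_seed") is not None:
        model.split_seed_ = payload["split_seed"]
    model.learners_ = {}
    model.coef_ = {}
    model.train_range_ = {}
    for name, entry in payload["features"].items():
        lo, hi = entry["range"]
        if entry["kind"] == "spline":
            model.learners_[name] = _FrozenSpline(entry["knots"], lo, hi, entry["monotone"])
        else:
            model.learners_[name] = _FrozenLinear(lo, hi)
        model.coef_[name] = np.asarray(entry["coef"], dtype=float)
        model.train_range_[name] = (lo, hi)
    model.feature_names_in_ = np.asarray(list(payload["features"]), dtype=object)
    return model
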