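"""Statistical-parameter surfaces and their prediction.

Alignment-score statistics of unrelated profiles are estimated in two
complementary settings:

* setting A strata profile pairs by their individual attributes
  {n1, l1; n2, l2} (ENO and length of each profile);
* setting B strata pairs by {lambda_u; l1; l2} — the pair's mutual
  compositional similarity (discretized to 0.1-wide bins) and lengths.

Per-stratum Gumbel parameters (mu-hat, sigma-hat) are fitted to the right
tail of the stratum's score sample.  Small feed-forward regressors (one
hidden layer) interpolate the parameters between grid knots; if a trained
regressor fails to reproduce the knots it is replaced by multilinear
scattered-data interpolation.

Predicted parameters are adjusted by the affine/exponential maps

    sigma~A = g_s * mu^^A + g_i          sigma~B = g_c * (exp(sigma^^B) - 1)
    mu~A    = h_s * mu^^A + h_i          mu~B    = mu^^B + h_c

(the first eliminating the need to predict sigma^^A, exploiting the high
correlation between scale and location across strata), and finally
combined by the conditional-mean estimators

    mu-hat    = a * mu~A + (1-a) * mu~B       (0 < a < 1)
    sigma-hat = b * sigma~A + (1-b) * sigma~B (0 < b < 1)

with a = b = 0.35 by default, giving compositional similarity the larger
weight.  The sigma^^B regressor is trained on log(1 + sigma-hat^B), so the
exponential map inverts the training transform and g_c is close to 1 when
predictions are accurate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .errors import FitError, InputError
from .tailstats import EVDParams

logger = logging.getLogger(__name__)

__all__ = [
    "SurfaceEstimates",
    "ParamPredictor",
    "AdjustmentParams",
    "align_profile_sets",
    "estimate_surfaces",
    "train_predictor",
    "adjust_predictions",
    "combine_conditional_mean",
    "default_adjustments",
    "tune_adjustments",
]

SCALE_FLOOR = 1e-3


def align_profile_sets(profile_sets: dict, config=None,
                       max_pairs_per_cellpair: int | None = None,
                       rng: np.random.Generator | None = None):
    """Align all cross-pairs between every pair of grid cells.

    ``profile_sets`` maps (length, eno) cells to profile lists.  Returns a
    pandas DataFrame with one row per alignment: score, omega, l1, l2,
    n1, n2 (cell attributes, higher-ENO profile first), lambda_u and its
    0.1-discretized bin.
    """
    import itertools

    import pandas as pd

    from .alignment import ScorerConfig, build_score_matrix, local_align
    from .composition import (discretize_lambda_u, score_distribution,
                              solve_lambda_u)
    from .errors import ConditionError

    config = config or ScorerConfig()
    rng = rng or np.random.default_rng()
    cells = sorted(profile_sets)
    rows = []
    lam_fallback = None
    for a_idx in range(len(cells)):
        for b_idx in range(a_idx, len(cells)):
            (la, na), (lb, nb) = cells[a_idx], cells[b_idx]
            pa, pb = profile_sets[cells[a_idx]], profile_sets[cells[b_idx]]
            if a_idx == b_idx:
                pairs = list(itertools.combinations(range(len(pa)), 2))
            else:
                pairs = list(itertools.product(range(len(pa)), range(len(pb))))
            if max_pairs_per_cellpair and len(pairs) > max_pairs_per_cellpair:
                sel = rng.choice(len(pairs), size=max_pairs_per_cellpair,
                                 replace=False)
                pairs = [pairs[i] for i in sel]
            for i, j in pairs:
                p1, p2 = pa[i], pb[j]
                m = build_score_matrix(p1, p2, config)
                try:
                    lam = solve_lambda_u(score_distribution(m))
                except ConditionError:
                    lam = None  # assigned the largest observed bin below
                res = local_align(p1, p2, config, matrix=m,
                                  check_expectation=False)
                rows.append((res.score, res.omega, la, lb, na, nb, lam))
    df = pd.DataFrame(rows, columns=["score", "omega", "l1", "l2",
                                     "n1", "n2", "lambda_u"])
    lam_fallback = df["lambda_u"].max()
    df["lambda_u"] = df["lambda_u"].fillna(lam_fallback)
    df["lambda_bin"] = [discretize_lambda_u(v) for v in df["lambda_u"]]
    # canonical attribute order: higher-ENO (then longer) profile first
    swap = (df["n2"] > df["n1"]) | ((df["n2"] == df["n1"]) & (df["l2"] > df["l1"]))
    for x, y in (("n1", "n2"), ("l1", "l2")):
        tmp = df.loc[swap, x].copy()
        df.loc[swap, x] = df.loc[swap, y]
        df.loc[swap, y] = tmp
    return df


def estimate_surfaces(profile_sets: dict, config=None, min_scores: int = 500,
                      tail_fraction: float = 0.10,
                      max_pairs_per_cellpair: int | None = None,
                      rng: np.random.Generator | None = None,
                      samples=None):
    """Fit per-stratum EVDs for settings A and B.

    Setting A strata are the (n1, l1, n2, l2) cell pairs; setting B pools
    the same alignments by (lambda_u bin, l1, l2).  Strata with fewer than
    ``min_scores`` alignments are skipped and listed.  Returns
    (surface_A, surface_B, samples DataFrame).
    """
    from .tailstats import ad_up_statistic, fit_evd_tail

    if samples is None:
        samples = align_profile_sets(profile_sets, config,
                                     max_pairs_per_cellpair, rng)
    surf_a = SurfaceEstimates("A")
    surf_b = SurfaceEstimates("B")
    for surf, cols, keyfn in (
        (surf_a, ["n1", "l1", "n2", "l2"], SurfaceEstimates.key_a),
        (surf_b, ["lambda_bin", "l1", "l2"], SurfaceEstimates.key_b),
    ):
        for key_vals, grp in samples.groupby(cols):
            key = keyfn(*key_vals)
            scores = grp["score"].to_numpy()
            if scores.size < min_scores:
                surf.skipped.append(key)
                continue
            try:
                params = fit_evd_tail(scores, tail_fraction)
            except (FitError, InputError) as exc:
                logger.warning("stratum %s: %s", key, exc)
                surf.skipped.append(key)
                continue
            _, star = ad_up_statistic(scores, params)
            surf.records[key] = params
            surf.diagnostics[key] = {"n": int(scores.size),
                                     "ad_up_star": float(star)}
    return surf_a, surf_b, samples


@dataclass
class SurfaceEstimates:
    """Per-stratum EVD estimates.

    Keys: setting A -> (n1, l1, n2, l2) with n2 <= n1 (queries with n2 > n1
    are swapped before lookup); setting B -> (lambda_bin, l1, l2) with
    l1 >= l2.
    """

    setting: str
    records: dict = field(default_factory=dict)  # key -> EVDParams
    diagnostics: dict = field(default_factory=dict)  # key -> dict
    skipped: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.setting not in ("A", "B"):
            raise InputError("setting must be 'A' or 'B'")

    @staticmethod
    def key_a(n1: float, l1: int, n2: float, l2: int) -> tuple:
        """Canonical setting-A key: the higher-ENO profile first."""
        if (n2, l2) > (n1, l1):
            n1, l1, n2, l2 = n2, l2, n1, l1
        return (float(n1), int(l1), float(n2), int(l2))

    @staticmethod
    def key_b(lam_bin: float, l1: int, l2: int) -> tuple:
        if l2 > l1:
            l1, l2 = l2, l1
        return (float(np.round(lam_bin, 6)), int(l1), int(l2))


def _features(setting: str, keys: np.ndarray) -> np.ndarray:
    keys = np.asarray(keys, dtype=float)
    if setting == "A":
        n1, l1, n2, l2 = keys.T
        return np.column_stack([np.log(l1), np.log(l2), n1, n2])
    lam, l1, l2 = keys.T
    return np.column_stack([lam, np.log(l1), np.log(l2)])


class ParamPredictor:
    """Predicts (mu, [log1p sigma]) from continuous attributes.

    A one-hidden-layer network (<= 8 tanh units) is trained on the grid
    estimates; if its knot reproduction exceeds 5% relative error on mu,
    the predictor falls back to multilinear scattered interpolation with
    nearest-neighbour extension outside the convex hull.  Prediction is a
    plain numpy forward pass, so the object serializes to lists.
    """

    def __init__(self, setting: str, keys: list, targets: np.ndarray,
                 kind: str, payload: dict):
        self.setting = setting
        self.keys = [tuple(k) for k in keys]
        self.targets = np.asarray(targets, dtype=float)
        self.kind = kind  # 'nn' or 'interp'
        self.payload = payload
        karr = np.asarray(self.keys, dtype=float)
        self._lo = karr.min(axis=0)
        self._hi = karr.max(axis=0)

    # -- prediction ----------------------------------------------------
    def clamp_key(self, key) -> tuple:
        return tuple(float(np.clip(v, lo, hi))
                     for v, lo, hi in zip(key, self._lo, self._hi))

    def predict(self, keys) -> np.ndarray:
        keys = np.atleast_2d(np.asarray(keys, dtype=float))
        keys = np.clip(keys, self._lo[None, :], self._hi[None, :])
        X = _features(self.setting, keys)
        if self.kind == "nn":
            p = self.payload
            Xs = (X - p["x_mean"]) / p["x_std"]
            h = np.tanh(Xs @ p["w1"] + p["b1"])
            y = h @ p["w2"] + p["b2"]
            return y * p["y_std"] + p["y_mean"]
        return self._interp(X)

    def _interp(self, X: np.ndarray) -> np.ndarray:
        from scipy.interpolate import LinearNDInterpolator, NearestNDInterpolator

        Xk = _features(self.setting, np.asarray(self.keys, dtype=float))
        out = np.empty((X.shape[0], self.targets.shape[1]))
        for j in range(self.targets.shape[1]):
            y = self.targets[:, j]
            try:
                lin = LinearNDInterpolator(Xk, y)
                vals = lin(X)
            except Exception:
                vals = np.full(X.shape[0], np.nan)
            near = NearestNDInterpolator(Xk, y)
            nanmask = np.isnan(vals)
            if np.any(nanmask):
                vals[nanmask] = near(X[nanmask])
            out[:, j] = vals
        return out

    # -- serialization -------------------------------------------------
    def to_dict(self) -> dict:
        payload = {k: (v.tolist() if isinstance(v, np.ndarray) else v)
                   for k, v in self.payload.items()}
        return {
            "setting": self.setting,
            "kind": self.kind,
            "keys": [list(k) for k in self.keys],
            "targets": self.targets.tolist(),
            "payload": payload,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ParamPredictor":
        payload = {k: (np.asarray(v) if isinstance(v, list) else v)
                   for k, v in d["payload"].items()}
        return cls(d["setting"], [tuple(k) for k in d["keys"]],
                   np.asarray(d["targets"]), d["kind"], payload)


def train_predictor(estimates: SurfaceEstimates, setting: str | None = None,
                    hidden: int = 8, knot_rtol: float = 0.05,
                    random_state: int = 0, kind: str = "nn") -> ParamPredictor:
    """Train the parameter regressor for one setting.

    Targets: mu for setting A; (mu, log1p(sigma)) for setting B.

    ``kind='nn'`` fits the small feed-forward reference regressor and
    falls back to multilinear interpolation when it fails to reproduce
    the knots; ``kind='interp'`` requests the interpolating predictor
    directly (exact at every knot, piecewise linear in between, immune
    to between-knot oscillation).
    """
    setting = setting or estimates.setting
    if setting != estimates.setting:
        raise InputError("setting mismatch")
    keys = sorted(estimates.records)
    if len(keys) < 8:
        raise InputError(
            f"need >= 8 strata to train a predictor, have {len(keys)}"
        )
    params = [estimates.records[k] for k in keys]
    if setting == "A":
        Y = np.array([[p.mu] for p in params])
    else:
        Y = np.array([[p.mu, np.log1p(p.sigma)] for p in params])
    X = _features(setting, np.asarray(keys, dtype=float))

    if kind == "interp":
        return ParamPredictor(setting, keys, Y, "interp", {})
    if kind != "nn":
        raise InputError(f"unknown predictor kind {kind!r}")
    nn_payload = _fit_small_nn(X, Y, hidden, random_state)
    predictor = ParamPredictor(setting, keys, Y, "nn", nn_payload)
    pred_mu = predictor.predict(np.asarray(keys, dtype=float))[:, 0]
    true_mu = Y[:, 0]
    rel = np.abs(pred_mu - true_mu) / np.maximum(np.abs(true_mu), 1e-6)
    if np.max(rel) > knot_rtol:
        logger.warning(
            "setting-%s regressor knot error %.1f%% exceeds %.0f%%; "
            "falling back to multilinear interpolation",
            setting, 100 * np.max(rel), 100 * knot_rtol,
        )
        predictor = ParamPredictor(setting, keys, Y, "interp", {})
    return predictor


def _fit_small_nn(X: np.ndarray, Y: np.ndarray, hidden: int,
                  random_state: int) -> dict:
    from sklearn.neural_network import MLPRegressor

    x_mean, x_std = X.mean(axis=0), np.maximum(X.std(axis=0), 1e-12)
    y_mean, y_std = Y.mean(axis=0), np.maximum(Y.std(axis=0), 1e-12)
    Xs = (X - x_mean) / x_std
    Ys = (Y - y_mean) / y_std
    mlp = MLPRegressor(
        hidden_layer_sizes=(hidden,), activation="tanh", solver="lbfgs",
        alpha=1e-6, max_iter=20000, tol=1e-12, random_state=random_state,
    )
    mlp.fit(Xs, Ys if Ys.shape[1] > 1 else Ys.ravel())
    w2 = mlp.coefs_[1]
    b2 = np.atleast_1d(mlp.intercepts_[1])
    if w2.ndim == 1:
        w2 = w2[:, None]
    return {
        "x_mean": x_mean, "x_std": x_std,
        "y_mean": y_mean, "y_std": y_std,
        "w1": mlp.coefs_[0], "b1": mlp.intercepts_[0],
        "w2": w2, "b2": b2,
    }


@dataclass
class AdjustmentParams:
    """The adjustment coefficients W = {g_s, g_i, g_c, h_s, h_i, h_c} and
    the conditional-mean weights a, b."""

    g_s: float
    g_i: float
    g_c: float
    h_s: float = 1.0
    h_i: float = 0.0
    h_c: float = 0.0
    a: float = 0.35
    b: float = 0.35

    def __post_init__(self) -> None:
        if not (0 < self.a < 1 and 0 < self.b < 1):
            raise InputError("a and b must lie in (0, 1)")

    @property
    def W(self) -> tuple:
        return (self.g_s, self.g_i, self.g_c, self.h_s, self.h_i, self.h_c)


def adjust_predictions(pred_a, pred_b, adj: AdjustmentParams):
    """Apply the adjustment maps to raw predictions.

    pred_a: mu^^A (sigma^^A is never needed); pred_b: (mu^^B, sigma^^B).
    Returns (mu~A, sigma~A, mu~B, sigma~B); nonpositive scales are floored.
    """
    mu_a = np.asarray(pred_a, dtype=float)
    mu_b, sig_b = (np.asarray(v, dtype=float) for v in pred_b)
    sig_ta = adj.g_s * mu_a + adj.g_i
    sig_tb = adj.g_c * np.expm1(sig_b)
    mu_ta = adj.h_s * mu_a + adj.h_i
    mu_tb = mu_b + adj.h_c
    if np.any(sig_ta < SCALE_FLOOR) or np.any(sig_tb < SCALE_FLOOR):
        logger.debug("adjusted scale at or below zero; floored at %g", SCALE_FLOOR)
    return (mu_ta, np.maximum(sig_ta, SCALE_FLOOR),
            mu_tb, np.maximum(sig_tb, SCALE_FLOOR))


def combine_conditional_mean(tilde_a, tilde_b, a: float = 0.35,
                             b: float = 0.35) -> EVDParams | tuple:
    """Conditional-mean combination of settings A and B.

    ``tilde_a`` and ``tilde_b`` are (mu~, sigma~) pairs (scalars or
    arrays).  Returns an :class:`EVDParams` for scalar inputs, else a
    (mu, sigma) array pair.
    """
    if not (0 < a < 1 and 0 < b < 1):
        raise InputError("a and b must lie in (0, 1)")
    mu_a, sig_a = tilde_a
    mu_b, sig_b = tilde_b
    mu = a * np.asarray(mu_a, dtype=float) + (1 - a) * np.asarray(mu_b, dtype=float)
    sigma = b * np.asarray(sig_a, dtype=float) + (1 - b) * np.asarray(sig_b, dtype=float)
    sigma = np.maximum(sigma, SCALE_FLOOR)
    if np.ndim(mu) == 0:
        return EVDParams(mu=float(mu), sigma=float(sigma))
    return mu, sigma


def default_adjustments(surface_a: SurfaceEstimates, pred_b: ParamPredictor,
                        surface_b: SurfaceEstimates,
                        a: float = 0.35, b: float = 0.35) -> AdjustmentParams:
    """Least-squares defaults for W.

    g_s, g_i regress the fitted sigma-hat^A on mu-hat^A across setting-A
    strata; g_c is the through-origin regression of sigma-hat^B on
    exp(sigma^^B) - 1 at the setting-B knots; the location maps default to
    identity (h_s=1, h_i=h_c=0).
    """
    mu_a = np.array([p.mu for p in surface_a.records.values()])
    sig_a = np.array([p.sigma for p in surface_a.records.values()])
    if mu_a.size < 2:
        raise InputError("need >= 2 setting-A strata")
    g_s, g_i = np.polyfit(mu_a, sig_a, 1)
    keys_b = sorted(surface_b.records)
    sig_b_true = np.array([surface_b.records[k].sigma for k in keys_b])
    sig_b_pred = np.expm1(pred_b.predict(np.asarray(keys_b, dtype=float))[:, 1])
    denom = float(sig_b_pred @ sig_b_pred)
    g_c = float(sig_b_true @ sig_b_pred / denom) if denom > 0 else 1.0
    return AdjustmentParams(g_s=float(g_s), g_i=float(g_i), g_c=g_c, a=a, b=b)


def tune_adjustments(defaults: AdjustmentParams, objective,
                     max_iter: int = 300) -> AdjustmentParams:
    """Tune W against a calibration objective (smaller is better).

    ``objective(AdjustmentParams) -> float`` typically measures the KS
    distance between reported null p-values and Uniform(0, 1).  a and b
    stay fixed.  Falls back to the defaults if optimization does not
    improve on them.
    """
    from scipy.optimize import minimize

    x0 = np.array(defaults.W, dtype=float)

    def f(x):
        try:
            adj = AdjustmentParams(*x, a=defaults.a, b=defaults.b)
        except InputError:
            return 1e6
        return objective(adj)

    base = f(x0)
    res = minimize(f, x0, method="Nelder-Mead",
                   options={"maxiter": max_iter, "xatol": 1e-4, "fatol": 1e-5})
    if res.fun < base:
        return AdjustmentParams(*res.x, a=defaults.a, b=defaults.b)
    logger.warning("adjustment tuning did not improve on defaults")
    return defaults
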