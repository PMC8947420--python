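"""Dynamic pressure-to-flow models fitted by nu-support-vector regression.

Four families relate normalized arterial pressure p(n) to flow velocity
v(n):

* FIR   — v(n) = w . (p(n), ..., p(n - n_p)), linear kernel
* NFIR  — v(n) = f(p(n), ..., p(n - n_p)), Gaussian kernel
* ARX   — adds v recurrences v(n-1), ..., v(n - n_v), linear kernel
* NARX  — recurrences plus Gaussian kernel

Models are trained one-step-ahead (teacher forcing: measured v in the
recurrence slots) on the first half of a recording and judged by Pearson
correlation of a free-run prediction — the recursion fed its own output —
over the second half.  Hyperparameters (C, nu, Gaussian width sigma) and
delay orders are selected by exhaustive grid search on that criterion.
nu-SVR sets its own epsilon tube from nu, so epsilon is not searched.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from sklearn.svm import NuSVR

from .errors import AlignmentError, DivergenceError, ParameterError, TrainingError
from .signals import UniformSignal

FAMILIES = ("FIR", "NFIR", "ARX", "NARX")
_LINEAR = {"FIR": True, "NFIR": False, "ARX": True, "NARX": False}
_RECURRENT = {"FIR": False, "NFIR": False, "ARX": True, "NARX": True}

#: free-run output is declared divergent beyond this multiple of the
#: training target range (normalized signals live in [-1, 1])
DIVERGENCE_BOUND = 10.0


@dataclass(frozen=True)
class ModelSpec:
    """One candidate model: family, delay orders and hyperparameters."""

    family: str
    n_p: int
    n_v: int = 0
    C: float = 1.0
    nu: float = 0.5
    sigma: float = 1.0

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ParameterError(f"unknown family {self.family!r}")
        if self.n_p < 0:
            raise ParameterError("pressure delay order must be non-negative")
        if _RECURRENT[self.family] and self.n_v < 1:
            raise ParameterError(f"{self.family} requires n_v >= 1")
        if not _RECURRENT[self.family] and self.n_v != 0:
            raise ParameterError(f"{self.family} must have n_v = 0")
        if not (0 < self.nu < 1):
            raise ParameterError("nu must lie in (0, 1)")
        if self.C <= 0 or self.sigma <= 0:
            raise ParameterError("C and sigma must be positive")

    @property
    def kernel(self) -> str:
        return "linear" if _LINEAR[self.family] else "rbf"

    @property
    def warmup(self) -> int:
        return max(self.n_p, self.n_v)


def embed(
    p: np.ndarray, v: np.ndarray, n_p: int, n_v: int
) -> tuple[np.ndarray, np.ndarray]:
    """Delay-embed a signal pair into a regression table.

    Row ``n`` (for ``n = max(n_p, n_v) .. L-1``) holds features
    ``(v(n-1), ..., v(n-n_v), p(n), p(n-1), ..., p(n-n_p))`` and target
    ``v(n)``; the table has ``L - max(n_p, n_v)`` rows.
    """
    p = np.asarray(p, dtype=float)
    v = np.asarray(v, dtype=float)
    if p.shape != v.shape or p.ndim != 1:
        raise AlignmentError("p and v must be 1-d arrays of equal length")
    w = max(n_p, n_v)
    if p.size <= w:
        raise AlignmentError(f"need more than {w} samples, got {p.size}")
    rows = np.arange(w, p.size)
    cols = []
    for lag in range(1, n_v + 1):
        cols.append(v[rows - lag])
    for lag in range(0, n_p + 1):
        cols.append(p[rows - lag])
    X = np.column_stack(cols)
    return X, v[rows]


@dataclass
class TrainedFlowModel:
    """A fitted nu-SVR flow model with its embedding and free-run machinery."""

    spec: ModelSpec
    svr: NuSVR
    dt: float
    train_description: str = ""
    # cached solution arrays for the fast free-run path
    _sv: np.ndarray = field(default=None, repr=False)
    _dual: np.ndarray = field(default=None, repr=False)
    _intercept: float = 0.0
    _gamma: float = 1.0
    _w: np.ndarray = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self._sv = self.svr.support_vectors_
        self._dual = self.svr.dual_coef_.ravel()
        self._intercept = float(self.svr.intercept_[0])
        self._gamma = float(self.svr._gamma)
        if self.spec.kernel == "linear":
            self._w = self._dual @ self._sv

    def predict_rows(self, X: np.ndarray) -> np.ndarray:
        """Decision function on embedded rows, bypassing estimator overhead.

        Algebraically identical to ``svr.predict`` (verified in tests);
        kept separate because the free-run recursion calls it per sample.
        """
        X = np.atleast_2d(X)
        if self._w is not None:
            return X @ self._w + self._intercept
        d2 = np.sum((X[:, None, :] - self._sv[None, :, :]) ** 2, axis=2)
        return np.exp(-self._gamma * d2) @ self._dual + self._intercept

    def one_step(self, p: np.ndarray, v: np.ndarray) -> np.ndarray:
        """One-step-ahead prediction with measured v in the recurrence slots."""
        X, _ = embed(p, v, self.spec.n_p, self.spec.n_v)
        return self.predict_rows(X)


def sigma_to_gamma(sigma: float) -> float:
    """RBF kernel exp(-||a-b||^2 / (2 sigma^2)) expressed as sklearn gamma."""
    return 1.0 / (2.0 * sigma**2)


def train_model(
    p_train: np.ndarray | UniformSignal,
    v_train: np.ndarray | UniformSignal,
    spec: ModelSpec,
    dt: float | None = None,
) -> TrainedFlowModel:
    """Fit one nu-SVR model one-step-ahead on a training segment.

    Deterministic given the data and spec (the underlying quadratic program
    has a unique optimum and the solver is seed-free).
    """
    if isinstance(p_train, UniformSignal):
        dt = p_train.dt
        p_train = p_train.values
    if isinstance(v_train, UniformSignal):
        v_train = v_train.values
    if dt is None:
        raise ParameterError("dt must be supplied when training from bare arrays")
    X, y = embed(p_train, v_train, spec.n_p, spec.n_v)
    if np.ptp(y) == 0:
        raise TrainingError("training targets are constant; nothing to fit")
    svr = NuSVR(
        kernel=spec.kernel,
        C=spec.C,
        nu=spec.nu,
        gamma=sigma_to_gamma(spec.sigma),
        tol=1e-4,
    )
    svr.fit(X, y)
    return TrainedFlowModel(spec=spec, svr=svr, dt=dt)


def free_run_predict(
    model: TrainedFlowModel,
    p_val: np.ndarray | UniformSignal,
    v_init: np.ndarray | None = None,
) -> np.ndarray:
    """Model-predictive (free-run) output over a validation pressure segment.

    For recurrent families the recursion is seeded with ``v_init`` (the last
    ``n_v`` training targets — never measured validation flow) and then fed
    its own predictions.  Feed-forward families ignore ``v_init``.  Output
    starts at sample ``n_p`` of the segment (pressure warm-up) and has
    length ``len(p_val) - n_p``.
    """
    if isinstance(p_val, UniformSignal):
        p_val = p_val.values
    p_val = np.asarray(p_val, dtype=float)
    n_p, n_v = model.spec.n_p, model.spec.n_v
    if p_val.size < n_p + 1:
        raise AlignmentError(f"validation pressure shorter than n_p+1={n_p + 1}")
    rows = np.arange(n_p, p_val.size)
    p_cols = np.column_stack([p_val[rows - lag] for lag in range(0, n_p + 1)])
    if n_v == 0:
        return model.predict_rows(p_cols)
    if v_init is None or len(v_init) < n_v:
        raise ParameterError(f"recurrent model needs {n_v} seed values in v_init")
    hist = list(np.asarray(v_init, dtype=float)[-n_v:])
    out = np.empty(rows.size)
    bound = DIVERGENCE_BOUND
    for i in range(rows.size):
        feats = np.concatenate((hist[::-1], p_cols[i]))
        vhat = float(model.predict_rows(feats[None, :])[0])
        if not np.isfinite(vhat) or abs(vhat) > bound:
            raise DivergenceError(
                f"free-run output diverged at step {i} (value {vhat!r})"
            )
        out[i] = vhat
        hist.append(vhat)
        hist.pop(0)
    return out


def pearson_cc(v: np.ndarray, v_hat: np.ndarray) -> float:
    """Pearson correlation coefficient between measured and predicted flow."""
    v = np.asarray(v, dtype=float)
    v_hat = np.asarray(v_hat, dtype=float)
    if v.shape != v_hat.shape or v.size < 3:
        raise AlignmentError("need equal-length series of at least 3 samples")
    if np.ptp(v) == 0 or np.ptp(v_hat) == 0:
        raise ParameterError("correlation undefined for a constant series")
    return float(np.corrcoef(v, v_hat)[0, 1])


def split_halves(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Exact 50/50 split by duration: first half trains, second validates."""
    x = np.asarray(x)
    half = x.size // 2
    return x[:half], x[half:]


def default_grid(
    family: str,
    reduced: bool = False,
) -> list[ModelSpec]:
    """Exhaustive hyperparameter grid for one family.

    Full grid: n_p in 1..10 (feed-forward) or 1..8 (recurrent), n_v in 1..6,
    C in 2^{-2..14}, nu in {0.1..0.9}, log2 sigma in -1..5, stepping the
    exponents by 2 to keep desk-scale runtime.  The reduced grid is a small
    sub-grid for smoke tests and synthetic-cohort runs.
    """
    if family not in FAMILIES:
        raise ParameterError(f"unknown family {family!r}")
    recurrent = _RECURRENT[family]
    linear = _LINEAR[family]
    if reduced:
        n_ps = [1, 2, 3]
        n_vs = [1, 2] if recurrent else [0]
        Cs = [1.0, 16.0]
        nus = [0.5]
        sigmas = [1.0, 4.0] if not linear else [1.0]
    else:
        n_ps = list(range(1, 9 if recurrent else 11))
        n_vs = list(range(1, 7)) if recurrent else [0]
        Cs = [2.0**e for e in range(-2, 15, 2)]
        nus = [round(0.1 * k, 1) for k in range(1, 10, 2)]
        sigmas = [2.0**e for e in range(-1, 6, 2)] if not linear else [1.0]
    grid = []
    for n_p, n_v, C, nu, sigma in itertools.product(n_ps, n_vs, Cs, nus, sigmas):
        grid.append(ModelSpec(family=family, n_p=n_p, n_v=n_v, C=C, nu=nu, sigma=sigma))
    return grid


@dataclass
class GridSearchResult:
    model: TrainedFlowModel
    cc_val: float
    cc_train: float
    table: list[tuple[ModelSpec, float]]
    n_failed: int = 0


def grid_search(
    p: np.ndarray | UniformSignal,
    v: np.ndarray | UniformSignal,
    family: str,
    grid: list[ModelSpec] | None = None,
    dt: float | None = None,
) -> GridSearchResult:
    """Train every grid candidate and keep the best free-run validator.

    The winner maximizes Pearson CC between measured and free-run-predicted
    flow on the validation half; ties break toward the simpler model
    (smaller n_p + n_v, then smaller C, then enumeration order).  Candidates
    whose free run diverges are discarded (counted in ``n_failed``).
    """
    if isinstance(p, UniformSignal):
        dt = p.dt
        p = p.values
    if isinstance(v, UniformSignal):
        v = v.values
    if dt is None:
        raise ParameterError("dt must be supplied when searching from bare arrays")
    grid = default_grid(family) if grid is None else list(grid)
    if not grid:
        raise ParameterError("empty hyperparameter grid")
    for spec in grid:
        if spec.family != family:
            raise ParameterError(f"grid entry {spec} does not belong to family {family}")
    p_tr, p_va = split_halves(np.asarray(p, dtype=float))
    v_tr, v_va = split_halves(np.asarray(v, dtype=float))
    best = None
    best_key = None
    table = []
    n_failed = 0
    for order, spec in enumerate(grid):
        try:
            model = train_model(p_tr, v_tr, spec, dt=dt)
            v_hat = free_run_predict(model, p_va, v_init=v_tr[-max(spec.n_v, 1):])
            cc = pearson_cc(v_va[spec.n_p:], v_hat)
        except (DivergenceError, TrainingError):
            n_failed += 1
            continue
        table.append((spec, cc))
        key = (-cc, spec.n_p + spec.n_v, spec.C, order)
        if best_key is None or key < best_key:
            best_key = key
            best = (model, cc)
    if best is None:
        raise TrainingError("every grid candidate failed or diverged")
    model, cc_val = best
    cc_train = pearson_cc(
        v_tr[model.spec.warmup:], model.one_step(p_tr, v_tr)
    )
    return GridSearchResult(
        model=model, cc_val=cc_val, cc_train=cc_train, table=table, n_failed=n_failed
    )
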