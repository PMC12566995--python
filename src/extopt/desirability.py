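"""Multi-response desirability optimization over the coded design region.

Each predicted response y is mapped to a desirability d in [0, 1] by a
one-sided linear ramp (the Derringer–Suich form): for maximization,
d = 0 below the ``low`` anchor, 1 above ``high``, and
((y - low)/(high - low))**exponent between; minimization mirrors it.  The
global desirability D is the geometric mean of the per-response values —
any fully undesirable response vetoes the whole point.  Harrington's
qualitative bands classify D: 0.8–1.00 quite acceptable, 0.63–0.79
acceptable, 0.37–0.62 satisfactory, below 0.37 unacceptable.

The optimum is located by a deterministic dense grid scan over the closed
coded cube [-alpha, alpha]**k followed by coordinate-wise refinement with
step halving, because reduced quadratics can be indefinite and the argmax
can sit on the cube boundary.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .design import Factor, coded_to_actual, rotatable_alpha
from .exceptions import ConfigError, InputError
from .model import QuadraticModel, predict

__all__ = [
    "DesirabilitySpec",
    "OptimumResult",
    "d_transform",
    "global_desirability",
    "classify_band",
    "optimize",
]

BANDS = ("quite_acceptable", "acceptable", "satisfactory", "unacceptable")


@dataclass(frozen=True)
class DesirabilitySpec:
    """Per-response desirability ramp: anchors, direction and exponent."""

    response_name: str
    objective: str = "maximize"
    low: float = 0.0
    high: float = 1.0
    exponent: float = 1.0

    def __post_init__(self) -> None:
        if self.objective not in ("maximize", "minimize"):
            raise ConfigError(f"objective must be maximize or minimize, got {self.objective!r}")
        if self.low == self.high:
            raise ConfigError(f"{self.response_name}: low and high anchors must differ")
        if not self.exponent > 0:
            raise ConfigError(f"{self.response_name}: exponent must be > 0")


@dataclass
class OptimumResult:
    """Argmax of global desirability with its per-response breakdown."""

    coded_point: tuple[float, ...]
    predicted: dict[str, float]
    per_response_d: dict[str, float]
    global_d: float
    band: str
    actual_point: tuple[float, ...] | None = None

    def to_dict(self) -> dict:
        return {
            "coded_point": list(self.coded_point),
            "actual_point": None if self.actual_point is None else list(self.actual_point),
            "predicted": dict(self.predicted),
            "per_response_d": dict(self.per_response_d),
            "global_d": self.global_d,
            "band": self.band,
        }


def d_transform(y, spec: DesirabilitySpec):
    """Map a response value (scalar or array) to desirability in [0, 1]."""
    arr = np.asarray(y, dtype=float)
    lo, hi = sorted((spec.low, spec.high))
    span = hi - lo
    frac = np.clip((arr - lo) / span, 0.0, 1.0)
    if spec.objective == "minimize":
        frac = 1.0 - frac
    elif spec.low > spec.high:
        # maximize with inverted anchors is a spec error, not silently flipped
        raise ConfigError(f"{spec.response_name}: low > high for a maximize objective")
    d = frac**spec.exponent
    return float(d) if arr.ndim == 0 else d


def global_desirability(d_values) -> float:
    """Geometric mean of component desirabilities; any zero vetoes to 0."""
    arr = np.asarray(list(d_values), dtype=float)
    if arr.size == 0:
        raise InputError("global desirability needs at least one component")
    if np.any((arr < 0) | (arr > 1)):
        raise InputError(f"desirabilities must be in [0, 1], got {arr}")
    if np.any(arr == 0.0):
        return 0.0
    return float(np.exp(np.mean(np.log(arr))))


def classify_band(D: float) -> str:
    """Harrington band for a global desirability; boundaries go to the higher band."""
    if not 0.0 <= D <= 1.0:
        raise InputError(f"D must be in [0, 1], got {D}")
    if D >= 0.8:
        return "quite_acceptable"
    if D >= 0.63:
        return "acceptable"
    if D >= 0.37:
        return "satisfactory"
    return "unacceptable"


def _global_d_array(models, specs, pts: np.ndarray) -> np.ndarray:
    """Vectorized D over points; log-mean with -inf marking any zero component."""
    logs = np.zeros(pts.shape[0])
    for m in models:
        d = d_transform(predict(m, pts), specs[m.response_name])
        with np.errstate(divide="ignore"):
            logs += np.log(d)
    return np.exp(logs / len(models))


def optimize(
    models: list[QuadraticModel],
    specs: list[DesirabilitySpec] | dict[str, DesirabilitySpec],
    alpha: float | None = None,
    grid_step: float = 0.01,
    factors: list[Factor] | None = None,
) -> OptimumResult:
    """Maximize global desirability over the closed coded cube.

    A full grid at ``grid_step`` resolution is scanned (ties broken toward
    the lexicographically smallest coded point), then each coordinate is
    refined by local scans with step halving down to 1e-4.  Deterministic
    for fixed inputs.
    """
    if not models:
        raise ConfigError("optimize requires at least one model")
    if not isinstance(specs, dict):
        specs = {s.response_name: s for s in specs}
    missing = [m.response_name for m in models if m.response_name not in specs]
    if missing:
        raise ConfigError(f"no desirability spec for responses: {missing}")
    k = models[0].n_factors
    if any(m.n_factors != k for m in models):
        raise ConfigError("all models must share the same number of factors")
    if alpha is None:
        alpha = rotatable_alpha(k)

    n_axis = int(round(2 * alpha / grid_step)) + 1
    axis = np.linspace(-alpha, alpha, n_axis)

    # chunked row-major scan: first occurrence of the max is the
    # lexicographically smallest argmax
    best_d = -1.0
    best_pt = np.zeros(k)
    tail = np.array(np.meshgrid(*([axis] * (k - 1)), indexing="ij")).reshape(k - 1, -1).T \
        if k > 1 else np.zeros((1, 0))
    for x0 in axis:
        pts = np.column_stack([np.full(tail.shape[0], x0), *tail.T]) if k > 1 \
            else np.array([[x0]])
        dvals = _global_d_array(models, specs, pts)
        i = int(np.argmax(dvals))
        if dvals[i] > best_d + 1e-15:
            best_d = float(dvals[i])
            best_pt = pts[i].copy()

    # coordinate-wise refinement with step halving
    step = grid_step
    while step > 1e-4:
        step /= 2.0
        improved = True
        while improved:
            improved = False
            for j in range(k):
                cand = []
                for delta in (-step, step):
                    p = best_pt.copy()
                    p[j] = np.clip(p[j] + delta, -alpha, alpha)
                    cand.append(p)
                dvals = _global_d_array(models, specs, np.array(cand))
                i = int(np.argmax(dvals))
                if dvals[i] > best_d + 1e-12:
                    best_d = float(dvals[i])
                    best_pt = cand[i]
                    improved = True

    predicted = {m.response_name: predict(m, best_pt) for m in models}
    per_d = {name: d_transform(v, specs[name]) for name, v in predicted.items()}
    for name, v in predicted.items():
        if "dpph" in name.lower() and not 0.0 <= v <= 100.0:
            warnings.warn(f"predicted {name} = {v:.2f}% outside [0, 100]", stacklevel=2)
    D = global_desirability(list(per_d.values()))
    actual = None
    if factors is not None:
        actual = tuple(coded_to_actual(c, f) for c, f in zip(best_pt, factors))
    return OptimumResult(
        coded_point=tuple(float(c) for c in best_pt),
        predicted=predicted,
        per_response_d=per_d,
        global_d=D,
        band=classify_band(D),
        actual_point=actual,
    )
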