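"""Rotatable central composite designs and coded/actual factor mappings.

A central composite rotational design (CCRD) for ``k`` factors consists of a
full 2**k factorial in coded levels ±1, 2k axial (star) points at distance
``alpha`` along each axis, and replicated center runs.  Rotatability —
uniform prediction variance on spheres around the center — requires
``alpha = (2**k) ** 0.25``; for three factors this is 1.6818, conventionally
printed as 1.68.

Factors live in two unit systems.  The *coded* system places the design
center at 0 and the factorial levels at ±1; the *actual* system is the
bench units (percent ethanol, minutes, % m/v).  The affine map

    actual = center + coded * step

with ``step = level(+1) - level(0)`` is authoritative at full precision;
printed level tables are its rounded image.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import ConfigError, InvalidDesignError, SchemaError

__all__ = [
    "Factor",
    "DesignPoint",
    "DesignMatrix",
    "make_ccrd",
    "rotatable_alpha",
    "coded_to_actual",
    "actual_to_coded",
]

POINT_TYPES = ("factorial", "axial", "center")


def rotatable_alpha(k: int) -> float:
    """Axial distance giving a rotatable design: alpha**4 = 2**k."""
    return float((2.0**k) ** 0.25)


@dataclass(frozen=True)
class Factor:
    """One controllable variable with its coded-to-actual affine map.

    Parameters
    ----------
    name : str
        Identifier used in file headers and model term labels.
    unit : str
        Actual unit for display (e.g. ``"%"``, ``"min"``, ``"% m/v"``).
    center : float
        Actual value at coded 0.
    step : float
        Actual-unit change per +1 coded unit; must be positive.
    display_decimals : int
        Decimals used when formatting actual values for output.  Internal
        arithmetic is never rounded.
    """

    name: str
    unit: str = ""
    center: float = 0.0
    step: float = 1.0
    display_decimals: int = 2

    def __post_init__(self) -> None:
        if not self.step > 0:
            raise ConfigError(f"factor {self.name!r}: step must be > 0, got {self.step}")
        if self.display_decimals < 0:
            raise ConfigError(f"factor {self.name!r}: display_decimals must be >= 0")

    def to_actual(self, coded: float) -> float:
        return coded_to_actual(coded, self)

    def to_coded(self, actual: float) -> float:
        return actual_to_coded(actual, self)


def coded_to_actual(coded, factor: Factor):
    """Map coded units to actual units: ``center + coded * step``.

    Accepts scalars or arrays.  Values that come out negative are physically
    impossible for quantities like a solid-to-liquid ratio; they are returned
    unchanged but with a warning so extreme coded inputs are not silent.
    """
    actual = factor.center + np.asarray(coded, dtype=float) * factor.step
    if np.any(actual < 0):
        warnings.warn(
            f"coded value maps to negative actual {factor.name} "
            f"({np.min(actual):.4g} {factor.unit}); physically impossible "
            "for non-negative quantities",
            stacklevel=2,
        )
    if np.isscalar(coded) or np.ndim(coded) == 0:
        return float(actual)
    return actual


def actual_to_coded(actual, factor: Factor):
    """Inverse map: ``(actual - center) / step``."""
    coded = (np.asarray(actual, dtype=float) - factor.center) / factor.step
    if np.isscalar(actual) or np.ndim(actual) == 0:
        return float(coded)
    return coded


@dataclass(frozen=True)
class DesignPoint:
    """A single run: id, point type, and coded coordinates."""

    run_id: int
    point_type: str
    coded: tuple[float, ...]

    def __post_init__(self) -> None:
        if self.point_type not in POINT_TYPES:
            raise InvalidDesignError(f"unknown point type {self.point_type!r}")


@dataclass
class DesignMatrix:
    """A CCRD run list in coded units, with optional factor definitions.

    ``points`` are stored in the standard construction order (factorial,
    axial, center); ``run_order`` is the randomized execution order as a
    permutation of run ids.
    """

    points: list[DesignPoint]
    alpha: float
    factors: list[Factor] | None = None
    run_order: list[int] = field(default_factory=list)
    seed: int | None = None

    def __post_init__(self) -> None:
        if not self.run_order:
            self.run_order = [p.run_id for p in self.points]
        if sorted(self.run_order) != sorted(p.run_id for p in self.points):
            raise InvalidDesignError("run_order is not a permutation of run ids")
        if self.factors is not None and len(self.factors) != self.k:
            raise InvalidDesignError(
                f"{len(self.factors)} factors supplied for a {self.k}-factor design"
            )

    @property
    def k(self) -> int:
        return len(self.points[0].coded)

    @property
    def n_runs(self) -> int:
        return len(self.points)

    def coded_array(self) -> np.ndarray:
        """(n_runs, k) coded coordinates in construction order."""
        return np.array([p.coded for p in self.points], dtype=float)

    def actual_array(self) -> np.ndarray:
        if self.factors is None:
            raise ConfigError("design has no factor definitions")
        coded = self.coded_array()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cols = [coded_to_actual(coded[:, j], f) for j, f in enumerate(self.factors)]
        return np.column_stack(cols)

    def center_run_ids(self) -> list[int]:
        return [p.run_id for p in self.points if p.point_type == "center"]

    def to_frame(self) -> pd.DataFrame:
        names = (
            [f.name for f in self.factors]
            if self.factors is not None
            else [f"X{j + 1}" for j in range(self.k)]
        )
        data = {
            "run_id": [p.run_id for p in self.points],
            "point_type": [p.point_type for p in self.points],
        }
        coded = self.coded_array()
        for j, name in enumerate(names):
            data[f"{name}_coded"] = coded[:, j]
        if self.factors is not None:
            actual = self.actual_array()
            for j, name in enumerate(names):
                data[f"{name}_actual"] = actual[:, j]
        return pd.DataFrame(data)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, factors: list[Factor] | None = None) -> "DesignMatrix":
        df = pd.read_csv(path)
        required = {"run_id", "point_type"}
        if not required.issubset(df.columns):
            raise SchemaError(f"design file missing columns {sorted(required - set(df.columns))}")
        coded_cols = [c for c in df.columns if c.endswith("_coded")]
        if not coded_cols:
            raise SchemaError("design file has no *_coded columns")
        if df["run_id"].duplicated().any():
            dup = int(df.loc[df["run_id"].duplicated(), "run_id"].iloc[0])
            raise SchemaError(f"duplicated run_id {dup}")
        coded_vals = df[coded_cols].to_numpy(dtype=float)
        pts = [
            DesignPoint(
                run_id=int(rid),
                point_type=str(ptype),
                coded=tuple(float(c) for c in row),
            )
            for rid, ptype, row in zip(df["run_id"], df["point_type"], coded_vals)
        ]
        axial = [abs(c) for p in pts if p.point_type == "axial" for c in p.coded if c != 0]
        alpha = max(axial) if axial else 1.0
        return cls(points=pts, alpha=alpha, factors=factors)


def make_ccrd(
    k: int,
    n_center: int = 3,
    alpha_mode: str = "rotatable",
    alpha_value: float | None = None,
    seed: int | None = None,
    factors: list[Factor] | None = None,
) -> DesignMatrix:
    """Construct a central composite design with 2**k + 2k + n_center runs.

    Parameters
    ----------
    k : int
        Number of factors; at least 2.
    n_center : int
        Number of replicated center runs; at least 1 (pure error needs >= 2).
    alpha_mode : {"rotatable", "face", "custom"}
        Axial distance rule: ``(2**k)**0.25`` for rotatable, 1.0 for
        face-centered, or an explicit ``alpha_value``.
    seed : int, optional
        When given, run order is a seed-determined random permutation;
        otherwise the construction order (factorial, axial, center) is kept.
    factors : list of Factor, optional
        Actual-unit definitions, one per factor.
    """
    if k < 2:
        raise InvalidDesignError(f"k must be >= 2, got {k}")
    if n_center < 1:
        raise InvalidDesignError(f"n_center must be >= 1, got {n_center}")
    if alpha_mode == "rotatable":
        alpha = rotatable_alpha(k)
    elif alpha_mode == "face":
        alpha = 1.0
    elif alpha_mode == "custom":
        if alpha_value is None or not alpha_value > 0:
            raise ConfigError("alpha_mode='custom' requires alpha_value > 0")
        alpha = float(alpha_value)
    else:
        raise ConfigError(f"unknown alpha_mode {alpha_mode!r}")

    points: list[DesignPoint] = []
    run_id = 1
    for combo in itertools.product((-1.0, 1.0), repeat=k):
        points.append(DesignPoint(run_id, "factorial", combo))
        run_id += 1
    for j in range(k):
        for sign in (-1.0, 1.0):
            coded = [0.0] * k
            coded[j] = sign * alpha
            points.append(DesignPoint(run_id, "axial", tuple(coded)))
            run_id += 1
    for _ in range(n_center):
        points.append(DesignPoint(run_id, "center", (0.0,) * k))
        run_id += 1

    ids = [p.run_id for p in points]
    if seed is not None:
        rng = np.random.default_rng(seed)
        order = [ids[i] for i in rng.permutation(len(ids))]
    else:
        order = ids
    return DesignMatrix(points=points, alpha=alpha, factors=factors, run_order=order, seed=seed)
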