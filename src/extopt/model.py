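"""Coded second-order response-surface models.

The full quadratic model for ``k`` coded factors,

    Y = b0 + sum_i bi Xi + sum_i bii Xi**2 + sum_{i<j} bij Xi Xj,

is fit by ordinary least squares on the design's coded coordinates.  Term
significance uses the t statistic ``coef / SE`` against a central t
reference with the residual degrees of freedom.  Term selection is a single
pass on the full-model p-values at a threshold (default 0.1, i.e. 90%
confidence), followed by one refit on the retained terms; no model hierarchy
is enforced, so an interaction may be retained without its parent linear
terms — the screening convention of effect-estimate tables in classical
response-surface software.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .design import DesignMatrix, rotatable_alpha
from .exceptions import InputError, ModelSpecError, SingularFitError

__all__ = [
    "ModelTerm",
    "QuadraticModel",
    "full_quadratic_terms",
    "build_model_matrix",
    "fit_full",
    "select_and_refit",
    "effect_table",
    "predict",
    "surface_grid",
]

_KIND_ORDER = {"intercept": 0, "linear": 1, "quadratic": 2, "interaction": 3}


@dataclass(frozen=True)
class ModelTerm:
    """One polynomial term: kind, factor indices, and fit statistics."""

    kind: str
    indices: tuple[int, ...] = ()
    coefficient: float = float("nan")
    std_error: float = float("nan")
    t_value: float = float("nan")
    p_value: float = float("nan")
    selected: bool = True

    def __post_init__(self) -> None:
        if self.kind not in _KIND_ORDER:
            raise ModelSpecError(f"unknown term kind {self.kind!r}")
        n_expected = {"intercept": 0, "linear": 1, "quadratic": 1, "interaction": 2}[self.kind]
        if len(self.indices) != n_expected:
            raise ModelSpecError(f"{self.kind} term needs {n_expected} indices, got {self.indices}")
        if self.kind == "interaction" and self.indices[0] == self.indices[1]:
            raise ModelSpecError("interaction term must reference two distinct factors")

    def evaluate(self, coded: np.ndarray) -> np.ndarray:
        """Evaluate the term at coded points of shape (n, k)."""
        coded = np.atleast_2d(np.asarray(coded, dtype=float))
        if self.kind == "intercept":
            return np.ones(coded.shape[0])
        if self.kind == "linear":
            return coded[:, self.indices[0]]
        if self.kind == "quadratic":
            return coded[:, self.indices[0]] ** 2
        i, j = self.indices
        return coded[:, i] * coded[:, j]

    def label(self, names: list[str] | None = None) -> str:
        def nm(i: int) -> str:
            return names[i] if names else f"X{i + 1}"

        if self.kind == "intercept":
            return "1"
        if self.kind == "linear":
            return nm(self.indices[0])
        if self.kind == "quadratic":
            return f"{nm(self.indices[0])}^2"
        return f"{nm(self.indices[0])}*{nm(self.indices[1])}"

    @classmethod
    def from_label(cls, label: str, **kw) -> "ModelTerm":
        """Parse labels like ``"1"``, ``"X2"``, ``"X1^2"``, ``"X2*X3"``."""
        s = label.strip()
        if s == "1":
            return cls("intercept", (), **kw)

        def idx(tok: str) -> int:
            tok = tok.strip()
            if not tok.upper().startswith("X"):
                raise ModelSpecError(f"cannot parse factor token {tok!r} in {label!r}")
            return int(tok[1:]) - 1

        if "*" in s:
            a, b = s.split("*")
            return cls("interaction", tuple(sorted((idx(a), idx(b)))), **kw)
        if "^2" in s:
            return cls("quadratic", (idx(s.replace("^2", "")),), **kw)
        return cls("linear", (idx(s),), **kw)

    def sort_key(self) -> tuple:
        return (_KIND_ORDER[self.kind], self.indices)


def full_quadratic_terms(k: int) -> list[ModelTerm]:
    """Intercept, k linear, k quadratic, and k(k-1)/2 interaction terms."""
    terms = [ModelTerm("intercept")]
    terms += [ModelTerm("linear", (i,)) for i in range(k)]
    terms += [ModelTerm("quadratic", (i,)) for i in range(k)]
    terms += [ModelTerm("interaction", (i, j)) for i in range(k) for j in range(i + 1, k)]
    return terms


@dataclass
class QuadraticModel:
    """A fitted (or externally specified) second-order polynomial."""

    response_name: str
    terms: list[ModelTerm]
    n_factors: int
    df_residual: int = 0
    sigma2_hat: float = float("nan")
    design_ref: str = ""

    @property
    def coefficients(self) -> dict[str, float]:
        return {t.label(): t.coefficient for t in self.terms}

    @classmethod
    def from_coefficients(
        cls, coefficients: dict[str, float], n_factors: int, response_name: str = ""
    ) -> "QuadraticModel":
        """Build a model from published coefficients (no fit statistics)."""
        terms = [
            ModelTerm.from_label(lbl, coefficient=float(c)) for lbl, c in coefficients.items()
        ]
        return cls(response_name=response_name, terms=terms, n_factors=n_factors)

    def predict(self, coded):
        return predict(self, coded)

    def to_json(self, path=None) -> str:
        payload = {
            "response_name": self.response_name,
            "n_factors": self.n_factors,
            "df_residual": self.df_residual,
            "sigma2_hat": self.sigma2_hat,
            "design_ref": self.design_ref,
            "terms": [
                {
                    "kind": t.kind,
                    "indices": list(t.indices),
                    "label": t.label(),
                    "coefficient": t.coefficient,
                    "std_error": t.std_error,
                    "t_value": t.t_value,
                    "p_value": t.p_value,
                    "selected": t.selected,
                }
                for t in self.terms
            ],
        }
        text = json.dumps(payload, indent=2, sort_keys=True)
        if path is not None:
            with open(path, "w", encoding="utf-8") as fh:
                fh.write(text + "\n")
        return text

    @classmethod
    def from_json(cls, source) -> "QuadraticModel":
        if hasattr(source, "read"):
            payload = json.load(source)
        else:
            try:
                payload = json.loads(source)
            except (json.JSONDecodeError, TypeError):
                with open(source, encoding="utf-8") as fh:
                    payload = json.load(fh)
        terms = [
            ModelTerm(
                kind=t["kind"],
                indices=tuple(t["indices"]),
                coefficient=t["coefficient"],
                std_error=t["std_error"],
                t_value=t["t_value"],
                p_value=t["p_value"],
                selected=t["selected"],
            )
            for t in payload["terms"]
        ]
        return cls(
            response_name=payload["response_name"],
            terms=terms,
            n_factors=payload["n_factors"],
            df_residual=payload["df_residual"],
            sigma2_hat=payload["sigma2_hat"],
            design_ref=payload.get("design_ref", ""),
        )


def _coded(design) -> np.ndarray:
    if isinstance(design, DesignMatrix):
        return design.coded_array()
    return np.atleast_2d(np.asarray(design, dtype=float))


def build_model_matrix(design, terms: list[ModelTerm]) -> np.ndarray:
    """Evaluate each term at each run: column j is term j over the design."""
    coded = _coded(design)
    labels = [t.label() for t in terms]
    if len(set(labels)) != len(labels):
        dup = sorted({l for l in labels if labels.count(l) > 1})
        raise ModelSpecError(f"duplicate model terms: {dup}")
    k = coded.shape[1]
    for t in terms:
        if any(i >= k for i in t.indices):
            raise ModelSpecError(f"term {t.label()} references factor beyond k={k}")
    return np.column_stack([t.evaluate(coded) for t in terms])


def _ols(X: np.ndarray, y: np.ndarray, labels: list[str]):
    """Least squares with SEs, t and two-sided p; raises on rank deficiency."""
    n, p = X.shape
    if n <= p:
        raise SingularFitError(f"n_runs={n} must exceed n_terms={p}")
    rank = np.linalg.matrix_rank(X)
    if rank < p:
        # name the collinear columns via QR pivoting on the gram matrix
        _, r = np.linalg.qr(X)
        bad = [labels[j] for j in range(p) if abs(r[j, j]) < 1e-10 * max(1.0, abs(r[0, 0]))]
        raise SingularFitError(f"model matrix is rank deficient (rank {rank} < {p}); "
                               f"collinear columns: {bad or 'undetermined'}")
    beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    df = n - p
    rss = float(resid @ resid)
    sigma2 = rss / df
    xtx_inv = np.linalg.inv(X.T @ X)
    var = sigma2 * np.diag(xtx_inv)
    se = np.sqrt(np.maximum(var, 0.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, beta / se, np.where(np.abs(beta) > 1e-12, np.inf, 0.0))
    pvals = 2.0 * stats.t.sf(np.abs(t), df)
    pvals = np.where(np.isinf(t), 0.0, pvals)
    pvals = np.where(t == 0.0, 1.0, pvals)
    return beta, se, t, pvals, df, sigma2


def fit_full(design, y, response_name: str = "", terms: list[ModelTerm] | None = None) -> QuadraticModel:
    """Fit the full quadratic model (or a given term set) by least squares."""
    coded = _coded(design)
    y = np.asarray(y, dtype=float)
    if y.shape[0] != coded.shape[0]:
        raise InputError(f"y has {y.shape[0]} entries for {coded.shape[0]} runs")
    k = coded.shape[1]
    if terms is None:
        terms = full_quadratic_terms(k)
    X = build_model_matrix(coded, terms)
    labels = [t.label() for t in terms]
    beta, se, tval, pval, df, sigma2 = _ols(X, y, labels)
    if sigma2 == 0.0:
        warnings.warn("residual variance is zero; t statistics are degenerate", stacklevel=2)
    fitted_terms = [
        replace(t, coefficient=float(b), std_error=float(s), t_value=float(tv),
                p_value=float(pv), selected=True)
        for t, b, s, tv, pv in zip(terms, beta, se, tval, pval)
    ]
    ref = design.seed if isinstance(design, DesignMatrix) else None
    return QuadraticModel(
        response_name=response_name,
        terms=fitted_terms,
        n_factors=k,
        df_residual=df,
        sigma2_hat=float(sigma2),
        design_ref="" if ref is None else f"ccrd-seed-{ref}",
    )


def select_and_refit(design, y, p_threshold: float = 0.1, response_name: str = "") -> QuadraticModel:
    """Screen full-model terms at ``p <= p_threshold`` and refit the survivors.

    The intercept is always retained.  Ties at exactly the threshold are
    kept.  If no other term survives, an intercept-only model is returned
    with a warning.
    """
    full = fit_full(design, y, response_name=response_name)
    kept = [t for t in full.terms if t.kind == "intercept" or t.p_value <= p_threshold]
    if len(kept) == 1:
        warnings.warn(
            f"no term significant at p <= {p_threshold}; returning intercept-only model",
            stacklevel=2,
        )
    coded = _coded(design)
    X = build_model_matrix(coded, kept)
    beta, se, tval, pval, df, sigma2 = _ols(X, np.asarray(y, dtype=float), [t.label() for t in kept])
    terms = [
        replace(t, coefficient=float(b), std_error=float(s), t_value=float(tv),
                p_value=float(pv), selected=True)
        for t, b, s, tv, pv in zip(kept, beta, se, tval, pval)
    ]
    out = QuadraticModel(
        response_name=response_name,
        terms=terms,
        n_factors=full.n_factors,
        df_residual=df,
        sigma2_hat=float(sigma2),
        design_ref=full.design_ref,
    )
    return out


def effect_table(model: QuadraticModel, p_threshold: float = 0.1) -> pd.DataFrame:
    """Ranked effects (Pareto order): |t| descending, intercept excluded.

    Ties in |t| break by term order (linear, quadratic, interaction, then
    factor index).  ``significant`` is ``p <= p_threshold``.
    """
    if model.df_residual < 1:
        raise InputError("effect table requires a fitted model with df_residual >= 1")
    if model.sigma2_hat == 0.0:
        warnings.warn("zero residual variance: all non-zero effects flagged significant",
                      stacklevel=2)
    rows = [t for t in model.terms if t.kind != "intercept"]
    rows.sort(key=lambda t: (-abs(t.t_value), t.sort_key()))
    return pd.DataFrame(
        {
            "term": [t.label() for t in rows],
            "coefficient": [t.coefficient for t in rows],
            "abs_t": [abs(t.t_value) for t in rows],
            "p_value": [t.p_value for t in rows],
            "significant": [t.p_value <= p_threshold for t in rows],
        }
    )


def predict(model: QuadraticModel, coded):
    """Evaluate the model polynomial at one or more coded points."""
    arr = np.asarray(coded, dtype=float)
    scalar = arr.ndim == 1
    pts = np.atleast_2d(arr)
    if pts.shape[1] != model.n_factors:
        raise InputError(f"point has {pts.shape[1]} coordinates, model expects {model.n_factors}")
    X = np.column_stack([t.evaluate(pts) for t in model.terms])
    beta = np.array([t.coefficient for t in model.terms])
    out = X @ beta
    return float(out[0]) if scalar else out


def surface_grid(
    model: QuadraticModel,
    factor_i: int,
    factor_j: int,
    fixed_values: dict[int, float] | None = None,
    resolution: int = 41,
    alpha: float | None = None,
) -> pd.DataFrame:
    """Predicted response on a regular (coded_i, coded_j) grid.

    The grid spans [-alpha, +alpha] in both axes; remaining factors are held
    at ``fixed_values`` (default 0, the design center).  Rows are emitted in
    row-major order (i varies slowest).
    """
    if factor_i == factor_j:
        raise InputError("factor_i and factor_j must differ")
    if resolution < 2:
        raise InputError("resolution must be >= 2")
    if alpha is None:
        alpha = rotatable_alpha(model.n_factors)
    fixed_values = fixed_values or {}
    axis = np.linspace(-alpha, alpha, resolution)
    gi, gj = np.meshgrid(axis, axis, indexing="ij")
    pts = np.zeros((resolution * resolution, model.n_factors))
    for idx, val in fixed_values.items():
        pts[:, idx] = val
    pts[:, factor_i] = gi.ravel()
    pts[:, factor_j] = gj.ravel()
    pred = predict(model, pts)
    return pd.DataFrame(
        {"coded_i": gi.ravel(), "coded_j": gj.ravel(), "predicted": pred}
    )
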