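"""Synthetic designed-extraction experiments.

The study's 17 run-level responses were never published, so every pipeline
stage is exercised against synthetic experiments: responses are drawn from
a known coded quadratic surface plus i.i.d. Gaussian noise on the response
scale, with the noise standard deviation anchored to the published
pure-error mean square (sd 1.79 for DPPH %).  One pseudo-random stream per
experiment is split by run index, so appending runs never perturbs earlier
draws; a seed fully determines the output.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .anova import anova_decompose
from .assay import AssayReading
from .design import DesignMatrix
from .exceptions import InputError
from .model import ModelTerm, QuadraticModel, fit_full, full_quadratic_terms, select_and_refit

__all__ = [
    "SyntheticConfig",
    "generate_responses",
    "generate_assay_readings",
    "recovery_experiment",
]


@dataclass(frozen=True)
class SyntheticConfig:
    """Ground truth for a synthetic experiment.

    ``true_coefficients`` maps term labels ("1", "X1", "X2^2", "X1*X3")
    to coefficients; unlisted terms are zero.  Clamping to a physical range
    (e.g. DPPH in [0, 100]) is off by default so recovery studies stay
    unbiased.
    """

    true_coefficients: dict
    design: DesignMatrix
    noise_sd: float = 1.79
    seed: int = 0
    response_floor: float | None = None
    response_ceiling: float | None = None

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise InputError(f"noise_sd must be >= 0, got {self.noise_sd}")

    def truth_model(self) -> QuadraticModel:
        return QuadraticModel.from_coefficients(
            self.true_coefficients, n_factors=self.design.k, response_name="truth"
        )


def _run_rng(seed: int, run_index: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(run_index,)))


def generate_responses(config: SyntheticConfig) -> np.ndarray:
    """Surface value plus seeded Gaussian noise for every design run."""
    truth = config.truth_model()
    k = config.design.k
    for t in truth.terms:
        if any(i >= k for i in t.indices):
            raise InputError(f"truth term {t.label()} invalid for k={k}")
    surface = truth.predict(config.design.coded_array())
    noise = np.array(
        [_run_rng(config.seed, i).normal(0.0, config.noise_sd) if config.noise_sd > 0 else 0.0
         for i in range(config.design.n_runs)]
    )
    y = surface + noise
    if config.response_floor is not None or config.response_ceiling is not None:
        y = np.clip(y, config.response_floor, config.response_ceiling)
    return y


def generate_assay_readings(
    target_inhibition: float,
    control_abs: float,
    n_replicates: int,
    reading_sd: float,
    seed: int = 0,
) -> list[AssayReading]:
    """Sample absorbances whose DPPH inhibition scatters around a target.

    Inverts I% = (A_c - A_s)/A_c * 100: the noiseless sample absorbance is
    ``control * (1 - target/100)``; Gaussian reading noise is added on the
    absorbance scale and negative absorbances are floored at 0.
    """
    if control_abs <= 0:
        raise InputError(f"control absorbance must be > 0, got {control_abs}")
    base = control_abs * (1.0 - target_inhibition / 100.0)
    rng = np.random.default_rng(seed)
    samples = base + rng.normal(0.0, reading_sd, size=n_replicates)
    return [
        AssayReading(absorbance_sample=max(float(a), 0.0), absorbance_control=control_abs)
        for a in samples
    ]


def _replicate_seed(base_seed: int, rep: int) -> int:
    return int(np.random.SeedSequence(entropy=[base_seed, rep]).generate_state(1)[0] % (2**31))


def recovery_experiment(
    truth: SyntheticConfig,
    n_replicates: int,
    p_threshold: float = 0.1,
    ci_level: float = 0.9,
) -> dict:
    """Repeat generate -> fit -> select -> ANOVA and summarize recovery.

    Returns per-term bias and RMSE of the full-model coefficient estimates,
    the per-term selection frequency of the p-screen, the coverage of the
    full-model ``ci_level`` confidence intervals, and the fraction of
    replicates reaching each ANOVA verdict (on the reduced model).
    """
    if n_replicates < 1:
        raise InputError("n_replicates must be >= 1")
    from scipy import stats  # local import keeps module load light

    design = truth.design
    k = design.k
    terms = full_quadratic_terms(k)
    labels = [t.label() for t in terms]
    true_beta = np.array([truth.true_coefficients.get(lbl, 0.0) for lbl in labels])

    estimates = np.empty((n_replicates, len(terms)))
    selected = np.zeros((n_replicates, len(terms)), dtype=bool)
    covered = np.zeros((n_replicates, len(terms)), dtype=bool)
    verdict_counts: dict[str, int] = {}

    for rep in range(n_replicates):
        cfg = replace(truth, seed=_replicate_seed(truth.seed, rep))
        y = generate_responses(cfg)
        full = fit_full(design, y)
        beta = np.array([t.coefficient for t in full.terms])
        se = np.array([t.std_error for t in full.terms])
        estimates[rep] = beta
        pvals = np.array([t.p_value for t in full.terms])
        selected[rep] = pvals <= p_threshold
        tcrit = stats.t.ppf(0.5 + ci_level / 2.0, full.df_residual)
        covered[rep] = np.abs(beta - true_beta) <= tcrit * se
        reduced = select_and_refit(design, y, p_threshold=p_threshold)
        table = anova_decompose(reduced, design, y, p_threshold=p_threshold)
        v = table.verdict
        verdict_counts[v] = verdict_counts.get(v, 0) + 1

    bias = estimates.mean(axis=0) - true_beta
    rmse = np.sqrt(((estimates - true_beta) ** 2).mean(axis=0))
    return {
        "terms": labels,
        "bias": dict(zip(labels, bias)),
        "rmse": dict(zip(labels, rmse)),
        "selection_frequency": dict(zip(labels, selected.mean(axis=0))),
        "ci_coverage": dict(zip(labels, covered.mean(axis=0))),
        "verdict_fractions": {v: c / n_replicates for v, c in verdict_counts.items()},
        "n_replicates": n_replicates,
    }
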