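"""Tabular IO, study configuration, and the end-to-end pipeline.

CSV dialect is fixed: comma separator, dot decimal, UTF-8, header required.
The pipeline mirrors the study workflow: fit the full quadratic per
response, screen at p <= 0.1 and refit, run the lack-of-fit ANOVA, then
optimize global desirability over the responses whose models came out
significant and predictive; non-predictive responses are reported but
excluded from the desirability aggregate.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .anova import anova_decompose
from .design import DesignMatrix, Factor
from .desirability import DesirabilitySpec, optimize
from .exceptions import ConfigError, SchemaError
from .model import effect_table, select_and_refit

log = logging.getLogger("extopt")

__all__ = ["StudyConfig", "read_table", "read_responses", "run_pipeline", "write_report"]


def read_table(path, schema: dict[str, type]) -> pd.DataFrame:
    """Read a CSV against a column schema; errors carry (row, column) coordinates."""
    path = Path(path)
    if not path.exists():
        raise SchemaError(f"file not found: {path}")
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing_cols = [c for c in schema if c not in df.columns]
    if missing_cols:
        raise SchemaError(f"{path.name}: missing columns {missing_cols}")
    out = {}
    for col, typ in schema.items():
        vals = []
        for i, raw in enumerate(df[col]):
            if raw == "":
                raise SchemaError(f"{path.name}: blank cell at (row {i + 2}, column {col!r})")
            if typ is str:
                vals.append(raw)
                continue
            try:
                vals.append(typ(raw))
            except ValueError:
                raise SchemaError(
                    f"{path.name}: non-numeric cell {raw!r} at (row {i + 2}, column {col!r})"
                ) from None
        out[col] = vals
    result = pd.DataFrame(out)
    if "run_id" in result.columns and result["run_id"].duplicated().any():
        dup = int(result.loc[result["run_id"].duplicated(), "run_id"].iloc[0])
        raise SchemaError(f"{path.name}: duplicated run_id {dup}")
    return result


def read_responses(path, response_names: list[str] | None = None) -> pd.DataFrame:
    """Responses CSV: run_id plus one numeric column per response."""
    header = pd.read_csv(path, nrows=0).columns.tolist()
    if "run_id" not in header:
        raise SchemaError(f"{Path(path).name}: missing column 'run_id'")
    names = response_names or [c for c in header if c != "run_id"]
    schema = {"run_id": int, **{n: float for n in names}}
    df = read_table(path, schema)
    return df.sort_values("run_id").reset_index(drop=True)


@dataclass
class StudyConfig:
    """Configuration for one designed-extraction study."""

    factors: list[Factor]
    responses: list[dict] = field(default_factory=list)  # name, unit, objective
    p_threshold: float = 0.1
    alpha_mode: str = "rotatable"
    desirability: dict[str, dict] = field(default_factory=dict)
    seed: int | None = None
    output_dir: str = "."

    def __post_init__(self) -> None:
        names = [r["name"] for r in self.responses]
        if len(set(names)) != len(names):
            raise ConfigError(f"response names not unique: {names}")
        if not 0.0 < self.p_threshold < 1.0:
            raise ConfigError(f"p_threshold must be in (0, 1), got {self.p_threshold}")

    @classmethod
    def from_yaml(cls, path) -> "StudyConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh)
        factors = [
            Factor(
                name=f["name"],
                unit=f.get("unit", ""),
                center=float(f["center"]),
                step=float(f["step"]),
                display_decimals=int(f.get("display_decimals", 2)),
            )
            for f in raw.get("factors", [])
        ]
        return cls(
            factors=factors,
            responses=raw.get("responses", []),
            p_threshold=float(raw.get("p_threshold", 0.1)),
            alpha_mode=raw.get("alpha_mode", "rotatable"),
            desirability=raw.get("desirability", {}),
            seed=raw.get("seed"),
            output_dir=raw.get("output_dir", "."),
        )


def _spec_for(config: StudyConfig, name: str, y: np.ndarray) -> DesirabilitySpec:
    block = config.desirability.get(name, {})
    objective = block.get("objective")
    if objective is None:
        objective = next(
            (r.get("objective", "maximize") for r in config.responses if r["name"] == name),
            "maximize",
        )
    # default ramp anchors: the observed response range
    return DesirabilitySpec(
        response_name=name,
        objective=objective,
        low=float(block.get("low", np.min(y))),
        high=float(block.get("high", np.max(y))),
        exponent=float(block.get("exponent", 1.0)),
    )


def run_pipeline(config: StudyConfig, design_path, responses_path, grid_step: float = 0.01) -> dict:
    """Full study: fit -> screen -> ANOVA -> desirability optimization -> report dict."""
    design = DesignMatrix.from_csv(design_path, factors=config.factors or None)
    resp_df = read_responses(responses_path)
    names = [r["name"] for r in config.responses] or [
        c for c in resp_df.columns if c != "run_id"
    ]
    report: dict = {"p_threshold": config.p_threshold, "responses": {}, "optimization": {}}

    predictive_models = []
    specs = {}
    for name in names:
        if name not in resp_df.columns:
            raise SchemaError(f"response {name!r} not in {Path(responses_path).name}")
        y = resp_df[name].to_numpy(dtype=float)
        log.info("fitting response %s", name)
        reduced = select_and_refit(design, y, p_threshold=config.p_threshold, response_name=name)
        table = anova_decompose(reduced, design, y, p_threshold=config.p_threshold)
        effects = effect_table(reduced, p_threshold=config.p_threshold)
        entry = {
            "model": {
                "terms": {t.label(): t.coefficient for t in reduced.terms},
                "df_residual": reduced.df_residual,
                "sigma2_hat": reduced.sigma2_hat,
            },
            "anova": table.to_dict(),
            "pareto": effects.to_dict(orient="records"),
            "verdict": table.verdict,
        }
        report["responses"][name] = entry
        if table.verdict == "significant_and_predictive":
            predictive_models.append(reduced)
            specs[name] = _spec_for(config, name, y)
        else:
            log.warning("response %s excluded from desirability (verdict: %s)", name, table.verdict)

    if predictive_models:
        opt = optimize(
            predictive_models,
            specs,
            grid_step=grid_step,
            factors=config.factors or None,
        )
        report["optimization"] = {"status": "ok", **opt.to_dict()}
    else:
        report["optimization"] = {"status": "no optimizable model"}
        log.warning("no response yielded a significant and predictive model")
    return report


def _round_floats(obj, nd: int):
    if isinstance(obj, float):
        return round(obj, nd)
    if isinstance(obj, dict):
        return {k: _round_floats(v, nd) for k, v in obj.items()}
    if isinstance(obj, list):
        return [_round_floats(v, nd) for v in obj]
    return obj


def write_report(report: dict, output_dir, formats=("json", "markdown"), decimals: int = 2):
    """Persist a pipeline report; JSON at full precision, markdown at table precision."""
    outdir = Path(output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []
    if "json" in formats:
        p = outdir / "report.json"
        with open(p, "w", encoding="utf-8") as fh:
            json.dump(report, fh, indent=2, sort_keys=True)
            fh.write("\n")
        written.append(p)
    if "markdown" in formats:
        p = outdir / "report.md"
        with open(p, "w", encoding="utf-8") as fh:
            fh.write(_render_markdown(report, decimals))
        written.append(p)
    if "csv-bundle" in formats:
        for name, entry in report.get("responses", {}).items():
            p = outdir / f"anova_{name}.csv"
            _anova_frame(entry["anova"]).to_csv(p, index=False)
            written.append(p)
            p = outdir / f"pareto_{name}.csv"
            pd.DataFrame(entry["pareto"]).to_csv(p, index=False)
            written.append(p)
    return written


def _anova_frame(a: dict) -> pd.DataFrame:
    rows = [
        ("Regression", a["ss_regression"], a["df_regression"],
         a["ss_regression"] / a["df_regression"], a["f_regression"], a["f_tab_regression"]),
        ("Residue", a["ss_residual"], a["df_residual"],
         a["ss_residual"] / a["df_residual"], None, None),
        ("Lack of fit", a["ss_lof"], a["df_lof"],
         a["ss_lof"] / a["df_lof"] if a["df_lof"] else None, a["f_lof"], a["f_tab_lof"]),
        ("Pure error", a["ss_pure_error"], a["df_pure_error"],
         a["ss_pure_error"] / a["df_pure_error"] if a["df_pure_error"] else None, None, None),
        ("Total", a["ss_total"], a["df_total"], None, None, None),
    ]
    return pd.DataFrame(rows, columns=["source", "SS", "df", "MS", "F_calc", "F_tab"])


def _render_markdown(report: dict, nd: int) -> str:
    lines = ["# Study report", ""]
    for name, entry in report.get("responses", {}).items():
        lines += [f"## Response: {name}", "", "| source | SS | df | MS | F_calc | F_tab |",
                  "|---|---|---|---|---|---|"]
        for _, row in _anova_frame(entry["anova"]).iterrows():
            cells = [row["source"]] + [
                "" if v is None or (isinstance(v, float) and not np.isfinite(v))
                else (f"{v:.{nd}f}" if isinstance(v, float) else str(v))
                for v in row[["SS", "df", "MS", "F_calc", "F_tab"]]
            ]
            lines.append("| " + " | ".join(str(c) for c in cells) + " |")
        a = entry["anova"]
        lines += ["", f"R² = {a['r2']:.{nd}f}, adjusted R² = {a['adj_r2']:.{nd}f}, "
                      f"verdict: {entry['verdict']}", ""]
        terms = entry["model"]["terms"]
        eq = " + ".join(
            f"{c:.{nd}f}" if lbl == "1" else f"{c:+.{nd}f}({lbl})" for lbl, c in terms.items()
        )
        lines += [f"Reduced model: Y = {eq}", ""]
    opt = report.get("optimization", {})
    lines += ["## Optimization", ""]
    if opt.get("status") == "ok":
        lines.append(f"Coded optimum: {[round(c, 4) for c in opt['coded_point']]}")
        if opt.get("actual_point"):
            lines.append(f"Actual optimum: {[round(c, nd) for c in opt['actual_point']]}")
        lines.append(f"Global desirability D = {opt['global_d']:.4f} ({opt['band']})")
    else:
        lines.append(opt.get("status", "not run"))
    lines.append("")
    return "\n".join(lines)
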