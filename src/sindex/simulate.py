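"""Synthetic multi-compound, multi-cell-line screens with known truth.

Generates screens in both file dialects so the fitter, scorer and
prioritizer can each be tested against ground truth without any
external download.  Each compound is assigned an effect class:

* ``null`` — test lines identical to the reference (true dS = 0);
* ``sensitive`` — test AC50 shifted down by a fixed number of decades
  at equal EFF, so true dS = -shift exactly;
* ``resistant`` — AC50 shifted up, true dS = +shift;
* ``partial_responder`` — equal AC50 but the test-line EFF plateaus in
  a 20-50 % control band, which dpAC50 cannot see but dS can;
* ``stimulatory`` — test-line zero-concentration asymptote above 100 %
  control (low-dose growth stimulation).

The raw-dialect table carries noisy responses on an 11-point
log-spaced concentration grid; the prefitted-dialect table carries the
noiseless true parameters; a truth sidecar carries per-record EFF, S
and per-pair dS, never mixed into the main tables.  A seed fully
determines every output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd

from .aggregate import (
    prioritize,
    rank_table,
    score_lookup,
    summarize_screen,
)
from .config import RunConfig
from .fourpl import fit_4pl, logistic4
from .io import ac50_um_to_lac50, prefitted_frame
from .scoring import score_screen
from .types import DoseResponseSeries, PrefittedRecord, ScreenTable

CLASSES = ("null", "sensitive", "resistant", "partial_responder", "stimulatory")


@dataclass(frozen=True)
class SyntheticConfig:
    """Generative settings for a synthetic screen.

    Concentrations follow the deposited 11-point layout, log-spaced over
    1e-3..1e2 micromolar.  Truth priors: zero-asymptote ~ Normal(100, 5)
    % control, infinite-dose asymptote ~ Uniform(0, 60), log10 AC50
    (micromolar) uniform over the grid interior, Hill slope ~
    Uniform(0.5, 3).  Noise on raw responses is additive Gaussian,
    homoscedastic, in % control.
    """

    n_compounds: int = 50
    reference: str = "REF-01"
    test_lines: tuple[str, ...] = ("PNF-01", "PNF-02", "PNF-03", "PNF-04")
    c_min_um: float = 1e-3
    c_max_um: float = 1e2
    n_concentrations: int = 11
    class_proportions: tuple[tuple[str, float], ...] = (
        ("null", 0.30),
        ("sensitive", 0.25),
        ("resistant", 0.25),
        ("partial_responder", 0.10),
        ("stimulatory", 0.10),
    )
    sensitive_shift_decades: float = 1.0
    resistant_shift_decades: float = 1.0
    partial_eff_range: tuple[float, float] = (20.0, 50.0)
    stimulatory_zero_range: tuple[float, float] = (105.0, 130.0)
    asym_zero_sd: float = 5.0
    asym_inf_range: tuple[float, float] = (0.0, 60.0)
    slope_range: tuple[float, float] = (0.5, 3.0)
    lac50_margin_decades: float = 1.5  # keep true AC50s this far inside the grid
    noise_sd: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        total = sum(p for _, p in self.class_proportions)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"class proportions must sum to 1, got {total}")
        if self.n_concentrations < 2:
            raise ValueError("concentration grid needs at least 2 points")
        if not 0 < self.c_min_um < self.c_max_um:
            raise ValueError("require 0 < c_min_um < c_max_um")

    @property
    def grid_um(self) -> np.ndarray:
        return np.logspace(
            math.log10(self.c_min_um), math.log10(self.c_max_um), self.n_concentrations
        )


@dataclass
class SyntheticScreen:
    """Generated screen: raw + prefitted dialects and the truth sidecar."""

    raw: pd.DataFrame
    prefitted: pd.DataFrame
    truth: pd.DataFrame
    config: SyntheticConfig

    def write(self, out_dir: Union[str, Path]) -> dict[str, Path]:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {}
        for name, df in (("raw", self.raw), ("prefitted", self.prefitted), ("truth", self.truth)):
            p = out / f"{name}.csv"
            df.to_csv(p, index=False)
            paths[name] = p
        return paths

    def prefitted_table(self) -> ScreenTable:
        """The noiseless prefitted dialect as an in-memory ScreenTable."""
        table = ScreenTable(dialect="prefitted", source="synthetic")
        for _, row in self.prefitted.iterrows():
            table.add(PrefittedRecord(
                compound_id=row["drug name"],
                cell_line_id=row["cell line name"],
                target_annotation=row["drug target"],
                lac50=row["LAC50"],
                r2=row["R2"],
                tauc=row["TAUC"],
                asym_inf=row["INF"],
                asym_zero=row["ZERO"],
            ))
        table.roles[self.config.reference] = "reference"
        for line in self.config.test_lines:
            table.roles[line] = "test"
        return table

    def raw_series(self) -> list[DoseResponseSeries]:
        grid_cols = [f"C{i}" for i in range(self.config.n_concentrations)]
        dat_cols = [f"dat{i}" for i in range(self.config.n_concentrations)]
        out = []
        for _, row in self.raw.iterrows():
            out.append(DoseResponseSeries(
                compound_id=row["drug name"],
                cell_line_id=row["cell line name"],
                concentrations=tuple(float(row[c]) for c in grid_cols),
                responses=tuple(float(row[c]) for c in dat_cols),
                target_annotation=row["drug target"],
            ))
        return out


def _true_params(cfg: SyntheticConfig, rng: np.random.Generator) -> dict:
    log_lo = math.log10(cfg.c_min_um) + cfg.lac50_margin_decades
    log_hi = math.log10(cfg.c_max_um) - cfg.lac50_margin_decades
    return {
        "asym_zero": float(rng.normal(100.0, cfg.asym_zero_sd)),
        "asym_inf": float(rng.uniform(*cfg.asym_inf_range)),
        "lac50_um": float(rng.uniform(log_lo, log_hi)),
        "slope": float(rng.uniform(*cfg.slope_range)),
    }


def _test_params(ref: dict, klass: str, cfg: SyntheticConfig, rng: np.random.Generator) -> dict:
    p = dict(ref)
    if klass == "sensitive":
        p["lac50_um"] = ref["lac50_um"] - cfg.sensitive_shift_decades
    elif klass == "resistant":
        p["lac50_um"] = ref["lac50_um"] + cfg.resistant_shift_decades
    elif klass == "partial_responder":
        eff = float(rng.uniform(*cfg.partial_eff_range))
        p["asym_inf"] = ref["asym_zero"] - eff
    elif klass == "stimulatory":
        p["asym_zero"] = float(rng.uniform(*cfg.stimulatory_zero_range))
    return p


def _auc_true(p: dict, cfg: SyntheticConfig, n_grid: int = 1001) -> float:
    grid = np.linspace(math.log10(cfg.c_min_um), math.log10(cfg.c_max_um), n_grid)
    vals = logistic4(grid, p["asym_zero"], p["asym_inf"], p["lac50_um"], p["slope"])
    return float(np.trapezoid(vals, grid))


def generate_screen(config: SyntheticConfig) -> SyntheticScreen:
    """Generate one synthetic screen.

    For the ``partial_responder`` class the reference line is given a
    near-complete response (asymptote minimum below 10 % control) so the
    partial plateau on the test side produces a clear EFF contrast.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    grid = cfg.grid_um
    log_grid = np.log10(grid)
    classes, props = zip(*cfg.class_proportions)
    assignments = rng.choice(len(classes), size=cfg.n_compounds, p=props)

    raw_rows, pre_rows, truth_rows = [], [], []
    for ci in range(cfg.n_compounds):
        klass = classes[assignments[ci]]
        compound = f"CPD-{ci + 1:04d}"
        ref_params = _true_params(cfg, rng)
        if klass == "partial_responder":
            ref_params["asym_inf"] = float(rng.uniform(0.0, 10.0))
        line_params = {cfg.reference: ref_params}
        for line in cfg.test_lines:
            line_params[line] = _test_params(ref_params, klass, cfg, rng)

        def true_s(p: dict) -> Optional[float]:
            eff = p["asym_zero"] - p["asym_inf"]
            if eff <= 0:
                return None
            return math.log10(eff) - p["lac50_um"]

        s_ref = true_s(ref_params)
        for line, p in line_params.items():
            curve = logistic4(log_grid, p["asym_zero"], p["asym_inf"], p["lac50_um"], p["slope"])
            noisy = curve + rng.normal(0.0, cfg.noise_sd, size=grid.size)
            target = "inert" if klass == "null" else "active"
            raw = {"cell line name": line, "drug name": compound, "drug target": target}
            for i in range(grid.size):
                raw[f"C{i}"] = grid[i]
                raw[f"dat{i}"] = noisy[i]
            raw_rows.append(raw)
            pre_rows.append({
                "cell line name": line,
                "drug name": compound,
                "drug target": raw["drug target"],
                "LAC50": ac50_um_to_lac50(10.0 ** p["lac50_um"]),
                "R2": 1.0,
                "TAUC": _auc_true(p, cfg),
                "INF": p["asym_inf"],
                "ZERO": p["asym_zero"],
            })
            s_line = true_s(p)
            truth_rows.append({
                "drug name": compound,
                "cell line name": line,
                "class": klass,
                "role": "reference" if line == cfg.reference else "test",
                "true_zero": p["asym_zero"],
                "true_inf": p["asym_inf"],
                "true_lac50": ac50_um_to_lac50(10.0 ** p["lac50_um"]),
                "true_slope": p["slope"],
                "true_eff": p["asym_zero"] - p["asym_inf"],
                "true_s": s_line,
                "true_delta_s": (
                    None if line == cfg.reference or s_ref is None or s_line is None
                    else s_ref - s_line
                ),
            })

    return SyntheticScreen(
        raw=pd.DataFrame(raw_rows),
        prefitted=pd.DataFrame(pre_rows),
        truth=pd.DataFrame(truth_rows),
        config=cfg,
    )


@dataclass
class RecoveryReport:
    """Outcome of the full fit -> score -> summarize -> prioritize chain."""

    confusion: dict = field(default_factory=dict)  # (true class, verdict) -> count
    recall: dict = field(default_factory=dict)     # class -> prioritized fraction
    ds_errors: np.ndarray = field(default_factory=lambda: np.empty(0))
    summaries: list = field(default_factory=list)
    n_compounds: int = 0

    @property
    def median_abs_ds_error(self) -> float:
        return float(np.median(np.abs(self.ds_errors))) if self.ds_errors.size else float("nan")


def end_to_end_recovery(config: SyntheticConfig, run_config: Optional[RunConfig] = None) -> RecoveryReport:
    """Generate, refit the noisy raw data, score, summarize and prioritize.

    Reports the confusion of prioritization verdicts against true effect
    classes, per-class prioritized recall (sensitive class counted as
    recovered when verdict is sensitive_prioritized, resistant likewise)
    and the distribution of per-pair dS estimation errors.
    """
    sim = generate_screen(config)
    fits = [(series, fit_4pl(series)) for series in sim.raw_series()]
    pre = prefitted_frame(fits)

    table = ScreenTable(dialect="prefitted", source="refit")
    for _, row in pre.iterrows():
        table.add(PrefittedRecord(
            compound_id=row["drug name"], cell_line_id=row["cell line name"],
            target_annotation=row["drug target"],
            lac50=None if pd.isna(row["LAC50"]) else float(row["LAC50"]),
            r2=None if pd.isna(row["R2"]) else float(row["R2"]),
            tauc=None if pd.isna(row["TAUC"]) else float(row["TAUC"]),
            asym_inf=None if pd.isna(row["INF"]) else float(row["INF"]),
            asym_zero=None if pd.isna(row["ZERO"]) else float(row["ZERO"]),
        ))
    table.roles[config.reference] = "reference"
    for line in config.test_lines:
        table.roles[line] = "test"

    deltas = score_screen(table, reference=config.reference)
    summaries = summarize_screen(deltas)
    summaries = prioritize(
        summaries, score_lookup(table), config.reference, list(config.test_lines),
        run_config or RunConfig(),
    )

    truth = sim.truth
    class_of = dict(zip(truth["drug name"], truth["class"]))
    true_ds = {
        (row["drug name"], row["cell line name"]): row["true_delta_s"]
        for _, row in truth.iterrows()
        if row["role"] == "test"
    }

    report = RecoveryReport(summaries=summaries, n_compounds=config.n_compounds)
    errors = []
    for d in deltas:
        t = true_ds.get((d.compound_id, d.test_cell_line))
        if d.delta_s is not None and t is not None and not pd.isna(t):
            errors.append(d.delta_s - float(t))
    report.ds_errors = np.asarray(errors)

    counts: dict[str, int] = {}
    hits: dict[str, int] = {}
    for summary in summaries:
        klass = class_of[summary.compound_id]
        key = (klass, summary.verdict)
        report.confusion[key] = report.confusion.get(key, 0) + 1
        counts[klass] = counts.get(klass, 0) + 1
        expected = {"sensitive": "sensitive_prioritized", "resistant": "resistant_prioritized"}
        if klass in expected and summary.verdict == expected[klass]:
            hits[klass] = hits.get(klass, 0) + 1
    for klass in counts:
        if klass in ("sensitive", "resistant"):
            report.recall[klass] = hits.get(klass, 0) / counts[klass]
    return report
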