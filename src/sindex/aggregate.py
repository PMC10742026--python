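"""Aggregation of per-pair dS into compound-level summaries and hit lists.

A compound's dS mean is the simple arithmetic mean of its per-test-line
dS values; its dispersion is tracked both as the sample variance and as
the variance of the mean (sample variance / n).  Prioritization keeps a
compound when (a) the curve fits are trustworthy (R^2 at or above a
threshold in every required line, the reference exempt when it shows no
concentration-response), (b) the effect is large enough
(|dS mean| > 0.5, about a 3-fold arithmetic change), and (c) the effect
is non-inferior to null once cross-line spread is discounted:
|dS mean| - sqrt(variance of the mean) must clear a 0.3 margin (about
2-fold).  Every predicate is recorded in an audit trail.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy.stats import rankdata, spearmanr

from .config import RunConfig
from .scoring import score_record
from .types import CompoundCellScore, CompoundSummary, PairwiseDelta, ScreenTable

_ENDPOINTS = ("delta_s", "delta_pac50", "delta_pauc")


def summarize_compound(deltas: Sequence[PairwiseDelta]) -> CompoundSummary:
    """Aggregate one compound's pairwise deltas into a :class:`CompoundSummary`.

    The mean is taken over defined dS values only; indeterminate lines
    are excluded from ``n_lines`` and counted separately.  Variance
    fields (sample variance and variance of the mean) require at least
    two defined lines.
    """
    if not deltas:
        raise ValueError("summarize_compound needs at least one PairwiseDelta")
    compounds = {d.compound_id for d in deltas}
    references = {d.reference_cell_line for d in deltas}
    if len(compounds) != 1 or len(references) != 1:
        raise ValueError("all deltas must share one compound and one reference")

    values = [d.delta_s for d in deltas if d.delta_s is not None]
    n = len(values)
    target = next((d.target_annotation for d in deltas if d.target_annotation), None)
    summary = CompoundSummary(
        compound_id=next(iter(compounds)),
        reference_cell_line=next(iter(references)),
        ds_values=values,
        n_lines=n,
        n_indeterminate=len(deltas) - n,
        target_annotation=target,
    )
    if n == 0:
        summary.verdict = "excluded:no_data"
        return summary
    summary.ds_mean = float(np.mean(values))
    if n >= 2:
        summary.ds_variance = float(np.var(values, ddof=1))
        summary.ds_variance_of_mean = summary.ds_variance / n
    return summary


def summarize_screen(deltas: Iterable[PairwiseDelta]) -> list[CompoundSummary]:
    """Group deltas by compound (preserving order) and summarize each."""
    groups: dict[str, list[PairwiseDelta]] = {}
    for d in deltas:
        groups.setdefault(d.compound_id, []).append(d)
    return [summarize_compound(g) for g in groups.values()]


def score_lookup(
    table: ScreenTable, eff_floor: Optional[float] = None
) -> dict[tuple[str, str], CompoundCellScore]:
    """Per-(compound, cell line) score lookup used by :func:`prioritize`."""
    return {key: score_record(rec, eff_floor) for key, rec in table.records.items()}


def prioritize(
    summaries: Iterable[CompoundSummary],
    quality: Mapping[tuple[str, str], CompoundCellScore],
    reference: str,
    test_lines: Sequence[str],
    config: Optional[RunConfig] = None,
) -> list[CompoundSummary]:
    """Apply the fit-quality, effect-size and non-inferiority filters.

    ``quality`` maps (compound, cell line) to its score record, carrying
    R^2 and flags.  A compound missing a fit (no record, or no R^2) in
    any required line is ``excluded:missing_fit`` — except the reference
    when its record shows no concentration-response, which is exempt
    from the R^2 requirement.  Verdicts and the full predicate audit are
    written onto the summaries, which are returned in input order.
    """
    cfg = config or RunConfig()
    out = []
    for summary in summaries:
        out.append(_prioritize_one(summary, quality, reference, list(test_lines), cfg))
    return out


def _prioritize_one(
    summary: CompoundSummary,
    quality: Mapping[tuple[str, str], CompoundCellScore],
    reference: str,
    test_lines: list[str],
    cfg: RunConfig,
) -> CompoundSummary:
    audit: dict = {}
    compound = summary.compound_id

    if summary.n_lines == 0:
        summary.verdict = "excluded:no_data"
        summary.audit = audit
        return summary

    # --- fit quality -------------------------------------------------------
    r2_values: dict[str, Optional[float]] = {}
    missing: list[str] = []
    exempt: list[str] = []
    for line in [reference] + test_lines:
        sc = quality.get((compound, line))
        if sc is None:
            missing.append(line)
            continue
        if line == reference and ("no_response" in sc.flags or "stimulatory" in sc.flags):
            # no concentration-response in the reference: R^2 requirement waived
            exempt.append(line)
            continue
        if sc.r2 is None:
            missing.append(line)
            continue
        r2_values[line] = sc.r2
    audit["r2_values"] = r2_values
    audit["r2_exempt"] = exempt
    if missing:
        audit["missing_lines"] = missing
        summary.verdict = "excluded:missing_fit"
        summary.audit = audit
        return summary

    test_r2 = [r2_values[l] for l in test_lines if l in r2_values]
    if cfg.r2_mode == "mean":
        tests_ok = bool(test_r2) and float(np.mean(test_r2)) >= cfg.r2_threshold
    else:
        tests_ok = all(r2 >= cfg.r2_threshold for r2 in test_r2)
    ref_ok = reference in exempt or r2_values.get(reference, -math.inf) >= cfg.r2_threshold
    audit["r2_ok"] = tests_ok and ref_ok

    # --- effect size -------------------------------------------------------
    effect_ok = summary.ds_mean is not None and abs(summary.ds_mean) > cfg.ds_mean_threshold
    audit["effect_ok"] = bool(effect_ok)

    # --- non-inferiority ---------------------------------------------------
    if summary.ds_variance_of_mean is None:
        audit["noninferiority_ok"] = False
        audit["noninferiority_margin"] = None
    else:
        margin = abs(summary.ds_mean) - math.sqrt(summary.ds_variance_of_mean)
        audit["noninferiority_margin"] = margin
        audit["noninferiority_ok"] = margin >= cfg.variance_floor

    if audit["r2_ok"] and audit["effect_ok"] and audit["noninferiority_ok"]:
        summary.verdict = (
            "sensitive_prioritized" if summary.ds_mean < 0 else "resistant_prioritized"
        )
    else:
        summary.verdict = "not_prioritized"
    summary.audit = audit
    return summary


def delta_delta_s(
    ds_mean_tumor: float,
    ds_mean_control: float,
    reference_tumor: Optional[str] = None,
    reference_control: Optional[str] = None,
) -> float:
    """ddS = (tumor-group dS mean) - (control-group dS mean).

    Both group means must be computed against the same designated
    reference line; a mismatch is a hard error.
    """
    if (
        reference_tumor is not None
        and reference_control is not None
        and reference_tumor != reference_control
    ):
        raise ValueError(
            f"ddS requires a shared reference: {reference_tumor!r} != {reference_control!r}"
        )
    return ds_mean_tumor - ds_mean_control


def _deltas_frame(deltas: Union[pd.DataFrame, Iterable[PairwiseDelta]]) -> pd.DataFrame:
    if isinstance(deltas, pd.DataFrame):
        return deltas
    return pd.DataFrame(
        {
            "compound": d.compound_id,
            "test_cell_line": d.test_cell_line,
            "delta_s": d.delta_s,
            "delta_pac50": d.delta_pac50,
            "delta_pauc": d.delta_pauc,
        }
        for d in deltas
    )


def endpoint_correlation(
    deltas: Union[pd.DataFrame, Iterable[PairwiseDelta]],
    group_by: Optional[str] = "test_cell_line",
    min_pairs: int = 3,
) -> pd.DataFrame:
    """Squared Pearson correlations between dS, dpAC50 and dpAUC.

    One row per (group, endpoint pair) with columns ``r2`` and ``n``.
    Incomplete pairs are dropped listwise within each cell; cells with
    fewer than ``min_pairs`` complete pairs, or zero variance in either
    vector, report ``r2 = NaN`` alongside their n.
    """
    df = _deltas_frame(deltas)
    groups = [("all", df)] if group_by is None else list(df.groupby(group_by))
    rows = []
    for name, g in groups:
        for i, x in enumerate(_ENDPOINTS):
            for y in _ENDPOINTS[i + 1:]:
                sub = g[[x, y]].dropna()
                n = len(sub)
                r2 = np.nan
                if n >= min_pairs:
                    xv, yv = sub[x].to_numpy(), sub[y].to_numpy()
                    if np.ptp(xv) > 0 and np.ptp(yv) > 0:
                        r2 = float(np.corrcoef(xv, yv)[0, 1] ** 2)
                rows.append({"group": name, "endpoint_x": x, "endpoint_y": y,
                             "r2": r2, "n": n})
    return pd.DataFrame(rows)


def endpoint_means(deltas: Union[pd.DataFrame, Iterable[PairwiseDelta]]) -> pd.DataFrame:
    """Per-compound means of dS, dpAC50 and dpAUC across test lines."""
    df = _deltas_frame(deltas)
    out = df.groupby("compound", sort=False)[list(_ENDPOINTS)].mean()
    out.columns = ["ds_mean", "dpac50_mean", "dpauc_mean"]
    return out.reset_index()


@dataclass
class RankComparison:
    """Per-compound ranks under the three endpoint means, plus concordance.

    Rank 1 is the most sensitive compound (most negative mean) under
    each endpoint; ties receive average ranks.  ``concordance`` holds
    pairwise Spearman rho over compounds defined under both endpoints.
    """

    table: pd.DataFrame = field(default_factory=pd.DataFrame)
    concordance: dict = field(default_factory=dict)


def rank_table(means: Union[pd.DataFrame, Iterable[PairwiseDelta]]) -> RankComparison:
    """Rank compounds under dS mean, dpAC50 mean and dpAUC mean.

    Accepts either the output of :func:`endpoint_means` or raw deltas.
    Undefined endpoint cells get no rank and are excluded pairwise from
    the Spearman concordance.
    """
    df = means if isinstance(means, pd.DataFrame) else endpoint_means(means)
    if "ds_mean" not in df.columns:
        df = endpoint_means(df)
    if len(df) < 2:
        raise ValueError("rank_table needs at least two compounds")
    out = df.copy()
    cols = ("ds_mean", "dpac50_mean", "dpauc_mean")
    for col in cols:
        vals = out[col].to_numpy(dtype=float)
        ranks = np.full(vals.shape, np.nan)
        defined = np.isfinite(vals)
        if defined.any():
            ranks[defined] = rankdata(vals[defined], method="average")
        out[f"rank_{col}"] = ranks
    concordance = {}
    for i, x in enumerate(cols):
        for y in cols[i + 1:]:
            sub = out[[x, y]].dropna()
            if len(sub) >= 2 and sub[x].nunique() > 1 and sub[y].nunique() > 1:
                rho = float(spearmanr(sub[x], sub[y]).statistic)
            else:
                rho = float("nan")
            concordance[(x, y)] = rho
    return RankComparison(table=out, concordance=concordance)


def ds_distribution_summary(
    deltas: Union[Iterable[PairwiseDelta], Sequence[float]],
    threshold: float = 0.5,
) -> tuple[np.ndarray, tuple[int, int, int]]:
    """Sorted dS values and counts (below -threshold, within, above threshold).

    Mirrors the low-to-high ordering used to display a cell line's dS
    distribution with the +/-0.5 significance thresholds marked.
    """
    values = []
    for d in deltas:
        v = d.delta_s if isinstance(d, PairwiseDelta) else d
        if v is not None and math.isfinite(v):
            values.append(float(v))
    if not values:
        raise ValueError("no defined dS values")
    arr = np.sort(np.asarray(values))
    below = int(np.sum(arr < -threshold))
    above = int(np.sum(arr > threshold))
    return arr, (below, len(arr) - below - above, above)
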