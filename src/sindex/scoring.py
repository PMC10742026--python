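"""The S index and its pairwise differences.

For one compound on one cell line, effectiveness is the asymptote span

    EFF = ZERO - INF            (% control)

and the combined potency-effectiveness score is

    S = log10(EFF / AC50)       (AC50 in micromolar)

The reference-vs-test difference dS = S_ref - S_test is unitless: joint
rescaling of response or concentration units shifts every S by the same
constant and cancels in the difference.  dS > 0 calls the test line
resistant, dS < 0 sensitive.  The potency-only analogue is
dAC50 = log10(AC50_ref / AC50_test) with dpAC50 = -dAC50, and dpAUC is
the same construction on areas under the curve.  On all three "dp"
endpoints, more-negative means the test line is more affected.
"""

from __future__ import annotations

import math
from typing import Optional

from .io import lac50_to_ac50_um
from .types import (
    CompoundCellScore,
    PairwiseDelta,
    PrefittedRecord,
    ScreenTable,
)

LOG_BASE = 10  # fixed; the deposited LAC50 scale and all thresholds are decimal


def effectiveness(asym_zero: Optional[float], asym_inf: Optional[float]) -> Optional[float]:
    """EFF = asymptote maximum (ZERO) minus asymptote minimum (INF).

    Positive for inhibitory responses.  Returns ``None`` when either
    asymptote is absent; callers flag EFF <= 0 as no_response (== 0) or
    stimulatory (< 0), under which S is undefined.
    """
    if asym_zero is None or asym_inf is None:
        return None
    if not (math.isfinite(asym_zero) and math.isfinite(asym_inf)):
        return None
    return asym_zero - asym_inf


def s_score(eff: Optional[float], ac50_um: Optional[float]) -> Optional[float]:
    """S = log10(EFF / AC50), with EFF in % control and AC50 in micromolar.

    Undefined (``None``) unless both arguments are positive — a flagged
    state, never a -inf that could leak into downstream arithmetic.
    """
    if eff is None or ac50_um is None:
        return None
    if not (eff > 0 and ac50_um > 0):
        return None
    return math.log10(eff / ac50_um)


def delta_s(s_ref: Optional[float], s_test: Optional[float]) -> Optional[float]:
    """dS = S_ref - S_test; ``None`` when either side is undefined."""
    if s_ref is None or s_test is None:
        return None
    return s_ref - s_test


def classify_delta_s(ds: Optional[float]) -> str:
    """Sensitivity call from the sign of dS.

    Resistant when dS > 0, sensitive when dS < 0, indeterminate when dS
    is exactly zero or undefined.
    """
    if ds is None or ds == 0:
        return "indeterminate"
    return "resistant" if ds > 0 else "sensitive"


def delta_pac50(
    ac50_ref_um: Optional[float], ac50_test_um: Optional[float]
) -> tuple[Optional[float], Optional[float]]:
    """Relative potency: (dAC50, dpAC50) with dpAC50 = -dAC50 exactly.

    dAC50 = log10(AC50_ref / AC50_test) > 0 means the test line is the
    more potent (more sensitive) side.
    """
    if ac50_ref_um is None or ac50_test_um is None:
        return None, None
    if not (ac50_ref_um > 0 and ac50_test_um > 0):
        return None, None
    d = math.log10(ac50_ref_um / ac50_test_um)
    return d, -d


def delta_pauc(auc_ref: Optional[float], auc_test: Optional[float]) -> Optional[float]:
    """Relative AUC: -log10(AUC_ref / AUC_test).

    Negative when the test AUC is below the reference (test more
    affected), matching dS's sensitive-is-negative orientation.
    """
    if auc_ref is None or auc_test is None:
        return None
    if not (auc_ref > 0 and auc_test > 0):
        return None
    return -math.log10(auc_ref / auc_test)


def score_record(record: PrefittedRecord, eff_floor: Optional[float] = None) -> CompoundCellScore:
    """Compute EFF, AC50 and S for one prefitted record, with quality flags.

    ``eff_floor``, when set, imputes EFF = floor for records whose
    asymptote span is non-positive (no concentration-response), keeping
    them scoreable; by default they stay flagged and undefined.
    """
    flags: set[str] = set()
    eff = effectiveness(record.asym_zero, record.asym_inf)
    if eff is None:
        flags.add("missing")
    elif eff < 0:
        flags.add("stimulatory")
    elif eff == 0:
        flags.add("no_response")
    if eff is not None and eff <= 0 and eff_floor is not None:
        eff = eff_floor

    ac50_um: Optional[float] = None
    if record.has_fit:
        ac50_um = lac50_to_ac50_um(record.lac50)
    else:
        flags.add("missing")

    s = s_score(eff, ac50_um)
    return CompoundCellScore(
        compound_id=record.compound_id,
        cell_line_id=record.cell_line_id,
        eff=eff,
        ac50_um=ac50_um,
        s=s,
        r2=record.r2,
        auc=record.tauc,
        flags=frozenset(flags),
        target_annotation=record.target_annotation,
    )


def _pair_reason(ref: Optional[CompoundCellScore], test: Optional[CompoundCellScore]) -> str:
    if ref is None and test is None:
        return "both_missing"
    if ref is None:
        return "ref_missing"
    if test is None:
        return "test_missing"
    ref_bad = ref.s is None
    test_bad = test.s is None
    if ref_bad and test_bad:
        return "both"
    if ref_bad:
        return "ref_no_response"
    return "test_no_response"


def score_screen(
    table: ScreenTable,
    reference: str,
    eff_floor: Optional[float] = None,
) -> list[PairwiseDelta]:
    """Score every (compound, test line) pair against the reference line.

    Returns one :class:`PairwiseDelta` per pair, grouped by compound in
    table order.  Pairs where either side cannot be scored are retained
    as indeterminate with the reason recorded, so downstream accounting
    (missing-line exclusion) sees them.
    """
    if reference not in table.cell_lines:
        raise ValueError(f"reference cell line {reference!r} not present in table")
    if table.dialect != "prefitted":
        raise ValueError("score_screen expects a prefitted-dialect table; fit raw data first")

    # roster-declared test lines count even when they have no records,
    # so a wholly missing line still surfaces as indeterminate(missing)
    seen = dict.fromkeys(table.cell_lines)
    for line, role in table.roles.items():
        if role == "test":
            seen.setdefault(line)
    test_lines = [cl for cl in seen if cl != reference
                  and table.roles.get(cl, "test") != "other"]
    out: list[PairwiseDelta] = []
    for compound in table.compounds:
        ref_rec = table.get(compound, reference)
        ref_score = score_record(ref_rec, eff_floor) if ref_rec is not None else None
        for line in test_lines:
            rec = table.get(compound, line)
            if rec is None and ref_rec is None:
                continue
            test_score = score_record(rec, eff_floor) if rec is not None else None
            target = None
            for sc in (ref_score, test_score):
                if sc is not None and sc.target_annotation:
                    target = sc.target_annotation
                    break
            if ref_score is None or test_score is None:
                out.append(PairwiseDelta(
                    compound_id=compound, reference_cell_line=reference,
                    test_cell_line=line, call="indeterminate",
                    reason="missing", target_annotation=target,
                ))
                continue
            ds = delta_s(ref_score.s, test_score.s)
            dac50, dpac50 = delta_pac50(ref_score.ac50_um, test_score.ac50_um)
            dpauc = delta_pauc(ref_score.auc, test_score.auc)
            reason = None if ds is not None else _pair_reason(ref_score, test_score)
            out.append(PairwiseDelta(
                compound_id=compound, reference_cell_line=reference,
                test_cell_line=line, delta_s=ds, delta_ac50=dac50,
                delta_pac50=dpac50, delta_pauc=dpauc,
                call=classify_delta_s(ds), reason=reason,
                target_annotation=target,
            ))
    return out
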