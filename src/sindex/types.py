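"""Domain containers shared across the pipeline.

Two input dialects exist side by side: *raw* records carry the measured
(concentration, response) points for one compound on one cell line, and
*prefitted* records carry 4PL parameters as deposited by the screening
facility (log10-molar AC50, asymptotes in % of DMSO control, R^2 and a
total area under the curve).  Both flow into the same scoring layer.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

#: maximum points per concentration series (C0..C10 layout)
MAX_POINTS = 11


class NoFitError(ValueError):
    """Raised when an operation requires a usable curve fit and none exists."""


@dataclass(frozen=True)
class DoseResponseSeries:
    """Measured concentration-response points for one compound x one cell line.

    Concentrations are in micromolar and strictly increasing after
    canonicalization; responses are in % of the DMSO (vehicle) control,
    where 100 means vehicle-like survival and 0 complete loss of signal.
    Pairs with a missing member are dropped before construction.
    """

    compound_id: str
    cell_line_id: str
    concentrations: tuple[float, ...]
    responses: tuple[float, ...]
    target_annotation: Optional[str] = None

    def __post_init__(self) -> None:
        conc = np.asarray(self.concentrations, dtype=float)
        resp = np.asarray(self.responses, dtype=float)
        if conc.shape != resp.shape:
            raise ValueError(
                f"{self.compound_id}/{self.cell_line_id}: "
                f"{conc.size} concentrations vs {resp.size} responses"
            )
        keep = np.isfinite(conc) & np.isfinite(resp)
        conc, resp = conc[keep], resp[keep]
        if not (2 <= conc.size <= MAX_POINTS):
            raise ValueError(
                f"{self.compound_id}/{self.cell_line_id}: "
                f"{conc.size} usable points, need 2..{MAX_POINTS}"
            )
        if np.any(conc <= 0):
            raise ValueError(
                f"{self.compound_id}/{self.cell_line_id}: non-positive concentration"
            )
        order = np.argsort(conc)
        conc, resp = conc[order], resp[order]
        if np.any(np.diff(conc) <= 0):
            raise ValueError(
                f"{self.compound_id}/{self.cell_line_id}: duplicate concentrations"
            )
        object.__setattr__(self, "concentrations", tuple(conc.tolist()))
        object.__setattr__(self, "responses", tuple(resp.tolist()))

    @property
    def n_points(self) -> int:
        return len(self.concentrations)


@dataclass(frozen=True)
class PrefittedRecord:
    """Deposited 4PL fit for one compound x one cell line.

    ``lac50`` is log10 of AC50 in molar units; ``asym_zero`` / ``asym_inf``
    are the response asymptotes extrapolated to zero / infinite
    concentration, in % control.  Any field may be absent (``None``); an
    absent ``lac50`` marks the record as having no usable fit.  Sentinel
    numbers are never used for missing values.
    """

    compound_id: str
    cell_line_id: str
    lac50: Optional[float] = None
    r2: Optional[float] = None
    tauc: Optional[float] = None
    asym_inf: Optional[float] = None
    asym_zero: Optional[float] = None
    target_annotation: Optional[str] = None

    def __post_init__(self) -> None:
        for name in ("lac50", "r2", "tauc", "asym_inf", "asym_zero"):
            v = getattr(self, name)
            if v is not None and not np.isfinite(v):
                object.__setattr__(self, name, None)

    @property
    def has_fit(self) -> bool:
        return self.lac50 is not None


@dataclass
class ScreenTable:
    """A screen keyed by (compound, cell line), with a cell-line roster.

    At most one record per key; duplicate keys are a reported error at
    parse time, never a silent overwrite.  ``roles`` tags each cell line
    as ``reference``, ``test`` or ``other`` for pairwise analyses.
    """

    records: dict[tuple[str, str], object] = field(default_factory=dict)
    roles: dict[str, str] = field(default_factory=dict)
    dialect: str = "prefitted"
    source: Optional[str] = None
    n_rejected: int = 0
    warnings: list[str] = field(default_factory=list)

    def add(self, record) -> None:
        key = (record.compound_id, record.cell_line_id)
        if key in self.records:
            raise ValueError(f"duplicate (compound, cell line) key: {key}")
        self.records[key] = record

    @property
    def compounds(self) -> list[str]:
        seen: dict[str, None] = {}
        for c, _ in self.records:
            seen.setdefault(c)
        return list(seen)

    @property
    def cell_lines(self) -> list[str]:
        seen: dict[str, None] = {}
        for _, cl in self.records:
            seen.setdefault(cl)
        return list(seen)

    def get(self, compound_id: str, cell_line_id: str):
        return self.records.get((compound_id, cell_line_id))


@dataclass(frozen=True)
class CompoundCellScore:
    """EFF, AC50 and S for one compound x one cell line.

    ``s`` is defined (non-None) only when EFF > 0 and AC50 > 0 and no
    disqualifying flag is set.  Flags are drawn from
    {"no_response", "stimulatory", "poor_fit", "missing"}.
    """

    compound_id: str
    cell_line_id: str
    eff: Optional[float]
    ac50_um: Optional[float]
    s: Optional[float]
    r2: Optional[float] = None
    auc: Optional[float] = None
    flags: frozenset[str] = frozenset()
    target_annotation: Optional[str] = None


@dataclass(frozen=True)
class PairwiseDelta:
    """Reference-vs-test comparison for one compound.

    ``delta_s = S_ref - S_test`` (unitless); positive means the test line
    is resistant relative to the reference, negative sensitive.
    ``delta_pac50 = -delta_ac50`` exactly, and ``delta_pauc`` is the AUC
    analogue on the same orientation (negative = test more affected).
    """

    compound_id: str
    reference_cell_line: str
    test_cell_line: str
    delta_s: Optional[float] = None
    delta_ac50: Optional[float] = None
    delta_pac50: Optional[float] = None
    delta_pauc: Optional[float] = None
    call: str = "indeterminate"
    reason: Optional[str] = None
    target_annotation: Optional[str] = None


@dataclass
class CompoundSummary:
    """dS aggregation across test lines for one compound.

    ``ds_variance`` is the sample variance (ddof=1) of the per-line dS
    values and ``ds_variance_of_mean`` that variance divided by the
    number of lines; both need >= 2 defined lines.  ``verdict`` is one of
    sensitive_prioritized / resistant_prioritized / not_prioritized /
    excluded:<reason>, with the filter predicates recorded in ``audit``.
    """

    compound_id: str
    ds_values: list[float]
    ds_mean: Optional[float] = None
    ds_variance: Optional[float] = None
    ds_variance_of_mean: Optional[float] = None
    n_lines: int = 0
    n_indeterminate: int = 0
    verdict: str = "not_prioritized"
    audit: dict = field(default_factory=dict)
    target_annotation: Optional[str] = None
    reference_cell_line: Optional[str] = None
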