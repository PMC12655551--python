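"""Drug-likeness pre-filter applied before virtual screening.

Three rules, matching the QikProp-style descriptors they are usually read
from: zero Lipinski Rule-of-Five violations (RuleOfFive < 1), polar surface
area strictly below 140 Å² (membrane permeability; CNS-optimised campaigns
may prefer < 90), and a predicted blood–brain-barrier partition coefficient
logBB inside the closed interval [−3.0, 1.2] — the range covering ~95% of
marketed drugs. Properties are inputs from any property calculator; this
module never computes them.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import DataError

PSA_MAX_DEFAULT = 140.0
LOGBB_RANGE_DEFAULT = (-3.0, 1.2)


@dataclass(frozen=True)
class PropertyRecord:
    compound_id: str
    mw: float
    logp: float
    hbd: int
    hba: int
    psa: float
    logbb: float

    def __post_init__(self):
        for name in ("mw", "logp", "hbd", "hba", "psa", "logbb"):
            v = getattr(self, name)
            if v is None or (isinstance(v, float) and not np.isfinite(v)):
                raise DataError(f"{self.compound_id!r}: missing property {name!r}")
        if self.mw <= 0:
            raise DataError(f"{self.compound_id!r}: mw must be positive")
        if self.hbd < 0 or self.hba < 0:
            raise DataError(f"{self.compound_id!r}: hbd/hba must be non-negative")
        if self.psa < 0:
            raise DataError(f"{self.compound_id!r}: psa must be non-negative")


def ro5_violations(rec: PropertyRecord) -> int:
    """Count of violated Lipinski conditions: MW > 500, logP > 5, HBD > 5,
    HBA > 10."""
    return int(rec.mw > 500) + int(rec.logp > 5) + int(rec.hbd > 5) + int(rec.hba > 10)


def screen_filter(records, max_violations: int = 0,
                  psa_max: float = PSA_MAX_DEFAULT,
                  logbb_range: tuple = LOGBB_RANGE_DEFAULT):
    """Partition records into (passed, failed-with-reasons).

    Pass requires RuleOfFive violations ≤ ``max_violations`` (default 0,
    i.e. "< 1"), PSA strictly below ``psa_max``, and logBB inside the
    closed ``logbb_range``. Each failure carries every violated rule.
    """
    lo, hi = logbb_range
    if not (np.isfinite(psa_max) and np.isfinite(lo) and np.isfinite(hi)):
        raise DataError("thresholds must be finite")
    if lo >= hi:
        raise DataError("logbb_range must satisfy low < high")
    passed, failed = [], []
    for rec in records:
        reasons = []
        if ro5_violations(rec) > max_violations:
            reasons.append("RuleOfFive")
        if not (rec.psa < psa_max):
            reasons.append("PSA")
        if not (lo <= rec.logbb <= hi):
            reasons.append("logBB")
        if reasons:
            failed.append((rec, reasons))
        else:
            passed.append(rec)
    return passed, failed
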