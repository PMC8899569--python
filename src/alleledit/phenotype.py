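"""ABR threshold-shift summaries and efficacy-phenotype correlation.

Hearing improvement per animal is the mean, over the tested frequencies, of
(contralateral non-injected threshold - injected threshold) in dB SPL:
positive values mean the injected ear hears better.  Mean shifts are binned
into four improvement categories and correlated (Pearson) with the
allele-specific editing efficacy measured by sequencing.

Category boundaries: marked >= 15 dB, moderate 10-14 dB, mild 5-9 dB,
minimal below 5 dB.  The stated 'mild 5-9' and 'minimal <=5' ranges overlap
at exactly 5 dB; this implementation uses half-open intervals with 5 -> mild
(the explicit 5-9 range is taken as inclusive of its endpoints), and
non-integer shifts are binned by the same intervals without rounding.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

DEFAULT_FREQUENCIES_KHZ = (6.0, 12.0, 18.0, 24.0, 30.0)
THRESHOLD_RANGE_DB = (10.0, 95.0)   # instrument range; 95 encodes "no response"
CATEGORIES = ("marked", "moderate", "mild", "minimal")
CATEGORY_CONVENTION = ("half-open intervals [15,inf) marked, [10,15) moderate, "
                       "[5,10) mild, (-inf,5) minimal; boundary 5 dB -> mild")


@dataclass(frozen=True)
class MouseRecord:
    """Per-animal ABR thresholds for both ears plus measured editing efficacy."""

    mouse_id: str
    thresholds_injected: Mapping[float, float]
    thresholds_contralateral: Mapping[float, float]
    treatment: str = ""
    efficacy_percent: float | None = None

    def __post_init__(self) -> None:
        inj = {float(k): float(v) for k, v in self.thresholds_injected.items()}
        con = {float(k): float(v) for k, v in self.thresholds_contralateral.items()}
        object.__setattr__(self, "thresholds_injected", inj)
        object.__setattr__(self, "thresholds_contralateral", con)
        if set(inj) != set(con):
            raise ValueError("both ears must be measured at the same frequencies")
        lo, hi = THRESHOLD_RANGE_DB
        for v in (*inj.values(), *con.values()):
            if not (lo <= v <= hi):
                raise ValueError(f"threshold {v} dB SPL outside the instrument "
                                 f"range [{lo}, {hi}]")


def abr_improvement(rec: MouseRecord,
                    frequencies: Sequence[float] = DEFAULT_FREQUENCIES_KHZ) -> float:
    """Mean (contralateral - injected) threshold over the given frequencies."""
    missing = [f for f in frequencies if float(f) not in rec.thresholds_injected]
    if missing:
        raise ValueError(f"mouse {rec.mouse_id}: missing frequencies {missing} kHz")
    shifts = [rec.thresholds_contralateral[float(f)]
              - rec.thresholds_injected[float(f)] for f in frequencies]
    return float(np.mean(shifts))


def categorize_improvement(mean_shift_db: float) -> str:
    """Bin a mean dB shift into marked/moderate/mild/minimal."""
    s = float(mean_shift_db)
    if not np.isfinite(s):
        raise ValueError("mean shift must be finite")
    if s >= 15.0:
        return "marked"
    if s >= 10.0:
        return "moderate"
    if s >= 5.0:
        return "mild"
    return "minimal"


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    n: int
    p_value: float

    def __post_init__(self) -> None:
        if not (-1.0 - 1e-12 <= self.r <= 1.0 + 1e-12):
            raise ValueError("Pearson r outside [-1, 1]")


def correlate_efficacy_improvement(
        records: Sequence[MouseRecord],
        frequencies: Sequence[float] = DEFAULT_FREQUENCIES_KHZ) -> CorrelationResult:
    """Pearson correlation of editing efficacy vs mean ABR improvement.

    Two-sided p-value from the usual t approximation (scipy).  Requires
    n >= 3, efficacy on every record, and nonzero variance in both variables
    (degenerate input raises rather than returning a silent NaN).
    """
    if len(records) < 3:
        raise ValueError("need at least 3 animals for a correlation")
    if any(r.efficacy_percent is None for r in records):
        raise ValueError("every record needs a measured efficacy")
    x = np.array([r.efficacy_percent for r in records], dtype=float)
    y = np.array([abr_improvement(r, frequencies) for r in records], dtype=float)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance in efficacy or improvement; "
                         "correlation undefined")
    res = stats.pearsonr(x, y)
    return CorrelationResult(r=float(res.statistic), n=len(records),
                             p_value=float(res.pvalue))


def efficacy_by_category(
        records: Sequence[MouseRecord],
        frequencies: Sequence[float] = DEFAULT_FREQUENCIES_KHZ) -> pd.DataFrame:
    """Per-improvement-category efficacy summary (n, mean, sd).

    Groups are reported in fixed order marked -> minimal; empty groups appear
    with n = 0 and NaN statistics.
    """
    rows = []
    for rec in records:
        shift = abr_improvement(rec, frequencies)
        rows.append({"mouse_id": rec.mouse_id,
                     "mean_shift_db": shift,
                     "category": categorize_improvement(shift),
                     "efficacy_percent": rec.efficacy_percent})
    df = pd.DataFrame(rows, columns=["mouse_id", "mean_shift_db", "category",
                                     "efficacy_percent"])
    out = []
    for cat in CATEGORIES:
        sub = df.loc[df["category"] == cat, "efficacy_percent"].dropna()
        out.append({
            "category": cat,
            "n": int(len(sub)),
            "mean_efficacy_percent": float(sub.mean()) if len(sub) else np.nan,
            "sd_efficacy_percent": float(sub.std(ddof=1)) if len(sub) > 1 else np.nan,
        })
    return pd.DataFrame(out)


def records_from_frame(df: pd.DataFrame,
                       frequencies: Sequence[float] = DEFAULT_FREQUENCIES_KHZ
                       ) -> list[MouseRecord]:
    """Build MouseRecords from a wide table.

    Expects columns ``mouse_id``, optional ``treatment`` and
    ``efficacy_percent``, and per-frequency threshold columns named
    ``inj_<f>kHz`` / ``con_<f>kHz`` (f formatted as an integer when whole).
    """
    def col(prefix: str, f: float) -> str:
        label = int(f) if float(f).is_integer() else f
        return f"{prefix}_{label}kHz"

    records = []
    for _, row in df.iterrows():
        eff = row.get("efficacy_percent")
        records.append(MouseRecord(
            mouse_id=str(row["mouse_id"]),
            treatment=str(row.get("treatment", "")),
            efficacy_percent=None if pd.isna(eff) else float(eff),
            thresholds_injected={f: row[col("inj", f)] for f in frequencies},
            thresholds_contralateral={f: row[col("con", f)] for f in frequencies},
        ))
    return records
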