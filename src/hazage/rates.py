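"""Crude age-specific incidence rates and birth-cohort indexing.

The crude rate of a cell is observed cases divided by person-years at risk,
kept internally in events per person-year; the conventional "per 100,000
person-years" factor is display-only.  The Poisson standard error of a crude
rate is sqrt(O)/PY; for a zero-count cell the SE is reported as 0 and the
cell flagged.  Cells whose count does not exceed the ``min_cases`` threshold
(15 by convention) are marked in an advisory retention mask.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .registry_io import AgeGrid, PeriodGrid, RegistryTable, validate_registry

__all__ = [
    "RateTable",
    "crude_rates",
    "apply_min_case_mask",
    "cohort_index",
    "cohort_count",
    "export_rates_tsv",
]

REPORT_SCALE = 1e5  # conventional display multiplier, per 100,000 person-years


@dataclass
class RateTable:
    """Crude rates (per person-year) with Poisson SEs and the retention mask."""

    rates: np.ndarray
    se: np.ndarray
    mask: np.ndarray
    age_grid: AgeGrid
    period_grid: PeriodGrid
    zero_count: np.ndarray = field(default=None)  # cells where O = 0 (SE set to 0)
    scale_report: float = REPORT_SCALE

    @property
    def rates_per_100k(self) -> np.ndarray:
        return self.rates * self.scale_report


def crude_rates(table: RegistryTable, threshold: int = 15) -> RateTable:
    """Cellwise O/PY with SE = sqrt(O)/PY and the min-case retention mask."""
    findings = validate_registry(table)
    hard = [f for f in findings if "person_years" in f or "shape" in f]
    if hard:
        raise ValueError("invalid registry table: " + "; ".join(hard))
    rates = table.cases / table.person_years
    se = np.sqrt(table.cases) / table.person_years
    return RateTable(
        rates=rates,
        se=se,
        mask=apply_min_case_mask(table, threshold),
        age_grid=table.age_grid,
        period_grid=table.period_grid,
        zero_count=table.cases == 0,
    )


def apply_min_case_mask(table: RegistryTable, threshold: int = 15) -> np.ndarray:
    """Boolean n x J mask, True where the cell count exceeds ``threshold``.

    Advisory: downstream fits may exclude (weight zero) or keep masked-out
    cells depending on ``RunConfig.exclude_masked``.
    """
    return table.cases > threshold


def cohort_index(i: int, j: int, n: int, J: int | None = None) -> int:
    """Anchored birth-cohort index k = j - i + n for 1-based age i, period j.

    Cells on one anti-diagonal (constant j - i) share a cohort; k runs over
    1 .. n + J - 1 (22 for the default 16 x 7 grid).
    """
    if not 1 <= i <= n:
        raise ValueError(f"age index i={i} outside 1..{n}")
    if j < 1 or (J is not None and j > J):
        raise ValueError(f"period index j={j} outside 1..{J if J else '...'}")
    return j - i + n


def cohort_count(n: int, J: int) -> int:
    """Number of distinct birth cohorts on an n x J grid."""
    return n + J - 1


def export_rates_tsv(path: str | Path, rate_table: RateTable) -> None:
    """Write rates per 100,000 person-years (4 decimals) plus a sidecar mask file."""
    scale = rate_table.scale_report
    lines = ["Age\t" + "\t".join(rate_table.period_grid.labels())]
    for i, lab in enumerate(rate_table.age_grid.labels()):
        lines.append(
            lab + "\t" + "\t".join("%.4f" % (v * scale) for v in rate_table.rates[i])
        )
    path = Path(path)
    path.write_text("\n".join(lines) + "\n")
    mask_lines = ["Age\t" + "\t".join(rate_table.period_grid.labels())]
    for i, lab in enumerate(rate_table.age_grid.labels()):
        mask_lines.append(
            lab + "\t" + "\t".join("1" if m else "0" for m in rate_table.mask[i])
        )
    path.with_suffix(path.suffix + ".mask").write_text("\n".join(mask_lines) + "\n")
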