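"""Registry matrix I/O: age/period grids, case/population tables, run configuration.

A cancer-registry extract is a pair of equally shaped matrices on an age x
calendar-period grid: observed case counts ``O[i, j]`` and person-years at
risk ``Pop[i, j]``.  Rows are five-year age intervals in ascending order,
columns are five-year diagnosis periods in ascending order.  Matrices travel
as plain tab-separated files; one header line and a leading age-label column
are tolerated and stripped on read.  All user-facing indices (age ``i``,
period ``j``, cohort ``k``) are 1-based.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable

import numpy as np

__all__ = [
    "AgeGrid",
    "PeriodGrid",
    "RegistryTable",
    "RunConfig",
    "RegistryFormatError",
    "read_matrix_tsv",
    "write_matrix_tsv",
    "load_fixture",
    "fixture_names",
    "validate_registry",
    "read_config",
    "write_config",
]

FIXTURES = {
    "stomach_men_entire_cases": "stomach_men_entire_cases.tsv",
    "men_entire_population": "men_entire_population.tsv",
}


class RegistryFormatError(ValueError):
    """Malformed registry matrix file or inconsistent table."""


@dataclass(frozen=True)
class AgeGrid:
    """Uniform grid of ``n`` age intervals of ``width`` years starting at ``start_age``.

    The default grid covers ages 20-99 in sixteen five-year intervals; the
    last interval ends at ``start_age + n * width - 1`` (99 by default).
    """

    start_age: int = 20
    width: int = 5
    n: int = 16

    def __post_init__(self) -> None:
        if self.start_age < 0:
            raise ValueError(f"start_age must be >= 0, got {self.start_age}")
        if self.width <= 0:
            raise ValueError(f"width must be positive, got {self.width}")
        if self.n < 2:
            raise ValueError(f"need at least 2 age intervals, got n={self.n}")

    @classmethod
    def from_range(cls, first_age: int, last_age: int, width: int = 5) -> "AgeGrid":
        """Grid spanning ``first_age`` .. ``last_age`` inclusive (e.g. 20..99)."""
        span = last_age - first_age + 1
        if span % width:
            raise ValueError(
                f"ages {first_age}-{last_age} do not tile with width {width}"
            )
        return cls(start_age=first_age, width=width, n=span // width)

    @property
    def end_age(self) -> int:
        return self.start_age + self.n * self.width - 1

    @property
    def midpoints(self) -> np.ndarray:
        """Interval midpoints t_i, e.g. 72.5 for the 70-74 interval."""
        return self.start_age + self.width * (np.arange(self.n) + 0.5)

    @property
    def left_edges(self) -> np.ndarray:
        return self.start_age + self.width * np.arange(self.n, dtype=float)

    def labels(self) -> list[str]:
        return [
            f"{self.start_age + i * self.width}-{self.start_age + (i + 1) * self.width - 1}"
            for i in range(self.n)
        ]


@dataclass(frozen=True)
class PeriodGrid:
    """Uniform grid of ``J`` calendar periods of ``width`` years from ``start_year``."""

    start_year: int = 1975
    width: int = 5
    J: int = 7

    def __post_init__(self) -> None:
        if self.width <= 0:
            raise ValueError(f"width must be positive, got {self.width}")
        if self.J < 1:
            raise ValueError(f"need at least one period, got J={self.J}")

    @classmethod
    def from_range(cls, first_year: int, last_year: int, width: int = 5) -> "PeriodGrid":
        span = last_year - first_year + 1
        if span % width:
            raise ValueError(
                f"years {first_year}-{last_year} do not tile with width {width}"
            )
        return cls(start_year=first_year, width=width, J=span // width)

    def labels(self) -> list[str]:
        return [
            f"{self.start_year + j * self.width}-{self.start_year + (j + 1) * self.width - 1}"
            for j in range(self.J)
        ]


@dataclass
class RegistryTable:
    """Paired case-count and person-year matrices for one stratum.

    ``cases`` holds the observed counts O[i, j] (float storage so that
    noiseless expected-count tables can flow through the same type; real
    extracts are integers and :func:`validate_registry` checks that),
    ``person_years`` the person-years at risk Pop[i, j].
    """

    cases: np.ndarray
    person_years: np.ndarray
    age_grid: AgeGrid = field(default_factory=AgeGrid)
    period_grid: PeriodGrid = field(default_factory=PeriodGrid)
    label: str = ""

    def __post_init__(self) -> None:
        self.cases = np.asarray(self.cases, dtype=float)
        self.person_years = np.asarray(self.person_years, dtype=float)
        expected = (self.age_grid.n, self.period_grid.J)
        for name, mat in (("cases", self.cases), ("person_years", self.person_years)):
            if mat.shape != expected:
                raise RegistryFormatError(
                    f"{name} matrix has shape {mat.shape}, expected {expected} "
                    f"(n age intervals x J periods)"
                )

    @property
    def shape(self) -> tuple[int, int]:
        return self.cases.shape

    def checksum(self) -> str:
        """SHA-256 over both matrices (row-major, canonical text) — change detector."""
        h = hashlib.sha256()
        for mat in (self.cases, self.person_years):
            h.update("\n".join("%.12g" % v for v in mat.ravel()).encode())
        return h.hexdigest()


@dataclass
class RunConfig:
    """Inputs of one analysis run, mirroring the manual-anchoring regime.

    ``period_index`` (j*) and ``age_index`` (i*) are the 1-based anchors;
    the anchored birth cohort follows as k* = j* - i* + n.  ``min_cases`` is
    the conventional retention threshold for an age x period cell
    (cells with more than ``min_cases`` cases are flagged as retained);
    whether sub-threshold cells are excluded from the likelihood is governed
    by ``exclude_masked`` (off by default: the Poisson likelihood handles
    low counts, and dropping whole young-age rows would bias the overall
    cumulative hazard).
    """

    title: str = ""
    start_age: int = 20
    start_year: int = 1975
    time_interval: int = 5
    period_index: int = 4
    age_index: int = 11
    min_cases: int = 15
    seed: int | None = None
    exclude_masked: bool = False
    zero_periods_before_anchor: bool = False

    def validate(self, age_grid: AgeGrid, period_grid: PeriodGrid) -> None:
        if not 1 <= self.period_index <= period_grid.J:
            raise ValueError(
                f"period_index {self.period_index} outside 1..{period_grid.J}"
            )
        if not 1 <= self.age_index <= age_grid.n:
            raise ValueError(f"age_index {self.age_index} outside 1..{age_grid.n}")

    def grids(self, n: int = 16, J: int = 7) -> tuple[AgeGrid, PeriodGrid]:
        return (
            AgeGrid(self.start_age, self.time_interval, n),
            PeriodGrid(self.start_year, self.time_interval, J),
        )


# ---------------------------------------------------------------------------
# TSV matrix dialect
# ---------------------------------------------------------------------------

def _parse_cell(cell: str, row: int, col: int) -> float:
    try:
        return float(cell)
    except ValueError:
        raise RegistryFormatError(
            f"non-numeric cell {cell!r} at data row {row + 1}, column {col + 1}"
        ) from None


def _parse_matrix_lines(lines: Iterable[str]) -> np.ndarray:
    rows: list[list[float]] = []
    for line in lines:
        line = line.rstrip("\n")
        if not line.strip():
            continue
        cells = line.split("\t")
        # A leading age label ("20-24") is stripped; a full header line
        # (no numeric cells at all) is skipped.
        def _numeric(c: str) -> bool:
            try:
                float(c)
                return True
            except ValueError:
                return False

        if not _numeric(cells[0]):
            cells = cells[1:]
        if not cells or not any(_numeric(c) for c in cells):
            continue  # header line
        rows.append(
            [_parse_cell(c, len(rows), col) for col, c in enumerate(cells)]
        )
    if not rows:
        raise RegistryFormatError("no numeric rows found")
    widths = {len(r) for r in rows}
    if len(widths) != 1:
        raise RegistryFormatError(f"ragged rows: widths {sorted(widths)}")
    return np.array(rows, dtype=float)


def read_matrix_tsv(
    path: str | Path,
    age_grid: AgeGrid | None = None,
    period_grid: PeriodGrid | None = None,
) -> np.ndarray:
    """Read an n x J registry matrix from a tab-separated file.

    Rows are age intervals ascending, columns periods ascending.  When grids
    are given the shape is validated against them.
    """
    text = Path(path).read_text()
    mat = _parse_matrix_lines(text.splitlines())
    if age_grid is not None and period_grid is not None:
        expected = (age_grid.n, period_grid.J)
        if mat.shape != expected:
            raise RegistryFormatError(
                f"{path}: expected {expected[0]} rows x {expected[1]} columns, "
                f"found {mat.shape[0]} x {mat.shape[1]}"
            )
    return mat


def _format_value(v: float) -> str:
    if float(v).is_integer() and abs(v) < 1e15:
        return str(int(v))
    return "%.15g" % v


def write_matrix_tsv(
    path: str | Path,
    matrix: np.ndarray,
    age_grid: AgeGrid | None = None,
    period_grid: PeriodGrid | None = None,
) -> None:
    """Write a matrix in the registry dialect (header + age-label column).

    Integer matrices round-trip bit-identically; reals keep 15 significant
    digits.  Grids default to the standard 16 x 7 layout when omitted.
    """
    matrix = np.asarray(matrix, dtype=float)
    n, J = matrix.shape
    age_grid = age_grid or AgeGrid(n=n)
    period_grid = period_grid or PeriodGrid(J=J)
    lines = ["Age\t" + "\t".join(period_grid.labels())]
    for i, lab in enumerate(age_grid.labels()):
        lines.append(lab + "\t" + "\t".join(_format_value(v) for v in matrix[i]))
    Path(path).write_text("\n".join(lines) + "\n")


def fixture_names() -> list[str]:
    return sorted(FIXTURES)


def load_fixture(name: str) -> np.ndarray:
    """Return one of the embedded 16 x 7 registry matrices.

    ``stomach_men_entire_cases`` — stomach-cancer case counts in men, all
    nine registry areas combined, 1975-2009; ``men_entire_population`` — the
    matching male person-years.
    """
    if name not in FIXTURES:
        raise KeyError(
            f"unknown fixture {name!r}; available: {', '.join(fixture_names())}"
        )
    text = resources.files("hazage.data").joinpath(FIXTURES[name]).read_text()
    return _parse_matrix_lines(text.splitlines())


def fixture_table(label: str = "stomach, men, entire region") -> RegistryTable:
    """The embedded stomach-cancer (men, all areas) case/population pair."""
    return RegistryTable(
        cases=load_fixture("stomach_men_entire_cases"),
        person_years=load_fixture("men_entire_population"),
        label=label,
    )


def validate_registry(table: RegistryTable) -> list[str]:
    """Return one finding string per invariant violation (empty list = valid)."""
    findings: list[str] = []
    if table.cases.shape != table.person_years.shape:
        findings.append(
            f"shape mismatch: cases {table.cases.shape} vs "
            f"person_years {table.person_years.shape}"
        )
        return findings
    bad_py = np.argwhere(table.person_years <= 0)
    for i, j in bad_py:
        findings.append(
            f"person_years[{i + 1},{j + 1}] = {table.person_years[i, j]:g} (must be > 0)"
        )
    neg = np.argwhere(table.cases < 0)
    for i, j in neg:
        findings.append(f"cases[{i + 1},{j + 1}] = {table.cases[i, j]:g} (negative)")
    frac = np.argwhere(np.abs(table.cases - np.round(table.cases)) > 1e-9)
    for i, j in frac:
        findings.append(
            f"cases[{i + 1},{j + 1}] = {table.cases[i, j]:g} (not an integer)"
        )
    if not np.all(np.isfinite(table.cases)) or not np.all(
        np.isfinite(table.person_years)
    ):
        findings.append("non-finite entries present")
    return findings


# ---------------------------------------------------------------------------
# Flat key=value run configuration
# ---------------------------------------------------------------------------

_CONFIG_KEYS = {
    "Title": ("title", str),
    "Start Age": ("start_age", int),
    "Start Year": ("start_year", int),
    "Time Interval": ("time_interval", int),
    "Period Index": ("period_index", int),
    "Age Index": ("age_index", int),
    "Min Cases": ("min_cases", int),
    "Seed": ("seed", int),
    "Exclude Masked": ("exclude_masked", lambda s: s.strip().lower() in ("1", "true", "yes")),
}


def write_config(path: str | Path, config: RunConfig) -> None:
    lines = [
        f"Title={config.title}",
        f"Start Age={config.start_age}",
        f"Start Year={config.start_year}",
        f"Time Interval={config.time_interval}",
        f"Period Index={config.period_index}",
        f"Age Index={config.age_index}",
        f"Min Cases={config.min_cases}",
        f"Exclude Masked={'true' if config.exclude_masked else 'false'}",
    ]
    if config.seed is not None:
        lines.append(f"Seed={config.seed}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_config(path: str | Path) -> RunConfig:
    config = RunConfig()
    for raw in Path(path).read_text().splitlines():
        line = raw.strip()
        if not line or line.startswith("#") or "=" not in line:
            continue
        key, value = line.split("=", 1)
        key = key.strip()
        if key not in _CONFIG_KEYS:
            raise RegistryFormatError(f"unknown configuration key {key!r}")
        attr, conv = _CONFIG_KEYS[key]
        setattr(config, attr, conv(value.strip()))
    return config
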