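"""Dose-response summary datasets and delimited-text I/O.

Two summary-data containers cover the standard bioassay reporting formats:
quantal (per-group subject and responder counts) and continuous (per-group
n, mean, SD).  Doses are mg/kg/day throughout; no unit conversion layer is
provided.  Packaged fixtures transcribe the male-rat lesion incidence table
from the 2-year GenX (HFPO-DA) chronic bioassay: doses 0, 0.1, 1 and
50 mg/kg/day with 70 animals per group.
"""

from __future__ import annotations

import csv
import io
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Literal, Sequence

__all__ = [
    "QuantalDataset",
    "ContinuousDataset",
    "BenchmarkResponse",
    "ValidationError",
    "FormatError",
    "load_quantal",
    "load_continuous",
    "save_quantal",
    "save_continuous",
    "builtin_fixture",
    "list_fixtures",
]


class ValidationError(ValueError):
    """A dataset violates a structural invariant (bad counts, duplicate doses...)."""


class FormatError(ValueError):
    """A delimited-text file does not have the expected columns."""


@dataclass(frozen=True)
class BenchmarkResponse:
    """Benchmark response (BMR): the effect-size definition anchoring a BMD.

    kind
        ``extra_risk``      — [P(d) − P(0)] / [1 − P(0)] reaches ``level``
        ``added_risk``      — P(d) − P(0) reaches ``level``
        ``one_sd``          — |μ(d) − μ(0)| reaches one (modeled) SD
        ``relative_deviation`` — |μ(d) − μ(0)| reaches ``level``·|μ(0)|
    level
        Fraction in (0, 1) for the risk kinds (e.g. 0.10); > 0 for
        relative deviation; ignored for ``one_sd``.
    """

    kind: Literal["extra_risk", "added_risk", "one_sd", "relative_deviation"]
    level: float | None = None

    def __post_init__(self) -> None:
        if self.kind in ("extra_risk", "added_risk"):
            if self.level is None or not (0.0 < self.level < 1.0):
                raise ValidationError(f"{self.kind} BMR level must be in (0, 1), got {self.level}")
        elif self.kind == "relative_deviation":
            if self.level is None or self.level <= 0.0:
                raise ValidationError(f"relative_deviation BMR level must be > 0, got {self.level}")
        elif self.kind == "one_sd":
            if self.level is not None:
                object.__setattr__(self, "level", None)
        else:
            raise ValidationError(f"unknown BMR kind {self.kind!r}")

    def label(self) -> str:
        if self.kind == "one_sd":
            return "1 SD"
        return f"{self.level:g} {self.kind.replace('_', ' ')}"


def _check_doses(doses: Sequence[float]) -> None:
    if len(doses) < 3:
        raise ValidationError(f"need at least 3 dose groups, got {len(doses)}")
    if any(d < 0 for d in doses):
        raise ValidationError("doses must be non-negative")
    for lo, hi in zip(doses, doses[1:]):
        if hi == lo:
            raise ValidationError(f"duplicate dose {lo}")
        if hi < lo:
            raise ValidationError("doses must be sorted ascending (normalize before construction)")


@dataclass(frozen=True)
class QuantalDataset:
    """Summary quantal (dichotomous) dose-response data.

    ``groups`` is an ordered tuple of (dose mg/kg/day, n subjects, n affected),
    strictly increasing in dose with exactly one control group at dose 0.
    """

    endpoint_name: str
    groups: tuple[tuple[float, int, int], ...]

    def __post_init__(self) -> None:
        groups = tuple(sorted(((float(d), int(n), int(x)) for d, n, x in self.groups)))
        object.__setattr__(self, "groups", groups)
        _check_doses([g[0] for g in groups])
        if groups[0][0] != 0.0:
            raise ValidationError("quantal dataset must include a control group at dose 0")
        for d, n, x in groups:
            if n <= 0:
                raise ValidationError(f"group at dose {d}: n must be positive, got {n}")
            if x < 0 or x > n:
                raise ValidationError(
                    f"group at dose {d}: affected count {x} outside [0, n={n}]"
                )

    @property
    def doses(self) -> tuple[float, ...]:
        return tuple(g[0] for g in self.groups)

    @property
    def n_subjects(self) -> tuple[int, ...]:
        return tuple(g[1] for g in self.groups)

    @property
    def n_affected(self) -> tuple[int, ...]:
        return tuple(g[2] for g in self.groups)

    @property
    def proportions(self) -> tuple[float, ...]:
        return tuple(x / n for _, n, x in self.groups)

    def scale_doses(self, c: float) -> "QuantalDataset":
        if c <= 0:
            raise ValidationError("dose scale factor must be positive")
        return QuantalDataset(self.endpoint_name, tuple((d * c, n, x) for d, n, x in self.groups))


@dataclass(frozen=True)
class ContinuousDataset:
    """Summary continuous dose-response data: per-group (dose, n, mean, SD)."""

    endpoint_name: str
    groups: tuple[tuple[float, int, float, float], ...]
    adverse_direction: Literal["increase", "decrease"] = "decrease"

    def __post_init__(self) -> None:
        groups = tuple(
            sorted(((float(d), int(n), float(m), float(s)) for d, n, m, s in self.groups))
        )
        object.__setattr__(self, "groups", groups)
        _check_doses([g[0] for g in groups])
        for d, n, m, s in groups:
            if n < 2:
                raise ValidationError(f"group at dose {d}: n must be >= 2, got {n}")
            if s <= 0:
                raise ValidationError(f"group at dose {d}: sd must be > 0, got {s}")
        if self.adverse_direction not in ("increase", "decrease"):
            raise ValidationError(f"adverse_direction must be increase/decrease")

    @property
    def doses(self) -> tuple[float, ...]:
        return tuple(g[0] for g in self.groups)

    @property
    def n_subjects(self) -> tuple[int, ...]:
        return tuple(g[1] for g in self.groups)

    @property
    def means(self) -> tuple[float, ...]:
        return tuple(g[2] for g in self.groups)

    @property
    def sds(self) -> tuple[float, ...]:
        return tuple(g[3] for g in self.groups)


# ---------------------------------------------------------------------------
# Delimited-text I/O.  Comma or tab, auto-detected; decimal point only.

_QUANTAL_COLS = ("dose", "n", "affected")
_CONTINUOUS_COLS = ("dose", "n", "mean", "sd")


def _read_rows(path: str | Path) -> list[dict[str, str]]:
    text = Path(path).read_text()
    try:
        dialect = csv.Sniffer().sniff(text.splitlines()[0], delimiters=",\t")
    except (csv.Error, IndexError):
        dialect = csv.excel
    reader = csv.DictReader(io.StringIO(text), dialect=dialect)
    return [row for row in reader if any(v.strip() for v in row.values() if v)]


def _require_columns(rows: list[dict[str, str]], cols: Iterable[str], path: str | Path) -> None:
    if not rows:
        raise FormatError(f"{path}: no data rows")
    missing = [c for c in cols if c not in rows[0]]
    if missing:
        raise FormatError(f"{path}: missing column(s) {missing}; expected header {list(cols)}")


def load_quantal(path: str | Path, endpoint_name: str | None = None) -> QuantalDataset:
    """Read a quantal dataset from CSV/TSV with header ``dose,n,affected``."""
    rows = _read_rows(path)
    _require_columns(rows, _QUANTAL_COLS, path)
    groups = []
    for i, row in enumerate(rows, start=2):
        try:
            groups.append((float(row["dose"]), int(row["n"]), int(row["affected"])))
        except ValueError as exc:
            raise FormatError(f"{path} line {i}: {exc}") from exc
    doses = [g[0] for g in groups]
    if len(set(doses)) != len(doses):
        dup = sorted(d for d in set(doses) if doses.count(d) > 1)
        raise ValidationError(f"{path}: duplicate dose(s) {dup}")
    name = endpoint_name or Path(path).stem
    return QuantalDataset(name, tuple(groups))


def load_continuous(
    path: str | Path,
    endpoint_name: str | None = None,
    adverse_direction: Literal["increase", "decrease"] = "decrease",
) -> ContinuousDataset:
    """Read a continuous dataset from CSV/TSV with header ``dose,n,mean,sd``."""
    rows = _read_rows(path)
    _require_columns(rows, _CONTINUOUS_COLS, path)
    groups = []
    for i, row in enumerate(rows, start=2):
        try:
            groups.append(
                (float(row["dose"]), int(row["n"]), float(row["mean"]), float(row["sd"]))
            )
        except ValueError as exc:
            raise FormatError(f"{path} line {i}: {exc}") from exc
    doses = [g[0] for g in groups]
    if len(set(doses)) != len(doses):
        dup = sorted(d for d in set(doses) if doses.count(d) > 1)
        raise ValidationError(f"{path}: duplicate dose(s) {dup}")
    name = endpoint_name or Path(path).stem
    return ContinuousDataset(name, tuple(groups), adverse_direction)


def save_quantal(data: QuantalDataset, path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(_QUANTAL_COLS)
        for d, n, x in data.groups:
            writer.writerow([format(d, "g"), n, x])


def save_continuous(data: ContinuousDataset, path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(_CONTINUOUS_COLS)
        for d, n, m, s in data.groups:
            writer.writerow([format(d, "g"), n, repr(m), repr(s)])


# ---------------------------------------------------------------------------
# Packaged fixtures: male-rat lesion incidence from the 2-year chronic rat
# bioassay (doses 0, 0.1, 1, 50 mg/kg/day; n = 70/group).  Tumor rows are
# included for demonstration; the non-neoplastic liver lesions are the ones
# normally modeled (the tumors reflect a non-genotoxic PPARα mode of action
# and are not treated as candidate endpoints here).

_FIXTURE_FILES = {
    "cystic_focal_degeneration": "cystic_focal_degeneration.csv",
    "centrilobular_hypertrophy": "centrilobular_hypertrophy.csv",
    "centrilobular_necrosis": "centrilobular_necrosis.csv",
    "hepatocellular_adenoma_carcinoma": "hepatocellular_adenoma_carcinoma.csv",
    "pancreas_adenoma_carcinoma": "pancreas_adenoma_carcinoma.csv",
    "leydig_cell_tumors": "leydig_cell_tumors.csv",
}


def list_fixtures() -> list[str]:
    """Names of the packaged chronic-bioassay incidence fixtures."""
    return sorted(_FIXTURE_FILES)


def builtin_fixture(name: str) -> QuantalDataset:
    """Return a packaged incidence dataset by endpoint name.

    Raises ``KeyError`` listing the available fixtures for an unknown name.
    """
    try:
        fname = _FIXTURE_FILES[name]
    except KeyError:
        raise KeyError(
            f"unknown fixture {name!r}; available: {', '.join(list_fixtures())}"
        ) from None
    ref = resources.files("bmdtox.data").joinpath(fname)
    with resources.as_file(ref) as path:
        return load_quantal(path, endpoint_name=name)
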