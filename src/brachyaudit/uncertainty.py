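"""Uncertainty budgets and derivation of gamma passing criteria.

Each dosimetry system carries a typed list of uncertainty components, split
into a dosimetric dimension (%) and a spatial dimension (mm).  Components
combine in quadrature to a combined standard uncertainty (k = 1); the
expanded uncertainty is exactly twice that (k = 2, ~95% coverage).  The
gamma passing criteria of the audit are not free parameters: they are the
k = 1 totals rounded up to the nearest whole percent / millimetre.

Type A (statistical) and type B (systematic) labels are carried as metadata
only — both enter the same quadrature, giving "A+B" totals.  Components
marked as bounds (e.g. "< 2.5 %" Monte-Carlo statistics) are stored but
excluded from quadrature arithmetic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources

import pandas as pd

__all__ = [
    "UncertaintyComponent",
    "UncertaintyBudget",
    "load_budget",
    "derive_criteria",
]


@dataclass(frozen=True)
class UncertaintyComponent:
    name: str
    type: str  # "A" or "B"
    dosimetric_pct: float | None = None
    spatial_mm: float | None = None
    bound: bool = False  # upper bound, excluded from quadrature
    note: str = ""

    def __post_init__(self) -> None:
        if self.type not in ("A", "B"):
            raise ValueError("component type must be 'A' or 'B'")
        for v in (self.dosimetric_pct, self.spatial_mm):
            if v is not None and v < 0:
                raise ValueError("uncertainty values must be non-negative")


@dataclass
class UncertaintyBudget:
    """Component list for one dosimetry system plus its quadrature totals."""

    name: str
    components: list[UncertaintyComponent] = field(default_factory=list)

    def _quadrature(self, dimension: str) -> float | None:
        vals = [
            getattr(c, dimension)
            for c in self.components
            if getattr(c, dimension) is not None and not c.bound
        ]
        if not vals:
            return None
        return math.sqrt(sum(v * v for v in vals))

    @property
    def dosimetric_k1(self) -> float | None:
        """Combined standard dosimetric uncertainty, % (k = 1)."""
        return self._quadrature("dosimetric_pct")

    @property
    def spatial_k1(self) -> float | None:
        """Combined standard spatial uncertainty, mm (k = 1)."""
        return self._quadrature("spatial_mm")

    @property
    def dosimetric_k2(self) -> float | None:
        v = self.dosimetric_k1
        return None if v is None else 2.0 * v

    @property
    def spatial_k2(self) -> float | None:
        v = self.spatial_k1
        return None if v is None else 2.0 * v

    def combine(self) -> dict[str, float | None]:
        """Totals at full precision plus the one-decimal display values.

        The displayed k = 2 value is twice the displayed k = 1 value (the
        convention of the protocol budget table); internally the expanded
        uncertainty is exactly twice the full-precision combined value.
        """

        def disp(v):
            return None if v is None else round(v, 1)

        def disp2(v):
            return None if v is None else round(2.0 * round(v, 1), 1)

        return {
            "dosimetric_k1": self.dosimetric_k1,
            "spatial_k1": self.spatial_k1,
            "dosimetric_k2": self.dosimetric_k2,
            "spatial_k2": self.spatial_k2,
            "dosimetric_k1_display": disp(self.dosimetric_k1),
            "spatial_k1_display": disp(self.spatial_k1),
            "dosimetric_k2_display": disp2(self.dosimetric_k1),
            "spatial_k2_display": disp2(self.spatial_k1),
        }


def load_budget(system: str) -> UncertaintyBudget:
    """Load a shipped component list: ``"osl"``, ``"film"`` or ``"computational"``.

    The files mirror the audit protocol budget tables and are
    plain CSV, editable without touching code.
    """
    path = resources.files("brachyaudit.data").joinpath(f"budget_{system}.csv")
    with resources.as_file(path) as p:
        df = pd.read_csv(p)
    comps = []
    for _, row in df.iterrows():
        comps.append(
            UncertaintyComponent(
                name=str(row["name"]),
                type=str(row["type"]),
                dosimetric_pct=None if pd.isna(row["dosimetric_pct"]) else float(row["dosimetric_pct"]),
                spatial_mm=None if pd.isna(row["spatial_mm"]) else float(row["spatial_mm"]),
                bound=bool(row["bound"]),
                note=str(row["note"]),
            )
        )
    return UncertaintyBudget(name=system, components=comps)


def _ceil_lenient(x: float) -> int:
    """Ceil that does not bump values already at a whole number (within 1e-9)."""
    return math.ceil(x - 1e-9)


def derive_criteria(budget: UncertaintyBudget) -> tuple[int, int]:
    """Gamma passing criteria (dose-difference %, DTA mm) from a budget.

    The k = 1 dosimetric total is rounded up to the nearest whole percent and
    the k = 1 spatial total up to the nearest whole millimetre.  The rounding
    rule is the package's reading of "criteria adapted to the uncertainty of
    each system"; it reproduces 4.4 % / 0.8 mm -> 5 % / 1 mm and
    3.8 % / 1.6 mm -> 4 % / 2 mm.
    """
    d = budget.dosimetric_k1
    s = budget.spatial_k1
    if d is None or s is None:
        raise ValueError("budget must carry both a dosimetric and a spatial dimension")
    return _ceil_lenient(d), _ceil_lenient(s)
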