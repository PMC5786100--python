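"""Experiment-versus-computation comparison statistics.

Operates on per-glycan records holding the experimental N₂ CCS and the
calculated CCS for each modeled protonation state (P3: proton on the
distal GlcNAc of the α1-3 branch, P6: on the α1-6 branch; the two
terminal-GlcNAc isomers carry a single state).  The published study
values ship with the package as a delimited table and can be replaced
with any table of the same layout.

Conventions (documented, since the aggregation rules are not uniquely
determined by the published tables alone):

* Per-state regressions include all glycans, single-state glycans
  contributing their only calculated value to both states.
* Per-state average |%diff| uses only glycans that actually have that
  state's value (nine per state in the packaged table).
* Isomer ΔCCS is globular − rod with the state of each member fixed in
  the pair specification.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import DomainError, ParseError

__all__ = [
    "ComparisonRecord", "IsomerPair", "ProtonationDelta",
    "percent_difference", "pearson_r", "protonation_delta", "isomer_separation",
    "load_published_table", "load_isomer_pairs", "state_statistics",
]

STATES = ("p3", "p6")


@dataclass(frozen=True)
class ComparisonRecord:
    """One glycan: experimental CCS and calculated CCS per protonation state (Å²)."""

    glycan: str
    exp_ccs: float
    calc_n2: dict[str, float] = field(default_factory=dict)
    calc_he: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.exp_ccs <= 0:
            raise DomainError(f"{self.glycan}: experimental CCS must be positive")
        if not self.calc_n2:
            raise DomainError(f"{self.glycan}: needs at least one calculated value")

    def percent_diff(self, state: str) -> float:
        """Signed (calc − exp)/exp × 100 for one state."""
        return percent_difference(self.calc_n2[state], self.exp_ccs)

    def any_state_value(self, state: str) -> float:
        """The state's value, falling back to the record's only state."""
        if state in self.calc_n2:
            return self.calc_n2[state]
        (only,) = self.calc_n2.values()
        return only


@dataclass(frozen=True)
class IsomerPair:
    pair: str
    globular: str
    globular_state: str
    rod: str
    rod_state: str


@dataclass(frozen=True)
class ProtonationDelta:
    per_glycan: dict[str, float]   # |CCS_P3 − CCS_P6|, dual-state glycans only
    mean: float
    argmax: tuple[str, ...]        # all glycans attaining the maximum
    argmin: tuple[str, ...]


def percent_difference(calc: float, exp: float) -> float:
    """Signed percentage difference (calc − exp)/exp × 100."""
    if exp <= 0:
        raise DomainError("experimental CCS must be positive")
    return (calc - exp) / exp * 100.0


def pearson_r(x, y) -> float:
    """Pearson product-moment correlation coefficient."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise DomainError("sequences must be one-dimensional and of equal length")
    if x.size < 3:
        raise DomainError("correlation needs at least 3 points")
    xc = x - x.mean()
    yc = y - y.mean()
    sx = float(np.sqrt((xc ** 2).sum()))
    sy = float(np.sqrt((yc ** 2).sum()))
    if sx == 0.0 or sy == 0.0:
        raise DomainError("correlation undefined for zero-variance input")
    return float((xc @ yc) / (sx * sy))


def protonation_delta(records: list[ComparisonRecord]) -> ProtonationDelta:
    """Absolute CCS difference between the two protonation states per glycan."""
    per = {r.glycan: abs(r.calc_n2["p3"] - r.calc_n2["p6"])
           for r in records if "p3" in r.calc_n2 and "p6" in r.calc_n2}
    if not per:
        raise DomainError("no glycan carries both protonation states")
    vmax = max(per.values())
    vmin = min(per.values())
    return ProtonationDelta(
        per_glycan=per,
        mean=float(np.mean(list(per.values()))),
        argmax=tuple(g for g, v in per.items() if v == vmax),
        argmin=tuple(g for g, v in per.items() if v == vmin),
    )


def isomer_separation(records: list[ComparisonRecord],
                      pairs: list[IsomerPair]) -> list[dict]:
    """Calculated and experimental globular − rod CCS differences per isomer pair."""
    by_name = {r.glycan: r for r in records}
    out = []
    for p in pairs:
        for member in (p.globular, p.rod):
            if member not in by_name:
                raise DomainError(f"pair {p.pair}: glycan {member} missing from records")
        g, r = by_name[p.globular], by_name[p.rod]
        if p.globular_state not in g.calc_n2 or p.rod_state not in r.calc_n2:
            raise DomainError(f"pair {p.pair}: requested state missing")
        out.append({
            "pair": p.pair,
            "calc_delta": g.calc_n2[p.globular_state] - r.calc_n2[p.rod_state],
            "exp_delta": g.exp_ccs - r.exp_ccs,
        })
    return out


def state_statistics(records: list[ComparisonRecord]) -> dict:
    """Per-state Pearson r (all glycans) and mean |%diff| (state-bearing glycans).

    Two averaging conventions are reported: ``avg_abs_pct_diff`` averages
    the full-precision per-glycan values, while
    ``avg_abs_pct_diff_printed`` averages the values after rounding each
    to one decimal — the convention a table of one-decimal entries
    implies, and the one that reproduces published state averages.
    """
    exp = [r.exp_ccs for r in records]
    out: dict[str, dict[str, float]] = {"pearson_r": {}, "avg_abs_pct_diff": {},
                                        "avg_abs_pct_diff_printed": {}}
    for state in STATES:
        calc_all = [r.any_state_value(state) for r in records]
        out["pearson_r"][state] = pearson_r(exp, calc_all)
        diffs = [abs(r.percent_diff(state)) for r in records if state in r.calc_n2]
        out["avg_abs_pct_diff"][state] = float(np.mean(diffs))
        out["avg_abs_pct_diff_printed"][state] = float(np.mean([round(d, 1)
                                                                for d in diffs]))
    return out


# ---------------------------------------------------------------------------
# Packaged study tables
# ---------------------------------------------------------------------------

def _data_path(name: str) -> Path:
    return Path(str(resources.files("glycoccs").joinpath(f"data/{name}")))


def load_published_table(path: str | Path | None = None) -> list[ComparisonRecord]:
    """Load a glycan CCS comparison table (packaged study values by default)."""
    path = _data_path("glycan_calculated_ccs.csv") if path is None else Path(path)
    df = pd.read_csv(path)
    required = {"glycan", "exp_n2_A2", "calc_n2_p3", "calc_n2_p6"}
    if not required.issubset(df.columns):
        raise ParseError(f"comparison table {path} missing columns "
                         f"{sorted(required - set(df.columns))}")
    records = []
    for _, row in df.iterrows():
        calc_n2 = {s: float(row[f"calc_n2_{s}"]) for s in STATES
                   if not pd.isna(row[f"calc_n2_{s}"])}
        calc_he = {s: float(row[f"calc_he_{s}"]) for s in STATES
                   if f"calc_he_{s}" in df.columns and not pd.isna(row[f"calc_he_{s}"])}
        records.append(ComparisonRecord(glycan=str(row["glycan"]),
                                        exp_ccs=float(row["exp_n2_A2"]),
                                        calc_n2=calc_n2, calc_he=calc_he))
    return records


def load_isomer_pairs(path: str | Path | None = None) -> list[IsomerPair]:
    """Load the isomer-pair (globular vs rod) specification table."""
    path = _data_path("isomer_pairs.csv") if path is None else Path(path)
    df = pd.read_csv(path)
    return [IsomerPair(pair=str(r["pair"]), globular=str(r["globular"]),
                       globular_state=str(r["globular_state"]).lower(),
                       rod=str(r["rod"]), rod_state=str(r["rod_state"]).lower())
            for _, r in df.iterrows()]
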