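"""Composite energy assembly for QM/MM reaction profiles.

The free-energy scheme assembled here combines three independently converged
ingredients::

    dG = dE_DFT(E)  +  ddE_CC  -  T*dS_DFT(S)

where ``dE_DFT(E)`` is a relative electronic energy from a well-converged
hybrid-DFT model (large QM region), ``ddE_CC`` is a coupled-cluster
correction evaluated at a *smaller* QM size — legitimate because the
CC-minus-DFT difference converges faster with QM size than the relative
energies themselves — and the entropic term comes from sampling with a
cheaper model and is treated as an external input here.

Coupled-cluster reference energies carry two extrapolations:

* complete-basis-set (CBS) limits from energies at consecutive basis cardinal
  numbers X, X+1 (inverse-cubic for correlation, two-point exponential for
  the mean-field part), and
* the local-approximation-free (LAF) limit from energies at the Normal and
  Tight local-correlation thresholds, with the printed uncertainty
  ±0.5·(E_Tight − E_Normal).

The composite reference then reads::

    E(N-T, CBS) = E(Normal, CBS) + E(N-T, X) - E(Normal, X)

Everything downstream works on relative energies (kcal/mol) over an ordered
path of stationary points, with barrier bookkeeping, mean-absolute-error
scoring against a reference profile, and QM-size convergence reports.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Mapping, Sequence

import pandas as pd

__all__ = [
    "HARTREE_TO_KCAL", "EnergyKey", "EnergyTable", "PathSpec", "Uncertain",
    "LasiComponents", "to_kcal", "cbs_extrapolate_corr", "cbs_extrapolate_hf",
    "laf_extrapolate", "lno_composite_reference", "relative_profile",
    "cc_correction", "lasi_assemble", "mae_vs_reference",
    "convergence_report", "ConvergenceReport", "read_energy_csv",
    "write_energy_csv", "propagate",
]

HARTREE_TO_KCAL = 627.5094740631

_VALID_LNO = ("Normal", "Tight", "N-T", "na")


class EnergyTableError(ValueError):
    """Raised on malformed energy tables or missing keys."""


def to_kcal(e_hartree: float) -> float:
    """Hartree → kcal/mol."""
    if not math.isfinite(e_hartree):
        raise ValueError("non-finite energy")
    return e_hartree * HARTREE_TO_KCAL


@dataclass(frozen=True)
class EnergyKey:
    """Index of one absolute energy: stationary point, method, basis cardinal
    (int or symbolic 'CBS(X,X+1)'), local-correlation threshold, QM size."""

    state: str
    method: str
    basis_cardinal: int | str
    lno_threshold: str = "na"
    qm_size: int = 0

    def __post_init__(self):
        if isinstance(self.basis_cardinal, int) and self.basis_cardinal < 2:
            raise EnergyTableError(f"numeric basis cardinal must be >= 2, got {self.basis_cardinal}")
        if self.lno_threshold not in _VALID_LNO:
            raise EnergyTableError(
                f"lno_threshold must be one of {_VALID_LNO}, got {self.lno_threshold!r}")


class EnergyTable:
    """Absolute energies (hartree) keyed by :class:`EnergyKey`."""

    def __init__(self, entries: Mapping[EnergyKey, float] | None = None):
        self._data: dict[EnergyKey, float] = {}
        if entries:
            for k, v in entries.items():
                self.add(k, v)

    def add(self, key: EnergyKey, value: float) -> None:
        if not math.isfinite(value):
            raise EnergyTableError(f"non-finite energy for {key}")
        if key in self._data:
            raise EnergyTableError(f"duplicate key {key}")
        self._data[key] = value

    def __getitem__(self, key: EnergyKey) -> float:
        return self._data[key]

    def __contains__(self, key: EnergyKey) -> bool:
        return key in self._data

    def __len__(self) -> int:
        return len(self._data)

    def get(self, key: EnergyKey, default=None):
        return self._data.get(key, default)

    def keys(self):
        return self._data.keys()

    def items(self):
        return self._data.items()

    def subset(self, **fixed) -> "EnergyTable":
        """Entries whose key fields equal all of the given values."""
        out = EnergyTable()
        for k, v in self._data.items():
            if all(getattr(k, f) == val for f, val in fixed.items()):
                out.add(k, v)
        return out


@dataclass
class PathSpec:
    """Ordered stationary points with a reference state and the tracked
    derived quantities (both barriers, their difference, reaction energy)."""

    states: Sequence[str] = ("RS", "TS1", "INT", "TS2", "PS")
    reference: str = "RS"

    def __post_init__(self):
        if self.reference not in self.states:
            raise EnergyTableError(
                f"reference {self.reference!r} not among states {list(self.states)}")

    def derived_quantities(self) -> dict[str, tuple[str, str]]:
        """Named differences tracked in convergence studies, as (a, b) → a−b."""
        out: dict[str, tuple[str, str]] = {}
        states = list(self.states)
        ts = [s for s in states if s.upper().startswith("TS")]
        for t in ts:
            out[f"{t}-{self.reference}"] = (t, self.reference)
        if len(ts) >= 2:
            out[f"{ts[0]}-{ts[1]}"] = (ts[0], ts[1])
        last = states[-1]
        if last != self.reference:
            out[f"{last}-{self.reference}"] = (last, self.reference)
        return out


@dataclass(frozen=True)
class Uncertain:
    """A value with a symmetric half-width uncertainty (same units)."""

    value: float
    halfwidth: float = 0.0

    def __post_init__(self):
        if self.halfwidth < 0:
            raise ValueError("halfwidth must be >= 0")

    # quadrature combination under a declared independence assumption;
    # worst-case (linear) accumulation available via `linear=True` helpers
    def __add__(self, other: "Uncertain") -> "Uncertain":
        return Uncertain(self.value + other.value,
                         math.hypot(self.halfwidth, other.halfwidth))

    def __sub__(self, other: "Uncertain") -> "Uncertain":
        return Uncertain(self.value - other.value,
                         math.hypot(self.halfwidth, other.halfwidth))

    def __mul__(self, k: float) -> "Uncertain":
        return Uncertain(k * self.value, abs(k) * self.halfwidth)

    __rmul__ = __mul__

    def add_linear(self, other: "Uncertain") -> "Uncertain":
        """Worst-case accumulation: half-widths add linearly."""
        return Uncertain(self.value + other.value, self.halfwidth + other.halfwidth)


@dataclass
class LasiComponents:
    """Ingredients of one composite free-energy value (kcal/mol)."""

    dE_DFT_E: float
    ddE_CC: float | None = None
    TdS: float = 0.0


def propagate(values: Sequence[Uncertain], coefficients: Sequence[float] | None = None,
              linear: bool = False) -> Uncertain:
    """Linear combination of uncertain values.

    Half-widths combine in quadrature under the declared independence
    assumption; ``linear=True`` switches to worst-case accumulation.
    """
    if coefficients is None:
        coefficients = [1.0] * len(values)
    if len(coefficients) != len(values):
        raise ValueError("one coefficient per value required")
    value = sum(c * v.value for c, v in zip(coefficients, values))
    if linear:
        hw = sum(abs(c) * v.halfwidth for c, v in zip(coefficients, values))
    else:
        hw = math.sqrt(sum((c * v.halfwidth) ** 2 for c, v in zip(coefficients, values)))
    return Uncertain(value, hw)


# ---------------------------------------------------------------------------
# Extrapolations
# ---------------------------------------------------------------------------

def cbs_extrapolate_corr(e_x: float, e_x1: float, x: int) -> float:
    """Two-point inverse-cubic CBS limit of a correlation energy.

    Assumes E(X) = E_CBS + A·X⁻³ at consecutive cardinals X, X+1.
    """
    if x < 2:
        raise ValueError(f"cardinal number must be >= 2, got {x}")
    x3, x13 = x ** 3, (x + 1) ** 3
    return (x13 * e_x1 - x3 * e_x) / (x13 - x3)


def cbs_extrapolate_hf(e_x: float, e_x1: float, x: int, alpha: float = 1.63) -> float:
    """Two-point exponential CBS limit of a mean-field (HF) energy.

    Assumes E(X) = E_CBS + A·exp(−alpha·X); solved for E_CBS from the pair
    (X, X+1).  ``alpha`` defaults to 1.63 and is configurable.
    """
    if x < 2:
        raise ValueError(f"cardinal number must be >= 2, got {x}")
    if alpha <= 0:
        raise ValueError(f"alpha must be > 0, got {alpha}")
    return e_x1 + (e_x1 - e_x) / (math.exp(alpha) - 1.0)


def laf_extrapolate(e_normal: float, e_tight: float,
                    coefficient: float = 0.5) -> Uncertain:
    """Local-approximation-free limit from Normal/Tight threshold energies.

    The extrapolant is E_Tight + c·(E_Tight − E_Normal) with c = 0.5 by
    default; the associated uncertainty half-width is |0.5·(E_Tight −
    E_Normal)| regardless of c.
    """
    delta = e_tight - e_normal
    return Uncertain(e_tight + coefficient * delta, abs(0.5 * delta))


def lno_composite_reference(e_normal_cbs: float, e_nt_x: float, e_normal_x: float) -> float:
    """Composite local-CC reference: CBS at the Normal threshold plus the
    threshold-extrapolation increment evaluated in the finite basis X::

        E = E_Normal^CBS + E_{N-T}^X - E_Normal^X
    """
    return e_normal_cbs + e_nt_x - e_normal_x


# ---------------------------------------------------------------------------
# Profiles and composites
# ---------------------------------------------------------------------------

def relative_profile(table: EnergyTable, path: PathSpec,
                     method_selector: Mapping | None = None,
                     unit: str = "hartree") -> dict[str, float]:
    """Relative energies E(state) − E(reference) in kcal/mol for one method.

    ``method_selector`` fixes the non-state key fields (method, basis, lno
    threshold, qm size); the table restricted to it must cover every path
    state exactly once.  Derived barriers and the reaction energy are added
    under their difference names (e.g. ``TS1-RS``).
    """
    sel = table.subset(**method_selector) if method_selector else table
    absolute: dict[str, float] = {}
    missing = []
    for state in path.states:
        matches = [v for k, v in sel.items() if k.state == state]
        if not matches:
            missing.append(state)
        elif len(matches) > 1:
            raise EnergyTableError(
                f"selector does not single out one energy for state {state!r}")
        else:
            absolute[state] = matches[0]
    if missing:
        raise EnergyTableError(f"missing states {missing} for selector {method_selector}")
    scale = HARTREE_TO_KCAL if unit == "hartree" else 1.0
    ref = absolute[path.reference]
    profile = {s: (absolute[s] - ref) * scale for s in path.states}
    for name, (a, b) in path.derived_quantities().items():
        profile[name] = profile[a] - profile[b]
    return profile


def cc_correction(d_e_cc_small: float, d_e_dft_small: float,
                  qm_size_cc: int | None = None,
                  qm_size_dft: int | None = None) -> float:
    """Coupled-cluster correction ddE_CC = dE_CC − dE_DFT, both evaluated as
    the same relative quantity at the same (reduced) QM size."""
    if qm_size_cc is not None and qm_size_dft is not None and qm_size_cc != qm_size_dft:
        raise EnergyTableError(
            f"correction inputs computed at different QM sizes: "
            f"{qm_size_cc} vs {qm_size_dft}")
    return d_e_cc_small - d_e_dft_small


def lasi_assemble(components: LasiComponents) -> float:
    """Composite free energy dG = dE_DFT(E) + ddE_CC − T·dS (kcal/mol)."""
    dd = components.ddE_CC if components.ddE_CC is not None else 0.0
    return components.dE_DFT_E + dd - components.TdS


def mae_vs_reference(profile: Mapping[str, float],
                     reference_profile: Mapping[str, float],
                     states: Sequence[str] | None = None,
                     exclude: Sequence[str] = ("RS",)) -> float:
    """Mean absolute error between relative-energy profiles.

    Compared over ``states`` (default: keys shared by both profiles that are
    plain states, i.e. contain no '-') with the reference state excluded,
    since its relative energy is identically zero.
    """
    if states is None:
        states = [s for s in profile if "-" not in s and s in reference_profile]
    states = [s for s in states if s not in exclude]
    missing = [s for s in states if s not in profile or s not in reference_profile]
    if missing:
        raise EnergyTableError(f"states absent from a profile: {missing}")
    if not states:
        raise EnergyTableError("no states to compare")
    return sum(abs(profile[s] - reference_profile[s]) for s in states) / len(states)


# ---------------------------------------------------------------------------
# QM-size convergence
# ---------------------------------------------------------------------------

@dataclass
class ConvergenceReport:
    """Per-quantity convergence against the largest-QM-size profile."""

    tol_kcal: float
    largest_size: int
    converged_size: dict[str, int | None]
    deviations: dict[str, dict[int, float]]
    non_monotonic: dict[str, bool] = field(default_factory=dict)

    def overall_converged_size(self) -> int | None:
        sizes = list(self.converged_size.values())
        if any(s is None for s in sizes):
            return None
        return max(sizes)


def convergence_report(series: Sequence[tuple[int, Mapping[str, float]]],
                       tol_kcal: float = 1.0,
                       quantities: Sequence[str] | None = None) -> ConvergenceReport:
    """Smallest QM size from which each tracked quantity stays within
    ``tol_kcal`` of its value at the largest size.

    ``series`` is a list of (qm_size, profile); the largest size is the
    asymptote.  A size qualifies only if *all* larger sizes also stay inside
    the band (a dip into the band followed by an exit does not count).
    Non-monotonic approach (deviation magnitude increasing anywhere along the
    series) is flagged per quantity.
    """
    if len(series) < 2:
        raise EnergyTableError("convergence report needs at least two QM sizes")
    ordered = sorted(series, key=lambda t: t[0])
    sizes = [s for s, _ in ordered]
    if len(set(sizes)) != len(sizes):
        raise EnergyTableError(f"duplicate QM sizes in series: {sizes}")
    largest_size, asymptote = ordered[-1]
    if quantities is None:
        quantities = [q for q in asymptote if "-" in q]
        if not quantities:
            quantities = list(asymptote)
    converged: dict[str, int | None] = {}
    deviations: dict[str, dict[int, float]] = {}
    non_mono: dict[str, bool] = {}
    for q in quantities:
        devs = {size: abs(prof[q] - asymptote[q]) for size, prof in ordered}
        deviations[q] = devs
        dev_list = [devs[s] for s in sizes]
        non_mono[q] = any(b > a + 1e-12 for a, b in zip(dev_list, dev_list[1:]))
        found: int | None = None
        for k, size in enumerate(sizes):
            if all(devs[s] <= tol_kcal for s in sizes[k:]):
                found = size
                break
        converged[q] = found
    return ConvergenceReport(
        tol_kcal=tol_kcal, largest_size=largest_size,
        converged_size=converged, deviations=deviations, non_monotonic=non_mono)


# ---------------------------------------------------------------------------
# CSV I/O
# ---------------------------------------------------------------------------

_CSV_COLUMNS = ["state", "method", "basis", "lno", "qm_size", "energy", "unit"]


def _parse_basis(token: str) -> int | str:
    token = str(token).strip()
    if token.upper().startswith("CBS"):
        return token
    return int(token)


def read_energy_csv(path: str | Path) -> EnergyTable:
    """Read a long-format energy table.

    Header: ``state,method,basis,lno,qm_size,energy,unit``; ``basis`` is a
    cardinal number or ``CBS(X,X+1)``; ``lno`` is Normal/Tight/N-T/na; values
    are stored internally in hartree (kcal/mol inputs are converted; any
    other unit is an error).
    """
    df = pd.read_csv(path)
    missing = [c for c in _CSV_COLUMNS if c not in df.columns]
    if missing:
        raise EnergyTableError(f"{path}: missing columns {missing}")
    table = EnergyTable()
    for _, row in df.iterrows():
        unit = str(row["unit"]).strip()
        value = float(row["energy"])
        if unit == "hartree":
            pass
        elif unit in ("kcal/mol", "kcal"):
            value /= HARTREE_TO_KCAL
        else:
            raise EnergyTableError(f"{path}: unknown unit {unit!r}")
        key = EnergyKey(
            state=str(row["state"]).strip(),
            method=str(row["method"]).strip(),
            basis_cardinal=_parse_basis(row["basis"]),
            lno_threshold=str(row["lno"]).strip(),
            qm_size=int(row["qm_size"]))
        table.add(key, value)
    return table


def write_energy_csv(table: EnergyTable, path: str | Path) -> None:
    rows = [
        {
            "state": k.state, "method": k.method, "basis": k.basis_cardinal,
            "lno": k.lno_threshold, "qm_size": k.qm_size,
            "energy": v, "unit": "hartree",
        }
        for k, v in table.items()
    ]
    pd.DataFrame(rows, columns=_CSV_COLUMNS).to_csv(path, index=False)
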