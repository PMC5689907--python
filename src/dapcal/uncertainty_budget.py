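"""Measurement-uncertainty accounting for the DAP_w calibration.

All components are relative standard uncertainties in percent (k = 1).
Independent components combine in quadrature.  Two deliberate
exceptions follow the worst-case treatments used in practice:

* the out-of-field film response uncertainty adds the energy-response
  allowance *linearly* to the base film uncertainty (correlated
  worst case, e.g. 2% + 5% = 7%);
* the in-/out-of-field film uncertainties combine as a *linear*
  average weighted by each region's contribution to the dose integral.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from ._rounding import round_sig

__all__ = [
    "BudgetComponent",
    "Budget",
    "combine_quadrature",
    "film_region_uncertainty",
    "weighted_integral_uncertainty",
    "field_area_uncertainty",
]

_GROUPS = ("dap", "response", "additional")


@dataclass
class BudgetComponent:
    """One named relative-standard-uncertainty component (%, k = 1)."""

    name: str
    u_pct: float
    group: str = "additional"

    def __post_init__(self) -> None:
        if self.u_pct < 0:
            raise ValueError("u_pct must be >= 0")
        if self.group not in _GROUPS:
            raise ValueError(f"group must be one of {_GROUPS}")


@dataclass
class Budget:
    """A named collection of uncertainty components.

    The combined uncertainty is always computed from the components,
    never entered directly.
    """

    components: list = field(default_factory=list)
    label: str = ""

    def add(self, name: str, u_pct: float, group: str = "additional") -> "Budget":
        self.components.append(BudgetComponent(name, u_pct, group))
        return self

    def combined_pct(self) -> float:
        return combine_quadrature([c.u_pct for c in self.components])

    def group_pct(self, group: str) -> float:
        vals = [c.u_pct for c in self.components if c.group == group]
        return combine_quadrature(vals)

    def to_json(self, path) -> None:
        payload = {
            "label": self.label,
            "components": [
                {"name": c.name, "u_pct": c.u_pct, "group": c.group}
                for c in self.components
            ],
            "combined_pct": self.combined_pct(),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "Budget":
        with open(path) as fh:
            payload = json.load(fh)
        b = cls(label=payload.get("label", ""))
        for c in payload["components"]:
            b.add(c["name"], c["u_pct"], c.get("group", "additional"))
        return b


def combine_quadrature(components, rounded: bool = False) -> float:
    """Quadrature combination sqrt(sum u_i**2) of k = 1 components (%).

    With ``rounded`` the result is reported half-up at two significant
    figures, the precision convention of commissioning tables.
    """
    u = np.asarray(list(components), dtype=float)
    if u.size == 0:
        raise ValueError("no components to combine")
    if np.any(u < 0):
        raise ValueError("components must be >= 0")
    out = float(np.sqrt((u**2).sum()))
    return round_sig(out, 2) if rounded else out


def film_region_uncertainty(u_base_pct: float, u_energy_pct: float) -> float:
    """Out-of-field film uncertainty: base + energy-response allowance.

    Linear (not quadrature) addition -- the energy under-response is a
    one-sided systematic treated as a correlated worst case.
    """
    if u_base_pct < 0 or u_energy_pct < 0:
        raise ValueError("uncertainties must be >= 0")
    return u_base_pct + u_energy_pct


def weighted_integral_uncertainty(u_in_pct: float, u_out_pct: float,
                                  f_out: float) -> float:
    """Uncertainty of the dose integral from regional film uncertainties.

    Linear combination weighted by each region's share of the total
    integral: ``(1 - f_out) * u_in + f_out * u_out`` where ``f_out`` is
    the out-of-field fraction of the integral.
    """
    if not 0 <= f_out <= 1:
        raise ValueError("f_out must be in [0, 1]")
    return (1.0 - f_out) * u_in_pct + f_out * u_out_pct


def field_area_uncertainty(side_cm: float, u_side_cm: float) -> float:
    """Relative uncertainty (%) of a square field's area from the
    per-side setting uncertainty.

    The two orthogonal side settings are independent, so the relative
    area uncertainty is sqrt(2) times the per-side relative uncertainty.
    The stated +-0.02 cm jaw tolerance is interpreted as the standard
    uncertainty of each side.
    """
    if side_cm <= 0:
        raise ValueError("side must be > 0")
    if u_side_cm < 0:
        raise ValueError("u_side must be >= 0")
    return 100.0 * np.sqrt(2.0) * u_side_cm / side_cm
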