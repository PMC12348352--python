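"""Stark and polarization energies, and linear field-response regression.

A molecule in a homogeneous field E acquires an induced dipole mu_ind =
polarizability * E and a polarization energy depending on the parallel and
perpendicular polarizability components and the orientation cosine Phi.  The
rotational Stark shifts are expressed in the symmetric-top quantum numbers
(J, K, M): the first-order energy -mu E M K / (J (J+1)), and a second-order
form linear in mu E times a field-specific proportionality constant Omega.

The polarizability here is distinct from the string-evolution parameter
(named string_alpha elsewhere); code names keep them apart.  Inputs are
declared in whatever consistent unit system the caller uses (SI or atomic);
no silent conversion is performed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .landscape import FieldScanTable

__all__ = ["RotorState", "ElectrostaticParams", "ResponseFit",
           "induced_dipole", "polarization_energy", "first_order_stark",
           "second_order_stark", "fit_linear_response", "fit_all_series"]


@dataclass(frozen=True)
class RotorState:
    """Symmetric-top quantum numbers: J, its molecular-axis projection K,
    and its field-axis projection M."""

    J: int
    K: int
    M: int

    def __post_init__(self):
        if self.J < 0:
            raise ValueError("J must be >= 0")
        if abs(self.K) > self.J or abs(self.M) > self.J:
            raise ValueError("|K| and |M| must not exceed J")


@dataclass(frozen=True)
class ElectrostaticParams:
    """Molecular response constants: permanent dipole mu, polarizability
    components, orientation cosine Phi, and the second-order constant Omega."""

    mu: float
    alpha_parallel: float
    alpha_perp: float
    Phi: float = 1.0
    Omega: float = 1.0
    units: str = "SI"

    def __post_init__(self):
        if self.alpha_parallel < 0 or self.alpha_perp < 0:
            raise ValueError("polarizabilities must be >= 0")
        if abs(self.Phi) > 1:
            raise ValueError("|Phi| must be <= 1")


def induced_dipole(polarizability: float, field_strength: float) -> float:
    """mu_ind = polarizability * E."""
    if polarizability < 0:
        raise ValueError("polarizability must be >= 0")
    return polarizability * field_strength


def polarization_energy(alpha_parallel: float, alpha_perp: float,
                        field_strength: float, Phi: float) -> float:
    """-1/2 (a_par - a_perp) E^2 Phi^2 - 1/2 a_perp E^2."""
    if abs(Phi) > 1:
        raise ValueError("|Phi| must be <= 1")
    e2 = field_strength * field_strength
    return -0.5 * (alpha_parallel - alpha_perp) * e2 * Phi * Phi - 0.5 * alpha_perp * e2


def first_order_stark(mu: float, field_strength: float, state: RotorState) -> float:
    """First-order shift -mu E M K / (J (J+1)); zero for J = 0."""
    if state.J == 0:
        return 0.0
    return -mu * field_strength * state.M * state.K / (state.J * (state.J + 1))


def second_order_stark(mu: float, field_strength: float, Omega: float,
                       state: RotorState) -> float:
    """Second-order shift, linear in mu E Omega.

    (1/2) mu E Omega [ (J^2-K^2)(J^2-M^2) / (J^3 (2J-1)(2J+1))
                      - ((J+1)^2-K^2)((J+1)^2-M^2) / ((J+1)^3 (2J+1)(2J+3)) ].
    Singular at J = 0 and rejected there.
    """
    j, k, m = state.J, state.K, state.M
    if j == 0:
        raise ValueError("second-order Stark shift is singular at J = 0")
    first = (j * j - k * k) * (j * j - m * m) / (j ** 3 * (2 * j - 1) * (2 * j + 1))
    jp = j + 1
    second = (jp * jp - k * k) * (jp * jp - m * m) / (jp ** 3 * (2 * j + 1) * (2 * j + 3))
    return 0.5 * mu * field_strength * Omega * (first - second)


@dataclass
class ResponseFit:
    """Ordinary-least-squares line of one observable against field strength."""

    slope: float
    intercept: float
    r_squared: float
    n_points: int
    quantity: str
    axis: str
    sign: int


def fit_linear_response(table: FieldScanTable, quantity: str, axis: str,
                        sign: int) -> ResponseFit:
    """OLS of observable value vs field strength for one signed direction."""
    series = table.series(quantity, axis, sign)
    if len(series) < 3:
        raise ValueError(
            f"series ({quantity}, {axis}, {sign:+d}) has {len(series)} points; need >= 3")
    x = series["strength_Vm"].to_numpy(dtype=float)
    y = series["value"].to_numpy(dtype=float)
    if np.var(y) == 0.0:
        raise ValueError("response has zero variance: R^2 undefined")
    res = stats.linregress(x, y)
    return ResponseFit(slope=float(res.slope), intercept=float(res.intercept),
                       r_squared=float(res.rvalue ** 2), n_points=len(series),
                       quantity=quantity, axis=axis, sign=int(sign))


def fit_all_series(table: FieldScanTable):
    """Fit every (quantity, axis, sign) series present in the table."""
    keys = table.data[["quantity", "axis", "sign"]].drop_duplicates()
    return [fit_linear_response(table, row.quantity, row.axis, int(row.sign))
            for row in keys.itertuples(index=False)]
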