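"""Three-compartment equilibrium model of reversible radioligand binding.

An intravenously injected radioligand crosses from blood (compartment 1)
into free brain tissue (compartment 2) and binds its target transporter
(compartment 3).  At equilibrium the association and dissociation fluxes
in compartment 3 balance:

    0 = k_on * f2 * C2 * (B_max - C3) - k_off * C3

Solving for the bound concentration C3 and taking the tracer-dose limit
(C3 << B_max) yields the binding potential

    BP = B_max * k_on / k_off  ~=  C3 / (f2 * C2)

which the specific binding ratio (target minus reference over reference)
estimates from count images.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = ["EquilibriumParams", "binding_potential", "equilibrium_c3"]


@dataclass(frozen=True)
class EquilibriumParams:
    """Rate and concentration parameters of the equilibrium binding model.

    Parameters
    ----------
    k_on : float
        Forward (association) rate constant, mL s^-1 kBq^-1.
    k_off : float
        Reverse (dissociation) rate constant, s^-1.
    B_max : float
        Maximum specific binding (transporter) concentration, kBq/mL.
    f2 : float
        Free fraction of ligand in tissue, dimensionless in (0, 1].
    C2 : float
        Free ligand concentration in tissue, kBq/mL.
    """

    k_on: float
    k_off: float
    B_max: float
    f2: float
    C2: float

    def __post_init__(self) -> None:
        if not self.k_on > 0:
            raise ValueError(f"k_on must be > 0, got {self.k_on}")
        if not self.k_off > 0:
            raise ValueError(f"k_off must be > 0, got {self.k_off}")
        if self.B_max < 0:
            raise ValueError(f"B_max must be >= 0, got {self.B_max}")
        if not 0 < self.f2 <= 1:
            raise ValueError(f"f2 must lie in (0, 1], got {self.f2}")
        if self.C2 < 0:
            raise ValueError(f"C2 must be >= 0, got {self.C2}")


def binding_potential(p: EquilibriumParams) -> float:
    """Binding potential BP = B_max * k_on / k_off.

    This is B_max / K_D with the dissociation constant K_D = k_off / k_on;
    at tracer doses it equals the bound-to-free concentration ratio
    C3 / (f2 * C2).
    """
    if p.k_off == 0:
        raise ZeroDivisionError("k_off must be nonzero for a finite BP")
    return p.B_max * p.k_on / p.k_off


def equilibrium_c3(p: EquilibriumParams) -> float:
    """Bound concentration C3 at equilibrium, without the tracer-dose limit.

    Closed form of 0 = k_on f2 C2 (B_max - C3) - k_off C3:

        C3 = B_max * k_on * f2 * C2 / (k_off + k_on * f2 * C2)

    Saturates at B_max for large free ligand concentration; reduces to
    BP * f2 * C2 when k_on * f2 * C2 << k_off.
    """
    denom = p.k_off + p.k_on * p.f2 * p.C2
    if denom == 0:
        raise ValueError("k_off + k_on*f2*C2 must be nonzero")
    return p.B_max * p.k_on * p.f2 * p.C2 / denom
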