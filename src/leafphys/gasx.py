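"""Derived stomatal indices and Rubisco velocity partitioning.

Stomatal indices from one steady-state observation:
intrinsic water-use efficiency WUE = A/gs, the internal-to-external CO2 ratio
Ci/Ca, and the stomatal limitation Ls = 1 − Ci/Ca.

Rubisco carboxylation/oxygenation velocities come from the fluorescence-based
partitioning that couples the linear electron transport rate with net
assimilation (electron costs of 4 per carboxylation and 4 per oxygenation):

    Vc = (ETR + 8·(A + Rd)) / 12        Vo = 2·(ETR − 4·(A + Rd)) / 12

which inverts the two stoichiometric identities A = Vc − 0.5·Vo − Rd and
ETR = 4·(Vc + Vo).  A negative Vo (ETR insufficient for the stated A) is
flagged rather than raised.
"""

from __future__ import annotations

from dataclasses import dataclass

from .records import GasExchangeRecord

#: electron-cost stoichiometry (per carboxylation, per oxygenation, combined)
ETR_STOICHIOMETRY = (8.0, 4.0, 12.0)


class GasIndexError(ValueError):
    pass


@dataclass
class DerivedGasIndices:
    wue: float          # µmol CO2 mol⁻¹ H2O
    ci_ca: float
    ls: float
    vc: float | None = None   # µmol m⁻² s⁻¹
    vo: float | None = None
    valid: bool = True


def stomatal_indices(record: GasExchangeRecord) -> tuple[float, float, float]:
    """Return (WUE, Ci/Ca, Ls) for one observation."""
    if record.gs <= 0:
        raise GasIndexError("gs must be > 0")
    if record.ca <= 0:
        raise GasIndexError("ca must be > 0")
    wue = record.a / record.gs
    ci_ca = record.ci / record.ca
    return wue, ci_ca, 1.0 - ci_ca


def rubisco_velocities(a: float, etr: float, rd: float = 1.0,
                       stoichiometry: tuple[float, float, float] = ETR_STOICHIOMETRY,
                       ) -> tuple[float, float, bool]:
    """Partition ETR and A into (Vc, Vo, valid_flag).

    ``valid_flag`` is False when Vo < 0, i.e. the supplied ETR cannot support
    the stated assimilation at the given stoichiometry.
    """
    if etr < 0:
        raise GasIndexError("etr must be ≥ 0")
    if rd < 0:
        raise GasIndexError("rd must be ≥ 0")
    k_c, k_o, k_t = stoichiometry
    s = a + rd
    vc = (etr + k_c * s) / k_t
    vo = 2.0 * (etr - k_o * s) / k_t
    return vc, vo, vo >= 0


def percent_change(control_mean: float, treated_mean: float) -> float:
    """Percent change 100·(control − treated)/control; a decline is positive."""
    if control_mean == 0:
        raise GasIndexError("control_mean must be non-zero")
    return 100.0 * (control_mean - treated_mean) / control_mean
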