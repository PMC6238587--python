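"""Reference kinetic parameter sets for the characterised enzymes.

Rate constants in min^-1, Vmax in uM/s (for 1 uM enzyme, Vmax in uM/s equals
k_cat in s^-1), KM in uM.  The electrode background coefficient is a typical
instrument value (the background correction is at most a few percent of the
enzymatic rate at saturating oxygen).

``ERP72_SUBSTRATE_LIKE`` is a synthetic stand-in for the
activation-plus-inactivation behaviour seen with ERp72 as substrate; no rate
constants were ever published for that condition, so its numbers are
plausible placeholders, not measurements.
"""

from __future__ import annotations

from dataclasses import dataclass

from .models import KineticParameters, ModelSpec

__all__ = ["EnzymePreset", "PRESETS", "ERO1A_PDI", "ERO1B_PDI", "ERV1P",
           "ERP72_SUBSTRATE_LIKE", "DEFAULT_BACKGROUND_X"]

#: typical electrode background coefficient (s^-1): ~0.5% of the enzymatic
#: rate at air saturation for a 1 uM Ero1 assay
DEFAULT_BACKGROUND_X = 2e-5


@dataclass(frozen=True)
class EnzymePreset:
    name: str
    params: KineticParameters
    spec: ModelSpec
    enzyme_conc: float = 1.0  # uM
    total_duration: float = 1100.0  # s, typical run length incl. plateau


ERO1A_PDI = EnzymePreset(
    name="Ero1a-PDI",
    params=KineticParameters(vmax=0.64, km=5.0, n=5.2, x=DEFAULT_BACKGROUND_X,
                             k1=1.04, k2=1.12),
    spec=ModelSpec("two_step"),
    total_duration=2800.0,
)

ERO1B_PDI = EnzymePreset(
    name="Ero1b-PDI",
    params=KineticParameters(vmax=1.00, km=7.6, n=3.1, x=DEFAULT_BACKGROUND_X,
                             k1=1.11),
    spec=ModelSpec("one_step"),
    total_duration=1900.0,
)

ERV1P = EnzymePreset(
    name="Erv1p",
    params=KineticParameters(vmax=0.41, km=89.0, n=1.0, x=DEFAULT_BACKGROUND_X),
    spec=ModelSpec("none"),
    total_duration=2400.0,
)

ERP72_SUBSTRATE_LIKE = EnzymePreset(
    name="ERp72-substrate-like",
    params=KineticParameters(vmax=0.20, km=7.0, n=3.5, x=DEFAULT_BACKGROUND_X,
                             k1=1.0, k3=0.04),
    spec=ModelSpec("one_step", inactivation=True),
    total_duration=3600.0,
)

PRESETS: dict[str, EnzymePreset] = {
    p.name: p for p in (ERO1A_PDI, ERO1B_PDI, ERV1P, ERP72_SUBSTRATE_LIKE)
}
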