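"""Reference experimental conditions for the four reporter-label variants.

Four reversible displacement constructs with 6-nt toeholds and 20-nt
recognition domains, differing in toehold orientation (5' or 3' on the gate
strand X2) and in FRET label placement (symmetric: FAM/BHQ1 adjacent;
asymmetric: separated by the toehold length).  The rate constants are the
values fitted to the measured fluorescence time courses for each construct;
the theoretical lumped rate for a 6-nt toehold, 5.0e-4 nM^-1 s^-1, applies
to both directions in the absence of label effects.

The positive-control (fluorophore-only) species, and hence the reporter
species driving the signal, is X4 for the 5'-symmetric and 3'-asymmetric
constructs and X3 for the other two.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Tuple

from .reaction_model import (
    Modification,
    ReactionState,
    ReporterSpecies,
    TMSDRSystem,
    ToeholdOrientation,
)

__all__ = [
    "THEORETICAL_RATE_6NT",
    "DEFAULT_INITIAL",
    "ReferenceCondition",
    "REFERENCE_CONDITIONS",
]

#: Theoretical lumped displacement rate for a 6-nt toehold, nM^-1 s^-1.
THEORETICAL_RATE_6NT = 5.0e-4

#: Default operating point: equal 10 nM invader and gate, no products.
DEFAULT_INITIAL = ReactionState(x1=10.0, x2=10.0, x3=0.0, x4=0.0)


@dataclass(frozen=True)
class ReferenceCondition:
    """One labelled construct with its fitted rate constants."""

    name: str
    system: TMSDRSystem


REFERENCE_CONDITIONS: Tuple[ReferenceCondition, ...] = (
    ReferenceCondition(
        "5p_symmetric",
        TMSDRSystem(
            ka=4.78e-5,
            kd=4.60e-3,
            toehold_orientation=ToeholdOrientation.FIVE_PRIME,
            modification=Modification.SYMMETRIC,
            reporter_species=ReporterSpecies.X4,
        ),
    ),
    ReferenceCondition(
        "5p_asymmetric",
        TMSDRSystem(
            ka=1.74e-4,
            kd=8.51e-4,
            toehold_orientation=ToeholdOrientation.FIVE_PRIME,
            modification=Modification.ASYMMETRIC,
            reporter_species=ReporterSpecies.X3,
        ),
    ),
    ReferenceCondition(
        "3p_asymmetric",
        TMSDRSystem(
            ka=6.48e-4,
            kd=2.98e-5,
            toehold_orientation=ToeholdOrientation.THREE_PRIME,
            modification=Modification.ASYMMETRIC,
            reporter_species=ReporterSpecies.X4,
        ),
    ),
    ReferenceCondition(
        "3p_symmetric",
        TMSDRSystem(
            ka=9.68e-5,
            kd=1.60e-3,
            toehold_orientation=ToeholdOrientation.THREE_PRIME,
            modification=Modification.SYMMETRIC,
            reporter_species=ReporterSpecies.X3,
        ),
    ),
)
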