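"""Core domain types for batch dehydration kinetics.

Internal units throughout the package: time in kiloseconds (ks),
concentrations in mol/L (M), second-order rate constants in M^-1 ks^-1,
temperature in K, energies in kJ/mol.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Tuple

import numpy as np

#: canonical species labels used in profiles and CSV files
REACTANT = "fructose"
PRIMARY = "HMF"
SECONDARY = "levulinic_acid"
SPECIES = (REACTANT, PRIMARY, SECONDARY)

VALID_ANIONS = ("Cl-", "Br-", "I-", "F-", "TfO-", "HSO4-", "none")


class ValidationError(ValueError):
    """Raised when an input violates a documented precondition."""


class MissingConditionError(KeyError):
    """Raised when a condition is not registered with a generator spec."""


class FormatError(ValueError):
    """Raised when a file does not follow the documented CSV dialect."""


class ConversionNotReachedError(ValueError):
    """Raised when a profile never attains the requested conversion."""

    def __init__(self, requested: float, attained: float):
        self.requested = requested
        self.attained = attained
        super().__init__(
            f"requested conversion {requested:.3f} never reached; "
            f"maximum attained is {attained:.3f}"
        )


@dataclass(frozen=True)
class ExperimentCondition:
    """Solvent/acid/salt/temperature metadata keying one batch experiment.

    ``gvl_massfrac`` is the organic co-solvent mass fraction (0 for pure
    water); ``solvent`` is a free-text label ("GVL/H2O", "THF/H2O",
    "dioxane/H2O", "water"). ``isotope`` distinguishes protiated (H) from
    deuterated (D) solvent for kinetic-isotope-effect experiments.
    """

    solvent: str = "GVL/H2O"
    gvl_massfrac: float = 0.9
    acid_name: str = "H2SO4"
    acid_conc: float = 0.005  # M
    salt_name: Optional[str] = None
    salt_conc: float = 0.0  # M
    anion: str = "none"
    temperature: float = 373.0  # K
    isotope: str = "H"

    def __post_init__(self):
        if not 0.0 <= self.gvl_massfrac <= 1.0:
            raise ValidationError(
                f"gvl_massfrac must be in [0, 1], got {self.gvl_massfrac}"
            )
        if self.acid_conc < 0 or self.salt_conc < 0:
            raise ValidationError("concentrations must be nonnegative")
        if self.temperature <= 0:
            raise ValidationError("temperature must be positive (K)")
        if self.anion not in VALID_ANIONS:
            raise ValidationError(
                f"anion must be one of {VALID_ANIONS}, got {self.anion!r}"
            )
        if self.isotope not in ("H", "D"):
            raise ValidationError("isotope must be 'H' or 'D'")


@dataclass
class KineticProfile:
    """Concentration-time series from one batch experiment.

    ``concentrations`` maps species label -> array (M) aligned with
    ``times`` (ks). The reactant series is mandatory; product series are
    optional.
    """

    condition: ExperimentCondition
    times: np.ndarray
    concentrations: Mapping[str, np.ndarray]

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.concentrations = {
            k: np.asarray(v, dtype=float) for k, v in self.concentrations.items()
        }
        if self.times.ndim != 1 or len(self.times) < 1:
            raise ValidationError("times must be a non-empty 1-D array")
        if np.any(self.times < 0):
            raise ValidationError("times must be nonnegative")
        if np.any(np.diff(self.times) <= 0):
            raise ValidationError("times must be strictly increasing")
        if REACTANT not in self.concentrations:
            raise ValidationError(f"profile must contain a {REACTANT!r} series")
        for name, conc in self.concentrations.items():
            if conc.shape != self.times.shape:
                raise ValidationError(
                    f"series {name!r} length {conc.shape} does not match times"
                )
            if np.any(conc < 0):
                raise ValidationError(f"series {name!r} has negative concentrations")
        if self.reactant[0] <= 0:
            raise ValidationError("initial reactant concentration must be positive")

    @property
    def reactant(self) -> np.ndarray:
        return self.concentrations[REACTANT]

    @property
    def primary(self) -> np.ndarray:
        return self.concentrations.get(PRIMARY, np.zeros_like(self.times))

    @property
    def secondary(self) -> np.ndarray:
        return self.concentrations.get(SECONDARY, np.zeros_like(self.times))


#: provenance note attached to every RateFit for the neglected general-acid
#: channel: the inverse solvent kinetic isotope effect (k_D/k_H > 1) shows the
#: reaction is specific-acid catalyzed, so the undissociated-acid rate constant
#: is fixed at zero rather than estimated.
K_GENERAL_NOTE = (
    "general-acid rate constant fixed at 0; inverse solvent KIE indicates "
    "specific-acid catalysis"
)


@dataclass
class RateFit:
    """Second-order rate constant estimate with 95% confidence interval.

    ``k`` is the specific-acid rate constant (M^-1 ks^-1) when
    ``catalyst == 'acid'``; for salt-only experiments the rate is referenced
    to the salt concentration instead. ``k_general`` is the general-acid
    channel, fixed at zero (see ``k_general_note``).
    """

    k: float
    ci95: Tuple[float, float]
    stderr: float
    residual_sse: float
    n_points: int
    converged: bool
    message: str = ""
    catalyst: str = "acid"
    k_general: float = 0.0
    k_general_note: str = K_GENERAL_NOTE
    condition: Optional[ExperimentCondition] = None


@dataclass
class YieldResult:
    """Conversion/yield/selectivity snapshot at one interpolated time."""

    conversion: float
    yield_: float
    selectivity: float
    at_time: float  # ks
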