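"""Stimulation design for superimposed frequency-tagged streams.

Two stimulus categories (faces, houses) flicker simultaneously at distinct
rates (defaults 6 and 7.5 Hz).  Which category is tagged at which rate is
counterbalanced across sequences, giving two conditions.  The base frequency
— the largest common divisor of the two rates — defines the cycle on which
analysis windows must end so that both rates fall exactly on FFT bins.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction


class InvalidDesignError(ValueError):
    """Raised when the stimulation parameters cannot form a valid design."""


class CounterbalancingError(ValueError):
    """Raised when the rate-to-category mappings cannot be balanced."""


#: condition label templates: category tagged at the *face* rate listed first
CONDITION_A = "faces@f1/houses@f2"
CONDITION_B = "faces@f2/houses@f1"


def rational_gcd(a: float, b: float) -> float:
    """Largest common divisor of two (possibly non-integer) rates in Hz."""
    x = Fraction(a).limit_denominator(10 ** 6)
    y = Fraction(b).limit_denominator(10 ** 6)
    while y:  # Euclid on rationals
        x, y = y, x % y
    return float(x)


@dataclass(frozen=True)
class StimulusDesign:
    """One run of the frequency-tagging experiment.

    ``f1``/``f2`` are the two stimulation rates; ``condition_of_sequence``
    maps each sequence to the condition label stating which category is
    tagged at which rate.
    """

    f1: float = 6.0
    f2: float = 7.5
    n_sequences: int = 4
    full_contrast_duration: float = 60.0
    fade_duration: float = 2.0
    contrast_max: float = 0.5
    n_color_changes: int = 15
    color_change_duration: float = 0.3
    base_frequency: float = field(init=False)
    condition_of_sequence: tuple[str, ...] = field(init=False)

    def __post_init__(self) -> None:
        if self.f1 <= 0 or self.f2 <= 0:
            raise InvalidDesignError("stimulation rates must be positive")
        if self.f1 == self.f2:
            raise InvalidDesignError("the two stimulation rates must differ")
        if self.n_sequences % 2:
            raise CounterbalancingError(
                "n_sequences must be even to counterbalance rate/category mapping"
            )
        base = rational_gcd(self.f1, self.f2)
        if base <= 0:
            raise InvalidDesignError("rates share no positive common divisor")
        object.__setattr__(self, "base_frequency", base)
        # alternate conditions so each mapping occurs in exactly half the sequences
        conds = [self.condition_a if i % 2 == 0 else self.condition_b
                 for i in range(self.n_sequences)]
        object.__setattr__(self, "condition_of_sequence", tuple(conds))

    @property
    def condition_a(self) -> str:
        return f"faces@{self.f1:g}/houses@{self.f2:g}"

    @property
    def condition_b(self) -> str:
        return f"faces@{self.f2:g}/houses@{self.f1:g}"

    @property
    def conditions(self) -> tuple[str, str]:
        return (self.condition_a, self.condition_b)

    @property
    def sequence_duration(self) -> float:
        """Total sequence duration (plateau plus fade-in and fade-out)."""
        return self.full_contrast_duration + 2.0 * self.fade_duration

    def rate_of(self, category: str, condition: str) -> float:
        """Stimulation rate of ``category`` ('faces'/'houses') in ``condition``."""
        if condition == self.condition_a:
            return self.f1 if category == "faces" else self.f2
        if condition == self.condition_b:
            return self.f2 if category == "faces" else self.f1
        raise KeyError(f"unknown condition label {condition!r}")


def make_design(face_rate: float = 6.0, house_rate: float = 7.5,
                n_sequences: int = 4, **kwargs) -> StimulusDesign:
    """Build a counterbalanced two-stream design.

    Parameters
    ----------
    face_rate, house_rate
        The two tagging rates in Hz; must differ and share a rational
        common divisor (6 and 7.5 share 1.5 Hz).
    n_sequences
        Number of 64-s sequences; must be even so each rate-to-category
        mapping occurs in exactly half of them.
    """
    return StimulusDesign(f1=face_rate, f2=house_rate,
                          n_sequences=n_sequences, **kwargs)
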