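"""Model parameters for the two-allele stepping-stone model with vacancies.

The model lives on a chain of demes, each holding exactly ``N`` particles
(wildtype individuals, mutant individuals, or vacancies).  ``a`` and ``b``
are the low-density growth rates per unit time of wildtype and mutant;
time units are fixed so that the single-particle diffusion constant is 1,
which makes the deterministic (pulled) wave speed of an all-wildtype
expansion equal to ``2*sqrt(a)``.
"""

from __future__ import annotations

from dataclasses import dataclass, replace


@dataclass(frozen=True)
class ModelParams:
    """All constants defining one simulation setup.

    Parameters
    ----------
    N : int
        Carrying capacity (particles per deme); inverse measure of local
        genetic drift.
    a : float
        Wildtype low-density growth rate per unit time, in (0, 1).  The
        open interval is required because a death event is accepted with
        probability ``1 - a``.
    b : float
        Mutant low-density growth rate per unit time, in (0, 1).
    L : int
        Number of demes in the co-moving box (default 300).
    mu : float
        Beneficial mutation rate per individual per unit time; only used
        when converting the normalized substitution rate phi into
        ``Lambda = mu * phi``.
    seed : int
        Master seed for the random stream.
    """

    N: int
    a: float
    b: float
    L: int = 300
    mu: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not isinstance(self.N, (int,)) or self.N < 2:
            raise ValueError(f"N must be an integer >= 2, got {self.N!r}")
        if not 0.0 < self.a < 1.0:
            raise ValueError(f"a must lie in (0, 1), got {self.a}")
        if not 0.0 < self.b < 1.0:
            raise ValueError(f"b must lie in (0, 1), got {self.b}")
        if self.L < 10:
            raise ValueError(f"box too small to host a front: L = {self.L} < 10")
        if self.mu < 0.0:
            raise ValueError(f"mu must be non-negative, got {self.mu}")

    @property
    def s(self) -> float:
        """Selective advantage of the mutant, s = (b - a) / a."""
        return (self.b - self.a) / self.a

    @property
    def gamma(self) -> float:
        """Relative fitness of the mutant, gamma = b / a."""
        return self.b / self.a

    @property
    def dt(self) -> float:
        """Model time advanced by one elementary (migration + duplication) step."""
        return 1.0 / (self.N * self.L)

    def with_(self, **kwargs) -> "ModelParams":
        """Return a copy with some fields replaced."""
        return replace(self, **kwargs)


# Presets: a cheap configuration for quick experiments and the parameter
# ranges explored in the study (N in [100, 1000]; a, b in [0.05, 0.5]).
FAST_PRESET = ModelParams(N=50, a=0.2, b=0.3, L=120)
PAPER_RANGE = {"N": (100, 1000), "a": (0.05, 0.5), "b": (0.05, 0.5)}
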