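"""Parameterization of the two-phase aging model.

The model divides a lifespan into two consecutive phases. Phase-1
individuals do not die but face a transition hazard that rises linearly
with age, ``p(t) = a*t + b`` for ``t > t0`` with ``t0 = -b/a``.
Phase-2 individuals die at a constant per-day rate ``k``, so an isolated
phase-2 subpopulation decays as ``exp(-k*t)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = ["ModelParams"]

# b and t0 are redundant (b = -a*t0); constructors accept either and must
# agree to this relative tolerance when both are given.
_REDUNDANCY_RTOL = 1e-12


@dataclass(frozen=True)
class ModelParams:
    """Complete parameter set of the two-phase aging model.

    Parameters
    ----------
    a : float
        Daily failure rate, per day^2: slope of the linear transition
        hazard from phase 1 to phase 2. Must be positive.
    k : float
        Death rate constant of phase 2, per day. Must be positive.
        Characteristic phase-2 lifetime is ``1/k``.
    b : float, optional
        Intercept of the transition hazard ``p(t) = a*t + b`` (per day).
        Non-positive; redundant with ``t0`` through ``b = -a*t0``.
    t0 : float, optional
        Tolerance, in days: first age at which a phase-2 individual can
        appear, ``t0 = -b/a``. Non-negative.
    p0 : float
        Initial phase-1 population size; 1.0 treats counts as fractions.

    Exactly one of ``b`` and ``t0`` may be omitted; the other is derived.
    """

    a: float
    k: float
    b: float | None = None
    t0: float | None = None
    p0: float = 1.0

    def __post_init__(self) -> None:
        if not self.a > 0:
            raise ValueError(f"a must be positive, got {self.a}")
        if not self.k > 0:
            raise ValueError(f"k must be positive, got {self.k}")
        if not self.p0 > 0:
            raise ValueError(f"p0 must be positive, got {self.p0}")
        if self.b is None and self.t0 is None:
            raise ValueError("provide at least one of b or t0")
        if self.t0 is None:
            object.__setattr__(self, "t0", -self.b / self.a)
        elif self.b is None:
            object.__setattr__(self, "b", -self.a * self.t0)
        else:
            expect = -self.a * self.t0
            scale = max(abs(self.b), abs(expect), 1e-300)
            if abs(self.b - expect) > _REDUNDANCY_RTOL * scale and abs(self.b - expect) > 1e-15:
                raise ValueError(
                    f"inconsistent b={self.b} and t0={self.t0}: expected b = -a*t0 = {expect}"
                )
        if self.t0 < 0:
            raise ValueError(f"t0 must be non-negative, got {self.t0}")

    def with_(self, **kwargs) -> "ModelParams":
        """Return a copy with some parameters replaced.

        Changing ``a`` keeps ``t0`` fixed (and rederives ``b``) unless an
        explicit ``b`` is passed, since ``t0`` is the biologically
        meaningful quantity.
        """
        new = {"a": self.a, "k": self.k, "p0": self.p0}
        if "b" in kwargs and "t0" not in kwargs:
            new["b"] = kwargs.pop("b")
        else:
            new["t0"] = kwargs.pop("t0", self.t0)
        new.update(kwargs)
        return ModelParams(**new)
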