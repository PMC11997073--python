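"""Model parameters and run labelling.

All rates are per epoch (one tau-leap / Euler step, ``dt = 1``).  With the
default ``gamma0 = 0.01`` and an epoch read as one day, the mean protocell
lifespan is ``1 / gamma0 = 100`` days.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

__all__ = ["ModelParams", "run_label"]


@dataclass(frozen=True)
class ModelParams:
    """Full parameter set of the protocell evolution model.

    Defaults reproduce the reference configuration: replication rate
    ``k0 = 0.1`` per unit food concentration, decay ``gamma0 = 0.01``,
    instantaneous-ish waste recycling ``s = 1``, quadratic replication
    advantage in both traits (``b_eta = b_zeta = 1``), a small chiral bias
    ``g`` placed in the decay rate, and an information-limiting factor ``f``
    that keeps the fitness peak off the ``zeta = L`` boundary.

    ``c`` rescales zeta as ``x = c * zeta``; when omitted it defaults to
    ``3 / (2 L)`` so that ``x`` spans ``[0, 1.5]``.
    """

    k0: float = 0.1          # total replication rate at the origin, per step per unit food
    gamma0: float = 0.01     # decay rate at the origin, per step
    s: float = 1.0           # waste -> food recycling rate, per step
    n: int = 1               # food-stoichiometry exponent
    b_eta: float = 1.0       # d2 ka / d eta2 at the origin
    a_zeta: float = 0.0      # d ka / d x at the origin (information drift)
    b_zeta: float = 1.0      # d2 ka / d x2 at the origin
    eps_eta: float = 0.01    # mutation scale in eta
    eps_zeta: float = 0.01   # mutation scale in zeta
    g: float = 0.002         # global chiral asymmetry factor (enters gamma)
    f: float = 1000.0        # information-limiting factor (x^8 penalty in gamma)
    L: float = 25.0          # upper zeta bound
    c: float | None = None   # zeta scaling; None -> 3 / (2 L)
    z: float = 1e-5          # kernel sparsification threshold on discrete mass
    rho0: int = 10**9        # total molecule count (exact invariant)
    U00: int = 1000          # initial protocells at the origin node
    dt: float = 1.0          # step size (one epoch)
    seed: int = 0            # RNG seed

    def __post_init__(self) -> None:
        if self.c is None:
            object.__setattr__(self, "c", 3.0 / (2.0 * self.L))
        if not (self.L > 0):
            raise ValueError(f"L must be positive, got {self.L}")
        for name in ("k0", "gamma0", "s"):
            if not (getattr(self, name) > 0):
                raise ValueError(f"{name} must be positive, got {getattr(self, name)}")
        if not (0 < self.eps_eta < 0.5):
            raise ValueError(
                f"eps_eta must satisfy 0 < eps_eta < 0.5 (mutations are small), got {self.eps_eta}"
            )
        if not (0 < self.eps_zeta < self.L / 10):
            raise ValueError(
                f"eps_zeta must satisfy 0 < eps_zeta < L/10 = {self.L / 10}, got {self.eps_zeta}"
            )
        if not (0 <= self.g < 1):
            raise ValueError(f"asymmetry factor g must lie in [0, 1), got {self.g}")
        if self.f < 0:
            raise ValueError(f"limiting factor f must be >= 0, got {self.f}")
        if not (0 < self.z < 1):
            raise ValueError(f"threshold z must lie in (0, 1), got {self.z}")
        if isinstance(self.n, bool) or not isinstance(self.n, int) or self.n < 1:
            raise ValueError(f"stoichiometry n must be an integer >= 1, got {self.n!r}")
        if not (self.rho0 > self.U00 >= 1):
            raise ValueError(
                f"need rho0 > U00 >= 1, got rho0={self.rho0}, U00={self.U00}"
            )
        if not (self.dt > 0):
            raise ValueError(f"dt must be positive, got {self.dt}")

    def to_dict(self) -> dict:
        return asdict(self)


def _frac_digits(value: float) -> str:
    """Digits after the decimal point, trailing zeros stripped: 0.005 -> '005'."""
    text = f"{value:.12f}".rstrip("0")
    if "." not in text:
        return "0"
    frac = text.split(".")[1]
    return frac if frac else "0"


def run_label(params: ModelParams, d: int) -> str:
    """Deterministic run identifier following the
    ``d{d}k{b_eta}e{eps}g{gamma0}a{g}[i{10 a_zeta}]f1E`` code family.

    The label is an opaque identifier; it is never parsed back into
    parameters.  ``eps`` uses ``eps_eta`` (all shipped scenarios set
    ``eps_eta == eps_zeta``).
    """
    parts = [
        f"d{int(d)}",
        f"k{params.b_eta:g}",
        f"e{_frac_digits(params.eps_eta)}",
        f"g{_frac_digits(params.gamma0)}",
        f"a{_frac_digits(params.g)}",
    ]
    if params.a_zeta > 0:
        parts.append(f"i{int(round(10 * params.a_zeta))}")
    if params.f == 1000.0:
        parts.append("f1E")
    else:
        parts.append(f"f{params.f:g}")
    return "".join(parts)
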