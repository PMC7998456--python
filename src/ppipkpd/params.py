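"""Population parameter containers and published ilaprazole estimates.

The fixed-effect values below are the published population estimates for
intravenous ilaprazole in healthy Chinese adults.  Between-subject
variability (BSV) is parameterised as log-normal: an individual parameter is
``theta * exp(eta)`` with ``eta ~ N(0, omega^2)``, so every ``omega_*`` field
is a standard deviation on the log scale.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields


def _require_positive(obj, names):
    for n in names:
        v = getattr(obj, n)
        if not (v > 0) or not math.isfinite(v):
            raise ValueError(f"{type(obj).__name__}.{n} must be strictly positive, got {v!r}")


def _require_nonnegative(obj, names):
    for n in names:
        v = getattr(obj, n)
        if v < 0 or not math.isfinite(v):
            raise ValueError(f"{type(obj).__name__}.{n} must be non-negative, got {v!r}")


@dataclass(frozen=True)
class PKParameters:
    """Population PK fixed effects, BSV and residual error.

    Two-compartment disposition with linear elimination.  ``theta_wt`` is the
    allometric exponent of body weight (referenced to 70 kg) on the central
    volume; ``theta_sex`` multiplies CLp for subjects coded ``sex = 1``
    (males, in the bundled generators).
    """

    CLp: float                  # central clearance, L/h
    CLt: float                  # inter-compartmental clearance, L/h
    Vc: float                   # central volume, L
    Vt: float                   # peripheral volume, L
    theta_wt: float = 0.0       # allometric weight exponent on Vc
    theta_sex: float = 1.0      # multiplicative sex effect on CLp
    omega_CLp: float = 0.0      # log-scale BSV SDs
    omega_CLt: float = 0.0
    omega_Vc: float = 0.0
    omega_Vt: float = 0.0
    sigma_prop: float = 0.0     # proportional residual error magnitude

    def __post_init__(self):
        _require_positive(self, ["CLp", "CLt", "Vc", "Vt", "theta_sex"])
        _require_nonnegative(
            self, ["omega_CLp", "omega_CLt", "omega_Vc", "omega_Vt", "sigma_prop"]
        )

    def omegas(self):
        return (self.omega_CLp, self.omega_CLt, self.omega_Vc, self.omega_Vt)

    def replace(self, **kw) -> "PKParameters":
        d = {f.name: getattr(self, f.name) for f in fields(self)}
        d.update(kw)
        return PKParameters(**d)


@dataclass(frozen=True)
class PDParameters:
    """Gastric-acid PD system parameters.

    The proton-pump turnover state E/E0 is synthesised at ``ksyn`` and
    degraded at ``kdeg``; at steady state ``ksyn = kdeg`` so ksyn is not a
    free field.  ``kd`` is the second-order irreversible inactivation
    constant (per (ng/mL) per h).  Acid secretion is ``kout * HBASE *
    f_circadian * E`` and elimination ``kout * H``.  ``MA``/``MW``/``MTmax``
    describe the nocturnal H+ surge (amplitude, width in h, peak clock time
    in h); ``FE4h``/``FE10h``/``kFE`` the meal-dilution bolus at 4 h and
    10 h after the 08:00 dose and its washout rate.
    """

    kdeg: float                 # 1/h
    kd: float                   # 1/((ng/mL) h)
    kout: float                 # 1/h
    HBASE: float                # mM
    MA: float = 0.0             # surge amplitude (dimensionless)
    MW: float = 1.0             # surge width, h
    MTmax: float = 22.0         # surge peak clock time, h
    FE4h: float = 0.0           # lunch dilution magnitude
    FE10h: float = 0.0          # dinner dilution magnitude
    kFE: float = 1.0            # food-effect washout, 1/h
    omega_kdeg: float = 0.0     # log-scale BSV SDs
    omega_kd: float = 0.0
    omega_kout: float = 0.0
    sigma_add: float = 0.0      # additive pH residual SD

    def __post_init__(self):
        _require_positive(self, ["kdeg", "kd", "kout", "HBASE", "MW", "kFE"])
        _require_nonnegative(
            self,
            ["MA", "FE4h", "FE10h", "omega_kdeg", "omega_kd", "omega_kout", "sigma_add"],
        )

    def omegas(self):
        return (self.omega_kdeg, self.omega_kd, self.omega_kout)

    def replace(self, **kw) -> "PDParameters":
        d = {f.name: getattr(self, f.name) for f in fields(self)}
        d.update(kw)
        return PDParameters(**d)


@dataclass(frozen=True)
class Demographics:
    """Weight distribution (truncated normal) and 1:1 sex allocation."""

    weight_mean: float
    weight_sd: float
    weight_min: float
    weight_max: float

    def __post_init__(self):
        if not (self.weight_min < self.weight_mean < self.weight_max):
            raise ValueError("inconsistent weight bounds")
        if self.weight_sd <= 0:
            raise ValueError("weight_sd must be positive")


#: Published population PK estimates (IV ilaprazole, healthy adults).
ILAPRAZOLE_PK = PKParameters(
    CLp=2.57,
    CLt=4.59,
    Vc=8.80,
    Vt=3.65,
    theta_wt=1.35,
    theta_sex=1.30,
    omega_CLp=0.23,
    omega_CLt=1.17,
    omega_Vc=0.062,
    omega_Vt=0.29,
    sigma_prop=0.12,
)

#: Published PD estimates.  The printed BSV entries (2.61, 1.38, 1.32) are
#: variances of the log-scale random effects; the SDs stored here are their
#: square roots.
ILAPRAZOLE_PD = PDParameters(
    kdeg=0.15,
    kd=18.24,
    kout=5.6,
    HBASE=0.033,
    MA=28.48,
    MW=0.99,
    MTmax=22.38,
    FE4h=40.04,
    FE10h=97.7,
    kFE=0.64,
    omega_kdeg=math.sqrt(2.61),
    omega_kd=math.sqrt(1.38),
    omega_kout=math.sqrt(1.32),
    sigma_add=1.28,
)

#: Demographics of the 16-subject internal study (mean 62.6 kg, SD 8.0,
#: range 52.0-79.0 kg).
HEALTHY_STUDY_DEMOGRAPHICS = Demographics(62.6, 8.0, 52.0, 79.0)

#: Demographics of the 2000-subject simulation population (median 70 kg,
#: range 40-80 kg); SD 8 kg chosen as a realistic adult spread given only
#: the median and range are stated.
SIMULATION_DEMOGRAPHICS = Demographics(70.0, 8.0, 40.0, 80.0)
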