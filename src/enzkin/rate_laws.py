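"""Steady-state rate equations and derived catalytic constants.

Velocities carry specific-activity units (µmol·min⁻¹·mg⁻¹) end to end; the
turnover number kcat (s⁻¹) and the log catalytic efficiency are derived views
computed on demand, never internal units.  All evaluators accept scalars or
numpy arrays and are pure functions of their arguments.

Rate laws implemented:

* Michaelis–Menten              v = Vmax·S / (Km + S)
* Hill                          v = Vmax·Sⁿ / (K₀.₅ⁿ + Sⁿ)
* rapid-equilibrium random bi-bi
                                v = Vmax·A·B / (Ka·Kb + Ka·B + Kb·A + A·B)
* linear competitive            v = Vmax·S / (Km·(1 + I/Ki) + S)
* linear mixed                  v = Vmax·S / (Km·(1 + I/Ki) + S·(1 + I/(α·Ki)))
* linear uncompetitive          v = Vmax·S / (Km + S·(1 + I/Ki))

The mixed law with α = 1 is the classical noncompetitive form; α < 1 means the
enzyme–inhibitor complex binds the co-substrate more tightly than free enzyme.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import ValidationError

__all__ = [
    "MichaelisModel", "HillModel", "RandomBiBiModel", "CompetitiveModel",
    "MixedModel", "UncompetitiveModel", "EnzymeMassModel", "DerivedConstants",
    "TemperatureScaling",
    "v_mm", "v_hill", "v_random_bibi", "v_competitive", "v_mixed",
    "v_uncompetitive", "kcat_from_specific_activity",
    "specific_activity_from_kcat", "catalytic_efficiency", "q10",
    "extrapolate_rate", "fold_change", "THA_PK_MASS",
]


def _check_nonneg(name: str, value) -> np.ndarray:
    arr = np.asarray(value, dtype=float)
    if np.any(arr < 0):
        raise ValidationError(f"{name} must be >= 0")
    return arr


def _check_pos(name: str, value: float) -> None:
    if not value > 0:
        raise ValidationError(f"{name} must be > 0, got {value}")


@dataclass(frozen=True)
class MichaelisModel:
    vmax: float   # µmol·min⁻¹·mg⁻¹
    km: float     # mM

    def __post_init__(self):
        _check_pos("vmax", self.vmax)
        _check_pos("km", self.km)


@dataclass(frozen=True)
class HillModel:
    vmax: float
    k05: float    # half-saturation concentration, mM
    n: float      # Hill coefficient

    def __post_init__(self):
        _check_pos("vmax", self.vmax)
        _check_pos("k05", self.k05)
        _check_pos("n", self.n)


@dataclass(frozen=True)
class RandomBiBiModel:
    """Rapid-equilibrium random-order bi-substrate model.

    A is the ionized phosphoenolpyruvate pool (PEP³⁻), B the metal·ADP
    complex; Ka and Kb are their Michaelis constants (mM).
    """

    vmax: float
    ka: float
    kb: float

    def __post_init__(self):
        _check_pos("vmax", self.vmax)
        _check_pos("ka", self.ka)
        _check_pos("kb", self.kb)


@dataclass(frozen=True)
class CompetitiveModel:
    vmax: float
    km: float
    ki: float     # inhibition constant, mM

    def __post_init__(self):
        _check_pos("vmax", self.vmax)
        _check_pos("km", self.km)
        _check_pos("ki", self.ki)


@dataclass(frozen=True)
class MixedModel:
    vmax: float
    km: float
    ki: float
    alpha: float  # inhibitor's effect on co-substrate affinity

    def __post_init__(self):
        _check_pos("vmax", self.vmax)
        _check_pos("km", self.km)
        _check_pos("ki", self.ki)
        _check_pos("alpha", self.alpha)


@dataclass(frozen=True)
class UncompetitiveModel:
    vmax: float
    km: float
    ki: float

    def __post_init__(self):
        _check_pos("vmax", self.vmax)
        _check_pos("km", self.km)
        _check_pos("ki", self.ki)


@dataclass(frozen=True)
class EnzymeMassModel:
    """Mass bookkeeping for converting specific activity to turnover.

    ``monomer_mass = core_monomer_mass + tag_mass`` and
    ``oligomer_mass = oligomer_count × monomer_mass`` hold by construction.
    """

    core_monomer_mass: float  # Da
    tag_mass: float           # Da (affinity tag + protease site, 0 if none)
    oligomer_count: int

    def __post_init__(self):
        _check_pos("core_monomer_mass", self.core_monomer_mass)
        if self.tag_mass < 0:
            raise ValidationError("tag_mass must be >= 0")
        if self.oligomer_count < 1:
            raise ValidationError("oligomer_count must be >= 1")

    @property
    def monomer_mass(self) -> float:
        return self.core_monomer_mass + self.tag_mass

    @property
    def oligomer_mass(self) -> float:
        return self.oligomer_count * self.monomer_mass


#: The tetrameric pyruvate kinase studied here: 59,147.48 Da core monomer plus
#: a 2,193.26 Da His6-tag/thrombin-site extension, assembled as a homotetramer
#: (oligomer mass ≈ 245.36 kDa).  The tetramer is the catalytic unit used for
#: kcat throughout.
THA_PK_MASS = EnzymeMassModel(core_monomer_mass=59147.48, tag_mass=2193.26,
                              oligomer_count=4)


@dataclass(frozen=True)
class DerivedConstants:
    kcat: float            # s⁻¹ per catalytic unit
    log_efficiency: float  # log10(kcat/K) with K in M

    def __post_init__(self):
        _check_pos("kcat", self.kcat)


@dataclass(frozen=True)
class TemperatureScaling:
    q10: float

    def __post_init__(self):
        _check_pos("q10", self.q10)


# --- rate-law evaluators -------------------------------------------------

def v_mm(s, model: MichaelisModel):
    s = _check_nonneg("s", s)
    return model.vmax * s / (model.km + s)


def v_hill(s, model: HillModel):
    s = _check_nonneg("s", s)
    sn = np.power(s, model.n)
    return model.vmax * sn / (model.k05 ** model.n + sn)


def v_random_bibi(a, b, model: RandomBiBiModel):
    a = _check_nonneg("a", a)
    b = _check_nonneg("b", b)
    return (model.vmax * a * b
            / (model.ka * model.kb + model.ka * b + model.kb * a + a * b))


def v_competitive(s, i, model: CompetitiveModel):
    s = _check_nonneg("s", s)
    i = _check_nonneg("i", i)
    return model.vmax * s / (model.km * (1.0 + i / model.ki) + s)


def v_mixed(s, i, model: MixedModel):
    s = _check_nonneg("s", s)
    i = _check_nonneg("i", i)
    return (model.vmax * s
            / (model.km * (1.0 + i / model.ki)
               + s * (1.0 + i / (model.alpha * model.ki))))


def v_uncompetitive(s, i, model: UncompetitiveModel):
    s = _check_nonneg("s", s)
    i = _check_nonneg("i", i)
    return model.vmax * s / (model.km + s * (1.0 + i / model.ki))


# --- derived constants ---------------------------------------------------

def kcat_from_specific_activity(vmax: float, mass: EnzymeMassModel) -> float:
    """Turnover number (s⁻¹ per oligomer) from specific activity.

    µmol·min⁻¹·mg⁻¹ × (g·mol⁻¹) gives µmol product per µmol enzyme per
    minute after the mg→g and µmol→mol factors cancel; dividing by 60 s/min
    leaves kcat = vmax × oligomer_mass / 60 000.
    """
    _check_pos("vmax", vmax)
    _check_pos("oligomer_mass", mass.oligomer_mass)
    return vmax * mass.oligomer_mass / 60000.0


def specific_activity_from_kcat(kcat: float, mass: EnzymeMassModel) -> float:
    """Inverse of :func:`kcat_from_specific_activity`."""
    _check_pos("kcat", kcat)
    return kcat * 60000.0 / mass.oligomer_mass


def catalytic_efficiency(kcat: float, k: float) -> float:
    """log10 of kcat/K in s⁻¹·M⁻¹; ``k`` is a Michaelis constant in mM."""
    _check_pos("kcat", kcat)
    _check_pos("k", k)
    return math.log10(kcat / (k * 1e-3))


def q10(rate1: float, t1: float, rate2: float, t2: float) -> TemperatureScaling:
    """Temperature coefficient from two rates: (r2/r1)^(10/(t2−t1))."""
    _check_pos("rate1", rate1)
    _check_pos("rate2", rate2)
    if t1 == t2:
        raise ValidationError("q10 requires two distinct temperatures")
    return TemperatureScaling(q10=(rate2 / rate1) ** (10.0 / (t2 - t1)))


def extrapolate_rate(rate: float, t_from: float, t_to: float,
                     scaling: TemperatureScaling) -> float:
    """Scale a rate across temperature: rate × Q10^((t_to − t_from)/10)."""
    _check_pos("rate", rate)
    return rate * scaling.q10 ** ((t_to - t_from) / 10.0)


def fold_change(value_a: float, value_b: float) -> float:
    """Ratio value_a / value_b; reporting layers round to the nearest integer."""
    if value_b == 0:
        raise ValidationError("fold_change denominator must be non-zero")
    if value_b < 0:
        raise ValidationError("fold_change denominator must be > 0")
    return value_a / value_b
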