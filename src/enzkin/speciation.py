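"""Equilibrium speciation of pyruvate-kinase assay mixtures.

The kinetically relevant species in a PK assay are not the weighed-in totals:
ADP is largely present as the metal·ADP complex (the true nucleotide
substrate), the divalent cation is split between free and complexed pools, and
phosphoenolpyruvate (PEP) is active as its fully ionized trianion, whose share
of the total is set by the assay pH against a pK of 6.3.  This module converts
total (analytical) compositions into those equilibrium pools and computes how
much inert 1:1 salt (modelling tetramethylammonium chloride) must be added to
hold the mixture at a constant target ionic strength.

Model scope: a single 1:1 metal–ADP binding equilibrium plus one PEP
protonation step.  ADP protonation and metal–PEP complexation are deliberately
ignored; see the methods note.  Concentrations are mM throughout.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import yaml

from .errors import ConfigurationError, InfeasibilityError, ValidationError

__all__ = [
    "AssayComposition",
    "BindingConstants",
    "SpeciatedMixture",
    "DEFAULT_SPECIES_CHARGES",
    "speciate",
    "ionized_fraction",
    "ionic_strength",
    "balance_ionic_strength",
    "load_binding_constants",
]

#: Integer charges used only for the ionic-strength sum.  PEP is carried as
#: trianion/dianion, ADP as trianion, the metal·ADP complex as net -1, and the
#: balancing salt as a pair of monovalent ions.  These are configuration, not
#: physics baked into code: supply your own map in :class:`BindingConstants`.
DEFAULT_SPECIES_CHARGES: dict[str, int] = {
    "metal_free": 2,
    "metal_adp": -1,
    "adp_free": -3,
    "pep_ionized": -3,
    "pep_protonated": -2,
}

#: Representative 1:1 dissociation constants (mM) for metal·ADP at ~0.1-0.2 M
#: ionic strength and neutral pH.  These are convenience defaults for
#: interactive use; every analysis in the test-suite and acceptance pipeline
#: supplies constants explicitly, so no default is load-bearing.
DEFAULT_KD_METAL_ADP = {"Mg": 0.25, "Mn": 0.10}


@dataclass(frozen=True)
class AssayComposition:
    """Total (weighed-in) composition of one reaction mixture, pre-equilibration.

    Concentrations in mM; ``buffer_contribution`` is the pre-computed ionic
    strength (mM) contributed by the buffer system, kept as a single number so
    buffer speciation stays out of scope.
    """

    metal_total: float
    adp_total: float
    pep_total: float
    pH: float
    temperature: float = 45.0
    target_ionic_strength: float = 200.0
    buffer_contribution: float = 0.0
    metal_identity: str = "Mg"

    def __post_init__(self):
        for name in ("metal_total", "adp_total", "pep_total",
                     "target_ionic_strength", "buffer_contribution"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0, got {getattr(self, name)}")
        if not 0.0 <= self.pH <= 14.0:
            raise ValidationError(f"pH must lie in [0, 14], got {self.pH}")
        if self.metal_identity not in ("Mg", "Mn"):
            raise ValidationError(f"metal_identity must be 'Mg' or 'Mn', got {self.metal_identity!r}")


@dataclass(frozen=True)
class BindingConstants:
    """Equilibrium constants and charge bookkeeping for speciation.

    ``kd_metal_adp`` is the dissociation constant (mM) of
    metal·ADP ⇌ metal²⁺ + ADP³⁻; ``pk_pep`` the acid pK of the PEP
    dianion/trianion couple (6.3 by default).
    """

    kd_metal_adp: float
    pk_pep: float = 6.3
    species_charges: Mapping[str, int] = field(
        default_factory=lambda: dict(DEFAULT_SPECIES_CHARGES))

    def __post_init__(self):
        if not self.kd_metal_adp > 0:
            raise ValidationError(f"kd_metal_adp must be > 0, got {self.kd_metal_adp}")
        if not 0.0 < self.pk_pep < 14.0:
            raise ValidationError(f"pk_pep must lie in (0, 14), got {self.pk_pep}")


@dataclass(frozen=True)
class SpeciatedMixture:
    """Equilibrium pools of one mixture, all in mM."""

    metal_free: float
    metal_adp: float
    adp_free: float
    pep_ionized: float
    pep_protonated: float
    balancing_salt: float
    achieved_ionic_strength: float


def ionized_fraction(pH: float, pK: float) -> float:
    """Henderson–Hasselbalch fraction of the deprotonated (ionized) form.

    Returns ``1 / (1 + 10**(pK - pH))``, i.e. 0.5 at pH = pK.
    """
    if not (0.0 < pH < 14.0 and 0.0 < pK < 14.0):
        raise ValidationError(f"pH and pK must lie in (0, 14); got pH={pH}, pK={pK}")
    return 1.0 / (1.0 + 10.0 ** (pK - pH))


def _complex_concentration(m_total: float, d_total: float, kd: float) -> float:
    """Unique non-negative root of the 1:1 binding mass-action system.

    The complex concentration c solves c² − (M + D + Kd)·c + M·D = 0 with
    0 ≤ c ≤ min(M, D).  The smaller quadratic root is evaluated in the
    cancellation-free form 2·M·D / (S + sqrt(S² − 4·M·D)), which stays accurate
    when Kd ≫ M, D (where the naive form subtracts nearly equal numbers).
    """
    if m_total == 0.0 or d_total == 0.0:
        return 0.0
    s = m_total + d_total + kd
    disc = s * s - 4.0 * m_total * d_total
    if disc < 0.0:  # cannot happen for valid input; guard against NaN roots
        raise EnvironmentError("mass-action discriminant negative — internal error")
    c = 2.0 * m_total * d_total / (s + math.sqrt(disc))
    return min(c, m_total, d_total)


def ionic_strength(species_concentrations: Mapping[str, float],
                   charges: Mapping[str, int]) -> float:
    """I = ½ Σ cᵢ·zᵢ² in mM; every species must have a charge entry."""
    total = 0.0
    for name, conc in species_concentrations.items():
        if name not in charges:
            raise ConfigurationError(f"no charge configured for species {name!r}")
        total += conc * charges[name] ** 2
    return 0.5 * total


def _unbalanced_ionic_strength(composition: AssayComposition,
                               speciated: SpeciatedMixture,
                               constants: BindingConstants) -> float:
    pools = {
        "metal_free": speciated.metal_free,
        "metal_adp": speciated.metal_adp,
        "adp_free": speciated.adp_free,
        "pep_ionized": speciated.pep_ionized,
        "pep_protonated": speciated.pep_protonated,
    }
    return ionic_strength(pools, constants.species_charges) + composition.buffer_contribution


def balance_ionic_strength(composition: AssayComposition,
                           speciated: SpeciatedMixture,
                           constants: BindingConstants) -> float:
    """mM of inert 1:1 monovalent salt needed to reach the target ionic strength.

    Each mM of a 1:1 salt contributes exactly 1 mM of ionic strength, so the
    answer is ``target − I_current``.  Raises :class:`InfeasibilityError`
    (reporting the excess) when the mixture already exceeds the target.
    """
    i_current = _unbalanced_ionic_strength(composition, speciated, constants)
    deficit = composition.target_ionic_strength - i_current
    if deficit < 0.0:
        raise InfeasibilityError(
            f"mixture ionic strength {i_current:.3f} mM exceeds target "
            f"{composition.target_ionic_strength:.3f} mM by {-deficit:.3f} mM",
            excess=-deficit)
    return deficit


def speciate(composition: AssayComposition,
             constants: BindingConstants,
             balance: bool = True) -> SpeciatedMixture:
    """Equilibrate one assay mixture.

    Solves the 1:1 metal–ADP binding equilibrium in closed form, splits PEP by
    the Henderson–Hasselbalch fraction at ``constants.pk_pep``, and (when
    ``balance``) computes the inert-salt addition that brings the mixture to
    its target ionic strength.  Mass balances hold to well below 1e-9 mM.
    """
    c = _complex_concentration(composition.metal_total, composition.adp_total,
                               constants.kd_metal_adp)
    frac = ionized_fraction(composition.pH, constants.pk_pep)
    pep_ion = frac * composition.pep_total
    mixture = SpeciatedMixture(
        metal_free=composition.metal_total - c,
        metal_adp=c,
        adp_free=composition.adp_total - c,
        pep_ionized=pep_ion,
        pep_protonated=composition.pep_total - pep_ion,
        balancing_salt=0.0,
        achieved_ionic_strength=0.0,
    )
    if balance:
        salt = balance_ionic_strength(composition, mixture, constants)
        i_total = _unbalanced_ionic_strength(composition, mixture, constants) + salt
    else:
        salt = 0.0
        i_total = _unbalanced_ionic_strength(composition, mixture, constants)
    return replace(mixture, balancing_salt=salt, achieved_ionic_strength=i_total)


def load_binding_constants(path: str | Path, metal: str = "Mg") -> BindingConstants:
    """Read binding constants from a YAML/JSON config file.

    Recognised keys: ``kd_mg_adp``, ``kd_mn_adp`` (mM), ``pk_pep``, and an
    optional ``species_charges`` mapping.  ``metal`` selects which Kd is used.
    """
    path = Path(path)
    if not path.exists():
        raise ConfigurationError(f"binding-constants file not found: {path}")
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ConfigurationError(f"binding-constants file {path} must hold a mapping")
    key = f"kd_{metal.lower()}_adp"
    known = {"kd_mg_adp", "kd_mn_adp", "pk_pep", "species_charges"}
    unknown = set(raw) - known
    if unknown:
        raise ConfigurationError(f"unknown keys in {path}: {sorted(unknown)}")
    if key not in raw:
        raise ConfigurationError(f"{path} has no entry {key!r} for metal {metal!r}")
    return BindingConstants(
        kd_metal_adp=float(raw[key]),
        pk_pep=float(raw.get("pk_pep", 6.3)),
        species_charges=dict(raw.get("species_charges", DEFAULT_SPECIES_CHARGES)),
    )
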