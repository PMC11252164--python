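"""Model parameters: rate constants, protein abundances, and mutant scalings.

Concentrations are nondimensionalized so that the total heterotrimeric G-protein
alpha-subunit pool ``Ga_tot`` is 1 by default; every other abundance is expressed
relative to it.  Time is in seconds.  Because the downstream readouts are fold
changes of steady-state effector complexes, results are invariant to the overall
concentration scale.

Two named presets ship with the package:

``initial``
    The first-pass parameterization: PLC-beta acts as a very strong GAP
    (``k_hyd2``/``k_hyd`` = 770, following reports that GAP-stimulated hydrolysis
    by PLC-beta1 can be ~1000-fold faster than basal) and the Q209 mutants bind
    both effectors at wild-type rates (effector bias 1).

``revised``
    The experimentally-informed update: ``k_hyd2``/``k_hyd`` = 20 (midpoint of the
    accepted 1-40 band on a log-ish scale) and the Q209 mutants bind TRIO with a
    4-fold elevated association rate relative to PLC-beta (effector bias 4).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import yaml

__all__ = [
    "VariantScalings",
    "ModelParameters",
    "load_preset",
    "PRESET_NAMES",
    "GALPHA_VARIANTS",
    "RECEPTOR_VARIANTS",
]

PRESET_NAMES = ("initial", "revised")

#: Variants that live on the G-alpha subunit (GNAQ / GNA11).
GALPHA_VARIANTS = ("Q209L", "Q209P", "R183C")
#: Variants that live on the receptor (CYSLTR2).
RECEPTOR_VARIANTS = ("L129Q",)


@dataclass
class VariantScalings:
    """Mutant-over-WT scalings applied to the mutant species pool.

    ``r_trio`` and ``r_plc`` scale the association rate constants of mutant
    GaGTP with TRIO and PLC-beta (dissociation rates are left at their WT
    values, so varying them changes the equilibrium dissociation constants).
    ``r_hyd`` scales intrinsic GTP hydrolysis and ``r_gap`` scales
    GAP-stimulated hydrolysis (both the RGS catalytic step and PLC-beta's
    GAP activity on its own complex).  ``f_act_mut`` is the fraction of
    mutant receptor in the active conformation and is only meaningful for
    receptor variants.
    """

    r_trio: float = 1.0
    r_plc: float = 1.0
    r_hyd: float = 1.0
    r_gap: float = 1.0
    f_act_mut: float = 1.0

    @property
    def effector_bias(self) -> float:
        """Mutant TRIO-over-PLC association bias, r_trio / r_plc."""
        return self.r_trio / self.r_plc

    def validate(self) -> None:
        for name in ("r_trio", "r_plc", "r_hyd", "r_gap"):
            v = getattr(self, name)
            if not v >= 0:
                raise ValueError(f"variant scaling {name} must be >= 0, got {v}")
        if not 0.0 <= self.f_act_mut <= 1.0:
            raise ValueError(f"f_act_mut must be in [0, 1], got {self.f_act_mut}")


_RATE_FIELDS = (
    "k_gef",
    "k_hyd",
    "k_rgs_on",
    "k_rgs_off",
    "k_rgs_cat",
    "k_on_trio",
    "k_off_trio",
    "k_on_plc",
    "k_off_plc",
    "k_hyd2",
    "k_gtp_off",
    "k_nt_load",
    "k_trimer",
)
_ABUNDANCE_FIELDS = ("R_tot", "Ga_tot", "Gbg_tot", "RGS_tot", "TRIO_tot", "PLC_tot")


@dataclass
class ModelParameters:
    """Full symbol table of the G-protein cycle model.

    Rate constants (time in seconds, concentrations relative to ``Ga_tot``):

    k_gef
        Receptor-catalyzed GDP->GTP exchange on the heterotrimer (per conc/s).
    k_hyd
        Intrinsic (basal) hydrolysis of Ga-bound GTP (1/s).
    k_rgs_on, k_rgs_off, k_rgs_cat
        The explicit RGS GAP enzyme cycle: association with GaGTP,
        dissociation, and catalyzed hydrolysis releasing GaGDP.
    k_on_trio, k_off_trio / k_on_plc, k_off_plc
        Association/dissociation of GaGTP with the effectors TRIO and
        PLC-beta.
    k_hyd2
        GAP-stimulated hydrolysis of GTP inside the GaGTP.PLC-beta complex
        (PLC-beta acting as its own GAP), releasing GaGDP and free PLC-beta.
    k_gtp_off, k_nt_load
        GTP release from free GaGTP yielding nucleotide-free Ga, and
        pseudo-first-order reloading (cellular GTP excess folded in).
    k_trimer
        Reassociation of GaGDP with free G-beta-gamma.
    """

    k_gef: float = 1.0
    k_hyd: float = 0.01
    k_rgs_on: float = 10.0
    k_rgs_off: float = 1.0
    k_rgs_cat: float = 2.0
    k_on_trio: float = 10.0
    k_off_trio: float = 1.0
    k_on_plc: float = 10.0
    k_off_plc: float = 1.0
    k_hyd2: float = 0.2
    k_gtp_off: float = 0.001
    k_nt_load: float = 10.0
    k_trimer: float = 10.0

    f_act_wt: float = 0.01
    stimulated_f_act: float = 1.0

    R_tot: float = 0.2
    Ga_tot: float = 1.0
    Gbg_tot: float = 1.0
    RGS_tot: float = 0.2
    TRIO_tot: float = 0.5
    PLC_tot: float = 0.5

    variants: dict[str, VariantScalings] = field(default_factory=dict)
    preset: str | None = None

    def validate(self) -> None:
        for name in _RATE_FIELDS + _ABUNDANCE_FIELDS:
            v = getattr(self, name)
            if not v >= 0:
                raise ValueError(f"parameter {name} must be nonnegative, got {v}")
        for name in ("f_act_wt", "stimulated_f_act"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for vname, vs in self.variants.items():
            try:
                vs.validate()
            except ValueError as exc:
                raise ValueError(f"variant {vname}: {exc}") from exc

    def scalings_for(self, variant: str) -> VariantScalings:
        if variant not in self.variants:
            raise KeyError(
                f"unknown variant {variant!r}; known: {sorted(self.variants)}"
            )
        return self.variants[variant]

    def replace(self, **overrides) -> "ModelParameters":
        """Return a copy with scalar fields replaced (variants are shared copies)."""
        new = dataclasses.replace(self, variants=dict(self.variants))
        for key, val in overrides.items():
            if not hasattr(new, key):
                raise KeyError(f"unknown parameter {key!r}")
            setattr(new, key, val)
        new.validate()
        return new

    def set_effector_bias(self, bias: float, variant: str = "Q209L") -> "ModelParameters":
        """Return a copy where ``variant``'s TRIO association scaling is set so
        that r_trio / r_plc equals ``bias`` (PLC scaling held fixed)."""
        new = self.replace()
        old = new.variants[variant]
        new.variants[variant] = dataclasses.replace(old, r_trio=bias * old.r_plc)
        return new

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        d = {name: getattr(self, name) for name in _RATE_FIELDS + _ABUNDANCE_FIELDS}
        d["f_act_wt"] = self.f_act_wt
        d["stimulated_f_act"] = self.stimulated_f_act
        d["variants"] = {
            vname: dataclasses.asdict(vs) for vname, vs in self.variants.items()
        }
        if self.preset:
            d["preset"] = self.preset
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ModelParameters":
        d = dict(d)
        variants = {
            vname: VariantScalings(**vs) for vname, vs in d.pop("variants", {}).items()
        }
        known = {f.name for f in dataclasses.fields(cls)} - {"variants"}
        unknown = set(d) - known
        if unknown:
            raise KeyError(f"unknown parameter keys: {sorted(unknown)}")
        params = cls(variants=variants, **d)
        params.validate()
        return params

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ModelParameters":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)


def load_preset(name: str) -> ModelParameters:
    """Load one of the shipped parameter presets (``initial`` or ``revised``)."""
    if name not in PRESET_NAMES:
        raise ValueError(f"unknown preset {name!r}; choose from {PRESET_NAMES}")
    ref = resources.files("gqcycle.data") / f"preset_{name}.yaml"
    params = ModelParameters.from_dict(yaml.safe_load(ref.read_text()))
    params.preset = name
    return params
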