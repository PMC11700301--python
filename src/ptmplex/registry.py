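"""Modification mass registry.

Monoisotopic delta masses (Da) for the modifications quantified by the
pipeline, with their target residues and fixed/dynamic status.  In TMT
searches the label is a fixed modification on lysine and the peptide
N-terminus, so a lysine acetylation — which blocks TMT labeling of that
lysine — is searched as a *dynamic* modification whose mass is the acetyl
mass minus the TMT mass (a negative delta relative to the fixed label).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import math

import yaml

from .errors import ConfigurationError, ValidationError

NTERM = "N-term"

# Monoisotopic masses, Da.  The acetyl mass is kept at the precision used
# when quoting the acetyl-minus-TMT delta (-262.196586 Da).
DEFAULT_MODS: dict[str, tuple[float, tuple[str, ...], bool]] = {
    "met_ox": (15.9949, ("M",), False),
    "nem": (125.047679, ("C",), False),
    "phospho": (79.9663, ("S", "T", "Y"), False),
    "tmt": (304.207146, ("K", NTERM), True),
    "acetyl": (42.01056, ("K",), False),
}


@dataclass(frozen=True)
class ModEntry:
    """One modification: delta mass, residues it targets, fixed/dynamic."""

    name: str
    delta_mass: float
    targets: tuple[str, ...]
    fixed: bool = False

    def __post_init__(self) -> None:
        if not math.isfinite(self.delta_mass):
            raise ValidationError(f"modification {self.name!r}: delta mass not finite")
        if not self.targets:
            raise ValidationError(
                f"modification {self.name!r}: must name at least one target residue or N-term"
            )


@dataclass
class ModRegistry:
    """Mapping from modification name to :class:`ModEntry`."""

    entries: dict[str, ModEntry] = field(default_factory=dict)

    def __contains__(self, name: str) -> bool:
        return name in self.entries

    def __getitem__(self, name: str) -> ModEntry:
        try:
            return self.entries[name]
        except KeyError:
            raise ConfigurationError(f"modification {name!r} not in registry") from None

    def add(self, name: str, delta_mass: float, targets, fixed: bool = False) -> None:
        self.entries[name] = ModEntry(name, float(delta_mass), tuple(targets), fixed)

    @classmethod
    def default(cls) -> "ModRegistry":
        reg = cls()
        for name, (mass, targets, fixed) in DEFAULT_MODS.items():
            reg.add(name, mass, targets, fixed)
        return reg

    @classmethod
    def from_yaml(cls, path) -> "ModRegistry":
        """Load a registry from a YAML mapping ``name: {delta_mass, targets, fixed}``.

        Entries merge on top of the built-in defaults so configs only need to
        list additions or overrides.
        """
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        if not isinstance(doc, Mapping):
            raise ConfigurationError(f"{path}: registry file must be a mapping")
        reg = cls.default()
        for name, spec in doc.items():
            if not isinstance(spec, Mapping) or "delta_mass" not in spec:
                raise ConfigurationError(f"{path}: entry {name!r} needs a delta_mass")
            reg.add(
                name,
                float(spec["delta_mass"]),
                tuple(spec.get("targets", ())) or (NTERM,),
                bool(spec.get("fixed", False)),
            )
        return reg


def acetyl_delta_vs_fixed_tmt(
    registry: ModRegistry, acetyl: str = "acetyl", tmt: str = "tmt"
) -> float:
    """Dynamic-search delta mass (Da) for acetyl-lysine under a fixed TMT label.

    An acetylated lysine cannot carry the TMT label, so with TMT fixed on K
    the acetylation appears as ``acetyl_mass - tmt_mass`` (signed, negative).
    """
    return registry[acetyl].delta_mass - registry[tmt].delta_mass
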