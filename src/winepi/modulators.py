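"""Odour activity values and essential-modulator assembly.

The model's degrees of freedom are five flavour-themed groups of volatile
compounds ("essential modulators"): fruity, herbal, floral, woody, and a
residual spicy/other group.  Membership is driven by the odour activity
value, OAV = concentration / odour detection threshold (ODT): compounds with
OAV > 1 are likely aroma contributors, and a small override list admits
compounds selected on sensory-correlation grounds despite sub-threshold OAVs
(benzaldehyde, heptan-1-ol, phenol).

The published membership list gives the "others" group only two compounds,
while the dimensionless-group construction wants three variables per group.
The default configuration adds guaiacol as a configurable third member; a
two-member group can be allowed explicitly, in which case it contributes a
two-variable form downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

__all__ = [
    "CompoundRecord",
    "ModulatorSet",
    "ModulatorError",
    "InvalidThresholdError",
    "MODULATOR_LABELS",
    "DEFAULT_OVERRIDES",
    "DEFAULT_ASSIGNMENT",
    "compute_oav",
    "select_compounds",
    "assemble_modulators",
]

#: Modulator labels in model order M1..M5.
MODULATOR_LABELS: tuple[str, ...] = ("fruity", "herbal", "floral", "woody", "other")

#: Compounds admitted regardless of OAV, on sensory-correlation grounds.
DEFAULT_OVERRIDES: frozenset[str] = frozenset(
    {"benzaldehyde", "heptan-1-ol", "phenol"}
)

#: Published membership, in stated order.  Eugenol appears in both the woody
#: and the other group; guaiacol is the configurable third "other" member.
DEFAULT_ASSIGNMENT: dict[str, tuple[str, ...]] = {
    "fruity": ("ethyl octanoate", "ethyl butanoate", "ethyl hexanoate"),
    "herbal": ("hexan-1-ol", "(E)-hex-3-en-1-ol", "heptan-1-ol"),
    "floral": ("beta-damascenone", "2-phenylethan-1-ol", "linalool"),
    "woody": ("eugenol", "benzaldehyde", "guaiacol"),
    "other": ("phenol", "eugenol", "guaiacol"),
}


class ModulatorError(ValueError):
    """Raised when a modulator set cannot be assembled as configured."""


class InvalidThresholdError(ValueError):
    """Raised for a non-positive odour detection threshold."""


def compute_oav(concentration: float, odt: float) -> float:
    """Odour activity value: concentration / ODT (both in ug/L).

    Degree-0 homogeneous: rescaling concentration and threshold by the same
    factor leaves the OAV unchanged, so the ratio is unit-free.
    """
    if not (odt > 0):
        raise InvalidThresholdError(f"odour detection threshold must be > 0, got {odt}")
    if concentration < 0:
        raise ValueError(f"concentration must be non-negative, got {concentration}")
    return concentration / odt


@dataclass(frozen=True)
class CompoundRecord:
    """One compound in one wine: concentration, threshold, derived OAV."""

    name: str
    concentration: float  # ug/L
    odt: float  # ug/L
    oav: float = field(init=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "oav", compute_oav(self.concentration, self.odt))


@dataclass(frozen=True)
class ModulatorSet:
    """One flavour group and its ordered member compounds (normally three)."""

    label: str
    members: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.label not in MODULATOR_LABELS:
            raise ModulatorError(f"unknown modulator label {self.label!r}")
        if len(set(self.members)) != len(self.members):
            raise ModulatorError(f"duplicate members in modulator {self.label!r}")

    @property
    def k_vars(self) -> int:
        return len(self.members)


def select_compounds(
    records: Iterable[CompoundRecord],
    overrides: Iterable[str] = DEFAULT_OVERRIDES,
) -> list[str]:
    """Names of compounds that qualify as aroma contributors.

    A compound is selected iff its OAV is strictly greater than 1, or its
    name is in ``overrides``.  Order of first appearance is preserved;
    repeated records of one compound select it if any record qualifies.
    """
    records = list(records)
    if not records:
        raise ValueError("no compound records given")
    override_set = set(overrides)
    selected: list[str] = []
    for rec in records:
        if (rec.oav > 1 or rec.name in override_set) and rec.name not in selected:
            selected.append(rec.name)
    return selected


def assemble_modulators(
    selected: Sequence[str],
    assignment: Mapping[str, Sequence[str]] = DEFAULT_ASSIGNMENT,
    allow_two_members: bool = False,
) -> list[ModulatorSet]:
    """Build the modulator sets from selected compound names.

    ``assignment`` maps each modulator label to its ordered member names (the
    published layout is the default; it is data, not code, so other studies
    can re-map compounds).  A member is available when it was selected.  Each
    set must end up with exactly three available members -- or two, when
    ``allow_two_members`` is set, mirroring the two-compound "others" group of
    the published list.  Deficient sets raise a :class:`ModulatorError`
    naming every offender.
    """
    selected_set = set(selected)
    sets: list[ModulatorSet] = []
    deficient: list[str] = []
    for label, members in assignment.items():
        available = tuple(m for m in members if m in selected_set)
        sizes = (2, 3) if allow_two_members else (3,)
        if len(available) not in sizes:
            deficient.append(
                f"{label} (needs {' or '.join(map(str, sizes))} members, "
                f"has {len(available)}: {list(available)})"
            )
            continue
        sets.append(ModulatorSet(label=label, members=available))
    if deficient:
        raise ModulatorError("cannot assemble modulators: " + "; ".join(deficient))
    return sets
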