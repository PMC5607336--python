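"""Chemical species and reaction tables.

Mobile water-radiolysis species diffuse; DNA constituents and histones are
static targets (diffusion coefficient zero, each DNA molecule carrying its
strand number). Only the OH radical reacts with DNA; the histone acts as an
absorber that persists after every encounter. The phosphate is non-reactive
toward OH by default (the deoxyribose is the backbone attack site); a flag
restores phosphate reactivity for sensitivity studies.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ..constants import (CONSTITUENT_RADII_NM, DIFFUSION_M2_S,
                         DNA_OH_RATES_1E9, HISTONE_RADIUS_NM,
                         WATER_REACTIONS_1E10)
from ..errors import ConfigurationError

MOBILE_SPECIES = tuple(DIFFUSION_M2_S)
DNA_SPECIES = ("deoxyribose", "phosphate", "adenine", "guanine",
               "thymine", "cytosine")


@dataclass(frozen=True)
class SpeciesSpec:
    name: str
    diffusion_m2_s: float
    radius_nm: float

    @property
    def is_static(self) -> bool:
        return self.diffusion_m2_s == 0.0


def default_species() -> dict[str, SpeciesSpec]:
    table = {name: SpeciesSpec(name, d, 0.0)
             for name, d in DIFFUSION_M2_S.items()}
    for name in DNA_SPECIES:
        table[name] = SpeciesSpec(name, 0.0, CONSTITUENT_RADII_NM[name])
    table["histone"] = SpeciesSpec("histone", 0.0, HISTONE_RADIUS_NM)
    return table


@dataclass(frozen=True)
class ReactionSpec:
    """One bimolecular channel.

    ``rate`` is the thermal rate constant in 1/(M s); ``None`` marks a
    contact reaction (the histone absorber, triggered at touching distance
    with no rate attributed). ``preserve_first`` keeps the first reactant in
    the simulation (absorption without consumption).
    """

    reactant_a: str
    reactant_b: str
    rate_m_s: float | None
    products: tuple[str, ...] = ()
    preserve_first: bool = False

    def __post_init__(self):
        if self.rate_m_s is not None and self.rate_m_s < 0:
            raise ConfigurationError("reaction rate must be >= 0")

    @property
    def pair(self) -> frozenset:
        return frozenset((self.reactant_a, self.reactant_b))


def default_reactions(include_phosphate_oh: bool = False) -> list[ReactionSpec]:
    """Water-radical table plus OH-DNA attack plus the histone absorber."""
    out = [ReactionSpec(a, b, r * 1e10, products)
           for a, b, r, products in WATER_REACTIONS_1E10]
    for name, r9 in DNA_OH_RATES_1E9.items():
        out.append(ReactionSpec(name, "OH", r9 * 1e9, ()))
    if include_phosphate_oh:
        out.append(ReactionSpec(
            "phosphate", "OH", DNA_OH_RATES_1E9["deoxyribose"] * 1e9, ()))
    out.append(ReactionSpec("histone", "*", None, (), preserve_first=True))
    return out


@dataclass
class ReactionTable:
    """Lookup structure mapping species pairs to their reaction."""

    reactions: list[ReactionSpec] = field(default_factory=default_reactions)

    def __post_init__(self):
        self._by_pair: dict[frozenset, ReactionSpec] = {}
        self._absorbers: dict[str, ReactionSpec] = {}
        for r in self.reactions:
            if r.reactant_b == "*":
                self._absorbers[r.reactant_a] = r
            else:
                self._by_pair[r.pair] = r

    def lookup(self, name_a: str, name_b: str) -> ReactionSpec | None:
        r = self._by_pair.get(frozenset((name_a, name_b)))
        if r is not None:
            return r
        for name in (name_a, name_b):
            if name in self._absorbers:
                other = name_b if name == name_a else name_a
                if other not in self._absorbers:
                    a = self._absorbers[name]
                    return ReactionSpec(name, other, None, a.products,
                                        preserve_first=True)
        return None

    def partners_of(self, name: str) -> set[str]:
        out = set()
        for pair in self._by_pair:
            if name in pair:
                rest = set(pair) - {name}
                out.add(rest.pop() if rest else name)
        if self._absorbers and name not in self._absorbers:
            out.update(self._absorbers)
        return out


def mutual_diffusion(species: dict[str, SpeciesSpec],
                     name_a: str, name_b: str) -> float:
    d = species[name_a].diffusion_m2_s + species[name_b].diffusion_m2_s
    if d <= 0:
        raise ConfigurationError(
            f"both {name_a} and {name_b} are static; no encounter possible")
    return d


def contact_distance(species: dict[str, SpeciesSpec],
                     name_a: str, name_b: str) -> float:
    return species[name_a].radius_nm + species[name_b].radius_nm
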