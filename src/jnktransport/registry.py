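"""Species catalogue for the scaffold--motor JNK transport network.

The model tracks 15 molecular species: the kinase JNK in its inactive (JNK)
and active (JNK*) forms, the upstream kinase MKK7, the phosphatase M3/6, the
scaffold JIP1, the kinesin motor KIF5, and every binary/ternary/quaternary
complex the binding reactions can form.  Each species is flagged by how it
moves:

* ``diffusive``  -- free proteins and motor-free complexes diffuse,
* ``advective``  -- cargo-loaded KIF5 complexes walk toward the periphery,
* ``immobile``   -- free KIF5 is autoinhibited (folded) and does not move.

Five molecular moieties (JNK core, MKK7, JIP1, KIF5, M3/6) are conserved by
every reaction; the integer composition matrix below is the basis for all
mass-conservation checks in the package.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

DIFFUSIVE = "diffusive"
ADVECTIVE = "advective"
IMMOBILE = "immobile"

#: Canonical species order, used for every concentration array in the package.
SPECIES: tuple[str, ...] = (
    "JNK",
    "JIP1",
    "MKK7",
    "JNK*",
    "M3/6",
    "JIP1-JNK",
    "JNK-MKK7",
    "JIP1-MKK7",
    "JIP1-JNK-MKK7",
    "JNK*-M3/6",
    "KIF5",
    "KIF5-JIP1",
    "KIF5-JIP1-JNK",
    "KIF5-JIP1-MKK7",
    "KIF5-JIP1-JNK-MKK7",
)

N_SPECIES = len(SPECIES)

#: Conserved moieties.  "JNK-core" counts JNK regardless of phosphorylation.
MOIETIES: tuple[str, ...] = ("JNK-core", "MKK7", "JIP1", "KIF5", "M3/6")

#: Moiety composition of each species (absent moieties are zero).
COMPOSITION: dict[str, dict[str, int]] = {
    "JNK": {"JNK-core": 1},
    "JIP1": {"JIP1": 1},
    "MKK7": {"MKK7": 1},
    "JNK*": {"JNK-core": 1},
    "M3/6": {"M3/6": 1},
    "JIP1-JNK": {"JIP1": 1, "JNK-core": 1},
    "JNK-MKK7": {"JNK-core": 1, "MKK7": 1},
    "JIP1-MKK7": {"JIP1": 1, "MKK7": 1},
    "JIP1-JNK-MKK7": {"JIP1": 1, "JNK-core": 1, "MKK7": 1},
    "JNK*-M3/6": {"JNK-core": 1, "M3/6": 1},
    "KIF5": {"KIF5": 1},
    "KIF5-JIP1": {"KIF5": 1, "JIP1": 1},
    "KIF5-JIP1-JNK": {"KIF5": 1, "JIP1": 1, "JNK-core": 1},
    "KIF5-JIP1-MKK7": {"KIF5": 1, "JIP1": 1, "MKK7": 1},
    "KIF5-JIP1-JNK-MKK7": {"KIF5": 1, "JIP1": 1, "JNK-core": 1, "MKK7": 1},
}

#: Diffusion coefficients in um^2/s for the diffusive species.  Heavier
#: complexes are slower (values for the two heaviest are taken as printed in
#: the source parameter table rather than recomputed from a mass rule).
DEFAULT_DIFFUSION: dict[str, float] = {
    "JNK": 10.0,
    "JIP1": 10.0,
    "MKK7": 10.0,
    "JNK*": 10.0,
    "M3/6": 10.0,
    "JIP1-JNK": 10.0,
    "JNK-MKK7": 7.07,
    "JIP1-MKK7": 10.0,
    "JIP1-JNK-MKK7": 5.77,
    "JNK*-M3/6": 10.0,
}

_MOBILITY: dict[str, str] = {name: DIFFUSIVE for name in DEFAULT_DIFFUSION}
_MOBILITY["KIF5"] = IMMOBILE
for _name in ("KIF5-JIP1", "KIF5-JIP1-JNK", "KIF5-JIP1-MKK7", "KIF5-JIP1-JNK-MKK7"):
    _MOBILITY[_name] = ADVECTIVE


def _build_moiety_matrix() -> np.ndarray:
    mat = np.zeros((len(MOIETIES), N_SPECIES), dtype=np.int64)
    for j, sp in enumerate(SPECIES):
        for moiety, count in COMPOSITION[sp].items():
            mat[MOIETIES.index(moiety), j] = count
    return mat


@dataclass(frozen=True)
class SpeciesRegistry:
    """Ordered species list with mobility flags and moiety stoichiometry."""

    names: tuple[str, ...] = SPECIES
    mobility: tuple[str, ...] = tuple(_MOBILITY[s] for s in SPECIES)
    diffusion_coeff: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_DIFFUSION)
    )
    moiety_names: tuple[str, ...] = MOIETIES
    moiety_matrix: np.ndarray = field(default_factory=_build_moiety_matrix)

    def index(self, name: str) -> int:
        try:
            return self.names.index(name)
        except ValueError:
            raise KeyError(f"unknown species {name!r}") from None

    def diffusion_array(self, diffusion: dict[str, float] | None = None) -> np.ndarray:
        """Per-species diffusion coefficients (0 for non-diffusive species)."""
        table = self.diffusion_coeff if diffusion is None else diffusion
        out = np.zeros(len(self.names))
        for i, (name, mob) in enumerate(zip(self.names, self.mobility)):
            if mob == DIFFUSIVE:
                if name not in table:
                    raise KeyError(f"missing diffusion coefficient for {name!r}")
                out[i] = float(table[name])
        return out

    def advective_mask(self) -> np.ndarray:
        return np.array([m == ADVECTIVE for m in self.mobility])

    def diffusive_mask(self) -> np.ndarray:
        return np.array([m == DIFFUSIVE for m in self.mobility])


def default_registry() -> SpeciesRegistry:
    return SpeciesRegistry()
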