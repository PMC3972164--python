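"""Mass-action kinetics of the JNK / JIP1 / KIF5 reaction network.

The network couples three processes:

1. phosphorylation of JNK by MKK7, in solution (kcat1 = 0.1/s) and on the
   JIP1 scaffold, free or motor-bound, where catalysis is four-fold faster
   (kcat = 0.4/s) -- the scaffold "unlocks" the kinase;
2. dephosphorylation of JNK* by the phosphatase M3/6 (kcat4 = 0.1/s);
3. assembly of transport cargo: JIP1 binds JNK and MKK7 (b1, b2) and the
   KIF5 motor (b5-b7); kinases can also load onto a motor-bound scaffold
   (b3, b4).

Catalysis on a scaffold releases the products (free JNK*, free MKK7 and the
bare scaffold); there is no product-rebinding shortcut.  The quaternary
complex KIF5-JIP1-JNK-MKK7 carries a single catalytic flux (K5): the two
reaction rows that form it share the same rate constant and the same
complex, so counting the flux twice would double motor-bound catalysis.
The ``double_motor_catalysis`` switch restores the two-flux reading
(kcat5 + kcat6) for sensitivity studies.

Units: concentrations in uM, time in s, lengths in um.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .registry import SPECIES, SpeciesRegistry, default_registry

__all__ = [
    "RateConstants",
    "default_constants",
    "rate_terms",
    "reaction_rhs",
    "moiety_totals",
    "stoichiometry_matrix",
    "FLUX_NAMES",
]


@dataclass(frozen=True)
class RateConstants:
    """Kinetic parameters of the 13 reactions.

    ``kf``/``kb``/``kcat`` (length 6) are the Michaelis-Menten-style
    association / dissociation / catalytic constants of the enzymatic
    reactions; ``b``/``u`` (length 7) are the binding / unbinding constants
    of the scaffold and motor assembly steps.  kf and b are in 1/(uM s),
    the rest in 1/s.
    """

    kf: np.ndarray
    kb: np.ndarray
    kcat: np.ndarray
    b: np.ndarray
    u: np.ndarray

    def __post_init__(self):
        for name, n in (("kf", 6), ("kb", 6), ("kcat", 6), ("b", 7), ("u", 7)):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != (n,):
                raise ValueError(f"{name} must have length {n}, got shape {arr.shape}")
            if np.any(~np.isfinite(arr)) or np.any(arr < 0):
                raise ValueError(f"{name} must be finite and nonnegative")
            object.__setattr__(self, name, arr)

    def __eq__(self, other):
        if not isinstance(other, RateConstants):
            return NotImplemented
        return all(
            np.array_equal(getattr(self, f), getattr(other, f))
            for f in ("kf", "kb", "kcat", "b", "u")
        )

    def as_dict(self) -> dict[str, list[float]]:
        return {f: getattr(self, f).tolist() for f in ("kf", "kb", "kcat", "b", "u")}

    @classmethod
    def from_dict(cls, d: dict) -> "RateConstants":
        return cls(**{f: np.asarray(d[f], dtype=float) for f in ("kf", "kb", "kcat", "b", "u")})


def default_constants() -> RateConstants:
    """The published parameter set (uM / s units)."""
    return RateConstants(
        kf=np.ones(6),
        kb=np.ones(6),
        kcat=np.array([0.1, 0.4, 0.4, 0.1, 0.4, 0.4]),
        b=np.array([0.1, 0.1, 0.5, 0.5, 0.5, 0.5, 0.5]),
        u=np.full(7, 0.1),
    )


# Reaction list: (flux name, reactants, products).  Binding fluxes are net
# (forward minus reverse); catalytic fluxes are irreversible.
_REACTIONS: tuple[tuple[str, dict[str, int], dict[str, int]], ...] = (
    ("A1", {"JNK": 1, "MKK7": 1}, {"JNK-MKK7": 1}),
    ("A2", {"JIP1-JNK": 1, "MKK7": 1}, {"JIP1-JNK-MKK7": 1}),
    ("A3", {"JIP1-MKK7": 1, "JNK": 1}, {"JIP1-JNK-MKK7": 1}),
    ("A4", {"JNK*": 1, "M3/6": 1}, {"JNK*-M3/6": 1}),
    ("A5", {"KIF5-JIP1-JNK": 1, "MKK7": 1}, {"KIF5-JIP1-JNK-MKK7": 1}),
    ("A6", {"KIF5-JIP1-MKK7": 1, "JNK": 1}, {"KIF5-JIP1-JNK-MKK7": 1}),
    ("K1", {"JNK-MKK7": 1}, {"JNK*": 1, "MKK7": 1}),
    ("K2", {"JIP1-JNK-MKK7": 1}, {"JIP1": 1, "JNK*": 1, "MKK7": 1}),
    ("K3", {"JIP1-JNK-MKK7": 1}, {"JIP1": 1, "JNK*": 1, "MKK7": 1}),
    ("K4", {"JNK*-M3/6": 1}, {"JNK": 1, "M3/6": 1}),
    ("K5", {"KIF5-JIP1-JNK-MKK7": 1}, {"KIF5-JIP1": 1, "JNK*": 1, "MKK7": 1}),
    ("B1", {"JNK": 1, "JIP1": 1}, {"JIP1-JNK": 1}),
    ("B2", {"MKK7": 1, "JIP1": 1}, {"JIP1-MKK7": 1}),
    ("B3", {"JNK": 1, "KIF5-JIP1": 1}, {"KIF5-JIP1-JNK": 1}),
    ("B4", {"MKK7": 1, "KIF5-JIP1": 1}, {"KIF5-JIP1-MKK7": 1}),
    ("B5", {"KIF5": 1, "JIP1": 1}, {"KIF5-JIP1": 1}),
    ("B6", {"KIF5": 1, "JIP1-JNK": 1}, {"KIF5-JIP1-JNK": 1}),
    ("B7", {"KIF5": 1, "JIP1-MKK7": 1}, {"KIF5-JIP1-MKK7": 1}),
)

FLUX_NAMES: tuple[str, ...] = tuple(name for name, _, _ in _REACTIONS)
_IDX = {name: i for i, name in enumerate(SPECIES)}


def stoichiometry_matrix() -> np.ndarray:
    """Species x flux stoichiometric matrix N, so that rhs = N @ flux."""
    mat = np.zeros((len(SPECIES), len(_REACTIONS)))
    for r, (_, reactants, products) in enumerate(_REACTIONS):
        for sp, count in reactants.items():
            mat[_IDX[sp], r] -= count
        for sp, count in products.items():
            mat[_IDX[sp], r] += count
    return mat


_STOICH = stoichiometry_matrix()


def _check_state(conc: np.ndarray, check: bool = True) -> np.ndarray:
    conc = np.asarray(conc, dtype=float)
    if conc.shape[0] != len(SPECIES):
        raise ValueError(f"state must have {len(SPECIES)} species on axis 0")
    if check and np.any(conc < 0):
        bad = [SPECIES[i] for i in np.unique(np.argwhere(conc < 0)[:, 0])]
        raise ValueError(f"negative concentrations for species: {bad}")
    return conc


def rate_terms(
    conc: np.ndarray,
    k: RateConstants,
    *,
    double_motor_catalysis: bool = False,
    check: bool = True,
) -> dict[str, np.ndarray | float]:
    """Named net reaction fluxes (uM/s) at one cell (or vectorized over cells).

    ``conc`` has species on axis 0; any trailing axes (e.g. mesh cells) are
    broadcast.  Keys are A1-A6 (enzyme-substrate association, net of the
    reverse), K1-K5 (catalysis), B1-B7 (scaffold/motor binding, net).
    ``check=False`` skips the nonnegativity validation (reference
    integrators may probe slightly negative trial states).
    """
    c = _check_state(conc, check)

    def g(name):  # concentration of one species
        return c[_IDX[name]]

    kq = k.kcat[4] + (k.kcat[5] if double_motor_catalysis else 0.0)
    terms: dict[str, np.ndarray | float] = {
        "A1": k.kf[0] * g("JNK") * g("MKK7") - k.kb[0] * g("JNK-MKK7"),
        "A2": k.kf[1] * g("JIP1-JNK") * g("MKK7") - k.kb[1] * g("JIP1-JNK-MKK7"),
        "A3": k.kf[2] * g("JIP1-MKK7") * g("JNK") - k.kb[2] * g("JIP1-JNK-MKK7"),
        "A4": k.kf[3] * g("JNK*") * g("M3/6") - k.kb[3] * g("JNK*-M3/6"),
        "A5": k.kf[4] * g("KIF5-JIP1-JNK") * g("MKK7") - k.kb[4] * g("KIF5-JIP1-JNK-MKK7"),
        "A6": k.kf[5] * g("KIF5-JIP1-MKK7") * g("JNK") - k.kb[5] * g("KIF5-JIP1-JNK-MKK7"),
        "K1": k.kcat[0] * g("JNK-MKK7"),
        "K2": k.kcat[1] * g("JIP1-JNK-MKK7"),
        "K3": k.kcat[2] * g("JIP1-JNK-MKK7"),
        "K4": k.kcat[3] * g("JNK*-M3/6"),
        "K5": kq * g("KIF5-JIP1-JNK-MKK7"),
        "B1": k.b[0] * g("JNK") * g("JIP1") - k.u[0] * g("JIP1-JNK"),
        "B2": k.b[1] * g("MKK7") * g("JIP1") - k.u[1] * g("JIP1-MKK7"),
        "B3": k.b[2] * g("KIF5-JIP1") * g("JNK") - k.u[2] * g("KIF5-JIP1-JNK"),
        "B4": k.b[3] * g("KIF5-JIP1") * g("MKK7") - k.u[3] * g("KIF5-JIP1-MKK7"),
        "B5": k.b[4] * g("JIP1") * g("KIF5") - k.u[4] * g("KIF5-JIP1"),
        "B6": k.b[5] * g("JIP1-JNK") * g("KIF5") - k.u[5] * g("KIF5-JIP1-JNK"),
        "B7": k.b[6] * g("JIP1-MKK7") * g("KIF5") - k.u[6] * g("KIF5-JIP1-MKK7"),
    }
    return terms


def reaction_rhs(
    conc: np.ndarray,
    k: RateConstants,
    *,
    double_motor_catalysis: bool = False,
    check: bool = True,
) -> np.ndarray:
    """Net production rate d[species]/dt (uM/s) for every species.

    Assembled as ``N @ flux`` from the stoichiometric matrix, which makes
    the five moiety conservation laws hold identically:
    ``moiety_matrix @ reaction_rhs(state) == 0`` for every admissible state.
    """
    terms = rate_terms(
        conc, k, double_motor_catalysis=double_motor_catalysis, check=check
    )
    flux = np.stack([np.asarray(terms[name], dtype=float) for name in FLUX_NAMES])
    return np.tensordot(_STOICH, flux, axes=(1, 0))


def moiety_totals(
    field: np.ndarray,
    dx: float,
    registry: SpeciesRegistry | None = None,
) -> np.ndarray:
    """Domain-integrated amount of each conserved moiety (uM um).

    ``field`` is a (species, cells) concentration array; the integral is the
    rectangle sum ``sum(conc) * dx`` per moiety.
    """
    reg = registry or default_registry()
    field = np.asarray(field, dtype=float)
    if field.ndim == 1:
        field = field[:, None]
    return (reg.moiety_matrix @ field).sum(axis=1) * float(dx)
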