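"""Reaction stoichiometry and standard-state catabolic reaction energetics.

Chemical species carry elemental composition, charge, phase and standard
formation energies (kJ/mol at 298.15 K); reactions are signed stoichiometric
maps over species names, with coefficients held as exact rationals so that
fractional stoichiometries like 12.25 or 3.755 never drift.  Standard
reaction energies are linear combinations of formation energies,

    dG0 = sum_i nu_i * dGf0_i        dH0 = sum_i nu_i * dHf0_i

with nu_i < 0 for reactants and nu_i > 0 for products.  The package bundles
a constants table covering the species appearing in anaerobic hexadecane and
benzoate degradation scenarios (acetogenic, hydrogenogenic, and
sulfate-coupled complete oxidation), including both the gas-phase and the
aqueous 1 M standard-state convention for molecular hydrogen.

Energy computations deliberately proceed on element-unbalanced reactions
(with a logged warning): published reaction tables occasionally omit a water
term, and reproducing a printed energy requires using the stoichiometry as
printed.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field, replace
from enum import Enum
from fractions import Fraction
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Union

logger = logging.getLogger(__name__)

#: Reference temperature for standard formation energies, K.
T_REF = 298.15

_FORMULA_RE = re.compile(r"([A-Z][a-z]?)(\d*)")


class Phase(str, Enum):
    AQUEOUS = "aqueous"
    LIQUID = "liquid"
    GAS = "gas"


class ReactionClass(str, Enum):
    HYDROGENOGENIC_OXIDATION = "hydrogenogenic_oxidation"
    ACETOGENIC_OXIDATION = "acetogenic_oxidation"
    COMPLETE_OXIDATION = "complete_oxidation"
    OTHER = "other"


class UnknownSpeciesError(KeyError):
    """A reaction references a species absent from the species table."""


class MissingConstantError(ValueError):
    """A species lacks the formation constant needed for the computation."""


def parse_formula(formula: str) -> dict[str, int]:
    """Parse a Hill-style formula string (e.g. ``C16H34``) into element counts."""
    counts: dict[str, int] = {}
    pos = 0
    for m in _FORMULA_RE.finditer(formula):
        if m.start() != pos:
            raise ValueError(f"unparseable formula {formula!r} at position {pos}")
        counts[m.group(1)] = counts.get(m.group(1), 0) + (int(m.group(2)) if m.group(2) else 1)
        pos = m.end()
    if pos != len(formula) or not counts:
        raise ValueError(f"unparseable formula: {formula!r}")
    return counts


@dataclass(frozen=True)
class SpeciesEntry:
    """A chemical species with composition, charge, phase and formation energies.

    ``dGf0``/``dHf0`` are kJ/mol at 298.15 K and may be ``None`` (unknown);
    a species with an unknown constant may appear in balance checks but not
    in energy computations.
    """

    name: str
    formula: Mapping[str, int]
    charge: int = 0
    phase: Phase = Phase.AQUEOUS
    dGf0: float | None = None
    dHf0: float | None = None
    provenance: str = ""

    def __post_init__(self) -> None:
        if not self.formula or any(c < 0 for c in self.formula.values()):
            raise ValueError(f"species {self.name!r}: formula counts must be >= 0 with at least one element")
        if all(c == 0 for c in self.formula.values()):
            raise ValueError(f"species {self.name!r}: empty formula")

    def constant(self, which: str) -> float:
        """Return ``dGf0`` or ``dHf0``, raising :class:`MissingConstantError` if absent."""
        value = getattr(self, which)
        if value is None:
            raise MissingConstantError(f"species {self.name!r} has no {which}")
        return float(value)


class SpeciesTable:
    """Name-indexed collection of :class:`SpeciesEntry` rows."""

    def __init__(self, entries: Iterable[SpeciesEntry]):
        self._entries: dict[str, SpeciesEntry] = {}
        for e in entries:
            if e.name in self._entries:
                raise ValueError(f"duplicate species {e.name!r}")
            self._entries[e.name] = e

    def __contains__(self, name: str) -> bool:
        return name in self._entries

    def __iter__(self):
        return iter(self._entries.values())

    def __len__(self) -> int:
        return len(self._entries)

    def get(self, name: str) -> SpeciesEntry:
        try:
            return self._entries[name]
        except KeyError:
            raise UnknownSpeciesError(f"unknown species {name!r}") from None

    def with_entry(self, entry: SpeciesEntry) -> "SpeciesTable":
        """Return a copy with ``entry`` added or replaced."""
        new = dict(self._entries)
        new[entry.name] = entry
        return SpeciesTable(new.values())

    def without_constant(self, name: str, which: str) -> "SpeciesTable":
        """Return a copy in which species ``name`` has ``which`` set to None."""
        return self.with_entry(replace(self.get(name), **{which: None}))

    @classmethod
    def from_tsv(cls, path: Union[str, Path]) -> "SpeciesTable":
        """Read a species constants TSV (columns name, formula, charge, phase,
        dGf0_kJ_mol, dHf0_kJ_mol, provenance; empty cell = unknown constant)."""
        entries = []
        with open(path) as fh:
            header = fh.readline().rstrip("\n").split("\t")
            idx = {col: i for i, col in enumerate(header)}
            for line in fh:
                if not line.strip():
                    continue
                row = line.rstrip("\n").split("\t")

                def cell(col: str, default: str = "") -> str:
                    i = idx.get(col)
                    return row[i] if i is not None and i < len(row) else default

                entries.append(
                    SpeciesEntry(
                        name=cell("name"),
                        formula=parse_formula(cell("formula")),
                        charge=int(cell("charge") or 0),
                        phase=Phase(cell("phase") or "aqueous"),
                        dGf0=float(cell("dGf0_kJ_mol")) if cell("dGf0_kJ_mol") else None,
                        dHf0=float(cell("dHf0_kJ_mol")) if cell("dHf0_kJ_mol") else None,
                        provenance=cell("provenance"),
                    )
                )
        return cls(entries)

    @classmethod
    def bundled(cls) -> "SpeciesTable":
        """The packaged formation-energy constants table."""
        with resources.as_file(resources.files("deepseep.data") / "formation_energies.tsv") as p:
            return cls.from_tsv(p)


CoefficientMap = Mapping[str, Fraction]


def _as_fraction(value) -> Fraction:
    # str round-trip keeps decimal literals like 12.25 exact even if a float
    # slipped in upstream
    if isinstance(value, float):
        value = repr(value)
    return Fraction(value)


@dataclass(frozen=True)
class Reaction:
    """A signed stoichiometric map over species names.

    Negative coefficients are reactants, positive are products.  Coefficients
    are exact :class:`~fractions.Fraction` values; pass decimal strings or
    floats with short decimal expansions and they are converted exactly.
    """

    id: str
    label: str
    coefficients: Mapping[str, Fraction]
    reaction_class: ReactionClass = ReactionClass.OTHER

    def __post_init__(self) -> None:
        coeffs = {name: _as_fraction(c) for name, c in self.coefficients.items()}
        if any(c == 0 for c in coeffs.values()):
            zeros = [n for n, c in coeffs.items() if c == 0]
            raise ValueError(f"reaction {self.id!r}: zero net coefficient for {zeros}")
        if not any(c < 0 for c in coeffs.values()) or not any(c > 0 for c in coeffs.values()):
            raise ValueError(f"reaction {self.id!r}: needs at least one reactant and one product")
        object.__setattr__(self, "coefficients", coeffs)
        object.__setattr__(self, "reaction_class", ReactionClass(self.reaction_class))

    def reversed(self) -> "Reaction":
        return Reaction(
            id=f"{self.id}_rev",
            label=f"reverse of {self.label}",
            coefficients={n: -c for n, c in self.coefficients.items()},
            reaction_class=self.reaction_class,
        )

    def scaled(self, k) -> "Reaction":
        k = _as_fraction(k)
        return Reaction(
            id=f"{self.id}_x{k}",
            label=self.label,
            coefficients={n: k * c for n, c in self.coefficients.items()},
            reaction_class=self.reaction_class,
        )

    @classmethod
    def from_string(
        cls,
        reaction_id: str,
        stoichiometry: str,
        label: str = "",
        reaction_class: ReactionClass | str = ReactionClass.OTHER,
    ) -> "Reaction":
        """Parse ``"species:coeff;species:coeff"`` with decimal-rational coefficients."""
        coeffs: dict[str, Fraction] = {}
        for part in stoichiometry.split(";"):
            part = part.strip()
            if not part:
                continue
            name, _, coeff = part.rpartition(":")
            if not name:
                raise ValueError(f"malformed stoichiometry term {part!r}")
            if name in coeffs:
                raise ValueError(f"species {name!r} listed twice in reaction {reaction_id!r}")
            coeffs[name] = Fraction(coeff)
        return cls(id=reaction_id, label=label or reaction_id, coefficients=coeffs,
                   reaction_class=ReactionClass(reaction_class))


def read_reactions_tsv(path: Union[str, Path]) -> list[Reaction]:
    """Read a reaction TSV (columns reaction_id, label, class, stoichiometry)."""
    reactions = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        idx = {col: i for i, col in enumerate(header)}
        for line in fh:
            if not line.strip():
                continue
            row = line.rstrip("\n").split("\t")
            reactions.append(
                Reaction.from_string(
                    reaction_id=row[idx["reaction_id"]],
                    stoichiometry=row[idx["stoichiometry"]],
                    label=row[idx["label"]],
                    reaction_class=row[idx["class"]],
                )
            )
    return reactions


def bundled_reactions() -> list[Reaction]:
    """The packaged deep-sea hexadecane/benzoate degradation scenarios."""
    with resources.as_file(resources.files("deepseep.data") / "reactions_deep_sea.tsv") as p:
        return read_reactions_tsv(p)


@dataclass(frozen=True)
class BalanceReport:
    """Element and charge residuals of a reaction (products minus reactants).

    ``residual(element) = sum_i nu_i * count_i(element)``, so a positive
    residual means the element appears in excess on the product side.
    """

    reaction_id: str
    element_residuals: Mapping[str, Fraction]
    charge_residual: Fraction

    @property
    def balanced(self) -> bool:
        return self.charge_residual == 0 and all(r == 0 for r in self.element_residuals.values())


def balance_note(report: "BalanceReport") -> str:
    """One-line human-readable summary of a balance report's residuals."""
    if report.balanced:
        return "balanced"
    def signed(r: Fraction) -> str:
        return f"+{r}" if r > 0 else str(r)

    parts = [f"{e}={signed(r)}" for e, r in sorted(report.element_residuals.items()) if r != 0]
    if report.charge_residual != 0:
        parts.append(f"charge={signed(report.charge_residual)}")
    return "unbalanced: " + ", ".join(str(p) for p in parts)


def check_balance(reaction: Reaction, db: SpeciesTable) -> BalanceReport:
    """Compute element/charge residuals of ``reaction`` against species in ``db``."""
    element_residuals: dict[str, Fraction] = {}
    charge = Fraction(0)
    for name, nu in reaction.coefficients.items():
        sp = db.get(name)
        for element, count in sp.formula.items():
            element_residuals[element] = element_residuals.get(element, Fraction(0)) + nu * count
        charge += nu * sp.charge
    return BalanceReport(reaction.id, element_residuals, charge)


def _energy_sum(coefficients: CoefficientMap, db: SpeciesTable, which: str) -> float:
    return float(sum(float(nu) * db.get(name).constant(which) for name, nu in coefficients.items()))


def standard_reaction_energy(
    reaction: Union[Reaction, CoefficientMap], db: SpeciesTable
) -> tuple[float, float]:
    """Standard reaction Gibbs energy and enthalpy (kJ) at 298.15 K.

    Accepts a :class:`Reaction` or a bare coefficient map (the latter allows
    evaluating linear combinations, including the empty net reaction, which
    returns ``(0.0, 0.0)``).  An element- or charge-unbalanced reaction is
    computed as given, with a warning, so that energies printed for
    slightly-misprinted published stoichiometries remain reproducible.
    """
    if isinstance(reaction, Reaction):
        coeffs: CoefficientMap = reaction.coefficients
        report = check_balance(reaction, db)
        if not report.balanced:
            logger.warning(
                "reaction %s is unbalanced (element residuals %s, charge %s); "
                "computing energy on the stoichiometry as given",
                reaction.id,
                {e: str(r) for e, r in report.element_residuals.items() if r != 0},
                report.charge_residual,
            )
    else:
        coeffs = {n: _as_fraction(c) for n, c in reaction.items()}
    dG0 = _energy_sum(coeffs, db, "dGf0")
    dH0 = _energy_sum(coeffs, db, "dHf0")
    return dG0, dH0


def derive_formation_energy(
    reaction: Union[Reaction, CoefficientMap],
    printed_value: float,
    db: SpeciesTable,
    unknown: str,
    which: str = "dGf0",
) -> float:
    """Back-derive the formation constant of one species from a printed reaction energy.

    Given a reaction in which exactly one participating species lacks the
    constant ``which`` (``"dGf0"`` or ``"dHf0"``), solve

        printed_value = sum_known nu_i * f_i + nu_unknown * f_unknown

    for ``f_unknown`` (kJ/mol).  Storing the result makes
    :func:`standard_reaction_energy` reproduce ``printed_value`` exactly.
    """
    coeffs = reaction.coefficients if isinstance(reaction, Reaction) else {
        n: _as_fraction(c) for n, c in reaction.items()
    }
    missing = [name for name in coeffs if getattr(db.get(name), which) is None]
    if missing != [unknown]:
        raise ValueError(
            f"need exactly one species lacking {which}, namely {unknown!r}; "
            f"species lacking it: {missing}"
        )
    known_sum = sum(float(nu) * db.get(name).constant(which) for name, nu in coeffs.items() if name != unknown)
    return (printed_value - known_sum) / float(coeffs[unknown])


def linear_combination(reactions: Iterable[Reaction], weights: Iterable) -> dict[str, Fraction]:
    """Net coefficient map of ``sum_j w_j * reaction_j`` (exact rational arithmetic).

    Species whose net coefficient cancels to zero are dropped; the result may
    be empty (the null reaction) and is suitable for
    :func:`standard_reaction_energy`.
    """
    net: dict[str, Fraction] = {}
    for rxn, w in zip(reactions, weights):
        w = _as_fraction(w)
        for name, nu in rxn.coefficients.items():
            net[name] = net.get(name, Fraction(0)) + w * nu
    return {n: c for n, c in net.items() if c != 0}
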