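"""Core metabolic-model data structures, file formats and unit conversions.

A :class:`MetabolicModel` is a minimal constraint-based model: metabolites,
reactions with signed stoichiometry and flux bounds, and one designated
growth reaction.  Models can be read from and written to either SBML
(level 3 + FBC, via cobrapy) or a small tabular TSV dialect that needs no
external files beyond this repository.

Units used throughout the package:

* fluxes — mmol·gDW⁻¹·h⁻¹
* masses — mg per gDW of media
* molecular weights — g·mol⁻¹  (so mg / (g·mol⁻¹) = mmol)
"""

from __future__ import annotations

import csv
import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Tuple

from scipy import sparse

__all__ = [
    "DEFAULT_BOUND",
    "Metabolite",
    "Reaction",
    "MetabolicModel",
    "MediaComposition",
    "MediaEntry",
    "CompoundRegistry",
    "ModelValidationError",
    "ModelFormatError",
    "mmol_from_mass",
    "stoichiometric_matrix",
    "read_model",
    "write_model",
    "read_media",
    "write_media",
]

#: Stand-in for "unbounded" flux; large but finite keeps LPs well-posed.
DEFAULT_BOUND = 1000.0


class ModelValidationError(ValueError):
    """A model, media composition or registry violates an invariant."""


class ModelFormatError(ValueError):
    """A model/media file could not be parsed in the declared dialect."""


@dataclass(frozen=True)
class Metabolite:
    """A chemical species in one compartment of a model.

    ``molecular_weight`` (g·mol⁻¹) is optional: it is only required for
    compounds that cross the envelope interface and therefore enter mass
    accounting.  Purely internal metabolites never need one.
    """

    id: str
    name: str = ""
    compartment: str = "c"
    molecular_weight: Optional[float] = None

    def __post_init__(self) -> None:
        if not self.id:
            raise ModelValidationError("metabolite id must be non-empty")
        if self.molecular_weight is not None and not self.molecular_weight > 0:
            raise ModelValidationError(
                f"metabolite {self.id!r}: molecular_weight must be > 0, "
                f"got {self.molecular_weight}"
            )


@dataclass
class Reaction:
    """A stoichiometric reaction with flux bounds.

    ``stoichiometry`` maps metabolite id to a signed coefficient
    (negative = consumed, positive = produced).  Bounds are in
    mmol·gDW⁻¹·h⁻¹.
    """

    id: str
    stoichiometry: Dict[str, float]
    lower_bound: float = -DEFAULT_BOUND
    upper_bound: float = DEFAULT_BOUND

    def __post_init__(self) -> None:
        if not self.id:
            raise ModelValidationError("reaction id must be non-empty")
        if not self.stoichiometry:
            raise ModelValidationError(f"reaction {self.id!r}: empty stoichiometry")
        for met, coef in self.stoichiometry.items():
            if not math.isfinite(coef) or coef == 0:
                raise ModelValidationError(
                    f"reaction {self.id!r}: coefficient for {met!r} must be "
                    f"finite and nonzero, got {coef}"
                )
        if not self.lower_bound <= self.upper_bound:
            raise ModelValidationError(
                f"reaction {self.id!r}: lower_bound {self.lower_bound} > "
                f"upper_bound {self.upper_bound}"
            )

    def copy(self) -> "Reaction":
        return Reaction(
            id=self.id,
            stoichiometry=dict(self.stoichiometry),
            lower_bound=self.lower_bound,
            upper_bound=self.upper_bound,
        )


@dataclass
class MetabolicModel:
    """Metabolites + ordered reactions + a designated growth reaction."""

    id: str
    metabolites: Dict[str, Metabolite]
    reactions: List[Reaction]
    growth_reaction_id: str
    #: metabolite ids the organism is known to be able to excrete; if empty,
    #: dead-end products (produced but never consumed) are used instead.
    excretable: frozenset = frozenset()

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        seen = set()
        for rxn in self.reactions:
            if rxn.id in seen:
                raise ModelValidationError(f"duplicate reaction id {rxn.id!r}")
            seen.add(rxn.id)
            for met in rxn.stoichiometry:
                if met not in self.metabolites:
                    raise ModelValidationError(
                        f"reaction {rxn.id!r} references unknown metabolite {met!r}"
                    )
        if self.growth_reaction_id not in seen:
            raise ModelValidationError(
                f"growth reaction {self.growth_reaction_id!r} not in model"
            )

    @property
    def reaction_ids(self) -> List[str]:
        return [r.id for r in self.reactions]

    def reaction(self, rxn_id: str) -> Reaction:
        for r in self.reactions:
            if r.id == rxn_id:
                return r
        raise KeyError(rxn_id)

    def copy(self) -> "MetabolicModel":
        return MetabolicModel(
            id=self.id,
            metabolites=dict(self.metabolites),
            reactions=[r.copy() for r in self.reactions],
            growth_reaction_id=self.growth_reaction_id,
            excretable=self.excretable,
        )

    def excretable_metabolites(self) -> List[str]:
        """Metabolites allowed a secretion path to Waste.

        Uses the explicitly declared set when provided, otherwise falls back
        to dead-end products: metabolites produced by some reaction but
        consumed by none (they must drain somewhere for steady state).
        """
        if self.excretable:
            return sorted(self.excretable)
        produced, consumed = set(), set()
        for rxn in self.reactions:
            for met, coef in rxn.stoichiometry.items():
                lo, hi = rxn.lower_bound, rxn.upper_bound
                # a reversible reaction can both produce and consume
                if (coef > 0 and hi > 0) or (coef < 0 and lo < 0):
                    produced.add(met)
                if (coef < 0 and hi > 0) or (coef > 0 and lo < 0):
                    consumed.add(met)
        return sorted(produced - consumed)


@dataclass(frozen=True)
class MediaEntry:
    compound_id: str
    mass_mg: float  # mg per gDW of media
    molecular_weight: float  # g·mol⁻¹
    transferable: bool = True

    def __post_init__(self) -> None:
        if self.mass_mg < 0:
            raise ModelValidationError(
                f"media compound {self.compound_id!r}: negative mass"
            )
        if not self.molecular_weight > 0:
            raise ModelValidationError(
                f"media compound {self.compound_id!r}: molecular weight must be > 0"
            )

    @property
    def mmol(self) -> float:
        return mmol_from_mass(self.mass_mg, self.molecular_weight)


@dataclass
class MediaComposition:
    """Feedstock composition, dosed per 1 gDW (= 1000 mg) of media.

    A composition may be partial (total < 1000 mg); the unaccounted mass is
    treated as inert and never enters the models.
    """

    entries: List[MediaEntry] = field(default_factory=list)

    MAX_TOTAL_MG = 1000.0

    def __post_init__(self) -> None:
        ids = [e.compound_id for e in self.entries]
        if len(ids) != len(set(ids)):
            raise ModelValidationError("duplicate compound in media composition")
        if self.total_mass_mg > self.MAX_TOTAL_MG * (1 + 1e-9):
            raise ModelValidationError(
                f"media mass {self.total_mass_mg:.3f} mg exceeds "
                f"{self.MAX_TOTAL_MG:.0f} mg per gDW"
            )

    @property
    def total_mass_mg(self) -> float:
        return sum(e.mass_mg for e in self.entries)

    @property
    def compound_ids(self) -> List[str]:
        return [e.compound_id for e in self.entries]

    def entry(self, compound_id: str) -> MediaEntry:
        for e in self.entries:
            if e.compound_id == compound_id:
                return e
        raise KeyError(compound_id)

    def without(self, compound_id: str) -> "MediaComposition":
        """Composition with one compound's mass nullified (entry kept at 0)."""
        return MediaComposition(
            [
                MediaEntry(e.compound_id, 0.0, e.molecular_weight, e.transferable)
                if e.compound_id == compound_id
                else e
                for e in self.entries
            ]
        )

    def with_added(self, compound_id: str, delta_mg: float) -> "MediaComposition":
        """Composition with ``delta_mg`` added to one compound (no renormalization)."""
        out, found = [], False
        for e in self.entries:
            if e.compound_id == compound_id:
                out.append(
                    MediaEntry(
                        e.compound_id,
                        e.mass_mg + delta_mg,
                        e.molecular_weight,
                        e.transferable,
                    )
                )
                found = True
            else:
                out.append(e)
        if not found:
            raise KeyError(compound_id)
        comp = MediaComposition.__new__(MediaComposition)
        comp.entries = out  # bypass the <=1000 mg check: gradient probes may exceed it
        return comp


class CompoundRegistry:
    """Canonical compound id → per-model metabolite id synonym map.

    One model metabolite per canonical compound per model.  Compounds a
    model cannot take up are simply absent (or mapped to ``"unmapped"``).
    """

    UNMAPPED = "unmapped"

    def __init__(self, mapping: Optional[Dict[str, Dict[str, str]]] = None):
        # mapping: canonical_id -> {model_id -> model_metabolite_id}
        self._map: Dict[str, Dict[str, str]] = {}
        if mapping:
            for canon, per_model in mapping.items():
                for model_id, met_id in per_model.items():
                    self.add(canon, model_id, met_id)

    def add(self, canonical_id: str, model_id: str, model_metabolite_id: str) -> None:
        per_model = self._map.setdefault(canonical_id, {})
        existing = per_model.get(model_id)
        if existing is not None and existing != model_metabolite_id:
            raise ModelValidationError(
                f"registry: {canonical_id!r} already mapped to {existing!r} "
                f"for model {model_id!r}"
            )
        per_model[model_id] = model_metabolite_id

    def resolve(self, canonical_id: str, model_id: str) -> Optional[str]:
        """Model metabolite id for a canonical compound, or None if unmapped."""
        met = self._map.get(canonical_id, {}).get(model_id)
        if met is None or met == self.UNMAPPED:
            return None
        return met

    def canonical_of(self, model_id: str, model_metabolite_id: str) -> Optional[str]:
        for canon, per_model in self._map.items():
            if per_model.get(model_id) == model_metabolite_id:
                return canon
        return None

    def canonical_ids(self) -> List[str]:
        return sorted(self._map)

    @classmethod
    def from_csv(cls, path: str | Path) -> "CompoundRegistry":
        reg = cls()
        with open(path, newline="") as fh:
            for row in csv.DictReader(fh):
                reg.add(
                    row["canonical_id"].strip(),
                    row["model_id"].strip(),
                    row["model_metabolite_id"].strip(),
                )
        return reg

    def to_csv(self, path: str | Path) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["canonical_id", "model_id", "model_metabolite_id"])
            for canon in sorted(self._map):
                for model_id in sorted(self._map[canon]):
                    w.writerow([canon, model_id, self._map[canon][model_id]])


# ---------------------------------------------------------------------------
# unit conversion


def mmol_from_mass(mass_mg: float, molecular_weight: float) -> float:
    """Convert a mass (mg) to an amount (mmol) via amount = weight / MW.

    With mass in mg and molecular weight in g·mol⁻¹ the result is in mmol,
    so a mass *rate* in mg·gDW⁻¹·h⁻¹ converts to mmol·gDW⁻¹·h⁻¹.
    """
    if not molecular_weight > 0:
        raise ValueError(f"molecular weight must be > 0, got {molecular_weight}")
    if mass_mg < 0:
        raise ValueError(f"mass must be >= 0, got {mass_mg}")
    return mass_mg / molecular_weight


# ---------------------------------------------------------------------------
# stoichiometric matrix


def stoichiometric_matrix(model: MetabolicModel) -> Tuple[sparse.csc_matrix, List[str]]:
    """Sparse metabolites × reactions coefficient matrix.

    Returns ``(S, row_ids)`` where ``row_ids`` lists the metabolite id of
    each row (only metabolites referenced by at least one reaction get a
    row).  Column order follows ``model.reactions``.
    """
    referenced: List[str] = []
    seen = set()
    for rxn in model.reactions:
        for met in rxn.stoichiometry:
            if met not in seen:
                seen.add(met)
                referenced.append(met)
    row_of = {m: i for i, m in enumerate(referenced)}
    data, rows, cols = [], [], []
    for j, rxn in enumerate(model.reactions):
        for met, coef in rxn.stoichiometry.items():
            rows.append(row_of[met])
            cols.append(j)
            data.append(coef)
    S = sparse.csc_matrix(
        (data, (rows, cols)), shape=(len(referenced), len(model.reactions))
    )
    return S, referenced


# ---------------------------------------------------------------------------
# tabular dialect
#
#   #growth=<reaction_id>
#   reaction_id <TAB> equation <TAB> lb <TAB> ub
#
# equation grammar: "1 glc -> 2 etoh + 2 co2"; "->" only (irreversibility is
# expressed through bounds); a side may be empty ("1 bmA ->" is a sink).

_TERM_RE = re.compile(r"^\s*(?:(\d+(?:\.\d+)?(?:/\d+)?)\s+)?(\S+)\s*$")


def _parse_side(side: str, line_no: int) -> Dict[str, float]:
    out: Dict[str, float] = {}
    side = side.strip()
    if not side:
        return out
    for term in side.split("+"):
        m = _TERM_RE.match(term)
        if not m:
            raise ModelFormatError(f"line {line_no}: cannot parse term {term!r}")
        coef_s, met = m.group(1), m.group(2)
        if coef_s is None:
            coef = 1.0
        elif "/" in coef_s:
            num, den = coef_s.split("/")
            coef = float(num) / float(den)
        else:
            coef = float(coef_s)
        out[met] = out.get(met, 0.0) + coef
    return out


def _parse_equation(eq: str, line_no: int) -> Dict[str, float]:
    if "->" not in eq:
        raise ModelFormatError(f"line {line_no}: equation {eq!r} lacks '->'")
    lhs, rhs = eq.split("->", 1)
    stoich: Dict[str, float] = {}
    for met, coef in _parse_side(lhs, line_no).items():
        stoich[met] = stoich.get(met, 0.0) - coef
    for met, coef in _parse_side(rhs, line_no).items():
        stoich[met] = stoich.get(met, 0.0) + coef
    stoich = {m: c for m, c in stoich.items() if c != 0}
    if not stoich:
        raise ModelFormatError(f"line {line_no}: equation {eq!r} cancels out")
    return stoich


def _read_tabular(path: Path) -> MetabolicModel:
    growth_id: Optional[str] = None
    excretable: set = set()
    reactions: List[Reaction] = []
    mets: Dict[str, Metabolite] = {}
    with open(path) as fh:
        for line_no, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith("#"):
                directive = line[1:].strip()
                if directive.startswith("growth="):
                    growth_id = directive.split("=", 1)[1].strip()
                elif directive.startswith("excretable="):
                    excretable.update(
                        m.strip()
                        for m in directive.split("=", 1)[1].split(",")
                        if m.strip()
                    )
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ModelFormatError(
                    f"{path}: line {line_no}: expected "
                    "reaction_id<TAB>equation[<TAB>lb<TAB>ub]"
                )
            rxn_id, eq = parts[0].strip(), parts[1]
            try:
                lb = float(parts[2]) if len(parts) > 2 and parts[2].strip() else -DEFAULT_BOUND
                ub = float(parts[3]) if len(parts) > 3 and parts[3].strip() else DEFAULT_BOUND
            except ValueError as exc:
                raise ModelFormatError(f"{path}: line {line_no}: bad bound: {exc}")
            stoich = _parse_equation(eq, line_no)
            for met in stoich:
                mets.setdefault(met, Metabolite(id=met, name=met))
            reactions.append(Reaction(rxn_id, stoich, lb, ub))
    if growth_id is None:
        raise ModelValidationError(f"{path}: missing '#growth=<reaction_id>' header")
    return MetabolicModel(
        id=path.stem,
        metabolites=mets,
        reactions=reactions,
        growth_reaction_id=growth_id,
        excretable=frozenset(excretable),
    )


def _format_equation(stoich: Dict[str, float]) -> str:
    def side(items: Iterable[Tuple[str, float]]) -> str:
        return " + ".join(f"{_fmt_coef(abs(c))} {m}" for m, c in items)

    lhs = [(m, c) for m, c in stoich.items() if c < 0]
    rhs = [(m, c) for m, c in stoich.items() if c > 0]
    return f"{side(lhs)} -> {side(rhs)}"


def _fmt_coef(c: float) -> str:
    return format(c, ".17g") if abs(c - round(c)) > 1e-12 else str(int(round(c)))


def _write_tabular(model: MetabolicModel, path: Path) -> None:
    with open(path, "w") as fh:
        fh.write(f"#growth={model.growth_reaction_id}\n")
        if model.excretable:
            fh.write("#excretable=" + ",".join(sorted(model.excretable)) + "\n")
        for rxn in model.reactions:
            fh.write(
                f"{rxn.id}\t{_format_equation(rxn.stoichiometry)}"
                f"\t{rxn.lower_bound:.17g}\t{rxn.upper_bound:.17g}\n"
            )


# ---------------------------------------------------------------------------
# SBML via cobrapy (kept behind lazy imports; SBML is optional at runtime)


def _read_sbml(path: Path) -> MetabolicModel:
    import cobra.io

    try:
        cb = cobra.io.read_sbml_model(str(path))
    except Exception as exc:  # cobra raises various parser errors
        raise ModelFormatError(f"{path}: SBML parse failed: {exc}") from exc
    mets: Dict[str, Metabolite] = {}
    for m in cb.metabolites:
        mw = None
        try:
            fw = m.formula_weight
            if fw:
                mw = float(fw)
        except Exception:
            mw = None
        mets[m.id] = Metabolite(
            id=m.id, name=m.name or m.id, compartment=m.compartment or "c",
            molecular_weight=mw,
        )
    reactions = []
    for r in cb.reactions:
        stoich = {m.id: float(c) for m, c in r.metabolites.items()}
        lb = r.lower_bound if r.lower_bound is not None else -DEFAULT_BOUND
        ub = r.upper_bound if r.upper_bound is not None else DEFAULT_BOUND
        reactions.append(Reaction(r.id, stoich, max(lb, -DEFAULT_BOUND), min(ub, DEFAULT_BOUND)))
    growth = None
    try:
        expr = cb.objective.expression
        for r in cb.reactions:
            if expr.has(r.forward_variable) and expr.coeff(r.forward_variable) != 0:
                growth = r.id
                break
    except Exception:
        growth = None
    if growth is None:
        for r in cb.reactions:
            if getattr(r, "objective_coefficient", 0):
                growth = r.id
                break
    if growth is None:
        raise ModelValidationError(f"{path}: no objective (growth) reaction in SBML")
    excretable = frozenset(
        m.id for r in cb.exchanges for m in r.metabolites
    )
    return MetabolicModel(
        id=cb.id or path.stem,
        metabolites=mets,
        reactions=reactions,
        growth_reaction_id=growth,
        excretable=excretable,
    )


def _write_sbml(model: MetabolicModel, path: Path) -> None:
    import cobra
    import cobra.io

    cb = cobra.Model(model.id)
    cb.add_metabolites(
        [
            cobra.Metabolite(m.id, name=m.name, compartment=m.compartment or "c")
            for m in model.metabolites.values()
        ]
    )
    for rxn in model.reactions:
        cr = cobra.Reaction(rxn.id, lower_bound=rxn.lower_bound, upper_bound=rxn.upper_bound)
        cb.add_reactions([cr])
        cr.add_metabolites(
            {cb.metabolites.get_by_id(m): c for m, c in rxn.stoichiometry.items()}
        )
    cb.objective = model.growth_reaction_id
    cobra.io.write_sbml_model(cb, str(path))


def read_model(path: str | Path, fmt: str = "tabular") -> MetabolicModel:
    """Read a model from disk.  ``fmt`` is ``"tabular"`` or ``"sbml"``."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if fmt == "tabular":
        return _read_tabular(path)
    if fmt == "sbml":
        return _read_sbml(path)
    raise ValueError(f"unknown model format {fmt!r}")


def write_model(model: MetabolicModel, path: str | Path, fmt: str = "tabular") -> None:
    path = Path(path)
    if fmt == "tabular":
        _write_tabular(model, path)
    elif fmt == "sbml":
        _write_sbml(model, path)
    else:
        raise ValueError(f"unknown model format {fmt!r}")


# ---------------------------------------------------------------------------
# media CSV


def read_media(path: str | Path) -> MediaComposition:
    """Read a media CSV: compound_id, mass_mg_per_gDW, molecular_weight_g_per_mol, transferable."""
    entries = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            try:
                entries.append(
                    MediaEntry(
                        compound_id=row["compound_id"].strip(),
                        mass_mg=float(row["mass_mg_per_gDW"]),
                        molecular_weight=float(row["molecular_weight_g_per_mol"]),
                        transferable=row.get("transferable", "1").strip() in ("1", "true", "True"),
                    )
                )
            except (KeyError, ValueError) as exc:
                raise ModelFormatError(f"{path}: bad media row {row!r}: {exc}") from exc
    return MediaComposition(entries)


def write_media(media: MediaComposition, path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(
            ["compound_id", "mass_mg_per_gDW", "molecular_weight_g_per_mol", "transferable"]
        )
        for e in media.entries:
            w.writerow(
                [e.compound_id, f"{e.mass_mg:g}", f"{e.molecular_weight:g}",
                 1 if e.transferable else 0]
            )
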