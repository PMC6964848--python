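"""Five-chamber envelope around a metabolic model.

The wrapped system partitions every metabolite into one of five chambers —
Media, Internal, Growth, Product, Waste — connected only by generated,
unidirectional transporter reactions:

* ``feed``        Outside → Media       (fixed to the media composition)
* ``uptake``      Media → Internal      (bounded by the fed amount)
* ``passthrough`` Media → Waste         (absorbs non-digested residuals)
* ``product``     Internal → Product    (exports only the target)
* ``secrete``     Internal → Waste      (excretable by-products)
* ``drain``       Growth/Product/Waste pool → Outside

No reaction connects the Internal chamber directly to the outside, so all
inputs and outputs of the system pass through the envelope.  Media is dosed
on a 1 gDW·gDW⁻¹·h⁻¹ basis: each feed flux is fixed to the molar equivalent
of the compound's mass fraction, so the mass-weighted feed total equals the
composition total (≤ 1000 mg·h⁻¹).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional

from .model_core import (
    DEFAULT_BOUND,
    CompoundRegistry,
    MediaComposition,
    MetabolicModel,
    Metabolite,
    ModelValidationError,
    Reaction,
    mmol_from_mass,
)

__all__ = [
    "Chamber",
    "OxygenPolicy",
    "TransporterRole",
    "OrganismModule",
    "EnvelopeError",
    "OXYGEN_CANONICAL_ID",
    "build_module",
    "apply_oxygen",
]

#: canonical compound id under which the registry may map molecular oxygen
OXYGEN_CANONICAL_ID = "o2"


class EnvelopeError(ValueError):
    """Module construction failed (unmappable target, missing weight, ...)."""


class Chamber(enum.Enum):
    MEDIA = "Media"
    INTERNAL = "Internal"
    GROWTH = "Growth"
    PRODUCT = "Product"
    WASTE = "Waste"


class TransporterRole(enum.Enum):
    FEED = "feed"
    UPTAKE = "uptake"
    GROWTH = "growth"
    PRODUCT = "product"
    SECRETE = "secrete"
    PASSTHROUGH = "passthrough"
    DRAIN = "drain"


@dataclass(frozen=True)
class OxygenPolicy:
    """Oxygen feed allowance: anaerobic, bounded(max mmol·gDW⁻¹·h⁻¹) or open."""

    kind: str  # "anaerobic" | "bounded" | "open"
    max_influx: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in ("anaerobic", "bounded", "open"):
            raise ValueError(f"unknown oxygen policy {self.kind!r}")
        if self.max_influx < 0:
            raise ValueError("oxygen influx bound must be >= 0")

    @classmethod
    def anaerobic(cls) -> "OxygenPolicy":
        return cls("anaerobic", 0.0)

    @classmethod
    def bounded(cls, max_influx: float) -> "OxygenPolicy":
        return cls("bounded", max_influx)

    @classmethod
    def open(cls) -> "OxygenPolicy":
        return cls("open", DEFAULT_BOUND)

    @property
    def upper_bound(self) -> float:
        if self.kind == "anaerobic":
            return 0.0
        if self.kind == "bounded":
            return self.max_influx
        return DEFAULT_BOUND


@dataclass(frozen=True)
class Transporter:
    reaction_id: str
    role: TransporterRole
    compound_id: Optional[str] = None  # canonical id for envelope-interface compounds


@dataclass
class OrganismModule:
    """An envelope-wrapped organism model, ready for the LP engine.

    ``network`` is the combined model (base reactions + transporters +
    pool drains); ``chamber_of`` assigns every metabolite of the network to
    exactly one chamber.
    """

    network: MetabolicModel
    base_model_id: str
    chamber_of: Dict[str, Chamber]
    transporters: List[Transporter]
    media: MediaComposition
    target_compound: str
    target_reaction_id: str
    oxygen_policy: OxygenPolicy
    registry: CompoundRegistry
    module_index: int = 0
    #: fixed feed flux (mmol·h⁻¹) per media compound
    feed_mmol: Dict[str, float] = field(default_factory=dict)

    @property
    def growth_reaction_id(self) -> str:
        return self.network.growth_reaction_id

    def transporter_id(self, role: TransporterRole, compound_id: str) -> str:
        for t in self.transporters:
            if t.role is role and t.compound_id == compound_id:
                return t.reaction_id
        raise KeyError(f"no {role.value} transporter for {compound_id!r}")

    def has_transporter(self, role: TransporterRole, compound_id: str) -> bool:
        return any(
            t.role is role and t.compound_id == compound_id for t in self.transporters
        )

    def transporters_with_role(self, role: TransporterRole) -> List[Transporter]:
        return [t for t in self.transporters if t.role is role]

    def copy(self) -> "OrganismModule":
        return OrganismModule(
            network=self.network.copy(),
            base_model_id=self.base_model_id,
            chamber_of=dict(self.chamber_of),
            transporters=list(self.transporters),
            media=self.media,
            target_compound=self.target_compound,
            target_reaction_id=self.target_reaction_id,
            oxygen_policy=self.oxygen_policy,
            registry=self.registry,
            module_index=self.module_index,
            feed_mmol=dict(self.feed_mmol),
        )

    # -- invariants ---------------------------------------------------------

    def validate(self) -> None:
        """Check envelope invariants beyond basic model validity."""
        self.network.validate()
        for met in self.network.metabolites:
            if met not in self.chamber_of:
                raise ModelValidationError(f"metabolite {met!r} has no chamber")
        transporter_ids = {t.reaction_id for t in self.transporters}
        base_growth = self.network.growth_reaction_id
        for rxn in self.network.reactions:
            chambers = {self.chamber_of[m] for m in rxn.stoichiometry}
            is_boundary = self._is_boundary(rxn)
            if rxn.id in transporter_ids:
                if rxn.lower_bound < 0:
                    raise ModelValidationError(
                        f"transporter {rxn.id!r} must be unidirectional"
                    )
            elif rxn.id != base_growth:
                # base reactions live wholly inside the Internal chamber and
                # must not touch the outside
                if chambers != {Chamber.INTERNAL}:
                    raise ModelValidationError(
                        f"base reaction {rxn.id!r} crosses chambers {chambers}"
                    )
                if is_boundary:
                    raise ModelValidationError(
                        f"base reaction {rxn.id!r} connects Internal to Outside"
                    )
            if Chamber.INTERNAL in chambers and is_boundary:
                raise ModelValidationError(
                    f"reaction {rxn.id!r} links Internal directly to Outside"
                )

    @staticmethod
    def _is_boundary(rxn: Reaction) -> bool:
        signs = {1 if c > 0 else -1 for c in rxn.stoichiometry.values()}
        return len(signs) < 2  # only consumes or only produces


def _tid(role: TransporterRole, compound: str, index: int) -> str:
    return f"{role.value}__{compound}__{index}"


def _media_met(compound: str) -> str:
    return f"media__{compound}"


GROWTH_POOL = "pool__growth"
PRODUCT_POOL = "pool__product"
WASTE_POOL = "pool__waste"


def build_module(
    model: MetabolicModel,
    media: MediaComposition,
    target: str,
    registry: CompoundRegistry,
    oxygen_policy: OxygenPolicy,
    module_index: int = 0,
) -> OrganismModule:
    """Wrap ``model`` in the five-chamber envelope for ``media`` and ``target``.

    Raises :class:`EnvelopeError` if the target cannot be mapped to (or
    produced by) the model, or a media compound lacks a molecular weight.
    """
    if not media.entries:
        raise EnvelopeError("media composition is empty")

    net = model.copy()
    net.id = f"{model.id}__module{module_index}"
    # close the base model: its own boundary (exchange/sink) reactions are
    # dropped and replaced by envelope transporters, so the Internal chamber
    # has no direct route to the outside
    net.reactions = [
        r
        for r in net.reactions
        if r.id == net.growth_reaction_id or not OrganismModule._is_boundary(r)
    ]
    chamber_of: Dict[str, Chamber] = {
        m: Chamber.INTERNAL for m in net.metabolites
    }
    transporters: List[Transporter] = []
    feed_mmol: Dict[str, float] = {}

    def add_met(met_id: str, chamber: Chamber, mw: Optional[float] = None) -> None:
        if met_id not in net.metabolites:
            net.metabolites[met_id] = Metabolite(
                id=met_id, name=met_id, compartment=chamber.value.lower(),
                molecular_weight=mw,
            )
        chamber_of[met_id] = chamber

    def add_rxn(rxn: Reaction, role: TransporterRole, compound: Optional[str]) -> None:
        net.reactions.append(rxn)
        transporters.append(Transporter(rxn.id, role, compound))

    add_met(GROWTH_POOL, Chamber.GROWTH)
    add_met(PRODUCT_POOL, Chamber.PRODUCT)
    add_met(WASTE_POOL, Chamber.WASTE)

    # growth reaction becomes the Internal -> Growth transporter: it gains
    # the growth pool as an extra product so growth mass leaves the Internal
    # chamber through a single accounted route
    growth_rxn = net.reaction(net.growth_reaction_id)
    growth_rxn.stoichiometry[GROWTH_POOL] = (
        growth_rxn.stoichiometry.get(GROWTH_POOL, 0.0) + 1.0
    )
    if growth_rxn.lower_bound < 0:
        growth_rxn.lower_bound = 0.0

    # --- media chamber -----------------------------------------------------
    for entry in media.entries:
        c = entry.compound_id
        add_met(_media_met(c), Chamber.MEDIA, entry.molecular_weight)
        fed = mmol_from_mass(entry.mass_mg, entry.molecular_weight)
        feed_mmol[c] = fed
        add_rxn(
            Reaction(
                _tid(TransporterRole.FEED, c, module_index),
                {_media_met(c): 1.0},
                lower_bound=fed,
                upper_bound=fed,
            ),
            TransporterRole.FEED,
            c,
        )
        internal = registry.resolve(c, model.id)
        if internal is not None:
            if internal not in model.metabolites:
                raise EnvelopeError(
                    f"registry maps {c!r} to unknown metabolite {internal!r} "
                    f"in model {model.id!r}"
                )
            add_rxn(
                Reaction(
                    _tid(TransporterRole.UPTAKE, c, module_index),
                    {_media_met(c): -1.0, internal: 1.0},
                    lower_bound=0.0,
                    upper_bound=fed,
                ),
                TransporterRole.UPTAKE,
                c,
            )
        # every media compound can pass through to Waste (residual route)
        add_rxn(
            Reaction(
                _tid(TransporterRole.PASSTHROUGH, c, module_index),
                {_media_met(c): -1.0, WASTE_POOL: 1.0},
                lower_bound=0.0,
                upper_bound=DEFAULT_BOUND,
            ),
            TransporterRole.PASSTHROUGH,
            c,
        )

    # --- oxygen feed (only when the registry maps it for this model) -------
    o2_internal = registry.resolve(OXYGEN_CANONICAL_ID, model.id)
    if o2_internal is not None and OXYGEN_CANONICAL_ID not in feed_mmol:
        add_met(_media_met(OXYGEN_CANONICAL_ID), Chamber.MEDIA, 32.0)
        add_rxn(
            Reaction(
                _tid(TransporterRole.FEED, OXYGEN_CANONICAL_ID, module_index),
                {_media_met(OXYGEN_CANONICAL_ID): 1.0},
                lower_bound=0.0,
                upper_bound=oxygen_policy.upper_bound,
            ),
            TransporterRole.FEED,
            OXYGEN_CANONICAL_ID,
        )
        add_rxn(
            Reaction(
                _tid(TransporterRole.UPTAKE, OXYGEN_CANONICAL_ID, module_index),
                {_media_met(OXYGEN_CANONICAL_ID): -1.0, o2_internal: 1.0},
                lower_bound=0.0,
                upper_bound=DEFAULT_BOUND,
            ),
            TransporterRole.UPTAKE,
            OXYGEN_CANONICAL_ID,
        )
        add_rxn(
            Reaction(
                _tid(TransporterRole.PASSTHROUGH, OXYGEN_CANONICAL_ID, module_index),
                {_media_met(OXYGEN_CANONICAL_ID): -1.0, WASTE_POOL: 1.0},
                lower_bound=0.0,
                upper_bound=DEFAULT_BOUND,
            ),
            TransporterRole.PASSTHROUGH,
            OXYGEN_CANONICAL_ID,
        )

    # --- product transporter ------------------------------------------------
    target_internal = registry.resolve(target, model.id)
    target_rxn_id = None
    if target_internal is not None and target_internal in model.metabolites:
        target_rxn_id = _tid(TransporterRole.PRODUCT, target, module_index)
        add_rxn(
            Reaction(
                target_rxn_id,
                {target_internal: -1.0, PRODUCT_POOL: 1.0},
                lower_bound=0.0,
                upper_bound=DEFAULT_BOUND,
            ),
            TransporterRole.PRODUCT,
            target,
        )
    if target_rxn_id is None:
        raise EnvelopeError(
            f"target {target!r} is not mapped to a metabolite of model "
            f"{model.id!r}; cannot create a product transporter"
        )

    # --- secretion routes ---------------------------------------------------
    for met in model.excretable_metabolites():
        add_rxn(
            Reaction(
                _tid(TransporterRole.SECRETE, met, module_index),
                {met: -1.0, WASTE_POOL: 1.0},
                lower_bound=0.0,
                upper_bound=DEFAULT_BOUND,
            ),
            TransporterRole.SECRETE,
            registry.canonical_of(model.id, met) or met,
        )

    # --- pool drains --------------------------------------------------------
    for pool, name in ((GROWTH_POOL, "growth"), (PRODUCT_POOL, "product"), (WASTE_POOL, "waste")):
        add_rxn(
            Reaction(
                _tid(TransporterRole.DRAIN, name, module_index),
                {pool: -1.0},
                lower_bound=0.0,
                upper_bound=DEFAULT_BOUND,
            ),
            TransporterRole.DRAIN,
            name,
        )

    module = OrganismModule(
        network=net,
        base_model_id=model.id,
        chamber_of=chamber_of,
        transporters=transporters,
        media=media,
        target_compound=target,
        target_reaction_id=target_rxn_id,
        oxygen_policy=oxygen_policy,
        registry=registry,
        module_index=module_index,
        feed_mmol=feed_mmol,
    )
    module.validate()
    return module


def apply_oxygen(module: OrganismModule, policy: OxygenPolicy) -> OrganismModule:
    """Return a copy of ``module`` with the oxygen feed bound set by ``policy``.

    Modules whose model has no mapped oxygen metabolite carry no oxygen feed;
    for those the policy is recorded but changes no bound.
    """
    out = module.copy()
    out.oxygen_policy = policy
    if out.has_transporter(TransporterRole.FEED, OXYGEN_CANONICAL_ID):
        rxn = out.network.reaction(
            out.transporter_id(TransporterRole.FEED, OXYGEN_CANONICAL_ID)
        )
        rxn.lower_bound = 0.0
        rxn.upper_bound = policy.upper_bound
    return out
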