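"""Single-step and serial two-step fermentation runs with mass accounting.

Yields are reported as percent of the *original* input media mass converted
into the target compound.  For a two-step run, step 2 is fed the residual
media of step 1 plus its transferable secreted by-products; the feed of
step 2 equals the transferred mass (no renormalization to 1 g), so the
yield denominator stays the original input mass.

Alternate-optima policy: the transfer media of each chain (min / max) is
derived from explicit LPs — growth fixed at its optimum, the product flux
fixed at its FVA min/max, then per-compound uptake and secretion fluxes
resolved by a second FVA layer — so the pipeline result never depends on
which witness vector a solver happens to return.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

from .envelope import (
    OrganismModule,
    OxygenPolicy,
    TransporterRole,
    build_module,
)
from .lp_engine import (
    FVA_EPSILON,
    KnockoutSpec,
    LpStatus,
    apply_knockouts,
    solve_fba,
    solve_fva,
)
from .model_core import (
    CompoundRegistry,
    MediaComposition,
    MediaEntry,
    MetabolicModel,
)

__all__ = [
    "Organism",
    "FermentationSetup",
    "StepResult",
    "PipelineResult",
    "PipelineError",
    "DEFAULT_NON_TRANSFERABLE",
    "run_single_step",
    "run_two_step",
    "run_pipeline",
    "derive_transfer_media",
]

#: volatile by-products that never carry over between steps by default
DEFAULT_NON_TRANSFERABLE = frozenset({"co2", "h2"})

_GROWTH_TOL = 1e-9
_MASS_TOL = 1e-6


class PipelineError(RuntimeError):
    """A fermentation run failed (infeasible LP, missing unit, ...)."""


@dataclass(frozen=True)
class Organism:
    model: MetabolicModel
    registry: CompoundRegistry


@dataclass
class FermentationSetup:
    """One pipe: 1 or 2 organisms, a media, a target and oxygen policies."""

    organisms: Sequence[Organism]
    media: MediaComposition
    target: str
    oxygen: Sequence[OxygenPolicy]
    knockouts: Sequence[KnockoutSpec] = ()
    #: feed organism-1 cell biomass to organism 2 (off by default)
    transfer_biomass: bool = False
    #: molecular weights for secreted compounds not present in the media
    compound_weights: Dict[str, float] = field(default_factory=dict)
    #: transferability overrides for secreted compounds (canonical id -> bool)
    transferable_overrides: Dict[str, bool] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.organisms) not in (1, 2):
            raise ValueError("a setup takes 1 or 2 organisms")
        if len(self.oxygen) != len(self.organisms):
            raise ValueError("one oxygen policy per organism is required")
        if self.knockouts and len(self.knockouts) != len(self.organisms):
            raise ValueError("when given, provide one KnockoutSpec per organism")

    def knockout_for(self, step: int) -> KnockoutSpec:
        return self.knockouts[step] if self.knockouts else KnockoutSpec()


@dataclass
class StepResult:
    """Outcome of one fermentation step (mass scale, mg per gDW of input).

    ``consumed``/``residual_media``/``secreted`` describe the max-product
    chain; the min chain is tracked internally by the pipeline.
    """

    organism_id: str
    bm_max: float
    product_min_mg: float
    product_max_mg: float
    consumed: Dict[str, float]
    residual_media: MediaComposition
    secreted_mmol: Dict[str, float]
    fed_mass_mg: float
    flags: List[str] = field(default_factory=list)


@dataclass
class PipelineResult:
    steps: List[StepResult]
    yield_min_pct: float
    yield_max_pct: float
    input_mass_mg: float
    flags: List[str] = field(default_factory=list)


@dataclass
class _ChainState:
    """Product mass and outgoing media along one optimization chain."""

    product_mg: float
    residual: Dict[str, float]  # compound -> mg left in media
    secreted: Dict[str, float]  # compound -> mg excreted to waste
    consumed: Dict[str, float]
    bm_max: float
    flags: List[str]


def _no_growth_chain(media: MediaComposition, flags: List[str]) -> _ChainState:
    return _ChainState(
        product_mg=0.0,
        residual={e.compound_id: e.mass_mg for e in media.entries},
        secreted={},
        consumed={e.compound_id: 0.0 for e in media.entries},
        bm_max=0.0,
        flags=flags,
    )


def _solve_chain(
    module: OrganismModule, media: MediaComposition, regime: str, target_mw: float
) -> _ChainState:
    """Solve one step and resolve its transfer-relevant fluxes for one regime.

    ``regime`` is ``"max"`` or ``"min"``: the product flux is pinned to its
    FVA max (resp. min) at optimal growth; residuals use the maximal uptake
    consistent with that point (conservative: the least mass is carried
    forward), secretions the minimal consistent excretion.
    """
    fba = solve_fba(module)
    if fba.status is LpStatus.INFEASIBLE:
        raise PipelineError(f"step on {module.base_model_id!r}: FBA infeasible")
    if fba.status is LpStatus.UNBOUNDED:
        raise PipelineError(f"step on {module.base_model_id!r}: FBA unbounded")
    bm_max = fba.bm_max or 0.0
    if bm_max <= _GROWTH_TOL:
        return _no_growth_chain(media, ["no-growth"])

    fva = solve_fva(module, module.target_reaction_id, bm_max)
    v_product = fva.v_max if regime == "max" else fva.v_min
    product_mg = v_product * target_mw

    # pin growth + product, then range each envelope flux
    slack = max(abs(v_product) * FVA_EPSILON, FVA_EPSILON)
    pinned = {
        module.target_reaction_id: (max(v_product - slack, 0.0), v_product + slack)
    }

    consumed: Dict[str, float] = {}
    residual: Dict[str, float] = {}
    for entry in media.entries:
        c = entry.compound_id
        if module.has_transporter(TransporterRole.UPTAKE, c):
            rng = solve_fva(
                module,
                module.transporter_id(TransporterRole.UPTAKE, c),
                bm_max,
                extra_fixed=pinned,
            )
            taken_mmol = rng.v_max  # maximal uptake -> minimal residual
        else:
            taken_mmol = 0.0
        taken_mg = min(taken_mmol * entry.molecular_weight, entry.mass_mg)
        consumed[c] = taken_mg
        residual[c] = entry.mass_mg - taken_mg

    secreted: Dict[str, float] = {}
    for t in module.transporters_with_role(TransporterRole.SECRETE):
        rng = solve_fva(module, t.reaction_id, bm_max, extra_fixed=pinned)
        v = rng.v_min  # minimal excretion consistent with the optimum
        if v > _MASS_TOL:
            secreted[t.compound_id] = secreted.get(t.compound_id, 0.0) + v
    return _ChainState(
        product_mg=product_mg,
        residual=residual,
        secreted=secreted,  # mmol for now; weighted later when media is built
        consumed=consumed,
        bm_max=bm_max,
        flags=[],
    )


def _target_weight(setup: FermentationSetup) -> float:
    """Molecular weight of the target compound (setup weights, then media)."""
    target = setup.target
    if target in setup.compound_weights:
        return setup.compound_weights[target]
    for e in setup.media.entries:
        if e.compound_id == target:
            return e.molecular_weight
    raise PipelineError(
        f"no molecular weight known for target compound {target!r}; "
        "add it to FermentationSetup.compound_weights"
    )


def _registry_weight(module: OrganismModule, compound: str) -> Optional[float]:
    met_id = module.registry.resolve(compound, module.base_model_id)
    if met_id is not None:
        met = module.network.metabolites.get(met_id)
        if met is not None and met.molecular_weight:
            return met.molecular_weight
    return None


def derive_transfer_media(
    chain: _ChainState,
    media: MediaComposition,
    setup: FermentationSetup,
    module: OrganismModule,
) -> MediaComposition:
    """Media for the next step: transferable residuals + secreted by-products.

    The product compound is always excluded (it is harvested between steps),
    volatiles default to non-transferable, and organism-1 cell biomass is
    excluded unless ``setup.transfer_biomass`` is set (biomass transfer
    requires a registry weight for the ``"biomass"`` compound).
    """
    entries: List[MediaEntry] = []
    for e in media.entries:
        left = chain.residual.get(e.compound_id, 0.0)
        if left <= _MASS_TOL:
            continue
        if not _is_transferable(e.compound_id, e.transferable, setup, module):
            continue
        entries.append(
            MediaEntry(e.compound_id, left, e.molecular_weight, e.transferable)
        )
    for compound, mmol in sorted(chain.secreted.items()):
        if compound == module.target_compound:
            continue  # the product is removed between steps
        if not _is_transferable(compound, True, setup, module):
            continue
        mw = setup.compound_weights.get(compound) or _registry_weight(module, compound)
        if mw is None:
            for e in media.entries:
                if e.compound_id == compound:
                    mw = e.molecular_weight
        if mw is None:
            raise PipelineError(
                f"secreted compound {compound!r} has no molecular weight; "
                "add it to FermentationSetup.compound_weights"
            )
        mass = mmol * mw
        if mass <= _MASS_TOL:
            continue
        merged = False
        for i, prev in enumerate(entries):
            if prev.compound_id == compound:
                entries[i] = MediaEntry(
                    compound, prev.mass_mg + mass, prev.molecular_weight,
                    prev.transferable,
                )
                merged = True
        if not merged:
            entries.append(MediaEntry(compound, mass, mw, True))
    return MediaComposition(entries)


def _is_transferable(
    compound: str, default: bool, setup: FermentationSetup, module: OrganismModule
) -> bool:
    if compound == module.target_compound:
        return False
    if compound in setup.transferable_overrides:
        return setup.transferable_overrides[compound]
    if compound in DEFAULT_NON_TRANSFERABLE:
        return False
    if compound == "biomass":
        return setup.transfer_biomass
    return default


def _build_step_module(
    setup: FermentationSetup, step: int, media: MediaComposition
) -> OrganismModule:
    org = setup.organisms[step]
    module = build_module(
        org.model,
        media,
        setup.target,
        org.registry,
        setup.oxygen[step],
        module_index=step,
    )
    ko = setup.knockout_for(step)
    if ko:
        module = apply_knockouts(module, ko)
    return module


def run_single_step(setup: FermentationSetup) -> PipelineResult:
    """Run a 1-organism fermentation and report min/max yields in % of input mass."""
    if len(setup.organisms) != 1:
        raise ValueError("run_single_step takes a 1-organism setup")
    return run_pipeline(setup)


def run_two_step(setup: FermentationSetup) -> PipelineResult:
    """Run a serial 2-organism fermentation; see the module docstring."""
    if len(setup.organisms) != 2:
        raise ValueError("run_two_step takes a 2-organism setup")
    return run_pipeline(setup)


def run_pipeline(setup: FermentationSetup) -> PipelineResult:
    input_mass = setup.media.total_mass_mg
    if input_mass <= 0 or not setup.media.entries:
        flags = ["no-growth", "empty-media"]
        return PipelineResult(
            steps=[], yield_min_pct=0.0, yield_max_pct=0.0,
            input_mass_mg=max(input_mass, 0.0), flags=flags,
        )

    target_mw = _target_weight(setup)
    chains: Dict[str, List[_ChainState]] = {"min": [], "max": []}
    fed: Dict[str, List[MediaComposition]] = {"min": [], "max": []}
    steps: List[StepResult] = []
    flags: List[str] = []
    for regime in ("min", "max"):
        media = setup.media
        for step in range(len(setup.organisms)):
            fed[regime].append(media)
            if not media.entries or media.total_mass_mg <= _MASS_TOL:
                chains[regime].append(_no_growth_chain(media, ["empty-media"]))
                media = MediaComposition([])
                continue
            module = _build_step_module(setup, step, media)
            chain = _solve_chain(module, media, regime, target_mw)
            chains[regime].append(chain)
            media = derive_transfer_media(chain, media, setup, module)

    for step in range(len(setup.organisms)):
        mn, mx = chains["min"][step], chains["max"][step]
        media_in = fed["max"][step]
        mw_of = {e.compound_id: e.molecular_weight for e in media_in.entries}
        steps.append(
            StepResult(
                organism_id=setup.organisms[step].model.id,
                bm_max=mx.bm_max,
                product_min_mg=mn.product_mg,
                product_max_mg=mx.product_mg,
                consumed=mx.consumed,
                residual_media=MediaComposition(
                    [
                        MediaEntry(c, m, mw_of.get(c, 1.0), True)
                        for c, m in sorted(mx.residual.items())
                        if m > _MASS_TOL
                    ]
                ),
                secreted_mmol=dict(mx.secreted),
                fed_mass_mg=media_in.total_mass_mg,
                flags=sorted(set(mn.flags) | set(mx.flags)),
            )
        )
        flags.extend(steps[-1].flags)

    total_min = sum(c.product_mg for c in chains["min"])
    total_max = sum(c.product_mg for c in chains["max"])
    return PipelineResult(
        steps=steps,
        yield_min_pct=100.0 * total_min / input_mass,
        yield_max_pct=100.0 * total_max / input_mass,
        input_mass_mg=input_mass,
        flags=sorted(set(flags)),
    )
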