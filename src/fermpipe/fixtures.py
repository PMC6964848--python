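"""Deterministic toy organisms, media and random viable networks.

Everything here is mass-balanced by construction via the assigned molecular
weights (glucose 180, xylose 150, ethanol 46, CO₂ 44, biomass precursors
180/150), so envelope mass-closure checks hold exactly and every hand-LP
value is a small rational.

TOY-A ferments glucose only::

    FERM:     glc -> 2 etoh + 2 co2        (180 = 2·46 + 2·44)
    GROW_PRE: glc -> bmA
    GROW:     bmA ->                        growth, UB 1.0 mmol·h⁻¹

TOY-B ferments xylose only::

    FERMX:    xyl -> 5/3 etoh + 5/3 co2    (150 = 5/3·46 + 5/3·44)
    GROW_PRE: xyl -> bmB
    GROW:     bmB ->                        growth, UB 0.5 mmol·h⁻¹
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from pathlib import Path
from typing import Dict, List

import numpy as np

from .model_core import (
    DEFAULT_BOUND,
    CompoundRegistry,
    MediaComposition,
    MediaEntry,
    MetabolicModel,
    Metabolite,
    Reaction,
    write_media,
    write_model,
)

__all__ = [
    "MW",
    "make_toy_A",
    "make_toy_B",
    "toy_registry_A",
    "toy_registry_B",
    "media_m1",
    "media_m2",
    "toy_compound_weights",
    "RandomCase",
    "make_random_network",
    "write_suite",
]

#: molecular weights (g·mol⁻¹) of the toy interface compounds
MW = {"glc": 180.0, "xyl": 150.0, "etoh": 46.0, "co2": 44.0, "bmA": 180.0, "bmB": 150.0}


def _mets(*ids: str) -> Dict[str, Metabolite]:
    return {i: Metabolite(id=i, name=i, molecular_weight=MW.get(i)) for i in ids}


def make_toy_A() -> MetabolicModel:
    return MetabolicModel(
        id="TOY-A",
        metabolites=_mets("glc", "etoh", "co2", "bmA"),
        reactions=[
            Reaction("FERM", {"glc": -1.0, "etoh": 2.0, "co2": 2.0}, 0.0, DEFAULT_BOUND),
            Reaction("GROW_PRE", {"glc": -1.0, "bmA": 1.0}, 0.0, DEFAULT_BOUND),
            Reaction("GROW", {"bmA": -1.0}, 0.0, 1.0),
        ],
        growth_reaction_id="GROW",
        excretable=frozenset({"etoh", "co2"}),
    )


def make_toy_B() -> MetabolicModel:
    five_thirds = 5.0 / 3.0
    return MetabolicModel(
        id="TOY-B",
        metabolites=_mets("xyl", "etoh", "co2", "bmB"),
        reactions=[
            Reaction(
                "FERMX",
                {"xyl": -1.0, "etoh": five_thirds, "co2": five_thirds},
                0.0,
                DEFAULT_BOUND,
            ),
            Reaction("GROW_PRE", {"xyl": -1.0, "bmB": 1.0}, 0.0, DEFAULT_BOUND),
            Reaction("GROW", {"bmB": -1.0}, 0.0, 0.5),
        ],
        growth_reaction_id="GROW",
        excretable=frozenset({"etoh", "co2"}),
    )


def toy_registry_A() -> CompoundRegistry:
    return CompoundRegistry(
        {
            "glc": {"TOY-A": "glc"},
            "etoh": {"TOY-A": "etoh"},
            "co2": {"TOY-A": "co2"},
        }
    )


def toy_registry_B() -> CompoundRegistry:
    return CompoundRegistry(
        {
            "xyl": {"TOY-B": "xyl"},
            "etoh": {"TOY-B": "etoh"},
            "co2": {"TOY-B": "co2"},
        }
    )


def media_m1() -> MediaComposition:
    """1000 mg glucose per gDW of media."""
    return MediaComposition([MediaEntry("glc", 1000.0, MW["glc"], True)])


def media_m2() -> MediaComposition:
    """500 mg glucose + 500 mg xylose per gDW of media."""
    return MediaComposition(
        [
            MediaEntry("glc", 500.0, MW["glc"], True),
            MediaEntry("xyl", 500.0, MW["xyl"], True),
        ]
    )


def toy_compound_weights() -> Dict[str, float]:
    return {"etoh": MW["etoh"], "co2": MW["co2"], "glc": MW["glc"], "xyl": MW["xyl"]}


# ---------------------------------------------------------------------------
# random viable networks (for LP-oracle equivalence testing)


@dataclass(frozen=True)
class RandomCase:
    """A random network plus everything needed to wrap and solve it."""

    model: MetabolicModel
    registry: CompoundRegistry
    media: MediaComposition
    target: str
    compound_weights: Dict[str, float]


def make_random_network(n_reactions: int, seed: int) -> RandomCase:
    """A mass-balanced, growth-feasible random network, deterministic per seed.

    Topology: substrate → chain of intermediates → biomass precursor, with a
    byproduct branch off the last intermediate.  Coefficients are drawn from
    a small rational set and metabolite weights are propagated so that every
    reaction conserves mass exactly.
    """
    if n_reactions < 3:
        raise ValueError("need at least 3 reactions")
    rng = np.random.default_rng(seed)
    model_id = f"RND-{n_reactions}-{seed}"

    coefs = [Fraction(1, 2), Fraction(1), Fraction(2), Fraction(3), Fraction(4)]
    weight: Dict[str, Fraction] = {"sub": Fraction(180)}
    mets: List[str] = ["sub"]
    reactions: List[Reaction] = []

    n_chain = n_reactions - 3  # conversions between substrate and biomass
    prev = "sub"
    for i in range(n_chain):
        met = f"m{i}"
        a = coefs[rng.integers(0, len(coefs))]
        weight[met] = weight[prev] / a
        mets.append(met)
        reactions.append(Reaction(f"C{i}", {prev: -1.0, met: float(a)}, 0.0, DEFAULT_BOUND))
        prev = met

    # byproduct branch off the deepest intermediate
    b = coefs[rng.integers(0, len(coefs))]
    weight["byp"] = weight[prev] / b
    mets.append("byp")
    reactions.append(Reaction("BYP", {prev: -1.0, "byp": float(b)}, 0.0, DEFAULT_BOUND))

    weight["bm"] = weight[prev]
    mets.append("bm")
    reactions.append(Reaction("GROW_PRE", {prev: -1.0, "bm": 1.0}, 0.0, DEFAULT_BOUND))
    growth_ub = float(rng.integers(2, 11)) / 10.0  # 0.2 .. 1.0
    reactions.append(Reaction("GROW", {"bm": -1.0}, 0.0, growth_ub))

    model = MetabolicModel(
        id=model_id,
        metabolites={
            m: Metabolite(id=m, name=m, molecular_weight=float(weight[m]))
            for m in mets
        },
        reactions=reactions,
        growth_reaction_id="GROW",
        excretable=frozenset({"byp"}),
    )
    registry = CompoundRegistry(
        {"sub": {model_id: "sub"}, "byp": {model_id: "byp"}}
    )
    media = MediaComposition([MediaEntry("sub", 1000.0, float(weight["sub"]), True)])
    weights = {"sub": float(weight["sub"]), "byp": float(weight["byp"])}
    return RandomCase(model, registry, media, "byp", weights)


def write_suite(out_dir: str | Path) -> List[Path]:
    """Write the toy suite (models, media, registries) into ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []
    for model in (make_toy_A(), make_toy_B()):
        p = out / f"{model.id}.tsv"
        write_model(model, p)
        written.append(p)
    for name, media in (("m1", media_m1()), ("m2", media_m2())):
        p = out / f"{name}.csv"
        write_media(media, p)
        written.append(p)
    for name, reg in (("registry_TOY-A", toy_registry_A()), ("registry_TOY-B", toy_registry_B())):
        p = out / f"{name}.csv"
        reg.to_csv(p)
        written.append(p)
    return written
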