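"""Independent LP oracle built on cobrapy + GLPK.

Translates an OrganismModule's network into a cobra.Model and solves the
same optimization problems through a completely different code path and
solver (optlang/GLPK instead of scipy/HiGHS).  Used to cross-check bm_max
and FVA bounds produced by the package's own LP engine.
"""

from __future__ import annotations

import cobra

from fermpipe.envelope import OrganismModule

GROWTH_EPS = 1e-6


def to_cobra(module: OrganismModule) -> cobra.Model:
    net = module.network
    cm = cobra.Model(net.id)
    cm.add_metabolites(
        [cobra.Metabolite(m, compartment="c") for m in net.metabolites]
    )
    for rxn in net.reactions:
        cr = cobra.Reaction(rxn.id, lower_bound=rxn.lower_bound, upper_bound=rxn.upper_bound)
        cm.add_reactions([cr])
        cr.add_metabolites({cm.metabolites.get_by_id(m): c for m, c in rxn.stoichiometry.items()})
    cm.objective = net.growth_reaction_id
    return cm


def oracle_bm_max(module: OrganismModule) -> float:
    cm = to_cobra(module)
    sol = cm.optimize()
    assert sol.status == "optimal", f"oracle FBA status {sol.status}"
    return float(sol.objective_value)


def oracle_fva(module: OrganismModule, target_reaction: str) -> tuple[float, float]:
    """(v_min, v_max) of ``target_reaction`` with growth fixed at its optimum."""
    cm = to_cobra(module)
    sol = cm.optimize()
    assert sol.status == "optimal"
    bm = float(sol.objective_value)
    growth = cm.reactions.get_by_id(module.growth_reaction_id)
    growth.lower_bound = bm - abs(bm) * GROWTH_EPS
    cm.objective = target_reaction
    cm.objective_direction = "max"
    v_max = float(cm.optimize().objective_value)
    cm.objective_direction = "min"
    v_min = float(cm.optimize().objective_value)
    return v_min, v_max
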