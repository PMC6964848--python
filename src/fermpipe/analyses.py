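"""Media sensitivity and gradient analyses, knockout screening, campaigns.

All analyses rerun the full fermentation pipeline on a perturbed setup and
report min and max yields separately:

* sensitivity — one media compound's feed nullified; relative yield in %
  of the baseline (values above 100% are legal and are not clamped).
* gradient — δ mg of one compound added (default δ = 1 mg/gDW, no
  renormalization); finite-difference mg product per mg compound.
* knockout scan — every (choice-in-organism-1, choice-in-organism-2) pair,
  each choice "none" or one reaction; yields in % of wild type.
* campaign planning — (single pipes + ordered distinct pairs) × media ×
  targets, crossed with oxygen conditions into tasks.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, replace
from typing import Iterator, List, Optional, Sequence, Tuple

from .lp_engine import KnockoutSpec
from .serial_pipeline import FermentationSetup, PipelineResult, run_pipeline

__all__ = [
    "SensitivityRow",
    "GradientRow",
    "KnockoutScenario",
    "Campaign",
    "sensitivity_scan",
    "gradient_scan",
    "enumerate_knockout_scenarios",
    "count_knockout_scenarios",
    "knockout_scan",
    "run_knockout_scenario",
    "plan_campaign",
]

_YIELD_TOL = 1e-9


@dataclass(frozen=True)
class SensitivityRow:
    compound: str
    relative_yield_min_pct: Optional[float]  # None when the baseline is 0
    relative_yield_max_pct: Optional[float]
    status: str = "ok"


@dataclass(frozen=True)
class GradientRow:
    compound: str
    gradient_min: float  # mg product per mg compound added
    gradient_max: float


@dataclass(frozen=True)
class KnockoutScenario:
    ko1: Optional[str]
    ko2: Optional[str]
    yield_min_rel_pct: Optional[float]
    yield_max_rel_pct: Optional[float]
    status: str = "ok"


@dataclass(frozen=True)
class Campaign:
    media: Tuple[str, ...]
    targets: Tuple[str, ...]
    organisms: Tuple[str, ...]
    conditions: Tuple[str, ...]
    configurations: Tuple[Tuple[Tuple[str, ...], str, str], ...]  # (pipe, media, target)
    tasks: Tuple[Tuple[Tuple[str, ...], str, str, str], ...]

    @property
    def n_configurations(self) -> int:
        return len(self.configurations)

    @property
    def n_tasks(self) -> int:
        return len(self.tasks)


# ---------------------------------------------------------------------------
# sensitivity (compound removal)


def sensitivity_scan(
    setup: FermentationSetup, baseline: Optional[PipelineResult] = None
) -> List[SensitivityRow]:
    """Relative yields after removing each media compound, one at a time."""
    base = baseline or run_pipeline(setup)
    # ratios are taken on the product-mass scale: removing a compound shrinks
    # the media total, so percent yields of the two runs have different
    # denominators and must not be divided directly
    base_min_mg, base_max_mg = _product_masses(base)
    rows = []
    for compound in setup.media.compound_ids:
        perturbed = replace(setup, media=setup.media.without(compound))
        res = run_pipeline(perturbed)
        new_min_mg, new_max_mg = _product_masses(res)
        rows.append(
            SensitivityRow(
                compound=compound,
                relative_yield_min_pct=_relative(new_min_mg, base_min_mg),
                relative_yield_max_pct=_relative(new_max_mg, base_max_mg),
                status="ok" if base_max_mg > _YIELD_TOL else "undefined-baseline",
            )
        )
    return rows


def _product_masses(res: PipelineResult) -> Tuple[float, float]:
    scale = res.input_mass_mg / 100.0
    return res.yield_min_pct * scale, res.yield_max_pct * scale


def _relative(new: float, old: float) -> Optional[float]:
    if old <= _YIELD_TOL:
        return None
    return 100.0 * new / old


# ---------------------------------------------------------------------------
# gradient (compound addition)


def gradient_scan(
    setup: FermentationSetup,
    delta_mg: float = 1.0,
    baseline: Optional[PipelineResult] = None,
) -> List[GradientRow]:
    """Finite-difference yield sensitivity to adding ``delta_mg`` of each compound.

    The perturbed media keeps the original total as the yield denominator
    basis (masses are not renormalized), so the gradient is simply
    (new − old) product mass divided by ``delta_mg``.
    """
    if delta_mg <= 0:
        raise ValueError("delta_mg must be > 0")
    base = baseline or run_pipeline(setup)
    base_min_mg = base.yield_min_pct / 100.0 * base.input_mass_mg
    base_max_mg = base.yield_max_pct / 100.0 * base.input_mass_mg
    rows = []
    for compound in setup.media.compound_ids:
        perturbed = replace(setup, media=setup.media.with_added(compound, delta_mg))
        res = run_pipeline(perturbed)
        new_min_mg = res.yield_min_pct / 100.0 * res.input_mass_mg
        new_max_mg = res.yield_max_pct / 100.0 * res.input_mass_mg
        rows.append(
            GradientRow(
                compound=compound,
                gradient_min=(new_min_mg - base_min_mg) / delta_mg,
                gradient_max=(new_max_mg - base_max_mg) / delta_mg,
            )
        )
    return rows


# ---------------------------------------------------------------------------
# knockout scenarios


def count_knockout_scenarios(n1: int, n2: int) -> int:
    """(n1+1)·(n2+1): each organism is wild type or has one reaction removed."""
    if n1 < 0 or n2 < 0:
        raise ValueError("reaction counts must be >= 0")
    return (n1 + 1) * (n2 + 1)


def enumerate_knockout_scenarios(
    choices1: Sequence[Optional[str]] | int, choices2: Sequence[Optional[str]] | int
) -> Tuple[int, Iterator[Tuple[Optional[str], Optional[str]]]]:
    """Scenario count and iterator over (choice₁, choice₂) pairs.

    Arguments may be reaction-id lists or bare reaction counts (in which
    case the iterator yields positional placeholders).
    """
    ids1 = _choices(choices1)
    ids2 = _choices(choices2)
    count = len(ids1) * len(ids2)
    assert count == count_knockout_scenarios(len(ids1) - 1, len(ids2) - 1)
    return count, itertools.product(ids1, ids2)


def _choices(arg: Sequence[Optional[str]] | int) -> List[Optional[str]]:
    if isinstance(arg, int):
        if arg < 0:
            raise ValueError("reaction count must be >= 0")
        return [None] + [f"r{i}" for i in range(arg)]
    return [None] + [c for c in arg if c is not None]


def run_knockout_scenario(payload: dict) -> dict:
    """Execute one knockout scenario; used as a task-runner work function.

    ``payload`` keys: setup (FermentationSetup), ko1, ko2, wt_min_pct,
    wt_max_pct.  Returns a flat result row.
    """
    setup: FermentationSetup = payload["setup"]  # knockouts already merged in
    ko1, ko2 = payload["ko1"], payload["ko2"]
    wt_min, wt_max = payload["wt_min_pct"], payload["wt_max_pct"]
    if ko1 is None and ko2 is None:
        # wild type of the screen, 100% by definition
        return {"ko1": "", "ko2": "", "yield_min_rel_pct": 100.0,
                "yield_max_rel_pct": 100.0, "status": "ok"}
    res = run_pipeline(setup)
    rel_min = _relative(res.yield_min_pct, wt_min)
    rel_max = _relative(res.yield_max_pct, wt_max)
    status = "ok" if rel_max is not None else "undefined-baseline"
    if rel_min is None and rel_max is not None:
        status = "undefined-min-baseline"
    return {
        "ko1": ko1 or "",
        "ko2": ko2 or "",
        "yield_min_rel_pct": rel_min,
        "yield_max_rel_pct": rel_max,
        "status": status,
    }


def knockout_scan(
    setup: FermentationSetup,
    scope1: Optional[Sequence[str]] = None,
    scope2: Optional[Sequence[str]] = None,
    base_knockouts: Sequence[KnockoutSpec] = (),
    runner=None,
) -> List[KnockoutScenario]:
    """Exhaustive (choice₁, choice₂) knockout screen relative to wild type.

    ``scope1``/``scope2`` default to all base-model reactions of each
    organism (envelope transporters are never part of the scope: they are
    wrapper artifacts, not organism genes).  ``base_knockouts`` (one spec
    per organism) is merged into every scenario, supporting nested screens
    where new knockouts accumulate on previously selected ones.

    Per-scenario failures are recorded in the row status, never aborting
    the scan.  ``runner`` is an optional callable ``(work_fn, payloads) ->
    rows`` used to parallelize; by default scenarios run in-process.
    """
    n_org = len(setup.organisms)
    if scope1 is None:
        scope1 = list(setup.organisms[0].model.reaction_ids)
    if n_org == 2 and scope2 is None:
        scope2 = list(setup.organisms[1].model.reaction_ids)
    scope2 = scope2 if n_org == 2 else []

    base = tuple(base_knockouts) if base_knockouts else ()
    wt_setup = replace(setup, knockouts=base if base else ())
    wt = run_pipeline(wt_setup)

    payloads = []
    _, scenarios = enumerate_knockout_scenarios(list(scope1), list(scope2) or [])
    for ko1, ko2 in scenarios:
        merged = _merge_base(setup, base, ko1, ko2)
        payloads.append(
            {"setup": merged, "ko1": ko1, "ko2": ko2,
             "wt_min_pct": wt.yield_min_pct, "wt_max_pct": wt.yield_max_pct}
        )

    if runner is not None:
        raw = runner(run_knockout_scenario, payloads)
    else:
        raw = []
        for p in payloads:
            try:
                raw.append(run_knockout_scenario(p))
            except Exception as exc:  # record, keep scanning
                raw.append(
                    {"ko1": p["ko1"] or "", "ko2": p["ko2"] or "",
                     "yield_min_rel_pct": None, "yield_max_rel_pct": None,
                     "status": f"failed: {exc}"}
                )
    return [
        KnockoutScenario(
            ko1=r["ko1"] or None,
            ko2=r["ko2"] or None,
            yield_min_rel_pct=r["yield_min_rel_pct"],
            yield_max_rel_pct=r["yield_max_rel_pct"],
            status=r["status"],
        )
        for r in raw
    ]


def _merge_base(
    setup: FermentationSetup,
    base: Sequence[KnockoutSpec],
    ko1: Optional[str],
    ko2: Optional[str],
) -> FermentationSetup:
    n = len(setup.organisms)
    specs = []
    for i in range(n):
        ids = set(base[i].reaction_ids) if base else set()
        ko = ko1 if i == 0 else ko2
        if ko:
            ids.add(ko)
        specs.append(KnockoutSpec(frozenset(ids)))
    return replace(setup, knockouts=tuple(specs))


# ---------------------------------------------------------------------------
# campaign planning


def plan_campaign(
    media: Sequence[str],
    targets: Sequence[str],
    organisms: Sequence[str],
    conditions: Sequence[str] = ("aerobic", "anaerobic"),
) -> Campaign:
    """Enumerate configurations (pipes × media × targets) and tasks.

    Pipes are all single organisms plus all *ordered* pairs of distinct
    organisms: n + n(n−1) pipes for n organisms.
    """
    if not media or not targets or not organisms or not conditions:
        raise ValueError("media, targets, organisms and conditions must be non-empty")
    if len(set(organisms)) != len(organisms):
        raise ValueError("duplicate organism ids")
    pipes: List[Tuple[str, ...]] = [(o,) for o in organisms]
    pipes += [
        (a, b) for a, b in itertools.permutations(organisms, 2)
    ]
    configurations = tuple(
        (pipe, m, t)
        for pipe in pipes
        for m in media
        for t in targets
    )
    tasks = tuple(
        (pipe, m, t, cond) for (pipe, m, t) in configurations for cond in conditions
    )
    return Campaign(
        media=tuple(media),
        targets=tuple(targets),
        organisms=tuple(organisms),
        conditions=tuple(conditions),
        configurations=configurations,
        tasks=tasks,
    )
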