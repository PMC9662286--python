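"""restoreplan: cost-effectiveness mapping for landscape restoration planning.

A desk-scale pipeline for practice-led restoration assessment: map current
and climate-constrained maximum above-ground biomass, compute the biomass
deficit, assign restoration methods through a threshold rule framework,
model biomass gains, costs and cost-effectiveness over investment horizons,
and extract uncertainty-aware priority areas under a pessimistic /
realistic / optimistic scenario ensemble.
"""

from importlib import resources

__version__ = "0.1.0"

from .grids import GridSpec, LandscapeStack, LANDCOVER_CODES, aggregate_block
from .synthetic import SyntheticConfig, generate_landscape, sample_plots
from .agb_mapping import (
    FitReport,
    PredictorSet,
    aggregate_to_hectare,
    fit_current_agb,
    screen_predictors,
    texture_index,
    upscale_agb,
)
from .max_agb import (
    EnvelopeTable,
    ReferenceSet,
    build_reference_set,
    envelope_uncertainty,
    fit_max_agb,
)
from .method_rules import (
    METHOD_CODES,
    DeficitMap,
    MethodMap,
    assign_methods,
    compute_deficit,
    distance_to,
    intact_mask,
)
from .scenarios import DEFAULT_SCENARIOS, GrowthParams, ScenarioParams
from .growth_cost import (
    CEResult,
    CostSchedule,
    EconomyParams,
    agb_gain,
    agc_to_agb,
    compute_cost,
    cost_effectiveness,
    years_to_recovery,
)
from .prioritize import (
    EnsembleResult,
    PriorityMap,
    run_ensemble,
    summarize,
    to_hectare,
    top_quantile_mask,
)
from .stats import kruskal_dunn, holm_adjust


def default_cost_schedule() -> CostSchedule:
    """The packaged default cost schedule (illustrative USD magnitudes)."""
    with resources.as_file(
        resources.files("restoreplan").joinpath("data/cost_schedule.yml")
    ) as p:
        return CostSchedule.from_yaml(p)
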