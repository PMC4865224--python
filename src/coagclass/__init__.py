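"""coagclass: in-silico thrombin-generation assay discovery.

Simulates tissue-factor-initiated clotting for synthetic patient cohorts,
converts the trajectories into high-dimensional feature sets, and uses
random-forest out-of-bag classification with Gini importances to find
small, time-localized combinations of chemical species that discriminate
clinical groups.
"""

from .kinetics import (
    ReactionNetwork,
    Reaction,
    Species,
    SimulationProfile,
    parse_model_file,
    parse_model_text,
    mass_action_rates,
    simulate,
)
from .cohort import (
    FACTORS,
    PHYSIOLOGICAL_MEANS,
    Cohort,
    CohortSpec,
    FactorSpec,
    default_synthetic_spec,
    lognormal_from_moments,
    read_cohort_table,
    sample_cohort,
    to_initial_conditions,
    write_cohort_table,
)
from .features import (
    FeatureMatrix,
    assemble_feature_matrix,
    conventional_features,
    fit_pchip,
    moving_averages,
    normalize_profile,
    reference_peaks,
)
from .forest import (
    ClassifierReport,
    ForestConfig,
    ImportanceTable,
    mdgini,
    oob_accuracy,
    repeated_accuracy,
    repeated_importances,
    repeated_run,
    train_forest,
)
from .selection import (
    SelectionResult,
    SpeciesScore,
    best_k_features,
    combination_report,
    select_species,
    time_resolved,
    top_fraction_mean,
)

__version__ = "0.1.0"

TOY_MODEL = "toy_model.txt"


def toy_model_path():
    """Filesystem path of the bundled reduced clotting-cascade model."""
    from importlib.resources import files

    return files("coagclass").joinpath("data/toy_model.txt")
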