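"""Kinetic modelling of yeast carbon-storage metabolism under feast/famine
substrate cycles: total and 13C-labelled mass balances, the three-stage
protocol emulation, a two-step regularized estimation pipeline, ensemble
robustness experiments and a synthetic-data generator.
"""

from .bundles import ObservationBundle, read_bundle, write_bundle
from .model import (
    BoundaryFlow,
    GlycogenTables,
    YeastModel,
    load_chemostat_state,
    ode_rhs_total,
    state_from_dict,
    state_to_dict,
)
from .params import (
    ParameterSet,
    load_calibrated_parameters,
    load_reference_parameters,
    load_table1,
    read_parameterset,
    write_parameterset,
)
from .protocol import FeedProtocol, Trajectory, cycle_summary, run_chemostat, run_cycles

__version__ = "0.1.0"

__all__ = [
    "BoundaryFlow",
    "FeedProtocol",
    "GlycogenTables",
    "ObservationBundle",
    "ParameterSet",
    "Trajectory",
    "YeastModel",
    "cycle_summary",
    "load_calibrated_parameters",
    "load_chemostat_state",
    "load_reference_parameters",
    "load_table1",
    "ode_rhs_total",
    "read_bundle",
    "read_parameterset",
    "run_chemostat",
    "run_cycles",
    "state_from_dict",
    "state_to_dict",
    "write_bundle",
    "write_parameterset",
    "__version__",
]


def default_protocol() -> FeedProtocol:
    """The shipped calibrated protocol configuration."""
    from importlib import resources

    import yaml

    path = resources.files("yeastff.data").joinpath("protocol_default.yaml")
    with open(path) as fh:
        return FeedProtocol(**yaml.safe_load(fh))
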