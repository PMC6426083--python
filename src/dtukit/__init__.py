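"""dtukit: differential transcript usage from bootstrapped abundance estimates."""

__version__ = "0.1.0"

from .config import RunConfig
from .model import AnnotationMap, ExperimentData, ReplicateQuant, align
from .simulate import SimulationConfig, TruthSet, simulate_experiment

__all__ = [
    "AnnotationMap",
    "ExperimentData",
    "ReplicateQuant",
    "RunConfig",
    "SimulationConfig",
    "TruthSet",
    "align",
    "simulate_experiment",
    "call_dtu",
    "run_dtu",
]


def __getattr__(name):
    # pipeline imports matplotlib-adjacent modules; keep top-level import light
    if name in ("call_dtu", "run_dtu"):
        from . import pipeline

        return getattr(pipeline, name)
    raise AttributeError(name)
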