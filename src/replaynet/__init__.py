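"""replaynet: recurrent-network models of hippocampal reverse replay.

Simulators and offline evaluators for a model family in which symmetric
spike-timing-dependent plasticity, modulated by Tsodyks-Markram short-term
plasticity, biases recurrent synaptic weights opposite to the direction of
firing-sequence propagation, supporting goal-directed path learning through
reverse replay.
"""

from . import bias_eval, plasticity

__version__ = "0.1.0"

__all__ = [
    "plasticity",
    "bias_eval",
    "rate_net_1d",
    "spiking_net_1d",
    "place_net_2d",
    "foraging",
    "interface",
    "__version__",
]


def __getattr__(name):
    # heavier modules (numba compilation) are imported lazily
    if name in __all__:
        import importlib

        return importlib.import_module(f".{name}", __name__)
    raise AttributeError(name)
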