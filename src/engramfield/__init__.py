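"""Neural-field and bioelectric-field analyses of memory ensembles.

Tools for testing whether the extracellular electric field generated by a
neural ensemble feeds back onto, and guides, the activity that produced it
(ephaptic coupling): a neural field simulator of cue-conditioned LFP-like
data, a bidomain forward model of the extracellular potential, Free-Energy
based Bayesian comparison of ephaptic vs. non-ephaptic generative models,
snapshot-based spatial Granger causality, Fourier-mode slaving diagnostics,
and representational similarity analysis across areas.
"""

__version__ = "0.1.0"

from . import field_model, inference, mode_dynamics, neural_field, rsa, spatial_gc, synthetic

__all__ = [
    "__version__",
    "field_model",
    "inference",
    "mode_dynamics",
    "neural_field",
    "rsa",
    "spatial_gc",
    "synthetic",
    "pipeline",
]


def __getattr__(name):
    # pipeline imports back into the package; load it lazily
    if name == "pipeline":
        from . import pipeline

        return pipeline
    raise AttributeError(name)
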