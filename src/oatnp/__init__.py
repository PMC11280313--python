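"""oatnp: natural-product metabolomics of renal OAT1/OAT3 knockouts.

Analysis library for comparing knockout (KO) vs wildtype (WT) serum
metabolomes with a focus on natural products (NPs): matching measured
metabolites against NP databases, differential-abundance statistics,
PLS-DA class separation, pathway fold-enrichment, chemical-space
characterization of transporter-dependent NPs, chemical-similarity
(ChemRICH-style) cluster enrichment, and in vitro transporter assay
analysis (bead-binding competition and uptake-inhibition dose response).

Every stage runs on synthetic data with planted ground truth
(:mod:`oatnp.synthdata`), so the full pipeline is testable offline.
"""

from importlib import resources as _resources

__version__ = "0.1.0"

__all__ = [
    "synthdata",
    "npdb",
    "stats",
    "plsda",
    "enrich",
    "chemspace",
    "chemcluster",
    "invitro",
    "pipeline",
]


def data_path(name: str):
    """Return a traversable handle to a packaged data resource."""
    return _resources.files("oatnp.data").joinpath(name)
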