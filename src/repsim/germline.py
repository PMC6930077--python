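"""Toy germline V/J reference bundled with the package.

Synthetic segments (~40-65 nt) with valid CDR3 anchors: seven beta V
genes matching the preset usage vectors, three beta J genes, and two
alpha V/J pairs so that canonical TRAV11-TRAJ18 dominance is a real
measurement rather than a tautology.  A real IMGT-derived reference is
accepted anywhere a :class:`~repsim.model.GermlineReference` is, once
annotated with the two anchor offsets.
"""

from importlib.resources import files

from .io import read_germline_fasta
from .model import GermlineReference

_FIXTURE = files("repsim.data") / "toy_germline.fasta"


def default_reference() -> GermlineReference:
    """Load the bundled toy germline reference."""
    return read_germline_fasta(str(_FIXTURE))


def default_reference_path() -> str:
    """Filesystem path of the bundled reference FASTA."""
    return str(_FIXTURE)
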