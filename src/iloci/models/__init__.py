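"""Shipped example penetrance-model spec files.

These are synthetic reconstructions of classic two-locus and network model
families from the epistasis-simulation literature, provided as editable
templates; they are not verbatim copies of any published supplement.
"""

from importlib import resources
from pathlib import Path

__all__ = ["model_path", "available_models"]


def model_path(name: str) -> Path:
    """Filesystem path of a shipped model spec (e.g. 'pure_epistasis_strong_maf02')."""
    if not name.endswith(".txt"):
        name += ".txt"
    ref = resources.files(__package__).joinpath(name)
    with resources.as_file(ref) as p:
        return Path(p)


def available_models() -> list[str]:
    return sorted(
        p.name[:-4]
        for p in resources.files(__package__).iterdir()
        if p.name.endswith(".txt")
    )
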