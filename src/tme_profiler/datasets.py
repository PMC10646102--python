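"""Packaged default gene sets."""

from __future__ import annotations

from importlib import resources
from pathlib import Path

from .cohort_io import GeneSet, read_gmt


def _data_path(name: str) -> Path:
    return Path(resources.files("tme_profiler").joinpath("data", name))


def immune_signature_sets() -> dict[str, GeneSet]:
    """Default IFNG / TIS / DYSFUNCTION / STING gene sets.

    IFNG and TIS memberships follow the published anti-PD-1 response
    signatures they are cited from and are meant to be replaced by the
    user's own GMT when a different membership is preferred.
    """
    return {gs.name: gs for gs in read_gmt(_data_path("immune_signatures.gmt"))}


def toy_metabolic_sets() -> dict[str, GeneSet]:
    """Toy OXPHOS/TCA/GLYC/ANGIOGENESIS sets matching the synthetic cohort."""
    return {gs.name: gs for gs in read_gmt(_data_path("toy_metabolic.gmt"))}
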