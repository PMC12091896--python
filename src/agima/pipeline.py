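"""Convenience layer: complex -> (F, N) graph pairs ready for the model."""

from __future__ import annotations

import warnings
from typing import Optional, Sequence

from .features import (
    element_default_chemistry,
    featurize,
    get_feature_set,
    perceive_chemistry,
)
from .graphs import build_adjacency_tensor, get_scheme, normalize
from .structures import ComplexStructure, extract_binding_site

__all__ = ["prepare_graph", "prepare_dataset"]


def prepare_graph(
    cs: ComplexStructure,
    feature_set: str = "F18",
    scheme: str = "AGIMA_2",
    cutoff: float = 4.0,
    chem=None,
):
    """Featurize one complex: returns (NodeFeatureMatrix, NormalizedAdjacency).

    Chemistry is perceived from the attached molecules when present;
    in-memory structures without bond information (synthetic fixtures)
    fall back to element-derived chemistry.
    """
    site = extract_binding_site(cs, cutoff)
    if chem is None:
        if cs.protein_mol is not None and cs.ligand_mol is not None:
            chem = perceive_chemistry(cs)
        else:
            chem = element_default_chemistry(cs)
    F = featurize(site, chem, get_feature_set(feature_set))
    tensor = build_adjacency_tensor(site, get_scheme(scheme))
    return F, normalize(tensor)


def prepare_dataset(
    dataset: Sequence[tuple[ComplexStructure, float]],
    feature_set: str = "F18",
    scheme: str = "AGIMA_2",
    cutoff: float = 4.0,
    skip_failures: bool = True,
):
    """Map (complex, label) pairs to (F, N, label) triples for training."""
    out = []
    for cs, label in dataset:
        try:
            F, N = prepare_graph(cs, feature_set, scheme, cutoff)
        except Exception as exc:
            if not skip_failures:
                raise
            warnings.warn(f"{cs.complex_id}: skipped ({exc})")
            continue
        out.append((F, N, label))
    return out
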