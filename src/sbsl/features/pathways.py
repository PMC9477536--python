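"""Pathway co-participation of a gene pair.

Uses the same hypergeometric expression as the mutual-exclusivity features,
with nA/nB = pathways containing each gene, nAB = pathways containing both,
and nT = total pathways. Note the tail direction: co-participation evidence
is a *high* overlap, yet the expression is evaluated exactly as for
exclusivity (its published form), so strongly co-participating pairs get
values near 1 rather than near 0. The classifier downstream is indifferent
to the orientation of a monotone transform.
"""

from __future__ import annotations

from typing import Dict, Set, Tuple

import numpy as np

from ..datatypes import canonical_pair
from .mutex import MutexCounts, hypergeom_exclusivity

__all__ = ["pathway_coparticipation"]


def pathway_coparticipation(pair: Tuple[str, str], pathways: Dict[str, Set[str]]) -> float:
    """Hypergeometric co-membership value; nan when a gene is in no pathway."""
    if not pathways:
        raise ValueError("pathway collection is empty")
    a, b = canonical_pair(*pair)
    nT = len(pathways)
    in_a = [name for name, members in pathways.items() if a in members]
    in_b = [name for name, members in pathways.items() if b in members]
    nA, nB = len(in_a), len(in_b)
    if nA == 0 or nB == 0:
        return np.nan
    nAB = len(set(in_a) & set(in_b))
    return hypergeom_exclusivity(MutexCounts(nA=nA, nB=nB, nAB=nAB, nT=nT))
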