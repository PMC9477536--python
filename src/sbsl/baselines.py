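"""Diagnostic baseline that memorizes the label graph.

This is deliberately NOT a molecular-feature model: it scores a pair purely
from the structure of the training label graph, by similarity-weighted
nearest-neighbour voting over labelled pairs. Genes with similar label rows
(as in selection-biased gold standards) transfer their partners' labels to
each other. Under pair-disjoint ("none") splits on biased label sets it
looks excellent; under double gene holdout it has no information and
collapses to chance — which is exactly what it exists to demonstrate.
"""

from __future__ import annotations

from typing import Sequence, Tuple

import numpy as np

from .datatypes import SLLabelSet, canonical_pair

__all__ = ["LabelGraphBaseline"]


class LabelGraphBaseline:
    """Similarity-weighted label-graph vote, fit on a training label set."""

    def __init__(self, train: SLLabelSet):
        self.genes = train.genes()
        gidx = {g: i for i, g in enumerate(self.genes)}
        n = len(self.genes)
        signed = np.zeros((n, n))
        labelled = np.zeros((n, n))
        positive = np.zeros((n, n))
        for (a, b), lab in zip(train.pairs, train.labels):
            i, j = gidx[a], gidx[b]
            signed[i, j] = signed[j, i] = 1.0 if lab == 1 else -1.0
            labelled[i, j] = labelled[j, i] = 1.0
            positive[i, j] = positive[j, i] = float(lab)
        norms = np.linalg.norm(signed, axis=1)
        unit = np.divide(signed, norms[:, None], out=np.zeros_like(signed), where=norms[:, None] > 0)
        sim = np.clip(unit @ unit.T, 0.0, None)
        np.fill_diagonal(sim, 1.0)
        self._gidx = gidx
        self._sim = sim
        self._labelled = labelled
        self._positive = positive
        # precompute similarity-propagated vote matrices
        self._num = sim @ positive @ sim.T
        self._den = sim @ labelled @ sim.T

    def score_pair(self, gene_a: str, gene_b: str) -> float:
        a, b = canonical_pair(gene_a, gene_b)
        ia = self._gidx.get(a)
        ib = self._gidx.get(b)
        if ia is None or ib is None:
            return 0.5  # unseen gene: no graph information
        den = self._den[ia, ib]
        if den <= 1e-12:
            return 0.5
        return float(self._num[ia, ib] / den)

    def score(self, pairs: Sequence[Tuple[str, str]]) -> np.ndarray:
        return np.array([self.score_pair(a, b) for a, b in pairs])
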