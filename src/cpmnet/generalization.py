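"""Cross-condition and cross-dataset application of trained models.

Two transfer regimes, mirroring how a trained connectome model can be
validated outside its training condition or sample:

* **Cross-condition** (same subjects, different scan condition): inside the
  usual leave-one-out loop, edges are selected and the strength model is
  fit on the training condition's matrices of n-1 subjects, and the
  held-out subject's strengths are computed from their *test*-condition
  matrix before applying the fitted polynomial.
* **Cross-dataset** (different subjects, possibly a different trait scale):
  the per-fold masks of a full cross-validated run are intersected —
  an edge survives only if selected in every fold — and these intersection
  networks are applied to the external stack. Performance is the Spearman
  correlation between network strength and trait, which is equivalent to
  prediction because the test data never touched training; no coefficients
  are transferred, so trait scales need not match.

The default edge-selection threshold for generalization analyses is the
less conservative P < 0.01, which limits overfitting to training-condition
idiosyncrasies.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .cpm import (
    NETWORKS,
    EdgeMaskPair,
    NetworkScore,
    PredictionResult,
    ThresholdSpec,
    make_folds,
    network_strength,
    score_performance,
    _cv_loop,
)
from .io import ConnectivityStack

DEFAULT_TRANSFER_THRESHOLD = ThresholdSpec("p", 0.01)


@dataclass
class IntersectionNetwork:
    """Edges selected in every cross-validation fold (CN and AN separately)."""

    pos: np.ndarray  # bool (n_edges,)
    neg: np.ndarray
    n_nodes: int
    provenance: dict = field(default_factory=dict)

    def as_mask_pair(self) -> EdgeMaskPair:
        return EdgeMaskPair(self.pos, self.neg, self.n_nodes)

    @property
    def is_empty(self) -> bool:
        return not (self.pos.any() or self.neg.any())


def intersect_masks(
    fold_masks: Sequence[EdgeMaskPair], provenance: dict | None = None
) -> IntersectionNetwork:
    """Logical AND of per-fold CN and AN masks.

    The result is a subset of every contributing fold mask. An empty
    intersection (both CN and AN) is allowed but warned about; downstream
    strength computation on empty masks returns zeros with a flag.
    """
    if not fold_masks:
        raise ValueError("need at least one fold mask")
    n_nodes = fold_masks[0].n_nodes
    pos = fold_masks[0].pos.copy()
    neg = fold_masks[0].neg.copy()
    for m in fold_masks[1:]:
        if m.n_nodes != n_nodes:
            raise ValueError("fold masks disagree on the node universe")
        pos &= m.pos
        neg &= m.neg
    net = IntersectionNetwork(pos, neg, n_nodes, dict(provenance or {}))
    if net.is_empty:
        warnings.warn("intersection network is empty (no edge survived all folds)")
    return net


def cross_condition_cv(
    train_stack: ConnectivityStack,
    test_stack: ConnectivityStack,
    trait: np.ndarray,
    threshold: ThresholdSpec | str = DEFAULT_TRANSFER_THRESHOLD,
    cv: str = "loo",
    k: int = 10,
    seed: int | None = None,
    covariates: np.ndarray | None = None,
    covariate_mode: str = "none",
) -> PredictionResult:
    """Cross-condition validation on a shared subject sample.

    Identical to ordinary cross-validated CPM except that the held-out
    subjects' network strengths come from ``test_stack``; with
    ``train_stack is test_stack`` the two are exactly equivalent.
    """
    if isinstance(threshold, str):
        threshold = ThresholdSpec.parse(threshold)
    if list(train_stack.subject_ids) != list(test_stack.subject_ids):
        raise ValueError("train and test stacks must share an identical subject list")
    if train_stack.n_nodes != test_stack.n_nodes:
        raise ValueError("train and test stacks must share the node universe")
    trait = np.asarray(trait, float)
    if np.isnan(trait).any():
        raise ValueError("trait contains missing values; drop those subjects first")
    folds = make_folds(train_stack.n_subjects, cv, k, seed)
    return _cv_loop(
        train_stack.edge_matrix(),
        test_stack.edge_matrix(),
        trait,
        threshold,
        folds,
        covariates,
        covariate_mode,
    )


def apply_external_model(
    intnet: IntersectionNetwork,
    test_stack: ConnectivityStack,
    trait: np.ndarray,
) -> dict[str, NetworkScore]:
    """Score an intersection network on an independent dataset.

    CN, AN, and combined strengths are computed for every test subject from
    the intersection masks (no coefficient refitting), and performance per
    network is the Spearman correlation between strength and trait, with
    the negative-correlation clamp applied to the percent-variance measure
    of the combined network. Empty masks yield a flagged zero score.
    """
    if intnet.n_nodes != test_stack.n_nodes:
        raise ValueError(
            "intersection network node universe does not match the test stack "
            f"({intnet.n_nodes} vs {test_stack.n_nodes}); restrict both to the "
            "shared covered nodes first"
        )
    trait = np.asarray(trait, float)
    if intnet.is_empty:
        warnings.warn("empty intersection network: zero performance reported")
        return {net: NetworkScore(0.0, 0.0, flagged=True) for net in NETWORKS}
    strengths = network_strength(test_stack.edge_matrix(), intnet.as_mask_pair())
    out: dict[str, NetworkScore] = {}
    for net in NETWORKS:
        s = strengths.by_network(net)
        if np.ptp(s) == 0:
            out[net] = NetworkScore(0.0, 0.0, flagged=True)
        else:
            out[net] = score_performance(s, trait)
    return out
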