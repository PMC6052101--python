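"""Significance machinery: family-aware permutation tests, FDR, exact
Mann-Whitney U, Steiger's z for dependent correlations, and split-half
stability.

Because cross-validation folds are not independent, model significance is
assessed by permutation: the trait vector is shuffled, the full CPM
cross-validation loop is re-run, and the p-value is the fraction of
permutations whose predicted-vs-permuted-trait correlation exceeds the
observed one. In samples with siblings the trait is heritable, so free
shuffling would break the null's dependence structure; permutations are
therefore restricted to exchangeability blocks: trait values may move only
between siblings of the same type (non-twin / DZ / MZ) within a family, and
between whole families with identical sibling-type composition.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .cpm import (
    PredictionResult,
    ThresholdSpec,
    edge_trait_association,
    fit_strength_model,
    network_strength,
    score_performance,
    select_edges,
)
from .io import CohortTable, ConnectivityStack

#: Sibling-type label given to members of size-1 families; all singletons
#: form one exchange group regardless of their recorded sibling type.
SINGLETON = "singleton"


@dataclass
class Family:
    family_id: str
    indices: np.ndarray  # cohort row positions
    sibling_types: list[str]

    @property
    def signature(self) -> tuple[str, ...]:
        return tuple(sorted(self.sibling_types))

    def slots_by_type(self) -> dict[str, np.ndarray]:
        """Member positions grouped by sibling type, in cohort order."""
        out: dict[str, list[int]] = {}
        for idx, st in zip(self.indices, self.sibling_types):
            out.setdefault(st, []).append(int(idx))
        return {t: np.array(v) for t, v in out.items()}


@dataclass
class ExchangeabilityBlocks:
    """Families grouped by identical structure (sibling-type multiset)."""

    families: list[Family]
    signature_groups: dict[tuple[str, ...], list[int]]  # signature -> family positions

    @property
    def n_subjects(self) -> int:
        return sum(len(f.indices) for f in self.families)


def build_blocks(cohort: CohortTable) -> ExchangeabilityBlocks:
    """Derive exchangeability blocks from a cohort's family columns.

    Subjects with missing family information are assumed to have no
    siblings in the sample and become singleton families. Every size-1
    family is relabeled ``singleton`` so that all singletons form one large
    exchange group.
    """
    t = cohort.table
    n = len(t)
    fam_col = t["family_id"] if "family_id" in t.columns else None
    sib_col = t["sibling_type"] if "sibling_type" in t.columns else None

    members: dict[str, list[int]] = {}
    order: list[str] = []
    for i in range(n):
        fid = None if fam_col is None else fam_col.iloc[i]
        if fid is None or (isinstance(fid, float) and np.isnan(fid)) or fid == "":
            fid = f"__solo_{i}"
        fid = str(fid)
        if fid not in members:
            members[fid] = []
            order.append(fid)
        members[fid].append(i)

    families: list[Family] = []
    for fid in order:
        idx = np.array(members[fid])
        if sib_col is None:
            types = ["nontwin"] * len(idx)
        else:
            types = [
                "nontwin" if (isinstance(s, float) and np.isnan(s)) else str(s)
                for s in sib_col.iloc[idx].tolist()
            ]
        if len(idx) == 1:
            types = [SINGLETON]
        families.append(Family(fid, idx, types))

    groups: dict[tuple[str, ...], list[int]] = {}
    for pos, fam in enumerate(families):
        groups.setdefault(fam.signature, []).append(pos)
    return ExchangeabilityBlocks(families, groups)


def permute_trait(
    trait: np.ndarray, blocks: ExchangeabilityBlocks, rng: np.random.Generator
) -> np.ndarray:
    """One restricted permutation of the trait vector.

    Two stages are composed on every draw: (a) within each group of
    identically structured families, whole-family trait blocks are randomly
    permuted across families, member slots matched by sibling type; (b)
    within each family, values are randomly permuted among members of the
    same sibling type. The output is always a permutation of the input
    multiset.
    """
    trait = np.asarray(trait, float)
    if len(trait) != blocks.n_subjects:
        raise ValueError("trait length does not match blocks")
    out = np.empty_like(trait)
    for sig in sorted(blocks.signature_groups):
        fam_pos = blocks.signature_groups[sig]
        perm = rng.permutation(len(fam_pos))
        for dest_i, src_i in enumerate(perm):
            dest = blocks.families[fam_pos[dest_i]]
            src = blocks.families[fam_pos[src_i]]
            dslots, sslots = dest.slots_by_type(), src.slots_by_type()
            for st, dpos in dslots.items():
                vals = trait[sslots[st]]
                out[dpos] = vals[rng.permutation(len(vals))]
    return out


def enumerate_reachable(
    trait: np.ndarray, blocks: ExchangeabilityBlocks
) -> set[tuple[float, ...]]:
    """Exhaustively enumerate every trait vector reachable by
    :func:`permute_trait` (small cohorts only; used for validation)."""
    trait = np.asarray(trait, float)
    reachable: set[tuple[float, ...]] = set()

    group_options: list[list[list[tuple[np.ndarray, np.ndarray]]]] = []
    for sig in sorted(blocks.signature_groups):
        fam_pos = blocks.signature_groups[sig]
        per_perm: list[list[tuple[np.ndarray, np.ndarray]]] = []
        for perm in itertools.permutations(range(len(fam_pos))):
            assignments: list[tuple[np.ndarray, np.ndarray]] = []
            for dest_i, src_i in enumerate(perm):
                dest = blocks.families[fam_pos[dest_i]]
                src = blocks.families[fam_pos[src_i]]
                dslots, sslots = dest.slots_by_type(), src.slots_by_type()
                for st, dpos in dslots.items():
                    assignments.append((dpos, sslots[st]))
            per_perm.append(assignments)
        group_options.append(per_perm)

    def expand(base: np.ndarray, pieces: list[tuple[np.ndarray, np.ndarray]], k: int):
        if k == len(pieces):
            reachable.add(tuple(base))
            return
        dpos, spos = pieces[k]
        for order in itertools.permutations(range(len(spos))):
            nxt = base.copy()
            nxt[dpos] = trait[spos[list(order)]]
            expand(nxt, pieces, k + 1)

    for combo in itertools.product(*group_options):
        pieces = [piece for group in combo for piece in group]
        expand(np.empty_like(trait), pieces, 0)
    return reachable


@dataclass
class NullDistribution:
    observed: float
    null_values: np.ndarray
    n_iterations: int
    seed: int | None
    p_value: float


def permutation_pvalue(
    model_runner: Callable[[ConnectivityStack | np.ndarray, np.ndarray], float] | None,
    stack: ConnectivityStack | np.ndarray,
    trait: np.ndarray,
    blocks: ExchangeabilityBlocks,
    n_iterations: int = 1000,
    seed: int | None = None,
    *,
    threshold: ThresholdSpec | str | None = None,
    cv: str = "loo",
    k: int = 10,
    cv_seed: int | None = None,
) -> NullDistribution:
    """Family-aware permutation p-value of a model's performance.

    The full cross-validated pipeline is re-run per permuted trait, and
    ``p`` is the plain fraction of iterations on which the permuted-trait
    statistic strictly exceeds the observed one (ties count for the
    observed side), so ``p = 0`` is reportable as ``p < 1/B``.

    ``model_runner(stack, trait)`` must return the performance statistic
    (Spearman ``r_s`` of predicted vs true trait). Passing
    ``model_runner=None`` selects the built-in combined-network CPM with
    the given ``threshold`` and CV scheme, evaluated for all permutations
    through the batched kernel (:func:`cpmnet.cpm.batched_cpm_combined`) —
    identical results, orders of magnitude faster.
    """
    if n_iterations < 1:
        raise ValueError("need at least one permutation iteration")
    rng = np.random.default_rng(seed)
    trait = np.asarray(trait, float)

    if model_runner is None:
        from .cpm import batched_cpm_combined, make_folds

        if threshold is None:
            threshold = ThresholdSpec("p", 0.01)
        if isinstance(threshold, str):
            threshold = ThresholdSpec.parse(threshold)
        edges = (
            stack.edge_matrix() if isinstance(stack, ConnectivityStack) else np.asarray(stack, float)
        )
        folds = make_folds(edges.shape[0], cv, k, cv_seed)
        t_mat = np.empty((len(trait), n_iterations + 1))
        t_mat[:, 0] = trait
        for b in range(n_iterations):
            t_mat[:, b + 1] = permute_trait(trait, blocks, rng)
        r_s, _ = batched_cpm_combined(edges, t_mat, threshold, folds)
        observed, null = float(r_s[0]), r_s[1:]
    else:
        observed = float(model_runner(stack, trait))
        null = np.empty(n_iterations)
        for b in range(n_iterations):
            null[b] = model_runner(stack, permute_trait(trait, blocks, rng))
    p = float(np.mean(null > observed))
    return NullDistribution(observed, null, n_iterations, seed, p)


def fdr_bh(p_values: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values (monotone, capped at 1)."""
    p = np.asarray(p_values, float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    _, q, _, _ = multipletests(p, method="fdr_bh")
    return q


# ---------------------------------------------------------------------------
# Mann-Whitney U (exact)
# ---------------------------------------------------------------------------

@dataclass
class MannWhitneyResult:
    u_x: float  # U statistic of the first sample
    rank_sum_x: float
    p_value: float  # two-sided
    exact: bool


def _exact_rank_sum_distribution(ranks2: np.ndarray, k: int) -> dict[int, int]:
    """Counts of each achievable k-subset sum of doubled midranks (DP)."""
    counts: list[dict[int, int]] = [dict() for _ in range(k + 1)]
    counts[0][0] = 1
    for r in ranks2:
        for j in range(min(k, len(ranks2)), 0, -1):
            for s, c in list(counts[j - 1].items()):
                counts[j][s + r] = counts[j].get(s + r, 0) + c
    return counts[k]


def mannwhitney_exact(x: Sequence[float], y: Sequence[float]) -> MannWhitneyResult:
    """Exact two-sided Mann-Whitney U test by enumeration of rank
    assignments.

    Pooled midranks are computed (ties averaged), and the null distribution
    of the smaller group's rank sum is obtained by exhaustive enumeration of
    all C(n_x + n_y, n_y) assignments of the observed (mid)ranks to groups.
    The two-sided p is ``min(1, 2 * min(P(R <= r_obs), P(R >= r_obs)))``.
    For pooled sizes above 25 the normal approximation is used and the
    result flagged non-exact.
    """
    x = np.asarray(list(x), float)
    y = np.asarray(list(y), float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both groups must be non-empty")
    n_x, n_y = len(x), len(y)
    n = n_x + n_y
    ranks = stats.rankdata(np.concatenate([x, y]))
    rank_sum_x = float(ranks[:n_x].sum())
    u_x = rank_sum_x - n_x * (n_x + 1) / 2.0

    if n > 25:
        res = stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
        return MannWhitneyResult(u_x, rank_sum_x, float(res.pvalue), exact=False)

    # Work with the smaller group's rank sum; doubled ranks are integers.
    ranks2 = np.round(ranks * 2).astype(int)
    if n_y <= n_x:
        k, obs2 = n_y, int(round(2 * ranks[n_x:].sum()))
    else:
        k, obs2 = n_x, int(round(2 * rank_sum_x))
    dist = _exact_rank_sum_distribution(ranks2, k)
    total = sum(dist.values())
    p_le = sum(c for s, c in dist.items() if s <= obs2) / total
    p_ge = sum(c for s, c in dist.items() if s >= obs2) / total
    p = min(1.0, 2.0 * min(p_le, p_ge))
    return MannWhitneyResult(u_x, rank_sum_x, p, exact=True)


# ---------------------------------------------------------------------------
# Steiger's z
# ---------------------------------------------------------------------------

@dataclass
class SteigerResult:
    z: float
    p_value: float  # one-tailed, upper


def steiger_z(r1: float, r2: float, r12: float, n: int) -> SteigerResult:
    """Steiger's Z1* for two dependent correlations sharing one variable.

    ``r1 = corr(a, y)`` and ``r2 = corr(b, y)`` are compared given
    ``r12 = corr(a, b)``, all measured on the same ``n`` subjects (here:
    two models' predictions ``a, b`` against the same trait ``y``). The
    Fisher-z difference is scaled by the pooled covariance term of Steiger
    (1980), using the mean correlation ``rbar = (r1 + r2) / 2`` as in the
    Lee-Preacher implementation; the one-tailed p comes from the standard
    normal upper tail.
    """
    for name, r in (("r1", r1), ("r2", r2), ("r12", r12)):
        if not -1 < r < 1:
            raise ValueError(f"{name} must lie strictly in (-1, 1)")
    if n < 4:
        raise ValueError("need at least 4 subjects")
    rbar = (r1 + r2) / 2.0
    psi = r12 * (1 - 2 * rbar**2) - 0.5 * rbar**2 * (1 - 2 * rbar**2 - r12**2)
    s = psi / (1 - rbar**2) ** 2
    z = (np.arctanh(r1) - np.arctanh(r2)) * np.sqrt((n - 3) / (2.0 - 2.0 * s))
    return SteigerResult(float(z), float(stats.norm.sf(z)))


# ---------------------------------------------------------------------------
# Split-half stability
# ---------------------------------------------------------------------------

@dataclass
class SplitHalfResult:
    r_s: np.ndarray  # per-iteration combined-network performance
    degrees_pos: np.ndarray  # iterations x nodes CN degree of trained masks
    degrees_neg: np.ndarray
    n_iterations: int
    seed: int | None


def split_half_stability(
    stack: ConnectivityStack | np.ndarray,
    trait: np.ndarray,
    threshold: ThresholdSpec | str = ThresholdSpec("p", 0.01),
    n_iterations: int = 1000,
    seed: int | None = None,
) -> SplitHalfResult:
    """Stability of model performance and anatomy under split-half training.

    Per iteration: subjects are randomly split in half, a single CPM model
    (edge selection + combined-network fit) is trained on one half and
    applied to the other, and the held-out Spearman ``r_s`` is recorded
    along with the trained mask's CN/AN node-degree vectors (for
    cross-iteration anatomy stability)."""
    from .anatomy import node_degree

    if isinstance(threshold, str):
        threshold = ThresholdSpec.parse(threshold)
    edges = stack.edge_matrix() if isinstance(stack, ConnectivityStack) else np.asarray(stack, float)
    trait = np.asarray(trait, float)
    n = edges.shape[0]
    if n < 8:
        raise ValueError("need at least 8 subjects for split-half analysis")
    rng = np.random.default_rng(seed)
    half = n // 2
    r_s = np.empty(n_iterations)
    deg_pos = deg_neg = None
    for it in range(n_iterations):
        perm = rng.permutation(n)
        a, b = perm[:half], perm[half:]
        r, p = edge_trait_association(edges[a], trait[a])
        masks = select_edges(r, p, threshold)
        if deg_pos is None:
            deg_pos = np.empty((n_iterations, masks.n_nodes), int)
            deg_neg = np.empty((n_iterations, masks.n_nodes), int)
        deg_pos[it] = node_degree(masks.pos, masks.n_nodes)
        deg_neg[it] = node_degree(masks.neg, masks.n_nodes)
        s_a = network_strength(edges[a], masks).combined
        s_b = network_strength(edges[b], masks).combined
        if np.ptp(s_a) == 0 or np.ptp(s_b) == 0:
            r_s[it] = 0.0
            continue
        coef = fit_strength_model(s_a, trait[a])
        pred = coef[0] + coef[1] * s_b
        r_s[it] = score_performance(pred, trait[b]).r_s
    return SplitHalfResult(r_s, deg_pos, deg_neg, n_iterations, seed)
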