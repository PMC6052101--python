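"""Synthetic cohorts and multi-condition connectivity stacks with ground truth.

The study's real connectomes are access-restricted, so testing and
calibration run on generated data that carries the statistical structure
the analysis assumes:

* a latent trait with family-structured covariance — for subject ``s`` in
  family ``f``, ``g_s = sqrt(rho_fam) * u_f + sqrt(1 - rho_fam) * e_s`` with
  ``u, e`` standard normal, so siblings correlate at ``rho_fam``;
* a planted subset of edges whose Fisher-z strengths depend linearly on the
  trait, with condition-specific amplification ``alpha`` (task conditions
  amplify the edge-trait relationship more than rest);
* optional sex-specific planted circuits, disjoint edge sets whose trait
  coupling is nonzero only within one sex and can be amplified by different
  conditions;
* a motion nuisance: per-subject displacement loads onto a fixed random
  edge pattern.

Edge ``(i, j)`` of subject ``s`` in condition ``k`` is drawn as::

    c_ij = mu_ij + alpha_k * beta * g_s * d_ij + sex terms
           + lambda * motion_sk * w_ij + N(0, sigma^2)

where ``d_ij`` is +1 on planted positive edges, -1 on planted negative
edges, 0 elsewhere, ``mu_ij ~ N(0.3, 0.1^2)`` is a cohort-level baseline on
the Fisher-z scale, and ``w_ij ~ N(0, 1)`` is the motion loading pattern.
For a planted edge the population edge-trait correlation is
``alpha * beta / sqrt(alpha^2 * beta^2 + sigma^2)`` (trait variance 1,
motion term ignored), which is how effect sizes are chosen in tests.

All randomness flows through a single integer seed; identical seeds give
bit-identical cohorts and stacks.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .edges import n_edges, vec_to_sym
from .io import CohortTable, ConnectivityStack, NodeAtlas

#: Default condition set: two task conditions amplifying the trait signal at
#: 1.0 and one rest condition at 0.5.
DEFAULT_CONDITIONS: dict[str, float] = {"task1": 1.0, "task2": 1.0, "rest1": 0.5}

#: Default family composition, as proportions of subjects.
DEFAULT_FAMILY_CONFIG: dict[str, float] = {
    "singleton": 0.4,
    "nontwin": 0.2,
    "DZ": 0.2,
    "MZ": 0.2,
}


@dataclass
class SyntheticGroundTruth:
    """Everything needed to audit a synthetic cohort against the generator."""

    n_nodes: int
    planted_pos_edges: np.ndarray  # edge indices, +1 coupling
    planted_neg_edges: np.ndarray  # edge indices, -1 coupling
    alpha: dict[str, float]  # per-condition amplification
    beta: float  # trait effect size (Fisher-z units per trait s.d.)
    sigma: float  # edge noise s.d.
    lambda_motion: float  # motion loading scale
    rho_fam: float  # family share of trait variance
    male_edges: np.ndarray = field(default_factory=lambda: np.array([], int))
    female_edges: np.ndarray = field(default_factory=lambda: np.array([], int))
    male_alpha: dict[str, float] = field(default_factory=dict)
    female_alpha: dict[str, float] = field(default_factory=dict)
    sex_beta: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.planted_pos_edges = np.asarray(self.planted_pos_edges, int)
        self.planted_neg_edges = np.asarray(self.planted_neg_edges, int)
        self.male_edges = np.asarray(self.male_edges, int)
        self.female_edges = np.asarray(self.female_edges, int)
        if np.intersect1d(self.planted_pos_edges, self.planted_neg_edges).size:
            raise ValueError("planted positive and negative edge sets overlap")
        if not 0 <= self.rho_fam < 1:
            raise ValueError("rho_fam must lie in [0, 1)")
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if any(a < 0 for a in self.alpha.values()):
            raise ValueError("condition amplification alpha must be >= 0")

    @property
    def conditions(self) -> list[str]:
        return list(self.alpha)

    def planted_direction(self) -> np.ndarray:
        """Per-edge coupling d in {-1, 0, +1} over the edge universe."""
        d = np.zeros(n_edges(self.n_nodes))
        d[self.planted_pos_edges] = 1.0
        d[self.planted_neg_edges] = -1.0
        return d

    def to_json(self, path: str | Path) -> None:
        rec = asdict(self)
        for k, v in rec.items():
            if isinstance(v, np.ndarray):
                rec[k] = v.tolist()
        Path(path).write_text(json.dumps(rec, indent=2, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "SyntheticGroundTruth":
        return cls(**json.loads(Path(path).read_text()))


def _build_families(
    n_subjects: int, family_config: Mapping[str, float], rng: np.random.Generator
) -> tuple[list[str], list[str]]:
    """Assign family ids and sibling types covering exactly n_subjects."""
    if abs(sum(family_config.values()) - 1.0) > 1e-9:
        raise ValueError("family proportions must sum to 1")
    fam_ids: list[str] = []
    sib_types: list[str] = []
    counter = 0
    kinds = list(family_config)
    probs = np.array([family_config[k] for k in kinds])
    while len(fam_ids) < n_subjects:
        kind = kinds[int(rng.choice(len(kinds), p=probs))]
        counter += 1
        fid = f"F{counter:04d}"
        if kind == "singleton" or n_subjects - len(fam_ids) < 2:
            fam_ids.append(fid)
            sib_types.append("nontwin")
        else:
            stype = {"nontwin": "nontwin", "DZ": "DZ", "MZ": "MZ"}[kind]
            fam_ids.extend([fid, fid])
            sib_types.extend([stype, stype])
    return fam_ids[:n_subjects], sib_types[:n_subjects]


def generate_cohort(
    n_subjects: int,
    family_config: Mapping[str, float] | None = None,
    sex_ratio: float = 0.5,
    trait_distribution: str = "normal",
    seed: int = 0,
    *,
    n_nodes: int = 268,
    conditions: Mapping[str, float] | None = None,
    rho_fam: float = 0.4,
    beta: float = 0.1,
    sigma: float = 0.25,
    lambda_motion: float = 0.05,
    sex_beta: float = 0.0,
    male_alpha: Mapping[str, float] | None = None,
    female_alpha: Mapping[str, float] | None = None,
    n_planted: int | None = None,
    trait_name: str = "gF",
    include_excluded: bool = False,
) -> tuple[CohortTable, SyntheticGroundTruth]:
    """Generate a cohort table and the ground truth for its connectomes.

    Parameters
    ----------
    n_subjects
        Cohort size (>= 4).
    family_config
        Proportions of subjects who are singletons, non-twin sibling pairs,
        DZ twin pairs, and MZ twin pairs; must sum to 1.
    sex_ratio
        Probability of male (sex = 1); MZ twins are forced same-sex.
    trait_distribution
        ``"normal"`` keeps the latent standard-normal trait; ``"pmat24"``
        maps it to an integer matrix-reasoning-like score (mean 17.5,
        s.d. 4.5, clipped to 5..24).
    rho_fam
        Share of trait variance carried by the family component.
    beta, sigma, lambda_motion
        Trait effect size, edge noise s.d., and motion loading scale of the
        downstream stack generator (recorded in the ground truth).
    conditions
        Mapping condition name -> amplification alpha (default two task
        conditions at 1.0 and one rest at 0.5).
    sex_beta, male_alpha, female_alpha
        Effect size and per-condition amplification of the two disjoint
        sex-specific planted circuits; ``sex_beta = 0`` disables them.
    n_planted
        Planted positive (and, equally, negative) edge count; default 1% of
        the edge universe, at least 10.
    include_excluded
        If True, ~10% of subjects are drawn with motion above the standard
        exclusion thresholds, to exercise the motion filter.
    """
    if n_subjects < 4:
        raise ValueError("need at least 4 subjects")
    family_config = dict(family_config or DEFAULT_FAMILY_CONFIG)
    conditions = dict(conditions or DEFAULT_CONDITIONS)
    rng = np.random.default_rng(seed)

    fam_ids, sib_types = _build_families(n_subjects, family_config, rng)

    # Family-structured latent trait.
    uniq = sorted(set(fam_ids))
    u = dict(zip(uniq, rng.standard_normal(len(uniq))))
    e = rng.standard_normal(n_subjects)
    g = np.sqrt(rho_fam) * np.array([u[f] for f in fam_ids]) + np.sqrt(1 - rho_fam) * e

    if trait_distribution == "normal":
        trait = g
    elif trait_distribution == "pmat24":
        trait = np.clip(np.round(17.5 + 4.5 * g), 5, 24)
    else:
        raise ValueError(f"unknown trait_distribution {trait_distribution!r}")

    # Sex: MZ pairs share sex by construction.
    sex = (rng.random(n_subjects) < sex_ratio).astype(int)
    fam_first: dict[str, int] = {}
    for i, (fid, st) in enumerate(zip(fam_ids, sib_types)):
        if st == "MZ":
            if fid in fam_first:
                sex[i] = sex[fam_first[fid]]
            else:
                fam_first[fid] = i

    rows = {
        "subject_id": [f"S{i + 1:04d}" for i in range(n_subjects)],
        "family_id": fam_ids,
        "sibling_type": sib_types,
        "sex": sex,
        trait_name: trait,
    }

    # Per-condition head motion, log-normal, kept under the default
    # exclusion thresholds unless excluded subjects were requested.
    excluded = (
        rng.random(n_subjects) < 0.1 if include_excluded else np.zeros(n_subjects, bool)
    )
    for cond in conditions:
        mean_fd = np.exp(rng.normal(np.log(0.06), 0.25, n_subjects))
        mean_fd = np.minimum(mean_fd, 0.095)
        mean_fd[excluded] = rng.uniform(0.105, 0.2, excluded.sum())
        max_fd = np.minimum(mean_fd * rng.uniform(1.2, 1.4, n_subjects), 0.145)
        max_fd[excluded] = np.maximum(max_fd[excluded], 0.16)
        rows[f"motion_mean_{cond}"] = mean_fd
        rows[f"motion_max_{cond}"] = max_fd

    cohort = CohortTable(pd.DataFrame(rows))

    # Planted circuits: disjoint positive / negative / male / female sets.
    e_total = n_edges(n_nodes)
    if n_planted is None:
        n_planted = max(10, round(0.01 * e_total))
    n_sex = n_planted if sex_beta != 0 else 0
    n_draw = 2 * n_planted + 2 * n_sex
    if n_draw > e_total:
        raise ValueError("planted edge sets exceed the edge universe")
    chosen = rng.choice(e_total, size=n_draw, replace=False)
    gt = SyntheticGroundTruth(
        n_nodes=n_nodes,
        planted_pos_edges=np.sort(chosen[:n_planted]),
        planted_neg_edges=np.sort(chosen[n_planted : 2 * n_planted]),
        alpha=dict(conditions),
        beta=beta,
        sigma=sigma,
        lambda_motion=lambda_motion,
        rho_fam=rho_fam,
        male_edges=np.sort(chosen[2 * n_planted : 2 * n_planted + n_sex]),
        female_edges=np.sort(chosen[2 * n_planted + n_sex :]),
        male_alpha=dict(male_alpha or {}),
        female_alpha=dict(female_alpha or {}),
        sex_beta=sex_beta,
        seed=seed,
    )
    return cohort, gt


def generate_stack(
    cohort: CohortTable,
    condition: str,
    ground_truth: SyntheticGroundTruth,
    n_nodes: int | None = None,
    seed: int | None = None,
    trait_name: str = "gF",
) -> ConnectivityStack:
    """Generate one condition's connectivity stack for a synthetic cohort.

    The trait entering the edge model is the cohort trait standardized to
    unit variance, so ``beta`` is in Fisher-z units per trait s.d. The
    cohort-level edge baseline ``mu`` and motion loadings ``w`` are drawn
    from the ground-truth seed (shared across conditions); condition noise
    is drawn from ``seed`` (default: derived from the ground-truth seed and
    the condition name).
    """
    gt = ground_truth
    if n_nodes is None:
        n_nodes = gt.n_nodes
    if n_nodes != gt.n_nodes:
        raise ValueError("n_nodes does not match ground truth")
    if condition not in gt.alpha:
        raise ValueError(f"condition {condition!r} has no amplification in ground truth")
    alpha = gt.alpha[condition]
    if alpha < 0:
        raise ValueError("alpha must be >= 0")

    e_total = n_edges(n_nodes)
    base_rng = np.random.default_rng(gt.seed)
    mu = base_rng.normal(0.3, 0.1, e_total)
    w = base_rng.standard_normal(e_total)

    if seed is None:
        cond_key = zlib.crc32(condition.encode()) % (2**31)
        rng = np.random.default_rng(np.random.SeedSequence([gt.seed, cond_key]))
    else:
        rng = np.random.default_rng(seed)

    trait = cohort.trait(trait_name)
    sdev = trait.std()
    if sdev == 0:
        raise ValueError("cohort trait is constant")
    g = (trait - trait.mean()) / sdev

    d = gt.planted_direction()
    n_sub = cohort.n_subjects
    motion_col = f"motion_mean_{condition}"
    motion = (
        cohort.table[motion_col].to_numpy(float)
        if motion_col in cohort.table.columns
        else np.zeros(n_sub)
    )

    vals = (
        mu[None, :]
        + alpha * gt.beta * g[:, None] * d[None, :]
        + gt.lambda_motion * motion[:, None] * w[None, :]
        + rng.normal(0.0, gt.sigma, (n_sub, e_total))
    )

    if gt.sex_beta != 0:
        sex = cohort.table["sex"].to_numpy(int)
        for edges, alphas, is_male in (
            (gt.male_edges, gt.male_alpha, 1),
            (gt.female_edges, gt.female_alpha, 0),
        ):
            a = alphas.get(condition, 0.0)
            if a and edges.size:
                mask = (sex == is_male).astype(float)
                vals[:, edges] += a * gt.sex_beta * (mask * g)[:, None]

    return ConnectivityStack(condition, cohort.subject_ids, vec_to_sym(vals, n_nodes))


def generate_timecourses(
    n_nodes: int,
    n_frames: int,
    seed: int = 0,
    ar: float = 0.3,
) -> np.ndarray:
    """Simple AR(1) node time courses (nodes x frames).

    Exists solely to exercise connectivity construction and time-course
    truncation; it does not attempt realistic spatial structure.
    """
    rng = np.random.default_rng(seed)
    tc = np.empty((n_nodes, n_frames))
    tc[:, 0] = rng.standard_normal(n_nodes)
    innov = rng.standard_normal((n_nodes, n_frames)) * np.sqrt(1 - ar**2)
    for t in range(1, n_frames):
        tc[:, t] = ar * tc[:, t - 1] + innov[:, t]
    return tc


def synthetic_atlas(
    n_nodes: int, seed: int = 0, n_uncovered: int = 0
) -> NodeAtlas:
    """A mirror-symmetric synthetic atlas with hemispheres, centroids, and
    canonical-network labels 1..10.

    Nodes come in left/right mirror pairs (odd ``n_nodes`` leaves one extra
    left node); ``n_uncovered`` nodes (chosen at random) are flagged
    uncovered to emulate restricted scan coverage.
    """
    rng = np.random.default_rng(seed)
    n_left = (n_nodes + 1) // 2
    xyz_left = np.column_stack(
        [
            -rng.uniform(5, 70, n_left),
            rng.uniform(-90, 60, n_left),
            rng.uniform(-50, 70, n_left),
        ]
    )
    nets_left = rng.integers(1, 11, n_left)
    xyz = np.vstack([xyz_left, xyz_left[: n_nodes - n_left] * [-1, 1, 1]])
    nets = np.concatenate([nets_left, nets_left[: n_nodes - n_left]])
    hemi = np.array(["L"] * n_left + ["R"] * (n_nodes - n_left))
    covered = np.ones(n_nodes, bool)
    if n_uncovered:
        covered[rng.choice(n_nodes, n_uncovered, replace=False)] = False
    df = pd.DataFrame(
        {
            "node_id": np.arange(1, n_nodes + 1),
            "hemisphere": hemi,
            "x": xyz[:, 0],
            "y": xyz[:, 1],
            "z": xyz[:, 2],
            "network": nets,
            "covered": covered,
        }
    )
    return NodeAtlas(df)
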