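"""End-to-end orchestration: synthesize or load data, run cross-validated
CPM per condition, permutation inference with FDR, task-vs-rest and
sex-stratified comparisons, generalization, and anatomy summaries, all
driven by one YAML config with mandatory seeds.

The stage order follows the analysis logic: per-condition models first,
their family-aware permutation p-values corrected across conditions by
FDR, a pooled Mann-Whitney comparison of task- vs rest-based model
performance (r_s^2, with the negative-correlation clamp applied before
pooling), per-stratum models compared by Steiger's z, cross-condition
transfer between the first task and first rest condition, and degree /
overlap / contribution / symmetry summaries of the intersection networks.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import yaml

from . import anatomy as anat
from . import inference as inf
from .cpm import ThresholdSpec, run_cpm_cv
from .generalization import cross_condition_cv, intersect_masks
from .io import CohortTable, ConnectivityStack, NodeAtlas, read_atlas, read_cohort, read_stack
from .synthetic import (
    DEFAULT_CONDITIONS,
    generate_cohort,
    generate_stack,
    synthetic_atlas,
)

log = logging.getLogger("cpmnet")

REPORT_VERSION = 1

#: Required report keys and the types of their values; validated on write.
REPORT_SCHEMA: dict[str, type] = {
    "report_version": int,
    "seed": int,
    "conditions": dict,
    "fdr_q": dict,
    "task_vs_rest": dict,
    "stratified": dict,
    "transfer": dict,
    "anatomy": dict,
}


@dataclass
class ConditionSpec:
    name: str
    kind: str  # "task" or "rest"
    alpha: float = 1.0

    def __post_init__(self) -> None:
        if self.kind not in ("task", "rest"):
            raise ValueError(f"condition kind must be task or rest, got {self.kind!r}")


@dataclass
class RunConfig:
    """Validated configuration of a full analysis run."""

    seed: int
    output_dir: str
    conditions: list[ConditionSpec]
    trait: str = "gF"
    threshold: str = "p:0.01"
    cv: str = "loo"
    k: int = 10
    permutation_iters: int = 100
    stratify: str | None = "sex"
    # synthetic-cohort inputs (used when no file paths are given)
    n_subjects: int = 120
    n_nodes: int = 40
    beta: float = 0.1
    sigma: float = 0.25
    rho_fam: float = 0.4
    # file inputs (all three must be set to use on-disk data)
    atlas_path: str | None = None
    cohort_path: str | None = None
    manifest_path: str | None = None

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("a seed is mandatory")
        if self.permutation_iters < 1:
            raise ValueError("permutation_iters must be >= 1")
        if not self.conditions:
            raise ValueError("at least one condition is required")
        ThresholdSpec.parse(self.threshold)
        paths = [self.atlas_path, self.cohort_path, self.manifest_path]
        if any(paths) and not all(paths):
            raise ValueError("atlas_path, cohort_path and manifest_path must be set together")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        conds = [ConditionSpec(**c) for c in raw.pop("conditions")]
        return cls(conditions=conds, **raw)


def validate_report(report: Mapping[str, Any]) -> None:
    """Check the report against the versioned schema before writing."""
    for key, typ in REPORT_SCHEMA.items():
        if key not in report:
            raise ValueError(f"report missing key {key!r}")
        if not isinstance(report[key], typ):
            raise ValueError(f"report key {key!r} has type {type(report[key]).__name__}, expected {typ.__name__}")
    if report["report_version"] != REPORT_VERSION:
        raise ValueError("report_version mismatch")


def _load_inputs(
    config: RunConfig,
) -> tuple[NodeAtlas, CohortTable, dict[str, ConnectivityStack]]:
    if config.atlas_path:
        atlas = read_atlas(config.atlas_path)
        cohort = read_cohort(config.cohort_path)
        stacks = {
            c.name: read_stack(config.manifest_path, c.name, cohort.subject_ids)
            for c in config.conditions
        }
        return atlas, cohort, stacks
    log.info("generating synthetic cohort (n=%d, nodes=%d)", config.n_subjects, config.n_nodes)
    atlas = synthetic_atlas(config.n_nodes, seed=config.seed)
    alphas = {c.name: c.alpha for c in config.conditions}
    cohort, gt = generate_cohort(
        config.n_subjects,
        seed=config.seed,
        n_nodes=config.n_nodes,
        conditions=alphas,
        beta=config.beta,
        sigma=config.sigma,
        rho_fam=config.rho_fam,
        trait_name=config.trait,
    )
    stacks = {c.name: generate_stack(cohort, c.name, gt) for c in config.conditions}
    return atlas, cohort, stacks


def run_full_analysis(config: RunConfig) -> dict[str, Any]:
    """Run every stage of the analysis and write ``report.json`` plus a
    human-readable summary to the configured output directory."""
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    threshold = ThresholdSpec.parse(config.threshold)
    rootseq = np.random.SeedSequence(config.seed)
    stage_seeds = {
        name: int(s.generate_state(1)[0] % (2**31))
        for name, s in zip(
            ("cv", "perm", "transfer"), rootseq.spawn(3)
        )
    }

    atlas, cohort, stacks = _load_inputs(config)
    trait = cohort.trait(config.trait)
    keep = ~np.isnan(trait)
    if not keep.all():
        log.info("dropping %d subjects with missing trait", int((~keep).sum()))
        kept_ids = [s for s, k in zip(cohort.subject_ids, keep) if k]
        cohort = cohort.subset(kept_ids)
        stacks = {c: s.subset_subjects(kept_ids) for c, s in stacks.items()}
        trait = cohort.trait(config.trait)

    blocks = inf.build_blocks(cohort)
    report: dict[str, Any] = {
        "report_version": REPORT_VERSION,
        "seed": config.seed,
        "conditions": {},
        "fdr_q": {},
        "task_vs_rest": {},
        "stratified": {},
        "transfer": {},
        "anatomy": {},
    }

    # --- Stage 1: per-condition CPM + permutation inference -----------------
    results = {}
    try:
        for cspec in config.conditions:
            stack = stacks[cspec.name]
            res = run_cpm_cv(
                stack, trait, threshold, cv=config.cv, k=config.k, seed=stage_seeds["cv"]
            )
            results[cspec.name] = res

            null = inf.permutation_pvalue(
                None, stack, trait, blocks,
                n_iterations=config.permutation_iters, seed=stage_seeds["perm"],
                threshold=threshold, cv=config.cv, k=config.k,
                cv_seed=stage_seeds["cv"],
            )
            report["conditions"][cspec.name] = {
                "kind": cspec.kind,
                "r_s": res.scores["combined"].r_s,
                "r_s_squared": res.scores["combined"].r_s_squared,
                "cn_r_s": res.scores["cn"].r_s,
                "an_r_s": res.scores["an"].r_s,
                "permutation_p": null.p_value,
                "permutation_iters": null.n_iterations,
            }
    except Exception as exc:  # pragma: no cover - stage naming only
        raise RuntimeError(f"stage 'cpm' failed: {exc}") from exc

    # --- Stage 2: FDR across conditions ------------------------------------
    names = [c.name for c in config.conditions]
    q = inf.fdr_bh(np.array([report["conditions"][n]["permutation_p"] for n in names]))
    report["fdr_q"] = {n: float(qv) for n, qv in zip(names, q)}

    # --- Stage 3: pooled task-vs-rest Mann-Whitney --------------------------
    task_r2 = [
        report["conditions"][c.name]["r_s_squared"]
        for c in config.conditions
        if c.kind == "task"
    ]
    rest_r2 = [
        report["conditions"][c.name]["r_s_squared"]
        for c in config.conditions
        if c.kind == "rest"
    ]
    if task_r2 and rest_r2:
        mw = inf.mannwhitney_exact(task_r2, rest_r2)
        report["task_vs_rest"] = {
            "task_r_s_squared": task_r2,
            "rest_r_s_squared": rest_r2,
            "u": mw.u_x,
            "rank_sum_task": mw.rank_sum_x,
            "p_two_sided": mw.p_value,
            "exact": mw.exact,
        }

    # --- Stage 4: stratified CPM + Steiger's z ------------------------------
    if config.stratify and config.stratify in cohort.table.columns:
        strata = sorted(cohort.table[config.stratify].unique())
        for stratum in strata:
            sel = cohort.table[config.stratify] == stratum
            ids = [s for s, m in zip(cohort.subject_ids, sel) if m]
            if len(ids) < 8:
                continue
            sub_trait = trait[sel.to_numpy()]
            entry: dict[str, Any] = {"n": len(ids), "conditions": {}, "steiger": {}}
            preds = {}
            for cspec in config.conditions:
                res = run_cpm_cv(
                    stacks[cspec.name].subset_subjects(ids),
                    sub_trait,
                    threshold,
                    cv=config.cv,
                    k=config.k,
                    seed=stage_seeds["cv"],
                )
                preds[cspec.name] = res.predicted["combined"]
                entry["conditions"][cspec.name] = {
                    "r_s": res.scores["combined"].r_s,
                    "r_s_squared": res.scores["combined"].r_s_squared,
                }
            for i, c1 in enumerate(names):
                for c2 in names[i + 1:]:
                    from scipy.stats import spearmanr

                    r1 = entry["conditions"][c1]["r_s"]
                    r2 = entry["conditions"][c2]["r_s"]
                    r12 = float(spearmanr(preds[c1], preds[c2]).statistic)
                    if max(abs(r1), abs(r2), abs(r12)) < 1:
                        st = inf.steiger_z(r1, r2, r12, len(ids))
                        entry["steiger"][f"{c1}_vs_{c2}"] = {
                            "z": st.z,
                            "p_one_tailed": st.p_value,
                        }
            report["stratified"][str(stratum)] = entry

    # --- Stage 5: cross-condition transfer ----------------------------------
    tasks = [c.name for c in config.conditions if c.kind == "task"]
    rests = [c.name for c in config.conditions if c.kind == "rest"]
    if tasks and rests:
        t, r = tasks[0], rests[0]
        for label, tr_name, te_name in ((f"{t}_to_{r}", t, r), (f"{r}_to_{t}", r, t)):
            res = cross_condition_cv(
                stacks[tr_name], stacks[te_name], trait, threshold,
                cv=config.cv, k=config.k, seed=stage_seeds["transfer"],
            )
            report["transfer"][label] = {
                "r_s": res.scores["combined"].r_s,
                "r_s_squared": res.scores["combined"].r_s_squared,
            }

    # --- Stage 6: anatomy ----------------------------------------------------
    homologs = anat.build_homolog_map(atlas)
    nets = atlas.networks
    degrees: dict[str, np.ndarray] = {}
    for cname, res in results.items():
        intnet = intersect_masks(res.fold_masks, {"condition": cname, "threshold": str(threshold)})
        dpos = anat.node_degree(intnet.pos, intnet.n_nodes)
        dneg = anat.node_degree(intnet.neg, intnet.n_nodes)
        degrees[cname] = dpos
        sym = anat.bilateral_symmetry(dpos + dneg, homologs, atlas)
        contrib = anat.network_contribution(intnet.pos, nets)
        report["anatomy"][cname] = {
            "n_cn_edges": int(intnet.pos.sum()),
            "n_an_edges": int(intnet.neg.sum()),
            "degree_pos_max": int(dpos.max()),
            "degree_neg_max": int(dneg.max()),
            "symmetry_left_to_right": sym["left_to_right"].r_s,
            "symmetry_right_to_left": sym["right_to_left"].r_s,
            "contribution_flagged": contrib.flagged,
        }
    overlap: dict[str, float] = {}
    fold_nets = {c: intersect_masks(results[c].fold_masks) for c in names}
    for i, c1 in enumerate(names):
        for c2 in names[i + 1:]:
            overlap[f"{c1}_vs_{c2}_cn"] = anat.edge_overlap(fold_nets[c1].pos, fold_nets[c2].pos)
            overlap[f"{c1}_vs_{c2}_an"] = anat.edge_overlap(fold_nets[c1].neg, fold_nets[c2].neg)
    report["anatomy"]["overlap_percent"] = {
        k: (None if np.isnan(v) else v) for k, v in overlap.items()
    }

    # --- Write outputs -------------------------------------------------------
    validate_report(report)
    report_path = out_dir / "report.json"
    report_path.write_text(json.dumps(report, indent=2, sort_keys=True))
    (out_dir / "summary.txt").write_text(_summarize(report))
    log.info("report written to %s", report_path)
    return report


def _summarize(report: Mapping[str, Any]) -> str:
    lines = ["CPM analysis summary", "====================", ""]
    ranked = sorted(
        report["conditions"].items(), key=lambda kv: -kv[1]["r_s_squared"]
    )
    for name, c in ranked:
        lines.append(
            f"{name:>10s} ({c['kind']}): r_s = {c['r_s']:+.3f}, "
            f"r_s^2 = {c['r_s_squared']:.1f}%  (perm p = {c['permutation_p']:.3g}, "
            f"q = {report['fdr_q'][name]:.3g})"
        )
    tv = report.get("task_vs_rest")
    if tv:
        lines.append("")
        lines.append(
            f"task vs rest (Mann-Whitney, pooled r_s^2): rank sum = "
            f"{tv['rank_sum_task']:.0f}, two-sided p = {tv['p_two_sided']:.3g}"
        )
    for label, t in report.get("transfer", {}).items():
        lines.append(f"transfer {label}: r_s^2 = {t['r_s_squared']:.1f}%")
    return "\n".join(lines) + "\n"
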