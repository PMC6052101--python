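"""Data containers, connectivity-matrix construction, inclusion rules, and file I/O.

Containers
----------
``NodeAtlas``
    One row per parcellation node: hemisphere, centroid (mm; the first axis
    is left-right with the midline at 0), canonical-network label (1-10),
    and a per-dataset coverage flag.
``CohortTable``
    One row per subject: trait scores, sex, family structure (family id and
    sibling type), per-condition head-motion summaries, and optional binary
    covariates.
``ConnectivityStack``
    A subjects x nodes x nodes array of Fisher-z connectivity matrices for
    one scan condition, aligned to a subject-id list.

Edge values are Fisher-z transformed Pearson correlations between node mean
time courses. The diagonal is stored as 0 and excluded from every
computation; only the strict upper triangle defines the edge universe.
Missing (uncovered) nodes are marked by NaN rows/columns.

File dialects
-------------
* Atlas: TSV with columns ``node_id  hemisphere  x  y  z  network  covered``.
* Cohort: CSV keyed by ``subject_id`` with family, sex, trait, and
  ``motion_mean_<cond>`` / ``motion_max_<cond>`` columns; missing traits are
  empty fields.
* Matrices: one whitespace-delimited ``nodes x nodes`` text file per subject
  per condition, indexed by a manifest CSV ``subject_id,condition,path``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .edges import sym_to_vec

SIBLING_TYPES = ("nontwin", "DZ", "MZ")
HEMISPHERES = ("L", "R")

#: |r| is clamped to this bound before arctanh so Fisher z stays finite.
R_CLAMP = 1.0 - 1e-7

#: Symmetry tolerance enforced when matrices are read from disk.
SYMMETRY_TOL = 1e-8

ATLAS_COLUMNS = ["node_id", "hemisphere", "x", "y", "z", "network", "covered"]


class InvalidInputError(ValueError):
    """Raised when an input file or array violates a container invariant."""


@dataclass
class NodeAtlas:
    """Node table of a functional parcellation.

    Parameters
    ----------
    table
        DataFrame with columns ``node_id`` (1-based, contiguous),
        ``hemisphere`` (L/R), ``x``/``y``/``z`` centroid coordinates in mm,
        ``network`` (canonical network 1-10), ``covered`` (bool).
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in ATLAS_COLUMNS if c not in self.table.columns]
        if missing:
            raise InvalidInputError(f"atlas missing columns: {missing}")
        t = self.table
        ids = t["node_id"].to_numpy()
        if len(np.unique(ids)) != len(ids):
            raise InvalidInputError("atlas node_ids are not unique")
        if not np.array_equal(np.sort(ids), np.arange(1, len(ids) + 1)):
            raise InvalidInputError("atlas node_ids must be contiguous from 1")
        if not set(t["hemisphere"]).issubset(set(HEMISPHERES)):
            raise InvalidInputError("hemisphere labels must be L or R")
        nets = t["network"].to_numpy()
        if nets.min() < 1 or nets.max() > 10:
            raise InvalidInputError("canonical network labels must lie in 1..10")
        if not np.isfinite(t[["x", "y", "z"]].to_numpy()).all():
            raise InvalidInputError("atlas centroids must be finite")
        self.table = t.sort_values("node_id").reset_index(drop=True)

    @property
    def n_nodes(self) -> int:
        return len(self.table)

    @property
    def node_ids(self) -> np.ndarray:
        return self.table["node_id"].to_numpy()

    @property
    def centroids(self) -> np.ndarray:
        return self.table[["x", "y", "z"]].to_numpy(float)

    @property
    def hemispheres(self) -> np.ndarray:
        return self.table["hemisphere"].to_numpy()

    @property
    def networks(self) -> np.ndarray:
        return self.table["network"].to_numpy(int)

    @property
    def covered(self) -> np.ndarray:
        return self.table["covered"].to_numpy(bool)

    def subset(self, node_ids: Sequence[int]) -> "NodeAtlas":
        """Restrict to ``node_ids``, renumbering nodes contiguously from 1.

        The original identity is preserved in an ``orig_node_id`` column.
        """
        keep = self.table[self.table["node_id"].isin(node_ids)].copy()
        keep = keep.sort_values("node_id").reset_index(drop=True)
        if "orig_node_id" not in keep.columns:
            keep["orig_node_id"] = keep["node_id"]
        keep["node_id"] = np.arange(1, len(keep) + 1)
        return NodeAtlas(keep)


@dataclass
class CohortTable:
    """Per-subject phenotype, family-structure, and motion table."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        t = self.table
        if "subject_id" not in t.columns:
            raise InvalidInputError("cohort table requires a subject_id column")
        sids = t["subject_id"].astype(str)
        if sids.duplicated().any():
            dups = sorted(sids[sids.duplicated()].unique())
            raise InvalidInputError(f"duplicate subject ids: {dups}")
        if "sibling_type" in t.columns:
            seen = set(t["sibling_type"].dropna().unique())
            bad = seen - set(SIBLING_TYPES)
            if bad:
                raise InvalidInputError(f"unknown sibling types: {sorted(bad)}")
        for col in t.columns:
            if col.startswith("motion_"):
                vals = t[col].to_numpy(float)
                if (vals < 0).any():
                    raise InvalidInputError(f"negative motion values in {col}")
        self.table = t.reset_index(drop=True)

    @property
    def n_subjects(self) -> int:
        return len(self.table)

    @property
    def subject_ids(self) -> list[str]:
        return self.table["subject_id"].astype(str).tolist()

    def trait(self, name: str) -> np.ndarray:
        if name not in self.table.columns:
            raise KeyError(f"trait column {name!r} not in cohort table")
        return self.table[name].to_numpy(float)

    def subset(self, subject_ids: Sequence[str]) -> "CohortTable":
        """Restrict to ``subject_ids``, preserving the given order."""
        idx = {s: i for i, s in enumerate(self.subject_ids)}
        missing = [s for s in subject_ids if s not in idx]
        if missing:
            raise KeyError(f"subjects not in cohort: {missing}")
        rows = [idx[s] for s in subject_ids]
        return CohortTable(self.table.iloc[rows].reset_index(drop=True))


@dataclass
class ConnectivityStack:
    """Fisher-z connectivity matrices for one condition, one per subject."""

    condition: str
    subject_ids: list[str]
    values: np.ndarray  # (n_subjects, n_nodes, n_nodes)

    def __post_init__(self) -> None:
        v = np.asarray(self.values, float)
        if v.ndim != 3 or v.shape[1] != v.shape[2]:
            raise InvalidInputError(f"stack values must be (S, N, N), got {v.shape}")
        if v.shape[0] != len(self.subject_ids):
            raise InvalidInputError("subject list does not match value array")
        with np.errstate(invalid="ignore"):
            asym = np.nanmax(np.abs(v - v.transpose(0, 2, 1))) if v.size else 0.0
        if asym > SYMMETRY_TOL:
            raise InvalidInputError(f"asymmetric connectivity matrix (max dev {asym:g})")
        self.values = v

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    @property
    def n_nodes(self) -> int:
        return self.values.shape[1]

    def edge_matrix(self) -> np.ndarray:
        """Subjects x edges view of the strict upper triangle."""
        return sym_to_vec(self.values)

    def subset_subjects(self, subject_ids: Sequence[str]) -> "ConnectivityStack":
        idx = {s: i for i, s in enumerate(self.subject_ids)}
        rows = [idx[s] for s in subject_ids]
        return ConnectivityStack(self.condition, list(subject_ids), self.values[rows])

    def subset_nodes(self, node_index: np.ndarray) -> "ConnectivityStack":
        """Restrict to the 0-based node positions in ``node_index``."""
        node_index = np.asarray(node_index)
        vals = self.values[:, node_index][:, :, node_index]
        return ConnectivityStack(self.condition, list(self.subject_ids), vals)


# ---------------------------------------------------------------------------
# Connectivity construction
# ---------------------------------------------------------------------------

def compute_connectivity(timecourses: np.ndarray) -> np.ndarray:
    """Node x node Fisher-z connectivity from node x frame time courses.

    Each node pair's mean time courses are Pearson-correlated and the
    coefficients are arctanh-transformed, with |r| clamped to ``R_CLAMP``
    so that perfectly (anti)correlated pairs stay finite. A node whose time
    course has zero variance cannot be correlated; its row and column are
    set to NaN, marking the node as uncovered.

    Raises
    ------
    InvalidInputError
        If fewer than 3 frames are supplied.
    """
    tc = np.asarray(timecourses, float)
    if tc.ndim != 2:
        raise InvalidInputError(f"timecourses must be nodes x frames, got {tc.shape}")
    n_nodes, n_frames = tc.shape
    if n_frames < 3:
        raise InvalidInputError(f"need at least 3 frames, got {n_frames}")
    sd = tc.std(axis=1)
    flat = sd == 0
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(tc)
    r = np.clip(r, -R_CLAMP, R_CLAMP)
    z = np.arctanh(r)
    z[flat, :] = np.nan
    z[:, flat] = np.nan
    np.fill_diagonal(z, 0.0)
    z = (z + z.T) / 2.0  # exact symmetry despite floating-point corrcoef
    np.fill_diagonal(z, 0.0)
    return z


def average_runs(mat_a: np.ndarray, mat_b: np.ndarray) -> np.ndarray:
    """Element-wise mean of two same-shape Fisher-z matrices (e.g. two
    phase-encoding runs of the same condition)."""
    a, b = np.asarray(mat_a, float), np.asarray(mat_b, float)
    if a.shape != b.shape:
        raise InvalidInputError(f"shape mismatch: {a.shape} vs {b.shape}")
    return (a + b) / 2.0


def truncate_timecourses(
    timecourses: Mapping[str, np.ndarray], n_frames: int
) -> dict[str, np.ndarray]:
    """Keep the first ``n_frames`` frames of every condition's time courses.

    Used to equate condition durations before recomputing connectivity:
    every condition is cut to the length of the shortest one.
    """
    if n_frames < 3:
        raise InvalidInputError("n_frames must be at least 3")
    out = {}
    for cond, tc in timecourses.items():
        tc = np.asarray(tc, float)
        if tc.shape[-1] < n_frames:
            raise InvalidInputError(
                f"condition {cond!r} has {tc.shape[-1]} frames < n_frames={n_frames}"
            )
        out[cond] = tc[..., :n_frames].copy()
    return out


# ---------------------------------------------------------------------------
# Inclusion rules
# ---------------------------------------------------------------------------

def motion_filter(
    cohort: CohortTable,
    conditions: Sequence[str] | None = None,
    mean_thresh: float = 0.1,
    max_thresh: float = 0.15,
) -> list[str]:
    """Subject ids passing the head-motion exclusion rule.

    A subject is retained iff, in every analyzed condition, mean
    frame-to-frame displacement is strictly below ``mean_thresh`` and
    maximum displacement strictly below ``max_thresh`` (defaults 0.1 mm and
    0.15 mm). Subjects missing a motion value are excluded with a warning.
    """
    t = cohort.table
    if conditions is None:
        conditions = sorted(
            c[len("motion_mean_"):] for c in t.columns if c.startswith("motion_mean_")
        )
    if not conditions:
        raise InvalidInputError("no motion columns found in cohort table")
    retained = []
    for _, row in t.iterrows():
        sid = str(row["subject_id"])
        ok = True
        for cond in conditions:
            mcol, xcol = f"motion_mean_{cond}", f"motion_max_{cond}"
            if mcol not in t.columns or xcol not in t.columns:
                raise InvalidInputError(f"missing motion columns for condition {cond!r}")
            m, x = row[mcol], row[xcol]
            if pd.isna(m) or pd.isna(x):
                warnings.warn(f"subject {sid}: missing motion for {cond}; excluded")
                ok = False
                break
            if not (m < mean_thresh and x < max_thresh):
                ok = False
                break
        if ok:
            retained.append(sid)
    return retained


def coverage_mask(
    stacks: Iterable[ConnectivityStack], atlas: NodeAtlas
) -> np.ndarray:
    """Node ids covered in every subject of every supplied stack.

    A node is dropped for *all* subjects if it is uncovered for any subject
    of any stack (conservative whole-sample exclusion): uncovered means the
    atlas flags it out, or its entire off-diagonal row is NaN for some
    subject. The retained id list is meant to be applied before any modeling
    step; cross-dataset analyses pass stacks from both datasets so only the
    common nodes survive.
    """
    covered = atlas.covered.copy()
    n = atlas.n_nodes
    for stack in stacks:
        if stack.n_nodes != n:
            raise InvalidInputError(
                f"stack {stack.condition!r} has {stack.n_nodes} nodes, atlas has {n}"
            )
        offdiag = ~np.eye(n, dtype=bool)
        row_all_nan = np.isnan(stack.values).all(axis=2, where=offdiag[None])  # (S, N)
        covered &= ~row_all_nan.any(axis=0)
    if not covered.any():
        raise InvalidInputError("no nodes survive coverage exclusion")
    return atlas.node_ids[covered]


# ---------------------------------------------------------------------------
# File I/O
# ---------------------------------------------------------------------------

def read_atlas(path: str | Path) -> NodeAtlas:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in ATLAS_COLUMNS if c not in df.columns]
    if missing:
        raise InvalidInputError(f"atlas file {path} missing columns {missing}")
    df["covered"] = df["covered"].astype(bool)
    return NodeAtlas(df)


def write_atlas(atlas: NodeAtlas, path: str | Path) -> None:
    atlas.table[
        [c for c in atlas.table.columns if c in ATLAS_COLUMNS or c == "orig_node_id"]
    ].to_csv(path, sep="\t", index=False)


def read_cohort(path: str | Path) -> CohortTable:
    df = pd.read_csv(path, dtype={"subject_id": str, "family_id": str})
    return CohortTable(df)


def write_cohort(cohort: CohortTable, path: str | Path) -> None:
    cohort.table.to_csv(path, index=False)


def write_stack(
    stack: ConnectivityStack,
    matrix_dir: str | Path,
    manifest_path: str | Path,
    fmt: str = "%.10g",
) -> None:
    """Write per-subject matrix files plus manifest rows for one condition.

    Appends to an existing manifest (other conditions may already be listed);
    paths in the manifest are relative to the manifest's directory.
    """
    matrix_dir = Path(matrix_dir)
    manifest_path = Path(manifest_path)
    matrix_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for sid, mat in zip(stack.subject_ids, stack.values):
        fname = f"{sid}_{stack.condition}.txt"
        np.savetxt(matrix_dir / fname, mat, fmt=fmt)
        rel = (matrix_dir / fname).relative_to(manifest_path.parent)
        rows.append({"subject_id": sid, "condition": stack.condition, "path": str(rel)})
    new = pd.DataFrame(rows)
    if manifest_path.exists():
        old = pd.read_csv(manifest_path, dtype=str)
        new = pd.concat([old, new], ignore_index=True)
    new.to_csv(manifest_path, index=False)


def read_stack(
    manifest_path: str | Path,
    condition: str,
    subject_ids: Sequence[str] | None = None,
) -> ConnectivityStack:
    """Load one condition's matrices as listed in a manifest CSV.

    Subject alignment is by explicit id: pass ``subject_ids`` (e.g. the
    cohort order) to fix the subject axis; otherwise manifest order is used.
    Matrices are checked for consistent node counts and symmetry
    (tolerance ``SYMMETRY_TOL``).
    """
    manifest_path = Path(manifest_path)
    man = pd.read_csv(manifest_path, dtype=str)
    for col in ("subject_id", "condition", "path"):
        if col not in man.columns:
            raise InvalidInputError(f"manifest missing column {col!r}")
    man = man[man["condition"] == condition]
    if man.empty:
        raise InvalidInputError(f"no manifest entries for condition {condition!r}")
    if man["subject_id"].duplicated().any():
        raise InvalidInputError(f"duplicate manifest entries for condition {condition!r}")
    paths = dict(zip(man["subject_id"], man["path"]))
    if subject_ids is None:
        subject_ids = man["subject_id"].tolist()
    else:
        missing = [s for s in subject_ids if s not in paths]
        if missing:
            raise InvalidInputError(f"manifest lacks subjects {missing} for {condition!r}")
    mats, n_nodes = [], None
    for sid in subject_ids:
        mat = np.loadtxt(manifest_path.parent / paths[sid])
        if mat.ndim != 2 or mat.shape[0] != mat.shape[1]:
            raise InvalidInputError(f"matrix for {sid} is not square: {mat.shape}")
        if n_nodes is None:
            n_nodes = mat.shape[0]
        elif mat.shape[0] != n_nodes:
            raise InvalidInputError(
                f"inconsistent node counts: {sid} has {mat.shape[0]}, expected {n_nodes}"
            )
        with np.errstate(invalid="ignore"):
            dev = np.nanmax(np.abs(mat - mat.T))
        if dev > SYMMETRY_TOL:
            raise InvalidInputError(
                f"matrix for {sid} asymmetric beyond tolerance ({dev:g} > {SYMMETRY_TOL:g})"
            )
        mats.append(mat)
    return ConnectivityStack(condition, list(subject_ids), np.stack(mats))
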