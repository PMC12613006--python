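"""Drug-tissue task construction, splits, episodic sampling and clinical
label binarisation.

A *task* is all response records for one (drug, tissue) pair; meta-learning
episodes draw disjoint support/query subsets from a task.  Splits are
deterministic per seed: unseen-drug holdout at drug level, train/validation
at task (drug-tissue pair) level.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .utils import rng_for

logger = logging.getLogger(__name__)

MIN_TASK_SIZE = 30
RECIST_RESPONDER = {"PR": True, "CR": True, "PD": False, "SD": False}


@dataclass(frozen=True)
class ResponseRecord:
    sample_id: str
    drug_id: str
    tissue: str
    ln_ic50: float
    responder: bool | None = None

    def __post_init__(self):
        if not np.isfinite(self.ln_ic50):
            raise ValueError("ln_ic50 must be finite")


@dataclass
class Task:
    drug_id: str
    tissue: str
    records: list[ResponseRecord]

    def __post_init__(self):
        for r in self.records:
            if r.drug_id != self.drug_id or r.tissue != self.tissue:
                raise ValueError("all task records must share drug and tissue")

    def __len__(self) -> int:
        return len(self.records)

    @property
    def key(self) -> tuple[str, str]:
        return (self.drug_id, self.tissue)


@dataclass
class Episode:
    support: list[ResponseRecord]
    query: list[ResponseRecord]

    def __post_init__(self):
        skeys = {(r.sample_id, r.drug_id) for r in self.support}
        qkeys = {(r.sample_id, r.drug_id) for r in self.query}
        if skeys & qkeys:
            raise ValueError("support and query must be disjoint")


# ----------------------------------------------------------------------
# task construction and splitting
# ----------------------------------------------------------------------

def group_tasks(records: list[ResponseRecord], min_size: int = MIN_TASK_SIZE) -> list[Task]:
    """One task per (drug, tissue) pair with at least ``min_size`` records.

    Exact duplicate (sample, drug, tissue) entries keep the first occurrence.
    """
    groups: dict[tuple[str, str], list[ResponseRecord]] = {}
    seen: set[tuple[str, str, str]] = set()
    n_dup = 0
    for r in records:
        key3 = (r.sample_id, r.drug_id, r.tissue)
        if key3 in seen:
            n_dup += 1
            continue
        seen.add(key3)
        groups.setdefault((r.drug_id, r.tissue), []).append(r)
    if n_dup:
        logger.warning("dropped %d duplicate response records", n_dup)
    return [Task(drug_id=d, tissue=t, records=rs)
            for (d, t), rs in sorted(groups.items()) if len(rs) >= min_size]


def holdout_unseen_drugs(tasks: list[Task], fraction: float = 0.10,
                         seed: int = 0) -> tuple[list[Task], list[Task]]:
    """Drug-level holdout: all tasks of the held-out drugs go to `unseen`."""
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must be in (0, 1)")
    drugs = sorted({t.drug_id for t in tasks})
    if len(drugs) < 2:
        raise ValueError("need at least 2 distinct drugs")
    n_hold = max(1, round(fraction * len(drugs)))
    rng = rng_for(seed, "split", "unseen")
    held = set(rng.choice(drugs, size=n_hold, replace=False))
    remaining = [t for t in tasks if t.drug_id not in held]
    unseen = [t for t in tasks if t.drug_id in held]
    return remaining, unseen


def split_train_val(tasks: list[Task], train_fraction: float = 0.85,
                    seed: int = 0) -> tuple[list[Task], list[Task]]:
    """Task-level (drug-tissue pair) train/validation partition."""
    if not 0.0 < train_fraction < 1.0:
        raise ValueError("train_fraction must be in (0, 1)")
    if len(tasks) < 2:
        raise ValueError("need at least 2 tasks to split")
    rng = rng_for(seed, "split", "trainval")
    order = rng.permutation(len(tasks))
    n_train = int(round(train_fraction * len(tasks)))
    n_train = min(max(n_train, 1), len(tasks) - 1)
    train_idx = set(order[:n_train].tolist())
    train = [t for i, t in enumerate(tasks) if i in train_idx]
    val = [t for i, t in enumerate(tasks) if i not in train_idx]
    return train, val


def sample_episode(task: Task, n_total: int = 30, n_support: int = 10,
                   n_query: int = 20, seed: int = 0) -> Episode:
    """Uniform without-replacement episode draw from one task."""
    if n_support + n_query != n_total:
        raise ValueError("n_support + n_query must equal n_total")
    if len(task.records) < n_total:
        raise ValueError(f"task {task.key} has {len(task.records)} < {n_total} records")
    rng = rng_for(seed, "episode", task.drug_id, task.tissue)
    idx = rng.choice(len(task.records), size=n_total, replace=False)
    support = [task.records[i] for i in idx[:n_support]]
    query = [task.records[i] for i in idx[n_support:]]
    return Episode(support=support, query=query)


# ----------------------------------------------------------------------
# statistics and labels
# ----------------------------------------------------------------------

def tissue_variation_test(records: list[ResponseRecord]) -> tuple[float, float]:
    """Kruskal-Wallis H-test of LN_IC50 across tissues for one drug."""
    groups: dict[str, list[float]] = {}
    for r in records:
        groups.setdefault(r.tissue, []).append(r.ln_ic50)
    usable = [v for v in groups.values() if len(v) >= 2]
    if len(usable) < 2:
        raise ValueError("need >= 2 tissues with >= 2 records each")
    h, p = stats.kruskal(*usable)
    return float(h), float(p)


def binarize_recist(labels: list[str]) -> list[bool]:
    """RECIST classes to responder flags (PR/CR true, PD/SD false)."""
    out = []
    for lab in labels:
        if lab not in RECIST_RESPONDER:
            raise ValueError(f"unknown RECIST class: {lab!r}")
        out.append(RECIST_RESPONDER[lab])
    return out


# ----------------------------------------------------------------------
# IO
# ----------------------------------------------------------------------

def load_response_csv(path) -> list[ResponseRecord]:
    """Read sample_id, drug_id, tissue, ln_ic50[, recist] records."""
    df = pd.read_csv(path, dtype={"sample_id": str, "drug_id": str, "tissue": str})
    records = []
    has_recist = "recist" in df.columns
    for row in df.itertuples(index=False):
        responder = None
        if has_recist and isinstance(row.recist, str):
            responder = binarize_recist([row.recist])[0]
        records.append(ResponseRecord(sample_id=row.sample_id, drug_id=row.drug_id,
                                      tissue=row.tissue, ln_ic50=float(row.ln_ic50),
                                      responder=responder))
    return records


def split_manifest(train: list[Task], val: list[Task],
                   unseen: list[Task]) -> dict:
    """JSON-serialisable audit record of which task went where."""
    def keys(ts):
        return [[t.drug_id, t.tissue] for t in ts]
    return {"train": keys(train), "val": keys(val), "unseen": keys(unseen)}
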