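"""Cross-run join alignment and post-alignment curation.

The join aligner matches per-run feature lists into an
:class:`AlignedMatrix` (rows = aligned compounds, columns = runs) with a
weighted m/z + RT proximity score.  Curation then removes rows shared
with blank-pipe runs and merges each sample's three solvent-extract
columns (TA/APW/MTBE) into one :class:`CompoundList`.

Greedy alignment is order-sensitive for borderline cases, so runs are
always processed in lexicographic run-id order; for well-separated data
(compound spacing > 2x tolerance) the induced feature partition is
independent of input order.
"""

from __future__ import annotations

import json
import logging
import uuid
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .features import Feature, Tolerance

log = logging.getLogger(__name__)

__all__ = ["AlignedMatrix", "CompoundList", "join_align", "remove_blank_shared",
           "merge_extracts"]

#: Column-metadata fields every AlignedMatrix carries per run.
COL_FIELDS = ("sample", "role", "solvent", "species")


@dataclass
class AlignedMatrix:
    """Aligned compounds x runs abundance matrix.

    ``abundance``: DataFrame, rows indexed by integer row id, columns by
    run id, NaN = absent.  ``row_meta``: per-row consensus m/z
    (intensity-weighted mean of member features) and consensus RT.
    ``col_meta``: per-run sample/role/solvent/species metadata.
    ``token``: identity of the alignment; compound lists are only
    comparable when drawn from the same matrix.
    """

    abundance: pd.DataFrame
    row_meta: pd.DataFrame
    col_meta: pd.DataFrame
    token: str = field(default_factory=lambda: uuid.uuid4().hex)

    def __post_init__(self):
        if not self.abundance.columns.equals(self.col_meta.index):
            raise ValueError("col_meta must be indexed by the abundance columns")
        if not self.abundance.index.equals(self.row_meta.index):
            raise ValueError("row_meta must be indexed by the abundance rows")

    @property
    def n_rows(self) -> int:
        return len(self.abundance)

    def runs_with_role(self, role: str) -> list[str]:
        return list(self.col_meta.index[self.col_meta["role"] == role])

    def to_csv(self, path: str | Path, sidecar: str | Path | None = None) -> None:
        """Write the wide matrix as CSV plus a JSON sidecar of row/column
        metadata."""
        path = Path(path)
        self.abundance.to_csv(path, index_label="row_id")
        if sidecar is None:
            sidecar = path.with_suffix(".meta.json")
        meta = {
            "token": self.token,
            "rows": {str(i): {"mz": float(r.mz), "rt": float(r.rt)}
                     for i, r in self.row_meta.iterrows()},
            "columns": {c: {k: self.col_meta.loc[c, k] for k in COL_FIELDS}
                        for c in self.abundance.columns},
        }
        Path(sidecar).write_text(json.dumps(meta, indent=1, sort_keys=True))


@dataclass
class CompoundList:
    """One sample's merged compound list: aligned row ids with the maximum
    abundance observed across the sample's solvent-extract runs."""

    sample: str
    members: pd.Series  # index = row ids, values = max abundance
    token: str

    def __post_init__(self):
        if (self.members <= 0).any() or self.members.isna().any():
            raise ValueError("compound list members must have positive abundance")

    @property
    def ids(self) -> frozenset:
        return frozenset(self.members.index)

    def __len__(self) -> int:
        return len(self.members)

    def to_csv(self, path: str | Path) -> None:
        self.members.rename("abundance").to_csv(path, index_label="row_id")


def join_align(
    features_by_run: Mapping[str, Sequence[Feature]],
    run_meta: Mapping[str, Mapping[str, str]],
    mz_tol: Tolerance = Tolerance(0.01, 5.0),
    rt_tol: float = 0.05,
    mz_weight: float = 10.0,
    rt_weight: float = 10.0,
    require_same_charge: bool = True,
) -> AlignedMatrix:
    """Join-align per-run feature lists into one matrix.

    Runs are processed in lexicographic run-id order.  Each feature is
    matched to the best-scoring existing row within both tolerances, with
    score ``w_mz * (1 - dmz/tol_mz) + w_rt * (1 - drt/tol_rt)``; no match
    opens a new row.  A run contributes at most one feature per row — a
    second same-run match opens a new row.  When ``require_same_charge``,
    rows and features with *both* charges determined must agree.
    The recorded abundance is the feature height.
    """
    if not features_by_run:
        raise ValueError("at least one run required")
    run_ids = sorted(features_by_run)

    row_mz_num: list[float] = []   # sum(mz * height)
    row_den: list[float] = []      # sum(height)
    row_rt_num: list[float] = []
    row_charge: list[int | None] = []
    cells: list[dict[str, float]] = []

    for run_id in run_ids:
        feats = sorted(features_by_run[run_id], key=lambda f: (f.mz, f.rt, -f.height))
        n_rows = len(row_den)
        cons_mz = (np.array(row_mz_num) / np.array(row_den)) if n_rows else np.empty(0)
        cons_rt = (np.array(row_rt_num) / np.array(row_den)) if n_rows else np.empty(0)
        taken = np.zeros(n_rows, dtype=bool)
        new_rows: list[tuple[Feature, int | None]] = []
        for f in feats:
            best_row, best_score = -1, -np.inf
            if n_rows:
                dmz = np.abs(cons_mz - f.mz)
                drt = np.abs(cons_rt - f.rt)
                win = mz_tol.window(cons_mz)
                ok = (dmz <= win) & (drt <= rt_tol) & ~taken
                if require_same_charge and f.charge is not None:
                    charges = np.array([c if c is not None else -1 for c in row_charge])
                    ok &= (charges == -1) | (charges == f.charge)
                idx = np.nonzero(ok)[0]
                if idx.size:
                    score = (mz_weight * (1 - dmz[idx] / win[idx])
                             + rt_weight * (1 - drt[idx] / rt_tol))
                    k = int(idx[np.argmax(score)])
                    best_row, best_score = k, float(score.max())
            if best_row >= 0:
                taken[best_row] = True
                row_mz_num[best_row] += f.mz * f.height
                row_den[best_row] += f.height
                row_rt_num[best_row] += f.rt * f.height
                if row_charge[best_row] is None:
                    row_charge[best_row] = f.charge
                cells[best_row][run_id] = f.height
            else:
                new_rows.append((f, f.charge))
        for f, charge in new_rows:
            row_mz_num.append(f.mz * f.height)
            row_den.append(f.height)
            row_rt_num.append(f.rt * f.height)
            row_charge.append(charge)
            cells.append({run_id: f.height})

    n = len(cells)
    abundance = pd.DataFrame(
        {run_id: [cells[i].get(run_id, np.nan) for i in range(n)] for run_id in run_ids},
        index=pd.RangeIndex(n, name="row_id"),
    )
    row_meta = pd.DataFrame({
        "mz": np.array(row_mz_num) / np.array(row_den),
        "rt": np.array(row_rt_num) / np.array(row_den),
        "charge": [c if c is not None else np.nan for c in row_charge],
    }, index=abundance.index)
    col_meta = pd.DataFrame(
        [{k: run_meta.get(r, {}).get(k, "") for k in COL_FIELDS} for r in run_ids],
        index=pd.Index(run_ids, name="run_id"),
    )
    return AlignedMatrix(abundance=abundance, row_meta=row_meta, col_meta=col_meta)


def remove_blank_shared(matrix: AlignedMatrix, rule: str = "any") -> AlignedMatrix:
    """Drop rows present in blank-pipe runs, then drop the blank columns.

    ``rule="any"`` (default, conservative): a row is blank-shared when it
    has abundance in at least one blank run.  ``rule="all"``: only when
    present in every blank run.
    """
    if rule not in ("any", "all"):
        raise ValueError("rule must be 'any' or 'all'")
    blank_cols = matrix.runs_with_role("blank")
    if not blank_cols:
        log.warning("remove_blank_shared: no blank-role columns; matrix unchanged")
        return matrix
    present = matrix.abundance[blank_cols].notna()
    shared = present.any(axis=1) if rule == "any" else present.all(axis=1)
    keep_rows = matrix.abundance.index[~shared]
    keep_cols = [c for c in matrix.abundance.columns if c not in blank_cols]
    return AlignedMatrix(
        abundance=matrix.abundance.loc[keep_rows, keep_cols],
        row_meta=matrix.row_meta.loc[keep_rows],
        col_meta=matrix.col_meta.loc[keep_cols],
        token=matrix.token,
    )


def merge_extracts(matrix: AlignedMatrix, sample: str) -> CompoundList:
    """Union-merge a sample's solvent-extract columns into one compound
    list; rows absent in all of the sample's runs are excluded, and each
    member carries its maximum abundance across the runs."""
    cols = matrix.col_meta.index[matrix.col_meta["sample"] == sample]
    if len(cols) == 0:
        raise KeyError(f"unknown sample id {sample!r}")
    sub = matrix.abundance[list(cols)]
    maxima = sub.max(axis=1)
    members = maxima[sub.notna().any(axis=1)]
    return CompoundList(sample=sample, members=members, token=matrix.token)
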