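"""Data containers, readers/writers, somite-stage conversion and splitting.

The central container is :class:`AnnotatedMatrix`: a sparse cell-by-feature
count matrix (raw scRNA-seq counts, or binarised scATAC-seq peaks) aligned
with per-cell metadata — collection time in days, a condition label (e.g.
sex), a batch label and an optional cell-type annotation used only for
evaluation.  On disk the counts live in Matrix Market format with TSV
sidecars, so every fixture stays plain text.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse

log = logging.getLogger(__name__)

SOMITE_DAYS = 2.0 / 34.0  # incremental developmental time per somite stage

_META_COLUMNS = ("cell_id", "time", "condition", "batch")


class DataValidationError(ValueError):
    """Raised when an input file or matrix violates the data contract."""


@dataclass
class AnnotatedMatrix:
    """Sparse counts plus aligned per-cell metadata for one modality.

    ``modality="atac"`` matrices are binarised (any positive count becomes 1)
    at construction; cells with zero total counts are dropped with a warning
    because per-cell depth scaling is undefined for them.
    """

    counts: sparse.csr_matrix
    feature_ids: list[str]
    cell_ids: list[str]
    time: np.ndarray
    condition: np.ndarray
    batch: np.ndarray
    cell_type: np.ndarray | None = None
    modality: str = "rna"

    def __post_init__(self):
        self.counts = sparse.csr_matrix(self.counts, dtype=np.float64)
        self.feature_ids = list(self.feature_ids)
        self.cell_ids = list(self.cell_ids)
        self.time = np.asarray(self.time, dtype=float)
        self.condition = np.asarray(self.condition, dtype=object)
        self.batch = np.asarray(self.batch, dtype=object)
        if self.cell_type is not None:
            self.cell_type = np.asarray(self.cell_type, dtype=object)
        if self.modality not in ("rna", "atac"):
            raise DataValidationError(f"unknown modality {self.modality!r}")
        n, p = self.counts.shape
        if len(self.cell_ids) != n:
            raise DataValidationError(
                f"{len(self.cell_ids)} cell ids vs {n} matrix rows")
        if len(self.feature_ids) != p:
            raise DataValidationError(
                f"{len(self.feature_ids)} feature ids vs {p} matrix columns")
        for name in ("time", "condition", "batch"):
            v = getattr(self, name)
            if len(v) != n:
                raise DataValidationError(
                    f"metadata column {name!r} has length {len(v)}, "
                    f"expected {n}")
        if self.cell_type is not None and len(self.cell_type) != n:
            raise DataValidationError("cell_type length mismatch")
        if not np.all(np.isfinite(self.time)):
            raise DataValidationError("time values must be finite")
        if self.counts.nnz and self.counts.data.min() < 0:
            raise DataValidationError("counts contain negative entries")
        if self.modality == "atac":
            self.counts.data = (self.counts.data > 0).astype(np.float64)
        depth = np.asarray(self.counts.sum(axis=1)).ravel()
        if np.any(depth == 0):
            keep = depth > 0
            log.warning("dropping %d zero-count cell(s)", int((~keep).sum()))
            self._subset_inplace(np.flatnonzero(keep))

    def _subset_inplace(self, idx: np.ndarray) -> None:
        self.counts = self.counts[idx]
        self.cell_ids = [self.cell_ids[i] for i in idx]
        self.time = self.time[idx]
        self.condition = self.condition[idx]
        self.batch = self.batch[idx]
        if self.cell_type is not None:
            self.cell_type = self.cell_type[idx]

    # -- convenience ---------------------------------------------------------
    @property
    def n_cells(self) -> int:
        return self.counts.shape[0]

    @property
    def n_features(self) -> int:
        return self.counts.shape[1]

    @property
    def library_size(self) -> np.ndarray:
        return np.asarray(self.counts.sum(axis=1)).ravel()

    def subset(self, idx) -> "AnnotatedMatrix":
        idx = np.asarray(idx)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return AnnotatedMatrix(
            counts=self.counts[idx],
            feature_ids=self.feature_ids,
            cell_ids=[self.cell_ids[i] for i in idx],
            time=self.time[idx],
            condition=self.condition[idx],
            batch=self.batch[idx],
            cell_type=None if self.cell_type is None else self.cell_type[idx],
            modality=self.modality,
        )

    def subset_by_ids(self, cell_ids) -> "AnnotatedMatrix":
        pos = {c: i for i, c in enumerate(self.cell_ids)}
        return self.subset(np.array([pos[c] for c in cell_ids]))

    def to_anndata(self):
        """Convert to an :class:`anndata.AnnData` (counts in ``.X``)."""
        import anndata as ad

        obs = pd.DataFrame(
            {"time": self.time, "condition": self.condition,
             "batch": self.batch},
            index=pd.Index(self.cell_ids, name="cell_id"),
        )
        if self.cell_type is not None:
            obs["cell_type"] = self.cell_type
        var = pd.DataFrame(index=pd.Index(self.feature_ids, name="feature_id"))
        return ad.AnnData(X=self.counts.copy(), obs=obs, var=var)

    @classmethod
    def from_anndata(cls, adata, modality: str = "rna") -> "AnnotatedMatrix":
        obs = adata.obs
        return cls(
            counts=sparse.csr_matrix(adata.X),
            feature_ids=list(adata.var_names),
            cell_ids=list(adata.obs_names),
            time=obs["time"].to_numpy(),
            condition=obs["condition"].to_numpy(),
            batch=obs["batch"].to_numpy(),
            cell_type=obs["cell_type"].to_numpy() if "cell_type" in obs else None,
            modality=modality,
        )


@dataclass(frozen=True)
class CoassayPairing:
    """One-to-one RNA/ATAC cell correspondence from a coassay experiment."""

    pairs: tuple[tuple[str, str], ...]

    def __post_init__(self):
        rna = [r for r, _ in self.pairs]
        atac = [a for _, a in self.pairs]
        if len(set(rna)) != len(rna) or len(set(atac)) != len(atac):
            raise DataValidationError("a cell id appears twice in the pairing")

    def __len__(self) -> int:
        return len(self.pairs)

    def validate_against(self, rna: AnnotatedMatrix, atac: AnnotatedMatrix):
        rna_ids = set(rna.cell_ids)
        atac_ids = set(atac.cell_ids)
        for r, a in self.pairs:
            if r not in rna_ids:
                raise DataValidationError(f"paired RNA cell {r!r} not in data")
            if a not in atac_ids:
                raise DataValidationError(f"paired ATAC cell {a!r} not in data")

    @classmethod
    def from_tsv(cls, path) -> "CoassayPairing":
        df = pd.read_csv(path, sep="\t")
        return cls(tuple(zip(df["rna_cell_id"], df["atac_cell_id"])))

    def to_tsv(self, path) -> None:
        pd.DataFrame(self.pairs, columns=["rna_cell_id", "atac_cell_id"]).to_csv(
            path, sep="\t", index=False)


@dataclass(frozen=True)
class SplitPlan:
    """Train/validation/test cell-id sets for a held-out-time experiment."""

    train_ids: tuple[str, ...]
    val_ids: tuple[str, ...]
    test_ids: tuple[str, ...]
    holdout_times: tuple[float, ...]
    val_ratio: float
    val_cap_per_time: int
    seed: int


def somite_to_day(somite_count: int, base_day: float = 8.0) -> float:
    """Convert a somite stage to developmental time in days.

    Each somite adds 2/34 day; ``base_day`` anchors somite stage 0 (the
    anchoring day is an assumption — staging atlases give the slope, not the
    intercept).
    """
    if somite_count < 0:
        raise ValueError(f"somite count must be non-negative, got {somite_count}")
    return float(base_day) + somite_count * SOMITE_DAYS


def make_split(data: AnnotatedMatrix, holdout_times, val_ratio: float = 0.2,
               val_cap: int = 2000, seed: int = 0) -> SplitPlan:
    """Hold out whole time points as test; split the rest 1:4 val:train.

    All cells collected at a ``holdout_times`` day form the test set.  Within
    every remaining time point the cells are shuffled (deterministically from
    ``seed``) and a ``val_ratio`` fraction — at most ``val_cap`` cells — goes
    to validation, the rest to training.
    """
    observed = np.unique(data.time)
    holdout_times = tuple(float(t) for t in np.atleast_1d(holdout_times))
    for t in holdout_times:
        if not np.any(np.isclose(observed, t)):
            raise ValueError(
                f"holdout time {t} not observed; observed times: "
                f"{sorted(observed.tolist())}")
    is_test = np.isin(data.time, holdout_times) | np.any(
        np.isclose(data.time[:, None], np.array(holdout_times)[None, :]), axis=1)
    test_idx = np.flatnonzero(is_test)
    rng = np.random.default_rng(seed)
    train_idx: list[int] = []
    val_idx: list[int] = []
    for t in observed:
        if any(np.isclose(t, h) for h in holdout_times):
            continue
        here = np.flatnonzero(np.isclose(data.time, t) & ~is_test)
        perm = rng.permutation(here)
        n_val = min(int(round(len(here) * val_ratio)), val_cap)
        val_idx.extend(perm[:n_val])
        train_idx.extend(perm[n_val:])
    if not train_idx:
        raise ValueError("no training cells remain after holding out "
                         f"times {holdout_times}")
    ids = np.asarray(data.cell_ids, dtype=object)
    return SplitPlan(
        train_ids=tuple(ids[sorted(train_idx)]),
        val_ids=tuple(ids[sorted(val_idx)]),
        test_ids=tuple(ids[test_idx]),
        holdout_times=holdout_times,
        val_ratio=val_ratio,
        val_cap_per_time=val_cap,
        seed=seed,
    )


# -- disk round trip ---------------------------------------------------------

def load_annotated_matrix(matrix_path, features_path, cells_meta_path,
                          modality: str = "rna") -> AnnotatedMatrix:
    """Read counts (Matrix Market, cells × features) + TSV sidecars.

    ``cells_meta_path`` must provide columns ``cell_id, time, condition,
    batch`` and may provide ``cell_type``; ``features_path`` is a headerless
    single-column TSV of feature ids.
    """
    matrix_path = Path(matrix_path)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        counts = sparse.csr_matrix(spio.mmread(matrix_path))
    features = pd.read_csv(features_path, sep="\t", header=None)[0].tolist()
    meta = pd.read_csv(cells_meta_path, sep="\t")
    missing = [c for c in _META_COLUMNS if c not in meta.columns]
    if missing:
        raise DataValidationError(
            f"{cells_meta_path}: missing metadata columns {missing}")
    if counts.shape[0] != len(meta):
        raise DataValidationError(
            f"{matrix_path} has {counts.shape[0]} cells but "
            f"{cells_meta_path} has {len(meta)} rows")
    if counts.shape[1] != len(features):
        raise DataValidationError(
            f"{matrix_path} has {counts.shape[1]} features but "
            f"{features_path} lists {len(features)}")
    return AnnotatedMatrix(
        counts=counts,
        feature_ids=features,
        cell_ids=meta["cell_id"].astype(str).tolist(),
        time=meta["time"].to_numpy(float),
        condition=meta["condition"].to_numpy(),
        batch=meta["batch"].to_numpy(),
        cell_type=meta["cell_type"].to_numpy() if "cell_type" in meta else None,
        modality=modality,
    )


def write_annotated_matrix(data: AnnotatedMatrix, out_dir,
                           prefix: str = "matrix") -> dict[str, Path]:
    """Write the Matrix Market + TSV triple read by :func:`load_annotated_matrix`."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "matrix": out_dir / f"{prefix}.mtx",
        "features": out_dir / f"{prefix}.features.tsv",
        "cells": out_dir / f"{prefix}.cells.tsv",
    }
    spio.mmwrite(paths["matrix"], sparse.coo_matrix(data.counts))
    pd.Series(data.feature_ids).to_csv(paths["features"], sep="\t",
                                       index=False, header=False)
    meta = pd.DataFrame({
        "cell_id": data.cell_ids,
        "time": data.time,
        "condition": data.condition,
        "batch": data.batch,
    })
    if data.cell_type is not None:
        meta["cell_type"] = data.cell_type
    meta.to_csv(paths["cells"], sep="\t", index=False)
    return paths
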