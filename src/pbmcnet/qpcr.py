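"""Relative quantification of qRT-PCR Cq tables.

Expression is reported as the relative copy number

    RCN = 2**(-dCq) * 100,    dCq = Cq(target) - Cq(reference),

where the per-subject reference Cq is the *median* of the designated
endogenous-control (housekeeping) genes.  RCN = 100 therefore means
"expressed at the level of the housekeeping reference"; each halving of
transcript abundance adds one cycle to Cq and halves the RCN.

The module also provides gene-wise z-score standardization (sample SD,
``ddof=1``), the scale on which metagenes (modular indices) are averaged.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CqTable",
    "ExpressionMatrix",
    "reference_cq",
    "compute_rcn",
    "quantify",
    "standardize",
]


@dataclass
class CqTable:
    """Raw quantification-cycle values, genes as rows and subjects as columns.

    Parameters
    ----------
    values
        DataFrame of Cq values (cycles); index = gene names, columns =
        subject IDs.  Missing measurements may be NaN, except for reference
        genes (checked by :func:`quantify`).
    reference_genes
        Housekeeping genes used for the per-subject reference Cq; must be a
        non-empty subset of the index.
    """

    values: pd.DataFrame
    reference_genes: tuple[str, ...]

    def __post_init__(self) -> None:
        self.reference_genes = tuple(self.reference_genes)
        idx = self.values.index
        if idx.has_duplicates:
            raise ValueError("CqTable: duplicate gene names")
        if self.values.columns.has_duplicates:
            raise ValueError("CqTable: duplicate subject IDs")
        if not self.reference_genes:
            raise ValueError("CqTable: reference_genes must be non-empty")
        missing = [g for g in self.reference_genes if g not in idx]
        if missing:
            raise ValueError(f"CqTable: reference genes absent from table: {missing}")
        finite = np.isfinite(self.values.to_numpy(dtype=float))
        nan = self.values.isna().to_numpy()
        if not np.all(finite | nan):
            raise ValueError("CqTable: Cq values must be finite where present")

    @property
    def genes(self) -> tuple[str, ...]:
        return tuple(self.values.index)

    @property
    def subjects(self) -> tuple[str, ...]:
        return tuple(self.values.columns)


@dataclass
class ExpressionMatrix:
    """Expression values, genes as rows and subjects as columns.

    ``scale`` is ``"rcn"`` (relative copy numbers, non-negative),
    ``"log2"`` (log2 RCN) or ``"zscore"`` (per-gene sample mean 0 and
    sample SD 1).
    """

    values: pd.DataFrame
    scale: str = "rcn"

    def __post_init__(self) -> None:
        if self.scale not in ("rcn", "log2", "zscore"):
            raise ValueError(f"ExpressionMatrix: unknown scale {self.scale!r}")
        if self.values.index.has_duplicates or self.values.columns.has_duplicates:
            raise ValueError("ExpressionMatrix: duplicate gene or subject IDs")
        arr = self.values.to_numpy(dtype=float)
        if self.scale == "rcn":
            ok = np.isnan(arr) | (np.isfinite(arr) & (arr >= 0))
            if not ok.all():
                raise ValueError("ExpressionMatrix: RCN values must be finite and >= 0")

    @property
    def genes(self) -> tuple[str, ...]:
        return tuple(self.values.index)

    @property
    def subjects(self) -> tuple[str, ...]:
        return tuple(self.values.columns)

    def subset(self, genes: Iterable[str]) -> "ExpressionMatrix":
        genes = list(genes)
        unknown = [g for g in genes if g not in self.values.index]
        if unknown:
            raise KeyError(f"unknown genes: {unknown}")
        return ExpressionMatrix(self.values.loc[genes].copy(), scale=self.scale)


def reference_cq(cq_values: Sequence[float]) -> float:
    """Median Cq of the endogenous-control genes for one subject.

    With an even number of controls the mean of the central pair is
    returned.  Raises ``ValueError`` on an empty or non-finite input.
    """
    arr = np.asarray(list(cq_values), dtype=float)
    if arr.size == 0:
        raise ValueError("reference_cq: no reference Cq values supplied")
    if not np.all(np.isfinite(arr)):
        raise ValueError("reference_cq: reference Cq values must be finite")
    return float(np.median(arr))


def compute_rcn(cq_target: float, cq_reference: float) -> float:
    """Relative copy number ``2**-(Cq_target - Cq_reference) * 100``."""
    if not (math.isfinite(cq_target) and math.isfinite(cq_reference)):
        raise ValueError("compute_rcn: Cq values must be finite")
    return float(2.0 ** -(cq_target - cq_reference) * 100.0)


def quantify(cq: CqTable) -> ExpressionMatrix:
    """Convert a Cq table to an RCN expression matrix.

    The reference Cq for each subject is the median of that subject's
    housekeeping Cq values; housekeeping genes are excluded from the output.
    A missing Cq for a reference gene in any subject is an error naming the
    subject.  Missing target Cq values propagate as NaN.
    """
    ref_block = cq.values.loc[list(cq.reference_genes)]
    bad = ref_block.columns[ref_block.isna().any(axis=0)]
    if len(bad):
        raise ValueError(
            f"quantify: missing reference-gene Cq for subject(s): {list(bad)}"
        )
    ref = ref_block.median(axis=0)  # per-subject median of the controls
    targets = [g for g in cq.genes if g not in cq.reference_genes]
    dcq = cq.values.loc[targets].sub(ref, axis=1)
    rcn = np.power(2.0, -dcq) * 100.0
    return ExpressionMatrix(rcn, scale="rcn")


def standardize(m: ExpressionMatrix) -> ExpressionMatrix:
    """Gene-wise z-scores: (x - mean) / SD with sample SD (``ddof=1``).

    Raises ``ValueError`` listing any gene with zero variance or fewer than
    two observed subjects.
    """
    vals = m.values
    n_obs = vals.notna().sum(axis=1)
    sd = vals.std(axis=1, ddof=1)
    bad = list(vals.index[(n_obs < 2) | (sd == 0) | sd.isna()])
    if bad:
        raise ValueError(f"standardize: zero-variance or underobserved genes: {bad}")
    z = vals.sub(vals.mean(axis=1), axis=0).div(sd, axis=0)
    return ExpressionMatrix(z, scale="zscore")
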