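"""Control-vs-patient contrasts: expression shifts and module structure.

Per-gene contrasts use cohort *medians* (RCN distributions are right-
skewed, so medians and a rank test are the defensible defaults):

    percent reduction = 100 * (median_CT - median_HT) / median_CT

with a two-sided Mann-Whitney test by default (Welch t on log2 RCN
optional).  Module-level reduction is the mean ± sample SD of the per-gene
reductions over a gene set.  Structure contrasts compare module counts,
within-module degree ranges and a module-fusion flag between cohorts mined
at identical thresholds.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .network import GeneModule
from .qpcr import ExpressionMatrix

__all__ = [
    "per_gene_contrast",
    "module_reduction",
    "StructureContrast",
    "structure_contrast",
]


def per_gene_contrast(
    ct: ExpressionMatrix,
    ht: ExpressionMatrix,
    test: str = "mann_whitney",
) -> pd.DataFrame:
    """Per-gene medians, percent reduction and test p-value.

    Returns a DataFrame indexed by gene with columns ``median_ct``,
    ``median_ht``, ``pct_reduction``, ``p``.  Both matrices must cover the
    same gene panel (an error names missing genes).
    """
    if test not in ("mann_whitney", "t_test"):
        raise ValueError(f"per_gene_contrast: unknown test {test!r}")
    ct_genes, ht_genes = set(ct.genes), set(ht.genes)
    missing = sorted(ct_genes ^ ht_genes)
    if missing:
        raise ValueError(f"per_gene_contrast: genes missing in one cohort: {missing}")
    rows = []
    for g in ct.genes:
        a = ct.values.loc[g].dropna().to_numpy(dtype=float)
        b = ht.values.loc[g].dropna().to_numpy(dtype=float)
        med_a, med_b = float(np.median(a)), float(np.median(b))
        if med_a <= 0:
            red = np.nan
        else:
            red = 100.0 * (med_a - med_b) / med_a
        if test == "mann_whitney":
            p = float(stats.mannwhitneyu(a, b, alternative="two-sided").pvalue)
        else:
            p = float(stats.ttest_ind(np.log2(a), np.log2(b), equal_var=False).pvalue)
        rows.append((g, med_a, med_b, red, p))
    return pd.DataFrame(
        rows, columns=["gene", "median_ct", "median_ht", "pct_reduction", "p"]
    ).set_index("gene")


def module_reduction(
    contrast: pd.DataFrame, genes: Sequence[str]
) -> tuple[float, float]:
    """Mean and sample SD (%) of per-gene percent reductions over a set."""
    genes = list(genes)
    if not genes:
        raise ValueError("module_reduction: empty gene set")
    missing = [g for g in genes if g not in contrast.index]
    if missing:
        raise ValueError(f"module_reduction: genes absent from contrast: {missing}")
    vals = contrast.loc[genes, "pct_reduction"].to_numpy(dtype=float)
    if np.isnan(vals).any():
        raise ValueError("module_reduction: undefined reductions (zero control median)")
    sd = float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0
    return float(np.mean(vals)), sd


@dataclass
class StructureContrast:
    """Module-structure differences between cohorts mined identically."""

    n_modules_ct: int
    n_modules_ht: int
    degree_range_ct: tuple[int, int]
    degree_range_ht: tuple[int, int]
    fusion: bool

    @property
    def degree_span_ct(self) -> int:
        return self.degree_range_ct[1] - self.degree_range_ct[0]

    @property
    def degree_span_ht(self) -> int:
        return self.degree_range_ht[1] - self.degree_range_ht[0]


def _degree_range(
    modules: Sequence[GeneModule], exclude: set[str]
) -> tuple[int, int]:
    ks = [
        k
        for m in modules
        for v, k in m.degrees.items()
        if v not in exclude
    ]
    if not ks:
        raise ValueError("structure_contrast: no module nodes for degree range")
    return (min(ks), max(ks))


def structure_contrast(
    ct_modules: Sequence[GeneModule],
    ht_modules: Sequence[GeneModule],
    exclude_genes: Sequence[str] = (),
) -> StructureContrast:
    """Compare module counts, degree ranges and fusion between cohorts.

    Degrees are within-module degrees of module members; ``exclude_genes``
    (e.g. leukocyte markers) are dropped from the ranges.  The fusion flag
    is true iff some patient module contains genes *exclusive* to two
    different control modules (shared boundary genes alone do not count).
    """
    if not ct_modules or not ht_modules:
        raise ValueError("structure_contrast: empty module list")
    excl = set(exclude_genes)
    ct_range = _degree_range(ct_modules, excl)
    ht_range = _degree_range(ht_modules, excl)

    # genes unique to each control module
    exclusive: list[set[str]] = []
    for i, m in enumerate(ct_modules):
        others = set().union(
            *(set(o.members) for j, o in enumerate(ct_modules) if j != i)
        ) if len(ct_modules) > 1 else set()
        exclusive.append(set(m.members) - others)
    fusion = False
    for hm in ht_modules:
        hit = sum(1 for ex in exclusive if ex & set(hm.members))
        if hit >= 2:
            fusion = True
            break
    return StructureContrast(
        n_modules_ct=len(ct_modules),
        n_modules_ht=len(ht_modules),
        degree_range_ct=ct_range,
        degree_range_ht=ht_range,
        fusion=fusion,
    )
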