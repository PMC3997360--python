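"""Phenotype-driven functional filtering, modular index, internal consistency.

A module's *modular index* (MI, a metagene) for a subject is the mean of
the z-scored RCNs of the module's member genes.  Gene-level filtering keeps
genes whose Pearson correlation with *every* requested phenotype variable
is significant at an unadjusted p < alpha — a deliberately liberal
criterion (per-gene screening, no multiplicity correction), applied with
the BMI correlation computed within the female stratum.

Because a literal coefficient of determination cannot be negative, the
signed effect-size convention ``signed_r2 = sign(r) * r**2`` is reported
alongside plain r for metagene-phenotype associations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .phenotypes import PhenotypeTable
from .qpcr import ExpressionMatrix, standardize

__all__ = [
    "PhenotypeAssociation",
    "phenotype_correlations",
    "functional_filter",
    "ModularIndexResult",
    "modular_index",
    "cronbach_alpha",
    "radial_profile",
    "DEFAULT_VARIABLES",
]

DEFAULT_VARIABLES = ("age", "AIx", "AoPP", "BMI")


@dataclass(frozen=True)
class PhenotypeAssociation:
    """Pearson association of one gene with one phenotype variable."""

    gene: str
    variable: str
    r: float
    p: float
    n: int
    stratum: str = "all"  # or "females"

    def __post_init__(self) -> None:
        if abs(self.r) > 1 + 1e-12:
            raise ValueError("PhenotypeAssociation: |r| must be <= 1")
        if self.n < 3:
            raise ValueError("PhenotypeAssociation: n must be >= 3")

    @property
    def signed_r2(self) -> float:
        return float(np.sign(self.r) * self.r**2)


def _pearson(x: np.ndarray, y: np.ndarray) -> tuple[float, float, int]:
    mask = np.isfinite(x) & np.isfinite(y)
    n = int(mask.sum())
    if n < 3:
        raise ValueError("phenotype correlation: fewer than 3 complete subjects")
    r, p = stats.pearsonr(x[mask], y[mask])
    return float(r), float(p), n


def phenotype_correlations(
    m: ExpressionMatrix,
    ph: PhenotypeTable,
    variables: Sequence[str] = DEFAULT_VARIABLES,
    bmi_stratum: str = "females",
) -> list[PhenotypeAssociation]:
    """Pearson r and two-sided p for every gene x variable pair.

    Subjects are aligned by intersection of IDs.  The BMI correlation is
    computed within ``bmi_stratum`` ("females" by default, or "all"); an
    error names the stratum if it holds fewer than 3 subjects.
    """
    if bmi_stratum not in ("females", "all"):
        raise ValueError(f"phenotype_correlations: unknown stratum {bmi_stratum!r}")
    common = [s for s in m.subjects if s in set(ph.subjects)]
    if len(common) < 3:
        raise ValueError("phenotype_correlations: fewer than 3 shared subjects")
    expr = m.values[common]
    pv = ph.values.loc[common]

    out: list[PhenotypeAssociation] = []
    for var in variables:
        if var not in pv.columns:
            raise ValueError(f"phenotype_correlations: missing variable {var!r}")
        if var == "BMI" and bmi_stratum == "females":
            sel = pv["sex"] == "F"
            stratum = "females"
            if int(sel.sum()) < 3:
                raise ValueError(
                    "phenotype_correlations: fewer than 3 subjects in stratum 'females'"
                )
        else:
            sel = pd.Series(True, index=pv.index)
            stratum = "all"
        y = pd.to_numeric(pv.loc[sel, var]).to_numpy(dtype=float)
        cols = list(pv.index[sel])
        for gene in expr.index:
            x = expr.loc[gene, cols].to_numpy(dtype=float)
            r, p, n = _pearson(x, y)
            out.append(PhenotypeAssociation(gene, var, r, p, n, stratum))
    return out


def functional_filter(
    assocs: Iterable[PhenotypeAssociation],
    variables: Sequence[str] = DEFAULT_VARIABLES,
    alpha: float = 0.05,
    require: str = "all",
) -> tuple[str, ...]:
    """Genes significant (unadjusted p < alpha) for ALL requested variables.

    Raises ``ValueError`` if any gene is missing an entry for a requested
    variable.  Monotone in alpha: alpha -> 1 returns every gene, alpha -> 0
    returns none.
    """
    if require != "all":
        raise ValueError("functional_filter: only require='all' is supported")
    if not 0.0 < alpha <= 1.0:
        raise ValueError("functional_filter: alpha must be in (0, 1]")
    table: dict[str, dict[str, float]] = {}
    for a in assocs:
        table.setdefault(a.gene, {})[a.variable] = a.p
    kept = []
    for gene, ps in table.items():
        missing = [v for v in variables if v not in ps]
        if missing:
            raise ValueError(
                f"functional_filter: gene {gene!r} missing variables {missing}"
            )
        if all(ps[v] < alpha for v in variables):
            kept.append(gene)
    return tuple(sorted(kept))


@dataclass
class ModularIndexResult:
    """Per-subject metagene values for one gene set.

    ``mi`` has mean 0 (to numerical tolerance) when standardization used the
    same population.  ``associations`` holds MI-phenotype Pearson statistics
    when a phenotype table was supplied.
    """

    genes: tuple[str, ...]
    mi: pd.Series
    cronbach_alpha: float
    associations: dict[str, PhenotypeAssociation] = field(default_factory=dict)


def modular_index(
    m: ExpressionMatrix,
    genes: Sequence[str],
    phenotypes: PhenotypeTable | None = None,
    variables: Sequence[str] = DEFAULT_VARIABLES,
    reference: ExpressionMatrix | None = None,
) -> ModularIndexResult:
    """Metagene MI = mean over member genes of the z-scored RCN.

    ``reference`` selects the standardizing population: by default each
    gene is z-scored against ``m`` itself; pass a control-cohort matrix to
    express patients on the control scale (mean/SD per gene taken from the
    reference, applied to ``m``).
    """
    genes = list(genes)
    if len(genes) < 2:
        raise ValueError("modular_index: need at least 2 genes")
    sub = m.subset(genes)
    if reference is None:
        z = standardize(sub).values
    else:
        ref = reference.subset(genes).values
        mu = ref.mean(axis=1)
        sd = ref.std(axis=1, ddof=1)
        if (sd == 0).any():
            raise ValueError("modular_index: zero-variance reference gene(s)")
        z = sub.values.sub(mu, axis=0).div(sd, axis=0)
    mi = z.mean(axis=0)
    mi.name = "MI"

    alpha = cronbach_alpha(m, genes, mode="standardized")
    result = ModularIndexResult(tuple(genes), mi, alpha)

    if phenotypes is not None:
        common = [s for s in mi.index if s in set(phenotypes.subjects)]
        pv = phenotypes.values.loc[common]
        for var in variables:
            if var == "BMI" and "sex" in pv.columns:
                sel = pv["sex"] == "F"
                stratum = "females"
            else:
                sel = pd.Series(True, index=pv.index)
                stratum = "all"
            y = pd.to_numeric(pv.loc[sel, var]).to_numpy(dtype=float)
            x = mi.loc[pv.index[sel]].to_numpy(dtype=float)
            r, p, n = _pearson(x, y)
            result.associations[var] = PhenotypeAssociation("MI", var, r, p, n, stratum)
    return result


def cronbach_alpha(
    m: ExpressionMatrix, genes: Sequence[str], mode: str = "standardized"
) -> float:
    """Cronbach's alpha of a gene set treated as scale items.

    raw mode:          alpha = K/(K-1) * (1 - sum(item variances) / var(sum))
    standardized mode: alpha = K*rbar / (1 + (K-1)*rbar), rbar = mean
                       inter-item Pearson r (Spearman-Brown form).

    The two agree when all items have equal variance.
    """
    genes = list(genes)
    K = len(genes)
    if K < 2:
        raise ValueError("cronbach_alpha: need at least 2 genes")
    sub = m.subset(genes).values.to_numpy(dtype=float)
    if sub.shape[1] < 3:
        raise ValueError("cronbach_alpha: need at least 3 subjects")
    if np.isnan(sub).any():
        raise ValueError("cronbach_alpha: missing values not supported")
    if mode == "raw":
        item_var = sub.var(axis=1, ddof=1)
        total_var = sub.sum(axis=0).var(ddof=1)
        if total_var == 0:
            raise ValueError("cronbach_alpha: zero total variance")
        return float(K / (K - 1) * (1.0 - item_var.sum() / total_var))
    if mode == "standardized":
        if (sub.std(axis=1, ddof=1) == 0).any():
            raise ValueError("cronbach_alpha: zero-variance item(s)")
        rmat = np.corrcoef(sub)
        iu = np.triu_indices(K, k=1)
        rbar = float(rmat[iu].mean())
        return float(K * rbar / (1.0 + (K - 1) * rbar))
    raise ValueError(f"cronbach_alpha: unknown mode {mode!r}")


def radial_profile(
    m: ExpressionMatrix,
    subject: str,
    reference: ExpressionMatrix | None = None,
) -> pd.Series:
    """Per-gene percent of the population median RCN for one subject.

    ``reference`` supplies the population whose per-gene medians define the
    100 % level (defaults to ``m`` itself; pass the control cohort to
    profile a patient against healthy levels).  Gene order follows the
    matrix row order.  Raises if any reference median is zero.
    """
    if subject not in m.values.columns:
        raise KeyError(f"radial_profile: unknown subject {subject!r}")
    ref = (reference if reference is not None else m).values
    ref = ref.loc[list(m.values.index)]
    med = ref.median(axis=1)
    zero = list(med.index[med == 0])
    if zero:
        raise ValueError(f"radial_profile: zero population median for genes: {zero}")
    pct = 100.0 * m.values[subject] / med
    pct.name = f"percent_of_median[{subject}]"
    return pct
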