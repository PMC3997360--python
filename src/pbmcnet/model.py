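"""Model/results interface over the full bottom-up analysis.

:class:`ModuleNetworkModel` is built from an RCN expression matrix (and
optionally a phenotype table); ``fit()`` runs correlation -> threshold
graph -> clique mining -> density-constrained merging -> connectivity
diagnostics -> phenotype filtering -> metagene, and returns a
:class:`ModuleNetworkResults` carrying every intermediate, with a
``summary()`` table in the spirit of statsmodels results objects.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import pandas as pd

from . import metagene as mg
from .correlation import CorrelationResult, correlation_matrix
from .network import (
    CoexpressionGraph,
    GeneModule,
    build_graph,
    hierarchy_signature,
    identify_hubs,
    maximal_cliques,
    merge_modules,
)
from .phenotypes import PhenotypeTable
from .qpcr import CqTable, ExpressionMatrix, quantify

__all__ = ["ModuleNetworkModel", "ModuleNetworkResults"]


class ModuleNetworkModel:
    """Co-expression module network of a targeted expression panel.

    Parameters
    ----------
    expression
        RCN expression matrix (genes x subjects).
    phenotypes
        Optional subject phenotype table; enables functional filtering and
        metagene-phenotype associations.
    """

    def __init__(
        self,
        expression: ExpressionMatrix,
        phenotypes: PhenotypeTable | None = None,
    ) -> None:
        if expression.scale != "rcn":
            raise ValueError("ModuleNetworkModel expects an RCN-scale matrix")
        self.expression = expression
        self.phenotypes = phenotypes

    @classmethod
    def from_cq(
        cls, cq: CqTable, phenotypes: PhenotypeTable | None = None
    ) -> "ModuleNetworkModel":
        """Build the model directly from a raw Cq table."""
        return cls(quantify(cq), phenotypes=phenotypes)

    def fit(
        self,
        tau: float = 0.7,
        gamma: float = 0.8,
        alpha_corr: float = 0.8,
        variables: Sequence[str] = mg.DEFAULT_VARIABLES,
        alpha: float = 0.05,
    ) -> "ModuleNetworkResults":
        """Run the full analysis at the given thresholds.

        ``tau`` is the |r| edge threshold (strict), ``gamma`` the merge
        density floor, ``alpha_corr`` the mean-|r| floor, and ``alpha`` the
        per-variable significance level of the functional filter.
        """
        corr = correlation_matrix(self.expression)
        graph = build_graph(corr, tau)
        cliques = maximal_cliques(graph)
        modules = merge_modules(cliques, corr, graph, gamma, alpha_corr)
        if modules:
            identify_hubs(graph, modules)
        slopes = {
            i: hierarchy_signature(
                [(k, m.clustering[v]) for v, k in m.degrees.items()]
            )
            for i, m in enumerate(modules)
        }

        associations: list[mg.PhenotypeAssociation] = []
        functional: tuple[str, ...] = ()
        mi_result = None
        if self.phenotypes is not None:
            associations = mg.phenotype_correlations(
                self.expression, self.phenotypes, variables
            )
            functional = mg.functional_filter(associations, variables, alpha)
            if len(functional) >= 2:
                mi_result = mg.modular_index(
                    self.expression, functional, self.phenotypes, variables
                )
        return ModuleNetworkResults(
            model=self,
            params=dict(tau=tau, gamma=gamma, alpha_corr=alpha_corr, alpha=alpha,
                        variables=tuple(variables)),
            correlations=corr,
            graph=graph,
            cliques=cliques,
            modules=modules,
            hierarchy_slopes=slopes,
            associations=associations,
            functional_genes=functional,
            modular_index=mi_result,
        )


@dataclass
class ModuleNetworkResults:
    """Fitted module network: modules, diagnostics and metagene."""

    model: ModuleNetworkModel
    params: dict
    correlations: CorrelationResult
    graph: CoexpressionGraph
    cliques: list
    modules: list[GeneModule]
    hierarchy_slopes: dict[int, float | None]
    associations: list[mg.PhenotypeAssociation] = field(default_factory=list)
    functional_genes: tuple[str, ...] = ()
    modular_index: mg.ModularIndexResult | None = None

    def association_frame(self) -> pd.DataFrame:
        rows = [
            (a.gene, a.variable, a.r, a.signed_r2, a.p, a.n, a.stratum)
            for a in self.associations
        ]
        return pd.DataFrame(
            rows, columns=["gene", "variable", "r", "signed_r2", "p", "n", "stratum"]
        )

    def module_frame(self) -> pd.DataFrame:
        rows = []
        for i, m in enumerate(self.modules):
            ks = list(m.degrees.values())
            rows.append(
                (
                    i,
                    len(m),
                    m.density,
                    m.mean_abs_corr,
                    min(ks) if ks else 0,
                    max(ks) if ks else 0,
                    self.hierarchy_slopes.get(i),
                    ",".join(m.hubs),
                    ",".join(m.members),
                )
            )
        return pd.DataFrame(
            rows,
            columns=[
                "module", "size", "density", "mean_abs_corr",
                "k_min", "k_max", "ck_slope", "hubs", "members",
            ],
        )

    def summary(self) -> str:
        """Human-readable report of the fitted network."""
        p = self.params
        lines = [
            "Co-expression module network",
            "=" * 60,
            f"genes: {len(self.correlations.genes)}   "
            f"subjects: {len(self.model.expression.subjects)}",
            f"edge threshold |r| > {p['tau']}, density floor {p['gamma']}, "
            f"mean-|r| floor {p['alpha_corr']}",
            f"maximal cliques: {len(self.cliques)}   modules: {len(self.modules)}",
            "",
        ]
        for i, m in enumerate(self.modules):
            slope = self.hierarchy_slopes.get(i)
            slope_s = f"{slope:+.3f}" if slope is not None else "undefined"
            lines.append(
                f"module {i}: size={len(m)} density={m.density:.3f} "
                f"mean|r|={m.mean_abs_corr:.3f} C(k)~k slope={slope_s}"
            )
            if m.hubs:
                lines.append(f"  hubs: {', '.join(m.hubs)}")
            lines.append(f"  members: {', '.join(m.members)}")
        if self.functional_genes:
            lines += [
                "",
                f"functional filter (p < {p['alpha']} for all of "
                f"{', '.join(p['variables'])}): {len(self.functional_genes)} genes",
                "  " + ", ".join(self.functional_genes),
            ]
        if self.modular_index is not None:
            lines += [
                "",
                f"modular index over {len(self.modular_index.genes)} genes, "
                f"Cronbach alpha (standardized) = {self.modular_index.cronbach_alpha:.4f}",
            ]
            for var, a in self.modular_index.associations.items():
                lines.append(
                    f"  MI ~ {var:5s}: r={a.r:+.3f} signed_r2={a.signed_r2:+.3f} "
                    f"p={a.p:.4f} n={a.n} [{a.stratum}]"
                )
        return "\n".join(lines)
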