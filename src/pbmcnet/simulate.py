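"""Seeded synthetic cohorts with planted co-expression structure.

The generator emulates a targeted qRT-PCR study of PBMC samples: a 45-gene
panel (plus three housekeeping controls) measured in a small cohort, with

* two co-expression modules driven by latent factors on the log2 (Cq)
  scale — a gene of module *m* has ``log2-expression = loading * f_m +
  noise``, so the planted pairwise correlation between two module genes is
  ``loading**2 / (loading**2 + noise_sd**2)`` (0.9 by default);
* a cardiovascular module (module 1) whose latent factor drives the
  vascular-health phenotypes: each coupled phenotype is generated as a
  child of the factor, ``z_v = w_v * f1 + sqrt(1 - w_v**2) * eps`` with
  ``w_v`` chosen so that the *per-gene* gene-phenotype correlation equals
  the requested coupling (negative for age/AIx/AoPP, positive for BMI, the
  latter in females only);
* abundant leukocyte genes uncorrelated with either factor;
* an optional hypertensive cohort with per-gene planted percent reductions
  of RCN (Beta-distributed with a configurable mean ± SD, clipped at 95 %)
  and a ``coupling_tightening`` factor >= 1 on the loadings that raises
  within- and between-module correlations, emulating module fusion and
  degree-range compaction in patients.

Because the coupled phenotypes are children of one latent factor, they are
mutually correlated (approximately the product of their coupling weights);
their residual components are independent.  Phenotype marginals are uniform
over the printed cohort ranges via a Gaussian copula.

Identical ``(spec, seed)`` pairs reproduce byte-identical tables.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace, asdict

import numpy as np
import pandas as pd
from scipy.stats import norm

from .panel import GenePanel, default_panel
from .phenotypes import PhenotypeTable
from .qpcr import CqTable

__all__ = [
    "CohortSpec",
    "default_control_spec",
    "default_hypertensive_spec",
    "generate_cohort",
    "noise_sd_for_pairwise_r",
    "null_spec",
    "saturated_module_spec",
]

#: default per-gene loading on the module latent factor (cycles per unit
#: latent).  Together with the default noise SD this plants a within-module
#: pairwise correlation of 0.9 on the log2 (Cq) scale with a total per-gene
#: log2 SD of ~0.53 cycles; at this moderate amplitude the Pearson
#: correlations the pipeline computes on the raw RCN scale stay close to
#: the planted log-scale values (lognormal attenuation < 2 %).
DEFAULT_LOADING = 0.5

#: noise SD (cycles) giving the planted pairwise correlation of 0.9 at the
#: default loading: r = loading^2 / (loading^2 + sd^2).
DEFAULT_NOISE_SD = DEFAULT_LOADING * math.sqrt(0.1 / 0.9)


def noise_sd_for_pairwise_r(r: float, loading: float = 1.0) -> float:
    """Noise SD (cycles) planting log2-scale pairwise correlation ``r``
    between equal-loading module genes: r = loading^2/(loading^2 + sd^2)."""
    if not 0.0 < r < 1.0:
        raise ValueError("noise_sd_for_pairwise_r: r must be in (0, 1)")
    return loading * math.sqrt((1.0 - r) / r)

_CONTROL_RANGES = {
    "age": (19.0, 58.0),
    "BMI": (19.2, 53.13),
    "AIx": (-8.0, 43.0),
    "AoPP": (19.0, 50.0),
    "AoSP": (87.0, 124.0),
}
_HT_RANGES = {
    "age": (41.0, 85.0),
    "BMI": (20.0, 39.0),
    "AIx": (5.0, 50.0),
    "AoPP": (25.0, 60.0),
    "AoSP": (100.0, 160.0),
}

#: target per-gene gene-phenotype correlations (log2 scale) for module 1:
#: strong negative vascular-aging couplings, strong positive BMI coupling
#: within females (the female stratum is small, n ~ 14, so its coupling is
#: planted at the top of the realistic per-gene range to keep the planted
#: signal recoverable there).
_DEFAULT_COUPLINGS = {"age": -0.85, "AIx": -0.85, "AoPP": -0.85, "BMI": 0.90}

_BASELINE_CQ_RANGES = {
    "module1": (26.0, 31.0),
    "module2": (25.0, 32.0),
    "leukocyte": (15.5, 19.5),
    "housekeeping": (17.5, 19.5),
}


def _default_baselines(panel: GenePanel) -> dict[str, float]:
    out: dict[str, float] = {}
    for cls in ("module1", "module2", "leukocyte", "housekeeping"):
        genes = panel.genes_of_class(cls)
        lo, hi = _BASELINE_CQ_RANGES[cls]
        vals = np.linspace(lo, hi, num=max(len(genes), 1))
        out.update(dict(zip(genes, map(float, vals))))
    return out


@dataclass
class CohortSpec:
    """Full parameterization of one synthetic cohort.

    ``module1_phenotype_couplings`` maps phenotype name -> signed target
    *per-gene* Pearson correlation between module-1 genes and that
    phenotype; the BMI coupling applies within females only.  Coupling
    magnitudes must stay below the module attenuation
    ``loading / sqrt(loading**2 + noise_sd**2)`` (≈0.92 at defaults).
    """

    n_subjects: int = 26
    cohort_label: str = "control"
    panel: GenePanel = field(default_factory=default_panel)
    module1_phenotype_couplings: dict[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_COUPLINGS)
    )
    module_loading: dict[str, float] = field(default_factory=dict)
    default_loading: float = DEFAULT_LOADING
    noise_sd: float = DEFAULT_NOISE_SD
    baseline_cq: dict[str, float] = field(default_factory=dict)
    ht_reduction_pct: tuple[float, float] = (72.0, 22.0)  # mean, SD (%)
    coupling_tightening: float = 1.0
    module_factor_corr: float = 0.1
    female_fraction: float = 14 / 26
    leukocyte_noise_sd: float = 1.0
    housekeeping_noise_sd: float = 0.1
    hub_genes: tuple[str, ...] = ()
    hub_primary_loading: float = 1.0
    hub_cross_loading: float = 0.0
    phenotype_ranges: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(_CONTROL_RANGES)
    )
    seed: int = 0

    # -- derived quantities -------------------------------------------------

    def loading(self, gene: str) -> float:
        return self.module_loading.get(gene, self.default_loading) * self.coupling_tightening

    @property
    def attenuation(self) -> float:
        """corr(gene, latent) for a module-1 gene at the mean loading."""
        lams = [self.loading(g) for g in self.panel.module1]
        lam = float(np.mean(lams)) if lams else 1.0
        return lam / math.sqrt(lam * lam + self.noise_sd**2)

    def baselines(self) -> dict[str, float]:
        base = _default_baselines(self.panel)
        base.update(self.baseline_cq)
        return base

    # -- validation ---------------------------------------------------------

    def validate(self) -> None:
        if self.n_subjects < 4:
            raise ValueError("CohortSpec.n_subjects: must be >= 4")
        if self.cohort_label not in ("control", "hypertensive"):
            raise ValueError("CohortSpec.cohort_label: must be control|hypertensive")
        if len(self.panel.housekeeping) < 3:
            raise ValueError("CohortSpec.panel: needs >= 3 housekeeping genes")
        if not self.noise_sd > 0:
            raise ValueError("CohortSpec.noise_sd: must be > 0")
        if self.coupling_tightening < 1.0:
            raise ValueError("CohortSpec.coupling_tightening: must be >= 1")
        if not -1.0 < self.module_factor_corr < 1.0:
            raise ValueError("CohortSpec.module_factor_corr: must be in (-1, 1)")
        if not 0.0 <= self.female_fraction <= 1.0:
            raise ValueError("CohortSpec.female_fraction: must be in [0, 1]")
        a = self.attenuation
        for var, c in self.module1_phenotype_couplings.items():
            if not abs(c) < 1.0:
                raise ValueError(
                    f"CohortSpec.module1_phenotype_couplings[{var!r}]: |coupling| must be < 1"
                )
            if abs(c) >= a:
                raise ValueError(
                    f"CohortSpec.module1_phenotype_couplings[{var!r}]: magnitude "
                    f"{abs(c):.3f} exceeds the module attenuation {a:.3f}"
                )
            if var != "BMI" and var not in self.phenotype_ranges:
                raise ValueError(f"CohortSpec.phenotype_ranges: missing range for {var!r}")
        mean, sd = self.ht_reduction_pct
        if not 0.0 < mean < 100.0:
            raise ValueError("CohortSpec.ht_reduction_pct: mean must be in (0, 100)")
        mu, var = mean / 100.0, (sd / 100.0) ** 2
        if not 0.0 < var < mu * (1 - mu):
            raise ValueError(
                "CohortSpec.ht_reduction_pct: SD incompatible with a (0,100)% Beta law"
            )
        unknown = [g for g in self.hub_genes if g not in self.panel.genes]
        if unknown:
            raise ValueError(f"CohortSpec.hub_genes: unknown genes {unknown}")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["panel"] = {"genes": list(self.panel.genes), "classes": dict(self.panel.classes)}
        return d


def default_control_spec(seed: int = 0, **overrides) -> CohortSpec:
    """Healthy cohort: n=26, two planted modules, coupled phenotypes."""
    return replace(CohortSpec(seed=seed), **overrides)


def default_hypertensive_spec(seed: int = 0, **overrides) -> CohortSpec:
    """Patient cohort: n=20, planted RCN reductions (72±22 %), tightened and
    fused module coupling."""
    spec = CohortSpec(
        n_subjects=20,
        cohort_label="hypertensive",
        coupling_tightening=1.6,
        module_factor_corr=0.95,
        female_fraction=0.30,
        phenotype_ranges=dict(_HT_RANGES),
        seed=seed,
    )
    return replace(spec, **overrides)


def null_spec(seed: int = 0, **overrides) -> CohortSpec:
    """A no-structure cohort: zero loadings, no phenotype couplings.

    Every gene is constant + modest independent noise and every phenotype
    is independent of expression — the null model for edge-rate and
    type-I-error checks.
    """
    spec = CohortSpec(
        default_loading=0.0,
        module1_phenotype_couplings={},
        module_factor_corr=0.0,
        leukocyte_noise_sd=0.3,
        seed=seed,
    )
    return replace(spec, **overrides)


#: planted log2-scale pairwise correlation whose *expected empirical* mean
#: inter-item Pearson correlation at n=26 is 0.80: the sample mean pairwise
#: r of a one-factor model is attenuated below the planted value at small n
#: (the factor's sample variance enters every pair), so the plant is
#: calibrated upward (Monte-Carlo over 150 seeds).
SATURATED_ITEM_R_PLANT = 0.81


def saturated_module_spec(seed: int = 0, **overrides) -> CohortSpec:
    """Cohort whose module items have expected mean inter-item r = 0.8 at
    n=26 — the saturation scenario for internal-consistency (Cronbach
    alpha) analysis of a 15-gene metagene."""
    spec = CohortSpec(
        noise_sd=noise_sd_for_pairwise_r(SATURATED_ITEM_R_PLANT, DEFAULT_LOADING),
        module1_phenotype_couplings={},
        seed=seed,
    )
    return replace(spec, **overrides)


def _draw_reductions(rng: np.random.Generator, mean: float, sd: float, size: int) -> np.ndarray:
    """Per-gene percent reductions: Beta on (0,100)% with the given mean/SD,
    clipped at 95 % (reductions beyond ~100 % are meaningless)."""
    mu, var = mean / 100.0, (sd / 100.0) ** 2
    nu = mu * (1 - mu) / var - 1.0
    a, b = mu * nu, (1 - mu) * nu
    pct = rng.beta(a, b, size=size) * 100.0
    return np.minimum(pct, 95.0)


def generate_cohort(
    spec: CohortSpec, return_latents: bool = False
) -> tuple[CqTable, PhenotypeTable] | tuple[CqTable, PhenotypeTable, pd.DataFrame]:
    """Generate one cohort: a Cq table and a matching phenotype table.

    With ``return_latents=True`` the per-subject latent factors ``f1``/``f2``
    are returned as a third element (diagnostics only).
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n = spec.n_subjects
    prefix = "CT" if spec.cohort_label == "control" else "HT"
    subjects = [f"{prefix}{i + 1:02d}" for i in range(n)]

    # fixed sex composition (like the study cohorts), shuffled positions
    n_female = int(round(spec.female_fraction * n))
    female = np.zeros(n, dtype=bool)
    female[rng.permutation(n)[:n_female]] = True
    f1 = rng.standard_normal(n)
    rho = spec.module_factor_corr
    f2 = rho * f1 + math.sqrt(1.0 - rho * rho) * rng.standard_normal(n)

    a = spec.attenuation
    pheno: dict[str, np.ndarray | list[str]] = {}
    for var in ("age", "BMI", "AIx", "AoPP", "AoSP"):
        lo, hi = spec.phenotype_ranges[var]
        c = spec.module1_phenotype_couplings.get(var, 0.0)
        w = c / a if c else 0.0  # latent weight reproducing the per-gene coupling
        eps = rng.standard_normal(n)
        if var == "BMI":
            z = np.where(female, w * f1 + math.sqrt(1 - w * w) * eps, eps)
        else:
            z = w * f1 + math.sqrt(1 - w * w) * eps
        pheno[var] = lo + (hi - lo) * norm.cdf(z)  # uniform marginal via copula

    sigma = spec.noise_sd
    baselines = spec.baselines()
    classes = spec.panel.classes
    x_rows: dict[str, np.ndarray] = {}
    for g in spec.panel.genes:
        cls = classes[g]
        eps = rng.standard_normal(n)
        if cls == "housekeeping":
            x = spec.housekeeping_noise_sd * eps
        elif cls == "leukocyte":
            x = spec.leukocyte_noise_sd * eps
        elif g in spec.hub_genes:
            lam = spec.loading(g)
            x = (
                spec.hub_primary_loading * lam * (f1 if cls == "module1" else f2)
                + spec.hub_cross_loading * (f2 if cls == "module1" else f1)
                + sigma * eps
            )
        elif cls == "module1":
            x = spec.loading(g) * f1 + sigma * eps
        else:  # module2
            x = spec.loading(g) * f2 + sigma * eps
        x_rows[g] = x

    if spec.cohort_label == "hypertensive":
        mean, sd = spec.ht_reduction_pct
        module_genes = [g for g in spec.panel.genes if classes[g] in ("module1", "module2")]
        pct = _draw_reductions(rng, mean, sd, len(module_genes))
        shift = {g: -math.log2(1.0 - p / 100.0) for g, p in zip(module_genes, pct)}
    else:
        shift = {}

    cq = pd.DataFrame(
        {
            g: baselines[g] - x_rows[g] + shift.get(g, 0.0)
            for g in spec.panel.genes
        },
        index=subjects,
    ).T
    cq.index.name = "gene"
    cq_table = CqTable(cq, reference_genes=spec.panel.housekeeping)

    pdf = pd.DataFrame(pheno, index=subjects)
    pdf["sex"] = np.where(female, "F", "M")
    pdf["cohort"] = spec.cohort_label
    pdf = pdf[["age", "sex", "BMI", "AIx", "AoPP", "AoSP", "cohort"]]
    pdf.index.name = "subject"
    pheno_table = PhenotypeTable(pdf)

    if return_latents:
        latents = pd.DataFrame({"f1": f1, "f2": f2}, index=subjects)
        return cq_table, pheno_table, latents
    return cq_table, pheno_table
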