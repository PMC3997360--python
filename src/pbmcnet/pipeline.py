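"""End-to-end orchestration with a reproducible run manifest.

Stages: simulate (or load) -> quantify -> correlate -> network -> metagene
-> compare.  Stages communicate only through files under the output
directory; the manifest records every threshold, the seed and the package
version, so a rerun from the same config reproduces module membership and
MI values bit-identically.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

from . import __version__, io
from . import metagene as mg
from .contrast import per_gene_contrast, module_reduction, structure_contrast
from .model import ModuleNetworkModel
from .panel import default_panel
from .simulate import default_control_spec, default_hypertensive_spec, generate_cohort

__all__ = ["RunConfig", "run_pipeline", "PipelineError"]


class PipelineError(RuntimeError):
    """A stage failure, annotated with the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    """Configuration of one pipeline run (round-trips through YAML)."""

    out_dir: str = "pbmcnet_run"
    seed: int = 0
    simulate: bool = True
    compare_hypertensive: bool = True
    cq_path: str | None = None
    pheno_path: str | None = None
    ht_cq_path: str | None = None
    ht_pheno_path: str | None = None
    reference_genes: tuple[str, ...] = ("B2M", "GAPDH", "RPL13")
    tau: float = 0.7
    gamma: float = 0.8
    alpha_corr: float = 0.8
    alpha: float = 0.05
    variables: tuple[str, ...] = tuple(mg.DEFAULT_VARIABLES)

    def validate(self) -> None:
        for name, lo, hi in (("tau", 0.0, 1.0), ("gamma", 0.0, 1.0),
                             ("alpha_corr", 0.0, 1.0), ("alpha", 0.0, 1.0)):
            v = getattr(self, name)
            if not lo <= v <= hi:
                raise ValueError(f"RunConfig.{name}: must be in [{lo}, {hi}]")
        if not self.simulate and (self.cq_path is None or self.pheno_path is None):
            raise ValueError("RunConfig: cq_path and pheno_path required when simulate=False")

    def to_yaml(self, path: str | Path) -> None:
        d = asdict(self)
        d["reference_genes"] = list(self.reference_genes)
        d["variables"] = list(self.variables)
        io.write_yaml(d, path)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        d = io.read_yaml(path)
        d["reference_genes"] = tuple(d.get("reference_genes", ()))
        d["variables"] = tuple(d.get("variables", mg.DEFAULT_VARIABLES))
        return cls(**d)


def _stage(name: str):
    def deco(fn):
        def wrapped(*a, **kw):
            try:
                return fn(*a, **kw)
            except PipelineError:
                raise
            except Exception as e:  # noqa: BLE001 - annotate and re-raise
                raise PipelineError(name, e) from e
        return wrapped
    return deco


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages; return (and write) the run manifest."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "config": json.loads(json.dumps(asdict(config), default=list)),
        "stages": {},
    }

    @_stage("input")
    def load_inputs():
        if config.simulate:
            spec = default_control_spec(seed=config.seed)
            cq, ph = generate_cohort(spec)
        else:
            cq = io.read_cq(config.cq_path, config.reference_genes or None)
            ph = io.read_phenotypes(config.pheno_path)
        io.write_cq(cq, out / "cq.tsv")
        io.write_phenotypes(ph, out / "pheno.tsv")
        return cq, ph

    cq, ph = load_inputs()
    manifest["stages"]["input"] = {"cq": "cq.tsv", "pheno": "pheno.tsv"}

    @_stage("fit")
    def fit_model():
        model = ModuleNetworkModel.from_cq(cq, phenotypes=ph)
        return model, model.fit(
            tau=config.tau, gamma=config.gamma, alpha_corr=config.alpha_corr,
            variables=config.variables, alpha=config.alpha,
        )

    model, res = fit_model()

    @_stage("outputs")
    def write_outputs():
        io.write_expression(model.expression, out / "rcn.tsv")
        io.write_matrix(res.correlations.r, out / "corr_r.tsv")
        io.write_matrix(res.correlations.p_raw, out / "corr_p.tsv")
        io.write_matrix(res.correlations.p_adj, out / "corr_p_adj.tsv")
        io.write_graph(res.graph, out / "graph.graphml", out / "edges.tsv")
        io.modules_to_json(res.modules, out / "modules.json")
        res.association_frame().to_csv(out / "associations.tsv", sep="\t", index=False)
        if res.modular_index is not None:
            res.modular_index.mi.to_frame().to_csv(out / "modular_index.tsv", sep="\t")
        (out / "summary.txt").write_text(res.summary() + "\n")

    write_outputs()
    manifest["stages"]["network"] = {
        "n_cliques": len(res.cliques),
        "n_modules": len(res.modules),
        "no_modules": len(res.modules) == 0,
        "modules": "modules.json",
    }
    manifest["stages"]["metagene"] = {
        "functional_genes": list(res.functional_genes),
        "cronbach_alpha": (
            None if res.modular_index is None else res.modular_index.cronbach_alpha
        ),
        "mi_associations": {
            var: {"r": a.r, "signed_r2": a.signed_r2, "p": a.p, "n": a.n}
            for var, a in (res.modular_index.associations.items()
                           if res.modular_index else ())
        },
    }

    if config.compare_hypertensive:
        @_stage("compare")
        def compare():
            panel = default_panel()
            if config.simulate:
                ht_spec = default_hypertensive_spec(seed=config.seed + 1)
                ht_cq, ht_ph = generate_cohort(ht_spec)
            else:
                if config.ht_cq_path is None:
                    return None
                ht_cq = io.read_cq(config.ht_cq_path, config.reference_genes or None)
                ht_ph = io.read_phenotypes(config.ht_pheno_path)
            io.write_cq(ht_cq, out / "ht_cq.tsv")
            io.write_phenotypes(ht_ph, out / "ht_pheno.tsv")
            ht_model = ModuleNetworkModel.from_cq(ht_cq, phenotypes=ht_ph)
            ht_res = ht_model.fit(
                tau=config.tau, gamma=config.gamma, alpha_corr=config.alpha_corr,
                variables=(), alpha=config.alpha,
            )
            io.modules_to_json(ht_res.modules, out / "ht_modules.json")
            cdf = per_gene_contrast(model.expression, ht_model.expression)
            cdf.to_csv(out / "contrast.tsv", sep="\t")
            info: dict = {"contrast": "contrast.tsv", "ht_modules": "ht_modules.json"}
            m1 = [g for g in panel.module1 if g in cdf.index]
            if m1:
                mean, sd = module_reduction(cdf, m1)
                info["module1_reduction_mean_pct"] = mean
                info["module1_reduction_sd_pct"] = sd
            if res.modules and ht_res.modules:
                sc = structure_contrast(res.modules, ht_res.modules,
                                        exclude_genes=panel.leukocyte)
                info["structure"] = {
                    "n_modules_ct": sc.n_modules_ct,
                    "n_modules_ht": sc.n_modules_ht,
                    "degree_range_ct": list(sc.degree_range_ct),
                    "degree_range_ht": list(sc.degree_range_ht),
                    "fusion": sc.fusion,
                }
            return info

        info = compare()
        if info is not None:
            manifest["stages"]["compare"] = info

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest
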