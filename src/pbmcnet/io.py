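"""Text-format I/O: TSV tables, module JSON, GraphML/edge lists, YAML specs."""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import networkx as nx
import pandas as pd
import yaml

from .network import CoexpressionGraph, GeneModule
from .phenotypes import PhenotypeTable
from .qpcr import CqTable, ExpressionMatrix

_FLOAT_FMT = "%.10g"


def write_cq(cq: CqTable, path: str | Path) -> None:
    df = cq.values.copy()
    df.index.name = "gene"
    df.to_csv(path, sep="\t", float_format=_FLOAT_FMT)
    ref_path = Path(path).with_suffix(".refs.txt")
    ref_path.write_text("\n".join(cq.reference_genes) + "\n")


def read_cq(path: str | Path, reference_genes: Sequence[str] | None = None) -> CqTable:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if reference_genes is None:
        ref_path = Path(path).with_suffix(".refs.txt")
        if not ref_path.exists():
            raise ValueError("read_cq: reference genes not given and no .refs.txt found")
        reference_genes = [
            line.strip() for line in ref_path.read_text().splitlines() if line.strip()
        ]
    return CqTable(df, tuple(reference_genes))


def write_phenotypes(ph: PhenotypeTable, path: str | Path) -> None:
    df = ph.values.copy()
    df.index.name = "subject"
    df.to_csv(path, sep="\t", float_format=_FLOAT_FMT)


def read_phenotypes(path: str | Path) -> PhenotypeTable:
    return PhenotypeTable(pd.read_csv(path, sep="\t", index_col=0))


def write_expression(m: ExpressionMatrix, path: str | Path) -> None:
    df = m.values.copy()
    df.index.name = "gene"
    df.to_csv(path, sep="\t", float_format=_FLOAT_FMT)


def read_expression(path: str | Path, scale: str = "rcn") -> ExpressionMatrix:
    return ExpressionMatrix(pd.read_csv(path, sep="\t", index_col=0), scale=scale)


def write_matrix(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", float_format=_FLOAT_FMT)


def write_graph(g: CoexpressionGraph, graphml_path: str | Path,
                edgelist_path: str | Path | None = None) -> None:
    nx.write_graphml(g.graph, graphml_path)
    if edgelist_path is not None:
        rows = [
            {"gene_a": a, "gene_b": b, "abs_r": d["weight"]}
            for a, b, d in g.graph.edges(data=True)
        ]
        pd.DataFrame(rows, columns=["gene_a", "gene_b", "abs_r"]).to_csv(
            edgelist_path, sep="\t", index=False, float_format=_FLOAT_FMT
        )


def modules_to_json(modules: Sequence[GeneModule], path: str | Path) -> None:
    payload = [
        {
            "members": list(m.members),
            "density": m.density,
            "mean_abs_corr": m.mean_abs_corr,
            "degrees": m.degrees,
            "clustering": m.clustering,
            "hubs": list(m.hubs),
        }
        for m in modules
    ]
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


def modules_from_json(path: str | Path) -> list[GeneModule]:
    payload = json.loads(Path(path).read_text())
    return [
        GeneModule(
            members=tuple(m["members"]),
            density=m["density"],
            mean_abs_corr=m["mean_abs_corr"],
            degrees={k: int(v) for k, v in m["degrees"].items()},
            clustering={k: float(v) for k, v in m["clustering"].items()},
            hubs=tuple(m["hubs"]),
        )
        for m in payload
    ]


def write_yaml(obj: dict, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(obj, sort_keys=True))


def read_yaml(path: str | Path) -> dict:
    return yaml.safe_load(Path(path).read_text())
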