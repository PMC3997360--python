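"""Default targeted qRT-PCR gene panel.

The panel holds 45 assay genes — primitive (stem/progenitor), cardiovascular
and tissue differentiation, and leukocyte lineage markers — plus three
endogenous-control (housekeeping) genes used for ΔCq normalization.

Each gene carries one class label:

``module1``
    The 15 primitive + cardiovascular differentiation markers whose
    expression tracks vascular-health variables (age, augmentation index,
    aortic pulse pressure, BMI in females) in healthy adults.
``module2``
    The remaining primitive / tissue differentiation markers, forming the
    second co-expression community.
``leukocyte``
    Abundant leukocyte-lineage genes (high relative copy number, not part of
    either co-expression module).
``housekeeping``
    Endogenous controls; the per-subject reference Cq is their median.
"""

from __future__ import annotations

from dataclasses import dataclass, field

GENE_CLASSES = ("module1", "module2", "leukocyte", "housekeeping")

#: Cardiovascular/primitive markers significantly correlated with all four
#: vascular-health variables in healthy adults.
MODULE1_GENES: tuple[str, ...] = (
    "ABCG2", "ALPL", "CAV3", "CNN1", "FSHR", "KDR", "KIT", "NANOG",
    "NES", "NKX2-5", "NOS3", "NOTCH4", "OLR1", "POU5F1", "TEK",
)

#: Other primitive and tissue-differentiation markers of the panel.
MODULE2_GENES: tuple[str, ...] = (
    "ADIPOQ", "CDH5", "GATA4", "KRT14", "MAP2", "MKI67", "PROM1",
    "CD34", "ST3GAL2", "THY1", "ACTA2", "ALDH1A1", "BGLAP",
    "SOX2", "MYH11", "RUNX2", "PPARG", "AFP", "NEUROD1", "DES", "VIM",
)

#: Abundant leukocyte-lineage genes.
LEUKOCYTE_GENES: tuple[str, ...] = (
    "PTPRC", "CD14", "CD3E", "CD79A", "ITGAM", "PECAM1", "NT5E",
    "CX3CR1", "CXCR4",
)

#: Endogenous controls (beta-2 microglobulin, GAPDH, RPL13).
HOUSEKEEPING_GENES: tuple[str, ...] = ("B2M", "GAPDH", "RPL13")


@dataclass(frozen=True)
class GenePanel:
    """An ordered gene panel with one class label per gene.

    Parameters
    ----------
    genes
        Ordered gene symbols (assay genes first, housekeeping last by
        convention; any order is accepted).
    classes
        Mapping gene -> class label, one of :data:`GENE_CLASSES`.
    """

    genes: tuple[str, ...]
    classes: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("panel: duplicate gene names")
        missing = [g for g in self.genes if g not in self.classes]
        if missing:
            raise ValueError(f"panel: genes without class label: {missing}")
        bad = {g: c for g, c in self.classes.items() if c not in GENE_CLASSES}
        if bad:
            raise ValueError(f"panel: unknown class labels: {bad}")

    def genes_of_class(self, cls: str) -> tuple[str, ...]:
        return tuple(g for g in self.genes if self.classes[g] == cls)

    @property
    def housekeeping(self) -> tuple[str, ...]:
        return self.genes_of_class("housekeeping")

    @property
    def assay_genes(self) -> tuple[str, ...]:
        """All genes except the housekeeping controls, in panel order."""
        return tuple(g for g in self.genes if self.classes[g] != "housekeeping")

    @property
    def module1(self) -> tuple[str, ...]:
        return self.genes_of_class("module1")

    @property
    def module2(self) -> tuple[str, ...]:
        return self.genes_of_class("module2")

    @property
    def leukocyte(self) -> tuple[str, ...]:
        return self.genes_of_class("leukocyte")


def default_panel() -> GenePanel:
    """The default 45-gene panel plus three housekeeping controls."""
    order = MODULE1_GENES + MODULE2_GENES + LEUKOCYTE_GENES + HOUSEKEEPING_GENES
    classes: dict[str, str] = {}
    classes.update({g: "module1" for g in MODULE1_GENES})
    classes.update({g: "module2" for g in MODULE2_GENES})
    classes.update({g: "leukocyte" for g in LEUKOCYTE_GENES})
    classes.update({g: "housekeeping" for g in HOUSEKEEPING_GENES})
    return GenePanel(genes=order, classes=classes)
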