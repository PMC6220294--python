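"""Synthetic qPCR crossing-point (Cp) tables with known ground truth.

The generator emulates a relative-expression experiment: one target gene and
one or more reference genes measured in control and treatment samples, each
with technical replicates.  Crossing points follow

    Cp = base_cp(gene) - log_E(concentration) + noise

where E is the gene's amplification efficiency.  Treatment samples carry
``true_ratio`` times the target template; reference genes are unaffected.
Technical replicates share the biological draw and add independent Gaussian
noise of ``cp_noise_sd`` cycles; an optional ``sample_sd`` adds biological
scatter per sample x gene.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd


@dataclass
class QpcrSimDesign:
    """Design of a simulated relative-expression experiment.

    Efficiencies default to perfect doubling (E = 2) for every gene.
    ``true_ratio`` is the fold change of the target in treatment relative to
    control; 1.0 is the null.
    """

    target: str = "Dnmt1"
    references: tuple[str, ...] = ("RpL13a", "rp49")
    efficiencies: Mapping[str, float] | None = None
    true_ratio: float = 1.0
    n_control: int = 4
    n_treatment: int = 4
    n_tech: int = 2
    cp_noise_sd: float = 0.15
    sample_sd: float = 0.0
    base_cp: float | Mapping[str, float] = 22.0
    seed: int = 0

    def genes(self) -> tuple[str, ...]:
        return (self.target,) + tuple(self.references)

    def efficiency(self, gene: str) -> float:
        if self.efficiencies is None:
            return 2.0
        return float(self.efficiencies[gene])

    def base(self, gene: str) -> float:
        if isinstance(self.base_cp, Mapping):
            return float(self.base_cp[gene])
        return float(self.base_cp)

    def validate(self) -> None:
        if self.true_ratio <= 0:
            raise ValueError("true_ratio must be positive")
        if self.n_tech < 1:
            raise ValueError("n_tech must be >= 1")
        if len(self.references) < 1:
            raise ValueError("at least one reference gene is required")
        for g in self.genes():
            if not 1.0 < self.efficiency(g) <= 2.2:
                raise ValueError(
                    f"efficiency of {g!r} must lie in (1, 2.2] "
                    f"(got {self.efficiency(g)})"
                )
        if self.cp_noise_sd < 0 or self.sample_sd < 0:
            raise ValueError("noise standard deviations must be non-negative")


def simulate_qpcr(design: QpcrSimDesign) -> pd.DataFrame:
    """Return a Cp table: columns ``sample, group, gene, tech_rep, cp``.

    Seeded and bit-reproducible for a fixed design.
    """
    design.validate()
    rng = np.random.default_rng(design.seed)
    rows = []
    samples = [("control", f"c{i + 1}") for i in range(design.n_control)] + [
        ("treatment", f"t{i + 1}") for i in range(design.n_treatment)
    ]
    for group, sample in samples:
        for gene in design.genes():
            e = design.efficiency(gene)
            conc = (
                design.true_ratio
                if (group == "treatment" and gene == design.target)
                else 1.0
            )
            bio_cp = design.base(gene) - np.log(conc) / np.log(e)
            if design.sample_sd > 0:
                bio_cp += rng.normal(0.0, design.sample_sd)
            for rep in range(1, design.n_tech + 1):
                cp = bio_cp
                if design.cp_noise_sd > 0:
                    cp += rng.normal(0.0, design.cp_noise_sd)
                rows.append((sample, group, gene, rep, cp))
    df = pd.DataFrame(rows, columns=["sample", "group", "gene", "tech_rep", "cp"])
    df.attrs["seed"] = design.seed
    df.attrs["true_ratio"] = design.true_ratio
    return df
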