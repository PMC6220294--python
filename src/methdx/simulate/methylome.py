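"""Ground-truth methylomes: per-cytosine methylation probabilities.

Three models cover the hypotheses of interest for an insect genome:

* ``null`` — no methylation anywhere (the unmethylated-genome hypothesis);
* ``uniform`` — every CpG methylated at a common level ``m``;
* ``mosaic`` — a random fraction of CpG dinucleotides methylated at
  ``m_high``, the rest at zero (gene-body-style mosaic methylation).

CpG methylation is maintained symmetrically, so mosaic assignment is made per
CpG dinucleotide and both strand-mates receive the same probability.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ..genome import ReferenceGenome
from ..methcall import CONTEXTS, index_cytosines


@dataclass
class Methylome:
    """Per-site methylation probabilities.

    ``sites`` has columns ``chrom, pos, strand, context, m`` with one row per
    cytosine site carrying a (possibly zero) methylation probability.
    """

    sites: pd.DataFrame
    model: str = "null"
    seed: int | None = None

    def __post_init__(self) -> None:
        m = self.sites["m"].to_numpy()
        if len(m) and (np.min(m) < 0 or np.max(m) > 1):
            raise ValueError("methylation probabilities must lie in [0, 1]")

    def level_arrays(self, genome: ReferenceGenome) -> dict[tuple[str, str], np.ndarray]:
        """Dense per-position m arrays keyed by (chrom, strand); zero where
        no site is recorded.  Used by the read/pileup simulators."""
        out: dict[tuple[str, str], np.ndarray] = {}
        for name in genome.names:
            for strand in "+-":
                out[(name, strand)] = np.zeros(genome.length(name))
        for (chrom, strand), grp in self.sites.groupby(["chrom", "strand"], sort=False):
            out[(chrom, strand)][grp["pos"].to_numpy()] = grp["m"].to_numpy()
        return out

    @property
    def n_methylated(self) -> int:
        return int((self.sites["m"] > 0).sum())


def simulate_methylome(
    genome: ReferenceGenome,
    model: str = "null",
    *,
    m: float | None = None,
    fraction: float | None = None,
    m_high: float | None = None,
    context: str = "CpG",
    seed: int = 0,
) -> Methylome:
    """Generate a ground-truth methylome for ``genome``.

    Parameters
    ----------
    model
        ``"null"``, ``"uniform"`` (requires ``m``) or ``"mosaic"`` (requires
        ``fraction`` and ``m_high``; assigned per CpG dinucleotide,
        symmetrically on both strands).
    context
        ``"CpG"`` restricts non-zero levels to CpG sites; ``"all"`` applies a
        uniform level to every cytosine.  Mosaic is CpG-only by definition.
    """
    if context not in ("CpG", "all"):
        raise ValueError("context must be 'CpG' or 'all'")
    wanted = ("CpG",) if context == "CpG" else CONTEXTS
    sites = index_cytosines(genome, wanted).copy()
    if model == "null":
        sites["m"] = 0.0
    elif model == "uniform":
        if m is None or not 0.0 <= m <= 1.0:
            raise ValueError("uniform model requires m in [0, 1]")
        sites["m"] = float(m)
    elif model == "mosaic":
        if fraction is None or not 0.0 <= fraction <= 1.0:
            raise ValueError("mosaic model requires fraction in [0, 1]")
        if m_high is None or not 0.0 <= m_high <= 1.0:
            raise ValueError("mosaic model requires m_high in [0, 1]")
        if context == "all":
            raise ValueError("mosaic methylation is CpG-specific")
        rng = np.random.default_rng(seed)
        # one Bernoulli draw per CpG dinucleotide, shared by both strands
        dinuc = sites["pos"] - (sites["strand"] == "-").astype(np.int64)
        keys = pd.MultiIndex.from_arrays([sites["chrom"], dinuc])
        uniq = keys.unique()
        hit = pd.Series(rng.random(len(uniq)) < fraction, index=uniq)
        sites["m"] = np.where(hit.reindex(keys).to_numpy(), float(m_high), 0.0)
    else:
        raise ValueError(f"unknown methylome model {model!r}")
    return Methylome(sites=sites, model=model, seed=seed)
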