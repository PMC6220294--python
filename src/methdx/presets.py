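"""Canonical study conditions for the embryo-WGBS simulation experiments.

These presets describe a directional WGBS experiment on a beetle-like genome
at ~6x coverage: a 2 Mb assembly of five placed chromosomes plus a small
complement of unplaced, repeat-derived scaffolds.  Repeat coverage in such
assemblies is bimodal — moderately repetitive scaffolds collapse tens of
genomic copies (tens-fold coverage), while satellite arrays collapse
thousands of copies into kilobases of assembly (thousands-fold coverage) —
so the unplaced stratum carries two negative-binomial coverage regimes.
Bisulfite chemistry runs at a per-cytosine non-conversion probability of
0.004 (a 99.6% conversion rate) with a 0.001 per-base sequencing error rate.

Shared-unconverted-site diagnostics computed under these conditions
reproduce, qualitatively, the published artifact signature of an
unmethylated insect genome: ~90% of replicate-shared unconverted CpGs on
unplaced scaffolds and a strongly negative coverage-proportion Spearman
correlation.
"""
from __future__ import annotations

from .genome import ReferenceGenome
from .simulate import SeqSimConfig, simulate_genome

#: assembly layout: 5 placed chromosomes, 6 moderately repetitive unplaced
#: scaffolds, 2 collapsed satellite scaffolds
CHROM_LENGTH = 400_000
N_CHROMOSOMES = 5
MODERATE_SCAFFOLD_LENGTH = 22_000
N_MODERATE_SCAFFOLDS = 6
SATELLITE_SCAFFOLD_LENGTH = 2_000
N_SATELLITE_SCAFFOLDS = 2
GC = 0.35
CPG_OE = 1.0

#: sequencing model
MEAN_DEPTH = 6.0
MODERATE_DEPTH = 60.0
MODERATE_NB_DISPERSION = 1.2
SATELLITE_DEPTH = 3_500.0
SATELLITE_NB_DISPERSION = 10.0
EPS_CONV = 0.004
EPS_SEQ = 0.001


def satellite_scaffold_names() -> list[str]:
    """Names of the collapsed-satellite scaffolds in the preset genome."""
    first = N_MODERATE_SCAFFOLDS + 1
    return [f"scaffold{first + i}" for i in range(N_SATELLITE_SCAFFOLDS)]


def wgbs_study_genome(seed: int = 0) -> ReferenceGenome:
    """The 2 Mb study assembly (placed chromosomes + unplaced scaffolds)."""
    lengths = (
        [CHROM_LENGTH] * N_CHROMOSOMES
        + [MODERATE_SCAFFOLD_LENGTH] * N_MODERATE_SCAFFOLDS
        + [SATELLITE_SCAFFOLD_LENGTH] * N_SATELLITE_SCAFFOLDS
    )
    return simulate_genome(
        n_chromosomes=N_CHROMOSOMES,
        n_unplaced=N_MODERATE_SCAFFOLDS + N_SATELLITE_SCAFFOLDS,
        lengths=lengths,
        gc=GC,
        cpg_oe_target=CPG_OE,
        seed=seed,
    )


def wgbs_study_config(seed: int = 0) -> SeqSimConfig:
    """Sequencing configuration for one replicate of the study."""
    overrides = {
        name: {
            "mean_depth": SATELLITE_DEPTH,
            "depth_model": "negative_binomial",
            "nb_dispersion": SATELLITE_NB_DISPERSION,
        }
        for name in satellite_scaffold_names()
    }
    return SeqSimConfig(
        mean_depth=MEAN_DEPTH,
        depth_model="poisson",
        eps_conv=EPS_CONV,
        eps_seq=EPS_SEQ,
        seed=seed,
        unplaced_mean_depth=MODERATE_DEPTH,
        unplaced_depth_model="negative_binomial",
        unplaced_nb_dispersion=MODERATE_NB_DISPERSION,
        depth_overrides=overrides,
    )
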