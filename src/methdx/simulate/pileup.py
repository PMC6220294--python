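"""Direct per-site pileup simulation.

Shares the stochastic model of the read simulator but skips read generation:
per cytosine site an informative depth is drawn from the configured depth
model, and basecalls follow

    p_C(true)  = m + (1 - m) * eps_conv                    (bisulfite chemistry)
    p_obs(C)   = (1-eps_seq) * p_C + (eps_seq/3) * (1-p_C) (sequencing error)
    p_obs(T)   = (1-eps_seq) * (1-p_C) + (eps_seq/3) * p_C
    p_obs(oth) = 2*eps_seq/3

so the output equals the marginal distribution of calling simulated reads.
Depth is Poisson by default; a negative-binomial model (with an optional
separate, much deeper stratum for unplaced scaffolds) emulates the
collapsed-repeat coverage regime where non-conversion artifacts concentrate.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ..genome import ReferenceGenome
from ..methcall import SITE_COLUMNS, index_cytosines
from .methylome import Methylome

_DEPTH_MODELS = ("poisson", "negative_binomial")


@dataclass
class SeqSimConfig:
    """Sequencing-simulation parameters.

    Parameters
    ----------
    mean_depth
        Expected informative reads per cytosine site (per strand-specific
        site, i.e. reads of the matching conversion strand).
    depth_model
        ``"poisson"`` or ``"negative_binomial"`` (with ``nb_dispersion`` as
        the NB size parameter; smaller = more overdispersed).
    eps_conv
        Per-cytosine bisulfite non-conversion probability (an unmethylated C
        read as C).  A conversion rate of 99.59% corresponds to ~0.0041.
    eps_seq
        Per-base sequencing error probability; errors are uniform over the
        three alternative bases.
    unplaced_mean_depth / unplaced_depth_model / unplaced_nb_dispersion
        Optional overrides for unplaced scaffolds, emulating the elevated
        fold coverage of repeat-derived sequence.  Defaults inherit the
        global settings.
    depth_overrides
        Optional per-sequence overrides, mapping a sequence name to a dict
        with any of ``mean_depth``, ``depth_model``, ``nb_dispersion``.
        Takes precedence over the placement-level settings; lets individual
        scaffolds model distinct repeat families (e.g. collapsed satellite
        arrays at thousands-fold coverage).
    """

    mean_depth: float = 6.0
    depth_model: str = "poisson"
    nb_dispersion: float = 3.0
    eps_conv: float = 0.004
    eps_seq: float = 0.001
    read_length: int = 100
    seed: int = 0
    unplaced_mean_depth: float | None = None
    unplaced_depth_model: str | None = None
    unplaced_nb_dispersion: float | None = None
    depth_overrides: dict | None = None

    def depth_spec(self, name: str, placed: bool) -> tuple[float, str, float]:
        """(mean, model, nb dispersion) effective for sequence ``name``."""
        mean = self.mean_depth
        model = self.depth_model
        disp = self.nb_dispersion
        if not placed:
            if self.unplaced_mean_depth is not None:
                mean = self.unplaced_mean_depth
            if self.unplaced_depth_model is not None:
                model = self.unplaced_depth_model
            if self.unplaced_nb_dispersion is not None:
                disp = self.unplaced_nb_dispersion
        if self.depth_overrides and name in self.depth_overrides:
            ov = self.depth_overrides[name]
            mean = ov.get("mean_depth", mean)
            model = ov.get("depth_model", model)
            disp = ov.get("nb_dispersion", disp)
        if model not in _DEPTH_MODELS:
            raise ValueError(f"depth model must be one of {_DEPTH_MODELS}")
        return float(mean), model, float(disp)

    def validate(self) -> None:
        if self.mean_depth <= 0:
            raise ValueError("mean_depth must be positive")
        if not 0.0 <= self.eps_conv < 1.0:
            raise ValueError("eps_conv must lie in [0, 1)")
        if not 0.0 <= self.eps_seq < 0.25:
            raise ValueError("eps_seq must lie in [0, 0.25)")
        if self.depth_model not in _DEPTH_MODELS:
            raise ValueError(f"depth_model must be one of {_DEPTH_MODELS}")
        if self.unplaced_depth_model is not None and (
            self.unplaced_depth_model not in _DEPTH_MODELS
        ):
            raise ValueError(f"unplaced_depth_model must be one of {_DEPTH_MODELS}")
        if self.read_length < 1:
            raise ValueError("read_length must be >= 1")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be positive")


def _draw_depth(rng: np.random.Generator, n: int, mean: float, model: str,
                dispersion: float) -> np.ndarray:
    if mean <= 0:
        return np.zeros(n, dtype=np.int64)
    if model == "poisson":
        return rng.poisson(mean, n)
    p = dispersion / (dispersion + mean)
    return rng.negative_binomial(dispersion, p, n)


def observed_basecall_probs(m: np.ndarray | float, eps_conv: float,
                            eps_seq: float) -> tuple[np.ndarray, np.ndarray]:
    """(p_obs(C), p_obs(T)) for true methylation level(s) ``m``."""
    p_c = m + (1.0 - np.asarray(m, dtype=float)) * eps_conv
    p_obs_c = (1.0 - eps_seq) * p_c + (eps_seq / 3.0) * (1.0 - p_c)
    p_obs_t = (1.0 - eps_seq) * (1.0 - p_c) + (eps_seq / 3.0) * p_c
    return p_obs_c, p_obs_t


def simulate_pileup(
    genome: ReferenceGenome,
    methylome: Methylome,
    cfg: SeqSimConfig,
) -> pd.DataFrame:
    """Simulate a per-cytosine tally table over all contexts.

    Returns the standard site-count frame (``chrom, pos, strand, context,
    n_unconverted, n_converted, n_other``) for sites with non-zero depth;
    ``attrs`` records the seed and parameters.  Conservation
    ``n_unconverted + n_converted + n_other == depth`` holds at every site.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    sites = index_cytosines(genome)
    # methylation level per enumerated site (0 where the methylome is silent)
    msites = methylome.sites.set_index(["chrom", "pos", "strand"])["m"]
    idx = pd.MultiIndex.from_arrays([sites["chrom"], sites["pos"], sites["strand"]])
    m = msites.reindex(idx).fillna(0.0).to_numpy()

    depth = np.zeros(len(sites), dtype=np.int64)
    chrom_col = sites["chrom"].to_numpy()
    for name in genome.names:
        mask = chrom_col == name
        n = int(mask.sum())
        if n == 0:
            continue
        mean, model, disp = cfg.depth_spec(name, genome.is_placed(name))
        depth[mask] = _draw_depth(rng, n, mean, model, disp)

    p_obs_c, p_obs_t = observed_basecall_probs(m, cfg.eps_conv, cfg.eps_seq)
    x = rng.binomial(depth, p_obs_c)
    with np.errstate(invalid="ignore", divide="ignore"):
        p_t_given_not_c = np.where(p_obs_c < 1.0, p_obs_t / (1.0 - p_obs_c), 0.0)
    conv = rng.binomial(depth - x, np.clip(p_t_given_not_c, 0.0, 1.0))
    other = depth - x - conv

    out = sites.copy()
    out["n_unconverted"] = x
    out["n_converted"] = conv
    out["n_other"] = other
    out = out[depth > 0].reset_index(drop=True)
    out = out[SITE_COLUMNS]
    out.attrs["cpg_merged"] = False
    out.attrs["seed"] = cfg.seed
    out.attrs["config"] = cfg.__dict__.copy()
    return out
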