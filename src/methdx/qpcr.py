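"""Efficiency-corrected relative expression (Pfaffl/REST machinery).

Relative expression of a target gene between treatment and control, corrected
for per-gene amplification efficiency E and normalized over one or more
reference genes:

    ratio = E_t^dCp_t / geomean_r( E_r^dCp_r ),   dCp_g = mean Cp(control) - mean Cp(treatment)

Up-regulation in treatment therefore gives ratio > 1.  Significance comes
from a pairwise fixed-reallocation randomization test (group labels permuted
jointly across genes per biological sample, two-sided on |log ratio|),
uncertainty from a within-group bootstrap percentile interval, and
multiple-testing control from Bonferroni.  Technical replicates are
QC-filtered on their standard deviation before any of this.
"""
from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass
from math import comb
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

CONTROL, TREATMENT = "control", "treatment"


# ---------------------------------------------------------------------------
# technical-replicate QC


def qc_technical_replicates(cp_table: pd.DataFrame, max_std: float = 0.5) -> pd.DataFrame:
    """Collapse technical replicates to ``mean_cp``, discarding noisy ones.

    A sample x gene measurement is kept only if the sample standard deviation
    (n-1 denominator; ``|a-b|/sqrt(2)`` for a pair) of its technical Cp values
    is strictly below ``max_std`` cycles.  Singletons pass with a warning.
    Excluded measurements are recorded in ``attrs['qc_excluded']``.
    """
    required = {"sample", "group", "gene", "cp"}
    missing = required - set(cp_table.columns)
    if missing:
        raise ValueError(f"Cp table lacks columns: {sorted(missing)}")
    grouped = cp_table.groupby(["sample", "group", "gene"], sort=False)["cp"]
    agg = grouped.agg(mean_cp="mean", cp_sd=lambda v: v.std(ddof=1), n_tech="count")
    agg = agg.reset_index()
    singles = agg["n_tech"] == 1
    if singles.any():
        warnings.warn(
            f"{int(singles.sum())} measurement(s) have a single technical "
            "replicate; kept without a QC check",
            stacklevel=2,
        )
    agg.loc[singles, "cp_sd"] = 0.0
    keep = agg["cp_sd"] < max_std
    out = agg[keep].reset_index(drop=True)
    out.attrs["qc_excluded"] = agg[~keep].reset_index(drop=True)
    out.attrs["max_std"] = max_std
    return out


# ---------------------------------------------------------------------------
# efficiency from a serial dilution curve


@dataclass
class EfficiencyEstimate:
    gene: str
    slope: float
    intercept: float
    r_squared: float

    @property
    def efficiency(self) -> float:
        return 10.0 ** (-1.0 / self.slope)

    @property
    def in_range(self) -> bool:
        """Accepted assay range 1 < E <= 2.2."""
        return 1.0 < self.efficiency <= 2.2


def efficiency_from_dilution(
    series: pd.DataFrame | Sequence[tuple[float, float]],
    gene: str = "",
) -> EfficiencyEstimate:
    """OLS fit of Cp against log10(dilution); ``E = 10^(-1/slope)``.

    A perfect-doubling assay has slope -3.3219 and E = 2.  Requires at least
    three dilution points and a negative slope.
    """
    if isinstance(series, pd.DataFrame):
        x = np.asarray(series["log10_dilution"], dtype=float)
        y = np.asarray(series["cp"], dtype=float)
        gene = gene or (str(series["gene"].iloc[0]) if "gene" in series else "")
    else:
        pairs = list(series)
        x = np.asarray([p[0] for p in pairs], dtype=float)
        y = np.asarray([p[1] for p in pairs], dtype=float)
    if len(x) < 3:
        raise ValueError("need at least 3 dilution points")
    fit = stats.linregress(x, y)
    if fit.slope >= 0:
        raise ValueError(
            f"invalid assay: non-negative dilution slope ({fit.slope:.3g})"
        )
    return EfficiencyEstimate(
        gene=gene,
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue**2),
    )


# ---------------------------------------------------------------------------
# Pfaffl ratio


def _resolve_eff(efficiencies: Mapping[str, float | EfficiencyEstimate], gene: str) -> float:
    if gene not in efficiencies:
        raise ValueError(f"missing efficiency for gene {gene!r}")
    e = efficiencies[gene]
    return e.efficiency if isinstance(e, EfficiencyEstimate) else float(e)


def _log_ratio(dcp: np.ndarray, log_e: np.ndarray) -> np.ndarray:
    """log ratio from per-gene dCp; gene axis last, target first."""
    target = dcp[..., 0] * log_e[0]
    refs = dcp[..., 1:] * log_e[1:]
    return target - refs.mean(axis=-1)


def pfaffl_ratio(
    mean_cp: pd.DataFrame,
    target: str,
    references: Sequence[str],
    efficiencies: Mapping[str, float | EfficiencyEstimate],
) -> float:
    """Efficiency-corrected expression ratio of ``target``, normalized over
    the geometric mean of the reference-gene factors.

    Computed over complete blocks: samples with a QC-excluded measurement for
    any involved gene are dropped, so the ratio, the randomization test and
    the bootstrap interval all see the same data.
    """
    if not references:
        raise ValueError("at least one reference gene is required")
    genes = [target] + list(references)
    log_e = np.array([math.log(_resolve_eff(efficiencies, g)) for g in genes])
    M, is_ctrl = _sample_matrix(mean_cp, genes)
    if is_ctrl.sum() == 0 or (~is_ctrl).sum() == 0:
        raise ValueError("a gene is missing in one of the groups")
    dcp = M[is_ctrl].mean(axis=0) - M[~is_ctrl].mean(axis=0)
    return float(math.exp(_log_ratio(dcp, log_e)))


# ---------------------------------------------------------------------------
# randomization test


@dataclass
class RandomizationResult:
    p: float
    observed_ratio: float
    n_assignments: int
    method: str  # "exact" | "sampled"


def _sample_matrix(
    mean_cp: pd.DataFrame, genes: Sequence[str]
) -> tuple[np.ndarray, np.ndarray]:
    """(samples x genes mean-Cp matrix, boolean control mask).  Samples
    missing any gene are dropped (complete-block permutation)."""
    wide = mean_cp.pivot_table(index=["sample", "group"], columns="gene",
                               values="mean_cp", aggfunc="mean")
    try:
        wide = wide[list(genes)]
    except KeyError as exc:
        raise ValueError(f"gene absent from Cp table: {exc}") from exc
    wide = wide.dropna()
    groups = wide.index.get_level_values("group").to_numpy()
    return wide.to_numpy(), groups == CONTROL


def randomization_test(
    mean_cp: pd.DataFrame,
    target: str,
    references: Sequence[str],
    efficiencies: Mapping[str, float | EfficiencyEstimate],
    n_iter: int = 10000,
    seed: int = 0,
    method: str = "auto",
    max_exact: int = 20000,
) -> RandomizationResult:
    """Pairwise fixed-reallocation randomization test on the expression ratio.

    Group labels are permuted jointly across all genes per biological sample;
    the two-sided p-value is the proportion of reallocations whose |log
    ratio| is at least the observed one.  All label assignments are
    enumerated exactly when their number is at most ``max_exact`` (or
    ``method="exact"``); otherwise ``n_iter`` random reallocations are drawn
    with +1 smoothing in numerator and denominator.
    """
    genes = [target] + list(references)
    log_e = np.array([math.log(_resolve_eff(efficiencies, g)) for g in genes])
    M, is_ctrl = _sample_matrix(mean_cp, genes)
    n = len(M)
    n_c = int(is_ctrl.sum())
    n_t = n - n_c
    if n_c == 0 or n_t == 0 or n < 4:
        raise ValueError("need at least 4 samples with both groups represented")

    def stat(mask: np.ndarray) -> np.ndarray:
        # mask: (k, n) boolean control assignment
        ctrl_mean = (mask @ M) / n_c
        trt_mean = ((~mask) @ M) / n_t
        return _log_ratio(ctrl_mean - trt_mean, log_e)

    obs = float(stat(is_ctrl[None, :])[0])
    n_total = comb(n, n_c)
    use_exact = method == "exact" or (method == "auto" and n_total <= max_exact)
    thresh = abs(obs) - 1e-12
    if use_exact:
        masks = np.zeros((n_total, n), dtype=bool)
        for i, combo in enumerate(itertools.combinations(range(n), n_c)):
            masks[i, list(combo)] = True
        lr = stat(masks)
        p = float((np.abs(lr) >= thresh).mean())
        return RandomizationResult(p, math.exp(obs), n_total, "exact")
    rng = np.random.default_rng(seed)
    masks = np.zeros((n_iter, n), dtype=bool)
    for i in range(n_iter):
        masks[i, rng.choice(n, n_c, replace=False)] = True
    lr = stat(masks)
    count = int((np.abs(lr) >= thresh).sum())
    p = (1 + count) / (1 + n_iter)
    return RandomizationResult(p, math.exp(obs), n_iter, "sampled")


# ---------------------------------------------------------------------------
# bootstrap CI


def bootstrap_ci(
    mean_cp: pd.DataFrame,
    target: str,
    references: Sequence[str],
    efficiencies: Mapping[str, float | EfficiencyEstimate],
    n_boot: int = 2000,
    seed: int = 0,
    level: float = 0.95,
) -> tuple[float, float]:
    """Percentile bootstrap interval for the ratio, resampling biological
    samples with replacement within each group."""
    genes = [target] + list(references)
    log_e = np.array([math.log(_resolve_eff(efficiencies, g)) for g in genes])
    M, is_ctrl = _sample_matrix(mean_cp, genes)
    Mc, Mt = M[is_ctrl], M[~is_ctrl]
    if len(Mc) == 0 or len(Mt) == 0:
        raise ValueError("both groups must be non-empty")
    if len(Mc) == 1 or len(Mt) == 1:
        warnings.warn("a group has a single sample; interval is degenerate",
                      stacklevel=2)
    rng = np.random.default_rng(seed)
    ic = rng.integers(0, len(Mc), size=(n_boot, len(Mc)))
    it = rng.integers(0, len(Mt), size=(n_boot, len(Mt)))
    dcp = Mc[ic].mean(axis=1) - Mt[it].mean(axis=1)  # (n_boot, genes)
    lr = _log_ratio(dcp, log_e)
    lo, hi = np.quantile(np.exp(lr), [(1 - level) / 2, (1 + level) / 2])
    return float(lo), float(hi)


# ---------------------------------------------------------------------------
# multiple testing


def adjust_bonferroni(pvals: Iterable[float], k: int) -> list[float]:
    """Bonferroni adjustment ``min(1, k*p)`` for a family of ``k`` comparisons."""
    ps = [float(p) for p in pvals]
    for p in ps:
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"p-value out of range: {p}")
    if k < len(ps):
        raise ValueError(f"family size {k} smaller than number of p-values {len(ps)}")
    return [min(1.0, k * p) for p in ps]


# ---------------------------------------------------------------------------
# one-stop analysis


@dataclass
class ExpressionResult:
    target: str
    ratio: float
    ci95: tuple[float, float]
    p: float
    p_adjusted: float
    n_control: int
    n_treatment: int
    n_assignments: int
    test_method: str


def relative_expression(
    mean_cp: pd.DataFrame,
    target: str,
    references: Sequence[str],
    efficiencies: Mapping[str, float | EfficiencyEstimate],
    n_iter: int = 10000,
    n_boot: int = 2000,
    seed: int = 0,
    family_size: int = 1,
) -> ExpressionResult:
    """Ratio + randomization p + bootstrap CI + Bonferroni, in one call."""
    ratio = pfaffl_ratio(mean_cp, target, references, efficiencies)
    rand = randomization_test(mean_cp, target, references, efficiencies,
                              n_iter=n_iter, seed=seed)
    ci = bootstrap_ci(mean_cp, target, references, efficiencies,
                      n_boot=n_boot, seed=seed)
    p_adj = adjust_bonferroni([rand.p], family_size)[0]
    sub = mean_cp[mean_cp["gene"] == target]
    return ExpressionResult(
        target=target,
        ratio=ratio,
        ci95=ci,
        p=rand.p,
        p_adjusted=p_adj,
        n_control=int((sub["group"] == CONTROL).sum()),
        n_treatment=int((sub["group"] == TREATMENT).sum()),
        n_assignments=rand.n_assignments,
        test_method=rand.method,
    )
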