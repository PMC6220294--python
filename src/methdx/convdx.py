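"""Bisulfite-conversion diagnostics and the absence-of-methylation inference.

In a genome without CpG methylation, every C basecall at a cytosine site is an
artifact — incomplete bisulfite conversion or a sequencing miscall.  Artifacts
leave a characteristic signature that genuine methylation does not:

* the overall conversion rate is very high (>= 99.5%);
* sites unconverted in both replicates concentrate in deep, repeat-like
  (typically unplaced) regions, simply because more basecalls mean more
  chances of at least one artifact;
* across those shared sites, the unconverted proportion falls as fold
  coverage rises (a strongly negative Spearman correlation), because the
  artifact count grows much slower than depth — whereas true methylation
  yields a depth-independent proportion;
* the pooled unconverted fraction at shared sites stays within a small
  multiple of the global non-conversion rate.

This module computes each diagnostic, the expected number of chance-shared
sites under independent artifacts, and a formal verdict
(absent / present / inconclusive) from configurable thresholds.
"""
from __future__ import annotations

import itertools
import json
import math
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .genome import ReferenceGenome
from .methcall import merge_cpg_strands

SCHEMA_VERSION = "1"


class DegenerateCorrelationError(ValueError):
    """Correlation undefined: fewer than 3 points or zero variance."""


# ---------------------------------------------------------------------------
# conversion rate


@dataclass
class ConversionSummary:
    """Pooled basecall-level conversion summary over a site-count table."""

    total_unconverted: int
    total_converted: int
    scope: str
    per_context: dict[str, float] = field(default_factory=dict)

    @property
    def conversion_rate(self) -> float:
        return self.total_converted / (self.total_converted + self.total_unconverted)

    @property
    def nonconversion_rate(self) -> float:
        return 1.0 - self.conversion_rate


_SCOPES = ("all", "non-CpG", "CpG")


def estimate_conversion_rate(sites: pd.DataFrame, scope: str = "all") -> ConversionSummary:
    """Pooled conversion rate ``converted / (converted + unconverted)``.

    Pooled over basecalls, not averaged over sites; ``scope`` filters to all
    cytosines, non-CpG only (the standard conversion control, since insect
    non-CpG methylation is negligible) or CpG only, before pooling.
    """
    if scope not in _SCOPES:
        raise ValueError(f"scope must be one of {_SCOPES}")
    if len(sites) == 0:
        raise ValueError("cannot estimate a conversion rate from an empty table")
    if scope == "non-CpG":
        sub = sites[sites["context"] != "CpG"]
    elif scope == "CpG":
        sub = sites[sites["context"] == "CpG"]
    else:
        sub = sites
    u = int(sub["n_unconverted"].sum())
    c = int(sub["n_converted"].sum())
    if u + c == 0:
        raise ValueError(f"no informative basecalls in scope {scope!r}")
    per_context = {}
    for ctx, grp in sites.groupby("context"):
        uu, cc = int(grp["n_unconverted"].sum()), int(grp["n_converted"].sum())
        if uu + cc:
            per_context[ctx] = cc / (uu + cc)
    return ConversionSummary(u, c, scope, per_context)


# ---------------------------------------------------------------------------
# unconverted-site tables

UNCONVERTED_COLUMNS = ["chrom", "pos", "strand", "context", "depth",
                       "n_unconverted", "proportion"]


def select_unconverted_sites(sites: pd.DataFrame, min_unconverted: int = 1) -> pd.DataFrame:
    """Sites with at least ``min_unconverted`` C basecalls.

    ``depth`` is the informative (C+T) depth and ``proportion`` the per-site
    unconverted fraction over it.  The frame's ``attrs`` carry the per-site
    mean proportion and the pooled basecall fraction, which differ: at low
    depth a per-site mean cannot fall below 1/depth even for pure artifacts.
    """
    ct = sites["n_unconverted"] + sites["n_converted"]
    keep = sites["n_unconverted"] >= min_unconverted
    out = sites.loc[keep, ["chrom", "pos", "strand", "context", "n_unconverted"]].copy()
    out["depth"] = ct[keep]
    with np.errstate(invalid="ignore", divide="ignore"):
        out["proportion"] = np.where(
            out["depth"] > 0, out["n_unconverted"] / out["depth"], np.nan
        )
    out = out[UNCONVERTED_COLUMNS].reset_index(drop=True)
    out.attrs["cpg_merged"] = bool(sites.attrs.get("cpg_merged", False))
    out.attrs["min_unconverted"] = min_unconverted
    out.attrs["mean_site_proportion"] = (
        float(np.nanmean(out["proportion"])) if len(out) else float("nan")
    )
    denom = out["depth"].sum()
    out.attrs["pooled_proportion"] = (
        float(out["n_unconverted"].sum() / denom) if denom else float("nan")
    )
    return out


SHARED_COLUMNS = ["chrom", "pos", "strand", "context", "depth_1", "x_1",
                  "depth_2", "x_2", "combined_depth", "pooled_proportion"]


def intersect_replicates(t1: pd.DataFrame, t2: pd.DataFrame) -> pd.DataFrame:
    """Inner join of two unconverted-site tables on (chrom, pos, strand).

    Both inputs must come from the same strand-handling mode (merged CpG
    dinucleotides or per-strand sites); mixing modes is an error.
    """
    m1 = bool(t1.attrs.get("cpg_merged", False))
    m2 = bool(t2.attrs.get("cpg_merged", False))
    if m1 != m2:
        raise ValueError("replicates use different CpG strand-merge modes")
    left = t1[["chrom", "pos", "strand", "context", "depth", "n_unconverted"]].rename(
        columns={"depth": "depth_1", "n_unconverted": "x_1"}
    )
    right = t2[["chrom", "pos", "strand", "depth", "n_unconverted"]].rename(
        columns={"depth": "depth_2", "n_unconverted": "x_2"}
    )
    shared = left.merge(right, on=["chrom", "pos", "strand"], how="inner")
    shared["combined_depth"] = shared["depth_1"] + shared["depth_2"]
    with np.errstate(invalid="ignore", divide="ignore"):
        shared["pooled_proportion"] = np.where(
            shared["combined_depth"] > 0,
            (shared["x_1"] + shared["x_2"]) / shared["combined_depth"],
            np.nan,
        )
    shared = shared[SHARED_COLUMNS]
    shared.attrs["cpg_merged"] = m1
    return shared


# ---------------------------------------------------------------------------
# placement partition


@dataclass
class PlacementSummary:
    n_placed: int
    n_unplaced: int

    @property
    def n_total(self) -> int:
        return self.n_placed + self.n_unplaced

    @property
    def placed_fraction(self) -> float:
        return self.n_placed / self.n_total

    @property
    def placed_percent(self) -> float:
        """Placed fraction as a percentage, rounded to one decimal."""
        return round(100.0 * self.placed_fraction, 1)


def partition_by_placement(shared: pd.DataFrame, genome: ReferenceGenome) -> PlacementSummary:
    """Count shared artifact sites on placed chromosomes vs unplaced scaffolds."""
    if len(shared) == 0:
        raise ValueError("cannot partition an empty shared-site table")
    unknown = set(shared["chrom"]) - set(genome.names)
    if unknown:
        raise ValueError(f"chromosomes absent from genome: {sorted(unknown)}")
    placed = shared["chrom"].map(genome.is_placed)
    n_placed = int(placed.sum())
    return PlacementSummary(n_placed, len(shared) - n_placed)


# ---------------------------------------------------------------------------
# Spearman coverage-proportion diagnostic


@dataclass
class CorrelationResult:
    rho: float
    n: int
    p: float
    method: str  # "t-approximation" | "exact permutation"

    def summary(self) -> str:
        p_str = "p < 0.001" if self.p < 0.001 else f"p = {self.p:.3g}"
        return f"rho = {self.rho:.3f}, n = {self.n}, {p_str}"


def _midranks(a: np.ndarray) -> np.ndarray:
    return stats.rankdata(a, method="average")


def _rho_of_ranks(rx: np.ndarray, ry: np.ndarray) -> float:
    xc = rx - rx.mean()
    yc = ry - ry.mean()
    denom = math.sqrt(float(xc @ xc) * float(yc @ yc))
    return float(xc @ yc) / denom


def spearman_coverage_correlation(
    table: pd.DataFrame,
    x: str = "combined_depth",
    y: str = "pooled_proportion",
    method: str = "auto",
) -> CorrelationResult:
    """Spearman rank correlation between fold coverage and unconverted
    proportion.

    rho is the Pearson correlation of midranks (average ranks on ties).  The
    two-sided p-value uses the t approximation
    ``t = rho * sqrt((n-2)/(1-rho^2))`` for n > 10 and exact enumeration of
    all rank permutations for n <= 10.
    """
    xv = np.asarray(table[x], dtype=float)
    yv = np.asarray(table[y], dtype=float)
    n = len(xv)
    if n < 3:
        raise DegenerateCorrelationError(f"need at least 3 sites (got {n})")
    if np.ptp(xv) == 0 or np.ptp(yv) == 0:
        raise DegenerateCorrelationError("zero variance in x or y")
    rx, ry = _midranks(xv), _midranks(yv)
    rho = _rho_of_ranks(rx, ry)
    if method == "auto":
        method = "exact permutation" if n <= 10 else "t-approximation"
    if method == "t-approximation":
        denom = 1.0 - rho * rho
        if denom < 1e-14:
            p = 0.0
        else:
            t = rho * math.sqrt((n - 2) / denom)
            p = min(float(2.0 * stats.t.sf(abs(t), df=n - 2)), 1.0)
    elif method == "exact permutation":
        xc = rx - rx.mean()
        norm_x = math.sqrt(float(xc @ xc))
        yc = ry - ry.mean()
        norm_y = math.sqrt(float(yc @ yc))
        thresh = abs(rho) - 1e-12
        count = 0
        total = 0
        chunk: list[tuple] = []
        chunk_size = 200_000

        def flush(chunk: list[tuple]) -> int:
            perm = np.asarray(chunk)
            rhos = (perm - ry.mean()) @ xc / (norm_x * norm_y)
            return int((np.abs(rhos) >= thresh).sum())

        for p_y in itertools.permutations(ry.tolist()):
            chunk.append(p_y)
            if len(chunk) == chunk_size:
                count += flush(chunk)
                total += len(chunk)
                chunk = []
        if chunk:
            count += flush(chunk)
            total += len(chunk)
        p = count / total
    else:
        raise ValueError("method must be 'auto', 't-approximation' or 'exact permutation'")
    return CorrelationResult(rho=rho, n=n, p=p, method=method)


# ---------------------------------------------------------------------------
# chance overlap


def expected_chance_overlap(
    depths1: Sequence[float],
    depths2: Sequence[float],
    eps_eff1: float,
    eps_eff2: float | None = None,
) -> float:
    """Expected number of sites unconverted in both replicates by chance.

    Under independent artifacts at per-basecall probability ``eps_eff`` the
    probability that a site of depth d shows at least one unconverted call is
    ``1 - (1 - eps_eff)^d``; the expectation sums the product over the common
    site universe.  ``depths1``/``depths2`` must be aligned per site (0 where
    a replicate has no coverage).
    """
    d1 = np.asarray(depths1, dtype=float)
    d2 = np.asarray(depths2, dtype=float)
    if d1.shape != d2.shape:
        raise ValueError("depth vectors must cover the same site universe")
    if eps_eff2 is None:
        eps_eff2 = eps_eff1
    for e in (eps_eff1, eps_eff2):
        if not 0.0 <= e < 1.0:
            raise ValueError("eps_eff must lie in [0, 1)")
    p1 = 1.0 - np.power(1.0 - eps_eff1, d1)
    p2 = 1.0 - np.power(1.0 - eps_eff2, d2)
    return float(np.sum(p1 * p2))


def chance_overlap_envelope(
    depths1: Sequence[float],
    depths2: Sequence[float],
    eps_eff1: float,
    eps_eff2: float | None = None,
    level: float = 0.99,
) -> tuple[float, float]:
    """Normal-approximation envelope for the Poisson-binomial shared-site
    count under independent artifacts."""
    d1 = np.asarray(depths1, dtype=float)
    d2 = np.asarray(depths2, dtype=float)
    if eps_eff2 is None:
        eps_eff2 = eps_eff1
    p = (1.0 - np.power(1.0 - eps_eff1, d1)) * (1.0 - np.power(1.0 - eps_eff2, d2))
    mu = float(p.sum())
    sd = float(np.sqrt(np.sum(p * (1.0 - p))))
    z = stats.norm.ppf(0.5 + level / 2.0)
    return (mu - z * sd, mu + z * sd)


# ---------------------------------------------------------------------------
# the verdict


@dataclass
class VerdictThresholds:
    """Decision thresholds for the absence/presence verdict.

    Defaults separate the pure-artifact signature from a mosaic 10%+
    methylated alternative at ~6x depth; all are configurable and echoed into
    the report.
    """

    min_conversion: float = 0.995
    max_rho: float = -0.8
    max_rho_p: float = 0.01
    absent_fold: float = 2.0
    present_fold: float = 10.0


@dataclass
class DiagnosticReport:
    """Full evidence chain behind the verdict; serializable to JSON."""

    conversion_rates: list[float]
    conversion_scope: str
    global_nonconversion: float
    n_shared: int
    expected_chance_shared: float
    placement: PlacementSummary | None
    pooled_shared_fraction: float | None
    mean_shared_site_proportion: float | None
    correlation: CorrelationResult | None
    verdict: str
    evidence: list[str]
    thresholds: VerdictThresholds
    cpg_merged: bool
    min_unconverted: int
    schema_version: str = SCHEMA_VERSION

    def to_dict(self) -> dict:
        d = asdict(self)
        return d

    def to_json(self, path=None, indent: int = 2) -> str:
        text = json.dumps(self.to_dict(), indent=indent, default=float)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text


def _rho_signature_met(corr: CorrelationResult | None, th: VerdictThresholds) -> bool:
    return corr is not None and corr.rho <= th.max_rho and corr.p < th.max_rho_p


def assess_methylation(
    rep1: pd.DataFrame,
    rep2: pd.DataFrame,
    genome: ReferenceGenome,
    *,
    thresholds: VerdictThresholds | None = None,
    min_unconverted: int = 1,
    merge_cpg: bool = False,
    conversion_scope: str = "auto",
) -> DiagnosticReport:
    """Run the full diagnostic chain on two replicate call tables.

    The verdict rule (all thresholds configurable):

    * ``absent``  — conversion rate at least ``min_conversion`` in both
      replicates, AND the coverage-proportion correlation at shared sites
      satisfies ``rho <= max_rho`` with ``p < max_rho_p``, AND the pooled
      shared-site unconverted fraction is at most ``absent_fold`` times the
      global non-conversion rate;
    * ``present`` — pooled shared-site fraction at least ``present_fold``
      times the global non-conversion rate and the correlation signature NOT
      met;
    * ``inconclusive`` otherwise.

    ``conversion_scope='auto'`` uses non-CpG cytosines as the conversion
    control when present (immune to true CpG methylation), else all
    cytosines.
    """
    th = thresholds or VerdictThresholds()
    if conversion_scope == "auto":
        has_noncpg = ((rep1["context"] != "CpG").any()) and (
            (rep2["context"] != "CpG").any()
        )
        conversion_scope = "non-CpG" if has_noncpg else "all"
    conv = [estimate_conversion_rate(r, conversion_scope) for r in (rep1, rep2)]
    global_eps = float(np.mean([c.nonconversion_rate for c in conv]))

    cpg1 = rep1[rep1["context"] == "CpG"].copy()
    cpg2 = rep2[rep2["context"] == "CpG"].copy()
    for c, src in ((cpg1, rep1), (cpg2, rep2)):
        c.attrs["cpg_merged"] = bool(src.attrs.get("cpg_merged", False))
    if merge_cpg:
        cpg1, cpg2 = merge_cpg_strands(cpg1), merge_cpg_strands(cpg2)
    t1 = select_unconverted_sites(cpg1, min_unconverted)
    t2 = select_unconverted_sites(cpg2, min_unconverted)
    shared = intersect_replicates(t1, t2)
    evidence: list[str] = []

    # depth universe for the chance-overlap expectation: outer join of CpG
    # informative depths, zero where uncovered
    ct1 = cpg1.assign(d=cpg1["n_unconverted"] + cpg1["n_converted"])
    ct2 = cpg2.assign(d=cpg2["n_unconverted"] + cpg2["n_converted"])
    uni = ct1[["chrom", "pos", "strand", "d"]].merge(
        ct2[["chrom", "pos", "strand", "d"]],
        on=["chrom", "pos", "strand"],
        how="outer",
        suffixes=("_1", "_2"),
    ).fillna(0.0)
    expected = expected_chance_overlap(
        uni["d_1"], uni["d_2"], conv[0].nonconversion_rate, conv[1].nonconversion_rate
    )

    placement = partition_by_placement(shared, genome) if len(shared) else None
    if len(shared):
        pooled = float(
            (shared["x_1"] + shared["x_2"]).sum() / shared["combined_depth"].sum()
        )
        mean_prop = float(shared["pooled_proportion"].mean())
    else:
        pooled, mean_prop = None, None
        evidence.append("no shared unconverted sites between replicates")

    try:
        corr = spearman_coverage_correlation(shared) if len(shared) >= 3 else None
        if corr is None and len(shared):
            evidence.append("too few shared sites for a defined correlation")
    except DegenerateCorrelationError as exc:
        corr = None
        evidence.append(f"correlation undefined: {exc}")

    rates = [c.conversion_rate for c in conv]
    conv_ok = all(r >= th.min_conversion for r in rates)
    rho_ok = _rho_signature_met(corr, th)
    pooled_low = pooled is not None and pooled <= th.absent_fold * global_eps
    pooled_high = pooled is not None and pooled >= th.present_fold * global_eps

    evidence.append(
        "conversion rates: "
        + ", ".join(f"{100 * r:.2f}%" for r in rates)
        + f" (threshold {100 * th.min_conversion:.2f}%)"
    )
    if corr is not None:
        evidence.append(f"coverage-proportion Spearman: {corr.summary()}")
    evidence.append(
        f"shared unconverted CpG sites: {len(shared)} observed, "
        f"{expected:.1f} expected by chance"
    )
    if pooled is not None:
        evidence.append(
            f"pooled shared-site unconverted fraction {pooled:.4g} vs global "
            f"non-conversion {global_eps:.4g} "
            f"({pooled / global_eps:.1f}-fold)" if global_eps > 0 else
            f"pooled shared-site unconverted fraction {pooled:.4g}"
        )
    if placement is not None:
        evidence.append(
            f"{placement.n_placed} of {placement.n_total} shared sites "
            f"({placement.placed_percent}%) on placed chromosomes"
        )

    if conv_ok and rho_ok and pooled_low:
        verdict = "absent"
    elif pooled_high and not rho_ok:
        verdict = "present"
    else:
        verdict = "inconclusive"

    return DiagnosticReport(
        conversion_rates=rates,
        conversion_scope=conversion_scope,
        global_nonconversion=global_eps,
        n_shared=len(shared),
        expected_chance_shared=expected,
        placement=placement,
        pooled_shared_fraction=pooled,
        mean_shared_site_proportion=mean_prop,
        correlation=corr,
        verdict=verdict,
        evidence=evidence,
        thresholds=th,
        cpg_merged=bool(shared.attrs.get("cpg_merged", False)),
        min_unconverted=min_unconverted,
    )
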