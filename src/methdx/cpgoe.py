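"""CpG observed/expected (normalized CpG content) and bimodality testing.

Sustained CpG methylation is mutagenic (methyl-C deaminates to T), so genomes
with a long methylation history are depleted of CpG dinucleotides.  The
per-sequence normalized CpG content

    o/e = n_CpG * L / (n_C * n_G)

is ~1 for unmethylated DNA and < 1 where methylation has eroded CpGs; gene
sets of methylated insect genomes typically show a bimodal o/e distribution
(methylated vs unmethylated gene classes).  The bimodality test compares 1-
vs 2-component Gaussian mixtures by a parametric-bootstrap likelihood-ratio
test, with a mean-separation criterion so heavy tails alone cannot trigger a
bimodal call.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.mixture import GaussianMixture

from .genome import ReferenceGenome

_C, _G = ord("C"), ord("G")
_ACGT = np.zeros(256, dtype=bool)
for _b in b"ACGT":
    _ACGT[_b] = True


@dataclass
class CpgOeRecord:
    seq_id: str
    length: int  # N-excluded base count
    n_c: int
    n_g: int
    n_cpg: int

    @property
    def oe(self) -> float:
        if self.n_c * self.n_g == 0:
            return float("nan")
        return self.n_cpg * self.length / (self.n_c * self.n_g)

    @property
    def defined(self) -> bool:
        return self.n_c * self.n_g > 0


def _count_one(seq: str) -> tuple[int, int, int, int]:
    arr = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)
    valid = _ACGT[arr]
    length = int(valid.sum())
    n_c = int((arr == _C).sum())
    n_g = int((arr == _G).sum())
    n_cpg = int(((arr[:-1] == _C) & (arr[1:] == _G)).sum()) if len(arr) > 1 else 0
    return length, n_c, n_g, n_cpg


def cpg_oe(
    sequences: Mapping[str, str] | Iterable[tuple[str, str]] | ReferenceGenome,
    window: int = 0,
) -> pd.DataFrame:
    """Normalized CpG content per sequence (or per non-overlapping window).

    N bases are excluded from the base counts and from L; overlapping CpG
    dinucleotides are counted on raw adjacency.  Sequences (or windows)
    without any C or G yield an undefined (NaN) o/e, flagged rather than
    dropped.  ``window=0`` scores whole sequences.
    """
    if isinstance(sequences, ReferenceGenome):
        items = list(sequences.sequences.items())
    elif isinstance(sequences, Mapping):
        items = list(sequences.items())
    else:
        items = list(sequences)
    rows = []
    for name, seq in items:
        if window and window > 0:
            for start in range(0, len(seq), window):
                chunk = seq[start : start + window]
                rec = CpgOeRecord(f"{name}:{start + 1}-{start + len(chunk)}",
                                  *_count_one(chunk))
                rows.append(rec)
        else:
            rows.append(CpgOeRecord(name, *_count_one(seq)))
    return pd.DataFrame(
        {
            "seq_id": [r.seq_id for r in rows],
            "length": [r.length for r in rows],
            "n_c": [r.n_c for r in rows],
            "n_g": [r.n_g for r in rows],
            "n_cpg": [r.n_cpg for r in rows],
            "oe": [r.oe for r in rows],
            "defined": [r.defined for r in rows],
        }
    )


# ---------------------------------------------------------------------------
# bimodality


@dataclass
class BimodalityResult:
    mean1: float
    sd1: float
    loglik1: float
    weights: tuple[float, float]
    means: tuple[float, float]
    sds: tuple[float, float]
    loglik2: float
    lrt: float
    p: float
    call: str  # "unimodal" | "bimodal"
    n: int
    n_boot: int
    separation: float  # |mu2 - mu1| / pooled sd


def _fit_one(x: np.ndarray) -> tuple[float, float, float]:
    mu = float(np.mean(x))
    sd = float(np.std(x))
    sd = max(sd, 1e-3)
    ll = float(np.sum(stats.norm.logpdf(x, mu, sd)))
    return mu, sd, ll


def _fit_two(
    x: np.ndarray, rng: np.random.Generator, n_restarts: int,
    tol: float, max_iter: int,
) -> GaussianMixture:
    """Best-of-restarts 2-component fit, initialized from quantile pairs
    (deterministic given the rng state)."""
    X = x.reshape(-1, 1)
    base_pairs = [(0.25, 0.75), (0.10, 0.90), (0.33, 0.66)]
    inits = [np.quantile(x, pair) for pair in base_pairs]
    lo, hi = np.quantile(x, [0.02, 0.98])
    while len(inits) < n_restarts:
        pick = np.sort(rng.uniform(lo, hi, 2))
        inits.append(pick)
    best = None
    best_ll = -np.inf
    for means in inits[:n_restarts]:
        gm = _quiet_fit(X, means, tol, max_iter, rng)
        ll = float(gm.score(X)) * len(x)
        if ll > best_ll:
            best, best_ll = gm, ll
    return best


def _quiet_fit(X, means, tol, max_iter, rng) -> GaussianMixture:
    import warnings as _warnings

    from sklearn.exceptions import ConvergenceWarning

    with _warnings.catch_warnings():
        # restarts that stop at max_iter are still scored; best LL wins
        _warnings.simplefilter("ignore", ConvergenceWarning)
        gm = GaussianMixture(
            n_components=2,
            covariance_type="diag",
            tol=tol,
            max_iter=max_iter,
            reg_covar=1e-6,  # variance floor => sd >= 1e-3
            means_init=np.asarray(means).reshape(-1, 1),
            weights_init=np.array([0.5, 0.5]),
            n_init=1,
            random_state=int(rng.integers(2**31 - 1)),
        )
        gm.fit(X)
    return gm


def bimodality_test(
    values: Iterable[float],
    n_boot: int = 200,
    seed: int = 0,
    n_restarts: int = 10,
    boot_restarts: int = 4,
    tol: float = 1e-8,
    max_iter: int = 500,
    alpha: float = 0.05,
    min_separation: float = 2.0,
) -> BimodalityResult:
    """Parametric-bootstrap likelihood-ratio test for a 2-component mixture.

    LRT = 2(LL2 - LL1); the null distribution is obtained by refitting both
    models on ``n_boot`` samples from the fitted single Gaussian, and
    ``p = (1 + #{LRT* >= LRT}) / (n_boot + 1)``.  The call is ``bimodal`` iff
    p < ``alpha`` AND the component means are separated by more than
    ``min_separation`` pooled standard deviations — the LRT alone
    over-rejects for heavy-tailed unimodal data.
    """
    x = np.asarray([v for v in values if np.isfinite(v)], dtype=float)
    if len(x) < 50:
        raise ValueError(f"need at least 50 finite values (got {len(x)})")
    if np.ptp(x) == 0:
        raise ValueError("degenerate input: zero variance")
    rng = np.random.default_rng(seed)
    mu1, sd1, ll1 = _fit_one(x)
    gm = _fit_two(x, rng, n_restarts, tol, max_iter)
    ll2 = float(gm.score(x.reshape(-1, 1))) * len(x)
    lrt = max(2.0 * (ll2 - ll1), 0.0)

    n_ge = 0
    for _ in range(n_boot):
        xb = rng.normal(mu1, sd1, len(x))
        _, _, ll1b = _fit_one(xb)
        gmb = _fit_two(xb, rng, boot_restarts, tol, max_iter)
        ll2b = float(gmb.score(xb.reshape(-1, 1))) * len(xb)
        if max(2.0 * (ll2b - ll1b), 0.0) >= lrt:
            n_ge += 1
    p = (1 + n_ge) / (n_boot + 1)

    means = gm.means_.ravel()
    sds = np.sqrt(gm.covariances_.ravel())
    weights = gm.weights_.ravel()
    order = np.argsort(means)
    means, sds, weights = means[order], sds[order], weights[order]
    pooled_sd = float(np.sqrt(0.5 * (sds[0] ** 2 + sds[1] ** 2)))
    separation = float(abs(means[1] - means[0]) / pooled_sd)
    call = "bimodal" if (p < alpha and separation > min_separation) else "unimodal"
    return BimodalityResult(
        mean1=mu1, sd1=sd1, loglik1=ll1,
        weights=(float(weights[0]), float(weights[1])),
        means=(float(means[0]), float(means[1])),
        sds=(float(sds[0]), float(sds[1])),
        loglik2=ll2, lrt=lrt, p=float(p), call=call,
        n=len(x), n_boot=n_boot, separation=separation,
    )
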