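"""Synthetic genome generator with controlled GC and CpG observed/expected.

Sequences are drawn from a first-order Markov chain built so that its
stationary base composition matches the requested GC content exactly and the
expected CpG dinucleotide frequency equals ``cpg_oe_target * pi_C * pi_G``.
Only the transition row out of C differs from the base distribution: the
C->G probability is scaled by the target o/e and the remaining mass is spread
proportionally; the non-C rows are solved so the stationary distribution is
unchanged.  With o/e = 1 this reduces to iid bases.
"""
from __future__ import annotations

import numpy as np

from ..genome import CHROMOSOME, UNPLACED, ReferenceGenome

_BASES = b"ACGT"


def _markov_rows(gc: float, cpg_oe: float) -> tuple[np.ndarray, np.ndarray]:
    """Return (stationary pi, 4x4 transition matrix), base order ACGT."""
    if not 0.0 < gc < 1.0:
        raise ValueError(
            f"gc must lie strictly between 0 and 1 (got {gc}); a genome "
            "without cytosines cannot be simulated"
        )
    if cpg_oe <= 0:
        raise ValueError("cpg_oe_target must be positive")
    pi = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    pg = pi[2]
    c_to_g = cpg_oe * pg
    if c_to_g > 1.0:
        raise ValueError(
            f"impossible composition: cpg_oe_target={cpg_oe} with gc={gc} "
            f"requires P(G|C)={c_to_g:.3f} > 1"
        )
    c_row = np.empty(4)
    c_row[2] = c_to_g
    rest = np.array([pi[0], pi[1], pi[3]])
    c_row[[0, 1, 3]] = (1.0 - c_to_g) * rest / rest.sum()
    # non-C rows share one distribution q chosen so pi stays stationary
    q = (pi - pi[1] * c_row) / (1.0 - pi[1])
    if (q < -1e-12).any():
        raise ValueError(
            f"impossible composition: gc={gc}, cpg_oe_target={cpg_oe} admits "
            "no stationary Markov chain"
        )
    q = np.clip(q, 0.0, None)
    q /= q.sum()
    trans = np.vstack([q, c_row, q, q])
    return pi, trans


def _sample_sequence(length: int, pi: np.ndarray, trans: np.ndarray,
                     rng: np.random.Generator) -> str:
    cum = [tuple(np.cumsum(row)[:3]) for row in trans]
    pi_cum = tuple(np.cumsum(pi)[:3])
    u = rng.random(length).tolist()
    out = bytearray(length)
    x = u[0]
    c0, c1, c2 = pi_cum
    state = 0 if x < c0 else 1 if x < c1 else 2 if x < c2 else 3
    out[0] = _BASES[state]
    for i in range(1, length):
        c0, c1, c2 = cum[state]
        x = u[i]
        state = 0 if x < c0 else 1 if x < c1 else 2 if x < c2 else 3
        out[i] = _BASES[state]
    return out.decode("ascii")


def simulate_genome(
    n_chromosomes: int,
    n_unplaced: int,
    lengths: int | list[int],
    gc: float = 0.4,
    cpg_oe_target: float = 1.0,
    seed: int = 0,
) -> ReferenceGenome:
    """Generate a genome of placed chromosomes plus unplaced scaffolds.

    Parameters
    ----------
    lengths
        One length applied to every sequence, or a list with one length per
        sequence (chromosomes first, then unplaced scaffolds).  Each must be
        at least 1000 bases.
    gc
        Target GC fraction, matched exactly in expectation.
    cpg_oe_target
        Target CpG observed/expected ratio (1.0 = no depletion).
    """
    n_total = n_chromosomes + n_unplaced
    if n_total < 1:
        raise ValueError("need at least one sequence")
    if isinstance(lengths, int):
        lengths = [lengths] * n_total
    if len(lengths) != n_total:
        raise ValueError(f"expected {n_total} lengths, got {len(lengths)}")
    if min(lengths) < 1000:
        raise ValueError("sequence lengths must be >= 1000 bases")
    pi, trans = _markov_rows(gc, cpg_oe_target)
    rng = np.random.default_rng(seed)
    sequences: dict[str, str] = {}
    placement: dict[str, str] = {}
    for i in range(n_chromosomes):
        name = f"chr{i + 1}"
        sequences[name] = _sample_sequence(lengths[i], pi, trans, rng)
        placement[name] = CHROMOSOME
    for j in range(n_unplaced):
        name = f"scaffold{j + 1}"
        sequences[name] = _sample_sequence(lengths[n_chromosomes + j], pi, trans, rng)
        placement[name] = UNPLACED
    return ReferenceGenome(sequences, placement)
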