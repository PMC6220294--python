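"""Bisulfite read simulation for a directional WGBS library.

Each read is assigned a conversion strand with equal probability: original-top
(tag ``XG:Z:CT``) or original-bottom (``XG:Z:GA``).  On a CT read, reference
cytosines are emitted as C with probability ``m + (1-m)*eps_conv`` and as T
otherwise; on a GA read the symmetric conversion applies to reference
guanines (the minus-strand cytosines), appearing as G vs A.  Every base is
then independently corrupted with probability ``eps_seq``, uniformly over the
three alternative bases.  Reads are written as coordinate-sorted, single-end
SAM records stored in forward-reference orientation with constant quality
strings; a per-site truth table (true m and informative depth) accompanies
them.
"""
from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import pysam

from ..genome import ReferenceGenome
from ..methcall import index_cytosines
from .methylome import Methylome
from .pileup import SeqSimConfig

_A, _C, _G, _T = (ord(b) for b in "ACGT")
# alternatives[base] = the three other bases, for uniform error substitution
_ALTS = np.zeros((256, 3), dtype=np.uint8)
for _b, _others in ((_A, (_C, _G, _T)), (_C, (_A, _G, _T)),
                    (_G, (_A, _C, _T)), (_T, (_A, _C, _G))):
    _ALTS[_b] = _others


def simulate_reads(
    genome: ReferenceGenome,
    methylome: Methylome,
    cfg: SeqSimConfig,
    sam_path: str | Path,
    truth_path: str | Path | None = None,
) -> pd.DataFrame:
    """Write simulated bisulfite alignments to ``sam_path``; return the truth
    table (``chrom, pos, strand, context, true_m, depth``).

    ``cfg.mean_depth`` is the expected *informative* depth per cytosine site,
    i.e. coverage by reads of the matching conversion strand; total physical
    coverage is twice that.  The truth table's ``depth`` column is the
    realized informative depth.  Output is bit-reproducible under a fixed
    ``cfg.seed`` and 1-based in the TSV written to ``truth_path``.
    """
    cfg.validate()
    if genome.total_length == 0:
        raise ValueError("empty genome")
    rng = np.random.default_rng(cfg.seed)
    levels = methylome.level_arrays(genome)

    header = pysam.AlignmentHeader.from_dict(
        {
            "HD": {"VN": "1.6", "SO": "coordinate"},
            "SQ": [
                {"SN": name, "LN": genome.length(name)} for name in genome.names
            ],
        }
    )
    truth_frames = []
    with pysam.AlignmentFile(str(sam_path), "wh", header=header) as out:
        for tid, name in enumerate(genome.names):
            seq = genome.sequences[name]
            L = len(seq)
            rl = min(cfg.read_length, L)
            mean, _, _ = cfg.depth_spec(name, genome.is_placed(name))
            n_reads = int(round(2.0 * mean * L / rl))
            arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
            starts = np.sort(rng.integers(0, L - rl + 1, n_reads))
            is_ct = rng.random(n_reads) < 0.5
            plus_m = levels[(name, "+")]
            minus_m = levels[(name, "-")]
            cov_plus = np.zeros(L + 1, dtype=np.int64)
            cov_minus = np.zeros(L + 1, dtype=np.int64)
            quals = pysam.qualitystring_to_array("I" * rl)
            for i in range(n_reads):
                s = int(starts[i])
                bases = arr[s : s + rl].copy()
                if is_ct[i]:
                    mask = bases == _C
                    m_here = plus_m[s : s + rl][mask]
                    keep_c = rng.random(mask.sum()) < (
                        m_here + (1.0 - m_here) * cfg.eps_conv
                    )
                    sub = bases[mask]
                    sub[~keep_c] = _T
                    bases[mask] = sub
                    cov_plus[s] += 1
                    cov_plus[s + rl] -= 1
                else:
                    mask = bases == _G
                    m_here = minus_m[s : s + rl][mask]
                    keep_g = rng.random(mask.sum()) < (
                        m_here + (1.0 - m_here) * cfg.eps_conv
                    )
                    sub = bases[mask]
                    sub[~keep_g] = _A
                    bases[mask] = sub
                    cov_minus[s] += 1
                    cov_minus[s + rl] -= 1
                if cfg.eps_seq > 0:
                    err = rng.random(rl) < cfg.eps_seq
                    n_err = int(err.sum())
                    if n_err:
                        picks = rng.integers(0, 3, n_err)
                        bases[err] = _ALTS[bases[err], picks]
                a = pysam.AlignedSegment(header)
                a.query_name = f"sim_{name}_{i}"
                a.flag = 0
                a.reference_id = tid
                a.reference_start = s
                a.mapping_quality = 42
                a.cigartuples = [(0, rl)]
                a.query_sequence = bases.tobytes().decode("ascii")
                a.query_qualities = quals
                a.set_tag("XG", "CT" if is_ct[i] else "GA", value_type="Z")
                out.write(a)
            depth_plus = np.cumsum(cov_plus[:-1])
            depth_minus = np.cumsum(cov_minus[:-1])
            sub_genome_sites = index_cytosines(
                ReferenceGenome({name: seq}, {name: genome.placement[name]})
            )
            pos = sub_genome_sites["pos"].to_numpy()
            strand = sub_genome_sites["strand"].to_numpy()
            depth = np.where(strand == "+", depth_plus[pos], depth_minus[pos])
            true_m = np.where(strand == "+", plus_m[pos], minus_m[pos])
            truth_frames.append(
                pd.DataFrame(
                    {
                        "chrom": name,
                        "pos": pos,
                        "strand": strand,
                        "context": sub_genome_sites["context"],
                        "true_m": true_m,
                        "depth": depth,
                    }
                )
            )
    truth = pd.concat(truth_frames, ignore_index=True)
    truth.attrs["seed"] = cfg.seed
    if truth_path is not None:
        out_tsv = truth.copy()
        out_tsv["pos"] = out_tsv["pos"] + 1
        out_tsv.to_csv(truth_path, sep="\t", index=False)
    return truth
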