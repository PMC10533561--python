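"""ASV inference: dereplication, greedy error-read absorption, aberrant-kappa
removal and the >= 10% read-support filter.

The denoiser is a greedy abundance-skew absorber: unique sequences are
visited in decreasing abundance, and a sequence at Hamming distance d
(1..max_d) from an already-accepted ASV is absorbed into it when its count is
at most 2^-(alpha*d + 1) of the parent's — the expected shape of a
substitution-error tail.  Anything more abundant than that founds a new ASV.
Counts are conserved: absorbed reads add to the parent.

Light-chain ASVs matching the aberrant Sp2/0 kappa reference (global identity
>= 97% over >= 90% length coverage by default) are flagged and excluded before
within-sample fractions are computed; heavy-chain ASVs are never flagged.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import edlib

from .config import AssayConfig, chain_locus
from .readproc import MergedRead
from .seqs import hamming


@dataclass
class Asv:
    sequence: str
    count: int
    well: str
    chain: str
    fraction: float = 0.0
    aberrant: bool = False
    absorbed: list[str] = field(default_factory=list)


def dereplicate(reads: list[MergedRead]) -> dict[str, int]:
    """Exact-sequence grouping; counts sum to the input size."""
    wells = {(r.well, r.chain) for r in reads}
    if len(wells) > 1:
        raise ValueError("dereplicate expects reads from a single well+chain")
    counts: dict[str, int] = {}
    for r in reads:
        counts[r.sequence] = counts.get(r.sequence, 0) + 1
    return counts


def denoise_asvs(
    derep: dict[str, int], well: str = "", chain: str = "",
    alpha: float = 2.0, max_d: int = 4,
) -> list[Asv]:
    """Collapse a dereplicated count map into ASVs (see module docstring).

    Ties in abundance are broken lexicographically by sequence, so the result
    is independent of input order.
    """
    if not derep:
        return []
    order = sorted(derep, key=lambda s: (-derep[s], s))
    accepted: list[Asv] = []
    for seq in order:
        count = derep[seq]
        parent = None
        best = None
        for asv in accepted:
            if len(asv.sequence) != len(seq):
                continue
            d = hamming(asv.sequence, seq)
            if not 1 <= d <= max_d:
                continue
            if count / asv.count > 2.0 ** -(alpha * d + 1):
                continue  # too abundant to be an error tail of this parent
            cand = (d, -asv.count, asv.sequence)
            if best is None or cand < best:
                best, parent = cand, asv
        if parent is not None:
            parent.count += count
            parent.absorbed.append(seq)
        else:
            accepted.append(Asv(sequence=seq, count=count, well=well, chain=chain))
    accepted.sort(key=lambda a: (-a.count, a.sequence))
    return accepted


def is_aberrant(
    sequence: str, aberrant_ref: str,
    min_identity: float = 0.97, min_coverage: float = 0.90,
) -> bool:
    """Does a sequence match the aberrant reference?

    The shorter of the two is globally aligned into the longer (edlib infix
    mode); a match requires identity >= min_identity over the shorter
    sequence and a length ratio >= min_coverage.
    """
    short, long_ = sorted((sequence, aberrant_ref), key=len)
    if not short or len(short) < min_coverage * len(long_):
        return False
    dist = edlib.align(short, long_, mode="HW", task="distance")["editDistance"]
    return 1.0 - dist / len(short) >= min_identity


def filter_aberrant(
    asvs: list[Asv], aberrant_ref: str | None,
    min_identity: float = 0.97, min_coverage: float = 0.90,
) -> list[Asv]:
    """Flag light-chain ASVs matching the aberrant reference (in place).

    Heavy-chain ASVs are never flagged.  A missing reference is a config
    error when light-chain ASVs are present.
    """
    for asv in asvs:
        if chain_locus(asv.chain) != "light":
            continue
        if aberrant_ref is None:
            raise ValueError("aberrant reference required for light-chain ASVs")
        asv.aberrant = is_aberrant(asv.sequence, aberrant_ref,
                                   min_identity, min_coverage)
    return asvs


def fraction_filter(asvs: list[Asv], min_fraction: float = 0.10) -> list[Asv]:
    """Compute within-sample fractions and retain ASVs at >= min_fraction.

    The denominator is the total retained-ASV read count for the well+chain
    after aberrant removal (ReadsPerPrimerWell); flagged ASVs are excluded
    from both numerator set and denominator.
    """
    kept = [a for a in asvs if not a.aberrant]
    total = sum(a.count for a in kept)
    for a in kept:
        a.fraction = a.count / total if total else 0.0
    return [a for a in kept if a.fraction >= min_fraction]


def denoise_well(
    reads: list[MergedRead], well: str, chain: str,
    config: AssayConfig | None = None,
) -> tuple[list[Asv], int]:
    """Full denoise stage for one well+chain.

    Returns (retained ASVs, ReadsPerPrimerWell denominator used for
    fractions).
    """
    config = config or AssayConfig()
    derep = dereplicate(reads)
    asvs = denoise_asvs(derep, well, chain,
                        config.denoise_alpha, config.denoise_max_d)
    filter_aberrant(asvs, config.aberrant_ref,
                    config.aberrant_min_identity, config.aberrant_min_coverage)
    denom = sum(a.count for a in asvs if not a.aberrant)
    retained = fraction_filter(asvs, config.min_fraction)
    return retained, denom
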