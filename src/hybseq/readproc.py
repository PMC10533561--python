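"""Read cleaning, inline-barcode demultiplexing, chain assignment and merging.

Stage order, matching the upstream cleaning the pipeline re-implements:

1. demultiplex on the R1 inline barcode (exact prefix match by default,
   longest barcode wins when barcodes nest), strip barcode + TSO;
2. assign heavy/kappa/lambda from the R2 nested-primer prefix (1 mismatch
   allowed by default), strip the primer;
3. discard any read pair containing an 'N';
4. trim trailing bases with Phred quality < 10 from the 3' ends;
5. merge the pair over the best overlap (>= 20 nt, <= 10% mismatches);
6. keep merged sequences of at least 385 nt.

Every read pair ends up in exactly one counter bucket, so
assigned + unassigned + discarded = total at each stage.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .config import AssayConfig
from .seqs import hamming, revcomp


@dataclass
class MergedRead:
    well: str
    chain: str                # heavy | kappa | lambda
    sequence: str
    qualities: np.ndarray     # per-base Phred

    def __len__(self) -> int:
        return len(self.sequence)


class SampleSheet:
    """Plate sample sheet: inline barcode -> well -> mAb ID."""

    REQUIRED = ("plate", "well", "barcode", "mab_id")

    def __init__(self, df: pd.DataFrame):
        missing = set(self.REQUIRED) - set(df.columns)
        if missing:
            raise ValueError(f"sample sheet missing columns: {sorted(missing)}")
        if df.empty:
            raise ValueError("sample sheet is empty")
        for plate, grp in df.groupby("plate"):
            if grp["barcode"].duplicated().any():
                raise ValueError(f"duplicate barcodes on plate {plate}")
            if grp["well"].duplicated().any():
                raise ValueError(f"duplicate wells on plate {plate}")
        for bc in df["barcode"]:
            if not 5 <= len(bc) <= 8:
                raise ValueError(f"barcode {bc!r} outside 5-8 nt")
        self.df = df.reset_index(drop=True)
        self.by_barcode = dict(zip(df["barcode"], df["well"]))
        self.mab_of_well = dict(zip(df["well"], df["mab_id"]))

    @classmethod
    def from_tsv(cls, path: str | Path) -> "SampleSheet":
        return cls(pd.read_csv(path, sep="\t", dtype=str))

    def to_tsv(self, path: str | Path) -> None:
        self.df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# per-read operations
# ---------------------------------------------------------------------------


def demultiplex_read(
    seq: str, sheet: SampleSheet, tso: str,
    max_mismatch: int = 0, tso_window: int = 20,
) -> tuple[str | None, int]:
    """Assign an R1 to a well by its barcode prefix; locate and strip the TSO.

    Returns (well or None, payload start offset).  The longest matching
    barcode wins; two equal-length matches are ambiguous -> unassigned.  The
    TSO must be found by exact match within ``tso_window`` nt after the
    barcode, guarding against barcode false positives.
    """
    hits: list[str] = []
    for bc in sheet.by_barcode:
        if len(bc) > len(seq):
            continue
        if hamming(seq[:len(bc)], bc) <= max_mismatch:
            hits.append(bc)
    if not hits:
        return None, 0
    best_len = max(len(b) for b in hits)
    best = [b for b in hits if len(b) == best_len]
    if len(best) != 1:
        return None, 0
    bc = best[0]
    pos = seq.find(tso, len(bc), len(bc) + tso_window + len(tso))
    if pos < 0:
        return None, 0
    return sheet.by_barcode[bc], pos + len(tso)


def assign_chain(
    read2_prefix: str, primers: dict[str, str], max_mismatch: int = 1,
) -> tuple[str | None, int]:
    """Match the R2 prefix against the nested chain primers.

    Returns (chain or None, primer length to strip).  Ties across chains ->
    unassigned.
    """
    best: list[tuple[int, str]] = []
    for chain, primer in primers.items():
        if len(read2_prefix) < len(primer):
            continue
        d = hamming(read2_prefix[:len(primer)], primer)
        if d <= max_mismatch:
            best.append((d, chain))
    if not best:
        return None, 0
    best.sort()
    if len(best) > 1 and best[0][0] == best[1][0]:
        return None, 0
    chain = best[0][1]
    return chain, len(primers[chain])


def drop_n_read(seq: str) -> bool:
    """True if the read should be kept (contains no 'N')."""
    return "N" not in seq


def quality_trim_3prime(
    seq: str, quals: np.ndarray, qmin: int = 10,
) -> tuple[str, np.ndarray]:
    """Remove the maximal trailing run of bases with quality < qmin."""
    if len(seq) != len(quals):
        raise ValueError("sequence/quality length mismatch")
    end = len(quals)
    while end > 0 and quals[end - 1] < qmin:
        end -= 1
    return seq[:end], quals[:end]


def merge_pairs(
    read1: tuple[str, np.ndarray], read2: tuple[str, np.ndarray],
    min_overlap: int = 20, mismatch_cap: float = 0.10,
) -> tuple[str, np.ndarray] | None:
    """Overlap-merge a pair; R2 is reverse-complemented internally.

    The offset maximizing matched bases wins, subject to overlap >= min_overlap
    and a mismatch fraction <= mismatch_cap.  At disagreeing positions the
    higher-quality base is taken with its quality; where mates agree the
    quality is min(q1 + q2, 41).  Returns None when no acceptable overlap
    exists (a counted, normal outcome).
    """
    s1, q1 = read1
    s2 = revcomp(read2[0])
    q2 = read2[1][::-1]
    if not s1 or not s2:
        return None
    a1 = np.frombuffer(s1.encode(), dtype="S1")
    a2 = np.frombuffer(s2.encode(), dtype="S1")
    n1, n2 = len(a1), len(a2)

    best = None  # (matches, -mismatches, offset)
    for off in range(0, n1 - min_overlap + 1):
        ln = min(n1 - off, n2)
        eq = a1[off:off + ln] == a2[:ln]
        matches = int(eq.sum())
        mism = ln - matches
        if mism > mismatch_cap * ln:
            continue
        cand = (matches, -mism, off)
        if best is None or cand > best:
            best = cand
    if best is None:
        return None
    off = best[2]
    ln = min(n1 - off, n2)

    o1, o2 = a1[off:off + ln], a2[:ln]
    oq1, oq2 = q1[off:off + ln], q2[:ln]
    agree = o1 == o2
    take2 = ~agree & (oq2 > oq1)
    cons = np.where(take2, o2, o1)
    consq = np.where(agree, np.minimum(oq1 + oq2, 41), np.maximum(oq1, oq2))

    seq = s1[:off] + cons.tobytes().decode() + s2[ln:]
    qual = np.concatenate([q1[:off], consq, q2[ln:]])
    return seq, qual


def length_filter(merged_len: int, min_len: int = 385) -> bool:
    """Keep merged sequences of at least ``min_len`` nt."""
    return merged_len >= min_len


# ---------------------------------------------------------------------------
# FASTQ I/O and the stage driver
# ---------------------------------------------------------------------------


def read_fastq(path: str | Path):
    """Yield (name, sequence, phred array) from a possibly gzipped FASTQ."""
    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(path, "rt") as fh:
        while True:
            name = fh.readline().strip()
            if not name:
                return
            seq = fh.readline().strip()
            fh.readline()
            qual = fh.readline().strip()
            yield name[1:], seq, np.frombuffer(qual.encode(), dtype=np.uint8) - 33


def process_reads(
    r1_path: str | Path, r2_path: str | Path, sheet: SampleSheet,
    config: AssayConfig | None = None,
) -> tuple[dict[tuple[str, str], list[MergedRead]], dict[str, int]]:
    """Run the full cleaning/merging stage over a plate's paired FASTQ.

    Returns merged reads keyed by (well, chain) plus per-stage counters that
    partition the input (total = sum of all terminal buckets).
    """
    config = config or AssayConfig()
    counts = {
        "total": 0, "unassigned_barcode": 0, "unassigned_chain": 0,
        "dropped_n": 0, "dropped_merge": 0, "dropped_short": 0, "merged": 0,
    }
    out: dict[tuple[str, str], list[MergedRead]] = {}
    for (n1, s1, p1), (n2, s2, p2) in zip(read_fastq(r1_path), read_fastq(r2_path)):
        counts["total"] += 1
        well, off1 = demultiplex_read(
            s1, sheet, config.tso, config.barcode_max_mismatch,
            config.tso_search_window)
        if well is None:
            counts["unassigned_barcode"] += 1
            continue
        chain, off2 = assign_chain(s2, config.primers, config.primer_max_mismatch)
        if chain is None:
            counts["unassigned_chain"] += 1
            continue
        s1t, p1t = s1[off1:], p1[off1:]
        s2t, p2t = s2[off2:], p2[off2:]
        if not (drop_n_read(s1t) and drop_n_read(s2t)):
            counts["dropped_n"] += 1
            continue
        s1t, p1t = quality_trim_3prime(s1t, p1t, config.qmin)
        s2t, p2t = quality_trim_3prime(s2t, p2t, config.qmin)
        merged = merge_pairs((s1t, p1t), (s2t, p2t),
                             config.min_overlap, config.overlap_mismatch_cap)
        if merged is None:
            counts["dropped_merge"] += 1
            continue
        if not length_filter(len(merged[0]), config.min_merged_len):
            counts["dropped_short"] += 1
            continue
        counts["merged"] += 1
        out.setdefault((well, chain), []).append(
            MergedRead(well=well, chain=chain, sequence=merged[0],
                       qualities=merged[1]))
    terminal = [v for k, v in counts.items() if k != "total"]
    assert sum(terminal) == counts["total"], "stage counters do not partition input"
    return out, counts

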