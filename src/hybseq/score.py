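"""Replicate-consistency star scoring and cohort census.

Each curated V_L/V_H sequence from one sequenced sample receives a 0-5 star
score combining read support and replicate consistency:

    ASV Score   = ReadPerSequence / ReadsPerPrimerWell          (0..1)
    MatchScore  = (BR + 0.75*TR) - (1 - (BR + TR)/TotalSeqs)
    TotalScore  = 3*ln(MatchScore) + 2*ASV Score

where BR counts biological replicates (other subclones of the same parent
hybridoma carrying the identical trimmed sequence for that chain), TR counts
technical replicates (other samples of the same subclone carrying it) and
TotalSeqs is the number of sequenced samples in the parent group for that
chain.  The ASV component contributes up to 2 points and the match component
up to 3, so the log term is clamped to [0, 3]: a MatchScore <= 1 (including
the negative values an unreplicated sequence produces) contributes nothing.

Samples are named ProjectID/ParentID.SubcloneID; sequences scoring below 3
stars are filtered out; the per-parent chain multiplicity is the mean number
of distinct retained sequences per sample, rounded to the nearest integer
(halves away from zero).
"""

from __future__ import annotations

import math
import re
import warnings
from dataclasses import dataclass

import pandas as pd


@dataclass(frozen=True)
class MabId:
    project: str
    parent: str
    subclone: str | None = None

    def __str__(self) -> str:
        base = f"{self.project}/{self.parent}"
        return f"{base}.{self.subclone}" if self.subclone is not None else base

    @property
    def parent_id(self) -> str:
        return f"{self.project}/{self.parent}"


def parse_mab_id(text: str) -> MabId:
    """Parse ProjectID/ParentID[.SubcloneID]; round-trips through str()."""
    m = re.fullmatch(r"([^/.]+)/([^/.]+)(?:\.([^/.]+))?", text.strip())
    if not m:
        raise ValueError(f"malformed mAb ID {text!r} "
                         "(expected ProjectID/ParentID.SubcloneID)")
    return MabId(m.group(1), m.group(2), m.group(3))


@dataclass
class ScoredEntry:
    mab_id: MabId
    plate: str
    well: str
    chain: str                 # heavy | light
    trimmed_nt: str
    read_per_sequence: int
    reads_per_primer_well: int
    asv_score: float = 0.0
    br: int = 0
    tr: int = 0
    total_seqs: int = 0
    match_score: float = 0.0
    total_score: float = 0.0


# ---------------------------------------------------------------------------
# the scoring formulas
# ---------------------------------------------------------------------------


def asv_score(read_per_sequence: int, reads_per_primer_well: int) -> float:
    """Read-support fraction for one sequence within its sample+chain."""
    if reads_per_primer_well <= 0:
        warnings.warn("ReadsPerPrimerWell is zero; ASV score set to 0")
        return 0.0
    if not 0 <= read_per_sequence <= reads_per_primer_well:
        raise ValueError("require 0 <= ReadPerSequence <= ReadsPerPrimerWell")
    return read_per_sequence / reads_per_primer_well


def match_score(br: int, tr: int, total_seqs: int) -> float:
    """Replicate-consistency raw score; may be <= 0 for unreplicated sequences."""
    if total_seqs < 1:
        raise ValueError("TotalSeqs must be >= 1")
    return (br + 0.75 * tr) - (1.0 - (br + tr) / total_seqs)


def match_component(ms: float) -> float:
    """The star contribution of a MatchScore: 3*ln clamped into [0, 3]."""
    if ms <= 1.0:
        return 0.0
    return min(3.0, 3.0 * math.log(ms))


def total_score(ms: float, asv: float) -> float:
    """Total stars in [0, 5]: clamped match component plus 2 * ASV score."""
    return match_component(ms) + 2.0 * asv


def quality_filter(entries: list[ScoredEntry], min_score: float = 3.0) -> list[ScoredEntry]:
    """Retain entries scoring at least ``min_score`` stars."""
    return [e for e in entries if e.total_score >= min_score]


# ---------------------------------------------------------------------------
# replicate counting over a cohort
# ---------------------------------------------------------------------------


def count_replicates(
    focal: ScoredEntry, cohort: list[ScoredEntry],
    totalseqs_mode: str = "samples", include_focal: bool = False,
) -> tuple[int, int, int]:
    """(BR, TR, TotalSeqs) for one entry against the whole cohort.

    A *sample* is one sequenced well (plate, well, mAb ID).  BR counts other
    samples of the same parent but a different subclone containing the focal
    trimmed sequence for the same chain; TR counts other samples of the same
    subclone containing it.  TotalSeqs is the number of samples of the parent
    group sequenced for that chain (``totalseqs_mode="sequences"`` instead
    counts distinct sequences returned for the group).
    """
    fid = focal.mab_id
    group = [e for e in cohort
             if e.chain == focal.chain and e.mab_id.parent_id == fid.parent_id]
    focal_key = (focal.plate, focal.well, str(focal.mab_id))

    samples: dict[tuple, dict] = {}
    for e in group:
        key = (e.plate, e.well, str(e.mab_id))
        rec = samples.setdefault(key, {"subclone": e.mab_id.subclone, "seqs": set()})
        rec["seqs"].add(e.trimmed_nt)

    br = tr = 0
    for key, rec in samples.items():
        if key == focal_key and not include_focal:
            continue
        if focal.trimmed_nt not in rec["seqs"]:
            continue
        if rec["subclone"] == fid.subclone:
            tr += 1
        else:
            br += 1
    if totalseqs_mode == "sequences":
        total = len({s for rec in samples.values() for s in rec["seqs"]})
    else:
        total = len(samples)
    return br, tr, max(total, 1)


def score_cohort(
    entries: list[ScoredEntry],
    totalseqs_mode: str = "samples", include_focal: bool = False,
) -> list[ScoredEntry]:
    """Fill BR/TR/TotalSeqs and all score fields for every entry (in place)."""
    for e in entries:
        e.br, e.tr, e.total_seqs = count_replicates(
            e, entries, totalseqs_mode, include_focal)
        e.asv_score = asv_score(e.read_per_sequence, e.reads_per_primer_well)
        e.match_score = match_score(e.br, e.tr, e.total_seqs)
        e.total_score = total_score(e.match_score, e.asv_score)
    return entries


# ---------------------------------------------------------------------------
# chain multiplicity and the cohort census
# ---------------------------------------------------------------------------


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def chain_multiplicity(entries: list[ScoredEntry], chain: str) -> int:
    """Mean distinct retained sequences per sample of a parent group, rounded.

    ``entries`` are the retained (post-filter) entries of one parent group;
    rounding is to the nearest integer with halves away from zero.  An empty
    group has multiplicity 0.
    """
    per_sample: dict[tuple, set] = {}
    for e in entries:
        if e.chain != chain:
            continue
        per_sample.setdefault((e.plate, e.well, str(e.mab_id)), set()).add(e.trimmed_nt)
    if not per_sample:
        return 0
    mean = sum(len(s) for s in per_sample.values()) / len(per_sample)
    return _round_half_away(mean)


CENSUS_CATEGORIES = (
    "vl_or_vh_zero",
    "both_present",
    "no_additional_chain",
    "additional_any",
    "one_additional_vl_only",
    "one_additional_vh_only",
    "one_additional_vl_and_vh",
)


def census_percentage(count: int, total: int) -> float:
    """A census percentage as displayed: 100*count/total to one decimal."""
    if total <= 0:
        raise ValueError("total must be positive")
    return round(100.0 * count / total, 1)


def summarize_cohort(
    multiplicities: pd.DataFrame, stratify: str | None = None,
) -> pd.DataFrame:
    """Census of a cohort of unique parent mAb IDs.

    ``multiplicities`` needs columns ``mab_id`` (parent-level), ``n_vl`` and
    ``n_vh`` (retained chain multiplicities); an optional categorical column
    named by ``stratify`` (e.g. fusion method) adds per-stratum count/percent
    columns.  Percentages are of the full cohort within each stratum.
    """
    df = multiplicities

    def _counts(sub: pd.DataFrame) -> dict[str, int]:
        nvl, nvh = sub["n_vl"], sub["n_vh"]
        both = (nvl >= 1) & (nvh >= 1)
        return {
            "vl_or_vh_zero": int(((nvl == 0) | (nvh == 0)).sum()),
            "both_present": int(both.sum()),
            "no_additional_chain": int((both & (nvl == 1) & (nvh == 1)).sum()),
            "additional_any": int((both & ((nvl >= 2) | (nvh >= 2))).sum()),
            "one_additional_vl_only": int((both & (nvl == 2) & (nvh == 1)).sum()),
            "one_additional_vh_only": int((both & (nvl == 1) & (nvh == 2)).sum()),
            "one_additional_vl_and_vh": int((both & (nvl == 2) & (nvh == 2)).sum()),
        }

    total = len(df)
    counts = _counts(df)
    out = pd.DataFrame({
        "category": CENSUS_CATEGORIES,
        "count": [counts[c] for c in CENSUS_CATEGORIES],
        "percent": [census_percentage(counts[c], total) if total else 0.0
                    for c in CENSUS_CATEGORIES],
    })
    if stratify is not None:
        for value, sub in df.groupby(stratify):
            c = _counts(sub)
            out[f"count_{value}"] = [c[k] for k in CENSUS_CATEGORIES]
            out[f"percent_{value}"] = [
                census_percentage(c[k], len(sub)) if len(sub) else 0.0
                for k in CENSUS_CATEGORIES]
    return out
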