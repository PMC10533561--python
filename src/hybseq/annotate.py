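"""IMGT numbering, FR/CDR segmentation and validity filtering of V domains.

Full germline-HMM numbering (as ANARCI does it) is replaced here by detection
of the four conserved V-domain anchors —

    1st-CYS at IMGT 23, conserved TRP at 41, 2nd-CYS at 104,
    and the J-region [FW]GxG motif whose F/W sits at IMGT 118 —

followed by the standard IMGT gap and insertion rules: framework regions have
fixed lengths (FR1 1-26, FR2 39-55, FR3 66-104, FR4 118-127 light / 118-128
heavy); short CDRs leave gaps in the middle of their slot ranges; CDR3 loops
longer than 13 residues receive lettered insertion positions at 111/112
(111A..., 112A... with the first extra position on the 112 side).

Anchor candidates within a window are ranked by a small residue profile, so a
single substitution at a non-anchor position does not derail the numbering.
The validity filters (no zero-length region, intact FR1 start / FR4 end, a
start codon upstream, no stop codon inside the V domain) are applied verbatim
from the curation rules this pipeline implements.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

from .config import chain_locus
from .seqs import translate

REGION_BOUNDS = {
    "FR1": (1, 26),
    "CDR1": (27, 38),
    "FR2": (39, 55),
    "CDR2": (56, 65),
    "FR3": (66, 104),
    "CDR3": (105, 117),
    "FR4": (118, 128),  # upper bound; light chains end at 127
}
REGION_ORDER = ("FR1", "CDR1", "FR2", "CDR2", "FR3", "CDR3", "FR4")

_J_MOTIF = re.compile(r"[FW]G.G")


class AnnotationError(ValueError):
    """Raised when a sequence cannot be assigned a V-domain numbering."""


def imgt_key(label: str) -> float:
    """Sort key giving the IMGT traversal order, including 111A../112A..

    Plain positions sort numerically; insertions run 111 < 111A < 111B < ...
    < 112B < 112A < 112 (letters ascend after 111, descend into 112).
    """
    m = re.fullmatch(r"(\d+)([A-Z]?)", label)
    if not m:
        raise ValueError(f"bad IMGT label {label!r}")
    num, letter = int(m.group(1)), m.group(2)
    if not letter:
        return float(num)
    rank = ord(letter) - ord("A") + 1
    if num == 111:
        return 111 + rank / 100.0
    if num == 112:
        return 112 - rank / 100.0
    raise ValueError(f"insertion labels only supported at 111/112, got {label!r}")


def region_of(label: str) -> str:
    """Region a single IMGT label belongs to."""
    num = int(re.fullmatch(r"(\d+)[A-Z]?", label).group(1))
    for name in REGION_ORDER:
        lo, hi = REGION_BOUNDS[name]
        if lo <= num <= hi:
            return name
    raise ValueError(f"IMGT position {label} outside 1-128")


@dataclass
class VDomainAnnotation:
    chain: str                       # "heavy" | "light"
    frame: int                       # reading-frame offset into the source nt
    aa_full: str                     # translation of the whole amplicon interior
    imgt_map: list[tuple[str, str]]  # (IMGT label, residue), in IMGT order
    regions: dict[str, str]
    trimmed_nt: str                  # codons of exactly the IMGT span
    v_start: int                     # aa index of the first IMGT residue
    v_end: int                       # aa index of the last IMGT residue
    has_start_codon: bool = True
    valid: bool = False
    reasons: list[str] = field(default_factory=list)

    @property
    def v_aa(self) -> str:
        return "".join(r for _, r in self.imgt_map)


# ---------------------------------------------------------------------------
# anchor detection
# ---------------------------------------------------------------------------

# typical CDR lengths used to disambiguate when several anchor candidates fit
_EXPECTED_CDR = {"light": (6, 3), "heavy": (8, 8)}


def _locate_anchors(aa: str, locus: str) -> dict[str, int]:
    """Find the aa indices of the four anchors, or raise AnnotationError.

    Works backwards from the J motif: the [FW]GxG closest to the 3' end fixes
    IMGT 118; FR3 has a fixed 39-residue length, so 2nd-CYS fixes everything
    upstream of CDR2; the windows for TRP-41 and 1st-CYS then follow from the
    allowed CDR2 (0-10) and CDR1 (0-12) slot counts.
    """
    j_hits = list(_J_MOTIF.finditer(aa))
    if not j_hits:
        raise AnnotationError("no J-region [FW]GxG motif")
    j = j_hits[-1].start()

    # 2nd-CYS: C with a plausible CDR3 (3-25 residues) before the J anchor,
    # preferring the canonical Y-x-C / x-Y-C context.
    best = None
    for p in range(max(0, j - 26), j - 3):
        if aa[p] != "C":
            continue
        score = 0
        if p >= 1 and aa[p - 1] in "YF":
            score += 2
        if p >= 2 and aa[p - 2] == "Y":
            score += 1
        cand = (score, p)  # ties -> largest p (shortest CDR3)
        if best is None or cand > best:
            best = cand
    if best is None:
        raise AnnotationError("no 2nd-CYS candidate upstream of the J motif")
    c104 = best[1]

    fr3_start = c104 - 38
    if fr3_start < 0:
        raise AnnotationError("sequence truncated inside FR3")

    exp_cdr1, exp_cdr2 = _EXPECTED_CDR[locus]
    # TRP-41: fr3_start = w + 15 + cdr2_len with cdr2_len in 0..10
    best = None
    for q in range(max(0, fr3_start - 25), fr3_start - 14):
        if aa[q] != "W":
            continue
        cdr2_len = fr3_start - q - 15
        cand = (-abs(cdr2_len - exp_cdr2), q)
        if best is None or cand > best:
            best = cand
    if best is None:
        raise AnnotationError("no conserved TRP-41 candidate")
    w41 = best[1]

    # 1st-CYS: w41 = c23 + 6 + cdr1_len with cdr1_len in 0..12
    best = None
    for r in range(max(0, w41 - 18), w41 - 5):
        if aa[r] != "C":
            continue
        cdr1_len = w41 - r - 6
        cand = (-abs(cdr1_len - exp_cdr1), r)
        if best is None or cand > best:
            best = cand
    if best is None:
        raise AnnotationError("no 1st-CYS candidate")
    c23 = best[1]

    return {"c23": c23, "w41": w41, "c104": c104, "j118": j}


def _middle_out_labels(lo: int, hi: int, n: int) -> list[str]:
    """IMGT labels for a CDR of n residues in slots lo..hi (gaps in the middle)."""
    slots = hi - lo + 1
    if n > slots:
        raise AnnotationError(f"CDR with {n} residues exceeds {slots} slots")
    head = (n + 1) // 2
    tail = n - head
    return [str(lo + i) for i in range(head)] + [str(hi - tail + 1 + i) for i in range(tail)]


def _cdr3_labels(n: int) -> list[str]:
    """Labels for a CDR3 of n residues: gaps if n < 13, 111/112 insertions if n > 13."""
    if n <= 13:
        return _middle_out_labels(105, 117, n)
    extra = n - 13
    n112 = (extra + 1) // 2  # first insertion goes on the 112 side
    n111 = extra - n112
    labels = [str(p) for p in range(105, 112)]
    labels += [f"111{chr(ord('A') + i)}" for i in range(n111)]
    labels += [f"112{chr(ord('A') + i)}" for i in reversed(range(n112))]
    labels += [str(p) for p in range(112, 118)]
    return labels


# ---------------------------------------------------------------------------
# public operations
# ---------------------------------------------------------------------------


def assign_imgt_numbering(aa_full: str, chain: str) -> list[tuple[str, str]]:
    """Number the V domain within a translated sequence.

    Returns the ordered (label, residue) map covering IMGT 1-127 (light) or
    1-128 (heavy) as far as the sequence extends; raises AnnotationError when
    an anchor cannot be found.
    """
    locus = chain_locus(chain)
    a = _locate_anchors(aa_full, locus)
    out: list[tuple[str, str]] = []

    # FR1: positions 1..23 end at the 1st-CYS; 24-26 follow.
    fr1_start = a["c23"] - 22
    for pos in range(1, 27):
        idx = fr1_start + (pos - 1) if pos <= 23 else a["c23"] + (pos - 23)
        if idx >= 0:
            out.append((str(pos), aa_full[idx]))

    # CDR1 between FR1 (ends c23+3) and FR2 (39,40 just before the TRP)
    cdr1 = aa_full[a["c23"] + 4: a["w41"] - 2]
    out += list(zip(_middle_out_labels(27, 38, len(cdr1)), cdr1))

    # FR2: 39-55 (TRP at 41)
    fr2 = aa_full[a["w41"] - 2: a["w41"] + 15]
    out += [(str(39 + i), r) for i, r in enumerate(fr2)]

    # CDR2 between FR2 and FR3
    fr3_start = a["c104"] - 38
    cdr2 = aa_full[a["w41"] + 15: fr3_start]
    out += list(zip(_middle_out_labels(56, 65, len(cdr2)), cdr2))

    # FR3: 66-104
    out += [(str(66 + i), aa_full[fr3_start + i]) for i in range(39)]

    # CDR3 between 2nd-CYS and the J anchor
    cdr3 = aa_full[a["c104"] + 1: a["j118"]]
    out += list(zip(_cdr3_labels(len(cdr3)), cdr3))

    # FR4: 118..127 (light) or ..128 (heavy)
    last = 127 if locus == "light" else 128
    for pos in range(118, last + 1):
        idx = a["j118"] + (pos - 118)
        if idx < len(aa_full):
            out.append((str(pos), aa_full[idx]))
    return out


def segment_regions(imgt_map: list[tuple[str, str]]) -> dict[str, str]:
    """Partition a numbered V domain into FR1-4/CDR1-3 residue runs."""
    regions = {name: "" for name in REGION_ORDER}
    for label, residue in imgt_map:
        regions[region_of(label)] += residue
    return regions


def find_reading_frame(asv_nt: str, chain: str) -> tuple[int, str]:
    """Select the reading frame in which the V-domain anchors are found.

    Requires an ATG-encoded Met upstream of IMGT position 1 (the leader start)
    and no stop codon between that Met and the end of FR4.  Raises
    AnnotationError if no frame qualifies.
    """
    locus = chain_locus(chain)
    errors = []
    for frame in range(3):
        aa = translate(asv_nt[frame:])
        try:
            a = _locate_anchors(aa, locus)
        except AnnotationError as exc:
            errors.append(f"frame {frame}: {exc}")
            continue
        fr1_start = max(0, a["c23"] - 22)
        last = 127 if locus == "light" else 128
        fr4_end = min(a["j118"] + (last - 118), len(aa) - 1)
        m = aa.rfind("M", 0, fr1_start)
        if m < 0:
            errors.append(f"frame {frame}: no start codon upstream of the V domain")
            continue
        if "*" in aa[m: fr4_end + 1]:
            errors.append(f"frame {frame}: stop codon between leader start and FR4")
            continue
        return frame, aa
    raise AnnotationError("; ".join(errors) or "no valid reading frame")


def validate_domain(ann: VDomainAnnotation) -> tuple[bool, list[str]]:
    """Apply the curation validity filters; returns (verdict, failure reasons)."""
    reasons: list[str] = []
    labels = {lab for lab, _ in ann.imgt_map}
    regions = ann.regions

    for name in REGION_ORDER:
        if not regions.get(name):
            reasons.append(f"zero-length region: {name}")

    if not all(str(p) in labels for p in range(1, 11)):
        reasons.append("FR1 incomplete: first 10 positions not all present")

    last = 127 if ann.chain == "light" else 128
    if not all(str(p) in labels for p in range(last - 9, last + 1)):
        reasons.append("FR4 incomplete: last 10 positions not all present")

    if "*" in ann.v_aa:
        reasons.append("stop codon within the V domain")

    if not ann.has_start_codon:
        reasons.append("no start codon upstream of the V domain")

    return (not reasons), reasons


def trim_to_imgt(asv_nt: str, ann: VDomainAnnotation) -> str:
    """Extract exactly the codons encoding the IMGT span."""
    start = ann.frame + 3 * ann.v_start
    end = ann.frame + 3 * (ann.v_end + 1)
    trimmed = asv_nt[start:end]
    if translate(trimmed) != ann.v_aa:
        raise AnnotationError("trimmed nucleotides do not encode the IMGT residues")
    return trimmed


def annotate_sequence(asv_nt: str, chain: str) -> VDomainAnnotation:
    """Full annotation of one ASV: frame, numbering, regions, validity, trim.

    ``chain`` may be a chain class (heavy/kappa/lambda) or a locus
    (heavy/light).  Anchor failures return an invalid annotation carrying the
    failure reason rather than raising, so pipeline counters can account for
    every sequence.
    """
    locus = chain_locus(chain) if chain in ("heavy", "kappa", "lambda") else chain
    try:
        frame, aa_full = find_reading_frame(asv_nt, locus)
        imgt_map = assign_imgt_numbering(aa_full, locus)
    except AnnotationError as exc:
        return VDomainAnnotation(
            chain=locus, frame=0, aa_full=translate(asv_nt), imgt_map=[],
            regions={name: "" for name in REGION_ORDER}, trimmed_nt="",
            v_start=0, v_end=0, has_start_codon=False,
            valid=False, reasons=[str(exc)],
        )
    a = _locate_anchors(aa_full, locus)
    fr1_start = max(0, a["c23"] - 22)
    last = 127 if locus == "light" else 128
    fr4_end = min(a["j118"] + (last - 118), len(aa_full) - 1)
    ann = VDomainAnnotation(
        chain=locus, frame=frame, aa_full=aa_full, imgt_map=imgt_map,
        regions=segment_regions(imgt_map), trimmed_nt="",
        v_start=fr1_start, v_end=fr4_end,
        has_start_codon=aa_full.rfind("M", 0, fr1_start) >= 0,
    )
    ann.trimmed_nt = trim_to_imgt(asv_nt, ann)
    ann.valid, ann.reasons = validate_domain(ann)
    return ann


def group_identical(entries: list[dict], on: str = "nt") -> list[dict]:
    """Additively merge annotated ASV entries with identical trimmed sequences.

    ``entries`` are dicts carrying at least ``trimmed_nt``, ``count`` and a
    shared ``reads_per_primer_well`` denominator; counts of merged entries are
    summed and fractions recomputed.  ``on="aa"`` groups at the protein level.
    """
    merged: dict[str, dict] = {}
    for e in entries:
        key = e["trimmed_nt"] if on == "nt" else translate(e["trimmed_nt"])
        if key in merged:
            merged[key]["count"] += e["count"]
        else:
            merged[key] = dict(e)
    out = list(merged.values())
    for e in out:
        denom = e.get("reads_per_primer_well", 0)
        e["fraction"] = e["count"] / denom if denom else 0.0
    return sorted(out, key=lambda e: (-e["count"], e["trimmed_nt"]))
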