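"""Gibson-Assembly gene-fragment design for R-mAbs and scFvs.

R-mAb V fragments are the curated IMGT-span nucleotides (light 1-127, heavy
1-128) flanked by fixed 50 bp homology overhangs into the expression-plasmid
backbone and joining fragment.  scFv fragments encode
leader - V_H - linker - V_L (orientation swappable) followed by HA, sortase
and 6xHis tags and a stop, flanked by vector homology arms; leader, linker
and tags are reverse-translated with a fixed one-codon-per-residue table so
designs are deterministic.  Inserts are screened for internal NotI/AscI/
BssHII sites, which would interfere with downstream subclass switching.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .config import AssayConfig
from .seqs import reverse_translate, translate

# 50 bp homology overhangs into the IgG2a expression plasmid backbone /
# joining fragment used for four-piece R-mAb assembly.
VL_OVERHANG_5 = "AGACCCAGGTACTCATGTCCCTGCTGCTCTGCATGTCTGGTGCGGCCGCA"
VL_OVERHANG_3 = "CGGGCTGATGCTGCACCAACTGTATCCATCTTCCCACCATCCAGTGAGCA"
VH_OVERHANG_5 = "CTGTTCTGCTAGTGGTGCTGCTATTGTTCACGAGTCCAGCCTCAAGCAGT"
VH_OVERHANG_3 = "GCGCGCCCAACAGCCCCATCGGTCTATCCACTGGCCCCTGTGTGTGGAGA"

RESTRICTION_SITES = {
    "NotI": "GCGGCCGC",
    "AscI": "GGCGCGCC",
    "BssHII": "GCGCGC",
}


@dataclass
class FragmentDesign:
    kind: str                       # rmab_vl | rmab_vh | scfv
    insert_nt: str                  # the V payload (without overhangs)
    full_nt: str                    # overhang + payload + overhang
    features: list[tuple[str, int, int]] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    def feature_seq(self, name: str) -> str:
        for n, s, e in self.features:
            if n == name:
                return self.full_nt[s:e]
        raise KeyError(name)


def _site_warnings(insert: str, label: str) -> list[str]:
    out = []
    for enzyme, motif in RESTRICTION_SITES.items():
        pos = insert.find(motif)
        if pos >= 0:
            out.append(f"internal {enzyme} site in {label} at {pos}")
    return out


def design_rmab_fragments(vl_nt: str, vh_nt: str) -> tuple[FragmentDesign, FragmentDesign]:
    """V_L and V_H gene fragments with their 50 bp Gibson overhangs."""
    for name, nt in (("vl_nt", vl_nt), ("vh_nt", vh_nt)):
        if not nt or len(nt) % 3:
            raise ValueError(f"{name} length must be a positive multiple of 3")

    def _one(kind: str, nt: str, oh5: str, oh3: str) -> FragmentDesign:
        full = oh5 + nt + oh3
        return FragmentDesign(
            kind=kind, insert_nt=nt, full_nt=full,
            features=[("overhang_5", 0, len(oh5)),
                      ("v_region", len(oh5), len(oh5) + len(nt)),
                      ("overhang_3", len(oh5) + len(nt), len(full))],
            warnings=_site_warnings(nt, kind),
        )

    return (_one("rmab_vl", vl_nt, VL_OVERHANG_5, VL_OVERHANG_3),
            _one("rmab_vh", vh_nt, VH_OVERHANG_5, VH_OVERHANG_3))


def design_scfv_fragment(
    vh_nt: str, vl_nt: str, orientation: str = "VH-linker-VL",
    config: AssayConfig | None = None,
) -> FragmentDesign:
    """scFv insert: leader - V - linker - V - HA - sortase - 6xHis - stop.

    The default orientation places V_H first; ``"VL-linker-VH"`` swaps the
    two domains (the fallback design used when the default fails to yield a
    functional scFv).
    """
    config = config or AssayConfig()
    if config.scfv_vector_overhangs is None:
        raise ValueError("scFv vector overhangs missing from config")
    if orientation not in ("VH-linker-VL", "VL-linker-VH"):
        raise ValueError(f"unknown orientation {orientation!r}")
    for name, nt in (("vh_nt", vh_nt), ("vl_nt", vl_nt)):
        if not nt or len(nt) % 3:
            raise ValueError(f"{name} length must be a positive multiple of 3")

    rt = lambda aa: reverse_translate(aa, config.codon_table)
    first, second = ((vh_nt, vl_nt) if orientation == "VH-linker-VL"
                     else (vl_nt, vh_nt))
    first_name, second_name = (("VH", "VL") if orientation == "VH-linker-VL"
                               else ("VL", "VH"))
    parts = [
        ("leader", rt(config.scfv_leader_aa)),
        (first_name, first),
        ("linker", rt(config.scfv_linker_aa)),
        (second_name, second),
    ]
    for tag, aa in config.tags_aa.items():
        parts.append((tag, rt(aa)))
    parts.append(("stop", rt("*")))

    oh5, oh3 = config.scfv_vector_overhangs
    payload = "".join(nt for _, nt in parts)
    full = oh5 + payload + oh3
    features = [("overhang_5", 0, len(oh5))]
    pos = len(oh5)
    for name, nt in parts:
        features.append((name, pos, pos + len(nt)))
        pos += len(nt)
    features.append(("overhang_3", pos, len(full)))

    design = FragmentDesign(
        kind="scfv", insert_nt=payload, full_nt=full, features=features,
        warnings=_site_warnings(vh_nt, "vh_nt") + _site_warnings(vl_nt, "vl_nt"),
    )
    aa = translate(payload)
    expected = (config.scfv_leader_aa + translate(first)
                + config.scfv_linker_aa + translate(second)
                + "".join(config.tags_aa.values()) + "*")
    if aa != expected:
        raise RuntimeError("scFv payload translation mismatch")  # pragma: no cover
    return design


@dataclass
class SwitchVerdict:
    ok: bool
    fragment_length: int | None
    messages: list[str] = field(default_factory=list)


def subclass_switch_check(plasmid_map: dict) -> SwitchVerdict:
    """Check a plasmid feature map supports NotI/BssHII subclass switching.

    ``plasmid_map`` carries ``sites`` (enzyme -> list of positions) and
    ``cassette`` ((start, end) of the V_L - joining fragment - V_H region).
    The switch requires exactly one NotI and one BssHII site, flanking the
    cassette; the verdict reports the excised fragment length.
    """
    sites = plasmid_map.get("sites", {})
    start, end = plasmid_map.get("cassette", (None, None))
    msgs = []
    for enzyme in ("NotI", "BssHII"):
        positions = sites.get(enzyme, [])
        if len(positions) == 0:
            msgs.append(f"no {enzyme} site")
        elif len(positions) > 1:
            msgs.append(f"multiple {enzyme} sites at {positions}")
    if msgs or start is None:
        if start is None:
            msgs.append("no cassette coordinates")
        return SwitchVerdict(False, None, msgs)
    noti, bssh = sites["NotI"][0], sites["BssHII"][0]
    lo, hi = sorted((noti, bssh))
    if not (lo <= start and end <= hi):
        msgs.append(f"sites at {lo},{hi} do not flank cassette {start}-{end}")
        return SwitchVerdict(False, None, msgs)
    return SwitchVerdict(True, hi - lo, [])
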