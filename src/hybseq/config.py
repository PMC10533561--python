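"""Assay configuration: adapter/primer sequences, thresholds, design constants.

The amplicons this pipeline processes have the layout

    inline barcode (5-8 nt) | TSO | 5'UTR | leader | V region | constant stub

where the constant stub ends in the reverse complement of a chain-specific
nested primer (the R2 sequencing primer landing site).  The TSO, UTR, leader,
constant stubs and nested primers are assay reagents: they are supplied by
the config, with synthetic defaults bundled here so the whole pipeline can be
exercised without any proprietary oligo sequences.  Every default is
overridable from YAML.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .seqs import CODON_TABLE, reverse_translate, revcomp

# chain classes used throughout
HEAVY = "heavy"
KAPPA = "kappa"
LAMBDA = "lambda"
CHAINS = (HEAVY, KAPPA, LAMBDA)


def chain_locus(chain: str) -> str:
    """Collapse kappa/lambda to the generic light-chain locus."""
    if chain == HEAVY:
        return "heavy"
    if chain in (KAPPA, LAMBDA, "light"):
        return "light"
    raise ValueError(f"unknown chain class {chain!r}")


# ---------------------------------------------------------------------------
# Synthetic assay oligos (defaults; real runs supply their own via YAML).
# ---------------------------------------------------------------------------

DEFAULT_TSO = "TAGCAGTGGTATCAACGCAGAGTACATGGG"  # 30 nt, G-tailed

DEFAULT_PRIMERS = {
    HEAVY: "CAGTGGATAGACCGATGGGGCT",
    KAPPA: "GATGGATACAGTTGGTGCAGCA",
    LAMBDA: "ACCTAGGACAGTCAGTTTGGTT",
}

DEFAULT_UTR = "GCTCTGACGCTCAGGAATTCAC"  # 22 nt of 5'UTR padding

#: 19-residue signal peptide preceding the mature V domain.
DEFAULT_LEADER_AA = "MDWTWRILFLVAAATGAHS"

#: Constant-region stub cores (between FR4 and the nested-primer landing site).
#: Chosen free of Phe/Trp so no spurious J-like [FW]GxG motif can appear
#: downstream of the genuine FR4 anchor.
_LIGHT_STUB_CORE_AA = "RADAAPTVSIPPPSSEQLTSG"  # 21 aa -> 63 nt
_HEAVY_STUB_CORE_AA = "AKTTPPSVYPLA"            # 12 aa -> 36 nt

DEFAULT_STUB_CORES = {
    "light": reverse_translate(_LIGHT_STUB_CORE_AA),
    "heavy": reverse_translate(_HEAVY_STUB_CORE_AA) + "CC",
}

# ---------------------------------------------------------------------------
# Synthetic mouse-like consensus V scaffolds (NOT real germlines).
# Framework residues are fixed; CDR residues are randomized per clone by the
# simulator.  Anchor residues: Cys at IMGT 23, Trp at 41, Cys at 104 and the
# J [FW]GxG motif at 118 are present by construction.
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class VScaffold:
    locus: str            # "light" | "heavy"
    fr1: str              # IMGT 1-26 (Cys at 23)
    fr2: str              # IMGT 39-55 (Trp at 41)
    fr3: str              # IMGT 66-104 (Cys at 104)
    fr4: str              # IMGT 118-127 (light) / 118-128 (heavy)
    cdr_lengths: tuple[int, int, int]

    def assemble(self, cdr1: str, cdr2: str, cdr3: str) -> str:
        return self.fr1 + cdr1 + self.fr2 + cdr2 + self.fr3 + cdr3 + self.fr4


LIGHT_SCAFFOLD = VScaffold(
    locus="light",
    fr1="DIQMTQSPSSLSASVGDRVTITCRAS",
    fr2="LNWYQQKPGKAPKLLIY",
    fr3="NRATGIPGVPSRFSGSGSGTDFTLTISSLQPEDIATYYC",
    fr4="FGQGTKLEIK",
    cdr_lengths=(6, 3, 9),
)

HEAVY_SCAFFOLD = VScaffold(
    locus="heavy",
    fr1="EVQLVESGGGSLVQPGGSLRLSCAAS",
    fr2="LGWVRQAPGKGLEAVAH",
    fr3="YADSVKGRFRFTISRDNSKNTLYLQMNSLRAEDTAVYYC",
    fr4="WGQGTLVTVSS",
    cdr_lengths=(8, 8, 13),
)

#: Residues the simulator may draw for CDR positions.  Cys/Trp/Phe/Met are
#: excluded so randomized loops can never fake an anchor, a J motif or a
#: start codon, and stop codons cannot arise at the protein level at all.
CDR_ALPHABET = "ADEGHIKLNPQRSTVY"


def _default_aberrant_interior() -> str:
    """Synthetic stand-in for the Sp2/0 (MOPC-21-derived) aberrant kappa transcript.

    A kappa-like V region carrying a 4 nt deletion in FR3 — frameshifted and
    therefore non-productive, like the real aberrant transcript every Sp2/0
    fusion hybridoma expresses.  Returned as the merged-read interior
    (UTR + leader + V + stub core), the coordinate frame in which the
    denoiser sees ASVs.
    """
    v_aa = LIGHT_SCAFFOLD.assemble("QDVSTA", "AAS", "QQHYSTPRT")
    v_nt = reverse_translate(DEFAULT_LEADER_AA) + reverse_translate(v_aa)
    # 4 nt deletion inside FR3 (well downstream of the leader)
    cut = len(reverse_translate(DEFAULT_LEADER_AA)) + 3 * (26 + 6 + 17 + 3 + 12)
    v_nt = v_nt[:cut] + v_nt[cut + 4:]
    return DEFAULT_UTR + v_nt + DEFAULT_STUB_CORES["light"]


# ---------------------------------------------------------------------------
# Fragment-design defaults (scFv leader/linker per the published constructs;
# tag protein sequences are canonical motifs, config-overridable).
# ---------------------------------------------------------------------------

SCFV_LEADER_AA = "MGWSCIILFLVATATGVHS"
SCFV_LINKER_AA = "GGGGSGGGGSGGGGSGGGS"
DEFAULT_TAGS_AA = {"HA": "YPYDVPDYA", "sortase": "LPETGG", "His6": "HHHHHH"}

#: Synthetic pcDNA-style homology arms for scFv Gibson Assembly (test defaults;
#: real vector overhangs must be supplied in the config).
DEFAULT_SCFV_OVERHANGS = (
    "CTGGCTAGCGTTTAAACTTAAGCTTGGTACCGAGCTCGGATCCACTAGTC",
    "CTGATCAGCCTCGACTGTGCCTTCTAGTTGCCAGCCATCTGTTGTTTGCC",
)


@dataclass
class AssayConfig:
    """Everything the pipeline needs to know about the wet-lab assay."""

    tso: str = DEFAULT_TSO
    primers: dict[str, str] = field(default_factory=lambda: dict(DEFAULT_PRIMERS))
    utr: str = DEFAULT_UTR
    leader_aa: str = DEFAULT_LEADER_AA
    stub_cores: dict[str, str] = field(default_factory=lambda: dict(DEFAULT_STUB_CORES))

    # read processing
    barcode_max_mismatch: int = 0
    primer_max_mismatch: int = 1
    tso_search_window: int = 20
    qmin: int = 10                    # 3' quality-trim threshold (Phred)
    min_overlap: int = 20
    overlap_mismatch_cap: float = 0.10
    min_merged_len: int = 385

    # denoising
    denoise_alpha: float = 2.0
    denoise_max_d: int = 4
    aberrant_ref: str = field(default_factory=_default_aberrant_interior)
    aberrant_min_identity: float = 0.97
    aberrant_min_coverage: float = 0.90
    min_fraction: float = 0.10

    # scoring
    min_score: float = 3.0
    totalseqs_mode: str = "samples"   # "samples" | "sequences"
    include_focal_in_replicates: bool = False
    group_on: str = "nt"              # "nt" | "aa" identical-sequence grouping
    consistency_min_frac: float = 0.5  # additional-chain: present in >= this frac of samples

    # design
    scfv_leader_aa: str = SCFV_LEADER_AA
    scfv_linker_aa: str = SCFV_LINKER_AA
    tags_aa: dict[str, str] = field(default_factory=lambda: dict(DEFAULT_TAGS_AA))
    scfv_vector_overhangs: tuple[str, str] | None = DEFAULT_SCFV_OVERHANGS
    codon_table: dict[str, str] = field(default_factory=lambda: dict(CODON_TABLE))

    def leader_nt(self) -> str:
        return reverse_translate(self.leader_aa, self.codon_table)

    def primer(self, chain: str) -> str:
        try:
            return self.primers[chain]
        except KeyError:
            raise KeyError(f"no nested primer configured for chain {chain!r}") from None

    def stub(self, chain: str) -> str:
        """Constant-region stub = core + reverse-complemented nested primer."""
        return self.stub_cores[chain_locus(chain)] + revcomp(self.primer(chain))

    # -- (de)serialisation ---------------------------------------------------

    def to_yaml(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        if d.get("scfv_vector_overhangs") is not None:
            d["scfv_vector_overhangs"] = list(d["scfv_vector_overhangs"])
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AssayConfig":
        d = yaml.safe_load(Path(path).read_text()) or {}
        if d.get("scfv_vector_overhangs") is not None:
            d["scfv_vector_overhangs"] = tuple(d["scfv_vector_overhangs"])
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)
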