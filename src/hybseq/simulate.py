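"""Synthetic plate simulator: paired-end amplicon reads with known ground truth.

Emulates the assay this pipeline processes: each well holds PCR product from
one hybridoma sample, amplified from the TSO end to a chain-specific nested
primer in the constant region, carrying a well-identifying inline barcode.
Light-chain pools are contaminated with the aberrant Sp2/0 kappa transcript at
a configurable fraction, as in every real Sp2/0-fusion hybridoma.  Reads are
300 bp from both ends of the 500-550 bp amplicon, with an independent per-base
substitution error model per mate (substitutions only by default; an optional
indel rate exists for robustness testing).

Clones are built on bundled synthetic consensus V scaffolds (not real
germlines) with per-clone randomized CDRs, so every simulated V region passes
the annotation validity filters by construction.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .annotate import annotate_sequence
from .config import (
    CDR_ALPHABET, HEAVY, HEAVY_SCAFFOLD, KAPPA, LIGHT_SCAFFOLD, AssayConfig,
    chain_locus,
)
from .seqs import reverse_translate, revcomp

READ_LEN = 300
_BASES = np.frombuffer(b"ACGT", dtype="S1")


@dataclass
class TruthClone:
    """Ground-truth hybridoma: one light and one heavy coding region.

    ``vl_nt``/``vh_nt`` span leader through FR4 (the amplicon's coding
    interior); ``extra_chains`` lists additional productive transcripts as
    (chain class, coding nt, abundance fraction), the fractions summing with
    the main chain to 1 within each chain class.
    """

    mab_id: str
    vl_nt: str
    vh_nt: str
    vl_trimmed: str = ""   # IMGT-span nucleotides (truth for the pipeline)
    vh_trimmed: str = ""
    light_chain: str = KAPPA
    extra_chains: list[tuple[str, str, float]] = field(default_factory=list)

    def coding(self, chain: str) -> str:
        return self.vh_nt if chain == HEAVY else self.vl_nt


@dataclass
class WellSpec:
    barcode: str
    clone: TruthClone
    mab_id: str      # sample-level ID (project/parent.subclone), may differ from clone.mab_id
    role: str = "primary"  # free-text replicate role, recorded in the truth table


@dataclass
class PlateSpec:
    wells: dict[str, WellSpec]
    error_rate: float = 0.001
    aberrant_fraction: float = 0.3
    depth: int = 200
    seed: int = 0
    plate: str = "P1"
    indel_rate: float = 0.0

    def __post_init__(self):
        if self.depth <= 0:
            raise ValueError("depth must be > 0")
        if not (0 <= self.aberrant_fraction < 1):
            raise ValueError("aberrant_fraction must be in [0, 1)")
        barcodes = [w.barcode for w in self.wells.values()]
        if len(set(barcodes)) != len(barcodes):
            raise ValueError("barcodes must be unique within a plate")
        for b in barcodes:
            if not 5 <= len(b) <= 8:
                raise ValueError(f"barcode {b!r} outside 5-8 nt")


# ---------------------------------------------------------------------------
# clone construction
# ---------------------------------------------------------------------------


def _random_cdrs(scaffold, rng: np.random.Generator) -> list[str]:
    return [
        "".join(rng.choice(list(CDR_ALPHABET), size=n))
        for n in scaffold.cdr_lengths
    ]


def _build_chain(scaffold, rng: np.random.Generator, config: AssayConfig) -> str:
    v_aa = scaffold.assemble(*_random_cdrs(scaffold, rng))
    return config.leader_nt() + reverse_translate(v_aa, config.codon_table)


def make_reference_set(
    n_clones: int, seed: int, config: AssayConfig | None = None,
    project: str = "SIM",
) -> list[TruthClone]:
    """Generate ``n_clones`` ground-truth clones; deterministic for a fixed seed.

    Every generated V region is checked against the annotation validity
    filters before being returned.
    """
    if n_clones < 1:
        raise ValueError("n_clones must be >= 1")
    config = config or AssayConfig()
    rng = np.random.default_rng(seed)
    clones = []
    for i in range(n_clones):
        vl = _build_chain(LIGHT_SCAFFOLD, rng, config)
        vh = _build_chain(HEAVY_SCAFFOLD, rng, config)
        ann_l = annotate_sequence(config.utr + vl + config.stub_cores["light"], KAPPA)
        ann_h = annotate_sequence(config.utr + vh + config.stub_cores["heavy"], HEAVY)
        if not (ann_l.valid and ann_h.valid):  # pragma: no cover - by construction
            raise RuntimeError(f"generated clone {i} failed validation")
        clones.append(TruthClone(
            mab_id=f"{project}/{i + 1}", vl_nt=vl, vh_nt=vh,
            vl_trimmed=ann_l.trimmed_nt, vh_trimmed=ann_h.trimmed_nt,
        ))
    return clones


def add_extra_light_chain(
    clone: TruthClone, seed: int, fraction: float = 0.4,
    config: AssayConfig | None = None,
) -> TruthClone:
    """Give a clone a second productive light chain at the given abundance."""
    if not 0 < fraction < 1:
        raise ValueError("fraction must be in (0, 1)")
    config = config or AssayConfig()
    rng = np.random.default_rng(seed)
    extra = _build_chain(LIGHT_SCAFFOLD, rng, config)
    clone.extra_chains.append((clone.light_chain, extra, fraction))
    return clone


# ---------------------------------------------------------------------------
# amplicon and read construction
# ---------------------------------------------------------------------------


def build_amplicon(clone_chain_nt: str, barcode: str, chain: str,
                   config: AssayConfig) -> str:
    """Assemble the sequenced molecule for one transcript.

    barcode + TSO + 5'UTR + coding region (leader..FR4) + constant stub, the
    stub terminating in the reverse-complemented nested primer.
    """
    if not 5 <= len(barcode) <= 8:
        raise ValueError("barcode must be 5-8 nt")
    return barcode + config.tso + config.utr + clone_chain_nt + config.stub(chain)


def interior_of(coding_nt: str, chain: str, config: AssayConfig) -> str:
    """The merged-read interior the pipeline should recover (no barcode/TSO/primer)."""
    return config.utr + coding_nt + config.stub_cores[chain_locus(chain)]


def _mutate(seq: str, error_rate: float, indel_rate: float,
            rng: np.random.Generator) -> str:
    if error_rate <= 0 and indel_rate <= 0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype="S1").copy()
    hits = np.nonzero(rng.random(arr.size) < error_rate)[0]
    if hits.size:
        # substitute with one of the three other bases
        subs = _BASES[rng.integers(0, 4, size=hits.size)]
        clash = subs == arr[hits]
        while clash.any():
            subs[clash] = _BASES[rng.integers(0, 4, size=int(clash.sum()))]
            clash = subs == arr[hits]
        arr[hits] = subs
    out = arr.tobytes().decode()
    if indel_rate > 0:
        chars = list(out)
        i = 0
        while i < len(chars):
            if rng.random() < indel_rate:
                if rng.random() < 0.5:
                    chars.insert(i, "ACGT"[rng.integers(0, 4)])
                    i += 1
                else:
                    chars.pop(i)
                    continue
            i += 1
        out = "".join(chars)
    return out


def _qualities(n: int, error_rate: float, rng: np.random.Generator) -> np.ndarray:
    """Per-base Phred scores: -10 log10(error_rate) plus seeded jitter, clipped."""
    base = 40.0 if error_rate <= 0 else -10.0 * np.log10(error_rate)
    q = np.rint(base + rng.integers(-3, 4, size=n)).astype(int)
    return np.clip(q, 2, 40)


def _fastq_record(name: str, seq: str, qual: np.ndarray) -> str:
    qstr = "".join(chr(q + 33) for q in qual)
    return f"@{name}\n{seq}\n+\n{qstr}\n"


def _well_templates(well: WellSpec, spec: PlateSpec, config: AssayConfig,
                    rng: np.random.Generator):
    """Yield (chain, template amplicon, n_reads, truth_label) for one well."""
    clone = well.clone
    light = clone.light_chain
    extra_light = [(c, nt, f) for c, nt, f in clone.extra_chains
                   if chain_locus(c) == "light"]
    extra_heavy = [(c, nt, f) for c, nt, f in clone.extra_chains
                   if chain_locus(c) == "heavy"]

    # light chain pool: aberrant + main + extras
    n_ab = int(rng.binomial(spec.depth, spec.aberrant_fraction))
    n_rest = spec.depth - n_ab
    fracs = [1.0 - sum(f for _, _, f in extra_light)] + [f for _, _, f in extra_light]
    counts = rng.multinomial(n_rest, fracs)
    if n_ab:
        ab_amplicon = (well.barcode + config.tso + config.aberrant_ref
                       + revcomp(config.primer(light)))
        yield light, ab_amplicon, n_ab, "aberrant"
    yield light, build_amplicon(clone.vl_nt, well.barcode, light, config), \
        int(counts[0]), "main"
    for (c, nt, _), n in zip(extra_light, counts[1:]):
        yield c, build_amplicon(nt, well.barcode, c, config), int(n), "extra"

    # heavy chain pool
    fracs = [1.0 - sum(f for _, _, f in extra_heavy)] + [f for _, _, f in extra_heavy]
    counts = rng.multinomial(spec.depth, fracs)
    yield HEAVY, build_amplicon(clone.vh_nt, well.barcode, HEAVY, config), \
        int(counts[0]), "main"
    for (c, nt, _), n in zip(extra_heavy, counts[1:]):
        yield c, build_amplicon(nt, well.barcode, c, config), int(n), "extra"


def simulate_plate(spec: PlateSpec, out_prefix: str | Path,
                   config: AssayConfig | None = None) -> dict[str, Path]:
    """Write R1/R2 FASTQ (gzip), a truth table TSV and the spec as YAML.

    R1 reads run from the barcode/TSO end, R2 from the constant-region end
    (reverse complement); both are exactly 300 bp.  Errors are drawn
    independently per mate.  Returns the paths written.
    """
    config = config or AssayConfig()
    out_prefix = Path(out_prefix)
    out_prefix.parent.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(spec.seed)

    r1_path = out_prefix.with_name(out_prefix.name + "_R1.fastq.gz")
    r2_path = out_prefix.with_name(out_prefix.name + "_R2.fastq.gz")
    truth_path = out_prefix.with_name(out_prefix.name + "_truth.tsv")
    spec_path = out_prefix.with_name(out_prefix.name + "_spec.yaml")

    truth_rows = []
    idx = 0
    with gzip.open(r1_path, "wt") as f1, gzip.open(r2_path, "wt") as f2:
        for well_label, well in spec.wells.items():
            for chain, amplicon, n_reads, label in _well_templates(
                    well, spec, config, rng):
                if label != "aberrant" and n_reads > 0:
                    coding = amplicon[len(well.barcode) + len(config.tso)
                                      + len(config.utr):
                                      len(amplicon) - len(config.stub(chain))]
                    ann = annotate_sequence(
                        interior_of(coding, chain, config), chain)
                    truth_rows.append({
                        "plate": spec.plate, "well": well_label,
                        "mab_id": well.mab_id, "chain": chain,
                        "role": well.role, "kind": label,
                        "sequence": ann.trimmed_nt,
                        "fraction": n_reads / spec.depth,
                        "n_reads": n_reads,
                    })
                rc = revcomp(amplicon)
                for _ in range(n_reads):
                    r1 = _mutate(amplicon[:READ_LEN], spec.error_rate,
                                 spec.indel_rate, rng)
                    r2 = _mutate(rc[:READ_LEN], spec.error_rate,
                                 spec.indel_rate, rng)
                    q1 = _qualities(len(r1), spec.error_rate, rng)
                    q2 = _qualities(len(r2), spec.error_rate, rng)
                    name = f"{spec.plate}:{well_label}:{idx}"
                    f1.write(_fastq_record(name + "/1", r1, q1))
                    f2.write(_fastq_record(name + "/2", r2, q2))
                    idx += 1

    pd.DataFrame(truth_rows).to_csv(truth_path, sep="\t", index=False)
    spec_path.write_text(yaml.safe_dump({
        "plate": spec.plate, "seed": spec.seed, "depth": spec.depth,
        "error_rate": spec.error_rate, "indel_rate": spec.indel_rate,
        "aberrant_fraction": spec.aberrant_fraction,
        "wells": {w: {"barcode": s.barcode, "mab_id": s.mab_id, "role": s.role}
                  for w, s in spec.wells.items()},
    }, sort_keys=False))
    return {"r1": r1_path, "r2": r2_path, "truth": truth_path, "spec": spec_path}


# ---------------------------------------------------------------------------
# plate layout helpers
# ---------------------------------------------------------------------------


def make_barcodes(n: int, seed: int) -> list[str]:
    """n unique, prefix-free inline barcodes with lengths cycling 5-8 nt."""
    rng = np.random.default_rng(seed)
    out: list[str] = []
    while len(out) < n:
        length = 5 + len(out) % 4
        bc = "".join(rng.choice(list("ACGT"), size=length))
        if any(bc.startswith(o) or o.startswith(bc) for o in out):
            continue
        out.append(bc)
    return out


def design_plate(
    clones: list[TruthClone], seed: int, *,
    n_subclones: int = 2, n_technical: int = 1,
    error_rate: float = 0.001, aberrant_fraction: float = 0.3,
    depth: int = 200, plate: str = "P1",
) -> PlateSpec:
    """Lay clones out as replicate wells following project/parent.subclone naming.

    Each clone (a parent hybridoma) gets ``n_subclones`` biological-replicate
    wells; the first subclone additionally gets ``n_technical`` extra wells
    (technical replicates of the same subclone).
    """
    wells: dict[str, WellSpec] = {}
    samples_per_clone = n_subclones + n_technical
    barcodes = make_barcodes(len(clones) * samples_per_clone, seed)
    i = 0
    for clone in clones:
        for sub in range(1, n_subclones + 1):
            reps = 1 + (n_technical if sub == 1 else 0)
            for t in range(reps):
                row, col = divmod(i, 12)
                label = f"{chr(ord('A') + row)}{col + 1}"
                role = "technical" if t > 0 else "biological"
                wells[label] = WellSpec(
                    barcode=barcodes[i], clone=clone,
                    mab_id=f"{clone.mab_id}.{sub}", role=role)
                i += 1
    return PlateSpec(wells=wells, error_rate=error_rate,
                     aberrant_fraction=aberrant_fraction, depth=depth,
                     seed=seed, plate=plate)


def sample_sheet(spec: PlateSpec) -> pd.DataFrame:
    """Derive the demultiplexing sample sheet for a simulated plate."""
    return pd.DataFrame([
        {"plate": spec.plate, "well": w, "barcode": s.barcode, "mab_id": s.mab_id}
        for w, s in spec.wells.items()
    ])
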