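"""Pipeline orchestration, flat-file database export and k-mer sequence search.

``run_pipeline`` chains read processing -> denoising -> annotation -> scoring
and writes the curated sequence database (TSV), the cohort census and a
per-stage QC counter file.  ``kmer_search`` is a seed-and-extend similarity
query over the database — a deliberately simple stand-in for a full
BLAT-style aligner (ungapped extension, no translated search).
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from . import annotate, denoise, readproc, score
from .config import AssayConfig, chain_locus

DB_COLUMNS = [
    "mab_id", "plate", "well", "chain", "trimmed_nt", "aa",
    "fr1", "cdr1", "fr2", "cdr2", "fr3", "cdr3", "fr4",
    "read_per_sequence", "reads_per_primer_well",
    "asv_score", "br", "tr", "total_seqs", "match_score", "total_score",
]


def run_pipeline(
    config: AssayConfig, r1: str | Path, r2: str | Path,
    sheet: readproc.SampleSheet, out_dir: str | Path,
    plate: str = "P1",
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Run the full pipeline on one plate; returns (database, census, counts).

    Writes ``db.tsv``, ``census.tsv`` and ``qc_counts.json`` under
    ``out_dir``.  Deterministic: identical inputs give byte-identical
    outputs.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    merged, counts = readproc.process_reads(r1, r2, sheet, config)

    entries: list[score.ScoredEntry] = []
    ann_counts = {"asvs": 0, "aberrant_removed": 0, "below_fraction": 0,
                  "invalid_annotation": 0, "curated": 0}
    for (well, chain), reads in sorted(merged.items()):
        derep = denoise.dereplicate(reads)
        asvs = denoise.denoise_asvs(derep, well, chain,
                                    config.denoise_alpha, config.denoise_max_d)
        ann_counts["asvs"] += len(asvs)
        denoise.filter_aberrant(asvs, config.aberrant_ref,
                                config.aberrant_min_identity,
                                config.aberrant_min_coverage)
        ann_counts["aberrant_removed"] += sum(a.aberrant for a in asvs)
        retained = denoise.fraction_filter(asvs, config.min_fraction)
        ann_counts["below_fraction"] += (
            sum(not a.aberrant for a in asvs) - len(retained))
        denom = sum(a.count for a in asvs if not a.aberrant)

        annotated = []
        for asv in retained:
            ann = annotate.annotate_sequence(asv.sequence, chain)
            if not ann.valid:
                ann_counts["invalid_annotation"] += 1
                continue
            annotated.append({
                "trimmed_nt": ann.trimmed_nt, "count": asv.count,
                "reads_per_primer_well": denom, "annotation": ann,
            })
        for entry in annotate.group_identical(annotated, config.group_on):
            ann_counts["curated"] += 1
            e = score.ScoredEntry(
                mab_id=score.parse_mab_id(sheet.mab_of_well[well]),
                plate=plate, well=well, chain=chain_locus(chain),
                trimmed_nt=entry["trimmed_nt"],
                read_per_sequence=entry["count"],
                reads_per_primer_well=entry["reads_per_primer_well"],
            )
            e.annotation = entry["annotation"]  # carried for export only
            entries.append(e)

    score.score_cohort(entries, config.totalseqs_mode,
                       config.include_focal_in_replicates)
    retained_entries = score.quality_filter(entries, config.min_score)

    db = _to_database(retained_entries)
    census = _census_from_entries(retained_entries)
    counts = {**counts, **ann_counts,
              "scored": len(entries),
              "retained_after_score": len(retained_entries)}

    db.to_csv(out_dir / "db.tsv", sep="\t", index=False)
    census.to_csv(out_dir / "census.tsv", sep="\t", index=False)
    (out_dir / "qc_counts.json").write_text(json.dumps(counts, indent=2))
    return db, census, counts


def _to_database(entries: list[score.ScoredEntry]) -> pd.DataFrame:
    rows = []
    for e in entries:
        ann = getattr(e, "annotation", None)
        regions = ann.regions if ann else {}
        rows.append({
            "mab_id": str(e.mab_id), "plate": e.plate, "well": e.well,
            "chain": e.chain, "trimmed_nt": e.trimmed_nt,
            "aa": ann.v_aa if ann else "",
            **{r.lower(): regions.get(r, "") for r in annotate.REGION_ORDER},
            "read_per_sequence": e.read_per_sequence,
            "reads_per_primer_well": e.reads_per_primer_well,
            "asv_score": round(e.asv_score, 6), "br": e.br, "tr": e.tr,
            "total_seqs": e.total_seqs,
            "match_score": round(e.match_score, 6),
            "total_score": round(e.total_score, 6),
        })
    df = pd.DataFrame(rows, columns=DB_COLUMNS)
    return df.sort_values(["mab_id", "chain", "trimmed_nt"],
                          kind="stable").reset_index(drop=True)


def _census_from_entries(entries: list[score.ScoredEntry]) -> pd.DataFrame:
    parents = sorted({e.mab_id.parent_id for e in entries})
    rows = []
    for parent in parents:
        group = [e for e in entries if e.mab_id.parent_id == parent]
        rows.append({
            "mab_id": parent,
            "n_vl": score.chain_multiplicity(group, "light"),
            "n_vh": score.chain_multiplicity(group, "heavy"),
        })
    df = pd.DataFrame(rows, columns=["mab_id", "n_vl", "n_vh"])
    return score.summarize_cohort(df) if len(df) else pd.DataFrame(
        columns=["category", "count", "percent"])


# ---------------------------------------------------------------------------
# k-mer seeded similarity search
# ---------------------------------------------------------------------------

_NT_ALPHABET = set("ACGTN")


def kmer_search(
    query: str, db: pd.DataFrame, k: int | None = None,
    min_identity: float = 0.8,
) -> pd.DataFrame:
    """Rank database records by ungapped identity to a nt or aa query.

    Seeds shared k-mers, extends each seed's diagonal over the full mutual
    overlap and scores identity = matches / aligned span; hits are ranked by
    identity then span.  The query alphabet decides whether nucleotide
    (``trimmed_nt``) or protein (``aa``) records are searched.
    """
    query = query.strip().upper()
    if not query:
        raise ValueError("empty query")
    is_nt = set(query) <= _NT_ALPHABET
    column = "trimmed_nt" if is_nt else "aa"
    if k is None:
        k = 11 if is_nt else 4
    if k < (6 if is_nt else 3):
        raise ValueError("seed length too small")

    qmers: dict[str, list[int]] = {}
    for i in range(len(query) - k + 1):
        qmers.setdefault(query[i:i + k], []).append(i)

    hits = []
    for idx, target in db[column].items():
        target = str(target)
        diagonals = set()
        for j in range(len(target) - k + 1):
            for i in qmers.get(target[j:j + k], ()):
                diagonals.add(j - i)
        best = None
        for off in diagonals:
            qs, ts = max(0, -off), max(0, off)
            span = min(len(query) - qs, len(target) - ts)
            if span <= 0:
                continue
            matches = sum(query[qs + x] == target[ts + x] for x in range(span))
            ident = matches / span
            cand = (ident, span)
            if best is None or cand > best:
                best = cand
        if best and best[0] >= min_identity:
            hits.append({"index": idx, "identity": best[0], "span": best[1]})

    out = pd.DataFrame(hits, columns=["index", "identity", "span"])
    out = out.sort_values(["identity", "span"], ascending=False,
                          kind="stable").reset_index(drop=True)
    if len(out) and "mab_id" in db.columns:
        out["mab_id"] = [db.loc[i, "mab_id"] for i in out["index"]]
        out["chain"] = [db.loc[i, "chain"] for i in out["index"]]
    return out


def export_roundtrip(db: pd.DataFrame, path: str | Path) -> pd.DataFrame:
    """Write the database TSV and read it back (round-trip helper)."""
    db.to_csv(path, sep="\t", index=False)
    return pd.read_csv(path, sep="\t", keep_default_na=False)

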