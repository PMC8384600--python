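"""Readers and writers for the on-disk formats plus the shared sample model.

Tables are plain TSV; AS events use the SUPPA ioe dialect; pairwise genome
correspondences use the UCSC chain format (see :mod:`polyas.chain`).
Coordinates are 0-based half-open internally; GTF is converted on read/write.
Missing values in PSI matrices are encoded as ``NA``; TPM is never NA
(absence of a transcript in a library is 0).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

# ---------------------------------------------------------------------------
# Sample model

#: variety -> (species, ploidy, subgenomes present)
VARIETIES: dict[str, tuple[str, str, tuple[str, ...]]] = {
    "AC": ("Triticum aestivum AC Barrie", "hexaploid", ("A", "B", "D")),
    "CS": ("Triticum aestivum Chinese Spring", "hexaploid", ("A", "B", "D")),
    "CM": ("Triticum durum CDC Commander", "tetraploid", ("A", "B")),
    "ST": ("Triticum durum CDC Strong Field", "tetraploid", ("A", "B")),
    "DV": ("Triticum monococcum DV92", "diploid", ("A",)),
    "SP": ("Aegilops speltoides TA2780", "diploid", ("B",)),
    "TA": ("Aegilops tauschii TA101132", "diploid", ("D",)),
}

STAGES: tuple[str, ...] = tuple(f"E{i:02d}" for i in range(1, 11))
EMBRYO_STAGES: tuple[str, ...] = STAGES[:7]

#: diploid ancestor carrying each subgenome
SUBGENOME_ANCESTOR: dict[str, str] = {"A": "DV", "B": "SP", "D": "TA"}

EVENT_TYPES: tuple[str, ...] = ("A5", "A3", "RI", "SE", "MX", "AF", "AL")


def tissue_class(stage: str) -> str:
    """Map a stage/tissue code E01..E10 to its tissue class."""
    if stage not in STAGES:
        raise ValueError(f"unknown stage/tissue: {stage!r}")
    n = int(stage[1:])
    if n <= 3:
        return "embryo_early"
    if n <= 7:
        return "embryo_late"
    if n <= 9:
        return "endosperm"
    return "pericarp"


def make_sample_table(replicates: int = 2) -> pd.DataFrame:
    """Enumerate the full design: every variety x stage/tissue x replicate."""
    rows = []
    for variety, (species, ploidy, subg) in VARIETIES.items():
        for stage in STAGES:
            for rep in range(1, replicates + 1):
                rows.append(
                    {
                        "sample_id": f"{variety}_{stage}_r{rep}",
                        "variety": variety,
                        "species": species,
                        "ploidy": ploidy,
                        "subgenomes_present": ",".join(subg),
                        "stage_tissue": stage,
                        "tissue_class": tissue_class(stage),
                        "replicate": rep,
                    }
                )
    return pd.DataFrame(rows).set_index("sample_id")


_PLOIDY_SUBG_COUNT = {"diploid": 1, "tetraploid": 2, "hexaploid": 3}


def validate_samples(samples: pd.DataFrame) -> pd.DataFrame:
    """Check sample-metadata invariants; returns the validated frame."""
    required = {
        "variety", "species", "ploidy", "subgenomes_present",
        "stage_tissue", "tissue_class", "replicate",
    }
    missing = required - set(samples.columns)
    if missing:
        raise ValueError(f"sample table missing columns: {sorted(missing)}")
    for sid, row in samples.iterrows():
        if row["variety"] not in VARIETIES:
            raise ValueError(f"{sid}: unknown variety {row['variety']!r}")
        if tissue_class(row["stage_tissue"]) != row["tissue_class"]:
            raise ValueError(f"{sid}: tissue_class inconsistent with stage_tissue")
        subg = tuple(s for s in str(row["subgenomes_present"]).split(",") if s)
        if len(subg) != _PLOIDY_SUBG_COUNT[row["ploidy"]]:
            raise ValueError(f"{sid}: subgenomes_present inconsistent with ploidy")
        if int(row["replicate"]) < 1:
            raise ValueError(f"{sid}: replicate must be a positive integer")
    return samples


def write_samples(samples: pd.DataFrame, path: str | Path) -> None:
    samples.to_csv(path, sep="\t", index=True, index_label="sample_id")


def read_samples(path: str | Path) -> pd.DataFrame:
    samples = pd.read_csv(path, sep="\t", index_col="sample_id")
    return validate_samples(samples)


# ---------------------------------------------------------------------------
# Transcript quantification table

_QUANT_META_COLS = ["gene_id", "subgenome", "chrom", "start", "end", "strand"]


@dataclass
class TranscriptQuant:
    """Transcripts x samples TPM matrix plus per-transcript annotation.

    ``tpm`` is indexed by transcript_id with one column per sample_id;
    ``transcripts`` carries gene_id, subgenome and the genomic interval.
    """

    tpm: pd.DataFrame
    transcripts: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.tpm.index.equals(self.transcripts.index):
            raise ValueError("tpm and transcript annotation must share an index")
        if (self.tpm.values < 0).any():
            raise ValueError("negative TPM values are not allowed")
        if self.transcripts["gene_id"].isna().any():
            raise ValueError("every transcript must map to exactly one gene_id")


def write_quant_table(quant: TranscriptQuant, path: str | Path) -> None:
    out = pd.concat([quant.transcripts[_QUANT_META_COLS], quant.tpm], axis=1)
    out.to_csv(path, sep="\t", index=True, index_label="transcript_id", float_format="%.6f")


def read_quant_table(path: str | Path, samples: pd.DataFrame) -> TranscriptQuant:
    """Read a transcript TPM TSV, aligning sample columns to metadata.

    Raises on sample columns absent from ``samples`` and on negative TPM.
    """
    df = pd.read_csv(path, sep="\t", index_col="transcript_id")
    sample_cols = [c for c in df.columns if c not in _QUANT_META_COLS]
    unknown = [c for c in sample_cols if c not in samples.index]
    if unknown:
        raise ValueError(f"sample column(s) missing from metadata: {unknown}")
    tpm = df[sample_cols].astype(float)
    if tpm.isna().any().any():
        raise ValueError("TPM values may not be NA; absence is encoded as 0")
    meta = df[_QUANT_META_COLS].copy()
    meta["start"] = meta["start"].astype(int)
    meta["end"] = meta["end"].astype(int)
    return TranscriptQuant(tpm=tpm, transcripts=meta)


# ---------------------------------------------------------------------------
# Event catalog (SUPPA ioe dialect)

_IOE_COLUMNS = ["seqname", "gene_id", "event_id", "alternative_transcripts", "total_transcripts"]


def parse_event_id(event_id: str) -> tuple[str, str, int, int, str]:
    """Parse ``GENE;TYPE:chrom:start-end:strand`` into its components."""
    try:
        _, rest = event_id.split(";", 1)
        etype, chrom, span, strand = rest.split(":")
        start_s, end_s = span.split("-")
        start, end = int(start_s), int(end_s)
    except ValueError as exc:
        raise ValueError(f"malformed event_id: {event_id!r}") from exc
    if etype not in EVENT_TYPES:
        raise ValueError(f"unknown event type in event_id: {event_id!r}")
    if strand not in "+-":
        raise ValueError(f"bad strand in event_id: {event_id!r}")
    return etype, chrom, start, end, strand


def make_event_id(gene_id: str, etype: str, chrom: str, start: int, end: int, strand: str) -> str:
    return f"{gene_id};{etype}:{chrom}:{start}-{end}:{strand}"


def validate_catalog(catalog: pd.DataFrame) -> pd.DataFrame:
    for eid, row in catalog.iterrows():
        inc, tot = set(row["inclusion"]), set(row["total"])
        if not inc:
            raise ValueError(f"event {eid}: empty inclusion set")
        if len(tot) < 2:
            raise ValueError(f"event {eid}: total set must contain >= 2 transcripts")
        if not inc < tot:
            raise ValueError(f"event {eid}: inclusion transcripts must be a strict subset of total")
    return catalog


def read_ioe(path: str | Path) -> pd.DataFrame:
    """Read a SUPPA-style ioe file into an event catalog.

    The catalog is a DataFrame indexed by event_id with columns gene_id,
    subgenome (last letter of the chromosome name), event_type, the genomic
    interval and the inclusion/total transcript tuples.
    """
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in _IOE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"ioe file missing columns: {missing}")
    rows = []
    for _, r in df.iterrows():
        etype, chrom, start, end, strand = parse_event_id(r["event_id"])
        if chrom != r["seqname"]:
            raise ValueError(f"event {r['event_id']}: seqname column disagrees with event_id")
        inc = tuple(str(r["alternative_transcripts"]).split(","))
        tot = tuple(str(r["total_transcripts"]).split(","))
        rows.append(
            {
                "event_id": r["event_id"],
                "gene_id": r["gene_id"],
                "subgenome": chrom[-1],
                "event_type": etype,
                "chrom": chrom,
                "start": start,
                "end": end,
                "strand": strand,
                "inclusion": inc,
                "total": tot,
            }
        )
    catalog = pd.DataFrame(rows).set_index("event_id")
    return validate_catalog(catalog)


def write_ioe(catalog: pd.DataFrame, path: str | Path) -> None:
    validate_catalog(catalog)
    out = pd.DataFrame(
        {
            "seqname": catalog["chrom"].values,
            "gene_id": catalog["gene_id"].values,
            "event_id": catalog.index.values,
            "alternative_transcripts": [",".join(t) for t in catalog["inclusion"]],
            "total_transcripts": [",".join(t) for t in catalog["total"]],
        }
    )
    out.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Phylostratum table

PS_LEVEL_NAMES: tuple[str, ...] = (
    "Cellular Organism", "Eukaryota", "Viridiplantae", "Embryophyta",
    "Tracheophyta", "Magnoliophyta", "Mesangiospermae", "Commelinids",
    "Poaceae", "BOP clade", "Pooideae", "Triticeae", "Triticinae", "Triticum",
)


def write_ps_table(ps: pd.Series, path: str | Path) -> None:
    df = pd.DataFrame({"ps_level": ps.astype(int)})
    df["ps_name"] = [PS_LEVEL_NAMES[v - 1] for v in df["ps_level"]]
    df.to_csv(path, sep="\t", index=True, index_label="gene_id")


def read_ps_table(path: str | Path) -> pd.Series:
    df = pd.read_csv(path, sep="\t", index_col="gene_id")
    ps = df["ps_level"].astype(int)
    if ((ps < 1) | (ps > 14)).any():
        bad = ps[(ps < 1) | (ps > 14)].index.tolist()
        raise ValueError(f"phylostratum levels must be in 1..14; offending genes: {bad[:5]}")
    return ps


# ---------------------------------------------------------------------------
# PSI matrices and generic labelled TSVs

def write_psi_matrix(psi: pd.DataFrame, path: str | Path) -> None:
    psi.to_csv(path, sep="\t", index=True, index_label="event_id",
               na_rep="NA", float_format="%.6f")


def read_psi_matrix(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col="event_id", na_values="NA")
    return df.astype(float)


# ---------------------------------------------------------------------------
# Minimal GTF (transcript/exon features, gene_id/transcript_id attributes)

def write_gtf(transcripts: pd.DataFrame, path: str | Path) -> None:
    """Write one transcript plus one exon line per transcript (1-based closed)."""
    with open(path, "w") as fh:
        for tid, row in transcripts.iterrows():
            attrs = f'gene_id "{row["gene_id"]}"; transcript_id "{tid}";'
            for feature in ("transcript", "exon"):
                fh.write(
                    "\t".join(
                        [
                            str(row["chrom"]), "polyas", feature,
                            str(int(row["start"]) + 1), str(int(row["end"])),
                            ".", row["strand"], ".", attrs,
                        ]
                    )
                    + "\n"
                )


def read_gtf(path: str | Path) -> pd.DataFrame:
    """Read transcript lines back into a transcript annotation frame."""
    rows = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 9 or parts[2] != "transcript":
                continue
            attrs = dict(
                kv.strip().split(" ", 1)
                for kv in parts[8].strip().strip(";").split(";")
            )
            tid = attrs["transcript_id"].strip('"')
            rows[tid] = {
                "gene_id": attrs["gene_id"].strip('"'),
                "subgenome": parts[0][-1],
                "chrom": parts[0],
                "start": int(parts[3]) - 1,
                "end": int(parts[4]),
                "strand": parts[6],
            }
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "transcript_id"
    return df
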