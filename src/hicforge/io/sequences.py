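"""FASTA and feature (GFF3/BED) input, plus design output writers."""
from __future__ import annotations

import json
from pathlib import Path
from typing import Dict, Iterable, List, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as BioSeqRecord

from ..design.records import Feature, Mutation, SequenceRecord

# GFF3 type / BED name -> feature kind
KIND_MAP = {
    "cds": "CDS",
    "gene": "CDS",
    "orf": "CDS",
    "centromere": "centromere",
    "telomere": "telomere",
    "trna": "tRNA",
    "trna_gene": "tRNA",
    "ars": "ARS_core",
    "ars_core": "ARS_core",
    "origin_of_replication": "ARS_core",
    "tfbs": "TFBS",
    "tf_binding_site": "TFBS",
    "intron_border": "intron_border",
    "ltr_retrotransposon": "retrotransposon",
    "retrotransposon": "retrotransposon",
    "transposable_element": "retrotransposon",
    "start_stop_codon": "start_stop_codon",
}


def read_fasta(path) -> List[SequenceRecord]:
    return [
        SequenceRecord(r.id, str(r.seq).upper()) for r in SeqIO.parse(str(path), "fasta")
    ]


def write_fasta(records: Iterable[SequenceRecord], path) -> None:
    SeqIO.write(
        [BioSeqRecord(Seq(r.seq), id=r.id, description=f"offset={r.offset}")
         for r in records],
        str(path),
        "fasta",
    )


def _kind(raw: str) -> str:
    return KIND_MAP.get(raw.strip().lower(), "other")


def read_gff3(path) -> Dict[str, List[Feature]]:
    """Features per seqid from a GFF3 file (9 plain TSV columns; the
    attribute field is mined for ID/Name only)."""
    out: Dict[str, List[Feature]] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 9:
                raise ValueError(f"malformed GFF3 line: {line[:80]!r}")
            seqid, _, ftype, start, end, _, strand, phase, attrs = parts
            fid = ""
            for token in attrs.split(";"):
                if token.startswith(("ID=", "Name=")):
                    fid = token.split("=", 1)[1]
                    break
            frame = int(phase) if phase in ("0", "1", "2") else 0
            out.setdefault(seqid, []).append(
                Feature(
                    _kind(ftype),
                    int(start) - 1,  # GFF3 is 1-based inclusive
                    int(end),
                    strand if strand in "+-" else "+",
                    frame,
                    fid,
                )
            )
    return out


def read_bed_features(path) -> Dict[str, List[Feature]]:
    """Features per chrom from BED (kind taken from the name column)."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    out: Dict[str, List[Feature]] = {}
    for row in df.itertuples(index=False):
        chrom, start, end = row[0], int(row[1]), int(row[2])
        name = str(row[3]) if len(row) > 3 else "other"
        strand = str(row[5]) if len(row) > 5 and str(row[5]) in "+-" else "+"
        out.setdefault(chrom, []).append(
            Feature(_kind(name), start, end, strand, 0, name)
        )
    return out


def read_anchors_bed(path, bin_size: int) -> Dict[str, List[int]]:
    """Anchor midpoint bins per chromosome from a BED file."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    out: Dict[str, List[int]] = {}
    for row in df.itertuples(index=False):
        mid = (int(row[1]) + int(row[2])) // 2
        out.setdefault(row[0], []).append(mid // bin_size)
    return out


def write_mutations_tsv(mutations: Sequence[Mutation], path, offset: int = 0) -> None:
    rows = []
    for m in mutations:
        syn = m.codon_context[2] if m.codon_context else ""
        rows.append(
            (m.pos + offset + 1, m.ref, m.alt, m.reason, m.enzyme or "",
             m.codon_context[0] if m.codon_context else "", syn)
        )
    pd.DataFrame(
        rows, columns=["pos_1based", "ref", "alt", "reason", "enzyme", "feature",
                       "synonymous"]
    ).to_csv(path, sep="\t", index=False)


def write_mutations_vcf(
    mutations: Sequence[Mutation], path, chrom: str, offset: int = 0
) -> None:
    """Minimal VCFv4.2 emitter for the mutation ledger."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=REASON,Number=1,Type=String,Description="Edit reason">\n')
        fh.write('##INFO=<ID=ENZYME,Number=1,Type=String,Description="Target enzyme">\n')
        fh.write('##INFO=<ID=SYN,Number=1,Type=String,Description="Synonymous in CDS">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for m in sorted(mutations, key=lambda m: m.pos):
            syn = (
                str(m.codon_context[2]).lower() if m.codon_context else "na"
            )
            info = f"REASON={m.reason};ENZYME={m.enzyme or 'NA'};SYN={syn}"
            fh.write(
                f"{chrom}\t{m.pos + offset + 1}\t.\t{m.ref}\t{m.alt}\t.\tPASS\t{info}\n"
            )


def write_sites_bed(placed: Dict[str, List[int]], path, chrom: str,
                    site_lengths: Dict[str, int], offset: int = 0) -> None:
    rows = []
    for enzyme, positions in placed.items():
        m = site_lengths[enzyme]
        for p in positions:
            rows.append((chrom, p + offset, p + offset + m, enzyme))
    rows.sort(key=lambda r: r[1])
    pd.DataFrame(rows, columns=["chrom", "start", "end", "name"]).to_csv(
        path, sep="\t", header=False, index=False
    )


def write_manifest(path, command: str, config: dict, seed=None) -> None:
    import time

    Path(path).write_text(
        json.dumps(
            {
                "command": command,
                "config": config,
                "seed": seed,
                "version": "0.1.0",
                "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
            },
            indent=1,
            default=str,
        )
    )
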