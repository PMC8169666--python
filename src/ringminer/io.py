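"""Plain-text readers/writers for the formats the pipeline exchanges."""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord


def write_fasta(records: Iterable[tuple[str, str]], path) -> None:
    """Write (id, sequence) records as 60-column wrapped FASTA."""
    seqs = [SeqRecord(Seq(s), id=i, description="") for i, s in records]
    with open(path, "w") as fh:
        SeqIO.write(seqs, fh, "fasta")


def read_fasta(path) -> list[tuple[str, str]]:
    return [(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]


def gff3_gene_lines(gene_id: str, chrom: str, start: int, end: int,
                    strand: str = "+",
                    exons: Sequence[tuple[int, int]] = (),
                    cds: Sequence[tuple[int, int]] = ()) -> list[str]:
    lines = [f"{chrom}\tringminer\tgene\t{start}\t{end}\t.\t{strand}\t.\t"
             f"ID={gene_id}"]
    for i, (s, e) in enumerate(exons, 1):
        lines.append(f"{chrom}\tringminer\texon\t{s}\t{e}\t.\t{strand}\t.\t"
                     f"ID={gene_id}.exon{i};Parent={gene_id}")
    for i, (s, e) in enumerate(cds, 1):
        lines.append(f"{chrom}\tringminer\tCDS\t{s}\t{e}\t.\t{strand}\t0\t"
                     f"ID={gene_id}.cds{i};Parent={gene_id}")
    return lines


def write_gff3(lines: Sequence[str], path) -> None:
    Path(path).write_text("##gff-version 3\n" + "\n".join(lines) + "\n")


def write_pairs_tsv(pairs: Iterable[tuple[str, str]], path) -> None:
    with open(path, "w") as fh:
        fh.write("gene_a\tgene_b\n")
        for a, b in pairs:
            fh.write(f"{a}\t{b}\n")


def read_pairs_tsv(path) -> list[tuple[str, str]]:
    df = pd.read_csv(path, sep="\t")
    return list(zip(df["gene_a"].astype(str), df["gene_b"].astype(str)))


def write_vcf_lite(variants, path) -> None:
    with open(path, "w") as fh:
        fh.write("#CHROM\tPOS\tID\tREF\tALT\n")
        for v in variants:
            fh.write(f"{v.chromosome}\t{v.position}\t{v.variant_id or '.'}\t"
                     f"{v.ref}\t{v.alt}\n")


def write_truth_json(truth: Mapping, path) -> None:
    Path(path).write_text(json.dumps(truth, indent=2, sort_keys=True) + "\n")
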