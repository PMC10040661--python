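"""Readers and writers for the formats the pipeline touches.

VCF 4.x genotypes (read through cyvcf2, written as plain text), GFF3 gene
models (through gffutils), FASTA/FASTQ (Biopython), and the simple tabular
interchange formats: panel TSV, PAV CSV (first column gene_id, remaining
columns cultivars, values 0/1) and contig hit TSV.

All coordinates stay 1-based inclusive. Counts of skipped or filtered
records are always logged.
"""

from __future__ import annotations

import logging
import sys
from pathlib import Path

import gffutils
import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .core import (
    MISSING,
    ContigHitSet,
    CultivarPanel,
    GeneModel,
    GenotypeMatrix,
    PAVMatrix,
    ReadRecord,
)

logger = logging.getLogger(__name__)


def setup_logging(log_file: str | Path | None = None, level=logging.INFO) -> None:
    """Log to stderr and, when given, a run-log file."""
    handlers: list[logging.Handler] = [logging.StreamHandler(sys.stderr)]
    if log_file is not None:
        handlers.append(logging.FileHandler(log_file))
    logging.basicConfig(
        level=level,
        format="%(asctime)s %(name)s %(levelname)s %(message)s",
        handlers=handlers,
        force=True,
    )


# ---------------------------------------------------------------- genotypes


def parse_genotypes(vcf_path: str | Path, panel: CultivarPanel) -> GenotypeMatrix:
    """Read biallelic SNP genotypes for the panel cultivars from a VCF.

    Multiallelic and non-SNP records are skipped (counts logged); uncalled
    or malformed GT fields become missing calls. Locus order is preserved.
    A panel cultivar absent from the VCF header is fatal.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(vcf_path), gts012=True)
    missing_samples = set(panel.cultivar_ids) - set(vcf.samples)
    if missing_samples:
        raise ValueError(
            f"panel cultivar(s) missing from VCF: {sorted(missing_samples)}"
        )
    col_of = {s: i for i, s in enumerate(vcf.samples)}
    order = [col_of[c] for c in panel.cultivar_ids]

    loci_rows = []
    call_rows = []
    n_multi = n_nonsnp = 0
    for v in vcf:
        if len(v.ALT) != 1:
            n_multi += 1
            continue
        if not v.is_snp:
            n_nonsnp += 1
            continue
        gt = np.asarray(v.gt_types)[order].astype(np.int8)
        gt[gt == 3] = MISSING  # cyvcf2 gts012 code 3 = unknown
        loci_rows.append((v.CHROM, v.POS, v.REF, v.ALT[0]))
        call_rows.append(gt)
    vcf.close()
    if n_multi or n_nonsnp:
        logger.info(
            "skipped %d multiallelic and %d non-SNP record(s)", n_multi, n_nonsnp
        )
    loci = pd.DataFrame(loci_rows, columns=["chrom", "pos", "ref", "alt"])
    calls = (
        np.vstack(call_rows)
        if call_rows
        else np.empty((0, len(panel.cultivar_ids)), dtype=np.int8)
    )
    return GenotypeMatrix(loci, calls, tuple(panel.cultivar_ids))


_GT_STRING = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def write_genotypes(gm: GenotypeMatrix, path: str | Path) -> None:
    """Write the genotype matrix as a minimal VCF 4.2 text file."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom, grp in gm.loci.groupby("chrom", sort=False):
            fh.write(
                f"##contig=<ID={chrom},length={int(grp['pos'].max()) + 1000}>\n"
            )
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(gm.cultivar_ids)
            + "\n"
        )
        for i in range(gm.n_loci):
            row = gm.loci.iloc[i]
            gts = "\t".join(_GT_STRING[int(c)] for c in gm.calls[i])
            fh.write(
                f"{row['chrom']}\t{int(row['pos'])}\t.\t{row['ref']}\t"
                f"{row['alt']}\t.\tPASS\t.\tGT\t{gts}\n"
            )


# --------------------------------------------------------------- gene models


def parse_gene_models(
    gff3_path: str | Path, annotation_key: str = "description"
) -> list[GeneModel]:
    """Gene features from a GFF3 file, sorted by (chromosome, start).

    Non-gene features (mRNA, exon, ...) are ignored. The free-text
    annotation is taken from ``annotation_key`` in column 9, falling back to
    ``Name`` then empty. A record with start > end is fatal.
    """
    db = gffutils.create_db(
        str(gff3_path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )
    genes = []
    for feat in db.features_of_type("gene"):
        ann_vals = feat.attributes.get(annotation_key) or feat.attributes.get(
            "Name"
        )
        annotation = ann_vals[0] if ann_vals else ""
        genes.append(
            GeneModel(
                gene_id=feat.id,
                chromosome=feat.seqid,
                start=feat.start,
                end=feat.end,
                annotation=annotation,
            )
        )
    genes.sort(key=lambda g: (g.chromosome, g.start, g.gene_id))
    logger.info("parsed %d gene model(s)", len(genes))
    return genes


def write_gene_models(genes: list[GeneModel], path: str | Path) -> None:
    with Path(path).open("w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            fh.write(
                f"{g.chromosome}\tpomepan\tgene\t{g.start}\t{g.end}\t.\t+\t.\t"
                f"ID={g.gene_id};description={g.annotation}\n"
            )


# -------------------------------------------------------------------- panel


def read_panel(path: str | Path) -> CultivarPanel:
    """Panel TSV with columns cultivar_id, subpopulation."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    return CultivarPanel(
        tuple(df["cultivar_id"]), tuple(df["subpopulation"])
    )


def write_panel(panel: CultivarPanel, path: str | Path) -> None:
    pd.DataFrame(
        {
            "cultivar_id": panel.cultivar_ids,
            "subpopulation": panel.subpopulations,
        }
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------- PAV


def read_pav_csv(path: str | Path) -> PAVMatrix:
    df = pd.read_csv(path, index_col=0)
    return PAVMatrix.from_frame(df)


def write_pav_csv(pav: PAVMatrix, path: str | Path) -> None:
    pav.to_frame().to_csv(path)


# ----------------------------------------------------------------- hit TSVs

HIT_COLUMNS = [
    "contig_id",
    "contig_len",
    "hit_start",
    "hit_end",
    "identity_pct",
    "evalue",
]


def read_hits_tsv(path: str | Path) -> list[ContigHitSet]:
    """Hit TSV -> one ContigHitSet per contig (contigs without hits allowed
    as rows with empty hit fields)."""
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    missing = set(HIT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"hit table missing columns {sorted(missing)}")
    hitsets = []
    for (contig_id, contig_len), grp in df.groupby(
        ["contig_id", "contig_len"], sort=False
    ):
        hits = [
            (int(r.hit_start), int(r.hit_end), float(r.identity_pct), float(r.evalue))
            for r in grp.itertuples()
            if not pd.isna(r.hit_start)
        ]
        hitsets.append(ContigHitSet(str(contig_id), int(contig_len), tuple(hits)))
    return hitsets


def write_hits_tsv(hitsets: list[ContigHitSet], path: str | Path) -> None:
    rows = []
    for hs in hitsets:
        if not hs.hits:
            rows.append((hs.contig_id, hs.contig_len, np.nan, np.nan, np.nan, np.nan))
        for start, end, ident, ev in hs.hits:
            rows.append((hs.contig_id, hs.contig_len, start, end, ident, ev))
    pd.DataFrame(rows, columns=HIT_COLUMNS).to_csv(path, sep="\t", index=False)


# ------------------------------------------------------------- reads / FASTA


def write_fastq(reads: list[ReadRecord], path: str | Path) -> None:
    records = []
    for r in reads:
        rec = SeqRecord(Seq(r.sequence), id=r.read_id, description="")
        rec.letter_annotations["phred_quality"] = list(r.qualities)
        records.append(rec)
    SeqIO.write(records, str(path), "fastq")


def read_fastq(path: str | Path, library_class: str = "paired_end") -> list[ReadRecord]:
    return [
        ReadRecord(
            rec.id,
            str(rec.seq),
            tuple(rec.letter_annotations["phred_quality"]),
            library_class,
        )
        for rec in SeqIO.parse(str(path), "fastq")
    ]


def write_fasta(seqs: list[tuple[str, str]], path: str | Path) -> None:
    SeqIO.write(
        [SeqRecord(Seq(s), id=name, description="") for name, s in seqs],
        str(path),
        "fasta",
    )


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    return [(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]
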