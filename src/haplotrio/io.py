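"""Readers/writers for the standard text formats the pipeline exchanges.

FASTA goes through Biopython; VCF, BED, bedGraph and TSV are emitted as
plain text in their standard layouts (VCF 4.2 with symbolic alleles for
SVs). All coordinates are 0-based half-open in memory and converted to the
1-based conventions of VCF on output.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .hetspectrum.variants import VariantRecord

__all__ = [
    "read_fasta",
    "write_fasta",
    "write_variant_vcf",
    "write_sv_vcf",
    "write_bed",
    "write_bedgraph",
    "write_truth_bundle",
]


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(path: str | Path, seqs: Mapping[str, object]) -> None:
    records = []
    for name, seq in seqs.items():
        if isinstance(seq, np.ndarray):
            seq = seq.tobytes().decode()
        elif isinstance(seq, bytes):
            seq = seq.decode()
        records.append(SeqRecord(Seq(seq), id=name, description=""))
    SeqIO.write(records, str(path), "fasta")


_VCF_HEADER = """##fileformat=VCFv4.2
##source=haplotrio
{extra}#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO
"""


def write_variant_vcf(path: str | Path, variants: Iterable[VariantRecord],
                      ref_seqs: Mapping[str, str] | None = None) -> None:
    """SNVs and small indels as explicit-allele VCF records.

    Indels need ``ref_seqs`` (maternal haplotype) for the anchor base.
    """
    lines = []
    for v in sorted(variants, key=lambda v: (v.ref_chrom, v.ref_start)):
        if v.var_class == "SNV":
            lines.append(f"{v.ref_chrom}\t{v.ref_start + 1}\t.\t{v.ref_allele}"
                         f"\t{v.alt_allele}\t.\tPASS\t.")
        elif v.var_class == "small_indel":
            if ref_seqs is None:
                raise ValueError("indel VCF output requires ref_seqs for anchor bases")
            anchor_pos = max(v.ref_start - 1, 0)
            anchor = ref_seqs[v.ref_chrom][anchor_pos]
            if v.kind == "deletion":
                ref, alt = anchor + v.ref_allele, anchor
            else:
                ref, alt = anchor, anchor + v.alt_allele
            lines.append(f"{v.ref_chrom}\t{anchor_pos + 1}\t.\t{ref}\t{alt}\t.\tPASS\t.")
    Path(path).write_text(_VCF_HEADER.format(extra="") + "\n".join(lines)
                          + ("\n" if lines else ""))


_SV_META = (
    '##ALT=<ID=DEL,Description="Deletion">\n'
    '##ALT=<ID=INS,Description="Insertion">\n'
    '##ALT=<ID=INV,Description="Inversion">\n'
    '##ALT=<ID=DUP,Description="Duplication">\n'
    '##ALT=<ID=BND,Description="Breakend">\n'
    '##INFO=<ID=SVTYPE,Number=1,Type=String,Description="SV class">\n'
    '##INFO=<ID=END,Number=1,Type=Integer,Description="End position">\n'
    '##INFO=<ID=SVLEN,Number=1,Type=Integer,Description="SV length">\n'
)

_SV_SYMBOL = {
    "large_indel": {"deletion": "DEL", "insertion": "INS"},
    "inversion": {"inversion": "INV"},
    "CNV": {"duplication": "DUP"},
    "translocation": {"translocation": "BND"},
    "inverted_translocation": {"translocation": "BND"},
}


def write_sv_vcf(path: str | Path, svs: Iterable[VariantRecord]) -> None:
    """SVs as symbolic-allele VCF records (SVTYPE/END/SVLEN)."""
    lines = []
    for v in sorted(svs, key=lambda v: (v.ref_chrom, v.ref_start)):
        sym = _SV_SYMBOL.get(v.var_class, {}).get(v.kind, "BND")
        svlen = -v.length if v.kind == "deletion" else v.length
        info = f"SVTYPE={sym};END={v.ref_end};SVLEN={svlen}"
        lines.append(f"{v.ref_chrom}\t{v.ref_start + 1}\t.\tN\t<{sym}>\t.\tPASS\t{info}")
    Path(path).write_text(_VCF_HEADER.format(extra=_SV_META) + "\n".join(lines)
                          + ("\n" if lines else ""))


def write_bed(path: str | Path, intervals: pd.DataFrame,
              cols: tuple[str, str, str] = ("chrom", "start", "end")) -> None:
    intervals[list(cols)].to_csv(path, sep="\t", header=False, index=False)


def write_bedgraph(path: str | Path, windows: pd.DataFrame, value_col: str) -> None:
    windows[["chrom", "start", "end", value_col]].to_csv(
        path, sep="\t", header=False, index=False)


def write_truth_bundle(truth, outdir: str | Path) -> dict[str, Path]:
    """Dump a simulated trio truth set as FASTA + VCF + TSV + BED files.

    Haplotype FASTAs, truth SNVs as VCF, truth indels/SVs and DNMs as TSV,
    and ROH intervals as BED. Returns the written paths by content name.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    for name, seqs in (("maternal", truth.maternal), ("paternal", truth.paternal),
                       ("child_maternal", truth.child_maternal),
                       ("child_paternal", truth.child_paternal)):
        paths[name] = outdir / f"{name}.fasta"
        write_fasta(paths[name], seqs)
    snvs = truth.variants[truth.variants["var_class"] == "SNV"]
    paths["snvs"] = outdir / "truth_snvs.vcf"
    records = [VariantRecord("SNV", r.ref_chrom, r.ref_start, r.ref_end,
                             r.qry_chrom, r.qry_start, r.qry_end, 1,
                             ref_allele=r.ref_allele, alt_allele=r.alt_allele)
               for r in snvs.itertuples()]
    write_variant_vcf(paths["snvs"], records)
    paths["variants"] = outdir / "truth_variants.tsv"
    truth.variants.to_csv(paths["variants"], sep="\t", index=False)
    paths["dnms"] = outdir / "truth_dnms.tsv"
    truth.dnms.to_csv(paths["dnms"], sep="\t", index=False)
    paths["roh"] = outdir / "truth_roh.bed"
    write_bed(paths["roh"], truth.roh)
    return paths
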