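"""Reading and writing the pipeline's on-disk formats.

VCF v4.2 is the genotype interchange format (diploid ``GT``, ``./.`` for
missing, hard-filter statistics in INFO).  Reading goes through ``cyvcf2``;
writing is a small text emitter because the fixtures are built de novo
(no template header exists to clone).
"""

from __future__ import annotations

import math
from pathlib import Path

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from .containers import MISSING, GenotypeTable

INFO_FIELDS = ("QD", "FS", "SOR", "MQ", "MQRankSum", "ReadPosRankSum", "AN")

_HEADER_TEMPLATE = """\
##fileformat=VCFv4.2
##source=ibexload
##INFO=<ID=QD,Number=1,Type=Float,Description="Quality by depth">
##INFO=<ID=FS,Number=1,Type=Float,Description="Fisher strand bias">
##INFO=<ID=SOR,Number=1,Type=Float,Description="Strand odds ratio">
##INFO=<ID=MQ,Number=1,Type=Float,Description="RMS mapping quality">
##INFO=<ID=MQRankSum,Number=1,Type=Float,Description="Mapping quality rank-sum">
##INFO=<ID=ReadPosRankSum,Number=1,Type=Float,Description="Read position rank-sum">
##INFO=<ID=AN,Number=1,Type=Integer,Description="Allele number">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
"""

_GT_STRINGS = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def _fmt_info(row) -> str:
    parts = []
    for key in INFO_FIELDS:
        val = row.get(key)
        if val is None or (isinstance(val, float) and math.isnan(val)):
            continue
        if key == "AN":
            parts.append(f"{key}={int(val)}")
        else:
            parts.append(f"{key}={val:g}")
    return ";".join(parts) if parts else "."


def write_vcf(path, table: GenotypeTable, info: pd.DataFrame | None = None) -> None:
    """Write an uncompressed VCF v4.2 file.

    ``info``, if given, is a per-site DataFrame providing any of the hard
    filter INFO fields (QD, FS, SOR, MQ, MQRankSum, ReadPosRankSum, AN);
    missing values are simply omitted from the record.
    """
    path = Path(path)
    sites = table.sites
    contigs = list(dict.fromkeys(sites["chrom"].astype(str)))
    with open(path, "w") as fh:
        fh.write(_HEADER_TEMPLATE)
        for contig in contigs:
            fh.write(f"##contig=<ID={contig}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(table.samples)
            + "\n"
        )
        info_records = (
            info.to_dict("records") if info is not None else [{}] * table.n_sites
        )
        for i in range(table.n_sites):
            row = sites.iloc[i]
            gts = "\t".join(_GT_STRINGS[int(d)] for d in table.dosage[i])
            fh.write(
                f"{row['chrom']}\t{int(row['pos'])}\t{row.get('id', '.')}\t"
                f"{row['ref']}\t{row['alt']}\t.\t.\t"
                f"{_fmt_info(info_records[i])}\tGT\t{gts}\n"
            )


def read_vcf(path) -> tuple[GenotypeTable, pd.DataFrame]:
    """Read a VCF into a :class:`GenotypeTable` plus an INFO DataFrame.

    Multiallelic records are kept with a comma-joined ALT string (so the
    polarization stage can mark them UNKNOWN); their dosage is the count of
    non-reference alleles.  An unparseable INFO value sets the
    ``parse_error`` flag for that site instead of raising.
    """
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    site_rows, dos_rows, info_rows = [], [], []
    for var in vcf:
        alt = ",".join(var.ALT) if var.ALT else "."
        site_rows.append(
            {
                "chrom": var.CHROM,
                "pos": var.POS,
                "id": var.ID or ".",
                "ref": var.REF,
                "alt": alt,
            }
        )
        # genotypes: count non-reference alleles; any missing allele -> missing
        dos = np.empty(len(samples), dtype=np.int8)
        for j, g in enumerate(var.genotypes):
            a, b = g[0], g[1]
            dos[j] = MISSING if (a < 0 or b < 0) else (a > 0) + (b > 0)
        dos_rows.append(dos)
        rec, parse_error = {}, False
        for key in INFO_FIELDS:
            raw = var.INFO.get(key)
            if raw is None:
                rec[key] = np.nan
                continue
            try:
                rec[key] = float(raw)
            except (TypeError, ValueError):
                rec[key] = np.nan
                parse_error = True
        rec["parse_error"] = parse_error
        info_rows.append(rec)
    sites = pd.DataFrame(
        site_rows, columns=["chrom", "pos", "id", "ref", "alt"]
    )
    dosage = (
        np.vstack(dos_rows) if dos_rows else np.empty((0, len(samples)), np.int8)
    )
    info = pd.DataFrame(info_rows, columns=list(INFO_FIELDS) + ["parse_error"])
    return GenotypeTable(sites, dosage, samples), info


# -- TSV helpers ----------------------------------------------------------


def write_tsv(path, df: pd.DataFrame, header_comments=()) -> None:
    """Write a TSV with optional ``#``-prefixed header comment lines."""
    with open(path, "w") as fh:
        for line in header_comments:
            fh.write(f"# {line}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")
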