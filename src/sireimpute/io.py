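"""Reading and writing genotype matrices, SNP maps and pedigrees.

Two genotype formats are supported:

* VCF v4.2 (GT field; biallelic sites; ``./.`` = missing).  Reading uses
  cyvcf2; writing emits plain-text VCF, optionally with phased GT, a GP
  (genotype probability) FORMAT field and a per-site AR2 INFO key.
* a tab-separated matrix: rows = animals, columns = SNPs, header row of SNP
  ids, first column ``animal``, missing = "NA".

Pedigrees are tab-separated with columns ``animal, sire, dam, generation``
("0" or "NA" = unknown parent).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .containers import MISSING, GenotypeMatrix, Pedigree, make_snp_table


class ParseError(ValueError):
    """Raised when an input file cannot be parsed; names the offending record."""


# ---------------------------------------------------------------------------
# genotypes
# ---------------------------------------------------------------------------

def read_genotypes(path, format="vcf", on_multiallelic="error"):
    """Read a genotype matrix from ``path``.

    Parameters
    ----------
    format : {"vcf", "matrix"}
    on_multiallelic : {"error", "skip"}
        VCF only: what to do with records having more than one ALT allele.

    Returns
    -------
    GenotypeMatrix
        When skipping multi-allelic sites, the count of skipped records is
        attached as ``geno.n_skipped_multiallelic``.
    """
    if format == "vcf":
        return _read_vcf(path, on_multiallelic)
    if format == "matrix":
        return _read_matrix(path)
    raise ValueError(f"unknown genotype format {format!r}")


def _read_vcf(path, on_multiallelic):
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    animals = list(vcf.samples)
    rows, recs = [], []
    n_skipped = 0
    for i, var in enumerate(vcf):
        if len(var.ALT) != 1:
            if on_multiallelic == "skip":
                n_skipped += 1
                continue
            raise ParseError(
                f"multi-allelic record at {var.CHROM}:{var.POS} (record {i + 1})"
            )
        gts = var.genotypes  # [[a0, a1, phased], ...]
        calls = np.empty(len(animals), dtype=np.int8)
        for j, gt in enumerate(gts):
            a, b = gt[0], gt[1]
            calls[j] = MISSING if (a < 0 or b < 0) else a + b
        rows.append(calls)
        recs.append(
            (
                var.ID if var.ID not in (None, ".") else f"{var.CHROM}_{var.POS}",
                var.CHROM,
                var.POS,
                var.REF,
                var.ALT[0],
            )
        )
    if not recs:
        raise ParseError(f"no biallelic records in {path}")
    ids, chroms, pos, ref, alt = zip(*recs)
    if len(set(ids)) != len(ids):
        dup = pd.Series(ids)[pd.Series(ids).duplicated()].iloc[0]
        raise ParseError(f"duplicate SNP id {dup!r} in {path}")
    snps = make_snp_table(ids, chrom=list(chroms), pos_bp=pos)
    snps["a1"] = ref
    snps["a2"] = alt
    geno = GenotypeMatrix(animals, snps, np.column_stack(rows))
    geno.n_skipped_multiallelic = n_skipped
    return geno


def _read_matrix(path):
    try:
        tab = pd.read_csv(path, sep="\t", dtype={0: str})
    except Exception as e:  # pragma: no cover - pandas message passthrough
        raise ParseError(f"cannot parse {path}: {e}") from e
    if tab.columns[0] != "animal":
        raise ParseError(f"{path}: first column must be 'animal', got {tab.columns[0]!r}")
    snp_ids = list(tab.columns[1:])
    if len(set(snp_ids)) != len(snp_ids):
        raise ParseError(f"duplicate SNP id in header of {path}")
    calls = tab.iloc[:, 1:].to_numpy(dtype=float)
    calls = np.where(np.isnan(calls), MISSING, calls).astype(np.int8)
    return GenotypeMatrix(list(tab["animal"]), make_snp_table(snp_ids), calls)


def write_genotypes(geno: GenotypeMatrix, path, format="matrix"):
    """Write ``geno`` as a tab-separated matrix ("NA" = missing) or VCF."""
    if format == "matrix":
        out = pd.DataFrame(
            geno.calls.astype(object), index=pd.Index(geno.animals, name="animal"),
            columns=geno.snp_ids,
        )
        out = out.where(geno.calls != MISSING, "NA")
        out.to_csv(path, sep="\t")
    elif format == "vcf":
        write_vcf(geno, path)
    else:
        raise ValueError(f"unknown genotype format {format!r}")


_GT_CODE = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
_PHASED_GT = {(0, 0): "0|0", (0, 1): "0|1", (1, 0): "1|0", (1, 1): "1|1"}


def write_vcf(geno: GenotypeMatrix, path, haplotypes=None, gp=None, ar2=None):
    """Write a VCF v4.2 file.

    Parameters
    ----------
    haplotypes : optional ndarray (n_animals, 2, n_snps) of 0/1
        When given, GT is written phased ("0|1") from the haplotype pair.
    gp : optional ndarray (n_animals, n_snps, 3)
        Posterior genotype probabilities, written as a GP FORMAT field.
    ar2 : optional ndarray (n_snps,)
        Estimated allelic R-squared, written as an AR2 INFO key.
    """
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        if gp is not None:
            fh.write(
                '##FORMAT=<ID=GP,Number=G,Type=Float,Description='
                '"Genotype probabilities">\n'
            )
        if ar2 is not None:
            fh.write(
                '##INFO=<ID=AR2,Number=1,Type=Float,Description='
                '"Estimated allelic R-squared">\n'
            )
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(str(a) for a in geno.animals)
            + "\n"
        )
        fmt = "GT" if gp is None else "GT:GP"
        for m in range(geno.n_snps):
            rec = geno.snps.iloc[m]
            info = "." if ar2 is None else f"AR2={ar2[m]:.4f}"
            fields = [
                str(rec["chrom"]), str(int(rec["pos_bp"])), str(rec["id"]),
                str(rec["a1"]), str(rec["a2"]), ".", "PASS", info, fmt,
            ]
            for i in range(geno.n_animals):
                if haplotypes is not None and geno.calls[i, m] != MISSING:
                    gt = _PHASED_GT[(int(haplotypes[i, 0, m]), int(haplotypes[i, 1, m]))]
                else:
                    gt = _GT_CODE[int(geno.calls[i, m])]
                if gp is not None:
                    gt += ":" + ",".join(f"{p:.4f}" for p in gp[i, m])
                fields.append(gt)
            fh.write("\t".join(fields) + "\n")


# ---------------------------------------------------------------------------
# pedigree
# ---------------------------------------------------------------------------

def read_pedigree(path, generations=None) -> Pedigree:
    tab = pd.read_csv(path, sep="\t", dtype=str)
    required = {"animal", "sire", "dam", "generation"}
    if not required.issubset(tab.columns):
        raise ParseError(f"{path}: pedigree needs columns {sorted(required)}")
    return Pedigree(tab, generations=list(generations) if generations else [])


def write_pedigree(ped: Pedigree, path):
    out = ped.table.copy()
    for col in ("sire", "dam"):
        out[col] = out[col].where(pd.notna(out[col]), "0").replace({None: "0"})
    out.to_csv(path, sep="\t", index=False)
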