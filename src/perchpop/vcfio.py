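"""VCF input/output for diploid biallelic genotype matrices.

Reading goes through cyvcf2; writing emits minimal VCF 4.2 with contig
headers and unphased GT-only genotypes.  Multiallelic records are skipped
(with a logged count), invariant records (no ALT allele) are retained when
requested so that nucleotide diversity can use the full denominator.
"""

from __future__ import annotations

import logging

import numpy as np
from cyvcf2 import VCF

from .core import MISSING, GenotypeMatrix, PopulationMap

log = logging.getLogger(__name__)


def read_vcf(
    path,
    population_map: PopulationMap | None = None,
    keep_invariant: bool = True,
) -> GenotypeMatrix:
    """Read a VCF 4.x file into a :class:`GenotypeMatrix`.

    Parameters
    ----------
    path : str
        VCF file (plain or bgzipped).
    population_map : optional
        When given, every sample in the VCF must be assigned in the map;
        offenders are reported in the raised error.
    keep_invariant : bool
        Retain records with no ALT allele (sites monomorphic for the
        reference), marked with ``alt == "."``.
    """
    vcf = VCF(str(path), gts012=True)
    samples = list(vcf.samples)
    if not samples:
        raise ValueError(f"{path}: VCF contains no samples")
    if population_map is not None:
        unmapped = [s for s in samples if s not in population_map.assignments]
        if unmapped:
            raise ValueError(
                f"{path}: samples absent from population map: {unmapped}"
            )

    chroms, poss, refs, alts, rows = [], [], [], [], []
    contigs: dict[str, int] = {}
    for name, length in zip(vcf.seqnames, vcf.seqlens or []):
        contigs[name] = length
    n_multi = 0
    for var in vcf:
        if len(var.ALT) > 1:
            n_multi += 1
            continue
        if len(var.ALT) == 0 and not keep_invariant:
            continue
        # gts012: 0=hom-ref, 1=het, 2=hom-alt, 3=missing
        gt = np.asarray(var.gt_types, dtype=np.int8)
        gt[gt == 3] = MISSING
        chroms.append(var.CHROM)
        poss.append(var.POS)
        refs.append(var.REF)
        alts.append(var.ALT[0] if var.ALT else ".")
        rows.append(gt)
    if n_multi:
        log.info("%s: skipped %d multiallelic records", path, n_multi)
    if not rows:
        raise ValueError(f"{path}: no usable biallelic records")
    dosage = np.stack(rows, axis=1)  # samples x sites
    return GenotypeMatrix(
        chrom=np.array(chroms, dtype=object),
        pos=np.array(poss, dtype=np.int64),
        ref=np.array(refs, dtype=object),
        alt=np.array(alts, dtype=object),
        dosage=dosage,
        samples=samples,
        contig_lengths=contigs or None,
    )


_GT_STRING = {MISSING: "./.", 0: "0/0", 1: "0/1", 2: "1/1"}


def write_vcf(gm: GenotypeMatrix, path, source: str = "perchpop") -> None:
    """Write a :class:`GenotypeMatrix` as VCF 4.2 (1-based, unphased GT)."""
    lut = np.empty(4, dtype=object)
    for k, v in _GT_STRING.items():
        lut[k] = v
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##source={source}\n")
        if gm.contig_lengths:
            for name, length in gm.contig_lengths.items():
                fh.write(f"##contig=<ID={name},length={length}>\n")
        else:
            for name in gm.chroms:
                fh.write(f"##contig=<ID={name}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(gm.samples) + "\n"
        )
        gts = lut[gm.dosage]  # samples x sites, object strings
        for j in range(gm.n_sites):
            fields = [
                str(gm.chrom[j]), str(gm.pos[j]), ".", str(gm.ref[j]),
                str(gm.alt[j]), ".", "PASS", ".", "GT",
            ]
            fh.write("\t".join(fields) + "\t" + "\t".join(gts[:, j]) + "\n")
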