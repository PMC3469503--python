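"""VCF and genetic-map I/O.

Reading goes through :mod:`cyvcf2`; only sorted, bi-allelic SNVs are
retained (anything else is skipped and counted to the log).  Genetic
positions are assigned to every retained site from a :class:`GeneticMap`
by linear interpolation.  A minimal VCF writer is provided for exporting
simulated cohorts.
"""

from __future__ import annotations

import logging

import numpy as np
from cyvcf2 import VCF

from .cohort import MISSING, Cohort, GeneticMap

log = logging.getLogger("ibdslice")

__all__ = [
    "read_vcf",
    "write_vcf",
    "read_genetic_map",
    "read_plink_map",
    "write_genetic_map",
]

_SNV_ALLELES = frozenset("ACGT")

# cyvcf2 gt_types: 0=HOM_REF 1=HET 2=UNKNOWN 3=HOM_ALT
_GT_TYPE_MAP = np.array([0, 1, MISSING, 2], dtype=np.int8)


def read_vcf(path, gmap: GeneticMap, known_sites: set[str] | None = None) -> Cohort:
    """Load a sorted VCF of bi-allelic SNVs into a :class:`Cohort`.

    Parameters
    ----------
    path
        VCF/VCF.gz path with GT (and optionally GQ) FORMAT fields.
    gmap
        Genetic map used to assign a cM position to every retained site.
    known_sites
        Optional set of variant IDs to flag as annotated (catalogue
        members).  When omitted, a site is annotated iff its VCF ID field
        is non-missing.

    Multi-allelic records, indels and non-ACGT alleles are skipped with a
    logged count.  Missing GQ values default to 0, so any positive GQ
    threshold downstream removes those calls.
    """
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    if len(samples) < 2:
        raise ValueError(f"{path}: need at least 2 samples, found {len(samples)}")

    chroms: list[str] = []
    pos: list[int] = []
    ref: list[str] = []
    alt: list[str] = []
    annotated: list[bool] = []
    geno_rows: list[np.ndarray] = []
    gq_rows: list[np.ndarray] = []
    hap_rows: list[np.ndarray] = []
    n_skipped = 0
    all_phased = True
    last: dict[str, int] = {}
    seen_order: list[str] = []

    for variant in vcf:
        if (
            len(variant.ALT) != 1
            or len(variant.REF) != 1
            or len(variant.ALT[0]) != 1
            or variant.REF not in _SNV_ALLELES
            or variant.ALT[0] not in _SNV_ALLELES
        ):
            n_skipped += 1
            continue
        c = variant.CHROM
        if c not in last:
            if seen_order and any(c == prev for prev in seen_order):
                raise ValueError(
                    f"{path}: unsorted VCF, chromosome {c} reappears at "
                    f"{c}:{variant.POS}"
                )
            seen_order.append(c)
            last[c] = -1
        if variant.POS <= last[c]:
            raise ValueError(
                f"{path}: unsorted VCF at {c}:{variant.POS} "
                f"(previous position {last[c]})"
            )
        last[c] = variant.POS

        chroms.append(c)
        pos.append(variant.POS)
        ref.append(variant.REF)
        alt.append(variant.ALT[0])
        vid = variant.ID
        if known_sites is not None:
            annotated.append(vid is not None and vid in known_sites)
        else:
            annotated.append(vid is not None and vid != ".")

        geno_rows.append(_GT_TYPE_MAP[variant.gt_types])
        try:
            gq = variant.gt_quals
            gq = np.where(np.isnan(gq) | (gq < 0), 0, gq).astype(np.int32)
        except Exception:
            gq = np.zeros(len(samples), dtype=np.int32)
        gq_rows.append(gq)

        hap = np.full((len(samples), 2), MISSING, dtype=np.int8)
        for s_idx, call in enumerate(variant.genotypes):
            a0, a1 = call[0], call[1]
            hap[s_idx, 0] = a0 if a0 >= 0 else MISSING
            hap[s_idx, 1] = a1 if a1 >= 0 else MISSING
            if a0 >= 0 and a1 >= 0 and a0 != a1 and not call[2]:
                all_phased = False
        hap_rows.append(hap)
    vcf.close()

    if n_skipped:
        log.info("%s: skipped %d non-bi-allelic-SNV record(s)", path, n_skipped)
    if not chroms:
        raise ValueError(f"{path}: no bi-allelic SNVs found")

    chrom_arr = np.asarray(chroms, dtype=object)
    pos_arr = np.asarray(pos, dtype=np.int64)
    cm_arr = np.empty(len(pos), dtype=float)
    for c in seen_order:
        m = np.array([x == c for x in chroms])
        cm_arr[m] = gmap.interpolate(c, pos_arr[m])

    genotypes = np.stack(geno_rows, axis=1)          # (s, n)
    gq_arr = np.stack(gq_rows, axis=1)
    haplotypes = np.stack(hap_rows, axis=2)          # (s, 2, n)

    return Cohort(
        samples=samples,
        chrom=chrom_arr,
        pos_bp=pos_arr,
        cm=cm_arr,
        ref=np.asarray(ref, dtype=object),
        alt=np.asarray(alt, dtype=object),
        annotated=np.asarray(annotated, dtype=bool),
        genotypes=genotypes,
        gq=gq_arr,
        haplotypes=haplotypes if all_phased else None,
        phased=all_phased,
    )


_GENO_TO_HAPS = {0: (0, 0), 2: (1, 1)}


def write_vcf(cohort: Cohort, path, extra_headers: list[str] | None = None) -> None:
    """Write a cohort as a VCFv4.2 text file with GT and GQ fields.

    Annotated sites get a synthetic ``rs<index>`` ID; novel sites get
    ``.``, so a read-back without an explicit catalogue reproduces the
    annotation flags.  Phased cohorts use ``|`` separators.
    """
    sep = "|" if cohort.phased else "/"
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for line in extra_headers or []:
            fh.write(line.rstrip("\n") + "\n")
        for c in cohort.chroms:
            lo, hi = cohort.chrom_range(c)
            fh.write(f"##contig=<ID={c},length={int(cohort.pos_bp[hi - 1]) + 1}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype Quality">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(cohort.samples)
            + "\n"
        )
        for m in range(cohort.n_sites):
            vid = f"rs{m + 1}" if cohort.annotated[m] else "."
            cols = [
                str(cohort.chrom[m]),
                str(int(cohort.pos_bp[m])),
                vid,
                str(cohort.ref[m]),
                str(cohort.alt[m]),
                ".",
                "PASS",
                ".",
                "GT:GQ",
            ]
            for s in range(cohort.n_samples):
                g = int(cohort.genotypes[s, m])
                if g == MISSING:
                    gt = f".{sep}."
                elif cohort.phased:
                    a0 = int(cohort.haplotypes[s, 0, m])
                    a1 = int(cohort.haplotypes[s, 1, m])
                    gt = f"{a0}{sep}{a1}"
                else:
                    a0, a1 = _GENO_TO_HAPS.get(g, (0, 1))
                    gt = f"{a0}{sep}{a1}"
                cols.append(f"{gt}:{int(cohort.gq[s, m])}")
            fh.write("\t".join(cols) + "\n")


def read_genetic_map(path) -> GeneticMap:
    """Read a whitespace-delimited ``chrom bp cM`` genetic map file."""
    points: dict[str, list[tuple[float, float]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: expected 'chrom bp cM'")
            points.setdefault(fields[0], []).append((float(fields[1]), float(fields[2])))
    if not points:
        raise ValueError(f"{path}: empty genetic map")
    return GeneticMap(points)


def read_plink_map(path) -> GeneticMap:
    """Read a PLINK ``.map`` file (``chrom id cM bp``)."""
    points: dict[str, list[tuple[float, float]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) < 4:
                raise ValueError(f"{path}:{lineno}: expected 'chrom id cM bp'")
            points.setdefault(fields[0], []).append((float(fields[3]), float(fields[2])))
    if not points:
        raise ValueError(f"{path}: empty genetic map")
    return GeneticMap(points)


def write_genetic_map(gmap: GeneticMap, path) -> None:
    with open(path, "w") as fh:
        for chrom in gmap.chroms:
            bps, cms = gmap._points[chrom]
            for bp, cm in zip(bps, cms):
                fh.write(f"{chrom}\t{int(bp)}\t{float(cm)!r}\n")
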