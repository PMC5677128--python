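"""Phased-haplotype panel analyses: morph-specific SNPs and association mapping.

Works on a :class:`HaplotypeMatrix` — phased haplotypes x ordered SNP sites
with per-haplotype labels (sample, morph/group) — read from a phased VCF.
Two analyses are provided:

* :func:`morph_specific_sites` finds sites where a target group of
  haplotypes (e.g. *theseus*) shares an allele absent from a reference
  group (e.g. *polytes*), with a configurable tolerance for missing or
  discordant calls in the target group, and
* :func:`site_association` runs a per-site exact allele x group test with
  Benjamini-Hochberg FDR correction across sites.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .mk import benjamini_hochberg, fisher_exact_rxc

__all__ = [
    "HaplotypeMatrix",
    "MorphSpecificSiteReport",
    "AssociationResult",
    "read_phased_vcf",
    "write_phased_vcf",
    "morph_specific_sites",
    "shared_specific_sites",
    "site_association",
]

MISSING = -1


@dataclass
class HaplotypeMatrix:
    """Phased alleles (haplotypes x sites) with labels.

    alleles : (n_haplotypes, n_sites) integer array; 0 = reference allele,
        1.. = alternative alleles, -1 = missing call
    positions : strictly increasing 1-based positions on ``contig``
    site_alleles : per site, the (REF, ALT1, ...) allele strings
    labels : DataFrame indexed by haplotype id (two per sample), carrying at
        least a ``sample`` column; analysis group columns are free-form
    """

    contig: str
    positions: np.ndarray
    alleles: np.ndarray
    labels: pd.DataFrame
    site_alleles: list[tuple[str, ...]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.alleles = np.asarray(self.alleles, dtype=np.int16)
        if self.alleles.ndim != 2:
            raise ValueError("alleles must be 2-D (haplotypes x sites)")
        if self.alleles.shape[1] != self.positions.size:
            raise ValueError("number of sites does not match positions")
        if self.positions.size > 1 and not (np.diff(self.positions) > 0).all():
            raise ValueError("positions must be strictly increasing")
        if len(self.labels) != self.alleles.shape[0]:
            raise ValueError("every haplotype row needs a label row")
        if not self.site_alleles:
            self.site_alleles = [
                ("A", "T") for _ in range(self.positions.size)
            ]

    @property
    def n_haplotypes(self) -> int:
        return self.alleles.shape[0]

    @property
    def n_sites(self) -> int:
        return self.alleles.shape[1]

    def group_rows(self, column: str, value: str) -> np.ndarray:
        """Row indices of haplotypes whose label ``column`` equals ``value``."""
        mask = (self.labels[column] == value).to_numpy()
        idx = np.nonzero(mask)[0]
        if idx.size == 0:
            raise ValueError(f"no haplotypes with {column} == {value!r}")
        return idx


def read_phased_vcf(
    path: str | Path,
    sample_labels: Mapping[str, Mapping[str, str]] | None = None,
    require_phased: bool = True,
) -> HaplotypeMatrix:
    """Read a phased diploid VCF into a HaplotypeMatrix (two rows per sample).

    ``sample_labels`` maps sample name to extra label columns (e.g.
    ``{"ind1": {"group": "theseus"}}``).  Heterozygous unphased genotypes
    raise an error naming the offending record; unphased homozygotes are
    accepted (their phase is unambiguous).
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    positions: list[int] = []
    site_alleles: list[tuple[str, ...]] = []
    columns: list[np.ndarray] = []
    contig = None
    for variant in vcf:
        if contig is None:
            contig = variant.CHROM
        elif variant.CHROM != contig:
            raise ValueError("matrix must live on a single contig")
        col = np.empty(2 * len(samples), dtype=np.int16)
        for s, gt in enumerate(variant.genotypes):
            a0, a1, phased = gt[0], gt[1], gt[-1]
            if (
                require_phased
                and not phased
                and a0 >= 0
                and a1 >= 0
                and a0 != a1
            ):
                raise ValueError(
                    f"unphased heterozygous genotype for sample "
                    f"{samples[s]!r} at {variant.CHROM}:{variant.POS}"
                )
            col[2 * s] = a0 if a0 >= 0 else MISSING
            col[2 * s + 1] = a1 if a1 >= 0 else MISSING
        positions.append(variant.POS)
        site_alleles.append((variant.REF, *variant.ALT))
        columns.append(col)
    vcf.close()
    if contig is None:
        raise ValueError(f"no variant records in {path}")
    hap_ids = [f"{s}_h{i}" for s in samples for i in (1, 2)]
    rows = {"sample": [s for s in samples for _ in (1, 2)]}
    labels = pd.DataFrame(rows, index=hap_ids)
    if sample_labels:
        extra = pd.DataFrame.from_dict(sample_labels, orient="index")
        for col_name in extra.columns:
            labels[col_name] = [
                extra[col_name].get(s) for s in labels["sample"]
            ]
    return HaplotypeMatrix(
        contig=contig,
        positions=np.array(positions),
        alleles=np.vstack(columns).T,
        labels=labels,
        site_alleles=site_alleles,
    )


def write_phased_vcf(matrix: HaplotypeMatrix, path: str | Path) -> None:
    """Write the matrix back out as a phased diploid VCF (plain text)."""
    samples = list(dict.fromkeys(matrix.labels["sample"]))
    sample_rows = {
        s: [i for i, samp in enumerate(matrix.labels["sample"]) if samp == s]
        for s in samples
    }
    for s, rows in sample_rows.items():
        if len(rows) != 2:
            raise ValueError(f"sample {s!r} must have exactly two haplotypes")
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##contig=<ID={matrix.contig}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(samples)
            + "\n"
        )
        for j in range(matrix.n_sites):
            alleles = matrix.site_alleles[j]
            ref, alts = alleles[0], alleles[1:]
            alt_field = ",".join(alts) if alts else "."
            gts = []
            for s in samples:
                r1, r2 = sample_rows[s]
                a = [matrix.alleles[r1, j], matrix.alleles[r2, j]]
                gts.append(
                    "|".join("." if x == MISSING else str(int(x)) for x in a)
                )
            fh.write(
                f"{matrix.contig}\t{matrix.positions[j]}\t.\t{ref}\t{alt_field}"
                f"\t.\tPASS\t.\tGT\t" + "\t".join(gts) + "\n"
            )


@dataclass(frozen=True)
class MorphSpecificSiteReport:
    """Sites carrying a target-group-specific allele."""

    positions: tuple[int, ...]
    table: pd.DataFrame  # position, allele, n_support, n_exceptions
    target_group: str
    reference_group: str
    max_exceptions_target: int
    max_exceptions_reference: int


def morph_specific_sites(
    matrix: HaplotypeMatrix,
    target_group: str,
    reference_group: str,
    max_exceptions_target: int = 0,
    max_exceptions_reference: int = 0,
    group_column: str = "group",
) -> MorphSpecificSiteReport:
    """Sites where the target group shares an allele absent from the reference.

    A site qualifies if some allele is carried by all target haplotypes with
    at most ``max_exceptions_target`` exceptions (a missing call or a
    different allele both count as exceptions) and at most
    ``max_exceptions_reference`` reference haplotypes carry that allele
    (default: none may).  When several alleles qualify at a site the best
    supported one is reported.
    """
    t_rows = matrix.group_rows(group_column, target_group)
    r_rows = matrix.group_rows(group_column, reference_group)
    if set(t_rows) & set(r_rows):
        raise ValueError("target and reference groups must be disjoint")
    records = []
    for j in range(matrix.n_sites):
        t_col = matrix.alleles[t_rows, j]
        r_col = matrix.alleles[r_rows, j]
        best = None
        for allele in np.unique(t_col):
            if allele == MISSING:
                continue
            support = int((t_col == allele).sum())
            exceptions = t_col.size - support
            if exceptions > max_exceptions_target:
                continue
            if int((r_col == allele).sum()) > max_exceptions_reference:
                continue
            if best is None or support > best[1]:
                best = (int(allele), support, exceptions)
        if best is not None:
            records.append(
                {
                    "position": int(matrix.positions[j]),
                    "allele": best[0],
                    "n_support": best[1],
                    "n_exceptions": best[2],
                }
            )
    table = pd.DataFrame(
        records, columns=["position", "allele", "n_support", "n_exceptions"]
    )
    return MorphSpecificSiteReport(
        positions=tuple(table["position"]),
        table=table,
        target_group=target_group,
        reference_group=reference_group,
        max_exceptions_target=max_exceptions_target,
        max_exceptions_reference=max_exceptions_reference,
    )


def shared_specific_sites(
    report_a: MorphSpecificSiteReport,
    report_b: MorphSpecificSiteReport,
    match_allele: bool = False,
) -> set:
    """Positions reported in both analyses (optionally requiring the same allele)."""
    if match_allele:
        a = set(zip(report_a.table["position"], report_a.table["allele"]))
        b = set(zip(report_b.table["position"], report_b.table["allele"]))
    else:
        a, b = set(report_a.positions), set(report_b.positions)
    return a & b


@dataclass(frozen=True)
class AssociationResult:
    """Per-site exact-test p and BH-adjusted q for a two-group comparison."""

    table: pd.DataFrame  # position, p, q
    group_sizes: tuple[int, int]
    groups: tuple[str, str]


def site_association(
    matrix: HaplotypeMatrix,
    groups: tuple[str, str],
    group_column: str = "group",
) -> AssociationResult:
    """Exact allele x group test per site, BH-corrected across all sites.

    Missing calls are excluded from each site's contingency table;
    monomorphic sites get p = 1 and still enter the BH correction.
    """
    rows_a = matrix.group_rows(group_column, groups[0])
    rows_b = matrix.group_rows(group_column, groups[1])
    if rows_a.size < 2 or rows_b.size < 2:
        raise ValueError("each group needs at least two haplotypes")
    ps = []
    for j in range(matrix.n_sites):
        col_a = matrix.alleles[rows_a, j]
        col_b = matrix.alleles[rows_b, j]
        col_a = col_a[col_a != MISSING]
        col_b = col_b[col_b != MISSING]
        alleles = np.unique(np.concatenate([col_a, col_b]))
        if alleles.size < 2:
            ps.append(1.0)
            continue
        table = np.array(
            [
                [(col_a == a).sum() for a in alleles],
                [(col_b == a).sum() for a in alleles],
            ]
        )
        ps.append(fisher_exact_rxc(table.T).p)
    q = benjamini_hochberg(ps)
    df = pd.DataFrame(
        {"position": matrix.positions, "p": ps, "q": q}
    )
    return AssociationResult(
        table=df, group_sizes=(rows_a.size, rows_b.size), groups=groups
    )
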