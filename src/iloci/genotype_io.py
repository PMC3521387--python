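"""Genotype data containers and I/O for case/control SNP datasets.

Genotypes are stored SNP-by-individual as small integer codes:

====  =========================
code  meaning
====  =========================
0     homozygous wild (w)
1     heterozygous (h)
2     homozygous variant (v)
-9    missing
====  =========================

"Wild" and "variant" are assigned per SNP as the major and minor allele in
the pooled case+control sample (lexicographic tie-break).  The downstream
pair statistic is invariant to which allele is called wild — swapping the
labels at one SNP negates the per-group correlations simultaneously and
leaves their contrast unchanged — so only reproducibility is at stake in
this convention.

Supported formats: PLINK text (.ped/.map), a simple tab-separated
SNP-by-individual dialect (see :func:`read_genotype_tsv`), and BED3 interval
files for gene-region filtering.  Coordinates are 0-based half-open
internally; .map positions (1-based) are converted on read.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

MISSING = -9

__all__ = [
    "MISSING",
    "GenotypeMatrix",
    "PhenotypeLabels",
    "RegionSet",
    "GenotypeParseError",
    "assign_alleles",
    "read_plink_text",
    "read_genotype_tsv",
    "write_genotype_tsv",
    "read_bed3",
    "filter_maf",
    "filter_regions",
    "maf",
]

_VALID_CODES = frozenset({0, 1, 2, MISSING})


class GenotypeParseError(ValueError):
    """Raised when an input genotype file violates its format contract."""


@dataclass
class GenotypeMatrix:
    """SNP-by-individual genotype codes plus per-SNP metadata.

    ``genotypes`` has shape (n_snps, n_samples), dtype int8, values in
    {0, 1, 2, -9}.  ``alleles[i]`` is the (wild, variant) pair; the variant
    slot is ``"."`` for monomorphic SNPs.
    """

    snp_ids: list[str]
    chrom: list[str]
    pos: np.ndarray  # int64, 0-based
    alleles: list[tuple[str, str]]
    genotypes: np.ndarray  # int8, (n_snps, n_samples)
    sample_ids: list[str]

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        bad = ~np.isin(self.genotypes, list(_VALID_CODES))
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise GenotypeParseError(
                f"invalid genotype code {self.genotypes[i, j]} at SNP "
                f"{self.snp_ids[i]!r}, sample {self.sample_ids[j]!r}"
            )
        if len(set(self.snp_ids)) != len(self.snp_ids):
            raise GenotypeParseError("duplicate SNP ids")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise GenotypeParseError("duplicate sample ids")
        if (self.pos < 0).any():
            raise GenotypeParseError("negative base-pair position")
        if self.genotypes.shape != (len(self.snp_ids), len(self.sample_ids)):
            raise GenotypeParseError(
                f"genotype matrix shape {self.genotypes.shape} does not match "
                f"{len(self.snp_ids)} SNPs x {len(self.sample_ids)} samples"
            )

    @property
    def n_snps(self) -> int:
        return len(self.snp_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def take_snps(self, index: np.ndarray) -> "GenotypeMatrix":
        """Subset SNPs (order-preserving) by integer index array."""
        index = np.asarray(index, dtype=np.intp)
        return GenotypeMatrix(
            snp_ids=[self.snp_ids[i] for i in index],
            chrom=[self.chrom[i] for i in index],
            pos=self.pos[index],
            alleles=[self.alleles[i] for i in index],
            genotypes=self.genotypes[index],
            sample_ids=list(self.sample_ids),
        )


@dataclass
class PhenotypeLabels:
    """Binary case/control status aligned to a GenotypeMatrix's samples."""

    sample_ids: list[str]
    status: np.ndarray  # bool, True = case

    def __post_init__(self) -> None:
        self.status = np.asarray(self.status, dtype=bool)
        if len(self.sample_ids) != self.status.size:
            raise ValueError("sample_ids and status length mismatch")
        if self.n_case < 1 or self.n_control < 1:
            raise ValueError("need at least one case and one control")

    @property
    def case_mask(self) -> np.ndarray:
        return self.status

    @property
    def control_mask(self) -> np.ndarray:
        return ~self.status

    @property
    def n_case(self) -> int:
        return int(self.status.sum())

    @property
    def n_control(self) -> int:
        return int((~self.status).sum())

    def check_aligned(self, gm: GenotypeMatrix) -> None:
        if self.sample_ids != gm.sample_ids:
            raise ValueError("phenotype sample ids do not match genotype matrix")


@dataclass
class RegionSet:
    """Genomic intervals (chrom, start, end), 0-based half-open, plus a flank.

    ``expanded()`` grows every interval by ``flank`` bp on both sides,
    clipping starts at 0 — the "within N kb of a gene model" convention.
    """

    intervals: list[tuple[str, int, int]] = field(default_factory=list)
    flank: int = 0

    def __post_init__(self) -> None:
        if self.flank < 0:
            raise ValueError("flank must be non-negative")
        for chrom, start, end in self.intervals:
            if start >= end:
                raise ValueError(f"empty interval {chrom}:{start}-{end}")

    def expanded(self) -> list[tuple[str, int, int]]:
        return [
            (chrom, max(0, start - self.flank), end + self.flank)
            for chrom, start, end in self.intervals
        ]


def assign_alleles(allele_counts: dict[str, int]) -> tuple[str, str, bool]:
    """Assign (wild, variant) for one SNP from pooled allele counts.

    Wild is the major allele over cases+controls combined; ties break
    lexicographically (alphabetically first allele is wild).  Returns
    ``(wild, variant, monomorphic)``; a monomorphic SNP gets variant ``"."``.

    Raises for >2 observed alleles (the 3x3 genotype model is biallelic).
    """
    observed = {a: c for a, c in allele_counts.items() if c > 0}
    if len(observed) > 2:
        raise GenotypeParseError(
            f"more than two alleles observed: {sorted(observed)}"
        )
    if not observed:
        raise GenotypeParseError("no observed alleles")
    # sort by (-count, allele): majority rule, then lexicographic
    ranked = sorted(observed.items(), key=lambda kv: (-kv[1], kv[0]))
    if len(ranked) == 1:
        return ranked[0][0], ".", True
    return ranked[0][0], ranked[1][0], False


def read_plink_text(ped_path, map_path) -> tuple[GenotypeMatrix, PhenotypeLabels]:
    """Read PLINK text format (.ped/.map) into coded genotypes.

    .ped columns: FID IID PAT MAT SEX PHENO, then two allele columns per
    SNP; missing allele is "0".  Phenotype must be 1 (control) or 2 (case).
    .map columns: chrom, snp_id, genetic distance, bp position (1-based;
    converted to 0-based).
    """
    snp_ids: list[str] = []
    chroms: list[str] = []
    positions: list[int] = []
    with open(map_path) as fh:
        for ln, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) < 4:
                raise GenotypeParseError(f"{map_path}: line {ln}: expected 4 columns")
            chroms.append(parts[0])
            snp_ids.append(parts[1])
            positions.append(int(parts[3]) - 1)  # 1-based -> 0-based
    n_snps = len(snp_ids)
    if n_snps == 0:
        raise GenotypeParseError(f"{map_path}: no SNPs")

    sample_ids: list[str] = []
    status: list[bool] = []
    allele_rows: list[list[str]] = []  # per sample: 2*n_snps allele strings
    with open(ped_path) as fh:
        for ln, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 6 + 2 * n_snps:
                raise GenotypeParseError(
                    f"{ped_path}: line {ln}: expected {6 + 2 * n_snps} fields "
                    f"(6 + 2x{n_snps} SNP alleles), got {len(parts)}"
                )
            sample_ids.append(parts[1])
            pheno = parts[5]
            if pheno == "1":
                status.append(False)
            elif pheno == "2":
                status.append(True)
            else:
                raise GenotypeParseError(
                    f"{ped_path}: line {ln}: phenotype {pheno!r} not in {{1,2}}"
                )
            allele_rows.append(parts[6:])
    if not sample_ids:
        raise GenotypeParseError(f"{ped_path}: no samples")

    n_samples = len(sample_ids)
    codes = np.full((n_snps, n_samples), MISSING, dtype=np.int8)
    alleles: list[tuple[str, str]] = []
    for i in range(n_snps):
        counts: dict[str, int] = {}
        for row in allele_rows:
            for a in (row[2 * i], row[2 * i + 1]):
                if a != "0":
                    counts[a] = counts.get(a, 0) + 1
        if not counts:  # all-missing SNP: keep, flag monomorphic-by-absence
            alleles.append((".", "."))
            continue
        wild, variant, _ = assign_alleles(counts)
        alleles.append((wild, variant))
        for j, row in enumerate(allele_rows):
            a1, a2 = row[2 * i], row[2 * i + 1]
            if a1 == "0" or a2 == "0":
                continue  # half-missing treated as missing
            codes[i, j] = (a1 != wild) + (a2 != wild)

    gm = GenotypeMatrix(snp_ids, chroms, np.array(positions), alleles, codes, sample_ids)
    labels = PhenotypeLabels(sample_ids, np.array(status))
    return gm, labels


def read_genotype_tsv(path, labels_path) -> tuple[GenotypeMatrix, PhenotypeLabels]:
    """Read the package's genotype TSV dialect plus a labels file.

    The TSV has a header line of sample ids, then one row per SNP:
    ``snp_id  chrom  pos  wild  variant  code_1 ... code_N``; "#" lines are
    comments.  The labels file has two columns: sample_id, case|control.
    """
    sample_ids: list[str] | None = None
    snp_ids: list[str] = []
    chroms: list[str] = []
    positions: list[int] = []
    alleles: list[tuple[str, str]] = []
    rows: list[list[int]] = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t")
            if sample_ids is None:
                sample_ids = parts
                continue
            if len(parts) != 5 + len(sample_ids):
                raise GenotypeParseError(
                    f"{path}: line {ln}: expected {5 + len(sample_ids)} columns, "
                    f"got {len(parts)}"
                )
            snp_ids.append(parts[0])
            chroms.append(parts[1])
            positions.append(int(parts[2]))
            alleles.append((parts[3], parts[4]))
            row = []
            for j, tok in enumerate(parts[5:]):
                code = int(tok)
                if code not in _VALID_CODES:
                    raise GenotypeParseError(
                        f"{path}: invalid code {code} at SNP {parts[0]!r}, "
                        f"sample {sample_ids[j]!r}"
                    )
                row.append(code)
            rows.append(row)
    if sample_ids is None:
        raise GenotypeParseError(f"{path}: empty file")
    if not rows:
        raise GenotypeParseError(f"{path}: no SNPs")

    gm = GenotypeMatrix(
        snp_ids, chroms, np.array(positions), alleles,
        np.array(rows, dtype=np.int8), sample_ids,
    )
    labels = read_labels_tsv(labels_path)
    labels.check_aligned(gm)
    return gm, labels


def read_labels_tsv(path) -> PhenotypeLabels:
    sample_ids: list[str] = []
    status: list[bool] = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 2 or parts[1] not in ("case", "control"):
                raise GenotypeParseError(
                    f"{path}: line {ln}: expected 'sample_id case|control'"
                )
            sample_ids.append(parts[0])
            status.append(parts[1] == "case")
    return PhenotypeLabels(sample_ids, np.array(status))


def write_genotype_tsv(gm: GenotypeMatrix, labels: PhenotypeLabels, path, labels_path) -> None:
    """Write a GenotypeMatrix + labels in the TSV dialect (lossless round-trip)."""
    labels.check_aligned(gm)
    with open(path, "w") as fh:
        fh.write("\t".join(gm.sample_ids) + "\n")
        for i in range(gm.n_snps):
            wild, variant = gm.alleles[i]
            fields = [gm.snp_ids[i], gm.chrom[i], str(int(gm.pos[i])), wild, variant]
            fields.extend(str(int(c)) for c in gm.genotypes[i])
            fh.write("\t".join(fields) + "\n")
    with open(labels_path, "w") as fh:
        for sid, is_case in zip(labels.sample_ids, labels.status):
            fh.write(f"{sid}\t{'case' if is_case else 'control'}\n")


def read_bed3(path, flank: int = 0) -> RegionSet:
    """Read a BED3 file (chrom, start, end; 0-based half-open) into a RegionSet."""
    intervals: list[tuple[str, int, int]] = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split()
            if len(parts) < 3:
                raise GenotypeParseError(f"{path}: line {ln}: expected >=3 BED columns")
            intervals.append((parts[0], int(parts[1]), int(parts[2])))
    return RegionSet(intervals=intervals, flank=flank)


def maf(gm: GenotypeMatrix) -> np.ndarray:
    """Per-SNP minor allele frequency over all non-missing genotypes.

    Computed from allele counts: each genotype contributes two alleles,
    code 1 contributing one of each.  Monomorphic SNPs get MAF 0.
    """
    g = gm.genotypes
    obs = g != MISSING
    n_alleles = 2 * obs.sum(axis=1)
    variant_alleles = np.where(obs, g, 0).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        freq = np.where(n_alleles > 0, variant_alleles / np.maximum(n_alleles, 1), 0.0)
    return np.minimum(freq, 1.0 - freq)


def filter_maf(gm: GenotypeMatrix, threshold: float) -> GenotypeMatrix:
    """Keep SNPs with minor allele frequency strictly above ``threshold``.

    The frequency is pooled over cases and controls together.  The strict
    inequality means a SNP at exactly the threshold is removed.
    """
    if not 0 <= threshold < 0.5:
        raise ValueError("MAF threshold must be in [0, 0.5)")
    keep = np.flatnonzero(maf(gm) > threshold)
    return gm.take_snps(keep)


def filter_regions(gm: GenotypeMatrix, regions: RegionSet) -> GenotypeMatrix:
    """Keep SNPs falling inside any interval after flank expansion.

    Inputs must share one genome build (caller's responsibility).  A warning
    lists genotype chromosomes absent from the region set.
    """
    expanded = regions.expanded()
    region_chroms = {c for c, _, _ in expanded}
    missing_chroms = sorted(set(gm.chrom) - region_chroms)
    if missing_chroms:
        warnings.warn(
            "chromosomes absent from region set: " + ", ".join(missing_chroms),
            stacklevel=2,
        )
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for c, s, e in expanded:
        by_chrom.setdefault(c, []).append((s, e))
    keep = [
        i
        for i in range(gm.n_snps)
        if any(s <= gm.pos[i] < e for s, e in by_chrom.get(gm.chrom[i], ()))
    ]
    return gm.take_snps(np.array(keep, dtype=np.intp))


def relabel_alleles(gm: GenotypeMatrix, snp_index: int) -> GenotypeMatrix:
    """Swap the wild/variant labels of one SNP (codes 0<->2; 1 and -9 fixed).

    Utility for invariance checks; the pair statistic's contrast is unchanged
    under this relabeling.
    """
    g = gm.genotypes.copy()
    row = g[snp_index]
    swapped = row.copy()
    swapped[row == 0] = 2
    swapped[row == 2] = 0
    g[snp_index] = swapped
    alleles = list(gm.alleles)
    w, v = alleles[snp_index]
    alleles[snp_index] = (v, w)
    return replace(gm, alleles=alleles, genotypes=g)
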