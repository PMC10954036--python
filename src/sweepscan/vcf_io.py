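"""Shared data model and standard-format I/O.

Coordinates are 1-based inclusive throughout the package (the VCF convention);
BED output converts at the boundary. Only biallelic SNPs are retained; anything
else is skipped with a logged count, never split.

The three in-memory containers are

``VariantTable``
    per-site coordinates and alleles, sorted by (scaffold, pos);
``HaplotypeSet``
    a (2·n_samples × n_sites) matrix of 0/1 allele codes (two rows per
    diploid, phase 0 then phase 1), -1 marking a missing call;
``PopulationMap``
    sample → population labels for the two-population contrasts.

Haplotype-level statistics (EHH and friends) refuse missing alleles; the
diploid dosage matrix tolerates them and per-site statistics use per-site
non-missing counts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from cyvcf2 import VCF

from .errors import DataError, ValidationError

logger = logging.getLogger(__name__)

MISSING = -1


@dataclass
class VariantTable:
    """Biallelic SNP coordinates, sorted by (scaffold, pos)."""

    scaffold: np.ndarray  # object/str array, one entry per site
    pos: np.ndarray  # int64, 1-based
    ref: np.ndarray
    alt: np.ndarray

    def __post_init__(self) -> None:
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.scaffold = np.asarray(self.scaffold, dtype=object)
        order_ok = True
        for name in self.scaffolds:
            p = self.pos[self.scaffold == name]
            if p.size > 1 and not np.all(np.diff(p) > 0):
                order_ok = False
        if not order_ok:
            raise DataError("positions must be strictly increasing within each scaffold")

    def __len__(self) -> int:
        return self.pos.size

    @property
    def scaffolds(self) -> list[str]:
        """Scaffold names in order of first appearance."""
        seen: dict[str, None] = {}
        for s in self.scaffold:
            seen.setdefault(s, None)
        return list(seen)

    def mask(self, scaffold: str) -> np.ndarray:
        return self.scaffold == scaffold

    def site_index(self) -> np.ndarray:
        """Dense 0-based index of each site within its scaffold."""
        out = np.empty(len(self), dtype=np.int64)
        for name in self.scaffolds:
            m = self.mask(name)
            out[m] = np.arange(m.sum())
        return out


@dataclass
class HaplotypeSet:
    """Phased 0/1 allele matrix, two rows per diploid sample."""

    alleles: np.ndarray  # int8, shape (2*n_samples, n_sites), -1 = missing
    sample_ids: list[str]

    def __post_init__(self) -> None:
        self.alleles = np.asarray(self.alleles, dtype=np.int8)
        if self.alleles.shape[0] != 2 * len(self.sample_ids):
            raise DataError(
                f"haplotype rows ({self.alleles.shape[0]}) != 2 x samples ({len(self.sample_ids)})"
            )
        bad = ~np.isin(self.alleles, (0, 1, MISSING))
        if bad.any():
            raise DataError("haplotype alleles must be 0, 1 or missing (-1)")

    @property
    def n_haplotypes(self) -> int:
        return self.alleles.shape[0]

    @property
    def haplotype_of_sample(self) -> list[tuple[str, int]]:
        """Row index -> (sample id, phase)."""
        return [(s, k) for s in self.sample_ids for k in (0, 1)]

    def require_complete(self, context: str = "this operation") -> None:
        if (self.alleles == MISSING).any():
            raise DataError(f"missing haplotype alleles are not supported by {context}")

    def rows_for_samples(self, samples: list[str]) -> np.ndarray:
        idx = {s: i for i, s in enumerate(self.sample_ids)}
        rows = []
        for s in samples:
            rows.extend((2 * idx[s], 2 * idx[s] + 1))
        return np.asarray(rows, dtype=np.int64)


@dataclass
class PopulationMap:
    """Sample → population assignment for two-population contrasts."""

    assignments: dict[str, str]
    populations: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.populations:
            seen: dict[str, None] = {}
            for p in self.assignments.values():
                seen.setdefault(p, None)
            self.populations = list(seen)

    def samples(self, population: str) -> list[str]:
        return [s for s, p in self.assignments.items() if p == population]

    def sample_indices(self, population: str, sample_ids: list[str]) -> np.ndarray:
        mine = set(self.samples(population))
        return np.asarray([i for i, s in enumerate(sample_ids) if s in mine], dtype=np.int64)

    def haplotype_rows(self, population: str, sample_ids: list[str]) -> np.ndarray:
        si = self.sample_indices(population, sample_ids)
        return np.sort(np.concatenate([2 * si, 2 * si + 1])) if si.size else np.empty(0, np.int64)


class ScaffoldInfo(dict):
    """scaffold id -> length in bp."""

    def validate(self, variants: VariantTable) -> None:
        for name in variants.scaffolds:
            if name not in self:
                raise DataError(f"scaffold {name!r} missing from scaffold lengths")
            top = int(variants.pos[variants.mask(name)].max())
            if self[name] < top:
                raise DataError(
                    f"scaffold {name!r} length {self[name]} < max SNP position {top}"
                )


def read_vcf(path, *, haplotypes: bool = True):
    """Read a VCF with GT fields.

    Returns ``(VariantTable, HaplotypeSet | None, genotypes, ScaffoldInfo)``
    where ``genotypes`` is a (n_samples × n_sites) int8 dosage matrix
    (0/1/2 alt-allele copies, -1 missing). Multi-allelic and non-SNP records
    are skipped with a logged count. When ``haplotypes`` is requested, any
    heterozygous unphased genotype is an error naming the offending sample
    and site (homozygous and missing calls carry no phase information and
    are accepted).
    """
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    if not samples:
        raise DataError(f"VCF {path} declares no samples")

    scaffolds: list[str] = []
    pos: list[int] = []
    ref: list[str] = []
    alt: list[str] = []
    hap_cols: list[np.ndarray] = []
    dose_cols: list[np.ndarray] = []
    n_skipped = 0

    for v in vcf:
        if len(v.ALT) != 1 or len(v.REF) != 1 or len(v.ALT[0]) != 1:
            n_skipped += 1
            continue
        gts = v.genotypes  # [[a0, a1, phased], ...]
        hap = np.empty(2 * len(samples), dtype=np.int8)
        for i, g in enumerate(gts):
            a0, a1 = g[0], g[1]
            phased = bool(g[2])
            a0 = MISSING if a0 < 0 else a0
            a1 = MISSING if a1 < 0 else a1
            if haplotypes and not phased and a0 != a1 and a0 != MISSING and a1 != MISSING:
                raise DataError(
                    f"unphased heterozygous genotype for sample {samples[i]!r} "
                    f"at {v.CHROM}:{v.POS}; phased GT required for haplotype output"
                )
            hap[2 * i] = a0
            hap[2 * i + 1] = a1
        scaffolds.append(v.CHROM)
        pos.append(v.POS)
        ref.append(v.REF)
        alt.append(v.ALT[0])
        hap_cols.append(hap)

    if not pos:
        raise DataError(f"VCF {path} contains no usable biallelic SNP records")
    if n_skipped:
        logger.info("read_vcf: skipped %d non-biallelic/non-SNP records", n_skipped)

    variants = VariantTable(
        np.asarray(scaffolds, dtype=object),
        np.asarray(pos, dtype=np.int64),
        np.asarray(ref, dtype=object),
        np.asarray(alt, dtype=object),
    )
    allele_matrix = np.stack(hap_cols, axis=1)  # (2n, S)
    a0 = allele_matrix[0::2].astype(np.int16)
    a1 = allele_matrix[1::2].astype(np.int16)
    genotypes = (a0 + a1).astype(np.int8)
    genotypes[(a0 == MISSING) | (a1 == MISSING)] = MISSING

    info = ScaffoldInfo()
    try:
        for name, length in zip(vcf.seqnames, vcf.seqlens):
            info[name] = int(length)
    except AttributeError:  # header without contig lengths
        pass

    hapset = HaplotypeSet(allele_matrix, samples) if haplotypes else None
    return variants, hapset, genotypes, info


def write_vcf(path, variants: VariantTable, hapset: HaplotypeSet,
              scaffold_info: ScaffoldInfo | None = None) -> None:
    """Write a minimal phased VCF 4.2 (GT only, '|' separators)."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=sweepscan\n")
        if scaffold_info:
            for name, length in scaffold_info.items():
                fh.write(f"##contig=<ID={name},length={length}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(hapset.sample_ids) + "\n")
        A = hapset.alleles
        for j in range(len(variants)):
            col = A[:, j]
            gts = []
            for i in range(len(hapset.sample_ids)):
                a0, a1 = col[2 * i], col[2 * i + 1]
                s0 = "." if a0 == MISSING else str(int(a0))
                s1 = "." if a1 == MISSING else str(int(a1))
                gts.append(f"{s0}|{s1}")
            fh.write(f"{variants.scaffold[j]}\t{variants.pos[j]}\t.\t{variants.ref[j]}\t"
                     f"{variants.alt[j]}\t.\tPASS\t.\tGT\t" + "\t".join(gts) + "\n")


def read_popmap(path, vcf_samples: list[str] | None = None,
                pop_pair: tuple[str, str] | None = None) -> PopulationMap:
    """Read a two-column (sample TAB population) map.

    Samples present in the VCF but absent from the map are an error; extra
    map samples produce a warning. With ``pop_pair``, samples from other
    populations are dropped with a log message.
    """
    assignments: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise DataError(f"{path}:{lineno}: expected 'sample<TAB>population'")
            sample, pop = parts
            if sample in assignments and assignments[sample] != pop:
                raise DataError(
                    f"{path}: sample {sample!r} assigned to both "
                    f"{assignments[sample]!r} and {pop!r}"
                )
            assignments[sample] = pop
    if vcf_samples is not None:
        missing = [s for s in vcf_samples if s not in assignments]
        if missing:
            raise DataError(f"samples missing from popmap: {', '.join(missing)}")
        extra = [s for s in assignments if s not in set(vcf_samples)]
        if extra:
            logger.warning("popmap samples not in VCF (ignored): %s", ", ".join(extra))
            for s in extra:
                del assignments[s]
    if pop_pair is not None:
        dropped = [s for s, p in assignments.items() if p not in pop_pair]
        if dropped:
            logger.info("dropping %d samples outside populations %s", len(dropped), pop_pair)
            for s in dropped:
                del assignments[s]
        return PopulationMap(assignments, populations=list(pop_pair))
    return PopulationMap(assignments)


def read_scaffold_lengths(path) -> ScaffoldInfo:
    """Read a two-column (scaffold TAB length) table."""
    info = ScaffoldInfo()
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise DataError(f"{path}:{lineno}: expected 'scaffold<TAB>length'")
            info[parts[0]] = int(parts[1])
    return info


def write_regions(regions, path, dialect: str = "tsv") -> None:
    """Write regions as TSV (1-based inclusive) or BED (0-based half-open).

    ``regions`` is an iterable with ``scaffold``/``start``/``end`` attributes
    or (scaffold, start, end) tuples, coordinates 1-based inclusive.
    """
    if dialect not in ("tsv", "bed"):
        raise ValidationError(f"unknown region dialect {dialect!r}")
    rows = []
    for r in regions:
        scaf, start, end = (
            (r.scaffold, r.start, r.end) if hasattr(r, "scaffold") else (r[0], r[1], r[2])
        )
        if start > end:
            raise DataError(f"region start {start} > end {end} on {scaf}")
        rows.append((scaf, int(start), int(end)))
    with open(path, "w") as fh:
        if dialect == "tsv":
            fh.write("# coordinates: 1-based inclusive (TSV dialect)\n")
            fh.write("scaffold\tstart\tend\n")
            for scaf, start, end in rows:
                fh.write(f"{scaf}\t{start}\t{end}\n")
        else:
            fh.write("# coordinates: 0-based half-open (BED dialect)\n")
            for scaf, start, end in rows:
                fh.write(f"{scaf}\t{start - 1}\t{end}\n")


def read_regions(path):
    """Inverse of :func:`write_regions`; returns (scaffold, start, end) tuples, 1-based."""
    out = []
    bed = False
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line.startswith("#"):
                bed = "BED dialect" in line
                continue
            if not line or line.startswith("scaffold\t"):
                continue
            scaf, start, end = line.split("\t")[:3]
            start, end = int(start), int(end)
            out.append((scaf, start + 1, end) if bed else (scaf, start, end))
    return out
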