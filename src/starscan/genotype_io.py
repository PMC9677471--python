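"""Genotype input, population assignment, and dataset validation.

Everything downstream works on derived-allele counts. A :class:`GenotypeMatrix`
holds diploid genotypes as codes in {0, 1, 2} (number of derived alleles the
individual carries at the site). Genotypes must be diploid, biallelic and
complete: a missing call is a hard error, not silently imputed.

Polarity convention: the ALT allele is assumed derived. If the VCF carries an
ancestral-allele annotation (``INFO/AA``) and it equals ALT, the REF allele is
treated as derived and the codes are flipped (``g -> 2 - g``); if AA matches
neither allele the site is dropped and counted in the log.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pysam

logger = logging.getLogger(__name__)

__all__ = [
    "Site",
    "GenotypeMatrix",
    "PopulationAssignment",
    "GenotypeError",
    "read_vcf",
    "write_vcf",
    "read_population_map",
    "validate_dataset",
]


class GenotypeError(ValueError):
    """Raised when genotype data violate the diploid/biallelic/no-missing contract."""


@dataclass(frozen=True)
class Site:
    """One biallelic SNP. ``pos`` is 1-based (VCF convention)."""

    chrom: str
    pos: int
    ref_allele: str
    alt_allele: str
    derived_is_alt: bool = True

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if self.ref_allele == self.alt_allele:
            raise ValueError("ref and alt alleles must differ")


class GenotypeMatrix:
    """Sites x individuals matrix of derived-allele counts.

    Parameters
    ----------
    chroms, pos : arrays of length n_sites
        Chromosome name and 1-based position per site. Sites must be sorted by
        (chrom, pos) with strictly increasing positions within a chromosome.
    ref_alleles, alt_alleles : sequences of str
    derived_is_alt : bool array
        Polarity flag per site; codes in ``G`` are always derived counts
        regardless of polarity.
    samples : list of str
    G : (n_sites, n_samples) integer array with values in {0, 1, 2}
    """

    def __init__(self, chroms, pos, ref_alleles, alt_alleles, derived_is_alt,
                 samples, G):
        self.chroms = np.asarray(chroms, dtype=object)
        self.pos = np.asarray(pos, dtype=np.int64)
        self.ref_alleles = list(ref_alleles)
        self.alt_alleles = list(alt_alleles)
        self.derived_is_alt = np.asarray(derived_is_alt, dtype=bool)
        self.samples = list(samples)
        self.G = np.asarray(G, dtype=np.int8)
        if self.G.shape != (len(self.pos), len(self.samples)):
            raise ValueError(
                f"G has shape {self.G.shape}, expected "
                f"({len(self.pos)}, {len(self.samples)})")
        self._sample_index = {s: i for i, s in enumerate(self.samples)}

    @property
    def n_sites(self) -> int:
        return len(self.pos)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def sample_index(self, sample: str) -> int:
        try:
            return self._sample_index[sample]
        except KeyError:
            raise KeyError(f"unknown sample {sample!r}") from None

    def sample_indices(self, samples) -> np.ndarray:
        return np.array([self.sample_index(s) for s in samples], dtype=np.intp)

    def site(self, i: int) -> Site:
        return Site(str(self.chroms[i]), int(self.pos[i]), self.ref_alleles[i],
                    self.alt_alleles[i], bool(self.derived_is_alt[i]))

    def chromosomes(self) -> list[str]:
        seen: list[str] = []
        for c in self.chroms:
            if not seen or seen[-1] != c:
                seen.append(str(c))
        return seen

    def chrom_mask(self, chrom: str) -> np.ndarray:
        return self.chroms == chrom

    def take_sites(self, index) -> "GenotypeMatrix":
        """Row-subset preserving order (index may be a boolean mask or indices)."""
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        return GenotypeMatrix(
            self.chroms[index], self.pos[index],
            [self.ref_alleles[i] for i in index],
            [self.alt_alleles[i] for i in index],
            self.derived_is_alt[index], self.samples, self.G[index])

    def flip_polarity(self, index) -> "GenotypeMatrix":
        """Return a copy with derived polarity flipped at the given sites."""
        index = np.asarray(index)
        flipped = self.derived_is_alt.copy()
        flipped[index] = ~flipped[index]
        G = self.G.copy()
        G[index] = 2 - G[index]
        return GenotypeMatrix(self.chroms, self.pos, self.ref_alleles,
                              self.alt_alleles, flipped, self.samples, G)


@dataclass
class PopulationAssignment:
    """Role assignment of samples: reference, target, and up to two sources.

    The reference population is assumed free of introgressed fragments; the
    target population is scanned for them. Sources are donor panels used only
    for match-rate attribution.
    """

    reference_ids: list[str]
    target_ids: list[str]
    sources: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        groups = [("reference", self.reference_ids), ("target", self.target_ids)]
        groups += [(f"source {k!r}", v) for k, v in self.sources.items()]
        for name, ids in groups:
            if not ids:
                raise ValueError(f"{name} population is empty")
        seen: dict[str, str] = {}
        for name, ids in groups:
            for s in ids:
                if s in seen:
                    raise ValueError(
                        f"sample {s!r} assigned to both {seen[s]} and {name}")
                seen[s] = name

    @property
    def all_ids(self) -> list[str]:
        out = list(self.reference_ids) + list(self.target_ids)
        for ids in self.sources.values():
            out.extend(ids)
        return out


def read_population_map(path, ref_label: str, tgt_label: str,
                        src_labels=()) -> PopulationAssignment:
    """Read a headerless two-column map ``sample<TAB>population_label``.

    Roles are bound to labels by the caller: ``ref_label`` names the reference
    population, ``tgt_label`` the target, and ``src_labels`` (up to two) the
    source populations. Labels not mentioned are ignored.
    """
    src_labels = list(src_labels)
    if len(src_labels) > 2:
        raise ValueError("at most two source populations are supported")
    by_label: dict[str, list[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 2:
                raise ValueError(
                    f"{path}:{lineno}: expected 'sample<TAB>label', got {line!r}")
            sample, label = parts
            by_label.setdefault(label, []).append(sample)
    for role, label in [("reference", ref_label), ("target", tgt_label),
                        *[("source", s) for s in src_labels]]:
        if label not in by_label:
            raise ValueError(f"no samples with {role} label {label!r} in {path}")
    return PopulationAssignment(
        reference_ids=by_label[ref_label],
        target_ids=by_label[tgt_label],
        sources={s: by_label[s] for s in src_labels},
    )


def _decode_genotype(rec, sample: str):
    gt = rec.samples[sample].get("GT")
    if gt is None or any(a is None for a in gt):
        raise GenotypeError(
            f"missing genotype at {rec.chrom}:{rec.pos} for sample {sample!r}")
    if len(gt) != 2:
        raise GenotypeError(
            f"non-diploid genotype at {rec.chrom}:{rec.pos} for sample {sample!r}")
    return sum(gt)


def read_vcf(path, samples=None) -> GenotypeMatrix:
    """Read biallelic SNPs from a VCF (plain or bgzipped) into a GenotypeMatrix.

    Multiallelic and non-SNP records are skipped (counted in the log).
    Missing or non-diploid genotype calls are hard errors. Polarity follows the
    module convention (ALT derived unless INFO/AA says otherwise).
    """
    vf = pysam.VariantFile(str(path))
    vcf_samples = list(vf.header.samples)
    if samples is None:
        samples = vcf_samples
    else:
        missing = [s for s in samples if s not in set(vcf_samples)]
        if missing:
            raise GenotypeError(f"samples not in VCF: {missing}")
        samples = list(samples)

    chroms, pos, refs, alts, polarity, rows = [], [], [], [], [], []
    n_multi = n_nonsnp = n_bad_aa = 0
    for rec in vf:
        if rec.alts is None or len(rec.alts) != 1:
            n_multi += 1
            continue
        ref, alt = rec.ref, rec.alts[0]
        if len(ref) != 1 or len(alt) != 1:
            n_nonsnp += 1
            continue
        alt_counts = np.array([_decode_genotype(rec, s) for s in samples],
                              dtype=np.int8)
        aa = rec.info.get("AA")
        if isinstance(aa, tuple):
            aa = aa[0]
        if aa is not None:
            aa = str(aa).upper()
        derived_is_alt = True
        if aa == alt.upper():
            derived_is_alt = False
        elif aa is not None and aa != ref.upper():
            n_bad_aa += 1
            continue
        chroms.append(rec.chrom)
        pos.append(rec.pos)
        refs.append(ref)
        alts.append(alt)
        polarity.append(derived_is_alt)
        rows.append(alt_counts if derived_is_alt else 2 - alt_counts)
    vf.close()
    if n_multi:
        logger.info("skipped %d multiallelic record(s)", n_multi)
    if n_nonsnp:
        logger.info("skipped %d non-SNP record(s)", n_nonsnp)
    if n_bad_aa:
        logger.info("dropped %d site(s) whose INFO/AA matches neither allele",
                    n_bad_aa)
    n = len(pos)
    G = (np.vstack(rows) if n else np.empty((0, len(samples)), dtype=np.int8))
    gm = GenotypeMatrix(chroms, pos, refs, alts, polarity, samples, G)
    # Sort by position within each chromosome, keeping first-appearance
    # chromosome order (chr10 must not jump ahead of chr2).
    order = np.concatenate(
        [np.flatnonzero(gm.chrom_mask(c))[np.argsort(gm.pos[gm.chrom_mask(c)],
                                                     kind="stable")]
         for c in gm.chromosomes()]) if n else np.arange(0)
    if not np.array_equal(order, np.arange(n)):
        gm = gm.take_sites(order)
    return gm


def write_vcf(gm: GenotypeMatrix, path) -> None:
    """Write a GenotypeMatrix as an uncompressed VCF 4.2 file.

    Polarity is preserved through ``INFO/AA`` so that ``read_vcf`` round-trips
    the derived-allele codes exactly.
    """
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=AA,Number=1,Type=String,Description="Ancestral allele">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in gm.chromosomes():
            mask = gm.chrom_mask(chrom)
            length = int(gm.pos[mask].max()) + 1 if mask.any() else 1
            fh.write(f"##contig=<ID={chrom},length={length}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(gm.samples) + "\n")
        for i in range(gm.n_sites):
            derived_is_alt = bool(gm.derived_is_alt[i])
            aa = gm.ref_alleles[i] if derived_is_alt else gm.alt_alleles[i]
            alt_counts = gm.G[i] if derived_is_alt else 2 - gm.G[i]
            gts = "\t".join("0/0" if c == 0 else "0/1" if c == 1 else "1/1"
                            for c in alt_counts)
            fh.write(f"{gm.chroms[i]}\t{gm.pos[i]}\t.\t{gm.ref_alleles[i]}\t"
                     f"{gm.alt_alleles[i]}\t.\t.\tAA={aa}\tGT\t{gts}\n")


def validate_dataset(gm: GenotypeMatrix, assignment: PopulationAssignment) -> list[str]:
    """Check the dataset contract; return a list of violation messages.

    An empty list means the dataset is scoreable. Checks: all assigned samples
    present, codes within {0,1,2}, sites sorted with strictly increasing
    positions within each chromosome, no duplicated positions.
    """
    violations: list[str] = []
    for s in assignment.all_ids:
        if s not in gm._sample_index:
            violations.append(f"assigned sample {s!r} not in genotype matrix")
    bad = (gm.G < 0) | (gm.G > 2)
    if bad.any():
        i, j = np.argwhere(bad)[0]
        violations.append(
            f"{int(bad.sum())} genotype code(s) outside {{0,1,2}} "
            f"(first at {gm.chroms[i]}:{gm.pos[i]}, sample {gm.samples[j]!r})")
    for chrom in set(gm.chroms.tolist()):
        p = gm.pos[gm.chrom_mask(chrom)]
        if len(p) > 1 and not np.all(np.diff(p) > 0):
            violations.append(
                f"sites on {chrom} not strictly increasing in position")
    return violations
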