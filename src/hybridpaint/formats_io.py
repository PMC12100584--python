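"""Readers, writers and in-memory containers for the formats the pipeline touches.

External coordinates (VCF ``POS``, Beagle marker names) are 1-based, as the
formats require.  All internal interval arithmetic — windows, ancestry tracts —
is 0-based half-open.  Conversion happens exactly once, at read/write time.

Containers
----------
``SiteTable``        biallelic SNP coordinates shared by every downstream stage
``GenotypeMatrix``   alt-allele dosages {0, 1, 2, missing} with per-genotype depth
``LikelihoodMatrix`` per-genotype likelihood triples, the low-coverage substrate
``ChromosomeMap``    chromosome lengths, avian size classes, sex linkage
``PanelAssignment``  which individual plays which role (parental reference,
                     hybrid, outgroup) and its sex
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "MISSING",
    "ParseError",
    "ValidationError",
    "ChromosomeMap",
    "SiteTable",
    "GenotypeMatrix",
    "LikelihoodMatrix",
    "PanelAssignment",
    "classify_size",
    "read_vcf",
    "write_vcf",
    "read_beagle_gl",
    "write_beagle_gl",
    "read_panels",
    "write_panels",
    "read_chrom_map",
    "write_chrom_map",
]

#: Sentinel dosage for a missing genotype call.
MISSING = -1

_BASES = ("A", "C", "G", "T")
#: ANGSD-style integer allele codes used by some Beagle GL writers.
_ALLELE_CODES = {"0": "A", "1": "C", "2": "G", "3": "T"}

ROLES = ("parentA_ref", "parentB_ref", "hybrid", "outgroup")
SEXES = ("male", "female", "unknown")
SIZE_CLASSES = ("macro", "intermediate", "micro")


class ParseError(ValueError):
    """A file could not be parsed as its declared format."""


class ValidationError(ValueError):
    """Parsed content violates a container invariant."""


def classify_size(length: int) -> str:
    """Avian chromosome size class for a length in bp.

    Macro chromosomes are strictly longer than 40 Mbp and intermediate ones
    strictly longer than 20 Mbp; lengths exactly on a boundary fall into the
    smaller class (the class definitions use strict inequalities).
    """
    if length > 40_000_000:
        return "macro"
    if length > 20_000_000:
        return "intermediate"
    return "micro"


@dataclass(frozen=True)
class ChromosomeEntry:
    name: str
    length: int
    size_class: str
    sex_linked: bool = False


@dataclass
class ChromosomeMap:
    """Ordered chromosome metadata: name, length (bp), size class, sex linkage."""

    entries: list[ChromosomeEntry]

    def __post_init__(self) -> None:
        names = [e.name for e in self.entries]
        if len(set(names)) != len(names):
            raise ValidationError("duplicate chromosome names in map")
        for e in self.entries:
            if e.length <= 0:
                raise ValidationError(f"chromosome {e.name!r} has length {e.length} <= 0")
            expected = classify_size(e.length)
            if e.size_class != expected:
                raise ValidationError(
                    f"chromosome {e.name!r}: size_class {e.size_class!r} inconsistent "
                    f"with length {e.length} (expected {expected!r})"
                )

    @classmethod
    def from_lengths(
        cls, lengths: dict[str, int], sex_linked: Iterable[str] = ()
    ) -> "ChromosomeMap":
        linked = set(sex_linked)
        return cls(
            [
                ChromosomeEntry(n, l, classify_size(l), n in linked)
                for n, l in lengths.items()
            ]
        )

    @property
    def names(self) -> list[str]:
        return [e.name for e in self.entries]

    def length(self, chrom: str) -> int:
        return self._by_name[chrom].length

    def size_class(self, chrom: str) -> str:
        return self._by_name[chrom].size_class

    def is_sex_linked(self, chrom: str) -> bool:
        return self._by_name[chrom].sex_linked

    @property
    def sex_linked_names(self) -> set[str]:
        return {e.name for e in self.entries if e.sex_linked}

    @property
    def _by_name(self) -> dict[str, ChromosomeEntry]:
        return {e.name: e for e in self.entries}


@dataclass
class SiteTable:
    """Coordinates and alleles of biallelic SNPs, sorted within chromosome.

    ``pos`` is 1-based (the VCF convention).  Chromosome blocks keep their
    input order; positions are strictly increasing within each block.
    """

    chrom: np.ndarray  # str
    pos: np.ndarray  # int64, 1-based
    ref: np.ndarray  # single characters
    alt: np.ndarray

    def __post_init__(self) -> None:
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.ref = np.asarray(self.ref, dtype=object)
        self.alt = np.asarray(self.alt, dtype=object)
        n = len(self.chrom)
        if not (len(self.pos) == len(self.ref) == len(self.alt) == n):
            raise ValidationError("SiteTable column lengths differ")
        for arr, label in ((self.ref, "ref"), (self.alt, "alt")):
            bad = [a for a in arr if a not in _BASES]
            if bad:
                raise ValidationError(f"non-SNP {label} allele(s): {bad[:3]}")
        if any(r == a for r, a in zip(self.ref, self.alt)):
            raise ValidationError("ref == alt at some site")
        seen: set[tuple[str, int]] = set()
        last_chrom, last_pos = None, -1
        for c, p in zip(self.chrom, self.pos):
            if (c, p) in seen:
                raise ValidationError(f"duplicate site {c}:{p}")
            seen.add((c, int(p)))
            if c == last_chrom and p <= last_pos:
                raise ValidationError(f"unsorted positions on {c} near {p}")
            last_chrom, last_pos = c, p

    def __len__(self) -> int:
        return len(self.pos)

    @property
    def n_sites(self) -> int:
        return len(self.pos)

    def subset(self, idx: np.ndarray) -> "SiteTable":
        return SiteTable(self.chrom[idx], self.pos[idx], self.ref[idx], self.alt[idx])

    def chrom_indices(self, chrom: str) -> np.ndarray:
        return np.nonzero(self.chrom == chrom)[0]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"chrom": self.chrom, "pos": self.pos, "ref": self.ref, "alt": self.alt}
        )


@dataclass
class GenotypeMatrix:
    """Hard-called genotypes: sites x individuals alt-allele dosages plus depth."""

    sites: SiteTable
    individuals: list[str]
    dosage: np.ndarray  # (n_sites, n_ind) int8; MISSING = -1
    depth: np.ndarray  # (n_sites, n_ind) int32, >= 0

    def __post_init__(self) -> None:
        self.dosage = np.asarray(self.dosage, dtype=np.int8)
        self.depth = np.asarray(self.depth, dtype=np.int32)
        shape = (self.sites.n_sites, len(self.individuals))
        if self.dosage.shape != shape or self.depth.shape != shape:
            raise ValidationError(
                f"genotype arrays have shape {self.dosage.shape}, expected {shape}"
            )
        vals = np.unique(self.dosage)
        if not np.all(np.isin(vals, [MISSING, 0, 1, 2])):
            raise ValidationError(f"dosages outside {{missing,0,1,2}}: {vals}")
        if np.any(self.depth < 0):
            raise ValidationError("negative depth")
        if len(set(self.individuals)) != len(self.individuals):
            raise ValidationError("duplicate individual IDs")

    @property
    def n_sites(self) -> int:
        return self.sites.n_sites

    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    @property
    def called(self) -> np.ndarray:
        return self.dosage != MISSING

    def column(self, individual: str) -> int:
        try:
            return self.individuals.index(individual)
        except ValueError:
            raise KeyError(f"unknown individual {individual!r}") from None

    def subset_sites(self, idx: np.ndarray) -> "GenotypeMatrix":
        return GenotypeMatrix(
            self.sites.subset(idx), list(self.individuals), self.dosage[idx], self.depth[idx]
        )

    def subset_individuals(self, ids: Sequence[str]) -> "GenotypeMatrix":
        cols = [self.column(i) for i in ids]
        return GenotypeMatrix(
            self.sites, list(ids), self.dosage[:, cols], self.depth[:, cols]
        )


#: GL triples closer than this to exactly uniform are treated as "no data".
_UNIFORM_TOL = 1e-9


@dataclass
class LikelihoodMatrix:
    """Normalised genotype-likelihood triples P(data | dosage g), g in {0,1,2}.

    An exactly uniform triple encodes a genotype with no read support and is
    masked out of likelihood computations downstream.
    """

    sites: SiteTable
    individuals: list[str]
    gl: np.ndarray  # (n_sites, n_ind, 3) float64, rows sum to 1

    def __post_init__(self) -> None:
        self.gl = np.asarray(self.gl, dtype=np.float64)
        shape = (self.sites.n_sites, len(self.individuals), 3)
        if self.gl.shape != shape:
            raise ValidationError(f"gl has shape {self.gl.shape}, expected {shape}")
        if np.any(self.gl < 0):
            raise ValidationError("negative genotype likelihood")
        sums = self.gl.sum(axis=2)
        if self.gl.size and np.any(np.abs(sums - 1.0) > 1e-6):
            raise ValidationError("GL triples must sum to 1 within 1e-6")

    @property
    def n_sites(self) -> int:
        return self.sites.n_sites

    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    @property
    def missing(self) -> np.ndarray:
        """(n_sites, n_ind) bool mask of no-data (uniform) triples."""
        return np.all(np.abs(self.gl - 1.0 / 3.0) < _UNIFORM_TOL, axis=2)

    def column(self, individual: str) -> int:
        try:
            return self.individuals.index(individual)
        except ValueError:
            raise KeyError(f"unknown individual {individual!r}") from None

    def subset_sites(self, idx: np.ndarray) -> "LikelihoodMatrix":
        return LikelihoodMatrix(self.sites.subset(idx), list(self.individuals), self.gl[idx])

    def subset_individuals(self, ids: Sequence[str]) -> "LikelihoodMatrix":
        cols = [self.column(i) for i in ids]
        return LikelihoodMatrix(self.sites, list(ids), self.gl[:, cols, :])


@dataclass
class PanelAssignment:
    """Role (parental reference / hybrid / outgroup) and sex per individual."""

    role: dict[str, str]
    sex: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for ind, r in self.role.items():
            if r not in ROLES:
                raise ValidationError(f"unknown role {r!r} for {ind!r}")
        for ind in self.role:
            self.sex.setdefault(ind, "unknown")
        for ind, s in self.sex.items():
            if s not in SEXES:
                raise ValidationError(f"unknown sex {s!r} for {ind!r}")

    def ids_with_role(self, role: str) -> list[str]:
        return [i for i, r in self.role.items() if r == role]

    @property
    def parent_a(self) -> list[str]:
        return self.ids_with_role("parentA_ref")

    @property
    def parent_b(self) -> list[str]:
        return self.ids_with_role("parentB_ref")

    @property
    def hybrids(self) -> list[str]:
        return self.ids_with_role("hybrid")

    @property
    def outgroup(self) -> list[str]:
        return self.ids_with_role("outgroup")

    def merged(self, other: "PanelAssignment") -> "PanelAssignment":
        dup = set(self.role) & set(other.role)
        if dup:
            raise ValidationError(f"individuals assigned twice: {sorted(dup)[:5]}")
        return PanelAssignment({**self.role, **other.role}, {**self.sex, **other.sex})


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def read_vcf(path: str, filter_biallelic: bool = True) -> GenotypeMatrix:
    """Read a VCF 4.x into a :class:`GenotypeMatrix`.

    Dosages count alt alleles; genotypes without a per-sample ``DP`` get depth
    0.  With ``filter_biallelic`` (the default) indels and multiallelic records
    are dropped; otherwise they raise.  Duplicate (chrom, pos) pairs raise
    :class:`ValidationError`.
    """
    from cyvcf2 import VCF

    try:
        vcf = VCF(str(path), gts012=True)
    except Exception as exc:  # cyvcf2 raises bare exceptions on bad headers
        raise ParseError(f"{path}: cannot parse VCF header: {exc}") from exc

    individuals = list(vcf.samples)
    chroms, poss, refs, alts = [], [], [], []
    dosages, depths = [], []
    lineno = 0
    try:
        for var in vcf:
            lineno += 1
            snp = (
                len(var.ALT) == 1
                and len(var.REF) == 1
                and var.REF in _BASES
                and len(var.ALT[0]) == 1
                and var.ALT[0] in _BASES
            )
            if not snp:
                if filter_biallelic:
                    continue
                raise ValidationError(
                    f"{path}: record {var.CHROM}:{var.POS} is not a biallelic SNP"
                )
            chroms.append(var.CHROM)
            poss.append(var.POS)
            refs.append(var.REF)
            alts.append(var.ALT[0])
            # gts012: 0/1/2 = alt dosage, 3 = missing
            gt = np.asarray(var.gt_types, dtype=np.int8)
            gt[gt == 3] = MISSING
            dosages.append(gt)
            dp = var.format("DP")
            if dp is None:
                depths.append(np.zeros(len(individuals), dtype=np.int32))
            else:
                dp = np.asarray(dp, dtype=np.int32).reshape(-1)
                dp[dp < 0] = 0  # missing DP sentinel
                depths.append(dp)
    except (ParseError, ValidationError):
        raise
    except Exception as exc:
        raise ParseError(f"{path}: malformed VCF record near data line {lineno + 1}: {exc}") from exc

    if chroms:
        pairs = list(zip(chroms, poss))
        if len(set(pairs)) != len(pairs):
            dup = [p for p in pairs if pairs.count(p) > 1][0]
            raise ValidationError(f"{path}: duplicate record at {dup[0]}:{dup[1]}")
    sites = SiteTable(np.array(chroms, dtype=object), np.array(poss, dtype=np.int64),
                      np.array(refs, dtype=object), np.array(alts, dtype=object))
    dosage = np.array(dosages, dtype=np.int8).reshape(len(chroms), len(individuals))
    depth = np.array(depths, dtype=np.int32).reshape(len(chroms), len(individuals))
    return GenotypeMatrix(sites, individuals, dosage, depth)


_GT_STRINGS = {MISSING: "./.", 0: "0/0", 1: "0/1", 2: "1/1"}


def write_vcf(gm: GenotypeMatrix, path: str, chrom_lengths: dict[str, int] | None = None) -> None:
    """Write a sorted VCF 4.2 with GT and DP; round-trips through :func:`read_vcf`."""
    chrom_order: list[str] = []
    for c in gm.sites.chrom:
        if c not in chrom_order:
            chrom_order.append(c)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=hybridpaint\n")
        for c in chrom_order:
            if chrom_lengths and c in chrom_lengths:
                fh.write(f"##contig=<ID={c},length={chrom_lengths[c]}>\n")
            else:
                fh.write(f"##contig=<ID={c}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read Depth">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(gm.individuals) + "\n")
        for j in range(gm.n_sites):
            fields = [
                str(gm.sites.chrom[j]),
                str(int(gm.sites.pos[j])),
                ".",
                str(gm.sites.ref[j]),
                str(gm.sites.alt[j]),
                ".",
                "PASS",
                ".",
                "GT:DP",
            ]
            for i in range(gm.n_individuals):
                fields.append(f"{_GT_STRINGS[int(gm.dosage[j, i])]}:{int(gm.depth[j, i])}")
            fh.write("\t".join(fields) + "\n")


# ---------------------------------------------------------------------------
# Beagle genotype likelihoods
# ---------------------------------------------------------------------------

def _parse_allele(token: str) -> str:
    token = str(token)
    if token in _BASES:
        return token
    if token in _ALLELE_CODES:
        return _ALLELE_CODES[token]
    raise ParseError(f"unknown allele code {token!r} in Beagle file")


def read_beagle_gl(path: str) -> LikelihoodMatrix:
    """Read a Beagle genotype-likelihood text file.

    Expected layout: header ``marker allele1 allele2`` followed by each
    individual's name repeated three times; one row per site with a triple of
    likelihoods per individual (order: hom-ref, het, hom-alt).  Triples are
    renormalised to sum to 1; an all-equal triple means "no data".  Markers are
    ``chrom_pos`` with 1-based positions; allele columns accept bases or the
    0–3 integer codes.
    """
    df = pd.read_csv(path, sep=r"\s+", header=0, dtype=str)
    if df.shape[1] < 3 or (df.shape[1] - 3) % 3 != 0:
        raise ParseError(
            f"{path}: expected 3 + 3*n_individuals columns, got {df.shape[1]}"
        )
    raw_names = list(df.columns[3:])
    individuals = raw_names[::3]
    # pandas mangles repeated headers to name, name.1, name.2
    for k, name in enumerate(individuals):
        trip = raw_names[3 * k : 3 * k + 3]
        base = [t.split(".")[0] if t.split(".")[-1].isdigit() else t for t in trip]
        if len(set(base)) != 1:
            raise ParseError(f"{path}: header columns {trip} are not one individual")
    if len(set(individuals)) != len(individuals):
        raise ParseError(f"{path}: duplicate individual names")

    chroms, poss = [], []
    for marker in df.iloc[:, 0]:
        if "_" not in str(marker):
            raise ParseError(f"{path}: marker {marker!r} is not chrom_pos")
        c, p = str(marker).rsplit("_", 1)
        try:
            poss.append(int(p))
        except ValueError:
            raise ParseError(f"{path}: marker {marker!r} has non-integer position") from None
        chroms.append(c)
    refs = [_parse_allele(a) for a in df.iloc[:, 1]]
    alts = [_parse_allele(a) for a in df.iloc[:, 2]]
    try:
        values = df.iloc[:, 3:].to_numpy(dtype=np.float64)
    except ValueError as exc:
        raise ParseError(f"{path}: non-numeric likelihood value: {exc}") from exc
    if np.any(~np.isfinite(values)):
        raise ParseError(f"{path}: missing or non-finite likelihood value")
    if np.any(values < 0):
        raise ValidationError(f"{path}: negative genotype likelihood")
    gl = values.reshape(len(df), len(individuals), 3)
    sums = gl.sum(axis=2)
    if np.any(sums <= 0):
        raise ValidationError(f"{path}: all-zero likelihood triple")
    gl = gl / sums[:, :, None]
    sites = SiteTable(
        np.array(chroms, dtype=object),
        np.array(poss, dtype=np.int64),
        np.array(refs, dtype=object),
        np.array(alts, dtype=object),
    )
    return LikelihoodMatrix(sites, individuals, gl)


def write_beagle_gl(lm: LikelihoodMatrix, path: str) -> None:
    """Write Beagle GL text: marker, alleles, then one normalised triple per individual."""
    with open(path, "w") as fh:
        header = ["marker", "allele1", "allele2"]
        for ind in lm.individuals:
            header.extend([ind, ind, ind])
        fh.write("\t".join(header) + "\n")
        for j in range(lm.n_sites):
            row = [
                f"{lm.sites.chrom[j]}_{int(lm.sites.pos[j])}",
                str(lm.sites.ref[j]),
                str(lm.sites.alt[j]),
            ]
            for i in range(lm.n_individuals):
                row.extend(f"{v:.10g}" for v in lm.gl[j, i])
            fh.write("\t".join(row) + "\n")


# ---------------------------------------------------------------------------
# Panels and chromosome maps (TSV)
# ---------------------------------------------------------------------------

def read_panels(path: str) -> PanelAssignment:
    """Read a panel TSV with columns id, role, sex (sex optional)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("id", "role"):
        if col not in df.columns:
            raise ParseError(f"{path}: missing required column {col!r}")
    if df["id"].duplicated().any():
        dup = df["id"][df["id"].duplicated()].iloc[0]
        raise ValidationError(f"{path}: duplicate individual id {dup!r}")
    role = dict(zip(df["id"], df["role"]))
    sex = dict(zip(df["id"], df["sex"])) if "sex" in df.columns else {}
    return PanelAssignment(role, sex)


def write_panels(panels: PanelAssignment, path: str) -> None:
    pd.DataFrame(
        {
            "id": list(panels.role),
            "role": [panels.role[i] for i in panels.role],
            "sex": [panels.sex[i] for i in panels.role],
        }
    ).to_csv(path, sep="\t", index=False)


def read_chrom_map(path: str) -> ChromosomeMap:
    """Read a chromosome map TSV (chrom, length, sex_linked); size class is derived."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    for col in ("chrom", "length"):
        if col not in df.columns:
            raise ParseError(f"{path}: missing required column {col!r}")
    sex_linked: list[str] = []
    if "sex_linked" in df.columns:
        truthy = {"true", "1", "yes"}
        sex_linked = [
            c
            for c, v in zip(df["chrom"], df["sex_linked"])
            if str(v).strip().lower() in truthy
        ]
    lengths = {}
    for c, l in zip(df["chrom"], df["length"]):
        lengths[str(c)] = int(l)
    if len(lengths) != len(df):
        raise ValidationError(f"{path}: duplicate chromosome name")
    return ChromosomeMap.from_lengths(lengths, sex_linked)


def write_chrom_map(cmap: ChromosomeMap, path: str) -> None:
    pd.DataFrame(
        {
            "chrom": [e.name for e in cmap.entries],
            "length": [e.length for e in cmap.entries],
            "size_class": [e.size_class for e in cmap.entries],
            "sex_linked": [str(e.sex_linked).lower() for e in cmap.entries],
        }
    ).to_csv(path, sep="\t", index=False)
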