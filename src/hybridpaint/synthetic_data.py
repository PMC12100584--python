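"""Hybrid-zone genome simulator with known ancestry truth.

Emulates the data structure the pipeline assumes: two parental populations
separated long enough to carry fixed differences, shared ancestral
polymorphism standing in for incomplete lineage sorting (ILS), Poisson
recombination, avian ZW sex chromosomes in three size classes, pedigree
hybrids (F1 / F2 / backcrosses), and coverage/error-driven genotype
likelihoods typical of low-coverage museum specimens.

The model is deliberately minimal:

* Sites are unlinked draws; linkage enters only through the tract structure
  created by pedigree recombination, not through a coalescent.
* A ``fixed_diff`` site is fixed for opposite alleles in the two parents —
  exactly the ancestry-informative-marker (AIM) definition downstream code
  detects.
* A ``shared_poly`` site segregates in *both* parents at one common
  Beta-distributed ancestral frequency: the ILS stand-in that makes reference
  individuals look admixed in a window.
* A ``private`` site segregates in one parent only.
* Crossovers per meiosis are Poisson with uniform placement (no interference).
* Males are ZZ, females ZW: a female's single Z is paternal, and she passes
  her Z intact to sons.  The W carries no modelled sites; female Z genotypes
  are hemizygous and stored as dosage 0 or 2.

Every function takes or derives a seeded generator; fixed seeds reproduce
byte-identical output.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .formats_io import (
    MISSING,
    ChromosomeMap,
    GenotypeMatrix,
    LikelihoodMatrix,
    PanelAssignment,
    SiteTable,
    ValidationError,
)

__all__ = [
    "SimConfig",
    "SimulatedPanels",
    "PedigreeMember",
    "PedigreeSpec",
    "PedigreeError",
    "AncestryTruth",
    "simulate_parental_panels",
    "simulate_pedigree",
    "canonical_pedigree",
    "hybrids_from_tracts",
    "TractHybrid",
    "genotypes_to_likelihoods",
    "likelihoods_from_read_counts",
    "write_truth_tracts",
]

_BASES = np.array(["A", "C", "G", "T"], dtype=object)

SITE_FIXED = "fixed_diff"
SITE_SHARED = "shared_poly"
SITE_PRIVATE = "private"


class PedigreeError(ValueError):
    """A pedigree references parents that cannot exist or have the wrong sex."""


@dataclass
class SimConfig:
    """Study conditions for the simulator.

    Chromosome complement defaults to a small avian-style genome: a few macro
    (> 40 Mbp), intermediate (20–40 Mbp) and micro (< 20 Mbp) autosomes plus a
    macro-sized Z.  ``fraction_fixed_diff`` and ``fraction_shared_poly`` set
    the per-site probabilities of AIM-grade fixed differences and ILS-style
    shared polymorphism; the remainder is private polymorphism.  Sequencing
    noise follows museum-grade short-read data: per-genotype read counts are
    Poisson(``depth_mean``) with per-base error ``error_rate``.
    """

    n_macro: int = 2
    n_intermediate: int = 2
    n_micro: int = 3
    include_z: bool = True
    macro_length: int = 50_000_000
    intermediate_length: int = 30_000_000
    micro_length: int = 12_000_000
    z_length: int = 72_000_000
    n_sites_per_chrom: int | Sequence[int] = 200
    fraction_fixed_diff: float = 0.30
    fraction_shared_poly: float = 0.20
    beta_shape_a: float = 0.8
    beta_shape_b: float = 0.8
    recomb_rate: float = 1.0  # expected crossovers per chromosome per meiosis
    depth_mean: float = 8.0
    error_rate: float = 0.01
    seed: int = 0
    #: per-chromosome (fraction_fixed_diff, fraction_shared_poly) overrides
    fraction_overrides: dict[str, tuple[float, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for f in (self.fraction_fixed_diff, self.fraction_shared_poly):
            if not 0.0 <= f <= 1.0:
                raise ValidationError(f"site-class fraction {f} outside [0, 1]")
        if self.fraction_fixed_diff + self.fraction_shared_poly > 1.0:
            raise ValidationError("site-class fractions sum to more than 1")
        for name, (ff, fs) in self.fraction_overrides.items():
            if ff + fs > 1.0 or min(ff, fs) < 0.0:
                raise ValidationError(f"invalid fraction override for {name!r}")
        if self.recomb_rate < 0:
            raise ValidationError("recomb_rate must be >= 0")
        if self.error_rate <= 0 or self.error_rate >= 0.5:
            raise ValidationError("error_rate must lie in (0, 0.5)")
        counts = self._site_counts()
        if any(n < 1 for n in counts):
            raise ValidationError("n_sites_per_chrom must be >= 1")

    def chromosome_map(self) -> ChromosomeMap:
        lengths: dict[str, int] = {}
        for k in range(self.n_macro):
            lengths[f"macro{k + 1}"] = self.macro_length
        for k in range(self.n_intermediate):
            lengths[f"int{k + 1}"] = self.intermediate_length
        for k in range(self.n_micro):
            lengths[f"micro{k + 1}"] = self.micro_length
        sex_linked = []
        if self.include_z:
            lengths["chrZ"] = self.z_length
            sex_linked = ["chrZ"]
        return ChromosomeMap.from_lengths(lengths, sex_linked)

    def _site_counts(self) -> list[int]:
        n_chrom = self.n_macro + self.n_intermediate + self.n_micro + int(self.include_z)
        if isinstance(self.n_sites_per_chrom, int):
            return [self.n_sites_per_chrom] * n_chrom
        counts = list(self.n_sites_per_chrom)
        if len(counts) != n_chrom:
            raise ValidationError(
                f"n_sites_per_chrom has {len(counts)} entries for {n_chrom} chromosomes"
            )
        return counts

    def class_fractions(self, chrom: str) -> tuple[float, float]:
        if chrom in self.fraction_overrides:
            return self.fraction_overrides[chrom]
        return self.fraction_fixed_diff, self.fraction_shared_poly


@dataclass
class SimulatedPanels:
    """Parental reference panels plus the per-site truth needed downstream."""

    gm: GenotypeMatrix
    site_labels: np.ndarray  # {fixed_diff, shared_poly, private} per site
    freq: np.ndarray  # (n_sites, 2) alt-allele frequency in pop A, pop B
    panels: PanelAssignment
    cmap: ChromosomeMap
    config: SimConfig

    @property
    def sites(self) -> SiteTable:
        return self.gm.sites


def _draw_positions(rng: np.random.Generator, length: int, n: int) -> np.ndarray:
    """n distinct 1-based positions on [1, length], sorted."""
    if n > length:
        raise ValidationError(f"cannot place {n} sites on a {length}-bp chromosome")
    pos: set[int] = set()
    while len(pos) < n:
        draw = rng.integers(1, length + 1, size=n - len(pos))
        pos.update(int(p) for p in draw)
    return np.array(sorted(pos), dtype=np.int64)


def simulate_parental_panels(
    cfg: SimConfig,
    n_a: int = 5,
    n_b: int = 5,
    n_outgroup: int = 0,
    rng: np.random.Generator | None = None,
) -> SimulatedPanels:
    """Simulate diploid genotypes for two parental panels (and optional outgroup).

    Site classes are drawn per site from the configured fractions.  At a
    ``fixed_diff`` site one panel is fixed for ref and the other for alt, with
    random orientation.  At a ``shared_poly`` site both panels share one
    ancestral Beta(a, b) frequency.  ``private`` sites segregate in a single
    random panel.  Outgroup individuals are homozygous for a per-site ancestral
    allele: an even coin between the two parental alleles at fixed differences,
    one Bernoulli(ancestral frequency) draw at shared polymorphisms, and ref at
    private sites — symmetric with respect to the two parents, so gene-flow
    tests on pure panels are null.
    """
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    cmap = cfg.chromosome_map()
    counts = cfg._site_counts()

    chroms, poss, labels, freq_a, freq_b, freq_out = [], [], [], [], [], []
    for entry, n_sites in zip(cmap.entries, counts):
        ff, fs = cfg.class_fractions(entry.name)
        pos = _draw_positions(rng, entry.length, n_sites)
        u = rng.random(n_sites)
        lab = np.where(u < ff, SITE_FIXED, np.where(u < ff + fs, SITE_SHARED, SITE_PRIVATE))
        fa = np.empty(n_sites)
        fb = np.empty(n_sites)
        fo = np.empty(n_sites)
        fixed = lab == SITE_FIXED
        swap = rng.random(n_sites) < 0.5
        fa[fixed] = np.where(swap[fixed], 1.0, 0.0)
        fb[fixed] = 1.0 - fa[fixed]
        fo[fixed] = np.where(rng.random(n_sites)[fixed] < 0.5, 1.0, 0.0)
        shared = lab == SITE_SHARED
        p_anc = rng.beta(cfg.beta_shape_a, cfg.beta_shape_b, size=n_sites)
        fa[shared] = p_anc[shared]
        fb[shared] = p_anc[shared]
        fo[shared] = (rng.random(n_sites)[shared] < p_anc[shared]).astype(float)
        priv = lab == SITE_PRIVATE
        p_priv = rng.beta(cfg.beta_shape_a, cfg.beta_shape_b, size=n_sites)
        in_a = rng.random(n_sites) < 0.5
        fa[priv] = np.where(in_a[priv], p_priv[priv], 0.0)
        fb[priv] = np.where(in_a[priv], 0.0, p_priv[priv])
        fo[priv] = 0.0
        chroms.append(np.full(n_sites, entry.name, dtype=object))
        poss.append(pos)
        labels.append(lab)
        freq_a.append(fa)
        freq_b.append(fb)
        freq_out.append(fo)

    chrom_arr = np.concatenate(chroms)
    pos_arr = np.concatenate(poss)
    label_arr = np.concatenate(labels).astype(object)
    freq = np.stack([np.concatenate(freq_a), np.concatenate(freq_b)], axis=1)
    f_out = np.concatenate(freq_out)
    n_total = len(pos_arr)

    ref_alt = np.empty((n_total, 2), dtype=object)
    for j in range(n_total):
        ref_alt[j] = rng.choice(_BASES, size=2, replace=False)
    sites = SiteTable(chrom_arr, pos_arr, ref_alt[:, 0], ref_alt[:, 1])

    z_mask = np.isin(chrom_arr, list(cmap.sex_linked_names))

    ids: list[str] = []
    role: dict[str, str] = {}
    sex: dict[str, str] = {}
    dosages = []
    groups = [("A", n_a, "parentA_ref", 0), ("B", n_b, "parentB_ref", 1)]
    for prefix, n_ind, role_name, col in groups:
        for k in range(n_ind):
            ind = f"{prefix}{k + 1}"
            ids.append(ind)
            role[ind] = role_name
            s = "male" if k % 2 == 0 else "female"
            sex[ind] = s
            p = freq[:, col]
            hap0 = (rng.random(n_total) < p).astype(np.int8)
            hap1 = (rng.random(n_total) < p).astype(np.int8)
            dose = hap0 + hap1
            if s == "female":
                dose[z_mask] = 2 * hap0[z_mask]  # hemizygous Z
            dosages.append(dose)
    for k in range(n_outgroup):
        ind = f"O{k + 1}"
        ids.append(ind)
        role[ind] = "outgroup"
        sex[ind] = "male" if k % 2 == 0 else "female"
        dosages.append((2 * f_out).astype(np.int8))

    dosage = np.stack(dosages, axis=1)
    depth = rng.poisson(cfg.depth_mean, size=dosage.shape).astype(np.int32)
    gm = GenotypeMatrix(sites, ids, dosage, depth)
    panels = PanelAssignment(role, sex)
    return SimulatedPanels(gm, label_arr, freq, panels, cmap, cfg)


# ---------------------------------------------------------------------------
# Pedigree simulation
# ---------------------------------------------------------------------------

FOUNDER_CLASSES = ("parentA", "parentB")


@dataclass
class PedigreeMember:
    id: str
    cls: str  # parentA, parentB, F1, F2, BC1A, BC1B, BC2A, BC2B, ...
    sex: str  # male / female
    mother: str | None = None
    father: str | None = None


@dataclass
class PedigreeSpec:
    members: list[PedigreeMember]

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for m in self.members:
            if m.id in seen:
                raise PedigreeError(f"duplicate pedigree id {m.id!r}")
            seen.add(m.id)
            if m.sex not in ("male", "female"):
                raise PedigreeError(f"{m.id!r}: sex must be male or female")
            founder = m.cls in FOUNDER_CLASSES
            if founder and (m.mother or m.father):
                raise PedigreeError(f"{m.id!r}: founders cannot have parents")
            if not founder and (m.mother is None or m.father is None):
                raise PedigreeError(
                    f"{m.id!r}: class {m.cls!r} requires both parents "
                    "(e.g. a BC1 without an F1 parent is impossible)"
                )


_CANONICAL_CROSSES = {
    # class -> (mother class, father class); the hybrid lineage is maternal,
    # so e.g. BC1B = F1 female x parent-B male, whose daughters carry a
    # parent-B Z (their single Z is paternal).
    "F1": ("parentA", "parentB"),
    "F2": ("F1", "F1"),
    "BC1A": ("F1", "parentA"),
    "BC1B": ("F1", "parentB"),
    "BC2A": ("BC1A", "parentA"),
    "BC2B": ("BC1B", "parentB"),
    "BC3A": ("BC2A", "parentA"),
    "BC3B": ("BC2B", "parentB"),
}


def canonical_pedigree(requests: Sequence[tuple[str, str, str]]) -> PedigreeSpec:
    """Expand ``(id, class, sex)`` requests into a full pedigree.

    Each request gets its own independent ancestor chain (fresh founders and
    intermediates, ids prefixed with ``_``), built from the canonical crosses
    above.
    """
    members: list[PedigreeMember] = []
    counter = [0]

    def build(cls: str, sex: str, ind_id: str | None = None) -> str:
        counter[0] += 1
        mid = ind_id if ind_id is not None else f"_{cls}_{counter[0]}"
        if cls in FOUNDER_CLASSES:
            members.append(PedigreeMember(mid, cls, sex))
            return mid
        if cls not in _CANONICAL_CROSSES:
            raise PedigreeError(f"unknown pedigree class {cls!r}")
        mcls, fcls = _CANONICAL_CROSSES[cls]
        mother = build(mcls, "female")
        father = build(fcls, "male")
        members.append(PedigreeMember(mid, cls, sex, mother, father))
        return mid

    for ind_id, cls, sex in requests:
        build(cls, sex, ind_id)
    return PedigreeSpec(members)


@dataclass
class AncestryTruth:
    """Ground-truth donor tracts per individual haplotype, 0-based half-open bp.

    Haplotype 0 is the maternal gamete and haplotype 1 the paternal one; a
    female's slot 0 on the Z is the (siteless) W and carries no tracts.
    """

    tracts: pd.DataFrame  # individual, chrom, haplotype, start, end, donor

    def validate(self, cmap: ChromosomeMap) -> None:
        for (ind, chrom, hap), grp in self.tracts.groupby(
            ["individual", "chrom", "haplotype"], sort=False
        ):
            grp = grp.sort_values("start")
            if grp["start"].iloc[0] != 0 or grp["end"].iloc[-1] != cmap.length(chrom):
                raise ValidationError(f"tracts do not span {chrom} for {ind} hap {hap}")
            if np.any(grp["start"].to_numpy()[1:] != grp["end"].to_numpy()[:-1]):
                raise ValidationError(f"tract gap/overlap on {chrom} for {ind} hap {hap}")

    def donor_fraction(
        self, individual: str, donor: str = "A", chroms: Iterable[str] | None = None
    ) -> float:
        """Length-weighted fraction of an individual's tracts from ``donor``."""
        df = self.tracts[self.tracts["individual"] == individual]
        if chroms is not None:
            df = df[df["chrom"].isin(set(chroms))]
        total = (df["end"] - df["start"]).sum()
        hit = df[df["donor"] == donor]
        return float((hit["end"] - hit["start"]).sum() / total) if total else float("nan")


# internal per-haplotype record: (alleles or None for W, tract list)
_Hap = tuple[np.ndarray | None, list[tuple[int, int, str]]]


def _founder_haps(
    rng: np.random.Generator,
    panels: SimulatedPanels,
    pop_col: int,
    donor: str,
    sex: str,
) -> dict[str, list[_Hap]]:
    """Draw a fresh founder from the stored per-population allele frequencies."""
    out: dict[str, list[_Hap]] = {}
    sites = panels.sites
    for entry in panels.cmap.entries:
        idx = sites.chrom_indices(entry.name)
        p = panels.freq[idx, pop_col]
        tract = [(0, entry.length, donor)]
        h0 = (rng.random(len(idx)) < p).astype(np.int8)
        h1 = (rng.random(len(idx)) < p).astype(np.int8)
        if entry.sex_linked and sex == "female":
            out[entry.name] = [(None, []), (h0, list(tract))]  # W, paternal Z
        else:
            out[entry.name] = [(h0, list(tract)), (h1, list(tract))]
    return out


def _clip_tracts(
    tracts: list[tuple[int, int, str]], start: int, end: int
) -> list[tuple[int, int, str]]:
    out = []
    for s, e, d in tracts:
        s2, e2 = max(s, start), min(e, end)
        if s2 < e2:
            out.append((s2, e2, d))
    return out


def _merge_tracts(tracts: list[tuple[int, int, str]]) -> list[tuple[int, int, str]]:
    merged: list[tuple[int, int, str]] = []
    for t in tracts:
        if merged and merged[-1][2] == t[2] and merged[-1][1] == t[0]:
            merged[-1] = (merged[-1][0], t[1], t[2])
        else:
            merged.append(t)
    return merged


def _recombine(
    rng: np.random.Generator,
    haps: list[_Hap],
    length: int,
    positions: np.ndarray,
    rate: float,
) -> _Hap:
    """One gamete from a diploid pair: Poisson(rate) crossovers, uniform placement."""
    n_x = rng.poisson(rate)
    bps = np.sort(rng.integers(1, length, size=n_x)) if n_x else np.empty(0, dtype=np.int64)
    current = int(rng.integers(2))
    alleles = np.empty(len(positions), dtype=np.int8)
    tracts: list[tuple[int, int, str]] = []
    bounds = [0, *[int(b) for b in bps], length]
    for seg_start, seg_end in zip(bounds[:-1], bounds[1:]):
        if seg_start >= seg_end:
            current = 1 - current
            continue
        src_alleles, src_tracts = haps[current]
        lo = np.searchsorted(positions, seg_start + 1, side="left")
        hi = np.searchsorted(positions, seg_end, side="right")
        alleles[lo:hi] = src_alleles[lo:hi]
        tracts.extend(_clip_tracts(src_tracts, seg_start, seg_end))
        current = 1 - current
    return alleles, _merge_tracts(tracts)


def simulate_pedigree(
    panels: SimulatedPanels,
    spec: PedigreeSpec,
    cfg: SimConfig | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[GenotypeMatrix, AncestryTruth]:
    """Simulate every pedigree member down from fresh parental founders.

    Gametes carry Poisson(``recomb_rate``) crossovers placed uniformly; the ZW
    rule is enforced (a son receives his mother's Z intact and a recombinant
    paternal Z; a daughter receives only the recombinant paternal Z).  Returns
    the genotype matrix for all members plus their ancestry truth tracts.
    """
    cfg = panels.config if cfg is None else cfg
    rng = np.random.default_rng(cfg.seed + 1) if rng is None else rng
    sites = panels.sites
    cmap = panels.cmap
    by_chrom_idx = {e.name: sites.chrom_indices(e.name) for e in cmap.entries}
    by_chrom_pos = {c: sites.pos[i] for c, i in by_chrom_idx.items()}

    members = {m.id: m for m in spec.members}
    haps: dict[str, dict[str, list[_Hap]]] = {}

    for m in spec.members:
        if m.cls in FOUNDER_CLASSES:
            col, donor = (0, "A") if m.cls == "parentA" else (1, "B")
            haps[m.id] = _founder_haps(rng, panels, col, donor, m.sex)
            continue
        for pid, want_sex, label in ((m.mother, "female", "mother"), (m.father, "male", "father")):
            if pid not in haps:
                raise PedigreeError(f"{m.id!r}: {label} {pid!r} not simulated before child")
            if members[pid].sex != want_sex:
                raise PedigreeError(f"{m.id!r}: {label} {pid!r} is not {want_sex}")
        child: dict[str, list[_Hap]] = {}
        for entry in cmap.entries:
            chrom = entry.name
            pos = by_chrom_pos[chrom]
            pat = _recombine(rng, haps[m.father][chrom], entry.length, pos, cfg.recomb_rate)
            if not entry.sex_linked:
                mat = _recombine(rng, haps[m.mother][chrom], entry.length, pos, cfg.recomb_rate)
                child[chrom] = [mat, pat]
            elif m.sex == "male":
                mz = haps[m.mother][chrom][1]  # mother's single Z, passed intact
                child[chrom] = [(mz[0].copy(), list(mz[1])), pat]
            else:
                child[chrom] = [(None, []), pat]
        haps[m.id] = child

    ids = [m.id for m in spec.members]
    n_sites = sites.n_sites
    dosage = np.zeros((n_sites, len(ids)), dtype=np.int8)
    rows = []
    for i, m in enumerate(spec.members):
        for entry in cmap.entries:
            chrom = entry.name
            idx = by_chrom_idx[chrom]
            h0, h1 = haps[m.id][chrom]
            if h0[0] is None:
                dosage[idx, i] = 2 * h1[0]  # hemizygous female Z
            else:
                dosage[idx, i] = h0[0] + h1[0]
            for hap_ix, (_, tracts) in enumerate((h0, h1)):
                for s, e, d in tracts:
                    rows.append((m.id, chrom, hap_ix, s, e, d))
    depth = rng.poisson(cfg.depth_mean, size=dosage.shape).astype(np.int32)
    gm = GenotypeMatrix(sites, ids, dosage, depth)
    truth = AncestryTruth(
        pd.DataFrame(rows, columns=["individual", "chrom", "haplotype", "start", "end", "donor"])
    )
    return gm, truth


@dataclass
class TractHybrid:
    """A hybrid specified directly by its donor tracts (for planted-truth tests).

    ``tracts[chrom]`` holds one tract list per haplotype; each list of
    (start, end, donor) tuples must tile [0, length).  Omitted chromosomes
    default to homozygous donor B.
    """

    id: str
    sex: str = "male"
    tracts: dict[str, tuple[list[tuple[int, int, str]], list[tuple[int, int, str]]]] = field(
        default_factory=dict
    )


def hybrids_from_tracts(
    panels: SimulatedPanels,
    specs: Sequence[TractHybrid],
    rng: np.random.Generator | None = None,
) -> tuple[GenotypeMatrix, AncestryTruth]:
    """Build hybrids whose ancestry tracts are chosen, not inherited.

    Alleles inside each tract are drawn from the donor population's allele
    frequencies, so fixed differences identify the donor exactly while shared
    polymorphism stays ambiguous — the same contrast the pedigree produces.
    """
    rng = np.random.default_rng(panels.config.seed + 2) if rng is None else rng
    sites = panels.sites
    cmap = panels.cmap
    dosage = np.zeros((sites.n_sites, len(specs)), dtype=np.int8)
    rows = []
    for i, spec in enumerate(specs):
        for entry in cmap.entries:
            chrom = entry.name
            idx = sites.chrom_indices(chrom)
            pos = sites.pos[idx]
            default = [(0, entry.length, "B")]
            hap_tracts = spec.tracts.get(chrom, (list(default), list(default)))
            hemi = entry.sex_linked and spec.sex == "female"
            total = np.zeros(len(idx), dtype=np.int8)
            for hap_ix, tracts in enumerate(hap_tracts):
                if hemi and hap_ix == 0:
                    continue  # W slot
                alleles = np.zeros(len(idx), dtype=np.int8)
                for s, e, d in tracts:
                    col = 0 if d == "A" else 1
                    sel = (pos - 1 >= s) & (pos - 1 < e)
                    p = panels.freq[idx[sel], col]
                    alleles[sel] = (rng.random(sel.sum()) < p).astype(np.int8)
                    rows.append((spec.id, chrom, hap_ix, s, e, d))
                total += alleles if not hemi else 2 * alleles
            dosage[idx, i] = total
    depth = rng.poisson(panels.config.depth_mean, size=dosage.shape).astype(np.int32)
    gm = GenotypeMatrix(sites, [s.id for s in specs], dosage, depth)
    truth = AncestryTruth(
        pd.DataFrame(rows, columns=["individual", "chrom", "haplotype", "start", "end", "donor"])
    )
    return gm, truth


# ---------------------------------------------------------------------------
# Genotype likelihoods
# ---------------------------------------------------------------------------

def likelihoods_from_read_counts(
    reads: np.ndarray,
    alt_reads: np.ndarray,
    error_rate: float,
    hemizygous: np.ndarray | None = None,
) -> np.ndarray:
    """GL triples from read counts: proportional to Binom(alt; reads, p_g).

    p_0 = error, p_1 = 1/2, p_2 = 1 - error.  ``hemizygous`` entries get a
    zero heterozygous likelihood.  Zero reads yield the uniform triple.
    Computed in log space so deep genotypes cannot underflow.
    """
    from scipy.stats import binom

    reads = np.asarray(reads)
    alt_reads = np.asarray(alt_reads)
    p_by_dosage = (error_rate, 0.5, 1.0 - error_rate)
    with np.errstate(divide="ignore"):
        loglik = np.stack(
            [binom.logpmf(alt_reads, reads, p) for p in p_by_dosage], axis=-1
        )
    if hemizygous is not None:
        loglik[hemizygous, 1] = -np.inf
    loglik -= loglik.max(axis=-1, keepdims=True)
    gl = np.exp(loglik)
    gl /= gl.sum(axis=-1, keepdims=True)
    gl[reads == 0] = 1.0 / 3.0
    return gl


def genotypes_to_likelihoods(
    gm: GenotypeMatrix,
    depth_mean: float,
    error_rate: float,
    seed: int,
    sex: dict[str, str] | None = None,
    sex_linked: Iterable[str] = (),
) -> LikelihoodMatrix:
    """Degrade hard genotypes into read-based genotype likelihoods.

    Per genotype: reads ~ Poisson(``depth_mean``); alt-read count ~
    Binomial(reads, p_g) with p_0 = error, p_1 = 1/2, p_2 = 1 - error; the GL
    triple is proportional to the three binomial likelihoods and normalised.
    Zero reads (or a missing input genotype) yield the uniform no-data triple.
    When ``sex`` and ``sex_linked`` are given, sex-linked genotypes of females
    are hemizygous: the heterozygous likelihood is zero and reads are drawn
    from the {0, 2} dosage actually stored.
    """
    if not 0.0 < error_rate < 0.5:
        raise ValidationError("error_rate must lie in (0, 0.5)")
    rng = np.random.default_rng(seed)
    n_sites, n_ind = gm.dosage.shape
    reads = rng.poisson(depth_mean, size=(n_sites, n_ind))
    p_by_dosage = np.array([error_rate, 0.5, 1.0 - error_rate])
    dose = np.clip(gm.dosage, 0, 2)
    alt_reads = rng.binomial(reads, p_by_dosage[dose])

    hemi = np.zeros((n_sites, n_ind), dtype=bool)
    linked = set(sex_linked)
    if sex and linked:
        z_sites = np.isin(gm.sites.chrom, list(linked))
        for i, ind in enumerate(gm.individuals):
            if sex.get(ind) == "female":
                hemi[z_sites, i] = True

    gl = likelihoods_from_read_counts(reads, alt_reads, error_rate, hemizygous=hemi)
    gl[gm.dosage == MISSING] = 1.0 / 3.0
    return LikelihoodMatrix(gm.sites, list(gm.individuals), gl)


def write_truth_tracts(truth: AncestryTruth, path: str) -> None:
    """BED-like TSV: chrom, start, end, individual, haplotype, donor."""
    truth.tracts[["chrom", "start", "end", "individual", "haplotype", "donor"]].to_csv(
        path, sep="\t", index=False
    )
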