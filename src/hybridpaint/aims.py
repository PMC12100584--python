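"""Ancestry-informative markers, hybrid profiling and generation classification.

An AIM is a site fixed for different alleles in the two parental reference
panels.  Genotyping a hybrid at the AIM set yields two summary coordinates:

* hybrid index  h = (2 n_homA + n_het) / (2 (n_homA + n_het + n_homB)) — the
  fraction of the hybrid's alleles at AIMs inherited from parent A;
* interspecific heterozygosity  H = n_het / (n_homA + n_het + n_homB) — the
  fraction of AIMs carrying one allele from each parent.

Expectations on the (h, H) triangle: parentals at (0, 0) / (1, 0), F1 at
(0.5, 1), F2 near (0.5, 0.5), first-generation backcrosses near (0.25, 0.5)
or (0.75, 0.5), with H halving each further backcross generation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .formats_io import (
    MISSING,
    ChromosomeMap,
    GenotypeMatrix,
    SiteTable,
    ValidationError,
)

__all__ = [
    "AIMSet",
    "HybridProfile",
    "detect_aims",
    "profile_hybrid",
    "classify_hybrid",
    "triangle_table",
    "TRIANGLE_VERTICES",
]

#: Admissible-region vertices of the (h, H) triangle: the two parentals and the F1.
TRIANGLE_VERTICES = ((0.0, 0.0), (1.0, 0.0), (0.5, 1.0))

CLASS_LABELS = (
    "parental_A",
    "parental_B",
    "F1",
    "F2",
    "backcross_into_A",
    "backcross_into_B",
    "later_generation",
    "unclassified",
)


@dataclass
class AIMSet:
    """Diagnostic fixed-difference sites with their parental allele identities."""

    sites: SiteTable
    #: dosage (0 or 2) that parent A is fixed for, per AIM
    parent_a_dosage: np.ndarray
    #: indices of the AIMs in the genotype matrix they were detected from
    source_index: np.ndarray

    def __post_init__(self) -> None:
        self.parent_a_dosage = np.asarray(self.parent_a_dosage, dtype=np.int8)
        if not np.all(np.isin(self.parent_a_dosage, [0, 2])):
            raise ValidationError("parent_a_dosage must be 0 (ref) or 2 (alt)")
        if len(self.parent_a_dosage) != self.sites.n_sites:
            raise ValidationError("parent_a_dosage length mismatch")

    def __len__(self) -> int:
        return self.sites.n_sites

    @property
    def parent_a_allele(self) -> np.ndarray:
        return np.where(self.parent_a_dosage == 0, self.sites.ref, self.sites.alt)

    @property
    def parent_b_allele(self) -> np.ndarray:
        return np.where(self.parent_a_dosage == 0, self.sites.alt, self.sites.ref)

    def to_frame(self) -> pd.DataFrame:
        df = self.sites.to_frame()
        df["parentA_allele"] = self.parent_a_allele
        df["parentB_allele"] = self.parent_b_allele
        return df


def detect_aims(
    gm: GenotypeMatrix,
    ids_a: list[str],
    ids_b: list[str],
    min_calls_per_panel: int = 2,
) -> AIMSet:
    """Sites fixed at different alleles between the two reference panels.

    A site is evaluable when each panel has at least ``min_calls_per_panel``
    non-missing genotypes; it is an AIM when every called parent-A genotype is
    homozygous for one allele and every called parent-B genotype homozygous for
    the other (per-site Weir–Cockerham theta-hat = 1).  Deterministic.
    """
    if not ids_a or not ids_b:
        raise ValidationError("both parental panels must be non-empty")
    if min_calls_per_panel < 1:
        raise ValidationError("min_calls_per_panel must be >= 1")
    fixed = {}
    for key, ids in (("a", ids_a), ("b", ids_b)):
        sub = gm.subset_individuals(ids)
        called = sub.called
        n = called.sum(axis=1)
        all0 = np.all(np.where(called, sub.dosage == 0, True), axis=1)
        all2 = np.all(np.where(called, sub.dosage == 2, True), axis=1)
        fixed[key] = (n >= min_calls_per_panel, all0, all2)
    ok_a, a0, a2 = fixed["a"]
    ok_b, b0, b2 = fixed["b"]
    is_aim = ok_a & ok_b & ((a0 & b2) | (a2 & b0))
    idx = np.nonzero(is_aim)[0]
    parent_a_dosage = np.where(a0[idx], 0, 2).astype(np.int8)
    return AIMSet(gm.sites.subset(idx), parent_a_dosage, idx)


@dataclass
class HybridProfile:
    """AIM genotype counts and derived (h, H) coordinates for one hybrid."""

    individual: str
    n_hom_a: int
    n_het: int
    n_hom_b: int
    n_missing: int
    h: float
    het: float  # interspecific heterozygosity H
    cls: str = "unclassified"
    #: per-AIM call track for painting plots: chrom, pos, state
    calls: pd.DataFrame | None = None
    #: hemizygous-Z allele counts for females: {"n_a": ..., "n_b": ...}
    z_counts: dict[str, int] | None = None

    @property
    def n_called(self) -> int:
        return self.n_hom_a + self.n_het + self.n_hom_b

    @property
    def hom_proportion(self) -> float:
        return (self.n_hom_a + self.n_hom_b) / self.n_called


_STATE_NAMES = np.array(["homB", "het", "homA", "missing"], dtype=object)


def profile_hybrid(
    gm: GenotypeMatrix,
    hybrid_id: str,
    aims: AIMSet,
    cmap: ChromosomeMap | None = None,
    sex: str | None = None,
) -> HybridProfile:
    """Genotype one hybrid at the AIM set and compute h and H.

    Missing AIMs are excluded from every denominator.  When a chromosome map
    and the hybrid's sex are supplied, sex-linked AIMs of a female are
    hemizygous: they are excluded from h/H (which assume two alleles) and
    reported separately as single-Z allele counts.
    """
    col = gm.column(hybrid_id)
    dose = gm.dosage[aims.source_index, col]
    # recode to parent-A allele count: 0 = hom B, 1 = het, 2 = hom A
    a_count = np.where(
        dose == MISSING, MISSING, np.where(aims.parent_a_dosage == 2, dose, 2 - dose)
    ).astype(np.int8)

    z_counts = None
    include = np.ones(len(aims), dtype=bool)
    if cmap is not None and sex == "female" and cmap.sex_linked_names:
        on_z = np.isin(aims.sites.chrom, list(cmap.sex_linked_names))
        include = ~on_z
        z_calls = a_count[on_z]
        z_calls = z_calls[z_calls != MISSING]
        # hemizygous: dosage is 0 or 2, i.e. 0 or 1 copies of the A allele
        z_counts = {"n_a": int((z_calls == 2).sum()), "n_b": int((z_calls == 0).sum())}

    used = a_count[include]
    n_hom_a = int((used == 2).sum())
    n_het = int((used == 1).sum())
    n_hom_b = int((used == 0).sum())
    n_missing = int((used == MISSING).sum())
    n_called = n_hom_a + n_het + n_hom_b
    if n_called == 0:
        raise ValidationError(f"{hybrid_id!r}: no non-missing AIM genotypes; profile undefined")
    h = (2 * n_hom_a + n_het) / (2.0 * n_called)
    het = n_het / n_called
    calls = pd.DataFrame(
        {
            "chrom": aims.sites.chrom,
            "pos": aims.sites.pos,
            "state": _STATE_NAMES[np.where(a_count == MISSING, 3, a_count)],
        }
    )
    return HybridProfile(hybrid_id, n_hom_a, n_het, n_hom_b, n_missing, h, het,
                         calls=calls, z_counts=z_counts)


def classify_hybrid(profile: HybridProfile, tol: float = 0.1) -> str:
    """Triangle-plot generation call from (h, H) with tolerance ``tol``.

    Bands around the pedigree expectations: parentals at (0 or 1, 0), F1 at
    (0.5, 1), F2 at (0.5, 0.5), first-generation backcrosses at (0.25 or
    0.75, 0.5).  Later backcross generations (H below the BC1 band but h still
    intermediate) are called ``later_generation``; anything else is
    ``unclassified``.  The direction of a backcross follows which homozygote
    class dominates (h below vs above 0.5).
    """
    h, het = profile.h, profile.het
    cls = "unclassified"
    if het <= tol and h >= 1.0 - tol:
        cls = "parental_A"
    elif het <= tol and h <= tol:
        cls = "parental_B"
    elif abs(h - 0.5) <= tol and het >= 1.0 - tol:
        cls = "F1"
    elif abs(h - 0.5) <= tol and abs(het - 0.5) <= tol:
        cls = "F2"
    elif abs(h - 0.75) <= tol and abs(het - 0.5) <= tol:
        cls = "backcross_into_A"
    elif abs(h - 0.25) <= tol and abs(het - 0.5) <= tol:
        cls = "backcross_into_B"
    elif het < 0.5 - tol and tol < h < 1.0 - tol:
        cls = "later_generation"
    profile.cls = cls
    return cls


def triangle_table(
    profiles: list[HybridProfile],
    tsv_path: str | None = None,
    plot_path: str | None = None,
    tol: float = 0.1,
) -> pd.DataFrame:
    """One row per hybrid (id, h, H, counts, class); optional TSV and plot."""
    if not profiles:
        raise ValidationError("no hybrid profiles to tabulate")
    for p in profiles:
        if p.cls == "unclassified":
            classify_hybrid(p, tol=tol)
    df = pd.DataFrame(
        {
            "id": [p.individual for p in profiles],
            "h": [p.h for p in profiles],
            "H": [p.het for p in profiles],
            "n_homA": [p.n_hom_a for p in profiles],
            "n_het": [p.n_het for p in profiles],
            "n_homB": [p.n_hom_b for p in profiles],
            "n_missing": [p.n_missing for p in profiles],
            "class": [p.cls for p in profiles],
        }
    )
    if tsv_path:
        df.to_csv(tsv_path, sep="\t", index=False)
    if plot_path:
        from .plotting import triangle_plot

        triangle_plot(df, plot_path)
    return df
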