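"""Site filtering, Weir–Cockerham F_ST, LD thinning and Patterson's D.

All statistics are computed from their published definitions on the
:class:`~hybridpaint.formats_io.GenotypeMatrix` container.  The Weir–Cockerham
estimator uses the two-population variance components a, b, c with the
observed-heterozygosity correction; windowed values are ratios of sums
(sum(a) / sum(a + b + c)), not means of ratios.  Patterson's D is the
frequency-weighted ABBA-BABA statistic with a block jackknife over contiguous
physical blocks.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .formats_io import MISSING, GenotypeMatrix, SiteTable, ValidationError

__all__ = [
    "FilterConfig",
    "FilterReport",
    "apply_filters",
    "population_allele_freqs",
    "wc_site_components",
    "weir_cockerham_fst",
    "ld_prune_every_nth",
    "ld_prune_indices",
    "DStatResult",
    "patterson_d",
    "patterson_d_from_genotypes",
]


@dataclass
class FilterConfig:
    """Hard-call filter thresholds.

    Defaults follow low-coverage joint-call practice on museum data: drop
    genotypes below 2x, then drop sites with minor allele frequency below
    0.03, call rate below 90%, or total site depth outside [10, 75].
    """

    min_maf: float = 0.03
    min_call_rate: float = 0.90
    min_ind_depth: int = 2
    min_site_depth: int = 10
    max_site_depth: int = 75
    ld_keep_every: int = 50

    def __post_init__(self) -> None:
        if not 0.0 <= self.min_maf < 0.5:
            raise ValidationError("min_maf must lie in [0, 0.5)")
        if not 0.0 < self.min_call_rate <= 1.0:
            raise ValidationError("min_call_rate must lie in (0, 1]")
        if self.min_site_depth > self.max_site_depth:
            raise ValidationError("site depth bounds out of order")
        if self.ld_keep_every < 1:
            raise ValidationError("ld_keep_every must be >= 1")


@dataclass
class FilterReport:
    n_sites_in: int = 0
    n_sites_out: int = 0
    genotypes_masked_low_depth: int = 0
    failed_maf: int = 0
    failed_call_rate: int = 0
    failed_site_depth: int = 0

    def as_dict(self) -> dict[str, int]:
        return dict(self.__dict__)


def apply_filters(gm: GenotypeMatrix, fc: FilterConfig) -> tuple[GenotypeMatrix, FilterReport]:
    """Mask low-depth genotypes, then drop sites failing MAF / call-rate / depth.

    A site may fail several rules; the report counts each rule independently.
    The operation is idempotent: filtering a filtered matrix is the identity.
    """
    report = FilterReport(n_sites_in=gm.n_sites)
    dosage = gm.dosage.copy()
    low = (gm.depth < fc.min_ind_depth) & (dosage != MISSING)
    report.genotypes_masked_low_depth = int(low.sum())
    dosage[low] = MISSING

    called = dosage != MISSING
    n_called = called.sum(axis=1)
    call_rate = n_called / max(gm.n_individuals, 1)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(called, dosage, 0).sum(axis=1) / (2.0 * n_called)
    maf = np.minimum(p, 1.0 - p)
    site_depth = gm.depth.sum(axis=1)

    ok_maf = (n_called > 0) & (maf >= fc.min_maf)
    ok_call = call_rate >= fc.min_call_rate
    ok_depth = (site_depth >= fc.min_site_depth) & (site_depth <= fc.max_site_depth)
    report.failed_maf = int((~ok_maf).sum())
    report.failed_call_rate = int((~ok_call).sum())
    report.failed_site_depth = int((~ok_depth).sum())

    keep = np.nonzero(ok_maf & ok_call & ok_depth)[0]
    report.n_sites_out = len(keep)
    if len(keep) == 0:
        warnings.warn("all sites removed by filters", stacklevel=2)
    out = GenotypeMatrix(gm.sites.subset(keep), list(gm.individuals), dosage[keep], gm.depth[keep])
    return out, report


def population_allele_freqs(gm: GenotypeMatrix, ids: list[str]) -> np.ndarray:
    """Per-site alt-allele frequency in a panel; NaN where no calls."""
    sub = gm.subset_individuals(ids)
    called = sub.called
    n = called.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(called, sub.dosage, 0).sum(axis=1) / (2.0 * n)


# ---------------------------------------------------------------------------
# Weir & Cockerham F_ST
# ---------------------------------------------------------------------------

def wc_site_components(
    gm: GenotypeMatrix, ids_a: list[str], ids_b: list[str], min_called: int = 2
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-site Weir–Cockerham variance components (a, b, c) for two panels.

    Sites with fewer than ``min_called`` called genotypes in either panel are
    NaN in all three components.  Missing genotypes reduce per-site sample
    sizes rather than dropping the site.
    """
    r = 2.0
    comp = []
    for ids in (ids_a, ids_b):
        sub = gm.subset_individuals(ids)
        called = sub.called
        n_i = called.sum(axis=1).astype(float)
        dose = np.where(called, sub.dosage, 0)
        with np.errstate(invalid="ignore", divide="ignore"):
            p_i = dose.sum(axis=1) / (2.0 * n_i)
            h_i = np.where(called, sub.dosage == 1, False).sum(axis=1) / n_i
        comp.append((n_i, p_i, h_i))
    (n1, p1, h1), (n2, p2, h2) = comp

    valid = (n1 >= min_called) & (n2 >= min_called)
    with np.errstate(invalid="ignore", divide="ignore"):
        n_bar = (n1 + n2) / r
        n_c = (r * n_bar - (n1**2 + n2**2) / (r * n_bar)) / (r - 1.0)
        p_bar = (n1 * p1 + n2 * p2) / (r * n_bar)
        s2 = (n1 * (p1 - p_bar) ** 2 + n2 * (p2 - p_bar) ** 2) / ((r - 1.0) * n_bar)
        h_bar = (n1 * h1 + n2 * h2) / (r * n_bar)
        inner = p_bar * (1.0 - p_bar) - ((r - 1.0) / r) * s2 - h_bar / 4.0
        a = (n_bar / n_c) * (s2 - inner / (n_bar - 1.0))
        b = (n_bar / (n_bar - 1.0)) * (
            p_bar * (1.0 - p_bar) - ((r - 1.0) / r) * s2 - ((2.0 * n_bar - 1.0) / (4.0 * n_bar)) * h_bar
        )
        c = h_bar / 2.0
    bad = ~valid | (n_bar <= 1) | (n_c <= 0)
    for arr in (a, b, c):
        arr[bad] = np.nan
    return a, b, c


def weir_cockerham_fst(
    gm: GenotypeMatrix,
    ids_a: list[str],
    ids_b: list[str],
    window_bp: int = 50_000,
    min_called: int = 2,
) -> pd.DataFrame:
    """Windowed Weir–Cockerham theta-hat between two panels.

    Windows are non-overlapping ``window_bp`` tiles (0-based half-open);
    theta-hat per window is sum(a) / sum(a + b + c) over informative sites,
    NaN where the denominator is zero or no site is informative.
    """
    a, b, c = wc_site_components(gm, ids_a, ids_b, min_called=min_called)
    usable = ~np.isnan(a)
    win_start = ((gm.sites.pos - 1) // window_bp) * window_bp
    df = pd.DataFrame(
        {
            "chrom": gm.sites.chrom,
            "start": win_start,
            "a": np.where(usable, a, 0.0),
            "abc": np.where(usable, a + b + c, 0.0),
            "n": usable.astype(int),
        }
    )
    grouped = df.groupby(["chrom", "start"], sort=False).sum().reset_index()
    with np.errstate(invalid="ignore", divide="ignore"):
        theta = np.where(
            (grouped["n"] > 0) & (grouped["abc"] != 0.0),
            grouped["a"] / grouped["abc"],
            np.nan,
        )
    return pd.DataFrame(
        {
            "chrom": grouped["chrom"],
            "start": grouped["start"].astype(int),
            "end": grouped["start"].astype(int) + window_bp,
            "theta": theta,
            "n_sites": grouped["n"].astype(int),
        }
    )


def ld_prune_indices(sites: SiteTable, n: int = 50) -> np.ndarray:
    """Indices of every n-th variant in genome-wide sorted order (first kept)."""
    if n < 1:
        raise ValidationError("n must be >= 1")
    return np.arange(0, sites.n_sites, n)


def ld_prune_every_nth(sites: SiteTable, n: int = 50) -> SiteTable:
    """Thin linkage by keeping every n-th variant genome-wide."""
    return sites.subset(ld_prune_indices(sites, n))


# ---------------------------------------------------------------------------
# Patterson's D (ABBA-BABA)
# ---------------------------------------------------------------------------

@dataclass
class DStatResult:
    n_abba: float
    n_baba: float
    d: float
    se: float  # NaN when fewer than 2 non-empty blocks
    z: float
    n_sites: int
    n_blocks: int
    block_size_bp: int


def patterson_d(
    p1: np.ndarray,
    p2: np.ndarray,
    p3: np.ndarray,
    p4: np.ndarray,
    chrom: np.ndarray,
    pos: np.ndarray,
    block_size_bp: int = 1_000_000,
) -> DStatResult:
    """Frequency-weighted Patterson's D with a block-jackknife standard error.

    Expected pattern weights per site: ABBA = (1-p1) p2 p3 (1-p4) and
    BABA = p1 (1-p2) p3 (1-p4), with p the alt-allele frequency in each
    population and P4 polarising the ancestral state.  D = (ABBA - BABA) /
    (ABBA + BABA).  The SE is a delete-one jackknife over contiguous
    ``block_size_bp`` blocks; Z = D / SE.
    """
    freqs = np.stack([p1, p2, p3, p4], axis=1)
    ok = ~np.isnan(freqs).any(axis=1)
    f = freqs[ok]
    abba = (1 - f[:, 0]) * f[:, 1] * f[:, 2] * (1 - f[:, 3])
    baba = f[:, 0] * (1 - f[:, 1]) * f[:, 2] * (1 - f[:, 3])
    n_abba, n_baba = float(abba.sum()), float(baba.sum())
    denom = n_abba + n_baba
    d = (n_abba - n_baba) / denom if denom > 0 else float("nan")

    block_keys = pd.Series(
        [f"{c}:{(int(p) - 1) // block_size_bp}" for c, p in zip(chrom[ok], pos[ok])]
    )
    blocks = block_keys.unique()
    n_blocks = len(blocks)
    se = float("nan")
    if n_blocks >= 2 and denom > 0:
        d_loo = []
        for blk in blocks:
            mask = (block_keys != blk).to_numpy()
            num = abba[mask].sum() - baba[mask].sum()
            den = abba[mask].sum() + baba[mask].sum()
            d_loo.append(num / den if den > 0 else d)
        d_loo = np.asarray(d_loo)
        se = float(np.sqrt((n_blocks - 1) / n_blocks * ((d_loo - d_loo.mean()) ** 2).sum()))
    z = d / se if se and se > 0 else float("nan")
    return DStatResult(n_abba, n_baba, d, se, z, int(ok.sum()), n_blocks, block_size_bp)


def patterson_d_from_genotypes(
    gm: GenotypeMatrix,
    pops: tuple[list[str], list[str], list[str], list[str]],
    block_size_bp: int = 1_000_000,
) -> DStatResult:
    """Convenience wrapper: allele frequencies per population, then :func:`patterson_d`."""
    freqs = [population_allele_freqs(gm, ids) for ids in pops]
    return patterson_d(*freqs, chrom=gm.sites.chrom, pos=gm.sites.pos, block_size_bp=block_size_bp)
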