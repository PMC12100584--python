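"""Windowed admixture painting of hybrid chromosomes with ILS control.

Each chromosome is cut into equal-width windows by size class — nine on macro
chromosomes (> 40 Mbp), seven on intermediate ones (20–40 Mbp), five on micro
chromosomes (< 20 Mbp) — and a K=2 genotype-likelihood admixture model is fit
per window over the reference panels and the hybrids jointly.  Fits are
oriented so Q_A = 1 means pure parent A.  A window where any reference
individual itself looks admixed cannot distinguish introgression from shared
ancestral polymorphism and is flagged as putative incomplete lineage sorting
(ILS); flagged windows are excluded from the boxplot summaries.  The headline
product is the per-window median Q_A across hybrids, drawn as an ideogram.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .formats_io import (
    ChromosomeMap,
    LikelihoodMatrix,
    PanelAssignment,
    ValidationError,
)
from .gl_admixture import admixture_em, orient_ancestry

__all__ = [
    "WINDOWS_PER_CLASS",
    "WindowScheme",
    "WindowPainting",
    "EmSettings",
    "partition_windows",
    "paint_windows",
    "flag_ils",
    "summarize_painting",
]

WINDOWS_PER_CLASS = {"macro": 9, "intermediate": 7, "micro": 5}


@dataclass
class WindowScheme:
    """Per-chromosome window boundaries, 0-based half-open bp intervals."""

    windows: dict[str, list[tuple[int, int]]]

    def n_windows(self, chrom: str) -> int:
        return len(self.windows[chrom])

    @property
    def total(self) -> int:
        return sum(len(w) for w in self.windows.values())


def partition_windows(cmap: ChromosomeMap) -> WindowScheme:
    """Equal-width windows per chromosome: 9 (macro), 7 (intermediate), 5 (micro).

    Widths are floor(L / n); the remainder is absorbed by the final window, so
    the windows tile [0, L) exactly.
    """
    windows: dict[str, list[tuple[int, int]]] = {}
    for entry in cmap.entries:
        n = WINDOWS_PER_CLASS[entry.size_class]
        if entry.length < n:
            raise ValidationError(f"{entry.name}: length {entry.length} shorter than {n} windows")
        width = entry.length // n
        bounds = [
            (i * width, (i + 1) * width if i < n - 1 else entry.length) for i in range(n)
        ]
        windows[entry.name] = bounds
    return WindowScheme(windows)


@dataclass
class EmSettings:
    """Per-window EM configuration (ten restarts, best likelihood kept)."""

    n_restarts: int = 10
    max_iter: int = 2000
    tol: float = 1e-6
    min_maf: float = 0.03
    min_sites: int = 50  # windows with fewer informative sites are left undefined
    seed: int = 0


@dataclass
class WindowPainting:
    """Per-window oriented admixture proportions for every individual."""

    table: pd.DataFrame  # chrom, window_index, start, end, n_sites, defined, ils_flag
    individuals: list[str]
    q_a: np.ndarray  # (n_windows, n_ind); NaN where undefined
    panels: PanelAssignment
    ils_threshold: float | None = None

    def _cols(self, ids: list[str]) -> list[int]:
        return [self.individuals.index(i) for i in ids]

    @property
    def hybrid_q(self) -> np.ndarray:
        return self.q_a[:, self._cols(self.panels.hybrids)]

    @property
    def reference_q(self) -> dict[str, np.ndarray]:
        return {
            "A": self.q_a[:, self._cols(self.panels.parent_a)],
            "B": self.q_a[:, self._cols(self.panels.parent_b)],
        }

    @property
    def median_q(self) -> np.ndarray:
        """Median Q_A across hybrids per window (NaN-aware)."""
        hy = self.hybrid_q
        with np.errstate(invalid="ignore"):
            out = np.full(len(self.table), np.nan)
            any_def = ~np.isnan(hy).all(axis=1)
            out[any_def] = np.nanmedian(hy[any_def], axis=1)
        return out

    def per_individual_frame(self) -> pd.DataFrame:
        df = self.table[["chrom", "window_index", "start", "end"]].copy()
        for i, ind in enumerate(self.individuals):
            df[ind] = self.q_a[:, i]
        return df


def paint_windows(
    lm: LikelihoodMatrix,
    scheme: WindowScheme,
    panels: PanelAssignment,
    settings: EmSettings | None = None,
) -> WindowPainting:
    """Fit K=2 admixture in every window, jointly over references and hybrids.

    Each window uses the sites whose (0-based) position falls inside it, runs
    the multi-restart EM with a window-specific seed derived deterministically
    from ``settings.seed``, and is oriented so Q_A = 1 is pure parent A.
    Windows with fewer informative sites than ``min_sites`` (or an ambiguous
    orientation) are reported undefined rather than fit.  Same seed, same data
    — identical painting.
    """
    settings = settings or EmSettings()
    if not panels.parent_a or not panels.parent_b:
        raise ValidationError("painting requires both parental reference panels")
    present = set(lm.individuals)
    used_ids = [
        i
        for i in lm.individuals
        if i in panels.role and panels.role[i] in ("parentA_ref", "parentB_ref", "hybrid")
    ]
    missing_refs = [i for i in panels.parent_a + panels.parent_b if i not in present]
    if missing_refs:
        raise ValidationError(f"reference individuals absent from data: {missing_refs[:5]}")
    sub = lm.subset_individuals(used_ids)

    rows = []
    q_rows = []
    for ci, (chrom, bounds) in enumerate(scheme.windows.items()):
        idx_chrom = sub.sites.chrom_indices(chrom)
        pos0 = sub.sites.pos[idx_chrom] - 1
        for wi, (start, end) in enumerate(bounds):
            idx = idx_chrom[(pos0 >= start) & (pos0 < end)]
            window_lm = sub.subset_sites(idx)
            seed = int(np.random.SeedSequence([settings.seed, ci, wi]).generate_state(1)[0] % (2**31))
            q_a = np.full(len(used_ids), np.nan)
            n_used = 0
            defined = False
            if len(idx) >= settings.min_sites:
                try:
                    fit = admixture_em(
                        window_lm,
                        k=2,
                        n_restarts=settings.n_restarts,
                        max_iter=settings.max_iter,
                        tol=settings.tol,
                        seed=seed,
                        min_maf=settings.min_maf,
                    )
                except ValidationError:
                    fit = None
                if fit is not None and fit.f.shape[1] >= settings.min_sites:
                    n_used = fit.f.shape[1]
                    oriented = orient_ancestry(fit, panels)
                    if not oriented.orientation_ambiguous:
                        q_a = oriented.q_a.copy()
                        defined = True
            rows.append((chrom, wi, start, end, n_used, defined, False))
            q_rows.append(q_a)

    table = pd.DataFrame(
        rows,
        columns=["chrom", "window_index", "start", "end", "n_sites", "defined", "ils_flag"],
    )
    return WindowPainting(table, used_ids, np.asarray(q_rows), panels)


def flag_ils(painting: WindowPainting, threshold: float = 0.05) -> WindowPainting:
    """Mark windows where the reference panel itself exhibits admixture.

    A window is flagged when any parent-A reference has Q_A < 1 - threshold or
    any parent-B reference has Q_A > threshold: there the parental panels are
    not cleanly separated and incomplete lineage sorting cannot be ruled out.
    Undefined windows are never flagged.  Raising the threshold can only
    un-flag windows.
    """
    refs = painting.reference_q
    with np.errstate(invalid="ignore"):
        bad_a = np.nan_to_num(1.0 - refs["A"], nan=0.0) > threshold
        bad_b = np.nan_to_num(refs["B"], nan=0.0) > threshold
    flags = (bad_a.any(axis=1) | bad_b.any(axis=1)) & painting.table["defined"].to_numpy()
    painting.table = painting.table.assign(ils_flag=flags)
    painting.ils_threshold = threshold
    return painting


def summarize_painting(
    painting: WindowPainting, cmap: ChromosomeMap
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Ideogram and boxplot tables.

    Ideogram: one row per window (chrom, start, end, median_QA, ils_flag,
    n_sites).  Boxplot: one row per (hybrid, window) keyed by size class and
    1-based window index, with ILS-flagged and undefined windows excluded.
    """
    ideo = painting.table[["chrom", "start", "end", "ils_flag", "n_sites", "defined"]].copy()
    ideo.insert(3, "median_QA", painting.median_q)

    hybrids = painting.panels.hybrids
    hy_q = painting.hybrid_q
    rows = []
    for w in range(len(painting.table)):
        rec = painting.table.iloc[w]
        if not rec["defined"] or rec["ils_flag"]:
            continue
        size_class = cmap.size_class(rec["chrom"])
        for j, hid in enumerate(hybrids):
            if not np.isnan(hy_q[w, j]):
                rows.append(
                    (size_class, int(rec["window_index"]) + 1, rec["chrom"], hid, hy_q[w, j])
                )
    box = pd.DataFrame(rows, columns=["size_class", "window", "chrom", "hybrid", "Q_A"])
    return ideo, box
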