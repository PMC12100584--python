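"""Reusable simulation experiments backing the analysis scripts and checks.

Each experiment builds its inputs with the synthetic-data module, runs one
pipeline stage and returns the measured quantity, so the number reported is
always recomputed from scratch for the seed supplied.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import synthetic_data as sd
from .aims import detect_aims, profile_hybrid
from .popgen_stats import patterson_d_from_genotypes

__all__ = [
    "f2_homozygous_aim_percent",
    "F2Experiment",
    "null_d_z_scores",
]


@dataclass
class F2Experiment:
    """Per-individual homozygous-AIM proportions and their mean (percent)."""

    per_individual: np.ndarray
    mean_percent: float
    n_aims: int
    n_f2: int


def f2_homozygous_aim_percent(
    seed: int,
    n_f2: int = 20,
    n_chrom: int = 30,
    n_sites_total: int = 1000,
) -> F2Experiment:
    """Share of AIMs genotyped homozygous in simulated F2 hybrids.

    Two parental panels carry ``n_sites_total`` fixed differences spread over
    ``n_chrom`` autosomes.  Two independent F1s are formed and crossed to give
    ``n_f2`` F2 individuals (Poisson(1) crossovers per chromosome per
    meiosis); every F2 is profiled at the detected AIM set on its error-free
    genotypes.  Mendelian expectation: an F2 is homozygous at half its AIMs.
    """
    base = n_sites_total // n_chrom
    extra = n_sites_total - base * n_chrom
    per_chrom = [base + 1] * extra + [base] * (n_chrom - extra)
    cfg = sd.SimConfig(
        n_macro=0,
        n_intermediate=0,
        n_micro=n_chrom,
        include_z=False,
        micro_length=10_000_000,
        n_sites_per_chrom=per_chrom,
        fraction_fixed_diff=1.0,
        fraction_shared_poly=0.0,
        recomb_rate=1.0,
        seed=seed,
    )
    panels = sd.simulate_parental_panels(cfg, n_a=5, n_b=5)
    aims = detect_aims(panels.gm, panels.panels.parent_a, panels.panels.parent_b)

    members = [
        sd.PedigreeMember("Af1", "parentA", "female"),
        sd.PedigreeMember("Bm1", "parentB", "male"),
        sd.PedigreeMember("Af2", "parentA", "female"),
        sd.PedigreeMember("Bm2", "parentB", "male"),
        sd.PedigreeMember("F1_f", "F1", "female", mother="Af1", father="Bm1"),
        sd.PedigreeMember("F1_m", "F1", "male", mother="Af2", father="Bm2"),
    ]
    members += [
        sd.PedigreeMember(f"F2_{i + 1}", "F2", "male" if i % 2 else "female",
                          mother="F1_f", father="F1_m")
        for i in range(n_f2)
    ]
    gm, _ = sd.simulate_pedigree(panels, sd.PedigreeSpec(members))

    props = np.array(
        [profile_hybrid(gm, f"F2_{i + 1}", aims).hom_proportion for i in range(n_f2)]
    )
    return F2Experiment(props, float(props.mean() * 100.0), len(aims), n_f2)


def null_d_z_scores(
    seed: int,
    n_replicates: int = 200,
    n_sites: int = 400,
    block_size_bp: int = 1_000_000,
) -> np.ndarray:
    """Patterson's D Z scores under the no-gene-flow null, one per replicate.

    P1 and P2 are two halves of the parent-A panel, P3 is parent B, P4 the
    outgroup; shared polymorphism is symmetric between P1 and P2, so D should
    be centred on zero with |Z| < 3 almost always.
    """
    rng = np.random.SeedSequence(seed)
    z_scores = []
    for child in rng.spawn(n_replicates):
        rep_seed = int(child.generate_state(1)[0] % (2**31))
        cfg = sd.SimConfig(
            n_macro=0,
            n_intermediate=0,
            n_micro=1,
            include_z=False,
            micro_length=12_000_000,
            n_sites_per_chrom=n_sites,
            fraction_fixed_diff=0.2,
            fraction_shared_poly=0.5,
            seed=rep_seed,
        )
        panels = sd.simulate_parental_panels(cfg, n_a=6, n_b=4, n_outgroup=2)
        a = panels.panels.parent_a
        res = patterson_d_from_genotypes(
            panels.gm,
            (a[:3], a[3:], panels.panels.parent_b, panels.panels.outgroup),
            block_size_bp=block_size_bp,
        )
        z_scores.append(res.z)
    return np.asarray(z_scores)
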