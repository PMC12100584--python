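import numpy as np
import pytest

from hybridpaint import formats_io as fio
from hybridpaint import synthetic_data as sd


def random_genotype_matrix(seed: int, n_sites: int = 40, n_ind: int = 6,
                           missing_rate: float = 0.1) -> fio.GenotypeMatrix:
    """A small random but valid GenotypeMatrix for round-trip/property tests."""
    rng = np.random.default_rng(seed)
    n_chrom = rng.integers(1, 4)
    chroms, poss = [], []
    for c in range(n_chrom):
        n = n_sites // n_chrom + (c == 0) * (n_sites % n_chrom)
        pos = np.sort(rng.choice(np.arange(1, 10 * n_sites + 2), size=n, replace=False))
        chroms.extend([f"chr{c + 1}"] * n)
        poss.extend(pos.tolist())
    bases = np.array(["A", "C", "G", "T"], dtype=object)
    ref = rng.choice(bases, size=n_sites)
    alt = np.array([rng.choice([b for b in bases if b != r]) for r in ref], dtype=object)
    sites = fio.SiteTable(np.array(chroms, dtype=object), np.array(poss), ref, alt)
    dosage = rng.integers(0, 3, size=(n_sites, n_ind)).astype(np.int8)
    dosage[rng.random((n_sites, n_ind)) < missing_rate] = fio.MISSING
    depth = rng.poisson(12, size=(n_sites, n_ind)).astype(np.int32)
    return fio.GenotypeMatrix(sites, [f"ind{i}" for i in range(n_ind)], dosage, depth)


@pytest.fixture(scope="session")
def small_panels() -> sd.SimulatedPanels:
    """5+5 parental panels with an outgroup on a 4-chromosome toy genome."""
    cfg = sd.SimConfig(
        n_macro=1, n_intermediate=1, n_micro=1, include_z=True,
        n_sites_per_chrom=150, seed=42,
    )
    return sd.simulate_parental_panels(cfg, n_a=5, n_b=5, n_outgroup=2)


@pytest.fixture(scope="session")
def painted_genome():
    """A painted toy genome with planted truth.

    Five BC-like hybrids carry heterozygous donor-A tracts exactly in the
    terminal windows of the macro chromosome and a pure parent-B Z; one micro
    chromosome is almost entirely shared ancestral polymorphism so its windows
    should attract ILS flags.  Returns (panels, all_panels, lm, scheme,
    settings, painting_result).
    """
    from hybridpaint import painting

    cfg = sd.SimConfig(
        n_macro=1, n_intermediate=1, n_micro=1, include_z=True,
        macro_length=45_000_000, intermediate_length=30_000_000,
        micro_length=15_000_000, z_length=45_000_000,
        n_sites_per_chrom=[540, 420, 300, 540],
        fraction_fixed_diff=0.6, fraction_shared_poly=0.1,
        seed=70, fraction_overrides={"micro1": (0.0, 0.9)},
    )
    panels = sd.simulate_parental_panels(cfg, 5, 5)
    L = 45_000_000
    w = L // 9
    specs = []
    for k in range(5):
        tracts = {
            "macro1": (
                [(0, w, "A"), (w, L - w, "B"), (L - w, L, "A")],
                [(0, L, "B")],
            )
        }
        specs.append(sd.TractHybrid(f"hyb{k}", "male" if k % 2 else "female", tracts))
    hyb_gm, truth = sd.hybrids_from_tracts(panels, specs, rng=np.random.default_rng(71))
    truth.validate(panels.cmap)
    gm = fio.GenotypeMatrix(
        panels.gm.sites,
        panels.gm.individuals + hyb_gm.individuals,
        np.concatenate([panels.gm.dosage, hyb_gm.dosage], axis=1),
        np.concatenate([panels.gm.depth, hyb_gm.depth], axis=1),
    )
    all_panels = panels.panels.merged(
        fio.PanelAssignment({s.id: "hybrid" for s in specs}, {s.id: s.sex for s in specs})
    )
    lm = sd.genotypes_to_likelihoods(gm, 8, 0.01, 72, sex=all_panels.sex,
                                     sex_linked={"chrZ"})
    scheme = painting.partition_windows(panels.cmap)
    settings = painting.EmSettings(n_restarts=4, seed=73, min_sites=30)
    result = painting.paint_windows(lm, scheme, all_panels, settings)
    painting.flag_ils(result, 0.05)
    return panels, all_panels, lm, scheme, settings, result
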