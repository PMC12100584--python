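#!/usr/bin/env python
"""Simulate a hybrid-zone dataset mirroring the study design.

Two parental reference panels (5 + 5) plus a 2-individual outgroup on an
avian-style genome (macro / intermediate / micro autosomes and a Z), with six
hybrids: one F2 and five first-generation backcrosses into parent B — the
composition reported for the contemporary hybrid zone.  Writes the joint-call
VCF, Beagle genotype likelihoods, panel and chromosome-map TSVs, and the
ground-truth ancestry tracts under results/data/.
"""

import pathlib

import numpy as np

from hybridpaint import formats_io as fio
from hybridpaint import synthetic_data as sd

OUT = pathlib.Path(__file__).resolve().parents[1] / "results" / "data"
SEED = 20240501

HYBRIDS = [("hyb21", "F2", "male")] + [
    (f"hyb{n}", "BC1B", sex)
    for n, sex in zip(range(22, 27), ["male", "male", "female", "male", "female"])
]


def simulate():
    # avian-style karyotype: ~30 chromosome pairs in three size classes plus Z;
    # fewer chromosomes than a real bird would exaggerate pedigree variance in
    # the hybrid-index/heterozygosity coordinates
    cfg = sd.SimConfig(
        n_macro=3, n_intermediate=4, n_micro=22, include_z=True,
        macro_length=50_000_000, intermediate_length=30_000_000,
        micro_length=12_000_000, z_length=72_000_000,
        n_sites_per_chrom=[360] * 3 + [280] * 4 + [150] * 22 + [360],
        fraction_fixed_diff=0.30, fraction_shared_poly=0.20,
        recomb_rate=1.5, depth_mean=8.0, error_rate=0.01, seed=SEED,
    )
    panels = sd.simulate_parental_panels(cfg, n_a=5, n_b=5, n_outgroup=2)
    ped = sd.canonical_pedigree(HYBRIDS)
    hyb_gm, truth = sd.simulate_pedigree(panels, ped)
    keep = [h[0] for h in HYBRIDS]
    hyb_gm = hyb_gm.subset_individuals(keep)

    gm = fio.GenotypeMatrix(
        panels.gm.sites,
        panels.gm.individuals + hyb_gm.individuals,
        np.concatenate([panels.gm.dosage, hyb_gm.dosage], axis=1),
        np.concatenate([panels.gm.depth, hyb_gm.depth], axis=1),
    )
    all_panels = panels.panels.merged(
        fio.PanelAssignment({h[0]: "hybrid" for h in HYBRIDS},
                            {h[0]: h[2] for h in HYBRIDS})
    )
    lm = sd.genotypes_to_likelihoods(
        gm, cfg.depth_mean, cfg.error_rate, SEED + 10,
        sex=all_panels.sex, sex_linked=panels.cmap.sex_linked_names,
    )
    return panels, gm, lm, all_panels, truth


def main():
    OUT.mkdir(parents=True, exist_ok=True)
    panels, gm, lm, all_panels, truth = simulate()
    lengths = {e.name: e.length for e in panels.cmap.entries}
    fio.write_vcf(gm, OUT / "hybrid_zone.vcf", chrom_lengths=lengths)
    fio.write_beagle_gl(lm, OUT / "hybrid_zone.beagle.gl")
    fio.write_panels(all_panels, OUT / "panels.tsv")
    fio.write_chrom_map(panels.cmap, OUT / "chrom_map.tsv")
    sd.write_truth_tracts(truth, OUT / "truth_tracts.tsv")

    n_fixed = int((panels.site_labels == sd.SITE_FIXED).sum())
    print(f"simulated {gm.n_sites} SNPs x {gm.n_individuals} individuals "
          f"({n_fixed} true fixed differences) with seed {SEED}")
    for h, cls, _ in HYBRIDS:
        frac = truth.donor_fraction(h, "A")
        print(f"  {h} ({cls}): true genome-wide donor-A fraction {frac:.3f}")
    print(f"wrote {OUT}/hybrid_zone.vcf, .beagle.gl, panels.tsv, chrom_map.tsv, "
          "truth_tracts.tsv")


if __name__ == "__main__":
    main()
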