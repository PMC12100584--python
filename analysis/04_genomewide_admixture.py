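#!/usr/bin/env python
"""Genome-wide admixture proportions from genotype likelihoods.

Fits the K=2 binomial admixture model to the Beagle genotype likelihoods with
ten EM restarts (best likelihood kept) and orients components so Q_A = 1 is
pure parent A.  Reference individuals should land at the extremes; the F2 at
~0.5; first-generation backcrosses into B at ~0.25.
"""

import pathlib

import pandas as pd

from hybridpaint import formats_io as fio
from hybridpaint import gl_admixture as ga

ROOT = pathlib.Path(__file__).resolve().parents[1] / "results"
DATA = ROOT / "data"
SEED = 17


def main():
    lm = fio.read_beagle_gl(str(DATA / "hybrid_zone.beagle.gl"))
    panels = fio.read_panels(str(DATA / "panels.tsv"))
    used = [i for i in lm.individuals if panels.role.get(i) != "outgroup"]
    lm = lm.subset_individuals(used)

    fit = ga.admixture_em(lm, k=2, n_restarts=10, seed=SEED, min_maf=0.03)
    fit = ga.orient_ancestry(fit, panels)
    print(f"best log-likelihood {fit.loglik:.1f} over 10 restarts "
          f"(converged={fit.converged} after {fit.n_iter} iterations)")

    table = pd.DataFrame({
        "id": fit.individuals,
        "role": [panels.role[i] for i in fit.individuals],
        "Q_A": fit.q_a.round(4),
    })
    table.to_csv(ROOT / "admixture_Q.tsv", sep="\t", index=False)
    print(table.to_string(index=False))
    print(f"wrote {ROOT}/admixture_Q.tsv")


if __name__ == "__main__":
    main()
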