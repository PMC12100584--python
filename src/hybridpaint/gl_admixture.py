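"""Admixture-proportion estimation from genotype likelihoods.

The model is the standard low-coverage admixture model: individual i draws
each of its two allele copies at site j from ancestral population k with
probability Q_ik, and that copy is the alternate allele with probability
F_kj.  The individual's alt-allele dose therefore has prior
Binomial(2, a_ij) with a_ij = sum_k Q_ik F_kj, and the observed-data
log-likelihood marginalises the genotype through the GL triple:

    loglik = sum_ij log sum_g GL_ijg * C(2,g) a_ij^g (1 - a_ij)^(2-g)

Fitting is plain EM on the expected ancestry-labelled allele counts, which is
monotone in the log-likelihood; multi-restart selection keeps the repetition
with the highest likelihood.  No-data (uniform) GL triples are excluded from
the likelihood and the expected counts so that siteless genotypes cannot pull
Q toward the prior.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .formats_io import LikelihoodMatrix, PanelAssignment, ValidationError

__all__ = [
    "AdmixtureFit",
    "admixture_loglik",
    "admixture_em",
    "orient_ancestry",
    "estimate_site_freq",
]

_F_BOUND = 1e-6


@dataclass
class AdmixtureFit:
    """Result of a multi-restart EM fit."""

    individuals: list[str]
    q: np.ndarray  # (n_ind, K), rows on the simplex
    f: np.ndarray  # (K, n_sites) in [0, 1]
    loglik: float
    n_iter: int
    converged: bool
    restart_logliks: list[float]
    seed: int
    loglik_trace: np.ndarray = field(default_factory=lambda: np.empty(0))
    #: set by orient_ancestry: component 0 is parent A
    oriented: bool = False
    orientation_ambiguous: bool = False

    @property
    def k(self) -> int:
        return self.q.shape[1]

    @property
    def q_a(self) -> np.ndarray:
        """Parent-A admixture proportion per individual (requires orientation)."""
        if not self.oriented:
            raise ValidationError("fit is not oriented; call orient_ancestry first")
        return self.q[:, 0]

    def q_of(self, individual: str) -> np.ndarray:
        return self.q[self.individuals.index(individual)]


def _check_simplex(q: np.ndarray) -> None:
    if np.any(q < 0) or np.any(np.abs(q.sum(axis=1) - 1.0) > 1e-8):
        raise ValidationError("Q rows must lie on the probability simplex")


def _site_loglik_terms(gl: np.ndarray, a: np.ndarray) -> np.ndarray:
    """P(data_ij | a_ij) = sum_g GL_g * Binom(2, a) pmf, shape (n_sites, n_ind)."""
    g0 = (1.0 - a) ** 2
    g1 = 2.0 * a * (1.0 - a)
    g2 = a**2
    return gl[:, :, 0] * g0 + gl[:, :, 1] * g1 + gl[:, :, 2] * g2


def admixture_loglik(lm: LikelihoodMatrix, q: np.ndarray, f: np.ndarray) -> float:
    """Total log-likelihood of (Q, F); no-data genotypes contribute zero."""
    q = np.asarray(q, dtype=float)
    f = np.asarray(f, dtype=float)
    if q.shape != (lm.n_individuals, f.shape[0]) or f.shape[1] != lm.n_sites:
        raise ValidationError(
            f"dimension mismatch: Q {q.shape}, F {f.shape}, "
            f"data {lm.n_sites} sites x {lm.n_individuals} individuals"
        )
    _check_simplex(q)
    a = (q @ f).T  # (n_sites, n_ind)
    lik = _site_loglik_terms(lm.gl, a)
    keep = ~lm.missing
    return float(np.log(np.clip(lik, 1e-300, None))[keep].sum())


def estimate_site_freq(lm: LikelihoodMatrix) -> np.ndarray:
    """Crude per-site alt frequency: mean posterior-mean dose under a flat prior."""
    keep = ~lm.missing
    dose = lm.gl[:, :, 1] + 2.0 * lm.gl[:, :, 2]
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(keep, dose, 0.0).sum(axis=1) / (2.0 * keep.sum(axis=1))


def _em_once(
    gl: np.ndarray,
    keep: np.ndarray,
    q: np.ndarray,
    f: np.ndarray,
    max_iter: int,
    tol: float,
) -> tuple[np.ndarray, np.ndarray, float, int, bool, np.ndarray]:
    n_sites, n_ind, _ = gl.shape
    sites_per_ind = keep.sum(axis=0).astype(float)  # (n_ind,)
    trace = []
    prev = -np.inf
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        a = (q @ f).T  # (n_sites, n_ind)
        a = np.clip(a, _F_BOUND, 1.0 - _F_BOUND)
        g0 = (1.0 - a) ** 2
        g1 = 2.0 * a * (1.0 - a)
        g2 = a**2
        lik = gl[:, :, 0] * g0 + gl[:, :, 1] * g1 + gl[:, :, 2] * g2
        ll = float(np.log(np.clip(lik, 1e-300, None))[keep].sum())
        trace.append(ll)
        if ll - prev < tol and it > 1:
            converged = True
            break
        prev = ll
        # expected alt-allele dose per genotype given the data
        e = (gl[:, :, 1] * g1 + 2.0 * gl[:, :, 2] * g2) / lik
        e = np.where(keep, e, 0.0)
        two_minus_e = np.where(keep, 2.0 - e, 0.0)
        # attribute alleles to ancestral components
        # alt_k = e * Q_ik F_kj / a_ij ; ref_k = (2 - e) * Q_ik (1 - F_kj) / (1 - a_ij)
        alt_sum_f = np.empty_like(f)
        ref_sum_f = np.empty_like(f)
        q_new = np.empty_like(q)
        for k in range(q.shape[1]):
            share_alt = (q[:, k][None, :] * f[k][:, None]) / a  # (n_sites, n_ind)
            share_ref = (q[:, k][None, :] * (1.0 - f[k][:, None])) / (1.0 - a)
            alt_k = e * share_alt
            ref_k = two_minus_e * share_ref
            alt_sum_f[k] = alt_k.sum(axis=1)
            ref_sum_f[k] = ref_k.sum(axis=1)
            q_new[:, k] = (alt_k + ref_k).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            f = alt_sum_f / (alt_sum_f + ref_sum_f)
        f = np.clip(np.nan_to_num(f, nan=0.5), _F_BOUND, 1.0 - _F_BOUND)
        q = q_new / np.maximum(2.0 * sites_per_ind, 1.0)[:, None]
        q = np.clip(q, 0.0, None)
        q /= q.sum(axis=1, keepdims=True)
    return q, f, trace[-1], it, converged, np.asarray(trace)


def admixture_em(
    lm: LikelihoodMatrix,
    k: int = 2,
    n_restarts: int = 10,
    max_iter: int = 2000,
    tol: float = 1e-6,
    seed: int = 0,
    min_maf: float = 0.03,
) -> AdmixtureFit:
    """Multi-restart EM fit; returns the restart with the highest log-likelihood.

    Sites with estimated minor allele frequency below ``min_maf`` are dropped
    before fitting (set ``min_maf=0`` to keep everything); the returned F spans
    the retained sites.  Restarts draw Q rows from a symmetric Dirichlet(1) and
    F from the empirical per-site frequency perturbed by uniform noise, all
    from a generator seeded by ``seed``; identical seeds give identical fits.
    """
    if lm.n_individuals < k:
        raise ValidationError(f"need at least K={k} individuals")
    if min_maf > 0:
        freq = estimate_site_freq(lm)
        with np.errstate(invalid="ignore"):
            maf = np.minimum(freq, 1.0 - freq)
        keep_sites = np.nonzero(np.nan_to_num(maf) >= min_maf)[0]
        lm = lm.subset_sites(keep_sites)
    if lm.n_sites == 0:
        raise ValidationError("no informative sites left to fit")

    rng = np.random.default_rng(seed)
    gl = lm.gl
    keep = ~lm.missing
    emp_freq = np.nan_to_num(estimate_site_freq(lm), nan=0.5)

    best = None
    restart_logliks: list[float] = []
    for _ in range(max(1, n_restarts)):
        q0 = rng.dirichlet(np.ones(k), size=lm.n_individuals)
        f0 = np.clip(
            emp_freq[None, :] + rng.uniform(-0.3, 0.3, size=(k, lm.n_sites)),
            _F_BOUND,
            1.0 - _F_BOUND,
        )
        result = _em_once(gl, keep, q0, f0, max_iter, tol)
        restart_logliks.append(result[2])
        if best is None or result[2] > best[2]:
            best = result
    q, f, ll, n_iter, converged, trace = best
    return AdmixtureFit(
        list(lm.individuals), q, f, ll, n_iter, converged, restart_logliks, seed, trace
    )


def orient_ancestry(fit: AdmixtureFit, panels: PanelAssignment) -> AdmixtureFit:
    """Relabel a K=2 fit so component 0 is the parent-A ancestry.

    The component with the larger mean Q among parent-A reference individuals
    becomes "A"; Q_A = 1 then means pure parent A.  If the parent-A references
    do not distinguish the components the fit is returned flagged
    ``orientation_ambiguous`` (and left in its original order).
    """
    if fit.k != 2:
        raise ValidationError("orientation requires a K=2 fit")
    ref_a = [i for i in panels.parent_a if i in fit.individuals]
    if not ref_a:
        raise ValidationError("no parent-A reference individuals in fit")
    rows = [fit.individuals.index(i) for i in ref_a]
    mean_q = fit.q[rows].mean(axis=0)
    if abs(mean_q[0] - mean_q[1]) < 1e-6:
        return replace(fit, oriented=True, orientation_ambiguous=True)
    order = [0, 1] if mean_q[0] > mean_q[1] else [1, 0]
    return replace(
        fit,
        q=fit.q[:, order].copy(),
        f=fit.f[order].copy(),
        oriented=True,
        orientation_ambiguous=False,
    )
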