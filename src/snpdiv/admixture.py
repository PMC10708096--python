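"""Model-based admixture inference (Gibbs sampling) and Evanno ΔK selection.

Per sweep: the cluster of origin of every allele copy is drawn from
q_i * p_k^a (1-p_k)^(1-a); cluster allele frequencies from their Beta full
conditional (flat Beta(1,1) priors, or the correlated-frequency F-model
prior with p_A and per-cluster drift F updated by Metropolis steps); and
each q_i from Dirichlet(alpha + copy counts) with alpha fixed at 1. Missing
calls contribute no allele copies. ln P(D) is estimated as
mean(logL) - var(logL)/2 over retained sweeps.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from scipy.optimize import linear_sum_assignment
from scipy.special import betaln

from .io_formats import MISSING, GenotypeMatrix


@dataclass(frozen=True)
class McmcConfig:
    """Sampler configuration; full-scale defaults (burn-in 10k, run 100k, 10 reps, K 1-10)."""

    k: int = 1
    burn_in: int = 10_000
    run_length: int = 100_000
    n_replicates: int = 10
    k_range: tuple[int, int] = (1, 10)
    seed: int = 0
    correlated_frequencies: bool = False
    alpha: float = 1.0

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if self.run_length < 1 or self.burn_in < 0:
            raise ValueError("run_length >= 1 and burn_in >= 0 required")
        if self.k_range[0] > self.k_range[1]:
            raise ValueError("empty k_range")


def desk_scale_config(**overrides) -> McmcConfig:
    """Desk-scale defaults: burn-in 2000, run 5000, 3 replicates, K 1-4."""
    base = dict(burn_in=2000, run_length=5000, n_replicates=3, k_range=(1, 4))
    base.update(overrides)
    return McmcConfig(**base)


@dataclass
class AdmixtureReplicate:
    k: int
    q_mean: np.ndarray  # accessions x K, rows sum to 1
    freq_mean: np.ndarray  # K x loci
    ln_p_d: float
    seed: int


@dataclass
class EvannoTable:
    k_values: list[int]
    mean_lnk: dict[int, float]
    sd_lnk: dict[int, float]
    l_prime: dict[int, float]  # L'(K), defined for K with a left neighbour
    l_double_abs: dict[int, float]  # |L''(K)|, interior K only
    delta_k: dict[int, float]  # interior K with sd > 0
    chosen_k: int | None


def gibbs_admixture(g: GenotypeMatrix, cfg: McmcConfig) -> AdmixtureReplicate:
    """One MCMC run at cfg.k with cfg.seed; returns posterior means."""
    k = cfg.k
    if k < 1:
        raise ValueError("K must be >= 1")
    if (g.dosage == MISSING).all(axis=1).any():
        raise ValueError("accession with all calls missing")
    n, L = g.n_accessions, g.n_loci
    rng = np.random.default_rng(cfg.seed)

    # allele copies: (2, N, L) in {0,1}, mask for called copies
    d = g.dosage
    copies = np.stack([np.where(d == 2, 1, 0), np.where(d >= 1, 1, 0)]).astype(float)
    called = np.broadcast_to(d != MISSING, (2, n, L)).copy()
    copies[~called] = 0.0

    q = np.full((n, k), 1.0 / k)
    p = rng.uniform(0.1, 0.9, size=(k, L))
    # F-model state (used when correlated_frequencies)
    p_anc = np.clip(np.nanmean(np.where(d == MISSING, np.nan, d), axis=0) / 2.0, 0.02, 0.98)
    f_drift = np.full(k, 0.1)

    q_sum = np.zeros((n, k))
    p_sum = np.zeros((k, L))
    loglik: list[float] = []
    n_kept = 0

    a = copies[..., None]  # (2, N, L, 1)

    for sweep in range(cfg.burn_in + cfg.run_length):
        # per-copy cluster likelihood: (2, N, L, K)
        p_t = p.T[None, None]  # (1, 1, L, K)
        like = np.where(a == 1.0, p_t, 1.0 - p_t)
        w = q[None, :, None, :] * like
        w_sum = w.sum(axis=-1)
        ll = float(np.log(w_sum[called]).sum())
        if not np.isfinite(ll):
            raise FloatingPointError("non-finite likelihood in admixture sampler")

        if k == 1:
            z = np.zeros((2, n, L), dtype=np.intp)
        else:
            cum = np.cumsum(w, axis=-1)
            u = rng.random((2, n, L, 1)) * cum[..., -1:]
            z = (u > cum).sum(axis=-1).clip(max=k - 1)

        # cluster allele counts
        n1 = np.zeros((k, L))
        n_tot = np.zeros((k, L))
        for cluster in range(k):
            sel = (z == cluster) & called
            n1[cluster] = (copies * sel).sum(axis=(0, 1))
            n_tot[cluster] = sel.sum(axis=(0, 1))
        n0 = n_tot - n1

        if cfg.correlated_frequencies:
            shape = (1.0 - f_drift) / f_drift  # per cluster
            alpha_p = p_anc[None, :] * shape[:, None]
            beta_p = (1.0 - p_anc)[None, :] * shape[:, None]
            p = rng.beta(alpha_p + n1, beta_p + n0)
            _update_f_model(rng, p, p_anc, f_drift)
        else:
            p = rng.beta(1.0 + n1, 1.0 + n0)
        p = np.clip(p, 1e-9, 1.0 - 1e-9)

        # q update from per-individual copy counts
        m = np.zeros((n, k))
        for cluster in range(k):
            m[:, cluster] = ((z == cluster) & called).sum(axis=(0, 2))
        gamma = rng.gamma(cfg.alpha + m)
        q = gamma / gamma.sum(axis=1, keepdims=True)

        if sweep >= cfg.burn_in:
            q_sum += q
            p_sum += p
            loglik.append(ll)
            n_kept += 1

    ll_arr = np.array(loglik)
    ln_p_d = float(ll_arr.mean() - 0.5 * ll_arr.var())
    q_mean = q_sum / n_kept
    if k == 1:
        q_mean = np.ones((n, 1))
    return AdmixtureReplicate(
        k=k, q_mean=q_mean, freq_mean=p_sum / n_kept, ln_p_d=ln_p_d, seed=cfg.seed
    )


def _update_f_model(
    rng: np.random.Generator, p: np.ndarray, p_anc: np.ndarray, f_drift: np.ndarray
) -> None:
    """Metropolis updates of the ancestral frequencies (reflected random walk
    in (0,1)) and per-cluster drift F (log-scale walk), in place."""
    k, L = p.shape

    def log_prior(pa: np.ndarray, f: np.ndarray) -> np.ndarray:
        shape = (1.0 - f) / f
        alpha = pa[None, :] * shape[:, None]
        beta = (1.0 - pa)[None, :] * shape[:, None]
        with np.errstate(divide="ignore"):
            return (
                (alpha - 1.0) * np.log(p)
                + (beta - 1.0) * np.log1p(-p)
                - betaln(alpha, beta)
            )

    # ancestral frequency per locus
    prop = p_anc + rng.normal(0.0, 0.05, size=L)
    prop = np.abs(prop)  # reflect at 0
    prop = np.where(prop > 1.0, 2.0 - prop, prop)
    prop = np.clip(prop, 1e-4, 1.0 - 1e-4)
    with np.errstate(invalid="ignore", over="ignore"):
        delta = (log_prior(prop, f_drift) - log_prior(p_anc, f_drift)).sum(axis=0)
    delta = np.where(np.isnan(delta), -np.inf, delta)
    accept = np.log(rng.random(L)) < delta
    p_anc[accept] = prop[accept]

    # per-cluster drift
    prop_f = np.clip(f_drift * np.exp(rng.normal(0.0, 0.2, size=k)), 1e-4, 0.9)
    with np.errstate(invalid="ignore", over="ignore"):
        delta_f = (log_prior(p_anc, prop_f) - log_prior(p_anc, f_drift)).sum(axis=1)
        delta_f += np.log(prop_f) - np.log(f_drift)  # log-scale proposal Jacobian
    delta_f = np.where(np.isnan(delta_f), -np.inf, delta_f)
    accept_f = np.log(rng.random(k)) < delta_f
    f_drift[accept_f] = prop_f[accept_f]


def replicate_seed(master_seed: int, k: int, rep: int) -> int:
    """Stable derived seed for one (K, replicate) run."""
    ss = np.random.SeedSequence(entropy=master_seed, spawn_key=(k, rep))
    return int(ss.generate_state(1)[0])


def run_K_sweep(g: GenotypeMatrix, cfg: McmcConfig) -> list[AdmixtureReplicate]:
    """n_replicates runs per K over k_range, each with a distinct derived
    seed; result order is (K ascending, replicate ascending)."""
    out: list[AdmixtureReplicate] = []
    for k in range(cfg.k_range[0], cfg.k_range[1] + 1):
        for rep in range(cfg.n_replicates):
            run_cfg = replace(cfg, k=k, seed=replicate_seed(cfg.seed, k, rep))
            out.append(gibbs_admixture(g, run_cfg))
    return out


def evanno(replicates: Sequence[AdmixtureReplicate]) -> EvannoTable:
    """ΔK = |L''(K)| / sd(L(K)), maximized over interior K."""
    by_k: dict[int, list[float]] = {}
    for rep in replicates:
        by_k.setdefault(rep.k, []).append(rep.ln_p_d)
    k_values = sorted(by_k)
    if len(k_values) < 3 or k_values != list(range(k_values[0], k_values[-1] + 1)):
        raise ValueError("need >= 3 consecutive K values")
    if any(len(v) < 2 for v in by_k.values()):
        raise ValueError("need >= 2 replicates per K")
    mean_lnk = {k: float(np.mean(by_k[k])) for k in k_values}
    sd_lnk = {k: float(np.std(by_k[k], ddof=1)) for k in k_values}
    l_prime = {k: mean_lnk[k] - mean_lnk[k - 1] for k in k_values[1:]}
    interior = k_values[1:-1]
    l_double = {k: abs(l_prime[k + 1] - l_prime[k]) for k in interior}
    delta_k = {k: l_double[k] / sd_lnk[k] for k in interior if sd_lnk[k] > 0}
    chosen: int | None = None
    if delta_k and max(delta_k.values()) > 0:
        chosen = max(delta_k, key=delta_k.get)
    return EvannoTable(
        k_values=k_values,
        mean_lnk=mean_lnk,
        sd_lnk=sd_lnk,
        l_prime=l_prime,
        l_double_abs=l_double,
        delta_k=delta_k,
        chosen_k=chosen,
    )


def align_replicates(
    replicates: Sequence[AdmixtureReplicate],
) -> tuple[list[AdmixtureReplicate], np.ndarray]:
    """Permute cluster columns of each replicate to best match the first
    (optimal assignment minimizing summed |Δq|); returns aligned copies and
    the consensus mean q."""
    if not replicates:
        raise ValueError("no replicates")
    k = replicates[0].k
    if any(rep.k != k for rep in replicates):
        raise ValueError("replicates have mismatched K")
    ref = replicates[0].q_mean
    aligned: list[AdmixtureReplicate] = []
    for rep in replicates:
        cost = np.abs(ref[:, :, None] - rep.q_mean[:, None, :]).sum(axis=0)
        _, cols = linear_sum_assignment(cost)
        aligned.append(
            AdmixtureReplicate(
                k=k,
                q_mean=rep.q_mean[:, cols],
                freq_mean=rep.freq_mean[cols, :],
                ln_p_d=rep.ln_p_d,
                seed=rep.seed,
            )
        )
    consensus = np.mean([rep.q_mean for rep in aligned], axis=0)
    return aligned, consensus


def alignment_cost(q_ref: np.ndarray, q_other: np.ndarray) -> float:
    """Summed |Δq| under the optimal column permutation (exposed for tests)."""
    cost = np.abs(q_ref[:, :, None] - q_other[:, None, :]).sum(axis=0)
    rows, cols = linear_sum_assignment(cost)
    return float(cost[rows, cols].sum())
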