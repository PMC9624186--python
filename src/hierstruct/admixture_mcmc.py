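"""Gibbs sampler for the Bayesian admixture clustering model.

The model: each individual i has admixture proportions q_i over K clusters;
each cluster k has allele frequencies p_{k,l,.} at every locus l; each gene
copy (i, l, c) has a latent origin z and, given z = k, the observed allele a
is drawn from p_{k,l,.}.  Priors: p ~ symmetric Dirichlet(λ) per (k, l)
simplex (independent-frequency model), q_i ~ symmetric Dirichlet(α) with α
optionally inferred by a Metropolis step under a uniform prior on (0, α_max].

All updates are the standard conjugate full conditionals:

* z: P(z = k) ∝ q_{i,k} · p_{k,l,a}
* p_{k,l,.} ~ Dirichlet(λ + allele counts currently assigned to k)
* q_i ~ Dirichlet(α + per-cluster copy counts of individual i)

Missing gene copies carry no z and contribute nothing to counts or to the
likelihood; internally the sampler iterates over a flat list of the
non-missing copies only.  The evidence for K is estimated from the thinned
post-burn-in log-likelihood trace as mean − var/2.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import linear_sum_assignment
from scipy.special import gammaln

from .genotype_data import GenotypeMatrix

try:
    from numba import njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba is an optional accelerator
    _HAVE_NUMBA = False

    def njit(*a, **k):  # type: ignore[misc]
        def wrap(f):
            return f

        return wrap


@dataclass
class MCMCConfig:
    K: int = 2
    burn_in: int = 2000
    reps: int = 8000
    freq_lambda: float = 1.0
    alpha: float = 1.0
    infer_alpha: bool = True
    alpha_max: float = 10.0
    alpha_proposal_sd: float = 0.05
    thin: int = 10
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.K < 1:
            raise ValueError("K must be >= 1")
        if self.burn_in < 0 or self.reps < 1:
            raise ValueError("burn_in must be >= 0 and reps >= 1")
        if self.freq_lambda <= 0 or self.alpha <= 0:
            raise ValueError("priors lambda and alpha must be > 0")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")


@dataclass
class SamplerState:
    """Mutable state of one chain.

    Non-missing gene copies live in flat arrays of length M: ``copy_ind``
    (individual index), ``copy_locus`` and ``copy_allele`` (densely recoded
    0..J_l-1 per locus); ``z`` holds each copy's latent origin.  The dense
    ``(N, L, 2)`` view of z, with -1 on missing copies, is available via
    :meth:`z_dense`.
    """

    n_individuals: int
    n_loci: int
    K: int
    copy_ind: np.ndarray
    copy_locus: np.ndarray
    copy_allele: np.ndarray
    valid: np.ndarray            # (N, L, 2) bool, for presentation only
    locus_n_alleles: np.ndarray  # (L,)
    allele_codes: list[np.ndarray]
    z: np.ndarray                # (M,)
    Q: np.ndarray                # (N, K)
    P: np.ndarray                # (K, L, Jmax)
    alpha: float
    freq_lambda: float
    rng: np.random.Generator
    _pl_flat: np.ndarray = field(default=None, repr=False)  # copy_locus*Jmax+copy_allele
    _pad: np.ndarray = field(default=None, repr=False)      # (L, Jmax) padded-slot mask

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.n_individuals, self.n_loci, self.K

    def z_dense(self) -> np.ndarray:
        out = np.full(self.valid.shape, -1, dtype=np.int64)
        out[self.valid] = self.z
        return out


@dataclass
class StructureRun:
    """Posterior summary of one MCMC run."""

    config: MCMCConfig
    individual_ids: list[str]
    pop_labels: list[str]
    Q: np.ndarray                # (N, K) posterior means
    P: np.ndarray                # (K, L, Jmax) posterior means
    allele_codes: list[np.ndarray]
    lnL_trace: np.ndarray
    lnPD: float

    def write_q_tsv(self, path: str) -> None:
        with open(path, "w") as fh:
            cols = "\t".join(f"q{k + 1}" for k in range(self.config.K))
            fh.write(f"individual\tpopulation\t{cols}\n")
            for ind, pop, row in zip(self.individual_ids, self.pop_labels, self.Q):
                vals = "\t".join(f"{v:.6f}" for v in row)
                fh.write(f"{ind}\t{pop}\t{vals}\n")

    def write_trace_tsv(self, path: str) -> None:
        with open(path, "w") as fh:
            fh.write("sample\tlnL\n")
            for i, v in enumerate(self.lnL_trace):
                fh.write(f"{i + 1}\t{v:.4f}\n")

    def write_summary_json(self, path: str) -> None:
        trace = np.asarray(self.lnL_trace)
        payload = {
            "K": self.config.K,
            "burn_in": self.config.burn_in,
            "reps": self.config.reps,
            "seed": self.config.seed,
            "lnPD": float(self.lnPD),
            "lnL_mean": float(trace.mean()),
            "lnL_var": float(trace.var(ddof=1)) if trace.size > 1 else 0.0,
            "n_samples": int(trace.size),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)


def _recode(g: GenotypeMatrix) -> tuple[np.ndarray, np.ndarray, list[np.ndarray]]:
    """Dense per-locus recoding of raw allele codes to 0..J_l-1 (-1 missing)."""
    n, L = g.n_individuals, g.n_loci
    recoded = np.full((n, L, 2), -1, dtype=np.int64)
    counts = np.empty(L, dtype=np.int64)
    code_maps: list[np.ndarray] = []
    for l in range(L):
        col = g.alleles[:, l, :]
        mask = col != g.missing_code
        codes, inv = np.unique(col[mask], return_inverse=True)
        if codes.size == 0:
            codes = np.array([0], dtype=np.int64)  # degenerate: all-missing locus
        recoded[:, l, :][mask] = inv
        counts[l] = codes.size
        code_maps.append(codes)
    return recoded, counts, code_maps


def init_state(g: GenotypeMatrix, cfg: MCMCConfig) -> SamplerState:
    """Initialize a chain: z uniform over clusters, P from its prior, Q = 1/K."""
    if g.n_individuals == 0 or g.n_loci == 0:
        raise ValueError("empty genotype matrix")
    rng = np.random.default_rng(cfg.seed)
    alleles, locus_n, code_maps = _recode(g)
    valid = alleles >= 0
    n, L = alleles.shape[:2]
    K = cfg.K
    jmax = int(locus_n.max())

    iidx = np.broadcast_to(np.arange(n)[:, None, None], alleles.shape)
    lidx = np.broadcast_to(np.arange(L)[None, :, None], alleles.shape)
    copy_ind = iidx[valid]
    copy_locus = lidx[valid]
    copy_allele = alleles[valid]
    m = copy_ind.size

    P = np.zeros((K, L, jmax))
    for l in range(L):
        j = int(locus_n[l])
        P[:, l, :j] = rng.dirichlet(np.full(j, cfg.freq_lambda), size=K)
    state = SamplerState(
        n_individuals=n,
        n_loci=L,
        K=K,
        copy_ind=copy_ind,
        copy_locus=copy_locus,
        copy_allele=copy_allele,
        valid=valid,
        locus_n_alleles=locus_n,
        allele_codes=code_maps,
        z=rng.integers(0, K, size=m),
        Q=np.full((n, K), 1.0 / K),
        P=P,
        alpha=cfg.alpha,
        freq_lambda=cfg.freq_lambda,
        rng=rng,
    )
    state._pl_flat = copy_locus * jmax + copy_allele
    state._pad = np.arange(jmax)[None, :] >= locus_n[:, None]
    return state


def _copy_weights(state: SamplerState) -> np.ndarray:
    """w[m, k] = Q[i_m, k] * P[k, l_m, a_m] for every non-missing copy m."""
    pf = state.P.reshape(state.K, -1)[:, state._pl_flat]  # (K, M)
    return state.Q[state.copy_ind, :] * pf.T


def update_Z(state: SamplerState) -> SamplerState:
    """Resample every non-missing gene copy's latent origin."""
    w = _copy_weights(state)
    c = np.cumsum(w, axis=1)
    u = state.rng.random(w.shape[0]) * c[:, -1]
    z = (c < u[:, None]).sum(axis=1)
    np.clip(z, 0, state.K - 1, out=z)
    state.z = z
    return state


def update_P(state: SamplerState) -> SamplerState:
    """Conjugate Dirichlet(λ + counts) resampling of all (k, l) simplexes."""
    K, L = state.K, state.n_loci
    jmax = state.P.shape[2]
    flat = state.z * (L * jmax) + state._pl_flat
    counts = np.bincount(flat, minlength=K * L * jmax).reshape(K, L, jmax)
    shape = counts + state.freq_lambda
    shape[:, state._pad] = 0.0
    draws = state.rng.gamma(np.maximum(shape, 1e-300)) * (shape > 0)
    sums = draws.sum(axis=2, keepdims=True)
    sums[sums == 0] = 1.0
    state.P = draws / sums
    return state


def update_Q(state: SamplerState) -> SamplerState:
    """Conjugate Dirichlet(α + copy counts) resampling of every q_i."""
    n, K = state.n_individuals, state.K
    flat = state.copy_ind * K + state.z
    counts = np.bincount(flat, minlength=n * K).reshape(n, K)
    draws = state.rng.gamma(counts + state.alpha)
    draws = np.maximum(draws, 1e-300)
    state.Q = draws / draws.sum(axis=1, keepdims=True)
    return state


def _alpha_log_lik(alpha: float, log_q_sum: float, n: int, K: int) -> float:
    return n * (gammaln(K * alpha) - K * gammaln(alpha)) + (alpha - 1.0) * log_q_sum


def update_alpha(state: SamplerState, alpha_max: float = 10.0, proposal_sd: float = 0.05) -> SamplerState:
    """Metropolis step on α with a symmetric normal proposal, uniform prior."""
    n, _, K = state.shape
    prop = state.alpha + state.rng.normal(0.0, proposal_sd)
    # draw the acceptance uniform unconditionally to keep the stream aligned
    u = state.rng.random()
    if prop <= 0.0 or prop > alpha_max:
        return state
    log_q_sum = float(np.log(np.maximum(state.Q, 1e-300)).sum())
    log_ratio = _alpha_log_lik(prop, log_q_sum, n, K) - _alpha_log_lik(
        state.alpha, log_q_sum, n, K
    )
    if np.log(u) < log_ratio:
        state.alpha = float(prop)
    return state


def log_likelihood(state: SamplerState) -> float:
    """ln Pr(X | P, Q) summed over non-missing gene copies."""
    mix = _copy_weights(state).sum(axis=1)
    if (mix <= 0).any():
        raise FloatingPointError("zero mixture probability encountered")
    return float(np.log(mix).sum())


def log_likelihood_direct(g: GenotypeMatrix, P: np.ndarray, Q: np.ndarray,
                          allele_codes: list[np.ndarray]) -> float:
    """Likelihood from raw inputs; per-copy loop, used as a slow reference."""
    total = 0.0
    lookup = [{int(a): j for j, a in enumerate(codes)} for codes in allele_codes]
    for i in range(g.n_individuals):
        for l in range(g.n_loci):
            for c in (0, 1):
                a = g.alleles[i, l, c]
                if a == g.missing_code:
                    continue
                j = lookup[l][int(a)]
                total += float(np.log((Q[i] * P[:, l, j]).sum()))
    return total


def estimate_lnPD(lnL_trace: np.ndarray) -> float:
    """Evidence estimate for K: mean(lnL) − var(lnL)/2 over the trace."""
    trace = np.asarray(lnL_trace, dtype=float)
    if trace.size < 2:
        raise ValueError("trace must contain at least 2 values")
    return float(trace.mean() - trace.var(ddof=1) / 2.0)


@njit(cache=True)
def _chain_kernel(copy_ind, pl_flat, locus_n, K, N, L, jmax,
                  burn_in, reps, thin, lam, alpha0, infer_alpha,
                  alpha_max, prop_sd, seed):  # pragma: no cover - exercised via run_mcmc
    """Whole-chain Gibbs loop; same full conditionals as the numpy functions."""
    np.random.seed(seed)
    LJ = L * jmax
    M = copy_ind.shape[0]
    z = np.empty(M, np.int64)
    for m in range(M):
        z[m] = np.random.randint(0, K)
    P = np.zeros((K, LJ))
    for k in range(K):
        for l in range(L):
            tot = 0.0
            for j in range(locus_n[l]):
                v = np.random.gamma(lam, 1.0)
                P[k, l * jmax + j] = v
                tot += v
            for j in range(locus_n[l]):
                P[k, l * jmax + j] /= tot
    Q = np.full((N, K), 1.0 / K)
    alpha = alpha0
    q_acc = np.zeros((N, K))
    p_acc = np.zeros((K, LJ))
    n_samples = (reps + thin - 1) // thin
    trace = np.empty(n_samples)
    w = np.empty(K)
    pcounts = np.zeros((K, LJ))
    qcounts = np.zeros((N, K))
    s_idx = 0
    for sweep in range(burn_in + reps):
        record = sweep >= burn_in and (sweep - burn_in) % thin == 0
        lnl = 0.0
        pcounts[:, :] = 0.0
        qcounts[:, :] = 0.0
        for m in range(M):
            i = copy_ind[m]
            base = pl_flat[m]
            tot = 0.0
            for k in range(K):
                wk = Q[i, k] * P[k, base]
                w[k] = wk
                tot += wk
            u = np.random.random() * tot
            acc = 0.0
            zk = K - 1
            for k in range(K):
                acc += w[k]
                if u < acc:
                    zk = k
                    break
            z[m] = zk
            pcounts[zk, base] += 1.0
            qcounts[i, zk] += 1.0
            if record:
                lnl += np.log(tot)
        for k in range(K):
            for l in range(L):
                tot = 0.0
                for j in range(locus_n[l]):
                    v = np.random.gamma(lam + pcounts[k, l * jmax + j], 1.0)
                    P[k, l * jmax + j] = v
                    tot += v
                for j in range(locus_n[l]):
                    P[k, l * jmax + j] /= tot
        for i in range(N):
            tot = 0.0
            for k in range(K):
                v = np.random.gamma(alpha + qcounts[i, k], 1.0)
                if v < 1e-300:
                    v = 1e-300
                Q[i, k] = v
                tot += v
            for k in range(K):
                Q[i, k] /= tot
        if infer_alpha and K > 1:
            prop = alpha + np.random.normal(0.0, prop_sd)
            u = np.random.random()
            if 0.0 < prop <= alpha_max:
                lq = 0.0
                for i in range(N):
                    for k in range(K):
                        qv = Q[i, k]
                        if qv < 1e-300:
                            qv = 1e-300
                        lq += np.log(qv)
                lr = (
                    N * (math.lgamma(K * prop) - K * math.lgamma(prop))
                    + (prop - 1.0) * lq
                ) - (
                    N * (math.lgamma(K * alpha) - K * math.lgamma(alpha))
                    + (alpha - 1.0) * lq
                )
                if np.log(u) < lr:
                    alpha = prop
        if record:
            q_acc += Q
            p_acc += P
            trace[s_idx] = lnl
            s_idx += 1
    return q_acc, p_acc, trace[:s_idx]


def _run_mcmc_fast(g: GenotypeMatrix, cfg: MCMCConfig) -> StructureRun:
    state = init_state(g, cfg)  # reuse recoding / flat-copy bookkeeping
    n, L, K = state.shape
    jmax = state.P.shape[2]
    seed = int(np.random.SeedSequence(cfg.seed).generate_state(1)[0])
    q_acc, p_acc, trace = _chain_kernel(
        state.copy_ind,
        state._pl_flat,
        state.locus_n_alleles,
        K,
        n,
        L,
        jmax,
        cfg.burn_in,
        cfg.reps,
        cfg.thin,
        cfg.freq_lambda,
        cfg.alpha,
        cfg.infer_alpha,
        cfg.alpha_max,
        cfg.alpha_proposal_sd,
        seed,
    )
    n_acc = trace.size
    if n_acc < 2:
        raise ValueError("too few post-burn-in samples; increase reps or lower thin")
    return StructureRun(
        config=cfg,
        individual_ids=list(g.individual_ids),
        pop_labels=list(g.pop_labels),
        Q=q_acc / n_acc,
        P=(p_acc / n_acc).reshape(K, L, jmax),
        allele_codes=state.allele_codes,
        lnL_trace=trace,
        lnPD=estimate_lnPD(trace),
    )


def run_mcmc(g: GenotypeMatrix, cfg: MCMCConfig, engine: str = "auto") -> StructureRun:
    """Run one chain: burn-in, then ``reps`` sweeps with thinned accumulation.

    One sweep = update_Z, update_P, update_Q and (optionally) update_alpha.
    Q and P are posterior means over the thinned post-burn-in sweeps; lnPD is
    the mean − var/2 evidence estimate from the thinned likelihood trace.

    ``engine``: "numba" (compiled whole-chain loop, default when available),
    "numpy" (the reference per-update implementation) or "auto".  Both
    engines sample the same full conditionals but use different RNG streams,
    so they agree statistically, not bitwise.
    """
    if engine not in ("auto", "numba", "numpy"):
        raise ValueError(f"unknown engine {engine!r}")
    if engine == "numba" and not _HAVE_NUMBA:
        raise RuntimeError("numba is not available")
    if engine in ("numba", "auto") and _HAVE_NUMBA:
        return _run_mcmc_fast(g, cfg)
    state = init_state(g, cfg)
    q_acc = np.zeros_like(state.Q)
    p_acc = np.zeros_like(state.P)
    trace: list[float] = []
    n_acc = 0
    infer = cfg.infer_alpha and cfg.K > 1
    for sweep in range(cfg.burn_in + cfg.reps):
        update_Z(state)
        update_P(state)
        update_Q(state)
        if infer:
            update_alpha(state, cfg.alpha_max, cfg.alpha_proposal_sd)
        if sweep >= cfg.burn_in and (sweep - cfg.burn_in) % cfg.thin == 0:
            q_acc += state.Q
            p_acc += state.P
            trace.append(log_likelihood(state))
            n_acc += 1
    if n_acc < 2:
        raise ValueError("too few post-burn-in samples; increase reps or lower thin")
    return StructureRun(
        config=cfg,
        individual_ids=list(g.individual_ids),
        pop_labels=list(g.pop_labels),
        Q=q_acc / n_acc,
        P=p_acc / n_acc,
        allele_codes=state.allele_codes,
        lnL_trace=np.array(trace),
        lnPD=estimate_lnPD(np.array(trace)),
    )


def align_runs(runs: list[StructureRun]) -> list[StructureRun]:
    """Permute cluster labels of each run to best match the first run.

    Uses an optimal linear assignment on the Q-column inner-product matrix
    (so total column agreement can never drop below the unaligned value).
    """
    if not runs:
        return []
    ref = runs[0]
    K = ref.config.K
    for r in runs[1:]:
        if r.config.K != K or r.Q.shape != ref.Q.shape:
            raise ValueError("all runs must share K and individuals")
    if K == 1:
        return list(runs)
    aligned = [ref]
    for r in runs[1:]:
        score = ref.Q.T @ r.Q  # score[k_ref, k_run]
        _, perm = linear_sum_assignment(-score)
        aligned.append(replace(r, Q=r.Q[:, perm].copy(), P=r.P[perm].copy()))
    return aligned
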