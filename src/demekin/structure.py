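"""Population-based structure inference from genotype likelihoods.

Implements the evolutionary-timescale track of the pipeline: an iterative
individual-allele-frequency PCA of the genotype-likelihood matrix (the
covariance is estimated from posterior expected genotypes, standardized by
the pooled frequency, and the individual frequencies are refined from the
top principal components), a maximum-likelihood admixture model fitted by
EM directly on the likelihoods, across-seed comparison of runs at each
number of ancestral components K, and a residual-correlation diagnostic of
model fit: when the admixture model fits, the pairwise correlation of
per-individual residuals is close to zero, while unmodelled structure or
family sampling leaves positive blocks.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

from demekin.genio import GLMatrix, SiteFrequencies, estimate_allele_frequencies, hwe_priors

_FREQ_EPS = 1e-5


@dataclass
class PCAResult:
    covariance: np.ndarray
    eigenvalues: np.ndarray
    eigenvectors: np.ndarray
    variance_fraction: np.ndarray
    iterations: int

    def scores(self, n: int | None = None) -> np.ndarray:
        """Individual scores on the leading components."""
        n = len(self.eigenvalues) if n is None else n
        return self.eigenvectors[:, :n] * np.sqrt(np.maximum(self.eigenvalues[:n], 0))


@dataclass
class AdmixtureResult:
    Q: np.ndarray  # (N, K) ancestry proportions
    A: np.ndarray  # (K, M) ancestral allele frequencies
    loglik: float
    seed: int
    iterations: int
    loglik_path: np.ndarray | None = None


@dataclass
class ResidualCorrelation:
    ids: list[str]
    correlation: np.ndarray
    block_means: pd.DataFrame | None = None


def _expected_genotypes(gl: np.ndarray, pi: np.ndarray) -> np.ndarray:
    """Posterior mean dosage under per-entry binomial priors at pi (N, M)."""
    prior = np.stack(
        [(1 - pi) ** 2, 2 * pi * (1 - pi), pi**2], axis=-1
    )
    post = gl * prior
    norm = post.sum(axis=-1, keepdims=True)
    norm[norm == 0] = 1.0
    post = post / norm
    return post @ np.arange(3.0)


# ---------------------------------------------------------------------------
# genotype-likelihood PCA
# ---------------------------------------------------------------------------

def pcangsd_pca(
    gl: GLMatrix,
    freqs: SiteFrequencies | None = None,
    n_components: int = 2,
    tol: float = 1e-5,
    max_iter: int = 100,
) -> PCAResult:
    """Iterative individual-allele-frequency PCA of genotype likelihoods.

    Expected genotypes e_is are computed under per-individual frequency
    priors pi_is (initially the pooled frequency f_s), the covariance
    C_ij = (1/M) sum_s (e_is - 2 pi_is)(e_js - 2 pi_js) / (2 f_s (1 - f_s))
    is eigendecomposed, the individual frequencies are reconstructed from
    the top ``n_components`` eigenvectors, and the loop repeats until the
    covariance stabilizes (Frobenius change below ``tol``).
    """
    if gl.n_individuals < 2:
        raise ValueError("need at least two individuals")
    if freqs is None:
        freqs = estimate_allele_frequencies(gl)
    keep = freqs.polymorphic
    if not keep.any():
        raise ValueError("no polymorphic sites")
    g = gl.gl[:, keep]
    f = freqs.freq[keep]
    n, m = g.shape[0], g.shape[1]
    denom = 2.0 * f * (1.0 - f)

    pi = np.tile(f, (n, 1))
    cov_prev = None
    iterations = 0
    for it in range(1, max_iter + 1):
        iterations = it
        e = _expected_genotypes(g, pi)
        # center by the pooled frequency: the individual frequencies enter
        # only through the genotype posterior, otherwise the structure the
        # components should capture would be subtracted before the PCA
        r = (e - 2.0 * f[None, :]) / np.sqrt(denom)[None, :]
        cov = (r @ r.T) / m
        vals, vecs = np.linalg.eigh(cov)
        order = np.argsort(vals)[::-1]
        vals, vecs = vals[order], vecs[:, order]
        if cov_prev is not None and np.linalg.norm(cov - cov_prev) < tol:
            break
        cov_prev = cov
        # refine individual frequencies from the top components
        u = vecs[:, :n_components]
        recon = u @ (u.T @ (e - 2.0 * f[None, :]))
        pi = np.clip(f[None, :] + recon / 2.0, _FREQ_EPS, 1 - _FREQ_EPS)

    var_frac = np.maximum(vals, 0)
    total = var_frac.sum()
    var_frac = var_frac / total if total > 0 else var_frac
    return PCAResult(
        covariance=cov,
        eigenvalues=vals,
        eigenvectors=vecs,
        variance_fraction=var_frac,
        iterations=iterations,
    )


# ---------------------------------------------------------------------------
# admixture EM
# ---------------------------------------------------------------------------

def admixture_loglik(gl_poly: np.ndarray, pi: np.ndarray) -> float:
    """sum_i sum_s log sum_g GL(g) Binom(g; 2, pi_is)."""
    prior = np.stack([(1 - pi) ** 2, 2 * pi * (1 - pi), pi**2], axis=-1)
    per = (gl_poly * prior).sum(axis=-1)
    per = np.maximum(per, 1e-300)
    return float(np.log(per).sum())


def admixture_em(
    gl: GLMatrix,
    K: int,
    seed: int = 0,
    freqs: SiteFrequencies | None = None,
    tol: float = 1e-4,
    max_iter: int = 2000,
    track_loglik: bool = False,
) -> AdmixtureResult:
    """Maximum-likelihood admixture proportions from genotype likelihoods.

    The model: individual i's derived-allele frequency at site s is
    pi_is = sum_k Q_ik A_ks, genotypes are Binomial(2, pi_is), and the data
    enter through their likelihoods.  EM attributes the posterior expected
    derived and ancestral allele counts to ancestries proportionally to
    Q_ik A_ks / pi_is (resp. Q_ik (1 - A_ks) / (1 - pi_is)) and renormalizes.
    Restricted to polymorphic sites; K = 1 reduces to the pooled-frequency
    model.
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    if K > gl.n_individuals:
        raise ValueError("K cannot exceed the number of individuals")
    if freqs is None:
        freqs = estimate_allele_frequencies(gl)
    keep = freqs.polymorphic
    if not keep.any():
        raise ValueError("no polymorphic sites")
    g = gl.gl[:, keep]
    n, m = g.shape[0], g.shape[1]
    rng = np.random.default_rng(seed)

    q = rng.dirichlet(np.ones(K), size=n)  # (N, K)
    a = np.clip(
        freqs.freq[keep][None, :] + rng.normal(0, 0.1, size=(K, m)),
        _FREQ_EPS,
        1 - _FREQ_EPS,
    )
    loglik_path = []
    prev_ll = -np.inf
    iterations = 0
    for it in range(1, max_iter + 1):
        iterations = it
        pi = np.clip(q @ a, _FREQ_EPS, 1 - _FREQ_EPS)  # (N, M)
        ll = admixture_loglik(g, pi)
        if track_loglik:
            loglik_path.append(ll)
        e = _expected_genotypes(g, pi)  # (N, M) expected derived count
        # expected ancestry-specific allele counts
        der = e / pi  # (N, M)
        anc = (2.0 - e) / (1.0 - pi)
        # Q update: average attributed allele count over 2M gametes
        q_new = q * (der @ a.T + anc @ (1.0 - a).T) / (2.0 * m)
        q_new = np.clip(q_new, 1e-12, None)
        q_new /= q_new.sum(axis=1, keepdims=True)
        # A update: derived fraction of alleles attributed to ancestry k
        num = a * (q.T @ der)
        den = num + (1.0 - a) * (q.T @ anc)
        a_new = np.where(den > 0, num / den, a)
        a_new = np.clip(a_new, _FREQ_EPS, 1 - _FREQ_EPS)
        q, a = q_new, a_new
        if it > 1 and ll - prev_ll < tol:
            prev_ll = ll
            break
        prev_ll = ll
    return AdmixtureResult(
        Q=q,
        A=a,
        loglik=prev_ll,
        seed=seed,
        iterations=iterations,
        loglik_path=np.array(loglik_path) if track_loglik else None,
    )


def align_q(q_ref: np.ndarray, q: np.ndarray) -> np.ndarray:
    """Permute ancestry labels of ``q`` to best match ``q_ref`` (Hungarian)."""
    cost = -(q_ref.T @ q)
    _, col = linear_sum_assignment(cost)
    return q[:, col]


def compare_k_runs(results: dict[int, list[AdmixtureResult]]) -> pd.DataFrame:
    """Per-K summary: best log-likelihood, dispersion, Q stability.

    ``results`` maps K to the runs performed with different seeds.  Mean
    pairwise Q agreement is computed after greedy label alignment as
    1 - mean |Q_a - Q_b|.  The table ranks Ks by best log-likelihood but
    makes no automatic claim about the true K.
    """
    rows = []
    for k, runs in sorted(results.items()):
        if not runs:
            raise ValueError(f"no runs for K={k}")
        lls = np.array([r.loglik for r in runs])
        agreements = []
        for i in range(len(runs)):
            for j in range(i + 1, len(runs)):
                qa = runs[i].Q
                qb = align_q(qa, runs[j].Q)
                agreements.append(1.0 - float(np.abs(qa - qb).mean()))
        rows.append(
            {
                "K": k,
                "n_runs": len(runs),
                "best_loglik": float(lls.max()),
                "loglik_sd": float(lls.std()),
                "loglik_range": float(lls.max() - lls.min()),
                "mean_q_agreement": float(np.mean(agreements)) if agreements else 1.0,
            }
        )
    table = pd.DataFrame(rows).sort_values("best_loglik", ascending=False)
    table["rank"] = np.arange(1, len(table) + 1)
    return table.sort_values("K").reset_index(drop=True)


# ---------------------------------------------------------------------------
# residual-correlation model evaluation
# ---------------------------------------------------------------------------

def residual_correlation(
    gl: GLMatrix,
    result: AdmixtureResult,
    freqs: SiteFrequencies | None = None,
    groups: dict[str, str] | None = None,
    min_sites: int = 20,
) -> ResidualCorrelation:
    """Pairwise correlation of per-individual model residuals.

    Residual at (i, s): E[g | GL, pi_is] - 2 pi_is under the fitted
    admixture model.  Correlations near zero indicate a good fit; positive
    within-group blocks reveal structure (or family sampling) the model did
    not absorb.  ``groups`` maps individual id to a group label for
    block-mean summaries.  Missing sites are excluded pairwise; individuals
    with fewer than ``min_sites`` informative sites are dropped.
    """
    if freqs is None:
        freqs = estimate_allele_frequencies(gl)
    keep = freqs.polymorphic
    g = gl.gl[:, keep]
    pi = np.clip(result.Q @ result.A, _FREQ_EPS, 1 - _FREQ_EPS)
    if pi.shape != (gl.n_individuals, int(keep.sum())):
        raise ValueError("admixture result was not fitted on this GLMatrix")
    e = _expected_genotypes(g, pi)
    resid = e - 2.0 * pi  # (N, M)
    missing = (
        np.isclose(g[:, :, 0], g[:, :, 1]) & np.isclose(g[:, :, 1], g[:, :, 2])
    )
    informative = (~missing).sum(axis=1)
    ok = informative >= min_sites
    if not ok.all():
        warnings.warn(
            f"excluding {int((~ok).sum())} individuals with < {min_sites} informative sites"
        )
    ids = [gl.ids[i] for i in np.flatnonzero(ok)]
    resid = resid[ok]
    missing = missing[ok]

    n = resid.shape[0]
    corr = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            shared = ~missing[i] & ~missing[j]
            if shared.sum() < min_sites:
                corr[i, j] = corr[j, i] = np.nan
                continue
            a, b = resid[i, shared], resid[j, shared]
            sa, sb = a.std(), b.std()
            if sa == 0 or sb == 0:
                corr[i, j] = corr[j, i] = np.nan
                continue
            corr[i, j] = corr[j, i] = float(np.corrcoef(a, b)[0, 1])

    block = None
    if groups is not None:
        labels = sorted(set(groups.get(i) for i in ids))
        recs = []
        for gi, ga in enumerate(labels):
            for gb in labels[gi:]:
                vals = [
                    corr[i, j]
                    for i in range(n)
                    for j in range(i + 1, n)
                    if {groups.get(ids[i]), groups.get(ids[j])} == ({ga, gb} if ga != gb else {ga})
                ]
                vals = [v for v in vals if np.isfinite(v)]
                recs.append(
                    {
                        "group_a": ga,
                        "group_b": gb,
                        "n_pairs": len(vals),
                        "mean_corr": float(np.mean(vals)) if vals else np.nan,
                    }
                )
        block = pd.DataFrame(recs)
    return ResidualCorrelation(ids=ids, correlation=corr, block_means=block)
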