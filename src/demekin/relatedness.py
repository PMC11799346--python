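"""Pairwise relatedness from genotype likelihoods.

Two complementary families of estimators are implemented:

* A maximum-likelihood estimate of the nine condensed Jacquard identity-state
  probabilities (Delta_1..Delta_9) of a dyad, fitted by EM directly on the
  genotype likelihoods so genotyping uncertainty propagates into the
  estimate.  The outbred Cotterman coefficients are k2 = Delta_7,
  k1 = Delta_8, k0 = Delta_9; the inbred states Delta_1..Delta_6 absorb the
  shortfall of k0+k1+k2 from 1 observed in inbred dyads.  The kinship
  coefficient theta, the individual inbreeding coefficients F_x and F_y and
  the Hedrick-Lacy relatedness r_xy (bounded by 1 even under inbreeding)
  are closed forms in the Deltas.

* Allele-frequency-free identity-by-state ratio statistics R0, R1 and
  KING-robust kinship, formed from expected joint genotype-combination
  counts.  For an outbred parent-offspring dyad without genotyping error
  these have the analytic values R0 = 0, R1 = 0.5 and KING = 0.25 at every
  allele frequency, which anchors the calibrated parent-offspring decision
  rule: a candidate dyad is called parent-offspring only when every metric
  falls inside the range observed across known parent-offspring pairs.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from demekin.genio import GLMatrix, SiteFrequencies, estimate_allele_frequencies, hwe_priors

METRICS = ("r_xy", "k0", "k1", "k2", "theta", "R0", "R1", "KING")

_OUTBRED_STATES = (6, 7, 8)  # zero-based indices of Delta_7, Delta_8, Delta_9


@dataclass
class JacquardEstimate:
    """EM estimate of the nine condensed identity-state probabilities."""

    delta: np.ndarray  # (9,)
    loglik: float
    iterations: int
    n_sites: int
    reliable: bool = True

    def __post_init__(self) -> None:
        self.delta = np.asarray(self.delta, dtype=float)
        if self.delta.shape != (9,):
            raise ValueError("delta must have nine entries")
        if np.any(self.delta < -1e-12) or abs(self.delta.sum() - 1.0) > 1e-8:
            raise ValueError("delta must lie on the 9-simplex")


@dataclass
class PairRelatedness:
    """All pairwise relatedness quantities for one dyad."""

    id_x: str
    id_y: str
    delta: np.ndarray
    k0: float
    k1: float
    k2: float
    theta: float
    F_x: float
    F_y: float
    r_xy: float
    R0: float
    R1: float
    KING: float
    n_sites: int
    loglik: float = float("nan")
    reliable: bool = True

    def as_dict(self) -> dict:
        d = {
            "id_x": self.id_x,
            "id_y": self.id_y,
            **{f"D{i + 1}": self.delta[i] for i in range(9)},
            "k0": self.k0,
            "k1": self.k1,
            "k2": self.k2,
            "theta": self.theta,
            "F_x": self.F_x,
            "F_y": self.F_y,
            "r_xy": self.r_xy,
            "R0": self.R0,
            "R1": self.R1,
            "KING": self.KING,
            "n_sites": self.n_sites,
            "loglik": self.loglik,
            "reliable": self.reliable,
        }
        return d


@dataclass
class PORanges:
    """Per-metric min/max over known parent-offspring dyads."""

    ranges: dict[str, tuple[float, float]]

    def __post_init__(self) -> None:
        for m, (lo, hi) in self.ranges.items():
            if lo > hi:
                raise ValueError(f"range for {m} has min > max")


# ---------------------------------------------------------------------------
# condensed Jacquard joint-genotype tables
# ---------------------------------------------------------------------------

def jacquard_tables(freq: np.ndarray) -> np.ndarray:
    """P(g_x, g_y | identity state, f) for the nine condensed states.

    Returns an array of shape (9, M, 3, 3) over derived-allele dosages.
    Rows follow the standard condensed ordering: state 1 = all four alleles
    identical by descent ... state 9 = no IBD.
    """
    p = np.asarray(freq, dtype=float)
    q = 1.0 - p
    m = p.shape[0]
    hw = hwe_priors(p)  # (M, 3)
    t = np.zeros((9, m, 3, 3))
    # S1: x and y are the same fully inbred individual
    t[0, :, 0, 0] = q
    t[0, :, 2, 2] = p
    # S2: both inbred, no sharing across
    t[1, :, 0, 0] = q * q
    t[1, :, 0, 2] = q * p
    t[1, :, 2, 0] = p * q
    t[1, :, 2, 2] = p * p
    # S3: x inbred, one of y's alleles IBD with x
    t[2, :, 0, 0] = q * q
    t[2, :, 0, 1] = q * p
    t[2, :, 2, 1] = p * q
    t[2, :, 2, 2] = p * p
    # S4: x inbred, y outbred unrelated
    t[3, :, 0, :] = q[:, None] * hw
    t[3, :, 2, :] = p[:, None] * hw
    # S5, S6: mirror images of S3, S4
    t[4] = np.transpose(t[2], (0, 2, 1))
    t[5] = np.transpose(t[3], (0, 2, 1))
    # S7: two IBD pairs across (outbred k2)
    t[6, :, 0, 0] = q * q
    t[6, :, 1, 1] = 2 * p * q
    t[6, :, 2, 2] = p * p
    # S8: one IBD pair across (outbred k1)
    t[7, :, 0, 0] = q**3
    t[7, :, 0, 1] = q * q * p
    t[7, :, 1, 0] = q * q * p
    t[7, :, 1, 1] = p * q
    t[7, :, 1, 2] = p * p * q
    t[7, :, 2, 1] = p * p * q
    t[7, :, 2, 2] = p**3
    # S9: no IBD (outbred k0)
    t[8] = hw[:, :, None] * hw[:, None, :]
    return t


def _informative_sites(
    gl_x: np.ndarray, gl_y: np.ndarray, freqs: SiteFrequencies
) -> np.ndarray:
    miss_x = np.isclose(gl_x[:, 0], gl_x[:, 1]) & np.isclose(gl_x[:, 1], gl_x[:, 2])
    miss_y = np.isclose(gl_y[:, 0], gl_y[:, 1]) & np.isclose(gl_y[:, 1], gl_y[:, 2])
    with np.errstate(invalid="ignore"):
        seg = freqs.defined & (freqs.freq > 0) & (freqs.freq < 1) & freqs.polymorphic
    return seg & ~miss_x & ~miss_y


def jacquard_em(
    gl_x: np.ndarray,
    gl_y: np.ndarray,
    freqs: SiteFrequencies,
    mode: str = "jacquard9",
    tol: float = 1e-6,
    max_iter: int = 5000,
    n_restarts: int = 3,
    min_sites: int = 20,
    seed: int = 0,
) -> JacquardEstimate:
    """Fit the condensed-Jacquard mixture to one dyad by EM.

    ``gl_x`` and ``gl_y`` are (M, 3) likelihood arrays for the two
    individuals.  The per-site mixture likelihood is
    sum_m Delta_m * sum_{gx,gy} GL_x(gx) GL_y(gy) P(gx,gy | m, f_s);
    monomorphic and missing sites carry no information and are skipped.
    EM starts from the uniform point on the simplex plus ``n_restarts``
    random restarts; the best log-likelihood is kept.  ``mode='k3'``
    restricts to the three outbred states (k2, k1, k0).
    """
    keep = _informative_sites(gl_x, gl_y, freqs)
    n_sites = int(keep.sum())
    f = freqs.freq[keep]
    if n_sites == 0:
        if not (freqs.defined & (freqs.freq > 0) & (freqs.freq < 1)).any():
            raise ValueError("degenerate frequencies: every site fixed")
        raise ValueError("no shared informative sites for this dyad")

    tables = jacquard_tables(f)  # (9, M, 3, 3)
    # per-site per-state likelihood: contract genotype axes with the GLs
    lx = gl_x[keep]
    ly = gl_y[keep]
    site_state = np.einsum("sa,sb,msab->sm", lx, ly, tables)  # (M, 9)

    if mode == "k3":
        active = list(_OUTBRED_STATES)
    elif mode == "jacquard9":
        active = list(range(9))
    else:
        raise ValueError(f"unknown mode {mode!r}")
    ls = site_state[:, active]
    k = len(active)

    rng = np.random.default_rng(seed)
    starts = [np.full(k, 1.0 / k)]
    for _ in range(n_restarts):
        starts.append(rng.dirichlet(np.ones(k)))

    best_delta, best_ll, best_iters = None, -np.inf, 0
    for start in starts:
        delta = start.copy()
        prev_ll = -np.inf
        for it in range(1, max_iter + 1):
            mix = ls @ delta  # (M,)
            mix = np.maximum(mix, 1e-300)
            ll = float(np.log(mix).sum())
            resp = ls * delta / mix[:, None]
            delta = resp.mean(axis=0)
            delta = np.maximum(delta, 0.0)
            delta /= delta.sum()
            if ll - prev_ll < tol and it > 1:
                prev_ll = ll
                break
            prev_ll = ll
        if prev_ll > best_ll:
            best_ll, best_delta, best_iters = prev_ll, delta, it

    full = np.zeros(9)
    full[active] = best_delta
    return JacquardEstimate(
        delta=full,
        loglik=best_ll,
        iterations=best_iters,
        n_sites=n_sites,
        reliable=n_sites >= min_sites,
    )


def summarize_relatedness(
    est: JacquardEstimate, id_x: str = "x", id_y: str = "y"
) -> PairRelatedness:
    """Closed-form kinship quantities from the Delta estimate.

    theta = D1 + (D3 + D5 + D7)/2 + D8/4;  F_x = D1+D2+D3+D4;
    F_y = D1+D2+D5+D6;  r_xy = 2 theta / (1 + (F_x + F_y)/2), which is
    bounded by 1 even for inbred dyads.
    """
    d = est.delta
    theta = d[0] + 0.5 * (d[2] + d[4] + d[6]) + 0.25 * d[7]
    f_x = d[0] + d[1] + d[2] + d[3]
    f_y = d[0] + d[1] + d[4] + d[5]
    r_xy = 2.0 * theta / (1.0 + 0.5 * (f_x + f_y))
    return PairRelatedness(
        id_x=id_x,
        id_y=id_y,
        delta=d.copy(),
        k0=d[8],
        k1=d[7],
        k2=d[6],
        theta=theta,
        F_x=f_x,
        F_y=f_y,
        r_xy=r_xy,
        R0=float("nan"),
        R1=float("nan"),
        KING=float("nan"),
        n_sites=est.n_sites,
        loglik=est.loglik,
        reliable=est.reliable,
    )


# ---------------------------------------------------------------------------
# identity-by-state ratio statistics
# ---------------------------------------------------------------------------

def _genotype_weights(
    gl: np.ndarray, freq: np.ndarray, call: bool
) -> np.ndarray:
    """Per-site genotype weights: posterior probabilities or hard calls."""
    if call:
        w = np.zeros_like(gl)
        w[np.arange(gl.shape[0]), gl.argmax(axis=1)] = 1.0
        return w
    post = gl * hwe_priors(freq)
    norm = post.sum(axis=1, keepdims=True)
    norm[norm == 0] = 1.0
    return post / norm


def ibs_stats(
    gl_x: np.ndarray,
    gl_y: np.ndarray,
    freqs: SiteFrequencies,
    call: bool = False,
) -> tuple[float, float, float]:
    """R0, R1 and KING-robust kinship from joint genotype-combination counts.

    n_ab = sum_s w_x(s, a) w_y(s, b) over the shared informative sites, with
    w the per-individual genotype weights (posterior by default, hard calls
    with ``call=True``).  Then

        R0   = (n02 + n20) / n11
        R1   = n11 / (n01 + n10 + n12 + n21 + n02 + n20)
        KING = (n11 - 2 (n02 + n20)) / (h_x + h_y),

    where h_x = sum_s w_x(s, 1).  For error-free outbred parent-offspring
    dyads these give R0 = 0, E[R1] = 0.5 and E[KING] = 0.25 at every allele
    frequency.  Undefined ratios (zero denominator) return NaN.
    """
    keep = _informative_sites(gl_x, gl_y, freqs)
    if not keep.any():
        raise ValueError("no shared informative sites for this dyad")
    f = freqs.freq[keep]
    wx = _genotype_weights(gl_x[keep], f, call)
    wy = _genotype_weights(gl_y[keep], f, call)
    n = wx.T @ wy  # (3, 3) expected combination counts
    opposing = n[0, 2] + n[2, 0]
    n11 = n[1, 1]
    discordant = n[0, 1] + n[1, 0] + n[1, 2] + n[2, 1] + opposing
    h_x = wx[:, 1].sum()
    h_y = wy[:, 1].sum()
    r0 = opposing / n11 if n11 > 0 else float("nan")
    r1 = n11 / discordant if discordant > 0 else float("nan")
    king = (n11 - 2.0 * opposing) / (h_x + h_y) if h_x + h_y > 0 else float("nan")
    return float(r0), float(r1), float(king)


def ibs_counts_bruteforce(g_x: np.ndarray, g_y: np.ndarray) -> np.ndarray:
    """Direct 3x3 genotype-combination counting from hard genotype vectors.

    Independent oracle for :func:`ibs_stats` on one-hot likelihoods.
    """
    n = np.zeros((3, 3))
    for a, b in zip(np.asarray(g_x).ravel(), np.asarray(g_y).ravel()):
        n[int(a), int(b)] += 1
    return n


# ---------------------------------------------------------------------------
# cohort-level driver
# ---------------------------------------------------------------------------

def pairwise_relatedness(
    gl: GLMatrix,
    freqs: SiteFrequencies | None = None,
    mode: str = "jacquard9",
    call: bool = False,
    pairs: list[tuple[str, str]] | None = None,
    **em_kwargs,
) -> pd.DataFrame:
    """All-dyad relatedness table (one row per pair, columns as PairRelatedness)."""
    if freqs is None:
        freqs = estimate_allele_frequencies(gl)
    if pairs is None:
        pairs = list(itertools.combinations(gl.ids, 2))
    idx = {name: i for i, name in enumerate(gl.ids)}
    rows = []
    for a, b in pairs:
        gx, gy = gl.gl[idx[a]], gl.gl[idx[b]]
        est = jacquard_em(gx, gy, freqs, mode=mode, **em_kwargs)
        pr = summarize_relatedness(est, a, b)
        pr.R0, pr.R1, pr.KING = ibs_stats(gx, gy, freqs, call=call)
        rows.append(pr.as_dict())
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# calibrated parent-offspring inference
# ---------------------------------------------------------------------------

def calibrate_po_ranges(known_pairs: pd.DataFrame) -> PORanges:
    """Empirical per-metric min/max over known parent-offspring dyads."""
    if len(known_pairs) < 2:
        raise ValueError("need at least two known parent-offspring pairs")
    ranges = {}
    for m in METRICS:
        vals = known_pairs[m].to_numpy(dtype=float)
        if np.isnan(vals).any():
            raise ValueError(f"known pair has undefined metric {m}")
        ranges[m] = (float(vals.min()), float(vals.max()))
    return PORanges(ranges)


def classify_po(candidates: pd.DataFrame, ranges: PORanges) -> pd.DataFrame:
    """Conservative parent-offspring calls: inside every calibrated range.

    A dyad is labelled parent-offspring iff every metric lies within the
    closed interval observed over known pairs; a dyad with any undefined
    metric is rejected and flagged, never passed.  The first failing metric
    is reported as the rejection reason.
    """
    out = candidates.copy()
    labels, reasons = [], []
    for _, row in candidates.iterrows():
        verdict, reason = True, ""
        for m in METRICS:
            v = float(row[m])
            lo, hi = ranges.ranges[m]
            if np.isnan(v):
                verdict, reason = False, f"undefined:{m}"
                break
            if not (lo <= v <= hi):
                verdict, reason = False, m
                break
        labels.append(verdict)
        reasons.append(reason)
    out["is_po"] = labels
    out["reject_reason"] = reasons
    return out


def flag_r1_outliers(
    all_pairs: pd.DataFrame, mad_mult: float = 2.0, frac: float = 0.9
) -> list[str]:
    """Individuals with anomalously high R1 against almost all partners.

    Mirrors the removal of samples showing elevated background relatedness
    to nearly everyone (a signature of cross-contamination): an individual
    is flagged when its R1 exceeds the cohort per-pair median by
    ``mad_mult`` median absolute deviations against at least ``frac`` of
    its partners.
    """
    r1 = all_pairs["R1"].to_numpy(dtype=float)
    med = np.nanmedian(r1)
    mad = np.nanmedian(np.abs(r1 - med))
    cut = med + mad_mult * mad
    flagged = []
    ids = sorted(set(all_pairs["id_x"]) | set(all_pairs["id_y"]))
    for ind in ids:
        mask = (all_pairs["id_x"] == ind) | (all_pairs["id_y"] == ind)
        vals = all_pairs.loc[mask, "R1"].to_numpy(dtype=float)
        vals = vals[~np.isnan(vals)]
        if vals.size and (vals > cut).mean() >= frac:
            flagged.append(ind)
    return flagged


# ---------------------------------------------------------------------------
# background-relatedness subsetting evaluation
# ---------------------------------------------------------------------------

def background_subset_report(
    gl: GLMatrix,
    groups: dict[str, list[str]],
    mode: str = "jacquard9",
    **em_kwargs,
) -> pd.DataFrame:
    """Within-group relatedness under pooled vs group-only reference panels.

    For each group, r_xy over within-group dyads is computed twice: once
    with allele frequencies and polymorphic sites estimated from the pooled
    sample, once from the group alone.  Low-diversity groups segregate at
    fewer sites on their own panel, and pooled background frequencies
    inflate their apparent relatedness; the report pairs the two summaries
    so that effect can be quantified.
    """
    if len(groups) < 1:
        raise ValueError("need at least one group")
    pooled_freqs = estimate_allele_frequencies(gl)
    idx = {name: i for i, name in enumerate(gl.ids)}
    rows = []
    for gname, members in groups.items():
        if len(members) < 2:
            warnings.warn(f"group {gname!r} has fewer than two members; skipped")
            continue
        sub = gl.subset([idx[m] for m in members])
        group_freqs = estimate_allele_frequencies(sub)
        pairs = list(itertools.combinations(members, 2))
        pooled_tab = pairwise_relatedness(
            gl, pooled_freqs, mode=mode, pairs=pairs, **em_kwargs
        )
        within_tab = pairwise_relatedness(
            sub, group_freqs, mode=mode, pairs=pairs, **em_kwargs
        )
        rows.append(
            {
                "group": gname,
                "n_members": len(members),
                "n_dyads": len(pairs),
                "n_polymorphic_pooled": int(pooled_freqs.polymorphic.sum()),
                "n_polymorphic_within": int(group_freqs.polymorphic.sum()),
                "mean_rxy_pooled": float(pooled_tab["r_xy"].mean()),
                "mean_rxy_within": float(within_tab["r_xy"].mean()),
                "median_rxy_pooled": float(pooled_tab["r_xy"].median()),
                "median_rxy_within": float(within_tab["r_xy"].median()),
            }
        )
    return pd.DataFrame(rows)
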